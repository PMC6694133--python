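"""Default parameter sets for the reduced two-stage models.

Units are mV, ms, nA, uS and nF throughout, so that ``I = g * V`` yields nA
and ``C dV/dt`` with C in nF is consistent (nF * mV / ms = nA).

The numeric values below are calibration constants for the reduced models.
They were fixed once so that the reference fast-spiking (FS) basket cell
fires in the gamma band (30-100 Hz) when 60 dispersed synapses are driven
by 50 Hz Poisson trains, fires at ~3 Hz under the sparse in-vivo-like
background protocol (32 excitatory + 8 inhibitory synapses), and so that
the control network encodes a memory engram spanning 25-30% of the
excitatory population.  See docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DendriticSubunitParams",
    "SomaParams",
    "BAPParams",
    "NeuronParams",
    "fs_reference_params",
    "excitatory_params",
    "interneuron_params",
]

SUBLINEAR_EXPONENT = 0.7  # fixed power-law exponent of the sublinear transfer


@dataclass(frozen=True)
class DendriticSubunitParams:
    """Passive and nonlinear properties shared by a cell's dendritic subunits.

    tau_b : membrane time constant of the subunit (ms)
    e_syn : synaptic depolarization scale (mV); one presynaptic spike of
        weight w increments the subunit voltage by w * e_syn / tau_b
    theta_dspike : dendritic spike / sigmoid midpoint voltage (mV)
    sigmoid_slope : logistic slope of the supralinear gain (mV)
    spike_amp : amplitude of the supralinear sigmoidal component (mV);
        the dendritic-spike contribution saturates at this value, as the
        local spike is an all-or-none regenerative event
    passive_gain : linear pass-through of a supralinear subunit's
        depolarization underneath the spike component (1.0 = full EPSP
        reaches the soma; < 1 models attenuated passive transfer)
    plateau_amp, plateau_dur : NMDA plateau depolarization (mV) and duration
        (ms) triggered when the subunit voltage crosses theta_dspike;
        zero disables plateaus (interneurons)
    """

    tau_b: float = 10.0
    e_syn: float = 15.0
    theta_dspike: float = 15.0
    sigmoid_slope: float = 3.0
    spike_amp: float = 12.0
    passive_gain: float = 0.3
    plateau_amp: float = 0.0
    plateau_dur: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_b <= 0:
            raise ValueError("tau_b must be positive")


@dataclass(frozen=True)
class SomaParams:
    """Adaptive integrate-and-fire soma.

    c : capacitance (nF); g_l : leak conductance (uS); e_l : rest (mV, 0 by
    convention); e_k : AHP reversal (mV); tau_ahp / a_ahp : adaptation time
    constant (ms) and quantal conductance increment scale (uS*ms; each spike
    adds a_ahp / tau_ahp to g_ahp); theta_soma : spike threshold (mV);
    g_syn : dendro-somatic coupling (uS); refractory : absolute refractory
    period (ms).
    """

    c: float = 0.2
    g_l: float = 0.01
    e_l: float = 0.0
    e_k: float = -15.0
    tau_ahp: float = 80.0
    a_ahp: float = 0.2
    theta_soma: float = 15.0
    g_syn: float = 0.013
    refractory: float = 2.0

    def __post_init__(self) -> None:
        if self.g_l <= 0 or self.tau_ahp <= 0 or self.c <= 0:
            raise ValueError("c, g_l and tau_ahp must be positive")
        if self.theta_soma <= self.e_l:
            raise ValueError("theta_soma must exceed e_l")


@dataclass(frozen=True)
class BAPParams:
    """Backpropagating action potential: V_bAP(t) = e_bap * exp(-t/tau_bap)."""

    e_bap: float = 5.0
    tau_bap: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_bap <= 0:
            raise ValueError("tau_bap must be positive")


@dataclass(frozen=True)
class NeuronParams:
    dend: DendriticSubunitParams = field(default_factory=DendriticSubunitParams)
    soma: SomaParams = field(default_factory=SomaParams)
    bap: BAPParams = field(default_factory=BAPParams)


def fs_reference_params() -> NeuronParams:
    """Reference FS basket cell: bimodal dendrites, weak backpropagation."""
    return NeuronParams()


def excitatory_params() -> NeuronParams:
    """Two-stage excitatory (pyramidal-like) neuron for the network model.

    Supralinear dendrites with NMDA plateaus, stronger backpropagation (so
    that plasticity-driving calcium reaches the 30 mV sigmoid midpoint when
    plateau and bAP coincide) and slower adaptation than FS cells.
    """
    return NeuronParams(
        dend=DendriticSubunitParams(
            tau_b=15.0,
            e_syn=15.0,
            theta_dspike=18.0,
            sigmoid_slope=3.0,
            spike_amp=0.0,
            passive_gain=1.0,
            plateau_amp=20.0,
            plateau_dur=40.0,
        ),
        soma=SomaParams(
            c=0.3,
            g_l=0.01,
            e_k=-15.0,
            tau_ahp=120.0,
            a_ahp=1.2,
            theta_soma=15.0,
            g_syn=0.006,
            refractory=2.0,
        ),
        bap=BAPParams(e_bap=15.0, tau_bap=10.0),
    )


def interneuron_params() -> NeuronParams:
    """Network interneuron (FS BC or SOM+): fast, strongly adapting soma."""
    return NeuronParams(
        dend=DendriticSubunitParams(
            tau_b=10.0,
            e_syn=15.0,
            theta_dspike=5.0,
            sigmoid_slope=2.0,
            spike_amp=15.0,
            passive_gain=0.3,
        ),
        soma=SomaParams(
            c=0.15,
            g_l=0.01,
            e_k=-15.0,
            tau_ahp=50.0,
            a_ahp=0.3,
            theta_soma=15.0,
            g_syn=0.008,
            refractory=2.0,
        ),
        bap=BAPParams(e_bap=5.0, tau_bap=5.0),
    )
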