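"""Reduced two-stage neuron: dendritic subunits + adaptive I&F soma.

Each dendritic subunit is a leaky integrator of its own synaptic input,

    tau_b dV_b/dt = sum_j w_j E_syn delta(t - t_ij) - V_b,

so a presynaptic spike of weight w increments V_b by w*E_syn/tau_b and V_b
decays exponentially between spikes.  The subunit voltage (plus the
backpropagating-AP component V_bAP) is passed through a static
nonlinearity — identity, a saturating power law V**0.7, or a sigmoidal
dendritic-spike gain — and the transformed depolarizations are summed at
an adaptive integrate-and-fire soma:

    C dV/dt      = -g_L (V - E_L) - g_AHP (V - E_K) + I_syn(t)
    tau_AHP dg_AHP/dt = a_AHP delta(t - t_spike) - g_AHP
    I_syn(t)     = g_syn * sum_n f(V_b,n + V_bAP) - IPSC(t)

A somatic spike resets V to E_L, increments the adaptation conductance,
enforces an absolute refractory period, and launches an exponentially
decaying backpropagating depolarization shared by all subunits.

All state variables are advanced with per-variable exponential-Euler
updates, which makes the homogeneous decays exact at any dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_for
from .integration import IntegrationMode
from .params import (
    SUBLINEAR_EXPONENT,
    BAPParams,
    DendriticSubunitParams,
    NeuronParams,
    SomaParams,
)

__all__ = [
    "TwoStageNeuron",
    "SimResult",
    "dendrite_step",
    "dendrite_output",
    "soma_step",
    "bap_component",
    "gap_junction_current",
    "mode_codes",
]

_MODE_CODE = {
    IntegrationMode.LINEAR: 0,
    IntegrationMode.SUPRALINEAR: 1,
    IntegrationMode.SUBLINEAR: 2,
}


def mode_codes(modes) -> np.ndarray:
    """Integer codes (0 linear, 1 supralinear, 2 sublinear) for vectorization."""
    return np.array([_MODE_CODE[IntegrationMode(m)] for m in modes], dtype=np.int8)


def dendrite_step(v_b, params: DendriticSubunitParams, spike_weights, dt: float):
    """One exponential-Euler step of the subunit voltage.

    `spike_weights` holds the weights w_j of the presynaptic spikes that
    arrived during this step (empty for none); each contributes a jump of
    w_j * e_syn / tau_b.  Weights must be nonnegative: dendritic synapses
    in this model are excitatory only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = np.asarray(spike_weights, dtype=float)
    if w.size and np.any(w < 0):
        raise ValueError("dendritic synaptic weights must be nonnegative")
    return v_b * np.exp(-dt / params.tau_b) + w.sum() * params.e_syn / params.tau_b


def dendrite_output(v_b, codes, params: DendriticSubunitParams, plateau_active=None):
    """Static subunit nonlinearity applied to the depolarization `v_b`.

    linear -> identity; sublinear -> clip(v_b, 0)**0.7; supralinear ->
    a saturating logistic dendritic-spike component of amplitude
    `spike_amp` centred at `theta_dspike`, on top of an attenuated passive
    pass-through `passive_gain * v_b` (the local spike is all-or-none, so
    its contribution saturates).  `plateau_active` (boolean, same shape)
    adds the NMDA plateau depolarization where set.
    """
    v = np.asarray(v_b, dtype=float)
    codes = np.asarray(codes)
    out = v.copy()
    sub = codes == 2
    if np.any(sub):
        out[sub] = np.clip(v[sub], 0.0, None) ** SUBLINEAR_EXPONENT
    supra = codes == 1
    if np.any(supra):
        gain = params.spike_amp / (
            1.0 + np.exp(-(v[supra] - params.theta_dspike) / params.sigmoid_slope)
        )
        out[supra] = params.passive_gain * v[supra] + gain
    if plateau_active is not None and params.plateau_amp > 0:
        out = out + params.plateau_amp * np.asarray(plateau_active, dtype=float)
    return out


def soma_step(v, g_ahp, i_syn, params: SomaParams, dt: float, refractory_left: float = 0.0):
    """One exponential-Euler soma step.

    Returns ``(v, g_ahp, spiked, refractory_left)``.  On a spike the voltage
    resets to E_L, g_AHP jumps by a_AHP / tau_AHP and the refractory clock
    restarts.  Scalar version used by tests and single-cell examples; the
    batch simulator inlines the same arithmetic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_ahp = g_ahp * np.exp(-dt / params.tau_ahp)
    spiked = False
    if refractory_left > 0:
        refractory_left = max(0.0, refractory_left - dt)
        v = params.e_l
    else:
        g_tot = params.g_l + g_ahp
        v_inf = (params.g_l * params.e_l + g_ahp * params.e_k + i_syn) / g_tot
        v = v_inf + (v - v_inf) * np.exp(-g_tot * dt / params.c)
        if v >= params.theta_soma:
            spiked = True
            v = params.e_l
            g_ahp += params.a_ahp / params.tau_ahp
            refractory_left = params.refractory
    return v, g_ahp, spiked, refractory_left


def bap_component(t_since_spike, params: BAPParams):
    """Backpropagating depolarization E_bAP * exp(-t/tau_bAP), t >= 0 (mV)."""
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since spike must be nonnegative")
    return params.e_bap * np.exp(-t / params.tau_bap)


def gap_junction_current(g_gap: float, v_post, v_pre):
    """Gap-junction current I_GJ = g_gap * (v_post - v_pre).

    With g_gap in uS and voltages in mV the current is in nA; positive when
    the postsynaptic compartment is depolarized relative to the presynaptic
    one. Default conductance in the field is 0.4 uS per junction.
    """
    if g_gap < 0:
        raise ValueError("gap junction conductance must be nonnegative")
    return g_gap * (np.asarray(v_post, dtype=float) - np.asarray(v_pre, dtype=float))


@dataclass
class SimResult:
    """Outcome of a (batched) single-neuron simulation."""

    rates: np.ndarray  # Hz, shape (batch,)
    spike_counts: np.ndarray  # shape (batch,)
    duration: float  # ms
    spike_times: list | None = None  # per batch row, only when recorded

    @property
    def rate(self) -> float:
        return float(self.rates[0])


class TwoStageNeuron:
    """A reduced neuron: `n_dendrites` subunits with per-subunit modes.

    Parameters
    ----------
    modes : sequence of IntegrationMode (or strings), one per subunit.
    params : NeuronParams bundle (dendritic, somatic, bAP constants).
    """

    def __init__(self, modes, params: NeuronParams | None = None):
        self.params = params or NeuronParams()
        self.codes = mode_codes(modes)
        self.modes = [IntegrationMode(m) for m in modes]
        if self.codes.size < 1:
            raise ValueError("neuron needs at least one dendritic subunit")

    @property
    def n_dendrites(self) -> int:
        return int(self.codes.size)

    # -- simulation ---------------------------------------------------------

    def simulate(
        self,
        counts,
        rate_hz: float = 50.0,
        duration: float = 1000.0,
        dt: float = 0.1,
        seed: int = 0,
        w: float = 1.0,
        drive=None,
        inh_rate_hz: float = 0.0,
        n_inh: int = 0,
        w_inh: float = 0.0,
        tau_ipsc: float = 10.0,
        record_spikes: bool = False,
    ) -> SimResult:
        """Drive the neuron and return firing rates.

        `counts` is the per-dendrite synapse-count vector (shape ``(D,)``)
        or a batch of them (``(B, D)``); each synapse receives an
        independent homogeneous Poisson train at `rate_hz`.  Identical unit
        weights make the superposed per-dendrite drive Poisson with rate
        ``count * rate_hz``, which is what the simulator samples.

        `drive` optionally replaces the Poisson sampling with an explicit
        per-step spike-count matrix of shape ``(n_steps, D)`` (single batch
        row only) — used for controlled-input experiments.

        `n_inh`/`inh_rate_hz`/`w_inh` attach perisomatic inhibitory
        background synapses delivering exponentially decaying IPSC pulses
        (time constant `tau_ipsc` ms, amplitude `w_inh` nA each).
        """
        p = self.params
        if dt <= 0 or dt > min(p.dend.tau_b, p.soma.tau_ahp) / 10.0:
            raise ValueError(
                f"dt={dt} unstable: use dt <= min(tau_b, tau_AHP)/10 = "
                f"{min(p.dend.tau_b, p.soma.tau_ahp) / 10.0:g} ms"
            )
        if rate_hz < 0:
            raise ValueError("rate must be nonnegative")
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        batch, n_dend = counts.shape
        if n_dend != self.n_dendrites:
            raise ValueError("counts length must equal number of dendrites")

        n_steps = int(round(duration / dt))
        rng = rng_for(seed, "neuron.simulate")
        lam = counts * (rate_hz * 1e-3) * dt  # expected spikes per dendrite per step
        lam_inh = n_inh * (inh_rate_hz * 1e-3) * dt

        decay_b = np.exp(-dt / p.dend.tau_b)
        decay_ahp = np.exp(-dt / p.soma.tau_ahp)
        decay_ipsc = np.exp(-dt / tau_ipsc)
        jump = w * p.dend.e_syn / p.dend.tau_b

        v_b = np.zeros((batch, n_dend))
        v = np.full(batch, p.soma.e_l)
        g_ahp = np.zeros(batch)
        ipsc = np.zeros(batch)
        refrac = np.zeros(batch)
        t_last = np.full(batch, np.inf)  # time since last somatic spike
        plateau_left = np.zeros((batch, n_dend))
        has_plateau = p.dend.plateau_amp > 0 and p.dend.plateau_dur > 0
        n_spikes = np.zeros(batch, dtype=int)
        spike_times: list[list[float]] | None = [[] for _ in range(batch)] if record_spikes else None

        use_drive = drive is not None
        if use_drive:
            drive = np.asarray(drive)
            if batch != 1 or drive.shape != (n_steps, n_dend):
                raise ValueError("explicit drive requires batch 1 and shape (n_steps, D)")

        for step in range(n_steps):
            spikes = drive[step][None, :] if use_drive else rng.poisson(lam)
            v_b = v_b * decay_b + spikes * jump
            t_last = t_last + dt
            v_bap = p.bap.e_bap * np.exp(-np.minimum(t_last, 1e6) / p.bap.tau_bap)
            v_eff = v_b + v_bap[:, None]
            if has_plateau:
                plateau_left = np.maximum(plateau_left - dt, 0.0)
                plateau_left[v_eff > p.dend.theta_dspike] = p.dend.plateau_dur
                active = plateau_left > 0
            else:
                active = None
            out = dendrite_output(v_eff, np.broadcast_to(self.codes, v_eff.shape), p.dend, active)
            if lam_inh > 0:
                ipsc = ipsc * decay_ipsc + rng.poisson(lam_inh, size=batch) * w_inh
            i_syn = p.soma.g_syn * out.sum(axis=1) - ipsc

            g_ahp = g_ahp * decay_ahp
            in_refrac = refrac > 0
            refrac = np.maximum(refrac - dt, 0.0)
            g_tot = p.soma.g_l + g_ahp
            v_inf = (p.soma.g_l * p.soma.e_l + g_ahp * p.soma.e_k + i_syn) / g_tot
            v = np.where(
                in_refrac, p.soma.e_l, v_inf + (v - v_inf) * np.exp(-g_tot * dt / p.soma.c)
            )
            fired = (~in_refrac) & (v >= p.soma.theta_soma)
            if np.any(fired):
                v[fired] = p.soma.e_l
                g_ahp[fired] += p.soma.a_ahp / p.soma.tau_ahp
                refrac[fired] = p.soma.refractory
                t_last[fired] = 0.0
                n_spikes[fired] += 1
                if record_spikes:
                    t_now = (step + 1) * dt
                    for b in np.flatnonzero(fired):
                        spike_times[b].append(t_now)

        rates = n_spikes / (duration * 1e-3)
        return SimResult(
            rates=rates, spike_counts=n_spikes, duration=duration, spike_times=spike_times
        )
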