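"""Synaptic tagging and capture (STC) plasticity with homeostasis.

Four processes act on the excitatory synapses of the network model:

1. **Calcium-dependent tagging.**  Each presynaptic spike admits calcium
   through an NMDA-like voltage sigmoid of the local dendritic
   depolarization; the calcium accumulated over a stimulus sets a synaptic
   tag — none (low), depotentiation (intermediate) or potentiation (high).
2. **Plasticity-related proteins (PRPs).**  Somatic PRP level jumps to 1.0
   when the neuron's total stimulus calcium crosses a threshold and decays
   exponentially afterwards; available PRP gates the consolidation of tags
   into permanent weights.
3. **Intrinsic excitability.**  Neurons that triggered PRP synthesis have
   their AHP adaptation transiently reduced for ~12 h, biasing them toward
   recruitment into subsequent memories (the substrate of memory linking).
4. **Homeostatic scaling.**  All weights of a neuron relax with a shared
   increment toward a fixed total, dw_j/dt = (1/tau_H)(1 - sum w / (w_init N)).

Interstimulus intervals (hours) are fast-forwarded with the closed-form
solutions of these slow dynamics rather than stepped at sub-ms resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Tag",
    "PlasticityParams",
    "calcium_influx",
    "update_tags",
    "prp_trigger",
    "prp_decay",
    "consolidate",
    "homeostasis_step",
    "homeostasis_forward",
    "intrinsic_excitability",
    "consolidation_integral",
]


class Tag(int, Enum):
    """Synaptic tag state."""

    NONE = 0
    DEPOTENTIATION = -1
    POTENTIATION = 1


@dataclass(frozen=True)
class PlasticityParams:
    """STC constants (calibration defaults; times in hours where noted).

    a_ca : maximal per-spike calcium influx (arbitrary units)
    tag_low, tag_high : accumulated-calcium thresholds separating
        none / depotentiation / potentiation tags
    theta_prp : total-neuron calcium threshold triggering PRP synthesis
    tau_prp_h : PRP decay time constant (hours)
    consolidation_rate_h : fraction of a tag consolidated per hour at
        PRP level 1.0
    pot_quantum, dep_quantum : weight change (in units of w_init) of a
        fully consolidated potentiation / depotentiation tag
    tau_h_h : homeostatic scaling time constant (hours; the effective
        relaxation time of the summed weight is tau_h_h * w_init)
    excitability_factor : multiplicative AHP reduction while excitability
        is elevated
    excitability_dur_h : duration of the excitability elevation (~12 h)
    """

    a_ca: float = 1.0
    tag_low: float = 4.0
    tag_high: float = 12.0
    theta_prp: float = 200.0
    tau_prp_h: float = 1.5
    consolidation_rate_h: float = 1.0
    pot_quantum: float = 2.0
    dep_quantum: float = 0.5
    tau_h_h: float = 48.0
    excitability_factor: float = 0.5
    excitability_dur_h: float = 12.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tag_low < self.tag_high):
            raise ValueError("tag thresholds must satisfy 0 <= low < high")
        if min(self.tau_prp_h, self.tau_h_h, self.consolidation_rate_h) <= 0:
            raise ValueError("time constants and rates must be positive")


def calcium_influx(v_b, v_bap, a_ca: float = 1.0):
    """Per-spike calcium influx: a_ca * sigmoid((V - 30 mV) / 5 mV).

    V = V_b + V_bAP is the subunit depolarization including the
    backpropagating component.  The sigmoid mimics the voltage dependence
    of NMDA receptors: half-maximal at 30 mV, saturating at a_ca.
    """
    if a_ca <= 0:
        raise ValueError("a_ca must be positive")
    v = np.asarray(v_b, dtype=float) + np.asarray(v_bap, dtype=float)
    return a_ca / (1.0 + np.exp(-(v - 30.0) / 5.0))


def update_tags(calcium, tag_low: float, tag_high: float):
    """Tag from accumulated stimulus calcium.

    calcium < low -> no tag; low <= calcium < high -> depotentiation;
    calcium >= high -> potentiation.  Vectorized; returns int8 codes
    matching :class:`Tag`.
    """
    if not tag_low < tag_high:
        raise ValueError("thresholds must be ordered low < high")
    c = np.asarray(calcium, dtype=float)
    tags = np.zeros(c.shape, dtype=np.int8)
    tags[(c >= tag_low) & (c < tag_high)] = Tag.DEPOTENTIATION
    tags[c >= tag_high] = Tag.POTENTIATION
    return tags if tags.shape else Tag(int(tags))


def prp_trigger(total_calcium, level, theta_prp: float):
    """PRP level after a stimulus: jumps to 1.0 where calcium > theta_prp."""
    c = np.asarray(total_calcium, dtype=float)
    lvl = np.asarray(level, dtype=float)
    return np.where(c > theta_prp, 1.0, lvl)


def prp_decay(level, hours: float, tau_prp_h: float):
    """Exponential PRP decay over an interval of `hours`."""
    if hours < 0:
        raise ValueError("interval must be nonnegative")
    return np.asarray(level, dtype=float) * math.exp(-hours / tau_prp_h)


def consolidation_integral(prp0, hours: float, tau_prp_h: float, rate_h: float):
    """Closed-form integral of rate * PRP(t) over [0, hours].

    With PRP(t) = prp0 * exp(-t/tau), the consolidated fraction is
    rate * tau * prp0 * (1 - exp(-hours/tau)), capped at 1 by the caller.
    """
    return rate_h * tau_prp_h * np.asarray(prp0, dtype=float) * (
        1.0 - math.exp(-hours / tau_prp_h)
    )


def consolidate(w, tags, fraction, w_init: float, pot_quantum: float, dep_quantum: float):
    """Consolidate tags into permanent weights.

    `fraction` is the consolidated fraction of each tag (rate x integrated
    PRP, capped at 1).  Potentiation tags raise the weight by up to
    pot_quantum * w_init, depotentiation tags lower it by up to
    dep_quantum * w_init (floored at 0).  Returns (new_weights, new_tags,
    remaining_fraction); tags are cleared once fully consolidated.
    """
    w = np.asarray(w, dtype=float).copy()
    tags = np.asarray(tags, dtype=np.int8).copy()
    frac = np.clip(np.asarray(fraction, dtype=float), 0.0, 1.0)
    frac = np.broadcast_to(frac, w.shape).copy()
    pot = tags == Tag.POTENTIATION
    dep = tags == Tag.DEPOTENTIATION
    w[pot] += frac[pot] * pot_quantum * w_init
    w[dep] -= frac[dep] * dep_quantum * w_init
    np.clip(w, 0.0, None, out=w)
    done = frac >= 1.0
    tags[done] = Tag.NONE
    return w, tags, np.where(done, 0.0, 1.0 - frac)


def homeostasis_step(w, w_init: float, n_syn: int, tau_h_h: float, dt_h: float):
    """One explicit-Euler step of the homeostatic scaling rule (testing aid).

    dw_j/dt = (1/tau_H)(1 - sum_j w_j / (w_init * N_syn)): the identical
    increment applied to every weight; fixed point at sum w = w_init * N.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    w = np.asarray(w, dtype=float)
    drift = (1.0 - w.sum() / (w_init * n_syn)) / tau_h_h
    return np.clip(w + drift * dt_h, 0.0, None)


def homeostasis_forward(w, w_init: float, tau_h_h: float, hours: float):
    """Closed-form fast-forward of homeostatic scaling over `hours`.

    Summing the per-synapse rule over the N synapses of the neuron gives
    dS/dt = (N/tau_H)(1 - S/(w_init N)), an exponential relaxation of the
    summed weight toward w_init*N with time constant tau_H * w_init.  The
    per-synapse share of the total change is identical for every weight.
    """
    if hours < 0:
        raise ValueError("interval must be nonnegative")
    w = np.asarray(w, dtype=float)
    n = w.size
    if n == 0 or hours == 0:
        return w.copy()
    target = w_init * n
    s0 = w.sum()
    s_t = target + (s0 - target) * math.exp(-hours / (tau_h_h * w_init))
    return np.clip(w + (s_t - s0) / n, 0.0, None)


def intrinsic_excitability(
    onset_h, now_h: float, factor: float = 0.5, duration_h: float = 12.0
):
    """AHP scale factor: `factor` within `duration_h` hours of PRP onset.

    `onset_h` is the PRP-synthesis onset time in hours (NaN / -inf for
    neurons that never triggered synthesis -> scale 1.0).  Restores to 1.0
    once the window has elapsed.
    """
    onset = np.asarray(onset_h, dtype=float)
    elapsed = now_h - onset
    active = np.isfinite(onset) & (elapsed >= 0) & (elapsed < duration_h)
    out = np.where(active, factor, 1.0)
    return out if out.shape else float(out)
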