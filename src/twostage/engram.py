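"""Memory-engram microcircuit of two-stage neurons.

The network contains two-stage excitatory neurons (20 dendritic subunits
with NMDA plateaus), fast-spiking basket cells (FS BCs, perisomatic
feedback inhibition) and SOM+ interneurons (dendritic feedback
inhibition), each interneuron with ten dendritic subunits.  Memory
afferents (a conditioned/CS half and an unconditioned/US half per memory)
contact excitatory dendrites with plastic synapses governed by the
synaptic-tagging-and-capture rules of :mod:`twostage.plasticity`.

Protocol: encoding co-activates the CS and US afferents of one memory with
50 Hz Poisson trains while the full voltage dynamics run; an interstimulus
interval (hours) is fast-forwarded in closed form (PRP decay, tag
consolidation, homeostatic scaling, excitability restoration); recall
presents the CS alone with plasticity frozen and reads out excitatory
rates.  Excitatory neurons firing above 10 Hz at recall form the engram.

The experimental dials are the FS BC dendritic configuration (linear vs an
equal supralinear/sublinear mix, "bimodal") and the allocation of the
excitatory feedback synapses on FS dendrites (dispersed over all subunits
vs grouped on ~a third of them).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_seed, rng_for
from .integration import IntegrationMode
from .neuron import dendrite_output, mode_codes
from .params import NeuronParams, excitatory_params, interneuron_params
from .plasticity import (
    PlasticityParams,
    Tag,
    calcium_influx,
    consolidation_integral,
    homeostasis_forward,
    intrinsic_excitability,
    prp_decay,
    update_tags,
)

__all__ = [
    "NetworkConfig",
    "EngramNetwork",
    "EngramReport",
    "engram_members",
    "treves_rolls_sparsity",
    "engram_overlap",
    "run_experiment_grid",
    "CONTROL_CONDITIONS",
]

ENGRAM_THRESHOLD_HZ = 10.0  # recall rate above which a neuron joins the engram


def _interneuron_modes(mode: str, n_dend: int) -> list[IntegrationMode]:
    """Per-subunit modes for an interneuron configuration label."""
    if mode == "bimodal":
        half = n_dend // 2
        return [IntegrationMode.SUPRALINEAR] * half + [IntegrationMode.SUBLINEAR] * (
            n_dend - half
        )
    return [IntegrationMode(mode)] * n_dend


@dataclass(frozen=True)
class NetworkConfig:
    """Composition, connectivity and protocol constants of the microcircuit.

    Population sizes default to a desk-scale network (400 excitatory, 40 FS,
    40 SOM).  Connection probabilities are single scalars per projection,
    calibrated once so the control engram occupies 25-30% of the excitatory
    population.  `fs_dendrite_mode` is "linear" or "bimodal"; the SOM mode
    may additionally be "sublinear"/"supralinear" (control: sublinear).
    `fs_input_allocation` places excitatory feedback synapses on FS
    dendrites either uniformly ("dispersed") or on ~33% of subunits
    ("grouped").
    """

    n_exc: int = 400
    n_fs: int = 40
    n_som: int = 40
    n_dend_exc: int = 20
    n_dend_int: int = 10
    fs_dendrite_mode: str = "bimodal"
    som_dendrite_mode: str = "sublinear"
    fs_input_allocation: str = "dispersed"
    # connectivity probabilities
    p_aff_exc: float = 0.25
    p_exc_fs: float = 0.15
    p_exc_som: float = 0.15
    p_fs_exc: float = 0.30
    p_som_exc: float = 0.30
    # synaptic strengths
    w_init: float = 2.8  # plastic afferent synapses, units of weight
    w_exc_fs: float = 2.0  # excitatory drive onto interneuron dendrites
    w_exc_som: float = 1.2
    w_fs_exc: float = 0.105  # perisomatic IPSC pulse amplitude (nA)
    w_som_exc: float = 1.0  # dendritic inhibition pulse (mV decrement scale)
    tau_ipsc: float = 10.0  # ms
    # memory / protocol constants
    n_memories: int = 2
    n_aff_per_memory: int = 100  # split into equal CS and US halves
    afferent_rate_hz: float = 50.0
    encode_duration_ms: float = 1000.0
    recall_duration_ms: float = 1000.0
    dt: float = 0.5  # ms

    def __post_init__(self) -> None:
        if min(self.n_exc, self.n_fs, self.n_som) <= 0:
            raise ValueError("all populations must be nonempty")
        if self.n_fs != self.n_som:
            raise ValueError("interneurons split 50/50 between FS and SOM")
        if self.fs_dendrite_mode not in ("linear", "bimodal"):
            raise ValueError("FS dendrites are 'linear' or 'bimodal'")
        if self.som_dendrite_mode not in ("linear", "bimodal", "sublinear", "supralinear"):
            raise ValueError("unknown SOM dendrite mode")
        if self.fs_input_allocation not in ("dispersed", "grouped"):
            raise ValueError("FS input allocation is 'dispersed' or 'grouped'")
        if self.n_aff_per_memory % 2:
            raise ValueError("afferents must split into equal CS and US halves")


@dataclass
class EngramReport:
    """Metrics of one experiment condition/trial."""

    condition: str
    trial: int
    size_pct: float
    mean_rate_hz: float
    sparsity: float
    overlap_pct: float | None = None
    chance_pct: float | None = None


def engram_members(rates, threshold: float = ENGRAM_THRESHOLD_HZ) -> np.ndarray:
    """Indices of neurons with recall rate strictly above `threshold` Hz."""
    rates = np.asarray(rates, dtype=float)
    return np.flatnonzero(rates > threshold)


def treves_rolls_sparsity(rates) -> float:
    """Population sparseness a = (mean r)^2 / mean(r^2).

    1 for perfectly uniform activity, 1/N when a single neuron is active;
    lower values indicate sparser coding.  Undefined (raises) when no
    neuron fires.
    """
    r = np.asarray(rates, dtype=float)
    if np.all(r == 0):
        raise ValueError("sparsity undefined for an all-silent population")
    return float(r.mean() ** 2 / np.mean(r**2))


def engram_overlap(members_1, members_2, n_exc: int) -> tuple[float, float]:
    """Overlap between two engrams, as % of the first engram.

    Returns ``(overlap_pct, chance_pct)``.  Overlap is
    |intersection| / |engram 1| * 100 (0 when engram 1 is empty); the
    chance level assumes independent membership, i.e. the product of the
    two engram fractions expressed as % of the population.
    """
    m1, m2 = set(np.asarray(members_1).tolist()), set(np.asarray(members_2).tolist())
    overlap = 100.0 * len(m1 & m2) / len(m1) if m1 else 0.0
    chance = 100.0 * (len(m1) / n_exc) * (len(m2) / n_exc)
    return overlap, chance


class EngramNetwork:
    """One wired instance of the microcircuit with its plasticity state."""

    def __init__(
        self,
        config: NetworkConfig | None = None,
        seed: int = 0,
        exc_params: NeuronParams | None = None,
        int_params: NeuronParams | None = None,
        plasticity: PlasticityParams | None = None,
    ):
        self.config = cfg = config or NetworkConfig()
        self.seed = seed
        self.exc_params = exc_params or excitatory_params()
        self.int_params = int_params or interneuron_params()
        self.plast = plasticity or PlasticityParams()
        self.now_h = 0.0
        self._wire(rng_for(seed, "engram.wiring"))
        self._init_state()

    # -- construction -------------------------------------------------------

    def _wire(self, rng: np.random.Generator) -> None:
        cfg = self.config
        # dendritic mode codes per population
        self.exc_codes = np.tile(
            mode_codes([IntegrationMode.SUPRALINEAR] * cfg.n_dend_exc), (cfg.n_exc, 1)
        )
        self.fs_codes = np.tile(
            mode_codes(_interneuron_modes(cfg.fs_dendrite_mode, cfg.n_dend_int)),
            (cfg.n_fs, 1),
        )
        self.som_codes = np.tile(
            mode_codes(_interneuron_modes(cfg.som_dendrite_mode, cfg.n_dend_int)),
            (cfg.n_som, 1),
        )

        # plastic afferent -> excitatory-dendrite synapses, all memories
        n_aff_total = cfg.n_memories * cfg.n_aff_per_memory
        pre, post_n, post_d = [], [], []
        for a in range(n_aff_total):
            targets = np.flatnonzero(rng.random(cfg.n_exc) < cfg.p_aff_exc)
            pre.append(np.full(len(targets), a))
            post_n.append(targets)
            post_d.append(rng.integers(0, cfg.n_dend_exc, size=len(targets)))
        self.syn_pre = np.concatenate(pre)
        self.syn_post = np.concatenate(post_n)
        self.syn_dend = np.concatenate(post_d)
        self.n_syn = len(self.syn_pre)
        self.syn_w = np.full(self.n_syn, cfg.w_init)
        self.syn_tag = np.zeros(self.n_syn, dtype=np.int8)
        self.syn_tag_frac = np.zeros(self.n_syn)  # unconsolidated fraction of the tag
        self.syn_calcium = np.zeros(self.n_syn)
        # memory -> afferent slice bookkeeping
        self.memories = []
        for m in range(cfg.n_memories):
            lo = m * cfg.n_aff_per_memory
            half = cfg.n_aff_per_memory // 2
            self.memories.append(
                {"cs": np.arange(lo, lo + half), "us": np.arange(lo + half, lo + cfg.n_aff_per_memory)}
            )
        self.encoded = [False] * cfg.n_memories

        def _project(n_pre, n_post, p, n_dend, grouped_subset=None):
            pre_i, post_i, dend_i = [], [], []
            for i in range(n_pre):
                tgt = np.flatnonzero(rng.random(n_post) < p)
                pre_i.append(np.full(len(tgt), i))
                post_i.append(tgt)
                if grouped_subset is not None:
                    dend_i.append(grouped_subset[tgt, rng.integers(0, grouped_subset.shape[1], len(tgt))])
                else:
                    dend_i.append(rng.integers(0, n_dend, size=len(tgt)))
            return (np.concatenate(pre_i), np.concatenate(post_i), np.concatenate(dend_i))

        # excitatory feedback onto FS dendrites: dispersed over all subunits
        # or grouped on ~33% of them (a fixed per-cell subset)
        if cfg.fs_input_allocation == "grouped":
            n_grp = max(1, round(cfg.n_dend_int / 3))  # ~33% of subunits
            subset = np.stack(
                [rng.choice(cfg.n_dend_int, size=n_grp, replace=False) for _ in range(cfg.n_fs)]
            )
        else:
            subset = None
        self.ef_pre, self.ef_post, self.ef_dend = _project(
            cfg.n_exc, cfg.n_fs, cfg.p_exc_fs, cfg.n_dend_int, subset
        )
        self.es_pre, self.es_post, self.es_dend = _project(
            cfg.n_exc, cfg.n_som, cfg.p_exc_som, cfg.n_dend_int
        )
        # interneuron feedback onto excitatory cells
        self.fe_pre, self.fe_post, _ = _project(cfg.n_fs, cfg.n_exc, cfg.p_fs_exc, 1)
        self.se_pre, self.se_post, self.se_dend = _project(
            cfg.n_som, cfg.n_exc, cfg.p_som_exc, cfg.n_dend_exc
        )

        # per-neuron plastic synapse counts for homeostasis
        self.syn_per_neuron = np.bincount(self.syn_post, minlength=cfg.n_exc)

    def _init_state(self) -> None:
        cfg = self.config
        self.prp = np.zeros(cfg.n_exc)
        self.prp_onset_h = np.full(cfg.n_exc, -np.inf)

    # -- dynamics -----------------------------------------------------------

    def _run(
        self,
        active_afferents: np.ndarray,
        duration: float,
        seed_key: str,
        plastic: bool,
    ) -> np.ndarray:
        """Simulate voltage dynamics with the given afferents active.

        Returns excitatory spike counts.  When `plastic`, per-synapse
        calcium accumulates for the synapses of active afferents.
        """
        cfg = self.config
        pe, pi, plast = self.exc_params, self.int_params, self.plast
        dt = cfg.dt
        n_steps = int(round(duration / dt))
        rng = rng_for(self.seed, seed_key)

        aff_active = np.zeros(cfg.n_memories * cfg.n_aff_per_memory, dtype=bool)
        aff_active[active_afferents] = True
        syn_live = aff_active[self.syn_pre]
        live_idx = np.flatnonzero(syn_live)
        lp, ln, ld = self.syn_pre[live_idx], self.syn_post[live_idx], self.syn_dend[live_idx]
        lw = self.syn_w[live_idx]
        lam_aff = cfg.afferent_rate_hz * 1e-3 * dt

        jump_e = pe.dend.e_syn / pe.dend.tau_b
        jump_i = pi.dend.e_syn / pi.dend.tau_b
        dec_be, dec_bi = np.exp(-dt / pe.dend.tau_b), np.exp(-dt / pi.dend.tau_b)
        dec_ae, dec_ai = np.exp(-dt / pe.soma.tau_ahp), np.exp(-dt / pi.soma.tau_ahp)
        dec_ipsc = np.exp(-dt / cfg.tau_ipsc)

        # state
        vb_e = np.zeros((cfg.n_exc, cfg.n_dend_exc))
        vb_f = np.zeros((cfg.n_fs, cfg.n_dend_int))
        vb_s = np.zeros((cfg.n_som, cfg.n_dend_int))
        v_e = np.zeros(cfg.n_exc)
        v_f = np.zeros(cfg.n_fs)
        v_s = np.zeros(cfg.n_som)
        ga_e = np.zeros(cfg.n_exc)
        ga_f = np.zeros(cfg.n_fs)
        ga_s = np.zeros(cfg.n_som)
        ref_e = np.zeros(cfg.n_exc)
        ref_f = np.zeros(cfg.n_fs)
        ref_s = np.zeros(cfg.n_som)
        ipsc_e = np.zeros(cfg.n_exc)
        t_last = np.full(cfg.n_exc, 1e9)
        plateau = np.zeros((cfg.n_exc, cfg.n_dend_exc))
        fired_e = np.zeros(cfg.n_exc, dtype=bool)
        fired_f = np.zeros(cfg.n_fs, dtype=bool)
        fired_s = np.zeros(cfg.n_som, dtype=bool)
        counts_e = np.zeros(cfg.n_exc, dtype=int)
        counts_f = np.zeros(cfg.n_fs, dtype=int)
        counts_s = np.zeros(cfg.n_som, dtype=int)
        # learning-induced excitability: transient AHP reduction
        ahp_scale = np.asarray(
            intrinsic_excitability(
                self.prp_onset_h, self.now_h, plast.excitability_factor, plast.excitability_dur_h
            )
        )
        a_ahp_e = pe.soma.a_ahp / pe.soma.tau_ahp * ahp_scale
        calcium = np.zeros(len(live_idx)) if plastic else None

        for _ in range(n_steps):
            # afferent drive onto excitatory dendrites
            aff_spk = rng.poisson(lam_aff, size=len(active_afferents))
            spikes_by_aff = np.zeros(cfg.n_memories * cfg.n_aff_per_memory)
            spikes_by_aff[active_afferents] = aff_spk
            drive = spikes_by_aff[lp] * lw * jump_e
            vb_e *= dec_be
            np.add.at(vb_e, (ln, ld), drive)
            # dendritic inhibition from SOM spikes of the previous step
            if np.any(fired_s):
                mask = fired_s[self.se_pre]
                np.add.at(
                    vb_e,
                    (self.se_post[mask], self.se_dend[mask]),
                    -cfg.w_som_exc,
                )
            t_last += dt
            vbap = pe.bap.e_bap * np.exp(-np.minimum(t_last, 1e6) / pe.bap.tau_bap)
            veff_e = vb_e + vbap[:, None]
            plateau = np.maximum(plateau - dt, 0.0)
            plateau[veff_e > pe.dend.theta_dspike] = pe.dend.plateau_dur
            out_e = dendrite_output(veff_e, self.exc_codes, pe.dend, plateau > 0)

            if plastic:
                spk_syn = spikes_by_aff[lp]
                hot = spk_syn > 0
                if np.any(hot):
                    # plasticity voltage includes the NMDA plateau depolarization
                    v_ca = veff_e + pe.dend.plateau_amp * (plateau > 0)
                    calcium[hot] += spk_syn[hot] * calcium_influx(
                        v_ca[ln[hot], ld[hot]], 0.0, plast.a_ca
                    )

            # perisomatic inhibition from FS spikes of the previous step
            ipsc_e *= dec_ipsc
            if np.any(fired_f):
                ipsc_e += np.bincount(
                    self.fe_post[fired_f[self.fe_pre]], minlength=cfg.n_exc
                ) * cfg.w_fs_exc
            i_syn_e = pe.soma.g_syn * out_e.sum(axis=1) - ipsc_e

            # excitatory soma update
            ga_e *= dec_ae
            in_ref = ref_e > 0
            ref_e = np.maximum(ref_e - dt, 0.0)
            g_tot = pe.soma.g_l + ga_e
            v_inf = (ga_e * pe.soma.e_k + i_syn_e) / g_tot
            v_e = np.where(in_ref, 0.0, v_inf + (v_e - v_inf) * np.exp(-g_tot * dt / pe.soma.c))
            fired_e = (~in_ref) & (v_e >= pe.soma.theta_soma)
            v_e[fired_e] = 0.0
            ga_e[fired_e] += a_ahp_e[fired_e]
            ref_e[fired_e] = pe.soma.refractory
            t_last[fired_e] = 0.0
            counts_e += fired_e

            # interneurons driven by excitatory spikes of this step
            for vb, codes, v, ga, ref, dec_b, dec_a, pp, pre_i, post_i, dend_i, w in (
                (vb_f, self.fs_codes, v_f, ga_f, ref_f, dec_bi, dec_ai, pi,
                 self.ef_pre, self.ef_post, self.ef_dend, cfg.w_exc_fs),
                (vb_s, self.som_codes, v_s, ga_s, ref_s, dec_bi, dec_ai, pi,
                 self.es_pre, self.es_post, self.es_dend, cfg.w_exc_som),
            ):
                vb *= dec_b
                if np.any(fired_e):
                    mask = fired_e[pre_i]
                    np.add.at(vb, (post_i[mask], dend_i[mask]), w * jump_i)
                out = dendrite_output(vb, codes, pp.dend)
                i_syn = pp.soma.g_syn * out.sum(axis=1)
                ga *= dec_a
                in_ref_i = ref > 0
                ref -= dt
                np.clip(ref, 0.0, None, out=ref)
                g_tot_i = pp.soma.g_l + ga
                v_inf_i = (ga * pp.soma.e_k + i_syn) / g_tot_i
                v_new = np.where(
                    in_ref_i, 0.0, v_inf_i + (v - v_inf_i) * np.exp(-g_tot_i * dt / pp.soma.c)
                )
                fired = (~in_ref_i) & (v_new >= pp.soma.theta_soma)
                v_new[fired] = 0.0
                ga[fired] += pp.soma.a_ahp / pp.soma.tau_ahp
                ref[fired] = pp.soma.refractory
                v[:] = v_new
                if vb is vb_f:
                    fired_f = fired
                    counts_f += fired
                else:
                    fired_s = fired
                    counts_s += fired

        self._last_int_rates = (
            counts_f / (duration * 1e-3),
            counts_s / (duration * 1e-3),
        )
        if plastic:
            self.syn_calcium[live_idx] += calcium
        return counts_e

    # -- protocol operations -------------------------------------------------

    def encode_memory(self, memory_id: int, duration: float | None = None) -> None:
        """Co-activate the CS and US afferents of one memory and tag synapses.

        Calcium accumulates during the stimulus; at stimulus end the
        per-synapse tags are set from accumulated calcium, somatic PRP
        synthesis triggers where the neuron's total calcium crosses the PRP
        threshold (with the ~12 h excitability elevation), and the
        accumulator resets.
        """
        cfg, plast = self.config, self.plast
        mem = self.memories[memory_id]
        afferents = np.concatenate([mem["cs"], mem["us"]])
        self._run(
            afferents,
            duration or cfg.encode_duration_ms,
            f"encode.{memory_id}.{self.now_h:.3f}",
            plastic=True,
        )
        # read out the calcium accumulator
        stim = self.syn_calcium > 0
        new_tags = update_tags(self.syn_calcium[stim], plast.tag_low, plast.tag_high)
        self.syn_tag[stim] = new_tags
        self.syn_tag_frac[stim] = np.where(new_tags != Tag.NONE, 1.0, 0.0)
        total_ca = np.bincount(self.syn_post, weights=self.syn_calcium, minlength=cfg.n_exc)
        triggered = total_ca > plast.theta_prp
        self.prp[triggered] = 1.0
        self.prp_onset_h[triggered] = self.now_h
        self.syn_calcium[:] = 0.0
        self.encoded[memory_id] = True

    def simulate_interval(self, hours: float) -> None:
        """Fast-forward the slow dynamics over an interstimulus interval.

        Applies, in order: PRP-gated tag consolidation (closed-form
        integral of the decaying PRP level), PRP decay, homeostatic weight
        scaling toward each neuron's fixed total, and the advance of the
        clock that restores intrinsic excitability.
        """
        if hours < 0:
            raise ValueError("interval must be nonnegative")
        if hours == 0:
            return
        cfg, plast = self.config, self.plast
        frac_neuron = np.clip(
            consolidation_integral(self.prp, hours, plast.tau_prp_h, plast.consolidation_rate_h),
            0.0,
            1.0,
        )
        applied = np.minimum(frac_neuron[self.syn_post], self.syn_tag_frac)
        pot = self.syn_tag == Tag.POTENTIATION
        dep = self.syn_tag == Tag.DEPOTENTIATION
        self.syn_w[pot] += applied[pot] * plast.pot_quantum * cfg.w_init
        self.syn_w[dep] -= applied[dep] * plast.dep_quantum * cfg.w_init
        np.clip(self.syn_w, 0.0, None, out=self.syn_w)
        self.syn_tag_frac -= applied
        done = self.syn_tag_frac <= 1e-12
        self.syn_tag[done] = Tag.NONE
        self.syn_tag_frac[done] = 0.0

        self.prp = prp_decay(self.prp, hours, plast.tau_prp_h)

        # homeostasis: per-neuron closed-form relaxation of the summed weight
        sums = np.bincount(self.syn_post, weights=self.syn_w, minlength=cfg.n_exc)
        n = self.syn_per_neuron
        ok = n > 0
        target = cfg.w_init * n[ok]
        tau = plast.tau_h_h * cfg.w_init
        s_t = target + (sums[ok] - target) * np.exp(-hours / tau)
        delta = np.zeros(cfg.n_exc)
        delta[ok] = (s_t - sums[ok]) / n[ok]
        self.syn_w += delta[self.syn_post]
        np.clip(self.syn_w, 0.0, None, out=self.syn_w)

        self.now_h += hours

    def recall(self, memory_id: int, duration: float | None = None) -> np.ndarray:
        """Present the CS alone with plasticity frozen; return exc rates (Hz)."""
        if not self.encoded[memory_id]:
            raise ValueError(f"memory {memory_id} has not been encoded")
        cfg = self.config
        dur = duration or cfg.recall_duration_ms
        counts = self._run(
            self.memories[memory_id]["cs"],
            dur,
            f"recall.{memory_id}.{self.now_h:.3f}",
            plastic=False,
        )
        return counts / (dur * 1e-3)


# ---------------------------------------------------------------------------
# Experiment grid


CONTROL_CONDITIONS = (
    ("bimodal", "dispersed"),
    ("bimodal", "grouped"),
    ("linear", "dispersed"),
    ("linear", "grouped"),
)


def single_memory_trial(
    fs_mode: str,
    allocation: str,
    seed: int,
    config: NetworkConfig | None = None,
    **net_kwargs,
) -> EngramReport:
    """Encode one memory, wait 24 h, recall; report engram metrics."""
    cfg = replace(
        config or NetworkConfig(), fs_dendrite_mode=fs_mode, fs_input_allocation=allocation
    )
    net = EngramNetwork(cfg, seed=seed, **net_kwargs)
    net.encode_memory(0)
    net.simulate_interval(24.0)
    rates = net.recall(0)
    members = engram_members(rates)
    return EngramReport(
        condition=f"{fs_mode}-{allocation}",
        trial=seed,
        size_pct=100.0 * len(members) / cfg.n_exc,
        mean_rate_hz=float(rates.mean()),
        sparsity=treves_rolls_sparsity(rates) if np.any(rates > 0) else np.nan,
    )


def two_memory_trial(
    fs_mode: str,
    allocation: str,
    separation_h: float,
    seed: int,
    config: NetworkConfig | None = None,
    **net_kwargs,
) -> EngramReport:
    """Encode two memories `separation_h` apart, consolidate 24 h, recall both."""
    cfg = replace(
        config or NetworkConfig(), fs_dendrite_mode=fs_mode, fs_input_allocation=allocation
    )
    net = EngramNetwork(cfg, seed=seed, **net_kwargs)
    net.encode_memory(0)
    net.simulate_interval(separation_h)
    net.encode_memory(1)
    net.simulate_interval(24.0)
    r1, r2 = net.recall(0), net.recall(1)
    m1, m2 = engram_members(r1), engram_members(r2)
    overlap, chance = engram_overlap(m1, m2, cfg.n_exc)
    rates = np.concatenate([r1, r2])
    return EngramReport(
        condition=f"{fs_mode}-{allocation}-{separation_h:g}h",
        trial=seed,
        size_pct=100.0 * len(m1) / cfg.n_exc,
        mean_rate_hz=float(r1.mean()),
        sparsity=treves_rolls_sparsity(r1) if np.any(r1 > 0) else np.nan,
        overlap_pct=overlap,
        chance_pct=chance,
    )


def run_experiment_grid(
    conditions=CONTROL_CONDITIONS,
    trials: int = 20,
    seed: int = 0,
    config: NetworkConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Single-memory engram metrics over a condition grid.

    Returns ``(reports, anova)``: one report row per condition x trial, and
    a one-way ANOVA across conditions per metric (None with a single
    condition, in which case the ANOVA is skipped).
    """
    if trials < 2:
        raise ValueError("need at least two trials")
    rows = []
    for fs_mode, allocation in conditions:
        for t in range(trials):
            rep = single_memory_trial(
                fs_mode, allocation, seed=child_seed(seed, f"grid.{fs_mode}.{allocation}.{t}"),
                config=config,
            )
            rep.trial = t
            rows.append(rep)
    reports = pd.DataFrame([vars(r) for r in rows])
    if len(conditions) < 2:
        return reports, None
    anova_rows = []
    for metric in ("size_pct", "mean_rate_hz", "sparsity"):
        groups = [g[metric].dropna().to_numpy() for _, g in reports.groupby("condition")]
        f, p = stats.f_oneway(*groups)
        anova_rows.append({"metric": metric, "F": float(f), "p_value": float(p)})
    return reports, pd.DataFrame(anova_rows)
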