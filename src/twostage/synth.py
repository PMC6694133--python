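"""Synthetic inputs: morphometry, spike trains, allocations, rate datasets.

Nothing in the pipeline requires downloads.  This module generates

* class-conditional dendrite morphometry (supralinear branches are
  large-volume / low input resistance, sublinear branches small-volume /
  high input resistance),
* homogeneous Poisson stimulus trains (50 Hz is the standard drive),
* dispersed and grouped synaptic allocation protocols, and
* surrogate firing-rate datasets produced by forward-simulating the
  reduced two-stage reference cell over many allocations — these stand in
  for the multicompartmental simulations that would otherwise supply
  (synapse-placement -> firing-rate) training data.

Every sampler takes an integer seed; identical seeds give bit-identical
output.  A single pipeline seed fans out to per-component streams via
:mod:`twostage._rng`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_seed, rng_for
from .integration import DendriteMorphometry, IntegrationMode, dendrite_volume
from .neuron import TwoStageNeuron
from .params import NeuronParams, fs_reference_params

__all__ = [
    "ClassMoments",
    "MorphometryDistributions",
    "SpikeTrain",
    "SynapticAllocation",
    "SurrogateDataset",
    "sample_morphology",
    "default_morphology",
    "reference_morphology",
    "assign_input_resistance",
    "generate_poisson_train",
    "allocate_dispersed",
    "allocate_grouped",
    "reference_neuron",
    "surrogate_firing_dataset",
]


@dataclass(frozen=True)
class ClassMoments:
    """Log-normal morphometry moments for one integration class.

    `length_median` (um) and `diam_median` (um) are the log-normal medians;
    the sigmas are the log-space dispersions.
    """

    length_median: float
    length_sigma: float
    diam_median: float
    diam_sigma: float

    def mean_length(self) -> float:
        return self.length_median * math.exp(self.length_sigma**2 / 2)

    def mean_volume(self, diam_cap: float | None = None) -> float:
        """Implied mean cylinder volume, E[pi/4 d^2 L] with d, L independent.

        With `diam_cap`, the second moment of the diameter is that of the
        log-normal truncated at the cap (branches above it are resampled),
        E[d^2 | d <= cap] = m^2 e^{2s^2} Phi(z - 2s) / Phi(z), z = ln(cap/m)/s.
        """
        mean_d2 = self.diam_median**2 * math.exp(2 * self.diam_sigma**2)
        if diam_cap is not None:
            from scipy.stats import norm

            z = math.log(diam_cap / self.diam_median) / self.diam_sigma
            mean_d2 *= norm.cdf(z - 2 * self.diam_sigma) / norm.cdf(z)
        return math.pi / 4.0 * mean_d2 * self.mean_length()


@dataclass(frozen=True)
class MorphometryDistributions:
    """Class mixture of branch morphometry.

    Defaults follow the hippocampal pattern: supralinear branches are
    longer and thicker (hence larger volume) than sublinear ones, and
    branches with mean diameter above `diam_cap` (1.2 um) are excluded and
    resampled.
    """

    supralinear: ClassMoments = field(
        default_factory=lambda: ClassMoments(110.0, 0.35, 0.90, 0.15)
    )
    sublinear: ClassMoments = field(default_factory=lambda: ClassMoments(60.0, 0.40, 0.55, 0.20))
    supra_fraction: float = 0.35
    diam_cap: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.supra_fraction <= 1.0):
            raise ValueError("supra_fraction must lie in [0, 1]")
        for cls in (self.supralinear, self.sublinear):
            if cls.length_sigma <= 0 or cls.diam_sigma <= 0:
                raise ValueError("dispersions must be positive")
            if cls.length_median <= 0 or cls.diam_median <= 0:
                raise ValueError("medians must be positive")
        if self.supralinear.mean_volume() <= self.sublinear.mean_volume():
            raise ValueError("supralinear class must have larger mean volume")


def assign_input_resistance(volume: float | np.ndarray) -> np.ndarray:
    """Input resistance (MOhm) from volume via a calibrated monotone map.

    R_in = 1000 / sqrt(V) places a ~78 um^3 supralinear branch near
    110 MOhm and a ~17 um^3 sublinear branch near 240 MOhm, preserving the
    large-volume/low-R_in vs small-volume/high-R_in separation.  This map
    replaces per-branch current injection, which needs a cable model.
    """
    return 1000.0 / np.sqrt(np.asarray(volume, dtype=float))


def sample_morphology(
    dist: MorphometryDistributions, n_dendrites: int, seed: int
) -> list[DendriteMorphometry]:
    """Sample `n_dendrites` labelled branches from the class mixture.

    Each branch carries a ground-truth mode label, cylinder-consistent
    volume and a volume-derived input resistance.  Branches whose mean
    diameter exceeds `dist.diam_cap` are discarded and resampled.
    """
    if n_dendrites < 2:
        raise ValueError("need at least two dendrites")
    if dist.supra_fraction in (0.0, 1.0) and n_dendrites > 0:
        pass  # degenerate mixtures are allowed; the invariant below is vacuous
    rng = rng_for(seed, "synth.morphology")
    branches: list[DendriteMorphometry] = []
    while len(branches) < n_dendrites:
        is_supra = rng.random() < dist.supra_fraction
        cls = dist.supralinear if is_supra else dist.sublinear
        diam = cls.diam_median * math.exp(rng.normal(0.0, cls.diam_sigma))
        if diam > dist.diam_cap:
            continue  # excluded; resample
        length = cls.length_median * math.exp(rng.normal(0.0, cls.length_sigma))
        vol = dendrite_volume(diam, length)
        branches.append(
            DendriteMorphometry(
                dendrite_id=len(branches),
                length=length,
                diam=diam,
                r_in=float(assign_input_resistance(vol)),
                mode=IntegrationMode.SUPRALINEAR if is_supra else IntegrationMode.SUBLINEAR,
            )
        )
    return branches


def default_morphology(seed: int = 0, n_dendrites: int = 40) -> list[DendriteMorphometry]:
    """A synthetic reference-cell morphology (40 branches)."""
    return sample_morphology(MorphometryDistributions(), n_dendrites, seed)


# The packaged reference FS cell is this fixed draw: single-cell protocol
# calibrations (gamma band, background rate) are statements about this cell,
# the way the original calibrations are statements about specific
# reconstructions.
REFERENCE_MORPHOLOGY_SEED = 1


def reference_morphology() -> list[DendriteMorphometry]:
    """The fixed morphology of the calibrated reference FS cell."""
    return default_morphology(REFERENCE_MORPHOLOGY_SEED)


# ---------------------------------------------------------------------------
# Poisson drive


@dataclass
class SpikeTrain:
    """Homogeneous Poisson spike train on [0, duration) ms."""

    times: np.ndarray  # ms, sorted ascending
    rate_hz: float
    duration: float  # ms
    seed: int

    def __len__(self) -> int:
        return len(self.times)


def generate_poisson_train(rate_hz: float, duration: float, seed: int) -> SpikeTrain:
    """Sample a homogeneous Poisson train (event count ~ Poisson(rate*T))."""
    if rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng_for(seed, "synth.poisson")
    n = rng.poisson(rate_hz * duration * 1e-3)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(times=times, rate_hz=rate_hz, duration=duration, seed=seed)


# ---------------------------------------------------------------------------
# Allocation protocols


@dataclass
class SynapticAllocation:
    """Per-dendrite synapse counts produced by a named protocol."""

    vector: np.ndarray  # length n_dendrites, nonnegative ints summing to nsyn
    protocol: str  # "dispersed" | "grouped"
    nsyn: int
    sclu: int | None = None  # group size, grouped protocol only

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=int)
        if self.vector.sum() != self.nsyn:
            raise ValueError("allocation counts must sum to nsyn")

    @property
    def counts(self) -> dict[int, int]:
        """Map dendrite-id -> synapse count (nonzero entries only)."""
        return {int(i): int(c) for i, c in enumerate(self.vector) if c > 0}

    @property
    def n_touched(self) -> int:
        return int((self.vector > 0).sum())


def _allocate(n_dend: int, nsyn: int, per_dend: int, rng: np.random.Generator) -> np.ndarray:
    """Place `per_dend` synapses on successive randomly ordered dendrites.

    The last selected dendrite takes the remainder when nsyn is not a
    multiple of per_dend.  If the morphology has fewer dendrites than
    needed, selection wraps around (small morphologies are forced to stack
    synapses).
    """
    vector = np.zeros(n_dend, dtype=int)
    order = rng.permutation(n_dend)
    remaining = nsyn
    i = 0
    while remaining > 0:
        d = order[i % n_dend]
        take = min(per_dend, remaining)
        vector[d] += take
        remaining -= take
        i += 1
    return vector


def allocate_dispersed(
    morph,
    nsyn: int,
    step: int = 2,
    repeats: int | None = None,
    seed: int = 0,
    nsyn_cap: int = 60,
) -> list[SynapticAllocation]:
    """Dispersed protocol: `step` synapses per randomly selected dendrite.

    `step` is 2, 5 or 10; dendrites are drawn without replacement so the
    allocation spreads across the tree.  The repeat structure mirrors the
    5-resamples-times-N-dendrites experimental design: by default
    ``repeats = 5 * n_dendrites`` independent allocations are produced;
    pass a smaller `repeats` for test-scale datasets.
    """
    n_dend = len(morph)
    if nsyn < 1 or nsyn > nsyn_cap:
        raise ValueError(f"nsyn must be in 1..{nsyn_cap}")
    if step not in (2, 5, 10):
        raise ValueError("step must be one of 2, 5, 10")
    if repeats is None:
        repeats = 5 * n_dend
    rng = rng_for(seed, "synth.dispersed")
    return [
        SynapticAllocation(_allocate(n_dend, nsyn, step, rng), "dispersed", nsyn)
        for _ in range(repeats)
    ]


def allocate_grouped(
    morph,
    nsyn: int,
    sclu: int = 20,
    repeats: int | None = None,
    seed: int = 0,
) -> list[SynapticAllocation]:
    """Grouped protocol: ceil(nsyn/sclu) dendrites receive `sclu` synapses.

    For nsyn = 60 and sclu = 20, three dendrites receive 20 synapses each;
    the last selected dendrite takes the remainder when sclu does not
    divide nsyn.
    """
    n_dend = len(morph)
    if sclu > nsyn:
        raise ValueError("group size sclu cannot exceed nsyn")
    if sclu < 1:
        raise ValueError("sclu must be positive")
    if repeats is None:
        repeats = 5 * n_dend
    rng = rng_for(seed, "synth.grouped")
    return [
        SynapticAllocation(_allocate(n_dend, nsyn, sclu, rng), "grouped", nsyn, sclu=sclu)
        for _ in range(repeats)
    ]


# ---------------------------------------------------------------------------
# In-vivo-like background protocol

# Calibration constants of the sparse background-activity protocol: 32
# excitatory synapses (weight W_BACKGROUND) and 8 perisomatic inhibitory
# synapses (IPSC amplitude W_INH_BACKGROUND nA), each independently active
# at BACKGROUND_RATE_HZ, produce ~3 Hz somatic firing in the reference cell.
N_BACKGROUND_EXC = 32
N_BACKGROUND_INH = 8
BACKGROUND_RATE_HZ = 10.0
W_BACKGROUND = 3.0
W_INH_BACKGROUND = 0.09


def background_counts(morph, seed: int) -> np.ndarray:
    """Place the 32 background excitatory synapses on random dendrites."""
    rng = rng_for(seed, "synth.background")
    return np.bincount(
        rng.choice(len(morph), size=N_BACKGROUND_EXC, replace=True), minlength=len(morph)
    )


def background_firing_rate(
    morph,
    seed: int,
    params: NeuronParams | None = None,
    duration: float = 5000.0,
    dt: float = 0.1,
) -> float:
    """Somatic rate (Hz) under the in-vivo-like background protocol."""
    neuron = reference_neuron(morph, params)
    counts = background_counts(morph, seed)
    res = neuron.simulate(
        counts[None, :],
        rate_hz=BACKGROUND_RATE_HZ,
        duration=duration,
        dt=dt,
        seed=seed,
        w=W_BACKGROUND,
        n_inh=N_BACKGROUND_INH,
        inh_rate_hz=BACKGROUND_RATE_HZ,
        w_inh=W_INH_BACKGROUND,
    )
    return res.rate


# ---------------------------------------------------------------------------
# Surrogate firing-rate datasets


def reference_neuron(morph, params: NeuronParams | None = None) -> TwoStageNeuron:
    """Two-stage neuron whose subunit modes follow the morphology labels."""
    modes = [b.mode if b.mode is not None else IntegrationMode.LINEAR for b in morph]
    return TwoStageNeuron(modes, params or fs_reference_params())


@dataclass
class SurrogateDataset:
    """(allocation -> mean firing rate) rows from the reference cell.

    `X` holds one per-dendrite synapse-count vector per row; `rates` the
    mean somatic firing rate (Hz) over the simulation trials; `protocols`
    the generating protocol tag per row.
    """

    X: np.ndarray  # (n_rows, n_dendrites)
    rates: np.ndarray  # Hz
    protocols: np.ndarray  # str per row
    seed: int
    reference_id: str = "fs-reference"

    def __post_init__(self) -> None:
        if len(self.X) != len(self.rates):
            raise ValueError("X and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def nsyn(self) -> np.ndarray:
        return self.X.sum(axis=1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"d{i}" for i in range(self.X.shape[1])])
        df["protocol"] = self.protocols
        df["nsyn"] = self.nsyn
        df["rate_hz"] = self.rates
        return df


def surrogate_firing_dataset(
    morph,
    allocations: list[SynapticAllocation],
    reference_params: NeuronParams | None = None,
    trials: int = 3,
    seed: int = 0,
    rate_hz: float = 50.0,
    duration: float = 500.0,
    dt: float = 0.5,
) -> SurrogateDataset:
    """Forward-simulate the reference cell over `allocations`.

    Each row's rate is the mean spike count per second averaged over
    `trials` independently seeded simulations of `duration` ms with every
    synapse driven at `rate_hz`.  An empty allocation list yields an empty
    dataset.
    """
    neuron = reference_neuron(morph, reference_params)
    n_dend = neuron.n_dendrites
    if not allocations:
        return SurrogateDataset(
            X=np.zeros((0, n_dend)), rates=np.zeros(0), protocols=np.array([], dtype=object),
            seed=seed,
        )
    X = np.stack([a.vector for a in allocations]).astype(float)
    rates = np.zeros(len(X))
    for t in range(trials):
        res = neuron.simulate(
            X, rate_hz=rate_hz, duration=duration, dt=dt,
            seed=child_seed(seed, f"synth.dataset.trial{t}"),
        )
        rates += res.rates
    rates /= trials
    protocols = np.array([a.protocol for a in allocations], dtype=object)
    return SurrogateDataset(X=X, rates=rates, protocols=protocols, seed=seed)


def protocol_grid_allocations(
    morph,
    seed: int,
    nsyn_values=tuple(range(4, 61, 4)),
    grid_reps: int = 6,
    challenge_reps: int = 30,
    dispersed_steps=(2, 5, 10),
    grouped_sizes=(10, 15, 20, 30, 60),
    challenge_counts=(20, 40, 60),
) -> list[SynapticAllocation]:
    """The full dispersed+grouped stimulation grid for dataset generation.

    Every total count in `nsyn_values` is allocated with each dispersed
    step and each admissible group size; the fixed-count challenge totals
    get `challenge_reps` repeats instead of `grid_reps` so that per-count
    comparisons have enough rows.
    """
    allocs: list[SynapticAllocation] = []
    for nsyn in nsyn_values:
        reps = challenge_reps if nsyn in challenge_counts else grid_reps
        for step in dispersed_steps:
            allocs += allocate_dispersed(
                morph, nsyn, step, repeats=reps, seed=child_seed(seed, f"grid.d{nsyn}.{step}")
            )
        for sclu in grouped_sizes:
            if sclu <= nsyn:
                allocs += allocate_grouped(
                    morph, nsyn, sclu, repeats=reps, seed=child_seed(seed, f"grid.g{nsyn}.{sclu}")
                )
    return allocs
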