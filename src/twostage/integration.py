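"""Dendritic integration modes: EPSP input-output curves and morphometry.

Fast-spiking basket cell dendrites summate synaptic inputs in one of two
modes.  *Supralinear* branches support local sodium spikes, so their
compound EPSP exceeds the linear sum of unitary EPSPs over at least a short
range of input counts.  *Sublinear* branches saturate: the compound EPSP
falls below the linear expectation for every input count tested.  The two
modes are anatomically determined — supralinear branches have large volume
and low input resistance, sublinear branches the opposite.

This module provides the expected-vs-actual curve machinery, the mode
classifier, the cylinder-volume and input-resistance closed forms, a
parametric surrogate for the two curve shapes, Welch group comparison, and
a minimal SWC branch-morphometry reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntegrationMode",
    "DendriteMorphometry",
    "IOCurve",
    "expected_curve",
    "classify_mode",
    "dendrite_volume",
    "input_resistance",
    "surrogate_dendrite_response",
    "surrogate_io_curve",
    "compare_groups",
    "read_swc_branches",
    "read_io_curves",
    "write_io_curves",
]


class IntegrationMode(str, Enum):
    """Dendritic EPSP summation mode."""

    SUPRALINEAR = "supralinear"
    SUBLINEAR = "sublinear"
    LINEAR = "linear"


def dendrite_volume(diam: float, length: float) -> float:
    """Cylinder volume of a branch, ``V = pi * (diam/2)**2 * length`` (um^3).

    Parameters
    ----------
    diam : mean branch diameter in um (> 0)
    length : total branch length in um (> 0)
    """
    if diam <= 0 or length <= 0:
        raise ValueError(f"diam and length must be positive, got {diam}, {length}")
    return math.pi * (diam / 2.0) ** 2 * length


def input_resistance(dv_mV: float, i_pA: float) -> float:
    """Input resistance ``R_in = DV / I`` in MOhm.

    `dv_mV` is the steady-state voltage deflection (mV) produced by a
    current injection of `i_pA` (pA); the standard probe is -100 pA per
    branch.  mV / nA = MOhm, so the pA input is converted to nA.
    """
    if i_pA == 0:
        raise ValueError("injected current must be nonzero")
    return dv_mV / (i_pA * 1e-3)


@dataclass
class DendriteMorphometry:
    """Per-branch anatomy with derived electrical descriptors.

    Volume is always the exact cylinder form of (`diam`, `length`).  The
    input resistance may be measured (SWC-free workflows assign it from a
    calibrated monotone map of volume, see :mod:`twostage.synth`).
    """

    dendrite_id: int
    length: float  # um
    diam: float  # um
    r_in: float | None = None  # MOhm
    mode: IntegrationMode | None = None

    @property
    def volume(self) -> float:
        return dendrite_volume(self.diam, self.length)


@dataclass
class IOCurve:
    """Expected vs. actual compound EPSP amplitudes for one branch.

    `expected[k-1]` is k times the unitary EPSP; `actual` holds the measured
    (or surrogate) compound amplitudes for the same synapse counts.
    """

    n_syn: np.ndarray
    unitary: float
    expected: np.ndarray
    actual: np.ndarray
    dendrite_id: int = 0

    def __post_init__(self) -> None:
        self.n_syn = np.asarray(self.n_syn, dtype=int)
        self.expected = np.asarray(self.expected, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)
        if not (len(self.n_syn) == len(self.expected) == len(self.actual)):
            raise ValueError("n_syn, expected and actual must have equal length")
        if len(self.n_syn) == 0:
            raise ValueError("empty IO curve")
        if np.any(np.diff(self.n_syn) <= 0):
            raise ValueError("synapse counts must be strictly increasing")


def expected_curve(unitary: float, n_max: int = 20) -> np.ndarray:
    """Linearly expected compound EPSP amplitudes for 1..n_max synapses.

    The expected amplitude for k synchronously activated synapses is the
    number of activated inputs multiplied by the unitary EPSP.
    """
    if unitary <= 0:
        raise ValueError("unitary EPSP must be positive")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    return unitary * np.arange(1, n_max + 1, dtype=float)


def classify_mode(curve: IOCurve, tol: float = 0.01) -> IntegrationMode:
    """Label a branch supralinear, sublinear or linear.

    Supralinear: the actual response exceeds the expected one by more than
    `tol` for at least one synapse count (a short supralinear range is
    enough).  Sublinear: no point lies above the expected curve beyond
    `tol` and at least one lies below it beyond `tol` — a curve may touch
    the diagonal (the one-synapse point does so by construction, since the
    unitary EPSP defines both curves there) and still summate sublinearly.
    Curves within tolerance everywhere are labelled linear, an explicit
    third label for the boundary case the strict dichotomy leaves
    undefined.
    """
    above = curve.actual > curve.expected + tol
    below = curve.actual < curve.expected - tol
    if np.any(above):
        return IntegrationMode.SUPRALINEAR
    if np.any(below):
        return IntegrationMode.SUBLINEAR
    return IntegrationMode.LINEAR


def surrogate_dendrite_response(
    mode: IntegrationMode,
    n_syn: int | np.ndarray,
    unitary: float = 0.5,
    threshold: float = 8.0,
    slope: float = 1.5,
    spike_amp: float = 6.0,
    baseline_gain: float = 0.8,
    sat_exponent: float = 0.7,
) -> np.ndarray:
    """Parametric actual-EPSP amplitude for a branch of the given mode (mV).

    Supralinear: a below-linear passive baseline (`baseline_gain` x linear)
    plus a sigmoidal sodium-spike component of amplitude `spike_amp`
    centred at `threshold` synapses with logistic `slope` (in synapses).
    Sublinear: a concave power law ``unitary * n**sat_exponent`` — exact at
    one synapse by construction.  Linear: exactly the expected curve.
    """
    n = np.asarray(n_syn, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_syn must be >= 1")
    if mode is IntegrationMode.SUPRALINEAR:
        out = baseline_gain * unitary * n + spike_amp / (1.0 + np.exp(-(n - threshold) / slope))
    elif mode is IntegrationMode.SUBLINEAR:
        out = unitary * n**sat_exponent
    elif mode is IntegrationMode.LINEAR:
        out = unitary * n
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown integration mode: {mode!r}")
    return out


def surrogate_io_curve(
    mode: IntegrationMode, unitary: float = 0.5, n_max: int = 20, dendrite_id: int = 0, **kwargs
) -> IOCurve:
    """Full surrogate IO curve for 1..n_max synapses under `mode`."""
    n = np.arange(1, n_max + 1)
    return IOCurve(
        n_syn=n,
        unitary=unitary,
        expected=expected_curve(unitary, n_max),
        actual=surrogate_dendrite_response(mode, n, unitary=unitary, **kwargs),
        dendrite_id=dendrite_id,
    )


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns ``(statistic, p_value)``.  Two groups with zero variance and
    equal means are reported as (0.0, 1.0) rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# File formats


def read_swc_branches(path: str | Path) -> list[DendriteMorphometry]:
    """Branch morphometry from a standard 7-column SWC reconstruction.

    A branch is the unbranched path between two branch points (or between a
    branch point and a terminal).  Branch length is the summed inter-node
    euclidean distance; mean diameter is the length-weighted mean of the
    distal node diameter (2 x radius) of each segment, so a fat soma parent
    never inflates a thin branch.  Soma nodes (type 1) delimit but do not
    contribute branches.
    """
    ids, parents, types = [], [], []
    xyz, radii = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        ids.append(int(parts[0]))
        types.append(int(parts[1]))
        xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
        radii.append(float(parts[5]))
        parents.append(int(parts[6]))
    index = {node_id: i for i, node_id in enumerate(ids)}
    xyz_arr = np.asarray(xyz)
    n_children: dict[int, int] = {}
    for p in parents:
        if p != -1:
            n_children[p] = n_children.get(p, 0) + 1

    branches: list[DendriteMorphometry] = []
    for i, node_id in enumerate(ids):
        # a branch ends at a terminal or at a branch point (>=2 children)
        if n_children.get(node_id, 0) != 0 and n_children.get(node_id, 0) < 2:
            continue
        if types[i] == 1:
            continue
        # walk rootwards to the previous branch point / soma / root
        seg_len, seg_diam_weighted = [], []
        j = i
        while True:
            p = parents[j]
            if p == -1 or p not in index:
                break
            pj = index[p]
            d = float(np.linalg.norm(xyz_arr[j] - xyz_arr[pj]))
            seg_len.append(d)
            seg_diam_weighted.append(d * 2.0 * radii[j])  # distal-node diameter
            if n_children.get(p, 0) >= 2 or types[pj] == 1:
                break
            j = pj
        total = float(sum(seg_len))
        if total <= 0:
            continue
        mean_diam = float(sum(seg_diam_weighted) / total)
        branches.append(
            DendriteMorphometry(dendrite_id=len(branches), length=total, diam=mean_diam)
        )
    return branches


def read_io_curves(path: str | Path, tol: float = 0.01) -> list[IOCurve]:
    """Read IO-curve tables (columns dendrite_id, n_syn, expected_mV, actual_mV)."""
    df = pd.read_csv(path)
    curves = []
    for did, grp in df.groupby("dendrite_id"):
        grp = grp.sort_values("n_syn")
        unitary = float(grp["expected_mV"].iloc[0] / grp["n_syn"].iloc[0])
        curves.append(
            IOCurve(
                n_syn=grp["n_syn"].to_numpy(),
                unitary=unitary,
                expected=grp["expected_mV"].to_numpy(),
                actual=grp["actual_mV"].to_numpy(),
                dendrite_id=int(did),
            )
        )
    return curves


def write_io_curves(curves: Sequence[IOCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for n, e, a in zip(c.n_syn, c.expected, c.actual):
            rows.append({"dendrite_id": c.dendrite_id, "n_syn": n, "expected_mV": e, "actual_mV": a})
    pd.DataFrame(rows).to_csv(path, index=False)
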