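"""ANN abstractions of a fast-spiking basket cell, fitted to rate data.

Four two-layer feed-forward reductions map a per-dendrite synapse-count
vector to a mean firing rate:

* **linear** — one hidden layer of five linear units (identical to ReLU
  under the positivity constraint);
* **supralinear** — same architecture with logistic-sigmoid hidden units;
* **sublinear** — same with the saturating activation y = (x+2)**0.7 - 2;
* **bimodal** (modular) — the hidden layer splits into a sigmoidal block
  fed only by the supralinear dendrites and a sublinear block fed only by
  the sublinear dendrites, both projecting linearly to the output.

All weights (and biases) are constrained to be nonnegative — the
biophysical cells receive only excitatory input — by projecting after each
Adam update.  Training minimizes mean squared error on a random 80% split;
the held-out 20% is used for evaluation only.

The module follows a Model/Results layout: :class:`SurrogateANN` holds the
data and architecture, ``fit()`` returns :class:`ANNFitResults` carrying
the trained weights, loss trace, and R-squared diagnostics with a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import rng_for
from .integration import IntegrationMode

__all__ = [
    "activation",
    "build_input_vector",
    "SurrogateANN",
    "ANNFitResults",
    "challenge_subsets",
    "r_squared",
    "compare_architectures",
    "fixed_count_comparison",
]

ARCHITECTURES = ("linear", "supralinear", "sublinear", "bimodal")
HIDDEN_WIDTH = 5  # hidden units per (block of the) hidden layer


def activation(kind: str, x):
    """Hidden-layer activation: 'linear', 'sigmoid' or 'sublinear'.

    The sublinear form is exactly ``(x + 2)**0.7 - 2`` and is only defined
    for x >= -2 (guaranteed here by the nonnegative weights and inputs).
    """
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return x
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "sublinear":
        if np.any(x < -2.0):
            raise ValueError("sublinear activation requires x >= -2")
        return (x + 2.0) ** 0.7 - 2.0
    raise ValueError(f"unknown activation: {kind!r}")


def _activation_grad(kind: str, x):
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return np.ones_like(x)
    if kind == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-x))
        return s * (1.0 - s)
    if kind == "sublinear":
        return 0.7 * (x + 2.0) ** (-0.3)
    raise ValueError(f"unknown activation: {kind!r}")


def build_input_vector(counts, modes, architecture: str = "bimodal"):
    """Order a synapse-count vector for the given architecture.

    For the bimodal modular network the vector is reordered so the
    supralinear-dendrite block comes first and the sublinear block second
    (returning ``(vector, n_supra)``); any other architecture keeps the
    flat dendrite order (``n_supra`` is None).  Every dendrite must carry a
    mode label for the modular ordering.
    """
    counts = np.asarray(counts, dtype=float)
    if architecture != "bimodal":
        return counts.copy(), None
    if modes is None or len(modes) != counts.shape[-1]:
        raise ValueError("every dendrite needs a mode label for the modular network")
    modes = [IntegrationMode(m) for m in modes]
    supra = [i for i, m in enumerate(modes) if m is IntegrationMode.SUPRALINEAR]
    other = [i for i, m in enumerate(modes) if m is not IntegrationMode.SUPRALINEAR]
    order = supra + other
    return counts[..., order], len(supra)


def r_squared(y_true, y_pred) -> tuple[float, float]:
    """(coefficient of determination, squared Pearson correlation).

    The coefficient of determination 1 - SS_res/SS_tot can be negative on
    held-out data; the squared Pearson correlation is reported alongside
    because "R^2" is used for both conventions in the field.
    """
    y, p = np.asarray(y_true, float), np.asarray(y_pred, float)
    if len(y) < 2:
        raise ValueError("need at least two points to evaluate R^2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0, 0.0
    cod = 1.0 - np.sum((y - p) ** 2) / ss_tot
    if p.std() == 0:
        return float(cod), 0.0
    r = np.corrcoef(y, p)[0, 1]
    return float(cod), float(r**2)


def challenge_subsets(X, y, counts=(20, 40, 60)):
    """Partition rows by total synapse count (the fixed-count challenge).

    Rows whose inputs sum to one of `counts` go to that subset; empty
    subsets are flagged by omission.  Returns {count: (X_sub, y_sub)}.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    nsyn = np.rint(X.sum(axis=1)).astype(int)
    out = {}
    for c in counts:
        m = nsyn == c
        if np.any(m):
            out[int(c)] = (X[m], y[m])
    return out


@dataclass
class _Params:
    """Nonnegative weights of one two-layer net (per hidden block)."""

    w1: list  # per block: (hidden, d_block)
    b1: list
    w2: list  # per block: (hidden,)
    b2: float

    def flat(self):
        for arr in (*self.w1, *self.b1, *self.w2):
            yield arr


class ANNFitResults:
    """Trained network, loss trace and evaluation record."""

    def __init__(self, model: "SurrogateANN", params: _Params, loss_trace, split_seed: int,
                 train_idx, test_idx):
        self.model = model
        self.params = params
        self.loss_trace = np.asarray(loss_trace)
        self.split_seed = split_seed
        self.train_idx = np.asarray(train_idx)
        self.test_idx = np.asarray(test_idx)

    # predictions -----------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        out = self.model._forward(np.atleast_2d(np.asarray(X, float)), self.params)[0]
        return out * self.model.y_scale

    @property
    def weights_nonnegative(self) -> bool:
        return all(np.all(a >= 0) for a in self.params.flat())

    # evaluation ------------------------------------------------------------

    def r2(self, X=None, y=None) -> float:
        """Coefficient of determination on the held-out split (default)."""
        if X is None:
            X, y = self.model.X[self.test_idx], self.model.y[self.test_idx]
        return r_squared(y, self.predict(X))[0]

    def evaluation(self, counts=(20, 40, 60)) -> pd.DataFrame:
        """Held-out R^2 overall and per fixed-synapse-count subset."""
        X, y = self.model.X[self.test_idx], self.model.y[self.test_idx]
        rows = []
        cod, pr2 = r_squared(y, self.predict(X))
        rows.append({"subset": "pooled", "n": len(y), "r2": cod, "pearson_r2": pr2})
        for c, (Xs, ys) in challenge_subsets(X, y, counts).items():
            if len(ys) < 2:
                continue
            cod, pr2 = r_squared(ys, self.predict(Xs))
            rows.append({"subset": str(c), "n": len(ys), "r2": cod, "pearson_r2": pr2})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ev = self.evaluation()
        lines = [
            f"Two-stage ANN fit ({self.model.architecture})",
            f"  hidden width      : {HIDDEN_WIDTH} per block",
            f"  train / test rows : {len(self.train_idx)} / {len(self.test_idx)}",
            f"  final train loss  : {self.loss_trace[-1]:.4f} (MSE, scaled units)",
            f"  weights >= 0      : {self.weights_nonnegative}",
            "  held-out R^2:",
        ]
        for _, row in ev.iterrows():
            lines.append(
                f"    {row['subset']:>7}  n={int(row['n']):4d}  "
                f"R2={row['r2']:+.4f}  pearson^2={row['pearson_r2']:.4f}"
            )
        return "\n".join(lines)


class SurrogateANN:
    """Model object: one ANN architecture plus its (X, y) dataset.

    Parameters
    ----------
    X : (n, d) per-dendrite synapse counts
    y : (n,) mean firing rates (Hz)
    architecture : one of 'linear', 'supralinear', 'sublinear', 'bimodal'
    modes : per-dendrite integration-mode labels (required for 'bimodal')
    """

    def __init__(self, X, y, architecture: str = "bimodal", modes=None):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("X and y must be nonempty and equal-length")
        self.architecture = architecture
        X_ordered, n_supra = build_input_vector(X, modes, architecture)
        self.X = X_ordered
        self.y = y
        # targets are trained in units of their own spread (conditioning);
        # predictions are mapped back to Hz
        self.y_scale = float(y.std()) or 1.0
        if architecture == "bimodal":
            self._blocks = [("sigmoid", slice(0, n_supra)), ("sublinear", slice(n_supra, X.shape[1]))]
        else:
            act = {"linear": "linear", "supralinear": "sigmoid", "sublinear": "sublinear"}[
                architecture
            ]
            self._blocks = [(act, slice(0, X.shape[1]))]

    @classmethod
    def from_dataset(cls, dataset, morph, architecture: str = "bimodal") -> "SurrogateANN":
        """Build from a :class:`~twostage.synth.SurrogateDataset` + morphology."""
        modes = [b.mode for b in morph]
        return cls(dataset.X, dataset.rates, architecture, modes=modes)

    # forward / backward ----------------------------------------------------

    def _forward(self, X, p: _Params):
        pre, hid = [], []
        out = np.full(len(X), p.b2)
        for (act, sl), w1, b1, w2 in zip(self._blocks, p.w1, p.b1, p.w2):
            z = X[:, sl] @ w1.T + b1
            h = activation(act, z)
            pre.append(z)
            hid.append(h)
            out = out + h @ w2
        return out, pre, hid

    def fit(
        self,
        lr: float = 3e-3,
        epochs: int = 2000,
        batch_size: int = 64,
        seed: int = 0,
        split: float = 0.8,
        patience: int = 200,
        tol: float = 1e-4,
    ) -> ANNFitResults:
        """Train with minibatch Adam + nonnegativity projection.

        A random `split` fraction of rows trains the network; the rest are
        held out and never touched by the optimizer.  Training stops early
        when the epoch loss has not improved by `tol` for `patience`
        epochs.  Raises on a non-finite loss.
        """
        rng = rng_for(seed, f"ann.fit.{self.architecture}")
        n = len(self.X)
        perm = rng.permutation(n)
        n_train = max(1, int(round(split * n)))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        Xt, yt = self.X[train_idx], self.y[train_idx] / self.y_scale

        p = _Params(w1=[], b1=[], w2=[], b2=0.0)
        for _, sl in self._blocks:
            d = sl.stop - sl.start
            p.w1.append(rng.uniform(0.0, 0.1, size=(HIDDEN_WIDTH, max(d, 0))))
            p.b1.append(rng.uniform(0.0, 0.1, size=HIDDEN_WIDTH))
            p.w2.append(rng.uniform(0.0, 1.0, size=HIDDEN_WIDTH))

        # Adam state per parameter array (+ scalar b2)
        arrays = [*p.w1, *p.b1, *p.w2]
        m = [np.zeros_like(a) for a in arrays] + [0.0]
        v = [np.zeros_like(a) for a in arrays] + [0.0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        loss_trace = []
        best, since_best = np.inf, 0
        for epoch in range(epochs):
            order = rng.permutation(len(Xt))
            epoch_loss = 0.0
            for start in range(0, len(Xt), batch_size):
                idx = order[start : start + batch_size]
                Xb, yb = Xt[idx], yt[idx]
                out, pre, hid = self._forward(Xb, p)
                err = out - yb
                loss = float(np.mean(err**2))
                epoch_loss += loss * len(idx)
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss; lower the learning rate")
                dout = 2.0 * err / len(idx)
                grads = []
                g_b2 = dout.sum()
                for (act, sl), w1, b1, w2, z, h in zip(
                    self._blocks, p.w1, p.b1, p.w2, pre, hid
                ):
                    g_w2 = h.T @ dout
                    dh = np.outer(dout, w2) * _activation_grad(act, z)
                    g_w1 = dh.T @ Xb[:, sl]
                    g_b1 = dh.sum(axis=0)
                    grads.append((g_w1, g_b1, g_w2))
                flat_grads = (
                    [g[0] for g in grads] + [g[1] for g in grads] + [g[2] for g in grads]
                )
                step += 1
                corr1 = 1.0 - beta1**step
                corr2 = 1.0 - beta2**step
                for k, (arr, g) in enumerate(zip(arrays, flat_grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g**2
                    arr -= lr * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + eps)
                    np.clip(arr, 0.0, None, out=arr)  # positivity projection
                m[-1] = beta1 * m[-1] + (1 - beta1) * g_b2
                v[-1] = beta2 * v[-1] + (1 - beta2) * g_b2**2
                p.b2 = max(0.0, p.b2 - lr * (m[-1] / corr1) / (np.sqrt(v[-1] / corr2) + eps))
            epoch_loss /= len(Xt)
            loss_trace.append(epoch_loss)
            if epoch_loss < best - tol:
                best, since_best = epoch_loss, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        return ANNFitResults(self, p, loss_trace, seed, train_idx, test_idx)


# ---------------------------------------------------------------------------
# Architecture comparisons


def compare_architectures(
    X, y, modes, architectures=("linear", "bimodal"), seed: int = 0, **fit_kwargs
) -> pd.DataFrame:
    """Fit each architecture on the same data; held-out R^2 side by side.

    All architectures share the same row split seed, so they are evaluated
    on identical held-out rows.
    """
    rows = []
    for arch in architectures:
        res = SurrogateANN(X, y, arch, modes=modes).fit(seed=seed, **fit_kwargs)
        rows.append({"architecture": arch, "r2": res.r2(), "n_test": len(res.test_idx)})
    return pd.DataFrame(rows)


def fixed_count_comparison(
    X,
    y,
    modes,
    counts=(20, 40, 60),
    architectures=("linear", "bimodal"),
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """The fixed-synapse-count challenge: one model per count per architecture.

    Rows with exactly `count` total synapses form a dataset of constant
    input power whose rate variance is driven purely by synapse location;
    each architecture is trained and evaluated (80/20) on that dataset
    alone.  Returns a tidy frame (count, architecture, r2, n_rows).
    """
    rows = []
    for count, (Xs, ys) in challenge_subsets(X, y, counts).items():
        for arch in architectures:
            res = SurrogateANN(Xs, ys, arch, modes=modes).fit(seed=seed, **fit_kwargs)
            rows.append(
                {"count": count, "architecture": arch, "r2": res.r2(), "n_rows": len(ys)}
            )
    return pd.DataFrame(rows)
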