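"""Dual-data construction and per-sample losses.

The tests in this package ask whether a set of "hypothesized features"
``S`` is relevant to predicting an outcome.  The central device is the
*dual* dataset ``Z``: a copy of the features with every column in ``S``
overwritten by an irrelevant constant ``M``.  By construction ``Z_S`` is
independent of everything, so comparing the best achievable risk with
``X`` against the best achievable risk with ``Z`` isolates the predictive
contribution of ``X_S`` given the remaining features.

This module provides the dual transform, a joint row permutation of the
hypothesized columns (used by the permutation-based tuning scheme),
per-sample loss functions, and an exact finite-support oracle for the
population risk difference ``R(f*) - R_S(g*)`` used to validate the
conditional-independence / risk-invariance equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "FeatureSet",
    "LossSpec",
    "DiscreteJoint",
    "make_dual",
    "permute_features",
    "per_sample_loss",
    "risk_difference_oracle",
    "read_delimited",
    "write_delimited",
    "parse_region",
]


class InvalidFeatureSetError(ValueError):
    """Feature indices outside the dataset's columns."""


class DegeneratePermutationError(ValueError):
    """Permutation requested on fewer than two rows."""


@dataclass(frozen=True)
class Dataset:
    """Feature matrix plus outcome vector.

    ``features`` is an (N, d) float array.  ``outcome`` is length N:
    real-valued for regression, integer class labels for classification.
    """

    features: np.ndarray
    outcome: np.ndarray
    column_names: tuple[str, ...] | None = None

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.outcome)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need at least one row and one column")
        if y.shape[0] != X.shape[0]:
            raise ValueError("outcome length must equal the number of rows")
        if np.isnan(X).any() or (y.dtype.kind == "f" and np.isnan(y).any()):
            raise ValueError("missing values are not supported")
        if self.column_names is not None and len(self.column_names) != X.shape[1]:
            raise ValueError("column_names length must equal d")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "outcome", y)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, rows) -> "Dataset":
        """Row-subset view (copying) with the same columns."""
        rows = np.asarray(rows)
        return Dataset(self.features[rows], self.outcome[rows], self.column_names)


@dataclass(frozen=True)
class FeatureSet:
    """Hypothesized feature indices (0-based) plus the mask constant M."""

    indices: tuple[int, ...]
    mask_value: float = 0.0

    def __post_init__(self):
        idx = tuple(sorted(int(i) for i in self.indices))
        if any(i < 0 for i in idx):
            raise InvalidFeatureSetError("negative feature index")
        if len(set(idx)) != len(idx):
            raise InvalidFeatureSetError("duplicate feature index")
        object.__setattr__(self, "indices", idx)

    def validate(self, data: Dataset, allow_empty: bool = True) -> None:
        if not allow_empty and not self.indices:
            raise InvalidFeatureSetError("empty hypothesized feature set")
        if self.indices and self.indices[-1] >= data.n_features:
            raise InvalidFeatureSetError(
                f"feature index {self.indices[-1]} out of range for d={data.n_features}"
            )


@dataclass(frozen=True)
class LossSpec:
    """Per-sample loss: 'squared', 'cross_entropy' or 'zero_one'.

    No averaging happens inside the loss; the test statistics need the
    per-sample values.  ``prob_floor`` clips predicted probabilities for
    the cross-entropy loss (zero probabilities would give infinite loss).
    """

    name: str = "squared"
    prob_floor: float = 1e-12

    _ALLOWED = ("squared", "cross_entropy", "zero_one")

    def __post_init__(self):
        if self.name not in self._ALLOWED:
            raise ValueError(f"loss must be one of {self._ALLOWED}")


def make_dual(data: Dataset, fs: FeatureSet) -> Dataset:
    """Replace the hypothesized columns by the mask constant M.

    Columns outside ``fs`` and the outcome are untouched; the input is not
    modified.  Idempotent by construction.
    """
    fs.validate(data)
    Z = data.features.copy()
    if fs.indices:
        Z[:, list(fs.indices)] = fs.mask_value
    return replace(data, features=Z)


def permute_features(data: Dataset, fs: FeatureSet, rng: np.random.Generator) -> Dataset:
    """Jointly row-permute the hypothesized columns with one uniform permutation.

    A single permutation pi is shared by every column in ``fs``, which
    preserves the dependence within the hypothesized set while breaking
    its link to the outcome and the remaining features.
    """
    fs.validate(data, allow_empty=False)
    if data.n_samples < 2:
        raise DegeneratePermutationError("need at least 2 rows to permute")
    pi = rng.permutation(data.n_samples)
    X = data.features.copy()
    cols = list(fs.indices)
    X[:, cols] = X[np.ix_(pi, cols)]
    return replace(data, features=X)


def per_sample_loss(predictions, outcomes, loss: LossSpec) -> np.ndarray:
    """Vector of per-sample losses l(f(x_i), y_i).

    squared:        (y - yhat)^2 for real predictions;
    cross_entropy:  -log p_hat[y] for probability-vector predictions;
    zero_one:       1{yhat != y} for label predictions.
    """
    y = np.asarray(outcomes)
    if loss.name == "squared":
        yhat = np.asarray(predictions, dtype=float).reshape(-1)
        if yhat.shape[0] != y.shape[0]:
            raise ValueError("prediction/outcome length mismatch")
        return (y.astype(float) - yhat) ** 2
    if loss.name == "cross_entropy":
        P = np.asarray(predictions, dtype=float)
        if P.ndim != 2 or P.shape[0] != y.shape[0]:
            raise ValueError("cross_entropy needs an (N, K) probability matrix")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("probability rows must sum to 1 within 1e-8")
        labels = y.astype(int)
        p_y = P[np.arange(P.shape[0]), labels]
        return -np.log(np.clip(p_y, loss.prob_floor, None))
    # zero_one
    yhat = np.asarray(predictions).reshape(-1)
    if yhat.shape[0] != y.shape[0]:
        raise ValueError("prediction/outcome length mismatch")
    return (yhat != y).astype(float)


# ---------------------------------------------------------------------------
# Exact discrete oracle for the population risk difference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteJoint:
    """Finite-support joint distribution of (X_S, X_Sc, Y).

    ``x_s`` (k, a) and ``x_c`` (k, b) hold the hypothesized / remaining
    feature values of the k support points; ``y`` their outcomes and
    ``probs`` their probabilities (nonnegative, summing to 1).
    """

    x_s: np.ndarray
    x_c: np.ndarray
    y: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if (p < -1e-15).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        k = p.shape[0]
        xs = np.atleast_2d(np.asarray(self.x_s, dtype=float))
        xc = np.atleast_2d(np.asarray(self.x_c, dtype=float))
        if xs.shape[0] != k or xc.shape[0] != k or np.asarray(self.y).shape[0] != k:
            raise ValueError("support arrays must share their first dimension")
        object.__setattr__(self, "x_s", xs)
        object.__setattr__(self, "x_c", xc)
        object.__setattr__(self, "y", np.asarray(self.y))
        object.__setattr__(self, "probs", p)


def _group_keys(*arrays) -> np.ndarray:
    """Integer group ids for rows of the horizontally stacked arrays."""
    stacked = np.column_stack([np.atleast_2d(a.T).T for a in arrays])
    _, ids = np.unique(stacked, axis=0, return_inverse=True)
    return ids


def _bayes_risk(joint: DiscreteJoint, cond_ids: np.ndarray, loss: LossSpec) -> float:
    """Exact risk of the Bayes rule predicting Y from the grouping ``cond_ids``.

    For the squared loss the Bayes rule is the conditional mean and the
    risk is the expected conditional variance.  For cross-entropy it is
    the conditional pmf and the risk is the conditional entropy.
    """
    p = joint.probs
    y = joint.y
    risk = 0.0
    for g in np.unique(cond_ids):
        sel = cond_ids == g
        pg = p[sel]
        mass = pg.sum()
        if mass <= 0:
            continue
        w = pg / mass
        if loss.name == "squared":
            yy = y[sel].astype(float)
            mu = float(w @ yy)
            risk += mass * float(w @ (yy - mu) ** 2)
        else:  # cross_entropy: conditional entropy sum -p log p(y|group)
            for yv in np.unique(y[sel]):
                py = w[y[sel] == yv].sum()
                if py > 0:
                    risk += -mass * py * np.log(py)
    return risk


def conditional_pmfs(joint: DiscreteJoint):
    """P(Y=y | X_S, X_Sc) and P(Y=y | X_Sc) tabulated on the support.

    Returns two dicts mapping (group key..., y value) -> probability,
    keyed by the full conditioning set and the masked one respectively.
    Used to check the cross-entropy equivalence between risk invariance
    and conditional independence by enumeration.
    """
    full_ids = _group_keys(joint.x_s, joint.x_c)
    masked_ids = _group_keys(joint.x_c)
    out = []
    for ids in (full_ids, masked_ids):
        pmf = {}
        for g in np.unique(ids):
            sel = ids == g
            mass = joint.probs[sel].sum()
            if mass <= 0:
                continue
            for yv in np.unique(joint.y[sel]):
                pmf[(g, yv)] = joint.probs[sel][joint.y[sel] == yv].sum() / mass
        out.append(pmf)
    full_pmf, masked_pmf = out
    # align: for every support point, pair the two conditional probabilities
    pairs = []
    for i in range(joint.probs.shape[0]):
        if joint.probs[i] <= 0:
            continue
        yv = joint.y[i]
        pairs.append((full_pmf[(full_ids[i], yv)], masked_pmf[(masked_ids[i], yv)]))
    return np.array(pairs)


def risk_difference_oracle(joint: DiscreteJoint, loss: LossSpec) -> float:
    """Exact R(f*) - R_S(g*) by enumeration over the finite support.

    f* is the Bayes rule on (X_S, X_Sc); g* the Bayes rule on the dual
    variable, i.e. on X_Sc alone (the masked columns are constant).  The
    difference is always <= 0: masking cannot improve the Bayes risk.
    Conditional independence of Y and X_S given X_Sc forces equality, and
    under cross-entropy equality holds only under conditional independence.
    """
    if loss.name not in ("squared", "cross_entropy"):
        raise ValueError("oracle supports squared and cross_entropy losses only")
    full_ids = _group_keys(joint.x_s, joint.x_c)
    masked_ids = _group_keys(joint.x_c)
    return _bayes_risk(joint, full_ids, loss) - _bayes_risk(joint, masked_ids, loss)


# ---------------------------------------------------------------------------
# External interfaces: delimited text and grid-region specifications
# ---------------------------------------------------------------------------


def read_delimited(path, outcome: str, sep: str = ",") -> Dataset:
    """Load a header-ed delimited file into a Dataset.

    ``outcome`` names the outcome column; every other column is a feature.
    Rows with missing values are rejected.
    """
    df = pd.read_csv(path, sep=sep)
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not in file")
    if df.isna().any().any():
        raise ValueError("missing values are not supported")
    y = df[outcome].to_numpy()
    Xdf = df.drop(columns=[outcome])
    return Dataset(Xdf.to_numpy(dtype=float), y, tuple(Xdf.columns))


def write_delimited(data: Dataset, path, outcome: str = "y", sep: str = ",") -> None:
    names = data.column_names or tuple(f"x{j}" for j in range(data.n_features))
    df = pd.DataFrame(data.features, columns=list(names))
    df[outcome] = data.outcome
    df.to_csv(path, sep=sep, index=False)


def parse_region(spec: str, height: int, width: int) -> tuple[int, ...]:
    """Convert "rows a:b, cols c:d" on an H x W grid to flattened indices.

    Ranges are half-open and 0-based; flattening is row-major, matching
    the layout of a flattened image.  Example on a 5x5 grid:
    "rows 2:4, cols 0:3" -> (10, 11, 12, 15, 16, 17).
    """
    import re

    m = re.fullmatch(
        r"\s*rows\s+(\d+)\s*:\s*(\d+)\s*,\s*cols\s+(\d+)\s*:\s*(\d+)\s*", spec
    )
    if not m:
        raise ValueError(f"cannot parse region spec {spec!r}")
    r0, r1, c0, c1 = map(int, m.groups())
    if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
        raise ValueError("region out of range")
    return tuple(r * width + c for r in range(r0, r1) for c in range(c0, c1))
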