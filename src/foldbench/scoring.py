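"""Score transformations and partition-curve machinery over (n, r) data.

A structure comparison is summarized by its matched length ``n`` and RMSD
``r``.  Beyond the simple ratios ``n/r`` and ``n^2/r``, two curve families in
the (n, r) plane are used:

* the Gaussian-damped random-similarity limit
  ``r = sqrt(n) * (1 - exp(-n^2 / (2 sigma^2)))`` with ``sigma = 70`` by
  default (dividing a comparison's RMSD by this limit gives the normalized
  score whose significance envelope is values below 1);

* the partition curve ``r = a * sqrt(n) / (1 + exp((bN - n + c) / d))``, a
  square-root growth gated by a sigmoid that switches on at ``n = bN + c``
  (where the factor is one half; ``N`` is the dataset's maximum matched
  length), so that short alignments are suppressed just as under the
  Gaussian limit but with a tunable switch location and steepness.  The
  value of ``a`` that makes the curve pass through a point doubles as that
  comparison's score (lower is better), and the curve that best separates
  same-fold from different-fold comparisons is found by maximizing
  ``s = 100 (TP - w FP) / (TP + FN)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonRecord",
    "ScoringConfig",
    "PartitionCurve",
    "BenchmarkCounts",
    "PartitionResult",
    "gaussian_limit",
    "normalized_sap_score",
    "ratio_scores",
    "curve_value",
    "curve_score",
    "partition_counts",
    "s_score",
    "optimize_partition",
    "rank_metric",
    "discrimination_curve",
    "records_to_frame",
    "read_records_tsv",
    "write_records_tsv",
]


@dataclass(frozen=True)
class ComparisonRecord:
    """One pairwise comparison: identifiers, (n, r), native scores and labels."""

    idA: str
    idB: str
    n: int
    r: float
    tm: float | None = None
    native_score: float | None = None
    same_fold: bool | None = None
    edit_dist: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if self.same_fold is not None and self.edit_dist is not None:
            if self.same_fold != (self.edit_dist == 0):
                raise ValueError("same_fold inconsistent with edit_dist")


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the Gaussian-damped limit.

    ``half_bell=True`` reads the damping exponent as ``-n^2 / (2 sigma^2)``,
    i.e. sigma is the standard deviation of the half bell; the alternative
    literal reading ``-n^2 / sigma^2`` is available with ``half_bell=False``.
    """

    sigma: float = 70.0
    half_bell: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class PartitionCurve:
    """Parameters (a, b, c, d, N) of the sigmoid-switched square-root boundary."""

    a: float
    b: float
    c: float
    d: float
    N: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("switch steepness d must be positive")
        if self.N <= 0:
            raise ValueError("maximum matched length N must be positive")

    @property
    def switch_point(self) -> float:
        """Matched length at which the sigmoid factor equals one half."""
        return self.b * self.N + self.c

    def to_line(self) -> str:
        return f"{self.a:.10g} {self.b:.10g} {self.c:.10g} {self.d:.10g} {self.N:.10g}"

    @classmethod
    def from_line(cls, line: str) -> "PartitionCurve":
        a, b, c, d, N = (float(x) for x in line.split())
        return cls(a, b, c, d, N)


@dataclass(frozen=True)
class BenchmarkCounts:
    """TP/FP/TN/FN tallies for a labelled comparison set under a curve."""

    TP: int
    FP: int
    TN: int
    FN: int
    w: float = 0.5

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def s(self) -> float:
        return s_score(self, self.w)

    @property
    def tp_fraction(self) -> float:
        """Fraction of the true (same-fold) records enclosed below the curve."""
        pos = self.TP + self.FN
        return self.TP / pos if pos else float("nan")


# ---------------------------------------------------------------------------
# closed-form scores

def gaussian_limit(n, sigma: float = 70.0, half_bell: bool = True):
    """Random-similarity RMSD limit ``sqrt(n) (1 - exp(-n^2 / (2 sigma^2)))``.

    Monotone increasing in ``n`` and asymptotic to ``sqrt(n)``; the Gaussian
    factor suppresses the limit at short lengths where super-secondary
    structure matches arise by chance.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise ValueError("n must be non-negative")
    denom = 2.0 * sigma**2 if half_bell else sigma**2
    out = np.sqrt(arr) * (1.0 - np.exp(-(arr**2) / denom))
    return float(out) if np.isscalar(n) or arr.ndim == 0 else out


def normalized_sap_score(r: float, n: int, sigma: float = 70.0, half_bell: bool = True) -> float:
    """RMSD divided by the Gaussian-damped limit; below 1 is significant."""
    if n <= 0:
        raise ValueError("normalized score undefined for n = 0")
    return float(r) / gaussian_limit(n, sigma, half_bell)


def ratio_scores(n: int, r: float) -> tuple[float, float]:
    """The simple pairwise scores ``n/r`` and ``n^2/r``.

    ``r = 0`` (an exact duplicate) maps to infinite scores so that duplicates
    outrank every finite comparison.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    if r == 0:
        return float("inf"), float("inf")
    return n / r, n * n / r


def _switch_factor(n, b: float, c: float, d: float, N: float):
    # sigmoid in n, 1/2 at n = bN + c, -> 1 for long matches
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((b * N - np.asarray(n, float) + c) / d))


def curve_value(n, curve: PartitionCurve):
    """Partition-curve RMSD bound at matched length *n*.

    ``a sqrt(n) / (1 + exp((bN - n + c)/d))``: square-root growth gated by a
    sigmoid that switches on at ``n = bN + c`` (where the factor is 1/2), so
    the boundary is suppressed at short lengths and tracks ``a sqrt(n)`` for
    long ones.
    """
    arr = np.asarray(n, dtype=float)
    out = curve.a * np.sqrt(arr) * _switch_factor(arr, curve.b, curve.c, curve.d, curve.N)
    return float(out) if np.isscalar(n) or arr.ndim == 0 else out


def curve_score(n, r, shape: PartitionCurve) -> float:
    """The unique scale ``a`` putting the curve through (n, r); lower is better."""
    if np.any(np.asarray(n) <= 0):
        raise ValueError("curve score undefined at n = 0 (curve passes the origin)")
    g = np.sqrt(np.asarray(n, float)) * _switch_factor(n, shape.b, shape.c, shape.d, shape.N)
    out = np.asarray(r, float) / g
    return float(out) if np.isscalar(n) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# partition and optimization

def partition_counts(records: Sequence[ComparisonRecord], curve: PartitionCurve, w: float = 0.5) -> BenchmarkCounts:
    """Count TP/FP/TN/FN against a curve (strictly below = positive).

    Same-fold records strictly below the curve are true positives; a record
    exactly on the curve counts as negative.
    """
    tp = fp = tn = fn = 0
    for rec in records:
        if rec.same_fold is None:
            raise ValueError(f"record {rec.idA}/{rec.idB} is unlabelled")
        below = rec.r < curve_value(rec.n, curve)
        if rec.same_fold:
            tp += below
            fn += not below
        else:
            fp += below
            tn += not below
    return BenchmarkCounts(TP=tp, FP=fp, TN=tn, FN=fn, w=w)


def s_score(counts: BenchmarkCounts, w: float | None = None) -> float:
    """Partition optimization score ``s = 100 (TP - w FP) / (TP + FN)``.

    Ignores the TN count, which is large and dataset-dependent; equals 100
    exactly when every same-fold record and no different-fold record lies
    below the curve.
    """
    if w is None:
        w = counts.w
    pos = counts.TP + counts.FN
    if pos == 0:
        raise ValueError("no true matches in dataset")
    return 100.0 * (counts.TP - w * counts.FP) / pos


@dataclass(frozen=True)
class PartitionResult:
    """Outcome of the partition-curve optimization."""

    curve: PartitionCurve
    counts: BenchmarkCounts
    s: float

    @property
    def tp_fraction(self) -> float:
        return self.counts.tp_fraction


def _best_threshold(
    a_vals: np.ndarray, is_true: np.ndarray, w: float, n_pos: int
) -> tuple[float, float, int, int]:
    """Best scale a for fixed shape: scan the piecewise-constant s over sorted a.

    Records are positive iff their pass-through scale is strictly below a, so
    s changes only at the distinct scales; ties are grouped.  Returns
    (s, a, TP, FP) with ties broken toward larger TP then smaller a.
    """
    order = np.argsort(a_vals, kind="stable")
    av = a_vals[order]
    tv = is_true[order]
    best = (-math.inf, math.inf, 0, 0)  # s, a, TP, FP
    tp = fp = 0
    finite_min = av[0] if len(av) else 1.0
    # k = 0: curve below every point
    s0 = 0.0
    cand_a = finite_min / 2.0 if np.isfinite(finite_min) and finite_min > 0 else 0.5
    best = (s0, cand_a, 0, 0)
    i = 0
    m = len(av)
    while i < m:
        j = i
        while j < m and av[j] == av[i]:
            tp += bool(tv[j])
            fp += not tv[j]
            j += 1
        # threshold strictly above av[i..j-1]
        if j < m:
            hi = av[j]
            cand_a = 0.5 * (av[i] + hi) if np.isfinite(hi) else av[i] * 1.5 + 1.0
        else:
            cand_a = av[i] * 1.5 + 1.0
        s = 100.0 * (tp - w * fp) / n_pos
        if (s, tp, -cand_a) > (best[0], best[2], -best[1]):
            best = (s, cand_a, tp, fp)
        i = j
    return best


def optimize_partition(
    records: Sequence[ComparisonRecord],
    w: float = 0.5,
    N: float | None = None,
    refine: bool = True,
) -> PartitionResult:
    """Fit the partition curve maximizing ``s`` over labelled (n, r) records.

    Coarse grid over the shape parameters (b in [0.3, 1.0] step 0.05, c in
    [-30, 30] step 5, d in [1, 20] step 1) with an exact 1-D scan over the
    scale ``a`` at each shape, followed by Nelder-Mead refinement of the
    shape from the best grid point.  Deterministic; ties are broken by larger
    TP then smaller a.  ``N`` defaults to the maximum matched length in the
    data.
    """
    recs = list(records)
    labels = np.array([bool(r.same_fold) for r in recs])
    if labels.all() or not labels.any():
        raise ValueError("records must contain both same-fold and different-fold labels")
    n_arr = np.array([r.n for r in recs], float)
    r_arr = np.array([r.r for r in recs], float)
    if N is None:
        N = float(n_arr.max())
    n_pos = int(labels.sum())

    sqrt_n = np.sqrt(n_arr)

    def a_values(b: float, c: float, d: float) -> np.ndarray:
        g = sqrt_n * _switch_factor(n_arr, b, c, d, N)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(g > 0, r_arr / np.where(g > 0, g, 1.0), np.inf)
        # r == 0 on a positive curve value: below for every a > 0
        a = np.where((r_arr == 0) & (g > 0), 0.0, a)
        return a

    def eval_shape(b: float, c: float, d: float):
        return _best_threshold(a_values(b, c, d), labels, w, n_pos)

    best_shape = None
    best = (-math.inf, math.inf, 0, 0)
    for b in np.arange(0.3, 1.0 + 1e-9, 0.05):
        for c in np.arange(-30.0, 30.0 + 1e-9, 5.0):
            for d in np.arange(1.0, 20.0 + 1e-9, 1.0):
                s, a, tp, fp = eval_shape(b, c, d)
                if (s, tp, -a) > (best[0], best[2], -best[1]):
                    best = (s, a, tp, fp)
                    best_shape = (float(b), float(c), float(d))

    if refine and best_shape is not None:
        from scipy.optimize import minimize

        def neg_s(x):
            b, c, d = x
            if d <= 0.05:
                return math.inf
            return -eval_shape(b, c, d)[0]

        res = minimize(
            neg_s, np.array(best_shape), method="Nelder-Mead",
            options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-6},
        )
        b, c, d = res.x
        if d > 0.05:
            s, a, tp, fp = eval_shape(b, c, d)
            if (s, tp, -a) > (best[0], best[2], -best[1]):
                best = (s, a, tp, fp)
                best_shape = (float(b), float(c), float(d))

    b, c, d = best_shape
    curve = PartitionCurve(a=best[1], b=b, c=c, d=d, N=N)
    counts = partition_counts(recs, curve, w=w)
    return PartitionResult(curve=curve, counts=counts, s=s_score(counts, w))


# ---------------------------------------------------------------------------
# ranking-based discrimination

def rank_metric(TP: int, FP: int) -> float:
    """Damped discrimination score ``(TP - FP) / (TP + FP + 100)``.

    The constant 100 in the denominator suppresses fluctuations at low
    counts when traversing a ranked list.
    """
    if TP < 0 or FP < 0:
        raise ValueError("counts must be non-negative")
    return (TP - FP) / (TP + FP + 100.0)


_RANK_KEYS = {
    "curve": (lambda rec, curve: curve_score(rec.n, rec.r, curve), True),
    "tm": (lambda rec, curve: rec.tm, False),
    "n_over_r": (lambda rec, curve: ratio_scores(rec.n, rec.r)[0], False),
    "n2_over_r": (lambda rec, curve: ratio_scores(rec.n, rec.r)[1], False),
    "native": (lambda rec, curve: rec.native_score, False),
}


def discrimination_curve(
    records: Sequence[ComparisonRecord],
    key: str = "curve",
    curve: PartitionCurve | None = None,
) -> pd.DataFrame:
    """Cumulative (FP, TP) growth and running rank metric along a ranked list.

    ``key`` selects the ranking: ``curve`` (pass-through scale a, ascending),
    ``tm``, ``n_over_r``, ``n2_over_r`` or ``native`` (all descending).
    Ties are broken deterministically by (idA, idB).
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}")
    fn, ascending = _RANK_KEYS[key]
    if key == "curve" and curve is None:
        raise ValueError("the 'curve' ranking requires a fitted PartitionCurve")
    scored = []
    for rec in records:
        if rec.same_fold is None:
            raise ValueError(f"record {rec.idA}/{rec.idB} is unlabelled")
        v = fn(rec, curve)
        if v is None:
            raise ValueError(f"record {rec.idA}/{rec.idB} lacks the score for key {key!r}")
        scored.append((v, rec))
    scored.sort(key=lambda t: ((t[0] if ascending else -t[0]), t[1].idA, t[1].idB))
    tp = fp = 0
    rows = []
    for v, rec in scored:
        if rec.same_fold:
            tp += 1
        else:
            fp += 1
        rows.append((rec.idA, rec.idB, v, fp, tp, rank_metric(tp, fp)))
    return pd.DataFrame(
        rows, columns=["idA", "idB", "score", "FP", "TP", "rank_metric"]
    )


# ---------------------------------------------------------------------------
# TSV interface

_COLUMNS = ["idA", "idB", "n", "r", "tm", "native_score", "same_fold", "edit_dist"]


def records_to_frame(records: Iterable[ComparisonRecord]) -> pd.DataFrame:
    rows = [
        (r.idA, r.idB, r.n, r.r, r.tm, r.native_score, r.same_fold, r.edit_dist)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_records_tsv(path, records: Iterable[ComparisonRecord]) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list[ComparisonRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ComparisonRecord(
                idA=str(row.idA),
                idB=str(row.idB),
                n=int(row.n),
                r=float(row.r),
                tm=None if pd.isna(row.tm) else float(row.tm),
                native_score=None if pd.isna(row.native_score) else float(row.native_score),
                same_fold=None if pd.isna(row.same_fold) else bool(row.same_fold),
                edit_dist=None if pd.isna(row.edit_dist) else int(row.edit_dist),
            )
        )
    return out
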