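"""Traditional data-driven careless-responding indices and flagging rules.

Each index returns an :class:`IndexScores` with a declared orientation:

================  ==========================  ===========================
method            computed on                 careless direction
================  ==========================  ===========================
``mahalanobis``   recoded responses           high (large distance)
``antonyms``      raw responses               high (near-zero/positive r)
``evenodd``       recoded responses           low (inconsistent halves)
``longstring``    raw responses               high (long identical runs)
``irv``           raw responses               two-sided (straightlining
                                              low, random responding high)
================  ==========================  ===========================

Undefined scores (zero within-person variance) are NaN and are never
flagged — a conservative choice with respect to Type-I flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ResponseMatrix, ScaleDesign, ValidationError, recode_reversed

__all__ = [
    "IndexScores",
    "FlagRule",
    "FlagVector",
    "TwoSidedFlags",
    "mahalanobis_scores",
    "antonym_scores",
    "evenodd_scores",
    "longstring_scores",
    "irv_scores",
    "apply_flag_rule",
    "max_run_lengths",
]


@dataclass(frozen=True)
class IndexScores:
    """Per-respondent scores of one detection index."""

    method: str
    scores: np.ndarray
    orientation: str  # 'high' | 'low' | 'two-sided'
    extras: dict = field(default_factory=dict)

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.scores).sum())


@dataclass(frozen=True)
class FlagRule:
    """Binary flagging rule.

    kind:
      * ``chi_square`` — flag score > chi2 quantile; params: alpha, df
      * ``absolute`` — flag beyond a fixed threshold in the careless
        direction; params: threshold, inclusive (default True)
      * ``percentile`` — flag beyond the sample percentile in the careless
        direction; params: q (percentile, 0-100)
      * ``two_sided_percentile`` — evaluate a low-tail and a high-tail
        percentile variant; params: lo, hi (percentiles)
    """

    kind: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FlagVector:
    """Binary predictions (True = flagged careless) plus the NA count."""

    flags: np.ndarray
    n_undefined: int = 0


@dataclass(frozen=True)
class TwoSidedFlags:
    """Both tails of a two-sided rule; the harness picks the better one."""

    low: FlagVector
    high: FlagVector


def mahalanobis_scores(X_recoded: ResponseMatrix, ridge: float = 0.0) -> IndexScores:
    """Squared Mahalanobis distances to the sample centroid.

    Computed with the sample mean and (n-1)-denominator covariance of the
    analysis sample itself, careless respondents included, on recoded data.
    ``ridge`` (lambda) adds lambda * trace(S)/J to the diagonal for n <= J
    situations; it is off by default because the benchmark samples have
    n (180) > J (60).
    """
    X = np.asarray(X_recoded.values, dtype=float)
    n, J = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    if ridge > 0:
        S = S + np.eye(J) * (ridge * np.trace(S) / J)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular covariance matrix; increase n or set ridge > 0"
        ) from None
    from scipy.linalg import solve_triangular

    sol = solve_triangular(L, Xc.T, lower=True)
    d2 = np.sum(sol**2, axis=0)
    return IndexScores("mahalanobis", d2, "high")


def _qualifying_pairs(X: np.ndarray, r_crit: float) -> tuple[np.ndarray, np.ndarray]:
    R = np.corrcoef(X.T)
    iu = np.triu_indices(X.shape[1], 1)
    mask = R[iu] <= r_crit
    return iu[0][mask], iu[1][mask]


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of paired rows; NaN where either row is constant."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((A**2).sum(axis=1))
    nb = np.sqrt((B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=1) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r

def antonym_scores(X: ResponseMatrix, r_crit: float = -0.20) -> IndexScores:
    """Psychometric-antonym consistency.

    All item pairs with sample correlation <= ``r_crit`` (raw, un-recoded
    data, across all scales) qualify; the score is each respondent's Pearson
    correlation between the first-element and second-element responses over
    those pairs. Consistent respondents score near -1; careless respondents
    near 0 or positive (orientation: high = careless).
    """
    first, second = _qualifying_pairs(np.asarray(X.values, float), r_crit)
    if len(first) < 3:
        raise ValidationError(
            f"only {len(first)} item pairs with r <= {r_crit}; "
            "use a laxer r_crit"
        )
    r = _rowwise_pearson(X.values[:, first].astype(float),
                         X.values[:, second].astype(float))
    return IndexScores("antonyms", r, "high",
                       extras={"n_pairs": int(len(first))})


def evenodd_scores(X: ResponseMatrix, design: ScaleDesign) -> IndexScores:
    """Even-odd consistency with Spearman-Brown adjustment.

    Reversed items are recoded first. Within each construct, items at odd
    positions (1st, 3rd, ...) and at even positions (2nd, 4th, ...) are
    averaged; the per-respondent Pearson correlation between the two
    half-score vectors across constructs is adjusted by r' = 2r / (1 + r).
    Orientation: low = careless.
    """
    Xr = recode_reversed(X, design).values.astype(float)
    odd_means, even_means = [], []
    for c in design.construct_ids:
        items = design.items_of(c)
        if len(items) < 2:
            raise ValidationError(f"construct {c} has fewer than 2 items")
        odd_means.append(Xr[:, items[0::2]].mean(axis=1))
        even_means.append(Xr[:, items[1::2]].mean(axis=1))
    O = np.column_stack(odd_means)
    E = np.column_stack(even_means)
    r = _rowwise_pearson(O, E)
    with np.errstate(invalid="ignore", divide="ignore"):
        adjusted = np.where(np.isclose(r, -1.0), -1.0, 2 * r / (1 + r))
    return IndexScores("evenodd", adjusted, "low")


def _run_lengths_row(row: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(row) != 0)
    edges = np.r_[-1, change, len(row) - 1]
    return np.diff(edges)


def max_run_lengths(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(max, mean) run length of identical consecutive entries per row."""
    n = values.shape[0]
    mx = np.empty(n, dtype=np.int64)
    mean = np.empty(n, dtype=float)
    for i in range(n):
        runs = _run_lengths_row(values[i])
        mx[i] = runs.max()
        mean[i] = runs.mean()
    return mx, mean


def longstring_scores(X: ResponseMatrix) -> IndexScores:
    """Longest run of identical consecutive responses, on raw data
    (before reverse coding), in administration order. High = careless."""
    mx, mean = max_run_lengths(X.values)
    return IndexScores("longstring", mx.astype(float), "high",
                       extras={"mean_run": mean})


def irv_scores(X: ResponseMatrix) -> IndexScores:
    """Intraindividual response variability: per-row sample SD (ddof=1)
    across all items, raw data. Two-sided: low = straightlining,
    high = random responding."""
    if X.n_items < 2:
        raise ValidationError("IRV needs at least 2 items")
    sd = np.std(X.values.astype(float), axis=1, ddof=1)
    return IndexScores("irv", sd, "two-sided")


def apply_flag_rule(scores: IndexScores, rule: FlagRule):
    """Turn index scores into binary flags.

    NaN scores are never flagged; their count is surfaced on the result.
    Two-sided rules return a :class:`TwoSidedFlags` with both tail variants;
    picking the better-performing tail (as the benchmark does, an
    acknowledged overestimate) is the caller's decision since it needs labels.
    """
    s = np.asarray(scores.scores, dtype=float)
    if s.size == 0:
        raise ValidationError("empty score vector")
    defined = ~np.isnan(s)
    n_und = int((~defined).sum())

    def _finish(mask):
        return FlagVector(np.where(defined, mask, False), n_und)

    if rule.kind == "chi_square":
        alpha = rule.params.get("alpha", 0.05)
        df = rule.params["df"]
        cutoff = stats.chi2.ppf(1 - alpha, df)
        return _finish(s > cutoff)
    if rule.kind == "absolute":
        thr = rule.params["threshold"]
        inclusive = rule.params.get("inclusive", True)
        if scores.orientation == "high":
            mask = s >= thr if inclusive else s > thr
        elif scores.orientation == "low":
            mask = s <= thr if inclusive else s < thr
        else:
            raise ValidationError("absolute rule needs a one-sided orientation")
        return _finish(mask)
    if rule.kind == "percentile":
        q = rule.params["q"]
        cut = np.nanpercentile(s, q)
        if scores.orientation == "high":
            return _finish(s > cut)
        if scores.orientation == "low":
            return _finish(s < cut)
        raise ValidationError("percentile rule needs a one-sided orientation")
    if rule.kind == "two_sided_percentile":
        lo = rule.params.get("lo", 5.0)
        hi = rule.params.get("hi", 95.0)
        lo_cut = np.nanpercentile(s, lo)
        hi_cut = np.nanpercentile(s, hi)
        return TwoSidedFlags(low=_finish(s < lo_cut), high=_finish(s > hi_cut))
    raise ValidationError(f"unknown rule kind {rule.kind!r}")
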