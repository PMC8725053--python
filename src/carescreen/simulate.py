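"""Labeled synthetic survey data with realistic ordinal structure.

Regular respondents are drawn from a Gaussian copula calibrated so that the
discretized 5-category items reproduce a target ordinal correlation matrix
with HEXACO-like structure: six constructs of ten items each, loadings of
mixed sign (reversed wording), weak between-construct correlations, and a
mean off-diagonal item intercorrelation magnitude near .05 with entries
confined to [-.45, .63].

Careless respondents come in three styles:

* ``random`` — iid uniform over the K categories (20% each for K=5),
* ``midpoint`` — concentrated on the scale middle (5/20/50/20/5 %),
* ``pattern`` — a repeating ascending run between two random categories
  (e.g. 1-2-3-1-2-3), tiled across the questionnaire.

Response-time paradata are log-normal at the item level with heavily
overlapping distributions across conditions and a faster careless median,
mirroring the qualitative shape of real screening studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import LabeledDataset, ResponseMatrix, RTMatrix, ScaleDesign, ValidationError

__all__ = [
    "OrdinalGeneratorSpec",
    "RTGeneratorParams",
    "RANDOM_PROBS",
    "MIDPOINT_PROBS",
    "build_hexaco_like_corr",
    "default_marginals",
    "calibrate_latent_corr",
    "implied_ordinal_corr",
    "make_generator_spec",
    "sample_regular",
    "sample_random_careless",
    "sample_midpoint_careless",
    "sample_pattern_careless",
    "sample_response_times",
    "assemble_condition",
    "nearest_positive_definite",
]

#: Uniform category probabilities of the random careless style (K=5).
RANDOM_PROBS = (0.20, 0.20, 0.20, 0.20, 0.20)
#: Midpoint careless style: mass concentrated on the scale middle.
MIDPOINT_PROBS = (0.05, 0.20, 0.50, 0.20, 0.05)

#: Default regular-responder category profile (agreement-leaning unimodal).
_BASE_MARGINAL = np.array([0.05, 0.12, 0.22, 0.38, 0.23])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def nearest_positive_definite(R: np.ndarray, eig_floor: float = 1e-6):
    """Eigenvalue-clipped positive-definite repair with unit-diagonal rescale.

    Returns the repaired matrix and the maximum absolute entry drift.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() > eig_floor:
        return R.copy(), 0.0
    w = np.clip(w, eig_floor, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2, float(np.max(np.abs(R2 - R)))


def build_hexaco_like_corr(
    design: ScaleDesign,
    loading_range: tuple[float, float] = (0.50, 0.79),
    seed=0,
    reversed_loading_range: tuple[float, float] | None = None,
    construct_corr_range: tuple[float, float] = (0.0, 0.20),
    facet_bump: float = 0.18,
    mean_abs_target: float | None = None,
    bounds: tuple[float, float] = (-0.45, 0.63),
) -> np.ndarray:
    """Target ordinal correlation matrix from a factor model per construct.

    Loading magnitudes are uniform on ``loading_range``; items flagged
    reversed in the design carry negative loadings (so raw-scale
    correlations of mixed sign arise, as in real keyed inventories) drawn
    from ``reversed_loading_range``, which defaults to a weaker band
    (0.9*lo, 0.72*hi) so that opposite-keyed pairs stay within the lower
    bound while same-keyed pairs can reach the upper bound. Construct
    intercorrelations are uniform on ``construct_corr_range``. On top of
    the factor structure, consecutive same-construct item pairs receive a
    ``facet_bump`` toward their keyed sign (clipped to ``bounds``),
    mimicking the facet substructure of real inventories. If
    ``mean_abs_target`` is given, the off-diagonal is shrunk so the mean
    absolute intercorrelation lands on it; no entry ever leaves ``bounds``.
    """
    if len(design.construct_ids) < 2:
        raise ValidationError("need at least 2 constructs")
    lo, hi = loading_range
    if not (0 <= lo <= hi <= 1):
        raise ValidationError(f"infeasible loading_range {loading_range}")
    if reversed_loading_range is None:
        reversed_loading_range = (0.9 * lo, 0.72 * hi)
    rlo, rhi = reversed_loading_range
    rng = _rng(seed)
    J = design.n_items
    C = len(design.construct_ids)
    lam = np.where(
        design.reversed_items,
        -rng.uniform(rlo, rhi, size=J),
        rng.uniform(lo, hi, size=J),
    )

    Phi = np.eye(C)
    iu = np.triu_indices(C, 1)
    vals = rng.uniform(*construct_corr_range, size=len(iu[0]))
    Phi[iu] = vals
    Phi.T[iu] = vals
    Phi, _ = nearest_positive_definite(Phi)

    L = np.zeros((J, C))
    cid_index = {c: k for k, c in enumerate(design.construct_ids)}
    for j in range(J):
        L[j, cid_index[design.constructs[j]]] = lam[j]
    R = L @ Phi @ L.T

    lo_b, hi_b = bounds
    for c in design.construct_ids:
        items = design.items_of(c)
        for k in range(0, len(items) - 1, 2):
            i1, i2 = items[k], items[k + 1]
            s = np.sign(lam[i1] * lam[i2])
            bumped = np.clip(R[i1, i2] + s * facet_bump, lo_b, hi_b)
            R[i1, i2] = R[i2, i1] = bumped
    np.fill_diagonal(R, 1.0)

    if mean_abs_target is not None:
        off = R[~np.eye(J, dtype=bool)]
        mean_abs = np.mean(np.abs(off))
        alpha = 1.0 if mean_abs == 0 else min(1.0, mean_abs_target / mean_abs)
        R = alpha * R
        np.fill_diagonal(R, 1.0)

    off = R[~np.eye(J, dtype=bool)]
    if off.min() < lo_b - 1e-12 or off.max() > hi_b + 1e-12:
        raise ValidationError(
            f"loading_range forces correlations outside [{lo_b}, {hi_b}]"
        )
    R, _ = nearest_positive_definite(R)
    return R


def default_marginals(design: ScaleDesign, seed=0, concentration: float = 6.0,
                      floor: float = 0.02) -> np.ndarray:
    """Per-item category probabilities: unimodal agreement-leaning base with
    per-item Dirichlet variation; reversed items carry the mirrored profile.

    The low default concentration produces the pronounced item-to-item
    heterogeneity of real personality inventories (item means spanning
    roughly 1.9 to 4.2 on a 5-point scale); ``floor`` keeps every category
    reachable so no item degenerates.
    """
    rng = _rng(seed)
    K = design.n_categories
    if K == len(_BASE_MARGINAL):
        base = _BASE_MARGINAL
    else:  # fall back to a symmetric unimodal profile for other K
        x = np.linspace(-1, 1, K)
        base = np.exp(-1.5 * x**2)
        base = base / base.sum()
    P = np.empty((design.n_items, K))
    for j in range(design.n_items):
        b = base[::-1] if design.reversed_items[j] else base
        p = rng.dirichlet(b * concentration)
        p = np.maximum(p, floor)
        P[j] = p / p.sum()
    return P


def _thresholds(marginals: np.ndarray) -> np.ndarray:
    """Latent-normal cut points per item: Phi^{-1} of cumulative probabilities."""
    cum = np.cumsum(marginals[:, :-1], axis=1)
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(cum)


def _ordinal_moments(marginals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = marginals.shape[1]
    cats = np.arange(1, K + 1)
    mu = marginals @ cats
    var = marginals @ cats**2 - mu**2
    return mu, np.sqrt(var)


def _hermite_profile(thresholds: np.ndarray, n_terms: int) -> np.ndarray:
    """A[j, m] = sum_k phi(t_jk) He_m(t_jk) / sqrt(m!), m = 0..n_terms-1.

    Normalized per-item factors of the tetrachoric series: the covariance of
    two discretized items at latent correlation rho is
    sum_{m>=1} (rho^m / m) * A[i, m-1] * A[j, m-1], since
    rho^m/m! * He_{m-1}(a)He_{m-1}(b) = (rho^m/m) * he_{m-1}(a)he_{m-1}(b)
    with he the orthonormalized polynomials. The 1/sqrt(m!) normalization
    keeps the recursion in float range (raw Hermite sums grow like sqrt(m!)).
    """
    t = thresholds
    phi = stats.norm.pdf(t)
    A = np.empty((t.shape[0], n_terms))
    he_prev = np.ones_like(t)   # he_0 = He_0 / sqrt(0!)
    he = t.copy()               # he_1
    A[:, 0] = (phi * he_prev).sum(axis=1)
    for m in range(1, n_terms):
        A[:, m] = (phi * he).sum(axis=1)
        he_prev, he = he, (t * he - np.sqrt(m) * he_prev) / np.sqrt(m + 1)
    return A


def implied_ordinal_corr(rho, t_i: np.ndarray, t_j: np.ndarray,
                         sd_i: float, sd_j: float, n_terms: int = 300) -> float:
    """Ordinal Pearson correlation implied by latent-normal correlation rho
    for one item pair, via the tetrachoric series of the bivariate normal CDF."""
    A = _hermite_profile(np.vstack([t_i, t_j]), n_terms)
    coef = A[0] * A[1] / np.arange(1, n_terms + 1)
    return float(np.polynomial.polynomial.polyval(rho, np.r_[0.0, coef]) / (sd_i * sd_j))


@dataclass(frozen=True)
class OrdinalGeneratorSpec:
    """Calibrated copula generator: marginals + target and latent correlations.

    ``target_corr`` holds the *effective* ordinal targets the calibrated
    copula reproduces (equal to the requested targets wherever those were
    attainable for the margins)."""

    marginals: np.ndarray          # (J, K) category probabilities
    target_corr: np.ndarray        # (J, J) effective ordinal correlations
    latent_corr: np.ndarray        # (J, J) calibrated latent-normal correlations
    thresholds: np.ndarray         # (J, K-1) latent cut points
    repair_drift: float            # max |entry| change from PD repair
    chol: np.ndarray               # Cholesky factor of latent_corr

    @property
    def n_items(self) -> int:
        return self.marginals.shape[0]


def calibrate_latent_corr(
    target_corr: np.ndarray,
    marginals: np.ndarray,
    tol: float = 1e-3,
    n_terms: int = 300,
    rho_max: float = 0.97,
    clamp: bool = False,
    return_effective: bool = False,
):
    """Latent-normal correlation matrix whose discretized ordinal correlations
    match ``target_corr`` (pairwise, within ``tol`` before PD repair).

    For each pair the implied ordinal correlation is a polynomial in the
    latent rho (tetrachoric series), solved by monotone bisection. Targets
    outside the attainable range for the given marginals raise an error
    naming the offending pair, unless ``clamp`` is set, in which case they
    are shrunk to 95% of the attainable bound (the generator pipeline uses
    this: a surrogate target matrix drawn independently of the margins can
    ask for the infeasible, which empirically calibrated matrices never
    do). Returns (latent_corr, repair_drift).
    """
    marginals = np.asarray(marginals, dtype=float)
    if np.any(marginals < -1e-9) or np.max(np.abs(marginals.sum(axis=1) - 1)) > 1e-9:
        raise ValidationError("marginals must be non-negative and sum to 1 per item")
    J = marginals.shape[0]
    t = _thresholds(marginals)
    _, sd = _ordinal_moments(marginals)
    A = _hermite_profile(t, n_terms)

    iu = np.triu_indices(J, 1)
    # coefficient matrix: (n_pairs, n_terms); coefficient of rho^(k+1) is C[:, k]
    C = (A[iu[0]] * A[iu[1]]) / (sd[iu[0]] * sd[iu[1]])[:, None]
    C = C / np.arange(1, n_terms + 1)[None, :]
    targets = np.asarray(target_corr, dtype=float)[iu]

    def implied(rho_vec: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(rho_vec)
        p = np.ones_like(rho_vec)
        for k in range(n_terms):
            p = p * rho_vec
            acc = acc + C[:, k] * p
        return acc

    r_hi = implied(np.full(len(targets), rho_max))
    r_lo = implied(np.full(len(targets), -rho_max))
    bad = (targets > r_hi + tol) | (targets < r_lo - tol)
    if bad.any():
        if clamp:
            targets = np.clip(targets, 0.95 * r_lo, 0.95 * r_hi)
        else:
            k = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"target ordinal correlation {targets[k]:.3f} for item pair "
                f"({iu[0][k]}, {iu[1][k]}) outside attainable range "
                f"[{r_lo[k]:.3f}, {r_hi[k]:.3f}]"
            )

    lo = np.full(len(targets), -rho_max)
    hi = np.full(len(targets), rho_max)
    for _ in range(50):
        mid = (lo + hi) / 2.0
        f = implied(mid)
        go_up = f < targets
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    rho = (lo + hi) / 2.0

    latent = np.eye(J)
    latent[iu] = rho
    latent.T[iu] = rho
    latent, drift = nearest_positive_definite(latent)
    if return_effective:
        effective = np.eye(J)
        eff = implied(rho)
        effective[iu] = eff
        effective.T[iu] = eff
        return latent, drift, effective
    return latent, drift


def make_generator_spec(
    design: ScaleDesign,
    seed=0,
    target_corr: np.ndarray | None = None,
    marginals: np.ndarray | None = None,
    **corr_kwargs,
) -> OrdinalGeneratorSpec:
    """Build and calibrate the regular-responder generator for a design."""
    if target_corr is None:
        target_corr = build_hexaco_like_corr(design, seed=seed, **corr_kwargs)
    if marginals is None:
        marginals = default_marginals(design, seed=seed)
    latent, drift, effective = calibrate_latent_corr(
        target_corr, marginals, clamp=True, return_effective=True)
    chol = np.linalg.cholesky(latent)
    return OrdinalGeneratorSpec(
        marginals=np.asarray(marginals, float),
        target_corr=effective,
        latent_corr=latent,
        thresholds=_thresholds(np.asarray(marginals, float)),
        repair_drift=drift,
        chol=chol,
    )


def sample_regular(n: int, spec: OrdinalGeneratorSpec, seed=0) -> ResponseMatrix:
    """Draw n regular respondents: latent MVN, discretized at the item cut points."""
    rng = _rng(seed)
    Z = rng.standard_normal((n, spec.n_items)) @ spec.chol.T
    X = np.empty((n, spec.n_items), dtype=np.int64)
    for j in range(spec.n_items):
        X[:, j] = 1 + np.searchsorted(spec.thresholds[j], Z[:, j])
    return ResponseMatrix(X)


def sample_random_careless(n: int, K: int = 5, J: int = 60, seed=0) -> ResponseMatrix:
    """iid uniform over {1..K} per cell."""
    rng = _rng(seed)
    return ResponseMatrix(rng.integers(1, K + 1, size=(n, J)))


def sample_midpoint_careless(n: int, K: int = 5, probs=MIDPOINT_PROBS,
                             J: int = 60, seed=0) -> ResponseMatrix:
    """iid draws from the midpoint-heavy category distribution."""
    probs = np.asarray(probs, float)
    if len(probs) != K or abs(probs.sum() - 1) > 1e-9 or (probs < 0).any():
        raise ValidationError("probs must be a length-K probability vector")
    rng = _rng(seed)
    u = rng.random((n, J))
    cum = np.cumsum(probs)
    X = 1 + np.searchsorted(cum[:-1], u.ravel(), side="right").reshape(n, J)
    return ResponseMatrix(X)


def sample_pattern_careless(n: int, K: int = 5, J: int = 60, seed=0) -> ResponseMatrix:
    """Fixed-pattern careless rows: an ascending run between two distinct
    random categories a < b, tiled across the J items (e.g. 1-2-3-1-2-3)."""
    if K < 2:
        raise ValidationError("pattern style needs K >= 2")
    rng = _rng(seed)
    X = np.empty((n, J), dtype=np.int64)
    for i in range(n):
        a = b = 0
        while a == b:
            a, b = rng.integers(1, K + 1, size=2)
        a, b = min(a, b), max(a, b)
        cycle = np.arange(a, b + 1)
        X[i] = np.tile(cycle, J // len(cycle) + 1)[:J]
    return ResponseMatrix(X)


@dataclass(frozen=True)
class RTGeneratorParams:
    """Log-normal item response-time parameters per condition (seconds).

    Medians/log-sds are deliberately overlapping: carelessness shows mainly
    in the lower tail, not as a cleanly separated distribution.
    """

    regular_median: float = 7.0
    regular_logsd: float = 0.45
    careless_median: float = 3.0
    careless_logsd: float = 0.55

    def __post_init__(self):
        if min(self.regular_logsd, self.careless_logsd) <= 0:
            raise ValidationError("log-sd scales must be positive")
        if min(self.regular_median, self.careless_median) <= 0:
            raise ValidationError("medians must be positive")


def sample_response_times(labels: np.ndarray, design: ScaleDesign,
                          params: RTGeneratorParams | None = None, seed=0) -> RTMatrix:
    """Item-level log-normal durations, condition-dependent via the labels."""
    params = params or RTGeneratorParams()
    rng = _rng(seed)
    labels = np.asarray(labels, dtype=int)
    n, J = len(labels), design.n_items
    mu = np.where(labels == 1, np.log(params.careless_median), np.log(params.regular_median))
    sigma = np.where(labels == 1, params.careless_logsd, params.regular_logsd)
    Z = rng.standard_normal((n, J))
    return RTMatrix(np.exp(mu[:, None] + sigma[:, None] * Z))


def _sample_careless(style: str, n: int, K: int, J: int, rng) -> ResponseMatrix:
    if style == "random":
        return ResponseMatrix(rng.integers(1, K + 1, size=(n, J)))
    if style == "midpoint":
        return sample_midpoint_careless(n, K=K, J=J, seed=rng)
    if style == "pattern":
        return sample_pattern_careless(n, K=K, J=J, seed=rng)
    raise ValidationError(f"unknown careless style {style!r}")


def assemble_condition(
    n: int,
    prevalence: float,
    style: str,
    spec: OrdinalGeneratorSpec,
    design: ScaleDesign,
    seed=0,
    with_rt: bool = False,
    rt_params: RTGeneratorParams | None = None,
) -> LabeledDataset:
    """One labeled sample: regular + careless blocks, shuffled.

    The careless count is round(prevalence * n); a zero count is an error
    because there would be no positives to evaluate.
    """
    rng = _rng(seed)
    n_careless = int(round(prevalence * n))
    if n_careless == 0:
        raise ValidationError("prevalence * n rounds to zero careless respondents")
    n_regular = n - n_careless
    K, J = design.n_categories, design.n_items
    Xr = sample_regular(n_regular, spec, seed=rng)
    Xc = _sample_careless(style, n_careless, K, J, rng)
    values = np.vstack([Xr.values, Xc.values])
    labels = np.r_[np.zeros(n_regular, dtype=int), np.ones(n_careless, dtype=int)]
    styles = np.r_[np.full(n_regular, "", dtype=object),
                   np.full(n_careless, style, dtype=object)]
    perm = rng.permutation(n)
    values, labels, styles = values[perm], labels[perm], styles[perm]
    rt = None
    if with_rt:
        rt = sample_response_times(labels, design, rt_params, seed=rng)
    return LabeledDataset(ResponseMatrix(values), labels, rt=rt, styles=styles)
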