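"""Graded response model (GRM) estimation and the polytomous Z_h person fit.

The questionnaire is modeled with between-item multidimensionality: one
unidimensional GRM per construct, each with an independent standard-normal
trait. Items have a discrimination a > 0 and K-1 strictly ordered category
thresholds b_1 < ... < b_{K-1} on the logit metric:

    P(X >= k | theta) = logistic(a (theta - b_{k-1})),   k = 2..K
    P(X = k) = P(X >= k) - P(X >= k+1)

Estimation is marginal maximum likelihood via EM with fixed Gauss-Hermite
quadrature and a standard-normal latent prior. Trait scores are EAP (finite
for every response pattern, including all-extreme ones). The Z_h statistic
standardizes the observed pattern log-likelihood at the trait estimate
against its conditional expectation and variance, summed over all items
(each item evaluated at its own construct's trait estimate); strongly
negative values signal person misfit and hence possible carelessness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import ResponseMatrix, ScaleDesign, ValidationError
from .indices import IndexScores

__all__ = [
    "GradedResponseModel",
    "GRMResults",
    "PersonFitResult",
    "grm_category_probs",
    "fit_grm",
    "estimate_theta",
    "zh_statistic",
    "zh_scores",
    "fit_personfit_models",
]

_EPS = 1e-300


def grm_category_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities of one GRM item at each theta.

    Returns an array of shape (len(theta), K) with rows summing to one.
    ``a`` may be zero (flat item); thresholds must be strictly increasing.
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or (np.diff(b) <= 0).any():
        raise ValidationError("thresholds must be strictly increasing")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    # cumulative P*(k) = P(X >= k), k = 1..K+1 with P*(1)=1, P*(K+1)=0
    z = a * (theta[:, None] - b[None, :])
    pstar = np.empty((len(theta), len(b) + 2))
    pstar[:, 0] = 1.0
    pstar[:, 1:-1] = 1.0 / (1.0 + np.exp(-z))
    pstar[:, -1] = 0.0
    return -np.diff(pstar, axis=1)


@dataclass
class GRMResults:
    """Fitted GRM for one construct: item parameters and fit diagnostics."""

    a: np.ndarray                 # (n_items,)
    b: np.ndarray                 # (n_items, K-1)
    n_categories: int
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    nodes: np.ndarray             # quadrature nodes
    weights: np.ndarray           # prior-weighted quadrature weights
    model: "GradedResponseModel | None" = field(default=None, repr=False)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def item_probs(self, theta: np.ndarray) -> np.ndarray:
        """(len(theta), n_items, K) category probabilities."""
        theta = np.atleast_1d(theta)
        P = np.empty((len(theta), len(self.a), self.n_categories))
        for j in range(len(self.a)):
            P[:, j, :] = grm_category_probs(self.a[j], self.b[j], theta)
        return P

    def eap_theta(self, X: np.ndarray) -> np.ndarray:
        """Expected-a-posteriori trait estimates for response rows X (1..K)."""
        return estimate_theta(self, X)

    def summary(self) -> str:
        lines = [
            "Graded Response Model (EM, Gauss-Hermite quadrature)",
            f"items: {len(self.a)}  categories: {self.n_categories}  "
            f"iterations: {self.n_iter}  converged: {self.converged}",
            f"log-likelihood: {self.loglik:.3f}",
            "item        a    " + "  ".join(f"b{k+1:<6}" for k in range(self.b.shape[1])),
        ]
        for j in range(len(self.a)):
            bs = "  ".join(f"{v: .3f}" for v in self.b[j])
            lines.append(f"{j + 1:>4}   {self.a[j]: .3f}  {bs}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "n_categories": self.n_categories,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRMResults":
        a = np.asarray(d["a"], float)
        b = np.asarray(d["b"], float)
        nodes, weights = _quadrature(41)
        return cls(a=a, b=b, n_categories=int(d["n_categories"]),
                   loglik_trace=np.array([np.nan]), converged=True, n_iter=0,
                   nodes=nodes, weights=weights)


def _quadrature(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite_e.hermegauss(n_quad)
    return x, w / w.sum()


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    return np.r_[np.log(a), b[0], np.log(np.diff(b))]


def _unpack(z: np.ndarray) -> tuple[float, np.ndarray]:
    # clipped exponentials keep line searches from overflowing
    a = float(np.exp(np.clip(z[0], -30.0, 6.0)))
    b = z[1] + np.r_[0.0, np.cumsum(np.exp(np.clip(z[2:], -30.0, 6.0)))]
    return a, b


def _negll_and_grad(z: np.ndarray, R: np.ndarray, nodes: np.ndarray):
    """Expected negative complete-data log-likelihood of one item and its
    gradient in the unconstrained parameterization (log a, b1, log gaps)."""
    a, b = _unpack(z)
    Km1 = len(b)
    th = nodes[:, None]
    Q = 1.0 / (1.0 + np.exp(np.clip(-a * (th - b[None, :]), -500, 500)))  # (Qn, K-1)
    P = np.empty((len(nodes), Km1 + 1))
    P[:, 0] = 1.0 - Q[:, 0]
    P[:, 1:-1] = Q[:, :-1] - Q[:, 1:]
    P[:, -1] = Q[:, -1]
    Ps = P + _EPS
    negll = -np.sum(R * np.log(Ps))
    # dL/dQ_k = -R_k/P_k + R_{k+1}/P_{k+1}  (L = sum R log P)
    ratio = R / Ps
    dL_dQ = -ratio[:, :-1] + ratio[:, 1:]
    Qd = Q * (1.0 - Q)
    dL_da = np.sum(dL_dQ * Qd * (th - b[None, :]))
    dL_db = np.sum(dL_dQ * Qd, axis=0) * (-a)
    # chain to z: b_k = z1 + sum_{i<k} exp(z_{2+i})
    g = np.empty_like(z)
    g[0] = -a * dL_da
    g[1] = -np.sum(dL_db)
    if Km1 > 1:
        gaps = np.exp(np.clip(z[2:], -30.0, 6.0))
        tail = np.cumsum(dL_db[::-1])[::-1]
        g[2:] = -gaps * tail[1:]
    return negll, g


class GradedResponseModel:
    """MML estimation of a unidimensional GRM for one construct's items.

    Parameters
    ----------
    X : ndarray of int, shape (n, n_items)
        Responses in 1..K for the items of a single construct.
    n_categories : int
        Number of ordered categories K.
    """

    def __init__(self, X: np.ndarray, n_categories: int):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValidationError("need a 2-D matrix with >= 2 items")
        if X.min() < 1 or X.max() > n_categories:
            raise ValidationError("responses outside 1..K")
        self.X = X.astype(np.int64)
        self.K = int(n_categories)
        self.n, self.n_items = X.shape

    def _start_values(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.ones(self.n_items)
        b = np.empty((self.n_items, self.K - 1))
        for j in range(self.n_items):
            counts = np.bincount(self.X[:, j], minlength=self.K + 1)[1:]
            p = (counts + 0.5) / (counts.sum() + 0.5 * self.K)
            sf = 1.0 - np.cumsum(p)[:-1]          # P(X > k)
            sf = np.clip(sf, 1e-3, 1 - 1e-3)
            b[j] = -np.log(sf / (1 - sf))
            b[j] = np.maximum.accumulate(b[j] + np.arange(self.K - 1) * 1e-6)
        return a, b

    def fit(
        self,
        max_iter: int = 200,
        tol: float = 1e-3,
        n_quad: int = 21,
        category_smoothing: float = 1e-3,
    ) -> GRMResults:
        """Run EM to convergence (max absolute parameter change < tol).

        ``category_smoothing`` adds a small prior-shaped pseudo-count to the
        expected category totals of every item, which keeps thresholds
        finite and strictly ordered when a category is rare or unobserved
        in the sample.
        """
        nodes, weights = _quadrature(n_quad)
        Q = len(nodes)
        a, b = self._start_values()
        trace = []
        converged = False
        it = 0

        onehot = np.zeros((self.n_items, self.n, self.K))
        for j in range(self.n_items):
            onehot[j, np.arange(self.n), self.X[:, j] - 1] = 1.0

        for it in range(1, max_iter + 1):
            # E-step: posterior over quadrature nodes per person
            logL = np.zeros((self.n, Q))
            P_all = np.empty((self.n_items, Q, self.K))
            for j in range(self.n_items):
                P = grm_category_probs(a[j], b[j], nodes)   # (Q, K)
                P_all[j] = P
                logL += np.log(P[:, self.X[:, j] - 1].T + _EPS)
            logpost = logL + np.log(weights)[None, :]
            m = logpost.max(axis=1, keepdims=True)
            post = np.exp(logpost - m)
            norm = post.sum(axis=1, keepdims=True)
            trace.append(float((np.log(norm) + m).sum()))
            W = post / norm                                  # (n, Q)

            # M-step: per-item weighted multinomial fit over the node grid
            max_change = 0.0
            for j in range(self.n_items):
                R = W.T @ onehot[j]                          # (Q, K) expected counts
                if category_smoothing > 0:
                    R = R + category_smoothing * weights[:, None] * P_all[j]

                z0 = _pack(a[j], b[j])
                res = optimize.minimize(
                    _negll_and_grad, z0, args=(R, nodes), jac=True,
                    method="L-BFGS-B", options={"maxiter": 20},
                )
                z1 = res.x if res.fun <= _negll_and_grad(z0, R, nodes)[0] else z0
                a_new, b_new = _unpack(z1)
                max_change = max(max_change,
                                 abs(a_new - a[j]),
                                 np.max(np.abs(b_new - b[j])))
                a[j], b[j] = a_new, b_new

            if max_change < tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"GRM EM did not converge in {max_iter} cycles "
                f"(last max parameter change {max_change:.2e}); "
                "returning best iterate"
            )
        return GRMResults(
            a=a, b=b, n_categories=self.K,
            loglik_trace=np.asarray(trace), converged=converged, n_iter=it,
            nodes=nodes, weights=weights, model=self,
        )


def fit_grm(X: np.ndarray, n_categories: int, **fit_kwargs) -> GRMResults:
    """Convenience wrapper: build the model and fit it."""
    return GradedResponseModel(X, n_categories).fit(**fit_kwargs)


def estimate_theta(results: GRMResults, X: np.ndarray) -> np.ndarray:
    """EAP trait estimates under the standard-normal prior.

    With zero items the posterior is the prior and the estimate is 0.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    if X.shape[1] == 0:
        return np.zeros(X.shape[0])
    nodes, weights = results.nodes, results.weights
    logL = np.zeros((X.shape[0], len(nodes)))
    for j in range(X.shape[1]):
        P = grm_category_probs(results.a[j], results.b[j], nodes)
        logL += np.log(P[:, X[:, j] - 1].T + _EPS)
    logpost = logL + np.log(weights)[None, :]
    m = logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost - m)
    post /= post.sum(axis=1, keepdims=True)
    return post @ nodes


@dataclass(frozen=True)
class PersonFitResult:
    """Z_h person-fit decomposition per respondent."""

    theta: dict                   # construct id -> (n,) EAP estimates
    loglik: np.ndarray            # observed pattern log-likelihood l
    expected: np.ndarray          # E[l | theta]
    variance: np.ndarray          # V[l | theta]
    zh: np.ndarray                # (l - E[l]) / sqrt(V[l])


def fit_personfit_models(
    X: ResponseMatrix, design: ScaleDesign, **fit_kwargs
) -> dict:
    """Fit one GRM per construct on the (possibly contaminated) sample."""
    fits = {}
    for c in design.construct_ids:
        items = design.items_of(c)
        fits[c] = fit_grm(X.values[:, items], design.n_categories, **fit_kwargs)
    return fits


def zh_statistic(
    X: ResponseMatrix, design: ScaleDesign, fits: dict,
    theta: dict | None = None,
) -> PersonFitResult:
    """Standardized person-fit statistic over all items.

    l_i = sum_j log P_{j, x_ij}(theta-hat); E and V are the conditional
    moments of l under the fitted model at theta-hat; Z_h = (l - E)/sqrt(V).
    Orientation: low = misfit. Items with (numerically) flat category
    probabilities contribute zero variance; if all items are flat the
    statistic is undefined and an error is raised.

    The standardization is exact conditional on the trait values; by
    default per-construct EAP estimates are plugged in (which shifts the
    null distribution upward by roughly 0.5 per estimated trait — the
    lower-tail flag is conservative under this shift). ``theta`` may
    supply known trait values per construct instead, e.g. for null
    calibration on simulees.
    """
    n = X.n
    l = np.zeros(n)
    El = np.zeros(n)
    Vl = np.zeros(n)
    thetas = {}
    for c in design.construct_ids:
        items = design.items_of(c)
        fit = fits[c]
        if theta is not None:
            th = np.asarray(theta[c], dtype=float)
        else:
            th = estimate_theta(fit, X.values[:, items])
        thetas[c] = th
        P = fit.item_probs(th)                       # (n, j, K)
        logP = np.log(P + _EPS)
        rows = np.arange(n)
        for jj, item in enumerate(items):
            x = X.values[:, item] - 1
            l += logP[rows, jj, x]
            mean_j = np.sum(P[:, jj] * logP[:, jj], axis=1)
            El += mean_j
            Vl += np.sum(P[:, jj] * logP[:, jj] ** 2, axis=1) - mean_j**2
    if np.any(Vl <= 0):
        raise ValidationError("zero conditional variance: all items are flat")
    zh = (l - El) / np.sqrt(Vl)
    return PersonFitResult(theta=thetas, loglik=l, expected=El, variance=Vl, zh=zh)


def zh_scores(X: ResponseMatrix, design: ScaleDesign,
              fits: dict | None = None, **fit_kwargs) -> IndexScores:
    """Z_h as a detection index (orientation: low = careless).

    By default the GRMs are calibrated on the full analysis sample being
    scored; pre-fitted parameters can be passed to share a calibration
    between samples.
    """
    if fits is None:
        fits = fit_personfit_models(X, design, **fit_kwargs)
    result = zh_statistic(X, design, fits)
    return IndexScores("zh", result.zh, "low")


def save_grm_fits(fits: dict, path) -> None:
    payload = {str(c): f.to_dict() for c, f in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_grm_fits(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for c, d in payload.items():
        key = int(c) if c.lstrip("-").isdigit() else c
        out[key] = GRMResults.from_dict(d)
    return out
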