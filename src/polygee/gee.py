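"""Generalized estimating equations for the gamma-type marginal model.

Squared association statistics are grouped into 1 cM clusters; within a
cluster the working correlation R_i is the reference-panel r² matrix.  The
mean is linear (identity link), mu_ij = x_ij' beta, and the variance is
quadratic, Var(y_ij) = phi * mu_ij^2.  Writing the gamma-family GEE objects
out for this case gives D_i = X_i and V_i = diag(mu_i) R_i diag(mu_i) (the
dispersion phi scales the estimating function and cancels at the root, so
it is dropped during solving and reported post hoc via the Pearson moment
estimator).  The estimating equations are

    g_n(beta) = sum_i D_i' V_i^{-1} (y_i - mu_i) = 0,

solved by Fisher scoring (Newton-Raphson with the expected derivative
H_n = sum_i D_i' V_i^{-1} D_i) with step halving to keep every mean
positive along the path.

Because adjacent 1 cM clusters share LD, they are not independent; the
sandwich covariance therefore carries cross-terms for each correlated pair:

    M_n = sum_i g_i g_i' + sum_{(i,j) adjacent} (g_i g_j' + g_j g_i'),
    Sigma = H_n^{-1} M_n H_n^{-1}.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GEEProblem",
    "GEEFit",
    "WaldTest",
    "gee_objects",
    "estimating_function",
    "solve",
    "sandwich",
    "dispersion",
    "wald",
]


class GEEProblem:
    """Clustered responses, covariates and working correlations.

    Parameters
    ----------
    ys
        Per-cluster response vectors (squared association statistics).
    Xs
        Per-cluster covariate matrices, typically columns [1, C_study * l].
    Rs
        Per-cluster working-correlation matrices (symmetric PD after the
        upstream repair); Cholesky factors are cached and shared by
        :meth:`with_responses`.
    adjacency
        Unordered pairs of cluster indices treated as correlated in the
        sandwich cross-term.
    """

    def __init__(
        self,
        ys: Sequence[np.ndarray],
        Xs: Sequence[np.ndarray],
        Rs: Sequence[np.ndarray],
        adjacency: frozenset[tuple[int, int]] = frozenset(),
    ) -> None:
        if not len(ys) == len(Xs) == len(Rs):
            raise ValueError("ys, Xs, Rs must have one entry per cluster")
        self.ys = [np.asarray(y, dtype=float) for y in ys]
        self.Xs = [np.atleast_2d(np.asarray(X, dtype=float)) for X in Xs]
        self.Rs = list(Rs)
        p = self.Xs[0].shape[1]
        for y, X, R in zip(self.ys, self.Xs, self.Rs):
            m = len(y)
            if X.shape != (m, p) or R.shape != (m, m):
                raise ValueError("inconsistent cluster dimensions")
            if np.any(y < 0):
                raise ValueError("responses must be nonnegative")
        for i, j in adjacency:
            if not (0 <= i < len(ys) and 0 <= j < len(ys)) or i == j:
                raise ValueError(f"invalid adjacency pair ({i}, {j})")
        self.adjacency = frozenset((min(i, j), max(i, j)) for i, j in adjacency)
        self.p = p
        self.n_clusters = len(ys)
        self.n_obs = sum(len(y) for y in self.ys)
        # R_i is fixed across iterations and replications: factor once.
        chols: dict[int, tuple] = {}
        self._chols = []
        for R in self.Rs:
            key = id(R)
            if key not in chols:
                chols[key] = cho_factor(np.asarray(R, dtype=float), lower=True)
            self._chols.append(chols[key])

    def with_responses(self, ys: Sequence[np.ndarray]) -> "GEEProblem":
        """Same clusters/correlations with new responses (factors shared)."""
        new = copy.copy(self)
        new.ys = [np.asarray(y, dtype=float) for y in ys]
        if len(new.ys) != self.n_clusters:
            raise ValueError("response count must match cluster count")
        new.n_obs = sum(len(y) for y in new.ys)
        return new

    def means(self, beta: np.ndarray) -> list[np.ndarray]:
        return [X @ beta for X in self.Xs]

    def admissible(self, beta: np.ndarray) -> bool:
        return all((X @ beta > 0).all() for X in self.Xs)


def gee_objects(problem: GEEProblem, beta: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Per-cluster model objects mu, A, Delta, D, V at ``beta``.

    For the gamma family with identity mean link: A = diag(mu^2) (phi
    dropped), Delta = diag(1/mu^2), hence D = A Delta X = X, and
    V = A^{1/2} R A^{1/2} = diag(mu) R diag(mu).
    """
    beta = np.asarray(beta, dtype=float)
    if not problem.admissible(beta):
        raise ValueError("inadmissible beta: some cluster mean <= 0")
    out = []
    for X, R in zip(problem.Xs, problem.Rs):
        mu = X @ beta
        out.append(
            {
                "mu": mu,
                "A": np.diag(mu**2),
                "Delta": np.diag(1.0 / mu**2),
                "D": X.copy(),
                "V": (R * mu).T * mu,
            }
        )
    return out


def _cluster_scores(problem: GEEProblem, beta: np.ndarray):
    """Per-cluster score vectors g_i and the scoring matrix H = sum D'V^{-1}D."""
    p = problem.p
    H = np.zeros((p, p))
    gis = []
    for y, X, chol in zip(problem.ys, problem.Xs, problem._chols):
        mu = X @ beta
        B = X / mu[:, None]  # diag(1/mu) X
        r = (y - mu) / mu
        gis.append(B.T @ cho_solve(chol, r))
        H += B.T @ cho_solve(chol, B)
    return gis, H


def estimating_function(problem: GEEProblem, beta: np.ndarray) -> np.ndarray:
    """g_n(beta) = sum_i D_i' V_i^{-1} (y_i - mu_i)."""
    beta = np.asarray(beta, dtype=float)
    if not problem.admissible(beta):
        raise ValueError("inadmissible beta: some cluster mean <= 0")
    gis, _ = _cluster_scores(problem, beta)
    return np.sum(gis, axis=0)


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    pvalue: float


@dataclass
class GEEFit:
    """Estimates, sandwich covariance and diagnostics from one GEE solve."""

    beta: np.ndarray
    cov: np.ndarray  # cross-cluster-corrected sandwich
    cov_model: np.ndarray  # phi * H^{-1}, model-based (diagnostics)
    phi: float
    iterations: int
    converged: bool
    n_clusters: int
    n_obs: int
    block_pearson: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def se(self) -> np.ndarray:
        # the cross-cluster-corrected M_n can be indefinite at very small
        # cluster counts; a negative diagonal surfaces as NaN, not an error
        d = np.diag(self.cov)
        with np.errstate(invalid="ignore"):
            return np.where(d >= 0, np.sqrt(np.abs(d)), np.nan)

    def wald(self, b: int) -> WaldTest:
        return wald(self, b)

    def _wald_entry(self, b: int) -> dict:
        try:
            w = self.wald(b)
        except ValueError:
            # indefinite cross-corrected M_n at very small cluster counts
            return {"coordinate": b, "statistic": None, "pvalue": None}
        return {"coordinate": b, "statistic": w.statistic, "pvalue": w.pvalue}

    def to_json(self, path: str | Path | None = None, estimator: str = "gee") -> str:
        payload = {
            "estimator": estimator,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "se_model": np.sqrt(np.diag(self.cov_model)).tolist(),
            "phi": self.phi,
            "wald": [self._wald_entry(b) for b in range(len(self.beta))],
            "n_clusters": self.n_clusters,
            "n_snps": self.n_obs,
            "iterations": self.iterations,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def solve(
    problem: GEEProblem,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    max_halvings: int = 30,
) -> GEEFit:
    """Solve g_n(beta) = 0 by Fisher scoring with step halving.

    The default start is beta1 = mean(y), all slopes 0 (admissible whenever
    the first covariate column is the intercept and not all responses are
    zero).  The full scoring step is the classical iteratively-reweighted
    update, which converges at a linear rate without being monotone in any
    residual norm; a trial step is therefore halved only when it would make
    a mean nonpositive or blow up the affine-invariant merit
    ``q = g' H^{-1} g`` (q is zero exactly at a root and puts the score
    components, whose raw scales differ by orders of magnitude, on a common
    footing).  Non-convergence is flagged on the returned fit, never silent.
    """
    if init is None:
        init = np.zeros(problem.p)
        init[0] = float(np.mean(np.concatenate(problem.ys)))
    beta = np.asarray(init, dtype=float).copy()
    if not problem.admissible(beta):
        raise ValueError("initial beta is inadmissible (some mean <= 0)")

    def merit(g: np.ndarray, H: np.ndarray) -> float:
        try:
            return float(g @ np.linalg.solve(H, g))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "scoring matrix H_n is singular; covariate columns are collinear"
            ) from err

    qtol = (tol * problem.n_clusters) ** 2
    gis, H = _cluster_scores(problem, beta)
    g = np.sum(gis, axis=0)
    q = merit(g, H)
    converged = q < qtol
    it = 0
    while not converged and it < max_iter:
        it += 1
        delta = np.linalg.solve(H, g)
        step = 1.0
        for _ in range(max_halvings):
            cand = beta + step * delta
            if problem.admissible(cand):
                gis_c, H_c = _cluster_scores(problem, cand)
                g_c = np.sum(gis_c, axis=0)
                q_c = merit(g_c, H_c)
                if q_c < 10.0 * q or q_c < qtol:
                    break
            step *= 0.5
        else:  # no acceptable step found
            break
        beta = cand
        gis, H, g, q = gis_c, H_c, g_c, q_c
        if np.max(np.abs(step * delta)) < tol or q < qtol:
            converged = True

    Sigma, Hinv = _sandwich_from_scores(problem, gis, H)
    phi = dispersion_at(problem, beta)
    block_pearson = np.array(
        [np.sum(((y - X @ beta) / (X @ beta)) ** 2) for y, X in zip(problem.ys, problem.Xs)]
    )
    return GEEFit(
        beta=beta,
        cov=Sigma,
        cov_model=phi * Hinv,
        phi=phi,
        iterations=it,
        converged=bool(converged),
        n_clusters=problem.n_clusters,
        n_obs=problem.n_obs,
        block_pearson=block_pearson,
    )


def _sandwich_from_scores(problem: GEEProblem, gis: list[np.ndarray], H: np.ndarray):
    M = np.zeros((problem.p, problem.p))
    for gi in gis:
        M += np.outer(gi, gi)
    for i, j in problem.adjacency:
        cross = np.outer(gis[i], gis[j])
        M += cross + cross.T
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "scoring matrix H_n is singular; covariate columns are collinear"
        ) from err
    Sigma = Hinv @ M @ Hinv
    return 0.5 * (Sigma + Sigma.T), 0.5 * (Hinv + Hinv.T)


def sandwich(problem: GEEProblem, beta: np.ndarray) -> np.ndarray:
    """Cross-cluster-corrected sandwich covariance at ``beta``.

    Reduces to the classical independence sandwich when the adjacency set
    is empty.
    """
    gis, H = _cluster_scores(problem, np.asarray(beta, dtype=float))
    return _sandwich_from_scores(problem, gis, H)[0]


def dispersion_at(problem: GEEProblem, beta: np.ndarray) -> float:
    """Pearson moment estimator of phi at ``beta``."""
    num = 0.0
    for y, X in zip(problem.ys, problem.Xs):
        mu = X @ beta
        num += float(np.sum(((y - mu) / mu) ** 2))
    return num / (problem.n_obs - problem.p)


def dispersion(problem: GEEProblem, fit: GEEFit) -> float:
    """Pearson dispersion ``phi_hat = sum((y - mu)^2 / mu^2) / (N - p)``."""
    return dispersion_at(problem, fit.beta)


def wald(fit: GEEFit, b: int) -> WaldTest:
    """Wald test of H0: beta_b = 0 using the sandwich variance.

    W = beta_b^2 / Sigma_bb is asymptotically chi-square(1) under H0.
    """
    var = fit.cov[b, b]
    if var <= 0:
        raise ValueError(f"nonpositive sandwich variance for coordinate {b}")
    W = float(fit.beta[b] ** 2 / var)
    return WaldTest(statistic=W, pvalue=float(stats.chi2.sf(W, df=1)))
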