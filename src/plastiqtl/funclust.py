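"""Functional clustering of QTL effect curves into modules.

Each significant QTL is summarised by its genetic standard deviation
(GSD) curve — the weighted population standard deviation, across
genotype classes, of the fitted mean plasticity at each time point:

    g_s(t) = sqrt( (1/n) sum_j n_j mu_j(t)^2 - ((1/n) sum_j n_j mu_j(t))^2 )

QTLs with similar temporal effect patterns are grouped by fitting a
finite mixture of T-variate normals to the GSD curves: module mean
curves are Legendre polynomials of configurable order, a single SAD(1)
covariance is shared across modules, and mixing proportions are
multinomial.  EM with k-means initialisation and multi-start maximises
the likelihood; the number of modules is chosen by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.optimize import minimize
from scipy.special import logsumexp

from .growth import TimeGrid
from .sad import SAD1Params, sad1_covariance

__all__ = [
    "GSDCurve",
    "ModuleSolution",
    "gsd_curve",
    "em_fit",
    "select_modules",
    "module_effect_summary",
]


@dataclass(frozen=True)
class GSDCurve:
    """Time-varying genetic standard deviation of one SNP (leaves units)."""

    snp_id: object
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < -1e-12):
            raise ValueError("GSD values must be non-negative")


def gsd_curve(model, grid: TimeGrid) -> GSDCurve:
    """GSD curve of a fitted per-genotype model (weights n_j / n).

    A single-class model has zero genetic variance at every time point.
    """
    curves = np.stack([c.mean_curve(grid) for c in model.classes])
    w = np.array([c.n for c in model.classes], dtype=float)
    w /= w.sum()
    if len(model.classes) == 1:
        import warnings

        warnings.warn("single genotype class: GSD curve is identically zero",
                      stacklevel=2)
        return GSDCurve(model.snp_index, np.zeros(len(grid)))
    m1 = w @ curves
    m2 = w @ curves**2
    var = np.clip(m2 - m1**2, 0.0, None)
    return GSDCurve(model.snp_index, np.sqrt(var))


@dataclass
class ModuleSolution:
    """Fitted mixture over GSD curves for one module count L."""

    L: int
    pi: np.ndarray                # (L,)
    coefficients: np.ndarray      # (L, order+1) Legendre coefficients
    mean_curves: np.ndarray       # (L, T)
    sad_params: SAD1Params
    responsibilities: np.ndarray  # (S, L)
    assignments: np.ndarray       # (S,) argmax responsibility
    loglik: float
    bic: float
    n_free_params: int
    loglik_path: np.ndarray

    def members(self, snp_ids) -> dict:
        out: dict = {l: [] for l in range(self.L)}
        for sid, a in zip(snp_ids, self.assignments):
            out[int(a)].append(sid)
        return out


def _legendre_basis(T: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, T)
    return np.polynomial.legendre.legvander(x, order)  # (T, order+1)


def _mvn_logpdf(G: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Rows of G against mean rows mu (L, T): returns (S, L)."""
    T = G.shape[1]
    chol = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    diff = G[:, None, :] - mu[None, :, :]  # (S, L, T)
    w = np.linalg.solve(chol, diff.reshape(-1, T).T).T.reshape(diff.shape)
    quad = np.sum(w * w, axis=-1)
    return -0.5 * (T * np.log(2 * np.pi) + logdet + quad)


def _fit_sad_q(S_mat: np.ndarray, start: tuple, T: int) -> tuple[SAD1Params, float]:
    """Maximise the Gaussian profile objective for a single SAD(1) block.

    Minimises log|Sigma| + tr(Sigma^{-1} S) over (phi, nu2) by Nelder-Mead
    on (arctanh phi, log nu2); returns the params and attained objective.
    """

    def obj(x):
        phi = float(np.clip(np.tanh(x[0]), -1 + 1e-9, 1 - 1e-9))
        nu2 = np.exp(np.clip(x[1], -25, 25))
        sigma = sad1_covariance(SAD1Params(phi, nu2), T)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return logdet + float(np.trace(np.linalg.solve(sigma, S_mat)))

    x0 = np.array([np.arctanh(np.clip(start[0], -0.99, 0.99)), np.log(start[1])])
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400})
    best = res.x if res.fun <= obj(x0) else x0
    phi = float(np.clip(np.tanh(best[0]), -1 + 1e-9, 1 - 1e-9))
    nu2 = float(np.exp(np.clip(best[1], -25, 25)))
    return SAD1Params(phi, nu2), float(min(res.fun, obj(x0)))


def _as_matrix(gsd) -> tuple[np.ndarray, list]:
    if isinstance(gsd, np.ndarray):
        return np.asarray(gsd, dtype=float), list(range(gsd.shape[0]))
    mats = np.stack([c.values for c in gsd])
    return mats, [c.snp_id for c in gsd]


def em_fit(
    gsd,
    L: int,
    seed: int = 0,
    order: int = 4,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ModuleSolution:
    """EM fit of the L-module mixture to a set of GSD curves.

    ``gsd`` is a list of GSDCurve or an (S, T) array.  Multi-start
    (k-means initialisations with different seeds), best log-likelihood
    kept; the log-likelihood is checked to be non-decreasing at every EM
    iteration.
    """
    G, _ = _as_matrix(gsd)
    S, T = G.shape
    if S == 0:
        raise ValueError("no GSD curves supplied")
    if not 1 <= L <= S:
        raise ValueError(f"need 1 <= L <= S, got L={L}, S={S}")
    best = None
    for k in range(max(n_starts, 1)):
        sol = _em_once(G, L, order, seed + k, max_iter, tol)
        if best is None or sol.loglik > best.loglik:
            best = sol
    return best


def _em_once(G, L, order, seed, max_iter, tol) -> ModuleSolution:
    S, T = G.shape
    B = _legendre_basis(T, order)
    rng = np.random.default_rng(seed)

    # initial hard assignment: k-means++ on the raw curves
    if L == 1:
        assign = np.zeros(S, dtype=int)
    else:
        _, assign = kmeans2(G, L, minit="++", seed=rng)
        # ensure no empty initial cluster
        for l in range(L):
            if not np.any(assign == l):
                assign[rng.integers(S)] = l
    resp = np.zeros((S, L))
    resp[np.arange(S), assign] = 1.0

    pi = np.full(L, 1.0 / L)
    coeffs = np.zeros((L, order + 1))
    sad = SAD1Params(0.5, max(float(np.var(G)), 1e-6))
    sigma = sad1_covariance(sad, T)
    loglik = -np.inf
    path = []

    for it in range(max_iter):
        # ---- M-step (from current responsibilities) ----
        nk = resp.sum(axis=0)
        nk = np.clip(nk, 1e-10, None)
        pi_new = nk / S
        gbar = (resp.T @ G) / nk[:, None]  # (L, T) weighted mean curves
        prec = np.linalg.inv(sigma)
        BtP = B.T @ prec
        H = BtP @ B
        coeffs_new = np.linalg.solve(H, BtP @ gbar.T).T
        mu = coeffs_new @ B.T  # (L, T)
        diff = G[:, None, :] - mu[None, :, :]
        S_resp = np.einsum("sl,slt,slu->tu", resp, diff, diff) / S
        sad_new, q_new = _fit_sad_q(S_resp, (sad.phi, sad.nu2), T)
        # keep the better of old/new covariance in the Q sense (EM safety)
        sigma_old = sad1_covariance(sad, T)
        q_old = float(
            np.linalg.slogdet(sigma_old)[1]
            + np.trace(np.linalg.solve(sigma_old, S_resp))
        )
        if q_new <= q_old:
            sad = sad_new
        sigma = sad1_covariance(sad, T)

        pi, coeffs = pi_new, coeffs_new
        mu = coeffs @ B.T

        # ---- E-step + log-likelihood ----
        logp = _mvn_logpdf(G, mu, sigma) + np.log(pi)[None, :]
        ll_rows = logsumexp(logp, axis=1)
        loglik_new = float(ll_rows.sum())
        resp = np.exp(logp - ll_rows[:, None])
        path.append(loglik_new)
        if loglik_new < loglik - 1e-6 * max(1.0, abs(loglik)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{loglik:.8g} -> {loglik_new:.8g}"
            )
        if np.isfinite(loglik) and abs(loglik_new - loglik) <= tol * max(1.0, abs(loglik)):
            loglik = loglik_new
            break
        loglik = loglik_new

    d = L * (order + 1) + 2 + (L - 1)
    bic = -2.0 * loglik + d * np.log(S)
    return ModuleSolution(
        L=L,
        pi=pi,
        coefficients=coeffs,
        mean_curves=coeffs @ B.T,
        sad_params=sad,
        responsibilities=resp,
        assignments=np.argmax(resp, axis=1),
        loglik=loglik,
        bic=float(bic),
        n_free_params=d,
        loglik_path=np.asarray(path),
    )


def select_modules(
    gsd,
    L_range,
    seed: int = 0,
    order: int = 4,
    n_starts: int = 10,
) -> tuple[int, dict, pd.DataFrame]:
    """Fit every candidate module count and pick the BIC minimiser.

    Returns (best L, {L: ModuleSolution}, BIC table).  Ties break toward
    the smaller L.
    """
    L_range = sorted(set(int(L) for L in L_range))
    if not L_range:
        raise ValueError("L_range is empty")
    G, _ = _as_matrix(gsd)
    if max(L_range) > G.shape[0]:
        raise ValueError("max module count exceeds the number of curves")
    solutions = {}
    for L in L_range:
        solutions[L] = em_fit(gsd, L, seed=seed + 1000 * L, order=order,
                              n_starts=n_starts)
    table = pd.DataFrame(
        {
            "L": L_range,
            "loglik": [solutions[L].loglik for L in L_range],
            "n_free_params": [solutions[L].n_free_params for L in L_range],
            "bic": [solutions[L].bic for L in L_range],
        }
    )
    best_L = int(table.loc[table["bic"].idxmin(), "L"])
    return best_L, solutions, table


def module_effect_summary(solution: ModuleSolution, gsd) -> pd.DataFrame:
    """Per-module mean effect curve on the grid plus member SNP lists."""
    _, snp_ids = _as_matrix(gsd)
    members = solution.members(snp_ids)
    rows = []
    for l in range(solution.L):
        rows.append(
            {
                "module": l,
                "pi": float(solution.pi[l]),
                "n_members": len(members[l]),
                "members": ",".join(str(s) for s in members[l]),
                **{
                    f"t{k + 1}": float(v)
                    for k, v in enumerate(solution.mean_curves[l])
                },
            }
        )
    return pd.DataFrame(rows)
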