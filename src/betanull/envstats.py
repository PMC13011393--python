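"""Environmental heterogeneity and community-environment association.

Variables are z-scored (mean 0, unit sample sd); heterogeneity is the
pairwise Euclidean distance on the standardized table.  Distance-based
redundancy analysis embeds the community dissimilarity by principal
coordinates (double-centred -0.5 * J D^2 J) and regresses the retained
axes on the standardized environmental variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .tables import EnvTable

__all__ = [
    "standardize",
    "env_distance",
    "beta_env_association",
    "dbrda",
    "DbRdaResult",
    "MantelResult",
]

logger = logging.getLogger(__name__)


def standardize(env: EnvTable) -> EnvTable:
    """z-score each variable (sample sd, n-1 denominator)."""
    sd = env.values.std(axis=0, ddof=1)
    constant = [v for v, s in zip(env.variable_names, sd) if s == 0]
    if constant:
        raise ValueError(f"constant environmental variable(s): {constant}")
    z = (env.values - env.values.mean(axis=0)) / sd
    return EnvTable(list(env.sample_ids), list(env.variable_names), z)


def env_distance(env_z: EnvTable) -> np.ndarray:
    """Square symmetric Euclidean distance matrix on a standardized table."""
    return squareform(pdist(env_z.values, metric="euclidean"))


@dataclass
class MantelResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_perm: int


def beta_env_association(
    beta_pairs: np.ndarray,
    env_pairs: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """OLS of pairwise beta on pairwise env distance, Mantel permutation p.

    Both inputs are condensed (upper-triangle) pairwise vectors over the
    same sample ordering.  Because pairs sharing a sample are not
    independent, significance is assessed by permuting sample labels of the
    beta matrix and recomputing the correlation.
    """
    beta_pairs = np.asarray(beta_pairs, dtype=float)
    env_pairs = np.asarray(env_pairs, dtype=float)
    if beta_pairs.shape != env_pairs.shape:
        raise ValueError("pair vectors must have matching shapes")
    if beta_pairs.size < 3:
        raise ValueError("need at least 3 pairs")
    slope, intercept = np.polyfit(env_pairs, beta_pairs, 1)
    if np.ptp(beta_pairs) == 0 or np.ptp(env_pairs) == 0:
        warnings.warn("degenerate (constant) pair vector", RuntimeWarning, stacklevel=2)
        return MantelResult(float(slope), float(intercept), float("nan"), 1.0, 0)
    r_obs = float(np.corrcoef(env_pairs, beta_pairs)[0, 1])
    beta_sq = squareform(beta_pairs)
    n = beta_sq.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(
            env_pairs, squareform(beta_sq[np.ix_(perm, perm)])
        )[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(float(slope), float(intercept), r_obs, float(p), n_perm)


@dataclass
class DbRdaResult:
    total_inertia: float
    constrained_inertia: float
    r_squared: float
    global_f: float
    global_p: float
    variable_f: dict[str, float]
    variable_p: dict[str, float]
    n_perm: int
    n_axes: int
    negative_eigenvalue_mass: float


def _pcoa_coordinates(dissim: np.ndarray, correction: bool = False):
    """PCoA embedding; returns (coordinates, discarded negative-eig mass)."""
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be square and symmetric")
    d2 = d**2
    if correction:
        # Lingoes: add 2c to all squared off-diagonal dissimilarities
        j = np.eye(n) - np.ones((n, n)) / n
        eigvals = np.linalg.eigvalsh(-0.5 * j @ d2 @ j)
        c = -eigvals.min()
        if c > 0:
            d2 = d2 + 2 * c * (1 - np.eye(n))
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-8 * max(abs(eigvals.max()), 1.0)
    pos = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    if neg_mass > 0:
        logger.info("discarded negative PCoA eigenvalue mass: %.6g", neg_mass)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    return coords, neg_mass


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def dbrda(
    community_dissim: np.ndarray,
    env_z: EnvTable,
    n_perm: int = 999,
    seed: int = 0,
    correction: bool = False,
) -> DbRdaResult:
    """Distance-based redundancy analysis of a dissimilarity on env_z.

    The global test permutes env rows; marginal per-variable tests permute
    residuals under the reduced model omitting that variable.
    """
    n = len(env_z.sample_ids)
    m = len(env_z.variable_names)
    if community_dissim.shape != (n, n):
        raise ValueError("dissimilarity and env table sample sets differ")
    if m > n - 1:
        raise ValueError("more explanatory variables than samples - 1")
    y, neg_mass = _pcoa_coordinates(community_dissim, correction=correction)
    y = y - y.mean(axis=0)
    x = env_z.values - env_z.values.mean(axis=0)
    total = float((y**2).sum())
    h = _hat(x)
    fitted = h @ y
    constrained = float((fitted**2).sum())
    residual = total - constrained
    df_res = n - m - 1
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    f_obs = (constrained / m) / (residual / df_res)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        hp = _hat(xp)
        cp = float(((hp @ y) ** 2).sum())
        fp = (cp / m) / ((total - cp) / df_res)
        if fp >= f_obs - 1e-12:
            hits += 1
    global_p = (hits + 1) / (n_perm + 1)

    var_f: dict[str, float] = {}
    var_p: dict[str, float] = {}
    for vj, name in enumerate(env_z.variable_names):
        x_red = np.delete(x, vj, axis=1)
        h_red = _hat(x_red) if x_red.shape[1] else np.zeros((n, n))
        fit_red = h_red @ y
        res_red = y - fit_red
        ss_red = float((fit_red**2).sum())
        fj_obs = (constrained - ss_red) / (residual / df_res)
        hits_j = 0
        for _ in range(n_perm):
            yp = fit_red + res_red[rng.permutation(n)]
            ss_full_p = float(((h @ yp) ** 2).sum())
            ss_red_p = float(((h_red @ yp) ** 2).sum())
            res_p = float((yp**2).sum()) - ss_full_p
            fj_p = (ss_full_p - ss_red_p) / (res_p / df_res)
            if fj_p >= fj_obs - 1e-12:
                hits_j += 1
        var_f[name] = float(fj_obs)
        var_p[name] = (hits_j + 1) / (n_perm + 1)

    return DbRdaResult(
        total_inertia=total,
        constrained_inertia=constrained,
        r_squared=constrained / total if total > 0 else 0.0,
        global_f=float(f_obs),
        global_p=float(global_p),
        variable_f=var_f,
        variable_p=var_p,
        n_perm=n_perm,
        n_axes=y.shape[1],
        negative_eigenvalue_mass=neg_mass,
    )
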