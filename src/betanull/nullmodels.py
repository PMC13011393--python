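"""Constrained taxonomic null models and the beta-deviation effect size.

Two randomization schemes are provided.  Both preserve each sample's
observed richness and total count and draw taxa only from the regional pool:

* MODEL_I ("gamma" scheme) — taxa drawn uniformly from the regional pool;
  the sample's observed non-zero abundance values are permuted onto the
  drawn taxa, so the abundance-value multiset is preserved exactly.
* MODEL_II ("pool" scheme) — taxa drawn without replacement with selection
  probability proportional to occurrence frequency (sp_freq); one
  individual is guaranteed per drawn taxon and the remaining individuals
  are allocated multinomially in proportion to the pooled relative
  abundances renormalized over the drawn set.

Weighted sampling without replacement uses Gumbel top-k keys, which is
distribution-equivalent to sequential draws with renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .diversity import pairwise_bray_curtis
from .tables import CommunityTable, RegionalPool, pool_region

__all__ = [
    "NullScheme",
    "NullEnsemble",
    "BetaDeviation",
    "ExpectedBetaGammaCurve",
    "null_model_I",
    "null_model_II",
    "null_ensemble",
    "beta_deviation",
    "interpret_deviation",
    "expected_beta_gamma",
    "weighted_sample_without_replacement",
    "draw_null_sample_counts",
]


class NullScheme(str, Enum):
    MODEL_I = "gamma"
    MODEL_II = "pool"


@dataclass
class NullEnsemble:
    region: str
    scheme: NullScheme
    n_perm: int
    seed: int
    null_beta_means: np.ndarray
    null_tables: list[np.ndarray] = field(default_factory=list)


@dataclass
class BetaDeviation:
    region: str
    scheme: NullScheme
    beta_obs: float
    null_mean: float
    null_sd: float
    ses: float  # NaN (flagged) when null_sd == 0


def weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of k items drawn without replacement, p proportional to weights."""
    weights = np.asarray(weights, dtype=float)
    if k > weights.size:
        raise ValueError("cannot draw more items than available")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    # Gumbel top-k == successive sampling proportional to weights.
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(keys, weights.size - k)[-k:]


def draw_null_sample_counts(
    rng: np.random.Generator,
    pool_rel_abund: np.ndarray,
    sp_freq: np.ndarray,
    richness: int,
    total: int,
) -> np.ndarray:
    """One pool-constrained null sample (MODEL_II / Raup-Crick style draw)."""
    gamma = pool_rel_abund.size
    if richness > gamma:
        raise ValueError("richness exceeds the regional pool size")
    if total < richness:
        raise ValueError("total count below richness")
    drawn = weighted_sample_without_replacement(rng, sp_freq, richness)
    counts = np.zeros(gamma, dtype=np.int64)
    counts[drawn] = 1
    remainder = total - richness
    if remainder > 0:
        p = pool_rel_abund[drawn]
        counts[drawn] += rng.multinomial(remainder, p / p.sum())
    return counts


def _null_table_model_I(
    rng: np.random.Generator, region_counts: np.ndarray
) -> np.ndarray:
    gamma, n_samples = region_counts.shape
    out = np.zeros_like(region_counts)
    for j in range(n_samples):
        values = region_counts[region_counts[:, j] > 0, j]
        drawn = rng.choice(gamma, size=values.size, replace=False)
        out[drawn, j] = rng.permutation(values)
    return out


def _null_table_model_II(
    rng: np.random.Generator, region_counts: np.ndarray, pool: RegionalPool
) -> np.ndarray:
    out = np.zeros_like(region_counts)
    for j in range(region_counts.shape[1]):
        col = region_counts[:, j]
        out[:, j] = draw_null_sample_counts(
            rng,
            pool.pool_rel_abund,
            pool.sp_freq.astype(float),
            richness=int((col > 0).sum()),
            total=int(col.sum()),
        )
    return out


def null_ensemble(
    table: CommunityTable,
    region: str,
    scheme: NullScheme | str,
    n_perm: int = 1000,
    seed: int = 0,
    keep_tables: bool = False,
) -> NullEnsemble:
    """Generate ``n_perm`` constrained null tables and their mean pairwise BC."""
    scheme = NullScheme(scheme)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sub, samples = table.region_submatrix(region)
    if len(samples) < 2:
        raise ValueError(f"region {region!r} has fewer than 2 samples")
    pool = pool_region(table, region)
    region_counts = sub[pool.taxa_idx]
    rng = np.random.default_rng(seed)
    betas = np.empty(n_perm)
    tables: list[np.ndarray] = []
    for p in range(n_perm):
        if scheme is NullScheme.MODEL_I:
            null = _null_table_model_I(rng, region_counts)
        else:
            null = _null_table_model_II(rng, region_counts, pool)
        betas[p] = pairwise_bray_curtis(null).mean()
        if keep_tables:
            tables.append(null)
    return NullEnsemble(
        region=region,
        scheme=scheme,
        n_perm=n_perm,
        seed=seed,
        null_beta_means=betas,
        null_tables=tables,
    )


def null_model_I(
    table: CommunityTable, region: str, n_perm: int = 1000, seed: int = 0, **kw
) -> NullEnsemble:
    return null_ensemble(table, region, NullScheme.MODEL_I, n_perm, seed, **kw)


def null_model_II(
    table: CommunityTable, region: str, n_perm: int = 1000, seed: int = 0, **kw
) -> NullEnsemble:
    return null_ensemble(table, region, NullScheme.MODEL_II, n_perm, seed, **kw)


def beta_deviation(beta_obs: float, ensemble: NullEnsemble) -> BetaDeviation:
    """Standardized effect size (beta_obs - mean(null)) / sd(null), ddof=1."""
    null = np.asarray(ensemble.null_beta_means, dtype=float)
    if null.size == 0:
        raise ValueError("empty null ensemble")
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if null_sd == 0:
        warnings.warn(
            f"null sd is zero for region {ensemble.region!r}; ses undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        ses = float("nan")
    else:
        ses = (beta_obs - null_mean) / null_sd
    return BetaDeviation(
        region=ensemble.region,
        scheme=ensemble.scheme,
        beta_obs=float(beta_obs),
        null_mean=null_mean,
        null_sd=null_sd,
        ses=ses,
    )


def interpret_deviation(ses: float, zero_tol: float = 0.05) -> str:
    """Qualitative reading of the beta-deviation sign.

    Positive: heterogeneous selection or dispersal limitation; negative:
    homogeneous selection or homogenizing dispersal; near zero: drift.
    """
    if not np.isfinite(ses):
        raise ValueError("ses must be finite")
    if abs(ses) < zero_tol:
        return "drift-dominated"
    return "HeS-or-DL" if ses > 0 else "HoS-or-HD"


@dataclass
class ExpectedBetaGammaCurve:
    gamma_grid: np.ndarray
    n_individuals: int
    sad_log_mean: float
    sad_log_sd: float
    reps: int
    seed: int
    expected_beta: np.ndarray
    mc_se: np.ndarray


def expected_beta_gamma(
    gamma_grid,
    n_individuals: int,
    sad_log_mean: float = 0.0,
    sad_log_sd: float = 1.0,
    reps: int = 200,
    seed: int = 0,
) -> ExpectedBetaGammaCurve:
    """Expected Bray-Curtis between random pairs drawn from lognormal pools.

    For each pool richness in ``gamma_grid``, a fresh lognormal abundance
    pool is drawn per replicate; two samples of ``n_individuals`` are taken
    multinomially and their Bray-Curtis averaged over replicates.
    """
    gamma_grid = np.asarray(gamma_grid, dtype=int)
    if np.any(np.diff(gamma_grid) <= 0):
        raise ValueError("gamma_grid must be strictly increasing")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    expected = np.empty(gamma_grid.size)
    se = np.empty(gamma_grid.size)
    for g_i, gamma in enumerate(gamma_grid):
        vals = np.empty(reps)
        for r in range(reps):
            if gamma == 1:
                vals[r] = 0.0
                continue
            abund = rng.lognormal(sad_log_mean, sad_log_sd, size=gamma)
            p = abund / abund.sum()
            x = rng.multinomial(n_individuals, p)
            y = rng.multinomial(n_individuals, p)
            vals[r] = np.abs(x - y).sum() / (2 * n_individuals)
        expected[g_i] = vals.mean()
        se[g_i] = vals.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
    return ExpectedBetaGammaCurve(
        gamma_grid=gamma_grid,
        n_individuals=int(n_individuals),
        sad_log_mean=sad_log_mean,
        sad_log_sd=sad_log_sd,
        reps=reps,
        seed=seed,
        expected_beta=expected,
        mc_se=se,
    )
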