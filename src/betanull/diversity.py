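"""Alpha, beta and gamma diversity on count tables.

Beta-diversity is the mean pairwise Bray-Curtis dissimilarity among the
samples within a region; gamma is the pooled observed richness.  Bray-Curtis
is computed on the (rarefied) counts directly rather than on relative
abundances — at equal depth the two are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import CommunityTable, pool_region

__all__ = [
    "bray_curtis",
    "pairwise_bray_curtis",
    "alpha_richness",
    "regional_diversity",
    "RegionalDiversity",
]


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    denom = float(x.sum() + y.sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def pairwise_bray_curtis(counts: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Bray-Curtis for columns of a counts matrix."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[1]
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("Bray-Curtis undefined for all-zero sample columns")
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        diff = np.abs(counts[:, i + 1 :] - counts[:, i : i + 1]).sum(axis=0)
        out[k : k + n - 1 - i] = diff / (totals[i + 1 :] + totals[i])
        k += n - 1 - i
    return out


def alpha_richness(column: np.ndarray) -> int:
    """Observed richness: number of taxa with count > 0."""
    return int((np.asarray(column) > 0).sum())


@dataclass
class RegionalDiversity:
    region: str
    alpha: dict[str, int]
    beta_pairs: list[tuple[str, str, float]]  # (sample_i, sample_j, BC)
    beta_mean: float
    gamma: int


def regional_diversity(table: CommunityTable, region: str) -> RegionalDiversity:
    """Per-region alpha richness, pairwise Bray-Curtis and pooled gamma."""
    sub, samples = table.region_submatrix(region)
    if len(samples) < 2:
        raise ValueError(f"region {region!r} has fewer than 2 samples")
    condensed = pairwise_bray_curtis(sub)
    pairs = []
    k = 0
    for i in range(len(samples) - 1):
        for j in range(i + 1, len(samples)):
            pairs.append((samples[i], samples[j], float(condensed[k])))
            k += 1
    return RegionalDiversity(
        region=region,
        alpha={s: alpha_richness(sub[:, j]) for j, s in enumerate(samples)},
        beta_pairs=pairs,
        beta_mean=float(condensed.mean()),
        gamma=pool_region(table, region).gamma,
    )
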