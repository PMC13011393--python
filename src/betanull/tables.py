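"""Community tables, metadata, rarefaction and regional pooling.

Community tables are stored taxa x samples (taxa as rows), matching the
common amplicon-table convention.  All randomness is routed through
``numpy.random.Generator`` objects seeded explicitly by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "RegionalPool",
    "EnvTable",
    "read_community_table",
    "read_metadata",
    "write_community_table",
    "read_env_table",
    "rarefy",
    "pool_region",
]


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


class TableValidationError(ValueError):
    """Raised when a parsed table violates a structural invariant."""


@dataclass
class CommunityTable:
    """Integer abundance matrix (taxa x samples) with a sample->region map."""

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), non-negative integers
    sample_region: dict[str, str]
    sample_latitude: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            raise TableValidationError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicate sample ids")
        if self.counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise TableValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise TableValidationError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.sample_region]
        if missing:
            raise TableValidationError(
                f"samples missing from metadata: {', '.join(missing)}"
            )
        empty = [
            s for j, s in enumerate(self.sample_ids) if self.counts[:, j].sum() == 0
        ]
        if empty:
            raise TableValidationError(
                f"all-zero sample columns: {', '.join(empty)}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.sample_region[s], None)
        return list(seen)

    def region_samples(self, region: str) -> list[str]:
        out = [s for s in self.sample_ids if self.sample_region[s] == region]
        if not out:
            raise KeyError(f"unknown region: {region!r}")
        return out

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def region_submatrix(self, region: str) -> tuple[np.ndarray, list[str]]:
        """Counts restricted to a region's samples (all taxa rows kept)."""
        samples = self.region_samples(region)
        idx = [self.sample_ids.index(s) for s in samples]
        return self.counts[:, idx], samples

    def prune_empty_taxa(self) -> "CommunityTable":
        keep = self.counts.sum(axis=1) > 0
        return CommunityTable(
            taxa_ids=[t for t, k in zip(self.taxa_ids, keep) if k],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep],
            sample_region=dict(self.sample_region),
            sample_latitude=dict(self.sample_latitude),
        )


@dataclass
class RegionalPool:
    """Per-region species-pool summary over the region's samples only."""

    region: str
    taxa_ids: list[str]  # taxa with pooled count > 0, table order
    taxa_idx: np.ndarray  # row indices into the parent table
    gamma: int
    sp_freq: np.ndarray  # occurrence frequency per pooled taxon
    pool_rel_abund: np.ndarray  # pooled relative abundance, sums to 1
    samp_rich: dict[str, int]
    samp_total: dict[str, int]

    def __post_init__(self) -> None:
        if self.gamma != len(self.taxa_ids):
            raise TableValidationError("gamma must equal the number of pooled taxa")
        if abs(float(self.pool_rel_abund.sum()) - 1.0) > 1e-9:
            raise TableValidationError("pool_rel_abund must sum to 1")
        n_samples = len(self.samp_rich)
        if np.any(self.sp_freq < 1) or np.any(self.sp_freq > n_samples):
            raise TableValidationError("sp_freq out of [1, n_samples]")
        for s, r in self.samp_rich.items():
            if r > self.gamma:
                raise TableValidationError(f"samp_rich[{s}] exceeds gamma")


@dataclass
class EnvTable:
    """Numeric environmental variables, samples x variables."""

    sample_ids: list[str]
    variable_names: list[str]
    values: np.ndarray  # (n_samples, n_vars), float, no NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variable_names)):
            raise TableValidationError("env values shape mismatch")
        if np.any(np.isnan(self.values)):
            raise TableValidationError("env table contains missing values")

    def subset(self, sample_ids: list[str]) -> "EnvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return EnvTable(list(sample_ids), list(self.variable_names), self.values[idx])


def read_metadata(path) -> tuple[dict[str, str], dict[str, float]]:
    """Read sample metadata TSV with columns sample, region, latitude."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "region": str})
    for col in ("sample", "region"):
        if col not in df.columns:
            raise TableFormatError(f"metadata missing required column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise TableValidationError(f"duplicate sample ids in metadata: {dup}")
    region = dict(zip(df["sample"], df["region"]))
    latitude = (
        dict(zip(df["sample"], df["latitude"].astype(float)))
        if "latitude" in df.columns
        else {}
    )
    return region, latitude


def read_community_table(path, metadata_path) -> CommunityTable:
    """Read a taxa-x-samples TSV (first column ``taxon_id``) plus metadata."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    taxa_ids = df[first].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy()
    for j, col in enumerate(sample_ids):
        colvals = raw[:, j]
        numeric = pd.to_numeric(pd.Series(colvals), errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"non-numeric count at taxon {taxa_ids[i]!r}, sample {col!r}"
            )
        vals = numeric.to_numpy()
        if np.any(vals < 0):
            i = int(np.flatnonzero(vals < 0)[0])
            raise TableFormatError(
                f"negative count at taxon {taxa_ids[i]!r}, sample {col!r}"
            )
        if np.any(vals != np.floor(vals)):
            i = int(np.flatnonzero(vals != np.floor(vals))[0])
            raise TableFormatError(
                f"non-integer count at taxon {taxa_ids[i]!r}, sample {col!r}"
            )
    counts = raw.astype(np.int64)
    region, latitude = read_metadata(metadata_path)
    missing = [s for s in sample_ids if s not in region]
    if missing:
        raise TableValidationError(
            f"samples missing from metadata: {', '.join(missing)}"
        )
    return CommunityTable(
        taxa_ids=taxa_ids,
        sample_ids=sample_ids,
        counts=counts,
        sample_region=region,
        sample_latitude=latitude,
    )


def write_community_table(table: CommunityTable, path) -> None:
    df = pd.DataFrame(table.counts, columns=table.sample_ids)
    df.insert(0, "taxon_id", table.taxa_ids)
    df.to_csv(path, sep="\t", index=False)


def write_metadata(table: CommunityTable, path) -> None:
    rows = [
        {
            "sample": s,
            "region": table.sample_region[s],
            "latitude": table.sample_latitude.get(s, float("nan")),
        }
        for s in table.sample_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_env_table(path, impute_mean: bool = False) -> EnvTable:
    """Read an env TSV (first column ``sample``).

    Missing values are rejected unless ``impute_mean`` is set, in which case
    each gap is filled with the variable's column mean.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        if impute_mean:
            values = values.fillna(values.mean())
        else:
            bad = values.columns[values.isna().any()].tolist()
            raise TableValidationError(
                f"missing values in environmental variables: {bad}"
            )
    return EnvTable(sample_ids, [str(c) for c in values.columns], values.to_numpy())


def write_env_table(env: EnvTable, path) -> None:
    df = pd.DataFrame(env.values, columns=env.variable_names)
    df.insert(0, "sample", env.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int,
    drop_shallow: bool = False,
) -> CommunityTable:
    """Subsample every column to ``depth`` reads without replacement.

    Draws are multivariate-hypergeometric per sample, so each rarefied count
    never exceeds the original and every retained column sums exactly to
    ``depth``.  Samples whose total is below ``depth`` raise unless
    ``drop_shallow`` is set, in which case they are discarded.
    """
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep: list[int] = []
    for j, s in enumerate(table.sample_ids):
        if totals[j] < depth:
            if drop_shallow:
                continue
            raise ValueError(
                f"sample {s!r} has total {totals[j]} below rarefaction depth {depth}"
            )
        keep.append(j)
    if not keep:
        raise ValueError("no samples at or above the rarefaction depth")
    out = np.zeros((table.n_taxa, len(keep)), dtype=np.int64)
    for k, j in enumerate(keep):
        col = table.counts[:, j]
        if totals[j] == depth:
            out[:, k] = col
        else:
            out[:, k] = rng.multivariate_hypergeometric(col, depth)
    sample_ids = [table.sample_ids[j] for j in keep]
    return CommunityTable(
        taxa_ids=list(table.taxa_ids),
        sample_ids=sample_ids,
        counts=out,
        sample_region=dict(table.sample_region),
        sample_latitude=dict(table.sample_latitude),
    )


def pool_region(table: CommunityTable, region: str) -> RegionalPool:
    """Summarize a region's species pool (taxa with pooled count > 0 only)."""
    sub, samples = table.region_submatrix(region)
    if len(samples) < 2:
        raise ValueError(f"region {region!r} has fewer than 2 samples")
    pooled = sub.sum(axis=1)
    idx = np.flatnonzero(pooled > 0)
    present = sub[idx] > 0
    return RegionalPool(
        region=region,
        taxa_ids=[table.taxa_ids[i] for i in idx],
        taxa_idx=idx,
        gamma=int(len(idx)),
        sp_freq=present.sum(axis=1).astype(np.int64),
        pool_rel_abund=pooled[idx] / pooled[idx].sum(),
        samp_rich={s: int((sub[:, j] > 0).sum()) for j, s in enumerate(samples)},
        samp_total={s: int(sub[:, j].sum()) for j, s in enumerate(samples)},
    )
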