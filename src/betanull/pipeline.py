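"""End-to-end orchestration: rarefaction through process partitioning.

Stages: rarefy -> per-region diversity -> null models (both schemes) ->
beta-deviation -> betaNTI/RC partition -> environmental heterogeneity ->
db-RDA.  Each stage writes a TSV and the run ends with a JSON manifest
recording every seed and parameter needed to regenerate the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import regional_diversity
from .envstats import beta_env_association, dbrda, env_distance, standardize
from .nullmodels import NullScheme, beta_deviation, interpret_deviation, null_ensemble
from .phylo import Phylogeny, partition_processes, region_process_metrics
from .tables import (
    CommunityTable,
    read_community_table,
    read_env_table,
    rarefy,
    write_community_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    community: str
    metadata: str
    tree: str | None = None
    env: str | None = None
    depth: int | None = None  # None: skip rarefaction
    drop_shallow: bool = False
    schemes: list[str] = field(default_factory=lambda: ["gamma", "pool"])
    n_perm: int = 1000
    n_null: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    bnti_shuffle: str = "tree"  # or "region"
    weighted: bool = True
    seed: int = 0
    out_dir: str = "betanull_out"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("load")
def _load(config: PipelineConfig) -> CommunityTable:
    return read_community_table(config.community, config.metadata)


@_stage("rarefy")
def _rarefy(config: PipelineConfig, table: CommunityTable, out: Path) -> CommunityTable:
    if config.depth is None:
        return table
    rarefied = rarefy(table, config.depth, seed=config.seed, drop_shallow=config.drop_shallow)
    write_community_table(rarefied, out / "rarefied.tsv")
    return rarefied


@_stage("diversity")
def _diversity(table: CommunityTable, out: Path) -> dict:
    summary, pairs = [], []
    results = {}
    for region in table.regions:
        rd = regional_diversity(table, region)
        results[region] = rd
        summary.append(
            {
                "region": region,
                "n_samples": len(rd.alpha),
                "gamma": rd.gamma,
                "alpha_mean": float(np.mean(list(rd.alpha.values()))),
                "beta_mean": rd.beta_mean,
            }
        )
        for si, sj, bc in rd.beta_pairs:
            pairs.append({"region": region, "sample_i": si, "sample_j": sj, "bray_curtis": bc})
    pd.DataFrame(summary).to_csv(out / "diversity_regions.tsv", sep="\t", index=False)
    pd.DataFrame(pairs).to_csv(out / "diversity_pairs.tsv", sep="\t", index=False)
    return results


@_stage("deviation")
def _deviation(config: PipelineConfig, table: CommunityTable, diversity, out: Path):
    rows = []
    for scheme in config.schemes:
        for region in table.regions:
            ens = null_ensemble(
                table, region, NullScheme(scheme), n_perm=config.n_perm, seed=config.seed
            )
            dev = beta_deviation(diversity[region].beta_mean, ens)
            rows.append(
                {
                    "region": region,
                    "scheme": scheme,
                    "beta_obs": dev.beta_obs,
                    "null_mean": dev.null_mean,
                    "null_sd": dev.null_sd,
                    "ses": dev.ses,
                    "label": (
                        interpret_deviation(dev.ses) if np.isfinite(dev.ses) else "undefined"
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(out / "beta_deviation.tsv", sep="\t", index=False)
    return rows


@_stage("partition")
def _partition(config: PipelineConfig, table: CommunityTable, out: Path):
    tree = Phylogeny.from_newick(config.tree)
    pair_rows, frac_rows = [], []
    for region in table.regions:
        metrics = region_process_metrics(
            table,
            region,
            tree,
            n_null=config.n_null,
            seed=config.seed,
            weighted=config.weighted,
            bnti_threshold=config.bnti_threshold,
            rc_threshold=config.rc_threshold,
            shuffle_pool=config.bnti_shuffle,
        )
        part = partition_processes(metrics)
        for m in metrics:
            pair_rows.append(
                {
                    "region": m.region,
                    "sample_i": m.sample_i,
                    "sample_j": m.sample_j,
                    "bray_curtis": m.bray_curtis,
                    "beta_mntd": m.beta_mntd_obs,
                    "beta_nti": m.beta_nti,
                    "rc_bray": m.rc_bray,
                    "process": m.process or "undefined",
                }
            )
        frac_rows.append({"region": region, "n_pairs": part.n_pairs, **part.fractions})
    pd.DataFrame(pair_rows).to_csv(out / "process_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(frac_rows).to_csv(out / "process_fractions.tsv", sep="\t", index=False)
    return frac_rows


@_stage("environment")
def _environment(config: PipelineConfig, table: CommunityTable, diversity, out: Path):
    env = read_env_table(config.env).subset(table.sample_ids)
    env_z = standardize(env)
    dist = env_distance(env_z)
    rows = []
    for i in range(len(env.sample_ids) - 1):
        for j in range(i + 1, len(env.sample_ids)):
            rows.append(
                {
                    "sample_i": env.sample_ids[i],
                    "sample_j": env.sample_ids[j],
                    "env_distance": dist[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(out / "env_distance.tsv", sep="\t", index=False)

    # within-region beta vs env-heterogeneity association
    assoc_rows = []
    sample_pos = {s: k for k, s in enumerate(env.sample_ids)}
    for region, rd in diversity.items():
        if len(rd.beta_pairs) < 3:
            continue
        beta = np.array([bc for _, _, bc in rd.beta_pairs])
        envd = np.array([dist[sample_pos[a], sample_pos[b]] for a, b, _ in rd.beta_pairs])
        if beta.std() == 0 or envd.std() == 0:
            continue
        res = beta_env_association(beta, envd, n_perm=config.n_perm, seed=config.seed)
        assoc_rows.append(
            {
                "region": region,
                "slope": res.slope,
                "intercept": res.intercept,
                "r": res.r,
                "p_value": res.p_value,
            }
        )
    pd.DataFrame(assoc_rows).to_csv(out / "beta_env_association.tsv", sep="\t", index=False)

    # db-RDA of the full Bray-Curtis matrix on standardized variables
    from .diversity import pairwise_bray_curtis
    from scipy.spatial.distance import squareform

    order = [table.sample_ids.index(s) for s in env.sample_ids]
    bc = squareform(pairwise_bray_curtis(table.counts[:, order]))
    res = dbrda(bc, env_z, n_perm=min(config.n_perm, 999), seed=config.seed)
    summary = {
        "total_inertia": res.total_inertia,
        "constrained_inertia": res.constrained_inertia,
        "r_squared": res.r_squared,
        "global_f": res.global_f,
        "global_p": res.global_p,
        "n_axes": res.n_axes,
        "negative_eigenvalue_mass": res.negative_eigenvalue_mass,
    }
    var_rows = [
        {"variable": v, "pseudo_f": res.variable_f[v], "p_value": res.variable_p[v]}
        for v in env.variable_names
    ]
    pd.DataFrame([summary]).to_csv(out / "dbrda_summary.tsv", sep="\t", index=False)
    pd.DataFrame(var_rows).to_csv(out / "dbrda_variables.tsv", sep="\t", index=False)
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = _load(config)
    table = _rarefy(config, table, out)
    diversity = _diversity(table, out)
    _deviation(config, table, diversity, out)
    if config.tree:
        _partition(config, table, out)
    if config.env:
        _environment(config, table, diversity, out)
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "regions": table.regions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
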