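"""End-to-end orchestration: validate -> filter -> aggregate -> alpha ->
beta -> indicator taxa -> networks -> cross-site comparison.

Every stochastic stage derives its own seed from the run seed, every stage's
outputs land under the run directory as TSV/JSON/Newick/GraphML, and a
manifest (tool version, config hash, input checksums, per-stage timing and
warnings) is written whether the run succeeds or halts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .alpha import alpha_pipeline
from .beta import (betadisper, envfit, nmds, pairwise_permanova, permanova,
                   pcoa, unifrac)
from .datatypes import GillnetError
from .indicators import indval_analysis
from .network import (compare_networks, export_network, site_networks,
                      node_metrics, top_n_subgraph)
from .preprocess import aggregate_by_rank, filter_dataset, to_relative_activity

logger = logging.getLogger(__name__)

DEFAULT_ENV_VARIABLES = ("latitude", "air_temperature", "water_temperature",
                         "salinity", "pH", "chlorophyll_a", "O2_concentration")

_DISTANCES = ("weighted_unifrac", "weighted_unifrac_raw", "unweighted_unifrac")


@dataclasses.dataclass
class RunConfig:
    """Fully explicit configuration for one pipeline run.

    Defaults reproduce the reference parameterization: a 10,000-count
    sample floor, a 1e-5 mean relative-activity feature floor, genus-level
    networks thresholded at |rho| > 0.4 with FDR < 0.05, 9,999 permutations
    everywhere, and an IndVal significance filter of 0.5 / 0.05.
    """

    table: str
    taxonomy: str
    metadata: str
    tree: str
    out_dir: str = "gillnet_run"
    seed: int = 0
    min_sample_total: float = 10_000.0
    min_mean_relative: float = 1e-5
    rank: str = "genus"
    permutations: int = 9999
    main_distance: str = "weighted_unifrac"
    pairwise_distance: str = "unweighted_unifrac"
    nmds_axes: int = 2
    nmds_starts: int = 20
    env_variables: tuple = DEFAULT_ENV_VARIABLES
    indval_threshold: float = 0.5
    indval_alpha: float = 0.05
    network_threshold: float = 0.4
    network_alpha: float = 0.05
    network_min_samples: int = 4
    network_top_n: int = 50

    def __post_init__(self):
        if self.main_distance not in _DISTANCES:
            raise GillnetError(f"unknown distance: {self.main_distance!r}")
        if self.pairwise_distance not in _DISTANCES:
            raise GillnetError(f"unknown distance: {self.pairwise_distance!r}")
        if self.permutations < 1:
            raise GillnetError("permutations must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise GillnetError(f"unknown config key(s): {unknown}")
        if "env_variables" in raw:
            raw["env_variables"] = tuple(raw["env_variables"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["env_variables"] = list(d["env_variables"])
        return d


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _distance(table, tree, which):
    if which == "weighted_unifrac":
        return unifrac(table, tree, weighted=True, normalized=True)
    if which == "weighted_unifrac_raw":
        return unifrac(table, tree, weighted=True, normalized=False)
    return unifrac(table, tree, weighted=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; halt on failure with prior outputs intact."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(8)]
    manifest = {
        "tool": "gillnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "inputs": {k: {"path": getattr(config, k),
                       "sha256": _checksum(getattr(config, k))}
                   for k in ("table", "taxonomy", "metadata", "tree")},
        "stages": [],
        "status": "running",
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def stage(name):
        def wrapper(fn):
            start = time.perf_counter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    result = fn()
                except Exception as exc:
                    manifest["stages"].append({
                        "name": name, "status": "failed", "error": str(exc),
                        "seconds": round(time.perf_counter() - start, 3)})
                    manifest["status"] = f"failed at stage {name}"
                    _write_manifest()
                    raise GillnetError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append({
                "name": name, "status": "ok",
                "seconds": round(time.perf_counter() - start, 3),
                "warnings": [str(w.message) for w in caught]})
            logger.info("stage %s done", name)
            _write_manifest()
            return result
        return wrapper

    # 1 — load and validate -------------------------------------------------
    def _load():
        table = gio.read_feature_table(config.table)
        taxonomy = gio.read_taxonomy(config.taxonomy)
        metadata = gio.read_metadata(config.metadata)
        tree = gio.read_tree(config.tree)
        subset, report = gio.validate_dataset(table, taxonomy, metadata, tree,
                                              strict=False)
        (out / "validation_report.json").write_text(report.to_json(indent=2))
        return subset, taxonomy, metadata, tree
    table, taxonomy, metadata, tree = stage("validate")(_load)

    # 2 — filter ------------------------------------------------------------
    def _filter():
        filtered, report = filter_dataset(
            table, min_sample_total=config.min_sample_total,
            min_mean_relative=config.min_mean_relative)
        gio.write_feature_table(filtered, out / "filtered_table.tsv")
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                 index=False)
        return filtered
    filtered = stage("filter")(_filter)
    meta_sub = metadata.select(filtered.sample_ids)

    # 3 — aggregate ---------------------------------------------------------
    def _aggregate():
        ranked = aggregate_by_rank(filtered, taxonomy, config.rank)
        gio.write_feature_table(ranked, out / f"{config.rank}_table.tsv")
        return ranked
    ranked = stage("aggregate")(_aggregate)

    # 4 — alpha -------------------------------------------------------------
    def _alpha():
        frame, tests = alpha_pipeline(filtered, tree, meta_sub)
        frame.to_csv(out / "alpha_diversity.tsv", sep="\t",
                     index_label="sample_id", float_format="%.10g")
        (out / "alpha_tests.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in tests.items()}, indent=2))
        return frame, tests
    stage("alpha")(_alpha)

    # 5 — beta --------------------------------------------------------------
    def _beta():
        dm_main = _distance(filtered, tree, config.main_distance)
        gio.write_distance_matrix(dm_main, out / f"{config.main_distance}.tsv")
        dm_pair = (dm_main if config.pairwise_distance == config.main_distance
                   else _distance(filtered, tree, config.pairwise_distance))
        if config.pairwise_distance != config.main_distance:
            gio.write_distance_matrix(dm_pair,
                                      out / f"{config.pairwise_distance}.tsv")
        groups = meta_sub.communities

        ord_res = pcoa(dm_main)
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                   index_label="sample_id", float_format="%.10g")
        perm = permanova(dm_main, groups, config.permutations, seed=seeds[0])
        pw = pairwise_permanova(dm_pair, groups, config.permutations,
                                seed=seeds[1])
        pw.to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False,
                  float_format="%.10g")
        disp = betadisper(dm_main, groups, config.permutations, seed=seeds[2])
        nm = nmds(dm_main, k=config.nmds_axes, n_starts=config.nmds_starts,
                  seed=seeds[3])
        nm.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t",
                              index_label="sample_id", float_format="%.10g")
        env_cols = [c for c in config.env_variables if c in meta_sub.df.columns]
        fit = envfit(nm.coordinates, meta_sub.df[env_cols],
                     config.permutations, seed=seeds[4])
        fit.to_csv(out / "envfit.tsv", sep="\t", index=False,
                   float_format="%.10g")
        beta_summary = {
            "pcoa_proportion_explained":
                [float(x) for x in ord_res.proportion_explained[:5]],
            "permanova": perm.to_dict(),
            "betadisper": disp.to_dict(),
            "nmds_stress": nm.stress,
        }
        (out / "beta_summary.json").write_text(
            json.dumps(beta_summary, indent=2))
        return beta_summary
    stage("beta")(_beta)

    # 6 — indicator taxa ----------------------------------------------------
    def _indval():
        res = indval_analysis(ranked, meta_sub.communities,
                              n_permutations=config.permutations,
                              seed=seeds[5],
                              indval_threshold=config.indval_threshold,
                              alpha=config.indval_alpha)
        res.to_csv(out / "indval.tsv", sep="\t", index=False,
                   float_format="%.10g")
        return res
    stage("indval")(_indval)

    # 7 — co-activity networks ----------------------------------------------
    def _networks():
        rel = to_relative_activity(filtered)
        ranked_rel = aggregate_by_rank(rel, taxonomy, config.rank)
        # phylum annotation: majority phylum per aggregated taxon
        tax_ranks = taxonomy.df
        phylum = (tax_ranks.groupby(tax_ranks[config.rank])["phylum"]
                  .agg(lambda s: s.mode().iat[0]).to_dict())
        nets = site_networks(ranked_rel, meta_sub.communities,
                             threshold=config.network_threshold,
                             alpha=config.network_alpha,
                             min_samples=config.network_min_samples,
                             phylum=phylum)
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        for site, net in nets.items():
            export_network(net, netdir / f"{site}_edges.tsv", "edgelist")
            export_network(top_n_subgraph(net, config.network_top_n),
                           netdir / f"{site}_top{config.network_top_n}.graphml",
                           "graphml")
            node_metrics(net).to_csv(netdir / f"{site}_node_metrics.tsv",
                                     sep="\t", index_label="node",
                                     float_format="%.10g")
        return nets
    nets = stage("networks")(_networks)

    # 8 — cross-site comparison ---------------------------------------------
    def _compare():
        tests, summary = compare_networks(nets)
        summary.to_csv(out / "network_summary.tsv", sep="\t",
                       float_format="%.10g")
        (out / "network_comparison.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in tests.items()}, indent=2))
        return summary
    stage("compare")(_compare)

    manifest["status"] = "ok"
    _write_manifest()
    return out
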