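"""End-to-end orchestration: simulate -> filter -> cluster -> diversity.

A single :class:`RunConfig` drives all stages; every run writes its
resolved configuration, a machine-readable report with per-stage counts
and the derived thresholds, and a manifest of artifacts. All outputs are
deterministic given the config (stage wall-clock times go to a separate
timings.json so data artifacts are byte-stable across reruns).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .blank_filter import BlankFilter
from .diversity import (
    beta_multisite,
    beta_pairwise,
    beta_resample,
    depth_residuals,
    exclusive_otus,
    faith_pd,
    richness,
    to_presence_absence,
)
from .errors import InputError, PreconditionError
from .obs_table import (
    ObservationTable,
    compute_stats,
    filter_by_identity,
    read_table,
    read_taxonomy,
    write_sample_meta,
    write_table,
)
from .otu_cluster import (
    aggregate_to_otus,
    choose_representatives,
    cluster_complete_linkage,
    collapse_tree,
    pairwise_distances,
)
from .synthetic_data import SimParams, simulate_dataset, score_filter

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    Defaults reproduce the reference settings: 84% taxonomy identity, 3%
    complete-linkage OTU cutoff, inclusive filter-1 comparison, 20-site /
    1000-iteration beta resampling.
    """

    out_dir: str = "RESULTS"
    seed: int = 42
    # stage toggles
    do_simulate: bool = True
    do_filter: bool = True
    do_cluster: bool = True
    do_diversity: bool = True
    # inputs when not simulating
    table_path: str | None = None
    samples_path: str | None = None
    taxonomy_path: str | None = None
    alignment_path: str | None = None
    tree_path: str | None = None
    # simulator
    sim: dict = field(default_factory=dict)
    # filter
    min_identity: float = 84.0
    min_blank_errors: int = 5
    filter1_strict: bool = False
    recompute_stats_after_filter1: bool = False
    # clustering
    cutoff: float = 0.03
    distance_model: str = "p"
    # diversity
    resample_sites: int = 20
    resample_iters: int = 1000
    resample_statistic: str = "multisite"
    include_root_pd: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    Artifacts are written under ``config.out_dir``; a failure in any stage
    raises after writing the partial report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    timings: dict[str, float] = {}
    manifest: list[str] = []

    def _write_report() -> None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "timings.json").write_text(json.dumps(timings, indent=2))
        (out / "manifest.json").write_text(json.dumps(sorted(set(manifest)), indent=2))

    table = truth = None
    alignment = None
    newick = None

    try:
        # ---------------- simulate ----------------
        if config.do_simulate:
            t0 = time.perf_counter()
            params = SimParams(**{**config.sim, "seed": config.seed})
            ds = simulate_dataset(params)
            table, truth = ds.table, ds.truth
            alignment, newick = ds.alignment, ds.newick
            write_table(table, out / "obs.tsv")
            write_sample_meta(table, out / "meta.tsv")
            truth.labels.to_csv(out / "truth.tsv", sep="\t", index=False)
            with open(out / "asvs.aln.fasta", "w") as fh:
                for name, seq in alignment:
                    fh.write(f">{name}\n{seq}\n")
            (out / "asvs.nwk").write_text(newick + "\n")
            params.to_json(out / "params.json")
            manifest += ["obs.tsv", "meta.tsv", "truth.tsv", "asvs.aln.fasta",
                         "asvs.nwk", "params.json"]
            report["stages"]["simulate"] = {
                "n_obs": table.n_obs,
                "n_reads": table.total_reads,
                "n_asvs": len(table.asv_ids),
                "n_samples": len(table.samples),
                "n_blanks": len(table.blank_sample_ids),
            }
            timings["simulate"] = time.perf_counter() - t0
        else:
            if config.table_path is None:
                raise InputError("table_path required when simulation is disabled")
            table = read_table(config.table_path, samples=config.samples_path)
            if config.alignment_path:
                alignment = config.alignment_path
            if config.tree_path:
                newick = Path(config.tree_path).read_text().strip()

        # ---------------- filter ----------------
        if config.do_filter:
            t0 = time.perf_counter()
            work = table
            if config.taxonomy_path:
                tax = read_taxonomy(config.taxonomy_path)
                work = filter_by_identity(work, tax, config.min_identity)
            bf = BlankFilter(
                min_blank_errors=config.min_blank_errors,
                filter1_strict=config.filter1_strict,
                recompute_stats_after_filter1=config.recompute_stats_after_filter1,
            )
            filtered = bf.fit_transform(work)
            thresholds = bf.thresholds_
            logger.info(
                "derived thresholds: t_reads=%d t_readprop=%.9g t_norm=%.9g",
                thresholds.t_reads, thresholds.t_readprop, thresholds.t_norm,
            )
            write_table(filtered, out / "filtered.tsv")
            thresholds.to_json(out / "thresholds.json")
            manifest += ["filtered.tsv", "thresholds.json"]
            stage = {
                "steps": bf.report_,
                "thresholds": {
                    "t_reads": thresholds.t_reads,
                    "t_readprop": thresholds.t_readprop,
                    "t_norm": thresholds.t_norm,
                },
                "n_obs": filtered.n_obs,
                "n_reads": filtered.total_reads,
                "n_asvs": len(filtered.asv_ids),
            }
            if truth is not None:
                stage["score"] = score_filter(truth, filtered).as_dict()
            report["stages"]["filter"] = stage
            timings["filter"] = time.perf_counter() - t0
            table = filtered

        # ---------------- cluster ----------------
        cm = None
        otu_tree = None
        if config.do_cluster:
            t0 = time.perf_counter()
            if alignment is None:
                raise PreconditionError(
                    "cluster stage needs an alignment (simulate stage or alignment_path)"
                )
            aln = alignment
            if not isinstance(aln, (str, Path)):
                present = set(table.asv_ids)
                aln = [(a, s) for a, s in alignment if a in present]
            dm = pairwise_distances(aln, model=config.distance_model)
            missing = sorted(set(table.asv_ids) - set(dm.ids))
            if missing:
                raise InputError(f"filtered ASVs missing from alignment: {missing}")
            assignment = cluster_complete_linkage(dm, config.cutoff)
            assignment = choose_representatives(assignment, table)
            cm = aggregate_to_otus(table, assignment)
            assignment.to_frame().to_csv(out / "otu_map.tsv", sep="\t", index=False)
            cm.to_csv(out / "otu_matrix.tsv", sep="\t")
            manifest += ["otu_map.tsv", "otu_matrix.tsv"]
            if newick is not None and len(assignment.representative) >= 2:
                otu_tree = collapse_tree(newick, assignment)
                with open(out / "otus.nwk", "w") as fh:
                    otu_tree.write(fh)
                manifest.append("otus.nwk")
            report["stages"]["cluster"] = {
                "n_asvs": len(assignment.mapping),
                "n_otus": len(assignment.otu_ids),
                "n_reads": int(cm.to_numpy().sum()),
            }
            timings["cluster"] = time.perf_counter() - t0

        # ---------------- diversity ----------------
        if config.do_diversity:
            t0 = time.perf_counter()
            if cm is None:
                raise PreconditionError("diversity stage needs the cluster stage")
            nonempty = cm.loc[cm.sum(axis=1) > 0]
            pa = to_presence_absence(nonempty)
            alpha = pd.DataFrame({
                "richness": richness(nonempty),
                "depth": nonempty.sum(axis=1).astype(int),
            })
            if otu_tree is not None:
                alpha["pd"] = faith_pd(nonempty, otu_tree, config.include_root_pd)
            alpha["residual_richness"] = depth_residuals(alpha["richness"], alpha["depth"])
            if "pd" in alpha:
                alpha["residual_pd"] = depth_residuals(alpha["pd"], alpha["depth"])
            alpha.index.name = "sample_id"
            alpha.to_csv(out / "alpha.tsv", sep="\t")
            manifest.append("alpha.tsv")

            groups = table.samples.set_index("sample_id")["group"].reindex(pa.index)
            pairs = [
                {"sample_i": i, "sample_j": j, **beta_pairwise(pa, i, j).as_dict()}
                for i, j in itertools.combinations(pa.index, 2)
            ]
            pd.DataFrame(pairs).to_csv(out / "beta_pairwise.tsv", sep="\t", index=False)
            manifest.append("beta_pairwise.tsv")

            multisite = {}
            for g in sorted(groups.dropna().unique()):
                sub = pa.loc[groups == g]
                if len(sub) >= 2:
                    multisite[g] = beta_multisite(sub).as_dict()
            (out / "beta_multisite.json").write_text(
                json.dumps(multisite, indent=2, sort_keys=True))
            manifest.append("beta_multisite.json")

            dists = beta_resample(
                pa, groups, n_sites=config.resample_sites,
                n_iter=config.resample_iters, seed=config.seed,
                statistic=config.resample_statistic,
            )
            draws = pd.concat([d.to_frame() for d in dists.values()],
                              ignore_index=True)
            draws.to_csv(out / "beta_resample.tsv", sep="\t", index=False)
            manifest.append("beta_resample.tsv")

            venn = exclusive_otus(pa, groups)
            (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
            manifest.append("venn.json")

            report["stages"]["diversity"] = {
                "n_samples": int(len(nonempty)),
                "pooled_richness": int((pa.any(axis=0)).sum()),
                "multisite": multisite,
                "resample_means": {g: d.mean() for g, d in dists.items()},
                "venn_exclusive": venn["exclusive"],
            }
            timings["diversity"] = time.perf_counter() - t0
    finally:
        _write_report()

    return report
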