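"""End-to-end analysis driver.

Runs the full two-modality analysis on a synthetic or user-provided cohort:
group-average functional matrix and representative Louvain partition,
edge-wise group statistics with module/sign classification, per-subject
metric curves over the sparsity grids with rewired-null normalization,
nodal and global group tests with FDR control, structural fiber-mask edge
tests, structure-function correlations, and the multimodal PCA with
covariate-adjusted associations. Every run writes a machine-readable
manifest (parameters, seeds, versions) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import child_int_seed
from .cohort import Cohort, CohortConfig, generate_cohort, GROUP_A, GROUP_B
from .community import (
    Partition,
    louvain_partition,
    nmi,
    positive_part,
    representative_partition,
)
from .connectivity import apply_fiber_mask
from .exceptions import DataError, SynconnError
from .groupstats import (
    classify_edge_difference,
    edgewise_group_test,
    global_metric_test,
    nodal_group_test,
    stratify_differences,
    structure_function_correlation,
)
from .metrics import (
    default_functional_grid,
    default_structural_grid,
    metric_curve,
    nodal_metrics,
)
from .pca import MetricPanel, associate_components, fit_pca
from . import io as sio

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run."""

    output_dir: str = "synconn_out"
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # file-based input (used when simulate is False)
    node_table: str | None = None
    functional_dir: str | None = None  # one z-matrix TSV per subject
    fiber_dir: str | None = None  # fiber-count matrix TSV per subject
    phenotype_table: str | None = None
    # analysis parameters
    functional_grid: tuple = tuple(default_functional_grid())
    structural_grid: tuple = tuple(default_structural_grid())
    n_nulls: int = 100
    n_louvain: int = 100
    n_partition_runs: int = 100
    n_swaps_per_edge: float = 10.0
    alpha: float = 0.05
    fdr_q: float = 0.05
    fiber_mask_threshold: float = 5.0
    pca_components: int = 4
    with_structural: bool = True
    seed: int = 0

    def validate(self) -> None:
        for grid in (self.functional_grid, self.structural_grid):
            g = np.asarray(grid, dtype=float)
            if np.any((g <= 0) | (g > 1)):
                raise DataError("sparsity grids must lie in (0, 1]")
        if self.fiber_mask_threshold <= 0:
            raise DataError("fiber mask threshold must be positive")
        if not (0 < self.alpha < 1 and 0 < self.fdr_q < 1):
            raise DataError("alpha and fdr_q must lie in (0, 1)")


class _Stage:
    """Context manager that reattaches the stage name to any error."""

    def __init__(self, name: str, log: list):
        self.name = name
        self.log = log

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise SynconnError(f"pipeline stage '{self.name}' failed: {exc}") from exc
        self.log.append(self.name)
        return False


def _load_cohort_from_files(config: PipelineConfig) -> Cohort:
    if not (config.node_table and config.functional_dir and config.phenotype_table):
        raise DataError("file-based runs need node_table, functional_dir and phenotype_table")
    node_set = sio.read_node_table(config.node_table)
    func_paths = sorted(Path(config.functional_dir).glob("*.tsv"))
    if not func_paths:
        raise DataError(f"no matrices in {config.functional_dir}")
    from .connectivity import FunctionalConnectome, StructuralConnectome

    functional = [
        FunctionalConnectome(weights=sio.read_matrix(p), subject_id=p.stem) for p in func_paths
    ]
    phenotypes = sio.read_phenotypes(config.phenotype_table)
    if len(phenotypes) != len(functional):
        raise DataError("phenotype rows must match number of functional matrices")
    groups = (phenotypes["group"] == GROUP_B).to_numpy().astype(int)
    structural = []
    if config.fiber_dir:
        for p in sorted(Path(config.fiber_dir).glob("*.tsv")):
            fc = np.round(sio.read_matrix(p)).astype(np.int64)
            nanm = np.full(fc.shape, np.nan)
            structural.append(
                StructuralConnectome(fiber_count=fc, fa_mean=nanm, md_mean=nanm, subject_id=p.stem)
            )
    return Cohort(
        config=config.cohort,
        node_set=node_set,
        groups=groups,
        subject_ids=[f.subject_id for f in functional],
        timeseries=[],
        functional=functional,
        structural=structural,
        phenotypes=phenotypes,
    )


def _metric_tables(cohort, weights_list, grid, config, stream):
    """Per-subject metric curves; returns (per-level frames, summary, integrated)."""
    summaries, integrated, levels = [], [], []
    for s, w in enumerate(weights_list):
        curve = metric_curve(
            w,
            grid=np.asarray(grid, dtype=float),
            n_nulls=config.n_nulls,
            n_louvain=config.n_louvain,
            seed=child_int_seed(config.seed, f"{stream}-curve-{s}"),
            n_swaps_per_edge=config.n_swaps_per_edge,
        )
        df = curve.to_dataframe()
        df.insert(0, "subject", cohort.subject_ids[s])
        levels.append(df.reset_index())
        summaries.append(curve.summary())
        integrated.append(curve.summary_integrated())
    idx = pd.Index(cohort.subject_ids, name="subject")
    return (
        pd.concat(levels, ignore_index=True),
        pd.DataFrame(summaries, index=idx),
        pd.DataFrame(integrated, index=idx),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a results dict and writes the bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    results: dict = {}
    is_a = None  # group masks, set in the cohort stage

    with _Stage("cohort", log):
        if config.simulate:
            cohort = generate_cohort(config.cohort, with_structural=config.with_structural)
        else:
            cohort = _load_cohort_from_files(config)
        is_a = cohort.groups == 0
        sio.write_node_table(cohort.node_set, out / "nodes.tsv")
        sio.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
        results["n_subjects"] = len(cohort.subject_ids)

    with _Stage("representative-partition", log):
        avg = cohort.average_functional()
        sio.write_matrix(avg, out / "average_functional.tsv")
        partition, diag = representative_partition(
            positive_part(avg),
            n_runs=config.n_partition_runs,
            seed=child_int_seed(config.seed, "rep-partition"),
        )
        sio.write_partition(partition, out / "functional_partition.tsv")
        subj_nmi = []
        for s, w in enumerate(cohort.functional_weights()):
            own = louvain_partition(
                positive_part(w), seed=child_int_seed(config.seed, f"subj-louvain-{s}")
            )
            subj_nmi.append(nmi(own.partition, partition))
        diag["subject_vs_group_nmi_mean"] = float(np.mean(subj_nmi))
        (out / "partition_diagnostics.json").write_text(json.dumps(diag, indent=2, sort_keys=True))
        results["partition"] = partition
        results["partition_diagnostics"] = diag

    with _Stage("edgewise-functional", log):
        wa = [w for w, a in zip(cohort.functional_weights(), is_a) if a]
        wb = [w for w, a in zip(cohort.functional_weights(), is_a) if not a]
        edge = edgewise_group_test(wa, wb, alpha=config.alpha, group_names=(GROUP_A, GROUP_B))
        edge = classify_edge_difference(edge, partition, cohort.node_set.coordinates)
        edge.to_csv(out / "edge_tests_functional.tsv", sep="\t", index=False)
        strat = {
            "strength": stratify_differences(edge, by="strength", group_names=(GROUP_A, GROUP_B)),
            "distance": stratify_differences(edge, by="distance", group_names=(GROUP_A, GROUP_B)),
        }
        (out / "edge_stratification.json").write_text(json.dumps(strat, indent=2, sort_keys=True))
        results["edge_tests"] = edge
        results["stratification"] = strat

    with _Stage("functional-metrics", log):
        lv, summ, integ = _metric_tables(
            cohort, cohort.functional_weights(), config.functional_grid, config, "func"
        )
        lv.to_csv(out / "functional_metric_levels.tsv", sep="\t", index=False)
        summ.to_csv(out / "functional_metric_summary.tsv", sep="\t")
        integ.to_csv(out / "functional_metric_integrated.tsv", sep="\t")
        gtest = global_metric_test(summ[is_a], summ[~is_a], q=config.fdr_q)
        gtest.to_csv(out / "functional_global_tests.tsv", sep="\t", index=False)
        results["functional_summary"] = summ
        results["functional_integrated"] = integ
        results["functional_global_tests"] = gtest

    with _Stage("nodal-metrics", log):
        nod = [
            nodal_metrics(w, partition, grid=np.asarray(config.functional_grid))
            for w in cohort.functional_weights()
        ]
        nodal_results = {}
        for key in ("clustering", "betweenness", "participation"):
            tab = np.stack([getattr(n, key) for n in nod])
            res = nodal_group_test(tab[is_a], tab[~is_a], q=config.fdr_q, alpha=config.alpha)
            res.to_csv(out / f"nodal_{key}_tests.tsv", sep="\t", index=False)
            nodal_results[key] = res
        results["nodal_tests"] = nodal_results

    have_struct = config.with_structural and len(cohort.structural) > 0
    if have_struct:
        with _Stage("structural-edges", log):
            mask = apply_fiber_mask(cohort.structural, threshold=config.fiber_mask_threshold)
            sio.write_edge_list(mask, out / "fiber_mask_edges.tsv")
            ii, jj = np.nonzero(np.triu(mask, k=1))
            struct_edge = {}
            for attr in ("fiber_count", "fa_mean", "md_mean"):
                mats_a = [getattr(c, attr) for c, a in zip(cohort.structural, is_a) if a]
                mats_b = [getattr(c, attr) for c, a in zip(cohort.structural, is_a) if not a]
                if attr != "fiber_count":
                    # undefined (NaN) edges outside each subject's own nonzero
                    # set: treat missing FA/MD as 0 contribution is wrong, so
                    # restrict to masked edges where all subjects are defined
                    defined = np.all(
                        [~np.isnan(getattr(c, attr)[ii, jj]) for c in cohort.structural], axis=0
                    )
                    e = (ii[defined], jj[defined])
                else:
                    e = (ii, jj)
                if e[0].size < 1:
                    continue
                df = edgewise_group_test(
                    mats_a, mats_b, edges=e, alpha=config.alpha, group_names=(GROUP_A, GROUP_B)
                )
                df = classify_edge_difference(df, partition, cohort.node_set.coordinates)
                df.to_csv(out / f"edge_tests_{attr}.tsv", sep="\t", index=False)
                struct_edge[attr] = df
            results["structural_edge_tests"] = struct_edge
            results["fiber_mask"] = mask

        with _Stage("structural-metrics", log):
            counts = [c.fiber_count.astype(float) for c in cohort.structural]
            lv, summ_s, integ_s = _metric_tables(
                cohort, counts, config.structural_grid, config, "struct"
            )
            lv.to_csv(out / "structural_metric_levels.tsv", sep="\t", index=False)
            summ_s.to_csv(out / "structural_metric_summary.tsv", sep="\t")
            integ_s.to_csv(out / "structural_metric_integrated.tsv", sep="\t")
            gtest_s = global_metric_test(summ_s[is_a], summ_s[~is_a], q=config.fdr_q)
            gtest_s.to_csv(out / "structural_global_tests.tsv", sep="\t", index=False)
            results["structural_summary"] = summ_s
            results["structural_global_tests"] = gtest_s

        with _Stage("structure-function", log):
            sf = {}
            for subset in ("all", "within", "between"):
                sf[subset] = structure_function_correlation(
                    cohort.functional,
                    cohort.structural,
                    results["fiber_mask"],
                    groups=cohort.groups,
                    subset=subset,
                    partition=partition,
                )
            pd.concat(
                [d["subjects"].assign(subset=k) for k, d in sf.items()], ignore_index=True
            ).to_csv(out / "structure_function.tsv", sep="\t", index=False)
            results["structure_function"] = sf

        with _Stage("pca", log):
            panel_df = summ.add_prefix("functional_").join(summ_s.add_prefix("structural_"))
            panel = MetricPanel(panel_df)
            pca = fit_pca(panel)
            pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
            pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            assoc = {
                which: associate_components(
                    pca,
                    cohort.phenotypes,
                    which,
                    n_components=config.pca_components,
                    fdr_q=config.fdr_q,
                    asd_label=GROUP_B,
                )
                for which in ("diagnosis", "age", "severity")
            }
            for which, df in assoc.items():
                df.to_csv(out / f"pca_association_{which}.tsv", sep="\t", index=False)
            results["pca"] = pca
            results["pca_associations"] = assoc

    with _Stage("manifest", log):
        cfg = asdict(config)
        cfg["functional_grid"] = [float(s) for s in config.functional_grid]
        cfg["structural_grid"] = [float(s) for s in config.structural_grid]
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "config": cfg,
            "stages_completed": log[:-1] + ["manifest"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    results["manifest_path"] = str(out / "manifest.json")
    results["stages"] = log
    return results
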