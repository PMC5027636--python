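"""End-to-end pipeline: simulate/load → normalize → calibrate → analyze.

``run_pipeline`` drives every stage in the order the analysis requires —
background estimation and ΔCt normalization, cell culling, paired
correlations with permutation tests, the in-silico gating screen, seed-network
growth, PCA + random-forest classification, and quadrant-trajectory
clustering — writing one CSV per stage plus a YAML manifest that records the
configuration, seeds, and input digests needed to re-run it.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, correlation, differential, multivariate, network, preprocess, trajectory
from .core import Analyte, CtTable, DeltaCtTable, StudyConfig, write_table

logger = logging.getLogger("peasta")

__all__ = ["PipelineManifest", "run_pipeline"]


@dataclass
class PipelineManifest:
    config: dict
    seeds: dict
    stage_outputs: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    failed_stage: str | None = None
    version: str = "0.1.0"

    def write(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def run_pipeline(ct: CtTable, config: StudyConfig, out_dir: str | Path,
                 seed_targets: set[str] | None = None,
                 n_permutations: int | None = None) -> PipelineManifest:
    """Run every analysis stage on a raw Ct table and write results to ``out_dir``.

    ``n_permutations`` overrides the config's permutation count (useful for
    smoke runs); ``seed_targets`` names the seed set for network growth
    (defaults to the first paired gene's two assays).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_perm = n_permutations or config.n_permutations
    manifest = PipelineManifest(
        config=asdict(config),
        seeds={"rng_seed": config.rng_seed, "n_permutations": n_perm},
        input_digests={"ct": _digest(ct.ct)},
    )
    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        bg = preprocess.estimate_protein_background(ct, config.ct_ceiling)
        write_table(bg.stats, out / "background.csv")
        dct = preprocess.combined_delta_ct(ct, bg, config.ct_ceiling)
        rna_ids = [t.target_id for t in dct.targets_of(Analyte.RNA)]
        dct, qc = preprocess.cull_cells(dct, rna_ids, config.cull_min_detected_rna)
        write_table(qc.per_cell, out / "qc_report.csv")
        write_table(dct.dct, out / "dct.csv")
        logger.info("preprocess: %d cells retained (%.2fs)",
                    len(dct.wells), time.perf_counter() - t0)
        manifest.stage_outputs[stage] = ["background.csv", "qc_report.csv", "dct.csv"]

        stage = "calibrate"
        thresholds = calibration.thresholds_for(bg, dct.target_ids, config.detection_alpha)
        thr_df = pd.DataFrame({tid: [t.threshold_dct, t.alpha]
                               for tid, t in thresholds.items()},
                              index=["threshold_dct", "alpha"]).T
        write_table(thr_df, out / "thresholds.csv")
        manifest.stage_outputs[stage] = ["thresholds.csv"]

        stage = "correlate"
        t0 = time.perf_counter()
        corr = correlation.paired_correlations(dct)
        write_table(corr.set_index(["gene", "time_point_hr"]), out / "correlations.csv")
        tps = dct.time_points()
        delta_records = []
        for gene in dct.paired_genes():
            for a, b in zip(tps[:-1], tps[1:]):
                res = correlation.delta_correlation_test(
                    dct, gene, a, b, n_permutations=n_perm, seed=config.rng_seed)
                delta_records.append({
                    "gene": gene, "time_a": a, "time_b": b, "delta_rho": res.delta_rho,
                    "null_mean": res.null_mean, "null_sd": res.null_sd,
                    "p_value": res.p_value})
        write_table(pd.DataFrame(delta_records).set_index("gene"), out / "delta_tests.csv")
        logger.info("correlate: %d genes (%.2fs)", corr["gene"].nunique(),
                    time.perf_counter() - t0)
        manifest.stage_outputs[stage] = ["correlations.csv", "delta_tests.csv"]

        stage = "gate"
        t0 = time.perf_counter()
        gates = differential.in_silico_gate_all(dct, thresholds)
        write_table(differential.gate_results_frame(gates).set_index("gate_target"),
                    out / "gate_tests.csv")
        logger.info("gate: %d tests (%.2fs)", len(gates), time.perf_counter() - t0)
        manifest.stage_outputs[stage] = ["gate_tests.csv"]

        stage = "network"
        if seed_targets is None:
            gene0 = dct.paired_genes()[0]
            seed_targets = {t.target_id for t in dct.targets if t.gene == gene0}
        all_edges = []
        for tp in tps:
            net = network.grow_seed_network(dct, seed_targets, tp,
                                            config.edge_rho_threshold)
            e = net.edges
            e["time_point_hr"] = tp
            if not e.empty:
                all_edges.append(e)
        if all_edges:
            edges = pd.concat(all_edges, ignore_index=True)
            write_table(edges.set_index("target"), out / "edges.csv")
        manifest.stage_outputs[stage] = ["edges.csv"]

        stage = "classify"
        t0 = time.perf_counter()
        labels = pd.Series({w.well_id: w.time_point_hr for w in dct.wells})
        auc_rows = []
        for subset_name, analyte in (("protein", Analyte.PROTEIN), ("rna", Analyte.RNA)):
            ids = [t.target_id for t in dct.targets_of(analyte)]
            pca = multivariate.pca_standardized(dct, ids)
            ev = multivariate.rf_timepoint_classifier(
                pca, labels, config.train_fraction, seed=config.rng_seed)
            for cls, a in ev.auc_by_class.items():
                auc_rows.append({"subset": subset_name, "time_point_hr": cls, "auc": a})
        write_table(pd.DataFrame(auc_rows).set_index("subset"), out / "auc.csv")
        logger.info("classify (%.2fs)", time.perf_counter() - t0)
        manifest.stage_outputs[stage] = ["auc.csv"]

        stage = "trajectory"
        profiles = trajectory.quadrant_profiles(dct, thresholds=thresholds)
        clus = trajectory.cluster_trajectories(profiles, config.trajectory_cut)
        quad_rows = []
        for p in profiles:
            for tp, row in p.proportions.iterrows():
                rec = {"gene": p.gene, "time_point_hr": tp}
                rec.update(row.to_dict())
                quad_rows.append(rec)
        write_table(pd.DataFrame(quad_rows).set_index("gene"), out / "quadrants.csv")
        write_table(clus.labels.to_frame(), out / "trajectory_clusters.csv")
        manifest.stage_outputs[stage] = ["quadrants.csv", "trajectory_clusters.csv"]
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.yaml")
        raise
    manifest.write(out / "manifest.yaml")
    return manifest
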