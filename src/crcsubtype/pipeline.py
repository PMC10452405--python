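"""End-to-end pipeline: io -> scoring -> NTP -> model systems -> dose-response.

A YAML/dict config selects stages and parameters; each enabled stage
writes its TSV outputs and contributes to a single JSON summary. One seed
in the config fans out to per-stage seeds by fixed offsets so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import dose_response as dr
from . import expression_io as eio
from . import icms_scoring, model_system_analysis as msa, ntp_classifier, synthetic_data as syn

logger = logging.getLogger("crcsubtype")

STAGE_SEED_OFFSETS = {"scoring": 11, "ntp": 23, "model_systems": 37, "dose_response": 53}


@dataclass
class RunConfig:
    """Paths, stage toggles and parameters for one pipeline run.

    When a stage's input paths are omitted the stage runs on synthetic
    data generated from the config seed — the self-contained demo mode.
    """

    out_dir: str = "crcsubtype_out"
    seed: int = 0
    force: bool = False

    run_scoring: bool = True
    run_ntp: bool = True
    run_model_systems: bool = True
    run_dose_response: bool = True

    matrix_path: str | None = None
    gmt_path: str | None = None
    metadata_path: str | None = None
    plate_path: str | None = None
    probe_map_path: str | None = None

    # stage parameters
    delta: float = 0.25            # pattern-classification threshold, log2
    fdr_threshold: float = 0.01
    lfc_threshold: float = 1.5
    lfc_rule: str = "any"
    alpha: float = 0.05
    ntp_metric: str = "cosine"
    cluster_distance: str = "pearson"
    cluster_linkage: str = "average"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for stage, path in [
            ("scoring", self.matrix_path),
            ("model_systems", self.metadata_path),
            ("dose_response", self.plate_path),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{stage}: input path {path} does not exist")


def _write_tsv(df: pd.DataFrame, path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True/--force to overwrite")
    df.to_csv(path, sep="\t")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages and write TSVs plus summary.json.

    Returns the summary dict. A stage failure raises with the stage name;
    outputs written before the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "stages": []}

    matrix = sets = None
    scores = None
    stage = "io"
    try:
        if config.run_scoring or config.run_ntp:
            if config.matrix_path and config.gmt_path:
                matrix = eio.read_expression(config.matrix_path, feature_level="probe")
                if config.probe_map_path:
                    mapping = pd.read_csv(config.probe_map_path, sep="\t")
                    matrix = eio.collapse_probes(matrix, mapping)
                else:
                    matrix = eio.ExpressionMatrix(matrix.data, feature_level="gene")
                sets = eio.read_gmt(config.gmt_path)
            else:
                spec = syn.CohortSpec(seed=config.seed + STAGE_SEED_OFFSETS["scoring"])
                matrix, labels, sets = syn.simulate_cohort(spec)
                summary["synthetic_cohort"] = {
                    "n_samples": int(matrix.n_samples), "n_genes": int(matrix.n_features),
                    "delta": spec.delta, "sigma": spec.sigma,
                }

        if config.run_scoring:
            stage = "scoring"
            scores = icms_scoring.score_cohort(matrix, sets)
            _write_tsv(scores, out / "icms_scores.tsv", config.force)
            calls = scores["consensus"].value_counts().to_dict()
            summary["scoring"] = {"calls": {k: int(v) for k, v in calls.items()}}
            summary["stages"].append("scoring")

        if config.run_ntp:
            stage = "ntp"
            ntp = ntp_classifier.ntp_cohort(
                matrix, sets, metric=config.ntp_metric,
                score_consensus=scores["consensus"] if scores is not None else None,
            )
            _write_tsv(ntp, out / "ntp_calls.tsv", config.force)
            summary["ntp"] = {
                "calls": {k: int(v) for k, v in ntp["call"].value_counts().items()},
            }
            if "score_agreement" in ntp.attrs:
                summary["ntp"]["score_agreement"] = ntp.attrs["score_agreement"]
            summary["stages"].append("ntp")

        if config.run_model_systems:
            stage = "model_systems"
            if config.matrix_path and config.metadata_path:
                ms_matrix = eio.read_expression(config.matrix_path, feature_level="gene")
                meta = eio.read_metadata(config.metadata_path)
            else:
                ms_spec = syn.ModelSystemSpec(
                    seed=config.seed + STAGE_SEED_OFFSETS["model_systems"]
                )
                ms_matrix, meta, _ = syn.simulate_model_systems(ms_spec)
            fspec = msa.FilterSpec(
                fdr_threshold=config.fdr_threshold,
                lfc_threshold=config.lfc_threshold,
                baseline="monolayer2D",
                contrasts=["spheroid", "xenograft"],
                lfc_rule=config.lfc_rule,
            )
            filt = msa.anova_filter(ms_matrix, meta, fspec)
            _write_tsv(filt.table, out / "gene_filter.tsv", config.force)
            patterns = msa.pattern_classify(
                ms_matrix, meta, delta=config.delta, genes=filt.passing or None
            )
            _write_tsv(patterns, out / "patterns.tsv", config.force)
            sim = msa.model_similarity(ms_matrix, meta, genes=filt.passing or list(ms_matrix.feature_ids))
            _write_tsv(sim, out / "model_similarity.tsv", config.force)
            clust = msa.hierarchical_cluster(
                ms_matrix, genes=filt.passing or None,
                distance=config.cluster_distance, linkage_method=config.cluster_linkage,
            )
            newick_path = out / "sample_dendrogram.nwk"
            if newick_path.exists() and not config.force:
                raise FileExistsError(f"{newick_path} exists")
            newick_path.write_text(clust.newick + "\n")
            summary["model_systems"] = {
                "n_passing": len(filt.passing),
                "pattern_counts": {
                    k: int(v) for k, v in patterns["category"].value_counts().items()
                },
                "characteristic_fraction": patterns.attrs["characteristic_fraction"],
                "spheroid_closer_fraction": float(
                    (sim["closer_to_xenograft"] == "spheroid").mean()
                ),
            }
            summary["stages"].append("model_systems")

        if config.run_dose_response:
            stage = "dose_response"
            if config.plate_path:
                plate_table = pd.read_csv(config.plate_path)
                readout = dr.PlateReadout(plate_table)
            else:
                pspec = syn.PlateSpec(seed=config.seed + STAGE_SEED_OFFSETS["dose_response"])
                readout = syn.simulate_plate(pspec)
            rows = []
            models = sorted(
                set(readout.table.loc[readout.table["condition"] != "titration", "model_id"])
            )
            for model_id in models:
                fit2d = dr.fit_plate(readout, model_id, "2D")
                fit3d = dr.fit_plate(readout, model_id, "spheroid")
                comp = dr.compare_ic50(fit2d, fit3d, model_id=model_id, alpha=config.alpha)
                rows.append({
                    "model_id": model_id,
                    "IC50_2D_uM": comp.ic50_2d, "SD_2D": fit2d.ic50_sd,
                    "IC50_3D_uM": comp.ic50_3d, "SD_3D": fit3d.ic50_sd,
                    "welch_t": comp.welch_t, "welch_df": comp.welch_df,
                    "p_value": comp.p_value, "significant_shift": comp.significant,
                })
            ic50_table = pd.DataFrame(rows).set_index("model_id")
            _write_tsv(ic50_table, out / "ic50_comparison.tsv", config.force)
            summary["dose_response"] = {
                "n_models": len(rows),
                "n_significant_shifts": int(ic50_table["significant_shift"].sum()),
            }
            summary["stages"].append("dose_response")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary_path = out / "summary.json"
    if summary_path.exists() and not config.force:
        raise FileExistsError(f"{summary_path} exists")
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", ", ".join(summary["stages"]))
    return summary
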