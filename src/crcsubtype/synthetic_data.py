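"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the study's data types so the full analysis is
testable without the original microarrays or plate reads:

* ``simulate_cohort`` — log2 expression cohorts with rank-shifts planted
  on the four iCMS marker classes (Gaussian log2 noise, microarray-like).
* ``simulate_model_systems`` — per-cell-line 2D/spheroid/xenograft groups
  with planted per-gene trajectory categories (increasing, decreasing,
  plateau variants) and an optional resistance-marker gene.
* ``simulate_plate`` — 4PL luminescence dose-response plates with
  multiplicative CV noise plus a day-0 seeded-cells titration.

All generators are deterministic under a fixed seed. Default effect sizes
(shift 1.0 log2, noise SD 0.5 log2) give realistic, non-trivial but high
recoverability; the default pattern composition (64 increasing, 25
decreasing, 3 increase-plateau, 18 decrease-plateau within 152 genes)
mirrors the composition the pattern taxonomy is designed to report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import PlateReadout, four_pl
from .expression_io import (
    ExpressionMatrix,
    FeatureLevel,
    ICMSGeneSets,
    SampleMetadata,
)

# ---------------------------------------------------------------------------
# iCMS cohorts


@dataclass
class CohortSpec:
    """Planted iCMS2/iCMS3 cohort: sizes, effect, noise.

    Each sample of label iCMS2 gets +delta on the iCMS2_up genes and
    -delta on iCMS2_down; iCMS3 samples likewise on the 3U/3D classes.
    """

    n_genes: int = 500
    class_size: int = 30          # genes per marker class
    n_per_label: int = 50         # samples per planted label
    delta: float = 1.0            # log2 shift
    sigma: float = 0.5            # log2 noise SD
    baseline_mean: float = 7.0    # log2 intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.class_size < 1:
            raise ValueError("class_size must be >= 1")
        if self.n_genes < 4 * self.class_size:
            raise ValueError("n_genes too small for four disjoint classes")


def cohort_gene_sets(spec: CohortSpec) -> ICMSGeneSets:
    """The four disjoint marker classes used by :func:`simulate_cohort`."""
    k = spec.class_size
    names = [f"G{i:04d}" for i in range(spec.n_genes)]
    return ICMSGeneSets(
        icms2_up=frozenset(names[0:k]),
        icms2_down=frozenset(names[k:2 * k]),
        icms3_up=frozenset(names[2 * k:3 * k]),
        icms3_down=frozenset(names[3 * k:4 * k]),
    )


def simulate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.Series, ICMSGeneSets]:
    """Generate a gene-level cohort with planted iCMS labels.

    Returns ``(matrix, labels, gene_sets)``; labels is a per-sample Series
    of planted "iCMS2"/"iCMS3" ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    sets = cohort_gene_sets(spec)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    k = spec.class_size

    labels = ["iCMS2"] * spec.n_per_label + ["iCMS3"] * spec.n_per_label
    sample_ids = [f"S{i:03d}" for i in range(len(labels))]

    values = spec.baseline_mean + rng.normal(0.0, spec.sigma, (spec.n_genes, len(labels)))
    for j, label in enumerate(labels):
        if label == "iCMS2":
            values[0:k, j] += spec.delta          # 2U up
            values[k:2 * k, j] -= spec.delta      # 2D down
        else:
            values[2 * k:3 * k, j] += spec.delta  # 3U up
            values[3 * k:4 * k, j] -= spec.delta  # 3D down

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        feature_level=FeatureLevel.gene,
    )
    return matrix, pd.Series(labels, index=sample_ids, name="label"), sets


# ---------------------------------------------------------------------------
# Model-system cohorts


@dataclass
class ModelSystemSpec:
    """Planted 2D/spheroid/xenograft cohort with trajectory categories.

    ``category_counts`` orders (increasing, decreasing, increase_then_
    plateau, decrease_then_plateau); the rest of ``n_genes`` move by less
    than the noise floor ("none"). ``monotone_step`` is each step's log2
    size for the monotone categories; ``plateau_step`` is the single first
    step of plateau genes. Defaults make the fold change vs 2D of
    monotone genes 2 x 1.2 = 2.4 log2 and of plateau genes 1.8 log2, so a
    1.5-log2 filter keeps all planted categories while a 2-log2 filter
    keeps only the monotone ones.
    """

    n_genes: int = 152
    category_counts: tuple[int, int, int, int] = (64, 25, 3, 18)
    monotone_step: float = 1.2    # log2 per step for increasing/decreasing
    plateau_step: float = 1.8     # log2 first step for plateau categories
    n_cell_lines: int = 4
    replicates: int = 2           # samples per cell line per model system
    sigma: float = 0.2            # log2 noise SD
    baseline_mean: float = 7.0
    baseline_spread: float = 1.0  # per-gene baseline SD (cell-line specific)
    marker_log2fc: float | None = 8.64  # planted resistance marker; None disables
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.category_counts) > self.n_genes:
            raise ValueError("category counts exceed n_genes")
        if self.sigma < 0 or self.replicates < 1 or self.n_cell_lines < 1:
            raise ValueError("invalid spec")


_SYSTEMS = ("monolayer2D", "spheroid", "xenograft")


def _gene_steps(spec: ModelSystemSpec) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-gene planted (category, step1, step2)."""
    n_inc, n_dec, n_ip, n_dp = spec.category_counts
    cats = (
        ["increasing"] * n_inc + ["decreasing"] * n_dec
        + ["increase_then_plateau"] * n_ip + ["decrease_then_plateau"] * n_dp
        + ["none"] * (spec.n_genes - sum(spec.category_counts))
    )
    s = spec.monotone_step
    p = spec.plateau_step
    step1 = np.array(
        [s] * n_inc + [-s] * n_dec + [p] * n_ip + [-p] * n_dp
        + [0.0] * (spec.n_genes - sum(spec.category_counts))
    )
    step2 = np.array(
        [s] * n_inc + [-s] * n_dec + [0.0] * (n_ip + n_dp)
        + [0.0] * (spec.n_genes - sum(spec.category_counts))
    )
    return cats, step1, step2


def simulate_model_systems(
    spec: ModelSystemSpec,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.Series]:
    """Generate the three-model-system cohort with planted categories.

    Returns ``(matrix, metadata, categories)``. Cell lines alternate
    between "resistant" and "sensitive" groups; when ``marker_log2fc`` is
    set, a gene named ``MARKER`` is appended with that log2 shift in
    resistant samples (emulating a CAV1-like resistance marker).
    Spheroid profiles sit between 2D and xenograft by construction, so
    spheroids correlate more strongly with xenografts than 2D does.
    """
    rng = np.random.default_rng(spec.seed)
    cats, step1, step2 = _gene_steps(spec)
    genes = [f"MS{i:04d}" for i in range(spec.n_genes)]

    system_offsets = {
        "monolayer2D": np.zeros(spec.n_genes),
        "spheroid": step1,
        "xenograft": step1 + step2,
    }

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for li in range(spec.n_cell_lines):
        line = f"CL{li:02d}"
        group = "resistant" if li % 2 == 0 else "sensitive"
        line_baseline = spec.baseline_mean + rng.normal(
            0.0, spec.baseline_spread, spec.n_genes
        )
        for system in _SYSTEMS:
            for rep in range(spec.replicates):
                sid = f"{line}_{system}_r{rep}"
                noise = rng.normal(0.0, spec.sigma, spec.n_genes) if spec.sigma > 0 else 0.0
                columns[sid] = line_baseline + system_offsets[system] + noise
                meta_rows.append(
                    {"sample_id": sid, "cell_line": line, "model_system": system,
                     "group": group}
                )

    data = pd.DataFrame(columns, index=genes)
    categories = pd.Series(cats, index=genes, name="category")

    if spec.marker_log2fc is not None:
        meta_df = pd.DataFrame(meta_rows)
        marker = pd.Series(spec.baseline_mean, index=data.columns, dtype=float)
        resistant = meta_df.loc[meta_df["group"] == "resistant", "sample_id"]
        marker[resistant] += spec.marker_log2fc
        if spec.sigma > 0:
            marker += rng.normal(0.0, spec.sigma, len(marker))
        data.loc["MARKER"] = marker
        categories.loc["MARKER"] = "none"

    matrix = ExpressionMatrix(data, feature_level=FeatureLevel.gene)
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    return matrix, meta, categories


# ---------------------------------------------------------------------------
# Dose-response plates


@dataclass
class CurveParams:
    """True 4PL parameters for one model/condition."""

    top: float = 1.0
    bottom: float = 0.0
    hill: float = 1.0
    ic50: float = 0.2  # µM


@dataclass
class PlateSpec:
    """Serial-dilution plate layout with true curves per model/condition.

    ``curves`` maps (model_id, condition) -> CurveParams. The default dose
    series is a 3-fold serial dilution from 10 µM over 8 doses (10 ->
    0.0046 µM, bracketing sub-µM oxaliplatin IC50s so both plateaus are
    sampled) plus a dose-0 control, 8 replicate spheroids per dose — the
    plate geometry of a 96-well cytotoxicity assay.
    """

    curves: dict[tuple[str, str], CurveParams] = field(
        default_factory=lambda: {
            ("M1", "2D"): CurveParams(ic50=0.1),
            ("M1", "spheroid"): CurveParams(ic50=0.4),
        }
    )
    top_dose_uM: float = 10.0
    dilution_factor: float = 3.0
    n_doses: int = 8
    replicates: int = 8
    noise_cv: float = 0.05
    control_signal: float = 50_000.0  # counts at dose 0
    day: int = 7
    seeded_cells: dict[str, int] = field(default_factory=lambda: {"M1": 1500})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.top_dose_uM <= 0 or self.dilution_factor <= 1 or self.n_doses < 2:
            raise ValueError("invalid dose series")

    def dose_series(self) -> np.ndarray:
        return self.top_dose_uM / self.dilution_factor ** np.arange(self.n_doses)


def simulate_plate(spec: PlateSpec) -> PlateReadout:
    """Generate endpoint dose-response wells plus a day-0 growth titration.

    Signal = control_signal x 4PL response x (1 + N(0, CV^2)), clipped at
    zero. The day-0 titration seeds 150-20,000 cells and emits a linear
    signal for the growth-kinetics QC.
    """
    rng = np.random.default_rng(spec.seed)
    doses = spec.dose_series()
    records = []
    for (model_id, condition), curve in spec.curves.items():
        clean = four_pl(doses, curve.top, curve.bottom, curve.hill, np.log10(curve.ic50))
        for rep in range(spec.replicates):
            # dose-0 control well
            noise0 = rng.normal(0.0, spec.noise_cv) if spec.noise_cv > 0 else 0.0
            records.append({
                "model_id": model_id, "condition": condition, "dose_uM": 0.0,
                "replicate": rep, "day": spec.day,
                "signal": max(0.0, spec.control_signal * (1.0 + noise0)),
            })
            for dose, resp in zip(doses, clean):
                noise = rng.normal(0.0, spec.noise_cv) if spec.noise_cv > 0 else 0.0
                records.append({
                    "model_id": model_id, "condition": condition,
                    "dose_uM": float(dose), "replicate": rep, "day": spec.day,
                    "signal": max(0.0, spec.control_signal * resp * (1.0 + noise)),
                })

    # day-0 seeded-cells titration (growth-kinetics QC)
    titration = np.array([150, 300, 500, 1500, 3000, 5000, 10_000, 20_000], dtype=float)
    per_cell = spec.control_signal / 1500.0
    for model_id in {mid for mid, _ in spec.curves}:
        for rep, cells in enumerate(titration):
            noise = rng.normal(0.0, spec.noise_cv) if spec.noise_cv > 0 else 0.0
            records.append({
                "model_id": model_id, "condition": "titration", "dose_uM": 0.0,
                "replicate": rep, "day": 0,
                "signal": max(0.0, per_cell * cells * (1.0 + noise)),
            })

    table = pd.DataFrame.from_records(records)
    table["titration_cells"] = np.nan
    day0 = table["day"] == 0
    table.loc[day0, "titration_cells"] = np.tile(
        titration, day0.sum() // len(titration)
    )
    return PlateReadout(table=table, seeded_cells=dict(spec.seeded_cells))
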