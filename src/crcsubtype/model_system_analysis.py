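"""Model-system comparison: gene filtering, expression-pattern taxonomy,
correlation analysis, clustering, and two-group marker ranking.

The study compares three preclinical representations of each CRC cell line
— 2D monolayer, 3D spheroid, subcutaneous xenograft — plus patient tumor
and normal-tissue references. Genes are filtered by a per-feature one-way
F-test with Benjamini-Hochberg FDR control combined with log2 fold-change
cuts against a baseline; filtered genes are categorized by how their mean
expression moves along 2D -> spheroid -> xenograft; Pearson correlation
per cell line asks which in vitro system better resembles the xenograft.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix, ModelSystem, SampleMetadata

logger = logging.getLogger("crcsubtype")

PATTERN_CATEGORIES = (
    "increasing",
    "decreasing",
    "increase_then_plateau",
    "decrease_then_plateau",
    "none",
)


@dataclass
class FilterSpec:
    """Thresholds and contrast layout for the F-test/fold-change filter.

    ``baseline`` and ``contrasts`` name values of ``group_by`` (a metadata
    column, default model_system). ``lfc_rule`` decides whether one
    ("any") or every ("all") contrast must exceed the fold-change cut.
    """

    fdr_threshold: float
    lfc_threshold: float
    baseline: str
    contrasts: list[str]
    group_by: str = "model_system"
    lfc_rule: str = "any"

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.lfc_rule not in ("any", "all"):
            raise ValueError("lfc_rule must be 'any' or 'all'")


@dataclass
class GeneFilterResult:
    table: pd.DataFrame  # per-feature F, p, q, log2FC per contrast, passes
    passing: list[str]
    spec: FilterSpec


def anova_filter(
    m: ExpressionMatrix, meta: SampleMetadata, spec: FilterSpec
) -> GeneFilterResult:
    """One-way F-test across groups + BH FDR + fold-change cut per feature.

    log2FC(contrast) = mean(contrast) - mean(baseline) on the log2 data.
    A feature passes when q < fdr_threshold AND the contrast fold changes
    exceed |lfc_threshold| under the any/all rule. Constant features (zero
    variance everywhere) have an undefined F and are excluded with a
    warning.
    """
    meta.check_matches(m)
    groups = [spec.baseline] + list(spec.contrasts)
    sample_sets = {}
    for g in groups:
        ids = meta.table.loc[meta.table[spec.group_by] == g, "sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has {len(ids)} sample(s); need >= 2")
        sample_sets[g] = ids

    arrays = [m.data[ids].to_numpy(dtype=float) for ids in sample_sets.values()]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p_val = stats.f_oneway(*arrays, axis=1)

    constant = ~np.isfinite(f_stat)
    if constant.any():
        logger.warning("anova_filter: excluded %d constant feature(s)", int(constant.sum()))

    table = pd.DataFrame({"F": f_stat, "p_value": p_val}, index=m.data.index)
    ok = ~constant
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok] = multipletests(p_val[ok], method="fdr_bh")[1]
    table["q_value"] = q

    base_mean = m.data[sample_sets[spec.baseline]].mean(axis=1)
    lfc_cols = []
    for g in spec.contrasts:
        col = f"log2FC_{g}_vs_{spec.baseline}"
        table[col] = m.data[sample_sets[g]].mean(axis=1) - base_mean
        lfc_cols.append(col)

    exceeds = table[lfc_cols].abs().gt(spec.lfc_threshold)
    lfc_pass = exceeds.any(axis=1) if spec.lfc_rule == "any" else exceeds.all(axis=1)
    table["passes"] = ok & (table["q_value"] < spec.fdr_threshold) & lfc_pass
    passing = list(table.index[table["passes"]])
    logger.info("anova_filter: %d/%d features pass (FDR<%g, |log2FC|>%g, rule=%s)",
                len(passing), len(table), spec.fdr_threshold, spec.lfc_threshold,
                spec.lfc_rule)
    return GeneFilterResult(table=table, passing=passing, spec=spec)


def pattern_classify(
    m: ExpressionMatrix,
    meta: SampleMetadata,
    delta: float = 0.25,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Categorize each gene's mean trajectory along 2D -> spheroid -> xenograft.

    With step1 = mean(spheroid) - mean(2D) and step2 = mean(xenograft) -
    mean(spheroid), a gene is ``increasing`` if both steps exceed +delta,
    ``decreasing`` if both fall below -delta, ``increase_then_plateau`` /
    ``decrease_then_plateau`` if only step1 clears the threshold and step2
    stays within it, else ``none``. Genes in any category but ``none``
    carry the "characteristic" flag; the overall characteristic fraction
    is stored in ``result.attrs["characteristic_fraction"]``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    meta.check_matches(m)
    systems = (ModelSystem.monolayer2D, ModelSystem.spheroid, ModelSystem.xenograft)
    cols = {}
    for ms in systems:
        ids = meta.samples_for(ms)
        if not ids:
            raise ValueError(f"no samples for model system {ms.value}")
        cols[ms.value] = m.data[ids].mean(axis=1)
    means = pd.DataFrame(cols)
    if genes is not None:
        means = means.loc[genes]

    step1 = means["spheroid"] - means["monolayer2D"]
    step2 = means["xenograft"] - means["spheroid"]

    category = np.full(len(means), "none", dtype=object)
    category[(step1 > delta) & (step2 > delta)] = "increasing"
    category[(step1 < -delta) & (step2 < -delta)] = "decreasing"
    category[(step1 > delta) & (step2.abs() <= delta)] = "increase_then_plateau"
    category[(step1 < -delta) & (step2.abs() <= delta)] = "decrease_then_plateau"

    result = means.copy()
    result["step1"] = step1
    result["step2"] = step2
    result["category"] = category
    result["characteristic"] = result["category"] != "none"
    result.index.name = "gene"
    result.attrs["characteristic_fraction"] = float(result["characteristic"].mean())
    return result


def model_similarity(
    m: ExpressionMatrix,
    meta: SampleMetadata,
    genes: list[str],
) -> pd.DataFrame:
    """Per cell line: which in vitro system correlates better with the xenograft.

    Profiles are per-system means over ``genes`` (replicates averaged);
    the verdict is "spheroid" iff Pearson r(spheroid, xenograft) exceeds
    r(2D, xenograft).
    """
    meta.check_matches(m)
    rows = []
    for cell_line, sub in meta.table.groupby("cell_line", sort=True):
        profiles = {}
        for ms in (ModelSystem.monolayer2D, ModelSystem.spheroid, ModelSystem.xenograft):
            ids = sub.loc[sub["model_system"] == ms.value, "sample_id"].tolist()
            if not ids:
                raise ValueError(f"cell line {cell_line!r} lacks {ms.value} samples")
            prof = m.data.loc[genes, ids].mean(axis=1).to_numpy(dtype=float)
            if np.ptp(prof) == 0:
                raise ValueError(f"constant profile for {cell_line!r}/{ms.value}")
            profiles[ms.value] = prof
        r_sph = float(stats.pearsonr(profiles["spheroid"], profiles["xenograft"])[0])
        r_2d = float(stats.pearsonr(profiles["monolayer2D"], profiles["xenograft"])[0])
        rows.append({
            "cell_line": cell_line,
            "r_spheroid_xenograft": r_sph,
            "r_2D_xenograft": r_2d,
            "closer_to_xenograft": "spheroid" if r_sph > r_2d else "monolayer2D",
        })
    return pd.DataFrame(rows).set_index("cell_line")


# ---------------------------------------------------------------------------
# Hierarchical clustering


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    ordered_data: pd.DataFrame


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    # rows = observations; 1 - Pearson r, clipped against fp drift
    r = np.corrcoef(X)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        a, b, height, _ = Z[i - n]
        la, ha = node(int(a))
        lb, hb = node(int(b))
        return (f"({la}:{height / 2 - ha:.6g},{lb}:{height / 2 - hb:.6g})", height / 2)

    tree, _ = node(2 * n - 2)
    return tree + ";"


def hierarchical_cluster(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    distance: str = "pearson",
    linkage_method: str = "average",
    axis: str = "samples",
) -> ClusterResult:
    """Agglomerative clustering of samples (or genes) over a gene subset.

    Defaults: 1 - Pearson correlation distance, average linkage. Leaf
    order is deterministic: scipy's ordering with observations presented
    in id-sorted order, so equal-distance merges resolve by smallest id.
    Returns the linkage matrix, leaf order, a Newick rendering of the
    dendrogram, and the data reordered to match.
    """
    data = m.data if genes is None else m.data.loc[genes]
    if data.isna().to_numpy().any():
        raise ValueError("NaN in selected genes")
    frame = data.T if axis == "samples" else data
    frame = frame.sort_index()  # id-sorted input makes tie-breaks reproducible
    if frame.shape[0] < 2:
        raise ValueError("need >= 2 observations to cluster")
    X = frame.to_numpy(dtype=float)
    if distance == "pearson":
        D = squareform(_correlation_distance(X), checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        D = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(D, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    labels = list(frame.index)
    leaf_order = [labels[i] for i in order]
    newick = _linkage_to_newick(Z, labels)
    ordered = data[leaf_order] if axis == "samples" else data.loc[leaf_order]
    return ClusterResult(linkage=Z, leaf_order=leaf_order, newick=newick, ordered_data=ordered)


def rank_two_group_markers(
    m: ExpressionMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Rank genes by log2 fold change of group A over group B.

    log2FC = mean(A) - mean(B) per gene; the table is sorted descending
    with gene-id tie-break, and the linear-scale fold (2**log2FC) is
    reported alongside. Used for the oxaliplatin resistant-vs-sensitive
    marker screen that surfaces CAV1-like genes.
    """
    meta.check_matches(m)
    ids_a = meta.samples_in_group(group_a)
    ids_b = meta.samples_in_group(group_b)
    if not ids_a:
        raise ValueError(f"group {group_a!r} is empty")
    if not ids_b:
        raise ValueError(f"group {group_b!r} is empty")
    lfc = m.data[ids_a].mean(axis=1) - m.data[ids_b].mean(axis=1)
    table = pd.DataFrame({"log2FC": lfc, "fold": np.exp2(lfc)})
    table.index.name = "gene"
    # descending log2FC, ties broken by gene id
    table = table.iloc[
        np.lexsort((table.index.to_numpy(), -table["log2FC"].to_numpy()))
    ]
    table["rank"] = np.arange(1, len(table) + 1)
    return table
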