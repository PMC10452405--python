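"""Nearest-template prediction of the iCMS class.

Each of the four marker classes (2U, 2D, 3U, 3D) defines an indicator
template over the union of marker genes found in the matrix. A sample's
profile over those genes is mean-centered and compared to each template by
cosine distance d = 1 - cos(x, t), d in [0, 2]. The class call uses the
distance-ordering rule

    D2U < D2D and D3U > D3D  ->  iCMS2
    D2U > D2D and D3U < D3D  ->  iCMS3
    any other constellation  ->  unstable

Note: the source protocol prints the second comparand of each rule as
"D3U > D3U" / "D3U < D3U", a self-comparison; D3D is the evident intent
and is used here. Inequalities are strict, so any exact tie routes to
``unstable`` rather than fabricating a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, FeatureLevel, ICMSGeneSets
from .icms_scoring import CLASS_KEYS

DISTANCE_COLUMNS = ["D2U", "D2D", "D3U", "D3D"]


@dataclass
class TemplateSet:
    """Indicator templates over the lexicographically ordered union genes."""

    union_genes: list[str]
    templates: dict[str, np.ndarray]  # class key -> 0/1 vector

    def __post_init__(self) -> None:
        n = len(self.union_genes)
        for key, t in self.templates.items():
            if t.shape != (n,):
                raise ValueError(f"template {key} has wrong length")
            if t.sum() < 1:
                raise ValueError(f"template {key} has no genes")


def build_templates(sets: ICMSGeneSets, m: ExpressionMatrix) -> TemplateSet:
    """Intersect the four classes with the matrix and build 0/1 templates."""
    genes_in_matrix = set(m.feature_ids)
    union = sorted(g for g in sets.union if g in genes_in_matrix)
    class_sets = dict(zip(CLASS_KEYS, sets.as_tuple()))
    templates = {}
    for key, gene_set in class_sets.items():
        vec = np.array([1.0 if g in gene_set else 0.0 for g in union])
        if vec.sum() < 1:
            raise ValueError(f"gene class {key} has no genes in the matrix")
        templates[key] = vec
    return TemplateSet(union_genes=union, templates=templates)


def sample_distance(
    x: np.ndarray,
    template: np.ndarray,
    metric: str = "cosine",
    center: bool = True,
) -> float:
    """Distance between one sample profile and one template.

    Cosine: d = 1 - cos(x_centered, t) in [0, 2]; centering subtracts the
    sample's mean over the union genes, so the distance responds to which
    genes sit above or below the sample's own average. Euclidean is
    available for comparison (computed on the same centered profile).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(template, dtype=float)
    if x.shape != t.shape:
        raise ValueError("profile and template lengths differ")
    if center:
        x = x - x.mean()
    nx = np.linalg.norm(x)
    nt = np.linalg.norm(t)
    if nx == 0:
        raise ValueError("constant profile: zero norm after centering")
    if metric == "cosine":
        return float(1.0 - x @ t / (nx * nt))
    if metric == "euclidean":
        return float(np.linalg.norm(x / nx - t / nt))
    raise ValueError(f"unknown metric {metric!r}")


def ntp_call(d2u: float, d2d: float, d3u: float, d3d: float) -> str:
    """Apply the strict distance-ordering decision rule."""
    for d in (d2u, d2d, d3u, d3d):
        if not np.isfinite(d):
            raise ValueError("non-finite distance")
    if d2u < d2d and d3u > d3d:
        return "iCMS2"
    if d2u > d2d and d3u < d3d:
        return "iCMS3"
    return "unstable"


def ntp_cohort(
    m: ExpressionMatrix,
    sets: ICMSGeneSets,
    metric: str = "cosine",
    center: bool = True,
    score_consensus: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample template distances and iCMS calls for a gene-level cohort.

    If ``score_consensus`` (per-sample iCMS2/iCMS3/discordant labels from
    the scoring route) is given, an ``agrees_with_score`` column marks
    samples where both routes produced the same class call; the agreement
    rate over samples called by both is stored in
    ``result.attrs["score_agreement"]``.
    """
    if m.feature_level is not FeatureLevel.gene:
        raise ValueError("ntp_cohort expects a gene-level matrix")
    ts = build_templates(sets, m)
    sub = m.data.loc[ts.union_genes]
    rows = {}
    for sample in m.sample_ids:
        x = sub[sample].to_numpy(dtype=float)
        dists = [
            sample_distance(x, ts.templates[k], metric=metric, center=center)
            for k in CLASS_KEYS
        ]
        rows[sample] = dists + [ntp_call(*dists)]
    result = pd.DataFrame.from_dict(
        rows, orient="index", columns=DISTANCE_COLUMNS + ["call"]
    )
    result.index.name = "sample_id"

    if score_consensus is not None:
        aligned = score_consensus.reindex(result.index)
        result["agrees_with_score"] = (result["call"] == aligned) & result["call"].isin(
            ["iCMS2", "iCMS3"]
        )
        both_called = result["call"].isin(["iCMS2", "iCMS3"]) & aligned.isin(
            ["iCMS2", "iCMS3"]
        )
        n_both = int(both_called.sum())
        agreement = (
            float((result.loc[both_called, "call"] == aligned[both_called]).mean())
            if n_both
            else float("nan")
        )
        result.attrs["score_agreement"] = agreement
        result.attrs["n_both_called"] = n_both
    return result


def permutation_pvalue(
    x: np.ndarray,
    template: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    metric: str = "cosine",
    center: bool = True,
) -> float:
    """Gene-label permutation p-value for one sample/template distance.

    Optional diagnostic only; class calls never depend on it. The observed
    distance is compared with distances to templates with permuted gene
    labels; p = (1 + #{perm <= observed}) / (1 + B).
    """
    rng = np.random.default_rng(seed)
    observed = sample_distance(x, template, metric=metric, center=center)
    count = 0
    t = np.asarray(template, dtype=float)
    for _ in range(n_permutations):
        perm = rng.permutation(t)
        if sample_distance(x, perm, metric=metric, center=center) <= observed:
            count += 1
    return (1 + count) / (1 + n_permutations)
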