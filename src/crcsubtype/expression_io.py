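"""Expression-matrix data model and readers/writers.

Log2 expression matrices (features x samples), gene sets in GMT format,
sample metadata tables, and probe-to-gene mean-collapsing. Matrices are
delimited text with feature ids in the first column and sample ids in the
header; the default dialect is tab-separated with a plain decimal point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crcsubtype")

REQUIRED_ICMS_SETS = ("iCMS2_up", "iCMS2_down", "iCMS3_up", "iCMS3_down")

METADATA_COLUMNS = ("sample_id", "cell_line", "model_system", "group")


class FeatureLevel(str, Enum):
    probe = "probe"
    gene = "gene"


class ModelSystem(str, Enum):
    """The five sample origins the study compares."""

    monolayer2D = "monolayer2D"
    spheroid = "spheroid"
    xenograft = "xenograft"
    patient_tumor = "patient_tumor"
    normal_tissue = "normal_tissue"


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Dense log2-intensity matrix, features in rows, samples in columns.

    Wraps a pandas DataFrame (index = feature ids, columns = sample ids).
    Every value must be finite and ids unique; construction validates.
    """

    data: pd.DataFrame
    feature_level: FeatureLevel = FeatureLevel.probe

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.feature_level = FeatureLevel(self.feature_level)
        dup_f = _find_duplicates(list(self.data.index))
        if dup_f:
            raise ValueError(f"duplicate feature ids: {dup_f}")
        dup_s = _find_duplicates(list(self.data.columns))
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleMetadata:
    """Per-sample annotations: cell line, model system, optional group label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", "cell_line", "model_system") if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if "group" not in self.table.columns:
            self.table = self.table.assign(group=None)
        dup = _find_duplicates(list(self.table["sample_id"]))
        if dup:
            raise ValueError(f"duplicate sample ids in metadata: {dup}")
        # validates every value is a known model system
        self.table = self.table.assign(
            model_system=[ModelSystem(v).value for v in self.table["model_system"]]
        )
        if self.table["model_system"].isna().any():
            raise ValueError("model_system must be set for every sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, model_system: str | ModelSystem) -> list[str]:
        ms = ModelSystem(model_system).value
        return list(self.table.loc[self.table["model_system"] == ms, "sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        meta_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            raise ValueError(
                f"metadata/matrix sample mismatch: only-in-metadata={sorted(meta_ids - mat_ids)}, "
                f"only-in-matrix={sorted(mat_ids - meta_ids)}"
            )


@dataclass
class ICMSGeneSets:
    """The four iCMS marker gene classes: 2U, 2D, 3U, 3D.

    iCMS2_up/iCMS2_down mark the canonical-epithelial intrinsic state,
    iCMS3_up/iCMS3_down the MSI-like state. The four sets must be pairwise
    disjoint; an overlapping symbol would contribute to both sides of a
    score and is treated as a curation error.
    """

    icms2_up: frozenset[str]
    icms2_down: frozenset[str]
    icms3_up: frozenset[str]
    icms3_down: frozenset[str]

    def __post_init__(self) -> None:
        names = dict(zip(REQUIRED_ICMS_SETS, self.as_tuple()))
        for name, s in names.items():
            if not s:
                raise ValueError(f"gene set {name} is empty")
        items = list(names.items())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                shared = sorted(set(items[i][1]) & set(items[j][1]))
                if shared:
                    raise ValueError(
                        f"gene sets {items[i][0]} and {items[j][0]} overlap: {shared}"
                    )

    def as_tuple(self) -> tuple[frozenset[str], ...]:
        return (self.icms2_up, self.icms2_down, self.icms3_up, self.icms3_down)

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(zip(REQUIRED_ICMS_SETS, self.as_tuple()))

    @property
    def union(self) -> frozenset[str]:
        u: frozenset[str] = frozenset()
        for s in self.as_tuple():
            u = u | s
        return u


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    feature_level: FeatureLevel | str = FeatureLevel.probe,
) -> ExpressionMatrix:
    """Read a delimited expression table (first column = feature ids).

    Raises ValueError naming the offending cell on non-numeric input and
    listing duplicates on repeated ids.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    return ExpressionMatrix(numeric.astype(float), feature_level=FeatureLevel(feature_level))


def write_expression(m: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    m.data.to_csv(path, sep=delimiter, index_label="feature_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata CSV with columns sample_id, cell_line, model_system[, group]."""
    df = pd.read_csv(path, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index=False, columns=list(METADATA_COLUMNS))


def read_gmt(
    path: str | Path,
    required_sets: Sequence[str] = REQUIRED_ICMS_SETS,
) -> ICMSGeneSets:
    """Parse a GMT file into the four iCMS gene classes.

    GMT lines are: set name, description, then tab-separated gene symbols.
    Duplicates within a line are dropped with a warning; a missing required
    set or an overlap between sets is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected name, description, genes")
            name = parts[0].strip()
            genes = [g.strip() for g in parts[2:] if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                dups = _find_duplicates(genes)
                logger.warning("GMT set %s: dropped duplicate genes %s", name, dups)
            sets[name] = frozenset(unique)
    missing = [s for s in required_sets if s not in sets]
    if missing:
        raise ValueError(f"required gene set(s) missing from GMT: {missing}")
    return ICMSGeneSets(*(sets[s] for s in required_sets))


def write_gmt(sets: ICMSGeneSets, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.as_dict().items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Probe collapsing


def collapse_probes(
    m: ExpressionMatrix,
    mapping: Mapping[str, str] | Mapping[str, Iterable[str]] | pd.DataFrame,
) -> ExpressionMatrix:
    """Mean-collapse probe-set rows to gene symbols.

    ``mapping`` maps probe id -> gene symbol (or an iterable of symbols; a
    probe annotated to several genes contributes to each). Each output gene
    row is the arithmetic mean over its probes, per sample. Unmapped probes
    are dropped and their count logged.
    """
    if m.feature_level is not FeatureLevel.probe:
        raise ValueError("collapse_probes expects a probe-level matrix")
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValueError("mapping table needs probe and gene columns")
        pairs = list(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    else:
        pairs = []
        for probe, genes in mapping.items():
            if isinstance(genes, str):
                pairs.append((str(probe), genes))
            else:
                pairs.extend((str(probe), g) for g in genes)

    gene_to_probes: dict[str, list[str]] = {}
    probe_index = set(m.feature_ids)
    matched_probes: set[str] = set()
    for probe, gene in pairs:
        probe, gene = probe.strip(), gene.strip()
        if probe in probe_index:
            gene_to_probes.setdefault(gene, []).append(probe)
            matched_probes.add(probe)
    if not gene_to_probes:
        raise ValueError("no probes in the mapping are present in the matrix")
    n_dropped = m.n_features - len(matched_probes)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_dropped)

    rows = {
        gene: m.data.loc[sorted(set(probes))].mean(axis=0)
        for gene, probes in gene_to_probes.items()
    }
    collapsed = pd.DataFrame(rows).T.sort_index()
    collapsed.columns = m.data.columns
    return ExpressionMatrix(collapsed, feature_level=FeatureLevel.gene)
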