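"""Core domain types and plain-text I/O shared by every pipeline stage.

Expression data travel as genes-by-samples matrices with an explicit scale
declaration (``linear`` or ``log2``), because the two screens state their
rules on different scales: the cell-line anchor-ratio rule is a linear fold
ratio, while differential testing and signature scoring operate on log2
values.  Clinical annotations, screen thresholds and gene signatures get
small dataclass wrappers with their invariants enforced at construction.

All on-disk formats are one-header TSV (plus an optional JSON provenance
sidecar for signatures); nothing binary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("linear", "log2")

M_STATUSES = ("M0", "M1", "unknown")
N_STATUSES = ("N0", "Nplus", "unknown")


class DataModelError(ValueError):
    """Raised when an input violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  No
        missing entries are allowed (the missing-value policy is applied
        at read time, not here).
    scale
        ``"linear"`` or ``"log2"``.  Linear matrices must be non-negative.
    entity_of
        Mapping from sample id to cancer-entity label.  Samples missing
        from the mapping are labelled ``"unassigned"``.
    """

    values: pd.DataFrame
    scale: str
    entity_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DataModelError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicated gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DataModelError(f"duplicated sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise DataModelError("expression matrix contains non-finite entries")
        if self.scale == "linear" and arr.size and (arr < 0).any():
            raise DataModelError("linear-scale matrix contains negative values")
        self.entity_of = {
            s: self.entity_of.get(s, "unassigned") for s in self.values.columns
        }

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def entities(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.entity_of[s], None)
        return list(seen)

    def samples_of_entity(self, entity: str) -> list[str]:
        return [s for s in self.values.columns if self.entity_of[s] == entity]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[:, sample_ids].copy(),
            scale=self.scale,
            entity_of={s: self.entity_of[s] for s in sample_ids},
        )


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on linear scale (2**x for log2 input; identity otherwise)."""
    if matrix.scale == "linear":
        return matrix
    return ExpressionMatrix(
        values=np.power(2.0, matrix.values),
        scale="linear",
        entity_of=dict(matrix.entity_of),
    )


def to_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return the matrix on log2 scale; linear input mapped by log2(x + pseudocount).

    The pseudocount guards against zeros in count-derived linear data
    (RSEM-style estimates contain exact zeros).
    """
    if matrix.scale == "log2":
        return matrix
    return ExpressionMatrix(
        values=np.log2(matrix.values + pseudocount),
        scale="log2",
        entity_of=dict(matrix.entity_of),
    )


def read_expression(
    path: str | Path,
    scale: str,
    entity_of: Mapping[str, str] | None = None,
    missing_policy: str = "drop-gene",
    duplicate_policy: str = "mean",
) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene ids, header sample ids).

    Duplicate gene rows are collapsed by ``duplicate_policy`` ("mean" or
    "error"); genes with any missing value are dropped under the default
    ``missing_policy="drop-gene"`` (row-wise complete case) and logged.
    Duplicated sample headers and non-numeric cells are fatal.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = [s for s in header if s in seen or seen.add(s)]
    if dups:
        raise DataModelError(f"{path}: duplicated sample ids in header: {sorted(set(dups))}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = header
    num = df.apply(pd.to_numeric, errors="coerce")
    # truly non-numeric = non-empty, non-NA original text that failed to parse
    orig_na = df.isna() | df.apply(lambda c: c.astype(str).str.strip().isin(["", "NA", "NaN", "nan"]))
    nonnum = num.isna() & ~orig_na
    if nonnum.to_numpy().any():
        r, c = np.argwhere(nonnum.to_numpy())[0]
        raise DataModelError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if num.index.duplicated().any():
        if duplicate_policy == "error":
            dups = num.index[num.index.duplicated()].unique().tolist()
            raise DataModelError(f"{path}: duplicated gene ids: {dups}")
        logger.info(
            "%s: collapsing %d duplicated gene rows by mean",
            path,
            int(num.index.duplicated().sum()),
        )
        num = num.groupby(level=0, sort=False).mean()
    if missing_policy == "drop-gene":
        n_before = len(num)
        num = num.dropna(axis=0, how="any")
        dropped = n_before - len(num)
        if dropped:
            logger.warning("%s: dropped %d genes with missing values", path, dropped)
    else:
        raise DataModelError(f"unknown missing_policy {missing_policy!r}")
    return ExpressionMatrix(values=num.astype(float), scale=scale, entity_of=dict(entity_of or {}))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(Path(path), sep="\t", index_label="gene_id")


def read_entities(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, entity) into a mapping."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "sample_id" not in df.columns or "entity" not in df.columns:
        raise DataModelError(f"{path}: expected columns sample_id and entity")
    return dict(zip(df["sample_id"], df["entity"]))


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id",
    "entity",
    "m_status",
    "n_status",
    "subtype",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "ihc_score",
]


@dataclass
class ClinicalTable:
    """Per-sample outcome annotations (TNM status, subtype, survival endpoints)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df["sample_id"].duplicated().any():
            raise DataModelError("duplicated sample_id in clinical table")
        for col in ("m_status",):
            bad = set(df[col].dropna()) - set(M_STATUSES)
            if bad:
                raise DataModelError(f"invalid m_status values: {bad}")
        bad = set(df["n_status"].dropna()) - set(N_STATUSES)
        if bad:
            raise DataModelError(f"invalid n_status values: {bad}")
        for endpoint in ("os", "rfs"):
            t, e = df[f"{endpoint}_time"], df[f"{endpoint}_event"]
            if (t.dropna() < 0).any():
                raise DataModelError(f"negative {endpoint}_time")
            if not set(e.dropna().astype(int)) <= {0, 1}:
                raise DataModelError(f"{endpoint}_event flags must be 0/1")
            if (e.notna() & t.isna()).any():
                raise DataModelError(f"{endpoint}_event recorded without {endpoint}_time")
        ihc = df["ihc_score"].dropna()
        if len(ihc) and not set(ihc.astype(int)) <= {0, 1, 2, 3}:
            raise DataModelError("ihc_score must be in {0,1,2,3}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def endpoint(self, which: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (times, events, sample_ids) for ``which`` in {"os", "rfs"},
        restricted to samples with a recorded time."""
        if which not in ("os", "rfs"):
            raise DataModelError(f"endpoint must be 'os' or 'rfs', got {which!r}")
        sub = self.table.dropna(subset=[f"{which}_time", f"{which}_event"])
        return (
            sub[f"{which}_time"].to_numpy(float),
            sub[f"{which}_event"].to_numpy(int),
            list(sub["sample_id"]),
        )


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str, "subtype": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataModelError(f"{path}: missing clinical columns {missing}")
    return ClinicalTable(df[CLINICAL_COLUMNS].copy())


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# ScreenConfig
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the discovery procedure.

    Defaults mirror the published rules: a 10-fold anchor ratio for the
    cell-line classification, raw p < 0.05 for the per-entity t-tests,
    Spearman r > 0.1 / r < -0.1 against the CDH1/VIM anchors for the tumor
    screen, and 2-cluster k-means with at most 50 iterations for patient
    stratification.
    """

    ratio_threshold: float = 10.0
    alpha: float = 0.05
    r_pos: float = 0.1
    r_neg: float = -0.1
    anchor_epithelial: str = "CDH1"
    anchor_mesenchymal: str = "VIM"
    k: int = 2
    max_iter: int = 50
    n_restarts: int = 10
    seed: int = 0
    welch: bool = False
    require_all_entities: bool = True
    min_samples_per_entity: int = 10

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1:
            raise DataModelError("ratio_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise DataModelError("alpha must be in (0, 1)")
        if not self.r_neg < 0 < self.r_pos:
            raise DataModelError("need r_neg < 0 < r_pos")
        if self.k < 2:
            raise DataModelError("k must be >= 2")
        if self.max_iter < 1:
            raise DataModelError("max_iter must be >= 1")


def read_config(path: str | Path) -> ScreenConfig:
    """Read a flat YAML file of ScreenConfig fields (missing keys keep defaults)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(ScreenConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DataModelError(f"{path}: unknown config keys {sorted(unknown)}")
    return ScreenConfig(**raw)


# ---------------------------------------------------------------------------
# GeneSignature
# ---------------------------------------------------------------------------


@dataclass
class GeneSignature:
    """Epithelial and mesenchymal gene lists with per-screen provenance.

    ``provenance`` maps gene id to a dict of supporting evidence keyed by
    screen/entity (free-form, JSON-serializable).
    """

    epithelial: list[str]
    mesenchymal: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.epithelial) & set(self.mesenchymal)
        if overlap:
            raise DataModelError(
                f"epithelial and mesenchymal lists overlap: {sorted(overlap)}"
            )
        if len(set(self.epithelial)) != len(self.epithelial):
            raise DataModelError("duplicated gene in epithelial list")
        if len(set(self.mesenchymal)) != len(self.mesenchymal):
            raise DataModelError("duplicated gene in mesenchymal list")

    @property
    def all_genes(self) -> list[str]:
        return list(self.epithelial) + list(self.mesenchymal)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSignature):
            return NotImplemented
        return (
            self.epithelial == other.epithelial
            and self.mesenchymal == other.mesenchymal
            and self.provenance == other.provenance
        )


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    """Write a two-column TSV (gene_id, class) plus a JSON provenance sidecar."""
    path = Path(path)
    rows = [(g, "epithelial") for g in sig.epithelial] + [
        (g, "mesenchymal") for g in sig.mesenchymal
    ]
    pd.DataFrame(rows, columns=["gene_id", "class"]).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(sig.provenance, fh, indent=1, sort_keys=True)


def read_signature(path: str | Path) -> GeneSignature:
    path = Path(path)
    epithelial: list[str] = []
    mesenchymal: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["gene_id", "class"]:
            raise DataModelError(f"{path}:1: expected header 'gene_id<TAB>class'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[1] not in ("epithelial", "mesenchymal"):
                raise DataModelError(f"{path}:{lineno}: malformed signature line {line!r}")
            (epithelial if parts[1] == "epithelial" else mesenchymal).append(parts[0])
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance: dict[str, dict] = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = json.load(fh)
    return GeneSignature(epithelial=epithelial, mesenchymal=mesenchymal, provenance=provenance)


__all__ = [
    "DataModelError",
    "ExpressionMatrix",
    "ClinicalTable",
    "ScreenConfig",
    "GeneSignature",
    "read_expression",
    "write_expression",
    "read_entities",
    "read_clinical",
    "write_clinical",
    "read_config",
    "read_signature",
    "write_signature",
    "to_linear",
    "to_log2",
]
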