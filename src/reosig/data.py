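"""Data containers, text-format I/O and preprocessing transforms.

The two substrates of every analysis in this package are an
:class:`ExpressionMatrix` (genes x samples, continuous log-scale values)
and a :class:`ClinicalTable` (per-sample recurrence-free survival,
pathological response state and coded clinical covariates).  Both wrap a
:class:`pandas.DataFrame` and validate their invariants on construction.

Preprocessing covers the standard upstream steps of a cross-platform
transcriptomic study: collapsing probe-level measurements to one value
per gene, intersecting gene universes across platforms, optional
log2 transformation of linear-scale values, and truncation of
follow-up at a fixed horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "ClinicalTable",
    "ProbeMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_probe_map",
    "collapse_probes",
    "intersect_gene_universe",
    "truncate_followup",
    "code_covariates",
]

RESPONSE_STATES = ("CR", "nonCR")
STAGE_LEVELS = ("II", "III", "IV")
GRADE_LEVELS = (2, 3)
RESIDUAL_LEVELS = ("0-10mm", ">=11mm")

#: Ordinal coding for tumor stage used in Cox models (IV vs. III vs. II).
STAGE_ORDINAL = {"II": 2, "III": 3, "IV": 4}

CLINICAL_COLUMNS = [
    "rfs_months",
    "event",
    "response_state",
    "age_years",
    "stage",
    "grade",
    "residual",
]


class DataError(ValueError):
    """Structured error for malformed input data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous log-scale expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers
        as columns.  Values must be finite floats; at least 2 genes and
        1 sample are required (a single gene admits no ordering).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dup}")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise DataError(
                f"need at least 2 genes and 1 sample, got shape {df.shape}"
            )
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                "non-finite value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        df = df.astype(float)
        df.index.name = None
        df.columns.name = None
        self.data = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values_for(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise DataError(f"gene {gene!r} not in expression matrix")
        return self.data.loc[gene].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :].copy())


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations keyed by unique sample id.

    Columns: ``rfs_months`` (non-negative, months), ``event`` (1 =
    recurrence observed, 0 = censored), ``response_state`` (``CR`` /
    ``nonCR`` / missing), ``age_years``, ``stage`` (II/III/IV),
    ``grade`` (2/3) and ``residual`` (``0-10mm`` / ``>=11mm``).
    Missing optional fields are encoded as NaN / None.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dup}")
        for col in ("rfs_months", "event"):
            if col not in df.columns:
                raise DataError(f"clinical table missing column {col!r}")
        df = df.copy()
        df["rfs_months"] = pd.to_numeric(df["rfs_months"], errors="raise")
        df["event"] = pd.to_numeric(df["event"], errors="raise")
        if (df["rfs_months"] < 0).any():
            bad = df.index[df["rfs_months"] < 0].tolist()
            raise DataError(f"negative rfs_months for samples {bad}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])].tolist()
            raise DataError(f"event must be 0/1; offending samples {bad}")
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        resp = df["response_state"].dropna()
        if not resp.isin(RESPONSE_STATES).all():
            bad = sorted(set(resp) - set(RESPONSE_STATES))
            raise DataError(f"unknown response_state values {bad}")
        stage = df["stage"].dropna()
        if not stage.isin(STAGE_LEVELS).all():
            bad = sorted(set(stage) - set(STAGE_LEVELS))
            raise DataError(f"unknown stage values {bad}")
        grade = pd.to_numeric(df["grade"], errors="raise").dropna()
        if not grade.isin(GRADE_LEVELS).all():
            bad = sorted(set(grade) - set(GRADE_LEVELS))
            raise DataError(f"unknown grade values {bad}")
        residual = df["residual"].dropna()
        if not residual.isin(RESIDUAL_LEVELS).all():
            bad = sorted(set(residual) - set(RESIDUAL_LEVELS))
            raise DataError(f"unknown residual values {bad}")
        df = df[CLINICAL_COLUMNS].copy()
        for col in ("response_state", "stage", "residual"):
            df[col] = df[col].where(df[col].notna(), np.nan)
        df.index.name = "sample_id"
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class ProbeMap:
    """Probe-to-gene association with ambiguous probes flagged invalid.

    Probes mapping to zero or more than one gene are excluded from
    :attr:`mapping` and recorded in :attr:`invalid`; each retained probe
    maps to exactly one gene id.
    """

    mapping: dict[str, str]
    invalid: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, pairs) -> "ProbeMap":
        genes_by_probe: dict[str, set[str]] = {}
        for probe, gene in pairs:
            genes_by_probe.setdefault(str(probe), set()).add(str(gene))
        mapping = {}
        invalid = set()
        for probe, genes in genes_by_probe.items():
            if len(genes) == 1:
                mapping[probe] = next(iter(genes))
            else:
                invalid.add(probe)
        return cls(mapping=mapping, invalid=frozenset(invalid))


def read_expression_matrix(path, log_offset: float | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    The file has gene ids in the first column, a header row of sample
    ids (first header cell ignored) and a numeric body.  If
    ``log_offset`` is given, values are assumed linear-scale (e.g. FPKM)
    and each cell x is replaced by ``log2(x + log_offset)``.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise DataError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().argmax()]
            raise DataError(f"empty cell at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    if log_offset is not None:
        if log_offset < 0:
            raise DataError("log_offset must be non-negative")
        if (numeric.to_numpy() + log_offset <= 0).any():
            raise DataError("log2(x + offset) undefined for some values")
        numeric = np.log2(numeric + log_offset)
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV; float repr round-trips bit-exactly."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical CSV (mandatory sample_id, rfs_months, event)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError("clinical table missing column 'sample_id'")
    df = df.set_index("sample_id")
    rename = {"age": "age_years"}
    df = df.rename(columns=rename)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, index_label="sample_id")


def read_probe_map(path) -> ProbeMap:
    """Read a two-column (probe_id, gene_id) TSV into a :class:`ProbeMap`."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataError("probe map must have two columns (probe_id, gene_id)")
    return ProbeMap.from_pairs(df.iloc[:, :2].itertuples(index=False))


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Average probe-level rows mapping to the same gene.

    Probes flagged invalid in the map (no gene or multiple genes) are
    dropped.  Mapped probes absent from the matrix are ignored with a
    logged warning.  The result has one row per gene, each value the
    arithmetic mean over that gene's valid probes in that sample.
    """
    present = [p for p in probe_map.mapping if p in probe_matrix.data.index]
    missing = set(probe_map.mapping) - set(present)
    if missing:
        logger.warning(
            "%d mapped probes absent from matrix (e.g. %s)",
            len(missing), sorted(missing)[:3],
        )
    if not present:
        raise DataError("no valid probe remains after applying the probe map")
    sub = probe_matrix.data.loc[present]
    genes = pd.Series({p: probe_map.mapping[p] for p in present})
    collapsed = sub.groupby(genes).mean()
    collapsed = collapsed.sort_index()
    if collapsed.shape[0] < 2:
        raise DataError("fewer than 2 genes after probe collapsing")
    return ExpressionMatrix(collapsed)


def intersect_gene_universe(*matrices: ExpressionMatrix) -> list[str]:
    """Sorted intersection of the gene universes of >= 2 matrices."""
    if len(matrices) < 2:
        raise DataError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise DataError("empty gene-universe intersection")
    return sorted(common)


def truncate_followup(clinical: ClinicalTable, horizon_months: float = 60.0) -> ClinicalTable:
    """Censor follow-up strictly beyond ``horizon_months`` at the horizon.

    Records with ``rfs_months > horizon`` are set to the horizon with
    ``event = 0``; a record at exactly the horizon is unchanged.  The
    operation is idempotent.
    """
    if horizon_months <= 0:
        raise DataError("horizon_months must be positive")
    df = clinical.data.copy()
    over = df["rfs_months"] > horizon_months
    df.loc[over, "rfs_months"] = horizon_months
    df.loc[over, "event"] = 0
    return ClinicalTable(df)


def code_covariates(clinical: ClinicalTable) -> pd.DataFrame:
    """Numeric Cox codings of the clinical covariates.

    age: >= 60 vs < 60 (binary); stage: ordinal 2/3/4 for II/III/IV;
    grade: 3 vs 2 (binary); residual tumor: >= 11 mm vs 0-10 mm
    (binary).  Missing fields stay NaN for per-model complete-case
    handling downstream.
    """
    df = clinical.data
    out = pd.DataFrame(index=df.index)
    out["age_ge60"] = (df["age_years"] >= 60).astype(float).where(df["age_years"].notna())
    out["stage_ord"] = df["stage"].map(STAGE_ORDINAL).astype(float)
    out["grade_3"] = (pd.to_numeric(df["grade"]) == 3).astype(float).where(df["grade"].notna())
    out["residual_ge11"] = (df["residual"] == ">=11mm").astype(float).where(df["residual"].notna())
    return out
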