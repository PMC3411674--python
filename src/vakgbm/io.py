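"""Readers and writers for clinical tables, expression matrices and binding tables.

All three formats are plain delimited text. Missing values may be written as an
empty cell or ``NA``; writers always emit ``NA``. Expression input is assumed to
be on the log2 (RMA-like) scale unless ``linear=True`` is passed, in which case
values are log2-transformed with a small positive floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

_NA_STRINGS = {"", "na", "nan", "null", "none"}

#: default column names; override via the ``schema`` mapping for TCGA/REMBRANDT-style exports
DEFAULT_CLINICAL_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "volume_mm3": "volume_mm3",
    "diameter_mm": "diameter_mm",
    "age_years": "age_years",
    "kps": "kps",
    "os_months": "os_months",
    "event": "event",
    "mgmt_betas": "mgmt_betas",
    "tmz": "tmz",
    "rt": "rt",
}

_MANDATORY_FIELDS = ("patient_id", "age_years", "kps", "os_months", "event")


def _is_na(token: str) -> bool:
    return token.strip().lower() in _NA_STRINGS


@dataclass
class ClinicalRecord:
    """One patient: imaging size, age, KPS, outcome, MGMT betas and therapy flags.

    ``diameter_mm`` is the mean of the two largest orthogonal lesion diameters,
    the 2D surrogate for volumetry.
    """

    patient_id: str
    age_years: float
    kps: int
    os_months: float
    event: int
    volume_mm3: float | None = None
    diameter_mm: float | None = None
    mgmt_betas: list[float] | None = None
    tmz: int | None = None
    rt: int | None = None

    def invariant_violations(self) -> list[str]:
        """Return human-readable messages for every violated invariant."""
        msgs: list[str] = []
        if self.volume_mm3 is not None and self.volume_mm3 < 0:
            msgs.append(f"volume_mm3 must be non-negative, got {self.volume_mm3}")
        if self.diameter_mm is not None and self.diameter_mm < 0:
            msgs.append(f"diameter_mm must be non-negative, got {self.diameter_mm}")
        if not self.age_years > 0:
            msgs.append(f"age_years must be positive, got {self.age_years}")
        if self.kps not in range(0, 101, 10):
            msgs.append(f"kps must be a multiple of 10 in [0, 100], got {self.kps}")
        if self.os_months < 0:
            msgs.append(f"os_months must be >= 0, got {self.os_months}")
        if self.event not in (0, 1):
            msgs.append(f"event must be 0 or 1, got {self.event}")
        if self.mgmt_betas is not None:
            bad = [b for b in self.mgmt_betas if not 0.0 <= b <= 1.0]
            if bad:
                msgs.append(f"mgmt_betas outside [0, 1]: {bad}")
        for name in ("tmz", "rt"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                msgs.append(f"{name} must be binary, got {v}")
        return msgs

    @property
    def mean_beta(self) -> float | None:
        """Average of the MGMT probe beta-values, or None when unavailable."""
        if not self.mgmt_betas:
            return None
        return float(np.mean(self.mgmt_betas))


@dataclass
class RowIssue:
    line: int
    message: str


@dataclass
class ClinicalCohort:
    """Validated clinical records plus a per-line report of rejected rows."""

    records: list[ClinicalRecord] = field(default_factory=list)
    rejected: list[RowIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "volume_mm3": r.volume_mm3,
                    "diameter_mm": r.diameter_mm,
                    "age_years": r.age_years,
                    "kps": r.kps,
                    "os_months": r.os_months,
                    "event": r.event,
                    "mgmt_betas": ";".join(f"{b:g}" for b in r.mgmt_betas)
                    if r.mgmt_betas
                    else None,
                    "tmz": r.tmz,
                    "rt": r.rt,
                }
            )
        return pd.DataFrame(rows)


def _parse_float(token: str, line: int, col: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ValidationError(f"line {line}, column '{col}': unparseable numeric '{token}'") from exc


def _parse_optional_float(token: str | None, line: int, col: str) -> float | None:
    if token is None or _is_na(token):
        return None
    return _parse_float(token, line, col)


def _parse_optional_int(token: str | None, line: int, col: str) -> int | None:
    v = _parse_optional_float(token, line, col)
    if v is None:
        return None
    if v != int(v):
        raise ValidationError(f"line {line}, column '{col}': expected integer, got '{token}'")
    return int(v)


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_clinical_table(
    path: str, schema: Mapping[str, str] | None = None
) -> ClinicalCohort:
    """Read a CSV/TSV clinical table, one patient per row.

    ``schema`` maps canonical field names (keys of :data:`DEFAULT_CLINICAL_SCHEMA`)
    to the column names actually present in the file. Rows violating record
    invariants are collected in ``cohort.rejected`` with their source line
    numbers; structurally missing mandatory columns raise :class:`SchemaError`.
    MGMT probe betas are a single column of ``;``-separated values.
    """
    colmap = dict(DEFAULT_CLINICAL_SCHEMA)
    if schema:
        colmap.update(schema)

    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [colmap[f] for f in _MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    have_vol = colmap["volume_mm3"] in df.columns
    have_diam = colmap["diameter_mm"] in df.columns
    if not have_vol and not have_diam:
        raise SchemaError(
            "clinical table must contain at least one size column "
            f"('{colmap['volume_mm3']}' or '{colmap['diameter_mm']}')"
        )

    def get(row, field_name) -> str | None:
        col = colmap[field_name]
        return row[col] if col in df.columns else None

    cohort = ClinicalCohort()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            betas_tok = get(row, "mgmt_betas")
            betas = None
            if betas_tok is not None and not _is_na(betas_tok):
                betas = [
                    _parse_float(tok, line, colmap["mgmt_betas"])
                    for tok in betas_tok.replace(",", ";").split(";")
                    if tok.strip()
                ]
            kps = _parse_optional_int(row[colmap["kps"]], line, colmap["kps"])
            event = _parse_optional_int(row[colmap["event"]], line, colmap["event"])
            if kps is None:
                raise ValidationError(f"line {line}: kps is missing")
            if event is None:
                raise ValidationError(f"line {line}: event is missing")
            rec = ClinicalRecord(
                patient_id=str(row[colmap["patient_id"]]),
                volume_mm3=_parse_optional_float(get(row, "volume_mm3"), line, colmap["volume_mm3"]),
                diameter_mm=_parse_optional_float(get(row, "diameter_mm"), line, colmap["diameter_mm"]),
                age_years=_parse_float(row[colmap["age_years"]], line, colmap["age_years"]),
                kps=kps,
                os_months=_parse_float(row[colmap["os_months"]], line, colmap["os_months"]),
                event=event,
                mgmt_betas=betas,
                tmz=_parse_optional_int(get(row, "tmz"), line, colmap["tmz"]),
                rt=_parse_optional_int(get(row, "rt"), line, colmap["rt"]),
            )
        except ValidationError as exc:
            cohort.rejected.append(RowIssue(line, str(exc)))
            continue
        violations = rec.invariant_violations()
        if violations:
            cohort.rejected.append(RowIssue(line, "; ".join(violations)))
        else:
            cohort.records.append(rec)
    return cohort


def write_clinical_table(cohort: ClinicalCohort, path: str) -> None:
    df = cohort.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression of genes and microRNAs across samples.

    ``values`` is features x samples; ``feature_kind`` labels every row as
    ``gene`` or ``microRNA``.
    """

    values: pd.DataFrame
    feature_kind: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValidationError(f"duplicate feature id(s): {dupes}")
        if self.values.columns.duplicated().any():
            dupes = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        if not self.feature_kind.index.equals(self.values.index):
            self.feature_kind = self.feature_kind.reindex(self.values.index)
        if self.feature_kind.isna().any():
            missing = list(self.feature_kind.index[self.feature_kind.isna()])
            raise ValidationError(f"feature_kind undefined for: {missing}")
        bad_kinds = set(self.feature_kind.unique()) - {"gene", "microRNA"}
        if bad_kinds:
            raise ValidationError(f"unknown feature kind(s): {sorted(bad_kinds)}")
        self.values.index.name = "feature_id"
        self.values.columns.name = None
        self.feature_kind.index.name = "feature_id"
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at feature '{self.values.index[i]}', "
                f"sample '{self.values.columns[j]}'"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.values.loc[self.feature_kind == kind]

    def linear(self) -> pd.DataFrame:
        """Anti-logged (2**x) values, used by the signature ratio."""
        return 2.0 ** self.values


def read_expression_matrix(path: str, linear: bool = False, floor: float = 1.0) -> ExpressionMatrix:
    """Read a TSV/GCT-like expression matrix.

    Layout: first column feature id, second column feature kind
    (``gene``/``microRNA``), remaining columns one per sample. A GCT ``#1.2``
    version line and the following dimensions line are tolerated and skipped.
    With ``linear=True`` the values are taken as linear scale and converted to
    log2 after flooring at ``floor``.
    """
    with open(path) as fh:
        first = fh.readline()
        skip = 2 if first.startswith("#1.2") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise SchemaError("expression matrix needs feature id, kind, and >= 1 sample column")
    id_col, kind_col = df.columns[0], df.columns[1]
    df = df.set_index(id_col)
    kind = df[kind_col].astype(str)
    vals = df.drop(columns=[kind_col])
    numeric = vals.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & vals.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at feature '{vals.index[i]}', sample '{vals.columns[j]}': "
            f"'{vals.iat[i, j]}'"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"missing expression value at feature '{numeric.index[i]}', sample '{numeric.columns[j]}'"
        )
    if linear:
        numeric = np.log2(numeric.clip(lower=floor))
    return ExpressionMatrix(values=numeric.astype(float), feature_kind=kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    out = matrix.values.copy()
    out.insert(0, "kind", matrix.feature_kind)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class BindingTable:
    """microRNA -> gene binding predictions with per-pair algorithm counts."""

    pairs: pd.DataFrame  # columns: mirna_id, gene_id, n_algorithms

    def __post_init__(self) -> None:
        required = ["mirna_id", "gene_id", "n_algorithms"]
        if list(self.pairs.columns) != required:
            self.pairs = self.pairs[required]
        if (self.pairs["n_algorithms"] < 1).any():
            bad = self.pairs.loc[self.pairs["n_algorithms"] < 1]
            raise ValidationError(f"n_algorithms must be >= 1; offending rows:\n{bad}")
        if self.pairs.duplicated(["mirna_id", "gene_id"]).any():
            raise ValidationError("duplicate (mirna_id, gene_id) pairs; collapse before constructing")

    def __len__(self) -> int:
        return len(self.pairs)

    def lookup(self) -> dict[tuple[str, str], int]:
        return {
            (m, g): int(n)
            for m, g, n in self.pairs.itertuples(index=False)
        }


def read_binding_table(path: str) -> BindingTable:
    """Read a 3-column TSV of (mirna_id, gene_id, n_algorithms).

    Duplicate pairs are collapsed keeping the maximum algorithm count, with a
    warning. An empty file yields an empty table plus a warning.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["mirna_id", "gene_id", "n_algorithms"],
        header=0,
        dtype={"mirna_id": str, "gene_id": str},
    )
    if df.empty:
        warnings.warn(f"binding table '{path}' is empty")
        return BindingTable(pd.DataFrame(columns=["mirna_id", "gene_id", "n_algorithms"]))
    bad = df[df["n_algorithms"] < 1]
    if not bad.empty:
        raise ValidationError(
            f"n_algorithms < 1 at file line(s) {[int(i) + 2 for i in bad.index]}"
        )
    n_dupes = int(df.duplicated(["mirna_id", "gene_id"]).sum())
    if n_dupes:
        warnings.warn(f"collapsed {n_dupes} duplicate binding pair(s) keeping max n_algorithms")
        df = (
            df.groupby(["mirna_id", "gene_id"], as_index=False, sort=False)["n_algorithms"]
            .max()
        )
    df["n_algorithms"] = df["n_algorithms"].astype(int)
    return BindingTable(df.reset_index(drop=True))


def write_binding_table(table: BindingTable, path: str) -> None:
    table.pairs.to_csv(path, sep="\t", index=False, na_rep="NA")
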