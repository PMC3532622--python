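"""On-disk artifacts and their domain types.

All tables are plain TSV so that frozen models and intermediate results are
diffable.  The expression matrix carries an optional orientation directive in
its first line (``#orientation: samples_in_rows`` or ``genes_in_rows``);
samples-in-rows is the default.  Signature models are stored as versioned
JSON.  Missing expression values are encoded as ``NA``; imputation is the
responsibility of :mod:`msisig.normalization`, never of the readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "SignatureModel",
    "MSI",
    "MSS",
    "MSI_LIKE",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signature",
    "write_signature",
    "read_clinical_table",
    "write_clinical_table",
    "validate_clinical_table",
    "read_variant_table",
    "write_variant_table",
    "validate_variant_table",
    "msi_binary_labels",
    "CLINICAL_COLUMNS",
    "VARIANT_COLUMNS",
]

# Three-way classification labels used throughout.
MSS = "MSS"
MSI_LIKE = "MSI_LIKE"
MSI = "MSI"

SIGNATURE_SCHEMA_VERSION = 1

CLINICAL_COLUMNS = [
    "sample_id",
    "msi_hospital",
    "stage",
    "braf",
    "dmfs_years",
    "dmfs_event",
]
_MSI_HOSPITAL_VALUES = {"MSI", "MSS", "MSI-L", "unknown"}
_STAGE_VALUES = {"I", "II", "III", "IV", "unknown"}
_BRAF_VALUES = {"mutant", "wildtype", "unknown"}

VARIANT_COLUMNS = [
    "sample_id",
    "gene_id",
    "position",
    "coverage",
    "variant_count",
    "fwd_variant_count",
    "rev_variant_count",
    "consequence",
    "in_normal_panel",
]
_CONSEQUENCE_VALUES = {"coding_change", "other"}


def _check_unique(ids, kind: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of log-ratio expression values.

    ``values[i, j]`` is the log-ratio of sample ``sample_ids[i]`` for gene
    ``gene_ids[j]``.  NaN cells are permitted only before imputation and are
    flagged in ``metadata['has_missing']``.  The log scale (log2/log10) is
    recorded in ``metadata['scale']``.
    """

    sample_ids: list
    gene_ids: list
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if np.isinf(self.values).any():
            raise ValidationError("expression values must be finite (NaN allowed pre-imputation)")
        if np.isnan(self.values).any():
            self.metadata["has_missing"] = True

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), dict(metadata or {}))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order; absent genes raise."""
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        cols = [idx[g] for g in gene_ids]
        return ExpressionMatrix(self.sample_ids, list(gene_ids), self.values[:, cols], dict(self.metadata))


def read_expression_matrix(path, orientation: str = "samples_in_rows") -> ExpressionMatrix:
    """Read an expression matrix TSV.

    The first line may be a ``#orientation:`` directive overriding
    ``orientation``.  Non-numeric cells parse as missing (NaN); duplicate
    identifiers and ragged rows raise.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#orientation:"):
            orientation = first.split(":", 1)[1].strip()
            skip = 1
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows; pandas names the line
        raise FormatError(f"{path}: {exc}") from exc
    if df.columns.isnull().any() or df.index.isnull().any():
        raise FormatError(f"{path}: malformed header or missing identifiers")
    values = df.apply(pd.to_numeric, errors="coerce")
    if orientation == "genes_in_rows":
        values = values.T
    try:
        return ExpressionMatrix.from_frame(values, {"orientation_on_disk": orientation})
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path, orientation: str = "samples_in_rows") -> None:
    """Write a matrix TSV with an orientation directive, 12 significant digits."""
    df = matrix.to_frame()
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise FormatError(f"unknown orientation {orientation!r}")
    with open(path, "w") as fh:
        fh.write(f"#orientation: {orientation}\n")
        df.to_csv(fh, sep="\t", float_format="%.17g", na_rep="NA", index_label="id")


@dataclass
class SignatureModel:
    """A frozen nearest-centroid signature: gene list, class centroids, thresholds.

    ``threshold_primary`` separates MSS from signature-positive samples;
    ``threshold_secondary`` (>= primary) separates MSI-like from MSI among the
    positives.  ``thresholds_stale`` marks models whose gene set changed after
    threshold optimization (e.g. platform reduction) and which therefore must
    be re-optimized before classification.
    """

    gene_ids: list
    centroid_msi: np.ndarray
    centroid_mss: np.ndarray
    threshold_primary: float | None = None
    threshold_secondary: float | None = None
    thresholds_stale: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        self.centroid_msi = np.asarray(self.centroid_msi, dtype=float)
        self.centroid_mss = np.asarray(self.centroid_mss, dtype=float)
        n = len(self.gene_ids)
        if self.centroid_msi.shape != (n,) or self.centroid_mss.shape != (n,):
            raise ValidationError(
                f"centroid lengths {self.centroid_msi.shape[0]}/{self.centroid_mss.shape[0]} "
                f"do not match {n} genes"
            )
        if self.threshold_primary is not None and self.threshold_secondary is not None:
            if self.threshold_secondary < self.threshold_primary:
                raise ValidationError(
                    f"threshold_secondary ({self.threshold_secondary}) < "
                    f"threshold_primary ({self.threshold_primary})"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def has_thresholds(self) -> bool:
        return self.threshold_primary is not None and self.threshold_secondary is not None

    def with_thresholds(self, primary: float, secondary: float) -> "SignatureModel":
        """Return a copy with fresh thresholds; clears the stale flag."""
        return SignatureModel(
            self.gene_ids,
            self.centroid_msi.copy(),
            self.centroid_mss.copy(),
            float(primary),
            float(secondary),
            False,
            dict(self.provenance),
        )


def write_signature(model: SignatureModel, path) -> None:
    doc = {
        "schema_version": SIGNATURE_SCHEMA_VERSION,
        "gene_ids": model.gene_ids,
        "centroid_msi": [float(x) for x in model.centroid_msi],
        "centroid_mss": [float(x) for x in model.centroid_mss],
        "threshold_primary": model.threshold_primary,
        "threshold_secondary": model.threshold_secondary,
        "thresholds_stale": model.thresholds_stale,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_signature(path) -> SignatureModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid signature JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != SIGNATURE_SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported signature schema version {version!r}")
    try:
        return SignatureModel(
            doc["gene_ids"],
            np.asarray(doc["centroid_msi"], dtype=float),
            np.asarray(doc["centroid_mss"], dtype=float),
            doc.get("threshold_primary"),
            doc.get("threshold_secondary"),
            bool(doc.get("thresholds_stale", False)),
            doc.get("provenance", {}),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing signature field {exc}") from exc


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample clinical annotation table.

    Columns: sample_id, msi_hospital (MSI/MSS/MSI-L/unknown), stage, braf,
    dmfs_years, dmfs_event.  A DMFS event indicator must be present exactly
    when a follow-up time is.
    """
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"clinical table missing columns: {missing_cols}")
    df = df[CLINICAL_COLUMNS].copy()
    _check_unique(df["sample_id"].tolist(), "sample")
    for col, allowed in [
        ("msi_hospital", _MSI_HOSPITAL_VALUES),
        ("stage", _STAGE_VALUES),
        ("braf", _BRAF_VALUES),
    ]:
        bad = set(df[col].dropna()) - allowed
        if bad:
            raise ValidationError(f"invalid {col} values: {sorted(bad)}")
    years = pd.to_numeric(df["dmfs_years"], errors="coerce")
    events = pd.to_numeric(df["dmfs_event"], errors="coerce")
    if (years.isna() != events.isna()).any():
        bad_ids = df.loc[years.isna() != events.isna(), "sample_id"].tolist()
        raise ValidationError(f"dmfs_event must be present iff dmfs_years is: {bad_ids}")
    if (years.dropna() < 0).any():
        raise ValidationError("dmfs_years must be nonnegative")
    if not events.dropna().isin([0, 1]).all():
        raise ValidationError("dmfs_event must be 0/1")
    df["dmfs_years"] = years
    df["dmfs_event"] = events
    return df


def read_clinical_table(path) -> pd.DataFrame:
    return validate_clinical_table(pd.read_csv(path, sep="\t"))


def write_clinical_table(df: pd.DataFrame, path) -> None:
    validate_clinical_table(df).to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def msi_binary_labels(clinical: pd.DataFrame) -> pd.Series:
    """Hospital MSI status as a 0/1 label, with MSI-L mapped to MSS.

    Low-grade instability is stored distinctly on disk but is treated as
    microsatellite-stable in every analysis.
    """
    status = clinical["msi_hospital"]
    if (status == "unknown").any():
        raise ValidationError("cannot binarize samples with unknown hospital MSI status")
    return (status == "MSI").astype(int).set_axis(clinical["sample_id"])


def validate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a candidate-variant table (one row per called variant)."""
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"variant table missing columns: {missing_cols}")
    df = df[VARIANT_COLUMNS].copy()
    if len(df) == 0:
        return df
    for col in ["position", "coverage", "variant_count", "fwd_variant_count", "rev_variant_count"]:
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any() or (vals != vals.astype(int)).any():
            raise ValidationError(f"{col} must be a nonnegative integer")
        df[col] = vals.astype(int)
    if df["in_normal_panel"].dtype != bool:
        df["in_normal_panel"] = df["in_normal_panel"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if df["in_normal_panel"].isna().any():
            raise ValidationError("in_normal_panel must be boolean")
    bad = set(df["consequence"]) - _CONSEQUENCE_VALUES
    if bad:
        raise ValidationError(f"invalid consequence values: {sorted(bad)}")
    strand_bad = df["fwd_variant_count"] + df["rev_variant_count"] != df["variant_count"]
    if strand_bad.any():
        raise ValidationError(
            f"strand counts do not sum to variant_count at rows {df.index[strand_bad].tolist()}"
        )
    cov_bad = df["variant_count"] > df["coverage"]
    if cov_bad.any():
        raise ValidationError(
            f"variant_count exceeds coverage at rows {df.index[cov_bad].tolist()}"
        )
    return df


def read_variant_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return validate_variant_table(df)


def write_variant_table(df: pd.DataFrame, path) -> None:
    validate_variant_table(df).to_csv(path, sep="\t", index=False)
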