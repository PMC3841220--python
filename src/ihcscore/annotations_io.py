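"""On-disk schemas and loaders for IHC annotation data.

The package consumes four plain TSV tables (UTF-8, tab-separated, header row
required):

``annotations.tsv``
    One row per immunohistochemistry (IHC) staining result.  Columns:
    ``antibody_id, gene, tissue, cell_type, sample_kind, cancer_type,
    patient_id, intensity, quantity``.  ``sample_kind`` is ``normal`` or
    ``cancer``; normal rows leave ``cancer_type`` and ``patient_id`` empty,
    cancer rows fill both.  ``intensity`` is one of Negative/Weak/Moderate/
    Strong and ``quantity`` one of Negative/Rare/<25%/25-75%/>75%.

``mappings.tsv``
    One row per cancer↔normal-cell-type pairing ("mapping"): ``mapping_id,
    cancer_type, normal_tissue, normal_cell_type``.  A registry covering 27
    mappings over 20 cancer types (ovarian excluded for lack of normal-ovary
    staining) ships with the package and is the default.

``cohort.tsv``
    Per-gene, per-patient tumor/adjacent-normal expression fold changes:
    ``gene, patient_id, fold_change`` with ``fold_change > 0``.

``gene_annotations.tsv``
    ``gene, is_biomarker, is_disease_related`` — boolean flags from an
    external knowledge base, used by the biomarker filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ANNOTATION_COLUMNS",
    "INTENSITY_LABELS",
    "QUANTITY_LABELS",
    "SchemaError",
    "IntegrityError",
    "StainAnnotation",
    "MappingDef",
    "normalize_quantity",
    "read_annotations",
    "write_annotations",
    "records_to_frame",
    "frame_to_records",
    "validate_annotation_frame",
    "load_mapping_registry",
    "read_cohort",
    "read_gene_annotations",
]

INTENSITY_LABELS: tuple[str, ...] = ("Negative", "Weak", "Moderate", "Strong")
QUANTITY_LABELS: tuple[str, ...] = ("Negative", "Rare", "<25%", "25-75%", ">75%")

ANNOTATION_COLUMNS: tuple[str, ...] = (
    "antibody_id",
    "gene",
    "tissue",
    "cell_type",
    "sample_kind",
    "cancer_type",
    "patient_id",
    "intensity",
    "quantity",
)

MAPPING_COLUMNS: tuple[str, ...] = (
    "mapping_id",
    "cancer_type",
    "normal_tissue",
    "normal_cell_type",
)

# Alternate spellings of the middle quantity band seen in the wild (hyphen vs
# en dash, percent sign on either side, reversed order) are folded onto one
# canonical token at read time.
_QUANTITY_ALIASES: dict[str, str] = {
    "75%-25%": "25-75%",
    "75%–25%": "25-75%",
    "75-25%": "25-75%",
    "25%-75%": "25-75%",
    "25–75%": "25-75%",
    "25%–75%": "25-75%",
}


class SchemaError(ValueError):
    """A table violates the documented column/value schema."""


class IntegrityError(ValueError):
    """A table is well-formed but internally inconsistent (duplicates)."""


def normalize_quantity(label: str) -> str:
    """Return the canonical spelling of a quantity label.

    Unknown labels are returned unchanged; validation happens downstream.
    """
    label = label.strip()
    return _QUANTITY_ALIASES.get(label, label)


@dataclass(frozen=True)
class StainAnnotation:
    """One expert-curated IHC staining result for one antibody.

    Normal-tissue rows carry exactly one (intensity, quantity) pair per
    (antibody, tissue, cell type); cancer rows carry one pair per patient.
    """

    antibody_id: str
    gene: str
    tissue: str
    cell_type: str
    sample_kind: str  # "normal" | "cancer"
    cancer_type: str
    patient_id: str
    intensity: str
    quantity: str

    def __post_init__(self) -> None:
        if self.sample_kind not in ("normal", "cancer"):
            raise SchemaError(f"unknown sample_kind {self.sample_kind!r}")
        if self.intensity not in INTENSITY_LABELS:
            raise SchemaError(f"unknown intensity label {self.intensity!r}")
        q = normalize_quantity(self.quantity)
        if q not in QUANTITY_LABELS:
            raise SchemaError(f"unknown quantity label {self.quantity!r}")
        object.__setattr__(self, "quantity", q)
        if self.sample_kind == "normal":
            if self.cancer_type or self.patient_id:
                raise SchemaError(
                    f"normal record for {self.antibody_id!r} must leave "
                    "cancer_type and patient_id empty"
                )
        else:
            if not self.cancer_type or not self.patient_id:
                raise SchemaError(
                    f"cancer record for {self.antibody_id!r} must name "
                    "cancer_type and patient_id"
                )


@dataclass(frozen=True)
class MappingDef:
    """A cancer type paired with the normal tissue/cell type it is scored against."""

    mapping_id: str
    cancer_type: str
    normal_tissue: str
    normal_cell_type: str


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def validate_annotation_frame(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    """Validate an annotation table in DataFrame form; returns a clean copy.

    Quantity spellings are normalized, enum membership and the normal/cancer
    field constraints are enforced, and duplicate normal records for one
    (antibody, tissue, cell_type) raise :class:`IntegrityError`.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")
    df = df.loc[:, list(ANNOTATION_COLUMNS)].copy()
    df["quantity"] = df["quantity"].map(normalize_quantity)

    bad_kind = ~df["sample_kind"].isin(("normal", "cancer"))
    if bad_kind.any():
        row = df.index[bad_kind][0]
        raise SchemaError(
            f"{source} row {row}: unknown sample_kind {df.at[row, 'sample_kind']!r}"
        )
    bad_int = ~df["intensity"].isin(INTENSITY_LABELS)
    if bad_int.any():
        row = df.index[bad_int][0]
        raise SchemaError(
            f"{source} row {row}: unknown intensity label {df.at[row, 'intensity']!r}"
        )
    bad_q = ~df["quantity"].isin(QUANTITY_LABELS)
    if bad_q.any():
        row = df.index[bad_q][0]
        raise SchemaError(
            f"{source} row {row}: unknown quantity label {df.at[row, 'quantity']!r}"
        )

    is_normal = df["sample_kind"] == "normal"
    bad_normal = is_normal & ((df["cancer_type"] != "") | (df["patient_id"] != ""))
    if bad_normal.any():
        row = df.index[bad_normal][0]
        raise SchemaError(
            f"{source} row {row}: normal record must leave cancer_type and "
            "patient_id empty"
        )
    bad_cancer = ~is_normal & ((df["cancer_type"] == "") | (df["patient_id"] == ""))
    if bad_cancer.any():
        row = df.index[bad_cancer][0]
        raise SchemaError(
            f"{source} row {row}: cancer record must name cancer_type and patient_id"
        )

    normals = df[is_normal]
    dup = normals.duplicated(subset=["antibody_id", "tissue", "cell_type"])
    if dup.any():
        key = normals.loc[normals.index[dup][0], ["antibody_id", "tissue", "cell_type"]]
        raise IntegrityError(
            f"{source}: duplicate normal record for "
            f"({key['antibody_id']}, {key['tissue']}, {key['cell_type']}); "
            "a normal cell type has exactly one intensity/quantity pair"
        )
    return df


def read_annotations(path: str | Path) -> list[StainAnnotation]:
    """Load and validate an ``annotations.tsv`` file."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    df = validate_annotation_frame(df, source=str(path))
    records = frame_to_records(df)
    logger.info(
        "read %d annotations (%d antibodies) from %s",
        len(records),
        df["antibody_id"].nunique(),
        path,
    )
    return records


def records_to_frame(records: Iterable[StainAnnotation]) -> pd.DataFrame:
    rows = [
        (
            r.antibody_id,
            r.gene,
            r.tissue,
            r.cell_type,
            r.sample_kind,
            r.cancer_type,
            r.patient_id,
            r.intensity,
            r.quantity,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[StainAnnotation]:
    return [
        StainAnnotation(*row)
        for row in df.loc[:, list(ANNOTATION_COLUMNS)].itertuples(index=False)
    ]


def write_annotations(
    records: Iterable[StainAnnotation] | pd.DataFrame, path: str | Path
) -> None:
    """Write an annotation collection back to TSV (inverse of read_annotations)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def _default_registry_path():
    return resources.files("ihcscore").joinpath("data/mappings.tsv")


def load_mapping_registry(path: str | Path | None = None) -> list[MappingDef]:
    """Load a mapping registry; without a path, the packaged default.

    The packaged registry pairs each of 20 cancer types with one or more
    normal tissue/cell-type contexts, 27 mappings in total.  Ovarian cancer
    has no mapping (no normal-ovary staining available); hepatocellular
    carcinoma and cholangiocarcinoma are distinct cancer types.
    """
    if path is None:
        with resources.as_file(_default_registry_path()) as p:
            df = _read_tsv(p, MAPPING_COLUMNS)
    else:
        df = _read_tsv(path, MAPPING_COLUMNS)
    dup = df["mapping_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate mapping_id {df.loc[df.index[dup][0], 'mapping_id']!r}"
        )
    return [
        MappingDef(*row)
        for row in df.loc[:, list(MAPPING_COLUMNS)].itertuples(index=False)
    ]


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load a paired tumor/normal cohort fold-change table.

    Returns a DataFrame with columns ``gene, patient_id, fold_change``
    (fold_change as float > 0), one row per (gene, patient).
    """
    df = _read_tsv(path, ("gene", "patient_id", "fold_change"))
    try:
        df["fold_change"] = df["fold_change"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric fold_change ({exc})") from exc
    bad = ~(df["fold_change"] > 0)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(
            f"{path} row {row}: fold_change must be > 0, got "
            f"{df.at[row, 'fold_change']!r}"
        )
    dup = df.duplicated(subset=["gene", "patient_id"])
    if dup.any():
        row = df.index[dup][0]
        raise IntegrityError(
            f"{path} row {row}: duplicate (gene, patient) pair "
            f"({df.at[row, 'gene']}, {df.at[row, 'patient_id']})"
        )
    logger.info(
        "read cohort: %d genes x %d patients (%d values) from %s",
        df["gene"].nunique(),
        df["patient_id"].nunique(),
        len(df),
        path,
    )
    return df.loc[:, ["gene", "patient_id", "fold_change"]]


_BOOL_TOKENS = {
    "true": True, "false": False, "yes": True, "no": False, "1": True, "0": False,
}


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    """Load biomarker/disease flags per gene (external-knowledge stand-in)."""
    df = _read_tsv(path, ("gene", "is_biomarker", "is_disease_related"))
    dup = df["gene"].duplicated()
    if dup.any():
        raise IntegrityError(f"{path}: duplicate gene {df.loc[df.index[dup][0], 'gene']!r}")
    for col in ("is_biomarker", "is_disease_related"):
        vals = df[col].str.strip().str.lower().map(_BOOL_TOKENS)
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise SchemaError(
                f"{path} row {row}: {col} must be boolean, got {df.at[row, col]!r}"
            )
        df[col] = vals.astype(bool)
    return df.loc[:, ["gene", "is_biomarker", "is_disease_related"]]
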