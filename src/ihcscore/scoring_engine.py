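"""Antibody scoring from ordinal IHC annotations.

For an antibody and a mapping (a cancer type paired with a normal tissue/cell
type), the ordinal staining annotations are made numeric —

    Intensity  Strong/Moderate/Weak/Negative -> I = 3/2/1/0
    Quantity   >75% / 25-75% / <25% / Rare / Negative -> Q = 75/50/25/5/0

— and the expression level of one staining is I*Q, between 0 and 225.
``EiN`` is the single normal-cell level, ``EiC`` the mean level over the
patient samples of the cancer type, and ``ED = EiC - EiN`` the overexpression
signal.  Two rank statistics are then taken through the standard normal CDF
Phi:

* significance ``SG = Phi((ED - mu_g) / sigma_g)``, z-scoring the antibody's
  ED against all antibodies of the same mapping — its rank among antibodies;
* specificity ``SP = Phi((ED - mu_p) / sigma_p)``, z-scoring against the same
  antibody's EDs over all mappings — the mapping's rank among mappings.

The final ``score = EiC * SG * SP`` lies in [0, 225] and is high only for
proteins abundant in the cancer whose overexpression is both significant and
specific to it.  Means and standard deviations are population moments
(divide by N; configurable) over the non-missing cells only — untested
(antibody, mapping) pairs are excluded, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotations_io import (
    MappingDef,
    SchemaError,
    StainAnnotation,
    load_mapping_registry,
    records_to_frame,
    validate_annotation_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "INTENSITY_TO_I",
    "QUANTITY_TO_Q",
    "ScoringConfig",
    "UnscorableError",
    "EDMatrix",
    "intensity_to_numeric",
    "quantity_to_numeric",
    "expression_level",
    "expression_in_normal",
    "expression_in_cancer",
    "expression_difference",
    "build_ed_matrix",
    "significance",
    "specificity",
    "compute_scores",
    "write_scores",
    "read_scores",
]

INTENSITY_TO_I: dict[str, int] = {"Negative": 0, "Weak": 1, "Moderate": 2, "Strong": 3}
QUANTITY_TO_Q: dict[str, int] = {
    "Negative": 0,
    "Rare": 5,
    "<25%": 25,
    "25-75%": 50,
    ">75%": 75,
}

SCORE_COLUMNS = (
    "antibody_id",
    "gene",
    "mapping_id",
    "EiN",
    "EiC",
    "n_patients",
    "ED",
    "SG",
    "SP",
    "score",
    "rank",
)


class UnscorableError(ValueError):
    """The z-normalization axis has fewer than two tested cells."""


@dataclass(frozen=True)
class ScoringConfig:
    """Numerical conventions of the scoring step.

    ddof
        Delta degrees of freedom of the z-score normalizations; 0 (population
        standard deviation) by default, 1 for the sample convention.
    degenerate_value
        SG/SP assigned when a normalization axis has zero dispersion: an axis
        that cannot discriminate neither rewards nor punishes, so z = 0 and
        Phi(0) = 0.5.
    """

    ddof: int = 0
    degenerate_value: float = 0.5


def intensity_to_numeric(label: str) -> int:
    """Ordinal staining intensity -> I in {0, 1, 2, 3}."""
    try:
        return INTENSITY_TO_I[label]
    except KeyError:
        raise SchemaError(f"unknown intensity label {label!r}") from None


def quantity_to_numeric(label: str) -> int:
    """Ordinal stained-cell fraction -> Q in {0, 5, 25, 50, 75}."""
    try:
        return QUANTITY_TO_Q[label]
    except KeyError:
        raise SchemaError(f"unknown quantity label {label!r}") from None


def expression_level(intensity: str, quantity: str) -> int:
    """I*Q of one staining annotation, in [0, 225]."""
    return intensity_to_numeric(intensity) * quantity_to_numeric(quantity)


def expression_in_normal(intensity: str, quantity: str) -> float:
    """EiN: expression in the mapped normal cell type (single annotation)."""
    return float(expression_level(intensity, quantity))


def expression_in_cancer(
    pairs: Sequence[tuple[str, str]]
) -> tuple[float, int]:
    """EiC: mean I*Q over the patient samples of one cancer type.

    Returns ``(EiC, n_patients)``; raises on an empty list (the antibody was
    not tested in this cancer).
    """
    if len(pairs) == 0:
        raise ValueError("antibody not tested in this cancer: no patient annotations")
    levels = [expression_level(i, q) for i, q in pairs]
    return float(np.mean(levels)), len(levels)


def expression_difference(eic: float | None, ein: float | None) -> float | None:
    """ED = EiC - EiN; None (missing) when either side is undefined."""
    if eic is None or ein is None:
        return None
    return eic - ein


class EDMatrix:
    """Antibody x mapping matrices of EiN, EiC, n_patients and ED.

    A cell is non-missing only when the antibody has both a normal record
    matching the mapping's tissue and cell type and at least one cancer
    record of the mapping's cancer type.  Column (per-mapping) and row
    (per-antibody) moments are cached and computed over non-missing cells.
    """

    def __init__(
        self,
        ein: pd.DataFrame,
        eic: pd.DataFrame,
        n_patients: pd.DataFrame,
        genes: pd.Series,
        config: ScoringConfig | None = None,
    ) -> None:
        self.ein = ein
        self.eic = eic
        self.n_patients = n_patients
        self.ed = eic - ein
        self.genes = genes
        self.config = config or ScoringConfig()
        for frame in (self.ein, self.eic, self.n_patients, self.ed):
            frame.index.name = "antibody_id"
            frame.columns.name = "mapping_id"

    @property
    def antibody_ids(self) -> list[str]:
        return list(self.ed.index)

    @property
    def mapping_ids(self) -> list[str]:
        return list(self.ed.columns)

    @cached_property
    def col_count(self) -> pd.Series:
        return self.ed.notna().sum(axis=0)

    @cached_property
    def col_mean(self) -> pd.Series:
        return self.ed.mean(axis=0)

    @cached_property
    def col_std(self) -> pd.Series:
        return self.ed.std(axis=0, ddof=self.config.ddof)

    @cached_property
    def row_count(self) -> pd.Series:
        return self.ed.notna().sum(axis=1)

    @cached_property
    def row_mean(self) -> pd.Series:
        return self.ed.mean(axis=1)

    @cached_property
    def row_std(self) -> pd.Series:
        return self.ed.std(axis=1, ddof=self.config.ddof)


def _as_frame(annotations) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        return validate_annotation_frame(annotations)
    # StainAnnotation instances validate themselves at construction
    return records_to_frame(list(annotations))


def build_ed_matrix(
    annotations: Iterable[StainAnnotation] | pd.DataFrame,
    registry: Sequence[MappingDef] | None = None,
    config: ScoringConfig | None = None,
) -> EDMatrix:
    """Assemble the antibody x mapping expression matrices (system initialization).

    This step is performed once; EiN, EiC and ED stay fixed while every
    antibody is scored against them.
    """
    if registry is None:
        registry = load_mapping_registry()
    if len(registry) == 0:
        raise ValueError("mapping registry is empty")
    df = _as_frame(annotations)
    df = df.assign(
        level=df["intensity"].map(INTENSITY_TO_I) * df["quantity"].map(QUANTITY_TO_Q)
    )

    antibodies = sorted(df["antibody_id"].unique())
    mapping_ids = [m.mapping_id for m in registry]
    genes = df.groupby("antibody_id")["gene"].first().reindex(antibodies)

    normals = df[df["sample_kind"] == "normal"]
    cancers = df[df["sample_kind"] == "cancer"]
    eic_by_ct: dict[str, pd.DataFrame] = {}
    if len(cancers):
        grouped = cancers.groupby(["cancer_type", "antibody_id"])["level"].agg(
            ["mean", "size"]
        )
        eic_by_ct = {ct: sub.droplevel(0) for ct, sub in grouped.groupby(level=0)}
    norm_by_context: dict[tuple[str, str], pd.Series] = {}
    if len(normals):
        for (tissue, cell), sub in normals.groupby(["tissue", "cell_type"]):
            norm_by_context[(tissue, cell)] = sub.set_index("antibody_id")["level"]

    empty = pd.Series(dtype=float)
    ein_cols, eic_cols, n_cols = {}, {}, {}
    for m in registry:
        ein_cols[m.mapping_id] = (
            norm_by_context.get((m.normal_tissue, m.normal_cell_type), empty)
            .reindex(antibodies)
            .astype(float)
        )
        sub = eic_by_ct.get(m.cancer_type)
        if sub is None:
            eic_cols[m.mapping_id] = empty.reindex(antibodies)
            n_cols[m.mapping_id] = empty.reindex(antibodies)
        else:
            eic_cols[m.mapping_id] = sub["mean"].reindex(antibodies)
            n_cols[m.mapping_id] = sub["size"].reindex(antibodies)

    ein = pd.DataFrame(ein_cols, index=antibodies, columns=mapping_ids)
    eic = pd.DataFrame(eic_cols, index=antibodies, columns=mapping_ids)
    npat = pd.DataFrame(n_cols, index=antibodies, columns=mapping_ids)
    # both sides must exist for a cell to count as tested
    mask = ein.notna() & eic.notna()
    ein, eic, npat = ein.where(mask), eic.where(mask), npat.where(mask)
    for frame in (ein, eic, npat):
        frame.index.name = "antibody_id"
        frame.columns.name = "mapping_id"
    logger.info(
        "ED matrix: %d antibodies x %d mappings, %d tested cells",
        len(antibodies),
        len(mapping_ids),
        int(mask.values.sum()),
    )
    return EDMatrix(ein, eic, npat, genes, config)


def _cell_ed(matrix: EDMatrix, antibody_id: str, mapping_id: str) -> float:
    try:
        ed = matrix.ed.at[antibody_id, mapping_id]
    except KeyError:
        raise KeyError(f"unknown antibody/mapping ({antibody_id}, {mapping_id})")
    if pd.isna(ed):
        raise ValueError(
            f"({antibody_id}, {mapping_id}) was not tested; no ED available"
        )
    return float(ed)


def significance(matrix: EDMatrix, antibody_id: str, mapping_id: str) -> float:
    """SG: Phi of the ED z-scored within the mapping's column."""
    ed = _cell_ed(matrix, antibody_id, mapping_id)
    if matrix.col_count[mapping_id] < 2:
        raise UnscorableError(
            f"mapping {mapping_id!r} has fewer than two tested antibodies"
        )
    sd = matrix.col_std[mapping_id]
    z = 0.0 if sd == 0 else (ed - matrix.col_mean[mapping_id]) / sd
    return float(norm.cdf(z)) if sd != 0 else matrix.config.degenerate_value


def specificity(matrix: EDMatrix, antibody_id: str, mapping_id: str) -> float:
    """SP: Phi of the ED z-scored within the antibody's row."""
    ed = _cell_ed(matrix, antibody_id, mapping_id)
    if matrix.row_count[antibody_id] < 2:
        raise UnscorableError(
            f"antibody {antibody_id!r} is tested on fewer than two mappings"
        )
    sd = matrix.row_std[antibody_id]
    z = 0.0 if sd == 0 else (ed - matrix.row_mean[antibody_id]) / sd
    return float(norm.cdf(z)) if sd != 0 else matrix.config.degenerate_value


def _phi_frame(z: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(norm.cdf(z.to_numpy(dtype=float)), index=z.index, columns=z.columns)


def compute_scores(
    annotations: Iterable[StainAnnotation] | pd.DataFrame | EDMatrix,
    registry: Sequence[MappingDef] | None = None,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Score every scorable (antibody, mapping) pair.

    Returns a long-form DataFrame with columns ``antibody_id, gene,
    mapping_id, EiN, EiC, n_patients, ED, SG, SP, score, rank``; ``rank``
    orders antibodies within each mapping by descending score (ties broken
    by ascending antibody id), starting at 1.  Cells whose column or row has
    fewer than two tested entries are omitted (logged).
    """
    if isinstance(annotations, EDMatrix):
        matrix = annotations
        if config is not None:
            matrix = EDMatrix(
                matrix.ein, matrix.eic, matrix.n_patients, matrix.genes, config
            )
    else:
        matrix = build_ed_matrix(annotations, registry, config)
    cfg = matrix.config
    ed = matrix.ed

    col_sd = matrix.col_std
    zg = ed.sub(matrix.col_mean, axis=1).div(col_sd.where(col_sd > 0), axis=1)
    degenerate_cols = (col_sd == 0) & (matrix.col_count >= 2)
    if degenerate_cols.any():
        zg.loc[:, degenerate_cols] = zg.loc[:, degenerate_cols].where(
            ed.loc[:, degenerate_cols].isna(), 0.0
        )
    zg.loc[:, matrix.col_count < 2] = np.nan

    row_sd = matrix.row_std
    zp = ed.sub(matrix.row_mean, axis=0).div(row_sd.where(row_sd > 0), axis=0)
    degenerate_rows = (row_sd == 0) & (matrix.row_count >= 2)
    if degenerate_rows.any():
        zp.loc[degenerate_rows, :] = zp.loc[degenerate_rows, :].where(
            ed.loc[degenerate_rows, :].isna(), 0.0
        )
    zp.loc[matrix.row_count < 2, :] = np.nan

    sg = _phi_frame(zg)
    sp = _phi_frame(zp)
    score = matrix.eic * sg * sp

    parts = {
        "EiN": matrix.ein,
        "EiC": matrix.eic,
        "n_patients": matrix.n_patients,
        "ED": ed,
        "SG": sg,
        "SP": sp,
        "score": score,
    }
    long = pd.concat(
        {name: frame.stack(future_stack=True) for name, frame in parts.items()}, axis=1
    ).reset_index()
    long = long.dropna(subset=["ED"])
    n_tested = len(long)
    long = long.dropna(subset=["SG", "SP"])
    if len(long) < n_tested:
        logger.info(
            "omitted %d tested cells with an unscorable row or column "
            "(fewer than two tested entries on the axis)",
            n_tested - len(long),
        )
    long["gene"] = long["antibody_id"].map(matrix.genes)
    long["n_patients"] = long["n_patients"].astype(int)
    long = long.sort_values(
        ["mapping_id", "score", "antibody_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    long["rank"] = long.groupby("mapping_id", sort=False).cumcount() + 1
    return long.loc[:, list(SCORE_COLUMNS)]


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table to TSV with floats at 6 significant digits."""
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df
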