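"""Candidate filtering: three rules and their eight on/off combinations.

Given a score table, a paired tumor/normal cohort of per-patient fold
changes, and optional biomarker/disease flags per gene, a gene survives

* Rule 1 when any of its antibodies scores at least ``score_threshold``
  (default 100) in any target mapping (e.g. both colorectal mappings);
* Rule 2 when its mean fold change over the cohort is at least
  ``fc_threshold`` (default 2);
* Rule 3 when its fold change reaches ``fc_threshold`` in strictly more
  than ``patient_count_threshold`` patients (default > 14, i.e. the
  majority of a 28-patient cohort).

Combination 1 applies no rules and defines the reference population: all
cohort genes indexed in the score table.  Combinations 2-8 apply Rule 1,
Rule 2, Rule 3, Rules 1+2, 1+3, 2+3 and 1+2+3 respectively; each report
carries survivor counts, biomarker/disease annotation counts, and
proportions both within the filtered set and against the Combination-1
population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COMBINATION_RULES",
    "FilterConfig",
    "FilterReport",
    "rule1_score",
    "rule2_mean_fc",
    "rule3_patient_count",
    "apply_combination",
    "write_filter_report",
    "write_candidates",
]

#: combination id -> set of active rules
COMBINATION_RULES: Mapping[int, frozenset[int]] = {
    1: frozenset(),
    2: frozenset({1}),
    3: frozenset({2}),
    4: frozenset({3}),
    5: frozenset({1, 2}),
    6: frozenset({1, 3}),
    7: frozenset({2, 3}),
    8: frozenset({1, 2, 3}),
}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering rules.

    Score and fold-change cuts are inclusive (>=); the patient count is a
    strict majority cut (> patient_count_threshold, i.e. at least 15 of a
    28-patient cohort at the defaults).
    """

    score_threshold: float = 100.0
    fc_threshold: float = 2.0
    patient_count_threshold: int = 14
    target_mappings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.score_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.patient_count_threshold < 0:
            raise ValueError("patient_count_threshold must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    """Outcome of one rule combination."""

    combination_id: int
    rules_applied: frozenset[int]
    n_population: int
    n_filtered: int
    n_biomarker_annotated: int
    n_disease_annotated: int
    #: % of the filtered set carrying each annotation
    prop_biomarker_of_filtered: float
    prop_disease_of_filtered: float
    #: % of the Combination-1 population (and its annotated subsets) retained
    prop_filtered_of_population: float
    prop_biomarker_of_population: float
    prop_disease_of_population: float
    #: per-gene evidence for the survivors
    genes: pd.DataFrame = field(repr=False)


def _gene_best_scores(scores: pd.DataFrame, config: FilterConfig) -> pd.Series:
    mappings = config.target_mappings or tuple(scores["mapping_id"].unique())
    sub = scores[scores["mapping_id"].isin(mappings)]
    return sub.groupby("gene")["score"].max()


def rule1_score(gene: str, scores: pd.DataFrame, config: FilterConfig) -> bool:
    """Any antibody of the gene scores >= threshold in any target mapping."""
    if not config.target_mappings:
        raise ValueError("rule 1 requires target_mappings in the FilterConfig")
    best = _gene_best_scores(scores, config)
    if gene not in best.index:
        return False  # gene not indexed in the score table
    return bool(best[gene] >= config.score_threshold)


def rule2_mean_fc(gene: str, cohort: pd.DataFrame, config: FilterConfig) -> bool:
    """Mean fold change over the available cohort patients >= threshold."""
    fc = cohort.loc[cohort["gene"] == gene, "fold_change"]
    if fc.empty:
        return False
    return bool(fc.mean() >= config.fc_threshold)


def rule3_patient_count(gene: str, cohort: pd.DataFrame, config: FilterConfig) -> bool:
    """Fold change >= threshold in strictly more than the patient-count cut."""
    fc = cohort.loc[cohort["gene"] == gene, "fold_change"]
    if fc.empty:
        return False
    return bool((fc >= config.fc_threshold).sum() > config.patient_count_threshold)


def apply_combination(
    combination_id: int,
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    gene_annotations: pd.DataFrame | None = None,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Apply one rule combination and report counts and proportions.

    The candidate population is restricted to cohort genes indexed in the
    score table (the Combination-1 population); survivors are the genes
    passing the conjunction of active rules.
    """
    if combination_id not in COMBINATION_RULES:
        raise ValueError(f"unknown combination id {combination_id!r} (must be 1-8)")
    config = config or FilterConfig()
    rules = COMBINATION_RULES[combination_id]
    if 1 in rules and not config.target_mappings:
        raise ValueError("rule 1 requires target_mappings in the FilterConfig")

    indexed = set(scores["gene"].unique())
    cohort_genes = cohort["gene"].unique()
    population = sorted(g for g in cohort_genes if g in indexed)
    logger.info(
        "combination %d: population %d of %d cohort genes indexed in the score table",
        combination_id,
        len(population),
        len(cohort_genes),
    )

    by_gene = cohort[cohort["gene"].isin(population)].groupby("gene")["fold_change"]
    mean_fc = by_gene.mean()
    n_qual = by_gene.apply(lambda fc: int((fc >= config.fc_threshold).sum()))
    best = _gene_best_scores(scores, config).reindex(population)

    table = pd.DataFrame(
        {
            "gene": population,
            "best_score": best.to_numpy(dtype=float),
            "mean_fold_change": mean_fc.reindex(population).to_numpy(dtype=float),
            "n_qualifying_patients": n_qual.reindex(population)
            .fillna(0)
            .to_numpy(dtype=int),
        }
    )
    if gene_annotations is not None:
        ann = gene_annotations.set_index("gene")
        table["is_biomarker"] = (
            ann["is_biomarker"].reindex(table["gene"]).fillna(False).to_numpy(dtype=bool)
        )
        table["is_disease_related"] = (
            ann["is_disease_related"]
            .reindex(table["gene"])
            .fillna(False)
            .to_numpy(dtype=bool)
        )
    else:
        table["is_biomarker"] = False
        table["is_disease_related"] = False

    keep = np.ones(len(table), dtype=bool)
    if 1 in rules:
        keep &= (table["best_score"] >= config.score_threshold).fillna(False).to_numpy()
    if 2 in rules:
        keep &= (table["mean_fold_change"] >= config.fc_threshold).to_numpy()
    if 3 in rules:
        keep &= (table["n_qualifying_patients"] > config.patient_count_threshold).to_numpy()

    survivors = (
        table[keep]
        .sort_values(["best_score", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    n_filtered = len(survivors)
    n_bio = int(survivors["is_biomarker"].sum())
    n_dis = int(survivors["is_disease_related"].sum())
    pop_bio = int(table["is_biomarker"].sum())
    pop_dis = int(table["is_disease_related"].sum())

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    return FilterReport(
        combination_id=combination_id,
        rules_applied=rules,
        n_population=len(population),
        n_filtered=n_filtered,
        n_biomarker_annotated=n_bio,
        n_disease_annotated=n_dis,
        prop_biomarker_of_filtered=pct(n_bio, n_filtered),
        prop_disease_of_filtered=pct(n_dis, n_filtered),
        prop_filtered_of_population=pct(n_filtered, len(population)),
        prop_biomarker_of_population=pct(n_bio, pop_bio),
        prop_disease_of_population=pct(n_dis, pop_dis),
        genes=survivors,
    )


def write_filter_report(reports: Sequence[FilterReport], path: str | Path) -> None:
    """Summarize one or more combination reports as a TSV table."""
    rows = []
    for r in reports:
        rows.append(
            {
                "combination_id": r.combination_id,
                "rules": "+".join(str(x) for x in sorted(r.rules_applied)) or "none",
                "n_population": r.n_population,
                "n_filtered": r.n_filtered,
                "n_biomarker_annotated": r.n_biomarker_annotated,
                "n_disease_annotated": r.n_disease_annotated,
                "prop_biomarker_of_filtered": r.prop_biomarker_of_filtered,
                "prop_disease_of_filtered": r.prop_disease_of_filtered,
                "prop_filtered_of_population": r.prop_filtered_of_population,
                "prop_biomarker_of_population": r.prop_biomarker_of_population,
                "prop_disease_of_population": r.prop_disease_of_population,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4g")


def write_candidates(report: FilterReport, path: str | Path) -> None:
    """Write the surviving genes with their per-gene evidence."""
    report.genes.to_csv(path, sep="\t", index=False, float_format="%.6g")
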