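"""Synthetic IHC annotation tables and paired-cohort fold changes.

Ordinal annotations are generated from a latent-Gaussian threshold model:
each (antibody, cancer type) has a true latent base level drawn from the
baseline distribution, shared between the cancer and its mapped normal
contexts (a tumor and the tissue it arises from express the same protein at
a related level); each mapping's normal context deviates from that base by
a small tissue effect.  The single normal staining and the per-patient
cancer stainings add observation noise; cancer samples add a small global
down-shift (most proteins trend down in tumors) plus, for planted markers,
a positive mapping-specific effect.  Latent values are cut into the four
intensity and five quantity labels, so inverting the ordinal-to-numeric
transforms recovers the intended I*Q regime.  Cancer samples are drawn per
cancer type, as in the real resource where sibling mappings (e.g. two
normal contexts of one cancer) share patient cohorts.

The cohort generator draws per-patient log2 fold changes from a normal
distribution: null genes centred at 0, planted up-regulated genes centred
high enough that both the mean-fold-change rule and the
majority-of-patients rule are expected to pass.

Every draw descends from a single seed; each antibody uses a sub-stream
derived from (seed, antibody index), so outputs are reproducible and stable
under antibody subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations_io import (
    INTENSITY_LABELS,
    QUANTITY_LABELS,
    MappingDef,
    load_mapping_registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedMarker",
    "CohortConfig",
    "SimConfig",
    "independent_registry",
    "plant_markers",
    "simulate_annotations",
    "simulate_cohort",
    "cohort_from_summary",
]


@dataclass(frozen=True)
class PlantedMarker:
    """A ground-truth overexpressed (antibody, mapping) pair.

    ``effect_size`` is the latent-scale shift added to that mapping's cancer
    samples, in units of the baseline latent SD when ``baseline_sd`` is 1.
    """

    antibody_id: str
    mapping_id: str
    effect_size: float


@dataclass(frozen=True)
class CohortConfig:
    """Shape and effect sizes of the simulated fold-change cohort.

    Defaults emulate a 28-patient paired tumor/normal cohort; null genes
    have log2 fold changes ~ N(0, 0.5), planted genes ~ N(2, 0.5) so the
    expected mean fold change is >= 2 and the expected number of patients
    with fold change >= 2 is well above half the cohort.
    """

    n_genes: int = 100
    n_patients: int = 28
    n_planted: int = 0
    null_log2fc_mean: float = 0.0
    null_log2fc_sd: float = 0.5
    planted_log2fc_mean: float = 2.0
    planted_log2fc_sd: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the annotation simulator.

    n_patients_per_cancer
        12 by default — each antibody is evaluated on at most 12 patients
        per cancer type.
    baseline_mean, baseline_sd
        Latent base-level distribution across (antibody, cancer type) pairs;
        the base level is shared by the cancer and its mapped normal
        contexts.
    tissue_sd
        SD of the per-mapping deviation of a normal context from the cancer
        type's base level (different normal tissues of one cancer express a
        protein at related but not identical levels).
    sample_noise_sd
        Observation noise of one staining around the true level.
    cancer_shift
        Global latent shift of cancer samples (negative by default: the
        bulk of proteins trends down in tumors, so population ED means are
        mildly negative while planted markers stand out positive).
    intensity_cuts, quantity_cuts
        Strictly increasing latent thresholds defining the ordinal labels
        (3 cuts -> 4 intensity labels; 4 cuts -> 5 quantity labels),
        roughly quartile-like on the latent marginal.
    missing_rate
        Probability that an (antibody, mapping) pair is untested.
    """

    n_antibodies: int = 200
    registry: tuple[MappingDef, ...] | None = None  # None -> packaged registry
    n_patients_per_cancer: int = 12
    planted_markers: tuple[PlantedMarker, ...] = ()
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    tissue_sd: float = 0.3
    sample_noise_sd: float = 0.5
    cancer_shift: float = -0.2
    intensity_cuts: tuple[float, ...] = (-1.0, 0.0, 1.0)
    quantity_cuts: tuple[float, ...] = (-1.5, -0.75, 0.0, 0.75)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        for cuts, n_labels, name in (
            (self.intensity_cuts, len(INTENSITY_LABELS), "intensity_cuts"),
            (self.quantity_cuts, len(QUANTITY_LABELS), "quantity_cuts"),
        ):
            if len(cuts) != n_labels - 1:
                raise ValueError(f"{name} needs {n_labels - 1} thresholds")
            if any(a >= b for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{name} must be strictly increasing")


def independent_registry(n_mappings: int = 27) -> list[MappingDef]:
    """A registry of mappings with one distinct synthetic cancer type each.

    Unlike the packaged registry — where sibling mappings of one cancer
    type share patient cohorts — every mapping here has its own cancer
    type, tissue and cell type, so mapping columns are statistically
    independent.  Used for planted-marker recovery and specificity studies.
    """
    return [
        MappingDef(
            mapping_id=f"Sim-{i:02d}",
            cancer_type=f"Simulated cancer {i:02d}",
            normal_tissue=f"sim tissue {i:02d}",
            normal_cell_type="glandular cells",
        )
        for i in range(1, n_mappings + 1)
    ]


def antibody_ids(n: int) -> list[str]:
    return [f"AB{i:05d}" for i in range(n)]


def plant_markers(
    n_antibodies: int,
    registry: Sequence[MappingDef],
    n_per_mapping: int,
    effect_size: float,
) -> list[PlantedMarker]:
    """Assign the first mappings*n_per_mapping antibodies as planted markers.

    Each antibody is planted for exactly one mapping, round-robin over the
    registry, so planted sets of different mappings are disjoint.
    """
    ids = antibody_ids(n_antibodies)
    needed = n_per_mapping * len(registry)
    if needed > n_antibodies:
        raise ValueError(
            f"cannot plant {n_per_mapping} markers for {len(registry)} mappings "
            f"with only {n_antibodies} antibodies"
        )
    markers = []
    i = 0
    for _ in range(n_per_mapping):
        for m in registry:
            markers.append(PlantedMarker(ids[i], m.mapping_id, effect_size))
            i += 1
    return markers


def _discretize(latent: np.ndarray, cuts: Sequence[float], labels: Sequence[str]):
    idx = np.searchsorted(np.asarray(cuts), latent, side="right")
    return np.asarray(labels, dtype=object)[idx]


def simulate_annotations(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an annotation table plus its ground truth.

    Returns ``(annotations, truth)``: ``annotations`` in the documented
    ``annotations.tsv`` schema (one normal record per tested (antibody,
    mapping) and ``n_patients_per_cancer`` cancer records per active
    (antibody, cancer type)); ``truth`` lists the planted markers
    (``antibody_id, mapping_id, effect_size``).
    """
    registry = list(config.registry) if config.registry else load_mapping_registry()
    mapping_ids = [m.mapping_id for m in registry]
    cancer_types = list(dict.fromkeys(m.cancer_type for m in registry))
    ct_index = {ct: i for i, ct in enumerate(cancer_types)}
    ct_of_mapping = np.array([ct_index[m.cancer_type] for m in registry])
    tissues = np.array([m.normal_tissue for m in registry], dtype=object)
    cells = np.array([m.normal_cell_type for m in registry], dtype=object)
    ct_names = np.array(cancer_types, dtype=object)

    ids = antibody_ids(config.n_antibodies)
    id_set = set(ids)
    mapping_set = set(mapping_ids)
    planted: dict[str, list[tuple[int, float]]] = {}
    for marker in config.planted_markers:
        if marker.mapping_id not in mapping_set:
            raise ValueError(
                f"planted marker references unknown mapping {marker.mapping_id!r}"
            )
        if marker.antibody_id not in id_set:
            raise ValueError(
                f"planted marker references unknown antibody {marker.antibody_id!r}"
            )
        planted.setdefault(marker.antibody_id, []).append(
            (mapping_ids.index(marker.mapping_id), marker.effect_size)
        )

    n_map = len(registry)
    n_ct = len(cancer_types)
    n_pat = config.n_patients_per_cancer
    patient_labels = np.array([f"pt{p + 1:02d}" for p in range(n_pat)], dtype=object)

    cols: dict[str, list[np.ndarray]] = {
        "antibody_id": [], "gene": [], "tissue": [], "cell_type": [],
        "sample_kind": [], "cancer_type": [], "patient_id": [], "latent": [],
    }

    def emit(ab, gene, tissue, cell, kind, ct, pid, latent):
        n = len(latent)
        cols["antibody_id"].append(np.full(n, ab, dtype=object))
        cols["gene"].append(np.full(n, gene, dtype=object))
        cols["tissue"].append(np.asarray(tissue, dtype=object))
        cols["cell_type"].append(np.asarray(cell, dtype=object))
        cols["sample_kind"].append(np.full(n, kind, dtype=object))
        cols["cancer_type"].append(np.asarray(ct, dtype=object))
        cols["patient_id"].append(np.asarray(pid, dtype=object))
        cols["latent"].append(np.asarray(latent, dtype=float))

    for i, ab in enumerate(ids):
        rng = np.random.default_rng([config.seed, i])
        mu_ct = config.baseline_mean + config.baseline_sd * rng.standard_normal(n_ct)
        effect_ct = np.zeros(n_ct)
        for m_idx, eff in planted.get(ab, ()):
            ct = ct_of_mapping[m_idx]
            # markers are tissue-specific: low (but not floor) normal
            # expression with strong cancer staining — at either end of the
            # bounded ordinal scale the ED would saturate away
            mu_ct[ct] = config.baseline_mean - config.baseline_sd * rng.uniform(
                0.0, 1.0
            )
            effect_ct[ct] += eff
        # normal contexts deviate from the cancer type's shared base level
        mu_map = mu_ct[ct_of_mapping] + config.tissue_sd * rng.standard_normal(n_map)
        tested = rng.random(n_map) >= config.missing_rate
        normal_latent = mu_map + config.sample_noise_sd * rng.standard_normal(n_map)
        cancer_latent = (
            mu_ct[:, None]
            + config.cancer_shift
            + effect_ct[:, None]
            + config.sample_noise_sd * rng.standard_normal((n_ct, n_pat))
        )

        gene = f"GENE{i:05d}"
        t_idx = np.flatnonzero(tested)
        if t_idx.size:
            emit(
                ab, gene, tissues[t_idx], cells[t_idx], "normal",
                np.full(t_idx.size, "", dtype=object),
                np.full(t_idx.size, "", dtype=object),
                normal_latent[t_idx],
            )
        active_ct = np.unique(ct_of_mapping[t_idx]) if t_idx.size else np.array([], int)
        if active_ct.size:
            n_rows = active_ct.size * n_pat
            emit(
                ab, gene,
                np.repeat(ct_names[active_ct], n_pat),
                np.full(n_rows, "", dtype=object),
                "cancer",
                np.repeat(ct_names[active_ct], n_pat),
                np.tile(patient_labels, active_ct.size),
                cancer_latent[active_ct, :].ravel(),
            )

    data = {k: np.concatenate(v) if v else np.array([], dtype=object) for k, v in cols.items()}
    latent = data.pop("latent")
    annotations = pd.DataFrame(data)
    annotations["intensity"] = _discretize(latent, config.intensity_cuts, INTENSITY_LABELS)
    annotations["quantity"] = _discretize(latent, config.quantity_cuts, QUANTITY_LABELS)
    annotations = annotations.loc[
        :,
        [
            "antibody_id", "gene", "tissue", "cell_type", "sample_kind",
            "cancer_type", "patient_id", "intensity", "quantity",
        ],
    ]
    truth = pd.DataFrame(
        [(m.antibody_id, m.mapping_id, m.effect_size) for m in config.planted_markers],
        columns=["antibody_id", "mapping_id", "effect_size"],
    )
    logger.info(
        "simulated %d annotation records for %d antibodies (%d planted markers)",
        len(annotations),
        config.n_antibodies,
        len(truth),
    )
    return annotations, truth


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a fold-change cohort table plus its ground truth.

    Gene names follow the annotation simulator (``GENE00000``, ...), so a
    cohort simulated with the same ``n_genes`` links to a simulated score
    table gene-for-gene.  The first ``n_planted`` genes are up-regulated.
    """
    # fixed sub-stream tag so the cohort never shares draws with antibody streams
    rng = np.random.default_rng([config.seed, 0xC0C0])
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    is_planted = np.arange(config.n_genes) < config.n_planted
    mean = np.where(is_planted, config.planted_log2fc_mean, config.null_log2fc_mean)
    sd = np.where(is_planted, config.planted_log2fc_sd, config.null_log2fc_sd)
    log2fc = mean[:, None] + sd[:, None] * rng.standard_normal(
        (config.n_genes, config.n_patients)
    )
    patients = [f"pt{p + 1:02d}" for p in range(config.n_patients)]
    cohort = pd.DataFrame(
        {
            "gene": np.repeat(genes, config.n_patients),
            "patient_id": np.tile(patients, config.n_genes),
            "fold_change": np.exp2(log2fc).ravel(),
        }
    )
    truth = pd.DataFrame({"gene": genes, "is_planted": is_planted})
    return cohort, truth


def cohort_from_summary(
    summaries: Sequence[tuple[str, float, int]],
    n_patients: int = 28,
    fc_threshold: float = 2.0,
    baseline: float = 1.0,
) -> pd.DataFrame:
    """Deterministic cohort with prescribed per-gene mean FC and patient count.

    Each entry ``(gene, mean_fc, n_qualifying)`` yields ``n_qualifying``
    patients at one common fold change >= ``fc_threshold`` and the rest at
    ``baseline``, chosen so the gene's mean fold change equals ``mean_fc``
    exactly.  Useful for reconstructing published per-gene summaries as
    patient-level input.
    """
    rows = []
    patients = [f"pt{p + 1:02d}" for p in range(n_patients)]
    for gene, mean_fc, n_qual in summaries:
        if not 0 < n_qual <= n_patients:
            raise ValueError(f"{gene}: n_qualifying must be in 1..{n_patients}")
        high = (mean_fc * n_patients - (n_patients - n_qual) * baseline) / n_qual
        if high < fc_threshold:
            raise ValueError(
                f"{gene}: mean {mean_fc} with {n_qual} qualifying patients is "
                f"not realizable above fold change {fc_threshold}"
            )
        values = [high] * n_qual + [baseline] * (n_patients - n_qual)
        rows.extend((gene, p, v) for p, v in zip(patients, values))
    return pd.DataFrame(rows, columns=["gene", "patient_id", "fold_change"])
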