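from importlib import resources

import pandas as pd
import pytest

import ihcscore as ihc


@pytest.fixture(scope="session")
def registry():
    """The packaged cancer<->normal mapping registry."""
    return ihc.load_mapping_registry()


@pytest.fixture(scope="session")
def breast_records():
    """The packaged breast worked-example records (1 normal + 12 patients)."""
    with resources.as_file(
        resources.files("ihcscore").joinpath("data/hpa034966_breast.tsv")
    ) as path:
        return ihc.read_annotations(path)


@pytest.fixture(scope="session")
def sim_registry():
    """27 mappings with one distinct synthetic cancer type each."""
    return ihc.independent_registry(27)


@pytest.fixture(scope="session")
def planted_sim(sim_registry):
    """A 300-antibody simulation with 2 planted markers per mapping (effect 3 SD).

    Returns (annotations, markers, scores).
    """
    markers = ihc.plant_markers(300, sim_registry, 2, 3.0)
    config = ihc.SimConfig(
        n_antibodies=300,
        registry=tuple(sim_registry),
        planted_markers=tuple(markers),
        seed=1,
    )
    annotations, _ = ihc.simulate_annotations(config)
    scores = ihc.compute_scores(annotations, sim_registry)
    return annotations, markers, scores


# Published per-gene evidence of the four colorectal-cancer candidates that
# survive all three rules: (gene, mean fold change, qualifying patients,
# best antibody score, biomarker flag).
TABLE4_ROWS = [
    ("CEACAM5", 6.41, 24, 200.5, True),
    ("CEACAM6", 4.32, 21, 155.2, True),
    ("ANXA4", 2.07, 15, 138.84, False),
    ("CAMP", 4.29, 20, 132.92, True),
]


def candidate_inputs(rows=TABLE4_ROWS, anxa4_patients=None):
    """Score table, cohort and gene flags reconstructed from per-gene summaries."""
    rows = [
        (g, fc, anxa4_patients if (g == "ANXA4" and anxa4_patients) else n, s, b)
        for g, fc, n, s, b in rows
    ]
    scores = pd.DataFrame(
        {
            "antibody_id": [f"AB-{g}" for g, *_ in rows],
            "gene": [g for g, *_ in rows],
            "mapping_id": "Colorectal-A",
            "score": [s for *_, s, _ in rows],
        }
    )
    cohort = ihc.cohort_from_summary(
        [(g, fc, n) for g, fc, n, _, _ in rows], n_patients=28
    )
    flags = pd.DataFrame(
        {
            "gene": [g for g, *_ in rows],
            "is_biomarker": [b for *_, b in rows],
            "is_disease_related": True,
        }
    )
    return scores, cohort, flags


@pytest.fixture()
def table4_inputs():
    return candidate_inputs()
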