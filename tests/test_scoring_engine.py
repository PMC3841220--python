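import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ihcscore as ihc
from ihcscore.scoring_engine import EDMatrix, ScoringConfig
from oracles import normal_cdf_series, population_sd


class TestOrdinalTransforms:
    @pytest.mark.parametrize(
        "label, value",
        [("Negative", 0), ("Weak", 1), ("Moderate", 2), ("Strong", 3)],
    )
    def test_intensity(self, label, value):
        assert ihc.intensity_to_numeric(label) == value

    @pytest.mark.parametrize(
        "label, value",
        [("Negative", 0), ("Rare", 5), ("<25%", 25), ("25-75%", 50), (">75%", 75)],
    )
    def test_quantity(self, label, value):
        assert ihc.quantity_to_numeric(label) == value

    @pytest.mark.parametrize("func", [ihc.intensity_to_numeric, ihc.quantity_to_numeric])
    def test_unknown_label_rejected(self, func):
        with pytest.raises(ihc.SchemaError):
            func("Faint")

    def test_maximum_expression_is_225(self):
        levels = [
            ihc.intensity_to_numeric(i) * ihc.quantity_to_numeric(q)
            for i in ihc.INTENSITY_LABELS
            for q in ihc.QUANTITY_LABELS
        ]
        assert max(levels) == 225
        assert min(levels) == 0


class TestExpressionLevels:
    @pytest.mark.parametrize(
        "intensity, quantity, expected",
        [("Moderate", ">75%", 150.0), ("Negative", ">75%", 0.0), ("Strong", ">75%", 225.0)],
    )
    def test_expression_in_normal(self, intensity, quantity, expected):
        assert ihc.expression_in_normal(intensity, quantity) == expected

    def test_expression_in_cancer_worked_example(self, breast_records):
        pairs = [
            (r.intensity, r.quantity)
            for r in breast_records
            if r.sample_kind == "cancer"
        ]
        eic, n = ihc.expression_in_cancer(pairs)
        assert n == 12
        assert eic == pytest.approx(2025 / 12)  # 168.75

    def test_expression_in_cancer_single_and_mixed(self):
        assert ihc.expression_in_cancer([("Strong", ">75%")]) == (225.0, 1)
        eic, n = ihc.expression_in_cancer([("Strong", ">75%"), ("Negative", "Negative")])
        assert (eic, n) == (112.5, 2)

    def test_expression_in_cancer_empty_rejected(self):
        with pytest.raises(ValueError, match="not tested"):
            ihc.expression_in_cancer([])

    @pytest.mark.parametrize(
        "eic, ein, expected", [(168.75, 150.0, 18.75), (50.0, 50.0, 0.0), (0.0, 225.0, -225.0)]
    )
    def test_expression_difference(self, eic, ein, expected):
        assert ihc.expression_difference(eic, ein) == expected

    def test_expression_difference_missing_side(self):
        assert ihc.expression_difference(None, 5.0) is None
        assert ihc.expression_difference(5.0, None) is None


class TestEDMatrixConstruction:
    def test_single_antibody_single_mapping(self, breast_records, registry):
        matrix = ihc.build_ed_matrix(breast_records, registry)
        assert matrix.ed.shape == (1, 27)
        assert matrix.ed.notna().sum().sum() == 1
        assert matrix.ed.at["HPA034966", "Breast"] == pytest.approx(18.75)
        assert matrix.n_patients.at["HPA034966", "Breast"] == 12

    def test_cancer_without_normal_record_stays_missing(self, registry):
        cancer_only = [
            ihc.StainAnnotation(
                "AB1", "G1", "colon", "", "cancer", "Colorectal cancer", "pt01",
                "Strong", ">75%",
            )
        ]
        matrix = ihc.build_ed_matrix(cancer_only, registry)
        assert matrix.ed.notna().sum().sum() == 0

    def test_full_design_cell_count(self, sim_registry):
        annotations, _ = ihc.simulate_annotations(
            ihc.SimConfig(n_antibodies=200, registry=tuple(sim_registry), seed=7)
        )
        matrix = ihc.build_ed_matrix(annotations, sim_registry)
        assert int(matrix.ed.notna().sum().sum()) == 200 * 27

    def test_empty_registry_rejected(self, breast_records):
        with pytest.raises(ValueError, match="registry"):
            ihc.build_ed_matrix(breast_records, [])

    def test_bounds(self, planted_sim, sim_registry):
        annotations, _, _ = planted_sim
        matrix = ihc.build_ed_matrix(annotations, sim_registry)
        assert ((matrix.ein >= 0) & (matrix.ein <= 225)).where(matrix.ein.notna(), True).all().all()
        assert ((matrix.eic >= 0) & (matrix.eic <= 225)).where(matrix.eic.notna(), True).all().all()
        diff = (matrix.ed - (matrix.eic - matrix.ein)).abs().max().max()
        assert diff == 0 or diff < 1e-12


def _matrix_from_ed(ed: pd.DataFrame, config=None) -> EDMatrix:
    """An EDMatrix with prescribed EDs (EiN = 0, EiC = ED)."""
    ein = ed * 0.0
    npat = ed.notna().astype(float)
    genes = pd.Series({a: f"G-{a}" for a in ed.index})
    return EDMatrix(ein, ed.copy(), npat, genes, config)


class TestSignificanceSpecificity:
    def test_sg_at_column_mean_is_half(self):
        ed = pd.DataFrame({"M1": [10.0, 20.0, 30.0]}, index=["A", "B", "C"])
        matrix = _matrix_from_ed(ed)
        assert ihc.significance(matrix, "B", "M1") == pytest.approx(0.5)

    def test_sg_derived_example(self):
        column = [0.0, 10.0, -10.0, 20.0, -20.0]
        ed = pd.DataFrame({"M1": column}, index=list("ABCDE"))
        matrix = _matrix_from_ed(ed)
        sigma = population_sd(column)
        expected = normal_cdf_series(20.0 / sigma)
        assert ihc.significance(matrix, "D", "M1") == pytest.approx(expected, abs=1e-9)

    def test_sg_degenerate_column_is_half(self):
        ed = pd.DataFrame({"M1": [5.0, 5.0, 5.0]}, index=list("ABC"))
        assert ihc.significance(_matrix_from_ed(ed), "A", "M1") == 0.5

    def test_sg_single_cell_column_unscorable(self):
        ed = pd.DataFrame({"M1": [5.0, np.nan]}, index=list("AB"))
        with pytest.raises(ihc.UnscorableError):
            ihc.significance(_matrix_from_ed(ed), "A", "M1")

    def test_sg_missing_cell_rejected(self):
        ed = pd.DataFrame({"M1": [5.0, np.nan]}, index=list("AB"))
        with pytest.raises(ValueError, match="not tested"):
            ihc.significance(_matrix_from_ed(ed), "B", "M1")

    def test_sp_derived_example(self):
        row = [100.0, 0.0, 0.0, 0.0]
        ed = pd.DataFrame([row], index=["A"], columns=["M1", "M2", "M3", "M4"])
        matrix = _matrix_from_ed(ed)
        sigma = population_sd(row)
        expected = normal_cdf_series((100.0 - 25.0) / sigma)
        assert ihc.specificity(matrix, "A", "M1") == pytest.approx(expected, abs=1e-9)

    def test_sp_dominant_mapping_beats_all_others(self):
        ed = pd.DataFrame(
            [[150.0] + [5.0] * 26], index=["A"], columns=[f"M{i}" for i in range(27)]
        )
        matrix = _matrix_from_ed(ed)
        dominant = ihc.specificity(matrix, "A", "M0")
        others = [ihc.specificity(matrix, "A", f"M{i}") for i in range(1, 27)]
        assert all(dominant > o for o in others)

    def test_sample_sd_convention_configurable(self):
        column = [0.0, 10.0, -10.0, 20.0, -20.0]
        ed = pd.DataFrame({"M1": column}, index=list("ABCDE"))
        matrix = _matrix_from_ed(ed, ScoringConfig(ddof=1))
        sigma = np.std(column, ddof=1)
        assert ihc.significance(matrix, "D", "M1") == pytest.approx(
            normal_cdf_series(20.0 / sigma), abs=1e-9
        )

    def test_oracle_equivalence_small_matrices(self):
        """SG/SP on <=5x5 matrices match a direct series-expansion oracle."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_ab, n_map = rng.integers(2, 6, size=2)
            ed = pd.DataFrame(
                rng.uniform(-225, 225, size=(n_ab, n_map)),
                index=[f"A{i}" for i in range(n_ab)],
                columns=[f"M{j}" for j in range(n_map)],
            )
            matrix = _matrix_from_ed(ed)
            for a in ed.index:
                for m in ed.columns:
                    col = ed[m].tolist()
                    mu, sd = np.mean(col), population_sd(col)
                    assert ihc.significance(matrix, a, m) == pytest.approx(
                        normal_cdf_series((ed.at[a, m] - mu) / sd), abs=1e-7
                    )
                    row = ed.loc[a].tolist()
                    mu, sd = np.mean(row), population_sd(row)
                    assert ihc.specificity(matrix, a, m) == pytest.approx(
                        normal_cdf_series((ed.at[a, m] - mu) / sd), abs=1e-7
                    )


class TestComputeScores:
    def test_score_is_product_and_bounded(self, planted_sim):
        _, _, scores = planted_sim
        recomputed = scores["EiC"] * scores["SG"] * scores["SP"]
        assert np.allclose(scores["score"], recomputed, atol=1e-9)
        assert scores["score"].between(0, 225).all()
        assert scores["SG"].between(0, 1, inclusive="neither").all()
        assert scores["SP"].between(0, 1, inclusive="neither").all()
        assert (scores["ED"] == scores["EiC"] - scores["EiN"]).all()

    def test_zero_eic_gives_zero_score(self):
        ed = pd.DataFrame(
            [[0.0, -50.0], [100.0, 0.0]], index=["A", "B"], columns=["M1", "M2"]
        )
        matrix = _matrix_from_ed(ed)
        matrix.eic.loc["A", :] = 0.0
        matrix.ed = matrix.eic - matrix.ein
        scores = ihc.compute_scores(matrix)
        assert (scores.loc[scores["antibody_id"] == "A", "score"] == 0).all()

    def test_column_z_scores_normalized(self, planted_sim, sim_registry):
        annotations, _, _ = planted_sim
        matrix = ihc.build_ed_matrix(annotations, sim_registry)
        z = matrix.ed.sub(matrix.col_mean, axis=1).div(matrix.col_std, axis=1)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_sg_strictly_increasing_in_ed_within_column(self, planted_sim):
        _, _, scores = planted_sim
        for _, sub in scores.groupby("mapping_id"):
            ordered = sub.sort_values("ED")
            sg_step = np.diff(ordered["SG"].to_numpy())
            assert (sg_step >= -1e-12).all()  # non-decreasing up to float noise
            # strict increase wherever EDs are separated beyond float noise
            ed_gap = np.diff(ordered["ED"].to_numpy()) > 1e-6
            assert (sg_step[ed_gap] > 0).all()

    def test_shift_invariance_of_sg(self):
        rng = np.random.default_rng(5)
        ed = pd.DataFrame(
            rng.normal(0, 40, size=(6, 3)),
            index=[f"A{i}" for i in range(6)],
            columns=["M1", "M2", "M3"],
        )
        base = {a: ihc.significance(_matrix_from_ed(ed), a, "M2") for a in ed.index}
        shifted_ed = ed.copy()
        shifted_ed["M2"] += 37.5
        shifted = _matrix_from_ed(shifted_ed)
        for a in ed.index:
            assert ihc.significance(shifted, a, "M2") == pytest.approx(base[a], abs=1e-12)

    def test_rank_orders_by_score_with_stable_ties(self, planted_sim):
        _, _, scores = planted_sim
        for _, sub in scores.groupby("mapping_id"):
            sub = sub.sort_values("rank")
            assert list(sub["rank"]) == list(range(1, len(sub) + 1))
            assert (sub["score"].diff().dropna() <= 1e-12).all()

    def test_planted_marker_ranks_first(self, sim_registry):
        markers = (ihc.PlantedMarker("AB00007", "Sim-05", 4.0),)
        config = ihc.SimConfig(
            n_antibodies=40, registry=tuple(sim_registry), planted_markers=markers, seed=11
        )
        annotations, _ = ihc.simulate_annotations(config)
        scores = ihc.compute_scores(annotations, sim_registry)
        top = scores[(scores["mapping_id"] == "Sim-05") & (scores["rank"] == 1)]
        assert top["antibody_id"].item() == "AB00007"

    def test_roundtrip_scores_tsv(self, tmp_path, planted_sim):
        _, _, scores = planted_sim
        path = tmp_path / "scores.tsv"
        ihc.write_scores(scores, path)
        back = ihc.read_scores(path)
        assert list(back.columns) == list(scores.columns)
        assert len(back) == len(scores)
        assert np.allclose(back["score"], scores["score"], rtol=1e-4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.lists(
            st.floats(min_value=-225, max_value=225, allow_nan=False),
            min_size=3,
            max_size=5,
        ),
        min_size=3,
        max_size=5,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_score_law_property(data):
    """score = EiC*SG*SP stays in [0, 225] with SG/SP in [0, 1] for any ED layout."""
    ed = pd.DataFrame(
        data,
        index=[f"A{i}" for i in range(len(data))],
        columns=[f"M{j}" for j in range(len(data[0]))],
    )
    matrix = _matrix_from_ed(ed)
    matrix.eic.loc[:, :] = np.abs(ed.to_numpy())  # any EiC in [0, 225]
    matrix.ed = matrix.eic - matrix.ein
    scores = ihc.compute_scores(matrix)
    assert scores["SG"].between(0, 1).all()
    assert scores["SP"].between(0, 1).all()
    assert scores["score"].between(0, 225 + 1e-9).all()
    assert np.allclose(scores["score"], scores["EiC"] * scores["SG"] * scores["SP"], atol=1e-9)
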