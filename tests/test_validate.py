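"""Validation stage: normalization, IDD/ISD, nonparametric retention, dose-response."""

import numpy as np
import pandas as pd
import pytest

from cardioscreen.imaging import measure_movie
from cardioscreen.screen import compute_icd
from cardioscreen.synth import GroupDesign, simulate_fly_table, simulate_group_movies, SimulationSpec
from cardioscreen.validate import (
    ValidationStudy,
    apply_normalization,
    compute_idd_isd,
    compute_normalizers,
    dose_response,
    dunn_test,
    retention_test,
)


def _records(edd_by_exp: dict) -> pd.DataFrame:
    rows = []
    for exp, edds in edd_by_exp.items():
        for v in edds:
            rows.append(
                {
                    "experiment_id": exp,
                    "genotype": "disease",
                    "treatment": "untreated",
                    "EDD": float(v),
                    "ESD": float(v) / 2,
                }
            )
    return pd.DataFrame(rows)


class TestNormalization:
    def test_single_experiment_is_identity(self):
        norms = compute_normalizers(_records({"E1": [90, 100, 110]}))
        assert len(norms) == 1
        assert norms[0].N_i == 1.0

    def test_two_experiment_hand_example(self):
        # anchor medians 100 and 110, grand median 105
        recs = _records({"E1": [90, 100, 110], "E2": [100, 110, 120]})
        norms = {n.experiment_id: n.N_i for n in compute_normalizers(recs)}
        assert norms["E1"] == pytest.approx(1.05)
        assert norms["E2"] == pytest.approx(105 / 110)

    def test_normalized_anchor_medians_equal_grand_median(self):
        recs = _records({"E1": [90, 100, 110], "E2": [100, 110, 120], "E3": [80, 95, 130]})
        normed = apply_normalization(recs)
        meds = normed.groupby("experiment_id")["EDD"].median()
        assert np.allclose(meds, recs["EDD"].median())
        # idempotence: renormalizing the normalized table gives N_i = 1
        again = compute_normalizers(normed)
        assert all(n.N_i == pytest.approx(1.0) for n in again)

    def test_experiment_without_anchor_rejected(self):
        recs = _records({"E1": [90, 100, 110]})
        orphan = pd.DataFrame(
            [{"experiment_id": "E2", "genotype": "control",
              "treatment": "untreated", "EDD": 60.0, "ESD": 25.0}]
        )
        with pytest.raises(ValueError, match="E2"):
            compute_normalizers(pd.concat([recs, orphan], ignore_index=True))


def _group(genotype, treatment, edd, esd, exp="E1"):
    return pd.DataFrame(
        {
            "experiment_id": exp,
            "genotype": genotype,
            "treatment": treatment,
            "EDD": np.asarray(edd, dtype=float),
            "ESD": np.asarray(esd, dtype=float),
        }
    )


class TestIddIsd:
    def test_lead_compound_worked_values(self):
        treated = _group("disease", "ptx", [134], [153])
        disease = _group("disease", "untreated", [181], [241])
        control = _group("control", "untreated", [100], [100])
        idd, isd = compute_idd_isd(treated, disease, control)
        assert idd == pytest.approx(34 / 81, abs=1e-12)
        assert round(idd, 2) == 0.42
        # the printed systolic elevations imply 53/141 = 0.376, i.e. the
        # printed index (0.37) to within one unit in its last digit
        assert isd == pytest.approx(53 / 141, abs=1e-12)
        assert isd == pytest.approx(0.37, abs=0.01)

    def test_treated_equal_control_scores_zero(self):
        control = _group("control", "untreated", [95, 100, 105], [40, 50, 60])
        disease = _group("disease", "untreated", [170, 181, 190], [230, 241, 250])
        treated = control.assign(genotype="disease", treatment="drug")
        assert compute_idd_isd(treated, disease, control) == (0.0, 0.0)

    def test_empty_group_rejected(self):
        g = _group("control", "untreated", [100], [50])
        with pytest.raises(ValueError, match="empty"):
            compute_idd_isd(g.iloc[:0], g, g)


class TestDunn:
    def test_hand_computed_three_group_example(self):
        # groups [1,2,3],[4,5,6],[7,8,9]: mean ranks 2,5,8; no ties;
        # se = sqrt((9*10/12)*(2/3)) = sqrt(5); z = -3/sqrt(5) = -1.3416
        # two-sided normal p = 0.17971
        p = dunn_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]], 0, 1)
        assert p == pytest.approx(0.17971, abs=1e-4)

    def test_symmetric_in_pair_order(self):
        g = [[1.0, 3, 5], [2.0, 4, 9], [1.5, 6, 7]]
        assert dunn_test(g, 0, 1) == pytest.approx(dunn_test(g, 1, 0))

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(2000):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            ps.append(dunn_test(groups, 0, 1))
        ps = np.asarray(ps)
        assert abs((ps < 0.5).mean() - 0.5) < 0.05
        assert 0.03 <= (ps < 0.05).mean() <= 0.07


class TestRetention:
    def test_identical_groups_not_retained(self):
        g = [80.0, 80.0, 80.0]
        res = retention_test(g, g, g)
        assert res.p_kruskal_dunn == 1.0
        assert not res.retained

    def test_planted_strong_suppressor_retained(self):
        rng = np.random.default_rng(12)
        control = rng.lognormal(np.log(60), 0.1, 30)
        disease = rng.lognormal(np.log(108.6), 0.1, 30)
        treated = rng.lognormal(np.log(60), 0.1, 30)  # treated ~ control
        res = retention_test(treated, disease, control, compound_id="hit")
        assert res.retained
        assert res.p_kruskal < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            retention_test([1.0], [1, 2, 3], [4, 5, 6])

    def test_all_pairs_option_never_larger_than_single_pair(self):
        rng = np.random.default_rng(13)
        t, d, c = (rng.normal(m, 1, 20) for m in (0.0, 1.0, 0.2))
        single = retention_test(t, d, c).p_kruskal_dunn
        allp = retention_test(t, d, c, comparison="all_pairs").p_kruskal_dunn
        assert allp <= single


class TestDoseResponse:
    def _dose_table(self, elevations, n_per_dose=40, seed=14):
        # disease flies at increasing dose; ESD medians set from percent
        # elevations over a control ESD of 25 um
        designs = []
        for dose, elev in elevations.items():
            designs.append(
                GroupDesign(
                    "disease_treated" if dose > 0 else "disease_untreated",
                    n_per_dose,
                    edd_mean=60.0 * 1.66,
                    esd_mean=25.0 * (1 + elev / 100),
                    compound_id="ptx" if dose > 0 else None,
                    concentration_um=dose if dose > 0 else None,
                )
            )
        return simulate_fly_table(designs, seed=seed)

    def test_printed_elevations_give_decreasing_esd(self):
        table = self._dose_table({0: 138, 1: 111, 5: 73, 10: 13})
        summary, trend = dose_response(table)
        assert trend["strictly_decreasing_medians"]
        assert trend["decreasing_trend"]
        assert list(summary["concentration_um"]) == [0, 1, 5, 10]

    def test_single_dose_rejected(self):
        table = self._dose_table({0: 138})
        with pytest.raises(ValueError, match="2 dose levels"):
            dose_response(table)

    def test_flat_profile_has_no_trend(self):
        table = self._dose_table({0: 138, 1: 138, 5: 138, 10: 138}, seed=15)
        _, trend = dose_response(table)
        assert not trend["decreasing_trend"]


class TestValidationStudy:
    def test_anchors_hold_exactly_on_pooled_data(self):
        designs = [
            GroupDesign("disease_untreated", 30, 108.6, 60.25),
            GroupDesign("control", 20, 60.0, 25.0),
            GroupDesign("disease_treated", 20, 84.0, 42.0, compound_id="drug"),
        ]
        flies = simulate_fly_table(designs, seed=16)
        flies["experiment_id"] = "E1"
        disease = flies[(flies.genotype == "disease") & (flies.treatment == "untreated")]
        control = flies[flies.genotype == "control"]
        idd, isd = compute_idd_isd(disease, disease, control)
        assert (idd, isd) == (1.0, 1.0)
        idd, isd = compute_idd_isd(control, disease, control)
        assert (idd, isd) == (0.0, 0.0)

    def test_full_movie_round_recovers_planted_effect(self):
        # three independent experiments, Fig.2-scale arms, planted protective
        # multiplier 0.5; movies -> imaging -> normalization -> pooled IDD.
        # Oracle: the closed-form index computed from the exact per-fly
        # diameters the generator drew (isolates the pipeline from the
        # between-fly sampling noise, which at these arm sizes has sd ~0.03
        # on the index itself).
        base_spec = SimulationSpec(n_frames=251, image_height=24, rate_jitter_cv=0.0)
        m = 0.5
        treated_edd = 60 + m * (108.6 - 60)
        treated_esd = 25 + m * (60.25 - 25)
        rows, truth_rows = [], []
        seed = 100
        for exp in ("E1", "E2", "E3"):
            for label, n, edd, esd, cid in (
                ("disease_treated", 22, treated_edd, treated_esd, "ptx"),
                ("disease_untreated", 19, 108.6, 60.25, None),
                ("control", 17, 60.0, 25.0, None),
            ):
                design = GroupDesign(label, n, edd, esd, compound_id=cid)
                records, movies = simulate_group_movies(design, seed, base_spec)
                seed += 1
                for rec, movie in zip(records.to_dict("records"), movies):
                    meas = measure_movie(movie)
                    rows.append(
                        {
                            "experiment_id": exp,
                            "genotype": rec["genotype"],
                            "treatment": rec["treatment"],
                            "EDD": meas.EDD,
                            "ESD": meas.ESD,
                            "FS": meas.FS,
                        }
                    )
                    truth_rows.append(
                        {"genotype": rec["genotype"], "treatment": rec["treatment"],
                         "EDD": rec["EDD"]}
                    )
        flies = pd.DataFrame(rows)
        truth = pd.DataFrame(truth_rows)
        idd_truth = compute_icd(
            truth.loc[truth.treatment == "ptx", "EDD"],
            truth.loc[(truth.genotype == "disease") & (truth.treatment == "untreated"), "EDD"],
            truth.loc[truth.genotype == "control", "EDD"],
        )
        assert abs(idd_truth - m) <= 0.15  # sampling keeps the draw near the design
        res = ValidationStudy(flies).fit()
        row = res.results.set_index("compound_id").loc["ptx"]
        assert abs(row["IDD"] - idd_truth) <= 0.05
        assert row["retained"]

    def test_summary_counts_retained_partition(self):
        designs = [
            GroupDesign("disease_untreated", 40, 108.6, 60.25),
            GroupDesign("control", 20, 60.0, 25.0),
            GroupDesign("disease_treated", 30, 62.0, 27.0, compound_id="supp"),
            GroupDesign("disease_treated", 30, 150.0, 90.0, compound_id="enh"),
        ]
        flies = simulate_fly_table(designs, seed=17)
        res = ValidationStudy(flies).fit()
        assert set(res.suppressors["compound_id"]) == {"supp"}
        assert set(res.enhancers["compound_id"]) == {"enh"}
        assert "retained:             2" in res.summary()
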