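import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliovol import (
    DegenerateInputError,
    MutationTable,
    absolute_auc,
    association_scan,
    auc_significance,
    cluster_and_test,
    correlation_matrix,
    normality_screen,
    roc_auc,
    shapiro_wilk,
    student_t_two_sided,
    simulate_cohort,
    preset_cohort,
)
from gliovol.volumetrics import FEATURE_NAMES, panels_to_frame


def pooled_t_oracle(a, b):
    """Independent closed-form evaluation of the pooled-variance t test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def auc_pair_oracle(scores, labels):
    """Brute-force pairwise concordance over all pos x neg pairs."""
    s, y = np.asarray(scores, float), np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t_two_sided([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_on_random_instances(self, rng):
        for _ in range(100):
            na, nb = rng.integers(2, 15, 2)
            a, b = rng.normal(0, 2, na), rng.normal(0.5, 2, nb)
            t, p = student_t_two_sided(a, b)
            t0, p0 = pooled_t_oracle(a, b)
            assert t == pytest.approx(t0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_matches_scipy_equal_var(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=12)
        t, p = student_t_two_sided(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(ref.statistic), abs=1e-12)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            student_t_two_sided([1, 2, 3], [4])

    def test_sign_convention(self):
        t, _ = student_t_two_sided([5, 6, 7], [1, 2, 3])
        assert t > 0


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(size=50)
            if shapiro_wilk(v).p_sw > 0.05:
                hits += 1
        assert hits >= 90

    def test_lognormal_samples_mostly_rejected(self):
        hits = 0
        for seed in range(100):
            v = np.exp(np.random.default_rng(seed).normal(0, 1.5, size=50))
            if shapiro_wilk(v).p_sw < 0.05:
                hits += 1
        assert hits >= 90

    def test_constant_input_flagged(self):
        res = shapiro_wilk([3.0] * 10)
        assert "constant_input" in res.flags
        assert math.isnan(res.w_stat)

    def test_agrees_with_reference_implementation(self, rng):
        v = rng.normal(size=40)
        res = shapiro_wilk(v)
        w_ref, p_ref = stats.shapiro(v)
        assert res.w_stat == pytest.approx(float(w_ref), abs=1e-6)
        assert res.p_sw == pytest.approx(float(p_ref), abs=1e-6)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_perfect_anti_separation(self):
        assert roc_auc([1, 2], [1, 0]) == 0.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            s = rng.integers(0, 6, n).astype(float)  # heavy ties
            assert roc_auc(s, y) == pytest.approx(auc_pair_oracle(s, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = 40
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            s = rng.normal(size=n) + y
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestAbsoluteAuc:
    def test_fixed_point_and_fold(self):
        assert absolute_auc(0.5) == 0.5
        assert absolute_auc(0.278) == pytest.approx(0.722)

    def test_symmetry_on_dense_grid(self):
        for x in np.linspace(0, 1, 201):
            assert absolute_auc(x) == pytest.approx(absolute_auc(1 - x), abs=1e-15)
            assert 0.5 <= absolute_auc(x) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            absolute_auc(1.2)


class TestAucSignificance:
    def test_perfect_separation_extreme(self, rng):
        s = np.concatenate([rng.normal(10, 0.1, 20), rng.normal(0, 0.1, 20)])
        y = np.array([1] * 20 + [0] * 20)
        p, lo, hi = auc_significance(s, y)
        assert p < 0.001
        assert lo <= 1.0 and hi <= 1.0

    def test_ci_brackets_reported_auc(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.sum() < 2 or y.sum() > 28:
                continue
            s = rng.normal(size=30)
            auc = roc_auc(s, y)
            _, lo, hi = auc_significance(s, y)
            assert lo <= absolute_auc(auc) <= hi

    def test_type_i_calibration_under_null(self):
        hits = 0
        n_sims = 500
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            s = r.normal(size=60)
            y = np.array([1] * 30 + [0] * 30)
            p, _, _ = auc_significance(s, y)
            if p < 0.05:
                hits += 1
        assert 0.01 <= hits / n_sims <= 0.10

    def test_normal_and_permutation_paths_agree(self):
        for seed in range(15):
            r = np.random.default_rng(seed)
            s = r.normal(size=30) + 0.4 * np.array([1] * 15 + [0] * 15)
            y = np.array([1] * 15 + [0] * 15)
            p_norm, _, _ = auc_significance(s, y, method="normal")
            p_perm, _, _ = auc_significance(
                s, y, method="permutation", n_permutations=4000,
                rng=np.random.default_rng(seed + 1000),
            )
            assert p_norm == pytest.approx(p_perm, abs=0.02)


def _synthetic_panel_frame(rng, n=60):
    """Random but internally consistent panel table for scan tests."""
    necrosis = rng.lognormal(8, 0.4, n)
    enhancing = rng.lognormal(8.7, 0.4, n)
    hyper = rng.lognormal(9.4, 0.4, n)
    from gliovol import panel_from_volumes

    panels = [
        panel_from_volumes(f"P{i:03d}", necrosis[i], enhancing[i],
                           necrosis[i] + enhancing[i] + hyper[i])
        for i in range(n)
    ]
    return panels_to_frame(panels)


class TestAssociationScan:
    def test_min_mut_filter_excludes_rare_genes(self, rng):
        frame = _synthetic_panel_frame(rng, n=30)
        status = pd.DataFrame(
            {"COMMON": [1] * 8 + [0] * 22, "RARE": [1] * 4 + [0] * 26},
            index=frame.index,
        )
        scan = association_scan(frame, MutationTable(status), min_mut=5)
        assert set(scan["gene"]) == {"COMMON"}
        assert len(scan) == len(FEATURE_NAMES)

    def test_no_gene_passes_filter_warns_and_is_empty(self, rng):
        frame = _synthetic_panel_frame(rng, n=20)
        status = pd.DataFrame({"RARE": [1] * 2 + [0] * 18}, index=frame.index)
        with pytest.warns(UserWarning, match="at least 5"):
            scan = association_scan(frame, MutationTable(status))
        assert scan.empty

    def test_complement_ratio_pairs_share_auc_and_p(self, rng):
        frame = _synthetic_panel_frame(rng, n=60)
        status = pd.DataFrame(
            {"G1": rng.integers(0, 2, 60), "G2": rng.integers(0, 2, 60)},
            index=frame.index,
        )
        scan = association_scan(frame, MutationTable(status)).set_index(["gene", "feature"])
        for gene in ("G1", "G2"):
            for fa, fb in [
                ("ratio_hyper_over_total", "ratio_bulk_over_total"),
                ("ratio_necrosis_over_enhancing", "ratio_enhancing_over_bulk"),
            ]:
                a, b = scan.loc[(gene, fa)], scan.loc[(gene, fb)]
                assert a["auc_abs"] == pytest.approx(b["auc_abs"], abs=1e-12)
                assert a["p_auc"] == pytest.approx(b["p_auc"], abs=1e-12)
                assert a["auc_raw"] == pytest.approx(1 - b["auc_raw"], abs=1e-12)

    def test_diff_sign_matches_t_sign(self, rng):
        frame = _synthetic_panel_frame(rng, n=50)
        status = pd.DataFrame({"G": rng.integers(0, 2, 50)}, index=frame.index)
        scan = association_scan(frame, MutationTable(status))
        ok = scan["testable"] & (scan["t_stat"] != 0)
        assert (np.sign(scan.loc[ok, "t_stat"]) == np.sign(scan.loc[ok, "mut_minus_wt_diff"])).all()

    def test_planted_effect_detected_in_single_cohort(self):
        cohort = simulate_cohort(
            preset_cohort("tp53_like", n_patients=76, seed=11, shape=(32, 32, 32)),
            render_images=False,
        )
        scan = association_scan(cohort.truth_panels(), cohort.mutation_table())
        row = scan.set_index(["gene", "feature"]).loc[("TP53", "enhancing_mm3")]
        assert row["p_t"] < 0.05
        assert row["mut_minus_wt_diff"] < 0

    def test_bh_multiplicity_is_more_conservative(self, rng):
        frame = _synthetic_panel_frame(rng, n=60)
        status = pd.DataFrame(
            {f"G{i}": rng.integers(0, 2, 60) for i in range(4)}, index=frame.index
        )
        raw = association_scan(frame, MutationTable(status), multiplicity="none")
        bh = association_scan(frame, MutationTable(status), multiplicity="bh")
        assert bh["significant_t"].sum() <= raw["significant_t"].sum()
        assert (bh["p_t_adj"] >= bh["p_t"] - 1e-15).all()

    def test_monotone_transform_invariance_of_auc(self, rng):
        frame = _synthetic_panel_frame(rng, n=40)
        status = pd.DataFrame({"G": rng.integers(0, 2, 40)}, index=frame.index)
        y = status["G"].to_numpy()
        v = frame["total_mm3"].to_numpy()
        auc = roc_auc(v, y)
        assert roc_auc(np.log(v), y) == pytest.approx(auc, abs=1e-12)
        assert roc_auc(-v, y) == pytest.approx(1 - auc, abs=1e-12)
        assert absolute_auc(roc_auc(-v, y)) == pytest.approx(absolute_auc(auc), abs=1e-12)


class TestMutationTable:
    def test_counts_are_column_sums(self, rng):
        status = pd.DataFrame(
            rng.integers(0, 2, (10, 3)), columns=list("ABC"),
            index=[f"P{i}" for i in range(10)],
        )
        table = MutationTable(status)
        assert (table.counts == status.sum()).all()

    def test_duplicate_patient_ids_rejected(self):
        status = pd.DataFrame({"A": [0, 1]}, index=["P1", "P1"])
        with pytest.raises(ValueError, match="duplicate"):
            MutationTable(status)

    def test_non_binary_rejected(self):
        status = pd.DataFrame({"A": [0, 2]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="0 or 1"):
            MutationTable(status)


class TestNormalityScreen:
    def test_screens_all_features(self, rng):
        frame = _synthetic_panel_frame(rng, n=40)
        screen = normality_screen(frame)
        assert list(screen["feature"]) == FEATURE_NAMES
        assert (screen["n"] == 40).all()
        assert ((screen["w_stat"] > 0) & (screen["w_stat"] <= 1)).all()


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal_bounded(self, rng):
        frame = _synthetic_panel_frame(rng, n=50)
        matrix, flagged = correlation_matrix(frame)
        assert not flagged
        m = matrix.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_matches_covariance_formula(self, rng):
        frame = _synthetic_panel_frame(rng, n=50)
        matrix, _ = correlation_matrix(frame)
        a = frame["necrosis_mm3"].to_numpy()
        b = frame["total_mm3"].to_numpy()
        r = ((a - a.mean()) * (b - b.mean())).sum() / math.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert matrix.loc["necrosis_mm3", "total_mm3"] == pytest.approx(r, abs=1e-10)

    def test_affine_duplicate_feature_has_r_one(self, rng):
        frame = _synthetic_panel_frame(rng, n=30)
        frame["ratio_bulk_over_total"] = 3.0 * frame["necrosis_mm3"] + 5.0
        matrix, _ = correlation_matrix(frame)
        assert matrix.loc["necrosis_mm3", "ratio_bulk_over_total"] == pytest.approx(1.0)

    def test_independent_noise_has_low_correlation(self, rng):
        n = 500
        frame = pd.DataFrame(
            rng.normal(size=(n, len(FEATURE_NAMES))), columns=FEATURE_NAMES,
            index=[f"P{i}" for i in range(n)],
        )
        matrix, _ = correlation_matrix(frame)
        off = matrix.to_numpy()[~np.eye(len(FEATURE_NAMES), dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_zero_variance_feature_flagged(self, rng):
        frame = _synthetic_panel_frame(rng, n=30)
        frame["ratio_enhancing_over_total"] = 0.25
        matrix, flagged = correlation_matrix(frame)
        assert flagged == ["ratio_enhancing_over_total"]
        assert matrix.loc["ratio_enhancing_over_total"].isna().all()


class TestClusterAndTest:
    @staticmethod
    def _blob_frame(rng, n_per=10, sep=8.0):
        data = rng.normal(size=(2 * n_per, len(FEATURE_NAMES)))
        data[n_per:, :] += sep
        return (
            pd.DataFrame(data, columns=FEATURE_NAMES,
                         index=[f"P{i}" for i in range(2 * n_per)]),
            np.array([0] * n_per + [1] * n_per),
        )

    def test_separated_blobs_recovered_up_to_label_swap(self, rng):
        frame, truth = self._blob_frame(rng)
        clinical = pd.DataFrame(index=frame.index)
        result = cluster_and_test(frame, clinical)
        got = result.assignments.to_numpy()
        agreement = max((got == truth).mean(), (got == 1 - truth).mean())
        assert agreement == 1.0

    def test_ward_cut_never_beats_exhaustive_optimum(self, rng):
        """Sanity on the 2-group objective: the exhaustive minimum-SSE
        2-partition lower-bounds whatever the agglomerative cut returns."""
        for _ in range(50):
            n = int(rng.integers(4, 9))
            data = rng.normal(size=(n, 3))
            frame = pd.DataFrame(
                np.tile(data, (1, 4))[:, : len(FEATURE_NAMES)], columns=FEATURE_NAMES,
                index=[f"P{i}" for i in range(n)],
            )
            result = cluster_and_test(frame, pd.DataFrame(index=frame.index))
            z = (frame - frame.mean()) / frame.std(ddof=1)
            z = z.dropna(axis=1)
            labels = result.assignments.to_numpy()
            got = sum(
                ((z.to_numpy()[labels == k] - z.to_numpy()[labels == k].mean(0)) ** 2).sum()
                for k in np.unique(labels)
            )
            best = np.inf
            zv = z.to_numpy()
            for bits in itertools.product((0, 1), repeat=n - 1):
                lab = np.array((0,) + bits)
                if lab.sum() in (0, n):
                    continue
                sse = sum(((zv[lab == k] - zv[lab == k].mean(0)) ** 2).sum() for k in (0, 1))
                best = min(best, sse)
            assert got >= best - 1e-9

    def test_chi_squared_calibrated_under_independent_clinical(self, rng):
        frame, _ = self._blob_frame(rng, n_per=20, sep=6.0)
        rejections = {"gender": 0, "dfs": 0, "kps": 0, "age": 0}
        n_reps = 200
        for rep in range(n_reps):
            r = np.random.default_rng(rep)
            clinical = pd.DataFrame(
                {
                    "gender": r.choice(["M", "F"], len(frame)),
                    "dfs": r.integers(0, 2, len(frame)),
                    "kps": r.choice([40, 60, 80, 100], len(frame)),
                    "age": r.integers(21, 86, len(frame)),
                },
                index=frame.index,
            )
            result = cluster_and_test(frame, clinical)
            for _, row in result.tests.iterrows():
                if np.isfinite(row["p"]) and row["p"] < 0.05:
                    rejections[row["variable"]] += 1
        for variable, hits in rejections.items():
            assert hits / n_reps <= 0.10, variable

    def test_identical_patients_single_cluster_flagged(self):
        frame = pd.DataFrame(
            np.ones((5, len(FEATURE_NAMES))), columns=FEATURE_NAMES,
            index=[f"P{i}" for i in range(5)],
        )
        result = cluster_and_test(frame, pd.DataFrame(index=frame.index))
        assert result.assignments.nunique() == 1
        assert any("single_cluster" in f for f in result.flags)

    def test_missing_clinical_excluded_per_variable(self, rng):
        frame, _ = self._blob_frame(rng)
        clinical = pd.DataFrame(
            {
                "gender": ["M"] * 10 + [None] * 10,
                "age": rng.integers(21, 86, 20).astype(float),
            },
            index=frame.index,
        )
        result = cluster_and_test(frame, clinical)
        gender_row = result.tests.set_index("variable").loc["gender"]
        assert gender_row["n"] == 10
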