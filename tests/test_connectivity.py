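import numpy as np
import pytest
from scipy.linalg import expm, logm, sqrtm

from conntraj import connectivity as cn
from conntraj.regions import RegionLabel, default_motor_labels

from conftest import random_spd


def _ts(data, labels=None):
    labels = labels or default_motor_labels(data.shape[1])
    return cn.RegionTimeSeries("s", data, labels)


class TestEstimateConnectivity:
    def test_perfect_correlation_shrunk(self, rng):
        x = rng.standard_normal(100)
        data = np.column_stack([x, x])
        out = cn.estimate_connectivity(_ts(data), shrinkage=0.1)
        assert out.values[0, 1] == pytest.approx(0.9)
        assert np.allclose(np.diag(out.values), 1.0)

    def test_independent_series_near_zero(self, rng):
        T = 4000
        data = rng.standard_normal((T, 5))
        out = cn.estimate_connectivity(_ts(data), shrinkage=0.01)
        off = out.values[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 4 / np.sqrt(T))

    def test_spd_guaranteed_even_when_T_small(self, rng):
        data = rng.standard_normal((12, 10))  # T close to R
        out = cn.estimate_connectivity(_ts(data), shrinkage=0.05)
        assert np.linalg.eigvalsh(out.values).min() > 0

    def test_zero_variance_region_named(self, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            cn.estimate_connectivity(_ts(data))


class TestTangentGeometry:
    def test_projection_at_reference_is_zero(self, rng):
        C = random_spd(rng, 6)
        t = cn.tangent_project(C, C)
        assert np.abs(t.values).max() < 1e-10

    def test_identity_reference_closed_form(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        t = cn.tangent_project(C, np.eye(2))
        # logm of a 2x2 correlation: off-diagonal atanh(rho)
        assert t.values[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_matches_scipy_logm_oracle(self, rng):
        for _ in range(10):
            C = random_spd(rng, 8)
            ref = random_spd(rng, 8)
            ours = cn.tangent_project(C, ref).values
            inv_sqrt = np.linalg.inv(sqrtm(ref))
            oracle = logm(inv_sqrt @ C @ inv_sqrt)
            assert np.abs(ours - oracle.real).max() < 1e-8

    def test_round_trip(self, rng):
        C = random_spd(rng, 7)
        ref = random_spd(rng, 7)
        back = cn.tangent_inverse(cn.tangent_project(C, ref), ref)
        assert np.abs(back - C).max() < 1e-10 * np.abs(C).max()

    def test_non_spd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError):
            cn.tangent_project(bad, np.eye(2))


class TestFrechetMean:
    def test_identical_inputs_fixed_point(self, rng):
        C = random_spd(rng, 5)
        mean = cn.frechet_mean([C] * 4)
        assert np.abs(mean - C).max() < 1e-8

    def test_commuting_diagonals_geometric_mean(self):
        mean = cn.frechet_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        assert np.abs(mean - np.diag([2.0, 2.0])).max() < 1e-8

    def test_two_matrix_geodesic_midpoint(self, rng):
        C1, C2 = random_spd(rng, 6), random_spd(rng, 6)
        mean = cn.frechet_mean([C1, C2], tol=1e-10)
        s = sqrtm(C1)
        si = np.linalg.inv(s)
        midpoint = s @ sqrtm(si @ C2 @ si) @ s
        assert np.abs(mean - midpoint.real).max() < 1e-8

    def test_permutation_invariance(self, rng):
        mats = [random_spd(rng, 4) for _ in range(5)]
        m1 = cn.frechet_mean(mats)
        m2 = cn.frechet_mean(mats[::-1])
        assert np.abs(m1 - m2).max() < 1e-6

    def test_congruence_equivariance(self, rng):
        mats = [random_spd(rng, 4) for _ in range(4)]
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        lhs = cn.frechet_mean([A @ m @ A.T for m in mats], tol=1e-10)
        rhs = A @ cn.frechet_mean(mats, tol=1e-10) @ A.T
        assert np.abs(lhs - rhs).max() < 1e-6 * np.abs(rhs).max()


class TestNormativeModel:
    def test_mask_size_formula(self):
        assert cn.mask_size(45 * 44 // 2) == 330
        assert cn.mask_size(3) == 1

    def test_fit_mask_and_mean(self, small_normative):
        _, _, mats, model = small_normative
        p = model.n_pairs
        assert model.n_masked_pairs == int(np.ceil(p / 3))
        # Karcher fixed point: the mean tangent at the reference is ~0
        rows, cols = cn.pair_index(model.n_regions)
        assert np.abs(model.pair_mean[rows, cols]).max() < 1e-2

    def test_identical_cohort_degenerate(self, rng):
        C = random_spd(rng, 4)
        with pytest.raises(cn.DegenerateCohortError):
            cn.fit_normative([C] * 5)

    def test_mask_tie_break_row_major(self):
        # three subjects built so two pairs tie exactly in tangent SD
        base = np.eye(3)
        mats = []
        for eps in (-0.1, 0.0, 0.1):
            m = base.copy()
            m[0, 1] = m[1, 0] = 0.3 + eps
            m[0, 2] = m[2, 0] = 0.3 + eps
            m[1, 2] = m[2, 1] = 0.01 * eps
            mats.append(m)
        model = cn.fit_normative(mats)
        rows, cols = cn.pair_index(3)
        sds = model.pair_sd[rows, cols]
        assert sds[0] == pytest.approx(sds[1], rel=1e-6)
        # ceil(3/3)=1 masked: one of the two tied high-variance pairs, and on
        # an exact tie the first in row-major order
        assert model.n_masked_pairs == 1
        assert model.variance_mask[0, 1] or model.variance_mask[0, 2]
        assert not model.variance_mask[1, 2]
        if sds[0] == sds[1]:
            assert model.variance_mask[0, 1]


class TestScoreAnomalies:
    def test_reference_patient_all_normal(self, small_normative):
        _, _, _, model = small_normative
        am = cn.score_anomalies(model.reference, model)
        assert len(am.anomalous_pairs()) == 0

    def test_boundary_z_exactly_3_is_normal(self, small_normative):
        _, _, _, model = small_normative
        rows, cols = cn.pair_index(model.n_regions)
        free = [(i, j) for i, j in zip(rows, cols) if not model.variance_mask[i, j]]
        i, j = free[0]
        t = model.pair_mean.copy()
        t[i, j] = t[j, i] = model.pair_mean[i, j] + 3.0 * model.pair_sd[i, j]
        patient = cn.tangent_inverse(t, model.reference)
        am = cn.score_anomalies(patient, model)
        assert abs(am.z_values[i, j] - 3.0) < 1e-8
        assert am.label(i, j) == "normal"
        # strictly beyond 3 flips to hyper
        t[i, j] = t[j, i] = model.pair_mean[i, j] + 3.2 * model.pair_sd[i, j]
        am2 = cn.score_anomalies(cn.tangent_inverse(t, model.reference), model)
        assert am2.label(i, j) == "hyper"

    def test_excluded_set_is_mask_plus_diagonal(self, small_normative):
        _, _, mats, model = small_normative
        am = cn.score_anomalies(mats[0], model)
        expected = model.variance_mask | np.eye(model.n_regions, dtype=bool)
        assert np.array_equal(am.excluded, expected)
        assert np.array_equal(am.codes, am.codes.T)

    def test_threshold_monotonicity(self, small_normative):
        """Raising sigma_threshold can only shrink the anomaly set."""
        _, cohort, mats, model = small_normative
        import dataclasses
        loose = dataclasses.replace(model, sigma_threshold=2.0)
        strict = dataclasses.replace(model, sigma_threshold=4.0)
        for m in mats[:5]:
            a_loose = {(i, j) for i, j, _ in cn.score_anomalies(m, loose).anomalous_pairs()}
            a_mid = {(i, j) for i, j, _ in cn.score_anomalies(m, model).anomalous_pairs()}
            a_strict = {(i, j) for i, j, _ in cn.score_anomalies(m, strict).anomalous_pairs()}
            assert a_strict <= a_mid <= a_loose

    def test_size_mismatch(self, small_normative, rng):
        _, _, _, model = small_normative
        with pytest.raises(ValueError, match="does not match"):
            cn.score_anomalies(random_spd(rng, 3), model)


def _anomaly_with(pairs, R, labels):
    codes = np.zeros((R, R), dtype=np.int8)
    for i, j, c in pairs:
        codes[i, j] = codes[j, i] = c
    excluded = np.eye(R, dtype=bool)
    return cn.AnomalyMatrix(codes, excluded, np.full((R, R), np.nan),
                            region_labels=labels)


class TestCountAnomalies:
    def setup_method(self):
        self.labels = [
            RegionLabel("SCEF", "R", "cortical"),
            RegionLabel("SCEF", "L", "cortical"),
            RegionLabel("Thalamus", "R", "subcortical"),
            RegionLabel("Thalamus", "L", "subcortical"),
        ]

    def test_all_normal_zero(self):
        am = _anomaly_with([], 4, self.labels)
        counts = cn.count_anomalies(am, lesion_side="right")
        assert counts.per_region[["hypo_count", "hyper_count"]].to_numpy().sum() == 0

    def test_single_hyper_pair_counted_at_both_endpoints(self):
        # hyper pair between right SCEF and right thalamus, right lesion
        am = _anomaly_with([(0, 2, cn.HYPER)], 4, self.labels)
        counts = cn.count_anomalies(am, lesion_side="right")
        df = counts.per_region.set_index(["region", "hemi"])
        assert df.loc[("SCEF", "R"), "hyper_count"] == 1
        assert df.loc[("Thalamus", "R"), "hyper_count"] == 1
        assert df.loc[("SCEF", "R"), "laterality"] == "ipsilesional"
        assert counts.total("hyper", laterality="ipsilesional") == 2
        assert counts.parcel_flag_count("hyper", laterality="ipsilesional") == 2
        assert counts.total("hypo") == 0

    def test_left_lesion_mirrors_right_lesion(self):
        """Mirroring the anomaly matrix across hemispheres and flipping the
        lesion side leaves laterality-stratified counts unchanged."""
        am_r = _anomaly_with([(0, 2, cn.HYPER), (1, 3, cn.HYPO)], 4, self.labels)
        am_l = _anomaly_with([(1, 3, cn.HYPER), (0, 2, cn.HYPO)], 4, self.labels)
        c_r = cn.count_anomalies(am_r, lesion_side="right")
        c_l = cn.count_anomalies(am_l, lesion_side="left")
        for lat in ("ipsilesional", "contralesional"):
            for d in ("hypo", "hyper"):
                assert c_r.total(d, laterality=lat) == c_l.total(d, laterality=lat)

    def test_totals_equal_per_region_sums(self):
        am = _anomaly_with([(0, 1, cn.HYPO), (2, 3, cn.HYPER), (0, 3, cn.HYPER)],
                           4, self.labels)
        counts = cn.count_anomalies(am, lesion_side="right")
        t = counts.totals()
        assert t["hypo_count"].sum() == counts.per_region["hypo_count"].sum()
        assert t["hyper_count"].sum() == counts.per_region["hyper_count"].sum()

    def test_unknown_lesion_side(self):
        am = _anomaly_with([], 4, self.labels)
        with pytest.raises(ValueError):
            cn.count_anomalies(am, lesion_side="bilateral")
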