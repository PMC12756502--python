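"""Group models, Mahalanobis ellipses, and the EM-like refinement loop."""

import numpy as np
import pytest
from scipy import stats

import docrefine as dr
from docrefine.errors import DegenerateGroupError, SeedSelectionError
from docrefine.refinement import (
    GroupModel,
    IterationRecord,
    RefinementState,
    e_step,
    pooled_covariance,
)


def fv(x, y, sid="p"):
    return dr.FeatureVector(dci=float(x), ici=float(y), subject_id=sid)


def model(mu, cov, ids=("a", "b", "c"), level=0.9):
    return GroupModel(
        centroid=np.asarray(mu, float),
        covariance=np.asarray(cov, float),
        level=level,
        member_ids=list(ids),
    )


class TestGroupModel:
    def test_hand_computed_covariance(self):
        pts = [fv(0, 0), fv(1, 0), fv(0, 1)]
        m = dr.fit_group_model(pts)
        np.testing.assert_allclose(m.centroid, [1 / 3, 1 / 3])
        # sample covariance (divisor n-1) of the three points by hand
        np.testing.assert_allclose(
            m.covariance, [[1 / 3, -1 / 6], [-1 / 6, 1 / 3]], atol=1e-12
        )

    def test_chi2_threshold_at_90(self):
        m = dr.fit_group_model([fv(0, 0), fv(1, 0), fv(0, 1)], level=0.9)
        assert m.chi2_threshold == pytest.approx(4.605, abs=5e-4)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateGroupError):
            dr.fit_group_model([fv(1, 1), fv(1, 1), fv(1, 1)])

    def test_too_few_members(self):
        with pytest.raises(DegenerateGroupError):
            dr.fit_group_model([fv(0, 0), fv(1, 1)])

    def test_ridge_rescues_near_collinear_cloud(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        pts = [fv(v, 2 * v + 1e-14 * rng.standard_normal(), str(i))
               for i, v in enumerate(x)]
        m = dr.fit_group_model(pts)
        assert np.linalg.eigvalsh(m.covariance)[0] > 0


class TestMahalanobis:
    def test_distance_to_own_centroid_is_zero(self):
        m = model([1.0, 2.0], np.eye(2))
        assert dr.mahalanobis_sq(fv(1, 2), m) == pytest.approx(0.0)

    def test_identity_reduces_to_euclidean(self):
        m = model([0.0, 0.0], np.eye(2))
        assert dr.mahalanobis_sq(fv(3, 4), m) == pytest.approx(25.0)

    def test_diagonal_hand_inversion(self):
        m = model([0.0, 0.0], np.diag([4.0, 1.0]))
        assert dr.mahalanobis_sq(fv(2, 1), m) == pytest.approx(2.0)

    def test_boundary_inclusive(self):
        m = model([0.0, 0.0], np.eye(2))
        d = np.sqrt(m.chi2_threshold)
        assert dr.inside_ellipse(fv(d, 0), m)
        assert not dr.inside_ellipse(fv(d + 1e-9, 0), m)
        assert dr.inside_ellipse(fv(0, 0), m)

    def test_monte_carlo_coverage(self):
        """~90% of draws from the model's own Gaussian land inside."""
        rng = np.random.default_rng(5)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        m = model([1.0, -1.0], cov)
        draws = rng.multivariate_normal(m.centroid, cov, size=100_000)
        diff = draws - m.centroid
        d2 = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
        assert np.mean(d2 <= m.chi2_threshold) == pytest.approx(0.90, abs=0.01)

    def test_affine_equivariance_of_containment(self):
        """Any invertible affine map of all points leaves verdicts fixed."""
        rng = np.random.default_rng(8)
        pts = rng.multivariate_normal([0.3, -0.2], [[1, 0.4], [0.4, 2]], 40)
        probes = rng.multivariate_normal([0.3, -0.2], [[1, 0.4], [0.4, 2]], 25)
        a = np.array([[2.0, 0.5], [-0.3, 1.5]])
        b = np.array([10.0, -4.0])
        m0 = dr.fit_group_model(pts)
        m1 = dr.fit_group_model(pts @ a.T + b)
        for p in probes:
            assert dr.inside_ellipse(p, m0) == dr.inside_ellipse(a @ p + b, m1)


class TestObjective:
    def make_state(self, uws_pts, hc_pts, uws_model, hc_model):
        features = {}
        sel = set()
        hc_ids = []
        for k, p in enumerate(uws_pts):
            sid = f"u{k}"
            features[sid] = fv(*p, sid)
            sel.add(sid)
        for k, p in enumerate(hc_pts):
            sid = f"h{k}"
            features[sid] = fv(*p, sid)
            hc_ids.append(sid)
        return RefinementState(
            iteration=1,
            selected_uws=sel,
            excluded_uws=set(),
            hc_ids=hc_ids,
            contrast=None,
            features=features,
            uws_model=uws_model,
            hc_model=hc_model,
            objective_value=0.0,
        )

    def test_lambda_zero_is_within_scatter_only(self):
        mu_u, mu_h = [0.5, 0.0], [3.0, 0.0]
        st_ = self.make_state(
            [(0, 0), (1, 0)], [(3, 1), (3, -1)],
            model(mu_u, np.eye(2), ids=["u0", "u1"]),
            model(mu_h, np.eye(2), ids=["h0", "h1"]),
        )
        assert dr.objective(st_, 0.0) == pytest.approx(0.25 + 0.25 + 1 + 1)

    def test_members_at_centroid_zero_scatter(self):
        st_ = self.make_state(
            [(1, 1), (1, 1)], [(4, 4), (4, 4)],
            model([1, 1], np.eye(2), ids=["u0", "u1"]),
            model([4, 4], np.eye(2), ids=["h0", "h1"]),
        )
        assert dr.objective(st_, 0.0) == pytest.approx(0.0)

    def test_hand_expanded_two_plus_two(self):
        # within: (0.25+0.25) + (1+1); between with pooled identity:
        # ||(0.5,0)-(3,0)||^2 = 6.25; L = 2.5 - 6.25
        st_ = self.make_state(
            [(0, 0), (1, 0)], [(3, 1), (3, -1)],
            model([0.5, 0.0], np.eye(2), ids=["u0", "u1"]),
            model([3.0, 0.0], np.eye(2), ids=["h0", "h1"]),
        )
        assert dr.objective(st_, 1.0) == pytest.approx(2.5 - 6.25)

    def test_pooled_covariance_weighted(self):
        m1 = model([0, 0], np.eye(2), ids=list("abcd"))  # n=4
        m2 = model([0, 0], 3 * np.eye(2), ids=list("ab"))  # n=2
        np.testing.assert_allclose(
            pooled_covariance(m1, m2), (3 * np.eye(2) + 1 * 3 * np.eye(2)) / 4
        )


class TestEStep:
    def make_state(self, features, selected, model_):
        sel = set(selected)
        return RefinementState(
            iteration=1,
            selected_uws=sel,
            excluded_uws=set(features) - sel,
            hc_ids=[],
            contrast=None,
            features={k: fv(*v, k) for k, v in features.items()},
            uws_model=model_,
            hc_model=model_,
            objective_value=0.0,
        )

    def test_all_inside_is_fixpoint(self):
        m = model([0, 0], np.eye(2))
        st_ = self.make_state(
            {"a": (0, 0), "b": (1, 0), "c": (0, 1)}, {"a", "b", "c"}, m
        )
        assert e_step(st_) == {"a", "b", "c"}

    def test_planted_outlier_deselected(self):
        m = model([0, 0], np.eye(2))
        st_ = self.make_state(
            {"a": (0, 0), "b": (1, 0), "c": (0, 1), "out": (9, 9)},
            {"a", "b", "c", "out"},
            m,
        )
        assert e_step(st_) == {"a", "b", "c"}

    def test_excluded_point_at_centroid_reincluded(self):
        m = model([0, 0], np.eye(2))
        st_ = self.make_state(
            {"a": (0, 0.5), "b": (1, 0), "c": (0, 1), "back": (0, 0)},
            {"a", "b", "c"},
            m,
        )
        assert e_step(st_) == {"a", "b", "c", "back"}

    def test_collapse_raises_with_trace(self):
        m = model([0, 0], np.eye(2))
        st_ = self.make_state(
            {"a": (9, 9), "b": (-9, 9), "c": (9, -9)}, {"a", "b", "c"}, m
        )
        st_.trace = [IterationRecord(1, ["a"], np.zeros(2), np.zeros(2), 1, 1, 0.0)]
        with pytest.raises(dr.errors.CollapseError) as exc:
            e_step(st_)
        assert exc.value.trace


@pytest.fixture(scope="module")
def tight_cohort():
    """All UWS planted representative, well separated from HC."""
    bp = dr.CohortBlueprint(
        n_regions=20,
        n_timepoints=150,
        group_sizes={"HC": 10, "rep_UWS": 6, "exc_UWS": 0,
                     "rep_MCS": 5, "exc_MCS": 0},
        decreased_edge_fraction=0.2,
        increased_edge_fraction=0.1,
        severity_halfwidth=0.1,
        rep_uws_low_crsr_count=4,
        rng_seed=11,
    )
    cohort, ts, truth = dr.simulate_cohort(bp)
    return cohort, dr.compute_edge_vectors(ts), truth


class TestRefineLoop:
    def test_all_representative_label_stability(self, tight_cohort):
        cohort, ev, truth = tight_cohort
        res = dr.refine(cohort, ev, dr.RefinementConfig())
        assert res.converged_by == "label_stability"
        assert res.final_state.iteration <= 2
        assert res.representative_uws == set(cohort.ids("UWS"))

    def test_partition_soundness(self, tight_cohort):
        cohort, ev, truth = tight_cohort
        res = dr.refine(cohort, ev, dr.RefinementConfig())
        assert res.representative_uws | res.excluded_uws == set(cohort.ids("UWS"))
        assert res.representative_mcs | res.excluded_mcs == set(cohort.ids("MCS"))
        assert not res.representative_uws & res.excluded_uws
        assert not res.representative_mcs & res.excluded_mcs

    def test_converged_membership_is_fixpoint(self, tight_cohort):
        """Re-seeding the E/M alternation with the converged representative
        set reproduces the same partition."""
        cohort, ev, truth = tight_cohort
        res = dr.refine(cohort, ev, dr.RefinementConfig())
        refiner = dr.Refiner(cohort, ev, dr.RefinementConfig())
        state = refiner.m_step(res.representative_uws, iteration=1)
        assert e_step(state) == res.representative_uws

    def test_m_step_idempotent_on_fixpoint(self, tight_cohort):
        cohort, ev, truth = tight_cohort
        refiner = dr.Refiner(cohort, ev, dr.RefinementConfig())
        sel = dr.select_seed_uws(cohort, 5)
        s1 = refiner.m_step(sel, iteration=1)
        s2 = refiner.m_step(sel, iteration=2)
        shift = np.linalg.norm(s1.uws_model.centroid - s2.uws_model.centroid)
        assert shift < 1e-12  # same membership -> identical recomputation

    def test_trace_records_each_iteration(self, tight_cohort):
        cohort, ev, truth = tight_cohort
        res = dr.refine(cohort, ev, dr.RefinementConfig())
        iters = [r.iteration for r in res.final_state.trace]
        assert iters == list(range(1, res.final_state.iteration + 1))

    def test_max_iter_safeguard(self, small_cohort):
        cohort, _, truth, ev = small_cohort
        res = dr.refine(cohort, ev, dr.RefinementConfig(max_iter=1))
        assert res.final_state.iteration == 1

    def test_missing_seed_aborts(self, small_cohort):
        cohort, _, truth, ev = small_cohort
        with pytest.raises(SeedSelectionError):
            dr.refine(cohort, ev, dr.RefinementConfig(seed_max_crsr=0))

    def test_m_step_centroid_moves_toward_planted_mean(self, small_cohort):
        """Growing the selected set toward the full planted representative
        group moves the UWS centroid toward that group's feature mean."""
        cohort, _, truth, ev = small_cohort
        refiner = dr.Refiner(cohort, ev, dr.RefinementConfig())
        seed = dr.select_seed_uws(cohort, 5)
        rep = set(truth.ids("rep_UWS"))
        s_seed = refiner.m_step(seed, iteration=1)
        s_full = refiner.m_step(rep, iteration=2)
        planted_mean = np.mean(
            [s_full.features[i].as_array() for i in sorted(rep)], axis=0
        )
        d_seed = np.linalg.norm(s_seed.uws_model.centroid - planted_mean)
        d_full = np.linalg.norm(s_full.uws_model.centroid - planted_mean)
        assert d_full < d_seed


class TestFineTune:
    def test_disabled_flag_leaves_result_unchanged(self, small_cohort):
        cohort, _, truth, ev = small_cohort
        res_off = dr.refine(cohort, ev, dr.RefinementConfig(fine_tune=False))
        res_off2 = dr.refine(cohort, ev, dr.RefinementConfig(fine_tune=False))
        assert res_off.representative_uws == res_off2.representative_uws

    def test_fine_tune_never_increases_objective(self, small_cohort):
        cohort, _, truth, ev = small_cohort
        refiner = dr.Refiner(cohort, ev, dr.RefinementConfig(fine_tune=True))
        res = refiner.run()
        pre = dr.Refiner(cohort, ev, dr.RefinementConfig(fine_tune=False)).run()
        assert (
            res.final_state.objective_value
            <= pre.final_state.objective_value + 1e-9
        )

    def test_no_candidates_returns_same_state(self, small_cohort):
        cohort, _, truth, ev = small_cohort
        refiner = dr.Refiner(
            cohort, ev, dr.RefinementConfig(fine_tune=True, fine_tune_band=1e-9)
        )
        state = refiner.m_step(dr.select_seed_uws(cohort, 5), iteration=1)
        assert refiner.fine_tune(state) is state


class TestEllipseCoverage:
    def test_fitted_ellipse_holds_level_out_of_sample(self):
        """A 90% ellipse fit on a large Gaussian sample contains ~90% of
        held-out draws from the same distribution."""
        rng = np.random.default_rng(17)
        cov = np.array([[1.5, -0.6], [-0.6, 0.8]])
        fit = rng.multivariate_normal([0.1, 0.2], cov, size=5000)
        held = rng.multivariate_normal([0.1, 0.2], cov, size=50_000)
        m = dr.fit_group_model(fit)
        diff = held - m.centroid
        d2 = np.einsum(
            "ij,ij->i", diff, np.linalg.solve(m.covariance, diff.T).T
        )
        assert np.mean(d2 <= m.chi2_threshold) == pytest.approx(0.90, abs=0.02)
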