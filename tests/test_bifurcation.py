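import numpy as np
import pytest

from cbb_ants import (
    bifurcation_diagram,
    compute_mu_double_star,
    compute_mu_star,
    lyapunov_instability_demo,
    lyapunov_rho,
    sotomayor_check,
)


class TestSotomayor:
    def test_full_system_transcritical_at_mu_star(self, baseline):
        res = sotomayor_check("E3", baseline)
        assert res.mu_bif == pytest.approx(compute_mu_star(baseline))
        assert res.c1 == 0.0
        assert res.c2 == pytest.approx(-1.65441, abs=1e-4)
        assert res.c3 == pytest.approx(-0.0021429, abs=1e-6)
        assert res.verdict == "transcritical"

    def test_reduced_system_transcritical_at_mu_double_star(self, baseline):
        res = sotomayor_check("E1_reduced", baseline)
        assert res.mu_bif == pytest.approx(0.85)
        assert res.c1 == 0.0
        assert res.c2 == pytest.approx(-0.47059, abs=1e-4)
        assert res.c3 == pytest.approx(-0.0011429, abs=1e-6)
        assert res.verdict == "transcritical"

    def test_numeric_cross_check_agrees_with_closed_forms(self, baseline):
        for eq in ("E3", "E1_reduced"):
            res = sotomayor_check(eq, baseline)
            assert res.c1_numeric == pytest.approx(0.0, abs=1e-10)
            assert res.c2_numeric == pytest.approx(res.c2, rel=1e-4)
            assert res.c3_numeric == pytest.approx(res.c3, rel=1e-4)

    def test_null_eigenvectors_match_printed_normalisation(self, baseline):
        p = baseline
        res = sotomayor_check("E3", p)
        kdto = p.k * p.delta + p.theta + p.omega
        np.testing.assert_allclose(res.v, [kdto / p.phi, 1.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(res.w, [kdto / p.omega, 1.0, 0.0], atol=1e-10)

    def test_requires_zero_eigenvalue(self, baseline):
        with pytest.raises(ValueError, match="near-zero"):
            sotomayor_check("E3", baseline, mu_bif=0.5)

    def test_works_on_random_parameter_sets(self):
        from cbb_ants import sample_params

        for p in sample_params(n=10, seed=9):
            if compute_mu_star(p) > 0:
                assert sotomayor_check("E3", p).verdict == "transcritical"
            assert sotomayor_check("E1_reduced", p).verdict == "transcritical"


class TestLyapunovDemo:
    def test_neighbourhood_radius(self, baseline):
        # min( r / (eps*sqrt(alpha^2+delta^2)), k )
        assert lyapunov_rho(baseline) == pytest.approx(3.5355, abs=1e-4)
        assert lyapunov_rho(baseline.replace(r=10.0)) == baseline.k
        assert lyapunov_rho(baseline.replace(alpha=0.0, delta=0.0)) == baseline.k

    def test_extinction_state_repels_in_the_nonhyperbolic_regime(self, baseline):
        # B0 = 1 (mu = mu**): classical linearisation is silent, but V = H
        # still strictly increases and every trajectory leaves the ball S
        p = baseline.replace(mu=compute_mu_double_star(baseline))
        demo = lyapunov_instability_demo(p, n_starts=20, seed=20230675)
        assert demo.all_escaped
        assert demo.min_dVdt_inside > 0.0
        assert np.all(np.linalg.norm(demo.sample_starts, axis=1) < demo.rho / 2)
        assert np.all(demo.sample_starts[:, 2] > 0)

    def test_demo_is_seed_deterministic(self, baseline):
        a = lyapunov_instability_demo(baseline, n_starts=5, seed=1)
        b = lyapunov_instability_demo(baseline, n_starts=5, seed=1)
        np.testing.assert_array_equal(a.sample_starts, b.sample_starts)
        np.testing.assert_array_equal(a.escape_times, b.escape_times)


@pytest.fixture(scope="module")
def diagram(baseline):
    return bifurcation_diagram(baseline, 0.01, 1.0, n_grid=100)


class TestBifurcationDiagram:
    def test_critical_values_recorded(self, diagram, baseline):
        assert diagram.bif_points["mu_star"] == pytest.approx(compute_mu_star(baseline))
        assert diagram.bif_points["mu_double_star"] == pytest.approx(0.85)

    def test_coexistence_branch_keeps_ants_at_capacity(self, diagram, baseline):
        e4 = diagram.branches.query("label == 'E4' and biological_sense")
        assert not e4.empty
        assert np.allclose(e4["H"], baseline.k)

    def test_ants_only_branch_flips_stability_once_at_mu_star(self, diagram, baseline):
        e3 = diagram.branches.query("label == 'E3'").sort_values("mu")
        flips = np.flatnonzero(np.diff(e3["stable"].astype(int)) != 0)
        # one flip; the nonhyperbolic grid point at mu* itself counts as not-LAS
        mu_vals = e3["mu"].to_numpy()
        flip_mus = mu_vals[flips]
        assert np.all(np.abs(flip_mus - compute_mu_star(baseline)) < 0.02)
        assert 1 <= len(flips) <= 2

    def test_borers_only_branch_shrinks_to_origin_at_mu_double_star(self, diagram):
        e2 = diagram.branches.query("label == 'E2' and biological_sense").sort_values("mu")
        below = e2[e2["mu"] < 0.85]
        assert below["A"].iloc[-1] < below["A"].iloc[0]
        near = e2[np.isclose(e2["mu"], 0.85)]
        assert np.allclose(near[["A", "I", "H"]], 0.0, atol=1e-9)

    def test_stability_switches_only_at_critical_values(self, diagram):
        for label, group in diagram.branches.groupby("label"):
            group = group.sort_values("mu")
            changes = group["mu"].to_numpy()[1:][
                np.diff(group["stable"].astype(int)) != 0
            ]
            for mu in changes:
                assert (
                    abs(mu - diagram.bif_points["mu_star"]) < 0.02
                    or abs(mu - diagram.bif_points["mu_double_star"]) < 0.02
                )

    def test_warns_when_grid_misses_critical_values(self, baseline):
        with pytest.warns(UserWarning, match="does not contain"):
            bifurcation_diagram(baseline, 0.2, 0.5, n_grid=10)
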