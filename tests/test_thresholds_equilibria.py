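import numpy as np
import pytest

from cbb_ants import (
    compute_B0,
    compute_Psi0,
    compute_mu_double_star,
    compute_mu_star,
    compute_thresholds,
    equilibria,
    reduced_equilibria,
    reduced_rhs,
    rhs,
    sample_params,
    sample_states_in_omega,
)
from helpers import find_roots_from_starts, matches_some


@pytest.mark.parametrize(
    "mu, expected_B0, expected_Psi0",
    [
        (0.03, 28.33, 1.1930),
        (0.5, 1.7, 0.5333),
        (0.85, 1.0, 0.3778),
    ],
)
def test_net_reproduction_rates_at_reference_mortalities(baseline, mu, expected_B0, expected_Psi0):
    assert compute_B0(baseline, mu=mu) == pytest.approx(expected_B0, abs=5e-3)
    assert compute_Psi0(baseline, mu=mu) == pytest.approx(expected_Psi0, abs=5e-5)


def test_thresholds_at_exact_collision_mortality(baseline):
    mu_star = compute_mu_star(baseline)
    assert mu_star == pytest.approx(0.1033, abs=5e-5)
    assert compute_Psi0(baseline, mu=mu_star) == pytest.approx(1.0, rel=1e-12)
    assert compute_B0(baseline, mu=mu_star) == pytest.approx(8.2258, abs=5e-5)


def test_critical_mortalities(baseline):
    assert compute_mu_double_star(baseline) == pytest.approx(0.85)
    assert compute_mu_star(baseline.replace(alpha=0.011, delta=0.011)) == pytest.approx(
        0.0481, abs=5e-5
    )
    # doubling the oviposition rate doubles mu**
    assert compute_mu_double_star(baseline.replace(phi=2 * baseline.phi)) == pytest.approx(1.7)
    # Psi0 at mu = mu** stays below one when predation acts
    assert compute_Psi0(baseline, mu=0.85) < 1.0


def test_predator_free_limit_of_Psi0(baseline):
    # as k -> 0 the with-predator threshold degenerates to B0
    tiny_k = baseline.replace(k=1e-12)
    assert compute_Psi0(tiny_k) == pytest.approx(compute_B0(baseline), rel=1e-9)
    assert compute_mu_star(tiny_k) == pytest.approx(compute_mu_double_star(baseline), rel=1e-9)


def test_threshold_ordering_on_random_parameters():
    # Psi0 < B0 and mu* < mu** whenever the predator is present
    for p in sample_params(n=500, seed=202):
        t = compute_thresholds(p)
        assert t.Psi0 < t.B0
        assert t.mu_star < t.mu_double_star
        assert t.B0 > 0 and t.Psi0 > 0


def test_negative_mu_star_reported_verbatim(baseline):
    # strong predation pushes mu* below zero: eradication for every mu > 0
    p = baseline.replace(alpha=1.0)
    t = compute_thresholds(p)
    assert t.mu_star < 0
    assert t.eradication_for_all_mu


def test_equilibria_coordinates(baseline):
    eqs, collisions = equilibria(baseline)
    by_label = {e.label: e for e in eqs}
    np.testing.assert_array_equal(by_label["E1"].coords, np.zeros(3))
    np.testing.assert_allclose(by_label["E3"].coords, [0.0, 0.0, 35.0])
    np.testing.assert_allclose(by_label["E2"].coords, [3826.67, 675.29, 0.0], atol=5e-3)
    np.testing.assert_allclose(by_label["E4"].coords, [50.66, 113.24, 35.0], atol=5e-3)
    assert all(e.biological_sense for e in eqs)
    assert collisions == []


def test_equilibria_collisions_at_critical_mortalities(baseline):
    at_star = baseline.replace(mu=compute_mu_star(baseline))
    eqs, collisions = equilibria(at_star)
    by_label = {e.label: e for e in eqs}
    assert by_label["E4"].collided_with == "E3"
    assert not by_label["E4"].exists_distinct
    np.testing.assert_allclose(by_label["E4"].coords, by_label["E3"].coords, atol=1e-9)
    assert [(c.pair, c.condition) for c in collisions] == [(("E4", "E3"), "Psi0 = 1")]

    at_dstar = baseline.replace(mu=compute_mu_double_star(baseline))
    eqs, collisions = equilibria(at_dstar)
    by_label = {e.label: e for e in eqs}
    assert by_label["E2"].collided_with == "E1"
    np.testing.assert_allclose(by_label["E2"].coords, np.zeros(3), atol=1e-9)
    assert [(c.pair, c.condition) for c in collisions] == [(("E2", "E1"), "B0 = 1")]


def test_borers_only_equilibrium_loses_sense_below_threshold(baseline):
    eqs, _ = equilibria(baseline.replace(mu=1.7))  # B0 = 0.5
    by_label = {e.label: e for e in eqs}
    assert not by_label["E2"].biological_sense
    assert not by_label["E4"].biological_sense
    assert by_label["E1"].biological_sense and by_label["E3"].biological_sense


def test_coexistence_branch_is_continuous_at_the_bifurcation(baseline):
    mu_star = compute_mu_star(baseline)
    e3 = np.array([0.0, 0.0, baseline.k])
    gaps = []
    for d_mu in (1e-3, 1e-5, 1e-7):
        eqs, _ = equilibria(baseline.replace(mu=mu_star - d_mu))
        e4 = next(e for e in eqs if e.label == "E4")
        gaps.append(np.linalg.norm(e4.coords - e3))
    assert gaps[0] > gaps[1] > gaps[2]
    assert gaps[2] < 1e-3


def test_reduced_equilibria(baseline):
    e1, e2 = reduced_equilibria(baseline)
    np.testing.assert_array_equal(e1.coords, np.zeros(2))
    np.testing.assert_allclose(e2.coords, [3826.67, 675.29], atol=5e-3)
    full_e2 = next(e for e in equilibria(baseline)[0] if e.label == "E2")
    np.testing.assert_allclose(e2.coords, full_e2.coords[:2])
    assert np.linalg.norm(reduced_rhs(e2.coords, baseline)) < 1e-8 * (
        1 + np.linalg.norm(e2.coords)
    )
    # at mu = mu** the borer equilibrium collides with the origin
    collided = reduced_equilibria(baseline.replace(mu=0.85))[1]
    np.testing.assert_allclose(collided.coords, np.zeros(2), atol=1e-12)
    assert collided.collided_with == "E1_reduced"


def test_numeric_root_search_finds_only_the_four_equilibria():
    """Newton searches from random starts in the invariant box recover no
    equilibrium in the non-negative octant besides E1..E4."""
    for i, p in enumerate(sample_params(n=20, seed=42)):
        references = [e.coords for e in equilibria(p)[0]]
        starts = sample_states_in_omega(p, n=20, seed=900 + i)
        for root_pt in find_roots_from_starts(p, starts):
            if matches_some(root_pt, references, tol=1e-6):
                continue
            # anything else must lie outside the octant, on the ant-growth
            # degeneracy line r + eps*(alpha*A + delta*I) = 0
            assert not np.all(root_pt >= -1e-9), (
                f"unexpected admissible equilibrium {root_pt} for params {p}"
            )
            assert p.r + p.epsilon * (
                p.alpha * root_pt[0] + p.delta * root_pt[1]
            ) == pytest.approx(0.0, abs=1e-6)
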