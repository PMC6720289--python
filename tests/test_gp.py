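import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepgp import (
    DeviationConfig,
    IndicatorPanel,
    evaluate_weights,
    grid_oracle,
    known_answer_panel,
    solve_extended,
    solve_minmax,
    solve_wgp,
)
from mepgp.gp import simplex_lattice

from conftest import assert_solution_identities, make_random_panel


class TestKnownAnswers:
    @pytest.mark.parametrize("case_id", ["single_indicator", "duplicate_columns"])
    @pytest.mark.parametrize(
        "solve", [solve_wgp, solve_minmax, lambda p: solve_extended(p, 0.5)],
        ids=["wgp", "minmax", "extended"],
    )
    def test_exactly_attainable_goals(self, case_id, solve):
        """A single goal (or duplicated goals) can be matched with zero deviation."""
        panel, expected = known_answer_panel(case_id)
        sol = solve(panel)
        assert_solution_identities(sol, panel)
        assert sol.z == pytest.approx(expected["z"], abs=1e-6)
        assert sol.d == pytest.approx(expected["d"], abs=1e-6)
        np.testing.assert_allclose(sol.mep, expected["mep"], atol=1e-6)

    def test_hand_2x2_evaluation(self):
        panel, expected = known_answer_panel("hand_2x2")
        ev = evaluate_weights(panel, expected["weights"])
        np.testing.assert_allclose(ev.mep, expected["mep"])
        np.testing.assert_allclose(ev.disagreements, expected["disagreements"])
        assert ev.z == expected["z"]
        assert ev.d == expected["d"]
        assert ev.z_weighted == expected["z"]


class TestEvaluateWeights:
    def test_unit_weight_zeroes_target_column(self, small_panel):
        m = small_panel.n_indicators
        for j in range(m):
            w = np.zeros(m)
            w[j] = 1.0
            ev = evaluate_weights(small_panel, w)
            assert ev.disagreements[j] == pytest.approx(0.0, abs=1e-12)

    def test_positive_homogeneity(self, small_panel):
        w = np.array([0.2, 0.3, 0.5])
        half = IndicatorPanel(
            small_panel.country_ids, small_panel.indicator_codes, small_panel.scores * 0.5
        )
        ev1 = evaluate_weights(small_panel, w)
        ev2 = evaluate_weights(half, w)
        assert ev2.z == pytest.approx(0.5 * ev1.z)
        assert ev2.d == pytest.approx(0.5 * ev1.d)
        np.testing.assert_allclose(ev2.disagreements, 0.5 * ev1.disagreements)

    def test_simplex_violation_rejected(self, small_panel):
        with pytest.raises(ValueError):
            evaluate_weights(small_panel, np.array([0.6, 0.6, -0.2]))

    @settings(deadline=None, max_examples=25, derandomize=True, database=None)
    @given(data=st.data())
    def test_accounting_identities_hold_for_any_weights(self, data):
        n = data.draw(st.integers(2, 5))
        m = data.draw(st.integers(2, 4))
        cells = data.draw(
            st.lists(st.integers(0, 100), min_size=n * m, max_size=n * m)
        )
        raw_w = data.draw(
            st.lists(st.floats(0.01, 1.0, allow_nan=False), min_size=m, max_size=m)
        )
        panel = IndicatorPanel(
            [f"C{i}" for i in range(n)],
            [f"X{j}" for j in range(m)],
            np.array(cells, dtype=float).reshape(n, m),
        )
        w = np.array(raw_w) / np.sum(raw_w)
        ev = evaluate_weights(panel, w)
        assert ev.z == pytest.approx(ev.disagreements.sum())
        assert ev.d == pytest.approx(ev.disagreements.max())
        assert (ev.mep >= panel.scores.min(axis=1) - 1e-9).all()
        assert (ev.mep <= panel.scores.max(axis=1) + 1e-9).all()


class TestGridOracle:
    def test_lattice_m2_step_half(self):
        pts = simplex_lattice(2, 2)
        assert sorted(map(tuple, pts.tolist())) == [(0, 2), (1, 1), (2, 0)]

    def test_single_indicator_oracle(self):
        panel, _ = known_answer_panel("single_indicator")
        best, w = grid_oracle(panel, step=0.5)
        assert best == pytest.approx(0.0)
        np.testing.assert_allclose(w, [1.0])

    def test_grid_guard(self, rng):
        panel = make_random_panel(rng, 3, 8)
        with pytest.raises(ValueError, match="guard"):
            grid_oracle(panel, step=0.001)

    @pytest.mark.parametrize("criterion, solve", [
        ("z_weighted", solve_wgp),
        ("d", solve_minmax),
    ])
    def test_lp_never_exceeds_lattice_minimum(self, rng, criterion, solve):
        """The lattice is a restriction of the LP's feasible set."""
        for _ in range(5):
            panel = make_random_panel(rng, 4, 3)
            sol = solve(panel)
            lp_obj = sol.z_weighted if criterion == "z_weighted" else sol.d
            best, _ = grid_oracle(panel, step=0.01, criterion=criterion)
            assert lp_obj <= best + 1e-9

    def test_gap_shrinks_with_step(self, rng):
        """Nested lattices: refining the grid can only lower the oracle minimum."""
        panel = make_random_panel(rng, 4, 3)
        lp = solve_wgp(panel).z_weighted
        gaps = []
        for step in (0.1, 0.01, 0.001):
            best, _ = grid_oracle(panel, step=step)
            gaps.append(best - lp)
        assert all(g >= -1e-9 for g in gaps)
        assert gaps[0] >= gaps[1] >= gaps[2] - 1e-12

    def test_composite_criterion_needs_lam(self, small_panel):
        with pytest.raises(ValueError, match="lam"):
            grid_oracle(small_panel, step=0.5, criterion="composite")


class TestModelRelations:
    def test_extended_limits(self, rng):
        for _ in range(3):
            panel = make_random_panel(rng, 6, 3)
            assert solve_extended(panel, 1.0).z_weighted == pytest.approx(
                solve_wgp(panel).z_weighted, abs=1e-6
            )
            assert solve_extended(panel, 0.0).d == pytest.approx(
                solve_minmax(panel).d, abs=1e-6
            )

    def test_intermediate_lam_beats_endpoint_solutions(self, rng):
        """The lam=0.5 optimum dominates the composite value of either endpoint solution."""
        panel = make_random_panel(rng, 4, 3)
        mid = solve_extended(panel, 0.5)
        for endpoint in (solve_wgp(panel), solve_minmax(panel)):
            composite = 0.5 * endpoint.z_weighted + 0.5 * endpoint.d
            assert mid.objective <= composite + 1e-7

    def test_lam_domain_error(self, small_panel):
        with pytest.raises(ValueError, match="lam"):
            solve_extended(small_panel, 1.5)

    def test_permutation_equivariance(self, rng):
        panel = make_random_panel(rng, 6, 3)
        perm = rng.permutation(panel.n_countries)
        shuffled = IndicatorPanel(
            [panel.country_ids[i] for i in perm],
            panel.indicator_codes,
            panel.scores[perm],
        )
        a, b = solve_wgp(panel), solve_wgp(shuffled)
        assert b.z_weighted == pytest.approx(a.z_weighted, abs=1e-7)
        assert b.d == pytest.approx(a.d, abs=1e-6)
        np.testing.assert_allclose(b.weights, a.weights, atol=1e-7)
        np.testing.assert_allclose(b.mep, a.mep[perm], atol=1e-6)

    def test_backends_agree(self, small_panel):
        z = {s: solve_wgp(small_panel, solver=s).z_weighted for s in ("highs", "highs-ds")}
        assert z["highs"] == pytest.approx(z["highs-ds"], abs=1e-6)


class TestDeviationConfig:
    def test_default_is_all_ones(self, small_panel):
        sol = solve_wgp(small_panel)
        assert sol.z_weighted == pytest.approx(sol.z)

    def test_both_directions_unpenalized_rejected(self):
        with pytest.raises(ValueError, match="alpha_j \\+ beta_j"):
            DeviationConfig(np.array([1.0, 0.0]), np.array([1.0, 0.0]))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            DeviationConfig(np.array([0.5, 1.0]), np.array([1.0, 1.0]))

    def test_one_sided_penalty_weakens_objective(self, rng):
        """Dropping penalties can only lower the optimal penalized deviation sum."""
        panel = make_random_panel(rng, 5, 3)
        full = solve_wgp(panel)
        one_sided = DeviationConfig(np.array([1.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]))
        relaxed = solve_wgp(panel, one_sided)
        assert_solution_identities(relaxed, panel)
        assert relaxed.z_weighted <= full.z_weighted + 1e-7

    def test_length_mismatch_rejected(self, small_panel):
        with pytest.raises(ValueError, match="length"):
            solve_wgp(small_panel, DeviationConfig(np.ones(2), np.ones(2)))
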