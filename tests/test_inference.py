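"""Exact slice inference vs joint enumeration; MAP-propagated forecasting."""

import numpy as np
import pytest

from scdforecast import (
    EvidenceError,
    forecast,
    forward_sample,
    initial_network,
    map_states,
    slice_posteriors,
)

from conftest import enumerate_posteriors, make_model, make_registry, random_network


class TestSlicePosteriors:
    def test_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(2024)
        for rep in range(8):
            n_nodes = int(rng.integers(3, 11))
            reg, parents, network = random_network(rng, n_nodes)
            n_evidence = int(rng.integers(0, n_nodes // 2 + 1))
            ev_vars = rng.choice(reg.names, size=n_evidence, replace=False)
            evidence = {v: int(rng.integers(0, reg.k(v))) for v in ev_vars}
            expected, _ = enumerate_posteriors(reg, network, evidence)
            got = slice_posteriors(network, evidence, reg)
            for v in reg.names:
                np.testing.assert_allclose(got[v], expected[v], atol=1e-9)

    def test_chain_with_downstream_evidence(self):
        # A -> B -> C, evidence on C; P(A | C) by hand enumeration
        reg = make_registry([("A", 2, "dynamic"), ("B", 2, "dynamic"), ("C", 2, "outcome")])
        a = np.array([0.6, 0.4])
        b = np.array([[0.9, 0.1], [0.3, 0.7]])
        c = np.array([[0.8, 0.2], [0.25, 0.75]])
        network = {"A": ((), a), "B": (("A",), b), "C": (("B",), c)}
        post = slice_posteriors(network, {"C": 1}, reg)
        # P(A=0, C=1) = 0.6*(0.9*0.2 + 0.1*0.75); P(A=1, C=1) = 0.4*(0.3*0.2+0.7*0.75)
        p0 = 0.6 * (0.9 * 0.2 + 0.1 * 0.75)
        p1 = 0.4 * (0.3 * 0.2 + 0.7 * 0.75)
        np.testing.assert_allclose(post["A"], [p0 / (p0 + p1), p1 / (p0 + p1)], atol=1e-12)

    def test_evidence_on_all_parents_gives_cpt_row(self):
        rng = np.random.default_rng(5)
        reg, parents, network = random_network(rng, 6)
        child = reg.names[-1]
        par = network[child][0]
        evidence = {p: 0 for p in par}
        post = slice_posteriors(network, evidence, reg)
        np.testing.assert_allclose(
            post[child], network[child][1][(0,) * len(par)], atol=1e-9
        )

    def test_no_evidence_gives_prior_marginals(self):
        rng = np.random.default_rng(11)
        reg, parents, network = random_network(rng, 5)
        expected, _ = enumerate_posteriors(reg, network, {})
        got = slice_posteriors(network, {}, reg)
        for v in reg.names:
            np.testing.assert_allclose(got[v], expected[v], atol=1e-9)

    def test_impossible_evidence_raises(self):
        reg = make_registry([("A", 2, "dynamic"), ("B", 2, "outcome")])
        network = {"A": ((), np.array([1.0, 0.0])), "B": (("A",), np.eye(2))}
        with pytest.raises(EvidenceError):
            slice_posteriors(network, {"A": 1}, reg)


class TestMapStates:
    @pytest.mark.parametrize(
        "dist,expected",
        [((0.6, 0.4), 0), ((0.5, 0.5), 0), ((0.2, 0.3, 0.5), 2)],
    )
    def test_mode_with_low_index_ties(self, dist, expected):
        assert map_states({"v": np.array(dist)})["v"] == expected


@pytest.fixture
def deterministic_toy():
    """x flips each slice; y copies x; alpha=0 so hard 0/1 CPTs are legal."""
    reg = make_registry([("x", 2, "dynamic"), ("y", 2, "outcome")])
    return make_model(
        reg,
        parents={"y": ("x",)},
        initial_tables={"x": np.array([1.0, 0.0]), "y": np.eye(2)},
        transition_tables={"x": np.array([[0.0, 1.0], [1.0, 0.0]])},
        alpha=0.0,
    )


class TestForecast:
    def test_horizon_zero_equals_slice_posteriors(self, deterministic_toy):
        m = deterministic_toy
        fc = forecast(m, {}, 0)
        direct = slice_posteriors(initial_network(m), {}, m.registry)
        for v in m.registry.names:
            np.testing.assert_allclose(fc.posteriors[0][v], direct[v])

    def test_deterministic_trajectory(self, deterministic_toy):
        fc = forecast(deterministic_toy, {}, 3)
        xs = [mp["x"] for mp in fc.map_states]
        ys = [mp["y"] for mp in fc.map_states]
        assert xs == [0, 1, 0, 1] and ys == xs  # x alternates, y copies x

    def test_intervention_changes_only_later_slices(self, deterministic_toy):
        base = forecast(deterministic_toy, {}, 2)
        intervened = forecast(deterministic_toy, {1: {"x": 0}}, 2)
        np.testing.assert_array_equal(
            base.posteriors[0]["y"], intervened.posteriors[0]["y"]
        )
        assert intervened.map_states[1]["x"] == 0 != base.map_states[1]["x"]

    def test_full_evidence_reproduced_as_map(self, deterministic_toy):
        ev = {0: {"x": 0, "y": 0}, 1: {"x": 0, "y": 0}, 2: {"x": 1, "y": 1}}
        fc = forecast(deterministic_toy, ev, 2)
        for t, e in ev.items():
            for v, c in e.items():
                assert fc.map_states[t][v] == c

    def test_age_required_and_truncation(self):
        from scdforecast import GeneratorConfig, fit_model, generate, search_structure

        table, _ = generate(GeneratorConfig.default(300, seed=4))
        model = fit_model(table, search_structure(table))
        with pytest.raises(EvidenceError, match="age"):
            forecast(model, {0: {"gender": "woman"}}, 1)
        with pytest.warns(UserWarning, match="truncated"):
            fc = forecast(model, {0: {"age": "75"}}, 4)
        assert fc.truncated and fc.horizon == 1  # one step to 80, then stop

    def test_static_variables_carried_forward(self, deterministic_toy):
        reg = make_registry([("g", 2, "static"), ("x", 2, "dynamic")])
        m = make_model(
            reg,
            parents={"x": ("g",)},
            initial_tables={"g": np.array([0.5, 0.5]),
                            "x": np.array([[0.9, 0.1], [0.1, 0.9]])},
            transition_tables={"x": np.array([[[0.9, 0.1], [0.1, 0.9]],
                                              [[0.9, 0.1], [0.1, 0.9]]]).transpose(0, 1, 2)},
        )
        fc = forecast(m, {0: {"g": 1}}, 2)
        assert all(mp["g"] == 1 for mp in fc.map_states)


class TestMonteCarloConsistency:
    def test_forward_samples_match_slice0_marginals(self):
        rng = np.random.default_rng(8)
        reg, parents, network = random_network(rng, 6)
        init = {v: network[v][1] for v in reg.names}
        model = make_model(reg, parents={v: network[v][0] for v in reg.names},
                           initial_tables=init,
                           transition_tables={})
        # dynamic vars need transitions for sampling beyond slice 0; horizon 0 here
        n = 100_000
        samples = forward_sample(model, {}, 0, n, seed=13)
        post = slice_posteriors(initial_network(model), {}, reg)
        for v in reg.names:
            freq = np.bincount(samples[v][:, 0], minlength=reg.k(v)) / n
            se = np.sqrt(post[v] * (1 - post[v]) / n) + 1e-12
            assert (np.abs(freq - post[v]) < 3 * se + 3e-3).all()

    def test_one_step_transition_from_fixed_state(self):
        reg = make_registry([("x", 2, "dynamic"), ("y", 2, "outcome")])
        trans = np.array([[0.25, 0.75], [0.6, 0.4]])
        m = make_model(
            reg,
            parents={"y": ("x",)},
            initial_tables={"x": np.array([1.0, 0.0]), "y": np.eye(2)},
            transition_tables={"x": trans},
            alpha=0.0,
        )
        n = 50_000
        s = forward_sample(m, {0: {"x": 0}}, 1, n, seed=21)
        freq = (s["x"][:, 1] == 1).mean()
        assert abs(freq - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)
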