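"""Scenario calculator, credible intervals, decision heatmap, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scdforecast import (
    EvidenceError,
    compare_scenarios,
    credible_interval,
    decision_heatmap,
    forecast,
    odds_ratio,
    outcome_cross_correlations,
)

from conftest import make_model, make_registry


class TestOddsRatio:
    @pytest.mark.parametrize(
        "pt,pc,expected",
        [(0.339, 0.402, 0.76), (0.3, 0.3, 1.0), (0.5, 0.25, 3.0)],
    )
    def test_examples(self, pt, pc, expected):
        assert round(odds_ratio(pt, pc), 2) == expected

    @given(
        st.floats(0.01, 0.99, allow_nan=False),
        st.floats(0.01, 0.99, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_reciprocal_identity(self, a, b):
        assert odds_ratio(a, b) * odds_ratio(b, a) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_boundary_rejected(self, bad):
        with pytest.raises(ValueError):
            odds_ratio(bad, 0.5)


@pytest.fixture
def intervention_toy():
    """Binary factor f drives outcome y: risk 0.8 if f=0, 0.2 if f=1."""
    reg = make_registry([("f", ("low", "high"), "dynamic"), ("y", ("good", "bad"), "outcome")])
    return make_model(
        reg,
        parents={"y": ("f",)},
        initial_tables={"f": np.array([1.0, 0.0]),
                        "y": np.array([[0.2, 0.8], [0.8, 0.2]])},
        transition_tables={"f": np.array([[1.0, 0.0], [0.0, 1.0]])},  # frozen
        alpha=0.0,
        counts_scale=1000.0,
    )


class TestCompareScenarios:
    def test_identity_scenario(self, intervention_toy):
        cur = {0: {"f": "low"}}
        cmp = compare_scenarios(intervention_toy, cur, dict(cur), 1, "y")
        assert cmp.absolute_reduction == 0.0 and cmp.odds_ratio == pytest.approx(1.0)

    def test_flip_toy_reduction_and_or(self, intervention_toy):
        cur = {0: {"f": "low"}}
        tgt = {0: {"f": "low"}, 1: {"f": "high"}}
        cmp = compare_scenarios(intervention_toy, cur, tgt, 1, "y")
        assert cmp.current_risk == pytest.approx(0.8)
        assert cmp.target_risk == pytest.approx(0.2)
        assert cmp.absolute_reduction == pytest.approx(60.0)
        assert cmp.odds_ratio == pytest.approx(0.0625)

    def test_antisymmetry(self, intervention_toy):
        reg = intervention_toy.registry
        cur = {0: {"f": "low"}, 1: {"f": "low"}}
        tgt = {0: {"f": "low"}, 1: {"f": "high"}}
        ab = compare_scenarios(intervention_toy, cur, tgt, 1, "y")
        ba = compare_scenarios(intervention_toy, tgt, cur, 1, "y")
        assert ab.odds_ratio * ba.odds_ratio == pytest.approx(1.0)
        assert ab.absolute_reduction == pytest.approx(-ba.absolute_reduction)

    def test_slice0_must_match(self, intervention_toy):
        with pytest.raises(EvidenceError):
            compare_scenarios(
                intervention_toy, {0: {"f": "low"}}, {0: {"f": "high"}}, 1, "y"
            )

    def test_non_outcome_rejected(self, intervention_toy):
        from scdforecast import SchemaError

        with pytest.raises(SchemaError):
            compare_scenarios(intervention_toy, {0: {"f": "low"}}, {0: {"f": "low"}}, 1, "f")


@pytest.fixture
def soft_toy():
    """Smoothed version of the intervention toy with modest counts."""
    reg = make_registry([("f", ("low", "high"), "dynamic"), ("y", ("good", "bad"), "outcome")])
    return make_model(
        reg,
        parents={"y": ("f",)},
        initial_tables={"f": np.array([0.7, 0.3]),
                        "y": np.array([[0.3, 0.7], [0.7, 0.3]])},
        transition_tables={"f": np.array([[0.9, 0.1], [0.2, 0.8]])},
        counts_scale=200.0,
    )


class TestCredibleInterval:
    CUR = {0: {"f": "low"}}
    TGT = {0: {"f": "low"}, 1: {"f": "high"}}

    def test_deterministic_for_fixed_seed(self, soft_toy):
        a = credible_interval(soft_toy, self.CUR, self.TGT, "y", 1, draws=200, seed=5)
        b = credible_interval(soft_toy, self.CUR, self.TGT, "y", 1, draws=200, seed=5)
        assert a == b

    def test_brackets_point_estimate(self, soft_toy):
        cmp = compare_scenarios(soft_toy, self.CUR, self.TGT, 1, "y")
        lo, hi = credible_interval(soft_toy, self.CUR, self.TGT, "y", 1, draws=2000, seed=7)
        assert lo < cmp.odds_ratio < hi

    def test_concentrates_with_infinite_data(self, soft_toy):
        import dataclasses

        big = dataclasses.replace(
            soft_toy,
            initial={k: dataclasses.replace(c, counts=c.counts * 1e6)
                     for k, c in soft_toy.initial.items()},
            transition={k: dataclasses.replace(c, counts=c.counts * 1e6)
                        for k, c in soft_toy.transition.items()},
        )
        cmp = compare_scenarios(big, self.CUR, self.TGT, 1, "y")
        lo, hi = credible_interval(big, self.CUR, self.TGT, "y", 1, draws=200, seed=3)
        assert hi - lo < 0.02 and lo < cmp.odds_ratio < hi

    def test_minimum_draws_enforced(self, soft_toy):
        with pytest.raises(ValueError):
            credible_interval(soft_toy, self.CUR, self.TGT, "y", 1, draws=50, seed=1)


@pytest.fixture
def heatmap_toy():
    """Two modifiable factors; only `act` moves the outcome."""
    reg = make_registry(
        [("act", ("inactive", "active"), "dynamic"),
         ("diet", ("poor", "good"), "dynamic"),
         ("y", ("good", "bad"), "outcome")]
    )
    return make_model(
        reg,
        parents={"y": ("act",)},
        initial_tables={
            "act": np.array([0.6, 0.4]),
            "diet": np.array([0.5, 0.5]),
            "y": np.array([[0.3, 0.7], [0.8, 0.2]]),
        },
        transition_tables={
            "act": np.array([[0.85, 0.15], [0.15, 0.85]]),
            "diet": np.array([[0.85, 0.15], [0.15, 0.85]]),
        },
        counts_scale=500.0,
    )


class TestDecisionHeatmap:
    CUR = {0: {"act": "inactive", "diet": "poor"}}

    def test_status_quo_delta_zero(self, heatmap_toy):
        m = decision_heatmap(heatmap_toy, self.CUR, "y")
        for f in m.factors:
            assert m.deltas[f][m.reference_level[f]] == 0.0

    def test_only_driving_factor_has_nonzero_deltas(self, heatmap_toy):
        m = decision_heatmap(heatmap_toy, self.CUR, "y")
        assert any(abs(d) > 1 for d in m.deltas["act"].values())
        assert all(abs(d) < 1e-9 for d in m.deltas["diet"].values())

    def test_cells_equal_direct_forecast(self, heatmap_toy):
        m = decision_heatmap(heatmap_toy, self.CUR, "y")
        for f in m.factors:
            for level in m.levels[f]:
                ev = {0: dict(self.CUR[0]), 1: {f: level}}
                fc = forecast(heatmap_toy, ev, 1)
                assert m.risks[f][level] == pytest.approx(
                    fc.outcome_probs[1]["y"], abs=1e-12
                )

    def test_dynamic_update_after_commit(self, heatmap_toy):
        first = decision_heatmap(heatmap_toy, self.CUR, "y")
        best = min(first.risks["act"], key=first.risks["act"].get)
        second = decision_heatmap(heatmap_toy, self.CUR, "y", committed=[("act", best)])
        assert second.baseline_risk == pytest.approx(first.risks["act"][best])
        assert second.reference_level["act"] == best

    def test_conflicting_commitments_rejected(self, heatmap_toy):
        with pytest.raises(EvidenceError, match="conflict"):
            decision_heatmap(
                heatmap_toy, self.CUR, "y",
                committed=[("act", "active"), ("act", "inactive")],
            )

    def test_render_text_mentions_levels(self, heatmap_toy):
        m = decision_heatmap(heatmap_toy, self.CUR, "y")
        text = m.render_text()
        assert "act" in text and "active=" in text


class TestCrossCorrelations:
    def test_independent_outcomes_near_zero(self):
        reg = make_registry(
            [("a", 2, "outcome"), ("b", 2, "health")]
        )
        m = make_model(
            reg, parents={},
            initial_tables={"a": np.array([0.6, 0.4]), "b": np.array([0.3, 0.7])},
        )
        out = outcome_cross_correlations(m, {}, horizon=0, seed=3, n_samples=20_000)
        phi = out["cross"]["phi"].to_numpy()
        assert (np.abs(phi) < 3 / np.sqrt(20_000)).all()

    def test_deterministic_persistence_autocorr_one(self):
        reg = make_registry([("x", 2, "dynamic"), ("y", 2, "outcome")])
        m = make_model(
            reg,
            parents={"y": ("x",)},
            initial_tables={"x": np.array([0.5, 0.5]), "y": np.eye(2)},
            transition_tables={"x": np.eye(2)},  # perfect persistence
            alpha=0.0,
        )
        out = outcome_cross_correlations(m, {}, horizon=2, seed=9, n_samples=5000)
        lag1 = out["auto"].query("var == 'y' and lag == 1")["phi"].iloc[0]
        assert lag1 == pytest.approx(1.0)

    def test_reproducible_for_fixed_seed(self, heatmap_toy):
        a = outcome_cross_correlations(heatmap_toy, self.curr(), 2, seed=4, n_samples=2000)
        b = outcome_cross_correlations(heatmap_toy, self.curr(), 2, seed=4, n_samples=2000)
        assert a["cross"].equals(b["cross"]) and a["auto"].equals(b["auto"])

    def test_degenerate_indicator_is_nan(self):
        reg = make_registry([("a", 2, "outcome"), ("b", 2, "health")])
        m = make_model(
            reg, parents={},
            initial_tables={"a": np.array([1.0, 0.0]), "b": np.array([0.5, 0.5])},
            alpha=0.0,
        )
        out = outcome_cross_correlations(m, {}, 0, seed=1, n_samples=1000)
        assert np.isnan(out["cross"]["phi"]).all()

    @staticmethod
    def curr():
        return {0: {"act": "inactive", "diet": "poor"}}
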