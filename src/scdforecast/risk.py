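"""Scenario comparison, credible intervals, decision heatmap, correlations.

These are the calculator-facing tools.  A *scenario* is an evidence set: the
current scenario fixes what is known today; the target scenario additionally
pins planned future states (an intervention, e.g. becoming physically active
in the next slice).  Comparing the two forecasts yields the absolute risk
reduction in percentage points and an odds ratio, with an equal-tailed
Bayesian credible interval obtained by resampling every CPT row from its
Dirichlet posterior (counts + alpha) and repeating both forecasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DBNModel, DYNAMIC, EvidenceError, SchemaError
from .inference import forecast

#: the modifiable lifestyle factors shown as heatmap rows, in registry order
MODIFIABLE_ROLES = (DYNAMIC,)


def odds_ratio(p_target: float, p_current: float) -> float:
    """Odds ratio of the target probability against the current probability."""
    for p in (p_target, p_current):
        if not 0.0 < p < 1.0:
            raise ValueError(f"probability {p} must lie strictly in (0, 1)")
    return (p_target / (1.0 - p_target)) / (p_current / (1.0 - p_current))


def _outcome_risk(model, evidence, horizon, outcome):
    fc = forecast(model, evidence, horizon)
    if fc.truncated or fc.horizon < horizon:
        raise EvidenceError("forecast truncated before the requested slice")
    return fc.outcome_probs[horizon][outcome]


def _check_outcome(model: DBNModel, outcome: str) -> None:
    role = model.registry.spec(outcome).role
    if role not in ("outcome", "health"):
        raise SchemaError(f"{outcome} is a {role} variable, not an outcome/health node")


@dataclass
class ScenarioComparison:
    outcome: str
    horizon: int
    current_risk: float
    target_risk: float
    absolute_reduction: float  # percentage points, current - target
    odds_ratio: float
    credible_interval: tuple[float, float] | None = None
    level: float | None = None


def sample_posterior_model(model: DBNModel, rng: np.random.Generator) -> DBNModel:
    """One draw of the model with every CPT row resampled from its Dirichlet posterior.

    Rows are drawn as normalized Gamma(counts + alpha) vectors; deterministic
    transitions (age) are kept as-is.
    """

    def draw(cpt):
        g = rng.gamma(cpt.counts + cpt.alpha)
        return replace(cpt, probs=g / g.sum(axis=-1, keepdims=True))

    initial = {name: draw(cpt) for name, cpt in model.initial.items()}
    transition = {
        name: (cpt if name in model.deterministic else draw(cpt))
        for name, cpt in model.transition.items()
    }
    return replace(model, initial=initial, transition=transition)


def credible_interval(
    model: DBNModel,
    current: Mapping[int, Mapping[str, object]],
    target: Mapping[int, Mapping[str, object]],
    outcome: str,
    horizon: int,
    level: float = 0.95,
    draws: int = 500,
    seed: int | None = None,
) -> tuple[float, float]:
    """Equal-tailed credible interval for the scenario odds ratio.

    Each draw resamples all CPT rows from their Dirichlet posteriors, reruns
    both forecasts and records the odds ratio; deterministic for a fixed seed.
    """
    if draws < 100:
        raise ValueError("draws must be >= 100")
    rng = np.random.default_rng(seed)
    ors = np.empty(draws)
    for i in range(draws):
        m = sample_posterior_model(model, rng)
        p_c = _outcome_risk(m, current, horizon, outcome)
        p_t = _outcome_risk(m, target, horizon, outcome)
        ors[i] = odds_ratio(p_t, p_c)
    lo, hi = np.quantile(ors, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def compare_scenarios(
    model: DBNModel,
    current: Mapping[int, Mapping[str, object]],
    target: Mapping[int, Mapping[str, object]],
    horizon: int,
    outcome: str,
    level: float = 0.95,
    draws: int | None = None,
    seed: int | None = None,
) -> ScenarioComparison:
    """What-if comparison of a target scenario against the current one.

    The target may differ from the current evidence only at future slices
    (t >= 1); risks are read at the requested horizon slice.  Pass ``draws``
    to attach a credible interval for the odds ratio.
    """
    _check_outcome(model, outcome)
    reg = model.registry
    if reg.encode_evidence(dict(current.get(0, {}))) != reg.encode_evidence(
        dict(target.get(0, {}))
    ):
        raise EvidenceError("target scenario may differ from current only at future slices")
    p_c = _outcome_risk(model, current, horizon, outcome)
    p_t = _outcome_risk(model, target, horizon, outcome)
    ci = None
    if draws is not None:
        ci = credible_interval(model, current, target, outcome, horizon, level, draws, seed)
    return ScenarioComparison(
        outcome=outcome,
        horizon=horizon,
        current_risk=p_c,
        target_risk=p_t,
        absolute_reduction=100.0 * (p_c - p_t),
        odds_ratio=odds_ratio(p_t, p_c),
        credible_interval=ci,
        level=level if ci is not None else None,
    )


# ---------------------------------------------------------------------------
# Decision heatmap
# ---------------------------------------------------------------------------


@dataclass
class DecisionMatrix:
    """Per-factor, per-level next-slice risks and deltas for one outcome.

    ``risks[f][l]`` is the outcome risk at slice 1 when factor ``f`` is pinned
    to level ``l`` at slice 1 (on top of the committed choices);
    ``deltas[f][l]`` is the difference in percentage points against the row's
    status-quo level (the committed level if committed, else the factor's
    slice-0 evidence level), so the status-quo cell's delta is exactly 0.
    ``baseline_risk`` is the committed-only forecast risk.
    """

    outcome: str
    factors: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]
    risks: dict[str, dict[str, float]]
    deltas: dict[str, dict[str, float]]
    reference_level: dict[str, str]
    committed: dict[str, str] = field(default_factory=dict)
    baseline_risk: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.factors:
            for l in self.levels[f]:
                rows.append(
                    {
                        "factor": f,
                        "level": l,
                        "risk": self.risks[f][l],
                        "delta_points": self.deltas[f][l],
                        "status_quo": l == self.reference_level[f],
                        "committed": self.committed.get(f) == l,
                    }
                )
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        """Aligned text table; deltas binned at +-1 / +-5 percentage points."""

        def bin_mark(d):
            if d <= -5:
                return "--"
            if d <= -1:
                return "-"
            if d >= 5:
                return "++"
            if d >= 1:
                return "+"
            return "."

        lines = [f"outcome: {self.outcome}   baseline risk: {100 * self.baseline_risk:.1f}%"]
        for f in self.factors:
            cells = []
            for l in self.levels[f]:
                tag = "*" if l == self.reference_level[f] else bin_mark(self.deltas[f][l])
                cells.append(f"{l}={100 * self.risks[f][l]:.1f}%[{tag}]")
            lines.append(f"  {f:<18} " + "  ".join(cells))
        return "\n".join(lines)


def decision_heatmap(
    model: DBNModel,
    current: Mapping[int, Mapping[str, object]],
    outcome: str,
    committed: Sequence[tuple[str, str]] | Mapping[str, str] = (),
    factors: Sequence[str] | None = None,
) -> DecisionMatrix:
    """Decision matrix of next-slice risks for every attainable factor level.

    Each cell pins one modifiable factor to one level at slice 1 (on top of
    the already committed choices) and forecasts the outcome risk one slice
    ahead.  Committing a choice and re-rendering updates every cell, making
    the matrix dynamic.
    """
    _check_outcome(model, outcome)
    reg = model.registry
    if factors is None:
        age_like = {v for v in reg.dynamic if v == "age"}
        factors = tuple(v for v in reg.dynamic if v not in age_like)
    committed_pairs = list(committed.items()) if isinstance(committed, Mapping) else list(committed)
    committed_map: dict[str, str] = {}
    for f, l in committed_pairs:
        if f in committed_map and committed_map[f] != l:
            raise EvidenceError(f"conflicting committed levels for {f}")
        committed_map[f] = reg.label(f, reg.encode_evidence({f: l})[f])

    ev0 = reg.encode_evidence(dict(current.get(0, {})))
    for f in factors:
        if f not in ev0:
            raise EvidenceError(f"current evidence must define modifiable factor {f!r}")

    def with_slice1(extra: Mapping[str, str]):
        ev = {int(t): dict(e) for t, e in current.items()}
        s1 = dict(ev.get(1, {}))
        s1.update(committed_map)
        s1.update(extra)
        ev[1] = s1
        return ev

    baseline_risk = _outcome_risk(model, with_slice1({}), 1, outcome)

    levels = {f: reg.spec(f).domain for f in factors}
    risks: dict[str, dict[str, float]] = {}
    deltas: dict[str, dict[str, float]] = {}
    reference: dict[str, str] = {}
    for f in factors:
        reference[f] = committed_map.get(f, reg.label(f, ev0[f]))
        risks[f] = {
            l: _outcome_risk(model, with_slice1({f: l}), 1, outcome) for l in levels[f]
        }
        ref_risk = risks[f][reference[f]]
        deltas[f] = {l: 100.0 * (risks[f][l] - ref_risk) for l in levels[f]}
    return DecisionMatrix(
        outcome=outcome,
        factors=tuple(factors),
        levels=levels,
        risks=risks,
        deltas=deltas,
        reference_level=reference,
        committed=committed_map,
        baseline_risk=baseline_risk,
    )


# ---------------------------------------------------------------------------
# Forward sampling and correlations
# ---------------------------------------------------------------------------


def forward_sample(
    model: DBNModel,
    evidence: Mapping[int, Mapping[str, object]],
    horizon: int,
    n_samples: int,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Ancestral samples of full trajectories; evidence values are clamped.

    Returns {variable: int array of shape (n_samples, horizon+1)}.  Unlike the
    forecast, sampling propagates the *sampled* previous states (no MAP
    collapse), which is the reference behaviour for Monte-Carlo checks.
    """
    reg = model.registry
    rng = np.random.default_rng(seed)
    ev_by_slice = {int(t): reg.encode_evidence(e) for t, e in evidence.items()}
    out = {v: np.empty((n_samples, horizon + 1), dtype=np.int64) for v in reg.names}
    statics = reg.by_role("static")

    u = {v: rng.random((n_samples, horizon + 1)) for v in reg.names}
    for t in range(horizon + 1):
        ev = ev_by_slice.get(t, {})
        for v in reg.names:  # registry order is topological within the slice
            if v in ev:
                out[v][:, t] = ev[v]
                continue
            if t > 0 and v in statics:
                out[v][:, t] = out[v][:, t - 1]
                continue
            if t > 0 and v in model.transition:
                cpt = model.transition[v]
                idx = (out[v][:, t - 1],) + tuple(out[p][:, t] for p in cpt.parents[1:])
            else:
                cpt = model.initial[v]
                idx = tuple(out[p][:, t] for p in cpt.parents)
            rows = cpt.probs[idx] if idx else np.broadcast_to(
                cpt.probs, (n_samples, cpt.probs.shape[-1])
            )
            cdf = rows.cumsum(axis=1)
            out[v][:, t] = (u[v][:, t][:, None] > cdf).sum(axis=1)
    return out


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def outcome_cross_correlations(
    model: DBNModel,
    evidence: Mapping[int, Mapping[str, object]],
    horizon: int,
    seed: int | None = None,
    n_samples: int = 10_000,
) -> dict[str, pd.DataFrame]:
    """Phi correlations among binary outcome/health indicators.

    Forward-samples trajectories under the evidence and reports, per slice,
    the within-slice cross-correlations between all outcome/health indicator
    pairs, and for each indicator its autocorrelation at lags 1..horizon
    (pooled over slice pairs).  Degenerate (constant) indicators yield NaN.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    reg = model.registry
    nodes = (*reg.outcomes, *reg.health)
    samples = forward_sample(model, evidence, horizon, n_samples, seed)
    ind = {v: (samples[v] == reg.k(v) - 1).astype(float) for v in nodes}

    cross_rows = []
    for t in range(horizon + 1):
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                cross_rows.append(
                    {"slice": t, "var_a": a, "var_b": b, "phi": _phi(ind[a][:, t], ind[b][:, t])}
                )
    auto_rows = []
    for v in nodes:
        for lag in range(1, horizon + 1):
            xs = np.concatenate([ind[v][:, t] for t in range(horizon + 1 - lag)])
            ys = np.concatenate([ind[v][:, t + lag] for t in range(horizon + 1 - lag)])
            auto_rows.append({"var": v, "lag": lag, "phi": _phi(xs, ys)})
    return {
        "cross": pd.DataFrame(cross_rows),
        "auto": pd.DataFrame(auto_rows),
    }
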