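"""Exact per-slice inference and MAP-propagated forecasting.

Within one time slice the model is an ordinary discrete Bayesian network of at
most 17 small nodes, so posterior marginals are computed exactly by variable
elimination (greedy min-fill ordering).  Between slices the forecast follows
the model's transition rule: each variable's marginal MAP state from slice
t-1 — overridden by any user-supplied evidence, which is how intervention
targets enter — feeds the temporal CPTs of slice t; age advances
deterministically; static variables are carried forward as evidence.  Full
posterior distributions are kept within each slice; only the point (MAP)
summary crosses slice boundaries, which bounds complexity and avoids
compounding uncertainty across the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import DBNModel, EvidenceError, STATIC, VariableRegistry

#: a slice network: variable -> (parent tuple, prob table with child axis last)
SliceNetwork = dict[str, tuple[tuple[str, ...], np.ndarray]]


# ---------------------------------------------------------------------------
# Factor algebra
# ---------------------------------------------------------------------------


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray

    def reduce(self, var: str, value: int) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :], np.take(self.table, value, axis=axis)
        )


def _product(a: _Factor, b: _Factor) -> _Factor:
    out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    a_shape = [(-1 if v in a.vars else 0) for v in out_vars]
    ta = a.table.reshape(a.table.shape + (1,) * (len(out_vars) - len(a.vars)))
    # move b's axes into out order
    perm = []
    tb = b.table
    b_axes = {v: i for i, v in enumerate(b.vars)}
    shape = []
    for v in out_vars:
        shape.append(tb.shape[b_axes[v]] if v in b_axes else 1)
    tb = np.transpose(tb, [b_axes[v] for v in out_vars if v in b_axes]).reshape(shape)
    del a_shape
    return _Factor(out_vars, ta * tb)


def _sum_out(f: _Factor, var: str) -> _Factor:
    axis = f.vars.index(var)
    return _Factor(f.vars[:axis] + f.vars[axis + 1 :], f.table.sum(axis=axis))


def _eliminate(factors: list[_Factor], keep: set[str]) -> _Factor:
    """Sum-product eliminate all variables not in ``keep`` (greedy min-fill)."""
    factors = [f for f in factors if f.vars or f.table.size]
    to_eliminate = {v for f in factors for v in f.vars} - keep
    while to_eliminate:
        # greedy: pick the variable whose elimination builds the smallest factor
        best_var, best_cost = None, None
        for v in to_eliminate:
            involved = [f for f in factors if v in f.vars]
            vars_union = {u for f in involved for u in f.vars} - {v}
            sizes = {}
            for f in involved:
                for u, s in zip(f.vars, f.table.shape):
                    sizes[u] = s
            cost = int(np.prod([sizes[u] for u in vars_union])) if vars_union else 1
            if best_cost is None or cost < best_cost:
                best_var, best_cost = v, cost
        involved = [f for f in factors if best_var in f.vars]
        rest = [f for f in factors if best_var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _product(prod, f)
        factors = rest + [_sum_out(prod, best_var)]
        to_eliminate.discard(best_var)
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _product(result, f)
    # order axes as sorted keep set for deterministic output
    order = tuple(sorted(result.vars))
    perm = [result.vars.index(v) for v in order]
    return _Factor(order, np.transpose(result.table, perm) if perm else result.table)


# ---------------------------------------------------------------------------
# Slice networks
# ---------------------------------------------------------------------------


def initial_network(model: DBNModel) -> SliceNetwork:
    """The slice-0 network: every variable with its initial CPT."""
    return {name: (cpt.parents, cpt.probs) for name, cpt in model.initial.items()}


def transition_network(model: DBNModel, prev_states: Mapping[str, int]) -> SliceNetwork:
    """A slice-t (t >= 1) network with previous-slice states fixed.

    Temporal variables use their transition CPT conditioned on the previous
    MAP state; all other variables are regenerated from their initial CPT.
    """
    net: SliceNetwork = {}
    for name, cpt in model.initial.items():
        if name in model.transition:
            tcpt = model.transition[name]
            prev = prev_states[name]
            net[name] = (tcpt.parents[1:], np.take(tcpt.probs, prev, axis=0))
        else:
            net[name] = (cpt.parents, cpt.probs)
    return net


# ---------------------------------------------------------------------------
# Posteriors, MAP, forecast
# ---------------------------------------------------------------------------


def slice_posteriors(
    network: SliceNetwork,
    evidence: Mapping[str, int],
    registry: VariableRegistry | None = None,
) -> dict[str, np.ndarray]:
    """Exact posterior marginals of every variable in one slice network.

    Evidence variables get a point-mass posterior.  Raises
    :class:`EvidenceError` if the evidence has zero probability.
    """
    base: list[_Factor] = []
    for child, (parents, probs) in network.items():
        f = _Factor((*parents, child), probs)
        for var in f.vars:
            if var in evidence:
                f = f.reduce(var, evidence[var])
        base.append(f)
    z_factor = _eliminate(base, set())
    z = float(z_factor.table)
    if not z > 0.0:
        raise EvidenceError("evidence has zero probability under the model")
    posteriors: dict[str, np.ndarray] = {}
    for child, (parents, probs) in network.items():
        if child in evidence:
            point = np.zeros(probs.shape[-1])
            point[evidence[child]] = 1.0
            posteriors[child] = point
        else:
            marg = _eliminate(base, {child})
            posteriors[child] = np.asarray(marg.table, dtype=float) / z
    return posteriors


def map_states(posteriors: Mapping[str, np.ndarray]) -> dict[str, int]:
    """Per-variable marginal mode; ties break toward the lower category index."""
    return {name: int(np.argmax(dist)) for name, dist in posteriors.items()}


@dataclass
class RiskForecast:
    """Per-slice posteriors, MAP states and outcome probabilities.

    ``outcome_probs[t][v]`` is the probability of the adverse category
    (declined / yes, i.e. the last category) of outcome or health node ``v``
    at slice ``t``.
    """

    posteriors: list[dict[str, np.ndarray]]
    map_states: list[dict[str, int]]
    outcome_probs: list[dict[str, float]]
    truncated: bool = False
    evidence: dict = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return len(self.posteriors) - 1


def forecast(
    model: DBNModel,
    evidence: Mapping[int, Mapping[str, object]],
    horizon: int,
    age_var: str | None = "age",
) -> RiskForecast:
    """Forecast all variables ``horizon`` slices ahead of the evidence.

    ``evidence`` maps slice index -> {variable: category label or code};
    slice-0 evidence must include the age group (the model's initial
    parameter) when the registry has one.  Slice 0 is inferred from the
    initial CPTs with the evidence conditioned on; each later slice
    conditions the temporal CPTs on the previous slice's MAP states, carries
    static variables forward, and treats user-supplied future evidence as an
    intervention target that replaces the propagated state (do-style: the
    variable's CPD becomes a point mass).  If age would pass its absorbing
    top category, the forecast stops there with a warning.
    """
    registry = model.registry
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    ev_by_slice = {int(t): registry.encode_evidence(e) for t, e in evidence.items()}
    if age_var is not None and age_var in registry:
        if age_var not in ev_by_slice.get(0, {}):
            raise EvidenceError(f"slice-0 evidence must include {age_var!r}")

    adverse = {v: registry.k(v) - 1 for v in (*registry.outcomes, *registry.health)}
    statics = registry.by_role(STATIC)

    posteriors: list[dict[str, np.ndarray]] = []
    maps: list[dict[str, int]] = []
    outcome_probs: list[dict[str, float]] = []
    truncated = False

    for t in range(horizon + 1):
        ev = dict(ev_by_slice.get(t, {}))
        if t == 0:
            net = initial_network(model)
        else:
            prev = maps[-1]
            if age_var is not None and age_var in registry:
                if prev[age_var] == registry.k(age_var) - 1:
                    warnings.warn(
                        "forecast truncated: age group reached its absorbing top category",
                        stacklevel=2,
                    )
                    truncated = True
                    break
            for s in statics:  # constant within a person
                ev.setdefault(s, prev[s])
            net = transition_network(model, prev)
            # future-slice evidence is an intervention target: it *replaces*
            # the propagated state, so the variable's own CPD becomes a point
            # mass instead of being conditioned on (which could contradict a
            # deterministic transition)
            for v, c in ev.items():
                point = np.zeros(model.registry.k(v))
                point[c] = 1.0
                net[v] = ((), point)
        post = slice_posteriors(net, ev, registry)
        posteriors.append(post)
        mp = map_states(post)
        mp.update(ev)
        maps.append(mp)
        outcome_probs.append({v: float(post[v][c]) for v, c in adverse.items()})

    return RiskForecast(posteriors, maps, outcome_probs, truncated, dict(ev_by_slice))
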