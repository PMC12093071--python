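"""Synthetic five-phase panel generator with planted, analytically known effects.

No deposited cohort exists for this study design, so the generator is the
toolkit's only data source.  It emulates the panel's *style*: baseline ages
40-60 (5-year bins advancing one bin per phase), ~80% women, lifestyle
factors evolving by sticky first-order Markov kernels whose per-phase
marginals track configured targets, outcomes and health conditions drawn per
phase from an additive category-log-odds (logistic) model, plus item
non-response and monotone panel dropout.

The outcome model is deliberately *not* a Bayesian network: being additive in
log-odds it yields an analytic ground truth (e.g. a planted physical-activity
odds ratio, a U-shaped alcohol effect) that is independent of the estimator
under test.  Per-phase intercepts are calibrated numerically so the marginal
prevalences match the configured targets whatever effects are planted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core import (
    MISSING,
    CohortTable,
    VariableRegistry,
    build_default_registry,
)
from .estimate import fit_model
from .inference import forecast
from .risk import compare_scenarios
from .structure import search_structure


class GeneratorConfigError(ValueError):
    """The generator configuration is inconsistent or infeasible."""


def _load_default_targets() -> dict:
    ref = importlib.resources.files("scdforecast").joinpath("data/generator_defaults.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class GeneratorConfig:
    """Everything the generator needs; ``default`` loads the shipped targets.

    ``factor_targets`` maps each dynamic lifestyle factor to a list of
    per-phase marginal vectors; ``outcome_targets`` gives each outcome/health
    node its per-phase adverse-category prevalence; ``effects`` maps an
    outcome to {factor: per-category log-odds vector} (the planted ground
    truth).  ``seed`` is mandatory: generation is bitwise-reproducible.
    """

    n_individuals: int
    seed: int
    phases: int = 5
    gender_dist: list[float] = field(default_factory=list)
    education_dist: list[float] = field(default_factory=list)
    baseline_age_dist: list[float] = field(default_factory=list)
    persistence: dict[str, float] = field(default_factory=dict)
    factor_targets: dict[str, list[list[float]]] = field(default_factory=dict)
    outcome_targets: dict[str, list[float]] = field(default_factory=dict)
    effects: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    dropout_hazard: float = 0.06
    dropout_scd_multiplier: float = 1.0

    @classmethod
    def default(cls, n_individuals: int, seed: int, **overrides) -> "GeneratorConfig":
        d = _load_default_targets()
        d.pop("version", None)
        d.update(overrides)
        return cls(n_individuals=n_individuals, seed=seed, **d)

    @classmethod
    def from_yaml(cls, path, n_individuals: int | None = None, seed: int | None = None):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("version", None)
        if n_individuals is not None:
            d["n_individuals"] = n_individuals
        if seed is not None:
            d["seed"] = seed
        return cls(**d)

    def validate(self, registry: VariableRegistry) -> None:
        for name, dist in (
            ("gender_dist", self.gender_dist),
            ("education_dist", self.education_dist),
            ("baseline_age_dist", self.baseline_age_dist),
        ):
            arr = np.asarray(dist, float)
            if arr.size == 0 or (arr < 0).any() or arr.sum() <= 0:
                raise GeneratorConfigError(f"{name}: not a valid distribution")
        for f, p in self.persistence.items():
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(f"persistence[{f}] must be in [0, 1]")
        for f, rows in self.factor_targets.items():
            k = registry.k(f)
            for t, row in enumerate(rows):
                arr = np.asarray(row, float)
                if arr.size != k or (arr < 0).any() or arr.sum() <= 0:
                    raise GeneratorConfigError(f"factor_targets[{f}][{t}] invalid")
        for o, targets in self.outcome_targets.items():
            if not all(0.0 < p < 1.0 for p in targets):
                raise GeneratorConfigError(f"outcome_targets[{o}] must be in (0, 1)")


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def _redraw_distributions(
    targets: list[list[float]], p_keep: float
) -> tuple[list[np.ndarray], list[np.ndarray], list[float]]:
    """Per-step redraw distributions so marginals hit the per-phase targets.

    The kernel is ``K_t = p_t*I + (1-p_t) 1 r_t'`` with marginal recursion
    ``m_t = p_t m_{t-1} + (1-p_t) r_t``.  The configured persistence acts as
    a *cap*: where a tabulated category shrinks faster than the cap allows
    (``target_j < p_keep * m_{t-1,j}``), the step's keep-probability is
    lowered just enough to keep ``r_t`` nonnegative, so the marginals always
    match the targets exactly.  Returns (redraw dists r_1..r_{T-1}, implied
    marginals == targets, effective per-step keep-probabilities).
    """
    m = [_normalize(np.asarray(targets[0], float))]
    redraws: list[np.ndarray] = []
    p_eff: list[float] = []
    if p_keep >= 1.0:  # explicit full persistence: freeze the factor entirely
        for _ in range(1, len(targets)):
            redraws.append(np.full_like(m[0], 1.0 / m[0].size))
            p_eff.append(1.0)
            m.append(m[0])
        return redraws, m, p_eff
    for t in range(1, len(targets)):
        tgt = _normalize(np.asarray(targets[t], float))
        prev = m[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(prev > 0, tgt / prev, np.inf)
        p = min(p_keep, float(ratios.min()))
        if p >= 1.0:  # targets identical: pure persistence step
            redraws.append(np.full_like(tgt, 1.0 / tgt.size))
            p_eff.append(1.0)
            m.append(tgt)
            continue
        r = np.clip((tgt - p * prev) / (1.0 - p), 0.0, None)
        r = _normalize(r)
        redraws.append(r)
        p_eff.append(p)
        m.append(tgt)
    return redraws, m, p_eff


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(c + eta)) = target for c (monotone; bracketed search)."""
    if eta.size == 0:
        return float(logit(target))
    if np.ptp(eta) == 0:
        return float(logit(target) - eta[0])
    f = lambda c: float(np.mean(expit(c + eta)) - target)
    lo, hi = -30.0, 30.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate(
    config: GeneratorConfig, registry: VariableRegistry | None = None
) -> tuple[CohortTable, dict]:
    """Sample a cohort table plus the exact generating ground truth.

    Phases are labelled 1..P.  Static variables are drawn once; dynamic
    factors evolve by the sticky kernels; outcomes/health nodes are drawn per
    phase from the calibrated logistic model; item non-response and monotone
    dropout are applied last.  Identical (config, registry) inputs give
    bitwise-identical output.
    """
    registry = registry or build_default_registry()
    config.validate(registry)
    rng = np.random.default_rng(config.seed)
    n, P = config.n_individuals, config.phases
    k_age = registry.k("age") if "age" in registry else None

    def draw_cat(dist: np.ndarray, size: int) -> np.ndarray:
        cdf = np.cumsum(_normalize(np.asarray(dist, float)))
        return np.searchsorted(cdf, rng.random(size), side="right").astype(np.int64)

    values: dict[str, np.ndarray] = {}  # var -> (n, P) codes before missingness
    gender = draw_cat(np.asarray(config.gender_dist), n)
    education = draw_cat(np.asarray(config.education_dist), n)
    values["gender"] = np.repeat(gender[:, None], P, axis=1)
    values["education"] = np.repeat(education[:, None], P, axis=1)

    if k_age is not None:
        base_age = draw_cat(np.asarray(config.baseline_age_dist), n)
        ages = np.minimum(base_age[:, None] + np.arange(P)[None, :], k_age - 1)
        values["age"] = ages.astype(np.int64)

    truth: dict = {"config": asdict(config), "redraw": {}, "intercepts": {}, "marginals": {}}
    truth["persistence_effective"] = {}
    for factor, targets in config.factor_targets.items():
        p_keep = config.persistence.get(factor, 0.8)
        redraws, marginals, p_eff = _redraw_distributions(targets[:P], p_keep)
        truth["redraw"][factor] = [r.tolist() for r in redraws]
        truth["marginals"][factor] = [m.tolist() for m in marginals]
        truth["persistence_effective"][factor] = p_eff
        arr = np.empty((n, P), dtype=np.int64)
        arr[:, 0] = draw_cat(np.asarray(targets[0], float), n)
        for t in range(1, P):
            keep = rng.random(n) < p_eff[t - 1]
            fresh = draw_cat(redraws[t - 1], n)
            arr[:, t] = np.where(keep, arr[:, t - 1], fresh)
        values[factor] = arr

    for outcome, targets in config.outcome_targets.items():
        effects = config.effects.get(outcome, {})
        arr = np.empty((n, P), dtype=np.int64)
        truth["intercepts"][outcome] = []
        for t in range(P):
            eta = np.zeros(n)
            for factor, coefs in effects.items():
                coefs = np.asarray(coefs, float)
                eta += coefs[values[factor][:, t]]
            c = _calibrate_intercept(eta, targets[t])
            truth["intercepts"][outcome].append(c)
            arr[:, t] = (rng.random(n) < expit(c + eta)).astype(np.int64)
        values[outcome] = arr

    # monotone dropout: once out, always out (phase 1 everyone responds)
    alive = np.ones((n, P), dtype=bool)
    for t in range(1, P):
        hazard = np.full(n, config.dropout_hazard)
        if config.dropout_scd_multiplier != 1.0 and "memory" in values:
            hazard = np.where(
                values["memory"][:, t - 1] == 1,
                np.minimum(1.0, hazard * config.dropout_scd_multiplier),
                hazard,
            )
        alive[:, t] = alive[:, t - 1] & (rng.random(n) >= hazard)

    # item non-response
    for var in registry.names:
        rate = float(config.missingness.get(var, 0.0))
        if rate > 0:
            mask = rng.random((n, P)) < rate
            values[var] = np.where(mask, MISSING, values[var])

    ids = np.repeat(np.arange(n), P)
    phases = np.tile(np.arange(1, P + 1), n)
    keep_rows = alive.reshape(-1)
    data = {"id": ids[keep_rows], "phase": phases[keep_rows]}
    for var in registry.names:
        data[var] = values[var].reshape(-1)[keep_rows]
    table = CohortTable(registry, pd.DataFrame(data))
    truth["n_rows"] = int(keep_rows.sum())
    return table, truth


def marginal_check(table: CohortTable, config: GeneratorConfig) -> pd.DataFrame:
    """Compare realized per-phase marginals with the configured targets.

    One row per (variable, phase, category) with the target frequency, the
    realized respondent frequency, its binomial z-score against the target,
    and a flag for |z| > 3.  For the Markov factors the comparison target is
    the kernel-implied marginal (the configured target, unless full
    persistence was requested, which freezes the factor at its baseline).
    """
    rows = []

    def add(var, t, category, target, obs_frac, n_resp):
        se = np.sqrt(target * (1 - target) / n_resp) if n_resp else np.nan
        z = (obs_frac - target) / se if se and se > 0 else np.nan
        rows.append(
            {
                "variable": var,
                "phase": t + 1,
                "category": category,
                "target": target,
                "observed": obs_frac,
                "respondents": n_resp,
                "z": z,
                "flag": bool(abs(z) > 3) if np.isfinite(z) else False,
            }
        )

    for factor, targets in config.factor_targets.items():
        p_keep = config.persistence.get(factor, 0.8)
        _, implied, _ = _redraw_distributions(targets[: config.phases], p_keep)
        for t in range(config.phases):
            col = table.codes.loc[table.codes["phase"] == t + 1, factor].to_numpy()
            col = col[col != MISSING]
            counts = np.bincount(col, minlength=table.registry.k(factor))
            for c, label in enumerate(table.registry.spec(factor).domain):
                add(factor, t, label, float(implied[t][c]),
                    counts[c] / col.size if col.size else np.nan, col.size)
    for outcome, targets in config.outcome_targets.items():
        for t in range(config.phases):
            col = table.codes.loc[table.codes["phase"] == t + 1, outcome].to_numpy()
            col = col[col != MISSING]
            adverse = table.registry.spec(outcome).domain[-1]
            add(outcome, t, adverse, float(targets[t]),
                (col == table.registry.k(outcome) - 1).mean() if col.size else np.nan,
                col.size)
    return pd.DataFrame(rows)


def recover_effects(
    table: CohortTable,
    max_parents: int = 3,
    alpha: float = 0.5,
    outcome: str = "memory",
    profile: Mapping[str, str] | None = None,
) -> dict:
    """Run the full learn -> fit -> what-if pipeline and report recovered effects.

    Compares the physical-activity intervention scenario (inactive now,
    active next slice) against staying inactive, and probes the fitted
    alcohol-level risk profile for non-monotonicity (a U shape: both extreme
    levels riskier than moderate).
    """
    registry = table.registry
    structure = search_structure(table, registry, max_parents=max_parents)
    model = fit_model(table, structure, alpha=alpha)

    base = dict(profile or {"age": "55", "gender": "woman"})
    current = {0: {**base, "ltpa": "inactive"}}
    target = {0: {**base, "ltpa": "inactive"}, 1: {"ltpa": "active"}}
    cmp = compare_scenarios(model, current, target, horizon=1, outcome=outcome)

    alcohol_risks = {}
    for level in registry.spec("alcohol").domain:
        fc = forecast(model, {0: {**base, "alcohol": "moderate"}, 1: {"alcohol": level}}, 1)
        alcohol_risks[level] = fc.outcome_probs[1][outcome]
    u_shape = (
        alcohol_risks["none"] > alcohol_risks["moderate"]
        and alcohol_risks["very_high"] > alcohol_risks["moderate"]
    )
    return {
        "outcome": outcome,
        "ltpa_odds_ratio": cmp.odds_ratio,
        "ltpa_current_risk": cmp.current_risk,
        "ltpa_target_risk": cmp.target_risk,
        "ltpa_protective": cmp.odds_ratio < 1.0,
        "alcohol_risks": alcohol_risks,
        "u_shape_recovered": bool(u_shape),
        "outcome_parents": {
            o: list(structure.intra_parents[o]) for o in registry.outcomes
        },
    }
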