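"""Model validation: Mann-Whitney AUROC and grouped k-fold cross-validation.

Cross-validation partitions *individuals* (not person-phase rows) into k
seeded folds so that no person's repeated measures leak between training and
test.  Per fold, structure search and CPT fitting run on the training
individuals only; each held-out person-phase with an observed outcome is then
scored with the posterior probability of the adverse outcome category given
that phase's observed non-outcome covariates (the other SCD outcomes are
excluded from the conditioning set).  AUROC is computed per outcome over the
pooled held-out predictions and per fold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, CohortTable, DBNModel, VariableRegistry
from .estimate import fit_model
from .inference import initial_network, slice_posteriors
from .structure import search_structure

logger = logging.getLogger("scdforecast")


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney pair formulation.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting ties as 1/2.  Invariant to strictly increasing
    score transforms.  Raises if only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _predict_outcome_probs(
    model: DBNModel, table: CohortTable, outcome: str
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior adverse-outcome probability for each eligible person-phase row.

    Evidence = the row's observed values of all non-outcome-role variables.
    Rows where every covariate is observed take a vectorized path that
    enumerates only the (unobserved) outcome block — valid because outcome
    nodes never parent non-outcome nodes under the expert ordering; rows with
    missing covariates fall back to cached exact inference.

    Returns (probabilities, labels) over rows with the outcome observed.
    """
    reg = model.registry
    outcome_vars = reg.outcomes
    covariates = [v for v in reg.names if v not in outcome_vars]
    X = table.codes[list(reg.names)].to_numpy()
    col = {v: i for i, v in enumerate(reg.names)}
    y = X[:, col[outcome]]
    eligible = y != MISSING
    Xe = X[eligible]
    ye = (y[eligible] == reg.k(outcome) - 1).astype(int)

    cov_idx = [col[v] for v in covariates]
    complete = (Xe[:, cov_idx] != MISSING).all(axis=1)
    probs = np.empty(Xe.shape[0])

    # --- fast path: enumerate the outcome block with covariates fixed -------
    if complete.any():
        rows = Xe[complete]
        n = rows.shape[0]
        combos = list(itertools.product(*(range(reg.k(v)) for v in outcome_vars)))
        weights = np.zeros((n, len(combos)))
        for ci, combo in enumerate(combos):
            state = dict(zip(outcome_vars, combo))
            w = np.ones(n)
            for v in outcome_vars:
                cpt = model.initial[v]
                idx = tuple(
                    np.full(n, state[p]) if p in state else rows[:, col[p]]
                    for p in cpt.parents
                ) + (np.full(n, state[v]),)
                w *= cpt.probs[idx]
            weights[:, ci] = w
        adverse = reg.k(outcome) - 1
        oc = outcome_vars.index(outcome)
        hit = np.array([combo[oc] == adverse for combo in combos])
        probs[complete] = weights[:, hit].sum(axis=1) / weights.sum(axis=1)

    # --- fallback: exact inference with caching by evidence pattern ---------
    if (~complete).any():
        net = initial_network(model)
        cache: dict[tuple, float] = {}
        adverse = reg.k(outcome) - 1
        for i in np.flatnonzero(~complete):
            ev = {
                v: int(Xe[i, col[v]]) for v in covariates if Xe[i, col[v]] != MISSING
            }
            key = tuple(sorted(ev.items()))
            if key not in cache:
                post = slice_posteriors(net, ev, reg)
                cache[key] = float(post[outcome][adverse])
            probs[i] = cache[key]
    return probs, ye


@dataclass
class CrossValidationResult:
    auroc: dict[str, float]
    per_fold: dict[str, list[float]]
    n_predictions: dict[str, int]
    k: int
    seed: int
    fold_sizes: list[int] = field(default_factory=list)


def cross_validate(
    table: CohortTable,
    registry: VariableRegistry | None = None,
    k: int = 5,
    target_outcomes: tuple[str, ...] | None = None,
    seed: int = 0,
    max_parents: int = 3,
    alpha: float = 0.5,
) -> CrossValidationResult:
    """Grouped k-fold cross-validated AUROC per outcome.

    Individuals are shuffled with the seed and split into k folds; per fold a
    full structure search + CPT fit runs on the training individuals, and the
    held-out person-phases are scored.  Folds whose held-out outcome is
    single-class are skipped (with a warning) in the per-fold lists; the
    pooled AUROC uses all predictions.
    """
    registry = registry or table.registry
    if k < 2:
        raise ValueError("k must be >= 2")
    outcomes = target_outcomes or registry.outcomes
    ids = np.sort(table.codes["id"].unique())
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    folds = np.array_split(ids, k)

    pooled_scores: dict[str, list[np.ndarray]] = {o: [] for o in outcomes}
    pooled_labels: dict[str, list[np.ndarray]] = {o: [] for o in outcomes}
    per_fold: dict[str, list[float]] = {o: [] for o in outcomes}
    for fold_ids in folds:
        train = table.subset_ids(np.setdiff1d(ids, fold_ids))
        test = table.subset_ids(fold_ids)
        structure = search_structure(train, registry, max_parents=max_parents)
        model = fit_model(train, structure, alpha=alpha,
                          age_var="age" if "age" in registry else None)
        for outcome in outcomes:
            p, y = _predict_outcome_probs(model, test, outcome)
            pooled_scores[outcome].append(p)
            pooled_labels[outcome].append(y)
            if y.size and 0 < y.sum() < y.size:
                per_fold[outcome].append(auroc(p, y))
            else:
                logger.warning("cross_validate: fold skipped for %s (single-class)", outcome)

    result_auc: dict[str, float] = {}
    n_predictions: dict[str, int] = {}
    for outcome in outcomes:
        p = np.concatenate(pooled_scores[outcome])
        y = np.concatenate(pooled_labels[outcome])
        n_predictions[outcome] = int(y.size)
        result_auc[outcome] = auroc(p, y)
    return CrossValidationResult(
        auroc=result_auc,
        per_fold=per_fold,
        n_predictions=n_predictions,
        k=k,
        seed=seed,
        fold_sizes=[len(f) for f in folds],
    )
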