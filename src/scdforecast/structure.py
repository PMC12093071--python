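"""Exhaustive qNML structure search under the expert node ordering.

Each node independently receives the parent subset (drawn from the variables
preceding it in the expert ordering, at most ``max_parents`` of them) that
maximizes the qNML family score on the pooled person-phase records complete
for that family.  Dynamic variables additionally carry the hardwired temporal
self-edge; the cap applies to intra-slice parents only.

Candidate subsets are evaluated in (size, lexicographic) order and a new best
must be strictly better, so ties resolve toward the smaller subset and then
the lexicographically first parent list.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .core import MISSING, CohortTable, LearningError, NetworkStructure, VariableRegistry
from .scoring import FamilyData, LearningDataError, qnml_family_score

logger = logging.getLogger("scdforecast")


def candidate_parents(node: str, registry: VariableRegistry) -> tuple[str, ...]:
    """All variables strictly preceding ``node`` in the expert ordering."""
    idx = registry.index(node)
    return tuple(name for name in registry.names if registry.index(name) < idx)


def _score_family(
    X: np.ndarray,
    obs: np.ndarray,
    registry: VariableRegistry,
    child: str,
    parents: tuple[str, ...],
    col_of: dict[str, int],
) -> float | None:
    """qNML score of one candidate family on its complete cases, or None if empty."""
    cols = [col_of[p] for p in parents] + [col_of[child]]
    mask = obs[:, cols].all(axis=1)
    codes = X[np.flatnonzero(mask)][:, cols]
    if codes.shape[0] == 0:
        return None
    fam = FamilyData.from_codes(
        codes,
        child,
        parents,
        registry.k(child),
        tuple(registry.k(p) for p in parents),
    )
    return qnml_family_score(fam)


def search_structure(
    table: CohortTable,
    registry: VariableRegistry | None = None,
    max_parents: int = 3,
    case_policy: str = "node",
) -> NetworkStructure:
    """Select each node's intra-slice parents by exhaustive qNML maximization.

    Scoring pools all person-phase records (time-homogeneity).  With the
    default ``case_policy="node"`` every candidate subset of one node is
    scored on the records complete for the child *and its entire candidate
    pool*, so the scores being compared share one sample size.
    ``case_policy="family"`` instead scores each candidate on its own
    available cases; note that log-NML scales roughly like ``-n * H``, so
    under that policy candidates containing high-missingness parents are
    scored on fewer records and thereby look artificially good.  Returns the
    structure with per-node scores, the total score, and each node's score
    margin over the runner-up subset.
    """
    registry = registry or table.registry
    if case_policy not in ("node", "family"):
        raise ValueError(f"unknown case_policy {case_policy!r}")
    X_all = table.code_matrix()
    if X_all.shape[0] == 0:
        raise LearningError("empty cohort table")
    obs_all = X_all != MISSING
    col_of = {name: i for i, name in enumerate(registry.names)}

    intra: dict[str, tuple[str, ...]] = {}
    family_scores: dict[str, float] = {}
    margins: dict[str, float] = {}
    for child in registry.names:
        cands = candidate_parents(child, registry)
        if case_policy == "node":
            pool_cols = [col_of[v] for v in (child, *cands)]
            rows = obs_all[:, pool_cols].all(axis=1)
            if not rows.any():
                raise LearningError(
                    f"node {child}: no records complete for the candidate pool"
                )
            X, obs = X_all[rows], obs_all[rows]
        else:
            X, obs = X_all, obs_all
        best_score = None
        best_parents: tuple[str, ...] = ()
        runner_up = None
        for size in range(0, min(max_parents, len(cands)) + 1):
            for parents in itertools.combinations(sorted(cands), size):
                score = _score_family(X, obs, registry, child, parents, col_of)
                if score is None:
                    if size == 0:
                        raise LearningError(f"node {child}: no complete cases")
                    logger.warning(
                        "search_structure: skipping %s | %s (no complete cases)",
                        child, parents,
                    )
                    continue
                if best_score is None or score > best_score:
                    runner_up = best_score
                    best_score, best_parents = score, parents
                elif runner_up is None or score > runner_up:
                    runner_up = score
        # report parents in expert ordering
        intra[child] = tuple(sorted(best_parents, key=registry.index))
        family_scores[child] = float(best_score)
        margins[child] = float("inf") if runner_up is None else float(best_score - runner_up)

    return NetworkStructure(
        intra_parents=intra,
        temporal_vars=frozenset(registry.dynamic),
        score=float(sum(family_scores.values())),
        family_scores=family_scores,
        margins=margins,
    )


def structure_report(structure: NetworkStructure) -> dict:
    """JSON-ready summary: per-node parents, family score and runner-up margin."""
    return {
        "total_score": structure.score,
        "nodes": {
            child: {
                "parents": list(parents),
                "score": structure.family_scores.get(child),
                "margin_over_runner_up": structure.margins.get(child),
                "temporal": child in structure.temporal_vars,
            }
            for child, parents in structure.intra_parents.items()
        },
    }
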