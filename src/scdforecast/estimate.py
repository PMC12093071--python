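"""CPT estimation with Dirichlet(1/2, ..., 1/2) smoothing on available cases.

Initial-slice CPTs are counted over all person-phase records complete for the
family (the model is time-homogeneous, so phases are pooled).  Transition CPTs
for the temporal variables are counted over consecutive-phase pairs of the
same person, complete for the child at t, its previous-slice value at t-1 and
the intra-slice parents at t.  The age-group transition is not estimated: age
advances deterministically by one 5-year bin per slice, absorbing at the top.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CPT,
    MISSING,
    CohortTable,
    DBNModel,
    NetworkStructure,
    SchemaError,
)


def count_family(
    table: CohortTable,
    child: str,
    parents: tuple[str, ...] | list[str],
    mode: str = "initial",
) -> np.ndarray:
    """Raw count table for one family, shape ``(*parent_ks, k_child)``.

    ``mode='initial'`` counts person-phase records complete for
    ``(child, *parents)``.  ``mode='transition'`` counts pairs of consecutive
    phases of the same person, adding the child's previous-slice value as the
    leading parent axis; non-consecutive phase pairs (e.g. phases 2 and 4) do
    not contribute.
    """
    registry = table.registry
    parents = tuple(parents)
    k_child = registry.k(child)
    if mode == "initial":
        cols = [*parents, child]
        sub = table.codes[cols].to_numpy()
        dims = tuple(registry.k(v) for v in cols)
        sub = sub[(sub != MISSING).all(axis=1)]
    elif mode == "transition":
        df = table.codes.sort_values(["id", "phase"])
        prev = df.groupby("id", sort=False)[child].shift(1)
        consecutive = df.groupby("id", sort=False)["phase"].diff() == 1
        cur = df[[*parents, child]].to_numpy()
        prev_col = prev.to_numpy()
        ok = consecutive.to_numpy() & ~np.isnan(prev_col)
        sub = np.column_stack([prev_col[ok].astype(np.int64), cur[ok]])
        dims = (k_child, *(registry.k(v) for v in parents), k_child)
        sub = sub[(sub != MISSING).all(axis=1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if sub.shape[0] == 0:
        return np.zeros(dims, dtype=np.int64)
    flat = np.ravel_multi_index(tuple(sub.T), dims)
    return np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)


def smooth_cpt(counts: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Posterior-mean probabilities under a per-cell Dirichlet(alpha) prior.

    Each cell becomes ``(n_cell + alpha) / (n_row + alpha * k_child)``; empty
    rows fall back to the uniform prior mean and no cell is exactly zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[-1]
    rows = counts.sum(axis=-1, keepdims=True)
    return (counts + alpha) / (rows + alpha * k)


def _deterministic_age_transition(k: int) -> np.ndarray:
    """Age advances one bin per 5-year slice, absorbing at the top category."""
    probs = np.zeros((k, k))
    for s in range(k):
        probs[s, min(s + 1, k - 1)] = 1.0
    return probs


def fit_model(
    table: CohortTable,
    structure: NetworkStructure,
    alpha: float = 0.5,
    age_var: str | None = "age",
) -> DBNModel:
    """Estimate all initial and transition CPTs for a learned structure.

    Initial CPTs condition on the learned intra-slice parents; transition CPTs
    (temporal variables only) condition on the previous-slice self plus the
    intra-slice parents.  ``age_var`` (if present in the registry) receives
    the deterministic +5-year transition instead of an estimated one.
    """
    registry = table.registry
    if set(structure.intra_parents) != set(registry.names):
        raise SchemaError("structure does not cover the registry's variables")
    structure.validate(registry, max_parents=max(
        (len(p) for p in structure.intra_parents.values()), default=3) or 3)

    deterministic: set[str] = set()
    initial: dict[str, CPT] = {}
    transition: dict[str, CPT] = {}
    n_per_family: dict[str, int] = {}
    for child in registry.names:
        parents = tuple(structure.intra_parents[child])
        counts = count_family(table, child, parents, mode="initial")
        initial[child] = CPT(child, parents, counts, smooth_cpt(counts, alpha), alpha)
        n_per_family[child] = int(counts.sum())
        if child in structure.temporal_vars:
            tcounts = count_family(table, child, parents, mode="transition")
            if age_var is not None and child == age_var:
                probs = np.broadcast_to(
                    _deterministic_age_transition(registry.k(child)).reshape(
                        registry.k(child),
                        *([1] * len(parents)),
                        registry.k(child),
                    ),
                    tcounts.shape,
                ).copy()
                deterministic.add(child)
            else:
                probs = smooth_cpt(tcounts, alpha)
            transition[child] = CPT(child, (child, *parents), tcounts, probs, alpha)

    model = DBNModel(
        registry=registry,
        structure=structure,
        alpha=alpha,
        initial=initial,
        transition=transition,
        deterministic=frozenset(deterministic),
        meta={"n_per_family": n_per_family, "n_individuals": table.n_individuals},
    )
    model.validate()
    return model
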