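"""Shared fixtures: tiny registries, toy cohorts and hand-built models."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from scdforecast import (
    CPT,
    CohortTable,
    DBNModel,
    NetworkStructure,
    VariableRegistry,
    VariableSpec,
    build_default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


def make_registry(spec_list):
    """Build a registry from (name, k or domain, role) tuples in order."""
    specs = []
    for i, (name, dom, role) in enumerate(spec_list):
        domain = tuple(f"c{j}" for j in range(dom)) if isinstance(dom, int) else tuple(dom)
        specs.append(VariableSpec(name, domain, role, i))
    return VariableRegistry(specs)


def make_table(registry, rows):
    """CohortTable from (id, phase, {var: code}) tuples; unset vars missing."""
    data = {"id": [], "phase": []}
    for name in registry.names:
        data[name] = []
    for pid, phase, values in rows:
        data["id"].append(pid)
        data["phase"].append(phase)
        for name in registry.names:
            data[name].append(values.get(name, -1))
    return CohortTable(registry, pd.DataFrame(data))


def make_model(registry, parents, initial_tables, transition_tables=None,
               counts_scale=100.0, alpha=0.5, deterministic=()):
    """Hand-built DBNModel; counts default to probs * counts_scale."""
    transition_tables = transition_tables or {}
    structure = NetworkStructure(
        intra_parents={v: tuple(parents.get(v, ())) for v in registry.names},
        temporal_vars=frozenset(registry.dynamic),
        score=0.0,
    )
    initial = {}
    for v in registry.names:
        probs = np.asarray(initial_tables[v], dtype=float)
        initial[v] = CPT(v, tuple(parents.get(v, ())), probs * counts_scale, probs, alpha)
    transition = {}
    for v, probs in transition_tables.items():
        probs = np.asarray(probs, dtype=float)
        transition[v] = CPT(
            v, (v, *parents.get(v, ())), probs * counts_scale, probs, alpha
        )
    return DBNModel(
        registry=registry,
        structure=structure,
        alpha=alpha,
        initial=initial,
        transition=transition,
        deterministic=frozenset(deterministic),
    )


def enumerate_posteriors(registry, network, evidence):
    """Brute-force joint enumeration oracle for one slice network."""
    names = list(network)
    ks = [registry.k(v) for v in names]
    pos = {v: i for i, v in enumerate(names)}
    marginals = {v: np.zeros(k) for v, k in zip(names, ks)}
    z = 0.0
    for state in itertools.product(*(range(k) for k in ks)):
        if any(state[pos[v]] != c for v, c in evidence.items()):
            continue
        p = 1.0
        for v, (par, table) in network.items():
            idx = tuple(state[pos[q]] for q in par) + (state[pos[v]],)
            p *= table[idx]
        z += p
        for v in names:
            marginals[v][state[pos[v]]] += p
    return {v: m / z for v, m in marginals.items()}, z


def random_network(rng, n_nodes, max_k=3, max_parents=3):
    """Random small registry + random-CPT slice network for oracle tests."""
    roles = ["dynamic"] * (n_nodes - 1) + ["outcome"]
    reg = make_registry(
        [(f"v{i}", int(rng.integers(2, max_k + 1)), roles[i]) for i in range(n_nodes)]
    )
    parents = {}
    network = {}
    for i, v in enumerate(reg.names):
        pool = list(reg.names[:i])
        n_par = int(rng.integers(0, min(max_parents, len(pool)) + 1))
        par = tuple(sorted(rng.choice(pool, size=n_par, replace=False))) if n_par else ()
        parents[v] = par
        shape = tuple(reg.k(p) for p in par) + (reg.k(v),)
        table = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1] or (1,))
        table = table.reshape(shape)
        network[v] = (par, table)
    return reg, parents, network
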