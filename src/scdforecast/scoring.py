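"""Quotient normalized maximum likelihood (qNML) family scoring.

The structure search scores a candidate family (child + parent set) with the
decomposable qNML criterion: the one-dimensional log-NML of the joint
child-and-parents column, minus the log-NML of the parents column, each column
treated as a single categorical variable over its full declared configuration
space.  The log-NML of a column with counts ``n_1..n_k`` is the multinomial
maximum log-likelihood ``sum n_j log(n_j/n)`` minus the log parametric
complexity (regret) ``log C(n, k)``.

The regret is computed exactly: ``C(n, 1) = 1``, ``C(n, 2)`` by its explicit
binomial sum, and higher ``k`` through the two-term recurrence
``C(n, k) = C(n, k-1) + (n / (k-2)) * C(n, k-2)``, all carried in log space so
large ``n * k`` regimes cannot overflow.  Exactness (rather than the usual
Szpankowski asymptotic) is cheap at survey-cohort sample sizes and lets the
implementation be checked against brute-force composition sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy


def categorical_log_ml(counts) -> float:
    """Multinomial maximum log-likelihood ``sum_j n_j log(n_j / n)`` in nats.

    ``0 * log 0`` is taken as 0.  Raises on an all-zero count vector.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    n = c.sum()
    if n <= 0:
        raise ValueError("empty data: all counts are zero")
    return float(xlogy(c, c / n).sum())


# log C(n, k) cache: n -> 1-d array with entry [k-1] = log C(n, k)
_REGRET_CACHE: dict[int, np.ndarray] = {}


def _log_c_n2(n: int) -> float:
    """log C(n, 2) via the explicit sum over binomial compositions."""
    if n == 0:
        return 0.0
    h = np.arange(n + 1, dtype=float)
    log_binom = gammaln(n + 1.0) - gammaln(h + 1.0) - gammaln(n - h + 1.0)
    terms = log_binom + xlogy(h, h / n) + xlogy(n - h, (n - h) / n)
    return float(logsumexp(terms))


def multinomial_regret(n: int, k: int) -> float:
    """Exact log parametric complexity ``log C(n, k)`` of a k-category multinomial.

    ``C(n, k)`` is the NML normalizer: the sum over all compositions
    ``n_1 + ... + n_k = n`` of the multinomial coefficient times the maximized
    likelihood ``prod (n_j / n)^{n_j}``.  ``C(0, k) = C(n, 1) = 1``.
    """
    n, k = int(n), int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0 or k == 1:
        return 0.0
    table = _REGRET_CACHE.get(n)
    if table is None or table.size < k:
        size = max(k, 8)
        table = np.empty(size)
        table[0] = 0.0
        table[1] = _log_c_n2(n)
        logn = np.log(n)
        for kk in range(3, size + 1):
            table[kk - 1] = np.logaddexp(table[kk - 2], logn - np.log(kk - 2) + table[kk - 3])
        _REGRET_CACHE[n] = table
    return float(table[k - 1])


def log_nml_column(counts, k: int) -> float:
    """log-NML of one categorical column over a declared k-cell space.

    ``counts`` may omit trailing/unobserved cells; ``k`` is the full declared
    configuration-space size (structural zeros still count toward the regret).
    """
    c = np.asarray(counts, dtype=float)
    if k < c.nonzero()[0].size:
        raise ValueError("k smaller than the number of observed cells")
    n = int(round(c.sum()))
    return categorical_log_ml(c) - multinomial_regret(n, k)


@dataclass(frozen=True)
class FamilyData:
    """Sufficient statistics of one candidate family on its complete cases.

    ``joint_counts`` is flat over the product configuration space with the
    child as the fastest-varying axis; ``parent_counts`` is flat over the
    parent configuration space (a single cell for an empty parent set).
    """

    child: str
    parents: tuple[str, ...]
    k_child: int
    k_parents: int
    joint_counts: np.ndarray
    parent_counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.joint_counts.sum())

    @classmethod
    def from_codes(
        cls,
        codes: np.ndarray,
        child: str,
        parents: tuple[str, ...],
        k_child: int,
        k_parents_each: tuple[int, ...],
    ) -> "FamilyData":
        """Build counts from a complete-case code matrix.

        ``codes`` has one row per complete case and columns ordered as
        ``(*parents, child)``.
        """
        dims = (*k_parents_each, k_child)
        if codes.size:
            flat = np.ravel_multi_index(tuple(codes.T), dims)
            joint = np.bincount(flat, minlength=int(np.prod(dims)))
        else:
            joint = np.zeros(int(np.prod(dims)), dtype=np.int64)
        k_parents = int(np.prod(k_parents_each)) if k_parents_each else 1
        parent_counts = joint.reshape(k_parents, k_child).sum(axis=1)
        return cls(child, parents, k_child, k_parents, joint, parent_counts)


def qnml_family_score(family: FamilyData) -> float:
    """qNML score of one family in nats.

    ``log NML(joint column over k_child * k_parents cells) - log NML(parent
    column over k_parents cells)``; for an empty parent set the denominator is
    the NML of a one-cell column, which is 0.
    """
    if family.n < 1:
        raise LearningDataError(
            f"family ({family.child} | {family.parents}): no complete cases"
        )
    joint = log_nml_column(family.joint_counts, family.k_child * family.k_parents)
    if family.k_parents == 1:
        return joint
    parent = log_nml_column(family.parent_counts, family.k_parents)
    return joint - parent


class LearningDataError(RuntimeError):
    """A candidate family has no usable data; callers skip it with a warning."""
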