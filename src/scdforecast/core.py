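"""Variable schema, cohort container and model containers.

The toolkit models a fixed panel of 17 discrete variables measured in repeated
survey phases five years apart: an exogenous age group (40-80 in 5-year bins),
two static sociodemographic covariates (gender, education), six modifiable
lifestyle factors (fruit/vegetable consumption, smoking, alcohol consumption,
leisure-time physical activity, insomnia symptoms, BMI), five physician-
diagnosed health conditions plus current pain, and three subjective cognitive
decline (SCD) outcomes: self-rated memory, learning and concentration, each
dichotomised as good vs declined.

Everything downstream (scoring, structure search, CPT estimation, inference)
works on 0-based integer category codes; ``MISSING`` (-1) marks item
non-response.  The expert node ordering stored in the registry constrains the
structure search: a node may only draw same-slice parents from variables that
precede it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("scdforecast")

MISSING: int = -1

#: variable roles
STATIC = "static"
DYNAMIC = "dynamic"
OUTCOME = "outcome"
HEALTH = "health"
ROLES = (STATIC, DYNAMIC, OUTCOME, HEALTH)


class SchemaError(ValueError):
    """A table or config does not match the declared variable schema."""


class IntegrityError(ValueError):
    """A cohort table violates a structural invariant (e.g. duplicate rows)."""


class LearningError(RuntimeError):
    """Structure or parameter learning cannot proceed (e.g. no complete cases)."""


class EvidenceError(ValueError):
    """Evidence is out of domain or has zero probability under the model."""


class ModelFormatError(ValueError):
    """A serialized model file is malformed or has an incompatible version."""


@dataclass(frozen=True)
class VariableSpec:
    """One discrete variable: its category labels, role and ordering slot."""

    name: str
    domain: tuple[str, ...]
    role: str
    ordering_index: int

    def __post_init__(self) -> None:
        if len(self.domain) < 2:
            raise SchemaError(f"{self.name}: domain must have k >= 2 categories")
        if len(set(self.domain)) != len(self.domain):
            raise SchemaError(f"{self.name}: duplicate category labels")
        if self.role not in ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")

    @property
    def k(self) -> int:
        return len(self.domain)


class VariableRegistry:
    """Ordered collection of :class:`VariableSpec`, indexed by the expert ordering."""

    def __init__(self, specs: Iterable[VariableSpec]) -> None:
        specs = sorted(specs, key=lambda s: s.ordering_index)
        indices = [s.ordering_index for s in specs]
        if indices != list(range(len(specs))):
            raise SchemaError("ordering_index values must be a permutation of 0..V-1")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names")
        self._specs: tuple[VariableSpec, ...] = tuple(specs)
        self._by_name: dict[str, VariableSpec] = {s.name: s for s in specs}

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self._specs)

    def spec(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def index(self, name: str) -> int:
        return self.spec(name).ordering_index

    def k(self, name: str) -> int:
        return self.spec(name).k

    def by_role(self, role: str) -> tuple[str, ...]:
        return tuple(s.name for s in self._specs if s.role == role)

    @property
    def dynamic(self) -> tuple[str, ...]:
        return self.by_role(DYNAMIC)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return self.by_role(OUTCOME)

    @property
    def health(self) -> tuple[str, ...]:
        return self.by_role(HEALTH)

    # -- label <-> code ---------------------------------------------------
    def code(self, name: str, label: str) -> int:
        spec = self.spec(name)
        try:
            return spec.domain.index(label)
        except ValueError:
            raise EvidenceError(
                f"{label!r} is not a category of {name} {spec.domain}"
            ) from None

    def label(self, name: str, code: int) -> str:
        return self.spec(name).domain[code]

    def encode_evidence(self, evidence: Mapping[str, object]) -> dict[str, int]:
        """Map {variable: label-or-code} to integer codes, validating domains."""
        out: dict[str, int] = {}
        for name, value in evidence.items():
            spec = self.spec(name)
            if isinstance(value, str):
                out[name] = self.code(name, value)
            else:
                code = int(value)
                if not 0 <= code < spec.k:
                    raise EvidenceError(f"{name}: code {code} out of range 0..{spec.k - 1}")
                out[name] = code
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": s.name,
                    "domain": list(s.domain),
                    "role": s.role,
                    "ordering_index": s.ordering_index,
                }
                for s in self._specs
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableRegistry":
        return cls(
            VariableSpec(v["name"], tuple(v["domain"]), v["role"], int(v["ordering_index"]))
            for v in d["variables"]
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VariableRegistry) and self._specs == other._specs


# ---------------------------------------------------------------------------
# Default study registry
# ---------------------------------------------------------------------------

AGE_GROUPS = tuple(str(a) for a in range(40, 85, 5))

_DEFAULT_VARIABLES: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("age", AGE_GROUPS, DYNAMIC),
    ("gender", ("woman", "man"), STATIC),
    ("education", ("basic", "secondary", "higher"), STATIC),
    ("fruit_veg", ("daily_both", "daily_either", "nondaily"), DYNAMIC),
    ("smoking", ("never", "ex_smoker", "current"), DYNAMIC),
    ("alcohol", ("none", "moderate", "high", "very_high"), DYNAMIC),
    ("ltpa", ("inactive", "active"), DYNAMIC),
    ("insomnia", ("lt4", "4to14", "gt14"), DYNAMIC),
    ("bmi", ("healthy", "overweight", "obese"), DYNAMIC),
    ("hypertension", ("no", "yes"), HEALTH),
    ("high_cholesterol", ("no", "yes"), HEALTH),
    ("diabetes", ("no", "yes"), HEALTH),
    ("mental_disorders", ("no", "yes"), HEALTH),
    ("pain", ("no", "yes"), HEALTH),
    ("concentration", ("good", "declined"), OUTCOME),
    ("memory", ("good", "declined"), OUTCOME),
    ("learning", ("good", "declined"), OUTCOME),
)


def build_default_registry() -> VariableRegistry:
    """The 17-variable study schema in its expert (structure-search) ordering.

    Age group runs 40-80 in nine 5-year bins; alcohol has four levels
    (none / moderate / high / very high risk); BMI uses the three tabulated
    levels (underweight merged with healthy weight); the three SCD outcomes
    are binary good vs declined.
    """
    return VariableRegistry(
        VariableSpec(name, domain, role, i)
        for i, (name, domain, role) in enumerate(_DEFAULT_VARIABLES)
    )


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Long-format person-phase records as integer category codes.

    ``codes`` has columns ``id``, ``phase`` and one int column per registry
    variable, with :data:`MISSING` (-1) for non-response.  Construction
    validates uniqueness of (id, phase), code ranges, and the within-person
    constancy of static variables.
    """

    registry: VariableRegistry
    codes: pd.DataFrame
    n_coerced: int = 0

    def __post_init__(self) -> None:
        expected = ["id", "phase", *self.registry.names]
        if list(self.codes.columns) != expected:
            missing = set(expected) - set(self.codes.columns)
            extra = set(self.codes.columns) - set(expected)
            raise SchemaError(
                f"cohort columns mismatch (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if self.codes.duplicated(["id", "phase"]).any():
            dup = self.codes[self.codes.duplicated(["id", "phase"])].iloc[0]
            raise IntegrityError(f"duplicate (id, phase) record: ({dup['id']}, {dup['phase']})")
        for spec in self.registry:
            col = self.codes[spec.name].to_numpy()
            if ((col < MISSING) | (col >= spec.k)).any():
                raise IntegrityError(f"{spec.name}: code out of range")
        for name in self.registry.by_role(STATIC):
            obs = self.codes.loc[self.codes[name] != MISSING, ["id", name]]
            if obs.groupby("id")[name].nunique().gt(1).any():
                raise IntegrityError(f"static variable {name} varies within a person")

    @property
    def n_individuals(self) -> int:
        return self.codes["id"].nunique()

    @property
    def phases(self) -> tuple[int, ...]:
        return tuple(sorted(self.codes["phase"].unique()))

    def code_matrix(self) -> np.ndarray:
        """(rows, V) int array of codes in registry order."""
        return self.codes[list(self.registry.names)].to_numpy(dtype=np.int64)

    def subset_ids(self, ids: Sequence) -> "CohortTable":
        mask = self.codes["id"].isin(set(ids))
        return CohortTable(self.registry, self.codes.loc[mask].reset_index(drop=True))

    def to_labels(self, missing_token: str = "") -> pd.DataFrame:
        """Decoded copy with category labels (missing as ``missing_token``)."""
        out = self.codes[["id", "phase"]].copy()
        for spec in self.registry:
            col = self.codes[spec.name].to_numpy()
            labels = np.array(list(spec.domain) + [missing_token], dtype=object)
            out[spec.name] = labels[col]  # MISSING == -1 picks the sentinel
        return out


def read_cohort(
    path,
    registry: VariableRegistry,
    missing_token: str = "",
    delimiter: str = ",",
) -> CohortTable:
    """Read a long-format delimited cohort file into a validated table.

    Out-of-domain tokens are coerced to missing (outlier rule) and tallied on
    the returned table's ``n_coerced``; unknown columns raise
    :class:`SchemaError`.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    expected = ["id", "phase", *registry.names]
    if list(raw.columns) != expected:
        raise SchemaError(
            f"expected columns {expected}, found {list(raw.columns)} in {path}"
        )
    codes = raw[["id", "phase"]].copy()
    codes["phase"] = codes["phase"].astype(int)
    try:  # keep integer person ids integral across write/read round trips
        codes["id"] = codes["id"].astype(np.int64)
    except ValueError:
        pass
    n_coerced = 0
    for spec in registry:
        mapping = {label: i for i, label in enumerate(spec.domain)}
        col = raw[spec.name].map(lambda v: mapping.get(v, MISSING)).astype(np.int64)
        bad = (col == MISSING) & (raw[spec.name] != missing_token)
        n_coerced += int(bad.sum())
        codes[spec.name] = col
    if n_coerced:
        logger.warning("read_cohort: %d out-of-domain values treated as missing", n_coerced)
    return CohortTable(registry, codes, n_coerced=n_coerced)


def write_cohort(
    table: CohortTable, path, missing_token: str = "", delimiter: str = ","
) -> None:
    table.to_labels(missing_token).to_csv(path, sep=delimiter, index=False)


def summarize_cohort(table: CohortTable, variable: str, phase: int) -> pd.DataFrame:
    """Per-category respondent counts and percentages for one variable/phase.

    Percentages are 100*count/respondents among non-missing values, matching
    how prevalence tables are reported for survey respondents.
    """
    spec = table.registry.spec(variable)
    col = table.codes.loc[table.codes["phase"] == phase, variable].to_numpy()
    col = col[col != MISSING]
    respondents = col.size
    if respondents == 0:
        raise IntegrityError(f"no respondents for {variable} at phase {phase}")
    counts = np.bincount(col, minlength=spec.k)
    return pd.DataFrame(
        {
            "category": list(spec.domain),
            "count": counts,
            "percent": 100.0 * counts / respondents,
        }
    ).set_index("category")


# ---------------------------------------------------------------------------
# Structure and CPT containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkStructure:
    """Learned intra-slice parent sets plus the hardwired temporal self-edges.

    ``intra_parents`` maps each variable to its same-slice parents (ordered by
    the expert ordering); ``temporal_vars`` are the dynamic variables carrying
    a hardwired self-edge from the previous slice; ``score`` is the total
    family score of the selected structure.
    """

    intra_parents: Mapping[str, tuple[str, ...]]
    temporal_vars: frozenset
    score: float
    family_scores: Mapping[str, float] = field(default_factory=dict)
    margins: Mapping[str, float] = field(default_factory=dict)

    def validate(self, registry: VariableRegistry, max_parents: int = 3) -> None:
        for child, parents in self.intra_parents.items():
            if len(parents) > max_parents:
                raise SchemaError(f"{child}: more than {max_parents} intra-slice parents")
            for p in parents:
                if registry.index(p) >= registry.index(child):
                    raise SchemaError(f"{child}: parent {p} does not precede it")
        if self.temporal_vars != frozenset(registry.dynamic):
            raise SchemaError("temporal_vars must equal the declared dynamic variables")


@dataclass
class CPT:
    """Count and probability table for one family.

    ``counts``/``probs`` have shape ``(*parent_ks, k_child)``; for transition
    CPTs the first parent axis is the child's own previous-slice copy.
    """

    child: str
    parents: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray
    alpha: float

    def validate(self) -> None:
        rows = self.probs.reshape(-1, self.probs.shape[-1])
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ModelFormatError(f"{self.child}: probability rows do not sum to 1")
        if self.alpha > 0 and not (rows > 0).all():
            raise ModelFormatError(f"{self.child}: zero probability despite smoothing")


@dataclass
class DBNModel:
    """A fitted time-homogeneous 2-slice model.

    ``initial`` holds one CPT per variable (parents = learned intra-slice
    parents); ``transition`` holds CPTs for the temporal variables (parents =
    previous-slice self, then intra-slice parents).  Variables in
    ``deterministic`` (age) keep a hand-set deterministic transition that is
    never resampled when drawing from the parameter posterior.
    """

    registry: VariableRegistry
    structure: NetworkStructure
    alpha: float
    initial: dict[str, CPT]
    transition: dict[str, CPT]
    deterministic: frozenset = frozenset()
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.structure.validate(self.registry, max_parents=max(
            (len(p) for p in self.structure.intra_parents.values()), default=0) or 3)
        for cpt in self.initial.values():
            cpt.validate()
        for name, cpt in self.transition.items():
            if name not in self.deterministic:
                cpt.validate()
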