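"""Cross-impact balance (CIB) data model and consistency algorithm.

A CIB system is a set of qualitative factors, each of which can be in one
of a small number of discrete states (typically ``low``/``high``).  Experts
judge, for every ordered pair of factors, how much each state of the source
factor promotes (+) or restricts (-) each state of the target factor, on an
integer scale from -2 to +2.  These judgments form the cross-impact matrix.

A *scenario* assigns one state to every factor.  Within a scenario, the
*impact balance* of a factor is the per-state sum of incoming judgments
from every other factor's assigned state.  A scenario is *consistent* when
every factor sits in a state of maximal impact balance: no factor is under
pressure to switch.  Consistent scenarios are the internally plausible
futures of the system, and finding them is the point of the analysis.

Two consistency modes are supported:

``weak``
    the chosen state's balance is greater than or equal to every
    alternative's (ties allowed) — fixed points of the succession operator;
``strict``
    the chosen state's balance is strictly greater than every
    alternative's (unique maximum).

Enumeration of consistent scenarios is exhaustive over the full state
space (2^n for n binary factors), with a hard guard against state spaces
that are too large to enumerate.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    ScoreRangeError,
    SizeGuardError,
    ValidationError,
)

SCORE_MIN = -2
SCORE_MAX = 2

FACTOR_CATEGORIES = ("outcome", "intermediary", "structural")

MODES = ("weak", "strict")

#: Refuse exhaustive enumeration beyond this many candidate scenarios.
ENUMERATION_GUARD = 2**24

_CHUNK = 1 << 14  # candidate scenarios evaluated per vectorised block


def _canon(label: str) -> str:
    """Canonical form used for state-label matching: trimmed, lower-cased."""
    return label.strip().lower()


@dataclass(frozen=True)
class FactorDef:
    """One system factor: a name, ordered state labels and a category.

    Parameters
    ----------
    name:
        Short unique identifier (used in files and scenario assignments).
    label:
        Human-readable display label; defaults to ``name``.
    states:
        Ordered state labels, at least two; default ``("low", "high")``.
        The declared order defines the state index used for tie-breaking
        and canonical scenario ordering.
    category:
        One of ``outcome``, ``intermediary``, ``structural``.
    """

    name: str
    label: str = ""
    states: tuple[str, ...] = ("low", "high")
    category: str = "intermediary"

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.strip())
        object.__setattr__(self, "label", self.label.strip() or self.name)
        object.__setattr__(self, "states", tuple(s.strip() for s in self.states))
        if not self.name:
            raise ValidationError("factor name must be non-empty")
        if len(self.states) < 2:
            raise ValidationError(
                f"factor {self.name!r} needs at least 2 states, got {self.states!r}"
            )
        canon = [_canon(s) for s in self.states]
        if len(set(canon)) != len(canon):
            raise ValidationError(
                f"factor {self.name!r} has duplicate state labels: {self.states!r}"
            )
        if self.category not in FACTOR_CATEGORIES:
            raise ValidationError(
                f"factor {self.name!r}: category {self.category!r} not one of "
                f"{FACTOR_CATEGORIES}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        """Index of a state label, matched case-insensitively after trimming."""
        target = _canon(label)
        for i, s in enumerate(self.states):
            if _canon(s) == target:
                return i
        raise ValidationError(
            f"factor {self.name!r} has no state {label!r}; declared: {self.states!r}"
        )


class Scenario(Mapping):
    """An immutable assignment of one state label to every factor.

    Behaves as a read-only mapping ``factor name -> state label``.  Equality
    and hashing are label-canonical (trimmed, case-insensitive states), so
    scenarios deduplicate correctly across regions regardless of label
    casing in input files.
    """

    __slots__ = ("_assignment", "_key")

    def __init__(self, assignment: Mapping[str, str]):
        items = tuple(sorted((k.strip(), v.strip()) for k, v in assignment.items()))
        object.__setattr__(self, "_assignment", dict(items))
        object.__setattr__(
            self, "_key", tuple((k, _canon(v)) for k, v in items)
        )

    def __getitem__(self, factor: str) -> str:
        return self._assignment[factor.strip()]

    def __iter__(self) -> Iterator[str]:
        return iter(self._assignment)

    def __len__(self) -> int:
        return len(self._assignment)

    def __hash__(self) -> int:
        return hash(self._key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Scenario):
            return NotImplemented
        return self._key == other._key

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self._assignment.items())
        return f"Scenario({inner})"

    @property
    def assignment(self) -> dict[str, str]:
        """A fresh plain-dict copy of the assignment."""
        return dict(self._assignment)


class CrossImpactMatrix:
    """The cross-impact judgment matrix of a CIB system.

    Stores an integer score for every (source factor, source state,
    target factor, target state) combination; unset combinations are 0.
    Diagonal blocks (a factor judging itself) are structurally zero and
    cannot be set.

    Internally the scores live in a dense ``(n, S, n, S)`` integer array
    (``S`` = maximum state count) so that impact balances over thousands
    of candidate scenarios vectorise.
    """

    def __init__(self, factors: Sequence[FactorDef]):
        factors = tuple(factors)
        if len(factors) < 1:
            raise ValidationError("a matrix needs at least one factor")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate factor names: {names!r}")
        self._factors = factors
        self._index = {f.name: i for i, f in enumerate(factors)}
        smax = max(f.n_states for f in factors)
        self._scores = np.zeros((len(factors), smax, len(factors), smax), dtype=np.int64)
        # valid[k, t] marks declared state slots of factor k
        self._valid = np.zeros((len(factors), smax), dtype=bool)
        for i, f in enumerate(factors):
            self._valid[i, : f.n_states] = True

    # -- structure ---------------------------------------------------------

    @property
    def factors(self) -> tuple[FactorDef, ...]:
        return self._factors

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self._factors)

    @property
    def n_factors(self) -> int:
        return len(self._factors)

    def factor(self, name: str) -> FactorDef:
        i = self._index.get(name.strip())
        if i is None:
            raise ValidationError(
                f"unknown factor {name!r}; declared: {self.factor_names!r}"
            )
        return self._factors[i]

    def factor_index(self, name: str) -> int:
        self.factor(name)
        return self._index[name.strip()]

    def state_space_size(self, fixed: Mapping[str, str] | None = None) -> int:
        """Number of scenarios extending ``fixed`` (the full space if empty)."""
        fixed_idx = self._fixed_indices(fixed or {})
        size = 1
        for i, f in enumerate(self._factors):
            if i not in fixed_idx:
                size *= f.n_states
        return size

    # -- scores ------------------------------------------------------------

    def set_score(
        self, source: str, source_state: str, target: str, target_state: str, value: int
    ) -> None:
        j = self.factor_index(source)
        k = self.factor_index(target)
        s = self._factors[j].state_index(source_state)
        t = self._factors[k].state_index(target_state)
        value = int(value)
        if not (SCORE_MIN <= value <= SCORE_MAX):
            raise ScoreRangeError(
                f"score {value} for ({source},{source_state})->({target},{target_state}) "
                f"outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        if j == k and value != 0:
            raise ValidationError(
                f"self-impact is not allowed: ({source},{source_state})->"
                f"({target},{target_state})"
            )
        self._scores[j, s, k, t] = value

    def score(
        self, source: str, source_state: str, target: str, target_state: str
    ) -> int:
        j = self.factor_index(source)
        k = self.factor_index(target)
        s = self._factors[j].state_index(source_state)
        t = self._factors[k].state_index(target_state)
        return int(self._scores[j, s, k, t])

    def nonzero_judgments(self) -> Iterator[tuple[str, str, str, str, int]]:
        """Iterate nonzero judgments as (source, src_state, target, tgt_state, score),
        in declared factor/state order."""
        for j, fj in enumerate(self._factors):
            for s, sl in enumerate(fj.states):
                for k, fk in enumerate(self._factors):
                    for t, tl in enumerate(fk.states):
                        v = int(self._scores[j, s, k, t])
                        if v != 0:
                            yield (fj.name, sl, fk.name, tl, v)

    def copy(self) -> "CrossImpactMatrix":
        out = CrossImpactMatrix(self._factors)
        out._scores[...] = self._scores
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossImpactMatrix):
            return NotImplemented
        return self._factors == other._factors and np.array_equal(
            self._scores, other._scores
        )

    def __repr__(self) -> str:
        nz = int(np.count_nonzero(self._scores))
        return (
            f"CrossImpactMatrix({self.n_factors} factors, {nz} nonzero judgments)"
        )

    # -- scenario plumbing -------------------------------------------------

    def scenario_indices(self, scenario: Mapping[str, str]) -> np.ndarray:
        """State-index vector of a complete, valid scenario (declared factor order)."""
        idx = np.empty(self.n_factors, dtype=np.int64)
        seen = set()
        for name, state in scenario.items():
            i = self.factor_index(name)
            idx[i] = self._factors[i].state_index(state)
            seen.add(i)
        if len(seen) != self.n_factors:
            missing = [f.name for i, f in enumerate(self._factors) if i not in seen]
            raise ValidationError(f"scenario is missing factors: {missing!r}")
        return idx

    def scenario_from_indices(self, idx: Sequence[int]) -> Scenario:
        return Scenario(
            {f.name: f.states[int(i)] for f, i in zip(self._factors, idx)}
        )

    def _fixed_indices(self, fixed: Mapping[str, str]) -> dict[int, int]:
        out: dict[int, int] = {}
        for name, state in fixed.items():
            i = self.factor_index(name)
            out[i] = self._factors[i].state_index(state)
        return out

    def _balance_array(self, assign: np.ndarray) -> np.ndarray:
        """Impact balances for a batch of scenarios.

        ``assign`` has shape (m, n); the result has shape (m, n, S) where
        entry [m, k, t] is the balance of state t of factor k in scenario m.
        Undeclared state slots are 0 and must be masked by callers.
        """
        m = assign.shape[0]
        bal = np.zeros((m, self.n_factors, self._scores.shape[1]), dtype=np.int64)
        for j in range(self.n_factors):
            bal += self._scores[j, assign[:, j]]
        return bal


@dataclass(frozen=True)
class ImpactBalance:
    """Per-state incoming-judgment sums for one factor within one scenario."""

    target: str
    scores: dict[str, int]

    def best_states(self) -> tuple[str, ...]:
        top = max(self.scores.values())
        return tuple(s for s, v in self.scores.items() if v == top)


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of checking one scenario against the matrix.

    ``inconsistency`` is the worst pressure to switch: the maximum over
    factors of (best alternative balance - chosen-state balance), floored
    at 0.  It is 0 exactly when the scenario is weakly consistent.
    """

    scenario: Scenario
    consistent: bool
    mode: str
    inconsistency: int
    violating_factors: tuple[str, ...] = field(default_factory=tuple)


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ConfigurationError(f"consistency mode must be one of {MODES}, got {mode!r}")
    return mode


def impact_balance(
    matrix: CrossImpactMatrix, scenario: Mapping[str, str], target: str
) -> ImpactBalance:
    """Impact balance of ``target`` under ``scenario``.

    For each state t of the target factor, the balance is the sum over all
    other factors j of the judgment score from (j, scenario[j]) onto
    (target, t).  The target's own (zero) diagonal block contributes
    nothing, so each entry lies in [-2(n-1), +2(n-1)].
    """
    k = matrix.factor_index(target)
    idx = matrix.scenario_indices(scenario)
    bal = matrix._balance_array(idx[None, :])[0, k]
    f = matrix.factors[k]
    return ImpactBalance(
        target=f.name, scores={s: int(bal[t]) for t, s in enumerate(f.states)}
    )


def consistency_report(
    matrix: CrossImpactMatrix,
    scenario: Mapping[str, str],
    mode: str = "weak",
    tolerance: int = 0,
) -> ConsistencyReport:
    """Check one scenario for consistency.

    Weak mode accepts ties (chosen balance >= every alternative); strict
    mode demands a unique maximum.  A non-negative ``tolerance`` relaxes
    the comparison: a factor passes when its balance deficit relative to
    the best alternative is <= tolerance (weak) or < tolerance (strict),
    so tolerance 0 recovers the exact definitions.
    """
    _check_mode(mode)
    if tolerance < 0:
        raise ConfigurationError(f"tolerance must be >= 0, got {tolerance}")
    idx = matrix.scenario_indices(scenario)
    bal = matrix._balance_array(idx[None, :])[0]  # (n, S)
    n = matrix.n_factors
    chosen = bal[np.arange(n), idx]
    # best alternative balance per factor (excluding the chosen state)
    alt = bal.astype(float)
    alt[~matrix._valid] = -np.inf
    alt[np.arange(n), idx] = -np.inf
    deficit = alt.max(axis=1) - chosen  # > 0 means pressure to switch
    if mode == "weak":
        fails = deficit > tolerance
    else:
        fails = deficit >= tolerance
    inconsistency = int(max(0.0, deficit.max()))
    violating = tuple(
        matrix.factors[i].name for i in range(n) if fails[i]
    )
    scen = scenario if isinstance(scenario, Scenario) else Scenario(scenario)
    return ConsistencyReport(
        scenario=scen,
        consistent=not fails.any(),
        mode=mode,
        inconsistency=inconsistency,
        violating_factors=violating,
    )


def enumerate_consistent(
    matrix: CrossImpactMatrix,
    fixed: Mapping[str, str] | None = None,
    mode: str = "weak",
    tolerance: int = 0,
    guard: int = ENUMERATION_GUARD,
) -> list[Scenario]:
    """All consistent scenarios extending a (possibly empty) fixing.

    Every candidate scenario in the state space that extends ``fixed`` is
    tested; those whose FREE factors all satisfy the mode's consistency
    condition are returned.  Fixed factors are exempt from the condition —
    that is what makes fixing an *intervention*: the factor is held in
    place by an external stimulus rather than by the system — but their
    states still feed every other factor's balance.

    Results come in canonical order: lexicographic by declared factor
    order and state index.  The list may be empty.

    Raises :class:`SizeGuardError` if the candidate count exceeds ``guard``.
    """
    _check_mode(mode)
    if tolerance < 0:
        raise ConfigurationError(f"tolerance must be >= 0, got {tolerance}")
    fixed = fixed or {}
    fixed_idx = matrix._fixed_indices(fixed)
    space = matrix.state_space_size(fixed)
    if space > guard:
        raise SizeGuardError(space, guard)

    n = matrix.n_factors
    free = np.array([i for i in range(n) if i not in fixed_idx], dtype=np.int64)
    per_factor = [
        [fixed_idx[i]] if i in fixed_idx else list(range(matrix.factors[i].n_states))
        for i in range(n)
    ]

    out: list[Scenario] = []
    it = itertools.product(*per_factor)
    while True:
        block = list(itertools.islice(it, _CHUNK))
        if not block:
            break
        assign = np.array(block, dtype=np.int64)
        bal = matrix._balance_array(assign)  # (m, n, S)
        m = assign.shape[0]
        chosen = np.take_along_axis(bal, assign[:, :, None], axis=2)[:, :, 0]
        alt = bal.astype(float)
        alt[:, ~matrix._valid] = -np.inf
        np.put_along_axis(alt, assign[:, :, None], -np.inf, axis=2)
        deficit = alt.max(axis=2) - chosen  # (m, n)
        if mode == "weak":
            ok_factor = deficit <= tolerance
        else:
            ok_factor = deficit < tolerance
        if free.size:
            ok = ok_factor[:, free].all(axis=1)
        else:
            ok = np.ones(m, dtype=bool)
        for row in assign[ok]:
            out.append(matrix.scenario_from_indices(row))
    return out


def succession(
    matrix: CrossImpactMatrix,
    scenario: Mapping[str, str],
    tie_rule: str = "keep_current",
) -> Scenario:
    """One step of the succession operator: each factor moves to a state of
    maximal impact balance.

    Ties are resolved by ``tie_rule``: ``keep_current`` retains the incoming
    state when it is among the maxima (so fixed points are exactly the
    weakly consistent scenarios); ``first_state`` takes the lowest-index
    maximal state.  This is a single-step operator used for testing the
    solver's fixed-point characterisation, not an iterative solver.
    """
    if tie_rule not in ("keep_current", "first_state"):
        raise ConfigurationError(
            f"tie_rule must be 'keep_current' or 'first_state', got {tie_rule!r}"
        )
    idx = matrix.scenario_indices(scenario)
    bal = matrix._balance_array(idx[None, :])[0].astype(float)
    bal[~matrix._valid] = -np.inf
    nxt = np.empty_like(idx)
    for k in range(matrix.n_factors):
        top = bal[k].max()
        maxima = np.flatnonzero(bal[k] == top)
        if tie_rule == "keep_current" and idx[k] in maxima:
            nxt[k] = idx[k]
        else:
            nxt[k] = maxima[0]
    return matrix.scenario_from_indices(nxt)
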