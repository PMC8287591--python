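"""Shared fixtures: a hand-checkable 3-factor toy system and an
independent pure-Python brute-force consistency oracle.

The oracle deliberately avoids the package's vectorised balance code: it
sums judgment scores one lookup at a time via the public ``score``
accessor, so solver tests compare two genuinely different routes.
"""

from __future__ import annotations

import itertools

import pytest

from cibscen import (
    CrossImpactMatrix,
    FactorDef,
    Scenario,
    default_factors,
    default_promoting_map,
)


def make_toy_matrix() -> CrossImpactMatrix:
    """3-factor cycle A -> B -> C -> A with hand-computable balances.

    A=high pushes B high (+/-2); A=low weakly pushes B low (+/-1);
    B=high weakly pushes C high (+/-1); B=low says nothing about C;
    C pushes A toward C's own state (+/-2 both rows).
    """
    factors = [FactorDef(n) for n in "ABC"]
    m = CrossImpactMatrix(factors)
    m.set_score("A", "high", "B", "low", -2)
    m.set_score("A", "high", "B", "high", 2)
    m.set_score("A", "low", "B", "low", 1)
    m.set_score("A", "low", "B", "high", -1)
    m.set_score("B", "high", "C", "low", -1)
    m.set_score("B", "high", "C", "high", 1)
    m.set_score("C", "high", "A", "low", -2)
    m.set_score("C", "high", "A", "high", 2)
    m.set_score("C", "low", "A", "low", 2)
    m.set_score("C", "low", "A", "high", -2)
    return m


@pytest.fixture
def toy_matrix() -> CrossImpactMatrix:
    return make_toy_matrix()


@pytest.fixture
def factors11():
    return default_factors()


@pytest.fixture
def pmap11():
    return default_promoting_map()


# ---------------------------------------------------------------------------
# independent oracle

def oracle_balance(matrix: CrossImpactMatrix, scenario, target: str) -> dict[str, int]:
    """Per-state incoming sums computed by plain score lookups."""
    tgt = matrix.factor(target)
    out = {}
    for state in tgt.states:
        total = 0
        for f in matrix.factors:
            if f.name == target:
                continue
            total += matrix.score(f.name, scenario[f.name], target, state)
        out[state] = total
    return out


def oracle_consistent(matrix, scenario, mode="weak", free=None) -> bool:
    """Is the scenario consistent?  ``free`` restricts the check to a
    subset of factors (fixed factors are exempt under an intervention)."""
    names = free if free is not None else [f.name for f in matrix.factors]
    for name in names:
        bal = oracle_balance(matrix, scenario, name)
        chosen = bal[scenario[name]]
        others = [v for s, v in bal.items() if s != scenario[name]]
        if mode == "weak":
            if any(v > chosen for v in others):
                return False
        else:
            if any(v >= chosen for v in others):
                return False
    return True


def oracle_enumerate(matrix, mode="weak", fixed=None) -> set[Scenario]:
    """Brute force every scenario in the state space."""
    fixed = fixed or {}
    names = [f.name for f in matrix.factors]
    free = [n for n in names if n not in fixed]
    choices = [
        [fixed[f.name]] if f.name in fixed else list(f.states)
        for f in matrix.factors
    ]
    out = set()
    for combo in itertools.product(*choices):
        scenario = dict(zip(names, combo))
        if oracle_consistent(matrix, scenario, mode=mode, free=free):
            out.add(Scenario(scenario))
    return out
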