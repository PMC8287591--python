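"""Seeded generators for synthetic elicitation data and test instances.

The regional cross-impact matrices behind published CIB studies are
rarely deposited; what is typically reported is summary structure — how
many of the possible directed relationships were elicited, and what
fraction were judged nonlinear.  The generators here emulate exactly that
structure for the default 11-factor system: three regional profiles with
(39, 0.87), (53, 0.81) and (60, 0.77) as (relationship count, nonlinear
fraction) for Brazil, Peru and Guatemala respectively, out of the 110
possible ordered pairs.  Synthetic fixtures therefore share the published
matrices' density and shape statistics, not their content: scenario sets
derived from them are plausible stand-ins, not reproductions.

Every generator is deterministic given its seed; per-region streams are
derived from (seed, region name) so regions are independently
reproducible.
"""

from __future__ import annotations

import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .core import CrossImpactMatrix, FactorDef, Scenario
from .defaults import default_factors
from .elicitation import (
    LINEAR_SHAPES,
    EncodingTable,
    RelationResponse,
    build_matrix,
)
from .errors import InfeasibleMarginError, ValidationError

#: (region, n elicited relationships of 110, nonlinear fraction)
DEFAULT_REGION_STATS: tuple[tuple[str, int, float], ...] = (
    ("Brazil", 39, 0.87),
    ("Peru", 53, 0.81),
    ("Guatemala", 60, 0.77),
)


@dataclass(frozen=True)
class RegionProfile:
    """Statistical profile of one region's elicitation round."""

    region: str
    n_relationships: int
    nonlinear_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relationships < 0:
            raise ValidationError(
                f"n_relationships must be >= 0, got {self.n_relationships}"
            )
        if not (0.0 <= self.nonlinear_fraction <= 1.0):
            raise ValidationError(
                f"nonlinear_fraction must lie in [0, 1], got {self.nonlinear_fraction}"
            )


def _rng(seed: int, name: str) -> np.random.Generator:
    """Stream derived from (seed, name); stable across runs and platforms."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def generate_responses(
    factors: Sequence[FactorDef],
    profile: RegionProfile,
    table: EncodingTable | None = None,
) -> list[RelationResponse]:
    """Draw one region's questionnaire responses.

    Exactly ``profile.n_relationships`` ordered pairs (sampled without
    replacement from the n(n-1) possibilities) get ``exists=true``; each
    draws a shape from the nonlinear class with probability
    ``nonlinear_fraction`` and from the linear class otherwise, uniformly
    within the class.  Pairs not drawn are returned as ``exists=false``
    responses so the output covers every ordered pair.
    """
    table = table or EncodingTable.default()
    names = [f.name for f in factors]
    pairs = [(a, b) for a in names for b in names if a != b]
    if profile.n_relationships > len(pairs):
        raise ValidationError(
            f"{profile.n_relationships} relationships requested but only "
            f"{len(pairs)} ordered pairs exist"
        )
    linear = sorted(s for s in table.shapes if s in LINEAR_SHAPES)
    nonlinear = sorted(s for s in table.shapes if s not in LINEAR_SHAPES)
    rng = _rng(profile.seed, profile.region)
    chosen_idx = rng.choice(len(pairs), size=profile.n_relationships, replace=False)
    chosen = {pairs[i] for i in chosen_idx}
    responses: list[RelationResponse] = []
    for pair in pairs:
        if pair not in chosen:
            responses.append(RelationResponse(pair[0], pair[1], exists=False))
            continue
        use_nonlinear = rng.random() < profile.nonlinear_fraction
        pool = nonlinear if use_nonlinear and nonlinear else linear
        if not pool:
            pool = nonlinear or list(table.shapes)
        shape = pool[int(rng.integers(len(pool)))]
        responses.append(RelationResponse(pair[0], pair[1], exists=True, shape=shape))
    return responses


def generate_random_matrix(
    n_factors: int,
    n_states: int = 2,
    density: float = 0.5,
    seed: int = 0,
) -> CrossImpactMatrix:
    """Random matrix for oracle testing: each off-diagonal block is nonzero
    with probability ``density``; nonzero entries are uniform on
    {-2, -1, 1, 2}."""
    if n_factors < 2:
        raise ValidationError(f"need at least 2 factors, got {n_factors}")
    if n_states < 2:
        raise ValidationError(f"need at least 2 states, got {n_states}")
    if not (0.0 <= density <= 1.0):
        raise ValidationError(f"density must lie in [0, 1], got {density}")
    states = tuple(f"s{i}" for i in range(n_states)) if n_states != 2 else ("low", "high")
    factors = [FactorDef(f"f{i}", states=states) for i in range(n_factors)]
    matrix = CrossImpactMatrix(factors)
    rng = _rng(seed, "random_matrix")
    values = np.array([-2, -1, 1, 2])
    for j in range(n_factors):
        for k in range(n_factors):
            if j == k:
                continue
            if rng.random() >= density:
                continue
            for s in range(n_states):
                for t in range(n_states):
                    v = int(values[rng.integers(4)])
                    matrix.set_score(
                        factors[j].name, states[s], factors[k].name, states[t], v
                    )
    return matrix


def plant_consistent_scenario(
    factors: Sequence[FactorDef],
    target: Mapping[str, str],
    margin: int = 4,
    seed: int = 0,
) -> CrossImpactMatrix:
    """Construct a matrix in which ``target`` is strictly consistent by a
    known margin.

    For every factor k, designated source factors are given judgments of
    +2 toward k's target state and -2 toward its alternatives, from the
    source's own target state.  Each such source contributes a balance gap
    of 4, so ceil(margin/4) sources are used per factor; a margin above
    4*(n-1) is infeasible on the +/-2 scale.

    Only the rows for the sources' *target* states are written; the rows
    for their alternative states stay zero.  The planted scenario is
    therefore guaranteed strictly consistent, but other scenarios (whose
    balances are all-zero ties) may additionally be weakly consistent.
    """
    if margin < 1:
        raise ValidationError(f"margin must be >= 1, got {margin}")
    factors = list(factors)
    n = len(factors)
    per_source_gap = 4  # +2 on the target state vs -2 on an alternative
    needed = math.ceil(margin / per_source_gap)
    if needed > n - 1:
        raise InfeasibleMarginError(
            f"margin {margin} needs {needed} source factors per target but only "
            f"{n - 1} are available on the +/-{2} scale"
        )
    matrix = CrossImpactMatrix(factors)
    target_scen = target if isinstance(target, Scenario) else Scenario(target)
    rng = _rng(seed, "plant")
    for k, fk in enumerate(factors):
        others = [j for j in range(n) if j != k]
        sources = rng.permutation(others)[:needed]
        tgt_state = target_scen[fk.name]
        fk.state_index(tgt_state)  # validate
        for j in sources:
            fj = factors[j]
            src_state = target_scen[fj.name]
            for state in fk.states:
                v = 2 if fk.state_index(state) == fk.state_index(tgt_state) else -2
                matrix.set_score(fj.name, src_state, fk.name, state, v)
    return matrix


@dataclass(frozen=True)
class RegionFixture:
    """One synthetic region: its profile, responses and encoded matrix."""

    profile: RegionProfile
    responses: tuple[RelationResponse, ...]
    matrix: CrossImpactMatrix


def make_multiregion_fixture(
    seed: int = 0,
    factors: Sequence[FactorDef] | None = None,
    table: EncodingTable | None = None,
) -> dict[str, RegionFixture]:
    """Three-region synthetic elicitation fixture over the default
    11-factor system (Brazil: 39 relationships, 87% nonlinear; Peru: 53,
    81%; Guatemala: 60, 77%).  Deterministic from ``seed``."""
    factors = list(factors) if factors is not None else default_factors()
    table = table or EncodingTable.default()
    out: dict[str, RegionFixture] = {}
    for region, n_rel, frac in DEFAULT_REGION_STATS:
        profile = RegionProfile(region, n_rel, frac, seed=seed)
        responses = generate_responses(factors, profile, table)
        matrix = build_matrix(responses, factors, table)
        out[region] = RegionFixture(
            profile=profile, responses=tuple(responses), matrix=matrix
        )
    return out
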