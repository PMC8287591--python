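"""Encoding of questionnaire responses into cross-impact judgment blocks.

The elicitation protocol asks, for each ordered pair of factors (X, Y):
"Does X directly influence Y?"  If yes, the expert selects, from a small
catalog, the graph shape that best describes the relationship (linear,
saturating, threshold, U-shaped, ...).  Each shape maps deterministically
to a 2x2 integer judgment block on the -2..+2 scale — rows indexed by the
source factor's state (low, high), columns by the target factor's state
(low, high) — which is written into the cross-impact matrix.

The default shape-to-block table is an explicit, overridable artifact of
this package (published elicitation studies do not always print their
mapping): linear shapes use the full +/-2 strength in both rows;
saturating shapes are strong (+/-2) at the low source state and weak
(+/-1) at the high one; threshold shapes are the reverse; U-shaped and
inverted-U shapes have both source states weakly pushing the target to
one side.  Every default block has zero-sum rows, so a source state's
promotion of one target state is balanced by restriction of the other.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .core import SCORE_MAX, SCORE_MIN, CrossImpactMatrix, FactorDef
from .errors import CatalogError, DuplicateJudgmentError, ValidationError

Block = tuple[tuple[int, int], tuple[int, int]]

#: shape id -> 2x2 block, rows = source state (low, high), cols = target (low, high)
DEFAULT_SHAPE_BLOCKS: dict[str, Block] = {
    "linear_increasing": ((2, -2), (-2, 2)),
    "linear_decreasing": ((-2, 2), (2, -2)),
    "saturating_increasing": ((2, -2), (-1, 1)),
    "saturating_decreasing": ((-2, 2), (1, -1)),
    "threshold_increasing": ((1, -1), (-2, 2)),
    "threshold_decreasing": ((-1, 1), (2, -2)),
    "u_shaped": ((-1, 1), (-1, 1)),
    "inverted_u": ((1, -1), (1, -1)),
}

#: shapes counted as linear; everything else in a catalog is nonlinear
LINEAR_SHAPES = frozenset({"linear_increasing", "linear_decreasing"})

ZERO_BLOCK: Block = ((0, 0), (0, 0))


@dataclass(frozen=True)
class RelationResponse:
    """One questionnaire answer about an ordered factor pair.

    ``exists`` records the direct-influence yes/no; ``shape`` is the
    selected relationship shape, required exactly when ``exists`` is true.
    """

    source: str
    target: str
    exists: bool
    shape: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", self.source.strip())
        object.__setattr__(self, "target", self.target.strip())
        if self.source == self.target:
            raise ValidationError(
                f"a factor cannot influence itself: {self.source!r}"
            )
        if self.exists and not self.shape:
            raise ValidationError(
                f"response {self.source}->{self.target}: exists=true requires a shape"
            )
        if not self.exists and self.shape:
            raise ValidationError(
                f"response {self.source}->{self.target}: exists=false forbids a shape"
            )


class EncodingTable:
    """Mapping from shape ids to 2x2 judgment blocks.

    Blocks are validated to the -2..+2 integer range on construction.
    Rows that do not sum to zero are legal but reported by
    :func:`validate_matrix`-style checks as warnings (see :meth:`issues`).
    """

    def __init__(self, blocks: Mapping[str, Sequence[Sequence[int]]]):
        if not blocks:
            raise ValidationError("encoding table must contain at least one shape")
        self._blocks: dict[str, Block] = {}
        for shape, block in blocks.items():
            arr = np.asarray(block, dtype=np.int64)
            if arr.shape != (2, 2):
                raise ValidationError(
                    f"shape {shape!r}: block must be 2x2, got {arr.shape}"
                )
            if arr.min() < SCORE_MIN or arr.max() > SCORE_MAX:
                raise ValidationError(
                    f"shape {shape!r}: block entries must lie in "
                    f"[{SCORE_MIN}, {SCORE_MAX}]: {arr.tolist()}"
                )
            self._blocks[shape.strip()] = tuple(map(tuple, arr.tolist()))

    @classmethod
    def default(cls) -> "EncodingTable":
        return cls(DEFAULT_SHAPE_BLOCKS)

    @property
    def shapes(self) -> tuple[str, ...]:
        return tuple(self._blocks)

    def block(self, shape: str) -> Block:
        try:
            return self._blocks[shape.strip()]
        except KeyError:
            raise CatalogError(shape, self.shapes) from None

    def __contains__(self, shape: str) -> bool:
        return shape.strip() in self._blocks

    def items(self):
        return self._blocks.items()

    def issues(self) -> list[str]:
        """Non-fatal warnings: rows whose entries do not sum to zero."""
        out = []
        for shape, block in self._blocks.items():
            for r, row in enumerate(block):
                if sum(row) != 0:
                    out.append(
                        f"shape {shape!r}: source-state row {r} is not zero-sum: {row}"
                    )
        return out


def encode_response(response: RelationResponse, table: EncodingTable) -> Block:
    """The judgment block a response contributes: all zeros if no direct
    influence, else the table's block for the selected shape."""
    if not response.exists:
        return ZERO_BLOCK
    return table.block(response.shape)  # type: ignore[arg-type]


def build_matrix(
    responses: Iterable[RelationResponse],
    factors: Sequence[FactorDef],
    table: EncodingTable | None = None,
) -> CrossImpactMatrix:
    """Assemble a cross-impact matrix from a full set of responses.

    Each ordered pair may carry at most one response (elicitation collects
    each relationship from a single expert); a duplicate pair raises.
    Pairs without a response, and responses with ``exists=false``, leave
    their block at zero.  All factors must be binary (two states) because
    shape blocks are 2x2.
    """
    table = table or EncodingTable.default()
    for f in factors:
        if f.n_states != 2:
            raise ValidationError(
                f"shape encoding requires binary factors; {f.name!r} has "
                f"{f.n_states} states"
            )
    matrix = CrossImpactMatrix(factors)
    seen: set[tuple[str, str]] = set()
    for resp in responses:
        pair = (resp.source, resp.target)
        if pair in seen:
            raise DuplicateJudgmentError(
                f"duplicate response for pair {resp.source}->{resp.target}"
            )
        seen.add(pair)
        block = encode_response(resp, table)
        src = matrix.factor(resp.source)
        tgt = matrix.factor(resp.target)
        for s, row in enumerate(block):
            for t, v in enumerate(row):
                if v != 0:
                    matrix.set_score(src.name, src.states[s], tgt.name, tgt.states[t], v)
    return matrix


@dataclass(frozen=True)
class ValidationReport:
    """Report-only matrix check: an empty issue list means valid."""

    issues: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_matrix(matrix: CrossImpactMatrix) -> ValidationReport:
    """Check score range and zero diagonal blocks of a matrix.

    Matrices built through :class:`CrossImpactMatrix` setters cannot
    violate these, but matrices assembled from files or by hand-editing
    internal arrays can; this is the guard used by readers and generators.
    """
    issues: list[str] = []
    scores = matrix._scores
    bad = np.argwhere((scores < SCORE_MIN) | (scores > SCORE_MAX))
    for j, s, k, t in bad:
        issues.append(
            f"score out of range [{SCORE_MIN},{SCORE_MAX}]: "
            f"({matrix.factors[j].name},{matrix.factors[j].states[s]})->"
            f"({matrix.factors[k].name},{matrix.factors[k].states[t]}) = "
            f"{int(scores[j, s, k, t])}"
        )
    for j, f in enumerate(matrix.factors):
        if np.any(scores[j, :, j, :] != 0):
            issues.append(f"nonzero self-impact block for factor {f.name!r}")
    return ValidationReport(issues=tuple(issues))
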