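"""Readers, writers and the scenario-table report.

File formats (all UTF-8 plain text):

matrix CSV
    header ``source_factor,source_state,target_factor,target_state,score``;
    one row per nonzero judgment, integer score in [-2, 2]; omitted pairs
    are zero; duplicate keys are an error.
responses CSV
    header ``source,target,exists,shape``; booleans as ``true``/``false``;
    shape empty when exists is false.
factor config (YAML or JSON)
    ``factors:`` list of ``{name, label, states, category,
    promoting_state}`` plus an optional ``outcomes:`` list (defaults to
    the factors with category ``outcome``).
encoding table (YAML or JSON)
    mapping shape id -> 4 integers, row-major (source low/high x target
    low/high).
scenarios CSV
    header ``region,number,<factor names...>,category,salubrious,
    promoting_count``.
sweep CSV / JSON
    one row per intervention: ``fixed_factor,fixed_state,n_scenarios,
    pct_promoting,pct_healthy,pct_mixed,pct_unhealthy,pct_salubrious``
    plus one ``pct_<outcome>`` column per outcome factor; percentages at
    one decimal place; metric cells empty for empty scenario sets.

Every written file starts with a comment line carrying the tool version
and a digest of the canonical body, so outputs are traceable; readers
skip leading ``#`` comment lines.  Write-after-read is byte-identical for
canonicalised inputs.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .analysis import (
    CATEGORY_ORDER,
    DEFAULT_SALUBRIOUS_THRESHOLD,
    InterventionResult,
    PooledScenarios,
    PromotingMap,
    ScenarioClassification,
    classify_scenario,
)
from .core import SCORE_MAX, SCORE_MIN, CrossImpactMatrix, FactorDef, Scenario
from .elicitation import EncodingTable, RelationResponse
from .errors import DuplicateJudgmentError, ParseError, ValidationError

_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


# ---------------------------------------------------------------------------
# header comments

def _with_header(body: str, extra: Mapping[str, str] | None = None) -> str:
    digest = hashlib.sha256(body.encode("utf-8")).hexdigest()[:12]
    parts = [f"# cibscen {__version__}", f"digest={digest}"]
    for k, v in (extra or {}).items():
        parts.append(f"{k}={v}")
    return " ".join(parts) + "\n" + body


def file_digest(path: str | Path) -> str:
    """Short sha256 digest of a file's bytes, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _read_lines(path: str | Path) -> list[tuple[int, str]]:
    """(1-based line number, content) pairs with comment lines removed."""
    p = Path(path)
    if not p.exists():
        raise ParseError(p, None, None, "file not found")
    out = []
    for i, line in enumerate(p.read_text(encoding="utf-8").splitlines(), start=1):
        if line.startswith("#"):
            continue
        out.append((i, line))
    return out


def _parse_csv(
    path: str | Path, expected_header: Sequence[str]
) -> list[tuple[int, dict[str, str]]]:
    lines = _read_lines(path)
    if not lines:
        raise ParseError(path, None, None, "empty file")
    header_line_no, header_line = lines[0]
    header = next(csv.reader([header_line]))
    if [h.strip() for h in header] != list(expected_header):
        raise ParseError(
            path,
            header_line_no,
            None,
            f"expected header {','.join(expected_header)!r}, got {header_line!r}",
        )
    rows = []
    for line_no, line in lines[1:]:
        if not line.strip():
            continue
        values = next(csv.reader([line]))
        if len(values) != len(expected_header):
            raise ParseError(
                path, line_no, None,
                f"expected {len(expected_header)} fields, got {len(values)}",
            )
        rows.append((line_no, dict(zip(expected_header, values))))
    return rows


# ---------------------------------------------------------------------------
# matrix CSV

MATRIX_HEADER = ("source_factor", "source_state", "target_factor", "target_state", "score")


def read_matrix_csv(path: str | Path, factors: Sequence[FactorDef]) -> CrossImpactMatrix:
    matrix = CrossImpactMatrix(factors)
    seen: set[tuple[str, str, str, str]] = set()
    for line_no, row in _parse_csv(path, MATRIX_HEADER):
        try:
            score = int(row["score"])
        except ValueError:
            raise ParseError(
                path, line_no, "score", f"not an integer: {row['score']!r}"
            ) from None
        if not (SCORE_MIN <= score <= SCORE_MAX):
            raise ParseError(
                path, line_no, "score",
                f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]",
            )
        key = (
            row["source_factor"].strip(),
            row["source_state"].strip().lower(),
            row["target_factor"].strip(),
            row["target_state"].strip().lower(),
        )
        if key in seen:
            raise ParseError(
                path, line_no, None,
                f"duplicate judgment row for "
                f"({row['source_factor']},{row['source_state']})->"
                f"({row['target_factor']},{row['target_state']})",
            )
        seen.add(key)
        try:
            matrix.set_score(
                row["source_factor"], row["source_state"],
                row["target_factor"], row["target_state"], score,
            )
        except ValidationError as exc:
            raise ParseError(path, line_no, None, str(exc)) from None
    return matrix


def matrix_to_csv_body(matrix: CrossImpactMatrix) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(MATRIX_HEADER)
    for src, s, tgt, t, v in matrix.nonzero_judgments():
        w.writerow([src, s, tgt, t, v])
    return buf.getvalue()


def write_matrix_csv(
    matrix: CrossImpactMatrix, path: str | Path,
    extra: Mapping[str, str] | None = None,
) -> None:
    Path(path).write_text(_with_header(matrix_to_csv_body(matrix), extra), encoding="utf-8")


# ---------------------------------------------------------------------------
# responses CSV

RESPONSES_HEADER = ("source", "target", "exists", "shape")


def _parse_bool(raw: str, path, line_no) -> bool:
    v = raw.strip().lower()
    if v in ("true", "yes", "1"):
        return True
    if v in ("false", "no", "0"):
        return False
    raise ParseError(path, line_no, "exists", f"not a boolean: {raw!r}")


def read_responses_csv(path: str | Path) -> list[RelationResponse]:
    responses = []
    seen: set[tuple[str, str]] = set()
    for line_no, row in _parse_csv(path, RESPONSES_HEADER):
        pair = (row["source"].strip(), row["target"].strip())
        if pair in seen:
            raise ParseError(
                path, line_no, None,
                f"duplicate response for pair {pair[0]}->{pair[1]}",
            )
        seen.add(pair)
        exists = _parse_bool(row["exists"], path, line_no)
        shape = row["shape"].strip() or None
        try:
            responses.append(
                RelationResponse(pair[0], pair[1], exists=exists, shape=shape)
            )
        except ValidationError as exc:
            raise ParseError(path, line_no, None, str(exc)) from None
    return responses


def responses_to_csv_body(responses: Sequence[RelationResponse]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(RESPONSES_HEADER)
    for r in responses:
        w.writerow([r.source, r.target, "true" if r.exists else "false", r.shape or ""])
    return buf.getvalue()


def write_responses_csv(
    responses: Sequence[RelationResponse], path: str | Path,
    extra: Mapping[str, str] | None = None,
) -> None:
    Path(path).write_text(
        _with_header(responses_to_csv_body(responses), extra), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# factor config (YAML/JSON)

def read_factor_config(path: str | Path) -> tuple[list[FactorDef], PromotingMap]:
    p = Path(path)
    if not p.exists():
        raise ParseError(p, None, None, "file not found")
    try:
        data = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(p, None, None, f"invalid YAML/JSON: {exc}") from None
    if not isinstance(data, dict) or "factors" not in data:
        raise ParseError(p, None, "factors", "config must contain a 'factors' list")
    factors: list[FactorDef] = []
    promoting: dict[str, str] = {}
    for i, item in enumerate(data["factors"]):
        if not isinstance(item, dict) or "name" not in item:
            raise ParseError(p, None, f"factors[{i}]", "each factor needs a 'name'")
        try:
            f = FactorDef(
                name=str(item["name"]),
                label=str(item.get("label", "")),
                states=tuple(str(s) for s in item.get("states", ("low", "high"))),
                category=str(item.get("category", "intermediary")),
            )
        except ValidationError as exc:
            raise ParseError(p, None, f"factors[{i}]", str(exc)) from None
        factors.append(f)
        if "promoting_state" in item:
            state = str(item["promoting_state"])
            f.state_index(state)  # validate against declared states
            promoting[f.name] = state
    missing = [f.name for f in factors if f.name not in promoting]
    if missing:
        raise ParseError(
            p, None, "promoting_state",
            f"factors without a promoting_state: {missing!r}",
        )
    outcomes = tuple(
        str(o) for o in data.get(
            "outcomes", [f.name for f in factors if f.category == "outcome"]
        )
    )
    try:
        pmap = PromotingMap(promoting=promoting, outcomes=outcomes)
    except ValidationError as exc:
        raise ParseError(p, None, "outcomes", str(exc)) from None
    return factors, pmap


def write_factor_config(
    factors: Sequence[FactorDef], promoting_map: PromotingMap, path: str | Path
) -> None:
    data = {
        "factors": [
            {
                "name": f.name,
                "label": f.label,
                "states": list(f.states),
                "category": f.category,
                "promoting_state": promoting_map.promoting[f.name],
            }
            for f in factors
        ],
        "outcomes": list(promoting_map.outcomes),
    }
    body = yaml.safe_dump(data, sort_keys=False)
    Path(path).write_text(_with_header(body), encoding="utf-8")


def read_promoting_map(path: str | Path) -> PromotingMap:
    """Standalone promoting-map file: ``promoting:`` mapping plus
    ``outcomes:`` list."""
    p = Path(path)
    if not p.exists():
        raise ParseError(p, None, None, "file not found")
    data = yaml.safe_load(p.read_text(encoding="utf-8"))
    if not isinstance(data, dict) or "promoting" not in data:
        raise ParseError(p, None, "promoting", "file must contain a 'promoting' mapping")
    try:
        return PromotingMap(
            promoting={str(k): str(v) for k, v in data["promoting"].items()},
            outcomes=tuple(str(o) for o in data.get("outcomes", ())),
        )
    except ValidationError as exc:
        raise ParseError(p, None, None, str(exc)) from None


# ---------------------------------------------------------------------------
# encoding table (YAML/JSON)

def read_encoding_table(path: str | Path) -> EncodingTable:
    p = Path(path)
    if not p.exists():
        raise ParseError(p, None, None, "file not found")
    data = yaml.safe_load(p.read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ParseError(p, None, None, "encoding table must be a mapping")
    blocks = {}
    for shape, flat in data.items():
        if not isinstance(flat, (list, tuple)) or len(flat) != 4:
            raise ParseError(
                p, None, str(shape),
                "each shape needs exactly 4 integers (row-major 2x2 block)",
            )
        blocks[str(shape)] = ((int(flat[0]), int(flat[1])), (int(flat[2]), int(flat[3])))
    try:
        return EncodingTable(blocks)
    except ValidationError as exc:
        raise ParseError(p, None, None, str(exc)) from None


def write_encoding_table(table: EncodingTable, path: str | Path) -> None:
    data = {
        shape: [block[0][0], block[0][1], block[1][0], block[1][1]]
        for shape, block in table.items()
    }
    body = yaml.safe_dump(data, sort_keys=False)
    Path(path).write_text(_with_header(body), encoding="utf-8")


# ---------------------------------------------------------------------------
# scenarios CSV

def scenarios_csv_header(factors: Sequence[FactorDef]) -> tuple[str, ...]:
    return (
        "region", "number", *[f.name for f in factors],
        "category", "salubrious", "promoting_count",
    )


def write_scenarios_csv(
    records: Sequence[tuple[str, Scenario]],
    factors: Sequence[FactorDef],
    promoting_map: PromotingMap,
    path: str | Path,
    threshold: int = DEFAULT_SALUBRIOUS_THRESHOLD,
    extra: Mapping[str, str] | None = None,
) -> None:
    header = scenarios_csv_header(factors)
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(header)
    for i, (region, scen) in enumerate(records, start=1):
        cls = classify_scenario(scen, promoting_map, threshold)
        w.writerow(
            [region, i, *[scen[f.name] for f in factors],
             cls.category, "true" if cls.salubrious else "false",
             cls.promoting_count]
        )
    Path(path).write_text(_with_header(buf.getvalue(), extra), encoding="utf-8")


def read_scenarios_csv(
    path: str | Path, factors: Sequence[FactorDef]
) -> list[tuple[str, Scenario]]:
    header = scenarios_csv_header(factors)
    out = []
    for line_no, row in _parse_csv(path, header):
        try:
            scen = Scenario({f.name: row[f.name] for f in factors})
            for f in factors:
                f.state_index(scen[f.name])
        except ValidationError as exc:
            raise ParseError(path, line_no, None, str(exc)) from None
        out.append((row["region"], scen))
    return out


# ---------------------------------------------------------------------------
# intervention sweep CSV/JSON

def _sweep_columns(promoting_map: PromotingMap) -> list[str]:
    return [
        "fixed_factor", "fixed_state", "n_scenarios", "pct_promoting",
        "pct_healthy", "pct_mixed", "pct_unhealthy", "pct_salubrious",
        *[f"pct_{o}" for o in promoting_map.outcomes],
    ]


def sweep_to_frame(
    results: Sequence[InterventionResult], promoting_map: PromotingMap
) -> pd.DataFrame:
    """Tidy one-row-per-intervention table; percentages at one decimal.

    Metric cells are left missing (``NaN``) for interventions whose
    consistent-scenario set is empty, keeping those rows visible.
    """
    rows = []
    for r in results:
        row: dict[str, object] = {
            "fixed_factor": r.fixed_factor or "baseline",
            "fixed_state": r.fixed_state or "",
            "n_scenarios": r.n_scenarios,
        }
        if r.empty:
            rows.append(row)
            continue
        row["pct_promoting"] = round(r.pct_promoting, 1)
        for cat in CATEGORY_ORDER:
            row[f"pct_{cat}"] = round(r.category_pcts[cat], 1)
        row["pct_salubrious"] = round(r.category_pcts["salubrious"], 1)
        for o in promoting_map.outcomes:
            row[f"pct_{o}"] = round(r.outcome_pcts[o], 1)
        rows.append(row)
    return pd.DataFrame(rows, columns=_sweep_columns(promoting_map))


def write_sweep_csv(
    results: Sequence[InterventionResult],
    promoting_map: PromotingMap,
    path: str | Path,
    extra: Mapping[str, str] | None = None,
) -> None:
    frame = sweep_to_frame(results, promoting_map)
    body = frame.to_csv(index=False, lineterminator="\n", float_format="%.1f")
    Path(path).write_text(_with_header(body, extra), encoding="utf-8")


def write_sweep_json(
    results: Sequence[InterventionResult],
    promoting_map: PromotingMap,
    path: str | Path,
) -> None:
    frame = sweep_to_frame(results, promoting_map)
    records = []
    for rec in frame.to_dict(orient="records"):
        records.append(
            {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        )
    payload = {"tool": f"cibscen {__version__}", "sweep": records}
    Path(path).write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Fig-1-style scenario table

_CATEGORY_BLOCK_ORDER = ("outcome", "intermediary", "structural")


@dataclass(frozen=True)
class ScenarioTable:
    """Scenario table report: factors as rows (outcomes first, then
    intermediaries, then structural factors), scenarios as numbered
    columns grouped by category, cells ``L``/``H`` (first letter of the
    state label), salubrious columns starred.

    ``states`` holds the cell letters, ``flags`` the parallel
    promoting/restricting (``P``/``R``) layer; both share MultiIndex
    columns (category, number, region).  ``empty`` tables carry an
    explicit no-consistent-scenarios message in ``text``.
    """

    states: pd.DataFrame
    flags: pd.DataFrame
    text: str

    @property
    def empty(self) -> bool:
        return self.states.shape[1] == 0

    def to_csv(self, path: str | Path, extra: Mapping[str, str] | None = None) -> None:
        if self.empty:
            body = "no consistent scenarios\n"
        else:
            buf = _io.StringIO()
            w = csv.writer(buf, lineterminator="\n")
            cats = [c[0] for c in self.states.columns]
            nums = [c[1] for c in self.states.columns]
            regions = [c[2] for c in self.states.columns]
            w.writerow(["category", *cats])
            w.writerow(["scenario", *nums])
            w.writerow(["region", *regions])
            for factor, row in self.states.iterrows():
                flag_row = self.flags.loc[factor]
                w.writerow(
                    [factor, *[f"{s}/{f}" for s, f in zip(row, flag_row)]]
                )
            body = buf.getvalue()
        Path(path).write_text(_with_header(body, extra), encoding="utf-8")


def render_scenario_table(
    records: PooledScenarios | Sequence[tuple[str, Scenario]],
    factors: Sequence[FactorDef],
    promoting_map: PromotingMap,
    threshold: int = DEFAULT_SALUBRIOUS_THRESHOLD,
) -> ScenarioTable:
    """Build the scenario-table report from tagged scenarios.

    Columns are numbered in pool order but grouped healthy, mixed,
    unhealthy (stable within groups); a ``*`` on the number marks
    salubrious-system scenarios.
    """
    if isinstance(records, PooledScenarios):
        records = list(records.records)
    else:
        records = list(records)
    row_order = [
        f for cat in _CATEGORY_BLOCK_ORDER for f in factors if f.category == cat
    ]
    if not records:
        empty = pd.DataFrame(
            index=[f.name for f in row_order],
            columns=pd.MultiIndex.from_tuples([], names=["category", "n", "region"]),
        )
        return ScenarioTable(
            states=empty, flags=empty.copy(), text="no consistent scenarios\n"
        )

    classified: list[tuple[int, str, Scenario, ScenarioClassification]] = []
    for i, (region, scen) in enumerate(records, start=1):
        cls = classify_scenario(scen, promoting_map, threshold)
        classified.append((i, region, scen, cls))
    classified.sort(key=lambda item: (_CATEGORY_RANK[item[3].category], item[0]))

    columns = []
    state_cols = []
    flag_cols = []
    for number, region, scen, cls in classified:
        star = "*" if cls.salubrious else ""
        columns.append((cls.category, f"{number}{star}", region))
        state_cols.append(
            [scen[f.name][:1].upper() for f in row_order]
        )
        flag_cols.append(
            [
                "P" if promoting_map.is_promoting(f.name, scen[f.name]) else "R"
                for f in row_order
            ]
        )
    col_index = pd.MultiIndex.from_tuples(columns, names=["category", "n", "region"])
    index = [f.name for f in row_order]
    states = pd.DataFrame(
        list(map(list, zip(*state_cols))), index=index, columns=col_index
    )
    flags = pd.DataFrame(
        list(map(list, zip(*flag_cols))), index=index, columns=col_index
    )
    text = states.to_string() + "\n\n(* = salubrious system scenario)\n"
    return ScenarioTable(states=states, flags=flags, text=text)
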