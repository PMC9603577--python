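"""Readers and writers for prediction-tool score tables and reference
variant sets.

The canonical interchange format for scores is a UTF-8, tab-delimited table
with header columns ``position  wt  mut  tool  score`` — one row per
(tool, substitution) pair.  Native server report dialects (PolyPhen-2,
PROVEAN, SIFT) are parsed into the same in-memory table; any class labels
the servers printed are discarded, because classification is recomputed
locally from configurable thresholds (see :mod:`satpred.thresholds`).

Reference variant sets are CSV with columns ``notation,label`` and an
optional ``source_note``; the labels "likely benign" and "likely pathogenic"
normalize onto the two binary classes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError
from .variant_model import Substitution, parse_substitution

#: The four prediction tools, in the fixed panel/report order.
TOOLS: tuple[str, ...] = ("humdiv", "humvar", "provean", "sift")

#: The designated three-tool consensus panel (the two PolyPhen-2 modes and
#: PROVEAN) used for P3/P2/B2/B3 tiering.
PANEL: tuple[str, ...] = ("humdiv", "humvar", "provean")

#: Human-readable tool names for reports.
TOOL_LABELS: dict[str, str] = {
    "humdiv": "PolyPhen-2 HumDiv",
    "humvar": "PolyPhen-2 HumVar",
    "provean": "PROVEAN",
    "sift": "SIFT",
}

SCORE_COLUMNS = ["position", "wt", "mut", "tool", "score"]


@dataclass(frozen=True)
class ToolScore:
    """One tool's raw score for one substitution."""

    tool: str
    substitution: Substitution
    score: float

    def __post_init__(self) -> None:
        validate_score(self.tool, self.score)


@dataclass(frozen=True)
class ReferenceVariant:
    """A labeled variant from a curated reference set."""

    substitution: Substitution
    label: str  # "pathogenic" | "benign"
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("pathogenic", "benign"):
            raise ValidationError(f"unknown reference label {self.label!r}")


def validate_score(tool: str, score: float) -> None:
    """Range-check a raw score for its tool.

    PolyPhen-2 (both modes) and SIFT score in [0, 1]; the PROVEAN delta
    score is an unbounded real (finite).
    """
    if tool not in TOOLS:
        raise ConfigurationError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    if not math.isfinite(score):
        raise ValidationError(f"non-finite {tool} score: {score!r}")
    if tool in ("humdiv", "humvar", "sift") and not 0.0 <= score <= 1.0:
        raise ValidationError(f"{tool} score {score} outside [0, 1]")


def normalize_label(raw: str) -> str:
    """Map reference-set label spellings onto the binary classes."""
    token = raw.strip().lower().replace("_", " ")
    if token in ("pathogenic", "likely pathogenic"):
        return "pathogenic"
    if token in ("benign", "likely benign"):
        return "benign"
    raise ParseError(f"unknown reference label {raw!r}")


# ---------------------------------------------------------------------------
# canonical score table


def scores_to_frame(scores: Iterable[ToolScore]) -> pd.DataFrame:
    rows = [
        (s.substitution.position, s.substitution.wt, s.substitution.mut, s.tool, s.score)
        for s in scores
    ]
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def frame_to_scores(frame: pd.DataFrame) -> list[ToolScore]:
    return [
        ToolScore(
            tool=row.tool,
            substitution=Substitution(int(row.position), row.wt, row.mut),
            score=float(row.score),
        )
        for row in frame.itertuples()
    ]


def _validate_score_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"score table is missing columns {missing}")
    frame = frame[SCORE_COLUMNS].copy()
    frame["position"] = frame["position"].astype(int)
    frame["score"] = frame["score"].astype(float)
    for row in frame.itertuples():
        Substitution(row.position, row.wt, row.mut)  # validates residues
        validate_score(row.tool, row.score)
    dup = frame.duplicated(subset=["position", "wt", "mut", "tool"])
    if dup.any():
        first = frame[dup].iloc[0]
        raise ValidationError(
            "duplicate (tool, substitution) rows, e.g. "
            f"{first.tool} {first.wt}{first.position}{first.mut}"
        )
    return frame


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read the canonical tab-delimited score table, with validation."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"wt": str, "mut": str})
    except ValueError as exc:
        raise ParseError(f"cannot parse score table {path}: {exc}") from exc
    if frame.empty and not set(SCORE_COLUMNS) <= set(frame.columns):
        raise ParseError(f"score table {path} is missing the canonical header")
    return _validate_score_frame(frame)


def write_score_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write the canonical score table (validated first).

    Scores are serialized with 6 significant decimals, which is more
    precision than any of the upstream servers report, so write/read
    round-trips are exact.
    """
    frame = _validate_score_frame(frame)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for row in frame.itertuples():
            fh.write(
                f"{row.position}\t{row.wt}\t{row.mut}\t{row.tool}\t{row.score:.6f}\n"
            )
    return path


# ---------------------------------------------------------------------------
# native server report dialects


def _parse_float(token: str, lineno: int, path: str | Path) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: unparseable number {token!r}") from exc


def _read_polyphen2(path: str | Path, tool: str) -> list[ToolScore]:
    """PolyPhen-2 batch output: tab-separated, '#'-prefixed header naming the
    columns, of which ``o_pos``, ``o_aa1``, ``o_aa2`` and ``pph2_prob`` are
    used.  The server's own ``prediction`` column is ignored.  Extra columns
    are tolerated.
    """
    scores: list[ToolScore] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = [c.strip() for c in line.lstrip("#").split("\t")]
                continue
            if header is None:
                raise ParseError(f"{path}:{lineno}: data before '#' header line")
            fields = [c.strip() for c in line.split("\t")]
            row = dict(zip(header, fields))
            try:
                pos = int(row["o_pos"])
                wt, mut = row["o_aa1"], row["o_aa2"]
                prob = _parse_float(row["pph2_prob"], lineno, path)
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: missing PolyPhen-2 column {exc}"
                ) from exc
            scores.append(ToolScore(tool, Substitution(pos, wt, mut), prob))
    return scores


def _read_provean(path: str | Path) -> list[ToolScore]:
    """PROVEAN protein-batch output: comma- or tab-separated VARIATION and
    SCORE columns; '#' comment lines skipped.
    """
    scores: list[ToolScore] = []
    with open(path, encoding="utf-8") as fh:
        reader: list[tuple[int, str]] = [
            (i, ln.rstrip("\n")) for i, ln in enumerate(fh, start=1)
        ]
    header: list[str] | None = None
    for lineno, line in reader:
        if not line.strip() or line.startswith("#"):
            continue
        sep = "," if "," in line else "\t"
        fields = [c.strip() for c in line.split(sep)]
        if header is None and any(f.upper() == "VARIATION" for f in fields):
            header = [f.upper() for f in fields]
            continue
        if header is not None:
            row = dict(zip(header, fields))
            var, sc = row.get("VARIATION"), row.get("SCORE")
            if var is None or sc is None:
                raise ParseError(f"{path}:{lineno}: missing VARIATION/SCORE field")
        else:
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'VARIATION, SCORE'")
            var, sc = fields[0], fields[1]
        scores.append(
            ToolScore("provean", parse_substitution(var), _parse_float(sc, lineno, path))
        )
    return scores


def _read_sift(path: str | Path) -> list[ToolScore]:
    """SIFT batch output: tab-separated with a substitution column and a
    score column (named like 'SIFT Score' or 'score'); '#' lines skipped.
    """
    scores: list[ToolScore] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [c.strip() for c in line.split("\t")]
            lowered = [f.lower() for f in fields]
            if header is None and any("score" in f for f in lowered):
                header = lowered
                continue
            if header is not None:
                row = dict(zip(header, fields))
                sub_tok = next(
                    (v for k, v in row.items() if "substitution" in k or "variant" in k),
                    fields[0],
                )
                score_tok = next(
                    (v for k, v in row.items() if "score" in k), None
                )
                if score_tok is None:
                    raise ParseError(f"{path}:{lineno}: no score field")
            else:
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected substitution and score")
                sub_tok, score_tok = fields[0], fields[1]
            scores.append(
                ToolScore(
                    "sift", parse_substitution(sub_tok), _parse_float(score_tok, lineno, path)
                )
            )
    return scores


def read_native_report(path: str | Path, tool: str) -> list[ToolScore]:
    """Parse a native server report into scores for ``tool``.

    ``humdiv``/``humvar`` name the PolyPhen-2 dialect (which mode the file
    holds is the caller's knowledge; the format is identical).
    """
    if tool in ("humdiv", "humvar"):
        return _read_polyphen2(path, tool)
    if tool == "provean":
        return _read_provean(path)
    if tool == "sift":
        return _read_sift(path)
    raise ConfigurationError(f"unknown report dialect {tool!r}")


# ---------------------------------------------------------------------------
# reference variant sets


def read_reference_set(path: str | Path) -> list[ReferenceVariant]:
    """Read a reference CSV with columns ``notation,label[,source_note]``."""
    variants: list[ReferenceVariant] = []
    seen: set[Substitution] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"notation", "label"} <= set(
            reader.fieldnames
        ):
            raise ParseError(f"{path}: expected CSV columns notation,label")
        for row in reader:
            sub = parse_substitution(row["notation"])
            if sub in seen:
                raise ValidationError(f"duplicate reference variant {sub.notation}")
            seen.add(sub)
            variants.append(
                ReferenceVariant(
                    substitution=sub,
                    label=normalize_label(row["label"]),
                    source_note=(row.get("source_note") or "").strip(),
                )
            )
    return variants


def write_reference_set(variants: Sequence[ReferenceVariant], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["notation", "label", "source_note"])
        for v in variants:
            writer.writerow([v.substitution.notation, v.label, v.source_note])
    return path


def reference_to_frame(variants: Sequence[ReferenceVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "notation": [v.substitution.notation for v in variants],
            "label": [v.label for v in variants],
            "source_note": [v.source_note for v in variants],
        }
    )
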