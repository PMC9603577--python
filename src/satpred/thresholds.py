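"""Per-tool categorical classification of raw scores and binarization.

Published operating points (the defaults):

* PolyPhen-2 HumDiv: score > 0.957 -> "probably damaging";
  score < 0.450 -> "benign"; the closed interval between is
  "possibly damaging".
* PolyPhen-2 HumVar: same scheme with boundaries 0.909 and 0.447.
* PROVEAN: delta score <= -2.5 -> "deleterious", else "neutral".  The
  boundary value -2.5 itself is deleterious, following the tool's own
  convention; exact-boundary scores are reported to the logger.
* SIFT: score < 0.05 -> "deleterious"; 0.05 or above -> "tolerated".

Binarization maps probably/possibly damaging and deleterious to
"pathogenic"; benign, neutral and tolerated to "benign".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from ._util import round_half_up
from .errors import ConfigurationError, ValidationError
from .tool_io import TOOLS, validate_score

logger = logging.getLogger(__name__)

#: Legal categories per tool.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "humdiv": ("benign", "possibly_damaging", "probably_damaging"),
    "humvar": ("benign", "possibly_damaging", "probably_damaging"),
    "provean": ("neutral", "deleterious"),
    "sift": ("tolerated", "deleterious"),
}

_PATHOGENIC_CATEGORIES = frozenset(
    {"probably_damaging", "possibly_damaging", "deleterious"}
)
_BENIGN_CATEGORIES = frozenset({"benign", "neutral", "tolerated"})


@dataclass(frozen=True)
class ThresholdConfig:
    """All classification boundaries in one overridable object."""

    humdiv_probably: float = 0.957
    humdiv_benign: float = 0.450
    humvar_probably: float = 0.909
    humvar_benign: float = 0.447
    provean_cutoff: float = -2.5
    sift_cutoff: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
        return replace(cls(), **{k: float(v) for k, v in raw.items()})


DEFAULT_THRESHOLDS = ThresholdConfig()


def classify_polyphen2(
    score: float, mode: str, config: ThresholdConfig = DEFAULT_THRESHOLDS
) -> str:
    """Three-way PolyPhen-2 category for ``mode`` in {'humdiv', 'humvar'}."""
    if mode not in ("humdiv", "humvar"):
        raise ConfigurationError(f"unknown PolyPhen-2 mode {mode!r}")
    validate_score(mode, score)
    if mode == "humdiv":
        hi, lo = config.humdiv_probably, config.humdiv_benign
    else:
        hi, lo = config.humvar_probably, config.humvar_benign
    if score > hi:
        return "probably_damaging"
    if score < lo:
        return "benign"
    return "possibly_damaging"


def classify_provean(
    score: float, config: ThresholdConfig = DEFAULT_THRESHOLDS
) -> str:
    """PROVEAN two-way category; the cutoff itself counts as deleterious."""
    if not math.isfinite(score):
        raise ValidationError(f"non-finite PROVEAN score {score!r}")
    if score == config.provean_cutoff:
        logger.info("PROVEAN score exactly at cutoff %s -> deleterious", score)
    return "deleterious" if score <= config.provean_cutoff else "neutral"


def classify_sift(score: float, config: ThresholdConfig = DEFAULT_THRESHOLDS) -> str:
    """SIFT two-way category; the cutoff itself counts as tolerated."""
    validate_score("sift", score)
    return "tolerated" if score >= config.sift_cutoff else "deleterious"


def classify(tool: str, score: float, config: ThresholdConfig = DEFAULT_THRESHOLDS) -> str:
    """Dispatch to the tool-specific classifier."""
    if tool in ("humdiv", "humvar"):
        return classify_polyphen2(score, tool, config)
    if tool == "provean":
        return classify_provean(score, config)
    if tool == "sift":
        return classify_sift(score, config)
    raise ConfigurationError(f"unknown tool {tool!r}")


def binarize(category: str) -> str:
    """Collapse a tool category to the binary pathogenic/benign call."""
    if category in _PATHOGENIC_CATEGORIES:
        return "pathogenic"
    if category in _BENIGN_CATEGORIES:
        return "benign"
    raise ConfigurationError(f"unknown category {category!r}")


def call(tool: str, score: float, config: ThresholdConfig = DEFAULT_THRESHOLDS) -> str:
    """Binary call straight from a raw score."""
    return binarize(classify(tool, score, config))


def classify_table(
    scores: pd.DataFrame, config: ThresholdConfig = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Append ``category`` and ``call`` columns to a canonical score table."""
    out = scores.copy()
    out["category"] = [
        classify(row.tool, float(row.score), config) for row in scores.itertuples()
    ]
    out["call"] = out["category"].map(binarize)
    return out


def tabulate_categories(
    scores: pd.DataFrame, config: ThresholdConfig = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Per-tool benign/pathogenic frequencies and percentages.

    One row per tool present in the table, with integer counts and
    percentages rounded half-up to one decimal; counts always sum to the
    tool's row total.
    """
    classified = classify_table(scores, config)
    rows = []
    for tool in TOOLS:
        part = classified[classified["tool"] == tool]
        if part.empty:
            continue
        n = len(part)
        n_path = int((part["call"] == "pathogenic").sum())
        n_ben = n - n_path
        rows.append(
            {
                "tool": tool,
                "benign_n": n_ben,
                "pathogenic_n": n_path,
                "total": n,
                "benign_pct": round_half_up(100.0 * n_ben / n, 1),
                "pathogenic_pct": round_half_up(100.0 * n_path / n, 1),
            }
        )
    if not rows:
        raise ValidationError("score table holds no known tools")
    return pd.DataFrame(rows)
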