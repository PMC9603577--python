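"""Multi-tool consensus calls and P3/P2/B2/B3 tiering.

The combination rules for 2-4 tools favour pathogenicity on a split vote:

* 2 tools: benign only when unanimously benign; one damaging output makes
  the consensus pathogenic.
* 3 tools: simple majority (two or more votes win).
* 4 tools: pathogenic when two or more outputs are damaging; benign when
  three or more are benign (the 2-2 tie resolves pathogenic).

Tiers count pathogenic votes from the designated three-tool panel
(PolyPhen-2 HumDiv, PolyPhen-2 HumVar, PROVEAN): 3 votes -> P3, 2 -> P2,
1 -> B2, 0 -> B3.  P-tiers binarize to pathogenic, B-tiers to benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .errors import ValidationError
from .thresholds import ThresholdConfig, DEFAULT_THRESHOLDS, call
from .tool_io import PANEL

TIER_NAMES: tuple[str, ...] = ("P3", "P2", "B2", "B3")

_VOTES_TO_TIER = {3: "P3", 2: "P2", 1: "B2", 0: "B3"}


def _check_calls(calls: Sequence[str]) -> None:
    bad = [c for c in calls if c not in ("pathogenic", "benign")]
    if bad:
        raise ValidationError(f"unknown binary calls: {bad}")


def combine(calls: Sequence[str]) -> str:
    """Consensus binary call from 2, 3, or 4 per-tool calls."""
    _check_calls(calls)
    k = len(calls)
    if k not in (2, 3, 4):
        raise ValidationError(f"combine() takes 2-4 calls, got {k}")
    n_path = sum(c == "pathogenic" for c in calls)
    if k == 2:
        return "pathogenic" if n_path >= 1 else "benign"
    if k == 3:
        return "pathogenic" if n_path >= 2 else "benign"
    return "pathogenic" if n_path >= 2 else "benign"


@dataclass(frozen=True)
class ConsensusTier:
    """Vote counts and tier for one substitution under the 3-tool panel."""

    pathogenic_votes: int
    benign_votes: int
    tier: str

    def __post_init__(self) -> None:
        if self.pathogenic_votes + self.benign_votes != 3:
            raise ValidationError("panel votes must sum to 3")
        if _VOTES_TO_TIER[self.pathogenic_votes] != self.tier:
            raise ValidationError(
                f"tier {self.tier} inconsistent with {self.pathogenic_votes} pathogenic votes"
            )

    @property
    def call(self) -> str:
        """Binary call implied by the tier (P* pathogenic, B* benign)."""
        return "pathogenic" if self.tier.startswith("P") else "benign"


def tier(panel_calls: Sequence[str]) -> ConsensusTier:
    """Tier from exactly three panel calls (fixed panel order)."""
    _check_calls(panel_calls)
    if len(panel_calls) != 3:
        raise ValidationError(f"tier() takes exactly 3 panel calls, got {len(panel_calls)}")
    n_path = sum(c == "pathogenic" for c in panel_calls)
    return ConsensusTier(
        pathogenic_votes=n_path, benign_votes=3 - n_path, tier=_VOTES_TO_TIER[n_path]
    )


def tier_map(
    scores: pd.DataFrame,
    config: ThresholdConfig = DEFAULT_THRESHOLDS,
    panel: Sequence[str] = PANEL,
) -> pd.DataFrame:
    """Per-substitution tiers over a saturation score table.

    ``scores`` is a canonical table that must contain a score from every
    panel tool for every substitution present.  Returns a table with columns
    ``position, wt, mut, votes, tier`` sorted by position then the order the
    substitutions appear.
    """
    panel = tuple(panel)
    if len(panel) != 3:
        raise ValidationError(f"tier panel must name exactly 3 tools, got {panel}")
    part = scores[scores["tool"].isin(panel)]
    wide = part.pivot_table(
        index=["position", "wt", "mut"], columns="tool", values="score", aggfunc="first"
    )
    missing_tools = [t for t in panel if t not in wide.columns]
    gaps = []
    if not missing_tools:
        gap_mask = wide[list(panel)].isna().any(axis=1)
        gaps = [f"{wt}{pos}{mut}" for pos, wt, mut in wide.index[gap_mask]]
    if missing_tools or gaps:
        detail = f"tools absent: {missing_tools}" if missing_tools else f"substitutions: {gaps[:10]}"
        raise ValidationError(f"incomplete panel scores ({detail})")

    rows = []
    for (pos, wt, mut), score_row in wide.iterrows():
        calls = [call(t, float(score_row[t]), config) for t in panel]
        t = tier(calls)
        rows.append(
            {"position": int(pos), "wt": wt, "mut": mut, "votes": t.pathogenic_votes, "tier": t.tier}
        )
    out = pd.DataFrame(rows).sort_values(["position", "mut"], kind="stable")
    return out.reset_index(drop=True)


def tier_summary(tiers: pd.DataFrame) -> dict[str, float]:
    """Class percentages of a tier table, rounded half-up to one decimal.

    Includes the pathogenic (P3+P2) and benign (B2+B3) aggregates; the four
    tier percentages sum to 100 up to rounding.
    """
    n = len(tiers)
    if n == 0:
        raise ValidationError("empty tier table")
    counts: Mapping[str, int] = tiers["tier"].value_counts().to_dict()
    pct = {name: round_half_up(100.0 * counts.get(name, 0) / n, 1) for name in TIER_NAMES}
    pct["pathogenic"] = round_half_up(
        100.0 * (counts.get("P3", 0) + counts.get("P2", 0)) / n, 1
    )
    pct["benign"] = round_half_up(
        100.0 * (counts.get("B2", 0) + counts.get("B3", 0)) / n, 1
    )
    return pct
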