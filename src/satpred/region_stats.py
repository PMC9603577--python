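"""Tier counts by region and the critical-vs-non-critical test of
proportion.

The hypothesis test is the classical two-sample test of proportion:
a pooled-variance z statistic

    z = (p1 - p2) / sqrt(p̂ (1 - p̂) (1/n1 + 1/n2)),   p̂ = (x1 + x2)/(n1 + n2)

with a two-sided p-value from the standard normal and no continuity
correction (so z² equals the 2x2 chi-square statistic).  The 95% CI for
p1 - p2 uses the unpooled (Wald) standard error, the usual pairing for this
test.  Significance is judged at α = 0.05 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from ._util import round_half_up
from .consensus import TIER_NAMES
from .conservation import Region, default_regions
from .errors import ValidationError


@dataclass(frozen=True)
class RegionTierCounts:
    """P3/P2/B2/B3 counts among substitutions falling in one region."""

    region: str
    critical: bool
    p3: int
    p2: int
    b2: int
    b3: int

    @property
    def total(self) -> int:
        return self.p3 + self.p2 + self.b2 + self.b3

    @property
    def pathogenic(self) -> int:
        return self.p3 + self.p2

    @property
    def benign(self) -> int:
        return self.b2 + self.b3


@dataclass(frozen=True)
class ProportionTestResult:
    """Result of the two-sample test of proportion.

    ``z`` is ``None`` (undefined) when the pooled proportion is degenerate
    (0 or 1), in which case both sample proportions are necessarily equal
    and the p-value is reported as 1.
    """

    p1: float
    p2: float
    z: float | None
    p_value: float
    ci95: tuple[float, float]
    significant: bool


def count_tiers_by_region(
    tiers: pd.DataFrame, regions: Sequence[Region] | None = None
) -> list[RegionTierCounts]:
    """Tier counts per region, plus an "other" bucket for substitutions
    outside every region.  Regions may overlap in principle; each is counted
    independently, while "other" counts positions in none of them.
    """
    if regions is None:
        regions = default_regions()
    out = []
    covered = pd.Series(False, index=tiers.index)
    for region in regions:
        mask = tiers["position"].between(region.start, region.end)
        covered |= mask
        vc = tiers.loc[mask, "tier"].value_counts()
        out.append(
            RegionTierCounts(
                region=region.name,
                critical=region.critical,
                p3=int(vc.get("P3", 0)),
                p2=int(vc.get("P2", 0)),
                b2=int(vc.get("B2", 0)),
                b3=int(vc.get("B3", 0)),
            )
        )
    vc = tiers.loc[~covered, "tier"].value_counts()
    out.append(
        RegionTierCounts(
            region="other",
            critical=False,
            p3=int(vc.get("P3", 0)),
            p2=int(vc.get("P2", 0)),
            b2=int(vc.get("B2", 0)),
            b3=int(vc.get("B3", 0)),
        )
    )
    return out


def region_counts_frame(counts: Sequence[RegionTierCounts]) -> pd.DataFrame:
    """Tabular report with per-tier percentages (one decimal, half-up)."""
    rows = []
    for c in counts:
        row: dict[str, object] = {
            "region": c.region,
            "critical": c.critical,
            "P3": c.p3,
            "P2": c.p2,
            "B2": c.b2,
            "B3": c.b3,
            "total": c.total,
        }
        for name, n in zip(TIER_NAMES, (c.p3, c.p2, c.b2, c.b3)):
            row[f"{name}_pct"] = (
                round_half_up(100.0 * n / c.total, 1) if c.total else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> ProportionTestResult:
    """Pooled two-sample z test of proportion without continuity correction,
    with an unpooled 95% (1-α) CI for the difference p1 - p2."""
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both groups must be non-empty")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se_unpooled = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    ci = (p1 - p2 - zcrit * se_unpooled, p1 - p2 + zcrit * se_unpooled)
    if pooled in (0.0, 1.0):
        # both sample proportions equal; the z statistic is undefined
        return ProportionTestResult(p1, p2, None, 1.0, ci, False)
    se_pooled = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se_pooled
    p_value = 2.0 * float(stats.norm.sf(abs(z)))
    return ProportionTestResult(p1, p2, z, p_value, ci, p_value < alpha)


def critical_vs_noncritical(
    counts: Sequence[RegionTierCounts], alpha: float = 0.05
) -> dict[str, ProportionTestResult]:
    """Compare pooled critical regions against pooled non-critical regions.

    Two planned comparisons: the pathogenic-tier proportion (P3+P2) and the
    benign-tier proportion (B2+B3).  Because the two proportions are
    complementary, the tests mirror each other (equal |z|, opposite sign);
    both are reported for transparency.  The "other" bucket is excluded.
    """
    crit = [c for c in counts if c.critical]
    noncrit = [c for c in counts if not c.critical and c.region != "other"]
    if not crit or not noncrit:
        raise ValidationError("need at least one critical and one non-critical region")
    n1 = sum(c.total for c in crit)
    n2 = sum(c.total for c in noncrit)
    path1 = sum(c.pathogenic for c in crit)
    path2 = sum(c.pathogenic for c in noncrit)
    return {
        "pathogenic": two_proportion_test(path1, n1, path2, n2, alpha),
        "benign": two_proportion_test(n1 - path1, n1, n2 - path2, n2, alpha),
    }
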