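"""Cross-species conservation summaries over a pre-aligned protein FASTA.

The module consumes an existing multiple alignment (it never aligns);
positions are expressed in the ungapped coordinates of the designated
reference (human) sequence.  "Identity" means exact residue match against
the reference: alignment columns where the reference carries a gap are not
reference positions, and a gap in the other species at a reference
position counts as a mismatch.

The default regions are the functional sites of the CDKL5 catalytic
domain — the ATP-binding site (aa 19-43), the S/T kinase active site
(aa 131-143) and the TEY activation motif (aa 169-171) as critical
regions, with two flanking windows (aa 144-168 and aa 257-297) as
designated non-critical comparison regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._util import round_half_up
from .errors import ParseError, ValidationError

GAP = "-"


@dataclass(frozen=True)
class Region:
    """A contiguous stretch of reference (ungapped) positions, 1-based
    inclusive."""

    name: str
    start: int
    end: int
    critical: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"bad region bounds {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def default_regions() -> list[Region]:
    """The five CDKL5 catalytic-domain regions (three critical, two not)."""
    return [
        Region("ATP-binding site", 19, 43, critical=True),
        Region("S/T kinase active site", 131, 143, critical=True),
        Region("TEY motif", 169, 171, critical=True),
        Region("non-critical 144-168", 144, 168, critical=False),
        Region("non-critical 257-297", 257, 297, critical=False),
    ]


@dataclass
class AlignedSet:
    """A pre-aligned set of species sequences with a designated reference."""

    reference_id: str
    rows: dict[str, str]
    _ref_columns: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("alignment needs at least 2 sequences")
        if self.reference_id not in self.rows:
            raise ValidationError(f"reference {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValidationError(f"aligned rows differ in length: {sorted(lengths)}")
        ref = self.rows[self.reference_id]
        # column index of each ungapped reference position (1-based pos -> col)
        self._ref_columns = [i for i, ch in enumerate(ref) if ch != GAP]

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str) -> "AlignedSet":
        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not rows:
            raise ParseError(f"no FASTA records in {path}")
        return cls(reference_id=reference_id, rows=rows)

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    @property
    def others(self) -> list[str]:
        return [s for s in self.rows if s != self.reference_id]

    @property
    def reference_length(self) -> int:
        """Ungapped length of the reference sequence."""
        return len(self._ref_columns)

    def columns_for(self, region: Region) -> list[int]:
        if region.end > self.reference_length:
            raise ValidationError(
                f"region {region.name!r} ({region.start}..{region.end}) exceeds "
                f"reference length {self.reference_length}"
            )
        return self._ref_columns[region.start - 1 : region.end]


def pairwise_identity(aln: AlignedSet, other: str, region: Region) -> float:
    """Percent of region positions where ``other`` matches the reference.

    Unrounded; reports round to one decimal.
    """
    if other not in aln.rows:
        raise ValidationError(f"unknown species {other!r}")
    cols = aln.columns_for(region)
    ref = aln.rows[aln.reference_id]
    oth = aln.rows[other]
    matches = sum(1 for c in cols if oth[c] == ref[c] and oth[c] != GAP)
    return 100.0 * matches / len(cols)


def region_conservation(aln: AlignedSet, region: Region) -> float:
    """Mean pairwise identity to the reference over all other species."""
    idents = [pairwise_identity(aln, sp, region) for sp in aln.others]
    return sum(idents) / len(idents)


def conservation_report(
    aln: AlignedSet, regions: list[Region] | None = None
) -> pd.DataFrame:
    """Per-species identity for each region, plus the cross-species mean.

    Percentages are rounded half-up to one decimal for reporting.
    """
    if regions is None:
        regions = default_regions()
    rows = []
    for region in regions:
        for sp in aln.others:
            rows.append(
                {
                    "region": region.name,
                    "critical": region.critical,
                    "start": region.start,
                    "end": region.end,
                    "species": sp,
                    "identity_pct": round_half_up(pairwise_identity(aln, sp, region), 1),
                }
            )
        rows.append(
            {
                "region": region.name,
                "critical": region.critical,
                "start": region.start,
                "end": region.end,
                "species": "mean",
                "identity_pct": round_half_up(region_conservation(aln, region), 1),
            }
        )
    return pd.DataFrame(rows)
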