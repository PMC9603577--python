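"""Protein sequences, single amino-acid substitutions, and saturation
enumeration.

Coordinates are 1-based and inclusive throughout: residue 1 is the first
character of the sequence (the initiator methionine for an N-terminal
domain).

The fixed amino-acid enumeration order groups residues by physicochemical
class — non-polar, polar uncharged, acidic, basic — with a fixed internal
order within each group.  This makes saturation sets, heatmap rows, and
round-trip comparisons deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, ParseError, ValidationError

#: Physicochemical groups of the 20 standard residues, in display order.
AA_GROUPS: dict[str, str] = {
    "nonpolar": "GAVLIMPFW",
    "polar_uncharged": "STCYNQ",
    "acidic": "DE",
    "basic": "KRH",
}

#: The documented fixed enumeration order (concatenation of the groups).
AA_ORDER: str = "".join(AA_GROUPS.values())

STANDARD_AA: frozenset[str] = frozenset(AA_ORDER)

assert len(AA_ORDER) == 20

_NOTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class Substitution:
    """One single amino-acid replacement, e.g. H145Y.

    ``wt == mut`` (a wild-type "self" record such as M1M) is representable —
    heatmap cells need it — but is never produced by enumeration.
    """

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for label, aa in (("wild-type", self.wt), ("mutant", self.mut)):
            if aa not in STANDARD_AA:
                raise ValidationError(
                    f"{label} residue {aa!r} is not a standard amino-acid code"
                )

    @property
    def is_wildtype(self) -> bool:
        return self.wt == self.mut

    @property
    def notation(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation


def parse_substitution(text: str) -> Substitution:
    """Parse one-letter protein-variant notation ``<WT><POS><MUT>``.

    >>> parse_substitution("H145Y")
    Substitution(position=145, wt='H', mut='Y')
    """
    m = _NOTATION_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed substitution notation: {text!r}")
    wt, pos_s, mut = m.group(1).upper(), m.group(2), m.group(3).upper()
    position = int(pos_s)
    if position < 1:
        raise ParseError(f"position must be >= 1 in {text!r}")
    for aa in (wt, mut):
        if aa not in STANDARD_AA:
            raise ParseError(
                f"non-standard amino-acid code {aa!r} in {text!r}"
            )
    return Substitution(position=position, wt=wt, mut=mut)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 standard one-letter codes.

    Residue numbering starts at 1.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("protein sequence must be non-empty")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValidationError(
                f"non-standard residues in {self.identifier!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValidationError(
                f"position {position} outside sequence of length {len(self.residues)}"
            )
        return self.residues[position - 1]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinSequence":
        """Read the first record of a protein FASTA file."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ParseError(f"no FASTA records in {path}")
        rec = records[0]
        return cls(identifier=rec.id, residues=str(rec.seq).upper())


def enumerate_saturation(
    seq: ProteinSequence, start: int = 1, end: int | None = None
) -> list[Substitution]:
    """All 19 non-wild-type replacements at every position of ``start..end``
    (1-based, inclusive), in the fixed amino-acid order.

    A region of L residues yields exactly 19 x L substitutions; a 300-residue
    catalytic domain yields 5700.
    """
    if end is None:
        end = len(seq)
    if not (1 <= start <= end <= len(seq)):
        raise ValidationError(
            f"range {start}..{end} outside sequence of length {len(seq)}"
        )
    out: list[Substitution] = []
    for pos in range(start, end + 1):
        wt = seq.residue(pos)
        out.extend(
            Substitution(position=pos, wt=wt, mut=mut)
            for mut in AA_ORDER
            if mut != wt
        )
    return out


_BATCH_DIALECTS = ("polyphen2", "provean", "sift")


def write_batch_input(
    subs: Sequence[Substitution] | Iterable[Substitution],
    accession: str,
    dialect: str,
    path: str | Path,
) -> Path:
    """Write a batch-query input file for one of the external prediction
    servers.

    Dialects:

    * ``polyphen2`` — one line per substitution: ``<accession> <pos> <wt> <mut>``
    * ``provean``   — one line per substitution: ``<WT><POS><MUT>``
    * ``sift``      — a single comma-separated list of substitutions

    Output is newline-terminated.  This writes query files only; running the
    servers and parsing their reports are separate steps.
    """
    subs = list(subs)
    if not subs:
        raise ValidationError("cannot write a batch input for an empty substitution set")
    if dialect not in _BATCH_DIALECTS:
        raise ConfigurationError(
            f"unknown batch dialect {dialect!r}; expected one of {_BATCH_DIALECTS}"
        )
    path = Path(path)
    if dialect == "polyphen2":
        body = "\n".join(f"{accession} {s.position} {s.wt} {s.mut}" for s in subs)
    elif dialect == "provean":
        body = "\n".join(s.notation for s in subs)
    else:  # sift
        body = ",".join(s.notation for s in subs)
    path.write_text(body + "\n", encoding="utf-8")
    return path
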