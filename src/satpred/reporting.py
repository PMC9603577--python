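"""Heatmap-matrix export of consensus tiers over a saturation set.

The matrix has one row per amino acid in the fixed group order (non-polar,
polar uncharged, acidic, basic) and one column per sequence position.  The
cell at (residue R, position p) holds the tier of the substitution
wt(p) -> R; the single wild-type cell per column is marked "." — the same
convention the field's saturation heatmaps use for self-substitutions.
The TSV serialization is the contract surface; raster rendering is an
optional extra on top of it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .consensus import TIER_NAMES
from .errors import ValidationError
from .variant_model import AA_ORDER, ProteinSequence

#: TSV marker for the wild-type (self-substitution) cell.
WT_MARK = "."


def build_heatmap(
    tiers: pd.DataFrame,
    sequence: ProteinSequence,
    start: int = 1,
    end: int | None = None,
) -> pd.DataFrame:
    """20 x L tier matrix (rows: residues in group order; columns: positions).

    ``tiers`` must hold a tier for every non-wild-type substitution in the
    range; missing cells are an error listing the gaps.
    """
    if end is None:
        end = len(sequence)
    if not 1 <= start <= end <= len(sequence):
        raise ValidationError(f"range {start}..{end} outside sequence")
    lookup = {
        (int(r.position), r.mut): r.tier
        for r in tiers.itertuples()
        if start <= r.position <= end
    }
    positions = list(range(start, end + 1))
    matrix = pd.DataFrame(index=list(AA_ORDER), columns=positions, dtype=object)
    missing: list[str] = []
    for pos in positions:
        wt = sequence.residue(pos)
        for aa in AA_ORDER:
            if aa == wt:
                matrix.at[aa, pos] = WT_MARK
                continue
            t = lookup.get((pos, aa))
            if t is None:
                missing.append(f"{wt}{pos}{aa}")
            elif t not in TIER_NAMES:
                raise ValidationError(f"unknown tier {t!r} for {wt}{pos}{aa}")
            else:
                matrix.at[aa, pos] = t
    if missing:
        head = ", ".join(missing[:10])
        raise ValidationError(
            f"{len(missing)} substitutions missing from the tier table: {head}"
        )
    matrix.index.name = "residue"
    return matrix


def write_heatmap_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", encoding="utf-8")
    return path


def read_heatmap_tsv(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    matrix.columns = [int(c) for c in matrix.columns]
    matrix.index.name = "residue"
    return matrix


def render_heatmap(matrix: pd.DataFrame, path: str | Path, dpi: int = 150) -> Path:
    """Optional raster rendering (tiers colored, wild-type cells white)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = {WT_MARK: 0, "P3": 1, "P2": 2, "B2": 3, "B3": 4}
    numeric = matrix.map(lambda v: order[v]).to_numpy()
    cmap = ListedColormap(["#ffffff", "#a50f15", "#fb6a4a", "#9ecae1", "#08519c"])
    fig, ax = plt.subplots(
        figsize=(max(6.0, matrix.shape[1] / 12.0), 5.0), constrained_layout=True
    )
    ax.imshow(numeric, aspect="auto", cmap=cmap, vmin=0, vmax=4, interpolation="nearest")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    step = max(1, matrix.shape[1] // 30)
    ax.set_xticks(range(0, matrix.shape[1], step), list(matrix.columns)[::step])
    ax.set_xlabel("position")
    ax.set_ylabel("substituted residue")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return Path(path)
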