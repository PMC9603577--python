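"""Published benchmark marginals for the CDKL5 catalytic-domain study.

The original benchmark evaluated the four predictors and all their
combinations against a curated ClinVar reference panel of 36 CDKL5
missense variants (33 pathogenic, 3 benign or likely benign) and printed
per-row accuracy, sensitivity and specificity percentages.  Those printed
marginals, together with the two class sizes, fully determine each row's
integer confusion counts by nearest-integer inversion
(:func:`satpred.performance.derive_confusion`), from which the MCC can be
recomputed exactly — including the rows whose MCC is undefined because a
marginal sum is zero.

Note: the published table lists one pair row as "PolyPhen-2 HumDiv &
PolyPhen2 HumDiv"; a subset sweep contains each distinct pair once, and the
only pair absent from the published list is HumDiv & HumVar, so that row is
recorded here as the (humdiv, humvar) pair with its printed marginals.
"""

from __future__ import annotations

import pandas as pd

from .performance import derive_confusion, metrics

#: Reference-panel class sizes.
REFERENCE_N_PATHOGENIC = 33
REFERENCE_N_BENIGN = 3

#: (tool subset, accuracy %, sensitivity %, specificity %) — the printed
#: benchmark marginals, ordered singles, pairs, triples, quadruple.
PUBLISHED_MARGINALS: list[tuple[tuple[str, ...], float, float, float]] = [
    (("humdiv",), 94.4, 100.0, 33.3),
    (("humvar",), 94.4, 97.0, 66.7),
    (("provean",), 94.4, 97.0, 66.7),
    (("sift",), 88.9, 97.0, 0.0),
    (("humdiv", "humvar"), 94.4, 100.0, 33.3),
    (("humdiv", "provean"), 94.4, 100.0, 33.3),
    (("humdiv", "sift"), 91.7, 100.0, 0.0),
    (("humvar", "provean"), 97.2, 100.0, 66.7),
    (("humvar", "sift"), 91.7, 100.0, 0.0),
    (("provean", "sift"), 88.9, 97.0, 0.0),
    (("humdiv", "humvar", "provean"), 97.2, 100.0, 66.7),
    (("humdiv", "humvar", "sift"), 94.4, 100.0, 33.3),
    (("humdiv", "provean", "sift"), 91.7, 97.0, 33.3),
    (("humvar", "provean", "sift"), 94.4, 97.0, 66.7),
    (("humdiv", "humvar", "provean", "sift"), 94.4, 100.0, 33.3),
]

#: The subset starred in the original study as the operating combination
#: (both PolyPhen-2 modes with PROVEAN).
STARRED_COMBINATION: tuple[str, ...] = ("humdiv", "humvar", "provean")


def published_benchmark() -> pd.DataFrame:
    """Reconstruct the full benchmark table from the printed marginals.

    Confusion counts come from nearest-integer inversion of each row's
    sensitivity/specificity at the fixed class sizes; accuracy and MCC are
    then recomputed from those counts (``mcc`` is NA where undefined).
    """
    rows = []
    for subset, accuracy, sens, spec in PUBLISHED_MARGINALS:
        c = derive_confusion(REFERENCE_N_PATHOGENIC, REFERENCE_N_BENIGN, sens, spec)
        m = metrics(c)
        rows.append(
            {
                "tools": ",".join(subset),
                "n_tools": len(subset),
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                "published_accuracy": accuracy,
                "accuracy": m.accuracy_pct,
                "sensitivity": m.sensitivity_pct,
                "specificity": m.specificity_pct,
                "mcc": m.mcc_3dp,
                "mcc_text": m.mcc_text,
            }
        )
    return pd.DataFrame(rows)
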