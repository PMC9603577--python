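"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from satpred import (
    ProteinSequence,
    ReferenceVariant,
    Substitution,
    enumerate_saturation,
)
from satpred.variant_model import AA_ORDER


@pytest.fixture(scope="session")
def seq300() -> ProteinSequence:
    """A deterministic 300-residue synthetic catalytic-domain-sized sequence."""
    rng = np.random.default_rng(2022)
    return ProteinSequence(
        identifier="synthetic-domain",
        residues="".join(rng.choice(list(AA_ORDER), size=300)),
    )


@pytest.fixture(scope="session")
def seq10() -> ProteinSequence:
    return ProteinSequence(identifier="toy", residues="MKIVSHLDEY")


@pytest.fixture
def perfect_scores(seq10) -> pd.DataFrame:
    """Panel scores that make every substitution unanimously pathogenic."""
    subs = enumerate_saturation(seq10)
    frames = []
    for tool, score in (("humdiv", 1.0), ("humvar", 1.0), ("provean", -10.0)):
        frames.append(
            pd.DataFrame(
                {
                    "position": [s.position for s in subs],
                    "wt": [s.wt for s in subs],
                    "mut": [s.mut for s in subs],
                    "tool": tool,
                    "score": score,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def reference_33_3(seq300) -> list[ReferenceVariant]:
    """A 36-variant synthetic reference with the 33/3 class structure."""
    subs = enumerate_saturation(seq300)[:36]
    return [
        ReferenceVariant(s, "pathogenic" if i < 33 else "benign", "synthetic")
        for i, s in enumerate(subs)
    ]
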