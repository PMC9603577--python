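"""Seeded generators for prediction-score tables and reference variant
sets, so every pipeline stage runs without access to the prediction
servers.

Score generation
----------------
Each substitution of a saturation set gets a latent pathogenic/benign
label (Bernoulli draw; the default latent pathogenic rate of 0.94 matches
the overall pathogenic fraction the saturation analysis reports for the
CDKL5 catalytic domain).  Each tool then draws a score from a
two-component class-conditional family:

* PolyPhen-2 modes — Beta components on [0, 1], the pathogenic component
  concentrated near 1 and the benign component near 0;
* SIFT — Beta components with the roles reversed (low scores deleterious);
* PROVEAN — normal (location-scale) components on the real line, the
  pathogenic component centred well below the -2.5 cutoff.

The mixture weights given the latent label are calibrated analytically so
that the *expected* post-threshold pathogenic-call rate per tool equals a
configured target (defaults: the marginal call rates of the original
saturation run — 95.8 / 92.3 / 82.6 / 88.0 % for HumDiv / HumVar /
PROVEAN / SIFT).  Empirical rates then fluctuate around the target with
binomial noise only.  An unreachable target under the configured family
and thresholds raises :class:`~satpred.errors.CalibrationError`.

Reference generation
--------------------
:func:`simulate_reference` builds a labeled reference set (default 33
pathogenic + 3 benign, the curated ClinVar panel structure) together with
per-tool binary calls whose confusion counts *exactly* equal the counts
implied by each tool's requested sensitivity/specificity.  The marginals
do not determine the joint error pattern across tools, so the overlap
structure is explicit: ``maximal`` (tools share error variants),
``disjoint`` (errors spread over distinct variants where possible) or
``random`` (seeded draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import CalibrationError, ConfigurationError, ValidationError
from .performance import ConfusionCounts, derive_confusion
from .thresholds import DEFAULT_THRESHOLDS, ThresholdConfig
from .tool_io import TOOLS, ReferenceVariant, SCORE_COLUMNS
from .variant_model import AA_ORDER, ProteinSequence, Substitution, enumerate_saturation

#: Default per-tool marginal pathogenic-call-rate targets (percent),
#: matching the original saturation run over the catalytic domain.
DEFAULT_TARGET_RATES: dict[str, float] = {
    "humdiv": 95.8,
    "humvar": 92.3,
    "provean": 82.6,
    "sift": 88.0,
}

#: Default class-conditional score families per tool:
#: (family, pathogenic-component params, benign-component params).
#: Beta params are (a, b); normal params are (loc, scale).
DEFAULT_FAMILIES: dict[str, tuple[str, tuple[float, float], tuple[float, float]]] = {
    "humdiv": ("beta", (6.0, 0.3), (0.3, 6.0)),
    "humvar": ("beta", (6.0, 0.3), (0.3, 6.0)),
    "provean": ("normal", (-7.0, 2.5), (0.0, 1.5)),
    "sift": ("beta", (0.08, 10.0), (2.0, 5.0)),
}

#: Default single-tool operating points (sensitivity %, specificity %) for
#: reference simulation, matching the published single-tool benchmark rows.
DEFAULT_REFERENCE_SPEC: dict[str, tuple[float, float]] = {
    "humdiv": (100.0, 33.3),
    "humvar": (97.0, 66.7),
    "provean": (97.0, 66.7),
    "sift": (97.0, 0.0),
}

OVERLAP_MODES = ("maximal", "disjoint", "random")


@dataclass
class SyntheticConfig:
    """Configuration for the score generator."""

    seed: int = 0
    length: int = 300
    latent_pathogenic_rate: float = 0.94
    target_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_RATES)
    )
    families: dict[str, tuple[str, tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES)
    )
    n_pathogenic: int = 33
    n_benign: int = 3
    reference_spec: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_SPEC)
    )
    overlap: str = "maximal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.latent_pathogenic_rate <= 1.0:
            raise ConfigurationError("latent_pathogenic_rate must be in [0, 1]")
        if self.overlap not in OVERLAP_MODES:
            raise ConfigurationError(
                f"overlap must be one of {OVERLAP_MODES}, got {self.overlap!r}"
            )
        for tool in self.target_rates:
            if tool not in TOOLS:
                raise ConfigurationError(f"unknown tool {tool!r} in target_rates")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        for key in (
            "seed",
            "length",
            "latent_pathogenic_rate",
            "n_pathogenic",
            "n_benign",
            "overlap",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "target_rates" in raw:
            kwargs["target_rates"] = {
                k: float(v) for k, v in raw.pop("target_rates").items()
            }
        if "families" in raw:
            kwargs["families"] = {
                k: (v["family"], tuple(v["pathogenic"]), tuple(v["benign"]))
                for k, v in raw.pop("families").items()
            }
        if "reference_spec" in raw:
            kwargs["reference_spec"] = {
                k: (float(v[0]), float(v[1])) for k, v in raw.pop("reference_spec").items()
            }
        if raw:
            raise ConfigurationError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)


def _distribution(family: str, params: tuple[float, float]):
    if family == "beta":
        return stats.beta(*params)
    if family == "normal":
        return stats.norm(*params)
    raise ConfigurationError(f"unknown score family {family!r}")


def _call_probability(tool: str, dist, thresholds: ThresholdConfig) -> float:
    """P(binary call = pathogenic) for a score drawn from ``dist``."""
    if tool == "humdiv":
        return float(1.0 - dist.cdf(thresholds.humdiv_benign))
    if tool == "humvar":
        return float(1.0 - dist.cdf(thresholds.humvar_benign))
    if tool == "provean":
        return float(dist.cdf(thresholds.provean_cutoff))
    if tool == "sift":
        return float(dist.cdf(thresholds.sift_cutoff))
    raise ConfigurationError(f"unknown tool {tool!r}")


def calibrate_weights(
    p_path: float, p_benign: float, latent_rate: float, target: float
) -> tuple[float, float]:
    """Mixture weights (w_pathogenic, w_benign) on the pathogenic-side
    component, conditional on the latent label, such that the expected
    overall pathogenic-call rate equals ``target`` (a fraction).

    ``p_path``/``p_benign`` are the call probabilities of the two
    components.  Starting from the fully separated assignment (pathogenic
    label -> pathogenic component, benign label -> benign component), one
    weight is relaxed linearly toward the target.
    """
    if not p_benign < p_path:
        raise CalibrationError(
            "pathogenic component must call pathogenic more often than the "
            f"benign component (got {p_path:.4f} vs {p_benign:.4f})"
        )
    if not p_benign <= target <= p_path:
        raise CalibrationError(
            f"target rate {target:.4f} unreachable: achievable range is "
            f"[{p_benign:.4f}, {p_path:.4f}] under the configured family"
        )
    span = p_path - p_benign
    pi = latent_rate
    base = pi * p_path + (1 - pi) * p_benign
    if target >= base:
        w_path = 1.0
        w_benign = 0.0 if pi == 1.0 else ((target - pi * p_path) / (1 - pi) - p_benign) / span
    else:
        w_benign = 0.0
        w_path = 1.0 if pi == 0.0 else ((target - (1 - pi) * p_benign) / pi - p_benign) / span
    w_path = min(max(w_path, 0.0), 1.0)
    w_benign = min(max(w_benign, 0.0), 1.0)
    return w_path, w_benign


def synthetic_sequence(length: int, seed: int, identifier: str = "synthetic") -> ProteinSequence:
    """A reproducible random protein sequence (uniform over the 20 codes)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    letters = rng.choice(list(AA_ORDER), size=length)
    return ProteinSequence(identifier=identifier, residues="".join(letters))


def simulate_scores(
    cfg: SyntheticConfig,
    sequence: ProteinSequence | None = None,
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a canonical score table over a full saturation set.

    Returns ``(scores, latent)``: the canonical score table (one row per
    tool and substitution) and the latent label table (columns
    ``position, wt, mut, latent_label``).  Fully reproducible from
    ``cfg.seed``.
    """
    if sequence is None:
        sequence = synthetic_sequence(cfg.length, cfg.seed)
    subs = enumerate_saturation(sequence)
    n = len(subs)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    latent_path = rng.random(n) < cfg.latent_pathogenic_rate

    score_frames = []
    for tool, target_pct in cfg.target_rates.items():
        family, path_params, ben_params = cfg.families[tool]
        d_path = _distribution(family, path_params)
        d_ben = _distribution(family, ben_params)
        p_a = _call_probability(tool, d_path, thresholds)
        p_b = _call_probability(tool, d_ben, thresholds)
        w_path, w_ben = calibrate_weights(
            p_a, p_b, cfg.latent_pathogenic_rate, target_pct / 100.0
        )
        comp_w = np.where(latent_path, w_path, w_ben)
        use_path_comp = rng.random(n) < comp_w
        draws_path = d_path.rvs(size=n, random_state=rng)
        draws_ben = d_ben.rvs(size=n, random_state=rng)
        scores = np.where(use_path_comp, draws_path, draws_ben)
        if family == "beta":
            # guard against exact 0/1 from numerical underflow
            scores = np.clip(scores, 0.0, 1.0)
        score_frames.append(
            pd.DataFrame(
                {
                    "position": [s.position for s in subs],
                    "wt": [s.wt for s in subs],
                    "mut": [s.mut for s in subs],
                    "tool": tool,
                    "score": scores,
                }
            )
        )
    score_table = pd.concat(score_frames, ignore_index=True)[SCORE_COLUMNS]
    latent = pd.DataFrame(
        {
            "position": [s.position for s in subs],
            "wt": [s.wt for s in subs],
            "mut": [s.mut for s in subs],
            "latent_label": np.where(latent_path, "pathogenic", "benign"),
        }
    )
    return score_table, latent


def _error_indices(
    n_class: int, n_errors: int, mode: str, offset: int, rng: np.random.Generator
) -> set[int]:
    if n_errors > n_class:
        raise ValidationError(f"cannot place {n_errors} errors among {n_class} variants")
    if mode == "maximal":
        return set(range(n_errors))
    if mode == "disjoint":
        return {(offset + i) % n_class for i in range(n_errors)}
    return set(rng.choice(n_class, size=n_errors, replace=False).tolist())


def simulate_reference(
    cfg: SyntheticConfig,
    sequence: ProteinSequence | None = None,
) -> tuple[list[ReferenceVariant], pd.DataFrame, dict[str, ConfusionCounts]]:
    """Construct a labeled reference set and per-tool calls realizing each
    tool's requested (sensitivity, specificity) *exactly*.

    Returns ``(reference, calls, expected_confusions)`` where ``calls`` has
    columns ``notation, tool, call`` and ``expected_confusions`` holds the
    per-tool counts the calls were built to satisfy (useful as an oracle).
    """
    if sequence is None:
        sequence = synthetic_sequence(cfg.length, cfg.seed)
    subs = enumerate_saturation(sequence)
    n_ref = cfg.n_pathogenic + cfg.n_benign
    if n_ref > len(subs):
        raise ValidationError("reference larger than the saturation set")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    picked = rng.choice(len(subs), size=n_ref, replace=False)
    chosen: list[Substitution] = [subs[i] for i in picked]
    pathogenic = chosen[: cfg.n_pathogenic]
    benign = chosen[cfg.n_pathogenic :]

    reference = [
        ReferenceVariant(s, "pathogenic", "synthetic") for s in pathogenic
    ] + [ReferenceVariant(s, "benign", "synthetic") for s in benign]

    rows = []
    expected: dict[str, ConfusionCounts] = {}
    fn_offset = fp_offset = 0
    for tool, (sens, spec) in cfg.reference_spec.items():
        c = derive_confusion(cfg.n_pathogenic, cfg.n_benign, sens, spec)
        expected[tool] = c
        fn_idx = _error_indices(cfg.n_pathogenic, c.fn, cfg.overlap, fn_offset, rng)
        fp_idx = _error_indices(cfg.n_benign, c.fp, cfg.overlap, fp_offset, rng)
        fn_offset += c.fn
        fp_offset += c.fp
        for i, s in enumerate(pathogenic):
            rows.append(
                {
                    "notation": s.notation,
                    "tool": tool,
                    "call": "benign" if i in fn_idx else "pathogenic",
                }
            )
        for i, s in enumerate(benign):
            rows.append(
                {
                    "notation": s.notation,
                    "tool": tool,
                    "call": "pathogenic" if i in fp_idx else "benign",
                }
            )
    return reference, pd.DataFrame(rows), expected
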