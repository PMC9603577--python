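# Methods

## Scope and data model

The pipeline operates at the protein level. A substitution is a 1-based
position plus wild-type and mutant residues in one-letter notation
(`H145Y`); saturation enumeration produces, for each position of a region,
the 19 replacements by every standard residue other than the wild type.
Residue order is fixed throughout (enumeration, heatmap rows): non-polar
`GAVLIMPFW`, polar uncharged `STCYNQ`, acidic `DE`, basic `KRH`. The
grouping follows standard physicochemical classes; the within-group order
is a package convention chosen for determinism, not a reproduction of any
published figure. Position 1 (the initiator methionine) is substitutable
like any other position, so a 300-residue domain yields exactly 5700
substitutions. Wild-type "self" records (`M1M`) are representable — the
heatmap needs one per column — but never enumerated.

Nucleotide-level representation (HGVS `c.` notation, codon reachability) is
out of scope, as is computing multiple alignments: the conservation module
consumes a pre-aligned FASTA.

## Classification thresholds

All boundaries live in one `ThresholdConfig` (YAML-overridable); the
defaults are the tools' published operating points. Two boundary
conventions deserve a note because the sources are loose about them:

* **PROVEAN −2.5.** The cutoff value itself is classified deleterious
  (`score ≤ −2.5`), matching the tool's own labeling; descriptions of the
  rule often say "below". The difference only affects scores exactly at
  the boundary; such scores are reported to the logger.
* **PolyPhen-2 middle interval.** Only "above" the probably-damaging
  boundary and "below" the benign boundary are named by the sources, so
  the closed interval between them is the only exhaustive completion for
  "possibly damaging"; both endpoints fall in it.

Binarization maps probably/possibly damaging and deleterious to
*pathogenic*; benign, neutral, and tolerated to *benign*. Native server
reports carry their own class labels; the readers discard them and the
pipeline recomputes classes locally, which keeps the analysis auditable and
threshold-configurable.

## Consensus

Combination rules for 2–4 tools are vote thresholds that favour
pathogenicity on a split: a 2-tool panel is benign only when unanimous; a
3-tool panel follows the majority; a 4-tool panel is pathogenic with two or
more damaging votes (the 2–2 tie is pathogenic by rule, not by tie-break
ambiguity). Consensus tiers P3/P2/B2/B3 count pathogenic votes from the
fixed panel {HumDiv, HumVar, PROVEAN}; the panel is configurable to any
three tools. The 3-tool combination rule and tier binarization agree by
construction, and a tier table always partitions its saturation set.

## Performance metrics

Accuracy, sensitivity and specificity are percentages of the confusion
counts; the MCC is the standard binary correlation. Undefined values (zero
denominator or zero marginal) are first-class: `None` internally, "―" in
rendered tables, excluded from "MCC > 0.5" counts. Coercing them to 0
would silently inflate or deflate such counts. Rounding is half-up, applied
at presentation only: one decimal for percentages, three for MCC.

`derive_confusion` inverts printed (sensitivity, specificity) pairs at
known class sizes into integer counts by nearest-integer reconstruction and
accepts the result only if the counts round-trip back to the printed
one-decimal values. This makes published benchmark tables machine-usable:
e.g. sensitivity 97.0% at n = 33 gives TP = round(32.01) = 32, and
specificity 0.0% at n = 3 gives TN = 0. The bundled benchmark marginals
(`benchmark_data.py`) are the published per-combination values for the
CDKL5 ClinVar panel (33 pathogenic, 3 benign); the printed source contains
one typographical duplicate row ("HumDiv & HumDiv"), recorded here as the
HumDiv & HumVar pair, the only pair otherwise absent from the printed list.
The sweep itself (`sweep_combinations`) always emits each distinct subset
exactly once: 2^k − 1 rows for k tools, ordered singles, pairs, triples,
quadruple.

## Conservation

Identity is the statistic: the percentage of region positions at which the
other species' aligned residue equals the reference residue. Columns where
the reference is gapped are not reference positions; a gap in the other
species counts as a mismatch. Region conservation is the arithmetic mean of
pairwise identities over the non-reference species. Published cross-species
"similarity" figures for this domain do not state their statistic; mean
pairwise identity to the reference is this package's documented choice, and
those specific decimals are not asserted anywhere. Substitution-matrix
similarity and phylogenetic conservation scores are out of scope.

The default region set is the CDKL5 catalytic-domain annotation: critical
regions ATP-binding site (19–43), S/T kinase active site (131–143), TEY
motif (169–171); non-critical comparison windows 144–168 and 257–297.

## Region statistics

Tier counts are tallied per region (plus an "other" bucket for positions
outside all regions; counts always total the full table). The
critical-vs-non-critical comparison pools the three critical regions
against the two non-critical windows — one pooled comparison per planned
contrast, matching how the enrichment question is posed — and applies the
classical two-sample test of proportion: pooled-variance z statistic
without continuity correction (so z² equals the 2×2 chi-square statistic,
which the tests verify against `scipy.stats.chi2_contingency` and
statsmodels), two-sided normal p-value, and an unpooled Wald 95% CI for the
difference. The pathogenic-proportion and benign-proportion tests are
complementary (equal |z|, opposite sign) and both are reported. With a
degenerate pooled proportion (0 or 1) the two sample proportions are
necessarily equal; z is undefined and p is reported as 1. α = 0.05 by
default; no multiple-testing correction is applied to the two planned
comparisons.

## Synthetic generator

The generator exists so the full pipeline is testable and reproducible
without the prediction servers.

**Scores.** Each substitution receives a latent pathogenic label
(Bernoulli, default rate 0.94 — the overall pathogenic fraction of the
original saturation analysis). Each tool draws its score from a
two-component class-conditional family:

| tool | family | pathogenic component | benign component |
|---|---|---|---|
| HumDiv / HumVar | Beta on [0,1] | Beta(6, 0.3) (mass near 1) | Beta(0.3, 6) |
| PROVEAN | normal | N(−7, 2.5²) | N(0, 1.5²) |
| SIFT | Beta on [0,1] | Beta(0.08, 10) (mass near 0) | Beta(2, 5) |

These are the simplest families that place adjustable mass on either side
of each threshold with realistic shapes (PolyPhen-2 scores pile up near the
extremes; PROVEAN deltas of clearly deleterious substitutions sit several
units below −2.5). The component call probabilities p_path and p_benign
are computed analytically from each distribution's CDF at the binarization
boundary, and the label-conditional mixture weights are solved linearly so
the *expected* pathogenic-call rate equals the configured target (defaults:
95.8 / 92.3 / 82.6 / 88.0 % — the marginal rates of the original run).
Calibration is exact in expectation; empirical rates carry only binomial
noise (verified within 3 binomial standard errors at n = 5700). Targets
outside [p_benign, p_path] raise a calibration error rather than silently
clipping.

**References.** `simulate_reference` draws reference variants from the
saturation set (default 33 pathogenic + 3 benign) and constructs per-tool
binary calls whose confusion counts equal `derive_confusion` of each
tool's requested (sensitivity, specificity) *exactly* — these are
constructed, not sampled. The tools' marginals do not determine their
joint error pattern, so the overlap structure is explicit:

* `maximal` (default) — all tools err on the same variants; consensus
  errors are then as large as the marginals allow;
* `disjoint` — errors spread over distinct variants where capacity allows;
* `random` — seeded draw.

With the three panel tools at sensitivity 100 / specificity 66.7 and
maximal overlap, the majority consensus realizes confusion (33, 2, 1, 0)
and hence accuracy 97.2%, MCC 0.804 — the configuration the acceptance
script uses.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` substreams; identical seed and configuration
give byte-identical output files (scores serialize at fixed 6-decimal
precision).

**What the generator does not emulate.** Scores are conditionally
independent across tools given the latent label, while real predictors are
correlated (they share conservation signal); per-position effects (e.g.
N-terminal substitutions scoring neutral) exist only through the optional
region-dependent latent rate; and the score marginals are parametric
idealizations, not fits to real server output corpora. Passing tests
therefore demonstrate the pipeline's correctness and calibration machinery,
not the accuracy of any particular prediction server on real variants.

## Problem sizes and determinism

The test suite and acceptance script run the full 5700-substitution
saturation scale (300 residues × 19) for generator calibration, tier
partition and heatmap checks, and the 36-variant reference scale for all
benchmark metrics; both complete in seconds. Property-based tests
(hypothesis) are seeded/derandomized. The acceptance script derives all
randomness from its `--seed`; the deterministic targets (metric values,
combination counts) are seed-invariant by construction, which was verified
across seeds.

## Known limitations

* Quantities that require live server scores for all 5700 substitutions —
  exact per-tool call counts, the exact tier split, per-region tier
  percentages of the real domain — cannot be recomputed here; the package
  recomputes their synthetic analogues and checks internal consistency
  only.
* The reference-scale benchmark inherits the weakness of its reference:
  with 3 benign variants, specificity is quantized to {0, 33.3, 66.7,
  100} and a single benign miscall can flip the MCC sign.
* Native report parsers accept a documented superset of the 2021–2022
  server output layouts and are permissive about extra columns; exotic
  layouts may need the canonical TSV path instead.
* No real CDKL5 sequences or alignments ship with the package; supply
  accession-derived FASTA inputs to run the real-domain analyses.
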