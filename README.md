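# satpred

Saturation missense-variant pathogenicity analysis for a protein catalytic
domain: classify per-tool prediction scores, combine tools into a consensus,
benchmark every tool combination against a labeled reference set, and relate
the results to sequence conservation and functional regions.

## The problem

Missense variants of uncertain significance are a routine headache in the
molecular diagnosis of rare disease. For a kinase such as CDKL5 — whose
loss-of-function variants cause CDKL5 deficiency disorder, and whose
pathogenic missense changes cluster in the catalytic domain (residues
1–300) — one practical strategy is *in-silico saturation*: score all
19 × L possible single amino-acid substitutions of the domain (19 × 300 =
5700) with several prediction tools, and ask which tool, or combination of
tools, best reproduces the pathogenic/benign labels of expert-curated
ClinVar variants.

satpred implements that workflow end to end for four predictors —
PolyPhen-2 in its HumDiv and HumVar modes, PROVEAN, and SIFT — using their
published operating thresholds:

| tool | pathogenic when | categories |
|---|---|---|
| PolyPhen-2 HumDiv | score ≥ 0.450 (probably damaging > 0.957) | probably/possibly damaging, benign |
| PolyPhen-2 HumVar | score ≥ 0.447 (probably damaging > 0.909) | probably/possibly damaging, benign |
| PROVEAN | delta score ≤ −2.5 | deleterious, neutral |
| SIFT | score < 0.05 | deleterious, tolerated |

A designated three-tool panel (HumDiv, HumVar, PROVEAN) assigns each
substitution a consensus tier by pathogenic vote count: **P3** (3 votes),
**P2** (2), **B2** (1), **B3** (0). Against a reference set with TP/TN/FP/FN
confusion counts, performance is summarized by accuracy, sensitivity,
specificity and the Matthews correlation coefficient

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which is *undefined* (rendered “―”, never coerced to 0) when any marginal
sum is zero — a situation that actually occurs on small references with few
benign variants.

Because the upstream prediction servers are interactive web services, the
package ships a seeded synthetic generator that emulates their output: a
class-conditional score model per tool, calibrated analytically so the
expected post-threshold pathogenic-call rates match the marginal rates
observed in the original CDKL5 saturation run (95.8 / 92.3 / 82.6 / 88.0 %
for HumDiv / HumVar / PROVEAN / SIFT), plus reference sets whose per-tool
confusion counts realize requested sensitivity/specificity pairs exactly.
The batch-input writers and native-report parsers let the same pipeline
consume real server output when you have it.

## Worked example

```python
from satpred import ConfusionCounts, metrics

# the best-performing combination (HumDiv + HumVar + PROVEAN) on a
# 36-variant reference: 33/33 pathogenic called, 1 of 3 benign miscalled
m = metrics(ConfusionCounts(tp=33, tn=2, fp=1, fn=0))
print(m.accuracy_pct, m.sensitivity_pct, m.specificity_pct, m.mcc_text)
# 97.2 100.0 66.7 0.804
```

A full synthetic saturation run over a 300-residue domain:

```python
from satpred import SyntheticConfig, simulate_scores, tabulate_categories, \
    tier_map, tier_summary

scores, _ = simulate_scores(SyntheticConfig(seed=1))
print(tabulate_categories(scores))
#    tool  benign_n  pathogenic_n  total  benign_pct  pathogenic_pct
#  humdiv       233          5467   5700         4.1            95.9
#  humvar       421          5279   5700         7.4            92.6
# provean       971          4729   5700        17.0            83.0
#    sift       677          5023   5700        11.9            88.1
print(tier_summary(tier_map(scores)))
# {'P3': 81.2, 'P2': 12.9, 'B2': 2.1, 'B3': 3.8,
#  'pathogenic': 94.1, 'benign': 5.9}
```

The per-tool pathogenic rates land on the calibration targets up to
binomial noise, and the consensus tiers partition all 5700 substitutions
into a ~94/6 pathogenic/benign split.

The same pipeline is available from the shell:

```sh
satpred simulate --seed 7 --out-dir sim/
satpred classify  --scores sim/scores.tsv --out classified.tsv --summary rates.tsv
satpred consensus --scores sim/scores.tsv --out tiers.tsv --summary tiers.json
satpred evaluate  --scores sim/scores.tsv --reference sim/reference.csv --out bench.tsv
satpred heatmap   --tiers tiers.tsv --fasta domain.fasta --out heatmap.tsv
```

`evaluate` emits the 15-row benchmark (4 singles, 6 pairs, 4 triples, 1
quadruple); `heatmap` exports the 20 × L tier matrix with wild-type cells
marked `.`.

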