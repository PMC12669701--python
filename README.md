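# irdyield

Diagnostic-yield analysis for inherited retinal disease (IRD) exome
cohorts. The package implements, as a tested and reusable pipeline, the
analysis layer of a cohort study that asks *who gets a molecular
diagnosis and why*:

- a **points-based ACMG/AMP classifier**: asserted criteria scored at
  8/4/2/1 points per strength (negated for benign direction), banded as
  B/LB (x < 0), VUS (0 <= x < 5), VUS-FP (x = 5), LP (6 <= x < 10),
  P (x >= 10);
- **case resolution** to fully solved / probably solved / unsolved from
  variant bands, per-gene inheritance mode, zygosity and phase (with
  in-trans confirmation or presumption for recessive het pairs);
- a **CNV read-ratio filter** for read-depth candidates (het deletion at
  0.3 <= RR <= 0.7, hom/hemi at RR < 0.1, duplications kept at RR > 1.3,
  ambiguous windows surfaced for review);
- **kinship deduplication** via the KING-robust estimator
  phi = (N_het,het − 2·N_opp,hom)/(N_het(i) + N_het(j)), degree cutoffs at
  1/2^(5/2) and 1/2^(7/2), and seeded one-per-component pruning;
- **cohort statistics**: stratified yields, exact Fisher and rank-sum
  tests (enumeration-exact where feasible, seeded Monte-Carlo for r x c),
  binomial logistic regression of solved status on onset age and family
  history, odds/risk ratios, recurrent gene/variant tables, and
  genotype-phenotype concordance;
- a **seeded synthetic cohort generator** that emulates a multi-ethnic
  Asian IRD cohort (ancestry mix, onset-age mixture with median ~31,
  32.8% family-history prevalence, phenotype-specific gene pools,
  founder variants, logit P(solved) = alpha − 0.026·onset + 0.78·FH
  calibrated to an overall yield of 0.49, injected relative pairs) with
  hidden ground truth, so every stage is testable end to end.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Run the whole pipeline (simulate → classify → resolve → kinship dedup →
analyze) on the default 506-proband configuration:

```python
from irdyield.pipeline import run_pipeline
from irdyield.simulate import GeneratorConfig

result = run_pipeline(GeneratorConfig(seed=7), mc_reps=20_000)
r = result.report
print(r["overall"])
print({k: v["yield_pct"] for k, v in sorted(r["yield_by_age_bin"].items())})
print(result.stage_counts["flagged_pairs"], result.stage_counts["retained_probands"])
print(round(r["logistic"]["params"]["age"], 4))
```

prints

```
{'fully_solved': 184, 'probably_solved': 56, 'solved': 240, 'yield_pct': 48.29}
{'60+': 37.9, '[0,20)': 67.4, '[20,40)': 43.3, '[40,60)': 32.8}
9 497
-0.0253
```

Reading: of 506 simulated probands, the nine injected first/second-degree
relative pairs are all flagged by kinship analysis and one member of each
removed (497 analyzed); 240 of the remaining probands are solved (48.3%
yield, within sampling error of the calibrated 49%); yield falls
monotonically across onset-age bins from 67.4% (onset < 20) to 37.9%
(onset 60+); and the logistic fit recovers the generating onset-age
slope of −0.026. The report also carries family-history contrasts
(e.g. 54.5% yield with 1–2 affected relatives vs 43.2% without, risk
ratio 1.26), recurrent-gene shares (USH2A 17.1% of solved in this run),
trans-confirmation rate among phased recessive pairs (0.91) and
genotype–phenotype concordance (89.6%).

The same pipeline is available from the shell:

```sh
irdyield run-all --seed 7 --out results/run7
irdyield simulate --seed 1 --out work/
irdyield classify work/variants.tsv --out work/classified.tsv
irdyield resolve work/classified.tsv work/probands.tsv --out work/status.tsv
irdyield kinship work/genotypes.tsv --out work/kin
irdyield analyze work/probands.tsv work/status.tsv --retain work/kin/retained_ids.txt --out work/report.json
```

All inputs and outputs are plain UTF-8 TSV with "." for missing values;
ACMG criteria travel as semicolon-joined `CODE:STRENGTH[:B]` tokens.

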