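# Methods

`irdyield` models the analysis layer of a diagnostic-yield study of an
inherited retinal disease (IRD) exome cohort: variants in a curated gene
panel arrive with asserted ACMG/AMP criteria, are scored and banded, cases
are resolved against per-gene inheritance models, related probands are
pruned, and yield determinants are quantified. This note records the
models, the defaults and why, and what the synthetic data does and does
not establish.

## Points-based variant classification

Each asserted criterion carries a strength worth 8 (very strong), 4
(strong), 2 (moderate) or 1 (supporting) point; benign-direction criteria
contribute the negated magnitude, which is what makes the benign band
(score < 0) reachable. The summed score x maps to five bands:

| score | band |
|---|---|
| x < 0 | benign / likely benign |
| 0 <= x < 5 | VUS |
| x = 5 | VUS-FP (VUS favouring pathogenic) |
| 6 <= x < 10 | likely pathogenic |
| x >= 10 | pathogenic |

With integer weights the interval (5, 6) is unreachable; the classifier
folds it into VUS-FP so the bands partition the reals even under a
user-supplied weight table. Criterion codes are free strings checked only
for uniqueness: strength modulation (e.g. PM2 applied at supporting
strength) is a judgement made upstream, and the engine deliberately does
not police code/strength compatibility. Criterion assessment itself —
from allele frequencies, computational predictors, functional data — is
out of scope; criteria arrive asserted.

## Case resolution

A case is *fully solved* when the allele count demanded by the causal
gene's inheritance mode is met entirely by P/LP alleles: one
heterozygous allele for autosomal dominant genes, one hemizygous allele
for X-linked males, and a homozygous variant or a heterozygous pair in
trans for autosomal recessive genes. It is *probably solved* when the
allele count is met, at least one contributing allele is VUS-FP, and the
gene's disease spectrum contains the presenting diagnosis. Design
choices where the convention is genuinely open:

- **Unphased recessive pairs** are presumed in trans by default
  (`assume_trans=True`) but recorded as unconfirmed; the presumption
  reflects the ~90% empirical trans confirmation rate among pairs that
  could be phased against parental DNA. Pairs confirmed in cis never
  combine.
- **Plain VUS alleles** qualify for probably-solved only under an
  explicit `allow_vus` flag; the default accepts only VUS-FP, the
  conservative reading.
- **Mitochondrial genes** are treated as dominant-like single-allele
  (no heteroplasmy model).
- **X-linked females** need biallelic hits unless `xl_female_single` is
  set.
- When several genes could explain a case, ties break on (status,
  contributing band sum, phenotype concordance, gene symbol).

## CNV read-ratio filter

Candidate CNVs from a read-depth caller carry a read-count ratio
(RR = observed/expected). Deletions: 0.3 <= RR <= 0.7 heterozygous,
RR < 0.1 homozygous/hemizygous; duplications retained only if RR > 1.3.
Deletions in the unclaimed windows [0.1, 0.3) and (0.7, inf) are labelled
*ambiguous* and surfaced for manual plot review rather than dropped —
in practice these are resolved by inspecting the caller's plots. All four
boundaries are configurable. Re-implementing the read-depth likelihood
itself is a non-goal.

## Kinship and deduplication

Pairwise kinship uses the within-family robust estimator
phi = (N_het,het − 2·N_opposite_hom) / (N_het(i) + N_het(j)), which is
exactly 0.5 for self-pairs and needs no allele-frequency estimates.
Degrees are called at the conventional power-of-two midpoints
(first > 0.177, second > 0.0884 = 1/2^(7/2)). Deduplication merges
genetic calls with any self-reported family links into one relatedness
graph and keeps a single uniformly chosen member per connected component
(seeded RNG), which generalises per-pair removal to chains. At the
default 5000 loci with allele frequencies ~ U(0.1, 0.9), the unrelated
phi estimate has a standard deviation of roughly 0.9/sqrt(L) ≈ 0.013, so
the second-degree cutoff sits ~7 sd from the unrelated mode and ~3 sd
below the second-degree mode: false calls in either direction are rare at
cohort scale, which is why nine injected pairs are recovered exactly.

## Statistics

- **Fisher exact, 2x2**: exact integer-arithmetic tail summation over the
  hypergeometric support (all tables with probability <= the observed
  table). **r x c**: seeded Monte-Carlo (default 1e5 tables) sampled from
  the fixed-margins null by sequential multivariate hypergeometric draws;
  the p estimate includes the observed table so it is never 0.
- **Rank-sum**: full permutation enumeration with midranks (exact under
  ties) for combined n <= 12; tie-corrected normal approximation without
  continuity correction otherwise.
- **Logistic regression** of solved status on onset age (and a family
  history indicator) is a binomial GLM fitted by IRLS, converging on a
  parameter-change tolerance of 1e-8 within 50 iterations;
  non-convergence or separation raises an error carrying the deviance
  trace.
- **Odds ratios** are ad/bc with log-scale Wald 95% intervals;
  zero cells get the Haldane–Anscombe 0.5 correction and are flagged.
  Risk ratios (ratios of yield fractions) are kept strictly separate
  from odds ratios. Report percentages round half-up at 1–2 dp, ratios
  at 2 dp.
- No multiple-testing correction is applied anywhere.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions, not tuning knobs:

- ancestry mix 0.802 / 0.093 / 0.079 / 0.026 (Chinese / Indian / Malay /
  other); 53.6% male; family-history prevalence 0.328, with a 25% chance
  of three-plus affected relatives among the positives.
- onset age (years) from 0.4·Gamma(2, 6) + 0.6·Gamma(8, 6) truncated to
  [0, 79]: an early-onset mode near 10 and an adult mode near 45, chosen
  so the truncated mixture's median is ~31; only the range, median and
  a two-mode shape are constrained by the cohort being emulated, so the
  component parameters are config-exposed.
- solved status ~ Bernoulli(expit(alpha + beta·onset + gamma·FH)) with
  beta = −0.026 and gamma = 0.78 (the log-odds gap implied by the 61.3%
  vs 42.1% family-history yields); alpha is solved by quadrature +
  Brent root-finding so the expected yield equals the 0.49 target.
- causal genes are drawn from per-phenotype pools weighted by observed
  cohort counts; recurrent-variant pools cover the founder-effect genes
  (EYS, USH2A, CYP4V2, PRPH2). EYS diagnoses are confined to Chinese
  probands and ABCA4 is up-weighted for Malay/Indian probands, the two
  ancestry effects the cohort data support.
- genotype–phenotype discordance is structural: gene pools follow the
  *presenting* diagnosis while each gene's disease spectrum excludes
  curated discordant entries (e.g. a Zellweger-spectrum PEX6 case
  presenting as Usher syndrome), giving ~8% discordance among solved
  cases. Probably-solved status (share 71/249 of solved) is assigned only
  to concordant cases, since resolution requires concordance for that
  call.
- recessive compound hets are generated in trans, phase observed with
  probability 0.6; phased *cis* pairs are planted in unsolved probands at
  a count derived from `trans_prob = 0.9` so the phased-pair trans
  fraction matches 0.9 in expectation. Cis pairs are always
  phase-observed — an unphased cis pair would be presumed in trans and
  wrongly solve its case.
- genotypes are 5000 biallelic loci in Hardy–Weinberg equilibrium with
  frequencies ~ U(0.1, 0.9); relatives are injected by Mendelian gene
  dropping (one transmitted gamete for first degree; through an
  unobserved intermediate for second degree) and relatives of solved
  probands inherit the causal variants, phenotype and status.

What the generator does **not** emulate: linkage disequilibrium and
population structure (so unrelated-pair kinship is centred at 0, not at
the slightly negative values heterogeneous cohorts show), sequence-level
realism, variant-calling noise, missing genotypes or phenotypes, and
age-dependent misclassification. Passing tests therefore demonstrate the
pipeline's correctness and calibration under its own assumptions, not
performance on real exomes.

## Problem sizes and determinism

Default analyses run at the emulated cohort scale (506 probands, 5000
loci; 515 with nine injected relative pairs for the deduplication
analysis). Parameter-recovery checks use 20 seeded cohorts of n = 5000;
distributional checks use n = 10000. Every stochastic step (generation,
Monte-Carlo tests, dedup tie-breaking) takes an explicit seed and is
bit-reproducible; `scripts/acceptance.py --seed N --out f.json` re-runs
the deduplication analysis from scratch at any seed.

## Known limitations

- The probably-solved rule is one reasonable operationalisation of a
  policy that in practice involves curator judgement.
- The r x c exact test is Monte-Carlo, not the network algorithm; its
  error is O(1/sqrt(reps)) and the seed is recorded.
- Confidence intervals for odds ratios are Wald-type only (method is
  config-exposed at the report layer, but no exact CI is implemented).
- Kinship assumes complete genotypes on the vectorised path; the
  per-pair estimator handles missingness.
- The 410-gene panel is abstracted to the ~65 genes that carry diagnoses
  in the emulated cohort; panel membership is configurable.
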