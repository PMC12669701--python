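"""Seeded synthetic IRD cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes, so every stage is testable without patient data.  The generator
emulates a multi-ethnic Asian exome cohort: an ancestry mix of
80.2 / 9.3 / 7.9 / 2.6% (Chinese / Indian / Malay / other), 32.8%
family-history prevalence, an onset-age distribution spanning 0-79 years
with median ~31 (a two-component gamma mixture of an early-onset and an
adult-onset mode), phenotype-specific causal-gene pools with
recurrent-variant weights (see :mod:`.paneldata`), and a logistic solve
model

    logit P(solved) = alpha + beta * onset_age + gamma * 1[family history]

with beta = -0.026 and gamma = 0.78 by default; alpha is calibrated
numerically so that the expected overall yield matches the configured
target (0.49).

Every proband carries hidden ground truth (true causal gene and variants,
true solved status, true relatedness) alongside the observable tables.
Variants are emitted with ACMG assertion sets that score into the band the
ground-truth status requires, so the classification and resolution stages
can recover the truth exactly when phase is fully observed.

Compound-heterozygous recessive diagnoses are generated in trans; phase is
experimentally observed for a configurable fraction of them.  To reproduce
the empirical ~90% trans confirmation rate among phased pairs, the
generator additionally plants phased *cis* pairs (two pathogenic-looking
alleles on one haplotype, which cannot solve a recessive case) in unsolved
probands, at a count derived from ``trans_prob``.

Relatedness is injected by Mendelian gene-dropping: a first-degree pair
shares one transmitted allele per locus (expected kinship 0.25), a
second-degree pair is simulated through an unobserved intermediate
(expected kinship 0.125).  Relatives of solved probands inherit a copy of
the causal variants, their phenotype and their solved status.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit

from .acmg import Band, EvidenceAssertion, classify_assertions
from .analytics import Ancestry, Cohort, ProbandCase
from .cnv import CnvCall, CnvKind
from .errors import ConfigurationError
from .kinship import Degree
from .paneldata import (
    CYP4V2_PARTNER,
    GENE_SPECTRUM,
    INHERITANCE,
    PANEL_GENES,
    PHENOTYPE_COUNTS,
    PHENOTYPE_POOLS,
    VARIANT_POOLS,
    Inheritance,
    default_gene_models,
)
from .resolution import Status, VariantRecord, Zygosity

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate", "inject_relatives",
           "calibrate_alpha"]

_ANCESTRIES = [Ancestry.CHINESE, Ancestry.INDIAN, Ancestry.MALAY, Ancestry.OTHER]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort, with cohort-realistic defaults."""

    n_probands: int = 506
    seed: int = 2018

    # demographics
    ancestry_probs: tuple[float, float, float, float] = (0.802, 0.093, 0.079, 0.026)
    male_prob: float = 0.536
    family_history_prob: float = 0.328
    fh_three_plus_prob: float = 0.25  # among family-history-positive probands

    # onset-age mixture (years): early-onset and adult-onset gamma modes,
    # truncated to [0, onset_max]; defaults give median ~31
    onset_weights: tuple[float, float] = (0.40, 0.60)
    onset_shapes: tuple[float, float] = (2.0, 8.0)
    onset_scales: tuple[float, float] = (6.0, 6.0)
    onset_max: float = 79.0
    exam_delay_shape: float = 4.0
    exam_delay_scale: float = 5.5

    # solve model
    target_yield: float = 0.49
    beta_onset: float = -0.026
    gamma_family_history: float = 0.78
    vusfp_share: float = 71 / 249  # probably-solved share of solved cases

    # variant structure
    trans_prob: float = 0.9
    phase_obs_prob: float = 0.6
    hom_prob: float = 0.3
    carrier_prob: float = 0.15
    vus_noise_prob: float = 0.2
    abca4_boost: tuple[tuple[str, float], ...] = (("malay", 3.0), ("indian", 2.0))

    # relatedness / genotypes
    n_related_pairs: int = 9
    first_degree_frac: float = 0.5
    genotypes: bool = True
    n_loci: int = 5000
    allele_freq_range: tuple[float, float] = (0.1, 0.9)

    # CNV candidates
    n_cnv_calls: int = 60
    cnv_panel_frac: float = 0.4

    def __post_init__(self):
        if self.n_probands < 1:
            raise ConfigurationError("n_probands must be >= 1")
        for name in ("ancestry_probs", "onset_weights"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be a probability vector")
        for name in ("family_history_prob", "trans_prob", "phase_obs_prob",
                     "hom_prob", "vusfp_share", "target_yield"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_related_pairs * 2 > self.n_probands:
            raise ConfigurationError("n_related_pairs exceeds cohort capacity")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its hidden ground truth."""

    cohort: Cohort
    truth: "pd.DataFrame"
    models: dict
    genotypes: Optional[np.ndarray]
    allele_freqs: Optional[np.ndarray]
    ids: list[str]
    related_pairs: list[tuple[str, str, Degree]]
    cnv_calls: list[CnvCall]
    config: GeneratorConfig
    alpha: float


# ---------------------------------------------------------------------------
# Solve-model calibration

def _onset_pdf(config: GeneratorConfig):
    w = config.onset_weights
    norm = sum(
        wk * stats.gamma.cdf(config.onset_max, a=k, scale=s)
        for wk, k, s in zip(w, config.onset_shapes, config.onset_scales)
    )

    def pdf(a):
        dens = sum(
            wk * stats.gamma.pdf(a, a=k, scale=s)
            for wk, k, s in zip(w, config.onset_shapes, config.onset_scales)
        )
        return dens / norm

    return pdf


def calibrate_alpha(config: GeneratorConfig) -> float:
    """Intercept for which the expected overall yield hits the target.

    Integrates the logistic solve probability over the truncated onset-age
    mixture and the family-history indicator, then solves for alpha by
    bracketing root search.  Deterministic given the config.
    """
    pdf = _onset_pdf(config)
    p_fh = config.family_history_prob

    def expected_yield(alpha):
        def integrand(a, fh):
            return expit(
                alpha + config.beta_onset * a + config.gamma_family_history * fh
            ) * pdf(a)

        y0 = integrate.quad(integrand, 0, config.onset_max, args=(0,), limit=200)[0]
        y1 = integrate.quad(integrand, 0, config.onset_max, args=(1,), limit=200)[0]
        return (1 - p_fh) * y0 + p_fh * y1

    return float(
        optimize.brentq(lambda a: expected_yield(a) - config.target_yield, -8, 8)
    )


# ---------------------------------------------------------------------------
# Variant construction

# ACMG assertion templates per target band; the scores are 10/12/10,
# 7/8/6, 5/5, 3/2 under the default weight table.
_TEMPLATES = {
    Band.PATHOGENIC: [
        [("PVS1", "very_strong"), ("PM2", "moderate")],
        [("PVS1", "very_strong"), ("PS3", "strong")],
        [("PS1", "strong"), ("PS3", "strong"), ("PM2", "moderate")],
    ],
    Band.LIKELY_PATHOGENIC: [
        [("PS1", "strong"), ("PM2", "moderate"), ("PP3", "supporting")],
        [("PS4", "strong"), ("PM2", "moderate"), ("PM5", "moderate")],
        [("PM1", "moderate"), ("PM2", "moderate"),
         ("PP3", "supporting"), ("PP4", "supporting")],
    ],
    Band.VUS_FP: [
        [("PS1", "strong"), ("PP3", "supporting")],
        [("PM1", "moderate"), ("PM2", "moderate"), ("PP3", "supporting")],
    ],
    Band.VUS: [
        [("PM2", "moderate"), ("PP3", "supporting")],
        [("PP3", "supporting"), ("PP4", "supporting")],
    ],
}


def _assertions_for(band: Band, rng) -> tuple[EvidenceAssertion, ...]:
    template = _TEMPLATES[band][rng.integers(len(_TEMPLATES[band]))]
    assertions = tuple(
        EvidenceAssertion(code, "pathogenic", strength) for code, strength in template
    )
    assert classify_assertions(assertions) == band
    return assertions


class _VariantFactory:
    """Draws variant identities per gene, with unique private alleles."""

    def __init__(self, rng):
        self.rng = rng
        self.novel_counter: dict[str, int] = {}

    def _novel(self, gene: str) -> tuple[str, str]:
        k = self.novel_counter.get(gene, 0) + 1
        self.novel_counter[gene] = k
        ref, alt = self.rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        return f"c.{1000 + 7 * k}{ref}>{alt}", ""

    def first_allele(self, gene: str) -> tuple[str, str]:
        pool = VARIANT_POOLS.get(gene)
        if pool is None:
            return self._novel(gene)
        weights = np.array([w for _, _, w in pool], dtype=float)
        idx = self.rng.choice(len(pool), p=weights / weights.sum())
        hgvs_c, hgvs_p, _ = pool[idx]
        if hgvs_c is None:
            return self._novel(gene)
        return hgvs_c, hgvs_p

    def second_allele(self, gene: str, first: str) -> tuple[str, str]:
        if gene == "CYP4V2" and first == VARIANT_POOLS["CYP4V2"][0][0]:
            if self.rng.random() < 0.5:
                return CYP4V2_PARTNER
        hgvs = self._novel(gene)
        while hgvs[0] == first:  # pragma: no cover - counter makes clashes impossible
            hgvs = self._novel(gene)
        return hgvs


def _weighted_gene_pool(phenotype: str, ancestry: Ancestry, sex: str,
                        config: GeneratorConfig):
    """Ancestry- and sex-adjusted causal-gene pool for one proband."""
    pool = PHENOTYPE_POOLS[phenotype]
    boost = dict(config.abca4_boost)
    genes, weights = [], []
    for gene, w in pool:
        if gene == "EYS" and ancestry != Ancestry.CHINESE:
            continue  # EYS diagnoses are confined to Chinese probands
        if INHERITANCE[gene] == Inheritance.X_LINKED and sex == "female":
            continue
        w = float(w)
        if gene == "ABCA4":
            w *= boost.get(ancestry.value, 1.0)
        genes.append(gene)
        weights.append(w)
    if not genes:  # e.g. an all-X-linked pool for a female proband
        genes = [g for g, _ in pool]
        weights = [float(w) for _, w in pool]
    weights = np.asarray(weights)
    return genes, weights / weights.sum()


def _causal_variants(pid, gene, fully, factory, config, rng):
    """Variant records realising a solved diagnosis in *gene*.

    Returns (variants, trans_truth): ``trans_truth`` is True for biallelic
    recessive configurations.
    """
    mode = INHERITANCE[gene]
    plp = lambda: Band.PATHOGENIC if rng.random() < 0.5 else Band.LIKELY_PATHOGENIC

    if mode in (Inheritance.AUTOSOMAL_DOMINANT, Inheritance.MITOCHONDRIAL,
                Inheritance.X_LINKED):
        zyg = (Zygosity.HEMIZYGOUS if mode == Inheritance.X_LINKED
               else Zygosity.HETEROZYGOUS)
        band = plp() if fully else Band.VUS_FP
        hgvs_c, hgvs_p = factory.first_allele(gene)
        return [VariantRecord(gene, hgvs_c, hgvs_p, zyg, band, None,
                              _assertions_for(band, rng))], False

    # autosomal recessive
    if rng.random() < config.hom_prob:
        band = plp() if fully else Band.VUS_FP
        hgvs_c, hgvs_p = factory.first_allele(gene)
        return [VariantRecord(gene, hgvs_c, hgvs_p, Zygosity.HOMOZYGOUS, band,
                              None, _assertions_for(band, rng))], True
    phased = rng.random() < config.phase_obs_prob
    groups = (f"{pid}:M", f"{pid}:P") if phased else (None, None)
    band1 = plp()
    band2 = plp() if fully else Band.VUS_FP
    c1, p1 = factory.first_allele(gene)
    c2, p2 = factory.second_allele(gene, c1)
    return [
        VariantRecord(gene, c1, p1, Zygosity.HETEROZYGOUS, band1, groups[0],
                      _assertions_for(band1, rng)),
        VariantRecord(gene, c2, p2, Zygosity.HETEROZYGOUS, band2, groups[1],
                      _assertions_for(band2, rng)),
    ], True


def _noise_variants(phenotype, factory, config, rng):
    """Non-diagnostic variants for unsolved probands: recessive carrier
    alleles and VUS-band findings."""
    out = []
    ar_genes = [g for g, _ in PHENOTYPE_POOLS[phenotype]
                if INHERITANCE[g] == Inheritance.AUTOSOMAL_RECESSIVE]
    if ar_genes and rng.random() < config.carrier_prob:
        gene = ar_genes[rng.integers(len(ar_genes))]
        band = Band.PATHOGENIC if rng.random() < 0.5 else Band.LIKELY_PATHOGENIC
        hgvs_c, hgvs_p = factory.first_allele(gene)
        out.append(VariantRecord(gene, hgvs_c, hgvs_p, Zygosity.HETEROZYGOUS,
                                 band, None, _assertions_for(band, rng)))
    if rng.random() < config.vus_noise_prob:
        pool = PHENOTYPE_POOLS[phenotype]
        gene = pool[rng.integers(len(pool))][0]
        hgvs_c, hgvs_p = factory.first_allele(gene)
        out.append(VariantRecord(gene, hgvs_c, hgvs_p, Zygosity.HETEROZYGOUS,
                                 Band.VUS, None,
                                 _assertions_for(Band.VUS, rng)))
    return out


# ---------------------------------------------------------------------------
# Genotype simulation

def _population_genotypes(rng, n, freqs):
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(np.int8)


def _transmit(rng, genotype, freqs):
    """One gamete from *genotype* plus one population allele."""
    gamete = np.where(
        genotype == 1, rng.integers(0, 2, size=genotype.shape), genotype // 2
    )
    return (gamete + rng.binomial(1, freqs)).astype(np.int8)


def _related_genotype(rng, anchor, freqs, degree: Degree):
    if degree == Degree.FIRST:  # parent-offspring
        return _transmit(rng, anchor, freqs)
    parent = _transmit(rng, anchor, freqs)  # unobserved intermediate
    return _transmit(rng, parent, freqs)


# ---------------------------------------------------------------------------
# Main generator

def _draw_onset(rng, config: GeneratorConfig) -> float:
    while True:
        comp = rng.choice(len(config.onset_weights), p=config.onset_weights)
        a = rng.gamma(config.onset_shapes[comp], config.onset_scales[comp])
        if a <= config.onset_max:
            return float(np.floor(a))


def generate(config: GeneratorConfig | None = None, seed: int | None = None
             ) -> SyntheticCohort:
    """Generate a seeded synthetic cohort with ground truth.

    ``seed`` overrides ``config.seed`` when given.  Deterministic for a
    fixed config and seed.
    """
    import pandas as pd

    config = config or GeneratorConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    alpha = calibrate_alpha(config)
    factory = _VariantFactory(rng)

    phenotypes = list(PHENOTYPE_COUNTS)
    ph_weights = np.array([t for _, t in PHENOTYPE_COUNTS.values()], dtype=float)
    ph_weights /= ph_weights.sum()

    cases: list[ProbandCase] = []
    truth_rows: list[dict] = []
    for i in range(config.n_probands):
        pid = f"P{i:05d}"
        ancestry = _ANCESTRIES[rng.choice(4, p=np.asarray(config.ancestry_probs))]
        sex = "male" if rng.random() < config.male_prob else "female"
        onset = _draw_onset(rng, config)
        exam = onset + rng.gamma(config.exam_delay_shape, config.exam_delay_scale)
        exam = float(np.floor(min(exam, 95.0)))
        has_fh = rng.random() < config.family_history_prob
        if not has_fh:
            relatives = 0
        elif rng.random() < config.fh_three_plus_prob:
            relatives = 3 + int(rng.poisson(0.7))
        else:
            relatives = int(rng.integers(1, 3))
        phenotype = phenotypes[rng.choice(len(phenotypes), p=ph_weights)]

        p_solved = float(expit(alpha + config.beta_onset * onset
                               + config.gamma_family_history * (relatives > 0)))
        solved = rng.random() < p_solved

        variants: list[VariantRecord] = []
        true_status = Status.UNSOLVED
        true_gene = None
        trans_truth = False
        if solved:
            genes, weights = _weighted_gene_pool(phenotype, ancestry, sex, config)
            gene = genes[rng.choice(len(genes), p=weights)]
            if INHERITANCE[gene] == Inheritance.X_LINKED:
                sex = "male"  # X-linked pools are male-only after filtering
            concordant = phenotype in GENE_SPECTRUM.get(gene, set())
            probably = concordant and rng.random() < config.vusfp_share
            true_status = Status.PROBABLY_SOLVED if probably else Status.FULLY_SOLVED
            true_gene = gene
            variants, trans_truth = _causal_variants(
                pid, gene, fully=not probably, factory=factory,
                config=config, rng=rng,
            )
        else:
            variants = _noise_variants(phenotype, factory, config, rng)

        cases.append(ProbandCase(
            proband_id=pid, ancestry=ancestry, sex=sex, age_at_exam=exam,
            age_of_onset=onset, affected_relatives=relatives,
            phenotype=phenotype, variants=variants, status=None,
        ))
        truth_rows.append({
            "proband_id": pid, "true_status": true_status.value,
            "true_gene": true_gene, "in_trans": trans_truth,
            "cis_pair": False, "relative_of": None, "degree": None,
            "p_solved": p_solved,
        })

    _plant_cis_pairs(cases, truth_rows, factory, config, rng)

    genotypes = allele_freqs = None
    if config.genotypes:
        lo, hi = config.allele_freq_range
        allele_freqs = rng.uniform(lo, hi, size=config.n_loci)
        genotypes = _population_genotypes(rng, config.n_probands, allele_freqs)

    cohort = SyntheticCohort(
        cohort=Cohort(cases),
        truth=pd.DataFrame(truth_rows),
        models=default_gene_models(),
        genotypes=genotypes,
        allele_freqs=allele_freqs,
        ids=[c.proband_id for c in cases],
        related_pairs=[],
        cnv_calls=_simulate_cnv_calls(cases, config, rng),
        config=config,
        alpha=alpha,
    )
    if config.n_related_pairs:
        inject_relatives(cohort, config.n_related_pairs,
                         config.first_degree_frac, rng)
    return cohort


def _plant_cis_pairs(cases, truth_rows, factory, config, rng):
    """Plant phased cis het pairs in unsolved probands.

    The number is chosen so that, among all phased biallelic pairs in the
    cohort, the in-trans fraction matches ``trans_prob`` in expectation.
    """
    n_trans_phased = sum(
        1 for case, row in zip(cases, truth_rows)
        if row["true_status"] != Status.UNSOLVED.value
        and sum(v.phase_group is not None for v in case.variants) >= 2
    )
    if config.trans_prob <= 0 or config.trans_prob >= 1:
        n_cis = 0
    else:
        n_cis = int(round(n_trans_phased * (1 - config.trans_prob)
                          / config.trans_prob))
    # Restrict to probands without qualifying alleles already: an unphased
    # carrier allele next to a planted cis pair would be read as a
    # presumed-trans biallelic hit and wrongly solve the case.
    qualifying = (Band.PATHOGENIC, Band.LIKELY_PATHOGENIC, Band.VUS_FP)
    unsolved_idx = [i for i, row in enumerate(truth_rows)
                    if row["true_status"] == Status.UNSOLVED.value
                    and not any(v.band in qualifying for v in cases[i].variants)]
    rng.shuffle(unsolved_idx)
    for i in unsolved_idx[:n_cis]:
        case = cases[i]
        ar_genes = [g for g, _ in PHENOTYPE_POOLS[case.phenotype]
                    if INHERITANCE[g] == Inheritance.AUTOSOMAL_RECESSIVE]
        if not ar_genes:
            continue
        gene = ar_genes[rng.integers(len(ar_genes))]
        group = f"{case.proband_id}:M"
        for _ in range(2):
            band = (Band.PATHOGENIC if rng.random() < 0.5
                    else Band.LIKELY_PATHOGENIC)
            hgvs_c, hgvs_p = factory.first_allele(gene)
            if any(v.hgvs_c == hgvs_c and v.gene == gene for v in case.variants):
                hgvs_c, hgvs_p = factory.second_allele(gene, hgvs_c)
            case.variants.append(VariantRecord(
                gene, hgvs_c, hgvs_p, Zygosity.HETEROZYGOUS, band, group,
                _assertions_for(band, rng)))
        truth_rows[i]["cis_pair"] = True


def inject_relatives(cohort: SyntheticCohort, n_pairs: int,
                     first_degree_frac: float = 0.5,
                     seed_or_rng=None) -> SyntheticCohort:
    """Inject first/second-degree relative pairs into a generated cohort.

    Disjoint pairs of probands are chosen at random; the second member of
    each pair has its genotypes re-simulated by Mendelian drop from the
    first and, when the first is solved, inherits a copy of the causal
    variants, the phenotype and the solved status.  Mutates and returns
    *cohort*; records the injected pairs in ``related_pairs`` and the
    truth table.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    cases = cohort.cohort.cases
    if 2 * n_pairs > len(cases):
        raise ConfigurationError("n_pairs exceeds half the cohort size")
    chosen = rng.choice(len(cases), size=2 * n_pairs, replace=False)
    truth = cohort.truth
    for k in range(n_pairs):
        ia, ib = int(chosen[2 * k]), int(chosen[2 * k + 1])
        a, b = cases[ia], cases[ib]
        degree = Degree.FIRST if rng.random() < first_degree_frac else Degree.SECOND
        if cohort.genotypes is not None:
            cohort.genotypes[ib] = _related_genotype(
                rng, cohort.genotypes[ia], cohort.allele_freqs, degree)
        if truth.loc[ia, "true_status"] != Status.UNSOLVED.value:
            b.phenotype = a.phenotype
            b.variants = [
                dataclasses.replace(
                    v,
                    phase_group=(v.phase_group.replace(a.proband_id, b.proband_id)
                                 if v.phase_group else None),
                )
                for v in a.variants
            ]
            for col in ("true_status", "true_gene", "in_trans", "cis_pair"):
                truth.loc[ib, col] = truth.loc[ia, col]
        truth.loc[ib, "relative_of"] = a.proband_id
        truth.loc[ib, "degree"] = degree.value
        cohort.related_pairs.append((a.proband_id, b.proband_id, degree))
    return cohort


def _simulate_cnv_calls(cases, config: GeneratorConfig, rng) -> list[CnvCall]:
    """Candidate CNV calls with read ratios spanning every dosage window."""
    if config.n_cnv_calls <= 0:
        return []
    panel = sorted(PANEL_GENES)
    calls = []
    for k in range(config.n_cnv_calls):
        case = cases[rng.integers(len(cases))]
        on_panel = rng.random() < config.cnv_panel_frac
        gene = (panel[rng.integers(len(panel))] if on_panel
                else f"OFFPANEL{rng.integers(1, 200)}")
        chrom = f"chr{rng.integers(1, 23)}"
        start = int(rng.integers(1, 2_000_000))
        end = start + int(rng.integers(1_000, 200_000))
        flavour = rng.random()
        if flavour < 0.35:
            kind, rr = CnvKind.DELETION, rng.normal(0.5, 0.08)
        elif flavour < 0.45:
            kind, rr = CnvKind.DELETION, abs(rng.normal(0.04, 0.02))
        elif flavour < 0.60:
            kind, rr = CnvKind.DELETION, rng.uniform(0.72, 1.0)
        elif flavour < 0.80:
            kind, rr = CnvKind.DUPLICATION, rng.normal(1.6, 0.15)
        else:
            kind, rr = CnvKind.DUPLICATION, rng.uniform(1.05, 1.3)
        calls.append(CnvCall(case.proband_id, chrom, start, end, kind,
                             max(float(rr), 0.0), frozenset({gene})))
    return calls
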