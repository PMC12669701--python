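"""Synthetic cohort generator: determinism, distributions, ground truth."""

import numpy as np
import pytest
import scipy.stats

from irdyield.errors import ConfigurationError
from irdyield.kinship import king_robust
from irdyield.paneldata import GENE_SPECTRUM, PHENOTYPE_POOLS
from irdyield.resolution import resolve_case
from irdyield.simulate import GeneratorConfig, calibrate_alpha, generate


def _light(n, seed, **overrides):
    params = dict(n_probands=n, seed=seed, genotypes=False,
                  n_related_pairs=0, n_cnv_calls=0)
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="module")
def big_cohort():
    return generate(_light(10_000, seed=101))


def test_determinism_for_fixed_seed():
    a = generate(_light(40, seed=5))
    b = generate(_light(40, seed=5))
    assert [c.proband_id for c in a.cohort.cases] \
        == [c.proband_id for c in b.cohort.cases]
    for ca, cb in zip(a.cohort.cases, b.cohort.cases):
        assert ca.variants == cb.variants
        assert (ca.ancestry, ca.sex, ca.age_of_onset, ca.phenotype) \
            == (cb.ancestry, cb.sex, cb.age_of_onset, cb.phenotype)
    assert a.truth.equals(b.truth)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(n_probands=0)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(ancestry_probs=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ConfigurationError):
        GeneratorConfig(trans_prob=1.5)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(n_probands=10, n_related_pairs=6)


def test_ancestry_mix_within_3_se(big_cohort):
    n = len(big_cohort.cohort.cases)
    frac = np.mean([c.ancestry.value == "chinese" for c in big_cohort.cohort.cases])
    se = np.sqrt(0.802 * 0.198 / n)
    assert abs(frac - 0.802) <= 3 * se


def test_family_history_prevalence_within_3_se(big_cohort):
    n = len(big_cohort.cohort.cases)
    frac = np.mean([c.affected_relatives > 0 for c in big_cohort.cohort.cases])
    se = np.sqrt(0.328 * 0.672 / n)
    assert abs(frac - 0.328) <= 3 * se


def test_onset_age_range_and_median(big_cohort):
    onsets = np.array([c.age_of_onset for c in big_cohort.cohort.cases])
    assert onsets.min() >= 0 and onsets.max() <= 79
    assert 29 <= np.median(onsets) <= 33


def test_overall_yield_near_calibrated_target(big_cohort):
    yld = (big_cohort.truth.true_status != "unsolved").mean()
    se = np.sqrt(0.49 * 0.51 / len(big_cohort.truth))
    assert abs(yld - 0.49) <= 3 * se


def test_yield_declines_with_onset_age(big_cohort):
    """Negative logistic slope: youngest onset bin out-yields the oldest."""
    truth_solved = dict(zip(big_cohort.truth.proband_id,
                            big_cohort.truth.true_status != "unsolved"))
    young = [truth_solved[c.proband_id] for c in big_cohort.cohort.cases
             if c.age_of_onset < 20]
    old = [truth_solved[c.proband_id] for c in big_cohort.cohort.cases
           if c.age_of_onset > 60]
    assert np.mean(young) > np.mean(old)


def test_gene_pools_match_configuration(big_cohort):
    """Chi-square goodness of fit of generated causal genes against the
    configured retinitis pigmentosa pool (Chinese probands, where no
    ancestry reweighting applies)."""
    truth = big_cohort.truth
    cases = {c.proband_id: c for c in big_cohort.cohort.cases}
    observed = {}
    for row in truth.itertuples(index=False):
        case = cases[row.proband_id]
        if (row.true_gene and case.phenotype == "retinitis_pigmentosa"
                and case.ancestry.value == "chinese"):
            observed[row.true_gene] = observed.get(row.true_gene, 0) + 1
    pool = dict(PHENOTYPE_POOLS["retinitis_pigmentosa"])
    # exclude X-linked genes (male-only) where sex filtering skews weights
    from irdyield.paneldata import INHERITANCE, Inheritance

    genes = [g for g in pool if INHERITANCE[g] != Inheritance.X_LINKED]
    counts = np.array([observed.get(g, 0) for g in genes], dtype=float)
    weights = np.array([pool[g] for g in genes], dtype=float)
    expected = weights / weights.sum() * counts.sum()
    chi2 = ((counts - expected) ** 2 / expected).sum()
    p = scipy.stats.chi2.sf(chi2, df=len(genes) - 1)
    assert p > 0.01


def test_eys_confined_to_chinese(big_cohort):
    cases = {c.proband_id: c for c in big_cohort.cohort.cases}
    for row in big_cohort.truth.itertuples(index=False):
        if row.true_gene == "EYS":
            assert cases[row.proband_id].ancestry.value == "chinese"


def test_ground_truth_recovered_with_full_phase():
    """acmg -> resolution on generated data reproduces the hidden status
    for >= 99% of cases when phase is fully observed."""
    syn = generate(_light(1500, seed=17, phase_obs_prob=1.0))
    match = sum(
        resolve_case(c.variants, syn.models, c.phenotype).status.value
        == row.true_status
        for c, row in zip(syn.cohort.cases, syn.truth.itertuples(index=False))
    )
    assert match / 1500 >= 0.99


def test_probably_solved_share_of_solved():
    syn = generate(_light(5000, seed=23))
    truth = syn.truth
    solved = truth[truth.true_status != "unsolved"]
    share = (solved.true_status == "probably_solved").mean()
    assert share == pytest.approx(71 / 249, abs=0.05)


def test_discordant_cases_generated(gene_models):
    syn = generate(_light(5000, seed=29))
    cases = {c.proband_id: c for c in syn.cohort.cases}
    discordant = sum(
        1 for row in syn.truth.itertuples(index=False)
        if row.true_gene
        and cases[row.proband_id].phenotype
        not in GENE_SPECTRUM.get(row.true_gene, set())
    )
    solved = (syn.truth.true_status != "unsolved").sum()
    assert 0.03 < discordant / solved < 0.15  # ~8% discordance by design


def test_injected_first_degree_pairs_have_quarter_kinship():
    cfg = GeneratorConfig(n_probands=60, seed=31, n_related_pairs=10,
                          first_degree_frac=1.0, n_loci=5000, n_cnv_calls=0)
    syn = generate(cfg)
    assert len(syn.related_pairs) == 10
    idx = {pid: i for i, pid in enumerate(syn.ids)}
    phis = [king_robust(syn.genotypes[idx[a]], syn.genotypes[idx[b]])
            for a, b, _ in syn.related_pairs]
    assert np.mean(phis) == pytest.approx(0.25, abs=0.02)


def test_relatives_of_solved_probands_share_causal_variants():
    cfg = GeneratorConfig(n_probands=200, seed=37, n_related_pairs=30,
                          genotypes=False, n_cnv_calls=0)
    syn = generate(cfg)
    cases = {c.proband_id: c for c in syn.cohort.cases}
    truth = syn.truth.set_index("proband_id")
    checked = 0
    for a, b, _ in syn.related_pairs:
        if truth.loc[a, "true_status"] != "unsolved":
            va = {(v.gene, v.hgvs_c) for v in cases[a].variants}
            vb = {(v.gene, v.hgvs_c) for v in cases[b].variants}
            assert va == vb
            checked += 1
    assert checked > 0


def test_cnv_calls_cover_every_dosage_window():
    from irdyield.cnv import CnvClass, classify_cnv, filter_to_panel
    from irdyield.paneldata import PANEL_GENES

    syn = generate(GeneratorConfig(n_probands=50, seed=41, genotypes=False,
                                   n_related_pairs=0, n_cnv_calls=200))
    classes = {classify_cnv(c) for c in syn.cnv_calls}
    assert CnvClass.HET_DELETION in classes
    assert CnvClass.RETAINED_DUPLICATION in classes
    assert CnvClass.REJECTED in classes
    on_panel = filter_to_panel(syn.cnv_calls, PANEL_GENES)
    assert 0 < len(on_panel) < len(syn.cnv_calls)


def test_calibrated_alpha_is_deterministic():
    cfg = GeneratorConfig()
    assert calibrate_alpha(cfg) == calibrate_alpha(cfg)
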