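"""Solved-status assignment from variant bands, zygosity and phase."""

import pytest

from irdyield.acmg import Band
from irdyield.errors import ConfigurationError, UndefinedResultError
from irdyield.resolution import (
    ResolutionConfig,
    Status,
    VariantRecord,
    resolve_case,
    trans_rate,
)


def V(gene, hgvs="c.1A>G", zyg="heterozygous", band=Band.PATHOGENIC, phase=None):
    return VariantRecord(gene, hgvs, "", zyg, band, phase)


def test_recessive_biallelic_plp_in_trans_is_fully_solved(gene_models):
    status = resolve_case(
        [V("EYS", "c.6416G>A", band=Band.LIKELY_PATHOGENIC, phase="h1"),
         V("EYS", "c.8107G>T", band=Band.LIKELY_PATHOGENIC, phase="h2")],
        gene_models, "retinitis_pigmentosa")
    assert status.status == Status.FULLY_SOLVED
    assert status.causal_gene == "EYS"
    assert status.trans_confirmed


def test_recessive_plp_plus_vusfp_concordant_is_probably_solved(gene_models):
    status = resolve_case(
        [V("USH2A", "c.2802T>G", band=Band.PATHOGENIC),
         V("USH2A", "c.100A>T", band=Band.VUS_FP)],
        gene_models, "retinitis_pigmentosa")
    assert status.status == Status.PROBABLY_SOLVED
    assert status.causal_gene == "USH2A"


def test_recessive_vusfp_discordant_phenotype_stays_unsolved(gene_models):
    status = resolve_case(
        [V("USH2A", "c.2802T>G", band=Band.PATHOGENIC),
         V("USH2A", "c.100A>T", band=Band.VUS_FP)],
        gene_models, "achromatopsia")
    assert status.status == Status.UNSOLVED


def test_recessive_single_het_is_unsolved(gene_models):
    status = resolve_case([V("EYS", band=Band.PATHOGENIC)],
                          gene_models, "retinitis_pigmentosa")
    assert status.status == Status.UNSOLVED
    assert status.causal_gene is None


def test_recessive_homozygote_is_fully_solved(gene_models):
    status = resolve_case([V("CYP4V2", zyg="homozygous", band=Band.PATHOGENIC)],
                          gene_models, "bietti_crystalline_dystrophy")
    assert status.status == Status.FULLY_SOLVED
    assert status.trans_confirmed


def test_confirmed_cis_pair_is_unsolved(gene_models):
    status = resolve_case(
        [V("EYS", "c.1A>G", band=Band.PATHOGENIC, phase="h1"),
         V("EYS", "c.2A>G", band=Band.PATHOGENIC, phase="h1")],
        gene_models, "retinitis_pigmentosa")
    assert status.status == Status.UNSOLVED


def test_unphased_pair_assumed_trans_but_not_confirmed(gene_models):
    variants = [V("EYS", "c.1A>G", band=Band.PATHOGENIC),
                V("EYS", "c.2A>G", band=Band.PATHOGENIC)]
    status = resolve_case(variants, gene_models, "retinitis_pigmentosa")
    assert status.status == Status.FULLY_SOLVED
    assert not status.trans_confirmed
    strict = resolve_case(variants, gene_models, "retinitis_pigmentosa",
                          ResolutionConfig(assume_trans=False))
    assert strict.status == Status.UNSOLVED


def test_dominant_single_lp_het_is_fully_solved(gene_models):
    status = resolve_case([V("RHO", band=Band.LIKELY_PATHOGENIC)],
                          gene_models, "retinitis_pigmentosa")
    assert status.status == Status.FULLY_SOLVED
    assert status.causal_gene == "RHO"


def test_xlinked_hemizygous_male_is_fully_solved(gene_models):
    status = resolve_case([V("RPGR", zyg="hemizygous", band=Band.PATHOGENIC)],
                          gene_models, "retinitis_pigmentosa")
    assert status.status == Status.FULLY_SOLVED


def test_xlinked_female_single_het_needs_config_override(gene_models):
    variants = [V("RPGR", band=Band.PATHOGENIC)]
    assert resolve_case(variants, gene_models,
                        "retinitis_pigmentosa").status == Status.UNSOLVED
    permissive = ResolutionConfig(xl_female_single=True)
    assert resolve_case(variants, gene_models, "retinitis_pigmentosa",
                        permissive).status == Status.FULLY_SOLVED


def test_plain_vus_pair_needs_allow_vus(gene_models):
    variants = [V("EYS", "c.1A>G", band=Band.VUS),
                V("EYS", "c.2A>G", band=Band.VUS)]
    assert resolve_case(variants, gene_models,
                        "retinitis_pigmentosa").status == Status.UNSOLVED
    lax = ResolutionConfig(allow_vus=True)
    assert resolve_case(variants, gene_models, "retinitis_pigmentosa",
                        lax).status == Status.PROBABLY_SOLVED


def test_no_variants_is_always_unsolved(gene_models):
    assert resolve_case([], gene_models, "retinitis_pigmentosa").status \
        == Status.UNSOLVED


def test_unknown_gene_raises_configuration_error(gene_models):
    with pytest.raises(ConfigurationError, match="NOTAGENE"):
        resolve_case([V("NOTAGENE")], gene_models, "retinitis_pigmentosa")


def test_band_upgrade_never_downgrades_status(gene_models):
    """Upgrading a contributing allele VUS -> VUS-FP -> LP -> P is monotone."""
    rank = {Status.UNSOLVED: 0, Status.PROBABLY_SOLVED: 1, Status.FULLY_SOLVED: 2}
    ladder = [Band.VUS, Band.VUS_FP, Band.LIKELY_PATHOGENIC, Band.PATHOGENIC]
    previous = -1
    for band in ladder:
        status = resolve_case(
            [V("USH2A", "c.1A>G", band=Band.PATHOGENIC),
             V("USH2A", "c.2A>G", band=band)],
            gene_models, "retinitis_pigmentosa")
        assert rank[status.status] >= previous
        previous = rank[status.status]


def test_gene_tiebreak_prefers_stronger_then_lexicographic(gene_models):
    # two dominant genes, both fully solvable: higher band sum wins
    status = resolve_case(
        [V("RHO", band=Band.LIKELY_PATHOGENIC),
         V("CRX", band=Band.PATHOGENIC)],
        gene_models, "retinitis_pigmentosa")
    assert status.causal_gene == "CRX"
    # equal band sums: lexicographically smaller gene wins
    status = resolve_case(
        [V("RHO", band=Band.PATHOGENIC), V("CRX", band=Band.PATHOGENIC)],
        gene_models, "retinitis_pigmentosa")
    assert status.causal_gene == "CRX"


def test_trans_rate_counts_phased_pairs(gene_models):
    cases = []
    for i in range(9):  # nine pairs in trans
        cases.append([V("EYS", "c.1A>G", band=Band.PATHOGENIC, phase=f"{i}a"),
                      V("EYS", "c.2A>G", band=Band.PATHOGENIC, phase=f"{i}b")])
    cases.append([V("EYS", "c.1A>G", band=Band.PATHOGENIC, phase="cis"),
                  V("EYS", "c.2A>G", band=Band.PATHOGENIC, phase="cis")])
    assert trans_rate(cases, gene_models) == pytest.approx(0.9)
    assert trans_rate(cases[:9], gene_models) == 1.0


def test_trans_rate_undefined_without_phase(gene_models):
    with pytest.raises(UndefinedResultError):
        trans_rate([[V("EYS", band=Band.PATHOGENIC)]], gene_models)
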