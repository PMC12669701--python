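"""Yield statistics: exact tests, logistic fit, ratios and tables."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from conftest import make_case, solved_case, unsolved_case
from irdyield.acmg import Band
from irdyield.analytics import (
    age_bin,
    concordance,
    family_history_stratum,
    fisher_exact,
    gene_frequency,
    logistic_fit,
    odds_ratio,
    overall_yield,
    rank_sum,
    risk_ratio,
    round_half_up,
    variant_frequency,
    yield_by_stratum,
)
from irdyield.errors import FitError, UndefinedResultError
from irdyield.resolution import VariantRecord


# ---------------------------------------------------------------------------
# yields

def _mixed_cohort(n_fully, n_probably, n_unsolved, **kwargs):
    cases = [solved_case(f"F{i}", "RHO", "retinitis_pigmentosa", fully=True,
                         **kwargs) for i in range(n_fully)]
    cases += [solved_case(f"Q{i}", "RHO", "retinitis_pigmentosa", fully=False,
                          **kwargs) for i in range(n_probably)]
    cases += [unsolved_case(f"U{i}", **kwargs) for i in range(n_unsolved)]
    return cases


def test_overall_yield_counts_fully_and_probably():
    fully, probably, total, yld = overall_yield(_mixed_cohort(3, 2, 5))
    assert (fully, probably, total) == (3, 2, 10)
    assert yld == pytest.approx(0.5)
    assert overall_yield(_mixed_cohort(0, 0, 4))[3] == 0.0


def test_stratum_yields_sum_to_overall():
    cases = _mixed_cohort(6, 2, 8)
    for i, c in enumerate(cases):
        c.age_of_onset = (i * 7) % 80
    table = yield_by_stratum(cases, age_bin)
    assert table["total"].sum() == len(cases)
    assert table["solved"].sum() == 8
    single = yield_by_stratum(cases, lambda c: "all")
    assert single.loc[0, "yield"] == overall_yield(cases)[3]


def test_family_history_strata():
    labels = [family_history_stratum(make_case(relatives=n))
              for n in (0, 1, 2, 3, 7)]
    assert labels == ["0", "1-2", "1-2", "3+", "3+"]


# ---------------------------------------------------------------------------
# Fisher exact

def _fisher_enumeration_oracle(table):
    """Exact two-sided p by rational enumeration over the 2x2 support."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = math.comb(n, c1)
    probs = {x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
             for x in range(max(0, c1 - r2), min(r1, c1) + 1)}
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize("table, expected", [
    ([[2, 0], [0, 2]], 1 / 3),
    ([[5, 5], [5, 5]], 1.0),
])
def test_fisher_2x2_known_values(table, expected):
    assert fisher_exact(table) == pytest.approx(expected, abs=1e-12)


def test_fisher_2x2_matches_enumeration_and_scipy():
    rng = np.random.default_rng(0)
    for _ in range(60):
        table = rng.integers(0, 9, size=(2, 2))
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            continue
        p = fisher_exact(table)
        assert p == pytest.approx(_fisher_enumeration_oracle(table.tolist()),
                                  abs=1e-12)
        assert p == pytest.approx(scipy.stats.fisher_exact(table).pvalue,
                                  abs=1e-9)


def test_fisher_zero_margin_raises():
    with pytest.raises(UndefinedResultError):
        fisher_exact([[0, 0], [1, 2]])


def test_fisher_rxc_monte_carlo_matches_exact_oracle():
    """Seeded MC p for a 3x2 table vs the exact network-algorithm value
    (0.2628548, independently computed with R's fisher.test)."""
    p = fisher_exact([[3, 1], [4, 2], [2, 5]], mc_reps=200_000, seed=5)
    assert p == pytest.approx(0.2628548, abs=0.01)
    # deterministic for a fixed seed
    assert p == fisher_exact([[3, 1], [4, 2], [2, 5]], mc_reps=200_000, seed=5)


# ---------------------------------------------------------------------------
# rank-sum

def _ranksum_permutation_oracle(x, y):
    """Two-sided p by brute-force enumeration in integer arithmetic
    (midranks doubled so ties stay exact)."""
    pooled = list(x) + list(y)
    ranks2 = [int(round(2 * r)) for r in scipy.stats.rankdata(pooled)]
    nx, n = len(x), len(pooled)
    mu2 = nx * (n + 1)  # twice the null mean rank sum
    dev = abs(sum(ranks2[:nx]) - mu2)
    hits = total = 0
    for combo in itertools.combinations(range(n), nx):
        total += 1
        if abs(sum(ranks2[i] for i in combo) - mu2) >= dev:
            hits += 1
    return hits / total


@pytest.mark.parametrize("x, y, expected", [
    ([1, 2], [3, 4], 1 / 3),
    ([1, 2, 3], [1, 2, 3], 1.0),
])
def test_ranksum_known_values(x, y, expected):
    _, p = rank_sum(x, y)
    assert p == pytest.approx(expected, abs=1e-12)


def test_ranksum_exact_matches_permutation_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 7))
        x = rng.integers(0, 6, nx).tolist()  # integer values force ties
        y = rng.integers(0, 6, ny).tolist()
        _, p = rank_sum(x, y)
        assert p == pytest.approx(_ranksum_permutation_oracle(x, y), abs=1e-12)


def test_ranksum_large_sample_uses_tie_corrected_normal():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.8, 1, 35)
    _, p = rank_sum(x, y)
    ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic",
                                   use_continuity=False).pvalue
    assert p == pytest.approx(ref, rel=1e-9)
    assert p < 0.01


# ---------------------------------------------------------------------------
# logistic regression

def _grid_loglik(y, x, b0, b1):
    eta = b0 + b1 * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def test_logistic_fit_matches_grid_search_oracle():
    """Single-covariate ML fit vs brute-force grid maximisation at n=30."""
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 60, 30)
    y = (rng.random(30) < 1 / (1 + np.exp(-(1.0 - 0.04 * x)))).astype(int)
    fit = logistic_fit(y, x)
    b0s = np.linspace(fit.params["const"] - 1, fit.params["const"] + 1, 81)
    b1s = np.linspace(fit.params["age"] - 0.05, fit.params["age"] + 0.05, 81)
    grid_best = max(_grid_loglik(y, x, b0, b1) for b0 in b0s for b1 in b1s)
    assert fit.llf >= grid_best - 1e-6
    assert fit.converged


def test_logistic_null_covariate_slope_near_zero():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 80, 4000)
    y = (rng.random(4000) < 0.5).astype(int)
    fit = logistic_fit(y, x)
    assert abs(fit.params["age"]) < 3 * fit.bse["age"]


def test_logistic_degenerate_inputs_raise():
    with pytest.raises(FitError):
        logistic_fit([1, 1, 1], [1.0, 2.0, 3.0])
    with pytest.raises(FitError):  # perfect separation
        x = np.arange(20, dtype=float)
        y = (x > 9.5).astype(int)
        logistic_fit(y, x)


# ---------------------------------------------------------------------------
# ratios

def test_odds_ratio_arithmetic_and_ci():
    result = odds_ratio([[20, 5], [5, 20]])
    assert result.value == pytest.approx(16.0)
    assert result.ci_low < 16 < result.ci_high
    assert odds_ratio([[10, 10], [10, 10]]).value == pytest.approx(1.0)


def test_odds_ratio_transpose_invariant():
    rng = np.random.default_rng(2)
    for _ in range(20):
        t = rng.integers(1, 30, (2, 2))
        assert odds_ratio(t).value == pytest.approx(odds_ratio(t.T).value)


def test_odds_ratio_zero_cell_correction_flagged():
    result = odds_ratio([[5, 0], [3, 4]])
    assert result.corrected
    assert math.isfinite(result.value)


def test_risk_ratio_rounding():
    assert risk_ratio(0.613, 0.421) == 1.46
    assert risk_ratio(0.5, 0.5) == 1.00
    assert risk_ratio(0.759, 0.421) == 1.80
    with pytest.raises(ValueError):
        risk_ratio(0.5, 0.0)


def test_round_half_up():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(48.828125, 1) == 48.8


# ---------------------------------------------------------------------------
# frequency tables and concordance

def test_gene_frequency_fractions_and_ordering():
    cases = (
        [solved_case(f"A{i}", "USH2A", "retinitis_pigmentosa") for i in range(3)]
        + [solved_case(f"B{i}", "EYS", "retinitis_pigmentosa") for i in range(3)]
        + [solved_case("C0", "RHO", "retinitis_pigmentosa")]
        + [unsolved_case("U0")]
    )
    table = gene_frequency(cases)
    assert table["fraction"].sum() == pytest.approx(1.0)
    assert list(table["gene"]) == ["EYS", "USH2A", "RHO"]  # tie -> lexicographic
    assert table.loc[0, "fraction"] == pytest.approx(3 / 7)


def test_variant_frequency_counts_probands_once():
    hom = VariantRecord("CYP4V2", "c.802-8_810del17insGC",
                        zygosity="homozygous", band=Band.PATHOGENIC)
    het1 = VariantRecord("CYP4V2", "c.802-8_810del17insGC",
                         band=Band.PATHOGENIC)
    het2 = VariantRecord("CYP4V2", "c.992A>C", band=Band.LIKELY_PATHOGENIC)
    cases = [
        solved_case("P1", "CYP4V2", "bietti_crystalline_dystrophy",
                    variants=[hom]),
        solved_case("P2", "CYP4V2", "bietti_crystalline_dystrophy",
                    variants=[het1, het2]),
    ]
    table = variant_frequency(cases, "CYP4V2")
    founder = table[table["hgvs_c"] == "c.802-8_810del17insGC"].iloc[0]
    assert founder["count"] == 2
    assert founder["fraction"] == pytest.approx(1.0)


def test_concordance_uses_gene_spectrum(gene_models):
    cases = [
        solved_case("P1", "USH2A", "retinitis_pigmentosa"),
        solved_case("P2", "PEX6", "usher_syndrome"),  # Zellweger-spectrum gene
    ]
    overall, table = concordance(cases, gene_models)
    assert overall == pytest.approx(0.5)
    ush = table[table["phenotype"] == "usher_syndrome"].iloc[0]
    assert ush["concordant"] == 0


def test_concordance_empty_spectrum_is_discordant():
    from irdyield.resolution import GeneModel

    models = {"RHO": GeneModel("RHO", "autosomal_dominant", frozenset())}
    overall, _ = concordance(
        [solved_case("P1", "RHO", "retinitis_pigmentosa")], models)
    assert overall == 0.0
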