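"""Diagnostic-yield statistics for a resolved cohort.

This module computes the quantities a cohort-level yield study reports:
the overall diagnostic yield (fully plus probably solved over total),
yields stratified by age of onset, family history, ancestry or clinical
phenotype, exact tests on contingency tables, rank-sum comparisons of
continuous variables between solved and unsolved probands, a binomial
logistic regression of solved status on age of diagnosis (and family
history), odds and risk ratios, causal gene / recurrent variant frequency
tables, and genotype-phenotype concordance.

Exact tests.  The 2x2 Fisher test is computed by exact hypergeometric
tail summation in integer arithmetic (two-sided: the probabilities of all
tables with the observed margins no more likely than the observed table
are summed), so the result is exact to floating-point representation.
Larger r x c tables use a seeded Monte-Carlo estimate over tables drawn
uniformly from the fixed-margins null.  The rank-sum test enumerates the
full permutation distribution (midranks, hence exact under ties) when the
combined sample size is at most 12 and otherwise uses the tie-corrected
normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import FitError, UndefinedResultError
from .resolution import GeneModel, SolvedStatus, Status, VariantRecord

__all__ = [
    "Ancestry",
    "ProbandCase",
    "Cohort",
    "overall_yield",
    "yield_by_stratum",
    "age_bin",
    "family_history_stratum",
    "fisher_exact",
    "rank_sum",
    "logistic_fit",
    "LogisticFit",
    "odds_ratio",
    "risk_ratio",
    "gene_frequency",
    "variant_frequency",
    "concordance",
    "round_half_up",
]


class Ancestry(str, Enum):
    CHINESE = "chinese"
    INDIAN = "indian"
    MALAY = "malay"
    OTHER = "other"


@dataclass
class ProbandCase:
    """One proband: demographics, phenotype, variants and solved status."""

    proband_id: str
    ancestry: Ancestry
    sex: str  # "female" / "male"
    age_at_exam: float
    age_of_onset: Optional[float]
    affected_relatives: int
    phenotype: str
    variants: list[VariantRecord] = field(default_factory=list)
    status: Optional[SolvedStatus] = None

    def __post_init__(self):
        self.ancestry = Ancestry(self.ancestry)
        if self.age_at_exam < 0:
            raise ValueError("age_at_exam must be non-negative")
        if self.age_of_onset is not None and self.age_of_onset < 0:
            raise ValueError("age_of_onset must be non-negative")
        if self.affected_relatives < 0:
            raise ValueError("affected_relatives must be non-negative")

    @property
    def solved(self) -> bool:
        return self.status is not None and self.status.status != Status.UNSOLVED


@dataclass
class Cohort:
    """A collection of proband cases, the unit of all analytics."""

    cases: list[ProbandCase]

    def __len__(self):
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def _cases(cohort) -> list[ProbandCase]:
    return list(cohort.cases) if isinstance(cohort, Cohort) else list(cohort)


# ---------------------------------------------------------------------------
# Yields

def overall_yield(cohort) -> tuple[int, int, int, float]:
    """(fully solved, probably solved, total, yield fraction)."""
    cases = _cases(cohort)
    if any(c.status is None for c in cases):
        raise ValueError("every case needs a resolved status")
    fully = sum(c.status.status == Status.FULLY_SOLVED for c in cases)
    probably = sum(c.status.status == Status.PROBABLY_SOLVED for c in cases)
    total = len(cases)
    return fully, probably, total, (fully + probably) / total if total else 0.0


def yield_by_stratum(
    cohort, stratifier: Callable[[ProbandCase], str]
) -> pd.DataFrame:
    """Solved / total / yield per stratum of a partitioning stratifier."""
    rows: dict[str, list[int]] = {}
    for case in _cases(cohort):
        label = stratifier(case)
        solved, total = rows.setdefault(label, [0, 0])
        rows[label][1] += 1
        if case.solved:
            rows[label][0] += 1
    table = pd.DataFrame(
        [(k, s, t, s / t) for k, (s, t) in rows.items()],
        columns=["stratum", "solved", "total", "yield"],
    )
    return table.sort_values("stratum", ignore_index=True)


#: Default half-open age bins for onset-age stratification.
AGE_BINS = [(0, 20), (20, 40), (40, 60), (60, math.inf)]


def age_bin(case: ProbandCase) -> str:
    """Stratifier: half-open onset-age bins [0,20), [20,40), [40,60), 60+."""
    age = case.age_of_onset
    if age is None:
        return "unknown"
    for low, high in AGE_BINS:
        if low <= age < high:
            return f"{low}+" if math.isinf(high) else f"[{low},{high})"
    return "unknown"


def family_history_stratum(case: ProbandCase) -> str:
    """Stratifier: 0, 1-2, or >=3 self-reported affected relatives."""
    n = case.affected_relatives
    return "0" if n == 0 else ("1-2" if n <= 2 else "3+")


# ---------------------------------------------------------------------------
# Exact tests

def _fisher_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher p for a 2x2 table, exact integer arithmetic.

    With margins fixed the table is determined by its top-left cell x; the
    (unnormalised) hypergeometric weight of x is C(r1, x) * C(r2, c1 - x).
    The two-sided p sums the weights of all x whose weight does not exceed
    the observed one, over the common denominator C(N, c1).
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return num / math.comb(r1 + r2, c1)


def _log_table_prob(table: np.ndarray, row_sums, col_sums, total) -> float:
    """Log multiple-hypergeometric probability of an r x c table."""
    return (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(table + 1).sum()
    )


def _sample_tables_fixed_margins(row_sums, col_sums, reps, rng):
    """Draw tables uniformly from the fixed-margins hypergeometric null.

    Rows are filled sequentially by multivariate hypergeometric draws from
    the remaining column mass; the two-row case is fully vectorised.
    """
    r = len(row_sums)
    if r == 2:
        first = rng.multivariate_hypergeometric(col_sums, row_sums[0], size=reps)
        return np.stack([first, col_sums[None, :] - first], axis=1)
    tables = np.empty((reps, r, len(col_sums)), dtype=np.int64)
    for k in range(reps):
        remaining = np.array(col_sums, dtype=np.int64)
        for i in range(r - 1):
            row = rng.multivariate_hypergeometric(remaining, row_sums[i])
            tables[k, i] = row
            remaining = remaining - row
        tables[k, r - 1] = remaining
    return tables


def fisher_exact(
    table, mc_reps: int = 100_000, seed: int | None = None
) -> float:
    """Two-sided Fisher exact test on an r x c contingency table.

    2x2 tables are computed exactly; larger tables use a seeded
    Monte-Carlo estimate with ``mc_reps`` tables drawn from the
    fixed-margins null (p includes the observed table, so p is in (0, 1]).
    Degenerate margins raise :class:`UndefinedResultError`.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise UndefinedResultError("table has a zero margin")
    if table.shape == (2, 2):
        return _fisher_2x2(table)
    rng = np.random.default_rng(seed)
    total = table.sum()
    log_obs = _log_table_prob(table, row_sums, col_sums, total)
    sampled = _sample_tables_fixed_margins(row_sums, col_sums, mc_reps, rng)
    log_p = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(sampled + 1).sum(axis=(1, 2))
    )
    hits = int((log_p <= log_obs + 1e-7).sum())
    return (hits + 1) / (mc_reps + 1)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the sum of midranks of ``x`` in the pooled sample.  For combined
    n <= 12 the full permutation distribution is enumerated (exact under
    ties); otherwise the tie-corrected normal approximation is used
    (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    ranks = _midranks(pooled)
    w_obs = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    if n <= 12:
        dev_obs = abs(w_obs - mu)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n), nx):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev_obs - 1e-9:
                hits += 1
        return w_obs, hits / total
    ny = n - nx
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w_obs, 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return w_obs, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Logistic regression

@dataclass(frozen=True)
class LogisticFit:
    params: dict[str, float]
    bse: dict[str, float]
    converged: bool
    n_iter: int
    llf: float


def logistic_fit(
    outcomes: Sequence[int],
    age: Sequence[float],
    family_history: Sequence[int] | None = None,
    *,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> LogisticFit:
    """Binomial logistic regression of solved status on age (and family
    history), fitted by iteratively reweighted least squares.

    Raises :class:`FitError` (with the deviance trace) on non-convergence
    or (quasi-)separation.
    """
    import statsmodels.api as sm

    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary")
    if y.min() == y.max():
        raise FitError("both outcome classes must be present")
    cols = {"const": np.ones_like(y), "age": np.asarray(age, dtype=float)}
    if family_history is not None:
        cols["family_history"] = np.asarray(family_history, dtype=float)
    X = np.column_stack(list(cols.values()))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol, tol_criterion="params")
    trace = list(np.atleast_1d(res.fit_history.get("deviance", [])))
    if not res.converged:
        raise FitError("IRLS did not converge", trace=trace)
    params = dict(zip(cols, res.params))
    bse = dict(zip(cols, res.bse))
    if any(abs(v) > 1e3 or not math.isfinite(v) for v in bse.values()):
        raise FitError("separation suspected: unstable standard errors", trace=trace)
    return LogisticFit(params, bse, bool(res.converged),
                       int(res.fit_history["iteration"]), float(res.llf))


# ---------------------------------------------------------------------------
# Ratios and frequency tables

@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to a zero cell


def odds_ratio(table) -> OddsRatio:
    """Odds ratio ad/bc of a 2x2 table with a log-scale Wald 95% CI.

    Zero cells trigger the Haldane-Anscombe correction (0.5 added to every
    cell), flagged on the result.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("odds_ratio needs a 2x2 table")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b, c, d = t.ravel()
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return OddsRatio(
        value,
        math.exp(math.log(value) - z * se),
        math.exp(math.log(value) + z * se),
        corrected,
    )


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding for report formatting."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def risk_ratio(yield_a: float, yield_b: float) -> float:
    """Fold change of two yield fractions, reported to 2 decimals."""
    if yield_b <= 0:
        raise ValueError("reference yield must be positive")
    return round_half_up(yield_a / yield_b, 2)


def gene_frequency(cohort) -> pd.DataFrame:
    """Causal-gene counts and fractions over the solved denominator,
    sorted by count descending with lexicographic tie-break."""
    solved = [c for c in _cases(cohort) if c.solved]
    if not solved:
        raise UndefinedResultError("no solved cases")
    counts: dict[str, int] = {}
    for case in solved:
        counts[case.status.causal_gene] = counts.get(case.status.causal_gene, 0) + 1
    denom = len(solved)
    table = pd.DataFrame(
        [(g, n, n / denom) for g, n in counts.items()],
        columns=["gene", "count", "fraction"],
    )
    return table.sort_values(
        ["count", "gene"], ascending=[False, True], ignore_index=True
    )


def variant_frequency(cohort, gene: str) -> pd.DataFrame:
    """Per-variant proband counts among probands solved by *gene*.

    A proband contributes once per distinct DNA-level variant it carries
    in the gene (a homozygote counts once); fractions use the gene-solved
    proband count as denominator.
    """
    solved = [
        c for c in _cases(cohort) if c.solved and c.status.causal_gene == gene
    ]
    if not solved:
        raise UndefinedResultError(f"no cases solved by {gene}")
    counts: dict[str, int] = {}
    for case in solved:
        carried = {v.hgvs_c for v in case.variants if v.gene == gene}
        for hgvs_c in carried:
            counts[hgvs_c] = counts.get(hgvs_c, 0) + 1
    denom = len(solved)
    table = pd.DataFrame(
        [(h, n, n / denom) for h, n in counts.items()],
        columns=["hgvs_c", "count", "fraction"],
    )
    return table.sort_values(
        ["count", "hgvs_c"], ascending=[False, True], ignore_index=True
    )


def concordance(
    cohort, models: Mapping[str, GeneModel]
) -> tuple[float, pd.DataFrame]:
    """Genotype-phenotype concordance over solved cases.

    A solved case is concordant iff its causal gene's disease spectrum
    contains the initial clinical diagnosis.  Returns the overall fraction
    and a per-diagnosis table.
    """
    solved = [c for c in _cases(cohort) if c.solved]
    if not solved:
        raise UndefinedResultError("no solved cases")
    rows: dict[str, list[int]] = {}
    n_concordant = 0
    for case in solved:
        model = models.get(case.status.causal_gene)
        is_concordant = model is not None and case.phenotype in model.phenotypes
        entry = rows.setdefault(case.phenotype, [0, 0])
        entry[1] += 1
        if is_concordant:
            entry[0] += 1
            n_concordant += 1
    table = pd.DataFrame(
        [(p, c, t, c / t) for p, (c, t) in rows.items()],
        columns=["phenotype", "concordant", "solved", "fraction"],
    ).sort_values("solved", ascending=False, ignore_index=True)
    return n_concordant / len(solved), table
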