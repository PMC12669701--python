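"""Cohort report: the full determinants-of-yield analysis as JSON/Markdown.

Every stochastic result carries the method and, where applicable, the seed
used, so a report is traceable to its run manifest.
"""

from __future__ import annotations

import json
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .analytics import (
    Ancestry,
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
from .errors import FitError, UndefinedResultError
from .resolution import trans_rate

__all__ = ["build_report", "render_markdown"]


def _yield_table_dict(table: pd.DataFrame) -> dict:
    return {
        row.stratum: {"solved": int(row.solved), "total": int(row.total),
                      "yield_pct": round_half_up(100 * row.yield_, 1)}
        for row in table.rename(columns={"yield": "yield_"}).itertuples(index=False)
    }


def build_report(cohort, models: Mapping, seed: int,
                 kinship_long: Optional[pd.DataFrame] = None,
                 mc_reps: int = 100_000) -> dict:
    """Compute the cohort analytics bundle for a resolved cohort."""
    cases = list(cohort.cases) if hasattr(cohort, "cases") else list(cohort)
    fully, probably, total, yld = overall_yield(cases)
    report: dict = {
        "n_probands": total,
        "overall": {
            "fully_solved": fully,
            "probably_solved": probably,
            "solved": fully + probably,
            "yield_pct": round_half_up(100 * yld, 2),
        },
    }

    report["yield_by_age_bin"] = _yield_table_dict(yield_by_stratum(cases, age_bin))
    report["yield_by_family_history"] = _yield_table_dict(
        yield_by_stratum(cases, family_history_stratum))
    report["yield_by_ancestry"] = _yield_table_dict(
        yield_by_stratum(cases, lambda c: c.ancestry.value))
    report["yield_by_phenotype"] = _yield_table_dict(
        yield_by_stratum(cases, lambda c: c.phenotype))

    # ancestry x solved exact test (r x c Monte-Carlo, seeded)
    ancestry_tab = np.array([
        [sum(1 for c in cases if c.ancestry == a and c.solved),
         sum(1 for c in cases if c.ancestry == a and not c.solved)]
        for a in Ancestry
    ])
    try:
        p = fisher_exact(ancestry_tab, mc_reps=mc_reps, seed=seed)
        report["ancestry_vs_solved"] = {
            "p_value": p, "method": "fisher_mc", "mc_reps": mc_reps, "seed": seed}
    except UndefinedResultError:
        report["ancestry_vs_solved"] = None

    # onset age, solved vs unsolved
    onset_solved = [c.age_of_onset for c in cases if c.solved
                    and c.age_of_onset is not None]
    onset_unsolved = [c.age_of_onset for c in cases if not c.solved
                      and c.age_of_onset is not None]
    if onset_solved and onset_unsolved:
        w, p = rank_sum(onset_solved, onset_unsolved)
        report["onset_vs_solved"] = {
            "median_solved": float(np.median(onset_solved)),
            "median_unsolved": float(np.median(onset_unsolved)),
            "statistic_w": w, "p_value": p, "method": "rank_sum",
        }

    # logistic regression of solved status on onset age + family history
    with_onset = [c for c in cases if c.age_of_onset is not None]
    try:
        fit = logistic_fit(
            [int(c.solved) for c in with_onset],
            [c.age_of_onset for c in with_onset],
            [int(c.affected_relatives > 0) for c in with_onset],
        )
        report["logistic"] = {"params": fit.params, "bse": fit.bse,
                              "n_iter": fit.n_iter, "method": "glm_binomial_irls"}
    except (FitError, ValueError) as exc:
        report["logistic"] = {"error": str(exc)}

    # family-history contrasts: 1-2 and 3+ affected relatives vs none
    fh = {row.stratum: (int(row.solved), int(row.total))
          for row in yield_by_stratum(cases, family_history_stratum)
          .itertuples(index=False)}
    if "0" in fh and fh["0"][1] and fh["0"][0]:
        base_solved, base_total = fh["0"]
        base_yield = base_solved / base_total
        contrasts = {}
        for label in ("1-2", "3+"):
            if label not in fh or fh[label][1] == 0:
                continue
            s, t = fh[label]
            table = [[s, t - s], [base_solved, base_total - base_solved]]
            orr = odds_ratio(table)
            contrasts[label] = {
                "yield_pct": round_half_up(100 * s / t, 1),
                "risk_ratio_vs_none": risk_ratio(s / t, base_yield),
                "odds_ratio": orr.value,
                "or_ci95": [orr.ci_low, orr.ci_high],
            }
        report["family_history_contrasts"] = {
            "baseline_yield_pct": round_half_up(100 * base_yield, 1),
            **contrasts,
        }

    # recurrent genes and variants
    try:
        genes = gene_frequency(cases)
        report["gene_frequency"] = [
            {"gene": r.gene, "count": int(r.count),
             "pct_of_solved": round_half_up(100 * r.fraction, 1)}
            for r in genes.head(10).itertuples(index=False)
        ]
        report["top5_gene_share_pct"] = round_half_up(
            100 * genes["fraction"].head(5).sum(), 1)
        report["variant_frequency"] = {}
        for gene in genes["gene"].head(3):
            table = variant_frequency(cases, gene)
            report["variant_frequency"][gene] = [
                {"hgvs_c": r.hgvs_c, "count": int(r.count),
                 "pct_of_gene_solved": round_half_up(100 * r.fraction, 1)}
                for r in table.head(5).itertuples(index=False)
            ]
    except UndefinedResultError:
        report["gene_frequency"] = []

    # genotype-phenotype concordance
    try:
        overall, table = concordance(cases, models)
        report["concordance"] = {
            "overall_pct": round_half_up(100 * overall, 1),
            "by_phenotype": {
                r.phenotype: {"concordant": int(r.concordant),
                              "solved": int(r.solved),
                              "pct": round_half_up(100 * r.fraction, 2)}
                for r in table.itertuples(index=False)
            },
        }
    except UndefinedResultError:
        report["concordance"] = None

    # trans confirmation rate among phased recessive pairs
    try:
        report["trans_rate"] = trans_rate([c.variants for c in cases], models)
    except UndefinedResultError:
        report["trans_rate"] = None

    return report


def _md_table(header: list[str], rows: list[list]) -> str:
    out = ["| " + " | ".join(header) + " |",
           "|" + "|".join("---" for _ in header) + "|"]
    out += ["| " + " | ".join(str(x) for x in row) + " |" for row in rows]
    return "\n".join(out)


def render_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of a report dict."""
    lines = ["# Diagnostic yield report", ""]
    ov = report["overall"]
    lines.append(
        f"Probands: {report['n_probands']}; solved {ov['solved']} "
        f"({ov['fully_solved']} fully + {ov['probably_solved']} probably), "
        f"overall yield {ov['yield_pct']}%."
    )
    for key, title in [
        ("yield_by_age_bin", "Yield by age of onset"),
        ("yield_by_family_history", "Yield by affected relatives"),
        ("yield_by_ancestry", "Yield by ancestry"),
        ("yield_by_phenotype", "Yield by clinical phenotype"),
    ]:
        table = report.get(key)
        if not table:
            continue
        lines += ["", f"## {title}", "",
                  _md_table(["stratum", "solved", "total", "yield %"],
                            [[k, v["solved"], v["total"], v["yield_pct"]]
                             for k, v in table.items()])]
    if report.get("gene_frequency"):
        lines += ["", "## Recurrent causal genes", "",
                  _md_table(["gene", "count", "% of solved"],
                            [[g["gene"], g["count"], g["pct_of_solved"]]
                             for g in report["gene_frequency"]])]
    conc = report.get("concordance")
    if conc:
        lines += ["", f"## Genotype-phenotype concordance: "
                      f"{conc['overall_pct']}% overall", "",
                  _md_table(["phenotype", "concordant", "solved", "%"],
                            [[p, v["concordant"], v["solved"], v["pct"]]
                             for p, v in conc["by_phenotype"].items()])]
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, json_path, md_path=None) -> None:
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
    if md_path is not None:
        with open(md_path, "w", encoding="utf-8") as fh:
            fh.write(render_markdown(report))
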