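"""TSV dialects, JSON config and the run manifest.

All tabular files are UTF-8 TSV with a header row and "." as the missing
value.  HGVS strings are passed through verbatim (no normalisation).
Criteria columns use the semicolon-joined token dialect of
:func:`irdyield.acmg.parse_assertions`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .acmg import format_assertions, parse_assertions
from .analytics import Ancestry, Cohort, ProbandCase
from .cnv import CnvCall, CnvKind
from .errors import InvalidInputError
from .resolution import SolvedStatus, Status, VariantRecord, Zygosity
from .simulate import GeneratorConfig

MISSING = "."

__all__ = [
    "read_tsv", "write_tsv",
    "probands_to_frame", "frame_to_probands",
    "variants_to_frame", "frame_to_variants",
    "status_to_frame", "frame_to_status",
    "cnv_to_frame", "frame_to_cnv",
    "write_genotypes", "read_genotypes",
    "read_vcf_variants",
    "load_generator_config", "dump_generator_config",
    "RunManifest", "sha256_file",
]


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_tsv(path, required: Iterable[str] = ()) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype=str,
                        keep_default_na=False)
    missing = set(required) - set(frame.columns)
    if missing:
        raise InvalidInputError(
            f"{path}: missing required column(s) {sorted(missing)}")
    return frame


def _opt(value) -> str | float:
    return MISSING if value is None else value


# ---------------------------------------------------------------------------
# Probands

_PROBAND_COLS = ["proband_id", "ancestry", "sex", "age_at_exam",
                 "age_of_onset", "affected_relatives", "phenotype"]


def probands_to_frame(cohort) -> pd.DataFrame:
    cases = cohort.cases if isinstance(cohort, Cohort) else list(cohort)
    return pd.DataFrame(
        [
            {
                "proband_id": c.proband_id,
                "ancestry": c.ancestry.value,
                "sex": c.sex,
                "age_at_exam": c.age_at_exam,
                "age_of_onset": _opt(c.age_of_onset),
                "affected_relatives": c.affected_relatives,
                "phenotype": c.phenotype,
            }
            for c in cases
        ],
        columns=_PROBAND_COLS,
    )


def frame_to_probands(frame: pd.DataFrame,
                      variants_by_proband: Mapping[str, list] | None = None
                      ) -> list[ProbandCase]:
    cases = []
    variants_by_proband = variants_by_proband or {}
    for row_num, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            onset = row.age_of_onset
            onset = None if onset in ("", MISSING) or pd.isna(onset) else float(onset)
            cases.append(ProbandCase(
                proband_id=str(row.proband_id),
                ancestry=Ancestry(row.ancestry),
                sex=str(row.sex),
                age_at_exam=float(row.age_at_exam),
                age_of_onset=onset,
                affected_relatives=int(row.affected_relatives),
                phenotype=str(row.phenotype),
                variants=list(variants_by_proband.get(str(row.proband_id), [])),
            ))
        except (ValueError, TypeError) as exc:
            raise InvalidInputError(f"probands row {row_num}: {exc}") from exc
    return cases


# ---------------------------------------------------------------------------
# Variants

_VARIANT_COLS = ["proband_id", "gene", "hgvs_c", "hgvs_p", "zygosity",
                 "phase_group", "criteria", "score", "band"]


def variants_to_frame(cohort, include_band: bool = True) -> pd.DataFrame:
    from .acmg import score_variant

    cases = cohort.cases if isinstance(cohort, Cohort) else list(cohort)
    rows = []
    for case in cases:
        for v in case.variants:
            row = {
                "proband_id": case.proband_id,
                "gene": v.gene,
                "hgvs_c": v.hgvs_c,
                "hgvs_p": v.hgvs_p or MISSING,
                "zygosity": v.zygosity.value,
                "phase_group": _opt(v.phase_group),
                "criteria": format_assertions(v.assertions),
            }
            if include_band:
                row["score"] = (score_variant(v.assertions)
                                if v.assertions else MISSING)
                row["band"] = v.band.value
            rows.append(row)
    cols = _VARIANT_COLS if include_band else _VARIANT_COLS[:7]
    return pd.DataFrame(rows, columns=cols)


def frame_to_variants(frame: pd.DataFrame,
                      classify: bool = True) -> dict[str, list[VariantRecord]]:
    """Group a variant table into per-proband VariantRecord lists.

    When ``classify`` is true the band is recomputed from the criteria
    column; otherwise a band column is required and trusted.
    """
    from .acmg import classify_assertions

    out: dict[str, list[VariantRecord]] = {}
    for row_num, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            assertions = tuple(parse_assertions(getattr(row, "criteria", "")))
            if classify:
                band = classify_assertions(assertions)
            else:
                band = row.band
            phase = getattr(row, "phase_group", MISSING)
            phase = None if phase in ("", MISSING) or pd.isna(phase) else str(phase)
            hgvs_p = getattr(row, "hgvs_p", MISSING)
            hgvs_p = "" if hgvs_p in ("", MISSING) or pd.isna(hgvs_p) else str(hgvs_p)
            record = VariantRecord(
                gene=str(row.gene), hgvs_c=str(row.hgvs_c), hgvs_p=hgvs_p,
                zygosity=Zygosity(row.zygosity), band=band,
                phase_group=phase, assertions=assertions,
            )
        except (ValueError, TypeError) as exc:
            raise InvalidInputError(f"variants row {row_num}: {exc}") from exc
        out.setdefault(str(row.proband_id), []).append(record)
    return out


# ---------------------------------------------------------------------------
# Solved status

def status_to_frame(cohort) -> pd.DataFrame:
    cases = cohort.cases if isinstance(cohort, Cohort) else list(cohort)
    return pd.DataFrame(
        [
            {
                "proband_id": c.proband_id,
                "status": c.status.status.value,
                "causal_gene": _opt(c.status.causal_gene),
                "trans_confirmed": str(c.status.trans_confirmed).lower(),
            }
            for c in cases
            if c.status is not None
        ],
        columns=["proband_id", "status", "causal_gene", "trans_confirmed"],
    )


def frame_to_status(frame: pd.DataFrame) -> dict[str, SolvedStatus]:
    out = {}
    for row in frame.itertuples(index=False):
        gene = row.causal_gene
        gene = None if gene in ("", MISSING) or pd.isna(gene) else str(gene)
        out[str(row.proband_id)] = SolvedStatus(
            Status(row.status), gene, str(row.trans_confirmed).lower() == "true")
    return out


# ---------------------------------------------------------------------------
# CNV calls (BED-like, but 1-based inclusive)

def cnv_to_frame(calls: Iterable[CnvCall],
                 classification: Iterable[str] | None = None) -> pd.DataFrame:
    rows = [
        {
            "proband_id": c.proband_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "kind": c.kind.value,
            "read_ratio": c.read_ratio,
            "genes": ";".join(sorted(c.genes)) or MISSING,
        }
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=["proband_id", "chrom", "start", "end",
                                        "kind", "read_ratio", "genes"])
    if classification is not None:
        frame["classification"] = list(classification)
    return frame


def frame_to_cnv(frame: pd.DataFrame) -> list[CnvCall]:
    calls = []
    for row_num, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            genes = row.genes
            genes = (frozenset() if genes in ("", MISSING) or pd.isna(genes)
                     else frozenset(str(genes).split(";")))
            calls.append(CnvCall(
                proband_id=str(row.proband_id), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end), kind=CnvKind(row.kind),
                read_ratio=float(row.read_ratio), genes=genes,
            ))
        except (ValueError, TypeError) as exc:
            raise InvalidInputError(f"cnv row {row_num}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# Genotypes (ids x loci integer matrix)

def write_genotypes(path, ids, genotypes: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        n_loci = genotypes.shape[1]
        fh.write("proband_id\t" + "\t".join(f"L{i}" for i in range(n_loci)) + "\n")
        for pid, row in zip(ids, genotypes):
            fh.write(str(pid) + "\t" + "\t".join(map(str, row)) + "\n")


def read_genotypes(path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    ids = frame["proband_id"].astype(str).tolist()
    return ids, frame.drop(columns="proband_id").to_numpy(dtype=np.int8)


# ---------------------------------------------------------------------------
# Minimal VCF ingest: CHROM/POS/REF/ALT plus INFO keys GENE, CRITERIA and
# optionally ZYG, PHASE, HGVSC, HGVSP; one proband per file.  CRITERIA
# tokens are '|'-separated (';' is reserved by the INFO field syntax).

def read_vcf_variants(path, proband_id: str) -> dict[str, list[VariantRecord]]:
    from .acmg import classify_assertions

    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingest requires cyvcf2") from exc

    records = []
    for variant in VCF(str(path)):
        gene = variant.INFO.get("GENE")
        if gene is None:
            continue
        criteria = (variant.INFO.get("CRITERIA", "") or "").replace("|", ";")
        assertions = tuple(parse_assertions(criteria))
        records.append(VariantRecord(
            gene=str(gene),
            hgvs_c=variant.INFO.get(
                "HGVSC", f"c.{variant.POS}{variant.REF}>{variant.ALT[0]}"),
            hgvs_p=variant.INFO.get("HGVSP", "") or "",
            zygosity=Zygosity(variant.INFO.get("ZYG", "heterozygous")),
            band=classify_assertions(assertions),
            phase_group=variant.INFO.get("PHASE") or None,
            assertions=assertions,
        ))
    return {proband_id: records}


# ---------------------------------------------------------------------------
# Config and manifest

def load_generator_config(path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in raw.items():
        if isinstance(value, list):
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return GeneratorConfig(**raw)


def dump_generator_config(config: GeneratorConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config hash, input digests, seeds."""

    seed: int
    config_hash: str
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S", time.gmtime()))
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    @staticmethod
    def for_config(config: GeneratorConfig, seed: int) -> "RunManifest":
        payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                             default=str).encode()
        return RunManifest(seed=seed,
                           config_hash=hashlib.sha256(payload).hexdigest())

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
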