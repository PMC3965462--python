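"""Carrier-concordance filtering of sequence variants and scoring of
validation-panel genotype tables.

The central rule: a candidate causal variant for a fully penetrant recessive
lethal must be heterozygous in every haplotype carrier, homozygous for the
non-risk allele in every non-carrier, and never homozygous for the risk
allele in any live animal. Animals homozygous for a sub-segment of the
haplotype (pre-mutation ancestral copies) are exempt from the het/hom
pattern but still must not be risk-allele homozygotes.

Because the risk-linked allele may be either the assembly reference ("A")
or the discovered alternate ("B"), concordance is judged under both allele
orientations and holds if either passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenotypeCountTable,
    HET,
    HOM_ALT,
    HOM_REF,
    Interval,
    NO_CALL,
    VariantCallSet,
)

# statuses used throughout: HaplotypeStatusTable values per animal
CARRIER = "carrier"
NON_CARRIER = "non_carrier"
HOM_SUBSEGMENT = "homozygous_subsegment"
UNKNOWN = "unknown"

_STATUS_TO_GROUP = {
    CARRIER: "Carrier",
    NON_CARRIER: "Normal",
    HOM_SUBSEGMENT: "Homozygous",
    UNKNOWN: "Unknown",
}


# ---------------------------------------------------------------------------
# Sequence-call filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterThresholds:
    """Read-support thresholds for reporting a candidate variant.

    ``min_depth_report`` defaults to 9, implementing a strict "more than
    8-fold coverage in every animal" reporting rule; pass 8 to relax to
    at-least-8.
    """

    min_mapq: int = 20
    min_depth_call: int = 4
    min_depth_report: int = 9
    max_indel_len: int = 6

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_depth_call, self.min_depth_report) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CandidateSV:
    site_index: int
    chrom: str
    pos_bp: int
    ref: str
    alt: str
    locus: str
    scope: str  # "genome" | "chromosome" | "locus"
    annotation: str = ""


def filter_candidates(
    calls: VariantCallSet,
    statuses: Mapping[str, str],
    locus: str,
    thresholds: FilterThresholds = FilterThresholds(),
    refined_interval: Interval | None = None,
    *,
    allow_missing_noncarrier: bool = False,
) -> list[CandidateSV]:
    """Retain sites whose genotype pattern co-segregates with carrier status.

    A site survives iff (a) every animal's call passes the mapq and calling
    depth thresholds and has reporting depth, (b) every carrier is
    heterozygous, and (c) every non-carrier is homozygous reference (or
    uncalled, when ``allow_missing_noncarrier``). Sub-segment homozygotes may
    be het or hom-ref but never hom-alt; unknown-status animals are ignored.
    Surviving sites are tagged with their scope tier relative to the locus.
    """
    if refined_interval is None:
        raise ValueError(f"locus {locus!r} has no refined interval")
    cols = {a: calls.animal_column(a) for a in calls.animal_ids}
    carrier_cols = [cols[a] for a, s in statuses.items() if s == CARRIER and a in cols]
    noncarrier_cols = [
        cols[a] for a, s in statuses.items() if s == NON_CARRIER and a in cols
    ]
    subseg_cols = [
        cols[a] for a, s in statuses.items() if s == HOM_SUBSEGMENT and a in cols
    ]
    unknown = {a for a, s in statuses.items() if s == UNKNOWN}
    missing_status = [a for a in calls.animal_ids if a not in statuses]
    if missing_status:
        raise ValueError(f"animals without status for locus {locus}: {missing_status}")
    scored_cols = [c for a, c in cols.items() if a not in unknown]
    if not carrier_cols:
        raise ValueError(f"no carriers with calls for locus {locus}")

    out: list[CandidateSV] = []
    for s, site in enumerate(calls.sites):
        if site.indel_len > thresholds.max_indel_len:
            continue
        gt = calls.genotypes[s]
        dp = calls.depth[s]
        mq = calls.mapq[s]
        support_ok = (
            np.all(mq[scored_cols] >= thresholds.min_mapq)
            and np.all(dp[scored_cols] >= thresholds.min_depth_call)
            and np.all(dp[scored_cols] >= thresholds.min_depth_report)
        )
        if not support_ok:
            continue
        if not np.all(gt[carrier_cols] == HET):
            continue
        nc = gt[noncarrier_cols]
        if allow_missing_noncarrier:
            if not np.all((nc == HOM_REF) | (nc == NO_CALL)):
                continue
        elif not np.all(nc == HOM_REF):
            continue
        if subseg_cols and np.any(gt[subseg_cols] == HOM_ALT):
            continue
        if refined_interval.contains(site.chrom, site.pos_bp):
            scope = "locus"
        elif site.chrom == refined_interval.chrom:
            scope = "chromosome"
        else:
            scope = "genome"
        out.append(
            CandidateSV(
                site_index=s,
                chrom=site.chrom,
                pos_bp=site.pos_bp,
                ref=site.ref,
                alt=site.alt,
                locus=locus,
                scope=scope,
            )
        )
    return out


def count_by_scope(candidates: Sequence[CandidateSV]) -> pd.DataFrame:
    """Nested candidate totals per locus: genome-wide, on the locus
    chromosome, and within the refined interval (each tier includes the
    narrower ones, matching how such counts are conventionally reported)."""
    rows = {}
    for c in candidates:
        row = rows.setdefault(c.locus, {"genome": 0, "chromosome": 0, "locus": 0})
        row["genome"] += 1
        if c.scope in ("chromosome", "locus"):
            row["chromosome"] += 1
        if c.scope == "locus":
            row["locus"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=["genome", "chromosome", "locus"]
    )
    if df.empty:
        df = pd.DataFrame(columns=["genome", "chromosome", "locus"], dtype=int)
    df.index.name = "locus"
    return df.fillna(0).astype(int)


# ---------------------------------------------------------------------------
# Validation-panel concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordancePolicy:
    """How a genotype-count table is judged.

    Missing calls never violate the pattern, but a table whose Carrier+Normal
    missing fraction exceeds ``max_missing_frac`` is downgraded to
    indeterminate rather than trusted either way.
    """

    max_missing_frac: float = 0.20
    exempt_subsegment_homozygotes: bool = True


@dataclass
class ConcordanceVerdict:
    sv_id: str
    verdict: str  # "concordant" | "non_concordant" | "indeterminate"
    risk_allele: str | None  # "A" | "B" under the chosen orientation
    violations: list[tuple[str, str, int]] = field(default_factory=list)
    note: str = ""


_CLASS_NAMES = ("AA", "AB", "BB")


def _orientation_violations(
    table: GenotypeCountTable, risk: str, policy: ConcordancePolicy
) -> list[tuple[str, str, int]]:
    risk_hom = "BB" if risk == "B" else "AA"
    safe_hom = "AA" if risk == "B" else "BB"
    idx = {name: i for i, name in enumerate(_CLASS_NAMES)}
    violations = []
    for group, row in table.counts.items():
        if group in ("Overall", "Unknown"):
            continue  # Overall duplicates the others; Unknown is unscored
        counts = dict(zip(_CLASS_NAMES, row[:3]))
        if group == "Carrier":
            for cls in (safe_hom, risk_hom):
                if counts[cls]:
                    violations.append((group, cls, counts[cls]))
        elif group == "Normal":
            for cls in ("AB", risk_hom):
                if counts[cls]:
                    violations.append((group, cls, counts[cls]))
        elif group == "Homozygous":
            if policy.exempt_subsegment_homozygotes:
                if counts[risk_hom]:
                    violations.append((group, risk_hom, counts[risk_hom]))
            else:
                for cls in (safe_hom, risk_hom):
                    if counts[cls]:
                        violations.append((group, cls, counts[cls]))
    del idx
    return violations


def judge_concordance(
    table: GenotypeCountTable, policy: ConcordancePolicy = ConcordancePolicy()
) -> ConcordanceVerdict:
    """Judge whether a candidate variant co-segregates with carrier status.

    Tries both risk-allele orientations; the table is concordant if either
    leaves no violations. Missing calls are ignored for the pattern but an
    excessive missing fraction yields an indeterminate verdict, as does a
    table with no called genotypes in the scored groups.
    """
    scored = [g for g in ("Carrier", "Normal") if g in table.counts]
    if not scored:
        raise ValueError(f"{table.sv_id}: Carrier and Normal groups both absent")
    called = sum(sum(table.counts[g][:3]) for g in scored)
    missing = sum(table.counts[g][3] for g in scored)
    if called == 0:
        return ConcordanceVerdict(
            table.sv_id, "indeterminate", None, note="no called genotypes"
        )
    frac_missing = missing / (called + missing)
    if frac_missing > policy.max_missing_frac:
        return ConcordanceVerdict(
            table.sv_id,
            "indeterminate",
            None,
            note=f"missing fraction {frac_missing:.2f} exceeds "
            f"{policy.max_missing_frac:.2f}",
        )
    per_orientation = {
        risk: _orientation_violations(table, risk, policy) for risk in ("B", "A")
    }
    for risk in ("B", "A"):  # prefer the discovered alternate as risk allele
        if not per_orientation[risk]:
            return ConcordanceVerdict(table.sv_id, "concordant", risk)
    best = min(per_orientation, key=lambda r: len(per_orientation[r]))
    return ConcordanceVerdict(
        table.sv_id, "non_concordant", best, violations=per_orientation[best]
    )


# ---------------------------------------------------------------------------
# Per-animal discordance resolution
# ---------------------------------------------------------------------------


@dataclass
class DiscordanceCase:
    animal_id: str
    status: str
    first_call: int
    final_call: int
    resolution: str  # sample_swap | assay_error | ancestral_copy | unresolved
    note: str = ""


@dataclass
class ResolutionReport:
    cases: list[DiscordanceCase]
    corrected_genotypes: dict[str, int]
    corrected_statuses: dict[str, str]


def _expected_calls(status: str) -> set[int]:
    if status == CARRIER:
        return {HET}
    if status == NON_CARRIER:
        return {HOM_REF}
    if status == HOM_SUBSEGMENT:
        # ancestral-copy exemption: het or hom-ref, never risk-homozygous
        return {HET, HOM_REF}
    return {HOM_REF, HET, HOM_ALT}


def resolve_discordances(
    genotypes: Mapping[str, int],
    statuses: Mapping[str, str],
    reassay_records: Mapping[str, int] | None = None,
    identity_results: Mapping[str, str] | None = None,
    corrected_statuses: Mapping[str, str] | None = None,
) -> ResolutionReport:
    """Resolve animals whose assay genotype contradicts their carrier status.

    For each discordant animal: an identity mismatch (re-genotyping plus
    parentage analysis, see :func:`lethalmap.finemap.check_identity`) marks a
    sample swap and adopts the corrected status; a re-assay that differs from
    the first call marks a platform assay error and replaces the genotype; a
    sub-segment homozygote heterozygous at the candidate site is an ancestral
    copy, not an error; anything else stays unresolved.
    """
    reassay_records = dict(reassay_records or {})
    identity_results = dict(identity_results or {})
    corrected_statuses_in = dict(corrected_statuses or {})
    for aid in list(reassay_records) + list(identity_results):
        if aid not in genotypes:
            raise ValueError(f"re-assay/identity record for unknown animal {aid!r}")

    cases: list[DiscordanceCase] = []
    final_gt = dict(genotypes)
    final_status = dict(statuses)
    for aid, gt in genotypes.items():
        status = statuses.get(aid, UNKNOWN)
        if gt == NO_CALL or gt in _expected_calls(status):
            if status == HOM_SUBSEGMENT and gt == HET:
                cases.append(
                    DiscordanceCase(
                        aid, status, gt, gt, "ancestral_copy",
                        "heterozygous sub-segment homozygote",
                    )
                )
            continue
        if identity_results.get(aid) == "mismatch":
            new_status = corrected_statuses_in.get(aid, UNKNOWN)
            final_status[aid] = new_status
            cases.append(
                DiscordanceCase(
                    aid, status, gt, gt, "sample_swap",
                    f"identity mismatch; status corrected to {new_status}",
                )
            )
            continue
        if aid in reassay_records and reassay_records[aid] != gt:
            final_gt[aid] = reassay_records[aid]
            cases.append(
                DiscordanceCase(
                    aid, status, gt, reassay_records[aid], "assay_error",
                    "re-assay replaced first call",
                )
            )
            continue
        cases.append(DiscordanceCase(aid, status, gt, gt, "unresolved"))
    return ResolutionReport(cases, final_gt, final_status)


def counts_from_genotypes(
    sv_id: str,
    genotypes: Mapping[str, int],
    statuses: Mapping[str, str],
    *,
    annotation: str = "",
    chrom: str = "",
    pos_bp: int = 0,
    ref_allele: str = "A",
    alt_allele: str = "B",
) -> GenotypeCountTable:
    """Aggregate per-animal calls into the validation-panel table shape."""
    counts = {g: [0, 0, 0, 0] for g in ("Overall", "Carrier", "Normal",
                                        "Homozygous", "Unknown")}
    slot = {HOM_REF: 0, HET: 1, HOM_ALT: 2, NO_CALL: 3}
    for aid, gt in genotypes.items():
        group = _STATUS_TO_GROUP[statuses.get(aid, UNKNOWN)]
        counts[group][slot[gt]] += 1
        counts["Overall"][slot[gt]] += 1
    table = GenotypeCountTable(
        sv_id=sv_id,
        annotation=annotation,
        chrom=chrom,
        pos_bp=pos_bp,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
    )
    table.counts = {g: tuple(v) for g, v in counts.items() if any(v) or g == "Overall"}
    return table
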