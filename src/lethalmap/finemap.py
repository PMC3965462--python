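"""Interval refinement from crossover haplotypes and sub-segment homozygotes.

A live animal that inherited the full risk haplotype from one parent and an
end-anchored piece of it from the other parent is homozygous across that
piece - so, for a fully penetrant lethal, the causal allele cannot lie
there, and the piece is trimmed off the interval. Interior homozygous
blocks are deliberately NOT trimmed: they are candidate pre-mutation
ancestral copies of the haplotype and are classified instead of used as
exclusion evidence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .haploscan import HaplotypeWindow
from .io_formats import (
    Interval,
    MISSING,
    MarkerMap,
    Pedigree,
    PhasedGenotypes,
)

HET_CODE = 1  # candidate-causal-site genotype codes follow io_formats


# ---------------------------------------------------------------------------
# Status tables
# ---------------------------------------------------------------------------


@dataclass
class LocusStatus:
    """Carrier-status assignments for one locus."""

    locus_id: str
    window: HaplotypeWindow
    allele_string: str
    statuses: dict[str, str]  # animal -> carrier|non_carrier|homozygous_subsegment|unknown


@dataclass
class HaplotypeStatusTable:
    loci: dict[str, LocusStatus] = field(default_factory=dict)

    def add(self, status: LocusStatus) -> None:
        self.loci[status.locus_id] = status

    def status_for(self, locus_id: str) -> Mapping[str, str]:
        return self.loci[locus_id].statuses


def write_status_csv(table: HaplotypeStatusTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus", "animal_id", "status"])
        for locus in table.loci.values():
            for aid, status in locus.statuses.items():
                w.writerow([locus.locus_id, aid, status])


def read_status_csv(path) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["locus"], {})[row["animal_id"]] = row["status"]
    return out


def call_carrier_status(
    phased: PhasedGenotypes,
    pedigree: Pedigree,
    window: HaplotypeWindow,
    allele_string: str | np.ndarray,
    *,
    min_subsegment_markers: int = 8,
    ambiguous_end_markers: int | None = None,
) -> dict[str, str]:
    """Assign per-animal carrier status for a target window haplotype.

    Exactly one full copy -> carrier. No full copy but homozygous for a
    run of at least ``min_subsegment_markers`` consecutive target alleles ->
    homozygous_subsegment (candidate ancestral copy). Two full copies are
    also reported as homozygous_subsegment (the run is the whole window) and
    should be escalated via :func:`classify_subsegment`. Missing alleles in
    the window -> unknown.

    An animal with no full copy but a single-strand END-ANCHORED match of at
    least ``ambiguous_end_markers`` (default: ``min_subsegment_markers``) is
    also unknown rather than non-carrier: such an animal may carry a fresh
    recombinant of the risk haplotype - possibly including the untyped
    causal allele - so declaring it a non-carrier would poison a validation
    panel. Calling it on the refined core interval keeps this ambiguous
    class small.
    """
    if ambiguous_end_markers is None:
        ambiguous_end_markers = min_subsegment_markers
    h = np.asarray(
        [int(c) for c in allele_string] if isinstance(allele_string, str)
        else allele_string,
        dtype=np.int8,
    )
    W = phased.haplotypes[:, window.first_marker_index : window.last_marker_index + 1]
    statuses: dict[str, str] = {}
    for i, aid in enumerate(phased.animal_ids):
        if aid in pedigree and not pedigree[aid].is_live:
            continue
        w = W[i]
        if np.any(w == MISSING):
            statuses[aid] = "unknown"
            continue
        full = [bool(np.all(w[:, k] == h)) for k in (0, 1)]
        if sum(full) == 1:
            statuses[aid] = "carrier"
            continue
        hom_match = (w[:, 0] == h) & (w[:, 1] == h)
        if sum(full) == 2 or _longest_run(hom_match) >= min_subsegment_markers:
            statuses[aid] = "homozygous_subsegment"
            continue
        end_run = 0
        for k in (0, 1):
            eq = w[:, k] == h
            prefix = int(np.argmin(eq)) if not eq.all() else len(eq)
            suffix = int(np.argmin(eq[::-1])) if not eq.all() else len(eq)
            end_run = max(end_run, prefix, suffix)
        if end_run >= ambiguous_end_markers:
            statuses[aid] = "unknown"
        else:
            statuses[aid] = "non_carrier"
    return statuses


def extend_haplotype(
    phased: PhasedGenotypes,
    mmap: MarkerMap,
    window: HaplotypeWindow,
    allele_string: str | np.ndarray,
    n_markers: int = 8,
) -> tuple[HaplotypeWindow, str]:
    """Extend a window haplotype by up to ``n_markers`` flanking markers.

    The extension allele at each flanking marker is the majority allele over
    the strands that fully match the haplotype inside the window (they are
    copies of one ancestral segment, so they agree except for recombinants
    and missing calls; ties resolve to the lower allele code). Extending the
    status window guards panel declaration: any strand carrying an untyped
    interior locus of the haplotype on an end-anchored recombinant piece
    then matches over at least ``n_markers``, which
    :func:`call_carrier_status` flags as ambiguous rather than non-carrier.
    Raises if no strand matches the haplotype.
    """
    if n_markers < 0:
        raise ValueError("n_markers must be >= 0")
    h = np.asarray(
        [int(c) for c in allele_string] if isinstance(allele_string, str)
        else allele_string,
        dtype=np.int8,
    )
    first_m, last_m = window.first_marker_index, window.last_marker_index
    W = phased.haplotypes[:, first_m : last_m + 1]
    match_rows, match_strands = np.where(
        np.all(W == h[None, :, None], axis=1) & ~np.any(W == MISSING, axis=1)
    )
    if len(match_rows) == 0:
        raise ValueError("no strand matches the target haplotype")
    chrom_idx = mmap.chrom_indices(window.chrom)
    new_first = max(first_m - n_markers, int(chrom_idx[0]))
    new_last = min(last_m + n_markers, int(chrom_idx[-1]))
    out: list[int] = []
    for j in range(new_first, new_last + 1):
        if first_m <= j <= last_m:
            out.append(int(h[j - first_m]))
            continue
        alleles = phased.haplotypes[match_rows, j, match_strands]
        alleles = alleles[alleles != MISSING]
        votes = np.bincount(alleles, minlength=2) if len(alleles) else np.array([1, 0])
        out.append(int(np.argmax(votes)))
    return (
        HaplotypeWindow(window.chrom, new_first, new_last),
        "".join(str(a) for a in out),
    )


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Crossover detection and trimming
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossoverMatch:
    """Maximal end-anchored match of the target haplotype on the non-
    transmitting parental side of a carrier animal.

    ``first``/``last`` are absolute marker indices; ``side`` is "left",
    "right", or "full" for a two-copy candidate homozygote (escalated, never
    trimmed).
    """

    animal_id: str
    side: str
    first: int
    last: int


def detect_crossovers(
    phased: PhasedGenotypes,
    pedigree: Pedigree,
    window: HaplotypeWindow,
    allele_string: str | np.ndarray,
    *,
    require_parent_carrier: bool = True,
) -> list[CrossoverMatch]:
    """Find live carriers whose other parental haplotype matches an
    end-anchored prefix or suffix of the target haplotype.

    A match is reported as a crossover only when the parent on the matching
    side itself carries the full target haplotype (progeny-to-parent
    comparison): the partial copy is then a fresh recombinant of the risk
    haplotype, and because the animal is alive the lethal cannot lie in the
    doubly-carried end region. Without that check an inherited ancestral
    block that happens to touch the window end would masquerade as a
    crossover and could trim away the causal region. Strand 0 is the
    paternal haplotype by convention. Set ``require_parent_carrier=False``
    to accept matches with ungenotyped parents (less safe).
    """
    h = np.asarray(
        [int(c) for c in allele_string] if isinstance(allele_string, str)
        else allele_string,
        dtype=np.int8,
    )
    first_m, last_m = window.first_marker_index, window.last_marker_index
    W = phased.haplotypes[:, first_m : last_m + 1]

    def carries_full(aid: str | None) -> bool:
        if aid is None or aid not in phased:
            return False
        w = W[phased.index_of(aid)]
        return any(
            not np.any(w[:, k] == MISSING) and bool(np.all(w[:, k] == h))
            for k in (0, 1)
        )

    out: list[CrossoverMatch] = []
    for i, aid in enumerate(phased.animal_ids):
        if aid in pedigree and not pedigree[aid].is_live:
            continue
        w = W[i]
        if np.any(w == MISSING):
            continue
        full = [bool(np.all(w[:, k] == h)) for k in (0, 1)]
        if not any(full):
            continue
        if all(full):
            out.append(CrossoverMatch(aid, "full", first_m, last_m))
            continue
        other_strand = 1 - full.index(True)
        if require_parent_carrier:
            rec = pedigree[aid] if aid in pedigree else None
            parent = (
                None
                if rec is None
                else (rec.sire_id if other_strand == 0 else rec.dam_id)
            )
            if not carries_full(parent):
                continue
        other = w[:, other_strand]
        eq = other == h
        prefix = int(np.argmin(eq)) if not eq.all() else len(eq)
        suffix = int(np.argmin(eq[::-1])) if not eq.all() else len(eq)
        if prefix > 0:
            out.append(CrossoverMatch(aid, "left", first_m, first_m + prefix - 1))
        if suffix > 0 and prefix < len(eq):
            out.append(CrossoverMatch(aid, "right", last_m - suffix + 1, last_m))
    return out


@dataclass(frozen=True)
class Trim:
    side: str  # "left" | "right"
    first: int  # absolute marker indices removed
    last: int
    supporting_animals: tuple[str, ...]


@dataclass
class RefinedInterval:
    """``refined`` spans the outermost retained markers (the convention
    printed interval boundaries follow); ``refined_conservative`` widens it
    into the gaps up to the innermost trimmed markers, since an off-array
    causal position is only excluded up to the last marker shown homozygous.
    """

    original: Interval
    refined: Interval
    refined_conservative: Interval
    original_window: HaplotypeWindow
    refined_window: HaplotypeWindow
    trims: list[Trim]


def refine_interval(
    window: HaplotypeWindow,
    mmap: MarkerMap,
    crossovers: Sequence[CrossoverMatch],
    *,
    min_support: int = 1,
    trim_margin: int = 0,
) -> RefinedInterval:
    """Trim end-anchored homozygous runs off the window.

    The left (right) trim is the largest end-anchored marker count matched by
    at least ``min_support`` live recombinant animals, minus ``trim_margin``
    markers held back as a guard band: beyond the true recombination
    breakpoint a haplotype can keep matching the target by chance (identity
    by state rather than descent), so the innermost matched markers of the
    deepest run are the least trustworthy. Interior blocks and full-window
    homozygotes never trim. Raises if trimming would empty the interval,
    which signals an inconsistent status table.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if trim_margin < 0:
        raise ValueError("trim_margin must be >= 0")
    first_m, last_m = window.first_marker_index, window.last_marker_index

    def end_lengths(side: str) -> dict[str, int]:
        lengths: dict[str, int] = {}
        for cx in crossovers:
            if cx.side != side:
                continue
            if side == "left" and cx.first <= first_m <= cx.last:
                lengths[cx.animal_id] = max(
                    lengths.get(cx.animal_id, 0), cx.last - first_m + 1
                )
            elif side == "right" and cx.first <= last_m <= cx.last:
                lengths[cx.animal_id] = max(
                    lengths.get(cx.animal_id, 0), last_m - cx.first + 1
                )
        return lengths

    def supported_trim(lengths: dict[str, int]) -> tuple[int, tuple[str, ...]]:
        if len(lengths) < min_support:
            return 0, ()
        ordered = sorted(lengths.values(), reverse=True)
        k = max(ordered[min_support - 1] - trim_margin, 0)
        if k == 0:
            return 0, ()
        return k, tuple(sorted(a for a, v in lengths.items() if v >= k))

    left_k, left_support = supported_trim(end_lengths("left"))
    right_k, right_support = supported_trim(end_lengths("right"))
    width = last_m - first_m + 1
    if left_k + right_k >= width:
        raise ValueError(
            "trimming would remove the whole interval; status table is "
            "inconsistent with a lethal inside it"
        )
    new_first, new_last = first_m + left_k, last_m - right_k
    trims: list[Trim] = []
    if left_k:
        trims.append(Trim("left", first_m, first_m + left_k - 1, left_support))
    if right_k:
        trims.append(Trim("right", last_m - right_k + 1, last_m, right_support))
    refined_window = HaplotypeWindow(window.chrom, new_first, new_last)
    conservative = Interval(
        window.chrom,
        int(mmap.positions[new_first - 1]) + 1 if left_k else
        int(mmap.positions[new_first]),
        int(mmap.positions[new_last + 1]) - 1 if right_k else
        int(mmap.positions[new_last]),
    )
    return RefinedInterval(
        original=mmap.marker_interval(first_m, last_m),
        refined=mmap.marker_interval(new_first, new_last),
        refined_conservative=conservative,
        original_window=window,
        refined_window=refined_window,
        trims=trims,
    )


# ---------------------------------------------------------------------------
# Sub-segment homozygote classification
# ---------------------------------------------------------------------------


def classify_subsegment(
    *,
    is_live: bool,
    homozygous_range: tuple[int, int],
    window: HaplotypeWindow,
    causal_genotype: int | None = None,
) -> str:
    """Classify an animal homozygous over (part of) the risk haplotype.

    Returns ``ancestral_copy`` when the animal can plausibly carry one
    pre-mutation copy of the haplotype (live, and heterozygous at the
    candidate causal site when that genotype is available);
    ``true_homozygote_violation`` when a live full-interval homozygote
    contradicts a fully penetrant lethal model; ``uninformative`` otherwise.
    """
    first, last = homozygous_range
    if not (window.first_marker_index <= first <= last <= window.last_marker_index):
        raise ValueError("homozygous range outside the window")
    full = (first == window.first_marker_index) and (last == window.last_marker_index)
    if causal_genotype == HET_CODE:
        # heterozygosity at the candidate site itself shows one of the two
        # matching segments predates the mutation
        return "ancestral_copy"
    if full:
        # no causal genotype to exonerate it: a live full homozygote breaks
        # the penetrance-1 haplotype model
        return "true_homozygote_violation"
    if is_live and causal_genotype is None:
        return "ancestral_copy"
    return "uninformative"


# ---------------------------------------------------------------------------
# Parentage / identity check
# ---------------------------------------------------------------------------


@dataclass
class IdentityResult:
    animal_id: str
    verdict: str  # "confirmed" | "mismatch" | "uninformative"
    opposing_rate: float
    n_informative: int
    parent_id: str | None = None
    note: str = ""


def check_identity(
    animal_id: str,
    phased: PhasedGenotypes,
    pedigree: Pedigree,
    *,
    threshold: float = 0.02,
) -> IdentityResult:
    """Verify a sample's recorded parentage via opposing homozygotes.

    A true parent and offspring can never be homozygous for opposite alleles
    at the same marker (barring genotyping error); an opposing-homozygote
    rate above ``threshold`` of informative markers marks an identity
    mismatch, the signature of a sample swap. Rates within 25% of the
    threshold are flagged in the note rather than silently classified.
    """
    if animal_id not in pedigree:
        return IdentityResult(animal_id, "uninformative", 0.0, 0, note="no pedigree")
    rec = pedigree[animal_id]
    child = phased.row(animal_id)
    worst: IdentityResult | None = None
    for pid in (rec.sire_id, rec.dam_id):
        if pid is None or pid not in phased:
            continue
        parent = phased.row(pid)
        called = ~np.any(child == MISSING, axis=1) & ~np.any(parent == MISSING, axis=1)
        child_hom = called & (child[:, 0] == child[:, 1])
        parent_hom = called & (parent[:, 0] == parent[:, 1])
        informative = child_hom & parent_hom
        n_inf = int(informative.sum())
        if n_inf == 0:
            continue
        opposing = int(
            np.count_nonzero(informative & (child[:, 0] != parent[:, 0]))
        )
        rate = opposing / n_inf
        result = IdentityResult(
            animal_id,
            "mismatch" if rate > threshold else "confirmed",
            rate,
            n_inf,
            parent_id=pid,
        )
        if abs(rate - threshold) <= 0.25 * threshold:
            result.note = (
                f"opposing-homozygote rate {rate:.4f} near threshold {threshold}"
            )
        if worst is None or result.opposing_rate > worst.opposing_rate:
            worst = result
    if worst is None:
        return IdentityResult(
            animal_id, "uninformative", 0.0, 0, note="no genotyped parent"
        )
    return worst


def interval_length_mbp(i: Interval) -> float:
    """Interval length in Mbp, rounded to one decimal (end - start)/1e6."""
    return round((i.end_bp - i.start_bp) / 1e6, 1)
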