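"""Missing-homozygosity scanning and fertility-deficit estimation.

A recessive embryonic-lethal allele announces itself as a haplotype that is
common enough for homozygotes to be expected under Mendelian transmission,
yet for which no live homozygote is observed. This module slides windows
along the marker map, computes the Mendelian expectation of homozygotes for
each window haplotype by conditioning on parental phased genotypes (falling
back to the population haplotype frequency for ungenotyped parents), and
flags haplotypes whose expectation is substantial while the observed count
is zero. The probability of seeing zero homozygotes is the exact product
prod_i (1 - p_i) over per-animal homozygosity probabilities, not a binomial
approximation, because the p_i are heterogeneous.

The companion fertility estimator quantifies the conception-rate deficit of
"at-risk" matings (heterozygous sire x daughter of a heterozygous sire)
against normal matings; under full penetrance the expected deficit is
base_rate/8, since the dam is a carrier with probability 1/2 and a carrier x
carrier conceptus is homozygous with probability 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .io_formats import MISSING, MarkerMap, MatingRecord, Pedigree, PhasedGenotypes


@dataclass(frozen=True)
class HaplotypeWindow:
    chrom: str
    first_marker_index: int
    last_marker_index: int

    @property
    def width(self) -> int:
        return self.last_marker_index - self.first_marker_index + 1


@dataclass
class DeficitResult:
    window: HaplotypeWindow
    allele_string: str  # e.g. "01101..."
    frequency: float
    observed_hom: int
    expected_hom: float
    p_zero: float
    uninformative: bool = False


@dataclass
class FertilityEstimate:
    deficit_pct: float
    se_pct: float
    n_at_risk: int
    n_normal: int
    base_rate_pct: float
    at_risk_rate_pct: float


def enumerate_windows(
    mmap: MarkerMap, width_markers: int, step: int = 1
) -> list[HaplotypeWindow]:
    """Sliding marker-index frames per chromosome; a trailing partial frame
    is dropped."""
    if width_markers < 2:
        raise ValueError("window width must be at least 2 markers")
    if step < 1:
        raise ValueError("step must be >= 1")
    frames: list[HaplotypeWindow] = []
    for chrom in dict.fromkeys(mmap.chroms):
        idx = mmap.chrom_indices(chrom)
        for start in range(0, len(idx) - width_markers + 1, step):
            frames.append(
                HaplotypeWindow(
                    chrom, int(idx[start]), int(idx[start + width_markers - 1])
                )
            )
    return frames


# ---------------------------------------------------------------------------
# Expected homozygotes
# ---------------------------------------------------------------------------


def _parent_index(
    phased: PhasedGenotypes, pedigree: Pedigree
) -> tuple[np.ndarray, np.ndarray]:
    """Row index of each animal's genotyped sire/dam (-1 when unavailable)."""
    n = len(phased.animal_ids)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i, aid in enumerate(phased.animal_ids):
        if aid not in pedigree:
            continue
        rec = pedigree[aid]
        for arr, pid in ((sire, rec.sire_id), (dam, rec.dam_id)):
            if (
                pid is not None
                and pid in pedigree
                and pedigree[pid].is_genotyped
                and pid in phased
            ):
                arr[i] = phased.index_of(pid)
    return sire, dam


def _live_mask(phased: PhasedGenotypes, pedigree: Pedigree) -> np.ndarray:
    return np.array(
        [
            aid in pedigree and pedigree[aid].is_live and pedigree[aid].is_genotyped
            for aid in phased.animal_ids
        ]
    )


def expected_homozygotes(
    window: HaplotypeWindow,
    allele_string: str | np.ndarray,
    phased: PhasedGenotypes,
    pedigree: Pedigree,
    *,
    condition_on: str = "parent_genotype",
    _ctx: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> DeficitResult:
    """Mendelian expectation of live homozygotes for one window haplotype.

    For each live genotyped animal, the per-animal homozygosity probability
    is P(sire transmits h) x P(dam transmits h): a genotyped parent transmits
    h with probability 0, 1/2 or 1 according to how many copies it carries;
    an ungenotyped parent contributes the population haplotype frequency.
    With ``condition_on="dam_sire_genotype"``, an ungenotyped dam with a
    genotyped sire instead contributes (P(her sire transmits h) + freq) / 2.
    Animals (or parents) with missing alleles inside the window are treated
    as uninformative, conservatively.

    ``_ctx`` carries precomputed (sire row index, dam row index, live mask)
    arrays so a scan over many window haplotypes pays the pedigree lookup
    once; it must match ``phased``/``pedigree``.
    """
    if condition_on not in ("parent_genotype", "dam_sire_genotype"):
        raise ValueError(f"unknown conditioning mode {condition_on!r}")
    h = np.asarray(
        [int(c) for c in allele_string] if isinstance(allele_string, str)
        else allele_string,
        dtype=np.int8,
    )
    if len(h) != window.width:
        raise ValueError("allele string length does not match window width")

    W = phased.haplotypes[:, window.first_marker_index : window.last_marker_index + 1]
    informative = ~np.any(W == MISSING, axis=(1, 2))
    match = np.all(W == h[None, :, None], axis=1)  # (n, 2)
    copies = np.where(informative[:, None], match, False).sum(axis=1)  # 0/1/2

    if _ctx is None:
        sire_idx, dam_idx = _parent_index(phased, pedigree)
        live = _live_mask(phased, pedigree)
    else:
        sire_idx, dam_idx, live = _ctx
    scored = live & informative
    n_inf = int(np.count_nonzero(scored))
    total_copies = int(copies[scored].sum())
    freq = total_copies / (2 * n_inf) if n_inf else 0.0

    if total_copies == 0:
        return DeficitResult(
            window, _to_string(h), 0.0, 0, 0.0, 1.0, uninformative=True
        )

    parent_informative = informative

    def transmit(parent_rows: np.ndarray) -> np.ndarray:
        t = np.full(len(parent_rows), freq)
        known = parent_rows >= 0
        rows = parent_rows[known]
        usable = parent_informative[rows]
        t_known = np.where(usable, copies[rows] / 2.0, freq)
        t[known] = t_known
        return t

    t_sire = transmit(sire_idx)
    t_dam = transmit(dam_idx)

    if condition_on == "dam_sire_genotype":
        # for ungenotyped dams, condition on the maternal grandsire instead
        for i, aid in enumerate(phased.animal_ids):
            if dam_idx[i] >= 0 or aid not in pedigree:
                continue
            rec = pedigree[aid]
            if rec.dam_id is None or rec.dam_id not in pedigree:
                continue
            mgs = pedigree[rec.dam_id].sire_id
            if mgs is not None and mgs in phased and parent_informative[
                phased.index_of(mgs)
            ]:
                t_mgs = copies[phased.index_of(mgs)] / 2.0
                t_dam[i] = (t_mgs + freq) / 2.0

    p = np.where(scored, t_sire * t_dam, 0.0)
    expected = float(p.sum())
    observed = int(np.count_nonzero((copies == 2) & scored))
    with np.errstate(divide="ignore"):
        log_pzero = np.log1p(-np.clip(p[scored], 0.0, 1.0)).sum()
    p_zero = float(np.exp(log_pzero)) if np.isfinite(log_pzero) else 0.0
    if np.any(p[scored] >= 1.0):
        p_zero = 0.0
    return DeficitResult(window, _to_string(h), freq, observed, expected, p_zero)


def _to_string(h: np.ndarray) -> str:
    return "".join(str(int(c)) for c in h)


def scan_deficits(
    phased: PhasedGenotypes,
    pedigree: Pedigree,
    mmap: MarkerMap,
    width_markers: int,
    *,
    step: int = 1,
    min_expected: float = 5.0,
    min_frequency: float = 0.01,
    correction: str = "none",
    alpha: float = 0.05,
    condition_on: str = "parent_genotype",
) -> list[DeficitResult]:
    """Scan every window haplotype for missing homozygosity.

    Flags (window, haplotype) pairs with zero observed homozygotes and
    expected count >= ``min_expected``; results are ranked by p_zero
    ascending. Haplotypes below ``min_frequency`` are not tested. With
    ``correction="bonferroni"``, a flag additionally requires
    p_zero <= alpha / n_tested.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(phased.animal_ids) == 0:
        return []
    frames = enumerate_windows(mmap, width_markers, step)
    live = _live_mask(phased, pedigree)
    ctx = (*_parent_index(phased, pedigree), live)
    results: list[DeficitResult] = []
    n_tested = 0
    for frame in frames:
        W = phased.haplotypes[:, frame.first_marker_index : frame.last_marker_index + 1]
        informative = ~np.any(W == MISSING, axis=(1, 2))
        rows = np.flatnonzero(live & informative)
        if not len(rows):
            continue
        n_haps = 2 * len(rows)
        seen: dict[bytes, int] = {}
        for i in rows:
            for k in (0, 1):
                key = W[i, :, k].tobytes()
                seen[key] = seen.get(key, 0) + 1
        for key, count in seen.items():
            if count / n_haps < min_frequency:
                continue
            h = np.frombuffer(key, dtype=np.int8)
            n_tested += 1
            res = expected_homozygotes(
                frame, h, phased, pedigree, condition_on=condition_on, _ctx=ctx
            )
            if res.observed_hom == 0 and res.expected_hom >= min_expected:
                results.append(res)
    if correction == "bonferroni" and n_tested:
        results = [r for r in results if r.p_zero <= alpha / n_tested]
    results.sort(key=lambda r: r.p_zero)
    return results


def cluster_flags(flags: Sequence[DeficitResult]) -> list[DeficitResult]:
    """Collapse overlapping flagged windows into one representative each.

    A sliding scan flags the same deficit in several overlapping windows;
    they are grouped into clusters of mutually overlapping windows per
    chromosome. The representative is the member whose centre lies closest
    to the centre of the cluster's flagged span: the deficit source sits
    inside every flagged member, so the central member frames it with the
    most exclusion evidence on both sides (edge members can place it within
    a couple of markers of their boundary, where downstream trimming and
    status calls are weakest). Clusters are returned in order of their best
    (lowest) p_zero.
    """
    clusters: list[dict] = []
    for f in sorted(
        flags, key=lambda r: (r.window.chrom, r.window.first_marker_index)
    ):
        w = f.window
        for c in clusters:
            if (
                w.chrom == c["chrom"]
                and w.first_marker_index <= c["last"] + 1
                and w.last_marker_index >= c["first"] - 1
            ):
                c["first"] = min(c["first"], w.first_marker_index)
                c["last"] = max(c["last"], w.last_marker_index)
                c["members"].append(f)
                break
        else:
            clusters.append(
                {
                    "chrom": w.chrom,
                    "first": w.first_marker_index,
                    "last": w.last_marker_index,
                    "members": [f],
                }
            )
    reps: list[tuple[float, DeficitResult]] = []
    for c in clusters:
        centre = (c["first"] + c["last"]) / 2
        rep = min(
            c["members"],
            key=lambda f: (
                abs(
                    (f.window.first_marker_index + f.window.last_marker_index) / 2
                    - centre
                ),
                f.p_zero,
            ),
        )
        reps.append((min(m.p_zero for m in c["members"]), rep))
    return [rep for _, rep in sorted(reps, key=lambda t: t[0])]


# ---------------------------------------------------------------------------
# Fertility deficit
# ---------------------------------------------------------------------------


def conception_deficit(matings: Sequence[MatingRecord]) -> FertilityEstimate:
    """Conception-rate deficit of at-risk matings, in percentage points.

    deficit = 100 (p_normal - p_risk); the standard error combines the two
    binomial sampling variances.
    """
    risk = [m for m in matings if m.design_group == "at_risk"]
    normal = [m for m in matings if m.design_group == "normal"]
    if not risk or not normal:
        raise ValueError("both design groups must be non-empty")
    p_risk = sum(m.conceived for m in risk) / len(risk)
    p_norm = sum(m.conceived for m in normal) / len(normal)
    se = 100.0 * sqrt(
        p_risk * (1 - p_risk) / len(risk) + p_norm * (1 - p_norm) / len(normal)
    )
    return FertilityEstimate(
        deficit_pct=100.0 * (p_norm - p_risk),
        se_pct=se,
        n_at_risk=len(risk),
        n_normal=len(normal),
        base_rate_pct=100.0 * p_norm,
        at_risk_rate_pct=100.0 * p_risk,
    )
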