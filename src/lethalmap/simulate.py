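"""Gene-drop simulation of an AI-structured cattle population carrying a
recessive embryonic-lethal haplotype.

The generator produces, from one seed, everything the analysis chain
consumes: a multi-generation pedigree with heavy sire usage, phased
SNP-array genotypes whose founder haplotypes come from a finite pool (which
creates the haplotype sharing the scan relies on), mating records in which
homozygous-lethal conceptuses surface only as conception failures, low-
frequency pre-mutation ancestral copies of the carrier haplotype, exome-like
variant calls with Poisson depth, and a truth set for parameter-recovery
tests.

Lethality is modelled at a causal locus lying between two array markers on
the carrier haplotype; homozygous conceptuses die with probability
``penetrance`` before observation, so genotype tables contain live animals
only - which is precisely what produces "missing homozygotes".
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    Interval,
    MarkerMap,
    MatingRecord,
    Pedigree,
    PedigreeRecord,
    PhasedGenotypes,
    VariantCallSet,
    VariantSite,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic population.

    The defaults describe a dairy-style nucleus: a few dozen heavily used
    sires per generation, a base conception rate of 0.31, full penetrance of
    the lethal, and a founder carrier-haplotype frequency chosen so the
    Mendelian expectation of (unobserved) homozygotes in the final cohort
    lands in the low tens.

    Marker density is a study condition, not a nuisance parameter: with
    sparse markers, successive crossovers in the two map gaps flanking the
    causal position can rebuild the full carrier-haplotype marker sequence
    without the causal allele ("excision recombinants"), producing live
    window homozygotes that defeat a missing-homozygosity scan. The default
    0.25 Mbp spacing keeps that per-replicate probability well below 1%;
    halving n_markers roughly quadruples it.
    """

    seed: int
    n_founder_sires: int = 25
    n_founder_dams: int = 250
    n_generations: int = 4  # bred generations after the founders
    sires_per_generation: int = 25
    daughters_per_sire: int = 48  # matings allocated to each active sire
    n_markers: int = 400
    chrom: str = "8"
    chrom_length_bp: int = 100_000_000
    recomb_rate_cM_per_Mbp: float = 1.0
    founder_pool_size: int = 30
    lethal_pos_bp: int = 45_500_000
    carrier_hap_freq: float = 0.22
    ancestral_copy_freq: float = 0.002
    ancestral_block_markers: int = 8
    base_conception_rate: float = 0.31
    penetrance: float = 1.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    sample_swap_rate: float = 0.0
    exome_depth_mean: float = 45.0
    mapq_low_frac: float = 0.05
    n_background_sites: int = 30

    def __post_init__(self) -> None:
        for name in (
            "carrier_hap_freq",
            "ancestral_copy_freq",
            "base_conception_rate",
            "penetrance",
            "genotype_error_rate",
            "missing_rate",
            "sample_swap_rate",
            "mapq_low_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.carrier_hap_freq + self.ancestral_copy_freq > 1.0:
            raise ValueError("carrier + ancestral haplotype frequency exceeds 1")
        if not 1 <= self.lethal_pos_bp <= self.chrom_length_bp:
            raise ValueError("lethal locus must lie on the simulated chromosome")
        if self.founder_pool_size < 2:
            raise ValueError("founder haplotype pool needs at least 2 haplotypes")
        if self.founder_pool_size > 2 ** min(self.n_markers, 62):
            raise ValueError(
                "more distinct founder haplotypes requested than the marker "
                "map can represent"
            )


@dataclass
class ConceptusRecord:
    mating_index: int
    causal_genotype: int | None  # copies of the lethal allele; None = no conceptus
    fate: str  # "no_conception" | "died" | "live"
    animal_id: str | None = None


@dataclass
class TruthSet:
    causal_site: VariantSite
    carrier_haplotype: np.ndarray  # marker alleles of the risk haplotype
    carriers: set[str]  # live animals with >= 1 mutated copy
    ancestral_carriers: set[str]  # live animals with >= 1 pre-mutation copy
    minimal_interval: Interval  # delimited by historical recombinations
    conceptuses: list[ConceptusRecord] = field(default_factory=list)
    sample_swaps: list[tuple[str, str]] = field(default_factory=list)


class _Animal:
    __slots__ = ("aid", "sex", "haps", "causal", "sire", "dam")

    def __init__(self, aid, sex, haps, causal, sire=None, dam=None):
        self.aid = aid
        self.sex = sex
        self.haps = haps  # (2, m) int8: 0 paternal, 1 maternal
        self.causal = causal  # (2,) bool
        self.sire = sire
        self.dam = dam

    @property
    def n_causal(self) -> int:
        return int(self.causal[0]) + int(self.causal[1])


def _meiosis(
    parent: _Animal,
    marker_pos: np.ndarray,
    chrom_len: int,
    rate_cM_per_Mbp: float,
    lethal_pos: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One gamete: crossovers as a Poisson process along a uniform genetic
    map; the causal allele travels with the segment covering its position."""
    mean_cx = chrom_len / 1e6 * rate_cM_per_Mbp / 100.0
    n_cx = rng.poisson(mean_cx)
    start = rng.integers(2)
    if n_cx == 0:
        return parent.haps[start].copy(), bool(parent.causal[start])
    cx = np.sort(rng.uniform(0, chrom_len, size=n_cx))
    phase = (start + np.searchsorted(cx, marker_pos)) % 2
    alleles = parent.haps[phase, np.arange(len(marker_pos))]
    causal_phase = (start + np.searchsorted(cx, lethal_pos)) % 2
    return alleles.astype(np.int8), bool(parent.causal[causal_phase])


def _founder_haplotype(
    pool: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    causal_marker: int,
) -> tuple[np.ndarray, bool]:
    u = rng.uniform()
    if u < config.carrier_hap_freq:
        return pool[0].copy(), True
    if u < config.carrier_hap_freq + config.ancestral_copy_freq:
        # pre-mutation ancestral copy: shares only a block of the carrier
        # haplotype around the (future) mutation site - older haplotypes have
        # been shortened by historical recombination - and lacks the causal
        # allele. This is what produces live sub-segment homozygotes.
        m = len(pool[0])
        block = min(config.ancestral_block_markers, m)
        # place the block so it straddles the causal position
        start = int(
            np.clip(causal_marker - 1 - rng.integers(0, max(block - 1, 1)), 0, m - block)
        )
        k = rng.integers(1, config.founder_pool_size)
        hap = pool[k].copy()
        hap[start : start + block] = pool[0][start : start + block]
        return hap, False
    k = rng.integers(1, config.founder_pool_size)
    return pool[k].copy(), False


def simulate_population(
    config: SimulationConfig,
) -> tuple[Pedigree, PhasedGenotypes, MarkerMap, list[MatingRecord], TruthSet]:
    """Run the gene-drop simulation; see the module docstring for the model."""
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_founder = np.random.default_rng(streams[0])
    rng_breed = np.random.default_rng(streams[1])
    rng_geno = np.random.default_rng(streams[2])

    m = config.n_markers
    marker_pos = np.linspace(
        config.chrom_length_bp / (m + 1),
        config.chrom_length_bp * m / (m + 1),
        m,
    ).astype(np.int64)
    mmap = MarkerMap(
        marker_ids=[f"M{j:04d}" for j in range(m)],
        chroms=[config.chrom] * m,
        positions=marker_pos,
        alleles=[("A", "B")] * m,
    )

    pool = rng_founder.integers(0, 2, size=(config.founder_pool_size, m)).astype(
        np.int8
    )
    # make the carrier haplotype distinct from every other pool haplotype
    while any(np.array_equal(pool[0], pool[k]) for k in range(1, len(pool))):
        pool[0] = rng_founder.integers(0, 2, size=m).astype(np.int8)

    causal_marker = int(np.searchsorted(marker_pos, config.lethal_pos_bp))

    def make_founder(aid: str, sex: str) -> _Animal:
        while True:
            h0, c0 = _founder_haplotype(pool, config, rng_founder, causal_marker)
            h1, c1 = _founder_haplotype(pool, config, rng_founder, causal_marker)
            if not (c0 and c1):  # a homozygous-lethal founder would not be alive
                return _Animal(aid, sex, np.stack([h0, h1]), np.array([c0, c1]))

    founder_sires = [make_founder(f"FS{i:03d}", "M") for i in range(config.n_founder_sires)]
    founder_dams = [make_founder(f"FD{i:03d}", "F") for i in range(config.n_founder_dams)]
    animals: list[_Animal] = founder_sires + founder_dams

    matings: list[MatingRecord] = []
    conceptuses: list[ConceptusRecord] = []
    males, females = list(founder_sires), list(founder_dams)
    sire_of = {a.aid: None for a in animals}

    for g in range(1, config.n_generations + 1):
        if not males or not females:
            break
        k = min(config.sires_per_generation, len(males))
        active = [males[i] for i in rng_breed.choice(len(males), size=k, replace=False)]
        next_males: list[_Animal] = []
        next_females: list[_Animal] = []
        born = 0
        for sire in active:
            for _ in range(config.daughters_per_sire):
                dam = females[rng_breed.integers(len(females))]
                dam_sire_carrier = bool(
                    sire_of[dam.aid] is not None and sire_of[dam.aid].n_causal > 0
                )
                design = (
                    "at_risk"
                    if sire.n_causal > 0 and dam_sire_carrier
                    else "normal"
                )
                idx = len(matings)
                if rng_breed.uniform() >= config.base_conception_rate:
                    matings.append(MatingRecord(sire.aid, dam.aid, False, design))
                    conceptuses.append(ConceptusRecord(idx, None, "no_conception"))
                    continue
                hp, cp = _meiosis(
                    sire, marker_pos, config.chrom_length_bp,
                    config.recomb_rate_cM_per_Mbp, config.lethal_pos_bp, rng_breed,
                )
                hm, cm = _meiosis(
                    dam, marker_pos, config.chrom_length_bp,
                    config.recomb_rate_cM_per_Mbp, config.lethal_pos_bp, rng_breed,
                )
                genotype = int(cp) + int(cm)
                if genotype == 2 and rng_breed.uniform() < config.penetrance:
                    matings.append(MatingRecord(sire.aid, dam.aid, False, design))
                    conceptuses.append(ConceptusRecord(idx, genotype, "died"))
                    continue
                aid = f"G{g}_{born:05d}"
                born += 1
                sex = "M" if rng_breed.uniform() < 0.5 else "F"
                child = _Animal(
                    aid, sex, np.stack([hp, hm]), np.array([cp, cm]),
                    sire=sire.aid, dam=dam.aid,
                )
                animals.append(child)
                sire_of[aid] = sire
                (next_males if sex == "M" else next_females).append(child)
                matings.append(MatingRecord(sire.aid, dam.aid, True, design))
                conceptuses.append(ConceptusRecord(idx, genotype, "live", aid))
        males, females = next_males, next_females

    pedigree = Pedigree(
        {
            a.aid: PedigreeRecord(
                sire_id=a.sire, dam_id=a.dam, sex=a.sex,
                is_live=True, is_genotyped=True,
            )
            for a in animals
        }
    )

    haps = np.transpose(
        np.stack([a.haps for a in animals]), (0, 2, 1)
    ).astype(np.int8)
    animal_ids = [a.aid for a in animals]

    # genotyping artifacts: allele flips, missing genotypes, sample swaps
    if config.genotype_error_rate > 0:
        flips = rng_geno.uniform(size=haps.shape) < config.genotype_error_rate
        haps = np.where(flips, 1 - haps, haps)
    if config.missing_rate > 0:
        miss = rng_geno.uniform(size=haps.shape[:2]) < config.missing_rate
        haps = np.where(miss[:, :, None], np.int8(-1), haps)
    phased = PhasedGenotypes(animal_ids, haps)

    truth = TruthSet(
        causal_site=VariantSite(config.chrom, config.lethal_pos_bp, "T", "C"),
        carrier_haplotype=pool[0].copy(),
        carriers={a.aid for a in animals if a.n_causal > 0},
        ancestral_carriers={
            a.aid
            for a in animals
            if any(
                not a.causal[k]
                and _is_carrier_sequence_at(a.haps[k], pool[0], marker_pos,
                                            config.lethal_pos_bp)
                for k in (0, 1)
            )
        },
        minimal_interval=_minimal_interval(
            animals, pool[0], marker_pos, config.chrom, config.lethal_pos_bp
        ),
        conceptuses=conceptuses,
    )

    n_swaps = int(config.sample_swap_rate * len(animal_ids) / 2)
    for _ in range(n_swaps):
        i, j = rng_geno.choice(len(animal_ids), size=2, replace=False)
        phased = inject_sample_swap(phased, animal_ids[i], animal_ids[j], truth=truth)

    return pedigree, phased, mmap, matings, truth


def _is_carrier_sequence_at(
    hap: np.ndarray, carrier: np.ndarray, marker_pos: np.ndarray, lethal_pos: int
) -> bool:
    """Does this haplotype match the carrier sequence at the markers flanking
    the causal position? (cheap proxy for carrying the ancestral segment)"""
    j = int(np.searchsorted(marker_pos, lethal_pos))
    lo, hi = max(0, j - 4), min(len(marker_pos), j + 4)
    return bool(np.all(hap[lo:hi] == carrier[lo:hi]))


def _minimal_interval(
    animals: Sequence[_Animal],
    carrier: np.ndarray,
    marker_pos: np.ndarray,
    chrom: str,
    lethal_pos: int,
) -> Interval:
    """Intersection, over live mutated haplotypes, of the maximal marker run
    around the causal position still matching the founder carrier sequence -
    the interval to which historical recombinations confine the mutation."""
    j_right = int(np.searchsorted(marker_pos, lethal_pos))
    j_left = j_right - 1
    best_left, best_right = 0, len(marker_pos) - 1
    found = False
    for a in animals:
        for k in (0, 1):
            if not a.causal[k]:
                continue
            hap = a.haps[k]
            eq = hap == carrier
            if j_left >= 0 and not eq[j_left]:
                continue
            left = j_left
            while left - 1 >= 0 and eq[left - 1]:
                left -= 1
            right = j_right
            while right + 1 < len(eq) and eq[right + 1]:
                right += 1
            best_left = max(best_left, left)
            best_right = min(best_right, right)
            found = True
    if not found or best_left > best_right:
        return Interval(chrom, max(1, lethal_pos - 1), lethal_pos + 1)
    return Interval(chrom, int(marker_pos[best_left]), int(marker_pos[best_right]))


def inject_sample_swap(
    phased: PhasedGenotypes, a: str, b: str, truth: TruthSet | None = None
) -> PhasedGenotypes:
    """Exchange the genotype rows of two animals (a DNA-archive retrieval
    error). Applying the same swap twice restores the original."""
    if a == b:
        raise ValueError("cannot swap an animal with itself")
    for aid in (a, b):
        if aid not in phased:
            raise ValueError(f"unknown animal {aid!r}")
    haps = phased.haplotypes.copy()
    ia, ib = phased.index_of(a), phased.index_of(b)
    haps[[ia, ib]] = haps[[ib, ia]]
    if truth is not None:
        truth.sample_swaps.append((a, b))
    return PhasedGenotypes(list(phased.animal_ids), haps)


# ---------------------------------------------------------------------------
# Exome-like variant calls
# ---------------------------------------------------------------------------


def _site_uniform(seed: int, pos_bp: int, key: str) -> float:
    """Uniform(0,1) deterministic in (seed, site position, key)."""
    digest = hashlib.blake2b(
        f"{seed}:{pos_bp}:{key}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2**64


def simulate_variant_calls(
    truth: TruthSet,
    animals: Sequence[str],
    config: SimulationConfig,
    *,
    interval: Interval | None = None,
    seed_offset: int = 1,
) -> VariantCallSet:
    """Emit per-animal calls at the causal site plus random background sites.

    The causal site is het in carriers and hom-ref elsewhere; background
    sites get Hardy-Weinberg genotypes at a random allele frequency. Depth is
    Poisson(``exome_depth_mean``) per call. Mapping quality is a property of
    the site, not of individual calls - low mapq comes from repetitive or
    poorly assembled regions, which depress every animal's alignments at
    once - so a ``mapq_low_frac`` fraction of background sites is drawn as
    low-mappability (mapq below 20 for all animals). The planted causal site
    is mappable by construction: it stands in for a variant that was in fact
    discoverable by exome sequencing. Genotype errors replace a call with a
    uniformly different genotype.
    """
    if not animals:
        raise ValueError("empty animal subset")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed, seed_offset))
    )
    sites = [truth.causal_site]
    lo = interval.start_bp if interval else 1
    hi = interval.end_bp if interval else config.chrom_length_bp
    span = max(hi - lo, config.n_background_sites + 1)
    bases = "ACGT"
    for pos in sorted(rng.choice(span, size=config.n_background_sites, replace=False)):
        p = int(lo + pos)
        if p == truth.causal_site.pos_bp:
            p += 1
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        sites.append(VariantSite(config.chrom, p, str(ref), str(alt)))

    n_sites, n_animals = len(sites), len(animals)
    gts = np.zeros((n_sites, n_animals), dtype=np.int8)
    for i, aid in enumerate(animals):
        gts[0, i] = HET if aid in truth.carriers else HOM_REF
    # Background genotypes are a deterministic function of (seed, site,
    # animal), so genotyping the same site in a different animal subset -
    # e.g. an exome panel first and a wider validation panel later - gives
    # consistent calls, like re-assaying the same DNA.
    for s in range(1, n_sites):
        maf = _site_uniform(config.seed, sites[s].pos_bp, "maf") * 0.45 + 0.05
        u = np.array(
            [_site_uniform(config.seed, sites[s].pos_bp, aid) for aid in animals]
        )
        gts[s] = np.where(
            u < (1 - maf) ** 2, HOM_REF, np.where(u < 1 - maf**2, HET, HOM_ALT)
        )
    if config.genotype_error_rate > 0:
        err = rng.uniform(size=gts.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=gts.shape)
        gts = np.where(err, (gts + shift) % 3, gts).astype(np.int8)

    depth = rng.poisson(config.exome_depth_mean, size=gts.shape).astype(np.int32)
    low_site = rng.uniform(size=n_sites) < config.mapq_low_frac
    low_site[0] = False  # the causal site is mappable by construction
    site_mq = np.where(low_site, rng.integers(0, 20, size=n_sites), 60)
    mapq = np.broadcast_to(site_mq[:, None], gts.shape).astype(np.int32).copy()
    return VariantCallSet(
        sites=sites,
        animal_ids=list(animals),
        genotypes=gts,
        depth=depth,
        mapq=mapq,
    )


# ---------------------------------------------------------------------------
# Mating-design fertility trial
# ---------------------------------------------------------------------------


def simulate_fertility_trial(
    n_at_risk: int,
    n_normal: int,
    *,
    base_conception_rate: float = 0.31,
    penetrance: float = 1.0,
    seed: int = 0,
) -> list[MatingRecord]:
    """Mechanistic trial of the at-risk mating design.

    Every at-risk mating pairs a heterozygous sire with a daughter of a
    heterozygous sire whose own carrier status is latent (probability 1/2);
    a carrier x carrier conceptus is homozygous with probability 1/4 and
    then dies with probability ``penetrance``, surfacing as a conception
    failure. Normal matings conceive at the base rate.
    """
    rng = np.random.default_rng(seed)
    records: list[MatingRecord] = []
    conceive = rng.uniform(size=n_at_risk) < base_conception_rate
    dam_carrier = rng.uniform(size=n_at_risk) < 0.5
    hom = dam_carrier & (rng.uniform(size=n_at_risk) < 0.25)
    dies = hom & (rng.uniform(size=n_at_risk) < penetrance)
    ok = conceive & ~dies
    for i in range(n_at_risk):
        records.append(MatingRecord("CS", f"RD{i}", bool(ok[i]), "at_risk"))
    normal_ok = rng.uniform(size=n_normal) < base_conception_rate
    for i in range(n_normal):
        records.append(MatingRecord("NS", f"ND{i}", bool(normal_ok[i]), "normal"))
    return records


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Same study conditions, different random stream."""
    return replace(config, seed=seed)
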