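"""File formats and shared domain types for the lethal-haplotype pipeline.

All genomic coordinates are 1-based and intervals are closed on both ends
(the convention SNP-array marker maps and printed haplotype boundaries use).
Converters to and from half-open 0-based BED coordinates live here so the
rest of the pipeline never has to think about the distinction.

Haplotype alleles are encoded as integers over ``{0, 1}`` with ``-1`` as the
single missing sentinel; 0 is the first (reference/major) allele in MAP-file
order, which removes strand ambiguity from every downstream rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1  # single missing-allele sentinel

#: genotype codes used by VariantCallSet
HOM_REF, HET, HOM_ALT, NO_CALL = 0, 1, 2, -1

#: canonical status-group labels for validation genotype-count tables,
#: with the synonyms seen in practice mapped onto them
GROUP_SYNONYMS = {
    "overall": "Overall",
    "carrier": "Carrier",
    "carriers": "Carrier",
    "normal": "Normal",
    "non-carrier": "Normal",
    "non-carriers": "Normal",
    "noncarrier": "Normal",
    "homozygous": "Homozygous",
    "homozygous-subsegment": "Homozygous",
    "unknown": "Unknown",
}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """1-based closed genomic interval."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")
        if self.start_bp < 1:
            raise ValueError("coordinates are 1-based; start_bp must be >= 1")

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos_bp <= self.end_bp

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def interval_to_bed(i: Interval) -> tuple[str, int, int]:
    """Closed 1-based interval -> half-open 0-based BED triple."""
    return (i.chrom, i.start_bp - 1, i.end_bp)


def bed_to_interval(chrom: str, start: int, end: int) -> Interval:
    """Half-open 0-based BED triple -> closed 1-based interval."""
    if end <= start:
        raise ValueError("BED interval must have end > start")
    return Interval(chrom, start + 1, end)


@dataclass
class MarkerMap:
    """Ordered biallelic markers with chromosome and 1-based bp position.

    ``alleles[j]`` gives the two allele symbols of marker ``j`` in MAP-file
    order; haplotype code 0 refers to ``alleles[j][0]``.
    """

    marker_ids: list[str]
    chroms: list[str]
    positions: np.ndarray  # int64, 1-based bp
    alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = len(self.marker_ids)
        if not (len(self.chroms) == len(self.positions) == len(self.alleles) == n):
            raise FormatError("marker map field lengths disagree")
        if len(set(self.marker_ids)) != n:
            raise FormatError("marker ids are not unique")
        if np.any(self.positions < 1):
            raise FormatError("marker positions must be positive (1-based)")
        for j, (a, b) in enumerate(self.alleles):
            if a == b:
                raise FormatError(f"marker {self.marker_ids[j]} is not biallelic")
        for chrom in dict.fromkeys(self.chroms):
            pos = self.positions[[c == chrom for c in self.chroms]]
            if np.any(np.diff(pos) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.marker_ids)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chroms) == chrom)

    def marker_interval(self, first: int, last: int) -> Interval:
        """Closed interval spanned by markers ``first..last`` (inclusive)."""
        if self.chroms[first] != self.chroms[last]:
            raise ValueError("marker range spans chromosomes")
        return Interval(
            self.chroms[first], int(self.positions[first]), int(self.positions[last])
        )


@dataclass(frozen=True)
class PedigreeRecord:
    sire_id: str | None
    dam_id: str | None
    sex: str  # "M" | "F" | "U"
    is_live: bool = True
    is_genotyped: bool = True


class Pedigree:
    """animal_id -> (sire, dam, sex, live/genotyped flags); acyclic by check."""

    def __init__(self, records: Mapping[str, PedigreeRecord]):
        self.records = dict(records)
        for aid, rec in self.records.items():
            for pid in (rec.sire_id, rec.dam_id):
                if pid is not None and pid not in self.records:
                    raise FormatError(f"parent {pid} of {aid} has no record")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(aid: str, stack: list[str]) -> None:
            if state.get(aid) == 1:
                return
            if state.get(aid) == 0:
                raise FormatError(f"pedigree cycle involving {aid}")
            state[aid] = 0
            rec = self.records[aid]
            for pid in (rec.sire_id, rec.dam_id):
                if pid is not None:
                    visit(pid, stack + [aid])
            state[aid] = 1

        for aid in self.records:
            visit(aid, [])

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, aid: str) -> bool:
        return aid in self.records

    def __getitem__(self, aid: str) -> PedigreeRecord:
        return self.records[aid]

    def animal_ids(self) -> list[str]:
        return list(self.records)


@dataclass
class PhasedGenotypes:
    """Phased allele matrix: ``haplotypes[i, j, 0]`` is the paternal allele of
    animal ``i`` at marker ``j``; ``[..., 1]`` the maternal allele.

    Missing is symmetric: a missing genotype sets both strands to ``MISSING``.
    """

    animal_ids: list[str]
    haplotypes: np.ndarray  # (n_animals, n_markers, 2) int8 over {0,1,MISSING}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise FormatError("haplotypes must have shape (n_animals, n_markers, 2)")
        if self.haplotypes.shape[0] != len(self.animal_ids):
            raise FormatError("animal_ids length does not match haplotype rows")
        miss = self.haplotypes == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise FormatError("missing alleles must be missing on both strands")
        self._index = {a: i for i, a in enumerate(self.animal_ids)}
        if len(self._index) != len(self.animal_ids):
            raise FormatError("duplicate animal ids")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def row(self, animal_id: str) -> np.ndarray:
        return self.haplotypes[self._index[animal_id]]

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos_bp: int
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass
class VariantCallSet:
    """Per-site, per-animal genotype calls with read depth and mapping quality."""

    sites: list[VariantSite]
    animal_ids: list[str]
    genotypes: np.ndarray  # (n_sites, n_animals) codes HOM_REF/HET/HOM_ALT/NO_CALL
    depth: np.ndarray  # (n_sites, n_animals) int32, >= 0
    mapq: np.ndarray  # (n_sites, n_animals) int32, >= 0

    def __post_init__(self) -> None:
        shape = (len(self.sites), len(self.animal_ids))
        for name in ("genotypes", "depth", "mapq"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise FormatError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if np.any(self.depth < 0) or np.any(self.mapq < 0):
            raise FormatError("depth and mapq must be non-negative")
        self._animal_index = {a: i for i, a in enumerate(self.animal_ids)}

    def animal_column(self, animal_id: str) -> int:
        return self._animal_index[animal_id]


@dataclass(frozen=True)
class MatingRecord:
    sire_id: str
    dam_id: str
    conceived: bool
    design_group: str  # "normal" | "at_risk"

    def __post_init__(self) -> None:
        if self.design_group not in ("normal", "at_risk"):
            raise ValueError(f"unknown design group {self.design_group!r}")


@dataclass
class GenotypeCountTable:
    """Per-status-group AA/AB/BB/missing counts for one candidate variant.

    "A" is the assembly reference allele and "B" the discovered alternate, as
    on a validation genotyping panel; ``counts[group]`` is
    ``(n_AA, n_AB, n_BB, n_missing)``.
    """

    sv_id: str
    annotation: str
    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    counts: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, row in self.counts.items():
            if group not in GROUP_SYNONYMS.values():
                raise FormatError(f"unknown status group label {group!r}")
            if any(c < 0 for c in row):
                raise FormatError(f"negative count in group {group!r}")

    def group(self, name: str) -> tuple[int, int, int, int]:
        return self.counts[name]

    def consistency_warnings(self) -> list[str]:
        """Soft check: Overall should equal the sum of the other groups.

        Printed validation tables contain small tallying slips, so violations
        are reported as warnings rather than raised.
        """
        if "Overall" not in self.counts or len(self.counts) < 2:
            return []
        warnings = []
        overall = self.counts["Overall"]
        summed = [0, 0, 0, 0]
        for group, row in self.counts.items():
            if group == "Overall":
                continue
            for k in range(4):
                summed[k] += row[k]
        for k, label in enumerate(("AA", "AB", "BB", "missing")):
            if summed[k] != overall[k]:
                warnings.append(
                    f"{self.sv_id}: Overall {label}={overall[k]} but groups sum "
                    f"to {summed[k]}"
                )
        return warnings


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------


def read_ped_map(ped_path, map_path) -> tuple[PhasedGenotypes, MarkerMap]:
    """Read a PLINK-style whitespace-delimited PED plus MAP file.

    The MAP dialect is ``chrom id cM pos [allele0 allele1]``; when the two
    allele columns are absent, allele order is inferred from first appearance
    in the PED. The two PED allele columns per marker are taken as the
    paternal and maternal allele of a phased genotype, mapped to {0,1} by
    MAP allele order; ``0`` in either column marks the genotype missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise FormatError(f"{map_path}:{ln}: expected 4 or 6 MAP columns")
            map_rows.append(parts)

    ped_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2:
                raise FormatError(f"{ped_path}:{ln}: malformed PED row")
            if (len(parts) - 6) // 2 != len(map_rows):
                raise FormatError(
                    f"{ped_path}:{ln}: {(len(parts) - 6) // 2} genotype columns "
                    f"for {len(map_rows)} MAP markers"
                )
            ped_rows.append(parts)

    # resolve allele order per marker
    alleles: list[tuple[str, str]] = []
    for j, row in enumerate(map_rows):
        if len(row) == 6:
            alleles.append((row[4], row[5]))
        else:
            seen: list[str] = []
            for parts in ped_rows:
                for a in parts[6 + 2 * j : 8 + 2 * j]:
                    if a != "0" and a not in seen:
                        seen.append(a)
            if len(seen) > 2:
                raise FormatError(f"marker {row[1]} has >2 alleles in PED")
            while len(seen) < 2:
                seen.append(f"?{len(seen)}")
            alleles.append((seen[0], seen[1]))

    mmap = MarkerMap(
        marker_ids=[r[1] for r in map_rows],
        chroms=[r[0] for r in map_rows],
        positions=np.array([int(r[3]) for r in map_rows], dtype=np.int64),
        alleles=alleles,
    )

    n, m = len(ped_rows), len(map_rows)
    haps = np.full((n, m, 2), MISSING, dtype=np.int8)
    animal_ids = []
    for i, parts in enumerate(ped_rows):
        animal_ids.append(parts[1])
        for j in range(m):
            a, b = parts[6 + 2 * j], parts[7 + 2 * j]
            if a == "0" or b == "0":
                continue
            try:
                haps[i, j, 0] = alleles[j].index(a)
                haps[i, j, 1] = alleles[j].index(b)
            except ValueError as exc:
                raise FormatError(
                    f"{ped_path}: animal {parts[1]} marker {mmap.marker_ids[j]}: "
                    f"allele not in MAP order {alleles[j]}"
                ) from exc
    return PhasedGenotypes(animal_ids, haps), mmap


def write_ped_map(
    phased: PhasedGenotypes,
    mmap: MarkerMap,
    ped_path,
    map_path,
    pedigree: Pedigree | None = None,
) -> None:
    with open(map_path, "w") as fh:
        for j in range(len(mmap)):
            a0, a1 = mmap.alleles[j]
            fh.write(
                f"{mmap.chroms[j]}\t{mmap.marker_ids[j]}\t0\t"
                f"{mmap.positions[j]}\t{a0}\t{a1}\n"
            )
    sex_code = {"M": "1", "F": "2", "U": "0"}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(phased.animal_ids):
            rec = pedigree[aid] if pedigree and aid in pedigree else None
            cols = [
                "0",
                aid,
                rec.sire_id if rec and rec.sire_id else "0",
                rec.dam_id if rec and rec.dam_id else "0",
                sex_code[rec.sex] if rec else "0",
                "-9",
            ]
            for j in range(len(mmap)):
                pair = phased.haplotypes[i, j]
                if pair[0] == MISSING:
                    cols += ["0", "0"]
                else:
                    cols += [mmap.alleles[j][pair[0]], mmap.alleles[j][pair[1]]]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Pedigree / mating CSV
# ---------------------------------------------------------------------------


def read_pedigree_csv(path) -> Pedigree:
    records: dict[str, PedigreeRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records[row["animal_id"]] = PedigreeRecord(
                sire_id=row["sire_id"] or None,
                dam_id=row["dam_id"] or None,
                sex=row.get("sex", "U") or "U",
                is_live=row.get("is_live", "1") in ("1", "True", "true"),
                is_genotyped=row.get("is_genotyped", "1") in ("1", "True", "true"),
            )
    return Pedigree(records)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "sire_id", "dam_id", "sex", "is_live", "is_genotyped"])
        for aid, rec in pedigree.records.items():
            w.writerow(
                [
                    aid,
                    rec.sire_id or "",
                    rec.dam_id or "",
                    rec.sex,
                    int(rec.is_live),
                    int(rec.is_genotyped),
                ]
            )


def read_matings_csv(path) -> list[MatingRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MatingRecord(
                    sire_id=row["sire_id"],
                    dam_id=row["dam_id"],
                    conceived=row["conceived"] in ("1", "True", "true"),
                    design_group=row["design_group"],
                )
            )
    return out


def write_matings_csv(matings: Sequence[MatingRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sire_id", "dam_id", "conceived", "design_group"])
        for m in matings:
            w.writerow([m.sire_id, m.dam_id, int(m.conceived), m.design_group])


# ---------------------------------------------------------------------------
# VCF (minimal VCFv4.2 text subset: GT + DP per sample, MQ from INFO
# or per-sample FORMAT)
# ---------------------------------------------------------------------------

_GT_TO_CODE = {
    "0/0": HOM_REF, "0|0": HOM_REF,
    "0/1": HET, "1/0": HET, "0|1": HET, "1|0": HET,
    "1/1": HOM_ALT, "1|1": HOM_ALT,
    "./.": NO_CALL, ".|.": NO_CALL, ".": NO_CALL,
}
_CODE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", NO_CALL: "./."}


def read_vcf(
    path, *, max_indel_len: int | None = None, missing_dp: str = "zero"
) -> VariantCallSet:
    """Read a minimal text VCF into a :class:`VariantCallSet`.

    Genotypes are normalised to hom_ref/het/hom_alt/missing. Sites whose
    indel length exceeds ``max_indel_len`` (when given) are rejected with a
    :class:`FormatError`. Multi-allelic records are rejected. A record with
    no per-sample DP is treated as depth 0 when ``missing_dp="zero"`` and is
    an error when ``missing_dp="error"``.
    """
    sites: list[VariantSite] = []
    gt_rows, dp_rows, mq_rows = [], [], []
    animal_ids: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise FormatError(f"{path}:{ln}: VCF has no sample columns")
                animal_ids = cols[9:]
                continue
            if not animal_ids:
                raise FormatError(f"{path}:{ln}: record before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(animal_ids):
                raise FormatError(f"{path}:{ln}: wrong number of columns")
            chrom, pos, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            if "," in alt:
                raise FormatError(f"{path}:{ln}: multi-allelic record not supported")
            try:
                site = VariantSite(chrom, int(pos), ref, alt)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad position {pos!r}") from exc
            if max_indel_len is not None and site.indel_len > max_indel_len:
                raise FormatError(
                    f"{path}:{ln}: indel length {site.indel_len} exceeds "
                    f"{max_indel_len}"
                )
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in cols[7].split(";")
                if kv and kv != "."
            )
            site_mq = int(float(info["MQ"])) if "MQ" in info else None
            fmt = cols[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: FORMAT lacks GT") from exc
            dp_i = fmt.index("DP") if "DP" in fmt else None
            mq_i = fmt.index("MQ") if "MQ" in fmt else None
            gts, dps, mqs = [], [], []
            for sample in cols[9:]:
                fields = sample.split(":")
                gt = fields[gt_i]
                if gt not in _GT_TO_CODE:
                    raise FormatError(f"{path}:{ln}: unsupported GT {gt!r}")
                gts.append(_GT_TO_CODE[gt])
                if dp_i is not None and dp_i < len(fields) and fields[dp_i] != ".":
                    dps.append(int(fields[dp_i]))
                elif missing_dp == "zero":
                    dps.append(0)
                else:
                    raise FormatError(f"{path}:{ln}: missing DP")
                if mq_i is not None and mq_i < len(fields) and fields[mq_i] != ".":
                    mqs.append(int(fields[mq_i]))
                elif site_mq is not None:
                    mqs.append(site_mq)
                else:
                    mqs.append(0)
            sites.append(site)
            gt_rows.append(gts)
            dp_rows.append(dps)
            mq_rows.append(mqs)
    return VariantCallSet(
        sites=sites,
        animal_ids=animal_ids,
        genotypes=np.array(gt_rows, dtype=np.int8).reshape(len(sites), -1),
        depth=np.array(dp_rows, dtype=np.int32).reshape(len(sites), -1),
        mapq=np.array(mq_rows, dtype=np.int32).reshape(len(sites), -1),
    )


def write_vcf(calls: VariantCallSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=MQ,Number=1,Type=Integer,Description="Mapping quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.animal_ids)
            + "\n"
        )
        for s, site in enumerate(calls.sites):
            samples = [
                f"{_CODE_TO_GT[int(calls.genotypes[s, i])]}:"
                f"{int(calls.depth[s, i])}:{int(calls.mapq[s, i])}"
                for i in range(len(calls.animal_ids))
            ]
            fh.write(
                f"{site.chrom}\t{site.pos_bp}\t.\t{site.ref}\t{site.alt}\t.\t.\t.\t"
                "GT:DP:MQ\t" + "\t".join(samples) + "\n"
            )


# ---------------------------------------------------------------------------
# Genotype-count tables (validation-panel CSVs)
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = [
    "locus",
    "sv_id",
    "annotation",
    "chrom",
    "pos_bp",
    "ref_allele",
    "alt_allele",
    "group",
    "n_AA",
    "n_AB",
    "n_BB",
    "n_missing",
]


def read_count_table(path) -> dict[str, list[GenotypeCountTable]]:
    """Read validation genotype-count tables from a long-format CSV.

    One row per (candidate variant, status group) with AA/AB/BB/missing
    counts. Returns tables grouped by locus label, in file order.
    """
    by_key: dict[tuple[str, str], GenotypeCountTable] = {}
    locus_of: dict[tuple[str, str], str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "group" not in reader.fieldnames:
            raise FormatError(f"{path}: not a genotype-count CSV")
        for row in reader:
            group_raw = row["group"].strip()
            group = GROUP_SYNONYMS.get(group_raw.lower())
            if group is None:
                raise FormatError(f"{path}: unknown status group {group_raw!r}")
            counts = []
            for col in ("n_AA", "n_AB", "n_BB", "n_missing"):
                value = int(row[col])
                if value < 0:
                    raise FormatError(f"{path}: negative count in {row['sv_id']}")
                counts.append(value)
            key = (row["locus"], row["sv_id"])
            if key not in by_key:
                by_key[key] = GenotypeCountTable(
                    sv_id=row["sv_id"],
                    annotation=row["annotation"],
                    chrom=row["chrom"],
                    pos_bp=int(row["pos_bp"]),
                    ref_allele=row["ref_allele"],
                    alt_allele=row["alt_allele"],
                )
                locus_of[key] = row["locus"]
            by_key[key].counts[group] = tuple(counts)
    if not by_key:
        raise FormatError(f"{path}: empty genotype-count table")
    out: dict[str, list[GenotypeCountTable]] = {}
    for key, table in by_key.items():
        out.setdefault(locus_of[key], []).append(table)
    return out


def write_count_table(tables: Mapping[str, Iterable[GenotypeCountTable]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COUNT_COLUMNS)
        for locus, tabs in tables.items():
            for t in tabs:
                for group, (aa, ab, bb, miss) in t.counts.items():
                    w.writerow(
                        [
                            locus,
                            t.sv_id,
                            t.annotation,
                            t.chrom,
                            t.pos_bp,
                            t.ref_allele,
                            t.alt_allele,
                            group,
                            aa,
                            ab,
                            bb,
                            miss,
                        ]
                    )


# ---------------------------------------------------------------------------
# Packaged data
# ---------------------------------------------------------------------------


def packaged_data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_validation_tables() -> dict[str, list[GenotypeCountTable]]:
    """Transcriptions of the published validation genotyping panels: per-locus
    AA/AB/BB/missing counts for every printed candidate-variant column
    (9 BH1 + 3 HH2 + 14 HH3)."""
    return read_count_table(packaged_data_path("validation_genotype_counts.csv"))


def load_candidate_counts():
    """Published counts of carrier-concordant sequence variants per locus at
    genome / chromosome / locus scope, as a DataFrame."""
    import pandas as pd

    return pd.read_csv(packaged_data_path("candidate_sv_counts.csv"))


def load_locus_intervals() -> dict[str, dict[str, Interval]]:
    """Published original and refined haplotype intervals per locus."""
    out: dict[str, dict[str, Interval]] = {}
    with open(packaged_data_path("locus_intervals.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["locus"], {})[row["stage"]] = Interval(
                row["chrom"], int(row["start_bp"]), int(row["end_bp"])
            )
    return out
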