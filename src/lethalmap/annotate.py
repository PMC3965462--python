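"""Genomic context and protein-level annotation of candidate variants.

Classifies sites against gene models (exonic / intronic / intergenic),
derives coding consequences by strand-aware codon translation, and scores
amino-acid substitutions with the canonical BLOSUM62 matrix and the
Kyte-Doolittle hydropathy scale (both taken from Biopython and restricted
to the 20 standard residues). A negative BLOSUM62 score marks an
evolutionarily disfavoured replacement; a hydropathy sign flip marks a
polarity change - the two reproducible lines of substitution evidence this
package computes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .io_formats import Interval, bed_to_interval

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A (possibly toy) protein-coding gene model.

    ``exons`` are the CDS exons in genomic coordinate order (ascending bp);
    for a complete model the summed exon length is divisible by 3. Exon
    indices reported to callers are 1-based and counted 5'->3' on the coding
    strand, so exon 1 of a minus-strand gene is the right-most genomic exon.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError("exon chromosome differs from gene chromosome")
        starts = [e.start_bp for e in self.exons]
        if sorted(starts) != starts:
            raise ValueError("exons must be in ascending genomic order")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end_bp >= b.start_bp:
                raise ValueError("exons overlap")

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start_bp, self.exons[-1].end_bp)

    @property
    def cds_length(self) -> int:
        return sum(e.end_bp - e.start_bp + 1 for e in self.exons)

    def exon_index(self, pos_bp: int) -> int | None:
        """1-based exon number in 5'->3' coding order, or None if intronic."""
        for i, e in enumerate(self.exons):
            if e.start_bp <= pos_bp <= e.end_bp:
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    def cds_offset(self, pos_bp: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS."""
        if self.strand == "+":
            off = 0
            for e in self.exons:
                if pos_bp > e.end_bp:
                    off += e.end_bp - e.start_bp + 1
                elif pos_bp >= e.start_bp:
                    return off + pos_bp - e.start_bp
                else:
                    return None
            return None
        off = 0
        for e in reversed(self.exons):
            if pos_bp < e.start_bp:
                off += e.end_bp - e.start_bp + 1
            elif pos_bp <= e.end_bp:
                return off + e.end_bp - pos_bp
            else:
                return None
        return None


def read_gene_models_bed(path) -> list[GeneModel]:
    """Read gene models from a BED file with one row per CDS exon
    (0-based half-open; column 4 = gene id, column 6 = strand)."""
    exons: dict[str, list[tuple[str, str, Interval]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track")):
                continue
            chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            exons.setdefault(gene, []).append(
                (chrom, strand, bed_to_interval(chrom, start, end))
            )
    return _assemble_models(exons)


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 CDS/exon features (1-based closed);
    the gene id is taken from the Parent= or ID= attribute."""
    exons: dict[str, list[tuple[str, str, Interval]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] not in ("CDS", "exon"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("Parent", attrs.get("ID", "unknown"))
            exons.setdefault(gene, []).append(
                (parts[0], parts[6], Interval(parts[0], int(parts[3]), int(parts[4])))
            )
    return _assemble_models(exons)


def _assemble_models(
    exons: Mapping[str, list[tuple[str, str, Interval]]]
) -> list[GeneModel]:
    models = []
    for gene, rows in exons.items():
        rows = sorted(rows, key=lambda r: r[2].start_bp)
        models.append(
            GeneModel(
                gene_id=gene,
                chrom=rows[0][0],
                strand=rows[0][1],
                exons=[r[2] for r in rows],
            )
        )
    return models


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteClass:
    kind: str  # "intergenic" | "intronic" | "exonic"
    gene_id: str | None = None
    exon_index: int | None = None  # 1-based, 5'->3' on the coding strand


def classify_site(
    chrom: str, pos_bp: int, models: Sequence[GeneModel]
) -> list[SiteClass]:
    """Classify a genomic position against gene models.

    Exonic if inside any exon, intronic if inside a gene span but no exon,
    else intergenic. Overlapping genes each contribute a classification.
    """
    hits: list[SiteClass] = []
    chrom_seen = False
    for model in models:
        if model.chrom != chrom:
            continue
        chrom_seen = True
        if not model.span.contains(chrom, pos_bp):
            continue
        idx = model.exon_index(pos_bp)
        if idx is not None:
            hits.append(SiteClass("exonic", model.gene_id, idx))
        else:
            hits.append(SiteClass("intronic", model.gene_id))
    if not hits:
        if models and not chrom_seen:
            warnings.warn(
                f"chromosome {chrom} absent from gene models; "
                "classifying as intergenic",
                stacklevel=2,
            )
        return [SiteClass("intergenic")]
    return hits


# ---------------------------------------------------------------------------
# Coding consequence
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionReport:
    label: str  # e.g. "F1135S"
    consequence: str  # intergenic | intronic | synonymous | non_synonymous | other
    ref_aa: str | None = None
    alt_aa: str | None = None
    aa_pos: int | None = None  # 1-based residue number
    blosum62: int | None = None
    hydropathy_ref: float | None = None
    hydropathy_alt: float | None = None
    conservation: tuple[int, int] | None = None


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def coding_consequence(
    chrom: str,
    pos_bp: int,
    ref_base: str,
    alt_base: str,
    model: GeneModel,
    transcript_seq: str,
) -> SubstitutionReport:
    """Locate the codon of a SNP within a spliced CDS and translate it.

    ``transcript_seq`` is the spliced CDS on the coding strand (starts with
    the initiator codon); ``ref_base``/``alt_base`` are given on the genome
    forward strand and are reverse-complemented for minus-strand genes.
    """
    if chrom != model.chrom:
        raise ValueError("site chromosome does not match the gene model")
    if len(transcript_seq) != model.cds_length:
        raise ValueError(
            f"transcript length {len(transcript_seq)} does not match "
            f"CDS length {model.cds_length}"
        )
    if len(ref_base) != 1 or len(alt_base) != 1:
        raise ValueError("coding_consequence handles single-base substitutions")
    offset = model.cds_offset(pos_bp)
    if offset is None:
        return SubstitutionReport(label="", consequence="other")
    seq = transcript_seq.upper()
    ref_cds = ref_base.upper()
    alt_cds = alt_base.upper()
    if model.strand == "-":
        ref_cds = _COMPLEMENT[ref_cds]
        alt_cds = _COMPLEMENT[alt_cds]
    if seq[offset] != ref_cds:
        raise ValueError(
            f"transcript base {seq[offset]} at CDS offset {offset} does not "
            f"match reference allele {ref_cds} (coding strand)"
        )
    codon_i = offset // 3
    within = offset % 3
    codon = seq[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:
        return SubstitutionReport(label="", consequence="other")
    alt_codon = codon[:within] + alt_cds + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    consequence = "synonymous" if ref_aa == alt_aa else "non_synonymous"
    report = SubstitutionReport(
        label=f"{ref_aa}{codon_i + 1}{alt_aa}",
        consequence=consequence,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        aa_pos=codon_i + 1,
    )
    if consequence == "non_synonymous" and {ref_aa, alt_aa} <= STANDARD_AA:
        report.blosum62 = blosum62_score(ref_aa, alt_aa)
        report.hydropathy_ref = hydropathy(ref_aa)
        report.hydropathy_alt = hydropathy(alt_aa)
    return report


# ---------------------------------------------------------------------------
# Substitution scores
# ---------------------------------------------------------------------------


def blosum62_score(aa_ref: str, aa_alt: str) -> int:
    """Symmetric BLOSUM62 log-odds score for a residue replacement."""
    a, b = aa_ref.upper(), aa_alt.upper()
    for aa in (a, b):
        if aa not in STANDARD_AA:
            raise ValueError(f"{aa!r} is not a standard amino-acid letter")
    return int(_BLOSUM62[a, b])


def hydropathy(aa: str) -> float:
    """Kyte-Doolittle hydropathy index; positive = hydrophobic/non-polar."""
    a = aa.upper()
    if a not in STANDARD_AA:
        raise ValueError(f"{a!r} is not a standard amino-acid letter")
    return float(_KYTE_DOOLITTLE[a])


def conservation_column(
    column: Mapping[str, str], ref_species: str
) -> tuple[int, int, list[tuple[str, str]]]:
    """Tally cross-species conservation of one alignment column.

    Returns ``(n_matching, n_total, exceptions)`` where ``n_matching`` counts
    species (including the reference) whose residue equals the reference
    residue and ``exceptions`` lists the divergent species with their
    residues. Gap characters are excluded from the tally.
    """
    if ref_species not in column:
        raise ValueError(f"reference species {ref_species!r} not in column")
    residues = {sp: aa.upper() for sp, aa in column.items()}
    non_gap = {sp: aa for sp, aa in residues.items() if aa not in ("-", ".")}
    if not non_gap:
        raise ValueError("gap-only alignment column")
    if len(non_gap) < 2:
        raise ValueError("conservation needs at least 2 non-gap species")
    ref_aa = non_gap.get(ref_species)
    if ref_aa is None:
        raise ValueError(f"reference species {ref_species!r} is gapped")
    exceptions = [(sp, aa) for sp, aa in non_gap.items() if aa != ref_aa]
    return len(non_gap) - len(exceptions), len(non_gap), exceptions


def load_orthologue_column_csv(path) -> dict[str, str]:
    """Read a species,residue CSV into an alignment-column mapping."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["species"]] = row["residue"]
    return out
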