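import numpy as np
import pytest

from lethalmap.finemap import (
    HaplotypeStatusTable,
    LocusStatus,
    call_carrier_status,
    check_identity,
    classify_subsegment,
    detect_crossovers,
    extend_haplotype,
    interval_length_mbp,
    read_status_csv,
    refine_interval,
    write_status_csv,
)
from lethalmap.haploscan import HaplotypeWindow
from lethalmap.io_formats import Interval, load_locus_intervals

from conftest import make_marker_map, make_population

# 10-marker target haplotype used throughout
H = "1011010011"
W = HaplotypeWindow("8", 0, 9)


def family(children):
    base = {
        "S": (H, "0000000000"),        # carrier sire
        "D": ("0110101100", "0101010101"),
    }
    base.update(children)
    parents = {c: ("S", "D") for c in children}
    return make_population(base, parents=parents)


class TestCarrierStatus:
    def test_basic_classes(self):
        phased, pedigree = family({
            "C_car": (H, "0110101100"),
            "C_non": ("0110101100", "0101010101"),
            "C_mis": (H[:5] + ".0011", "01101.1100"),
        })
        statuses = call_carrier_status(phased, pedigree, W, H)
        assert statuses["C_car"] == "carrier"
        assert statuses["C_non"] == "non_carrier"
        assert statuses["C_mis"] == "unknown"
        assert statuses["S"] == "carrier"

    def test_subsegment_homozygote(self):
        # both strands share an 8-marker interior run of H
        sub0 = H[:8] + "00"
        sub1 = H[:8] + "10"
        phased, pedigree = family({"C_sub": (sub0, sub1)})
        statuses = call_carrier_status(phased, pedigree, W, H,
                                       min_subsegment_markers=8)
        assert statuses["C_sub"] == "homozygous_subsegment"

    def test_two_full_copies_reported_as_subsegment(self):
        phased, pedigree = family({"C_hom": (H, H)})
        statuses = call_carrier_status(phased, pedigree, W, H)
        assert statuses["C_hom"] == "homozygous_subsegment"

    def test_end_anchored_partial_match_is_ambiguous(self):
        # single strand matching the last 8 markers of H: possible
        # recombinant carrier, must not be declared non-carrier
        frag = "00" + H[2:]
        phased, pedigree = family({"C_frag": (frag, "0101010101")})
        statuses = call_carrier_status(phased, pedigree, W, H,
                                       ambiguous_end_markers=8)
        assert statuses["C_frag"] == "unknown"
        # with a stricter threshold the same animal is a non-carrier
        # (the chance match at marker 1 makes the actual suffix run 9)
        statuses = call_carrier_status(phased, pedigree, W, H,
                                       ambiguous_end_markers=10)
        assert statuses["C_frag"] == "non_carrier"

    def test_dead_animals_excluded(self):
        phased, pedigree = family({"C_dead": (H, H)})
        pedigree.records["C_dead"] = pedigree.records["C_dead"].__class__(
            "S", "D", "U", is_live=False)
        statuses = call_carrier_status(phased, pedigree, W, H)
        assert "C_dead" not in statuses


class TestExtendHaplotype:
    def test_majority_vote_over_matching_strands(self):
        inner = HaplotypeWindow("8", 2, 7)
        h = H[2:8]
        phased, _ = make_population({
            "A1": (H, "0000000000"),
            "A2": ("11" + H[2:8] + "00", "0101010101"),
            "A3": (H, "0110101100"),
        })
        mmap = make_marker_map(10)
        ext_w, ext_h = extend_haplotype(phased, mmap, inner, h, n_markers=2)
        assert (ext_w.first_marker_index, ext_w.last_marker_index) == (0, 9)
        # majority of the three matching strands equals H at the flanks
        assert ext_h == H

    def test_no_matching_strand_raises(self):
        phased, _ = make_population({"A1": ("0000000000", "0000000000")})
        with pytest.raises(ValueError):
            extend_haplotype(phased, make_marker_map(10), W, H)


class TestCrossoversAndRefine:
    def test_trim_requires_carrier_parent(self):
        # C_rec is a carrier whose maternal strand matches the first 4
        # markers of H, but the dam is not a carrier: no crossover evidence
        phased, pedigree = family({"C_rec": (H, H[:4] + "101100")})
        assert detect_crossovers(phased, pedigree, W, H) == []
        # with an H-carrying dam the same pattern is a left crossover
        phased2, pedigree2 = make_population(
            {
                "S": (H, "0000000000"),
                "D2": (H, "0101010101"),
                "C_rec": (H, H[:4] + "101100"),
            },
            parents={"C_rec": ("S", "D2")},
        )
        cx = detect_crossovers(phased2, pedigree2, W, H)
        assert [(c.animal_id, c.side, c.first, c.last) for c in cx] \
            == [("C_rec", "left", 0, 3)]

    def test_refine_trims_supported_runs(self):
        mmap = make_marker_map(10)
        phased, pedigree = make_population(
            {
                "S": (H, "0000000000"),
                "D2": (H, "0101010101"),
                "C_a": (H, H[:4] + "101100"),
                "C_b": (H, H[:3] + "0101100"),
                "C_c": (H, "0110101" + H[7:]),
            },
            parents={c: ("S", "D2") for c in ("C_a", "C_b", "C_c")},
        )
        cx = detect_crossovers(phased, pedigree, W, H)
        refined = refine_interval(W, mmap, cx, min_support=1)
        # left trim = deepest left run (4), right trim = 3
        assert refined.refined_window.first_marker_index == 4
        assert refined.refined_window.last_marker_index == 6
        # with min_support=2 only the left side has two supporters (depth 3)
        refined2 = refine_interval(W, mmap, cx, min_support=2)
        assert refined2.refined_window.first_marker_index == 3
        assert refined2.refined_window.last_marker_index == 9
        # trim_margin backs the trim off
        refined3 = refine_interval(W, mmap, cx, min_support=1, trim_margin=2)
        assert refined3.refined_window.first_marker_index == 2
        assert refined3.refined_window.last_marker_index == 8

    def test_conservative_interval_extends_into_gaps(self):
        mmap = make_marker_map(10)
        phased, pedigree = make_population(
            {
                "S": (H, "0000000000"),
                "D2": (H, "0101010101"),
                "C_a": (H, H[:4] + "101100"),
            },
            parents={"C_a": ("S", "D2")},
        )
        cx = detect_crossovers(phased, pedigree, W, H)
        refined = refine_interval(W, mmap, cx, min_support=1)
        assert refined.refined.start_bp == int(mmap.positions[4])
        # conservative bound reaches into the gap after the last trimmed marker
        assert refined.refined_conservative.start_bp == int(mmap.positions[3]) + 1

    def test_full_trim_raises(self):
        mmap = make_marker_map(10)
        phased, pedigree = make_population(
            {
                "S": (H, "0000000000"),
                "D2": (H, "0101010101"),
                "C_a": (H, H),  # full double copy: never trims
                "C_b": (H, H[:9] + "0"),   # left run of 9
                "C_c": (H, "0" + H[1:]),   # right run of 9
            },
            parents={c: ("S", "D2") for c in ("C_a", "C_b", "C_c")},
        )
        cx = detect_crossovers(phased, pedigree, W, H)
        with pytest.raises(ValueError):
            refine_interval(W, mmap, cx, min_support=1)

    def test_refine_without_crossovers_is_identity(self):
        mmap = make_marker_map(10)
        refined = refine_interval(W, mmap, [], min_support=1)
        assert refined.refined == refined.original
        assert refined.trims == []


class TestClassifySubsegment:
    def test_het_at_causal_site_is_ancestral(self):
        assert classify_subsegment(
            is_live=True, homozygous_range=(0, 9), window=W,
            causal_genotype=1) == "ancestral_copy"

    def test_live_full_homozygote_is_violation(self):
        assert classify_subsegment(
            is_live=True, homozygous_range=(0, 9), window=W,
            causal_genotype=None) == "true_homozygote_violation"

    def test_partial_live_block_defaults_to_ancestral(self):
        assert classify_subsegment(
            is_live=True, homozygous_range=(2, 9), window=W,
            causal_genotype=None) == "ancestral_copy"

    def test_range_outside_window_rejected(self):
        with pytest.raises(ValueError):
            classify_subsegment(is_live=True, homozygous_range=(0, 10),
                                window=W)


class TestIdentity:
    def test_true_parentage_confirmed(self):
        phased, pedigree = make_population(
            {"S": ("1111100000", "1111100000"),
             "C": ("1111100000", "1111100110")},
            parents={"C": ("S", None)},
        )
        res = check_identity("C", phased, pedigree)
        assert res.verdict == "confirmed" and res.opposing_rate == 0.0
        assert res.n_informative == 8  # markers where both are homozygous

    def test_swapped_sample_flagged(self):
        # child homozygous opposite to its recorded sire at many markers
        phased, pedigree = make_population(
            {"S": ("1111111111", "1111111111"),
             "C": ("0000000000", "0000000000")},
            parents={"C": ("S", None)},
        )
        res = check_identity("C", phased, pedigree)
        assert res.verdict == "mismatch" and res.opposing_rate == 1.0

    def test_no_genotyped_parent_uninformative(self):
        phased, pedigree = make_population({"A": (H, H)})
        assert check_identity("A", phased, pedigree).verdict == "uninformative"


class TestStatusCsv:
    def test_round_trip(self, tmp_path):
        table = HaplotypeStatusTable()
        table.add(LocusStatus("L1", W, H, {"A": "carrier", "B": "unknown"}))
        write_status_csv(table, tmp_path / "s.csv")
        assert read_status_csv(tmp_path / "s.csv") == {
            "L1": {"A": "carrier", "B": "unknown"}}


class TestIntervalLength:
    def test_printed_refined_intervals(self):
        intervals = load_locus_intervals()
        assert interval_length_mbp(intervals["HH2"]["refined"]) == 1.7
        assert interval_length_mbp(intervals["HH3"]["refined"]) == 0.4

    def test_rounding(self):
        assert interval_length_mbp(Interval("1", 1, 1_250_001)) == 1.2
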