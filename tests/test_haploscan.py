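import itertools

import numpy as np
import pytest

from lethalmap.haploscan import (
    DeficitResult,
    HaplotypeWindow,
    cluster_flags,
    conception_deficit,
    enumerate_windows,
    expected_homozygotes,
    scan_deficits,
)
from lethalmap.io_formats import MatingRecord
from lethalmap.simulate import SimulationConfig, simulate_population

from conftest import make_marker_map, make_population


def brute_force_expectation(window, h, phased, pedigree):
    """Exhaustive oracle: per live animal, enumerate the four equally likely
    parental strand transmissions; an ungenotyped parent transmits h with
    the population haplotype frequency."""
    first, last = window.first_marker_index, window.last_marker_index
    W = phased.haplotypes[:, first : last + 1]
    hv = np.array([int(c) for c in h], dtype=np.int8)

    def informative(i):
        return not np.any(W[i] == -1)

    def copies(i):
        return sum(bool(np.all(W[i, :, k] == hv)) for k in (0, 1))

    live = [i for i, a in enumerate(phased.animal_ids)
            if pedigree[a].is_live and informative(i)]
    freq = sum(copies(i) for i in live) / (2 * len(live))

    total = 0.0
    p_zero = 1.0
    observed = 0
    for i in live:
        aid = phased.animal_ids[i]
        rec = pedigree[aid]
        probs = []
        for pid in (rec.sire_id, rec.dam_id):
            if pid is None or pid not in phased or not informative(
                    phased.index_of(pid)):
                probs.append(freq)
            else:
                j = phased.index_of(pid)
                # enumerate the two transmissible strands
                hits = [bool(np.all(W[j, :, k] == hv)) for k in (0, 1)]
                probs.append(sum(hits) / 2.0)
        p = probs[0] * probs[1]
        total += p
        p_zero *= 1 - p
        observed += copies(i) == 2
    return total, observed, p_zero


HAP = "1011"


def small_family():
    # sires S1 (one copy of HAP), S2 (none); dams D1 (one copy), D2 (two...
    # impossible for a lethal, so keep one copy), D3 none.
    return make_population(
        {
            "S1": (HAP, "0000"),
            "S2": ("0100", "0010"),
            "D1": (HAP, "1110"),
            "D2": ("0001", HAP),
            "D3": ("0110", "0000"),
            "C1": (HAP, "1110"),   # S1 x D1
            "C2": ("0000", HAP),   # S1 x D2
            "C3": ("0100", "0110"),  # S2 x D3
            "C4": ("0010", "0000"),  # S2 x D1
        },
        parents={
            "C1": ("S1", "D1"), "C2": ("S1", "D2"),
            "C3": ("S2", "D3"), "C4": ("S2", "D1"),
        },
    )


class TestExpectedHomozygotes:
    def test_matches_exhaustive_enumeration_on_small_pedigree(self):
        phased, pedigree = small_family()
        window = HaplotypeWindow("8", 0, 3)
        res = expected_homozygotes(window, HAP, phased, pedigree)
        exp, obs, p_zero = brute_force_expectation(window, HAP, phased,
                                                   pedigree)
        assert res.expected_hom == pytest.approx(exp)
        assert res.observed_hom == obs
        assert res.p_zero == pytest.approx(p_zero)

    def test_oracle_over_random_small_pedigrees(self):
        rng = np.random.default_rng(0)
        for trial in range(25):
            n_founders, n_children = 4, 6  # 10 animals <= 12
            haps = {}
            parents = {}
            for f in range(n_founders):
                strands = rng.integers(0, 2, size=(2, 4))
                # seed the target haplotype into some founders
                if rng.uniform() < 0.5:
                    strands[0] = [int(c) for c in HAP]
                haps[f"F{f}"] = ("".join(map(str, strands[0])),
                                 "".join(map(str, strands[1])))
            for c in range(n_children):
                s, d = rng.choice(n_founders, size=2, replace=False)
                strands = rng.integers(0, 2, size=(2, 4))
                haps[f"C{c}"] = ("".join(map(str, strands[0])),
                                 "".join(map(str, strands[1])))
                parents[f"C{c}"] = (f"F{s}", f"F{d}")
            phased, pedigree = make_population(haps, parents=parents)
            window = HaplotypeWindow("8", 0, 3)
            res = expected_homozygotes(window, HAP, phased, pedigree)
            exp, obs, p_zero = brute_force_expectation(window, HAP, phased,
                                                       pedigree)
            assert res.expected_hom == pytest.approx(exp), f"trial {trial}"
            assert res.observed_hom == obs
            assert res.p_zero == pytest.approx(p_zero)

    def test_closed_form_p_zero_on_20_mating_toy(self):
        # 20 offspring of het x het matings: p_i = 1/4 each, so
        # P(no homozygote) = 0.75^20. The het parents get dead non-carrier
        # parents of their own so their transmission terms are exactly zero
        # and the product is the clean closed form.
        haps = {"S": (HAP, "0000"), "D": (HAP, "0100")}
        live = {}
        for g in ("GSa", "GSb", "GDa", "GDb"):
            haps[g] = ("0000", "0110")
            live[g] = False
        parents = {"S": ("GSa", "GSb"), "D": ("GDa", "GDb")}
        for k in range(20):
            haps[f"C{k}"] = ("0000", "0100")  # alive, not homozygous
            parents[f"C{k}"] = ("S", "D")
        phased, pedigree = make_population(haps, parents=parents, live=live)
        res = expected_homozygotes(HaplotypeWindow("8", 0, 3), HAP, phased,
                                   pedigree)
        assert res.p_zero == pytest.approx(0.75**20)
        assert res.expected_hom == pytest.approx(20 * 0.25)

    def test_dead_animals_are_not_counted(self):
        haps = {"S": (HAP, "0000"), "D": (HAP, "0100"),
                "C": (HAP, HAP)}
        phased, pedigree = make_population(
            haps, parents={"C": ("S", "D")}, live={"C": False})
        res = expected_homozygotes(HaplotypeWindow("8", 0, 3), HAP, phased,
                                   pedigree)
        # the dead double-copy animal C is neither observed nor expected;
        # only the two live het founders contribute (freq^2 = 0.25 each)
        assert res.observed_hom == 0
        assert res.expected_hom == pytest.approx(0.5)

    def test_unknown_haplotype_uninformative(self):
        phased, pedigree = small_family()
        res = expected_homozygotes(HaplotypeWindow("8", 0, 3), "1111", phased,
                                   pedigree)
        assert res.uninformative and res.expected_hom == 0.0


class TestWindows:
    def test_enumerate_windows_step_and_trailing(self):
        mmap = make_marker_map(10)
        frames = enumerate_windows(mmap, 4, step=3)
        assert [(f.first_marker_index, f.last_marker_index) for f in frames] \
            == [(0, 3), (3, 6), (6, 9)]

    def test_width_validation(self):
        with pytest.raises(ValueError):
            enumerate_windows(make_marker_map(5), 1)


class TestClusterFlags:
    @staticmethod
    def flag(first, last, p_zero, chrom="8"):
        return DeficitResult(HaplotypeWindow(chrom, first, last), "0" * 4,
                             0.2, 0, 10.0, p_zero)

    def test_overlapping_flags_collapse_to_central(self):
        flags = [self.flag(0, 19, 1e-9), self.flag(5, 24, 1e-8),
                 self.flag(10, 29, 1e-7)]
        reps = cluster_flags(flags)
        assert len(reps) == 1
        assert reps[0].window.first_marker_index == 5  # central member

    def test_disjoint_clusters_ranked_by_best_p_zero(self):
        flags = [self.flag(0, 9, 1e-3), self.flag(50, 59, 1e-12)]
        reps = cluster_flags(flags)
        assert [r.window.first_marker_index for r in reps] == [50, 0]

    def test_different_chromosomes_never_merge(self):
        flags = [self.flag(0, 9, 1e-3), self.flag(0, 9, 1e-4, chrom="9")]
        assert len(cluster_flags(flags)) == 2


class TestScanDeficits:
    def test_null_population_yields_no_flags(self):
        # penetrance 0: homozygotes live, so nothing is missing
        cfg = SimulationConfig(seed=4, penetrance=0.0, n_founder_sires=5,
                               n_founder_dams=40, n_generations=2,
                               sires_per_generation=5, daughters_per_sire=30,
                               n_markers=60)
        pedigree, phased, mmap, _, _ = simulate_population(cfg)
        flags = scan_deficits(phased, pedigree, mmap, 20, step=5)
        assert flags == []

    def test_bonferroni_is_a_subset(self):
        cfg = SimulationConfig(seed=4, n_founder_sires=5, n_founder_dams=40,
                               n_generations=2, sires_per_generation=5,
                               daughters_per_sire=30, n_markers=60)
        pedigree, phased, mmap, _, _ = simulate_population(cfg)
        plain = scan_deficits(phased, pedigree, mmap, 20, step=5)
        strict = scan_deficits(phased, pedigree, mmap, 20, step=5,
                               correction="bonferroni")
        plain_keys = {(f.window, f.allele_string) for f in plain}
        assert {(f.window, f.allele_string) for f in strict} <= plain_keys


class TestConceptionDeficit:
    def test_hand_counts(self):
        matings = (
            [MatingRecord("S", f"R{i}", i < 25, "at_risk") for i in range(100)]
            + [MatingRecord("S", f"N{i}", i < 31, "normal") for i in range(100)]
        )
        est = conception_deficit(matings)
        assert est.deficit_pct == pytest.approx(6.0)
        assert est.n_at_risk == 100 and est.n_normal == 100
        assert est.base_rate_pct == pytest.approx(31.0)

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            conception_deficit([MatingRecord("S", "D", True, "normal")])
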