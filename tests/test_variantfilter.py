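import itertools

import numpy as np
import pytest

from lethalmap.io_formats import (
    GenotypeCountTable,
    HET,
    HOM_ALT,
    HOM_REF,
    Interval,
    NO_CALL,
    VariantCallSet,
    VariantSite,
)
from lethalmap.variantfilter import (
    ConcordancePolicy,
    FilterThresholds,
    count_by_scope,
    counts_from_genotypes,
    filter_candidates,
    judge_concordance,
    resolve_discordances,
)


def make_calls(genotypes, depth=None, mapq=None, sites=None, animals=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_animals = genotypes.shape
    if sites is None:
        sites = [VariantSite("8", 1000 * (s + 1), "T", "C")
                 for s in range(n_sites)]
    animals = animals or [f"A{i}" for i in range(n_animals)]
    depth = np.full_like(genotypes, 30, dtype=np.int32) if depth is None \
        else np.asarray(depth, dtype=np.int32)
    mapq = np.full_like(genotypes, 60, dtype=np.int32) if mapq is None \
        else np.asarray(mapq, dtype=np.int32)
    return VariantCallSet(sites=list(sites), animal_ids=list(animals),
                          genotypes=genotypes, depth=depth, mapq=mapq)


IV = Interval("8", 500, 5000)


class TestFilterCandidates:
    STATUSES = {"A0": "carrier", "A1": "carrier", "A2": "non_carrier",
                "A3": "homozygous_subsegment", "A4": "unknown"}

    def test_concordant_site_survives_with_scope(self):
        calls = make_calls([[HET, HET, HOM_REF, HET, HOM_ALT]])
        out = filter_candidates(calls, self.STATUSES, "L1",
                                refined_interval=IV)
        assert len(out) == 1 and out[0].scope == "locus"

    def test_low_depth_in_one_animal_drops_site(self):
        # a single carrier at depth 3 removes the whole site
        depth = np.full((1, 5), 30)
        depth[0, 1] = 3
        calls = make_calls([[HET, HET, HOM_REF, HET, HOM_REF]], depth=depth)
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []

    def test_depth_of_unknown_animal_is_ignored(self):
        depth = np.full((1, 5), 30)
        depth[0, 4] = 0  # unknown-status animal
        calls = make_calls([[HET, HET, HOM_REF, HET, HOM_REF]], depth=depth)
        assert len(filter_candidates(calls, self.STATUSES, "L1",
                                     refined_interval=IV)) == 1

    def test_low_mapq_drops_site(self):
        mapq = np.full((1, 5), 60)
        mapq[0, 2] = 19
        calls = make_calls([[HET, HET, HOM_REF, HET, HOM_REF]], mapq=mapq)
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []

    def test_reporting_depth_stricter_than_calling_depth(self):
        depth = np.full((1, 5), 8)  # callable but below the >8 reporting rule
        calls = make_calls([[HET, HET, HOM_REF, HET, HOM_REF]], depth=depth)
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []
        relaxed = FilterThresholds(min_depth_report=8)
        assert len(filter_candidates(calls, self.STATUSES, "L1",
                                     thresholds=relaxed,
                                     refined_interval=IV)) == 1

    def test_carrier_not_het_drops_site(self):
        calls = make_calls([[HET, HOM_REF, HOM_REF, HET, HOM_REF]])
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []

    def test_subsegment_hom_alt_drops_site(self):
        calls = make_calls([[HET, HET, HOM_REF, HOM_ALT, HOM_REF]])
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []

    def test_noncarrier_no_call_needs_flag(self):
        calls = make_calls([[HET, HET, NO_CALL, HET, HOM_REF]])
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []
        out = filter_candidates(calls, self.STATUSES, "L1",
                                refined_interval=IV,
                                allow_missing_noncarrier=True)
        assert len(out) == 1

    def test_long_indel_excluded(self):
        sites = [VariantSite("8", 1000, "T", "TACGTACG")]
        calls = make_calls([[HET, HET, HOM_REF, HET, HOM_REF]], sites=sites)
        assert filter_candidates(calls, self.STATUSES, "L1",
                                 refined_interval=IV) == []

    def test_scope_tiers(self):
        sites = [VariantSite("8", 1000, "T", "C"),       # in interval
                 VariantSite("8", 900_000, "T", "C"),    # same chromosome
                 VariantSite("12", 1000, "T", "C")]      # elsewhere
        gts = [[HET, HET, HOM_REF, HET, HOM_REF]] * 3
        out = filter_candidates(make_calls(gts, sites=sites), self.STATUSES,
                                "L1", refined_interval=IV)
        assert [c.scope for c in out] == ["locus", "chromosome", "genome"]
        df = count_by_scope(out)
        assert df.loc["L1"].tolist() == [3, 2, 1]  # nested totals

    def test_no_carriers_rejected(self):
        calls = make_calls([[HOM_REF]], animals=["A2"])
        with pytest.raises(ValueError):
            filter_candidates(calls, {"A2": "non_carrier"}, "L1",
                              refined_interval=IV)

    def test_missing_status_rejected(self):
        calls = make_calls([[HET, HET]], animals=["A0", "ZZ"])
        with pytest.raises(ValueError):
            filter_candidates(calls, {"A0": "carrier"}, "L1",
                              refined_interval=IV)


def table(carrier, normal, homozygous=None, unknown=None):
    counts = {"Carrier": carrier, "Normal": normal}
    if homozygous:
        counts["Homozygous"] = homozygous
    if unknown:
        counts["Unknown"] = unknown
    return GenotypeCountTable("sv", "", "8", 1, "A", "B", counts=counts)


class TestJudgeConcordance:
    def test_clean_table_concordant_risk_b(self):
        v = judge_concordance(table((0, 10, 0, 0), (20, 0, 0, 0)))
        assert v.verdict == "concordant" and v.risk_allele == "B"

    def test_opposite_orientation_concordant_risk_a(self):
        v = judge_concordance(table((0, 10, 0, 0), (0, 0, 20, 0)))
        assert v.verdict == "concordant" and v.risk_allele == "A"

    def test_orientation_symmetry(self):
        # swapping AA and BB counts everywhere flips the risk allele only
        t1 = table((1, 10, 0, 0), (20, 3, 0, 0))
        t2 = table((0, 10, 1, 0), (0, 3, 20, 0))
        v1, v2 = judge_concordance(t1), judge_concordance(t2)
        assert v1.verdict == v2.verdict == "non_concordant"
        assert len(v1.violations) == len(v2.violations)

    def test_homozygous_group_exempt_but_no_risk_hom(self):
        v = judge_concordance(
            table((0, 10, 0, 0), (20, 0, 0, 0), homozygous=(3, 2, 0, 0)))
        assert v.verdict == "concordant"
        v = judge_concordance(
            table((0, 10, 0, 0), (20, 0, 0, 0), homozygous=(0, 0, 1, 0)))
        assert v.verdict == "non_concordant"

    def test_exemption_can_be_disabled(self):
        policy = ConcordancePolicy(exempt_subsegment_homozygotes=False)
        v = judge_concordance(
            table((0, 10, 0, 0), (20, 0, 0, 0), homozygous=(3, 2, 0, 0)),
            policy)
        assert v.verdict == "non_concordant"

    def test_high_missing_fraction_indeterminate(self):
        v = judge_concordance(table((0, 8, 0, 4), (12, 0, 0, 2)))
        assert v.verdict == "indeterminate" and "missing" in v.note

    def test_unknown_group_not_scored(self):
        v = judge_concordance(
            table((0, 10, 0, 0), (20, 0, 0, 0), unknown=(1, 1, 5, 0)))
        assert v.verdict == "concordant"

    def test_no_calls_indeterminate(self):
        v = judge_concordance(table((0, 0, 0, 5), (0, 0, 0, 5)))
        assert v.verdict == "indeterminate"

    def test_matches_per_animal_enumeration(self):
        # oracle: a table built from <= 12 animals is concordant iff some
        # orientation satisfies every animal individually
        rng = np.random.default_rng(7)
        status_pool = ["carrier", "non_carrier", "homozygous_subsegment",
                       "unknown"]
        for trial in range(300):
            n = int(rng.integers(2, 13))
            statuses = {f"A{i}": status_pool[rng.integers(4)]
                        for i in range(n)}
            genotypes = {f"A{i}": int(rng.integers(-1, 3))
                         for i in range(n)}
            t = counts_from_genotypes("sv", genotypes, statuses)
            if "Carrier" not in t.counts and "Normal" not in t.counts:
                continue
            verdict = judge_concordance(t)

            def animal_ok(status, gt, risk):
                if gt == NO_CALL or status == "unknown":
                    return True
                risk_hom = HOM_ALT if risk == "B" else HOM_REF
                if gt == risk_hom:
                    return False
                if status == "carrier":
                    return gt == HET
                if status == "non_carrier":
                    return gt == (HOM_REF if risk == "B" else HOM_ALT)
                return True  # homozygous_subsegment: het or safe hom

            oracle_ok = any(
                all(animal_ok(statuses[a], genotypes[a], risk)
                    for a in statuses)
                for risk in ("B", "A")
            )
            scored = [a for a in statuses
                      if statuses[a] in ("carrier", "non_carrier")]
            called = [a for a in scored if genotypes[a] != NO_CALL]
            if not called:
                assert verdict.verdict == "indeterminate", f"trial {trial}"
                continue
            frac_missing = (len(scored) - len(called)) / len(scored)
            if frac_missing > 0.20:
                assert verdict.verdict == "indeterminate", f"trial {trial}"
                continue
            expected = "concordant" if oracle_ok else "non_concordant"
            assert verdict.verdict == expected, f"trial {trial}"


class TestResolveDiscordances:
    def test_all_resolution_categories(self):
        genotypes = {"SWAP": HOM_ALT, "ASSAY": HOM_REF, "ANC": HET,
                     "BAD": HOM_ALT, "OK": HET}
        statuses = {"SWAP": "carrier", "ASSAY": "carrier",
                    "ANC": "homozygous_subsegment", "BAD": "non_carrier",
                    "OK": "carrier"}
        report = resolve_discordances(
            genotypes, statuses,
            reassay_records={"ASSAY": HET},
            identity_results={"SWAP": "mismatch"},
            corrected_statuses={"SWAP": "non_carrier"},
        )
        res = {c.animal_id: c.resolution for c in report.cases}
        assert res == {"SWAP": "sample_swap", "ASSAY": "assay_error",
                       "ANC": "ancestral_copy", "BAD": "unresolved"}
        assert report.corrected_genotypes["ASSAY"] == HET
        assert report.corrected_statuses["SWAP"] == "non_carrier"

    def test_unknown_animal_record_rejected(self):
        with pytest.raises(ValueError):
            resolve_discordances({"A": HET}, {"A": "carrier"},
                                 reassay_records={"ZZ": HET})

    def test_concordant_animals_untouched(self):
        report = resolve_discordances({"A": HET}, {"A": "carrier"})
        assert report.cases == []
        assert report.corrected_genotypes == {"A": HET}


class TestCountsFromGenotypes:
    def test_groups_and_overall(self):
        genotypes = {"C1": HET, "N1": HOM_REF, "N2": NO_CALL, "H1": HET,
                     "U1": HOM_ALT}
        statuses = {"C1": "carrier", "N1": "non_carrier", "N2": "non_carrier",
                    "H1": "homozygous_subsegment", "U1": "unknown"}
        t = counts_from_genotypes("sv", genotypes, statuses)
        assert t.counts["Carrier"] == (0, 1, 0, 0)
        assert t.counts["Normal"] == (1, 0, 0, 1)
        assert t.counts["Homozygous"] == (0, 1, 0, 0)
        assert t.counts["Unknown"] == (0, 0, 1, 0)
        assert t.counts["Overall"] == (1, 2, 1, 1)
        assert t.consistency_warnings() == []
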