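# lethalmap

Mapping recessive embryonic-lethal alleles in livestock populations from the
signature they leave in genotype data: haplotypes that are never observed in
the homozygous state despite many at-risk matings. The package provides the
full analysis chain on synthetic data — a gene-drop population simulator, a
missing-homozygosity window scan, recombinant-based interval refinement,
carrier-concordance variant filtering with validation-panel scoring, and
coding-consequence annotation — wired into a file-based pipeline with a CLI.

## Quick start

```sh
lethalmap run --seed 1 --out run1/
cat run1/summary.json
```

This simulates a dairy-cattle-like population (4 generations, 25 elite sires
per generation, a carrier haplotype at 22% frequency carrying a fully
penetrant recessive lethal), scans it, refines the flagged region, filters
exome variants against carrier status, scores candidate concordance on the
full validation panel, annotates the surviving candidate, and reports whether
the planted causal site was recovered as the unique concordant candidate.

Each stage can be re-run individually against the same output directory
(`lethalmap scan|finemap|filter|concord|annotate --seed 1 --out run1/`), or
configured via YAML (`--config demo.yaml`; see `PipelineConfig.from_yaml`).

## Modules

| Module | Contents |
| --- | --- |
| `lethalmap.io_formats` | PED/MAP, VCF, BED, CSV pedigree/mating/count-table readers and writers; `Interval`, `MarkerMap`, `Pedigree`, `PhasedGenotypes` containers; packaged-data access |
| `lethalmap.simulate` | seeded gene-drop population simulator (`simulate_population`) and synthetic exome variant-call generator (`simulate_variant_calls`) |
| `lethalmap.haploscan` | `expected_homozygotes` (Mendelian transmission expectation), `scan_deficits` sliding-window missing-homozygosity scan, `cluster_flags`, `conception_deficit` fertility estimator |
| `lethalmap.finemap` | `detect_crossovers`, `refine_interval` (recombinant-based exclusion with support and guard-band policy), `call_carrier_status`, `extend_haplotype`, `interval_length_mbp` |
| `lethalmap.variantfilter` | `filter_candidates` (mapping-quality/depth/status gates), `count_by_scope`, `judge_concordance` (orientation search, ancestral-copy exemption), `resolve_discordances` |
| `lethalmap.annotate` | gene models from BED/GFF3, `classify_site`, `coding_consequence` (codon re-translation), `blosum62_score`, `hydropathy`, `conservation_column` |
| `lethalmap.pipeline` | `PipelineConfig`, per-stage functions, `run_end_to_end` with manifest + structured log |
| `lethalmap.cli` | `lethalmap` command group |

## Key conventions

- Genotype codes: 0 = hom ref, 1 = het, 2 = hom alt, −1 = no call.
  Haplotype alleles are 0/1 strings; −1 marks missing.
- Genomic intervals are 1-based and closed on both ends; BED conversion is
  explicit via `interval_to_bed`/`bed_to_interval`.
- All randomness flows from a single integer seed; the same seed reproduces
  every file of a run bit-for-bit (recorded in `manifest.json`).

## Validation

`pytest` exercises unit oracles (exhaustive gene-drop expectation on small
pedigrees, per-animal concordance enumeration, whole-CDS re-translation),
printed-data reproduction from the packaged count tables, and the end-to-end
recovery property. `python scripts/acceptance.py --seed 0 --out results.json`
writes the headline acceptance numbers. `docs/methods.md` documents the
statistical methods, the simulator calibration, and known limitations.
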