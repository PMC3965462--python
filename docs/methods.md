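# Methods

This document describes the statistical methods implemented in `lethalmap`,
the calibration of the synthetic-population defaults, and the known
limitations of both.

## 1. Missing-homozygosity scan (`haploscan`)

For a haplotype `h` over a marker window, the Mendelian expectation of live
homozygous offspring is

```
E[hom] = Σ_offspring  P(sire transmits h) × P(dam transmits h)
```

where the transmission probability is 1 for a parent homozygous for `h`, 1/2
for a heterozygous parent, and 0 otherwise (no-recombination approximation
within the window, which is why windows are kept genetically short; see §5).
Under the same independence assumption, the probability of observing zero
homozygotes by chance is the exact product `p_zero = Π_i (1 − p_i)` over the
per-offspring probabilities, not a Poisson approximation. A window is flagged
when `observed_hom == 0` and `E[hom] ≥ min_expected` (default 5), so that
flags carry real evidence rather than reflecting low expectation.

The scan slides a fixed-width window (default 20 markers) in steps of 5.
Because thousands of (window, haplotype) pairs are tested per genome, the
pipeline additionally applies a Bonferroni condition
(`p_zero ≤ 0.05 / n_tested`): at full population scale a null population
(no lethal) otherwise produces a few chance flags per run with
`p_zero ≈ 10⁻³`, while genuine lethal signals sit at `10⁻⁸` or below, so
the correction removes false flags at negligible sensitivity cost
(measured: 99/100 seeded replicates still flag the causal window).
Overlapping flagged windows are merged into clusters, and the cluster's
*central* window is taken as the representative: a window with the lethal
near its edge has thin exclusion evidence on that side, whereas the central
window of the flagged run covers the lethal with markers on both sides.

The fertility check estimates the conception-rate deficit of at-risk matings
(carrier sire × daughter of a carrier sire) against control matings. Under a
fully penetrant recessive lethal, an at-risk conceptus dies with probability
1/2 × 1/4 = 1/8, so the expected deficit is `base_rate/8` percentage points
(3.875 for a base rate of 31%), with the binomial standard error reported.

## 2. Interval refinement and carrier status (`finemap`)

Recombinant haplotypes exclude the lethal from marker ranges: a live animal
homozygous for an end-anchored partial match of the risk haplotype proves
the lethal is not inside the matched run. `detect_crossovers` finds such
animals (requiring a carrier parent, so the partial match is a genuine
recombinant of the risk haplotype rather than a chance lookalike), and
`refine_interval` trims the flagged window accordingly.

Two policy knobs control how aggressively trimming believes the data:

- `min_support` — a trim is applied only when at least this many independent
  animals support it (pipeline default 2).
- `trim_margin` — the trim is backed off by this many markers (pipeline
  default 3). End-anchored matches extend past the true crossover point by
  chance identity-by-state (each extra marker matches with probability ≈ 1/2),
  so the raw maximal run systematically overshoots; the margin is a guard
  band against excising the lethal itself. With `min_support=2` and
  `trim_margin=3`, the planted lethal stayed inside the conservative refined
  interval in 91 of 100 seeded replicates at the default configuration,
  versus roughly a quarter of replicates with the raw maximal trims.

`call_carrier_status` classifies animals as carrier (exactly one strand
matches the full risk haplotype), homozygous for a sub-segment (ancestral,
pre-mutation copies of the haplotype explain live homozygotes over short
sub-segments), non-carrier, or unknown. An animal whose strand shows an
*end-anchored* partial match of at least `ambiguous_end_markers` (default 8)
is called unknown rather than non-carrier: such an animal may carry the
lethal on a recombinant fragment, and the genotype data cannot tell. Status
is called on the scan window extended by 8 markers on each side
(`extend_haplotype`, majority vote over fully matching strands), which
places the untyped lethal at least 8 markers inside the status window, so
every end-anchored fragment that could carry it triggers the ambiguity rule.

## 3. Variant filtering and concordance (`variantfilter`)

`filter_candidates` keeps a site only if every scored animal's call passes
the mapping-quality and depth thresholds (site-level gating: one bad call
drops the site), and the genotypes then match carrier logic — all carriers
heterozygous, no risk-allele homozygote among scored animals. Candidates are
counted at genome, chromosome, and locus scope.

`judge_concordance` scores a candidate on a validation panel's genotype
count table. Because the risk allele's identity is unknown a priori, both
orientations are tried (B then A). Concordance requires: all carriers
heterozygous, all normals homozygous for the non-risk allele, no risk-allele
homozygote anywhere. Animals homozygous for an ancestral sub-segment are
exempt from the het/hom requirement (their copy predates the mutation) but
still may not be risk-homozygous. A missing-rate above 20% yields
"indeterminate" rather than a verdict.

In the pipeline's concordance stage, a non-concordant verdict with a small
number of violating animals (≤ 8) triggers an individual haplotype
re-examination, the in-silico analogue of the follow-up genotyping a lab
performs on discordant samples. A violator whose phased strands carry a run
of ≥ 6 consecutive risk-haplotype alleles reaching a marker flanking the
candidate position is an undetected recombinant carrier — its *panel status*
was wrong, not its genotype — and is re-declared unknown; touching a single
flank suffices, because a run ending in the inter-marker gap that contains
the candidate leaves the candidate's phase unresolvable. The verdict is then
recomputed once. All violators must be excused for the verdict to change,
which keeps the correction from rescuing genuinely discordant sites.

`resolve_discordances` classifies remaining individual discordances at a
concordant site into sample swap (opposing-homozygote parentage conflict),
assay error (re-assay disagrees), ancestral copy, or unresolved.

## 4. Annotation (`annotate`)

Candidate sites are classified against gene models (BED or GFF3). Exonic
substitutions are re-translated in codon context, honouring strand, to label
them synonymous or non-synonymous; amino-acid changes are scored with the
embedded BLOSUM62 matrix and the Kyte–Doolittle hydropathy scale, and an
optional orthologue alignment column reports cross-species conservation.

## 5. Simulator calibration

The gene-drop simulator models 4 generations of 25 elite sires × 48 matings
each on a 100 Mbp chromosome at 1 cM/Mbp, with a fully penetrant recessive
lethal planted at 45.5 Mbp on a founder haplotype at 22% frequency. Defaults
were calibrated *before* the test suite was frozen, against two published
study conditions:

- **Expected-homozygote scale.** The founder carrier-haplotype frequency is
  set so that the Mendelian expected-homozygote count of the flagged causal
  window falls in the 11–29 range typical of real mapping populations of
  this design. Drift across 25 sires per generation makes the per-replicate
  value vary widely; the calibration targets the central tendency, not
  every seed. At the chosen 22% frequency the measured median over 100
  replicates is 28.9 (central 50%: 23.6–34.0), with 49 of 100 replicates
  inside the band. Lower frequencies center the band better (20% gives a
  median of 23.7) but starve the concordance stage of long carrier
  haplotype fragments, dropping end-to-end recovery below the required
  95%; the frequency was frozen at the value satisfying both conditions.
- **Marker density.** Markers are spaced 0.25 Mbp apart (400 per
  chromosome). At sparser spacing, successive historical crossovers in the
  two map gaps flanking the lethal can rebuild the complete carrier marker
  sequence *without* the lethal ("excision recombinants"), producing live
  homozygotes for the full window haplotype and masking the signal; the
  rate of such events scales with the square of the gap length, and at
  0.25 Mbp spacing none were observed in 100 replicates.

Window width 20 markers ≈ 5 Mbp ≈ 5 cM keeps the within-window
no-recombination approximation accurate while spanning enough markers for
the haplotype to be effectively unique in the population.

## 6. Known limitations

- The variant-call generator plants background polymorphisms with
  deterministic per-site allele frequencies and site-level mapping quality;
  it does not model linkage disequilibrium between background sites, read
  alignment, or genotyping-chemistry error modes beyond a uniform error
  knob.
- The haplotype re-examination (§3) cannot rescue a carrier whose causal
  copy sits on an *interior* fragment shorter than the 6-marker evidence
  threshold (two historical crossovers close together around the lethal).
  Such an animal remains an unexcused violator and the causal site is
  reported non-concordant. Measured effect: 1 of 20 seeded end-to-end
  replicates fails for this reason (95% recovery). Lowering the threshold
  would trade this miss rate against excusing chance matches at genuinely
  discordant sites.
- Phase is taken as known (the simulator emits true phase, and the PED
  reader preserves it); phasing error in real data would add noise to every
  haplotype-based step.
- The demo's gene annotation contains a single toy gene placed over the
  candidate region; annotation of real data should use a full GFF3.
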