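# Methods

`introscan` asks one question: given two recently diverged, morphologically
cryptic species that co-occur in the field and can hybridize in the
laboratory, is there detectable introgression between them?  Because no
single statistic answers this reliably when the candidate donor and
recipient are closely related, the package combines three detectors with
different sensitivities — the three-population f3 statistic, windowed
absolute divergence (d_XY), and a per-window quartet branch-length
statistic — and calibrates all three against a coalescent simulator in
which the true amount and direction of admixture is known.

## The demographic model

Three populations with topology `((I1, I2), O)`: two ingroups that split
recently and an outgroup, standing in for an allopatric reference
population (I1), a sympatric population of the same species (I2), and the
cryptic sister species (O).  Times are in coalescent units of 4N
generations, with the ms convention that a pair of lineages in a
population of relative size 1 coalesces at rate 2 per time unit.

Defaults (the calibration study's conditions):

| parameter | default | meaning |
|---|---|---|
| `samples_per_population` | 8 | haploid sequences per population (24 total) |
| `split_time_ingroups` | 0.4 | I1/I2 divergence (4N units) |
| `split_time_root` | 1.5 | root divergence (4N units) |
| `recombination_rate` | 0.001 | 4Nr per bp |
| `chromosome_length` | 25 Mb | configurable down for tests |
| `branch_scale` | 0.01 | expected substitutions/site per 4N-generation unit |
| `hky_kappa` | 2.0 | HKY transition/transversion ratio |
| `base_frequencies` | uniform | HKY stationary frequencies |

Gene flow is modelled purely as instantaneous admixture pulses: backwards
in time, each lineage in the recipient population at the pulse time
relabels to the donor with probability equal to the pulse fraction.  A
single en-masse event sits at 0.01; the five-event schedule places pulses
at 0.01, 0.008, 0.006, 0.004 and 0.002.  The five-event per-pulse fraction
defaults to the compound form `q = 1 - (1 - f)^(1/5)` so the cumulative
admixed ancestry equals the nominal total `f` exactly; an `f/5`-per-pulse
mode is available.  Pulse times must pre-date the ingroup split, since the
recipient and donor must both exist.

Useful closed forms under this model (used as test oracles): the expected
pairwise I1–I2 coalescence time at f=0 is 0.4 + 1/2 = 0.9; for a single
O→I2 pulse of fraction f at a time near zero, the expected unnormalised f3
with target I2 is proportional to `0.39 − 3.37 f + 2.98 f²`, which is
positive at f = 0.1 and negative from f = 0.2 — the detection threshold
the calibration reproduces is a property of the demography, not of any
particular run.

## Simulation

Genealogies come from a structured coalescent simulated backwards in time,
with population splits and pulses handled as events on a time line.
Recombination uses the Markovian (SMC) approximation: breakpoints arrive
along the chromosome as a Poisson process with rate `4Nr × total branch
length`; at each breakpoint a uniformly chosen branch point is detached,
the dissolved coalescence is spliced out, and the floating lineage
re-coalesces into the pruned tree under the same structured process,
conditional on the realised population membership of the surviving
branches (each branch's population history through pulse events is
recorded for this purpose).  A faster `blocks` mode draws an independent
tree per fixed-size block (default 1 kb) instead; the window-averaged
statistics computed here are insensitive to linkage detail, and the two
modes agree on all calibration behaviour.  Linked-selection,
gene conversion, population-size change and continuous migration are all
out of scope: the study design uses pulses only.

Sequences evolve site-by-site along each marginal tree under HKY85, with
branch lengths converted to expected substitutions per site via
`branch_scale`.  Transition probabilities use the closed-form HKY
solution (verified against matrix exponentials); for uniform base
frequencies the sampler draws the number of changed sites per branch from
the exact Binomial(ℓ, 1 − P_ii) and assigns transition/transversion
targets with the exact conditional probabilities, which makes 25-Mb
simulations tractable in pure numpy.  With kappa = 1 and uniform
frequencies the model reduces to Jukes–Cantor, giving the closed-form
divergence check `p = (3/4)(1 − e^{−4d/3})`.

One master seed drives two independent streams (genealogies, mutations);
identical model + seed reproduces the haplotype matrix byte for byte.

## Statistics

All statistics consume per-site, per-population allele counts, so haploid
simulated data and diploid VCF data share one code path (a diploid
genotype contributes two alleles; heterozygotes are carried in sequence
space as IUPAC ambiguity codes).

* **π** — per site `(n² − Σc²)/(n(n−1))` over called alleles, the unbiased
  multi-allelic form; window value is the mean over callable sites
  (monomorphic sites contribute 0).
* **d_XY** — per site `1 − Σ_a p_A,a p_B,a`, averaged over sites callable
  in both populations.  On complete data this equals the mean pairwise
  mismatch fraction across all inter-population sequence pairs exactly,
  which is the oracle test.  An "all non-N sites" denominator mode exists
  for comparison with tools that count differently.
* **F_ST** — Weir & Cockerham (1984) variance components per biallelic
  site with two populations and the window value `Σa / Σ(a+b)` (the
  weighted, ratio-of-sums estimator used by standard VCF tooling).
  Alleles are the sampling unit; the within-individual component is
  dropped, which is exact for haploid data and a standard approximation
  for genotype counts.
* **Tajima's D** — the 1989 statistic with constants from the window's
  modal per-site called-allele count.  The canonical formula assumes a
  constant number of sequences; with ragged missingness the modal n
  minimises the distortion.  This is an approximation and documented as
  such; S = 0 windows are NA.
* **f3** — per site `(ĉ−â)(ĉ−b̂) − ĥ_C/n_C` with the unbiased target
  heterozygosity `ĥ_C = ĉ(1−ĉ)n_C/(n_C−1)`, averaged over sites biallelic
  and polymorphic in the pooled three populations (no MAF filter).  The
  statistic is reported unnormalised; a normalised mode divides by the
  mean target heterozygosity.  Standard errors use a weighted delete-one
  block jackknife (Busing et al. 1999) over contiguous 500-kb blocks,
  weighted by per-block site counts; 500 kb gives 50 blocks on the 25-Mb
  design and scales down to `chromosome_length/10` for short test
  chromosomes.
* **Tree-tip proportion** — per 50-kb window and per (I2, O) sample pair,
  a four-tip tree over {I2, O, I1, I1} (the two I1 anchors fixed across
  all combinations) gives `Proportion_ab = d_a/(d_a + d_b)`, where d_a is
  the I2–O patristic distance and d_b the mean of the two I1–O patristic
  distances.  ~0.5 under the species tree; ≪0.5 flags candidate
  introgressed windows.

### Quartet trees

Per-window trees are distance-based rather than maximum-likelihood: for
four taxa the proportion statistic depends only on patristic distances,
and a Jukes–Cantor + least-squares tree is deterministic, dependency-free
and fast.  Distances use mismatch fractions over jointly callable sites,
with IUPAC codes contributing their mean mismatch over compatible base
resolutions (het vs matching homozygote = 0.5); saturated comparisons
(p ≥ 0.75) are capped at a configurable maximum (default 5.0) so
degenerate windows are flagged rather than fatal.  The topology is the
four-point-condition split (smallest within-cherry distance sum); the
five branch lengths are the least-squares fit, clamped at zero.  On
additive matrices the fitted patristic distances reproduce the input to
numerical precision.  An import path accepts externally computed Newick
trees per window for users who prefer ML branch lengths.

### Tails and scans

Per sample combination, windows are counted above and below the mean
proportion at offsets 0.05, 0.10 and 0.15; symmetric counts argue against
widespread admixture, and windows below mean − 0.15 are flagged and
aggregated per scaffold for follow-up with 10-kb/2-kb sliding d_XY.  The
divergence scan ranks windows by d_XY and by F_ST, takes the top
`ceil(1%)` of analysed windows under each, and reports the intersection
plus each window's percentile under the other statistic.

### Missing-data rules

VCF reading masks genotypes with depth < 5 and drops sites where more
than 40% of samples are missing after masking.  All windowed statistics
return NA unless more than 20% of the window's base pairs are callable
for that statistic — this generalises the tree-window genotyping rule to
every windowed quantity for consistency.  NA windows never enter means,
tails or top-1% scans.  Coordinates are 0-based half-open internally,
1-based inclusive in reports, BED dialect for interchange.

## What the simulator does and does not emulate

The generator reproduces the study conditions: neutral coalescent
genealogies with the stated splits, pulse admixture, uniform
recombination and HKY mutation, and complete genotype calls.  It does not
emulate sequencing error, reference bias, alignment-driven missingness,
repeat content, or selection — so passing calibration shows the
statistics behave correctly under the stated demography, not that any
particular empirical dataset is free of those artefacts.  The empirical
path (VCF + population map) is exercised on simulator output round-tripped
through VCF.

## Numerical and scale choices

Tests and the acceptance script run the calibration at 5 Mb (100 windows,
10 jackknife blocks per replicate) with 5 replicates per grid cell, and
unit tests at 0.1–3 Mb; these sizes keep the full suite a desk-scale
computation while leaving every threshold behaviour intact, since the f3
detection threshold is driven by expectation rather than genome length.
The f=0 grid cell is direction-free and simulated once per replicate.
Seeds are fixed small integers; every reported quantity is a deterministic
function of them.  Degenerate inputs fail loudly (no usable sites, fewer
than two jackknife blocks, fewer than 30 proportions per combination)
rather than returning silently biased values.

## Known limitations

* The SMC approximation ignores some long-range linkage correlations;
  this affects nothing averaged over 50-kb windows but the simulator is
  not a source of exact linkage disequilibrium structure.
* Tajima's D under heavy, uneven missingness inherits the modal-n
  approximation above.
* The W&C F_ST drops the within-individual component for diploid data
  (no inbreeding correction).
* f4/D statistics and f4-ratio estimation are deliberately absent; with
  only one outgroup available the design cannot polarise them.
* Per-window π standard deviations are reported per window rather than
  via genome-wide jackknife resampling.
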