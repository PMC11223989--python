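# Methods

## Problem

Absence of heterozygosity (AOH, also called a run of homozygosity) is an
extended genomic region in which both haplotypes carry identical alleles —
typically the footprint of uniparental isodisomy, identity by descent, or
consanguinity. AOH is clinically relevant through imprinting disorders and
recessive-disease mechanisms, and is conventionally detected with SNP
microarrays. `lpaoh` detects AOH from **ultra-low-pass genome sequencing**
(well below 1-fold coverage, single-end short reads), where individual
genotypes cannot be called: at a typical 0.1–0.8× depth most polymorphic
sites receive zero or one read, and all usable signal comes from the small
minority of sites covered by two or more reads.

## Model

### Per-site genotype likelihoods

For a biallelic site with population alternate-allele frequency *p* and
observed ref/alt read counts (*r*, *a*), reads are conditionally independent
given the genotype, and each read reports the wrong allele with probability
ε:

* **Diploid (biparental) model** — genotypes RR, RA, AA with Hardy–Weinberg
  priors (1−p)², 2p(1−p), p²; per-read alt probabilities ε, ½, 1−ε.
* **Haploid (AOH) model** — both haplotypes identical, so effective
  genotypes RR, AA with priors (1−p), p; per-read alt probabilities ε, 1−ε.

The per-site log-likelihood ratio (natural log, haploid minus diploid) is
exactly zero for any single-read site — the marginal alt-read probability is
p(1−ε) + (1−p)ε under both models — which is why depth enters the problem
only through the rate of multi-read sites, ≈ λ²/2 per site at per-site mean
depth λ. A concordant read pair shifts evidence toward AOH (up to ≈ +0.28
nats at p = 0.5), a discordant pair strongly toward biparental (≈ −2.6
nats). Averaged over a U-shaped frequency spectrum the expected evidence is
≈ 0.08 nats per multi-read site inside AOH.

### Binning and HMM smoothing

Per-site LLRs are summed over fixed-width bins tiling each chromosome
(default 1 Mb, last bin truncated). A two-state hidden Markov model over
bins — states *biparental* and *AOH* — is decoded exactly by
forward–backward, per chromosome:

* log emission ratio of a bin = its summed LLR;
* start distribution (1−π, π) with AOH prior π = 0.01;
* symmetric per-boundary switch probability
  t = 1 − exp(−w / (L·10⁶)) with bin width w and expected segment length
  L = 10 Mb (t ≈ 0.095 at the defaults).

The per-bin AOH posterior γ is the "AOH prediction likelihood" track. With
a symmetric chain the prior π acts at the chromosome start and the state
marginal relaxes toward ½ along the chromosome in the absence of evidence;
in practice every bin carries evidence and the posterior is driven by the
local LLR field. A design alternative — prior-preserving transitions
(t·π entering, t·(1−π) leaving) — keeps the no-evidence posterior at π
everywhere but was measurably less sensitive for mid-size events (a clean
15 Mb constitutional AOH at ~0.12× peaked below the call threshold) and was
rejected in favour of the symmetric formulation.

Segments are maximal runs of bins with γ ≥ 0.5 (ties included, no merging
across sub-threshold gaps — so a mosaic chromosome visibly fragments into
subregions rather than being silently bridged), discarded below a reporting
floor (default 5 Mb, the clinical convention; lowered to 1 Mb in the
depth-titration harness so that sub-5 Mb truth classes are measurable at
all). Size classes: `lt5` (< 5 Mb), `5to10` (5–10 Mb inclusive), `gt10`
(> 10 Mb), `chromosomal` (≥ 90% of the chromosome).

### Copy ratio and mosaicism

Bin read counts divided by the genome-wide (autosomal) median give a
copy-ratio track. Two estimators address a mosaic aberrant cell line at
fraction f:

* **Copy-ratio estimator** (default for whole-chromosome events with a
  depth shift): the regional median m satisfies m = 1 ∓ f/2 for mosaic
  monosomy/trisomy, so f = 2·|m − 1|, clipped to [0, 1]. Requires ≥ 20 bins.
* **Allele-based MLE**: grid search over f ∈ {0, 0.001, …, 1}. Heterozygous
  genotypes emit alt reads with probability q(1−ε) + (1−q)ε where q is an
  equal mixture of (1−f)/2 and (1+f)/2 (the aberrant line contributes only
  one of the two carried alleles). Single-read sites are provably flat in f,
  so at least one multi-read site is required.

AOH calls whose bins' median copy ratio deviates from 1 by more than 0.1
are flagged `possible_cnv_or_mosaic`, since a hemizygous deletion mimics
AOH in the allelic signal.

## Synthetic data

The generator emulates the caller's inputs rather than reads or alignments:

* **Panel** — sites placed uniformly at 1 common SNP/kb; alternate-allele
  frequencies drawn (inverse-CDF, properly truncated) from Beta(0.8, 0.8)
  restricted to [0.01, 0.99] — U-shaped like a real site-frequency spectrum
  after a 1% frequency floor. One panel per genome is generated and shared
  across a simulated cohort, as a population panel is a fixed resource.
* **Genome** — 3 chromosomes of 120/100/80 Mb (300 Mb total). Detection
  power depends on per-site depth λ and SNP density, not genome size, so
  λ is matched to the read budget under study
  (λ = UAHR · read length / genome length, read length 35 bp).
* **Sample** — Hardy–Weinberg genotype per site; inside a planted segment an
  AOH line derived from the same zygote (keeps homozygous genotypes,
  collapses heterozygotes onto one allele at random; marginally AA with
  probability p) mixed at cell fraction f, with regional read depth scaled
  by 1 − f + f·c for relative copy number c ∈ {0.5, 1, 1.5}; per-site read
  count Poisson(λ·depth factor); each read samples a cell line
  proportionally to its copy number, then an allele, then flips with
  probability ε = 0.01.
* **Thinning** — binomial per-read retention; thinned Poisson counts are
  exactly Poisson at the reduced rate, so one deep dataset emulates any
  shallower run.

Features of real data deliberately not emulated: linkage disequilibrium
between panel sites (genotypes are independent given AF), GC/mappability
bias (a multiplicative bias hook exists in the copy-ratio normaliser),
multi-site reads, alignment artifacts, and panel ascertainment structure.
Passing tests therefore demonstrate correctness of the machinery and
calibration under idealised inputs, not clinical performance.

## Evaluation machinery

* **Reciprocal overlap** of two intervals: min(|a∩b|/|a|, |a∩b|/|b|);
  concordance cutoff > 0.5.
* **Region matching**: a truth region is matched when *some subset* of the
  calls overlapping it achieves union reciprocal overlap above the cutoff
  (exact subset enumeration up to 12 overlapping calls, greedy prefixes
  beyond). The subset form handles a region fragmented into sub-calls and
  keeps matching monotone: an additional call can never unmatch a region.
* **Sample confusion**: a sample is call-positive iff it has a reported
  segment at or above the reporting floor; sensitivity/specificity over
  positive/negative samples.
* **Depth titration**: a 14-point UAHR ladder (1.25–70 M), binomial
  thinning, re-calling, per-size-class region sensitivity; the plateau is
  the smallest budget whose overall sensitivity is within 0.1 percentage
  points of the grid maximum.

## Problem sizes and numerical choices

The bundled validation studies use the 300 Mb genome at these sizes, chosen
so each study carries enough regions per size class to resolve ~0.5%
sensitivity differences: 40 + 40 samples for the sample-level study
(one 10–40 Mb constitutional AOH per positive, 0.8×-equivalent depth);
400 `gt10` + 100 `chromosomal` regions for the 10 M-UAHR titration point;
506 regions in the 4 : 21 : 397 : 84 clinical size mix for the 15 M point;
138 region bins of mean count 500 against a 3000-bin genome for the mosaic
recovery. Truth sizes: lt5 ~ U(2, 5) Mb, 5to10 ~ U(5, 10) Mb, gt10 ~
U(10, 40) Mb, chromosomal = the whole chromosome.

Numerics: likelihoods are computed in log space (binomial coefficients via
`gammaln`, included consistently in both models so they cancel in ratios); forward–backward
uses log-space recursions with `logaddexp`; allele frequencies of exactly 0
or 1 are tolerated (−∞ genotype priors drop out of the mixture); the
posterior threshold includes ties; empty bins carry zero evidence; the
copy-ratio normaliser refuses an all-zero genome.

## Known limitations

* Sensitivity near the 10 Mb / 0.1× corner is intrinsically marginal under
  these conditions: with a U-shaped AF panel at 1 SNP/kb the expected
  evidence is ≈ 0.5 nats per Mb at λ = 0.117, so 10–12 Mb regions sit
  within one standard deviation of the call threshold and per-cohort
  sensitivity fluctuates around ~99.5–99.8%.
* No base-quality-aware likelihoods, mapping-quality model, or indel sites.
* No learned smoother: the HMM is a fully specified, testable substitute
  for black-box sequence models over the same track.
* The allele-based mosaic MLE assumes the copy-ratio direction is known or
  copy-neutral; it does not jointly estimate f and copy state.
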