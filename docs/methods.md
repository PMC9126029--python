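# Methods

This note records the statistical model behind each scan, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Data model

Genotypes are held as an allele-B dosage matrix (SNPs × samples; 0/1/2,
−1 missing) with a SNP map (1-based positions, strictly increasing; closed
intervals throughout the TSV outputs) and a sample sheet (sex, population,
species ∈ {focal, outgroup}). Phased data adds a (samples × 2 × SNPs)
haplotype array; outside the PAR a male's two rows are duplicates of his
single X copy, and every scan that works on haplotypes takes exactly one row
per male there.

## QC and PAR detection

SNP filters: GenTrain < 0.4 and GenCall ≤ 0.8 (skipped, with a log message,
when array metadata is absent — it rarely survives export), call rate
< 0.90, and Hardy–Weinberg exact-test p < 1e-7 (strict inequality, so a SNP
exactly at the threshold is kept). The HWE test is the exact conditional
test with the mid-p correction, computed on diploid calls only: females
outside the PAR, all samples inside it. Hemizygous males cannot be at
Hardy–Weinberg proportions, so including them would only create artifacts.
Individuals with call rate < 0.95 are removed after the SNP pass.

The PAR boundary is detected from male observed heterozygosity H_O: males
are diploid (H_O ≈ 0.3 on a typical array) inside the PAR and hemizygous
(H_O ≈ 0) beyond it. For each SNP index the mean H_O over the following 50
SNPs is computed; the boundary is placed before the first index from which
this mean stays below 0.01 for the rest of the chromosome, then refined
within that window to just past the last SNP with H_O > 0.1, so a trailing
diploid SNP is not clipped while isolated mis-genotyped SNPs (H_O of one or
two males) are ignored. Only the resulting boundary, not the algorithm, is
identifiable from real data, so both the window (50 SNPs) and floor (0.01)
are exposed as parameters. Male-heterozygous calls beyond the boundary are
physically impossible; any SNP carrying one is reported and dropped
(configurable to only set the calls missing).

Ancestral alleles are the outgroup majority allele, counted per allele copy
over non-missing outgroup calls; exact ties and all-missing SNPs stay
`unknown` and are excluded from iHS/nSL scoring (but retained as haplotype
background). Recoding to 0 = ancestral / 1 = derived is an involution.

## eROHi

ROH are called in diploid females only. A qualifying run has ≥ 15 SNPs,
≥ 250 kb, adjacent-SNP gaps ≤ 250 kb and at least one SNP per 20 kb. Runs
are called independently per length class — 0.25–1, 1–2, 2–4, 4–8, 8–16 and
> 16 Mb — with heterozygote allowances (0, 0, 0, 1, 2, 4) and missing
allowances (0, 1, 2, 4, 8, 16). The strictest class (0.25–1 Mb: nothing
allowed) is pinned by design; the longer-class allowances follow common
HD-chip practice, scale with the array's ~0.25% genotyping error rate, and
are fully configurable since published analyses rarely print them. A run
found under a class's allowance is reported only if its bp length falls in
that class's range, so per-class scans stay independent. The caller is a
two-pointer scan over maximal windows; its contract (every maximal
qualifying run, reported once) is enforced in tests against an
all-subsegments oracle.

Per SNP, the ROH frequency is the fraction of females with ≥ 1 covering
segment (union over classes; a female counts once however many of her
segments overlap). The "normalised by the mean frequency" transform is
implemented as a z-score over SNPs, (f − mean)/sd, mapped through the
one-sided upper-tail standard-normal probability to −log₁₀(P): islands are
high-frequency excursions, so only the upper tail is of interest. Runs of
≥ 2 consecutive outlier SNPs become signals, ranked by their peak −log₁₀(P).

simpleM computes the effective number of independent tests as the number of
leading eigenvalues of the SNP–SNP Pearson correlation matrix (missing
dosages mean-imputed, constant SNPs excluded) needed to reach 99.5% of the
total variance — the method's published default. Optional fixed-size block
processing (summing per-block m_eff) keeps very large maps tractable. The
threshold is −log₁₀(0.05 / m_eff); on the default simulated females this
lands at m_eff ≈ 99 and a bar of ≈ 3.3, which is also the package-wide
fixed default where a precomputed threshold is preferred.

## iHS and nSL

EHH of an allele at a core SNP, at distance d, is the probability that two
random carriers are identical at every SNP from the core out to d; it is
computed by refining carrier partitions SNP-by-SNP, which is exactly the
pairwise definition but linear in carriers. iHH is the trapezoidal integral
of the EHH decay over physical bp, both directions summed, truncated once
EHH < 0.05 (the first sub-cutoff point is included so the drop itself is
integrated); no gap penalty is applied. Integration uses physical distance —
a uniform per-bp map — because dense-array X data typically has no genetic
map; the choice only rescales iHH ratios computed on the same map. Raw
iHS = ln(iHH_ancestral / iHH_derived). nSL replaces distance by SNP count:
the mean over carrier pairs of the shared-tract length in SNPs (counting the
core), which equals 1 + the sum of the per-step pair-identity fractions, with
no truncation other than the chromosome ends. Both statistics are NA when
the minor allele frequency is below 5%, the ancestral state is unknown, an
allele has < 2 carriers, or an integral is zero; NA SNPs still serve as
haplotype background for neighbouring cores.

Raw scores are standardized within derived-allele-frequency bins of width
0.025. Bins with fewer than 10 scored SNPs are merged leftward (the
leftover tail joins its neighbour) to avoid zero-variance artifacts in tiny
bins; within each merged bin z = (raw − mean)/sd, and
−log₁₀(P) = −log₁₀(2(1 − Φ(|z|))) is two-sided since extreme scores of
either sign are informative. Windows of 500 kb sliding by 100 kb (grid
aligned to the slide) count SNPs with −log₁₀(P) > 2 as outliers; windows
with > 10% outliers are significant candidates and are thinned greedily by
descending proportion so the reported set is non-overlapping. The outlier
proportion uses scored (non-NA) SNPs as its denominator; the all-SNPs count
is emitted alongside, since both conventions appear in practice. Unphased
heterozygous input is rejected rather than heuristically phased.

## HRiD

Windows are 70 SNPs with a step of 35, over non-PAR SNPs only; only full
70-SNP windows are scored (a trailing remainder is logged and left
unscanned) because n_h values are only comparable when computed over the
same number of SNPs. Within a window, males with any missing call are
excluded by default (`max_missing_frac = 0`, configurable); the remaining
hemizygous haplotype strings give counts whose frequencies enter
n_h = 1/Σpₖ². Interior windows score
HRiD(wᵢ) = (n_h(wᵢ₋₁) + n_h(wᵢ₊₁)) / (2·n_h(wᵢ)); the first and last
windows use 2·n_h of their single flank as the numerator. An unusable
window or flank propagates NA — the other flank is never silently
substituted.

Normalization is a z-score over non-NA windows mapped through the one-sided
upper-tail normal to −log₁₀(P); richness *drops* (large HRiD) are the
signal, so the lower tail is uninteresting. The default significance bar is
the fixed −log₁₀(P) ≥ 3.3 (z ≈ 3.29); a simpleM-style window-level
correction can be computed instead. Significant windows are merged into
signals when their spans overlap or their indices are consecutive; an
unmerged mode reports each significant window separately, the convention
under which two half-overlapping windows over one swept region appear as
two listed signals. HRiD is invariant to allele relabeling, haplotype
order, and any rescaling of all n_h values.

## Median-joining networks

Unique haplotypes (complete strings only; rows with missing calls are
excluded with a warning) are collapsed into counted nodes. The network is
built Bandelt-style: the minimum-spanning network (every edge whose
endpoints are disconnected by strictly shorter edges; `epsilon` relaxes the
comparison) augmented iteratively with majority-consensus medians of node
triplets, accepting at each step the median that most shortens the minimum
spanning tree, until none helps; useless medians are pruned at the end.
Median nodes carry count 0. For binary SNP haplotypes the consensus median
is the coordinate-wise majority.

The favourable group is the most frequent observed node plus every observed
node within 3 mutations, measured along shortest network paths (median
nodes may lie on the path) — the network-distance reading of "three
mutations away"; direct Hamming distance is available as an option. Ties
for the most frequent node seed the group jointly and are reported rather
than broken arbitrarily. The origin call compares the most common outgroup
haplotype with the group: inside → ancestral, outside → derived, ties
straddling the boundary → ambiguous. Breed evenness reports, per focal
population, the share of its haplotypes falling in the group, plus the
max/min share ratio.

## Synthetic data

The generator is a founder-mosaic copying model, chosen over a coalescent
simulator to keep the package dependency-light and the output exactly
reproducible from a seed. A root haplotype (all-ancestral) spawns K = 30
founders by independent per-SNP mutation (rate 0.3); founder frequencies
are Dirichlet(1,…,1). Each sampled chromosome copies one founder, switching
founders at each SNP boundary with probability 0.02 (≈ historical
recombination); females draw two copies, males one outside the PAR and two
inside. Outgroup chromosomes copy only the founders nearest the root, with
geometrically concentrated weights so one ancestral haplotype dominates —
this gives the outgroup a well-defined most-common haplotype (as a small,
closely related wild population has) and makes the outgroup majority allele
track the ancestral state. Defaults mirror an array-typed X scaled to desk
size: 2,000 SNPs (150 PAR), inter-SNP spacing ~7 kb, 100 focal males, 101
females, 10 outgroup animals (5 male), missing rate 0.002 and symmetric
genotyping error 0.0025 — the error flips one allele of a diploid call or
the single allele of a hemizygous call, which is what creates realistic
male-heterozygote artifacts for the PAR detector to clean. Noise is applied
at the haplotype level and dosages derived from the noisy haplotypes, so
dosage/haplotype consistency holds by construction; the pre-noise
haplotypes are kept in the truth object.

Hard sweeps replace each focal haplotype inside a SNP span with a
designated swept haplotype with probability f_s: the founder nearest the
root (`origin="ancestral"`) or a novel haplotype ≥ 5 mutations from every
founder on the span (`origin="derived"`). Sweep spans must avoid the PAR.

What the generator does **not** emulate: demographic history (bottlenecks,
migration, family structure), linkage-disequilibrium decay calibrated to a
real map, soft sweeps, allele-frequency ascertainment of array design, or
batch effects. Passing tests therefore demonstrate the statistics'
behaviour under a clean hard-sweep-vs-neutral contrast at realistic sample
sizes — not their operating characteristics on any particular real
population.

## Problem sizes and numerics

Tests and the acceptance script run the full stack at the generator's
default scale (2,000 SNPs, ~50 HRiD windows, 50 seeded replicates for the
stochastic checks) and exercise the oracles at small n where enumeration is
exact. Zero-variance situations (constant ROH frequencies, constant HRiD
profiles) raise instead of returning NaN. Ties are broken deterministically
everywhere (stable sorts, index order), and every random draw flows from a
single integer seed, so reruns are byte-identical.

## Known limitations

* The eROHi −log(P) transform treats standardized ROH frequencies as
  normal; the empirical frequency distribution is skewed, so the transform
  is a ranking device more than a calibrated tail probability.
* iHS integrates over physical distance; where a genetic map exists and
  recombination is very heterogeneous, scores will differ from map-based
  implementations (nSL and HRiD are unaffected by construction).
* The median-joining search enumerates node triplets and is intended for
  signal-sized windows (tens of unique haplotypes), not whole-chromosome
  haplotype sets.
* HRiD loses power for swept regions longer than the window, since the
  flanking windows are then also richness-depleted.
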