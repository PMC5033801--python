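# Methods

This note documents the models, parameter choices and numerical details
behind `chalkmap`, and what the synthetic study design does and does not
establish about real data.

## Population model

The simulator draws F7 single-seed-descent RIL genomes directly at the
target generation instead of simulating six rounds of meiosis.  The
justification is exact, not asymptotic: a selfing lineage observed at two
loci is a Markov chain on 16 ordered diploid states (haplotypes coded by
parental origin at each locus), and linearising that chain at a small
inter-locus distance yields the per-Morgan densities of the genotype
mosaic at generation F(g+1):

* homozygous A|B junction density `lam_hom` (1.781/Morgan at F7,
  approaching the classical fixation value 2 as g → ∞),
* heterozygous tract boundary density (0.375/Morgan at F7), hence a
  tract-start density of 0.187/Morgan and, combined with the marginal
  heterozygosity (1/2)^g = 1/64, a mean residual het tract of
  8.3 cM.

Genomes are then composed per chromosome as a two-state A/B mosaic with
Poisson junctions at `lam_hom`, overlaid with stationary
exponential-length heterozygous tracts (tract starts extend beyond the
chromosome ends so edge tracts are not under-represented).  Genetic
position maps linearly to physical position.  A per-meiosis
gamete-dropping simulator is kept in the test suite as an independent
oracle; the direct sampler matches its junction-count distribution (KS
test at α = 0.01, n = 1,000 lines) and mean within sampling error.

Assumptions: no crossover interference in the underlying meioses
(Poisson crossovers), uniform recombination along each chromosome, no
segregation distortion, and heterozygous tracts placed independently of
the homozygous backbone.  The overlay deletes the ~1.6% of backbone
junctions covered by a het tract, a second-order approximation.

## GBS observation channel

SNP sites are placed uniformly at `snp_density` (default 330/Mb ≈ 123k
genome-wide sites, the scale of a filtered aa×bb set).  Each individual
observes each site independently with probability `capture_fraction`
(default 0.07) at a depth drawn from a Poisson (mean 11.76) truncated at
one read; an observed call flips away from the truth with probability
`genotyping_error` (default 1%; homozygotes flip to the opposite
homozygote, heterozygotes to a random homozygote).  Real GBS capture is
restriction-site driven and therefore *shared* across individuals and
clustered in the genome; the independent-capture model preserves the
quantities the downstream rules consume (per-line informative-site
spacing and counts) but not cross-individual sharing, so population-level
per-site coverage is thinner than in real data.  Mapping quality is
drawn high (N(55, 5) with a 3% low tail) merely to exercise the filter.

## Bin genotyping

Windows of 15 consecutive *observed* SNPs slide one SNP at a time along
each line; each SNP takes its centred window's consensus: missing if
fewer than `min_called_in_window` = 5 calls, homozygous if ≥ `hom_min`
= 11 calls agree, heterozygous otherwise.  The two thresholds are not
fixed by the source protocol; 11/15 follows the homozygosity ratio used
in the sliding-window genotyping literature, and 5 makes the masking
rule coherent.  End windows are truncated and judged by the same ratio
(threshold rescaled by window width).  Windows run over observed sites
because at 7% capture a fixed-size window over the population site list
would almost never contain five calls.

Two consensus artefacts are corrected before segments are formed:

* **Transition zones.**  Around a true A|B junction the straddling
  windows necessarily report H over a band of up to ~15 SNPs.  A short H
  run between discordant homozygous runs whose raw calls contain almost
  no per-SNP H calls (< 50%) is such a band, not a segment; it is
  collapsed to a single breakpoint at its centre.  A genuine residual
  het tract keeps an H-call majority and survives.
* **Diluted double recombinants.**  A homozygous core of ~5–12 SNPs
  inside the opposite background is smeared to H by windows straddling
  its ends.  The flanking genotype identifies the contaminant, so an H
  run beside one homozygous genotype is re-called to the opposite
  genotype when it contains ≥ 5 supporting calls, with boundaries
  trimmed to the core's first/last supporting SNP.  Isolated 1% call
  errors cannot assemble five same-parent calls, so this does not create
  spurious segments.

Breakpoints sit midway between the bounding SNPs of consecutive runs.
Segments shorter than 300 kb with fewer than 5 supporting SNPs are
masked as missing (conjunctive rule; an optional merge-with-next mode is
not the default because the conjunctive form is the one motivated by
false double recombination).  The union of all retained breakpoints cuts
the genome into intervals; per-line interval genotypes come from the
covering segment, adjacent intervals with identical population vectors
are merged, and surviving intervals become `mk1 … mkN` in genome order.
Coordinates are 1-based inclusive throughout; BED output converts to
0-based half-open at the boundary.  On the default design ~94% of true
junctions are recovered within 300 kb; the remainder are sub-resolution
(terminal fragments ahead of the first observed SNP, double recombinants
under 5 observed SNPs, short het tracts).

## Linkage map

Marker order is fixed by physical position; distances are two-point
between adjacent bins.  The observed recombination fraction R counts
discordant homozygote pairs over informative pairs (het/missing excluded
pairwise).  R is corrected to meiotic r and converted with Kosambi's
function d = 25·ln((1+2r)/(1−2r)).  Two corrections are offered:

* the classical fully-inbred Haldane–Waddington relation R = 2r/(1+2r),
  inverted in closed form (r = R/(2(1−R)));
* the default for this package: numeric inversion of the *exact*
  finite-generation relation R_hom(r; g) = P(discordant | both loci
  homozygous) from the same two-locus chain, with g = 6 (F7).  At F7 the
  homozygous junction density is 1.81/Morgan rather than 2, so the
  fully-inbred formula would understate map length by ~10%.

The remaining downward bias of estimated chromosome lengths (~5% at the
default design) is detection loss — recombination events hidden in
masked or sub-resolution segments — not estimator bias; it shrinks with
marker density and vanishes on error-free markers.  Per-chromosome
summaries report average spacing as length ÷ marker count, the
convention of the field's summary tables.  R ≥ 0.5 is clamped to 0.4999
with a warning; a zero-informative interval contributes 0 cM.

## ICIM-ADD scan

Per trait and environment: genotype scores x ∈ {+1, 0, −1} for {A, H, B}
(missing mean-imputed for regression only), forward–backward stepwise
selection with entry at partial-F p ≤ `p_in` = 0.001 and removal at
p > `p_out` = 2·p_in (the removal probability is not fixed by the
protocol; twice the entry value is the conventional choice and is
configurable).  Walking a 1 cM grid, the phenotype is adjusted by the
fitted coefficients of all selected markers except the two flanking the
current interval.  QTL genotype probabilities per line condition on the
flanking genotypes through the Markov RIL process (cM → meiotic r by
inverse Kosambi, then R = 2r/(1+2r) per sub-interval); a single
informative flank conditions on that flank alone, double-het flanks are
assigned to the het component, double-missing gives the ½ prior.

At each position a three-component normal mixture (means m+a, m, m−a,
common σ; the het mean constrained to midparent — no dominance in the
additive model) is fitted by EM with per-line mixing probabilities.  The
M-step solves the 2×2 weighted least-squares system for (m, a); the
log-likelihood is asserted non-decreasing (tolerance 1e-8) and iterated
to ΔlogL < 1e-6 or 100 iterations.  LOD = log10 L1/L0 against a single
normal; with fully informative genotypes this equals the closed-form
regression LOD (n/2)·log10(RSS0/RSS1) to 1e-6.  Peaks are grid local
maxima ≥ 2.5 separated by ≥ 1-LOD valleys; each peak reports the markers
bracketing its 1-LOD support interval, the additive effect a =
(μ_A − μ_B)/2, and PVE = 100·Var(â·x̂)/Var(y) with x̂ the posterior
expected score at the peak.  Because the adjustment removes the signal
everywhere except the selected marker's own intervals, ICIM profiles are
spiky and support intervals narrow; peak location inherits the
uncertainty of the stepwise marker choice (~2 cM SD at PVE 10%,
n = 192), and PVE estimates of detected peaks carry the usual selection
inflation (~+2 points at PVE 10).

Stability and clustering follow the study's definitions: same-trait QTLs
with overlapping flanking-marker intervals in ≥ 3 distinct environments
are stable; QTLs of different traits with overlapping intervals form
clusters by single linkage, the cluster interval being the union.  PVE
and PEV are treated as the same quantity.

## Differential expression

The contrasts are unreplicated (two parents; two bulked pools), so
dispersion is fixed rather than estimated: default 0.01 (biological CV
0.1, the conventional value for genetically near-identical material),
configurable.  The test conditions on the two-sample sum t: the
conditional distribution of one count given t is enumerated from NB
masses with means proportional to library sizes (Poisson at dispersion
0, where the conditional is exactly binomial with p = ls_a/(ls_a+ls_b)),
and the two-sided p-value is the total mass of splits no more probable
than the observed one (log-scale comparison with 1e-10 tie tolerance).
Fold changes are reported on CPM with a prior count of 0.5 (bounded
log2FC at zero counts) and a direction sign relative to the baseline
sample (PYZX and H-Pool are the baselines).  BH adjustment uses the
standard step-up (via statsmodels), checked against a brute-force
implementation of the definition.  Significance is FDR ≤ 0.05 AND
|log2FC| ≥ 1, both inclusive.  The upstream "background noise"
normalisation between the parental and pool contrasts is not
reconstructable from its description; an optional filter that drops pool
DEGs whose direction contradicts the parental contrast can be applied by
users but is deliberately not part of any default path.

## Co-localization

A cluster's physical interval runs from its left flanking marker's start
to its right flanking marker's end (1-based inclusive).  Genes overlap
an interval if [start, end] intersects [interval ± flank]; the default
flank is 0 (strict containment) because "near the QTL" carries no stated
distance, and within-flank hits are labelled distinctly with their
distance.  Counts per cluster equal a brute-force scan by construction
(tested).

## Problem sizes and calibration checks

The acceptance script and test suite size the experiments to desk scale:
the full default design (12 chromosomes, 373 Mb, 1,172 cM meiotic,
123k sites, 192 lines) for breakpoint recovery and the end-to-end run;
two ~43/36 Mb chromosomes × 10 replicates for map-length recovery
(replicate-averaged, since realized recombination varies ~5% per
chromosome per replicate); 50 replicates of a two-chromosome genome with
error-free markers at 1.25 cM spacing for QTL power and PVE recovery
(isolating the scan from the GBS channel, which the other checks cover);
5,000 null + 100 spiked genes × 20 replicates for FDR calibration; 5,000
independent null markers for distortion-test calibration.

## Limitations

* Uniform SNP placement and independent per-line capture; no
  restriction-fragment clustering, no shared capture across lines.
* No crossover interference; Kosambi is used for distance conversion
  only.
* Phenotypes are strictly additive across loci with per-environment
  effect multipliers; no epistasis or G×E beyond that.
* Two-point map estimation loses events hidden in masked or
  heterozygous bins (~5% length deflation at the default design);
  multipoint estimation is out of scope by design.
* The DE test's fixed dispersion is an assumption, not an estimate; its
  FDR calibration is demonstrated when the assumed dispersion matches
  the data-generating one.
* Passing recovery tests on this generator shows the estimators are
  correct under the stated design; it does not certify performance under
  real GBS artefacts (allele-specific capture, mapping bias, clustered
  errors).
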