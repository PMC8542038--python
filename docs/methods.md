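# Methods

`chromarch` reimplements, as a tested pipeline, a differential analysis of
3D genome architecture between two cell states (a wild-type and a knockout
hepatocyte line): contact-matrix balancing, A/B compartment calling and
switch quantification, TAD/boundary analysis, chromatin loop calling, a
compartment-constrained polymer model of the nucleus, and the joining of
expression changes to compartment switches. Because the original sequencing
libraries are not processed here, every stage is validated against synthetic
two-condition genomes whose architecture is planted and therefore exactly
known. This note records the models, the parameters that matter, and the
choices made where the underlying procedure left the design open.

## The generative model

Contacts are intra-chromosomal only; every structure analysed (compartments,
TADs, loops) is called per chromosome. Architecture lives on a
multi-resolution grid planted once per genome: compartment labels on coarse
bins (default 500 kb), TAD boundaries on an intermediate grid (50 kb), loop
pixels on the finest grid (25 kb). One fine-resolution library is sampled per
condition and coarser matrices are obtained by block summation, the way one
sequencing library serves all analysis resolutions in practice.

Expected contact between fine bins i and j of one chromosome:

    E[i, j] = d * max(|i - j|, 1)^(-alpha) * m(i, j)

where `m` multiplies `rho` when the bins share a compartment label, `tau`
when they share a TAD, and `loop_boost` on planted loop pixels; observed
counts are independent Poisson draws on the upper triangle, mirrored.
Defaults: `alpha = 1.0`, `rho = 1.4`, `tau = 2.0`, `loop_boost = 3.0`,
chosen so the checkerboard, the block-diagonal triangles and the focal peaks
are each visible without any one dominating — the callers must succeed from
realistic, not caricatured, signal. `d` (expected counts at unit fine-bin
distance) is exposed as a parameter because real per-condition depths vary
by orders of magnitude; recovery experiments use `d = 1e6` (deep) and the
expression experiment `1e4`.

Compartment labels form alternating A/B runs with geometric lengths (mean
4 compartment bins ~ 2 Mb) and a stationary A fraction of 0.6, typical of a
gene-rich cultured cell. TAD sizes are uniform on 8-25 TAD bins
(0.4-1.25 Mb at 50 kb). Loops get uniform anchor separations of 12-80 fine
bins (0.3-2 Mb at 25 kb), at least 6 bins from chromosome ends — closer
pixels are structurally uncallable under the donut caller's eligibility
rule, and sub-300-kb loops are rare in practice.

Condition 2 differs from condition 1 in three recorded edits:

* **Flips** — exactly `round(flip_fraction * n_compartment_bins)` bins
  change label, planted as contiguous segments (mean ~2.5 bins) because
  switching in real data affects regions, not isolated 500-kb bins. The
  default fraction, 0.121, is the switching rate the pipeline is expected
  to recover.
* **Boundary weakening** — a fraction of boundaries receive a merge
  exponent mu ~ U(0.3, 0.75): contacts between the two flanking domains are
  multiplied by `tau^mu` (mu = 0 intact, mu = 1 fully merged). The range is
  deliberately heterogeneous: the phenomenon being modelled is that most
  affected boundaries weaken while some TADs merge outright. Under the TAD
  caller's defaults the detection-loss probability rises from <5% below
  mu = 0.5 to ~60% at mu = 0.75, so this range yields ~85% of weakened
  boundaries still detected (and classified weaker) and ~15% genuine merges
  (driving the fewer-and-larger-domains signature).
* **Loop loss** — exactly `round(loop_loss_fraction * n_loops)` planted
  pixels are absent from condition 2 (default fraction 0.3).

An optional `checkerboard_attenuation` scales the condition-2 compartment
affinity toward 1 (`rho_2 = 1 + (rho-1)*attenuation`), emulating the
knockout's visibly weakened plaid pattern; it is off (1.0) by default so
that the two conditions differ only through the three recorded edits.

Marker tracks emit 2.0 (enriched) vs 0.5 (depleted) coverage units per fine
bin — H3K4me1/H3K27ac high over A, H3K9me3/H3K27me3 high over B — with
Gaussian noise of sd `2.0 / snr`. Genes are placed uniformly (midpoint-bin
assignment; unambiguous for genes straddling bin edges), expression is
log-normal around 8 FPKM, and genes in flipped bins get a planted fold
change (`/de_effect` for A->B, `*de_effect` for B->A) plus log-normal noise
(sd 0.25 in log2). A 5% background of stable-bin genes receives the same
effect size in a random direction so that the DE/switch overlap is
non-trivial, as in real data where most expression changes are unrelated to
compartment switching. `de_flag` derives from the planted expected fold
change (|log2| >= 1), reflecting that differential-expression calls are an
input to this pipeline, not something it computes.

### What the generator does not emulate

No inter-chromosomal contacts, no read-level simulation, no
restriction-fragment or mappability structure, no replicate batch effects,
no distance-dependent noise beyond Poisson counting. Passing tests therefore
demonstrate that the callers recover planted architecture under Poisson
sampling, not that they are robust to the full noise anatomy of real Hi-C.

## Balancing and normalization

KR-style balancing is implemented as symmetric alternating scaling
(Sinkhorn-type): `B = D A D` with D iterated until every unmasked row sum
equals the mean raw unmasked row sum within `tol` (default 1e-8, max 3000
sweeps; non-convergence raises with the residual). Balanced rows sum to the
mean raw row sum rather than 1, keeping counts on an interpretable scale for
the Poisson loop test. Bins with zero contacts, plus bins below the 1st
percentile of nonzero row sums, are masked before balancing — standard
unmappable-bin practice that also prevents divergence; the percentile is
configurable. O/E normalization divides each entry by the mean unmasked
entry at its genomic offset on the same chromosome; empty offsets yield 0.

## Compartments

Per chromosome, the Pearson correlation matrix of the O/E matrix (masked and
zero-variance bins excluded; at least 10 usable bins required) is
eigendecomposed and the top eigenvector (PC1, unit norm) taken. The sign is
set against histone marks: s = sum of Pearson correlations of PC1 with the
two active-mark tracks minus the sum with the two repressive-mark tracks;
PC1 is negated when s < 0, and |s| < 0.05 raises an explicit ambiguity error
rather than guessing — a silent wrong sign would invert every downstream
label. A bins have oriented PC1 > 0; exact zeros take the nearest nonzero
neighbour's label (tie -> B). The compartment degree is the oriented PC1
divided by its maximum absolute entry, a monotone per-chromosome activity
index in [-1, 1]; the reference formula behind the published "compartment
degree" is not reproducible from the text, so this simplest max-abs
normalization is pinned here and recorded in output metadata. Known
limitation: on short chromosomes with strongly skewed A/B composition the
compartment signal can migrate to the second eigenvector (near-degenerate
eigenvalues); the top-eigenvector contract is kept, and the regime is
excluded from the validated envelope (chromosomes of ~100+ compartment
bins).

Switch classification intersects two profiles bin-wise (masked in either ->
masked) into stable A, stable B, A->B, B->A; percentages are over unmasked
bins.

## TADs

binSignal at position i is the mean balanced contact between the w bins
ending at i and the w bins starting at i+1 (default w = 5 at 50 kb),
clipped at ends and skipping masked bins; a centred running mean (span 3)
smooths it. Boundaries are prominent local minima of the smoothed signal:
the leftmost bin of a minimal plateau over a +-w window whose prominence
(min of left/right window maxima minus the minimum) is at least
`min_depth = 0.1` of that local flanking maximum. The relative criterion is
deliberate — an absolute threshold makes detection depend on the compartment
context the boundary sits in. The reported boundary bin is the binSignal
minimum, which sits on the last bin of the upstream domain (one bin left of
the first bin of the downstream domain); truth comparisons use +-1 bin
slack accordingly. Boundary strength is the insulation depth: mean
binSignal over the two flanking domain interiors (boundary bins excluded)
minus binSignal at the boundary. Two-condition comparison matches
boundaries greedily by nearest position within 2 bins (sampling jitter
moves minima by ~1 bin) and classifies relative strength changes beyond
+-10% as stronger/weaker; unmatched boundaries are gained/lost. The
original significance procedure behind "significantly weakened" boundaries
is unstated; this package reports effect-size classes and makes no claim to
reproduce that test.

## Loops

A transparent, simplified donut caller at 25 kb: for each eligible pixel
(upper triangle, more than `r_outer` bins from the diagonal and every edge,
both bins unmasked) the local background is the mean over the Chebyshev
annulus `r_inner < r <= r_outer` (defaults 2 and 5) excluding the pixel's
row/column stripes and masked bins. The rounded balanced count gets a
Poisson upper-tail p-value against that background (balanced counts are
near-counts at these depths; an approximation, documented as such), with
plain per-chromosome Benjamini-Hochberg control — matrix sizes here do not
need HiCCUPS's lambda-chunking. Retained pixels must also clear two
enrichment floors: 1.75x the donut background, and 1.4x the mean of the
lower-left quadrant of the annulus. The quadrant guard exists because a
domain-corner pixel is ~tau-fold enriched over a full-donut background that
averages in-domain and out-of-domain territory, so at Hi-C depths corners
are otherwise called with arbitrarily small q; the lower-left quadrant
stays inside the domain and neutralizes exactly this geometry, while 1.4
sits below the enrichment a genuine cross-boundary loop retains over
in-domain background (loop_boost/tau = 1.5 under the generative model).
Surviving pixels are merged 8-connected, keeping each cluster's most
significant pixel. The caller never claims pixel-level concordance with
HiCCUPS. Loop-set comparison matches pixels within Chebyshev distance 1.

## 3D model

One chain per chromosome, one bead per compartment-resolution bin, inside a
nucleus of radius R = 10 (arbitrary length units). Three potentials: bonds
`k_b (|x_{i+1}-x_i| - b)^2` with b = 0.5 and k_b = 50; a radial bias
`k_r (|x_i| - t_i)^2` with k_r = 5 and `t_i = R(0.5 - 0.35 * degree_i)`
(degree +1 -> 0.15R, -1 -> 0.85R, masked -> 0.5R; the linear map and its
coefficients are a design choice, config-exposed); and soft-core repulsion
`k_rep (sigma - r)^2` for r < sigma = 0.8b, k_rep = 10. Active chromatin is
placed toward the nucleus centre — the convention adopted by the modelled
study, kept here deliberately even though much literature places active
chromatin peripherally within territories. Optimization is damped Langevin
descent: gradient steps (step 2e-3, per-bead displacement clipped at 0.5b)
plus Gaussian noise decaying geometrically over the first 90% of steps
(simulated-annealing flavour), then noiseless descent; the best-energy
configuration visited is returned, so the recorded energy trajectory is
non-increasing by construction. Several restarts (default 5) are optimized
and the lowest kept, with all restart energies reported — restarting from
random structures to suppress conformational variation. The chain count
follows the input profiles; given the 21 chromosomes of a male mouse genome
it reproduces a 21-chain system, without hard-coding that number.

Reported summaries (mean radius by compartment label; compactness = mean
within-chain pairwise bead distance, deterministically subsampled above 1e5
pairs) are isometry-invariant and agree across seeds to within ~10%; bead
coordinates themselves are not reproducible quantities.

**Limitation — the "loosening" comparison.** The knockout's looser
chromatin cannot be reproduced by this model class, and the package does
not pretend otherwise. The 3D stage consumes only the normalized
compartment degree plus connectivity: planted TAD weakening and loop loss
never reach it, and the flip set alone has no reliable directional effect
on compactness (measured effect is sign-unstable across architectures,
~±0.2 on a score of ~4.5). Physically, "loosened chromatin" is the
weakening of attractive pairwise contacts, and this model — by its stated
scope — contains no attractive pairwise term (Hi-C distance restraints
between arbitrary bead pairs are out of scope). Weakening the radial
segregation instead *compacts* the model genome, because it shrinks the
radius variance inside a fixed nucleus. The compactness comparison is still
computed and reported; the corresponding test documents the expected
direction and fails honestly.

## Expression integration

Genes are assigned the switch class of their midpoint bin; log2 fold change
uses a pseudocount of 0.01 FPKM. Per-class summaries (n, median, mean, IQR)
come with a two-sided Mann-Whitney U test of A->B vs B->A. Candidate genes
are DE genes in switched bins whose direction is concordant with the switch
(down in A->B, up in B->A); whether the original candidate list required
concordance or only positional overlap is not stated, so the discordant set
is emitted separately and the Venn counts use positional overlap, making
either convention recoverable. As an operational restatement of the
expression-switch coupling, the Spearman correlation between gene log2FC
and the bin's compartment-degree change (KO minus WT) is reported.

## Problem sizes

Validation experiments run at: 5 chromosomes x 200 compartment bins (fine
grid 4000 bins) for switch recovery; 2 x 100 compartment bins over 5 seeds
for the TAD signature (weakening planted in isolation — flips create and
destroy genuine A/B-interface insulation dips that would otherwise dominate
the domain-count comparison); single 500-800-fine-bin chromosomes for loop
calibration (20 null seeds) and recovery (3 seeds); 3 chains x 60 beads
over 5 seeds for the 3D summaries; 2 x 100 compartment bins with 2000 genes
for the expression coupling. These sizes make the full validation suite a
desk-scale computation while keeping every per-chromosome statistic at a
scale where its estimator is well-behaved.
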