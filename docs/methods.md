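# Methods

## The DNS score and its moments

Aligned read intervals from two replicates × two MNase digest levels are
counted into fixed 10-bp bins; a read contributes one count to every bin it
overlaps by at least 1 bp (the bins are the reference elements, matching
`bedmap --count` semantics). Each sample's track is scaled to counts per
million genome-wide uniquely mapped reads, and the per-bin DNS score is the
light minus the heavy normalized coverage; per-replicate scores are averaged
for presentation and downstream aggregation. Negative scores mark
hyper-resistant (closed), positive scores hyper-sensitive (open) chromatin.

Bins with zero raw coverage in all four samples (unassembled or unmappable
space in real data) are masked: they carry a stored value of 0 but are
excluded from genome-wide moments, correlations and interval aggregation.
Genome mean and SD use the population formula over unmasked bins — at
genome scale the sample/population distinction is immaterial and the choice
is fixed for determinism. Terminal bins of chromosomes whose length is not
a bin multiple keep their true (shorter) width and are treated as ordinary
bins. Interval aggregation reports the *unweighted* mean over overlapping
bins, which keeps scores comparable across regions of different size;
interval sums are additive over disjoint unions.

Replicate agreement is Pearson's r over mutually unmasked bins. Its value
depends strongly on the unit: at 10-bp bins and simulation-scale depth it is
noise-dominated (≈0.4 at 30×), while at 1-Mb windows, where real chromatin
structure dominates counting noise, it exceeds 0.99. Both units are
computed; published genome-scale values (r ≈ 0.98) are consistent with the
window-scale regime of a 14-Gb genome at ~10⁹ reads.

## Footprint calling

Each replicate's DNS track is standardized by its own genome-wide mean and
SD. MSFs are maximal runs of bins with z ≥ cutoff (default 1.5), MRFs runs
with z ≤ −cutoff. Runs separated by at most `max_gap_bins` bins of
sub-threshold but same-sign z may be merged; a merged segment is kept only
if its mean |z| still clears the cutoff, and segments shorter than
`min_len_bins` are dropped. Module defaults are deliberately conservative
(gap 0, minimum length 1 bin): the thresholded-run rule is an explicit,
reproducible segmenter, not a reimplementation of any external
segmentation program, and the 1.5-SD biological cutoff is the contract.

For 100–200-bp size-selected fragment data we recommend — and use in the
acceptance analyses — `max_gap_bins=15, min_len_bins=3`: 15 bins is one
fragment length, the correlation scale of the coverage noise, so gaps up to
one fragment are bridged while isolated 1–2-bin noise excursions are
discarded.

Consensus footprints are the coordinate intersection of same-kind intervals
from the two replicates ("above the cutoff in both"), rescored on the
replicate-averaged track; a union mode exists behind a flag. Fragment-length
physics limits boundary precision to roughly half a fragment (~75 bp), so
recovery of planted features is assessed by Jaccard overlap, with feature
sizes several-fold above the fragment length.

## Genomic context and enrichment

Every footprint receives exactly one context label, decided by its midpoint
under the precedence gene body > 2-kb upstream > 2-kb downstream (both
strand-aware from the CDS boundaries) > TE > unannotated intergenic, so
proportions sum to one; a `te-first` precedence is available because
published category totals do not disambiguate TEs inside genic envelopes.
Nearest-gene distances are measured midpoint to gene-model edge (0 inside);
their distribution mode is the peak of a Gaussian KDE (Silverman bandwidth)
on log10(d+1), back-transformed, which is the natural location summary for
these heavily right-skewed distributions (the reported "mode" is therefore
the log-scale density peak). Enrichment uses two-sided Fisher's exact
tests; segment-level tests (distal R1+R3 vs interior) count base pairs
because segment sizes differ, while TE-composition tests count elements.

## Gene-centred profiles and homoeolog bias

All gene-anchored windows are strand-oriented with the CDS start as origin.
The metagene profile averages DNS in 10-bp steps over −1 kb..+1 kb; regions
a/b/c/d are the four 500-bp windows spanning −1 kb..+1 kb, computed only
for genes whose full window fits on the chromosome (fixed-width
comparability across subgenomes). Expression–accessibility association is
Pearson's r between log10(tpm) and the region's mean DNS, restricted to
expressed genes (mean tpm ≥ 0.1); a pseudocount flag exists for analyses
including zeros.

Homoeologous triplets with summed expression ≥ 0.5 tpm are assigned to
seven bias categories by nearest Euclidean centroid on their relative
contributions (rA, rB, rD): balanced (⅓,⅓,⅓), single-homoeolog dominant
(1 on one subgenome), single-homoeolog suppressed (0 on one subgenome, ½ on
the others); exact ties resolve to balanced and the centroid table is
configurable — it is this package's operationalization of the published
seven-category scheme, not a restatement of the original thresholds.
Cross-subgenome differences in region a/b/c/d scores are tested per
category with Kruskal-Wallis plus pairwise Mann-Whitney under
Benjamini-Hochberg adjustment; rank tests use scipy's implementations
(exact small-sample Mann-Whitney when tie-free, tie-corrected normal
approximation otherwise), validated in the test suite against brute-force
permutation enumeration.

## Intergenic space and TEs

Overlapping gene models are merged into occupied blocks; one intergenic
interval spans each adjacent block pair (terminal gaps excluded), classed by
length as <10 kb, 10–100 kb, 100 kb–1 Mb, ≥1 Mb (left-closed boundaries).
Decay profiles lay 1-kb windows from each flanking edge inward until the
midpoint — floor((L/2)/1000) windows per side, both flanks pooled — and the
class background score is the KDE mode (Silverman, linear scale, smaller
mode on ties) of the pooled window values, requiring at least 100 windows.
Short-vs-long spacing comparisons use Mann-Whitney on equal-size random
subsamples, genome-wide and within distal (R1+R3) and pericentromeric (C)
strata. TE statistics are per-element interval means summarized (mean,
sample SD) by family, superfamily and subgenome; the Gypsy correlation is
Spearman's ρ between RLG covered-bp fraction and mean DNS in 1-Mb windows
with 200-kb step, over windows containing any RLG. A TE is
"promoter-proximal" if it overlaps a strand-aware 2-kb upstream window by
≥1 bp; a gene is "TE-near" if any TE lies within 2 kb of its model.

## Centromere prediction

Works at window resolution (1 Mb for wheat-scale chromosomes; the window
must not exceed half the expected CENH3 interval). Candidate regions are
maximal runs of windows whose Cereba covered-bp fraction reaches the
per-chromosome quantile of nonzero densities, capped at half the
chromosome maximum so a dense core split across adjacent windows stays one
run. The predicted point is the centre of the window maximizing smoothed
DNS within the candidates — the DNS peak, not the coverage minimum, is the
primary locator, since read-depth and repeat-density minima can be
displaced from the functional centromere while the DNS peak tracks CENH3
chromatin. Without any Cereba annotation the global DNS argmax is returned
with a low-confidence flag. Ties within 1% of the smoothed-DNS range
resolve to the lower-depth window, then the smaller coordinate (the
range-based band keeps predictions invariant to uniform score shifts).

## Variance partitioning (GREML)

Unmasked 10-bp bins are ranked by DNS and cut into quantile groups (five by
default, each 20% of the scored genome; ties break by genomic order). SNPs
are filtered MAF > 0.002, thinned to the first SNP per 10-kb genomic tile,
restricted to gene bodies ±1 kb, and assigned to the group of their
containing bin; the filter order is configurable since thinning before or
after the genic restriction changes counts. For the most closed and most
open groups, repeated random subsets build a VanRaden GRM
(A = ZZᵀ/m on allele-frequency-standardized genotypes, missing values
mean-imputed, monomorphic SNPs dropped) and the single-component model
y = μ + g + e with g ~ N(0, Aσg²) is fitted by REML: after an
eigendecomposition of A the restricted likelihood is profiled over the
variance ratio λ = σg²/σe², leaving a smooth 1-D maximization (bounded
Brent on log λ ∈ [−8, 8]·ln 10); σe² has a closed form at each λ. The
reported V(G)/V(p) = λ/(1+λ) is clipped to [0,1] with boundary fits
flagged; its standard error comes from the observed information of the
restricted likelihood via the delta method. With A = I the ratio is
unidentifiable and the profiled likelihood is flat — the fit is returned
but flagged at the search boundary. The estimator is validated against a
dense-matrix λ-grid search (10⁴ log-spaced points) to 10⁻³ in V(G)/V(p).

## The synthetic genome

The generator defines the study conditions; its defaults are fixed and the
tests are recovery-based against its ground truth.

**Genome.** Six chromosomes (homoeologous groups 1–2 × subgenomes A/B/D) of
8 Mb, segmented R1/R2a/C/R2b/R3 at fractions 0.20/0.25/0.10/0.25/0.20 with
a CENH3 interval covering the central half of C.

**Accessibility surface.** Per 10-bp bin,
a(x) = amp_g·q(x) + grad(x)·(1−q(x)), where q(x) = exp(−d/κ) decays with
distance d to the nearest gene block (κ = 3 kb), amp_g is a per-gene
openness amplitude ~ N(0.35, 0.35²) clipped to [−0.6, 1.5] and shared by
the three homoeologs of a template gene (negative amplitudes model
silenced genes — required for genic SNPs to populate the closed
genome-wide quintiles), and grad declines linearly from +0.25 at the
telomeres to −0.25 at the centromere. TE bodies add family-specific
effects (−0.4 to +0.3 across six families spanning Gypsy/Copia/LINE/CACTA/
Mutator codes). Planted footprints (100 per genome, 400–1000 bp, MSF/MRF
at random, placed ≥5 kb from genes, ≥1 kb from TEs and clear of the CENH3
core) *set* the surface to ±1.1 rather than adding to it, so every
footprint realizes the same DNS contrast (|z| ≈ 3.2 per replicate at 30×)
wherever it lands. Inside CENH3 the surface gains +0.5 (light exceeds
heavy) while both digest rates are scaled by 0.3 (the coverage dip), and
Cereba elements tile ~60% of the core and ~8% of the surrounding C
segment; a decoy Cereba block on one chromosome exercises the
multi-candidate path.

**Reads.** Per bin, fragment counts are Poisson with rate
depth·exp(±a(x)/2) (light +, heavy −), independently per replicate;
`depth` is the expected fragments per bin (2.0 ≈ 30× with 150-bp
fragments). Fragment midpoints are uniform in the bin and lengths
N(150, 20²) clipped to the 100–200-bp size selection. The symmetric
exp(±a/2) construction makes the expected DNS track a(x) in sign while
total coverage is a-independent to first order, keeping footprint contrast
separable from the centromeric depth factor. Midpoint (rather than
start-point) placement keeps the planted feature's coverage ramp centred
on its boundaries — the half-effect point falls at the true edge.

**Expression and triplets.** log10 tpm = 0.8 + 1.0·(promoter
accessibility) + noise, where the noise has a per-triplet shared component
(SD 0.25; the tpm table emulates replicate-averaged data, and homoeologs
share growth-condition effects) plus a small homoeolog-independent residual
(SD 0.08). Non-balanced triplets additionally shift the focal homoeolog's
promoter surface (+0.5 over −500..+500 for dominant; −0.5 over regions
a and d for suppressed) and multiply its tpm (×12 dominant, ×0.05
suppressed), keeping accessibility and expression shifts aligned.

**Genotypes and phenotypes.** SNP positions are uniform in gene bodies
±1 kb; genotypes are iid Binomial(2, p), p ~ U(0.05, 0.5). Causal effects
are drawn only for SNPs in the top (respectively bottom) quintile of the
genic-SNP accessibility distribution, scaled to total variances h²_open
and h²_closed (defaults 0.5 and 0.1); the phenotype adds normal noise.

**What the generator does not emulate.** Mappability and GC structure,
PCR duplicates, alignment error, linkage disequilibrium between SNPs,
TE sequence content, and the within-replicate overdispersion of real
libraries (counts are Poisson by default, with an overdispersion hook for
robustness checks). Passing recovery tests therefore demonstrates
correctness of the measurement and inference chain under a faithful but
idealized noise model, not robustness to artefacts absent from it.

## Numerical and problem-size choices

Test and acceptance analyses run at scales chosen to keep a full session
on one CPU in minutes: the footprint-recovery genome is the 48-Mb default
at 30×; the triplet analysis uses a denser 54-Mb three-group genome
(~740 triplets, ≥100 per bias category on average) at 15×; centromere
calling uses twenty 4-Mb chromosomes at 15× with 100-kb windows; GREML
recovery uses n = 500 individuals × 2000 SNPs and the open/closed
experiment a 12-Mb genome with 12,000 SNPs, thinned at 300 bp (the 10-kb
tile of the full-genome setting is rescaled with the genome).

Two estimator details are deliberate: the intergenic decay rate is fitted
on a fixed subset of ≥30-kb intervals over their shared window range with
the first 1-kb window excluded, because the planted promoter-bias shifts
extend up to ~1 kb past gene edges and the fixed subset removes
interval-composition drift across distances; and the genic-flatness check
regresses gene-body DNS on the planted amplitude before testing for a
segment effect, because amplitudes are shared across homoeologs and a
finite draw can be segment-imbalanced by chance.

At 30× the per-bin DNS lives on a coarse count lattice (standardized-score
atoms ≈ 0.13 apart), so the genome-wide tail mass at |z| ≥ 1.5 is
sensitive to where the threshold cuts the lattice and varies several
percent between runs. Null-calibration checks therefore compare called
footprint base pairs against a Monte-Carlo estimate of the null fragment
process (mean ± 3 SD over independent runs) rather than a continuous
binomial band; the continuous band is asserted where it is exact, on iid
standard-normal score tracks.
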