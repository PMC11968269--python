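# Methods

## The extrusion-processivity contact model

Cohesin processivity λ is the mean genomic length (bp) of DNA extruded by a
cohesin complex before release. The expected contact intensity between an
enhancer element and a locus `d` bp away is

    C_cond(d) = A · exp(−d / λ_cond) + c · (max(d, b) / b)^(−α)

with condition-specific processivity λ_cond, extrusion contact amplitude
`A` (default 10), and a distance power-law polymer background with
coefficient `c` (default 0.5), exponent α (default 1, the classic
contact-probability decay) and genomic unit `b` (default 10 kb, also the
floor below which the background saturates). With the background disabled
the mutant/WT contact ratio is exactly `exp(−d·Δ(1/λ))` where
`Δ(1/λ) = 1/λ_mut − 1/λ_wt`; positive Δ(1/λ) means reduced processivity.
Defaults are λ_wt = 400 kb and λ_mut = 150 kb.

**Coupling convention.** Transcription and cohesin occupancy respond to the
extrusion-*delivered* contact component only: the mutant expression mean is
`μ_mut = μ_wt · exp(−d·Δ(1/λ))^η` with coupling exponent η (default 1), so
the expected expression log2 fold change is exactly
`−η·d·Δ(1/λ)/ln 2`. The rationale is that basal polymer collisions are not
enhancer-mediated activation; only the looped, extrusion-delivered contacts
count. No quantitative contact-to-expression law is established
experimentally — η is a generator convention, and the package treats it as
a free parameter of the simulation, not a biological claim. Contact
matrices, being literal contact maps, always include the background term;
this flattens the contact-modality distance trend by a few percent at
default settings (the fitted λ_mut from contacts lands near 155 kb against
a planted 150 kb, still within the 10% recovery band), while RNA and ChIP
recover the planted value to within ~1%.

## The synthetic locus

The generator lays out, deterministically from a config, a
clustered-protocadherin-like locus on one 100-Mb chromosome: 14 α, 22 β and
22 γ genes (58 total) at 16-kb spacing with 2.4-kb variable exons, followed
downstream by the enhancer elements HS5-1, HS7, HS5-1bL, HS18-20, HS21,
HS22 and HS7L (spaced so distinct elements occupy distinct 10-kb matrix
bins). Cluster-to-enhancer assignment is α→HS5-1, β→HS18-22, γ→HS5-1bL;
the element reference point is the midpoint of the element set's spanning
interval (the enhancer-side anchor is not uniquely defined by convention;
midpoint is this package's documented choice, with a nearest-edge
alternative). Gene anchors are 5′-UTR positions. The geometry guarantees
that every β-gene distance exceeds every γ-gene distance, so reduced
processivity depresses β genes more than γ genes — the cluster-ordering
property the analysis stages must detect. 2000 background genes are spread
evenly over the rest of the chromosome for the enrichment-scan null; a
configurable fraction (default 5%, 60% of them down) receives planted
condition effects of ±1.5 log2 units, emulating genome-wide differential
expression. Coordinates are 0-based half-open throughout; BED files are
written natively in that convention.

Replicate counts are negative binomial with variance `μ + φμ²`
(gamma–Poisson mixture), dispersion φ = 0.05, 3 replicates per condition,
20 M mapped reads per library — typical bulk RNA-seq scale. Cluster genes
default to 20 FPKM baselines (lognormal jitter, σ = 0.4); background genes
draw lognormal FPKM (median 5, σ = 1). ChIP peak tables place one
promoter peak per cluster gene (mutant mean scaled by the extrusion contact
ratio at the gene's distance) and one peak per enhancer; enhancer peaks
with CTCF sites are attenuated by a fixed factor 0.5 in the mutant, while
the HS7 analog carries no CTCF site and keeps a condition-independent
expectation. 4C tracks tile the locus with 2-kb fragments and draw Poisson
counts proportional to the viewpoint's contact profile.

Contact matrices cover a 10-Mb window around the locus at 10-kb bins.
Expected counts combine the power-law background, a ×3 elevation for bin
pairs within the same planted domain (domains are ~0.8–1.3 Mb, the typical
TAD scale; the locus sits inside one elevated superTAD block so that the
block factor cancels from every enhancer–promoter ratio), and the full
`C_cond(d)` profile along enhancer-anchored rows. The matrix is scaled to
an expected cis total of 5 M contacts and Poisson-sampled on the upper
triangle, then mirrored, so symmetry is exact.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analyses consume: replicate
over-dispersion, distance-decaying fold changes with a known slope, planted
domain blocks, enhancer-anchored contact decay, a genome-wide DEG
background. It does not simulate reads, polymer dynamics, individual
extrusion trajectories, CTCF-site orientation, allele-specific choice, or
between-replicate batch structure. Passing tests therefore demonstrate that
the analysis stages correctly invert the generator's model at realistic
noise levels — not that the model itself is a complete account of real
chromatin.

## Quantification

FPKM is `counts · 10⁹ / (length_bp · mapped_total)`; peak enrichment uses
the same formula with peak length. RPM tracks are `count · 10⁶ / total`.
Fold changes are `log2((mean_mut + p)/(mean_wt + p))` with pseudo-count
p = 0.01 FPKM for log stability. Significance uses an unpaired two-tailed
t-test across replicates — Welch's unequal-variance form by default (a
pooled-variance flag is provided) — computed on `log2(level + p)`: with
three replicates the raw-scale test is degenerate for strong fold changes
because the variance scales with the mean, and log-scale testing is the
standard practice for FPKM data (a raw-scale flag is provided). At n = 3
the Welch test runs slightly conservative (empirical type-I error ≈ 0.04
at nominal 0.05). Benjamini–Hochberg adjustment is applied within each
modality across all tested features. DEG thresholds are strict:
|log2FC| > 0.5 and padj < 0.05, boundary values excluded. Interval
assignment everywhere is any-overlap of ≥1 bp in half-open arithmetic.

Virtual-4C per-gene contact values sum the RPM-normalized viewpoint rows of
a gene's assigned enhancer elements over the bins overlapping its variable
exon. Contact matrices have no replicates, so contact fold changes carry no
p-value (flagged NaN rather than an error).

## Enrichment scan

The genome is tiled with non-overlapping 1-Mb bins by default (a `step`
option provides sliding windows; both conventions appear in practice and
the package surfaces the choice rather than hiding it). Hits are
downregulated-gene 5′-UTR anchors, each assigned to the single bin
containing it (half-open; a boundary anchor belongs to the bin starting
there). The Poisson rate is the maximum-likelihood estimate
λ = (total hits)/(number of bins); an option restricts the denominator to
bins overlapping at least one annotated transcript, since the effective
bin count of a real genome is ambiguous (assembly gaps, unplaced
scaffolds). Upper-tail probabilities P(X ≥ k) are computed in log space
from the log-pmf series with an explicit geometric remainder bound, so
p-values far below the double-precision underflow threshold (~1e-308)
remain finite as −log10 p; k = 0 gives p = 1 exactly. Fold enrichment is
k/λ. Raw Poisson p-values rank the bins (a BH column is emitted for
convenience only).

## Topology

Depth normalization scales a matrix so its cis total equals a target
(default 1e8), leaving relative structure untouched; it is applied before
balancing (the order affects only the absolute scale of a balanced
matrix). Knight–Ruiz balancing computes weights `w` with
`w_i·M_ij·w_j` having unit row sums over non-empty bins, using the
inner–outer Newton/conjugate-gradient iteration with a symmetric
iterative-proportional-fitting fallback if Newton stalls (both converge to
the same fixed point); all-zero rows are masked and reported as NaN
weights, and non-convergence raises an error carrying the residual.
Tolerance 1e-8 on the row-sum residual yields row-sum coefficients of
variation below 1e-9 on dense positive matrices.

The directionality index over a window of W bins (default 2 Mb worth) is

    DI = sign(B − A) · ((A−E)²/E + (B−E)²/E),  E = (A+B)/2

with A the upstream and B the downstream contact sum. Edge bins with
truncated windows are flagged; zero-coverage bins are NaN and linearly
interpolated (not zeroed) before HMM fitting. DI is antisymmetric under
mirror reversal of the matrix.

State decoding uses a three-state HMM (upstream-biased, unbiased,
downstream-biased; labels assigned by emission mean) fit by Baum–Welch
with deterministic scale-based initialization and sticky transitions.
Emissions default to a **3-component Gaussian mixture per state**. This is
a deliberate choice: within a biased run the DI decays smoothly from a
large boundary spike toward the mid-domain zero crossing, a heavy-tailed
distribution a single Gaussian cannot cover — with single-Gaussian
emissions the decoded biased runs carry median posteriors around 0.92, and
the ≥0.99 posterior filter below would discard every region regardless of
sequencing depth. The mixture emission family (as in the original
DI-based domain-calling formulation) assigns near-certain posteriors to
the same decoded runs; `mixture_components=1` restores the single-Gaussian
form, and the fitter falls back to it automatically if mixture EM
degenerates on very short tracks. A constant DI track short-circuits to
the unbiased state.

TAD assembly merges consecutive identical maximum-posterior states
(posterior ties resolve to the unbiased state) into regions, then applies
two filters exactly: regions with fewer than 3 bins, or with a median
posterior (of their own state) below 0.99, are excluded with a recorded
reason. A domain extends from the start of a retained downstream-biased
region to the end of the next retained upstream-biased region. Differential
maps are the elementwise mutant − WT difference of identically binned,
equally depth-normalized matrices.

The planted-boundary benchmark uses 500-bin matrices at 20-kb bins
(10 Mb), 8 boundaries with domains of at least 25 bins, elevation 3 and
2 M cis contacts. The 20-kb bin size keeps domains (~1–2 Mb) below the
2-Mb DI window: the DI-HMM formulation assumes domains smaller than the
window, so that every in-domain bin is directionally biased and the DI
traces a V through the domain. Recovery is scored as the fraction of
planted boundaries with a called boundary within ±1 bin; at these
conditions it is ~100%, and the acceptance suite requires ≥90% over 10
matrices.

## Distance-bias fitting and processivity recovery

Fold changes are paired with distances by gene name (inner join; duplicate
ids are an error, missing genes are dropped with a warning). The trend is
ordinary least squares of log2FC on distance in bp — on the log scale the
generator's exponential model is linear, so OLS on noiseless data returns
the generating slope to machine precision. The inversion is
`Δ(1/λ) = −slope·ln2/η` and `λ_mut = 1/(1/λ_wt + Δ(1/λ))` given an assumed
λ_wt; a non-positive implied rate is flagged inconsistent rather than
raised. Cluster contrasts report per-cluster mean/median log2FC with
bootstrap 95% CIs (default 1000 resamples).

Monte-Carlo checks at the default conditions (50 seeds): the mean fitted
slope agrees with −η·Δ(1/λ)/ln2 within 3 Monte-Carlo standard errors for
the RNA and ChIP modalities, and for the contact modality with the polymer
background disabled — the condition under which the closed form holds
exactly. λ_mut recovery is within 10% of the planted 150 kb from all three
modalities at full defaults. The small residual biases are understood: the
log-of-mean estimator's Jensen bias at low mutant counts (RNA/ChIP) and
the background-term flattening (contacts).

## Pipeline

One root seed spawns per-stage seeds through `numpy.random.SeedSequence`;
every stage logs its derived seed, the report records the config hash, and
a rerun with the same config and seed reproduces the report hash
bit-identically. All thresholds (DEG cutoffs, KR tolerance, DI window,
HMM states and mixture components, domain filters) are config keys, none
hard-coded. Problem sizes used by the test and acceptance suites — a
10-Mb contact window at 10-kb bins, 500-bin benchmark matrices, 50–100
simulation seeds — were chosen to keep a full run in seconds-to-minutes
while leaving Monte-Carlo errors well below the tested tolerances.

## Known limitations

* The processivity inversion assumes the single-exponential extrusion
  model; on real data, curvature from enhancer competition, insulation or
  compartmentalization would bias the slope, and λ_wt must be supplied.
* The Poisson scan models bin counts as homogeneous; gene-density
  variation across real bins over-disperses the null, so real-data
  p-values are anti-conservative (the gene-bearing-bins option mitigates
  but does not remove this).
* The t-test stage is a deliberately simple stand-in for count-model DE
  inference; it has no dispersion shrinkage and loses power for
  low-expression genes.
* DI-based calling reports domains only at the scale set by the window;
  nested sub-domain structure is out of scope.
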