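# Methods

`tendomics` reimplements, as a tested library, an integrative analysis of
bulk RNA-seq and ATAC-seq over a postnatal developmental time course
(weekly samples P0-P35 from growing mouse tendon): time-course differential
expression, differential chromatin accessibility over a stringent consensus
peak set, temporal module discovery, peak-gene correlation linkage, and
motif / gene-set enrichment. This note records the models, the parameters
that matter, the numerical choices, and the limits of what the synthetic
validation shows.

## Count model and differential testing

Counts for feature *i* in sample *j* follow a negative binomial (NB2) with
mean mu_ij and dispersion alpha_i (Var = mu + alpha mu^2). Two nested GLMs
with log link and log size-factor offsets are fitted per feature:

    full:     log mu_ij = b_0 + b_RIN x_RIN,j + b_TP[tp_j]
    reduced:  log mu_ij = b_0 + b_RIN x_RIN,j

RIN (RNA integrity number) enters as a blocking covariate so the
likelihood-ratio test of full vs reduced isolates the time effect from
RNA-quality variation. Time points are reference-coded against the
earliest (P0). The LRT statistic 2(ll_full - ll_reduced), clipped at zero,
is referred to chi-square with df = (number of time points - 1).
Per-feature Wald contrasts between time-point pairs use the full-model
coefficient covariance. ATAC samples carry no RIN measurement, so
differential accessibility uses full = intercept + timepoint against an
intercept-only reduced model.

Size factors are median-of-ratios: for sample *j*, the median over
features (with positive geometric mean) of count_ij / geomean_i. CPM
rescales size-factor-normalized columns to one million.

### Dispersion estimation

Both fits of a feature share one dispersion so the models stay strictly
nested. The dispersion is estimated in three stages, all from Cox-Reid
(CR) adjusted profile log-likelihoods ll(alpha) - 0.5 log det(X'WX)
evaluated on a shared log-alpha grid:

1. a per-feature point estimate (grid argmax with parabolic refinement);
2. a parametric mean-dispersion trend alpha(m) = a0 + a1/m, fitted by
   maximizing the pooled CR profile likelihood across features;
3. a per-feature posterior mode under a log-normal prior centered on the
   trend, i.e. a precision-weighted combination of point estimate and
   trend with sampling variance trigamma((n_samples - n_params)/2) and
   prior variance the robust (MAD-based) excess spread of the point
   estimates around the trend (floor 0.05).

The reported p-value additionally averages the chi-square tail over the
dispersion posterior (3-point Gauss-Hermite quadrature in log alpha,
refitting both models at each node), rather than plugging in the
posterior mode.

Plain per-feature maximum likelihood — even CR-adjusted — is visibly
anti-conservative at 6-9 replicates per time point (8-11% of null features
at nominal 5%), because dispersion-estimation noise propagates convexly
into the LRT; plugging in even the moderated estimate leaves a residual
~1-2 point excess. Moderation plus posterior averaging restores
calibration (measured: 4.6-6.0% of raw p < 0.05 and Kolmogorov-Smirnov
distance < 0.02 to Uniform(0,1) on 2,000-feature null simulations with an
active RIN effect). This is the same family of remedy the standard
RNA-seq engines apply; exact output matching with any of them is out of
scope, and the type-I-error simulation in the acceptance suite is the
validation.

At the ATAC design's 2 replicates per time point the chi-square
approximation itself is mildly liberal (~7.5% at nominal 5% even with the
true dispersion), so realized FDR for differential accessibility sits
slightly above nominal; the stringent both-replicate consensus rule is the
compensating filter, trading false negatives for false positives.

### Independent filtering

Features with consistently low counts are removed before multiple-testing
correction: candidate thresholds are the 0-0.95 quantiles (step 0.01) of
mean normalized count; BH is applied above each threshold; the threshold
maximizing the (window-5 moving-average smoothed) rejection count at
alpha = 0.05 wins, ties to the lowest threshold. Filtered features keep
their raw p but receive no adjusted p.

## Consensus peaks and annotation

Per-replicate peak calls overlapping an exclusion blacklist or a
naked-DNA control peak (>= 1 shared base, 0-based half-open) are spurious
and removed. Remaining calls are pooled and merged by transitive overlap;
a merged region enters the consensus iff at least one time point
contributes overlapping calls from both of its replicates (time points
with a single successful replicate are excluded, mirroring a dropped
collection). Each consensus peak is emitted at exactly 500 bp, centered
on the summit of the highest-scoring supporting call (ties -> leftmost).
Fragment counting is midpoint containment: start <= (start+end)/2 < end,
which is unambiguous at peak borders.

Peaks are annotated at their summit with precedence promoter > 5'UTR >
3'UTR > exon > intron > downstream > distal intergenic; the promoter
window is TSS -3,000/+3,000 (strand-aware, configurable). The nearest
gene minimizes |summit - TSS| and is assigned only within +/- 50 kb of
the summit; ties break to the lexicographically smaller gene id. Signed
distances are positive downstream of the TSS in the gene's orientation,
binned at 0-1, 1-3, 3-5, 5-10, 10-100, > 100 kb per direction.

## Normalization for clustering, PAM modules

Significant features (DE genes or DA peaks) are normalized CPM ->
log2(x+1) -> column quantile normalization (ties receive the average of
the tied ranks' reference values) -> row z-score; this order puts quantile
normalization on the log scale and leaves rows in the z units the module
heatmaps display. Replicate columns are kept, not averaged. Constant
rows z-score to zero with a warning.

Modules come from Partitioning Around Medoids on the Pearson distance
d = 1 - r (range [0,2]; zero-variance rows get d = 1 to everything).
BUILD seeds medoids greedily; SWAP applies steepest-descent medoid swaps
until no swap lowers the total within-cluster dissimilarity — each step
strictly decreases the cost, so termination is guaranteed and the run is
deterministic given the input order. Fuzzy membership weights are
proportional to inverse medoid distance (exact medoid matches get weight
1); the hard label is their argmax. k is a configuration choice: 6 for
the DE-gene set, 5 for DA-peak and integrated pair sets, 2 for the
motif-family subset. Rows within a module are ordered for display by
average-linkage hierarchical clustering on the module's Pearson
distances (scipy).

The exact fuzzy-weight formula of the R implementation the analysis
emulates is not published; any monotone scheme consistent with the hard
argmax is acceptable, and the one above is validated by module-recovery
tests (ARI = 1 on six well-separated planted profiles) rather than output
matching.

## Peak-gene integration

Each differentially accessible peak with an assigned gene forms a pair.
Accessibility and expression profiles are quantile-normalized log2-CPM
values averaged over replicates per time point and aligned on the time
points shared by both assays (the RNA series includes a time point the
ATAC series lacks; with the default design 5 of 6 are shared). Pearson r
over the shared profile classifies the pair: positive iff r > 0.5
(candidate enhancers), negative iff r < -0.5, otherwise unclassified —
strict inequalities at the boundary. Pairs need >= 3 shared time points
and finite profile variance; otherwise they stay unclassified with a
recorded reason. Positive pairs are re-clustered with PAM (k = 5) on the
concatenation of their z-scored accessibility and expression profiles,
and can be subset to peaks carrying a motif-family hit (default TEA
family, k = 2) to separate coordinated up- from down-regulation.

Whether the original analysis correlated replicate-level or
timepoint-mean profiles is not documented; replicate means on shared time
points is the minimal consistent choice with unequal replicate counts
(6-9 RNA vs 2 ATAC) and is recorded in the pair table's provenance
attributes.

## Motif scanning and enrichment

A motif is a position probability matrix with pseudocount 0.01 and a
uniform background. Scanning scores every window of summit-centered peak
sequence (and TSS-centered promoter sequence) on both strands with the
log2 odds sum; windows containing N score -infinity. The hit threshold
defaults to 60% of the motif's maximal attainable score — the calibrated
per-motif thresholds of HOMER-style tools are not reproducible without
their background distribution files. Overlapping same-strand hits within
1 bp collapse to the best scorer. Offsets are reported relative to the
summit; their distribution is summarized in 25-bp bins with the fraction
within 100 bp.

Enrichment per module is a one-sided hypergeometric test on the
peak-level hit indicator, foreground = the module's peaks, background =
the remaining consensus peaks (config-exposed; not a GC-matched genomic
sample), BH-adjusted across motifs, significance gated at padj < 0.01 and
q < 0.05 with q = BH-adjusted p by default. Family-level tests pool
member motifs into one indicator and report the best member. Promoter
enrichment applies the same statistic with genes as units, and motifs
significant in both the distal and promoter tests are reported together.
An expression gate keeps only motifs whose transcription factor reaches a
minimum count in at least one RNA sample.

## Gene-set ORA and qPCR statistics

Over-representation of a gene set in a module is the hypergeometric upper
tail on the overlap, with the universe defaulting to all detected genes
(those passing independent filtering) — the conventional conservative
background when the original choice is undocumented. The gene ratio
(overlap / module size) is reported for plotting.

Relative expression from Ct tables: technical replicates collapse by
mean; dCt = Ct_target - Ct_reference (reference gene Ppia in the source
assay); ddCt subtracts the calibrator group's mean dCt; fold change =
2^(-ddCt). Group statistics operate on the dCt values: Kruskal-Wallis
(tie-corrected, scipy) followed by Dunn's pairwise z tests with
tie-corrected variance and BH adjustment across pairs.

## Synthetic study generator

The generator emulates the study design: 6 weekly time points, 6-9 RNA
replicates per time point (drawn per time point), 2 ATAC replicates with
the 4th time point dropped, RIN ~ Uniform(6.7, 10) (the study's inclusion
floor), and a RIN coefficient of 0.15 per unit on log-mean counts.
Gene-level counts are NB draws around log-mean = baseline + module
profile + RIN effect + log library-size factor (log-normal, sigma 0.25).
A fraction frac_de (default 0.22, matching the reported DE share) of
genes receives one of six profile shapes — monotone up/down with early or
late onset, a transient burst at the second time point, and an
intermittent oscillation — with a 2.0 natural-log amplitude (~7-fold),
the scale of strong developmental regulators. Dispersions are
Uniform(0.05, 0.15). Peaks are 500-bp windows on one synthetic
chromosome; a linked fraction (default 0.6, 62% positive) sits within
+/- 50 kb of a differentially expressed gene's TSS and shares (or
opposes) its temporal profile; unlinked peaks are flat, some in a gene
desert beyond every 50 kb window. Per-replicate narrowPeak calls jitter
around true summits, plus irreproducible single-replicate calls and
spurious calls inside emitted blacklist/control intervals. Motif
consensus strings are planted near summits (offsets ~ Normal(0, 40 bp),
matching the observed concentration of motifs within 100 bp of summits)
and in promoters of genes of the matching modules, on either strand.
Default problem sizes (400 genes, 300 peaks) keep a full pipeline run in
the minutes range; they are desk-scale stand-ins, not the study's
genome-wide feature counts.

What the generator does **not** emulate: read-level data, fragment-length
structure, Tn5 sequence bias, GC effects, gene-gene correlation, batch
structure beyond the RIN covariate, and realistic motif co-occurrence.
Passing tests therefore demonstrate correctness of the statistical
machinery and rule fidelity on data satisfying the model's assumptions —
not robustness to the full messiness of real sequencing data, and not
reproduction of the original study's genome-wide counts, which depend on
raw data unavailable at desk scale.

## Reproducibility

A single run seed drives every stochastic stage through CRC32-based
stage-name derivation (all derived seeds < 2^31); identical configuration
and seed give byte-identical outputs and report checksums. All thresholds
(alpha = 0.05 on adjusted p for DE/DA; padj < 0.01 and q < 0.05 for
enrichment; |r| > 0.5 for pair classes; 500 bp width; +/- 50 kb
assignment) are configuration with the defaults above.
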