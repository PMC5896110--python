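# Methods

This note records the models, estimators and numerical choices behind
`intrest`, what the synthetic-data generator does and does not emulate, and
the known limitations of each component.

## Coordinates and reference construction

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
inclusive) is converted at the parsing boundary and every emitted TSV is
1-based inclusive again, matching annotation conventions.  Per gene, the
exons of all isoforms are collapsed to their union — bookended exons
(`[a,b) + [b,c)`) merge, since a zero-length intron cannot exist — and the
introns are exactly the gaps between consecutive collapsed exons.  This
avoids biases from alternative exons or from exonic sequence of one isoform
overlapping an annotated intron of another.  Ordinals number features
1-based within a gene following genomic coordinates (not transcription
direction), which keeps numbering strand-independent; the junction
reference keeps one copy of each distinct exon–exon junction implied by any
transcript's consecutive exon pairs and links each to the collapsed intron
it spans exactly, when one exists.  Introns shared in coordinates by two
overlapping genes are kept as two rows (and fragments count toward both);
the duplication is transparent and filterable downstream.  Repeat masking
never removes rows: the masked sub-intervals are stored per feature and
counting can skip fragments whose feature overlap lies entirely inside
repeats.

## Counting model

The counting unit is the fragment: a single-end read, or a proper read pair
with the mates' aligned blocks unioned (overlapping mates therefore never
double-count).  Blocks derive from CIGAR M/=/X/D; N operations split blocks
and are recorded as splice gaps; a gap contradicted by a block of the other
mate is discarded.  Default filters drop unmapped, secondary and
supplementary alignments; duplicates are counted unless excluded; counting
is unstranded unless a library orientation is given.

Retention support (rule a): a block overlapping the intron that crosses an
intron–exon boundary with at least `junction_anchor` bases on each side
(default 1).  Rule b (default on): a block lying entirely inside the
intron.  A fragment whose splice gap equals the intron exactly is spliced
across it and never supports its retention.  Junction support: a splice gap
matching the junction exactly, with anchored flanking blocks.  A fragment
increments any single feature at most once.  Because per-feature counts are
sums of independent per-fragment indicators, partial counts from any batch
partition merge by addition; counts are therefore invariant to chunk size
and worker scheduling, which the tests check bit-for-bit.

## FPKM (transcript-scaled)

For intron *i* of gene *g*: `FPKM_ig = X_ig / (L_ig · Σ_k X_kg) · 1e9`,
where the sum runs over the gene's introns.  The denominator makes the
quantity a within-gene retention profile: `Σ_i FPKM_ig · L_ig = 1e9`
exactly for every gene with nonzero intron counts (a tested identity).
Genes with all-zero counts yield NaN, never 0 — this NA-propagation rule
holds everywhere in the package.  Exon rows are scaled by the analogous
exon-sum denominator.

## PSI and the geometry of matched support

`Ψ = R/(R+S)`, defined when `R+S ≥ min_support` (default 10).  For Ψ to
estimate the molecule-level retention fraction *r*, R and S must count
events with identical geometric opportunity.  A junction read must span one
splice point; fragments touching the intron body have opportunity
proportional to intron length plus fragment length, and counting them as R
overestimates *r* by a factor of ~2–3 in realistic geometries.  The PSI
pipeline therefore counts R with *matched* geometry
(`psi_counting_options()`): only fragments whose block crosses the intron's
donor boundary — the same genomic point a junction read must span — with
intron-contained fragments excluded.  Conditional on the total support
`n = R+S`, R is then Binomial(n, r), giving the sampling bound
`|Ψ − r| ≤ 3·√(r(1−r)/n)` used in validation.  The descriptive IntRet
counts (FPKM, fold changes) keep the inclusive default counting; the two
configurations serve different estimands.

Known limitation: at a transcription-terminal intron whose terminal exon is
shorter than the fragment length, the junction read's placement window is
truncated by the molecule end while the retention window is not, biasing Ψ
upward toward `2r/(1+r)` at such introns.  This is a property of the data,
not of the estimator's implementation; interpret terminal-intron Ψ with
caution when terminal exons are short.

## U12-type classification

Donor and branch-point position-weight matrices are shipped as TSVs
(probability columns; `#anchor=` marks the first intron base or the branch
adenosine).  The packaged matrices encode the published U12 donor
consensus GTATCCTT, the U12 branch-point consensus TTCCTTAAC (branch A at
position 8) and the U2 donor GTAAGT; a pseudo-probability floor (1e-3,
renormalized) keeps log-odds finite.  Sequences are scored as
`Σ log2(p(base,pos)/background(base))` with N contributing 0, and rescaled
to a relative score in [0, 1] by the matrix's attainable minimum and
maximum — a scale-free criterion that transfers across matrices of
different widths and sharpness.  The branch-point window slides over
offsets −40..−5 from the intron 3' end (clipped to stay inside the intron
and clear of the donor window), keeping the best-scoring offset with ties
broken toward the 3' end.  Class rule: U12 iff donor and branch-point
relative scores both reach their thresholds (default 0.8/0.8); otherwise U2
when the termini are canonical GT..AG or AT..AC; otherwise unannotated.
Introns shorter than the two windows combined are flagged and left
unannotated.  Minus-strand introns are reverse-complemented before scoring,
and classification is invariant under reverse-complementing the genome with
strands flipped (tested).  The U2 donor score is reported but plays no role
in the call — U12 identification is a two-motif threshold rule, not a
likelihood-ratio contest, so unusual U2-like donors cannot veto a strong
U12 signature.  No AT-AC terminus requirement is imposed for U12 calls,
since GT-AG U12-type introns are common.

## Differential retention model

Per intron, the retention counts `Y_is` and the summed counts `J_is` of the
junction(s) spanning it form 2S observations of one negative-binomial GLM
with log link and `Var = μ + α μ²`.  Size factors are computed per
measurement type by median-of-ratios (total-count ratio as fallback,
normalized to geometric mean 1) and enter as offsets, so depth differences
between runs or modes cannot masquerade as retention changes; an option
shares one factor set across types.

**Paired design.**  The default design is
`~ sample + measurement_type + condition:measurement_type` (with
sample-level covariates entering as covariate×type interactions).  The two
measurements of one intron in one sample come from the same RNA sample and
share its expression level, so their noise is strongly positively
correlated; the per-sample intercepts absorb that shared component and the
interaction coefficient — the tested quantity, reported as
`log2_fold_change = β/ln 2` — cleanly measures the change of retention
odds.  Treating the two measurements as independent NB draws (available as
`paired_design=False`) both mis-states the null distribution on correlated
data and, by double-counting expression noise, roughly halves the power of
the interaction test.  The gene-wise usage style applies the same paired
design to (this intron) vs (sum of the gene's other introns) on intron
counts only, which is the classic differential-usage formulation; its null
is "this intron moved like the rest of the gene", so globally uniform
shifts are invisible to it by construction.

**Dispersion.**  Per-feature dispersions are estimated on the Cox–Reid
adjusted profile likelihood (the adjustment compensates for the estimated
coefficients), maximized by bounded 1-D search on log α ∈ [1e-8, 10].
Because the per-feature maximum frequently collapses to the lower bound at
these sample sizes, moderation uses a *common dispersion* — the maximizer
of the summed adjusted profile likelihood over (a subsample of) features —
as the center of a log-normal prior (sd 0.5 on the natural-log scale), and
each feature's final dispersion is the MAP under that prior.  This keeps
boundary-collapsed features from being treated as Poisson while still
adapting to genuine heterogeneity.  Calibration is verified empirically:
under null simulations the p < 0.05 fraction sits near nominal and the
p-value distribution passes a Kolmogorov–Smirnov uniformity check at
n = 2000.

**Tests.**  deseq-style: Wald test (normal reference, SE from the Fisher
information at convergence) on the interaction, with an outlier filter:
observations' Cook's distances `r_P² h / (p (1−h)²)` are computed at a
*robust* method-of-moments dispersion (MAD-based per replicate cell, so an
outlier cannot inflate the dispersion and mask itself), and a feature with
any distance above the 0.99 quantile of F(p, m−p) is removed from testing
with reason `cooks_outlier`.  edger-style: likelihood-ratio χ²(1) of the
full vs interaction-dropped fit at the same dispersion, no outlier filter.
Features with total count below 10 are excluded before testing and do not
count toward the Benjamini–Hochberg hypothesis number; BH is the exact
step-up procedure (NaNs pass through).  Directions are assigned at the
adjusted-p threshold with the sign of the fold change.

**Trend test.**  The Jonckheere–Terpstra statistic
`Σ_{a<b} #{y > x} + ½#{ties}` over ordered group pairs, with a
label-permutation p-value using the +1 correction
`(1 + #{permuted ≥ observed})/(1 + n_perm)` — its floor at 10000
permutations is 1/10001 ≈ 0.0001, so a maximally consistent trend reports
p = 0.0001, never 0.

## Synthetic data

`make_genome` builds random genes (alternating strands) with planted intron
classes: U12-flagged introns carry the donor and branch-point consensus (the
branch-point window starting 20 nt upstream of the 3' end) and, reflecting
the minor spliceosome's lower efficiency, their baseline retention odds are
multiplied by 4 by default; all introns have GT..AG termini.  Baseline
retention fractions are Beta(2, 18) draws (mean ≈ 10%, the regime the
package targets) unless explicit values are planted; differential introns
have their retention multiplied (capped at 0.95) in the test condition.

`simulate_reads` draws per-gene expression from a gamma mixture (NB
fragment totals, dispersion 0.1), then per fragment: (1) a source molecule
— each intron independently retained with probability r; (2) a
length-proportional acceptance step, so molecules at molar frequency r
contribute fragments in proportion to their length exactly as shotgun
sequencing does (without this step, per-point read densities differ between
isoforms and Ψ is biased low); (3) a uniform position on the accepted
molecule.  Reads are written with correct CIGAR/FLAG/mate fields, sorted
and indexed.  Per-sample generator seeds derive from the master seed by
fixed offsets, so adding samples never perturbs earlier ones; all outputs
are byte-deterministic given the seed.  Defaults describe a small
two-condition experiment: 20 genes, 2–4 introns each, 15% U12, 4 samples
per condition, 20 000 paired 75-nt fragments per sample (mean insert 180 ±
20).

The generator deliberately simplifies: retention is decided per fragment
independently (no isoform-level phasing across introns — adequate for
per-intron estimators, wrong for co-retention questions); no sequencing
errors, alternative splice sites, exon skipping or expression covariance;
single-isoform annotations.  Passing tests therefore demonstrate
correctness of counting and estimation under the stated data model, not
robustness to alignment artifacts or annotation incompleteness in real
libraries.

Count-level generators serve the statistical components directly.
`simulate_counts` is the count marginal of the read model: total
informative fragments `N ~ NB(b·lib, 0.1)` split binomially between
retention and splicing at the intron's odds, with log-normal odds jitter
across replicates (variance log(1+0.02) — modest biological variability of
splicing efficiency) and the condition effect multiplying the odds.
`simulate_usage_counts` draws gene totals and splits them multinomially
among the gene's introns (usage jitter 0.02) for the gene-wise test, whose
null lives within genes.  Designed experiments state their own conditions:
the power study floors expected baseline intron coverage at 30 fragments;
the replicate-scaling study uses two-fold effects without a floor so
detection does not saturate; the Ψ-recovery study plants retention
fractions {0.05, 0.1, 0.25, 0.5, 0.9} with exons longer than the fragment
so every splice point has an untruncated placement window (see the
terminal-intron caveat above).

## Numerical choices

IRLS convergence at max |Δβ| < 1e-8 or 100 iterations, steps damped to
keep the linear predictor in [−30, 30]; non-converged or all-zero features
are flagged and excluded from testing with reasons rather than reported at
face value.  Dispersion search tolerance 1e-2 on log α.  Boxplot-style
summaries use linear-interpolation ("type 7") quantiles, whiskers at
1.5×IQR clipped to the data range, and 64 fixed bins over the pooled range,
stated because such statistics are convention-dependent.  Pipeline stages
checkpoint on a hash of the config echo plus SHA-256 of their outputs;
corrupted or missing intermediates trigger re-execution.

## Limitations

Beyond the simulator simplifications above: no CRAM or UMI support; no
multi-mapper reassignment (primary alignments only by default); the
differential tests require exactly two condition levels (ordered designs
are served by the trend test); numerical identity with the established
count-model packages is not a goal — their methodology is followed in
spirit and their agreement is checked at the level of effect estimates and
top-ranked calls, not p-value equality.
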