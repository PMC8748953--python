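# Methods

## Study design encoded by the package

The pipeline targets a four-arm mouse experiment: lean controls held on a
low-fat diet (LD/LD-V), obese controls held on a Western diet (WD/WD-V),
and two diet-switch arms (WD → LD) receiving vehicle (WD/LD-V) or an NNMT
inhibitor (WD/LD-T). Cecal 16S sequencing yields an ASV × sample count
table with taxonomy; an adipose metabolite matrix may accompany it.
Sample accounting is explicit: 8 + 6 + 8 + 8 animals enrolled, minus
2/1/1/1 ceca lost to early saline flushing, gives the 6/5/7/7 = 25
retained samples that every default in the package assumes.

## Taxonomic profiling

Counts aggregate to a rank by summing ASVs sharing that rank's label;
ASVs lacking an assignment pool into a single `unclassified` row, decided
per rank (an ASV can have a phylum but no genus). Relative abundance is
the taxon's percentage of the sample's total at that rank, with the
unclassified bin kept in the denominator; all-zero samples are rejected
loudly rather than dropped. Observed richness counts nonzero ASVs per
sample, excluding ASVs whose whole lineage is unclassified. No
rarefaction is performed anywhere; library size is available as a
covariate through `FeatureTable.library_sizes()`. The per-sample
*Firmicutes*:*Bacteroidetes* ratio is undefined (NaN, never infinite)
when Bacteroidetes is absent; note that group means of this ratio are
heavy-tailed when Bacteroidetes abundances approach zero.

## Diversity

Alpha metrics use raw counts (all values are positive, so no shift is
needed): Shannon H in log base 2; Simpson D = 1 − Σp²; evenness
E = (1/Σp²)/S_obs; Chao1 in its bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)); Faith's PD as the total branch length of
every edge whose subtree contains a present tip, including the root's own
edge when it carries a length (whole-tree convention). Faith's PD is
computed in-package because the convention must also cover multifurcating
(star) roots; it is cross-checked against scikit-bio on binary trees.

Bray–Curtis runs on per-sample relative abundances by default (library
sizes differ between samples); UniFrac goes through scikit-bio and
requires a rooted tree (a root with more than two children is treated as
the unrooted signature and rejected — rooting is the caller's job).
Weighted UniFrac is normalised by default. PCoA is classical scaling
(double-centring of −D²/2, symmetric eigendecomposition); negative
eigenvalues of non-Euclidean inputs are reported, never silently dropped,
and percent-explained is taken over the positive part of the spectrum.

ANOSIM ranks all off-diagonal distances with average ranks on ties and
permutes labels with a seeded generator; p = (1 + #{R_perm ≥ R_obs}) /
(n_perm + 1), with 999 permutations by default (resolution 0.001). The
statistic matches scikit-bio's exactly; the in-package implementation
exists so the permutation stream is reproducible from a seed.

## Conditional group comparisons

Every feature follows the same decision path, recorded in full in its
result object: (1) add exactly 1e−13 to each value (so zero-heavy
abundances can later be logged; switch off for already-positive data);
(2) if any group has zero variance, use Kruskal–Wallis immediately;
(3) otherwise test each group with Shapiro–Wilk and the groups jointly
with Brown–Forsythe (median-centred Levene); "non-normal and/or
heteroscedastic" is read strictly — any group p < α or the
homoscedasticity p < α trips it; (4) failing that, log10 the shifted
values and retest — a successful rescue runs the ANOVA on the logs;
(5) otherwise Kruskal–Wallis on the shifted, un-logged values. α = 0.05,
two-tailed throughout. The path is a pure function of the data.
Brown–Forsythe is conservative at these group sizes (≈1.5 % null
rejections at n = 7 per group); this is a property of the test, not a
bug, and the suite asserts level control rather than exact calibration.

Across the features of one rank, main-effect p-values receive
Benjamini–Hochberg FDR (phyla and genera corrected independently).
Features significant at α get pairwise post-hoc comparisons in the same
family as their omnibus test (pooled-variance t after ANOVA, rank-sum
after KW — the pairwise statistic is this package's documented choice),
on the same scale the omnibus analysed, corrected with the
Benjamini–Krieger–Yekutieli two-stage linear step-up: stage 1 is BH at
q′ = q/(1+q); m0 = m − r1 estimates the true nulls; stage 2 is BH at
q′·m/m0. Reported adjusted values satisfy (adjusted ≤ q) ⇔ rejection and
agree with statsmodels' `fdr_tsbky` flags exactly. The two-stage
procedure is *not* a strict superset of plain BH at the same q (it can
reject fewer when stage 1 comes up empty); tests assert the containments
that do hold.

## The correlation decider

For one paired (x, y), n ≥ 4: Shapiro–Wilk per variable and a two-sided
F-test comparing the two variances. Normality is the binding criterion
for Pearson — two variables on different measurement scales almost always
differ in variance, so a variance imbalance between two *normal*
variables triggers a log10 variance-stabilisation attempt (only when both
are strictly positive) but never demotes to Spearman by itself. A
non-normal variable gets a log10 rescue attempt when strictly positive;
if both variables end up normal, Pearson runs on the (possibly
transformed) values, otherwise Spearman runs on the originals. Spearman
uses average ranks; its p-value comes from the t-approximation at n ≥ 10
and exact permutation enumeration below that. The decision is symmetric
in its arguments.

Each pair is evaluated twice: on the full data, and after removing the
union of points falling strictly outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] in
either variable (quartiles by inclusive linear interpolation, the
spreadsheet convention), so n varies per correlation. A pair whose
coefficient moves by strictly more than 0.2 between arms is flagged
outlier-influenced but is *not* excluded from FDR correction. Fewer than
4 surviving pairs marks the record not-evaluable. Across a genus ×
metabolite grid, BH at 5 % is applied separately to the with- and
without-outlier p-lists. Note that on heavy-tailed marginals the IQR
step removes the tail points that carry most of the Pearson signal, so
without-outlier power is intrinsically lower there; the power checks in
the suite therefore use nominally outlier-free (Gaussian) grids.

## K-means profiling

Samples are clustered on ASV-level relative-abundance vectors (a rank
flag allows genus level) with scikit-learn's Lloyd k-means, best of 50
seeded restarts per k, no feature scaling beyond the percentages
(a standardisation flag exists, default off). The SSE curve over
k = 1…10 is always reported; when k is not fixed, the elbow is the k
maximising the second forward difference of SSE. The study-scale default
fixes k = 5. Cluster ids are canonicalised by decreasing size, then the
lexicographically smallest member, so outputs are deterministic; the
composition report marks clusters drawn from a single treatment group as
exclusive.

## Species consensus

Species tables from a best-hit search (percent identity, e-value) and a
Bayesian classifier (bootstrap confidence) are compared per ASV after
label normalisation (whitespace, case, and stripping the provisional
bracket convention, so "[Clostridium] cocleatum" matches its unbracketed
form). Only exact agreement is definitive. Genus-level consistency
reports, per genus: consistent (all definitive calls name one species),
inconsistent, or no-evidence (zero definitive calls — reported
explicitly, not counted as consistent). No identity/confidence threshold
gates a call; any such filtering belongs upstream.

## Synthetic cohorts

The generator draws, per sample, a genus composition from a Dirichlet
whose mean encodes the group and whose total concentration (default 20)
sets inter-animal variability, then ASV counts from a multinomial at a
lognormal library size (mean 130,000 tags, σ = 0.25, floor 1,000);
column sums equal the drawn library sizes exactly. Group means come from
base genus weights times per-genus and per-phylum fold changes, with the
dominant genus's mean pinned directly per group (defaults 51/68/40/41 %),
the remaining mass shared proportionally — so planted fold changes are
damped by compositional renormalisation, as in real relative-abundance
data. Within-genus ASV weights are drawn once per cohort, giving ASVs of
a genus a shared signal. The default effect set reproduces the study's
qualitative structure: diet-driven shifts in the dominant genus and the
Bacteroidetes/Actinobacteria balance, switch-driven blooms
(*Parasutterella*, *Akkermansia*, *Erysipelatoclostridium*), a strong
treated-arm *Lactobacillus* bloom, presence/absence genera, and an
unclassified-bin effect. The concentration and effect scales were chosen
to land in the weak-clustering regime the design implies — overlapping
groups, a mixed largest k-means cluster, a separable treated arm — rather
than a cleanly separated one.

Metabolites are lognormal; a planted (genus, metabolite, r) links the
metabolite's latent normal to the genus's rank-based (Blom) normal scores
with weight r — a Gaussian copula, so r is a rank correlation, preserved
under the monotone marginals (Spearman's expectation (6/π)·asin(r/2) ≈ r)
and attenuated for zero-inflated genera whose ties compress the ranks.
Multiple genera may target one metabolite; the implied latent system is
checked for positive definiteness before sampling and infeasible targets
raise immediately. A ground-truth ledger (group assignment, library
sizes, mean compositions, planted effects and correlations) accompanies
every cohort.

Random trees join same-genus ASVs first with short branches and genus
subtrees with longer ones (genus-level monophyly), all branch lengths
positive, root edge included. The species-assignment generator is a
synthetic stand-in for aligner/classifier outputs, with configurable
agreement structure (defaults: 60 agreements, 11 disagreements, 20
best-hit-only calls).

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific overdispersion (one concentration governs all genera, so
rare genera are strongly zero-inflated), phylogenetic signal in
abundances, or compositional artefacts beyond the multinomial. Passing
tests demonstrate the machinery's correctness and calibration under this
model, not performance on any particular real data set.

## Numerical and design choices

- Counts are int64; abundances double precision; column sums checked to
  1e−9.
- The 1e−13 shift is applied exactly once per analysis (it is not
  idempotent by design).
- Kruskal–Wallis on completely constant data (possible for all-zero
  taxa) returns p = 1 rather than erroring.
- Seeds: one master seed derives per-stage seeds via `SeedSequence`
  spawning (kept below 2³¹); same config ⇒ bit-identical outputs,
  including TSVs.
- Problem sizes in the test suite (e.g. 50-replicate calibrations,
  20-seed power runs, a 10,200-pair grid exercised once) are chosen to
  give stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

- The per-sample F:B ratio explodes when Bacteroidetes nearly vanishes;
  group medians are more robust than the means the reports print.
- The decider's without-outlier arm loses power on heavy-tailed data by
  construction (see above).
- The single-concentration Dirichlet makes low-abundance genera spikier
  than typical real data, which makes the conditional screen lean heavily
  on Kruskal–Wallis, and slightly conservative overall.
- Longitudinal measurements (body weight over time) are handled only as
  independent per-timepoint comparisons; there is no repeated-measures
  model.
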