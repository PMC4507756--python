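# Methods

## Correlation model and edge rule

The screen treats each genotype's RPKM profile as one observation per gene
and measures pairwise linear association with the Pearson product-moment
coefficient. Significance uses the exact null distribution of r under
bivariate normality via the t transform t = r·√df / √(1 − r²), two-tailed.
Degrees of freedom default to n_obs − 2; `NetworkConfig.df_override` pins
df to a fixed value instead, for replicating analyses that quoted a
specific df (the replication profile uses df = 11, i.e. 13 effective
observations). An edge is *positive* iff r > r_min (0.65) and P < p_max
(0.05), both strict, so boundary values are excluded. Negative and
undefined correlations are reported but never become edges; a zero-variance
profile yields an explicit undefined state (NaN r) rather than r = 0, which
would silently deflate degree counts. P-values are deliberately
unadjusted — the decision rule is a hard r threshold with a per-pair
significance guard, not a controlled-FDR discovery procedure; an optional
Benjamini–Hochberg helper exists for exploratory use.

Numerics: coefficients within 1e-14 of ±1 are snapped to ±1 with the
limiting values t = ±∞, P = 0; computed r is clipped to [−1, 1]. Matrix
round-trips write floats at 17 significant digits and read with pandas'
round-trip parser so values survive IO exactly.

At df = 11 the two-tailed critical |r| at P = 0.05 is
t₀.₉₇₅,₁₁/√(t² + 11) ≈ 0.553 < 0.65: the r threshold is binding, and a
printed coefficient table whose entries all exceed 0.65 needs no separate
significance column. This is why `count_positive_links` can recount a
published table from its coefficients alone.

## Screening

Candidates are correlated against every guide role (isoforms such as
PAL1/PAL2 count separately); a candidate is retained at ≥ min_links
(default 4) positive links. Ties in the report are ordered by descending
link count then lexicographic gene ID, purely for determinism. Candidates
missing from the matrix are skipped with a logged count — annotation-derived
TF lists routinely include unexpressed genes — while missing *guides* are a
hard error, since the guide set defines the screen. RPKM max/min in a
record are taken over all samples of the matrix; a mean over samples is the
natural "average RPKM" companion statistic and differs in general from the
midpoint of the printed extremes.

By default correlation runs on RPKM as loaded; `transform="log2p1"`
correlates log2(RPKM+1). Raw log-normal RPKM has heavier tails than the
normal model behind the t-test, which inflates the null rate of spurious
r > 0.65 calls roughly several-fold at n = 16 (observed empirically in the
test suite); the log transform restores the nominal tail. The default stays
"none" because the screening recipe being reproduced states no transform;
outputs record which was used.

## Filtering, DEG counting, clustering

Expressed means RPKM strictly > 0.5 per sample; the per-sample tallies are
the "number of expressed genes" statistic. DEG counting compares two
genotypes: up when (q + c₀)/(c + c₀) > fold (default fold 2, pseudocount
c₀ = 0), down for the reciprocal, evaluated as cross-multiplication so a
zero denominator cleanly yields the infinite-ratio convention (q > 0,
c = 0 → up). Genes expressed in neither compared sample are excluded first,
which removes 0/0 cases. With c₀ = 0 the counts are invariant to common
rescaling of both profiles (given a fixed considered set) and exactly
antisymmetric: n_up(A,B) = n_down(B,A). A published tally that violates
this identity is an inconsistency of that tally, not a property to emulate.

Genotype clustering defaults to correlation distance (1 − Pearson r) on
log2(RPKM+1) profiles with average linkage — the common choice for
expression-profile dendrograms — with Euclidean-on-log and complete/Ward as
alternatives; the metric and linkage are recorded in output metadata and
the tree exports as Newick via scikit-bio.

## qPCR quantification

Replicate Cts are averaged arithmetically on the Ct scale before ΔCt
(standard Livak usage); replicate dispersion propagates to the ΔCt scale in
quadrature, √(sd_target² + sd_ref²). The ΔΔCt baseline is the mean ΔCt over
all control samples, matching designs that compare each independent treated
fruit against the pooled controls; a single control is allowed with a
warning. Fold change is 2^(−ΔΔCt); with an efficiency estimate supplied the
base becomes 1 + E (Pfaffl-style), but efficiency is reported-only by
default. Group significance is a two-sided Welch t-test (two groups) or
one-way ANOVA (≥ 3 groups, e.g. developmental stages); all-identical inputs
return the limiting p = 1 with a degeneracy flag, and zero within-group
variance with differing means returns p = 0 flagged likewise. Replicate SDs
are reported per sample (technical dispersion); between-fruit dispersion is
available from the per-sample fold changes themselves.

## Synthetic data generator

`simulate_population` models what the screen assumes about a two-parent ×
F1 design profiled at one stage: log-normal RPKM marginals
(RPKM = exp(μ + σz), default μ = 3, σ = 1, i.e. median ≈ 20 RPKM with a
realistic right tail), a single-factor equicorrelated latent module over
the co-regulated guide roles (default ρ = 0.8; the tannin/flavonol roles
LAR, ANR, FLS and F3'H stay independent, mirroring the observed pathway
structure), planted TF candidates, and independent background genes sized
so candidates total 1897 by default. Sample count defaults to 16 (2 parents
+ 14 progeny). Parents are drawn from the same population distribution as
progeny — no heterosis or segregation-distortion model.

A planted TF tracking guide subset S at target latent correlation ρ is
w·u + √(1 − w²)·ε, where u is the standardised mean of the linked guides'
latents and w solves the target: for exchangeable linked guides
corr(TF, gᵢ) = w·sd(u·den) gives w = ρ·√(k/(1 + (k−1)ρ_g)) with k = |S| and
ρ_g the module correlation; for mixed subsets w is set so the *mean*
intended correlation equals ρ. w ∉ (0, 1] means the implied correlation
matrix is not PSD (e.g. ρ > 1/√k over independent guides) and the generator
refuses before sampling. The truth record stores latent-scale targets; the
RPKM-scale correlation they induce is validated empirically in tests rather
than assumed equal. Planted TFs also correlate incidentally with non-linked
module guides (w·ρ_g-scaled), as a real co-regulated TF would.

Dropout marks each background gene with probability `dropout_fraction` and
rescales its row below 0.5 RPKM in every sample, so the expressed filter
removes exactly the marked set; the count is Binomial(n_background, f).
All randomness flows from one `numpy` Generator seeded by the config, so a
config determines its output bit-for-bit.

What the generator does **not** emulate: count-based sampling noise
(RPKM here is continuous log-normal, not derived from reads), gene-length
and library-depth coupling, batch effects, segregating eQTL structure, or
between-gene competition for reads. Passing recovery tests therefore shows
the screen's statistical logic is sound at the stated n and ρ, not that
real octoploid fruit data will yield the same candidate list.

## qPCR simulation

Ct = baseline − log2(relative abundance) + N(0, sd) per replicate, with the
reference gene at abundance 1 everywhere and treated samples at the true
fold. Defaults: triplicates, 3 treated + 3 control samples, 0.2-cycle
noise — typical instrument-level replicate scatter. At zero noise the
estimator is exact by construction (ΔΔCt = −log2 F), making the noisy runs
a pure calibration of noise propagation.

## Problem sizes in the validation suite

The packaged checks run the screen at 16 samples with 500 background genes
over 20 seeds, the estimator calibration at 50 seeds × 3 fruits, the
brute-force network comparison on 100 matrices of ≤ 6 genes × ≤ 8 samples,
and the permutation-null comparison at 10⁵ replicates × 10 fixtures. These
sizes give stable Monte-Carlo margins (3 SE) while keeping the whole suite
in the seconds range.

## Known limitations

- The t-test P assumes bivariate normality; on raw RPKM the reported P is
  anti-conservative (see the transform note above).
- `df_override` applies one df to every pair; per-pair missing data is not
  modelled (the loader enforces complete matrices).
- The screen is correlation-only by design: no partial correlation, mutual
  information or soft thresholding, and negative regulators correlated
  inversely with the pathway will not be found by the positive-link rule.
- DEG counts carry no replication-based inference (no dispersion model or
  test) — they are descriptive fold-ratio tallies, as in the original
  recipe.
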