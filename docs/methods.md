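# Methods

`perturbsig` analyses paired pre-/post-exposure microbiome count tables in
Aitchison (log-ratio) geometry, discovers minimal log-ratio signatures with
cross-validated random forests, and clusters exposure groups by how their
compositional *change* co-locates the mice that go on to react
anaphylactically. This note records the model, the tunable parameters, the
numerical choices, and what the synthetic data do and do not establish.

## Compositional model

A sample of P taxon counts carries only relative information, so every
analysis starts from the closure C[x]_j = x_j / Σ_k x_k, which maps a count
row onto the unit simplex. Zero counts are treated as rounded zeros (taxon
present, below detection) and replaced multiplicatively: a single constant
δ — by default the smallest nonzero proportion observed anywhere in the
closed pre *and* post tables — is substituted for each zero, and the
nonzero parts of the row are shrunk by (1 − z·δ), z the row's zero count,
so the row stays on the simplex and ratios among nonzero parts are
untouched. δ is read on the proportion scale because all downstream
formulas operate on closed rows; an explicit `delta=` override supports
sensitivity analysis. The change from pre (X″) to post (Y″) is the
Aitchison perturbation difference Z″ = Y″ ⊖ X″ = C[Y″/X″], the group
operation of the simplex: it inverts exactly (C[X″·Z″] = Y″) and equals the
identity (uniform composition) when nothing changed.

Three log-ratio transforms are provided: ALR ln(x_j/x_ref) (P−1 features,
one reference denominator), CLR ln(x_j/g(x)) with g the geometric mean
(P features, rows sum to zero), and the full pairwise set PLR ln(x_i/x_j),
i<j (P(P−1)/2 features; 26,335 at P = 230). The CLR here accepts a
per-taxon weight vector but defaults to uniform weights, which makes it the
plain CLR; no principled non-uniform weighting presented itself, so the
hook exists for experimentation only. The Aitchison distance is the
Euclidean distance between CLR rows and equals 1/√P times the Euclidean
distance between full-PLR rows — the package computes it by the CLR route
and *tests* the identity rather than assuming it.

## ALR reference selection

The ALR needs one denominator taxon. Each candidate is scored by how well
its (P−1)-dimensional configuration of inter-sample distances matches the
full-PLR configuration under symmetric Procrustes (translation, rotation,
isotropic scaling; correlation √(1−m²)); the argmax wins, ties breaking to
the lowest taxon index. Both configurations are principal-coordinate
embeddings using *all* axes with eigenvalue > 1e-9, zero-padded to equal
width — no axis cap, since truncation would make the score depend on an
arbitrary dimension choice. Selection runs separately for the pre-exposure
composition and for the perturbation, which generally pick different
references.

A caution discovered while testing: a taxon with exactly constant share is
*not* a perfect reference (correlation exactly 1). The ALR is an oblique —
not orthogonal — linear image of the log data, so even a constant
denominator distorts relative inter-sample distances slightly. The constant
taxon does reliably attain the maximum correlation (≈ 0.99 on random
compositions), and the test suite asserts that, not perfection.

## Distance-based inference

One-way PERMANOVA partitions the squared-distance sum of squares into
between/within-group parts via the Gower-centered decomposition,
SS_total = Σ_{i<j} d²_ij / n and SS_within summed per group, giving
pseudo-F = (SS_B/(a−1))/(SS_W/(n−a)). Significance comes from whole-label
permutations with the add-one rule p = (b+1)/(m+1); when the number of
distinct label arrangements is ≤ 20,000 the null is enumerated exactly
(p then = b/total, observed arrangement included). Default m = 9,999.
PERMDISP2 embeds the distance matrix by PCoA keeping negative-eigenvalue
axes as "imaginary" coordinates (each sample's distance to its group
centroid is √max(d₊² − d₋², 0)), and applies a one-way ANOVA F to those
distances with a label-permutation p. Centroids, not spatial medians, and
no bias adjustment. Pairwise PERMANOVA reuses the full-data distances per
group pair (distances are computed once from the signature; no
re-imputation per pair) and is Benjamini–Hochberg corrected across all
C(g,2) pairs, flagged at α = 0.06 — an unusual level, kept configurable.
The per-feature Kruskal–Wallis screen uses the tie-corrected H statistic
with BH across features; constant features are flagged degenerate with
H = 0, p = 1.

## Signature discovery

Random forests (500 trees, √d features per split, unlimited depth by
default; all knobs exposed via `rf_params`) drive two selectors:

- **Boruta** (binary strain task): each iteration appends a column-shuffled
  shadow copy of every feature, fits a forest, and scores a hit when a real
  feature's impurity importance beats the best shadow. After ≤ `max_iter`
  (default 100) iterations a one-sided binomial test at 0.05 confirms or
  rejects each feature; leftover tentative features are kept when their
  median importance beats the median max-shadow importance.
- **RF-RFE** (multiclass strain×food task): repeatedly drop the
  lowest-importance 20% of remaining features, tracking inner-CV AUROC
  (default 3 inner folds) at each subset size; return the smallest subset
  within one standard error of the best score. The one-SE rule favours
  minimal signatures at a small cost in raw AUROC.

Both selectors are re-run *inside every training fold* of a repeated
stratified CV (published design: 10×10-fold binary, 10×5-fold multiclass),
so held-out AUROC carries no selection bias; the suite checks this by
confirming null-data AUROC stays near 0.5 even with selection switched on.
Binary AUROC is the rank-based (midrank ties) statistic; multiclass AUROC
is Hand & Till's average of pairwise AUCs, computed in-package and verified
against scikit-learn's `ovo` macro average. Both the mean-over-folds and
the pooled-prediction AUROC are reported, since either convention is
defensible. Model significance: the same CV is repeated on (default) 100
label permutations, p = (#{permuted ≥ observed} + 1)/(n_perm + 1).

The final signature is selected and fit on the full data after CV.
Per-feature importance is the permutation-accuracy decrease computed on the
training data with `sklearn.inspection.permutation_importance` (10
repeats); an out-of-bag variant was considered but scikit-learn exposes no
public per-tree OOB indices, and the training-set permutation importance
ranks features identically in practice on these data. The group-mean
signature S̄ (one row per strain×food group, one column per selected
log-ratio) summarizes each group's average response.

## Reactor-entropy clustering

Group pairs whose perturbations the pairwise PERMANOVA could *not*
distinguish (BH-adjusted p > α) are joined by an edge weighted by the
pair's pseudo-F, as stated in the published construction; because a larger
pseudo-F means *less* similarity this convention is counterintuitive, so an
`invert_weights` option (1/F) is provided and documented — on the cases
tested both conventions give the same partitions, since edge *presence*
(driven by the BH test) dominates. Isolated groups remain as singleton
nodes. The Leiden algorithm (configuration-modularity objective,
`leidenalg`, seeded, iterated to convergence) partitions the graph; the
resolution parameter is scanned over a grid (default 40 log-spaced values
in [0.05, 5]) and the chosen partition minimizes the Shannon entropy of the
reactor distribution across clusters — H = −Σ_c q_c ln q_c, q_c the share
of all reactor mice whose group sits in cluster c — with ties broken to the
*largest* resolution (most clusters). Significance of reactor concentration
is a permutation test: reactor labels are shuffled across mice (group sizes
fixed), entropy recomputed, p = (#{null ≤ observed} + 1)/(n_perm + 1).
Per-cluster log-ratio profiles report means with normal-theory 95% CIs
(mean ± 1.96·SE); positive values read as enrichment of the numerator
taxon relative to the signature denominator.

## Synthetic data

`generate_study` emulates the target design: two strains (one
anaphylaxis-prone) × five foods = 10 groups, default 8 mice per group
(mirroring the 7–10 per group of the motivating cohort), paired counts for
P taxa (default 230) at sequencing depth 20,000. Latent compositions are
logistic-normal — log-abundance = community baseline N(0, 3.5²) + strain
shift ± overdispersion N(0, 0.6²) — so planted effects compose *exactly* in
Aitchison geometry, matching the analysis's own algebra (a Dirichlet model
would not). Six strain-informative taxa are shifted ±2.5 log units between
strains; each non-reactor group perturbs five of its own taxa by ±2.0; the
three reactor groups (prone strain × peanut/walnut/egg) share one
perturbation direction plus a 2.5-log-unit depletion of a designated
barrier taxon, whose baseline abundance is pinned to a prevalent level
(+1 sd) because it emulates an abundant mucin-degrading organism and a
depletion below detection depth would leave no trace in counts. Mice in
reactor groups react with probability 0.7 (0.02 elsewhere). Zeros arise
only from multinomial sampling at finite depth — no separate zero-inflation
process — and the defaults land near the 0.55 zero-cell fraction typical of
ASV tables at this scale (tested to ±0.1).

What passing tests on these data show: the pipeline recovers planted
strain/perturbation structure, its permutation machinery is calibrated, and
its algebra is exact. What they do not show: behaviour under real-data
features the generator omits — phylogenetic correlation among taxa,
zero-inflation beyond sampling, uneven sequencing depth, batch effects, or
label noise in reactor calls.

## Problem sizes and numerics

The test suite and `scripts/acceptance.py` run the full chain at reduced
sizes chosen for desk-scale turnaround: P = 50–60 taxa, 6–8 mice per group,
depth 5,000–20,000, 5-fold (binary) / 3-fold (multiclass) CV, 60–100-tree
forests, 15–20 Boruta iterations, 24 label permutations per model, and 999
distance permutations. The published design's full sizes (P = 230, 10×10
and 10×5 CV, 100 permutations, m = 9,999) remain the library defaults.
Numerical conventions throughout: natural logarithms; 1e-9 tolerances on
simplex/symmetry invariants; PCoA drops axes with eigenvalue ≤ 1e-9;
permutation exceedance comparisons use a 1e-12 slack so ties count as
exceedances; empirical p-values never fall below 1/(m+1). Degenerate inputs
are handled explicitly: all-zero count rows are errors naming the sample,
constant features are dropped (selection) or flagged (screens), a
single-feature constant signature yields a zero distance matrix with a
warning, and an empty selection falls back to all features with a warning
rather than fitting on nothing.

## Known limitations

- The CLR "weights" hook is uniform by default and untested against any
  non-uniform weighting scheme.
- Boruta uses impurity importances within iterations (fast) rather than
  permutation importances (slower, sometimes more robust).
- The reactor-entropy objective ignores cluster sizes; a partition that
  dumps *all* mice in one cluster trivially achieves zero entropy — the
  maximal-resolution tie-break and the permutation test are what keep the
  result informative.
- PERMDISP p-values permute the computed centroid distances rather than
  re-deriving centroids per permutation, the standard (vegan-style)
  approximation.
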