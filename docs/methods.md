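# Methods

## Screen data model

The unit of analysis is a well-level table: one record per (plate, well)
with the well's role (`sample` or a user-declared control name), the
targeted gene (symbol + Entrez id), an optional reagent id, and 1–100
numeric data columns. Plate geometry defaults to 384-well (16 × 24,
labels `A01`–`P24`); 96-well and other rectangular layouts are supported,
with labels normalized to a zero-padded form so lexicographic order is
plate order. Tables are *raw* (loaded from CSV) or *derived*; a derived
table records its parent and an append-only log of the operations that
produced it, so any number in a final hit list can be traced back to the
upload. Persistence is a plain directory of TSV tables plus a JSON
metadata file — provenance is what matters analytically, not a relational
backend. Missing numeric cells are explicit (NaN) and excluded from every
statistic; they are never imputed.

## Normalizations

All four normalizations are strictly plate-local, so plate-to-plate drift
cannot leak between plates, and permuting plates permutes outputs.

**Z score.** `Z_i = (x_i − x̄_p)/σ_p` with the mean and *sample* SD
(n − 1 denominator) over all wells of plate *p*. The sample SD is the
common screening convention and gives the convenient
`[1, 2, 3] → [−1, 0, 1]` behaviour. A zero-variance plate yields missing
values with a warning rather than infinities.

**Control score.** `(x_i − x̄_pos,p)/(x̄_pos,p − x̄_neg,p)`, which pins
the positive-control mean to 0 on every plate — useful when the positive
control is the biological reference, as with a strong trafficking
regulator in a toxin-resistance assay. `orientation="percent"` gives the
conventional fraction-of-activation `(x_i − x̄_neg,p)/(x̄_pos,p −
x̄_neg,p)` (0 at the negative, 1 at the positive control) for users who
prefer that scale. With a single control type the score reduces to fold
change `(x_i − x̄_c,p)/x̄_c,p`.

**B score.** Each plate is decomposed by Tukey's two-way median polish:
starting from residuals = data, each sweep subtracts row medians from the
residuals (folding them into the row effects), re-centres the column
effects by their median, then does the same for columns and row effects.
Iteration stops when the largest absolute effect change falls below `tol`
(default 1e-6) or after `max_iter` sweeps (default 10 — median polish
contracts quickly and deep convergence buys little for screening data).
Rows are swept first, matching the formula convention the B score is
usually written with. The reconstruction identity `overall + row_i +
col_j + residual_ij = input_ij` holds exactly on non-missing cells at
every iteration. The B score is `R_ijp / MAD_p` with
`MAD_p = median(|R_ijp|)` over measured wells — the plain median absolute
residual, with no 1.4826 normal-consistency constant (a `scaled_mad` flag
enables it). A purely additive plate has zero MAD; its B scores are
reported missing rather than inflated.

*Invariance caveat.* Offsets constant within each row are removed exactly
by the first row sweep, so B scores are invariant to them to machine
precision. Surfaces involving column offsets are only asymptotically
removed: the alternating L1 sweeps can stall at different fixed points
for the shifted and unshifted plate, leaving B-score differences of order
0.01–0.3 even at full convergence. This is intrinsic to median polish
(R's `stats::medpolish` behaves identically), not an implementation
artifact; what *is* exact is that the residual difference under any
additive row+column surface is itself an additive surface — the
interaction structure of the plate is untouched.

## Quality control

The Z′ factor is computed in the Zhang et al. form
`1 − 3(σ_p + σ_n)/|μ_p − μ_n|` (sample SDs). Quick Analysis reports
box-plot statistics per well type (quartiles by linear interpolation, the
numpy default, so they are exactly testable against order statistics) and
a Z′ for every ordered pair of declared control types — which control is
"positive" is declared by the user, never inferred from the values.
Replicate agreement is the Pearson r over pairwise-complete wells with
the standard correlation t test, `t = r√(n−2)/√(1−r²)`, two-sided p from
the t distribution with n − 2 df.

## Hit identification and multi-reagent validation

Thresholds come from a `CutoffSpec`: `mean(reference) ± k·SD` over
samples or a named control, an explicit value, or the value at a given
rank of the descending-ordered column. Finalizing appends a 0/1 hit
column (missing scores score 0) and returns the passing genes. The
direction of "hit" (≥ or ≤) is always explicit. Raising a ≥ threshold is
monotone: it can only remove hits.

Multi Reagent Analysis operates on deconvolution screens (one row per
gene × reagent). Each scored reagent is flagged against the threshold,
flags are aggregated per gene, and genes are ranked by the number of
passing reagents, ties broken lexicographically by gene symbol for
determinism. A reagent with a missing score is excluded from both the
numerator and its gene's reagent total, so unmeasured reagents do not
penalize a gene. Finalization appends the per-reagent 0/1 flag column and
the per-gene count column. The usual validation rule — a gene is
validated when ≥ 2 independent reagents pass — is exposed as
`validated_genes(min_reagents=2)`.

## GO enrichment and PPI mining

Annotation snapshots are NCBI-style tab-delimited files (gzip
transparent): a gene2go-like layout for gene → GO term assignments
(category strings mapped to BP/CC/MF; unmappable rows skipped and
counted) and an interactions-like layout for undirected PPI edges
(canonicalized smaller-id-first; self-loops and duplicates dropped and
counted).

Enrichment of a selected set of x genes is scored per GO category with
Fisher's exact test on `[[g_c, G_c], [x − g_c, N − G_c]]`, where g_c is
the selected-set overlap with the category, G_c the category's size in
the store, and N the genome size (default 22 000 protein-coding genes).
Note the second column counts the whole genome rather than the
non-selected complement — this is the screen-table convention the package
reproduces; `background="standard"` builds the conventional complement
table `[[g_c, G_c − g_c], [x − g_c, N − G_c − (x − g_c)]]`. The test is
one-sided (enrichment) by default with a two-sided option; the odds ratio
is the sample cross-product ratio, with zero cells reported as 0/inf
rather than continuity-corrected. No multiple-testing correction is
applied by default (the classic workflow filters on raw p ≤ 0.01); a
Benjamini–Hochberg flag is available. Gene identity is keyed on Entrez id
throughout; symbols are display-only.

GO term search is a case-insensitive substring match on the term text
("annotations containing the term"), optionally restricted by namespace;
exclusion (e.g. of "proteasome" genes whose knockdown perturbs a
luciferase readout directly) removes matching genes from a table with the
term logged in the provenance. PPI subnetwork extraction returns every
stored edge with both endpoints in the query set — equivalent to
searching all C(n, 2) pairs — and exports as 2-column TSV or SIF
(`A pp B`).

## Synthetic screens

The generator emulates the workflow the analyses target: pre-printed
384-well library plates with controls in the two outer columns (cycling
STX16/CLTC/KDELR1/PLK1/GFP), one gene per sample well, and replicate
readout columns. Defaults mimic a control-normalized luminescence scale:
negative control at 0 and strong positive at 1 (SD 0.05, giving the
textbook Z′ of 1 − 6·0.05 = 0.70), samples at baseline 0 with SD 0.1.
Planted hits are shifted by 5 sample-SDs by default — the strength of a
solid trafficking regulator, comfortably above a 2–3 SD threshold but far
below the 20 SD control separation; an `effect_sampler` hook supports
dense or graded effect distributions. Systematic errors are additive:
per-plate uniform baseline drift and per-row/per-column uniform offset
surfaces, with amplitudes in readout units. Replicate columns share the
gene effects but draw independent artifact surfaces and noise, as
separate physical plates would. Deconvolution screens emit one row per
(gene, reagent) with score = gene effect × reagent potency + noise;
potencies are explicit (e.g. `(1, 1, 1, 0)` for constructions with a
known answer) or drawn uniformly from 0.3–1.0, reflecting that single
siRNAs are less potent than pools. Annotation stores plant a term at a
stated fold-enrichment in a target set over a uniform background
(annotation probability 0.05 per term), Bernoulli background PPI edges,
and fully connected cliques. All generators are pure functions of
(spec, seed); gene ids start at 9 000 001, outside the real Entrez range,
so fixtures can never be mistaken for real data.

What the generator does *not* model: cell-death confounding (PLK1 wells
are just another control band), non-Gaussian readout noise, spatially
smooth (non-separable) artifacts, image-derived multi-feature readouts,
and siRNA off-target structure beyond potency. Passing tests therefore
demonstrate correctness of the computations and recoverability under
additive Gaussian conditions, not robustness to every pathology of real
screens.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to be
informative yet quick: 100 random 16 × 24 plates for the polish oracle,
50 plates for surface-invariance measurement, 20 replicate screens
(2 × 384-well plates each) for hit recovery, 20 artifact-laden plates for
the B-vs-Z benchmark, a 1000-gene × 4-reagent deconvolution set, and the
exhaustive Fisher grid x ≤ 20, G_c ≤ 200 at N = 22 000 (~41 000 tables).
Thresholds used in tests (2 SD for hit calling, 0.30 for deconvolution,
p ≤ 0.01 for enrichment) are the workflow's standard values, fixed before
the data are drawn. Degenerate inputs (zero-variance plates, equal
control means, zero MAD, division by zero, non-positive logs) uniformly
become missing values with a warning, or raise a typed error when no
meaningful output exists.
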