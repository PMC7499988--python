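# Methods

## Scope and data model

`proma` analyses single-channel functional protein microarray experiments:
one GPR (GenePix Results, ATF dialect) file per sample, all exported from
the same platform with identical column headers. A spot is identified by
its 1-based (block, column, row) geometry and carries a protein name and
ID plus per-channel intensity statistics. The parser accepts LF or CRLF
endings and optional double-quoting of text fields (with `""` escaping),
because real GenePix exports vary; empty intensity cells become missing
values, never zero, since zero is a legal intensity. Files are checked for
identical column headers and identical spot layouts before assembly; the
layout comparison is order-insensitive because assembly aligns spots by
their (block, column, row, ID) key. The "same file extension" convention
is enforced at the CLI, not in the parser, which accepts any text stream.

Foreground/background channels are chosen explicitly, by platform lookup
(ProtoArray and HuProt both map to `F635 Median`/`B635 Median`), or by a
generic pattern: the first `F<wavelength> Median`-style column paired with
its `B<wavelength>`-style counterpart. If nothing matches, the error lists
the candidate columns so the caller can choose.

## Preprocessing

The order is fixed: background subtraction on the linear count scale, then
technical-replicate averaging (still linear), then log2. Averaging before
the log keeps the replicate mean an unbiased estimate of the spot's
expected count. Matrices carry an explicit stage tag
(`raw → background_corrected → averaged → logged → normalized`) and every
operation refuses out-of-order input.

Background-corrected values below a floor (default 0.5 counts, the common
half-count convention) are clipped to the floor rather than dropped; this
keeps the matrix rectangular and the log2 transform defined. Negative
differences are common on empty spots, so the number of floored cells is
recorded and surfaced as a warning. The floor is configurable.

Replicates are keyed by protein ID, falling back to the name when the ID
is empty, within one sample; missing values are excluded from the mean and
an all-missing group stays missing. Positive-control spots are exempt from
*cross-block* collapsing: the block covariate is exactly what the
normalization model needs, so a control is averaged only within its block
and keeps one row per block. Ordinary proteins collapsed across blocks
record all source blocks; at normalization time such rows receive the mean
of their source blocks' fitted offsets.

## Control-based normalization

Positive controls are detected by case-insensitive regex patterns over
protein names and IDs (anti-human-IgG gradients, biotin and Alexa markers,
"control"-labelled spots — the ProtoArray/HuProt conventions); the pattern
table is an argument, so other platforms' conventions can be added without
code changes. The detected panel can be edited (set semantics, removals
win over additions) or extended from a two-column CSV at the CLI.

The model for a control spot's log2 signal is additive in control type,
array (sample) and block:

    y = μ + γ_type + α_array + β_block + ε

with treatment coding — the first array and block are the reference, so
α₁ = β₁ = 0 exactly, and "non-zero array/block coefficients" are exactly
the estimated technical biases. Main effects only; no array×block
interaction is modelled, which keeps the design estimable with the usual
one-spot-per-(control, block) layouts. The fit is Huber M-estimation via
iteratively reweighted least squares: start at the OLS solution,
re-estimate the residual scale each iteration as MAD/0.6745 (MAD about
zero), weight by min(1, c·scale/|r|) with c = 1.345 (95% Gaussian
efficiency), and stop when the largest coefficient change falls below 1e-8
or after 50 iterations (non-convergence returns the fit with a warning,
`converged=False`). A zero scale (perfect fit) short-circuits as
converged. Rank-deficient designs abort naming the collinear columns
(identified by pivoted QR); an array with no control observations aborts
with an actionable error rather than silently receiving a zero offset,
because its bias would be unidentifiable.

Normalization subtracts α̂_a + β̂_b from every value; γ̂ and μ̂ describe the
controls themselves and are left in place. Because of the reference-level
coding, normalized values retain the constant α*₁ + β*₁ of the true
biases — a global shift that cancels in any between-sample contrast.
Levels unseen by the fit (possible only when normalizing a matrix the fit
was not built from) get offset 0 with a warning.

## Differential reactivity

The sample metadata is a two-column (filename, group) table; filenames are
matched to samples by stem, extension-insensitively, and a header row is
tolerated. A design needs ≥ 2 groups and strictly more samples than
groups — the minimal two-group design has three samples. The primary
interface is a two-group contrast (test minus reference, reference
defaulting to the second group seen and overridable); with more groups,
each non-reference group can be contrasted against the reference, each
contrast forming its own BH family.

Per protein, a group-means model is fitted by least squares on complete
cases only (no imputation): effect b_g = mean(test) − mean(reference),
residual variance s²_g pooled over all groups on d_g = n_complete − k
degrees of freedom, and SE multiplier u_g = √(1/n_test + 1/n_ref).
Proteins with d_g = 0 or an entirely missing group are excluded from
moderation and reported separately.

The empirical-Bayes prior assumes s²_g ~ s₀²·F(d_g, d₀) and is estimated
by moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess
spread var(e)·(G−1)/G − mean ψ′(d_g/2) equals ψ′(d₀/2), inverted by a
Newton iteration on the trigamma function; non-positive excess spread
means d₀ = ∞ (complete pooling, normal reference distribution). Then
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Zero sample variances (possible
after flooring) cannot enter the log-moment method; they are pooled as if
their variance were 10⁻³ × the smallest positive variance and flagged.
Fewer than two usable proteins disables moderation (d₀ = 0, posterior =
sample variance) with a warning — in that limit the statistic is exactly
the classical pooled two-sample t.

Moderated t̃_g = b_g/(s̃_g·u_g) with s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),
two-sided p on d₀ + d_g df. BH adjustment is the step-up
q_(i) = min_{j≥i} min(1, p_(j)·m/j) over all tested proteins in one run
(no pre-filtering of the family). The result table keeps every tested
protein, sorted by adjusted p (ties: raw p, then ID), with adjusted
p < 0.05 flagged significant by default.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets. Default
conditions: 5 vs 5 samples, 2000 proteins in technical duplicate spread
across 12 blocks, 12 control proteins of 3 types printed once per block,
20 differential proteins at Δ = 2.0 log2, spot noise σ = 0.4 log2.
Values chosen once as typical for this assay class and not tuned:
baseline 10 log2 counts with protein-level spread 1.5; control-type means
13.0 / 11.5 / 12.5 log2 (IgG / biotin / Alexa); array offsets drawn
N(0, 0.5) and block offsets N(0, 0.25) per experiment unless given
explicitly; background ~ N(150, 30) counts truncated at zero. Biases are
additive on the log2 scale (multiplicative on counts), matching the
linear-model-on-logs normalization target, and foreground is written as
signal + background so background subtraction is exactly identifiable.
All randomness flows from a single integer seed through one generator, so
the same config reproduces byte-identical GPR text.

What the generator does *not* emulate — spatial gradients within blocks,
scanner saturation, non-additive background, batch-correlated controls,
heavy-tailed spot noise beyond the optional gross-outlier mixture — bounds
what passing tests show: they demonstrate correctness of the algorithms
under the stated model, not robustness to every artefact of real slides.

## Numerical and design choices

- Log base 2 throughout; effect sizes are log2 fold changes.
- GPR text is written with 10 significant digits; the round-trip contract
  is 1e-6 relative on intensities, text fields exact.
- The BH implementation uses a stable sort; ties produce equal adjusted
  values identical to the literal step-up definition.
- Problem sizes in the test-suite and acceptance script (e.g. a
  50-protein shared fixture, the 2000-protein default run, 1000 random
  p-vectors, 100 round-trip files) were chosen to exercise every code
  path at comfortably interactive runtimes.
- The CLI writes every intermediate matrix so each analysis step's output
  can be inspected or fed to other tools; a `normalize` subcommand stops
  after normalization. Stages that would need to reload a matrix CSV
  (which no longer carries block geometry) are not offered as standalone
  re-entry points; re-running from the GPR files is cheap and exact.
- `--skip-normalization` runs the identical testing path on the logged
  matrix, for platforms without usable controls.

## Limitations

Single-channel intensities only (no two-colour ratios, no GAL files, no
image processing); additive main-effects bias model (no array×block
interaction, no within-array spatial smoothing); plain moderated t (no
trend or robust eBayes variants); no in-process enrichment analysis — the
ranked significant-ID list is written for hand-off to external tools.
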