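# Methods

This note documents the models and algorithmic choices in `tidmap`:
what each statistic is, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Coordinates and conventions

All coordinates are 0-based, half-open; bin `i` covers
`[i·bin_size, (i+1)·bin_size)`. Bacterial chromosomes are circular, so
genomic separation is `s(i,j) = min(|i−j|, N−|i−j|)` and window
extraction, envelope interpolation and extension wrap around the
origin by default; every operation takes a `circular` flag for linear
fixtures. A bundle that spans the origin keeps `end_bin` (and
`peak_bin`) beyond `N` so the interval stays half-open.

## Contact-map preprocessing

**ICE balancing.** Symmetric iterative correction: each round divides
`M[i,j]` by `sqrt(b_i·b_j)`, where `b_i` is bin `i`'s row sum relative
to the mean over unmasked bins, until the coefficient of variation of
unmasked row sums falls below `tol` (default 1e-6, `max_iter` 1000).
The scheme preserves the mean row sum, is idempotent up to a global
scale, and is the same operator as the doubly stochastic normalization
used by the contact models (target sum 1 instead of the mean).
All-zero unmasked rows are added to the mask with a warning.

**White lines.** A bin is masked when its coverage (row sum of the raw
map) is below `median − 3·MAD`, `MAD = median(|x − median|)`. When the
MAD is zero the threshold degenerates to "below the median"; the strict
inequality is kept (constant coverage yields an empty mask) and a
warning is emitted.

**Distance decay.** `p(s)` is the mean balanced contact over unmasked
pairs at each circular separation; separations with no valid pair are
filled by linear interpolation. Downsampling draws a multivariate
hypergeometric sample over upper-triangle counts (exact total,
contacts without replacement). Rebinning block-sums; a coarse bin is
masked when more than half of its fine bins are masked.

**Row-correlation matrix.** Pearson correlation between rows of the
balanced map over unmasked columns, without per-distance detrending
(the convention of the directionality-index literature this follows);
a `log` option transforms rows by `log1p` first. Constant rows get
correlation 0 with a warning.

## Bundle (TID) calling

The bundle motif — dense short-range contacts along the diagonal — is
matched with an `n×n` Gaussian template (default n = 5),

    M[i,j] = (1/√2) · exp(−½ · [(|i−j| + |n−1−i−j|) / (2(n−1))]²),

whose maximum 1/√2 runs along the anti-diagonal (the local image's main
diagonal). The per-bin score is the elementwise product of the kernel
with the local image centred on `(i,i)`, summed; masked bins contribute
zero, and the score at a masked centre is undefined.

**Second-envelope removal.** To flatten regional trends, `E1` is the
piecewise-linear interpolation through the local minima of the score
(non-strict minima; wrap-around on circular tracks; endpoints anchor
linear tracks) and `E2` is the same operator applied to `E1`; the
corrected score is `score − E2`. Undefined positions are interpolated
before envelope construction and restored afterwards.

**Peak calling and extension.** Peaks are strict local maxima of the
corrected score (leftmost bin of a plateau) above a median threshold;
each peak is extended in both directions while the corrected score
stays at or above one third of the peak value; overlapping extensions
merge (the merged peak is the higher one); domains shorter than
`min_size_bins` (default 2) are dropped. Extension never crosses a
masked run longer than 2 bins.

**Threshold choice.** Whether the median threshold refers to the score
before or after envelope subtraction is genuinely ambiguous. The
median of the *corrected* track sits at the centre of its noise
distribution whenever bundles cover less than half the genome, and
background local maxima lie in the upper tail of that distribution by
construction — so that reading calls a false bundle at essentially
every background noise peak regardless of sequencing depth. The
default therefore compares corrected peaks against the median of the
*raw* score, which measures the typical diagonal signal level: a peak
qualifies only when its height above the regional background exceeds
the typical total diagonal signal, which rejects background
fluctuations (a few percent of that level) while keeping ≥2-fold
bundles. `call_bundles(raw_score=None)` gives the other reading.

## Boundary calling

**Directionality index.** For bin `i`, the vectors `L_k = corr(i, i−k)`
and `R_k = corr(i, i+k)`, `k = 1..w`, are compared by a paired t-test:
`t = mean(d)/(sd(d)/√w)` with `d = R − L` and the sample (n−1) sd.
Positive `t` means downstream bias. Pairs with a masked member are
dropped; fewer than 2 usable pairs, or differences at floating-point
noise level, give `t = 0`/undefined. Boundaries are the first bin of a
run with `t ≥ +2` following a run with `t ≤ −2` (P ≈ 0.05), allowing at
most `max_gap_bins` (default 2) non-significant bins between the runs;
the opposite transition is a domain interior, not a boundary. The DI is
resolution-sensitive; the conventional operating point here is the
5-kb map with a 100-kb window.

**Relative insulation.** For window `w`: `A` and `B` are the
within-block contact sums (unordered pairs, diagonal excluded) of
`[i−w, i)` and `[i, i+w)` and `C` the between-block rectangle sum;
`RI = (A+B−C)/(A+B+C)` is bounded in [−1, 1], scale-free and maximal at
contact-depleted junctions (RI = 1 when `C = 0`). RI is averaged over
the window set (default 10, 15, 20, 25, 30 kb on the 1-kb map), the
second envelope is removed with the same operator as above, and
boundaries are strict local maxima at least `mean + z·sd` of the
corrected track (z = 1 by default — a package default, not a claim
about any particular dataset).

## Pileups

The top `ceil(fraction·n)` genes by RPKM are active (ties broken by
genomic order); a "TU start" is an active gene with no other active
gene overlapping its strand-aware 3-kb upstream interval. Windows of
`width_bp` (default 50 kb; 100 kb also used in the literature for the
same analysis) are centred on start codons; reverse-strand windows are
rotated 180° so genes always point rightwards (the rotation preserves
matrix symmetry). The pileup is the per-cell mean over windows,
ignoring masked cells. The control divides by the pileup of one
random anchor per gene, drawn uniformly within ±100 kb — matched
regional background, same strand. The transcription comparison
correlates the pileup's adjacent-bin diagonal profile (`P[k,k+1]`)
with the averaged, strand-oriented expression track resampled to the
same inter-bin positions.

## Polymerase-occupancy contact models

`C_i` is the ChIP occupancy profile rescaled so `max C = ε ∈ (0, 1]`
(the single free parameter). Contacts at bin `i` split into a
polymerase-mediated fraction `C_i` and a remainder `1 − C_i`:

* variant 1: `w(i,j) = C_iC_j + (1−C_i)(1−C_j)` — all polymerase pairs
  interact;
* variant 2: `w(i,j) = m·C_iC_j + (1−C_i)(1−C_j)` with
  `m = Σ_{n strictly between i,j} C_n` (zero for adjacent pairs; the
  sum runs along the arc realizing the genomic separation). The factor
  is implemented exactly as this formula states, in which intervening
  occupancy *scales* the polymerase term; a reading in which
  intervening polymerases insulate instead would replace `m` by a
  decreasing function such as `1/(1+m)` — the formula form is the
  default and the package's model semantics.

The expected map is `p(s_ij)·w(i,j)`, made doubly stochastic by
symmetric Sinkhorn scaling (divide by `sqrt(r_i·r_j)` per iteration,
tolerance 1e-8) so entries are contact probabilities.

**Fitting ε.** Default grid 0.01–1.00 in steps of 0.01; support =
unmasked upper-triangle pairs with separation ≤ 200 kb (the occupancy
signature is local; full-matrix option available); diagonal excluded.
Two objectives:

* `likelihood` (default): the un-normalized expected map is scaled to
  the observed raw total and scored by Poisson log-likelihood. This is
  scale-aware: the occupancy signature enters the weights at first
  order through the `(1−C)` depletion and at higher order through the
  polymerase terms, so the likelihood resolves ε finely (±0.01–0.02 at
  2M contacts per Mb in the synthetic benchmark).
* `spearman`: rank correlation between the balanced observed map and
  the doubly stochastic model map, the classical scoring. Balancing
  removes the rank-one `(1−C_i)(1−C_j)` factor exactly, the residual
  polymerase term scales roughly as ε³ with nearly fixed shape, and
  rank correlations are invariant to that amplitude — so this
  objective orders *models* well but identifies ε only coarsely. It is
  retained for compatibility and always reported for model comparison.

**Model selection** compares the maximized log-likelihoods (same data,
same support, one free parameter each); each fit also reports the
Spearman rho of its best model against the balanced map.

## Synthetic data

The generator is the package's study-condition definition, not a
tuning knob. Defaults: 1-Mb circular genome at 1-kb bins;
transcription units drawn log-uniform over 1–20 kb (operon lengths
skew short), placed without overlap with random gaps and strands;
log-normal expression (μ = ln 50, σ = 1.5); the top 10% are active.
Distance decay `p(s) ∝ (s + 1)^−0.8` — a shallow short-range decay in
the range observed for bacterial nucleoids; with steeper decay the
near-diagonal fraction of each row is so large that ICE balancing
dilutes any fixed raw short-range enrichment below ~2.5×, which is why
0.8 (rather than 1.0) is the default. Contact expectations follow the
variant-2 occupancy weights times a plaid term
`1 + κ·a_i·a_j·[s ≤ 25 kb]` (`a` = active-bin indicator, κ = 8), so
that the *balanced* adjacent-bin enrichment inside active TUs — the
quantity the caller sees — is ≈3×. Counts are Poisson at 2×10⁶
contacts per Mb; a few random bins are zeroed and masked as white
lines. `rifampicin=True` zeroes all native expression; an optional
T7-like unit (115-kb track, occupancy decaying exponentially with a
40-kb length from the promoter, peak = ε_true) survives it. Optional
block domains (uniform within-domain boost) provide planted truth for
the boundary callers.

What the generator does **not** emulate: restriction-fragment
structure and ligation artifacts, copy-number gradients from
replication, loop extrusion, condensin/MatP-type long-range features,
inter-replichore symmetry, and real operon architecture. Passing
recovery tests on this generator therefore demonstrates correctness of
the statistics under the stated generative model, not performance on
any real dataset.

## Numerical choices and degenerate inputs

Symmetry is validated at 1e-9 relative tolerance on input. Sinkhorn
and ICE warn and return partial results on non-convergence. Paired-t
differences below 1e-12 give t = 0 (floating-point mirror symmetry).
Spearman/Pearson on constant inputs return NaN or raise, as
documented per function. Plateau peaks take the leftmost bin.
Greedy border matching pairs nearest borders first, each at most once.
The Gaussian blur kernel is truncated at 4σ and renormalized; σ is
expressed in bp and converted by the track's bin size.

## Known limitations

* The bundle caller's sensitivity limit is ~2× balanced enrichment
  sustained over ≥3 bins; 1–2-bin domains at threshold enrichment are
  found only when flanked by other active regions.
* ε recovery by rank correlation alone is ill-posed after balancing
  (see above); the likelihood objective assumes Poisson counts, which
  real Hi-C only approximates after duplicate filtering.
* Model selection between the two occupancy variants requires the
  third-order `m`-term to rise above counting noise; at ε ≤ 0.15 and
  ~2×10⁶ contacts per Mb with a decaying occupancy track the variants
  are near-indistinguishable, and the selection direction should be
  read only from deeper data or larger ε.
* The DI caller reports one border per negative run; closely spaced
  boundaries within `max_gap_bins` merge.
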