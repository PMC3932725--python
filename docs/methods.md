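# Methods

This note records the models, conventions and numerical choices behind
`metricmine`, in the order the pipeline uses them.

## Images, binning, entropies

Images are dense 2-D/3-D scalar voxel grids; metrics treat them as flat
intensity vectors (no affine-space reasoning — candidates are assumed
voxelwise comparable on one grid). Histograms are equal-width with half-open
bins, last bin closed; default B = 64 bins for marginals and (64, 64) for
joints. When two images are compared, their joint histogram is binned over
the **union** of the two intensity ranges, so identical images always bin
identically and land on the joint's diagonal. (Near-)degenerate ranges are
widened symmetrically so constant data occupies a single bin instead of
dividing by zero. Entropies are in bits; the log base cancels in every
ratio-form metric. All variances are population (1/N) moments, matching the
1/N normalizations in the metric definitions; conditional variances are
computed two-pass (residuals about the group mean), which is exact for
constant groups — a one-pass formula leaves ~1e-16 residues that explode in
the Woods σ/μ ratio.

An optional background mask (exclude reference voxels equal to a given
value) is exposed on every metric and on the battery, but is **off by
default**: voxel-level measures can be dominated by background, and leaving
masking explicit keeps the default battery assumption-free.

## Conditioning for the correlation ratio and Woods criterion

`cor` and `woo` condition S on the intensity *level* of R. By default the
levels are the exact distinct intensity values of R — N(i) is literally the
number of voxels of R with value i — rather than 64-bin groups. This is the
definition the formulas state, and it is the only convention under which a
candidate identical to the reference scores exactly 1 (any coarser binning
leaves positive within-bin variance). It presupposes a reference whose
values repeat, which is true of integer-valued scanner output and of the
quantized phantoms below; for a continuous-valued reference, pass
`cond_bins` to condition on equal-width bins instead. Conditioning is always
on the reference R; both metrics are asymmetric by construction. Woods
levels with |μ(i)| ≤ ε (default ε = 1e-8) are skipped — a coefficient of
variation is meaningless around zero mean — and the skipped count is
reported rather than silently absorbed.

## Score normalization

Raw metrics live on incommensurable scales, so each gets a score in [0, 1]
with 1 optimal. The mappings are this package's convention (the requirement
is the [0, 1]/1-optimal contract, not any particular mapping):

- `msd`, `adi`: 1 − raw/D² and 1 − raw/D, with D the shared dynamic range —
  the worst possible voxelwise disagreement maps to 0.
- `edi`: Shannon entropy of the binned difference image, scored
  1 − H/log2(B). A constant difference (perfect reproduction up to offset)
  scores 1; a structureless uniform difference scores 0. The difference
  metric named "entropy of differences" is implemented as an actual Shannon
  entropy (with the minus sign); a voxel-indexed Σ p·log p without the sign
  is not an entropy and is treated as a typographical slip in its source.
- MI family from one joint histogram: `mif` scored I/min(H_R, H_S) (the
  uncertainty-coefficient form, so identity gives 1), `nmi` → raw − 1,
  `red` → 2·raw, `uni` and `aum` → 1 − raw.
- `ncc`: affine map (raw + 1)/2 from [−1, 1].
- `cor`, `woo`: the raw value, clamped.

Out-of-range raws (Woods routinely exceeds [0, 1] on background-dominated
images) are clamped with a logged warning. Degenerate inputs raise typed
errors at the function level (`ncc`/`cor` on constant images, `woo` with all
levels skipped) and become flagged missing cells — never fabricated values —
inside a battery. Two constant images under the MI family score 1 if
voxelwise identical, else 0, flagged degenerate; with exactly one constant
image the mutual information is 0 and all five scores are 0 (no dependence
is measurable through a zero-entropy marginal).

## Rank replacement and robust PCA

Mining replaces each score column by within-column ascending ranks (average
on ties; `drop_row` is the default policy for rows with missing cells, with
`column_mean_rank` imputation available). The Spearman matrix is the Pearson
correlation of the rank columns; the PCA eigendecomposes that correlation
matrix (not the rank covariance — with ties the two differ slightly, and the
correlation is the named object; for tie-free tables they coincide up to the
known factor (n² − 1)/12, which the tests verify). Candidate scores are
centered rank rows projected on unit-norm eigenvectors. Determinism: ties in
sorting break by row-mean rank then run id; eigenvector signs are fixed by
making the largest-magnitude loading positive, then PC1 is re-oriented to
correlate positively with the row-mean rank (the across-metric consensus) so
"larger PC1 = better" regardless of the solver's sign choice. Rank 1 is the
best candidate.

A score column that is constant across candidates carries no ranking
information and has an undefined Spearman correlation; the high-level
`RankPCARanker` excludes such columns (recorded in `dropped_metrics_`, with
a warning) while the low-level functions stay strict and raise.

Metric clustering is average-linkage agglomerative clustering at distance
1 − ρ; the consistency report gives the minimum pairwise correlation within
the consensus subset (all metrics except `edi` and `woo`, the two known
discordant ones) and flags any metric whose mean correlation with that
subset falls below a threshold (default 0, i.e. anticorrelation).

## The store

Runs and metric values go into an embedded single-file sqlite database with
a plain-SQL schema (`runs`, `metric_values` keyed by (run_id, metric_name)).
One battery is committed atomically per run: a failure mid-write rolls back
to zero rows for that run. Timestamps are UTC ISO-8601; parameter
assignments are stored as key-sorted JSON for deterministic diffs. A
client-server SQL backend is a drop-in replacement for the engine.

## Synthetic candidate sets

The generator stands in for external registration outputs and defines the
conditions under which the end-to-end claims are tested.

- **Phantom**: a sum of `n_blobs` = 6 anisotropic Gaussian blobs on a dark
  background, normalized to [0, 1] and quantized to 256 equally spaced
  levels — mimicking integer-valued scanner output, and giving the
  value-conditioned metrics real level populations. Default shape
  (16, 16, 8) = 2048 voxels: large enough for 64-bin joint histograms to be
  populated, small enough that a 186-candidate battery runs in seconds.
- **Perturbation**: severity s ∈ [0, ∞) scales all of: a rigid transform
  (translation up to 3 voxels along a seeded random direction and rotation
  up to 10° in the first-axes plane at s = 1; linear interpolation,
  background padding), a multiplicative sinusoidal low-frequency bias field
  (amplitude 0.2·s), and additive Gaussian noise (σ = 0.05·s in intensity
  units, i.e. 5% of the dynamic range at s = 1). These magnitudes were
  chosen once as a realistic span from sub-voxel misregistration to gross
  failure; s = 0 skips the transform entirely and returns a voxelwise copy.
- **Candidate sets** cycle a severity grid (default: evenly spaced on
  [0, 1], including 0) with per-candidate seeds derived from one master
  seed, and write NIfTI or text grids plus a JSON manifest holding every
  spec and ground-truth severity.

What the generator does *not* emulate: anatomy, modality differences
(metrics like MI exist for multi-modal pairs; the phantom is mono-modal),
spatially correlated noise, or the specific error modes of real registration
algorithms. Passing the end-to-end tests therefore shows the meta-algorithm
recovers a planted monotone quality ordering under mixed geometric/
intensity/noise degradation — not that any particular registration tool is
well ranked on clinical data.

## Problem sizes and checks

The test suite cross-checks every metric against literal loop-over-voxels/
levels implementations on an exhaustive sweep of all 4-voxel, 3-level image
pairs (6561 ordered pairs) plus seeded 8-voxel, 4-level pairs, at 1e-9; the
Spearman matrix against its definition for n ≤ 6, p ≤ 3; and the full
pipeline on 10 independent 50-candidate sets, where the oriented-PC1
ranking attains mean Spearman ≥ 0.9 with the planted order and the
unperturbed candidate is ranked first in every replicate. Monotonicity of
the consensus-metric mean score in severity is asserted on the seed-averaged
curve (20 levels × 10 seeds) via its rank correlation with severity, the
appropriate finite-sample reading of a claim about expectations.

## Known limitations

- The Woods criterion without masking is effectively a background-noise
  detector on dark-background images; its score saturates at the clamp
  boundaries. This is faithful to its definition and is why it sits outside
  the consensus subset.
- Exact-value conditioning makes `cor`/`woo` trivially 1 on references with
  no repeated intensities; use `cond_bins` there.
- Score normalizations for the distance metrics depend on the pair's shared
  dynamic range, so scores (not raws, not ranks — and the mining uses ranks)
  are not comparable across references with different ranges.
- The store serializes concurrent writers at the database level; it is a
  logging sink, not a high-throughput queue.
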