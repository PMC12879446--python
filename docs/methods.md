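# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `woifc`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Optical model and spectroscopy inversion

Wide-field optical intrinsic signal imaging measures diffuse reflectance of
the brain surface under sequentially fired LEDs. Absorption is dominated by
oxy- and deoxyhemoglobin, whose extinction spectra differ across
wavelengths, so reflectance fluctuations encode hemodynamic concentration
changes. We use the modified Beer–Lambert law in its differential form:

    ΔA(λ, t, p) = −ln( I(λ, t, p) / ⟨I(λ, ·, p)⟩_t )
                = Σ_i ε_i(λ) · L(λ) · Δc_i(t, p)

with chromophores i ∈ {HbO₂, HbR}. Assumptions: fluctuations are small
enough for the linearized law; scattering changes are negligible; the
photon path is summarized by one wavelength-dependent differential
pathlength factor L(λ). Because the reference intensity is the *temporal
mean*, Δc is determined only up to a per-pixel constant; all downstream
analysis uses band-passed (hence mean-free) contrasts, and the generator's
forward/inverse consistency check compares temporally demeaned fields.

Shipped constants (replaceable via `SpectroscopyModel`):

| λ (nm) | ε_HbO₂ (µM·cm)⁻¹ | ε_HbR (µM·cm)⁻¹ | L (cm) |
|--------|------------------|-----------------|--------|
| 530    | 0.039036         | 0.039036        | 0.5    |
| 590    | 0.013640         | 0.037020        | 0.7    |
| 625    | 0.001506         | 0.005888        | 1.3    |

The values follow the scale and qualitative structure of standard
tabulated hemoglobin spectra (530 nm near an isosbestic point, 590 nm
deoxy-dominant, 625 nm weakly absorbing with the longest path). For the
pipeline's correctness properties only the full column rank of ε·L matters,
since generator and inversion share the model; for quantitative work on
real data users should substitute the calibrated constants of their rig.
With three wavelengths and two chromophores the inversion is the Moore–
Penrose pseudoinverse solution; systems with condition number above 1e8 are
rejected.

## 2. Preprocessing chain

Fixed order, recorded in the `HemoStack.provenance`:

1. **Downsample** — spatial block mean (integer factors only; the study
   configuration is 1200×1600 → 75×100) and temporal k-wise frame
   averaging (16 → 8 frames/s). Block means preserve photon statistics;
   no interpolation is performed.
2. **Mask** — user-supplied brain mask with left/right hemisphere labels
   (encoding 0/1/2, vein = 3). Conventions: row-major, origin top-left,
   rows anterior→posterior, left hemisphere at lower column indices.
3. **Detrend** — second-order temporal and spatial detrending. Per pixel,
   a quadratic-in-time least-squares fit of the deviation about the
   temporal mean is removed. The spatial component removes a quadratic 2-D
   surface (1, x, y, x², xy, y²) over in-mask pixels whose per-frame
   coefficients are constrained to a quadratic temporal trend
   (`spatial_mode="drift"`, the default): this targets spatially smooth
   *drift* such as illumination and vignetting fluctuations. A literal
   per-frame surface fit (`spatial_mode="per_frame"`) is available but not
   default, because fitting every frame independently removes the quadratic
   spatial moments of the functional signal itself; on generator data this
   measurably distorts large-scale correlation structure — the same
   mechanism by which global-signal removal induces anticorrelation. The
   temporal mean is re-added so the log-mean step remains well defined.
   Order (temporal before spatial) is a documented convention; in drift
   mode the removed subspace is contained in the per-pixel temporal
   quadratic span, so the order is immaterial to the result.
4. **Log-mean transform** — ln(I/⟨I⟩_t); requires strictly positive
   values and errors otherwise, naming the offending pixel count.
5. **Spectroscopy** — pathlength adjustment and inversion (Section 1),
   giving HbO₂ and HbR contrast matrices. Downstream analysis uses HbO₂.
6. **Smoothing** — per-frame 5×5 Gaussian, σ = 1.3 px, with the kernel
   renormalized over in-mask support (masked-normalized convolution), so
   out-of-mask values never bleed inward and a constant in-mask image is
   exactly preserved.
7. **Hemispheric signal regression** — each hemisphere's in-mask mean
   trace g is regressed (with intercept, so residuals are mean-free) out of
   that hemisphere's pixels. Residuals are exactly orthogonal to g. Note
   this shifts non-homotopic correlations negative and perturbs homotopic
   values by a computable amount that depends on the latent structure and
   region weights; see Section 5.
8. **Bandpass** — zero-phase (forward–backward `sosfiltfilt`) Butterworth
   bandpass, order 5, 0.02–0.167 Hz at 8 frames/s. Zero-phase filtering
   avoids lag distortion of correlations; the forward–backward pass squares
   the magnitude response (≥ 95% attenuation at 0.5 Hz, unity ± a few
   permil in mid-band). Series shorter than the filter's padding length
   are rejected with the minimum length in the message.
9. **Censoring** — frames whose spatial mean of squared HbO₂ contrast
   exceeds the threshold (default 1, in squared concentration units) are
   dropped and their original indices recorded. A mean (not a sum) is used
   so the statistic is comparable across masks of different sizes.
   Censoring is idempotent.

Runs from one individual are concatenated along time after censoring, with
per-run boundaries recorded and censored indices re-offset.

## 3. Parcellation and clustering

**Seeding.** The Pearson matrix over analysis pixels (brain minus vein) is
decomposed; because the matrix is symmetric, singular vectors coincide with
eigenvectors ordered by |eigenvalue|. Each of the leading m = ⌈n_parcels/2⌉
vectors v_j (singular value s_j) spawns a positive and a negative candidate
parcel; pixel p joins the candidate maximizing s_j·max(±v_j(p), 0). Empty
candidates are dropped. Requesting the default 30 parcels therefore uses 15
vectors. Argmax ties go to the lowest candidate index.

**Iteration.** Repeat {parcel mean traces → pixel-parcel correlations →
reassign each pixel to its maximum-correlation parcel} until no assignment
changes. Ties keep the current parcel when it attains the maximum,
otherwise the lowest parcel id — this promotes convergence. Emptied
parcels are dropped (ids relabeled contiguously, order-preserving) between
iterations. The iteration has no convergence guarantee: assignment-state
hashes detect oscillation, and hitting `max_iter` (default 100) reports
`converged=False` rather than failing. A converged map satisfies the exact
per-pixel argmax audit (`IterativeParcellation.audit_fixed_point`).

**Vein handling.** The midline venous sinus carries a strong signal of its
own, so vein pixels form their own parcels. After a first pass, parcels
whose pixel centroid column lies in the configured midline band *and* at
least half of whose pixels lie in that band are flagged; their pixels are
masked and the parcellation runs a second time. The band-fraction guard is
needed because strong homotopic correlation can produce legitimate parcels
whose pixels span both hemispheres — their centroids also sit near the
midline, but their mass does not. A manual parcel-id override is available
(the original analysis did this step by hand).

**Clustering.** Parcel mean traces are clustered agglomeratively (average
linkage on correlation distance 1 − r; other linkages are exposed). The
dendrogram is cut at the *minimal depth*: the largest merge height whose
induced partition has at least `min_clusters` (default 8) clusters, with
the convention that merges strictly below the cut height are applied.
Raising `min_clusters` therefore only refines the partition (dendrogram
cuts are nested).

**Hemisphere division.** Each parcel is assigned the hemisphere holding
the majority of its pixels (exact ties to left, with a warning), and every
cluster splits into hemisphere-specific groups. Ordering is geometry-
derived and deterministic: left hemisphere first, groups by mean anterior–
posterior centroid, parcels by centroid within group — permuting input ids
cannot change it. For pixel-level scoring and maps,
`pixelwise_hemisphere_clusters` divides the *map* instead: each pixel gets
(its own hemisphere, its parcel's cluster). This is the right object when
single parcels straddle the midline.

Estimator shape: `IterativeParcellation` and `TraceHierarchy` follow
scikit-learn conventions (`fit` on (n_samples, n_features), trailing-
underscore attributes, `get_params`/`set_params`) and compose with sklearn
model-selection tooling; the module-level functions wrap them.

## 4. Statistics

**Matrix delta.** Mean of |a_ij − b_ij| over unique off-diagonal pairs.
Absolute differences are used because a signed mean would cancel;
similarity requires a magnitude.

**Shuffle null.** The unique off-diagonal entries are permuted and written
back symmetrically (diagonal untouched), preserving the value multiset so
the null speaks only to *structure*. A row/column label permutation is
available as an alternative (`unit="labels"`).

**Between-individual test.** Observed statistic: mean delta over all
unordered pairs of individuals. Null: for each pair, both matrices are
shuffled independently `n_shuffles` times (default 1000) and the deltas
pooled across pairs. Reported value: the ECDF quantile of the observed
statistic in the pooled null — the fraction of null deltas ≤ observed; it
is 0 only when the observed value lies below every null draw. Note that
with more than two individuals the observed statistic is a mean over pairs
while the null pools single-pair deltas, so the quantile is conservative
rather than exactly uniform; calibration checks therefore use two-individual
cohorts, where the permutation argument is exact.

**Split-half test.** The frame series (censoring already applied) is split
into halves, region matrices are computed per half, and the identical
machinery runs on that single pair.

**Normality screen.** One-sample Kolmogorov–Smirnov against a standard
normal after standardization (n ≥ 5); used only to justify reporting a
rank-based contrast — the pipeline always proceeds to the rank-sum test.

**Rank-sum test.** Two-sided Wilcoxon rank-sum with midranks. For
n₁+n₂ ≤ 10 the p-value is exact by full enumeration of all C(n, n₁) rank
assignments; otherwise a tie-corrected normal approximation with continuity
correction is used (z is antisymmetric under sample swap in both regimes;
identical pooled values give the degenerate p = 1).

## 5. Synthetic study conditions

The generator emulates the structure of the motivating recordings. Default
conditions (all configurable through `Scenario`):

| parameter | default | meaning |
|---|---|---|
| shape | 48×64 px | field of view (desk-scale; real config is 75×100) |
| regions | 5 per hemisphere | mirrored Lloyd-relaxed Voronoi tessellation |
| frames | 4800 @ 8 fps | two concatenated 5-min runs after downsampling |
| homotopic r | 0.6 | latent target for mirror pairs |
| neighbor r | 0.2 | consecutive regions within a hemisphere |
| HbO₂ amplitude | 0.5 µM | region latent amplitude |
| pixel noise | 0.8 µM | white, per pixel and frame |
| substructure | 0.3 µM | two zero-mean spatial gradients per region |
| structured noise | 0.15 µM | 20 smooth random fields × band-limited traces |
| hemispheric nuisance | 0.3 µM | one band-limited trace per hemisphere |
| vein | half-width 1 col, 1.0 µM | independent trace (latents projected out) |
| HbR coupling | −0.5 × HbO₂ + 0.1 µM noise | keeps spectroscopy well-posed |
| drift | ±0.5% | second-order in time, per wavelength |
| vignette | 0.85–1.0 | radial multiplicative field |
| quantization | 16 bit, baselines 24k/20k/26k counts | camera output |

Rationale for the non-obvious entries. *Latent traces* are band-limited
Gaussian noise, empirically whitened and colored with the symmetric square
root of the target matrix, so the empirical correlation equals the target
at any length (strictly stronger than asymptotic convergence; perfectly
correlated targets yield identical traces). *Within-region substructure*
(two orthogonal linear gradients per region, spatially zero-mean inside the
region, each with its own band-limited course) emulates the
sub-functionalization of anatomical regions; it is what sustains a stable
parcellation finer than the region map, and because it is spatially
zero-mean it leaves region-average traces untouched. *Structured noise*
(smooth random fields with band-limited time courses) stands in for
vascular/physiological noise that is spatially coherent. Noise amplitudes
were chosen once so that ground-truth recovery passes with a margin under
the default conditions, and the real data's signal-to-noise ratio is
unknown — these levels are assumptions, not measurements.

What recovery results do and do not show: hemisphere-divided clusters
recover the true regions (ARI ≥ 0.8 at the default conditions) and
homotopic correlations come back within 0.1 of the 0.6 target — but the
generator's regions are internally much more homogeneous than real tissue,
its noise is Gaussian, and its mirror symmetry is exact, so these numbers
bound the pipeline's *correctness*, not its field performance. Hemispheric
regression deterministically reshapes correlations (for the default latent
structure the ideal post-regression homotopic values are 0.61–0.69 and
non-homotopic pairs move to ≈ −0.1…−0.4); recovered values should be read
against that transformation, which is the same caveat that applies to
global-signal regression on real data.

## 6. Degenerate inputs and numerical conventions

- Zero-variance pixels/units are rejected with their indices (tolerance
  1e-12 relative, so float-constant traces are caught).
- Correlation matrices are validated (symmetric to 1e-8, unit diagonal,
  |r| ≤ 1), then symmetrized and clipped exactly.
- The spatial detrend falls back to a planar, then constant basis with a
  warning when the masked design is singular (e.g., single-column masks).
- A hemisphere whose mean trace has zero variance is mean-centered only,
  with a warning.
- All randomness is `numpy.random.Generator`-based and seed-derived;
  identical seeds give bit-identical synthetic stacks and identical
  shuffle nulls.

## 7. Known limitations

- Anatomical naming is a user-supplied label table (cluster → region
  name); no atlas registration is attempted.
- Motion correction and physiological (cardiac/respiratory) filtering are
  out of scope; censoring is the only spike defense.
- HbR is computed and stored but no HbR-based analysis is provided.
- The acceptance-scale scenario runs at 48×64 px for desk-scale runtimes;
  the algorithms are the same at 75×100, only slower (the pixel-pixel
  correlation matrix and its eigendecomposition dominate, scaling as the
  cube of the in-mask pixel count).
- The iterative parcellation is a fixed-point heuristic: the solution
  depends on the seeding, and non-convergence, while rare, is possible and
  is reported rather than repaired.
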