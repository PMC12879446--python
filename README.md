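# woifc — functional connectivity from wide-field optical imaging

`woifc` reconstructs resting-state functional connectivity maps from
wide-field optical intrinsic signal (OIS) recordings of the dorsal brain
surface — the kind of camera-based reflectance imaging used to map
hemodynamic networks in small animals such as mice and, more recently,
birds. It is written for researchers who have (or want to prototype
against) multi-wavelength LED reflectance stacks and need a tested,
scriptable alternative to ad-hoc analysis code: the package turns raw
interleaved frames into hemoglobin contrasts, partitions the field of view
into functional parcels and clusters, and quantifies the consistency and
bilateral symmetry of the resulting correlation structure.

Because raw recordings of this kind are rarely shareable, the package ships
a first-class synthetic-data generator with known ground truth (mirrored
region layouts, latent correlations, optics, artifacts), so the entire
pipeline is testable end to end without any download.

## The method

**Spectroscopy.** Reflectance changes at each LED wavelength λ are converted
to differential absorption ΔA(λ, t, p) = −ln(I/⟨I⟩_t) and inverted through
the modified Beer–Lambert law

    ΔA(λ, t, p) = Σ_i ε_i(λ) · L(λ) · Δc_i(t, p),    i ∈ {HbO₂, HbR}

where ε_i are molar extinction coefficients, L(λ) the differential
pathlength factor, and Δc the concentration contrasts; with three
wavelengths the inversion is the least-squares (pseudoinverse) solution.
The preprocessing chain is fixed and recorded in each run's provenance:
downsample → mask → second-order detrend → log-mean → spectroscopy →
masked 5×5 Gaussian smoothing (σ = 1.3 px) → per-hemisphere global-signal
regression → zero-phase 0.02–0.167 Hz Butterworth bandpass → frame
censoring (spatial mean of HbO₂² above 1 drops the frame).

**Parcellation.** Pixels are partitioned by functional time course: the
pixel–pixel Pearson matrix is decomposed by SVD; the leading
⌈n_parcels/2⌉ singular vectors each seed a positive and a negative
candidate parcel via their signed loadings; then pixels are iteratively
reassigned to their maximum-correlation parcel until a fixed point. Parcels
sitting on the midline vein (a large venous sinus obscures the signal
there) are masked and the parcellation is rerun. Parcel mean traces are
hierarchically clustered (average linkage on distance 1 − r) and the
dendrogram is cut at the shallowest level with at least 8 clusters;
clusters are finally divided by hemisphere.

**Statistics.** Similarity of connectivity structure between individuals
(or between split halves of one recording) is tested by randomization: the
observed statistic is the mean |Δr| over corresponding matrix entries, the
null permutes each matrix's off-diagonal entries (1000 shuffles per pair by
default), and the ECDF quantile of the observed value in the pooled null is
reported. Homotopic (mirror-region) versus non-homotopic correlations are
contrasted with a two-sided Wilcoxon rank-sum test (exact by enumeration
for n₁+n₂ ≤ 10, tie-corrected normal approximation otherwise), gated by a
Kolmogorov–Smirnov normality screen.

## Worked example

```python
import numpy as np
from woifc import Scenario, simulate, preprocess_stack, parcellate
from woifc.connectivity import (RegionTable, unit_traces,
                                correlation_matrix, extract_homotopic)
from woifc.stats import rank_sum_test

raw, mask, truth = simulate(Scenario(seed=1))   # 48x64 px, 4800 frames @ 8 fps
hemo = preprocess_stack(raw, mask)
parcels, clusters, vein = parcellate(hemo)

table = RegionTable.from_ground_truth(truth)
corr = correlation_matrix(unit_traces(hemo, table.membership), table.table)
homo, non = extract_homotopic(corr, table)
res = rank_sum_test(homo, non)
```

Output (printed by the snippet above with the shown statements):

```
frames kept: 4760 (censored 40)
parcels: 14 (converged in 13 iterations)
clusters at minimal-depth cut: 8; vein pixels masked: 178
homotopic r: [0.527 0.553 0.649 0.663 0.677]
median homotopic r = 0.649, median non-homotopic r = -0.186
rank-sum z = 3.59, p = 0.00033
```

Reading this: 40 of 4800 frames were censored as motion/physiology spikes;
the iterative parcellation converged to 14 parcels, grouped into 8 clusters
at the minimal-depth dendrogram cut; all 178 pixels of the midline vein
were discovered and masked. The five homotopic region pairs (latent target
r = 0.6) are recovered at r ≈ 0.53–0.68, clearly separated from the
non-homotopic median of −0.19 — the slight negative shift of non-homotopic
pairs is the expected signature of hemispheric (global) signal regression.

The same pipeline is available from the shell:

```bash
woifc simulate   --seed 1 --out sim/
woifc preprocess --stack sim/raw.tif --mask sim/mask.tif --out run.h5
woifc parcellate --run run.h5 --out parcels/
woifc connect    --run run.h5 --parcels parcels/ --out fc/
woifc stats      --fc-dir fc/ --out stats.json
```

## Further reading

`docs/methods.md` documents the model assumptions, every tunable parameter
with units and defaults, what the synthetic generator does and does not
emulate, and the numerical conventions (tie-breaking, cut definition,
filter design).
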