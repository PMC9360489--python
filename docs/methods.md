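# Methods

## Measurement model

Ischemic water uptake lowers CT attenuation roughly in proportion to
ischemia severity. The analysis band of 21–50 HU (inclusive at both
edges; "below 21" and "above 50" are discarded) restricts regional means
to plausible parenchyma, excluding CSF and chronic infarcts below the
band and calcification above it. For each ASPECTS region the relative
attenuation rHU is the ratio of the band-filtered mean on the (known)
ischemic side to the contralateral homologue; ratios cancel scanner
offsets, which is why absolute HU are never compared across subjects.
Regional means are taken over full 3-D region volumes (the alternative —
averaging on the two canonical 2-D ASPECTS slices — discards most of the
voxels and was not adopted). The contralateral homologue is found by
label pairing in the region table, not by geometric reflection, so an
edited or relabelled atlas still pairs correctly.

The score is the weighted sum Σ β_r·rHU_r with weights fitted by OLS of
core volume (ml) on the 10 rHU covariates plus an intercept. The
intercept is reported in the fit metadata but excluded from the score:
it shifts every subject equally and cannot change rank-based evaluation
(ROC, Spearman). Weights are fitted per modality and never mixed;
in-sample fitting is the default (matching how such weights are derived
on a single cohort), and `cross_fit=k` provides k-fold out-of-sample
scores for honest evaluation — the no-signal regression test uses it,
because with 10 covariates an in-sample fit on ~70 subjects produces
optimistic apparent discrimination even from pure noise.

Degenerate regions (no band-retained voxels on either side) yield
rHU = 1.0 with a flag rather than aborting the subject; an uninformative
neutral value keeps cohort pipelines running on extreme confounder
draws.

## Core definition

The ground-truth core is thresholded from perfusion-surrogate maps:
relative CBF strictly below 25% of the contralateral value AND
time-to-peak delay strictly greater than 5 s, within brain parenchyma
minus the subtentorial compartment. Both inequalities are strict,
reading "less than" and "greater than" literally; the TTP criterion is
implemented as an absolute delay in seconds relative to the
contralateral timing (a delay *ratio* is a defensible alternative
reading; the phantom's maps satisfy either convention by construction).
Volumes are voxel count × voxel volume with no rounding; display
rounding to 2 decimals is cosmetic. A core of ≥ 70 ml (inclusive) is a
"large core".

## The automated-ASPECTS comparator

Commercial automated ASPECTS must infer the affected hemisphere. The
comparator mimics this: each region pair yields two directional ratios
(left/right and right/left of band-filtered means); a region is abnormal
on side *s* when its ratio falls below τ (default 0.95, i.e. a 5% mean
decrement); the detected side has the most abnormal regions, ties going
to the side with the lower summed ratio; the score is 10 − abnormal
count on the detected side. τ and the tie-break are free parameters —
the commercial algorithm is proprietary — and both are configurable.
Because detection never consults the true side, side mistakes are
possible; comparisons against the side-informed wHU score therefore run
on the side-correct subset per modality (the paired design requires both
markers valid on the same subjects), while the NCCT-vs-CTA comparison of
the wHU scores uses the whole cohort.

## Statistics

* **Spearman**: mid-rank correlation; two-sided p by the t
  approximation, appropriate for the cohort sizes targeted (n ≈ 20–73);
  an exact enumeration option exists for n ≤ 8 (beyond that the
  factorial permutation space is impractical and the t approximation is
  already accurate). Verbal bands on |rho|: [0, 0.2) slight, [0.2, 0.4)
  fair, [0.4, 0.6) moderate, [0.6, 0.8) substantial, [0.8, 1] almost
  perfect; boundaries assigned to the upper band.
* **ROC/AUC**: empirical Mann–Whitney AUC (ties count half). One
  orientation convention — higher score = more positive — serves all
  markers; ASPECTS is negated on entry and its cutoff reported back in
  "≤ k" form.
* **Youden cutoff**: exhaustive search over all distinct thresholds
  (plus −∞) of J = Se + Sp − 1; ties in J break toward higher
  sensitivity (a screening context favours sensitivity), then toward
  the lower cutoff. Se/Sp are computed unrounded and rounded only for
  display.
* **DeLong**: placement-value (structural-component) covariance of
  paired empirical AUCs, z = ΔAUC/se, two-sided normal p. Self- or
  monotone-transform comparisons return p = 1 exactly. The
  implementation reproduces an independent R reference (pROC) to 12
  decimals on a frozen fixture.
* **Bootstrap**: 500 unstratified case resamples by default, percentile
  2.5/97.5 interval, fixed default seed 20220726; single-class resamples
  are redrawn and counted. Simulation places the type-I error of the
  DeLong test at 5% ± 2% and percentile-CI coverage of a known AUC at
  95% ± 3% (checked in the test suite at n = 100 per cohort).

All pipeline statistics are computed unrounded; tables round AUC to 3
decimals, Se/Sp to 2, percentages to 1. Excluded subjects are handled
pairwise per comparison, and any stratum lacking a class or enough
subjects is reported as skipped with a reason, never dropped silently.

## The phantom

What it emulates: two exactly mirror-symmetric hemispheres partitioned
into the 10 ASPECTS regions (deep structures small, cortical M
territories large — region sizes are deliberately unequal to give the
regression weights something to do); baseline parenchyma at 36 HU ± 2 HU
per-voxel noise with small symmetric per-region offsets, sitting
centrally in the analysis band so the filter does not truncate normal
tissue; a contiguous lesion grown by breadth-first search (from a seed
voxel in the insula when targeting a volume, or within each named region
when targeting involvement fractions), lowering HU by the subject's
severity on NCCT and by severity × 1.5 on CTA-source (greater early
conspicuity on CTA-source imaging is documented qualitatively; the gain
magnitude is a free modeling choice); scattered CSF-like (10 HU, 5% of
brain voxels) and calcification-like (80 HU, 0.5%) confounders drawn
over the whole brain so some land inside lesioned regions; and perfusion
surrogates that are exactly normal (ratio 1, delay 0) outside the lesion
and beyond-threshold inside it, so the thresholded core equals the
ground-truth mask voxel-for-voxel.

Cohort defaults are the study conditions the analysis assumes: n = 73,
30.1% of subjects drawn large-core (volume uniform on 72–220 ml; small
cores log-normal, median 20 ml, clipped below 68 ml), 53.4% imaged
early; subjects in the late window draw 1.3× the mean severity,
reflecting stronger hypoattenuation at later times. Severity scatter
across subjects is **absolute** (s.d. 1.5 HU around the configured
mean, truncated at 0): the score observes involvement × severity while
the volume depends on involvement alone, so severity scatter is the
dominant noise source linking score to volume, and cohorts with weaker
mean severity are genuinely harder — this produces the monotone
AUC-versus-severity relationship asserted in the tests. The default
grid is 64 × 64 × 32 voxels of 2 × 2 × 4 mm (≈ 620 ml per hemisphere),
small enough that a 73-subject cohort simulates in seconds yet every
region keeps ≥ 200 voxels for stable means. Every random element flows
from one master seed through derived per-subject seeds: identical
configs give byte-identical cohorts.

What it does not emulate — and hence what passing tests do not show
about real data: no CT physics (beam hardening, partial volume, dose
noise structure), no anatomical variability or registration error, no
in-band chronic pathology. The last point matters for the comparator:
real automated-ASPECTS side mistakes (≈ 20–26% clinically) are driven
largely by asymmetric in-band confounders such as leukoaraiosis and old
cortical infarcts, which the phantom's out-of-band confounders cannot
produce; in default cohorts the comparator's side detection is nearly
always correct and the side-mistake rate is close to zero. The
side-mistake machinery is exercised instead by constructed adversarial
fixtures and by the subset bookkeeping tests. Similarly, phantom rHU
separations are cleaner than clinical ones, so absolute AUC levels here
exceed clinically reported values; only orderings and internal
consistency transfer.

## Numerical choices

Band and core thresholds as stated above (inclusive band, strict core
inequalities, inclusive 70 ml label). Lesion blob growth uses
6-connectivity with a fixed neighbour order, so blobs are deterministic
given the start voxel. OLS via the standard QR-based solver; a
rank-deficient design names the collinear regions and aborts. The wHU
dot product is exact to accumulation tolerance. Youden/J comparisons use
a 1e-12 slack when breaking ties. Bootstrap seeds below 2^31. The
end-to-end problem sizes used by the test suite and the acceptance
script (73-subject cohorts on the default grid, 500 bootstrap samples,
1000-cohort calibration sweeps at n = 100) keep a full run in the
low minutes on one CPU.
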