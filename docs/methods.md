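# Methods

## The measurement problem

Laser speckle flowgraphy (LSFG) images the fundus with an infrared laser;
moving red blood cells blur the speckle pattern, and the per-pixel *mean
blur rate* (MBR, arbitrary units) is linearly proportional to relative
blood-flow velocity. A clinical acquisition produces a composite map —
the temporal average over a few seconds of video — of the optic nerve head
and surrounding retina on a 750 × 360 px sensor (stored here row-major as
shape `(360, 750)`, origin top-left, 0-based pixel coordinates). Pixels
without a stable speckle signal are undefined and carried in a validity
mask (encoded as NaN on disk).

The scientific question the package serves is paired and cross-sectional:
does the treated eye of each patient show less flow than that patient's
untreated fellow eye, and does the deficit grow with time from treatment?

## Peripapillary annulus analysis

The standard LSFG readout measures flow in a ring around the optic disc:
inner circle on the disc margin (radius *r*, user-supplied), outer circle
at 2*r*. Ring membership uses Euclidean pixel-centre distance,
`inner ≤ d < outer`. Within the ring, valid MBR values are split by a
threshold into vessel pixels (mean **MV**, dominated by superficial
retinal arterioles and venules) and tissue pixels (mean **MT**, dominated
by choroidal flow).

The vendor software's thresholding rule is unpublished; this package uses
**Otsu's method on a 256-bin histogram** over the ring's value range — a
reproducible, data-driven cut with the described behaviour. Two properties
are enforced and tested: the count-weighted mean of (MV, MT) equals the
plain ring mean to 1e-9 relative, and scaling all MBR by c > 0 scales MV,
MT and the threshold by c. Constant ring values make the split undefined
and raise an error, as does a ring with fewer than 100 valid pixels (an
invented robustness floor). Disc centre and radius are inputs (per-eye
columns in the cohort table or CLI flags); automatic disc detection is out
of scope. Note that Otsu on a strongly unequal mixture sits close to the
dense mode: for 500 values near 8 AU and 100 near 25 AU, the cut falls at
≈9.5 AU, not at the midpoint of the two modes.

## Whole-scan superpixel analysis

The novel readout covers the entire frame. The single-channel MBR image is
partitioned with **SLIC** (simple linear iterative clustering) into a
target of **1500 superpixels** at **compactness 50** — grid-seeded
k-means, 10 iterations, distance a compactness-weighted combination of MBR
difference and spatial distance, connectivity enforced (orphan fragments
merged into adjacent superpixels; the realised count k therefore deviates
slightly from the target, within ±10% on full frames). Invalid pixels are
in-filled with the mean valid MBR *for clustering only*, so holes do not
distort superpixel shapes. The segmentation is deterministic for fixed
input.

Each superpixel is summarised by the mean of its valid pixels; a
superpixel with fewer than 50% valid pixels is **undefined** (the cutoff
is a design choice; the clinical display convention only marks such
superpixels white). Defined means are binned into five categorical flow
ranges with half-open edges

    [0, 5), [5, 10), [10, 15), [15, 20), [20, ∞)   AU

so a boundary value belongs to the upper bin, consistent with the top
range owning "≥ 20". Percentages are reported over defined superpixels
only. The two headline per-eye measures are `pct_ge20` (retinal-vessel
flow area) and `pct_lt5` (lowest choroidal flow area); the three middle
ranges are also computed and carried through the statistics. Per-range
pixel masks tile the frame together with the undefined regions. An
optional exclusion mask removes regions (e.g. a tumor shadow) from the
histogram; by default the full frame is included.

## Perfusion pressure

Mean arterial pressure MAP = DBP + (SBP − DBP)/3; ocular perfusion
pressure OPP = ⅔·MAP − IOP (sitting). OPP is computed per eye from the
cohort table; a non-positive OPP is returned with a warning rather than
rejected. At SBP/DBP 136/80 mmHg and IOP 14.4 mmHg: MAP = 98.67,
OPP = 51.38 mmHg.

## Cohort statistics

Per-eye values are arithmetic means of the three repeat scans (a
`--allow-missing-scans` escape accepts ≥1 with a warning). Thresholding
(Otsu, per scan) happens before averaging; whether per-scan or per-eye
thresholding better matches clinical practice is unknowable from public
information, and the per-scan choice is the documented one.

* **Paired t**: t = mean(d) / (sd(d)/√n), d = irradiated − fellow, sd with
  n−1 denominator, two-tailed p on n−1 df. Zero-variance differences are
  degenerate: all-zero is an error, constant-nonzero reports p = 0.
* **Regression vs time**: OLS slope per month, two-tailed p on n−2 df;
  irradiated and fellow eyes regressed separately. Constant response gives
  (slope 0, p 1); an exact line is reported as the zero-residual limit
  p = 0.
* **Spearman matrix** over MV, MT, pct_ge20, pct_lt5, time from treatment,
  dose to disc, distance tumor-to-disc (irradiated-eye values): mid-ranks
  for ties, p from the t-approximation t = ρ√((n−2)/(1−ρ²)) — adequate at
  n ≈ 25 — with pairwise-complete deletion so sparsely recorded dose or
  distance reduce n only for their own pairs. Significance is flagged at
  α = 0.01 (matching a 99% CI convention); no multiple-testing correction
  is applied by default, with Bonferroni available behind a flag.

Implementations are thin wrappers over scipy.stats; the test suite checks
t, β, ρ and all p-values against independent closed-form oracles to 1e-9.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. One eye's anatomy is built once and shared by its three repeat
scans:

* **Choroidal background**: Gaussian white noise low-pass filtered at
  correlation length 30 px (σ = 15 px), rescaled to sd 3 AU around a mean
  of 10 AU — giving the patchy low-flow regions characteristic of
  choroidal maps.
* **Vessel tree**: 5 trunks leave the disc centre at jittered, evenly
  spaced headings and meander outward (random-walk heading, 0.06 rad/step),
  spawning 2 children per segment for 2 generations, widths tapering from
  12 px. The vessel-pixel fraction is coerced into [2%, 20%] of the frame
  by morphological dilation/erosion. Vessel pixels are set to 25 AU. Trunk
  calibre ≈ one superpixel pitch (≈13 px at 1500 superpixels) is what
  makes vessel-dominated superpixels exceed the 20 AU bin, as in real
  scans where major arcade vessels dominate whole superpixels.
* **Optic disc**: a disk of radius 40 px at the frame centre at 30 AU
  (high on-disc flow).
* **Irradiation effect**: the treated eye's whole map is multiplied by
  m(t) = max(m_min, 1 − k·t months), defaults k = 0.01/month,
  m_min = 0.4; fellow eyes always receive 1. m(0) = 1, m is
  non-increasing and floors at m_min — so expected treated-eye flow
  declines linearly for five years and then plateaus at 40%.
* **Scan noise and dropouts**: i.i.d. Gaussian noise (sd 1 AU) per scan,
  clipped at zero (MBR is non-negative); 0.5% of pixels undefined,
  uniformly at random (no public description of their spatial pattern
  exists).
* **Covariates**: times from treatment uniform on 0.5–144 months; SBP
  136 ± 17, DBP 80 ± 10 (drawn as DBP + pulse to keep SBP > DBP), IOP
  14.4 ± 3.8 / 15.2 ± 3.2 mmHg (treated/fellow), dose to disc 38 ± 20 Gy,
  tumor-to-disc distance 5 ± 3 mm, all truncated to plausible ranges.

All randomness descends from one master seed through per-patient
`SeedSequence` spawns; cohorts are byte-identical across runs with the
same seed.

**What the generator does not emulate**: optical speckle physics and raw
video frames (only composite maps are generated); pulse-waveform
structure; eye-motion artefacts; spatially structured dropout; tumor
shadows; any anatomical correlation between a patient's two eyes (left
and right anatomies are independent); and absolute AU calibration, which
is set only qualitatively to typical clinical colour scales. Passing
tests therefore demonstrate correct recovery of a *multiplicative,
time-linear* flow deficit under these idealisations — not performance on
real scans.

## Replicate studies and problem sizes

Two simulation studies characterise the pipeline end to end
(`lsfg_superpix.studies`):

* **Effect recovery**: 100 cohorts of 25 patients at the default injury
  model; success means all four paired effects significant with the
  correct signs (MV, MT, pct_ge20 lower; pct_lt5 higher; p < 0.05) and
  the treated-eye regression signs correct. Fellow-eye non-significance
  rates should sit near the nominal 95%.
* **Type-I error**: 400 cohorts of 10 patients with the effect switched
  off (k = 0); the paired test's rejection rate at α = 0.05 must lie in
  the binomial 99% interval around 0.05. The calibration measure is MT:
  under the null, MV's paired differences are heavy-tailed (excess
  kurtosis ≈ 6) because small anatomy differences can flip the Otsu
  threshold between eyes, which makes the t-test conservative for MV
  (observed rejection ≈ 1.5%). That is a property of the MV measure, not
  of the test; it is a known limitation of threshold-based readouts on
  noisy bimodal data.

Both studies run on 64 × 128 frames produced by `CohortGeometry.for_shape`,
which rescales disc radius, vessel calibre and background correlation
length by the linear scale factor while `matched_n_superpixels` keeps the
superpixel pitch at the same fraction of vessel calibre (the superpixel
count then stays ≈1500 regardless of frame size). This preserves the scan
composition — vessel/background contrast per superpixel, disc area in
superpixels — so reduced-frame operating characteristics are
representative of full frames, at a few percent of the cost.

## Numerical and degenerate-input conventions

* CSV scan dialect round-trips float64 exactly; float TIFF is float32 and
  documented as lossy at epsilon.
* Negative finite values in a scan file are rejected (MBR is a
  non-negative quantity); non-finite values become invalid pixels.
* A cohort table must give every patient exactly two eyes, three scans per
  eye and exactly one irradiated eye; only dose and distance may be
  missing.
* Annuli that cross the frame edge are rejected with a re-centre/shrink
  hint; empty or near-empty rings surface as the too-few-valid-pixels
  error.
* Spearman pairs need ≥4 complete observations; constant variables are
  errors rather than silently-NaN correlations.
* SLIC accepts a `seed` argument for interface symmetry but is
  deterministic by construction.

## Known limitations

* The Otsu stand-in for the vendor's unpublished threshold means absolute
  MV/MT levels need not match vendor-software outputs; comparisons within
  a consistently processed cohort are unaffected.
* MV is noisier than MT (threshold jitter, above); studies needing a
  calibrated paired test on vessel flow should prefer the superpixel
  `pct_ge20` measure, whose differences are better behaved.
* The cross-sectional regressions estimate a population time trend, not
  within-patient progression; no mixed-effects modelling is attempted.
* The injury model is multiplicative and spatially uniform; focal
  (sector-shaped) injury is not simulated, although the superpixel
  analysis is precisely the tool that would detect it on real data.
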