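# Methods

`mitoflux` analyses the two data streams produced when an extracellular
flux assay is followed by high-content fluorescence imaging of the same
plate: per-well OCR/ECAR kinetics, and four-channel images (Hoechst
nuclear stain, MitoTracker, TMRE, MitoSOX) of each well. This note
documents the models, the algorithmic choices, the synthetic-data
generator that the test suite scores against, and the known limitations.

## Rate data and normalization

A rate series is an ordered list of (time, OCR, ECAR) measurements with
an injection schedule. The mito-stress-test protocol partitions the run
into four equal phases (default 3 measurements each) separated by
oligomycin, FCCP and rotenone/antimycin A; the spare port delivers the
staining dye after the last measurement, which is how imaging is coupled
to the assay without extra handling.

Raw OCR scales with the number of respiring cells under the sensor, so
three normalization denominators are supported:

* `seeded` — manually seeded cell count (per 1000 cells);
* `nuclei` — imaged nuclei count in the central sensed region (per 1000
  nuclei). The centre restriction matters because the instrument's
  microchamber measures oxygen over the middle of the well;
* `mitounit` — total per-well MitoTracker fluorescence (per 10⁶ A.U.).
  Normalizing by mitochondrial content rather than cell number separates
  "fewer mitochondria" from "less active mitochondria": a condition with
  half the mitochondria but normal per-mitochondrion respiration halves
  the nuclei-normalized OCR while leaving the MitoUnit-normalized OCR
  unchanged.

The scaling constants (10³ cells, 10⁶ A.U.) keep normalized values
O(1–100) and are fixed so outputs are comparable across runs. Wells with
zero/absent denominators are excluded with a `non_respiring` or
`low_signal` flag — never divided.

Stress-test parameters use the standard vendor conventions — last basal
measurement, minimum of the post-oligomycin and post-rotenone/AA phases,
maximum of the post-FCCP phase — with a phase-mean alternative in
config. `basal = atp_linked + proton_leak` is computed so the identity
holds exactly in floating point. Negative derived values (e.g. an FCCP
overdose collapsing respiration) are returned but flagged.

## Plate-position QC

Perimeter wells systematically under-read OCR because cells drift toward
well edges, away from the sensed centre; cell counting cannot correct
this, so the pipeline flags rather than corrects. Per-column medians of
time-averaged basal normalized OCR are compared against an interior
reference (columns 3–10, rows B–G, configurable); a column is flagged
when its median deviates more than 20% (relative) from the reference.
Rows A/H and columns 1/12 always carry a static `perimeter` advisory
independent of the data. The basal window is everything before the first
poison injection, so stress-test responses cannot masquerade as position
artifacts.

## Nuclei segmentation

Background is estimated by grayscale morphological opening with a disk
roughly 4 nuclear diameters across and subtracted; the foreground is an
Otsu threshold on the lightly smoothed result; touching nuclei are split
by watershed on the Euclidean distance transform seeded at its regional
maxima. Two numerical details:

* The peak-separation floor is 0.45× the expected nuclear diameter, not
  the 0.6× of the centre-to-centre geometry. The distance-transform
  maxima of a partially overlapping pair sit closer together than the
  centres do (for a 30%-area-overlap pair of 10 µm nuclei they are
  ~0.45 diameters apart); a 0.6× floor would merge exactly the pairs the
  watershed exists to split.
* A flat or noise-only channel returns an empty, `low_signal`-flagged
  result rather than raising; the guard requires the 99.5th percentile of
  the background-subtracted image to exceed 6× the robust noise sd.

Objects outside the 20–500 µm² area gate are discarded (debris and
unresolvable clumps); border-touching objects are kept but excluded from
counts. Segmentation is exactly intensity-scale invariant: multiplying
the channel by k changes no mask and scales every integrated intensity
by k, which the gating below relies on.

## Cell-cycle gating

Background-subtracted integrated nuclear intensity is proportional to
DNA content, so on a log₂ axis the 2N and 4N populations are two
Gaussian modes exactly one unit apart. A two-component 1-D mixture with
the equality constraint µ₂ = µ₁ + 1 is fitted by EM (the constraint is
what makes the fit identifiable on small or arrest-shifted populations;
it also rules out off-the-shelf unconstrained mixture fitters). The EM
runs from two starts — lower mode as 2N, or upper mode as 4N — and keeps
the higher-likelihood fit, so heavily arrested populations do not pull
µ₁ onto the 4N peak.

Two numerical choices matter for unbiased phase fractions:

* **Flank-robust sigmas.** S-phase forms a bridge between the modes;
  including it in the component variances inflates both sigmas and
  shifts the gates. Each sigma is therefore re-estimated from the
  uncontaminated outer flank of its mode (scaled MAD of points at or
  below µ₁, respectively at or above µ₂).
* **Gate width 1.5σ.** Gates sit at c₁ = µ₁ + kσ₁, c₂ = µ₂ − kσ₂ with
  k = 1.5 by default, with `> 4N` above c₃ = µ₂ + 3σ₂. For S-phase
  uniform in intensity on (I₀, 2I₀) and 7% lognormal CV, the fraction of
  S captured inside the gates is 2^(1−ks/ln2·…) in closed form:
  k = 2 captures only ~59% of S (an S-fraction bias of −0.065), whereas
  k = 1.5 captures ~69% and the symmetric G1/G2M spill-in almost exactly
  cancels the residual loss (net S bias ≈ −0.01). k is configurable
  (`GatingParams.gate_sigma`) for distributions with different S shapes.

If the fitted gates cross (c₁ > c₂, heavy overlap), assignment falls
back to the maximum posterior between G1 and G2M with S unassigned and
the well flagged. Wells with under 200 usable nuclei abstain entirely.
All of this is an explicit, documented stand-in: instrument vendors gate
these histograms with unpublished heuristics, so the package uses a
reproducible model-based rule instead.

## Perinuclear ROIs and mitochondrial readouts

Organelle signal is assigned to cells via distance-constrained
perinuclear regions: each ROI is the set of pixels within 10 µm of its
nucleus border, excluding the nucleus itself and any pixel nearer to a
different nucleus (a Euclidean Voronoi partition computed with one
distance transform). ROIs are disjoint by construction; signal outside
every ROI is reported as an `unassigned_fraction` QC number rather than
silently dropped.

* **MitoUnit** is the background-subtracted MitoTracker sum over each
  ROI, summed over cells (clipped at zero). Background defaults to the
  median over pixels belonging to neither a nucleus nor an ROI. Wells
  whose mean per-cell signal falls below 5000 A.U. (configurable;
  ~2.5% of a healthy cell at default generator brightness) are flagged
  `non_respiring` — the phenotype of mtDNA-depleted cells whose
  potential-dependent dye uptake collapses along with their respiration.
* **Object detection** applies a white top-hat (structuring element
  ≈ 2 µm), smooths the response by 0.5 px, thresholds by Otsu over ROI
  pixels, and labels components with 8-connectivity (which keeps blur
  halos attached to their parent object). Components of any size are
  kept by default: at 0.65 µm/px a sub-micron punctum occupies 1–2
  pixels, so a 3-px floor would silently erase the fragmented phenotype.
  An SNR guard (threshold ≥ 5× robust noise sd) prevents a signal-free
  well from shattering its noise floor into spurious objects.
* **Fragmentation class.** An object is *fragmented* if area ≤ 2 µm²
  and form factor 4πA/P² ≥ 0.6, else *granulated* (larger, networked or
  aggregated). These thresholds are explicit stand-ins for unpublished
  commercial spot-analysis settings and must be recalibrated per imaging
  system; both are config values. Perimeter uses the Crofton estimator
  and the form factor is capped at 1.0 (few-pixel objects otherwise
  exceed 1 through discretisation). Well-level and per-cell fractions
  are both reported. At extreme compositions the detected fraction is
  compressed toward the middle by ~0.1 (dim puncta merging, tubule-edge
  crumbs), which leaves dose-response ordering intact.
* **TMRE / MitoSOX** are quantified as background-subtracted per-cell
  ROI means plus the well mean (and per-cell quartiles for MitoSOX).
  Because the generator renders these channels as the mitochondrial
  geometry rescaled by a condition factor, factor ratios are recovered
  directly from the well-mean ratios (within ~15% at the default noise
  and 40–100 cells/field). TMRE requires live-cell imaging in practice;
  that sequencing constraint is a wet-lab concern outside this package's
  scope.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions the
test suite and acceptance checks measure under.

**Kinetics.** OCR(t) = n_cells × per_cell_ocr × phase_multiplier(t) ×
edge_artifact + ε with ε ~ N(0, rate_noise_sd × signal); ECAR is
generated analogously with an independent per-cell rate and its own
phase response. Defaults: 5 pmol O₂/min per 1000 cells, stress response
(0.4, 1.5, 0.1) — i.e. basal 100 → 40/150/10 for 20k cells — 3
measurements per phase at 6.5 min intervals, 5% relative noise. Negative
noisy rates are clipped at zero and flagged.

**Images.** One 16-bit field of view per well (default 1024² px at
0.65 µm/px). `field_fraction` (default 2%) maps seeded cells/well to
nuclei/field, so the canonical 3k–50k seeding range produces ~60–1000
nuclei/field; the imaged field stands for the central region of the
well. Nuclei are jittered ellipses (radius ~5 µm, ±15% axes) placed
uniformly in a disc by dart-throwing with a 2.2-radius minimum
separation, never within two radii of the border; integrated intensity
is I₀ × DNA content (G1 = 1, S ~ U(1, 2), G2M = 2, >4N = 4) with 7%
lognormal cell-to-cell CV. Mitochondria are rendered per cell — with
probability `frag_prob` as 15–40 puncta (diameter ≤ 1 µm, ≥ 2 µm apart),
otherwise as 3–6 curvilinear tubules (~0.6 µm wide, 5–15 µm long) — in
an annulus chosen so every object lies strictly outside every nucleus
and within 10 µm of its own nucleus border (in a 2-D projection,
organelles drawn over a nucleus would be unassignable, so placement
rejects such positions). Total per-cell mito intensity is
`mito_per_cell` with 15% lognormal CV; TMRE and MitoSOX are the
noiseless mito geometry rescaled by their condition factors. All
channels then get background (default 100 counts), Poisson shot noise
and Gaussian read noise (sd 5), and are quantised to uint16 with
saturation flagged. Camera noise magnitudes are placeholders exposed in
config — they emulate structure, not a measured instrument.

Every nucleus (position, phase, true integrated intensity) and every
mito object (class, parent, intensity) is recorded in `truth.json`,
along with noiseless per-channel pixel sums, so pixel-sum, matching and
classification oracles are exact. All outputs are deterministic,
byte-identical functions of the seed (per-well substreams are derived
from the seed and well index, independent of iteration order).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: optics beyond a Gaussian blur (no PSF
tails, aberration or depth effects), 3-D mitochondrial networks and
z-stacks, photobleaching, uneven illumination, debris and dead-cell
artifacts, cell-to-cell contact geometry, and suspension cells. The
fragmentation thresholds and the non-respiring cutoff in particular are
calibrated to this renderer and must be re-derived on real images.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: counting
checks at 150–1200 nuclei per 1024² field, imaging conditions at 40–100
cells per 512² field with 3–5 replicate wells, gating at 2000 nuclei per
population, plate QC on a 60-well layout, and 25 wells for the
fragmentation dose series. These sizes give the binomial/noise headroom
the stated tolerances need while keeping a full run to a few minutes on
one CPU.

## Known limitations

* The Voronoi partition is Euclidean, not geodesic; for touching cells
  the boundary can cut through a neighbour's cytoplasm.
* Counting accuracy degrades above ~60% nuclear coverage; the generator
  refuses to render such fields rather than producing unscorable truth.
* The `non_respiring` flag is an absolute per-cell threshold; plates
  with globally dim staining need it re-tuned (it is not relative to the
  plate median by design, so a uniformly sick plate is not silently
  re-baselined).
* ECAR is normalized identically to OCR; interpretation of normalized
  ECAR is left to the user.
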