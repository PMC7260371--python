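"""Nuclei segmentation, central-region counting and cell-cycle gating.

The nuclear (Hoechst) channel drives three analyses:

1. **Segmentation & counting** — background removal by large-kernel
   morphological opening, Otsu thresholding, and a distance-transform
   watershed to split touching nuclei.  Counts are restricted to the
   central region of the well because that is where the flux instrument's
   microchamber senses oxygen.
2. **Cell-cycle gating** — integrated (background-subtracted) nuclear
   intensity is proportional to DNA content, so on a log2 axis the 2N and
   4N populations are two Gaussian modes exactly one unit apart.  A
   two-component 1-D Gaussian mixture constrained to mu2 = mu1 + 1 is
   fitted by EM; phase gates are placed at a configurable number of
   component sigmas.
3. **Nuclear size statistics** — e.g. the enlarged nuclei that accompany
   G2/M arrest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .image import WellImage

PHASES = ("G1", "S", "G2M", "gt4N")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the nuclear segmentation recipe.

    ``expected_diameter_um`` anchors both the background kernel (4x the
    diameter) and the watershed peak separation (0.6x the diameter).
    The area gate rejects debris and merged clumps.
    """

    expected_diameter_um: float = 10.0
    background_kernel_factor: float = 4.0
    # distance-transform maxima of a partially overlapping pair sit closer
    # together than the nucleus centres do, so the peak-separation floor is
    # below the geometric 0.6 x diameter of the centres themselves
    watershed_sep_factor: float = 0.45
    min_area_um2: float = 20.0
    max_area_um2: float = 500.0
    smoothing_sigma_um: float = 0.65
    low_signal_snr: float = 6.0   # p99.5 of background-subtracted image vs noise


@dataclass
class NucleusRecord:
    """One segmented nucleus."""

    nucleus_id: int
    centroid_um: tuple[float, float]     # (x, y)
    area_um2: float
    integrated_intensity: float          # background-subtracted sum over mask
    in_center: bool = False
    phase: str = "unassigned"
    touches_border: bool = False


@dataclass
class SegmentationResult(Sequence):
    """Sequence of :class:`NucleusRecord` plus the label image and flags."""

    records: list[NucleusRecord]
    labels: np.ndarray | None = None
    flags: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[NucleusRecord]:
        return iter(self.records)


def _robust_noise_sd(arr: np.ndarray) -> float:
    med = np.median(arr)
    return 1.4826 * np.median(np.abs(arr - med))


def segment_nuclei(
    image: WellImage, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Segment the nuclear channel into :class:`NucleusRecord` objects.

    Objects outside the area gate are discarded; objects touching the
    image border are kept but flagged (and excluded from counts).  A flat
    or empty channel yields an empty result flagged ``low_signal`` rather
    than an exception.  Records are sorted by (y, x) and the label image
    is relabelled to match ``nucleus_id``.
    """
    params = params or SegmentationParams()
    px = image.pixel_size_um
    img = image.channel("nuclear").astype(np.float64)

    diam_px = params.expected_diameter_um / px
    bg_radius = max(int(round(params.background_kernel_factor * diam_px / 2.0)), 3)
    background = opening(img, disk(bg_radius, decomposition="sequence"))
    sub = img - background

    noise_sd = _robust_noise_sd(sub)
    peak = np.percentile(sub, 99.5)
    if peak <= 0 or (noise_sd > 0 and peak < params.low_signal_snr * noise_sd) or (
        noise_sd == 0 and np.ptp(sub) == 0
    ):
        return SegmentationResult(records=[], labels=np.zeros_like(img, dtype=np.int32),
                                  flags={"low_signal"})

    smooth = ndi.gaussian_filter(sub, sigma=params.smoothing_sigma_um / px)
    try:
        thr = threshold_otsu(smooth)
    except ValueError:
        return SegmentationResult(records=[], labels=np.zeros_like(img, dtype=np.int32),
                                  flags={"low_signal"})
    mask = smooth > thr
    min_px = max(int(params.min_area_um2 / px ** 2 / 4), 4)
    lbl, _ = ndi.label(mask)
    sizes = np.bincount(lbl.ravel())
    mask = sizes[lbl] >= min_px
    mask &= lbl > 0
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return SegmentationResult(records=[], labels=np.zeros_like(img, dtype=np.int32),
                                  flags={"low_signal"})

    # watershed on the distance transform to split touching nuclei
    dist = ndi.distance_transform_edt(mask)
    blob_labels, _ = ndi.label(mask)
    min_dist = max(int(round(params.watershed_sep_factor * diam_px)), 1)
    coords = peak_local_max(dist, min_distance=min_dist, labels=blob_labels,
                            exclude_border=False)
    markers = np.zeros_like(blob_labels)
    for k, (r, c) in enumerate(coords, start=1):
        markers[r, c] = k
    # make sure every connected blob carries at least one marker
    has_marker = set(np.unique(blob_labels[markers > 0]))
    for blob in np.unique(blob_labels):
        if blob == 0 or blob in has_marker:
            continue
        inside = np.where(blob_labels == blob)
        j = np.argmax(dist[inside])
        markers[inside[0][j], inside[1][j]] = markers.max() + 1
    labels = watershed(-dist, markers, mask=mask)

    h, w = img.shape
    props = regionprops(labels, intensity_image=sub)
    entries = []
    for p in props:
        area_um2 = p.area * px ** 2
        if not params.min_area_um2 <= area_um2 <= params.max_area_um2:
            continue
        r0, c0, r1, c1 = p.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cy, cx = p.centroid
        integ = max(float(p.image_intensity[p.image].sum()), 0.0)
        entries.append((p.label, (cx * px, cy * px), area_um2, integ, touches))

    entries.sort(key=lambda e: (e[1][1], e[1][0]))  # by (y, x)
    records = []
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    for new_id, (old_label, centroid, area, integ, touches) in enumerate(entries, start=1):
        relabel[old_label] = new_id
        records.append(
            NucleusRecord(
                nucleus_id=new_id,
                centroid_um=centroid,
                area_um2=area,
                integrated_intensity=integ,
                touches_border=touches,
            )
        )
    new_labels = relabel[labels]
    return SegmentationResult(records=records, labels=new_labels)


def count_center_nuclei(
    records: Sequence[NucleusRecord],
    image: WellImage,
    center_fraction: float = 0.5,
) -> tuple[int, int]:
    """Count nuclei overall and within the central sensed region.

    ``nuclei_center`` counts non-border nuclei whose centroid lies within
    ``center_fraction x well_radius`` of the well centre; ``nuclei_total``
    counts all non-border nuclei.  Also sets ``in_center`` on the records.
    """
    if not 0.0 < center_fraction <= 1.0:
        raise ValueError("center_fraction must lie in (0, 1]")
    px = image.pixel_size_um
    cy, cx = image.well_center_px
    center_um = (cx * px, cy * px)
    radius_um = image.well_radius_px * px * center_fraction
    total = 0
    center = 0
    for r in records:
        if r.touches_border:
            r.in_center = False
            continue
        total += 1
        d = math.hypot(r.centroid_um[0] - center_um[0], r.centroid_um[1] - center_um[1])
        r.in_center = d <= radius_um
        if r.in_center:
            center += 1
    return total, center


# ---------------------------------------------------------------------------
# cell-cycle gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingParams:
    """Cell-cycle gating parameters.

    The G1/S and S/G2M gates sit ``gate_sigma`` component-sigmas from the
    2N and 4N means; the >4N gate sits ``gt4n_sigma`` above the 4N mean.
    ``min_records`` guards against fitting noise on sparse wells.
    Component sigmas are re-estimated robustly from the outer flank of
    each mode so the S-phase bridge between them cannot inflate the fit.
    """

    min_records: int = 200
    gate_sigma: float = 1.5
    gt4n_sigma: float = 3.0
    max_iter: int = 500
    tol: float = 1e-8
    robust_sigma: bool = True
    min_spread: float = 0.02   # log2 units; below this the fit is degenerate


@dataclass
class GatingResult:
    phase_fractions: dict[str, float] | None
    mu1: float | None = None
    sigma1: float | None = None
    sigma2: float | None = None
    weight1: float | None = None
    thresholds: tuple[float, float, float] | None = None
    flags: set[str] = field(default_factory=set)
    n_assigned: int = 0


def _constrained_gmm(x: np.ndarray, max_iter: int, tol: float):
    """EM for a 1-D two-Gaussian mixture with means (mu, mu + 1).

    Run from two starts — the lower mode as 2N, or the upper mode as 4N —
    and keep the higher-likelihood fit, so G2/M-arrested populations where
    the 4N peak dominates do not pull mu1 onto the wrong mode.
    """
    best = None
    for mu0 in (float(np.percentile(x, 25.0)), float(np.percentile(x, 75.0)) - 1.0):
        fit = _constrained_gmm_from(x, mu0, max_iter, tol)
        if best is None or fit[-1] > best[-1]:
            best = fit
    return best[:-1]


def _constrained_gmm_from(x: np.ndarray, mu0: float, max_iter: int, tol: float):
    mu = mu0
    s1 = s2 = max(float(np.std(x)) / 2.0, 1e-3)
    w = 0.7
    ll = ll_old = -np.inf
    for _ in range(max_iter):
        logp1 = np.log(w) - 0.5 * ((x - mu) / s1) ** 2 - np.log(s1)
        logp2 = np.log1p(-w) - 0.5 * ((x - mu - 1.0) / s2) ** 2 - np.log(s2)
        m = np.maximum(logp1, logp2)
        denom = np.exp(logp1 - m) + np.exp(logp2 - m)
        r1 = np.exp(logp1 - m) / denom
        r2 = 1.0 - r1
        ll = float(np.sum(m + np.log(denom)))
        # weighted mean shared by both components (second shifted by 1)
        a = np.sum(r1) / s1 ** 2 + np.sum(r2) / s2 ** 2
        b = np.sum(r1 * x) / s1 ** 2 + np.sum(r2 * (x - 1.0)) / s2 ** 2
        mu = b / a
        s1 = math.sqrt(max(np.sum(r1 * (x - mu) ** 2) / max(np.sum(r1), 1e-12), 1e-8))
        s2 = math.sqrt(max(np.sum(r2 * (x - mu - 1.0) ** 2) / max(np.sum(r2), 1e-12), 1e-8))
        w = float(np.clip(np.mean(r1), 1e-6, 1.0 - 1e-6))
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return mu, s1, s2, w, r1, ll


def _flank_sigma(x: np.ndarray, mu: float, side: str, fallback: float) -> float:
    """Robust sigma from the uncontaminated outer flank of a mode."""
    flank = x[x <= mu] if side == "left" else x[x >= mu]
    if flank.size < 20:
        return fallback
    mad = np.median(np.abs(flank - mu))
    return float(max(1.4826 * mad, 1e-3))


def classify_cell_cycle(
    records: Sequence[NucleusRecord],
    params: GatingParams | None = None,
) -> GatingResult:
    """Gate nuclei into G1 / S / G2M / >4N from integrated intensity.

    Fits the constrained log2-intensity mixture, places gates at
    ``c1 = mu1 + k*sigma1``, ``c2 = mu2 - k*sigma2``, ``c3 = mu2 +
    k'*sigma2`` and assigns phases in place on the records.  If the two
    modes overlap so heavily that ``c1 > c2``, assignment falls back to
    the maximum posterior between G1 and G2M with S left unassigned and
    the well flagged ``cycle_overlap``.
    """
    params = params or GatingParams()
    usable = [r for r in records if r.integrated_intensity > 0]
    if len(usable) < params.min_records:
        warnings.warn(
            f"cell-cycle gating skipped: {len(usable)} nuclei with positive "
            f"intensity < minimum {params.min_records}",
            stacklevel=2,
        )
        return GatingResult(phase_fractions=None, flags={"too_few_nuclei"})

    x = np.log2([r.integrated_intensity for r in usable])
    if float(np.std(x)) < params.min_spread:
        return GatingResult(phase_fractions=None, flags={"degenerate_fit"})

    mu, s1, s2, w, _ = _constrained_gmm(x, params.max_iter, params.tol)
    if params.robust_sigma:
        s1 = _flank_sigma(x, mu, "left", s1)
        s2 = _flank_sigma(x, mu + 1.0, "right", s2)

    c1 = mu + params.gate_sigma * s1
    c2 = mu + 1.0 - params.gate_sigma * s2
    c3 = mu + 1.0 + params.gt4n_sigma * s2

    flags: set[str] = set()
    counts = {p: 0 for p in PHASES}
    if c1 > c2:
        flags.add("cycle_overlap")
        for r, xi in zip(usable, x):
            p1 = w * math.exp(-0.5 * ((xi - mu) / s1) ** 2) / s1
            p2 = (1 - w) * math.exp(-0.5 * ((xi - mu - 1.0) / s2) ** 2) / s2
            if xi > c3:
                r.phase = "gt4N"
            else:
                r.phase = "G1" if p1 >= p2 else "G2M"
            counts[r.phase] += 1
    else:
        for r, xi in zip(usable, x):
            if xi < c1:
                r.phase = "G1"
            elif xi < c2:
                r.phase = "S"
            elif xi <= c3:
                r.phase = "G2M"
            else:
                r.phase = "gt4N"
            counts[r.phase] += 1

    n_assigned = sum(counts.values())
    fractions = {p: counts[p] / n_assigned for p in PHASES}
    return GatingResult(
        phase_fractions=fractions,
        mu1=mu, sigma1=s1, sigma2=s2, weight1=w,
        thresholds=(c1, c2, c3),
        flags=flags,
        n_assigned=n_assigned,
    )


# ---------------------------------------------------------------------------
# nuclear size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeStats:
    mean_area_um2: float
    median_area_um2: float
    sd_area_um2: float   # 0.0 for a single record, by convention
    n: int


def nuclear_size_stats(records: Sequence[NucleusRecord]) -> SizeStats | None:
    """Area statistics over non-border nuclei; ``None`` if there are none."""
    areas = np.array([r.area_um2 for r in records if not r.touches_border])
    if areas.size == 0:
        return None
    sd = float(np.std(areas, ddof=1)) if areas.size > 1 else 0.0
    return SizeStats(
        mean_area_um2=float(np.mean(areas)),
        median_area_um2=float(np.median(areas)),
        sd_area_um2=sd,
        n=int(areas.size),
    )
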