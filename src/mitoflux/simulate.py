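"""Synthetic flux-plate and well-image generator with ground truth.

This module emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* **Plate kinetics** — per-well OCR/ECAR time series following the
  mito-stress-test phase structure (basal → oligomycin → FCCP →
  rotenone/antimycin A), with OCR proportional to cell number, optional
  multiplicative edge artifacts, and relative Gaussian measurement noise.
* **Well images** — one field of view per well with four channels:
  nuclei rendered as jittered ellipses whose integrated intensity is
  proportional to DNA content (G1 = 1x, S uniform in (1x, 2x), G2/M = 2x,
  >4N = 4x, with lognormal cell-to-cell scatter); mitochondria rendered
  per cell as either small perinuclear puncta (fragmented phenotype) or
  curvilinear tubules (granulated/networked phenotype) confined to an
  annulus within 10 µm of the nucleus border; TMRE and MitoSOX channels
  share the mitochondrial geometry rescaled by per-condition factors.
  All channels receive background, Poisson and Gaussian camera noise and
  are quantised to the 16-bit range.

Every generated object is recorded in a ground-truth structure so that
segmentation, gating, ROI capture and normalization can be scored against
known answers.  All outputs are deterministic functions of the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .errors import DensityError, ValidationError
from .image import WellImage, write_well_tiffs
from .xf_io import (
    Measurement,
    PlateLayout,
    RateSeries,
    WellAssignment,
    annotate_injections,
    write_layout,
    write_rate_table,
)

PHASES = ("G1", "S", "G2M", "gt4N")
PHASE_DNA = {"G1": 1.0, "G2M": 2.0, "gt4N": 4.0}  # S drawn uniform in (1, 2)


@dataclass(frozen=True)
class Noise:
    """Camera noise model: counts = Poisson((x + bg)/g)·g + N(0, sd)."""

    poisson_scale: float = 1.0   # camera gain g; 0 disables shot noise
    gaussian_sd: float = 5.0     # read noise, counts; 0 disables
    background_level: float = 100.0

    @classmethod
    def off(cls, background_level: float = 0.0) -> "Noise":
        return cls(poisson_scale=0.0, gaussian_sd=0.0, background_level=background_level)


@dataclass
class WellSpec:
    """Generative parameters for one well (the study condition)."""

    well_id: str
    n_cells: int = 20000
    per_cell_ocr: float = 0.005          # pmol O2/min per cell
    per_cell_ecar: float = 0.002         # mpH/min per cell
    mito_per_cell: float = 2.0e5         # mean mito fluorescence per cell (A.U.)
    frag_prob: float = 0.2               # P(cell renders puncta rather than tubules)
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.6, "S": 0.2, "G2M": 0.2, "gt4N": 0.0}
    )
    tmre_factor: float = 1.0
    mitosox_factor: float = 1.0
    edge_artifact: float = 1.0           # multiplier on OCR/ECAR
    stress_response: tuple[float, float, float] = (0.4, 1.5, 0.1)
    ecar_response: tuple[float, float, float] = (1.3, 1.2, 1.1)
    nuclear_radius_scale: float = 1.0    # e.g. enlarged nuclei after G2/M arrest
    group: str = "default"
    treatment: str = ""

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError(f"{self.well_id}: n_cells must be >= 0")
        if not 0.0 <= self.frag_prob <= 1.0:
            raise ValidationError(f"{self.well_id}: frag_prob must lie in [0, 1]")
        total = sum(self.phase_fractions.get(p, 0.0) for p in PHASES)
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"{self.well_id}: phase_fractions must sum to 1")
        for name in ("tmre_factor", "mitosox_factor", "edge_artifact",
                     "mito_per_cell", "nuclear_radius_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.well_id}: {name} must be >= 0")


@dataclass
class SimConfig:
    """Plate-level simulation configuration.

    ``field_fraction`` maps seeded cells/well to nuclei in the imaged
    central field of view (the imager sees a fixed central field, not the
    whole well), so e.g. 3k–50k cells/well yields ~60–1000 nuclei/field
    at the default 2%.
    """

    seed: int
    wells: list[WellSpec]
    pixel_size_um: float = 0.65
    image_size_px: tuple[int, int] = (1024, 1024)
    noise: Noise = field(default_factory=Noise)
    rate_noise_sd: float = 0.05          # relative sd of OCR/ECAR measurements
    measurements_per_phase: int = 3
    measurement_interval_min: float = 6.5
    protocol: str = "mito_stress_test"   # or "basal_only"
    field_fraction: float = 0.02
    nuclear_i0: float = 5.0e5            # integrated 2N nuclear intensity (A.U.)
    nuclear_radius_um: float = 5.0
    intensity_cv: float = 0.07           # lognormal CV of nuclear intensity
    mito_cv: float = 0.15                # lognormal CV of per-cell mito total
    annulus_um: float = 10.0             # perinuclear ROI convention

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate well ids in SimConfig.wells")

    def layout(self) -> PlateLayout:
        return PlateLayout(
            [
                WellAssignment(
                    well_id=w.well_id, group=w.group, treatment=w.treatment,
                    seeded_cells=w.n_cells,
                )
                for w in self.wells
            ]
        )

    def cells_in_field(self, spec: WellSpec) -> int:
        return int(round(spec.n_cells * self.field_fraction))


def _rng_for(config: SimConfig, kind: int, index: int) -> np.random.Generator:
    """Deterministic per-well generator independent of iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(kind, index))
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _phase_multipliers(spec: WellSpec, n: int, per_phase: int, protocol: str,
                       response: tuple[float, float, float]) -> np.ndarray:
    if protocol == "basal_only":
        return np.ones(n)
    mult = np.ones(n)
    o, f, r = response
    mult[per_phase: 2 * per_phase] = o
    mult[2 * per_phase: 3 * per_phase] = f
    mult[3 * per_phase:] = r
    return mult


def simulate_plate_kinetics(config: SimConfig) -> tuple[list[RateSeries], pd.DataFrame]:
    """Generate per-well OCR/ECAR series plus the generative truth table.

    With noise off the basal OCR is exactly ``n_cells × per_cell_ocr ×
    edge_artifact`` and each poison phase is that times its response
    multiplier.  Negative noisy rates are clipped at zero and the well is
    flagged ``clipped_negative``.
    """
    n = 4 * config.measurements_per_phase if config.protocol == "mito_stress_test" \
        else 3 * config.measurements_per_phase
    times = (np.arange(1, n + 1)) * config.measurement_interval_min
    series: list[RateSeries] = []
    rows = []
    for i, spec in enumerate(config.wells):
        rng = _rng_for(config, kind=0, index=i)
        ocr_mult = _phase_multipliers(spec, n, config.measurements_per_phase,
                                      config.protocol, spec.stress_response)
        ecar_mult = _phase_multipliers(spec, n, config.measurements_per_phase,
                                       config.protocol, spec.ecar_response)
        basal_ocr = spec.n_cells * spec.per_cell_ocr * spec.edge_artifact
        basal_ecar = spec.n_cells * spec.per_cell_ecar * spec.edge_artifact
        ocr = basal_ocr * ocr_mult
        ecar = basal_ecar * ecar_mult
        if config.rate_noise_sd > 0:
            ocr = ocr + rng.normal(0.0, config.rate_noise_sd * np.abs(ocr))
            ecar = ecar + rng.normal(0.0, config.rate_noise_sd * np.abs(ecar))
        flags = set()
        if np.any(ocr < 0) or np.any(ecar < 0):
            flags.add("clipped_negative")
            ocr = np.clip(ocr, 0.0, None)
            ecar = np.clip(ecar, 0.0, None)
        measurements = [
            Measurement(index=j + 1, time_min=float(times[j]),
                        ocr=float(ocr[j]), ecar=float(ecar[j]))
            for j in range(n)
        ]
        s = RateSeries(well_id=spec.well_id, measurements=measurements, flags=flags)
        s = annotate_injections(s, config.protocol, config.measurements_per_phase)
        s.flags |= flags
        series.append(s)
        rows.append(
            {
                "well": spec.well_id,
                "group": spec.group,
                "treatment": spec.treatment,
                "n_cells": spec.n_cells,
                "per_cell_ocr": spec.per_cell_ocr,
                "per_cell_ecar": spec.per_cell_ecar,
                "edge_artifact": spec.edge_artifact,
                "basal_ocr": basal_ocr,
                "basal_ecar": basal_ecar,
                "oligo_frac": spec.stress_response[0],
                "fccp_frac": spec.stress_response[1],
                "rotaa_frac": spec.stress_response[2],
            }
        )
    return series, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nucleus intensity model (shared by renderer and gating tests)
# ---------------------------------------------------------------------------

def sample_phases(phase_fractions: dict[str, float], n: int,
                  rng: np.random.Generator) -> list[str]:
    p = np.array([phase_fractions.get(ph, 0.0) for ph in PHASES], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(PHASES), size=n, p=p)
    return [PHASES[i] for i in idx]


def sample_nuclear_intensity(phase: str, i0: float, cv: float,
                             rng: np.random.Generator) -> float:
    """Integrated nuclear intensity for one cell: DNA content × lognormal scatter."""
    if phase == "S":
        base = rng.uniform(1.0, 2.0)
    else:
        base = PHASE_DNA[phase]
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        base *= rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma)
    return float(i0 * base)


def sample_nucleus_population(
    phase_fractions: dict[str, float],
    n: int,
    i0: float = 1.0,
    cv: float = 0.07,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    """Draw (phases, integrated intensities) for ``n`` nuclei.

    This is the renderer's intensity model without the pixel rendering;
    it lets cell-cycle gating be exercised at population sizes that would
    not fit in a single field of view.
    """
    rng = rng or np.random.default_rng(0)
    phases = sample_phases(phase_fractions, n, rng)
    intensities = np.array(
        [sample_nuclear_intensity(ph, i0, cv, rng) for ph in phases]
    )
    return phases, intensities


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _place_centers(
    n: int,
    center: tuple[float, float],
    radius: float,
    min_sep: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random centres in a disc with a minimum separation (RSA).

    Grid-accelerated dart throwing; raises :class:`DensityError` if the
    requested count cannot be placed.
    """
    if n == 0:
        return np.zeros((0, 2))
    cell = min_sep / np.sqrt(2.0)
    grid: dict[tuple[int, int], int] = {}
    pts = np.empty((n, 2))
    placed = 0
    max_tries = max(2000, 400 * n)
    tries = 0
    while placed < n and tries < max_tries:
        tries += 1
        r = radius * np.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * np.pi)
        p = np.array([center[0] + r * np.sin(th), center[1] + r * np.cos(th)])
        gx, gy = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dx in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                j = grid.get((gx + dx, gy + dy))
                if j is not None and np.hypot(*(pts[j] - p)) < min_sep:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid[(gx, gy)] = placed
            placed += 1
    if placed < n:
        raise DensityError(
            f"could only place {placed}/{n} nuclei at min separation "
            f"{min_sep:.1f}px in radius {radius:.0f}px"
        )
    return pts


def _camera(arr: np.ndarray, noise: Noise, rng: np.random.Generator) -> np.ndarray:
    out = arr + noise.background_level
    if noise.poisson_scale > 0:
        g = noise.poisson_scale
        out = rng.poisson(np.clip(out, 0, None) / g).astype(np.float64) * g
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(np.round(out), 0, 65535)


def _stamp(img: np.ndarray, rr: np.ndarray, cc: np.ndarray, value: float) -> None:
    img[rr, cc] += value


def render_well_image(
    spec: WellSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_cells_override: int | None = None,
) -> tuple[WellImage, dict]:
    """Render the four channels of one well field plus its ground truth.

    Returns ``(image, truth)`` where ``truth`` records every nucleus
    (position in µm, phase, true integrated intensity, radius) and every
    mitochondrial object (class, parent cell, true total intensity), plus
    per-channel noiseless above-background pixel sums.
    """
    if rng is None:
        idx = next((i for i, w in enumerate(config.wells) if w.well_id == spec.well_id), 0)
        rng = _rng_for(config, kind=1, index=idx)
    h, w = config.image_size_px
    px = config.pixel_size_um
    n_cells = config.cells_in_field(spec) if n_cells_override is None else n_cells_override

    r_um = config.nuclear_radius_um * spec.nuclear_radius_scale
    r_px = r_um / px
    well_radius = min(h, w) / 2.0 - 2.0
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    margin = 2.0 * r_px  # nuclei never placed within 2 radii of the border
    place_radius = well_radius - margin
    if place_radius <= 0:
        raise DensityError("image too small for the nuclear radius")

    # expected area coverage must stay under 60%
    coverage = n_cells * np.pi * r_px ** 2 / (np.pi * place_radius ** 2)
    if coverage > 0.6:
        raise DensityError(
            f"{spec.well_id}: {n_cells} nuclei would cover {coverage:.0%} "
            "of the field (limit 60%)"
        )
    min_sep = 2.2 * r_px
    centers = _place_centers(n_cells, center, place_radius, min_sep, rng)

    nuclear = np.zeros((h, w))
    mito = np.zeros((h, w))
    phases = sample_phases(spec.phase_fractions, n_cells, rng)
    # mito objects must not be drawn over any nucleus (in 2-D projection),
    # so object placement rejects positions near other nuclei too
    tree = cKDTree(centers) if n_cells > 1 else None
    nuc_clear_px = 1.15 * r_px + 1.5 / px  # worst-case axis + margin

    nuclei_truth = []
    mito_truth = []
    for i in range(n_cells):
        cy, cx = centers[i]
        # jittered ellipse axes and orientation
        a = r_px * rng.uniform(0.85, 1.15)
        b = r_px * rng.uniform(0.85, 1.15)
        theta = rng.uniform(0.0, np.pi)
        intensity = sample_nuclear_intensity(phases[i], config.nuclear_i0,
                                             config.intensity_cv, rng)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        if rr.size == 0:
            continue
        _stamp(nuclear, rr, cc, intensity / rr.size)
        eff_radius = float(np.sqrt(a * b))
        nuclei_truth.append(
            {
                "x_um": cx * px,
                "y_um": cy * px,
                "radius_um": eff_radius * px,
                "area_um2": float(rr.size) * px ** 2,
                "phase": phases[i],
                "integrated_intensity": intensity,
            }
        )

        # --- mitochondria in the perinuclear annulus -----------------------
        if spec.mito_per_cell <= 0:
            continue
        total = spec.mito_per_cell
        if config.mito_cv > 0:
            s = np.sqrt(np.log(1.0 + config.mito_cv ** 2))
            total *= rng.lognormal(mean=-s ** 2 / 2.0, sigma=s)
        fragmented = rng.uniform() < spec.frag_prob
        # annulus bounds from the worst-case ellipse axes so every object
        # lies outside the nucleus yet within annulus_um of its border
        max_ax_um = max(a, b) * px
        min_ax_um = min(a, b) * px
        inner = max_ax_um + 1.5
        outer = max(min_ax_um + config.annulus_um - 1.3, inner + 1.0)
        objects = []

        def clear_of_neighbors(oy: float, ox: float) -> bool:
            if tree is None:
                return True
            dists, idx = tree.query([oy, ox], k=2)
            for dd, jj in zip(np.atleast_1d(dists), np.atleast_1d(idx)):
                if jj != i and dd < nuc_clear_px:
                    return False
            return True
        if fragmented:
            k = int(rng.integers(15, 41))
            shares = rng.uniform(0.5, 1.5, size=k)
            shares /= shares.sum()
            placed_puncta: list[tuple[float, float]] = []
            min_gap_px = 2.0 / px  # keep puncta resolvable as separate objects
            for j in range(k):
                oy = ox = None
                for _ in range(30):
                    d = rng.uniform(inner, outer - 0.5)
                    ang = rng.uniform(0.0, 2.0 * np.pi)
                    ty = cy + (d / px) * np.sin(ang)
                    tx = cx + (d / px) * np.cos(ang)
                    if not clear_of_neighbors(ty, tx):
                        continue
                    if all(np.hypot(ty - py, tx - qx) >= min_gap_px
                           for py, qx in placed_puncta):
                        oy, ox = ty, tx
                        break
                if oy is None:
                    continue
                placed_puncta.append((oy, ox))
                pr = rng.uniform(0.3, 0.5) / px  # punctum radius, diameter <= 1 um
                rr2, cc2 = draw_disk((oy, ox), max(pr, 0.7), shape=(h, w))
                if rr2.size == 0:
                    continue
                mito[rr2, cc2] += shares[j] * total / rr2.size
                objects.append({"cls": "puncta", "intensity": float(shares[j] * total)})
        else:
            m = int(rng.integers(3, 7))
            shares = rng.uniform(0.5, 1.5, size=m)
            shares /= shares.sum()
            for j in range(m):
                ys = xs = None
                for _ in range(15):
                    d = rng.uniform(inner + 0.5, outer - 0.5)
                    length = rng.uniform(5.0, 15.0)
                    ang0 = rng.uniform(0.0, 2.0 * np.pi)
                    dang = length / d  # arc subtending the tubule length
                    npts = max(int(length / px / 0.5), 4)
                    angs = ang0 + np.linspace(0.0, dang, npts)
                    wob = rng.normal(0.0, 0.25, size=npts).cumsum()
                    wob -= wob.mean()
                    dd = np.clip(d + wob * 0.3, inner, outer)
                    ty = cy + (dd / px) * np.sin(angs)
                    tx = cx + (dd / px) * np.cos(angs)
                    if all(clear_of_neighbors(yy, xx)
                           for yy, xx in zip(ty[::3], tx[::3])):
                        ys, xs = ty, tx
                        break
                if ys is None:
                    continue
                mask = np.zeros((h, w), dtype=bool)
                half_w = max(0.3 / px, 0.8)  # tubule half-width ~0.3 um
                for yy, xx in zip(ys, xs):
                    rr2, cc2 = draw_disk((yy, xx), half_w, shape=(h, w))
                    mask[rr2, cc2] = True
                npx = int(mask.sum())
                if npx == 0:
                    continue
                mito[mask] += shares[j] * total / npx
                objects.append({"cls": "tubule", "intensity": float(shares[j] * total)})
        for o in objects:
            o["parent"] = i
        mito_truth.extend(objects)

    # mild optical blur (single focal plane, widefield-style)
    nuclear = ndi.gaussian_filter(nuclear, sigma=0.8)
    mito = ndi.gaussian_filter(mito, sigma=0.5)
    tmre = mito * spec.tmre_factor
    mitosox = mito * spec.mitosox_factor

    clean = {"nuclear": nuclear, "mito": mito, "tmre": tmre, "mitosox": mitosox}
    channel_sums = {ch: float(arr.sum()) for ch, arr in clean.items()}

    channels = {ch: _camera(arr, config.noise, rng) for ch, arr in clean.items()}
    flags = {ch for ch, arr in channels.items() if np.any(arr >= 65535)}

    img = WellImage(
        well_id=spec.well_id,
        channels=channels,
        pixel_size_um=px,
        well_center_px=center,
        well_radius_px=well_radius,
        flags={f"saturated_{ch}" for ch in flags},
    )
    truth = {
        "well_id": spec.well_id,
        "n_cells": n_cells,
        "pixel_size_um": px,
        "well_center_px": list(center),
        "well_radius_px": well_radius,
        "frag_prob": spec.frag_prob,
        "tmre_factor": spec.tmre_factor,
        "mitosox_factor": spec.mitosox_factor,
        "mito_per_cell": spec.mito_per_cell,
        "nuclei": nuclei_truth,
        "mito_objects": mito_truth,
        "channel_sums": channel_sums,
        "background_level": config.noise.background_level,
    }
    return img, truth


# ---------------------------------------------------------------------------
# full fixture directories
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig, out_dir: str | Path,
                     render_images: bool = True) -> dict:
    """Write a complete fixture: rate CSV, layout CSV, per-channel TIFFs
    and ``truth.json``.  Deterministic under a fixed seed.

    Returns a manifest dict of the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc

    layout = config.layout()
    series, kin_truth = simulate_plate_kinetics(config)

    rate_path = out_dir / "rates.csv"
    layout_path = out_dir / "layout.csv"
    write_rate_table(series, layout, rate_path)
    write_layout(layout, layout_path)

    image_dir = out_dir / "images"
    truth: dict = {
        "seed": config.seed,
        "protocol": config.protocol,
        "pixel_size_um": config.pixel_size_um,
        "field_fraction": config.field_fraction,
        "kinetics": kin_truth.to_dict(orient="records"),
        "wells": {},
    }
    tiff_paths: list[Path] = []
    if render_images:
        for i, spec in enumerate(config.wells):
            rng = _rng_for(config, kind=1, index=i)
            img, well_truth = render_well_image(spec, config, rng=rng)
            tiff_paths.extend(write_well_tiffs(img, image_dir))
            truth["wells"][spec.well_id] = well_truth

    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
        fh.write("\n")

    return {
        "rate_table": rate_path,
        "layout": layout_path,
        "truth": truth_path,
        "images": tiff_paths,
        "image_dir": image_dir if render_images else None,
    }
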