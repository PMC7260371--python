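"""OCR/ECAR normalization and plate-position quality control.

Raw rates scale with the number of (respiring) cells under the sensor, so
each series can be normalized by one of three denominators:

* ``seeded``  — the manually seeded cell count (per 1000 cells);
* ``nuclei``  — the imaged nuclei count in the central sensed region
  (per 1000 nuclei), the preferred cell-number correction;
* ``mitounit`` — total per-well MitoTracker fluorescence (per 10^6 A.U.),
  which decouples "fewer mitochondria" from "less active mitochondria".

Plate-position QC compares per-column medians of basal normalized OCR
against an interior-well reference; perimeter wells additionally carry a
static advisory because cells drift toward well edges there, depressing
OCR in a way that cell counting cannot correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DenominatorError, QCError
from .xf_io import (
    Agent,
    Injection,
    PlateLayout,
    RateSeries,
    WellSummary,
    parse_well_id,
)

MODES = ("seeded", "nuclei", "mitounit")

#: denominator scaling constants keeping normalized values O(1-100)
SCALES = {"seeded": 1e3, "nuclei": 1e3, "mitounit": 1e6}

POISONS = {Agent.OLIGOMYCIN, Agent.FCCP, Agent.ROTENONE_ANTIMYCIN}

INTERIOR_COLUMNS = tuple(range(3, 11))   # 3..10
INTERIOR_ROWS = "BCDEFG"
PERIMETER_COLUMNS = (1, 12)
PERIMETER_ROWS = ("A", "H")


@dataclass
class NormalizedRates:
    """A rate series divided by a per-well denominator."""

    well_id: str
    mode: str
    values: list[tuple[float, float, float]]   # (time_min, ocr_norm, ecar_norm)
    denominator: float                          # raw denominator (cells / nuclei / A.U.)
    injections: list[Injection] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def _basal_slice(self) -> slice:
        first_poison = None
        for inj in self.injections:
            if inj.agent in POISONS:
                first_poison = inj.after_index
                break
        return slice(0, first_poison) if first_poison else slice(None)

    @property
    def basal_ocr_norm(self) -> float:
        vals = [v[1] for v in self.values[self._basal_slice()]]
        return float(np.mean(vals))

    @property
    def basal_ocr_raw(self) -> float:
        return self.basal_ocr_norm * self.denominator / SCALES[self.mode]


def _denominator(summary: WellSummary, layout: PlateLayout, mode: str) -> float | None:
    if mode == "seeded":
        seeded = layout[summary.well_id].seeded_cells if summary.well_id in layout else None
        return float(seeded) if seeded is not None else None
    if mode == "nuclei":
        return float(summary.nuclei_center)
    if mode == "mitounit":
        return float(summary.mitounit)
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_rates(
    series: RateSeries,
    summary: WellSummary,
    layout: PlateLayout,
    mode: str,
) -> NormalizedRates:
    """Normalize one series; raises :class:`DenominatorError` rather than
    dividing by a zero/absent denominator (the caller decides exclusion).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    denom = _denominator(summary, layout, mode)
    flags = set(summary.flags) | set(series.flags)
    if denom is None or denom <= 0:
        if mode == "mitounit":
            flags.add("non_respiring")
        else:
            flags.add("low_signal")
        raise DenominatorError(
            f"well {series.well_id}: {mode} denominator absent or non-positive",
            flags=flags,
        )
    scale = denom / SCALES[mode]
    values = [
        (m.time_min, m.ocr / scale, m.ecar / scale) for m in series.measurements
    ]
    return NormalizedRates(
        well_id=series.well_id,
        mode=mode,
        values=values,
        denominator=denom,
        injections=list(series.injections),
        flags=flags,
    )


def normalize_plate(
    series: Iterable[RateSeries],
    summaries: Mapping[str, WellSummary],
    layout: PlateLayout,
    mode: str,
) -> tuple[list[NormalizedRates], dict[str, set[str]]]:
    """Normalize every well; wells with unusable denominators (or flagged
    ``non_respiring``) are excluded and returned with their flags.
    """
    norms: list[NormalizedRates] = []
    excluded: dict[str, set[str]] = {}
    for s in series:
        summ = summaries.get(s.well_id)
        if summ is None:
            excluded[s.well_id] = {"no_summary"}
            continue
        if mode == "mitounit" and "non_respiring" in summ.flags:
            excluded[s.well_id] = set(summ.flags)
            continue
        try:
            norms.append(normalize_rates(s, summ, layout, mode))
        except DenominatorError as exc:
            excluded[s.well_id] = exc.flags
    return norms, excluded


# ---------------------------------------------------------------------------
# plate-position QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnProfile:
    column: int
    median_norm_ocr: float
    iqr: float
    n_wells: int
    flagged: bool = False


@dataclass
class ColumnProfileReport:
    profiles: list[ColumnProfile]
    interior_median: float


def column_profile(
    norms: Sequence[NormalizedRates],
    layout: PlateLayout,
    interior_columns: Sequence[int] = INTERIOR_COLUMNS,
    interior_rows: str = INTERIOR_ROWS,
) -> ColumnProfileReport:
    """Per-column median/IQR of time-averaged basal normalized OCR.

    The interior reference is the median over wells in columns 3-10 and
    rows B-G, the region conventionally reserved for experiments.
    """
    by_col: dict[int, list[float]] = {}
    interior_vals: list[float] = []
    for n in norms:
        row, col = parse_well_id(n.well_id)
        by_col.setdefault(col, []).append(n.basal_ocr_norm)
        if col in interior_columns and row in interior_rows:
            interior_vals.append(n.basal_ocr_norm)
    populated_interior = [c for c in by_col if c in interior_columns]
    if len(populated_interior) < 2:
        raise QCError(
            f"column profile needs data in >= 2 interior columns, "
            f"found {len(populated_interior)}"
        )
    if not interior_vals:
        raise QCError("no interior wells (columns 3-10, rows B-G) with data")
    profiles = []
    for col in sorted(by_col):
        vals = np.array(by_col[col])
        q75, q25 = np.percentile(vals, [75, 25])
        profiles.append(
            ColumnProfile(
                column=col,
                median_norm_ocr=float(np.median(vals)),
                iqr=float(q75 - q25),
                n_wells=int(vals.size),
            )
        )
    return ColumnProfileReport(
        profiles=profiles, interior_median=float(np.median(interior_vals))
    )


@dataclass
class EdgeQCResult:
    flagged_columns: set[int]
    perimeter_advisories: set[str]       # wells in row A/H or column 1/12
    well_flags: dict[str, set[str]]
    rel_threshold: float


def edge_effect_qc(
    report: ColumnProfileReport,
    norms: Sequence[NormalizedRates],
    rel_threshold: float = 0.2,
) -> EdgeQCResult:
    """Flag columns whose median deviates from the interior reference.

    A column is flagged iff ``|median_col - median_interior| /
    median_interior > rel_threshold``.  Independently of the data, wells
    in rows A/H and columns 1/12 carry a static ``perimeter`` advisory.
    With ``rel_threshold = 0`` any nonzero deviation flags the column
    (documented degenerate behaviour).
    """
    ref = report.interior_median
    flagged = set()
    for p in report.profiles:
        if ref != 0 and abs(p.median_norm_ocr - ref) / abs(ref) > rel_threshold:
            flagged.add(p.column)
    # rebuild profiles with flags set
    report.profiles = [
        ColumnProfile(p.column, p.median_norm_ocr, p.iqr, p.n_wells,
                      flagged=p.column in flagged)
        for p in report.profiles
    ]
    advisories = set()
    well_flags: dict[str, set[str]] = {}
    for n in norms:
        row, col = parse_well_id(n.well_id)
        wf = well_flags.setdefault(n.well_id, set())
        if row in PERIMETER_ROWS or col in PERIMETER_COLUMNS:
            advisories.add(n.well_id)
            wf.add("perimeter")
        if col in flagged:
            wf.add("edge_flag")
            n.flags.add("edge_flag")
    return EdgeQCResult(
        flagged_columns=flagged,
        perimeter_advisories=advisories,
        well_flags=well_flags,
        rel_threshold=rel_threshold,
    )


# ---------------------------------------------------------------------------
# seeding-density linearity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedingReport:
    slope: float          # pmol O2/min per cell
    intercept: float
    r_squared: float
    cv_normalized: float  # CV of group-mean normalized OCR across densities
    n_groups: int


def seeding_linearity_report(
    norms_by_density: Mapping[float, Sequence[NormalizedRates]],
) -> SeedingReport:
    """Raw-OCR-vs-density linearity and normalized-OCR consistency.

    Least-squares fit of time-averaged basal *raw* OCR against seeding
    density over all wells, plus the coefficient of variation of the
    group-mean *normalized* basal OCR across densities.  Requires at
    least three density groups.
    """
    if len(norms_by_density) < 3:
        raise QCError(
            f"seeding linearity needs >= 3 density groups, got {len(norms_by_density)}"
        )
    xs: list[float] = []
    ys: list[float] = []
    group_means: list[float] = []
    for density, norms in sorted(norms_by_density.items()):
        if not norms:
            raise QCError(f"density group {density} has no wells")
        for n in norms:
            xs.append(float(density))
            ys.append(n.basal_ocr_raw)
        group_means.append(float(np.mean([n.basal_ocr_norm for n in norms])))
    fit = stats.linregress(xs, ys)
    gm = np.array(group_means)
    cv = float(np.std(gm, ddof=0) / np.mean(gm)) if np.mean(gm) != 0 else float("inf")
    return SeedingReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        cv_normalized=cv,
        n_groups=len(norms_by_density),
    )
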