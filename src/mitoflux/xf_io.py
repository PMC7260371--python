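"""Reading and writing of flux-assay text formats.

The extracellular-flux instrument side of the platform is represented by
three plain-text artifacts:

* a **rate table** — the per-well kinetic export with one row per
  measurement: ``Measurement,Well,Group,Time_min,OCR,ECAR`` (OCR in
  pmol O2/min, ECAR in mpH/min, time in minutes);
* a **plate layout** — group / treatment / seeded-cell assignments for a
  96-well plate, as CSV (``well,group,treatment,seeded_cells``) or YAML;
* a **well-summary table** — per-well aggregates produced by the imaging
  side (nuclei counts, MitoUnit, cell-cycle fractions, dye means).

The dialects are deliberately fixed and documented here rather than
sniffed; a short conversion note for real instrument exports lives in the
package docs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import FormatError, LayoutError, ProtocolError, ValidationError

ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))

RATE_TABLE_COLUMNS = ["Measurement", "Well", "Group", "Time_min", "OCR", "ECAR"]

SUMMARY_COLUMNS = [
    "well",
    "nuclei_total",
    "nuclei_center",
    "mitounit",
    "fragmentation_fraction",
    "frac_G1",
    "frac_S",
    "frac_G2M",
    "frac_gt4N",
    "mean_tmre",
    "mean_mitosox",
    "flags",
]

PHASES = ("G1", "S", "G2M", "gt4N")


class Agent(str, Enum):
    """Injection-port contents recognised by the pipeline."""

    OLIGOMYCIN = "oligomycin"
    FCCP = "fccp"
    ROTENONE_ANTIMYCIN = "rotenone_antimycin"
    DYE = "dye"
    CUSTOM = "custom"


def parse_well_id(well_id: str) -> tuple[str, int]:
    """Split a well id like ``"B7"`` into (row letter, column int).

    Raises
    ------
    LayoutError
        If the id is not a row A–H / column 1–12 address.
    """
    wid = well_id.strip()
    if len(wid) < 2 or wid[0].upper() not in ROWS:
        raise LayoutError(f"invalid well id {well_id!r}: row must be A-H")
    try:
        col = int(wid[1:])
    except ValueError:
        raise LayoutError(f"invalid well id {well_id!r}: column must be an integer") from None
    if col not in COLUMNS:
        raise LayoutError(f"invalid well id {well_id!r}: column must be 1-12")
    return wid[0].upper(), col


def sort_key(well_id: str) -> tuple[int, int]:
    row, col = parse_well_id(well_id)
    return ROWS.index(row), col


@dataclass(frozen=True)
class WellAssignment:
    """One layout entry: which group/treatment a well belongs to."""

    well_id: str
    group: str
    treatment: str = ""
    seeded_cells: int | None = None

    def __post_init__(self):
        parse_well_id(self.well_id)
        if not self.group:
            raise LayoutError(f"well {self.well_id}: group must be nonempty")
        if self.seeded_cells is not None and self.seeded_cells < 0:
            raise LayoutError(f"well {self.well_id}: seeded_cells must be nonnegative")


@dataclass
class PlateLayout:
    """A 96-well plate layout (groups, treatments, seeded cell counts)."""

    wells: list[WellAssignment]
    plate_format: int = 96

    def __post_init__(self):
        if self.plate_format != 96:
            raise LayoutError(f"unsupported plate format {self.plate_format}")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LayoutError(f"duplicate well ids in layout: {dupes}")
        self._by_id = {w.well_id: w for w in self.wells}

    def __contains__(self, well_id: str) -> bool:
        return well_id in self._by_id

    def __getitem__(self, well_id: str) -> WellAssignment:
        return self._by_id[well_id]

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for w in self.wells:
            out.setdefault(w.group, []).append(w.well_id)
        return out


@dataclass(frozen=True)
class Measurement:
    """One kinetic measurement point."""

    index: int
    time_min: float
    ocr: float
    ecar: float


@dataclass(frozen=True)
class Injection:
    """A port injection occurring after measurement ``after_index``."""

    after_index: int
    agent: Agent


@dataclass
class RateSeries:
    """Per-well OCR/ECAR time series with its injection schedule."""

    well_id: str
    measurements: list[Measurement]
    injections: list[Injection] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        parse_well_id(self.well_id)
        self.validate()

    def validate(self) -> None:
        idx = [m.index for m in self.measurements]
        if idx != list(range(1, len(idx) + 1)):
            raise ValidationError(
                f"well {self.well_id}: measurement indices must be contiguous from 1"
            )
        times = [m.time_min for m in self.measurements]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"well {self.well_id}: measurement times must be strictly increasing"
            )
        if times and times[0] < 0:
            raise ValidationError(f"well {self.well_id}: times must be nonnegative")
        n = len(self.measurements)
        seen_gaps = set()
        for inj in self.injections:
            if not 0 <= inj.after_index <= n:
                raise ValidationError(
                    f"well {self.well_id}: injection after_index {inj.after_index} "
                    f"outside measurement range 0..{n}"
                )
            if inj.after_index in seen_gaps:
                raise ValidationError(
                    f"well {self.well_id}: more than one injection after index "
                    f"{inj.after_index}"
                )
            seen_gaps.add(inj.after_index)

    @property
    def times(self) -> list[float]:
        return [m.time_min for m in self.measurements]

    @property
    def ocr(self) -> list[float]:
        return [m.ocr for m in self.measurements]

    @property
    def ecar(self) -> list[float]:
        return [m.ecar for m in self.measurements]

    def injection_after(self, agent: Agent) -> Injection | None:
        for inj in self.injections:
            if inj.agent == agent:
                return inj
        return None

    def scaled(self, factor: float) -> "RateSeries":
        """Return a copy with OCR and ECAR multiplied by ``factor``."""
        ms = [replace(m, ocr=m.ocr * factor, ecar=m.ecar * factor) for m in self.measurements]
        return RateSeries(self.well_id, ms, list(self.injections), set(self.flags))


@dataclass
class WellSummary:
    """Per-well aggregates from the imaging side, used for normalization."""

    well_id: str
    nuclei_total: int
    nuclei_center: int
    mitounit: float
    fragmentation_fraction: float | None = None
    phase_fractions: dict[str, float] | None = None
    mean_tmre: float | None = None
    mean_mitosox: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        parse_well_id(self.well_id)
        if self.nuclei_center > self.nuclei_total:
            raise ValidationError(
                f"well {self.well_id}: nuclei_center ({self.nuclei_center}) exceeds "
                f"nuclei_total ({self.nuclei_total})"
            )
        if self.mitounit < 0:
            raise ValidationError(f"well {self.well_id}: mitounit must be >= 0")
        if self.fragmentation_fraction is not None and not (
            0.0 <= self.fragmentation_fraction <= 1.0
        ):
            raise ValidationError(
                f"well {self.well_id}: fragmentation_fraction outside [0, 1]"
            )
        if self.phase_fractions is not None:
            if set(self.phase_fractions) != set(PHASES):
                raise ValidationError(
                    f"well {self.well_id}: phase_fractions keys must be {PHASES}"
                )
            vals = list(self.phase_fractions.values())
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValidationError(
                    f"well {self.well_id}: phase fractions must lie in [0, 1]"
                )
            if abs(sum(vals) - 1.0) > 1e-6:
                raise ValidationError(
                    f"well {self.well_id}: phase fractions must sum to 1"
                )


# ---------------------------------------------------------------------------
# plate layouts
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from CSV (``well,group,treatment,seeded_cells``) or YAML."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        return _read_layout_yaml(path)
    return _read_layout_csv(path)


def _read_layout_csv(path: Path) -> PlateLayout:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"well", "group"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise FormatError(f"{path}: layout CSV missing column(s) {missing}")
        wells = []
        for row in reader:
            seeded = row.get("seeded_cells", "")
            wells.append(
                WellAssignment(
                    well_id=row["well"].strip(),
                    group=row["group"].strip(),
                    treatment=(row.get("treatment") or "").strip(),
                    seeded_cells=int(float(seeded)) if seeded not in ("", None) else None,
                )
            )
    return PlateLayout(wells)


def _read_layout_yaml(path: Path) -> PlateLayout:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "wells" not in data:
        raise FormatError(f"{path}: layout YAML must contain a 'wells' mapping or list")
    entries = data["wells"]
    wells = []
    if isinstance(entries, dict):
        entries = [{"well": k, **v} for k, v in entries.items()]
    for e in entries:
        wells.append(
            WellAssignment(
                well_id=str(e["well"]).strip(),
                group=str(e["group"]).strip(),
                treatment=str(e.get("treatment", "")).strip(),
                seeded_cells=int(e["seeded_cells"]) if e.get("seeded_cells") is not None else None,
            )
        )
    return PlateLayout(wells, plate_format=int(data.get("plate_format", 96)))


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "group", "treatment", "seeded_cells"])
        for w in sorted(layout.wells, key=lambda w: sort_key(w.well_id)):
            writer.writerow(
                [w.well_id, w.group, w.treatment,
                 "" if w.seeded_cells is None else w.seeded_cells]
            )


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

def read_rate_table(path: str | Path, layout: PlateLayout) -> list[RateSeries]:
    """Read a rate-table CSV into one :class:`RateSeries` per well.

    Rows are grouped by well; within each well the rows must already be in
    strictly increasing time order (the parser never reorders measurements).
    Wells not present in ``layout`` are rejected.  Wells with fewer
    measurements than the plate mode are kept but flagged ``short_series``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"rate table not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse CSV ({exc})") from exc
    for col in RATE_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    series: list[RateSeries] = []
    for well_id, grp in df.groupby("Well", sort=False):
        well_id = str(well_id)
        try:
            parse_well_id(well_id)
        except LayoutError as exc:
            raise LayoutError(f"{path}: {exc}") from None
        if well_id not in layout:
            raise LayoutError(f"{path}: well {well_id} not present in plate layout")
        times = grp["Time_min"].to_numpy(dtype=float)
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"{path}: well {well_id} has non-monotone Time_min values"
            )
        measurements = [
            Measurement(index=i + 1, time_min=float(t), ocr=float(o), ecar=float(e))
            for i, (t, o, e) in enumerate(
                zip(times, grp["OCR"].to_numpy(dtype=float), grp["ECAR"].to_numpy(dtype=float))
            )
        ]
        series.append(RateSeries(well_id=well_id, measurements=measurements))

    if series:
        mode_len = _mode([len(s.measurements) for s in series])
        for s in series:
            if len(s.measurements) < mode_len:
                s.flags.add("short_series")
    return series


def _mode(values: Sequence[int]) -> int:
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return max(counts, key=lambda k: (counts[k], k))


def write_rate_table(
    series: Iterable[RateSeries], layout: PlateLayout, path: str | Path
) -> None:
    """Write rate series back to the documented CSV dialect."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RATE_TABLE_COLUMNS)
        for s in sorted(series, key=lambda s: sort_key(s.well_id)):
            group = layout[s.well_id].group if s.well_id in layout else ""
            for m in s.measurements:
                writer.writerow(
                    [m.index, s.well_id, group,
                     _fmt(m.time_min), _fmt(m.ocr), _fmt(m.ecar)]
                )


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


# ---------------------------------------------------------------------------
# injection schedules
# ---------------------------------------------------------------------------

def annotate_injections(
    series: RateSeries,
    protocol: str,
    measurements_per_phase: int = 3,
) -> RateSeries:
    """Attach the injection schedule implied by an assay protocol.

    ``mito_stress_test`` divides the run into four equal phases (default 3
    measurements each) separated by oligomycin, FCCP and rotenone/antimycin A
    injections; ``basal_only`` adds no poisons.  Both protocols end with the
    staining-dye injection delivered from the spare port after the final
    measurement.
    """
    n = len(series.measurements)
    if protocol == "basal_only":
        injections = [Injection(after_index=n, agent=Agent.DYE)]
    elif protocol == "mito_stress_test":
        if measurements_per_phase < 1:
            raise ProtocolError("measurements_per_phase must be >= 1")
        if n != 4 * measurements_per_phase:
            raise ProtocolError(
                f"well {series.well_id}: {n} measurements incompatible with 4 phases "
                f"of {measurements_per_phase}"
            )
        p = measurements_per_phase
        injections = [
            Injection(after_index=p, agent=Agent.OLIGOMYCIN),
            Injection(after_index=2 * p, agent=Agent.FCCP),
            Injection(after_index=3 * p, agent=Agent.ROTENONE_ANTIMYCIN),
            Injection(after_index=n, agent=Agent.DYE),
        ]
    else:
        raise ProtocolError(f"unknown protocol {protocol!r}")
    return RateSeries(
        well_id=series.well_id,
        measurements=list(series.measurements),
        injections=injections,
        flags=set(series.flags),
    )


# ---------------------------------------------------------------------------
# well summaries
# ---------------------------------------------------------------------------

def write_well_summaries(summaries: Iterable[WellSummary], path: str | Path) -> None:
    """Write per-well summaries as CSV (one row per well, fixed columns).

    Absent optional values are written as empty cells; values round-trip to
    at least 6 significant digits.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("write_well_summaries: no summaries given")
    ids = [s.well_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate well ids in summaries: {dupes}")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for s in sorted(summaries, key=lambda s: sort_key(s.well_id)):
            pf = s.phase_fractions or {}
            writer.writerow(
                [
                    s.well_id,
                    s.nuclei_total,
                    s.nuclei_center,
                    _fmt(s.mitounit),
                    _opt(s.fragmentation_fraction),
                    _opt(pf.get("G1")),
                    _opt(pf.get("S")),
                    _opt(pf.get("G2M")),
                    _opt(pf.get("gt4N")),
                    _opt(s.mean_tmre),
                    _opt(s.mean_mitosox),
                    ";".join(sorted(s.flags)),
                ]
            )


def _opt(x: float | None) -> str:
    return "" if x is None else _fmt(x)


def read_well_summaries(path: str | Path) -> list[WellSummary]:
    """Read back a summaries CSV written by :func:`write_well_summaries`."""
    path = Path(path)
    out: list[WellSummary] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(SUMMARY_COLUMNS).issubset(reader.fieldnames):
            missing = sorted(set(SUMMARY_COLUMNS) - set(reader.fieldnames or []))
            raise FormatError(f"{path}: summary CSV missing column(s) {missing}")
        for row in reader:
            fracs = {p: row[f"frac_{p}"] for p in PHASES}
            has_fracs = all(v != "" for v in fracs.values())
            pf = {p: float(v) for p, v in fracs.items()} if has_fracs else None
            if pf is not None:
                # renormalise tiny rounding drift from the 10-sig-digit format
                total = sum(pf.values())
                if total > 0 and not math.isclose(total, 1.0, abs_tol=1e-6):
                    raise ValidationError(f"{path}: phase fractions for {row['well']} do not sum to 1")
            out.append(
                WellSummary(
                    well_id=row["well"],
                    nuclei_total=int(row["nuclei_total"]),
                    nuclei_center=int(row["nuclei_center"]),
                    mitounit=float(row["mitounit"]),
                    fragmentation_fraction=_opt_float(row["fragmentation_fraction"]),
                    phase_fractions=pf,
                    mean_tmre=_opt_float(row["mean_tmre"]),
                    mean_mitosox=_opt_float(row["mean_mitosox"]),
                    flags=set(filter(None, row["flags"].split(";"))),
                )
            )
    return out


def _opt_float(s: str) -> float | None:
    return None if s == "" else float(s)


def summaries_by_well(summaries: Iterable[WellSummary]) -> Mapping[str, WellSummary]:
    return {s.well_id: s for s in summaries}
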