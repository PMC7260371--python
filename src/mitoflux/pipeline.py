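"""Config-driven end-to-end runs and demo-scenario construction.

``run_pipeline`` ties the modules together in the order a plate flows
through the platform: rate-table and layout ingestion → nuclei
segmentation, central counting and cell-cycle gating → perinuclear ROI
quantification of mitochondrial content, fragmentation, TMRE and MitoSOX
→ per-well summaries → normalization in every requested mode → plate QC
→ stress-test parameters.  Outputs are plain CSV/PNG/JSON files plus a
machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, PipelineError, QCError
from .image import read_well_tiffs
from .mito import (
    MitoDetectParams,
    build_cell_rois,
    classify_fragmentation,
    detect_mito_objects,
    quantify_membrane_potential,
    quantify_mito_content,
    quantify_mtros,
)
from .normalize import (
    MODES,
    column_profile,
    edge_effect_qc,
    normalize_plate,
)
from .nuclei import (
    GatingParams,
    SegmentationParams,
    classify_cell_cycle,
    count_center_nuclei,
    segment_nuclei,
)
from .plotting import plate_heatmap
from .simulate import Noise, SimConfig, WellSpec, generate_dataset
from .stress import stress_test_parameters
from .xf_io import (
    WellSummary,
    annotate_injections,
    read_layout,
    read_rate_table,
    write_well_summaries,
)

logger = logging.getLogger("mitoflux")

_KNOWN_KEYS = {
    "rate_table", "image_dir", "layout", "out_dir", "pixel_size_um",
    "protocol", "modes", "center_fraction", "seed", "verbosity",
    "channels", "nuclei", "mito", "normalization", "stress_test",
}


@dataclass
class RunConfig:
    rate_table: Path
    image_dir: Path | None
    layout: Path
    out_dir: Path
    pixel_size_um: float = 0.65
    protocol: str = "mito_stress_test"
    modes: list[str] = field(default_factory=lambda: ["nuclei", "mitounit"])
    center_fraction: float = 0.5
    seed: int = 0
    verbosity: str = "info"
    nuclei_params: SegmentationParams = field(default_factory=SegmentationParams)
    gating_params: GatingParams = field(default_factory=GatingParams)
    mito_params: MitoDetectParams = field(default_factory=MitoDetectParams)
    max_roi_distance_um: float = 10.0
    frag_max_area_um2: float = 2.0
    frag_min_form_factor: float = 0.6
    non_respiring_per_cell: float = 5000.0
    edge_rel_threshold: float = 0.2
    measurements_per_phase: int = 3
    config_text: str = ""     # raw YAML, hashed into the manifest

    def validate(self) -> None:
        if not self.rate_table.exists():
            raise ConfigError(f"rate_table not found: {self.rate_table}")
        if not self.layout.exists():
            raise ConfigError(f"layout not found: {self.layout}")
        if self.image_dir is not None and not self.image_dir.exists():
            raise ConfigError(f"image_dir not found: {self.image_dir}")
        bad = [m for m in self.modes if m not in MODES]
        if bad:
            raise ConfigError(f"unknown normalization mode(s) {bad}; valid: {MODES}")
        if self.protocol not in ("mito_stress_test", "basal_only"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")
        if not 0 < self.center_fraction <= 1:
            raise ConfigError("center_fraction must lie in (0, 1]")


def _subparams(cls, block: dict, label: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in {label!r} block: {sorted(unknown)}")
    return cls(**block)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    for key in ("rate_table", "layout", "out_dir"):
        if key not in data:
            raise ConfigError(f"missing required configuration key {key!r}")
    base = path.parent

    def _p(v):
        q = Path(v)
        return q if q.is_absolute() else base / q

    norm_block = dict(data.get("normalization", {}))
    unknown_norm = set(norm_block) - {"modes", "edge_rel_threshold", "non_respiring_per_cell"}
    if unknown_norm:
        raise ConfigError(f"unknown key(s) in 'normalization' block: {sorted(unknown_norm)}")
    stress_block = dict(data.get("stress_test", {}))
    if set(stress_block) - {"measurements_per_phase"}:
        raise ConfigError("unknown key(s) in 'stress_test' block")
    mito_block = dict(data.get("mito", {}))
    frag_area = mito_block.pop("frag_max_area_um2", 2.0)
    frag_ff = mito_block.pop("frag_min_form_factor", 0.6)
    roi_dist = mito_block.pop("max_roi_distance_um", 10.0)
    nuclei_block = dict(data.get("nuclei", {}))
    gating_block = nuclei_block.pop("gating", {})

    cfg = RunConfig(
        rate_table=_p(data["rate_table"]),
        image_dir=_p(data["image_dir"]) if data.get("image_dir") else None,
        layout=_p(data["layout"]),
        out_dir=_p(data["out_dir"]),
        pixel_size_um=float(data.get("pixel_size_um", 0.65)),
        protocol=data.get("protocol", "mito_stress_test"),
        modes=list(norm_block.get("modes", data.get("modes", ["nuclei", "mitounit"]))),
        center_fraction=float(data.get("center_fraction", 0.5)),
        seed=int(data.get("seed", 0)),
        verbosity=str(data.get("verbosity", "info")),
        nuclei_params=_subparams(SegmentationParams, nuclei_block, "nuclei"),
        gating_params=_subparams(GatingParams, gating_block, "nuclei.gating"),
        mito_params=_subparams(MitoDetectParams, mito_block, "mito"),
        max_roi_distance_um=float(roi_dist),
        frag_max_area_um2=float(frag_area),
        frag_min_form_factor=float(frag_ff),
        non_respiring_per_cell=float(norm_block.get("non_respiring_per_cell", 5000.0)),
        edge_rel_threshold=float(norm_block.get("edge_rel_threshold", 0.2)),
        measurements_per_phase=int(stress_block.get("measurements_per_phase", 3)),
        config_text=text,
    )
    cfg.validate()
    return cfg


@dataclass
class RunBundle:
    summaries: list[WellSummary]
    normalized: dict[str, list]                 # mode -> list[NormalizedRates]
    excluded: dict[str, dict[str, set[str]]]    # mode -> well -> flags
    stress_params: dict[str, object]
    qc: object | None
    outputs: dict[str, Path]
    well_errors: dict[str, str]


def analyze_well_image(image, config: RunConfig) -> WellSummary:
    """Run the full imaging analysis for one well image."""
    seg = segment_nuclei(image, config.nuclei_params)
    total, center = count_center_nuclei(seg.records, image, config.center_fraction)
    gating = classify_cell_cycle(seg.records, config.gating_params)
    rois = build_cell_rois(seg, image, config.max_roi_distance_um)
    mq = quantify_mito_content(
        image, rois, non_respiring_per_cell=config.non_respiring_per_cell
    )
    objects = detect_mito_objects(image, rois, config.mito_params)
    frag = classify_fragmentation(
        objects, config.frag_max_area_um2, config.frag_min_form_factor
    )
    tmre = quantify_membrane_potential(image, rois)
    sox = quantify_mtros(image, rois)
    flags = set(seg.flags) | set(gating.flags) | set(mq.flags) | set(image.flags)
    return WellSummary(
        well_id=image.well_id,
        nuclei_total=total,
        nuclei_center=center,
        mitounit=mq.well_mitounit,
        fragmentation_fraction=frag.fragmentation_fraction,
        phase_fractions=gating.phase_fractions,
        mean_tmre=None if "missing_channel" in tmre.flags else tmre.well_mean,
        mean_mitosox=None if "missing_channel" in sox.flags else sox.well_mean,
        flags=flags,
    )


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the full pipeline and write the report bundle.

    Per-well imaging failures are logged and aggregated; the run fails
    (raises :class:`PipelineError`) only if *no* well could be analysed.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    layout = read_layout(config.layout)
    series = read_rate_table(config.rate_table, layout)
    series = [
        annotate_injections(s, config.protocol, config.measurements_per_phase)
        for s in series
    ]

    summaries: list[WellSummary] = []
    well_errors: dict[str, str] = {}
    if config.image_dir is not None:
        for s in series:
            try:
                image = read_well_tiffs(s.well_id, config.image_dir, config.pixel_size_um)
            except FileNotFoundError:
                logger.warning("well %s: no images found, skipping imaging", s.well_id)
                continue
            try:
                summaries.append(analyze_well_image(image, config))
                logger.info("well %s: imaging analysis complete", s.well_id)
            except Exception as exc:  # aggregate, never abort the plate
                logger.error("well %s: imaging analysis failed: %s", s.well_id, exc)
                well_errors[s.well_id] = str(exc)

    outputs: dict[str, Path] = {}
    if summaries:
        summary_path = out / "well_summaries.csv"
        write_well_summaries(summaries, summary_path)
        outputs["well_summaries"] = summary_path
    elif config.image_dir is not None and well_errors:
        raise PipelineError("imaging failed for every well", well_errors)

    by_well = {s.well_id: s for s in summaries}
    normalized: dict[str, list] = {}
    excluded: dict[str, dict[str, set[str]]] = {}
    for mode in config.modes:
        if mode != "seeded" and not summaries:
            continue
        norms, excl = normalize_plate(series, by_well, layout, mode)
        normalized[mode] = norms
        excluded[mode] = excl
        p = out / f"normalized_{mode}.csv"
        _write_normalized(norms, p)
        outputs[f"normalized_{mode}"] = p

    qc = None
    qc_mode = next((m for m in ("nuclei", "seeded", "mitounit") if normalized.get(m)), None)
    if qc_mode:
        try:
            report = column_profile(normalized[qc_mode], layout)
            qc = edge_effect_qc(report, normalized[qc_mode], config.edge_rel_threshold)
            qc_path = out / "qc_columns.csv"
            _write_qc(report, qc, qc_path)
            outputs["qc_columns"] = qc_path
            heat_path = out / f"heatmap_basal_ocr_{qc_mode}.png"
            plate_heatmap(
                {n.well_id: n.basal_ocr_norm for n in normalized[qc_mode]},
                heat_path,
                title=f"basal OCR per {qc_mode} (normalized)",
            )
            outputs["heatmap"] = heat_path
        except QCError as exc:
            logger.warning("plate QC skipped: %s", exc)

    stress: dict[str, object] = {}
    if config.protocol == "mito_stress_test":
        for s in series:
            stress[s.well_id] = stress_test_parameters(s)
        p = out / "stress_params.csv"
        _write_stress(stress, p)
        outputs["stress_params"] = p

    manifest = {
        "package": "mitoflux",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.config_text.encode()).hexdigest(),
        "protocol": config.protocol,
        "modes": config.modes,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "well_errors": well_errors,
        "excluded": {m: {w: sorted(f) for w, f in e.items()} for m, e in excluded.items()},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = manifest_path

    return RunBundle(
        summaries=summaries,
        normalized=normalized,
        excluded=excluded,
        stress_params=stress,
        qc=qc,
        outputs=outputs,
        well_errors=well_errors,
    )


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _write_normalized(norms, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["well", "mode", "time_min", "ocr_norm", "ecar_norm",
                    "denominator", "flags"])
        for n in norms:
            for t, o, e in n.values:
                w.writerow([n.well_id, n.mode, _fmt(t), _fmt(o), _fmt(e),
                            _fmt(n.denominator), ";".join(sorted(n.flags))])


def _write_qc(report, qc, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["column", "median_norm_ocr", "iqr", "n_wells", "flagged"])
        for p in report.profiles:
            w.writerow([p.column, _fmt(p.median_norm_ocr), _fmt(p.iqr),
                        p.n_wells, int(p.flagged)])


def _write_stress(stress, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["well", "nonmito", "basal_resp", "atp_linked", "proton_leak",
                    "maximal", "spare_capacity", "flags"])
        for well in sorted(stress):
            p = stress[well]
            w.writerow([well, _fmt(p.nonmito), _fmt(p.basal_resp), _fmt(p.atp_linked),
                        _fmt(p.proton_leak), _fmt(p.maximal), _fmt(p.spare_capacity),
                        ";".join(sorted(p.flags))])


# ---------------------------------------------------------------------------
# demo scenarios
# ---------------------------------------------------------------------------

SCENARIOS = (
    "seeding_series",
    "taxol_like",
    "rho0_like",
    "pgc1a_like",
    "antimycin_like",
    "oxidant_like",
)

_INTERIOR_WELLS = [f"{r}{c}" for r in "BCDEFG" for c in range(3, 11)]


def _demo_config(scenario: str, seed: int) -> tuple[SimConfig, dict]:
    """Build the documented synthetic scenario and its expected outcomes."""
    wells: list[WellSpec] = []
    expected: dict = {"scenario": scenario}
    slots = iter(_INTERIOR_WELLS)

    if scenario == "seeding_series":
        densities = [3000, 10000, 20000, 50000]
        for d in densities:
            for _ in range(4):
                wells.append(WellSpec(well_id=next(slots), n_cells=d,
                                      group=f"seed_{d}"))
        expected["densities"] = densities
        expected["raw_ocr_increases_with_density"] = True
        expected["normalized_ocr_constant"] = True
    elif scenario == "taxol_like":
        doses = [0.0, 0.25, 0.5, 0.75, 1.0]
        g2_fracs = [0.2, 0.325, 0.45, 0.575, 0.7]
        for dose, g2 in zip(doses, g2_fracs):
            pf = {"G1": round(0.85 - g2, 6), "S": 0.15,
                  "G2M": round(g2 * 0.8, 6), "gt4N": round(g2 * 0.2, 6)}
            wells.append(
                WellSpec(well_id=next(slots), n_cells=50000, phase_fractions=pf,
                         per_cell_ocr=0.005 * (1.0 + 0.3 * dose),
                         nuclear_radius_scale=1.0 + 0.3 * dose,
                         group=f"taxol_{dose}", treatment=f"taxol {dose}")
            )
        expected["g2m_plus_gt4n_fractions"] = g2_fracs
        expected["g2m_fraction_increases"] = True
        expected["nuclear_size_increases"] = True
    elif scenario == "rho0_like":
        for _ in range(3):
            wells.append(WellSpec(well_id=next(slots), n_cells=20000, group="wt"))
        for _ in range(3):
            wells.append(
                WellSpec(well_id=next(slots), n_cells=20000, per_cell_ocr=1e-4,
                         mito_per_cell=500.0, tmre_factor=0.05, group="rho0",
                         treatment="mtDNA depleted")
            )
        expected["rho0_wells_non_respiring"] = True
    elif scenario == "pgc1a_like":
        for _ in range(4):
            wells.append(WellSpec(well_id=next(slots), n_cells=20000, group="control"))
        for _ in range(4):
            # half the mitochondria, same respiration per mitochondrion
            wells.append(
                WellSpec(well_id=next(slots), n_cells=20000, per_cell_ocr=0.0025,
                         mito_per_cell=1.0e5, group="knockdown")
            )
        expected["nuclei_normalized_ocr_ratio"] = 0.5
        expected["mitounit_normalized_ocr_ratio"] = 1.0
    elif scenario == "antimycin_like":
        frag_probs = [0.1, 0.3, 0.5, 0.7, 0.9]
        for fp in frag_probs:
            for _ in range(5):
                wells.append(
                    WellSpec(well_id=next(slots), n_cells=20000,
                             per_cell_ocr=0.005 * (1.0 - 0.9 * fp),
                             frag_prob=fp, group=f"aa_{fp}")
                )
        expected["frag_probs"] = frag_probs
        expected["fragmentation_fraction_increases"] = True
        expected["ocr_decreases"] = True
    elif scenario == "oxidant_like":
        sox_factors = [1.0, 2.5, 4.0]
        for sf in sox_factors:
            for _ in range(3):
                wells.append(
                    WellSpec(well_id=next(slots), n_cells=20000,
                             per_cell_ocr=0.005 / sf, mitosox_factor=sf,
                             group=f"oxidant_{sf}")
                )
        expected["mitosox_factors"] = sox_factors
        expected["mitosox_up_ocr_down"] = True
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )

    config = SimConfig(
        seed=seed,
        wells=wells,
        image_size_px=(512, 512),
        field_fraction=0.004,
        protocol="mito_stress_test",
        noise=Noise(),
    )
    return config, expected


def make_demo(
    out_dir: str | Path,
    scenario: str,
    seed: int = 0,
    render_images: bool = True,
) -> dict:
    """Generate a named synthetic scenario fixture plus ``expected.json``.

    Scenarios model the platform's canonical experiments: a seeding-
    density series, a G2/M-arrest dose series, mtDNA-depleted cells, a
    mitochondrial-biogenesis knockdown pair, a fragmentation dose series,
    and an oxidant challenge.
    """
    out_dir = Path(out_dir)
    config, expected = _demo_config(scenario, seed)
    manifest = generate_dataset(config, out_dir, render_images=render_images)
    expected_path = out_dir / "expected.json"
    with open(expected_path, "w") as fh:
        json.dump(expected, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["expected"] = expected_path
    manifest["config"] = config
    return manifest
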