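"""Single-command pipeline: from raw stacks to the results CSV and report.

Per image/series the chain is: read → validate → saturated projection
(segmentation substrate) → ROI segmentation → depth-normalized stacked
projection of both signal channels → mask → wavelet background/noise
subtraction → Gaussian smoothing → percentile cut → particle localization
per channel → cross-channel matching → fractional cell count → summary row.
With the classical segmentation backend the whole chain is deterministic:
identical inputs and configuration give byte-identical CSV output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

from . import outputs
from .cell_stats import AnalysisRecord, count_cells, summarize
from .colocalization import match_particles, pearson_pixel_correlation
from .detection import (DEFAULT_GRID, DetectionParams, estimate_plateau,
                        locate_particles, sweep_percentiles)
from .image_io import ImageStack, assign_channels, read_image, validate_stack
from .preprocess import PreprocessParams, gaussian_smooth, wbns
from .preprocess import percentile_cut
from .projection import project_normalized_stacked, project_saturated
from .segmentation import (CellposeBackend, ClassicalBackend, apply_mask,
                           segment_roi)

logger = logging.getLogger("spotcoloc")


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the package's recommended values.

    ``max_displacement`` defaults to the particle diameter when left None.
    """

    inputs: tuple[str, ...] = ()
    series: int | None = None
    channel_a: int = 0
    channel_b: int = 1
    channel_nuclear: int = 2
    model: str = "cyto"
    cell_diameter: float = 48.0
    exclude_nuclei: bool = False
    particle_diameter: int = 9
    minmass: float = 80.0
    separation: float | None = None
    percentile: float = 90.0
    sigma: float = 1.0
    wbns_resolution: float = 3.0
    wbns_noise_levels: int = 1
    max_displacement: float | None = None
    backend: str = "classical"
    out_prefix: str = "spotcoloc"
    out_dir: str = "."
    sweep: bool = False
    grid: tuple[float, ...] = DEFAULT_GRID
    pcc: bool = False

    def __post_init__(self):
        if self.model not in ("cyto", "nuclei"):
            raise ConfigError(f"model must be 'cyto' or 'nuclei', got {self.model!r}")
        if not 0 <= self.percentile < 100:
            raise ConfigError(f"percentile must be in [0, 100), got {self.percentile}")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.cell_diameter <= 0:
            raise ConfigError("cell_diameter must be positive")
        if self.particle_diameter < 3 or self.particle_diameter % 2 == 0:
            raise ConfigError("particle_diameter must be an odd integer >= 3")
        if self.max_displacement is not None and self.max_displacement <= 0:
            raise ConfigError("max_displacement must be positive")
        if self.backend not in ("classical", "cellpose"):
            raise ConfigError(f"unknown backend {self.backend!r}")

    @property
    def r_max(self) -> float:
        # The matching radius defaults to the particle diameter.
        return (self.max_displacement if self.max_displacement is not None
                else float(self.particle_diameter))

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**values)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a plain ``key = value`` config file; CLI overrides win."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {line!r}")
            key, _, raw = line.partition("=")
            values[key.strip()] = _coerce(key.strip(), raw.strip())
        values.update(overrides)
        return cls.from_dict(values)


def _coerce(key: str, raw: str):
    field_types = {f.name: f for f in fields(RunConfig)}
    if key not in field_types:
        raise ConfigError(f"unknown configuration key: {key!r}")
    if key in ("inputs", "grid"):
        parts = [p for p in raw.replace(",", " ").split() if p]
        return tuple(float(p) for p in parts) if key == "grid" else tuple(parts)
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    if raw.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def analyze_stack(stack: ImageStack, config: RunConfig,
                  image_id: str = "", series: int = 0) -> tuple[AnalysisRecord, dict]:
    """Run the analysis chain on one validated stack.

    Returns the per-image :class:`AnalysisRecord` and an artifacts dict with
    the intermediate projections, mask, particle tables, match set and
    (optionally) the percentile sweep — everything the report and tests need.
    """
    stack = validate_stack(stack)
    backend = CellposeBackend() if config.backend == "cellpose" else ClassicalBackend()

    sat_a = project_saturated(stack, "signal_a")
    sat_nuc = project_saturated(stack, "nuclear")
    roi = segment_roi(sat_a, sat_nuc, mode=config.model,
                      cell_diameter=config.cell_diameter, backend=backend,
                      exclude_nuclei=config.exclude_nuclei)
    nuclei_roi = roi if config.model == "nuclei" else segment_roi(
        sat_a, sat_nuc, mode="nuclei", cell_diameter=config.cell_diameter * 0.5,
        backend=backend)

    det_params = DetectionParams(diameter=config.particle_diameter,
                                 minmass=config.minmass,
                                 separation=config.separation)
    pre = PreprocessParams(sigma=config.sigma, percentile=config.percentile,
                           wavelet_resolution_px=config.wbns_resolution,
                           noise_levels=config.wbns_noise_levels)

    tables = {}
    denoised = {}
    masked = {}
    for role in ("signal_a", "signal_b"):
        proj = project_normalized_stacked(stack, role)
        masked[role] = apply_mask(proj, roi)
        smooth = gaussian_smooth(
            wbns(masked[role], pre.wavelet_resolution_px, pre.noise_levels),
            pre.sigma)
        denoised[role] = smooth
        cut, _threshold = percentile_cut(smooth, pre.percentile)
        tables[role] = locate_particles(cut, det_params, channel=role)
        if len(tables[role]) == 0:
            logger.warning("%s: no particles detected in %s", image_id, role)

    matches = match_particles(tables["signal_a"], tables["signal_b"],
                              r_max=config.r_max)
    cells = count_cells(nuclei_roi)
    if cells.total == 0:
        logger.warning("%s: zero cells counted", image_id)

    parameters = {
        "percentile": config.percentile, "sigma": config.sigma,
        "diameter": config.particle_diameter,
        "max_displacement": config.r_max,
    }
    record = summarize(matches, tables["signal_a"], tables["signal_b"], cells,
                       image_id=image_id, series=series, parameters=parameters)
    artifacts = {
        "roi": roi, "nuclei_roi": nuclei_roi, "tables": tables,
        "matches": matches, "masked": masked, "denoised": denoised,
        "cells": cells, "saturated": {"signal_a": sat_a, "nuclear": sat_nuc},
    }
    if config.pcc:
        artifacts["pcc"] = pearson_pixel_correlation(
            masked["signal_a"], masked["signal_b"], roi)
    if config.sweep:
        sweep = sweep_percentiles(denoised["signal_a"], denoised["signal_b"],
                                  det_params, config.r_max, config.grid)
        artifacts["sweep"] = sweep
        artifacts["plateau"] = estimate_plateau(sweep)
    return record, artifacts


def run_pipeline(config: RunConfig, stacks=None) -> tuple[list[AnalysisRecord], int]:
    """Run the full pipeline over configured inputs and write outputs.

    ``stacks`` may supply pre-loaded ``(image_id, series, ImageStack)``
    triples (used by the simulate path); otherwise ``config.inputs`` are
    read from disk.  Per-image failures are logged and skipped.  Returns
    the records and an exit code: 0 all succeeded, 1 partial, 2 all failed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mapping = {"signal_a": config.channel_a, "signal_b": config.channel_b,
               "nuclear": config.channel_nuclear}

    work: list[tuple[str, int, ImageStack | None, str | None]] = []
    if stacks is not None:
        for image_id, series, stack in stacks:
            work.append((image_id, series, stack, None))
    else:
        for inp in config.inputs:
            stem = Path(inp).stem
            if stem.endswith(".ome"):
                stem = stem[:-4]
            work.append((stem, config.series or 0, None, inp))
    if not work:
        raise ConfigError("no inputs given")

    records: list[AnalysisRecord] = []
    failures = 0
    for image_id, series, stack, path in work:
        try:
            if stack is None:
                stack = read_image(path, series=series)
            stack = assign_channels(stack, mapping)
            record, artifacts = analyze_stack(stack, config,
                                              image_id=image_id, series=series)
            records.append(record)
            report_path = out_dir / f"{config.out_prefix}_{image_id}.pdf"
            outputs.render_report(
                {"signal_a": artifacts["masked"]["signal_a"],
                 "signal_b": artifacts["masked"]["signal_b"]},
                artifacts["tables"], artifacts["matches"], report_path,
                diameter=config.particle_diameter, title=image_id)
            if config.sweep and "sweep" in artifacts:
                artifacts["sweep"].to_csv(
                    out_dir / f"{config.out_prefix}_{image_id}_sweep.csv",
                    index=False)
        except Exception:
            failures += 1
            logger.exception("analysis failed for %s (series %s)", image_id, series)

    csv_path = out_dir / f"{config.out_prefix}_results.csv"
    outputs.write_csv(records, csv_path)
    _write_config(config, out_dir / f"{config.out_prefix}_config.txt")
    if records:
        logger.info("analysis complete: output files are available under %s",
                    out_dir)
        print(f"Analysis complete — output files are available: {csv_path}")
    exit_code = 0 if failures == 0 else (1 if records else 2)
    return records, exit_code


def _write_config(config: RunConfig, path: Path) -> None:
    lines = []
    for key, value in asdict(config).items():
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")


def with_overrides(config: RunConfig, **overrides) -> RunConfig:
    return replace(config, **overrides)
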