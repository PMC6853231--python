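"""Run orchestration: configuration, the period loop, logging, reports.

`run_generate` drives the whole chain — load inputs, optionally crop to a
study region, gap-fill baselines, then for each requested period scale,
calibrate, clip, and write `out/<age>kyr/bio<k>.asc` — and appends one
JSON-lines log record per period (age, Ts, scale factor, sea level, and
per-variable clamp/missing counts).  Everything the CLI can do is reachable
from here with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from oscillayers import raster_core
from oscillayers.anomaly_engine import PeriodGenerator
from oscillayers.chronology import TemperatureCurve, load_curve, build_timeline
from oscillayers.interpolation import FillConfig
from oscillayers.raster_core import BioclimStack, ClimateRaster, crop, read_ascii_grid, read_stack
from oscillayers.validation import compare_stacks

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a generation run needs.

    ``periods`` is a START:END:STEP selection in kyr BP (inclusive ends);
    ``bbox`` is an optional (west, south, east, north) study region crop;
    ``variables`` of None means every variable present in both stacks.
    """

    present_dir: str | Path
    lgm_dir: str | Path
    dem_path: str | Path
    curve_path: str | Path
    out_dir: str | Path
    variables: list[str] | None = None
    periods: tuple[float, float, float] = (20, 5400, 10)
    bbox: tuple[float, float, float, float] | None = None
    fill: FillConfig = field(default_factory=FillConfig)
    clamp: bool = True
    connectivity: int = 8
    ts_present_c: float | None = None
    ts_lgm_c: float | None = None
    decimals: int = 4
    log_path: str | Path | None = None

    def resolved(self) -> dict:
        d = asdict(self)
        for k in ("present_dir", "lgm_dir", "dem_path", "curve_path", "out_dir", "log_path"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


def _load_inputs(config: RunConfig) -> tuple[BioclimStack, BioclimStack, ClimateRaster, TemperatureCurve]:
    present = read_stack(config.present_dir, config.variables)
    lgm = read_stack(config.lgm_dir, config.variables)
    dem = read_ascii_grid(config.dem_path, variable="dem")
    curve = load_curve(
        config.curve_path,
        ts_present_c=config.ts_present_c,
        ts_lgm_c=config.ts_lgm_c,
    )
    if config.bbox is not None:
        dem = crop(dem, config.bbox)
        present = BioclimStack(
            dem.spec, {v: crop(present[v], config.bbox) for v in present.variables}
        )
        lgm = BioclimStack(
            dem.spec, {v: crop(lgm[v], config.bbox) for v in lgm.variables}
        )
    return present, lgm, dem, curve


def run_generate(config: RunConfig) -> Path:
    """Generate the clipped per-period stacks; returns the output root."""
    present, lgm, dem, curve = _load_inputs(config)
    start, end, step = config.periods
    ages = build_timeline(start, end, step)
    periods = curve.select(ages)
    if not periods:
        raise ValueError("empty period selection")

    gen = PeriodGenerator(
        present, lgm, dem, curve,
        fill_config=config.fill, clamp=config.clamp,
        connectivity=config.connectivity, variables=config.variables,
    )
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    log_path = Path(config.log_path) if config.log_path else out_root / "run_log.jsonl"
    with log_path.open("w") as log:
        log.write(json.dumps({"config": config.resolved()}) + "\n")
        for period in periods:
            stack = gen.generate(period)
            period_dir = out_root / f"{period.age_kyr:g}kyr"
            raster_core.write_stack(stack, period_dir, decimals=config.decimals)
            log.write(json.dumps(gen.last_period_stats) + "\n")
    logger.info("wrote %d periods x %d variables under %s",
                len(periods), len(gen.variables), out_root)
    return out_root


def run_validate(
    a_dir: str | Path,
    b_dir: str | Path,
    report_path: str | Path,
    variables: list[str] | None = None,
):
    """Compare two layer directories; writes the per-variable CSV report."""
    a = read_stack(a_dir, variables)
    b = read_stack(b_dir, variables)
    return compare_stacks(a, b, report_path=report_path)
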