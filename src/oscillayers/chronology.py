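"""The time axis: temperature/sea-level curve and the anomaly scale factor.

The pipeline walks a lattice of 10-kyr periods (20, 30, ..., 5400 kyr BP for
the full Plio-Pleistocene run: 539 periods).  Each period carries a global
mean surface temperature Ts and a eustatic sea-level stand.  The anomaly
scale factor for a period is

    f(T) = (Ts_T - Ts_LGM) / (Ts_present - Ts_LGM)

so f = 0 at the LGM and f = 1 at the present; interglacials warmer than
today (e.g. the Pliocene) give f > 1 and stadials colder than the LGM give
f < 0.  The anchor constants default to Ts_present = 13.90 °C and
Ts_LGM = 9.46 °C (an LGM 4.44 °C colder than today, per the benthic-isotope
derived global temperature reconstruction the method builds on).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default anchor temperatures, °C: an LGM 4.44 °C colder than the present.
TS_LGM_C = 9.46
TS_PRESENT_C = TS_LGM_C + 4.44

#: The LGM period age in kyr BP; the full lattice runs 20..5400 inclusive.
LGM_AGE_KYR = 20
FULL_START_KYR = 20
FULL_END_KYR = 5400
STEP_KYR = 10


@dataclass(frozen=True)
class TimePeriod:
    """One 10-kyr time bin.

    ``index`` follows the T-convention age = 10 * index (T2 = 20 kyr BP,
    T3 = 30 kyr, ...).  ``sea_level_m`` is eustatic sea level relative to
    present (negative during glacials).
    """

    age_kyr: float
    ts_c: float
    sea_level_m: float

    def __post_init__(self) -> None:
        if not self.age_kyr > 0:
            raise ValueError(f"age must be positive, got {self.age_kyr}")

    @property
    def index(self) -> int:
        return int(round(self.age_kyr / STEP_KYR))


@dataclass
class TemperatureCurve:
    """Ordered time periods plus the present/LGM anchor temperatures."""

    periods: list[TimePeriod]
    ts_present_c: float = TS_PRESENT_C
    ts_lgm_c: float = TS_LGM_C

    def __post_init__(self) -> None:
        self.periods = sorted(self.periods, key=lambda p: p.age_kyr)
        ages = [p.age_kyr for p in self.periods]
        if len(set(ages)) != len(ages):
            dupes = sorted({a for a in ages if ages.count(a) > 1})
            raise ValueError(f"duplicate period ages: {dupes}")
        for p in self.periods:
            if not (np.isfinite(p.ts_c) and np.isfinite(p.sea_level_m)):
                raise ValueError(f"non-finite curve values at age {p.age_kyr}")
        if not self.ts_present_c - self.ts_lgm_c > 0:
            raise ValueError(
                f"ts_present ({self.ts_present_c}) must exceed ts_lgm ({self.ts_lgm_c})"
            )

    def __len__(self) -> int:
        return len(self.periods)

    def __iter__(self):
        return iter(self.periods)

    @property
    def ages(self) -> list[float]:
        return [p.age_kyr for p in self.periods]

    @property
    def min_sea_level_m(self) -> float:
        return min(p.sea_level_m for p in self.periods)

    def period_at(self, age_kyr: float) -> TimePeriod:
        for p in self.periods:
            if abs(p.age_kyr - age_kyr) < 1e-9:
                return p
        raise KeyError(f"no period at age {age_kyr} kyr")

    def select(self, ages: list[float]) -> list[TimePeriod]:
        return [self.period_at(a) for a in ages]


def build_timeline(
    start_kyr: float = FULL_START_KYR,
    end_kyr: float = FULL_END_KYR,
    step_kyr: float = STEP_KYR,
) -> list[float]:
    """Ages ``start, start+step, ..., end`` inclusive.

    The full Plio-Pleistocene lattice build_timeline(20, 5400, 10) has
    exactly 539 periods.
    """
    if step_kyr <= 0:
        raise ValueError(f"step must be positive, got {step_kyr}")
    if start_kyr > end_kyr:
        raise ValueError(f"start {start_kyr} > end {end_kyr}")
    n = int(np.floor((end_kyr - start_kyr) / step_kyr + 1e-9)) + 1
    return [start_kyr + i * step_kyr for i in range(n)]


def scale_factor(ts_t: float, curve: TemperatureCurve) -> float:
    """Anomaly scale factor (Ts_T - Ts_LGM) / (Ts_present - Ts_LGM).

    Exactly 0 at the LGM anchor, 1 at the present anchor; may exceed [0, 1]
    for periods warmer than present or colder than the LGM.
    """
    return (ts_t - curve.ts_lgm_c) / (curve.ts_present_c - curve.ts_lgm_c)


_META_RE = re.compile(r"^#\s*(ts_present_c|ts_lgm_c)\s*[:=]\s*([-+0-9.eE]+)")


def load_curve(
    path: str | Path,
    ts_present_c: float | None = None,
    ts_lgm_c: float | None = None,
    interp: str = "linear",
    ages: list[float] | None = None,
) -> TemperatureCurve:
    """Load a temperature/sea-level curve from a delimited text table.

    The file is a CSV with header ``age_kyr,ts_c,sea_level_m``; optional
    comment lines ``# ts_present_c: 13.90`` / ``# ts_lgm_c: 9.46`` carry the
    anchors (explicit arguments override them; defaults are the standard
    anchors).  If ``ages`` is given, the table is interpolated onto that
    lattice (``interp`` = 'linear' or 'nearest').
    """
    path = Path(path)
    meta: dict[str, float] = {}
    lines = path.read_text().splitlines()
    data_lines = []
    for line in lines:
        m = _META_RE.match(line)
        if m:
            meta[m.group(1)] = float(m.group(2))
        elif not line.lstrip().startswith("#"):
            data_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(data_lines)), float_precision="round_trip")
    required = {"age_kyr", "ts_c", "sea_level_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: curve table must have columns {sorted(required)}")
    if df[list(required)].isna().any().any():
        raise ValueError(f"{path}: non-finite values in curve table")
    df = df.sort_values("age_kyr")
    if df["age_kyr"].duplicated().any():
        dupes = sorted(df.loc[df["age_kyr"].duplicated(), "age_kyr"].unique())
        raise ValueError(f"{path}: duplicate ages {dupes}")

    if ages is not None:
        logger.info("interpolating curve onto %d-age lattice (%s)", len(ages), interp)
        src_age = df["age_kyr"].to_numpy()
        out = {"age_kyr": ages}
        for col in ("ts_c", "sea_level_m"):
            src = df[col].to_numpy()
            if interp == "linear":
                out[col] = np.interp(ages, src_age, src)
            elif interp == "nearest":
                idx = np.abs(np.subtract.outer(ages, src_age)).argmin(axis=1)
                out[col] = src[idx]
            else:
                raise ValueError(f"unknown interp {interp!r}")
        df = pd.DataFrame(out)

    periods = [
        TimePeriod(age_kyr=float(r.age_kyr), ts_c=float(r.ts_c), sea_level_m=float(r.sea_level_m))
        for r in df.itertuples()
    ]
    tp = ts_present_c if ts_present_c is not None else meta.get("ts_present_c", TS_PRESENT_C)
    tl = ts_lgm_c if ts_lgm_c is not None else meta.get("ts_lgm_c", TS_LGM_C)
    return TemperatureCurve(periods, ts_present_c=tp, ts_lgm_c=tl)


def save_curve(curve: TemperatureCurve, path: str | Path) -> None:
    """Write a curve as CSV with anchor metadata comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# ts_present_c: {curve.ts_present_c!r}\n")
        fh.write(f"# ts_lgm_c: {curve.ts_lgm_c!r}\n")
        fh.write("age_kyr,ts_c,sea_level_m\n")
        for p in curve.periods:
            fh.write(f"{p.age_kyr!r},{p.ts_c!r},{p.sea_level_m!r}\n")
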