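"""Sample-table I/O and whole-workflow report assembly.

The on-disk sample format is a plain CSV with header
``sample_id,town,x,y,Cd,Cu,Pb,Zn[,As,Cr,Hg,Ni]``: one row per composite
topsoil sample, concentrations in mg/kg dry soil, empty cell = missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import guidelines as gl
from . import hhra, indices, spatial
from . import stats as town_stats
from .guidelines import CORE_METALS, METALS, GuidelineSet

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("sample_id", "town")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample CSV into the standard survey DataFrame.

    Unparseable concentration cells are warned about and treated as
    missing; duplicated sample ids and missing mandatory columns are hard
    errors.  Row count is preserved.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "town": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")
    metal_cols = [c for c in df.columns if c in METALS]
    if not metal_cols:
        raise ValueError(f"{path}: no metal concentration columns found "
                         f"(recognised: {', '.join(METALS)})")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicated sample_id(s): {', '.join(dup.unique())}")
    for col in list(metal_cols) + [c for c in ("x", "y") if c in df.columns]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        for idx in df.index[bad]:
            logger.warning("%s: unparseable %s value %r in sample %s; "
                           "treated as missing", path, col, df.at[idx, col],
                           df.at[idx, "sample_id"])
        df[col] = coerced
    neg = {c: df.loc[df[c] < 0, "sample_id"].tolist()
           for c in metal_cols if (df[c] < 0).any()}
    if neg:
        raise ValueError(f"{path}: negative concentrations in {neg}")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    """Write a survey DataFrame to the standard CSV format."""
    df.to_csv(path, index=False, float_format="%.6g")


@dataclass
class RunConfig:
    """Configuration of a full-workflow run."""

    samples: pd.DataFrame
    guideline: GuidelineSet = gl.MNS_2019
    metals: Sequence[str] = CORE_METALS
    receptors: Sequence[str] = ("adult", "child")
    toxicity: Mapping[str, hhra.Toxicity] | None = None
    scenarios: Mapping[str, hhra.ExposureScenario] | None = None
    make_maps: bool = False
    map_config: spatial.InterpolatorConfig = field(
        default_factory=spatial.InterpolatorConfig)
    cell_size: float = 10.0
    out_dir: Path | None = None
    seed: int = 0


def full_report(config: RunConfig) -> dict:
    """Run the full assessment workflow on one survey.

    Produces guideline screening, pollution indices, the risk table and
    the between-town comparison; per-town IPI_N rasters when
    ``config.make_maps`` is set.  All tables are derived from the same
    sample universe and the run is deterministic given the input and seed.
    When ``config.out_dir`` is set the tables are also written as CSV
    (rasters as ESRI ASCII grids).

    Returns a dict with keys ``screening``, ``indices``, ``town_indices``,
    ``risk``, ``comparison`` and optionally ``maps``.
    """
    df = config.samples
    if df.empty:
        raise ValueError("empty survey; nothing to report")

    report: dict = {}
    report["screening"] = gl.screen_survey(df, config.guideline)
    per_sample, per_town = indices.survey_ipin(df, config.guideline,
                                               config.metals)
    report["indices"] = per_sample
    report["town_indices"] = per_town
    report["risk"] = hhra.risk_table(df, config.receptors, config.metals,
                                     config.toxicity, config.scenarios)
    if "town" in df.columns and df["town"].nunique() >= 2:
        report["comparison"] = town_stats.compare_all(df, config.metals)

    if config.make_maps:
        maps = {}
        merged = df.merge(per_sample[["sample_id", "ipin"]], on="sample_id")
        for town, sub in merged.groupby("town", sort=False):
            model = spatial.fit_interpolator(sub, "ipin", config.map_config)
            pad = config.map_config.search_radius / 2.0
            spec = spatial.RasterSpec.from_bounds(
                sub["x"].min() - pad, sub["y"].min() - pad,
                sub["x"].max() + pad, sub["y"].max() + pad,
                cell_size=config.cell_size)
            raster, variance = spatial.predict_grid(model, spec)
            maps[town] = {"raster": raster, "variance": variance,
                          "spec": spec}
        report["maps"] = maps

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(report["screening"], out / "screening.csv")
        _write_csv(report["indices"], out / "indices.csv")
        _write_csv(report["town_indices"], out / "town_indices.csv")
        _write_csv(_format_risk(report["risk"]), out / "risk.csv")
        if "comparison" in report:
            _write_csv(report["comparison"], out / "comparison.csv")
        for town, m in report.get("maps", {}).items():
            stem = town.lower().replace(" ", "_")
            spatial.write_esri_ascii(out / f"ipin_{stem}.asc",
                                     m["raster"], m["spec"])
    return report


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _format_risk(risk: pd.DataFrame) -> pd.DataFrame:
    """Risk table with scientific 3-significant-figure formatting."""
    out = risk.copy()
    for col in ("HQ_ing", "HQ_derm", "HI", "CR"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else f"{v:.2E}")
    out["C_mean"] = out["C_mean"].map(lambda v: f"{v:.3g}")
    return out
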