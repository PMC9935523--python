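"""Pollution indices: per-metal PI and the adapted Integrated Nemerow
Pollution Index (IPI_N).

The per-metal pollution index is the ratio of the measured concentration to
the permissible content, PI_i = C_i / T_i.  The integrated index combines
the mean and the maximum of the per-metal indices,

    IPI_N = sqrt((PI_avg^2 + PI_max^2) / 2),

which weights the worst single pollutant equally with the overall average.
Class scale: <= 0.7 safe; (0.7, 1) precaution; [1, 2) slight; [2, 3)
moderate; >= 3 heavy pollution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .guidelines import CORE_METALS, GuidelineSet

logger = logging.getLogger(__name__)

IPIN_CLASSES = ("safe", "precaution", "slight", "moderate", "heavy")


def pollution_index(concentration: float, threshold: float) -> float:
    """Single-metal pollution index PI = C / T (dimensionless).

    ``threshold`` must be strictly positive; ``concentration`` non-negative.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be strictly positive, got {threshold}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration / threshold


def integrated_nemerow(pi_values: Sequence[float] | Iterable[float]
                       ) -> tuple[float, float, float]:
    """Combine per-metal PIs into (pi_avg, pi_max, ipin).

    ipin = sqrt((pi_avg^2 + pi_max^2)/2); requires at least one finite,
    non-negative PI value.
    """
    pis = np.asarray(list(pi_values), dtype=float)
    if pis.size == 0:
        raise ValueError("integrated_nemerow requires at least one PI value")
    if not np.all(np.isfinite(pis)) or np.any(pis < 0):
        raise ValueError("PI values must be finite and non-negative")
    pi_avg = float(pis.mean())
    pi_max = float(pis.max())
    ipin = math.sqrt((pi_avg ** 2 + pi_max ** 2) / 2.0)
    return pi_avg, pi_max, ipin


def classify_ipin(ipin: float) -> str:
    """Map an IPI_N value to its pollution class label.

    Closure: safe = [0, 0.7], precaution = (0.7, 1), slight = [1, 2),
    moderate = [2, 3), heavy = [3, inf).
    """
    if not math.isfinite(ipin) or ipin < 0:
        raise ValueError(f"IPI_N must be finite and non-negative, got {ipin}")
    if ipin <= 0.7:
        return "safe"
    if ipin < 1:
        return "precaution"
    if ipin < 2:
        return "slight"
    if ipin < 3:
        return "moderate"
    return "heavy"


@dataclass(frozen=True)
class PollutionIndexResult:
    """Pollution indices for one sample (or one aggregate label)."""

    sample_id: str
    pi: dict[str, float]
    pi_avg: float
    pi_max: float
    ipin: float
    ipin_class: str
    metals_used: tuple[str, ...]


def sample_ipin(sample, guideline: GuidelineSet,
                metals: Sequence[str] = CORE_METALS) -> PollutionIndexResult:
    """Compute PI per metal and IPI_N for one sample.

    *sample* is a mapping / pandas row with metal-symbol keys (mg/kg).
    Every requested metal must have a threshold in *guideline* and a
    present concentration in the sample.
    """
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    sample = dict(sample)
    sid = str(sample.get("sample_id", "<unnamed>"))
    missing_t = [m for m in metals if m not in guideline]
    if missing_t:
        raise ValueError(
            f"guideline set {guideline.name!r} lacks thresholds for "
            f"{', '.join(missing_t)}")
    pis = {}
    for metal in metals:
        c = sample.get(metal)
        if c is None or pd.isna(c):
            raise ValueError(f"sample {sid!r} lacks a {metal} concentration")
        pis[metal] = pollution_index(float(c), guideline[metal])
    pi_avg, pi_max, ipin = integrated_nemerow(list(pis.values()))
    return PollutionIndexResult(sid, pis, pi_avg, pi_max, ipin,
                                classify_ipin(ipin), tuple(metals))


def survey_ipin(samples: pd.DataFrame, guideline: GuidelineSet,
                metals: Sequence[str] = CORE_METALS
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample pollution indices and a per-town summary for a survey.

    Samples missing any requested metal are skipped with a log entry.

    Returns
    -------
    per_sample : DataFrame
        One row per usable sample: ``sample_id, town, PI_<metal>..., pi_avg,
        pi_max, ipin, ipin_class``.
    per_town : DataFrame
        One row per town with the arithmetic mean of per-sample IPI_N
        (``mean_sample_ipin``) and, separately, the IPI_N evaluated at the
        town's mean concentrations (``ipin_of_means``).  The two differ in
        general because IPI_N is nonlinear; both carry class labels.
    """
    rows = []
    skipped = 0
    for rec in samples.to_dict("records"):
        try:
            res = sample_ipin(rec, guideline, metals)
        except ValueError as exc:
            skipped += 1
            logger.info("skipping sample in survey_ipin: %s", exc)
            continue
        row = {"sample_id": res.sample_id, "town": rec.get("town", "<all>")}
        row.update({f"PI_{m}": res.pi[m] for m in metals})
        row.update({"pi_avg": res.pi_avg, "pi_max": res.pi_max,
                    "ipin": res.ipin, "ipin_class": res.ipin_class})
        rows.append(row)
    if not rows:
        raise ValueError("no sample had all requested metals; nothing to index")
    if skipped:
        logger.info("survey_ipin skipped %d of %d samples with missing metals",
                    skipped, len(samples))
    per_sample = pd.DataFrame(rows)

    town_rows = []
    for town, sub in per_sample.groupby("town", sort=False):
        mean_ipin = float(sub["ipin"].mean())
        if "town" in samples.columns:
            town_samples = samples[samples["town"] == town]
        else:
            town_samples = samples
        # only samples that contributed per-sample indices enter the mean
        town_samples = town_samples[
            town_samples["sample_id"].astype(str).isin(sub["sample_id"])
        ] if "sample_id" in town_samples.columns else town_samples
        _, _, ipin_means = integrated_nemerow(
            [pollution_index(float(town_samples[m].mean()), guideline[m])
             for m in metals])
        town_rows.append({
            "town": town, "n": len(sub),
            "mean_sample_ipin": mean_ipin,
            "mean_sample_ipin_class": classify_ipin(mean_ipin),
            "ipin_of_means": ipin_means,
            "ipin_of_means_class": classify_ipin(ipin_means),
        })
    per_town = pd.DataFrame(town_rows)
    return per_sample, per_town
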