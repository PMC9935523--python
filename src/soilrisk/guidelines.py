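"""Regulatory soil guideline sets and screening of samples against them.

Three guideline sets ship as immutable built-ins:

* ``mns2019`` — permissible metal(loid) contents of the Mongolian national
  soil-quality standard MNS 5850:2019,
* ``dsg-target`` — Dutch Soil Guidelines target values (sustainable soil
  quality),
* ``dsg-intervention`` — Dutch Soil Guidelines intervention values (serious
  contamination requiring remediation).

Screening is strict: a concentration exactly at the threshold is compliant.
Metals without a threshold in the chosen set (or without a measured
concentration) are flagged ``not_evaluable`` rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of recognised metal(loid) symbols.
METALS: tuple[str, ...] = ("Cd", "Cu", "Pb", "Zn", "As", "Cr", "Hg", "Ni")

#: The four metals measured in every sample of the reference survey design.
CORE_METALS: tuple[str, ...] = ("Cd", "Cu", "Pb", "Zn")

GUIDELINE_KINDS = ("permissible", "target", "intervention")

#: DSG classification labels.
DSG_CLASSES = ("below_target", "target_to_intervention", "above_intervention",
               "not_evaluable")


def validate_metal(symbol: str) -> str:
    """Return *symbol* if it is a recognised metal(loid), else raise ValueError."""
    if symbol not in METALS:
        raise ValueError(
            f"unknown metal symbol {symbol!r}; recognised symbols: {', '.join(METALS)}"
        )
    return symbol


@dataclass(frozen=True)
class GuidelineSet:
    """A named map metal -> threshold concentration (mg/kg dry soil).

    Parameters
    ----------
    name
        Short identifier, e.g. ``"mns2019"``.
    kind
        One of ``"permissible"``, ``"target"``, ``"intervention"``.
    thresholds
        Mapping metal symbol -> strictly positive threshold in mg/kg.
    """

    name: str
    kind: str
    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in GUIDELINE_KINDS:
            raise ValueError(
                f"guideline kind must be one of {GUIDELINE_KINDS}, got {self.kind!r}")
        clean: dict[str, float] = {}
        for metal, value in dict(self.thresholds).items():
            validate_metal(metal)
            value = float(value)
            if not value > 0:
                raise ValueError(
                    f"threshold for {metal} in set {self.name!r} must be "
                    f"strictly positive, got {value}")
            if metal in clean:
                raise ValueError(f"metal {metal} appears twice in set {self.name!r}")
            clean[metal] = value
        object.__setattr__(self, "thresholds", MappingProxyType(clean))

    def __getitem__(self, metal: str) -> float:
        return self.thresholds[metal]

    def __contains__(self, metal: str) -> bool:
        return metal in self.thresholds

    def merged_with(self, overrides: Mapping[str, float],
                    name: str | None = None) -> "GuidelineSet":
        """Return a new set with *overrides* merged over these thresholds."""
        merged = dict(self.thresholds)
        merged.update({validate_metal(m): float(v) for m, v in overrides.items()})
        return GuidelineSet(name or f"{self.name}+custom", self.kind, merged)


MNS_2019 = GuidelineSet(
    "mns2019", "permissible",
    {"As": 20, "Cd": 3, "Cr": 150, "Cu": 100, "Hg": 2, "Ni": 150,
     "Pb": 100, "Zn": 300},
)

DSG_TARGET = GuidelineSet(
    "dsg-target", "target",
    {"As": 29, "Cd": 0.8, "Cr": 100, "Cu": 36, "Hg": 0.3, "Ni": 35,
     "Pb": 85, "Zn": 140},
)

DSG_INTERVENTION = GuidelineSet(
    "dsg-intervention", "intervention",
    {"As": 55, "Cd": 12, "Cr": 380, "Cu": 190, "Hg": 10, "Ni": 210,
     "Pb": 530, "Zn": 720},
)

_BUILTINS = {g.name: g for g in (MNS_2019, DSG_TARGET, DSG_INTERVENTION)}


def builtin_guidelines() -> list[GuidelineSet]:
    """Return the three built-in guideline sets (MNS 5850:2019, DSG target,
    DSG intervention)."""
    return [MNS_2019, DSG_TARGET, DSG_INTERVENTION]


def get_guideline(name: str) -> GuidelineSet:
    """Look up a built-in guideline set by name."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"no built-in guideline set {name!r}; available: "
            f"{', '.join(sorted(_BUILTINS))}") from None


@dataclass(frozen=True)
class MetalScreening:
    """Screening outcome for one metal of one sample."""

    metal: str
    concentration: float | None
    threshold: float | None
    ratio: float | None
    exceeded: bool | None
    evaluable: bool


@dataclass(frozen=True)
class ScreeningResult:
    """Per-sample screening against a guideline set."""

    sample_id: str
    guideline: str
    metals: dict[str, MetalScreening] = field(default_factory=dict)

    @property
    def exceedances(self) -> list[str]:
        return [m for m, s in self.metals.items() if s.exceeded]

    @property
    def n_exceeding(self) -> int:
        return len(self.exceedances)


def _conc_of(sample) -> tuple[str, str | None, dict[str, float]]:
    """Normalise a sample record (mapping / pandas row) to (id, town, conc)."""
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    sample = dict(sample)
    sid = str(sample.get("sample_id", "<unnamed>"))
    town = sample.get("town")
    conc = {}
    for metal in METALS:
        if metal in sample and pd.notna(sample[metal]):
            conc[metal] = float(sample[metal])
    return sid, town, conc


def screen_sample(sample, guideline: GuidelineSet) -> ScreeningResult:
    """Screen one soil sample against a guideline set.

    *sample* may be a mapping or :class:`pandas.Series` with a ``sample_id``
    key and metal-symbol keys holding concentrations in mg/kg.  Every metal
    present in either the sample or the set appears in the result; metals
    lacking a threshold or a measured concentration are flagged
    ``not evaluable``.  Exceedance is strict (ratio > 1).
    """
    sid, _, conc = _conc_of(sample)
    for metal, c in conc.items():
        if c < 0:
            raise ValueError(
                f"sample {sid!r} has negative {metal} concentration {c}")
    overlap = set(conc) & set(guideline.thresholds)
    if not overlap:
        raise ValueError(
            f"sample {sid!r} shares no metals with guideline set "
            f"{guideline.name!r}")
    metals: dict[str, MetalScreening] = {}
    for metal in METALS:
        c = conc.get(metal)
        t = guideline.thresholds.get(metal)
        if c is None and t is None:
            continue
        if c is None or t is None:
            metals[metal] = MetalScreening(metal, c, t, None, None, False)
            continue
        ratio = c / t
        metals[metal] = MetalScreening(metal, c, t, ratio, ratio > 1.0, True)
    return ScreeningResult(sid, guideline.name, metals)


def dsg_class(concentration: float | None, metal: str,
              target: GuidelineSet = DSG_TARGET,
              intervention: GuidelineSet = DSG_INTERVENTION) -> str:
    """Classify a concentration on the Dutch target/intervention ladder.

    Returns one of ``below_target``, ``target_to_intervention``,
    ``above_intervention`` or ``not_evaluable`` (missing value or no
    threshold for the metal). Boundaries are strict: a value exactly at a
    threshold stays in the lower class.
    """
    if concentration is None or pd.isna(concentration):
        return "not_evaluable"
    if metal not in target or metal not in intervention:
        return "not_evaluable"
    if concentration > intervention[metal]:
        return "above_intervention"
    if concentration > target[metal]:
        return "target_to_intervention"
    return "below_target"


def screen_survey(samples: pd.DataFrame | Iterable[Mapping],
                  guideline: GuidelineSet,
                  by_town: bool = True) -> pd.DataFrame:
    """Screen a whole survey and summarise exceedances per metal.

    Parameters
    ----------
    samples
        DataFrame (or iterable of mappings) with ``sample_id`` and metal
        columns; a ``town`` column enables the per-town breakdown.
    guideline
        Set to screen against.
    by_town
        If true and towns are present, include one row per (town, metal) in
        addition to the survey-wide rows (town = ``"<all>"``).

    Returns
    -------
    DataFrame with columns ``town, metal, n_evaluated, n_exceeding,
    max_ratio``. Totals over towns partition the survey-wide counts.
    """
    if isinstance(samples, pd.DataFrame):
        records = samples.to_dict("records")
    else:
        records = [dict(s) for s in samples]
    if not records:
        raise ValueError("screen_survey requires a non-empty sample collection")

    rows = []
    for rec in records:
        sid, town, _ = _conc_of(rec)
        res = screen_sample(rec, guideline)
        for metal, s in res.metals.items():
            if not s.evaluable:
                logger.debug("sample %s metal %s not evaluable against %s",
                             sid, metal, guideline.name)
                continue
            rows.append({"town": town if town is not None else "<all>",
                         "metal": metal, "ratio": s.ratio,
                         "exceeded": s.exceeded})
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError(
            f"no sample could be evaluated against guideline set "
            f"{guideline.name!r}")

    def _agg(df: pd.DataFrame, town_label: str) -> pd.DataFrame:
        g = df.groupby("metal", sort=False).agg(
            n_evaluated=("ratio", "size"),
            n_exceeding=("exceeded", "sum"),
            max_ratio=("ratio", "max"),
        ).reset_index()
        g.insert(0, "town", town_label)
        g["n_exceeding"] = g["n_exceeding"].astype(int)
        return g

    parts = [_agg(detail, "<all>")]
    if by_town and detail["town"].nunique() > 1 or (
            by_town and detail["town"].iloc[0] != "<all>"):
        for town, sub in detail.groupby("town", sort=False):
            if town != "<all>":
                parts.append(_agg(sub, town))
    out = pd.concat(parts, ignore_index=True)
    return out
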