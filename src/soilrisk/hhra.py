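"""Human health risk assessment for soil metal(loid) exposure.

Chronic average daily doses (ADD, mg/(kg.day)) are estimated for two
pathways — incidental soil ingestion and dermal contact —

    ADD_ing  = C_soil * IngR * EF * ED / (BW * AT) * 1e-6
    ADD_derm = C_soil * SA * AF * ABS * EF * ED / (BW * AT) * 1e-6

with C_soil in mg/kg, ingestion rate IngR in mg/day, exposure frequency EF
in days/year, exposure duration ED in years, body weight BW in kg,
averaging time AT in days, skin surface area SA in cm^2, adherence factor
AF in mg/cm^2 and dermal absorption fraction ABS.  The 1e-6 factor converts
mg of soil to kg.

Non-carcinogenic risk is expressed as hazard quotients HQ = ADD/RfD per
pathway and their sum, the hazard index HI; HI > 1 flags potential adverse
effects.  Carcinogenic risk CR = ADD_ing(lifetime-averaged) * SF_ing is
computed for metals with an ingestion slope factor (here Cd and Pb); the
regulatory bands are <= 1e-6 virtually safe, 1e-6..1e-4 acceptable,
>= 1e-4 unacceptable.

Built-in receptor scenarios and toxicity values follow the reference urban
soil survey of the three Mongolian coal mining towns; all of them can be
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .guidelines import CORE_METALS, validate_metal

MG_TO_KG = 1e-6

CR_CATEGORIES = ("virtually_safe", "acceptable", "unacceptable")


@dataclass(frozen=True)
class ExposureScenario:
    """Receptor exposure parameter bundle.

    Units: IngR mg/day; EF days/year; ED years; BW kg; AT_nc and AT_ca days;
    SA cm^2; AF mg/cm^2; LT years.  For the built-ins AT_nc = ED * 365 and
    AT_ca = LT * 365.
    """

    receptor: str
    IngR: float
    EF: float
    ED: float
    BW: float
    AT_nc: float
    SA: float
    AF: float
    LT: float = 70.0

    def __post_init__(self) -> None:
        for name in ("IngR", "EF", "ED", "BW", "AT_nc", "SA", "AF", "LT"):
            if not getattr(self, name) > 0:
                raise ValueError(
                    f"scenario {self.receptor!r}: {name} must be strictly "
                    f"positive, got {getattr(self, name)}")

    @property
    def AT_ca(self) -> float:
        """Carcinogenic averaging time: lifetime in days."""
        return self.LT * 365.0

    def with_overrides(self, **kwargs) -> "ExposureScenario":
        return replace(self, **kwargs)


ADULT = ExposureScenario("adult", IngR=100, EF=350, ED=24, BW=65.0,
                         AT_nc=8760, SA=4350, AF=0.07, LT=70)
CHILD = ExposureScenario("child", IngR=200, EF=350, ED=6, BW=15.9,
                         AT_nc=2190, SA=1600, AF=0.20, LT=70)

BUILTIN_SCENARIOS: dict[str, ExposureScenario] = {"adult": ADULT, "child": CHILD}


@dataclass(frozen=True)
class Toxicity:
    """Toxicity values for one metal.

    RfD in mg/(kg.day); ABS dimensionless in (0, 1]; SF_ing in
    (mg/(kg.day))^-1, present only for carcinogens.
    """

    rfd_ing: float
    rfd_derm: float
    abs_derm: float
    sf_ing: float | None = None

    def __post_init__(self) -> None:
        if not self.rfd_ing > 0 or not self.rfd_derm > 0:
            raise ValueError("reference doses must be strictly positive")
        if not 0 < self.abs_derm <= 1:
            raise ValueError(f"ABS must lie in (0, 1], got {self.abs_derm}")
        if self.sf_ing is not None and not self.sf_ing > 0:
            raise ValueError("slope factor must be strictly positive if present")


#: Ingestion/dermal reference doses, dermal absorption and ingestion slope
#: factors for the four core metals.
DEFAULT_TOXICITY: dict[str, Toxicity] = {
    "Cd": Toxicity(1.00e-03, 1.00e-05, 0.001, 1.50e+01),
    "Cu": Toxicity(4.00e-02, 1.20e-02, 0.001, None),
    "Pb": Toxicity(3.50e-03, 5.25e-04, 0.001, 8.50e-03),
    "Zn": Toxicity(3.00e-01, 6.00e-02, 0.001, None),
}


def toxicity_profile(overrides: Mapping[str, Toxicity] | None = None
                     ) -> dict[str, Toxicity]:
    """The built-in toxicity table, optionally with per-metal overrides."""
    profile = dict(DEFAULT_TOXICITY)
    if overrides:
        for metal, tox in overrides.items():
            profile[validate_metal(metal)] = tox
    return profile


def add_ingestion(c_soil: float, scenario: ExposureScenario,
                  averaging: str = "nc") -> float:
    """Average daily dose via incidental soil ingestion, mg/(kg.day).

    ``averaging``: ``"nc"`` uses AT_nc (non-carcinogenic), ``"ca"`` the
    lifetime averaging time AT_ca.
    """
    if c_soil < 0:
        raise ValueError(f"soil concentration must be non-negative, got {c_soil}")
    at = _averaging_time(scenario, averaging)
    return (c_soil * scenario.IngR * scenario.EF * scenario.ED
            / (scenario.BW * at)) * MG_TO_KG


def add_dermal(c_soil: float, scenario: ExposureScenario, abs_derm: float,
               averaging: str = "nc") -> float:
    """Average daily dose via dermal contact with soil, mg/(kg.day)."""
    if c_soil < 0:
        raise ValueError(f"soil concentration must be non-negative, got {c_soil}")
    if not 0 < abs_derm <= 1:
        raise ValueError(f"ABS must lie in (0, 1], got {abs_derm}")
    at = _averaging_time(scenario, averaging)
    return (c_soil * scenario.SA * scenario.AF * abs_derm * scenario.EF
            * scenario.ED / (scenario.BW * at)) * MG_TO_KG


def _averaging_time(scenario: ExposureScenario, averaging: str) -> float:
    if averaging == "nc":
        return scenario.AT_nc
    if averaging == "ca":
        return scenario.AT_ca
    raise ValueError(f"averaging must be 'nc' or 'ca', got {averaging!r}")


def hazard_index(c_soil: float, metal: str, scenario: ExposureScenario,
                 tox: Mapping[str, Toxicity] | None = None
                 ) -> tuple[float, float, float]:
    """(HQ_ing, HQ_derm, HI) for one metal, receptor and soil concentration.

    HQ = ADD(nc)/RfD per pathway; HI is their sum over the two pathways.
    """
    tox = DEFAULT_TOXICITY if tox is None else tox
    validate_metal(metal)
    if metal not in tox:
        raise ValueError(f"no toxicity values for metal {metal}")
    t = tox[metal]
    hq_ing = add_ingestion(c_soil, scenario, "nc") / t.rfd_ing
    hq_derm = add_dermal(c_soil, scenario, t.abs_derm, "nc") / t.rfd_derm
    return hq_ing, hq_derm, hq_ing + hq_derm


def carcinogenic_risk(c_soil: float, metal: str, scenario: ExposureScenario,
                      tox: Mapping[str, Toxicity] | None = None) -> float:
    """Incremental lifetime cancer risk CR = ADD_ing(ca) * SF_ing.

    Only the ingestion pathway carries a slope factor; metals without one
    (Cu, Zn) raise a ValueError rather than reporting a spurious zero.
    """
    tox = DEFAULT_TOXICITY if tox is None else tox
    validate_metal(metal)
    t = tox.get(metal)
    if t is None or t.sf_ing is None:
        raise ValueError(
            f"{metal} is not a carcinogen in this toxicity profile "
            f"(no ingestion slope factor)")
    return add_ingestion(c_soil, scenario, "ca") * t.sf_ing


def cr_category(cr: float) -> str:
    """Regulatory category of a carcinogenic risk value."""
    if cr < 0:
        raise ValueError(f"CR must be non-negative, got {cr}")
    if cr <= 1e-6:
        return "virtually_safe"
    if cr < 1e-4:
        return "acceptable"
    return "unacceptable"


def risk_table(samples: pd.DataFrame,
               receptors: Sequence[str] = ("adult", "child"),
               metals: Sequence[str] = CORE_METALS,
               tox: Mapping[str, Toxicity] | None = None,
               scenarios: Mapping[str, ExposureScenario] | None = None,
               by: str = "town") -> pd.DataFrame:
    """Average risk per group x receptor x metal, in the layout of the
    reference survey's summary table.

    Parameters
    ----------
    samples
        DataFrame with metal columns (mg/kg).  If a *by* column is present
        the table is grouped by it; otherwise a single ``<all>`` group is
        reported.  Pre-aggregated town means (one row per town) are equally
        valid input: every risk quantity is linear in concentration, so the
        risk of the mean equals the mean of per-sample risks.
    receptors
        Receptor names resolved against *scenarios* (default: built-in
        adult and child).

    Returns
    -------
    Tidy DataFrame with one row per (group, receptor, metal) and columns
    ``HQ_ing, HQ_derm, HI, CR, CR_category`` (CR columns NaN/None where the
    metal has no slope factor).
    """
    tox = toxicity_profile() if tox is None else dict(tox)
    scen_map = dict(BUILTIN_SCENARIOS)
    if scenarios:
        scen_map.update(scenarios)
    missing = [r for r in receptors if r not in scen_map]
    if missing:
        raise ValueError(f"unknown receptor(s): {', '.join(missing)}")
    if samples.empty:
        raise ValueError("risk_table requires a non-empty sample table")

    if by in samples.columns:
        groups: Iterable[tuple[str, pd.DataFrame]] = samples.groupby(
            by, sort=False)
    else:
        groups = [("<all>", samples)]

    rows = []
    for label, sub in groups:
        for receptor in receptors:
            scenario = scen_map[receptor]
            for metal in metals:
                if metal not in sub.columns:
                    raise ValueError(
                        f"samples lack a {metal} concentration column")
                c_mean = float(sub[metal].mean())
                hq_ing, hq_derm, hi = hazard_index(c_mean, metal, scenario, tox)
                t = tox.get(metal)
                if t is not None and t.sf_ing is not None:
                    cr = carcinogenic_risk(c_mean, metal, scenario, tox)
                    cat = cr_category(cr)
                else:
                    cr, cat = np.nan, None
                rows.append({by: label, "receptor": receptor, "metal": metal,
                             "C_mean": c_mean, "HQ_ing": hq_ing,
                             "HQ_derm": hq_derm, "HI": hi, "CR": cr,
                             "CR_category": cat, "HI_above_1": hi > 1})
    return pd.DataFrame(rows)
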