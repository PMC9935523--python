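"""Synthetic soil-survey generator emulating the reference study design.

The reference survey sampled the topsoil of three Mongolian coal mining
towns — Baganuur (48 samples), Nalaikh (50) and Sharyn Gol (44) — on
regular hexagonal networks, 142 composite samples in total.  Concentrations
of Cd, Cu, Pb and Zn are right-skewed with town means around
0.87/13.6/29.6/51.7 mg/kg (Baganuur), 1.21/13.8/36.4/73.7 (Nalaikh) and
1.46/22.1/69.0/87.6 (Sharyn Gol), exceed the Mongolian permissible values
only rarely (once in Cu at Baganuur, three times in Pb at Sharyn Gol, the
worst Pb value also above the Dutch intervention value), and cluster
spatially in the original town centres, ger areas, and next to the Sharyn
Gol mining waste heaps.

Concentrations are modelled as i.i.d. lognormal per metal with parameters
solved so the arithmetic mean hits the target and the coefficient of
variation matches the spec, then multiplied by distance-decaying hotspot
enrichment.  ``fixture_towns`` additionally post-conditions each town so
the arithmetic means equal the targets exactly and the guideline
exceedances are exactly the ones listed above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon, box
from shapely import points as shapely_points

from .guidelines import CORE_METALS, MNS_2019, validate_metal

#: Town mean concentrations (mg/kg) of the reference survey.
TOWN_MEANS: dict[str, dict[str, float]] = {
    "Baganuur": {"Cd": 0.87, "Cu": 13.6, "Pb": 29.6, "Zn": 51.7},
    "Nalaikh": {"Cd": 1.21, "Cu": 13.8, "Pb": 36.4, "Zn": 73.7},
    "Sharyn Gol": {"Cd": 1.46, "Cu": 22.1, "Pb": 69.0, "Zn": 87.6},
}

#: Sample counts per town in the reference design.
TOWN_N: dict[str, int] = {"Baganuur": 48, "Nalaikh": 50, "Sharyn Gol": 44}

#: Default geometric coefficient of variation of the lognormal model.
DEFAULT_CV = 0.5


@dataclass(frozen=True)
class Hotspot:
    """A circular enrichment feature: values inside ``radius`` of the centre
    are multiplied by 1 + (enrichment-1)*(1 - d/radius) per metal."""

    x: float
    y: float
    radius: float
    enrichment: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("hotspot radius must be strictly positive")
        for metal, e in self.enrichment.items():
            validate_metal(metal)
            if e < 1:
                raise ValueError(
                    f"hotspot enrichment for {metal} must be >= 1, got {e}")

    def factor(self, x: np.ndarray, y: np.ndarray, metal: str) -> np.ndarray:
        e = float(self.enrichment.get(metal, 1.0))
        d = np.hypot(np.asarray(x) - self.x, np.asarray(y) - self.y)
        return 1.0 + (e - 1.0) * np.clip(1.0 - d / self.radius, 0.0, None)


@dataclass(frozen=True)
class TownSpec:
    """Design of one synthetic town survey."""

    name: str
    region: Polygon | tuple[float, float, float, float]
    n_samples: int
    means: Mapping[str, float]
    cv: float | Mapping[str, float] = DEFAULT_CV
    hotspots: Sequence[Hotspot] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for metal, m in self.means.items():
            validate_metal(metal)
            if not m > 0:
                raise ValueError(f"target mean for {metal} must be > 0, got {m}")

    def polygon(self) -> Polygon:
        if isinstance(self.region, Polygon):
            return self.region
        return box(*self.region)

    def cv_for(self, metal: str) -> float:
        if isinstance(self.cv, Mapping):
            return float(self.cv.get(metal, DEFAULT_CV))
        return float(self.cv)


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with given arithmetic mean and CV.

    sigma = sqrt(ln(1 + cv^2)); mu = ln(mean) - sigma^2/2, so that
    E[X] = mean exactly.  cv = 0 degenerates to a point mass at ``mean``.
    """
    if not mean > 0:
        raise ValueError(f"mean must be strictly positive, got {mean}")
    if cv < 0:
        raise ValueError(f"CV must be non-negative, got {cv}")
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, sigma


def hex_grid_points(region: Polygon | tuple[float, float, float, float],
                    n_target: int) -> np.ndarray:
    """Hexagonal (triangular-lattice) sampling points clipped to *region*.

    The lattice pitch is found by bisection so that the clipped point count
    equals ``n_target`` exactly; when a pitch yields a few extra points the
    ones nearest the region boundary are dropped, ties broken by (y, x).

    Returns an (n_target, 2) array of (x, y), sorted by (y, x).
    """
    poly = region if isinstance(region, Polygon) else box(*region)
    if poly.area <= 0:
        raise ValueError("region must have positive area")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target == 1:
        c = poly.centroid
        return np.array([[c.x, c.y]])

    if n_target > 200_000:
        raise ValueError(
            f"n_target={n_target} exceeds the achievable point density "
            f"for this region")
    minx, miny, maxx, maxy = poly.bounds
    diameter = math.hypot(maxx - minx, maxy - miny)
    # triangular lattice density is 2/(sqrt(3) pitch^2) points per unit area
    pitch_ideal = math.sqrt(2.0 * poly.area / (math.sqrt(3.0) * n_target))
    pitch_min = pitch_ideal / 8.0

    cx, cy = poly.centroid.x, poly.centroid.y

    def lattice(pitch: float) -> np.ndarray:
        dy = pitch * math.sqrt(3.0) / 2.0
        j = np.arange(math.floor((miny - cy) / dy) - 1,
                      math.ceil((maxy - cy) / dy) + 2)
        i = np.arange(math.floor((minx - cx) / pitch) - 2,
                      math.ceil((maxx - cx) / pitch) + 2)
        jj, ii = np.meshgrid(j, i, indexing="ij")
        xs = cx + ii * pitch + (jj % 2) * (pitch / 2.0)
        ys = cy + jj * dy
        arr = np.column_stack([xs.ravel(), ys.ravel()])
        inbox = ((arr[:, 0] >= minx - pitch) & (arr[:, 0] <= maxx + pitch)
                 & (arr[:, 1] >= miny - dy) & (arr[:, 1] <= maxy + dy))
        arr = arr[inbox]
        inside = poly.covers(shapely_points(arr))
        return arr[inside]

    def count(pitch: float) -> int:
        return len(lattice(pitch))

    if count(pitch_min) < n_target:
        raise ValueError(
            f"n_target={n_target} exceeds the achievable point density "
            f"for this region")

    # count is (near-)monotone decreasing in pitch: bisect for the largest
    # pitch still giving >= n_target points
    lo, hi = pitch_min, diameter
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if count(mid) >= n_target:
            lo = mid
        else:
            hi = mid
    pts = lattice(lo)

    extra = len(pts) - n_target
    if extra > 0:
        boundary = poly.boundary
        dist = np.array([boundary.distance(Point(p)) for p in pts])
        order = np.lexsort((pts[:, 0], pts[:, 1], dist))
        keep = np.ones(len(pts), dtype=bool)
        keep[order[:extra]] = False
        pts = pts[keep]
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]


def simulate_survey(spec: TownSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate one town survey from its design spec.

    Points are laid on a hexagonal network; each metal's concentrations are
    i.i.d. lognormal with arithmetic mean ``spec.means[metal]`` and CV
    ``spec.cv``, multiplied by the hotspot enrichment factors.  Fully
    reproducible from the seed (``spec.seed`` unless overridden).

    Returns a DataFrame ``sample_id, town, x, y, <metal columns>``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pts = hex_grid_points(spec.polygon(), spec.n_samples)
    x, y = pts[:, 0], pts[:, 1]
    data = {
        "sample_id": [f"{spec.name.replace(' ', '')}-{i + 1:03d}"
                      for i in range(spec.n_samples)],
        "town": spec.name, "x": x, "y": y,
    }
    for metal, mean in spec.means.items():
        cv = spec.cv_for(metal)
        if cv == 0:
            values = np.full(spec.n_samples, float(mean))
        else:
            mu, sigma = lognormal_params(float(mean), cv)
            values = rng.lognormal(mu, sigma, size=spec.n_samples)
        for h in spec.hotspots:
            values = values * h.factor(x, y, metal)
        data[metal] = values
    return pd.DataFrame(data)


def _cap_and_rescale(values: np.ndarray, target_mean: float, cap: float,
                     exceed_values: Sequence[float] = ()) -> np.ndarray:
    """Condition a positive sample so its mean is exactly *target_mean*,
    no value other than the injected ``exceed_values`` exceeds *cap*, and
    the injected values replace the largest draws.

    The non-injected values are multiplied by a common factor c and capped
    at *cap*; c solves mean(min(c*v, cap)) = required mean by bisection
    (monotone in c), so the overall mean is exact while relative spatial
    structure below the cap is preserved.
    """
    values = np.asarray(values, dtype=float).copy()
    n = len(values)
    k = len(exceed_values)
    if k >= n:
        raise ValueError("cannot inject as many exceedances as samples")
    out = values.copy()
    if k:
        top = np.argsort(values)[-k:]
        out[top] = np.sort(np.asarray(exceed_values, dtype=float))
        rest_idx = np.setdiff1d(np.arange(n), top)
    else:
        rest_idx = np.arange(n)
    rest = values[rest_idx]
    need = target_mean * n - (out.sum() - rest.sum())
    mean_rest = need / len(rest)
    if not 0 < mean_rest < cap:
        raise ValueError(
            f"required residual mean {mean_rest:.4g} not attainable below "
            f"cap {cap:.4g}")

    def f(c: float) -> float:
        return float(np.minimum(c * rest, cap).mean()) - mean_rest

    c_hi = cap / rest.min()  # all values capped -> mean == cap > mean_rest
    c = brentq(f, 0.0, c_hi, xtol=1e-15, rtol=1e-15)
    out[rest_idx] = np.minimum(c * rest, cap)
    return out


def _default_town_specs(seed: int) -> list[TownSpec]:
    """The three-town design: separated rectangular town footprints with a
    town-centre hotspot (Baganuur, Sharyn Gol), a ger-area hotspot
    (Nalaikh) and an eastern mining-waste gradient (Sharyn Gol)."""
    enrich2 = {m: 2.0 for m in CORE_METALS}
    return [
        TownSpec(
            "Baganuur", (0.0, 0.0, 4000.0, 3000.0), TOWN_N["Baganuur"],
            TOWN_MEANS["Baganuur"],
            hotspots=(Hotspot(2000.0, 1500.0, 600.0, enrich2),),
            seed=seed,
        ),
        TownSpec(
            "Nalaikh", (20000.0, 0.0, 23500.0, 3000.0), TOWN_N["Nalaikh"],
            TOWN_MEANS["Nalaikh"],
            hotspots=(Hotspot(20700.0, 2300.0, 700.0, enrich2),),
            seed=seed + 1,
        ),
        TownSpec(
            "Sharyn Gol", (40000.0, 0.0, 43000.0, 3500.0), TOWN_N["Sharyn Gol"],
            TOWN_MEANS["Sharyn Gol"],
            hotspots=(
                Hotspot(41500.0, 1750.0, 500.0, enrich2),
                Hotspot(43000.0, 1750.0, 1200.0,
                        {"Cd": 1.9, "Cu": 2.0, "Pb": 2.0, "Zn": 2.0}),
            ),
            seed=seed + 2,
        ),
    ]


def fixture_towns(seed: int = 20230216) -> pd.DataFrame:
    """The built-in deterministic three-town survey bundle (142 samples).

    Each town is simulated on its hexagonal network and then conditioned in
    "mean-exact" mode: per metal, concentrations are rescaled so the town's
    arithmetic mean equals the reference mean exactly, while staying
    strictly below the Mongolian permissible value everywhere except the
    injected exceedances — one Cu value in Baganuur and three Pb values in
    Sharyn Gol (the largest of which also exceeds the Dutch intervention
    value of 530 mg/kg).

    Returns a single DataFrame of all 142 samples.
    """
    frames = []
    exceed_plan = {
        ("Baganuur", "Cu"): (115.0,),          # MNS Cu = 100
        ("Sharyn Gol", "Pb"): (105.0, 118.0, 540.0),  # MNS Pb = 100, DSG int 530
    }
    for spec in _default_town_specs(seed):
        df = simulate_survey(spec)
        for metal, target in spec.means.items():
            cap = 0.95 * MNS_2019[metal]
            exceed = exceed_plan.get((spec.name, metal), ())
            df[metal] = _cap_and_rescale(df[metal].to_numpy(), float(target),
                                         cap, exceed)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
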