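"""Synthetic survey world with known ground truth.

Emulates the ingredients of a decadal citizen-science niche-modelling
study: smooth climate grids that drift slightly between decades while
staying analogous, species whose true suitability is a Gaussian function
of climate with range archetypes (widespread/narrow x common/rare),
and fixed survey circles revisited yearly with detection error and rare
misidentifications. Every stochastic step draws from a stream keyed by
(seed, op-name, entity-id), so adding a species never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import stream
from .climate import ClimateStack
from .gridio import GridGeometry

__all__ = [
    "LandscapeConfig",
    "TrueSpecies",
    "SurveyWorld",
    "GenerationError",
    "generate_climate",
    "generate_species",
    "place_circles",
    "simulate_surveys",
    "build_world",
    "DECADE_LABELS",
]

DECADE_LABELS = ("1950s", "1960s", "1970s", "1980s", "1990s")

# archetype -> (prevalence, detectability); "rare" = 0.3 x common occupancy
# density and 0.5 x common detectability
ARCHETYPE_DEFAULTS = {
    "WC": (0.25, 0.8),
    "WR": (0.25 * 0.3, 0.8 * 0.5),
    "NEC": (0.035, 0.8),
    "NER": (0.035 * 0.3, 0.8 * 0.5),
}
TREND_FACTORS = {"stable": 1.0, "increasing": 1.2, "decreasing": 1.0 / 1.2}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape and survey design."""

    grid_rows: int = 120
    grid_cols: int = 120
    n_decades: int = 5
    n_climate_vars: int = 4
    spatial_corr_length: float = 6.0
    inter_var_corr: float = 0.0
    corr_pairs: tuple[tuple[int, int], ...] = ()
    decadal_drift_sd: float = 0.05
    rng_seed: int = 0
    circle_block: int = 5           # one candidate circle per block x block
    circle_active_fraction: float = 0.8
    circle_radius: float = 2.0      # cells; ~15-mile diameter at ~5 km cells
    start_year: int = 1950
    narrow_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_decades < 1:
            raise ValueError("need at least one decade")
        if self.n_climate_vars < 1:
            raise ValueError("need at least one climate variable")
        if not -1.0 <= self.inter_var_corr <= 1.0:
            raise ValueError("inter_var_corr must lie in [-1, 1]")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_rows, self.grid_cols)

    @property
    def decades(self) -> list[str]:
        return [f"{self.start_year + 10 * d}s" for d in range(self.n_decades)]

    def decade_years(self, d: int) -> list[int]:
        y0 = self.start_year + 10 * d
        return list(range(y0, y0 + 10))


@dataclass
class TrueSpecies:
    """A species with a known climate niche and trait labels."""

    species_id: str
    range_class: str                 # WC / WR / NEC / NER
    migratory: str = "R"             # N / T / R
    habitat: str = "G"               # S/W/G/E/D/B/O
    trend: str = "stable"
    mass_cat: int = 1
    niche_center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    niche_breadth: np.ndarray = field(default_factory=lambda: np.zeros(0))
    prevalence: float = 0.1
    detectability: float = 0.8
    suitability: dict[str, np.ndarray] = field(default_factory=dict)
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)

    def occupied_fraction(self, decade: str) -> float:
        occ = self.occupancy[decade]
        return float(occ.sum()) / occ.size


@dataclass
class SurveyWorld:
    """Climate, species truth, circles and detection records together."""

    config: LandscapeConfig
    stacks: list[ClimateStack]
    species: list[TrueSpecies]
    circles: pd.DataFrame            # circle_id, row, col, radius
    records: pd.DataFrame            # circle_id, species_id, year, detected

    @property
    def decades(self) -> list[str]:
        return [s.decade for s in self.stacks]

    def effort(self) -> dict[str, set[int]]:
        """Circle id -> set of surveyed years (all active-circle years)."""
        years = [y for d in range(self.config.n_decades)
                 for y in self.config.decade_years(d)]
        return {cid: set(years) for cid in self.circles["circle_id"]}


def generate_climate(config: LandscapeConfig) -> list[ClimateStack]:
    """Smoothed Gaussian-random-field climate grids, one stack per decade.

    Each variable's base field is white noise smoothed with a Gaussian
    kernel of scale ``spatial_corr_length`` and standardized; designated
    variable pairs are mixed to the target inter-variable correlation.
    Decades share the base field and differ by a cumulative random mean
    shift with per-decade increments N(0, decadal_drift_sd). The shift
    is tapered toward zero at the variable's range limits, so every
    decade's values stay inside the base range cell-for-cell: the
    decades are climatically analogous by construction (no novel
    climates, no clamping) while interior cells drift by roughly the
    drawn increment.
    """
    geom = config.geometry
    k = config.n_climate_vars

    def smooth_field(rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((geom.rows, geom.cols))
        f = ndimage.gaussian_filter(z, sigma=config.spatial_corr_length,
                                    mode="wrap")
        sd = f.std()
        return (f - f.mean()) / (sd if sd > 0 else 1.0)

    base = [smooth_field(stream(config.rng_seed, "climate-base", j))
            for j in range(k)]
    rho = config.inter_var_corr
    for (i, j) in config.corr_pairs:
        base[j] = rho * base[i] + np.sqrt(max(0.0, 1.0 - rho ** 2)) * base[j]
        sd = base[j].std()
        base[j] = (base[j] - base[j].mean()) / (sd if sd > 0 else 1.0)

    drift_rng = stream(config.rng_seed, "climate-drift")
    shifts = np.zeros((config.n_decades, k))
    for d in range(1, config.n_decades):
        shifts[d] = shifts[d - 1] + drift_rng.normal(
            0.0, config.decadal_drift_sd, size=k)

    def shifted(b: np.ndarray, delta: float) -> np.ndarray:
        if delta == 0.0:
            return b.copy()
        lo, hi = b.min(), b.max()
        mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
        taper = 1.0 - ((b - mid) / half) ** 2   # 0 at range limits, 1 at mid
        return b + delta * taper

    stacks = []
    for d, label in enumerate(config.decades):
        grids = {f"v{j + 1}": shifted(base[j], shifts[d, j])
                 for j in range(k)}
        stacks.append(ClimateStack(decade=label, grids=grids, geometry=geom))
    return stacks


def _gaussian_suitability(stack: ClimateStack, center: np.ndarray,
                          breadth: np.ndarray) -> np.ndarray:
    vals = stack.as_array()          # (k, rows, cols)
    z = (vals - center[:, None, None]) / breadth[:, None, None]
    return np.exp(-0.5 * (z ** 2).sum(axis=0))


def generate_species(config: LandscapeConfig,
                     stacks: list[ClimateStack],
                     species_id: str,
                     range_class: str,
                     migratory: str = "R",
                     habitat: str = "G",
                     trend: str = "stable",
                     mass_cat: int = 1,
                     prevalence: float | None = None,
                     detectability: float | None = None,
                     niche_breadth_scale: float = 0.8) -> TrueSpecies:
    """A species with a Gaussian climate niche and archetype-consistent
    occupancy.

    True suitability in each decade is a Gaussian kernel of the decade's
    climate around a randomly placed niche center. Occupancy is the top-m
    suitable cells among those passing a fixed per-cell rarity mask, with
    m = round(prevalence * n_cells * trend_factor**decade); counts
    therefore hit the prevalence target exactly and trends are monotone.
    """
    if range_class not in ARCHETYPE_DEFAULTS:
        raise ValueError(f"unknown range class {range_class!r}")
    prev_default, det_default = ARCHETYPE_DEFAULTS[range_class]
    prevalence = prev_default if prevalence is None else prevalence
    detectability = det_default if detectability is None else detectability
    if not 0.0 < detectability <= 1.0:
        raise ValueError("detectability must be in (0, 1]")

    rng = stream(config.rng_seed, "species", species_id)
    geom = config.geometry
    n_cells = geom.n_cells
    k = config.n_climate_vars

    # anchor the niche at an existing cell's climate so it is occupiable
    anchor = (rng.integers(geom.rows), rng.integers(geom.cols))
    center = stacks[0].as_array()[:, anchor[0], anchor[1]].copy()
    breadth = np.full(k, niche_breadth_scale)
    if range_class.startswith("NE"):
        breadth *= 0.5               # narrow endemics: tighter niche

    # fixed per-cell jitter: deterministic tie-break that is stable
    # across decades, so zero-drift worlds have identical occupancy
    jitter = rng.random(n_cells) * 1e-9

    factor = TREND_FACTORS[trend]
    sp = TrueSpecies(species_id=species_id, range_class=range_class,
                     migratory=migratory, habitat=habitat, trend=trend,
                     mass_cat=mass_cat, niche_center=center,
                     niche_breadth=breadth, prevalence=prevalence,
                     detectability=detectability)
    for d, stack in enumerate(stacks):
        suit = _gaussian_suitability(stack, center, breadth)
        m = int(round(prevalence * n_cells * factor ** d))
        m = min(m, n_cells)
        if m < 4:
            raise GenerationError(
                f"species {species_id!r}: prevalence {prevalence} yields "
                f"{m} occupied cells in decade {stack.decade} (< 4)")
        order = np.argsort(-(suit.ravel() + jitter), kind="stable")
        occ = np.zeros(n_cells, dtype=bool)
        occ[order[:m]] = True
        sp.suitability[stack.decade] = suit
        sp.occupancy[stack.decade] = occ.reshape(geom.rows, geom.cols)
    return sp


def place_circles(config: LandscapeConfig) -> pd.DataFrame:
    """Survey circles: one candidate per block, a random fraction active."""
    rng = stream(config.rng_seed, "circles")
    geom = config.geometry
    b = config.circle_block
    rows = []
    cid = 0
    for br in range(0, geom.rows, b):
        for bc in range(0, geom.cols, b):
            r = br + int(rng.integers(min(b, geom.rows - br)))
            c = bc + int(rng.integers(min(b, geom.cols - bc)))
            rows.append((f"C{cid:03d}", r, c, config.circle_radius))
            cid += 1
    circles = pd.DataFrame(rows, columns=["circle_id", "row", "col", "radius"])
    keep = rng.random(len(circles)) < config.circle_active_fraction
    if not keep.any():
        keep[0] = True
    return circles[keep].reset_index(drop=True)


def _circle_cells(geom: GridGeometry, row: int, col: int,
                  radius: float) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.ogrid[:geom.rows, :geom.cols]
    mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2
    return np.nonzero(mask)


def simulate_surveys(config: LandscapeConfig,
                     species: list[TrueSpecies],
                     circles: pd.DataFrame,
                     misid_rate: float = 0.01,
                     detectability: float | None = None) -> pd.DataFrame:
    """CBC-style yearly detection records.

    For each (circle, year, species): if any occupied cell of the
    species' decade-truth lies within the circle, the species is detected
    with its detectability; otherwise a false detection occurs with
    probability ``misid_rate``. ``detectability`` overrides every
    species' own value when given (used for noise-free worlds).
    """
    if not 0.0 <= misid_rate < 1.0:
        raise ValueError("misid_rate must lie in [0, 1)")
    geom = config.geometry
    cell_idx = {
        cid: _circle_cells(geom, r, c, rad)
        for cid, r, c, rad in circles[["circle_id", "row", "col",
                                       "radius"]].itertuples(index=False)
    }
    decades = config.decades
    out = []
    for sp in species:
        det = sp.detectability if detectability is None else detectability
        rng = stream(config.rng_seed, "survey", sp.species_id)
        for cid, cells in cell_idx.items():
            for d, label in enumerate(decades):
                present = bool(sp.occupancy[label][cells].any())
                years = config.decade_years(d)
                if present:
                    hits = rng.random(len(years)) < det
                else:
                    hits = rng.random(len(years)) < misid_rate
                for y, h in zip(years, hits):
                    if h:
                        out.append((cid, sp.species_id, y, True))
    return pd.DataFrame(out, columns=["circle_id", "species_id", "year",
                                      "detected"])


def build_world(config: LandscapeConfig,
                species_specs: list[dict] | None = None,
                n_species: int = 12,
                misid_rate: float = 0.01,
                detectability: float | None = None) -> SurveyWorld:
    """Assemble climate, species, circles and survey records.

    Without explicit ``species_specs``, cycles species through the four
    range archetypes with alternating migratory and trend labels.
    """
    stacks = generate_climate(config)
    if species_specs is None:
        classes = ["WC", "WR", "NEC", "NER"]
        migr = ["N", "T", "R"]
        trends = ["stable", "increasing", "decreasing"]
        species_specs = [
            {"species_id": f"sp{i:02d}", "range_class": classes[i % 4],
             "migratory": migr[i % 3], "trend": trends[i % 3],
             "habitat": "GWSE"[i % 4], "mass_cat": i % 4 + 1}
            for i in range(n_species)
        ]
    species = [generate_species(config, stacks, **spec)
               for spec in species_specs]
    circles = place_circles(config)
    records = simulate_surveys(config, species, circles,
                               misid_rate=misid_rate,
                               detectability=detectability)
    return SurveyWorld(config=config, stacks=stacks, species=species,
                       circles=circles, records=records)
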