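"""Decadal climate aggregation, bioclim variables, collinearity and
extrapolation diagnostics.

The pipeline works on :class:`ClimateStack` objects: one named grid per
climate variable for one decade, all sharing a :class:`GridGeometry`.
Stacks can hold the 19 standard bioclim summaries computed from monthly
normals, or arbitrary synthetic variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gridio import GridGeometry

__all__ = [
    "ClimateStack",
    "MonthlyClimate",
    "CollinearityReport",
    "decadal_average",
    "compute_bioclim",
    "vif",
    "vif_screen",
    "mess_surface",
    "BIOCLIM_NAMES",
]

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))

# sentinel for a MESS score that is undefined (constant reference variable,
# cell value off the constant)
MESS_UNDEFINED = -np.inf


@dataclass
class ClimateStack:
    """Named climate grids for one decade over a shared geometry."""

    decade: str
    grids: dict[str, np.ndarray]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        for name, g in self.grids.items():
            g = np.asarray(g, dtype=float)
            if g.shape != (self.geometry.rows, self.geometry.cols):
                raise ValueError(
                    f"grid {name!r} shape {g.shape} does not match geometry "
                    f"{(self.geometry.rows, self.geometry.cols)}"
                )
            self.grids[name] = g

    @property
    def variables(self) -> list[str]:
        return list(self.grids)

    def as_array(self, variables: list[str] | None = None) -> np.ndarray:
        """Stack grids into an (n_vars, rows, cols) array."""
        names = variables if variables is not None else self.variables
        return np.stack([self.grids[v] for v in names])

    def sample(self, cells: np.ndarray,
               variables: list[str] | None = None) -> np.ndarray:
        """Values at (row, col) cells -> (n_cells, n_vars) array."""
        cells = np.asarray(cells)
        names = variables if variables is not None else self.variables
        rows, cols = cells[:, 0], cells[:, 1]
        return np.column_stack([self.grids[v][rows, cols] for v in names])

    def table(self, cells: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(self.sample(cells), columns=self.variables)


@dataclass
class MonthlyClimate:
    """Per-year monthly grids of tmin/tmax/prec (and optionally tmean).

    Arrays are keyed by variable and year: ``data[var][year]`` is a
    (12, rows, cols) array. Units: temperatures in degrees C,
    precipitation in mm/month.
    """

    data: dict[str, dict[int, np.ndarray]]
    geometry: GridGeometry

    def years(self) -> list[int]:
        anyvar = next(iter(self.data.values()))
        return sorted(anyvar)


def decadal_average(monthly: MonthlyClimate,
                    years: list[int]) -> dict[str, np.ndarray]:
    """Monthly climate normals for one decade.

    For each variable, the normal for month m is the cell-wise arithmetic
    mean of that month's grid over the decade's years. Returns
    ``{var: (12, rows, cols)}``.
    """
    if not years:
        raise ValueError("decade contains no years")
    normals: dict[str, np.ndarray] = {}
    for var, per_year in monthly.data.items():
        grids = []
        for y in years:
            if y not in per_year:
                raise ValueError(f"missing data for year {y}, variable {var!r}")
            g = np.asarray(per_year[y], dtype=float)
            if g.shape[0] != 12:
                raise ValueError(f"year {y} variable {var!r} lacks 12 months")
            grids.append(g)
        normals[var] = np.mean(grids, axis=0)
    return normals


def _quarter_sums(x: np.ndarray) -> np.ndarray:
    """Sums over the 12 wrap-around 3-month windows; x is (12, ...)."""
    ext = np.concatenate([x, x[:2]], axis=0)
    return np.stack([ext[i:i + 3].sum(axis=0) for i in range(12)])


def compute_bioclim(normals: dict[str, np.ndarray],
                    geometry: GridGeometry,
                    decade: str = "",
                    sd_ddof: int = 0) -> ClimateStack:
    """The 19 bioclim variables from monthly normals.

    Quarters are all 12 windows of 3 consecutive months with December to
    January wrap-around; the wettest/driest/warmest/coldest quarter is
    chosen per cell (ties broken by the earliest starting month).
    ``sd_ddof`` selects the SD convention for bio4/bio15 (0 = population
    SD, the default; 1 = sample SD).
    """
    tmin = np.asarray(normals["tmin"], dtype=float)
    tmax = np.asarray(normals["tmax"], dtype=float)
    prec = np.asarray(normals["prec"], dtype=float)
    tmean = np.asarray(normals.get("tmean", (tmin + tmax) / 2.0), dtype=float)
    for name, arr in [("tmin", tmin), ("tmax", tmax), ("prec", prec),
                      ("tmean", tmean)]:
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))
            raise ValueError(f"non-finite {name} normal at (month,cell) {bad[0]}")

    bio: dict[str, np.ndarray] = {}
    bio["bio1"] = tmean.mean(axis=0)
    bio["bio2"] = (tmax - tmin).mean(axis=0)
    bio["bio4"] = 100.0 * tmean.std(axis=0, ddof=sd_ddof)
    bio["bio5"] = tmax.max(axis=0)
    bio["bio6"] = tmin.min(axis=0)
    bio["bio7"] = bio["bio5"] - bio["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio3"] = np.where(bio["bio7"] != 0,
                               100.0 * bio["bio2"] / bio["bio7"], 0.0)
    bio["bio12"] = prec.sum(axis=0)
    bio["bio13"] = prec.max(axis=0)
    bio["bio14"] = prec.min(axis=0)
    bio["bio15"] = 100.0 * prec.std(axis=0, ddof=sd_ddof) / (
        1.0 + bio["bio12"] / 12.0)

    psum = _quarter_sums(prec)                      # (12, ...)
    tq = _quarter_sums(tmean) / 3.0                 # quarter mean temps
    wettest = psum.argmax(axis=0)
    driest = psum.argmin(axis=0)
    warmest = tq.argmax(axis=0)
    coldest = tq.argmin(axis=0)

    def pick(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None, ...], axis=0)[0]

    bio["bio8"] = pick(tq, wettest)
    bio["bio9"] = pick(tq, driest)
    bio["bio10"] = pick(tq, warmest)
    bio["bio11"] = pick(tq, coldest)
    bio["bio16"] = pick(psum, wettest)
    bio["bio17"] = pick(psum, driest)
    bio["bio18"] = pick(psum, warmest)
    bio["bio19"] = pick(psum, coldest)

    grids = {name: np.atleast_2d(bio[name]) for name in BIOCLIM_NAMES}
    return ClimateStack(decade=decade, grids=grids, geometry=geometry)


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column: 1/(1 - R^2_j) from
    regressing column j on the remaining columns (with intercept)."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        if np.ptp(yj) == 0:
            out[j] = np.inf
            continue
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class CollinearityReport:
    """Result of a collinearity screen over sampled climate values."""

    vif: pd.Series
    flagged: list[str]
    method: str
    threshold: float
    steps: list[str] = field(default_factory=list)

    def kept(self) -> list[str]:
        return [v for v in self.vif.index if v not in self.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vif": self.vif,
            "flagged": [v in self.flagged for v in self.vif.index],
        })


def vif_screen(values: pd.DataFrame | np.ndarray,
               threshold: float = 0.9,
               method: str = "pairwise-correlation",
               variables: list[str] | None = None) -> CollinearityReport:
    """Iteratively flag collinear variables.

    method="pairwise-correlation": while some pair has |r| > threshold,
    flag the member of the worst pair with the larger VIF (the cited
    ``vifcor`` semantics; the study's 0.9 threshold is a correlation).
    method="stepwise-VIF": while max VIF > threshold, flag the max-VIF
    variable (``vifstep`` semantics). Ties are broken toward the lowest
    column index. Constant columns get infinite VIF and are flagged.
    """
    if isinstance(values, pd.DataFrame):
        names = list(values.columns)
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        names = variables or [f"v{i + 1}" for i in range(X.shape[1])]
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least n_vars + 2 sample points")

    full_vif = pd.Series(vif(X), index=names)
    active = list(range(len(names)))
    flagged: list[str] = []
    steps: list[str] = []

    # constant columns are degenerate under both methods
    for j in list(active):
        if np.ptp(X[:, j]) == 0:
            flagged.append(names[j])
            steps.append(f"{names[j]}: constant (VIF=inf)")
            active.remove(j)

    # exactly collinear sets (infinite VIF) escape a pairwise |r| screen,
    # so resolve them first; lowest index removed first on ties
    while len(active) >= 2:
        v = vif(X[:, active])
        bad = np.nonzero(~np.isfinite(v))[0]
        if len(bad) == 0:
            break
        gi = active[int(bad[0])]
        flagged.append(names[gi])
        steps.append(f"{names[gi]}: exact collinearity (VIF=inf)")
        active.remove(gi)

    if method == "pairwise-correlation":
        while len(active) >= 2:
            sub = X[:, active]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = np.corrcoef(sub, rowvar=False)
            np.fill_diagonal(r, 0.0)
            absr = np.abs(r)
            if np.nanmax(absr) <= threshold:
                break
            i, j = np.unravel_index(np.nanargmax(absr), absr.shape)
            v = vif(sub)
            # drop the higher-VIF member; ties -> lower index
            drop_local = i if v[i] >= v[j] else j
            if v[i] == v[j]:
                drop_local = min(i, j)
            gi = active[drop_local]
            flagged.append(names[gi])
            steps.append(
                f"{names[gi]}: |r|={absr[i, j]:.3f} with "
                f"{names[active[j if drop_local == i else i]]}, VIF={v[drop_local]:.2f}"
            )
            active.remove(gi)
    elif method == "stepwise-VIF":
        while len(active) >= 2:
            v = vif(X[:, active])
            jmax = int(np.argmax(v))  # argmax returns first max: lowest index
            if v[jmax] <= threshold:
                break
            gi = active[jmax]
            flagged.append(names[gi])
            steps.append(f"{names[gi]}: VIF={v[jmax]:.2f}")
            active.remove(gi)
    else:
        raise ValueError(f"unknown method {method!r}")

    return CollinearityReport(vif=full_vif, flagged=flagged, method=method,
                              threshold=threshold, steps=steps)


def mess_surface(reference: np.ndarray | pd.DataFrame,
                 stack: ClimateStack,
                 variables: list[str] | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate environmental similarity of a stack to a reference
    sample.

    For each variable and cell, with f the percentage of reference values
    strictly below the cell value, min/max the reference extremes:

    * f = 0:        S = 100 (v - min) / (max - min)
    * 0 < f <= 50:  S = 2 f
    * 50 < f < 100: S = 2 (100 - f)
    * f = 100:      S = 100 (max - v) / (max - min) + 100

    The cell's MESS is the minimum S over variables; negative values mark
    cells outside the reference range on at least one variable. Returns
    (mess_grid, most_dissimilar_variable_index_grid).
    """
    if isinstance(reference, pd.DataFrame):
        names = list(reference.columns)
        ref = reference.to_numpy(dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
        names = variables or stack.variables
    if ref.size == 0:
        raise ValueError("reference sample is empty")
    n_ref = ref.shape[0]

    sims = np.empty((len(names), stack.geometry.rows, stack.geometry.cols))
    for k, name in enumerate(names):
        rv = np.sort(ref[:, k])
        lo, hi = rv[0], rv[-1]
        v = stack.grids[name]
        f = 100.0 * np.searchsorted(rv, v.ravel(), side="left") / n_ref
        f = f.reshape(v.shape)
        if hi == lo:
            s = np.where(v == lo, 0.0, MESS_UNDEFINED)
            if np.any(v != lo):
                warnings.warn(
                    f"variable {name!r} constant in reference; cells off the "
                    "constant get -inf similarity")
        else:
            span = hi - lo
            s = np.where(
                f == 0.0, 100.0 * (v - lo) / span,
                np.where(f <= 50.0, 2.0 * f,
                         np.where(f < 100.0, 2.0 * (100.0 - f),
                                  100.0 * (hi - v) / span + 100.0)))
        sims[k] = s
    mess = sims.min(axis=0)
    mdv = sims.argmin(axis=0)
    return mess, mdv
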