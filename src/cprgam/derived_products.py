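"""Scientific products derived from a fitted occurrence model.

All products are computed on a regular (east, north, doy) lattice of
cell centres, evaluated per year:

* per-component spatial probability density functions (each integrating
  to 1 over its component's domain);
* peak-timing maps (day of year of the local seasonal maximum), masked
  to the highest-density core of each component;
* zonally integrated latitude x day-of-year densities per component;
* annual abundance indices (spatial-seasonal integrals, arbitrary
  linear units) with central 67% posterior intervals from coefficient
  resampling.

Multi-year products average the per-year *normalized* distributions.
Day/night is fixed to a declared convention (default: the average of the
day and night predictions).  Component labels are assigned per cell from
the unprojected latitude (north iff latitude >= split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import geo_time
from .bernoulli_gam import FittedModel, assign_component

__all__ = [
    "GridAxes",
    "PredictionGrid",
    "PeakTimingMap",
    "ZonalMarginal",
    "make_grid_axes",
    "evaluate_grid",
    "spatial_pdf",
    "peak_timing_map",
    "zonal_marginal",
    "annual_index",
    "hdr_mask",
]

_CHUNK_ROWS = 60_000


@dataclass(frozen=True)
class GridAxes:
    """Regular lattice axes (cell centres, uniform spacing)."""

    east: np.ndarray
    north: np.ndarray
    doy: np.ndarray

    def __post_init__(self) -> None:
        for name in ("east", "north", "doy"):
            ax = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, ax)
            if ax.ndim != 1 or ax.size < 1:
                raise ValueError(f"{name} axis must be a 1-D array")
            if ax.size > 1:
                d = np.diff(ax)
                if np.any(d <= 0):
                    raise ValueError(f"{name} axis must be strictly increasing")
                if not np.allclose(d, d[0], rtol=1e-6):
                    raise ValueError(f"{name} axis must be uniformly spaced")

    def _step(self, ax: np.ndarray, default: float) -> float:
        return float(ax[1] - ax[0]) if ax.size > 1 else default

    @property
    def d_east(self) -> float:
        return self._step(self.east, 1.0)

    @property
    def d_north(self) -> float:
        return self._step(self.north, 1.0)

    @property
    def d_doy(self) -> float:
        return self._step(self.doy, 1.0)

    @property
    def cell_measure(self) -> float:
        """Cell volume Δe * Δn * Δdoy."""
        return self.d_east * self.d_north * self.d_doy

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.doy.size, self.north.size, self.east.size)


def make_grid_axes(
    east_bounds: tuple[float, float],
    north_bounds: tuple[float, float],
    n_east: int = 50,
    n_north: int = 80,
    doy_step: float = 5.0,
) -> GridAxes:
    """Cell-centre axes covering the given planar bounding box."""
    de = (east_bounds[1] - east_bounds[0]) / n_east
    dn = (north_bounds[1] - north_bounds[0]) / n_north
    east = east_bounds[0] + de * (np.arange(n_east) + 0.5)
    north = north_bounds[0] + dn * (np.arange(n_north) + 0.5)
    doy = np.arange(doy_step / 2.0, 365.0, doy_step)
    return GridAxes(east=east, north=north, doy=doy)


@dataclass
class PredictionGrid:
    """Occurrence probabilities on a (year, doy, north, east) lattice.

    ``valid`` marks the spatial cells inside the analysis domain (e.g.
    with sampling support); all derived products integrate over valid
    cells only.
    """

    axes: GridAxes
    years: list
    prob: np.ndarray                 # (n_years, n_doy, n_north, n_east)
    comp: np.ndarray                 # (n_north, n_east) of "north"/"south"
    lat: np.ndarray                  # (n_north, n_east) degrees
    dn_convention: str = "average"
    split_latitude: float = 53.0
    valid: Optional[np.ndarray] = None          # (n_north, n_east) bool
    extrapolated: Optional[np.ndarray] = None   # (n_doy*n_north*n_east,) flags

    def __post_init__(self) -> None:
        if np.any(self.prob <= 0.0) or np.any(self.prob >= 1.0):
            raise ValueError("grid probabilities must lie strictly in (0, 1)")
        if self.valid is None:
            self.valid = np.ones(self.comp.shape, dtype=bool)

    def comp_mask(self, label: str) -> np.ndarray:
        return (self.comp == label) & self.valid

    @property
    def labels(self) -> tuple[str, str]:
        return ("north", "south")


def support_mask(
    axes: GridAxes, east: np.ndarray, north: np.ndarray, radius_m: Optional[float] = None
) -> np.ndarray:
    """Spatial cells within ``radius_m`` of at least one observation.

    Mirrors drawing the region of interest around the sampled domain:
    cells far from any transect carry no information about the smooth
    and are excluded from integrated products.  Default radius: the
    larger cell side (one cell of slack).
    """
    from scipy.spatial import cKDTree

    if radius_m is None:
        radius_m = max(axes.d_east, axes.d_north)
    tree = cKDTree(np.column_stack([np.asarray(east, float), np.asarray(north, float)]))
    E2, N2 = np.meshgrid(axes.east, axes.north)
    d, _ = tree.query(np.column_stack([E2.ravel(), N2.ravel()]), k=1)
    return (d <= radius_m).reshape(E2.shape)


def _spatial_frame(axes: GridAxes, comp: np.ndarray, ref_year) -> pd.DataFrame:
    nd, nn, ne = axes.shape
    D, N, E = np.meshgrid(axes.doy, axes.north, axes.east, indexing="ij")
    frame = pd.DataFrame(
        {
            "east": E.ravel(),
            "north": N.ravel(),
            "doy": D.ravel(),
            "comp": np.broadcast_to(comp, (nd, nn, ne)).ravel(),
            "year": float(ref_year),
            "dn": "night",
        }
    )
    return frame


def _block_groups(model: FittedModel):
    year_blocks = [b for b in model.design.blocks if "year" in b.term.variables]
    space_blocks = [b for b in model.design.blocks if "year" not in b.term.variables]
    return space_blocks, year_blocks


def _year_offsets(
    model: FittedModel, beta_mat: np.ndarray, years: Sequence
) -> np.ndarray:
    """Year-smooth contribution per (year, comp, draw)."""
    _, year_blocks = _block_groups(model)
    labels = ("north", "south")
    out = np.zeros((len(years), 2, beta_mat.shape[1]))
    if not year_blocks:
        return out
    frame = pd.DataFrame(
        {
            "year": np.repeat([float(y) for y in years], 2),
            "comp": np.tile(labels, len(years)),
        }
    )
    for b in year_blocks:
        B = b.build(frame)                       # (2*n_years, dim)
        out += (B @ beta_mat[b.sl]).reshape(len(years), 2, -1)
    return out


def _eta_space(
    model: FittedModel, frame: pd.DataFrame, beta_mat: np.ndarray
) -> np.ndarray:
    """Linear predictor of all non-year terms (night state), chunked.

    Returns (n_rows, n_draws).
    """
    space_blocks, _ = _block_groups(model)
    n = len(frame)
    eta = np.empty((n, beta_mat.shape[1]))
    for start in range(0, n, _CHUNK_ROWS):
        sl = slice(start, min(start + _CHUNK_ROWS, n))
        sub = frame.iloc[sl]
        acc = np.broadcast_to(beta_mat[0], (sl.stop - sl.start, beta_mat.shape[1])).copy()
        for b in space_blocks:
            acc += b.build(sub) @ beta_mat[b.sl]
        eta[sl] = acc
    return eta


def _prob_from_eta(eta: np.ndarray, dn_coef, convention: str) -> np.ndarray:
    if convention == "night":
        return expit(eta)
    if convention == "day":
        return expit(eta + dn_coef)
    if convention == "average":
        return 0.5 * (expit(eta) + expit(eta + dn_coef))
    raise ValueError(f"unknown dn convention {convention!r}")


def evaluate_grid(
    model: FittedModel,
    axes: GridAxes,
    years: Optional[Sequence] = None,
    dn: str = "average",
    valid: Optional[np.ndarray] = None,
) -> PredictionGrid:
    """Evaluate the fitted model on the lattice, one slab per year.

    ``valid`` (optional, (n_north, n_east) bool) restricts the analysis
    domain of downstream products; see :func:`support_mask`.
    """
    if years is None:
        years = [0]
    years = list(years)
    split = model.spec.split_latitude
    E2, N2 = np.meshgrid(axes.east, axes.north)
    _, lat = geo_time.unproject_plane(E2, N2)
    comp = assign_component(lat, split)

    frame = _spatial_frame(axes, comp, ref_year=years[0])
    beta_mat = model.beta.reshape(-1, 1)
    eta_s = _eta_space(model, frame, beta_mat)[:, 0]
    offsets = _year_offsets(model, beta_mat, years)[:, :, 0]  # (n_years, 2)

    comp_rows = frame["comp"].to_numpy()
    is_north = comp_rows == "north"
    nd, nn, ne = axes.shape
    prob = np.empty((len(years), nd, nn, ne))
    for yi in range(len(years)):
        off = np.where(is_north, offsets[yi, 0], offsets[yi, 1])
        p = _prob_from_eta(eta_s + off, model.dn_coefficient, dn)
        prob[yi] = p.reshape(nd, nn, ne)

    # extrapolation flags from the spatial/seasonal terms
    flags = np.zeros(len(frame), dtype=bool)
    space_blocks, year_blocks = _block_groups(model)
    for b in space_blocks:
        flags |= b.out_of_support(frame)
    if year_blocks:
        yframe = pd.DataFrame({"year": [float(y) for y in years]})
        for b in year_blocks:
            for m in b.term.margins:
                lo, hi = m.support()
                if np.any((yframe["year"] < lo) | (yframe["year"] > hi)):
                    flags |= True  # coarse: whole grid flagged for out-of-range years

    return PredictionGrid(
        axes=axes,
        years=years,
        prob=prob,
        comp=comp,
        lat=lat,
        dn_convention=dn,
        split_latitude=split,
        valid=valid,
        extrapolated=flags,
    )


def spatial_pdf(grid: PredictionGrid) -> dict[str, np.ndarray]:
    """Per-component spatial densities (north, east), each integrating
    to 1 over the component's own domain.

    Per year, probability is integrated over day of year, normalized
    within each component, and the per-year normalized fields averaged.
    Relative levels between components are NOT comparable.
    """
    axes = grid.axes
    area = axes.d_east * axes.d_north
    out: dict[str, np.ndarray] = {}
    for label in grid.labels:
        mask = grid.comp_mask(label)
        dens_years = []
        for yi in range(len(grid.years)):
            s = grid.prob[yi].sum(axis=0) * axes.d_doy      # (nn, ne)
            s = np.where(mask, s, 0.0)
            mass = s.sum() * area
            if mass <= 0:
                raise ValueError(f"no probability mass in component {label!r}")
            dens_years.append(s / mass)
        out[label] = np.mean(dens_years, axis=0)
    return out


def hdr_mask(density: np.ndarray, cell_area: float, mass: float = 0.75) -> np.ndarray:
    """Smallest set of cells holding at least ``mass`` of the density.

    Cells are sorted by density, descending; ties broken by flat cell
    index for determinism.
    """
    flat = density.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order] * cell_area)
    total = csum[-1]
    n_in = int(np.searchsorted(csum, mass * total, side="left") + 1)
    sel = np.zeros(flat.size, dtype=bool)
    sel[order[:n_in]] = True
    return sel.reshape(density.shape)


@dataclass
class PeakTimingMap:
    """Day-of-year of the seasonal probability maximum, core-masked."""

    peak_doy: np.ndarray          # (nn, ne), NaN outside core / flat cells
    core_mask: np.ndarray         # (nn, ne) bool
    n_flat_masked: int
    core_mass: float


def peak_timing_map(grid: PredictionGrid, core_mass: float = 0.75) -> PeakTimingMap:
    """Per-cell argmax day of year, masked to each component's
    highest-density core of the spatial PDF."""
    axes = grid.axes
    pbar = grid.prob.mean(axis=0)              # (nd, nn, ne), year-averaged
    arg = np.argmax(pbar, axis=0)
    peak = axes.doy[arg].astype(float)
    flat = (pbar.max(axis=0) - pbar.min(axis=0)) < 1e-12

    pdfs = spatial_pdf(grid)
    area = axes.d_east * axes.d_north
    core = np.zeros(peak.shape, dtype=bool)
    for label in grid.labels:
        mask = grid.comp_mask(label)
        dens = np.where(mask, pdfs[label], 0.0)
        core |= hdr_mask(dens, area, core_mass) & mask
    out = np.where(core & ~flat, peak, np.nan)
    return PeakTimingMap(
        peak_doy=out,
        core_mask=core,
        n_flat_masked=int((flat & core).sum()),
        core_mass=core_mass,
    )


@dataclass
class ZonalMarginal:
    """Latitude x day-of-year densities per component (east integrated
    out; the northing axis is relabelled to latitude at the central
    meridian for presentation)."""

    doy: np.ndarray
    north: np.ndarray
    latitude: np.ndarray
    density: dict[str, np.ndarray]     # label -> (nd, nn)

    def peak_doy(self, label: str) -> float:
        """Day of year of the marginal (latitude-integrated) peak."""
        m = self.density[label].sum(axis=1)
        return float(self.doy[int(np.argmax(m))])


def zonal_marginal(grid: PredictionGrid) -> ZonalMarginal:
    """Integrate eastings out; per-component (doy, north) density with
    unit integral, averaged over per-year normalized fields."""
    axes = grid.axes
    _, lat_axis = geo_time.unproject_plane(
        np.full(axes.north.shape, 500_000.0), axes.north
    )
    density: dict[str, np.ndarray] = {}
    for label in grid.labels:
        mask = grid.comp_mask(label)           # (nn, ne)
        per_year = []
        for yi in range(len(grid.years)):
            m = (grid.prob[yi] * mask[None, :, :]).sum(axis=2) * axes.d_east  # (nd, nn)
            mass = m.sum() * axes.d_north * axes.d_doy
            if mass <= 0:
                raise ValueError(f"no probability mass in component {label!r}")
            per_year.append(m / mass)
        density[label] = np.mean(per_year, axis=0)
    return ZonalMarginal(
        doy=axes.doy, north=axes.north, latitude=lat_axis, density=density
    )


def annual_index(
    model: FittedModel,
    axes: GridAxes,
    years: Sequence,
    n_draws: int = 200,
    seed: int = 0,
    dn: str = "average",
    valid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Annual abundance indices with central 67% posterior intervals.

    For each posterior coefficient draw, occurrence probability is
    integrated over (east, north, doy) per year and component; the
    median and the 16.5%/83.5% quantiles across draws are reported.
    Units are arbitrary but linear in the cell measure.
    """
    years = list(years)
    split = model.spec.split_latitude
    E2, N2 = np.meshgrid(axes.east, axes.north)
    _, lat = geo_time.unproject_plane(E2, N2)
    comp = assign_component(lat, split)
    frame = _spatial_frame(axes, comp, ref_year=years[0])

    draws = model.posterior_draws(n_draws, seed=seed)          # (n_draws, p)
    beta_mat = draws.T                                         # (p, n_draws)
    eta_s = _eta_space(model, frame, beta_mat)                 # (rows, n_draws)
    offsets = _year_offsets(model, beta_mat, years)            # (ny, 2, n_draws)
    dn_coefs = beta_mat[1]                                     # (n_draws,)

    is_north = frame["comp"].to_numpy() == "north"
    if valid is None:
        row_valid = np.ones(len(frame), dtype=bool)
    else:
        nd = axes.doy.size
        row_valid = np.broadcast_to(valid, (nd,) + valid.shape).ravel()
    measure = axes.cell_measure
    records = []
    for yi, year in enumerate(years):
        off = np.where(is_north[:, None], offsets[yi, 0], offsets[yi, 1])
        p = _prob_from_eta(eta_s + off, dn_coefs[None, :], dn)
        for label, mask in (
            ("north", is_north & row_valid),
            ("south", ~is_north & row_valid),
        ):
            idx = p[mask].sum(axis=0) * measure                # (n_draws,)
            lo, med, hi = np.quantile(idx, [0.165, 0.5, 0.835])
            records.append(
                {
                    "year": year,
                    "component": label,
                    "median": med,
                    "lo67": lo,
                    "hi67": hi,
                }
            )
    return pd.DataFrame(records)
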