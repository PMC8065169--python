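"""Seeded synthetic SST and velocity fields with planted spatial structure.

The generator emulates the statistical features the ecoregionalization
analysis assumes in real reanalysis fields:

* spatially contiguous regions whose cells share a highly correlated latent
  AR(1) signal (plus independent per-cell noise at a configurable
  signal-to-noise ratio),
* lagged linear couplings between region latents, so a planted, directed
  functional network exists by construction,
* a 12-month seasonal sinusoid and a linear warming trend per cell,
* velocity jets traced along the shared boundaries of adjacent regions, so
  kinetic-energy fronts coincide with region boundaries by construction.

Everything is deterministic given ``SynthConfig.seed``; the planted labels,
couplings and jet geometry are returned as :class:`GroundTruth` for recovery
testing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import signal as _sig

from .grid import GriddedField

__all__ = [
    "SynthConfig", "GroundTruth", "Coupling", "Jet",
    "generate_truth", "generate_latents", "generate_sst", "generate_velocity",
    "save_truth", "load_truth",
]

_BURN = 120  # AR(1) burn-in months discarded before the record starts


@dataclass(frozen=True)
class Coupling:
    """Lagged linear coupling: target latent follows source latent by `lag` months."""
    source: int
    target: int
    lag: int
    coef: float


@dataclass(frozen=True)
class Jet:
    """A boundary current: ordered cell chain with a speed amplitude (m/s)."""
    cells: tuple
    amplitude: float
    regions: tuple


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic ocean.

    Defaults are the conditions used throughout the test-suite: a 40x40 grid
    at 0.375 deg spacing (Mediterranean-like latitudes), 30 years of monthly
    data, 4 regions covering 90% of the ocean, latent AR(1) coefficient 0.5,
    snr = 5 (per-cell noise std = latent std / 5), a 2 degC seasonal cycle and
    a 0.04 degC/yr warming trend.
    """

    nlat: int = 40
    nlon: int = 40
    n_years: int = 30
    n_regions: int = 4
    ar1_coef: float = 0.5
    snr: float = 5.0
    seasonal_amp: float = 2.0
    trend: float = 0.04            # degC per year
    land_fraction: float = 0.0
    seed: int = 0
    region_coverage: float = 0.9   # fraction of ocean covered by planted regions
    jet_speed: float = 0.3         # m/s, typical boundary-current speed
    jet_halfwidth: int = 1         # 8-neighbor dilations of the jet axis (finite width)
    background_speed_fraction: float = 0.1
    couplings: tuple | None = None  # None -> defaults for the region count
    cell_deg: float = 0.375
    lat0: float = 30.0
    lon0: float = -5.0
    start_year: int = 1987
    tau_max: int = 12

    def __post_init__(self) -> None:
        if min(self.nlat, self.nlon) < 4:
            raise ValueError("grid dimensions must be >= 4")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not 0 < self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in (0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if not 0 <= self.land_fraction < 1:
            raise ValueError("land_fraction must lie in [0, 1)")
        if not 0.5 <= self.region_coverage <= 1.0:
            raise ValueError("region_coverage must lie in [0.5, 1]")

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    @property
    def lat(self) -> np.ndarray:
        return self.lat0 + np.arange(self.nlat) * self.cell_deg

    @property
    def lon(self) -> np.ndarray:
        return self.lon0 + np.arange(self.nlon) * self.cell_deg

    @property
    def time(self) -> pd.DatetimeIndex:
        return pd.date_range(f"{self.start_year}-01-01", periods=self.n_months, freq="MS")

    def resolved_couplings(self) -> tuple:
        """Explicit couplings, or defaults scaled to the region count."""
        if self.couplings is not None:
            out = tuple(Coupling(*c) if not isinstance(c, Coupling) else c
                        for c in self.couplings)
        else:
            out = ()
            if self.n_regions >= 2:
                out += (Coupling(1, 2, 3, 0.5),)
            if self.n_regions >= 4:
                out += (Coupling(3, 4, 5, -0.45),)
        targets = [c.target for c in out]
        for c in out:
            if not (1 <= c.source <= self.n_regions and 1 <= c.target <= self.n_regions):
                raise ValueError(f"coupling {c} references a region outside 1..{self.n_regions}")
            if c.source == c.target:
                raise ValueError("coupling source and target must differ")
            if abs(c.lag) > self.tau_max:
                raise ValueError(f"coupling lag {c.lag} outside [-{self.tau_max}, {self.tau_max}]")
            if not abs(c.coef) < 1:
                raise ValueError("coupling coefficient must have |coef| < 1")
            if c.source in targets:
                raise ValueError("coupling chains are not supported (source is also a target)")
        if len(set(targets)) != len(targets):
            raise ValueError("each region may be the target of at most one coupling")
        return out


@dataclass
class GroundTruth:
    """Planted structure: region labels, couplings, jet geometry and the seed."""

    label_map: np.ndarray          # (nlat, nlon) int, 0 = background, k>0 = region k
    mask: np.ndarray               # True = ocean
    couplings: tuple
    jets: tuple
    seed: int

    def region_cells(self, k: int) -> list:
        ii, jj = np.nonzero(self.label_map == k)
        return list(zip(ii.tolist(), jj.tolist()))

    def jet_mask(self, halfwidth: int = 0) -> np.ndarray:
        """Ocean cells carrying jet speed, axis cells dilated `halfwidth` times."""
        from scipy import ndimage
        m = np.zeros(self.mask.shape, dtype=bool)
        for j in self.jets:
            for c in j.cells:
                m[c] = True
        if halfwidth > 0:
            m = ndimage.binary_dilation(
                m, structure=np.ones((3, 3), bool), iterations=halfwidth
            )
        return m & self.mask

    @property
    def n_regions(self) -> int:
        return int(self.label_map.max())


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _neighbors4(i: int, j: int, nlat: int, nlon: int):
    if i > 0:
        yield i - 1, j
    if i < nlat - 1:
        yield i + 1, j
    if j > 0:
        yield i, j - 1
    if j < nlon - 1:
        yield i, j + 1


def generate_truth(cfg: SynthConfig) -> GroundTruth:
    """Plant disjoint 4-connected regions and trace jets along their shared
    boundaries.

    Regions are grown by seeded random breadth-first accretion from seed cells
    placed by farthest-point sampling, in round-robin order so sizes stay
    roughly balanced, until ``region_coverage`` of the ocean is claimed.

    Raises
    ------
    ValueError
        If the grid is too small to hold ``n_regions`` disjoint regions.
    """
    rng = _rng(cfg.seed, 0)
    mask = np.ones((cfg.nlat, cfg.nlon), dtype=bool)
    n_land = int(round(cfg.land_fraction * mask.size))
    if n_land:
        # rectangular land block along the northern edge
        rows = int(np.ceil(n_land / cfg.nlon))
        flat = np.ones(mask.size, dtype=bool)
        flat[:n_land] = False
        mask = flat.reshape(mask.shape)
        del rows
    ocean = list(zip(*map(np.ndarray.tolist, map(np.asarray, np.nonzero(mask)))))
    n_ocean = len(ocean)
    if cfg.n_regions * 4 > n_ocean:
        raise ValueError(
            f"grid too small to place {cfg.n_regions} disjoint 4-connected regions: "
            f"only {n_ocean} ocean cells available (need >= {4 * cfg.n_regions})"
        )

    # farthest-point seed placement (deterministic given the rng)
    seeds = [ocean[int(rng.integers(n_ocean))]]
    pts = np.array(ocean, dtype=float)
    while len(seeds) < cfg.n_regions:
        d = np.min(
            [np.hypot(pts[:, 0] - s[0], pts[:, 1] - s[1]) for s in seeds], axis=0
        )
        seeds.append(ocean[int(np.argmax(d))])

    labels = np.zeros((cfg.nlat, cfg.nlon), dtype=int)
    frontiers = []
    for k, s in enumerate(seeds, start=1):
        labels[s] = k
        frontiers.append(set(
            c for c in _neighbors4(*s, cfg.nlat, cfg.nlon) if mask[c] and labels[c] == 0
        ))
    target = int(round(cfg.region_coverage * n_ocean))
    assigned = cfg.n_regions
    while assigned < target:
        progressed = False
        for k in range(1, cfg.n_regions + 1):
            fr = frontiers[k - 1]
            fr.intersection_update({c for c in fr if labels[c] == 0})
            if not fr or assigned >= target:
                continue
            cands = sorted(fr)
            cell = cands[int(rng.integers(len(cands)))]
            fr.discard(cell)
            labels[cell] = k
            assigned += 1
            progressed = True
            for c in _neighbors4(*cell, cfg.nlat, cfg.nlon):
                if mask[c] and labels[c] == 0:
                    fr.add(c)
        if not progressed:
            break
    # fill single-cell background pinholes (every ocean 4-neighbor in one
    # region): random accretion artifacts, not meaningful background
    changed = True
    while changed:
        changed = False
        for i, j in ocean:
            if labels[i, j] != 0:
                continue
            nb = {labels[c] for c in _neighbors4(i, j, cfg.nlat, cfg.nlon) if mask[c]}
            if len(nb) == 1:
                k = nb.pop()
                if k > 0:
                    labels[i, j] = k
                    assigned += 1
                    changed = True

    if assigned < 0.5 * n_ocean:
        raise ValueError(
            f"could only cover {assigned}/{n_ocean} ocean cells; planted regions "
            "must cover at least 50% of the ocean"
        )

    jets = _trace_jets(labels, mask, cfg)
    return GroundTruth(
        label_map=labels, mask=mask, couplings=cfg.resolved_couplings(),
        jets=jets, seed=cfg.seed,
    )


def _trace_jets(labels: np.ndarray, mask: np.ndarray, cfg: SynthConfig) -> tuple:
    """One jet per adjacent region pair, on the two-cell interface band."""
    nlat, nlon = labels.shape
    band: dict = {}
    for i in range(nlat):
        for j in range(nlon):
            a = labels[i, j]
            if a <= 0:
                continue
            for c in _neighbors4(i, j, nlat, nlon):
                b = labels[c]
                if b > 0 and b != a:
                    key = (int(min(a, b)), int(max(a, b)))
                    band.setdefault(key, set()).update([(i, j), c])
    jets = []
    for key in sorted(band):
        cells = sorted(band[key])
        # greedy nearest-neighbour chain for a deterministic polyline ordering
        chain = [cells.pop(0)]
        while cells:
            last = chain[-1]
            nxt = min(cells, key=lambda c: (max(abs(c[0] - last[0]), abs(c[1] - last[1])), c))
            cells.remove(nxt)
            chain.append(nxt)
        jets.append(Jet(cells=tuple(chain), amplitude=cfg.jet_speed, regions=key))
    return tuple(jets)


def generate_latents(truth: GroundTruth, cfg: SynthConfig) -> np.ndarray:
    """Region latent signals, shape (n_regions, T), each standardized.

    Latents are unit-variance AR(1) processes; coupled targets are rebuilt as
    ``coef * source(t - lag) + sqrt(1 - coef^2) * own``, then re-standardized,
    so the planted lagged cross-correlation equals ``coef`` by construction.
    """
    R, T = truth.n_regions, cfg.n_months
    max_lag = max([abs(c.lag) for c in truth.couplings], default=0)
    n = T + _BURN + max_lag
    rng = _rng(cfg.seed, 1)
    eps = rng.standard_normal((R, n)) * np.sqrt(1.0 - cfg.ar1_coef**2)
    base = _sig.lfilter([1.0], [1.0, -cfg.ar1_coef], eps, axis=1)
    lat = base.copy()
    for c in truth.couplings:
        src = base[c.source - 1]
        own = base[c.target - 1]
        shifted = np.zeros(n)
        if c.lag >= 0:
            shifted[c.lag:] = src[: n - c.lag]
        else:
            shifted[: n + c.lag] = src[-c.lag:]
        lat[c.target - 1] = c.coef * shifted + np.sqrt(1.0 - c.coef**2) * own
    lat = lat[:, -T:]
    lat = lat - lat.mean(axis=1, keepdims=True)
    lat = lat / lat.std(axis=1, keepdims=True)
    return lat


def generate_sst(truth: GroundTruth, cfg: SynthConfig) -> GriddedField:
    """Monthly SST field: region latent + noise + seasonal cycle + trend.

    Cells of region k carry the (standardized) latent signal of k plus
    independent white noise of std 1/snr; background ocean cells carry
    independent noise of matching total variance.  Every ocean cell then
    receives the same 12-month sinusoid of amplitude ``seasonal_amp``, a
    linear trend of ``trend`` degC/yr and a 15 degC baseline.  Land is NaN.
    """
    if truth.label_map.shape != (cfg.nlat, cfg.nlon):
        raise ValueError("truth grid does not match config grid")
    T = cfg.n_months
    rng = _rng(cfg.seed, 2)
    latents = generate_latents(truth, cfg)
    noise = rng.standard_normal((T, cfg.nlat, cfg.nlon))

    vals = np.full((T, cfg.nlat, cfg.nlon), np.nan)
    bg_std = np.sqrt(1.0 + cfg.snr**-2)
    bg = truth.mask & (truth.label_map == 0)
    vals[:, bg] = noise[:, bg] * bg_std
    for k in range(1, truth.n_regions + 1):
        sel = truth.label_map == k
        vals[:, sel] = latents[k - 1][:, None] + noise[:, sel] / cfg.snr

    tindex = np.arange(T)
    months = cfg.time.month.to_numpy()
    seasonal = cfg.seasonal_amp * np.cos(2 * np.pi * (months - 8) / 12.0)
    trend = cfg.trend * tindex / 12.0
    vals[:, truth.mask] += (seasonal + trend + 15.0)[:, None]
    return GriddedField(vals, cfg.time, cfg.lat, cfg.lon, truth.mask, units="degC")


def generate_velocity(truth: GroundTruth, cfg: SynthConfig):
    """(u, v) fields with finite-width jets along planted boundaries.

    Jet cells (the boundary axis dilated ``jet_halfwidth`` times, emulating
    the finite cross-section of a boundary current) carry speed ``jet_speed``
    directed along the tangent of the nearest axis cell; the background ocean
    gets a random static direction and a speed of
    ``background_speed_fraction * jet_speed`` modulated per cell by U(0.5, 1.5).
    Both components receive 1% multiplicative temporal noise; land is NaN.
    """
    T = cfg.n_months
    rng = _rng(cfg.seed, 3)
    theta = rng.uniform(0, 2 * np.pi, size=(cfg.nlat, cfg.nlon))
    fac = rng.uniform(0.5, 1.5, size=(cfg.nlat, cfg.nlon))
    bg_speed = cfg.jet_speed * cfg.background_speed_fraction * fac
    u0 = bg_speed * np.cos(theta)
    v0 = bg_speed * np.sin(theta)
    axis_dir = {}
    for jet in truth.jets:
        chain = jet.cells
        for idx, cell in enumerate(chain):
            ref = chain[idx + 1] if idx + 1 < len(chain) else chain[idx - 1]
            dy, dx = ref[0] - cell[0], ref[1] - cell[1]
            norm = np.hypot(dx, dy)
            if norm == 0:
                dx, dy, norm = 1.0, 0.0, 1.0
            axis_dir[cell] = (dx / norm, dy / norm, jet.amplitude)
    if axis_dir:
        axis_cells = sorted(axis_dir)
        apts = np.array(axis_cells, dtype=float)
        jm = truth.jet_mask(cfg.jet_halfwidth)
        for cell in zip(*map(np.ndarray.tolist, np.nonzero(jm))):
            d2 = (apts[:, 0] - cell[0]) ** 2 + (apts[:, 1] - cell[1]) ** 2
            tx, ty, amp = axis_dir[axis_cells[int(np.argmin(d2))]]
            u0[cell] = amp * tx
            v0[cell] = amp * ty
    nu = 1.0 + 0.01 * rng.standard_normal((T, cfg.nlat, cfg.nlon))
    nv = 1.0 + 0.01 * rng.standard_normal((T, cfg.nlat, cfg.nlon))
    uu = np.where(truth.mask, u0, np.nan) * nu
    vv = np.where(truth.mask, v0, np.nan) * nv
    u = GriddedField(uu, cfg.time, cfg.lat, cfg.lon, truth.mask, units="m s-1")
    v = GriddedField(vv, cfg.time, cfg.lat, cfg.lon, truth.mask, units="m s-1")
    return u, v


# -- ground-truth serialization -----------------------------------------

def save_truth(truth: GroundTruth, json_path, labels_nc_path=None) -> None:
    """Write GroundTruth as JSON (+ optional NetCDF integer label map)."""
    payload = {
        "seed": truth.seed,
        "couplings": [asdict(c) for c in truth.couplings],
        "jets": [
            {"cells": [list(c) for c in j.cells], "amplitude": j.amplitude,
             "regions": list(j.regions)}
            for j in truth.jets
        ],
        "label_map": truth.label_map.tolist(),
        "mask": truth.mask.astype(int).tolist(),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, default=int)
    if labels_nc_path is not None:
        ds = xr.Dataset({
            "labels": (("lat", "lon"), truth.label_map.astype(np.int32)),
            "mask": (("lat", "lon"), truth.mask.astype(np.int8)),
        })
        ds.to_netcdf(labels_nc_path, engine="scipy")


def load_truth(json_path) -> GroundTruth:
    with open(json_path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        label_map=np.asarray(payload["label_map"], dtype=int),
        mask=np.asarray(payload["mask"], dtype=bool),
        couplings=tuple(Coupling(**c) for c in payload["couplings"]),
        jets=tuple(
            Jet(cells=tuple(tuple(c) for c in j["cells"]),
                amplitude=j["amplitude"], regions=tuple(j["regions"]))
            for j in payload["jets"]
        ),
        seed=payload["seed"],
    )
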