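"""Synthetic microwell-chip scenes with per-cell ground truth.

The simulator emulates the imaging side of a rare-cell enumeration assay on a
PDMS microwell array: nucleated cells settle into 30 um wells (about 1-2 cells
per well on average), the dominant population are CD45+ leukocytes with low
NeuN background, and a small CD45-/NeuN-high subpopulation of circulating
neural cells (CNCs) is present at a configurable prevalence.  Two imaging
rounds are modelled: a live round (2-NBDG glucose uptake + CD45 on unfixed
cells) and a fixed round (DAPI / NeuN-FITC / CD45-APC after fixation and
permeabilization).  Every simulated cell carries its true class, channel
amplitudes and viability, so downstream detection, gating and enumeration can
be scored against ground truth.

Cells are rendered as smoothed top-hat spots: a uniform disk of the marker's
amplitude with an erf-shaped edge of width ``psf_sigma_um``.  This keeps the
forward model honest for plateau-based photometry while making crowded wells
segmentable, and it reflects how a ~6 um nucleus looks at ~1 um/px sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import special
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InputError, PlacementError

# Channel names (fixed order recorded in the fixture sidecar).
CH_DAPI = "DAPI"
CH_NEUN = "NeuN_FITC"
CH_CD45 = "CD45_APC"
CH_NBDG = "NBDG"
CH_BRIGHT = "brightfield"

LIVE_ROUND = "live_round"
FIXED_ROUND = "fixed_round"

#: Channels rendered per acquisition round.  DAPI and NeuN only exist after
#: fixation/permeabilization; 2-NBDG only before it.
ROUND_CHANNELS: dict[str, tuple[str, ...]] = {
    LIVE_ROUND: (CH_CD45, CH_NBDG),
    FIXED_ROUND: (CH_DAPI, CH_NEUN, CH_CD45),
}

CLASS_LEUKOCYTE = "leukocyte"
CLASS_CNC = "cnc"
CLASS_DEBRIS = "debris"

TRUTH_COLUMNS = [
    "cell_id",
    "block_id",
    "well_id",
    "x_px",
    "y_px",
    "true_class",
    "is_live",
    "dapi_true",
    "neun_true",
    "cd45_true",
    "nbdg_true",
]

UINT16_MAX = 65535


# ---------------------------------------------------------------------------
# intensity distributions
# ---------------------------------------------------------------------------

def draw_dist(dist: Mapping[str, Any], size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` samples from a named intensity distribution.

    Supported kinds: ``lognormal`` (median, sigma on the log scale), ``normal``
    (mean, sd; clipped at 0) and ``constant`` (value).
    """
    kind = dist["kind"]
    if kind == "lognormal":
        return dist["median"] * np.exp(dist["sigma"] * rng.standard_normal(size))
    if kind == "normal":
        return np.clip(rng.normal(dist["mean"], dist["sd"], size), 0.0, None)
    if kind == "constant":
        return np.full(size, float(dist["value"]))
    raise ConfigurationError(f"unknown distribution kind: {kind!r}")


def dist_mean(dist: Mapping[str, Any]) -> float:
    """Linear-scale mean of a named distribution."""
    kind = dist["kind"]
    if kind == "lognormal":
        return dist["median"] * math.exp(dist["sigma"] ** 2 / 2.0)
    if kind == "normal":
        return float(dist["mean"])
    if kind == "constant":
        return float(dist["value"])
    raise ConfigurationError(f"unknown distribution kind: {kind!r}")


def dist_sd(dist: Mapping[str, Any]) -> float:
    """Linear-scale standard deviation of a named distribution."""
    kind = dist["kind"]
    if kind == "lognormal":
        s2 = dist["sigma"] ** 2
        return dist["median"] * math.sqrt(math.exp(s2) * (math.exp(s2) - 1.0))
    if kind == "normal":
        return float(dist["sd"])
    if kind == "constant":
        return 0.0
    raise ConfigurationError(f"unknown distribution kind: {kind!r}")


def dist_median(dist: Mapping[str, Any]) -> float:
    kind = dist["kind"]
    if kind == "lognormal":
        return float(dist["median"])
    if kind == "normal":
        return float(dist["mean"])
    if kind == "constant":
        return float(dist["value"])
    raise ConfigurationError(f"unknown distribution kind: {kind!r}")


def _validate_dist(name: str, dist: Mapping[str, Any], errors: list[str]) -> None:
    try:
        m = dist_mean(dist)
        s = dist_sd(dist)
    except (KeyError, ConfigurationError) as exc:
        errors.append(f"{name}: {exc}")
        return
    if m < 0 or s < 0:
        errors.append(f"{name}: intensity parameters must be nonnegative")


# ---------------------------------------------------------------------------
# chip layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipLayout:
    """Geometry of the microwell array shared by simulator and quantifier.

    The default is a desk-scale chip: 100 blocks of 64 wells (6,400 wells) with
    30 um wells on a 40 um square pitch, imaged at 1 um/px.  The physical
    device geometry (30 um diameter, 20 um depth) follows the assay; the full
    ~112,000-well chip is reachable through configuration, block analysis at
    100 blocks being the granularity that matters downstream.
    """

    block_grid: tuple[int, int] = (10, 10)
    well_grid: tuple[int, int] = (8, 8)
    well_diameter_um: float = 30.0
    well_depth_um: float = 20.0
    well_pitch_um: float = 40.0
    pixel_size_um: float = 1.0
    block_gap_um: float = 40.0
    margin_um: float = 40.0

    def __post_init__(self):
        errors = []
        for name in ("well_diameter_um", "well_depth_um", "well_pitch_um",
                     "pixel_size_um", "block_gap_um", "margin_um"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        for name in ("block_grid", "well_grid"):
            grid = getattr(self, name)
            if len(grid) != 2 or any(int(g) != g or g < 1 for g in grid):
                errors.append(f"{name} must be a pair of positive integers")
        if self.well_pitch_um < self.well_diameter_um:
            errors.append(
                "well_pitch_um must be >= well_diameter_um (wells must not overlap)"
            )
        if errors:
            raise ConfigurationError("invalid layout: " + "; ".join(errors))
        object.__setattr__(self, "block_grid", tuple(int(g) for g in self.block_grid))
        object.__setattr__(self, "well_grid", tuple(int(g) for g in self.well_grid))

    # -- derived geometry ---------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return self.block_grid[0] * self.block_grid[1]

    @property
    def wells_per_block(self) -> int:
        return self.well_grid[0] * self.well_grid[1]

    @property
    def total_wells(self) -> int:
        return self.n_blocks * self.wells_per_block

    @property
    def pitch_px(self) -> float:
        return self.well_pitch_um / self.pixel_size_um

    @property
    def well_radius_px(self) -> float:
        return self.well_diameter_um / 2.0 / self.pixel_size_um

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered scene covering the whole array."""
        br, bc = self.block_grid
        wr, wc = self.well_grid
        gap = self.block_gap_um / self.pixel_size_um
        margin = self.margin_um / self.pixel_size_um
        height = 2 * margin + br * wr * self.pitch_px + (br - 1) * gap
        width = 2 * margin + bc * wc * self.pitch_px + (bc - 1) * gap
        return int(round(height)), int(round(width))

    def well_centers(self) -> pd.DataFrame:
        """Well center coordinates: columns block_id, well_id, x_px, y_px.

        Coordinates are 0-based pixel indices, origin at the top-left corner,
        x = column and y = row.  Wells tile each block on a regular square
        grid; ordering is row-major in blocks, then row-major in wells.
        """
        br, bc = self.block_grid
        wr, wc = self.well_grid
        pitch = self.pitch_px
        gap = self.block_gap_um / self.pixel_size_um
        margin = self.margin_um / self.pixel_size_um
        block_h = wr * pitch
        block_w = wc * pitch

        rows = []
        for bi in range(br):
            for bj in range(bc):
                block_id = bi * bc + bj
                y0 = margin + bi * (block_h + gap)
                x0 = margin + bj * (block_w + gap)
                for wi in range(wr):
                    for wj in range(wc):
                        rows.append((
                            block_id,
                            wi * wc + wj,
                            x0 + (wj + 0.5) * pitch,
                            y0 + (wi + 0.5) * pitch,
                        ))
        return pd.DataFrame(rows, columns=["block_id", "well_id", "x_px", "y_px"])


def _near_square_grid(n: int) -> tuple[int, int]:
    for r in range(int(math.isqrt(n)), 0, -1):
        if n % r == 0:
            return (r, n // r)
    raise ConfigurationError(f"cannot factor {n} into a grid")  # pragma: no cover


_LAYOUT_FIELDS = {
    "block_grid", "well_grid", "well_diameter_um", "well_depth_um",
    "well_pitch_um", "pixel_size_um", "block_gap_um", "margin_um",
}


def build_layout(config: Mapping[str, Any] | None = None, **overrides: Any) -> ChipLayout:
    """Build a :class:`ChipLayout` from a configuration mapping.

    Accepts either explicit ``block_grid`` / ``well_grid`` pairs or scalar
    ``n_blocks`` / ``wells_per_block`` counts, which are factorized into a
    near-square grid.  Inconsistent or unknown fields raise
    :class:`ConfigurationError` naming the offenders.
    """
    cfg = dict(config or {})
    cfg.update(overrides)

    block_grid = cfg.pop("block_grid", None)
    well_grid = cfg.pop("well_grid", None)
    n_blocks = cfg.pop("n_blocks", None)
    wells_per_block = cfg.pop("wells_per_block", None)

    if block_grid is not None:
        block_grid = tuple(int(g) for g in block_grid)
        if n_blocks is not None and block_grid[0] * block_grid[1] != int(n_blocks):
            raise ConfigurationError(
                f"n_blocks={n_blocks} does not match block_grid={block_grid}"
            )
    elif n_blocks is not None:
        block_grid = _near_square_grid(int(n_blocks))

    if well_grid is not None:
        well_grid = tuple(int(g) for g in well_grid)
        if wells_per_block is not None and well_grid[0] * well_grid[1] != int(wells_per_block):
            raise ConfigurationError(
                f"wells_per_block={wells_per_block} does not match well_grid={well_grid}"
            )
    elif wells_per_block is not None:
        well_grid = _near_square_grid(int(wells_per_block))

    unknown = set(cfg) - _LAYOUT_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown layout fields: {sorted(unknown)}")
    kwargs = dict(cfg)
    if block_grid is not None:
        kwargs["block_grid"] = block_grid
    if well_grid is not None:
        kwargs["well_grid"] = well_grid
    return ChipLayout(**kwargs)


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

def _d(**kw: Any) -> dict:
    return dict(kw)


@dataclass
class PopulationModel:
    """Statistical model of the cell population loaded onto a chip.

    Defaults reflect the assay's study conditions: Poisson occupancy with a
    mean of 1.5 cells/well (midpoint of the stated 1-2 cells per well), a
    dominant CD45+ leukocyte population with low NeuN background, a rare
    CD45-/NeuN-high CNC subpopulation at 19% prevalence (the mouse-chip
    scale; the patient-scale 2% is a configuration away), a 60.4% live
    (2-NBDG+) fraction among CNCs, and a small DAPI- debris class.  Intensity
    laws are log-normal (fluorescence intensities are right-skewed and
    nonnegative), in arbitrary units on a 16-bit scale.
    """

    mean_cells_per_well: float = 1.5
    cnc_prevalence: float = 0.19
    live_fraction: float = 0.604
    leuko_live_fraction: float = 0.95
    debris_rate: float = 0.02

    leuko_neun_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=100.0, sigma=0.25))
    cnc_neun_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=900.0, sigma=0.35))
    leuko_cd45_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=1500.0, sigma=0.30))
    cnc_cd45_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=25.0, sigma=0.50))
    dapi_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=1200.0, sigma=0.25))
    nbdg_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=600.0, sigma=0.35))
    debris_dapi_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=10.0, sigma=0.60))
    debris_offtarget_dist: dict = field(default_factory=lambda: _d(kind="lognormal", median=15.0, sigma=0.50))

    background_level: float = 100.0
    read_noise_sd: float = 5.0
    psf_sigma_um: float = 0.75
    spot_radius_um: float = 3.0
    cell_diameter_um: float = 9.0
    round_jitter_px: int = 0

    def __post_init__(self):
        errors: list[str] = []
        if self.mean_cells_per_well < 0:
            errors.append("mean_cells_per_well must be >= 0")
        for name in ("cnc_prevalence", "live_fraction", "leuko_live_fraction", "debris_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1]")
        for name in ("background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("psf_sigma_um", "spot_radius_um", "cell_diameter_um"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.round_jitter_px < 0:
            errors.append("round_jitter_px must be >= 0")
        for name in ("leuko_neun_dist", "cnc_neun_dist", "leuko_cd45_dist",
                     "cnc_cd45_dist", "dapi_dist", "nbdg_dist",
                     "debris_dapi_dist", "debris_offtarget_dist"):
            _validate_dist(name, getattr(self, name), errors)
        if not errors:
            # Self-consistency: the CNC NeuN law must sit above the leukocyte
            # mean + 3 SD, otherwise the anchored gate cannot separate classes.
            cutoff = dist_mean(self.leuko_neun_dist) + 3.0 * dist_sd(self.leuko_neun_dist)
            if dist_median(self.cnc_neun_dist) <= cutoff:
                errors.append(
                    "central mass of cnc_neun_dist must lie above the leukocyte "
                    f"NeuN mean + 3 SD ({cutoff:.1f})"
                )
        if errors:
            raise ConfigurationError("invalid population model: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ground-truth sampling
# ---------------------------------------------------------------------------

def _uniform_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _place_points(k: int, radius: float, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Place ``k`` cell centers in a disk with pairwise separation >= min_sep.

    Cells in a monolayer exclude each other physically, so the separation
    constraint is real; it is relaxed progressively only when a drawn count
    cannot be packed, keeping per-well counts exactly Poisson.
    """
    if k == 0:
        return np.empty((0, 2))
    if k <= 3:
        pts: list[np.ndarray] = []
        for _ in range(k):
            sep = min_sep
            placed = False
            for attempt in range(200):
                if attempt == 100:
                    sep *= 0.7
                elif attempt == 150:
                    sep *= 0.7
                cand = _uniform_disk(1, radius, rng)[0]
                if all(np.hypot(*(cand - p)) >= sep for p in pts):
                    pts.append(cand)
                    placed = True
                    break
            if not placed:  # pathologically tight; accept the last candidate
                pts.append(cand)
        return np.asarray(pts)

    # Crowded well: jittered center + ring template, randomly rotated.
    ring_n = k - 1
    ring_r = min(radius, max(min_sep * 1.1, min_sep / (2.0 * math.sin(math.pi / ring_n) + 1e-9)))
    ring_r = min(ring_r, radius)
    theta0 = 2.0 * np.pi * rng.random()
    angles = theta0 + 2.0 * np.pi * np.arange(ring_n) / ring_n
    pts_arr = np.zeros((k, 2))
    pts_arr[1:, 0] = ring_r * np.cos(angles)
    pts_arr[1:, 1] = ring_r * np.sin(angles)
    pts_arr += rng.normal(0.0, 0.3, pts_arr.shape)
    # keep inside the disk
    norm = np.hypot(pts_arr[:, 0], pts_arr[:, 1])
    over = norm > radius
    if over.any():
        pts_arr[over] *= (radius / norm[over])[:, None]
    return pts_arr


def sample_population(
    layout: ChipLayout,
    model: PopulationModel,
    seed: int | np.random.SeedSequence | np.random.Generator,
    exact_n_cnc: int | None = None,
) -> pd.DataFrame:
    """Draw a ground-truth cell table for one chip.

    Per-well counts are Poisson with ``model.mean_cells_per_well``; each
    non-debris cell is a CNC with probability ``model.cnc_prevalence``
    (independently), unless ``exact_n_cnc`` requests a spike-in experiment
    with an exact number of true CNCs.  Identical seed => identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = layout.well_centers()
    counts = rng.poisson(model.mean_cells_per_well, len(centers))

    place_radius = max(layout.well_radius_px - model.spot_radius_um / layout.pixel_size_um, 1.0)
    min_sep = model.cell_diameter_um / layout.pixel_size_um

    block_ids: list[int] = []
    well_ids: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    cw = centers[["block_id", "well_id", "x_px", "y_px"]].to_numpy()
    for i in np.nonzero(counts)[0]:
        k = int(counts[i])
        offsets = _place_points(k, place_radius, min_sep, rng)
        bid, wid, cx, cy = cw[i]
        block_ids.extend([int(bid)] * k)
        well_ids.extend([int(wid)] * k)
        xs.extend((cx + offsets[:, 0]).tolist())
        ys.extend((cy + offsets[:, 1]).tolist())

    n = len(xs)
    is_debris = rng.random(n) < model.debris_rate
    non_debris_idx = np.nonzero(~is_debris)[0]

    is_cnc = np.zeros(n, dtype=bool)
    if exact_n_cnc is None:
        is_cnc[non_debris_idx] = rng.random(len(non_debris_idx)) < model.cnc_prevalence
    else:
        if exact_n_cnc > len(non_debris_idx):
            raise ConfigurationError(
                f"exact_n_cnc={exact_n_cnc} exceeds the {len(non_debris_idx)} "
                "non-debris cells available"
            )
        if exact_n_cnc > 0:
            chosen = rng.choice(non_debris_idx, size=exact_n_cnc, replace=False)
            is_cnc[chosen] = True

    true_class = np.where(is_debris, CLASS_DEBRIS,
                          np.where(is_cnc, CLASS_CNC, CLASS_LEUKOCYTE))
    is_leuko = ~is_debris & ~is_cnc

    live_draw = rng.random(n)
    is_live = pd.array([pd.NA] * n, dtype="boolean")
    is_live[is_cnc] = live_draw[is_cnc] < model.live_fraction
    is_live[is_leuko] = live_draw[is_leuko] < model.leuko_live_fraction

    dapi = np.where(is_debris, draw_dist(model.debris_dapi_dist, n, rng),
                    draw_dist(model.dapi_dist, n, rng))
    off = draw_dist(model.debris_offtarget_dist, n, rng)
    neun = np.where(is_cnc, draw_dist(model.cnc_neun_dist, n, rng),
                    np.where(is_leuko, draw_dist(model.leuko_neun_dist, n, rng), off))
    cd45 = np.where(is_cnc, draw_dist(model.cnc_cd45_dist, n, rng),
                    np.where(is_leuko, draw_dist(model.leuko_cd45_dist, n, rng), off))
    nbdg = draw_dist(model.nbdg_dist, n, rng)
    live_mask = (is_live == True).to_numpy(dtype=bool, na_value=False)  # noqa: E712
    nbdg = np.where(live_mask, nbdg, 0.0)

    truth = pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in range(n)],
        "block_id": np.asarray(block_ids, dtype=int),
        "well_id": np.asarray(well_ids, dtype=int),
        "x_px": np.asarray(xs),
        "y_px": np.asarray(ys),
        "true_class": true_class,
        "is_live": is_live,
        "dapi_true": dapi,
        "neun_true": neun,
        "cd45_true": cd45,
        "nbdg_true": nbdg,
    })
    return truth[TRUTH_COLUMNS]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneImage:
    """A rendered multichannel scene for one acquisition round.

    ``channels`` maps channel name to a 2-D uint16 grid; all grids share the
    same dimensions and the channel set is fixed by the round.
    """

    channels: dict[str, np.ndarray]
    round_id: str
    layout: ChipLayout

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise InputError(f"channel {name!r} not present in {self.round_id} image")
        return self.channels[name]


_CHANNEL_AMPLITUDE_COLUMN = {
    CH_DAPI: "dapi_true",
    CH_NEUN: "neun_true",
    CH_CD45: "cd45_true",
    CH_NBDG: "nbdg_true",
}


def render_images(
    truth: pd.DataFrame,
    layout: ChipLayout,
    model: PopulationModel,
    round_id: str,
    seed: int | np.random.SeedSequence | np.random.Generator,
    include_brightfield: bool = False,
) -> SceneImage:
    """Render one acquisition round as a multichannel 16-bit scene.

    Each cell becomes a smoothed top-hat spot (disk radius
    ``model.spot_radius_um``, erf edge of width ``model.psf_sigma_um``) whose
    plateau equals the cell's true amplitude in that channel, on a flat
    background with additive Gaussian read noise, clipped to the 16-bit range.
    Seed-deterministic.
    """
    if round_id not in ROUND_CHANNELS:
        raise InputError(f"unknown round_id {round_id!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = layout.image_shape

    x = truth["x_px"].to_numpy(float)
    y = truth["y_px"].to_numpy(float)
    if round_id == LIVE_ROUND and model.round_jitter_px > 0 and len(x):
        j = model.round_jitter_px
        x = x + rng.integers(-j, j + 1, len(x))
        y = y + rng.integers(-j, j + 1, len(y))

    r0 = model.spot_radius_um / layout.pixel_size_um
    sig = model.psf_sigma_um / layout.pixel_size_um
    reach = r0 + 4.0 * sig
    if len(x):
        out = (x < reach) | (x > shape[1] - 1 - reach) | (y < reach) | (y > shape[0] - 1 - reach)
        if out.any():
            bad = truth["cell_id"].to_numpy()[out][:5]
            raise PlacementError(
                f"{int(out.sum())} cell(s) outside renderable bounds, e.g. {list(bad)}"
            )

    rpatch = int(math.ceil(reach)) + 1
    sq2sig = math.sqrt(2.0) * sig
    channels: dict[str, np.ndarray] = {}
    for ch in ROUND_CHANNELS[round_id]:
        amps = truth[_CHANNEL_AMPLITUDE_COLUMN[ch]].to_numpy(float)
        canvas = np.full(shape, model.background_level, dtype=np.float32)
        for i in np.nonzero(amps > 0)[0]:
            cx, cy = x[i], y[i]
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = ix - rpatch, ix + rpatch + 1
            y0, y1 = iy - rpatch, iy + rpatch + 1
            gy, gx = np.mgrid[y0:y1, x0:x1]
            d = np.hypot(gx - cx, gy - cy)
            profile = 0.5 * special.erfc((d - r0) / sq2sig)
            canvas[y0:y1, x0:x1] += (amps[i] * profile).astype(np.float32)
        if model.read_noise_sd > 0:
            canvas += model.read_noise_sd * rng.standard_normal(shape, dtype=np.float32)
        np.clip(canvas, 0, UINT16_MAX, out=canvas)
        channels[ch] = np.rint(canvas).astype(np.uint16)

    if include_brightfield:
        bf = np.full(shape, 30000.0, dtype=np.float32)
        if model.read_noise_sd > 0:
            bf += model.read_noise_sd * rng.standard_normal(shape, dtype=np.float32)
        channels[CH_BRIGHT] = np.rint(np.clip(bf, 0, UINT16_MAX)).astype(np.uint16)

    return SceneImage(channels=channels, round_id=round_id, layout=layout)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    truth: pd.DataFrame,
    images: Sequence[SceneImage],
    path: str | Path,
    model: PopulationModel | None = None,
) -> dict[str, str]:
    """Write a simulated chip to disk: one multipage TIFF per round, the truth
    CSV and a JSON sidecar recording layout, model and channel order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    layout = images[0].layout if images else None

    rounds_meta: dict[str, dict] = {}
    written: dict[str, str] = {}
    for img in images:
        fname = f"{img.round_id}.tif"
        order = list(img.channels)
        stack = np.stack([img.channels[c] for c in order])
        tifffile.imwrite(path / fname, stack, photometric="minisblack")
        rounds_meta[img.round_id] = {"file": fname, "channels": order}
        written[img.round_id] = str(path / fname)

    truth.to_csv(path / "truth.csv", index=False)
    written["truth"] = str(path / "truth.csv")

    meta = {
        "layout": asdict(layout) if layout is not None else None,
        "model": model.to_dict() if model is not None else None,
        "rounds": rounds_meta,
        "truth_columns": TRUTH_COLUMNS,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    written["meta"] = str(path / "meta.json")
    return written


def read_fixture(path: str | Path):
    """Read a fixture written by :func:`write_fixture`.

    Returns ``(truth, images, layout, model)`` where ``images`` maps round_id
    to :class:`SceneImage` and ``model`` may be None if it was not recorded.
    """
    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    layout_dict = meta["layout"]
    if layout_dict is not None:
        layout_dict["block_grid"] = tuple(layout_dict["block_grid"])
        layout_dict["well_grid"] = tuple(layout_dict["well_grid"])
        layout = ChipLayout(**layout_dict)
    else:
        layout = None
    model = PopulationModel(**meta["model"]) if meta.get("model") else None

    truth = pd.read_csv(path / "truth.csv", dtype={"is_live": "boolean"})
    truth["cell_id"] = truth["cell_id"].astype(str)

    images: dict[str, SceneImage] = {}
    for round_id, rmeta in meta["rounds"].items():
        stack = tifffile.imread(path / rmeta["file"])
        if stack.ndim == 2:
            stack = stack[None]
        channels = {name: stack[i] for i, name in enumerate(rmeta["channels"])}
        images[round_id] = SceneImage(channels=channels, round_id=round_id, layout=layout)
    return truth, images, layout, model


# ---------------------------------------------------------------------------
# truth-based scoring helpers
# ---------------------------------------------------------------------------

def match_to_truth(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance: float = 3.0,
) -> pd.Series:
    """For each detected record, the cell_id of the nearest truth cell within
    ``tolerance`` pixels (NA when none).  Index follows ``records``."""
    if len(truth) == 0 or len(records) == 0:
        return pd.Series([pd.NA] * len(records), index=records.index, dtype="object")
    tree = cKDTree(truth[["x_px", "y_px"]].to_numpy(float))
    dist, idx = tree.query(records[["x_px", "y_px"]].to_numpy(float))
    matched = np.where(dist <= tolerance, truth["cell_id"].to_numpy()[idx], None)
    return pd.Series(matched, index=records.index, dtype="object")


def detection_scores(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance: float = 3.0,
    classes: tuple[str, ...] = (CLASS_LEUKOCYTE, CLASS_CNC),
) -> dict[str, float]:
    """Recall/precision of detected records against simulator truth.

    Recall is computed over truth cells of the given classes (debris is
    excluded by default: it is DAPI-dim by construction and not a detection
    target); precision counts records with any truth neighbour within
    tolerance.
    """
    target = truth[truth["true_class"].isin(classes)]
    n_truth = len(target)
    if len(records):
        rec_xy = records[["x_px", "y_px"]].to_numpy(float)
        hit = np.zeros(len(records), dtype=bool)
        if len(truth):
            tree = cKDTree(truth[["x_px", "y_px"]].to_numpy(float))
            dist, _ = tree.query(rec_xy)
            hit = dist <= tolerance
        precision = float(hit.mean())
        if n_truth:
            rtree = cKDTree(rec_xy)
            dist, _ = rtree.query(target[["x_px", "y_px"]].to_numpy(float))
            recall = float((dist <= tolerance).mean())
        else:
            recall = float("nan")
    else:
        precision = float("nan")
        recall = 0.0 if n_truth else float("nan")
    return {"recall": recall, "precision": precision,
            "n_truth": n_truth, "n_records": len(records)}
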