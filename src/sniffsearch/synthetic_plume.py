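"""Synthetic per-sniff detection-rate maps.

Turbulent odor plumes produce sparse, binary detection events: at each
sniff the odor concentration either exceeds the agent's threshold or it
does not. Averaged over realizations of the flow, this yields a static
*detection rate map* r(x, y) — the per-sniff probability of a
supra-threshold detection at each position relative to the source, one
map per sensing modality. Airborne plumes extend farther downwind and
wider crosswind than ground-level plumes, because odor near the ground is
depleted by surface adsorption and confined by the boundary layer.

This module builds such maps in closed form (separable downwind x
crosswind profiles), produces matched air/ground pairs with the air map
strictly containing the ground map, perturbs maps (rescaling, meander)
for robustness experiments, and draws the Bernoulli sniff observations
an agent would experience.

Coordinates are source-relative: x increases downwind (an agent downwind
of the source has x > 0), y is crosswind. Grid cell (i, j) has its
downwind center at (i - i0 + 0.5) * cell_size and its crosswind center at
(j - j0) * cell_size, where (i0, j0) is the source cell ``origin``; the
plume occupies x > 0 and is symmetric about y = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PlumeParams",
    "DetectionRateMap",
    "make_separable_map",
    "make_dns_like_pair",
    "perturb_map",
    "sample_observation",
    "isoline_extent",
]


@dataclass(frozen=True)
class PlumeParams:
    """Geometry of a separable plume detection-rate profile.

    Parameters
    ----------
    x_thr
        Downwind detection range (m): detections possible for 0 < x < x_thr.
    y_thr
        Crosswind width scale (m). For the Gaussian profile this is the
        standard deviation of g(y); for the rectangular profile the full
        crosswind extent.
    peak_rate
        Per-sniff detection probability in the plume core, in (0, 1].
    shape
        ``separable_gaussian`` — r(x, y) = peak * f(x) * exp(-y^2 / 2 y_thr^2)
        with f(x) = 1 on 0 < x < x_thr;
        ``rectangular`` — uniform peak rate on the x_thr-by-y_thr box.
    """

    x_thr: float
    y_thr: float
    peak_rate: float = 0.5
    shape: str = "separable_gaussian"

    def __post_init__(self) -> None:
        if not self.x_thr > 0:
            raise ValueError(f"x_thr must be positive, got {self.x_thr}")
        if not self.y_thr > 0:
            raise ValueError(f"y_thr must be positive, got {self.y_thr}")
        if not 0 < self.peak_rate <= 1:
            raise ValueError(f"peak_rate must lie in (0, 1], got {self.peak_rate}")
        if self.shape not in ("separable_gaussian", "rectangular"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class DetectionRateMap:
    """Gridded per-sniff detection probability for one sensing modality.

    ``values`` has shape ``grid_shape = (n_x, n_y)``; entry (i, j) is the
    probability that a single sniff at displacement (i, j) relative to the
    source cell ``origin`` yields a detection. ``modality`` is ``"air"``
    or ``"ground"``.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[int, int]
    modality: str = "air"
    params: PlumeParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("detection probabilities must lie in [0, 1]")
        i0, j0 = self.origin
        n_x, n_y = vals.shape
        if not (0 <= i0 < n_x and 0 <= j0 < n_y):
            raise ValueError(f"origin {self.origin} outside grid {vals.shape}")
        if self.modality not in ("air", "ground"):
            raise ValueError(f"modality must be 'air' or 'ground', got {self.modality!r}")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Source-relative coordinates (m) of cell centers, as 1-D arrays.

        Downwind centers sit at (i - i0 + 0.5) h so the source cell's body
        lies just inside the plume (0 < x < x_thr starts at the source);
        crosswind centers at (j - j0) h so the plume axis passes through
        cell centers and the profile is symmetric about it.
        """
        n_x, n_y = self.values.shape
        i0, j0 = self.origin
        x = (np.arange(n_x) - i0 + 0.5) * self.cell_size
        y = (np.arange(n_y) - j0) * self.cell_size
        return x, y

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the map as a CSV matrix plus a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        meta = {
            "cell_size": self.cell_size,
            "origin": list(self.origin),
            "modality": self.modality,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "DetectionRateMap":
        path = Path(path)
        values = np.atleast_2d(np.loadtxt(path, delimiter=","))
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            values=values,
            cell_size=meta["cell_size"],
            origin=tuple(meta["origin"]),
            modality=meta["modality"],
        )


def _profile(params: PlumeParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate peak * f(x) * g(y) on the outer product of coordinates."""
    f = ((x > 0) & (x < params.x_thr)).astype(float)
    if params.shape == "separable_gaussian":
        g = np.exp(-(y**2) / (2.0 * params.y_thr**2))
    else:  # rectangular
        g = (np.abs(y) <= params.y_thr / 2.0).astype(float)
    return params.peak_rate * np.outer(f, g)


def make_separable_map(
    params: PlumeParams,
    grid_shape: tuple[int, int],
    cell_size: float,
    origin: tuple[int, int] | None = None,
    modality: str = "air",
) -> DetectionRateMap:
    """Build a separable detection-rate map r(x, y) = peak * f(x) * g(y).

    f(x) is the indicator of the downwind band 0 < x < x_thr and g(y) is
    either a Gaussian of width y_thr or the indicator of |y| <= y_thr / 2,
    evaluated at cell centers. ``origin`` defaults to the upwind quarter
    of the grid, centered crosswind, leaving room for the plume downwind.
    """
    n_x, n_y = grid_shape
    if origin is None:
        origin = (n_x // 4, n_y // 2)
    stub = DetectionRateMap(
        values=np.zeros(grid_shape), cell_size=cell_size, origin=origin, modality=modality
    )
    x, y = stub.cell_centers()
    if params.x_thr > x[-1] + cell_size / 2:
        raise ValueError(
            f"grid extends only {x[-1] + cell_size / 2:.3g} m downwind of the "
            f"source; cannot contain x_thr={params.x_thr:.3g} m"
        )
    return replace(stub, values=_profile(params, x, y), params=params)


def make_dns_like_pair(
    air: PlumeParams,
    ground: PlumeParams,
    grid_shape: tuple[int, int],
    cell_size: float,
    origin: tuple[int, int] | None = None,
) -> tuple[DetectionRateMap, DetectionRateMap]:
    """Matched (air, ground) maps on one grid, air plume at least as large.

    Emulates the key feature of turbulence-resolved plume statistics: the
    region where airborne odor is detectable extends farther downwind and
    at least as wide crosswind as the region of detectable ground odor,
    because odor is adsorbed at the surface. Any isoline of the air map
    therefore encloses at least the area of the same isoline of the
    ground map.
    """
    if not (air.x_thr >= ground.x_thr and air.y_thr >= ground.y_thr):
        raise ValueError(
            "air plume must be at least as long (x_thr) and as wide (y_thr) "
            f"as the ground plume; got air={air}, ground={ground}"
        )
    air_map = make_separable_map(air, grid_shape, cell_size, origin, modality="air")
    ground_map = make_separable_map(
        ground, grid_shape, cell_size, air_map.origin, modality="ground"
    )
    return air_map, ground_map


def default_pair_params(
    prior_length: float, air_peak: float = 0.3, ground_peak: float = 0.6
) -> tuple[PlumeParams, PlumeParams]:
    """Default air/ground plume geometry for a prior of given length (m).

    The DNS-derived isolines fix only ratios, not closed forms; these
    defaults place the air plume's reach at 60% of the prior length and
    the ground plume's at 10%, with the ground plume half as wide and a
    higher core rate (ground odor is smoother and more reliably above
    threshold near the source, airborne odor sparser but farther-reaching).
    """
    air = PlumeParams(x_thr=0.6 * prior_length, y_thr=0.05 * prior_length,
                      peak_rate=air_peak)
    ground = PlumeParams(x_thr=0.1 * prior_length, y_thr=0.025 * prior_length,
                         peak_rate=ground_peak)
    return air, ground


def perturb_map(
    base: DetectionRateMap,
    mode: str,
    magnitude: float,
    frequency: float = 0.0,
    t: float = 0.0,
) -> DetectionRateMap:
    """Perturbed copy of a map for robustness tests.

    ``rescale`` stretches the plume isotropically: the returned map takes
    at (x, y) the base value at (x / magnitude, y / magnitude), which
    multiplies both x_thr and y_thr by ``magnitude``. ``meander`` rotates
    the map rigidly about the source by angle
    ``magnitude * sin(2 pi frequency t)`` radians. Both use nearest-cell
    resampling; cells mapping outside the base grid get rate zero and the
    result is clipped to [0, 1].
    """
    if mode not in ("rescale", "meander"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if mode == "rescale" and not magnitude > 0:
        raise ValueError("rescale magnitude must be positive")
    if mode == "meander" and frequency < 0:
        raise ValueError("meander frequency must be nonnegative")

    x, y = base.cell_centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    if mode == "rescale":
        if magnitude == 1.0:
            return base
        Xs, Ys = X / magnitude, Y / magnitude
    else:
        theta = magnitude * np.sin(2.0 * np.pi * frequency * t)
        if theta == 0.0:
            return base
        c, s = np.cos(-theta), np.sin(-theta)  # inverse rotation of coords
        Xs, Ys = c * X - s * Y, s * X + c * Y

    i0, j0 = base.origin
    h = base.cell_size
    # invert the cell-center conventions: x = (i - i0 + 0.5) h, y = (j - j0) h
    ii = np.floor(Xs / h).astype(int) + i0
    jj = np.round(Ys / h).astype(int) + j0
    n_x, n_y = base.grid_shape
    inside = (ii >= 0) & (ii < n_x) & (jj >= 0) & (jj < n_y)
    vals = np.zeros_like(base.values)
    vals[inside] = base.values[ii[inside], jj[inside]]
    return replace(base, values=np.clip(vals, 0.0, 1.0), params=None)


def sample_observation(
    rate_map: DetectionRateMap, state: tuple[int, int], rng: np.random.Generator
) -> str:
    """One Bernoulli sniff at grid cell ``state``.

    Detections per sniff are independent with probability equal to the
    map value at the agent's position (memoryless detection model: the
    mean rate matches the plume statistics, temporal correlations do not).
    """
    i, j = state
    n_x, n_y = rate_map.grid_shape
    if not (0 <= i < n_x and 0 <= j < n_y):
        raise ValueError(f"state {state} outside grid {rate_map.grid_shape}")
    return "detection" if rng.random() < rate_map.values[i, j] else "no_detection"


def isoline_extent(rate_map: DetectionRateMap, level: float) -> tuple[float, float]:
    """Bounding box (m) of the region where r >= level * max(r).

    Returns (downwind extent, crosswind extent) of the superlevel set,
    measured as span of the contributing cells including their width, so
    a rectangular plume of aligned dimensions returns exactly
    (x_thr, y_thr). An empty region gives (0.0, 0.0).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    peak = rate_map.values.max()
    mask = rate_map.values >= level * peak if peak > 0 else np.zeros_like(rate_map.values, bool)
    if not mask.any():
        return 0.0, 0.0
    x, y = rate_map.cell_centers()
    ix, jy = np.nonzero(mask)
    h = rate_map.cell_size
    return (x[ix.max()] - x[ix.min()] + h, y[jy.max()] - y[jy.min()] + h)
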