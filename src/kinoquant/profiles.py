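"""Tip-registered intensity profiling along kinocilia.

Implements the fluorescence-distribution measurement used for ciliary
protein localization: fixed-step (0.064 um) line profiles sampled on the
maximum Z-projection with a 2-pixel line width, a 32 um minimum-length
eligibility filter, registration of all profiles at the distal tip over a
32 um window (501 samples), position-wise averaging, min-max rescaling to
0-100, a log2(1 + x) transform, and a Loess smooth.  A regionalization
index (normalized intensity centroid) turns the qualitative
uniform / middle-proximal / distal pattern classes into a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthetic import VoxelGrid
from .tracing import TracedPath

__all__ = [
    "PROFILE_STEP_UM",
    "WINDOW_UM",
    "IntensityProfile",
    "RegisteredEnsemble",
    "AveragedProfile",
    "DegenerateProfileError",
    "max_project",
    "sample_profile",
    "filter_measurable",
    "register_distal",
    "average_rescale_log",
    "loess_fit",
    "regionalization_index",
    "path_to_polyline",
    "profile_stack",
]

#: Arc-length sampling step along a profile (um), the lateral pixel pitch.
PROFILE_STEP_UM = 0.064
#: Distal window over which profiles are registered and averaged (um).
WINDOW_UM = 32.0

_EPS = 1e-9


class DegenerateProfileError(ValueError):
    """The averaged profile is perfectly flat; min-max rescaling is undefined."""


@dataclass
class IntensityProfile:
    """Gray values of one kinocilium at fixed arc-length steps from the base."""

    kinocilium_id: str
    positions: np.ndarray   # um from base, strictly increasing, step 0.064
    values: np.ndarray      # mean gray values, >= 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be matching 1D arrays")
        if len(self.positions) > 1:
            steps = np.diff(self.positions)
            if np.any(np.abs(steps - steps[0]) > 1e-6) or steps[0] <= 0:
                raise ValueError("positions must increase with a constant step")
        if np.any(self.values < 0):
            raise ValueError("gray values must be >= 0")

    @property
    def length_um(self) -> float:
        return float(self.positions[-1])

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class RegisteredEnsemble:
    """Distal-aligned profile matrix: K kinocilia x 501 window positions.

    Column 0 is the proximal end of the 32 um window and the last column is
    the distal-most tip of every kinocilium.
    """

    matrix: np.ndarray
    kinocilium_ids: list[str]
    window_um: float = WINDOW_UM
    step_um: float = PROFILE_STEP_UM

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        expected = int(round(self.window_um / self.step_um)) + 1
        if self.matrix.shape[1] != expected:
            raise ValueError(f"registered rows must have {expected} columns, "
                             f"got {self.matrix.shape[1]}")
        if len(self.kinocilium_ids) != self.matrix.shape[0]:
            raise ValueError("one id per row required")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.matrix.shape[1]) * self.step_um

    @property
    def n_kinocilia(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AveragedProfile:
    """Ensemble-averaged profile with its presentation transforms."""

    positions: np.ndarray
    mean_gray: np.ndarray
    rescaled: np.ndarray     # min-max to [0, 100]
    log2_values: np.ndarray  # log2(1 + rescaled)
    loess: np.ndarray        # Loess smooth of log2_values
    span: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position_um": self.positions,
            "mean_gray": self.mean_gray,
            "rescaled": self.rescaled,
            "log2_value": self.log2_values,
            "loess": self.loess,
        })


def max_project(stack: VoxelGrid) -> np.ndarray:
    """Maximum Z-projection of a stack: per-(y, x) maximum over slices."""
    if stack.data.shape[0] < 1 or stack.data.size == 0:
        raise ValueError("cannot project an empty stack")
    return stack.data.max(axis=0)


def sample_profile(image: np.ndarray, polyline_um: np.ndarray,
                   spacing_xy: float, kinocilium_id: str = "k00",
                   width_px: int = 2, step_um: float = PROFILE_STEP_UM
                   ) -> IntensityProfile:
    """Sample a fixed-step line profile along a 2D polyline.

    ``polyline_um`` is an (M, 2) array of (y, x) vertices in um on the
    projected image.  Samples are taken every ``step_um`` of arc length; the
    value at each sample is the mean of ``width_px`` bilinear interpolations
    spaced one pixel apart perpendicular to the local line direction and
    centered on the line (the 2-pixel-wide segmented-line convention).
    """
    image = np.asarray(image, dtype=float)
    poly = np.asarray(polyline_um, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
        raise ValueError("polyline must be (M, 2) of (y, x) um with M >= 2")
    if step_um <= 0 or spacing_xy <= 0:
        raise ValueError("step_um and spacing_xy must be positive")

    ny, nx = image.shape
    poly_px = poly / spacing_xy
    for i, (py, px) in enumerate(poly_px):
        if not (0 <= py <= ny - 1 and 0 <= px <= nx - 1):
            raise ValueError(f"polyline vertex {i} at ({poly[i, 0]:.3f}, "
                             f"{poly[i, 1]:.3f}) um lies outside the image")

    seg = np.diff(poly, axis=0)
    seg_len = np.sqrt((seg ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = int(np.floor(total / step_um + _EPS)) + 1
    positions = np.arange(n_samples) * step_um

    # interpolate sample points and local tangents along arc length
    pts = np.empty((n_samples, 2))
    pts[:, 0] = np.interp(positions, cum, poly[:, 0])
    pts[:, 1] = np.interp(positions, cum, poly[:, 1])
    seg_idx = np.clip(np.searchsorted(cum, positions, side="right") - 1,
                      0, len(seg) - 1)
    tangents = seg[seg_idx] / seg_len[seg_idx, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)

    # width_px samples spaced 1 px apart, centered on the line
    offsets_px = (np.arange(width_px) - (width_px - 1) / 2.0)
    vals = np.zeros(n_samples)
    for off in offsets_px:
        sample_px = (pts + off * spacing_xy * normals) / spacing_xy
        vals += map_coordinates(image, sample_px.T, order=1, mode="nearest")
    vals /= max(width_px, 1)
    return IntensityProfile(kinocilium_id, positions, np.clip(vals, 0.0, None))


def filter_measurable(profiles: list[IntensityProfile],
                      min_len_um: float = WINDOW_UM) -> list[IntensityProfile]:
    """Keep profiles long enough to cover the analysis window (inclusive)."""
    return [p for p in profiles if p.length_um >= min_len_um - _EPS]


def register_distal(profiles: list[IntensityProfile],
                    window_um: float = WINDOW_UM) -> RegisteredEnsemble:
    """Align profiles at the distal tip over the analysis window.

    Each row keeps only the distal-most ``window_um`` of its profile
    (501 samples at the 0.064 um step); proximal overhang of longer
    kinocilia is discarded.  Profiles shorter than the window should have
    been removed by :func:`filter_measurable` and raise an error here.
    """
    n_cols = int(round(window_um / PROFILE_STEP_UM)) + 1
    rows, ids = [], []
    for p in profiles:
        if len(p) < n_cols:
            raise ValueError(
                f"profile {p.kinocilium_id!r} spans {p.length_um:.3f} um "
                f"< window {window_um} um; filter before registering")
        rows.append(p.values[-n_cols:])
        ids.append(p.kinocilium_id)
    if not rows:
        raise ValueError("no profiles to register")
    return RegisteredEnsemble(np.vstack(rows), ids, window_um=window_um)


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.75) -> np.ndarray:
    """Degree-1 Loess smooth (tricube weights) evaluated at every ``x``."""
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    return lowess(y, x, frac=span, return_sorted=False)


def average_rescale_log(ensemble: RegisteredEnsemble,
                        loess_span: float = 0.75) -> AveragedProfile:
    """Average the ensemble and apply the presentation transforms.

    Column means are min-max rescaled to a 0-100 scale (each ensemble is
    scaled against its own extrema, which removes overall brightness
    differences between transgenes), transformed as log2(1 + x), and
    smoothed with a Loess curve of the given span.
    """
    mean_gray = ensemble.matrix.mean(axis=0)
    lo, hi = float(mean_gray.min()), float(mean_gray.max())
    if hi - lo < _EPS:
        raise DegenerateProfileError("averaged profile is flat; min-max "
                                     "normalization is undefined")
    rescaled = 100.0 * (mean_gray - lo) / (hi - lo)
    # the extrema must map to exactly 0 and 100, not within float error
    rescaled[mean_gray == lo] = 0.0
    rescaled[mean_gray == hi] = 100.0
    log2_values = np.log2(1.0 + rescaled)
    smooth = loess_fit(ensemble.positions, log2_values, span=loess_span)
    return AveragedProfile(ensemble.positions.copy(), mean_gray, rescaled,
                           log2_values, smooth, span=loess_span)


def regionalization_index(profile_values: np.ndarray, tau: float = 0.05
                          ) -> tuple[float, str]:
    """Normalized intensity centroid and pattern class of a profile.

    With positions normalized to s in [0, 1] (0 = proximal end of the
    window, 1 = distal tip), the centroid is s_bar = sum(s * w) / sum(w).
    Classes: ``proximal`` if s_bar < 0.5 - tau, ``distal`` if
    s_bar > 0.5 + tau, else ``uniform``.
    """
    w = np.asarray(profile_values, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("profile_values must be a 1D array of length >= 2")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("all-zero weights: centroid undefined")
    s = np.linspace(0.0, 1.0, len(w))
    s_bar = float((s * w).sum() / w.sum())
    if s_bar < 0.5 - tau:
        label = "proximal"
    elif s_bar > 0.5 + tau:
        label = "distal"
    else:
        label = "uniform"
    return s_bar, label


# ------------------------------------------------------- pipeline helpers

def path_to_polyline(path: TracedPath, resample_um: float = 0.5) -> np.ndarray:
    """Flatten a traced 3D path to a smooth 2D (y, x) polyline in um.

    The voxel-resolution path zig-zags at the pixel scale, which would
    inflate its apparent arc length; resampling the projected path at
    ``resample_um`` spacing by linear interpolation of cumulative chord
    length removes the jaggedness before profile sampling.
    """
    yx = path.physical_points[:, 1:]  # (y, x) um
    if len(yx) < 2:
        return np.vstack([yx, yx])
    seg = np.sqrt((np.diff(yx, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(np.round(total / resample_um)) + 1, 2)
    s = np.linspace(0.0, total, n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(s, cum, yx[:, 0])
    out[:, 1] = np.interp(s, cum, yx[:, 1])
    return out


def profile_stack(stack: VoxelGrid, paths: list[TracedPath],
                  ids: list[str] | None = None, width_px: int = 2,
                  min_len_um: float = WINDOW_UM, loess_span: float = 0.75
                  ) -> tuple[AveragedProfile, RegisteredEnsemble]:
    """Full profiling pipeline for one stack and its traced kinocilia.

    Projects the stack, samples a fixed-step profile along each flattened
    path, keeps kinocilia covering the analysis window, registers them at
    the distal tip and returns the averaged, rescaled, smoothed profile
    together with the registered ensemble.
    """
    ids = ids or [f"k{i:02d}" for i in range(len(paths))]
    image = max_project(stack)
    profiles = [
        sample_profile(image, path_to_polyline(p), stack.spacing_xy,
                       kinocilium_id=i, width_px=width_px)
        for p, i in zip(paths, ids)
    ]
    kept = filter_measurable(profiles, min_len_um=min_len_um)
    if not kept:
        raise ValueError(f"no kinocilium spans the {min_len_um} um window")
    ensemble = register_distal(kept, window_um=min_len_um)
    averaged = average_rescale_log(ensemble, loess_span=loess_span)
    return averaged, ensemble
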