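"""Synthetic confocal scenes of hair-cell kinocilia.

This module generates ground-truthed stand-ins for live confocal imaging of
zebrafish lateral-crista kinocilia: curved 3D filaments ~25-40 um long,
rendered into anisotropic voxel grids (0.064 um lateral pitch, optical
sections every ~0.65 um) with a Gaussian point-spread function, a constant
background and optional Gaussian/Poisson noise.  Along-filament intensity
follows one of four qualitative localization patterns observed for tagged
ciliary proteins: uniform (tubulin-like), middle-proximal restricted,
distal-enriched, or distal-enriched with a bulbed tip.

It also simulates hierarchical per-larva kinocilium length studies (larva
level offset plus within-larva scatter) to feed the morphometry statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DEFAULT_SPACING_XY",
    "DEFAULT_SPACING_Z",
    "PATTERNS",
    "VoxelGrid",
    "GroundTruthCurve",
    "SceneManifest",
    "OutOfBoundsError",
    "generate_curve",
    "profile_model",
    "render_stack",
    "simulate_length_study",
    "fig4_length_design",
    "read_stack",
    "write_stack",
    "read_length_table",
    "write_length_table",
]

#: Lateral pixel pitch of the acquisition being emulated (um/pixel).
DEFAULT_SPACING_XY = 0.064
#: Axial step between optical sections (um/slice), midpoint of 0.6-0.7 um.
DEFAULT_SPACING_Z = 0.65

PATTERNS = ("uniform", "proximal", "distal", "bulbed")

_MAX_GRAY = 65535


class OutOfBoundsError(ValueError):
    """A curve leaves the physical extent of the voxel grid."""


@dataclass
class VoxelGrid:
    """A 3D intensity stack with anisotropic physical voxel spacing.

    ``data`` is indexed (z, y, x); intensities live on the 16-bit scale.
    """

    data: np.ndarray
    spacing_xy: float
    spacing_z: float
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be 3D (z, y, x) with at least 1 slice")
        if self.spacing_xy <= 0 or self.spacing_z <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.data.size and (self.data.min() < 0 or self.data.max() > _MAX_GRAY):
            raise ValueError("intensities must lie in [0, 65535]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """(z, y, x) extent in um spanned by voxel centres."""
        nz, ny, nx = self.data.shape
        return ((nz - 1) * self.spacing_z, (ny - 1) * self.spacing_xy,
                (nx - 1) * self.spacing_xy)


@dataclass
class GroundTruthCurve:
    """Centre-line of one simulated kinocilium, in physical (x, y, z) um.

    ``arc_length`` is the polyline length of ``control_points`` and is the
    ground-truth length used to validate the tracer.  ``pattern`` selects the
    along-filament localization model and ``amplitude`` the peak emitter
    brightness in gray units above background.
    """

    control_points: np.ndarray  # (N, 3) as (x, y, z) um
    pattern: str = "uniform"
    amplitude: float = 3000.0
    pattern_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[0] < 2 \
                or self.control_points.shape[1] != 3:
            raise ValueError("curve needs >= 2 control points of (x, y, z)")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; one of {PATTERNS}")
        if self.arc_length <= 0:
            raise ValueError("curve must have positive arc length")

    @property
    def arc_length(self) -> float:
        seg = np.diff(self.control_points, axis=0)
        return float(np.sqrt((seg ** 2).sum(axis=1)).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.control_points[-1] - self.control_points[0]))

    def to_dict(self) -> dict:
        return {
            "control_points": self.control_points.tolist(),
            "pattern": self.pattern,
            "amplitude": self.amplitude,
            "pattern_params": dict(self.pattern_params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthCurve":
        return cls(np.asarray(d["control_points"], dtype=float), d["pattern"],
                   float(d["amplitude"]), dict(d.get("pattern_params", {})))


def generate_curve(length_um: float, curvature_amp: float = 0.0,
                   n_points: int = 256, rng_seed: int = 0, *,
                   pattern: str = "uniform", amplitude: float = 3000.0,
                   pattern_params: dict | None = None) -> GroundTruthCurve:
    """Generate a gently curved filament centre-line of exact arc length.

    The curve is a straight axis along +x with a single-arch sinusoidal
    lateral displacement of amplitude ``curvature_amp`` (um) in a random
    azimuthal direction of the y-z plane, rescaled so that the returned
    polyline's arc length equals ``length_um``.  ``curvature_amp = 0`` gives
    a straight segment whose chord equals its arc length.

    Parameters
    ----------
    length_um : target arc length in um (> 0).
    curvature_amp : peak lateral displacement in um (>= 0); larger values
        model the bent phenotypes seen with microtubule-stabilizer excess.
    n_points : number of control points (>= 2).
    rng_seed : seeds the azimuth of the bend plane.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if curvature_amp < 0:
        raise ValueError("curvature_amp must be >= 0")

    rng = np.random.default_rng(rng_seed)
    azimuth = rng.uniform(0.0, 2.0 * np.pi)
    lateral = np.array([0.0, np.cos(azimuth), np.sin(azimuth)])

    t = np.linspace(0.0, 1.0, n_points)
    pts = np.empty((n_points, 3))
    pts[:, 0] = length_um * t
    pts[:, 1:] = curvature_amp * np.sin(np.pi * t)[:, None] * lateral[None, 1:]

    # Rescale the whole polyline so its arc length is exactly length_um.
    seg = np.diff(pts, axis=0)
    arc = np.sqrt((seg ** 2).sum(axis=1)).sum()
    pts *= length_um / arc
    return GroundTruthCurve(pts, pattern=pattern, amplitude=amplitude,
                            pattern_params=pattern_params or {})


def profile_model(pattern: str, s, pattern_params: dict | None = None):
    """Relative emitter intensity in [0, 1] at normalized arc position ``s``.

    Patterns (shape constants are this module's own parameterization of the
    qualitative localization classes):

    - ``uniform``   : constant 1 (axoneme-filling, tubulin-like).
    - ``proximal``  : logistic shoulder, bright plateau near the base then a
      monotone fall-off past the mid region (``knot`` = 0.45, ``width`` = 0.06).
    - ``distal``    : logistic rise toward the tip with middle-proximal
      depletion (``knot`` = 0.60, ``width`` = 0.08, ``floor`` = 0.05).
    - ``bulbed``    : distal plus a Gaussian tip bump of physical sigma
      ``bulb_sigma_um`` (default 1.5 um over a ``length_um`` = 32 um axis),
      renormalized so the maximum is 1.
    """
    p = dict(pattern_params or {})
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValueError("normalized arc position s must lie in [0, 1]")

    def _logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    if pattern == "uniform":
        out = np.ones_like(s_arr)
    elif pattern == "proximal":
        knot = p.get("knot", 0.45)
        width = p.get("width", 0.06)
        out = _logistic((knot - s_arr) / width)
    elif pattern == "distal":
        knot = p.get("knot", 0.60)
        width = p.get("width", 0.08)
        floor = p.get("floor", 0.05)
        out = floor + (1.0 - floor) * _logistic((s_arr - knot) / width)
    elif pattern == "bulbed":
        base = np.asarray(profile_model("distal", s_arr, p))
        sigma_s = p.get("bulb_sigma_um", 1.5) / p.get("length_um", 32.0)
        gain = p.get("bulb_gain", 1.0)
        bump = gain * np.exp(-((s_arr - 1.0) ** 2) / (2 * sigma_s ** 2))
        # both terms peak at s=1, so the analytic maximum is distal(1) + gain
        peak = float(profile_model("distal", 1.0, p)) + gain
        out = (base + bump) / peak
    else:
        raise ValueError(f"unknown pattern {pattern!r}; one of {PATTERNS}")
    return out if out.ndim else float(out)


@dataclass
class SceneManifest:
    """Ground-truth bookkeeping for one rendered scene.

    Serializes losslessly to JSON; rendering the same manifest with the same
    seed is bit-reproducible.  ``gaussian_sd`` is additive read-noise sigma in
    gray units; ``poisson`` switches on shot noise on the noise-free signal.
    """

    curves: list[GroundTruthCurve]
    psf_sigma_xy: float = 0.15   # um; lateral PSF sigma
    psf_sigma_z: float = 0.50    # um; axial PSF sigma
    background: float = 100.0    # gray units
    gaussian_sd: float = 0.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_xy < 0 or self.psf_sigma_z < 0:
            raise ValueError("PSF sigmas must be >= 0")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")

    def tracer_seeds(self, spacing_xy: float, spacing_z: float
                     ) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
        """Per-curve (base, tip) voxel seeds as (z, y, x) index triples."""
        out = []
        for c in self.curves:
            base = _to_voxel(c.control_points[0], spacing_xy, spacing_z)
            tip = _to_voxel(c.control_points[-1], spacing_xy, spacing_z)
            out.append((base, tip))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "curves": [c.to_dict() for c in self.curves],
            "psf_sigma_xy": self.psf_sigma_xy,
            "psf_sigma_z": self.psf_sigma_z,
            "background": self.background,
            "gaussian_sd": self.gaussian_sd,
            "poisson": self.poisson,
            "seed": self.seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneManifest":
        d = json.loads(text)
        return cls([GroundTruthCurve.from_dict(c) for c in d["curves"]],
                   d["psf_sigma_xy"], d["psf_sigma_z"], d["background"],
                   d["gaussian_sd"], d["poisson"], d["seed"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SceneManifest":
        return cls.from_json(Path(path).read_text())


def _to_voxel(point_xyz: np.ndarray, spacing_xy: float, spacing_z: float
              ) -> tuple[int, int, int]:
    """Nearest-voxel (z, y, x) index of a physical (x, y, z) point."""
    x, y, z = point_xyz
    return (int(round(z / spacing_z)), int(round(y / spacing_xy)),
            int(round(x / spacing_xy)))


def _arc_resample(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~``step`` um; returns (points, normalized s)."""
    seg = np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s_abs = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(s_abs, cum, points[:, k])
    return out, s_abs / total


def render_stack(manifest: SceneManifest, shape: tuple[int, int, int],
                 spacing_xy: float = DEFAULT_SPACING_XY,
                 spacing_z: float = DEFAULT_SPACING_Z,
                 name: str = "scene", quantize: bool = True) -> VoxelGrid:
    """Render a manifest into a 16-bit stack.

    Each filament is a max-composited anisotropic Gaussian tube: the voxel
    value contributed by a curve is ``amplitude * profile_model(pattern, s)``
    attenuated by the squared Mahalanobis distance to the nearest curve
    sample (sigma_xy laterally, sigma_z axially), so the on-axis brightness
    encodes the localization pattern exactly and scales linearly with
    ``amplitude``.  Background is added, then Gaussian/Poisson noise, then
    the result is clipped to [0, 65535] and cast to uint16 (``quantize=False``
    skips rounding and keeps float gray values).
    """
    nz, ny, nx = shape
    ext_z, ext_y, ext_x = (nz - 1) * spacing_z, (ny - 1) * spacing_xy, (nx - 1) * spacing_xy
    signal = np.zeros(shape, dtype=float)

    sig_xy = max(manifest.psf_sigma_xy, 1e-6)
    sig_z = max(manifest.psf_sigma_z, 1e-6)
    ry = rx = max(int(np.ceil(3.0 * sig_xy / spacing_xy)), 1)
    rz = max(int(np.ceil(3.0 * sig_z / spacing_z)), 1)

    for ci, curve in enumerate(manifest.curves):
        pts = curve.control_points
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > ext_x
                or pts[:, 1].min() < 0 or pts[:, 1].max() > ext_y
                or pts[:, 2].min() < 0 or pts[:, 2].max() > ext_z):
            raise OutOfBoundsError(
                f"curve {ci} ({curve.pattern}) leaves the grid extent "
                f"x<={ext_x:.2f} y<={ext_y:.2f} z<={ext_z:.2f} um")
        dense, s_norm = _arc_resample(pts, step=min(spacing_xy, spacing_z) / 2.0)
        values = curve.amplitude * np.atleast_1d(
            profile_model(curve.pattern, s_norm, curve.pattern_params))

        zc = np.arange(-rz, rz + 1)[:, None, None] * spacing_z
        yc = np.arange(-ry, ry + 1)[None, :, None] * spacing_xy
        xc = np.arange(-rx, rx + 1)[None, None, :] * spacing_xy
        for p, v in zip(dense, values):
            iz, iy, ix = _to_voxel(p, spacing_xy, spacing_z)
            z0, z1 = max(iz - rz, 0), min(iz + rz, nz - 1)
            y0, y1 = max(iy - ry, 0), min(iy + ry, ny - 1)
            x0, x1 = max(ix - rx, 0), min(ix + rx, nx - 1)
            dz = zc[z0 - iz + rz: z1 - iz + rz + 1] + iz * spacing_z - p[2]
            dy = yc[:, y0 - iy + ry: y1 - iy + ry + 1] + iy * spacing_xy - p[1]
            dx = xc[:, :, x0 - ix + rx: x1 - ix + rx + 1] + ix * spacing_xy - p[0]
            foot = v * np.exp(-(dx ** 2 + dy ** 2) / (2 * sig_xy ** 2)
                              - dz ** 2 / (2 * sig_z ** 2))
            np.maximum(signal[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1], foot,
                       out=signal[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1])

    image = signal + manifest.background
    rng = np.random.default_rng(manifest.seed)
    if manifest.poisson:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if manifest.gaussian_sd > 0:
        image = image + rng.normal(0.0, manifest.gaussian_sd, size=shape)
    if quantize:
        data = np.clip(np.rint(image), 0, _MAX_GRAY).astype(np.uint16)
    else:
        data = np.clip(image, 0, _MAX_GRAY)
    return VoxelGrid(data, spacing_xy, spacing_z, name=name)


def fig4_length_design() -> dict[str, dict]:
    """Default group design for the length study.

    Group means and larva counts follow the saxo2 overexpression series
    (non-transgenic and mild/intermediate/severe phenotypes: means 35.4,
    35.3, 32.1, 26.1 um with n = 8, 8, 7, 5 larvae).  The variance components
    are this module's choice (1 um between larvae, 2 um within a larva) since
    raw scatter is not published; 10 kinocilia per larva keeps the top-5 rule
    meaningful.
    """
    common = dict(sd_between_larvae=1.0, sd_within_larva=2.0,
                  n_larvae=8, kinocilia_per_larva=10)
    design = {
        "non_tg": {**common, "true_mean": 35.4, "n_larvae": 8},
        "mild": {**common, "true_mean": 35.3, "n_larvae": 8},
        "intermediate": {**common, "true_mean": 32.1, "n_larvae": 7},
        "severe": {**common, "true_mean": 26.1, "n_larvae": 5},
    }
    return design


def simulate_length_study(group_specs: dict[str, dict], rng_seed: int = 0
                          ) -> pd.DataFrame:
    """Simulate a hierarchical per-larva kinocilium length dataset.

    Each larva draws a normal offset (``sd_between_larvae``) around its
    group's ``true_mean``; each kinocilium adds within-larva normal scatter
    (``sd_within_larva``).  Lengths are truncated at zero from below (a tiny
    positive floor).  Returns tidy rows (group, larva, kinocilium,
    length_um, measurable).
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for group, spec in group_specs.items():
        n_larvae = int(spec["n_larvae"])
        per = int(spec["kinocilia_per_larva"])
        if n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if per < 5:
            raise ValueError(
                "kinocilia_per_larva must be >= 5: the per-larva statistic is "
                "the mean of the five tallest kinocilia")
        sd_b = float(spec["sd_between_larvae"])
        sd_w = float(spec["sd_within_larva"])
        if sd_b < 0 or sd_w < 0:
            raise ValueError("standard deviations must be >= 0")
        for li in range(n_larvae):
            larva = f"{group}_L{li:02d}"
            mu = spec["true_mean"] + rng.normal(0.0, sd_b) if sd_b > 0 else spec["true_mean"]
            lengths = mu + (rng.normal(0.0, sd_w, size=per) if sd_w > 0 else np.zeros(per))
            lengths = np.clip(lengths, 1e-6, None)
            for ki, ln in enumerate(lengths):
                rows.append((group, larva, f"k{ki:02d}", float(ln), True))
    return pd.DataFrame(rows, columns=["group", "larva", "kinocilium",
                                       "length_um", "measurable"])


# ---------------------------------------------------------------- file I/O

def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a multi-page 16-bit TIFF plus a JSON spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(grid.data, dtype=np.uint16))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"spacing_xy": grid.spacing_xy,
                                   "spacing_z": grid.spacing_z,
                                   "name": grid.name}))


def read_stack(path: str | Path) -> VoxelGrid:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"no spacing sidecar for {path}; assuming defaults")
        meta = {"spacing_xy": DEFAULT_SPACING_XY, "spacing_z": DEFAULT_SPACING_Z,
                "name": path.stem}
    return VoxelGrid(data, meta["spacing_xy"], meta["spacing_z"],
                     name=meta.get("name", path.stem))


def write_length_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_length_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"group", "larva", "kinocilium", "length_um", "measurable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"length table missing columns: {sorted(missing)}")
    return df
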