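"""Synthetic cranial CT phantoms with exact landmark ground truth.

Each case is a simple parametric "skull": an ellipsoidal vault shell, a
half-torus mandibular arch whose rami run up to the skull base, and a
small bone blob at each of the 16 catalog landmark positions so that
every landmark has a distinct local shape cue and provably lies on bone.
Head centers are jittered with a larger scatter along y than along x,
emulating how patients are centered left-right on the scanner table but
positioned variably front-to-back; bilateral landmarks mirror about the
head's midsagittal plane.

Intensities are drawn from disjoint uniform bands: bone strictly above
the binarization threshold, soft tissue strictly below, air at zero — so
bone segmentation by thresholding behaves exactly as it does on real
stored-value CT.  Optional Gaussian noise can be added; it is off by
default so the intensity-band invariants hold exactly.

All random draws are taken from a single per-case stream seeded by
(seed, case_index): cohorts are order-independent and bit-reproducible.
Geometry draws are made in normalized (unit) space before being mapped
through the pixel-valued parameters, so scaling a spec with
:meth:`PhantomSpec.scaled` scales every ground-truth coordinate exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .landmarks import CODES, LandmarkTable, write_table
from .volume_io import CaseVolume, RawSlice, write_series


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom cohort.

    Length-valued fields are in pixels at the spec's own grid; radii are
    fractions of the half-grid (in-plane) or of the z extent (vertical),
    so the same spec geometry is meaningful at any grid size.
    """

    seed: int = 0
    n_cases: int = 120
    grid: tuple[int, int, int] = (512, 512, 81)  # (width, height, depth slices)
    z_step_px: float = 5.12  # slice interval in pixel units
    in_plane_mm: float = 500.0 / 512.0

    # vault ellipsoid: radii as fractions of W/2, H/2 and z extent
    rx_frac: tuple[float, float] = (0.56, 0.64)
    ry_frac: tuple[float, float] = (0.48, 0.56)
    rz_frac: tuple[float, float] = (0.28, 0.34)
    shell_thickness: float = 10.0  # px

    # mandibular arch
    mandible_radius_frac: float = 0.72  # of the mean in-plane vault radius
    mandible_tube: float = 9.0  # px

    # head-center scatter (sigma_y > sigma_x: front-back positioning varies
    # more than left-right centering); sigma_z jitters the vault vertically
    sigma_x: float = 10.0
    sigma_y: float = 30.0
    sigma_z: float = 8.0

    # per-landmark displacement on the shell
    feature_jitter: float = 3.0  # px, uniform per axis
    z_plane_jitter: float = 2.0  # px, around the landmark's slice plane
    blob_radius: float = 8.0  # px, bone blob at each landmark

    # stored-value intensity bands (binarization threshold between them)
    threshold: int = 1100
    bone_intensity: tuple[int, int] = (1500, 2500)
    soft_intensity: tuple[int, int] = (200, 800)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.bone_intensity[0] <= self.threshold:
            raise ParameterError("bone intensity must lie above the threshold")
        if self.soft_intensity[1] >= self.threshold:
            raise ParameterError("soft-tissue intensity must lie below the threshold")
        if self.sigma_y <= self.sigma_x:
            raise ParameterError("y scatter must exceed x scatter (sigma_y > sigma_x)")

    @property
    def z_extent(self) -> float:
        return (self.grid[2] - 1) * self.z_step_px

    @property
    def slice_mm(self) -> float:
        return self.z_step_px * self.in_plane_mm

    @classmethod
    def desk_scale(cls, seed: int = 0, n_cases: int = 120) -> "PhantomSpec":
        """96 x 96 x 24 cohort; spacing scaled by 512/96 from full scale."""
        return cls(
            seed=seed,
            n_cases=n_cases,
            grid=(96, 96, 24),
            in_plane_mm=500.0 / 96.0,
            shell_thickness=2.0,
            mandible_tube=1.8,
            sigma_x=2.0,
            sigma_y=6.0,
            sigma_z=1.6,
            feature_jitter=0.6,
            z_plane_jitter=0.4,
            blob_radius=1.6,
        )

    @classmethod
    def full_scale(cls, seed: int = 0, n_cases: int = 120) -> "PhantomSpec":
        return cls(seed=seed, n_cases=n_cases)

    def scaled(self, s: float) -> "PhantomSpec":
        """Scale the in-plane grid and every pixel-valued length by ``s``."""
        w, h, d = self.grid
        return dataclasses.replace(
            self,
            grid=(int(round(w * s)), int(round(h * s)), d),
            z_step_px=self.z_step_px * s,
            in_plane_mm=self.in_plane_mm / s,
            shell_thickness=self.shell_thickness * s,
            mandible_tube=self.mandible_tube * s,
            sigma_x=self.sigma_x * s,
            sigma_y=self.sigma_y * s,
            sigma_z=self.sigma_z * s,
            feature_jitter=self.feature_jitter * s,
            z_plane_jitter=self.z_plane_jitter * s,
            blob_radius=self.blob_radius * s,
        )


# landmark shell directions (dx, dy, dz); anterior is -y, cranial is +z.
# "L" landmarks take +dx, "R" landmarks -dx (mirror about the midsagittal
# plane).  Entries marked interior sit inside the vault (skull base /
# midface) and are realised by their bone blob.
_SHELL_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "L01": (0.0, -0.99, -0.30),  # A point: anterior, low midface
    "L02": (0.0, -0.95, -0.22),  # anterior nasal spine
    "L04": (0.62, -0.72, -0.25),  # inferior lateral orbital rim
    "L06": (0.40, -0.85, 0.12),  # supraorbital incisura
    "L05": (0.97, 0.05, -0.18),  # porion: lateral
    "L08": (0.0, -0.98, 0.02),  # nasion
    "L09": (0.0, 0.99, -0.12),  # external occipital protuberance
}
_INTERIOR_POINTS: dict[str, tuple[float, float, float]] = {
    # fractions of (rx, ry, rz) from the vault center
    "L10": (0.0, -0.35, -0.30),  # posterior nasal spine
    "L15": (0.0, -0.05, -0.15),  # sella
    "L16": (0.0, -0.55, 0.02),  # crista galli
}
_MIRROR = {"L04": "L12", "L05": "L13", "L06": "L14"}

_GONION_THETA = 1.75  # arc parameter of the gonion (radians from the chin)
_ARC_MAX = 1.95


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(case_index)])


def _mandible_curve(cx, cy, rm, z_low, shell_pt_left, shell_pt_right, n=256):
    """Polyline: horizontal arch at z_low plus two rami up to the shell."""
    theta = np.linspace(-_ARC_MAX, _ARC_MAX, n)
    arch = np.stack(
        [cx + rm * np.sin(theta), cy - rm * np.cos(theta), np.full(n, z_low)], axis=1
    )
    t = np.linspace(0.0, 1.0, n // 4)[:, None]
    ramus_l = arch[-1] * (1 - t) + np.asarray(shell_pt_left) * t
    ramus_r = arch[0] * (1 - t) + np.asarray(shell_pt_right) * t
    return np.concatenate([arch, ramus_l, ramus_r], axis=0), theta, arch


def generate_case(spec: PhantomSpec, case_index: int) -> tuple[CaseVolume, LandmarkTable]:
    """Deterministically generate one phantom case and its ground truth."""
    rng = _case_rng(spec.seed, case_index)
    w, h, d = spec.grid
    zext = spec.z_extent
    zstep = spec.z_step_px

    # --- unit-space draws (grid-independent order and count) -----------
    # center jitter is truncated at 2.5 sigma so the sampled vault always
    # fits the grid under the default radii fractions
    u_center = np.clip(rng.standard_normal(3), -2.5, 2.5)
    u_radii = rng.uniform(size=3)
    u_feat = rng.uniform(-1.0, 1.0, size=(len(CODES), 3))
    u_zjit = rng.uniform(-1.0, 1.0, size=len(CODES))

    cx = w / 2.0 + u_center[0] * spec.sigma_x
    cy = h / 2.0 + u_center[1] * spec.sigma_y
    cz = zext * 0.58 + u_center[2] * spec.sigma_z
    rx = (spec.rx_frac[0] + u_radii[0] * (spec.rx_frac[1] - spec.rx_frac[0])) * w / 2.0
    ry = (spec.ry_frac[0] + u_radii[1] * (spec.ry_frac[1] - spec.ry_frac[0])) * h / 2.0
    rz = (spec.rz_frac[0] + u_radii[2] * (spec.rz_frac[1] - spec.rz_frac[0])) * zext

    margin = spec.shell_thickness + 1.0
    if (
        cx - rx < margin
        or cx + rx > w - margin
        or cy - ry < margin
        or cy + ry > h - margin
        or cz + rz > zext
    ):
        raise ParameterError(
            f"case {case_index}: vault (center ({cx:.1f},{cy:.1f},{cz:.1f}), "
            f"radii ({rx:.1f},{ry:.1f},{rz:.1f})) does not fit grid {spec.grid}"
        )

    center = np.array([cx, cy, cz])
    radii = np.array([rx, ry, rz])
    delta = spec.shell_thickness / float(np.mean(radii))
    rho_mid = 1.0 - delta / 2.0

    def shell_point(direction) -> np.ndarray:
        dvec = np.asarray(direction, dtype=float)
        return center + radii * dvec * (rho_mid / np.linalg.norm(dvec))

    # --- mandible ------------------------------------------------------
    rm = spec.mandible_radius_frac * (rx + ry) / 2.0
    z_low = max(zstep, cz - 0.92 * rz)
    z_low = round(z_low / zstep) * zstep  # arch on a slice plane
    ram_top_l = shell_point((0.85, 0.15, -0.35))
    ram_top_r = shell_point((-0.85, 0.15, -0.35))
    curve, theta, arch = _mandible_curve(cx, cy, rm, z_low, ram_top_l, ram_top_r)

    # --- landmark ground truth ------------------------------------------
    points = np.zeros((len(CODES), 3))
    for i, code in enumerate(CODES):
        if code in _SHELL_DIRECTIONS:
            p = shell_point(_SHELL_DIRECTIONS[code])
        elif code in ("L12", "L13", "L14"):
            left = {v: k for k, v in _MIRROR.items()}[code]
            dx, dy, dz = _SHELL_DIRECTIONS[left]
            p = shell_point((-dx, dy, dz))
        elif code in _INTERIOR_POINTS:
            p = center + radii * np.asarray(_INTERIOR_POINTS[code])
        elif code == "L07":  # menton: chin of the arch
            p = np.array([cx, cy - rm, z_low])
        elif code == "L03":  # left gonion
            p = np.array(
                [cx + rm * np.sin(_GONION_THETA), cy - rm * np.cos(_GONION_THETA), z_low]
            )
        elif code == "L11":  # right gonion
            p = np.array(
                [cx - rm * np.sin(_GONION_THETA), cy - rm * np.cos(_GONION_THETA), z_low]
            )
        else:  # pragma: no cover
            raise AssertionError(code)
        # slice assignment uses the unjittered geometry so bilateral pairs
        # land on the same slice; jitter then scatters around the plane
        k = int(np.clip(np.round(p[2] / zstep), 0, d - 1))
        p = p + u_feat[i] * spec.feature_jitter
        p[2] = k * zstep + u_zjit[i] * spec.z_plane_jitter
        points[i] = p

    if np.any(points[:, 0] < 0) or np.any(points[:, 0] >= w) or np.any(
        points[:, 1] < 0
    ) or np.any(points[:, 1] >= h):
        raise ParameterError(f"case {case_index}: a landmark falls outside the grid")

    # --- voxelization ----------------------------------------------------
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    zs = np.arange(d) * zstep
    azim2 = (((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2)[:, :, None]
    # slab-integrated voxelization: a voxel is shell if the ellipsoid band
    # crosses anywhere in its z slab [z - step/2, z + step/2]; this keeps
    # the voxelized shell 26-connected across the coarse slice spacing
    dz = np.abs(zs - cz)
    z_lo = np.maximum(dz - zstep / 2.0, 0.0) / rz
    z_hi = (dz + zstep / 2.0) / rz
    rho_lo = np.sqrt(azim2 + (z_lo**2)[None, None, :])
    rho_hi = np.sqrt(azim2 + (z_hi**2)[None, None, :])
    shell = (rho_lo <= 1.0) & (rho_hi >= 1.0 - delta)
    rho = np.sqrt(azim2 + (((zs - cz) / rz) ** 2)[None, None, :])
    interior = rho < 1.0 - delta

    bone = shell.copy()

    # mandible: anisotropic tube (z compressed so every slice the curve
    # crosses receives an in-plane disc and stays 26-connected)
    zscale = spec.mandible_tube / (0.75 * zstep)
    tree = cKDTree(curve * np.array([1.0, 1.0, zscale]))
    lo = np.maximum(np.floor(curve.min(axis=0) - spec.mandible_tube - 1), 0).astype(int)
    hi = np.ceil(curve.max(axis=0) + spec.mandible_tube + 1).astype(int)
    kz = np.arange(d)[(zs >= curve[:, 2].min() - 0.75 * zstep) & (zs <= curve[:, 2].max() + 0.75 * zstep)]
    if kz.size:
        sub_y = np.arange(max(lo[1], 0), min(hi[1] + 1, h))
        sub_x = np.arange(max(lo[0], 0), min(hi[0] + 1, w))
        gy, gx, gk = np.meshgrid(sub_y, sub_x, kz, indexing="ij")
        q = np.stack([gx.ravel(), gy.ravel(), gk.ravel() * zstep * zscale], axis=1)
        dist, _ = tree.query(q, workers=-1)
        hitmask = dist <= spec.mandible_tube
        bone[gy.ravel()[hitmask], gx.ravel()[hitmask], gk.ravel()[hitmask]] = True

    # landmark blobs: an in-plane bone disc on the landmark's slice
    for p in points:
        k = int(np.clip(np.round(p[2] / zstep), 0, d - 1))
        r = spec.blob_radius
        x0, x1 = int(np.floor(p[0] - r)), int(np.ceil(p[0] + r)) + 1
        y0, y1 = int(np.floor(p[1] - r)), int(np.ceil(p[1] + r)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        by, bx = np.mgrid[y0:y1, x0:x1]
        disc = (bx - p[0]) ** 2 + (by - p[1]) ** 2 <= r**2
        bone[y0:y1, x0:x1, k] |= disc
        bone[int(np.clip(round(p[1]), 0, h - 1)), int(np.clip(round(p[0]), 0, w - 1)), k] = True

    soft = interior & ~bone

    # --- intensities ------------------------------------------------------
    vol = np.zeros((h, w, d), dtype=np.float64)
    vol[soft] = rng.uniform(*spec.soft_intensity, size=int(soft.sum()))
    vol[bone] = rng.uniform(*spec.bone_intensity, size=int(bone.sum()))
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    vol = np.clip(np.round(vol), 0, 4071).astype(np.uint16)

    case_id = f"case{case_index:04d}"
    slices = [
        RawSlice(pixels=vol[:, :, k], slice_position=k * spec.slice_mm, order_index=k)
        for k in range(d)
    ]
    volume = CaseVolume(
        case_id=case_id,
        slices=slices,
        in_plane_spacing_mm=spec.in_plane_mm,
        slice_interval_mm=spec.slice_mm,
    )
    return volume, LandmarkTable(case_id=case_id, points=points)


def generate_cohort(spec: PhantomSpec) -> tuple[list[CaseVolume], list[LandmarkTable]]:
    """Generate ``spec.n_cases`` independent cases."""
    if spec.n_cases < 1:
        raise ParameterError("n_cases must be >= 1")
    volumes, tables = [], []
    for i in range(spec.n_cases):
        v, t = generate_case(spec, i)
        volumes.append(v)
        tables.append(t)
    return volumes, tables


def write_cohort(
    volumes: list[CaseVolume], tables: list[LandmarkTable], directory: str | Path
) -> Path:
    """Write DICOM series per case plus the ground-truth landmark CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for v in volumes:
        write_series(v, directory / v.case_id)
    csv_path = directory / "landmarks.csv"
    write_table(tables, csv_path)
    return csv_path
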