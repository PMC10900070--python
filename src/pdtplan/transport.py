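"""Voxel Monte Carlo fluence-rate simulation.

Produces per-voxel fluence-rate maps in mW cm⁻² *per mW delivered* for a
source placed inside the cavity. Maps for higher delivered powers are
obtained by exact linear scaling (:func:`scale_fluence`), capped at
10,000 mW.

Source models:

* ``flat_cleaved`` — the bare fiber used clinically: emission uniform
  over the core disk, directions uniform in solid angle within the
  acceptance cone θ_max = arcsin(NA / n_medium);
* ``spherical_diffuser`` — a 2 mm diffusing bulb: Lambertian emission
  from the bulb surface;
* ``isotropic_point`` — an idealized point source used for analytic
  validation (inverse-square and Beer–Lambert oracles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _mc
from .geometry import Region
from .optics import REFRACTIVE_INDEX, OpticalVolume

__all__ = [
    "SourceModel",
    "FluenceMap",
    "simulate_fluence",
    "launch_flat_cleaved",
    "launch_spherical_diffuser",
    "scale_fluence",
    "POWER_CAP_MW",
]

POWER_CAP_MW = 10_000.0

_KIND_CODES = {
    "isotropic_point": _mc.SRC_ISOTROPIC_POINT,
    "flat_cleaved": _mc.SRC_FLAT_CLEAVED,
    "spherical_diffuser": _mc.SRC_SPHERICAL_DIFFUSER,
}


@dataclass(frozen=True)
class SourceModel:
    """Light source placed at ``position_mm`` (cavity centroid in practice).

    ``core_diameter_um`` and ``na`` apply to the flat-cleaved fiber
    (defaults: 400 µm core, NA 0.22 — a typical clinical bare PDT fiber);
    ``diffuser_diameter_mm`` to the spherical diffuser (2 mm bulb).
    """

    kind: str
    position_mm: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    core_diameter_um: float = 400.0
    na: float = 0.22
    diffuser_diameter_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown source kind {self.kind!r}")
        ax = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(ax)
        if norm == 0:
            raise ValueError("source axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / norm))
        if self.kind == "flat_cleaved":
            if not 0.0 < self.na < 1.0:
                raise ValueError("numerical aperture must lie in (0, 1)")
            if self.core_diameter_um <= 0:
                raise ValueError("core diameter must be positive")
        if self.kind == "spherical_diffuser" and self.diffuser_diameter_mm <= 0:
            raise ValueError("diffuser diameter must be positive")

    def acceptance_half_angle(self, n_medium: float = REFRACTIVE_INDEX) -> float:
        """θ_max = arcsin(NA / n) in radians (flat-cleaved fiber)."""
        ratio = self.na / n_medium
        if ratio >= 1.0:
            raise ValueError("NA / n_medium must be < 1")
        return math.asin(ratio)


@dataclass
class FluenceMap:
    """Per-voxel fluence rate, mW cm⁻² per ``power_mw`` delivered."""

    values: np.ndarray
    pitch_mm: float
    n_packets: int
    seed: int
    power_mw: float
    absorbed_weight: float
    escaped_weight: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def energy_balance_error(self) -> float:
        """Relative error of absorbed + escaped vs. launched weight."""
        total = self.absorbed_weight + self.escaped_weight
        return abs(total - self.n_packets) / self.n_packets


def _source_kernel_args(source: SourceModel, n_medium: float) -> tuple:
    pos_cm = np.asarray(source.position_mm, dtype=float) / 10.0
    ax = np.asarray(source.axis, dtype=float)
    r_core_cm = source.core_diameter_um / 2.0 * 1.0e-4
    if source.kind == "flat_cleaved":
        cos_max = math.cos(source.acceptance_half_angle(n_medium))
    else:
        cos_max = 1.0
    r_sphere_cm = source.diffuser_diameter_mm / 2.0 / 10.0
    return (
        _KIND_CODES[source.kind],
        pos_cm[0], pos_cm[1], pos_cm[2],
        ax[0], ax[1], ax[2],
        r_core_cm, cos_max, r_sphere_cm,
    )


def simulate_fluence(
    optical_volume: OpticalVolume,
    source: SourceModel,
    n_packets: int = 1_000_000,
    seed: int = 0,
) -> FluenceMap:
    """Run the voxel Monte Carlo and return the 1 mW-normalized fluence map.

    Fluence is scored with the track-length estimator: per voxel,
    φ = Σ w·ℓ / (N · V_voxel), so voxels with zero absorption still score.
    The returned map satisfies the energy ledger
    absorbed + escaped = launched weight to ~1e-12 relative.
    """
    if n_packets < 1000:
        raise ValueError("at least 1000 photon packets are required")
    lv = optical_volume.label_volume
    mua, mus, g = optical_volume.coefficient_arrays()
    if not (np.isfinite(mua).all() and np.isfinite(mus).all() and np.isfinite(g).all()):
        raise ValueError("optical coefficients must be finite")

    pos_vox = (np.asarray(source.position_mm) - lv.origin_mm) / lv.pitch_mm
    idx = np.floor(pos_vox).astype(int)
    if (idx < 0).any() or (idx >= np.array(lv.shape)).any():
        raise ValueError("source position lies outside the grid")
    if lv.labels[tuple(idx)] != Region.INTERIOR:
        raise ValueError("source position must lie inside the cavity (INTERIOR)")

    pitch_cm = lv.pitch_mm / 10.0
    phi = np.zeros(lv.shape, dtype=np.float64)
    # kernel positions are relative to the grid corner, in cm
    kind, sx, sy, sz, ax, ay, az, r_core, cos_max, r_sph = _source_kernel_args(
        source, optical_volume.region_props[Region.INTERIOR].n
    )
    origin_cm = lv.origin_mm / 10.0
    absorbed, escaped = _mc.run_transport(
        lv.labels,
        mua,
        mus,
        g,
        pitch_cm,
        int(n_packets),
        np.uint64(seed),
        kind,
        sx - origin_cm[0],
        sy - origin_cm[1],
        sz - origin_cm[2],
        ax,
        ay,
        az,
        r_core,
        cos_max,
        r_sph,
        phi,
    )
    phi /= n_packets * pitch_cm**3
    return FluenceMap(
        values=phi,
        pitch_mm=lv.pitch_mm,
        n_packets=int(n_packets),
        seed=int(seed),
        power_mw=1.0,
        absorbed_weight=absorbed,
        escaped_weight=escaped,
    )


def scale_fluence(fluence_map: FluenceMap, power_mw: float) -> FluenceMap:
    """Linearly scale a 1 mW map to ``power_mw`` delivered (cap 10,000 mW)."""
    if power_mw <= 0:
        raise ValueError("power must be positive")
    if power_mw > POWER_CAP_MW:
        raise ValueError(f"power {power_mw} mW exceeds the {POWER_CAP_MW:.0f} mW cap")
    scaled = replace(
        fluence_map,
        values=fluence_map.values * (power_mw / fluence_map.power_mw),
        power_mw=power_mw,
    )
    return scaled


def launch_flat_cleaved(
    source: SourceModel,
    rng: np.random.Generator,
    n: int = 1,
    n_medium: float = REFRACTIVE_INDEX,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample initial positions (mm) and unit directions for the bare fiber.

    Positions are uniform over the fiber core disk perpendicular to the
    axis; directions uniform in solid angle within the acceptance cone.
    """
    if source.kind != "flat_cleaved":
        raise ValueError("source kind must be 'flat_cleaved'")
    axis = np.asarray(source.axis)
    e1, e2 = _orthobasis_np(axis)
    r_mm = source.core_diameter_um / 2000.0 * np.sqrt(rng.random(n))
    ang = 2 * np.pi * rng.random(n)
    pos = (
        np.asarray(source.position_mm)
        + r_mm[:, None] * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    )
    cos_max = math.cos(source.acceptance_half_angle(n_medium))
    ct = 1.0 - rng.random(n) * (1.0 - cos_max)
    st = np.sqrt(1.0 - ct**2)
    ph = 2 * np.pi * rng.random(n)
    dirs = (
        (st * np.cos(ph))[:, None] * e1
        + (st * np.sin(ph))[:, None] * e2
        + ct[:, None] * axis
    )
    return pos, dirs


def launch_spherical_diffuser(
    source: SourceModel,
    rng: np.random.Generator,
    n: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample initial positions (mm) and directions for the spherical diffuser.

    Positions uniform on the bulb surface; directions cosine-weighted
    (Lambertian) about the outward normal, so every draw points outward.
    """
    if source.kind != "spherical_diffuser":
        raise ValueError("source kind must be 'spherical_diffuser'")
    normal = rng.standard_normal((n, 3))
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    radius = source.diffuser_diameter_mm / 2.0
    pos = np.asarray(source.position_mm) + radius * normal
    ct = np.sqrt(rng.random(n))
    st = np.sqrt(1.0 - ct**2)
    ph = 2 * np.pi * rng.random(n)
    dirs = np.empty((n, 3))
    for i in range(n):
        e1, e2 = _orthobasis_np(normal[i])
        dirs[i] = st[i] * np.cos(ph[i]) * e1 + st[i] * np.sin(ph[i]) * e2 + ct[i] * normal[i]
    return pos, dirs


def _orthobasis_np(n_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(n_vec[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n_vec, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_vec, e1)
    return e1, e2
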