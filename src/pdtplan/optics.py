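"""Per-region tissue and Intralipid optical properties at 665 nm.

Diffuse-reflectance spectroscopy recovers absorption µa and *reduced*
scattering µs′ = µs(1−g); the transport code needs µs and the anisotropy
g separately. Conventions used throughout:

* anisotropy g = 0.7 inside the cavity (Intralipid at 665 nm) and g = 0.9
  in the wall and surrounding tissue;
* Intralipid reduced scattering is linear in volume concentration at
  665 nm, µs′ = 11.4 cm⁻¹ per 1%;
* a single refractive index n = 1.37 everywhere — the index-matched
  reading of the intra-cavity fluid; no Fresnel events at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LabelVolume, Region
from .phantoms import SubjectOptics

__all__ = [
    "OpticalProperties",
    "OpticalVolume",
    "intralipid_musp",
    "musp_to_mus",
    "assign_region_optics",
    "INTRALIPID_MUSP_PER_PCT",
    "ASSUMED_WALL",
    "G_INTERIOR",
    "G_TISSUE",
    "DEFAULT_INTERIOR_MUA",
    "REFRACTIVE_INDEX",
]

#: µs′ (cm⁻¹) of Intralipid per 1% volume concentration at 665 nm.
INTRALIPID_MUSP_PER_PCT = 11.4

G_INTERIOR = 0.7
G_TISSUE = 0.9

#: Intra-cavity absorption (cm⁻¹): dilute saline at 665 nm; config-exposed.
DEFAULT_INTERIOR_MUA = 0.004

REFRACTIVE_INDEX = 1.37


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption µa, scattering µs (both cm⁻¹), anisotropy g, index n."""

    mua: float
    mus: float
    g: float
    n: float = REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise ValueError("absorption and scattering coefficients must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if not np.isfinite([self.mua, self.mus, self.g, self.n]).all():
            raise ValueError("optical properties must be finite")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient µs′ = µs(1−g)."""
        return self.mus * (1.0 - self.g)


def intralipid_musp(concentration_pct: float) -> float:
    """Reduced scattering (cm⁻¹) of Intralipid at 665 nm vs. concentration (%).

    Linear: 1% -> 11.4 cm⁻¹. Valid on the swept range 0–1%.
    """
    if concentration_pct < 0:
        raise ValueError("Intralipid concentration must be non-negative")
    return INTRALIPID_MUSP_PER_PCT * concentration_pct


def musp_to_mus(musp: float, g: float) -> float:
    """Invert the similarity relation: µs = µs′ / (1−g)."""
    if g >= 1.0:
        raise ValueError("anisotropy g must be < 1 to recover µs from µs′")
    if musp < 0:
        raise ValueError("µs′ must be non-negative")
    return musp / (1.0 - g)


#: Assumed homogeneous wall/tissue properties (peritoneal-tissue values).
ASSUMED_WALL = OpticalProperties(mua=0.2, mus=100.0, g=G_TISSUE)


@dataclass(frozen=True)
class OpticalVolume:
    """A LabelVolume with optical properties bound to each region.

    BOUNDARY is photon-terminating and carries no properties.
    """

    label_volume: LabelVolume
    region_props: dict
    intralipid_pct: float

    def __post_init__(self) -> None:
        present = {Region(v) for v in np.unique(self.label_volume.labels)}
        present.discard(Region.BOUNDARY)
        missing = present - set(self.region_props)
        if missing:
            raise ValueError(f"regions without optical properties: {missing}")

    def coefficient_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(µa, µs, g) arrays indexed by region label, cm⁻¹; BOUNDARY zeros."""
        mua = np.zeros(4)
        mus = np.zeros(4)
        g = np.zeros(4)
        for region, props in self.region_props.items():
            mua[int(region)] = props.mua
            mus[int(region)] = props.mus
            g[int(region)] = props.g
        return mua, mus, g

    def manifest(self) -> dict:
        """Region-optics table for the run manifest (JSON-serializable)."""
        return {
            "intralipid_pct": self.intralipid_pct,
            "regions": {
                Region(r).name: {"mua": p.mua, "mus": p.mus, "g": p.g, "n": p.n}
                for r, p in self.region_props.items()
            },
        }


def assign_region_optics(
    label_volume: LabelVolume,
    subject: SubjectOptics | None = None,
    condition: str = "assumed",
    intralipid_pct: float = 1.0,
    interior_mua: float = DEFAULT_INTERIOR_MUA,
) -> OpticalVolume:
    """Bind per-region optical properties for one simulation condition.

    condition="assumed": wall (and tissue) get the homogeneous assumed
    values µa = 0.2, µs = 100 cm⁻¹, g = 0.9, regardless of the subject.
    condition="measured": the wall gets the subject's post-MB values and
    the tissue its pre-MB values (four-region); in a three-region volume
    the merged wall+tissue region gets post-MB values everywhere.

    The cavity interior always gets the Intralipid scattering for the given
    concentration at g = 0.7, with a small background absorption.
    """
    if condition not in ("assumed", "measured"):
        raise ValueError(f"unknown condition {condition!r}")
    if not 0.0 <= intralipid_pct <= 1.0:
        raise ValueError("Intralipid concentration must lie in [0, 1] percent")

    interior = OpticalProperties(
        mua=interior_mua,
        mus=musp_to_mus(intralipid_musp(intralipid_pct), G_INTERIOR),
        g=G_INTERIOR,
    )

    three_region = not (label_volume.labels == Region.WALL).any()

    if condition == "assumed":
        wall = tissue = ASSUMED_WALL
    else:
        if subject is None:
            raise ValueError("condition='measured' requires subject optics")
        wall = OpticalProperties(
            mua=subject.post_mua,
            mus=musp_to_mus(subject.post_musp, G_TISSUE),
            g=G_TISSUE,
        )
        if three_region:
            tissue = wall  # post-MB everywhere
        else:
            tissue = OpticalProperties(
                mua=subject.pre_mua,
                mus=musp_to_mus(subject.pre_musp, G_TISSUE),
                g=G_TISSUE,
            )

    props = {Region.INTERIOR: interior, Region.TISSUE: tissue}
    if not three_region:
        props[Region.WALL] = wall
    return OpticalVolume(label_volume=label_volume, region_props=props, intralipid_pct=intralipid_pct)
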