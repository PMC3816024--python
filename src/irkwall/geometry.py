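"""Analytic ray tracing for the three scene types.

Coordinate conventions (fixed, matching the experimental layouts):

* chamber scenes put the chamber centre at the origin with the point
  source on the negative z axis at ``(0, 0, -source_distance)``;
* phantom scenes put the cylinder axis on z with the base at z = 0;
* the encapsulated source puts the capsule axis on z, centred at the
  origin, and scores laterally along +x.

Tangent rays resolve to zero-length segments (the two quadratic roots
coincide), and points exactly on an interface classify into the denser
region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .physics_data import Material, load_material

_EPS = 1e-12


# -- scene specifications ----------------------------------------------------


@dataclass(frozen=True)
class ChamberSpec:
    """Concentric-sphere cavity chamber in an ambient medium.

    The central electrode is ignored: from outside in the regions are
    ambient, wall and cavity.
    """

    inner_radius: float  # cm
    outer_radius: float  # cm
    wall_material: Material
    cavity_material: Material
    ambient_material: Material
    source_distance: float = 100.0  # cm, point source to chamber centre

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.source_distance <= self.outer_radius:
            raise ValueError("source_distance must exceed outer_radius")

    @property
    def wall_thickness(self) -> float:
        return self.outer_radius - self.inner_radius


@dataclass(frozen=True)
class SourceCapsuleSpec:
    """Cylindrical active core inside a sealed cylindrical capsule."""

    core_length: float  # cm
    core_diameter: float  # cm
    core_material: Material  # iridium
    capsule_outer_length: float  # cm
    capsule_radial_thickness: float  # cm
    capsule_material: Material  # stainless steel

    def __post_init__(self) -> None:
        dims = (
            self.core_length,
            self.core_diameter,
            self.capsule_outer_length,
            self.capsule_radial_thickness,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all capsule dimensions must be positive")
        if self.core_length > self.capsule_outer_length:
            raise ValueError("core does not fit inside the capsule")

    @property
    def core_radius(self) -> float:
        return 0.5 * self.core_diameter

    @property
    def capsule_outer_radius(self) -> float:
        # capsule wall sits snug on the core
        return self.core_radius + self.capsule_radial_thickness


def hdr_ir192_classic_source() -> SourceCapsuleSpec:
    """The encapsulated HDR Ir-192 source: 3.5 mm x 0.6 mm iridium core in
    a 5.0 mm stainless-steel capsule of 250 um radial wall."""
    return SourceCapsuleSpec(
        core_length=0.35,
        core_diameter=0.06,
        core_material=load_material("iridium"),
        capsule_outer_length=0.50,
        capsule_radial_thickness=0.025,
        capsule_material=load_material("steel316"),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """PMMA cylinder with an axial air cavity holding the source."""

    radius: float = 10.0  # cm
    height: float = 14.0  # cm
    cavity_radius: float = 1.0  # cm
    body_material: Material = field(default_factory=lambda: load_material("pmma"))
    cavity_material: Material = field(default_factory=lambda: load_material("air"))
    source_height: float = 7.0  # cm above the base

    def __post_init__(self) -> None:
        if not 0 < self.cavity_radius < self.radius:
            raise ValueError("need 0 < cavity_radius < radius")
        if not 0 < self.source_height < self.height:
            raise ValueError("source_height must lie inside the phantom")


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray  # cm
    direction: np.ndarray  # unit vector

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        norm = math.sqrt(float(d @ d))
        if abs(norm - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector (|d| = 1 to 1e-12)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    @classmethod
    def through(cls, origin, target) -> "Ray":
        o = np.asarray(origin, dtype=np.float64)
        d = np.asarray(target, dtype=np.float64) - o
        return cls(o, d / np.linalg.norm(d))


# -- intersection primitives -------------------------------------------------


def sphere_intersections(ray: Ray, radius: float) -> tuple[float, float]:
    """Signed ray parameters (t_in, t_out) against a sphere centred at the
    origin, or (inf, inf) on a miss. Tangency gives t_in == t_out."""
    o, d = ray.origin, ray.direction
    b = float(o @ d)
    c = float(o @ o) - radius * radius
    disc = b * b - c
    if disc < 0.0:
        return math.inf, math.inf
    s = math.sqrt(disc)
    return -b - s, -b + s


def cylinder_intersections(ray: Ray, radius: float) -> tuple[float, float]:
    """Signed parameters against the infinite cylinder x^2 + y^2 = r^2."""
    ox, oy = ray.origin[0], ray.origin[1]
    dx, dy = ray.direction[0], ray.direction[1]
    a = dx * dx + dy * dy
    if a < _EPS:
        return math.inf, math.inf
    b = ox * dx + oy * dy
    c = ox * ox + oy * oy - radius * radius
    disc = b * b - a * c
    if disc < 0.0:
        return math.inf, math.inf
    s = math.sqrt(disc)
    return (-b - s) / a, (-b + s) / a


# -- region classification ---------------------------------------------------


def chamber_region(chamber: ChamberSpec, point) -> str:
    """{cavity, wall, ambient}; interface points go to the denser region
    (wall on both of its surfaces, since graphite >> air)."""
    r = float(np.linalg.norm(np.asarray(point, dtype=float)))
    if r < chamber.inner_radius:
        return "cavity"
    if r <= chamber.outer_radius:
        return "wall"
    return "ambient"


def locate(phantom: PhantomSpec, point) -> str:
    """{outside, body, cavity}; boundary points resolve to body (denser)."""
    p = np.asarray(point, dtype=float).reshape(3)
    r = math.hypot(p[0], p[1])
    if not (0.0 <= p[2] <= phantom.height) or r > phantom.radius:
        return "outside"
    if r < phantom.cavity_radius and 0.0 < p[2] < phantom.height:
        return "cavity"
    return "body"


# -- boundary stepping -------------------------------------------------------


def _chamber_candidates(chamber: ChamberSpec, ray: Ray) -> list[float]:
    ts = []
    for radius in (chamber.inner_radius, chamber.outer_radius):
        t1, t2 = sphere_intersections(ray, radius)
        ts.extend(t for t in (t1, t2) if t > _EPS and math.isfinite(t))
    return ts


def _phantom_candidates(phantom: PhantomSpec, ray: Ray) -> list[float]:
    ts = []
    for radius in (phantom.cavity_radius, phantom.radius):
        t1, t2 = cylinder_intersections(ray, radius)
        ts.extend(t for t in (t1, t2) if t > _EPS and math.isfinite(t))
    dz = ray.direction[2]
    if abs(dz) > _EPS:
        for z0 in (0.0, phantom.height):
            t = (z0 - ray.origin[2]) / dz
            if t > _EPS:
                ts.append(t)
    return ts


def first_boundary_distance(scene, ray: Ray) -> tuple[float, str, str]:
    """Smallest positive distance at which the ray changes region, with the
    region labels on either side; (inf, region, 'escape') if it never does."""
    if isinstance(scene, ChamberSpec):
        classify, cands = chamber_region, _chamber_candidates(scene, ray)
    elif isinstance(scene, PhantomSpec):
        classify, cands = locate, _phantom_candidates(scene, ray)
    else:
        raise TypeError(f"unsupported scene {type(scene).__name__}")
    before = classify(scene, ray.origin + 1e-9 * ray.direction)
    for t in sorted(cands):
        after = classify(scene, ray.origin + (t + 1e-9) * ray.direction)
        if after != before:
            return t, before, after
    return math.inf, before, "escape"


def wall_entry_path(chamber: ChamberSpec, ray: Ray) -> float:
    """Wall path length an unscattered photon traverses before first
    entering the cavity (the t of the e^{+mu t} unfolding); 0 if the
    cavity is never entered.  The ray must originate outside the chamber."""
    if chamber_region(chamber, ray.origin) != "ambient":
        raise ValueError("ray must originate outside the chamber")
    ci, _ = sphere_intersections(ray, chamber.inner_radius)
    if not math.isfinite(ci) or ci <= 0.0:
        return 0.0
    wi, _ = sphere_intersections(ray, chamber.outer_radius)
    return ci - wi


def cavity_chord(chamber: ChamberSpec, ray: Ray) -> float:
    """Length of the forward ray's intersection with the cavity sphere."""
    t1, t2 = sphere_intersections(ray, chamber.inner_radius)
    if not math.isfinite(t1) or t2 <= 0.0:
        return 0.0
    return t2 - max(t1, 0.0)


# -- YAML serialization ------------------------------------------------------


def chamber_to_yaml(chamber: ChamberSpec) -> str:
    """Serialize to a key-value config (lengths cm, densities g/cm^3).
    Materials are referenced by embedded-table name."""
    return yaml.safe_dump(
        {
            "kind": "chamber",
            "inner_radius_cm": chamber.inner_radius,
            "outer_radius_cm": chamber.outer_radius,
            "source_distance_cm": chamber.source_distance,
            "wall_material": chamber.wall_material.name,
            "wall_density_g_cm3": chamber.wall_material.density,
            "cavity_material": chamber.cavity_material.name,
            "cavity_density_g_cm3": chamber.cavity_material.density,
            "ambient_material": chamber.ambient_material.name,
            "ambient_density_g_cm3": chamber.ambient_material.density,
        },
        sort_keys=False,
    )


def chamber_from_yaml(text: str) -> ChamberSpec:
    cfg = yaml.safe_load(text)
    if cfg.get("kind") != "chamber":
        raise ValueError("config is not a chamber spec")
    return ChamberSpec(
        inner_radius=float(cfg["inner_radius_cm"]),
        outer_radius=float(cfg["outer_radius_cm"]),
        source_distance=float(cfg.get("source_distance_cm", 100.0)),
        wall_material=load_material(
            cfg["wall_material"], cfg.get("wall_density_g_cm3")
        ),
        cavity_material=load_material(
            cfg["cavity_material"], cfg.get("cavity_density_g_cm3")
        ),
        ambient_material=load_material(
            cfg["ambient_material"], cfg.get("ambient_density_g_cm3")
        ),
    )


def phantom_to_yaml(phantom: PhantomSpec) -> str:
    return yaml.safe_dump(
        {
            "kind": "phantom",
            "radius_cm": phantom.radius,
            "height_cm": phantom.height,
            "cavity_radius_cm": phantom.cavity_radius,
            "source_height_cm": phantom.source_height,
            "body_material": phantom.body_material.name,
            "body_density_g_cm3": phantom.body_material.density,
            "cavity_material": phantom.cavity_material.name,
            "cavity_density_g_cm3": phantom.cavity_material.density,
        },
        sort_keys=False,
    )


def phantom_from_yaml(text: str) -> PhantomSpec:
    cfg = yaml.safe_load(text)
    if cfg.get("kind") != "phantom":
        raise ValueError("config is not a phantom spec")
    return PhantomSpec(
        radius=float(cfg["radius_cm"]),
        height=float(cfg["height_cm"]),
        cavity_radius=float(cfg["cavity_radius_cm"]),
        source_height=float(cfg["source_height_cm"]),
        body_material=load_material(
            cfg["body_material"], cfg.get("body_density_g_cm3")
        ),
        cavity_material=load_material(
            cfg["cavity_material"], cfg.get("cavity_density_g_cm3")
        ),
    )
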