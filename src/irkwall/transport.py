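"""Photon Monte Carlo engine with kerma-approximation scoring.

Analog transport: exponential free paths across region boundaries,
photoelectric/incoherent dispatch, Klein-Nishina scattering.  Secondary
electrons are not transported — energy transfer is scored locally via
the track-length collision-kerma estimator (fluence x E x muen/rho),
which is the classic approach for wall-factor work since the wall
factors are ratios of cavity kerma and are insensitive to the cavity
response model.

Primary/scatter tagging realises the split of the cavity deposit into
eps_P and eps_S: a photon is primary until its first interaction.  While
primary, the optical depth accumulated in *wall* material (mu * path,
graphite only — ambient air is transported but not unfolded) is kept so
that each primary deposit can carry the companion e^{+mu t} weight that
estimates the wall-free chamber reading.

Histories are independent; variance is history-by-history.  Identical
(specs, config, seed) give bit-identical tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from numba import njit

from .geometry import ChamberSpec, PhantomSpec
from .physics_data import (
    Material,
    _compton_sample,
    _interp_linlog,
    _interp_loglog,
    energy_absorption_coefficient,
)
from .source_model import Spectrum

_NUDGE = 1e-9  # cm pushed past a boundary before reclassifying
_WORLD_MARGIN = 5.0  # cm of ambient kept beyond the source distance


@dataclass
class RunConfig:
    """Monte Carlo run parameters.

    ``estimator`` selects cavity scoring: 'track_length' scores expected
    collision kerma along every cavity chord; 'analog' scores the energy
    transferred at actual interaction sites (useful with an artificially
    dense cavity).  ``beam_half_angle`` (radians) overrides the
    chamber-subtending cone to make e.g. a central pencil beam.
    """

    n_histories: int = 1_000_000
    seed: int = 12345
    photon_cutoff: float = 0.001  # MeV
    estimator: str = "track_length"
    cone_half_angle_margin: float = 0.05
    beam_half_angle: float | None = None

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.photon_cutoff <= 0:
            raise ValueError("photon_cutoff must be positive")
        if self.estimator not in ("track_length", "analog"):
            raise ValueError("estimator must be 'track_length' or 'analog'")


@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    energy: float  # MeV
    weight: float = 1.0
    n_scatters: int = 0
    wall_optical_depth: float = 0.0  # frozen after the first scatter


@dataclass
class TallyAccumulator:
    """Running sums of tagged cavity deposits with per-history second
    moments (the cross moment of primary+scatter is kept for the
    scatter-factor uncertainty)."""

    n_histories: int = 0
    sum_primary: float = 0.0
    sum_primary_unattenuated: float = 0.0
    sum_scatter: float = 0.0
    sumsq_primary: float = 0.0
    sumsq_unattenuated: float = 0.0
    sumsq_scatter: float = 0.0
    sumsq_total: float = 0.0
    cavity_material: Material | None = None


def score_cavity_track(
    state: PhotonState, chord: float, accumulator: TallyAccumulator
) -> float:
    """Track-length collision-kerma deposit for one cavity traversal.

    deposit = w * E * muen/rho(cavity, E) * rho_cavity * chord, tagged
    primary (with the e^{+mu t} companion) or scatter by ``n_scatters``.
    Returns the deposit.  The jitted kernels inline the same formula and
    aggregate per history; this entry point treats each traversal as its
    own history-level contribution.
    """
    if chord < 0:
        raise ValueError("chord must be >= 0")
    mat = accumulator.cavity_material
    if mat is None:
        raise ValueError("accumulator has no cavity_material attached")
    dep = (
        state.weight
        * state.energy
        * energy_absorption_coefficient(mat, state.energy)
        * mat.density
        * chord
    )
    if state.n_scatters == 0:
        unatt = dep * math.exp(state.wall_optical_depth)
        accumulator.sum_primary += dep
        accumulator.sum_primary_unattenuated += unatt
        accumulator.sumsq_primary += dep * dep
        accumulator.sumsq_unattenuated += unatt * unatt
    else:
        accumulator.sum_scatter += dep
        accumulator.sumsq_scatter += dep * dep
    accumulator.sumsq_total += dep * dep
    return dep


# -- jitted helpers ----------------------------------------------------------


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cos_t, phi):
    """Rotate a unit vector by polar angle acos(cos_t) and azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(dz) < 0.999999:
        den = math.sqrt(1.0 - dz * dz)
        nx = dx * cos_t + sin_t * (dx * dz * cp - dy * sp) / den
        ny = dy * cos_t + sin_t * (dy * dz * cp + dx * sp) / den
        nz = dz * cos_t - sin_t * den * cp
    else:
        sign = 1.0 if dz > 0.0 else -1.0
        nx = sin_t * cp
        ny = sign * sin_t * sp
        nz = sign * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _sphere_exit(b, c):
    """Positive root -b + sqrt(b^2 - c) for a point inside the sphere."""
    return -b + math.sqrt(b * b - c)


@njit(cache=True)
def _draw_energy(mono_energy, edges, cdf):
    if mono_energy > 0.0:
        return mono_energy
    u = np.random.random()
    idx = np.searchsorted(cdf, u)
    if idx >= cdf.size:
        idx = cdf.size - 1
    return edges[idx] + np.random.random() * (edges[idx + 1] - edges[idx])


@njit(cache=True)
def _chamber_kernel(
    n_histories,
    seed,
    mono_energy,
    edges,
    cdf,
    src_dist,
    r_in,
    r_out,
    cos_min,
    e_kill,
    analog,
    amb_log,
    amb_mu,
    amb_pf,
    amb_rho,
    wall_log,
    wall_mu,
    wall_pf,
    wall_rho,
    cav_log,
    cav_mu,
    cav_muen,
    cav_pf,
    cav_rho,
):
    np.random.seed(seed)
    world_r = src_dist + _WORLD_MARGIN
    world2 = world_r * world_r
    rin2 = r_in * r_in
    rout2 = r_out * r_out

    s_p = 0.0
    s_u = 0.0
    s_s = 0.0
    q_p = 0.0
    q_u = 0.0
    q_s = 0.0
    q_t = 0.0

    for _ in range(n_histories):
        energy = _draw_energy(mono_energy, edges, cdf)
        cos_b = cos_min + (1.0 - cos_min) * np.random.random()
        sin_b = math.sqrt(max(0.0, 1.0 - cos_b * cos_b))
        phi = 2.0 * math.pi * np.random.random()
        x = 0.0
        y = 0.0
        z = -src_dist
        dx = sin_b * math.cos(phi)
        dy = sin_b * math.sin(phi)
        dz = cos_b
        w = 1.0
        nsc = 0
        wall_tau = 0.0
        hp = 0.0
        hu = 0.0
        hs = 0.0

        alive = True
        while alive:
            tau = -math.log(np.random.random())
            # walk boundary-delimited segments until tau is consumed
            while True:
                r2 = x * x + y * y + z * z
                if r2 >= world2:
                    alive = False
                    break
                b = x * dx + y * dy + z * dz
                if r2 < rin2:
                    region = 0
                    d_b = _sphere_exit(b, r2 - rin2)
                elif r2 < rout2:
                    region = 1
                    d_b = _sphere_exit(b, r2 - rout2)
                    disc = b * b - (r2 - rin2)
                    if disc > 0.0:
                        t1 = -b - math.sqrt(disc)
                        if t1 > _NUDGE:
                            d_b = min(d_b, t1)
                else:
                    region = 2
                    d_b = _sphere_exit(b, r2 - world2)
                    disc = b * b - (r2 - rout2)
                    if disc > 0.0:
                        t1 = -b - math.sqrt(disc)
                        if t1 > _NUDGE:
                            d_b = min(d_b, t1)

                if region == 0:
                    mu_lin = _interp_loglog(cav_log, cav_mu, energy) * cav_rho
                elif region == 1:
                    mu_lin = _interp_loglog(wall_log, wall_mu, energy) * wall_rho
                else:
                    mu_lin = _interp_loglog(amb_log, amb_mu, energy) * amb_rho

                if mu_lin > 0.0 and mu_lin * d_b >= tau:
                    step = tau / mu_lin
                    interact = True
                else:
                    step = d_b
                    interact = False

                if region == 0 and analog == 0:
                    dep = (
                        w
                        * energy
                        * _interp_loglog(cav_log, cav_muen, energy)
                        * cav_rho
                        * step
                    )
                    if nsc == 0:
                        hp += dep
                        hu += dep * math.exp(wall_tau)
                    else:
                        hs += dep
                if region == 1 and nsc == 0:
                    wall_tau += mu_lin * step

                if not interact:
                    adv = step + _NUDGE
                    x += adv * dx
                    y += adv * dy
                    z += adv * dz
                    tau -= mu_lin * step
                    continue

                # interaction point
                x += step * dx
                y += step * dy
                z += step * dz
                if region == 0:
                    pf = _interp_linlog(cav_log, cav_pf, energy)
                elif region == 1:
                    pf = _interp_linlog(wall_log, wall_pf, energy)
                else:
                    pf = _interp_linlog(amb_log, amb_pf, energy)

                if np.random.random() < pf:
                    # photoelectric absorption ends the history
                    if analog == 1 and region == 0:
                        if nsc == 0:
                            hp += w * energy
                            hu += w * energy * math.exp(wall_tau)
                        else:
                            hs += w * energy
                    alive = False
                    break

                e_new, cos_t = _compton_sample(energy)
                if analog == 1 and region == 0:
                    dep = w * (energy - e_new)
                    if nsc == 0:
                        hp += dep
                        hu += dep * math.exp(wall_tau)
                    else:
                        hs += dep
                psi = 2.0 * math.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cos_t, psi)
                nsc += 1
                if e_new < e_kill:
                    if analog == 1 and region == 0:
                        hs += w * e_new
                    alive = False
                else:
                    energy = e_new
                break  # resample optical depth

        s_p += hp
        s_u += hu
        s_s += hs
        q_p += hp * hp
        q_u += hu * hu
        q_s += hs * hs
        q_t += (hp + hs) * (hp + hs)

    return s_p, s_u, s_s, q_p, q_u, q_s, q_t


@njit(cache=True)
def _phantom_kernel(
    n_histories,
    seed,
    edges,
    cdf,
    sx,
    sy,
    sz,
    r_cav,
    r_body,
    height,
    cube_x,
    cube_half,
    cube_z,
    e_kill,
    cav_log,
    cav_mu,
    cav_pf,
    cav_rho,
    body_log,
    body_mu,
    body_muen,
    body_pf,
    body_rho,
):
    np.random.seed(seed)
    n_cubes = cube_x.size
    dep = np.zeros(n_cubes)
    sums = np.zeros(n_cubes)
    sqs = np.zeros(n_cubes)
    rcav2 = r_cav * r_cav
    rbody2 = r_body * r_body
    z_lo = cube_z - cube_half
    z_hi = cube_z + cube_half
    y_lo = -cube_half
    y_hi = cube_half

    for _ in range(n_histories):
        energy = _draw_energy(-1.0, edges, cdf)
        cos_b = 2.0 * np.random.random() - 1.0
        sin_b = math.sqrt(max(0.0, 1.0 - cos_b * cos_b))
        phi = 2.0 * math.pi * np.random.random()
        x = sx
        y = sy
        z = sz
        dx = sin_b * math.cos(phi)
        dy = sin_b * math.sin(phi)
        dz = cos_b
        w = 1.0
        for i in range(n_cubes):
            dep[i] = 0.0

        alive = True
        while alive:
            tau = -math.log(np.random.random())
            while True:
                rxy2 = x * x + y * y
                if z < 0.0 or z > height or rxy2 >= rbody2:
                    alive = False
                    break
                in_cavity = rxy2 < rcav2

                # distance to the nearest radial or axial boundary
                a = dx * dx + dy * dy
                bq = x * dx + y * dy
                d_b = 1e30
                if a > 1e-20:
                    if in_cavity:
                        d_b = (-bq + math.sqrt(bq * bq - a * (rxy2 - rcav2))) / a
                    else:
                        d_b = (-bq + math.sqrt(bq * bq - a * (rxy2 - rbody2))) / a
                        disc = bq * bq - a * (rxy2 - rcav2)
                        if disc > 0.0:
                            t1 = (-bq - math.sqrt(disc)) / a
                            if t1 > _NUDGE:
                                d_b = min(d_b, t1)
                if dz > 1e-20:
                    d_b = min(d_b, (height - z) / dz)
                elif dz < -1e-20:
                    d_b = min(d_b, -z / dz)

                if in_cavity:
                    mu_lin = _interp_loglog(cav_log, cav_mu, energy) * cav_rho
                else:
                    mu_lin = _interp_loglog(body_log, body_mu, energy) * body_rho

                if mu_lin > 0.0 and mu_lin * d_b >= tau:
                    step = tau / mu_lin
                    interact = True
                else:
                    step = d_b
                    interact = False

                # score track-length kerma in any scoring cube overlapped
                if not in_cavity and step > 0.0:
                    seg_z0 = z
                    seg_z1 = z + step * dz
                    seg_y0 = y
                    seg_y1 = y + step * dy
                    if (
                        max(seg_z0, seg_z1) >= z_lo
                        and min(seg_z0, seg_z1) <= z_hi
                        and max(seg_y0, seg_y1) >= y_lo
                        and min(seg_y0, seg_y1) <= y_hi
                    ):
                        kq = w * energy * _interp_loglog(body_log, body_muen, energy)
                        for i in range(n_cubes):
                            t0 = 0.0
                            t1 = step
                            ok = True
                            for ax in range(3):
                                if ax == 0:
                                    p = x
                                    d = dx
                                    lo = cube_x[i] - cube_half
                                    hi = cube_x[i] + cube_half
                                elif ax == 1:
                                    p = y
                                    d = dy
                                    lo = y_lo
                                    hi = y_hi
                                else:
                                    p = z
                                    d = dz
                                    lo = z_lo
                                    hi = z_hi
                                if abs(d) < 1e-14:
                                    if p < lo or p > hi:
                                        ok = False
                                        break
                                else:
                                    ta = (lo - p) / d
                                    tb = (hi - p) / d
                                    if ta > tb:
                                        ta, tb = tb, ta
                                    if ta > t0:
                                        t0 = ta
                                    if tb < t1:
                                        t1 = tb
                                    if t0 >= t1:
                                        ok = False
                                        break
                            if ok:
                                dep[i] += kq * (t1 - t0)

                if not interact:
                    adv = step + _NUDGE
                    x += adv * dx
                    y += adv * dy
                    z += adv * dz
                    tau -= mu_lin * step
                    continue

                x += step * dx
                y += step * dy
                z += step * dz
                if in_cavity:
                    pf = _interp_linlog(cav_log, cav_pf, energy)
                else:
                    pf = _interp_linlog(body_log, body_pf, energy)
                if np.random.random() < pf:
                    alive = False
                    break
                e_new, cos_t = _compton_sample(energy)
                psi = 2.0 * math.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cos_t, psi)
                if e_new < e_kill:
                    alive = False
                else:
                    energy = e_new
                break

        for i in range(n_cubes):
            sums[i] += dep[i]
            sqs[i] += dep[i] * dep[i]

    return sums, sqs


# -- public drivers ----------------------------------------------------------


def _material_arrays(mat: Material):
    return (
        mat.log_energy_grid,
        mat.mu_over_rho,
        mat.photoelectric_fraction,
        mat.density,
    )


def _source_arrays(source: Union[Spectrum, float]):
    if isinstance(source, Spectrum):
        cdf = np.cumsum(source.fluence)
        cdf = np.ascontiguousarray(cdf / cdf[-1])
        return -1.0, source.bin_edges, cdf, float(source.bin_edges[-1])
    energy = float(source)
    if energy <= 0:
        raise ValueError("monoenergetic source energy must be positive")
    dummy = np.array([energy, energy + 1e-6])
    return energy, dummy, np.array([1.0]), energy


def _effective_cutoff(config: RunConfig, *materials: Material) -> float:
    floor = max(float(m.energy_grid[0]) for m in materials)
    return max(config.photon_cutoff, floor)


def simulate_chamber(
    chamber: ChamberSpec, source: Union[Spectrum, float], config: RunConfig
) -> TallyAccumulator:
    """Run the point-source-at-distance chamber problem.

    Photons are emitted into the cone subtending the chamber (plus the
    configured angular margin); since the wall factors are deposit
    ratios the cone normalisation cancels and history weights stay 1.
    """
    mono, edges, cdf, e_max = _source_arrays(source)
    for mat in (chamber.ambient_material, chamber.wall_material, chamber.cavity_material):
        if e_max > mat.energy_grid[-1]:
            raise ValueError(
                f"source energies exceed the {mat.name} table "
                f"({mat.energy_grid[-1]} MeV)"
            )
    if config.beam_half_angle is not None:
        half = config.beam_half_angle
        if not 0 < half < math.pi / 2:
            raise ValueError("beam_half_angle must lie in (0, pi/2)")
    else:
        half = math.asin(chamber.outer_radius / chamber.source_distance) * (
            1.0 + config.cone_half_angle_margin
        )
        half = min(half, math.pi / 2 * 0.999)
    cos_min = math.cos(half)
    if cos_min >= 1.0:
        raise ValueError("emission cone has zero probability")

    amb_log, amb_mu, amb_pf, amb_rho = _material_arrays(chamber.ambient_material)
    wall_log, wall_mu, wall_pf, wall_rho = _material_arrays(chamber.wall_material)
    cav = chamber.cavity_material
    e_kill = _effective_cutoff(
        config, chamber.ambient_material, chamber.wall_material, cav
    )

    s_p, s_u, s_s, q_p, q_u, q_s, q_t = _chamber_kernel(
        config.n_histories,
        config.seed,
        mono,
        np.ascontiguousarray(edges),
        np.ascontiguousarray(cdf),
        chamber.source_distance,
        chamber.inner_radius,
        chamber.outer_radius,
        cos_min,
        e_kill,
        1 if config.estimator == "analog" else 0,
        amb_log, amb_mu, amb_pf, amb_rho,
        wall_log, wall_mu, wall_pf, wall_rho,
        cav.log_energy_grid, cav.mu_over_rho, cav.muen_over_rho,
        cav.photoelectric_fraction, cav.density,
    )
    return TallyAccumulator(
        n_histories=config.n_histories,
        sum_primary=s_p,
        sum_primary_unattenuated=s_u,
        sum_scatter=s_s,
        sumsq_primary=q_p,
        sumsq_unattenuated=q_u,
        sumsq_scatter=q_s,
        sumsq_total=q_t,
        cavity_material=cav,
    )


SOURCE_POSITIONS = ("central_axis", "A", "B")

#: outer radius of the HDR source capsule (core radius 0.3 mm + 250 um
#: steel wall).  A capsule resting against the cavity wall has its active
#: core centred this far from the surface, which matters at the
#: millimetre distances of the nearest scoring cube.
CAPSULE_STANDOFF_CM = 0.055


@dataclass(frozen=True)
class DoseProfile:
    """Cube-averaged collision kerma along the monitoring line.

    ``dose_per_history`` is in MeV/g per emitted photon; all published
    comparisons are ratios, so the absolute normalisation never enters.
    """

    distances: np.ndarray  # cm from the cavity axis
    dose_per_history: np.ndarray
    rel_std_err: np.ndarray
    source_position: str

    def __post_init__(self) -> None:
        d = np.ascontiguousarray(self.distances, dtype=np.float64)
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        object.__setattr__(self, "distances", d)
        for attr in ("dose_per_history", "rel_std_err"):
            arr = np.ascontiguousarray(getattr(self, attr), dtype=np.float64)
            if arr.shape != d.shape:
                raise ValueError(f"{attr} must match distances")
            object.__setattr__(self, attr, arr)
        if np.any(self.rel_std_err < 0):
            raise ValueError("rel_std_err must be >= 0")

    def dose_at(self, distance: float) -> float:
        idx = np.nonzero(np.isclose(self.distances, distance))[0]
        if idx.size == 0:
            raise KeyError(f"no scoring cube at {distance} cm")
        return float(self.dose_per_history[idx[0]])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "distance_cm": self.distances,
                "dose_per_history": self.dose_per_history,
                "rel_std_err": self.rel_std_err,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source_position: str = "unknown") -> "DoseProfile":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["distance_cm"].to_numpy(),
            df["dose_per_history"].to_numpy(),
            df["rel_std_err"].to_numpy(),
            source_position,
        )


def monitoring_distances(phantom: PhantomSpec, side: float = 0.5) -> np.ndarray:
    """Scoring-cube centres: 0.5 cm cubes packed along the monitoring
    radius from the cavity surface to the phantom surface."""
    first = phantom.cavity_radius + side / 2.0
    n = int(math.floor((phantom.radius - phantom.cavity_radius) / side))
    return first + side * np.arange(n)


def source_point(
    phantom: PhantomSpec, source_position: str, standoff: float = CAPSULE_STANDOFF_CM
) -> np.ndarray:
    """Emission point: on the cavity axis, or — for the displaced cases —
    at the centre of a source capsule resting against the cavity wall, B
    on the side nearest the monitoring line (+x), A diametrically
    opposite.  ``standoff`` is the capsule outer radius; pass 0 for an
    idealised point source exactly on the surface."""
    if source_position not in SOURCE_POSITIONS:
        raise ValueError(f"source_position must be one of {SOURCE_POSITIONS}")
    if not 0 <= standoff < phantom.cavity_radius:
        raise ValueError("standoff must lie in [0, cavity_radius)")
    r = phantom.cavity_radius - max(standoff, 1e-9)
    if source_position == "central_axis":
        return np.array([0.0, 0.0, phantom.source_height])
    if source_position == "B":
        return np.array([r, 0.0, phantom.source_height])
    return np.array([-r, 0.0, phantom.source_height])


def simulate_phantom(
    phantom: PhantomSpec,
    source_position: str,
    source: Spectrum,
    config: RunConfig,
    standoff: float = CAPSULE_STANDOFF_CM,
) -> DoseProfile:
    """Isotropic point source in the phantom cavity; track-length kerma
    scoring in the 0.5 cm cubes along the monitoring line at source
    height.  Photons leaving the phantom are lost (no room scatter)."""
    if not isinstance(source, Spectrum):
        raise TypeError("phantom runs sample energies from a Spectrum")
    pos = source_point(phantom, source_position, standoff)
    cube_x = monitoring_distances(phantom)
    side = 0.5
    cav = phantom.cavity_material
    body = phantom.body_material
    e_kill = _effective_cutoff(config, cav, body)
    cdf = np.cumsum(source.fluence)
    cdf = np.ascontiguousarray(cdf / cdf[-1])

    sums, sqs = _phantom_kernel(
        config.n_histories,
        config.seed,
        np.ascontiguousarray(source.bin_edges),
        cdf,
        pos[0], pos[1], pos[2],
        phantom.cavity_radius,
        phantom.radius,
        phantom.height,
        np.ascontiguousarray(cube_x),
        side / 2.0,
        phantom.source_height,
        e_kill,
        cav.log_energy_grid, cav.mu_over_rho, cav.photoelectric_fraction, cav.density,
        body.log_energy_grid, body.mu_over_rho, body.muen_over_rho,
        body.photoelectric_fraction, body.density,
    )
    n = config.n_histories
    volume = side**3
    mean = sums / n
    var = np.maximum(sqs / n - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var / n) / np.maximum(mean, 1e-300), 0.0)
    return DoseProfile(
        distances=cube_x,
        dose_per_history=mean / volume,
        rel_std_err=rel,
        source_position=source_position,
    )
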