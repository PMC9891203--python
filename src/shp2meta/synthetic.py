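"""Synthetic inputs for every stage of the pipeline — no downloads needed.

Three generators:

* **Two-basin CV-space landscapes** with basins at the closed/open reference
  coordinates of the SHP2 distance CVs and a tunable well-depth asymmetry.
  When a target ΔG_closed→open is requested, the open-well depth is adjusted
  by root-finding so that the Boltzmann-quadrature ΔG at the given
  temperature matches the target to 1e-4 kcal/mol.  Wells are inverted
  Gaussians (analytic gradients) inside quartic confining walls.

* **Toy three-domain bead proteins** whose residue ids mirror SHP2 numbering
  so the real CV suite runs unmodified.  The closed/open poses are built
  analytically to hit the crystal-structure CV references; domain-internal
  bead offsets are seeded and shared between states, so frames pair atom by
  atom for RMSD work.

* **Bernoulli hydrogen-bond event series** (and matching two-residue frame
  trajectories) with prescribed occupancy.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .metad import KB, BasinSpec, BiasState, Landscape, MetaDParams, MetaDRun, run_wtmetad, write_hills
from .structures import Structure

__all__ = [
    "TwoStateLandscapeSpec",
    "TwoStateLandscape",
    "make_two_state_landscape",
    "boltzmann_delta_g",
    "ToyProteinSpec",
    "make_toy_protein",
    "make_toy_trajectory",
    "make_hbond_series",
    "make_hbond_frames",
    "ReferenceRun",
    "make_metad_reference_run",
]

# Closed/open reference coordinates of the two distance CVs (Å)
CLOSED_CENTER_2D = (16.1, 35.1)
OPEN_CENTER_2D = (37.9, 18.4)


# --- Two-basin landscapes -----------------------------------------------------

@dataclass
class TwoStateLandscapeSpec:
    """Parameters of a two-basin CV landscape.

    ``barrier`` is the depth of the closed well below the inter-well plateau
    (the wells are far enough apart that the saddle sits essentially at the
    plateau level, so this is the closed→open barrier).  ``well_depths``
    overrides the (closed, open) depths explicitly; otherwise the closed
    depth equals ``barrier`` and the open depth is tuned to
    ``target_delta_g`` when given.
    """

    closed_center: Sequence[float] = CLOSED_CENTER_2D
    open_center: Sequence[float] = OPEN_CENTER_2D
    barrier: float = 12.0
    well_depths: tuple[float, float] | None = None
    well_sigma: float = 3.0
    target_delta_g: float | None = None
    temperature: float = 298.0
    basin_radius_fraction: float = 0.45
    wall_stiffness: float = 0.5
    box_pad: float = 10.0

    def __post_init__(self) -> None:
        self.closed_center = np.atleast_1d(np.asarray(self.closed_center, dtype=float))
        self.open_center = np.atleast_1d(np.asarray(self.open_center, dtype=float))
        if self.closed_center.shape != self.open_center.shape:
            raise ParameterError("centers must have the same dimension")
        if np.allclose(self.closed_center, self.open_center):
            raise ParameterError("closed and open centers must be distinct")
        if self.barrier <= max(0.0, abs(self.target_delta_g or 0.0)):
            raise ParameterError("barrier must exceed max(0, |target_delta_g|)")
        if self.well_sigma <= 0 or self.temperature <= 0:
            raise ParameterError("well_sigma and temperature must be positive")

    @property
    def dimension(self) -> int:
        return len(self.closed_center)

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.open_center - self.closed_center))

    @classmethod
    def for_target(cls, target_delta_g: float, **kwargs) -> "TwoStateLandscapeSpec":
        """Spec with the barrier rule barrier = |ΔG| + 5 kcal/mol, which keeps
        the closed→open barrier a fixed margin above the asymmetry."""
        return cls(target_delta_g=target_delta_g,
                   barrier=abs(target_delta_g) + 5.0, **kwargs)


@dataclass
class TwoStateLandscape:
    """A generated landscape bundled with its basin regions and quadrature ΔG."""

    landscape: Landscape
    spec: TwoStateLandscapeSpec
    basin_closed: BasinSpec
    basin_open: BasinSpec
    depths: tuple[float, float]
    delta_g_quadrature: float


def _two_state_energy_factory(spec: TwoStateLandscapeSpec, depths: tuple[float, float],
                              box: np.ndarray):
    """Vectorized energy/gradient for Gaussian wells + quartic walls."""
    cc = spec.closed_center
    oc = spec.open_center
    dc, do = depths
    s2 = spec.well_sigma ** 2
    k = spec.wall_stiffness
    lo_soft = box[:, 0] + 2.0
    hi_soft = box[:, 1] - 2.0

    def energy_vec(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        gc = np.exp(-0.5 * np.sum((pts - cc) ** 2, axis=1) / s2)
        go = np.exp(-0.5 * np.sum((pts - oc) ** 2, axis=1) / s2)
        u = -dc * gc - do * go
        under = np.clip(lo_soft - pts, 0.0, None)
        over = np.clip(pts - hi_soft, 0.0, None)
        u = u + k * np.sum(under ** 4 + over ** 4, axis=1)
        return u

    def energy(s) -> float:
        return float(energy_vec(np.atleast_1d(np.asarray(s, dtype=float))[None, :])[0])

    def gradient(s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        gc = math.exp(-0.5 * float(np.sum((s - cc) ** 2)) / s2)
        go = math.exp(-0.5 * float(np.sum((s - oc) ** 2)) / s2)
        g = dc * (s - cc) / s2 * gc + do * (s - oc) / s2 * go
        under = np.clip(lo_soft - s, 0.0, None)
        over = np.clip(s - hi_soft, 0.0, None)
        g = g - 4.0 * k * under ** 3 + 4.0 * k * over ** 3
        return g

    return energy, gradient, energy_vec


def boltzmann_delta_g(
    energy_vec,
    basin_a: BasinSpec,
    basin_b: BasinSpec,
    temperature: float,
    spacing: float = 0.05,
) -> float:
    """ΔG_{a→b} by direct Boltzmann quadrature of an analytic energy.

    Each (center, radius) basin is gridded relative to its own center so a
    mirror-symmetric landscape yields exactly 0.
    """
    beta = 1.0 / (KB * temperature)

    def z(basin: BasinSpec) -> float:
        c = np.asarray(basin.center, dtype=float)
        r = basin.radius
        n = int(math.ceil(2 * r / spacing)) + 1
        ax = np.linspace(-r, r, n)
        mesh = np.meshgrid(*([ax] * len(c)), indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        keep = np.sum(pts ** 2, axis=1) <= r ** 2
        pts = pts[keep] + c
        return float(np.sum(np.exp(-beta * energy_vec(pts))))

    za = z(basin_a)
    zb = z(basin_b)
    return float(-KB * temperature * math.log(zb / za))


def make_two_state_landscape(spec: TwoStateLandscapeSpec) -> TwoStateLandscape:
    """Build a two-basin landscape, tuning the open-well depth to any target ΔG.

    The returned bundle carries the analytic :class:`Landscape`, disjoint
    closed/open basin regions (radius = ``basin_radius_fraction`` × the
    center separation) and the quadrature ΔG_closed→open actually achieved.
    """
    dim = spec.dimension
    cmin = np.minimum(spec.closed_center, spec.open_center)
    cmax = np.maximum(spec.closed_center, spec.open_center)
    pad = 3.0 * spec.well_sigma + spec.box_pad
    box = np.stack([cmin - pad, cmax + pad], axis=1)

    radius = spec.basin_radius_fraction * spec.separation
    basin_closed = BasinSpec("closed", center=tuple(spec.closed_center), radius=radius)
    basin_open = BasinSpec("open", center=tuple(spec.open_center), radius=radius)

    d_closed = spec.well_depths[0] if spec.well_depths else spec.barrier

    def quad_dg(d_open: float) -> float:
        _, _, evec = _two_state_energy_factory(spec, (d_closed, d_open), box)
        return boltzmann_delta_g(evec, basin_closed, basin_open, spec.temperature)

    if spec.well_depths is not None:
        d_open = spec.well_depths[1]
    elif spec.target_delta_g is None:
        d_open = d_closed
    else:
        target = spec.target_delta_g
        lo, hi = 1e-6, d_closed + abs(target) + 30.0
        try:
            d_open = brentq(lambda d: quad_dg(d) - target, lo, hi, xtol=1e-10, rtol=1e-12)
        except ValueError as exc:
            raise ParameterError(
                f"target ΔG {target} kcal/mol unreachable with closed depth {d_closed}"
            ) from exc

    energy, gradient, energy_vec = _two_state_energy_factory(spec, (d_closed, d_open), box)
    achieved = boltzmann_delta_g(energy_vec, basin_closed, basin_open, spec.temperature)
    landscape = Landscape(dimension=dim, energy=energy, gradient=gradient, box=box)
    return TwoStateLandscape(
        landscape=landscape,
        spec=spec,
        basin_closed=basin_closed,
        basin_open=basin_open,
        depths=(float(d_closed), float(d_open)),
        delta_g_quadrature=float(achieved),
    )


# --- Toy three-domain proteins ------------------------------------------------

@dataclass
class ToyProteinSpec:
    """Layout of the synthetic bead protein (residue ids mirror SHP2)."""

    seed: int = 2024
    nsh2_residues: tuple[int, int] = (40, 90)
    csh2_residues: tuple[int, int] = (160, 175)
    ptp_filler_residues: tuple[int, int] = (300, 315)
    interface_jitter: float = 3.0
    com_jitter: float = 4.0
    filler_jitter: float = 3.0
    patch_separation: float = 30.0  # distance between the two PTP interface CoMs

    # residues of the two PTP interface patches (Cα CoM groups of the distance CVs)
    @property
    def patch1(self) -> list[int]:
        return [*range(255, 258), *range(465, 468), *range(495, 498), *range(508, 512)]

    @property
    def patch2(self) -> list[int]:
        return [*range(224, 227), *range(479, 483), *range(520, 523)]


#: CV reference values (closed, open) used as construction targets
_CV_TARGETS = {
    "dist1_np": (16.1, 37.9),
    "dist2_np": (35.1, 18.4),
    "dih_ncpp": (-59.5, 66.4),
    "psi_t218": (13.4, 154.5),
    "dist_k76_r265": (9.9, 47.9),
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero vector")
    return v / n


def place_atom(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place p4 so that |p4-p3| = bond, angle(p2,p3,p4) = angle and
    dihedral(p1,p2,p3,p4) = torsion (degrees).  Standard internal-coordinate
    (NeRF) construction."""
    theta = math.radians(angle)
    tau = math.radians(torsion)
    b2 = _unit(p3 - p2)
    n = _unit(np.cross(p2 - p1, b2))
    m = np.cross(n, b2)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        -bond * math.sin(theta) * math.sin(tau),
    ])
    return p3 + d[0] * b2 + d[1] * m + d[2] * n


def _zero_mean_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    off = rng.normal(scale=radius / 2.0, size=(n, 3))
    return off - off.mean(axis=0)


def _com_anchor_position(d1: float, d2: float, p: float) -> np.ndarray:
    """Planar triangulation: point at distance d1 from the origin and d2 from
    (p, 0, 0), in the upper half of the xy-plane."""
    x = (d1 ** 2 - d2 ** 2 + p ** 2) / (2.0 * p)
    y2 = d1 ** 2 - x ** 2
    if y2 <= 0:
        raise ParameterError(
            f"CV targets geometrically inconsistent: d1={d1}, d2={d2}, patch separation={p}"
        )
    return np.array([x, math.sqrt(y2), 0.0])


def make_toy_protein(spec: ToyProteinSpec, state: str) -> Structure:
    """Build a three-domain bead structure in the requested state.

    The returned structure carries one pseudo-Cα per residue needed by the CV
    suite plus filler beads; in either pose the five-CV suite evaluates to
    the corresponding crystal-structure references (distances exact by
    construction, torsions to float precision).  The same seed yields
    pairable atoms across states.
    """
    if state not in ("closed", "open"):
        raise ValueError("state must be 'closed' or 'open'")
    col = 0 if state == "closed" else 1
    rng = np.random.default_rng(spec.seed)

    atoms: dict[tuple[int, str], tuple[str, str, np.ndarray]] = {}

    def put(rid: int, name: str, element: str, resname: str, pos: np.ndarray) -> None:
        atoms[(rid, name)] = (element, resname, np.asarray(pos, dtype=float))

    # --- PTP domain: two rigid interface patches + filler (state-independent)
    p1_center = np.zeros(3)
    p2_center = np.array([spec.patch_separation, 0.0, 0.0])
    off1 = _zero_mean_offsets(rng, len(spec.patch1), spec.interface_jitter)
    off2 = _zero_mean_offsets(rng, len(spec.patch2), spec.interface_jitter)
    for rid, off in zip(spec.patch1, off1):
        put(rid, "CA", "C", "ALA", p1_center + off)
    for rid, off in zip(spec.patch2, off2):
        put(rid, "CA", "C", "ALA", p2_center + off)
    filler_lo, filler_hi = spec.ptp_filler_residues
    ptp_core = np.array([spec.patch_separation / 2.0, -12.0, -6.0])
    for rid in range(filler_lo, filler_hi + 1):
        put(rid, "CA", "C", "ALA", ptp_core + rng.normal(scale=spec.filler_jitter, size=3))
    # Cα of residue 265 belongs to the rigid PTP domain (state-independent);
    # only its Cβ (placed below) tracks the interface distance CV
    put(265, "CA", "C", "ARG", ptp_core + rng.normal(scale=spec.filler_jitter, size=3))

    # --- N-SH2 blocking segment: Cα CoM triangulated from the two distances
    d1 = _CV_TARGETS["dist1_np"][col]
    d2 = _CV_TARGETS["dist2_np"][col]
    com = _com_anchor_position(d1, d2, spec.patch_separation)
    com_res = list(range(54, 87))
    com_off = _zero_mean_offsets(rng, len(com_res), spec.com_jitter)
    for rid, off in zip(com_res, com_off):
        resname = "GLU" if rid == 76 else "ALA"
        put(rid, "CA", "C", resname, com + off)
    # remaining N-SH2 beads (44 is re-placed below as a torsion anchor)
    nsh2_lo, nsh2_hi = spec.nsh2_residues
    extra = [r for r in range(nsh2_lo, nsh2_hi + 1) if r not in com_res and r != 44]
    for rid in extra:
        put(rid, "CA", "C", "ALA", com + rng.normal(scale=spec.com_jitter, size=3))

    # --- C-SH2 blob
    csh2_center = np.array([15.0, 20.0, 8.0])
    cs_lo, cs_hi = spec.csh2_residues
    for rid in range(cs_lo, cs_hi + 1):
        if rid == 168:
            put(rid, "CA", "C", "ALA", csh2_center)
        else:
            put(rid, "CA", "C", "ALA", csh2_center + rng.normal(scale=spec.filler_jitter, size=3))

    # --- pseudo-dihedral anchor: Cα44 placed by internal coordinates so that
    # dihedral(Cα44, Cα168, Cα497, Cα510) hits the target
    dih_target = _CV_TARGETS["dih_ncpp"][col]
    a168 = atoms[(168, "CA")][2]
    a497 = atoms[(497, "CA")][2]
    a510 = atoms[(510, "CA")][2]
    # torsions are chain-reversal symmetric: placing Cα44 down the reversed
    # chain with the same torsion gives dihedral(44, 168, 497, 510) = target
    ca44 = place_atom(a510, a497, a168, bond=12.0, angle=85.0, torsion=dih_target)
    put(44, "CA", "C", "SER", ca44)

    # --- ψ_T218 backbone unit in the C-SH2/PTP linker
    psi_target = _CV_TARGETS["psi_t218"][col]
    n218 = np.array([20.0, 12.0, 4.0])
    ca218 = n218 + np.array([1.46, 0.0, 0.0])
    c218 = place_atom(n218 + np.array([0.0, 0.0, 1.0]), n218, ca218,
                      bond=1.52, angle=111.0, torsion=-60.0)
    n219 = place_atom(n218, ca218, c218, bond=1.33, angle=116.0, torsion=psi_target)
    ca219 = place_atom(ca218, c218, n219, bond=1.46, angle=121.0, torsion=180.0)
    put(218, "N", "N", "THR", n218)
    put(218, "CA", "C", "THR", ca218)
    put(218, "C", "C", "THR", c218)
    put(219, "N", "N", "THR", n219)
    put(219, "CA", "C", "THR", ca219)
    put(217, "CA", "C", "ALA", n218 + np.array([-2.0, -1.0, 0.5]))

    # --- Cβ pair distance (side-chain anchor of the interface hydrogen bond)
    cb_target = _CV_TARGETS["dist_k76_r265"][col]
    ca76 = atoms[(76, "CA")][2]
    cb76 = ca76 + 1.53 * _unit(np.array([0.3, -0.8, 0.5]))
    put(76, "CB", "C", "GLU", cb76)
    toward_ptp = _unit(ptp_core - cb76)
    cb265 = cb76 + cb_target * toward_ptp
    put(265, "CB", "C", "ARG", cb265)

    # --- assemble in residue order
    keys = sorted(atoms.keys(), key=lambda k: (k[0], k[1]))
    serials, names, elements, resnames, rids, chains, coords = [], [], [], [], [], [], []
    for i, key in enumerate(keys, start=1):
        element, resname, pos = atoms[key]
        serials.append(i)
        names.append(key[1])
        elements.append(element)
        resnames.append(resname)
        rids.append(key[0])
        chains.append("A")
        coords.append(pos)
    return Structure(serials, names, elements, resnames, rids, chains,
                     np.asarray(coords), label=f"toy-{state}")


def make_toy_trajectory(
    spec: ToyProteinSpec,
    states: Sequence[str],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[Structure]:
    """A frame sequence of toy structures in the given states, with optional
    i.i.d. Gaussian coordinate noise on every frame."""
    rng = np.random.default_rng(seed)
    base = {s: make_toy_protein(spec, s) for s in set(states)}
    frames = []
    for state in states:
        f = base[state].copy()
        if noise_sigma > 0:
            f.coords = f.coords + rng.normal(scale=noise_sigma, size=f.coords.shape)
        f.label = f"toy-{state}"
        frames.append(f)
    return frames


# --- Hydrogen-bond event series -----------------------------------------------

def make_hbond_series(occupancy_target: float, n_frames: int, seed: int) -> np.ndarray:
    """I.i.d. Bernoulli(occupancy/100) presence series."""
    if not (0.0 <= occupancy_target <= 100.0):
        raise ValueError("occupancy target must be in [0, 100]")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    return rng.random(n_frames) < (occupancy_target / 100.0)


def make_hbond_frames(present: Sequence[bool]) -> list[Structure]:
    """Two-residue frames realizing a prescribed presence series.

    A glutamate side-chain carboxylate oxygen (residue 76) faces an arginine
    side-chain N–H (residue 265).  In "present" frames the geometry is an
    ideal linear hydrogen bond (2.9 Å donor–acceptor); in absent frames the
    acceptor is displaced beyond the distance cutoff.
    """
    frames = []
    for flag in np.asarray(present, dtype=bool):
        acceptor_x = 2.9 if flag else 5.5
        serials = [1, 2, 3, 4]
        names = ["NE", "HE", "CD", "OE1"]
        elements = ["N", "H", "C", "O"]
        resnames = ["ARG", "ARG", "GLU", "GLU"]
        rids = [265, 265, 76, 76]
        chains = ["A"] * 4
        coords = np.array([
            [0.0, 0.0, 0.0],        # donor N
            [1.0, 0.0, 0.0],        # donor H, pointing at the acceptor
            [acceptor_x + 1.3, 0.9, 0.0],
            [acceptor_x, 0.0, 0.0],  # acceptor O
        ])
        frames.append(Structure(serials, names, elements, resnames, rids, chains, coords,
                                label="hbond-frame"))
    return frames


# --- Seeded metadynamics reference run ----------------------------------------

@dataclass
class ReferenceRun:
    """Deterministic end-to-end metadynamics fixture on a 1D double well."""

    landscape: Landscape
    params: MetaDParams
    n_steps: int
    dt: float
    diffusion: float
    seed: int
    run: MetaDRun
    hills: str
    basin_left: BasinSpec
    basin_right: BasinSpec
    expected_delta_g: float
    barrier_height: float


def double_well_landscape(h: float = 4.0, half_width: float = 1.7,
                          tilt: float = 0.0) -> Landscape:
    """1D quartic double well U(x) = h·(x²−1)² + tilt·x with minima near ±1
    and barrier h at x = 0."""

    def energy(s) -> float:
        x = float(np.atleast_1d(s)[0])
        return h * (x * x - 1.0) ** 2 + tilt * x

    def gradient(s) -> np.ndarray:
        x = float(np.atleast_1d(s)[0])
        return np.array([4.0 * h * x * (x * x - 1.0) + tilt])

    return Landscape(dimension=1, energy=energy, gradient=gradient,
                     box=np.array([[-half_width, half_width]]))


def make_metad_reference_run(seed: int, n_steps: int = 500_000,
                             barrier: float = 4.0) -> ReferenceRun:
    """Run the seeded 1D double-well reference simulation.

    Fixed study conditions: barrier 4 kcal/mol, T = 298 K, Gaussian width
    0.1 (one fifth of the well width), initial height 0.25 kcal/mol
    (≈ 0.4 kBT), a deposition every 200 steps and bias factor 10.  The
    expected ΔG between the two basins is 0 by symmetry (and is recomputed
    here by quadrature rather than assumed).
    """
    landscape = double_well_landscape(h=barrier)
    params = MetaDParams(sigma=0.1, w0=0.25, stride=200, bias_factor=10.0,
                         temperature=298.0)
    dt = 0.1
    diffusion = 0.03
    run = run_wtmetad(landscape, params, n_steps=n_steps, dt=dt,
                      diffusion=diffusion, seed=seed,
                      initial=np.array([-1.0]))
    basin_left = BasinSpec("closed", box=[(-1.45, -0.3)])
    basin_right = BasinSpec("open", box=[(0.3, 1.45)])

    def energy_vec(pts: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(pts)[:, 0]
        return barrier * (x * x - 1.0) ** 2

    # quadrature over box basins on a fine grid
    beta = 1.0 / (KB * params.temperature)

    def z(lo: float, hi: float) -> float:
        x = np.linspace(lo, hi, 2001)
        return float(np.trapezoid(np.exp(-beta * barrier * (x * x - 1.0) ** 2), x))

    expected = -KB * params.temperature * math.log(
        z(0.3, 1.45) / z(-1.45, -0.3)
    )
    return ReferenceRun(
        landscape=landscape,
        params=params,
        n_steps=n_steps,
        dt=dt,
        diffusion=diffusion,
        seed=seed,
        run=run,
        hills=write_hills(run),
        basin_left=basin_left,
        basin_right=basin_right,
        expected_delta_g=float(expected),
        barrier_height=barrier,
    )
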