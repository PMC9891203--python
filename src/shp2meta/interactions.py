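"""Hydrogen-bond occupancy and pairwise nonbonded inter-domain energies.

Hydrogen bonds follow the donor–acceptor distance cutoff of 3.5 Å combined
with a 20° linearity cutoff on the D–H···A angle; explicit hydrogens are
required (protonation is never guessed).  Nonbonded energies are the 12-6
Lennard-Jones plus direct Coulomb sum over cross-group atom pairs, with a
CHARMM-style atom-based force-switching envelope between r_on = 10 Å and
r_off = 12 Å.  Force-field parameters (ε, Rmin/2, q per atom type) are a
user-supplied table; no parameter library is redistributed with the package.

Coulomb interactions are evaluated directly (no Ewald): a pairwise
interaction-energy decomposition between two atom groups is not an
Ewald-defined quantity, so the direct sum is this package's convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ParameterError
from .geometry import angle_between, pair_distance
from .structures import Structure

__all__ = [
    "HBondRecord",
    "NonbondedParams",
    "EnergyBreakdown",
    "hbond_present",
    "sidechain_hbond_scan",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "interdomain_energy",
    "occupancy",
    "hbond_report",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

#: Backbone atoms excluded from the side-chain hydrogen-bond scan.
_BACKBONE_POLAR = {"N", "O", "OXT"}


def occupancy(per_frame: Sequence[bool] | np.ndarray) -> float:
    """Percentage of frames in which an event is present, in [0, 100]."""
    arr = np.asarray(per_frame, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty frame series")
    return 100.0 * float(arr.sum()) / arr.size


@dataclass
class HBondRecord:
    """One donor→acceptor hydrogen bond tracked over a trajectory."""

    donor: tuple[str, int, str, str]  # (chain, residue_id, residue_name, atom_name)
    hydrogen: tuple[str, int, str, str] | None
    acceptor: tuple[str, int, str, str]
    per_frame: np.ndarray = field(repr=False)

    @property
    def occupancy(self) -> float:
        return occupancy(self.per_frame)

    def key(self) -> tuple:
        return (self.donor, self.hydrogen, self.acceptor)


def hbond_present(
    donor_pos,
    hydrogen_pos,
    acceptor_pos,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 20.0,
) -> bool:
    """Geometric hydrogen-bond test.

    True iff the donor–acceptor distance is within ``distance_cutoff`` and the
    D–H···A arrangement deviates from linearity by at most ``angle_cutoff``
    degrees (i.e. the angle at the hydrogen is at least 180° − cutoff).
    """
    d = pair_distance(donor_pos, acceptor_pos)
    if d < 1e-6:
        raise DegenerateGeometryError("donor and acceptor coincide")
    if d > distance_cutoff:
        return False
    theta = angle_between(donor_pos, hydrogen_pos, acceptor_pos)
    return (180.0 - theta) <= angle_cutoff


def _is_hydrogen(element: str, name: str) -> bool:
    if element:
        return element.upper() == "H"
    return name.startswith("H") or (name[:1].isdigit() and name[1:2] == "H")


def _polar_heavy(element: str) -> bool:
    return element.upper() in ("N", "O")


def _atom_key(s: Structure, i: int) -> tuple[str, int, str, str]:
    return (str(s.chains[i]), int(s.residue_ids[i]), str(s.residue_names[i]), str(s.names[i]))


def _sidechain_polar_atoms(s: Structure, residue_ids: set[int]) -> tuple[list[tuple[int, int]], list[int]]:
    """(donor, attached-H) index pairs and acceptor indices among side-chain
    N/O atoms of the given residues.  Hydrogen attachment is inferred by a
    1.25 Å covalent-distance criterion within the same residue."""
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i in range(len(s)):
        rid = int(s.residue_ids[i])
        if rid not in residue_ids:
            continue
        name = str(s.names[i])
        elem = str(s.elements[i])
        if not _polar_heavy(elem) or name in _BACKBONE_POLAR:
            continue
        acceptors.append(i)
        same_res = np.nonzero(s.residue_ids == rid)[0]
        for j in same_res:
            if _is_hydrogen(str(s.elements[j]), str(s.names[j])):
                if pair_distance(s.coords[i], s.coords[j]) <= 1.25:
                    donors.append((i, int(j)))
    return donors, acceptors


def sidechain_hbond_scan(
    frames: Sequence[Structure],
    group_a: Iterable[int],
    group_b: Iterable[int],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 20.0,
) -> list[HBondRecord]:
    """Scan a trajectory for side-chain hydrogen bonds between two residue groups.

    Donors are side-chain N/O atoms carrying an explicit hydrogen; acceptors
    are side-chain N/O atoms.  Both directions (donor in A, acceptor in B and
    vice versa) are enumerated; backbone amide/carbonyl atoms are excluded.
    Records are keyed by (donor, hydrogen, acceptor) atom identity; each
    carries a per-frame presence series and its occupancy.

    An empty list is a legal result — it is exactly what a trajectory without
    cross-group polar contacts (e.g. the mutant interface) produces.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames given")
    ga = {int(r) for r in group_a}
    gb = {int(r) for r in group_b}
    if ga & gb:
        raise ValueError("residue groups must be disjoint")

    first = frames[0]
    n_h = sum(1 for i in range(len(first)) if _is_hydrogen(str(first.elements[i]), str(first.names[i])))
    if n_h == 0:
        raise ValueError(
            "no hydrogen atoms found: the side-chain hydrogen-bond scan requires "
            "protonated input structures"
        )

    candidates: dict[tuple, list[bool]] = {}
    for f_idx, frame in enumerate(frames):
        donors_a, acc_a = _sidechain_polar_atoms(frame, ga)
        donors_b, acc_b = _sidechain_polar_atoms(frame, gb)
        present_this_frame: set[tuple] = set()
        for donors, acceptors in ((donors_a, acc_b), (donors_b, acc_a)):
            for (di, hi) in donors:
                for ai in acceptors:
                    if not hbond_present(
                        frame.coords[di], frame.coords[hi], frame.coords[ai],
                        distance_cutoff, angle_cutoff,
                    ):
                        continue
                    key = (_atom_key(frame, di), _atom_key(frame, hi), _atom_key(frame, ai))
                    present_this_frame.add(key)
        for key in present_this_frame:
            if key not in candidates:
                # first observed now: absent in all earlier frames
                candidates[key] = [False] * f_idx
        for key, series in candidates.items():
            series.append(key in present_this_frame)

    records = []
    for key, series in candidates.items():
        records.append(
            HBondRecord(donor=key[0], hydrogen=key[1], acceptor=key[2],
                        per_frame=np.asarray(series, dtype=bool))
        )
    records.sort(key=lambda r: -r.occupancy)
    return records


def hbond_report(records: Sequence[HBondRecord]) -> pd.DataFrame:
    """Tabular report (donor, hydrogen, acceptor, occupancy %), occupancy-descending."""
    rows = []
    for r in sorted(records, key=lambda r: -r.occupancy):
        fmt = lambda k: f"{k[0]}:{k[2]}{k[1]}:{k[3]}"
        rows.append(
            {
                "donor": fmt(r.donor),
                "hydrogen": fmt(r.hydrogen) if r.hydrogen else "",
                "acceptor": fmt(r.acceptor),
                "occupancy_percent": round(r.occupancy, 2),
            }
        )
    return pd.DataFrame(rows, columns=["donor", "hydrogen", "acceptor", "occupancy_percent"])


# --- Nonbonded energies -------------------------------------------------------

@dataclass
class NonbondedParams:
    """Per-atom-type Lennard-Jones/charge table plus global nonbonded options.

    ``table`` maps an atom key to (epsilon [kcal/mol], rmin_half [Å],
    charge [e]).  Keys are looked up as ``"RESNAME:ATOMNAME"`` first, then the
    bare atom name — so a table may be residue-specific or generic.
    """

    table: Mapping[str, tuple[float, float, float]]
    r_on: float = 10.0
    r_off: float = 12.0
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 1.0
    switching: bool = True

    def __post_init__(self) -> None:
        if self.r_on >= self.r_off:
            raise ParameterError("r_on must be smaller than r_off")
        for key, (eps, rmin_half, _q) in self.table.items():
            if eps < 0:
                raise ParameterError(f"negative epsilon for {key!r}")
            if rmin_half <= 0:
                raise ParameterError(f"non-positive rmin_half for {key!r}")

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float, float]:
        key = f"{residue_name}:{atom_name}"
        if key in self.table:
            return self.table[key]
        if atom_name in self.table:
            return self.table[atom_name]
        raise ParameterError(f"no nonbonded parameters for atom {key!r}")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NonbondedParams":
        df = pd.read_csv(path)
        required = {"atom_key", "epsilon", "rmin_half", "charge"}
        if not required.issubset(df.columns):
            raise ParameterError(f"parameter table must have columns {sorted(required)}")
        table = {
            str(row.atom_key): (float(row.epsilon), float(row.rmin_half), float(row.charge))
            for row in df.itertuples()
        }
        return cls(table=table, **kwargs)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Lennard-Jones / Coulomb decomposition of a group-group interaction."""

    lj: float
    coulomb: float
    pair_count: int

    @property
    def total(self) -> float:
        return self.lj + self.coulomb

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.lj + other.lj, self.coulomb + other.coulomb,
                               self.pair_count + other.pair_count)


def _switch_poly(r_on: float, r_off: float) -> tuple[np.ndarray, float]:
    """Coefficients (in powers of r²) of the switching function S(r) on
    [r_on, r_off]: S = (a0 + a1 t + a2 t² + a3 t³)/denom with t = r².
    S(r_on) = 1, S(r_off) = 0, S'(r_on) = S'(r_off) = 0."""
    A2 = r_off ** 2
    B2 = r_on ** 2
    denom = (A2 - B2) ** 3
    coeffs = np.array([A2 ** 2 * (A2 - 3.0 * B2), 6.0 * A2 * B2, -3.0 * (A2 + B2), 2.0])
    return coeffs, denom


def _plain_energy(terms: Sequence[tuple[float, int]], r):
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for c, m in terms:
        out += c * r ** m
    return out


def _switched_terms_antiderivative(terms, r_on, r_off):
    """Antiderivative G(s) of the switched force S(s)·F(s), F = -dU/ds,
    returned as a callable.  Termwise: each U-term c·s^m contributes force
    -c·m·s^(m-1); multiplied by the polynomial S(s) in s² and integrated,
    giving power terms plus (possibly) a logarithm."""
    coeffs, denom = _switch_poly(r_on, r_off)
    power_terms: list[tuple[float, int]] = []  # (coefficient, exponent) of G
    log_coeff = 0.0
    for c, m in terms:
        for k, a in enumerate(coeffs):
            # force term: -(c*m) * a/denom * s^(2k + m - 1)
            fc = -(c * m) * a / denom
            p = 2 * k + m - 1
            if p == -1:
                log_coeff += fc
            else:
                power_terms.append((fc / (p + 1), p + 1))

    def G(s):
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for fc, p in power_terms:
            out += fc * s ** p
        if log_coeff != 0.0:
            out = out + log_coeff * np.log(s)
        return out

    return G


def _switched_energy(terms: Sequence[tuple[float, int]], r, r_on: float, r_off: float):
    """Energy of a power-law potential U(r) = Σ c·r^m under atom-based force
    switching: the force is multiplied by the smooth switch S(r) on
    [r_on, r_off] (zero beyond), and the energy is the integral of that
    switched force from r_off inward — continuous everywhere, exactly zero at
    and beyond r_off."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    out = np.zeros_like(r)
    G = _switched_terms_antiderivative(terms, r_on, r_off)
    in_switch = (r >= r_on) & (r < r_off)
    below = r < r_on
    if np.any(in_switch):
        out[in_switch] = G(r_off) - G(r[in_switch])
    if np.any(below):
        u_on_sw = G(r_off) - G(r_on)
        out[below] = _plain_energy(terms, r[below]) - _plain_energy(terms, r_on) + u_on_sw
    return float(out[0]) if scalar else out


def lj_pair_energy(r, epsilon_ij: float, rmin_ij: float, params: NonbondedParams) -> float | np.ndarray:
    """12-6 Lennard-Jones pair energy ε[(Rmin/r)¹² − 2(Rmin/r)⁶], kcal/mol.

    With ``params.switching`` the force-switching envelope is applied between
    r_on and r_off (energy exactly 0 for r ≥ r_off); otherwise the plain,
    untruncated potential is returned.
    """
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be positive")
    terms = [(epsilon_ij * rmin_ij ** 12, -12), (-2.0 * epsilon_ij * rmin_ij ** 6, -6)]
    if not params.switching:
        val = _plain_energy(terms, r)
        return float(val) if np.ndim(r) == 0 else val
    return _switched_energy(terms, r, params.r_on, params.r_off)


def coulomb_pair_energy(r, q_i: float, q_j: float, params: NonbondedParams) -> float | np.ndarray:
    """Direct Coulomb pair energy k·q_i·q_j/(ε_r·r), kcal/mol, with the same
    optional force-switching envelope as the Lennard-Jones term."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be positive")
    c = params.coulomb_constant * q_i * q_j / params.dielectric
    terms = [(c, -1)]
    if not params.switching:
        val = _plain_energy(terms, r)
        return float(val) if np.ndim(r) == 0 else val
    return _switched_energy(terms, r, params.r_on, params.r_off)


def interdomain_energy(
    s: Structure,
    group_a: Iterable[int],
    group_b: Iterable[int],
    params: NonbondedParams,
) -> EnergyBreakdown:
    """Total nonbonded (LJ + Coulomb) energy between two disjoint residue groups.

    Lorentz–Berthelot combination in the CHARMM Rmin convention:
    ε_ij = √(ε_i ε_j), Rmin_ij = Rmin_half_i + Rmin_half_j.  Symmetric in the
    two groups and additive over partitions of either group.
    """
    ga = {int(r) for r in group_a}
    gb = {int(r) for r in group_b}
    if ga & gb:
        raise ValueError("residue groups must be disjoint")
    ia = [i for i in range(len(s)) if int(s.residue_ids[i]) in ga]
    ib = [i for i in range(len(s)) if int(s.residue_ids[i]) in gb]
    if not ia or not ib:
        return EnergyBreakdown(0.0, 0.0, 0)

    missing = []
    def params_for(indices):
        eps, rmh, q = [], [], []
        for i in indices:
            try:
                e, rh, qi = params.lookup(str(s.residue_names[i]), str(s.names[i]))
            except ParameterError:
                missing.append(f"{s.residue_names[i]}{s.residue_ids[i]}:{s.names[i]}")
                e, rh, qi = np.nan, np.nan, np.nan
            eps.append(e)
            rmh.append(rh)
            q.append(qi)
        return np.array(eps), np.array(rmh), np.array(q)

    eps_a, rmh_a, q_a = params_for(ia)
    eps_b, rmh_b, q_b = params_for(ib)
    if missing:
        raise ParameterError(f"missing nonbonded parameters for atoms: {sorted(set(missing))}")

    from scipy.spatial.distance import cdist

    r = cdist(s.coords[ia], s.coords[ib]).ravel()
    eps_ij = np.sqrt(np.outer(eps_a, eps_b)).ravel()
    rmin_ij = np.add.outer(rmh_a, rmh_b).ravel()
    qq = np.outer(q_a, q_b).ravel()

    # vectorized evaluation grouped by identical (eps, rmin) pairs is not
    # worth the bookkeeping at the problem sizes in scope; evaluate termwise.
    lj = 0.0
    for k in range(len(r)):
        lj += lj_pair_energy(float(r[k]), float(eps_ij[k]), float(rmin_ij[k]), params)
    qp = NonbondedParams(table={}, r_on=params.r_on, r_off=params.r_off,
                         coulomb_constant=params.coulomb_constant,
                         dielectric=params.dielectric, switching=params.switching)
    coul = float(np.sum(coulomb_pair_energy(r, 1.0, 1.0, qp) * qq))
    return EnergyBreakdown(lj=float(lj), coulomb=coul, pair_count=len(r))
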