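"""Geometric kernels for structural analysis.

Centers of mass, distances, torsion angles, optimal rigid-body superposition
(Kabsch) and RMSD under separate alignment/measurement selections — the
conventions used throughout conformational analysis of multi-domain proteins:
a domain RMSD is computed self-aligned, while an "overall" RMSD is computed
after aligning on one (the least mobile) domain only.

Angles are degrees externally, radians internally.  Backbone heavy atoms are
{N, CA, C, O}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, MissingAtomError

if TYPE_CHECKING:  # pragma: no cover
    from .structures import Structure

logger = logging.getLogger(__name__)

#: Backbone heavy atoms ("heavy" excludes only hydrogens, so the carbonyl O is in).
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")


@dataclass
class PointSet:
    """A weighted set of 3D points (Å); default weights are unit masses."""

    points: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("points must be a non-empty N x 3 array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.points),):
                raise ValueError("weights must match point count")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")

    def __len__(self) -> int:
        return len(self.points)


def _as_points(ps: PointSet | np.ndarray | Sequence) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(ps, PointSet):
        return ps.points, ps.weights
    arr = np.asarray(ps, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 3)
    return arr, None


def center_of_mass(ps: PointSet | np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted mean position of a point set (unit weights by default)."""
    pts, w = _as_points(ps)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    if w is None:
        return pts.mean(axis=0)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return (pts * w[:, None]).sum(axis=0) / total


def pair_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance |a - b| in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180].

    Convention: with b1 = b-a, b2 = c-b, b3 = d-c, n1 = b1 x b2, n2 = b2 x b3,
    the angle is atan2((n1 x b2_hat) . n2, n1 . n2).  Positive angles are
    clockwise rotations of d relative to a when sighting along b -> c
    (IUPAC-consistent).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n2_b2 = np.linalg.norm(b2)
    if n2_b2 < 1e-10:
        raise DegenerateGeometryError("central atoms b and c coincide")
    b2_hat = b2 / n2_b2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10:
        raise DegenerateGeometryError("a, b, c are collinear; torsion undefined")
    if np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("b, c, d are collinear; torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2_hat), n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle_between(a, b, c) -> float:
    """Angle at vertex b of the triple a-b-c, degrees in [0, 180]."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError("coincident atoms in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def kabsch_superpose(mobile: PointSet | np.ndarray, reference: PointSet | np.ndarray) -> RigidTransform:
    """Least-squares optimal proper rigid transform mapping ``mobile`` onto ``reference``.

    Classic SVD solution with the determinant correction that excludes
    reflections.  Weights, when present on the point sets, enter the
    cross-covariance.
    """
    mpts, mw = _as_points(mobile)
    rpts, rw = _as_points(reference)
    if len(mpts) != len(rpts):
        raise ValueError(f"point count mismatch: {len(mpts)} vs {len(rpts)}")
    if len(mpts) < 3:
        raise ValueError("superposition requires at least 3 points")
    w = mw if mw is not None else rw
    cm = center_of_mass(mpts, w)
    cr = center_of_mass(rpts, w)
    P = mpts - cm
    Q = rpts - cr
    if w is not None:
        C = P.T @ (Q * w[:, None])
    else:
        C = P.T @ Q
    U, S, Vt = np.linalg.svd(C)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise DegenerateGeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return RigidTransform(R, t)


def rmsd(a: PointSet | np.ndarray, b: PointSet | np.ndarray) -> float:
    """Root-mean-square deviation between paired points, no fitting."""
    apts, _ = _as_points(a)
    bpts, _ = _as_points(b)
    if apts.shape != bpts.shape:
        raise ValueError(f"point count mismatch: {apts.shape} vs {bpts.shape}")
    return float(np.sqrt(np.mean(np.sum((apts - bpts) ** 2, axis=1))))


def superposed_rmsd(mobile, reference) -> float:
    """RMSD after optimal superposition of ``mobile`` onto ``reference``."""
    tf = kabsch_superpose(mobile, reference)
    mpts, _ = _as_points(mobile)
    rpts, _ = _as_points(reference)
    return rmsd(tf.apply(mpts), rpts)


def _paired_coords(
    mobile: "Structure",
    reference: "Structure",
    residue_ids: Iterable[int],
    atom_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    """Coordinates of atoms present in both structures, paired by
    (chain, residue_id, atom_name), in reference order."""
    rid_set = set(int(r) for r in residue_ids)
    name_set = set(atom_names)

    def keymap(s: "Structure") -> dict:
        out = {}
        for i in range(len(s)):
            rid = int(s.residue_ids[i])
            nm = s.names[i]
            if rid in rid_set and nm in name_set:
                out[(s.chains[i], rid, nm)] = i
        return out

    mmap = keymap(mobile)
    rmap = keymap(reference)
    common = [k for k in rmap if k in mmap]
    common.sort(key=lambda k: rmap[k])
    dropped = (len(mmap) - len(common)) + (len(rmap) - len(common))
    if dropped:
        logger.info("atom pairing dropped %d unpaired atoms", dropped)
    mcoords = np.array([mobile.coords[mmap[k]] for k in common], dtype=float).reshape(-1, 3)
    rcoords = np.array([reference.coords[rmap[k]] for k in common], dtype=float).reshape(-1, 3)
    return mcoords, rcoords, common


def align_and_rmsd(
    mobile: "Structure",
    reference: "Structure",
    align_on: Iterable[int],
    measure_on: Iterable[int],
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> float:
    """Superpose on ``align_on`` residues, then report the unfitted RMSD over
    ``measure_on`` residues.

    Atoms are paired by (chain, residue_id, atom_name) intersected over the
    residues resolved in both structures; unpaired atoms are dropped with a
    logged count.  With ``align_on == measure_on`` this is the ordinary
    self-aligned RMSD; with ``align_on`` set to one rigid domain it yields the
    "overall RMSD aligned on that domain" convention.
    """
    align_on = list(align_on)
    measure_on = list(measure_on)
    ma, ra, keys = _paired_coords(mobile, reference, align_on, atom_names)
    if len(ma) < 3:
        missing = sorted(set(align_on) - {k[1] for k in keys})
        raise MissingAtomError(
            f"only {len(ma)} paired alignment atoms (need >= 3); "
            f"residues missing from one structure: {missing[:20]}"
        )
    tf = kabsch_superpose(ma, ra)
    mm, rm, _ = _paired_coords(mobile, reference, measure_on, atom_names)
    if len(mm) == 0:
        raise MissingAtomError("no paired atoms in the measurement selection")
    return rmsd(tf.apply(mm), rm)
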