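"""Collective variables for the SHP2 closed/open conformational switch.

Five CVs describe the rearrangement of the N-SH2 domain relative to the PTP
domain and the hinge that lets it happen:

* ``dist1_np`` / ``dist2_np`` — distances between the Cα center of mass of
  the N-SH2 blocking segment (I54–G86) and Cα CoMs of two rigid PTP surface
  patches, one at the autoinhibitory interface and one at the interface the
  N-SH2 domain occupies in the open state.
* ``dih_ncpp`` — a pseudo-dihedral over four Cα atoms (S44, T168, V497,
  Q510), one in each SH2 domain and two in PTP, capturing the inter-domain
  rotation.
* ``psi_t218`` — the backbone ψ torsion of T218 in the C-SH2/PTP linker.
* ``dist_k76_r265`` — the Cβ–Cβ distance of the residue-76/R265 pair whose
  side-chain hydrogen bond anchors the closed interface.

Each CV carries reference values measured on the closed (wild-type,
autoinhibited) and open (E76K) crystal structures, used both to classify
conformations and as the default basin coordinates of the synthetic
two-state landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import MissingAtomError
from .geometry import center_of_mass, dihedral, pair_distance
from .structures import Structure, select_atoms

__all__ = [
    "AnchorGroup",
    "CVSpec",
    "CVValue",
    "shp2_cv_suite",
    "evaluate_cv",
    "evaluate_suite",
    "classify_state",
    "cv_timeseries",
    "suite_to_yaml",
    "suite_from_yaml",
    "circular_difference",
]

CV_KINDS = ("com_distance", "atom_distance", "pseudo_dihedral", "backbone_psi")


@dataclass(frozen=True)
class AnchorGroup:
    """A set of atoms anchoring one geometric endpoint of a CV."""

    residue_ids: tuple[int, ...]
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        if not self.residue_ids or not self.atom_names:
            raise ValueError("anchor group needs at least one residue and atom name")


@dataclass(frozen=True)
class CVSpec:
    """Definition of one collective variable plus its two reference values."""

    name: str
    kind: str
    groups: tuple[AnchorGroup, ...]
    periodic: bool
    reference_closed: float
    reference_open: float
    unit: str

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        n = len(self.groups)
        if self.kind == "com_distance" and n != 2:
            raise ValueError("com_distance needs exactly 2 groups")
        if self.kind == "atom_distance" and n != 2:
            raise ValueError("atom_distance needs exactly 2 single-atom anchors")
        if self.kind in ("pseudo_dihedral", "backbone_psi"):
            if n != 4:
                raise ValueError(f"{self.kind} needs exactly 4 single-atom anchors")
            for g in self.groups:
                if len(g.residue_ids) != 1 or len(g.atom_names) != 1:
                    raise ValueError(f"{self.kind} anchors must be single atoms")
        if self.kind == "backbone_psi":
            rids = [g.residue_ids[0] for g in self.groups]
            if rids[3] != rids[0] + 1 or len(set(rids[:3])) != 1:
                raise ValueError("backbone_psi anchors must be N,CA,C of residue i and N of i+1")
        if not (np.isfinite(self.reference_closed) and np.isfinite(self.reference_open)):
            raise ValueError("reference values must be finite")

    @property
    def reference_gap(self) -> float:
        """Separation between the closed and open references (periodic-aware)."""
        if self.periodic:
            return abs(circular_difference(self.reference_open, self.reference_closed))
        return abs(self.reference_open - self.reference_closed)


@dataclass(frozen=True)
class CVValue:
    """One evaluated CV: Å for distances, degrees in (-180, 180] for angles."""

    spec_name: str
    value: float
    frame_index: int | str = 0


def circular_difference(a: float, b: float) -> float:
    """Signed minimum-image difference a - b on the (-180, 180] circle."""
    d = (a - b + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else d


def _rng(lo: int, hi: int) -> tuple[int, ...]:
    return tuple(range(lo, hi + 1))


def shp2_cv_suite() -> list[CVSpec]:
    """The five SHP2 CVs with their crystal-structure reference values.

    Residue ranges are inclusive, author numbering, single chain.  Reference
    values: closed state from the autoinhibited wild-type structure, open
    state from the E76K structure.
    """
    return [
        CVSpec(
            name="dist1_np",
            kind="com_distance",
            groups=(
                AnchorGroup(_rng(54, 86)),
                AnchorGroup(_rng(255, 257) + _rng(465, 467) + _rng(495, 497) + _rng(508, 511)),
            ),
            periodic=False,
            reference_closed=16.1,
            reference_open=37.9,
            unit="angstrom",
        ),
        CVSpec(
            name="dist2_np",
            kind="com_distance",
            groups=(
                AnchorGroup(_rng(54, 86)),
                AnchorGroup(_rng(224, 226) + _rng(479, 482) + _rng(520, 522)),
            ),
            periodic=False,
            reference_closed=35.1,
            reference_open=18.4,
            unit="angstrom",
        ),
        CVSpec(
            name="dih_ncpp",
            kind="pseudo_dihedral",
            groups=(
                AnchorGroup((44,)),
                AnchorGroup((168,)),
                AnchorGroup((497,)),
                AnchorGroup((510,)),
            ),
            periodic=True,
            reference_closed=-59.5,
            reference_open=66.4,
            unit="degrees",
        ),
        CVSpec(
            name="psi_t218",
            kind="backbone_psi",
            groups=(
                AnchorGroup((218,), ("N",)),
                AnchorGroup((218,), ("CA",)),
                AnchorGroup((218,), ("C",)),
                AnchorGroup((219,), ("N",)),
            ),
            periodic=True,
            reference_closed=13.4,
            reference_open=154.5,
            unit="degrees",
        ),
        CVSpec(
            name="dist_k76_r265",
            kind="atom_distance",
            groups=(
                AnchorGroup((76,), ("CB",)),
                AnchorGroup((265,), ("CB",)),
            ),
            periodic=False,
            reference_closed=9.9,
            reference_open=47.9,
            unit="angstrom",
        ),
    ]


def _group_com(spec: CVSpec, group: AnchorGroup, s: Structure) -> np.ndarray:
    sel = select_atoms(s, residue_ids=group.residue_ids, names=group.atom_names)
    if len(sel) == 0:
        raise MissingAtomError(
            f"CV {spec.name!r}: no atoms for residues {group.residue_ids[:5]}... "
            f"names {group.atom_names}"
        )
    if len(sel) < len(group.residue_ids):
        import logging

        logging.getLogger(__name__).warning(
            "CV %s: %d of %d anchor residues unresolved; CoM over resolved atoms",
            spec.name, len(group.residue_ids) - len(sel), len(group.residue_ids),
        )
    return center_of_mass(sel.coords)


def _single_atom(spec: CVSpec, group: AnchorGroup, s: Structure) -> np.ndarray:
    rid = group.residue_ids[0]
    name = group.atom_names[0]
    idx = s.find(rid, name)
    if idx is None:
        raise MissingAtomError(f"CV {spec.name!r}: atom {name} of residue {rid} not found")
    return s.coords[idx]


def evaluate_cv(spec: CVSpec, s: Structure, frame_index: int | str = 0) -> CVValue:
    """Evaluate one CV on a structure (Å or degrees)."""
    if spec.kind == "com_distance":
        a = _group_com(spec, spec.groups[0], s)
        b = _group_com(spec, spec.groups[1], s)
        value = pair_distance(a, b)
    elif spec.kind == "atom_distance":
        a = _single_atom(spec, spec.groups[0], s)
        b = _single_atom(spec, spec.groups[1], s)
        value = pair_distance(a, b)
    else:  # pseudo_dihedral / backbone_psi
        pts = [_single_atom(spec, g, s) for g in spec.groups]
        value = dihedral(*pts)
    return CVValue(spec_name=spec.name, value=float(value), frame_index=frame_index)


def evaluate_suite(
    s: Structure, suite: Sequence[CVSpec] | None = None, frame_index: int | str = 0
) -> list[CVValue]:
    """Evaluate all suite CVs on a structure, in suite order."""
    suite = list(suite) if suite is not None else shp2_cv_suite()
    out = []
    for spec in suite:
        try:
            out.append(evaluate_cv(spec, s, frame_index))
        except MissingAtomError:
            raise
        except Exception as exc:
            raise MissingAtomError(f"CV {spec.name!r} failed: {exc}") from exc
    return out


def classify_state(
    values: Sequence[CVValue],
    suite: Sequence[CVSpec] | None = None,
    threshold_fraction: float = 0.25,
) -> str:
    """Label a conformation ``closed`` / ``open`` / ``intermediate``.

    A conformation is closed when *every* CV lies within
    ``threshold_fraction * |open_ref - closed_ref|`` of its closed reference
    (periodic difference for angles), open symmetrically, else intermediate.
    """
    suite = list(suite) if suite is not None else shp2_cv_suite()
    if not (0.0 < threshold_fraction < 0.5):
        raise ValueError("threshold_fraction must lie in (0, 0.5)")
    by_name = {v.spec_name: v for v in values}
    if set(by_name) != {sp.name for sp in suite}:
        raise ValueError("CV values do not match the suite")
    all_closed = True
    all_open = True
    for sp in suite:
        v = by_name[sp.name].value
        if sp.periodic:
            d_closed = abs(circular_difference(v, sp.reference_closed))
            d_open = abs(circular_difference(v, sp.reference_open))
        else:
            d_closed = abs(v - sp.reference_closed)
            d_open = abs(v - sp.reference_open)
        thr = threshold_fraction * sp.reference_gap
        all_closed &= d_closed <= thr
        all_open &= d_open <= thr
    if all_closed:
        return "closed"
    if all_open:
        return "open"
    return "intermediate"


def cv_timeseries(
    frames: Iterable[Structure],
    suite: Sequence[CVSpec] | None = None,
    threshold_fraction: float = 0.25,
) -> pd.DataFrame:
    """Evaluate the CV suite on every frame.

    Returns a DataFrame with one row per frame, one column per CV and a
    ``state`` label column.  Frames on which evaluation fails are skipped;
    the skip count is stored in ``df.attrs['n_skipped']`` and logged.
    """
    import logging

    suite = list(suite) if suite is not None else shp2_cv_suite()
    rows = []
    n_skipped = 0
    for i, frame in enumerate(frames):
        try:
            vals = evaluate_suite(frame, suite, frame_index=i)
        except Exception as exc:
            logging.getLogger(__name__).warning("frame %d skipped: %s", i, exc)
            n_skipped += 1
            continue
        row: dict = {"frame": i}
        row.update({v.spec_name: v.value for v in vals})
        row["state"] = classify_state(vals, suite, threshold_fraction)
        rows.append(row)
    if not rows:
        raise ValueError("no frames could be evaluated")
    df = pd.DataFrame(rows)
    df.attrs["n_skipped"] = n_skipped
    return df


# --- YAML round-trip ----------------------------------------------------------

def suite_to_yaml(suite: Sequence[CVSpec]) -> str:
    docs = []
    for sp in suite:
        docs.append(
            {
                "name": sp.name,
                "kind": sp.kind,
                "periodic": sp.periodic,
                "reference_closed": sp.reference_closed,
                "reference_open": sp.reference_open,
                "unit": sp.unit,
                "groups": [
                    {"residue_ids": list(g.residue_ids), "atom_names": list(g.atom_names)}
                    for g in sp.groups
                ],
            }
        )
    return yaml.safe_dump({"cvs": docs}, sort_keys=False)


def suite_from_yaml(text: str) -> list[CVSpec]:
    data = yaml.safe_load(text)
    out = []
    for d in data["cvs"]:
        groups = tuple(
            AnchorGroup(tuple(int(r) for r in g["residue_ids"]), tuple(g["atom_names"]))
            for g in d["groups"]
        )
        out.append(
            CVSpec(
                name=d["name"],
                kind=d["kind"],
                groups=groups,
                periodic=bool(d["periodic"]),
                reference_closed=float(d["reference_closed"]),
                reference_open=float(d["reference_open"]),
                unit=d.get("unit", "angstrom"),
            )
        )
    return out
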