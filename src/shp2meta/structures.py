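"""Macromolecular structure representation, PDB I/O and the SHP2 domain map.

SHP2 comprises two tandem SH2 domains (N-SH2, C-SH2) followed by the catalytic
PTP domain; in the autoinhibited closed state N-SH2 docks onto the PTP active
site, while activating mutations such as E76K favour an open arrangement.
This module parses single-chain PDB coordinate files (author residue
numbering, first altloc kept, hetero records ignored), writes them back, and
provides the residue-range partition of SHP2 into its three domains plus the
C-SH2/PTP linker used by every downstream analysis.

File parsing/writing is delegated to biotite; this module owns the in-memory
model and the selection semantics.
"""

from __future__ import annotations

import io
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import NoAtomsError, PDBParseError

__all__ = [
    "Atom",
    "Structure",
    "DomainPartition",
    "parse_pdb",
    "write_pdb",
    "select_atoms",
    "default_shp2_partition",
    "fetch_pdb",
]


@dataclass(frozen=True)
class Atom:
    """A single atom record (author numbering, Å coordinates)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")


class Structure:
    """An ordered collection of atoms stored as parallel arrays.

    Guarantees stable atom order and no duplicate (chain, residue_id, name)
    among parsed non-altloc atoms.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        chains: Sequence[str],
        coords: np.ndarray,
        label: str = "",
    ):
        n = len(names)
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.label = label
        for arr in (self.serials, self.elements, self.residue_names, self.residue_ids, self.chains):
            if len(arr) != n:
                raise ValueError("all atom annotation arrays must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_id=int(self.residue_ids[i]),
                chain=str(self.chains[i]),
                position=self.coords[i].copy(),
            )
            for i in range(len(self))
        ]

    @property
    def resolved_residues(self) -> set[tuple[str, int]]:
        return {(str(c), int(r)) for c, r in zip(self.chains, self.residue_ids)}

    def resolved_ids(self) -> set[int]:
        return {int(r) for r in self.residue_ids}

    def subset(self, mask: np.ndarray, label: str | None = None) -> "Structure":
        return Structure(
            self.serials[mask],
            self.names[mask],
            self.elements[mask],
            self.residue_names[mask],
            self.residue_ids[mask],
            self.chains[mask],
            self.coords[mask],
            label=self.label if label is None else label,
        )

    def copy(self) -> "Structure":
        return self.subset(np.ones(len(self), dtype=bool))

    def find(self, residue_id: int, name: str) -> int | None:
        """Index of the first atom matching (residue_id, name), or None."""
        hits = np.nonzero((self.residue_ids == residue_id) & (self.names == name))[0]
        return int(hits[0]) if len(hits) else None

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Structure {self.label!r}: {len(self)} atoms, {len(self.resolved_residues)} residues>"


def select_atoms(
    s: Structure,
    residue_ids: Iterable[int] | None = None,
    names: Iterable[str] | None = None,
) -> Structure:
    """Atoms matching both filters, in structure order.

    ``None`` leaves a filter unconstrained; an explicit empty set matches
    nothing.  An empty selection is a legal value — callers decide whether
    that is an error.
    """
    mask = np.ones(len(s), dtype=bool)
    if residue_ids is not None:
        rid_set = set(int(r) for r in residue_ids)
        mask &= np.array([int(r) in rid_set for r in s.residue_ids], dtype=bool)
    if names is not None:
        name_set = set(names)
        mask &= np.array([n in name_set for n in s.names], dtype=bool)
    return s.subset(mask)


# --- PDB I/O -----------------------------------------------------------------

def _prescan_pdb(text: str) -> None:
    """Cheap validation pass so malformed ATOM records fail with a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError("ATOM record shorter than the coordinate columns", lineno)
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise PDBParseError("unparsable coordinates in columns 31-54", lineno) from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError("unparsable residue sequence number", lineno) from None


def parse_pdb(text: str, chain: str | None = None, label: str = "") -> Structure:
    """Parse PDB-format content into a :class:`Structure`.

    Only ATOM records are kept (no waters/heteroatoms); when ``chain`` is
    given, only that chain is returned.  Altloc duplicates are resolved by
    keeping the first variant; occupancy is ignored.  Residue ids are the
    author's numbering, preserved as-is (crystal gaps stay gaps).
    """
    from biotite.structure.io.pdb import PDBFile

    _prescan_pdb(text)
    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises various types on malformed input
        raise PDBParseError(f"could not parse PDB content: {exc}") from exc

    mask = ~arr.hetero
    if chain is not None:
        mask &= arr.chain_id == chain
    if not np.any(mask):
        raise NoAtomsError(
            f"no atoms in chain {chain!r}" if chain is not None else "no ATOM records found"
        )
    arr = arr[mask]
    return Structure(
        serials=arr.atom_id,
        names=arr.atom_name,
        elements=arr.element,
        residue_names=arr.res_name,
        residue_ids=arr.res_id,
        chains=arr.chain_id,
        coords=arr.coord,
        label=label,
    )


def load_pdb(path: str | Path, chain: str | None = None) -> Structure:
    """Read a PDB file from disk (see :func:`parse_pdb`)."""
    path = Path(path)
    return parse_pdb(path.read_text(), chain=chain, label=path.stem)


def write_pdb(s: Structure) -> str:
    """Serialize a structure to fixed-column PDB ATOM records.

    Round-trips through :func:`parse_pdb` reproduce names, ids and
    coordinates to the format's 3-decimal precision.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if len(s) == 0:
        raise NoAtomsError("cannot write an empty structure")
    if np.any(np.abs(s.coords) >= 10000.0):
        raise ValueError("coordinates overflow the fixed PDB columns (|x| >= 10000 Å)")
    arr = struc.AtomArray(len(s))
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = np.asarray(s.chains, dtype="U4")
    arr.res_id = s.residue_ids
    arr.res_name = np.asarray(s.residue_names, dtype="U5")
    arr.atom_name = np.asarray(s.names, dtype="U6")
    arr.element = np.asarray(s.elements, dtype="U2")
    arr.hetero = np.zeros(len(s), dtype=bool)
    arr.set_annotation("atom_id", s.serials)
    pdb = PDBFile()
    pdb.set_structure(arr)
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_pdb(pdb_id: str, cache_dir: str | Path = "data/pdb", timeout: float = 30.0) -> str:
    """Return PDB-format text for an RCSB entry, using a local cache.

    Looks for ``<cache_dir>/<id>.pdb`` first; otherwise downloads from RCSB
    and caches the file.  Raises ``OSError`` when the entry is neither cached
    nor reachable (e.g. offline).
    """
    pdb_id = pdb_id.lower()
    cache = Path(cache_dir) / f"{pdb_id}.pdb"
    if cache.exists():
        return cache.read_text()
    url = _RCSB_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:  # may raise URLError
        text = resp.read().decode()
    cache.parent.mkdir(parents=True, exist_ok=True)
    cache.write_text(text)
    return text


# --- Domain partition ---------------------------------------------------------

@dataclass(frozen=True)
class DomainPartition:
    """Residue-id ranges (inclusive) of the SHP2 domains.

    The three domain ranges must be pairwise disjoint; the C-SH2/PTP linker
    annotation (N217–G246) deliberately overlaps the start of the PTP range —
    it tags the hinge whose unwinding accompanies the domain rearrangement,
    not a fourth disjoint domain.
    """

    nsh2: tuple[int, int] = (3, 103)
    csh2: tuple[int, int] = (112, 216)
    ptp: tuple[int, int] = (221, 524)
    linker_cs_ptp: tuple[int, int] = (217, 246)

    def __post_init__(self) -> None:
        for name in ("nsh2", "csh2", "ptp", "linker_cs_ptp"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: empty range {lo}-{hi}")
        ranges = [self.nsh2, self.csh2, self.ptp]
        for i in range(len(ranges)):
            for j in range(i + 1, len(ranges)):
                if ranges[i][0] <= ranges[j][1] and ranges[j][0] <= ranges[i][1]:
                    raise ValueError("domain ranges must be pairwise disjoint")

    def residues(self, domain: str) -> range:
        lo, hi = getattr(self, domain)
        return range(lo, hi + 1)

    def domain_of(self, residue_id: int) -> str | None:
        for name in ("nsh2", "csh2", "ptp"):
            lo, hi = getattr(self, name)
            if lo <= residue_id <= hi:
                return name
        return None

    def all_domain_residues(self) -> list[int]:
        return sorted(set(self.residues("nsh2")) | set(self.residues("csh2")) | set(self.residues("ptp")))

    def to_dict(self) -> dict:
        return {
            "nsh2": list(self.nsh2),
            "csh2": list(self.csh2),
            "ptp": list(self.ptp),
            "linker_cs_ptp": list(self.linker_cs_ptp),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainPartition":
        kwargs = {}
        for key, value in d.items():
            if key not in ("nsh2", "csh2", "ptp", "linker_cs_ptp"):
                raise ValueError(f"unknown domain key {key!r}")
            lo, hi = value
            kwargs[key] = (int(lo), int(hi))
        return cls(**kwargs)


def default_shp2_partition() -> DomainPartition:
    """The default SHP2 domain map: N-SH2 3–103, C-SH2 112–216, PTP 221–524,
    with the C-SH2/PTP linker annotated as 217–246.

    Domain boundaries are a design choice following the standard SHP2
    architecture; they are configurable because domain-wise RMSD values
    depend on them.
    """
    return DomainPartition()
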