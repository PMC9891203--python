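"""Trajectory-level analytics: RMSD time series, circular dihedral
statistics, bimodality detection and RMSD-based clustering.

RMSD series follow the multi-domain convention: a domain is measured
self-aligned (alignment set = measurement set), while the overall structure
is measured after aligning on one reference domain only, so relative domain
motion shows up in full.  Angle statistics are circular: the mean is the
direction of the resultant vector and the standard deviation is
√(−2 ln R̄) with R̄ the mean resultant length.  Clustering is deterministic
leader-style clustering on pairwise aligned RMSD with one medoid-refinement
pass — chosen for auditability over sophistication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .geometry import BACKBONE_ATOMS, align_and_rmsd
from .structures import Structure

__all__ = [
    "TimeSeries",
    "CircularSummary",
    "ClusterResult",
    "rmsd_timeseries",
    "circular_summary",
    "bimodality_report",
    "cluster_by_rmsd",
    "state_report",
]


@dataclass
class TimeSeries:
    """An ordered per-frame scalar series."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, self.label or "value": self.values})


def rmsd_timeseries(
    frames: Sequence[Structure],
    reference: Structure,
    align_on: Iterable[int],
    measure_on: Iterable[int],
    atom_names: Sequence[str] = BACKBONE_ATOMS,
    label: str = "rmsd",
) -> TimeSeries:
    """Per-frame aligned RMSD against a reference structure.

    Superposition uses ``align_on`` residues; the deviation is measured over
    ``measure_on`` residues without refitting.  A trajectory measured against
    its own first frame starts at exactly 0.
    """
    align_on = list(align_on)
    measure_on = list(measure_on)
    values = [
        align_and_rmsd(frame, reference, align_on, measure_on, atom_names)
        for frame in frames
    ]
    return TimeSeries(times=np.arange(len(values), dtype=float),
                      values=np.asarray(values), label=label)


@dataclass(frozen=True)
class CircularSummary:
    """Directional mean and circular standard deviation of an angle sample."""

    mean: float  # degrees in (-180, 180]
    std: float  # degrees, sqrt(-2 ln R_bar)
    n: int


def circular_summary(angles: Sequence[float]) -> CircularSummary:
    """Circular mean/std of angles in degrees.

    The mean is atan2 of the mean sine and cosine; the standard deviation is
    √(−2 ln R̄) converted to degrees, which reduces to the ordinary standard
    deviation for tightly concentrated samples and saturates for dispersed
    ones.  Invariant (equivariant for the mean) under global rotation.
    """
    arr = np.asarray(angles, dtype=float)
    if arr.size == 0:
        raise ValueError("empty angle series")
    mean = float(sstats.circmean(arr, high=180.0, low=-180.0))
    std = float(sstats.circstd(arr, high=180.0, low=-180.0))
    if mean <= -180.0:
        mean += 360.0
    elif mean > 180.0:
        mean -= 360.0
    return CircularSummary(mean=mean, std=std, n=int(arr.size))


def bimodality_report(
    angles: Sequence[float],
    bin_width: float = 5.0,
    min_separation: float = 60.0,
    min_mass: float = 0.10,
) -> list[tuple[float, float]]:
    """Detect modes of a periodic angle distribution.

    Histograms the sample on [-180, 180) with periodic wrap, finds strict
    local maxima, keeps peaks by descending height while enforcing a minimum
    circular separation, and reports (mode center, mass fraction) for peaks
    whose mass — the sample fraction within half the separation window —
    reaches ``min_mass``.  Sorted by mass, descending.  A flat histogram has
    no strict maxima and therefore no modes.
    """
    if not (0 < bin_width <= 120) or abs((360.0 / bin_width) - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    arr = (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0
    if arr.size == 0:
        raise ValueError("empty angle series")
    n_bins = int(round(360.0 / bin_width))
    counts, edges = np.histogram(arr, bins=n_bins, range=(-180.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])

    left = np.roll(counts, 1)
    right = np.roll(counts, -1)
    is_peak = (counts > left) & (counts > right) & (counts > 0)
    order = np.argsort(-counts[is_peak])
    peak_idx = np.nonzero(is_peak)[0][order]

    def circ_dist(a: float, b: float) -> float:
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)

    kept: list[float] = []
    for idx in peak_idx:
        c = float(centers[idx])
        if all(circ_dist(c, k) >= min_separation for k in kept):
            kept.append(c)

    half = min_separation / 2.0
    modes = []
    for c in kept:
        d = np.abs((arr - c + 180.0) % 360.0 - 180.0)
        mass = float(np.mean(d <= half))
        if mass >= min_mass:
            modes.append((c, mass))
    modes.sort(key=lambda m: -m[1])
    return modes


@dataclass
class ClusterResult:
    """Frame-to-cluster assignments with medoid representatives."""

    assignments: np.ndarray
    medoid_frames: list[int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_frames)

    def to_frame(self) -> pd.DataFrame:
        medoids = set(self.medoid_frames)
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.assignments)),
                "cluster": self.assignments,
                "is_medoid": [int(i in medoids) for i in range(len(self.assignments))],
            }
        )


def cluster_by_rmsd(
    frames: Sequence[Structure],
    align_on: Iterable[int],
    measure_on: Iterable[int],
    cutoff: float = 3.0,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> ClusterResult:
    """Leader-style clustering on pairwise aligned RMSD.

    Frames are scanned in order; each joins the first existing cluster whose
    medoid is within ``cutoff`` Å, else opens a new cluster (its own medoid).
    A single refinement pass then replaces each medoid by the member
    minimizing the summed in-cluster RMSD.  Fully deterministic for a fixed
    frame order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to cluster")
    align_on = list(align_on)
    measure_on = list(measure_on)

    def dist(i: int, j: int) -> float:
        return align_and_rmsd(frames[i], frames[j], align_on, measure_on, atom_names)

    assignments = np.full(len(frames), -1, dtype=int)
    medoids: list[int] = []
    for i in range(len(frames)):
        for c, m in enumerate(medoids):
            if dist(i, m) <= cutoff:
                assignments[i] = c
                break
        else:
            assignments[i] = len(medoids)
            medoids.append(i)

    # one medoid-refinement pass (never increases the summed in-cluster RMSD)
    for c in range(len(medoids)):
        members = np.nonzero(assignments == c)[0]
        if len(members) <= 2:
            continue
        sums = []
        for i in members:
            sums.append(sum(dist(int(i), int(j)) for j in members if j != i))
        medoids[c] = int(members[int(np.argmin(sums))])

    return ClusterResult(assignments=assignments, medoid_frames=medoids, cutoff=float(cutoff))


def state_report(
    cv_table: pd.DataFrame,
    clusters: ClusterResult | None = None,
    fes=None,
) -> tuple[str, pd.DataFrame]:
    """Summarize a classified CV table: per-state frame counts and CV means.

    Returns (markdown report, summary DataFrame).  When a clustering result
    is given, medoid frames are listed per state; when an FES is given, its
    grid extent is noted.
    """
    if "state" not in cv_table.columns:
        raise ValueError("cv_table must carry a 'state' column")
    cv_cols = [c for c in cv_table.columns if c not in ("frame", "state")]
    rows = []
    for state, grp in cv_table.groupby("state", sort=True):
        row = {"state": state, "n_frames": len(grp),
               "fraction": len(grp) / len(cv_table)}
        for c in cv_cols:
            row[f"mean_{c}"] = float(grp[c].mean())
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values("n_frames", ascending=False).reset_index(drop=True)

    lines = ["# Conformational state report", ""]
    lines.append(f"Frames analysed: {len(cv_table)}")
    lines.append("")
    for _, row in summary.iterrows():
        lines.append(f"## {row['state']}")
        lines.append(f"- frames: {int(row['n_frames'])} ({100 * row['fraction']:.1f}%)")
        for c in cv_cols:
            lines.append(f"- mean {c}: {row[f'mean_{c}']:.2f}")
        if clusters is not None:
            frame_ids = set(cv_table.loc[cv_table["state"] == row["state"], "frame"])
            meds = [m for m in clusters.medoid_frames if m in frame_ids]
            if meds:
                lines.append(f"- medoid frames: {meds}")
        lines.append("")
    if fes is not None:
        extent = ", ".join(f"[{ax[0]:.1f}, {ax[-1]:.1f}]" for ax in fes.axes)
        lines.append(f"FES grid extent: {extent}")
        lines.append("")
    return "\n".join(lines), summary
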