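"""Geometric interaction detection and persistence statistics.

Hydrogen bonds use the acceptor-donor distance and the angle at the
hydrogen (acceptor-H-donor), both as strict inequalities; occupancy is the
percentage of frames in which an interaction's criteria hold.  Salt
bridges, ion coordination and plain atom pairs are distance series;
ring stacking and long-range electrostatic proxies are (mass-weighted)
group-centroid distance series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from gamdkit.structure_metrics import probability_distribution, rc_distance_series
from gamdkit.toy_systems.trajectory import TrajectoryEnsemble

Kind = Literal["hbond", "salt_bridge", "pi_pi", "group_ei", "ion_coord"]

#: default "formed" cutoff for charged-pair distances, A
DEFAULT_SALT_BRIDGE_CUTOFF = 5.5


@dataclass(frozen=True)
class HBondCriteria:
    """Strict thresholds: D-A distance < ``max_da_distance`` (A) and
    acceptor-H-donor angle > ``min_angle_at_h`` (degrees)."""

    max_da_distance: float = 3.5
    min_angle_at_h: float = 120.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_angle_at_h <= 180:
            raise ValueError("min_angle_at_h must lie in (0, 180]")


@dataclass
class InteractionRecord:
    """A labeled geometric interaction with per-frame series and occupancy."""

    kind: Kind
    members: tuple  # indices: triplet (hbond), pair, or (tuple, tuple) groups
    distance_series: np.ndarray  # A
    angle_series: np.ndarray | None = None  # degrees, hbond only
    formed_series: np.ndarray | None = None  # bool per frame, when criteria exist
    criteria: object = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def occupancy(self) -> float | None:
        """Percentage of frames satisfying the criteria, to 0.1."""
        if self.formed_series is None:
            return None
        return occupancy(self)

    @property
    def n_frames(self) -> int:
        return len(self.distance_series)


def occupancy(record: InteractionRecord) -> float:
    """100 x mean of the boolean formed series, rounded to 0.1 percent."""
    if record.formed_series is None:
        raise ValueError(f"record {record.label or record.kind} has no formed series")
    series = np.asarray(record.formed_series, dtype=bool)
    if series.size == 0:
        raise ValueError("empty formed series")
    return round(100.0 * series.mean(), 1)


def _angle_at(b: np.ndarray, a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c at vertex b, degrees, per frame."""
    v1 = a - b
    v2 = c - b
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbond_series(
    traj: TrajectoryEnsemble,
    donor: int,
    hydrogen: int,
    acceptor: int,
    criteria: HBondCriteria = HBondCriteria(),
) -> InteractionRecord:
    """Per-frame hydrogen-bond test on a donor / hydrogen / acceptor triplet."""
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen and acceptor indices must be distinct")
    n = traj.n_particles
    for i in (donor, hydrogen, acceptor):
        if not 0 <= i < n:
            raise IndexError(f"index {i} out of range for {n} particles")
    dh0 = np.linalg.norm(
        traj.coordinates[0, donor] - traj.coordinates[0, hydrogen]
    )
    metadata = {}
    if dh0 >= 1.5:
        import warnings

        warnings.warn(
            f"donor-hydrogen distance {dh0:.2f} A in frame 0 exceeds 1.5 A; "
            "check the triplet ordering"
        )
        metadata["suspect_dh_distance"] = float(dh0)

    da = rc_distance_series(traj, donor, acceptor)
    ang = _angle_at(
        traj.coordinates[:, hydrogen],
        traj.coordinates[:, donor],
        traj.coordinates[:, acceptor],
    )
    formed = (da < criteria.max_da_distance) & (ang > criteria.min_angle_at_h)
    return InteractionRecord(
        kind="hbond",
        members=(donor, hydrogen, acceptor),
        distance_series=da,
        angle_series=ang,
        formed_series=formed,
        criteria=criteria,
        metadata=metadata,
    )


def atom_pair_distance_series(
    traj: TrajectoryEnsemble,
    i: int,
    j: int,
    kind: Kind = "salt_bridge",
    cutoff: float | None = None,
) -> InteractionRecord:
    """Per-frame distance between two atoms, with an optional formed cutoff.

    Salt bridges default to a 5.5 A cutoff; other kinds carry no criterion
    unless ``cutoff`` is given.
    """
    d = rc_distance_series(traj, i, j)
    if cutoff is None and kind == "salt_bridge":
        cutoff = DEFAULT_SALT_BRIDGE_CUTOFF
    formed = (d < cutoff) if cutoff is not None else None
    return InteractionRecord(
        kind=kind,
        members=(i, j),
        distance_series=d,
        formed_series=formed,
        criteria=cutoff,
    )


def group_centroid_distance_series(
    traj: TrajectoryEnsemble,
    group_a,
    group_b,
    mass_weighted: bool = True,
    kind: Kind = "pi_pi",
) -> InteractionRecord:
    """Per-frame distance between the (mass-weighted) centroids of two
    disjoint particle groups."""
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be nonempty")
    if set(a.tolist()) & set(b.tolist()):
        raise ValueError("groups must be disjoint")
    n = traj.n_particles
    if a.max() >= n or b.max() >= n or a.min() < 0 or b.min() < 0:
        raise IndexError("group indices out of range")

    def centroid(idx):
        w = traj.masses[idx] if mass_weighted else np.ones(idx.size)
        return np.einsum("fpc,p->fc", traj.coordinates[:, idx, :], w) / w.sum()

    d = np.linalg.norm(centroid(a) - centroid(b), axis=1)
    return InteractionRecord(
        kind=kind,
        members=(tuple(a.tolist()), tuple(b.tolist())),
        distance_series=d,
        metadata={"mass_weighted": mass_weighted},
    )


# ---------------------------------------------------------------------------
# manifest-driven tables


def _label_of(traj: TrajectoryEnsemble, i: int) -> str:
    lb = traj.labels[i]
    return f"{lb.resname}{lb.resid + 1}:{lb.name}"


def compute_interaction(traj: TrajectoryEnsemble, entry: dict) -> InteractionRecord:
    """Build one record from a manifest entry (0-based indices)."""
    kind = entry["kind"]
    if kind == "hbond":
        crit = HBondCriteria(
            max_da_distance=float(entry.get("max_da_distance", 3.5)),
            min_angle_at_h=float(entry.get("min_angle_at_h", 120.0)),
        )
        rec = detect_hbond_series(
            traj, int(entry["donor"]), int(entry["hydrogen"]),
            int(entry["acceptor"]), crit,
        )
    elif kind in ("salt_bridge", "ion_coord"):
        rec = atom_pair_distance_series(
            traj, int(entry["i"]), int(entry["j"]), kind=kind,
            cutoff=entry.get("cutoff"),
        )
    elif kind in ("pi_pi", "group_ei"):
        rec = group_centroid_distance_series(
            traj, entry["group_a"], entry["group_b"],
            mass_weighted=bool(entry.get("mass_weighted", True)), kind=kind,
        )
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")
    rec.label = entry.get("label", "")
    return rec


def interaction_table(
    traj: TrajectoryEnsemble, manifest: list[dict], bin_width: float = 0.05
) -> tuple[pd.DataFrame, list[InteractionRecord], list[str]]:
    """One row per manifest entry: kind, 1-based member labels, occupancy,
    mean distance and distribution peaks.

    Unresolvable entries are reported in the returned failure list; the
    remaining entries are still computed.
    """
    rows = []
    records: list[InteractionRecord] = []
    failures: list[str] = []
    for pos, entry in enumerate(manifest):
        try:
            rec = compute_interaction(traj, entry)
        except (KeyError, ValueError, IndexError, LookupError) as exc:
            failures.append(f"entry {pos} ({entry.get('label', '?')}): {exc}")
            continue
        records.append(rec)
        if rec.kind == "hbond":
            member_labels = "-".join(_label_of(traj, i) for i in rec.members)
        elif rec.kind in ("pi_pi", "group_ei"):
            member_labels = " vs ".join(
                "+".join(_label_of(traj, i) for i in grp) for grp in rec.members
            )
        else:
            member_labels = "-".join(_label_of(traj, i) for i in rec.members)
        if rec.n_frames >= 10:
            peaks = probability_distribution(
                rec.distance_series, bin_width=bin_width
            ).peak_positions
            peak_str = ",".join(f"{p:.3f}" for p in peaks[:3])
        else:
            peak_str = ""
        rows.append(
            {
                "label": rec.label or f"entry{pos}",
                "kind": rec.kind,
                "members": member_labels,
                "occupancy_pct": rec.occupancy,
                "mean_distance_A": float(rec.distance_series.mean()),
                "distance_peaks_A": peak_str,
            }
        )
    return pd.DataFrame(rows), records, failures
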