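"""Rigid-body superposition and per-frame / per-particle descriptors.

RMSD is reported after a weighted least-squares (Kabsch) fit on the same
selection it is measured over; RMSF is measured about an iteratively
aligned mean structure (two passes).  Distances carry no periodic imaging.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from gamdkit.toy_systems.trajectory import ParticleLabels, TrajectoryEnsemble

# ---------------------------------------------------------------------------
# selections


@dataclass
class Selection:
    """A resolved, sorted, unique particle-index list with its source expression."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if idx.size == 0:
            raise ValueError(f"selection {self.expression!r} resolves to no particles")
        self.indices = idx

    def __len__(self) -> int:
        return self.indices.size


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def select(traj: TrajectoryEnsemble, expression: str) -> Selection:
    """Resolve a selection mini-language against trajectory labels.

    Grammar: ``all``, ``protein``, ``name <N>...``, ``element <E>...``,
    ``resname <R>...``, ``resid <a>-<b>`` or ``resid <a> <b>...`` (1-based),
    combined with ``and``, ``or``, ``not`` and parentheses.
    """
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise ValueError("empty selection expression")
    labels = traj.labels
    n = traj.n_particles
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    keywords = {"and", "or", "not", "(", ")", "name", "element", "resname",
                "resid", "all", "protein"}

    def parse_or():
        left = parse_and()
        while peek() == "or":
            advance()
            left = left | parse_and()
        return left

    def parse_and():
        left = parse_not()
        while peek() == "and":
            advance()
            left = left & parse_not()
        return left

    def parse_not():
        if peek() == "not":
            advance()
            return ~parse_not()
        return parse_atom()

    def gather_values():
        vals = []
        while peek() is not None and peek() not in keywords:
            vals.append(advance())
        if not vals:
            raise ValueError("selection keyword needs at least one value")
        return vals

    def parse_atom():
        tok = advance()
        if tok == "(":
            inner = parse_or()
            if advance() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return inner
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "protein":
            # toy convention: every labeled residue is 'protein'
            return np.ones(n, dtype=bool)
        if tok == "name":
            names = set(gather_values())
            return np.array([lb.name in names for lb in labels])
        if tok == "element":
            els = {v.upper() for v in gather_values()}
            return np.array([lb.element.upper() in els for lb in labels])
        if tok == "resname":
            rs = set(gather_values())
            return np.array([lb.resname in rs for lb in labels])
        if tok == "resid":
            vals = gather_values()
            wanted = set()
            for v in vals:
                if "-" in v.strip("-"):
                    a, b = v.split("-", 1)
                    wanted.update(range(int(a), int(b) + 1))
                else:
                    wanted.add(int(v))
            # resid is 1-based at the user boundary
            return np.array([(lb.resid + 1) in wanted for lb in labels])
        raise ValueError(f"unknown selection token {tok!r}")

    mask = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in selection: {tokens[pos:]}")
    return Selection(indices=np.flatnonzero(mask), expression=expression)


def _resolve(traj: TrajectoryEnsemble, selection) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_particles)
    if isinstance(selection, Selection):
        return selection.indices
    if isinstance(selection, str):
        return select(traj, selection).indices
    return Selection(indices=np.asarray(selection)).indices


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    weighted least-squares sense.  The rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 particles")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    rank_ok = s[1] > max(s[0] * 1e-12, 1e-300)
    if not rank_ok:
        raise ValueError("degenerate fit: collinear or coincident particles")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = (w @ reference) - rotation @ (w @ mobile)
    fitted = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - ref_c) ** 2)))
    return rotation, translation, rmsd


def _align_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[f], reference)
        out[f] = coords[f] @ rot.T + trans
    return out


def iterative_mean_structure(
    coords: np.ndarray, passes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Align to frame 0, average, then re-align to the mean (``passes`` times).

    Returns ``(mean, aligned_coordinates)``.
    """
    reference = coords[0]
    aligned = coords
    for _ in range(passes):
        aligned = _align_frames(coords, reference)
        reference = aligned.mean(axis=0)
    return reference, aligned


# ---------------------------------------------------------------------------
# descriptors


@dataclass
class RMSFProfile:
    rmsf: np.ndarray  # A, per selected particle
    indices: np.ndarray
    reference_kind: Literal["mean", "first-frame"] = "mean"

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")


def rmsd_series(
    traj: TrajectoryEnsemble,
    reference_frame: int | np.ndarray = 0,
    selection=None,
) -> np.ndarray:
    """Per-frame best-fit RMSD (A) over ``selection``, superposed on the
    same selection."""
    idx = _resolve(traj, selection)
    if isinstance(reference_frame, (int, np.integer)):
        ref = traj.coordinates[int(reference_frame)][idx]
    else:
        ref = np.asarray(reference_frame, dtype=float)
        if ref.shape[0] == traj.n_particles:
            ref = ref[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.coordinates[f][idx], ref)
    return out


def rmsf(
    traj: TrajectoryEnsemble, selection=None, align: bool = True
) -> RMSFProfile:
    """Per-particle root-mean-square fluctuation about the (aligned) mean."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _resolve(traj, selection)
    coords = traj.coordinates[:, idx, :]
    if align:
        mean, coords = iterative_mean_structure(coords)
    else:
        mean = coords.mean(axis=0)
    disp2 = np.sum((coords - mean) ** 2, axis=2)
    return RMSFProfile(rmsf=np.sqrt(disp2.mean(axis=0)), indices=idx)


def delta_rmsf(a: RMSFProfile, b: RMSFProfile) -> np.ndarray:
    """Elementwise ``a - b`` (e.g. variant minus reference profile)."""
    if a.rmsf.shape != b.rmsf.shape:
        raise ValueError(
            f"profile length mismatch: {a.rmsf.shape} vs {b.rmsf.shape}"
        )
    return a.rmsf - b.rmsf


def radius_of_gyration(
    traj: TrajectoryEnsemble, selection=None, mass_weighted: bool = True
) -> np.ndarray:
    """Per-frame radius of gyration (A) over ``selection``."""
    idx = _resolve(traj, selection)
    coords = traj.coordinates[:, idx, :]
    m = traj.masses[idx] if mass_weighted else np.ones(idx.size)
    com = np.einsum("fpc,p->fc", coords, m) / m.sum()
    d2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    return np.sqrt((d2 * m).sum(axis=1) / m.sum())


def rc_distance_series(
    traj: TrajectoryEnsemble, particle_i: int, particle_j: int
) -> np.ndarray:
    """Euclidean distance (A) between two particles, per frame, no imaging."""
    n = traj.n_particles
    for p in (particle_i, particle_j):
        if not 0 <= p < n:
            raise IndexError(f"particle index {p} out of range for {n} particles")
    diff = traj.coordinates[:, particle_i, :] - traj.coordinates[:, particle_j, :]
    return np.linalg.norm(diff, axis=1)


def _find_particle(traj: TrajectoryEnsemble, resid: int, atom_name: str) -> int:
    for i, lb in enumerate(traj.labels):
        if lb.resid + 1 == resid and lb.name == atom_name:
            return i
    raise LookupError(f"no atom {atom_name!r} in residue {resid}")


def rc_from_selection_pair(
    traj: TrajectoryEnsemble,
    residue_a: int,
    atom_name_a: str,
    residue_b: int,
    atom_name_b: str,
) -> np.ndarray:
    """Distance series between two atoms named by (1-based residue, atom name)."""
    i = _find_particle(traj, residue_a, atom_name_a)
    j = _find_particle(traj, residue_b, atom_name_b)
    return rc_distance_series(traj, i, j)


# ---------------------------------------------------------------------------
# distributions


@dataclass
class DistributionSummary:
    bin_edges: np.ndarray
    density: np.ndarray  # unit trapezoid area
    peak_positions: np.ndarray  # sorted by height descending
    peak_heights: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])


def probability_distribution(
    series: np.ndarray, bin_width: float = 0.05, smooth: bool = False
) -> DistributionSummary:
    """Unit-area histogram with local-maximum peak reporting.

    Peaks are interior local maxima of the (optionally 3-bin moving-average
    smoothed) density, reported at bin centers, sorted by height descending;
    plateau ties resolve to the leftmost bin.  A zero-variance series
    collapses to a single delta-like bin.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        edges = np.array([lo - 0.5 * bin_width, lo + 0.5 * bin_width])
        density = np.array([1.0 / bin_width])
        return DistributionSummary(
            bin_edges=edges,
            density=density,
            peak_positions=np.array([lo]),
            peak_heights=density.copy(),
        )
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (counts.sum() * bin_width)

    probe = density
    if smooth and density.size >= 3:
        probe = np.convolve(density, np.ones(3) / 3.0, mode="same")
    peaks = []
    for i in range(probe.size):
        left = probe[i - 1] if i > 0 else -np.inf
        right = probe[i + 1] if i < probe.size - 1 else -np.inf
        if probe[i] > left and probe[i] >= right and probe[i] > 0:
            peaks.append(i)
    centers = 0.5 * (edges[1:] + edges[:-1])
    peaks = sorted(peaks, key=lambda i: (-probe[i], centers[i]))
    return DistributionSummary(
        bin_edges=edges,
        density=density,
        peak_positions=centers[peaks],
        peak_heights=density[peaks],
    )
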