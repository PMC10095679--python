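"""Unbiased free-energy surfaces from boosted ensembles, plus basin detection.

A boosted frame carries a non-negative lift ``dV``; the unbiased density in
a reaction-coordinate bin j is recovered either by the exponential average

    p(j) = p*(j) <exp(dV / kT)>_j

or by its second-order cumulant expansion

    p(j) = p*(j) exp( <dV>_j / kT + Var(dV)_j / (2 kT^2) )

where p* is the biased (histogram) density.  The PMF is ``-kT ln p``,
min-shifted to zero over visited bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Method = Literal["none", "exp_avg", "cumulant2"]


@dataclass
class PMFGrid:
    """Binned free-energy surface over 1-2 reaction coordinates."""

    rc_names: list[str]
    bin_edges: list[np.ndarray]
    pmf: np.ndarray  # kcal/mol, min-shifted; empty bins at max(visited)+kT
    counts: np.ndarray
    method: Method
    kt: float
    empty_value: float
    metadata: dict = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return self.pmf.ndim

    @property
    def bin_centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.bin_edges]

    @property
    def visited(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class Basin:
    """A local PMF minimum, labeled EB1, EB2, ... by ascending PMF."""

    label: str
    bin_index: tuple[int, ...]
    rc_values: tuple[float, ...]
    pmf_value: float
    depth: float  # kcal/mol below the lowest escape saddle


def reweight_pmf(
    rc_samples: np.ndarray,
    dv_series: np.ndarray,
    bin_edges,
    kt: float,
    method: Method = "cumulant2",
    rc_names: list[str] | None = None,
) -> PMFGrid:
    """Histogram per-frame reaction-coordinate values into a PMF, reweighting
    the boost out with the requested ``method``.

    ``rc_samples`` is (n_frames,) for 1-D or (n_frames, 2) for 2-D grids.
    Bins with fewer than 2 frames cannot support a variance estimate: under
    ``cumulant2`` they receive the first-order (mean-only) correction and are
    flagged in ``metadata['first_order_bins']``.
    """
    rc = np.asarray(rc_samples, dtype=float)
    if rc.ndim == 1:
        rc = rc[:, None]
    n_frames, ndim = rc.shape
    if ndim not in (1, 2):
        raise ValueError("reaction coordinates must be 1- or 2-dimensional")
    dv = np.asarray(dv_series, dtype=float)
    if dv.shape != (n_frames,):
        raise ValueError("dv_series length must match rc_samples")
    if kt <= 0:
        raise ValueError("kT must be positive")
    if method not in ("none", "exp_avg", "cumulant2"):
        raise ValueError(f"unknown reweighting method {method!r}")

    if isinstance(bin_edges, (list, tuple)) and len(bin_edges) == ndim:
        edges = [np.asarray(e, dtype=float) for e in bin_edges]
    else:
        edges = [np.asarray(bin_edges, dtype=float)]
    if len(edges) != ndim:
        raise ValueError("need one bin-edge array per reaction coordinate")

    shape = tuple(len(e) - 1 for e in edges)
    counts = np.zeros(shape)
    # flat bin index per frame; out-of-range frames dropped
    idx = np.empty((n_frames, ndim), dtype=np.int64)
    inside = np.ones(n_frames, dtype=bool)
    for a in range(ndim):
        k = np.searchsorted(edges[a], rc[:, a], side="right") - 1
        # fold the closed upper edge into the last bin
        k = np.where(rc[:, a] == edges[a][-1], shape[a] - 1, k)
        inside &= (k >= 0) & (k < shape[a])
        idx[:, a] = np.clip(k, 0, shape[a] - 1)
    flat = np.ravel_multi_index(idx[inside].T, shape)
    dv_in = dv[inside]
    nbins = int(np.prod(shape))
    counts = np.bincount(flat, minlength=nbins).astype(float)
    if counts.sum() == 0:
        raise ValueError("no reaction-coordinate samples fall inside the grid")

    visited = counts > 0
    density = counts / counts.sum()

    first_order = np.zeros(nbins, dtype=bool)
    if method == "none":
        log_weight = np.zeros(nbins)
    elif method == "exp_avg":
        # per-bin <exp(dV/kT)>, computed against the bin max for stability
        w = np.exp((dv_in - dv_in.max()) / kt) if dv_in.size else dv_in
        sum_w = np.bincount(flat, weights=w, minlength=nbins)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_weight = np.where(
                visited, np.log(sum_w / np.maximum(counts, 1)), 0.0
            ) + dv_in.max() / kt if dv_in.size else np.zeros(nbins)
    else:  # cumulant2
        sum_dv = np.bincount(flat, weights=dv_in, minlength=nbins)
        sum_dv2 = np.bincount(flat, weights=dv_in**2, minlength=nbins)
        mean_dv = np.where(visited, sum_dv / np.maximum(counts, 1), 0.0)
        var_dv = np.where(
            visited, sum_dv2 / np.maximum(counts, 1) - mean_dv**2, 0.0
        )
        var_dv = np.maximum(var_dv, 0.0)
        first_order = visited & (counts < 2)
        var_dv[first_order] = 0.0
        log_weight = mean_dv / kt + var_dv / (2.0 * kt**2)

    with np.errstate(divide="ignore"):
        neg_log_p = np.where(
            visited, -kt * (np.log(density, where=visited, out=np.full(nbins, np.nan))
                            + log_weight), np.nan
        )
    pmf_flat = neg_log_p - np.nanmin(neg_log_p)
    empty_value = float(np.nanmax(pmf_flat)) + kt
    pmf_flat = np.where(visited, pmf_flat, empty_value)

    names = rc_names if rc_names is not None else [f"rc{i + 1}" for i in range(ndim)]
    return PMFGrid(
        rc_names=list(names),
        bin_edges=edges,
        pmf=pmf_flat.reshape(shape),
        counts=counts.reshape(shape),
        method=method,
        kt=kt,
        empty_value=empty_value,
        metadata={
            "n_frames_used": int(counts.sum()),
            "n_frames_dropped": int(n_frames - counts.sum()),
            "first_order_bins": int(first_order.sum()),
        },
    )


# ---------------------------------------------------------------------------
# basin detection


def _neighbors(index: tuple[int, ...], shape: tuple[int, ...]):
    for a in range(len(shape)):
        for step in (-1, 1):
            j = index[a] + step
            if 0 <= j < shape[a]:
                yield index[:a] + (j,) + index[a + 1 :]


def detect_basins(
    pmf: PMFGrid, max_basins: int = 10, min_depth: float = 0.0
) -> list[Basin]:
    """Local PMF minima with watershed (persistence) depths.

    Bins are flooded in ascending PMF order with union-find merging; a
    basin's depth is the level at which its catchment first touches a deeper
    one (the lowest escape saddle), and the deepest basin takes the full
    relief of the visited surface.  Empty bins never participate.  Minima
    shallower than ``min_depth`` are suppressed (merged), the surviving
    basins are labeled EB1, EB2, ... by ascending PMF, and at most
    ``max_basins`` are returned.
    """
    if max_basins < 1:
        raise ValueError("max_basins must be >= 1")
    grid = pmf.pmf
    shape = grid.shape
    visited = pmf.visited

    order = sorted(
        (idx for idx in np.ndindex(shape) if visited[idx]), key=lambda i: grid[i]
    )
    if not order:
        return []

    owner: dict[tuple[int, ...], tuple[int, ...]] = {}  # bin -> root minimum
    root_min: dict[tuple[int, ...], float] = {}
    saddle: dict[tuple[int, ...], float] = {}  # root -> escape level

    def find(r):
        while owner[r] != r:
            owner[r] = owner[owner[r]]
            r = owner[r]
        return r

    for idx in order:
        neighbor_roots = {
            find(n) for n in _neighbors(idx, shape) if n in owner
        }
        if not neighbor_roots:
            owner[idx] = idx
            root_min[idx] = grid[idx]
            continue
        roots = sorted(neighbor_roots, key=lambda r: root_min[r])
        best = roots[0]
        owner[idx] = best
        for r in roots[1:]:
            if r not in saddle:
                saddle[r] = grid[idx]
            owner[r] = best

    global_root = find(order[0])
    relief = float(grid[order[-1]] - grid[global_root])
    saddle[global_root] = grid[global_root] + relief
    # roots of components never reached by the flood (disconnected across
    # empty bins) escape only through unvisited territory: use the
    # empty-bin level as their saddle
    for r in root_min:
        saddle.setdefault(r, pmf.empty_value)

    # a flat surface has zero relief everywhere -> no basins at all
    candidates = [
        (r, float(saddle[r] - root_min[r]))
        for r in root_min
        if saddle[r] - root_min[r] > 0 and saddle[r] - root_min[r] >= min_depth
    ]
    candidates.sort(key=lambda c: root_min[c[0]])
    centers = pmf.bin_centers
    basins = []
    for rank, (r, depth) in enumerate(candidates[:max_basins], start=1):
        basins.append(
            Basin(
                label=f"EB{rank}",
                bin_index=r,
                rc_values=tuple(centers[a][r[a]] for a in range(len(shape))),
                pmf_value=float(grid[r]),
                depth=depth,
            )
        )
    return basins
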