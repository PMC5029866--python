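"""Nucleus boundary delineation on radial profiles via a cyclic MRF.

A square search window (default 30x30 px) is centered on each seed.
The combined saliency map is resampled along ``n_profiles`` spokes of
equally spaced angles; each spoke ``i`` must choose a boundary radius
label ``l_i`` in ``{1..max_radius}``.  The configuration energy is

    E(l) = sum_i  E_data(i, l_i)  +  sum_(i,j adjacent)  E_smooth(l_i, l_j)

where the data cost is the negative (window-normalized) saliency at the
candidate boundary point — the boundary ridge of the combined map is
bright, hence cheap — and the smoothness cost is ``lambda * |l_i - l_j|``
for deviations strictly below ``smoothness_limit`` (default 5 px) and
infinite beyond, enforcing a closed, smoothly evolving contour.  The
spokes form a cycle (the last spoke neighbors the first), so the MRF is
loopy; the energy is minimized by synchronous min-sum loopy belief
propagation, with an exact conditioning-plus-chain-DP solver provided as
an independent oracle.

Coordinate convention: 0-based (row, col); spoke angle theta is measured
from the +col axis with +row pointing down, so a point at radius phi on
spoke theta sits at ``(row + phi*sin(theta), col + phi*cos(theta))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tensor_voting import SaliencyMap, SeedPoint

__all__ = [
    "RadialProfileGrid",
    "BoundaryMRF",
    "BoundaryLabeling",
    "BoundaryContour",
    "sample_radial_profiles",
    "build_mrf",
    "run_lbp",
    "exact_boundary_oracle",
    "decode_boundary",
    "mrf_energy",
]

#: Finite stand-in for the infinite smoothness/data cost inside message
#: arithmetic (keeps min-sum updates NaN-free); decoded energies at or
#: above this are reported as infinite.
_BIG = 1e9


@dataclass(frozen=True)
class RadialProfileGrid:
    """Polar resampling of the combined saliency map around one seed.

    ``values[i, p]`` is the bilinear saliency sample at radius ``p + 1``
    on spoke ``i``; samples falling outside the image are NaN (their
    labels receive infinite data cost downstream).
    """

    seed: SeedPoint
    angles: np.ndarray
    max_radius: int
    values: np.ndarray

    @property
    def n_profiles(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class BoundaryMRF:
    """Cyclic chain over spokes with per-spoke radius labels.

    ``data_cost[i, l-1]`` is the unary cost of placing the boundary at
    radius ``l`` on spoke ``i``; adjacent spokes (cyclically) pay
    ``smoothness_weight * |l_i - l_j|`` when ``|l_i - l_j| <
    smoothness_limit`` and an infinite cost otherwise.
    """

    data_cost: np.ndarray
    smoothness_limit: int
    smoothness_weight: float

    @property
    def n_profiles(self) -> int:
        return self.data_cost.shape[0]

    @property
    def n_labels(self) -> int:
        return self.data_cost.shape[1]

    def pairwise(self) -> np.ndarray:
        """Dense (L, L) pairwise cost matrix, with np.inf beyond the limit."""
        lab = np.arange(1, self.n_labels + 1)
        delta = np.abs(lab[:, None] - lab[None, :])
        return np.where(
            delta < self.smoothness_limit, self.smoothness_weight * delta, np.inf
        )


@dataclass(frozen=True)
class BoundaryLabeling:
    """One radius label per spoke plus the Eq-style total energy."""

    labels: np.ndarray  # 1-based radii, one per spoke
    energy: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class BoundaryContour:
    """Closed boundary polygon in image coordinates, one vertex per spoke."""

    vertices: np.ndarray  # (n_profiles, 2) float (row, col)
    seed: SeedPoint


def sample_radial_profiles(
    combined: SaliencyMap,
    seed: SeedPoint,
    window: int = 30,
    n_profiles: int = 32,
) -> RadialProfileGrid:
    """Sample the combined saliency map along spokes radiating from a seed.

    ``max_radius = floor(window / 2)``; spokes use ``n_profiles`` equally
    spaced angles over [0, 2pi).  Samples are bilinear; positions outside
    the image are NaN rather than shrinking the window.
    """
    h, w = combined.shape
    if not (0 <= seed.row < h and 0 <= seed.col < w):
        raise ValueError("seed lies outside the image")
    if n_profiles < 4:
        raise ValueError("need at least 4 radial profiles")
    max_radius = window // 2
    if max_radius < 2:
        raise ValueError("window too small")
    angles = np.arange(n_profiles) * (2.0 * np.pi / n_profiles)
    radii = np.arange(1, max_radius + 1, dtype=np.float64)
    rows = seed.row + radii[None, :] * np.sin(angles)[:, None]
    cols = seed.col + radii[None, :] * np.cos(angles)[:, None]
    values = ndimage.map_coordinates(
        combined.values, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(n_profiles, max_radius)
    outside = (rows < 0) | (rows > h - 1) | (cols < 0) | (cols > w - 1)
    values = np.where(outside, np.nan, values)
    return RadialProfileGrid(seed=seed, angles=angles, max_radius=max_radius, values=values)


def build_mrf(
    grid: RadialProfileGrid,
    smoothness_limit: int = 5,
    smoothness_weight: float = 0.5,
) -> BoundaryMRF:
    """Turn a radial-profile grid into unary costs on the spoke cycle.

    Saliency samples are min-max normalized to [0, 1] within the window
    and negated: a bright boundary ridge is a cheap label.  Off-image
    samples cost infinity.
    """
    if smoothness_limit < 1:
        raise ValueError("smoothness_limit must be >= 1")
    finite = np.isfinite(grid.values)
    norm = np.zeros_like(grid.values)
    if finite.any():
        lo = float(grid.values[finite].min())
        hi = float(grid.values[finite].max())
        if hi - lo > 0.0:
            norm[finite] = (grid.values[finite] - lo) / (hi - lo)
    data_cost = np.where(finite, -norm, np.inf)
    return BoundaryMRF(
        data_cost=data_cost,
        smoothness_limit=int(smoothness_limit),
        smoothness_weight=float(smoothness_weight),
    )


def mrf_energy(mrf: BoundaryMRF, labels: np.ndarray) -> float:
    """Total energy of a labeling: unary terms plus each cyclic edge once."""
    labels = np.asarray(labels, dtype=int)
    idx = labels - 1
    pair = mrf.pairwise()
    energy = float(mrf.data_cost[np.arange(mrf.n_profiles), idx].sum())
    energy += float(pair[idx, np.roll(idx, -1)].sum())
    return energy


def run_lbp(
    mrf: BoundaryMRF,
    max_iters: int = 50,
    tol: float = 1e-6,
    damping: float = 0.5,
    normalize: bool = True,
) -> BoundaryLabeling:
    """Min-sum loopy belief propagation on the spoke cycle.

    All messages start at 0 and are updated synchronously: the message
    from spoke ``i`` to neighbor ``j`` minimizes, over the sender's
    labels, the sender's data cost plus the pairwise cost plus the
    incoming messages to ``i`` excluding the one from ``j``.  Messages
    are normalized (minimum subtracted) each round and optionally
    damped.  Iteration stops at ``max_iters`` or when the largest
    message change drops below ``tol``.  Each spoke's label is the
    argmin of its belief, ties resolved toward the smaller radius; the
    returned energy is recomputed from the decoded labels.
    """
    n, L = mrf.n_profiles, mrf.n_labels
    data = np.where(np.isfinite(mrf.data_cost), mrf.data_cost, _BIG)
    if not np.isfinite(mrf.data_cost).any(axis=1).all():
        raise ValueError("a spoke has no feasible label; nucleus rejected")
    pair = np.where(np.isfinite(mrf.pairwise()), mrf.pairwise(), _BIG)

    # fwd[i] = message i -> i+1 (mod n); bwd[i] = message i -> i-1.
    fwd = np.zeros((n, L))
    bwd = np.zeros((n, L))
    converged = False
    iterations = 0
    for iterations in range(1, max_iters + 1):
        in_from_prev = np.roll(fwd, 1, axis=0)  # message (i-1) -> i
        in_from_next = np.roll(bwd, -1, axis=0)  # message (i+1) -> i
        new_fwd = np.min((data + in_from_prev)[:, :, None] + pair[None, :, :], axis=1)
        new_bwd = np.min((data + in_from_next)[:, :, None] + pair[None, :, :], axis=1)
        if normalize:
            new_fwd -= new_fwd.min(axis=1, keepdims=True)
            new_bwd -= new_bwd.min(axis=1, keepdims=True)
        if damping:
            new_fwd = (1.0 - damping) * new_fwd + damping * fwd
            new_bwd = (1.0 - damping) * new_bwd + damping * bwd
        change = max(np.abs(new_fwd - fwd).max(), np.abs(new_bwd - bwd).max())
        fwd, bwd = new_fwd, new_bwd
        if change < tol:
            converged = True
            break

    beliefs = data + np.roll(fwd, 1, axis=0) + np.roll(bwd, -1, axis=0)
    labels = np.argmin(beliefs, axis=1) + 1  # first argmin = smallest radius
    return BoundaryLabeling(
        labels=labels,
        energy=mrf_energy(mrf, labels),
        converged=converged,
        iterations=iterations,
    )


def exact_boundary_oracle(mrf: BoundaryMRF) -> BoundaryLabeling:
    """Exact global minimum of the cyclic energy, for testing LBP.

    Conditions on the label of spoke 0 and solves the remaining open
    chain by dynamic programming, keeping the best over all
    conditionings.  Ties resolve toward smaller labels (smaller spoke-0
    label first; within the chain, the earliest minimizer wins).
    """
    n, L = mrf.n_profiles, mrf.n_labels
    data = mrf.data_cost
    pair = mrf.pairwise()
    best_energy = np.inf
    best_labels: np.ndarray | None = None
    for l0 in range(L):
        if not np.isfinite(data[0, l0]):
            continue
        cost = data[1] + pair[l0]  # chain spoke 1 conditioned on l0
        back = np.zeros((n, L), dtype=int)
        for i in range(2, n):
            trans = cost[:, None] + pair  # (prev label, cur label)
            back[i] = np.argmin(trans, axis=0)
            cost = trans[back[i], np.arange(L)] + data[i]
        total = data[0, l0] + cost + pair[:, l0]  # close the cycle
        j = int(np.argmin(total))
        if total[j] < best_energy:
            best_energy = float(total[j])
            labels = np.empty(n, dtype=int)
            labels[0] = l0
            labels[n - 1] = j
            for i in range(n - 1, 1, -1):
                labels[i - 1] = back[i][labels[i]]
            best_labels = labels + 1
    if best_labels is None:
        raise ValueError("no feasible labeling exists")
    return BoundaryLabeling(
        labels=best_labels, energy=best_energy, converged=True, iterations=0
    )


def decode_boundary(labeling: BoundaryLabeling, grid: RadialProfileGrid) -> BoundaryContour:
    """Map a finite-energy labeling to a closed polygon around the seed."""
    if not np.isfinite(labeling.energy) or labeling.energy >= _BIG / 2:
        raise ValueError("cannot decode an infeasible (infinite-energy) labeling")
    radii = labeling.labels.astype(np.float64)
    rows = grid.seed.row + radii * np.sin(grid.angles)
    cols = grid.seed.col + radii * np.cos(grid.angles)
    return BoundaryContour(vertices=np.column_stack([rows, cols]), seed=grid.seed)
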