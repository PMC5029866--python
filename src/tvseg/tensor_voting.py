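"""Stick tensor voting for nuclei saliency maps and seed detection.

Every pixel with an appreciable gradient acts as a *voter*: it carries a
short oriented stick and casts decaying votes to nearby *receiver*
pixels.  Votes fall off with the arc length ``s`` of the osculating
circular arc joining voter and receiver and with its curvature ``k``::

    decay(s, k) = exp(-(s**2 + c * k**2) / sigma**2)

with ``c = -16 * log10(0.1) * (sigma - 1) / pi**2 = 16 (sigma-1) / pi**2``
(the classical curvature penalty; a natural-log variant is available via
``log_base_ten=False``).  Each vote is weighted by ``G * (1 - A)`` so
that strong, dark edge pixels — nucleus boundaries — dominate.

Two voting passes are run:

* *parallel*: sticks aligned with the gradient direction.  Radial
  gradients on a roughly convex nucleus all point through its center, so
  the parallel saliency map peaks at nucleus centers — these peaks are
  the candidate seed points.
* *perpendicular*: sticks rotated 90 degrees, i.e. tangent to the edge.
  Tangential votes reinforce one another along the boundary, producing a
  bright closed ridge on the nucleus outline.

The *combined* map (perpendicular minus parallel, rescaled to [0, 1])
shows boundaries bright and centers dark; it is the observation field
for the boundary-extraction MRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima

from .preprocessing import GradientField

__all__ = [
    "VotingParams",
    "SaliencyMap",
    "SeedPoint",
    "decay_kernel_value",
    "stick_geometry",
    "cast_votes",
    "combine_saliency",
    "detect_seeds",
]


@dataclass(frozen=True)
class VotingParams:
    """Parameters of the stick voting field.

    Attributes
    ----------
    sigma : float
        Scale of the voting stick in pixels (> 1); sets the neighborhood
        size.  Default 5, suited to nuclei of ~5-12 px radius at x40.
    support_radius : float
        Truncation radius of the kernel; defaults to ``3 * sigma``.
    angular_aperture : float
        Maximum angle (radians) between the stick axis and the
        voter-to-receiver chord for a vote to be cast; default pi/4.
    gradient_floor : float or None
        Absolute gradient-magnitude threshold below which a pixel does
        not vote.  ``None`` resolves, per image, to
        ``gradient_floor_fraction * max(G)``.
    gradient_floor_fraction : float
        Fraction used when ``gradient_floor`` is None (default 0.05).
    log_base_ten : bool
        Use the base-10 logarithm in the curvature constant ``c``
        (default True, giving ``c = 16 (sigma-1) / pi**2``).
    """

    sigma: float = 5.0
    support_radius: float | None = None
    angular_aperture: float = np.pi / 4
    gradient_floor: float | None = None
    gradient_floor_fraction: float = 0.05
    log_base_ten: bool = True

    def __post_init__(self):
        if not self.sigma > 1:
            raise ValueError("sigma must exceed 1 pixel")
        if self.support_radius is None:
            object.__setattr__(self, "support_radius", 3.0 * self.sigma)
        if self.support_radius < self.sigma:
            raise ValueError("support_radius must be >= sigma")
        if not 0.0 < self.angular_aperture <= np.pi / 2:
            raise ValueError("angular_aperture must lie in (0, pi/2]")

    @property
    def curvature_constant(self) -> float:
        """The decay constant ``c = -16 log(0.1) (sigma - 1) / pi**2``."""
        log01 = np.log10(0.1) if self.log_base_ten else np.log(0.1)
        return -16.0 * log01 * (self.sigma - 1.0) / np.pi**2


@dataclass(frozen=True)
class SaliencyMap:
    """Accumulated vote field; ``kind`` is parallel/perpendicular/combined."""

    values: np.ndarray
    kind: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True, order=True)
class SeedPoint:
    """A candidate nucleus center: a suppressed peak of the parallel map."""

    row: int
    col: int
    score: float = field(compare=False, default=0.0)


def decay_kernel_value(s, k, params: VotingParams):
    """Unit-weight stick-vote decay ``exp(-(s^2 + c k^2)/sigma^2)``.

    ``s`` is the arc length and ``k`` the curvature of the circular arc
    from voter to receiver; the caller multiplies by the voter weight
    ``G * (1 - A)``.  Accepts scalars or broadcastable arrays.
    """
    s = np.asarray(s, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    c = params.curvature_constant
    out = np.exp(-(s**2 + c * k**2) / params.sigma**2)
    return float(out) if out.ndim == 0 else out


def _fold_angle(delta):
    """Fold an angle difference into [0, pi/2].

    The voting field is symmetric about the stick axis and identical on
    the two lobes (forward/backward along the stick), so only the acute
    angle between chord and stick axis matters.
    """
    return np.abs((np.asarray(delta) + np.pi / 2) % np.pi - np.pi / 2)


def stick_geometry(voter_pos, receiver_pos, stick_orientation: float):
    """Arc length, curvature and chord length of a single vote.

    The voter sits at ``voter_pos`` (row, col) with its stick axis at
    angle ``stick_orientation`` (radians from the +col axis, +row
    downward).  With ``a`` the acute angle between the stick axis and
    the voter-to-receiver chord of length ``l``, the osculating arc has

        s = a * l / sin(a),      k = 2 * sin(a) / l,

    with the straight-line limit ``s = l, k = 0`` as ``a -> 0``.
    """
    vr, vc = float(voter_pos[0]), float(voter_pos[1])
    rr, rc = float(receiver_pos[0]), float(receiver_pos[1])
    drow, dcol = rr - vr, rc - vc
    length = float(np.hypot(drow, dcol))
    if length == 0.0:
        raise ValueError("receiver coincides with voter; self-vote undefined")
    a = float(_fold_angle(np.arctan2(drow, dcol) - stick_orientation))
    if a < 1e-12:
        return length, 0.0, length
    sin_a = np.sin(a)
    return a * length / sin_a, 2.0 * sin_a / length, length


def cast_votes(
    gray: np.ndarray,
    grad: GradientField,
    params: VotingParams | None = None,
    mode: str = "parallel",
) -> SaliencyMap:
    """Accumulate stick votes from every sufficiently strong gradient pixel.

    In ``parallel`` mode each voter's stick is aligned with its gradient
    direction; in ``perpendicular`` mode it is rotated by 90 degrees.
    Votes are cast symmetrically on both lobes of the stick, to
    receivers within ``support_radius`` and ``angular_aperture``, each
    weighted by ``G * (1 - A)`` at the voter.
    """
    params = params or VotingParams()
    gray = np.asarray(gray, dtype=np.float64)
    if gray.shape != grad.shape:
        raise ValueError("grayscale and gradient shapes differ")
    if mode not in ("parallel", "perpendicular"):
        raise ValueError(f"unknown voting mode {mode!r}")

    h, w = gray.shape
    mag, direction = grad.magnitude, grad.direction
    floor = params.gradient_floor
    if floor is None:
        floor = params.gradient_floor_fraction * float(mag.max())

    # Offset geometry is shared by all voters: only the stick angle and
    # the voter weight change from pixel to pixel.
    r_int = int(np.ceil(params.support_radius))
    drow, dcol = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    length = np.hypot(drow, dcol)
    chord_angle = np.arctan2(drow, dcol)
    in_support = (length > 0) & (length <= params.support_radius)

    c = params.curvature_constant
    sigma2 = params.sigma**2
    rotate = 0.0 if mode == "parallel" else np.pi / 2

    out = np.zeros((h, w), dtype=np.float64)
    voters = np.argwhere(mag > floor)
    for vr, vc in voters:
        beta = direction[vr, vc] + rotate
        a = _fold_angle(chord_angle - beta)
        mask = in_support & (a <= params.angular_aperture)
        if vr < r_int or vc < r_int or vr >= h - r_int or vc >= w - r_int:
            rows = vr + drow
            cols = vc + dcol
            mask = mask & (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        am = a[mask]
        lm = length[mask]
        sin_a = np.sin(am)
        small = am < 1e-12
        s = np.where(small, lm, am * lm / np.where(small, 1.0, sin_a))
        k = np.where(small, 0.0, 2.0 * sin_a / lm)
        weight = mag[vr, vc] * (1.0 - gray[vr, vc])
        votes = weight * np.exp(-(s**2 + c * k**2) / sigma2)
        # offsets are unique within one voter, so fancy += is safe
        out[vr + drow[mask], vc + dcol[mask]] += votes
    return SaliencyMap(values=out, kind=mode)


def combine_saliency(
    parallel: SaliencyMap, perpendicular: SaliencyMap, flip_sign: bool = False
) -> SaliencyMap:
    """Perpendicular-minus-parallel map, min-max rescaled to [0, 1].

    Boundaries come out bright, nucleus centers dark.  ``flip_sign``
    inverts the subtraction direction.  A constant difference map
    rescales to all zeros by convention.
    """
    if parallel.kind != "parallel" or perpendicular.kind != "perpendicular":
        raise ValueError("arguments must be a parallel and a perpendicular map")
    if parallel.shape != perpendicular.shape:
        raise ValueError("saliency maps have different shapes")
    diff = perpendicular.values - parallel.values
    if flip_sign:
        diff = -diff
    lo, hi = float(diff.min()), float(diff.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        values = np.zeros_like(diff)
    else:
        values = (diff - lo) / (hi - lo)
    return SaliencyMap(values=values, kind="combined")


def detect_seeds(
    parallel: SaliencyMap,
    min_distance: float = 10.0,
    min_height_fraction: float = 0.1,
    smooth_sigma: float = 5.0,
) -> list[SeedPoint]:
    """Candidate nucleus centers from the parallel saliency map.

    The map is Gaussian-smoothed at the voting scale — inside nuclei
    larger than the stick scale the parallel votes form a ridge ring
    rather than a single central blob, and smoothing at that scale
    merges the ring into one central peak.  Regional maxima above
    ``min_height_fraction`` of the global maximum are collected, and
    peaks closer than ``min_distance`` are suppressed greedily in
    descending score order (ties broken by row-major position).

    Each accepted peak is then refined to the intensity-weighted
    centroid of the bright neighborhood around it: for the largest
    nuclei the smoothed field retains a flat annular top, and the
    centroid — symmetric about the nucleus center — localizes better
    than the raw argmax.
    """
    if parallel.kind != "parallel":
        raise ValueError("seed detection expects the parallel saliency map")
    values = ndimage.gaussian_filter(parallel.values, smooth_sigma) if smooth_sigma else parallel.values
    vmax = float(values.max())
    if vmax <= 0.0 or float(values.min()) == vmax:
        return []
    peaks = np.argwhere(local_maxima(values, connectivity=2))
    if peaks.size == 0:
        return []
    scores = values[peaks[:, 0], peaks[:, 1]]
    keep = scores >= min_height_fraction * vmax
    peaks, scores = peaks[keep], scores[keep]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -scores))
    refine_radius = int(np.ceil(0.8 * min_distance))
    seeds: list[SeedPoint] = []
    for idx in order:
        r, c = int(peaks[idx, 0]), int(peaks[idx, 1])
        if any((r - s.row) ** 2 + (c - s.col) ** 2 < min_distance**2 for s in seeds):
            continue
        r, c = _refine_peak(values, r, c, refine_radius)
        if any((r - s.row) ** 2 + (c - s.col) ** 2 < min_distance**2 for s in seeds):
            continue
        seeds.append(SeedPoint(row=r, col=c, score=float(values[r, c])))
    return seeds


def _refine_peak(values: np.ndarray, row: int, col: int, radius: int) -> tuple[int, int]:
    """Intensity-weighted centroid of the near-maximal plateau at a peak.

    Only pixels within a few percent of the peak value participate: for
    a sharp peak this is the peak itself, while for the flat annular top
    left by heavy smoothing of a large nucleus it is the whole plateau,
    whose centroid is the nucleus center.
    """
    h, w = values.shape
    r0, r1 = max(row - radius, 0), min(row + radius + 1, h)
    c0, c1 = max(col - radius, 0), min(col + radius + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    window = values[r0:r1, c0:c1]
    weight = np.where(
        ((rr - row) ** 2 + (cc - col) ** 2 <= radius**2)
        & (window >= 0.98 * values[row, col]),
        window,
        0.0,
    )
    total = weight.sum()
    if total <= 0:
        return row, col
    return (
        int(round(float((rr * weight).sum() / total))),
        int(round(float((cc * weight).sum() / total))),
    )
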