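"""Straight-line detection in edge maps via the Hough transform.

Every boundary pixel (x, y) maps to the sinusoid ``rho = x*cos(theta) +
y*sin(theta)`` in (theta, rho) parameter space; collinear pixels
intersect at one parameter pair, so lines appear as vote peaks in the
discretized accumulator.  theta is restricted to [0, pi) so each
undirected line has a unique parameterization.

Coordinate convention (fixed for reproducibility): origin at the top-left
corner, x = column index, y = row index, both 0-based; rho is measured in
this frame, in pixels.

Peaks only give infinite lines; :func:`extract_segments` walks the edge
pixels near each peak line and chains them into finite segments so that
per-cell lengths can be reported.  Runs shorter than the 20-pixel floor
are discarded — short runs are dominated by noise, and it is this floor
that rejects small rounded floating cells (their largest near-straight
chord stays under the threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

DEFAULT_MIN_LENGTH = 20.0  # pixels; detection floor for straight runs


@dataclass(frozen=True)
class LineSegment:
    """A detected straight segment with its generating Hough parameters.

    ``start`` and ``end`` are (x, y) pixel coordinates; ``theta`` is in
    [0, pi) radians and ``rho`` in pixels per the module's convention.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    theta: float
    rho: float

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)

    @property
    def direction(self) -> tuple[float, float]:
        """Unit direction vector; raises on degenerate segments."""
        dx = self.end[0] - self.start[0]
        dy = self.end[1] - self.start[1]
        norm = math.hypot(dx, dy)
        if norm == 0.0:
            raise ValueError("zero-length segment has no direction")
        return (dx / norm, dy / norm)


@dataclass
class HoughAccumulator:
    """Vote matrix over the discretized (theta, rho) parameter space.

    ``votes[i, j]`` counts the edge pixels whose sinusoid passes nearest
    to ``(thetas[i], rhos[j])``.  Total votes equal (#edge pixels) x
    (#theta bins) because every pixel votes once per theta bin.
    """

    votes: np.ndarray
    thetas: np.ndarray
    rhos: np.ndarray

    @property
    def theta_step(self) -> float:
        return float(self.thetas[1] - self.thetas[0]) if len(self.thetas) > 1 else math.pi

    @property
    def rho_step(self) -> float:
        return float(self.rhos[1] - self.rhos[0]) if len(self.rhos) > 1 else 1.0


def hough_accumulate(
    edges: np.ndarray,
    theta_step: float = math.radians(1.0),
    rho_step: float = 1.0,
) -> HoughAccumulator:
    """Accumulate Hough votes for every edge pixel.

    For each edge pixel (x, y) and each theta bin, one vote goes to the
    rho bin nearest ``x*cos(theta) + y*sin(theta)`` (half-way values
    round up).  The rho axis spans [-D, D] where D is the image diagonal
    rounded up, so every vote lands inside the array.

    An empty edge image yields a valid all-zero accumulator.
    """
    edges = np.asarray(edges, dtype=bool)
    if theta_step <= 0 or theta_step > math.pi:
        raise ValueError("theta_step must give at least one bin in [0, pi)")
    if rho_step <= 0:
        raise ValueError(f"rho_step must be positive, got {rho_step}")

    h, w = edges.shape
    thetas = np.arange(0.0, math.pi - 1e-12, theta_step)
    diag = math.ceil(math.hypot(h - 1, w - 1))
    n_half = math.ceil(diag / rho_step)
    rhos = np.arange(-n_half, n_half + 1) * rho_step

    votes = np.zeros((len(thetas), len(rhos)), dtype=np.int64)
    ys, xs = np.nonzero(edges)
    if len(xs):
        cos_t, sin_t = np.cos(thetas), np.sin(thetas)
        rho = xs[:, None] * cos_t[None, :] + ys[:, None] * sin_t[None, :]
        # np.round on rho/step, not floor(x + 0.5): adding 0.5 can carry
        # values just below a half up to it and flip the nearest bin
        j = (np.round(rho / rho_step) + n_half).astype(np.intp)
        i = np.broadcast_to(np.arange(len(thetas), dtype=np.intp), j.shape)
        flat = np.bincount(
            (i * len(rhos) + j).ravel(), minlength=votes.size
        )
        votes = flat.reshape(votes.shape).astype(np.int64)
    return HoughAccumulator(votes=votes, thetas=thetas, rhos=rhos)


def find_peaks(
    acc: HoughAccumulator,
    min_votes: int = 20,
    nhood: int | tuple[int, int] = 11,
) -> list[tuple[float, float]]:
    """Select accumulator peaks with non-maximum suppression.

    Returns (theta, rho) pairs of local maxima with at least
    ``min_votes`` votes, in descending vote order; ties break toward the
    lower theta bin, then the lower rho bin, so the result is
    deterministic.  ``nhood`` is the suppression window in bins (odd; a
    single int applies to both axes).  The theta axis wraps at pi as the
    same undirected line with rho negated, and the suppression window
    respects that wrap.
    """
    if min_votes < 1:
        raise ValueError(f"min_votes must be >= 1, got {min_votes}")
    nt, nr = (nhood, nhood) if isinstance(nhood, int) else nhood
    nt, nr = max(1, nt) | 1, max(1, nr) | 1  # force odd
    votes = acc.votes
    if not votes.any():
        return []

    # theta-axis wrap: bin (theta - k*step) maps to (pi - k*step, -rho),
    # i.e. the rho-reversed copy of the last/first theta rows.
    pad = nt // 2
    if pad and votes.shape[0] > pad:
        flipped = votes[:, ::-1]
        ext = np.vstack([flipped[-pad:], votes, flipped[:pad]])
    else:
        ext = votes
        pad = 0
    local_max = ndi.maximum_filter(ext, size=(nt, nr), mode="constant")
    if pad:
        local_max = local_max[pad:-pad]
    cand = np.argwhere((votes >= min_votes) & (votes == local_max))
    if not len(cand):
        return []

    # Greedy suppression with the deterministic tie-break.
    order = np.lexsort((cand[:, 1], cand[:, 0], -votes[cand[:, 0], cand[:, 1]]))
    cand = cand[order]
    n_theta = votes.shape[0]
    accepted: list[tuple[int, int]] = []
    for ti, ri in cand:
        ok = True
        for ta, ra in accepted:
            dt = abs(int(ti) - ta)
            if dt <= nt // 2 and abs(int(ri) - ra) <= nr // 2:
                ok = False
                break
            # wrapped theta distance pairs rho with its mirror bin
            if n_theta - dt <= nt // 2 and abs(
                (len(acc.rhos) - 1 - int(ri)) - ra
            ) <= nr // 2:
                ok = False
                break
        if ok:
            accepted.append((int(ti), int(ri)))
    return [(float(acc.thetas[t]), float(acc.rhos[r])) for t, r in accepted]


def extract_segments(
    edges: np.ndarray,
    peaks: list[tuple[float, float]],
    min_length: float = DEFAULT_MIN_LENGTH,
    max_gap: float = 3.0,
    lateral_tol: float = 2.0,
) -> list[LineSegment]:
    """Trace finite segments along each peak line.

    Edge pixels within ``lateral_tol`` of a peak's infinite line are
    projected onto the line direction and chained into maximal runs
    whose internal gaps do not exceed ``max_gap``; each run of Euclidean
    length >= ``min_length`` is emitted with the generating (theta, rho).
    """
    if min_length <= 0:
        raise ValueError(f"min_length must be positive, got {min_length}")
    edges = np.asarray(edges, dtype=bool)
    ys, xs = np.nonzero(edges)
    segments: list[LineSegment] = []
    if not len(xs):
        return segments

    xs_f = xs.astype(np.float64)
    ys_f = ys.astype(np.float64)
    for theta, rho in peaks:
        c, s = math.cos(theta), math.sin(theta)
        lateral = xs_f * c + ys_f * s - rho
        sel = np.abs(lateral) <= lateral_tol
        if not sel.any():
            continue
        px, py = xs_f[sel], ys_f[sel]
        t = -px * s + py * c  # position along the line direction
        order = np.argsort(t, kind="stable")
        px, py, t = px[order], py[order], t[order]
        breaks = np.nonzero(np.diff(t) > max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(t) - 1]])
        for a, b in zip(starts, ends):
            p0 = (px[a], py[a])
            p1 = (px[b], py[b])
            if math.dist(p0, p1) >= min_length:
                segments.append(
                    LineSegment(start=p0, end=p1, theta=theta, rho=rho)
                )
    return segments


def detect_lines(
    edges: np.ndarray,
    *,
    theta_step: float = math.radians(1.0),
    rho_step: float = 1.0,
    min_votes: int = 20,
    nhood: int | tuple[int, int] = 11,
    min_length: float = DEFAULT_MIN_LENGTH,
    max_gap: float = 3.0,
    lateral_tol: float = 2.0,
) -> list[LineSegment]:
    """Accumulate, pick peaks, and trace segments in one call."""
    acc = hough_accumulate(edges, theta_step=theta_step, rho_step=rho_step)
    peaks = find_peaks(acc, min_votes=min_votes, nhood=nhood)
    return extract_segments(edges, peaks, min_length=min_length,
                            max_gap=max_gap, lateral_tol=lateral_tol)
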