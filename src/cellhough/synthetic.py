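"""Synthetic brightfield scenes with ground truth for offline testing.

The generator emulates the imaging conditions of 200x brightfield frames
of adherent epithelial cells: adherent cells are darker than the medium
(the cytoplasm transmits less light), detached floating cells are bright
and rounded, illumination is not uniform across the field, boundaries
are blurred by the optics, and the sensor adds salt-and-pepper noise.
Three object classes are rendered:

* ``elongated`` — dark capsules along a straight centerline (slender
  fibroblast-like cells after the epithelial-mesenchymal transition);
* ``cobblestone`` — dark low-eccentricity ellipses (the epithelial
  control phenotype);
* ``floating`` — small bright discs (detached cells that a line
  detector must ignore).

Each placed object is recorded in a :class:`GroundTruth` so that
detection and quantification can be scored without real study images.
All randomness flows from the mandatory ``seed`` through one generator,
so a fixed spec reproduces the scene bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .postprocess import PolylineCell


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without crowding."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Intensities are fractions in [0, 1] and must satisfy
    ``cell_intensity < background_intensity < floating_intensity`` —
    the contrast structure of a brightfield frame.  ``clearance`` is the
    minimum surface-to-surface gap between placed objects, in pixels;
    the default keeps distinct cells resolvable by the post-processing
    rules (a sparse field, as after serum starvation).
    """

    seed: int
    size: tuple[int, int] = (320, 320)
    n_cobblestone: int = 0
    n_elongated: int = 0
    n_floating: int = 0
    elongated_length: tuple[float, float] = (50.0, 70.0)
    elongated_aspect: tuple[float, float] = (5.0, 7.0)
    cobblestone_diameter: tuple[float, float] = (14.0, 24.0)
    cobblestone_aspect: tuple[float, float] = (1.0, 1.5)
    floating_radius: tuple[float, float] = (4.0, 8.0)
    cell_intensity: float = 0.45
    background_intensity: float = 0.75
    floating_intensity: float = 0.95
    salt_pepper_rate: float = 0.002
    illumination_amplitude: float = 0.1
    blur_sigma: float = 1.0
    clearance: float = 16.0
    max_attempts: int = 500

    def __post_init__(self):
        if not (0.0 <= self.cell_intensity < self.background_intensity
                < self.floating_intensity <= 1.0):
            raise ValueError(
                "intensities must satisfy cell < background < floating "
                "within [0, 1]"
            )
        if min(self.n_cobblestone, self.n_elongated, self.n_floating) < 0:
            raise ValueError("object counts must be non-negative")
        if self.elongated_aspect[0] < 3.0:
            raise ValueError("elongated aspect ratio must be >= 3")


@dataclass
class CellRecord:
    """Ground-truth record for one placed object."""

    kind: str  # "cobblestone" | "elongated" | "floating"
    centroid: tuple[float, float]
    # elongated cells: centerline endpoints (x, y); others: None
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None
    radius: float | None = None  # rounded cells: effective radius

    @property
    def length(self) -> float:
        if self.endpoints is None:
            raise ValueError(f"{self.kind} record has no centerline")
        return math.dist(*self.endpoints)

    @property
    def angle(self) -> float:
        """Centerline direction in [0, pi) radians."""
        (x1, y1), (x2, y2) = self.endpoints
        return math.atan2(y2 - y1, x2 - x1) % math.pi


@dataclass
class GroundTruth:
    records: list[CellRecord] = field(default_factory=list)
    spec: SceneSpec | None = None

    def of_kind(self, kind: str) -> list[CellRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_json(self) -> str:
        payload = {
            "records": [asdict(r) for r in self.records],
            "spec": asdict(self.spec) if self.spec else None,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        records = []
        for r in payload["records"]:
            ep = r.get("endpoints")
            records.append(CellRecord(
                kind=r["kind"],
                centroid=tuple(r["centroid"]),
                endpoints=tuple(tuple(p) for p in ep) if ep else None,
                radius=r.get("radius"),
            ))
        spec = SceneSpec(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in payload["spec"].items()}) \
            if payload.get("spec") else None
        return cls(records=records, spec=spec)


def _capsule_mask(shape, p1, p2, half_width):
    """Pixels within ``half_width`` of the segment p1-p2."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    vx, vy = p2[0] - p1[0], p2[1] - p1[1]
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0:
        d2 = (xs - p1[0]) ** 2 + (ys - p1[1]) ** 2
    else:
        t = ((xs - p1[0]) * vx + (ys - p1[1]) * vy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d2 = (xs - (p1[0] + t * vx)) ** 2 + (ys - (p1[1] + t * vy)) ** 2
    return d2 <= half_width ** 2


def _ellipse_mask(shape, center, a, b, phi):
    """Pixels inside an ellipse with semi-axes a, b rotated by phi."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - center[0], ys - center[1]
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene and its ground truth.

    Objects are placed by rejection sampling with the spec's clearance;
    if an object cannot be placed within ``max_attempts`` tries a
    :class:`PlacementError` is raised (the scene is overcrowded).  After
    drawing, the illumination gradient, Gaussian blur, and
    salt-and-pepper noise are applied in that order.

    Returns an ``H x W x 3`` uint8 image and the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    occupied = np.zeros((h, w), dtype=bool)
    truth = GroundTruth(spec=spec)

    def place(make_masks, label):
        for _ in range(spec.max_attempts):
            core, cleared, record = make_masks()
            if core is None:  # out of frame
                continue
            if not (cleared & occupied).any():
                occupied[:] |= core
                truth.records.append(record)
                return core
        raise PlacementError(
            f"could not place {label} after {spec.max_attempts} attempts"
        )

    margin = 4.0

    for _ in range(spec.n_elongated):
        def make():
            length = rng.uniform(*spec.elongated_length)
            aspect = rng.uniform(*spec.elongated_aspect)
            half_w = length / aspect / 2.0
            phi = rng.uniform(0.0, math.pi)
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            dx, dy = math.cos(phi) * length / 2, math.sin(phi) * length / 2
            p1, p2 = (cx - dx, cy - dy), (cx + dx, cy + dy)
            pad = half_w + margin
            if not all(pad <= p[0] < w - pad and pad <= p[1] < h - pad
                       for p in (p1, p2)):
                return None, None, None
            core = _capsule_mask((h, w), p1, p2, half_w)
            cleared = _capsule_mask((h, w), p1, p2, half_w + spec.clearance)
            rec = CellRecord(kind="elongated", centroid=(cx, cy),
                             endpoints=(p1, p2), radius=half_w)
            return core, cleared, rec
        core = place(make, "elongated cell")
        img[core] = spec.cell_intensity

    for _ in range(spec.n_cobblestone):
        def make():
            diam = rng.uniform(*spec.cobblestone_diameter)
            aspect = rng.uniform(*spec.cobblestone_aspect)
            a, b = diam / 2.0, diam / (2.0 * aspect)
            phi = rng.uniform(0.0, math.pi)
            pad = a + margin
            cx = rng.uniform(pad, w - pad)
            cy = rng.uniform(pad, h - pad)
            core = _ellipse_mask((h, w), (cx, cy), a, b, phi)
            cleared = _ellipse_mask((h, w), (cx, cy),
                                    a + spec.clearance, b + spec.clearance,
                                    phi)
            rec = CellRecord(kind="cobblestone", centroid=(cx, cy), radius=a)
            return core, cleared, rec
        core = place(make, "cobblestone cell")
        img[core] = spec.cell_intensity

    for _ in range(spec.n_floating):
        def make():
            r = rng.uniform(*spec.floating_radius)
            pad = r + margin
            cx = rng.uniform(pad, w - pad)
            cy = rng.uniform(pad, h - pad)
            core = _ellipse_mask((h, w), (cx, cy), r, r, 0.0)
            cleared = _ellipse_mask((h, w), (cx, cy),
                                    r + spec.clearance, r + spec.clearance,
                                    0.0)
            rec = CellRecord(kind="floating", centroid=(cx, cy), radius=r)
            return core, cleared, rec
        core = place(make, "floating cell")
        img[core] = spec.floating_intensity

    # illumination gradient: multiplicative linear ramp across the field
    if spec.illumination_amplitude > 0:
        phi = rng.uniform(0.0, 2 * math.pi)
        ys, xs = np.mgrid[0:h, 0:w]
        proj = xs * math.cos(phi) + ys * math.sin(phi)
        span = proj.max() - proj.min()
        ramp = (proj - proj.min()) / span - 0.5 if span else 0.0
        img = img * (1.0 + spec.illumination_amplitude * ramp)

    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=spec.blur_sigma)

    if spec.salt_pepper_rate > 0:
        noise = rng.random((h, w))
        img[noise < spec.salt_pepper_rate / 2] = 0.0
        img[noise > 1.0 - spec.salt_pepper_rate / 2] = 1.0

    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return np.repeat(img8[:, :, None], 3, axis=2), truth


@dataclass
class RecoveryMetrics:
    """Scores of detected polylines against elongated ground truth."""

    n_detected: int
    n_truth: int
    n_matched: int
    length_errors: list[float]  # per-match relative errors
    matches: list[tuple[int, int]] = field(default_factory=list)
    # accepted (detection index, truth index) pairs

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0

    @property
    def count_error(self) -> float:
        """Signed relative error of the detected count."""
        if not self.n_truth:
            return float("nan")
        return (self.n_detected - self.n_truth) / self.n_truth

    @property
    def mean_length_error(self) -> float:
        return float(np.mean(self.length_errors)) \
            if self.length_errors else float("nan")


def _polyline_angle(cell: PolylineCell) -> float:
    (x1, y1), (x2, y2) = cell.endpoints
    return math.atan2(y2 - y1, x2 - x1) % math.pi


def _angle_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % math.pi
    return math.degrees(min(d, math.pi - d))


def evaluate_recovery(
    cells: list[PolylineCell],
    truth: GroundTruth,
    match_dist: float = 15.0,
    match_angle: float = 20.0,
) -> RecoveryMetrics:
    """Greedy one-to-one matching of detections to true centerlines.

    A detection is eligible to match a true elongated cell when their
    midpoints lie within ``match_dist`` pixels and their undirected
    directions within ``match_angle`` degrees; eligible pairs are
    accepted in order of increasing midpoint distance.  Per-match
    relative length error compares the polyline's total length with the
    true centerline length.
    """
    targets = truth.of_kind("elongated")
    pairs = []
    for i, cell in enumerate(cells):
        mx, my = cell.midpoint
        ca = _polyline_angle(cell)
        for j, rec in enumerate(targets):
            (x1, y1), (x2, y2) = rec.endpoints
            tx, ty = (x1 + x2) / 2, (y1 + y2) / 2
            d = math.hypot(mx - tx, my - ty)
            if d <= match_dist and _angle_diff_deg(ca, rec.angle) <= match_angle:
                pairs.append((d, i, j))
    pairs.sort()
    used_det, used_truth = set(), set()
    matches: list[tuple[int, int]] = []
    errors = []
    for d, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        matches.append((i, j))
        true_len = targets[j].length
        errors.append(abs(cells[i].total_length - true_len) / true_len)
    return RecoveryMetrics(
        n_detected=len(cells),
        n_truth=len(targets),
        n_matched=len(matches),
        length_errors=errors,
        matches=matches,
    )
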