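"""Annotated overlays: each cell's piecewise line in green, with its
start point marked red and end point yellow."""

from __future__ import annotations

import numpy as np
from skimage.draw import disk, line

from .postprocess import PolylineCell

GREEN = (0, 255, 0)
RED = (255, 0, 0)
YELLOW = (255, 255, 0)
_MARKER_RADIUS = 2  # px


def render_overlay(img: np.ndarray,
                   cells: list[PolylineCell]) -> np.ndarray:
    """Draw detected cells onto a copy of the input image.

    Each member segment is drawn in green; the polyline's start point
    (the terminal with the smaller (y, x)) gets a red marker and its
    end point a yellow one, so exactly one red and one yellow marker
    appear per cell.  With no cells the input is returned unchanged
    (as a copy).
    """
    out = np.asarray(img).copy()
    if out.ndim == 2:
        out = np.repeat(out[:, :, None], 3, axis=2)
    h, w = out.shape[:2]

    def clip_rc(rr, cc):
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        return rr[keep], cc[keep]

    for cell in cells:
        for seg in cell.segments:
            rr, cc = line(int(round(seg.start[1])), int(round(seg.start[0])),
                          int(round(seg.end[1])), int(round(seg.end[0])))
            rr, cc = clip_rc(rr, cc)
            out[rr, cc] = GREEN
    for cell in cells:  # markers drawn last so lines cannot cover them
        start, end = cell.endpoints
        for point, color in ((start, RED), (end, YELLOW)):
            rr, cc = disk((point[1], point[0]), _MARKER_RADIUS,
                          shape=(h, w))
            out[rr, cc] = color
    return out
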