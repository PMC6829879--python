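import math

import numpy as np
import pytest

from cellhough import LineSegment


def make_segment(x1, y1, x2, y2) -> LineSegment:
    """Build a LineSegment with consistent Hough parameters.

    theta is the normal direction of the carrying line in [0, pi);
    rho follows rho = x*cos(theta) + y*sin(theta).
    """
    theta = (math.atan2(y2 - y1, x2 - x1) + math.pi / 2.0) % math.pi
    rho = x1 * math.cos(theta) + y1 * math.sin(theta)
    return LineSegment(start=(float(x1), float(y1)),
                       end=(float(x2), float(y2)), theta=theta, rho=rho)


def draw_run(shape, x0, y0, x1, y1):
    """Binary image with a rasterized straight run of edge pixels."""
    from skimage.draw import line

    img = np.zeros(shape, dtype=bool)
    rr, cc = line(int(y0), int(x0), int(y1), int(x1))
    img[rr, cc] = True
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
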