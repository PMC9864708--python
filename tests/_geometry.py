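"""Small geometric helpers shared across test modules."""

import numpy as np


def octagon_square(side: float, center=(0.0, 0.0)) -> np.ndarray:
    """Axis-aligned square with edge midpoints (8 vertices)."""
    h = side / 2.0
    cx, cy = center
    pts = [(-h, -h), (0, -h), (h, -h), (h, 0), (h, h), (0, h), (-h, h), (-h, 0)]
    return np.array([(cx + x, cy + y) for x, y in pts])


def circle(r: float, n: int = 120, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)], axis=1)
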