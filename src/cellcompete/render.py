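"""Deterministic PNG rendering of lattice snapshots.

Colouring follows the convention used throughout the figures this simulator
produces: hue encodes cell type (purple for the type-A mutants, green for
the type-B wild type), lineage is shown by cycling each type through four
shades with generation, and medium is white. Identical states render to
byte-identical images.
"""

from __future__ import annotations

import numpy as np

from .engine import CellRegistry, LatticeState
from .params import MEDIUM, TYPE_A, TYPE_B

# four generation shades per type (generation mod 4)
_SHADES_A = np.array([[106, 27, 154], [142, 36, 170],
                      [171, 71, 188], [206, 147, 216]], dtype=np.uint8)
_SHADES_B = np.array([[27, 94, 32], [56, 142, 60],
                      [102, 187, 106], [165, 214, 167]], dtype=np.uint8)
_MEDIUM_RGB = np.array([255, 255, 255], dtype=np.uint8)


def snapshot_array(state: LatticeState, registry: CellRegistry) -> np.ndarray:
    """RGB uint8 image of the lattice, one pixel per site."""
    n = registry.next_id
    lut = np.tile(_MEDIUM_RGB, (n, 1))
    ids = np.arange(n)
    gen = registry.generation[:n] % 4
    for code, shades in ((TYPE_A, _SHADES_A), (TYPE_B, _SHADES_B)):
        m = (registry.type_code[:n] == code) & registry.alive[:n] & (ids > 0)
        lut[m] = shades[gen[m]]
    return lut[state.grid]


def render_snapshot(state: LatticeState, registry: CellRegistry,
                    path: str) -> np.ndarray:
    """Write the snapshot as an 8-bit PNG; returns the pixel array."""
    import imageio.v3 as iio

    img = snapshot_array(state, registry)
    iio.imwrite(path, img, extension=".png")
    return img
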