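"""Nominal layout and colors of the 24-patch color calibration card.

The card emulated here follows the classic 24-patch ColorChecker layout:
a dark frame enclosing a 6 x 4 grid of matte patches whose sRGB values are
published by the manufacturer.  The physical width of the card is known, which
is what turns pixels into millimetres during calibration.
"""

from __future__ import annotations

import numpy as np

# Classic 24-patch nominal sRGB values (8-bit), row-major: 4 rows x 6 columns.
# Row 1: natural tones, row 2: misc, row 3: primaries, row 4: grayscale.
PATCH_SRGB = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67], [133, 128, 177], [103, 189, 170],
        [214, 126, 44], [80, 91, 166], [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31], [187, 86, 149], [8, 133, 161],
        [243, 243, 242], [200, 200, 200], [160, 160, 160], [122, 122, 121], [85, 85, 85], [52, 52, 52],
    ],
    dtype=np.uint8,
)

N_PATCHES = 24
GRID_COLS = 6
GRID_ROWS = 4

# Physical dimensions (mm) of the mini card, frame included.
CARD_WIDTH_MM = 109.0
CARD_HEIGHT_MM = 63.5
FRAME_MM = 4.0          # dark frame thickness around the patch grid
PATCH_GAP_MM = 2.0      # dark gap between adjacent patches
FRAME_RGB = (35, 33, 32)


def patch_centers_and_size(width_px: float, height_px: float):
    """Patch center coordinates and patch size for a card of given pixel size.

    Returns (centers, (patch_w, patch_h)) where ``centers`` is a (24, 2) array
    of (x, y) offsets from the card's top-left corner, row-major to match
    :data:`PATCH_SRGB`.
    """
    sx = width_px / CARD_WIDTH_MM
    sy = height_px / CARD_HEIGHT_MM
    frame_x, frame_y = FRAME_MM * sx, FRAME_MM * sy
    gap_x, gap_y = PATCH_GAP_MM * sx, PATCH_GAP_MM * sy
    inner_w = width_px - 2 * frame_x
    inner_h = height_px - 2 * frame_y
    patch_w = (inner_w - (GRID_COLS - 1) * gap_x) / GRID_COLS
    patch_h = (inner_h - (GRID_ROWS - 1) * gap_y) / GRID_ROWS
    centers = np.empty((N_PATCHES, 2), dtype=float)
    for r in range(GRID_ROWS):
        for c in range(GRID_COLS):
            x = frame_x + c * (patch_w + gap_x) + patch_w / 2
            y = frame_y + r * (patch_h + gap_y) + patch_h / 2
            centers[r * GRID_COLS + c] = (x, y)
    return centers, (patch_w, patch_h)
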