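"""Field matrices -> RGB images -> concatenated network inputs.

Each field matrix is rendered through a fixed rainbow colormap (blue = low,
red = high, scaled by the encoder's theoretical range so colours are
comparable across instances).  The per-channel colour images of one instance
are then split into their R/G/B planes and like-coloured planes are stacked
vertically, giving a single 3 x (n*m) x n tensor for an m-channel instance —
the network keeps three input channels no matter how many sensors there are.

Images are plain ``float`` arrays of shape (3, height, width) with values in
[0, 1], channel order R, G, B.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .encoding import FieldMatrix
from .errors import FormatError, InvalidArgumentError, InvalidInputError

__all__ = ["colormap_rainbow", "concat_rgb", "write_png", "read_png"]

# Five-anchor piecewise-linear rainbow: u=0 -> blue, 0.25 -> cyan,
# 0.5 -> green, 0.75 -> yellow, 1 -> red.  Extremes are pure blue/red.
_ANCHOR_U = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_ANCHOR_RGB = np.array(
    [
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [0.0, 1.0, 0.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 0.0],
    ]
)

_RANGE_TOL = 1e-9


def colormap_rainbow(matrix: FieldMatrix) -> np.ndarray:
    """Map a field matrix to a (3, n, n) RGB image via the rainbow colormap.

    Entries are first normalised by the matrix's *theoretical* range
    ((-1, 1) for GASF/GADF, (0, 1) for MTF), then passed through the
    five-anchor piecewise-linear rainbow.  Larger values are redder, smaller
    values bluer.
    """
    lo, hi = matrix.theoretical_range
    v = np.asarray(matrix.values, dtype=float)
    if v.min() < lo - _RANGE_TOL or v.max() > hi + _RANGE_TOL:
        raise InvalidInputError(
            f"{matrix.method} entries outside theoretical range [{lo}, {hi}]: "
            f"observed [{v.min()}, {v.max()}]"
        )
    u = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return np.stack(
        [np.interp(u, _ANCHOR_U, _ANCHOR_RGB[:, c]) for c in range(3)]
    )


def concat_rgb(
    images: Sequence[np.ndarray], order: Sequence[int] | None = None
) -> np.ndarray:
    """Channel-split concatenation of m per-sensor RGB images.

    For each colour plane c in R, G, B, the output plane is the vertical
    stack of plane c of ``images[order[0]]``, ..., ``images[order[m-1]]``.
    The result has shape (3, n*m, n): three colour channels regardless of the
    number of sensors, height n*m, width n.

    ``order`` is a 0-based permutation of ``range(m)``; ``None`` means the
    natural order.  Permuting it permutes the n-row blocks of every colour
    plane identically (the "spurious edge" pattern under study).
    """
    if len(images) == 0:
        raise InvalidInputError("need at least one image to concatenate")
    arrs = [np.asarray(im, dtype=float) for im in images]
    shape = arrs[0].shape
    if len(shape) != 3 or shape[0] != 3 or shape[1] != shape[2]:
        raise InvalidInputError(f"expected (3, n, n) images, got {shape}")
    for a in arrs[1:]:
        if a.shape != shape:
            raise InvalidInputError(
                f"all images must share one shape; got {a.shape} vs {shape}"
            )
    m = len(arrs)
    if order is None:
        order = range(m)
    order = [int(i) for i in order]
    if sorted(order) != list(range(m)):
        raise InvalidArgumentError(
            f"order must be a permutation of 0..{m - 1}, got {order}"
        )
    return np.concatenate([arrs[i] for i in order], axis=1)


def write_png(image: np.ndarray, path) -> None:
    """Write a (3, h, w) image with values in [0, 1] as an 8-bit RGB PNG.

    Pixel bytes are ``round(v * 255)``; a write/read round-trip reproduces
    the quantised bytes exactly.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise InvalidInputError(f"expected a (3, h, w) image, got {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidInputError("image values must lie in [0, 1]")
    bytes_ = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(bytes_.transpose(1, 2, 0), mode="RGB").save(path, format="PNG")


def read_png(path) -> np.ndarray:
    """Read an 8-bit RGB PNG back to a (3, h, w) float image in [0, 1]."""
    try:
        with Image.open(path) as img:
            if img.mode != "RGB":
                raise FormatError(
                    f"expected an 8-bit RGB PNG, got mode {img.mode!r}"
                )
            arr = np.asarray(img, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise FormatError(f"not a readable image file: {path}") from exc
    return arr.transpose(2, 0, 1).astype(float) / 255.0
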