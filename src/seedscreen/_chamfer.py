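"""Two-pass 3-4 chamfer distance transform (numba kernel).

The classic integer chamfer metric assigns 3 to edge steps and 4 to diagonal
steps; dividing by 3 yields an approximation of the Euclidean distance to the
nearest background pixel that is exact on axis-aligned paths and within ~6%
on diagonals.  Two raster passes (forward then backward) suffice for a 3x3
neighbourhood mask.
"""

from __future__ import annotations

import numba
import numpy as np

_INF = np.int32(1 << 28)


@numba.njit(cache=True)
def chamfer_3_4(fg):  # pragma: no cover - exercised through chamfer_distance
    H, W = fg.shape
    d = np.empty((H, W), np.int32)
    for i in range(H):
        for j in range(W):
            d[i, j] = _INF if fg[i, j] else 0
    # forward raster pass: upper-left half of the neighbourhood
    for i in range(H):
        for j in range(W):
            v = d[i, j]
            if v == 0:
                continue
            if j > 0 and d[i, j - 1] + 3 < v:
                v = d[i, j - 1] + 3
            if i > 0:
                if d[i - 1, j] + 3 < v:
                    v = d[i - 1, j] + 3
                if j > 0 and d[i - 1, j - 1] + 4 < v:
                    v = d[i - 1, j - 1] + 4
                if j < W - 1 and d[i - 1, j + 1] + 4 < v:
                    v = d[i - 1, j + 1] + 4
            d[i, j] = v
    # backward raster pass: lower-right half
    for i in range(H - 1, -1, -1):
        for j in range(W - 1, -1, -1):
            v = d[i, j]
            if v == 0:
                continue
            if j < W - 1 and d[i, j + 1] + 3 < v:
                v = d[i, j + 1] + 3
            if i < H - 1:
                if d[i + 1, j] + 3 < v:
                    v = d[i + 1, j] + 3
                if j < W - 1 and d[i + 1, j + 1] + 4 < v:
                    v = d[i + 1, j + 1] + 4
                if j > 0 and d[i + 1, j - 1] + 4 < v:
                    v = d[i + 1, j - 1] + 4
            d[i, j] = v
    return d
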