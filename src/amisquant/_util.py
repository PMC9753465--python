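"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def partition_indices(n: int, k: int) -> list[slice]:
    """Partition ``range(n)`` into ``k`` contiguous, near-equal slices.

    When ``k`` does not divide ``n`` the remainder is given to the
    *earliest* slices, so the partition is deterministic and
    order-independent.  Requires ``n >= k >= 1``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k:
        raise ValueError(f"cannot partition {n} items into {k} non-empty slices")
    base, rem = divmod(n, k)
    slices = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        slices.append(slice(start, start + size))
        start += size
    return slices


def perpendicular_offsets(width_um: float, pixel_size_um: float) -> np.ndarray:
    """Offsets (μm) of the perpendicular sub-samples of a width-averaged
    line-scan.

    The sub-sample count is ``ceil(width/pixel_size)`` forced odd, so one
    sub-sample always sits on the path itself; spacing equals the pixel
    size.  A 0.8 μm band at 0.2 μm pixels therefore yields 5 sub-samples
    at -0.4, -0.2, 0, 0.2, 0.4 μm.
    """
    if width_um <= 0:
        raise ValueError("width_um must be > 0")
    n = int(np.ceil(width_um / pixel_size_um))
    if n % 2 == 0:
        n += 1
    half = (n - 1) / 2.0
    return (np.arange(n) - half) * pixel_size_um
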