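from __future__ import annotations

import numpy as np
import pytest

from contourqc import LabelMask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def box_mask(shape=(10, 12, 30), spacing=(1.0, 1.0, 1.0), pad=0) -> LabelMask:
    """A solid axis-aligned box, optionally surrounded by `pad` empty voxels."""
    full = tuple(s + 2 * pad for s in shape)
    vox = np.zeros(full, dtype=np.uint8)
    vox[pad:pad + shape[0], pad:pad + shape[1], pad:pad + shape[2]] = 1
    return LabelMask(vox, spacing=spacing)


def cylinder_mask(radius=8, n_slices=100, x_shifts=None, margin=6) -> LabelMask:
    """A z-aligned cylinder with optional per-slice integer x shifts."""
    if x_shifts is None:
        x_shifts = np.zeros(n_slices, dtype=int)
    half = int(radius + max(abs(int(s)) for s in x_shifts) + margin)
    size = 2 * half + 1
    X, Y = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    vox = np.zeros((size, size, n_slices), dtype=np.uint8)
    for k in range(n_slices):
        cx = half + int(x_shifts[k])
        vox[:, :, k] = (X - cx) ** 2 + (Y - half) ** 2 <= radius**2
    return LabelMask(vox)
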