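"""Small shared numerics: integer/subpixel volume translation, seeding."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import ndimage

from ._errors import ParameterError


def translate_volume(
    volume: np.ndarray,
    shift_zyx: tuple[float, float, float],
    fill: float = 0.0,
) -> np.ndarray:
    """Translate a 3D volume by ``shift_zyx`` voxels, filling exposed voxels.

    Integer shifts are applied by slicing (bit-exact, no interpolation);
    fractional shifts use first-order spline interpolation.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ParameterError(f"expected a 3D volume, got ndim={volume.ndim}")
    shift = np.asarray(shift_zyx, dtype=float)
    if shift.shape != (3,):
        raise ParameterError("shift must have exactly three components (dz, dy, dx)")
    if not np.all(np.isfinite(shift)):
        raise ParameterError("shift components must be finite")
    if np.any(np.abs(shift) >= np.asarray(volume.shape)):
        raise ParameterError(
            f"shift {tuple(shift)} meets or exceeds the frame extent {volume.shape}"
        )
    if np.allclose(shift, np.round(shift)):
        out = np.full_like(volume, fill)
        src = []
        dst = []
        for ax, s in enumerate(np.round(shift).astype(int)):
            n = volume.shape[ax]
            if s >= 0:
                src.append(slice(0, n - s))
                dst.append(slice(s, n))
            else:
                src.append(slice(-s, n))
                dst.append(slice(0, n + s))
        out[tuple(dst)] = volume[tuple(src)]
        return out
    return ndimage.shift(
        volume.astype(float), shift, order=1, mode="constant", cval=fill
    )


def stable_cell_seed(base_seed: int, cell_id: str) -> np.random.SeedSequence:
    """Seed sequence derived reproducibly from a cell identifier.

    Uses CRC32 of the id rather than Python's ``hash`` so ranking tie-breaks
    survive interpreter restarts.
    """
    return np.random.SeedSequence([int(base_seed), zlib.crc32(cell_id.encode())])
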