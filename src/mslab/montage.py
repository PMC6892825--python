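"""Standard 10-20 scalp montage for the 19-channel clinical layout.

Electrode positions come from the template 10-20 montage shipped with MNE,
re-centred and projected onto the unit sphere. A spherical montage is all the
downstream stages need: spherical-spline interpolation and the synthetic
topography generator both operate on unit direction vectors.
"""

from __future__ import annotations

import warnings

import numpy as np

#: The 19 channels of the classic clinical 10-20 layout, in recording order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

_cache: dict[tuple[str, ...], np.ndarray] = {}


def standard_1020_positions(channels: tuple[str, ...] = CHANNELS_1020) -> np.ndarray:
    """Unit-sphere electrode positions for `channels`.

    Returns an (n_channels, 3) array of unit vectors in head coordinates
    (+x right, +y anterior, +z up).
    """
    key = tuple(channels)
    if key not in _cache:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            mont = mne.channels.make_standard_montage("standard_1020")
        ch_pos = mont.get_positions()["ch_pos"]
        missing = [ch for ch in key if ch not in ch_pos]
        if missing:
            raise ValueError(f"channels not in the 10-20 template: {missing}")
        pos = np.array([ch_pos[ch] for ch in key], dtype=float)
        pos = pos - pos.mean(axis=0)
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        _cache[key] = pos
    return _cache[key].copy()


def validate_montage(pos: np.ndarray, min_sep: float = 1e-6) -> np.ndarray:
    """Check an electrode position array and return it unit-normalised.

    Raises ValueError on coincident electrodes or zero-length positions.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("montage must be an (n_channels, 3) array")
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms < min_sep):
        raise ValueError("montage contains zero-length position vectors")
    unit = pos / norms[:, None]
    # pairwise chordal distances on the sphere
    d = np.linalg.norm(unit[:, None, :] - unit[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < min_sep:
        raise ValueError("montage contains coincident electrodes")
    return unit
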