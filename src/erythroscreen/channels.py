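"""Canonical cytometry channel set and intensity transforms.

All simulation and gating in this package happens on a transformed
(asinh-like) intensity scale, except the DNA (7-AAD) channel which is
kept linear so that 2N/4N content gating at a multiple of the 2N modal
signal behaves the way it does on a real cytometer.
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order for event tables.
CHANNELS: tuple[str, ...] = (
    "FSC",
    "SSC",
    "Hoechst",
    "Ter119",
    "CD44",
    "PI",
    "BrdU",
    "DNA",
)

#: Channels modelled on the transformed (asinh) scale; DNA stays linear.
TRANSFORMED_CHANNELS: frozenset[str] = frozenset(CHANNELS) - {"DNA"}

#: Column layout of an event CSV. ``truth_label`` may be blank for real data.
EVENT_COLUMNS: tuple[str, ...] = ("event_id",) + CHANNELS + ("truth_label",)


def asinh_transform(x: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """Standard cytometry asinh transform, ``asinh(x / cofactor)``.

    Linear near zero, logarithmic for large intensities; the cofactor sets
    the crossover scale.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def identity_transform(x: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """No-op transform for data already on the analysis scale."""
    return np.asarray(x, dtype=float)


TRANSFORMS = {"identity": identity_transform, "asinh": asinh_transform}
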