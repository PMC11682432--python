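"""Acquisition protocols for multi-b-value, dual-echo-time DWI.

A protocol records the b-value schedule (with the number of replicate
samples acquired at each b), the two echo times, and the voxel grid the
volumes live on.  Two presets reproduce the clinical protocols the
package is modeled on: a 5-b-value scheme at TE 80/100 ms and a second
scheme at TE 76/90 ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "COHORT1_PROTOCOL",
    "COHORT2_PROTOCOL",
    "get_protocol",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """A multi-b-value DWI protocol acquired at two echo times.

    Parameters
    ----------
    name:
        Short identifier (``"cohort1"``, ``"cohort2"``, or user-defined).
    b_values:
        Tuple of ``(b, n_samples)`` pairs, b in s/mm^2.  Replicate samples
        at the same b are acquired (and later averaged) to boost SNR.
    te_pair:
        The two echo times in ms, ``(te_short, te_long)``.
    grid_shape:
        3-D voxel grid of the reconstructed volumes.
    voxel_size:
        Voxel dimensions in mm.
    """

    name: str
    b_values: tuple[tuple[float, int], ...]
    te_pair: tuple[float, float]
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (1.7, 1.7, 3.0)

    def __post_init__(self) -> None:
        if len(self.b_values) == 0:
            raise ValueError("b_values must be non-empty")
        bs = [b for b, _ in self.b_values]
        counts = [c for _, c in self.b_values]
        if any(b < 0 for b in bs):
            raise ValueError("all b-values must be >= 0")
        if 0.0 not in [float(b) for b in bs]:
            raise ValueError("the schedule must contain b = 0")
        if any(c < 1 or int(c) != c for c in counts):
            raise ValueError("every b-value needs >= 1 sample")
        if len(set(bs)) != len(bs):
            raise ValueError("duplicate b-value entries in schedule")
        if sorted(bs) != bs:
            object.__setattr__(
                self,
                "b_values",
                tuple(sorted(self.b_values, key=lambda bc: bc[0])),
            )
        te1, te2 = self.te_pair
        if not (0 < te1 < te2):
            raise ValueError("te_pair must satisfy 0 < te_short < te_long")
        if len(self.grid_shape) != 3 or any(int(d) <= 0 for d in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")

    @property
    def te_short(self) -> float:
        return self.te_pair[0]

    @property
    def te_long(self) -> float:
        return self.te_pair[1]

    @property
    def unique_b(self) -> np.ndarray:
        """Distinct b-values, ascending."""
        return np.array([b for b, _ in self.b_values], dtype=float)

    @property
    def sample_b(self) -> np.ndarray:
        """Per-frame b-value for the full 4-D acquisition (replicates expanded)."""
        return np.repeat(self.unique_b, [c for _, c in self.b_values])

    @property
    def n_frames(self) -> int:
        return int(sum(c for _, c in self.b_values))

    def with_grid(
        self,
        grid_shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float] | None = None,
    ) -> "AcquisitionProtocol":
        """Return a copy of the protocol on a different voxel grid."""
        kwargs: dict = {"grid_shape": tuple(int(d) for d in grid_shape)}
        if voxel_size is not None:
            kwargs["voxel_size"] = tuple(float(v) for v in voxel_size)
        return dataclasses.replace(self, **kwargs)


COHORT1_PROTOCOL = AcquisitionProtocol(
    name="cohort1",
    b_values=((0.0, 7), (200.0, 6), (1000.0, 6), (2000.0, 6), (3000.0, 6)),
    te_pair=(80.0, 100.0),
)

COHORT2_PROTOCOL = AcquisitionProtocol(
    name="cohort2",
    b_values=((0.0, 2), (50.0, 6), (800.0, 6), (1500.0, 12), (3000.0, 18)),
    te_pair=(76.0, 90.0),
)

_PRESETS = {"cohort1": COHORT1_PROTOCOL, "cohort2": COHORT2_PROTOCOL}


def get_protocol(name: str) -> AcquisitionProtocol:
    """Look up a bundled protocol preset by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
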