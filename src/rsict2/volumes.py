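"""In-memory containers for DWI studies and derived voxel maps.

All volumes are plain numpy arrays on a shared 3-D grid.  Voxels outside
the analysis mask carry NaN (never 0), so that medians and maxima taken
downstream are not contaminated by out-of-mask values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import AcquisitionProtocol

__all__ = ["DWIStudy", "CompartmentMaps", "T2Maps", "RsirsMap", "PatientMaps"]

N_COMPARTMENTS = 4


@dataclass
class DWIStudy:
    """A patient's pair of 4-D multi-b-value DWI volumes, one per TE.

    ``volumes`` maps TE (ms) to an array of shape ``grid_shape + (n_frames,)``
    holding every replicate sample in ascending-b order.  ``masks`` holds
    binary volumes on the same grid; ``"prostate"`` is required for masked
    fitting, ``"pz"``/``"tz"`` are anatomical zones and ``"lesion"`` is the
    union of lesion contours (absent for patients without lesions).
    """

    protocol: AcquisitionProtocol
    volumes: dict[float, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        grid = tuple(self.protocol.grid_shape)
        for te, vol in self.volumes.items():
            if vol.shape != grid + (self.protocol.n_frames,):
                raise ValueError(
                    f"volume at TE={te} has shape {vol.shape}, expected "
                    f"{grid + (self.protocol.n_frames,)}"
                )
        for name, m in self.masks.items():
            if m.shape != grid:
                raise ValueError(f"mask {name!r} is not on the acquisition grid")

    @property
    def te_values(self) -> list[float]:
        return sorted(self.volumes)

    def mask(self, name: str) -> np.ndarray | None:
        m = self.masks.get(name)
        return None if m is None else m.astype(bool)

    def b0_volume(self, te: float) -> np.ndarray:
        """Replicate-averaged b = 0 frame of the acquisition at ``te``."""
        vol = self.volumes[te]
        n0 = int(self.protocol.b_values[0][1])
        return vol[..., :n0].mean(axis=-1)


@dataclass
class CompartmentMaps:
    """Per-voxel compartment signal contributions C1..C4 for one TE.

    ``c`` has shape ``grid + (4,)``; out-of-mask voxels are NaN.
    ``residual`` is the per-voxel RMS misfit of the signal-vs-b curve.
    """

    c: np.ndarray
    te: float
    residual: np.ndarray
    b_values: np.ndarray

    def __post_init__(self) -> None:
        if self.c.shape[-1] != N_COMPARTMENTS:
            raise ValueError("expected four compartments on the last axis")
        if self.residual.shape != self.c.shape[:-1]:
            raise ValueError("residual grid does not match compartment maps")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.c.shape[:-1]

    def compartment(self, i: int) -> np.ndarray:
        """1-based accessor: ``compartment(1)`` is the restricted compartment C1."""
        if not 1 <= i <= N_COMPARTMENTS:
            raise IndexError("compartment index must be 1..4")
        return self.c[..., i - 1]


@dataclass
class T2Maps:
    """Per-voxel compartmental T2 (ms) with validity flags.

    ``t2`` has shape ``grid + (4,)``.  A voxel/compartment is valid when the
    two-TE decay was physical and the estimate fell inside the censoring
    window; invalid entries are NaN.
    """

    t2: np.ndarray
    valid: np.ndarray
    te_pair: tuple[float, float]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.t2.shape != self.valid.shape or self.t2.shape[-1] != N_COMPARTMENTS:
            raise ValueError("t2/valid must share a grid with four compartments")

    def compartment(self, i: int) -> np.ndarray:
        if not 1 <= i <= N_COMPARTMENTS:
            raise IndexError("compartment index must be 1..4")
        return self.t2[..., i - 1]


@dataclass
class RsirsMap:
    """Dimensionless RSI restriction score map.

    RSIrs = C1 / median in-prostate b=0 signal; the denominator is stored
    as ``reference_value`` for provenance.
    """

    rsirs: np.ndarray
    reference_value: float
    reference_te: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.reference_value) or self.reference_value <= 0:
            raise ValueError("reference_value must be finite and > 0")


@dataclass
class PatientMaps:
    """Everything the statistics and classifier stages need for one patient:
    fitted compartment maps per TE, the T2 maps, the RSIrs map, and masks."""

    patient_id: str
    label: bool
    grade_group: int
    masks: dict[str, np.ndarray]
    compartments: dict[float, "CompartmentMaps"]
    t2: "T2Maps"
    rsirs: "RsirsMap"

    @property
    def reference_c1(self) -> np.ndarray:
        """C1 map of the acquisition the RSIrs denominator came from."""
        return self.compartments[self.rsirs.reference_te].compartment(1)

    def mask(self, name: str) -> np.ndarray | None:
        m = self.masks.get(name)
        return None if m is None else m.astype(bool)
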