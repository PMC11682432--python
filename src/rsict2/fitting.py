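"""Per-voxel fitting of the four-compartment diffusion signal model.

The measured signal at each b-value is modeled as a non-negative linear
combination of exponential decays

    S(b) = sum_i C_i * exp(-b * D_i),   i = 1..4

with the apparent diffusion coefficients D_i fixed to values representing
restricted diffusion, hindered diffusion, free diffusion, and vascular
flow.  The per-voxel contributions C_i are obtained by non-negative least
squares (NNLS) against the replicate-averaged signal-vs-b curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .protocols import AcquisitionProtocol
from .volumes import CompartmentMaps, DWIStudy, N_COMPARTMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DIFFUSIVITIES",
    "CompartmentModel",
    "average_b_samples",
    "fit_compartments",
    "fit_volume",
]

#: Fixed apparent diffusion coefficients (mm^2/s): restricted, hindered,
#: free, and vascular-flow compartments.
DEFAULT_DIFFUSIVITIES: tuple[float, ...] = (1.1e-4, 1.8e-3, 3.6e-3, 0.1220)


@dataclass(frozen=True)
class CompartmentModel:
    """The fixed-ADC compartment basis used for signal decomposition."""

    diffusion_coeffs: tuple[float, ...] = DEFAULT_DIFFUSIVITIES

    def __post_init__(self) -> None:
        d = np.asarray(self.diffusion_coeffs, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("need at least two diffusion coefficients")
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("diffusion coefficients must be finite and > 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diffusion coefficients must be strictly increasing")

    @property
    def n_compartments(self) -> int:
        return len(self.diffusion_coeffs)

    def design_matrix(self, b_values: np.ndarray) -> np.ndarray:
        """Exponential-decay basis evaluated at ``b_values``; shape (n_b, n_comp)."""
        b = np.asarray(b_values, dtype=float)
        if b.ndim != 1 or np.any(b < 0) or np.any(~np.isfinite(b)):
            raise ValueError("b_values must be a 1-D array of finite values >= 0")
        d = np.asarray(self.diffusion_coeffs, dtype=float)
        return np.exp(-np.outer(b, d))


def average_b_samples(
    volume_4d: np.ndarray, protocol: AcquisitionProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Average replicate samples at each b-value.

    Parameters
    ----------
    volume_4d:
        Array whose last axis enumerates every acquired sample in
        ascending-b order (replicates contiguous), as stored in
        :class:`~rsict2.volumes.DWIStudy`.
    protocol:
        The schedule describing how many samples each b-value has.

    Returns
    -------
    (unique_b, averaged):
        ``unique_b`` ascending, and a volume with one frame per unique b
        equal to the arithmetic mean of that b's replicates.
    """
    vol = np.asarray(volume_4d, dtype=float)
    counts = [int(c) for _, c in protocol.b_values]
    if vol.shape[-1] != sum(counts):
        raise ValueError(
            f"volume has {vol.shape[-1]} frames but the schedule expects "
            f"{sum(counts)}"
        )
    frames = []
    start = 0
    for c in counts:
        frames.append(vol[..., start : start + c].mean(axis=-1))
        start += c
    return protocol.unique_b, np.stack(frames, axis=-1)


def fit_compartments(
    signal_per_b: np.ndarray,
    b_values: np.ndarray,
    model: CompartmentModel | None = None,
) -> tuple[np.ndarray, float]:
    """NNLS decomposition of one voxel's signal-vs-b curve.

    Returns ``(coeffs, rms_residual)`` where ``coeffs`` are the
    non-negative contributions C1..C4 minimizing
    ``sum_b (S(b) - sum_i C_i exp(-b D_i))**2``.
    """
    model = model or CompartmentModel()
    s = np.asarray(signal_per_b, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signal and b_values must be matching 1-D arrays")
    if np.any(~np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    if len(np.unique(b)) < model.n_compartments:
        raise ValueError(
            f"need >= {model.n_compartments} distinct b-values, got {len(np.unique(b))}"
        )
    if np.all(s == 0):
        return np.zeros(model.n_compartments), 0.0
    design = model.design_matrix(b)
    coeffs, rnorm = scipy.optimize.nnls(design, s)
    return coeffs, float(rnorm / np.sqrt(len(b)))


def _fit_signals_2d(signals: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NNLS for many voxels sharing one design matrix.

    The unconstrained least-squares solution is computed for all voxels in
    one batched solve; by the KKT conditions it equals the NNLS solution
    wherever it is already non-negative.  Only voxels whose unconstrained
    solution goes negative fall back to per-voxel NNLS.
    """
    pinv = np.linalg.pinv(design)
    coeffs = signals @ pinv.T
    neg = np.any(coeffs < -1e-12, axis=1)
    for idx in np.flatnonzero(neg):
        coeffs[idx], _ = scipy.optimize.nnls(design, signals[idx])
    coeffs[coeffs < 0] = 0.0
    resid = signals - coeffs @ design.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return coeffs, rms


def fit_volume(
    study: DWIStudy,
    model: CompartmentModel | None = None,
    mask_name: str = "prostate",
) -> dict[float, CompartmentMaps]:
    """Fit the compartment model to both TE volumes of a study.

    Replicate samples are averaged per b-value first, then every in-mask
    voxel is decomposed independently (the result does not depend on voxel
    order).  Out-of-mask voxels are set to NaN.  If the named mask is
    missing, the whole grid is fitted and a warning is logged.
    """
    model = model or CompartmentModel()
    mask = study.mask(mask_name)
    grid = tuple(study.protocol.grid_shape)
    if mask is None:
        logger.warning(
            "study %s has no %r mask; fitting the full grid",
            study.patient_id,
            mask_name,
        )
        mask = np.ones(grid, dtype=bool)

    out: dict[float, CompartmentMaps] = {}
    for te in study.te_values:
        unique_b, averaged = average_b_samples(study.volumes[te], study.protocol)
        design = model.design_matrix(unique_b)
        signals = averaged[mask]  # (n_vox, n_b)
        coeffs, rms = _fit_signals_2d(signals, design)
        c = np.full(grid + (model.n_compartments,), np.nan)
        residual = np.full(grid, np.nan)
        c[mask] = coeffs
        residual[mask] = rms
        out[te] = CompartmentMaps(c=c, te=te, residual=residual, b_values=unique_b)
    return out
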