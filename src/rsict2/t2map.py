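"""Compartmental T2 mapping from two echo times, and the RSIrs biomarker.

Each compartment's signal contribution decays monoexponentially with TE,
C_i(TE) = A_i * exp(-TE / T2_i).  With exactly two echo times the
least-squares monoexponential fit has the closed form

    T2 = (te2 - te1) / ln(C_i(te1) / C_i(te2))

which is what this module evaluates voxelwise.  Non-physical estimates
(non-decaying pairs, near-zero contributions, values outside a censoring
window) are flagged invalid and carried as NaN rather than clamped, so
that medians over valid voxels stay unbiased by arbitrary caps.

RSIrs divides the restricted-compartment contribution C1 by the median
b = 0 signal within the whole prostate, removing global scanner scaling
and providing an index of apparent T2-weighting in the prostate.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .volumes import CompartmentMaps, DWIStudy, RsirsMap, T2Maps, N_COMPARTMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_T2_WINDOW",
    "compartmental_t2",
    "t2_volume",
    "rsirs_map",
    "rsirs_from_study",
    "median_summary",
]

#: Censoring window (ms) outside which a two-point T2 estimate is discarded.
DEFAULT_T2_WINDOW: tuple[float, float] = (1.0, 2000.0)

_EPS = 1e-12


def compartmental_t2(
    c_te1: float,
    c_te2: float,
    te1: float,
    te2: float,
    window: tuple[float, float] = DEFAULT_T2_WINDOW,
    eps: float = _EPS,
) -> float:
    """Two-point T2 estimate in ms, or NaN when invalid.

    Valid requires ``c_te1 > c_te2 > eps`` (a genuine decay) and the
    closed-form value inside the censoring window.
    """
    if not te1 < te2:
        raise ValueError("te1 must be smaller than te2")
    if not (np.isfinite(c_te1) and np.isfinite(c_te2)):
        return math.nan
    if c_te2 <= eps or c_te1 <= c_te2:
        return math.nan
    t2 = (te2 - te1) / math.log(c_te1 / c_te2)
    lo, hi = window
    return t2 if lo <= t2 <= hi else math.nan


def t2_volume(
    maps_te1: CompartmentMaps,
    maps_te2: CompartmentMaps,
    window: tuple[float, float] = DEFAULT_T2_WINDOW,
    eps: float = _EPS,
) -> T2Maps:
    """Voxelwise two-point compartmental T2 over a pair of C-map sets."""
    if maps_te1.te == maps_te2.te:
        raise ValueError("the two compartment-map sets must have different TEs")
    if maps_te1.te > maps_te2.te:
        maps_te1, maps_te2 = maps_te2, maps_te1
    if maps_te1.c.shape != maps_te2.c.shape:
        raise ValueError("compartment maps are not on the same grid")
    te1, te2 = float(maps_te1.te), float(maps_te2.te)

    c1 = maps_te1.c
    c2 = maps_te2.c
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = c1 / c2
        t2 = (te2 - te1) / np.log(ratio)
    valid = (
        np.isfinite(c1)
        & np.isfinite(c2)
        & (c2 > eps)
        & (c1 > c2)
        & np.isfinite(t2)
        & (t2 >= window[0])
        & (t2 <= window[1])
    )
    t2 = np.where(valid, t2, np.nan)
    return T2Maps(t2=t2, valid=valid, te_pair=(te1, te2), window=tuple(window))


def rsirs_map(
    c1_map: np.ndarray,
    b0_volume: np.ndarray,
    prostate_mask: np.ndarray,
    reference_te: float = float("nan"),
) -> RsirsMap:
    """RSIrs = C1 / median in-prostate b=0 signal.

    The denominator (``reference_value``) is recorded on the result so the
    normalization is auditable.
    """
    c1 = np.asarray(c1_map, dtype=float)
    b0 = np.asarray(b0_volume, dtype=float)
    mask = np.asarray(prostate_mask, dtype=bool)
    if c1.shape != b0.shape or c1.shape != mask.shape:
        raise ValueError("C1 map, b0 volume and mask must share a grid")
    if not mask.any():
        raise ValueError("prostate mask is empty")
    ref = float(np.median(b0[mask]))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"median b=0 signal must be > 0, got {ref}")
    return RsirsMap(rsirs=c1 / ref, reference_value=ref, reference_te=reference_te)


def rsirs_from_study(
    study: DWIStudy,
    maps: dict[float, CompartmentMaps],
    reference: str = "short",
) -> RsirsMap:
    """Compute RSIrs for a study from already-fitted compartment maps.

    ``reference`` selects which acquisition supplies both the C1 map and
    the b=0 denominator; the shorter TE is the default.
    """
    tes = sorted(maps)
    te = tes[0] if reference == "short" else tes[-1]
    mask = study.mask("prostate")
    if mask is None:
        raise ValueError("RSIrs needs a whole-prostate mask")
    return rsirs_map(
        maps[te].compartment(1), study.b0_volume(te), mask, reference_te=te
    )


def median_summary(
    t2_maps: T2Maps,
    rsirs: RsirsMap | None,
    masks: dict[str, np.ndarray],
    c1_map: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-patient summary statistics.

    For every mask in ``masks`` and compartment i, the median T2 over
    *valid* voxels (``t2_c{i}_{mask}``); plus ``max_rsirs`` and ``max_c1``
    over the whole-prostate mask when those maps are supplied.  A mask/
    compartment with zero valid voxels yields NaN and a log entry.
    """
    out: dict[str, float] = {}
    for mask_name, mask in masks.items():
        m = np.asarray(mask, dtype=bool)
        if not m.any():
            raise ValueError(f"mask {mask_name!r} is empty")
        for i in range(1, N_COMPARTMENTS + 1):
            vals = t2_maps.compartment(i)[m]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                logger.info(
                    "no valid T2 voxels for compartment %d in mask %r", i, mask_name
                )
                out[f"t2_c{i}_{mask_name}"] = math.nan
            else:
                out[f"t2_c{i}_{mask_name}"] = float(np.median(vals))
    prostate = np.asarray(masks.get("prostate"), dtype=bool) if "prostate" in masks else None
    if rsirs is not None and prostate is not None:
        vals = rsirs.rsirs[prostate]
        out["max_rsirs"] = float(np.nanmax(vals))
    if c1_map is not None and prostate is not None:
        vals = np.asarray(c1_map, dtype=float)[prostate]
        out["max_c1"] = float(np.nanmax(vals))
    return out
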