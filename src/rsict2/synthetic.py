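"""Seeded synthetic cohorts for the multi-TE RSI pipeline.

Real multi-TE prostate DWI is not redistributable, so every downstream
stage is exercised on simulated patients.  Each voxel carries ground-truth
compartment signal fractions f1..f4 and compartmental T2 values; the
forward model composes the two decay laws the pipeline later inverts:

    S(b, TE) = gain * sum_i f_i * exp(-TE / T2_i) * exp(-b * D_i)

The phantom geometry is deliberately simple (ellipsoidal prostate with an
inner transition zone and, for csPCa patients, an embedded ellipsoidal
lesion) because geometry enters no formula.  Tissue parameters encode the
qualitative structure the pipeline is meant to detect: benign T2 ordering
T2(C3) > T2(C2) > T2(C4) > T2(C1), lesions with a larger restricted
fraction f1, higher T2 in C1/C2 and lower T2 in C3, plus a mild global
("field") T2 shift in the benign tissue of csPCa patients.  Between-patient
biology is modeled by per-patient, per-tissue-class lognormal multipliers;
within-patient heterogeneity by per-voxel lognormal dispersion; scanner
gain by a per-patient global scale factor shared across b-values and TEs
(which RSIrs cancels but raw C1 does not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitting import DEFAULT_DIFFUSIVITIES
from .protocols import AcquisitionProtocol
from .volumes import DWIStudy, N_COMPARTMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "TissueClass",
    "NoiseModel",
    "LesionSpec",
    "GroundTruth",
    "SyntheticPatient",
    "default_tissue_parameters",
    "t2_independent_tissue_parameters",
    "null_tissue_parameters",
    "forward_signal",
    "generate_patient",
    "generate_cohort",
]


@dataclass(frozen=True)
class TissueClass:
    """Ground-truth parameters of one tissue class.

    ``fractions`` are the four compartment signal fractions at TE = 0 (sum
    to 1 before dispersion); ``t2_values`` the compartmental T2s in ms.
    ``dispersion`` is the sigma of the per-voxel lognormal spread applied
    to fractions and T2s alike (tissue heterogeneity within a region).
    ``patient_dispersion`` / ``patient_fraction_dispersion`` are the sigmas
    of per-patient lognormal multipliers on T2s and fractions respectively,
    drawn once per patient and tissue class (between-patient biology;
    compartment fractions vary far more across patients than T2s do).
    """

    name: str
    fractions: tuple[float, float, float, float]
    t2_values: tuple[float, float, float, float]
    dispersion: float = 0.30
    t2_dispersion: float | None = None
    patient_dispersion: float = 0.04
    patient_fraction_dispersion: float = 0.35

    @property
    def effective_t2_dispersion(self) -> float:
        return self.dispersion if self.t2_dispersion is None else self.t2_dispersion

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        t2 = np.asarray(self.t2_values, dtype=float)
        if f.shape != (N_COMPARTMENTS,) or t2.shape != (N_COMPARTMENTS,):
            raise ValueError("fractions and t2_values must have four entries")
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")
        if np.any(t2 <= 0) or np.any(~np.isfinite(t2)):
            raise ValueError("T2 values must be finite and > 0")
        if min(self.dispersion, self.patient_dispersion,
               self.patient_fraction_dispersion) < 0:
            raise ValueError("dispersion sigmas must be >= 0")
        if self.t2_dispersion is not None and self.t2_dispersion < 0:
            raise ValueError("t2_dispersion must be >= 0")


def default_tissue_parameters() -> dict[str, TissueClass]:
    """Default tissue classes.

    The magnitudes are illustrative (chosen to be physiologically plausible
    at 3 T), not literature values; what matters is the encoded structure:
    benign T2 ordering C3 > C2 > C4 > C1, and lesions with larger f1,
    higher T2(C1)/T2(C2), lower T2(C3), and unchanged C4.
    """
    return {
        "benign_pz": TissueClass(
            name="benign_pz",
            fractions=(0.10, 0.30, 0.45, 0.15),
            t2_values=(60.0, 120.0, 350.0, 90.0),
            t2_dispersion=0.12,
        ),
        "benign_tz": TissueClass(
            name="benign_tz",
            fractions=(0.13, 0.37, 0.33, 0.17),
            t2_values=(55.0, 110.0, 300.0, 90.0),
            t2_dispersion=0.12,
        ),
        "cspca_lesion": TissueClass(
            name="cspca_lesion",
            fractions=(0.22, 0.30, 0.30, 0.18),
            t2_values=(66.0, 130.0, 280.0, 90.0),
            dispersion=0.25,
            t2_dispersion=0.12,
        ),
    }


def t2_independent_tissue_parameters() -> dict[str, TissueClass]:
    """Tissue classes whose csPCa effect acts *only* through the restricted
    fraction f1: compartmental T2 is identical for every class and carries
    no voxel-to-voxel or patient-to-patient variation (it still differs
    across compartments, preserving the C3 > C2 > C4 > C1 ordering).

    Under this configuration voxelwise T2 holds no information about csPCa
    beyond what RSIrs already encodes — knowing T2 cannot refine the
    restricted fraction, because T2 never varies — so a logistic model
    adding compartmental T2 to RSIrs must rank patients exactly as RSIrs
    does.  This is the cleanest in-silico statement of the headline null
    result, and it doubles as a pipeline self-check: any AUC difference
    that appears here is manufactured by the pipeline, not the data.
    Pair with ``field_effect=(1, 1, 1, 1)`` and ``NoiseModel.none()``.
    """
    params = {}
    benign_t2 = default_tissue_parameters()["benign_pz"].t2_values
    for name, tc in default_tissue_parameters().items():
        params[name] = TissueClass(
            name=name,
            fractions=tc.fractions,
            t2_values=benign_t2,
            dispersion=tc.dispersion,
            t2_dispersion=0.0,
            patient_dispersion=0.0,
            patient_fraction_dispersion=tc.patient_fraction_dispersion,
        )
    return params


def null_tissue_parameters() -> dict[str, TissueClass]:
    """All three tissue classes share the benign-PZ parameters.

    Every region (peripheral zone, transition zone, lesion) then draws from
    one distribution, with independent per-patient multipliers per region —
    the simulator null for checking the type-I error of the group tests.
    Pair with ``field_effect=(1, 1, 1, 1)``.
    """
    ben = default_tissue_parameters()["benign_pz"]
    return {
        name: TissueClass(
            name=name,
            fractions=ben.fractions,
            t2_values=ben.t2_values,
            dispersion=ben.dispersion,
            t2_dispersion=ben.t2_dispersion,
            patient_dispersion=ben.patient_dispersion,
            patient_fraction_dispersion=ben.patient_fraction_dispersion,
        )
        for name in ("benign_pz", "benign_tz", "cspca_lesion")
    }


#: Grade-dependence of the restricted fraction: the lesion class's f1 is
#: scaled by ``1 + LESION_GRADE_F1_SCALE * (grade_group - 2)`` (then the
#: fractions are renormalized), so higher-grade tumors are more restricted
#: and low-grade csPCa overlaps the benign range.
LESION_GRADE_F1_SCALE = 0.35


#: Multiplicative T2 shift applied to the *benign* tissue of csPCa patients
#: (a global "field effect"): C1 up, C3 down, C2/C4 untouched.  This is what
#: makes whole-prostate median T2 differ between patients with and without
#: csPCa even though lesions occupy a small volume fraction.
DEFAULT_FIELD_EFFECT: tuple[float, float, float, float] = (1.05, 1.0, 0.88, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise.  ``sigma`` is relative to the mean in-prostate
    noiseless b=0 signal (so 0.03 means SNR ~ 33 at b=0)."""

    kind: str = "rician"
    sigma: float = 0.004

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError("noise kind must be 'none', 'gaussian' or 'rician'")
        if self.sigma < 0 or not np.isfinite(self.sigma):
            raise ValueError("noise sigma must be finite and >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(kind="none", sigma=0.0)

    @classmethod
    def rician(cls, sigma: float) -> "NoiseModel":
        return cls(kind="rician", sigma=sigma)

    @classmethod
    def gaussian(cls, sigma: float) -> "NoiseModel":
        return cls(kind="gaussian", sigma=sigma)


@dataclass(frozen=True)
class LesionSpec:
    """Placement request for one ellipsoidal lesion.

    ``center`` and ``radii`` are in fractional grid coordinates; ``None``
    center means "place randomly inside the prostate".
    """

    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = (0.10, 0.10, 0.16)


@dataclass
class GroundTruth:
    """Per-voxel simulated truth: fractions (grid+(4,)), T2s (grid+(4,)),
    and the patient's global gain factor."""

    fractions: np.ndarray
    t2: np.ndarray
    gain: float

    def expected_contribution(self, te: float) -> np.ndarray:
        """Noise-free compartment contribution C_i(TE) = gain*f_i*exp(-TE/T2_i)."""
        return self.gain * self.fractions * np.exp(-te / self.t2)


@dataclass
class SyntheticPatient:
    study: DWIStudy
    truth: GroundTruth
    label: bool
    grade_group: int
    patient_id: str
    seed: int

    def __post_init__(self) -> None:
        prostate = self.study.mask("prostate")
        lesion = self.study.mask("lesion")
        if lesion is not None and np.any(lesion & ~prostate):
            raise ValueError("lesion mask extends outside the prostate")
        if self.label != (self.grade_group >= 2):
            raise ValueError("csPCa label must equal (grade_group >= 2)")
        if self.label and (lesion is None or not lesion.any()):
            raise ValueError("csPCa patients must carry a non-empty lesion mask")


def forward_signal(fractions, t2_values, diffusion_coeffs, b, te):
    """Noise-free signal of the composed diffusion/T2 decay model.

    ``b`` may be a scalar or array; the result has the shape of ``b``.
    """
    f = np.asarray(fractions, dtype=float)
    t2 = np.asarray(t2_values, dtype=float)
    d = np.asarray(diffusion_coeffs, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    for name, arr in (("fractions", f), ("t2_values", t2), ("diffusion_coeffs", d)):
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    if f.shape != t2.shape or f.shape != d.shape:
        raise ValueError("fractions, t2_values, diffusion_coeffs must align")
    if np.any(f < 0):
        raise ValueError("fractions must be >= 0")
    if np.any(t2 <= 0):
        raise ValueError("T2 values must be > 0")
    if np.any(d <= 0):
        raise ValueError("diffusion coefficients must be > 0")
    if np.any(~np.isfinite(b_arr)) or np.any(b_arr < 0):
        raise ValueError("b must be finite and >= 0")
    if not np.isfinite(te) or te <= 0:
        raise ValueError("te must be finite and > 0")
    weights = f * np.exp(-te / t2)  # (4,)
    decay = np.exp(-np.multiply.outer(b_arr, d))  # b-shape + (4,)
    out = decay @ weights
    return float(out) if np.isscalar(b) or b_arr.ndim == 0 else out


def _ellipsoid(grid: tuple[int, int, int], center, semiaxes) -> np.ndarray:
    idx = np.indices(grid, dtype=float)
    r2 = sum(
        ((idx[k] - center[k]) / semiaxes[k]) ** 2 for k in range(3)
    )
    return r2 <= 1.0


def _build_masks(
    grid: tuple[int, int, int],
    lesion_specs: tuple[LesionSpec, ...],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    nx, ny, nz = grid
    center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    prostate_ax = (0.36 * nx, 0.36 * ny, 0.40 * nz)
    prostate = _ellipsoid(grid, center, prostate_ax)
    # transition zone: inner ellipsoid shifted anteriorly
    tz_center = (center[0], center[1] - 0.08 * ny, center[2])
    tz = _ellipsoid(grid, tz_center, tuple(0.55 * a for a in prostate_ax)) & prostate
    pz = prostate & ~tz
    masks = {"prostate": prostate, "pz": pz, "tz": tz}

    lesion_total = np.zeros(grid, dtype=bool)
    for k, spec in enumerate(lesion_specs):
        radii = tuple(spec.radii[i] * grid[i] for i in range(3))
        if spec.center is not None:
            c = tuple(spec.center[i] * grid[i] for i in range(3))
        else:
            # random center well inside the prostate
            candidates = np.argwhere(
                _ellipsoid(grid, center, tuple(0.6 * a for a in prostate_ax))
            )
            c = tuple(candidates[rng.integers(len(candidates))].astype(float))
        lesion = _ellipsoid(grid, c, radii) & prostate
        if lesion.sum() >= prostate.sum():
            raise ValueError("lesion covers the entire prostate; shrink its radii")
        if not lesion.any():
            raise ValueError(f"lesion {k} is empty on this grid")
        lesion_total |= lesion
        masks[f"lesion_{k}"] = lesion
    if lesion_specs:
        masks["lesion"] = lesion_total
    return masks


def generate_patient(
    protocol: AcquisitionProtocol,
    tissue_params: dict[str, TissueClass] | None = None,
    lesion_specs: tuple[LesionSpec, ...] = (),
    noise: NoiseModel | None = None,
    seed: int = 0,
    grade_group: int | None = None,
    gain: float | None = None,
    gain_sigma: float = 0.40,
    field_effect: tuple[float, float, float, float] = DEFAULT_FIELD_EFFECT,
    patient_id: str = "patient",
) -> SyntheticPatient:
    """Simulate one patient: masks, per-voxel truth, and both TE volumes.

    Deterministic for a fixed seed.  Both TE volumes share the same
    ground-truth fractions/T2s and masks (the volumes are born
    co-registered).  Replicate samples at each b-value are materialized
    individually so that replicate averaging is a real downstream step.
    """
    tissue_params = tissue_params or default_tissue_parameters()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    grid = tuple(protocol.grid_shape)

    if grade_group is None:
        grade_group = 2 if lesion_specs else 0
    label = grade_group >= 2
    if label and not lesion_specs:
        raise ValueError("grade_group >= 2 requires at least one lesion spec")
    if not label and lesion_specs:
        raise ValueError("lesion specs given for a non-csPCa patient")

    masks = _build_masks(grid, lesion_specs, rng)

    # per-patient, per-class multipliers (independent across classes, so the
    # lesion region and surrounding tissue carry independent patient effects)
    class_t2_mult: dict[str, np.ndarray] = {}
    class_f_mult: dict[str, np.ndarray] = {}
    for name in sorted(tissue_params):
        tc = tissue_params[name]
        class_t2_mult[name] = np.exp(
            rng.normal(0.0, tc.patient_dispersion, N_COMPARTMENTS)
        )
        class_f_mult[name] = np.exp(
            rng.normal(0.0, tc.patient_fraction_dispersion, N_COMPARTMENTS)
        )

    # voxelwise class assignment
    class_map = np.full(grid, "", dtype=object)
    class_map[masks["pz"]] = "benign_pz"
    class_map[masks["tz"]] = "benign_tz"
    if "lesion" in masks:
        class_map[masks["lesion"]] = "cspca_lesion"

    fractions = np.zeros(grid + (N_COMPARTMENTS,))
    t2 = np.full(grid + (N_COMPARTMENTS,), np.nan)
    prostate = masks["prostate"]
    field = np.asarray(field_effect, dtype=float)
    for name in sorted(tissue_params):
        sel = class_map == name
        n = int(sel.sum())
        if n == 0:
            continue
        tc = tissue_params[name]
        base_t2 = np.asarray(tc.t2_values) * class_t2_mult[name]
        base_f = np.asarray(tc.fractions) * class_f_mult[name]
        if label and name.startswith("benign"):
            base_t2 = base_t2 * field
        if name == "cspca_lesion" and grade_group >= 2:
            base_f = base_f.copy()
            base_f[0] *= 1.0 + LESION_GRADE_F1_SCALE * (grade_group - 2)
        vox_t2 = base_t2 * np.exp(
            rng.normal(0.0, tc.effective_t2_dispersion, (n, N_COMPARTMENTS))
        )
        vox_f = base_f * np.exp(rng.normal(0.0, tc.dispersion, (n, N_COMPARTMENTS)))
        vox_f /= vox_f.sum(axis=1, keepdims=True)
        t2[sel] = vox_t2
        fractions[sel] = vox_f

    if gain is None:
        gain = float(np.exp(rng.normal(0.0, gain_sigma)))
    if gain <= 0 or not np.isfinite(gain):
        raise ValueError("gain must be finite and > 0")

    d = np.asarray(DEFAULT_DIFFUSIVITIES)
    f_mask = fractions[prostate]  # (n_vox, 4)
    t2_mask = t2[prostate]
    unique_b = protocol.unique_b
    counts = [int(c) for _, c in protocol.b_values]

    volumes: dict[float, np.ndarray] = {}
    sigma_abs = None
    for te in protocol.te_pair:
        weights = gain * f_mask * np.exp(-te / t2_mask)  # (n_vox, 4)
        decay = np.exp(-np.outer(unique_b, d))  # (n_b, 4)
        clean = weights @ decay.T  # (n_vox, n_b)
        if sigma_abs is None:
            # noise floor referenced to the shorter-TE b=0 signal
            sigma_abs = noise.sigma * float(clean[:, 0].mean()) if clean.size else 0.0
        vol = np.zeros(grid + (protocol.n_frames,))
        in_mask = np.repeat(clean, counts, axis=1)  # (n_vox, n_frames)
        vol[prostate] = in_mask
        if noise.kind != "none" and sigma_abs > 0:
            if noise.kind == "gaussian":
                vol = vol + rng.normal(0.0, sigma_abs, vol.shape)
            else:  # rician: magnitude of complex Gaussian noise
                re = vol + rng.normal(0.0, sigma_abs, vol.shape)
                im = rng.normal(0.0, sigma_abs, vol.shape)
                vol = np.sqrt(re**2 + im**2)
        volumes[te] = vol

    study = DWIStudy(
        protocol=protocol, volumes=volumes, masks=masks, patient_id=patient_id
    )
    truth = GroundTruth(fractions=fractions, t2=t2, gain=gain)
    return SyntheticPatient(
        study=study,
        truth=truth,
        label=label,
        grade_group=int(grade_group),
        patient_id=patient_id,
        seed=int(seed),
    )


#: grade-group distribution for simulated patients: non-csPCa patients are
#: benign (0) or grade group 1; csPCa patients span grade groups 2-5.
_NEG_GG = ([0, 1], [0.7, 0.3])
_POS_GG = ([2, 3, 4, 5], [0.45, 0.30, 0.10, 0.15])


def generate_cohort(
    n_patients: int,
    cspca_prevalence: float = 0.5,
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
    tissue_params: dict[str, TissueClass] | None = None,
    noise: NoiseModel | None = None,
    gain_sigma: float = 0.40,
    field_effect: tuple[float, float, float, float] = DEFAULT_FIELD_EFFECT,
) -> list[SyntheticPatient]:
    """Simulate a cohort with a fixed csPCa prevalence.

    Exactly ``round(n * prevalence)`` patients are csPCa-positive; each
    patient's seed is derived deterministically from the cohort seed.
    """
    from .protocols import COHORT1_PROTOCOL

    protocol = protocol or COHORT1_PROTOCOL
    if n_patients < 2:
        raise ValueError("need at least two patients")
    if not 0 < cspca_prevalence < 1:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    n_pos = int(round(n_patients * cspca_prevalence))
    if n_pos < 1 or n_pos > n_patients - 1:
        raise ValueError("cohort too small to contain both classes at this prevalence")

    rng = np.random.default_rng(seed)
    labels = np.zeros(n_patients, dtype=bool)
    labels[:n_pos] = True
    rng.shuffle(labels)
    patient_seeds = rng.integers(0, 2**31, size=n_patients)

    patients = []
    for i in range(n_patients):
        if labels[i]:
            gg = int(rng.choice(_POS_GG[0], p=_POS_GG[1]))
            specs: tuple[LesionSpec, ...] = (LesionSpec(),)
        else:
            gg = int(rng.choice(_NEG_GG[0], p=_NEG_GG[1]))
            specs = ()
        patients.append(
            generate_patient(
                protocol,
                tissue_params=tissue_params,
                lesion_specs=specs,
                noise=noise,
                seed=int(patient_seeds[i]),
                grade_group=gg,
                gain_sigma=gain_sigma,
                field_effect=field_effect,
                patient_id=f"p{i:03d}",
            )
        )
    return patients
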