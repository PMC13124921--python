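"""Seeded 3-D brain-like phantoms realizing a three-component model spec.

Geometry: an ellipsoidal cerebrum whose white-matter core is separated from
the surface by a constant-thickness cortical GM shell, a solid cerebellar GM
compartment (the reference label covers only its insulated interior), and an
extracerebral rim with moderate off-target uptake standing in for scalp,
skull marrow and venous sinuses.  The WM-core size is solved by bisection so
the realized GM/WM split of the parenchyma matches the spec's 43%/57%
design.  G2 voxels are planted as a contiguous anterior cortical territory
(rank along the anterior-posterior axis; default) or as smooth-field blobs.
The volume is blurred to PET-like resolution, Gaussian noise is added, and
probability maps are blurred tissue indicators.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidArgumentError, InvalidInputError
from .model import ThreeComponentSpec
from .suvr import COMPOSITE_REGIONS
from .volumes import ScalarVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# per-voxel component assignment codes
BG, A_G1, A_G2, A_WM, A_CEREB, A_EXTRA = 0, 1, 2, 3, 4, 5

# composite-region anchor directions in normalized ellipsoid coordinates
_REGION_ANCHORS: List[Tuple[str, Tuple[float, float, float]]] = [
    ("frontal", (0.0, 0.9, 0.3)),
    ("posterior_cingulate", (0.0, -0.9, 0.25)),
    ("precuneus", (0.0, -0.55, 0.85)),
    ("parietal", (0.0, 0.1, 1.0)),
    ("lateral_temporal", (1.0, 0.0, -0.1)),
    ("lateral_temporal", (-1.0, 0.0, -0.1)),
]

REGION_LABELS: Dict[str, int] = {
    "cerebellar_cortex": 1,
    "frontal": 2,
    "posterior_cingulate": 3,
    "precuneus": 4,
    "parietal": 5,
    "lateral_temporal": 6,
    "other_cortex": 7,
    "white_matter": 8,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging-chain parameters of the synthetic phantom.

    The default grid is large enough that the cortical shell is ~14 mm thick,
    keeping partial-volume contamination at 6 mm FWHM small enough for the
    pipeline to recover planted mixture parameters.  ``extracerebral_suvr``
    sets the off-target uptake of the non-brain rim; a zero-uptake
    surround would drag the smoothed cortical rim far below its planted mean.
    """

    grid_dims: Tuple[int, int, int] = (104, 104, 80)
    voxel_size_mm: Tuple[float, float, float] = (2.3, 2.3, 4.0)
    probability_blur_fwhm_mm: float = 3.0
    pet_smoothing_fwhm_mm: float = 6.0
    noise_sd: float = 0.03
    seed: int = 0
    g2_placement: str = "gradient"  # 'gradient' (anterior territory) or 'field' (blobs)
    g2_patch_scale_mm: float = 50.0  # correlation length for 'field' placement
    extracerebral_suvr: float = 1.2
    extracerebral_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.grid_dims) < 16:
            raise InvalidArgumentError("grid dimensions must be >= 16 per axis")
        if min(self.voxel_size_mm) <= 0:
            raise InvalidArgumentError("voxel sizes must be positive")
        if self.probability_blur_fwhm_mm < 0 or self.pet_smoothing_fwhm_mm < 0:
            raise InvalidArgumentError("FWHMs must be non-negative")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if self.g2_placement not in ("gradient", "field"):
            raise InvalidArgumentError(f"unknown g2_placement {self.g2_placement!r}")

    def to_dict(self) -> dict:
        return {
            "grid_dims": list(self.grid_dims),
            "voxel_size_mm": list(self.voxel_size_mm),
            "probability_blur_fwhm_mm": self.probability_blur_fwhm_mm,
            "pet_smoothing_fwhm_mm": self.pet_smoothing_fwhm_mm,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "g2_placement": self.g2_placement,
            "g2_patch_scale_mm": self.g2_patch_scale_mm,
            "extracerebral_suvr": self.extracerebral_suvr,
            "extracerebral_sd": self.extracerebral_sd,
        }


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    spec: ThreeComponentSpec
    assignment: np.ndarray = field(repr=False)
    reference_mean_suv: float = 1.0
    expected_com_suvr: float = 1.0
    gm_fraction: float = 0.0
    wm_fraction: float = 0.0
    counts: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_spec": json.loads(self.spec.to_json()),
                "reference_mean_suv": self.reference_mean_suv,
                "expected_com_suvr": self.expected_com_suvr,
                "gm_fraction": self.gm_fraction,
                "wm_fraction": self.wm_fraction,
                "counts": self.counts,
            },
            sort_keys=True,
            indent=2,
        )


def _fwhm_sigma_vox(fwhm_mm: float, voxel_size_mm) -> list:
    return [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]


def _build_geometry(pspec: PhantomSpec, wm_target: float):
    """Component assignment + label map from the ellipsoidal geometry."""
    dims = pspec.grid_dims
    vx = np.asarray(pspec.voxel_size_mm)
    fov = np.asarray(dims) * vx
    grids = np.meshgrid(
        *(np.arange(n) * v + v / 2 for n, v in zip(dims, vx)), indexing="ij"
    )

    cer_center = (0.50 * fov[0], 0.55 * fov[1], 0.62 * fov[2])
    cer_semi = np.array([0.42 * fov[0], 0.42 * fov[1], 0.28 * fov[2]])
    cbl_center = (0.50 * fov[0], 0.30 * fov[1], 0.19 * fov[2])
    cbl_semi = np.array([0.22 * fov[0], 0.17 * fov[1], 0.11 * fov[2]])

    def _r2(center, semi):
        return sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))

    r2_cer = _r2(cer_center, cer_semi)
    r2_cbl = _r2(cbl_center, cbl_semi)
    cerebrum = r2_cer <= 1.0
    # cerebellum: solid GM compartment; the reference label covers only its
    # interior, insulated from extracerebral bleed by the outer ring
    cerebellum = (r2_cbl <= 1.0) & ~cerebrum
    cbl_ref = (r2_cbl <= 0.55**2) & cerebellum
    n_total = int(cerebrum.sum()) + int(cerebellum.sum())
    if n_total == 0:
        raise InvalidInputError("invalid phantom spec: empty parenchyma")

    # constant-thickness cortical shell: solve the shell thickness t so the
    # WM core takes the designed fraction of the parenchyma
    def core_of(t: float) -> np.ndarray:
        return (_r2(cer_center, np.maximum(cer_semi - t, 1e-6)) <= 1.0) & cerebrum

    lo, hi = 0.5, float(cer_semi.min()) - 0.5
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if int(core_of(mid).sum()) / n_total > wm_target:
            lo = mid
        else:
            hi = mid
    core = core_of(0.5 * (lo + hi))
    shell = cerebrum & ~core
    if not shell.any():
        raise InvalidInputError("invalid phantom spec: empty GM shell")
    if not cbl_ref.any():
        raise InvalidInputError("invalid phantom spec: empty cerebellar reference")

    # extracerebral rim (scalp/skull/sinus off-target uptake)
    head = (_r2(cer_center, cer_semi * 1.22) <= 1.0) | (r2_cbl <= 1.5)
    extra = head & ~cerebrum & ~cerebellum

    # label shell voxels by nearest anchor direction (Voronoi on the sphere)
    u = np.stack(
        [((g - c) / s)[shell] for g, c, s in zip(grids, cer_center, cer_semi)], axis=1
    )
    u = u / np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-12)
    anchors = np.array([a for _, a in _REGION_ANCHORS], dtype=float)
    anchors = anchors / np.linalg.norm(anchors, axis=1, keepdims=True)
    nearest = np.argmax(u @ anchors.T, axis=1)

    labels = np.zeros(dims, dtype=np.int32)
    labels[core] = REGION_LABELS["white_matter"]
    labels[cerebellum] = REGION_LABELS["other_cortex"]  # uninsulated cerebellar ring
    labels[cbl_ref] = REGION_LABELS["cerebellar_cortex"]
    shell_labels = np.array(
        [REGION_LABELS[name] for name, _ in _REGION_ANCHORS], dtype=np.int32
    )
    labels[shell] = shell_labels[nearest]

    assignment = np.zeros(dims, dtype=np.int8)
    assignment[shell] = A_G1
    assignment[core] = A_WM
    assignment[cerebellum] = A_CEREB
    assignment[extra] = A_EXTRA
    return assignment, labels, grids[1]


def _plant_g2(
    assignment: np.ndarray,
    piG2: float,
    pspec: PhantomSpec,
    rng: np.random.Generator,
    y_mm: np.ndarray,
) -> np.ndarray:
    """Turn a contiguous part of the cerebral cortex into G2 so that
    G2 voxels / all GM voxels ~= piG2."""
    out = assignment.copy()
    shell = assignment == A_G1
    n_gm_total = int(((assignment == A_G1) | (assignment == A_CEREB)).sum())
    n_g2 = min(int(round(piG2 * n_gm_total)), int(shell.sum()))
    if n_g2 == 0:
        return out
    if pspec.g2_placement == "gradient":
        score = y_mm  # anterior-predominant territory, deterministic
    else:
        score = gaussian_filter(
            rng.standard_normal(assignment.shape),
            sigma=_fwhm_sigma_vox(pspec.g2_patch_scale_mm, pspec.voxel_size_mm),
        )
    vals = score[shell]
    cut = np.partition(vals, vals.size - n_g2)[vals.size - n_g2]
    g2 = shell & (score >= cut)
    extra = int(g2.sum()) - n_g2  # threshold ties
    if extra > 0:
        flat = g2.ravel()
        flat[np.flatnonzero(flat)[:extra]] = False
        g2 = flat.reshape(assignment.shape)
    out[g2] = A_G2
    return out


def _expected_com_suvr(
    assignment: np.ndarray, labels: np.ndarray, tspec: ThreeComponentSpec
) -> float:
    planted = np.zeros(assignment.shape)
    planted[assignment == A_G1] = tspec.muG1
    planted[assignment == A_G2] = tspec.muG2
    planted[assignment == A_WM] = tspec.muW
    planted[assignment == A_CEREB] = tspec.muG1
    means = []
    for name in COMPOSITE_REGIONS:
        sel = labels == REGION_LABELS[name]
        means.append(float(planted[sel].mean()))
    return float(np.mean(means))


def generate_phantom(
    pspec: PhantomSpec, tspec: ThreeComponentSpec
) -> Tuple[ScalarVolume, ScalarVolume, ScalarVolume, ScalarVolume, PhantomTruth]:
    """Generate (suv, p_gm, p_wm, labels, truth) realizing the model spec.

    The cerebellar reference is drawn at mean SUV equal to muG1's scale, so
    SUVR truth is exact by construction (up to smoothing and noise).
    """
    rng = np.random.default_rng(pspec.seed)
    assignment, labels, y_mm = _build_geometry(pspec, tspec.wm_fraction)
    assignment = _plant_g2(assignment, tspec.piG2, pspec, rng, y_mm)

    comp_mu = {
        A_G1: tspec.muG1,
        A_G2: tspec.muG2,
        A_WM: tspec.muW,
        A_CEREB: tspec.muG1,
        A_EXTRA: pspec.extracerebral_suvr,
    }
    comp_sd = {
        A_G1: tspec.sigmaG1,
        A_G2: tspec.sigmaG2,
        A_WM: tspec.sigmaW,
        A_CEREB: tspec.sigmaG1,
        A_EXTRA: pspec.extracerebral_sd,
    }
    suv = np.zeros(pspec.grid_dims, dtype=float)
    for code in (A_G1, A_G2, A_WM, A_CEREB, A_EXTRA):
        sel = assignment == code
        suv[sel] = rng.normal(comp_mu[code], comp_sd[code], size=int(sel.sum()))

    ref_mean = float(suv[labels == REGION_LABELS["cerebellar_cortex"]].mean())

    if pspec.pet_smoothing_fwhm_mm > 0:
        suv = gaussian_filter(
            suv, sigma=_fwhm_sigma_vox(pspec.pet_smoothing_fwhm_mm, pspec.voxel_size_mm)
        )
    if pspec.noise_sd > 0:
        suv = suv + rng.normal(0.0, pspec.noise_sd, size=suv.shape)

    gm_ind = (
        (assignment == A_G1) | (assignment == A_G2) | (assignment == A_CEREB)
    ).astype(float)
    wm_ind = (assignment == A_WM).astype(float)
    if pspec.probability_blur_fwhm_mm > 0:
        sig = _fwhm_sigma_vox(pspec.probability_blur_fwhm_mm, pspec.voxel_size_mm)
        gm_ind = gaussian_filter(gm_ind, sigma=sig)
        wm_ind = gaussian_filter(wm_ind, sigma=sig)
    p_gm = np.clip(gm_ind, 0.0, 1.0)
    p_wm = np.clip(wm_ind, 0.0, 1.0)

    counts = {
        "g1": int((assignment == A_G1).sum()),
        "g2": int((assignment == A_G2).sum()),
        "wm": int((assignment == A_WM).sum()),
        "cerebellar_gm": int((assignment == A_CEREB).sum()),
        "extracerebral": int((assignment == A_EXTRA).sum()),
    }
    n_par = counts["g1"] + counts["g2"] + counts["wm"] + counts["cerebellar_gm"]
    gm_n = counts["g1"] + counts["g2"] + counts["cerebellar_gm"]
    truth = PhantomTruth(
        spec=tspec,
        assignment=assignment,
        reference_mean_suv=ref_mean,
        expected_com_suvr=_expected_com_suvr(assignment, labels, tspec),
        gm_fraction=gm_n / n_par,
        wm_fraction=counts["wm"] / n_par,
        counts=counts,
    )

    mk = lambda data, kind: ScalarVolume.from_voxel_size(data, pspec.voxel_size_mm, kind)
    return (
        mk(suv, "suv"),
        mk(p_gm, "probability"),
        mk(p_wm, "probability"),
        mk(labels, "label"),
        truth,
    )


def graded_cohort_specs(
    n_subjects: int,
    muG2_range: Tuple[float, float] = (1.1, 1.9),
    piG2_range: Tuple[float, float] = (0.1, 0.6),
) -> List[ThreeComponentSpec]:
    """Model specs for a synthetic cohort with graded amyloid burden.

    muG2 and piG2 increase together across subjects, yielding planted
    composite SUVRs spanning roughly 1.1-1.6 at the default fractions.
    """
    specs = []
    for t in np.linspace(0.0, 1.0, n_subjects):
        specs.append(
            ThreeComponentSpec(
                muG2=muG2_range[0] + t * (muG2_range[1] - muG2_range[0]),
                piG2=piG2_range[0] + t * (piG2_range[1] - piG2_range[0]),
            )
        )
    return specs
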