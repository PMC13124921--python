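"""Per-subject evaluation pipeline and cohort-level correlation reporting.

evaluate_subject runs: SUVR normalization -> regional/composite SUVR on the
native grid -> upsampling -> parenchyma (>50%) and GM/WM (>60%) masks ->
0.05-bin histograms -> whole-brain descriptive parameters -> two-Gaussian GM
decomposition and WM Gaussian fit.  Every threshold, factor and seed enters
the record's config digest; stage failures propagate with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, PipelineError
from .histostats import (
    DescriptiveParams,
    Histogram,
    build_histogram,
    descriptive_params,
    sample_excess_kurtosis,
)
from .mixture import (
    MixtureConfig,
    MixtureFit,
    WMFit,
    fit_two_gaussians,
    fit_wm_gaussian,
)
from .suvr import (
    RegionScheme,
    com_suvr,
    compute_suvr,
    default_scheme,
    reference_mask_from_labels,
    regional_suvr,
)
from .volumes import (
    ScalarVolume,
    load_volume,
    make_parenchyma_mask,
    make_tissue_mask,
    resample_upsample,
)


@dataclass(frozen=True)
class PipelineConfig:
    upsample_factor: int = 2
    interpolation: str = "cubic"
    parenchyma_threshold: float = 0.5
    tissue_threshold: float = 0.6
    bin_width: float = 0.05
    use_binned_fit: bool = False  # fit the mixture on binned counts instead of raw values
    kurtosis_variant: str = "standard"
    com_weighted: bool = False
    mixture: MixtureConfig = field(default_factory=MixtureConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SubjectRecord:
    subject_id: str
    com_suvr: float
    whole: DescriptiveParams
    gm_kurtosis: float
    mixture: MixtureFit
    wm: WMFit
    mask_voxel_counts: Dict[str, int]
    config_digest: str
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "com_suvr": self.com_suvr,
            "whole": self.whole.to_dict(),
            "gm_kurtosis": self.gm_kurtosis,
            "mixture": self.mixture.to_dict(),
            "wm": self.wm.to_dict(),
            "mask_voxel_counts": dict(self.mask_voxel_counts),
            "config_digest": self.config_digest,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        return cls(
            subject_id=d["subject_id"],
            com_suvr=d["com_suvr"],
            whole=DescriptiveParams(**d["whole"]),
            gm_kurtosis=d["gm_kurtosis"],
            mixture=MixtureFit(**d["mixture"]),
            wm=WMFit(**d["wm"]),
            mask_voxel_counts=dict(d["mask_voxel_counts"]),
            config_digest=d["config_digest"],
            warnings=list(d["warnings"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "SubjectRecord":
        return cls.from_dict(json.loads(text))

    def parameter(self, name: str) -> float:
        """Look up a scalar parameter by its reporting name."""
        lookup = {
            "com_suvr": self.com_suvr,
            "skewness": self.whole.skewness,
            "mmr": self.whole.mmr,
            "gm_kurtosis": self.gm_kurtosis,
            "muG1": self.mixture.muG1,
            "muG2": self.mixture.muG2,
            "piG2": self.mixture.piG2,
            "muW": self.wm.muW,
        }
        return lookup[name]


DEFAULT_PARAMETERS = ("skewness", "mmr", "gm_kurtosis", "muG1", "muG2", "piG2", "muW")


class _Stage:
    """Context manager that re-raises any failure tagged with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(self.name, exc) from exc
        return False


def evaluate_subject_volumes(
    suv: ScalarVolume,
    p_gm: ScalarVolume,
    p_wm: ScalarVolume,
    labels: ScalarVolume,
    scheme: Optional[RegionScheme] = None,
    config: Optional[PipelineConfig] = None,
    subject_id: str = "subject",
) -> SubjectRecord:
    """Run the full per-subject evaluation on in-memory volumes."""
    scheme = scheme or default_scheme()
    config = config or PipelineConfig()
    warnings_: List[str] = []

    with _Stage("suvr"):
        ref_mask = reference_mask_from_labels(labels, scheme)
        suvr_vol = compute_suvr(suv, ref_mask) if suv.kind == "suv" else suv

    with _Stage("regional_suvr"):
        table = regional_suvr(suvr_vol, labels, scheme)
        com = com_suvr(table, scheme, weighted=config.com_weighted)

    with _Stage("upsample"):
        f = config.upsample_factor
        suvr_up = resample_upsample(suvr_vol, f, method=config.interpolation)
        p_gm_up = resample_upsample(p_gm, f, method=config.interpolation)
        p_wm_up = resample_upsample(p_wm, f, method=config.interpolation)

    with _Stage("masks"):
        parenchyma = make_parenchyma_mask(p_gm_up, p_wm_up, config.parenchyma_threshold)
        gm_mask = make_tissue_mask(p_gm_up, config.tissue_threshold)
        wm_mask = make_tissue_mask(p_wm_up, config.tissue_threshold)

    with _Stage("histograms"):
        whole_h = build_histogram(suvr_up, parenchyma, config.bin_width, source="whole")
        gm_h = build_histogram(suvr_up, gm_mask, config.bin_width, source="gm")
        wm_h = build_histogram(suvr_up, wm_mask, config.bin_width, source="wm")

    with _Stage("descriptive"):
        whole = descriptive_params(
            suvr_up, parenchyma, whole_h, kurtosis_variant=config.kurtosis_variant
        )
        gm_values = suvr_up.data[gm_mask.data]
        gm_kurt = sample_excess_kurtosis(gm_values, variant=config.kurtosis_variant)

    with _Stage("mixture"):
        if config.use_binned_fit:
            fit = fit_two_gaussians(histogram=gm_h, config=config.mixture)
        else:
            fit = fit_two_gaussians(values=gm_values, config=config.mixture)
        if fit.degenerate:
            warnings_.append(
                "degenerate mixture: component means nearly coincide; piG2 unreliable"
            )
        if not fit.converged:
            warnings_.append("mixture EM did not converge within max_iter")
        wm_fit = fit_wm_gaussian(values=suvr_up.data[wm_mask.data])

    return SubjectRecord(
        subject_id=subject_id,
        com_suvr=com,
        whole=whole,
        gm_kurtosis=float(gm_kurt),
        mixture=dataclasses.replace(fit, trace=None),
        wm=wm_fit,
        mask_voxel_counts={
            "parenchyma": parenchyma.voxel_count,
            "gm": gm_mask.voxel_count,
            "wm": wm_mask.voxel_count,
            "reference": ref_mask.voxel_count,
        },
        config_digest=config.digest(),
        warnings=warnings_,
    )


def evaluate_subject(
    pet_path,
    p_gm_path,
    p_wm_path,
    labels_path,
    scheme: Optional[RegionScheme] = None,
    config: Optional[PipelineConfig] = None,
    subject_id: Optional[str] = None,
    pet_kind: str = "suv",
) -> SubjectRecord:
    """Load NIfTI inputs and run the per-subject evaluation."""
    with _Stage("load"):
        suv = load_volume(pet_path, pet_kind)
        p_gm = load_volume(p_gm_path, "probability")
        p_wm = load_volume(p_wm_path, "probability")
        labels = load_volume(labels_path, "label")
    sid = subject_id or str(pet_path)
    return evaluate_subject_volumes(suv, p_gm, p_wm, labels, scheme, config, sid)


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    observed = abs(rho)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = stats.pearsonr(rx, ry[list(perm)]).statistic
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def cohort_correlations(
    records: Sequence[SubjectRecord],
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Spearman rho of each parameter vs composite SUVR, plus OLS R-squared.

    Exact permutation p-values for n <= 9, t-approximation otherwise.
    Constant parameters yield an undefined correlation and are flagged.
    """
    if len(records) < 3:
        raise InvalidInputError("cohort correlations need at least 3 records")
    com = np.array([r.com_suvr for r in records], dtype=float)
    rows = []
    for name in parameters:
        vals = np.array([r.parameter(name) for r in records], dtype=float)
        if np.all(vals == vals[0]) or np.all(com == com[0]):
            rows.append(
                {"parameter": name, "rho": np.nan, "p_value": np.nan,
                 "r_squared": np.nan, "n": len(records), "undefined": True}
            )
            continue
        res = stats.spearmanr(vals, com)
        rho = float(res.statistic)
        if len(records) <= 9:
            p = _exact_spearman_pvalue(vals, com, rho)
        else:
            p = float(res.pvalue)
        lin = stats.linregress(com, vals)
        rows.append(
            {"parameter": name, "rho": rho, "p_value": p,
             "r_squared": float(lin.rvalue**2), "n": len(records), "undefined": False}
        )
    return pd.DataFrame(rows)
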