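"""SUVR normalization against a reference region and composite SUVR.

SUVR divides each voxel by the mean uptake over the reference mask
(cerebellar cortex), so the reference itself averages to 1.  ComSUVR is the
unweighted mean of the regional SUVR values over the five composite cortical
regions; a voxel-weighted variant is available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, MissingRegionError
from .volumes import BinaryMask, ScalarVolume


@dataclass(frozen=True)
class RegionScheme:
    """Maps integer labels to region names and declares reference/composite sets."""

    label_to_name: Dict[int, str]
    reference_regions: FrozenSet[str]
    composite_regions: FrozenSet[str]

    def __post_init__(self) -> None:
        names = set(self.label_to_name.values())
        if not self.reference_regions or not self.composite_regions:
            raise InvalidInputError("reference and composite region sets must be non-empty")
        if self.reference_regions & self.composite_regions:
            raise InvalidInputError("reference and composite region sets must be disjoint")
        missing = (self.reference_regions | self.composite_regions) - names
        if missing:
            raise InvalidInputError(f"regions with no labels: {sorted(missing)}")

    def labels_for(self, regions: Iterable[str]) -> np.ndarray:
        wanted = set(regions)
        return np.array(
            sorted(l for l, n in self.label_to_name.items() if n in wanted), dtype=int
        )

    @property
    def region_names(self) -> tuple:
        return tuple(sorted(set(self.label_to_name.values())))

    @classmethod
    def from_dict(cls, d: dict) -> "RegionScheme":
        return cls(
            label_to_name={int(k): str(v) for k, v in d["labels"].items()},
            reference_regions=frozenset(d["reference"]),
            composite_regions=frozenset(d["composite"]),
        )

    @classmethod
    def from_file(cls, path) -> "RegionScheme":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return {
            "labels": {str(k): v for k, v in sorted(self.label_to_name.items())},
            "reference": sorted(self.reference_regions),
            "composite": sorted(self.composite_regions),
        }


COMPOSITE_REGIONS = (
    "frontal",
    "posterior_cingulate",
    "precuneus",
    "parietal",
    "lateral_temporal",
)


def default_scheme() -> RegionScheme:
    """Default label scheme matching the phantom generator's label map."""
    return RegionScheme(
        label_to_name={
            1: "cerebellar_cortex",
            2: "frontal",
            3: "posterior_cingulate",
            4: "precuneus",
            5: "parietal",
            6: "lateral_temporal",
            7: "other_cortex",
            8: "white_matter",
        },
        reference_regions=frozenset({"cerebellar_cortex"}),
        composite_regions=frozenset(COMPOSITE_REGIONS),
    )


def compute_suvr(suv: ScalarVolume, reference_mask: BinaryMask) -> ScalarVolume:
    """Divide a SUV volume by its mean over the reference mask."""
    if reference_mask.source_shape != suv.shape:
        raise InvalidInputError("reference mask grid does not match the SUV volume")
    if reference_mask.voxel_count == 0:
        raise InvalidInputError("reference mask is empty")
    ref_mean = float(suv.data[reference_mask.data].mean())
    if ref_mean <= 0:
        raise InvalidInputError(f"non-positive reference mean: {ref_mean}")
    return ScalarVolume(data=suv.data / ref_mean, affine=suv.affine.copy(), kind="suvr")


def reference_mask_from_labels(labels: ScalarVolume, scheme: RegionScheme) -> BinaryMask:
    """Binary mask of all voxels whose label belongs to a reference region."""
    ref_labels = scheme.labels_for(scheme.reference_regions)
    return BinaryMask.from_array(np.isin(labels.data, ref_labels))


def regional_suvr(
    suvr: ScalarVolume, labels: ScalarVolume, scheme: RegionScheme
) -> pd.DataFrame:
    """Mean SUVR per named region.

    Returns a table with columns ``region``, ``rsuvr``, ``voxel_count``.
    Reference and composite regions must be non-empty; other named regions
    are simply omitted when absent.
    """
    if labels.kind != "label":
        raise InvalidInputError("regional_suvr requires a label volume")
    if not suvr.same_grid(labels):
        raise InvalidInputError("labels are not on the SUVR grid")
    rows = []
    present = set()
    for region in scheme.region_names:
        mask = np.isin(labels.data, scheme.labels_for([region]))
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            {"region": region, "rsuvr": float(suvr.data[mask].mean()), "voxel_count": n}
        )
        present.add(region)
    required = scheme.reference_regions | scheme.composite_regions
    for region in sorted(required - present):
        raise MissingRegionError(region)
    return pd.DataFrame(rows, columns=["region", "rsuvr", "voxel_count"])


def com_suvr(table: pd.DataFrame, scheme: RegionScheme, weighted: bool = False) -> float:
    """Composite SUVR: mean of the composite regions' regional SUVR values.

    With ``weighted=True`` the regional means are combined weighted by voxel
    count (equivalent to pooling the composite voxels).
    """
    sub = table[table["region"].isin(scheme.composite_regions)]
    for region in sorted(scheme.composite_regions - set(sub["region"])):
        raise MissingRegionError(region)
    if weighted:
        w = sub["voxel_count"].to_numpy(dtype=float)
        return float(np.average(sub["rsuvr"].to_numpy(), weights=w))
    return float(sub["rsuvr"].mean())
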