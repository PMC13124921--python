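"""Three-component forward model of the parenchymal SUVR distribution.

The parenchyma is modeled as three Gaussian components: G1 (gray matter
without pathological amyloid, mean 1 by construction of SUVR), G2 (gray
matter with amyloid, mean above G1), and WM (white matter with off-target
uptake, mean 1.5 by default).  Gray matter makes up 43% and white matter 57%
of the parenchymal volume; within gray matter a proportion piG2 belongs to
G2.  Expected histogram curves integrate each Gaussian density over the bins
(difference of CDFs), so component masses are exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.stats import norm

from .errors import InvalidArgumentError, InvalidInputError

COMPONENT_NAMES = ("G1", "G2", "WM")


@dataclass(frozen=True)
class ThreeComponentSpec:
    """Forward-model parameters (SUVR units)."""

    muG1: float = 1.0
    muG2: float = 1.4
    muW: float = 1.5
    sigmaG1: float = 0.15
    sigmaG2: float = 0.15
    sigmaW: float = 0.30
    piG2: float = 0.0
    gm_fraction: float = 0.43
    wm_fraction: float = 0.57

    def __post_init__(self) -> None:
        if abs(self.gm_fraction + self.wm_fraction - 1.0) > 1e-9:
            raise InvalidInputError("gm_fraction + wm_fraction must equal 1")
        if min(self.sigmaG1, self.sigmaG2, self.sigmaW) <= 0:
            raise InvalidInputError("all component standard deviations must be positive")
        if not (0.0 <= self.piG2 <= 1.0):
            raise InvalidInputError("piG2 must lie in [0, 1]")

    @property
    def component_weights(self) -> np.ndarray:
        """Mixture weights of (G1, G2, WM) within the parenchyma."""
        return np.array(
            [
                self.gm_fraction * (1.0 - self.piG2),
                self.gm_fraction * self.piG2,
                self.wm_fraction,
            ]
        )

    @property
    def component_means(self) -> np.ndarray:
        return np.array([self.muG1, self.muG2, self.muW])

    @property
    def component_sigmas(self) -> np.ndarray:
        return np.array([self.sigmaG1, self.sigmaG2, self.sigmaW])

    @property
    def mean(self) -> float:
        """Closed-form expectation of the whole-parenchyma distribution."""
        return float(np.dot(self.component_weights, self.component_means))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ThreeComponentSpec":
        return cls(**json.loads(text))


@dataclass
class ComponentCurves:
    """Expected per-bin masses of each component and their sums."""

    bin_centers: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    wm: np.ndarray
    bin_width: float

    @property
    def gm_total(self) -> np.ndarray:
        return self.g1 + self.g2

    @property
    def whole(self) -> np.ndarray:
        return self.g1 + self.g2 + self.wm


def expected_curves(
    spec: ThreeComponentSpec,
    bin_width: float = 0.05,
    range: Tuple[float, float] = (0.0, 3.0),
) -> ComponentCurves:
    """Expected histogram curves: Gaussian densities integrated over the bins.

    Each component's curve sums to its mixture weight (g1 to
    gm_fraction*(1-piG2), g2 to gm_fraction*piG2, wm to wm_fraction) when the
    range covers the distributions; a narrow range triggers a warning
    reporting the mass deficit.
    """
    lo, hi = range
    if hi <= lo:
        raise InvalidArgumentError("range upper bound must exceed lower bound")
    need_lo = float(np.min(spec.component_means - 5 * spec.component_sigmas))
    need_hi = float(np.max(spec.component_means + 5 * spec.component_sigmas))
    edges = np.arange(
        np.floor(lo / bin_width), np.floor(hi / bin_width) + 1
    ) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    curves = []
    for mu, sigma, wgt in zip(
        spec.component_means, spec.component_sigmas, spec.component_weights
    ):
        cdf = norm.cdf(edges, loc=mu, scale=sigma)
        curves.append(wgt * np.diff(cdf))
    g1, g2, wm = curves

    if lo > need_lo or hi < need_hi:
        deficit = float(spec.component_weights.sum() - (g1.sum() + g2.sum() + wm.sum()))
        warnings.warn(
            f"histogram range ({lo}, {hi}) does not cover mu +/- 5 sigma of all "
            f"components; mass deficit {deficit:.3e}",
            stacklevel=2,
        )
    return ComponentCurves(bin_centers=centers, g1=g1, g2=g2, wm=wm, bin_width=bin_width)


def sample_voxels(
    spec: ThreeComponentSpec, n: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo twin of :func:`expected_curves`.

    Draws ``n`` voxel values: each is assigned to G1/G2/WM with the spec's
    mixture weights and then sampled from that component's Gaussian.  Returns
    ``(values, labels)`` with labels from ``COMPONENT_NAMES``; reproducible
    for a fixed seed.
    """
    if n < 0:
        raise InvalidArgumentError("n must be non-negative")
    rng = np.random.default_rng(seed)
    idx = rng.choice(3, size=n, p=spec.component_weights)
    values = rng.normal(spec.component_means[idx], spec.component_sigmas[idx])
    labels = np.array(COMPONENT_NAMES)[idx]
    return values, labels
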