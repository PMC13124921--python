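"""Histograms over masked voxels and descriptive histogram parameters.

Bins are half-open ``[a, a + w)`` with edges aligned to integer multiples of
the bin width (default 0.05 SUVR).  Descriptive parameters follow the
bias-corrected sample formulas:

    skewness = n / ((n-1)(n-2)) * sum(((x_i - m) / s)^3)

    excess kurtosis = n(n+1) / ((n-1)(n-2)(n-3)) * sum(((x_i - m) / s)^4)
                      - 3 (n-1)^2 / ((n-2)(n-3))

with ``s`` the (n-1)-denominator sample standard deviation.  A variant of
the kurtosis correction term using ``3(n-1)`` in place of ``3(n-1)^2`` is
available behind ``variant='alt'``; the two agree as n grows.  The
mode-to-mean ratio (MMR) is mode / mean, with the mode read off the binned
histogram (ties broken toward the lowest bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError, UndefinedResultError
from .volumes import BinaryMask, ScalarVolume

HIST_SOURCES = ("whole", "gm", "wm", "model")


@dataclass
class Histogram:
    """Uniform-width binned counts; ``counts[i]`` covers ``[edges[i], edges[i+1])``."""

    bin_edges: np.ndarray
    counts: np.ndarray
    source: str = "whole"
    clipped: bool = False  # values fell outside an explicit range and were clamped

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.source not in HIST_SOURCES:
            raise InvalidArgumentError(f"unknown histogram source {self.source!r}")
        if self.bin_edges.size != self.counts.size + 1:
            raise InvalidInputError("len(bin_edges) must equal len(counts) + 1")
        widths = np.diff(self.bin_edges)
        if widths.size and (widths.min() <= 0 or np.ptp(widths) > 1e-9):
            raise InvalidInputError("bin edges must be strictly increasing and uniform")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class DescriptiveParams:
    mean: float
    mode: float
    skewness: float
    mmr: float
    excess_kurtosis: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "mode": self.mode,
            "skewness": self.skewness,
            "mmr": self.mmr,
            "excess_kurtosis": self.excess_kurtosis,
            "n": self.n,
        }


def _bin_index(values: np.ndarray, width: float) -> np.ndarray:
    return np.floor(values / width).astype(np.int64)


def build_histogram(
    volume: ScalarVolume,
    mask: BinaryMask,
    bin_width: float = 0.05,
    range: Optional[Tuple[float, float]] = None,
    source: str = "whole",
) -> Histogram:
    """Histogram of masked voxel values on edges aligned to multiples of the width.

    Without an explicit range, the edges run from ``floor(min/w)*w`` up to the
    bin containing the maximum.  With a range, values falling outside are
    counted in the clamped end bins and the histogram is flagged ``clipped``.
    """
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")
    if mask.source_shape != volume.shape:
        raise InvalidInputError("mask grid does not match the volume")
    if mask.voxel_count == 0:
        raise InvalidInputError("mask is empty")
    values = volume.data[mask.data]
    idx = _bin_index(values, bin_width)

    clipped = False
    if range is not None:
        lo, hi = range
        if hi <= lo:
            raise InvalidArgumentError("range upper bound must exceed lower bound")
        first, last = int(np.floor(lo / bin_width)), int(np.floor(hi / bin_width))
        if np.any(idx < first) or np.any(idx > last):
            clipped = True
        idx = np.clip(idx, first, last)
    else:
        first, last = int(idx.min()), int(idx.max())

    counts = np.bincount(idx - first, minlength=last - first + 1).astype(float)
    edges = (np.arange(first, last + 2)) * bin_width
    return Histogram(bin_edges=edges, counts=counts, source=source, clipped=clipped)


def _standardized_moment_sum(values: np.ndarray, power: int) -> Tuple[int, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    m = values.mean()
    s = values.std(ddof=1)
    if s == 0:
        raise UndefinedResultError("zero variance")
    return n, float(np.sum(((values - m) / s) ** power))


def sample_skewness(values) -> float:
    """Bias-corrected sample skewness; requires n >= 3 and positive variance."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise UndefinedResultError(f"skewness needs n >= 3, got n={values.size}")
    n, s3 = _standardized_moment_sum(values, 3)
    return n / ((n - 1) * (n - 2)) * s3


def sample_excess_kurtosis(values, variant: str = "standard") -> float:
    """Bias-corrected excess kurtosis; requires n >= 4 and positive variance.

    ``variant='standard'`` subtracts ``3(n-1)^2/((n-2)(n-3))`` (the usual
    bias-corrected estimator); ``variant='alt'`` subtracts
    ``3(n-1)/((n-2)(n-3))`` instead.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise UndefinedResultError(f"kurtosis needs n >= 4, got n={values.size}")
    if variant not in ("standard", "alt"):
        raise InvalidArgumentError(f"unknown kurtosis variant {variant!r}")
    n, s4 = _standardized_moment_sum(values, 4)
    lead = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * s4
    if variant == "standard":
        return lead - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return lead - 3 * (n - 1) / ((n - 2) * (n - 3))


def mode_value(h: Histogram) -> float:
    """Center of the maximal-count bin; ties broken toward the lowest bin."""
    if h.total <= 0:
        raise InvalidInputError("histogram has no counts")
    return float(h.bin_centers[int(np.argmax(h.counts))])


def binned_moments(h: Histogram, variant: str = "standard") -> dict:
    """Mean/skewness/kurtosis computed from bin centers weighted by counts.

    Treats counts as frequency weights with ``n = total``; exists for parity
    checks against the exact voxel-value moments.
    """
    n = h.total
    if n < 4:
        raise UndefinedResultError("binned moments need total count >= 4")
    x, w = h.bin_centers, h.counts
    m = float(np.average(x, weights=w))
    var = float(np.sum(w * (x - m) ** 2) / (n - 1))
    if var <= 0:
        raise UndefinedResultError("zero variance")
    s = np.sqrt(var)
    z = (x - m) / s
    s3 = float(np.sum(w * z**3))
    s4 = float(np.sum(w * z**4))
    skew = n / ((n - 1) * (n - 2)) * s3
    lead = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * s4
    if variant == "standard":
        kurt = lead - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    else:
        kurt = lead - 3 * (n - 1) / ((n - 2) * (n - 3))
    return {"mean": m, "sd": s, "skewness": skew, "excess_kurtosis": kurt}


def descriptive_params(
    volume: ScalarVolume,
    mask: BinaryMask,
    h: Optional[Histogram] = None,
    bin_width: float = 0.05,
    kurtosis_variant: str = "standard",
) -> DescriptiveParams:
    """Mean/skewness/kurtosis from the masked voxel values, mode and MMR from the histogram."""
    if h is None:
        h = build_histogram(volume, mask, bin_width=bin_width)
    values = volume.data[mask.data]
    mean = float(values.mean())
    if mean == 0:
        raise UndefinedResultError("mean is zero; MMR undefined")
    mode = mode_value(h)
    return DescriptiveParams(
        mean=mean,
        mode=mode,
        skewness=sample_skewness(values),
        mmr=mode / mean,
        excess_kurtosis=sample_excess_kurtosis(values, variant=kurtosis_variant),
        n=int(values.size),
    )
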