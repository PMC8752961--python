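"""ROI summary estimators for CSF-contaminated tissue metrics.

Multi-compartment diffusion models (NODDI, free-water elimination) report
tissue-space metrics per voxel (e.g. NDI, ODI) together with the voxel's
tissue fraction TF = 1 - FWF.  Under CSF partial volume the conventional
(equal-weight) arithmetic ROI mean is a biased estimate of the mean metric
over the ROI's *tissue*: weighting each voxel by its TF removes that bias.

The bias admits a closed form.  Writing ``m_i`` for the metric and ``t_i``
for the tissue fraction of voxel i, the conventional mean ``mbar`` and the
tissue-weighted mean ``mbar_t = sum(t*m)/sum(t)`` satisfy

    mbar - mbar_t = -Cov(m, t) / tbar

with the population (1/N) covariance.  The bias therefore vanishes only
when metric and tissue fraction are uncorrelated within the ROI, is
positive under negative correlation, and grows as mean TF falls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ROISample",
    "ROISummary",
    "DegenerateROIError",
    "conventional_mean",
    "tissue_weighted_mean",
    "population_covariance",
    "predicted_bias",
    "roi_median",
    "summarise",
]


class DegenerateROIError(ValueError):
    """Raised for ROI samples on which a requested statistic is undefined
    (empty sample, or zero total tissue fraction for tissue-weighted
    operations)."""


@dataclass(frozen=True)
class ROISample:
    """Per-voxel metric values and tissue fractions for one ROI.

    Parameters
    ----------
    metric_values
        Voxelwise tissue metric (NDI, ODI, ...), finite, one per voxel.
    tissue_fractions
        Voxelwise tissue fraction in [0, 1], aligned with
        ``metric_values``.
    metric_name
        Tag naming the metric ("NDI", "ODI" or anything else).
    roi_label
        Optional integer label or abbreviation of the region.

    Use :meth:`from_voxels` to build a sample from raw voxel data: it
    drops non-finite voxels pairwise and (by default) clips tissue
    fractions into [0, 1], which is what the image-extraction layer does.
    The direct constructor validates and rejects invalid input instead.
    """

    metric_values: np.ndarray
    tissue_fractions: np.ndarray
    metric_name: str = "other"
    roi_label: int | str | None = None

    def __post_init__(self) -> None:
        m = np.array(self.metric_values, dtype=float, copy=True)
        t = np.array(self.tissue_fractions, dtype=float, copy=True)
        if m.ndim != 1 or t.ndim != 1:
            raise ValueError("metric_values and tissue_fractions must be 1-D")
        if m.shape != t.shape:
            raise ValueError(
                f"length mismatch: {m.size} metric values vs "
                f"{t.size} tissue fractions"
            )
        if m.size == 0:
            raise DegenerateROIError("empty ROI sample (no voxels)")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite metric values; remove them upstream")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite tissue fractions; remove them upstream")
        if np.any(t < 0.0) or np.any(t > 1.0):
            raise ValueError("tissue fractions must lie in [0, 1]")
        m.flags.writeable = False
        t.flags.writeable = False
        object.__setattr__(self, "metric_values", m)
        object.__setattr__(self, "tissue_fractions", t)

    @classmethod
    def from_voxels(
        cls,
        metric_values: Sequence[float] | np.ndarray,
        tissue_fractions: Sequence[float] | np.ndarray,
        *,
        metric_name: str = "other",
        roi_label: int | str | None = None,
        clip_tf: bool = True,
    ) -> "ROISample":
        """Build a sample from raw voxel vectors.

        Voxels where either value is non-finite are dropped (pairwise, so
        conventional and tissue-weighted statistics see the same voxels).
        Tissue fractions outside [0, 1] — which imperfect model fits can
        produce — are clipped with a warning when ``clip_tf`` is true,
        otherwise rejected.
        """
        m = np.asarray(metric_values, dtype=float).ravel()
        t = np.asarray(tissue_fractions, dtype=float).ravel()
        if m.shape != t.shape:
            raise ValueError(
                f"length mismatch: {m.size} metric values vs "
                f"{t.size} tissue fractions"
            )
        keep = np.isfinite(m) & np.isfinite(t)
        if not np.any(keep):
            raise DegenerateROIError(
                "all voxels excluded as non-finite"
                + (f" in ROI {roi_label!r}" if roi_label is not None else "")
            )
        m, t = m[keep], t[keep]
        out_of_range = (t < 0.0) | (t > 1.0)
        if np.any(out_of_range):
            if not clip_tf:
                raise ValueError(
                    f"{int(out_of_range.sum())} tissue fractions outside [0, 1] "
                    "and clip_tf=False"
                )
            warnings.warn(
                f"clipped {int(out_of_range.sum())} tissue fraction(s) "
                "outside [0, 1]",
                stacklevel=2,
            )
            t = np.clip(t, 0.0, 1.0)
        return cls(m, t, metric_name=metric_name, roi_label=roi_label)

    @property
    def n_voxels(self) -> int:
        return int(self.metric_values.size)


@dataclass(frozen=True)
class ROISummary:
    """All per-ROI summary statistics for one subject and one metric."""

    conventional_mean: float
    tissue_weighted_mean: float
    bias: float
    mean_tf: float
    mean_product: float
    covariance: float
    median: float
    n_voxels: int
    metric_name: str = "other"
    roi_label: int | str | None = None


def conventional_mean(sample: ROISample) -> float:
    """Equal-weight arithmetic mean of the metric over ROI voxels."""
    return float(np.mean(sample.metric_values))


def tissue_weighted_mean(sample: ROISample) -> float:
    """TF-weighted ROI mean, ``sum(t*m) / sum(t)``.

    Estimates the mean metric over the tissue within the ROI rather than
    over its voxels.  Undefined when the ROI contains no tissue at all.
    """
    t = sample.tissue_fractions
    total = float(np.sum(t))
    if total <= 0.0:
        raise DegenerateROIError(
            "sum of tissue fractions is zero (all-CSF ROI); "
            "tissue-weighted mean undefined"
        )
    return float(np.sum(t * sample.metric_values) / total)


def population_covariance(sample: ROISample) -> float:
    """Covariance of metric and tissue fraction with the 1/N denominator.

    The 1/N (no Bessel correction) form is what makes the bias identity
    ``mbar - mbar_t == -cov/tbar`` exact.  A single voxel has zero
    covariance by this definition.
    """
    m = sample.metric_values
    t = sample.tissue_fractions
    return float(np.mean((m - m.mean()) * (t - t.mean())))


def predicted_bias(sample: ROISample) -> float:
    """Closed-form bias of the conventional mean, ``-Cov(m, t) / tbar``.

    Algebraically identical to ``conventional_mean - tissue_weighted_mean``;
    positive when metric and tissue fraction are negatively correlated.
    """
    mean_tf = float(np.mean(sample.tissue_fractions))
    if mean_tf <= 0.0:
        raise DegenerateROIError("mean tissue fraction is zero; bias undefined")
    return -population_covariance(sample) / mean_tf


def roi_median(sample: ROISample) -> float:
    """Sample median of the metric (midpoint convention for even N).

    Included for comparison: the median's bias under CSF partial volume
    is of similar magnitude to the conventional mean's, so it is not a
    substitute for the tissue-weighted mean.
    """
    return float(np.median(sample.metric_values))


def summarise(sample: ROISample) -> ROISummary:
    """Compute every per-ROI statistic at once.

    ``bias`` is stored as the difference of the two means; the identity
    with ``-covariance/mean_tf`` holds to floating-point rounding and is
    enforced by the test suite, not recomputed here.
    """
    conv = conventional_mean(sample)
    tw = tissue_weighted_mean(sample)
    return ROISummary(
        conventional_mean=conv,
        tissue_weighted_mean=tw,
        bias=conv - tw,
        mean_tf=float(np.mean(sample.tissue_fractions)),
        mean_product=float(
            np.mean(sample.tissue_fractions * sample.metric_values)
        ),
        covariance=population_covariance(sample),
        median=roi_median(sample),
        n_voxels=sample.n_voxels,
        metric_name=sample.metric_name,
        roi_label=sample.roi_label,
    )
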