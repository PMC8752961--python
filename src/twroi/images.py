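"""NIfTI-backed ROI extraction: parameter maps + label image -> tables.

Consumes already-fitted scalar parameter maps (NDI, ODI, and a tissue- or
free-water-fraction map) and an integer ROI label image, all resampled to
the same voxel grid.  Atlas propagation and registration are upstream
concerns; this layer only verifies that the grids agree, pulls voxel
vectors per labelled region, and delegates the statistics to
:mod:`twroi.estimators`.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .estimators import ROISample, summarise

__all__ = [
    "GridMismatchError",
    "LabelNotFoundError",
    "load_image",
    "tf_from_fwf",
    "validate_grid",
    "extract_roi_sample",
    "load_roi_definitions",
    "summarise_subject",
    "voxel_density",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Fixed column order of per-subject and cohort summary tables.
SUMMARY_COLUMNS = [
    "subject_id",
    "group",
    "roi",
    "metric",
    "n_voxels",
    "mean_tf",
    "conventional_mean",
    "tissue_weighted_mean",
    "bias",
    "covariance",
    "median",
]

AFFINE_ATOL = 1e-4
FWF_RANGE_TOL = 0.01


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


class LabelNotFoundError(KeyError):
    """A requested ROI label is absent from the label image."""


def load_image(path: str | Path) -> nib.spatialimages.SpatialImage:
    """Load a NIfTI volume, failing early if the file is missing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    return nib.load(str(path))


def _data(img: nib.spatialimages.SpatialImage) -> np.ndarray:
    return np.asarray(img.get_fdata(dtype=np.float64))


def tf_from_fwf(fwf: nib.spatialimages.SpatialImage) -> nib.Nifti1Image:
    """Convert a free-water-fraction map to a tissue-fraction map (1 - FWF).

    FWF values are volume fractions and must lie in [0, 1]; values within
    ``FWF_RANGE_TOL`` of that interval (fit noise) are clipped with a
    warning, anything further out raises.  Non-finite voxels pass through
    unchanged and are excluded later during extraction.
    """
    data = _data(fwf)
    finite = np.isfinite(data)
    vals = data[finite]
    if vals.size and (vals.min() < -FWF_RANGE_TOL or vals.max() > 1.0 + FWF_RANGE_TOL):
        raise ValueError(
            f"free-water fractions outside [{-FWF_RANGE_TOL}, {1 + FWF_RANGE_TOL}] "
            f"(range {vals.min():.4f}..{vals.max():.4f}); "
            "is this really a fraction map?"
        )
    clipped = finite & ((data < 0.0) | (data > 1.0))
    if np.any(clipped):
        warnings.warn(
            f"clipped {int(clipped.sum())} free-water fraction voxel(s) "
            "into [0, 1]",
            stacklevel=2,
        )
        data = np.where(finite, np.clip(data, 0.0, 1.0), data)
    return nib.Nifti1Image(1.0 - data, fwf.affine, dtype=np.float64)


def validate_grid(*images: nib.spatialimages.SpatialImage) -> None:
    """Check that all images share one voxel grid.

    Shapes must match exactly and affines elementwise to ``AFFINE_ATOL``
    (header round-tripping through different tools perturbs affines at
    the 1e-6 level).  The offending pair is named in the error.
    """
    if len(images) < 2:
        raise ValueError("need at least two images to compare grids")
    ref = images[0]
    for i, img in enumerate(images[1:], start=1):
        if img.shape[:3] != ref.shape[:3]:
            raise GridMismatchError(
                f"shape mismatch: image 0 has {ref.shape[:3]}, "
                f"image {i} has {img.shape[:3]}"
            )
        if not np.allclose(img.affine, ref.affine, atol=AFFINE_ATOL, rtol=0.0):
            raise GridMismatchError(
                f"affine mismatch between image 0 and image {i} "
                f"(max |diff| = {np.abs(img.affine - ref.affine).max():.2e})"
            )


def extract_roi_sample(
    metric: nib.spatialimages.SpatialImage,
    tf: nib.spatialimages.SpatialImage,
    labels: nib.spatialimages.SpatialImage,
    label_id: int,
    *,
    metric_name: str = "other",
    roi_label: int | str | None = None,
) -> ROISample:
    """Pull the voxel vectors of one labelled region into an
    :class:`~twroi.estimators.ROISample`.

    Includes exactly the voxels where ``labels == label_id`` and both the
    metric and the tissue fraction are finite; the flattening order is
    irrelevant to every downstream statistic.
    """
    validate_grid(metric, tf, labels)
    lab = np.asarray(labels.dataobj)
    if not np.issubdtype(lab.dtype, np.integer):
        rounded = np.rint(lab)
        if not np.allclose(lab, rounded, atol=1e-6):
            raise ValueError("label image is not integer-valued")
        lab = rounded.astype(np.int64)
    mask = lab == int(label_id)
    if not np.any(mask):
        present = np.unique(lab[lab != 0])
        raise LabelNotFoundError(
            f"label {label_id} absent from label image; "
            f"available labels: {present.tolist()}"
        )
    m = _data(metric)[mask]
    t = _data(tf)[mask]
    n_dropped = int(np.sum(~(np.isfinite(m) & np.isfinite(t))))
    if n_dropped:
        logger.info(
            "ROI %s: excluded %d non-finite voxel(s) of %d",
            roi_label if roi_label is not None else label_id,
            n_dropped,
            m.size,
        )
    return ROISample.from_voxels(
        m,
        t,
        metric_name=metric_name,
        roi_label=roi_label if roi_label is not None else int(label_id),
    )


def load_roi_definitions(path: str | Path | None = None) -> pd.DataFrame:
    """Load an ROI definition table (label_id, abbreviation, full_name,
    periventricular).

    With no argument, returns the packaged JHU ICBM-DTI-81 white-matter
    table: 48 regions, 29 flagged periventricular (bordering the
    ventricles, hence prone to CSF partial volume) and 19 not.  Users can
    supply their own CSV with the same columns for other atlases.
    """
    if path is None:
        ref = importlib.resources.files("twroi.data") / "jhu_icbm_dti81_rois.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"label_id", "abbreviation", "full_name", "periventricular"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI definition table missing columns: {sorted(missing)}")
    if df["abbreviation"].duplicated().any():
        raise ValueError("ROI abbreviations must be unique")
    df["label_id"] = df["label_id"].astype(int)
    df["periventricular"] = df["periventricular"].astype(bool)
    return df


def summarise_subject(
    metrics: dict[str, nib.spatialimages.SpatialImage],
    tf: nib.spatialimages.SpatialImage,
    labels: nib.spatialimages.SpatialImage,
    roidefs: pd.DataFrame,
    *,
    subject_id: str = "subject",
    group: str = "",
) -> pd.DataFrame:
    """Compute both ROI means (and the rest of the summary) for every
    metric and every defined region present in the label image.

    Returns a long-format table with :data:`SUMMARY_COLUMNS`, one row per
    (region x metric).  Regions listed in ``roidefs`` but absent from the
    label image are reported in a warning rather than silently dropped —
    small structures can vanish entirely after masking.
    """
    validate_grid(*metrics.values(), tf, labels)
    lab = np.asarray(labels.dataobj)
    present = set(np.unique(np.rint(lab).astype(np.int64))) - {0}
    rows: list[dict] = []
    missing: list[str] = []
    for rec in roidefs.itertuples(index=False):
        if rec.label_id not in present:
            missing.append(rec.abbreviation)
            continue
        for name, img in metrics.items():
            sample = extract_roi_sample(
                img, tf, labels, rec.label_id,
                metric_name=name, roi_label=rec.abbreviation,
            )
            s = summarise(sample)
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "roi": rec.abbreviation,
                    "metric": name,
                    "n_voxels": s.n_voxels,
                    "mean_tf": s.mean_tf,
                    "conventional_mean": s.conventional_mean,
                    "tissue_weighted_mean": s.tissue_weighted_mean,
                    "bias": s.bias,
                    "covariance": s.covariance,
                    "median": s.median,
                }
            )
    if missing:
        warnings.warn(
            f"{len(missing)} ROI(s) absent from label image for subject "
            f"{subject_id!r}: {', '.join(missing)}",
            stacklevel=2,
        )
    if not rows:
        warnings.warn(
            f"label image for subject {subject_id!r} contains no defined ROI",
            stacklevel=2,
        )
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def voxel_density(voxel_size_mm: float | tuple[float, float, float],
                  per_volume_mm3: float = 1000.0) -> float:
    """Number of voxels per ``per_volume_mm3`` cubic millimetres.

    A quick way to compare acquisitions: 2 mm isotropic data packs 125
    voxels into 1000 mm^3 where 2.5 mm isotropic data packs 64, i.e. about
    twice the voxel count for the same anatomy.
    """
    if np.isscalar(voxel_size_mm):
        vol = float(voxel_size_mm) ** 3
    else:
        dims = tuple(float(v) for v in voxel_size_mm)  # type: ignore[union-attr]
        if len(dims) != 3:
            raise ValueError("voxel_size_mm must be a scalar or a 3-tuple")
        vol = dims[0] * dims[1] * dims[2]
    if vol <= 0:
        raise ValueError("voxel volume must be positive")
    return per_volume_mm3 / vol
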