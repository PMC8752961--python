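"""Synthetic phantoms and cohorts with exact ground truth.

Real NODDI maps cannot ship with the package, so validation rests on two
generators whose truth is known by construction:

* **Fine-grid phantoms** (:class:`FineGridPhantom`): a high-resolution
  field of local neurite density with a CSF mask, block-averaged into
  coarse "acquisition" voxels.  Each coarse voxel's tissue fraction is
  the fraction of non-CSF sub-elements it covers and its metric value is
  the mean density over those sub-elements — exactly how a
  multi-compartment model's tissue metric relates to the underlying
  anatomy.  The tissue-weighted mean of the coarse voxels equals the
  fine-grid tissue mean *identically* (the weighted sum telescopes into
  the sum over tissue sub-elements), which is the defining correctness
  property of the estimator; the conventional mean does not.

* **Parametric ROI samples** (:func:`simulate_roi_sample`): tissue
  fractions drawn from a scaled Beta distribution and metric values
  coupled to them through a linear slope ``kappa``, so the expected
  covariance is ``kappa * Var(t)`` and the closed-form bias
  ``-kappa * Var(t) / tbar`` is analytic.  :func:`simulate_cohort`
  stacks these into two-group cohorts (with between-subject variation
  and group differences in both metric and tissue fraction, emulating
  atrophy) and can write the whole cohort out as NIfTI volumes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .estimators import ROISample, summarise
from .images import SUMMARY_COLUMNS

__all__ = [
    "FineGridPhantom",
    "make_random_phantom",
    "downsample_phantom",
    "simulate_roi_sample",
    "MetricSpec",
    "ROISpec",
    "SimulationConfig",
    "default_config",
    "simulate_cohort",
]

TRUTH_COLUMNS = [
    "subject_id",
    "group",
    "roi",
    "metric",
    "true_tissue_mean",
    "true_cov",
    "true_mean_tf",
]


# ---------------------------------------------------------------------------
# Fine-grid phantoms


@dataclass(frozen=True)
class FineGridPhantom:
    """Sub-voxel neurite-density field with a CSF mask.

    ``density_field`` holds the local neurite density in [0, 1] on a fine
    grid (2-D or 3-D); where ``csf_mask`` is true the element is free
    water and its density value is ignored.  ``block_factor`` is the
    linear down-sampling factor mapping fine elements to acquisition
    voxels and must divide every dimension.
    """

    density_field: np.ndarray
    csf_mask: np.ndarray
    block_factor: int

    def __post_init__(self) -> None:
        d = np.asarray(self.density_field, dtype=float)
        c = np.asarray(self.csf_mask, dtype=bool)
        if d.shape != c.shape:
            raise ValueError("density_field and csf_mask shapes differ")
        if d.ndim not in (2, 3):
            raise ValueError("phantom must be 2-D or 3-D")
        b = int(self.block_factor)
        if b < 1:
            raise ValueError("block_factor must be >= 1")
        if any(s % b for s in d.shape):
            raise ValueError(
                f"block_factor {b} does not divide grid shape {d.shape}"
            )
        tissue = ~c
        if not np.all(np.isfinite(d[tissue])):
            raise ValueError("non-finite density in tissue elements")
        object.__setattr__(self, "density_field", d)
        object.__setattr__(self, "csf_mask", c)
        object.__setattr__(self, "block_factor", b)


def _block_view(arr: np.ndarray, b: int) -> np.ndarray:
    """Reshape to (coarse grid..., b**ndim) gathering each block's elements."""
    ndim = arr.ndim
    inter = []
    for s in arr.shape:
        inter += [s // b, b]
    arr = arr.reshape(inter)
    order = list(range(0, 2 * ndim, 2)) + list(range(1, 2 * ndim, 2))
    out_shape = [arr.shape[i] for i in range(0, 2 * ndim, 2)] + [b**ndim]
    return arr.transpose(order).reshape(out_shape)


def downsample_phantom(
    phantom: FineGridPhantom,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Block-average a phantom into acquisition voxels.

    Returns ``(tf, metric, exact_tissue_mean)`` where, per coarse voxel,
    ``tf`` is the fraction of non-CSF sub-elements and ``metric`` the
    mean density over them (NaN for fully-CSF voxels, which carry no
    tissue information).  ``exact_tissue_mean`` is the mean density over
    every tissue sub-element of the whole phantom — the quantity the
    tissue-weighted mean of the coarse voxels recovers exactly.
    """
    b = phantom.block_factor
    tissue = (~phantom.csf_mask).astype(float)
    dens = np.where(phantom.csf_mask, 0.0, phantom.density_field)
    if tissue.sum() == 0:
        raise ValueError("phantom is fully CSF; tissue mean undefined")
    t_blocks = _block_view(tissue, b)
    d_blocks = _block_view(dens, b)
    n_tissue = t_blocks.sum(axis=-1)
    tf = n_tissue / (b**phantom.density_field.ndim)
    with np.errstate(invalid="ignore", divide="ignore"):
        metric = np.where(
            n_tissue > 0, d_blocks.sum(axis=-1) / n_tissue, np.nan
        )
    exact = float(dens.sum() / tissue.sum())
    return tf, metric, exact


def make_random_phantom(
    rng: np.random.Generator,
    shape: tuple[int, ...] = (24, 24),
    block_factor: int = 4,
    csf_base: float = 0.1,
    csf_slope: float = 0.5,
    density_mean: float = 0.55,
    density_slope: float = 0.3,
    density_sd: float = 0.05,
) -> FineGridPhantom:
    """Random phantom with controllable metric/TF coupling.

    CSF probability and local density both vary linearly along the first
    axis: with positive ``csf_slope`` and positive ``density_slope`` the
    densest tissue sits where CSF contamination is worst, so the coarse
    voxels' metric and tissue fraction are negatively correlated and the
    conventional mean is biased upward (and vice versa for a negative
    ``density_slope``).
    """
    x = np.linspace(0.0, 1.0, shape[0])
    x = x.reshape((-1,) + (1,) * (len(shape) - 1))
    p_csf = np.clip(csf_base + csf_slope * x, 0.0, 0.9)
    csf = rng.random(shape) < p_csf
    dens = rng.normal(density_mean + density_slope * (x - 0.5), density_sd,
                      size=shape)
    dens = np.clip(dens, 0.0, 1.0)
    return FineGridPhantom(dens, csf, block_factor)


# ---------------------------------------------------------------------------
# Parametric ROI samples


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    if not 0.0 < mean < 1.0:
        raise ValueError(f"tf_mean must lie in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ValueError("tf_spread must be positive")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"tf_spread {sd} too large for tf_mean {mean} "
            "(Beta variance bound exceeded)"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def simulate_roi_sample(
    n: int,
    tf_mean: float,
    tf_spread: float,
    kappa: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    metric_name: str = "other",
    roi_label: int | str | None = None,
) -> tuple[ROISample, dict]:
    """Draw one ROI's voxel vectors with analytic ground truth.

    Tissue fractions come from a Beta distribution with the requested
    mean and spread; the noiseless metric is
    ``m0 = mu + kappa * (t - mean(t))`` so the population covariance of
    (m0, t) is exactly ``kappa * Var(t)`` and the closed-form bias of the
    conventional mean is ``-kappa * Var(t) / tbar``.  Gaussian voxel
    noise of standard deviation ``sigma`` is added on top and the result
    clipped to [0, 1] (a warning is raised if clipping touches more than
    5% of voxels, since heavy clipping breaks the analytic covariance).

    Returns the sample plus a ground-truth dict with the tissue-weighted
    mean of the noiseless component (``true_tissue_mean``), the realised
    noiseless covariance (``true_cov``) and the realised mean TF.
    """
    if n < 2:
        raise ValueError("need at least 2 voxels")
    t = _draw_tf(n, tf_mean, tf_spread, rng)
    m, m0 = _metric_given_tf(t, kappa, mu, sigma, rng)
    sample = ROISample(m, t, metric_name=metric_name, roi_label=roi_label)
    return sample, _truth_row(t, m0)


def _draw_tf(
    n: int, tf_mean: float, tf_spread: float, rng: np.random.Generator
) -> np.ndarray:
    a, b = _beta_params(tf_mean, tf_spread)
    t = rng.beta(a, b, size=n)
    # exclude exact zero so every generated voxel holds some tissue
    return np.clip(t, 1e-9, 1.0)


def _metric_given_tf(
    t: np.ndarray,
    kappa: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    m0 = mu + kappa * (t - t.mean())
    m = m0 + (rng.normal(0.0, sigma, size=t.size) if sigma > 0 else 0.0)
    clipped = (m < 0.0) | (m > 1.0)
    if clipped.mean() > 0.05:
        warnings.warn(
            f"{clipped.mean():.1%} of voxels clipped to [0, 1]; "
            "parameters push the metric against its bounds",
            stacklevel=2,
        )
    return np.clip(m, 0.0, 1.0), m0


def _truth_row(t: np.ndarray, m0: np.ndarray) -> dict:
    return {
        "true_tissue_mean": float(np.sum(t * m0) / np.sum(t)),
        "true_cov": float(np.mean((m0 - m0.mean()) * (t - t.mean()))),
        "true_mean_tf": float(t.mean()),
    }


# ---------------------------------------------------------------------------
# Cohort configuration


@dataclass
class MetricSpec:
    """Generative parameters of one tissue metric within one region.

    ``mu`` and ``kappa`` map group name to the tissue-metric mean and the
    metric-vs-TF slope (expected covariance is kappa * Var(t)); ``sigma``
    is voxelwise noise SD and ``between_subject_sd`` the SD of the
    subject-level shift of ``mu``.
    """

    mu: dict[str, float]
    kappa: dict[str, float]
    sigma: float = 0.05
    between_subject_sd: float = 0.025


@dataclass
class ROISpec:
    """Generative parameters of one region.

    ``label_id`` is the integer written into the label image (the
    region's atlas label); left unset, regions are numbered 1..n in
    listing order.
    """

    abbreviation: str
    n_voxels: int
    tf_mean: dict[str, float]
    metrics: dict[str, MetricSpec]
    tf_spread: float = 0.08
    tf_between_sd: float = 0.01
    label_id: int | None = None


@dataclass
class SimulationConfig:
    """Two-group cohort recipe: regions, group sizes, grid, seed."""

    rois: list[ROISpec]
    groups: tuple[str, str] = ("control", "patient")
    n_subjects: tuple[int, int] = (21, 30)
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)  # type: ignore[assignment]
        self.n_subjects = tuple(int(n) for n in self.n_subjects)  # type: ignore[assignment]
        self.grid_shape = tuple(int(s) for s in self.grid_shape)  # type: ignore[assignment]
        if len(self.groups) != 2 or len(self.n_subjects) != 2:
            raise ValueError("exactly two groups required")
        if any(n < 2 for n in self.n_subjects):
            raise ValueError("need at least 2 subjects per group")
        total = sum(r.n_voxels for r in self.rois)
        capacity = int(np.prod(self.grid_shape))
        if total > capacity:
            raise ValueError(
                f"ROIs need {total} voxels but grid holds {capacity}"
            )
        for r in self.rois:
            if r.n_voxels < 2:
                raise ValueError(f"ROI {r.abbreviation}: n_voxels must be >= 2")
            for g in self.groups:
                if g not in r.tf_mean:
                    raise ValueError(
                        f"ROI {r.abbreviation}: tf_mean missing group {g!r}"
                    )
                for mname, ms in r.metrics.items():
                    if g not in ms.mu or g not in ms.kappa:
                        raise ValueError(
                            f"ROI {r.abbreviation}/{mname}: mu/kappa "
                            f"missing group {g!r}"
                        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        try:
            rois = [
                ROISpec(
                    abbreviation=r["abbreviation"],
                    n_voxels=int(r["n_voxels"]),
                    tf_mean=dict(r["tf_mean"]),
                    tf_spread=float(r.get("tf_spread", 0.08)),
                    tf_between_sd=float(r.get("tf_between_sd", 0.01)),
                    label_id=(int(r["label_id"])
                              if r.get("label_id") is not None else None),
                    metrics={
                        name: MetricSpec(
                            mu=dict(m["mu"]),
                            kappa=dict(m["kappa"]),
                            sigma=float(m.get("sigma", 0.05)),
                            between_subject_sd=float(
                                m.get("between_subject_sd", 0.025)
                            ),
                        )
                        for name, m in r["metrics"].items()
                    },
                )
                for r in raw["rois"]
            ]
            kwargs = {k: raw[k] for k in
                      ("groups", "n_subjects", "grid_shape", "voxel_size_mm",
                       "seed") if k in raw}
            return cls(rois=rois, **kwargs)
        except KeyError as exc:
            raise ValueError(f"config missing field {exc.args[0]!r}") from exc


def default_config(
    roidefs: pd.DataFrame | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """Cohort recipe at the scale of a typical atrophy study.

    21 vs 30 subjects over the 48 packaged white-matter regions.  Mean
    tissue fractions are lower in periventricular regions and lower again
    in the patient group (atrophy); the metric-vs-TF slope ``kappa`` is
    negative for ODI everywhere (ODI over-estimated by the conventional
    mean, worst where TF is low) and mixed-sign for NDI in
    periventricular regions, matching how these couplings behave in
    white matter.  Region sizes span roughly 100-1000 voxels.
    """
    from .images import load_roi_definitions

    if roidefs is None:
        roidefs = load_roi_definitions()
    rois: list[ROISpec] = []
    for i, rec in enumerate(roidefs.itertuples(index=False)):
        pv = bool(rec.periventricular)
        # deterministic per-ROI variety without touching the cohort RNG
        u = (i * 0.6180339887) % 1.0
        if pv:
            tf_c = 0.70 + 0.18 * u
            tf_drop = 0.05 + 0.03 * u
            tf_spread = 0.10
            kappa_ndi = 0.10 if i % 2 else -0.10
            kappa_odi_c, kappa_odi_p = -0.22, -0.32
        else:
            tf_c = 0.88 + 0.09 * u
            tf_drop = 0.015
            tf_spread = 0.04
            kappa_ndi = -0.05
            kappa_odi_c, kappa_odi_p = -0.10, -0.14
        n_vox = int(100 + 900 * ((i * 0.3819660113) % 1.0))
        rois.append(
            ROISpec(
                abbreviation=rec.abbreviation,
                label_id=int(rec.label_id),
                n_voxels=n_vox,
                tf_mean={"control": tf_c, "patient": tf_c - tf_drop},
                tf_spread=tf_spread,
                tf_between_sd=0.012,
                metrics={
                    "NDI": MetricSpec(
                        mu={"control": 0.60 + 0.06 * u,
                            "patient": 0.57 + 0.06 * u},
                        kappa={"control": kappa_ndi, "patient": kappa_ndi},
                    ),
                    "ODI": MetricSpec(
                        mu={"control": 0.42 + 0.08 * u,
                            "patient": 0.40 + 0.08 * u},
                        kappa={"control": kappa_odi_c, "patient": kappa_odi_p},
                    ),
                },
            )
        )
    return SimulationConfig(rois=rois, seed=seed)


# ---------------------------------------------------------------------------
# Cohort generation


def _subject_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for group, n in zip(config.groups, config.n_subjects):
        out += [(f"{group}{k + 1:02d}", group) for k in range(n)]
    return out


def simulate_cohort(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Path] | None]:
    """Generate a full two-group cohort.

    Per subject and region, tissue fractions and metric values are drawn
    by :func:`simulate_roi_sample` with subject-level shifts of the
    group-level ``mu`` and ``tf_mean`` (between-subject variation), and
    summarised into the long-format cohort table.  A parallel
    ground-truth table records the noiseless tissue mean per cell.

    With ``outdir`` set, every subject's metric and TF maps plus the
    shared label image are also written as NIfTI volumes on the
    configured grid, so the image-extraction path can be exercised
    end-to-end; the returned dict maps subject ids (and ``"labels"``) to
    paths.  Everything is reproducible from the seed (``seed`` overrides
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = config.grid_shape
    capacity = int(np.prod(grid))
    # flat, contiguous voxel allocation per ROI on the shared label grid
    label_flat = np.zeros(capacity, dtype=np.int16)
    slices: dict[str, slice] = {}
    cursor = 0
    label_ids = [
        r.label_id if r.label_id is not None else i
        for i, r in enumerate(config.rois, start=1)
    ]
    if len(set(label_ids)) != len(label_ids):
        raise ValueError("duplicate ROI label ids")
    for label_id, roi in zip(label_ids, config.rois):
        slices[roi.abbreviation] = slice(cursor, cursor + roi.n_voxels)
        label_flat[slices[roi.abbreviation]] = label_id
        cursor += roi.n_voxels
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])

    paths: dict[str, Path] | None = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        label_img = nib.Nifti1Image(
            label_flat.reshape(grid).astype(np.int16), affine
        )
        label_path = outdir / "labels.nii.gz"
        nib.save(label_img, label_path)
        paths = {"labels": label_path}

    metric_names = sorted({m for r in config.rois for m in r.metrics})
    cohort_rows: list[dict] = []
    truth_rows: list[dict] = []
    for subject_id, group in _subject_ids(config):
        vols = {name: np.full(capacity, np.nan) for name in metric_names}
        tf_vol = np.full(capacity, np.nan)
        for roi in config.rois:
            tf_mean_s = roi.tf_mean[group] + rng.normal(0.0, roi.tf_between_sd)
            tf_mean_s = float(np.clip(tf_mean_s, 0.05, 0.99))
            sl = slices[roi.abbreviation]
            # one TF vector per subject and region, shared by all metrics —
            # a subject has a single tissue-fraction map
            t = _draw_tf(roi.n_voxels, tf_mean_s, roi.tf_spread, rng)
            tf_vol[sl] = t
            for name in metric_names:
                if name not in roi.metrics:
                    continue
                ms = roi.metrics[name]
                mu_s = ms.mu[group] + rng.normal(0.0, ms.between_subject_sd)
                m, m0 = _metric_given_tf(
                    t, ms.kappa[group], mu_s, ms.sigma, rng
                )
                truth = _truth_row(t, m0)
                sample = ROISample(
                    m, t, metric_name=name, roi_label=roi.abbreviation
                )
                s = summarise(sample)
                cohort_rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "roi": roi.abbreviation,
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
                truth_rows.append(
                    {"subject_id": subject_id, "group": group,
                     "roi": roi.abbreviation, "metric": name, **truth}
                )
                vols[name][sl] = sample.metric_values
        if outdir is not None and paths is not None:
            subj_paths = {}
            for name in metric_names:
                p = outdir / f"{subject_id}_{name}.nii.gz"
                nib.save(
                    nib.Nifti1Image(vols[name].reshape(grid), affine,
                                    dtype=np.float64), p
                )
                subj_paths[name] = p
            p = outdir / f"{subject_id}_TF.nii.gz"
            nib.save(
                nib.Nifti1Image(tf_vol.reshape(grid), affine,
                                dtype=np.float64), p
            )
            subj_paths["TF"] = p
            paths[subject_id] = subj_paths  # type: ignore[assignment]

    cohort = pd.DataFrame(cohort_rows, columns=SUMMARY_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return cohort, truth, paths
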