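"""Group-level statistics over cohort tables of ROI summaries.

The workflow mirrors how region-of-interest group studies are usually
run: per-region Welch t-tests on mean tissue fraction, one-sample and
two-sample tests on the conventional-mean bias, Pearson correlation of
bias magnitude against inverse mean TF (the closed-form bias predicts
|bias| proportional to 1/tbar at fixed covariance), a periventricular vs
non-periventricular comparison, and Cohen's d_s effect sizes computed
once per estimator so their distortion by CSF partial volume can be seen
directly.

Primitive tests are implemented explicitly from their textbook formulas
(the test suite cross-checks them against SciPy); Bonferroni correction
treats the set of regions within one metric/test combination as the
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .images import SUMMARY_COLUMNS

__all__ = [
    "TestResult",
    "welch_t_test",
    "one_sample_t_test",
    "bonferroni",
    "cohens_ds",
    "mean_tf_group_comparison",
    "bias_analysis",
    "bias_tf_correlation",
    "periventricular_bias_comparison",
    "effect_size_comparison",
    "GroupAnalysis",
    "GroupAnalysisResults",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: float
    p_value: float


def _check_vector(x: np.ndarray, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"{name} must be 1-D with at least {min_n} values")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def welch_t_test(x, y) -> TestResult:
    """Two-tailed Welch two-sample t-test (unequal variances).

    t = (xbar - ybar) / sqrt(s2x/nx + s2y/ny) with Bessel-corrected
    variances and Welch-Satterthwaite (fractional) degrees of freedom.
    When both groups have zero variance and equal means the test is
    vacuous and p = 1 is returned by convention.
    """
    x = _check_vector(x, 2, "x")
    y = _check_vector(y, 2, "y")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(nx + ny - 2), 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return TestResult(float(t), float(dof), float(p))


def one_sample_t_test(x, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of mean(x) against ``mu0``.

    Zero sample variance leaves t undefined unless the mean equals the
    null value exactly, in which case p = 1.
    """
    x = _check_vector(x, 2, "x")
    n = x.size
    s = x.std(ddof=1)
    if s == 0.0:
        if x.mean() == mu0:
            return TestResult(0.0, float(n - 1), 1.0)
        raise ValueError("zero variance with mean != mu0; t undefined")
    t = (x.mean() - mu0) / (s / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(p))


def bonferroni(p, alpha: float = 0.05, k: int | None = None):
    """Bonferroni family-wise error control: adjusted p = min(1, k*p).

    ``k`` defaults to the number of p-values supplied; pass it explicitly
    when the family is larger than the vector at hand.  Returns
    (adjusted p-values, significance flags at ``alpha``).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if k is None:
        k = p.size
    adj = np.minimum(1.0, k * p)
    return adj, adj < alpha


def cohens_ds(x, y) -> float:
    """Cohen's d_s: standardised mean difference of two independent
    samples using the pooled (Bessel-corrected) standard deviation.

    d = (xbar - ybar) / s_pooled,
    s_pooled = sqrt(((nx-1) s2x + (ny-1) s2y) / (nx+ny-2)).
    """
    x = _check_vector(x, 2, "x")
    y = _check_vector(y, 2, "y")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# Cohort-table workflow


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUMMARY_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    dup = cohort.duplicated(subset=["subject_id", "roi", "metric"])
    if dup.any():
        raise ValueError("duplicate (subject, roi, metric) rows in cohort table")
    return cohort


def _groups(cohort: pd.DataFrame, contrast: tuple[str, str] | None):
    names = list(pd.unique(cohort["group"]))
    if contrast is None:
        if len(names) != 2:
            raise ValueError(
                f"expected exactly two groups, found {names}; pass contrast="
            )
        return names[0], names[1]
    a, b = contrast
    if a not in names or b not in names:
        raise ValueError(f"contrast {contrast} not among groups {names}")
    return a, b


def mean_tf_group_comparison(
    cohort: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region Welch comparison of mean tissue fraction between groups.

    Mean TF is a property of the region, not of the metric, so duplicate
    rows across metrics are collapsed first.  Bonferroni correction runs
    across regions.
    """
    cohort = _check_cohort(cohort)
    ga, gb = _groups(cohort, contrast)
    tf = cohort.drop_duplicates(subset=["subject_id", "roi"])
    rows = []
    for roi, sub in tf.groupby("roi", sort=False):
        x = sub.loc[sub["group"] == ga, "mean_tf"].to_numpy()
        y = sub.loc[sub["group"] == gb, "mean_tf"].to_numpy()
        res = welch_t_test(x, y)
        rows.append(
            {
                "roi": roi,
                "group_a": ga,
                "group_b": gb,
                "mean_a": x.mean(),
                "sd_a": x.std(ddof=1),
                "mean_b": y.mean(),
                "sd_b": y.std(ddof=1),
                "statistic": res.statistic,
                "dof": res.dof,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"], out["significant"] = bonferroni(out["p"], alpha=alpha)
    return out


def bias_analysis(
    cohort: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Test the conventional-mean bias per region and metric.

    Returns two tables:

    ``one_sample``  — per (region, metric, group), two-tailed one-sample
    t-test of the per-subject bias against zero;
    ``between_groups`` — per (region, metric), Welch test of bias between
    the two groups.  Both Bonferroni-corrected across regions within each
    metric (and group, for the one-sample family).
    """
    cohort = _check_cohort(cohort)
    ga, gb = _groups(cohort, contrast)
    one_rows, two_rows = [], []
    for (metric, roi), sub in cohort.groupby(["metric", "roi"], sort=False):
        x = sub.loc[sub["group"] == ga, "bias"].to_numpy()
        y = sub.loc[sub["group"] == gb, "bias"].to_numpy()
        for gname, vals in ((ga, x), (gb, y)):
            res = one_sample_t_test(vals, 0.0)
            one_rows.append(
                {
                    "roi": roi,
                    "metric": metric,
                    "group": gname,
                    "mean_bias": vals.mean(),
                    "sd_bias": vals.std(ddof=1),
                    "statistic": res.statistic,
                    "dof": res.dof,
                    "p": res.p_value,
                }
            )
        res = welch_t_test(x, y)
        two_rows.append(
            {
                "roi": roi,
                "metric": metric,
                "group_a": ga,
                "group_b": gb,
                "mean_a": x.mean(),
                "mean_b": y.mean(),
                "statistic": res.statistic,
                "dof": res.dof,
                "p": res.p_value,
            }
        )
    one = pd.DataFrame(one_rows)
    two = pd.DataFrame(two_rows)
    one["p_adjusted"] = np.nan
    one["significant"] = False
    for _, idx in one.groupby(["metric", "group"]).groups.items():
        adj, sig = bonferroni(one.loc[idx, "p"], alpha=alpha)
        one.loc[idx, "p_adjusted"] = adj
        one.loc[idx, "significant"] = sig
    two["p_adjusted"] = np.nan
    two["significant"] = False
    for _, idx in two.groupby("metric").groups.items():
        adj, sig = bonferroni(two.loc[idx, "p"], alpha=alpha)
        two.loc[idx, "p_adjusted"] = adj
        two.loc[idx, "significant"] = sig
    return {"one_sample": one, "between_groups": two}


def _per_roi_group_means(cohort: pd.DataFrame) -> pd.DataFrame:
    """Between-subject means of |bias| and 1/mean_tf per (metric, group, roi)."""
    df = cohort.copy()
    df["abs_bias"] = df["bias"].abs()
    df["inv_mean_tf"] = 1.0 / df["mean_tf"]
    return (
        df.groupby(["metric", "group", "roi"], sort=False)[
            ["abs_bias", "inv_mean_tf"]
        ]
        .mean()
        .reset_index()
    )


def bias_tf_correlation(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-region mean |bias| against per-region
    mean 1/mean_tf, per metric and group.

    The closed-form bias -Cov(m,t)/tbar predicts |bias| proportional to
    the inverse mean tissue fraction at fixed covariance, so strong
    positive r indicates CSF-partial-volume-driven bias.  Region values
    are between-subject means; needs at least three regions.
    """
    cohort = _check_cohort(cohort)
    per_roi = _per_roi_group_means(cohort)
    rows = []
    for (metric, group), sub in per_roi.groupby(["metric", "group"], sort=False):
        if len(sub) < 3:
            raise ValueError("need at least 3 ROIs for correlation")
        if sub["abs_bias"].nunique() == 1 or sub["inv_mean_tf"].nunique() == 1:
            raise ValueError("constant input; correlation undefined")
        r, p = stats.pearsonr(sub["abs_bias"], sub["inv_mean_tf"])
        rows.append(
            {"metric": metric, "group": group, "r": float(r),
             "p": float(p), "n": len(sub)}
        )
    return pd.DataFrame(rows)


def periventricular_bias_comparison(
    cohort: pd.DataFrame,
    roidefs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch comparison of per-region mean |bias| between periventricular
    and non-periventricular regions, per metric and group.

    One observation per region (bilateral regions are separate rows of
    the definition table); the decision threshold is uncorrected
    ``alpha``.
    """
    cohort = _check_cohort(cohort)
    flags = roidefs.set_index("abbreviation")["periventricular"]
    per_roi = _per_roi_group_means(cohort)
    unknown = set(per_roi["roi"]) - set(flags.index)
    if unknown:
        raise ValueError(f"ROIs without periventricular flag: {sorted(unknown)}")
    per_roi["periventricular"] = per_roi["roi"].map(flags).astype(bool)
    rows = []
    for (metric, group), sub in per_roi.groupby(["metric", "group"], sort=False):
        pv = sub.loc[sub["periventricular"], "abs_bias"].to_numpy()
        npv = sub.loc[~sub["periventricular"], "abs_bias"].to_numpy()
        if pv.size < 2 or npv.size < 2:
            raise ValueError(
                "both periventricular classes need >= 2 ROIs "
                f"(got {pv.size} vs {npv.size})"
            )
        res = welch_t_test(pv, npv)
        rows.append(
            {
                "metric": metric,
                "group": group,
                "mean_abs_bias_pv": pv.mean(),
                "mean_abs_bias_npv": npv.mean(),
                "statistic": res.statistic,
                "dof": res.dof,
                "p": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


def effect_size_comparison(
    cohort: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cohen's d_s for the group contrast, computed per region and metric
    from the conventional mean and again from the tissue-weighted mean.

    When the two groups carry different bias (different CSF partial
    volume, e.g. through atrophy), the conventional-mean effect size is
    distorted relative to the tissue-weighted one; ``difference`` =
    d_conventional - d_tissue_weighted exposes that.  Welch significance
    per estimator, Bonferroni across regions within each metric.
    """
    cohort = _check_cohort(cohort)
    ga, gb = _groups(cohort, contrast)
    rows = []
    for (metric, roi), sub in cohort.groupby(["metric", "roi"], sort=False):
        a = sub[sub["group"] == ga]
        b = sub[sub["group"] == gb]
        row: dict = {"roi": roi, "metric": metric, "group_a": ga, "group_b": gb}
        for colname, tag in (
            ("conventional_mean", "conventional"),
            ("tissue_weighted_mean", "tissue_weighted"),
        ):
            x = a[colname].to_numpy()
            y = b[colname].to_numpy()
            row[f"d_{tag}"] = cohens_ds(x, y)
            res = welch_t_test(x, y)
            row[f"p_{tag}"] = res.p_value
        row["difference"] = row["d_conventional"] - row["d_tissue_weighted"]
        rows.append(row)
    out = pd.DataFrame(rows)
    for tag in ("conventional", "tissue_weighted"):
        out[f"p_adjusted_{tag}"] = np.nan
        out[f"sig_{tag}"] = False
        for _, idx in out.groupby("metric").groups.items():
            adj, sig = bonferroni(out.loc[idx, f"p_{tag}"], alpha=alpha)
            out.loc[idx, f"p_adjusted_{tag}"] = adj
            out.loc[idx, f"sig_{tag}"] = sig
    return out


# ---------------------------------------------------------------------------
# Model-style wrapper


@dataclass
class GroupAnalysisResults:
    """Container for all analysis tables of one cohort run.

    Attributes hold one DataFrame per analysis; :meth:`save` writes each
    as CSV plus a run-metadata text block, :meth:`summary` prints a
    compact overview.
    """

    mean_tf: pd.DataFrame
    bias_one_sample: pd.DataFrame
    bias_between_groups: pd.DataFrame
    bias_tf_correlation: pd.DataFrame
    periventricular: pd.DataFrame
    effect_sizes: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    _TABLES = (
        "mean_tf",
        "bias_one_sample",
        "bias_between_groups",
        "bias_tf_correlation",
        "periventricular",
        "effect_sizes",
    )

    def save(self, outdir) -> list[str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self._TABLES:
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(str(path))
        meta = outdir / "run_metadata.txt"
        with open(meta, "w") as fh:
            for key, val in self.metadata.items():
                fh.write(f"{key}: {val}\n")
        written.append(str(meta))
        return written

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "Group analysis summary",
            "======================",
            f"contrast:            {md.get('contrast')}",
            f"alpha:               {md.get('alpha')}",
            f"Bonferroni family:   {md.get('family')}",
            f"ROIs with lower mean TF in group B (significant): "
            f"{int((self.mean_tf['significant'] & (self.mean_tf['statistic'] > 0)).sum())}"
            f"/{len(self.mean_tf)}",
            f"(roi, metric, group) cells with non-zero bias (significant): "
            f"{int(self.bias_one_sample['significant'].sum())}"
            f"/{len(self.bias_one_sample)}",
        ]
        for rec in self.bias_tf_correlation.itertuples(index=False):
            lines.append(
                f"|bias| vs 1/mean_tf, {rec.metric} {rec.group}: "
                f"r = {rec.r:.3f} (n = {rec.n})"
            )
        diff = self.effect_sizes["difference"]
        lines.append(
            "effect-size distortion d_conv - d_tw: "
            f"median {diff.median():+.3f}, extreme {diff.abs().max():.3f}"
        )
        return "\n".join(lines)


class GroupAnalysis:
    """Full group-difference workflow over a long-format cohort table.

    Parameters
    ----------
    cohort
        Long-format table with :data:`~twroi.images.SUMMARY_COLUMNS`,
        one row per (subject, region, metric).
    roidefs
        ROI definition table (defaults to the packaged JHU table).
    contrast
        Pair (reference group, comparison group) defining the mean
        difference direction; defaults to first-listed minus second.
    alpha
        Family-wise significance level.

    ``fit()`` runs every analysis and returns a
    :class:`GroupAnalysisResults`.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        roidefs: pd.DataFrame | None = None,
        contrast: tuple[str, str] | None = None,
        alpha: float = 0.05,
    ) -> None:
        from .images import load_roi_definitions

        self.cohort = _check_cohort(cohort)
        self.roidefs = load_roi_definitions() if roidefs is None else roidefs
        self.contrast = _groups(self.cohort, contrast)
        self.alpha = float(alpha)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def fit(self) -> GroupAnalysisResults:
        n_rois = self.cohort["roi"].nunique()
        bias_tables = bias_analysis(self.cohort, self.contrast, self.alpha)
        results = GroupAnalysisResults(
            mean_tf=mean_tf_group_comparison(
                self.cohort, self.contrast, self.alpha
            ),
            bias_one_sample=bias_tables["one_sample"],
            bias_between_groups=bias_tables["between_groups"],
            bias_tf_correlation=bias_tf_correlation(self.cohort),
            periventricular=periventricular_bias_comparison(
                self.cohort, self.roidefs, self.alpha
            ),
            effect_sizes=effect_size_comparison(
                self.cohort, self.contrast, self.alpha
            ),
            metadata={
                "contrast": f"{self.contrast[0]} - {self.contrast[1]}",
                "alpha": self.alpha,
                "family": f"{n_rois} ROIs per metric/test combination",
            },
        )
        return results
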