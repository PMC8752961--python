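# twroi — tissue-weighted ROI statistics for diffusion-MRI tissue metrics

Multi-compartment diffusion-MRI models such as NODDI and the free-water
elimination method report, per voxel, metrics of the *tissue* compartment
(e.g. neurite density index NDI, orientation dispersion index ODI)
together with the voxel's tissue fraction TF = 1 − FWF, where FWF is the
estimated free-water (CSF) volume fraction. Region-of-interest studies
then summarise these maps by an ROI mean — and the conventional,
equal-weight arithmetic mean is a **biased** estimate of the mean metric
over the region's tissue whenever the ROI contains CSF partial volume.
The bias is largest in periventricular white matter and in cohorts with
ventricular enlargement (atrophy), where it can under- or over-state
group differences.

`twroi` implements the corrected summary — the **tissue-weighted mean**
— along with the bias decomposition, NIfTI-based ROI extraction, the
group-difference workflow, and a synthetic-cohort generator with exact
ground truth. It is aimed at neuroimaging researchers running atlas-based
ROI analyses of NODDI-style tissue metrics.

## The estimators

For an ROI with voxels *i* = 1…N, metric values *mᵢ* and tissue
fractions *tᵢ*:

- conventional mean m̄ = (1/N) Σ mᵢ
- tissue-weighted mean m̄ₜ = Σ tᵢ mᵢ / Σ tᵢ = t͞m̄ / t̄

and the two are linked by the identity

    m̄ − m̄ₜ = −Cov(m, t) / t̄

with the population (1/N) covariance. The conventional mean is unbiased
only when metric and tissue fraction are uncorrelated within the ROI;
negative correlation inflates it, and at fixed covariance the bias
scales with 1/t̄, i.e. with the degree of CSF contamination. The
tissue-weighted mean of block-averaged voxels reproduces the underlying
tissue mean *exactly* (the weighted sum telescopes into the sum over
tissue sub-elements), which the package demonstrates on fine-grid
phantoms.

## Worked example

```python
import numpy as np
from twroi import ROISample, summarise

ndi = np.array([0.55, 0.60])   # per-voxel NDI
tf  = np.array([0.5, 1.0])     # per-voxel tissue fraction
s = summarise(ROISample(ndi, tf, metric_name="NDI"))
print(f"conventional mean   : {s.conventional_mean:.4f}")
print(f"tissue-weighted mean: {s.tissue_weighted_mean:.4f}")
print(f"bias (conv - tw)    : {s.bias:+.4f}")
```

```
conventional mean   : 0.5750
tissue-weighted mean: 0.5833
bias (conv - tw)    : -0.0083
```

The half-CSF voxel (TF = 0.5) is over-weighted by the conventional mean,
dragging it below the tissue's true mean NDI; the tissue-weighted mean
down-weights it in proportion to its tissue content, and the bias equals
−Cov(m, t)/t̄ = −0.0083 exactly.

At cohort scale, simulate a 21-vs-30-subject study over the 48 packaged
JHU white-matter regions and run the full group workflow:

```python
from twroi import GroupAnalysis
from twroi.simulate import default_config, simulate_cohort

cohort, truth, _ = simulate_cohort(default_config(seed=1))
print(GroupAnalysis(cohort).fit().summary())
```

```
Group analysis summary
======================
contrast:            control - patient
alpha:               0.05
Bonferroni family:   48 ROIs per metric/test combination
ROIs with lower mean TF in group B (significant): 46/48
(roi, metric, group) cells with non-zero bias (significant): 177/192
|bias| vs 1/mean_tf, NDI control: r = 0.889 (n = 48)
|bias| vs 1/mean_tf, ODI control: r = 0.874 (n = 48)
|bias| vs 1/mean_tf, NDI patient: r = 0.948 (n = 48)
|bias| vs 1/mean_tf, ODI patient: r = 0.947 (n = 48)
effect-size distortion d_conv - d_tw: median -0.003, extreme 0.095
```

The simulated patient group has lower tissue fractions (atrophy) and a
stronger negative ODI/TF coupling, so almost every region shows
significantly lower mean TF in patients, widespread non-zero bias, and
bias magnitudes that track the inverse mean tissue fraction — the
pattern the tissue-weighted mean is designed to correct.

## Command line

The same workflow is scriptable:

```sh
twroi simulate --outdir sim --seed 1                # synthetic cohort + NIfTI volumes
twroi roistats --metric NDI=ndi.nii.gz --metric ODI=odi.nii.gz \
      --tf fwf.nii.gz --tf-kind freewater \
      --labels jhu_labels.nii.gz \
      --subject-id sub01 --group control --out sub01.csv
twroi group --table cohort.csv --alpha 0.05 --outdir results/
```

`roistats` accepts either a tissue-fraction map (`--tf-kind tissue`) or
a free-water-fraction map (`--tf-kind freewater`, converted as 1 − FWF),
and requires all images on one voxel grid — atlas propagation /
registration is out of scope. ROI definitions default to the packaged
JHU ICBM-DTI-81 table (48 regions with periventricular flags); pass
`--roidefs` to use another atlas.

## Documentation

See `docs/methods.md` for the statistical model, generator design,
numerical conventions, and known limitations.
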