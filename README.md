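# atrophybench

Quantifying how image modifications perturb **voxel-wise normative
brain-atrophy z-score maps**, on fully synthetic gray-matter phantoms.

Anonymizing structural brain MRI by *defacing* (removing or replacing facial
features) is standard practice before data sharing — but the modified voxels
can leak into downstream morphometry. Automated single-subject atrophy
estimation compares a patient's preprocessed gray-matter (GM) density map
against sex- and age-specific normative templates: for each voxel *v* inside
a GM analysis mask,

```
z(v) = (GM_subject(v) − mean_ref(v)) / sd_ref(v)
```

where the reference mean/SD maps are computed over healthy subjects of the
same sex whose age lies within ±2 years of the patient's. Negative z means
GM density below the peer reference; |z| ≤ 2.5 is conventionally read as
volume change within expected limits.

`atrophybench` measures the *impact* of an image modification as the
root-mean-square error between the z-maps of the original and modified scans
over the mask,

```
RMSE = sqrt( mean_v∈mask ( z_modified(v) − z_original(v) )² )
```

and puts it in context with a **test–retest benchmark**: the RMSE between
z-maps of two unmodified same-session acquisitions of the same subject. Two
outlier criteria flag meaningfully impacted cases:

* **benchmark percentile** — RMSE strictly greater than the 75th percentile
  of the benchmark RMSE distribution;
* **iterative Grubbs's test** (maximum normalized residual,
  G = maxᵢ |xᵢ − x̄| / s, two-sided, α = 0.05), removing each detected
  outlier and retesting until none remain.

Because real defacing binaries and MRI preprocessing are out of scope, the
package ships a synthetic-cohort generator: ellipsoidal GM phantoms with
smooth age-related decline, a sex offset, smooth between-subject and
within-scan random fields, patients with regionally planted atrophy of known
z-magnitude, repeat-scan noise, and parameterized perturbation operators
(localized bias fields, global scaling, sub-voxel jitter, regional erosion,
stochastic "crashes") that emulate defacing-style corruption.

## Worked example

```python
import atrophybench as ab

cfg = ab.default_config(seed=1)          # 32³ phantom, 4 perturbation presets
report = ab.run_experiment(cfg)
print(ab.render_report_text(report))
```

prints (numbers produced by this exact call):

```
Benchmark (test-retest) RMSE:
  mean 0.30 +/- 0.01  range 0.28-0.33  75th percentile 0.31  (n=30)

method                failed    mean RMSE +/- SD               range (IQR)      Grubbs   benchmark
gentle_mask             0/30      0.03 +/- 0.00   0.02-0.03 (0.03-0.03)     0 (0.0%)     0 (0.0%)
frontal_bias            0/30      0.18 +/- 0.00   0.17-0.18 (0.17-0.18)     0 (0.0%)     0 (0.0%)
temporal_erosion        0/30      0.08 +/- 0.00   0.08-0.09 (0.08-0.08)     0 (0.0%)     0 (0.0%)
global_reface           3/30      0.54 +/- 0.01   0.51-0.56 (0.53-0.55)     0 (0.0%)    27 (100.0%)

processing success: 97.5% (117/120)
```

Reading it: the test–retest benchmark RMSE is ~0.30, so z-maps of two
acquisitions of the same head differ by about a third of a z-unit per voxel —
the noise floor of the whole pipeline. A gentle face-region bias
(`gentle_mask`) sits far below that floor and flags no outliers; a strong
global modification (`global_reface`) exceeds the 75th-percentile benchmark
threshold for every successfully processed case and also crashes on 3 of 30
patients, which is booked separately from the RMSE statistics.

The same experiment is available from the shell:

```bash
atrophybench evaluate --seed 1 --out results/
atrophybench report --results results/
```

with subcommands `simulate`, `build-templates`, `zmap` and `benchmark` for
the individual stages; a YAML config (see
`atrophybench.pipeline.ExperimentConfig`) drives all of them. Volumes are
written as NIfTI, per-subject tables as TSV, the report as JSON plus the
rendered text table.

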