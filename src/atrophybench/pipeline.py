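"""End-to-end experiment: cohort -> templates -> z-maps -> RMSE -> outliers.

Reproduces the structure of a perturbation-impact study on synthetic data:

1. a reference cohort is generated and sex/age-windowed normative templates
   are built per patient stratum (cached by sex and rounded age);
2. a test-retest **benchmark** is computed: for each benchmark subject two
   independent same-session acquisitions are simulated and the RMSE between
   their z-maps measured; the 75th percentile of these RMSEs becomes the
   outlier threshold for the perturbation arms;
3. each patient's full-face scan is perturbed by every configured operator,
   z-maps are compared, and per-method RMSE distributions, iterative-Grubbs
   and benchmark-percentile outliers, failure counts and spatial deviation
   maps are reported.

Patients, benchmark subjects and the reference cohort are three disjoint
sets drawn from the same generator.  Everything is deterministic given the
configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .grid import GridSpec, build_region_atlas
from .synthetic import (CohortSpec, PerturbationSpec, PerturbationFailure,
                        SubjectScan, mean_model, generate_reference_cohort,
                        generate_patient_scan, simulate_repeat,
                        apply_perturbation, default_perturbation_suite)
from .templates import (NormativeTemplate, AnalysisMask, select_reference_subjects,
                        build_template, derive_gm_mask, InsufficientReferenceError,
                        DEFAULT_WINDOW, DEFAULT_MIN_N, DEFAULT_MEAN_THRESHOLD,
                        DEFAULT_SD_FLOOR)
from .zscore import zscore_map
from .metrics import ImpactRecord, rmse, deviation_map, summarize_rmse
from .outliers import iterative_grubbs, benchmark_outliers
from . import io as abio

__all__ = ["ExperimentConfig", "PatientSpec", "BenchmarkSpec", "TemplateParams",
           "OutlierParams", "ConfigError", "TemplateProvider", "run_benchmark",
           "run_experiment", "render_report_text", "default_config"]


class ConfigError(ValueError):
    """Configuration-level failure detected before subject processing."""


@dataclass(frozen=True)
class PatientSpec:
    """Demographics and planted pathology of the synthetic patient group."""

    n: int = 30
    age_range: tuple[float, float] = (55.0, 74.0)
    sex_ratio: float = 0.5
    atrophy_regions: dict = field(default_factory=lambda: {"temporal": 2.5})
    acquisition_noise_sd: float = 0.011
    seed: int = 101


@dataclass(frozen=True)
class BenchmarkSpec:
    """Test-retest arm: two independent acquisitions per subject."""

    n: int = 30
    repeat_sd: float = 0.011
    seed: int = 202


@dataclass(frozen=True)
class TemplateParams:
    window: float = DEFAULT_WINDOW
    min_n: int = DEFAULT_MIN_N
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD
    sd_floor: float = DEFAULT_SD_FLOOR
    #: "cohort" estimates templates from the generated reference cohort;
    #: "analytic" uses the generator's exact mean model with a spatially
    #: constant SD (``analytic_sd``) — the controlled setting for noise
    #: calibration studies.
    mode: str = "cohort"
    analytic_sd: float = 0.054


@dataclass(frozen=True)
class OutlierParams:
    alpha: float = 0.05
    percentile: float = 75.0


@dataclass(frozen=True)
class ExperimentConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    reference: CohortSpec = field(default_factory=CohortSpec)
    patients: PatientSpec = field(default_factory=PatientSpec)
    benchmark: BenchmarkSpec = field(default_factory=BenchmarkSpec)
    perturbations: tuple = ()
    template: TemplateParams = field(default_factory=TemplateParams)
    outliers: OutlierParams = field(default_factory=OutlierParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["perturbations"] = [asdict(p) for p in self.perturbations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        kwargs = {}
        if "grid" in d:
            g = dict(d["grid"])
            g["shape"] = tup(g.get("shape", (32, 32, 32)))
            g["voxel_size"] = tup(g.get("voxel_size", (4.0, 4.0, 4.0)))
            kwargs["grid"] = GridSpec(**g)
        if "reference" in d:
            r = dict(d["reference"])
            if "age_range" in r:
                r["age_range"] = tup(r["age_range"])
            kwargs["reference"] = CohortSpec(**r)
        if "patients" in d:
            p = dict(d["patients"])
            if "age_range" in p:
                p["age_range"] = tup(p["age_range"])
            kwargs["patients"] = PatientSpec(**p)
        if "benchmark" in d:
            kwargs["benchmark"] = BenchmarkSpec(**d["benchmark"])
        if "template" in d:
            kwargs["template"] = TemplateParams(**d["template"])
        if "outliers" in d:
            kwargs["outliers"] = OutlierParams(**d["outliers"])
        if "perturbations" in d:
            perts = []
            for pd_ in d["perturbations"]:
                pd_ = dict(pd_)
                if "bias_center" in pd_:
                    pd_["bias_center"] = tup(pd_["bias_center"])
                perts.append(PerturbationSpec(**pd_))
            kwargs["perturbations"] = tuple(perts)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_config(seed: int = 0) -> ExperimentConfig:
    """Default experiment: 32^3 phantom, age-targeted reference cohort.

    The reference cohort is sampled uniformly over ages 50-77 (enriched over
    the patient age range 55-74) with balanced sexes so that every patient's
    sex/age +-2-year stratum comfortably exceeds the minimum reference count
    for any seed; patients carry planted temporal atrophy of 2.5 z-units.
    """
    return ExperimentConfig(
        grid=GridSpec(shape=(32, 32, 32), voxel_size=(4.0, 4.0, 4.0)),
        reference=CohortSpec(n_subjects=500, age_range=(50.0, 77.0),
                             age_mean=None, sex_ratio=0.5, seed=seed),
        patients=PatientSpec(seed=seed + 1_000_001),
        benchmark=BenchmarkSpec(seed=seed + 2_000_002),
        perturbations=tuple(default_perturbation_suite(seed + 3_000_003)),
    )


class TemplateProvider:
    """Per-stratum normative templates with caching keyed by (sex, rounded age).

    In ``cohort`` mode templates are estimated from the reference cohort; in
    ``analytic`` mode the exact generator mean model is used with a constant
    SD map.  The single pooled analysis mask (one mask for all subjects, so
    RMSEs are comparable across subjects) comes from a template over the
    whole cohort, or from the analytic model at the pooled reference age.
    """

    def __init__(self, config: ExperimentConfig,
                 cohort: list[SubjectScan] | None = None):
        self.config = config
        self.params = config.template
        self.grid = config.grid
        self._cache: dict[tuple[str, int], NormativeTemplate] = {}
        if self.params.mode == "cohort":
            if cohort is None:
                cohort = generate_reference_cohort(config.reference, config.grid)
            self.cohort = cohort
        elif self.params.mode == "analytic":
            self.cohort = []
        else:
            raise ConfigError(f"unknown template mode {self.params.mode!r}")

    def get(self, sex: str, age: float) -> NormativeTemplate:
        key = (sex, int(round(age)))
        if key not in self._cache:
            self._cache[key] = self._build(sex, float(key[1]))
        return self._cache[key]

    def _build(self, sex: str, target_age: float) -> NormativeTemplate:
        p = self.params
        if p.mode == "analytic":
            mean = mean_model(self.config.reference, self.grid, target_age, sex)
            sd = np.full(self.grid.shape, p.analytic_sd)
            return NormativeTemplate(mean_map=mean, sd_map=sd, sex=sex,
                                     target_age=target_age, window=p.window,
                                     n_ref=0)
        selected = select_reference_subjects(self.cohort, sex, target_age, p.window)
        return build_template(selected, sex, target_age, p.window, p.min_n)

    def pooled_mask(self) -> AnalysisMask:
        p = self.params
        if p.mode == "analytic":
            ages = self.config.patients.age_range
            mid = 0.5 * (ages[0] + ages[1])
            mean = mean_model(self.config.reference, self.grid, mid, "F")
            sd = np.full(self.grid.shape, p.analytic_sd)
            pooled = NormativeTemplate(mean_map=mean, sd_map=sd, sex="pooled",
                                       target_age=mid, window=p.window, n_ref=0)
        else:
            stack = np.stack([s.volume for s in self.cohort], axis=0)
            pooled = NormativeTemplate(
                mean_map=stack.mean(axis=0), sd_map=stack.std(axis=0, ddof=1),
                sex="pooled",
                target_age=float(np.mean([s.age for s in self.cohort])),
                window=p.window, n_ref=len(self.cohort))
        return derive_gm_mask(pooled, p.mean_threshold, p.sd_floor)


def _draw_demographics(rng: np.random.Generator, n: int,
                       age_range: tuple[float, float],
                       sex_ratio: float) -> list[tuple[float, str]]:
    out = []
    for _ in range(n):
        age = float(rng.uniform(age_range[0], age_range[1]))
        sex = "F" if rng.random() < sex_ratio else "M"
        out.append((age, sex))
    return out


def _precheck_strata(provider: TemplateProvider,
                     demographics: list[tuple[float, str]]) -> None:
    missing = []
    for age, sex in demographics:
        try:
            provider.get(sex, age)
        except InsufficientReferenceError as exc:
            missing.append(str(exc))
    if missing:
        raise ConfigError(
            "insufficient reference subjects for "
            f"{len(missing)} stratum/strata:\n" + "\n".join(sorted(set(missing)))
        )


def run_benchmark(config: ExperimentConfig,
                  provider: TemplateProvider | None = None,
                  mask: AnalysisMask | None = None) -> dict:
    """Test-retest benchmark: RMSE between z-maps of two repeat acquisitions.

    Each benchmark subject's anatomy is the cohort mean model for a drawn
    age/sex; two independent smoothed-noise acquisitions (point SD
    ``repeat_sd``) of it are z-scored against the subject's normative
    template, and the RMSE of their z-difference is recorded.  Returns the
    RMSE list, its summary, and the percentile threshold used downstream.
    """
    if provider is None:
        provider = TemplateProvider(config)
    if mask is None:
        mask = provider.pooled_mask()
    bm = config.benchmark
    pat = config.patients
    rng = np.random.default_rng(bm.seed)
    demographics = _draw_demographics(rng, bm.n, pat.age_range, pat.sex_ratio)
    _precheck_strata(provider, demographics)

    records: list[ImpactRecord] = []
    values: list[float] = []
    fwhm = config.reference.smoothness_fwhm
    for i, (age, sex) in enumerate(demographics):
        clean = SubjectScan(volume=mean_model(config.reference, config.grid, age, sex),
                            age=age, sex=sex, subject_id=f"bench{i:04d}")
        seed_a = (bm.seed + 7919 * i + 1) % 2**31
        seed_b = (bm.seed + 7919 * i + 104729) % 2**31
        acq_a = simulate_repeat(clean, bm.repeat_sd, fwhm, seed_a, grid=config.grid)
        acq_a.condition = "fullface"
        acq_b = simulate_repeat(clean, bm.repeat_sd, fwhm, seed_b, grid=config.grid)
        template = provider.get(sex, age)
        za = zscore_map(acq_a, template, mask)
        zb = zscore_map(acq_b, template, mask)
        val = rmse(za, zb, mask)
        values.append(val)
        records.append(ImpactRecord(subject_id=clean.subject_id,
                                    condition_a="fullface", condition_b="repeat",
                                    rmse=val))
    summary = summarize_rmse(records)
    threshold = float(np.percentile(values, config.outliers.percentile))
    grubbs = iterative_grubbs(values, config.outliers.alpha,
                              ids=[r.subject_id for r in records])
    return {"records": records, "values": values, "summary": summary,
            "threshold": threshold, "grubbs": grubbs}


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Full perturbation-impact experiment; optionally writes all artifacts.

    Returns a report dictionary with the benchmark summary and, per
    perturbation method, the RMSE distribution, failure counts and both
    outlier criteria; deviation maps and per-subject records ride along under
    ``"arrays"`` / ``"records"`` keys (not serialized into the JSON report).
    """
    provider = TemplateProvider(config)
    mask = provider.pooled_mask()
    atlas = build_region_atlas(config.grid)

    bench = run_benchmark(config, provider, mask)

    pat = config.patients
    rng = np.random.default_rng(pat.seed)
    demographics = _draw_demographics(rng, pat.n, pat.age_range, pat.sex_ratio)
    _precheck_strata(provider, demographics)

    fwhm = config.reference.smoothness_fwhm
    patients: list[SubjectScan] = []
    z_fullface = []
    for j, (age, sex) in enumerate(demographics):
        template = provider.get(sex, age)
        clean = generate_patient_scan(age, sex, dict(pat.atrophy_regions),
                                      template, atlas, cohort=config.reference,
                                      subject_id=f"pat{j:04d}")
        if pat.acquisition_noise_sd > 0:
            scan = simulate_repeat(clean, pat.acquisition_noise_sd, fwhm,
                                   (pat.seed + 7919 * j + 13) % 2**31,
                                   grid=config.grid)
            scan.condition = "fullface"
        else:
            scan = clean
        patients.append(scan)
        z_fullface.append(zscore_map(scan, template, mask))

    methods: dict[str, dict] = {}
    records_by_method: dict[str, list[ImpactRecord]] = {}
    deviation_by_method: dict[str, np.ndarray] = {}
    for pert in config.perturbations:
        records: list[ImpactRecord] = []
        pairs = []
        for j, scan in enumerate(patients):
            pert_j = pert.with_seed((pert.seed * 100_003 + 9176 * j + 7) % 2**31)
            result = apply_perturbation(scan, pert_j, atlas)
            if isinstance(result, PerturbationFailure):
                records.append(ImpactRecord(subject_id=scan.subject_id,
                                            condition_a=f"perturbed:{pert.name}",
                                            condition_b="fullface",
                                            status=f"failed:{result.stage}"))
                continue
            template = provider.get(scan.sex, scan.age)
            zp = zscore_map(result, template, mask)
            val = rmse(zp, z_fullface[j], mask)
            records.append(ImpactRecord(subject_id=scan.subject_id,
                                        condition_a=f"perturbed:{pert.name}",
                                        condition_b="fullface", rmse=val))
            pairs.append((zp, z_fullface[j]))
        records_by_method[pert.name] = records

        ok = [r for r in records if r.ok]
        entry: dict = {"n_total": len(records),
                       "n_failed": len(records) - len(ok),
                       "n_ok": len(ok)}
        if ok:
            summary = summarize_rmse(records)
            grubbs = iterative_grubbs([r.rmse for r in ok], config.outliers.alpha,
                                      ids=[r.subject_id for r in ok])
            bench_rep = benchmark_outliers(records, bench["values"],
                                           config.outliers.percentile)
            entry["rmse"] = summary.as_dict()
            entry["grubbs_outliers"] = {
                "count": grubbs.n_flagged,
                "pct": 100.0 * grubbs.n_flagged / len(ok),
                "ids": list(grubbs.flagged_ids),
                "alpha": config.outliers.alpha,
            }
            entry["benchmark_outliers"] = {
                "count": bench_rep.n_flagged,
                "pct": 100.0 * bench_rep.n_flagged / len(ok),
                "ids": list(bench_rep.flagged_ids),
                "threshold": bench_rep.parameters["threshold"],
            }
            dev = deviation_map(pairs, mask)
            deviation_by_method[pert.name] = dev.map
        methods[pert.name] = entry

    n_attempts = len(config.perturbations) * pat.n
    n_success = sum(m["n_ok"] for m in methods.values())
    report = {
        "benchmark": {
            **bench["summary"].as_dict(),
            "threshold_p75": bench["threshold"],
            "grubbs_outlier_count": bench["grubbs"].n_flagged,
        },
        "methods": methods,
        "n_patients": pat.n,
        "n_attempts": n_attempts,
        "processing_success_pct": (100.0 * n_success / n_attempts
                                   if n_attempts else 100.0),
        "config": config.to_dict(),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        abio.write_records_tsv(bench["records"], outdir / "benchmark.tsv")
        for name, recs in records_by_method.items():
            abio.write_records_tsv(recs, outdir / f"rmse_{name}.tsv")
        for name, dev in deviation_by_method.items():
            abio.save_volume(np.nan_to_num(dev, nan=0.0), config.grid,
                             outdir / f"deviation_{name}.nii")
        abio.save_mask(mask, config.grid, outdir / "analysis")
        abio.write_json(outdir / "report.json", report)
        (outdir / "report.txt").write_text(render_report_text(report))

    report["arrays"] = {"deviation_maps": deviation_by_method,
                        "mask": mask.mask}
    report["records"] = {"benchmark": bench["records"], **records_by_method}
    return report


def render_report_text(report: dict) -> str:
    """Plain-text summary table mirroring the benchmark + per-method layout."""
    b = report["benchmark"]
    lines = [
        "Benchmark (test-retest) RMSE:",
        (f"  mean {b['mean']:.2f} +/- {b['sd']:.2f}  "
         f"range {b['min']:.2f}-{b['max']:.2f}  "
         f"75th percentile {b['threshold_p75']:.2f}  (n={b['n_ok']})"),
        "",
        f"{'method':<20}{'failed':>8}{'mean RMSE +/- SD':>20}"
        f"{'range (IQR)':>26}{'Grubbs':>12}{'benchmark':>12}",
    ]
    for name, m in report["methods"].items():
        if m["n_ok"] == 0:
            lines.append(f"{name:<20}{m['n_failed']}/{m['n_total']:>4}"
                         + " " * 18 + "-- no successful cases --")
            continue
        r = m["rmse"]
        g = m["grubbs_outliers"]
        k = m["benchmark_outliers"]
        lines.append(
            f"{name:<20}"
            f"{str(m['n_failed']) + '/' + str(m['n_total']):>8}"
            f"{r['mean']:>10.2f} +/- {r['sd']:.2f}"
            f"   {r['min']:.2f}-{r['max']:.2f} ({r['q25']:.2f}-{r['q75']:.2f})"
            f"{g['count']:>6} ({g['pct']:.1f}%)"
            f"{k['count']:>6} ({k['pct']:.1f}%)"
        )
    lines.append("")
    lines.append(f"processing success: {report['processing_success_pct']:.1f}% "
                 f"({report['n_attempts'] - sum(m['n_failed'] for m in report['methods'].values())}"
                 f"/{report['n_attempts']})")
    return "\n".join(lines) + "\n"
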