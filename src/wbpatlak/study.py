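"""End-to-end synthetic study: simulate → extract → fit → quantify → compare.

Emulates the clinical study design: a cohort of subjects (default 21) each
receives one simulated 75-min standard dynamic scan; the two-short-dynamic
dataset is the exact frame subset of that session (0–6 min + 60–75 min).
Per subject, MR_FDG and DV maps are produced from both arms with the
identical fit code path — only the input-function integral differs — VOIs
are defined on the standard maps and copied unchanged to the two-short
maps, and max/mean/peak values are extracted.  Pooled paired samples per
metric then run through the Passing–Bablok / Bland–Altman / Spearman
battery.

Per-organ kinetic parameters are drawn around macro targets (MR_FDG and DV
means representative of normal-organ FDG physiology at ~5.5 mmol/L
glucose); blood glucose is truncated below the clinical exclusion bound of
11 mmol/L (≈198 mg/dl).
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import (DynamicImage, NoiseModel, PhantomSpec, Region,
                          build_schedule, render_phantom)
from .agreement import MetricAgreement, PairedSample, compare_methods
from .idif import extract_idif, fit_gap_model, merge_tacs, read_tac_csv, split_tac, write_tac_csv
from .kinetics import KineticParams, feng4_default
from .patlak import make_maps
from .voi import peak_sphere_means, region_stats, segment_threshold41, sphere_voi

__all__ = ["OrganSpec", "StudyConfig", "StudyResult", "build_phantom",
           "simulate_subject", "run_study", "METRICS"]

METRICS = ["MR-max", "MR-mean", "MR-peak", "DV-max", "DV-mean", "DV-peak"]

#: reference glucose (mmol/L) used to convert the organ MR targets to Ki
REFERENCE_GLUCOSE = 5.5


@dataclass(frozen=True)
class OrganSpec:
    """Macro-level kinetic targets and geometry for one normal organ."""

    name: str
    mr_mean: float            # µmol/min/ml at the reference glucose
    dv_mean: float            # percent
    vb: float
    beta: float               # k2 + k3 (1/min)
    center: tuple             # voxel indices
    diameter_mm: float
    voi_diameter_mm: float = 10.0

    def macro_targets(self):
        return self.mr_mean / REFERENCE_GLUCOSE, self.dv_mean / 100.0


DEFAULT_ORGANS = (
    OrganSpec("brain",      0.17, 59.17, 0.04, 0.30, (24, 24, 40), 40.0),
    OrganSpec("lung",       0.01,  4.14, 0.02, 0.25, (12, 17, 30), 30.0),
    OrganSpec("liver",      0.04, 28.35, 0.10, 0.25, (15, 24, 15), 40.0, 25.0),
    OrganSpec("spleen",     0.04, 21.89, 0.10, 0.25, (35, 28, 15), 20.0),
    OrganSpec("heart_wall", 0.12, 48.83, 0.10, 0.30, (24, 17, 29), 24.0),
    OrganSpec("bone",       0.04, 14.62, 0.04, 0.25, (38, 38, 30), 16.0),
    OrganSpec("muscle",     0.01,  6.96, 0.03, 0.25, (10, 38, 14), 22.0),
)

#: candidate lesion centres, all clear of the default organs and aorta
LESION_CANDIDATES = ((36, 12, 38), (10, 10, 40), (38, 24, 42), (10, 28, 40),
                     (36, 36, 12), (24, 6, 12), (40, 10, 16), (8, 24, 28))

AORTA_BOUNDS = ((23, 24), (30, 31), (8, 44))


@dataclass
class StudyConfig:
    """Reproducible study description; every random draw flows from ``seed``."""

    n_subjects: int = 21
    seed: int = 20220428
    sigma0: float = 0.5               # noise scale, kBq/ml·min^0.5
    glucose_mean: float = 5.5         # mmol/L
    glucose_sd: float = 1.2
    glucose_max: float = 10.9         # exclusion bound (< 11 mmol/L ≈ 198 mg/dl)
    glucose_min: float = 3.5
    subject_cv: float = 0.15          # between-subject spread of Ki and V
    gap_family: str = "tri_exponential"
    lesion_count_range: tuple = (1, 3)
    lesion_ki_range: tuple = (0.02, 0.06)
    lesion_v_range: tuple = (0.3, 0.7)
    lesion_vb: float = 0.08
    lesion_diameter_range_mm: tuple = (12.0, 18.0)
    dose_mbq: float = 260.0           # ≈ 3.71 MBq/kg × 70 kg
    weight_kg: float = 70.0
    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 4.0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.glucose_max >= 11.0:
            raise ValueError("glucose_max must stay below 11 mmol/L")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def build_phantom(cfg: StudyConfig, rng: np.random.Generator,
                  noiseless_targets: bool = False):
    """One subject's phantom: organs + lesions + aorta, with drawn kinetics.

    Returns (PhantomSpec, glucose, truth) where truth maps region name to
    its (ki_true, v_true).  ``noiseless_targets`` pins every draw at its
    central value (used for idealized runs).
    """
    glucose = (cfg.glucose_mean if noiseless_targets else
               _truncnorm(rng, cfg.glucose_mean, cfg.glucose_sd,
                          cfg.glucose_min, cfg.glucose_max))
    regions = []
    truth = {}
    for org in DEFAULT_ORGANS:
        ki0, v0 = org.macro_targets()
        if noiseless_targets:
            ki, v = ki0, v0
        else:
            ki = ki0 * _truncnorm(rng, 1.0, cfg.subject_cv, 0.5, 1.6)
            v = v0 * _truncnorm(rng, 1.0, cfg.subject_cv, 0.5, 1.6)
        v = max(v, org.vb + 1e-3)
        p = KineticParams.from_macro(ki, v, org.vb, org.beta)
        regions.append(Region(org.name, "sphere", org.center, org.diameter_mm,
                              params=p))
        truth[org.name] = (p.ki_true, p.v_true)

    n_lo, n_hi = cfg.lesion_count_range
    n_lesions = 1 if noiseless_targets else int(rng.integers(n_lo, n_hi + 1))
    centers = (LESION_CANDIDATES[:n_lesions] if noiseless_targets else
               [LESION_CANDIDATES[i] for i in
                rng.choice(len(LESION_CANDIDATES), n_lesions, replace=False)])
    for j, c in enumerate(centers):
        if noiseless_targets:
            ki, v, d = 0.04, 0.5, 14.0
        else:
            ki = float(rng.uniform(*cfg.lesion_ki_range))
            v = float(rng.uniform(*cfg.lesion_v_range))
            d = float(rng.uniform(*cfg.lesion_diameter_range_mm))
        p = KineticParams.from_macro(ki, v, cfg.lesion_vb, 0.30)
        name = f"lesion_{j}"
        regions.append(Region(name, "sphere", tuple(c), d, params=p))
        truth[name] = (p.ki_true, p.v_true)

    regions.append(Region("aorta", "box", bounds=AORTA_BOUNDS, params=None))
    spec = PhantomSpec(cfg.grid_shape, cfg.voxel_size_mm, tuple(regions),
                       "aorta", glucose)
    return spec, glucose, truth


def simulate_subject(cfg: StudyConfig, subject: int, out_dir: Path | None = None,
                     noiseless: bool = False) -> pd.DataFrame:
    """Simulate one subject and return paired region stats for both arms."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subject,))
    rng = np.random.default_rng(ss)
    spec, glucose, truth = build_phantom(cfg, rng, noiseless_targets=noiseless)
    input_fn = feng4_default(scale=1.0 if noiseless else
                             float(rng.uniform(0.8, 1.2)))
    noise_seed = int(rng.integers(2 ** 31))
    noise = None if (noiseless or cfg.sigma0 == 0) else \
        NoiseModel(cfg.sigma0, noise_seed)

    sched = build_schedule("standard")
    img_std = render_phantom(spec, input_fn, sched, noise)
    # the two-short dataset is the exact frame subset of the same session
    img_tsd = img_std.restrict([(0.0, 6.0), (60.0, 75.0)])

    aorta_mask = spec.masks()["aorta"]
    idif_std = extract_idif(img_std, aorta_mask)
    idif_tsd = extract_idif(img_tsd, aorta_mask)
    # the merged-CSV workflow: split, merge, (optionally persist), refit
    early, late = split_tac(idif_tsd, at=6.0)
    merged = merge_tacs(early, late)
    if out_dir is not None:
        write_tac_csv(merged, out_dir / f"subject{subject:02d}_idif_merged.csv")
        merged = read_tac_csv(out_dir / f"subject{subject:02d}_idif_merged.csv")
    gap = fit_gap_model(merged, cfg.gap_family)

    maps_std = make_maps(img_std, idif_std, glucose, gap=None,
                         dose_mbq=cfg.dose_mbq, weight_kg=cfg.weight_kg)
    maps_tsd = make_maps(img_tsd, merged, glucose, gap=gap,
                         dose_mbq=cfg.dose_mbq, weight_kg=cfg.weight_kg)

    # VOIs on the standard maps, copied unchanged to the two-short maps
    vois = {}
    for org in DEFAULT_ORGANS:
        vois[org.name] = ("organ", sphere_voi(org.center, org.voi_diameter_mm,
                                              cfg.grid_shape, cfg.voxel_size_mm))
    masks = spec.masks()
    for r in spec.regions:
        if r.name.startswith("lesion"):
            # seed at the hottest MR voxel inside the lesion geometry (the
            # voxel a reader would click), robust to noise at the centre
            lesion_mr = np.where(masks[r.name], maps_std.mr_map, -np.inf)
            seed = np.unravel_index(int(np.nanargmax(lesion_mr)),
                                    lesion_mr.shape)
            vois[r.name] = ("lesion",
                            segment_threshold41(maps_std.mr_map, seed))

    rows = []
    planes = {"MR": (maps_std.mr_map, maps_tsd.mr_map),
              "DV": (maps_std.dv_map, maps_tsd.dv_map)}
    sphere_cache = {(q, arm): peak_sphere_means(m, cfg.voxel_size_mm)
                    for q, pair in planes.items()
                    for arm, m in zip(("std", "tsd"), pair)}
    for name, (kind, voi) in vois.items():
        for q, (m_std, m_tsd) in planes.items():
            st = region_stats(m_std, voi, cfg.voxel_size_mm, sphere_cache[(q, "std")])
            ts = region_stats(m_tsd, voi, cfg.voxel_size_mm, sphere_cache[(q, "tsd")])
            for stat in ("max", "mean", "peak"):
                rows.append({
                    "subject": subject, "region": name, "region_type": kind,
                    "metric": f"{q}-{stat}",
                    "std": getattr(st, stat), "tsd": getattr(ts, stat),
                    "glucose": glucose,
                    "ki_true": truth.get(name, (np.nan, np.nan))[0],
                    "v_true": truth.get(name, (np.nan, np.nan))[1],
                })
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Pooled paired values and the agreement battery per metric."""

    paired: pd.DataFrame
    agreement: dict            # group -> metric -> MetricAgreement
    config: StudyConfig

    def agreement_frame(self) -> pd.DataFrame:
        rows = []
        for group, metrics in self.agreement.items():
            for metric, res in metrics.items():
                rows.append({
                    "group": group, "metric": metric, "n": res.pb.n,
                    "intercept_A": res.pb.intercept,
                    "intercept_A_ci_lo": res.pb.intercept_ci[0],
                    "intercept_A_ci_hi": res.pb.intercept_ci[1],
                    "slope_B": res.pb.slope,
                    "slope_B_ci_lo": res.pb.slope_ci[0],
                    "slope_B_ci_hi": res.pb.slope_ci[1],
                    "cusum_p": res.cusum_p,
                    "ba_bias": res.ba.bias,
                    "ba_loa_lo": res.ba.lower_limit,
                    "ba_loa_hi": res.ba.upper_limit,
                    "spearman_rho": res.spearman.rho,
                    "spearman_ci_lo": res.spearman.ci[0],
                    "spearman_ci_hi": res.spearman.ci[1],
                    "spearman_p": res.spearman.p_value,
                })
        return pd.DataFrame(rows)


def _battery(df: pd.DataFrame, ci_level: float) -> dict:
    out = {}
    for metric in METRICS:
        sub = df[df.metric == metric].dropna(subset=["std", "tsd"])
        if len(sub) < 3:
            continue
        sample = PairedSample(sub["std"].to_numpy(), sub["tsd"].to_numpy(),
                              metric, tuple(sub["region"]))
        out[metric] = compare_methods(sample, ci_level)
    return out


def run_study(cfg: StudyConfig, out_dir=None, noiseless: bool = False) -> StudyResult:
    """Run the full cohort and the pooled agreement battery.

    Writes paired values, the agreement report, the config and a manifest
    into ``out_dir`` when given; reruns with the same config are
    bit-identical.
    """
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
    frames = []
    failures = []
    for s in range(cfg.n_subjects):
        try:
            frames.append(simulate_subject(cfg, s, out_path, noiseless))
        except Exception as exc:   # stage failure: skip subject, keep going
            failures.append({"subject": s, "error": repr(exc)})
    if not frames:
        raise RuntimeError(f"all subjects failed: {failures}")
    paired = pd.concat(frames, ignore_index=True)

    agreement = {
        "organs": _battery(paired[paired.region_type == "organ"], cfg.ci_level),
        "lesions": _battery(paired[paired.region_type == "lesion"], cfg.ci_level),
        "pooled": _battery(paired, cfg.ci_level),
    }
    result = StudyResult(paired, agreement, cfg)

    if out_path is not None:
        paired.to_csv(out_path / "paired_values.csv", index=False)
        result.agreement_frame().to_csv(out_path / "agreement.csv", index=False)
        cfg.to_yaml(out_path / "config.yaml")
        manifest = {
            "n_subjects": cfg.n_subjects, "seed": cfg.seed,
            "failures": failures,
            "paired_values_sha256": hashlib.sha256(
                (out_path / "paired_values.csv").read_bytes()).hexdigest(),
        }
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return result
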