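"""End-to-end orchestration: simulate -> render -> extract -> exclude ->
stage -> analyze, with reproducible per-stage seeding and a run manifest.

The master seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence`` spawning, so each stage is individually
reproducible from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import STAGES, SemSpec, default_params, simulate_cohort
from .mediation import PRESETS, bootstrap_ci
from .petquant import (
    A_CUTOFF,
    NEOCORTEX_COMPOSITE,
    T_CUTOFF,
    TEMPORAL_META_ROI,
    classify_at,
    composite_suvr,
    mask_meninges,
    smooth_to_fwhm,
    vr_suvr,
)
from .phantom import ParticipantRecord, PhantomBundle, simulate_phantom
from .stats import oneway_anova_tukey, zscores_vs_reference
from .volumes import GridSpec
from .volumetrics import (
    CHOROID_LABELS,
    VENTRICLE_LABELS,
    apply_ei_exclusion,
    evans_index,
    grey_matter_volume,
    icv,
    region_volume,
    residualize,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "extract_features",
    "demo_config",
]

PIPELINE_STAGES = ("simulate", "extract", "exclude", "stage", "group-stats", "mediate")


def extract_features(
    bundle: PhantomBundle,
    fwhm_mm: float = 8.0,
    erosion_mm: float = 2.0,
    vr_before_smoothing: bool = False,
) -> dict:
    """Image-derived biomarkers of one phantom: volumes, Evans' Index and
    SUVRs (meninges masking, then smoothing, then quantification).

    ``vr_before_smoothing`` computes the ventricular-radioactivity SUVR on
    the unsmoothed (masked) images instead of the smoothed ones.
    """
    labels = bundle.labels
    row = {
        "id": bundle.truth.id,
        "vv": region_volume(labels, list(VENTRICLE_LABELS)),
        "cpv": region_volume(labels, list(CHOROID_LABELS)),
        "icv": icv(labels),
        "gm_volume": grey_matter_volume(labels),
        "ei": evans_index(labels).ei,
    }
    for tracer, vol, roi in (
        ("abeta_neocortex", bundle.amyloid, NEOCORTEX_COMPOSITE),
        ("tau_metaroi", bundle.tau, TEMPORAL_META_ROI),
    ):
        if vol is None:
            continue
        masked = mask_meninges(vol, labels)
        smoothed = smooth_to_fwhm(masked, fwhm_mm)
        row[tracer] = composite_suvr(smoothed, labels, roi)
        vr_src = masked if vr_before_smoothing else smoothed
        key = "vr_amyloid" if vol.tracer == "amyloid" else "vr_tau"
        row[key] = vr_suvr(vr_src, labels, erosion_mm=erosion_mm)
    return row


@dataclass
class PipelineConfig:
    sem: SemSpec = field(default_factory=default_params)
    grid: GridSpec = field(default_factory=GridSpec)
    stages: tuple[str, ...] = PIPELINE_STAGES
    ei_threshold: float = 0.3
    a_cut: float = A_CUTOFF
    t_cut: float = T_CUTOFF
    erosion_mm: float = 2.0
    fwhm_mm: float = 8.0
    alpha: float = 0.05
    n_boot: int = 1000
    mediation_preset: str = "abeta_mediates_tau"
    out_dir: str = "ventricsf_run"
    master_seed: int = 0

    def validate(self) -> None:
        if tuple(self.stages) != PIPELINE_STAGES[: len(self.stages)]:
            raise ValueError(
                f"stages must be a prefix of {PIPELINE_STAGES}, got {self.stages}"
            )
        for name, v in (("ei", self.ei_threshold), ("a_cut", self.a_cut), ("t_cut", self.t_cut)):
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")
        self.sem.validate()

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {k: repr(v) for k, v in asdict(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(out_dir: str = "ventricsf_run", master_seed: int = 0) -> PipelineConfig:
    """A scaled-down configuration (62 participants) that runs in seconds."""
    sem = default_params()
    sem.group_sizes = {"CU(Y)": 10, "A-T-": 20, "A+T-": 10, "A-T+": 2, "A+T+": 20}
    return PipelineConfig(sem=sem, out_dir=out_dir, master_seed=master_seed)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict
    files: list
    n_simulated: int = 0
    n_excluded: int = 0
    n_retained: int = 0

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured pipeline stages in order.

    Emits, under ``config.out_dir``: the simulated cohort CSV, the per-
    participant biomarker CSV, the exclusion report, the A/T staging CSV,
    group-statistics JSON, mediation JSON, and the run manifest.  Identical
    config and master seed reproduce identical tables.
    """
    config.validate()
    n_total = sum(config.sem.group_sizes.values())
    if n_total == 0:
        raise ValueError("configuration requests zero participants")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    seed_map = dict(zip(("simulate", "phantom", "extract", "mediate"), seeds))
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seeds=seed_map, files=[]
    )

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.files.append(str(path))
        return path

    try:
        cohort = simulate_cohort(config.sem, seed=seed_map["simulate"])
        manifest.n_simulated = len(cohort)
        emit("cohort.csv", lambda p: cohort.to_csv(p, index=False))

        if "extract" not in config.stages:
            return manifest
        phantoms = {}
        rows = []
        for i, (_, r) in enumerate(cohort.iterrows()):
            rec = ParticipantRecord.from_row(r)
            b = simulate_phantom(rec, grid=config.grid, seed=seed_map["phantom"] + i)
            phantoms[rec.id] = b
            rows.append(
                extract_features(b, fwhm_mm=config.fwhm_mm, erosion_mm=config.erosion_mm)
            )
        features = pd.DataFrame(rows)
        emit("features.csv", lambda p: features.to_csv(p, index=False))

        if "exclude" not in config.stages:
            return manifest
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, report = apply_ei_exclusion(
                cohort, {k: v.labels for k, v in phantoms.items()}, threshold=config.ei_threshold
            )
        manifest.n_excluded = len(report)
        manifest.n_retained = len(retained)
        emit("exclusion.csv", lambda p: report.to_csv(p, index=False))
        features = features[features["id"].isin(retained["id"])].reset_index(drop=True)
        table = retained.merge(features.drop(columns=["icv"]), on="id")

        if "stage" not in config.stages:
            return manifest
        staging = []
        for _, r in table.iterrows():
            st = classify_at(r["abeta_neocortex"], r["tau_metaroi"], config.a_cut, config.t_cut)
            staging.append(
                dict(
                    id=r["id"],
                    abeta_neocortex=r["abeta_neocortex"],
                    tau_metaroi=r["tau_metaroi"],
                    a_pos=st.a_positive,
                    t_pos=st.t_positive,
                    stage_measured=st.stage_label,
                )
            )
        emit("staging.csv", lambda p: pd.DataFrame(staging).to_csv(p, index=False))

        if "group-stats" not in config.stages:
            return manifest
        is_ref = (table["stage"] == "CU(Y)").to_numpy()
        gstats = {}
        for col in ("vv", "cpv", "vr_amyloid"):
            vals = table[col].to_numpy(dtype=float)
            if col in ("vv", "cpv"):
                vals = residualize(vals, table["icv"].to_numpy(dtype=float))
            z = zscores_vs_reference(vals, is_ref)
            entry = {
                "mean_z_by_stage": {
                    s: float(z[(table["stage"] == s).to_numpy()].mean())
                    for s in STAGES
                    if (table["stage"] == s).any()
                }
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gc = oneway_anova_tukey(vals, table["stage"].to_numpy(), q=config.alpha)
            entry["anova"] = {"f": gc.f_stat, "df": gc.df, "p": gc.p}
            entry["pairwise"] = [
                dict(a=a, b=b, mean_diff=d, tukey_p=tp, fdr_p=ap, reject=rej)
                for a, b, d, tp, ap, rej in gc.pairwise
            ]
            gstats[col] = entry
        emit("group_stats.json", lambda p: p.write_text(json.dumps(gstats, indent=2)))

        if "mediate" not in config.stages:
            return manifest
        preset = PRESETS[config.mediation_preset]
        from dataclasses import replace as _replace

        spec = _replace(preset, n_boot=config.n_boot, seed=seed_map["mediate"], alpha=config.alpha)
        med = bootstrap_ci(table, spec)
        payload = {
            "paths": {f"{a}->{b}": v for (a, b), v in med.path_coefficients.items()},
            "indirect": [
                dict(path=list(e.path), estimate=e.estimate, ci=list(e.bc_ci95), significant=e.significant)
                for e in med.indirect_effects
            ],
            "n_boot": med.n_boot_used,
        }
        emit("mediation.json", lambda p: p.write_text(json.dumps(payload, indent=2)))
    except Exception as exc:
        manifest.save(out / "manifest.partial.json")
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    manifest.save(out / "manifest.json")
    manifest.files.append(str(out / "manifest.json"))
    return manifest
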