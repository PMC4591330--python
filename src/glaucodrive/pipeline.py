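"""End-to-end orchestration: simulate -> metrics -> fit -> evaluate -> report.

Each stage is a pure function of (inputs, config, seed) writing delimited
text tables (and figures for the report stage) under one output directory.
A run manifest records the config hash, seed, package versions, the file
inventory and per-stage timing so a run can be reproduced bit-for-bit.

Stage products
--------------
simulate : subjects.csv, visits.csv, events.csv, config.yaml and, for a
    small subset of subjects, raw per-visit telemetry and stimulus logs
    (raw/<subject>/visit<k>_telemetry.csv, ..._events.csv).
metrics  : metrics.csv — simulator metrics recomputed from the raw
    telemetry/event logs (demonstrating the measurement pipeline).
fit      : table2_univariable.csv, table3_multivariable.csv analogs plus a
    text model summary.  Fits use the per-visit covariates in visits.csv
    (the values that drive the generating hazard).
evaluate : table1_baseline.csv, glaucoma_vs_control.csv, summary.json with
    Royston R² for the driving-simulator and UFOV multivariable models.
report   : km_curve.csv/png and predicted-survival trajectories for the
    highest- and lowest-risk subjects.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import compare_groups, comparisons_frame, royston_r2
from .metrics import StimulusEventLog, TelemetryTrace, compute_metrics
from .simulate import (
    GLAUCOMA,
    CohortConfig,
    cohort_frames,
    generate_cohort,
    generate_road_profile,
    generate_stimulus_log,
    generate_telemetry,
    write_cohort,
)
from .survival import WeibullTDModel, build_episodes, kaplan_meier

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "metrics", "fit", "evaluate", "report")

#: Table 3 analog adjustment sets
SIM_MODEL = ["rt_low", "curve_coherence", "moca", "sap_binoc_db", "age", "mileage_week"]
UFOV_MODEL = ["ufov_ms", "moca", "sap_binoc_db", "age", "mileage_week"]
UNIVARIABLE = [
    "rt_low", "rt_high", "rt_corrected", "curve_coherence",
    "ufov_ms", "sap_binoc_db", "moca", "age", "mileage_week",
]
FLIP_SIGN = ["curve_coherence", "sap_binoc_db", "moca"]

N_RAW_SUBJECTS = 3  # subjects for which raw telemetry/event logs are emitted
DRIVE_SECONDS = 240.0
SAMPLE_RATE = 10.0


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict[str, str]
    files: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _hash_config(config: CohortConfig) -> str:
    import yaml

    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _versions() -> dict[str, str]:
    import lifelines
    import scipy
    import statsmodels

    return {
        "glaucodrive": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
    }


def _register(manifest: RunManifest, outdir: Path, *paths: Path) -> None:
    for p in paths:
        manifest.files[str(p.relative_to(outdir))] = hashlib.sha256(
            p.read_bytes()
        ).hexdigest()[:16]


def _stage_simulate(config: CohortConfig, outdir: Path, manifest: RunManifest) -> None:
    subjects = generate_cohort(config)
    paths = write_cohort(subjects, outdir)
    config.to_yaml(outdir / "config.yaml")
    _register(manifest, outdir, *paths.values(), outdir / "config.yaml")

    raw_dir = outdir / "raw"
    glaucoma = [s for s in subjects if s.group == GLAUCOMA][:N_RAW_SUBJECTS]
    for s in glaucoma:
        sdir = raw_dir / s.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        for k, vrow in enumerate(s.visits.itertuples()):
            ability = float(s.trajectory.ability(vrow.time))
            seed_k = (config.seed * 1000003 + zlib.crc32(f"{s.subject_id}:{k}".encode())) % (2**31)
            road = generate_road_profile(DRIVE_SECONDS, SAMPLE_RATE, seed_k)
            trace = generate_telemetry(
                road, ability, lag=8, noise_sd=0.004, seed=seed_k, sample_rate=SAMPLE_RATE
            )
            log = generate_stimulus_log(
                DRIVE_SECONDS, ability, seed=seed_k,
                n_per_contrast=config.stimuli_per_contrast,
                rt_noise_sd=config.rt_noise_sd,
            )
            tpath = sdir / f"visit{k}_telemetry.csv"
            epath = sdir / f"visit{k}_events.csv"
            trace.to_frame().to_csv(tpath, index=False, float_format="%.6g")
            log.to_frame().to_csv(epath, index=False, float_format="%.6g")
            _register(manifest, outdir, tpath, epath)


def _stage_metrics(outdir: Path, manifest: RunManifest) -> None:
    raw_dir = outdir / "raw"
    rows = []
    for sdir in sorted(raw_dir.iterdir()) if raw_dir.exists() else []:
        for tpath in sorted(sdir.glob("visit*_telemetry.csv")):
            k = int(tpath.stem.split("_")[0].removeprefix("visit"))
            trace = TelemetryTrace.from_frame(pd.read_csv(tpath))
            log = StimulusEventLog.from_frame(
                pd.read_csv(sdir / f"visit{k}_events.csv")
            )
            m = compute_metrics(trace, log)
            rows.append({"subject_id": sdir.name, "visit": k, **m.as_dict()})
    out = outdir / "metrics.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6g")
    _register(manifest, outdir, out)


def _load_tables(outdir: Path):
    subjects = pd.read_csv(outdir / "subjects.csv")
    visits = pd.read_csv(outdir / "visits.csv")
    visits = visits.merge(subjects[["subject_id", "age"]], on="subject_id")
    return subjects, visits


def _glaucoma_episodes(outdir: Path, covariates):
    subjects, visits = _load_tables(outdir)
    g = subjects[subjects["group"] == GLAUCOMA]
    gv = visits[visits["subject_id"].isin(g["subject_id"])]
    flips = [c for c in covariates if c in FLIP_SIGN]
    return build_episodes(g, gv, covariates, flip_sign=flips)


def _stage_fit(outdir: Path, manifest: RunManifest) -> None:
    uni_rows = []
    for cov in UNIVARIABLE:
        ep = _glaucoma_episodes(outdir, [cov])
        fit = WeibullTDModel(ep).fit()
        uni_rows.append(fit.hr_table.iloc[0].to_dict())
    t2 = outdir / "table2_univariable.csv"
    pd.DataFrame(uni_rows).to_csv(t2, index=False, float_format="%.6g")

    summaries = []
    for name, covs in (("driving_simulation", SIM_MODEL), ("ufov", UFOV_MODEL)):
        ep = _glaucoma_episodes(outdir, covs)
        fit = WeibullTDModel(ep).fit()
        tbl = fit.hr_table.copy()
        tbl.insert(0, "model", name)
        summaries.append((name, fit, tbl))
    t3 = outdir / "table3_multivariable.csv"
    pd.concat([t for _, _, t in summaries]).to_csv(t3, index=False, float_format="%.6g")
    txt = outdir / "model_summaries.txt"
    txt.write_text(
        "\n\n".join(f"[{name}]\n{fit.summary()}" for name, fit, _ in summaries)
    )
    _register(manifest, outdir, t2, t3, txt)


def _stage_evaluate(outdir: Path, manifest: RunManifest) -> None:
    subjects, visits = _load_tables(outdir)
    g = subjects[subjects["group"] == GLAUCOMA]

    # Table 1 analog: baseline characteristics, MVC vs no-MVC
    baseline = visits[visits["time"] == 0.0].merge(
        g[["subject_id", "event", "female"]], on="subject_id"
    )
    variables = [
        "age", "female", "sap_binoc_db", "mileage_week", "moca",
        "ufov_ms", "rt_low", "rt_high", "rt_corrected", "curve_coherence",
    ]
    t1 = comparisons_frame(
        compare_groups(baseline, "event", variables, categorical=["female"])
    )
    p1 = outdir / "table1_baseline.csv"
    t1.to_csv(p1, index=False, float_format="%.6g")

    # glaucoma vs control at the last visit
    last = visits.sort_values("time").groupby("subject_id").last().reset_index()
    last = last.merge(subjects[["subject_id", "group"]], on="subject_id")
    gc = comparisons_frame(
        compare_groups(last, "group", ["rt_low", "rt_high", "ufov_ms", "curve_coherence"])
    )
    p2 = outdir / "glaucoma_vs_control.csv"
    gc.to_csv(p2, index=False, float_format="%.6g")

    # Royston R² of the two multivariable models
    r2 = {}
    for name, covs in (("driving_simulation", SIM_MODEL), ("ufov", UFOV_MODEL)):
        ep = _glaucoma_episodes(outdir, covs)
        fit = WeibullTDModel(ep).fit()
        res = royston_r2(fit, ep)
        r2[name] = {"D": res.D, "r2": res.r2}
    summary = {
        "n_glaucoma": int(len(g)),
        "n_controls": int((subjects["group"] != GLAUCOMA).sum()),
        "n_events": int(g["event"].sum()),
        "event_fraction": float(g["event"].mean()),
        "mean_followup_years": float(g["followup_years"].mean()),
        "royston_r2": r2,
    }
    p3 = outdir / "summary.json"
    p3.write_text(json.dumps(summary, indent=2, sort_keys=True))
    _register(manifest, outdir, p1, p2, p3)


def _stage_report(outdir: Path, manifest: RunManifest) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subjects, visits = _load_tables(outdir)
    g = subjects[subjects["group"] == GLAUCOMA]
    km = kaplan_meier(g["followup_years"], g["event"])
    kcsv = outdir / "km_curve.csv"
    km.to_frame().to_csv(kcsv, index=False, float_format="%.6g")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(km.times, 1.0 - km.survival, where="post")
    ax.set_xlabel("Follow-up (years)")
    ax.set_ylabel("Cumulative probability of MVC")
    ax.set_ylim(0, max(0.25, float(1 - km.survival.min()) * 1.3))
    fig.tight_layout()
    kpng = outdir / "km_curve.png"
    fig.savefig(kpng, dpi=120)
    plt.close(fig)

    # individual predicted-survival trajectories: refit the simulator model,
    # then show the subjects with the highest and lowest mean risk
    ep = _glaucoma_episodes(outdir, SIM_MODEL)
    fit = WeibullTDModel(ep).fit()
    beta = fit.beta.to_numpy()
    pis = ep.data.groupby("subject_id")[SIM_MODEL].mean().to_numpy() @ beta
    ids = ep.data["subject_id"].unique()
    order = np.argsort(pis)
    picks = {"lowest_risk": ids[order[0]], "highest_risk": ids[order[-1]]}
    fig, ax = plt.subplots(figsize=(5, 4))
    frames = []
    for label, sid in picks.items():
        sd = ep.data[ep.data["subject_id"] == sid]
        history = [(r.start, [getattr(r, c) for c in SIM_MODEL]) for r in sd.itertuples()]
        curve = fit.predict_survival(history, horizon=3.0)
        ax.plot(curve.times, curve.survival, label=f"{label} ({sid})")
        f = curve.to_frame()
        f.insert(0, "subject_id", sid)
        f.insert(0, "profile", label)
        frames.append(f)
    ax.set_xlabel("Years from baseline")
    ax.set_ylabel("Predicted MVC-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    tpng = outdir / "predicted_survival.png"
    fig.savefig(tpng, dpi=120)
    plt.close(fig)
    tcsv = outdir / "predicted_survival.csv"
    pd.concat(frames).to_csv(tcsv, index=False, float_format="%.6g")
    _register(manifest, outdir, kcsv, kpng, tpng, tcsv)


_STAGE_FUNCS = {
    "metrics": _stage_metrics,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


def run_pipeline(
    config: CohortConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    stages: tuple[str, ...] = STAGES,
) -> RunManifest:
    """Run the requested stages in order and write a manifest.

    ``config`` may be a CohortConfig or a YAML path; ``seed`` overrides the
    config's seed.  Stage failures propagate as exceptions after the
    manifest (with partial file inventory) is saved.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    if seed is not None:
        config = config.replace(seed=int(seed))
    config.validate()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(config), seed=config.seed, versions=_versions()
    )
    try:
        for stage in [s for s in STAGES if s in stages]:
            t0 = time.perf_counter()
            if stage == "simulate":
                _stage_simulate(config, outdir, manifest)
            else:
                _STAGE_FUNCS[stage](outdir, manifest)
            manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
    finally:
        manifest.save(outdir / "manifest.json")
    return manifest
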