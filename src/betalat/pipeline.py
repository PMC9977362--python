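"""End-to-end orchestration: simulate -> tfr -> ami/roi -> li -> phase -> stats.

The pipeline is deterministic under a fixed run seed: one root
``numpy.random.SeedSequence`` is spawned into per-subject streams (schedule,
EEG, behavior) and per-stage streams (cluster permutations, phase
permutations), so rerunning an identical configuration reproduces every
table byte for byte. Each stage writes its artifact under the output
directory and later stages can reuse cached artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as beh
from . import phase_analysis as ph
from . import stats as st
from .attention_index import (
    channel_adjacency,
    cluster_permutation_test,
    compute_ami,
    roi_size_from_clusters,
    select_rois,
)
from .lateralization import ANALYSIS_WINDOW, li_frame, li_timecourses
from .layout import balanced_subset_layout
from .schedule import build_session
from .simulate import SimConfig, SyntheticSubject, simulate_behavior, simulate_eeg
from .timefreq import band_freq_grid, band_average, band_timecourse, morlet_tfr

STAGES = ("simulate", "tfr", "ami", "li", "phase", "stats")
PRESEQUENCE_WINDOW = (-0.2, 0.0)


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis-side knobs (windows in seconds, band in Hz)."""

    band: tuple = (14.0, 24.0)
    freq_step: float = 0.5
    time_step: float = 0.05
    presequence_window: tuple = PRESEQUENCE_WINDOW
    analysis_window: tuple = ANALYSIS_WINDOW
    roi_k: int = 10
    roi_size_from_clusters: bool = False
    n_permutations: int = 10_000
    alpha: float = 0.05
    smooth_window: float = 0.25


@dataclass(frozen=True)
class RunConfig:
    n_subjects: int = 20
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    out_dir: Optional[str] = None
    stages: tuple = STAGES

    def parameter_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(
                dataclasses.replace(self, out_dir=None)
            ),
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def tiny_run_config(n_subjects: int = 10, seed: int = 0,
                    out_dir=None, **sim_overrides) -> RunConfig:
    """Reduced-scale configuration for calibration sweeps and tests:
    200 Hz, 16-channel balanced layout, 2 epochs per block, 2-Hz beta grid,
    4-channel ROIs, 2000 permutations."""
    layout = balanced_subset_layout(7, 2)
    sim = SimConfig(
        sampling_rate=200.0,
        epochs_per_block=2,
        channels=tuple(layout.names),
        **sim_overrides,
    )
    analysis = AnalysisParams(freq_step=2.0, roi_k=4, n_permutations=2000)
    return RunConfig(n_subjects=n_subjects, sim=sim, analysis=analysis,
                     seed=seed, out_dir=out_dir)


def recovery_run_config(n_subjects: int = 20, seed: int = 0,
                        out_dir=None, **sim_overrides) -> RunConfig:
    """High-SNR parameter-recovery configuration (full-hemisphere coverage
    for 10-channel ROIs, planted effects at the package defaults)."""
    layout = balanced_subset_layout(13, 2)
    over = dict(snr=0.5, epochs_per_block=4, sampling_rate=200.0,
                phase_jitter_sd=0.6, channels=tuple(layout.names))
    over.update(sim_overrides)
    sim = SimConfig(**over)
    analysis = AnalysisParams(freq_step=2.0, roi_k=10, n_permutations=2000)
    return RunConfig(n_subjects=n_subjects, sim=sim, analysis=analysis,
                     seed=seed, out_dir=out_dir)


# ---------------------------------------------------------------------------
# per-subject feature extraction

@dataclass
class SubjectFeatures:
    """Per-subject reductions of the time-frequency data.

    ami_presequence : per-channel AMI in the selection window (-0.2-0 s)
    ami_window : {predictability: per-channel AMI over 0-2.2 s}
    ami_window_pooled : per-channel AMI over 0-2.2 s, conditions pooled
        (basis for the individual ROIs of the time-resolved stage; a
        time-averaged selection basis leaves no onset-locked imprint on the
        demeaned LI, unlike selecting on the window adjacent to t = 0)
    tc : {(attended_tempo, attended_ear): channel x time trial-mean beta
        power over the full epoch grid}
    """

    subject: int
    ami_presequence: np.ndarray
    ami_window: dict
    ami_window_pooled: np.ndarray
    tc: dict
    times: np.ndarray
    behavior: beh.BehaviorSummary
    musical_experience: float


def extract_features(subject_id: int, subj: SyntheticSubject,
                     params: AnalysisParams) -> SubjectFeatures:
    freqs = band_freq_grid(params.band, params.freq_step)
    tfr = morlet_tfr(subj.epochs, freqs=freqs, time_step=params.time_step)
    meta = tfr.meta

    # selection window is half-open so it shares no bin with the analysis
    # window (selection/inference separation)
    pre = band_average(tfr, params.band, params.presequence_window,
                       closed="left")
    win = band_average(tfr, params.band, params.analysis_window)

    def ear_mean(values, mask_extra=None):
        out = {}
        for ear in ("left", "right"):
            m = np.asarray(meta["attended_ear"] == ear)
            if mask_extra is not None:
                m &= mask_extra
            out[ear] = values[m].mean(axis=0)
        return out

    pre_means = ear_mean(pre)
    ami_pre = compute_ami(pre_means["left"], pre_means["right"])
    win_means = ear_mean(win)
    ami_win_pooled = compute_ami(win_means["left"], win_means["right"])

    ami_window = {}
    for pred in ("high", "low"):
        m = np.asarray(meta["predictability"] == pred)
        means = ear_mean(win, m)
        ami_window[pred] = compute_ami(means["left"], means["right"])

    btc, times = band_timecourse(tfr, params.band)
    tc = {}
    for tempo in ("slow", "fast"):
        for ear in ("left", "right"):
            m = np.asarray(
                (meta["attended_tempo"] == tempo) & (meta["attended_ear"] == ear)
            )
            tc[(tempo, ear)] = btc[m].mean(axis=0)

    records = beh.categorize_responses(subj.behavior, subj.schedule)
    summary = beh.summarize_behavior(records, subj.schedule)
    return SubjectFeatures(
        subject=subject_id,
        ami_presequence=ami_pre,
        ami_window=ami_window,
        ami_window_pooled=ami_win_pooled,
        tc=tc,
        times=times,
        behavior=summary,
        musical_experience=subj.musical_experience,
    )


# ---------------------------------------------------------------------------
# group analysis

@dataclass
class GroupResult:
    roi_pair: object
    roi_size: int
    cluster_result: object
    anova: st.AnovaResult
    interaction_bf: st.BayesFactorResult
    anova_cells: np.ndarray  # subjects x hemisphere x predictability
    li_courses: list  # LITimeCourse, 2 per subject
    phase_frame: pd.DataFrame
    rayleigh: dict  # (frequency label, attention label) -> CircTestResult
    harrison_kanji: dict  # effect -> CircTestResult
    resultant_perm: dict  # condition -> CircTestResult
    modulation_strength: np.ndarray  # per subject
    behavior_frame: pd.DataFrame
    correlations: pd.DataFrame
    robust_fit: st.RobustFit
    retained_mask: np.ndarray


def analyze_group(features: list, layout, params: AnalysisParams,
                  rng: Optional[np.random.Generator] = None) -> GroupResult:
    """Group-level analysis over per-subject features."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(features)

    # --- channel selection on the presequence window ------------------------
    ami_pre = np.stack([f.ami_presequence for f in features])
    adj = channel_adjacency(layout)
    cluster = cluster_permutation_test(
        ami_pre, np.zeros_like(ami_pre), adj,
        n_permutations=params.n_permutations, rng=rng,
    )
    if params.roi_size_from_clusters:
        k = roi_size_from_clusters(cluster, fallback=params.roi_k)
    else:
        k = params.roi_k
    roi_pair = select_rois(ami_pre.mean(axis=0), layout, k=k, basis="group")
    left_idx = [layout.index(c) for c in roi_pair.left]
    right_idx = [layout.index(c) for c in roi_pair.right]

    # --- AMI x predictability rmANOVA on group-ROI means --------------------
    cells = np.empty((n, 2, 2))
    for s, f in enumerate(features):
        for j, pred in enumerate(("high", "low")):
            cells[s, 0, j] = f.ami_window[pred][left_idx].mean()
            cells[s, 1, j] = f.ami_window[pred][right_idx].mean()
    anova = st.rm_anova_2x2(cells)
    interaction_bf = st.anova_interaction_bf(cells)

    # --- time-resolved LI with individual ROIs ------------------------------
    li_courses = []
    for f in features:
        indiv = select_rois(f.ami_window_pooled, layout, k=k,
                            basis="individual")
        pseudo_power = np.stack(
            [f.tc[(tempo, ear)] for tempo in ("slow", "fast")
             for ear in ("left", "right")]
        )
        meta = pd.DataFrame(
            {
                "attended_tempo": ["slow", "slow", "fast", "fast"],
                "attended_ear": ["left", "right", "left", "right"],
            }
        )
        courses = li_timecourses(
            pseudo_power, f.times, meta, indiv, layout,
            window=params.analysis_window,
            smooth_window=params.smooth_window, subject=f.subject,
        )
        li_courses.extend(courses.values())

    # --- phase extraction and circular statistics ---------------------------
    phases = ph.phase_table(li_courses, dt=params.time_step)
    rayleigh = {}
    for (freq, label), grp in phases.groupby(["frequency", "label"]):
        rayleigh[(freq, label)] = ph.rayleigh_test(grp["phase_rad"].to_numpy())
    hk = ph.harrison_kanji_test(
        phases["phase_rad"].to_numpy(),
        phases["label"].to_numpy(),
        phases["frequency"].to_numpy(),
        factor_names=("attention", "frequency"),
    )
    resultant = {}
    for condition in ("attend_slow", "attend_fast"):
        sub = phases[phases["condition"] == condition].sort_values("subject")
        att = sub.loc[sub["label"] == "attended", "phase_rad"].to_numpy()
        unatt = sub.loc[sub["label"] == "unattended", "phase_rad"].to_numpy()
        resultant[condition] = ph.resultant_diff_perm_test(
            att, unatt, n_permutations=params.n_permutations, rng=rng,
        )

    # --- behavior associations ----------------------------------------------
    strength = np.array(
        [
            st.attention_modulation_strength(
                np.mean([f.ami_window[p][left_idx].mean() for p in ("high", "low")]),
                np.mean([f.ami_window[p][right_idx].mean() for p in ("high", "low")]),
            )
            for f in features
        ]
    )
    retained = st.zscore_outlier_screen(strength)
    behavior_frame = beh.summary_frame(
        {f.subject: f.behavior for f in features}
    )
    behavior_frame["musical_experience"] = [
        f.musical_experience for f in features
    ]
    behavior_frame["modulation_strength"] = strength

    tails = {"prop_hits": "greater", "prop_se": "less", "prop_re": "less",
             "tdr": "greater"}
    behavior_frame["tdr"] = (
        behavior_frame["tdr_high"] + behavior_frame["tdr_low"]
    ) / 2
    rows = []
    x = strength[retained]
    if retained.sum() >= 4:
        for measure, tail in tails.items():
            y = behavior_frame.loc[retained, measure].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r, p = st.correlate(x, y, method="pearson", tail=tail)
            rows.append((measure, "pearson", tail, r, p))
    correlations = pd.DataFrame(
        rows, columns=["measure", "method", "tail", "r", "p"]
    )
    robust = (
        st.robust_regression(
            x, behavior_frame.loc[retained, "prop_re"].to_numpy()
        )
        if retained.sum() >= 5
        else None
    )

    return GroupResult(
        roi_pair=roi_pair,
        roi_size=k,
        cluster_result=cluster,
        anova=anova,
        interaction_bf=interaction_bf,
        anova_cells=cells,
        li_courses=li_courses,
        phase_frame=phases,
        rayleigh=rayleigh,
        harrison_kanji=hk,
        resultant_perm=resultant,
        modulation_strength=strength,
        behavior_frame=behavior_frame,
        correlations=correlations,
        robust_fit=robust,
        retained_mask=retained,
    )


# ---------------------------------------------------------------------------
# seeded simulation helpers

def subject_seeds(seed: int, n_subjects: int):
    """Deterministic per-subject seed streams from the run seed."""
    return np.random.SeedSequence(seed).spawn(n_subjects)


def simulate_subjects(config: RunConfig) -> list:
    out = []
    for s, ss in enumerate(subject_seeds(config.seed, config.n_subjects)):
        rng = np.random.default_rng(ss)
        session = build_session(rng)
        epochs = simulate_eeg(session, config.sim, rng)
        behavior = simulate_behavior(session, rng=rng)
        gmsi = float(np.clip(rng.normal(66.0, 17.6), 18, 126))
        out.append(
            SyntheticSubject(
                epochs=epochs, schedule=session, config=config.sim,
                behavior=behavior, musical_experience=gmsi,
            )
        )
    return out


def run_group(config: RunConfig) -> GroupResult:
    """Simulate a cohort and run the full group analysis in memory."""
    subjects = simulate_subjects(config)
    layout = config.sim.resolve_layout()
    features = [
        extract_features(s, subj, config.analysis)
        for s, subj in enumerate(subjects)
    ]
    analysis_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(config.n_subjects + 1)[-1]
    )
    return analyze_group(features, layout, config.analysis, rng=analysis_rng)


# ---------------------------------------------------------------------------
# staged, artifact-writing pipeline

def _result_tables(result: GroupResult) -> dict:
    anova_rows = [
        (e.effect, e.F, e.df[0], e.df[1], e.p, e.omega2, e.omega2_label)
        for e in result.anova.effects()
    ]
    anova_df = pd.DataFrame(
        anova_rows,
        columns=["effect", "F", "df1", "df2", "p", "omega2", "omega2_label"],
    )
    circ_rows = []
    for (freq, label), r in sorted(result.rayleigh.items()):
        circ_rows.append(("rayleigh", f"{freq} Hz {label}", r.kind,
                          r.statistic, "", r.p))
    for effect, r in result.harrison_kanji.items():
        circ_rows.append(("harrison_kanji", effect, r.kind, r.statistic,
                          "/".join(str(d) for d in r.df), r.p))
    for condition, r in result.resultant_perm.items():
        circ_rows.append(("resultant_diff_perm", condition, r.kind,
                          r.statistic, "", r.p))
    circ_df = pd.DataFrame(
        circ_rows, columns=["test", "context", "kind", "statistic", "df", "p"]
    )
    roi_df = pd.DataFrame(
        {
            "channel": list(result.roi_pair.left) + list(result.roi_pair.right),
            "roi": ["left"] * len(result.roi_pair.left)
            + ["right"] * len(result.roi_pair.right),
        }
    )
    return {
        "anova.tsv": anova_df,
        "circular_tests.tsv": circ_df,
        "roi.tsv": roi_df,
        "li.tsv": li_frame(result.li_courses),
        "phases.tsv": result.phase_frame,
        "behavior.tsv": result.behavior_frame,
        "correlations.tsv": result.correlations,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages, write artifacts, return the manifest.

    Stages run in dependency order; a disabled stage's artifact must already
    exist in ``out_dir`` or a stage-dependency error is raised.
    """
    if config.out_dir is None:
        raise ValueError("run_pipeline needs an output directory")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {
        "parameter_hash": config.parameter_hash(),
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "stages": list(stages),
        "outputs": {},
    }
    layout = config.sim.resolve_layout()

    def require(path: Path, stage: str):
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing upstream artifact {path.name}; "
                "run the producing stage first"
            )
        return path

    # simulate ---------------------------------------------------------------
    subjects = None
    if "simulate" in stages:
        subjects = simulate_subjects(config)
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        for s, subj in enumerate(subjects):
            subj.epochs.save(sim_dir / f"subject{s:02d}_epochs.zip")
            subj.schedule.to_tsv(sim_dir / f"subject{s:02d}_schedule.tsv")
        pd.DataFrame(
            [(s, t, b) for s, subj in enumerate(subjects)
             for t, b in subj.behavior],
            columns=["subject", "time_s", "block"],
        ).to_csv(sim_dir / "responses.tsv", sep="\t", index=False)
        manifest["outputs"]["simulate"] = sorted(
            p.name for p in sim_dir.iterdir()
        )

    # tfr / feature extraction ----------------------------------------------
    features = None
    feat_path = out / "features.json"
    if "tfr" in stages:
        if subjects is None:
            subjects = simulate_subjects(config)
        features = [
            extract_features(s, subj, config.analysis)
            for s, subj in enumerate(subjects)
        ]
        _save_features(features, feat_path)
        manifest["outputs"]["tfr"] = [feat_path.name]

    remaining = [s for s in ("ami", "li", "phase", "stats") if s in stages]
    if remaining:
        if features is None:
            features = _load_features(require(feat_path, remaining[0]))
        analysis_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(config.n_subjects + 1)[-1]
        )
        result = analyze_group(features, layout, config.analysis,
                               rng=analysis_rng)
        tables = _result_tables(result)
        stage_tables = {
            "ami": ("anova.tsv", "roi.tsv"),
            "li": ("li.tsv",),
            "phase": ("phases.tsv", "circular_tests.tsv"),
            "stats": ("behavior.tsv", "correlations.tsv"),
        }
        for stage in remaining:
            names = stage_tables[stage]
            for name in names:
                df = tables[name]
                df.to_csv(out / name, sep="\t", index=False,
                          float_format="%.10g")
            manifest["outputs"][stage] = list(names)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _save_features(features: list, path: Path) -> None:
    payload = []
    for f in features:
        payload.append(
            {
                "subject": f.subject,
                "ami_presequence": f.ami_presequence.tolist(),
                "ami_window": {k: v.tolist() for k, v in f.ami_window.items()},
                "ami_window_pooled": f.ami_window_pooled.tolist(),
                "tc": {f"{t}|{e}": v.tolist() for (t, e), v in f.tc.items()},
                "times": f.times.tolist(),
                "behavior": dataclasses.asdict(f.behavior),
                "musical_experience": f.musical_experience,
            }
        )
    path.write_text(json.dumps(payload))


def _load_features(path: Path) -> list:
    payload = json.loads(path.read_text())
    out = []
    for d in payload:
        tc = {}
        for key, v in d["tc"].items():
            tempo, ear = key.split("|")
            tc[(tempo, ear)] = np.asarray(v)
        out.append(
            SubjectFeatures(
                subject=d["subject"],
                ami_presequence=np.asarray(d["ami_presequence"]),
                ami_window={k: np.asarray(v) for k, v in d["ami_window"].items()},
                ami_window_pooled=np.asarray(d["ami_window_pooled"]),
                tc=tc,
                times=np.asarray(d["times"]),
                behavior=beh.BehaviorSummary(**d["behavior"]),
                musical_experience=d["musical_experience"],
            )
        )
    return out


def make_fixtures(scale: str = "tiny", out_dir=".", seed: int = 1234) -> dict:
    """Write small deterministic fixture datasets for the test suite.

    ``tiny``: 3 subjects on the reduced layout; ``default``: 5 subjects.
    Returns the pipeline manifest.
    """
    n = {"tiny": 3, "default": 5}[scale]
    config = dataclasses.replace(
        tiny_run_config(n_subjects=n, seed=seed), out_dir=str(out_dir)
    )
    return run_pipeline(config)
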