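"""Synthetic affect-study generator with known ground truth.

Generates studies shaped like a DEAP-style experiment — ``n_subjects``
participants each rating ``n_trials`` one-minute stimuli for arousal and
valence on a continuous 1-9 scale — together with trial-level spectral
parameters (aperiodic exponent and offset, alpha peak power and center
frequency) produced by exactly the linear mixed structure the statistics
module assumes: per-subject random intercepts and rating slopes, fixed
arousal/valence effects, a prestimulus covariate correlated with the task
value, and residual noise.  Matching time-domain epochs can be synthesized
whose spectra carry the trial's true parameters, so the whole
multitaper -> parameterization -> mixed-model chain can be validated
round-trip against known effects.

The default arousal effect on the task exponent (0.0162 per rating unit)
is the size reported for the empirical dataset this design emulates; all
remaining effect sizes and variance components have no published values
and are package defaults chosen to give realistic feature distributions
(documented in the methods note).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import gaussian_model

__all__ = ["GeneratorConfig", "GroundTruth", "generate_study",
           "synthesize_epoch", "write_dataset", "read_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape, effect-size and noise settings of the generator.

    Effects are per rating unit on the named spectral feature.  Baselines
    are the feature values at rating 0 for an average subject.
    """

    n_subjects: int = 32
    n_trials: int = 40
    epoch_s: float = 60.0
    pre_s: float = 5.0
    fs: float = 256.0

    # fixed effects (per 1-9 rating unit)
    beta_arousal_exponent: float = 0.0162
    beta_arousal_offset: float = 0.015
    beta_arousal_alpha: float = -0.02
    beta_valence_exponent: float = 0.0
    beta_valence_offset: float = 0.0
    beta_valence_alpha: float = 0.0
    beta_interaction: float = 0.0      # arousal x valence, all features
    beta_prestim: float = 0.25         # carry-over of prestimulus feature

    # baselines (task feature at zero ratings, before carry-over)
    base_exponent: float = 1.2
    base_offset: float = 0.3
    base_alpha: float = 0.7            # log10 height above aperiodic
    base_alpha_cf: float = 10.0        # Hz
    alpha_width: float = 1.2           # Hz (Gaussian sd)

    # random-effect standard deviations (between subjects)
    sd_intercept: float = 0.25
    sd_arousal_slope: float = 0.01
    sd_valence_slope: float = 0.01
    sd_alpha_cf: float = 0.5           # subject-specific alpha frequency

    # residual standard deviations (within subject, per trial)
    sd_residual: float = 0.18
    sd_prestim: float = 0.2            # spread of prestimulus features

    # rating distribution: Gaussian, clipped to the scale bounds
    rating_mean: float = 5.0
    rating_sd: float = 2.0

    # fraction of trials with a detectable alpha peak (rest: alpha missing)
    p_alpha_detected: float = 0.9

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("counts must be positive")
        for name in ("sd_intercept", "sd_arousal_slope", "sd_valence_slope",
                     "sd_residual", "sd_prestim", "rating_sd", "sd_alpha_cf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_alpha_detected <= 1:
            raise ValueError("p_alpha_detected must lie in [0, 1]")
        if self.fs <= 2 * (self.base_alpha_cf + 4 * self.alpha_width):
            raise ValueError("fs must exceed twice the highest modeled "
                             "frequency")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic study."""

    config: GeneratorConfig
    subject_effects: pd.DataFrame    # intercepts & slopes per subject/feature
    betas: dict                      # feature -> dict of generating betas

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "betas": self.betas,
            "subject_effects": self.subject_effects.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


_FEATURES = ("exponent", "offset", "alpha")


def generate_study(config: GeneratorConfig | None = None) -> tuple:
    """Draw one synthetic study.

    Returns ``(records, truth)``: a trial table with the canonical columns
    and a :class:`GroundTruth`.  The task feature of trial i in subject s is

    ``X_is = base + b_pre X_pre,is + (b_A + u_As) A_i + (b_V + u_Vs) V_i
    + b_AV A_i V_i + u_0s + e_is``

    with the prestimulus feature drawn around the subject's baseline so the
    carry-over coefficient is recoverable.  Trials without a detectable
    alpha peak get missing alpha features.  Fully seed-deterministic.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n_s, n_t = config.n_subjects, config.n_trials

    betas = {}
    for feat in _FEATURES:
        betas[feat] = {
            "arousal": getattr(config, f"beta_arousal_{feat}"),
            "valence": getattr(config, f"beta_valence_{feat}"),
            "interaction": config.beta_interaction,
            "prestimulus": config.beta_prestim,
            "baseline": getattr(config, f"base_{feat}"),
        }

    subj_rows = []
    for s in range(n_s):
        row = {"subject_id": f"S{s + 1:02d}",
               "alpha_cf": config.base_alpha_cf
               + config.sd_alpha_cf * rng.standard_normal()}
        for feat in _FEATURES:
            row[f"u0_{feat}"] = config.sd_intercept * rng.standard_normal()
            row[f"uA_{feat}"] = (config.sd_arousal_slope
                                 * rng.standard_normal())
            row[f"uV_{feat}"] = (config.sd_valence_slope
                                 * rng.standard_normal())
        subj_rows.append(row)
    subjects = pd.DataFrame(subj_rows)

    records = []
    for s, srow in subjects.iterrows():
        arousal = np.clip(rng.normal(config.rating_mean, config.rating_sd,
                                     n_t), 1.0, 9.0)
        valence = np.clip(rng.normal(config.rating_mean, config.rating_sd,
                                     n_t), 1.0, 9.0)
        has_alpha = rng.random(n_t) < config.p_alpha_detected
        for t in range(n_t):
            rec = {"subject_id": srow["subject_id"], "trial_id": t + 1,
                   "arousal": arousal[t], "valence": valence[t],
                   "alpha_cf": srow["alpha_cf"]}
            for feat in _FEATURES:
                b = betas[feat]
                pre = (b["baseline"] + srow[f"u0_{feat}"]
                       + config.sd_prestim * rng.standard_normal())
                task = (b["baseline"] + srow[f"u0_{feat}"]
                        + b["prestimulus"] * pre
                        + (b["arousal"] + srow[f"uA_{feat}"]) * arousal[t]
                        + (b["valence"] + srow[f"uV_{feat}"]) * valence[t]
                        + b["interaction"] * arousal[t] * valence[t]
                        + config.sd_residual * rng.standard_normal())
                rec[f"pre_{feat}"] = pre
                rec[f"task_{feat}"] = task
            if not has_alpha[t]:
                rec["task_alpha"] = np.nan
                rec["pre_alpha"] = np.nan
            records.append(rec)
    table = pd.DataFrame(records)
    table = table[["subject_id", "trial_id", "arousal", "valence",
                   "task_exponent", "task_offset", "task_alpha",
                   "pre_exponent", "pre_offset", "pre_alpha", "alpha_cf"]]
    return table, GroundTruth(config=config, subject_effects=subjects,
                              betas=betas)


def generate_cluster_study(config: GeneratorConfig | None = None,
                           clusters: tuple = ("prefrontal", "frontal",
                                              "frontocentral", "central",
                                              "centroparietal", "parietal",
                                              "parietooccipital",
                                              "right_temporal",
                                              "left_temporal"),
                           arousal_effects: dict | None = None,
                           valence_effects: dict | None = None) -> tuple:
    """Draw a study with per-cluster spectral features.

    Subject random effects and the trial ratings are shared across
    clusters; each cluster gets its own prestimulus draw and residual
    noise.  ``arousal_effects`` / ``valence_effects`` map cluster name to
    the fixed effect on each feature (defaults to the config's global
    effect for every cluster), so spatially localized effects can be
    planted and recovered.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n_s, n_t = config.n_subjects, config.n_trials

    base_betas = {feat: {
        "arousal": getattr(config, f"beta_arousal_{feat}"),
        "valence": getattr(config, f"beta_valence_{feat}"),
        "interaction": config.beta_interaction,
        "prestimulus": config.beta_prestim,
        "baseline": getattr(config, f"base_{feat}"),
    } for feat in _FEATURES}

    subj_rows = []
    for s in range(n_s):
        row = {"subject_id": f"S{s + 1:02d}"}
        for feat in _FEATURES:
            row[f"u0_{feat}"] = config.sd_intercept * rng.standard_normal()
            row[f"uA_{feat}"] = (config.sd_arousal_slope
                                 * rng.standard_normal())
            row[f"uV_{feat}"] = (config.sd_valence_slope
                                 * rng.standard_normal())
        subj_rows.append(row)
    subjects = pd.DataFrame(subj_rows)

    records = []
    for s, srow in subjects.iterrows():
        arousal = np.clip(rng.normal(config.rating_mean, config.rating_sd,
                                     n_t), 1.0, 9.0)
        valence = np.clip(rng.normal(config.rating_mean, config.rating_sd,
                                     n_t), 1.0, 9.0)
        for t in range(n_t):
            for c in clusters:
                rec = {"subject_id": srow["subject_id"], "trial_id": t + 1,
                       "cluster": c, "arousal": arousal[t],
                       "valence": valence[t]}
                for feat in _FEATURES:
                    b = dict(base_betas[feat])
                    if arousal_effects is not None:
                        b["arousal"] = arousal_effects.get(c, 0.0)
                    if valence_effects is not None:
                        b["valence"] = valence_effects.get(c, 0.0)
                    pre = (b["baseline"] + srow[f"u0_{feat}"]
                           + config.sd_prestim * rng.standard_normal())
                    task = (b["baseline"] + srow[f"u0_{feat}"]
                            + b["prestimulus"] * pre
                            + (b["arousal"] + srow[f"uA_{feat}"]) * arousal[t]
                            + (b["valence"] + srow[f"uV_{feat}"]) * valence[t]
                            + b["interaction"] * arousal[t] * valence[t]
                            + config.sd_residual * rng.standard_normal())
                    rec[f"pre_{feat}"] = pre
                    rec[f"task_{feat}"] = task
                records.append(rec)
    table = pd.DataFrame(records)
    betas = {feat: dict(base_betas[feat]) for feat in _FEATURES}
    return table, GroundTruth(config=config, subject_effects=subjects,
                              betas=betas)


def synthesize_epoch(exponent: float, offset: float, alpha_power: float,
                     alpha_cf: float, alpha_width: float = 1.2,
                     epoch_s: float = 60.0, fs: float = 256.0,
                     seed: int = 0) -> np.ndarray:
    """Synthesize a time series whose PSD has the given parameters.

    White Gaussian noise is shaped in the frequency domain so its one-sided
    PSD follows ``10**(offset - exponent*log10 f + G(f))`` with ``G`` the
    alpha Gaussian in log10 power (``alpha_power`` may be 0 for a pure
    aperiodic signal).  Shaping amplitudes multiply independent unit-variance
    spectral coefficients, so a multitaper estimate of the output recovers
    the target parameters up to estimator noise.
    """
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    if alpha_cf >= fs / 2:
        raise ValueError(f"alpha center {alpha_cf} Hz at/above Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(epoch_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    log_psd = np.zeros_like(freqs)
    pos = freqs > 0
    log_psd[pos] = offset - exponent * np.log10(freqs[pos])
    if alpha_power != 0.0:
        log_psd = log_psd + gaussian_model(freqs, alpha_power, alpha_cf,
                                           alpha_width)
    psd = 10.0 ** log_psd
    psd[0] = 0.0
    # spectral coefficients with E|X_k|^2 matching the target one-sided PSD
    amp = np.sqrt(psd * fs * n / 2.0)
    phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(
        freqs.size)
    phases /= np.sqrt(2.0)
    coeffs = amp * phases
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = amp[-1] * rng.standard_normal()
    return np.fft.irfft(coeffs, n=n)


def write_dataset(table: pd.DataFrame, truth: GroundTruth,
                  path: str | Path, epochs: dict | None = None,
                  fs: float | None = None) -> None:
    """Write a generated study to ``path``.

    Layout: ``trials.csv`` (trial table), ``ground_truth.json``, and when
    ``epochs`` is given ({(subject_id, trial_id): 1-d array}) one
    whitespace-delimited text file per epoch under ``epochs/`` plus a
    ``manifest.json`` recording the sampling rate, units and file list.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table.to_csv(path / "trials.csv", index=False)
    truth.to_json(path / "ground_truth.json")
    if epochs is not None:
        epoch_dir = path / "epochs"
        epoch_dir.mkdir(exist_ok=True)
        manifest = {"fs": fs or truth.config.fs, "units": "arbitrary",
                    "files": {}}
        for (subject_id, trial_id), samples in epochs.items():
            name = f"{subject_id}_trial{trial_id:03d}.txt"
            np.savetxt(epoch_dir / name, np.asarray(samples))
            manifest["files"][f"{subject_id}/{trial_id}"] = f"epochs/{name}"
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def read_dataset(path: str | Path) -> tuple:
    """Read back a dataset written by :func:`write_dataset`.

    Returns ``(table, truth_dict, epochs)``; epochs is None when the
    dataset has no epoch container.
    """
    path = Path(path)
    table = pd.read_csv(path / "trials.csv")
    with open(path / "ground_truth.json") as fh:
        truth = json.load(fh)
    epochs = None
    manifest_path = path / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        epochs = {}
        for key, rel in manifest["files"].items():
            subject_id, trial_id = key.split("/")
            epochs[(subject_id, int(trial_id))] = np.loadtxt(path / rel)
    return table, truth, epochs
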