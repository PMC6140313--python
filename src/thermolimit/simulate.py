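"""Synthetic velocity traces with known immobilisation times.

The generator emulates the structure the detector assumes: each individual
swims actively (positive, noisy velocity with occasional pause bouts), slows
across a short decline window, and is immobile afterwards (velocity at the
tracking-jitter floor), with frame dropouts throughout. The true
immobilisation time T* is drawn from a linear covariate model — an additive
treatment effect plus a body-size slope plus Gaussian residual — so that
every downstream stage (detection, calibration, reporting) can be checked
against ground truth.

The velocity process is deliberately simple: the method only needs a
separable active/immobile contrast plus realistic nuisance (pauses,
dropouts, jitter). Traces are generated directly at the analysis rate
(default 3 obs/s), since the pipeline never sees the raw camera frame rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import (
    Dataset,
    SubjectMeta,
    VelocityTrack,
    join_dataset,
    write_metadata,
    write_tracking,
)

logger = logging.getLogger(__name__)

#: True treatment effect (s) between 17 and 22 degC acclimation used by the
#: calibration preset, and the size slope (s/mm); the residual SD and size
#: spread are chosen so the covariate model explains ~0.6 of the variance.
CALIBRATION_EFFECT_S = 566.58
SIZE_SLOPE_S_PER_MM = -114.97

#: Validation preset: per-degC slope anchored so the 17->22 degC span
#: reproduces the calibration effect.
VALIDATION_SLOPE_S_PER_DEGC = CALIBRATION_EFFECT_S / 5.0
VALIDATION_TEMPS_C = (12, 17, 20, 24, 28)


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Covariate model (units: seconds):
        T* = t_star_base + effect(treatment) + beta_size * (size - mid size)
             + Normal(0, sigma_t), truncated below at t_star_min.

    Velocity process (units: mm/s), per subject at ``sample_rate`` obs/s:
    active speed is gamma-distributed with per-subject mean (lognormal
    around ``active_mean`` with CV ``between_subject_cv``) and within-subject
    CV ``active_cv``; pause bouts (stationary occupancy ``pause_prob``, mean
    duration ``pause_mean_s``, capped at ``pause_max_s`` — a voluntary pause
    longer than that would be indistinguishable from immobilisation and the
    true T* would no longer be the time mobility was lost) replace the speed
    with exponential draws of mean ``pause_speed``; across a per-subject
    decline phase (lognormal duration, mean ``decline_window_s``, CV
    ``decline_cv``) ending at T*, swimming becomes intermittent: each sample
    is a fading burst with probability falling linearly to zero, otherwise a
    moribund flicker at the pause speed — with ``pause_prob`` zero the
    decline degenerates to a clean linear ramp and the mean
    ramps linearly to zero; after T* the track shows only unsigned Gaussian
    jitter whose SD varies between subjects (lognormal around
    ``resid_noise_mm_s`` with CV ``jitter_cv`` — tracking noise differs with
    well position, focus and lighting); each sample is independently missing
    with probability ``dropout_prob``. Recording covers the last
    immobilisation plus ``tail_s``.
    """

    n_per_treatment: int = 315
    treatments: Mapping[str, float] = field(
        default_factory=lambda: {"17": 0.0, "22": CALIBRATION_EFFECT_S}
    )
    beta_size: float = SIZE_SLOPE_S_PER_MM
    t_star_base: float = 1200.0
    sigma_t: float = 240.0
    t_star_min: float = 60.0
    size_range_mm: tuple[float, float] = (1.5, 3.5)
    sample_rate: float = 3.0
    active_mean: float = 2.0
    active_cv: float = 0.5
    between_subject_cv: float = 0.3
    pause_prob: float = 0.04
    pause_mean_s: float = 5.0
    pause_max_s: float = 20.0
    pause_refractory_s: float = 30.0
    pause_speed: float = 0.05
    decline_window_s: float = 60.0
    decline_cv: float = 0.6
    resid_noise_mm_s: float = 0.02
    jitter_cv: float = 0.3
    dropout_prob: float = 0.01
    tail_s: float = 120.0
    intro_spacing_s: float = 4.5
    plate_capacity: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_treatment < 0:
            raise ValueError("n_per_treatment must be >= 0")
        if not self.treatments:
            raise ValueError("at least one treatment level is required")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if not self.active_mean > 0:
            raise ValueError("active_mean must be > 0")
        if self.size_range_mm[0] <= 0 or self.size_range_mm[1] < self.size_range_mm[0]:
            raise ValueError("size_range_mm must be a positive (min, max) pair")
        if not 0 <= self.pause_prob < 1:
            raise ValueError("pause_prob must be in [0, 1)")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.resid_noise_mm_s < 0 or self.sigma_t < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.resid_noise_mm_s > 0.05 * self.active_mean:
            warnings.warn(
                "tracking jitter is large relative to active swimming speed; "
                "no velocity threshold may separate active from immobile"
            )
        if self.plate_capacity < 1 or self.intro_spacing_s < 0:
            raise ValueError("plate_capacity must be >= 1 and intro_spacing_s >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated individual."""

    subject_id: str
    true_t_star_s: float
    treatment: str
    body_size_mm: float
    intro_offset_s: float
    block: str
    run: str


def _truth_rng(params: SimParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)))


def _track_rng(params: SimParams, subject_index: int) -> np.random.Generator:
    # one stream per subject so each trace is reproducible independently of
    # collection order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(1, subject_index))
    )


def sample_truth(params: SimParams, rng: np.random.Generator | None = None) -> list[SyntheticTruth]:
    """Draw covariates and true immobilisation times for every subject.

    Subjects are grouped by treatment (each treatment is a separate recording
    block, as in a two-block acclimation design); introduction offsets cycle
    within plates of ``plate_capacity`` wells at ``intro_spacing_s`` spacing.
    """
    rng = rng or _truth_rng(params)
    mid_size = 0.5 * (params.size_range_mm[0] + params.size_range_mm[1])
    truths: list[SyntheticTruth] = []
    n_truncated = 0
    i = 0
    for treatment, effect in params.treatments.items():
        for j in range(params.n_per_treatment):
            size = float(rng.uniform(*params.size_range_mm))
            t_star = (
                params.t_star_base
                + effect
                + params.beta_size * (size - mid_size)
                + float(rng.normal(0.0, params.sigma_t))
            )
            if t_star < params.t_star_min:
                t_star = params.t_star_min
                n_truncated += 1
            plate = j // params.plate_capacity
            truths.append(
                SyntheticTruth(
                    subject_id=f"s{i:04d}",
                    true_t_star_s=float(t_star),
                    treatment=str(treatment),
                    body_size_mm=size,
                    intro_offset_s=(j % params.plate_capacity) * params.intro_spacing_s,
                    block=f"block-{treatment}",
                    run=f"run-{plate}",
                )
            )
            i += 1
    if truths and n_truncated > 0.01 * len(truths):
        warnings.warn(
            f"{n_truncated}/{len(truths)} true immobilisation times hit the "
            f"{params.t_star_min} s floor; effect sizes are inconsistent with t_star_base"
        )
    return truths


def _pause_mask(rng: np.random.Generator, n: int, params: SimParams) -> np.ndarray:
    """Boolean pause-state series from an alternating renewal process.

    Bout lengths are geometric with mean ``pause_mean_s * sample_rate``
    samples, truncated at ``pause_max_s`` (pauses are transient by
    definition). Each bout is followed by a refractory swimming period of at
    least ``pause_refractory_s`` plus a geometric gap whose mean makes the
    stationary pause occupancy approximately ``pause_prob``. The refractory
    period bounds the pause fraction of any window, so pause episodes can
    never masquerade as immobilisation under a wide median.
    """
    mask = np.zeros(n, dtype=bool)
    if params.pause_prob <= 0 or n == 0:
        return mask
    rate = params.sample_rate
    mean_len = max(params.pause_mean_s * rate, 1.0)
    max_len = max(int(round(params.pause_max_s * rate)), 1)
    refractory = int(round(params.pause_refractory_s * rate))
    q = 1.0 / mean_len  # pause exit probability
    pi = params.pause_prob
    mean_gap = mean_len * (1.0 - pi) / pi
    p_on = 1.0 / max(mean_gap - refractory, 1.0)
    pos = 0
    while pos < n:
        gap = refractory + int(rng.geometric(min(p_on, 1.0)))
        bout = min(int(rng.geometric(min(q, 1.0))), max_len)
        start = pos + gap
        mask[start : start + bout] = True
        pos = start + bout
    return mask


def simulate_velocity(
    truth: SyntheticTruth,
    params: SimParams,
    rng: np.random.Generator,
    n_samples: int,
) -> VelocityTrack:
    """One subject's velocity trace of ``n_samples`` at the analysis rate.

    The recording clock starts after the subject was introduced, so in video
    time the animal immobilises at ``true_t_star_s - intro_offset_s``
    (floored at zero).
    """
    rate = params.sample_rate
    t_video = max(truth.true_t_star_s - truth.intro_offset_s, 0.0)
    if params.pause_prob > 0 and params.decline_cv > 0:
        sd = np.sqrt(np.log1p(params.decline_cv**2))
        decline = float(
            rng.lognormal(np.log(params.decline_window_s) - 0.5 * sd**2, sd)
        )
    else:
        decline = params.decline_window_s
    if decline >= t_video and t_video > 0:
        warnings.warn(
            f"subject {truth.subject_id!r}: decline window clipped to the "
            f"{t_video:.1f} s available before immobilisation"
        )
    decline = min(decline, t_video)
    t = np.arange(n_samples) / rate
    # per-subject baseline speed: individuals differ in how fast they swim
    if params.between_subject_cv > 0:
        s = np.sqrt(np.log1p(params.between_subject_cv**2))
        subject_mean = float(
            rng.lognormal(np.log(params.active_mean) - 0.5 * s**2, s)
        )
    else:
        subject_mean = params.active_mean
    means = np.zeros(n_samples)
    active = t < t_video - decline
    means[active] = subject_mean
    declining = (t >= t_video - decline) & (t < t_video)
    if decline > 0:
        if params.pause_prob > 0:
            # intermittent fade: bursts of fading vigour become rarer as the
            # animal approaches immobilisation; between bursts it only
            # flickers at the moribund (pause) speed
            u = (t[declining] - (t_video - decline)) / decline
            burst = rng.random(u.size) < (1.0 - u)
            means[declining] = np.where(burst, subject_mean * (1.0 - u), -1.0)
        else:
            means[declining] = subject_mean * (t_video - t[declining]) / decline
    v = np.zeros(n_samples)
    moribund = means < 0
    v[moribund] = rng.exponential(params.pause_speed, size=int(moribund.sum()))
    means[moribund] = 0.0
    moving = means > 0
    if params.active_cv > 0:
        shape = 1.0 / params.active_cv**2
        v[moving] = rng.gamma(shape, 1.0, size=int(moving.sum())) * (
            means[moving] / shape
        )
    else:
        v[moving] = means[moving]
    pauses = _pause_mask(rng, n_samples, params) & active
    if pauses.any():
        v[pauses] = rng.exponential(params.pause_speed, size=int(pauses.sum()))
    post = t >= t_video
    if params.resid_noise_mm_s > 0:
        if params.jitter_cv > 0:
            sj = np.sqrt(np.log1p(params.jitter_cv**2))
            subject_jitter = float(
                rng.lognormal(np.log(params.resid_noise_mm_s) - 0.5 * sj**2, sj)
            )
        else:
            subject_jitter = params.resid_noise_mm_s
        v[post] = np.abs(rng.normal(0.0, subject_jitter, size=int(post.sum())))
    else:
        v[post] = 0.0
    if params.dropout_prob > 0:
        v[rng.random(n_samples) < params.dropout_prob] = np.nan
    return VelocityTrack(
        subject_id=truth.subject_id,
        sample_rate=rate,
        velocities=v,
        intro_offset_s=truth.intro_offset_s,
    )


def simulate_experiment(
    params: SimParams, out_dir: str | Path | None = None
) -> tuple[Dataset, pd.DataFrame]:
    """Full synthetic experiment: truths, tracks, metadata, optional files.

    All tracks share one recording length covering the latest video-time
    immobilisation plus ``tail_s`` (a single camera films the whole plate;
    recording stops shortly after the last animal is motionless). When
    ``out_dir`` is given, writes ``tracking.csv``, ``metadata.csv`` and
    ``truth.csv`` in the canonical formats.
    """
    truths = sample_truth(params)
    if not truths:
        raise ValueError("simulated design has no subjects")
    duration = max(max(t.true_t_star_s - t.intro_offset_s, 0.0) for t in truths)
    n_samples = int(np.ceil((duration + params.tail_s) * params.sample_rate)) + 1
    tracks = [
        simulate_velocity(truth, params, _track_rng(params, i), n_samples)
        for i, truth in enumerate(truths)
    ]
    meta = [
        SubjectMeta(
            subject_id=t.subject_id,
            treatment=t.treatment,
            body_size_mm=t.body_size_mm,
            intro_offset_s=t.intro_offset_s,
            block=t.block,
            run=t.run,
        )
        for t in truths
    ]
    dataset = join_dataset(tracks, meta)
    truth_df = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in truths],
            "true_t_star_s": [t.true_t_star_s for t in truths],
            "treatment": [t.treatment for t in truths],
            "body_size_mm": [t.body_size_mm for t in truths],
            "intro_offset_s": [t.intro_offset_s for t in truths],
        }
    )
    logger.info(
        "simulated %d subjects x %d samples (%.0f s at %g obs/s)",
        len(tracks), n_samples, n_samples / params.sample_rate, params.sample_rate,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tracking(tracks, out_dir / "tracking.csv")
        write_metadata(meta, out_dir / "metadata.csv")
        truth_df.to_csv(out_dir / "truth.csv", index=False)
    return dataset, truth_df


def calibration_params(seed: int = 0, n_per_treatment: int = 315, **overrides) -> SimParams:
    """Two-treatment acclimation design (17 vs 22 degC blocks)."""
    return replace(
        SimParams(seed=seed, n_per_treatment=n_per_treatment), **overrides
    )


def validation_params(seed: int = 0, **overrides) -> SimParams:
    """Five-temperature gradient design (12-28 degC, nine per group).

    True effects are linear in acclimation temperature, anchored so the
    17->22 degC span equals the calibration effect.
    """
    effects = {
        str(temp): VALIDATION_SLOPE_S_PER_DEGC * (temp - VALIDATION_TEMPS_C[0])
        for temp in VALIDATION_TEMPS_C
    }
    return replace(
        SimParams(seed=seed, n_per_treatment=9, treatments=effects), **overrides
    )


PRESETS = {"calibration": calibration_params, "validation": validation_params}
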