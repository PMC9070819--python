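"""Seeded generation of synthetic cat landing trials.

No public recording of the landing cohort exists, so this module emulates its
structure: 56 cats x 10 trials x 4 drop heights (60-120 cm), three-channel
ground reaction force (GRF) at 1,000 Hz and four sagittal segment-angle traces
per trial.  Vertical impact magnitude grows with drop height (impact speed is
proportional to the square root of the height), cats differ by smooth random
offsets, and a configurable *effect profile* plants a known distal-to-proximal
shift in which joint's trajectories discriminate adjacent heights.  The planted
profile is recoverable through :func:`planted_truth`, which is what lets the
downstream relevance-propagation pipeline be tested against a ground truth.

Waveform family: each GRF channel is a sum of smooth bumps gated by a contact
ramp; each segment angle is a logistic flexion ramp.  Cat-level variability is
a random multiplicative force scale plus additive angle offsets; trial-level
variability is low-pass-filtered white noise, so every generated channel is a
plausible smooth biomechanical trace.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import ConfigurationError

G = 9.81  # m/s^2

#: fixed trajectory order used throughout the package
JOINTS = ("wrist", "elbow", "shoulder")

#: default discriminative weights per adjacent height pair (wrist, elbow, shoulder):
#: distal-heavy for the lowest pair, uniform in the middle, proximal-heavy on top.
DEFAULT_EFFECT_PROFILE: dict[tuple[int, int], tuple[float, float, float]] = {
    (60, 80): (0.6, 0.3, 0.1),
    (80, 100): (1 / 3, 1 / 3, 1 / 3),
    (100, 120): (0.1, 0.3, 0.6),
}


@dataclass(frozen=True)
class CatProfile:
    """Per-cat anthropometry: body mass and the three forelimb segment lengths.

    Segment numbering is distal to proximal: L1 = carpal link, L2 = forearm,
    L3 = arm.  Lengths are in metres, body mass in kg.
    """

    cat_id: str
    body_mass: float
    segment_lengths: tuple[float, float, float]

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ConfigurationError("body_mass must be positive")
        if any(L <= 0 for L in self.segment_lengths):
            raise ConfigurationError("segment_lengths must all be positive")
        if self.segment_lengths[0] >= min(self.segment_lengths[1:]):
            raise ConfigurationError(
                "segment_lengths: the carpal segment (L1) must be the shortest"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for cohort generation.

    Defaults reproduce the cohort geometry of the emulated experiment:
    56 cats, 10 trials per cat per height, heights 60/80/100/120 cm at
    1,000 Hz.  ``effect_profile`` maps each adjacent height pair to
    (wrist, elbow, shoulder) weights summing to 1; moving one height up the
    ladder increments the weighted joints' flexion excursions by
    ``effect_scale`` times the weight, which is the planted discriminative
    signal.
    """

    n_cats: int = 56
    trials_per_cat_per_height: int = 10
    heights: tuple[int, ...] = (60, 80, 100, 120)
    sample_rate: float = 1000.0
    duration_range_s: tuple[float, float] = (0.12, 0.25)
    pre_contact_s: float = 0.04
    post_phase_s: float = 0.06
    body_mass_mean: float = 4.32
    body_mass_sd: float = 0.53
    segment_length_means: tuple[float, float, float] = (0.05, 0.10, 0.11)
    segment_length_sd_frac: float = 0.06
    grf_cat_scale_sd: float = 0.08
    grf_trial_scale_sd: float = 0.05
    grf_noise_N: float = 2.0
    angle_cat_offset_sd_deg: float = 2.0
    angle_noise_deg: float = 0.8
    effect_scale: float = 0.5
    effect_profile: Mapping[tuple[int, int], tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cats <= 0:
            raise ConfigurationError("n_cats must be positive")
        if self.trials_per_cat_per_height <= 0:
            raise ConfigurationError("trials_per_cat_per_height must be positive")
        if len(self.heights) == 0 or any(h <= 0 for h in self.heights):
            raise ConfigurationError("heights must be positive")
        if any(b <= a for a, b in zip(self.heights, self.heights[1:])):
            raise ConfigurationError("heights must be strictly increasing")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ConfigurationError("duration_range_s must satisfy 0 < lo <= hi")
        if self.body_mass_mean <= 0:
            raise ConfigurationError("body_mass_mean must be positive")
        if any(L <= 0 for L in self.segment_length_means):
            raise ConfigurationError("segment_length_means must be positive")
        for pair, w in self.pair_effect_profile().items():
            if len(w) != len(JOINTS):
                raise ConfigurationError(f"effect_profile[{pair}] needs one weight per joint")
            if any(x < 0 for x in w):
                raise ConfigurationError(f"effect_profile[{pair}] weights must be non-negative")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ConfigurationError(f"effect_profile[{pair}] weights must sum to 1")

    def pair_effect_profile(self) -> dict[tuple[int, int], tuple[float, float, float]]:
        """Effect weights keyed by adjacent height pair, filled with defaults."""
        if self.effect_profile is not None:
            prof = {tuple(k): tuple(v) for k, v in self.effect_profile.items()}
        else:
            prof = {}
        out = {}
        for lo, hi in zip(self.heights, self.heights[1:]):
            if (lo, hi) in prof:
                out[(lo, hi)] = prof[(lo, hi)]
            elif (lo, hi) in DEFAULT_EFFECT_PROFILE:
                out[(lo, hi)] = DEFAULT_EFFECT_PROFILE[(lo, hi)]
            else:
                out[(lo, hi)] = tuple([1.0 / len(JOINTS)] * len(JOINTS))
        return out


@dataclass
class LandingTrial:
    """One landing recording: GRF channels (N) and segment angles (degrees).

    ``grf_x`` is medial/lateral, ``grf_y`` anterior/posterior, ``grf_z``
    vertical.  ``alpha1..alpha3`` are the carpal-link, forearm and arm segment
    angles versus the horizontal; ``alpha4`` is the shoulder joint angle.
    """

    cat_id: str
    height_cm: int
    sample_rate: float
    grf_x: np.ndarray
    grf_y: np.ndarray
    grf_z: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha3: np.ndarray
    alpha4: np.ndarray
    body_mass: float = float("nan")
    segment_lengths: tuple[float, float, float] | None = None
    trial_index: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.grf_z)

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "grf_x": self.grf_x, "grf_y": self.grf_y, "grf_z": self.grf_z,
            "alpha1": self.alpha1, "alpha2": self.alpha2,
            "alpha3": self.alpha3, "alpha4": self.alpha4,
        }

    def validate(self, max_angle_jump_deg: float = 10.0) -> None:
        chans = self.channels()
        n = self.n_samples
        for name, c in chans.items():
            if len(c) != n:
                raise ConfigurationError(f"channel {name} length {len(c)} != {n}")
            if not np.all(np.isfinite(c)):
                raise ConfigurationError(f"channel {name} contains non-finite values")
        if np.any(self.grf_z < 0):
            raise ConfigurationError("grf_z must be non-negative")
        for name in ("alpha1", "alpha2", "alpha3", "alpha4"):
            if np.max(np.abs(np.diff(chans[name]))) > max_angle_jump_deg:
                raise ConfigurationError(f"channel {name} has a per-sample jump above bound")

    def trimmed(self, start: int, stop: int) -> "LandingTrial":
        """Copy of this trial restricted to sample window [start, stop]."""
        kw = {k: v[start:stop + 1].copy() for k, v in self.channels().items()}
        return LandingTrial(
            cat_id=self.cat_id, height_cm=self.height_cm, sample_rate=self.sample_rate,
            body_mass=self.body_mass, segment_lengths=self.segment_lengths,
            trial_index=self.trial_index, **kw,
        )


# Angle templates live in *joint space*: the carpal-link pitch (alpha1) and
# the wrist/elbow/shoulder joint angles each get their own base posture (deg),
# flexion excursion (deg), cat offset and trial noise, and the forearm/arm
# segment angles are derived from the chain.  Building the curves this way
# keeps each joint's angle block statistically independent of the others
# (no shared segment noise) while the planted modulation still reaches the
# segment angles that generate the corresponding joint moments: the wrist
# weight drives alpha1 (and hence the carpal moment), and part of the
# shoulder weight drives an arm-segment rotation so the shoulder moment
# carries shoulder signal too.
_JOINT_BASES = {"alpha1": 30.0, "wrist": 150.0, "elbow": 135.0, "shoulder": 125.0}
_JOINT_EXCURSIONS = {"alpha1": -28.0, "wrist": -36.0, "elbow": -25.0, "shoulder": -50.0}
_JOINT_EFFECT = {"alpha1": "wrist", "wrist": "wrist", "elbow": "elbow", "shoulder": "shoulder"}
#: shoulder-weighted arm-segment rotation (deg) — the kinetic route of the
#: shoulder's planted share
_ARM_SHOULDER_EXCURSION = 15.0


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, fs: float, cutoff: float = 15.0) -> np.ndarray:
    """Low-pass-filtered white noise with the requested pointwise sd."""
    if sd <= 0 or n < 20:
        return np.zeros(n)
    w = rng.standard_normal(n + 60)
    b, a = butter(2, cutoff / (fs / 2))
    s = filtfilt(b, a, w)[30:30 + n]
    s_sd = s.std()
    return s * (sd / s_sd) if s_sd > 0 else np.zeros(n)


def _flexion_profile(s: np.ndarray) -> np.ndarray:
    """Normalized monotone flexion ramp: 0 at contact (s=0), 1 at phase end (s=1).

    The transition is kept gentle (logistic width 0.18 of the phase) so the
    angle content stays below the 6 Hz analysis band at realistic landing
    durations.
    """
    logistic = 1.0 / (1.0 + np.exp(-(s - 0.5) / 0.18))
    l0 = 1.0 / (1.0 + np.exp(0.5 / 0.18))
    l1 = 1.0 / (1.0 + np.exp(-0.5 / 0.18))
    core = (logistic - l0) / (l1 - l0)
    ramp = 0.85 * core + 0.15 * s  # keep a nonzero slope through the plateau
    ramp = np.clip(ramp, 0.0, None) * (s >= 0)
    # past the landing phase the limb re-extends, so maximum flexion is an
    # interior event of the recording rather than its final sample
    post = s > 1.0
    ramp[post] = 1.0 - 0.8 * (s[post] - 1.0)
    return ramp


def cumulative_effect(config: GeneratorConfig) -> dict[int, dict[str, float]]:
    """Per-height multiplicative modulation of each joint's flexion excursion.

    Walking up the height ladder adds ``effect_scale * weight`` for each
    adjacent pair crossed, so the *difference* between the two heights of a
    pair is exactly the planted pair weight (times the scale).
    """
    prof = config.pair_effect_profile()
    mods: dict[int, dict[str, float]] = {}
    acc = dict.fromkeys(JOINTS, 0.0)
    for i, h in enumerate(config.heights):
        if i > 0:
            pair = (config.heights[i - 1], h)
            for j, joint in enumerate(JOINTS):
                acc[joint] += config.effect_scale * prof[pair][j]
        mods[h] = dict(acc)
    return mods


def planted_truth(config: GeneratorConfig) -> dict[tuple[int, int], dict[str, float]]:
    """The discriminative ground truth actually injected, keyed by height pair.

    Returns, for each adjacent pair, the per-joint weights the generator used;
    relevance-recovery tests compare LRP joint rankings against these.
    """
    return {
        pair: dict(zip(JOINTS, w))
        for pair, w in config.pair_effect_profile().items()
    }


def generate_cats(config: GeneratorConfig, rng: np.random.Generator) -> list[CatProfile]:
    cats = []
    for i in range(config.n_cats):
        mass = float(np.clip(
            rng.normal(config.body_mass_mean, config.body_mass_sd),
            0.3 * config.body_mass_mean, None))
        lengths = tuple(
            float(np.clip(rng.normal(mu, config.segment_length_sd_frac * mu), 0.5 * mu, None))
            for mu in config.segment_length_means
        )
        # enforce the carpal-shortest ordering the anatomy implies
        if lengths[0] >= min(lengths[1:]):
            lengths = (0.9 * min(lengths[1:]), lengths[1], lengths[2])
        cats.append(CatProfile(cat_id=f"cat{i:03d}", body_mass=mass, segment_lengths=lengths))
    return cats


def _generate_trial(config: GeneratorConfig, cat: CatProfile, cat_state: dict,
                    height: int, mods: dict[str, float], trial_index: int,
                    rng: np.random.Generator) -> LandingTrial:
    fs = config.sample_rate
    dur = rng.uniform(*config.duration_range_s)
    n_pre = int(round(config.pre_contact_s * fs))
    n_phase = max(int(round(dur * fs)), 20)
    n = n_pre + n_phase + int(round(config.post_phase_s * fs))
    t = np.arange(n) / fs
    s = (t - config.pre_contact_s) / dur  # landing-phase fraction; <0 before contact

    # --- ground reaction forces -------------------------------------------
    h_m = height / 100.0
    bw = cat.body_mass * G
    peak = bw * (1.4 + 2.2 * np.sqrt(h_m)) * cat_state["grf_scale"] \
        * (1.0 + rng.normal(0.0, config.grf_trial_scale_sd))
    ramp = np.where(s > 0, 1.0 - np.exp(-(np.clip(s, 0, None) / 0.06) ** 2), 0.0)
    bump = lambda mu, w: np.exp(-(((s - mu) / w) ** 2))
    fz = (peak * bump(0.22, 0.13) + 0.5 * peak * bump(0.60, 0.25)) * ramp
    fy = peak * (-0.28 * bump(0.18, 0.10) + 0.12 * bump(0.65, 0.25)) * ramp
    fx = cat_state["lateral_sign"] * 0.07 * peak * bump(0.30, 0.20) * ramp
    fz = fz + _smooth_noise(rng, n, config.grf_noise_N, fs) * ramp
    fy = fy + _smooth_noise(rng, n, 0.8 * config.grf_noise_N, fs) * ramp
    fx = fx + _smooth_noise(rng, n, 0.8 * config.grf_noise_N, fs) * ramp
    fz = np.clip(fz, 0.0, None)

    # --- angles: joint-space curves, then the segment chain ----------------
    f = _flexion_profile(s)
    joint = {}
    for name in ("alpha1", "wrist", "elbow", "shoulder"):
        exc = _JOINT_EXCURSIONS[name] * (1.0 + mods[_JOINT_EFFECT[name]])
        base = _JOINT_BASES[name] + cat_state["angle_offsets"][name]
        joint[name] = base + exc * f + _smooth_noise(rng, n, config.angle_noise_deg, fs)
    alpha1 = joint["alpha1"]
    alpha2 = alpha1 + 180.0 - joint["wrist"]
    alpha3 = 180.0 + alpha2 - joint["elbow"] \
        + _ARM_SHOULDER_EXCURSION * (1.0 + mods["shoulder"]) * f
    alpha4 = joint["shoulder"]

    return LandingTrial(
        cat_id=cat.cat_id, height_cm=height, sample_rate=fs,
        grf_x=fx, grf_y=fy, grf_z=fz,
        alpha1=alpha1, alpha2=alpha2, alpha3=alpha3, alpha4=alpha4,
        body_mass=cat.body_mass, segment_lengths=cat.segment_lengths,
        trial_index=trial_index,
    )


def generate_cohort(config: GeneratorConfig) -> dict[int, list[LandingTrial]]:
    """Generate the full cohort, grouped by drop height.

    A pure function of the config (including its seed): identical configs give
    bit-identical trials.  Each height key maps to
    ``n_cats * trials_per_cat_per_height`` trials.
    """
    root = np.random.SeedSequence(config.seed)
    cat_ss, trial_ss = root.spawn(2)
    cats = generate_cats(config, np.random.default_rng(cat_ss))

    mods = cumulative_effect(config)
    cohort: dict[int, list[LandingTrial]] = {h: [] for h in config.heights}
    trial_rngs = trial_ss.spawn(config.n_cats)
    for ci, cat in enumerate(cats):
        rng = np.random.default_rng(trial_rngs[ci])
        cat_state = {
            "grf_scale": 1.0 + rng.normal(0.0, config.grf_cat_scale_sd),
            "lateral_sign": float(rng.choice([-1.0, 1.0])),
            "angle_offsets": {
                name: rng.normal(0.0, config.angle_cat_offset_sd_deg)
                for name in ("alpha1", "wrist", "elbow", "shoulder")
            },
        }
        for h in config.heights:
            for k in range(config.trials_per_cat_per_height):
                cohort[h].append(
                    _generate_trial(config, cat, cat_state, h, mods[h], k, rng))
    return cohort


# ---------------------------------------------------------------------------
# long-form CSV I/O


def trials_to_frame(trials: Sequence[LandingTrial]):
    """Long-form table of trials (one row per sample), for CSV export."""
    import pandas as pd

    frames = []
    for ti, tr in enumerate(trials):
        n = tr.n_samples
        frames.append(pd.DataFrame({
            "cat_id": tr.cat_id,
            "height_cm": tr.height_cm,
            "trial_index": tr.trial_index,
            "sample_index": np.arange(n),
            "t_s": np.arange(n) / tr.sample_rate,
            "grf_x_N": tr.grf_x, "grf_y_N": tr.grf_y, "grf_z_N": tr.grf_z,
            "alpha1_deg": tr.alpha1, "alpha2_deg": tr.alpha2,
            "alpha3_deg": tr.alpha3, "alpha4_deg": tr.alpha4,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_trials(df, sample_rate: float,
                    cats: Mapping[str, CatProfile] | None = None) -> list[LandingTrial]:
    """Inverse of :func:`trials_to_frame`."""
    trials = []
    for (cat_id, height, tix), g in df.groupby(["cat_id", "height_cm", "trial_index"], sort=True):
        g = g.sort_values("sample_index")
        cat = cats.get(cat_id) if cats else None
        trials.append(LandingTrial(
            cat_id=cat_id, height_cm=int(height), sample_rate=sample_rate,
            grf_x=g["grf_x_N"].to_numpy(), grf_y=g["grf_y_N"].to_numpy(),
            grf_z=g["grf_z_N"].to_numpy(),
            alpha1=g["alpha1_deg"].to_numpy(), alpha2=g["alpha2_deg"].to_numpy(),
            alpha3=g["alpha3_deg"].to_numpy(), alpha4=g["alpha4_deg"].to_numpy(),
            body_mass=cat.body_mass if cat else float("nan"),
            segment_lengths=cat.segment_lengths if cat else None,
            trial_index=int(tix),
        ))
    return trials


def cohort_manifest(config: GeneratorConfig, cats: Sequence[CatProfile]) -> dict:
    """JSON-serializable echo of the generating config plus per-cat anthropometry."""
    cfg = asdict(config)
    cfg["effect_profile"] = {
        f"{lo}-{hi}": list(w) for (lo, hi), w in config.pair_effect_profile().items()
    }
    return {
        "config": cfg,
        "cats": {
            c.cat_id: {"body_mass_kg": c.body_mass,
                       "segment_lengths_m": list(c.segment_lengths)}
            for c in cats
        },
    }
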