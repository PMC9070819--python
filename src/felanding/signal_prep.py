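"""Filtering, contact detection, landing-phase segmentation and time
normalization.

The landing phase runs from initial ground contact (vertical GRF first
exceeding 10 N, strict) to maximum elbow flexion, and every curve is
re-sampled to 100 points over that window so trials of unequal duration are
comparable.  GRF channels are low-passed at 50 Hz and angle channels at 6 Hz
with fourth-order zero-phase (forward-backward) Butterworth filters; events
are detected on the filtered traces (GRF events on the 50 Hz vertical channel,
the flexion extremum on the 6 Hz elbow angle).

Joint angles are derived from the segment-versus-horizontal angles as

    wrist    = 180 - (alpha2 - alpha1)
    elbow    = 180 + (alpha2 - alpha3)
    shoulder = alpha4

so that flexion reads as a *decreasing* joint angle and maximum elbow flexion
is the minimum of the elbow trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import ConfigurationError, NoContactError, DegeneratePhaseError, SignalError
from .synthetic import LandingTrial

CONTACT_THRESHOLD_N = 10.0

#: fixed column order of the 6 x 100 trajectory blocks in every dataset matrix
TRAJECTORIES = (
    "wrist_angle", "elbow_angle", "shoulder_angle",
    "wrist_moment", "elbow_moment", "shoulder_moment",
)
PRE_DYNAMICS_CURVES = (
    "grf_x", "grf_y", "grf_z", "wrist_angle", "elbow_angle", "shoulder_angle",
)
N_PHASE_POINTS = 100


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification.

    ``order`` is the single-pass order; applied forward-backward the effective
    magnitude response is the squared single-pass response.
    """

    order: int = 4
    cutoff_hz: float = 50.0

    def __post_init__(self):
        if self.order <= 0 or self.order % 2:
            raise ConfigurationError("order must be positive and even")
        if self.cutoff_hz <= 0:
            raise ConfigurationError("cutoff_hz must be positive")


GRF_FILTER = FilterSpec(order=4, cutoff_hz=50.0)
ANGLE_FILTER = FilterSpec(order=4, cutoff_hz=6.0)


def zero_phase_lowpass(signal: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Forward-backward Butterworth low-pass; zero net phase shift.

    Edge transients are suppressed by reflection padding of length 3x the
    filter order.  Raises :class:`SignalError` for signals shorter than the
    padding requires and :class:`ConfigurationError` when the cutoff reaches
    the Nyquist frequency.
    """
    signal = np.asarray(signal, dtype=float)
    if spec.cutoff_hz >= rate / 2:
        raise ConfigurationError(
            f"cutoff_hz {spec.cutoff_hz} must be below the Nyquist frequency {rate / 2}")
    padlen = 3 * spec.order
    if len(signal) <= padlen:
        raise SignalError(
            f"signal length {len(signal)} too short for zero-phase filtering "
            f"(needs > {padlen} samples)")
    b, a = butter(spec.order, spec.cutoff_hz / (rate / 2))
    return filtfilt(b, a, signal, padtype="even", padlen=padlen)


def detect_contact(vertical_grf: np.ndarray, threshold: float = CONTACT_THRESHOLD_N) -> int:
    """First sample index where the vertical GRF strictly exceeds ``threshold``.

    A value of exactly the threshold does not trigger.  Raises
    :class:`NoContactError` if the trace never exceeds it.
    """
    vertical_grf = np.asarray(vertical_grf)
    if vertical_grf.size == 0:
        raise SignalError("empty vertical GRF trace")
    above = np.nonzero(vertical_grf > threshold)[0]
    if above.size == 0:
        raise NoContactError(f"vertical GRF never exceeds {threshold} N")
    return int(above[0])


def joint_angles(trial: LandingTrial) -> dict[str, np.ndarray]:
    """Wrist/elbow/shoulder joint angle traces (degrees) from segment angles."""
    return {
        "wrist_angle": 180.0 - (trial.alpha2 - trial.alpha1),
        "elbow_angle": 180.0 + (trial.alpha2 - trial.alpha3),
        "shoulder_angle": trial.alpha4.copy(),
    }


def filter_trial(trial: LandingTrial,
                 grf_spec: FilterSpec = GRF_FILTER,
                 angle_spec: FilterSpec = ANGLE_FILTER) -> LandingTrial:
    """Return a copy with GRF channels filtered at ``grf_spec`` and angles at
    ``angle_spec``; the filtered vertical GRF is clipped at zero to preserve
    the non-negativity invariant."""
    fs = trial.sample_rate
    return replace(
        trial,
        grf_x=zero_phase_lowpass(trial.grf_x, grf_spec, fs),
        grf_y=zero_phase_lowpass(trial.grf_y, grf_spec, fs),
        grf_z=np.clip(zero_phase_lowpass(trial.grf_z, grf_spec, fs), 0.0, None),
        alpha1=zero_phase_lowpass(trial.alpha1, angle_spec, fs),
        alpha2=zero_phase_lowpass(trial.alpha2, angle_spec, fs),
        alpha3=zero_phase_lowpass(trial.alpha3, angle_spec, fs),
        alpha4=zero_phase_lowpass(trial.alpha4, angle_spec, fs),
    )


def landing_phase_window(trial: LandingTrial) -> tuple[int, int]:
    """(contact index, maximum-elbow-flexion index) of an already-filtered trial.

    Maximum elbow flexion is the global minimum of the elbow joint angle
    trace (earliest index on ties); if it falls at or before contact the
    landing phase is degenerate and an error is raised.
    """
    i0 = detect_contact(trial.grf_z)
    elbow = joint_angles(trial)["elbow_angle"]
    # global flexion extremum; on ties the earliest index after contact wins
    # (tie tolerance absorbs the float-level ripple zero-phase filtering
    # leaves on constant traces)
    min_val = elbow.min()
    tol = 1e-6 * max(1.0, float(np.ptp(elbow)))
    candidates = np.flatnonzero(elbow <= min_val + tol)
    after = candidates[candidates > i0]
    if after.size == 0:
        raise DegeneratePhaseError(
            f"maximum elbow flexion (sample {int(candidates[0])}) at or before "
            f"contact (sample {i0})")
    return i0, int(after[0])


def segment_landing_phase(trial: LandingTrial) -> LandingTrial:
    """Trim an already-filtered trial to [contact, maximum elbow flexion]."""
    i0, i1 = landing_phase_window(trial)
    if i1 - i0 + 1 < 2:
        raise DegeneratePhaseError("landing phase shorter than two samples")
    return trial.trimmed(i0, i1)


def time_normalize(curve: np.ndarray, n_points: int = N_PHASE_POINTS) -> np.ndarray:
    """Resample a curve to ``n_points`` by piecewise-linear interpolation on a
    uniform phase grid (fractions 0, 1/(n-1), ..., 1); endpoints are preserved
    exactly."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or len(curve) < 2:
        raise SignalError("time_normalize needs a 1-D curve of length >= 2")
    src = np.linspace(0.0, 1.0, len(curve))
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, curve)


@dataclass
class NormalizedTrial:
    """Six named 100-point curves over the landing phase (0% = contact,
    100% = maximum elbow flexion) plus trial metadata."""

    cat_id: str
    height_cm: int
    trial_index: int
    curves: dict[str, np.ndarray]

    def __post_init__(self):
        for name, c in self.curves.items():
            if len(c) != N_PHASE_POINTS:
                raise ConfigurationError(
                    f"curve {name} has {len(c)} points, expected {N_PHASE_POINTS}")


def normalize_trial(trial: LandingTrial, curve_names: Sequence[str] = PRE_DYNAMICS_CURVES,
                    n_points: int = N_PHASE_POINTS) -> NormalizedTrial:
    """Time-normalize the requested curves of a segmented trial.

    Pre-dynamics curve set: three GRF channels plus the three joint angles.
    """
    available = dict(trial.channels())
    available.update(joint_angles(trial))
    curves = {name: time_normalize(available[name], n_points) for name in curve_names}
    return NormalizedTrial(cat_id=trial.cat_id, height_cm=trial.height_cm,
                           trial_index=trial.trial_index, curves=curves)


def preprocess_trial(trial: LandingTrial,
                     grf_spec: FilterSpec = GRF_FILTER,
                     angle_spec: FilterSpec = ANGLE_FILTER) -> tuple[LandingTrial, NormalizedTrial]:
    """Filter, segment and normalize one raw trial.

    Returns the trimmed filtered trial (for inverse dynamics, which needs the
    un-normalized time base) together with the 100-point pre-dynamics curves.
    """
    filtered = filter_trial(trial, grf_spec, angle_spec)
    trimmed = segment_landing_phase(filtered)
    return trimmed, normalize_trial(trimmed)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class HeightDataset:
    """Trials x 600 matrix for one drop height.

    Columns are six contiguous 100-point blocks in the fixed order
    ``TRAJECTORIES`` (wrist/elbow/shoulder angle then wrist/elbow/shoulder
    moment)."""

    height_cm: int
    matrix: np.ndarray
    trial_ids: list[tuple[str, int]]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(TRAJECTORIES) * N_PHASE_POINTS:
            raise ConfigurationError(
                f"HeightDataset matrix must have {len(TRAJECTORIES) * N_PHASE_POINTS} columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ConfigurationError("HeightDataset matrix must be finite")
        if len(self.trial_ids) != self.matrix.shape[0]:
            raise ConfigurationError("trial_ids length must match the number of rows")

    def block(self, name: str) -> np.ndarray:
        """The 100-column block of one trajectory."""
        i = TRAJECTORIES.index(name)
        return self.matrix[:, i * N_PHASE_POINTS:(i + 1) * N_PHASE_POINTS]


@dataclass
class PairDataset:
    """Labeled concatenation of two adjacent-height datasets.

    By convention the *lower* height is the positive class (label 1)."""

    pair_id: str
    heights: tuple[int, int]
    matrix: np.ndarray
    labels: np.ndarray
    trial_ids: list[tuple[str, int, int]]

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.labels):
            raise ConfigurationError("labels length must match the number of rows")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ConfigurationError("labels must be binary (1 = lower height)")


def build_height_dataset(trials: Sequence[NormalizedTrial], height_cm: int) -> HeightDataset:
    """Stack normalized trials (angle + moment curves) into a trials x 600 matrix."""
    if not trials:
        raise ConfigurationError("no trials supplied")
    rows = []
    ids = []
    for tr in trials:
        if tr.height_cm != height_cm:
            raise ConfigurationError(
                f"trial from height {tr.height_cm} cannot enter the {height_cm} cm dataset")
        missing = [c for c in TRAJECTORIES if c not in tr.curves]
        if missing:
            raise ConfigurationError(f"trial missing curves: {missing}")
        rows.append(np.concatenate([tr.curves[c] for c in TRAJECTORIES]))
        ids.append((tr.cat_id, tr.trial_index))
    return HeightDataset(height_cm=height_cm, matrix=np.vstack(rows), trial_ids=ids)


def build_pair_dataset(low: HeightDataset, high: HeightDataset, pair_id: str) -> PairDataset:
    """Concatenate two height datasets; the lower height becomes the positive class."""
    if low.height_cm >= high.height_cm:
        raise ConfigurationError("first argument must be the lower height")
    if low.matrix.shape[1] != high.matrix.shape[1]:
        raise ConfigurationError("height datasets have mismatched column counts")
    matrix = np.vstack([low.matrix, high.matrix])
    labels = np.concatenate([
        np.ones(low.matrix.shape[0], dtype=int),
        np.zeros(high.matrix.shape[0], dtype=int),
    ])
    ids = [(cid, low.height_cm, tix) for cid, tix in low.trial_ids] + \
          [(cid, high.height_cm, tix) for cid, tix in high.trial_ids]
    return PairDataset(pair_id=pair_id, heights=(low.height_cm, high.height_cm),
                       matrix=matrix, labels=labels, trial_ids=ids)


# ---------------------------------------------------------------------------
# CSV round-trip


def dataset_column_names() -> list[str]:
    return [f"{traj}_{p + 1:03d}" for traj in TRAJECTORIES for p in range(N_PHASE_POINTS)]


def write_height_dataset(ds: HeightDataset, path) -> None:
    """Full-precision CSV (plus implied column map); reader round-trips bit-exactly."""
    import pandas as pd

    df = pd.DataFrame(ds.matrix, columns=dataset_column_names())
    df.insert(0, "cat_id", [cid for cid, _ in ds.trial_ids])
    df.insert(1, "trial_index", [tix for _, tix in ds.trial_ids])
    # default float formatting is the shortest round-trip repr: bit-exact I/O
    df.to_csv(path, index=False)


def read_height_dataset(path, height_cm: int) -> HeightDataset:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    ids = list(zip(df["cat_id"], df["trial_index"].astype(int)))
    return HeightDataset(height_cm=height_cm,
                         matrix=df[dataset_column_names()].to_numpy(),
                         trial_ids=ids)
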