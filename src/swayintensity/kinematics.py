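"""Trunk-sway kinematics: filtering and posturographic feature extraction.

A trial is a two-axis angular time series recorded by a lumbar IMU:
anterior-posterior (AP, pitch) and medial-lateral (ML, roll) sway angles in
degrees. Features follow standard posturography conventions:

* RMS of the demeaned angle per axis and of the planar (Phi) angle, where
  ``phi(t)^2 = ap(t)^2 + ml(t)^2``.
* Mean sway velocity (MV, deg/s) per axis from first differences, and planar
  MV from the planar step length.
* Path length (deg): cumulative planar distance travelled by the sway
  trajectory.
* Elliptical area (deg^2): area of the ellipse covering a given fraction
  (default 95%) of the planar scatter, from the chi-square(2) quantile applied
  to the sample covariance.

Both axes are demeaned before any feature computation, which makes RMS a
dispersion measure and gives two exact identities used as internal
cross-checks: ``phi_rms^2 = ap_rms^2 + ml_rms^2`` and
``phi_mv * span = path_length`` where ``span = (n - 1) / sample_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.stats import chi2

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "SwayTrial",
    "KinematicFeatures",
    "FEATURE_NAMES",
    "filter_sway",
    "compute_features",
    "elliptical_area",
]

#: untransformed feature names, in canonical output order
FEATURE_NAMES = (
    "phi_rms",
    "ap_rms",
    "ml_rms",
    "phi_mv",
    "ap_mv",
    "ml_mv",
    "path_length",
    "elliptical_area",
)


@dataclass(frozen=True)
class SwayTrial:
    """One balance trial: AP/ML sway angles sampled on a uniform time grid."""

    participant_id: str
    exercise_id: str
    trial_number: int
    time_s: np.ndarray
    ap_deg: np.ndarray
    ml_deg: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        ap = np.asarray(self.ap_deg, dtype=float)
        ml = np.asarray(self.ml_deg, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ap_deg", ap)
        object.__setattr__(self, "ml_deg", ml)
        if not (len(t) == len(ap) == len(ml)):
            raise ConfigurationError("time, AP and ML series must have equal length")
        if len(t) < 2:
            raise InsufficientDataError("a trial needs at least 2 samples")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ConfigurationError("time stamps must be strictly increasing")
        nominal = 1.0 / self.sample_rate_hz
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ConfigurationError(
                "sample spacing deviates more than 1% from 1/sample_rate_hz"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def span_s(self) -> float:
        """Time spanned by the samples, (n - 1) / fs."""
        return (self.n_samples - 1) / self.sample_rate_hz


@dataclass(frozen=True)
class KinematicFeatures:
    """The eight sway features of one trial plus their natural-log transforms.

    A log transform of a zero feature is undefined; such fields are NaN and
    listed in ``log_undefined`` so callers can decide how to exclude them.
    """

    participant_id: str
    exercise_id: str
    trial_number: int
    phi_rms: float
    ap_rms: float
    ml_rms: float
    phi_mv: float
    ap_mv: float
    ml_mv: float
    path_length: float
    elliptical_area: float
    log_phi_rms: float = math.nan
    log_ap_rms: float = math.nan
    log_ml_rms: float = math.nan
    log_phi_mv: float = math.nan
    log_ap_mv: float = math.nan
    log_ml_mv: float = math.nan
    log_path_length: float = math.nan
    log_elliptical_area: float = math.nan
    log_undefined: tuple = field(default=())

    def as_dict(self) -> dict:
        d = {"participant_id": self.participant_id,
             "exercise_id": self.exercise_id,
             "trial": self.trial_number}
        for name in FEATURE_NAMES:
            d[name] = getattr(self, name)
        for name in FEATURE_NAMES:
            d["log_" + name] = getattr(self, "log_" + name)
        return d


def _butter_sos(cutoff_hz: float, order: int, fs: float):
    if cutoff_hz >= fs / 2:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz is at or above the Nyquist frequency {fs / 2} Hz"
        )
    if order < 1:
        raise ConfigurationError("filter order must be >= 1")
    return signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")


def filter_sway(trial: SwayTrial, cutoff_hz: float = 3.0, order: int = 2) -> SwayTrial:
    """Zero-phase low-pass filter both axes of a trial.

    The stated design (Butterworth of the given order and cutoff) is applied
    forward and backward (``sosfiltfilt``), so the effective amplitude response
    is the single-pass magnitude squared: 0.5 at the cutoff for order 2.
    """
    sos = _butter_sos(cutoff_hz, order, trial.sample_rate_hz)
    # default sosfiltfilt padding; shorter series cannot be filtered stably
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trial.n_samples <= padlen:
        raise InsufficientDataError(
            f"series of {trial.n_samples} samples is shorter than the filter "
            f"warm-up ({padlen + 1} samples required)"
        )
    ap = signal.sosfiltfilt(sos, trial.ap_deg)
    ml = signal.sosfiltfilt(sos, trial.ml_deg)
    return replace(trial, ap_deg=ap, ml_deg=ml)


def elliptical_area(ml_series, ap_series, coverage: float = 0.95) -> float:
    """Area of the ellipse covering ``coverage`` of the planar (ML, AP) scatter.

    The ellipse is the level set of the Mahalanobis distance under the 2x2
    sample covariance of the demeaned points; its area is
    ``pi * q * sqrt(lambda1 * lambda2)`` with ``q`` the chi-square(2) quantile
    at ``coverage``. Rank-deficient scatter (e.g. collinear points) yields 0.
    """
    ml = np.asarray(ml_series, dtype=float)
    ap = np.asarray(ap_series, dtype=float)
    if ml.shape != ap.shape or ml.ndim != 1:
        raise ConfigurationError("ML and AP series must be 1-D and equally long")
    if len(ml) < 3:
        raise InsufficientDataError("elliptical area needs at least 3 points")
    if not 0.0 < coverage < 1.0:
        raise ConfigurationError("coverage must lie strictly between 0 and 1")
    pts = np.column_stack([ml - ml.mean(), ap - ap.mean()])
    cov = pts.T @ pts / (len(ml) - 1)
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    det = eigvals[0] * eigvals[1]
    if det <= 0.0:
        return 0.0
    q = chi2.ppf(coverage, df=2)
    return float(math.pi * q * math.sqrt(det))


def compute_features(trial: SwayTrial, coverage: float = 0.95) -> KinematicFeatures:
    """Compute all sway features for one (already filtered) trial.

    Axes are demeaned first. Velocities use first differences scaled by the
    sample rate; planar MV is the path length divided by the spanned time,
    making ``phi_mv * span == path_length`` exact.
    """
    fs = trial.sample_rate_hz
    ap = trial.ap_deg - trial.ap_deg.mean()
    ml = trial.ml_deg - trial.ml_deg.mean()

    ap_rms = float(np.sqrt(np.mean(ap**2)))
    ml_rms = float(np.sqrt(np.mean(ml**2)))
    phi_rms = float(math.hypot(ap_rms, ml_rms))

    d_ap = np.diff(ap)
    d_ml = np.diff(ml)
    ap_mv = float(np.mean(np.abs(d_ap)) * fs)
    ml_mv = float(np.mean(np.abs(d_ml)) * fs)
    steps = np.hypot(d_ap, d_ml)
    path_length = float(np.sum(steps))
    phi_mv = path_length / trial.span_s

    area = elliptical_area(ml, ap, coverage=coverage)

    values = {
        "phi_rms": phi_rms, "ap_rms": ap_rms, "ml_rms": ml_rms,
        "phi_mv": phi_mv, "ap_mv": ap_mv, "ml_mv": ml_mv,
        "path_length": path_length, "elliptical_area": area,
    }
    logs = {}
    undefined = []
    for name, v in values.items():
        if v > 0.0:
            logs["log_" + name] = math.log(v)
        else:
            logs["log_" + name] = math.nan
            undefined.append(name)
    return KinematicFeatures(
        participant_id=trial.participant_id,
        exercise_id=trial.exercise_id,
        trial_number=trial.trial_number,
        **values,
        **logs,
        log_undefined=tuple(undefined),
    )
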