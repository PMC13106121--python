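"""Raw sEMG -> normalized 100-point activation envelopes.

The stage order is fixed: band-pass (20-450 Hz, 4th-order Butterworth,
zero-lag) -> 50 Hz notch -> full-wave rectification -> linear envelope
(8 Hz low-pass, 4th-order Butterworth, zero-lag) -> time normalization to a
100-point movement-cycle grid -> peak amplitude normalization across the
repetitions of each subject x muscle. "Zero-lag" means forward-backward
application (scipy ``filtfilt``), which doubles the effective magnitude order
and cancels phase.

Peak normalization uses the task maximum (largest envelope value across the
subject's repetitions for that muscle) rather than a maximum voluntary
contraction, so all profiles are unitless in [0, 1] and the maximum over a
subject x muscle's repetitions is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import TrialRecording
from .errors import DegenerateInputError, LengthError, ParameterError, SchemaError

logger = logging.getLogger(__name__)

N_POINTS = 100  # points on the normalized movement-cycle grid


@dataclass(frozen=True)
class FilterSettings:
    """Filtering parameters of the envelope pipeline (all frequencies in Hz).

    Orders are design orders of the Butterworth prototypes; each filter is
    applied forward-backward, so the effective magnitude order is doubled.
    """

    bp_low: float = 20.0
    bp_high: float = 450.0
    bp_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    env_cutoff: float = 8.0
    env_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.bp_low < self.bp_high):
            raise ParameterError("need 0 < bp_low < bp_high")
        if not (0 < self.env_cutoff < self.bp_low):
            raise ParameterError("need 0 < env_cutoff < bp_low")
        if not (self.bp_low < self.notch_freq < self.bp_high):
            raise ParameterError("notch_freq must lie inside the pass band")
        if self.bp_order < 1 or self.env_order < 1 or self.notch_q <= 0:
            raise ParameterError("filter orders and notch Q must be positive")


def _check_signal(x: np.ndarray, fs: float, settings: FilterSettings) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise LengthError("expected a 1-D signal")
    if fs <= 2.0 * settings.bp_high:
        raise ParameterError(f"fs={fs} too low for bp_high={settings.bp_high}")
    # filtfilt needs more than 3x the padding length; be conservative
    if x.size <= 9 * (settings.bp_order + 1):
        raise LengthError(f"signal of {x.size} samples is too short to filter")
    return x


def bandpass(x, fs: float, settings: FilterSettings = FilterSettings()) -> np.ndarray:
    """Zero-lag Butterworth band-pass; removes motion artefact and high-frequency noise."""
    x = _check_signal(x, fs, settings)
    sos = sps.butter(
        settings.bp_order, [settings.bp_low, settings.bp_high], btype="bandpass", fs=fs, output="sos"
    )
    return sps.sosfiltfilt(sos, x)


def notch(x, fs: float, settings: FilterSettings = FilterSettings()) -> np.ndarray:
    """Zero-lag IIR notch at the power-line frequency (default 50 Hz, Q=30)."""
    x = _check_signal(x, fs, settings)
    b, a = sps.iirnotch(settings.notch_freq, settings.notch_q, fs=fs)
    return sps.filtfilt(b, a, x)


def rectify(x) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value); idempotent."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ParameterError("cannot rectify non-finite samples")
    return np.abs(x)


def envelope(x, fs: float, settings: FilterSettings = FilterSettings()) -> np.ndarray:
    """Linear envelope: zero-lag low-pass of a rectified signal, clipped at zero.

    Low-pass overshoot can produce small negative excursions; they are clipped
    because the envelope represents an activation magnitude.
    """
    x = _check_signal(x, fs, settings)
    sos = sps.butter(settings.env_order, settings.env_cutoff, btype="lowpass", fs=fs, output="sos")
    return np.clip(sps.sosfiltfilt(sos, x), 0.0, None)


def time_normalize(y, n_points: int = N_POINTS) -> np.ndarray:
    """Resample onto ``n_points`` spanning the record, endpoints included.

    Point j sits at fraction j/(n_points-1) of the record; values are linearly
    interpolated, so the first and last samples are preserved exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise LengthError("time_normalize needs a 1-D signal of length >= 2")
    grid = np.linspace(0.0, y.size - 1.0, n_points)
    return np.interp(grid, np.arange(y.size), y)


def peak_normalize(envelopes: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    """Scale all repetitions of one subject x muscle by their common maximum.

    Returns (scaled envelopes, peak_value, 1-based index of the repetition
    holding the peak). Raises ``DegenerateInputError`` if every envelope is zero.
    """
    envs = [np.asarray(e, dtype=float) for e in envelopes]
    if not envs:
        raise DegenerateInputError("no repetitions to normalize")
    maxima = np.array([e.max() if e.size else 0.0 for e in envs])
    peak = float(maxima.max())
    if peak <= 0.0:
        raise DegenerateInputError("all-zero envelopes cannot be peak-normalized")
    rep_of_peak = int(np.argmax(maxima)) + 1
    return [e / peak for e in envs], peak, rep_of_peak


def preprocess_trial(
    trial: TrialRecording, settings: FilterSettings = FilterSettings()
) -> dict[str, np.ndarray]:
    """Band-pass -> notch -> rectify -> envelope for every channel of one trial."""
    out = {}
    for ch in trial.channels:
        x = trial.channel(ch)
        out[ch] = envelope(rectify(notch(bandpass(x, trial.fs, settings), trial.fs, settings)), trial.fs, settings)
    return out


def preprocess_cohort(
    trials: Iterable[TrialRecording],
    settings: FilterSettings = FilterSettings(),
    n_points: int = N_POINTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline over a cohort of trials.

    Returns ``(profiles, normalization)``:

    * ``profiles`` — long table (subject_id, muscle, rep_index, point_index,
      value): one ``n_points``-point normalized profile per
      subject x muscle x repetition, peak-normalized within subject x muscle.
    * ``normalization`` — audit table (subject_id, muscle, peak_value,
      rep_of_peak) of the scaling divisors.

    Any repetition whose raw peak exceeds 5x the median peak of its
    subject x muscle group is logged (never removed).
    """
    trials = list(trials)
    if not trials:
        raise SchemaError("no trials supplied")
    channels = trials[0].channels
    by_subject: dict[str, list[TrialRecording]] = {}
    for tr in trials:
        if tr.channels != channels:
            raise SchemaError(
                f"subject {tr.subject_id} rep {tr.rep_index}: channels {tr.channels} "
                f"do not match expected {channels}"
            )
        by_subject.setdefault(tr.subject_id, []).append(tr)

    prof_rows: list[pd.DataFrame] = []
    norm_rows = []
    for subject_id, subj_trials in by_subject.items():
        subj_trials = sorted(subj_trials, key=lambda tr: tr.rep_index)
        envelopes = {tr.rep_index: preprocess_trial(tr, settings) for tr in subj_trials}
        for muscle in channels:
            reps = sorted(envelopes)
            curves = [time_normalize(envelopes[r][muscle], n_points) for r in reps]
            raw_peaks = np.array([c.max() for c in curves])
            med = np.median(raw_peaks)
            if med > 0 and (raw_peaks > 5.0 * med).any():
                for r, p in zip(reps, raw_peaks):
                    if p > 5.0 * med:
                        logger.warning(
                            "subject %s muscle %s rep %d: peak %.3g exceeds 5x group median %.3g",
                            subject_id, muscle, r, p, med,
                        )
            scaled, peak, rep_of_peak = peak_normalize(curves)
            norm_rows.append(
                {
                    "subject_id": subject_id,
                    "muscle": muscle,
                    "peak_value": peak,
                    "rep_of_peak": reps[rep_of_peak - 1],
                }
            )
            for r, vals in zip(reps, scaled):
                prof_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": subject_id,
                            "muscle": muscle,
                            "rep_index": r,
                            "point_index": np.arange(n_points),
                            "value": vals,
                        }
                    )
                )
    profiles = pd.concat(prof_rows, ignore_index=True)
    normalization = pd.DataFrame(norm_rows)
    return profiles, normalization


class EnvelopeExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping raw trials to the normalized-profile table.

    ``transform`` takes a sequence of :class:`~emgrepro.cohort.TrialRecording`
    and returns the long-format profile table of :func:`preprocess_cohort`;
    the normalization audit table is stored as ``normalization_``.
    """

    def __init__(
        self,
        bp_low: float = 20.0,
        bp_high: float = 450.0,
        bp_order: int = 4,
        notch_freq: float = 50.0,
        notch_q: float = 30.0,
        env_cutoff: float = 8.0,
        env_order: int = 4,
        n_points: int = N_POINTS,
    ):
        self.bp_low = bp_low
        self.bp_high = bp_high
        self.bp_order = bp_order
        self.notch_freq = notch_freq
        self.notch_q = notch_q
        self.env_cutoff = env_cutoff
        self.env_order = env_order
        self.n_points = n_points

    def _settings(self) -> FilterSettings:
        return FilterSettings(
            bp_low=self.bp_low,
            bp_high=self.bp_high,
            bp_order=self.bp_order,
            notch_freq=self.notch_freq,
            notch_q=self.notch_q,
            env_cutoff=self.env_cutoff,
            env_order=self.env_order,
        )

    def fit(self, X: Sequence[TrialRecording], y=None) -> "EnvelopeExtractor":
        self.settings_ = self._settings()  # validates parameters
        return self

    def transform(self, X: Sequence[TrialRecording]) -> pd.DataFrame:
        if not hasattr(self, "settings_"):
            self.fit(X)
        profiles, normalization = preprocess_cohort(X, self.settings_, self.n_points)
        self.normalization_ = normalization
        return profiles
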