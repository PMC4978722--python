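"""LFP characteristics: AEP amplitude, band-limited power, and phase-locking value.

Three features are extracted from multichannel LFP, after rejecting
burst-suppression episodes:

* **AEP P1 amplitude** -- the absolute value of the minimum single-trial LFP
  deflection within 50 ms after a tone-burst onset, with the matching
  pre-onset minimum as the spontaneous reference.
* **Band power** -- the RMS of the band-pass-filtered LFP within an analysis
  window, per site, for the five canonical bands (theta 4-8, alpha 8-14,
  beta 14-30, low-gamma 30-40, high-gamma 60-80 Hz).
* **PLV** -- the phase-locking value between two sites,
  ``PLV(j,k) = |mean_t exp(i (theta_j(t) - theta_k(t)))|``, where the
  instantaneous phase comes from the Hilbert transform of the band-passed
  signal. PLV is 1 for a constant phase difference and near 0 for
  independent phases.

Burst episodes are detected from the trailing 100-ms windowed SD of every
channel: a sample belongs to a burst when more than ``min_sites`` channels
exceed a per-recording threshold (mean + 3 SD of windowed SDs over a
calibration segment) and the supra-threshold run lasts at least 150 ms.
Analysis windows are taken 1-29 s after tone onset (sound-induced) or tone
offset (spontaneous), as non-overlapping 1000-ms periods; a period is
discarded whenever any of its samples is burst-marked.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .synthetic_data import ConfigurationError, LfpRecording

#: Canonical frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "low_gamma": (30.0, 40.0),
    "high_gamma": (60.0, 80.0),
}

WINDOW_LENGTHS_MS = (200, 400, 600, 800, 1000)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float


def get_band(band: str | tuple[float, float] | BandDefinition) -> BandDefinition:
    """Resolve a band name, an (lo, hi) tuple, or a BandDefinition."""
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        try:
            lo, hi = BANDS[band]
        except KeyError as exc:
            raise ConfigurationError(f"unknown band {band!r}") from exc
        return BandDefinition(band, lo, hi)
    lo, hi = band
    return BandDefinition(f"{lo:g}-{hi:g}Hz", float(lo), float(hi))


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

@dataclass
class BurstMask:
    """Boolean per-sample burst mask and the threshold that produced it."""

    mask: np.ndarray
    threshold_uv: float
    fs_hz: float
    win_ms: float = 100.0
    min_sites: int = 24
    min_burst_ms: float = 150.0

    def intervals(self) -> list[tuple[float, float]]:
        """Maximal burst runs as (start_s, end_s) half-open intervals."""
        padded = np.concatenate(([False], self.mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        return [
            (edges[i] / self.fs_hz, edges[i + 1] / self.fs_hz)
            for i in range(0, len(edges), 2)
        ]


def windowed_sd(data: np.ndarray, fs_hz: float, win_ms: float = 100.0) -> np.ndarray:
    """Trailing windowed SD at every sample (step one sample).

    At sample ``t`` the SD is taken over the trailing ``win_ms`` of signal,
    i.e. samples ``(t - w, t]``; during the first ``w`` samples the window is
    the available prefix. Accepts 1-D or channels x samples input.
    """
    x = np.atleast_2d(np.asarray(data))
    w = int(round(win_ms * fs_hz / 1000.0))
    if w < 2:
        raise ConfigurationError("SD window must span at least 2 samples")
    if w > x.shape[1]:
        raise ConfigurationError("SD window longer than the recording")
    out = np.empty(x.shape, dtype=np.float32)
    idx = np.arange(x.shape[1])
    lo = np.maximum(idx - w + 1, 0)
    count = (idx - lo + 1).astype(np.float64)
    for ch in range(x.shape[0]):
        xi = x[ch].astype(np.float64)
        c1 = np.concatenate(([0.0], np.cumsum(xi)))
        c2 = np.concatenate(([0.0], np.cumsum(xi * xi)))
        s1 = c1[idx + 1] - c1[lo]
        s2 = c2[idx + 1] - c2[lo]
        var = np.maximum(s2 / count - (s1 / count) ** 2, 0.0)
        out[ch] = np.sqrt(var)
    return out if np.asarray(data).ndim == 2 else out[0]


def estimate_burst_threshold(
    recording: LfpRecording | np.ndarray,
    fs_hz: float | None = None,
    calibration_s: float = 60.0,
    win_ms: float = 100.0,
) -> float:
    """Per-recording burst threshold: mean + 3 SD of pooled windowed SDs.

    The statistic is computed once per recording over a calibration segment
    (default: the first 60 s, or the whole recording when shorter), pooling
    the trailing windowed SDs of all channels.
    """
    if isinstance(recording, LfpRecording):
        data, fs = recording.data, recording.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing a raw array")
        data, fs = np.atleast_2d(recording), fs_hz
    n_cal = min(int(round(calibration_s * fs)), data.shape[1])
    if n_cal < int(10 * fs):
        raise ConfigurationError("calibration segment must be at least 10 s")
    w = int(round(win_ms * fs / 1000.0))
    sds = windowed_sd(data[:, :n_cal], fs, win_ms)[:, w - 1:]
    return float(sds.mean() + 3.0 * sds.std())


def detect_bursts(
    recording: LfpRecording | np.ndarray,
    threshold_uv: float,
    fs_hz: float | None = None,
    min_sites: int = 24,
    min_burst_ms: float = 150.0,
    win_ms: float = 100.0,
) -> BurstMask:
    """Mark burst samples: windowed SD above threshold on more than ``min_sites`` channels.

    The supra-threshold run is eroded by the SD window (undoing the forward
    smear of the trailing window) so the mask approximates the physical burst
    support, and runs shorter than ``min_burst_ms`` are then discarded: every
    maximal run in the returned mask lasts at least that long, and bursts
    physically shorter than ``min_burst_ms`` are rejected.
    """
    if threshold_uv < 0:
        raise ConfigurationError("threshold must be non-negative")
    if isinstance(recording, LfpRecording):
        data, fs = recording.data, recording.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing a raw array")
        data, fs = np.atleast_2d(recording), fs_hz
    sds = windowed_sd(data, fs, win_ms)
    counts = (sds > threshold_uv).sum(axis=0)
    elevated = counts > min_sites
    # the trailing SD window smears a burst forward by up to win_ms; a sample
    # belongs to the burst support when every SD window that starts at it is
    # supra-threshold (forward erosion), so the duration rule applies to the
    # physical burst duration
    w = int(round(win_ms * fs / 1000.0))
    csum = np.concatenate(([0], np.cumsum(elevated.astype(np.int64))))
    n = len(elevated)
    support = np.zeros(n, dtype=bool)
    valid = n - w + 1
    if valid > 0:
        support[:valid] = (csum[w:] - csum[:-w]) == w
    min_run = int(round(min_burst_ms * fs / 1000.0))
    mask = np.zeros_like(support)
    padded = np.concatenate(([False], support, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i in range(0, len(edges), 2):
        if edges[i + 1] - edges[i] >= min_run:
            mask[edges[i]:edges[i + 1]] = True
    return BurstMask(
        mask=mask, threshold_uv=float(threshold_uv), fs_hz=fs,
        win_ms=win_ms, min_sites=min_sites, min_burst_ms=min_burst_ms,
    )


# ---------------------------------------------------------------------------
# analysis windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisWindow:
    """One analysis window inside the sustained part of a trial.

    ``condition`` is ``"sound"`` (aligned to tone onset) or ``"spontaneous"``
    (aligned to tone offset); ``frequency_hz`` is the trial's tone frequency
    either way, so sound and spontaneous windows can be paired per frequency.
    """

    trial_id: int
    frequency_hz: float
    condition: str
    start_s: float
    length_ms: int


def extract_windows(
    recording: LfpRecording,
    burst_mask: BurstMask | None = None,
    length_ms: int = 1000,
    period_s: float = 1.0,
    span_s: tuple[float, float] = (1.0, 29.0),
    samples_per_label: int | None = None,
    seed: int = 0,
) -> list[AnalysisWindow]:
    """Non-overlapping candidate periods 1-29 s from tone onset and offset.

    For every long-tone trial, 28 consecutive 1000-ms periods follow the
    onset (sound) and 28 follow the offset (spontaneous); the analysis window
    of ``length_ms`` starts at each period's beginning. A period is discarded
    if any of its samples overlaps the burst mask. With ``samples_per_label``
    the surviving windows are subsampled (seeded, without replacement) to a
    fixed count per (frequency, condition) label.
    """
    if length_ms not in WINDOW_LENGTHS_MS:
        raise ConfigurationError(f"length_ms must be one of {WINDOW_LENGTHS_MS}")
    if recording.schedule.protocol != "long_tone":
        raise ConfigurationError("analysis windows are defined for long_tone recordings")
    lo, hi = span_s
    fs = recording.fs_hz
    mask = burst_mask.mask if burst_mask is not None else None
    n_periods = int(round((hi - lo) / period_s))
    windows: list[AnalysisWindow] = []
    for trial_id, ev in recording.schedule.events.iterrows():
        if lo < 0 or ev["onset_s"] + ev["duration_s"] + hi > recording.duration_s + 1e-9:
            raise ConfigurationError("analysis span falls outside the recording")
        for align, condition in ((ev["onset_s"], "sound"), (ev["onset_s"] + ev["duration_s"], "spontaneous")):
            for k in range(n_periods):
                start = align + lo + k * period_s
                i0 = int(round(start * fs))
                i1 = int(round((start + period_s) * fs))
                if mask is not None and mask[i0:i1].any():
                    continue
                windows.append(
                    AnalysisWindow(
                        trial_id=int(trial_id),
                        frequency_hz=float(ev["frequency_hz"]),
                        condition=condition,
                        start_s=float(start),
                        length_ms=int(length_ms),
                    )
                )
    if samples_per_label is not None:
        rng = np.random.default_rng(seed)
        by_label: dict[tuple[float, str], list[int]] = {}
        for i, w in enumerate(windows):
            by_label.setdefault((w.frequency_hz, w.condition), []).append(i)
        keep: list[int] = []
        for label in sorted(by_label):
            idx = by_label[label]
            if len(idx) > samples_per_label:
                chosen = rng.choice(len(idx), size=samples_per_label, replace=False)
                idx = [idx[j] for j in np.sort(chosen)]
            keep.extend(idx)
        windows = [windows[i] for i in sorted(keep)]
    return windows


# ---------------------------------------------------------------------------
# filtering, power, phase locking
# ---------------------------------------------------------------------------

_FILTER_ORDER = 4


def _design_sos(band: BandDefinition, fs_hz: float) -> np.ndarray:
    if not (0.0 < band.lo_hz < band.hi_hz < fs_hz / 2.0):
        raise ConfigurationError(f"band ({band.lo_hz}, {band.hi_hz}) outside (0, fs/2)")
    return sps.butter(_FILTER_ORDER, (band.lo_hz, band.hi_hz), btype="bandpass", fs=fs_hz, output="sos")


def bandpass(
    segment: np.ndarray,
    band: str | tuple[float, float] | BandDefinition,
    fs_hz: float,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    Applied forward-backward (``sosfiltfilt``) with reflective edge padding,
    so the output has no phase distortion and the same length as the input.
    """
    bdef = get_band(band)
    sos = _design_sos(bdef, fs_hz)
    x = np.asarray(segment, dtype=np.float64)
    min_len = 3 * (2 * _FILTER_ORDER + 1)
    if x.shape[-1] < min_len:
        raise ConfigurationError(f"segment must be at least {min_len} samples for filtering")
    return sps.sosfiltfilt(sos, x, axis=-1)


def band_power(
    window_lfp: np.ndarray,
    band: str | tuple[float, float] | BandDefinition,
    fs_hz: float,
) -> np.ndarray | float:
    """RMS of the band-passed signal over the window (per channel if 2-D)."""
    y = bandpass(window_lfp, band, fs_hz)
    rms = np.sqrt(np.mean(np.square(y), axis=-1))
    return float(rms) if np.ndim(window_lfp) == 1 else rms


def plv(
    window_j: np.ndarray,
    window_k: np.ndarray,
    band: str | tuple[float, float] | BandDefinition | None = None,
    fs_hz: float = 1000.0,
) -> float:
    """Phase-locking value between two equal-length windows.

    Both signals are band-passed (unless ``band`` is None, for signals that
    are already narrow-band), their instantaneous phases are taken from the
    analytic signal, and the magnitude of the time-averaged unit phasor of
    the phase difference is returned. Always in [0, 1]; symmetric in (j, k).
    """
    x = np.asarray(window_j, dtype=np.float64)
    y = np.asarray(window_k, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("windows must be equal-length 1-D arrays")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance segment has undefined phase")
    if band is not None:
        x = bandpass(x, band, fs_hz)
        y = bandpass(y, band, fs_hz)
    tj = np.angle(sps.hilbert(x))
    tk = np.angle(sps.hilbert(y))
    return float(np.abs(np.mean(np.exp(1j * (tj - tk)))))


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """samples x features values with per-sample labels and per-feature descriptors.

    Descriptors are site ids for AEP/band-power features and ordered
    ``(site_j, site_k)`` pairs (j < k) for PLV features.
    """

    values: np.ndarray
    labels: np.ndarray
    descriptors: list
    kind: str
    band: str | None = None
    window_ms: int | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _padded_segment(
    data: np.ndarray, fs_hz: float, start_s: float, length_ms: int, pad_ms: float
) -> tuple[np.ndarray, slice]:
    i0 = int(round(start_s * fs_hz))
    i1 = i0 + int(round(length_ms * fs_hz / 1000.0))
    pad = int(round(pad_ms * fs_hz / 1000.0))
    j0 = max(i0 - pad, 0)
    j1 = min(i1 + pad, data.shape[1])
    return data[:, j0:j1], slice(i0 - j0, i1 - j0)


def build_feature_matrix(
    recording: LfpRecording,
    windows: Sequence[AnalysisWindow],
    band: str | tuple[float, float] | BandDefinition,
    kind: str,
    label_by: str = "condition",
    pad_ms: float = 200.0,
) -> FeatureMatrix:
    """Band-power or PLV feature matrix over the given analysis windows.

    One row per window; 1 column per site for ``band_power`` and one per
    unordered site pair (``S(S-1)/2``; 4560 for 96 sites) for ``plv``.
    Filtering and the Hilbert transform are applied to the window padded by
    ``pad_ms`` of contiguous data on each side, then cropped, to avoid
    end-point artifacts. ``label_by`` picks the per-row label: the window
    condition ("sound"/"spontaneous") or its tone frequency.
    """
    if kind not in ("band_power", "plv"):
        raise ConfigurationError("kind must be 'band_power' or 'plv'")
    if label_by not in ("condition", "frequency"):
        raise ConfigurationError("label_by must be 'condition' or 'frequency'")
    bdef = get_band(band)
    site_ids = recording.site_map.site_ids
    n_sites = len(site_ids)
    if kind == "band_power":
        descriptors: list = [int(s) for s in site_ids]
    else:
        iu = np.triu_indices(n_sites, k=1)
        descriptors = [(int(site_ids[j]), int(site_ids[k])) for j, k in zip(*iu)]
    rows = np.empty((len(windows), len(descriptors)), dtype=np.float64)
    for r, w in enumerate(windows):
        seg, crop = _padded_segment(recording.data, recording.fs_hz, w.start_s, w.length_ms, pad_ms)
        filt = bandpass(seg, bdef, recording.fs_hz)
        if kind == "band_power":
            rows[r] = np.sqrt(np.mean(np.square(filt[:, crop]), axis=1))
        else:
            analytic = sps.hilbert(filt, axis=1)[:, crop]
            mag = np.abs(analytic)
            mag[mag == 0] = 1.0
            z = analytic / mag
            t = z.shape[1]
            coh = np.abs(z @ z.conj().T) / t
            rows[r] = coh[iu]
    if label_by == "condition":
        labels = np.array([w.condition for w in windows])
    else:
        labels = np.array([f"{w.frequency_hz:g}" for w in windows])
    return FeatureMatrix(
        values=rows, labels=labels, descriptors=descriptors, kind=kind,
        band=bdef.name, window_ms=windows[0].length_ms if windows else None,
    )


# ---------------------------------------------------------------------------
# auditory evoked potentials
# ---------------------------------------------------------------------------

def aep_amplitude(
    lfp_trial: np.ndarray, event_onset_s: float, fs_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """P1 and spontaneous amplitudes around one tone-burst onset, per channel.

    P1 is the absolute value of the minimum over the 50 ms following the
    onset (half-open ``(onset, onset + 50 ms]``); the spontaneous reference
    is the matching minimum over the 50 ms preceding the onset.
    """
    data = np.atleast_2d(np.asarray(lfp_trial))
    o = int(round(event_onset_s * fs_hz))
    w = int(round(0.05 * fs_hz))
    if o - w + 1 < 0 or o + w + 1 > data.shape[1]:
        raise ValueError("need at least 50 ms of signal on both sides of the onset")
    p1 = np.abs(data[:, o + 1: o + w + 1].min(axis=1))
    spont = np.abs(data[:, o - w + 1: o + 1].min(axis=1))
    return p1, spont


def build_aep_feature_matrix(
    recording: LfpRecording,
    frequency_hz: float | None = None,
    levels_db: Sequence[float] | None = None,
) -> FeatureMatrix:
    """AEP-vs-spontaneous samples from a tone-burst recording.

    For every matching event, the per-site P1 vector becomes a "sound" row
    and the pre-onset minima a "spontaneous" row (96 features each with the
    default grid).
    """
    if recording.schedule.protocol != "tone_burst":
        raise ConfigurationError("AEP features require a tone_burst recording")
    ev = recording.schedule.events
    sel = np.ones(len(ev), dtype=bool)
    if frequency_hz is not None:
        sel &= np.isclose(ev["frequency_hz"].to_numpy(), frequency_hz)
    if levels_db is not None:
        sel &= np.isin(ev["level_db"].to_numpy(), np.asarray(levels_db))
    onsets = ev.loc[sel, "onset_s"].to_numpy()
    values, labels = [], []
    for onset in onsets:
        p1, spont = aep_amplitude(recording.data, onset, recording.fs_hz)
        values.append(p1)
        labels.append("sound")
        values.append(spont)
        labels.append("spontaneous")
    return FeatureMatrix(
        values=np.asarray(values, dtype=np.float64),
        labels=np.asarray(labels),
        descriptors=[int(s) for s in recording.site_map.site_ids],
        kind="aep",
    )
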