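"""Synthetic tonotopic cortex: site maps, stimulus schedules, LFP and spike simulation.

This module builds a ground-truth-known stand-in for a dense microelectrode
recording of rat auditory cortex under anesthesia: a 10x10 grid of recording
sites (400-um pitch, four inactive corners, 96 active sites) covering core
(A1/AAF), belt, and non-auditory territory, with a log-linear tonotopic
characteristic-frequency (CF) gradient along each field's axis and
region-dependent spike latencies (core faster than belt).

Two stimulus protocols are generated:

* ``tone_burst`` -- short (25-ms) tone pips over a frequency x level grid,
  used to characterize frequency response areas and onset latencies and to
  evoke auditory evoked potentials (AEPs).
* ``long_tone`` -- 30-s pure tones interleaved with 30-s silent blocks, used
  to study sustained band-limited power and pairwise phase locking.

The LFP simulator plants the effects the downstream analysis is meant to
recover: 1/f-like background noise, negative AEP deflections at CF-matched
sites after tone-burst onsets, a sustained narrow-band (default 60-80 Hz)
oscillation with controlled inter-site phase locking at CF-matched sites
during long tones, and global multiplicative burst-suppression episodes.
All randomness flows through a single seeded generator, so identical seeds
and configurations give bit-identical output.

Units are microvolts, seconds and Hz throughout; grid indices are 0-based
and time intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

REGIONS = ("core", "belt", "non_auditory")

#: CF range represented on the simulated cortical surface (Hz).
CF_RANGE_HZ = (1600.0, 64000.0)

#: The standard 18-frequency / 7-level tone-burst characterization grid.
TONE_BURST_FREQUENCIES_HZ = (
    1600.0, 2000.0, 2500.0, 3200.0, 4000.0, 5000.0, 6400.0, 8000.0, 10000.0,
    13000.0, 16000.0, 20000.0, 25000.0, 32000.0, 40000.0, 50000.0, 57000.0,
    64000.0,
)
TONE_BURST_LEVELS_DB = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: Tone-burst frequencies used for the AEP discrimination task (Hz) and levels (dB SPL).
AEP_FREQUENCIES_HZ = (13000.0, 20000.0, 32000.0, 50000.0)
AEP_LEVELS_DB = (50.0, 60.0, 70.0)

DEFAULT_FS_HZ = 1000.0


class ConfigurationError(ValueError):
    """Invalid layout or simulation configuration."""


# ---------------------------------------------------------------------------
# site map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorticalField:
    """Rectangular patch of grid cells with one region label and tonotopic axis.

    ``rows``/``cols`` are inclusive 0-based bounds; ``axis`` is a (d_row, d_col)
    direction along which CF increases log-linearly (None for non-auditory).
    """

    name: str
    region: str
    rows: tuple[int, int]
    cols: tuple[int, int]
    axis: tuple[float, float] | None = None

    def cells(self) -> list[tuple[int, int]]:
        return [
            (r, c)
            for r in range(self.rows[0], self.rows[1] + 1)
            for c in range(self.cols[0], self.cols[1] + 1)
        ]


def default_field_layout() -> list[CorticalField]:
    """Default partition of the 10x10 grid into core, belt and non-auditory fields.

    Active-site totals are 44 core / 37 belt / 15 non-auditory. The core is
    split into A1 (posterior-to-anterior CF gradient) and AAF (reversed
    gradient); the belt into four surrounding subfields with their own axes.
    """
    return [
        CorticalField("NA-dorsal", "non_auditory", (0, 0), (0, 9)),
        CorticalField("NA-medial", "non_auditory", (1, 1), (0, 6)),
        CorticalField("A1", "core", (2, 5), (0, 5), axis=(0.0, 1.0)),
        CorticalField("AAF", "core", (2, 6), (6, 9), axis=(0.0, -1.0)),
        CorticalField("PAF", "belt", (1, 1), (7, 9), axis=(0.0, -1.0)),
        CorticalField("VAF", "belt", (6, 6), (0, 5), axis=(0.0, 1.0)),
        CorticalField("SRAF", "belt", (7, 8), (0, 9), axis=(0.0, 1.0)),
        CorticalField("AVAF", "belt", (9, 9), (1, 8), axis=(0.0, 1.0)),
    ]


@dataclass
class SiteMap:
    """Per-site geometry and ground truth for the simulated cortex.

    ``table`` columns: site_id, row, col, x_um, y_um, region, subfield,
    cf_hz (NaN for non-auditory sites), latency_ms (NaN for non-auditory).
    """

    table: pd.DataFrame
    grid_shape: tuple[int, int] = (10, 10)
    pitch_um: float = 400.0

    @property
    def n_sites(self) -> int:
        return len(self.table)

    @property
    def site_ids(self) -> np.ndarray:
        return self.table["site_id"].to_numpy()

    @property
    def cf_hz(self) -> np.ndarray:
        return self.table["cf_hz"].to_numpy(dtype=float)

    @property
    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    def sites_in(self, region: str) -> np.ndarray:
        return self.table.loc[self.table["region"] == region, "site_id"].to_numpy()

    def region_totals(self) -> dict[str, int]:
        counts = self.table["region"].value_counts()
        return {r: int(counts.get(r, 0)) for r in REGIONS}


def _corner_cells(rows: int, cols: int) -> set[tuple[int, int]]:
    return {(0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1)}


def generate_site_map(
    grid_rows: int = 10,
    grid_cols: int = 10,
    field_layout: Sequence[CorticalField] | None = None,
    seed: int = 0,
    *,
    cf_range_hz: tuple[float, float] = CF_RANGE_HZ,
    cf_jitter_octaves: float = 0.1,
    latency_mean_ms: dict[str, float] | None = None,
    latency_sd_ms: dict[str, float] | None = None,
    pitch_um: float = 400.0,
) -> SiteMap:
    """Build the simulated cortical surface.

    CF varies log-linearly along each field's tonotopic axis over
    ``cf_range_hz``, with a small per-site jitter clipped to less than half
    the inter-step octave spacing so the gradient stays monotone along the
    axis. Latencies are drawn per region (core shorter than belt);
    non-auditory sites carry neither CF nor latency. The four grid corners
    are inactive.
    """
    if grid_rows <= 0 or grid_cols <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    layout = list(field_layout) if field_layout is not None else default_field_layout()
    latency_mean_ms = latency_mean_ms or {"core": 12.0, "belt": 22.0, "non_auditory": math.nan}
    latency_sd_ms = latency_sd_ms or {"core": 2.0, "belt": 3.0, "non_auditory": 0.0}

    corners = _corner_cells(grid_rows, grid_cols)
    active = [
        (r, c) for r in range(grid_rows) for c in range(grid_cols)
        if (r, c) not in corners
    ]

    # validate the layout: each active cell in exactly one field, core non-empty
    owner: dict[tuple[int, int], CorticalField] = {}
    for fld in layout:
        if fld.region not in REGIONS:
            raise ConfigurationError(f"unknown region {fld.region!r} in field {fld.name!r}")
        for cell in fld.cells():
            if cell in corners:
                continue
            if cell in owner:
                raise ConfigurationError(
                    f"fields {owner[cell].name!r} and {fld.name!r} overlap at {cell}"
                )
            owner[cell] = fld
    missing = [cell for cell in active if cell not in owner]
    if missing:
        raise ConfigurationError(f"layout leaves active cells unassigned: {missing[:4]}...")
    if not any(f.region == "core" for f in layout):
        raise ConfigurationError("layout has an empty core region")

    rng = np.random.default_rng(seed)
    lo_oct, hi_oct = math.log2(cf_range_hz[0]), math.log2(cf_range_hz[1])
    octave_range = hi_oct - lo_oct

    # per-field axis coordinates -> normalized position t in [0, 1]
    axis_info: dict[str, tuple[dict[tuple[int, int], float], float]] = {}
    for fld in layout:
        if fld.axis is None:
            continue
        cells = [c for c in fld.cells() if c not in corners]
        coords = {cell: fld.axis[0] * cell[0] + fld.axis[1] * cell[1] for cell in cells}
        values = sorted(set(coords.values()))
        span = values[-1] - values[0]
        n_steps = max(len(values) - 1, 1)
        step_oct = octave_range / n_steps
        tmap = {
            cell: 0.5 if span == 0 else (coords[cell] - values[0]) / span
            for cell in cells
        }
        axis_info[fld.name] = (tmap, step_oct)

    records = []
    for site_id, (r, c) in enumerate(active):
        fld = owner[(r, c)]
        if fld.region == "non_auditory":
            cf = math.nan
            lat = math.nan
        else:
            if fld.axis is not None:
                tmap, step_oct = axis_info[fld.name]
                log2cf = lo_oct + tmap[(r, c)] * octave_range
            else:
                step_oct = octave_range
                log2cf = 0.5 * (lo_oct + hi_oct)
            jit = rng.normal(0.0, cf_jitter_octaves)
            jit = float(np.clip(jit, -0.45 * step_oct, 0.45 * step_oct))
            log2cf = float(np.clip(log2cf + jit, lo_oct, hi_oct))
            cf = 2.0 ** log2cf
            lat = float(rng.normal(latency_mean_ms[fld.region], latency_sd_ms[fld.region]))
            lat = max(lat, 1.0)
        records.append(
            dict(
                site_id=site_id, row=r, col=c,
                x_um=c * pitch_um, y_um=r * pitch_um,
                region=fld.region, subfield=fld.name,
                cf_hz=cf, latency_ms=lat,
            )
        )
    table = pd.DataFrame.from_records(records)
    return SiteMap(table=table, grid_shape=(grid_rows, grid_cols), pitch_um=pitch_um)


# ---------------------------------------------------------------------------
# stimulus schedules
# ---------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    """Ordered stimulus events plus the protocol they belong to.

    ``events`` columns: onset_s, duration_s, frequency_hz, level_db.
    ``protocol`` is ``"tone_burst"`` or ``"long_tone"``.
    """

    events: pd.DataFrame
    protocol: str
    total_duration_s: float

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.unique(self.events["frequency_hz"].to_numpy())


def generate_tone_burst_protocol(
    frequencies_hz: Sequence[float] | None = None,
    levels_db: Sequence[float] | None = None,
    repeats: int = 20,
    iti_ms: float = 600.0,
    seed: int = 0,
    duration_ms: float = 25.0,
) -> StimulusSchedule:
    """Pseudorandom tone-burst schedule over a frequency x level grid.

    Defaults are the 18-frequency (1.6-64 kHz) x 7-level (20-80 dB SPL)
    characterization grid: 126 conditions, each repeated ``repeats`` times,
    at a fixed onset-to-onset interval ``iti_ms``. The first onset is one
    inter-tone interval in, so every trial has a pre-onset baseline.
    """
    freqs = list(frequencies_hz) if frequencies_hz is not None else list(TONE_BURST_FREQUENCIES_HZ)
    levels = list(levels_db) if levels_db is not None else list(TONE_BURST_LEVELS_DB)
    if not freqs or not levels:
        raise ConfigurationError("frequency and level lists must be non-empty")
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")

    conditions = [(f, l) for f in freqs for l in levels]
    pool = np.repeat(np.arange(len(conditions)), repeats)
    rng = np.random.default_rng(seed)
    order = rng.permutation(pool)
    iti_s = iti_ms / 1000.0
    onsets = (np.arange(len(order)) + 1) * iti_s
    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": duration_ms / 1000.0,
            "frequency_hz": [conditions[i][0] for i in order],
            "level_db": [conditions[i][1] for i in order],
        }
    )
    total = (len(order) + 1) * iti_s
    return StimulusSchedule(events=events, protocol="tone_burst", total_duration_s=total)


def generate_long_tone_protocol(
    frequencies_hz: Sequence[float],
    repeats: int = 8,
    level_db: float = 60.0,
    tone_s: float = 30.0,
    silence_s: float = 30.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Long pure tones interleaved with silent blocks, in pseudorandom order.

    Each event is a ``tone_s`` (default 30 s) tone followed by a
    ``silence_s`` silent block, so the recording is ``n_events * 60 s`` long
    with the defaults.
    """
    freqs = list(frequencies_hz)
    if not freqs:
        raise ConfigurationError("frequency list must be non-empty")
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(len(freqs)), repeats))
    block = tone_s + silence_s
    events = pd.DataFrame(
        {
            "onset_s": np.arange(len(order)) * block,
            "duration_s": tone_s,
            "frequency_hz": [freqs[i] for i in order],
            "level_db": level_db,
        }
    )
    return StimulusSchedule(
        events=events, protocol="long_tone", total_duration_s=len(order) * block
    )


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTuning:
    """Gaussian (in octaves) frequency tuning of the simulated multi-unit sites.

    ``gain_hz`` is the peak evoked-rate increment at CF and maximum level;
    the evoked response starts at each site's ground-truth latency and decays
    exponentially with ``decay_ms``. Non-auditory sites fire at baseline only.
    """

    baseline_hz: float = 4.0
    gain_hz: float = 60.0
    bandwidth_octaves: float = 0.5
    decay_ms: float = 8.0
    response_window_s: float = 0.05
    min_level_db: float = 20.0
    max_level_db: float = 80.0


@dataclass
class SpikeTrainSet:
    """Per-site spike times (seconds), aligned to the generating schedule."""

    trains: dict[int, np.ndarray]
    schedule: StimulusSchedule

    def __getitem__(self, site_id: int) -> np.ndarray:
        return self.trains[site_id]


def _tuning_weight(freq_hz: np.ndarray | float, cf_hz: float, sd_octaves: float) -> np.ndarray:
    if not np.isfinite(cf_hz):
        return np.zeros_like(np.asarray(freq_hz, dtype=float))
    d = np.log2(np.asarray(freq_hz, dtype=float) / cf_hz)
    return np.exp(-0.5 * (d / sd_octaves) ** 2)


def simulate_spike_trains(
    site_map: SiteMap,
    schedule: StimulusSchedule,
    tuning: SpikeTuning | None = None,
    seed: int = 0,
) -> SpikeTrainSet:
    """Inhomogeneous point-process spike trains for every site.

    Baseline Poisson firing everywhere; for each tone-burst event a site with
    CF cf receives an extra Poisson-count response with mean
    ``gain * G(log2(f/cf); bandwidth) * level_scale * response_window`` whose
    spike times start at the site's ground-truth latency and decay
    exponentially. Spike times are strictly increasing per site.
    """
    if schedule.protocol != "tone_burst":
        raise ConfigurationError("spike simulation expects a tone_burst schedule")
    tuning = tuning or SpikeTuning()
    rng = np.random.default_rng(seed)
    duration = schedule.total_duration_s
    onsets = schedule.events["onset_s"].to_numpy()
    freqs = schedule.events["frequency_hz"].to_numpy()
    levels = schedule.events["level_db"].to_numpy()
    level_scale = np.clip(
        (levels - tuning.min_level_db) / (tuning.max_level_db - tuning.min_level_db), 0.0, 1.0
    )

    trains: dict[int, np.ndarray] = {}
    for _, site in site_map.table.iterrows():
        n_base = rng.poisson(tuning.baseline_hz * duration)
        base_times = rng.uniform(0.0, duration, size=n_base)
        times = [base_times]
        if site["region"] != "non_auditory" and tuning.gain_hz > 0:
            w = _tuning_weight(freqs, site["cf_hz"], tuning.bandwidth_octaves)
            lam = tuning.gain_hz * w * level_scale * tuning.response_window_s
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total:
                ev_onsets = np.repeat(onsets, counts)
                jitter = rng.exponential(tuning.decay_ms / 1000.0, size=total)
                times.append(ev_onsets + site["latency_ms"] / 1000.0 + jitter)
        all_times = np.concatenate(times)
        all_times = np.unique(all_times[(all_times >= 0) & (all_times < duration)])
        trains[int(site["site_id"])] = all_times
    return SpikeTrainSet(trains=trains, schedule=schedule)


# ---------------------------------------------------------------------------
# LFP simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LfpEffects:
    """Planted effect sizes for the LFP simulator (microvolts / Hz / radians).

    ``sustained_amplitude_uv`` scales the CF-matched narrow-band oscillation
    added during long tones; ``plv_phase_jitter_sd_rad`` is the SD of each
    coupled site's slowly varying phase jitter around the shared source, so
    the expected PLV between two strongly coupled sites is approximately
    ``exp(-sd^2)``. ``amplitude_jitter_sd`` is the SD of the log response
    gain, drawn as a slowly varying process per site and event (and once per
    event for AEPs), emulating the large across-trial and within-trial
    variability of evoked cortical responses. Setting the
    amplitudes to zero yields a null recording.
    """

    background_sd_uv: float = 40.0
    ar_coef: float = 0.95
    aep_amplitude_uv: float = 150.0
    aep_peak_ms: float = 20.0
    aep_width_ms: float = 8.0
    sustained_amplitude_uv: float = 20.0
    effect_band_hz: tuple[float, float] = (60.0, 80.0)
    cf_match_sd_octaves: float = 0.5
    plv_phase_jitter_sd_rad: float = 0.4
    amplitude_jitter_sd: float = 0.3
    min_level_db: float = 20.0
    max_level_db: float = 80.0


@dataclass(frozen=True)
class BurstParams:
    """Global burst-suppression episodes: multiplicative amplitude envelopes.

    ``occupancy`` is the target fraction of time covered by bursts; each
    episode multiplies the signal by ``gain`` on a random subset of at least
    ``min_sites`` channels, with durations drawn uniformly from
    ``duration_range_s``.
    """

    occupancy: float = 0.0
    gain: float = 6.0
    min_sites: int = 80
    duration_range_s: tuple[float, float] = (0.15, 1.0)


@dataclass
class LfpRecording:
    """Multichannel LFP (channels x samples, microvolts) plus its provenance."""

    data: np.ndarray
    fs_hz: float
    site_map: SiteMap
    schedule: StimulusSchedule
    burst_log: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("LFP data must be channels x samples")
        if self.data.shape[0] != self.site_map.n_sites:
            raise ValueError(
                f"channel count {self.data.shape[0]} != active site count {self.site_map.n_sites}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _ar1_background(rng: np.random.Generator, n: int, sd_uv: float, a: float) -> np.ndarray:
    # drive scaled so the stationary SD of the AR(1) output equals sd_uv
    drive = rng.standard_normal(n) * sd_uv * math.sqrt(max(1.0 - a * a, 1e-12))
    return sps.lfilter([1.0], [1.0, -a], drive)


def _smooth_gain_log(rng: np.random.Generator, n: int, sd_log: float) -> np.ndarray:
    """Slow log-gain process (~0.5 s correlation time at 1 kHz) with given SD."""
    if sd_log <= 0:
        return np.zeros(n)
    x = sps.lfilter([1.0], [1.0, -0.998], rng.standard_normal(n))
    s = x.std()
    return x / s * sd_log if s > 0 else np.zeros(n)


def _smooth_phase_jitter(rng: np.random.Generator, n: int, sd_rad: float) -> np.ndarray:
    if sd_rad <= 0:
        return np.zeros(n)
    x = sps.lfilter([1.0], [1.0, -0.99], rng.standard_normal(n))
    s = x.std()
    return x / s * sd_rad if s > 0 else np.zeros(n)


def simulate_lfp_session(
    site_map: SiteMap,
    schedule: StimulusSchedule,
    effects: LfpEffects | None = None,
    bursts: BurstParams | None = None,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
) -> LfpRecording:
    """Simulate a full multichannel LFP session for the given schedule.

    ``tone_burst`` schedules receive a negative AEP deflection within 50 ms of
    each onset at CF-matched sites; ``long_tone`` schedules receive a sustained
    band-limited oscillation with shared-source phase coupling at CF-matched
    sites during each tone. Burst episodes multiply the signal on a large
    channel subset; their true intervals are kept in ``burst_log``.
    """
    effects = effects or LfpEffects()
    bursts = bursts or BurstParams()
    lo, hi = effects.effect_band_hz
    if not (0.0 < lo < hi < fs_hz / 2.0):
        raise ConfigurationError("effect band must lie inside (0, fs/2)")
    if schedule.protocol not in ("tone_burst", "long_tone"):
        raise ConfigurationError(f"unknown protocol {schedule.protocol!r}")

    rng = np.random.default_rng(seed)
    n_ch = site_map.n_sites
    n_samp = int(round(schedule.total_duration_s * fs_hz))
    data = np.empty((n_ch, n_samp), dtype=np.float32)
    for ch in range(n_ch):
        data[ch] = _ar1_background(rng, n_samp, effects.background_sd_uv, effects.ar_coef)

    cf = site_map.cf_hz
    onsets = schedule.events["onset_s"].to_numpy()
    freqs = schedule.events["frequency_hz"].to_numpy()
    levels = schedule.events["level_db"].to_numpy()
    durations = schedule.events["duration_s"].to_numpy()
    responsive: dict[float, list[int]] = {}

    if schedule.protocol == "tone_burst" and effects.aep_amplitude_uv > 0:
        k_len = int(round(0.05 * fs_hz)) + 1
        t_k = np.arange(k_len) / fs_hz
        kernel = -np.exp(-0.5 * ((t_k - effects.aep_peak_ms / 1000.0) / (effects.aep_width_ms / 1000.0)) ** 2)
        level_scale = np.clip(
            (levels - effects.min_level_db) / (effects.max_level_db - effects.min_level_db),
            0.0, 1.0,
        )
        with np.errstate(invalid="ignore"):
            cf_safe = np.where(np.isfinite(cf), cf, 1.0)
        for ev in range(len(onsets)):
            i0 = int(round(onsets[ev] * fs_hz))
            i1 = min(i0 + k_len, n_samp)
            wgt = np.exp(-0.5 * (np.log2(freqs[ev] / cf_safe) / effects.cf_match_sd_octaves) ** 2)
            wgt[~np.isfinite(cf)] = 0.0
            gains = np.exp(rng.normal(0.0, effects.amplitude_jitter_sd, size=n_ch))
            amps = effects.aep_amplitude_uv * wgt * gains * float(level_scale[ev])
            hit = wgt * float(level_scale[ev]) > 0.01
            if hit.any():
                data[hit, i0:i1] += (
                    amps[hit, None] * kernel[None, : i1 - i0]
                ).astype(np.float32)

    if schedule.protocol == "long_tone" and effects.sustained_amplitude_uv > 0:
        f_c = 0.5 * (lo + hi)
        ramp_n = int(round(0.1 * fs_hz))
        for ev in range(len(onsets)):
            f_ev = freqs[ev]
            i0 = int(round((onsets[ev] + 0.5) * fs_hz))
            i1 = int(round((onsets[ev] + durations[ev] - 0.5) * fs_hz))
            i1 = min(i1, n_samp)
            n_seg = i1 - i0
            if n_seg <= 2 * ramp_n:
                continue
            t_seg = np.arange(n_seg) / fs_hz
            phase = 2.0 * math.pi * f_c * t_seg
            env = np.ones(n_seg)
            ramp = 0.5 * (1.0 - np.cos(np.linspace(0, math.pi, ramp_n)))
            env[:ramp_n] = ramp
            env[-ramp_n:] = ramp[::-1]
            strong: list[int] = []
            for ch in range(n_ch):
                wgt = float(_tuning_weight(f_ev, cf[ch], effects.cf_match_sd_octaves))
                if wgt < 0.05:
                    continue
                if wgt >= 0.5:
                    strong.append(int(site_map.table.iloc[ch]["site_id"]))
                jitter = _smooth_phase_jitter(rng, n_seg, effects.plv_phase_jitter_sd_rad)
                gain = np.exp(_smooth_gain_log(rng, n_seg, effects.amplitude_jitter_sd))
                osc = gain * effects.sustained_amplitude_uv * wgt * env * np.sin(phase + jitter)
                data[ch, i0:i1] += osc.astype(np.float32)
            key = float(f_ev)
            responsive.setdefault(key, sorted(set(strong)))

    burst_log: list[dict] = []
    if bursts.occupancy > 0:
        mean_dur = 0.5 * sum(bursts.duration_range_s)
        rate = bursts.occupancy / mean_dur
        t = rng.exponential(1.0 / rate)
        while t < schedule.total_duration_s:
            dur = rng.uniform(*bursts.duration_range_s)
            n_aff = int(rng.integers(min(bursts.min_sites, n_ch), n_ch + 1))
            chans = np.sort(rng.choice(n_ch, size=n_aff, replace=False))
            i0 = int(round(t * fs_hz))
            i1 = min(int(round((t + dur) * fs_hz)), n_samp)
            if i1 > i0:
                data[chans, i0:i1] *= bursts.gain
                burst_log.append(
                    {"start_s": i0 / fs_hz, "end_s": i1 / fs_hz, "channels": chans.tolist()}
                )
            t += dur + rng.exponential(1.0 / rate)

    meta = {
        "seed": int(seed),
        "effects": asdict(effects),
        "bursts": asdict(bursts),
        "responsive_sites": {str(k): v for k, v in responsive.items()},
    }
    return LfpRecording(
        data=data, fs_hz=fs_hz, site_map=site_map, schedule=schedule,
        burst_log=burst_log, meta=meta,
    )
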