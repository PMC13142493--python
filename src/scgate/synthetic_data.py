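"""Synthetic inactivation-session generator with known ground truth.

Emulates a reversible-inactivation electrophysiology session: a population
of superior-colliculus-like neurons from three functional classes (visual,
visual-movement, movement) firing as inhomogeneous Poisson processes;
stimulus presentations before and during inactivation; spontaneous saccades
with presaccadic motor bursts; guided-saccade behavior governed by a
ground-truth scotoma; 1 kHz eye traces whose planted saccades satisfy the
detector's thresholds by construction; and laminar multiunit activity with
a known surface channel.

Scenarios
---------
``LGN``
    near-complete multiplicative suppression of visual drive during
    inactivation; motor drive untouched.
``LGN_plus_contraSC``
    a third phase adds contralateral-SC silencing; visual gain is unchanged
    relative to the LGN-only phase (no rescue) and saccades into the
    inactivated field slow down.
``V1``
    partial suppression whose strength tracks the stimulus-scotoma overlap.

The During/Before visual gain is shared by all neurons of a class
(amplitudes are suppressed multiplicatively), so population means and the
per-neuron Before-vs-During correlation structure both match the configured
scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .laminar import THETA_GRID, LaminarMUASet
from .saccades import (DISPLAY_HALF_X, DISPLAY_HALF_Y, EyePositionTrace,
                       ResponseField, score_guided_trial)
from .scotoma import ScotomaModel, StimulusAperture, mass_contour, stimulus_overlap

CLASSES = ("visual", "visual_movement", "movement")

# ---------------------------------------------------------------------------
# rate kernels

# visual response kernel: two log-normal-shaped bumps, rising ~30 ms after
# stimulus onset, peaking at 50 ms with a smaller second peak near 90 ms
_VIS_PEAKS = ((50.0, 0.18, 1.0), (90.0, 0.15, 0.35))
_VIS_WINDOW = (30.0, 130.0)

# presaccadic motor burst: raised cosine peaking 10 ms before saccade onset
_MOTOR_CENTER = -10.0
_MOTOR_HALFWIDTH = 30.0
_MOTOR_WINDOW = (-50.0, 25.0)


def _vis_kernel_raw(t_ms: np.ndarray) -> np.ndarray:
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    for peak, s, w in _VIS_PEAKS:
        out[pos] += w * np.exp(-(np.log(t[pos] / peak)) ** 2 / (2 * s * s))
    return out


def visual_kernel(t_ms: np.ndarray) -> np.ndarray:
    """Unit-area visual kernel: mean value over the 30-130 ms response window
    is 1, so an amplitude of ``a`` yields an expected evoked rate change of
    exactly ``a`` spikes/s in that window."""
    grid = np.arange(_VIS_WINDOW[0], _VIS_WINDOW[1], 0.1) + 0.05
    mean_in_window = float(np.mean(_vis_kernel_raw(grid)))
    return _vis_kernel_raw(t_ms) / mean_in_window


def motor_kernel(t_ms: np.ndarray) -> np.ndarray:
    """Unit-area presaccadic burst kernel (mean over -50..+25 ms equals 1)."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    inside = np.abs(t - _MOTOR_CENTER) < _MOTOR_HALFWIDTH
    out[inside] = 0.5 * (1 + np.cos(np.pi * (t[inside] - _MOTOR_CENTER)
                                    / _MOTOR_HALFWIDTH))
    grid = np.arange(_MOTOR_WINDOW[0], _MOTOR_WINDOW[1], 0.1) + 0.05
    raw = np.zeros_like(grid)
    ins = np.abs(grid - _MOTOR_CENTER) < _MOTOR_HALFWIDTH
    raw[ins] = 0.5 * (1 + np.cos(np.pi * (grid[ins] - _MOTOR_CENTER)
                                 / _MOTOR_HALFWIDTH))
    return out / float(np.mean(raw))


# ---------------------------------------------------------------------------
# distributions


def truncated_normal(mean: float, sd: float, lower: float, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample a normal truncated below at ``lower`` whose *realized* mean is
    ``mean``: the parent location is re-solved so truncation does not inflate
    the population mean."""
    if sd <= 0:
        return np.full(size, float(mean))
    if mean <= lower:
        raise ValueError("requested mean must exceed the truncation bound")

    def trunc_mean(loc):
        a = (lower - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - mean

    lo, hi = lower - 10 * sd, mean + sd
    loc = optimize.brentq(trunc_mean, lo, hi)
    a = (lower - loc) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=size,
                               random_state=rng)


def sample_inhomogeneous_poisson(rate_hz: np.ndarray, n_trials: int,
                                 rng: np.random.Generator,
                                 t0_ms: float = 0.0) -> list[np.ndarray]:
    """Per-trial spike times from a rate vector on a 1 ms grid.

    Counts per bin are Poisson with mean rate*dt; times are jittered
    uniformly within their bin, so the expected count in any window equals
    the integral of the rate over it.
    """
    rate = np.asarray(rate_hz, dtype=float)
    counts = rng.poisson(rate * 1e-3, size=(n_trials, rate.size))
    bin_t = t0_ms + np.arange(rate.size, dtype=float)
    out = []
    for row in counts:
        total = int(row.sum())
        if total == 0:
            out.append(np.empty(0))
            continue
        times = np.repeat(bin_t, row) + rng.random(total)
        times.sort()
        out.append(times)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Complete description of a synthetic inactivation session."""

    seed: int = 0
    scenario: str = "LGN"
    n_neurons_by_class: dict = field(
        default_factory=lambda: {"visual": 90, "visual_movement": 25,
                                 "movement": 7})
    evoked_mean_before: dict = field(
        default_factory=lambda: {"visual": 48.8, "visual_movement": 22.8,
                                 "movement": 0.0})
    evoked_mean_during: dict = field(
        default_factory=lambda: {"visual": 1.0, "visual_movement": 0.4,
                                 "movement": 0.0})
    evoked_between_neuron_sd: dict = field(
        default_factory=lambda: {"visual": 36.0, "visual_movement": 20.0,
                                 "movement": 0.0})
    # smallest evoked amplitude a neuron can have and still be functionally
    # classified as visually responsive (spikes/s)
    evoked_min: float = 12.0
    baseline_rate: float = 10.0
    motor_burst_peak: float = 80.0          # mean motor rate change, spikes/s
    motor_between_neuron_sd: float = 40.0
    motor_min: float = 10.0
    n_stim_trials_per_phase: int = 150
    n_behavior_trials_per_phase: int = 40   # guided trials to the RF target
    n_map_trials_per_phase: int = 196       # guided trials tiling the field
    n_saccade_trials_per_phase: int = 30    # spontaneous in-RF saccades
    rf_center: ResponseField = field(
        default_factory=lambda: ResponseField(direction=225.0, eccentricity=8.0))
    stimulus_aperture: StimulusAperture | None = None
    scotoma_truth: ScotomaModel | None = None
    before_failure_floor: float = 0.13
    # laminar MUA
    n_channels: int = 32
    channel_spacing_um: float = 50.0
    true_surface_channel: int = 5
    n_mua_trials: int = 100
    mua_noise_rate: float = 20.0            # crossings/s at theta = -3 SD
    mua_evoked_rate: float = 40.0           # evoked crossings/s at -3 SD
    mua_theta_lambda: float = 1.0           # rate(theta) = rate(-3) e^{-(|t|-3)/lam}
    mua_bleed_rate: float = 15.0            # volume-conducted drive above surface
    mua_bleed_theta_lambda: float = 0.8
    mua_bleed_space_um: float = 150.0
    # waveform peak amplitudes in noise-SD units: volume-conducted spikes are
    # small and never cross thresholds beyond ~4.8 SD; genuine multiunit
    # waveforms peak between 5 and 6 SD, so the deepest thresholds lose
    # channels heterogeneously
    mua_bleed_max_sd: float = 4.8
    mua_unit_max_sd_range: tuple = (5.0, 6.0)
    # contralateral-SC add-on
    velocity_reduction_factor: float = 0.75
    fixation_noise_sd: float = 0.05
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.scenario not in ("LGN", "LGN_plus_contraSC", "V1"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for cls in CLASSES:
            if self.n_neurons_by_class.get(cls, 0) < 0:
                raise ValueError("neuron counts must be >= 0")
            for d in (self.evoked_mean_before, self.evoked_mean_during):
                if d.get(cls, 0.0) < 0:
                    raise ValueError("rates must be >= 0")
        if sum(self.n_neurons_by_class.values()) < 1:
            raise ValueError("need at least one neuron")
        for name in ("baseline_rate", "motor_burst_peak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_stim_trials_per_phase", "n_behavior_trials_per_phase",
                     "n_map_trials_per_phase", "n_saccade_trials_per_phase",
                     "n_mua_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.rf_center.eccentricity <= 0:
            raise ValueError("rf eccentricity must be > 0")
        if self.scenario == "V1" and self.stimulus_aperture is None:
            raise ValueError("V1 scenario requires a stimulus_aperture")
        if self.stimulus_aperture is None:
            self.stimulus_aperture = StimulusAperture(
                center=self.rf_center.center_xy, radius=3.0)
        if self.scotoma_truth is None:
            cx, cy = self.rf_center.center_xy
            self.scotoma_truth = ScotomaModel(
                amplitude=0.85, x0=cx, y0=cy, sigma_x=6.0, sigma_y=4.5,
                rotation=0.4, offset=0.05)
        if not 1 <= self.true_surface_channel <= self.n_channels:
            raise ValueError("true_surface_channel outside the probe")

    @property
    def phases(self) -> tuple:
        if self.scenario == "LGN_plus_contraSC":
            return ("before", "during_lgn", "during_both")
        return ("before", "during")

    def visual_gain(self, cls: str) -> float:
        before = self.evoked_mean_before.get(cls, 0.0)
        if before == 0:
            return 0.0
        return self.evoked_mean_during.get(cls, 0.0) / before

    def phase_gain(self, cls: str, phase: str) -> float:
        return 1.0 if phase == "before" else self.visual_gain(cls)


@dataclass
class NeuronRecord:
    """One simulated neuron with its ground truth."""

    id: int
    functional_class: str
    depth_um: float                  # signed, relative to the true surface
    snr: float
    true_evoked_before: float
    true_evoked_during: float
    true_motor_amplitude: float
    stim_spikes: dict = field(default_factory=dict)   # phase -> [trial arrays]
    motor_spikes: dict = field(default_factory=dict)  # phase -> [trial arrays]
    baseline_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.functional_class == "visual" and self.true_motor_amplitude != 0:
            raise ValueError("visual neurons have no motor drive")
        if self.functional_class == "movement" and (
                self.true_evoked_before != 0 or self.true_evoked_during != 0):
            raise ValueError("movement neurons have no visual drive")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")

    @property
    def mean_rate(self) -> float:
        """Overall firing rate (spikes/s) across all stimulus-trial windows."""
        n_spk = sum(sum(len(a) for a in trials)
                    for trials in self.stim_spikes.values())
        n_trials = sum(len(trials) for trials in self.stim_spikes.values())
        if n_trials == 0:
            return self.baseline_rate
        return n_spk / (n_trials * (_STIM_SPAN[1] - _STIM_SPAN[0]) / 1000.0)


@dataclass
class SessionBundle:
    """Everything generated for one synthetic session."""

    config: GeneratorConfig
    neurons: list
    behavior: pd.DataFrame
    eye_traces: dict                 # trial_id -> EyePositionTrace
    free_view_traces: dict           # phase -> EyePositionTrace
    saccade_onsets: dict             # phase -> in-RF saccade onset times (ms)
    event_table: pd.DataFrame        # trial_id, event, t_ms, phase
    mua: dict                        # phase -> LaminarMUASet

    def stim_onsets(self, phase: str) -> np.ndarray:
        sel = (self.event_table["event"] == "stim_onset") \
            & (self.event_table["phase"] == phase)
        return self.event_table.loc[sel, "t_ms"].to_numpy()


# spike support around each stimulus onset / saccade onset (ms, half-open)
_STIM_SPAN = (-300.0, 500.0)
_MOTOR_SPAN = (-400.0, 200.0)
_PHASE_BLOCK = 10_000_000.0
_MOTOR_BLOCK = 5_000_000.0
_TRIAL_SLOT = 1000.0
_TRIAL_ONSET = 300.0


# ---------------------------------------------------------------------------
# eye traces


@dataclass
class PlannedSaccade:
    onset_ms: float
    end_xy: tuple
    duration_ms: float | None = None   # main-sequence duration when None


def main_sequence_duration(amplitude_deg: float) -> float:
    """Main-sequence-like duration: D = 2.2 * amplitude + 21 ms."""
    return 2.2 * amplitude_deg + 21.0


def _smooth_noise(n: int, sd: float, rng: np.random.Generator,
                  width: int = 21) -> np.ndarray:
    """Band-limited fixational noise with the requested position SD."""
    raw = rng.standard_normal(n + width)
    kernel = np.ones(width) / width
    sm = np.convolve(raw, kernel, mode="same")[:n]
    scale = sd / (1.0 / math.sqrt(width))
    return sm * scale


def generate_eye_trace(plan, duration_ms: float,
                       noise_sd: float = 0.05,
                       start_xy=(0.0, 0.0),
                       rng: np.random.Generator | None = None) -> EyePositionTrace:
    """1 kHz eye trace with fixational noise and planted saccades.

    Each planned saccade follows a raised-cosine velocity profile whose
    duration comes from the main sequence (so peak velocity grows with
    amplitude and every planted saccade of a degree or more exceeds the
    detector's velocity threshold). Positions are continuous; saccades must
    not overlap and endpoints must stay within the display.
    """
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_ms))
    t = np.arange(n, dtype=float)
    x = np.full(n, float(start_xy[0]))
    y = np.full(n, float(start_xy[1]))

    plan = sorted(plan, key=lambda s: s.onset_ms)
    cur = (float(start_xy[0]), float(start_xy[1]))
    prev_end_t = -np.inf
    for sac in plan:
        ex, ey = sac.end_xy
        if abs(ex) > DISPLAY_HALF_X or abs(ey) > DISPLAY_HALF_Y:
            raise ValueError(f"planned endpoint {sac.end_xy} outside display "
                             f"bounds (+-{DISPLAY_HALF_X}, +-{DISPLAY_HALF_Y})")
        amp = math.hypot(ex - cur[0], ey - cur[1])
        dur = sac.duration_ms if sac.duration_ms is not None \
            else main_sequence_duration(amp)
        dur = max(dur, 12.0)
        if sac.onset_ms < prev_end_t:
            raise ValueError("planned saccades overlap")
        if sac.onset_ms < 0 or sac.onset_ms + dur > n:
            raise ValueError("planned saccade outside trace span")
        # raised-cosine velocity -> displacement profile s(p) = p - sin(2*pi*p)/(2*pi)
        seg = (t >= sac.onset_ms) & (t < sac.onset_ms + dur)
        p = (t[seg] - sac.onset_ms) / dur
        s = p - np.sin(2 * np.pi * p) / (2 * np.pi)
        x[seg] = cur[0] + (ex - cur[0]) * s
        y[seg] = cur[1] + (ey - cur[1]) * s
        x[t >= sac.onset_ms + dur] = ex
        y[t >= sac.onset_ms + dur] = ey
        cur = (ex, ey)
        prev_end_t = sac.onset_ms + dur

    x += _smooth_noise(n, noise_sd, rng)
    y += _smooth_noise(n, noise_sd, rng)
    return EyePositionTrace(t, x, y, np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# laminar MUA


def _depth_profile(config: GeneratorConfig) -> np.ndarray:
    """Stimulus-drive scaling per channel: zero above the surface, full drive
    for ~600 um below it, tapering out by ~1.1 mm."""
    ch = np.arange(1, config.n_channels + 1)
    depth = (ch - config.true_surface_channel) * config.channel_spacing_um
    prof = np.zeros(config.n_channels)
    below = depth >= 0
    prof[below] = np.clip(1.0 - (depth[below] - 600.0) / 500.0, 0.0, 1.0)
    return prof


def _bleed_profile(config: GeneratorConfig) -> np.ndarray:
    """Volume-conducted evoked component on channels above the surface,
    decaying with distance from the surface."""
    ch = np.arange(1, config.n_channels + 1)
    above = ch < config.true_surface_channel
    dist = (config.true_surface_channel - ch) * config.channel_spacing_um
    prof = np.zeros(config.n_channels)
    prof[above] = np.exp(-dist[above] / config.mua_bleed_space_um)
    return prof


def theta_rate_factor(theta: float, lam: float) -> float:
    """Event-rate attenuation of a |theta| SD threshold relative to -3 SD:
    rate(theta) = rate(-3) * exp(-(|theta| - 3) / lam)."""
    return math.exp(-(abs(theta) - 3.0) / lam)


def generate_laminar_mua(config: GeneratorConfig, phase: str,
                         rng: np.random.Generator | None = None) -> LaminarMUASet:
    """Per-channel, per-threshold Poisson event streams for one phase.

    Channels above the true surface carry noise plus a weak volume-conducted
    stimulus component whose rate decays faster with |theta| than genuine
    MUA; channels at and below the surface carry stimulus-locked drive scaled
    by the depth profile and by the scenario's During visual gain.
    """
    rng = rng or np.random.default_rng(config.seed)
    gain = config.phase_gain("visual", phase)
    bins = np.arange(*_STIM_SPAN)
    kern = visual_kernel(bins + 0.5)
    drive = _depth_profile(config)
    bleed = _bleed_profile(config)
    # largest waveform excursion per channel (noise-SD units): thresholds
    # beyond it collect no crossings from that channel's units
    unit_max_sd = rng.uniform(*config.mua_unit_max_sd_range, config.n_channels)

    # events are drawn once at the -3 SD level and thinned for deeper
    # thresholds (a -5 SD crossing is by definition also a -3 SD crossing),
    # so per-channel counts are non-increasing in |theta| exactly
    def survival(theta, lam, max_sd):
        if abs(theta) > max_sd:
            return 0.0
        return theta_rate_factor(theta, lam)

    components = []   # (per-channel rate scale, kernel?, lambda, max_sd per ch)
    chan_events = [[] for _ in range(config.n_channels)]   # (times, u) per trial
    for ch in range(config.n_channels):
        specs = [
            (np.full(bins.size, config.mua_noise_rate),
             config.mua_theta_lambda, np.inf),
            (config.mua_evoked_rate * drive[ch] * gain * kern,
             config.mua_theta_lambda, float(unit_max_sd[ch])),
            (config.mua_bleed_rate * bleed[ch] * gain * kern,
             config.mua_bleed_theta_lambda, config.mua_bleed_max_sd),
        ]
        per_trial = [[] for _ in range(config.n_mua_trials)]
        for rate, lam, max_sd in specs:
            if not np.any(rate > 0):
                continue
            trials = sample_inhomogeneous_poisson(
                rate, config.n_mua_trials, rng, t0_ms=_STIM_SPAN[0])
            for i, times in enumerate(trials):
                per_trial[i].append((times, rng.random(times.size), lam, max_sd))
        chan_events[ch] = per_trial

    events = {}
    for theta in THETA_GRID:
        chans = []
        for ch in range(config.n_channels):
            trials_out = []
            for comps in chan_events[ch]:
                kept = [times[u <= survival(theta, lam, max_sd)]
                        for times, u, lam, max_sd in comps]
                merged = np.sort(np.concatenate(kept)) if kept else np.empty(0)
                trials_out.append(merged)
            chans.append(trials_out)
        events[float(theta)] = chans
    return LaminarMUASet(events=events, n_channels=config.n_channels,
                         channel_spacing_um=config.channel_spacing_um,
                         noise_sd=rng.normal(10.0, 1.0, config.n_channels),
                         thetas=tuple(float(t) for t in THETA_GRID))


# ---------------------------------------------------------------------------
# session generation


def _neuron_truths(config: GeneratorConfig, rng: np.random.Generator):
    records = []
    nid = 0
    depth_ranges = {"visual": (0.0, 600.0), "visual_movement": (300.0, 1000.0),
                    "movement": (800.0, 1500.0)}
    for cls in CLASSES:
        n = config.n_neurons_by_class.get(cls, 0)
        if n == 0:
            continue
        mean_b = config.evoked_mean_before.get(cls, 0.0)
        sd = config.evoked_between_neuron_sd.get(cls, 0.0) \
            if isinstance(config.evoked_between_neuron_sd, dict) \
            else config.evoked_between_neuron_sd
        gain = config.visual_gain(cls)
        if cls == "movement" or mean_b == 0:
            before = np.zeros(n)
        else:
            before = truncated_normal(mean_b, sd, config.evoked_min, n, rng)
        during = before * gain
        if cls == "visual":
            motor = np.zeros(n)
        else:
            motor = truncated_normal(config.motor_burst_peak,
                                     config.motor_between_neuron_sd,
                                     config.motor_min, n, rng)
        lo, hi = depth_ranges[cls]
        depths = rng.uniform(lo, hi, n)
        snrs = rng.uniform(2.0, 6.0, n)
        for i in range(n):
            records.append(NeuronRecord(
                id=nid, functional_class=cls, depth_um=float(depths[i]),
                snr=float(snrs[i]),
                true_evoked_before=float(before[i]),
                true_evoked_during=float(during[i]),
                true_motor_amplitude=float(motor[i]),
                baseline_rate=config.baseline_rate))
            nid += 1
    return records


def _phase_offset(config: GeneratorConfig, phase: str) -> float:
    return config.phases.index(phase) * _PHASE_BLOCK


def _stim_onsets_for(config: GeneratorConfig, phase: str) -> np.ndarray:
    base = _phase_offset(config, phase)
    i = np.arange(config.n_stim_trials_per_phase)
    return base + i * _TRIAL_SLOT + _TRIAL_ONSET


def _saccade_onsets_for(config: GeneratorConfig, phase: str) -> np.ndarray:
    base = _phase_offset(config, phase) + _MOTOR_BLOCK
    i = np.arange(config.n_saccade_trials_per_phase)
    return base + i * _TRIAL_SLOT + 500.0


def _evoked_amp(neuron: NeuronRecord, phase: str) -> float:
    return neuron.true_evoked_before if phase == "before" \
        else neuron.true_evoked_during


def _generate_stim_spikes(config: GeneratorConfig, neurons, rng) -> None:
    bins = np.arange(*_STIM_SPAN)
    vis_k = visual_kernel(bins + 0.5)
    for neuron in neurons:
        for phase in config.phases:
            amp = _evoked_amp(neuron, phase)
            rate = config.baseline_rate + amp * vis_k
            onsets = _stim_onsets_for(config, phase)
            rel = sample_inhomogeneous_poisson(
                rate, onsets.size, rng, t0_ms=_STIM_SPAN[0])
            neuron.stim_spikes[phase] = [r + t0 for r, t0 in zip(rel, onsets)]


def _generate_motor_spikes(config: GeneratorConfig, neurons, rng) -> None:
    mbins = np.arange(*_MOTOR_SPAN)
    mot_k = motor_kernel(mbins + 0.5)
    for neuron in neurons:
        for phase in config.phases:
            mrate = config.baseline_rate + neuron.true_motor_amplitude * mot_k
            monsets = _saccade_onsets_for(config, phase)
            mrel = sample_inhomogeneous_poisson(
                mrate, monsets.size, rng, t0_ms=_MOTOR_SPAN[0])
            neuron.motor_spikes[phase] = [r + t0 for r, t0 in zip(mrel, monsets)]


def _map_targets(config: GeneratorConfig) -> np.ndarray:
    """Grid of guided-saccade targets tiling the affected quadrant."""
    cx, cy = config.rf_center.center_xy
    xs = cx + np.arange(-12.0, 13.0, 4.0)
    ys = cy + np.arange(-12.0, 13.0, 4.0)
    pts = [(x, y) for y in ys for x in xs
           if abs(x) <= DISPLAY_HALF_X - 2 and abs(y) <= DISPLAY_HALF_Y - 2]
    return np.array(pts)


def _behavior_phase_tag(phase: str) -> str:
    return "before" if phase == "before" else "during"


def _generate_behavior(config: GeneratorConfig, rng) -> tuple:
    """Guided-saccade trials with synthetic eye traces, scored by the detector."""
    truth = config.scotoma_truth
    rf_xy = config.rf_center.center_xy
    grid = _map_targets(config)
    rows = []
    traces = {}
    trial_id = 0
    go_cue = 800.0
    span = 2000.0
    for phase in config.phases:
        targets = []
        targets += [(rf_xy, True)] * config.n_behavior_trials_per_phase
        idx = np.arange(config.n_map_trials_per_phase) % len(grid)
        targets += [((grid[i][0], grid[i][1]), False) for i in idx]
        for (tx, ty), is_rf in targets:
            if phase == "before":
                p_fail = config.before_failure_floor
            else:
                p_fail = float(truth.failure_probability(tx, ty))
            intended_fail = rng.random() < p_fail
            plan = []
            if not intended_fail:
                latency = rng.uniform(150.0, 350.0)
                end = (tx + rng.normal(0, 0.3), ty + rng.normal(0, 0.3))
                end = (float(np.clip(end[0], -DISPLAY_HALF_X, DISPLAY_HALF_X)),
                       float(np.clip(end[1], -DISPLAY_HALF_Y, DISPLAY_HALF_Y)))
                plan.append(PlannedSaccade(onset_ms=go_cue + latency, end_xy=end))
            trace = generate_eye_trace(plan, span, config.fixation_noise_sd,
                                       rng=rng)
            scored = score_guided_trial(trace, (tx, ty), go_cue)
            rows.append((trial_id, _behavior_phase_tag(phase), phase, tx, ty,
                         scored.outcome, scored.latency_ms, is_rf,
                         "fail" if intended_fail else "success", go_cue))
            traces[trial_id] = trace
            trial_id += 1
    behavior = pd.DataFrame(rows, columns=[
        "trial_id", "phase", "phase_detail", "target_x_deg", "target_y_deg",
        "outcome", "latency_ms", "is_rf_target", "intended_outcome", "go_cue_ms"])
    return behavior, traces


def _generate_free_viewing(config: GeneratorConfig, rng) -> tuple:
    """Free-viewing traces with planted in-RF saccades (and return saccades)."""
    rf = config.rf_center
    traces = {}
    onsets = {}
    for phase in config.phases:
        slow = (phase == "during_both")
        scale = 1.0 / config.velocity_reduction_factor if slow else 1.0
        n = config.n_saccade_trials_per_phase
        plan = []
        sac_onsets = []
        for k in range(n):
            t0 = k * _TRIAL_SLOT + 500.0
            direction = rf.direction + rng.uniform(-6.0, 6.0)
            amp = rf.eccentricity * rng.uniform(0.9, 1.3)
            th = math.radians(direction)
            end = (amp * math.cos(th), amp * math.sin(th))
            dur = main_sequence_duration(amp) * scale
            plan.append(PlannedSaccade(t0, end, duration_ms=dur))
            plan.append(PlannedSaccade(t0 + 400.0, (0.0, 0.0)))
            sac_onsets.append(t0)
        trace = generate_eye_trace(plan, n * _TRIAL_SLOT,
                                   config.fixation_noise_sd, rng=rng)
        base = _phase_offset(config, phase) + _MOTOR_BLOCK
        trace = EyePositionTrace(trace.t + base, trace.x, trace.y, trace.valid)
        traces[phase] = trace
        onsets[phase] = base + np.asarray(sac_onsets)
    return traces, onsets


ALL_PARTS = frozenset({"stimulus", "motor", "behavior", "mua"})


def generate_session(config: GeneratorConfig,
                     parts=ALL_PARTS) -> SessionBundle:
    """Generate a full synthetic session.

    ``parts`` selects which components to synthesize ({"stimulus", "motor",
    "behavior", "mua"}); unrequested components are left empty. Each
    component consumes an independent child stream of the configured seed, so
    identical (config, seed) always produce bit-identical output regardless
    of which other parts are requested.
    """
    parts = frozenset(parts)
    unknown = parts - ALL_PARTS
    if unknown:
        raise ValueError(f"unknown parts {sorted(unknown)}")
    ss = np.random.SeedSequence(config.seed)
    keys = ("truth", "stimulus", "motor_spikes", "behavior", "mua", "free")
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    neurons = _neuron_truths(config, rngs["truth"])
    if "stimulus" in parts:
        _generate_stim_spikes(config, neurons, rngs["stimulus"])
    if "motor" in parts:
        _generate_motor_spikes(config, neurons, rngs["motor_spikes"])

    events = []
    for phase in config.phases:
        for i, t in enumerate(_stim_onsets_for(config, phase)):
            events.append((i, "stim_onset", t, phase))
        for i, t in enumerate(_saccade_onsets_for(config, phase)):
            events.append((i, "saccade_onset", t, phase))
    event_table = pd.DataFrame(events, columns=["trial_id", "event", "t_ms",
                                                "phase"])

    if "behavior" in parts:
        behavior, eye_traces = _generate_behavior(config, rngs["behavior"])
    else:
        behavior, eye_traces = pd.DataFrame(), {}

    if "motor" in parts:
        free_traces, sac_onsets = _generate_free_viewing(config, rngs["free"])
    else:
        free_traces, sac_onsets = {}, {}

    mua = {}
    if "mua" in parts:
        for phase in config.phases:
            mua[phase] = generate_laminar_mua(config, phase, rngs["mua"])

    return SessionBundle(config=config, neurons=neurons, behavior=behavior,
                         eye_traces=eye_traces, free_view_traces=free_traces,
                         saccade_onsets=sac_onsets, event_table=event_table,
                         mua=mua)


# ---------------------------------------------------------------------------
# scenario presets (population parameters match the printed study values)


def lgn_session_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """LGN inactivation: near-complete suppression of visual drive.

    Class compositions and Before/During evoked means follow the LGN
    experiment (visual 48.8 -> 1.0, visual-movement 22.8 -> 0.4 spikes/s;
    90 + 25 visually responsive neurons, 7 pure movement neurons); Before
    failure floor 13% and a scotoma whose failure probability at the RF
    center is 0.90.
    """
    return GeneratorConfig(seed=seed, scenario="LGN", **overrides)


def contra_sc_session_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """LGN + contralateral SC: same visual gain in both During phases
    (no rescue), slowed saccades into the inactivated field."""
    defaults = dict(
        scenario="LGN_plus_contraSC",
        n_neurons_by_class={"visual": 17, "visual_movement": 14, "movement": 7},
    )
    defaults.update(overrides)
    return GeneratorConfig(seed=seed, **defaults)


#: per-session suppression fractions for the pooled V1 population: the full
#: overlap session at 0.95 and the partial-overlap example at 0.78 are the
#: printed values; the remaining two partial sessions are set so the
#: neuron-weighted mean equals the printed population mean of 61.5%.
V1_SESSION_SUPPRESSIONS = (0.95, 0.78, 0.40, 0.31)
V1_SESSION_NEURONS = (14, 14, 14, 13)


def v1_session_config(seed: int = 0, suppression: float = 0.95,
                      n_visual: int = 14, **overrides) -> GeneratorConfig:
    """One V1-inactivation session with overlap-dependent suppression."""
    n_vis = max(1, round(n_visual * 0.7))
    n_vm = n_visual - n_vis
    counts = {"visual": n_vis, "visual_movement": max(n_vm, 0), "movement": 2}
    before = {"visual": 48.8, "visual_movement": 22.8, "movement": 0.0}
    during = {c: before[c] * (1.0 - suppression) for c in before}
    defaults = dict(
        scenario="V1",
        n_neurons_by_class=counts,
        evoked_mean_before=before,
        evoked_mean_during=during,
        stimulus_aperture=StimulusAperture(
            center=ResponseField(225.0, 8.0).center_xy, radius=3.0),
        scotoma_truth=ScotomaModel(amplitude=0.78,
                                   x0=ResponseField(225.0, 8.0).center_xy[0],
                                   y0=ResponseField(225.0, 8.0).center_xy[1],
                                   sigma_x=4.0, sigma_y=2.5, rotation=0.3,
                                   offset=0.05),
        before_failure_floor=0.104,
    )
    defaults.update(overrides)
    return GeneratorConfig(seed=seed, **defaults)


def generate_overlap_conditions(n_conditions: int = 12,
                                rng: np.random.Generator | None = None,
                                slope: float = 90.0, intercept: float = 3.0,
                                noise_sd: float = 8.0,
                                neurons_per_condition=(4, 20)):
    """Stimulus-scotoma overlap conditions with monotone suppression.

    A fixed scotoma contour is probed by apertures placed along a line so
    geometric overlap fractions (computed with :func:`stimulus_overlap`)
    spread over [0, 1]; per-condition mean percent reduction is a linear
    function of overlap plus condition-level Gaussian noise. Returns a list
    of (overlap, percent_reduction, n_neurons).
    """
    rng = rng or np.random.default_rng(0)
    model = ScotomaModel(amplitude=0.8, x0=-8.0, y0=-4.0, sigma_x=4.0,
                         sigma_y=3.0, rotation=0.3, offset=0.05)
    contour = mass_contour(model, 0.95)
    out = []
    shifts = np.linspace(0.0, 2.2, n_conditions)
    for i, s in enumerate(shifts):
        center = (model.x0 + s * contour.a, model.y0 + 0.3 * s * contour.b)
        frac = stimulus_overlap(contour, StimulusAperture(center, 3.0))
        reduction = intercept + slope * frac + rng.normal(0.0, noise_sd)
        n = int(rng.integers(neurons_per_condition[0],
                             neurons_per_condition[1] + 1))
        out.append((float(frac), float(reduction), n))
    return out
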