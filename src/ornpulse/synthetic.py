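"""Forward simulators with ground truth for every analysis stage.

Calcium traces are generated as a Poisson event train convolved with a
peak-normalized difference-of-exponentials kernel, riding on a baseline
with optional linear drift and Gaussian camera noise. Stimulus-response
traces follow a phenomenological two-regime model: a sustained,
fluctuating response that undershoots the pre-stimulus baseline at
light offset ("wild-type-like"), or a strong onset that adapts
exponentially during stimulation and relaxes slowly back to baseline
afterwards ("mutant-like"). Image stacks paint traces into disjoint
ROI footprints over a flat background. Trajectories are persistent
random walks inside a circular arena, with a Bernoulli decision drawn
once per approach to a quadrant boundary.

Every generator is a pure function of its parameters including the
seed, and attaches the ground truth needed for parameter-recovery
tests.

Default calibration: with an evoked response maximum of 0.676 ΔF/F0
and the default event amplitude of 0.413 ΔF/F0, spontaneous events
average 61.1% of the evoked maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .behavior import ArenaConfig, TrajectorySet
from .imaging_io import ROI, FluorescenceTrace, ImageStack
from .trace_analysis import StimulusProtocol

__all__ = [
    "CalciumSimParams",
    "StimSimParams",
    "BehaviorSimParams",
    "GroundTruth",
    "simulate_calcium_trace",
    "simulate_stim_response_trace",
    "simulate_image_stack",
    "simulate_trajectories",
    "write_ground_truth",
    "DEFAULT_EVOKED_DFF_MAX",
    "DEFAULT_EVENT_AMPLITUDE",
]

# evoked ΔF/F0max calibration target (fraction) and the event amplitude
# that puts spontaneous events at 61.1% of it
DEFAULT_EVOKED_DFF_MAX = 0.676
DEFAULT_EVENT_AMPLITUDE = 0.413

# kernel settings under which a 2σ run detector recovers the generator
# rate to within 20% up to ~1 event/s: at the GCaMP6f-like default
# kernel (decay 0.4 s) events at that rate overlap too heavily for any
# threshold detector to resolve, so rate-recovery studies use this
# sharper transient
RECOVERY_KERNEL = {
    "kernel_rise_tau": 0.015,
    "kernel_decay_tau": 0.08,
    "event_amplitude_cv": 0.2,
    "noise_sigma": 2.0,
}


def recovery_params(event_rate: float, seed: int, **overrides) -> "CalciumSimParams":
    """CalciumSimParams preset for rate-recovery studies (see RECOVERY_KERNEL)."""
    kwargs = {**RECOVERY_KERNEL, "event_rate": event_rate, "seed": seed, **overrides}
    return CalciumSimParams(**kwargs)


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass
class CalciumSimParams:
    """Parameters of the spontaneous-event trace generator."""

    event_rate: float = 0.9  # events / s
    event_amplitude_mean: float = DEFAULT_EVENT_AMPLITUDE  # ΔF/F0
    event_amplitude_cv: float = 0.3
    kernel_rise_tau: float = 0.05  # s
    kernel_decay_tau: float = 0.4  # s
    baseline_level: float = 100.0  # camera units
    noise_sigma: float = 0.0  # camera units
    drift_slope: float = 0.0  # camera units / s
    duration: float = 60.0  # s
    sample_rate: float = 20.0  # frames / s
    rate_mod_freq: float = 0.0  # Hz; > 0 turns on sinusoidal rate modulation
    rate_mod_depth: float = 0.0  # in [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "event_rate",
            "event_amplitude_mean",
            "event_amplitude_cv",
            "kernel_rise_tau",
            "kernel_decay_tau",
            "baseline_level",
            "noise_sigma",
            "drift_slope",
            "duration",
            "sample_rate",
            "rate_mod_freq",
            "rate_mod_depth",
        ):
            _check_finite(name, getattr(self, name))
        _require(self.event_rate >= 0, f"event_rate must be >= 0, got {self.event_rate}")
        _require(
            self.kernel_decay_tau > self.kernel_rise_tau > 0,
            "kernel taus must satisfy kernel_decay_tau > kernel_rise_tau > 0 "
            f"(got rise {self.kernel_rise_tau}, decay {self.kernel_decay_tau})",
        )
        _require(self.duration > 0, f"duration must be > 0, got {self.duration}")
        _require(self.sample_rate > 0, f"sample_rate must be > 0, got {self.sample_rate}")
        _require(self.noise_sigma >= 0, f"noise_sigma must be >= 0, got {self.noise_sigma}")
        _require(self.baseline_level > 0, f"baseline_level must be > 0, got {self.baseline_level}")
        _require(
            self.event_amplitude_mean >= 0,
            f"event_amplitude_mean must be >= 0, got {self.event_amplitude_mean}",
        )
        _require(
            self.event_amplitude_cv >= 0,
            f"event_amplitude_cv must be >= 0, got {self.event_amplitude_cv}",
        )
        _require(
            0 <= self.rate_mod_depth <= 1,
            f"rate_mod_depth must be in [0, 1], got {self.rate_mod_depth}",
        )
        _require(self.rate_mod_freq >= 0, f"rate_mod_freq must be >= 0, got {self.rate_mod_freq}")


@dataclass
class StimSimParams:
    """Parameters of the stimulus-response trace generator.

    ``adaptation_tau=None`` selects the sustained (wild-type-like)
    regime; a finite value selects the exponentially adapting
    (mutant-like) regime. ``undershoot_depth`` only applies to the
    sustained regime.
    """

    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol("continuous", [5.0], [18.0])
    )
    onset_gain: float = DEFAULT_EVOKED_DFF_MAX  # ΔF/F0
    adaptation_tau: float | None = None  # s; None = sustained
    fluctuation_sigma: float = 0.0  # ΔF/F0
    undershoot_depth: float = 0.1  # ΔF/F0, >= 0
    recovery_tau: float = 2.0  # s
    baseline_level: float = 100.0
    noise_sigma: float = 0.0
    duration: float = 40.0
    sample_rate: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "onset_gain",
            "fluctuation_sigma",
            "undershoot_depth",
            "recovery_tau",
            "baseline_level",
            "noise_sigma",
            "duration",
            "sample_rate",
        ):
            _check_finite(name, getattr(self, name))
        _require(self.recovery_tau > 0, f"recovery_tau must be > 0, got {self.recovery_tau}")
        _require(
            self.undershoot_depth >= 0,
            f"undershoot_depth must be >= 0, got {self.undershoot_depth}",
        )
        if self.adaptation_tau is not None:
            _check_finite("adaptation_tau", self.adaptation_tau)
            _require(self.adaptation_tau > 0, "adaptation_tau must be > 0 or None")
        _require(self.duration > 0, f"duration must be > 0, got {self.duration}")
        _require(self.sample_rate > 0, f"sample_rate must be > 0, got {self.sample_rate}")
        _require(self.noise_sigma >= 0, f"noise_sigma must be >= 0, got {self.noise_sigma}")
        _require(self.baseline_level > 0, f"baseline_level must be > 0, got {self.baseline_level}")
        _require(self.fluctuation_sigma >= 0, "fluctuation_sigma must be >= 0")
        _require(
            self.protocol.final_offset <= self.duration,
            "protocol windows must lie within the trace duration",
        )


@dataclass
class BehaviorSimParams:
    """Parameters of the larval random-walk generator."""

    n_larvae: int = 10
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    step_length_mean: float = 0.1  # cm / frame
    heading_persistence: float = 0.8  # in [0, 1]
    p_turn_back_lit_to_dark: float = 0.955
    p_enter_dark_to_lit: float = 0.75
    duration: float = 300.0  # s
    frame_rate: float = 1.0  # frames / s
    band_width: float = 0.5  # cm; boundary-decision band
    start_positions: list[tuple[float, float]] | None = None  # default: arena center
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_larvae >= 1, f"n_larvae must be >= 1, got {self.n_larvae}")
        for name, p in (
            ("p_turn_back_lit_to_dark", self.p_turn_back_lit_to_dark),
            ("p_enter_dark_to_lit", self.p_enter_dark_to_lit),
        ):
            _require(0 <= p <= 1, f"{name} must be in [0, 1], got {p}")
        _require(
            0 <= self.heading_persistence <= 1,
            f"heading_persistence must be in [0, 1], got {self.heading_persistence}",
        )
        _require(self.step_length_mean >= 0, "step_length_mean must be >= 0")
        _require(self.duration > 0, f"duration must be > 0, got {self.duration}")
        _require(self.frame_rate > 0, f"frame_rate must be > 0, got {self.frame_rate}")
        _require(
            0 < self.band_width < self.arena.radius,
            "band_width must be positive and smaller than the arena radius",
        )
        if self.start_positions is not None:
            _require(
                len(self.start_positions) == self.n_larvae,
                "start_positions must list one position per larva",
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    event_times: np.ndarray | None = None  # s, sorted
    event_amplitudes: np.ndarray | None = None  # ΔF/F0
    boundary_events: list[dict] | None = None  # larva_id, time, origin, outcome
    crossings: dict[int, int] | None = None  # per-larva cross counts

    def __post_init__(self) -> None:
        if self.event_times is not None:
            self.event_times = np.asarray(self.event_times, dtype=float)
            if np.any(np.diff(self.event_times) < 0):
                raise ValueError("ground-truth event times must be sorted")

    @property
    def n_events(self) -> int:
        return 0 if self.event_times is None else self.event_times.size


def _event_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference of exponentials, peak-normalized to 1."""
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    tp = np.maximum(t, 0.0)
    k = np.where(t >= 0, np.exp(-tp / decay) - np.exp(-tp / rise), 0.0)
    return k / peak


def _lognormal_amplitudes(rng, mean: float, cv: float, n: int) -> np.ndarray:
    if mean == 0 or n == 0:
        return np.zeros(n)
    if cv == 0:
        return np.full(n, mean)
    s2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * s2
    return rng.lognormal(mu, math.sqrt(s2), size=n)


def simulate_calcium_trace(params: CalciumSimParams) -> tuple[FluorescenceTrace, GroundTruth]:
    """Simulate one spontaneous-activity trace; returns the raw trace and its ground truth."""
    rng = np.random.default_rng(params.seed)
    n = round(params.duration * params.sample_rate)
    t = np.arange(n) / params.sample_rate

    # homogeneous Poisson train, thinned when rate modulation is on
    lam = params.event_rate
    if lam > 0:
        lam_max = lam * (1.0 + params.rate_mod_depth)
        n_cand = rng.poisson(lam_max * params.duration)
        cand = np.sort(rng.uniform(0.0, params.duration, size=n_cand))
        if params.rate_mod_depth > 0 and params.rate_mod_freq > 0:
            accept_p = (
                1.0 + params.rate_mod_depth * np.sin(2 * math.pi * params.rate_mod_freq * cand)
            ) / (1.0 + params.rate_mod_depth)
            keep = rng.uniform(size=n_cand) < accept_p
            event_times = cand[keep]
        else:
            event_times = cand
    else:
        event_times = np.array([])
    amps = _lognormal_amplitudes(
        rng, params.event_amplitude_mean, params.event_amplitude_cv, event_times.size
    )

    dff = np.zeros(n)
    for t0, a in zip(event_times, amps):
        dff += a * _event_kernel(t - t0, params.kernel_rise_tau, params.kernel_decay_tau)

    F = params.baseline_level * (1.0 + dff) + params.drift_slope * t
    if params.noise_sigma > 0:
        F = F + params.noise_sigma * rng.standard_normal(n)
    trace = FluorescenceTrace(F, params.sample_rate, label=f"sim_seed{params.seed}")
    return trace, GroundTruth(event_times=event_times, event_amplitudes=amps)


def simulate_stim_response_trace(params: StimSimParams) -> FluorescenceTrace:
    """Simulate a light-stimulation response trace (see module docstring).

    In the sustained regime the response drops to ``-undershoot_depth``
    at stimulus offset and relaxes back to baseline with
    ``recovery_tau``; in the adapting regime it decays with
    ``adaptation_tau`` during stimulation and relaxes from its offset
    value toward baseline with ``recovery_tau``, never dropping below
    baseline.
    """
    rng = np.random.default_rng(params.seed)
    n = round(params.duration * params.sample_rate)
    t = np.arange(n) / params.sample_rate
    r = np.zeros(n)

    for on, off in params.protocol.windows:
        during = (t >= on) & (t < off)
        after = t >= off
        td = t[during] - on
        ta = t[after] - off
        if params.adaptation_tau is None:
            r[during] = params.onset_gain
            if params.fluctuation_sigma > 0 and during.any():
                wobble = rng.standard_normal(int(during.sum()))
                # smooth to ~1 s correlation time, renormalize to unit sd
                w = max(1, int(round(params.sample_rate)))
                kernel = np.ones(w) / w
                wobble = np.convolve(wobble, kernel, mode="same")
                sd = wobble.std()
                if sd > 0:
                    wobble = wobble / sd
                r[during] += params.fluctuation_sigma * wobble
            if params.onset_gain != 0:
                r[after] = -params.undershoot_depth * np.exp(-ta / params.recovery_tau)
        else:
            r[during] = params.onset_gain * np.exp(-td / params.adaptation_tau)
            r_off = params.onset_gain * math.exp(-(off - on) / params.adaptation_tau)
            r[after] = r_off * np.exp(-ta / params.recovery_tau)

    F = params.baseline_level * (1.0 + r)
    if params.noise_sigma > 0:
        F = F + params.noise_sigma * rng.standard_normal(n)
    return FluorescenceTrace(F, params.sample_rate, label=f"stim_seed{params.seed}")


def simulate_image_stack(
    rois: list[ROI],
    traces: list[FluorescenceTrace],
    shape: tuple[int, int],
    background_level: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ImageStack:
    """Paint per-ROI traces into disjoint footprints over a flat background."""
    if len(rois) != len(traces):
        raise ValueError("need exactly one trace per ROI")
    if not rois:
        raise ValueError("need at least one ROI")
    H, W = shape
    occupancy = np.zeros(shape, dtype=int)
    for roi in rois:
        if roi.mask.shape != (H, W):
            raise ValueError(f"ROI {roi.label!r} mask shape does not match frame shape")
        occupancy += roi.mask
    if occupancy.max() > 1:
        raise ValueError("ROI footprints overlap")
    n = traces[0].n_samples
    rate = traces[0].sample_rate
    for tr in traces[1:]:
        if tr.n_samples != n or tr.sample_rate != rate:
            raise ValueError("all traces must share length and sample rate")
    frames = np.full((n, H, W), float(background_level))
    for roi, tr in zip(rois, traces):
        frames[:, roi.mask] = tr.values[:, None]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + noise_sigma * rng.standard_normal(frames.shape)
    return ImageStack(frames, frame_interval=1.0 / rate)


# ---------------------------------------------------------------------------
# trajectories

_FORCE_LIMIT = 200  # frames; safety cap on forced boundary resolution


def simulate_trajectories(params: BehaviorSimParams) -> tuple[TrajectorySet, GroundTruth]:
    """Persistent random walks with Bernoulli boundary decisions.

    Each larva performs a correlated random walk (heading noise scaled
    by ``1 - heading_persistence``), reflecting specularly off the dish
    wall. On entering the boundary band around a quadrant line from a
    definite side, one Bernoulli draw fixes the outcome (turn back or
    cross), and the walk is steered perpendicular to the line until the
    outcome is realized; the draw and its realization are recorded as
    ground truth.
    """
    rng = np.random.default_rng(params.seed)
    arena = params.arena
    n_frames = round(params.duration * params.frame_rate)
    band = params.band_width
    step = params.step_length_mean
    turn_sd = (1.0 - params.heading_persistence) * math.pi

    positions: dict[int, np.ndarray] = {}
    gt_events: list[dict] = []
    crossings: dict[int, int] = {}

    for larva in range(params.n_larvae):
        if params.start_positions is not None:
            start = np.asarray(params.start_positions[larva], dtype=float)
        else:
            start = np.asarray(arena.center, dtype=float)
        uv = arena.to_rotated(start)
        heading = rng.uniform(0, 2 * math.pi)
        traj = np.empty((n_frames, 2))
        traj[0] = uv
        crossings[larva] = 0

        last_side: bool | None = None  # lit flag of last out-of-band frame
        forced: dict | None = None  # active approach being steered

        def in_band(p) -> bool:
            return min(abs(p[0]), abs(p[1])) <= band

        def lit_flag(p) -> bool:
            same = (p[0] > 0) == (p[1] > 0)
            return same if arena.lit_pair == "I-III" else not same

        if not in_band(uv):
            last_side = lit_flag(uv)

        for i in range(1, n_frames):
            p = traj[i - 1].copy()
            if forced is not None:
                axis = forced["axis"]
                direction = forced["dir"]
                p[axis] += direction * max(step, 1e-9)
                forced["frames"] += 1
                done = False
                if forced["outcome"] == "turn_back":
                    done = (not in_band(p)) and math.copysign(1, p[axis]) == forced["sign"]
                else:
                    done = (not in_band(p)) and math.copysign(1, p[axis]) == -forced["sign"]
                if done or forced["frames"] > _FORCE_LIMIT:
                    heading_uv = math.atan2(direction * (axis == 1), direction * (axis == 0))
                    heading = heading_uv
                    if forced["outcome"] == "cross":
                        crossings[larva] += 1
                    forced = None
            else:
                heading = heading + turn_sd * rng.standard_normal()
                p = p + step * np.array([math.cos(heading), math.sin(heading)])

            # specular-ish reflection at the dish wall (radial fold)
            rad = math.hypot(p[0], p[1])
            if rad > arena.radius:
                p = p * (2 * arena.radius - rad) / rad
                heading = heading + math.pi
                rad = math.hypot(p[0], p[1])
                if rad > arena.radius:  # pathological fold; clamp
                    p = p * (arena.radius - 1e-9) / rad

            if forced is None and in_band(p) and last_side is not None:
                # one Bernoulli decision per approach
                origin_lit = last_side
                if origin_lit:
                    turn_back = rng.uniform() < params.p_turn_back_lit_to_dark
                else:
                    turn_back = not (rng.uniform() < params.p_enter_dark_to_lit)
                axis = 0 if abs(p[0]) <= abs(p[1]) else 1
                sign = math.copysign(1, p[axis]) if p[axis] != 0 else (1.0 if last_side else -1.0)
                outcome = "turn_back" if turn_back else "cross"
                forced = {
                    "axis": axis,
                    "sign": sign,
                    "dir": sign if turn_back else -sign,
                    "outcome": outcome,
                    "frames": 0,
                }
                gt_events.append(
                    {
                        "larva_id": larva,
                        "time": i / params.frame_rate,
                        "origin": "lit" if origin_lit else "dark",
                        "outcome": outcome,
                    }
                )

            if not in_band(p):
                last_side = lit_flag(p)
            traj[i] = p

        positions[larva] = arena.from_rotated(traj)

    ts = TrajectorySet(positions, params.frame_rate)
    return ts, GroundTruth(boundary_events=gt_events, crossings=crossings)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """JSON-style sidecar with the generator's ground truth."""
    payload: dict = {}
    if gt.event_times is not None:
        payload["event_times"] = [float(x) for x in gt.event_times]
    if gt.event_amplitudes is not None:
        payload["event_amplitudes"] = [float(x) for x in np.asarray(gt.event_amplitudes)]
    if gt.boundary_events is not None:
        payload["boundary_events"] = gt.boundary_events
    if gt.crossings is not None:
        payload["crossings"] = {str(k): int(v) for k, v in gt.crossings.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
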