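"""Synthetic accelerometer recordings with known ground truth.

The generator emulates what a phone or watch riding on a power wheelchair
records.  Each axis reading is modeled as true acceleration plus noise,
where the noise has a white component and a slowly drifting bias component
that is nearly identical between consecutive samples — the property that
makes consecutive-sample differencing an effective noise canceller.
Concretely, per axis:

    reading = scale * (gravity projection
                       + bias random walk + white noise        (stationary)
                       + movement vibration + transients + bumps)

Movement adds broadband vibration (white noise of larger sd plus a
low-frequency sinusoid of random phase/frequency — floor texture); any
spectral model that separates the variance regimes would do.  Sampling is
event-driven: inter-sample gaps are drawn uniformly from the device's rate
range (13-30 Hz by default), so timestamps are irregular.

Device heterogeneity (sensitivity scale, noise level, sampling range,
orientation) is captured by :class:`DeviceProfile`; the catalog values are
plausible placeholders spanning the variation consumer hardware shows, not
measurements of any particular device.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import MOVING, STATIONARY, IntervalTruth, RawRecording

GRAVITY = 9.81

STYLE_SMOOTH = "smooth"
STYLE_ROUGH_START = "rough_start"
STYLE_ROUGH_STOP = "rough_stop"
STYLE_WITH_BUMP = "with_bump"
_STYLES = (STYLE_SMOOTH, STYLE_ROUGH_START, STYLE_ROUGH_STOP, STYLE_WITH_BUMP)


@dataclass
class NoiseModel:
    """Noise parameters of one device, all in m/s^2 (rates in events/min).

    Defaults are calibrated to published example data: consecutive-sample
    differences of a stationary phone scatter with sd ~0.04 m/s^2 per axis
    (white noise sd ~0.03), while differences during movement reach rms
    ~1.1 m/s^2 per axis (vibration sd ~0.75).
    """

    stationary_noise_sd: float = 0.03
    bias_walk_sd: float = 0.005
    moving_vibration_sd: float = 0.75
    bump_rate: float = 0.0
    bump_magnitude: float = 2.0

    def __post_init__(self) -> None:
        if min(self.stationary_noise_sd, self.bias_walk_sd,
               self.moving_vibration_sd, self.bump_rate, self.bump_magnitude) < 0:
            raise ValidationError("noise parameters must be >= 0")


@dataclass
class DeviceProfile:
    """Sampling, sensitivity and noise description of one device."""

    name: str = "device"
    rate_range: tuple = (13.0, 30.0)
    scale: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    orientation: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.rate_range
        if not 0 < lo <= hi:
            raise ValidationError("rate_range must satisfy 0 < min <= max")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")
        o = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(o) - 1.0) > 1e-6:
            raise ValidationError("orientation must be a unit vector")


@dataclass
class ScenarioStep:
    state: str
    duration: float
    style: str = STYLE_SMOOTH

    def __post_init__(self) -> None:
        if self.state not in (STATIONARY, MOVING):
            raise ValidationError(f"unknown state {self.state!r}")
        if self.duration <= 0:
            raise ValidationError("step durations must be > 0")
        if self.style not in _STYLES:
            raise ValidationError(f"unknown style {self.style!r}")


@dataclass
class Scenario:
    """A scripted maneuver itinerary (alternating stationary/moving steps)."""

    name: str
    steps: list
    ramp_time: float = 1.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("a scenario needs at least one step")
        if self.ramp_time < 0:
            raise ValidationError("ramp_time must be >= 0")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.steps))

    def truth(self) -> IntervalTruth:
        starts, ends, states = [], [], []
        t = 0.0
        for s in self.steps:
            starts.append(t)
            t += s.duration
            ends.append(t)
            states.append(s.state)
        return IntervalTruth(start_s=np.array(starts), end_s=np.array(ends), state=states)


def _bump_waveform(t: np.ndarray, t0: float, magnitude: float) -> np.ndarray:
    """Damped 8 Hz oscillation over ~0.4 s — a jolt and its ring-down."""
    dt = t - t0
    active = (dt >= 0) & (dt < 0.4)
    w = np.zeros_like(t)
    w[active] = magnitude * np.exp(-dt[active] / 0.08) * np.cos(2 * np.pi * 8.0 * dt[active])
    return w


def _motion_plan(scenario: Scenario, rng: np.random.Generator) -> list[dict]:
    """Draw the physical (device-independent) randomness of one run: per
    moving step the vibration sinusoid's frequency, phase and direction, and
    per with-bump stationary step the jolt direction.  All devices riding
    the same run share this plan."""
    plan = []
    for step in scenario.steps:
        entry: dict = {}
        if step.state == MOVING:
            entry["freq"] = rng.uniform(1.5, 3.5)
            entry["phase"] = rng.uniform(0.0, 2 * np.pi)
            d = rng.normal(size=3)
            entry["direction"] = d / np.linalg.norm(d)
        elif step.style == STYLE_WITH_BUMP:
            d = rng.normal(size=3)
            entry["direction"] = d / np.linalg.norm(d)
        plan.append(entry)
    return plan


def _render(
    scenario: Scenario,
    plan: list[dict],
    profile: DeviceProfile,
    rng: np.random.Generator,
) -> RawRecording:
    """Sample the shared physical run through one device's sensor."""
    total = scenario.total_duration
    lo, hi = profile.rate_range
    nz = profile.noise

    # event-driven timestamps: gaps uniform in [1/max_hz, 1/min_hz]
    n_max = int(total * hi) + 2
    gaps = rng.uniform(1.0 / hi, 1.0 / lo, size=n_max)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t = t[t < total]
    n = len(t)

    orientation = np.asarray(profile.orientation, dtype=float)
    signal = np.tile(GRAVITY * orientation, (n, 1))
    signal += np.cumsum(rng.normal(0.0, nz.bias_walk_sd, size=(n, 3)), axis=0)
    signal += rng.normal(0.0, nz.stationary_noise_sd, size=(n, 3))

    t0 = 0.0
    for step, entry in zip(scenario.steps, plan):
        t1 = t0 + step.duration
        in_step = (t >= t0) & (t < t1)
        if step.state == MOVING:
            # ramped vibration envelope: the chair spins up and coasts down
            ramp = min(scenario.ramp_time, step.duration / 2)
            env = np.ones(n)
            if ramp > 0:
                env = np.clip(np.minimum(t - t0, t1 - t) / ramp, 0.0, 1.0)
            env[~in_step] = 0.0
            if step.style == STYLE_ROUGH_START:
                win = in_step & (t < t0 + min(3.0, step.duration / 2))
                env[win] *= (np.sin(2 * np.pi * (t[win] - t0) / 1.6) > 0).astype(float)
            elif step.style == STYLE_ROUGH_STOP:
                win = in_step & (t >= t1 - min(3.0, step.duration / 2))
                env[win] *= (np.sin(2 * np.pi * (t1 - t[win]) / 1.6) > 0).astype(float)
            elif step.style == STYLE_WITH_BUMP:
                # mid-bout near-stop: vibration collapses for ~1.5 s (a dip)
                mid = (t0 + t1) / 2
                env[in_step & (np.abs(t - mid) < 0.75)] *= 0.05
            white = rng.normal(0.0, nz.moving_vibration_sd, size=(n, 3))
            sine = nz.moving_vibration_sd * np.sin(
                2 * np.pi * entry["freq"] * t + entry["phase"]
            )
            signal += env[:, None] * (white + sine[:, None] * entry["direction"])
        else:
            if step.style == STYLE_WITH_BUMP:
                w = _bump_waveform(t, (t0 + t1) / 2, nz.bump_magnitude)
                signal += w[:, None] * entry["direction"]
            if nz.bump_rate > 0:
                n_bumps = rng.poisson(nz.bump_rate * step.duration / 60.0)
                for _ in range(n_bumps):
                    tb = rng.uniform(t0, t1)
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    signal += _bump_waveform(t, tb, nz.bump_magnitude)[:, None] * d
        t0 = t1

    signal *= profile.scale
    return RawRecording(
        t_us=np.round(t * 1e6).astype(np.int64),
        ax=signal[:, 0],
        ay=signal[:, 1],
        az=signal[:, 2],
        device_id=profile.name,
    )


def generate_recording(
    scenario: Scenario, profile: DeviceProfile, seed: int
) -> tuple[RawRecording, IntervalTruth]:
    """Simulate one recording of ``scenario`` as seen by ``profile``.

    Identical ``seed`` yields a bitwise-identical recording.  The returned
    truth intervals tile the scenario exactly.
    """
    ss = np.random.SeedSequence(seed)
    rng_motion, rng_dev = (np.random.default_rng(s) for s in ss.spawn(2))
    plan = _motion_plan(scenario, rng_motion)
    return _render(scenario, plan, profile, rng_dev), scenario.truth()


def generate_trial(
    scenario: Scenario, profiles: list[DeviceProfile], seed: int
) -> tuple[list[RawRecording], IntervalTruth]:
    """Simulate one physical run observed simultaneously by several devices.

    All devices share the run's physical randomness (vibration spectrum,
    jolt directions) but sample it on their own event-driven clocks with
    their own sensor noise — the tray-of-phones setting of a cross-device
    agreement experiment.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles) + 1)
    plan = _motion_plan(scenario, np.random.default_rng(children[0]))
    recs = [
        _render(scenario, plan, prof, np.random.default_rng(child))
        for prof, child in zip(profiles, children[1:])
    ]
    return recs, scenario.truth()


def jitter_scenario(scenario: Scenario, seed: int, frac: float = 0.15) -> Scenario:
    """A copy of ``scenario`` with every step duration scaled by an
    independent uniform factor in [1-frac, 1+frac] — trial-to-trial
    variation of an itinerary driven by a human."""
    rng = np.random.default_rng(seed)
    steps = [
        replace(s, duration=s.duration * rng.uniform(1.0 - frac, 1.0 + frac))
        for s in scenario.steps
    ]
    return replace(scenario, steps=steps)


# Bout durations for the itinerary-style presets.  series1 mimics a trial of
# ten 10-25 s bouts through a building wing; series2 two long 40-70 s bouts.
_SERIES1_BOUTS = [15.3, 16.3, 13.1, 17.7, 16.2, 10.5, 19.9, 15.1, 16.3, 17.4]
_SERIES1_GAPS = [7.0, 8.0, 6.0, 9.0, 7.0, 8.0, 6.0, 7.0, 9.0, 8.0]
_SERIES1_STYLES = [
    STYLE_SMOOTH, STYLE_ROUGH_START, STYLE_SMOOTH, STYLE_SMOOTH, STYLE_ROUGH_STOP,
    STYLE_SMOOTH, STYLE_SMOOTH, STYLE_ROUGH_START, STYLE_SMOOTH, STYLE_SMOOTH,
]


def preset_scenarios() -> list[Scenario]:
    """The scripted itineraries used throughout tests and benchmarks."""
    s1_steps = [ScenarioStep(STATIONARY, 8.0)]
    for dur, gap, style in zip(_SERIES1_BOUTS, _SERIES1_GAPS, _SERIES1_STYLES):
        s1_steps.append(ScenarioStep(MOVING, dur, style))
        s1_steps.append(ScenarioStep(STATIONARY, gap))
    s2_steps = [
        ScenarioStep(STATIONARY, 10.0),
        ScenarioStep(MOVING, 52.0),
        ScenarioStep(STATIONARY, 12.0),
        ScenarioStep(MOVING, 61.0),
        ScenarioStep(STATIONARY, 10.0),
    ]
    return [
        Scenario("series1", s1_steps),
        Scenario("series2", s2_steps),
        Scenario("spike", [
            ScenarioStep(STATIONARY, 25.0, STYLE_WITH_BUMP),
            ScenarioStep(MOVING, 15.0),
            ScenarioStep(STATIONARY, 15.0),
        ]),
        Scenario("dip", [
            ScenarioStep(STATIONARY, 10.0),
            ScenarioStep(MOVING, 40.0, STYLE_WITH_BUMP),
            ScenarioStep(STATIONARY, 10.0),
        ]),
        Scenario("rough_start", [
            ScenarioStep(STATIONARY, 12.0),
            ScenarioStep(MOVING, 20.0, STYLE_ROUGH_START),
            ScenarioStep(STATIONARY, 12.0),
        ]),
        Scenario("disturbed", [
            ScenarioStep(STATIONARY, 12.0, STYLE_WITH_BUMP),
            ScenarioStep(MOVING, 30.0, STYLE_WITH_BUMP),
            ScenarioStep(STATIONARY, 10.0),
            ScenarioStep(MOVING, 20.0, STYLE_ROUGH_START),
            ScenarioStep(STATIONARY, 12.0),
        ]),
    ]


def preset_scenario(name: str) -> Scenario:
    for sc in preset_scenarios():
        if sc.name == name:
            return sc
    raise ValidationError(
        f"unknown scenario {name!r}; known: {[s.name for s in preset_scenarios()]}"
    )


def device_catalog() -> list[DeviceProfile]:
    """Heterogeneous device profiles (sensitivity x0.5-x2, noise x0.5-x3,
    sampling ranges within 13-30 Hz, varied orientations)."""
    base = NoiseModel()
    s3 = np.sqrt(3)
    return [
        DeviceProfile("holder-phone", (13.0, 30.0), 1.0, base, (0.0, 0.0, 1.0)),
        DeviceProfile("tray-phone", (20.0, 30.0), 0.5, replace(base, stationary_noise_sd=0.06, moving_vibration_sd=0.90), (0.0, 1.0, 0.0)),
        DeviceProfile("wrist-watch", (13.0, 20.0), 2.0, replace(base, stationary_noise_sd=0.06, bias_walk_sd=0.01, moving_vibration_sd=0.50), (1 / s3, 1 / s3, 1 / s3)),
        DeviceProfile("quiet-phone", (15.0, 25.0), 1.5, replace(base, stationary_noise_sd=0.015, moving_vibration_sd=1.0), (0.0, -1.0, 0.0)),
        DeviceProfile("noisy-phone", (13.0, 30.0), 0.8, replace(base, stationary_noise_sd=0.045, bias_walk_sd=0.008, moving_vibration_sd=0.75), (1.0, 0.0, 0.0)),
    ]


def device_profile(name: str) -> DeviceProfile:
    for p in device_catalog():
        if p.name == name:
            return p
    raise ValidationError(
        f"unknown profile {name!r}; known: {[p.name for p in device_catalog()]}"
    )
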