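"""Synthetic two-class e-nose breath cohorts with known, configurable class structure.

The generator emulates the device's acquisition protocol: for each participant a
baseline phase (chamber flushed with ambient air) is recorded, then the breath
sample enters the chamber and each metal-oxide sensor's voltage rises toward a
plateau.  The response of sensor *s* for class *c* at time *t* after breath
injection is modelled as a saturating exponential with linear drift and i.i.d.
Gaussian read noise::

    v(t) = baseline_level + A(s, c) * (1 - exp(-t / tau)) + drift * t + N(0, sd^2)

Lung-cancer cohorts are planted with elevated response amplitudes ``A`` in a
configurable subset of sensors (default TGS2602 > TGS2620 > MQ2 > MQ135), giving
every downstream stage — ablation, attribution, classification — a known ground
truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical sensor-array order; all I/O and feature flattening follow it.
CANONICAL_SENSORS: tuple[str, ...] = (
    "TGS2600",
    "TGS2602",
    "TGS2620",
    "MQ2",
    "MQ3",
    "MQ4",
    "MQ5",
    "MQ6",
    "MQ7",
    "MQ9",
    "MQ135",
    "Alkane",
)

LABEL_HEALTHY = "healthy"
LABEL_CANCER = "cancer"
ORIGIN_REAL = "real"
ORIGIN_SYNTHETIC = "synthetic"

#: Default class-amplitude gaps (volts) for the planted discriminative sensors,
#: ordered TGS2602 > TGS2620 > MQ2 > MQ135.  Sized so a 46-sample cohort has
#: separability comparable to clinical breathprint studies: no single sensor
#: classifies alone, but the four jointly support cross-validated AUC near 0.95.
DEFAULT_EFFECT_GAPS: dict[str, float] = {
    "TGS2602": 0.095,
    "TGS2620": 0.092,
    "MQ2": 0.089,
    "MQ135": 0.086,
}


class CohortValidationError(ValueError):
    """A cohort or sensor configuration violates its invariants."""


@dataclass(frozen=True)
class SensorSpec:
    """Physical response model of one gas sensor.

    Parameters
    ----------
    name : str
        Sensor model name; must be unique within an array.
    baseline_level : float
        Resting output in volts with clean air in the chamber.
    response_amplitude_healthy, response_amplitude_cancer : float
        Plateau rise (volts) above baseline for each class.
    rise_time_constant : float
        Exponential rise time constant in seconds; must be positive.
    noise_sd : float
        Standard deviation of additive Gaussian read noise, volts.
    drift_slope : float
        Slow linear drift, volts per second.
    """

    name: str
    baseline_level: float
    response_amplitude_healthy: float
    response_amplitude_cancer: float
    rise_time_constant: float
    noise_sd: float
    drift_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise CohortValidationError(f"{self.name}: noise_sd must be >= 0")
        if self.rise_time_constant <= 0:
            raise CohortValidationError(f"{self.name}: rise_time_constant must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and acquisition grid.

    Defaults reproduce the study design: 28 healthy controls, 18 lung-cancer
    participants, 29 response points per sensor sampled at ~0.97 Hz after a
    29-point baseline phase.
    """

    n_healthy: int = 28
    n_cancer: int = 18
    sampling_rate: float = 0.97
    n_response_points: int = 29
    n_baseline_points: int = 29
    seed: int = 0
    #: Optional shared-noise fraction across sensors (cross-sensitivity); 0 = off.
    cross_correlation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_cancer", "n_response_points", "n_baseline_points"):
            if getattr(self, name) < 1:
                raise CohortValidationError(f"{name} must be >= 1")
        if self.sampling_rate <= 0:
            raise CohortValidationError("sampling_rate must be > 0")
        if not 0.0 <= self.cross_correlation < 1.0:
            raise CohortValidationError("cross_correlation must be in [0, 1)")


@dataclass
class BreathSample:
    """One participant's sensor-array recording.

    ``baseline`` and ``response`` are (n_sensors, n_points) voltage matrices in
    canonical sensor order; ``time_grid`` holds the response-phase time stamps
    in seconds, strictly increasing with spacing 1 / sampling_rate.
    """

    sample_id: str
    label: str
    origin: str
    sensor_names: tuple[str, ...]
    baseline: np.ndarray
    response: np.ndarray
    time_grid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        n_sensors = len(self.sensor_names)
        if len(set(self.sensor_names)) != n_sensors:
            raise CohortValidationError("sensor names must be unique")
        if self.baseline.shape[0] != n_sensors or self.response.shape[0] != n_sensors:
            raise CohortValidationError(
                "matrix row count must equal the sensor-array size"
            )
        if self.response.shape[1] != self.time_grid.shape[0]:
            raise CohortValidationError("time_grid length must match response columns")
        if self.time_grid.size > 1 and not np.all(np.diff(self.time_grid) > 0):
            raise CohortValidationError("time_grid must be strictly increasing")
        if self.label not in (LABEL_HEALTHY, LABEL_CANCER):
            raise CohortValidationError(f"unknown label {self.label!r}")
        if self.origin not in (ORIGIN_REAL, ORIGIN_SYNTHETIC):
            raise CohortValidationError(f"unknown origin {self.origin!r}")


def response_points(duration_s: float = 30.0, sampling_rate: float = 0.97) -> int:
    """Number of samples per sensor for a phase of ``duration_s`` at ``sampling_rate``.

    30 s at 0.97 Hz yields floor(30 * 0.97) = 29 points.
    """
    return math.floor(duration_s * sampling_rate)


def time_grid(n_points: int, sampling_rate: float) -> np.ndarray:
    """Time stamps t_k = (k + 1) / rate, k = 0..n_points-1, seconds after phase start."""
    return (np.arange(n_points) + 1.0) / sampling_rate


def default_sensor_array(
    effect_gaps: dict[str, float] | None = None,
    noise_sd: float = 0.18,
) -> list[SensorSpec]:
    """The 12-sensor array with default baselines, amplitudes and planted effects.

    Baseline levels and healthy amplitudes vary across sensors (different target
    VOCs respond with different gains); the class gap is zero except for the
    sensors in ``effect_gaps`` (default :data:`DEFAULT_EFFECT_GAPS`).
    """
    if effect_gaps is None:
        effect_gaps = DEFAULT_EFFECT_GAPS
    unknown = set(effect_gaps) - set(CANONICAL_SENSORS)
    if unknown:
        raise CohortValidationError(f"unknown sensors in effect_gaps: {sorted(unknown)}")
    baselines = [1.10, 1.45, 1.30, 0.95, 1.05, 0.90, 1.00, 0.85, 1.20, 1.15, 1.35, 0.80]
    amps = [0.55, 0.70, 0.62, 0.48, 0.52, 0.40, 0.45, 0.38, 0.50, 0.42, 0.60, 0.35]
    taus = [5.0, 4.2, 4.8, 6.0, 5.5, 6.5, 5.8, 6.2, 5.2, 6.8, 4.5, 7.0]
    specs = []
    for i, name in enumerate(CANONICAL_SENSORS):
        gap = effect_gaps.get(name, 0.0)
        specs.append(
            SensorSpec(
                name=name,
                baseline_level=baselines[i],
                response_amplitude_healthy=amps[i],
                response_amplitude_cancer=amps[i] + gap,
                rise_time_constant=taus[i],
                noise_sd=noise_sd,
                drift_slope=5e-4,
            )
        )
    return specs


def null_sensor_array(noise_sd: float = 0.18) -> list[SensorSpec]:
    """Sensor array with no class signal (equal amplitudes): a null cohort."""
    return default_sensor_array(effect_gaps={}, noise_sd=noise_sd)


def swap_class_amplitudes(specs: list[SensorSpec]) -> list[SensorSpec]:
    """Exchange the healthy and cancer amplitude profiles (class-exchangeability)."""
    return [
        replace(
            s,
            response_amplitude_healthy=s.response_amplitude_cancer,
            response_amplitude_cancer=s.response_amplitude_healthy,
        )
        for s in specs
    ]


def _simulate_noise(
    rng: np.random.Generator, shape: tuple[int, int], sds: np.ndarray, rho: float
) -> np.ndarray:
    """Per-sensor Gaussian noise, optionally sharing a common component across sensors."""
    eps = rng.standard_normal(shape)
    if rho > 0:
        shared = rng.standard_normal((1, shape[1]))
        eps = math.sqrt(1.0 - rho) * eps + math.sqrt(rho) * shared
    return eps * sds[:, None]


def generate_cohort(
    config: CohortConfig, specs: list[SensorSpec] | None = None
) -> list[BreathSample]:
    """Simulate a labelled cohort of breath recordings.

    Returns ``n_healthy + n_cancer`` samples (healthy first).  Identical
    ``config`` (including seed) and ``specs`` produce a byte-identical cohort.
    """
    if specs is None:
        specs = default_sensor_array()
    if not specs:
        raise CohortValidationError("specs must be non-empty")
    names = tuple(s.name for s in specs)
    if len(set(names)) != len(names):
        raise CohortValidationError("sensor names must be unique")

    rng = np.random.default_rng(config.seed)
    t_resp = time_grid(config.n_response_points, config.sampling_rate)
    base_levels = np.array([s.baseline_level for s in specs])
    sds = np.array([s.noise_sd for s in specs])
    taus = np.array([s.rise_time_constant for s in specs])
    drifts = np.array([s.drift_slope for s in specs])
    amp_h = np.array([s.response_amplitude_healthy for s in specs])
    amp_c = np.array([s.response_amplitude_cancer for s in specs])

    rise = 1.0 - np.exp(-t_resp[None, :] / taus[:, None])  # (n_sensors, n_resp)

    samples: list[BreathSample] = []
    plan = [(LABEL_HEALTHY, "H", config.n_healthy, amp_h), (LABEL_CANCER, "LC", config.n_cancer, amp_c)]
    for label, prefix, count, amps in plan:
        for i in range(count):
            baseline = base_levels[:, None] + _simulate_noise(
                rng, (len(specs), config.n_baseline_points), sds, config.cross_correlation
            )
            clean = (
                base_levels[:, None]
                + amps[:, None] * rise
                + drifts[:, None] * t_resp[None, :]
            )
            response = clean + _simulate_noise(
                rng, (len(specs), config.n_response_points), sds, config.cross_correlation
            )
            samples.append(
                BreathSample(
                    sample_id=f"{prefix}{i + 1:03d}",
                    label=label,
                    origin=ORIGIN_REAL,
                    sensor_names=names,
                    baseline=baseline,
                    response=response,
                    time_grid=t_resp.copy(),
                )
            )
    return samples
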