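"""Generative model of two-channel closed-tube barcoding melt curves.

A run of the assay records fluorescence while temperature ramps from 40 to
87 degC; hybridized probe-target duplexes dissociate in sigmoidal transitions,
so a raw curve is modelled as a decreasing-logistic mixture plus a linear
baseline.  Two optical channels report the two COI mini-barcode segments
(BS1, which always carries the internal ThermaMark temperature marker as its
rightmost transition, and BS2).  The derivative of such a curve shows one
trough per duplex transition — the "fluorescent signature" that identifies
a species.

The noise model captures the dominant artefacts of real runs:

* a global log-normal amplitude scale (template degradation changes peak
  heights and valley depths, not positions),
* a single rigid temperature offset per run (instrument calibration drift,
  later removed using the marker trough),
* per-component amplitude jitter (probe-binding variability),
* additive instrument noise, applied before the global scale so that
  signal-to-noise is independent of template quality.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MARKER_TM",
    "MARKER_COMPONENT",
    "AcquisitionGrid",
    "MeltComponent",
    "SegmentModel",
    "SpeciesSignatureModel",
    "NoiseModel",
    "RawMeltCurve",
    "RunRecord",
    "simulate_curve",
    "simulate_run",
]

#: Temperature (degC) of the internal marker trough in BS1.  Fixed above every
#: species transition so "rightmost trough" is unambiguous.
MARKER_TM = 84.0


@dataclass(frozen=True)
class AcquisitionGrid:
    """Evenly spaced temperature grid of one melt acquisition (per segment)."""

    t_min: float = 40.0
    t_max: float = 87.0
    n_points: int = 4076

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be below t_max")
        if self.n_points < 16:
            raise ValueError("grid needs at least 16 points")

    @property
    def temperatures(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.n_points)

    @property
    def step(self) -> float:
        return (self.t_max - self.t_min) / (self.n_points - 1)


@dataclass(frozen=True)
class MeltComponent:
    """One probe-target duplex dissociation transition."""

    tm: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tm) and np.isfinite(self.width) and np.isfinite(self.amplitude)):
            raise ValueError("melt component parameters must be finite")
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")


#: The ThermaMark transition present in every BS1 segment model.
MARKER_COMPONENT = MeltComponent(tm=MARKER_TM, width=0.4, amplitude=0.6)


@dataclass
class SegmentModel:
    """Mixture model of one barcode segment's melt curve."""

    components: list[MeltComponent] = field(default_factory=list)
    includes_tm_marker: bool = False
    baseline_slope: float = 0.0
    baseline_offset: float = 0.2

    def all_components(self) -> list[MeltComponent]:
        comps = list(self.components)
        if self.includes_tm_marker:
            comps.append(MARKER_COMPONENT)
        return comps


@dataclass
class SpeciesSignatureModel:
    """Per-species generative parameters for both barcode segments."""

    species_name: str
    english_name: str
    cites_listed: bool
    group: str  # "shark" | "ray"
    bs1: SegmentModel
    bs2: SegmentModel
    bs1_failure_prob: float = 0.0
    bs2_failure_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.bs1_failure_prob, self.bs2_failure_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("failure probabilities must lie in [0, 1]")
        if not self.bs1.includes_tm_marker:
            raise ValueError("BS1 segment models must include the TM marker")


@dataclass(frozen=True)
class NoiseModel:
    amplitude_scale_sigma: float = 0.10
    temperature_offset_sigma: float = 0.30
    additive_noise_sigma: float = 0.002
    per_component_jitter: float = 0.05
    #: multiplier on amplitude_scale_sigma for degraded ("processed") samples
    degradation_factor: float = 3.5

    def __post_init__(self) -> None:
        for s in (self.amplitude_scale_sigma, self.temperature_offset_sigma,
                  self.additive_noise_sigma, self.per_component_jitter):
            if s < 0:
                raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)

    def degraded(self) -> "NoiseModel":
        return replace(self, amplitude_scale_sigma=self.amplitude_scale_sigma * self.degradation_factor)


@dataclass
class RawMeltCurve:
    temperatures: np.ndarray
    fluorescence: np.ndarray
    channel: str  # "BS1" | "BS2"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence vectors differ in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class RunRecord:
    """One qPCR run: a BS1/BS2 curve pair plus specimen metadata.

    ``injected_failure`` is simulator ground truth ("none",
    "hybridization_bs1", "hybridization_bs2" or "inconsistent"); it is never
    consulted by the analysis side of the pipeline.
    """

    run_id: str
    specimen_id: str
    species_name: str | None
    replicate: int
    sample_condition: str  # "fresh" | "processed"
    bs1_curve: RawMeltCurve
    bs2_curve: RawMeltCurve
    injected_failure: str = "none"


def _mixture(components: list[MeltComponent], temps: np.ndarray,
             baseline_offset: float, baseline_slope: float) -> np.ndarray:
    f = baseline_offset + baseline_slope * (temps - temps[0])
    for c in components:
        f = f + c.amplitude / (1.0 + np.exp(-(c.tm - temps) / c.width))
    return f


def simulate_curve(segment: SegmentModel, grid: AcquisitionGrid, noise: NoiseModel,
                   seed: int | np.random.Generator,
                   channel: str = "BS1",
                   temperature_offset: float | None = None,
                   amplitude_scale: float | None = None) -> RawMeltCurve:
    """Simulate one raw melt curve.

    With all noise sigmas zero the output is exactly the closed-form logistic
    mixture.  ``temperature_offset`` / ``amplitude_scale`` override the random
    draws so that the two channels of one run can share them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comps = segment.all_components()
    if noise.per_component_jitter > 0 and comps:
        jit = rng.normal(0.0, noise.per_component_jitter, size=len(comps))
        comps = [replace(c, amplitude=c.amplitude * max(1.0 + j, 0.05))
                 for c, j in zip(comps, jit)]
    if temperature_offset is None:
        temperature_offset = rng.normal(0.0, noise.temperature_offset_sigma) \
            if noise.temperature_offset_sigma > 0 else 0.0
    if amplitude_scale is None:
        amplitude_scale = float(np.exp(rng.normal(0.0, noise.amplitude_scale_sigma))) \
            if noise.amplitude_scale_sigma > 0 else 1.0

    temps = grid.temperatures
    # an instrument reading T degC while the sample sits at T - offset shifts
    # every transition trough to tm + offset
    f = _mixture(comps, temps - temperature_offset,
                 segment.baseline_offset, segment.baseline_slope)
    if noise.additive_noise_sigma > 0:
        f = f + rng.normal(0.0, noise.additive_noise_sigma, size=f.shape)
    f = f * amplitude_scale
    return RawMeltCurve(temperatures=temps, fluorescence=f, channel=channel)


def _perturbed(segment: SegmentModel, rng: np.random.Generator,
               grid: AcquisitionGrid) -> SegmentModel:
    """Shift every species transition by a few degC (an 'inconsistent' run)."""
    comps = []
    for c in segment.components:
        shift = rng.uniform(2.5, 4.5) * rng.choice([-1.0, 1.0])
        tm = float(np.clip(c.tm + shift, grid.t_min + 4.0, MARKER_TM - 4.0))
        comps.append(replace(c, tm=tm))
    return replace_segment(segment, comps)


def replace_segment(segment: SegmentModel, components: list[MeltComponent]) -> SegmentModel:
    new = copy.copy(segment)
    new.components = components
    return new


def simulate_run(model: SpeciesSignatureModel, *, run_id: str, specimen_id: str,
                 replicate: int, sample_condition: str,
                 grid: AcquisitionGrid, noise: NoiseModel,
                 seed: int | np.random.Generator,
                 pinned_failure: str | None = None) -> RunRecord:
    """Simulate the BS1/BS2 curve pair of one run.

    Failure modes are drawn from the species' hybridization-failure
    probabilities unless ``pinned_failure`` fixes one ("none" pins a clean
    run).  A failed BS1 retains only the marker transition; a failed BS2 is
    baseline plus noise.  Both channels share the run's temperature offset
    and amplitude scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    run_noise = noise.degraded() if sample_condition == "processed" else noise

    if pinned_failure is None:
        failure = "none"
        if rng.random() < model.bs1_failure_prob:
            failure = "hybridization_bs1"
        elif rng.random() < model.bs2_failure_prob:
            failure = "hybridization_bs2"
    else:
        failure = pinned_failure

    bs1_model, bs2_model = model.bs1, model.bs2
    if failure == "hybridization_bs1":
        bs1_model = replace_segment(bs1_model, [])  # marker only
    elif failure == "hybridization_bs2":
        bs2_model = replace_segment(bs2_model, [])
    elif failure == "inconsistent":
        bs1_model = _perturbed(bs1_model, rng, grid)
        bs2_model = _perturbed(bs2_model, rng, grid)

    offset = rng.normal(0.0, run_noise.temperature_offset_sigma) \
        if run_noise.temperature_offset_sigma > 0 else 0.0
    scale = float(np.exp(rng.normal(0.0, run_noise.amplitude_scale_sigma))) \
        if run_noise.amplitude_scale_sigma > 0 else 1.0

    bs1 = simulate_curve(bs1_model, grid, run_noise, rng, channel="BS1",
                         temperature_offset=offset, amplitude_scale=scale)
    bs2 = simulate_curve(bs2_model, grid, run_noise, rng, channel="BS2",
                         temperature_offset=offset, amplitude_scale=scale)
    return RunRecord(run_id=run_id, specimen_id=specimen_id,
                     species_name=model.species_name, replicate=replicate,
                     sample_condition=sample_condition,
                     bs1_curve=bs1, bs2_curve=bs2, injected_failure=failure)
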