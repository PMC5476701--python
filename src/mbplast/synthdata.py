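"""Synthetic GCaMP cohort generator.

Emulates per-compartment ROI fluorescence recordings of DANs and KCs
during the paired/unpaired trace-conditioning protocols: odorant and
4-pulse shock responses shaped by a difference-of-exponentials calcium
kernel, a logarithmic shock-response current dependence, per-trial
sensor bleaching, CS-concentration run-down, and injectable associative
plasticity (a multiplicative CS-response gain in DANs from the trial
after the first pairing; a multiplicative CS-response depression in
β'-lobe/junction KCs from the trial after the second pairing). Every
fly carries its generating parameters (``truth``) so downstream
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .compartments import GENOTYPES, compartments_for
from .protocol import (
    RECORDING_DURATION,
    SAMPLING_RATE,
    StimulationProtocol,
    StimulusEvent,
    StimulusKind,
    TRAINING_TRIALS,
)

HEMISPHERES = ("left", "right")

#: Compartments with injected associative plasticity. DANs strengthen
#: their CS response in the γ- and β'-lobe compartments and the
#: junction; KCs depress theirs in the β'-lobe and junction.
DAN_PLASTICITY_COMPARTMENTS = ("γ1", "γ2", "γ3", "γ4", "γ5", "β'1", "β'2", "junction")
KC_DEPRESSION_COMPARTMENTS = ("β'1", "β'2", "junction")

#: Plasticity becomes visible one trial after the first pairing in DANs
#: (trial 5) and one trial after the second pairing in KCs (trial 6).
DAN_GAIN_ONSET_TRIAL = 5
KC_DEPRESSION_ONSET_TRIAL = 6

# Per-compartment peak BUT (CS) odorant response amplitudes, ΔF/F.
# DAN odorant responses are strongest in the γ-lobe; KCs respond
# broadly to odorants with stronger solvent responses than DANs.
_DAN_BUT = {
    "α1/α'1": 0.30, "β2": 0.50, "β'1": 0.60, "β'2": 0.90,
    "γ1": 0.50, "γ2": 1.00, "γ3": 0.90, "γ4": 0.70, "γ5": 0.80,
    "junction": 0.60, "EB": 0.20, "FB": 0.20,
}
_KC_BUT = {
    "α1/α'1": 0.60, "β2": 0.80, "β'1": 0.70, "β'2": 0.90,
    "γ1": 0.50, "γ2": 1.20, "γ3": 1.10, "γ4": 0.80, "γ5": 0.70,
    "junction": 0.70, "IPCs": 0.20,
}
# Relative amplitude of the other odorants: responses are strongest to
# BUT, weaker to MCH and weakest to the solvent MO (relatively stronger
# in KCs).
_MCH_FACTOR = {"DAN": 0.60, "KC": 0.65}
_MO_FACTOR = {"DAN": 0.12, "KC": 0.25}

# Shock-response current dependence: ΔF/F = a*log10(I/nA) + b, floored
# at 0. Slopes span the 0.024 (α1/α'1) to 0.715 (γ1) ΔF/F-per-decade
# range seen in DANs; KC shock responses are much weaker. The
# intercepts are set so the response at the typical current
# (10^2.5 ≈ 316 nA) equals the target amplitude below.
_DAN_SLOPE = {
    "α1/α'1": 0.024, "β2": 0.30, "β'1": 0.25, "β'2": 0.45,
    "γ1": 0.715, "γ2": 0.60, "γ3": 0.35, "γ4": 0.30, "γ5": 0.40,
    "junction": 0.30, "EB": 0.05, "FB": 0.05,
}
_DAN_SHOCK_AT_TYPICAL = {
    "α1/α'1": 0.25, "β2": 0.50, "β'1": 0.45, "β'2": 0.80,
    "γ1": 1.30, "γ2": 1.10, "γ3": 0.60, "γ4": 0.50, "γ5": 0.70,
    "junction": 0.50, "EB": 0.15, "FB": 0.15,
}
_KC_SLOPE = {
    "α1/α'1": 0.02, "β2": 0.03, "β'1": 0.08, "β'2": 0.10,
    "γ1": 0.03, "γ2": 0.03, "γ3": 0.06, "γ4": 0.03, "γ5": 0.03,
    "junction": 0.05, "IPCs": 0.02,
}
_KC_SHOCK_AT_TYPICAL = {
    "α1/α'1": 0.08, "β2": 0.10, "β'1": 0.18, "β'2": 0.25,
    "γ1": 0.10, "γ2": 0.12, "γ3": 0.15, "γ4": 0.10, "γ5": 0.10,
    "junction": 0.12, "IPCs": 0.05,
}

_TYPICAL_LOG_CURRENT = 2.5  # log10(nA)


def _default_odor_amplitudes() -> dict[tuple[str, str, str], float]:
    amps: dict[tuple[str, str, str], float] = {}
    for genotype, table in (("DAN", _DAN_BUT), ("KC", _KC_BUT)):
        for comp, but in table.items():
            amps[(genotype, comp, "BUT")] = but
            amps[(genotype, comp, "MCH")] = but * _MCH_FACTOR[genotype]
            amps[(genotype, comp, "MO")] = but * _MO_FACTOR[genotype]
    return amps


def _default_shock_params() -> dict[tuple[str, str], tuple[float, float]]:
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for genotype, slopes, targets in (
        ("DAN", _DAN_SLOPE, _DAN_SHOCK_AT_TYPICAL),
        ("KC", _KC_SLOPE, _KC_SHOCK_AT_TYPICAL),
    ):
        for comp, slope in slopes.items():
            intercept = targets[comp] - slope * _TYPICAL_LOG_CURRENT
            params[(genotype, comp)] = (slope, intercept)
    return params


@dataclass
class SyntheticConfig:
    """Free parameters of the generator.

    Amplitudes are peak ΔF/F of the stimulus-evoked waveform; rates are
    fractions per trial (or per CS presentation for ``rundown_rate``);
    currents are log10(nA). The plasticity gain/depression apply only
    to paired-group flies, from their onset trials onward, in the
    compartment sets above.
    """

    kernel_rise: float = 0.4       # s, GCaMP fluorescence rise time constant
    kernel_decay: float = 1.5      # s, decay time constant; fast enough
    # that the CS response is near baseline at shock onset (the 5 s
    # stimulus-free gap of the trace-conditioning design)
    odor_amplitudes: Mapping[tuple[str, str, str], float] = field(
        default_factory=_default_odor_amplitudes)
    shock_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_shock_params)
    dan_gain: float = 1.5          # paired DAN CS-response gain from trial 5
    kc_depression: float = 0.7     # paired KC CS-response factor from trial 6
    bleach_rate: float = 0.02      # fractional baseline loss per trial
    rundown_rate: float = 0.03     # fractional CS-amplitude loss per CS exposure
    noise_sd: float = 0.05         # ΔF/F units, white per frame
    current_log_mean: float = 2.5  # log10(nA)
    current_log_sd: float = 0.3
    baseline_F: float = 100.0      # arbitrary fluorescence units
    fly_amplitude_cv: float = 0.2  # lognormal between-fly response scaling
    gamma1_dropout: float = 0.3    # per-hemisphere probability γ1 is missing
    hemisphere_right_shift: float = 0.0  # additive amp offset, right side
    genotypes: tuple[str, ...] = GENOTYPES
    compartments: tuple[str, ...] | None = None  # None = all for genotype
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dan_gain <= 0:
            raise ValueError("dan_gain must be > 0")
        if not 0 < self.kc_depression <= 1:
            raise ValueError("kc_depression must lie in (0, 1]")
        if self.kernel_decay <= self.kernel_rise:
            raise ValueError("kernel_decay must exceed kernel_rise")
        for name in ("bleach_rate", "rundown_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")

    def compartments_for(self, genotype: str) -> tuple[str, ...]:
        full = compartments_for(genotype)
        if self.compartments is None:
            return full
        return tuple(c for c in full if c in self.compartments)


@dataclass
class FlyRecording:
    """Raw per-compartment traces plus metadata for one fly.

    ``traces`` maps (hemisphere, compartment, trial) to a 225-sample
    raw-fluorescence array (45 s at 5 Hz); ``shock_currents`` maps
    trial index to the current (nA) of that trial's shock train.
    """

    fly_id: str
    genotype: str
    group: str
    hemispheres: dict[str, tuple[str, ...]]
    traces: dict[tuple[str, str, int], np.ndarray]
    shock_currents: dict[int, float]
    truth: dict = field(default_factory=dict)


def response_kernel(t, rise: float, decay: float):
    """Peak-normalized difference-of-exponentials calcium kernel.

    ``exp(-t/decay) - exp(-t/rise)``, zero for t < 0, rescaled so its
    maximum over t >= 0 equals 1.
    """
    if rise <= 0:
        raise ValueError("rise must be > 0")
    if decay <= rise:
        raise ValueError("decay must exceed rise")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    # analytic peak location of the difference of exponentials
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return out / peak


def shock_amplitude(current: float, slope: float, intercept: float) -> float:
    """ΔF/F shock-response amplitude: slope*log10(I/nA)+intercept, >= 0."""
    if current <= 0:
        raise ValueError("current must be > 0")
    return max(0.0, slope * np.log10(current) + intercept)


def current_from_voltage(u_def: float, r_def: float, r_meter: float) -> float:
    """Current through the fly from the voltage over the defined resistor.

    The oscilloscope (input resistance ``r_meter``) is connected across
    the defined resistor ``r_def``, so the fly current equals the
    measured voltage divided by their parallel combination.
    """
    if r_def <= 0 or r_meter <= 0:
        raise ValueError("resistances must be > 0")
    r_parallel = r_def * r_meter / (r_def + r_meter)
    return u_def / r_parallel


def _unit_waveform(event: StimulusEvent, trial_onset: float,
                   n_frames: int, fs: float, rise: float, decay: float):
    """Evoked unit waveform: stimulus indicator convolved with the
    calcium kernel, peak-normalized so the event amplitude is the peak
    ΔF/F."""
    dt = 1.0 / fs
    t = np.arange(n_frames) * dt
    ind = np.zeros(n_frames)
    for start, end in event.pulse_windows():
        rel0, rel1 = start - trial_onset, end - trial_onset
        ind[(t >= rel0) & (t < rel1)] = 1.0
    k = response_kernel(np.arange(n_frames) * dt, rise, decay)
    wave = np.convolve(ind, k)[:n_frames] * dt
    peak = wave.max()
    if peak <= 0:
        return wave
    return wave / peak


def cs_exposure_count(trial_index: int) -> int:
    """Number of CS (BUT) presentations before the given trial.

    BUT is presented in trial 2, each training trial 4-9, and trials 10
    and 13; concentration run-down accrues with every presentation,
    recorded or not.
    """
    cs_trials = (2,) + TRAINING_TRIALS + (10, 13)
    return sum(1 for t in cs_trials if t < trial_index)


def generate_cohort(
    protocol_pair: tuple[StimulationProtocol, StimulationProtocol],
    config: SyntheticConfig,
    n_flies_per_cell: int,
) -> list[FlyRecording]:
    """Generate a cohort: ``n_flies_per_cell`` flies per genotype x group.

    Each recorded trial's trace is
    ``baseline_F * (1-bleach)^(trial-1) * (1 + sum of evoked responses)``
    plus Gaussian noise of standard deviation ``baseline * noise_sd``
    (so the noise is ``noise_sd`` in ΔF/F units). Fully reproducible
    for a fixed config seed.
    """
    if n_flies_per_cell < 1:
        raise ValueError("n_flies_per_cell must be >= 1")
    by_group = {p.group: p for p in protocol_pair}
    if set(by_group) != {"paired", "unpaired"}:
        raise ValueError("protocol_pair must contain one paired and one "
                         "unpaired protocol")

    rng = np.random.default_rng(config.seed)
    fs = SAMPLING_RATE
    n_frames = int(round(RECORDING_DURATION * fs))

    # unit waveforms are shared across flies and compartments
    wave_cache: dict[tuple[str, int, int], np.ndarray] = {}
    for group, proto in by_group.items():
        for trial in proto.trials:
            for j, ev in enumerate(trial.recorded_events()):
                wave_cache[(group, trial.index, j)] = _unit_waveform(
                    ev, trial.onset, n_frames, fs,
                    config.kernel_rise, config.kernel_decay)

    odor_key = {StimulusKind.SOLVENT_MO: "MO", StimulusKind.CS_BUT: "BUT",
                StimulusKind.CONTROL_MCH: "MCH"}

    flies: list[FlyRecording] = []
    for genotype in config.genotypes:
        comps = config.compartments_for(genotype)
        for group, proto in sorted(by_group.items()):
            for i in range(n_flies_per_cell):
                fly_id = f"{genotype}_{group}_{i:03d}"
                fly_scale = (
                    float(rng.lognormal(0.0, config.fly_amplitude_cv))
                    if config.fly_amplitude_cv > 0 else 1.0)
                hemis: dict[str, tuple[str, ...]] = {}
                for side in HEMISPHERES:
                    avail = list(comps)
                    if ("γ1" in avail
                            and rng.random() < config.gamma1_dropout):
                        avail.remove("γ1")
                    hemis[side] = tuple(avail)

                currents = {
                    t.index: float(10 ** rng.normal(config.current_log_mean,
                                                    config.current_log_sd))
                    for t in proto.trials
                    if any(ev.kind is StimulusKind.SHOCK_US for ev in t.events)
                }

                traces: dict[tuple[str, str, int], np.ndarray] = {}
                for trial in proto.trials:
                    bleach = (1.0 - config.bleach_rate) ** (trial.index - 1)
                    base = config.baseline_F * bleach
                    events = trial.recorded_events()
                    for side in HEMISPHERES:
                        for comp in hemis[side]:
                            r = np.zeros(n_frames)
                            for j, ev in enumerate(events):
                                amp = _event_amplitude(
                                    ev, trial.index, genotype, group, comp,
                                    config, currents)
                                if side == "right":
                                    amp += config.hemisphere_right_shift
                                if amp != 0.0:
                                    r += (fly_scale * amp
                                          * wave_cache[(group, trial.index, j)])
                            trace = base * (1.0 + r)
                            if config.noise_sd > 0:
                                trace = trace + base * config.noise_sd \
                                    * rng.standard_normal(n_frames)
                            traces[(side, comp, trial.index)] = trace

                flies.append(FlyRecording(
                    fly_id=fly_id, genotype=genotype, group=group,
                    hemispheres=hemis, traces=traces,
                    shock_currents=currents,
                    truth={"fly_scale": fly_scale,
                           "seed": config.seed,
                           "dan_gain": config.dan_gain,
                           "kc_depression": config.kc_depression},
                ))
    return flies


def _event_amplitude(event: StimulusEvent, trial_index: int, genotype: str,
                     group: str, comp: str, config: SyntheticConfig,
                     currents: dict[int, float]) -> float:
    if event.kind is StimulusKind.SHOCK_US:
        slope, intercept = config.shock_params.get((genotype, comp), (0.0, 0.0))
        return shock_amplitude(currents[trial_index], slope, intercept)
    odor = {StimulusKind.SOLVENT_MO: "MO", StimulusKind.CS_BUT: "BUT",
            StimulusKind.CONTROL_MCH: "MCH"}[event.kind]
    amp = config.odor_amplitudes.get((genotype, comp, odor), 0.0)
    if event.kind is StimulusKind.CS_BUT:
        amp *= (1.0 - config.rundown_rate) ** cs_exposure_count(trial_index)
        if group == "paired":
            if (genotype == "DAN" and comp in DAN_PLASTICITY_COMPARTMENTS
                    and trial_index >= DAN_GAIN_ONSET_TRIAL):
                amp *= config.dan_gain
            if (genotype == "KC" and comp in KC_DEPRESSION_COMPARTMENTS
                    and trial_index >= KC_DEPRESSION_ONSET_TRIAL):
                amp *= config.kc_depression
    return amp
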