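"""Trace-conditioning stimulation protocols.

A protocol is a fixed 13-trial schedule with a 210 s inter-trial
interval. Trials 1-3 present single odorant pulses (solvent MO, the CS
odorant 1-butanol, the control odorant MCH), trials 4-9 are training
trials combining one 10 s CS pulse with a train of four 1.5 s, 90 V
electric-shock pulses (US), and trials 10-13 present CS, MCH, US and a
final run-down-check CS. The paired and unpaired groups differ only in
the CS-US onset interval within training trials: 15 s (paired, trace
conditioning with a 5 s stimulus-free gap) versus 90 s (unpaired, with
pseudorandomized, balanced CS/US order). Imaging covers only the first
45 s of each trial, so in the unpaired group only the first stimulus of
each training trial is recorded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import yaml

# Fixed schedule constants (seconds unless noted).
N_TRIALS = 13
INTER_TRIAL_INTERVAL = 210.0
RECORDING_DURATION = 45.0
SAMPLING_RATE = 5.0  # Hz
ODOR_PULSE_DURATION = 10.0
SHOCK_N_PULSES = 4
SHOCK_PULSE_DURATION = 1.5
SHOCK_VOLTAGE = 90.0
CS_US_INTERVAL_PAIRED = 15.0
CS_US_INTERVAL_UNPAIRED = 90.0
TRAINING_TRIALS = tuple(range(4, 10))

#: Within-trial onset of the first stimulus. Chosen so the baseline
#: window (frames 3-24 at 5 Hz, i.e. 0.4-4.8 s) precedes stimulus onset.
DEFAULT_FIRST_ONSET = 5.0
#: Inter-pulse gap of the 4-pulse shock train (configurable; the train
#: then spans 10.5 s and fits the recording window).
DEFAULT_SHOCK_GAP = 1.5

GROUPS = ("paired", "unpaired")


class StimulusKind(str, enum.Enum):
    """Stimulus categories used throughout the analysis."""

    SOLVENT_MO = "MO"
    CS_BUT = "CS"
    CONTROL_MCH = "MCH"
    SHOCK_US = "US"


ODORANT_KINDS = (StimulusKind.SOLVENT_MO, StimulusKind.CS_BUT, StimulusKind.CONTROL_MCH)

#: Odorant dilutions in mineral oil (fraction); MO is the pure solvent.
ODORANT_DILUTION = {
    StimulusKind.SOLVENT_MO: 1.0,
    StimulusKind.CS_BUT: 1.0 / 500.0,
    StimulusKind.CONTROL_MCH: 1.0 / 1000.0,
}


class ProtocolError(ValueError):
    """Raised when a protocol or one of its parts violates an invariant."""


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation.

    ``onset`` is in seconds from protocol start. For odorants
    ``pulse_spec`` is a single pulse duration; for the shock US it is an
    ordered list of ``(pulse_onset_offset, pulse_duration, voltage)``
    triples relative to ``onset``. ``intensity`` is the odorant dilution
    fraction, or the shock voltage.
    """

    kind: StimulusKind
    onset: float
    pulse_spec: float | tuple[tuple[float, float, float], ...]
    intensity: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ProtocolError(f"event onset must be >= 0, got {self.onset}")
        if self.kind is StimulusKind.SHOCK_US:
            if len(self.pulse_spec) != SHOCK_N_PULSES:
                raise ProtocolError(
                    f"shock US must carry exactly {SHOCK_N_PULSES} pulses"
                )
            for off, dur, volt in self.pulse_spec:
                if dur != SHOCK_PULSE_DURATION or volt != SHOCK_VOLTAGE:
                    raise ProtocolError(
                        "shock pulses must be 1.5 s at 90 V, got "
                        f"({off}, {dur}, {volt})"
                    )
        else:
            if self.pulse_spec != ODOR_PULSE_DURATION:
                raise ProtocolError("odorant pulses must last 10 s")

    @property
    def duration(self) -> float:
        """Extent from onset to the end of the last pulse."""
        if self.kind is StimulusKind.SHOCK_US:
            return max(off + dur for off, dur, _ in self.pulse_spec)
        return float(self.pulse_spec)

    def pulse_windows(self) -> list[tuple[float, float]]:
        """Absolute (start, end) windows of every pulse of this event."""
        if self.kind is StimulusKind.SHOCK_US:
            return [(self.onset + off, self.onset + off + dur)
                    for off, dur, _ in self.pulse_spec]
        return [(self.onset, self.onset + float(self.pulse_spec))]


@dataclass(frozen=True)
class Trial:
    index: int
    onset: float
    events: tuple[StimulusEvent, ...]
    recording_window: tuple[float, float] = (0.0, RECORDING_DURATION)
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_TRIALS:
            raise ProtocolError(f"trial index {self.index} outside 1..{N_TRIALS}")
        if self.recording_window != (0.0, RECORDING_DURATION):
            raise ProtocolError(
                "recording window must be the first 45 s of the trial"
            )
        for ev in self.events:
            if not (self.onset <= ev.onset < self.onset + INTER_TRIAL_INTERVAL):
                raise ProtocolError(
                    f"event at {ev.onset} s lies outside trial {self.index}"
                )

    @property
    def is_training(self) -> bool:
        return self.index in TRAINING_TRIALS

    def recorded_events(self) -> tuple[StimulusEvent, ...]:
        """Events whose full extent lies inside the 45 s recording window."""
        start = self.onset + self.recording_window[0]
        end = self.onset + self.recording_window[1]
        return tuple(
            ev for ev in self.events
            if ev.onset >= start and ev.onset + ev.duration <= end
        )


@dataclass(frozen=True)
class StimulationProtocol:
    group: str
    trials: tuple[Trial, ...]
    sampling_rate: float = SAMPLING_RATE
    rng_seed: int = 0
    first_onset: float = DEFAULT_FIRST_ONSET
    shock_gap: float = DEFAULT_SHOCK_GAP

    def trial(self, index: int) -> Trial:
        return self.trials[index - 1]

    @property
    def n_frames(self) -> int:
        return int(round(RECORDING_DURATION * self.sampling_rate))


def _odor_event(kind: StimulusKind, onset: float) -> StimulusEvent:
    return StimulusEvent(kind, onset, ODOR_PULSE_DURATION, ODORANT_DILUTION[kind])


def _shock_event(onset: float, gap: float) -> StimulusEvent:
    period = SHOCK_PULSE_DURATION + gap
    pulses = tuple(
        (i * period, SHOCK_PULSE_DURATION, SHOCK_VOLTAGE)
        for i in range(SHOCK_N_PULSES)
    )
    return StimulusEvent(StimulusKind.SHOCK_US, onset, pulses, SHOCK_VOLTAGE)


def build_protocol(
    group: str,
    seed: int = 0,
    *,
    first_onset: float = DEFAULT_FIRST_ONSET,
    shock_gap: float = DEFAULT_SHOCK_GAP,
) -> StimulationProtocol:
    """Construct the paired or unpaired 13-trial protocol.

    The paired schedule is fully deterministic. For the unpaired group
    the CS/US order within the six training trials is a seeded balanced
    pseudorandom sequence: exactly three trials are CS-first and three
    US-first, so exactly three CS and three US fall inside recording
    windows.
    """
    if group not in GROUPS:
        raise ProtocolError(f"unknown group {group!r}; expected one of {GROUPS}")
    if seed < 0:
        raise ProtocolError("seed must be >= 0")

    if group == "unpaired":
        rng = np.random.default_rng(seed)
        cs_first = np.zeros(len(TRAINING_TRIALS), dtype=bool)
        cs_first[: len(TRAINING_TRIALS) // 2] = True
        rng.shuffle(cs_first)
    else:
        cs_first = np.ones(len(TRAINING_TRIALS), dtype=bool)

    trials: list[Trial] = []
    pre_kinds = (StimulusKind.SOLVENT_MO, StimulusKind.CS_BUT,
                 StimulusKind.CONTROL_MCH)
    for idx in range(1, N_TRIALS + 1):
        t0 = (idx - 1) * INTER_TRIAL_INTERVAL
        tags: tuple[str, ...] = ()
        if idx <= 3:
            events = (_odor_event(pre_kinds[idx - 1], t0 + first_onset),)
        elif idx in TRAINING_TRIALS:
            interval = (CS_US_INTERVAL_PAIRED if group == "paired"
                        else CS_US_INTERVAL_UNPAIRED)
            if cs_first[idx - TRAINING_TRIALS[0]]:
                cs_on, us_on = t0 + first_onset, t0 + first_onset + interval
            else:
                us_on, cs_on = t0 + first_onset, t0 + first_onset + interval
            events = tuple(sorted(
                (_odor_event(StimulusKind.CS_BUT, cs_on),
                 _shock_event(us_on, shock_gap)),
                key=lambda ev: ev.onset,
            ))
        else:
            post = {10: StimulusKind.CS_BUT, 11: StimulusKind.CONTROL_MCH,
                    13: StimulusKind.CS_BUT}
            if idx == 12:
                events = (_shock_event(t0 + first_onset, shock_gap),)
            else:
                events = (_odor_event(post[idx], t0 + first_onset),)
            if idx == 13:
                tags = ("rundown_check",)
        trials.append(Trial(index=idx, onset=t0, events=events, tags=tags))

    protocol = StimulationProtocol(
        group=group, trials=tuple(trials), rng_seed=seed,
        first_onset=first_onset, shock_gap=shock_gap,
    )
    validate_protocol(protocol)
    return protocol


def validate_protocol(protocol: StimulationProtocol) -> None:
    """Check the full set of schedule invariants; raise on violation."""
    trials = protocol.trials
    if len(trials) != N_TRIALS:
        raise ProtocolError(f"expected {N_TRIALS} trials, got {len(trials)}")
    for a, b in zip(trials, trials[1:]):
        if b.onset - a.onset != INTER_TRIAL_INTERVAL:
            raise ProtocolError("consecutive trial onsets must differ by 210 s")
    n_cs = n_us = 0
    for trial in trials:
        kinds = [ev.kind for ev in trial.events]
        if trial.is_training:
            if sorted(k.value for k in kinds) != ["CS", "US"]:
                raise ProtocolError(
                    f"training trial {trial.index} must contain one CS and one US"
                )
            cs = next(ev for ev in trial.events if ev.kind is StimulusKind.CS_BUT)
            us = next(ev for ev in trial.events if ev.kind is StimulusKind.SHOCK_US)
            gap = abs(us.onset - cs.onset)
            expected = (CS_US_INTERVAL_PAIRED if protocol.group == "paired"
                        else CS_US_INTERVAL_UNPAIRED)
            if gap != expected:
                raise ProtocolError(
                    f"trial {trial.index}: |US-CS| onset interval {gap} != {expected}"
                )
            if protocol.group == "paired" and us.onset - cs.onset != expected:
                raise ProtocolError("paired protocol requires CS before US")
            n_cs += 1
            n_us += 1
    if n_cs != 6 or n_us != 6:
        raise ProtocolError("training must comprise six CS and six US")
    expected_single = {1: "MO", 2: "CS", 3: "MCH", 10: "CS", 11: "MCH",
                       12: "US", 13: "CS"}
    for idx, kind in expected_single.items():
        evs = trials[idx - 1].events
        if len(evs) != 1 or evs[0].kind.value != kind:
            raise ProtocolError(f"trial {idx} must contain exactly one {kind}")


def total_duration(protocol: StimulationProtocol) -> float:
    """Protocol duration: last trial onset plus one inter-trial interval."""
    if not protocol.trials:
        raise ProtocolError("protocol has no trials")
    return protocol.trials[-1].onset + INTER_TRIAL_INTERVAL


def recorded_stimuli(protocol: StimulationProtocol) -> list[tuple[int, StimulusKind]]:
    """Every stimulus fully inside a trial's 45 s recording window."""
    out: list[tuple[int, StimulusKind]] = []
    for trial in protocol.trials:
        out.extend((trial.index, ev.kind) for ev in trial.recorded_events())
    return out


# ---------------------------------------------------------------------------
# Serialization (human-readable YAML)

def protocol_to_dict(protocol: StimulationProtocol) -> dict:
    return {
        "group": protocol.group,
        "rng_seed": int(protocol.rng_seed),
        "sampling_rate_hz": protocol.sampling_rate,
        "first_onset_s": protocol.first_onset,
        "shock_gap_s": protocol.shock_gap,
        "trials": [
            {
                "index": t.index,
                "onset_s": t.onset,
                "tags": list(t.tags),
                "events": [
                    {
                        "kind": ev.kind.value,
                        "onset_s": ev.onset,
                        "pulse_spec": (
                            ev.pulse_spec if isinstance(ev.pulse_spec, float)
                            else [list(p) for p in ev.pulse_spec]
                        ),
                        "intensity": ev.intensity,
                    }
                    for ev in t.events
                ],
            }
            for t in protocol.trials
        ],
    }


def protocol_from_dict(data: dict) -> StimulationProtocol:
    trials = []
    for td in data["trials"]:
        events = []
        for ed in td["events"]:
            spec = ed["pulse_spec"]
            if isinstance(spec, list):
                spec = tuple(tuple(p) for p in spec)
            events.append(StimulusEvent(StimulusKind(ed["kind"]), ed["onset_s"],
                                        spec, ed["intensity"]))
        trials.append(Trial(index=td["index"], onset=td["onset_s"],
                            events=tuple(events), tags=tuple(td.get("tags", ()))))
    protocol = StimulationProtocol(
        group=data["group"], trials=tuple(trials),
        sampling_rate=data.get("sampling_rate_hz", SAMPLING_RATE),
        rng_seed=data.get("rng_seed", 0),
        first_onset=data.get("first_onset_s", DEFAULT_FIRST_ONSET),
        shock_gap=data.get("shock_gap_s", DEFAULT_SHOCK_GAP),
    )
    validate_protocol(protocol)
    return protocol


def write_protocol(protocol: StimulationProtocol, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False,
                       allow_unicode=True)


def read_protocol(path) -> StimulationProtocol:
    with open(path, encoding="utf-8") as fh:
        return protocol_from_dict(yaml.safe_load(fh))
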