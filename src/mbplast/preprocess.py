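"""ΔF/F₀ extraction, within-fly normalization and hemisphere selection.

The baseline F₀ of every trial is the mean of frames 3-24 (1-based,
inclusive; 0.4-4.8 s at 5 Hz), which precede stimulus onset. Because
absolute signal amplitude varies between flies, all ΔF/F₀ traces of a
fly are divided by the maximum of the BUT-evoked response in trial 2 in
the strongest-responding compartment, making traces comparable across
animals ("response traces"). Analysis uses one hemisphere per fly: the
one in which the underrepresented γ1 compartment is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import StimulationProtocol, StimulusKind
from .synthdata import FlyRecording

#: F₀ window in 1-based inclusive frame numbers.
DEFAULT_F0_FRAMES = (3, 24)
#: Width (frames) of the moving average applied before locating the
#: trial-2 BUT peak; damps the upward bias that frame noise adds to a
#: maximum taken over many near-plateau frames.
DEFAULT_PEAK_SMOOTH = 5


class PreprocessError(ValueError):
    """Raised for degenerate recordings (non-positive F₀ or peak)."""


def _one_based_inclusive_to_slice(window: tuple[int, int]) -> slice:
    """Convert a 1-based inclusive frame window to a 0-based slice.

    Centralized so the "frames 3-24" convention cannot drift: frame 3
    is index 2, frame 24 is index 23, slice(2, 24).
    """
    first, last = window
    if first < 1 or last < first:
        raise ValueError(f"invalid frame window {window}")
    return slice(first - 1, last)


def compute_dff(raw_trace: np.ndarray,
                f0_frames: tuple[int, int] = DEFAULT_F0_FRAMES) -> np.ndarray:
    """(F - F₀)/F₀ with F₀ the mean of the designated baseline frames."""
    raw = np.asarray(raw_trace, dtype=float)
    sl = _one_based_inclusive_to_slice(f0_frames)
    if sl.stop > raw.size:
        raise PreprocessError(
            f"F0 window {f0_frames} extends past trace of {raw.size} frames")
    f0 = raw[sl].mean()
    if f0 <= 0:
        raise PreprocessError(f"non-positive F0 ({f0:g}); degenerate trace")
    return (raw - f0) / f0


@dataclass
class ResponseTraceSet:
    """Normalized ΔF/F₀ traces for one fly (selected hemisphere)."""

    fly_id: str
    genotype: str
    group: str
    normalization_factor: float
    traces: dict[tuple[str, int], np.ndarray]  # (compartment, trial) -> 225
    hemisphere: str = "left"
    shock_currents: dict[int, float] = field(default_factory=dict)

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.traces}))


def _smooth(trace: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return trace
    return np.convolve(trace, np.ones(w) / w, mode="same")


def normalize_fly(
    dff_traces: dict[tuple[str, int], np.ndarray],
    protocol: StimulationProtocol,
    *,
    smooth_frames: int = DEFAULT_PEAK_SMOOTH,
    window: str = "stimulus",
) -> tuple[dict[tuple[str, int], np.ndarray], float]:
    """Divide all traces by the trial-2 BUT response maximum.

    The maximum is taken across compartments over the BUT stimulus
    window (onset to onset + 10 s; ``window="trial"`` uses the whole
    trial) on lightly smoothed traces. Returns the normalized traces
    and the factor.
    """
    trial2 = protocol.trial(2)
    ev = next(e for e in trial2.events if e.kind is StimulusKind.CS_BUT)
    fs = protocol.sampling_rate
    rel = ev.onset - trial2.onset
    if window == "stimulus":
        i0 = int(np.ceil(rel * fs))
        i1 = int(np.ceil((rel + ev.duration) * fs))
    elif window == "trial":
        i0, i1 = 0, protocol.n_frames
    else:
        raise ValueError(f"unknown normalization window {window!r}")

    peaks = [
        _smooth(trace, smooth_frames)[i0:i1].max()
        for (comp, trial), trace in dff_traces.items() if trial == 2
    ]
    if not peaks:
        raise PreprocessError("trial 2 not present; cannot normalize")
    factor = float(max(peaks))
    if factor <= 0:
        raise PreprocessError(
            f"non-positive trial-2 BUT maximum ({factor:g}); degenerate fly")
    return {k: v / factor for k, v in dff_traces.items()}, factor


def select_hemisphere(recording: FlyRecording) -> str:
    """Pick the analysis hemisphere.

    Prefer the side where γ1 is visible; if both or neither qualify,
    prefer the side with more compartments, ties broken toward left.
    """
    sides = {s: set(c) for s, c in recording.hemispheres.items() if c}
    if not sides:
        raise PreprocessError(f"fly {recording.fly_id} has no compartments")
    with_g1 = [s for s in ("left", "right") if s in sides and "γ1" in sides[s]]
    if len(with_g1) == 1:
        return with_g1[0]
    candidates = with_g1 if with_g1 else [s for s in ("left", "right")
                                          if s in sides]
    return max(candidates, key=lambda s: (len(sides[s]), s == "left"))


def process_recording(
    recording: FlyRecording,
    protocol: StimulationProtocol,
    *,
    f0_frames: tuple[int, int] = DEFAULT_F0_FRAMES,
    smooth_frames: int = DEFAULT_PEAK_SMOOTH,
    norm_window: str = "stimulus",
    hemisphere: str | None = None,
) -> ResponseTraceSet:
    """Full front-end for one fly: hemisphere selection, ΔF/F₀,
    within-fly normalization."""
    side = hemisphere or select_hemisphere(recording)
    dff = {
        (comp, trial): compute_dff(trace, f0_frames)
        for (s, comp, trial), trace in recording.traces.items()
        if s == side
    }
    normed, factor = normalize_fly(dff, protocol, smooth_frames=smooth_frames,
                                   window=norm_window)
    return ResponseTraceSet(
        fly_id=recording.fly_id, genotype=recording.genotype,
        group=recording.group, normalization_factor=factor,
        traces=normed, hemisphere=side,
        shock_currents=dict(recording.shock_currents),
    )
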