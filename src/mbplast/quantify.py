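"""Response-strength quantification and paired-vs-unpaired contrasts.

"Response strength" is the mean of the response trace over the time of
stimulus application (10 s for odorants, the union of the four 1.5 s
pulse windows for shock), taken relative to the frame immediately
preceding stimulus onset, and referenced to the corresponding
pre-training trial (trial 2 for the CS, trial 3 for the control
odorant, and the first shock presentation for the US). Frame-wise
paired-vs-unpaired differences are summarized as a rank-sum p-value
barcode with the conventional 0.05/0.01/0.001 bands.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import ResponseTraceSet
from .protocol import (
    SAMPLING_RATE,
    StimulationProtocol,
    StimulusEvent,
    StimulusKind,
    Trial,
)

#: Reference (pre-training) trial per stimulus class. The US reference
#: is each fly's first *recorded* shock (trial 4 for paired flies).
REFERENCE_TRIALS = {StimulusKind.CS_BUT: 2, StimulusKind.CONTROL_MCH: 3}

DEFAULT_P_THRESHOLDS = (0.05, 0.01, 0.001)
POST_TRAINING_CS_TRIALS = (10,)


class QuantifyError(ValueError):
    pass


def _window_frames(event: StimulusEvent, trial: Trial,
                   fs: float) -> tuple[np.ndarray, int]:
    """Frame indices covered by the stimulus and the pre-onset frame.

    A frame belongs to a pulse if its onset time falls in the half-open
    pulse window [start, end).
    """
    frames: list[int] = []
    for start, end in event.pulse_windows():
        rel0, rel1 = start - trial.onset, end - trial.onset
        i0 = int(np.ceil(rel0 * fs - 1e-9))
        i1 = int(np.ceil(rel1 * fs - 1e-9))
        frames.extend(range(i0, i1))
    idx = np.unique(frames)
    first = int(np.ceil((event.onset - trial.onset) * fs - 1e-9))
    return idx, first - 1


def stimulus_window_mean(trace: np.ndarray, event: StimulusEvent,
                         trial: Trial, fs: float = SAMPLING_RATE) -> float:
    """Mean response over the stimulus window, relative to the frame
    prior to (the first pulse of) the stimulus."""
    trace = np.asarray(trace, dtype=float)
    idx, pre = _window_frames(event, trial, fs)
    if pre < 0 or idx[-1] >= trace.size:
        raise QuantifyError(
            f"stimulus window [{idx[0]}..{idx[-1]}] outside trace "
            f"of {trace.size} frames")
    return float(trace[idx].mean() - trace[pre])


def window_mean_table(trace_set: ResponseTraceSet,
                      protocol: StimulationProtocol) -> pd.DataFrame:
    """Raw (not reference-subtracted) stimulus-window means for every
    recorded stimulus of one fly; the quantity pattern vectors use."""
    rows = []
    for trial in protocol.trials:
        for ev in trial.recorded_events():
            for (comp, tr), trace in trace_set.traces.items():
                if tr != trial.index:
                    continue
                rows.append({
                    "fly_id": trace_set.fly_id,
                    "genotype": trace_set.genotype,
                    "group": trace_set.group,
                    "compartment": comp,
                    "trial": trial.index,
                    "stimulus": ev.kind.value,
                    "window_mean": stimulus_window_mean(
                        trace, ev, trial, protocol.sampling_rate),
                })
    return pd.DataFrame(rows)


def response_strength(trace_set: ResponseTraceSet,
                      protocol: StimulationProtocol) -> pd.DataFrame:
    """Reference-corrected response strengths for one fly.

    strength(trial) = window_mean(trial) - window_mean(reference trial
    of the same stimulus class). Reference trials themselves therefore
    score exactly 0. The solvent (MO, trial 1 only) has no reference
    class and is omitted.
    """
    wm = window_mean_table(trace_set, protocol)
    rows = []
    for stim_kind, ref_trial in _reference_map(wm).items():
        sub = wm[wm.stimulus == stim_kind]
        ref = sub[sub.trial == ref_trial].set_index("compartment")["window_mean"]
        if ref.empty:
            raise QuantifyError(
                f"fly {trace_set.fly_id}: reference trial {ref_trial} for "
                f"{stim_kind} not recorded")
        for _, row in sub.iterrows():
            if row.compartment not in ref.index:
                raise QuantifyError(
                    f"fly {trace_set.fly_id}: compartment {row.compartment} "
                    f"missing in reference trial {ref_trial}")
            rows.append({
                **row[["fly_id", "genotype", "group", "compartment",
                       "trial", "stimulus", "window_mean"]].to_dict(),
                "strength": row.window_mean - ref[row.compartment],
                "reference_trial": ref_trial,
            })
    return pd.DataFrame(rows)


def _reference_map(wm: pd.DataFrame) -> dict[str, int]:
    refs = {StimulusKind.CS_BUT.value: REFERENCE_TRIALS[StimulusKind.CS_BUT],
            StimulusKind.CONTROL_MCH.value:
                REFERENCE_TRIALS[StimulusKind.CONTROL_MCH]}
    us_trials = wm.loc[wm.stimulus == StimulusKind.SHOCK_US.value, "trial"]
    if not us_trials.empty:
        refs[StimulusKind.SHOCK_US.value] = int(us_trials.min())
    return refs


def cohort_strength_table(
    trace_sets: Iterable[ResponseTraceSet],
    protocols: dict[str, StimulationProtocol],
) -> pd.DataFrame:
    """Concatenated response-strength table for a whole cohort."""
    parts = [response_strength(ts, protocols[ts.group]) for ts in trace_sets]
    return pd.concat(parts, ignore_index=True)


def cohort_window_table(
    trace_sets: Iterable[ResponseTraceSet],
    protocols: dict[str, StimulationProtocol],
) -> pd.DataFrame:
    parts = [window_mean_table(ts, protocols[ts.group]) for ts in trace_sets]
    return pd.concat(parts, ignore_index=True)


def trace_difference(post: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """Elementwise post-minus-pre response-trace difference."""
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if post.shape != pre.shape:
        raise QuantifyError(
            f"trace length mismatch: {post.shape} vs {pre.shape}")
    return post - pre


def _band(p: float, thresholds: Sequence[float]) -> str:
    t1, t2, t3 = thresholds
    if p < t3:
        return f"p<{t3}"
    if p < t2:
        return f"p<{t2}"
    if p < t1:
        return f"p<{t1}"
    return "ns"


def framewise_pbarcode(
    paired_traces: np.ndarray,
    unpaired_traces: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS,
    fdr: bool = False,
) -> pd.DataFrame:
    """Frame-wise two-sample rank-sum (Mann-Whitney / Wilcoxon) test
    between groups.

    Rows of the inputs are flies, columns frames. No multiplicity
    correction by default (each frame is displayed on its own);
    ``fdr=True`` applies Benjamini-Hochberg across frames.
    """
    paired = np.atleast_2d(np.asarray(paired_traces, dtype=float))
    unpaired = np.atleast_2d(np.asarray(unpaired_traces, dtype=float))
    if paired.shape[0] < 2 or unpaired.shape[0] < 2:
        raise QuantifyError("need at least 2 flies per group")
    if paired.shape[1] != unpaired.shape[1]:
        raise QuantifyError("frame counts differ between groups")
    pvals = np.empty(paired.shape[1])
    for j in range(paired.shape[1]):
        a, b = paired[:, j], unpaired[:, j]
        if np.all(a[0] == a) and np.all(b[0] == b) and a[0] == b[0]:
            pvals[j] = 1.0
            continue
        pvals[j] = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    if fdr:
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "frame": np.arange(pvals.size),
        "p": pvals,
        "band": [_band(p, thresholds) for p in pvals],
    })


def associative_effect(
    table: pd.DataFrame,
    post_trials: Sequence[int] = POST_TRAINING_CS_TRIALS,
    stimulus: str = "CS",
    significance_fn: Callable[[pd.DataFrame], float] | None = None,
) -> pd.DataFrame:
    """Paired-minus-unpaired mean post-training CS response strength
    per (genotype, compartment).

    Only trials recorded in both groups enter any contrast; post-
    training presentations (trial 10 by default) are recorded in both.
    ``significance_fn`` maps a single-cell strength table to a p-value
    (e.g. a mixed-model group test from the stats module).
    """
    sub = table[(table.stimulus == stimulus) & table.trial.isin(post_trials)]
    rows = []
    for (genotype, comp), cell in sub.groupby(["genotype", "compartment"],
                                              sort=True):
        means = cell.groupby("group")["strength"].mean()
        if "paired" not in means or "unpaired" not in means:
            raise QuantifyError(
                f"({genotype}, {comp}): both groups required for the contrast")
        row = {
            "genotype": genotype,
            "compartment": comp,
            "effect": means["paired"] - means["unpaired"],
            "n_paired": int((cell.group == "paired").sum()),
            "n_unpaired": int((cell.group == "unpaired").sum()),
        }
        if significance_fn is not None:
            full_cell = table[(table.stimulus == stimulus)
                              & (table.genotype == genotype)
                              & (table.compartment == comp)]
            row["p"] = significance_fn(full_cell)
            row["significant"] = row["p"] < 0.05
        rows.append(row)
    return pd.DataFrame(rows)


def common_trials(table: pd.DataFrame, stimulus: str) -> list[int]:
    """Trials in which the stimulus was recorded in both groups
    (trials missing from the unpaired group are excluded from group
    statistics)."""
    sub = table[table.stimulus == stimulus]
    per_group = sub.groupby("group")["trial"].agg(lambda s: set(s))
    if len(per_group) < 2:
        return sorted(set(sub.trial))
    return sorted(set.intersection(*per_group))
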