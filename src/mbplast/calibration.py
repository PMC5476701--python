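"""Simulation-based validation harnesses.

Parameter-recovery and calibration studies that exercise the full
pipeline on generated cohorts: recovery of an injected DAN CS-response
gain, type-I-error calibration of the frame-wise rank-sum barcode and
of the mixed-model group test under null (no-plasticity) cohorts, and
recovery of the shock-response current law. Used by the test suite and
the reproduction script; each harness takes an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import process_recording
from .protocol import build_protocol
from .quantify import (
    associative_effect,
    cohort_strength_table,
    framewise_pbarcode,
)
from .stats import group_effect_p, shock_current_correlation
from .synthdata import (
    DAN_PLASTICITY_COMPARTMENTS,
    SyntheticConfig,
    generate_cohort,
    shock_amplitude,
)

#: Compartment set for DAN-only recovery studies: the nine shared
#: compartments plus the junction (all plasticity targets included).
_DAN_RECOVERY_COMPARTMENTS = (
    "α1/α'1", "β2", "β'1", "β'2", "γ1", "γ2", "γ3", "γ4", "γ5", "junction")


def _protocol_pair(seed: int):
    return build_protocol("paired", seed), build_protocol("unpaired", seed)


def _strengths_for(config: SyntheticConfig, n_flies: int) -> pd.DataFrame:
    pair = _protocol_pair(0)
    protocols = {p.group: p for p in pair}
    cohort = generate_cohort(pair, config, n_flies)
    sets = [process_recording(f, protocols[f.group]) for f in cohort]
    return cohort_strength_table(sets, protocols)


def _dan_config(seed: int, noise_sd: float, fly_cv: float,
                dan_gain: float = 1.5) -> SyntheticConfig:
    return SyntheticConfig(
        genotypes=("DAN",), compartments=_DAN_RECOVERY_COMPARTMENTS,
        gamma1_dropout=0.0, noise_sd=noise_sd, fly_amplitude_cv=fly_cv,
        dan_gain=dan_gain, seed=seed)


def dan_gain_recovery(n_flies: int = 20, n_seeds: int = 20,
                      noise_sd: float = 0.05, base_seed: int = 0
                      ) -> pd.DataFrame:
    """Recover the injected paired-only DAN CS gain from noisy cohorts.

    The injected magnitude per compartment is the paired-minus-unpaired
    post-training CS effect computed from the noiseless forward model
    (zero noise, no between-fly scaling); recovery averages the same
    measurement over ``n_seeds`` noisy cohorts of ``n_flies`` per cell.
    """
    ref_cfg = _dan_config(1, noise_sd=0.0, fly_cv=0.0)
    reference = (
        associative_effect(_strengths_for(ref_cfg, 1))
        .set_index("compartment")["effect"])

    per_seed = []
    for k in range(n_seeds):
        cfg = _dan_config(base_seed + 1000 + k, noise_sd=noise_sd,
                          fly_cv=0.2)
        eff = associative_effect(_strengths_for(cfg, n_flies))
        per_seed.append(eff.set_index("compartment")["effect"])
    recovered = pd.concat(per_seed, axis=1)

    out = pd.DataFrame({
        "injected": reference,
        "recovered_mean": recovered.mean(axis=1),
        "recovered_min": recovered.min(axis=1),
    })
    out["injected_compartment"] = [
        c in DAN_PLASTICITY_COMPARTMENTS for c in out.index]
    out["rel_err"] = np.where(
        out.injected != 0,
        (out.recovered_mean - out.injected).abs() / out.injected.abs(),
        np.nan)
    return out


def barcode_null_rejection(n_flies: int = 16, n_seeds: int = 5,
                           base_seed: int = 0, alpha: float = 0.05
                           ) -> tuple[float, int]:
    """Fraction of frames with p < alpha in null (no-plasticity)
    cohorts: post-training CS traces, paired vs unpaired group.

    Returns (rejection rate, number of frame-wise tests).
    """
    pair = _protocol_pair(0)
    protocols = {p.group: p for p in pair}
    n_tests = 0
    n_reject = 0
    for k in range(n_seeds):
        cfg = SyntheticConfig(
            genotypes=("DAN",), compartments=("γ2", "β'2"),
            gamma1_dropout=0.0, dan_gain=1.0, kc_depression=1.0,
            seed=base_seed + 2000 + k)
        cohort = generate_cohort(pair, cfg, n_flies)
        sets = [process_recording(f, protocols[f.group]) for f in cohort]
        for comp in cfg.compartments:
            mats = {
                grp: np.array([ts.traces[(comp, 10)] for ts in sets
                               if ts.group == grp])
                for grp in ("paired", "unpaired")
            }
            p = framewise_pbarcode(mats["paired"], mats["unpaired"]).p
            n_tests += p.size
            n_reject += int((p < alpha).sum())
    return n_reject / n_tests, n_tests


def group_model_null_rejection(n_reps: int = 500, n_flies: int = 8,
                               base_seed: int = 0, alpha: float = 0.05
                               ) -> tuple[float, int]:
    """Type-I error of the mixed-model group test on null cohorts."""
    pair = _protocol_pair(0)
    protocols = {p.group: p for p in pair}
    rejections = 0
    for k in range(n_reps):
        cfg = SyntheticConfig(
            genotypes=("DAN",), compartments=("γ2",), gamma1_dropout=0.0,
            dan_gain=1.0, kc_depression=1.0, seed=base_seed + 3000 + k)
        cohort = generate_cohort(pair, cfg, n_flies)
        sets = [process_recording(f, protocols[f.group]) for f in cohort]
        table = cohort_strength_table(sets, protocols)
        cs = table[(table.stimulus == "CS") & (table.compartment == "γ2")]
        rejections += group_effect_p(cs) < alpha
    return rejections / n_reps, n_reps


def shock_slope_recovery(seed: int = 0, n: int = 50, slope: float = 0.3,
                         intercept: float = 0.05, noise_sd: float = 0.02):
    """Recover the generating log10-current slope from noisy
    (strength, current) samples, plus Spearman rho on noiseless
    strictly monotone data."""
    rng = np.random.default_rng(seed)
    currents = 10 ** rng.normal(2.5, 0.4, size=n)
    strengths = np.array([shock_amplitude(c, slope, intercept)
                          for c in currents])
    strengths = strengths + rng.normal(0.0, noise_sd, size=n)
    noisy = shock_current_correlation(strengths, currents)

    mono_currents = np.array([10.0, 50.0, 120.0, 300.0, 900.0])
    mono = shock_current_correlation(
        slope * np.log10(mono_currents) + intercept, mono_currents)
    return noisy, mono
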