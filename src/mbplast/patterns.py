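"""Cross-compartmental spatial activity-pattern dissimilarity.

The per-trial activity pattern of a fly is the 9-dimensional vector of
normalized mean response strengths (raw stimulus-window means) in the
nine MB compartments shared between DANs and KCs, in the fixed order
α1/α'1, β2, β'1, β'2, γ1, γ2, γ3, γ4, γ5. Pattern dissimilarity is the
angle φ between two vectors, cos φ = (α⃗·β⃗)/(‖α⃗‖‖β⃗‖) — a measure
independent of overall response strength — or their Euclidean
distance. Trial courses compare each trial's pattern to a reference:
the first CS (trial 2), the first recorded US, or the fly's mean
training-US pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compartments import SHARED_COMPARTMENTS
from .protocol import TRAINING_TRIALS

PATTERN_ORDER = SHARED_COMPARTMENTS
SCHEMES = ("CS_vs_firstCS", "US_vs_firstUS", "CS_vs_meanUS")
METRICS = ("angle", "euclidean")


class PatternError(ValueError):
    pass


def pattern_vector(window_table: pd.DataFrame, fly_id: str, trial: int,
                   stimulus: str) -> np.ndarray:
    """9-component pattern vector for one (fly, trial, stimulus).

    Components are the raw normalized stimulus-window means (not
    reference-subtracted), so they are predominantly non-negative and
    angles fall mostly in [0, π/2]. Negative components arising from
    noise are retained.
    """
    sub = window_table[(window_table.fly_id == fly_id)
                       & (window_table.trial == trial)
                       & (window_table.stimulus == stimulus)]
    values = sub.set_index("compartment")["window_mean"]
    missing = [c for c in PATTERN_ORDER if c not in values.index]
    if missing:
        raise PatternError(
            f"fly {fly_id}, trial {trial}, {stimulus}: missing "
            f"compartment(s) {missing}")
    return np.array([values[c] for c in PATTERN_ORDER], dtype=float)


def angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (radians, [0, π]) between two pattern vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PatternError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise PatternError("undefined angle: zero-norm pattern vector")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PatternError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def rad_to_deg_int(rad: float) -> int:
    """Degrees rounded to integer, for dual radian/degree reporting."""
    return int(round(np.degrees(rad)))


_METRIC_FN = {"angle": angle, "euclidean": euclidean}


def _fly_vectors(window_table: pd.DataFrame, fly_id: str,
                 stimulus: str) -> dict[int, np.ndarray]:
    sub = window_table[(window_table.fly_id == fly_id)
                       & (window_table.stimulus == stimulus)]
    return {int(t): pattern_vector(window_table, fly_id, int(t), stimulus)
            for t in sorted(sub.trial.unique())}


def dissimilarity_course(
    window_table: pd.DataFrame,
    scheme: str,
    metric: str = "angle",
) -> pd.DataFrame:
    """Per-group, per-trial mean ± SEM dissimilarity curves.

    The table must contain only flies with all nine shared compartments
    (others are excluded upstream). Unpaired trials without the
    relevant recorded stimulus are simply absent from the curve.
    """
    if scheme not in SCHEMES:
        raise PatternError(f"unknown scheme {scheme!r}; expected {SCHEMES}")
    if metric not in _METRIC_FN:
        raise PatternError(f"unknown metric {metric!r}; expected {METRICS}")
    dist = _METRIC_FN[metric]
    shared = window_table[window_table.compartment.isin(PATTERN_ORDER)]

    records = []
    for (genotype, group, fly_id), fly_tbl in shared.groupby(
            ["genotype", "group", "fly_id"]):
        cs = _fly_vectors(shared, fly_id, "CS")
        us = _fly_vectors(shared, fly_id, "US")
        if scheme == "CS_vs_firstCS":
            if 2 not in cs:
                raise PatternError(f"fly {fly_id}: first CS (trial 2) missing")
            ref, course = cs[2], cs
        elif scheme == "US_vs_firstUS":
            if not us:
                raise PatternError(f"fly {fly_id}: no recorded US")
            ref, course = us[min(us)], us
        else:  # CS_vs_meanUS
            training_us = [v for t, v in us.items() if t in TRAINING_TRIALS]
            if not training_us:
                raise PatternError(f"fly {fly_id}: no recorded training US")
            ref, course = np.mean(training_us, axis=0), cs
        for trial, vec in course.items():
            records.append({"genotype": genotype, "group": group,
                            "fly_id": fly_id, "trial": trial,
                            "value": dist(vec, ref)})

    per_fly = pd.DataFrame(records)
    out = (
        per_fly.groupby(["genotype", "group", "trial"])["value"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s))
             if len(s) > 1 else np.nan, n="count")
        .reset_index()
    )
    out.insert(0, "metric", metric)
    out.insert(0, "scheme", scheme)
    return out


def all_courses(window_table: pd.DataFrame,
                metrics: tuple[str, ...] = METRICS) -> pd.DataFrame:
    """All scheme x metric dissimilarity curves in one table."""
    parts = [dissimilarity_course(window_table, scheme, metric)
             for scheme in SCHEMES for metric in metrics]
    return pd.concat(parts, ignore_index=True)
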