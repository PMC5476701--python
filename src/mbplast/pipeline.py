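"""End-to-end orchestration: protocol → synthetic cohort → ΔF/F₀ →
response strengths → barcodes, associative effects, pattern courses and
group statistics, with a provenance manifest.

All stages are deterministic for a fixed configuration, so re-running a
config reproduces bit-identical output files (the manifest records
per-file checksums plus a hash of the configuration itself).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_cohort, write_json, write_table
from .patterns import PATTERN_ORDER, all_courses
from .preprocess import DEFAULT_F0_FRAMES, DEFAULT_PEAK_SMOOTH, process_recording
from .protocol import build_protocol, write_protocol
from .quantify import (
    DEFAULT_P_THRESHOLDS,
    associative_effect,
    cohort_strength_table,
    cohort_window_table,
    framewise_pbarcode,
)
from .stats import (
    StatsError,
    fit_group_model,
    group_effect_p,
    hemisphere_test,
    shock_current_correlation,
)
from .synthdata import SyntheticConfig, generate_cohort

log = logging.getLogger("mbplast")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    n_flies_per_cell: int = 8
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    protocol_first_onset: float = 5.0
    protocol_shock_gap: float = 1.5
    f0_frames: tuple[int, int] = DEFAULT_F0_FRAMES
    peak_smooth_frames: int = DEFAULT_PEAK_SMOOTH
    norm_window: str = "stimulus"
    p_thresholds: tuple[float, float, float] = DEFAULT_P_THRESHOLDS
    barcode_trial: int = 10
    post_trials: tuple[int, ...] = (10,)
    boxcox_dan: bool = True  # Box-Cox-transform DAN strengths before ANOVA
    out_dir: str = "results"

    def __post_init__(self) -> None:
        t1, t2, t3 = self.p_thresholds
        if not t1 > t2 > t3 > 0:
            raise ConfigError(
                f"p thresholds must be strictly decreasing, got "
                f"{self.p_thresholds}")
        if self.n_flies_per_cell < 1:
            raise ConfigError("n_flies_per_cell must be >= 1")
        # the cohort seed follows the global seed unless set explicitly
        if self.synth.seed == 0 and self.seed != 0:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["odor_amplitudes"] = {
            "|".join(k): v for k, v in self.synth.odor_amplitudes.items()}
        d["synth"]["shock_params"] = {
            "|".join(k): list(v) for k, v in self.synth.shock_params.items()}
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True,
                              allow_unicode=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_from_yaml(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    synth_raw = raw.pop("synth", {})
    for key, caster in (("odor_amplitudes", float), ("shock_params", tuple)):
        if key in synth_raw:
            synth_raw[key] = {tuple(k.split("|")): (
                caster(v) if caster is float else tuple(v))
                for k, v in synth_raw[key].items()}
    for tkey in ("genotypes", "compartments"):
        if synth_raw.get(tkey) is not None:
            synth_raw[tkey] = tuple(synth_raw[tkey])
    synth = SyntheticConfig(**synth_raw)
    for tkey in ("f0_frames", "p_thresholds", "post_trials"):
        if tkey in raw:
            raw[tkey] = tuple(raw[tkey])
    return RunConfig(synth=synth, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return the run manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    files: dict[str, Path] = {}

    # --- protocol -----------------------------------------------------
    paired = build_protocol("paired", config.seed,
                            first_onset=config.protocol_first_onset,
                            shock_gap=config.protocol_shock_gap)
    unpaired = build_protocol("unpaired", config.seed,
                              first_onset=config.protocol_first_onset,
                              shock_gap=config.protocol_shock_gap)
    protocols = {"paired": paired, "unpaired": unpaired}
    for name, proto in protocols.items():
        path = out / f"protocol_{name}.yaml"
        write_protocol(proto, path)
        files[f"protocol_{name}"] = path
    log.info("protocol: built paired and unpaired schedules (13 trials)")

    # --- synthetic cohort --------------------------------------------
    cohort = generate_cohort((paired, unpaired), config.synth,
                             config.n_flies_per_cell)
    files.update(write_cohort(cohort, out / "cohort"))
    log.info("synthdata: %d flies generated", len(cohort))

    # --- preprocessing ------------------------------------------------
    trace_sets = [
        process_recording(fly, protocols[fly.group],
                          f0_frames=config.f0_frames,
                          smooth_frames=config.peak_smooth_frames,
                          norm_window=config.norm_window)
        for fly in cohort
    ]
    norm_rows = pd.DataFrame([
        {"fly_id": ts.fly_id, "genotype": ts.genotype, "group": ts.group,
         "hemisphere": ts.hemisphere,
         "normalization_factor": ts.normalization_factor}
        for ts in trace_sets])
    files["normalization"] = write_table(norm_rows, out / "normalization.csv")

    trace_rows = []
    for ts in trace_sets:
        for (comp, trial), trace in sorted(ts.traces.items()):
            trace_rows.append(pd.DataFrame({
                "fly_id": ts.fly_id, "genotype": ts.genotype,
                "group": ts.group, "compartment": comp, "trial": trial,
                "frame": np.arange(trace.size), "dff_norm": trace}))
    files["traces_norm"] = write_table(
        pd.concat(trace_rows, ignore_index=True), out / "traces_norm.csv")
    log.info("preprocess: %d flies normalized", len(trace_sets))

    # --- quantification -----------------------------------------------
    strengths = cohort_strength_table(trace_sets, protocols)
    files["strengths"] = write_table(strengths, out / "strengths.csv")
    windows = cohort_window_table(trace_sets, protocols)
    files["window_means"] = write_table(windows, out / "window_means.csv")
    log.info("quantify: %d strength rows", len(strengths))

    # frame-wise barcodes: post-training CS trace, paired vs unpaired
    barcode_parts = []
    for (genotype, comp), _ in strengths.groupby(["genotype", "compartment"]):
        groups = {}
        for grp in ("paired", "unpaired"):
            mats = [ts.traces[(comp, config.barcode_trial)]
                    for ts in trace_sets
                    if ts.genotype == genotype and ts.group == grp
                    and (comp, config.barcode_trial) in ts.traces]
            groups[grp] = np.array(mats)
        if min(len(groups["paired"]), len(groups["unpaired"])) < 2:
            continue
        bc = framewise_pbarcode(groups["paired"], groups["unpaired"],
                                config.p_thresholds)
        bc.insert(0, "compartment", comp)
        bc.insert(0, "genotype", genotype)
        barcode_parts.append(bc)
    files["barcodes"] = write_table(
        pd.concat(barcode_parts, ignore_index=True), out / "barcodes.csv")

    # associative effects with mixed-model significance
    def _sig(cell: pd.DataFrame) -> float:
        transform = ("boxcox" if config.boxcox_dan
                     and cell.genotype.iloc[0] == "DAN" else None)
        try:
            return group_effect_p(cell, transform=transform)
        except StatsError:
            return float("nan")

    effects = associative_effect(strengths, post_trials=config.post_trials,
                                 significance_fn=_sig)
    files["effects"] = write_table(effects, out / "effects.csv")
    log.info("quantify: associative effects for %d cells", len(effects))

    # --- pattern analysis ---------------------------------------------
    complete = [
        ts.fly_id for ts in trace_sets
        if all(c in ts.compartments for c in PATTERN_ORDER)
    ]
    pattern_windows = windows[windows.fly_id.isin(complete)]
    n_excluded = windows.fly_id.nunique() - len(complete)
    if n_excluded:
        log.info("patterns: excluded %d flies lacking a shared compartment",
                 n_excluded)
    if pattern_windows.empty:
        log.warning("patterns: no fly has all nine shared compartments; "
                    "writing empty course table")
        courses = pd.DataFrame(columns=["scheme", "metric", "genotype", "group",
                                        "trial", "mean", "sem", "n"])
    else:
        courses = all_courses(pattern_windows)
    files["pattern_courses"] = write_table(courses, out / "pattern_courses.csv")

    # --- statistics ---------------------------------------------------
    stat_rows = []
    for (genotype, comp), cell in strengths[strengths.stimulus == "CS"] \
            .groupby(["genotype", "compartment"]):
        transform = ("boxcox" if config.boxcox_dan and genotype == "DAN"
                     else None)
        try:
            for res in fit_group_model(cell, transform=transform,
                                       compartment=comp, genotype=genotype):
                stat_rows.append(dataclasses.asdict(res))
        except StatsError as err:
            log.warning("stats: (%s, %s) skipped: %s", genotype, comp, err)
    files["stats_group"] = write_table(
        pd.DataFrame(stat_rows), out / "stats_group.csv")

    # hemisphere comparison on raw per-hemisphere CS window means
    hemi_rows = []
    for fly in cohort:
        proto = protocols[fly.group]
        for side in fly.hemispheres:
            ts = process_recording(fly, proto, hemisphere=side,
                                   f0_frames=config.f0_frames,
                                   smooth_frames=config.peak_smooth_frames,
                                   norm_window=config.norm_window)
            tbl = cohort_strength_table([ts], protocols)
            tbl.insert(3, "hemisphere", side)
            hemi_rows.append(tbl)
    hemi = pd.concat(hemi_rows, ignore_index=True)
    hemi_stats = []
    for (genotype, comp), cell in hemi[hemi.stimulus == "CS"] \
            .groupby(["genotype", "compartment"]):
        try:
            res = hemisphere_test(cell, compartment=comp, genotype=genotype)
            hemi_stats.append(dataclasses.asdict(res))
        except StatsError:
            continue
    files["stats_hemisphere"] = write_table(
        pd.DataFrame(hemi_stats), out / "stats_hemisphere.csv")

    # shock-current dose-response per (genotype, compartment)
    corr_rows = []
    us = strengths[strengths.stimulus == "US"]
    current_lookup = {fly.fly_id: fly.shock_currents for fly in cohort}
    for (genotype, comp), cell in us.groupby(["genotype", "compartment"]):
        # pre-training-style dose response: each fly's first recorded US
        first = cell.loc[cell.groupby("fly_id")["trial"].idxmin()]
        vals = first.apply(
            lambda r: (r.window_mean,
                       current_lookup[r.fly_id].get(int(r.trial))), axis=1)
        pairs = [(v, c) for v, c in vals if c is not None]
        if len(pairs) < 3:
            continue
        s, c = map(np.array, zip(*pairs))
        try:
            res = shock_current_correlation(s, c, compartment=comp)
        except StatsError:
            continue
        corr_rows.append({"genotype": genotype,
                          **dataclasses.asdict(res)})
    files["shock_correlation"] = write_table(
        pd.DataFrame(corr_rows), out / "shock_correlation.csv")
    log.info("stats: group, hemisphere and dose-response tables written")

    # --- manifest ------------------------------------------------------
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_flies": len(cohort),
        "checksums": {name: _sha256(Path(p)) for name, p in files.items()},
        "elapsed_s": round(time.time() - t_start, 3),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
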