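"""End-to-end orchestration: cohort simulation, per-subject analysis,
group statistics, and reproducible reports.

The raw trace is conditioned twice, independently: the CSD chain
(0.005 Hz high-pass + 100 Hz low-pass) feeds DC-shift detection,
frequency and propagation speed; the epileptiform chain (0.5 Hz
high-pass + 100 Hz low-pass) feeds spike detection, bouts, onset, the
terminal class, severity, and the pairwise cross-correlations over the
terminal ten minutes.

Per-subject seeds derive from the master seed by a counter scheme
(``SeedSequence(master, spawn_key=(index,))``), so reruns with the same
configuration are bit-identical and subjects are mutually independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .csd import (CsdDetectParams, CsdSummary, assert_contralateral_silent,
                  csd_frequency, detect_csds, propagation_speed)
from .epileptiform import SpikeDetectParams, annotate_channel, is_generalized
from .exceptions import ChannelQualityError, CsdScopeError, UndefinedSpeedError
from .filters import apply_filter
from .recording import (CSD_FILTER, EPI_FILTER, GROUPS, Recording,
                        SubjectMeta)
from .simulate import SimParams, group_preset, sample_subject_params, \
    simulate_recording
from .stats import SubjectSummary, report_to_frame, run_study
from .xcorr import pairwise_xcorr

log = logging.getLogger("csdscope")

#: study design: subjects per genotype x group cell
DEFAULT_DESIGN = {
    ("WT", "male"): 8, ("WT", "female"): 8,
    ("WT", "aged_male"): 7, ("WT", "PM_female"): 7,
    ("G301R", "male"): 9, ("G301R", "female"): 9,
    ("G301R", "aged_male"): 9, ("G301R", "PM_female"): 9,
}


@dataclass
class StudyConfig:
    design: dict = field(default_factory=lambda: dict(DEFAULT_DESIGN))
    master_seed: int = 0
    duration_s: float = 3600.0
    fs: float = 300.0
    preset_overrides: dict = field(default_factory=dict)
    csd_params: CsdDetectParams = field(default_factory=CsdDetectParams)
    spike_params: SpikeDetectParams = field(default_factory=SpikeDetectParams)
    csd_count_channel: str = "S1_left"   # first to register each wave
    severity_channel: str = "M1_left"    # activity consistently starts here

    def provenance(self) -> dict:
        d = {"csdscope_version": __version__,
             "master_seed": self.master_seed,
             "duration_s": self.duration_s, "fs": self.fs,
             "design": {f"{g}/{grp}": n for (g, grp), n in self.design.items()},
             "preset_overrides": self.preset_overrides,
             "csd_params": dataclasses.asdict(self.csd_params),
             "spike_params": dataclasses.asdict(self.spike_params),
             "csd_count_channel": self.csd_count_channel,
             "severity_channel": self.severity_channel}
        blob = json.dumps(d, sort_keys=True, default=str)
        d["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return d


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed from the master seed and a counter."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def analyze_subject(rec: Recording,
                    csd_params: CsdDetectParams = CsdDetectParams(),
                    spike_params: SpikeDetectParams = SpikeDetectParams(),
                    csd_count_channel: str = "S1_left",
                    severity_channel: str = "M1_left") -> SubjectSummary:
    """Run the full per-subject analysis chain on one recording."""
    t_start = time.perf_counter()
    meta = rec.subject or SubjectMeta(subject_id="anonymous")
    summary = SubjectSummary(meta=meta)

    # channel QC: a flat channel excludes the subject from xcorr analyses
    flat = [role for role in rec.channels
            if np.ptp(rec.channel(role)) <= 1e-12]
    if flat:
        summary.excluded = True
        summary.flags["bad_channels"] = flat

    # --- CSD chain ---
    events = {}
    for role in ("M1_left", "S1_left", "M1_right"):
        if role in flat:
            events[role] = []
            continue
        dc = apply_filter(rec.channel(role), rec.fs, CSD_FILTER)
        events[role] = detect_csds(dc, rec.fs, csd_params, channel=role)
    summary.csd_frequency_per_hr = csd_frequency(
        events[csd_count_channel], rec.duration_s)
    summary.flags["contralateral_silent"] = assert_contralateral_silent(
        events["M1_right"])
    try:
        summary.propagation_speed_mm_per_min = propagation_speed(
            events["M1_left"], events["S1_left"])
    except UndefinedSpeedError as exc:
        summary.propagation_speed_mm_per_min = None
        summary.flags["speed_undefined"] = str(exc)

    # --- epileptiform chain ---
    # spike annotations are needed on the reference channel (onset, class,
    # severity) and contralaterally (generalization check); the remaining
    # channel is conditioned only for the cross-correlation stage
    annotations = {}
    hp_data = {}
    for role in ("M1_left", "S1_left", "M1_right"):
        if role in flat:
            continue
        hp = apply_filter(rec.channel(role), rec.fs, EPI_FILTER)
        hp_data[role] = hp
        if role in (severity_channel, "M1_left", "M1_right"):
            annotations[role] = annotate_channel(
                hp, rec.fs, channel=role, params=spike_params,
                compute_severity=(role == severity_channel))
    ref = annotations.get(severity_channel)
    if ref is not None:
        summary.epi_onset_s = ref.onset_s
        summary.epi_class = ref.activity_class
        summary.severity = ref.severity
        if "M1_left" in annotations and "M1_right" in annotations:
            summary.flags["generalized"] = is_generalized(annotations)

    # --- cross-correlation over the terminal window (reuse the filtered
    # traces rather than conditioning the recording a second time) ---
    if not summary.excluded:
        try:
            hp_rec = rec.copy_with(
                data=np.vstack([hp_data[r] for r in rec.channels]))
            results = pairwise_xcorr(hp_rec, prefiltered=True)
            summary.xcorr_coeffs = {f"{a}|{b}": r.max_coeff
                                    for (a, b), r in
                                    ((r.pair, r) for r in results)}
            summary.xcorr_lags = {f"{r.pair[0]}|{r.pair[1]}": r.lag_s
                                  for r in results}
        except ChannelQualityError as exc:
            summary.excluded = True
            summary.flags["xcorr_excluded"] = str(exc)

    log.info("analyze_subject subject=%s duration=%.2fs outcome=%s",
             meta.subject_id, time.perf_counter() - t_start,
             "excluded" if summary.excluded else "ok")
    return summary


def build_cohort_params(config: StudyConfig
                        ) -> list[tuple[SubjectMeta, SimParams]]:
    """Expand a study design into per-subject simulator parameters."""
    out = []
    idx = 0
    for (genotype, group), n in sorted(config.design.items()):
        preset = group_preset(genotype, group)
        preset = preset.replace(duration_s=config.duration_s, fs=config.fs,
                                **config.preset_overrides.get(
                                    f"{genotype}/{group}", {}))
        for j in range(n):
            seed = subject_seed(config.master_seed, idx)
            rng = np.random.default_rng(seed)
            params = sample_subject_params(preset, rng, genotype)
            meta = SubjectMeta(subject_id=f"{genotype}_{group}_{j:02d}",
                               genotype=genotype, group=group)
            out.append((meta, params))
            idx += 1
    return out


def run_cohort(config: StudyConfig) -> dict:
    """Simulate and analyze a whole cohort; return the report bundle.

    The bundle holds per-subject summaries, the statistical report, and a
    provenance block (seeds, parameter values, config hash); identical
    configurations reproduce it bit-for-bit.
    """
    t_start = time.perf_counter()
    summaries: list[SubjectSummary] = []
    failures: list[dict] = []
    for meta, params in build_cohort_params(config):
        try:
            rec, _truth = simulate_recording(params, subject=meta)
            summaries.append(analyze_subject(
                rec, config.csd_params, config.spike_params,
                config.csd_count_channel, config.severity_channel))
        except CsdScopeError as exc:  # keep going, report per subject
            failures.append({"subject": meta.subject_id, "error": str(exc)})
            log.warning("subject %s failed: %s", meta.subject_id, exc)
    report = run_study(summaries)
    bundle = {"provenance": config.provenance(),
              "subjects": [s.to_dict() for s in summaries],
              "failures": failures,
              "study": report,
              "runtime_s": time.perf_counter() - t_start}
    return bundle


def bundle_to_json(bundle: dict) -> str:
    """Serialize a report bundle (TestResult objects included) to JSON."""
    from .stats import TestResult

    def default(o):
        if isinstance(o, TestResult):
            return o.to_dict()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(bundle, indent=2, default=default)


def bundle_tables(bundle: dict):
    """Tidy DataFrame of every test in the bundle's study report."""
    return report_to_frame(bundle["study"])


def design_effect_pattern(report: dict) -> dict:
    """Which of the cohort design's group effects the battery recovered.

    Checks the three headline effects: every per-group wild-type vs mutant
    frequency comparison significant, the post-menopausal-female reduction
    within mutants detected by the Kruskal-Wallis + Dunn family, and every
    per-group speed comparison significant.
    """
    freq = report["tests"].get("csd_frequency_wt_vs_mut", [])
    all_freq = len(freq) == 4 and all(t.significant for t in freq)
    speed = report["tests"].get("propagation_speed_wt_vs_mut", [])
    all_speed = len(speed) == 4 and all(t.significant for t in speed)
    pm = False
    sec = report["tests"].get("csd_frequency_G301R_groups")
    if sec and sec["kruskal_wallis"].significant:
        rows = [d for d in sec["dunn"] if "PM_female" in d.comparison]
        pm = len(rows) == 3 and all(d.significant for d in rows)
    return {"frequency_wt_vs_mut_all_significant": all_freq,
            "pm_female_reduction_detected": pm,
            "speed_wt_vs_mut_all_significant": all_speed}
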