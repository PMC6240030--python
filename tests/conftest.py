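import numpy as np
import pytest

import csdscope as cs
from csdscope.filters import apply_filter
from csdscope.recording import CSD_FILTER, EPI_FILTER


@pytest.fixture(scope="session")
def default_g301r_sim():
    """One default mutant recording with ground truth (expensive; shared)."""
    params = cs.group_preset("G301R", "female", seed=7)
    rec, truth = cs.simulate_recording(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def g301r_filtered(default_g301r_sim):
    """DC- and spike-band conditioned traces of the shared recording."""
    _, rec, _ = default_g301r_sim
    dc = {r: apply_filter(rec.channel(r), rec.fs, CSD_FILTER)
          for r in rec.channels}
    hp = {r: apply_filter(rec.channel(r), rec.fs, EPI_FILTER)
          for r in rec.channels}
    return dc, hp


@pytest.fixture(scope="session")
def noise_only_sim():
    """A 25-minute noise-only recording (no CSDs, no spikes)."""
    params = cs.SimParams(csd_rate_per_hr=0.0, epi_escalation="none",
                          epi_onset_s=None, duration_s=1500.0, seed=42)
    rec, truth = cs.simulate_recording(params)
    return params, rec, truth


def match_events(detected, truth, tol):
    """Greedy one-to-one matching; returns (n_matched, recall, precision)."""
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for t in detected:
        if truth.size == 0:
            break
        d = np.abs(truth - t)
        j = int(np.argmin(np.where(used, np.inf, d)))
        if not used[j] and d[j] <= tol:
            used[j] = True
            tp += 1
    recall = tp / truth.size if truth.size else float("nan")
    precision = tp / detected.size if detected.size else float("nan")
    return tp, recall, precision
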