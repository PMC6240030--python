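"""The study-level statistical battery.

Per-subject summaries (CSD frequency and propagation speed, epileptiform
onset, terminal class, severity, cross-correlation peaks) are compared
with the nonparametric battery this design calls for: Mann-Whitney U
between wild-type and mutant cells, Kruskal-Wallis across groups with
Dunn's multiple comparisons (Bonferroni corrected) after a significant
omnibus, ordinary-least-squares slope t-tests for the severity/onset vs
frequency relations, and paired t-tests on the three channel-pair
cross-correlation metrics.  All tests are two-tailed at alpha = 0.05.

Mann-Whitney U is reported as the larger of the two U values, the
convention under which complete separation of samples of sizes n1 and n2
prints U = n1*n2 (e.g. 72 for 8 vs 9).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .exceptions import DegenerateDataError
from .recording import GROUPS, SubjectMeta

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float | tuple | None
    p_value: float
    comparison: str = ""
    n: tuple | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "df": self.df, "p_value": self.p_value,
                "comparison": self.comparison, "n": self.n,
                "corrected": self.corrected}


@dataclass
class SubjectSummary:
    """One animal's derived quantities, the unit of the group analysis."""

    meta: SubjectMeta
    csd_frequency_per_hr: float = 0.0
    propagation_speed_mm_per_min: float | None = None
    epi_onset_s: float | None = None
    epi_class: str = "none"
    severity: float | None = None
    xcorr_coeffs: dict | None = None   # pair-name -> max coefficient
    xcorr_lags: dict | None = None     # pair-name -> lag (s)
    excluded: bool = False
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"meta": self.meta.to_dict(),
                "csd_frequency_per_hr": self.csd_frequency_per_hr,
                "propagation_speed_mm_per_min": self.propagation_speed_mm_per_min,
                "epi_onset_s": self.epi_onset_s, "epi_class": self.epi_class,
                "severity": self.severity, "xcorr_coeffs": self.xcorr_coeffs,
                "xcorr_lags": self.xcorr_lags, "excluded": self.excluded,
                "flags": self.flags}


# ------------------------------------------------------------- primitives

def mann_whitney_u(a, b, comparison: str = "") -> TestResult:
    """Two-tailed Mann-Whitney U with midrank ties.

    The p-value is exact (full enumeration) for small samples without
    ties, otherwise a tie-corrected normal approximation with continuity
    correction.  The statistic is the larger of U(a,b) and U(b,a), so
    complete separation yields ``n1 * n2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both samples must be non-empty")
    has_ties = np.unique(np.r_[a, b]).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 25 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = max(u1, a.size * b.size - u1)
    return TestResult(test="Mann-Whitney U", statistic=u,
                      df=(int(a.size), int(b.size)),
                      p_value=min(float(res.pvalue), 1.0),
                      comparison=comparison, n=(int(a.size), int(b.size)))


def kruskal_wallis(groups, comparison: str = "") -> TestResult:
    """Kruskal-Wallis H with tie correction; df = k - 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise DegenerateDataError("need >= 2 non-empty groups")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(test="Kruskal-Wallis", statistic=0.0, df=k - 1,
                          p_value=1.0, comparison=comparison,
                          n=tuple(int(g.size) for g in groups))
    h, p = scipy.stats.kruskal(*groups)
    return TestResult(test="Kruskal-Wallis", statistic=float(h), df=k - 1,
                      p_value=float(p), comparison=comparison,
                      n=tuple(int(g.size) for g in groups))


def dunn_bonferroni(groups, labels=None) -> list[TestResult]:
    """Dunn's post-hoc z tests on mean-rank differences, Bonferroni corrected.

    For each unordered pair (i, j):
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` with
    tie correction ``T = sum(t^3 - t) / (12 (N - 1))``; each two-sided p is
    multiplied by the number of pairs and capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DegenerateDataError("need >= 2 groups for post-hoc comparisons")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(groups))]
    N = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(2.0 * scipy.stats.norm.sf(abs(z)) * m, 1.0)
        out.append(TestResult(
            test="Dunn (Bonferroni)", statistic=float(z),
            df=None, p_value=float(p),
            comparison=f"{labels[i]} vs {labels[j]}",
            n=(int(sizes[i]), int(sizes[j])), corrected=True))
    return out


def linear_regression_t(x, y, comparison: str = "") -> TestResult:
    """OLS slope with t = slope / SE, df = n - 2, two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant: slope undefined")
    res = scipy.stats.linregress(x, y)
    if res.stderr == 0:
        t, p = math.inf * math.copysign(1, res.slope), 0.0
    else:
        t = res.slope / res.stderr
        p = float(res.pvalue)
    return TestResult(test="linear regression (slope t)", statistic=float(t),
                      df=x.size - 2, p_value=p, comparison=comparison,
                      n=(int(x.size),))


def paired_t(a, b, comparison: str = "") -> TestResult:
    """Paired t-test on differences; df = n - 1, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise DegenerateDataError("need equal-length samples with n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            raise DegenerateDataError("all paired differences are zero")
        return TestResult(test="paired t", statistic=math.copysign(math.inf, d[0]),
                          df=a.size - 1, p_value=0.0, comparison=comparison,
                          n=(int(a.size),))
    import warnings

    with warnings.catch_warnings():
        # near-constant differences (e.g. lags quantized to the sample
        # grid) trip scipy's catastrophic-cancellation warning; the test
        # itself is well-defined, exact-constant shifts are handled above
        warnings.filterwarnings("ignore", "Precision loss occurred",
                                RuntimeWarning)
        res = scipy.stats.ttest_rel(a, b)
    return TestResult(test="paired t", statistic=float(res.statistic),
                      df=a.size - 1, p_value=float(res.pvalue),
                      comparison=comparison, n=(int(a.size),))


# ------------------------------------------------------------ study battery

def _values(subjects, attr):
    out = []
    for s in subjects:
        v = getattr(s, attr)
        if v is not None and np.isfinite(v):
            out.append(v)
    return np.asarray(out, dtype=float)


def run_study(cohort: list[SubjectSummary]) -> dict:
    """Run the full statistical battery over a cohort of subjects.

    Returns a report dict with one section per result family:
    CSD susceptibility (frequency), propagation speed,
    epileptiform onset (wild types pooled), the severity/onset
    regressions over mutant subjects, and paired comparisons of the
    cross-correlation metrics.  Tests on empty cells are skipped with a
    reason.
    """
    usable = [s for s in cohort if not s.excluded]
    report: dict = {"n_subjects": len(cohort),
                    "n_excluded": len(cohort) - len(usable),
                    "skipped": [], "tests": {}}

    def cell(genotype, group):
        return [s for s in usable if s.meta.genotype == genotype
                and s.meta.group == group]

    # --- WT vs G301R Mann-Whitney per group, frequency and speed ---
    for metric, attr in (("csd_frequency", "csd_frequency_per_hr"),
                         ("propagation_speed", "propagation_speed_mm_per_min")):
        rows = []
        for group in GROUPS:
            wt = _values(cell("WT", group), attr)
            mut = _values(cell("G301R", group), attr)
            label = f"WT {group} vs G301R {group}"
            if wt.size == 0 or mut.size == 0:
                report["skipped"].append(f"{metric}: {label}: empty cell")
                continue
            rows.append(mann_whitney_u(wt, mut, comparison=label))
        report["tests"][f"{metric}_wt_vs_mut"] = rows

    # --- within-genotype 4-group Kruskal-Wallis + Dunn ---
    for metric, attr in (("csd_frequency", "csd_frequency_per_hr"),
                         ("propagation_speed", "propagation_speed_mm_per_min")):
        for genotype in ("WT", "G301R"):
            gvals = [_values(cell(genotype, g), attr) for g in GROUPS]
            key = f"{metric}_{genotype}_groups"
            if any(v.size == 0 for v in gvals):
                report["skipped"].append(f"{key}: empty cell")
                continue
            kw = kruskal_wallis(gvals, comparison=f"{genotype} groups ({metric})")
            section = {"kruskal_wallis": kw, "dunn": []}
            if kw.significant:
                section["dunn"] = dunn_bonferroni(
                    gvals, labels=[f"{genotype} {g}" for g in GROUPS])
            report["tests"][key] = section

    # --- epileptiform onset: pooled WT + the four G301R cells ---
    wt_onsets = _values([s for s in usable if s.meta.genotype == "WT"],
                        "epi_onset_s")
    onset_groups = [wt_onsets]
    onset_labels = ["WT (pooled)"]
    for g in GROUPS:
        onset_groups.append(_values(cell("G301R", g), "epi_onset_s"))
        onset_labels.append(f"G301R {g}")
    n_no_onset = sum(1 for s in usable if s.epi_onset_s is None)
    report["n_without_epileptiform_onset"] = n_no_onset
    if all(v.size > 0 for v in onset_groups):
        kw = kruskal_wallis(onset_groups, comparison="epileptiform onset")
        section = {"kruskal_wallis": kw, "dunn": []}
        if kw.significant:
            section["dunn"] = dunn_bonferroni(onset_groups, labels=onset_labels)
        report["tests"]["epi_onset_groups"] = section
    else:
        report["skipped"].append("epi_onset_groups: empty cell after excluding "
                                 "subjects without epileptiform activity")

    # --- regressions over G301R subjects only ---
    muts = [s for s in usable if s.meta.genotype == "G301R"]
    regs = {}
    pairs = (("severity_vs_frequency", "csd_frequency_per_hr", "severity"),
             ("onset_vs_frequency", "csd_frequency_per_hr", "epi_onset_s"),
             ("severity_vs_onset", "epi_onset_s", "severity"))
    for key, xattr, yattr in pairs:
        pts = [(getattr(s, xattr), getattr(s, yattr)) for s in muts
               if getattr(s, xattr) is not None and getattr(s, yattr) is not None]
        if len(pts) < 3:
            report["skipped"].append(f"regression {key}: n < 3")
            continue
        x, y = map(np.asarray, zip(*pts))
        try:
            regs[key] = linear_regression_t(x, y, comparison=key)
        except DegenerateDataError as exc:
            report["skipped"].append(f"regression {key}: {exc}")
    report["tests"]["regressions_g301r"] = regs

    # --- paired t on cross-correlation peaks and their (absolute) lags ---
    withx = [s for s in muts if s.xcorr_coeffs and s.xcorr_lags]
    xsec = {}
    if len(withx) >= 2:
        pair_names = list(withx[0].xcorr_coeffs)
        for metric, getter in (
                ("max_coeff", lambda s, pn: s.xcorr_coeffs[pn]),
                ("abs_lag", lambda s, pn: abs(s.xcorr_lags[pn]))):
            rows = []
            for pa, pb in itertools.combinations(pair_names, 2):
                a = [getter(s, pa) for s in withx]
                b = [getter(s, pb) for s in withx]
                try:
                    rows.append(paired_t(a, b, comparison=f"{pa} vs {pb}"))
                except DegenerateDataError as exc:
                    report["skipped"].append(f"paired t {metric} {pa}/{pb}: {exc}")
            xsec[metric] = rows
    else:
        report["skipped"].append("xcorr paired tests: fewer than 2 subjects "
                                 "with cross-correlation results")
    report["tests"]["xcorr_paired"] = xsec
    return report


def report_to_frame(report: dict):
    """Flatten a study report into a tidy DataFrame of test rows."""
    import pandas as pd

    rows = []

    def add(section, tr: TestResult):
        rows.append({"section": section, **tr.to_dict()})

    for key, val in report["tests"].items():
        if isinstance(val, list):
            for tr in val:
                add(key, tr)
        elif isinstance(val, dict):
            for sub, v in val.items():
                if isinstance(v, TestResult):
                    add(f"{key}.{sub}", v)
                elif isinstance(v, list):
                    for tr in v:
                        add(f"{key}.{sub}", tr)
    return pd.DataFrame(rows)
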