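"""Repeatability and group statistics for TSC measurement tables.

Works on long-format tables (subject, group, muscle, session, tsc). Provides
the two-way ICC family with F-based confidence intervals, Bland-Altman
limits of agreement, the Friedman test across muscles with an exact
permutation p-value, and exact Wilcoxon signed-rank / rank-sum tests whose
null distributions are enumerated by dynamic programming over (mid)rank
sums — feasible exactly because ranks are small integers (or half-integers).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

MUSCLES = ("GM", "TA", "S")
SESSIONS = ("M1", "M2", "M3")


# ---------------------------------------------------------------------------
# Measurement table helpers
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "muscle", "session", "tsc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    dup = table.duplicated(["subject", "muscle", "session"])
    if dup.any():
        raise ValueError("duplicate (subject, muscle, session) keys")
    return table


def subject_session_matrix(table: pd.DataFrame, muscle: str) -> np.ndarray:
    """Complete n_subjects x k_sessions matrix for one muscle."""
    sub = validate_table(table)[table.muscle == muscle]
    mat = sub.pivot(index="subject", columns="session", values="tsc")
    if mat.isna().any().any():
        raise ValueError(f"incomplete sessions for muscle {muscle!r}; no imputation")
    return mat.to_numpy(dtype=float)


def session_mean_by_muscle(table: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Per-subject value per muscle, averaged over sessions."""
    t = validate_table(table)
    if group is not None:
        t = t[t.group == group]
    wide = t.groupby(["subject", "muscle"])["tsc"].mean().unstack("muscle")
    return wide[list(MUSCLES)]


# ---------------------------------------------------------------------------
# ICC (two-way, subjects x sessions)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ICCResult:
    variant: str
    value: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k_sessions: int


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_twoway(x: np.ndarray | pd.DataFrame, variant: str = "Ck",
               confidence: float = 0.95) -> ICCResult:
    """Two-way (subjects x sessions) intraclass correlation.

    Variants: A1/Ak absolute agreement (single / average of k measures),
    C1/Ck consistency (single / average). Ck equals 1 - MSE/MSR, the
    average-measures consistency coefficient. Confidence intervals are
    F-based: exact for C1/Ck, the standard approximation for A1/Ak.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete n x k matrix with n >= 2, k >= 2")
    if np.isnan(x).any():
        raise ValueError("missing cells; no imputation")
    n, k = x.shape
    msr, msc, mse = _two_way_mean_squares(x)
    alpha = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)

    if variant == "C1":
        value = (msr - mse) / (msr + (k - 1) * mse)
    elif variant == "Ck":
        value = 1.0 - mse / msr if msr > 0 else 0.0
    elif variant == "A1":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    elif variant == "Ak":
        value = (msr - mse) / (msr + (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")

    if variant in ("C1", "Ck"):
        f_obs = msr / mse if mse > 0 else np.inf
        if not np.isfinite(f_obs):
            ci = (1.0, 1.0)
        else:
            fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
            if variant == "C1":
                ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
            else:
                ci = (1 - 1 / fl, 1 - 1 / fu)
    else:
        # McGraw & Wong approximate (Satterthwaite) CI for absolute agreement
        r1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        if r1 < 1:
            a = (k * r1) / (n * (1 - r1))
            b = 1 + (k * r1 * (n - 1)) / (n * (1 - r1))
            v = ((a * msc + b * mse) ** 2) / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
        else:
            v = df2
        fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
        fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
        if variant == "Ak":
            # Spearman-Brown step-up of the single-measures bounds
            lo = k * lo / (1 + (k - 1) * lo)
            hi = k * hi / (1 + (k - 1) * hi)
        ci = (lo, hi)
    return ICCResult(variant=variant, value=float(value), ci_low=float(ci[0]),
                     ci_high=float(ci[1]), msr=msr, msc=msc, mse=mse,
                     n_subjects=n, k_sessions=k)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AgreementResult:
    pair: str
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    fraction_within: float
    n: int


def bland_altman(table: pd.DataFrame, muscle: str,
                 session_pair: tuple[str, str]) -> AgreementResult:
    """Limits of agreement (mean +- 1.96 sd of paired differences) between
    two sessions for one muscle."""
    t = validate_table(table)[table.muscle == muscle]
    a = t[t.session == session_pair[0]].set_index("subject")["tsc"]
    b = t[t.session == session_pair[1]].set_index("subject")["tsc"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("Bland-Altman needs at least 3 paired subjects")
    d = (a.loc[common] - b.loc[common]).to_numpy(dtype=float)
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi))) if sd > 0 else 1.0
    return AgreementResult(pair=f"{session_pair[0]}-vs-{session_pair[1]}",
                           mean_diff=mean, sd_diff=sd, loa_low=float(lo),
                           loa_high=float(hi), fraction_within=within, n=len(d))


def bland_altman_plot(table: pd.DataFrame, muscle: str,
                      session_pair: tuple[str, str], path=None):
    """Standard Bland-Altman scatter with mean and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = validate_table(table)[table.muscle == muscle]
    a = t[t.session == session_pair[0]].set_index("subject")["tsc"]
    b = t[t.session == session_pair[1]].set_index("subject")["tsc"]
    common = a.index.intersection(b.index)
    res = bland_altman(table, muscle, session_pair)
    fig, axp = plt.subplots(figsize=(4, 3))
    avg = (a.loc[common] + b.loc[common]) / 2
    diff = a.loc[common] - b.loc[common]
    axp.scatter(avg, diff, s=18)
    for yv, ls in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        axp.axhline(yv, color="k", linestyle=ls, linewidth=0.8)
    axp.set_xlabel("mean TSC (mmol/L)")
    axp.set_ylabel(f"{session_pair[0]} - {session_pair[1]} (mmol/L)")
    axp.set_title(f"{muscle}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Exact nonparametric tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TestResult:
    method: str
    statistic: float
    p_exact: float | None
    p_asymptotic: float
    correction: str = "none"
    n: int = 0

    @property
    def p(self) -> float:
        return self.p_exact if self.p_exact is not None else self.p_asymptotic


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _signed_rank_null_cdf(ranks2: np.ndarray):
    """Distribution of W+ (doubled ranks, integers) over all sign flips,
    by generating-polynomial DP. Returns counts indexed by doubled sum."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x, y=None, mode: str = "exact",
                         m_comparisons: int = 1) -> TestResult:
    """Paired Wilcoxon signed-rank test with an exactly enumerated null.

    Zero differences are dropped (standard convention), ties get midranks.
    The exact two-sided p enumerates all 2^n sign assignments via the
    rank-sum generating polynomial; the asymptotic p uses the tie-corrected
    normal approximation. ``m_comparisons`` applies a Bonferroni factor.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("signed_rank", 0.0, 1.0, 1.0,
                          "bonferroni" if m_comparisons > 1 else "none", 0)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # asymptotic (tie-corrected normal)
    mu = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
    z = (w_plus - mu) / math.sqrt(var) if var > 0 else 0.0
    p_asym = min(1.0, 2.0 * sps.norm.sf(abs(z)))

    p_exact = None
    if mode == "exact" and n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_null_cdf(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        p_exact = min(1.0, 2.0 * min(cdf, sf))
    elif mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")

    corr = "bonferroni" if m_comparisons > 1 else "none"
    if m_comparisons > 1:
        p_asym = min(1.0, m_comparisons * p_asym)
        if p_exact is not None:
            p_exact = min(1.0, m_comparisons * p_exact)
    return TestResult("signed_rank", w_plus, p_exact, p_asym, corr, n)


def _rank_sum_null_counts(ranks2: np.ndarray, n2: int):
    """Counts of (number chosen, doubled rank sum) over all subsets, DP."""
    total = int(ranks2.sum())
    counts = np.zeros((n2 + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        upd = counts.copy()
        upd[1:, r:] += counts[:-1, : total + 1 - r]
        counts = upd
    return counts[n2]


def wilcoxon_rank_sum(a, b, mode: str = "exact") -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    The exact null enumerates all C(n1+n2, n2) group assignments through a
    subset-sum DP on doubled midranks (feasible whenever the count is at
    most ~1e6, which covers the study's sample sizes); otherwise, and for
    ``mode='asymptotic'``, the tie-corrected normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    w = float(ranks[n1:].sum())   # rank sum of the second group
    mu = n2 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    ties = np.unique(ranks, return_counts=True)[1]
    tie_term = ((ties**3 - ties).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (w - mu) / math.sqrt(var) if var > 0 else 0.0
    p_asym = min(1.0, 2.0 * sps.norm.sf(abs(z)))

    p_exact = None
    if mode == "exact" and math.comb(n, n2) <= 10**6:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _rank_sum_null_counts(ranks2, n2)
        total = counts.sum()
        w2 = int(round(2 * w))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        p_exact = min(1.0, 2.0 * min(cdf, sf))
    elif mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult("rank_sum", w, p_exact, p_asym, "none", n)


def friedman_test(values: np.ndarray, mode: str = "exact") -> TestResult:
    """Friedman test across k related conditions (columns) for n subjects.

    Statistic: chi2 = 12/(n k (k+1)) sum_j R_j^2 - 3 n (k+1) with midranks
    within subjects. The exact p enumerates the joint null distribution of
    the column rank sums by per-subject dynamic programming over all
    permutations of each subject's (possibly tied) rank vector; the
    asymptotic p applies the usual tie-corrected chi-square.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an n x k block, k >= 2")
    n, k = x.shape
    if np.allclose(x, x[:, [0]]):   # no variation across conditions
        return TestResult("friedman", 0.0, 1.0, 1.0, "none", n)
    ranks = np.apply_along_axis(_midranks, 1, x)
    rsum = ranks.sum(axis=0)

    def statistic(col_sums):
        return (12.0 / (n * k * (k + 1))) * np.sum(np.asarray(col_sums) ** 2) \
            - 3.0 * n * (k + 1)

    stat = float(statistic(rsum))
    # tie correction for the asymptotic chi-square
    tie_sum = 0.0
    for row in x:
        _, cts = np.unique(row, return_counts=True)
        tie_sum += (cts**3 - cts).sum()
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1))
    stat_corr = stat / denom if denom > 0 else 0.0
    p_asym = float(sps.chi2.sf(stat_corr, k - 1)) if denom > 0 else 1.0

    p_exact = None
    if mode == "exact":
        # joint distribution of the first k-1 doubled column sums
        dist = {tuple([0] * (k - 1)): 1.0}
        for row in ranks:
            row2 = np.rint(2 * row).astype(int)
            perms = {p[: k - 1] for p in itertools.permutations(tuple(row2))}
            new: dict = {}
            for state, cnt in dist.items():
                for p in perms:
                    key = tuple(s + v for s, v in zip(state, p))
                    new[key] = new.get(key, 0.0) + cnt
            dist = new
        total_all = 2 * ranks.sum()   # doubled grand rank total per dataset
        ge = 0.0
        tot = 0.0
        for state, cnt in dist.items():
            sums = list(s / 2.0 for s in state)
            sums.append((total_all - sum(state)) / 2.0)
            tot += cnt
            if statistic(sums) >= stat - 1e-12:
                ge += cnt
        p_exact = ge / tot
    elif mode != "asymptotic":
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult("friedman", stat, p_exact, p_asym, "none", n)


def pairwise_signed_rank(wide: pd.DataFrame, mode: str = "exact") -> dict:
    """All pairwise signed-rank tests between columns with Bonferroni
    correction for the number of pairs."""
    cols = list(wide.columns)
    m = len(cols) * (len(cols) - 1) // 2
    out = {}
    for i, j in itertools.combinations(range(len(cols)), 2):
        out[f"{cols[i]}-vs-{cols[j]}"] = wilcoxon_signed_rank(
            wide[cols[i]].to_numpy(), wide[cols[j]].to_numpy(),
            mode=mode, m_comparisons=m,
        )
    return out


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (report display convention)."""
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
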