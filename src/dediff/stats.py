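"""Behavioral scoring and inferential statistics.

Implements the small set of tests the analyses rely on: pooled-variance
independent t, paired t, a classical balanced mixed (split-plot) ANOVA with
one between-subject and one within-subject factor, and Bonferroni
thresholds.  The ANOVA uses the textbook sums-of-squares partition so its
2-level within-factor F equals the square of the paired t on the level
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

RESPONSE_OLD = "old"
RESPONSE_NEW = "new"
NO_RESPONSE = "none"

#: (status, response) -> outcome
OUTCOME_TABLE = {
    ("intact", RESPONSE_OLD): "hit",
    ("intact", RESPONSE_NEW): "miss",
    ("recombined", RESPONSE_NEW): "CR",
    ("recombined", RESPONSE_OLD): "FA",
}


@dataclass
class BehavioralSummary:
    """Per-subject trial counts and rates from the test phase."""

    counts: dict[str, int]
    n_intact: int
    n_recombined: int
    p_hit: float
    p_cr: float
    p_fa: float
    p_miss: float
    corrected_recognition: float
    denominator: str = "presented"


def classify_outcome(status: str, response: str) -> str:
    if response == NO_RESPONSE:
        return "no-response"
    key = (status, response)
    if key not in OUTCOME_TABLE:
        raise ValueError(f"unknown status/response combination {key!r}")
    return OUTCOME_TABLE[key]


def score_behavior(test_events: pd.DataFrame, denominator: str = "presented") -> BehavioralSummary:
    """Score test-phase events into hits/CRs/FAs/misses/no-responses.

    ``denominator`` controls the rate denominators: ``"presented"`` counts
    no-responses against accuracy (rates over all presented trials of a
    status); ``"responded"`` excludes them.
    """
    if denominator not in ("presented", "responded"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    counts = {"hit": 0, "miss": 0, "CR": 0, "FA": 0, "no-response": 0}
    n_intact = n_recomb = 0
    nr_intact = nr_recomb = 0
    for status, response in zip(test_events["status"], test_events["response"]):
        outcome = classify_outcome(status, response)
        counts[outcome] += 1
        if status == "intact":
            n_intact += 1
            nr_intact += outcome == "no-response"
        else:
            n_recomb += 1
            nr_recomb += outcome == "no-response"
    d_int = n_intact - (nr_intact if denominator == "responded" else 0)
    d_rec = n_recomb - (nr_recomb if denominator == "responded" else 0)
    if d_int == 0 or d_rec == 0:
        raise ValueError("no scorable trials for at least one pair status")
    p_hit = counts["hit"] / d_int
    p_fa = counts["FA"] / d_rec
    return BehavioralSummary(
        counts=counts,
        n_intact=n_intact,
        n_recombined=n_recomb,
        p_hit=p_hit,
        p_cr=counts["CR"] / d_rec,
        p_fa=p_fa,
        p_miss=counts["miss"] / d_int,
        corrected_recognition=p_hit - p_fa,
        denominator=denominator,
    )


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float | None = None


def independent_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> TTestResult:
    """Independent-samples t from summary statistics (pooled by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("group SDs must be non-negative and not both zero")
    diff = mean1 - mean2
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return TTestResult(t=float(t), df=float(df), p=float(p), cohen_d=float(diff / sp))


def independent_t_from_data(a, b, welch: bool = False) -> TTestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return independent_t(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, welch=welch)


def paired_t(a, b) -> TTestResult:
    """Paired-samples t on two equal-length value vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired t needs two equal-length vectors, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=float(n - 1), p=float(p),
                       cohen_d=float(d.mean() / sd) if sd > 0 else None)


def one_sample_t(a, popmean: float = 0.0) -> TTestResult:
    a = np.asarray(a, float)
    return paired_t(a, np.full(a.shape, popmean))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-test alpha for ``m`` tests: alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "subject",
    between: str = "group",
) -> pd.DataFrame:
    """Balanced mixed (split-plot) ANOVA: one between factor, one within.

    Every subject must have exactly one value at every within level
    (missing cells raise).  Returns a table with rows for the between
    effect, the within effect, their interaction, and the two error strata.
    """
    df = data.loc[:, [subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in dv")
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv,
                          aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every within level")
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("duplicate subject x level cells")

    y = wide.to_numpy(float)  # subjects x levels
    groups = wide.index.get_level_values(between).to_numpy()
    glabels = pd.unique(groups)
    n_subj, k = y.shape
    g = len(glabels)
    ns = np.array([(groups == gl).sum() for gl in glabels])
    if ns.min() < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[groups == gl].mean() for gl in glabels])
    level_means = y.mean(axis=0)

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (ns * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group

    # within-levels partition; cell means weighted by group sizes
    ss_level = n_subj * ((level_means - grand) ** 2).sum()
    ss_inter = 0.0
    for gi, gl in enumerate(glabels):
        cell = y[groups == gl].mean(axis=0)
        ss_inter += ns[gi] * ((cell - group_means[gi] - level_means + grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subj - ss_level - ss_inter

    df_group, df_subj = g - 1, n_subj - g
    df_level, df_inter = k - 1, (g - 1) * (k - 1)
    df_err = (n_subj - g) * (k - 1)

    def row(name, ss, dfx, ss_err, df_err_x):
        ms = ss / dfx
        mse = ss_err / df_err_x
        f = ms / mse if mse > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(f, dfx, df_err_x)) if np.isfinite(f) else 0.0
        return {"effect": name, "ss": ss, "df": dfx, "ms": ms, "F": f, "p": p}

    rows = []
    if g > 1:
        rows.append(row(between, ss_group, df_group, ss_subj_within, df_subj))
    rows.append(
        {"effect": f"subjects({between})", "ss": ss_subj_within, "df": df_subj,
         "ms": ss_subj_within / df_subj, "F": np.nan, "p": np.nan}
    )
    rows.append(row(within, ss_level, df_level, ss_err_within, df_err))
    if g > 1:
        rows.append(row(f"{between} * {within}", ss_inter, df_inter,
                        ss_err_within, df_err))
    rows.append(
        {"effect": f"error({within})", "ss": ss_err_within, "df": df_err,
         "ms": ss_err_within / df_err, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)
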