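"""Nonparametric group-comparison battery for the skill metrics.

The study's analysis plan: a Kolmogorov-Smirnov normality screen (which
rejected normality, motivating nonparametrics), Friedman tests for
within-participant factors, Bonferroni-adjusted pairwise comparisons, and
Cohen's d for every contrast.

Implementation notes.  The Friedman statistic is the tie-corrected form

    chi2_F = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

with average ranks on ties; for small problems the p-value is computed by
exact enumeration of all within-block rank permutations, otherwise by the
chi-squared asymptote with k - 1 degrees of freedom.  The KS screen estimates
mean and SD from the sample, so its null distribution is Lilliefors', obtained
by seeded Monte Carlo.  Pairwise contrasts use the rank-sum test for
independent groups and the signed-rank test for paired conditions, with the
Bonferroni adjustment p_adj = min(1, m * p) over the comparison family
(m = 6 for the four experience groups).  Cohen's d uses the pooled-SD form
for independent samples and mean-difference / SD-of-differences for paired.

Because the four experience groups are independent samples of unequal size,
between-group contrasts use rank-sum + Bonferroni; the Friedman test is
reserved for the within-participant factors (tooth, task, trial), which is
the design its blocked structure supports.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "ks_normality",
    "friedman",
    "pairwise_bonferroni",
    "cohens_d",
    "run_study_analysis",
]


@dataclass(frozen=True)
class StatsResult:
    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    effect_size_d: float | None = None
    comparison: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.p_adjusted is not None:
            if not (self.p_value - 1e-12 <= self.p_adjusted <= 1.0):
                raise ValueError("p_adjusted must lie in [p_value, 1]")

    @property
    def significance(self) -> str:
        """Marker convention: * for p < 0.05, ** for p < 0.001 (adjusted)."""
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        if p < 0.001:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "comparison": self.comparison,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "effect_size_d": self.effect_size_d,
            "significance": self.significance,
            **self.extra,
        }


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance of the standardized sample to the standard normal."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def ks_normality(sample, reps: int = 10_000, seed: int = 0) -> StatsResult:
    """One-sample KS normality screen with estimated mean/SD (Lilliefors).

    The p-value comes from ``reps`` seeded Monte-Carlo replicates of the null
    (standard normal samples of the same size, re-standardized the same way).
    Requires n >= 5 and non-constant data.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError("ks_normality requires at least 5 observations")
    if x.std(ddof=1) < 1e-12:
        raise ValueError("ks_normality is undefined for a constant sample")
    d_obs = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    n = len(x)
    sims = rng.standard_normal((reps, n))
    sims.sort(axis=1)
    mean = sims.mean(axis=1, keepdims=True)
    sd = sims.std(axis=1, ddof=1, keepdims=True)
    z = (sims - mean) / sd
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_sim = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    p = float((1 + np.sum(d_sim >= d_obs - 1e-15)) / (reps + 1))
    return StatsResult(
        test_name="ks-lilliefors",
        statistic=d_obs,
        p_value=p,
        extra={"n": n, "reps": reps},
    )


def _friedman_statistic(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 1e-12:
        return 0.0
    return float(num / denom)


def friedman(block_matrix, exact_limit: int = 100_000) -> StatsResult:
    """Friedman test on an n-blocks x k-conditions matrix.

    Ranks within blocks with average ranks on ties; tie-corrected statistic.
    When the number of distinct within-block rank arrangements (k!)^n is at
    most ``exact_limit``, the p-value is computed by exact enumeration of the
    permutation distribution; otherwise the chi-squared (k-1 df) asymptote is
    used.  The matrix must be complete (no NaNs).
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("block matrix must be 2-D (blocks x conditions)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 conditions")
    if np.any(~np.isfinite(m)):
        raise ValueError("block matrix contains missing cells")
    ranks = np.vstack([sps.rankdata(row) for row in m])
    stat = _friedman_statistic(ranks)

    n_arrangements = math.factorial(k) ** n
    if n_arrangements <= exact_limit:
        perms = np.array(list(itertools.permutations(range(1, k + 1))), dtype=float)
        count = 0
        total = 0
        for combo in itertools.product(range(len(perms)), repeat=n):
            r = perms[list(combo)]
            if _friedman_statistic(r) >= stat - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        p = float(sps.chi2.sf(stat, k - 1))
        method = "asymptotic"
    return StatsResult(
        test_name="friedman",
        statistic=stat,
        p_value=p,
        extra={"n_blocks": n, "k": k, "method": method},
    )


def cohens_d(x, y, paired: bool = False) -> float:
    """Cohen's d; sign follows x - y.

    Independent: mean difference over the pooled SD (n-1 denominators).
    Paired: mean of differences over the SD of differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("cohens_d requires at least 2 observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired cohens_d requires equal lengths")
        diff = x - y
        sd = diff.std(ddof=1)
        if sd < 1e-12:
            raise ValueError("zero variance of differences")
        return float(diff.mean() / sd)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled < 1e-12:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def pairwise_bonferroni(
    groups: dict,
    kind: str = "independent",
    m: int | None = None,
    label_prefix: str = "",
) -> list[StatsResult]:
    """All pairwise contrasts with Bonferroni adjustment and effect sizes.

    ``groups`` maps label -> sample.  Independent contrasts use the two-sided
    rank-sum (Mann-Whitney) test, paired ones the signed-rank (Wilcoxon) test
    (equal lengths required).  ``m`` defaults to the number of pairs in the
    family; p_adjusted = min(1, m * p).
    """
    if kind not in ("independent", "paired"):
        raise ValueError("kind must be 'independent' or 'paired'")
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(labels, 2))
    m_family = m if m is not None else len(pairs)
    results = []
    for la, lb in pairs:
        x = np.asarray(groups[la], dtype=float)
        y = np.asarray(groups[lb], dtype=float)
        if kind == "paired":
            if len(x) != len(y):
                raise ValueError(f"paired comparison {la} vs {lb}: unequal lengths")
            diff = x - y
            if np.all(np.abs(diff) < 1e-12):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(x, y, zero_method="wilcox")
        else:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        try:
            d = cohens_d(x, y, paired=(kind == "paired"))
        except ValueError:
            d = None
        results.append(
            StatsResult(
                test_name="rank-sum" if kind == "independent" else "signed-rank",
                statistic=float(stat),
                p_value=float(p),
                p_adjusted=float(min(1.0, m_family * p)),
                effect_size_d=d,
                comparison=f"{label_prefix}{la} vs {lb}",
                extra={"m": m_family, "n_x": len(x), "n_y": len(y)},
            )
        )
    return results


def _records_frame(records, valid_only: bool) -> pd.DataFrame:
    from .metrics import records_to_dataframe

    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if valid_only and "valid" in df.columns:
        df = df[df["valid"].fillna(True)]
    return df.reset_index(drop=True)


_METRICS = ("distance_mm", "ratio_pct", "ellipticity", "time_s")


def run_study_analysis(
    records,
    valid_only: bool = True,
    ks_reps: int = 2_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Full comparison battery over a cohort's metric records.

    Per metric: KS normality screen per group; Friedman across the four
    within-participant tooth conditions per group x trial (and across tasks
    1-4 for manipulation time); between-group rank-sum + Bonferroni (m = 6)
    per tooth x trial; paired Trial-1 vs Trial-2 contrast per group (on
    participant means, m = 1); Cohen's d for every contrast.  Returns a
    JSON-serializable report keyed by metric and comparison family.
    """
    df = _records_frame(records, valid_only)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("run_study_analysis requires records from >= 2 groups")
    trials = sorted(df["trial"].unique())
    teeth = sorted(df["tooth"].unique())
    report: dict = {
        "n_records": int(len(df)),
        "groups": groups,
        "alpha": alpha,
        "metrics": {},
    }
    for metric in _METRICS:
        entry: dict = {"ks_normality": {}, "friedman_by_tooth": {},
                       "between_groups": {}, "trial_comparison": {}}
        for g in groups:
            vals = df.loc[df["group"] == g, metric].to_numpy()
            try:
                entry["ks_normality"][g] = ks_normality(
                    vals, reps=ks_reps, seed=seed).to_dict()
            except ValueError as exc:
                entry["ks_normality"][g] = {"error": str(exc)}
        # Friedman across the 4 tooth conditions within participants
        for g in groups:
            for tr in trials:
                sub = df[(df["group"] == g) & (df["trial"] == tr)]
                mat = sub.pivot_table(index="participant_id", columns="tooth",
                                      values=metric, aggfunc="mean")
                if mat.shape[1] == len(teeth) and not mat.isna().any().any() and len(mat) >= 2:
                    entry["friedman_by_tooth"][f"{g} trial {tr}"] = friedman(
                        mat.to_numpy()).to_dict()
        # between-group contrasts per tooth x trial, Bonferroni family m = 6
        for tr in trials:
            for tooth in teeth:
                sub = df[(df["trial"] == tr) & (df["tooth"] == tooth)]
                fam = {g: sub.loc[sub["group"] == g, metric].to_numpy() for g in groups}
                fam = {g: v for g, v in fam.items() if len(v) >= 2}
                if len(fam) >= 2:
                    res = pairwise_bonferroni(
                        fam, kind="independent",
                        label_prefix=f"tooth {tooth} trial {tr}: ")
                    entry["between_groups"][f"tooth {tooth} trial {tr}"] = [
                        r.to_dict() for r in res]
        # Trial 1 vs Trial 2 within groups, on participant means (m = 1)
        if set(trials) >= {1, 2}:
            for g in groups:
                sub = df[df["group"] == g]
                mat = sub.pivot_table(index="participant_id", columns="trial",
                                      values=metric, aggfunc="mean")
                if {1, 2} <= set(mat.columns) and not mat[[1, 2]].isna().any().any():
                    res = pairwise_bonferroni(
                        {"trial 1": mat[1].to_numpy(), "trial 2": mat[2].to_numpy()},
                        kind="paired", m=1, label_prefix=f"{g}: ")
                    entry["trial_comparison"][g] = res[0].to_dict()
        report["metrics"][metric] = entry
    # manipulation time: Friedman across tasks 1-4 (Trial 1 learning effect)
    time_entry = report["metrics"]["time_s"]
    time_entry["friedman_by_task"] = {}
    for g in groups:
        sub = df[(df["group"] == g) & (df["trial"] == 1)]
        mat = sub.pivot_table(index="participant_id", columns="task_index",
                              values="time_s", aggfunc="mean")
        if mat.shape[1] == 4 and not mat.isna().any().any() and len(mat) >= 2:
            time_entry["friedman_by_task"][g] = friedman(mat.to_numpy()).to_dict()
    return report
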