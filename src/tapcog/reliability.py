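"""Test-retest reliability, age norms, and variance reduction by averaging.

* **ICC** — intraclass correlation from a random-intercept linear mixed
  model fitted by REML: ICC = s2_between / (s2_between + s2_within).
  Conventional bands: 0.50-0.75 moderate, 0.75-0.90 good, >=0.90 excellent.
  The 95% CI comes from a parametric bootstrap of the fitted model.
* **Age-normative band** — a linear regression of score on age in the
  reference (healthy) cohort with a 90% new-observation prediction band;
  query trials are flagged when they fall *above* the band (the impaired
  side — higher composite = more impaired).
* **Averaging** — non-overlapping blocks of n consecutive trials replace
  single measurements by their block means; under iid noise this cuts
  within-subject variance by 1 − 1/n (75% at n=4), while slow real trends
  are preserved and bound the reduction below that.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cohort import GroupComparisonResult

__all__ = [
    "ICCReport",
    "NormBand",
    "icc_random_intercept",
    "icc_band",
    "window_average",
    "variance_reduction",
    "median_variance_reduction",
    "yearly_median_scores",
    "age_norm_band",
    "paired_change_test",
]


@dataclass
class ICCReport:
    icc: float
    ci95: tuple[float, float]
    var_between: float
    var_within: float
    n_subjects: int
    n_obs: int
    note: str = ""

    @property
    def band(self) -> str:
        return icc_band(self.icc)


def icc_band(icc: float) -> str:
    if icc >= 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def _fit_variance_components(df: pd.DataFrame) -> tuple[float, float]:
    """REML random-intercept fit; returns (between, within) variances.

    Falls back through optimizers: near-zero between-subject variance can
    make a single method hit a singular profiled information matrix.
    """
    last_exc: Exception | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("score ~ 1", df, groups=df["subject_id"])
                res = model.fit(reml=True, method=method)
            var_b = float(np.asarray(res.cov_re)[0, 0])
            var_w = float(res.scale)
            return max(var_b, 0.0), var_w
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise last_exc


def icc_random_intercept(
    long: pd.DataFrame,
    score_col: str = "score",
    subject_col: str = "subject_id",
    n_boot: int = 500,
    seed: int = 0,
) -> ICCReport:
    """ICC from a random-intercept mixed model on long-format repeated scores.

    Requires at least 5 subjects with >= 2 observations. The CI is a
    parametric bootstrap: ``n_boot`` datasets are simulated from the fitted
    variance components (same subject/visit structure), refitted, and the
    2.5/97.5 ICC percentiles reported. Set ``n_boot=0`` to skip the CI.
    """
    df = long[[subject_col, score_col]].dropna().rename(
        columns={subject_col: "subject_id", score_col: "score"}
    )
    counts = df.groupby("subject_id").size()
    if (counts >= 2).sum() < 5:
        raise ValueError("need >=2 observations for >=5 subjects")
    note = ""
    # exact repeats: zero within-subject variance, ICC 1 by definition
    within_sd = df.groupby("subject_id")["score"].std(ddof=0)
    if np.allclose(within_sd.fillna(0.0), 0.0) and df["score"].std() > 0:
        return ICCReport(1.0, (1.0, 1.0), float(df.groupby("subject_id")["score"].mean().var()),
                         0.0, len(counts), len(df), note="zero within-subject variance")
    var_b, var_w = _fit_variance_components(df)
    if var_b == 0.0:
        note = "zero between-subject variance; CI degenerate at 0"
    icc = var_b / (var_b + var_w) if (var_b + var_w) > 0 else math.nan
    ci = (math.nan, math.nan)
    if n_boot > 0:
        grand_mean = df["score"].mean()
        sizes = counts.to_numpy()
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            intercepts = rng.normal(0.0, math.sqrt(var_b), size=len(sizes))
            scores = np.concatenate(
                [grand_mean + u + rng.normal(0.0, math.sqrt(var_w), size=k)
                 for u, k in zip(intercepts, sizes)]
            )
            sim = pd.DataFrame(
                {"subject_id": np.repeat(counts.index.to_numpy(), sizes), "score": scores}
            )
            try:
                vb, vw = _fit_variance_components(sim)
            except (np.linalg.LinAlgError, ValueError):
                boot[b] = np.nan
                continue
            boot[b] = vb / (vb + vw) if (vb + vw) > 0 else np.nan
        ok = boot[~np.isnan(boot)]
        ci = (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))
    return ICCReport(float(icc), ci, var_b, var_w, len(counts), len(df), note=note)


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def window_average(series: Sequence[float], n: int = 4) -> np.ndarray:
    """Means of non-overlapping blocks of ``n`` consecutive scores.

    The trailing remainder (< n values) is dropped. Non-overlapping blocks
    keep block means independent under iid noise, so the variance-reduction
    factor 1 − 1/n is exact in expectation.
    """
    x = np.asarray(series, dtype=float)
    k = len(x) // n
    if k == 0:
        return np.empty(0)
    return x[: k * n].reshape(k, n).mean(axis=1)


def variance_reduction(series: Sequence[float], n: int = 4) -> float:
    """Percent within-subject variance removed by n-trial block averaging.

    100 × (1 − var(block means) / var(raw)); NaN when the raw variance is
    zero or fewer than two blocks exist.
    """
    x = np.asarray(series, dtype=float)
    raw_var = np.var(x, ddof=1) if len(x) > 1 else 0.0
    if raw_var == 0:
        return math.nan
    blocks = window_average(x, n)
    if len(blocks) < 2:
        return math.nan
    return float(100.0 * (1.0 - np.var(blocks, ddof=1) / raw_var))


def median_variance_reduction(
    long: pd.DataFrame,
    n: int = 4,
    score_col: str = "score",
    subject_col: str = "subject_id",
    time_col: str = "session_time",
) -> float:
    """Median across subjects of the per-subject variance reduction."""
    per_subject = []
    for _, g in long.sort_values(time_col).groupby(subject_col):
        r = variance_reduction(g[score_col].to_numpy(), n)
        if not math.isnan(r):
            per_subject.append(r)
    if not per_subject:
        return math.nan
    return float(np.median(per_subject))


# ---------------------------------------------------------------------------
# Age-normative band
# ---------------------------------------------------------------------------

def yearly_median_scores(
    long: pd.DataFrame,
    score_col: str = "score",
    subject_col: str = "subject_id",
    time_col: str = "session_time",
    age_col: str = "age",
) -> pd.DataFrame:
    """One row per subject per calendar year from first trial: median score,
    age at that year. Used to build reference norm curves."""
    df = long.dropna(subset=[score_col]).copy()
    first = df.groupby(subject_col)[time_col].transform("min")
    years = ((pd.to_datetime(df[time_col]) - pd.to_datetime(first)).dt.days // 365).astype(int)
    df["_year"] = years
    out = (
        df.groupby([subject_col, "_year"])
        .agg(score=(score_col, "median"), age=(age_col, "first"))
        .reset_index()
    )
    out["age"] = out["age"] + out["_year"]
    return out.drop(columns="_year")


@dataclass
class NormBand:
    """Age-normative band: linear score~age fit on a reference cohort with a
    two-sided new-observation prediction band (default 90%, so 5% of healthy
    observations are expected above the upper bound)."""

    level: float
    _ols: object = field(repr=False)
    warning: str = ""

    def predict(self, age) -> np.ndarray:
        X = sm.add_constant(pd.DataFrame({"age": np.atleast_1d(np.asarray(age, float))}),
                            has_constant="add")
        return np.asarray(self._ols.predict(X))

    def bounds(self, age) -> tuple[np.ndarray, np.ndarray]:
        X = sm.add_constant(pd.DataFrame({"age": np.atleast_1d(np.asarray(age, float))}),
                            has_constant="add")
        frame = self._ols.get_prediction(X).summary_frame(alpha=1 - self.level)
        return frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()

    def flag_above(self, age, score) -> np.ndarray:
        """True where a (age, score) trial lies above the upper band bound —
        the impaired side only."""
        _, hi = self.bounds(age)
        return np.atleast_1d(np.asarray(score, float)) > hi


def age_norm_band(
    reference: pd.DataFrame,
    level: float = 0.90,
    score_col: str = "score",
    age_col: str = "age",
) -> NormBand:
    """Fit the age-normative prediction band on a reference (healthy) cohort.

    Expects per-subject yearly-median scores (see
    :func:`yearly_median_scores`). Requires n >= 10; an age span under 10
    years triggers an unstable-band warning carried on the result.
    """
    ref = reference.dropna(subset=[score_col, age_col])
    if len(ref) < 10:
        raise ValueError(f"need a reference of >=10 points, got {len(ref)}")
    note = ""
    span = ref[age_col].max() - ref[age_col].min()
    if span < 10:
        note = f"unstable band: reference age range only {span:.1f} years"
        warnings.warn(note)
    X = sm.add_constant(ref[[age_col]].rename(columns={age_col: "age"}), has_constant="add")
    ols = sm.OLS(ref[score_col], X).fit()
    return NormBand(level=level, _ols=ols, warning=note)


def paired_change_test(baseline, followup) -> GroupComparisonResult:
    """Wilcoxon signed-rank test of within-subject change (e.g. month 0 vs 12)."""
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValueError(f"need >=5 complete pairs, got {len(x)}")
    if np.all(x == y):
        return GroupComparisonResult("baseline", "followup", "signed-rank", 0.0,
                                     math.nan, len(x), len(y), note="all differences zero")
    stat, p = stats.wilcoxon(x, y)
    return GroupComparisonResult("baseline", "followup", "signed-rank",
                                 float(stat), float(p), len(x), len(y))
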