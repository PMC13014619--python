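"""Cohort protocol and the proportional-odds composite model.

The composite digital biomarker is built by ordinal logistic regression
against a three-level diagnostic continuum assumed, on clinical grounds, to
carry ascending cognitive impairment::

    HD < RR-MS < P-MS        (P-MS pools SP-MS and PP-MS)

The proportional-odds (cumulative-logit) model

    logit P(Y <= j | x) = zeta_j - x'beta,   zeta_1 < zeta_2

returns one weight per digital biomarker; the threshold-free linear
predictor ``x'beta`` (on training-standardized features) serves as the
composite score, oriented so that higher = more impaired. Non-MS groups
(NIND, OIND, RIS, CIS) are never fitted — they are scored with the frozen
model only.

The surrounding protocol: MS subjects are split 2/3 train : 1/3 validation
stratified on SDMT quartiles; training uses up to the first ten sessions
per subject while validation uses only the first; group contrasts use
Wilcoxon rank-sum / signed-rank tests with raw p-values.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "MODEL_CLASSES",
    "MS_DIAGNOSES",
    "FEATURE_SETS",
    "FitError",
    "GroupComparisonResult",
    "collapse_diagnosis",
    "split_train_validation",
    "select_trials",
    "OrdinalComposite",
    "OrdinalCompositeResults",
    "compare_groups",
]

#: Ordered model classes (ascending impairment).
MODEL_CLASSES = ("HD", "RR-MS", "P-MS")
MS_DIAGNOSES = ("RR-MS", "SP-MS", "PP-MS")

#: First-class composite variants: which biomarkers each model uses.
FEATURE_SETS = {
    "verbal": ["ImmVRLa", "DelVRLa", "ImmVRI", "DelVRI"],
    "spatial": ["StaticSRLa", "DynamicSRLa", "StaticSRI", "DynamicSRI",
                "StaticSRM", "DynamicSRM"],
    "spatial+ismpt": ["StaticSRLa", "DynamicSRLa", "StaticSRI", "DynamicSRI",
                      "StaticSRM", "DynamicSRM", "iSMPT_S_static", "iSMPT_S_dynamic"],
    "global": ["ImmVRLa", "DelVRLa", "ImmVRI", "DelVRI",
               "StaticSRLa", "DynamicSRLa", "StaticSRI", "DynamicSRI",
               "StaticSRM", "DynamicSRM"],
}

_COLLAPSE = {"SP-MS": "P-MS", "PP-MS": "P-MS"}


class FitError(RuntimeError):
    """Maximum-likelihood fit failed (separation or non-convergence)."""


def collapse_diagnosis(diagnosis: pd.Series | Sequence[str]) -> pd.Series:
    """Map the 8-level diagnostic vocabulary onto model classes where possible
    (SP-MS and PP-MS pool into P-MS); other labels pass through unchanged."""
    s = pd.Series(diagnosis)
    return s.replace(_COLLAPSE)


def split_train_validation(
    subjects: pd.DataFrame,
    frac: float = 2 / 3,
    seed: int = 0,
    sdmt_col: str = "sdmt",
) -> tuple[list[str], list[str]]:
    """Stratified 2/3 : 1/3 split of the MS subjects by SDMT quartile.

    Only MS subjects (RR-MS, SP-MS, PP-MS) enter the split; healthy donors
    are model anchors reused in both roles and non-MS groups are score-only.
    Within each SDMT-quartile stratum, ``ceil(frac * n)`` subjects go to
    training. Deterministic given ``seed``.
    """
    ms = subjects[subjects["diagnosis"].isin(MS_DIAGNOSES)].copy()
    ms = ms.dropna(subset=[sdmt_col])
    if ms.empty:
        raise ValueError("no MS subjects with SDMT available to split")
    strata = pd.qcut(ms[sdmt_col], q=4, labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    validation: list[str] = []
    for _, idx in ms.groupby(strata).groups.items():
        ids = sorted(ms.loc[idx, "subject_id"].tolist())
        if len(ids) == 1:
            warnings.warn("stratum of size 1 assigned to training")
            train.extend(ids)
            continue
        order = rng.permutation(len(ids))
        n_train = math.ceil(frac * len(ids))
        train.extend(ids[i] for i in order[:n_train])
        validation.extend(ids[i] for i in order[n_train:])
    return sorted(train), sorted(validation)


def select_trials(records: pd.DataFrame, role: str, max_train: int = 10) -> pd.DataFrame:
    """Apply the trial-selection rule: training keeps each subject's first
    (up to) ten sessions chronologically; validation keeps only the first."""
    if role not in ("train", "validation"):
        raise ValueError(f"role must be 'train' or 'validation', got {role!r}")
    n = max_train if role == "train" else 1
    out = (
        records.sort_values(["subject_id", "session_time"], kind="mergesort")
        .groupby("subject_id", sort=False)
        .head(n)
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class GroupComparisonResult:
    group_a: str
    group_b: str
    test: str            # "rank-sum" or "signed-rank"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    note: str = ""


def compare_groups(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | Sequence[str],
    paired: bool = False,
) -> list[GroupComparisonResult]:
    """All pairwise group contrasts with Wilcoxon tests, raw p-values.

    Unpaired groups use the rank-sum (Mann-Whitney) test; ``paired=True``
    aligns observations positionally within each pair of groups and uses
    the signed-rank test. No multiplicity adjustment is applied.
    """
    scores = np.asarray(scores, dtype=float)
    labels = pd.Series(list(labels))
    results = []
    for ga, gb in combinations(pd.unique(labels), 2):
        xa = scores[(labels == ga).to_numpy()]
        xb = scores[(labels == gb).to_numpy()]
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        if len(xa) == 0 or len(xb) == 0:
            results.append(
                GroupComparisonResult(ga, gb, "rank-sum", math.nan, math.nan,
                                      len(xa), len(xb), note="empty group; contrast skipped")
            )
            continue
        if paired:
            if len(xa) != len(xb):
                raise ValueError(f"paired comparison requires equal group sizes ({ga}/{gb})")
            diffs = xa - xb
            if np.all(diffs == 0):
                results.append(
                    GroupComparisonResult(ga, gb, "signed-rank", 0.0, math.nan,
                                          len(xa), len(xb), note="all differences zero")
                )
                continue
            stat, p = stats.wilcoxon(xa, xb)
            results.append(GroupComparisonResult(ga, gb, "signed-rank", float(stat), float(p),
                                                 len(xa), len(xb)))
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            results.append(GroupComparisonResult(ga, gb, "rank-sum", float(stat), float(p),
                                                 len(xa), len(xb)))
    return results


# ---------------------------------------------------------------------------
# Proportional-odds composite: Model / Results
# ---------------------------------------------------------------------------

class OrdinalComposite:
    """Proportional-odds composite model of ordered diagnostic classes.

    Parameters
    ----------
    data : DataFrame
        One row per trial, containing the feature columns and a diagnosis
        column. Diagnoses are collapsed onto the model classes; rows from
        other groups are dropped at fit time. Complete-case analysis.
    features : sequence of str
        Digital biomarker columns used as predictors.
    target : str
        Diagnosis column name.
    ordering : tuple of str
        The ordered classes, ascending impairment.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: Sequence[str],
        target: str = "diagnosis",
        ordering: tuple[str, ...] = MODEL_CLASSES,
    ) -> None:
        if len(ordering) < 3:
            raise ValueError("the ordinal model requires at least 3 ordered classes")
        self.features = list(features)
        self.ordering = tuple(ordering)
        self.target = target
        d = data.copy()
        d[target] = collapse_diagnosis(d[target])
        d = d[d[target].isin(self.ordering)]
        d = d.dropna(subset=self.features + [target])
        self.data = d.reset_index(drop=True)
        present = set(self.data[self.target])
        missing = [c for c in self.ordering if c not in present]
        if missing:
            raise ValueError(f"classes absent from the training data: {missing}")

    @classmethod
    def from_dataframe(cls, data, features, **kwargs) -> "OrdinalComposite":
        return cls(data, features, **kwargs)

    def fit(self, folds: int = 10, seed: int = 0) -> "OrdinalCompositeResults":
        """Maximum-likelihood cumulative-logit fit on z-scored features,
        with k-fold cross-validated classification accuracy."""
        X = self.data[self.features].to_numpy(dtype=float)
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            flat = [f for f, s in zip(self.features, sd) if s == 0]
            raise FitError(f"features with zero variance: {flat}")
        Xz = (X - mean) / sd
        y = pd.Categorical(self.data[self.target], categories=self.ordering, ordered=True)
        codes = np.asarray(y.codes)

        params, cov, thresholds = self._mle(Xz, codes)
        cv_acc = self._cv_accuracy(Xz, codes, folds, seed)
        coefs = params[: len(self.features)]

        # orientation: higher composite = greater impairment
        lp = Xz @ coefs
        mask_lo = codes == 0
        mask_hi = codes == len(self.ordering) - 1
        sign = 1.0
        if lp[mask_hi].mean() < lp[mask_lo].mean():
            sign = -1.0

        return OrdinalCompositeResults(
            model=self,
            coefficients=coefs,
            thresholds=thresholds,
            cov_params=cov[: len(self.features), : len(self.features)],
            standardization=(mean, sd),
            orientation=sign,
            cv_accuracy=cv_acc,
            n=len(self.data),
            seed=seed,
        )

    def _mle(self, Xz: np.ndarray, codes: np.ndarray):
        mod = OrderedModel(codes, Xz, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = mod.fit(method="bfgs", disp=False, maxiter=500)
            except Exception as exc:  # singular hessian etc.
                raise FitError(f"ordinal fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise FitError(
                "ordinal fit did not converge "
                f"(gradient norm {np.max(np.abs(res.mle_retvals.get('gopt', np.nan))):.3g}); "
                "check for separation or collinear features"
            )
        k = Xz.shape[1]
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)):
            raise FitError("non-finite coefficients; likely separation")
        thresholds = mod.transform_threshold_params(params)[1:-1]
        if not np.all(np.diff(thresholds) > 0):
            raise FitError(f"thresholds not strictly increasing: {thresholds}")
        cov = np.asarray(res.cov_params())
        return params, cov, np.asarray(thresholds)

    def _cv_accuracy(self, Xz, codes, folds, seed) -> float:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        hits = 0
        for tr, te in skf.split(Xz, codes):
            mod = OrderedModel(codes[tr], Xz[tr], distr="logit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mod.fit(method="bfgs", disp=False, maxiter=500)
            prob = res.model.predict(res.params, exog=Xz[te])
            hits += int(np.sum(np.argmax(prob, axis=1) == codes[te]))
        return hits / len(codes)


class OrdinalCompositeResults:
    """Fitted proportional-odds composite: weights, thresholds, scoring."""

    def __init__(self, model, coefficients, thresholds, cov_params,
                 standardization, orientation, cv_accuracy, n, seed):
        self.model = model
        self.features = model.features
        self.ordering = model.ordering
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.thresholds = np.asarray(thresholds, dtype=float)
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.feature_means, self.feature_sds = (np.asarray(a, float) for a in standardization)
        self.orientation = float(orientation)
        self.cv_accuracy = float(cv_accuracy)
        self.n = int(n)
        self.seed = seed

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def score(self, data: pd.DataFrame | dict) -> pd.Series | float:
        """Composite score: standardized features · coefficients (orientation
        fixed so higher = more impaired). Rows with a missing feature score NaN."""
        if isinstance(data, dict):
            out = self.score(pd.DataFrame([data]))
            return float(out.iloc[0])
        X = data[self.features].to_numpy(dtype=float)
        Xz = (X - self.feature_means) / self.feature_sds
        lp = self.orientation * (Xz @ self.coefficients)
        lp = np.where(np.isnan(X).any(axis=1), np.nan, lp)
        return pd.Series(lp, index=data.index, name="composite")

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-feature odds ratio with Wald CI and Wald p-value.

        OR = exp(coef) per SD of the feature (features are z-scored);
        CI = exp(coef ± z_{1−α/2}·SE).
        """
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        ok = np.isfinite(se) & (se > 0)
        coef = self.coefficients
        with np.errstate(invalid="ignore", divide="ignore"):
            wald_z = np.where(ok, coef / se, np.nan)
        df = pd.DataFrame(
            {
                "feature": self.features,
                "coef": coef,
                "se": np.where(ok, se, np.nan),
                "odds_ratio": np.exp(coef),
                "ci_low": np.where(ok, np.exp(coef - z * se), np.nan),
                "ci_high": np.where(ok, np.exp(coef + z * se), np.nan),
                "wald_p": np.where(ok, 2 * stats.norm.sf(np.abs(wald_z)), np.nan),
            }
        )
        return df.set_index("feature")

    def summary(self) -> str:
        lines = [
            "Proportional-odds composite model",
            "=" * 50,
            f"classes (ascending impairment): {' < '.join(self.ordering)}",
            f"n obs: {self.n}   CV accuracy: {self.cv_accuracy:.3f}   seed: {self.seed}",
            f"thresholds: {np.array2string(self.thresholds, precision=3)}",
            f"orientation: {'+' if self.orientation > 0 else '-'}",
            "-" * 50,
            f"{'feature':<18}{'coef':>9}{'SE':>8}{'OR':>8}{'95% CI':>18}{'p':>9}",
        ]
        ors = self.odds_ratios()
        for f, row in ors.iterrows():
            lines.append(
                f"{f:<18}{row['coef']:>9.3f}{row['se']:>8.3f}{row['odds_ratio']:>8.3f}"
                f"  [{row['ci_low']:>6.3f},{row['ci_high']:>7.3f}]{row['wald_p']:>9.2g}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "format": "tapcog-ordinal-composite",
            "version": 1,
            "features": self.features,
            "ordering": list(self.ordering),
            "coefficients": self.coefficients.tolist(),
            "thresholds": self.thresholds.tolist(),
            "cov_params": self.cov_params.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "orientation": self.orientation,
            "cv_accuracy": self.cv_accuracy,
            "n": self.n,
            "seed": self.seed,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "OrdinalCompositeResults":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        if d.get("format") != "tapcog-ordinal-composite":
            raise ValueError("not a serialized ordinal composite model")

        class _Stub:
            pass

        stub = _Stub()
        stub.features = list(d["features"])
        stub.ordering = tuple(d["ordering"])
        return cls(
            model=stub,
            coefficients=np.array(d["coefficients"]),
            thresholds=np.array(d["thresholds"]),
            cov_params=np.array(d["cov_params"]),
            standardization=(np.array(d["feature_means"]), np.array(d["feature_sds"])),
            orientation=d["orientation"],
            cv_accuracy=d["cv_accuracy"],
            n=d["n"],
            seed=d["seed"],
        )
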