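"""SDMT prediction and the prediction-envelope quality-control check.

Because the spatial memory stages and the Symbol Digit Modalities Test
(SDMT) probe overlapping functions (information-processing speed plus
visuospatial working memory), spatial biomarkers should predict SDMT. An
ordinary least-squares model is fitted on the training cohort with all
eight spatial biomarkers as candidates, optionally reduced by bidirectional
stepwise AIC search; around each prediction an exact t-based 95% interval
for a *new* observation (residual variance plus leverage) defines the
expected SDMT range given the observed memory performance. SDMT scores
falling outside that envelope are flagged as discordant — a data-driven
quality-control signal for unsupervised testing.

Agreement statistics for measured-vs-predicted comparisons: Spearman's Rho,
R-squared, Lin's concordance correlation coefficient, and participant-level
bootstrap confidence intervals (subjects resampled with replacement so that
repeated trials of one subject travel together).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SDMTModel",
    "SDMTModelResults",
    "QCVerdict",
    "spearman_rho",
    "lins_ccc",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class QCVerdict:
    """Per-trial QC outcome against the prediction envelope."""

    observed: float
    predicted: float
    lower: float
    upper: float
    flag: str                 # "concordant" | "discordant"
    extrapolation: bool = False

    def __post_init__(self) -> None:
        inside = self.lower <= self.observed <= self.upper
        assert (self.flag == "concordant") == inside


class SDMTModel:
    """OLS model predicting SDMT from spatial memory biomarkers.

    Parameters
    ----------
    data : DataFrame
        Training rows with the feature columns and the target column.
        Complete-case analysis: rows with any missing value are dropped.
    features : sequence of str
        Candidate predictors (typically the eight spatial biomarkers).
    target : str
        SDMT column name.
    """

    def __init__(self, data: pd.DataFrame, features: Sequence[str], target: str = "sdmt"):
        self.features = list(features)
        self.target = target
        d = data.dropna(subset=self.features + [target]).reset_index(drop=True)
        if len(d) <= len(self.features) + 2:
            raise ValueError(
                f"need n > k+2 observations (k={len(self.features)}), got n={len(d)}"
            )
        X = d[self.features].to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
        if rank < len(self.features) + 1:
            aliased = _aliased_features(X, self.features)
            raise ValueError(f"collinear (aliased) features: {aliased}")
        self.data = d

    def fit(self) -> "SDMTModelResults":
        X = sm.add_constant(self.data[self.features], has_constant="add")
        ols = sm.OLS(self.data[self.target], X).fit()
        return SDMTModelResults(self, ols)


def _aliased_features(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify columns linearly dependent on earlier ones (QR pivoting)."""
    aliased = []
    cols = [np.ones(len(X))]
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [X[:, j]])
        if np.linalg.matrix_rank(trial) == len(cols):
            aliased.append(name)
        else:
            cols.append(X[:, j])
    return aliased


class SDMTModelResults:
    """Fitted SDMT predictor with exact new-observation intervals.

    Carries the training design summary needed for exact t-based prediction
    intervals — residual variance, degrees of freedom and the inverse
    cross-product matrix — so a serialized model predicts identically to
    the in-memory fit.
    """

    def __init__(self, model: SDMTModel | None, ols_results=None, state: dict | None = None):
        if state is not None:
            self.model = None
            self._ols = None
            for k, v in state.items():
                setattr(self, k, v)
            return
        self.model = model
        self.features = model.features
        self._ols = ols_results
        self.params = np.asarray(ols_results.params, dtype=float)  # [const, features...]
        self.resid_var = float(ols_results.scale)
        self.df_resid = float(ols_results.df_resid)
        self.n = int(ols_results.nobs)
        X = np.column_stack(
            [np.ones(len(model.data))] + [model.data[f].to_numpy(float) for f in model.features]
        )
        self.xtx_inv = np.linalg.inv(X.T @ X)
        self._aic = float(ols_results.aic)
        self._rsquared = float(ols_results.rsquared)
        self._train_min = model.data[model.features].min()
        self._train_max = model.data[model.features].max()

    @property
    def aic(self) -> float:
        return self._aic

    @property
    def rsquared(self) -> float:
        return self._rsquared

    def summary(self):
        if self._ols is None:
            raise ValueError("summary unavailable on a deserialized model")
        return self._ols.summary()

    def _design(self, data: pd.DataFrame) -> np.ndarray:
        return np.column_stack(
            [np.ones(len(data))] + [data[f].to_numpy(float) for f in self.features]
        )

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self._design(data) @ self.params

    def to_json(self, path=None) -> dict:
        d = {
            "format": "tapcog-sdmt-model",
            "version": 1,
            "features": self.features,
            "params": np.asarray(self.params).tolist(),
            "resid_var": self.resid_var,
            "df_resid": self.df_resid,
            "n": self.n,
            "xtx_inv": np.asarray(self.xtx_inv).tolist(),
            "aic": self._aic,
            "rsquared": self._rsquared,
            "train_min": self._train_min.to_dict(),
            "train_max": self._train_max.to_dict(),
        }
        if path is not None:
            from pathlib import Path

            Path(path).write_text(__import__("json").dumps(d, indent=2, sort_keys=True) + "\n")
        return d

    @classmethod
    def from_json(cls, source) -> "SDMTModelResults":
        import json as _json
        from pathlib import Path

        d = source if isinstance(source, dict) else _json.loads(Path(source).read_text())
        if d.get("format") != "tapcog-sdmt-model":
            raise ValueError("not a serialized SDMT prediction model")
        state = {
            "features": list(d["features"]),
            "params": np.array(d["params"], float),
            "resid_var": float(d["resid_var"]),
            "df_resid": float(d["df_resid"]),
            "n": int(d["n"]),
            "xtx_inv": np.array(d["xtx_inv"], float),
            "_aic": float(d["aic"]),
            "_rsquared": float(d["rsquared"]),
            "_train_min": pd.Series(d["train_min"]),
            "_train_max": pd.Series(d["train_max"]),
        }
        return cls(None, state=state)

    def stepwise(self) -> "SDMTModelResults":
        """Bidirectional stepwise AIC search starting from the full model.

        Each accepted step strictly lowers the AIC; the intercept-only
        model is admissible. Returns a refitted reduced model.
        """
        data, target = self.model.data, self.model.target
        current = list(self.features)

        def fit_aic(feats: list[str]) -> float:
            X = sm.add_constant(data[feats] if feats else pd.DataFrame(index=data.index),
                                has_constant="add")
            return float(sm.OLS(data[target], X).fit().aic)

        best_aic = fit_aic(current)
        improved = True
        while improved:
            improved = False
            candidates: list[tuple[float, list[str]]] = []
            for f in current:  # drop steps
                feats = [g for g in current if g != f]
                candidates.append((fit_aic(feats), feats))
            for f in self.features:  # add-back steps
                if f not in current:
                    feats = current + [f]
                    candidates.append((fit_aic(feats), feats))
            if candidates:
                aic, feats = min(candidates, key=lambda c: c[0])
                if aic < best_aic - 1e-9:
                    best_aic, current, improved = aic, feats, True
        if not current:
            # intercept-only: keep a degenerate but valid results object
            X = sm.add_constant(pd.DataFrame(index=data.index), has_constant="add")
            ols = sm.OLS(data[target], X).fit()
            reduced = SDMTModel.__new__(SDMTModel)
            reduced.features = []
            reduced.target = target
            reduced.data = data
            return SDMTModelResults(reduced, ols)
        return SDMTModel(data, current, target).fit()

    def predict_with_interval(
        self,
        data: pd.DataFrame,
        observed: Sequence[float] | None = None,
        level: float = 0.95,
    ) -> list[QCVerdict]:
        """Point predictions with exact t-based prediction intervals.

        The interval is for a *new* observation: it combines the residual
        variance with the leverage of the query point,

            se² = s² · (1 + x' (X'X)⁻¹ x),   bounds = x'b ± t_{df} · se,

        so it is narrowest at the training feature means. When ``observed``
        SDMT scores are supplied each row receives a concordant/discordant
        flag; queries outside the training feature hull carry an
        extrapolation warning.
        """
        X = self._design(data)
        mean = X @ self.params
        leverage = np.einsum("ij,jk,ik->i", X, self.xtx_inv, X)
        se = np.sqrt(self.resid_var * (1.0 + leverage))
        tcrit = stats.t.ppf(0.5 + level / 2, self.df_resid)
        lo = mean - tcrit * se
        hi = mean + tcrit * se
        if observed is None:
            observed = [math.nan] * len(mean)
        observed = np.asarray(observed, dtype=float)
        extrap = np.zeros(len(mean), dtype=bool)
        if self.features:
            q = data[self.features].to_numpy(dtype=float)
            tmin = self._train_min.reindex(self.features).to_numpy(dtype=float)
            tmax = self._train_max.reindex(self.features).to_numpy(dtype=float)
            extrap = ((q < tmin) | (q > tmax)).any(axis=1)
            if extrap.any():
                warnings.warn(f"{int(extrap.sum())} query rows outside the training feature hull")
        out = []
        for i in range(len(mean)):
            obs = observed[i]
            if math.isnan(obs):
                flag = "concordant" if lo[i] <= mean[i] <= hi[i] else "discordant"
                obs_val = mean[i]
            else:
                flag = "concordant" if lo[i] <= obs <= hi[i] else "discordant"
                obs_val = obs
            out.append(
                QCVerdict(
                    observed=float(obs_val),
                    predicted=float(mean[i]),
                    lower=float(lo[i]),
                    upper=float(hi[i]),
                    flag=flag,
                    extrapolation=bool(extrap[i]),
                )
            )
        return out


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank-order correlation with average-rank ties.

    Returns NaN when either vector is constant (undefined sentinel).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 cov(x,y) / (var(x) + var(y) + (mean(x) − mean(y))²), with
    n-denominator moments as in Lin's original estimator. Measures 1:1
    agreement: precision (correlation) times accuracy (bias correction).
    Returns NaN when both variances are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length vectors with n >= 3")
    vx, vy = np.var(x), np.var(y)
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return math.nan
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / denom)


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    table: pd.DataFrame,
    unit: str = "subject_id",
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Participant-level nonparametric bootstrap percentile interval.

    Subjects (values of ``unit``) are resampled with replacement; all rows
    of a resampled subject travel together, preserving the within-subject
    correlation structure. ``statistic`` maps a resampled table to a float.
    A warning is raised (and the interval computed from the remainder) when
    the statistic is undefined in more than 10% of replicates.
    """
    units = table[unit].unique()
    if len(units) < 10:
        raise ValueError(f"need >=10 resampling units, got {len(units)}")
    groups = {u: df for u, df in table.groupby(unit, sort=False)}
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        chosen = rng.choice(units, size=len(units), replace=True)
        sample = pd.concat([groups[u] for u in chosen], ignore_index=True)
        try:
            vals[b] = statistic(sample)
        except Exception:
            vals[b] = np.nan
    ok = vals[~np.isnan(vals)]
    if len(ok) < 0.9 * B:
        warnings.warn(
            f"statistic undefined in {B - len(ok)}/{B} bootstrap replicates; interval may be unstable"
        )
    alpha = 1 - level
    lo, hi = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
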