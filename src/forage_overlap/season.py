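"""Seasonal contrasts in trip metrics via random-intercept mixed models.

Each trip-level response (duration, distance, home range, depths) is
log-transformed and modelled as

    log(y_ik) = b0 + beta * spring_k + u_i + e_ik,   u_i ~ N(0, s_u^2)

with a random intercept u_i per bird to absorb repeated trips by the same
individual; ``beta`` is the spring-vs-autumn contrast on the log scale.
Fits use REML.  Season varies between birds, so Wald inference uses
containment-style degrees of freedom (number of birds minus the number of
fixed-effect parameters), which is near-exact for a between-cluster factor.
Singular fits (random-intercept variance estimated at zero) indicate
negligible between-individual variation; they are flagged, not treated as
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["SeasonEffect", "SeasonEffectModel", "fit_season_model"]


@dataclass
class SeasonEffect:
    """A fitted spring-vs-autumn contrast for one response variable."""

    response: str
    estimate: float           # log-scale fixed effect, spring vs autumn
    ci_low: float
    ci_high: float
    p_value: float
    re_variance: float        # random-intercept variance
    resid_variance: float
    singular: bool
    df: float
    n_obs: int
    n_birds: int

    def summary_row(self) -> dict:
        return {
            "response": self.response,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "singular": self.singular,
        }


class SeasonEffectModel(BaseEstimator):
    """Random-intercept LMM for a log-transformed trip response.

    ``fit(X)`` takes a DataFrame with columns ``bird_id``, ``season``
    (autumn/spring) and the response column.  Fitted attributes:
    ``effect_`` (a :class:`SeasonEffect`) plus the usual scalars.
    """

    def __init__(self, response_col: str = "value", alpha: float = 0.05,
                 reml: bool = True, baseline: str = "autumn"):
        self.response_col = response_col
        self.alpha = alpha
        self.reml = reml
        self.baseline = baseline

    def fit(self, X: pd.DataFrame, y=None):
        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        df = X[["bird_id", "season", self.response_col]].dropna().copy()
        seasons = set(df["season"].unique())
        if len(seasons) < 2:
            raise ValueError("both seasons must be present to estimate a contrast")
        n_birds = df["bird_id"].nunique()
        if n_birds < 2:
            raise ValueError("need at least 2 birds")
        bad = df.index[df[self.response_col] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive response (cannot log-transform) at rows {bad.tolist()}"
            )
        df["logy"] = np.log(df[self.response_col].astype(float))
        other = sorted(seasons - {self.baseline})[0]
        df["spring"] = (df["season"] == other).astype(float)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = smf.mixedlm("logy ~ spring", data=df, groups=df["bird_id"])
            fit = None
            # variance components on the boundary can break gradient methods
            for method in ("lbfgs", "powell", "nm"):
                try:
                    fit = model.fit(reml=self.reml, method=method)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if fit is None:
                raise RuntimeError("mixed-model fit failed under all optimizers")

        est = float(fit.fe_params["spring"])
        se = float(fit.bse_fe["spring"])
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        resid_var = float(fit.scale)
        singular = re_var < 1e-6 * max(resid_var, 1e-300)
        dof = max(float(n_birds - 2), 1.0)
        tval = est / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(tval), dof))
        tcrit = float(stats.t.ppf(1.0 - self.alpha / 2.0, dof))
        self.effect_ = SeasonEffect(
            response=self.response_col, estimate=est,
            ci_low=est - tcrit * se, ci_high=est + tcrit * se, p_value=p,
            re_variance=re_var, resid_variance=resid_var, singular=singular,
            df=dof, n_obs=len(df), n_birds=n_birds,
        )
        self.n_features_in_ = X.shape[1]
        return self


def fit_season_model(
    trip_table: pd.DataFrame, response_col: str, alpha: float = 0.05
) -> SeasonEffect:
    """Convenience wrapper: fit the LMM and return the :class:`SeasonEffect`."""
    return SeasonEffectModel(response_col=response_col, alpha=alpha).fit(trip_table).effect_


def season_report(trip_table: pd.DataFrame, responses: list[str]) -> pd.DataFrame:
    """Per-response report: medians and ranges on the original scale per season,
    plus the log-scale contrast, CI and p-value."""
    rows = []
    for resp in responses:
        eff = fit_season_model(trip_table, resp)
        row = eff.summary_row()
        for season, sub in trip_table.groupby("season"):
            v = sub[resp].dropna()
            row[f"{season}_median"] = float(v.median())
            row[f"{season}_min"] = float(v.min())
            row[f"{season}_max"] = float(v.max())
        rows.append(row)
    return pd.DataFrame(rows)
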