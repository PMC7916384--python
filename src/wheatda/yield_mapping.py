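"""Stage-weighted yield estimation and validation.

Assimilated LAI and topsoil moisture are composited over the four
yield-forming phenophases (green-up, jointing, heading-filling, milking)
with fixed weights from an analytic-hierarchy-process style prioritisation,
then regressed on measured yield separately for irrigated and rain-fed
areas and for each assimilation strategy.  Validation reports RMSE
(kg ha-1) and ARE, the mean absolute relative error across validation
sites in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rasters import Raster

YIELD_STAGES = ("green_up", "jointing", "heading_filling", "milking")
REGIMES = ("irrigated", "rain_fed")
STRATEGIES = ("LAI_only", "SM_only", "joint")


@dataclass(frozen=True)
class StageWeights:
    """Per-stage contribution weights; must be non-negative and sum to 1."""

    kind: str  # "LAI" | "SM"
    weights: tuple  # ordered as YIELD_STAGES

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.kind not in ("LAI", "SM"):
            raise ValueError("kind must be 'LAI' or 'SM'")
        if len(w) != 4 or np.any(w < 0):
            raise ValueError("need 4 non-negative stage weights")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"stage weights must sum to 1 (got {w.sum():.6f})")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


#: default stage weights for the LAI and soil-moisture composites
LAI_STAGE_WEIGHTS = StageWeights("LAI", (0.0550, 0.2650, 0.5660, 0.1140))
SM_STAGE_WEIGHTS = StageWeights("SM", (0.0555, 0.5655, 0.2605, 0.1185))


def stage_composite(values, w: StageWeights) -> float:
    """Weighted sum over the four stages; `values` is a mapping or 4-sequence."""
    if isinstance(values, dict):
        missing = [s for s in YIELD_STAGES if s not in values]
        if missing:
            raise ValueError(f"missing stage value for: {', '.join(missing)}")
        v = np.array([float(values[s]) for s in YIELD_STAGES])
    else:
        v = np.asarray(values, dtype=float)
        if v.shape[-1] != 4:
            raise ValueError("need one value per stage (4)")
        if np.any(np.isnan(v)):
            bad = YIELD_STAGES[int(np.argmax(np.isnan(np.atleast_2d(v)).any(axis=0)))]
            raise ValueError(f"missing stage value for: {bad}")
    out = v @ w.as_array()
    return float(out) if np.ndim(out) == 0 else out


def _p_class(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


class StageWeightedYieldModel:
    """Linear yield model on stage-weighted composites for one regime/strategy.

    Predictors per strategy: LAI composite (``LAI_only``), soil-moisture
    composite (``SM_only``) or both (``joint``).  ``fit()`` returns a
    :class:`YieldResults` wrapping an OLS fit.
    """

    def __init__(self, data: pd.DataFrame, regime: str, strategy: str):
        if regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        self.regime = regime
        self.strategy = strategy
        self.predictors = {
            "LAI_only": ["lai_composite"],
            "SM_only": ["sm_composite"],
            "joint": ["lai_composite", "sm_composite"],
        }[strategy]
        need = set(self.predictors) | {"yield"}
        if not need.issubset(data.columns):
            raise ValueError(f"data must have columns {sorted(need)}")
        self.data = data.reset_index(drop=True)
        if len(self.data) < len(self.predictors) + 2:
            raise ValueError("too few sites for the number of predictors")

    @classmethod
    def from_dataframe(cls, data, regime, strategy):
        return cls(data, regime, strategy)

    def fit(self) -> "YieldResults":
        X = self.data[self.predictors].to_numpy(dtype=float)
        if len(self.predictors) == 2:
            corr = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
            if not np.isfinite(corr) or abs(corr) > 1 - 1e-10:
                raise ValueError("collinear predictors in the joint yield model")
        if np.any(np.ptp(X, axis=0) == 0):
            raise ValueError("degenerate (constant) predictor")
        y = self.data["yield"].to_numpy(dtype=float)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        return YieldResults(self, res)


class YieldResults:
    """Fitted yield model: coefficients, R^2, significance class, predict()."""

    def __init__(self, model: StageWeightedYieldModel, ols_results):
        self.model = model
        self._res = ols_results
        self.intercept = float(ols_results.params[0])
        self.coefficients = dict(
            zip(model.predictors, (float(c) for c in ols_results.params[1:]))
        )
        self.r2 = float(ols_results.rsquared)
        self.p_value = float(ols_results.f_pvalue)
        self.p_class = _p_class(self.p_value)
        self.n = int(ols_results.nobs)

    @property
    def regime(self) -> str:
        return self.model.regime

    @property
    def strategy(self) -> str:
        return self.model.strategy

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.model.predictors].to_numpy(dtype=float)
        out = self.intercept + X @ np.array(
            [self.coefficients[p] for p in self.model.predictors]
        )
        return np.clip(out, 0.0, None)

    def equation(self) -> str:
        terms = [
            f"{self.coefficients[p]:.1f} x {'LAI' if p.startswith('lai') else 'theta'}"
            for p in self.model.predictors
        ]
        sign = "+" if self.intercept >= 0 else "-"
        return f"Y = {' + '.join(terms)} {sign} {abs(self.intercept):.1f}"

    def summary(self) -> str:
        lines = [
            f"Stage-weighted yield model [{self.regime}, {self.strategy}]",
            "-" * 50,
            f"  {self.equation()}",
            f"  R2 = {self.r2:.3f}   p = {self.p_value:.4g} ({self.p_class})   n = {self.n}",
        ]
        return "\n".join(lines)


def fit_yield_model(
    composites: pd.DataFrame, yields, regime: str, strategy: str
) -> YieldResults:
    """OLS of measured yield on stage composites (functional wrapper)."""
    data = composites.copy()
    data["yield"] = np.asarray(yields, dtype=float)
    return StageWeightedYieldModel(data, regime, strategy).fit()


def predict_yield(
    models: dict,
    regime_codes: Raster,
    lai_composite: Raster | None = None,
    sm_composite: Raster | None = None,
) -> Raster:
    """Per-pixel yield raster applying the regime-appropriate model.

    `models` maps regime name -> YieldResults; `regime_codes` carries integer
    classes (1 irrigated, 2 rain_fed, 0/NaN elsewhere -> nodata in the
    output).  Composite rasters must be aligned with the mask.
    """
    if regime_codes is None:
        raise ValueError("regime mask missing")
    out = np.full(regime_codes.shape, np.nan)
    comp = {"lai_composite": lai_composite, "sm_composite": sm_composite}
    for code, regime in ((1, "irrigated"), (2, "rain_fed")):
        if regime not in models:
            continue
        res = models[regime]
        sel = regime_codes.data == code
        if not sel.any():
            continue
        cols = {}
        for p in res.model.predictors:
            r = comp[p]
            if r is None:
                raise ValueError(f"missing composite raster for predictor {p}")
            regime_codes.require_aligned(r, p)
            cols[p] = r.data[sel]
        X = pd.DataFrame(cols)
        out[sel] = res.predict(X)
    return regime_codes.like(out)


@dataclass
class ValidationReport:
    regime: str
    strategy: str
    rmse: float  # kg ha-1
    are: float  # percent
    n_sites: int
    residuals: np.ndarray = field(repr=False, default=None)


def validate(predicted, measured, regime: str = "", strategy: str = "") -> ValidationReport:
    """RMSE and mean absolute relative error of paired site yields."""
    p = np.asarray(predicted, dtype=float).ravel()
    m = np.asarray(measured, dtype=float).ravel()
    if p.shape != m.shape:
        raise ValueError("predicted and measured must pair up")
    if len(p) < 2:
        raise ValueError("need at least 2 validation pairs")
    if np.any(m <= 0):
        raise ValueError("measured yields must be positive")
    resid = p - m
    return ValidationReport(
        regime=regime,
        strategy=strategy,
        rmse=float(np.sqrt(np.mean(resid**2))),
        are=float(100.0 * np.mean(np.abs(resid) / m)),
        n_sites=len(p),
        residuals=resid,
    )


def compare_strategies(reports: list[ValidationReport]) -> pd.DataFrame:
    """Rank strategies by RMSE then ARE within each regime.

    Returns a table with a `rank` column and a `recommended` flag on each
    regime's winner.  Ties on both metrics break by strategy declaration
    order and are flagged in the `tie` column.
    """
    if not reports:
        raise ValueError("no validation reports")
    rows = [
        {
            "regime": r.regime,
            "strategy": r.strategy,
            "rmse": r.rmse,
            "are": r.are,
            "n_sites": r.n_sites,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    df["_order"] = df["strategy"].map({s: i for i, s in enumerate(STRATEGIES)})
    out = []
    for regime, grp in df.groupby("regime", sort=False):
        grp = grp.sort_values(["rmse", "are", "_order"]).reset_index(drop=True)
        grp["rank"] = np.arange(1, len(grp) + 1)
        grp["recommended"] = grp["rank"] == 1
        tie = (
            len(grp) > 1
            and np.isclose(grp.loc[0, "rmse"], grp.loc[1, "rmse"])
            and np.isclose(grp.loc[0, "are"], grp.loc[1, "are"])
        )
        grp["tie"] = False
        if tie:
            grp.loc[[0, 1], "tie"] = True
            warnings.warn(f"tied strategies in regime {regime}; broke by declaration order")
        if len(grp) == 1:
            warnings.warn(f"single strategy for regime {regime}; returned as winner")
        out.append(grp)
    return pd.concat(out, ignore_index=True).drop(columns="_order")
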