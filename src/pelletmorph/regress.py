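"""Multiple linear regression of median pellet diameter on cultivation
parameters.

The model regresses ln(median area-equivalent diameter) on ln(spore
concentration), ln(shaking frequency), talc concentration (untransformed)
and a 0/1 baffle indicator, treating each shake-flask replicate as an
independent observation. Replicates with fewer than 30 pellets or a
multimodal diameter distribution are excluded before fitting. Assumption
diagnostics (residual cloud, QQ agreement, heteroscedasticity score),
a predictor correlation matrix and variance inflation factors accompany
every fit; non-significant predictors are removed by single-pass backward
elimination.

The reduced two-predictor model yields the back-transformed prediction

    PD (µm) = exp(b0 + bA·ln(A) + bT·T)

with default coefficients (15.863, −1.7769, −0.10856) for shaking
frequency A (rpm) and talc concentration T (g L⁻¹), valid for predicted
diameters of roughly 150–1200 µm.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthgen import PREDICTION_COEFFICIENTS

logger = logging.getLogger(__name__)

FULL_PREDICTORS = ("ln_spore", "ln_agitation", "talc", "baffled")
REDUCED_PREDICTORS = ("ln_agitation", "talc")

#: back-transformed predictions outside this range are flagged
VALID_PREDICTION_RANGE_UM = (150.0, 1200.0)

#: multicollinearity is conventionally flagged above this VIF
VIF_CRITICAL = 10.0


@dataclass(frozen=True)
class ConditionIndex:
    """One cultivation condition of the study grid."""

    spore_conc: float  # spores mL⁻¹
    agitation: float  # rpm
    talc: float  # g L⁻¹
    baffled: bool


@dataclass
class RegressionDataset:
    """Admissible replicate rows with transformed model columns."""

    frame: pd.DataFrame  # includes ln_pd, ln_spore, ln_agitation, talc, baffled

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclass
class RegressionModel:
    """OLS fit with inference, multicollinearity and diagnostics hooks."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adjusted_r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    vif: pd.Series
    correlation_matrix: pd.DataFrame
    conf_int: pd.DataFrame
    nobs: int
    elimination_trace: list = field(default_factory=list)


def load_replicate_table(path: str | Path) -> pd.DataFrame:
    """Read a replicate-median table.

    Expected columns: spore_conc, agitation_rpm, talc_g_per_l, baffled,
    replicate_id, median_ed_um, n_pellets, modality. This is also the
    schema in which a user can supply the study's own replicate table.
    """
    df = pd.read_csv(path)
    required = {
        "spore_conc", "agitation_rpm", "talc_g_per_l", "baffled",
        "median_ed_um", "n_pellets", "modality",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"replicate table is missing columns: {sorted(missing)}")
    return df


def build_dataset(summaries: pd.DataFrame) -> RegressionDataset:
    """Apply exclusion rules and ln transforms to the replicate table.

    Rows with fewer than 30 pellets or a multimodal population are dropped;
    pellet diameter, spore concentration and shaking frequency are
    ln-transformed; talc stays on its natural scale; baffled is encoded 0/1.
    """
    df = summaries.copy()
    admissible = (df["n_pellets"] >= 30) & (df["modality"] == "unimodal")
    df = df.loc[admissible].reset_index(drop=True)
    if df.empty:
        raise ValueError("no admissible rows (all excluded or multimodal)")
    df["ln_pd"] = np.log(df["median_ed_um"].astype(float))
    df["ln_spore"] = np.log(df["spore_conc"].astype(float))
    df["ln_agitation"] = np.log(df["agitation_rpm"].astype(float))
    df["talc"] = df["talc_g_per_l"].astype(float)
    df["baffled"] = df["baffled"].astype(bool).astype(int)
    if not np.isfinite(df[["ln_pd", "ln_spore", "ln_agitation"]].to_numpy()).all():
        raise ValueError("non-finite values after ln transform")
    return RegressionDataset(frame=df)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: VIF_j = 1 / (1 − R²_j).

    R²_j comes from regressing predictor j on the remaining predictors
    (with intercept). Perfectly collinear predictors are reported as
    infinite with a warning.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col).to_numpy(dtype=float))
        fit = sm.OLS(design[col].to_numpy(dtype=float), others).fit()
        r2 = fit.rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor '{col}' is perfectly collinear; VIF is infinite")
            out[col] = float("inf")
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_ols(
    dataset: RegressionDataset,
    predictors: tuple[str, ...] = FULL_PREDICTORS,
    response: str = "ln_pd",
) -> RegressionModel:
    """Least-squares fit of the response on the chosen predictor subset.

    Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1); p values are two-sided
    from the t distribution with n − p − 1 degrees of freedom. A
    rank-deficient design raises an error naming the collinear columns.
    """
    df = dataset.frame
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValueError("not enough rows for the requested predictor set")
    x = df[list(predictors)].to_numpy(dtype=float)
    exog = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        bad = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"design is rank deficient; collinear columns: {bad or predictors}")
    fit = sm.OLS(df[response].to_numpy(dtype=float), exog).fit()
    names = ["const"] + list(predictors)
    # a constant response has zero total sum of squares; define R² = 0 there
    r2 = float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0
    adj_r2 = float(fit.rsquared_adj) if np.isfinite(fit.rsquared_adj) else 0.0
    if len(predictors) >= 2:
        vif_series = vif(df[list(predictors)])
        corr_mat = df[list(predictors)].corr()
    else:
        vif_series = pd.Series({p: 1.0 for p in predictors})
        corr_mat = df[list(predictors)].corr()
    ci = fit.conf_int(alpha=0.05)
    return RegressionModel(
        predictors=tuple(predictors),
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        tvalues=pd.Series(fit.tvalues, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        r2=r2,
        adjusted_r2=adj_r2,
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        vif=vif_series,
        correlation_matrix=corr_mat,
        conf_int=pd.DataFrame(ci, index=names, columns=["lo95", "hi95"]),
        nobs=n,
    )


def diagnostics(model: RegressionModel) -> dict:
    """Assumption diagnostics as data (plots optional downstream).

    - residual-vs-fitted pairs (random cloud around zero expected);
    - QQ pairs of ordered residuals against normal quantiles;
    - heteroscedasticity score: Pearson correlation of |residual| with the
      fitted value (a numeric stand-in for the visual funnel-shape check);
    - normality statistic: correlation of the ordered residuals with their
      normal order-statistic quantiles (probability-plot correlation).
    A perfect fit (all residuals zero) is flagged as degenerate.
    """
    resid = model.residuals
    fitted = model.fitted
    degenerate = bool(np.allclose(resid, 0.0))
    if degenerate:
        return {
            "residuals": resid,
            "fitted": fitted,
            "qq": (np.array([]), np.array([])),
            "heteroscedasticity_score": 0.0,
            "normality_ppcc": float("nan"),
            "degenerate": True,
        }
    (osm, osr), _ = stats.probplot(resid, dist="norm")
    het = float(stats.pearsonr(np.abs(resid), fitted)[0]) if np.std(fitted) > 0 else 0.0
    ppcc = float(np.corrcoef(osm, osr)[0, 1])
    return {
        "residuals": resid,
        "fitted": fitted,
        "qq": (osm, osr),
        "heteroscedasticity_score": het,
        "normality_ppcc": ppcc,
        "degenerate": False,
    }


def eliminate_nonsignificant(
    dataset: RegressionDataset,
    alpha: float = 0.05,
    predictors: tuple[str, ...] = FULL_PREDICTORS,
    response: str = "ln_pd",
) -> RegressionModel:
    """Backward elimination: drop the worst p > alpha predictor, refit, repeat.

    The elimination trace (predictor, p value at removal) is kept on the
    returned model. If everything is eliminated, an intercept-only model is
    returned with a warning.
    """
    current = list(predictors)
    trace: list[tuple[str, float]] = []
    while current:
        if len(current) == 1:
            # single-predictor fit; VIF undefined, handled inside fit_ols
            model = fit_ols(dataset, tuple(current), response=response)
        else:
            model = fit_ols(dataset, tuple(current), response=response)
        pvals = model.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            model.elimination_trace = trace
            return model
        trace.append((worst, float(pvals[worst])))
        current.remove(worst)
    warnings.warn("all predictors eliminated; returning intercept-only model")
    df = dataset.frame
    y = df[response].to_numpy(dtype=float)
    fit = sm.OLS(y, np.ones((len(y), 1))).fit()
    model = RegressionModel(
        predictors=(),
        params=pd.Series(fit.params, index=["const"]),
        bse=pd.Series(fit.bse, index=["const"]),
        tvalues=pd.Series(fit.tvalues, index=["const"]),
        pvalues=pd.Series(fit.pvalues, index=["const"]),
        r2=0.0,
        adjusted_r2=0.0,
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        vif=pd.Series(dtype=float),
        correlation_matrix=pd.DataFrame(),
        conf_int=pd.DataFrame(fit.conf_int(), index=["const"], columns=["lo95", "hi95"]),
        nobs=len(y),
        elimination_trace=trace,
    )
    return model


def predict_diameter(
    agitation: float,
    talc: float,
    coefficients: tuple[float, float, float] = PREDICTION_COEFFICIENTS,
) -> float:
    """Back-transformed median-diameter prediction PD = exp(b0 + bA·ln A + bT·T).

    Valid for predictions of roughly 150–1200 µm; out-of-range predictions
    are flagged with a warning but still returned.
    """
    if agitation <= 0:
        raise ValueError("agitation must be positive (rpm)")
    if talc < 0:
        raise ValueError("talc concentration must be >= 0")
    b0, b_a, b_t = coefficients
    pd_um = math.exp(b0 + b_a * math.log(agitation) + b_t * talc)
    lo, hi = VALID_PREDICTION_RANGE_UM
    if not lo <= pd_um <= hi:
        warnings.warn(
            f"prediction {pd_um:.1f} µm is outside the validated range "
            f"{lo:.0f}–{hi:.0f} µm"
        )
    return pd_um


def model_summary_dict(model: RegressionModel) -> dict:
    """JSON-serialisable model summary for reports."""
    return {
        "predictors": list(model.predictors),
        "coefficients": model.params.to_dict(),
        "std_errors": model.bse.to_dict(),
        "p_values": model.pvalues.to_dict(),
        "r2": model.r2,
        "adjusted_r2": model.adjusted_r2,
        "vif": model.vif.to_dict(),
        "correlation_matrix": model.correlation_matrix.to_dict(),
        "n_observations": model.nobs,
        "elimination_trace": model.elimination_trace,
    }
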