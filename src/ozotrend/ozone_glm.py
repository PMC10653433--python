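"""Concentration retrieval: station rules, log-link GLM, annual surfaces.

The retrieval stage turns hourly station ozone records into daily response
values (8-h moving averages with the 6-of-8 validity rule, daily means
under the strict >75% completeness rule), joins them with per-day gridded
covariates into a design table, and fits a generalized linear model with a
log link.  The family is Gaussian: the response is a continuous
concentration and only the link is prescribed by the retrieval design.
Variable selection is bidirectional stepwise on AIC starting from the full
model, followed by iterative removal of coefficients with p > 0.05.

Predicted daily surfaces exp(x'beta) are averaged into annual means, and a
binary rise indicator marks pixels whose annual mean did not decrease
between the two analysis years (ties count as a rise).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .geodata import CategoricalRaster, ContinuousRaster, GridError, Grid

__all__ = [
    "CovariateStack",
    "CvReport",
    "OzoneGLM",
    "o3_8h_series",
    "daily_mean",
    "station_daily",
    "build_design",
    "fit_glm",
    "stepwise_aic",
    "cross_validate",
    "predict_annual",
    "rise_indicator",
]

logger = logging.getLogger(__name__)

#: daily mean is valid only if strictly more than 75% of the 24 hourly
#: slots are valid, i.e. at least 19
MIN_VALID_HOURS = 19
#: the 8-h moving average needs at least 6 of its 8 hours
MIN_HOURS_8H = 6


# ---------------------------------------------------------------------------
# Covariate container


@dataclass
class CovariateStack:
    """Per-day covariate surfaces on a common grid.

    ``layers[date][name]`` is a :class:`ContinuousRaster`; every day holds
    the same variable set (including the deterministic LON/LAT/DNS layers).
    ``dns_origin`` anchors the day-number-sequence variable: DNS = 1 on the
    origin date.
    """

    grid: Grid
    dns_origin: _date
    layers: dict = field(default_factory=dict)

    @property
    def dates(self) -> list:
        return sorted(self.layers)

    @property
    def var_names(self) -> list[str]:
        first = self.layers[self.dates[0]]
        return list(first)

    def add_day(self, day: _date, rasters: dict) -> None:
        self.layers[day] = dict(rasters)

    def day_arrays(self, day: _date) -> dict[str, np.ndarray]:
        return {name: r.values for name, r in self.layers[day].items()}

    def dates_for_year(self, year: int) -> list:
        return [d for d in self.dates if d.year == year]


# ---------------------------------------------------------------------------
# Station preprocessing


def o3_8h_series(raw: pd.Series) -> pd.Series:
    """8-h moving average of an hourly series with the 6-of-8 validity rule.

    ``raw`` is indexed by hourly timestamps (gaps allowed).  The value at
    hour t is the mean of the raw values at hours t-7..t provided at least
    6 of those 8 hours are present; otherwise it is missing.
    """
    if raw.empty:
        return raw.astype(float)
    idx = pd.date_range(raw.index.min(), raw.index.max(), freq="h")
    full = raw.reindex(idx)
    if not full.index.is_monotonic_increasing:
        raise ValueError("timestamps must be strictly increasing")
    return full.rolling(window=8, min_periods=MIN_HOURS_8H).mean()


def daily_mean(series: pd.Series) -> pd.DataFrame:
    """Daily means of an hourly series under the strict >75% rule.

    Returns a frame with columns date, value, valid, n_valid; a day is
    valid only when at least 19 of its 24 hourly slots carry a value
    (18/24 = 75% exactly does not qualify).
    """
    if series.empty:
        return pd.DataFrame(columns=["date", "value", "valid", "n_valid"])
    days = series.index.floor("D")
    grouped = series.groupby(days)
    out = pd.DataFrame(
        {
            "value": grouped.mean(),
            "n_valid": grouped.count(),
        }
    )
    out["valid"] = out["n_valid"] >= MIN_VALID_HOURS
    out.index = out.index.date
    out = out.rename_axis("date").reset_index()
    return out[["date", "value", "valid", "n_valid"]]


def station_daily(hourly: pd.DataFrame, response: str = "o3_8h") -> pd.DataFrame:
    """Per-station daily response values from a raw hourly table.

    ``hourly`` has columns station_id, timestamp, o3_ugm3.  ``response``
    selects the quantity averaged into the daily value: the 8-h moving
    average series (default) or the raw hourly values.
    """
    if response not in {"o3_8h", "hourly"}:
        raise ValueError("response must be 'o3_8h' or 'hourly'")
    frames = []
    for sid, g in hourly.groupby("station_id"):
        s = pd.Series(
            g["o3_ugm3"].to_numpy(), index=pd.DatetimeIndex(g["timestamp"])
        ).sort_index()
        base = o3_8h_series(s) if response == "o3_8h" else s.reindex(
            pd.date_range(s.index.min(), s.index.max(), freq="h")
        )
        d = daily_mean(base)
        d.insert(0, "station_id", sid)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def build_design(
    daily: pd.DataFrame, covariates: CovariateStack, stations: pd.DataFrame
) -> pd.DataFrame:
    """Design table with one row per valid (station, day) pair.

    Predictors are sampled at the station's pixel for the matching day;
    LON/LAT come from the station position, DNS is the day index counted
    from the covariate stack's origin (origin day = 1).  Rows with any
    missing predictor are dropped and counted.
    """
    grid = covariates.grid
    st = stations.set_index("station_id")
    rows, cols, keep = {}, {}, []
    for sid, s in st.iterrows():
        r, c = grid.xy_to_rowcol(s["lon"], s["lat"])
        if grid.contains_rowcol(r, c):
            rows[sid], cols[sid] = int(r), int(c)
            keep.append(sid)
        else:
            warnings.warn(f"station {sid} outside the covariate grid; dropped")
    day_set = set(covariates.dates)
    var_names = covariates.var_names
    records = []
    n_missing = 0
    for _, row in daily.iterrows():
        sid, day = row["station_id"], row["date"]
        if not row["valid"] or sid not in rows or day not in day_set:
            continue
        arrays = covariates.day_arrays(day)
        r, c = rows[sid], cols[sid]
        rec = {"station_id": sid, "date": day, "y": row["value"]}
        for name in var_names:
            if name == "LON":
                rec[name] = float(st.loc[sid, "lon"])
            elif name == "LAT":
                rec[name] = float(st.loc[sid, "lat"])
            elif name == "DNS":
                rec[name] = float((day - covariates.dns_origin).days + 1)
            else:
                rec[name] = float(arrays[name][r, c])
        if any(not np.isfinite(rec[n]) for n in var_names) or not np.isfinite(rec["y"]):
            n_missing += 1
            continue
        records.append(rec)
    if n_missing:
        logger.info("build_design: dropped %d row(s) with missing predictors", n_missing)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# The GLM estimator


@dataclass
class CvReport:
    """Cross-validation summary: squared correlation and percent RMSE."""

    r2: float
    rmse_pct: float
    n: int
    k_used: int


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that are (numerically) linear combinations of earlier ones."""
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    keep = []
    for j, col in enumerate(X.columns):
        sub = mat[:, [0] + [1 + X.columns.get_loc(c) for c in keep] + [1 + j]]
        if np.linalg.matrix_rank(sub) == sub.shape[1]:
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear predictor {col!r}")
    return X[keep]


def _glm_fit(y: np.ndarray, X: pd.DataFrame, max_iter: int):
    """Gaussian GLM with log link, warm-started from an OLS on log(y)."""
    Xc = sm.add_constant(X, has_constant="add")
    start = None
    try:
        start = np.linalg.lstsq(Xc.to_numpy(float), np.log(y), rcond=None)[0]
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        pass
    model = sm.GLM(y, Xc, family=sm.families.Gaussian(sm.families.links.Log()))
    with warnings.catch_warnings():
        # a numerically exact continuous fit trips the separation heuristic
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(start_params=start, maxiter=max_iter)
    if not res.converged:
        # IRLS's deviance criterion oscillates at machine precision when the
        # fit is numerically perfect; accept iff the solution is stationary
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            probe = model.fit(start_params=np.asarray(res.params), maxiter=2)
        move = np.max(np.abs(np.asarray(probe.params) - np.asarray(res.params)))
        if move <= 1e-8 * (1.0 + np.max(np.abs(np.asarray(res.params)))):
            return probe
        raise RuntimeError(
            f"GLM did not converge after {max_iter} iterations "
            f"(deviance {res.deviance:.4g}, vars {list(X.columns)})"
        )
    return res


class OzoneGLM(RegressorMixin, BaseEstimator):
    """Log-link Gaussian GLM for daily ozone concentrations.

    Parameters
    ----------
    selection
        ``"none"`` fits all supplied predictors; ``"aic"`` runs
        bidirectional stepwise selection from the full model (each step
        applies the single add/drop move that most reduces AIC) and then
        iteratively removes variables with p-values above ``p_threshold``,
        refitting after each removal.
    p_threshold
        Significance ceiling for retained variables under AIC selection.
    max_iter
        IRLS iteration cap.

    Attributes
    ----------
    variables_ : list of retained predictor names
    params_ : pd.Series of coefficients (including ``const``)
    pvalues_ : pd.Series of per-coefficient p-values
    aic_ : float
    n_dropped_nonpositive_ : rows discarded because y <= 0 (log link)
    """

    def __init__(self, selection: str = "aic", p_threshold: float = 0.05, max_iter: int = 200):
        self.selection = selection
        self.p_threshold = p_threshold
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _fit_subset(self, y, X, variables):
        return _glm_fit(y, X[list(variables)], self.max_iter)

    def _stepwise_aic(self, y, X):
        current = list(X.columns)
        res = self._fit_subset(y, X, current)
        best_aic = res.aic
        improved = True
        while improved:
            improved = False
            moves = [("drop", v) for v in current] + [
                ("add", v) for v in X.columns if v not in current
            ]
            best_move = None
            for kind, v in moves:
                trial = [c for c in current if c != v] if kind == "drop" else current + [v]
                try:
                    cand = self._fit_subset(y, X, trial)
                except (RuntimeError, np.linalg.LinAlgError):
                    continue
                if cand.aic < best_aic - 1e-9:
                    best_aic, best_move, best_res = cand.aic, (kind, v, trial), cand
            if best_move is not None:
                current = best_move[2]
                res = best_res
                improved = True
                logger.info(
                    "stepwise AIC: %s %s -> AIC %.3f", best_move[0], best_move[1], best_aic
                )
        # p-value pruning, worst offender first, refit after each removal
        while current:
            pv = res.pvalues.drop("const", errors="ignore")
            if pv.empty or pv.max() <= self.p_threshold:
                break
            worst = pv.idxmax()
            current = [c for c in current if c != worst]
            logger.info("excluding %s (p=%.3f > %.2f)", worst, pv.max(), self.p_threshold)
            res = self._fit_subset(y, X, current)
        if not current:
            warnings.warn("stepwise selection removed every variable; intercept-only model")
            res = self._fit_subset(y, X, [])
        return current, res

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        pos = y > 0
        self.n_dropped_nonpositive_ = int((~pos).sum())
        if self.n_dropped_nonpositive_:
            logger.info(
                "dropping %d row(s) with non-positive response (log link)",
                self.n_dropped_nonpositive_,
            )
        X, y = X.loc[pos].reset_index(drop=True), y[pos]
        if len(X) < X.shape[1] + 2:
            raise ValueError("need at least Q+2 rows to fit the GLM")
        X = _drop_collinear(X)
        if self.selection == "aic":
            self.variables_, res = self._stepwise_aic(y, X)
        elif self.selection == "none":
            self.variables_, res = list(X.columns), self._fit_subset(y, X, X.columns)
        else:
            raise ValueError("selection must be 'aic' or 'none'")
        self.result_ = res
        self.params_ = res.params
        self.pvalues_ = res.pvalues
        self.aic_ = float(res.aic)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        lin = np.full(len(X), float(self.params_["const"]))
        for v in self.variables_:
            lin = lin + self.params_[v] * X[v].to_numpy(float)
        return np.exp(lin)

    def predict_from_arrays(self, arrays: dict) -> np.ndarray:
        """Vectorized prediction from a name -> ndarray mapping (raster math)."""
        lin = None
        for v in self.variables_:
            term = self.params_[v] * arrays[v]
            lin = term if lin is None else lin + term
        if lin is None:
            lin = 0.0
        return np.exp(float(self.params_["const"]) + lin)


# ---------------------------------------------------------------------------
# Functional wrappers and downstream surfaces


def _split_design(design: pd.DataFrame):
    meta = [c for c in ("station_id", "date", "y") if c in design.columns]
    X = design.drop(columns=meta)
    return X, design["y"].to_numpy(float)


def fit_glm(design: pd.DataFrame, selection: str = "none") -> OzoneGLM:
    """Fit the log-link GLM on a design table (columns: y + predictors)."""
    X, y = _split_design(design)
    return OzoneGLM(selection=selection).fit(X, y)


def stepwise_aic(design: pd.DataFrame) -> OzoneGLM:
    """AIC-stepwise GLM (bidirectional from the full model, then p > 0.05 pruning)."""
    return fit_glm(design, selection="aic")


def cross_validate(
    design: pd.DataFrame, k: int = 10, seed: int = 0, selection: str = "aic"
) -> CvReport:
    """k-fold cross-validation of the GLM pipeline on a design table.

    Rows are partitioned at random (seeded) into k folds; the model —
    including variable selection — is refit on each training split and the
    pooled out-of-fold predictions are scored: R^2 is the squared Pearson
    correlation of predicted vs observed, RMSE is reported as a percent of
    the observed mean.
    """
    X, y = _split_design(design)
    if len(y) < k:
        raise ValueError("fewer rows than folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.full(len(y), np.nan)
    used = 0
    for train, test in kf.split(X):
        try:
            est = OzoneGLM(selection=selection).fit(X.iloc[train], y[train])
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"fold skipped (degenerate fit: {exc})")
            continue
        pred[test] = est.predict(X.iloc[test])
        used += 1
    ok = np.isfinite(pred)
    obs, est_vals = y[ok], pred[ok]
    r = np.corrcoef(obs, est_vals)[0, 1]
    rmse = float(np.sqrt(np.mean((obs - est_vals) ** 2)))
    return CvReport(
        r2=float(r**2), rmse_pct=100.0 * rmse / float(np.mean(obs)), n=int(ok.sum()), k_used=used
    )


def predict_annual(fit: OzoneGLM, covariates: CovariateStack, year: int) -> ContinuousRaster:
    """Annual mean concentration surface: per-day exp(x'beta), averaged.

    Pixels missing any day's covariate value propagate to nodata.
    """
    days = covariates.dates_for_year(year)
    if not days:
        raise ValueError(f"covariate stack has no days in year {year}")
    grid = covariates.grid
    lon, lat = grid.center_grids()
    acc = np.zeros(grid.shape)
    for day in days:
        arrays = dict(covariates.day_arrays(day))
        arrays.setdefault("LON", lon)
        arrays.setdefault("LAT", lat)
        arrays["DNS"] = np.full(grid.shape, float((day - covariates.dns_origin).days + 1))
        acc += fit.predict_from_arrays(arrays)
    return ContinuousRaster(grid, acc / len(days), units="ug/m3")


def rise_indicator(a2015: ContinuousRaster, a2020: ContinuousRaster) -> CategoricalRaster:
    """Binary raster: 1 where the annual mean did not decrease (ties rise)."""
    if not a2015.grid.aligned(a2020.grid):
        raise GridError("annual surfaces are not on the same grid")
    valid = a2015.valid_mask & a2020.valid_mask
    codes = np.full(a2015.values.shape, -1, dtype=np.int32)
    codes[valid] = (a2015.values[valid] <= a2020.values[valid]).astype(np.int32)
    return CategoricalRaster(
        a2015.grid, codes, nodata=-1, legend={0: "no rise", 1: "rise"}
    )
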