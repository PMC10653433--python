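"""Rise-probability modelling: sampling, screening, logistic trend model.

Sample pixels are drawn from the change map by stratified random sampling
(Cochran-sized), described by their change category (CLA) and the twelve
window pattern indices, and labelled with the rise indicator.  After a
Pearson screen of index-vs-trend correlations, a logistic regression is
built by forward stepwise selection on the deviance statistic: at each
step the candidate with the largest deviance drop enters, provided the
drop passes a chi-square test at level alpha; every tested move is
recorded in a fitting ledger.  The fitted model is evaluated by the
percent of test samples correctly predicted at the 0.5 threshold (PCP)
and the rank-based AUC, and finally mapped into a per-pixel probability
surface with district means.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .geodata import CategoricalRaster, ContinuousRaster, GridError
from .winmetrics import MetricStack

__all__ = [
    "SampleSpec",
    "EvalReport",
    "RiseLogit",
    "cochran_n",
    "stratified_sample",
    "build_feature_table",
    "pearson_screen",
    "fit_lrm",
    "deviance",
    "deviance_from_probs",
    "stepwise_deviance",
    "evaluate",
    "predict_surface",
    "district_means",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [f"{m}{w}" for w in (3, 5, 7) for m in ("HET", "HOM", "DMG", "CON")]


@dataclass(frozen=True)
class SampleSpec:
    """Inputs of the Cochran sample-size formula (percent scale)."""

    p: float = 60.0  # expected accuracy, percent
    e: float = 5.0  # allowed error, percent
    z: float = 1.96  # standard normal deviate at 95% confidence

    def __post_init__(self):
        if not (0.0 < self.p < 100.0):
            raise ValueError("expected accuracy p must be in (0, 100)")
        if self.e <= 0 or self.z <= 0:
            raise ValueError("E and Z must be positive")


def cochran_n(spec: SampleSpec) -> int:
    """Sample size N = ceil(Z^2 p (100 - p) / E^2), p and E in percent."""
    raw = spec.z**2 * spec.p * (100.0 - spec.p) / spec.e**2
    return int(math.ceil(round(raw, 9)))


# ---------------------------------------------------------------------------
# Sampling


def _largest_remainder(counts: dict, n: int) -> dict:
    """Proportional allocation with largest-remainder rounding, >=1 per
    present category, capped at availability."""
    total = sum(counts.values())
    quota = {c: n * cnt / total for c, cnt in counts.items()}
    alloc = {c: int(math.floor(q)) for c, q in quota.items()}
    rest = n - sum(alloc.values())
    order = sorted(quota, key=lambda c: (quota[c] - alloc[c], counts[c], -c), reverse=True)
    for c in order[:rest]:
        alloc[c] += 1
    # minimum one per present category
    for c in alloc:
        if alloc[c] == 0 and counts[c] > 0:
            alloc[c] = 1
            donor = max(
                (d for d in alloc if alloc[d] > 1), key=lambda d: alloc[d], default=None
            )
            if donor is not None:
                alloc[donor] -= 1
    # cap at availability, pushing overflow to categories with room
    over = {c: alloc[c] - counts[c] for c in alloc if alloc[c] > counts[c]}
    for c, excess in over.items():
        alloc[c] = counts[c]
        room = sorted(
            (d for d in alloc if alloc[d] < counts[d]),
            key=lambda d: counts[d] - alloc[d],
            reverse=True,
        )
        for d in room[:excess]:
            alloc[d] += 1
    return alloc


def stratified_sample(
    change: CategoricalRaster,
    n: int,
    seed: int,
    eligible_mask: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw ``n`` sample pixels stratified by change category.

    Per-category allocation is proportional to the category's share of the
    eligible area (largest-remainder rounding, at least one pixel for every
    category present); within categories, simple random sampling without
    replacement.  ``eligible_mask`` restricts the frame (e.g. to pixels
    with complete 7x7 metric windows); ``exclude`` removes already-drawn
    pixels so a test set can be disjoint from training.
    """
    rng = np.random.default_rng(seed)
    mask = change.valid_mask.copy()
    if eligible_mask is not None:
        mask &= eligible_mask
    if exclude is not None:
        mask &= ~exclude
    codes = change.codes
    counts = {
        int(c): int((codes[mask] == c).sum()) for c in np.unique(codes[mask]).tolist()
    }
    total = sum(counts.values())
    if n > total:
        raise ValueError(f"requested {n} samples but only {total} eligible pixels")
    alloc = _largest_remainder(counts, n)
    rows_out, cols_out, cats = [], [], []
    for c in sorted(alloc):
        take = alloc[c]
        if take == 0:
            continue
        rr, cc = np.nonzero(mask & (codes == c))
        pick = rng.choice(rr.size, size=take, replace=False)
        rows_out.extend(rr[pick].tolist())
        cols_out.extend(cc[pick].tolist())
        cats.extend([change.legend[c]] * take)
    out = pd.DataFrame({"row": rows_out, "col": cols_out, "CLA": cats})
    assert len(out) == n
    return out


def build_feature_table(
    samples: pd.DataFrame,
    metrics: MetricStack,
    rise: CategoricalRaster | None = None,
    dgoc: ContinuousRaster | None = None,
) -> pd.DataFrame:
    """Attach window metrics (and optionally labels / trend) to sample pixels."""
    rows = samples["row"].to_numpy(int)
    cols = samples["col"].to_numpy(int)
    out = samples.copy().reset_index(drop=True)
    for name in [f"{m}{w}" for w in metrics.window_sizes for m in ("HET", "HOM", "DMG", "CON")]:
        out[name] = metrics.layer(name).values[rows, cols]
    if rise is not None:
        lab = rise.codes[rows, cols]
        out["label"] = lab.astype(int)
    if dgoc is not None:
        out["dGOC"] = dgoc.values[rows, cols]
    return out


# ---------------------------------------------------------------------------
# Pearson screen


def pearson_screen(features: pd.DataFrame, trend_col: str = "dGOC") -> pd.DataFrame:
    """Pearson r of each pattern index against the concentration trend.

    Stars follow the usual three-level convention: *** p<0.01, ** p<0.05,
    * p<0.1.  Zero-variance columns are flagged with undefined r.
    """
    if trend_col not in features:
        raise ValueError(f"feature table lacks the trend column {trend_col!r}")
    if len(features) < 3:
        raise ValueError("need at least three rows for a correlation test")
    y = features[trend_col].to_numpy(float)
    rows = []
    for name in [c for c in METRIC_COLUMNS if c in features.columns]:
        x = features[name].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan, "zero variance"))
            continue
        r, p = stats.pearsonr(x, y)
        stars = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""
        rows.append((name, r, p, stars))
    return pd.DataFrame(rows, columns=["index", "r", "p_value", "stars"]).set_index("index")


# ---------------------------------------------------------------------------
# Logistic trend model


def deviance_from_probs(labels: np.ndarray, probs: np.ndarray) -> float:
    """-2 log-likelihood ratio against the saturated model, 0*ln(0/0) = 0.

    For exact 0/1 predictions contradicted by the label the deviance is
    infinite, and reported as such.
    """
    i = np.asarray(labels, dtype=float)
    y = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(i > 0, i * np.log(y / np.where(i > 0, i, 1.0)), 0.0)
        t0 = np.where(i < 1, (1 - i) * np.log((1 - y) / np.where(i < 1, 1 - i, 1.0)), 0.0)
    total = -2.0 * (t1 + t0).sum()
    return float(total)


class RiseLogit(ClassifierMixin, BaseEstimator):
    """Logistic regression for the per-pixel rise probability.

    The change category column (default ``CLA``) enters as dummy
    indicators against the most frequent category; all other columns are
    numeric.  ``selection="deviance"`` runs forward stepwise selection on
    the deviance statistic with a chi-square test at level ``alpha``; the
    CLA dummy block is added atomically with df = (#categories - 1) under
    the default block encoding, or as a single integer-coded column under
    ``cla_encoding="scalar"``.

    Attributes (after fit): ``variables_`` (selected, ``"CLA"`` stands for
    the whole block), ``params_``, ``deviance_``, ``ledger_`` (every
    tested step: entered variables, candidate, deviance drop, df,
    p-value), ``cla_reference_``.
    """

    def __init__(
        self,
        selection: str = "none",
        alpha: float = 0.05,
        cla_col: str = "CLA",
        cla_encoding: str = "block",
        max_iter: int = 100,
    ):
        self.selection = selection
        self.alpha = alpha
        self.cla_col = cla_col
        self.cla_encoding = cla_encoding
        self.max_iter = max_iter

    # -- design ------------------------------------------------------------

    def _encode_cla(self, s: pd.Series) -> pd.DataFrame:
        if self.cla_encoding == "scalar":
            codes = s.map(self._cla_code_map_).astype(float)
            return pd.DataFrame({self.cla_col: codes})
        d = pd.get_dummies(s, prefix=self.cla_col, dtype=float)
        ref = f"{self.cla_col}_{self.cla_reference_}"
        if ref in d.columns:
            d = d.drop(columns=ref)
        keep = [f"{self.cla_col}_{c}" for c in self.cla_categories_ if c != self.cla_reference_]
        for col in keep:
            if col not in d.columns:
                d[col] = 0.0
        return d[keep]

    def _design(self, X: pd.DataFrame, variables) -> pd.DataFrame:
        parts = []
        for v in variables:
            if v == self.cla_col:
                parts.append(self._encode_cla(X[self.cla_col].astype(str)))
            else:
                parts.append(X[[v]].astype(float))
        if parts:
            D = pd.concat(parts, axis=1)
        else:
            D = pd.DataFrame(index=X.index)
        return sm.add_constant(D, has_constant="add")

    def _fit_design(self, D: pd.DataFrame, y: np.ndarray):
        """Binomial IRLS fit (converges on the deviance criterion, as R's glm).

        Individual quasi-separated dummy levels inflate their own
        coefficient but leave the deviance well-defined, which is what the
        stepwise chi-square ledger needs.  Full perfect separation (a
        zero-deviance fit) is raised as an error naming the worst
        offender.
        """
        import warnings as _warnings

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = sm.GLM(y, D, family=sm.families.Binomial()).fit(
                    maxiter=self.max_iter
                )
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular design while fitting {list(D.columns)}"
            ) from exc
        if res.deviance < 1e-6 and len(D.columns) > 1:
            coefs = res.params.drop("const", errors="ignore").abs()
            raise PerfectSeparationError(
                f"perfect separation while fitting {list(D.columns)}; "
                f"worst offender {coefs.idxmax()!r}"
            )
        return res

    def _df_of(self, X: pd.DataFrame, v: str) -> int:
        if v == self.cla_col and self.cla_encoding == "block":
            return max(len(self.cla_categories_) - 1, 1)
        return 1

    # -- stepwise ----------------------------------------------------------

    def _stepwise(self, X: pd.DataFrame, y: np.ndarray, candidates):
        current: list[str] = []
        res = self._fit_design(self._design(X, current), y)
        dev_cur = deviance_from_probs(y, res.predict())
        ledger = []
        step = 0
        while True:
            step += 1
            tested = []
            for v in [c for c in candidates if c not in current]:
                row = {
                    "step": step,
                    "model": "1" + "".join(f",{s}" for s in current),
                    "candidate": v,
                    "df": self._df_of(X, v),
                }
                try:
                    r = self._fit_design(self._design(X, current + [v]), y)
                    dev = deviance_from_probs(y, r.predict())
                    drop = dev_cur - dev
                    p = float(stats.chi2.sf(drop, row["df"]))
                    row.update(deviance_drop=drop, p_value=p, significant=p < self.alpha)
                    tested.append((drop, v, r, dev, row))
                except (PerfectSeparationError, RuntimeError, np.linalg.LinAlgError) as exc:
                    logger.info("stepwise: candidate %s unfittable (%s)", v, exc)
                    row.update(deviance_drop=np.nan, p_value=np.nan, significant=False)
                row["selected"] = False
                ledger.append(row)
            qualifying = [t for t in tested if t[4]["significant"]]
            if not qualifying:
                break
            drop, v, r, dev, row = max(qualifying, key=lambda t: t[0])
            row["selected"] = True
            current.append(v)
            res, dev_cur = r, dev
            logger.info("stepwise deviance: added %s (drop %.3f)", v, drop)
        if not current:
            warnings.warn("no candidate ever significant; intercept-only model")
        return current, res, pd.DataFrame(ledger)

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X: pd.DataFrame, y, candidates=None):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        uniq = set(np.unique(y).tolist())
        if not uniq <= {0.0, 1.0} or len(uniq) < 2:
            raise ValueError("labels must contain both classes 0 and 1")
        self.classes_ = np.array([0, 1])
        if self.cla_col in X.columns:
            vc = X[self.cla_col].astype(str).value_counts()
            self.cla_categories_ = sorted(vc.index.tolist())
            self.cla_reference_ = vc.idxmax()
            self._cla_code_map_ = {c: i for i, c in enumerate(self.cla_categories_)}
        else:
            self.cla_categories_, self.cla_reference_ = [], None
        if candidates is None:
            candidates = ([self.cla_col] if self.cla_col in X.columns else []) + [
                c for c in X.columns if c != self.cla_col
            ]
        if self.selection == "deviance":
            self.variables_, res, self.ledger_ = self._stepwise(X, y, candidates)
        elif self.selection == "none":
            self.variables_ = list(candidates)
            res = self._fit_design(self._design(X, self.variables_), y)
            self.ledger_ = pd.DataFrame()
        else:
            raise ValueError("selection must be 'deviance' or 'none'")
        self.result_ = res
        self.params_ = res.params
        self.intercept_ = float(res.params["const"])
        self.deviance_ = deviance_from_probs(y, res.predict())
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        D = self._design(pd.DataFrame(X).reset_index(drop=True), self.variables_)
        D = D[self.result_.params.index]
        p1 = np.asarray(self.result_.predict(D), dtype=float)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # ties at 0.5 classify as a rise, mirroring the indicator's tie rule
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Functional wrappers


def _split_features(features: pd.DataFrame, variables=None):
    drop = [c for c in ("row", "col", "label", "dGOC") if c in features.columns]
    X = features.drop(columns=drop)
    if variables is not None:
        X = X[[v for v in variables]]
    return X, features["label"].to_numpy(float)


def fit_lrm(features: pd.DataFrame, variables=None, **kwargs) -> RiseLogit:
    """Maximum-likelihood logistic fit on a feature table (no selection)."""
    X, y = _split_features(features, variables)
    return RiseLogit(selection="none", **kwargs).fit(X, y)


def stepwise_deviance(features: pd.DataFrame, alpha: float = 0.05, **kwargs) -> RiseLogit:
    """Forward deviance-stepwise logistic model with a fitting ledger."""
    X, y = _split_features(features)
    return RiseLogit(selection="deviance", alpha=alpha, **kwargs).fit(X, y)


def deviance(fit: RiseLogit, features: pd.DataFrame) -> float:
    """Deviance of a fitted model evaluated on a labelled feature table."""
    X, y = _split_features(features)
    return deviance_from_probs(y, fit.predict_proba(X)[:, 1])


@dataclass
class EvalReport:
    """Held-out performance: percent correctly predicted and rank AUC."""

    pcp: float
    auc: float
    n: int


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie correction."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate(fit: RiseLogit, testset: pd.DataFrame) -> EvalReport:
    """PCP at the 0.5 threshold (ties predict a rise) and rank-based AUC."""
    X, y = _split_features(testset)
    p = fit.predict_proba(X)[:, 1]
    pred = (p >= 0.5).astype(int)
    pcp = 100.0 * float((pred == y.astype(int)).mean())
    auc = _rank_auc(y.astype(int), p)
    if math.isnan(auc):
        warnings.warn("test set contains a single class; AUC undefined")
    return EvalReport(pcp=pcp, auc=auc, n=len(y))


# ---------------------------------------------------------------------------
# Surfaces


def predict_surface(
    fit: RiseLogit, metrics: MetricStack, change: CategoricalRaster
) -> ContinuousRaster:
    """Per-pixel rise probability from the fitted model's layers."""
    needed = [v for v in fit.variables_ if v != fit.cla_col]
    for v in needed:
        if v not in metrics.layers:
            raise KeyError(f"metric layer {v!r} required by the model is missing")
    valid = change.valid_mask.copy()
    for v in needed:
        valid &= metrics.layer(v).valid_mask
    if fit.cla_col in fit.variables_:
        known = np.isin(
            change.codes, [c for c, lab in change.legend.items() if lab in fit.cla_categories_]
        )
        n_unknown = int((valid & ~known).sum())
        if n_unknown:
            warnings.warn(
                f"{n_unknown} pixel(s) carry change categories unseen in training; nodata"
            )
        valid &= known
    rows, cols = np.nonzero(valid)
    data = {fit.cla_col: [change.legend[c] for c in change.codes[rows, cols].tolist()]}
    for v in needed:
        data[v] = metrics.layer(v).values[rows, cols]
    probs = fit.predict_proba(pd.DataFrame(data))[:, 1]
    out = np.full(change.codes.shape, np.nan)
    out[rows, cols] = probs
    return ContinuousRaster(change.grid, out, units="probability")


def district_means(surface: ContinuousRaster, zones: CategoricalRaster) -> pd.DataFrame:
    """Arithmetic mean of the valid rise probability per district."""
    if not surface.grid.aligned(zones.grid):
        raise GridError("probability surface and zones are not on the same grid")
    rows = []
    for d in sorted(int(v) for v in np.unique(zones.codes[zones.valid_mask]).tolist()):
        in_d = (zones.codes == d) & surface.valid_mask
        n = int(in_d.sum())
        if n == 0:
            warnings.warn(f"district {d} has no valid probability pixels")
            rows.append((d, zones.legend.get(d, str(d)), np.nan, 0))
        else:
            rows.append((d, zones.legend.get(d, str(d)), float(surface.values[in_d].mean()), n))
    return pd.DataFrame(rows, columns=["district", "name", "mean_p", "n_pixels"])
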