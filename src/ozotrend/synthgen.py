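"""Synthetic study-area generator with a persisted truth record.

The generator emulates the statistical structure the analysis assumes,
at desk scale, so every pipeline stage can be exercised and checked
against known truth without any external data:

* a pair of patchy 5-class land-cover maps whose differences are confined
  to the six plausible transitions among artificial surfaces (A),
  cultivated land (C) and forest (F), with forest-to-artificial the most
  frequent — the signature of rapid urbanization;
* smooth daily covariate fields (the ten reanalysis-style variables are
  drawn on a coarse grid and brought to the 1 km grid by nearest-neighbor
  resampling, mimicking their native resolution; LST is generated at the
  fine scale; LON/LAT/DNS are deterministic);
* hourly station series from a known log-linear concentration model with
  a sinusoidal diel cycle, additive Gaussian noise and random missingness
  (so the 75% daily and 6-of-8 validity rules actually bite);
* a landscape-driven trend: a known logistic model on the change category
  and the window-7 pattern indices assigns each pixel a latent rise label,
  which is injected into the second year's LST field, so rising
  concentrations are genuinely attributable to landscape structure.

Everything is a pure function of the configuration (seed included); the
truth record keeps the coefficients and realized labels for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import changemap
from .changemap import encode_change, ChangeEncoding
from .geodata import CategoricalRaster, ContinuousRaster, Grid, resample_nearest
from .ozone_glm import CovariateStack
from .winmetrics import MetricStack, focal_metrics

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "Scene",
    "gen_landcover_pair",
    "gen_covariates",
    "gen_station_hourly",
    "gen_districts",
    "generate_scene",
    "generate_glm_dataset",
]

#: covariate roster: (name, generated on the coarse grid?)
COVARIATE_VARS = [
    ("RH", True),
    ("BCTP", True),
    ("BCCMASS", True),
    ("OCSMASS", True),
    ("DUSMASS25", True),
    ("SO2SMASS", True),
    ("SO4SMASS", True),
    ("SSSMASS25", True),
    ("PGENTOT", True),
    ("QV2M", True),
    ("LST", False),
]

DEFAULT_BETA = {
    "const": 4.05,
    "RH": -0.12,
    "BCTP": -0.05,
    "BCCMASS": 0.08,
    "OCSMASS": 0.05,
    "DUSMASS25": 0.04,
    "SO2SMASS": 0.06,
    "SO4SMASS": 0.05,
    "SSSMASS25": -0.04,
    "PGENTOT": -0.03,
    "QV2M": -0.08,
    "LST": 0.045,
    "LON": 0.0,
    "LAT": 0.0,
    "DNS": 0.0,
}

#: logistic truth for the landscape-driven rise label: relative weights of
#: the standardized features; the latent score is re-standardized and
#: scaled by ``signal_gain`` so the overall signal strength is controlled
#: independently of the correlations among the realized metrics
DEFAULT_B_TRUE = {"changed": 1.2, "HET7": 2.0, "HOM7": -0.8, "CON7": -1.5}
DEFAULT_EPS_TRUE = 0.5

_STREAMS = {
    "landcover": 11,
    "change": 12,
    "districts": 13,
    "covariates": 14,
    "stations": 15,
    "labels": 16,
}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study area; the seed fixes every draw."""

    n_rows: int = 72
    n_cols: int = 72
    pixel_size: float = 0.009  # ~1 km in degrees at the study latitude
    origin_x: float = 113.75
    origin_y: float = 22.90
    crs_id: str = "synthetic-lonlat"

    n_classes: int = 5
    class_props: tuple = (0.34, 0.08, 0.38, 0.08, 0.12)  # A, C, F, G, W
    smooth_sigma: float = 2.5
    change_rate: float = 0.15
    change_sigma: float = 3.0
    # how the changed area splits across source classes, and where each goes
    source_change_weights: tuple = (("F", 0.55), ("A", 0.35), ("C", 0.10))
    transition_weights: tuple = (
        ("F", (("A", 0.65), ("C", 0.35))),
        ("A", (("F", 0.60), ("C", 0.40))),
        ("C", (("A", 0.60), ("F", 0.40))),
    )

    n_stations: int = 15
    n_districts: int = 10
    years: tuple = (2015, 2020)
    days_per_year: int = 12
    season_month: int = 7
    season_day: int = 1
    dns_origin: date = date(2014, 5, 13)

    beta_true: tuple = tuple(sorted(DEFAULT_BETA.items()))
    coarse_factor: int = 6
    field_sigma: float = 1.5  # smoothing of coarse covariate fields (coarse pixels)
    lst_mean: float = 28.0
    lst_sd: float = 3.0
    lst_rise_amp: float = 6.0  # degC added to year-2 LST where the label says rise

    diurnal_amplitude: float = 0.3
    noise_sd: float = 8.0
    missing_rate: float = 0.08

    b_true: tuple = tuple(sorted(DEFAULT_B_TRUE.items()))
    eps_true: float = DEFAULT_EPS_TRUE
    signal_gain: float = 8.0  # sd of the latent logistic score; 0 = null

    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.change_rate <= 1.0):
            raise ValueError("change_rate must be in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least two land-cover classes")

    # -- convenience -------------------------------------------------------

    @property
    def grid(self) -> Grid:
        return Grid(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            pixel_size=self.pixel_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            crs_id=self.crs_id,
        )

    @property
    def beta(self) -> dict:
        return dict(self.beta_true)

    @property
    def b(self) -> dict:
        return dict(self.b_true)

    def dates(self) -> list[date]:
        out = []
        for y in self.years:
            start = date(y, self.season_month, self.season_day)
            out.extend(start + timedelta(days=i) for i in range(self.days_per_year))
        return out

    @classmethod
    def strong_signal(cls, **overrides) -> "SynthConfig":
        """Defaults: a landscape signal strong enough to dominate the trend."""
        return cls(**overrides)

    @classmethod
    def null_signal(cls, **overrides) -> "SynthConfig":
        """No landscape signal: rise labels are fair coin flips."""
        return cls(signal_gain=0.0, eps_true=0.0, lst_rise_amp=0.0, **overrides)


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], cfg.seed])


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, re-standardized to mean 0 / sd 1."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Land cover


def gen_landcover_pair(cfg: SynthConfig) -> tuple[CategoricalRaster, CategoricalRaster]:
    """Two spatially autocorrelated 5-class maps differing on ~change_rate cells.

    The first map quantile-thresholds a smooth random field into classes at
    the configured proportions.  Change is drawn patchily (a second smooth
    field ranks eligible cells) and only along the six whitelisted
    transitions, split across source classes by ``source_change_weights``
    so forest-to-artificial dominates.
    """
    rng = _rng(cfg, "landcover")
    grid = cfg.grid
    base = _smooth_field(rng, grid.shape, cfg.smooth_sigma)
    props = np.asarray(cfg.class_props, dtype=float)
    props = props / props.sum()
    edges = np.quantile(base, np.cumsum(props)[:-1])
    codes1 = (np.digitize(base, edges) + 1).astype(np.int32)
    legend = {code: lab for lab, code in changemap.CLASS_CODES.items()}
    map1 = CategoricalRaster(grid, codes1, legend=dict(legend))

    n_total = codes1.size
    n_change = int(round(cfg.change_rate * n_total))
    codes2 = codes1.copy()
    if n_change > 0:
        chg_field = _smooth_field(rng, grid.shape, cfg.change_sigma)
        src_w = dict(cfg.source_change_weights)
        trans_w = {k: dict(v) for k, v in cfg.transition_weights}
        # allocate the changed area across source classes (largest remainder)
        quota = {lab: n_change * w for lab, w in src_w.items()}
        alloc = {lab: int(np.floor(q)) for lab, q in quota.items()}
        rest = n_change - sum(alloc.values())
        for lab in sorted(quota, key=lambda l: quota[l] - alloc[l], reverse=True)[:rest]:
            alloc[lab] += 1
        for lab, n_lab in alloc.items():
            code = changemap.CLASS_CODES[lab]
            flat = np.flatnonzero(codes1.ravel() == code)
            if n_lab > flat.size:
                raise ValueError(
                    f"change_rate {cfg.change_rate} cannot be honored: "
                    f"class {lab} has {flat.size} cells, {n_lab} requested"
                )
            order = flat[np.argsort(chg_field.ravel()[flat])[::-1][:n_lab]]
            targets, weights = zip(*trans_w[lab].items())
            w = np.asarray(weights, dtype=float)
            draw = rng.choice(
                [changemap.CLASS_CODES[t] for t in targets], size=n_lab, p=w / w.sum()
            )
            codes2.ravel()[order] = draw
    map2 = CategoricalRaster(grid, codes2, legend=dict(legend))
    return map1, map2


def gen_districts(cfg: SynthConfig) -> CategoricalRaster:
    """Voronoi (nearest-seed) partition of the study area into districts."""
    if cfg.n_districts < 1:
        raise ValueError("need at least one district")
    rng = _rng(cfg, "districts")
    grid = cfg.grid
    idx = rng.choice(grid.n_rows * grid.n_cols, size=cfg.n_districts, replace=False)
    seed_r, seed_c = np.unravel_index(idx, grid.shape)
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    d2 = (rr[..., None] - seed_r) ** 2 + (cc[..., None] - seed_c) ** 2
    codes = (np.argmin(d2, axis=-1) + 1).astype(np.int32)
    legend = {i + 1: f"D{i + 1}" for i in range(cfg.n_districts)}
    return CategoricalRaster(grid, codes, legend=legend)


# ---------------------------------------------------------------------------
# Covariates and stations


def gen_covariates(cfg: SynthConfig, rise_sign: np.ndarray | None = None) -> CovariateStack:
    """Daily covariate stack; coarse variables pass through nearest-neighbor
    resampling from their native coarse grid, as reanalysis fields would.

    ``rise_sign`` (+1/-1 per pixel) injects the landscape trend into the
    LST fields of the last configured year.
    """
    rng = _rng(cfg, "covariates")
    grid = cfg.grid
    f = cfg.coarse_factor
    coarse = Grid(
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        pixel_size=grid.pixel_size * f,
        n_rows=int(np.ceil(grid.n_rows / f)),
        n_cols=int(np.ceil(grid.n_cols / f)),
        crs_id=grid.crs_id,
    )
    lon, lat = grid.center_grids()
    stack = CovariateStack(grid=grid, dns_origin=cfg.dns_origin)
    last_year = max(cfg.years)
    for day in cfg.dates():
        rasters: dict[str, ContinuousRaster] = {}
        for name, is_coarse in COVARIATE_VARS:
            if is_coarse:
                fld = _smooth_field(rng, coarse.shape, cfg.field_sigma)
                src = ContinuousRaster(coarse, fld)
                rasters[name] = resample_nearest(src, grid)
            else:  # LST, generated at the fine scale, in degC
                fld = cfg.lst_mean + cfg.lst_sd * _smooth_field(
                    rng, grid.shape, cfg.smooth_sigma
                )
                if rise_sign is not None and day.year == last_year and len(cfg.years) > 1:
                    fld = fld + cfg.lst_rise_amp * rise_sign
                rasters[name] = ContinuousRaster(grid, fld, units="degC")
        rasters["LON"] = ContinuousRaster(grid, lon, units="deg")
        rasters["LAT"] = ContinuousRaster(grid, lat, units="deg")
        dns = float((day - cfg.dns_origin).days + 1)
        rasters["DNS"] = ContinuousRaster(grid, np.full(grid.shape, dns))
        stack.add_day(day, rasters)
    return stack


def _true_log_concentration(cfg: SynthConfig, stack: CovariateStack, day: date) -> np.ndarray:
    beta = cfg.beta
    arrays = stack.day_arrays(day)
    lin = np.full(cfg.grid.shape, beta.get("const", 0.0))
    for name, b in beta.items():
        if name == "const" or b == 0.0:
            continue
        lin = lin + b * arrays[name]
    return lin


def gen_station_hourly(
    cfg: SynthConfig, covariates: CovariateStack
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Station table and hourly ozone records from the log-linear truth.

    Hourly concentration = exp(x'beta) * diurnal(h) + N(0, noise_sd),
    truncated at zero, with the diel factor a sinusoid peaking at 15:00
    whose daily mean is exactly 1.  A ``missing_rate`` fraction of hours is
    deleted at random.
    """
    rng = _rng(cfg, "stations")
    grid = cfg.grid
    idx = rng.choice(grid.n_rows * grid.n_cols, size=cfg.n_stations, replace=False)
    rows, cols = np.unravel_index(idx, grid.shape)
    xs, ys = grid.cell_centers()
    stations = pd.DataFrame(
        {
            "station_id": [f"S{i + 1:02d}" for i in range(cfg.n_stations)],
            "lon": xs[cols],
            "lat": ys[rows],
            "row": rows,
            "col": cols,
        }
    )
    hours = np.arange(24)
    diurnal = 1.0 + cfg.diurnal_amplitude * np.cos(2 * np.pi * (hours - 15) / 24.0)
    days = covariates.dates
    mu = np.empty((cfg.n_stations, len(days)))
    for j, day in enumerate(days):
        lin = _true_log_concentration(cfg, covariates, day)
        mu[:, j] = np.exp(lin[rows, cols])
    values = mu[:, :, None] * diurnal[None, None, :]
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    keep = rng.random(values.shape) >= cfg.missing_rate

    n_st, n_days, _ = values.shape
    day_ts = pd.to_datetime([pd.Timestamp(d) for d in days])
    ts = (day_ts.values[None, :, None] + np.timedelta64(1, "h") * hours[None, None, :])
    sid = np.repeat(stations["station_id"].to_numpy(), n_days * 24)
    hourly = pd.DataFrame(
        {
            "station_id": sid[keep.ravel()],
            "timestamp": np.broadcast_to(ts, values.shape)[keep],
            "o3_ugm3": values[keep],
        }
    )
    return stations, hourly


# ---------------------------------------------------------------------------
# Scene assembly


@dataclass
class TruthRecord:
    """Ground truth persisted alongside the generated data."""

    beta_true: dict
    b_true: dict
    eps_true: float
    rise_labels: CategoricalRaster
    landscape_labels: CategoricalRaster
    annual_true: dict

    def to_json(self, path) -> str:
        payload = {
            "beta_true": self.beta_true,
            "b_true": self.b_true,
            "eps_true": self.eps_true,
            "rise_labels": self.rise_labels.codes.tolist(),
            "landscape_labels": self.landscape_labels.codes.tolist(),
            "annual_true": {
                str(y): r.values.tolist() for y, r in self.annual_true.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return str(path)


@dataclass
class Scene:
    """Everything one synthetic study area comprises."""

    cfg: SynthConfig
    map1: CategoricalRaster
    map2: CategoricalRaster
    change: ChangeEncoding
    metrics: MetricStack
    districts: CategoricalRaster
    covariates: CovariateStack
    stations: pd.DataFrame
    hourly: pd.DataFrame
    truth: TruthRecord


def _landscape_labels(cfg: SynthConfig, change, metrics: MetricStack) -> CategoricalRaster:
    """Latent rise labels from the logistic truth on landscape features."""
    rng = _rng(cfg, "labels")
    b = cfg.b
    grid = cfg.grid
    score = np.zeros(grid.shape)
    changed = (change.raster.codes >= 6) & change.raster.valid_mask
    score = score + b.get("changed", 0.0) * changed.astype(float)
    for name, coef in b.items():
        if name == "changed" or coef == 0.0:
            continue
        layer = metrics.layer(name).values
        ok = np.isfinite(layer)
        std = np.zeros(grid.shape)
        sd = layer[ok].std()
        if sd > 0:
            std[ok] = (layer[ok] - layer[ok].mean()) / sd
        score = score + coef * std
    # re-standardize the weighted score so signal_gain sets the latent sd
    sd = score.std()
    if sd > 0 and cfg.signal_gain != 0.0:
        score = cfg.signal_gain * (score - score.mean()) / sd
    else:
        score = np.zeros(grid.shape)
    z = cfg.eps_true + score
    labels = (rng.random(grid.shape) < expit(z)).astype(np.int32)
    return CategoricalRaster(grid, labels, nodata=-9, legend={0: "no rise", 1: "rise"})


def generate_scene(cfg: SynthConfig) -> Scene:
    """Generate the full synthetic study area (pure function of ``cfg``)."""
    if len(cfg.years) != 2:
        raise ValueError("a scene needs exactly two analysis years")
    map1, map2 = gen_landcover_pair(cfg)
    change = encode_change(map1, map2)
    metrics = focal_metrics(change.raster)
    labels = _landscape_labels(cfg, change, metrics)
    rise_sign = 2.0 * labels.codes.astype(float) - 1.0
    covariates = gen_covariates(cfg, rise_sign=rise_sign)
    stations, hourly = gen_station_hourly(cfg, covariates)
    districts = gen_districts(cfg)

    annual_true = {}
    for y in cfg.years:
        days = covariates.dates_for_year(y)
        acc = np.zeros(cfg.grid.shape)
        for day in days:
            acc += np.exp(_true_log_concentration(cfg, covariates, day))
        annual_true[y] = ContinuousRaster(cfg.grid, acc / len(days), units="ug/m3")
    y1, y2 = min(cfg.years), max(cfg.years)
    rise = (annual_true[y1].values <= annual_true[y2].values).astype(np.int32)
    rise_r = CategoricalRaster(cfg.grid, rise, nodata=-9, legend={0: "no rise", 1: "rise"})

    truth = TruthRecord(
        beta_true=cfg.beta,
        b_true=cfg.b,
        eps_true=cfg.eps_true,
        rise_labels=rise_r,
        landscape_labels=labels,
        annual_true=annual_true,
    )
    return Scene(
        cfg, map1, map2, change, metrics, districts, covariates, stations, hourly, truth
    )


#: change-category sampling frequencies for feature-table studies,
#: proportional to a realistic stratified training allocation
STUDY_CLA_FREQ = {
    "A": 124, "C": 11, "F": 105, "G": 7, "W": 12,
    "AC": 8, "AF": 26, "CA": 17, "CF": 14, "FA": 35, "FC": 10,
}


def gen_stepwise_study(
    n: int = 369,
    seed: int = 0,
    b_changed: float = 2.2,
    b_het7: float = 1.0,
    b_hom7: float = -0.85,
    b_con7: float = -0.95,
    eps: float = 0.3,
    rho_dmg_con: float = 0.8,
    loadings: tuple = (0.45, 0.5),
    idio_sd: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Feature table for model-selection studies with known logistic truth.

    The informative variables are the change category (through a shared
    "changed" effect), HET7, HOM7 and CON7; DMG7 is approximately
    collinear with CON7 (correlation ``rho_dmg_con``) but carries no
    signal of its own.  The window-3/5 indices are modelled as low-rank
    proxies of their window-7 counterparts: loading ``a`` on the w=7
    value plus one shared fine-scale texture factor and a small
    idiosyncratic term, mimicking how nested moving windows of the same
    map co-vary.  Labels are Bernoulli draws from the logistic truth.

    Returns the feature table (CLA, 12 metric columns, label) and a dict
    with the true coefficients and the informative variable set.
    """
    rng = np.random.default_rng([21, seed])
    cats = list(STUDY_CLA_FREQ)
    p = np.array([STUDY_CLA_FREQ[c] for c in cats], dtype=float)
    p /= p.sum()
    cla = rng.choice(cats, size=n, p=p)
    changed = np.isin(cla, [c for c in cats if len(c) == 2]).astype(float)
    f = {f"{fam}7": rng.standard_normal(n) for fam in ("HET", "HOM", "DMG", "CON")}
    f["DMG7"] = rho_dmg_con * f["CON7"] + np.sqrt(1 - rho_dmg_con**2) * rng.standard_normal(n)
    texture = rng.standard_normal(n)
    for fam in ("HET", "HOM", "DMG", "CON"):
        for w, a in zip(("3", "5"), loadings):
            shared = np.sqrt(max(1.0 - a * a - idio_sd**2, 0.0))
            f[f"{fam}{w}"] = (
                a * f[f"{fam}7"] + shared * texture + idio_sd * rng.standard_normal(n)
            )
    z = (
        eps
        + b_changed * changed
        + b_het7 * f["HET7"]
        + b_hom7 * f["HOM7"]
        + b_con7 * f["CON7"]
    )
    y = (rng.random(n) < expit(z)).astype(int)
    table = pd.DataFrame(f)
    table.insert(0, "CLA", cla)
    table["label"] = y
    truth = {
        "informative": ["CLA", "HET7", "HOM7", "CON7"],
        "eps": eps,
        "b": {"changed": b_changed, "HET7": b_het7, "HOM7": b_hom7, "CON7": b_con7},
    }
    return table, truth


def generate_glm_dataset(cfg: SynthConfig):
    """Covariates + stations + hourly records only (no landscape stage).

    Convenient for concentration-model recovery studies; supports a single
    configured year.
    """
    covariates = gen_covariates(cfg, rise_sign=None)
    stations, hourly = gen_station_hourly(cfg, covariates)
    return covariates, stations, hourly
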