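"""Seeded generator of FLUXNET-like multi-site monthly datasets.

Each site gets four climate drivers (air temperature, precipitation, global
radiation, vapor pressure deficit) plus potential top-of-atmosphere radiation,
seven surface-reflectance bands driven by a latent greenness state, and a net
ecosystem exchange (NEE) series whose respiration term depends on a carbon
pool that integrates past productivity.  The pool gives NEE a *known* memory
horizon (half-life ``ln 2 / -ln(1 - lam)`` months), so models that exploit
temporal context can be benchmarked against models that cannot.

Sign convention: negative NEE = net CO2 uptake by the ecosystem.

Randomness is split hierarchically (master seed -> site -> variable stream),
so adding sites never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

BANDS = ["blue", "green", "red", "nir", "swir1", "swir2", "tir"]
CLIMATE_VARS = ["tair", "precip", "rg", "vpd"]
PFTS = ["deciduous", "evergreen", "mixed", "savanna"]
CLIMATE_CLASSES = ["arid", "boreal", "temperate", "tropical"]

# per-site RNG stream ids
_STREAM_SITE_META = 0
_STREAM_CLIMATE = 1
_STREAM_VEGETATION = 2
_STREAM_NEE = 3
_STREAM_OBS = 4
_STREAM_AUX = 5


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class SiteRecord:
    """Static metadata for one synthetic flux-tower site."""

    site_id: str
    latitude: float
    pft: str
    climate_class: str
    age_1982: float
    disturbance_year: Optional[int]
    window_start: tuple[int, int]  # (year, month), inclusive
    window_end: tuple[int, int]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world.

    The defaults emulate the structure of the multi-decadal eddy-covariance +
    Landsat archives the pipeline is designed for: 185 forest sites observed
    monthly 1982-2015, measurement windows of 3-12 years inside 2000-2015,
    cloud-driven reflectance gaps (heavier in the tropics), and a respiration
    carbon pool with a decay of 0.2 month^-1 (half-life ~3.1 months).
    """

    n_sites: int = 185
    period: tuple[int, int] = (1982, 2015)

    # carbon-cycle core
    pool_decay: float = 0.2       # lam, month^-1; pool half-life ln2/-ln(1-lam)
    pool_gain: float = 1.0        # gamma, fraction of last month's GPP entering the pool
    gpp_light_use: float = 0.05   # eps, gC m-2 d-1 per (W m-2 * greenness)
    resp_base: float = 0.07       # r_b
    resp_temp_sens: float = 0.07  # k, degC^-1 (Q10 ~ 2)
    allow_infinite_pool: bool = False

    # disturbance / recovery
    disturbance_prob: float = 0.25
    disturbance_drop: float = 0.5  # fraction of greenness lost at the event
    recovery_tau: float = 24.0     # months

    # observation model
    gap_rate_reflectance: float = 0.10
    tropical_gap_multiplier: float = 2.5
    qc_alpha: float = 20.0
    qc_beta: float = 1.0
    window_years: tuple[int, int] = (3, 12)
    window_period: tuple[int, int] = (2000, 2015)

    # noise scales (set to 0 for the deterministic core)
    noise_tair: float = 1.5       # degC, AR(1)
    noise_rg: float = 25.0        # W m-2, AR(1)
    noise_vpd: float = 2.0        # hPa
    noise_precip_sigma: float = 0.4   # lognormal sigma
    noise_greenness: float = 0.04     # AR(1) interannual vegetation variability
    noise_reflectance: float = 0.01
    noise_tir: float = 1.0        # K
    noise_nee: float = 0.3        # gC m-2 d-1
    climate_ar: float = 0.7
    greenness_ar: float = 0.8

    # auxiliary (MODIS-like) reflectance + surface-temperature product used by
    # stage-1 gap-filling
    aux_start_year: int = 2000
    aux_noise: float = 0.005
    aux_noise_tir: float = 0.5  # K

    pft_weights: tuple[float, ...] = (0.25, 0.45, 0.15, 0.15)
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        y0, y1 = self.period
        if y1 - y0 + 1 < 5:
            raise ConfigurationError("period must span at least 5 years")
        if not (0.0 < self.pool_decay <= 1.0):
            if self.pool_decay == 0.0 and self.allow_infinite_pool:
                pass
            else:
                raise ConfigurationError(
                    "pool_decay must lie in (0, 1]; lam=0 (infinite-memory pool) "
                    "requires allow_infinite_pool=True"
                )
        for name in ("disturbance_prob", "gap_rate_reflectance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.qc_alpha <= 0 or self.qc_beta <= 0:
            raise ConfigurationError("qc_alpha and qc_beta must be positive")
        if self.window_years[0] < 1 or self.window_years[0] > self.window_years[1]:
            raise ConfigurationError("window_years must be a nondecreasing pair >= 1")

    def n_months(self) -> int:
        return (self.period[1] - self.period[0] + 1) * 12


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=tuple(key))
    )


def _time_index(config: GeneratorConfig) -> pd.DataFrame:
    y0, y1 = config.period
    years = np.repeat(np.arange(y0, y1 + 1), 12)
    months = np.tile(np.arange(1, 13), y1 - y0 + 1)
    return pd.DataFrame({"year": years, "month": months})


def climate_class_from_latitude(latitude: float) -> str:
    """Deterministic bioclimatic class from |latitude| bands."""
    a = abs(latitude)
    if a < 15:
        return "tropical"
    if a < 30:
        return "arid"
    if a < 55:
        return "temperate"
    return "boreal"


def potential_radiation(latitude: float, month: np.ndarray | int) -> np.ndarray:
    """Noise-free daily-mean top-of-atmosphere solar radiation (W m-2).

    Standard solar-geometry closed form evaluated at the mid-month day of
    year; extraterrestrial radiation in MJ m-2 day-1 converted to W m-2.
    """
    month = np.asarray(month)
    doy = 15.0 + (month - 1) * 30.4
    phi = np.deg2rad(latitude)
    delta = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * doy / 365.0)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    gsc = 0.0820  # MJ m-2 min-1
    ra = (24 * 60 / np.pi) * gsc * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0) * (1e6 / 86400.0)  # MJ m-2 d-1 -> W m-2


def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """AR(1) noise with stationary marginal sd ``sigma``."""
    if sigma == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), n)
    out = np.empty(n)
    prev = rng.normal(0.0, sigma)
    for t in range(n):
        prev = rho * prev + eps[t]
        out[t] = prev
    return out


def generate_sites(config: GeneratorConfig) -> list[SiteRecord]:
    """Draw site metadata (location, PFT, age, disturbance, window)."""
    config.validate()
    y0, y1 = config.period
    w0 = max(config.window_period[0], y0)
    w1 = min(config.window_period[1], y1)
    sites = []
    for i in range(config.n_sites):
        rng = _rng(config, i, _STREAM_SITE_META)
        hemisphere = 1.0 if rng.random() < 0.8 else -1.0
        latitude = float(hemisphere * rng.uniform(2.0, 68.0))
        pft = str(rng.choice(PFTS, p=np.asarray(config.pft_weights)))
        age = float(rng.lognormal(mean=4.0, sigma=0.8))
        disturbed = rng.random() < config.disturbance_prob
        disturbance_year = int(rng.integers(y0 + 2, y1 + 1)) if disturbed else None
        span = int(rng.integers(config.window_years[0], config.window_years[1] + 1))
        span = min(span, w1 - w0 + 1)
        start_year = int(rng.integers(w0, w1 - span + 2))
        window_start = (start_year, 1)
        window_end = (start_year + span - 1, 12)
        sites.append(
            SiteRecord(
                site_id=f"SYN{i:04d}",
                latitude=latitude,
                pft=pft,
                climate_class=climate_class_from_latitude(latitude),
                age_1982=age,
                disturbance_year=disturbance_year,
                window_start=window_start,
                window_end=window_end,
            )
        )
    return sites


def simulate_climate(site: SiteRecord, config: GeneratorConfig) -> pd.DataFrame:
    """Monthly climate block: tair, precip, rg, vpd, rpot.

    Temperature and radiation follow latitude-dependent sinusoidal seasonal
    cycles (southern hemisphere phase-shifted by 6 months) plus AR(1) noise;
    VPD increases monotonically with temperature; precipitation is lognormal
    around a seasonal mean; rpot is the closed-form top-of-atmosphere flux.
    """
    idx = _time_index(config)
    n = len(idx)
    m = idx["month"].to_numpy().astype(float)
    rng = _rng(config, _site_index(site), _STREAM_CLIMATE)

    a = abs(site.latitude)
    phase = 7.0 if site.latitude >= 0 else 1.0  # warmest month
    seas = np.cos(2 * np.pi * (m - phase) / 12.0)

    t_mean = 26.0 - 0.32 * a
    t_amp = 2.0 + 16.0 * a / 68.0
    tair = t_mean + t_amp * seas + _ar1(rng, n, config.noise_tair, config.climate_ar)

    rg_mean = 230.0 - 1.3 * a
    rg_amp = 15.0 + 130.0 * a / 68.0
    rg = rg_mean + rg_amp * seas + _ar1(rng, n, config.noise_rg, config.climate_ar)
    rg = np.maximum(rg, 5.0)

    # saturation vapor pressure (hPa) scaled by a fixed saturation deficit
    esat = 6.112 * np.exp(17.62 * tair / (tair + 243.12))
    vpd = 0.35 * esat + rng.normal(0.0, config.noise_vpd, n)
    vpd = np.maximum(vpd, 0.0)

    p_mean = np.maximum(80.0 - 0.5 * a + 30.0 * seas, 10.0)
    if config.noise_precip_sigma > 0:
        precip = p_mean * rng.lognormal(
            -0.5 * config.noise_precip_sigma**2, config.noise_precip_sigma, n
        )
    else:
        precip = p_mean.copy()

    rpot = potential_radiation(site.latitude, idx["month"].to_numpy())

    out = idx.copy()
    out["tair"] = tair
    out["precip"] = precip
    out["rg"] = rg
    out["vpd"] = vpd
    out["rpot"] = rpot
    return out


def simulate_vegetation(
    site: SiteRecord, climate: pd.DataFrame, config: GeneratorConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Latent greenness in [0, 1] plus the seven reflectance bands.

    Greenness has a PFT-dependent seasonal amplitude (deciduous > mixed >
    evergreen), AR(1) interannual variability, and - if the site carries a
    disturbance year - an abrupt drop that relaxes back exponentially with
    time constant ``recovery_tau``.  Bands are affine in greenness (NIR
    increasing; red/SWIR decreasing; TIR tied to air temperature).
    """
    n = len(climate)
    m = climate["month"].to_numpy().astype(float)
    years = climate["year"].to_numpy()
    rng = _rng(config, _site_index(site), _STREAM_VEGETATION)

    phase = 7.0 if site.latitude >= 0 else 1.0
    seas = np.cos(2 * np.pi * (m - phase) / 12.0)
    amp = {"deciduous": 0.35, "mixed": 0.25, "savanna": 0.28, "evergreen": 0.08}[site.pft]
    base = {"deciduous": 0.50, "mixed": 0.52, "savanna": 0.45, "evergreen": 0.60}[site.pft]
    g = base + amp * seas + _ar1(rng, n, config.noise_greenness, config.greenness_ar)

    if site.disturbance_year is not None:
        event = np.flatnonzero((years == site.disturbance_year) & (m == 7))
        if event.size:
            t0 = int(event[0])
            drop = config.disturbance_drop * g[t0]
            dt = np.arange(n) - t0
            deficit = np.where(dt >= 0, drop * np.exp(-dt / config.recovery_tau), 0.0)
            g = g - deficit
    g = np.clip(g, 0.0, 1.0)

    bands = pd.DataFrame(index=climate.index)
    bn = config.noise_reflectance
    bands["blue"] = 0.08 - 0.03 * g + rng.normal(0, bn, n)
    bands["green"] = 0.10 + 0.04 * g + rng.normal(0, bn, n)
    bands["red"] = 0.32 - 0.24 * g + rng.normal(0, bn, n)
    bands["nir"] = 0.12 + 0.50 * g + rng.normal(0, bn, n)
    bands["swir1"] = 0.40 - 0.22 * g + rng.normal(0, bn, n)
    bands["swir2"] = 0.30 - 0.20 * g + rng.normal(0, bn, n)
    for b in bands.columns:
        bands[b] = np.clip(bands[b].to_numpy(), 0.0, 1.0)
    bands["tir"] = (
        climate["tair"].to_numpy() + 273.15 + rng.normal(0, config.noise_tir, n)
    )
    return g, bands


def simulate_nee(
    site: SiteRecord,
    climate: pd.DataFrame,
    greenness: np.ndarray,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """NEE from a light-use GPP model and a one-pool respiration model.

    GPP_t   = eps * Rg_t * G_t * f_T(T_t) * f_W(VPD_t)
    C_t     = (1 - lam) * C_{t-1} + gamma * GPP_{t-1},  C_0 = steady state
    Reco_t  = r_b * exp(k * T_t) * C_t
    NEE_t   = Reco_t - GPP_t + noise       (negative = uptake)

    The pool carries the memory: with decay lam its half-life is
    ln2 / -ln(1-lam) months; lam=1, gamma=0 yields a memoryless flux.
    """
    if config.pool_decay == 0.0 and not config.allow_infinite_pool:
        raise ConfigurationError(
            "pool_decay=0 builds an infinite-memory pool; set allow_infinite_pool=True"
        )
    n = len(climate)
    rng = _rng(config, _site_index(site), _STREAM_NEE)
    tair = climate["tair"].to_numpy()
    rg = climate["rg"].to_numpy()
    vpd = climate["vpd"].to_numpy()

    f_t = 1.0 / (1.0 + np.exp(-(tair - 10.0) / 5.0))
    f_w = np.exp(-vpd / 40.0)
    gpp = config.gpp_light_use * rg * greenness * f_t * f_w

    lam, gamma = config.pool_decay, config.pool_gain
    pool = np.empty(n)
    # spin-up at the mean influx so the panel does not start with a transient
    c0 = gamma * gpp.mean() / lam if lam > 0 else 0.0
    prev = c0
    for t in range(n):
        prev = (1.0 - lam) * prev + gamma * (gpp[t - 1] if t > 0 else gpp.mean())
        pool[t] = prev
    reco = config.resp_base * np.exp(config.resp_temp_sens * tair) * pool
    nee = reco - gpp + rng.normal(0.0, config.noise_nee, n)

    out = climate[["year", "month"]].copy()
    out["gpp"] = gpp
    out["reco"] = reco
    out["pool"] = pool
    out["nee"] = nee
    return out


def apply_observation_model(
    panel: pd.DataFrame, site: SiteRecord, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impose the measurement window, quality fractions and reflectance gaps.

    Returns the observed panel and a ground-truth frame holding the withheld
    reflectance values (for gap-fill testing).
    """
    rng = _rng(config, _site_index(site), _STREAM_OBS)
    out = panel.copy()
    n = len(out)

    out["nee_quality"] = rng.beta(config.qc_alpha, config.qc_beta, n)
    ym = out["year"] * 12 + (out["month"] - 1)
    w0 = site.window_start[0] * 12 + (site.window_start[1] - 1)
    w1 = site.window_end[0] * 12 + (site.window_end[1] - 1)
    in_window = (ym >= w0) & (ym <= w1)
    out.loc[~in_window, "nee"] = np.nan

    gap_rate = config.gap_rate_reflectance
    if site.climate_class == "tropical":
        gap_rate = min(1.0, gap_rate * config.tropical_gap_multiplier)

    truth = out[["year", "month"]].copy()
    for b in BANDS:
        gaps = rng.random(n) < gap_rate
        out[f"{b}_obs"] = ~gaps
        truth[b] = np.where(gaps, panel[b].to_numpy(), np.nan)
        out.loc[gaps, b] = np.nan
    return out, truth


def _site_index(site: SiteRecord) -> int:
    return int(site.site_id[3:])


@dataclass
class SyntheticDataset:
    """Sites, observed panels, and per-site ground truth / auxiliaries."""

    config: GeneratorConfig
    sites: list[SiteRecord]
    panels: dict[str, pd.DataFrame]
    truth: dict[str, pd.DataFrame]      # latent gpp/reco/pool/greenness + withheld bands
    aux: dict[str, pd.DataFrame]        # MODIS-like co-located reflectance (subperiod)

    def site(self, site_id: str) -> SiteRecord:
        return next(s for s in self.sites if s.site_id == site_id)


def generate_dataset(config: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Compose the full generator; optionally write the on-disk CSV layout."""
    config.validate()
    sites = generate_sites(config)
    panels: dict[str, pd.DataFrame] = {}
    truths: dict[str, pd.DataFrame] = {}
    auxs: dict[str, pd.DataFrame] = {}
    for site in sites:
        climate = simulate_climate(site, config)
        greenness, bands = simulate_vegetation(site, climate, config)
        nee = simulate_nee(site, climate, greenness, config)

        panel = climate.copy()
        for b in BANDS:
            panel[b] = bands[b].to_numpy()
        panel["nee"] = nee["nee"].to_numpy()
        observed, withheld = apply_observation_model(panel, site, config)
        panels[site.site_id] = observed

        truth = withheld.rename(columns={b: f"{b}_withheld" for b in BANDS})
        truth["greenness"] = greenness
        truth["gpp"] = nee["gpp"].to_numpy()
        truth["reco"] = nee["reco"].to_numpy()
        truth["pool"] = nee["pool"].to_numpy()
        truths[site.site_id] = truth

        rng = _rng(config, _site_index(site), _STREAM_AUX)
        cover = climate["year"].to_numpy() >= config.aux_start_year
        aux = climate.loc[cover, ["year", "month"]].copy()
        for b in BANDS:
            sigma = config.aux_noise_tir if b == "tir" else config.aux_noise
            aux[f"aux_{b}"] = panel.loc[cover, b].to_numpy() + rng.normal(
                0.0, sigma, int(cover.sum())
            )
        auxs[site.site_id] = aux

    ds = SyntheticDataset(config=config, sites=sites, panels=panels, truth=truths, aux=auxs)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in ds.sites:
        rows.append(
            {
                "site_id": s.site_id,
                "latitude": s.latitude,
                "pft": s.pft,
                "climate_class": s.climate_class,
                "age_class": age_class(s.age_1982),
                "disturbance_year": s.disturbance_year,
                "window_start": f"{s.window_start[0]}-{s.window_start[1]:02d}",
                "window_end": f"{s.window_end[0]}-{s.window_end[1]:02d}",
            }
        )
    pd.DataFrame(rows).to_csv(out / "sites.csv", index=False)
    for sid, panel in ds.panels.items():
        panel.to_csv(out / f"panel_{sid}.csv", index=False)
    gt = pd.concat(
        [t.assign(site_id=sid) for sid, t in ds.truth.items()], ignore_index=True
    )
    gt.to_csv(out / "ground_truth.csv", index=False)


def read_dataset(in_dir: str | Path) -> tuple[list[SiteRecord], dict[str, pd.DataFrame]]:
    """Read the sites.csv / panel_*.csv layout back into memory."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "sites.csv")
    sites = []
    for _, r in meta.iterrows():
        ws = tuple(int(x) for x in str(r["window_start"]).split("-"))
        we = tuple(int(x) for x in str(r["window_end"]).split("-"))
        sites.append(
            SiteRecord(
                site_id=r["site_id"],
                latitude=float(r["latitude"]),
                pft=r["pft"],
                climate_class=r["climate_class"],
                age_1982=np.nan,
                disturbance_year=None if pd.isna(r["disturbance_year"]) else int(r["disturbance_year"]),
                window_start=(ws[0], ws[1]),
                window_end=(we[0], we[1]),
            )
        )
    panels = {
        s.site_id: pd.read_csv(in_dir / f"panel_{s.site_id}.csv") for s in sites
    }
    return sites, panels


def age_class(age_1982: float) -> str:
    """Six forest-age classes used for stratified reporting."""
    edges = [(10, "0-10"), (20, "10-20"), (50, "20-50"), (100, "50-100"), (150, "100-150")]
    for hi, name in edges:
        if age_1982 < hi:
            return name
    return "150+"


def memory_half_life(pool_decay: float) -> float:
    """Half-life of the carbon pool, in months."""
    if pool_decay >= 1.0:
        return 0.0
    return np.log(2.0) / -np.log(1.0 - pool_decay)
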