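"""Synthetic gridded flux and driver fields with controlled IAV structure.

The generator emulates the statistical structure the downstream analysis
assumes: each cell's monthly GPP is a mean seasonal cycle plus an optional
linear trend plus two regionally coherent year-effect modes — an
"amplification" mode (coherent growing-season excursion, half-sine over
Apr-Sep) and a "compensation" mode (spring-positive / summer-negative
see-saw) — plus white observation noise.  Year effects are coupled to
jointly normal growing-season temperature and soil-moisture anomalies
(dT_y, dM_y) with configurable coefficients; NEE is generated as an opposing
fraction of the GPP anomaly (positive NEE = source to atmosphere) around its
own seasonal cycle, with independent respiration noise.

All randomness flows from one integer seed; region-level effects and
per-cell noise use separate counter-derived streams, so changing the grid
size does not reorder the region-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import FluxGrid, GridContractError, NEE_SIGN_CONVENTION, month_range

__all__ = [
    "ModeShapes",
    "RegionParams",
    "GridSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "default_mode_shapes",
    "generate_dataset",
    "preset",
]


@dataclass
class ModeShapes:
    """Unit-norm 12-month patterns for the two year-effect modes.

    ``amp_shape``: non-negative, peaked over Apr-Sep (coherent enhancement).
    ``comp_shape``: positive Apr-Jun, negative Jul-Sep, near-zero Apr-Sep sum.
    """

    amp_shape: np.ndarray
    comp_shape: np.ndarray

    def __post_init__(self) -> None:
        self.amp_shape = np.asarray(self.amp_shape, dtype=float)
        self.comp_shape = np.asarray(self.comp_shape, dtype=float)
        for name, v in (("amp_shape", self.amp_shape), ("comp_shape", self.comp_shape)):
            if v.shape != (12,):
                raise GridContractError(f"{name} must have 12 entries")
            if not np.isclose(np.linalg.norm(v), 1.0):
                raise GridContractError(f"{name} must have unit Euclidean norm")
        a_spring = self.amp_shape[3:6].mean()
        a_summer = self.amp_shape[6:9].mean()
        if a_spring * a_summer < 0:
            raise GridContractError("amp_shape spring/summer means must share a sign")
        c_spring = self.comp_shape[3:6].mean()
        c_summer = self.comp_shape[6:9].mean()
        if c_spring * c_summer >= 0:
            raise GridContractError("comp_shape spring/summer means must have opposite signs")


def default_mode_shapes() -> ModeShapes:
    """Half-sine amplification over Apr-Sep; +/-1 spring/summer compensation."""
    amp = np.zeros(12)
    amp[3:9] = np.sin(np.pi * (np.arange(6) + 0.5) / 6.0)
    comp = np.zeros(12)
    comp[3:6] = 1.0
    comp[6:9] = -1.0
    return ModeShapes(amp / np.linalg.norm(amp), comp / np.linalg.norm(comp))


@dataclass
class RegionParams:
    """Generative parameters for one longitudinal band of the domain."""

    name: str
    lon_bounds: tuple[float, float]  # cells whose centre falls here belong to it
    seasonal_amplitude: float = 40.0  # G: peak of the mean GPP cycle (gC m-2 month-1)
    sigma_amp: float = 10.0  # s.d. of the idiosyncratic amplification year effect
    sigma_comp: float = 2.0  # s.d. of the idiosyncratic compensation year effect
    sigma_eps: float = 2.0  # per-cell white observation noise (gC m-2 month-1)
    trend: float = 0.0  # beta: linear trend (gC m-2 month-1 per year)
    gamma_t: float = 0.0  # amplification response per K of Apr-Sep dT
    gamma_m: float = 0.0  # amplification response per m3 m-3 of dM
    kappa: float = 0.0  # compensation response per K of spring dT (acts on GPP)

    def __post_init__(self) -> None:
        for nm in ("sigma_amp", "sigma_comp", "sigma_eps"):
            if getattr(self, nm) < 0:
                raise GridContractError(f"{nm} must be >= 0")


@dataclass
class GridSpec:
    lat_bounds: tuple[float, float] = (24.0, 52.0)
    lon_bounds: tuple[float, float] = (-125.0, -65.0)
    dlat: float = 4.0
    dlon: float = 5.0

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        lat = np.arange(self.lat_bounds[0] + self.dlat / 2, self.lat_bounds[1], self.dlat)
        lon = np.arange(self.lon_bounds[0] + self.dlon / 2, self.lon_bounds[1], self.dlon)
        return lat, lon


@dataclass
class SyntheticConfig:
    """Full description of one synthetic experiment (defaults emulate 17 years)."""

    years: int = 17
    start_year: int = 2001
    grid: GridSpec = field(default_factory=GridSpec)
    regions: list[RegionParams] = field(default_factory=list)
    sigma_t: float = 1.0  # s.d. of yearly growing-season dT (K)
    sigma_m: float = 0.01  # s.d. of yearly growing-season dM (m3 m-3)
    rho_tm: float = -0.77  # corr(dT, dM): warm years are dry years
    lambda_nee: float = 0.5  # NEE anomaly opposes GPP anomaly at this fraction
    sigma_resp: float = 2.0  # NEE respiration noise (gC m-2 month-1)
    split_lon: float | None = None  # analysis split meridian (two-region runs)
    seed: int = 0
    shapes: ModeShapes = field(default_factory=default_mode_shapes)

    def __post_init__(self) -> None:
        if self.years < 3:
            raise GridContractError("need at least 3 years")
        if not abs(self.rho_tm) < 1:
            raise GridContractError("|rho_tm| must be < 1")
        if not self.regions:
            self.regions = [RegionParams("all", self.grid.lon_bounds)]


@dataclass
class RegionTruth:
    """The latent year effects actually drawn for a region (for verification)."""

    dt: np.ndarray  # (years,) growing-season temperature anomaly (K)
    dm: np.ndarray  # (years,) soil-moisture anomaly (m3 m-3)
    amp_effect: np.ndarray  # a_y (gC m-2 month-1, on the unit amp shape)
    comp_effect: np.ndarray  # c_y


@dataclass
class SyntheticDataset:
    gpp: FluxGrid
    nee: FluxGrid
    t: FluxGrid
    m: FluxGrid
    truth: dict[str, RegionTruth]
    config: SyntheticConfig


# fixed seasonal cycles for the driver fields (anomalies are what matters)
def _t_clim(months: np.ndarray) -> np.ndarray:
    return 280.0 + 15.0 * np.cos(2 * np.pi * (months - 7) / 12.0)


def _m_clim(months: np.ndarray) -> np.ndarray:
    return 0.25 - 0.05 * np.cos(2 * np.pi * (months - 3) / 12.0)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate (GPP, NEE, T, M) grids plus the latent truth, deterministically.

    Per cell in region r, year y, calendar month m:

        GPP = clim(m) + beta * (t - t0) + a_y * amp(m) + c_y * comp(m) + eps
        a_y = gamma_t * dT_y + gamma_m * dM_y + eta_a
        c_y = kappa * dT_y + eta_c

    with (dT_y, dM_y) jointly normal at correlation rho_tm, and NEE =
    nee_clim(m) - lambda * (GPP anomaly structure) + respiration noise.
    Driver fields carry the year effects over Apr-Sep plus small monthly
    noise.
    """
    cfg = config
    lat, lon = cfg.grid.centers()
    n_months = cfg.years * 12
    time = month_range((cfg.start_year, 1), n_months)
    months = np.array([m for _, m in time])
    year_idx = np.array([y - cfg.start_year for y, _ in time])
    t_frac = np.array([(y - cfg.start_year) + (m - 0.5) / 12.0 for y, m in time])

    amp = cfg.shapes.amp_shape[months - 1]
    comp = cfg.shapes.comp_shape[months - 1]
    gs = ((months >= 4) & (months <= 9)).astype(float)

    # region-level draws (stream 0): independent of grid size
    truth: dict[str, RegionTruth] = {}
    region_of_cell = np.full(lon.size, -1)
    for r, rp in enumerate(cfg.regions):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0, r)))
        z = rng.standard_normal((cfg.years, 2))
        dt = cfg.sigma_t * z[:, 0]
        dm = cfg.sigma_m * (cfg.rho_tm * z[:, 0] + np.sqrt(1 - cfg.rho_tm**2) * z[:, 1])
        eta_a = rng.normal(0.0, rp.sigma_amp, cfg.years)
        eta_c = rng.normal(0.0, rp.sigma_comp, cfg.years)
        a_y = rp.gamma_t * dt + rp.gamma_m * dm + eta_a
        c_y = rp.kappa * dt + eta_c
        truth[rp.name] = RegionTruth(dt=dt, dm=dm, amp_effect=a_y, comp_effect=c_y)
        lo, hi = rp.lon_bounds
        region_of_cell[(lon >= lo) & (lon < hi)] = r
    if np.any(region_of_cell < 0):
        raise GridContractError("region longitude bands do not cover the grid")

    gpp = np.empty((n_months, lat.size, lon.size))
    nee = np.empty_like(gpp)
    tfield = np.empty_like(gpp)
    mfield = np.empty_like(gpp)

    t_clim = _t_clim(months)
    m_clim = _m_clim(months)

    for r, rp in enumerate(cfg.regions):
        cols = np.where(region_of_cell == r)[0]
        if cols.size == 0:
            continue
        tr = truth[rp.name]
        clim12 = rp.seasonal_amplitude * cfg.shapes.amp_shape / cfg.shapes.amp_shape.max()
        gpp_clim = clim12[months - 1]
        nee_clim = 5.0 - 0.45 * gpp_clim
        signal = (
            rp.trend * t_frac
            + tr.amp_effect[year_idx] * amp
            + tr.comp_effect[year_idx] * comp
        )
        for j in cols:
            for i in range(lat.size):
                # per-cell noise (stream 1): keyed by cell index
                crng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1, i, j)))
                eps = crng.normal(0.0, rp.sigma_eps, n_months)
                eps_r = crng.normal(0.0, cfg.sigma_resp, n_months)
                t_noise = crng.normal(0.0, 0.2, n_months)
                m_noise = crng.normal(0.0, 0.002, n_months)
                gpp[:, i, j] = gpp_clim + signal + eps
                nee[:, i, j] = nee_clim - cfg.lambda_nee * signal + eps_r
                tfield[:, i, j] = t_clim + tr.dt[year_idx] * gs + t_noise
                mfield[:, i, j] = m_clim + tr.dm[year_idx] * gs + m_noise

    def mk(name, vals, units, sign=""):
        return FluxGrid(
            variable_name=name,
            values=vals,
            time=list(time),
            lat_centers=lat,
            lon_centers=lon,
            units=units,
            sign_convention=sign,
        )

    return SyntheticDataset(
        gpp=mk("GPP", gpp, "gC m-2 month-1"),
        nee=mk("NEE", nee, "gC m-2 month-1", NEE_SIGN_CONVENTION),
        t=mk("T", tfield, "K"),
        m=mk("M", mfield, "m3 m-3"),
        truth=truth,
        config=cfg,
    )


# -- presets ----------------------------------------------------------------

# east/west Apr-Sep total GPP contrast targeted by the two-region preset
EAST_WEST_GPP_MEAN_RATIO = 7.6

_WEST = dict(
    seasonal_amplitude=40.0,
    sigma_amp=10.0,
    sigma_comp=2.0,
    sigma_eps=2.0,
    gamma_t=-5.0,
    gamma_m=500.0,
    kappa=0.0,
)
# warm springs raise spring GPP and depress summer GPP (kappa > 0 on GPP;
# through NEE = -lambda * GPP this advances uptake, i.e. a negative NEE
# compensation coupling); moisture ties to the amplification component
_EAST = dict(
    seasonal_amplitude=152.0,
    sigma_amp=2.0,
    sigma_comp=10.0,
    sigma_eps=2.0,
    gamma_t=0.0,
    gamma_m=150.0,
    kappa=10.0,
)


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Named configurations: "west-like", "east-like", or "two-region".

    "west-like" is amplification-dominant (sigma_comp/sigma_amp = 0.2) with
    moisture-coupled year effects and a small seasonal cycle; "east-like" is
    compensation-dominant (ratio 5) with a spring-temperature coupling and a
    large seasonal cycle.  "two-region" places both on one grid, split at
    105 W (a cell edge of the default 4 x 5 grid, so each cell is wholly in
    one region), with the east seasonal amplitude set so the east/west
    Apr-Sep total GPP ratio is 7.6 by construction.
    """
    full = (-125.0, -65.0)
    if name == "west-like":
        cfg = SyntheticConfig(regions=[RegionParams("west", full, **_WEST)], seed=seed)
    elif name == "east-like":
        cfg = SyntheticConfig(regions=[RegionParams("east", full, **_EAST)], seed=seed)
    elif name == "two-region":
        split = -105.0
        west = RegionParams("west", (-125.0, split), **_WEST)
        east = RegionParams("east", (split, -65.0), **_EAST)
        # same latitude band on both sides: the area ratio is the longitude
        # width ratio, so the target total-flux contrast fixes the east
        # per-area amplitude exactly
        width_w = split - full[0]
        width_e = full[1] - split
        east.seasonal_amplitude = (
            EAST_WEST_GPP_MEAN_RATIO * west.seasonal_amplitude * width_w / width_e
        )
        cfg = SyntheticConfig(regions=[west, east], split_lon=split, seed=seed)
    else:
        raise GridContractError(f"unknown preset {name!r}")
    return cfg
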