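"""Synthetic multi-biome seasonal dataset generator with known ground truth.

The generator emulates the structure of a Northern-hemisphere conifer
dataset: per biome (boreal, temperate, Mediterranean) and per site, seasonal
series of daily carbon fluxes (NEE, GPP, RECO), weekly wood-formation cell
counts (cambial activity, cell enlargement, cell wall thickening and
lignification) and monthly NSC concentrations (starch peaks; soluble-sugar
minima), plus a site-by-variable bioclimatic table with planted clusters.

Timing structure is configured as per-process lags relative to the biome's
GPP peak, so every pairwise lag is internally consistent by construction.
A site-level shared jitter shifts all of a site's processes together
(preserving site-level lags), a process-specific jitter decorrelates them
partially (so cross-site scaling lines have realistic scatter), and year
and species effects add further structured variation.  All randomness goes
through one seed; identical seeds give byte-identical output.

Ground-truth tables record every configured biome event time, pairwise lag,
site/year-level true peak, and cluster label, so every quantity the
pipeline estimates has a truth entry to compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bioclim import BioclimTable
from .curves import (
    CurveFamily,
    CurveSpec,
    SkewNormalParams,
    VExpParams,
    curve_extremum,
    evaluate_curve,
)
from .fitting import Biome, Organ, Process, SeasonalSeries, month_axis_to_doy

__all__ = [
    "BiomeTimingConfig",
    "BioclimConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "ConfigError",
    "default_paper_like_config",
    "generate_dataset",
    "FLUX_PROCESSES",
    "WOOD_PROCESSES",
    "NSC_EVENTS",
]

FLUX_PROCESSES = (Process.NEE, Process.GPP, Process.RECO)
WOOD_PROCESSES = (
    Process.CAMBIAL_ACTIVITY,
    Process.CELL_ENLARGEMENT,
    Process.WALL_THICKENING,
)
#: (process, organ) pairs for the NSC series
NSC_EVENTS = tuple(
    (p, o)
    for p in (Process.STARCH, Process.SOLUBLE_SUGARS)
    for o in (Organ.NEEDLES, Organ.STEM, Organ.ROOTS)
)


class ConfigError(ValueError):
    """Invalid or internally inconsistent generator configuration."""


def _event_key(process: Process, organ: Organ = Organ.NONE) -> str:
    return process.value if organ is Organ.NONE else f"{process.value}:{organ.value}"


@dataclass
class BiomeTimingConfig:
    """Seasonal timing and shape parameters for one biome.

    ``lags`` maps event labels (``"NEE"``, ``"cambial_activity"``,
    ``"starch:stem"``, ...) to days relative to the biome's GPP peak
    (negative = earlier); soluble-sugar entries locate the concentration
    minimum.  Widths are curve scales in days (omega for skew-normal
    events; the half-width at which a sugar dip recovers to its shoulder).
    """

    gpp_peak_doy: float
    lags: dict[str, float]
    flux_width: float
    wood_width: float
    starch_width: float
    sugar_halfwidth: float  # lower bound on the dip half-width, days
    skew_alpha: float = 2.0

    def event_time(self, label: str) -> float:
        if label == Process.GPP.value:
            return self.gpp_peak_doy
        if label not in self.lags:
            raise ConfigError(f"no lag configured for event '{label}'")
        return self.gpp_peak_doy + self.lags[label]


@dataclass
class BioclimConfig:
    """Planted bioclimatic clusters.

    ``centers`` has one row per cluster over the base variables; three
    extra near-duplicate variables (|r| > 0.7 with a base variable) are
    appended to exercise collinearity filtering.
    """

    n_clusters: int = 4
    n_base_variables: int = 10
    spread_sd: float = 1.0
    center_scale: float = 6.0
    n_collinear_extra: int = 3


@dataclass
class SyntheticConfig:
    biomes: dict[Biome, BiomeTimingConfig]
    sites_per_biome: int = 27
    nsc_sites_per_biome: int = 19
    years: tuple[int, ...] = (2016, 2017)
    species_pool: dict[Biome, tuple[str, ...]] = field(default_factory=dict)
    site_jitter_sd: float = 6.0
    process_jitter_sd: float = 3.0
    year_effect_sd: float = 2.0
    species_effect_sd: float = 4.0
    noise_sd: float = 0.05
    sugar_min_level: float = 0.15
    wood_doy: tuple[int, int, int] = (50, 330, 7)  # start, stop, weekly step
    flux_doy_step: int = 1
    integer_counts: bool = False
    max_cells: int = 40
    bioclim: BioclimConfig = field(default_factory=BioclimConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("site_jitter_sd", "process_jitter_sd", "year_effect_sd",
                     "species_effect_sd", "noise_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if not (0 < self.sugar_min_level < 1):
            raise ConfigError("sugar_min_level must be in (0, 1)")
        if self.sites_per_biome < 1:
            raise ConfigError("sites_per_biome must be >= 1")
        if self.nsc_sites_per_biome > self.sites_per_biome:
            raise ConfigError("nsc_sites_per_biome cannot exceed sites_per_biome")
        if len(self.years) < 1:
            raise ConfigError("need at least one year")
        for biome, bt in self.biomes.items():
            for name in ("flux_width", "wood_width", "starch_width",
                         "sugar_halfwidth"):
                if getattr(bt, name) <= 0:
                    raise ConfigError(f"{biome.value}: {name} must be > 0")
            for label, lag in bt.lags.items():
                if not math.isfinite(lag):
                    raise ConfigError(f"{biome.value}: non-finite lag for {label}")

    def lag(self, event_a: str, event_b: str, biome: Biome) -> float:
        """Configured lag (days) of event_a relative to event_b."""
        bt = self.biomes[biome]
        return bt.event_time(event_a) - bt.event_time(event_b)


@dataclass
class SyntheticDataset:
    series: list[SeasonalSeries]
    bioclim: BioclimTable
    truth: dict[str, pd.DataFrame]
    config: SyntheticConfig


_DEFAULT_SPECIES = {
    Biome.BOREAL: ("Picea mariana", "Pinus sylvestris", "Larix sibirica"),
    Biome.TEMPERATE: ("Picea abies", "Abies alba", "Pinus nigra"),
    Biome.MEDITERRANEAN: ("Pinus halepensis", "Pinus pinaster", "Juniperus thurifera"),
}


def default_paper_like_config(seed: int = 0) -> SyntheticConfig:
    """Timing structure patterned on the multi-biome event sequence.

    Cambial activity peaks 30/45/60 days before GPP (boreal/temperate/
    Mediterranean); cell enlargement peaks 13 days before GPP, cell wall
    thickening and lignification 9 days after, NEE 32 days before, RECO 12
    days after; starch peaks follow the cambial peak by about a week;
    soluble-sugar minima close the season (latest in Mediterranean roots).
    The configured event spans between earliest and latest biome events are
    60, 73 and 170 days for boreal, temperate and Mediterranean.
    """

    def lags(cambial: float, sugars: tuple[float, float, float]) -> dict[str, float]:
        sn, ss, sr = sugars
        return {
            "NEE": -32.0,
            "RECO": 12.0,
            "cambial_activity": cambial,
            "cell_enlargement": -13.0,
            "wall_thickening_lignification": 9.0,
            "starch:needles": cambial + 7.0,
            "starch:stem": cambial + 9.0,
            "starch:roots": cambial + 12.0,
            "soluble_sugars:needles": sn,
            "soluble_sugars:stem": ss,
            "soluble_sugars:roots": sr,
        }

    biomes = {
        Biome.BOREAL: BiomeTimingConfig(
            gpp_peak_doy=170.0,
            lags=lags(-30.0, (20.0, 24.0, 28.0)),
            flux_width=20.0, wood_width=15.0, starch_width=20.0,
            sugar_halfwidth=45.0, skew_alpha=2.0,
        ),
        Biome.TEMPERATE: BiomeTimingConfig(
            gpp_peak_doy=166.0,
            lags=lags(-45.0, (20.0, 24.0, 28.0)),
            flux_width=28.0, wood_width=20.0, starch_width=25.0,
            sugar_halfwidth=55.0, skew_alpha=2.0,
        ),
        Biome.MEDITERRANEAN: BiomeTimingConfig(
            gpp_peak_doy=155.0,
            lags=lags(-60.0, (70.0, 90.0, 110.0)),
            flux_width=45.0, wood_width=30.0, starch_width=40.0,
            sugar_halfwidth=70.0, skew_alpha=2.0,
        ),
    }
    cfg = SyntheticConfig(
        biomes=biomes, species_pool=dict(_DEFAULT_SPECIES), seed=seed
    )
    cfg.validate()
    return cfg


def _skew_mode_offset(omega: float, alpha: float) -> float:
    """Mode minus xi for a skew-normal with the given shape."""
    spec = CurveSpec(
        CurveFamily.SKEW_NORMAL, SkewNormalParams(xi=0.0, omega=omega, alpha=alpha)
    )
    return curve_extremum(spec)[0]


def _unit_peak_skew_spec(peak_doy, omega, alpha, mode_offset=None) -> CurveSpec:
    """Skew-normal spec whose mode is at ``peak_doy`` with peak value 1."""
    if mode_offset is None:
        mode_offset = _skew_mode_offset(omega, alpha)
    xi = peak_doy - mode_offset
    raw = CurveSpec(
        CurveFamily.SKEW_NORMAL, SkewNormalParams(xi=xi, omega=omega, alpha=alpha)
    )
    peak_val = evaluate_curve(raw, xi + mode_offset)
    return CurveSpec(
        CurveFamily.SKEW_NORMAL,
        SkewNormalParams(xi=xi, omega=omega, alpha=alpha, amplitude=1.0 / peak_val),
    )


def _sugar_dip_spec(min_doy: float, halfwidth: float, min_level: float) -> CurveSpec:
    """Minimum-type V-exponential recovering to 1 at +/- halfwidth."""
    lam = math.log(1.0 / min_level) / (halfwidth * halfwidth)
    return CurveSpec(
        CurveFamily.V_EXPONENTIAL,
        VExpParams(ymax=min_level, mu=math.exp(lam), xmax=min_doy),
    )


def _sample_series(spec: CurveSpec, times: np.ndarray, noise_sd: float,
                   rng: np.random.Generator, cap: float | None = None) -> np.ndarray:
    vals = evaluate_curve(spec, times)
    if cap is not None:
        vals = np.minimum(vals, cap)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=len(times))
    return np.maximum(vals, 0.0)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate observations, bioclimatic covariates and truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    species_pool = config.species_pool or dict(_DEFAULT_SPECIES)
    wood_times = np.arange(
        config.wood_doy[0], config.wood_doy[1] + 1, config.wood_doy[2], dtype=float
    )
    flux_times = np.arange(1, 366, config.flux_doy_step, dtype=float)
    nsc_times = month_axis_to_doy(np.arange(1, 13))

    # cache skew-normal mode offsets per (omega, alpha)
    offsets: dict[tuple[float, float], float] = {}

    def offset(om: float, al: float) -> float:
        key = (om, al)
        if key not in offsets:
            offsets[key] = _skew_mode_offset(om, al)
        return offsets[key]

    all_events = [
        (_event_key(p), p, Organ.NONE) for p in FLUX_PROCESSES + WOOD_PROCESSES
    ] + [(_event_key(p, o), p, o) for p, o in NSC_EVENTS]

    year_effects = {
        y: rng.normal(0.0, config.year_effect_sd) if config.year_effect_sd > 0 else 0.0
        for y in config.years
    }
    species_effects: dict[str, float] = {}
    for biome in config.biomes:
        for sp in species_pool.get(biome, ("unknown",)):
            species_effects.setdefault(
                sp,
                rng.normal(0.0, config.species_effect_sd)
                if config.species_effect_sd > 0
                else 0.0,
            )

    series: list[SeasonalSeries] = []
    site_rows = []
    peak_rows = []
    event_rows = []
    lag_rows = []

    for biome, bt in config.biomes.items():
        pool = species_pool.get(biome, ("unknown",))
        for label, proc, organ in all_events:
            event_rows.append(
                {"biome": biome.value, "event": label,
                 "true_time": bt.event_time(label)}
            )
            if label != Process.GPP.value:
                lag_rows.append(
                    {"biome": biome.value, "event": label,
                     "lag_vs_gpp": bt.lags[label]}
                )

        for s in range(config.sites_per_biome):
            site_id = f"{biome.value[:3]}_{s + 1:03d}"
            species = pool[s % len(pool)]
            shared = (
                rng.normal(0.0, config.site_jitter_sd)
                if config.site_jitter_sd > 0 else 0.0
            )
            proc_jit = {
                label: (
                    rng.normal(0.0, config.process_jitter_sd)
                    if config.process_jitter_sd > 0 else 0.0
                )
                for label, _, _ in all_events
            }
            has_nsc = s < config.nsc_sites_per_biome
            site_rows.append(
                {"site_id": site_id, "biome": biome.value, "species": species,
                 "site_shift": shared, "has_nsc": has_nsc}
            )

            for year in config.years:
                for label, proc, organ in all_events:
                    if organ is not Organ.NONE and not has_nsc:
                        continue
                    is_wood = proc in WOOD_PROCESSES
                    t_event = (
                        bt.event_time(label)
                        + shared
                        + proc_jit[label]
                        + year_effects[year]
                        + (species_effects[species] if is_wood else 0.0)
                    )
                    if proc in FLUX_PROCESSES:
                        times, width = flux_times, bt.flux_width
                    elif is_wood:
                        times, width = wood_times, bt.wood_width
                    elif proc is Process.STARCH:
                        times, width = nsc_times, bt.starch_width
                    else:  # soluble sugars
                        times, width = nsc_times, bt.sugar_halfwidth

                    if proc is Process.SOLUBLE_SUGARS:
                        # the dip recovers to its shoulder at the farthest
                        # sampled time, so the series is an exact member of
                        # the V-exponential family over the whole window
                        d_far = max(
                            abs(times.max() - t_event),
                            abs(times.min() - t_event),
                            width,
                        )
                        spec = _sugar_dip_spec(t_event, d_far, config.sugar_min_level)
                        vals = _sample_series(spec, times, config.noise_sd, rng)
                    else:
                        spec = _unit_peak_skew_spec(
                            t_event, width, bt.skew_alpha,
                            mode_offset=offset(width, bt.skew_alpha),
                        )
                        vals = _sample_series(spec, times, config.noise_sd, rng)
                        if is_wood and config.integer_counts:
                            vals = np.round(vals * config.max_cells)

                    series.append(
                        SeasonalSeries(
                            process=proc, organ=organ, biome=biome,
                            site_id=site_id, species=species if is_wood else None,
                            year=year, times=times.copy(), values=vals,
                            normalized=False,
                        )
                    )
                    peak_rows.append(
                        {"site_id": site_id, "biome": biome.value,
                         "species": species if is_wood else "",
                         "year": year, "process": proc.value,
                         "organ": organ.value, "event": label,
                         "true_peak_doy": t_event}
                    )

    bioclim_table, cluster_truth = _generate_bioclim(config, site_rows, rng)

    truth = {
        "site_peaks": pd.DataFrame(peak_rows),
        "biome_events": pd.DataFrame(event_rows),
        "lags_vs_gpp": pd.DataFrame(lag_rows),
        "clusters": cluster_truth,
        "sites": pd.DataFrame(site_rows),
    }
    return SyntheticDataset(
        series=series, bioclim=bioclim_table, truth=truth, config=config
    )


def _generate_bioclim(config: SyntheticConfig, site_rows, rng):
    bc = config.bioclim
    sites = pd.DataFrame(site_rows)
    n_sites = len(sites)
    # Between-cluster structure of k clusters has rank k-1, so the planted
    # separation lives in k-1 "signal" variables whose cluster means follow
    # mutually orthogonal sign patterns (Hadamard columns: zero correlation
    # between signal variables across clusters); remaining base variables
    # are uninformative local-climate noise.
    if bc.n_clusters > 4:
        raise ConfigError("planted-center design supports at most 4 clusters")
    hadamard = np.array(
        [[1, 1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, 1]], dtype=float
    )
    n_signal = bc.n_clusters - 1
    if bc.n_base_variables < n_signal:
        raise ConfigError("need n_base_variables >= n_clusters - 1")
    centers = np.zeros((bc.n_clusters, bc.n_base_variables))
    centers[:, :n_signal] = hadamard[: bc.n_clusters, :n_signal] * bc.center_scale

    # climate clusters cross biome boundaries (a biome is not a climate
    # cluster); deterministic round-robin assignment keeps cluster sizes
    # balanced regardless of the site count
    labels = np.arange(n_sites) % bc.n_clusters

    X = centers[labels] + rng.normal(0.0, bc.spread_sd, size=(n_sites, bc.n_base_variables))
    cols = [f"bio{i + 1}" for i in range(bc.n_base_variables)]
    df = pd.DataFrame(X, index=sites["site_id"].values, columns=cols)
    # near-duplicate variables to exercise the collinearity filter
    for j in range(bc.n_collinear_extra):
        src = cols[j % len(cols)]
        df[f"bio{bc.n_base_variables + j + 1}"] = (
            0.95 * df[src] + rng.normal(0.0, 0.3 * bc.spread_sd, size=n_sites)
        )
    df.index.name = "site_id"
    cluster_truth = pd.DataFrame(
        {"site_id": sites["site_id"], "biome": sites["biome"], "cluster": labels}
    )
    return BioclimTable(df), cluster_truth
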