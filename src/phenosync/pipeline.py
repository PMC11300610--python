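"""End-to-end orchestration of the source-sink timing analysis.

Stages (in dependency order):

``simulate``    generate the synthetic multi-biome dataset (observations,
                bioclimatic table, ground truth)
``fit``         normalize and fit seasonal curves: biome-pooled per
                process/organ, per-site (years pooled) and per-site-year
                for GPP and the wood phases
``phenology``   phenometrics of the biome curves: peaks, percentile times,
                maximum-activity intervals, AUCs, event sequences and
                growing-season spans
``deltas``      flux-vs-wood timing deltas per biome, level and limb
``sma``         standardized-major-axis scaling of wood-phase peak timing
                on GPP peak timing across sites, with cross-biome tests
``cluster``     bioclimatic collinearity filter, PAM clustering with
                WSS-based k selection, PCA ordination
``importance``  random-forest permutation importance of biome, site,
                species and year for peak timing

Each stage reads and writes CSV files in the output directory, so stages
can be re-run independently; a JSON manifest records the configuration
hash, seed, per-stage timings, warnings and the SHA-256 of every output.

Biome-pooled fits average the per-series normalized values on the shared
sampling grid before fitting; with equal observation counts per grid time
this yields exactly the least-squares parameters of the joint fit to all
normalized points, at a fraction of the cost.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .bioclim import BioclimTable, choose_k_wss, filter_collinear, pam_cluster, pca_ordination, standardize
from .curves import CurveFamily, ExtremumType, Limb
from .fitting import (
    Biome,
    MINIMUM_TYPE_PROCESSES,
    Organ,
    Process,
    SeasonalSeries,
    _f_test_p_value,
    fit_seasonal_curve,
    normalize_series,
    select_curve_family,
)
from .importance import run_importance
from .phenometrics import (
    PERCENTILE_LEVELS,
    PhenoMetrics,
    compute_phenometrics,
    event_sequence,
    growing_season_span,
    timing_delta,
)
from .sma import DegenerateDataError, common_slope_test, intercept_test, sma_fit
from .synthetic import (
    FLUX_PROCESSES,
    WOOD_PROCESSES,
    SyntheticConfig,
    default_paper_like_config,
    generate_dataset,
)

__all__ = [
    "STAGES",
    "PipelineError",
    "RunManifest",
    "load_config",
    "run_pipeline",
]

STAGES = ("simulate", "fit", "phenology", "deltas", "sma", "cluster", "importance")

#: files each stage requires -> the stage that produces them
STAGE_INPUTS: dict[str, dict[str, str]] = {
    "simulate": {},
    "fit": {"observations.csv": "simulate"},
    "phenology": {"fits_biome.csv": "fit"},
    "deltas": {"phenometrics.csv": "phenology", "phenometrics_long.csv": "phenology"},
    "sma": {"peaks_site.csv": "fit"},
    "cluster": {"bioclim.csv": "simulate"},
    "importance": {"peaks_site_year.csv": "fit"},
}

#: processes analysed at site level (scaling and importance analyses)
SITE_LEVEL_PROCESSES = (Process.GPP,) + WOOD_PROCESSES


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class AnalysisOptions:
    rf_trees: int = 500
    rf_cv: tuple[int, int] | None = (5, 5)
    k_max: int = 8
    collinearity_threshold: float = 0.7
    delta_levels: tuple[float, ...] = PERCENTILE_LEVELS + (1.0,)
    #: which fit granularities to run: biome-pooled curves feed phenology and
    #: deltas; site and site-year fits feed the sma and importance stages
    fit_scope: tuple[str, ...] = ("biome", "site", "site_year")


def load_config(path: str | Path | None) -> tuple[SyntheticConfig, AnalysisOptions]:
    """Load a YAML config overriding the default generator parameters.

    Top-level keys map onto :class:`SyntheticConfig` fields; a nested
    ``biomes:`` mapping overrides per-biome timing fields, and an
    ``analysis:`` section carries stage options (rf_trees, rf_cv, k_max,
    collinearity_threshold).
    """
    cfg = default_paper_like_config()
    opts = AnalysisOptions()
    if path is None:
        return cfg, opts
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    analysis = raw.pop("analysis", {}) or {}
    for key, val in analysis.items():
        if not hasattr(opts, key):
            raise PipelineError(f"unknown analysis option: {key}")
        if key == "rf_cv" and val is not None:
            val = tuple(val)
        setattr(opts, key, val)
    biome_over = raw.pop("biomes", {}) or {}
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise PipelineError(f"unknown config key: {key}")
        if key == "years":
            val = tuple(int(v) for v in val)
        if key == "wood_doy":
            val = tuple(int(v) for v in val)
        setattr(cfg, key, val)
    for biome_name, fields_ in biome_over.items():
        biome = Biome(biome_name)
        bt = cfg.biomes[biome]
        for key, val in (fields_ or {}).items():
            if key == "lags":
                bt.lags.update({k: float(v) for k, v in val.items()})
            elif hasattr(bt, key):
                setattr(bt, key, float(val))
            else:
                raise PipelineError(f"unknown biome config key: {biome_name}.{key}")
    cfg.validate()
    return cfg, opts


def _config_hash(cfg: SyntheticConfig, opts: AnalysisOptions) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, (Process, Organ, Biome)):
            return o.value
        return str(o)

    payload = json.dumps(
        {"config": cfg, "analysis": opts}, default=default, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out_dir: Path, stage: str, requested: list[str]) -> None:
    for fname, producer in STAGE_INPUTS[stage].items():
        if not (out_dir / fname).exists() and producer not in requested:
            raise PipelineError(
                f"stage '{stage}' is missing input '{fname}' "
                f"(produced by stage '{producer}'; run it first or request it)"
            )


# --------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: SyntheticConfig, out_dir: Path, seed: int) -> list[str]:
    cfg = replace(cfg, seed=seed)
    ds = generate_dataset(cfg)
    psio.write_observations(ds.series, out_dir / "observations.csv")
    ds.bioclim.data.to_csv(out_dir / "bioclim.csv")
    written = ["observations.csv", "bioclim.csv"]
    for name, df in ds.truth.items():
        fname = f"truth_{name}.csv"
        df.to_csv(out_dir / fname, index=False)
        written.append(fname)
    return written


def _grid_mean_series(
    group: list[SeasonalSeries], site_id: str
) -> tuple[SeasonalSeries, float, float]:
    """Average normalized series on their shared sampling grid.

    Returns the re-normalized mean series plus the (offset, range) of the
    mean curve, so pooled residual diagnostics can be computed on the same
    scale the curve was fitted on.
    """
    times = group[0].times
    stack = np.vstack([s.values for s in group])
    mean = stack.mean(axis=0)
    m_min = float(mean.min())
    m_rng = float(mean.max() - mean.min())
    proto = group[0]
    series = SeasonalSeries(
        process=proto.process, organ=proto.organ, biome=proto.biome,
        site_id=site_id, species=None, year=None,
        times=times.copy(), values=(mean - m_min) / m_rng, normalized=True,
    )
    return series, m_min, m_rng


def _pooled_diagnostics(fit, group: list[SeasonalSeries], m_min: float,
                        m_rng: float):
    """Replace mean-series diagnostics by pooled all-points diagnostics.

    With equal observation counts per grid time, least squares on the grid
    mean gives the same parameters as on all points; the residual spread
    (hence RSE and the F-test) must however be measured against the
    individual normalized observations.
    """
    from .curves import evaluate_curve as _eval

    if fit.spec is None:
        return fit
    y_all, resid = [], []
    for s in group:
        y = (s.values - m_min) / m_rng
        y_all.append(y)
        resid.append(y - _eval(fit.spec, s.times))
    y_all = np.concatenate(y_all)
    resid = np.concatenate(resid)
    sse = float(np.sum(resid**2))
    n, k = len(y_all), fit.n_params
    fit.sse = sse
    fit.n_obs = n
    fit.rse = float(np.sqrt(sse / (n - k))) if n > k else float("nan")
    fit.p_value = _f_test_p_value(y_all, sse, k)
    return fit


def _fit_series(series: SeasonalSeries, seed: int):
    if series.process in MINIMUM_TYPE_PROCESSES:
        return fit_seasonal_curve(series, CurveFamily.V_EXPONENTIAL, seed=seed)
    _, fit = select_curve_family(series, seed=seed)
    return fit


def _stage_fit(out_dir: Path, seed: int, opts: AnalysisOptions,
               manifest: RunManifest) -> list[str]:
    series = psio.read_observations(out_dir / "observations.csv")
    norm = []
    for s in series:
        try:
            norm.append(normalize_series(s))
        except Exception as exc:
            manifest.warnings.append(f"fit: skipped {s.site_id}/{s.label}: {exc}")
    written: list[str] = []

    if "biome" in opts.fit_scope:
        pooled: dict[tuple, list[SeasonalSeries]] = {}
        for s in norm:
            pooled.setdefault((s.biome, s.process, s.organ), []).append(s)
        biome_fits = []
        for (biome, proc, organ), group in sorted(
            pooled.items(),
            key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value),
        ):
            mean_series, m_min, m_rng = _grid_mean_series(
                group, site_id=f"pooled_{biome.value}"
            )
            fit = _fit_series(mean_series, seed)
            fit = _pooled_diagnostics(fit, group, m_min, m_rng)
            if not fit.converged:
                manifest.warnings.append(
                    "fit: biome fit did not converge: "
                    f"{biome.value}/{proc.value}/{organ.value}"
                )
            biome_fits.append(
                {"biome": biome.value, "process": proc.value, "organ": organ.value,
                 "n_series": len(group), "t_min": mean_series.times.min(),
                 "t_max": mean_series.times.max(), "fit": fit}
            )
        psio.fits_to_frame(biome_fits).to_csv(out_dir / "fits_biome.csv", index=False)
        written.append("fits_biome.csv")

    site_level = [s for s in norm if s.process in SITE_LEVEL_PROCESSES]

    if "site_year" in opts.fit_scope:
        site_year_rows = []
        for s in site_level:
            fit = _fit_series(s, seed)
            if fit.converged and fit.spec is not None:
                site_year_rows.append(
                    {"site_id": s.site_id, "biome": s.biome.value,
                     "species": s.species or "", "year": s.year,
                     "process": s.process.value, "peak_doy": fit.peak_time,
                     "p_value": fit.p_value, "rse": fit.rse}
                )
            else:
                manifest.warnings.append(
                    f"fit: site-year fit failed: {s.site_id}/{s.process.value}/{s.year}"
                )
        pd.DataFrame(site_year_rows).to_csv(
            out_dir / "peaks_site_year.csv", index=False
        )
        written.append("peaks_site_year.csv")

    if "site" in opts.fit_scope:
        by_site: dict[tuple, list[SeasonalSeries]] = {}
        for s in site_level:
            by_site.setdefault((s.biome, s.site_id, s.process), []).append(s)
        site_rows = []
        for (biome, site_id, proc), group in sorted(
            by_site.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2].value)
        ):
            mean_series, _, _ = _grid_mean_series(group, site_id=site_id)
            species = next((s.species for s in group if s.species), "")
            fit = _fit_series(mean_series, seed)
            if fit.converged and fit.spec is not None:
                site_rows.append(
                    {"site_id": site_id, "biome": biome.value,
                     "species": species or "", "process": proc.value,
                     "peak_doy": fit.peak_time, "p_value": fit.p_value,
                     "rse": fit.rse}
                )
            else:
                manifest.warnings.append(f"fit: site fit failed: {site_id}/{proc.value}")
        pd.DataFrame(site_rows).to_csv(out_dir / "peaks_site.csv", index=False)
        written.append("peaks_site.csv")
    return written


def _stage_phenology(out_dir: Path, manifest: RunManifest) -> list[str]:
    fits = pd.read_csv(out_dir / "fits_biome.csv")
    metric_rows, long_rows, metrics_objs = [], [], []
    for _, row in fits.iterrows():
        if not row["converged"] or pd.isna(row.get("peak_doy")):
            continue
        if row["p_value"] >= 0.05:
            manifest.warnings.append(
                f"phenology: not significant (p={row['p_value']:.3g}): "
                f"{row['biome']}/{row['process']}/{row['organ']}"
            )
            continue
        # an extremum far outside the sampled season marks a degenerate
        # (monotone-limb) fit whose timing metrics would be meaningless
        if not (row["t_min"] - 30.0 <= row["peak_doy"] <= row["t_max"] + 30.0):
            manifest.warnings.append(
                f"phenology: extremum outside sampled window "
                f"({row['peak_doy']:.0f}): {row['biome']}/{row['process']}/"
                f"{row['organ']}"
            )
            continue
        spec = psio.spec_from_row(row)
        from .fitting import FittedCurve  # context-only reconstruction

        fit = FittedCurve(
            spec=spec, sse=row["sse"], rse=row["rse"], p_value=row["p_value"],
            n_obs=int(row["n_obs"]), converged=True,
            family=CurveFamily(row["family"]),
        )
        m = compute_phenometrics(
            fit,
            process=Process(row["process"]),
            organ=Organ(row["organ"]),
            biome=Biome(row["biome"]),
        )
        metrics_objs.append(m)
        metric_rows.append(
            {"biome": m.biome.value, "process": m.process.value,
             "organ": m.organ.value, "event": m.event_name,
             "peak_doy": m.peak_time, "extremum_type": m.extremum_type.value,
             "activity_start": m.max_activity[0], "activity_end": m.max_activity[1],
             "auc_total": m.auc_total, "auc_max_activity": m.auc_max_activity}
        )
        for (level, limb), t in sorted(m.percentile_times.items()):
            long_rows.append(
                {"biome": m.biome.value, "process": m.process.value,
                 "organ": m.organ.value, "event": m.event_name,
                 "level": level, "limb": limb.value, "time_doy": t}
            )
        long_rows.append(
            {"biome": m.biome.value, "process": m.process.value,
             "organ": m.organ.value, "event": m.event_name,
             "level": 1.0, "limb": "", "time_doy": m.peak_time}
        )
    pd.DataFrame(metric_rows).to_csv(out_dir / "phenometrics.csv", index=False)
    pd.DataFrame(long_rows).to_csv(out_dir / "phenometrics_long.csv", index=False)

    seq_rows, span_rows = [], []
    for biome in Biome:
        biome_metrics = [m for m in metrics_objs if m.biome is biome]
        if len(biome_metrics) < 2:
            continue
        for order, (event, t) in enumerate(event_sequence(biome_metrics, biome)):
            seq_rows.append({"biome": biome.value, "order": order,
                             "event": event, "time_doy": t})
        start, end, dur = growing_season_span(biome_metrics, biome)
        span_rows.append({"biome": biome.value, "start_doy": start,
                          "end_doy": end, "duration_days": dur})
    pd.DataFrame(seq_rows).to_csv(out_dir / "event_sequence.csv", index=False)
    pd.DataFrame(span_rows).to_csv(out_dir / "growing_season.csv", index=False)
    return ["phenometrics.csv", "phenometrics_long.csv", "event_sequence.csv",
            "growing_season.csv"]


def _metrics_from_tables(meta_row, long_df) -> PhenoMetrics:
    sel = long_df[
        (long_df["biome"] == meta_row["biome"])
        & (long_df["process"] == meta_row["process"])
        & (long_df["organ"] == meta_row["organ"])
    ]
    pct = {}
    for _, r in sel.iterrows():
        if r["level"] == 1.0:
            continue
        pct[(float(r["level"]), Limb(r["limb"]))] = float(r["time_doy"])
    return PhenoMetrics(
        process=Process(meta_row["process"]),
        organ=Organ(meta_row["organ"]),
        biome=Biome(meta_row["biome"]),
        peak_time=float(meta_row["peak_doy"]),
        extremum_type=ExtremumType(meta_row["extremum_type"]),
        percentile_times=pct,
        max_activity=(float(meta_row["activity_start"]), float(meta_row["activity_end"])),
        auc_total=float(meta_row["auc_total"]),
        auc_max_activity=float(meta_row["auc_max_activity"]),
    )


def _stage_deltas(out_dir: Path, opts: AnalysisOptions) -> list[str]:
    meta = pd.read_csv(out_dir / "phenometrics.csv")
    long_df = pd.read_csv(out_dir / "phenometrics_long.csv").fillna({"limb": ""})
    rows = []
    for biome in meta["biome"].unique():
        sub = meta[meta["biome"] == biome]
        fluxes = {p.value: r for p in FLUX_PROCESSES
                  for _, r in sub[sub["process"] == p.value].iterrows()}
        woods = {p.value: r for p in WOOD_PROCESSES
                 for _, r in sub[sub["process"] == p.value].iterrows()}
        for fname, frow in fluxes.items():
            fm = _metrics_from_tables(frow, long_df)
            for wname, wrow in woods.items():
                wm = _metrics_from_tables(wrow, long_df)
                for level in opts.delta_levels:
                    limbs = [None] if level == 1.0 else [Limb.ASCENDING, Limb.DESCENDING]
                    for limb in limbs:
                        rec = timing_delta(fm, wm, level, limb)
                        rows.append(
                            {"biome": biome, "flux_process": fname,
                             "wood_phase": wname, "level": level,
                             "limb": limb.value if limb else "",
                             "delta_days": rec.delta}
                        )
    pd.DataFrame(rows).to_csv(out_dir / "deltas.csv", index=False)
    return ["deltas.csv"]


def _stage_sma(out_dir: Path, manifest: RunManifest) -> list[str]:
    peaks = pd.read_csv(out_dir / "peaks_site.csv")
    gpp = peaks[peaks["process"] == Process.GPP.value][["site_id", "biome", "peak_doy"]]
    gpp = gpp.rename(columns={"peak_doy": "gpp_peak_doy"})
    fit_rows, test_rows = [], []
    for phase in WOOD_PROCESSES:
        ph = peaks[peaks["process"] == phase.value][["site_id", "biome", "peak_doy"]]
        merged = ph.merge(gpp, on=["site_id", "biome"])
        groups, names = [], []
        for biome, g in merged.groupby("biome", sort=True):
            x = g["gpp_peak_doy"].to_numpy()
            y = g["peak_doy"].to_numpy()
            try:
                f = sma_fit(x, y)
            except DegenerateDataError as exc:
                manifest.warnings.append(f"sma: {phase.value}/{biome}: {exc}")
                continue
            groups.append((x, y))
            names.append(biome)
            fit_rows.append(
                {"phase": phase.value, "biome": biome, "intercept": f.intercept,
                 "slope": f.slope, "ci_lo": f.slope_ci[0], "ci_hi": f.slope_ci[1],
                 "r2": f.r2, "r": f.r, "n": f.n}
            )
        if len(groups) >= 2:
            cs = common_slope_test(groups, names)
            row = {"phase": phase.value, "lr_stat": cs.lr_stat, "df": cs.df,
                   "p_common_slope": cs.p_common_slope,
                   "common_slope": cs.common_slope,
                   "wald_stat": np.nan, "p_intercepts": np.nan}
            if cs.common_slope is not None:
                it = intercept_test(groups, cs.common_slope, names)
                row["wald_stat"] = it.wald_stat
                row["p_intercepts"] = it.p_intercepts
            test_rows.append(row)
    pd.DataFrame(fit_rows).to_csv(out_dir / "sma.csv", index=False)
    pd.DataFrame(test_rows).to_csv(out_dir / "sma_tests.csv", index=False)
    return ["sma.csv", "sma_tests.csv"]


def _stage_cluster(out_dir: Path, opts: AnalysisOptions, manifest: RunManifest) -> list[str]:
    df = pd.read_csv(out_dir / "bioclim.csv", index_col=0)
    table = BioclimTable(df)
    filtered = filter_collinear(table, threshold=opts.collinearity_threshold)
    n = len(filtered.data)
    k_sel, wss = choose_k_wss(filtered, range(1, min(opts.k_max, n - 1) + 1))
    Z = standardize(filtered.data).values
    diff = Z[:, None, :] - Z[None, :, :]
    D2 = np.einsum("ijk,ijk->ij", diff, diff)
    medoids, labels, cost = pam_cluster(D2, k_sel)
    scores, loadings, var_exp = pca_ordination(filtered)

    pd.DataFrame(
        {"site_id": filtered.data.index, "cluster": labels,
         "is_medoid": np.isin(np.arange(n), medoids)}
    ).to_csv(out_dir / "cluster_labels.csv", index=False)
    pd.DataFrame(
        {"k": list(wss), "wss": [wss[k] for k in wss],
         "selected": [k == k_sel for k in wss]}
    ).to_csv(out_dir / "wss_curve.csv", index=False)
    scores.to_csv(out_dir / "pca_scores.csv")
    loadings.assign(variance_explained=var_exp).to_csv(out_dir / "pca_loadings.csv")
    pd.Series(filtered.variables, name="variable").to_csv(
        out_dir / "bioclim_retained.csv", index=False
    )
    return ["cluster_labels.csv", "wss_curve.csv", "pca_scores.csv",
            "pca_loadings.csv", "bioclim_retained.csv"]


def _stage_importance(out_dir: Path, opts: AnalysisOptions, seed: int,
                      manifest: RunManifest) -> list[str]:
    peaks = pd.read_csv(out_dir / "peaks_site_year.csv").fillna({"species": ""})
    imp_rows, met_rows = [], []
    for proc in SITE_LEVEL_PROCESSES:
        rec = peaks[peaks["process"] == proc.value].copy()
        if len(rec) < 30:
            manifest.warnings.append(
                f"importance: too few records for {proc.value} ({len(rec)})"
            )
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = run_importance(
                rec, response="peak_doy", trees=opts.rf_trees, cv=opts.rf_cv,
                seed=seed,
            )
        for w in caught:
            manifest.warnings.append(f"importance/{proc.value}: {w.message}")
        for pred, val in res.importance.items():
            imp_rows.append({"process": proc.value, "predictor": pred,
                             "inc_mse_pct": val})
        met_rows.append(
            {"process": proc.value, "variance_explained_pct": res.variance_explained,
             "r2_train": res.r2_train, "r2_test": res.r2_test,
             "rmse_test": res.rmse_test, "cv_rmse": res.cv_rmse,
             "cv_r2": res.cv_r2, "n_records": res.n_records}
        )
    pd.DataFrame(imp_rows).to_csv(out_dir / "importance.csv", index=False)
    pd.DataFrame(met_rows).to_csv(out_dir / "importance_metrics.csv", index=False)
    return ["importance.csv", "importance_metrics.csv"]


# --------------------------------------------------------------------------


def run_pipeline(
    config: SyntheticConfig | str | Path | None = None,
    out_dir: str | Path = "results",
    stages: list[str] | tuple[str, ...] | None = None,
    seed: int | None = None,
    options: AnalysisOptions | None = None,
) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest."""
    if isinstance(config, (str, Path)):
        cfg, opts = load_config(config)
    elif isinstance(config, SyntheticConfig):
        cfg, opts = config, options or AnalysisOptions()
    else:
        cfg, opts = default_paper_like_config(), options or AnalysisOptions()
    if options is not None:
        opts = options
    seed = cfg.seed if seed is None else int(seed)

    requested = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config_hash=_config_hash(cfg, opts), seed=seed, stages=requested,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for stage in requested:
        _require(out_dir, stage, requested)

    for stage in requested:
        t0 = time.perf_counter()
        if stage == "simulate":
            written = _stage_simulate(cfg, out_dir, seed)
        elif stage == "fit":
            written = _stage_fit(out_dir, seed, opts, manifest)
        elif stage == "phenology":
            written = _stage_phenology(out_dir, manifest)
        elif stage == "deltas":
            written = _stage_deltas(out_dir, opts)
        elif stage == "sma":
            written = _stage_sma(out_dir, manifest)
        elif stage == "cluster":
            written = _stage_cluster(out_dir, opts, manifest)
        elif stage == "importance":
            written = _stage_importance(out_dir, opts, seed, manifest)
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        for fname in written:
            manifest.outputs[fname] = _sha256(out_dir / fname)

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
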