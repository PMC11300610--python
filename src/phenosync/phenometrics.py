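"""Timing tables, event sequences and cross-process deltas from fitted curves.

Each significant fitted curve yields a :class:`PhenoMetrics` record: the
extremum time, the 10/25/50/75/90%-level crossing times on both limbs, the
maximum-activity interval and two areas (total, and over the activity
interval).  Deltas between a carbon-flux metric and a wood-formation metric
at matched level/limb quantify source-sink asynchrony; the convention is
``delta = flux time - wood time``, negative when the flux event is earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .curves import (
    CrossingDomainError,
    ExtremumType,
    Limb,
    curve_auc,
    curve_extremum,
    max_activity_interval,
    percentile_times,
    search_window,
)
from .fitting import Biome, FittedCurve, Organ, Process

__all__ = [
    "PERCENTILE_LEVELS",
    "CANONICAL_EVENT_ORDER",
    "PhenoMetrics",
    "DeltaRecord",
    "compute_phenometrics",
    "timing_delta",
    "event_sequence",
    "growing_season_span",
]

PERCENTILE_LEVELS = (0.10, 0.25, 0.50, 0.75, 0.90)

# fixed tie-break order for simultaneous events
CANONICAL_EVENT_ORDER = (
    "NEE",
    "cambial_activity",
    "starch:needles",
    "starch:stem",
    "starch:roots",
    "cell_enlargement",
    "GPP",
    "RECO",
    "wall_thickening_lignification",
    "soluble_sugars:needles",
    "soluble_sugars:stem",
    "soluble_sugars:roots",
)


@dataclass
class PhenoMetrics:
    """Phenometrics of one fitted process/organ/biome curve."""

    process: Process
    organ: Organ
    biome: Biome
    peak_time: float
    extremum_type: ExtremumType
    percentile_times: Mapping[tuple[float, Limb], float]
    max_activity: tuple[float, float]
    auc_total: float
    auc_max_activity: float
    site_id: str | None = None
    year: int | None = None

    @property
    def event_name(self) -> str:
        organ = "" if self.organ is Organ.NONE else f":{self.organ.value}"
        return f"{self.process.value}{organ}"


@dataclass(frozen=True)
class DeltaRecord:
    """Timing difference between a flux and a wood-formation metric."""

    flux_process: Process
    wood_phase: Process
    biome: Biome
    level: float
    limb: Limb | None
    delta: float  # days, flux time - wood time; negative = flux earlier


def compute_phenometrics(
    fit: FittedCurve,
    process: Process | None = None,
    organ: Organ | None = None,
    biome: Biome | None = None,
    site_id: str | None = None,
    year: int | None = None,
    levels: Sequence[float] = PERCENTILE_LEVELS,
) -> PhenoMetrics:
    """Derive all phenometrics from a converged, significant fit.

    Context fields default to those of the fitted series when present.
    """
    if not fit.converged or fit.spec is None:
        raise ValueError("cannot compute phenometrics for a non-converged fit")
    if fit.p_value >= 0.05:
        raise ValueError(
            f"fit not significant (p = {fit.p_value:.3g}); phenometrics undefined"
        )
    s = fit.series
    process = process or (s.process if s else None)
    organ = organ or (s.organ if s else Organ.NONE)
    biome = biome or (s.biome if s else None)
    site_id = site_id if site_id is not None else (s.site_id if s else None)
    year = year if year is not None else (s.year if s else None)
    if process is None or biome is None:
        raise ValueError("process and biome context required")

    spec = fit.spec
    try:
        t_ext, _ = curve_extremum(spec)
        pct: dict[tuple[float, Limb], float] = {}
        for limb in (Limb.ASCENDING, Limb.DESCENDING):
            times = percentile_times(spec, levels, limb)
            for q, t in times.items():
                pct[(q, limb)] = t
        interval = max_activity_interval(spec)
        lo, hi = search_window(spec)
        auc_total = curve_auc(spec, (lo, hi))
        auc_max = curve_auc(spec, interval)
    except CrossingDomainError as exc:
        raise CrossingDomainError(
            exc.level,
            exc.limb,
            f"{process.value}/{organ.value}/{biome.value}: {exc}",
        ) from exc
    return PhenoMetrics(
        process=process,
        organ=organ,
        biome=biome,
        peak_time=t_ext,
        extremum_type=spec.extremum_type,
        percentile_times=pct,
        max_activity=interval,
        auc_total=auc_total,
        auc_max_activity=auc_max,
        site_id=site_id,
        year=year,
    )


def _time_at(metrics: PhenoMetrics, level: float, limb: Limb | None) -> float:
    if level == 1.0:
        return metrics.peak_time
    if limb is None:
        raise ValueError("limb required for levels below 1.0")
    key = (level, Limb(limb))
    if key not in metrics.percentile_times:
        raise ValueError(f"level {level} not available in metrics")
    return metrics.percentile_times[key]


def timing_delta(
    metrics_a: PhenoMetrics,
    metrics_b: PhenoMetrics,
    level: float,
    limb: Limb | str | None = None,
) -> DeltaRecord:
    """Delta = time_a - time_b at a matched level/limb (level 1.0: peaks)."""
    if metrics_a.biome is not metrics_b.biome:
        raise ValueError(
            f"cannot compare metrics across biomes "
            f"({metrics_a.biome.value} vs {metrics_b.biome.value})"
        )
    limb_e = None if level == 1.0 else Limb(limb)
    delta = _time_at(metrics_a, level, limb_e) - _time_at(metrics_b, level, limb_e)
    return DeltaRecord(
        flux_process=metrics_a.process,
        wood_phase=metrics_b.process,
        biome=metrics_a.biome,
        level=level,
        limb=limb_e,
        delta=delta,
    )


def _canonical_rank(event_name: str) -> int:
    try:
        return CANONICAL_EVENT_ORDER.index(event_name)
    except ValueError:
        return len(CANONICAL_EVENT_ORDER)


def event_sequence(
    metrics_list: Iterable[PhenoMetrics], biome: Biome
) -> list[tuple[str, float]]:
    """Events (peak times; minimum times for sugars) sorted ascending.

    Ties are broken by the fixed canonical process order.
    """
    events = [
        (m.event_name, m.peak_time) for m in metrics_list if m.biome is biome
    ]
    if len(events) < 2:
        raise ValueError(f"need >= 2 events for biome {biome.value}")
    return sorted(events, key=lambda e: (e[1], _canonical_rank(e[0]), e[0]))


def growing_season_span(
    metrics_list: Iterable[PhenoMetrics], biome: Biome
) -> tuple[float, float, float]:
    """(start, end, duration): span between earliest and latest event times."""
    seq = event_sequence(metrics_list, biome)
    start, end = seq[0][1], seq[-1][1]
    return (start, end, end - start)
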