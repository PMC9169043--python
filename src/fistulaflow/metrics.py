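"""Thrombosis-risk metrics: TAWSS, OSI, thresholded wall areas, OBV, flow split.

Wall-based metrics use the standard definitions over one cardiac cycle T:

    TAWSS = (1/T) ∫ |τ| dt
    OSI   = 0.5 (1 − |∫ τ dt| / ∫ |τ| dt)      (0 if ∫|τ|dt = 0)

OSI ranges from 0 (unidirectional shear) to 0.5 (fully reversing, zero-mean
shear).  The thrombosis-association thresholds used throughout are
OSI > 0.3 and TAWSS < 10 dyne/cm² (= 1 Pa; 1 Pa = 10 dyne/cm²).

Volume-based metrics come from the washout simulation: OBVF (%) is the
old-blood volume fraction of the fistula region, and OBV = OBVF/100 × fistula
measure is the corresponding old-blood volume (mm³).  In 2D, wall "areas" are
arc length × 1 mm depth and "volumes" are planar area × 1 mm depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .geometry import DomainGrid, Region
from .solver import FlowCycle, WallShearSeries

__all__ = [
    "PA_TO_DYNE_PER_CM2",
    "WallMetricMap",
    "StasisReport",
    "compute_tawss",
    "compute_osi",
    "wall_metric_map",
    "threshold_area",
    "compute_obv",
    "compute_flow_split",
]

PA_TO_DYNE_PER_CM2 = 10.0


def _periodic_trapezoid(samples: np.ndarray, period: float) -> np.ndarray:
    """Cycle mean of uniformly sampled periodic data via the trapezoid rule.

    The sample at t+T equals the first sample, so the wrapped trapezoid rule
    reduces to the plain average of the samples.
    """
    return samples.mean(axis=-1)


def compute_tawss(series: WallShearSeries) -> np.ndarray:
    """Per-face time-averaged |τ| (Pa) over the periodic cycle."""
    if series.tau.size == 0 or series.tau.shape[1] == 0:
        raise ValueError("empty wall shear series")
    period = float(series.times[-1] - series.times[0]) + float(
        series.times[1] - series.times[0]) if len(series.times) > 1 else 1.0
    return _periodic_trapezoid(np.abs(series.tau), period)


def compute_osi(series: WallShearSeries) -> np.ndarray:
    """Per-face oscillatory shear index in [0, 0.5].

    Faces with identically zero shear take OSI = 0 by convention.
    """
    if series.tau.size == 0 or series.tau.shape[1] == 0:
        raise ValueError("empty wall shear series")
    mean_signed = np.abs(series.tau.mean(axis=-1))
    mean_abs = np.abs(series.tau).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - np.where(mean_abs > 0, mean_signed /
                                    np.where(mean_abs > 0, mean_abs, 1.0),
                                    1.0))
    return np.clip(osi, 0.0, 0.5)


@dataclass
class WallMetricMap:
    """Per-wall-face TAWSS and OSI with face measures and region tags."""

    tawss_pa: np.ndarray
    osi: np.ndarray
    face_measure_mm2: np.ndarray
    region: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray

    @property
    def tawss_dyne_cm2(self) -> np.ndarray:
        return self.tawss_pa * PA_TO_DYNE_PER_CM2


def wall_metric_map(series: WallShearSeries) -> WallMetricMap:
    return WallMetricMap(
        tawss_pa=compute_tawss(series),
        osi=compute_osi(series),
        face_measure_mm2=series.face_measure.astype(float),
        region=series.region,
        x_mm=series.x.astype(float),
        y_mm=series.y.astype(float),
    )


def threshold_area(metric_map: WallMetricMap, metric: str, threshold: float,
                   direction: str = ">",
                   region_scope: str = "fistula_wall") -> tuple[float, float]:
    """(area mm², proportion %) of wall faces passing a metric threshold.

    ``region_scope`` is ``'fistula_wall'`` (faces whose adjacent fluid cell
    is tagged fistula or aneurysm — the default, since fistula thrombosis is
    what is being quantified) or ``'all_wall'``.
    """
    if metric == "osi":
        vals = metric_map.osi
    elif metric == "tawss":
        vals = metric_map.tawss_pa
    elif metric == "tawss_dyne":
        vals = metric_map.tawss_dyne_cm2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if region_scope == "fistula_wall":
        scope = (metric_map.region == int(Region.FISTULA)) | \
                (metric_map.region == int(Region.ANEURYSM))
    elif region_scope == "all_wall":
        scope = np.ones_like(vals, dtype=bool)
    else:
        raise ValueError(f"unknown region scope {region_scope!r}")
    if metric_map.face_measure_mm2.size == 0:
        raise ValueError("empty wall metric map")
    if direction == ">":
        passing = vals > threshold
    elif direction == "<":
        passing = vals < threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    total = float(metric_map.face_measure_mm2[scope].sum())
    area = float(metric_map.face_measure_mm2[scope & passing].sum())
    proportion = 100.0 * area / total if total > 0 else 0.0
    return area, proportion


def compute_obv(obvf_percent: float, fistula_measure_mm3: float) -> float:
    """Old blood volume (mm³) = OBVF/100 × fistula measure."""
    if not (0.0 <= obvf_percent <= 100.0 + 1e-9):
        raise ValueError(f"OBVF {obvf_percent} out of [0, 100]")
    if fistula_measure_mm3 <= 0:
        raise ValueError("fistula measure must be positive")
    return obvf_percent / 100.0 * fistula_measure_mm3


def compute_flow_split(cycle: FlowCycle, grid: DomainGrid) -> dict[str, float]:
    """Cycle-averaged outlet flow percentages of the inlet flow.

    Integrates each outlet port's outward flux over the cycle and normalizes
    by the integrated inlet flux.  A conservation mismatch beyond 1% attaches
    a warning to the result.
    """
    q_in = float(cycle.inlet_flux.sum())
    if q_in == 0.0:
        raise ValueError("cycle has zero integrated inlet flux")
    split = {name: 100.0 * float(flux.sum()) / q_in
             for name, flux in cycle.port_flux.items()}
    total = sum(split.values())
    if abs(total - 100.0) > 1.0:
        warnings.warn(
            f"outlet fluxes sum to {total:.2f}% of the inlet flux "
            "(conservation off by more than 1%)", stacklevel=2)
    return split


@dataclass
class StasisReport:
    """The four thrombosis metrics plus diagnostics for one model variant."""

    variant: str
    obvf_percent: float
    obv_mm3: float
    fistula_measure_mm3: float
    aneurysm_measure_mm3: float
    high_osi_area_mm2: float
    high_osi_proportion_percent: float
    low_tawss_area_mm2: float
    aortic_flow_percent: float
    washout_cycles: int
    washout_converged: bool
    config_hash: str = ""

    def __post_init__(self) -> None:
        expected = compute_obv(self.obvf_percent, self.fistula_measure_mm3)
        if abs(expected - self.obv_mm3) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(
                f"OBV {self.obv_mm3} inconsistent with OBVF "
                f"{self.obvf_percent}% of {self.fistula_measure_mm3} mm^3")
        for name in ("obvf_percent", "high_osi_proportion_percent"):
            val = getattr(self, name)
            if not (0.0 <= val <= 100.0 + 1e-9):
                raise ValueError(f"{name} = {val} out of [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StasisReport":
        return cls(**d)
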