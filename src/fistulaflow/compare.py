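"""Occlusion-position decision logic.

Compares the stasis metrics of the two virtual treatments — aneurysm-reserved
(distal occlusion, the sac stays) versus aneurysm-removed (proximal occlusion,
the sac is excised) — and recommends an occlusion position:

* a large relative OBV difference (default ≥ 50%) means proximal occlusion
  clearly reduces stasis: recommend **proximal**;
* a sub-threshold difference with a small aneurysm (V_A/V_F below the
  dominance threshold, default 0.25) means removing the sac buys little:
  **either** treatment is acceptable;
* a sub-threshold difference with a large aneurysm means proximal occlusion
  would sacrifice substantial supply for little stasis benefit: recommend
  **distal**.

The 50% cutoff and the V_A/V_F = 0.25 morphology tie-break are this package's
formalization of the clinical reasoning in the literature (which states no
numeric cutoffs);
both are exposed as parameters.  A fistula entrance diameter above 8 mm also
raises the guideline anticoagulation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum

from .metrics import StasisReport

__all__ = [
    "OcclusionChoice",
    "TreatmentComparison",
    "Recommendation",
    "compare_treatments",
    "recommend_occlusion",
]

AHA_ANTICOAGULATION_DIAMETER_MM = 8.0


class OcclusionChoice(str, Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"
    EITHER = "either"


@dataclass
class TreatmentComparison:
    """Metric-by-metric comparison of the two occluded variants."""

    reserved: StasisReport
    removed: StasisReport
    obv_relative_difference_percent: float | None
    aneurysm_to_fistula_ratio: float
    non_decreasing_metrics: tuple[str, ...]
    all_metrics_decreased: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["non_decreasing_metrics"] = list(self.non_decreasing_metrics)
        return d


@dataclass
class Recommendation:
    choice: OcclusionChoice
    rationale: tuple[str, ...]
    anticoagulation_indicated: bool | None = None

    def to_dict(self) -> dict:
        return {
            "choice": self.choice.value,
            "rationale": list(self.rationale),
            "anticoagulation_indicated": self.anticoagulation_indicated,
        }


_COMPARED_METRICS = (
    "high_osi_proportion_percent",
    "high_osi_area_mm2",
    "obvf_percent",
    "obv_mm3",
)


def compare_treatments(reserved: StasisReport,
                       removed: StasisReport) -> TreatmentComparison:
    """Derive the OBV difference, morphology ratio and anomaly flags.

    Both reports must come from matched configurations (identical config
    hashes when present).  Any of the four metrics that did *not* decrease
    in the removed variant is listed as an anomaly.
    """
    if reserved.config_hash and removed.config_hash and \
            reserved.config_hash != removed.config_hash:
        raise ValueError(
            "reports come from different configurations "
            f"({reserved.config_hash[:12]} vs {removed.config_hash[:12]})")
    if reserved.obv_mm3 > 0:
        rel = 100.0 * (reserved.obv_mm3 - removed.obv_mm3) / reserved.obv_mm3
    else:
        rel = None
    if reserved.fistula_measure_mm3 <= 0:
        raise ValueError("reserved variant has no fistula measure")
    ratio = reserved.aneurysm_measure_mm3 / reserved.fistula_measure_mm3
    anomalies = tuple(
        name for name in _COMPARED_METRICS
        if not getattr(removed, name) < getattr(reserved, name))
    return TreatmentComparison(
        reserved=reserved,
        removed=removed,
        obv_relative_difference_percent=rel,
        aneurysm_to_fistula_ratio=ratio,
        non_decreasing_metrics=anomalies,
        all_metrics_decreased=not anomalies,
    )


def recommend_occlusion(cmp: TreatmentComparison,
                        obv_diff_threshold: float = 50.0,
                        aneurysm_dominance_threshold: float = 0.25,
                        entrance_diameter_mm: float | None = None,
                        ) -> Recommendation:
    """Recommend the occlusion position from the comparison.

    Deterministic rule set (tokens in the rationale name the fired rule):

    a. OBV relative difference ≥ ``obv_diff_threshold`` → proximal.
    b. Below threshold and V_A/V_F < ``aneurysm_dominance_threshold``
       (small aneurysm) → either.
    c. Below threshold and V_A/V_F ≥ threshold (large aneurysm whose
       removal sacrifices supply) → distal.

    An undefined difference (OBV_reserved = 0: no stasis to reduce) yields
    "either" with a degenerate-input token.
    """
    tokens: list[str] = []
    diff = cmp.obv_relative_difference_percent
    if diff is None:
        tokens.append("degenerate:obv_reserved_zero")
        choice = OcclusionChoice.EITHER
    elif diff >= obv_diff_threshold:
        tokens.append(f"rule_a:obv_difference {diff:.1f}% >= "
                      f"{obv_diff_threshold:.1f}%")
        choice = OcclusionChoice.PROXIMAL
    elif cmp.aneurysm_to_fistula_ratio < aneurysm_dominance_threshold:
        tokens.append(f"rule_b:obv_difference {diff:.1f}% < "
                      f"{obv_diff_threshold:.1f}% and small aneurysm "
                      f"V_A/V_F {cmp.aneurysm_to_fistula_ratio:.3f} < "
                      f"{aneurysm_dominance_threshold:.2f}")
        choice = OcclusionChoice.EITHER
    else:
        tokens.append(f"rule_c:obv_difference {diff:.1f}% < "
                      f"{obv_diff_threshold:.1f}% and large aneurysm "
                      f"V_A/V_F {cmp.aneurysm_to_fistula_ratio:.3f} >= "
                      f"{aneurysm_dominance_threshold:.2f}")
        choice = OcclusionChoice.DISTAL
    anticoag = None
    if entrance_diameter_mm is not None:
        anticoag = entrance_diameter_mm > AHA_ANTICOAGULATION_DIAMETER_MM
        tokens.append(
            f"anticoagulation:{'indicated' if anticoag else 'not_indicated'}"
            f" (D_E {entrance_diameter_mm:.1f} mm vs "
            f"{AHA_ANTICOAGULATION_DIAMETER_MM:.0f} mm)")
    return Recommendation(choice=choice, rationale=tuple(tokens),
                          anticoagulation_indicated=anticoag)
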