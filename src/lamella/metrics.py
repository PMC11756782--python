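"""The plan-quality metric panel.

Prescription convention: the prescribed dose (PD) is assigned to the target
boundary as D_{V-0.01cc} — the minimum dose covering the GTV minus 0.01 cc
(i.e. D_>95% for GTV > 0.20 cc) — or as D_95% for GTV <= 0.20 cc, so that
the uncovered GTV never exceeds the equivalent of a 3 mm diameter lesion.
Plans are rescaled multiplicatively until the prescription metric equals PD.

Quality is then read off a family of equivalent-isodose-volume statistics on
an expanded evaluation region around the target:

* spillage — volume outside the GTV receiving >= 100 / 75 / 50% of PD
  (conformity and dose-falloff steepness);
* D_eIIV of a reference structure — the minimum dose whose irradiated
  isodose volume (IIV) equals that structure's volume; equals PD exactly for
  a perfectly conformal plan;
* coverage of the reference structure by its own D_eIIV — 100% iff the
  isodose surface wraps the structure concentrically ("concentric
  lamellarity"); evaluated on the GTV and its +2 / -2 / -4 mm shells;
* dose inhomogeneity — prescription metric as % of the near-maximum dose
  D_0.01cc (low values = hot center).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np

from . import dvh as _dvh
from . import structures as _structures
from .geometry import DoseGrid, StructureMask

__all__ = [
    "PrescriptionRule", "Prescription", "ShellRecord", "PlanMetrics", "EvalConfig",
    "round_half_up", "prescription_for", "prescription_dose_metric", "rescale",
    "spillage_volumes", "d_near_max", "inhomogeneity", "d_eiiv", "coverage_by",
    "evaluate_plan",
]

SMALL_GTV_CC = 0.20  # at or below: prescribe to D_95%; above: to D_{V-0.01cc}
NEAR_MAX_SMALL_GTV_CC = 0.20  # below (strict): near-max is D_5% instead of D_0.01cc
UNCOVERED_CC = 0.01  # the allowed uncovered volume (3 mm diameter sphere equiv.)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (the clinical reporting convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class PrescriptionRule(str, Enum):
    D_V_MINUS_001CC = "D_V-0.01cc"
    D_95PCT = "D_95%"


@dataclass(frozen=True)
class Prescription:
    pd_gy: float
    rule: PrescriptionRule
    coverage_pct: float  # GTV coverage (%) implied by the rule, 2 decimals


def prescription_for(gtv_volume_cc: float, pd_gy: float) -> Prescription:
    """Select the prescription rule and its implied GTV coverage.

    For V > 0.20 cc the implied coverage is 100*(V - 0.01)/V (rounded
    half-up to two decimals for reporting); at or below 0.20 cc the fixed
    95.00% convention applies.
    """
    if gtv_volume_cc <= 0:
        raise ValueError("GTV volume must be positive")
    if pd_gy <= 0:
        raise ValueError("prescribed dose must be positive")
    if gtv_volume_cc > SMALL_GTV_CC:
        cov = round_half_up(100.0 * (gtv_volume_cc - UNCOVERED_CC) / gtv_volume_cc, 2)
        return Prescription(pd_gy, PrescriptionRule.D_V_MINUS_001CC, cov)
    return Prescription(pd_gy, PrescriptionRule.D_95PCT, 95.00)


def prescription_dose_metric(dose: DoseGrid, gtv: StructureMask,
                             presc: Prescription) -> float:
    """The prescription-point dose of a plan: D_{V-0.01cc} or D_95% (Gy)."""
    curve = _dvh.build_dvh(dose, gtv)
    if presc.rule is PrescriptionRule.D_95PCT:
        return _dvh.dose_at_relative_volume(curve, 95.0)
    v = gtv.volume_cc - UNCOVERED_CC
    if v <= 0:  # degenerate: GTV below the uncovered allowance
        return float(curve.doses_desc[-1])
    return _dvh.dose_at_volume(curve, v)


def rescale(dose: DoseGrid, gtv: StructureMask,
            presc: Prescription) -> tuple[DoseGrid, float]:
    """Scale the plan so its prescription metric equals the prescribed dose.

    Returns the scaled dose and the (unrounded) rescaling ratio; report the
    ratio to three decimals.
    """
    metric = prescription_dose_metric(dose, gtv, presc)
    if metric <= 0:
        raise ValueError("prescription metric is non-positive; no dose in the GTV?")
    ratio = presc.pd_gy / metric
    return dose.scaled(ratio), ratio


def spillage_volumes(dose: DoseGrid, gtv: StructureMask, region: StructureMask,
                     pd_gy: float) -> dict[int, float]:
    """PIV / 75% / 50% spillage: volume (cc) outside the GTV within the
    evaluation region receiving >= 100 / 75 / 50% of the prescribed dose.

    Set-difference convention: voxels at or above threshold AND outside the
    GTV (always >= 0; equals "IIV minus GTV volume" whenever the GTV is
    fully covered at that level).
    """
    dose.require_same_geometry(gtv)
    dose.require_same_geometry(region)
    outside = region.voxels & ~gtv.voxels
    vv = region.grid.voxel_volume_cc
    out: dict[int, float] = {}
    for f in (1.00, 0.75, 0.50):
        out[int(f * 100)] = float((outside & (dose.values >= f * pd_gy)).sum()) * vv
    return out


def d_near_max(dose: DoseGrid, gtv: StructureMask) -> float:
    """Near-maximum GTV dose: D_0.01cc for GTV >= 0.20 cc, else D_5% (Gy)."""
    curve = _dvh.build_dvh(dose, gtv)
    if gtv.volume_cc >= NEAR_MAX_SMALL_GTV_CC:
        return _dvh.dose_at_volume(curve, UNCOVERED_CC)
    return _dvh.dose_at_relative_volume(curve, 5.0)


def inhomogeneity(presc_metric_gy: float, near_max_gy: float) -> float:
    """Dose inhomogeneity (%): prescription metric relative to D_near-max."""
    if not near_max_gy >= presc_metric_gy > 0:
        raise ValueError(
            f"near-max {near_max_gy:g} Gy below prescription metric "
            f"{presc_metric_gy:g} Gy — corrupted plan?"
        )
    return 100.0 * presc_metric_gy / near_max_gy


def d_eiiv(region_curve: _dvh.DVHCurve, ref_volume_cc: float) -> float:
    """Minimum dose whose IIV equals ``ref_volume_cc`` (Gy).

    The lookup is ``dose_at_volume`` on the evaluation-region DVH: the dose
    level t* with exactly ``ref_volume_cc`` of the region at or above it.
    """
    if not 0 < ref_volume_cc <= region_curve.total_volume_cc:
        raise ValueError(
            f"reference volume {ref_volume_cc:g} cc exceeds the region "
            f"({region_curve.total_volume_cc:g} cc)"
        )
    return _dvh.dose_at_volume(region_curve, ref_volume_cc)


def coverage_by(dose: DoseGrid, tv: StructureMask, threshold_gy: float) -> float:
    """Percent of a reference structure receiving at least ``threshold_gy``."""
    dose.require_same_geometry(tv)
    n = tv.voxel_count
    if n == 0:
        raise ValueError(f"empty reference structure {tv.label!r}")
    return 100.0 * float((dose.values[tv.voxels] >= threshold_gy).sum()) / n


@dataclass(frozen=True)
class ShellRecord:
    """D_eIIV panel entry for one reference structure."""

    volume_cc: float
    d_eiiv_gy: float
    d_eiiv_pct: float  # % of prescribed dose
    coverage_pct: float  # % of the structure at or above its D_eIIV


@dataclass(frozen=True)
class EvalConfig:
    pd_gy: float = 43.0
    eval_margin_mm: float = 20.0  # evaluation region margin, within [10, 30]
    shell_margins_mm: tuple[float, ...] = (2.0, -2.0, -4.0)


@dataclass
class PlanMetrics:
    """The full per-plan metric panel (all doses after rescaling)."""

    pd_gy: float
    prescription: Prescription
    rescaling_ratio: float  # unrounded; report to 3 decimals
    gtv_volume_cc: float
    piv_spillage_cc: float
    piv75_spillage_cc: float
    piv50_spillage_cc: float
    d_near_max_gy: float
    inhomogeneity_pct: float
    shells: dict[str, ShellRecord]  # keys: "GTV", "GTV+2mm", "GTV-2mm", "GTV-4mm"
    eligibility: _structures.ShellEligibility

    def to_row(self) -> dict[str, float]:
        """Flat reporting row with the field's printed precisions
        (ratio 3 dp, volumes 2 dp, percentages 1 dp)."""
        row: dict[str, float] = {
            "gtv_cc": round_half_up(self.gtv_volume_cc, 2),
            "pd_gy": self.pd_gy,
            "coverage_pct": self.prescription.coverage_pct,
            "rescaling_ratio": round_half_up(self.rescaling_ratio, 3),
            "piv_spillage_cc": round_half_up(self.piv_spillage_cc, 2),
            "piv75_spillage_cc": round_half_up(self.piv75_spillage_cc, 2),
            "piv50_spillage_cc": round_half_up(self.piv50_spillage_cc, 2),
            "inhomogeneity_pct": round_half_up(self.inhomogeneity_pct, 1),
        }
        for name, rec in self.shells.items():
            key = name.lower().replace("+", "_plus_").replace("-", "_minus_").replace("mm", "")
            row[f"{key}_d_eiiv_pct"] = round_half_up(rec.d_eiiv_pct, 1)
            row[f"{key}_coverage_pct"] = round_half_up(rec.coverage_pct, 1)
        return row


def evaluate_plan(dose: DoseGrid, gtv: StructureMask,
                  config: EvalConfig) -> PlanMetrics:
    """Rescale a plan to its prescription and fill the whole metric panel.

    Deterministic given the inputs. Interior shells below their minimum
    meaningful volume (0.72 cc for -2 mm, 2.20 cc for -4 mm) are omitted
    from ``shells`` and flagged in ``eligibility``.
    """
    dose.require_same_geometry(gtv)
    if gtv.is_empty():
        raise ValueError("empty GTV")
    gtv_cc = gtv.volume_cc
    presc = prescription_for(gtv_cc, config.pd_gy)
    dose, ratio = rescale(dose, gtv, presc)

    surface = _structures.mask_surface(gtv)
    region = _structures.evaluation_region(gtv, config.eval_margin_mm, surface=surface)
    spill = spillage_volumes(dose, gtv, region, config.pd_gy)
    near_max = d_near_max(dose, gtv)
    inhom = inhomogeneity(config.pd_gy, near_max)

    region_curve = _dvh.build_dvh(dose, region)
    elig = _structures.eligible_shells(gtv_cc)
    refs: list[tuple[str, StructureMask | None]] = [("GTV", gtv)]
    for m in config.shell_margins_mm:
        if m == -2.0 and not elig.minus2:
            continue
        if m == -4.0 and not elig.minus4:
            continue
        shell = _structures.margin(gtv, m, surface=surface,
                                   label=f"GTV{m:+g}mm")
        if shell.is_empty():
            continue
        refs.append((f"GTV{m:+g}mm", shell))

    shells: dict[str, ShellRecord] = {}
    for name, ref in refs:
        t = d_eiiv(region_curve, ref.volume_cc)
        shells[name] = ShellRecord(
            volume_cc=ref.volume_cc,
            d_eiiv_gy=t,
            d_eiiv_pct=100.0 * t / config.pd_gy,
            coverage_pct=coverage_by(dose, ref, t),
        )

    return PlanMetrics(
        pd_gy=config.pd_gy,
        prescription=presc,
        rescaling_ratio=ratio,
        gtv_volume_cc=gtv_cc,
        piv_spillage_cc=spill[100],
        piv75_spillage_cc=spill[75],
        piv50_spillage_cc=spill[50],
        d_near_max_gy=near_max,
        inhomogeneity_pct=inhom,
        shells=shells,
        eligibility=elig,
    )
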