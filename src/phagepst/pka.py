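"""Planktonic killing assay (PKA) statistics.

The PKA calls a strain phage-sensitive from liquid growth curves: the OD600
of the infected culture is integrated over 0-24 h and normalised against the
uninfected control,

    AUC_norm = AUC[0,24h](with phage) / AUC[0,24h](without phage),

with AUC_norm < 0.8 scored as lysis and >= 0.8 as no lysis. For lytic pairs
the time of lysis is the first sampled time point at which the expanding-
window AUC_norm over [0, t] first drops below the cutoff.

No blank or baseline subtraction is applied: ratios are taken on raw OD, so
a shared blank offset in both wells slightly compresses them toward 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateControlError, RangeError, ValidationError
from .io_tables import LYSIS, NO_LYSIS, GrowthCurve, HostRangeMatrix
import pandas as pd

DEFAULT_CUTOFF = 0.8


@dataclass(frozen=True)
class PKAResult:
    """AUC statistics and lysis call for one phage-strain pair."""

    phage: str
    strain: str
    auc_with: float
    auc_without: float
    auc_norm: float
    call: str  # "lysis" | "no_lysis"
    time_of_lysis: float | None


def trapezoid_auc(curve: GrowthCurve, t_start: float, t_end: float) -> float:
    """Trapezoidal integral of OD over [t_start, t_end] hours.

    Window endpoints falling between samples are linearly interpolated.
    For piecewise-linear curves this is exact and invariant under grid
    refinement.
    """
    if t_start >= t_end:
        raise RangeError(f"empty window [{t_start}, {t_end}]")
    t, y = curve.times, curve.od
    if t_start < t[0] or t_end > t[-1]:
        raise RangeError(
            f"window [{t_start}, {t_end}] outside sampled range [{t[0]}, {t[-1]}]"
        )
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    yy = np.concatenate((
        [np.interp(t_start, t, y)], y[inside], [np.interp(t_end, t, y)],
    ))
    return float(np.trapezoid(yy, tt))


def auc_norm(with_curve: GrowthCurve, control_curve: GrowthCurve,
             t_start: float = 0.0, t_end: float = 24.0) -> float:
    """Normalised AUC: infected integral divided by control integral."""
    denom = trapezoid_auc(control_curve, t_start, t_end)
    if denom <= 0:
        raise DegenerateControlError(
            f"control well {control_curve.well_id}: zero AUC over "
            f"[{t_start}, {t_end}] h"
        )
    return trapezoid_auc(with_curve, t_start, t_end) / denom


def classify_pka(auc_norm_value: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Lysis iff AUC_norm is strictly below the cutoff (default 0.8)."""
    if auc_norm_value < 0:
        raise ValidationError(f"AUC_norm must be >= 0, got {auc_norm_value}")
    return LYSIS if auc_norm_value < cutoff else NO_LYSIS


def resample_to(curve: GrowthCurve, times: np.ndarray) -> GrowthCurve:
    """Linearly resample a curve onto a target grid (within its range)."""
    t = np.asarray(times, dtype=float)
    if t[0] < curve.times[0] or t[-1] > curve.times[-1]:
        raise RangeError(f"target grid extends beyond well {curve.well_id}")
    return GrowthCurve(curve.well_id, t, np.interp(t, curve.times, curve.od))


def time_of_lysis(with_curve: GrowthCurve, control_curve: GrowthCurve,
                  cutoff: float = DEFAULT_CUTOFF) -> float | None:
    """First sampled time at which the expanding AUC_norm drops below cutoff.

    Curves are resampled to the control grid if needed. Returns ``None`` when
    the full-window call is no_lysis, so the result is always consistent with
    :func:`classify_pka` over the whole window.
    """
    t = control_curve.times
    if len(with_curve.times) != len(t) or not np.allclose(with_curve.times, t):
        with_curve = resample_to(with_curve, t)
    yw, yc = with_curve.od, control_curve.od
    # cumulative trapezoid integrals up to each sample
    cw = np.concatenate(([0.0], np.cumsum(np.diff(t) * (yw[1:] + yw[:-1]) / 2)))
    cc = np.concatenate(([0.0], np.cumsum(np.diff(t) * (yc[1:] + yc[:-1]) / 2)))
    if cc[-1] <= 0:
        raise DegenerateControlError(
            f"control well {control_curve.well_id}: zero AUC over full window"
        )
    if cw[-1] / cc[-1] >= cutoff:  # full-window call is no_lysis
        return None
    for i in range(1, len(t)):
        if cc[i] <= 0:
            raise DegenerateControlError(
                f"control well {control_curve.well_id}: zero-area prefix at t={t[i]}"
            )
        if cw[i] / cc[i] < cutoff:
            return float(t[i])
    return float(t[-1])


# ---------------------------------------------------------------------------
# plate-level pipeline


def mean_curve(curves: list[GrowthCurve], well_id: str) -> GrowthCurve:
    """Pointwise-mean OD of replicate curves sharing a time grid."""
    base = curves[0].times
    aligned = [c.od if np.allclose(c.times, base) else resample_to(c, base).od
               for c in curves]
    return GrowthCurve(well_id, base, np.mean(aligned, axis=0))


def pka_table(plate, cutoff: float = DEFAULT_CUTOFF,
              t_end: float = 24.0) -> list[PKAResult]:
    """Compute one :class:`PKAResult` per phage-strain pair on a plate.

    ``plate`` is the output of :func:`phagepst.io_tables.read_plate`.
    Replicates are averaged as curves (pointwise-mean OD) before any AUC is
    taken; each strain's uninfected control wells are averaged the same way.
    Curves ending before ``t_end`` are integrated to the common final time.
    """
    controls: dict[str, list[GrowthCurve]] = defaultdict(list)
    infected: dict[tuple[str, str], list[GrowthCurve]] = defaultdict(list)
    for curve, ann in plate:
        if ann.role == "control":
            controls[ann.strain].append(curve)
        else:
            infected[(ann.strain, ann.phage)].append(curve)

    results = []
    for (strain, phage), curves in infected.items():
        if strain not in controls:
            raise ValidationError(f"strain {strain}: no uninfected control well")
        ctrl = mean_curve(controls[strain], f"{strain}:control")
        wc = mean_curve(curves, f"{strain}:{phage}")
        end = min(t_end, ctrl.times[-1], wc.times[-1])
        aw = trapezoid_auc(wc, 0.0, end)
        ac = trapezoid_auc(ctrl, 0.0, end)
        if ac <= 0:
            raise DegenerateControlError(f"strain {strain}: zero control AUC")
        ratio = aw / ac
        call = classify_pka(ratio, cutoff)
        tol = time_of_lysis(wc, ctrl, cutoff) if call == LYSIS else None
        results.append(PKAResult(phage, strain, aw, ac, ratio, call, tol))
    results.sort(key=lambda r: (r.phage, r.strain))
    return results


def pka_matrix(results: list[PKAResult],
               strain_meta: dict[str, str] | None = None) -> HostRangeMatrix:
    """Assemble PKA calls into a two-level host-range matrix."""
    phages = sorted({r.phage for r in results})
    strains = sorted({r.strain for r in results})
    calls = pd.DataFrame(index=strains, columns=phages, dtype=object)
    calls[:] = None
    for r in results:
        calls.at[r.strain, r.phage] = r.call
    return HostRangeMatrix(phages, strains, calls, "PKA", strain_meta)
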