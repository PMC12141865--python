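"""MOI-series virulence quantification (local index vi, global index vp).

For each multiplicity of infection the local virulence index is

    vi = 1 - AUC[0, t_s](with phage) / AUC[0, t_s](without phage),

where t_s is the onset of the stationary phase of the uninfected control.
vi is 0 for a phage with no effect and 1 for instantaneous complete killing;
it is clamped to [0, 1] here, since regrowth above the control carries no
extra virulence information and negative values would corrupt the second
integration.

The global virulence index integrates vi a second time over log10(MOI):

    vp = A_p / A_max,

with A_p the trapezoidal area under the vi-versus-log10(MOI) curve and
A_max the width of the log10-MOI range (the area a vi == 1 everywhere phage
would achieve). For the standard ladder 1, 0.1, ..., 0.0001 the range spans
4 decades, so A_max = 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateControlError, ValidationError
from .io_tables import GrowthCurve
from .pka import trapezoid_auc

DEFAULT_MOI_LADDER = (1.0, 0.1, 0.01, 0.001, 0.0001)
DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class MOISeries:
    """Growth curves of one phage on one strain across an MOI ladder."""

    phage: str
    strain: str
    entries: tuple  # of (moi, GrowthCurve)
    control: GrowthCurve

    def __post_init__(self):
        mois = [m for m, _ in self.entries]
        if any(m <= 0 or not math.isfinite(m) for m in mois):
            raise ValidationError("all MOIs must be positive and finite")
        if len(set(mois)) != len(mois):
            raise ValidationError("duplicate MOI in series")


@dataclass(frozen=True)
class VirulenceResult:
    phage: str
    strain: str
    stationary_onset: float
    local_vi: dict[float, float]
    area_ap: float
    area_amax: float
    vp: float


def detect_stationary_onset(control: GrowthCurve, window: int = DEFAULT_WINDOW,
                            tol: float = 0.0) -> float:
    """Time of the first local maximum of the control curve.

    A sample is the onset if its OD is not exceeded (beyond ``tol``) by any
    of the next ``window`` samples — i.e. growth has stopped for ``window``
    consecutive readings (75 min at the 15-min cadence with the default 5).
    Falls back to the final time point when the curve never plateaus.
    """
    if window < 1:
        raise ValidationError("window must be >= 1 sample")
    t, y = control.times, control.od
    if len(y) < window + 1:
        raise ValidationError(
            f"curve has {len(y)} samples; need more than window ({window})"
        )
    for i in range(len(y) - window):
        if y[i] >= np.max(y[i + 1:i + 1 + window]) - tol:
            return float(t[i])
    return float(t[-1])


def local_virulence(with_curve: GrowthCurve, control: GrowthCurve,
                    t_stationary: float) -> float:
    """Local virulence index vi over [0, t_stationary], clamped to [0, 1]."""
    denom = trapezoid_auc(control, 0.0, t_stationary)
    if denom <= 0:
        raise DegenerateControlError(
            f"control well {control.well_id}: zero AUC over [0, {t_stationary}] h"
        )
    vi = 1.0 - trapezoid_auc(with_curve, 0.0, t_stationary) / denom
    return float(min(1.0, max(0.0, vi)))


def global_virulence(series: MOISeries, window: int = DEFAULT_WINDOW,
                     tol: float = 0.0) -> VirulenceResult:
    """Global virulence index vp from an MOI ladder of infection curves.

    The stationary-phase onset is detected on the uninfected control only;
    every infected curve is integrated to that same bound.
    """
    if len(series.entries) < 2:
        raise ValidationError("vp needs >= 2 distinct MOIs")
    t_s = detect_stationary_onset(series.control, window, tol)
    vi_map = {moi: local_virulence(curve, series.control, t_s)
              for moi, curve in series.entries}
    pairs = sorted((math.log10(m), v) for m, v in vi_map.items())
    log_moi = np.array([lm for lm, _ in pairs])
    vi_sorted = np.array([v for _, v in pairs])
    ap = float(np.trapezoid(vi_sorted, log_moi))
    amax = float(log_moi[-1] - log_moi[0])
    vp = min(1.0, max(0.0, ap / amax))
    return VirulenceResult(series.phage, series.strain, t_s, vi_map, ap, amax, vp)
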