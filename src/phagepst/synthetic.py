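"""Synthetic growth curves, host-range matrices and antibiograms.

Every generator is a pure function of (parameters, seed), so each pipeline
stage is testable offline against known ground truth.

The growth model is phenomenological, not mechanistic: an uninfected culture
follows logistic growth

    OD(t) = K * od0 / (od0 + (K - od0) * exp(-r t)),

starting at OD 0.1 and plateauing within 24 h at default rates. An infected
culture tracks the control until a lysis onset

    t_L = max(0, t0 - tau * log10(MOI))

(higher MOI, earlier onset), then decays exponentially toward a debris floor;
optionally a resistant subpopulation regrows logistically from a seeded time.
Measurement noise is additive Gaussian truncated at OD 0, so noise-free AUCs
of the piecewise model provide analytic oracles for the assay statistics.

A single global seed fans out to per-well substreams by stable hashing of
(strain, phage, moi, replicate): adding wells never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .io_tables import (LYSIS, NO_LYSIS, REDUCED_GROWTH, Antibiogram,
                        BreakpointRow, BreakpointTable, GrowthCurve,
                        HostRangeMatrix, WellAnnotation)

DEFAULT_GRID = np.arange(0.0, 24.0 + 1e-9, 0.25)  # 0-24 h every 15 min


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth of the uninfected control."""

    od0: float = 0.1      # inoculation OD600
    r: float = 0.6        # growth rate per h (plateau well before 24 h)
    K: float = 1.2        # carrying-capacity OD600
    noise_sd: float = 0.0  # additive OD noise
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self):
        if not (self.od0 > 0 and self.r > 0 and self.K > self.od0):
            raise ValidationError("need od0 > 0, r > 0, K > od0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LysisParams:
    """MOI-dependent lysis kinetics of an infected culture."""

    t0: float = 4.0          # lysis onset at MOI 1, hours
    tau: float = 1.0         # onset shift per decade of MOI, hours
    lam: float = 2.0         # post-onset OD decay rate per h
    floor: float = 0.05      # debris OD the culture decays toward
    regrow_frac: float = 0.0  # probability of resistant regrowth
    r2: float = 0.3          # regrowth rate per h

    def __post_init__(self):
        if min(self.t0, self.tau, self.lam, self.floor,
               self.regrow_frac, self.r2) < 0:
            raise ValidationError("all lysis parameters must be >= 0")
        if not (0 <= self.regrow_frac <= 1):
            raise ValidationError("regrow_frac must be a probability")


def substream(seed: int, *key) -> np.random.Generator:
    """Per-well RNG derived from the global seed by stable hashing of key."""
    digest = hashlib.sha256(repr(tuple(map(str, key))).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *words]))


# ---------------------------------------------------------------------------
# closed-form noise-free means (also the oracle surface for tests)


def logistic_od(t, g: GrowthParams):
    """Noise-free control OD(t)."""
    t = np.asarray(t, dtype=float)
    return g.K * g.od0 / (g.od0 + (g.K - g.od0) * np.exp(-g.r * t))


def lysis_onset(l: LysisParams, moi: float) -> float:
    """Lysis onset time t_L = max(0, t0 - tau * log10(moi))."""
    if moi <= 0:
        raise ValidationError("moi must be > 0")
    return max(0.0, l.t0 - l.tau * math.log10(moi))


def infected_od(t, g: GrowthParams, l: LysisParams, moi: float,
                regrow_at: float | None = None):
    """Noise-free infected OD(t): logistic, then exponential decay to floor.

    ``regrow_at`` (hours, after onset) switches on logistic regrowth of a
    resistant subpopulation at rate r2 from the decayed OD at that time.
    """
    t = np.asarray(t, dtype=float)
    if l.lam == 0 and regrow_at is None:
        return logistic_od(t, g)  # null phage: no lysis effect at all
    t_l = lysis_onset(l, moi)
    od_tl = float(logistic_od(t_l, g))
    decay = l.floor + (od_tl - l.floor) * np.exp(-l.lam * np.maximum(t - t_l, 0.0))
    out = np.where(t <= t_l, logistic_od(t, g), decay)
    if regrow_at is not None:
        if regrow_at < t_l:
            raise ValidationError("regrowth cannot precede lysis onset")
        od_r = float(l.floor + (od_tl - l.floor) * math.exp(-l.lam * (regrow_at - t_l)))
        od_r = max(od_r, 1e-4)  # a zero population cannot regrow
        late = t > regrow_at
        g2 = GrowthParams(od0=od_r, r=max(l.r2, 1e-9), K=g.K)
        out = np.where(late, logistic_od(np.clip(t - regrow_at, 0, None), g2), out)
    return out


# ---------------------------------------------------------------------------
# curve generators


def _with_noise(mean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.asarray(mean, dtype=float).copy()
    return np.maximum(mean + rng.normal(0.0, sd, size=len(mean)), 0.0)


def simulate_control_curve(g: GrowthParams, seed: int,
                           well_id: str = "control") -> GrowthCurve:
    rng = substream(seed, "control", well_id)
    return GrowthCurve(well_id, g.grid, _with_noise(logistic_od(g.grid, g),
                                                    g.noise_sd, rng))


def simulate_infected_curve(g: GrowthParams, l: LysisParams, moi: float,
                            seed: int, well_id: str = "infected") -> GrowthCurve:
    rng = substream(seed, "infected", well_id, moi)
    regrow_at = None
    if l.regrow_frac > 0 and rng.random() < l.regrow_frac:
        t_l = lysis_onset(l, moi)
        regrow_at = float(rng.uniform(t_l + 1.0, max(t_l + 2.0, g.grid[-1] - 2.0)))
    mean = infected_od(g.grid, g, l, moi, regrow_at)
    return GrowthCurve(well_id, g.grid, _with_noise(mean, g.noise_sd, rng))


# ---------------------------------------------------------------------------
# host-range matrices


def simulate_host_range(n_phages: int, n_strains: int,
                        genus_blocks: list[list[int]] | None = None,
                        p_within: float = 0.7, p_between: float = 0.05,
                        p_reduced: float = 0.15,
                        planted_set: list[int] | None = None,
                        seed: int = 0, assay: str = "DPA") -> HostRangeMatrix:
    """Block-correlated Bernoulli host-range matrix with optional planting.

    ``genus_blocks`` partitions phage indices into genera; each genus draws a
    shared susceptible strain group, inside which its phages lyse with
    probability ``p_within`` (``p_between`` elsewhere) — emulating the
    genus-clustered column structure of real panels. A fraction ``p_reduced``
    of non-lysed DPA cells is scored reduced growth.

    When ``planted_set`` (phage indices) is given, the matrix is post-edited
    so that exactly that set is the unique maximum-coverage set of its size:
    each planted phage receives a private group of strains no other phage
    lyses, sized so any substitution strictly loses coverage.
    """
    if n_phages < 1 or n_strains < 1:
        raise ValidationError("need >= 1 phage and >= 1 strain")
    for p in (p_within, p_between, p_reduced):
        if not (0 <= p <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")
    rng = substream(seed, "host_range", n_phages, n_strains)
    phages = [f"P{i + 1:02d}" for i in range(n_phages)]
    strains = [f"S{j + 1:03d}" for j in range(n_strains)]
    if genus_blocks is None:
        genus_blocks = [[i] for i in range(n_phages)]
    seen = sorted(i for b in genus_blocks for i in b)
    if seen != list(range(n_phages)):
        raise ValidationError("genus_blocks must partition the phage indices")

    lys = np.zeros((n_strains, n_phages), dtype=bool)
    for block in genus_blocks:
        susceptible = rng.random(n_strains) < 0.5
        for i in block:
            prob = np.where(susceptible, p_within, p_between)
            lys[:, i] = rng.random(n_strains) < prob

    if planted_set is not None:
        k = len(planted_set)
        if k < 1 or len(set(planted_set)) != k or \
           any(i < 0 or i >= n_phages for i in planted_set):
            raise GenerationError("planted_set must be distinct valid phage indices")
        # private-group size m with leftover R = n_strains - k*m and m >= R+1
        # guarantees any k-set missing a planted phage covers strictly less
        m = math.ceil((n_strains + 1) / (k + 1))
        if k * m > n_strains:
            raise GenerationError(
                f"cannot plant {k} phages uniquely into {n_strains} strains"
            )
        reserved = rng.permutation(n_strains)[:k * m]
        lys[reserved, :] = False
        for gi, i in enumerate(planted_set):
            lys[reserved[gi * m:(gi + 1) * m], i] = True

    calls = np.where(lys, LYSIS, NO_LYSIS).astype(object)
    if assay == "DPA" and p_reduced > 0:
        reduced = (~lys) & (rng.random((n_strains, n_phages)) < p_reduced)
        if planted_set is not None:
            # reserved strains stay clean so reduced growth cannot blur planting
            mask = np.ones(n_strains, dtype=bool)
            mask[reserved] = False
            reduced &= mask[:, None]
        calls[reduced] = REDUCED_GROWTH
    df = pd.DataFrame(calls, index=strains, columns=phages)
    return HostRangeMatrix(phages, strains, df, assay)


# ---------------------------------------------------------------------------
# antibiograms


def example_breakpoints() -> BreakpointTable:
    """Illustrative disc-diffusion breakpoint table (synthetic values).

    Shaped like an EUCAST table for *P. aeruginosa* with the four MRGN lead
    substances plus two non-leads, but the numbers are plausible placeholders
    for simulation and testing, not a vetted clinical release.
    """
    return BreakpointTable([
        BreakpointRow("piperacillin", "penicillins", True, 24.0, 18.0),
        BreakpointRow("piperacillin/tazobactam", "penicillins", False, 24.0, 18.0),
        BreakpointRow("ceftazidime", "cephalosporins", True, 21.0, 17.0),
        BreakpointRow("meropenem", "carbapenems", True, 24.0, 18.0),
        BreakpointRow("imipenem", "carbapenems", False, 22.0, 17.0),
        BreakpointRow("ciprofloxacin", "fluoroquinolones", True, 26.0, 23.0),
    ])


def simulate_antibiogram(n_strains: int, breakpoints: BreakpointTable,
                         class_resistance_probs: dict[str, float],
                         seed: int = 0) -> list[Antibiogram]:
    """Zone diameters per strain with per-class Bernoulli resistance states.

    A resistant class draws every one of its antibiotics uniformly inside the
    R range (below r_max), a susceptible class inside the S range (at or
    above s_min), so the expected 3MRGN/4MRGN fractions follow directly from
    the class probabilities.
    """
    for c, p in class_resistance_probs.items():
        if not (0 <= p <= 1):
            raise ValidationError(f"resistance probability for {c} must be in [0, 1]")
    out = []
    for j in range(n_strains):
        strain = f"S{j + 1:03d}"
        rng = substream(seed, "antibiogram", strain)
        state = {c: rng.random() < p for c, p in class_resistance_probs.items()}
        zones = {}
        for row in breakpoints:
            resistant = state.get(row.abx_class, False)
            if resistant:
                lo = max(0.0, row.r_max_mm - 8.0)
                zones[row.antibiotic] = float(rng.uniform(lo, row.r_max_mm - 1e-6))
            else:
                hi = min(60.0, row.s_min_mm + 8.0)
                zones[row.antibiotic] = float(rng.uniform(row.s_min_mm, hi))
        out.append(Antibiogram(strain, zones))
    return out


# ---------------------------------------------------------------------------
# plate-level generators


def simulate_moi_series(g: GrowthParams, l: LysisParams, phage: str, strain: str,
                        mois=(1.0, 0.1, 0.01, 0.001, 0.0001), seed: int = 0):
    """An MOI ladder of infected curves plus the uninfected control."""
    from .virulence import MOISeries  # local import to avoid a cycle
    control = simulate_control_curve(g, seed, f"{strain}:control")
    entries = tuple(
        (moi, simulate_infected_curve(g, l, moi, seed, f"{strain}:{phage}:{moi:g}"))
        for moi in mois
    )
    return MOISeries(phage, strain, entries, control)


def simulate_pka_plate(truth: HostRangeMatrix, g: GrowthParams,
                       kill: LysisParams, seed: int = 0, moi: float = 0.1,
                       n_replicates: int = 1):
    """A full plate realising a ground-truth susceptibility matrix.

    Pairs called lysis in ``truth`` get killing kinetics; no_lysis (and
    reduced-growth) pairs get a null phage that leaves the control's growth
    untouched. Returns ``[(GrowthCurve, WellAnnotation), ...]`` ready for
    :func:`phagepst.io_tables.write_plate` or the PKA pipeline.
    """
    null = LysisParams(t0=kill.t0, tau=kill.tau, lam=0.0, floor=0.0,
                       regrow_frac=0.0, r2=0.0)
    plate, w = [], 0
    for s in truth.strains:
        for rep in range(1, n_replicates + 1):
            w += 1
            well = f"W{w:03d}"
            rng_key = (s, "control", rep)
            curve = GrowthCurve(well, g.grid, _with_noise(
                logistic_od(g.grid, g), g.noise_sd, substream(seed, *rng_key)))
            plate.append((curve, WellAnnotation(well, s, None, None, rep, "control")))
        for p in truth.phages:
            params = kill if truth.calls.at[s, p] == LYSIS else null
            for rep in range(1, n_replicates + 1):
                w += 1
                well = f"W{w:03d}"
                rng = substream(seed, s, p, moi, rep)
                mean = infected_od(g.grid, g, params, moi)
                curve = GrowthCurve(well, g.grid, _with_noise(mean, g.noise_sd, rng))
                plate.append((curve,
                              WellAnnotation(well, s, p, moi, rep, "infected")))
    return plate
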