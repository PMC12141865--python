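"""Host-range coverage summaries and DPA/PKA concordance analysis.

The solid-phase double agar overlay plaque assay (DPA) scores each phage-
strain pair as lysis, reduced growth, or no lysis; the liquid planktonic
killing assay (PKA) scores lysis or no lysis. Pairs tested with both assays
fall into six concordance groups:

    1  DPA no_lysis        + PKA no_lysis
    2  DPA reduced_growth  + PKA no_lysis
    3  DPA lysis           + PKA no_lysis
    4  DPA no_lysis        + PKA lysis
    5  DPA reduced_growth  + PKA lysis
    6  DPA lysis           + PKA lysis

Only groups 1 and 6 count as concordant: group 2 is an ambiguous outcome
(reduced growth is itself neither call), not an agreement.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io_tables import (DPA_CALLS, LYSIS, NO_LYSIS, PKA_CALLS, REDUCED_GROWTH,
                        HostRangeMatrix, PhageMetadata)

_GROUP_MAP = {
    (NO_LYSIS, NO_LYSIS): 1,
    (REDUCED_GROWTH, NO_LYSIS): 2,
    (LYSIS, NO_LYSIS): 3,
    (NO_LYSIS, LYSIS): 4,
    (REDUCED_GROWTH, LYSIS): 5,
    (LYSIS, LYSIS): 6,
}

CONCORDANT_GROUPS = (1, 6)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 rounds away from zero), for display percents."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class CoverageSummary:
    phage: str
    n_lysis: int
    n_reduced: int
    n_no_lysis: int
    n_total: int
    pct_lysis: float        # exact
    pct_lysis_int: int      # half-up integer percent for display


def coverage_summary(matrix: HostRangeMatrix) -> list[CoverageSummary]:
    """Per-phage counts of each call level over non-missing strains."""
    if not matrix.phages or not matrix.strains:
        raise ValidationError("empty host-range matrix")
    out = []
    for p in matrix.phages:
        col = [matrix.calls.at[s, p] for s in matrix.strains]
        present = [c for c in col if c is not None]
        n_l = sum(c == LYSIS for c in present)
        n_r = sum(c == REDUCED_GROWTH for c in present)
        n_n = sum(c == NO_LYSIS for c in present)
        pct = 100.0 * n_l / len(present) if present else 0.0
        out.append(CoverageSummary(p, n_l, n_r, n_n, len(present), pct,
                                   int(round_half_up(pct))))
    return out


def coverage_by_category(matrix: HostRangeMatrix) -> pd.DataFrame:
    """Percent of lysed strains per (phage, infection category).

    Strains without metadata are pooled under ``"not available"``; categories
    with zero tested strains yield missing cells.
    """
    meta = matrix.strain_meta or {}
    if not any(s in meta for s in matrix.strains):
        raise ValidationError("no strain metadata supplied")
    categories = sorted({meta.get(s, "not available") for s in matrix.strains})
    rows = {}
    for p in matrix.phages:
        row = {}
        for cat in categories:
            strains = [s for s in matrix.strains
                       if meta.get(s, "not available") == cat
                       and matrix.calls.at[s, p] is not None]
            if not strains:
                row[cat] = float("nan")
            else:
                n_l = sum(matrix.calls.at[s, p] == LYSIS for s in strains)
                row[cat] = 100.0 * n_l / len(strains)
        rows[p] = row
    return pd.DataFrame.from_dict(rows, orient="index")[categories]


def concordance_classify(dpa_call: str, pka_call: str) -> int:
    """Map one (DPA call, PKA call) pair to its concordance group 1-6."""
    if dpa_call not in DPA_CALLS:
        raise ValidationError(f"invalid DPA call {dpa_call!r}")
    if pka_call not in PKA_CALLS:
        raise ValidationError(f"invalid PKA call {pka_call!r} "
                              "(reduced_growth is DPA-only)")
    return _GROUP_MAP[(dpa_call, pka_call)]


@dataclass(frozen=True)
class ConcordanceSummary:
    n_pairs: int
    group_counts: dict[int, int]
    group_fractions: dict[int, float]
    concordance: float  # fraction in groups 1 and 6
    by_genus: pd.DataFrame | None = None


def concordance_summary(dpa_matrix: HostRangeMatrix, pka_matrix: HostRangeMatrix,
                        phage_meta: dict[str, PhageMetadata] | None = None
                        ) -> ConcordanceSummary:
    """Six-group breakdown of all phage-strain pairs tested with both assays."""
    if dpa_matrix.assay != "DPA" or pka_matrix.assay != "PKA":
        raise ValidationError("expected a DPA matrix and a PKA matrix")
    phages = [p for p in dpa_matrix.phages if p in set(pka_matrix.phages)]
    strains = [s for s in dpa_matrix.strains if s in set(pka_matrix.strains)]
    if not phages or not strains:
        raise ValidationError("DPA and PKA matrices share no phage-strain pairs")
    if len(phages) < max(len(dpa_matrix.phages), len(pka_matrix.phages)) or \
       len(strains) < max(len(dpa_matrix.strains), len(pka_matrix.strains)):
        warnings.warn("DPA and PKA matrices differ; using their intersection",
                      stacklevel=2)

    counts = {g: 0 for g in range(1, 7)}
    genus_counts: dict[str, dict[int, int]] = {}
    for p in phages:
        genus = phage_meta[p].genus if phage_meta and p in phage_meta else None
        for s in strains:
            d = dpa_matrix.calls.at[s, p]
            k = pka_matrix.calls.at[s, p]
            if d is None or k is None:
                continue
            g = concordance_classify(d, k)
            counts[g] += 1
            if genus is not None:
                genus_counts.setdefault(genus, {gg: 0 for gg in range(1, 7)})[g] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("no pair has calls in both matrices")
    fractions = {g: c / n for g, c in counts.items()}
    concordance = sum(fractions[g] for g in CONCORDANT_GROUPS)

    by_genus = None
    if genus_counts:
        recs = {}
        for genus, gc in sorted(genus_counts.items()):
            gn = sum(gc.values())
            rec = {f"group_{g}": (gc[g] / gn if gn else float("nan"))
                   for g in range(1, 7)}
            rec["n_pairs"] = gn
            rec["concordance"] = sum(gc[g] for g in CONCORDANT_GROUPS) / gn if gn else float("nan")
            recs[genus] = rec
        by_genus = pd.DataFrame.from_dict(recs, orient="index")
    return ConcordanceSummary(n, counts, fractions, concordance, by_genus)
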