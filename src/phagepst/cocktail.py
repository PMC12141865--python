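"""Maximum-coverage phage-cocktail design over a susceptibility matrix.

A cocktail of k phages covers a strain when at least one member lyses it
(reduced growth does not count by default). Finding the k-set with the most
covered strains is the classic maximum-coverage problem; the exhaustive
solver enumerates all C(n, k) subsets (the default up to 10^6 subsets, which
comfortably includes a realistic panel: 18 safe phages at k = 6 is 18,564
subsets) and reports every co-optimal set, while the greedy solver provides
the standard (1 - 1/e)-approximation for much larger panels. Everything is
deterministic: ties resolve lexicographically on phage names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .errors import ValidationError
from .io_tables import LYSIS, REDUCED_GROWTH, HostRangeMatrix, PhageMetadata
from .host_range import round_half_up

EXHAUSTIVE_LIMIT = 10 ** 6
CO_OPTIMAL_CAP = 10_000


@dataclass(frozen=True)
class CocktailResult:
    k: int
    best_coverage: int
    n_strains: int
    pct: float
    optimal_sets: tuple[tuple[str, ...], ...]  # lexicographically ordered
    method: str  # "exhaustive" | "greedy"
    truncated: bool = False  # co-optimal enumeration hit the cap

    @property
    def pct_int(self) -> int:
        return int(round_half_up(self.pct))


def _lysis_sets(matrix: HostRangeMatrix, include_reduced: bool = False
                ) -> dict[str, int]:
    """Bitmask of covered strains per phage (bit i = strain i)."""
    hits = {LYSIS, REDUCED_GROWTH} if include_reduced else {LYSIS}
    masks = {}
    for p in matrix.phages:
        m = 0
        for i, s in enumerate(matrix.strains):
            if matrix.calls.at[s, p] in hits:
                m |= 1 << i
        masks[p] = m
    return masks


def coverage_of_set(matrix: HostRangeMatrix, phages,
                    include_reduced: bool = False) -> int:
    """Number of strains lysed by at least one phage in the set."""
    unknown = [p for p in phages if p not in set(matrix.phages)]
    if unknown:
        raise ValidationError(f"unknown phage name(s): {', '.join(sorted(unknown))}")
    masks = _lysis_sets(matrix, include_reduced)
    m = 0
    for p in phages:
        m |= masks[p]
    return m.bit_count()


def _candidates(matrix: HostRangeMatrix, safe_only: bool,
                phage_meta: dict[str, PhageMetadata] | None) -> list[str]:
    if not safe_only:
        return sorted(matrix.phages)
    if phage_meta is None:
        raise ValidationError("safe_only requires phage metadata")
    return sorted(p for p in matrix.phages if p in phage_meta and phage_meta[p].safe)


def optimize_cocktail(matrix: HostRangeMatrix, k: int, safe_only: bool = False,
                      phage_meta: dict[str, PhageMetadata] | None = None,
                      method: str = "auto",
                      include_reduced: bool = False) -> CocktailResult:
    """Best k-phage cocktail by covered-strain count.

    ``method`` is ``exhaustive`` (global optimum, all co-optimal sets
    enumerated), ``greedy`` (best marginal gain per step, lexicographic
    tie-break) or ``auto`` (exhaustive when C(n, k) <= 10^6).
    """
    if k < 1:
        raise ValidationError("cocktail size k must be >= 1")
    cand = _candidates(matrix, safe_only, phage_meta)
    if k > len(cand):
        raise ValidationError(f"k = {k} exceeds the {len(cand)} candidate phages")
    if method not in ("auto", "exhaustive", "greedy"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "auto":
        method = "exhaustive" if math.comb(len(cand), k) <= EXHAUSTIVE_LIMIT \
            else "greedy"
    masks = _lysis_sets(matrix, include_reduced)
    n_strains = len(matrix.strains)

    if method == "exhaustive":
        best, best_sets, truncated = -1, [], False
        for subset in combinations(cand, k):
            m = 0
            for p in subset:
                m |= masks[p]
            c = m.bit_count()
            if c > best:
                best, best_sets, truncated = c, [subset], False
            elif c == best:
                if len(best_sets) < CO_OPTIMAL_CAP:
                    best_sets.append(subset)
                else:
                    truncated = True
        sets = tuple(sorted(best_sets))
    else:
        chosen, covered = [], 0
        for _ in range(k):
            gains = [((masks[p] | covered).bit_count(), p)
                     for p in cand if p not in chosen]
            best_gain = max(g for g, _ in gains)
            pick = min(p for g, p in gains if g == best_gain)
            chosen.append(pick)
            covered |= masks[pick]
        best = covered.bit_count()
        sets = (tuple(sorted(chosen)),)
        truncated = False
    pct = 100.0 * best / n_strains if n_strains else 0.0
    return CocktailResult(k, best, n_strains, pct, sets, method, truncated)


def coverage_table(matrix: HostRangeMatrix, k_max: int, safe_only: bool = False,
                   phage_meta: dict[str, PhageMetadata] | None = None,
                   method: str = "auto",
                   include_reduced: bool = False) -> list[CocktailResult]:
    """One :class:`CocktailResult` per cocktail depth k = 1 ... k_max."""
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    return [optimize_cocktail(matrix, k, safe_only, phage_meta, method,
                              include_reduced)
            for k in range(1, k_max + 1)]
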