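"""Therapeutic-potential scoring rubric and panel ranking.

Each phage scores points in four categories:

* DPA host range: 3 points for >= 42 lysed strains, 2 for 21-41, 1 below 21
* PKA host range: 3 points for >= 63 lysed strains, 2 for 31-62, 1 below 31
* global virulence index: 3 points for vp >= 0.6, 2 for 0.3 <= vp < 0.6,
  1 for vp < 0.3
* safety: 1 point for a strictly lytic phage free of virulence factors and
  resistance genes, otherwise 0

for a total of 3-10. All bins are half-open with an inclusive lower edge.
The count thresholds are defaults calibrated to a 141-strain panel (roughly
30%/15% and 45%/22% of it) and scale as configuration to other panels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

DEFAULT_DPA_BINS = (21, 42)   # 1 pt below first, 2 pts in [first, second), 3 pts above
DEFAULT_PKA_BINS = (31, 63)
DEFAULT_VP_BINS = (0.3, 0.6)


@dataclass(frozen=True)
class RankingScore:
    phage: str
    pts_dpa: int
    pts_pka: int
    pts_safety: int
    pts_vp: int

    @property
    def total(self) -> int:
        return self.pts_dpa + self.pts_pka + self.pts_safety + self.pts_vp


def _bin_points(value, bins) -> int:
    lo, hi = bins
    if lo > hi:
        raise ValidationError(f"bin edges out of order: {bins}")
    if value >= hi:
        return 3
    if value >= lo:
        return 2
    return 1


def score_phage(phage: str, dpa_lysed: int, pka_lysed: int, vp: float, safe: bool,
                dpa_bins=DEFAULT_DPA_BINS, pka_bins=DEFAULT_PKA_BINS,
                vp_bins=DEFAULT_VP_BINS) -> RankingScore:
    """Apply the scoring rubric to one phage."""
    if dpa_lysed < 0 or pka_lysed < 0:
        raise ValidationError("lysed-strain counts must be >= 0")
    if not (0 <= vp <= 1):
        raise ValidationError(f"vp must lie in [0, 1], got {vp}")
    return RankingScore(
        phage,
        pts_dpa=_bin_points(dpa_lysed, dpa_bins),
        pts_pka=_bin_points(pka_lysed, pka_bins),
        pts_safety=1 if safe else 0,
        pts_vp=_bin_points(vp, vp_bins),
    )


def rank_phages(scores: list[RankingScore]) -> list[RankingScore]:
    """Sort best-first; ties broken by (pts_pka, pts_dpa, pts_vp, name)."""
    return sorted(scores, key=lambda s: (-s.total, -s.pts_pka, -s.pts_dpa,
                                         -s.pts_vp, s.phage))
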