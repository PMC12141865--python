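"""EUCAST disc-diffusion interpretation and 3MRGN/4MRGN classification.

Zone diameters are interpreted against breakpoints as S (diameter >= S
breakpoint), R (diameter < R breakpoint) or I in between. The German (RKI)
multidrug-resistance scheme for Gram-negatives then counts resistance to the
lead substance of four antibiotic classes — acylureidopenicillins
(piperacillin), 3rd/4th-generation cephalosporins (ceftazidime), carbapenems
(meropenem) and fluoroquinolones (ciprofloxacin): resistant to three leads is
3MRGN, to all four is 4MRGN. "I" (susceptible, increased exposure) counts as
not resistant by default; breakpoints are data, never hardcoded, since EUCAST
revises them annually.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .io_tables import Antibiogram, BreakpointRow, BreakpointTable

DEFAULT_LEADS = {
    "penicillins": "piperacillin",
    "cephalosporins": "ceftazidime",
    "carbapenems": "meropenem",
    "fluoroquinolones": "ciprofloxacin",
}


@dataclass(frozen=True)
class SIRCall:
    antibiotic: str
    call: str  # "S" | "I" | "R"


@dataclass(frozen=True)
class MRGNClass:
    value: str  # "none" | "3MRGN" | "4MRGN"
    resistant_classes: tuple[str, ...]


def interpret_zone(diameter_mm: float, breakpoint: BreakpointRow) -> SIRCall:
    """S if diameter >= s_min, R if diameter < r_max, I otherwise."""
    if diameter_mm < 0:
        raise ValidationError(f"negative zone diameter {diameter_mm}")
    if diameter_mm >= breakpoint.s_min_mm:
        call = "S"
    elif diameter_mm < breakpoint.r_max_mm:
        call = "R"
    else:
        call = "I"
    return SIRCall(breakpoint.antibiotic, call)


def interpret_antibiogram(antibiogram: Antibiogram,
                          breakpoints: BreakpointTable) -> dict[str, SIRCall]:
    """SIR call for every antibiotic present in both zone map and breakpoints."""
    out = {}
    for abx, d in antibiogram.zones.items():
        try:
            bp = breakpoints.get(abx)
        except ValidationError:
            continue  # antibiotic carried but uninterpretable: skipped
        out[abx] = interpret_zone(d, bp)
    return out


def classify_mrgn(antibiogram: Antibiogram, breakpoints: BreakpointTable,
                  leads: dict[str, str] | None = None,
                  i_as_resistant: bool = False) -> MRGNClass:
    """MRGN class of one strain from its disc-diffusion antibiogram.

    Only the four lead substances decide the class; combination agents and
    other antibiotics in the antibiogram are ignored. ``i_as_resistant``
    counts I as resistant for sensitivity analysis.
    """
    leads = dict(DEFAULT_LEADS if leads is None else leads)
    resistant = []
    for abx_class in sorted(leads):
        abx = leads[abx_class]
        if abx not in antibiogram.zones:
            raise ValidationError(
                f"strain {antibiogram.strain}: lead antibiotic {abx} "
                f"({abx_class}) missing from antibiogram"
            )
        call = interpret_zone(antibiogram.zones[abx], breakpoints.get(abx)).call
        if call == "R" or (i_as_resistant and call == "I"):
            resistant.append(abx_class)
    n = len(resistant)
    value = "4MRGN" if n == 4 else "3MRGN" if n == 3 else "none"
    return MRGNClass(value, tuple(resistant))
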