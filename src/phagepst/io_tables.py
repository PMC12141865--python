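"""Data model and table IO for phage susceptibility testing.

All on-disk formats are delimited text (comma or tab, auto-detected on read;
writers emit tabs), UTF-8, LF line endings, deterministic row order.

Canonical tables
----------------
plate series   : columns ``time_h, well, od600`` (long/tidy format)
plate map      : columns ``well, strain, phage, moi, replicate, role``
host range     : first column ``strain``, one column per phage; cells are
                 call tokens (``no_lysis``/``reduced_growth``/``lysis``),
                 their integer codes (0/1/2) or ``NA`` for missing
antibiogram    : columns ``strain, antibiotic, zone_mm``
breakpoints    : columns ``antibiotic, abx_class, lead, s_min_mm, r_max_mm``
phage metadata : columns ``phage, genus, morphotype, lifestyle, safe``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError

# ---------------------------------------------------------------------------
# call levels

NO_LYSIS = "no_lysis"
REDUCED_GROWTH = "reduced_growth"
LYSIS = "lysis"

DPA_CALLS = (NO_LYSIS, REDUCED_GROWTH, LYSIS)
PKA_CALLS = (NO_LYSIS, LYSIS)

_CALL_CODES = {NO_LYSIS: 0, REDUCED_GROWTH: 1, LYSIS: 2}
_CODE_CALLS = {v: k for k, v in _CALL_CODES.items()}

MORPHOTYPES = ("myovirus", "podovirus", "siphovirus")
LIFESTYLES = ("lytic", "temperate")


def decode_call(token, assay: str = "DPA"):
    """Decode one host-range cell token to a canonical call or ``None``.

    Accepts integer codes (0/1/2) and text tokens, case-insensitively.
    ``NA`` / empty cells decode to ``None`` (missing).
    """
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip().lower()
    if s in ("", "na", "nan"):
        return None
    if s in ("0", "1", "2"):
        call = _CODE_CALLS[int(s)]
    elif s in _CALL_CODES:
        call = s
    else:
        raise FormatError(f"unknown host-range cell token {token!r}")
    if assay.upper() == "PKA" and call == REDUCED_GROWTH:
        raise ValidationError(
            "reduced_growth is a DPA-only call level and may not appear in a PKA matrix"
        )
    return call


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series on an ascending time grid (hours)."""

    well_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValidationError(f"well {self.well_id}: times and od must be equal-length 1-d")
        if len(t) < 2:
            raise ValidationError(f"well {self.well_id}: need at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise DataError(f"well {self.well_id}: times must be strictly increasing")
        if t[0] < 0:
            raise ValidationError(f"well {self.well_id}: negative time")
        if np.any(y < 0) or np.any(~np.isfinite(y)):
            raise ValidationError(f"well {self.well_id}: OD values must be finite and >= 0")


@dataclass(frozen=True)
class WellAnnotation:
    """Plate-map entry: which strain/phage/MOI a well holds."""

    well_id: str
    strain: str
    phage: str | None
    moi: float | None
    replicate: int
    role: str  # "control" | "infected"

    def __post_init__(self):
        if self.role not in ("control", "infected"):
            raise ValidationError(f"well {self.well_id}: role must be control or infected")
        if (self.role == "control") != (self.phage is None):
            raise ValidationError(
                f"well {self.well_id}: role == control iff phage is absent"
            )
        if (self.role == "infected") != (self.moi is not None):
            raise ValidationError(f"well {self.well_id}: moi present iff role == infected")
        if self.moi is not None and self.moi <= 0:
            raise ValidationError(f"well {self.well_id}: moi must be > 0")
        if self.replicate < 1:
            raise ValidationError(f"well {self.well_id}: replicate must be >= 1")


@dataclass(frozen=True)
class PhageMetadata:
    name: str
    genus: str
    morphotype: str
    lifestyle: str
    safe: bool

    def __post_init__(self):
        if self.morphotype not in MORPHOTYPES:
            raise ValidationError(f"phage {self.name}: unknown morphotype {self.morphotype!r}")
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(f"phage {self.name}: unknown lifestyle {self.lifestyle!r}")
        # temperate phages are excluded from therapy regardless of genome screen
        if self.lifestyle == "temperate" and self.safe:
            raise ValidationError(f"phage {self.name}: a temperate phage cannot be safe")


@dataclass
class HostRangeMatrix:
    """Phages x strains call matrix from either assay.

    ``calls`` is a strains-by-phages DataFrame whose cells are canonical call
    strings or ``None`` for explicitly missing pairs.
    """

    phages: list[str]
    strains: list[str]
    calls: pd.DataFrame
    assay: str  # "DPA" | "PKA"
    strain_meta: dict[str, str] | None = None

    def __post_init__(self):
        if self.assay not in ("DPA", "PKA"):
            raise ValidationError(f"assay must be DPA or PKA, got {self.assay!r}")
        if len(set(self.phages)) != len(self.phages):
            raise ValidationError("duplicate phage names")
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("duplicate strain names")
        df = self.calls.reindex(index=self.strains, columns=self.phages)
        allowed = set(PKA_CALLS if self.assay == "PKA" else DPA_CALLS)
        for col in df.columns:
            for v in df[col]:
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    continue
                if v not in allowed:
                    raise ValidationError(f"call {v!r} not allowed in a {self.assay} matrix")
        self.calls = df.where(pd.notna(df), None)

    def call(self, strain: str, phage: str):
        return self.calls.at[strain, phage]

    def n_missing(self) -> int:
        return int(self.calls.isna().sum().sum())


@dataclass(frozen=True)
class Antibiogram:
    """Disc-diffusion zone diameters (mm) for one strain."""

    strain: str
    zones: dict[str, float]

    def __post_init__(self):
        for abx, d in self.zones.items():
            if not (0 <= d <= 60):
                raise ValidationError(
                    f"strain {self.strain}: zone {d} mm for {abx} outside plate bounds [0, 60]"
                )


@dataclass(frozen=True)
class BreakpointRow:
    antibiotic: str
    abx_class: str
    lead: bool
    s_min_mm: float
    r_max_mm: float

    def __post_init__(self):
        if self.s_min_mm < self.r_max_mm:
            raise ValidationError(
                f"{self.antibiotic}: inverted breakpoints (s_min {self.s_min_mm} < r_max {self.r_max_mm})"
            )


@dataclass
class BreakpointTable:
    rows: list[BreakpointRow] = field(default_factory=list)

    def __post_init__(self):
        names = [r.antibiotic for r in self.rows]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate antibiotic in breakpoint table")
        leads: dict[str, str] = {}
        for r in self.rows:
            if r.lead:
                if r.abx_class in leads:
                    raise ValidationError(
                        f"class {r.abx_class} has two lead substances "
                        f"({leads[r.abx_class]}, {r.antibiotic})"
                    )
                leads[r.abx_class] = r.antibiotic

    def __iter__(self):
        return iter(self.rows)

    def get(self, antibiotic: str) -> BreakpointRow:
        for r in self.rows:
            if r.antibiotic == antibiotic:
                return r
        raise ValidationError(f"antibiotic {antibiotic!r} not in breakpoint table")

    @property
    def lead_map(self) -> dict[str, str]:
        return {r.abx_class: r.antibiotic for r in self.rows if r.lead}


# ---------------------------------------------------------------------------
# delimited-text helpers


def _read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, auto-detecting the dialect."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False, comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {', '.join(missing)}")


def _to_float(s: str, what: str) -> float:
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"{what}: cannot parse number {s!r}") from None


# ---------------------------------------------------------------------------
# plate series + map


def read_plate(series_path, map_path) -> list[tuple[GrowthCurve, WellAnnotation]]:
    """Read a long-format plate series and its plate map.

    Returns one ``(GrowthCurve, WellAnnotation)`` pair per well, in plate-map
    order. Every well in the series must be annotated in the map.
    """
    series = _read_table(series_path)
    _require_columns(series, ("time_h", "well", "od600"), "plate series")
    plate_map = _read_table(map_path)
    _require_columns(plate_map, ("well", "strain", "phage", "moi", "replicate", "role"),
                     "plate map")

    curves: dict[str, GrowthCurve] = {}
    for well, grp in series.groupby("well", sort=False):
        t = np.array([_to_float(v, f"well {well} time") for v in grp["time_h"]])
        y = np.array([_to_float(v, f"well {well} od600") for v in grp["od600"]])
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        if np.any(np.diff(t) <= 0):
            raise DataError(f"well {well}: duplicate or non-increasing time points")
        curves[str(well)] = GrowthCurve(str(well), t, y)

    annotations: dict[str, WellAnnotation] = {}
    for _, row in plate_map.iterrows():
        well = str(row["well"]).strip()
        phage = row["phage"].strip() or None
        if phage is not None and phage.upper() == "NA":
            phage = None
        moi_s = str(row["moi"]).strip()
        moi = None if moi_s in ("", "NA", "na") else _to_float(moi_s, f"well {well} moi")
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise FormatError(f"well {well}: replicate must be an integer") from None
        ann = WellAnnotation(well, str(row["strain"]).strip(), phage, moi, rep,
                             str(row["role"]).strip().lower())
        if well in annotations:
            raise ValidationError(f"well {well}: duplicated in plate map")
        annotations[well] = ann

    unmapped = sorted(set(curves) - set(annotations))
    if unmapped:
        raise ValidationError(
            f"well(s) present in series but absent from plate map: {', '.join(unmapped)}"
        )
    out = []
    for well, ann in annotations.items():
        if well not in curves:
            continue  # mapped but empty well: tolerated
        out.append((curves[well], ann))
    return out


def write_plate(curves_annotations, series_path, map_path):
    """Write plate series + map in the canonical long format (tab-delimited)."""
    srows, mrows = [], []
    for curve, ann in curves_annotations:
        for t, y in zip(curve.times, curve.od):
            # shortest repr that round-trips bit-exactly
            srows.append((repr(float(t)), curve.well_id, repr(float(y))))
        mrows.append((
            ann.well_id, ann.strain,
            "" if ann.phage is None else ann.phage,
            "" if ann.moi is None else format(ann.moi, "g"),
            str(ann.replicate), ann.role,
        ))
    with open(series_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_h\twell\tod600\n")
        for t, w, y in srows:
            fh.write(f"{t}\t{w}\t{y}\n")
    with open(map_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("well\tstrain\tphage\tmoi\treplicate\trole\n")
        for r in mrows:
            fh.write("\t".join(r) + "\n")


# ---------------------------------------------------------------------------
# host-range matrices


def read_host_range(path, assay: str, strain_meta: dict[str, str] | None = None
                    ) -> HostRangeMatrix:
    """Read a strains-by-phages call table for the given assay (DPA or PKA)."""
    assay = assay.upper()
    if assay not in ("DPA", "PKA"):
        raise ValidationError(f"assay must be DPA or PKA, got {assay!r}")
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError("host-range table needs a strain column plus >= 1 phage column")
    strain_col = df.columns[0]
    phages = list(df.columns[1:])
    strains = [str(s).strip() for s in df[strain_col]]
    if len(set(strains)) != len(strains):
        raise ValidationError("duplicate strain row in host-range table")
    calls = pd.DataFrame(index=strains, columns=phages, dtype=object)
    for p in phages:
        calls[p] = [decode_call(v, assay) for v in df[p]]
    return HostRangeMatrix(phages, strains, calls, assay, strain_meta)


def write_host_range(matrix: HostRangeMatrix, path, encode: str = "text"):
    """Write a host-range matrix; ``encode`` is ``"text"`` or ``"int"``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("strain\t" + "\t".join(matrix.phages) + "\n")
        for s in matrix.strains:
            cells = []
            for p in matrix.phages:
                v = matrix.calls.at[s, p]
                if v is None:
                    cells.append("NA")
                elif encode == "int":
                    cells.append(str(_CALL_CODES[v]))
                else:
                    cells.append(v)
            fh.write(s + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# antibiograms & breakpoints


def read_antibiograms(path) -> list[Antibiogram]:
    """Read a long-format antibiogram table (strain, antibiotic, zone_mm)."""
    df = _read_table(path)
    _require_columns(df, ("strain", "antibiotic", "zone_mm"), "antibiogram")
    out = []
    for strain, grp in df.groupby("strain", sort=False):
        zones = {}
        for _, row in grp.iterrows():
            abx = str(row["antibiotic"]).strip()
            if abx in zones:
                raise ValidationError(f"strain {strain}: duplicate antibiotic {abx}")
            zones[abx] = _to_float(row["zone_mm"], f"strain {strain} zone")
        out.append(Antibiogram(str(strain), zones))
    return out


def write_antibiograms(antibiograms, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("strain\tantibiotic\tzone_mm\n")
        for ab in antibiograms:
            for abx, d in ab.zones.items():
                fh.write(f"{ab.strain}\t{abx}\t{format(d, 'g')}\n")


def read_breakpoints(path) -> BreakpointTable:
    df = _read_table(path)
    _require_columns(df, ("antibiotic", "abx_class", "lead", "s_min_mm", "r_max_mm"),
                     "breakpoint table")
    rows = []
    for _, row in df.iterrows():
        lead_s = str(row["lead"]).strip().lower()
        if lead_s not in ("true", "false", "1", "0", "yes", "no"):
            raise FormatError(f"breakpoints: lead must be boolean, got {row['lead']!r}")
        rows.append(BreakpointRow(
            str(row["antibiotic"]).strip(), str(row["abx_class"]).strip(),
            lead_s in ("true", "1", "yes"),
            _to_float(row["s_min_mm"], "breakpoints s_min_mm"),
            _to_float(row["r_max_mm"], "breakpoints r_max_mm"),
        ))
    return BreakpointTable(rows)


def write_breakpoints(table: BreakpointTable, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("antibiotic\tabx_class\tlead\ts_min_mm\tr_max_mm\n")
        for r in table:
            fh.write(f"{r.antibiotic}\t{r.abx_class}\t{str(r.lead).lower()}\t"
                     f"{format(r.s_min_mm, 'g')}\t{format(r.r_max_mm, 'g')}\n")


# ---------------------------------------------------------------------------
# phage metadata


def read_phage_metadata(path) -> dict[str, PhageMetadata]:
    df = _read_table(path)
    _require_columns(df, ("phage", "genus", "morphotype", "lifestyle", "safe"),
                     "phage metadata")
    out: dict[str, PhageMetadata] = {}
    for _, row in df.iterrows():
        name = str(row["phage"]).strip()
        if name in out:
            raise ValidationError(f"duplicate phage {name} in metadata")
        safe_s = str(row["safe"]).strip().lower()
        out[name] = PhageMetadata(
            name, str(row["genus"]).strip(),
            str(row["morphotype"]).strip().lower(),
            str(row["lifestyle"]).strip().lower(),
            safe_s in ("true", "1", "yes"),
        )
    return out


def write_phage_metadata(meta: dict[str, PhageMetadata], path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("phage\tgenus\tmorphotype\tlifestyle\tsafe\n")
        for m in meta.values():
            fh.write(f"{m.name}\t{m.genus}\t{m.morphotype}\t{m.lifestyle}\t"
                     f"{str(m.safe).lower()}\n")
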