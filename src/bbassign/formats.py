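"""Readers and writers for the text formats the assignment pipeline touches.

The peak-list dialect is the Sparky export format: a header row, a blank
row, then one peak per row with columns ``name  w1  w2  (w3)  (intensity)``.
For triple-resonance lists the axes are (15N, 13C, 1HN); for the 15N-1H
HSQC they are (15N, 1HN).  Assigned peak names follow the grammar
``X(n)N-Cx-HN`` for internal carbon correlations, ``X(n)N-Y(n-1)Cx-X(n)HN``
for sequential ones and ``X(n)N-HN`` for amide (HSQC) peaks, where X/Y are
one-letter residue codes and Cx is CA, CB or CO.  Unassigned peaks are
named ``?-?-?``.

Sequence files are whitespace-separated uppercase three-letter codes;
secondary-structure files are whitespace-separated lowercase tokens
``helx``/``strd``/``loop``/``xxxx``, one per residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Experiment",
    "Peak",
    "PeakList",
    "RowDiagnostic",
    "ProteinSequence",
    "SS",
    "PeakName",
    "FormatError",
    "parse_peak_list",
    "write_peak_list",
    "parse_sequence",
    "write_sequence",
    "parse_sequence_oneletter",
    "write_sequence_oneletter",
    "parse_ss_file",
    "write_ss_file",
    "parse_peak_name",
    "format_peak_name",
    "UNASSIGNED_NAME",
]

UNASSIGNED_NAME = "?-?-?"

# one- and three-letter residue codes for the 20 standard amino acids
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

NUCLEI = ("CA", "CB", "CO")


class FormatError(ValueError):
    """Raised for structurally invalid input files."""


class Experiment(str, Enum):
    """The seven supported peak-list types.

    ``_ii1`` lists hold both internal (i) and sequential (i-1) carbon
    correlations, ``_i1`` lists hold sequential ones only.
    """

    HNCA_ii1 = "HNCA_ii1"
    HNCA_i1 = "HNCA_i1"
    HNCB_ii1 = "HNCB_ii1"
    HNCB_i1 = "HNCB_i1"
    HNCO_ii1 = "HNCO_ii1"
    HNCO_i1 = "HNCO_i1"
    HSQC = "HSQC"

    @property
    def is_triple_resonance(self) -> bool:
        return self is not Experiment.HSQC

    @property
    def nucleus(self) -> str | None:
        """The 13C nucleus the experiment's carbon axis reports (None for HSQC).

        HNCB lists may additionally carry CA rows; that is resolved per row
        by intensity sign during spin-system labeling.
        """
        if self in (Experiment.HNCA_ii1, Experiment.HNCA_i1):
            return "CA"
        if self in (Experiment.HNCB_ii1, Experiment.HNCB_i1):
            return "CB"
        if self in (Experiment.HNCO_ii1, Experiment.HNCO_i1):
            return "CO"
        return None

    @property
    def sequential_only(self) -> bool:
        return self in (Experiment.HNCA_i1, Experiment.HNCB_i1, Experiment.HNCO_i1)


# deterministic processing order used throughout the package
EXPERIMENT_ORDER = (
    Experiment.HSQC,
    Experiment.HNCO_i1,
    Experiment.HNCA_ii1,
    Experiment.HNCA_i1,
    Experiment.HNCB_ii1,
    Experiment.HNCB_i1,
    Experiment.HNCO_ii1,
)


@dataclass
class Peak:
    """One picked resonance: a name, ppm coordinates and an optional height."""

    name: str = UNASSIGNED_NAME
    w_n: float = 0.0
    w_c: float | None = None
    w_hn: float = 0.0
    intensity: float | None = None
    row: int = -1  # 0-based data-row index within its list; provenance key

    def coords_ok(self) -> bool:
        """Sanity window for amide coordinates (warn outside, never reject)."""
        return 100.0 <= self.w_n <= 135.0 and 5.0 <= self.w_hn <= 12.0


@dataclass
class RowDiagnostic:
    line: int
    text: str
    reason: str


@dataclass
class PeakList:
    experiment: Experiment
    peaks: list[Peak] = field(default_factory=list)
    has_ca_in_hncb: bool = False
    header: str = ""
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class ProteinSequence:
    """Residues as one-letter codes with 1-based numbering (plus offset)."""

    residues: str
    offset: int = 1

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first(self) -> int:
        return self.offset

    @property
    def last(self) -> int:
        return self.offset + len(self.residues) - 1

    def residue(self, number: int) -> str:
        """One-letter code of the residue with this sequence number."""
        i = number - self.offset
        if not 0 <= i < len(self.residues):
            raise IndexError(f"residue number {number} outside sequence "
                             f"[{self.first}..{self.last}]")
        return self.residues[i]

    def numbers(self) -> range:
        return range(self.first, self.last + 1)


class SS(str, Enum):
    HELIX = "helix"
    STRAND = "strand"
    COIL = "coil"
    UNKNOWN = "unknown"


SS_TOKENS = {"helx": SS.HELIX, "strd": SS.STRAND, "loop": SS.COIL, "xxxx": SS.UNKNOWN}
SS_TO_TOKEN = {v: k for k, v in SS_TOKENS.items()}


@dataclass(frozen=True)
class PeakName:
    """Structured form of an assigned peak name.

    ``nucleus`` is None for amide (HSQC) names.  For sequential names the
    carbon belongs to ``prev`` (one-letter code, number); for internal
    names ``prev`` is None.
    """

    residue: str  # one-letter code
    number: int
    nucleus: str | None = None
    sequential: bool = False
    prev: tuple[str, int] | None = None


_RE_INTERNAL = re.compile(r"^([A-Z])(\d+)N-(CA|CB|CO)-HN$")
_RE_SEQUENTIAL = re.compile(r"^([A-Z])(\d+)N-([A-Z])(\d+)(CA|CB|CO)-([A-Z])(\d+)HN$")
_RE_AMIDE = re.compile(r"^([A-Z])(\d+)N-HN$")


def parse_peak_name(name: str) -> PeakName | None:
    """Parse an assigned peak name; return None for the unassigned name.

    Raises FormatError for names matching neither grammar.
    """
    if name == UNASSIGNED_NAME:
        return None
    m = _RE_INTERNAL.match(name)
    if m:
        return PeakName(m.group(1), int(m.group(2)), m.group(3), False, None)
    m = _RE_SEQUENTIAL.match(name)
    if m:
        if (m.group(6), m.group(7)) != (m.group(1), m.group(2)):
            raise FormatError(f"inconsistent amide labels in peak name {name!r}")
        return PeakName(m.group(1), int(m.group(2)), m.group(5), True,
                        (m.group(3), int(m.group(4))))
    m = _RE_AMIDE.match(name)
    if m:
        return PeakName(m.group(1), int(m.group(2)), None, False, None)
    raise FormatError(f"unparseable peak name {name!r}")


def format_peak_name(pn: PeakName | None) -> str:
    if pn is None:
        return UNASSIGNED_NAME
    if pn.nucleus is None:
        return f"{pn.residue}{pn.number}N-HN"
    if pn.sequential:
        if pn.prev is None:
            raise FormatError("sequential peak name needs the preceding residue")
        pl, pnum = pn.prev
        return (f"{pn.residue}{pn.number}N-{pl}{pnum}{pn.nucleus}"
                f"-{pn.residue}{pn.number}HN")
    return f"{pn.residue}{pn.number}N-{pn.nucleus}-HN"


def _split_rows(text: str) -> tuple[str, list[tuple[int, str]]]:
    lines = text.splitlines()
    if not lines:
        raise FormatError("empty peak list: missing header row")
    header = lines[0]
    if len(lines) < 2 or lines[1].strip():
        raise FormatError("peak list must have a blank row after the header")
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if i >= 2 and ln.strip()]
    return header, rows


def parse_peak_list(
    text: str,
    experiment: Experiment,
    require_intensity: bool = False,
    column_map: Sequence[int] | None = None,
    has_ca_in_hncb: bool = False,
) -> PeakList:
    """Parse a Sparky-dialect peak list.

    Malformed data rows are reported as per-row diagnostics rather than
    aborting the parse; the row counts always satisfy
    ``rows in == peaks out + diagnostics out``.

    ``column_map`` optionally reorders custom columns into the canonical
    order (indices of name, w1, w2[, w3][, intensity] in the input row).
    """
    header, rows = _split_rows(text)
    ncoord = 3 if experiment.is_triple_resonance else 2
    out = PeakList(experiment=experiment, header=header,
                   has_ca_in_hncb=has_ca_in_hncb)
    for lineno, raw in rows:
        fields = raw.split()
        if column_map is not None:
            try:
                fields = [fields[i] for i in column_map]
            except IndexError:
                out.diagnostics.append(RowDiagnostic(lineno, raw, "column map out of range"))
                continue
        if len(fields) < 1 + ncoord:
            out.diagnostics.append(
                RowDiagnostic(lineno, raw, f"expected at least {1 + ncoord} columns"))
            continue
        name = fields[0]
        try:
            coords = [float(x) for x in fields[1:1 + ncoord]]
        except ValueError:
            out.diagnostics.append(RowDiagnostic(lineno, raw, "non-numeric chemical shift"))
            continue
        intensity: float | None = None
        if len(fields) > 1 + ncoord:
            try:
                intensity = float(fields[1 + ncoord])
            except ValueError:
                out.diagnostics.append(RowDiagnostic(lineno, raw, "non-numeric intensity"))
                continue
        elif require_intensity:
            out.diagnostics.append(RowDiagnostic(lineno, raw, "missing intensity column"))
            continue
        try:
            parse_peak_name(name)
        except FormatError:
            out.diagnostics.append(RowDiagnostic(lineno, raw, "malformed peak name"))
            continue
        if experiment.is_triple_resonance:
            peak = Peak(name, coords[0], coords[1], coords[2], intensity,
                        row=len(out.peaks))
        else:
            peak = Peak(name, coords[0], None, coords[1], intensity,
                        row=len(out.peaks))
        out.peaks.append(peak)
    if require_intensity and rows and not any(p.intensity is not None
                                              for p in out.peaks):
        raise FormatError(f"{experiment.value}: intensity column required but absent")
    return out


def write_peak_list(plist: PeakList, ppm_decimals: int = 3) -> str:
    """Serialize a peak list in the Sparky dialect (header, blank row, rows)."""
    header = plist.header or _default_header(plist.experiment,
                                             any(p.intensity is not None for p in plist.peaks))
    lines = [header, ""]
    for p in plist.peaks:
        cols = [p.name, f"{p.w_n:.{ppm_decimals}f}"]
        if plist.experiment.is_triple_resonance:
            cols.append(f"{(p.w_c if p.w_c is not None else float('nan')):.{ppm_decimals}f}")
        cols.append(f"{p.w_hn:.{ppm_decimals}f}")
        if p.intensity is not None:
            cols.append(f"{p.intensity:.3e}")
        lines.append("  ".join(cols))
    return "\n".join(lines) + "\n"


def _default_header(experiment: Experiment, with_intensity: bool) -> str:
    cols = ["Assignment", "w1", "w2"] + (["w3"] if experiment.is_triple_resonance else [])
    if with_intensity:
        cols.append("Data Height")
    return "  ".join(cols)


def parse_sequence(text: str, offset: int = 1) -> ProteinSequence:
    """Parse a whitespace-separated uppercase three-letter-code sequence."""
    out = []
    for pos, token in enumerate(text.split(), start=1):
        if token not in AA_3TO1:
            raise FormatError(f"unknown residue token {token!r} at position {pos}")
        out.append(AA_3TO1[token])
    return ProteinSequence("".join(out), offset=offset)


def write_sequence(seq: ProteinSequence, per_line: int = 10) -> str:
    tokens = [AA_1TO3[c] for c in seq.residues]
    lines = [" ".join(tokens[i:i + per_line]) for i in range(0, len(tokens), per_line)]
    return "\n".join(lines) + "\n"


def parse_sequence_oneletter(text: str, offset: int = 1) -> ProteinSequence:
    """Parse a concatenated one-letter-code sequence (custom dialect)."""
    letters = "".join(text.split()).upper()
    for pos, c in enumerate(letters, start=1):
        if c not in AA_1TO3:
            raise FormatError(f"unknown residue letter {c!r} at position {pos}")
    return ProteinSequence(letters, offset=offset)


def write_sequence_oneletter(seq: ProteinSequence) -> str:
    return seq.residues + "\n"


def parse_ss_file(text: str, sequence_length: int) -> list[SS]:
    """Parse a secondary-structure file (helx/strd/loop/xxxx tokens)."""
    labels = []
    for pos, token in enumerate(text.split(), start=1):
        if token not in SS_TOKENS:
            raise FormatError(f"unknown secondary-structure token {token!r} "
                              f"at position {pos} (tokens are lowercase "
                              f"helx/strd/loop/xxxx)")
        labels.append(SS_TOKENS[token])
    if len(labels) != sequence_length:
        raise FormatError(f"secondary-structure file has {len(labels)} tokens "
                          f"for a {sequence_length}-residue sequence")
    return labels


def write_ss_file(labels: Iterable[SS], per_line: int = 10) -> str:
    tokens = [SS_TO_TOKEN[l] for l in labels]
    lines = [" ".join(tokens[i:i + per_line]) for i in range(0, len(tokens), per_line)]
    return "\n".join(lines) + "\n"
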