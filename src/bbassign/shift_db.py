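"""Reference chemical-shift statistics and deuterium isotope-shift corrections.

Three bundled tables drive all scoring:

* ``ConsensusShiftTable`` — per (residue type, secondary-structure class,
  nucleus) mean and standard deviation of the 13C chemical shift, in the
  style of database-derived consensus statistics.  Glycine has no CB
  entries (a *defined-missing* value, not an error).
* ``RandomCoilTable`` — random-coil shifts plus the full-helix and
  full-strand secondary-shift offsets used by the propensity profile.
* ``IsotopeShiftTable`` — per (residue type, nucleus) 2H isotope shift
  (deuterated minus protonated, negative because deuteration moves 13C
  shifts upfield).  Corrected shifts are ``observed - delta``, i.e. the
  correction convention is data, not code.  Partially deuterated samples
  use the same values as perdeuterated ones.

All tables are plain TSV files and can be replaced by the user.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from .formats import NUCLEI, SS, AA_1TO3

__all__ = [
    "ConsensusShiftTable",
    "RandomCoilTable",
    "IsotopeShiftTable",
    "ShiftTables",
    "load_consensus",
    "load_random_coil",
    "load_isotope_shifts",
    "load_default_tables",
]

SS_CLASSES = (SS.HELIX, SS.STRAND, SS.COIL)


def _read_tsv(path) -> list[dict]:
    if hasattr(path, "read_text"):
        text = path.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


@dataclass
class ConsensusShiftTable:
    """(residue, ss, nucleus) -> (mean ppm, sd ppm); None where undefined."""

    entries: dict[tuple[str, SS, str], tuple[float, float]] = field(default_factory=dict)

    def lookup(self, residue: str, ss: SS, nucleus: str) -> tuple[float, float] | None:
        """Return (mean, sd) or None for a defined-missing combination
        (glycine CB).  Unknown residues/nuclei raise KeyError."""
        if residue not in AA_1TO3:
            raise KeyError(f"unknown residue type {residue!r}")
        if nucleus not in NUCLEI:
            raise KeyError(f"unknown nucleus {nucleus!r}")
        if ss not in SS_CLASSES:
            raise KeyError(f"consensus statistics need a concrete SS class, got {ss}")
        return self.entries.get((residue, ss, nucleus))

    def validate(self) -> None:
        for res in AA_1TO3:
            for ss in SS_CLASSES:
                for nuc in NUCLEI:
                    ent = self.entries.get((res, ss, nuc))
                    if res == "G" and nuc == "CB":
                        if ent is not None:
                            raise ValueError("glycine must not have CB statistics")
                        continue
                    if ent is None:
                        raise ValueError(f"missing consensus entry ({res},{ss.value},{nuc})")
                    if not ent[1] > 0:
                        raise ValueError(f"non-positive sd for ({res},{ss.value},{nuc})")


@dataclass
class RandomCoilTable:
    """Random-coil shifts and full-SS secondary-shift offsets per nucleus."""

    rc: dict[tuple[str, str], float] = field(default_factory=dict)
    helix_delta: dict[tuple[str, str], float] = field(default_factory=dict)
    strand_delta: dict[tuple[str, str], float] = field(default_factory=dict)

    def lookup(self, residue: str, nucleus: str) -> float | None:
        return self.rc.get((residue, nucleus))


@dataclass
class IsotopeShiftTable:
    """(residue, nucleus) -> deuterated-minus-protonated 13C shift (ppm)."""

    delta: dict[tuple[str, str], float] = field(default_factory=dict)

    def correction(self, residue: str, nucleus: str) -> float:
        """Signed delta for this combination; glycine CB is defined-missing 0."""
        if residue == "G" and nucleus == "CB":
            return 0.0
        try:
            return self.delta[(residue, nucleus)]
        except KeyError:
            raise KeyError(f"isotope-shift table has no entry for "
                           f"({residue}, {nucleus})") from None

    def correct(self, observed: float, residue: str, nucleus: str) -> float:
        """Map an observed deuterated-sample shift onto the protonated scale."""
        return observed - self.correction(residue, nucleus)

    def uncorrect(self, corrected: float, residue: str, nucleus: str) -> float:
        return corrected + self.correction(residue, nucleus)


@dataclass
class ShiftTables:
    """Bundle of the three tables, threaded through scoring and the profile."""

    consensus: ConsensusShiftTable
    random_coil: RandomCoilTable
    isotope: IsotopeShiftTable


def load_consensus(path=None) -> ConsensusShiftTable:
    rows = _read_tsv(path if path is not None else _data_file("consensus_shifts.tsv"))
    table = ConsensusShiftTable()
    for r in rows:
        key = (r["residue"], SS(r["ss"]), r["nucleus"])
        table.entries[key] = (float(r["mean"]), float(r["sd"]))
    table.validate()
    return table


def load_random_coil(path=None) -> RandomCoilTable:
    rows = _read_tsv(path if path is not None else _data_file("random_coil.tsv"))
    table = RandomCoilTable()
    for r in rows:
        key = (r["residue"], r["nucleus"])
        table.rc[key] = float(r["rc"])
        table.helix_delta[key] = float(r["helix_delta"])
        table.strand_delta[key] = float(r["strand_delta"])
    return table


def load_isotope_shifts(path=None) -> IsotopeShiftTable:
    rows = _read_tsv(path if path is not None else _data_file("isotope_shifts.tsv"))
    table = IsotopeShiftTable()
    for r in rows:
        table.delta[(r["residue"], r["nucleus"])] = float(r["delta"])
    return table


def _data_file(name: str):
    return resources.files("bbassign").joinpath("data", name)


def load_default_tables(consensus_path=None, random_coil_path=None,
                        isotope_path=None) -> ShiftTables:
    return ShiftTables(
        consensus=load_consensus(consensus_path),
        random_coil=load_random_coil(random_coil_path),
        isotope=load_isotope_shifts(isotope_path),
    )
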