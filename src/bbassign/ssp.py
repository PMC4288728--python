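"""Secondary-structure propensity (SSP) profile from assigned 13C shifts.

For each assigned residue the secondary shift ``dd = observed - random
coil`` is computed per nucleus (CA and CB by default; CO optional).  Each
secondary shift is turned into a propensity in [-1, 1] by normalizing
against the residue's full-helix or full-strand secondary-shift
reference: a shift on the helix side of random coil divided by the
full-helix value approaches +1 in a formed helix, one on the strand side
divided by the full-strand magnitude approaches -1 in a formed strand.
Propensities are averaged over a five-residue window (the residue, two
before, two after; truncated at chain ends and assignment gaps) with
inverse-variance-style reliability weights per nucleus — nuclei with a
larger full secondary shift relative to the consensus spread count more.
By construction a long stretch at full-helix consensus scores ~+1, one at
full-strand consensus ~-1 and random-coil shifts score exactly 0.

Deuterated-sample shifts are isotope-corrected before the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .assign_engine import AssignmentState
from .formats import SS, ProteinSequence, SS_TO_TOKEN
from .shift_db import ShiftTables
from .spin_label import SpinSystem

__all__ = [
    "SSPProfile",
    "observed_shifts",
    "secondary_shifts",
    "compute_ssp",
    "export_ssp",
    "parse_ssp",
]

DEFAULT_NUCLEI = ("CA", "CB")
WINDOW_WEIGHTS = {-2: 1.0, -1: 2.0, 0: 3.0, 1: 2.0, 2: 1.0}
# consensus spreads used for the per-nucleus reliability weighting
_NUC_SD = {"CA": 1.0, "CB": 1.1, "CO": 1.0}


@dataclass
class SSPProfile:
    scores: dict[int, float | None] = field(default_factory=dict)
    coverage: dict[int, tuple[str, ...]] = field(default_factory=dict)


def observed_shifts(state: AssignmentState, systems: Sequence[SpinSystem],
                    sequence: ProteinSequence) -> dict[int, dict[str, float]]:
    """Per-residue 13C shifts from the assignment.

    Residue i's carbons are seen twice: internally by the system at i and
    sequentially by the system at i+1; both observations are averaged.
    """
    by_id = {s.id: s for s in systems}
    values: dict[int, dict[str, list[float]]] = {}
    for res, sid in state.mapping.items():
        sys_ = by_id[sid]
        for nuc, v in sys_.internal.items():
            values.setdefault(res, {}).setdefault(nuc, []).append(v)
        if res - 1 >= sequence.first:
            for nuc, v in sys_.sequential.items():
                values.setdefault(res - 1, {}).setdefault(nuc, []).append(v)
    return {res: {nuc: sum(vs) / len(vs) for nuc, vs in d.items()}
            for res, d in values.items()}


def secondary_shifts(shifts: dict[int, dict[str, float]],
                     sequence: ProteinSequence, tables: ShiftTables,
                     deuterated: bool = False) -> dict[int, dict[str, float]]:
    """Secondary shifts (observed - random coil) per residue and nucleus."""
    out: dict[int, dict[str, float]] = {}
    for res, d in shifts.items():
        res_type = sequence.residue(res)
        for nuc, v in d.items():
            rc = tables.random_coil.lookup(res_type, nuc)
            if rc is None:
                continue
            if deuterated:
                v = tables.isotope.correct(v, res_type, nuc)
            out.setdefault(res, {})[nuc] = v - rc
    return out


def _propensity(delta: float, helix_full: float, strand_full: float) -> float:
    """Map one secondary shift onto the [-1, 1] propensity scale."""
    if delta == 0.0:
        return 0.0
    helix_side = (delta > 0) == (helix_full > 0)
    if helix_side:
        return abs(delta / helix_full)
    return -abs(delta / strand_full)


def compute_ssp(deltas: dict[int, dict[str, float]],
                sequence: ProteinSequence, tables: ShiftTables,
                nuclei: tuple[str, ...] = DEFAULT_NUCLEI,
                window: int = 2) -> SSPProfile:
    """Windowed propensity profile; None where no shift falls in the window."""
    profile = SSPProfile()
    for res in sequence.numbers():
        num = 0.0
        den = 0.0
        contributing: list[str] = []
        for off, wwin in WINDOW_WEIGHTS.items():
            if abs(off) > window:
                continue
            j = res + off
            d = deltas.get(j)
            if not d:
                continue
            res_type = sequence.residue(j)
            for nuc in nuclei:
                if nuc not in d:
                    continue
                hf = tables.random_coil.helix_delta.get((res_type, nuc))
                sf = tables.random_coil.strand_delta.get((res_type, nuc))
                if hf is None or sf is None or hf == 0 or sf == 0:
                    continue
                p = _propensity(d[nuc], hf, sf)
                ref = abs(hf) if (d[nuc] > 0) == (hf > 0) else abs(sf)
                w = wwin * (ref / _NUC_SD[nuc]) ** 2
                num += w * p
                den += w
                if off == 0:
                    contributing.append(nuc)
        profile.scores[res] = (num / den) if den > 0 else None
        profile.coverage[res] = tuple(contributing)
    return profile


def export_ssp(profile: SSPProfile, sequence: ProteinSequence,
               expected_ss: Sequence[SS] | None = None) -> str:
    """TSV export: residue, score (NA when undefined), expected label."""
    header = ["residue", "score"] + (["expected"] if expected_ss is not None else [])
    lines = ["\t".join(header)]
    for res in sequence.numbers():
        score = profile.scores.get(res)
        row = [str(res), "NA" if score is None else f"{score:.4f}"]
        if expected_ss is not None:
            row.append(SS_TO_TOKEN[expected_ss[res - sequence.offset]])
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_ssp(text: str) -> SSPProfile:
    lines = [l for l in text.splitlines() if l.strip()]
    profile = SSPProfile()
    for line in lines[1:]:
        parts = line.split("\t")
        res = int(parts[0])
        profile.scores[res] = None if parts[1] == "NA" else float(parts[1])
    return profile
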