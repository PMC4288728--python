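"""Sequential connectivity analysis and placement scoring.

Two spin systems are *connected* (predecessor -> successor) when the
successor's sequential CA/CB/CO shifts agree with the predecessor's
internal ones within tolerance; agreement of one, two or three nuclei is
called Match 1, 2 and 3.  Glycine predecessors lack CB: when neither side
offers a CB and the sequential CA falls in the glycine window, CA + CO
agreement already counts as Match 3.

Connected systems are chained into fragments (all directed simple paths
of 2..10 systems).  If any (size, match) group would exceed the fragment
cap, every tolerance is scaled down by the back-off factor and the build
restarts, down to a tolerance floor.

Each placement of a fragment onto the sequence is scored with a reduced
chi-squared statistic against consensus shift statistics:

    chi2 = scale * sum_i sum_j ((d_obs_ij - d_db_ij)^2 / sd_ij^2) / N

where i runs over the probed residues, j over the compared 13C shifts,
d_db and sd are the consensus mean and spread for the candidate residue
type, secondary-structure class and nucleus, N is the total number of
compared shifts and scale = 10 adjusts the numeric range.  A low value
means a more probable placement.  Because each probed residue carries its
own secondary-structure label and the score decomposes residue-wise, the
best label combination is found by per-residue minimization (provably
equal to enumerating all 3^n combinations).  The amide of spin system m
sits at residue start+m; its sequential shifts probe residue start+m-1,
so a fragment of k systems probes residues start-1 .. start+k-1.
Deuterated-sample shifts are compared after adding the candidate residue
type's isotope correction to the reference values, which is equivalent to
correcting the observed shifts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .formats import NUCLEI, SS, ProteinSequence
from .shift_db import SS_CLASSES, ShiftTables
from .spin_label import SpinSystem

__all__ = [
    "MatchConfig",
    "ScoringConfig",
    "Fragment",
    "FragmentBuild",
    "ScoredPlacement",
    "ResultList",
    "AnalysisResult",
    "match_level",
    "build_fragments",
    "fragment_observations",
    "score_placement",
    "best_ss_combination",
    "enumerate_placements",
    "analyze_all",
    "result_file_name",
    "write_result_file",
    "parse_result_file",
]

SS_LETTER = {SS.HELIX: "H", SS.STRAND: "E", SS.COIL: "C", SS.UNKNOWN: "x"}
LETTER_SS = {v: k for k, v in SS_LETTER.items()}
RESULT_LIMIT = 20


@dataclass
class MatchConfig:
    tol_ca: float = 0.2
    tol_cb: float = 0.2
    tol_co: float = 0.2
    match_level: int = 1          # lowest match level to analyze
    max_fragment_size: int = 10
    fragment_cap: int = 1000
    backoff_factor: float = 0.9
    tol_floor: float = 0.005
    gly_ca_window: tuple[float, float] = (42.0, 48.0)

    def __post_init__(self) -> None:
        if min(self.tol_ca, self.tol_cb, self.tol_co) <= 0:
            raise ValueError("tolerances must be positive")
        if not 2 <= self.max_fragment_size <= 10:
            raise ValueError("max_fragment_size must be in [2, 10]")
        if not 0 < self.backoff_factor < 1:
            raise ValueError("backoff_factor must be in (0, 1)")
        if self.match_level not in (1, 2, 3):
            raise ValueError("match_level must be 1, 2 or 3")

    def tolerance(self, nucleus: str) -> float:
        return {"CA": self.tol_ca, "CB": self.tol_cb, "CO": self.tol_co}[nucleus]


@dataclass
class ScoringConfig:
    scale_factor: float = 10.0
    restrict_to_expected_ss: bool = False
    # an observed CB mapped onto glycine is scored as this many sd
    gly_cb_penalty_sd: float = 10.0
    # amides are never placed on the first sequence position
    skip_first_residue: bool = True

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass(frozen=True)
class Fragment:
    """An ordered chain of connected spin systems (predecessor -> successor)."""

    system_ids: tuple[int, ...]
    match_level_used: int

    def __len__(self) -> int:
        return len(self.system_ids)


@dataclass
class FragmentBuild:
    groups: dict[tuple[int, int], list[Fragment]]  # (size, match level) -> fragments
    tol_ca: float
    tol_cb: float
    tol_co: float
    backoff_rounds: int = 0


def match_level(pred: SpinSystem, succ: SpinSystem, config: MatchConfig) -> int:
    """Number of CA/CB/CO shift pairs agreeing within tolerance (0..3).

    Both observations of a nucleus must exist to count.  The glycine rule:
    if neither side has a CB and the sequential CA lies in the glycine
    window, matching CA + CO is promoted to level 3.
    """
    matched = 0
    compared: set[str] = set()
    for nuc in NUCLEI:
        a = pred.internal.get(nuc)
        b = succ.sequential.get(nuc)
        if a is None or b is None:
            continue
        compared.add(nuc)
        if abs(a - b) <= config.tolerance(nuc):
            matched += 1
        else:
            # a shared nucleus that disagrees rules the link out: lower match
            # levels cover *missing* shifts, not conflicting ones
            return 0
    if matched == 2 and "CB" not in compared:
        ca = succ.sequential.get("CA", pred.internal.get("CA"))
        lo, hi = config.gly_ca_window
        if (pred.internal.get("CB") is None and succ.sequential.get("CB") is None
                and ca is not None and lo <= ca <= hi):
            return 3
    return matched


def _edges(systems: Sequence[SpinSystem], config: MatchConfig) -> dict[tuple[int, int], int]:
    """All connectable ordered pairs with their match level."""
    out: dict[tuple[int, int], int] = {}
    for pred in systems:
        for succ in systems:
            if pred.id == succ.id:
                continue
            lvl = match_level(pred, succ, config)
            if lvl >= 1:
                out[(pred.id, succ.id)] = lvl
    return out


class _CapOverflow(Exception):
    pass


def _paths_for_level(edge_lvls, system_ids, level, max_size,
                     cap: int) -> dict[int, list[tuple[int, ...]]]:
    """All directed simple paths of 2..max_size using edges of >= level.

    Aborts as soon as any size bucket exceeds ``cap`` (the caller then
    backs off the tolerances), so degenerate graphs cannot hang the DFS.
    """
    adj: dict[int, list[int]] = {sid: [] for sid in system_ids}
    for (a, b), lvl in edge_lvls.items():
        if lvl >= level:
            adj[a].append(b)
    for sid in adj:
        adj[sid].sort()
    by_size: dict[int, list[tuple[int, ...]]] = {k: [] for k in range(2, max_size + 1)}

    def extend(path: list[int], on_path: set[int]) -> None:
        if len(path) >= 2:
            bucket = by_size[len(path)]
            bucket.append(tuple(path))
            if len(bucket) > cap:
                raise _CapOverflow
        if len(path) == max_size:
            return
        for nxt in adj[path[-1]]:
            if nxt not in on_path:
                path.append(nxt)
                on_path.add(nxt)
                extend(path, on_path)
                on_path.remove(nxt)
                path.pop()

    for sid in sorted(system_ids):
        extend([sid], {sid})
    return by_size


def build_fragments(systems: Sequence[SpinSystem],
                    config: MatchConfig) -> FragmentBuild:
    """Enumerate fragments per (size, match level), with tolerance back-off.

    Whenever any group exceeds the fragment cap, all three tolerances are
    multiplied by the back-off factor and the whole build restarts.  A
    tolerance below the floor with the cap still exceeded raises, advising
    cleaner peak lists.
    """
    cfg = config
    rounds = 0
    while True:
        edge_lvls = _edges(systems, cfg)
        system_ids = [s.id for s in systems]
        groups: dict[tuple[int, int], list[Fragment]] = {}
        overflow = False
        for level in (3, 2, 1):
            if level < config.match_level:
                continue
            try:
                by_size = _paths_for_level(edge_lvls, system_ids, level,
                                           cfg.max_fragment_size,
                                           cfg.fragment_cap)
            except _CapOverflow:
                overflow = True
                break
            for size, paths in by_size.items():
                groups[(size, level)] = [Fragment(p, level) for p in paths]
        if not overflow:
            return FragmentBuild(groups, cfg.tol_ca, cfg.tol_cb, cfg.tol_co,
                                 backoff_rounds=rounds)
        new = replace(cfg,
                      tol_ca=cfg.tol_ca * cfg.backoff_factor,
                      tol_cb=cfg.tol_cb * cfg.backoff_factor,
                      tol_co=cfg.tol_co * cfg.backoff_factor)
        if min(new.tol_ca, new.tol_cb, new.tol_co) < cfg.tol_floor:
            raise RuntimeError(
                "fragment cap still exceeded at the tolerance floor; the peak "
                "lists are too degenerate — clean up overlapped peaks and rerun")
        cfg = new
        rounds += 1


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class Observation:
    """One observed 13C shift of a fragment, in placement coordinates.

    ``offset`` is relative to the first system's amide position: internal
    shifts of system m have offset m, sequential ones offset m-1.
    """

    offset: int
    nucleus: str
    value: float


def fragment_observations(fragment: Fragment,
                          systems_by_id: dict[int, SpinSystem]) -> list[Observation]:
    obs: list[Observation] = []
    for m, sid in enumerate(fragment.system_ids):
        sys_ = systems_by_id[sid]
        for nuc in NUCLEI:
            v = sys_.sequential.get(nuc)
            if v is not None:
                obs.append(Observation(m - 1, nuc, v))
            v = sys_.internal.get(nuc)
            if v is not None:
                obs.append(Observation(m, nuc, v))
    return obs


class SequenceArrays:
    """Consensus statistics laid out per sequence position for fast scoring.

    ``mean[pos_idx, ss_idx, nuc_idx]`` / ``sd[...]`` with NaN marking
    defined-missing entries (glycine CB).  In deuterated mode the isotope
    correction of the position's residue type is added to the mean, which
    is equivalent to correcting the observed shifts.
    """

    def __init__(self, sequence: ProteinSequence, tables: ShiftTables,
                 deuterated: bool = False):
        self.sequence = sequence
        L = len(sequence)
        self.mean = np.full((L, 3, 3), np.nan)
        self.sd = np.full((L, 3, 3), np.nan)
        for i, res in enumerate(sequence.residues):
            for si, ss in enumerate(SS_CLASSES):
                for ni, nuc in enumerate(NUCLEI):
                    ent = tables.consensus.lookup(res, ss, nuc)
                    if ent is None:
                        continue
                    mean, sd = ent
                    if deuterated:
                        mean += tables.isotope.correction(res, nuc)
                    self.mean[i, si, ni] = mean
                    self.sd[i, si, ni] = sd


def _score_arrays(obs: list[Observation], seqarr: SequenceArrays,
                  start_indices: np.ndarray, scoring: ScoringConfig):
    """Standardized squared deviations for all starts at once.

    Returns (terms[s, o, ss], included[s, o], offsets[o]).  Terms for
    defined-missing references (observed CB on glycine) carry the fixed
    penalty; observations probing positions before the sequence are
    excluded (mask False).
    """
    L = len(seqarr.sequence)
    off = np.array([o.offset for o in obs])
    nuc = np.array([NUCLEI.index(o.nucleus) for o in obs])
    val = np.array([o.value for o in obs])
    pos = start_indices[:, None] + off[None, :]          # (S, O)
    included = (pos >= 0) & (pos < L)
    safe_pos = np.clip(pos, 0, L - 1)
    mean = seqarr.mean[safe_pos, :, nuc[None, :]]        # (S, O, 3)
    sd = seqarr.sd[safe_pos, :, nuc[None, :]]
    with np.errstate(invalid="ignore"):
        terms = ((val[None, :, None] - mean) / sd) ** 2
    terms = np.where(np.isnan(mean), scoring.gly_cb_penalty_sd ** 2, terms)
    terms = np.where(included[:, :, None], terms, 0.0)
    return terms, included, off


def score_placement(obs: list[Observation], seqarr: SequenceArrays,
                    start_residue: int, ss_assignment: dict[int, SS],
                    scoring: ScoringConfig | None = None) -> tuple[float, int]:
    """Reduced chi2 of one placement under an explicit SS assignment.

    ``ss_assignment`` maps probed residue numbers to concrete SS classes.
    Returns (chi2, n_shifts); n_shifts == 0 raises (undefined score).
    """
    scoring = scoring or ScoringConfig()
    start_idx = start_residue - seqarr.sequence.offset
    terms, included, off = _score_arrays(obs, seqarr,
                                         np.array([start_idx]), scoring)
    total = 0.0
    n = 0
    for o in range(len(obs)):
        if not included[0, o]:
            continue
        res_number = start_residue + off[o]
        ss = ss_assignment[res_number]
        total += terms[0, o, SS_CLASSES.index(ss)]
        n += 1
    if n == 0:
        raise ValueError("placement compares no shifts; score undefined")
    return scoring.scale_factor * total / n, n


def best_ss_combination(obs: list[Observation], seqarr: SequenceArrays,
                        start_residue: int,
                        scoring: ScoringConfig | None = None,
                        expected_ss: Sequence[SS] | None = None,
                        ) -> tuple[dict[int, SS], float, int]:
    """Minimal-chi2 SS labeling of one placement, by per-residue minima.

    With ``scoring.restrict_to_expected_ss`` and an expected-SS list,
    residues with a known expected label are fixed to it.
    Returns (labels by residue number, chi2, n_shifts).
    """
    scoring = scoring or ScoringConfig()
    chi2, n, labels = _best_scores(obs, seqarr,
                                   np.array([start_residue - seqarr.sequence.offset]),
                                   scoring, expected_ss)
    if n[0] == 0:
        raise ValueError("placement compares no shifts; score undefined")
    out = {start_residue + o: ss for o, ss in labels[0].items()}
    return out, float(chi2[0]), int(n[0])


def _best_scores(obs, seqarr, start_indices, scoring, expected_ss):
    """Vectorized best-SS scoring for many candidate starts.

    Returns (chi2[s], n[s], labels[s] as {offset: SS}).
    """
    terms, included, off = _score_arrays(obs, seqarr, start_indices, scoring)
    S = len(start_indices)
    uniq_off = sorted(set(off.tolist()))
    chi2 = np.zeros(S)
    n = included.sum(axis=1)
    labels: list[dict[int, SS]] = [dict() for _ in range(S)]
    L = len(seqarr.sequence)
    for u in uniq_off:
        sel = off == u
        res_terms = terms[:, sel, :].sum(axis=1)         # (S, 3)
        has_any = included[:, sel].any(axis=1)
        pos = start_indices + u
        if expected_ss is not None and scoring.restrict_to_expected_ss:
            for s in range(S):
                if not has_any[s]:
                    continue
                p = pos[s]
                exp = expected_ss[p] if 0 <= p < L else SS.UNKNOWN
                if exp in (SS.HELIX, SS.STRAND, SS.COIL):
                    si = SS_CLASSES.index(exp)
                    chi2[s] += res_terms[s, si]
                    labels[s][u] = exp
                else:
                    si = int(np.argmin(res_terms[s]))
                    chi2[s] += res_terms[s, si]
                    labels[s][u] = SS_CLASSES[si]
        else:
            best = np.argmin(res_terms, axis=1)
            chi2 += np.where(has_any, res_terms[np.arange(S), best], 0.0)
            for s in range(S):
                if has_any[s]:
                    labels[s][u] = SS_CLASSES[int(best[s])]
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(n > 0, scoring.scale_factor * chi2 / np.maximum(n, 1), np.nan)
    return chi2, n, labels


@dataclass
class ScoredPlacement:
    fragment: Fragment
    start_residue: int
    ss_labels: dict[int, SS]     # probed residue number -> class at the minimum
    chi2: float
    n_shifts: int
    highlighted: bool = False
    result_index: str = ""

    @property
    def amide_residues(self) -> range:
        return range(self.start_residue, self.start_residue + len(self.fragment))


@dataclass
class ResultList:
    fragment: Fragment
    placements: list[ScoredPlacement] = field(default_factory=list)
    reason: str = ""


def _valid_starts(fragment_len: int, sequence: ProteinSequence,
                  scoring: ScoringConfig) -> list[int]:
    """Starts whose amide window avoids prolines and the first residue."""
    first = sequence.first + (1 if scoring.skip_first_residue else 0)
    out = []
    for s in range(first, sequence.last - fragment_len + 2):
        window = [sequence.residue(r) for r in range(s, s + fragment_len)]
        if "P" not in window:
            out.append(s)
    return out


def enumerate_placements(fragment: Fragment,
                         systems_by_id: dict[int, SpinSystem],
                         seqarr: SequenceArrays,
                         scoring: ScoringConfig | None = None,
                         expected_ss: Sequence[SS] | None = None,
                         frag_number: int = 1,
                         limit: int = RESULT_LIMIT) -> ResultList:
    """Score every valid placement; return the top ``limit`` by ascending chi2.

    Ties are broken by start residue; indices are stable across reruns.
    When an expected-SS list is given, placements whose optimal labels
    reproduce it over the probed window (unknown matches anything) are
    flagged highlighted.
    """
    scoring = scoring or ScoringConfig()
    seq = seqarr.sequence
    obs = fragment_observations(fragment, systems_by_id)
    starts = _valid_starts(len(fragment), seq, scoring)
    if not starts or not obs:
        return ResultList(fragment, [], reason="no valid placement")
    start_idx = np.array([s - seq.offset for s in starts])
    chi2, n, labels = _best_scores(obs, seqarr, start_idx, scoring, expected_ss)
    order = sorted(range(len(starts)),
                   key=lambda i: (float(chi2[i]) if n[i] > 0 else np.inf, starts[i]))
    placements = []
    for rank, i in enumerate(order[:limit], start=1):
        if n[i] == 0:
            continue
        ss_labels = {starts[i] + o: ss for o, ss in labels[i].items()}
        hl = False
        if expected_ss is not None:
            hl = all(
                expected_ss[r - seq.offset] in (SS.UNKNOWN, ss)
                for r, ss in ss_labels.items())
        placements.append(ScoredPlacement(
            fragment, starts[i], ss_labels, float(chi2[i]), int(n[i]), hl,
            result_index=f"S{len(fragment)}M{fragment.match_level_used}"
                         f"F{frag_number}R{rank}"))
    if not placements:
        return ResultList(fragment, [], reason="no scoreable placement")
    return ResultList(fragment, placements)


@dataclass
class AnalysisResult:
    groups: dict[tuple[int, int], list[ResultList]]
    build: FragmentBuild

    def all_lists(self) -> Iterable[tuple[tuple[int, int], ResultList]]:
        for key in sorted(self.groups, reverse=True):
            for rl in self.groups[key]:
                yield key, rl


def analyze_all(systems: Sequence[SpinSystem],
                sequence: ProteinSequence,
                tables: ShiftTables,
                match_config: MatchConfig | None = None,
                scoring: ScoringConfig | None = None,
                expected_ss: Sequence[SS] | None = None,
                deuterated: bool = False,
                out_dir: str | None = None) -> AnalysisResult:
    """Run the full connectivity + scoring analysis.

    Returns result lists per (fragment size, match level) and optionally
    writes one TSV per group (``results_s{size}_m{match}.tsv``).
    """
    if not systems:
        raise ValueError("no spin systems to analyze — run labeling first")
    match_config = match_config or MatchConfig()
    scoring = scoring or ScoringConfig()
    build = build_fragments(systems, match_config)
    seqarr = SequenceArrays(sequence, tables, deuterated=deuterated)
    by_id = {s.id: s for s in systems}
    groups: dict[tuple[int, int], list[ResultList]] = {}
    for key in sorted(build.groups, reverse=True):
        lists = []
        for fn, frag in enumerate(build.groups[key], start=1):
            lists.append(enumerate_placements(frag, by_id, seqarr, scoring,
                                              expected_ss, frag_number=fn))
        groups[key] = lists
    result = AnalysisResult(groups, build)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for (size, match), lists in groups.items():
            path = os.path.join(out_dir, result_file_name(size, match))
            with open(path, "w") as fh:
                fh.write(write_result_file(lists))
    return result


def result_file_name(size: int, match: int) -> str:
    return f"results_s{size}_m{match}.tsv"


_RESULT_COLUMNS = ("index", "systems", "start_residue", "chi2", "n_shifts",
                   "ss", "highlighted")


def write_result_file(lists: list[ResultList]) -> str:
    lines = ["\t".join(_RESULT_COLUMNS)]
    for rl in lists:
        for p in rl.placements:
            ss_str = "".join(SS_LETTER[p.ss_labels[r]]
                             for r in sorted(p.ss_labels))
            lines.append("\t".join([
                p.result_index,
                ",".join(str(i) for i in p.fragment.system_ids),
                str(p.start_residue),
                f"{p.chi2:.6f}",
                str(p.n_shifts),
                ss_str,
                "1" if p.highlighted else "0",
            ]))
    return "\n".join(lines) + "\n"


def parse_result_file(text: str) -> list[ScoredPlacement]:
    """Re-parse a result TSV into placements (fragment match level from index)."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines or lines[0].split("\t") != list(_RESULT_COLUMNS):
        raise ValueError("not a result file")
    out = []
    for line in lines[1:]:
        idx, systems, start, chi2, n, ss_str, hl = line.split("\t")
        sys_ids = tuple(int(x) for x in systems.split(","))
        match = int(idx.split("M")[1].split("F")[0])
        start = int(start)
        probed = sorted(range(start - 1, start + len(sys_ids)))[-len(ss_str):]
        labels = {r: LETTER_SS[c] for r, c in zip(probed, ss_str)}
        out.append(ScoredPlacement(Fragment(sys_ids, match), start, labels,
                                   float(chi2), int(n), hl == "1", idx))
    return out
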