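"""Stateful assignment engine: apply placements, track conflicts and
linkage, compute completeness, scan positions, support manual assignment
and shift editing, persist sessions, and export assigned peak lists.

The state is a bijection between residue numbers and spin-system ids.
Applying a placement is all-or-nothing: a residue occupied by a different
system, or a system already placed elsewhere, raises a ConflictError and
leaves the state untouched.  Re-applying an identical placement is a
no-op.

``auto_assign`` replaces the interactive approval loop: it traverses the
result lists from the largest fragment size and highest match level
downward and accepts a rank-1 placement only if its chi2 is below an
absolute threshold, the second-best placement is worse by at least the
ambiguity ratio (or the list has a single entry) and it creates no
conflict; passes repeat until nothing changes.  Shift edits do not touch
previously computed result lists but flow into the propensity profile and
the exported peak lists.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Sequence

from .connect import (AnalysisResult, MatchConfig, ScoringConfig, Fragment,
                      ScoredPlacement, SequenceArrays, best_ss_combination,
                      fragment_observations, match_level)
from .formats import (Experiment, PeakList, PeakName, ProteinSequence,
                      format_peak_name)
from .spin_label import SpinSystem

__all__ = [
    "AssignmentState",
    "AutoPolicy",
    "ConflictError",
    "apply_placement",
    "linkage_status",
    "completeness_stats",
    "scan_position",
    "manual_assign",
    "edit_shift",
    "save_session",
    "load_session",
    "auto_assign",
    "export_assigned",
    "statistics_report",
]

SESSION_VERSION = 1


class ConflictError(RuntimeError):
    """An assignment collides with the existing residue/system mapping."""


@dataclass
class AssignmentState:
    mapping: dict[int, int] = field(default_factory=dict)   # residue -> system id
    reverse: dict[int, int] = field(default_factory=dict)   # system id -> residue
    manual: set[int] = field(default_factory=set)           # residues assigned manually
    history: list[str] = field(default_factory=list)        # applied result indices
    edits: list[dict] = field(default_factory=list)         # shift-edit log

    def audit(self) -> None:
        """Verify the residue<->system bijection invariant."""
        if len(self.mapping) != len(self.reverse):
            raise AssertionError("mapping/reverse size mismatch")
        for res, sid in self.mapping.items():
            if self.reverse.get(sid) != res:
                raise AssertionError(f"bijection broken at residue {res}")

    def copy(self) -> "AssignmentState":
        return copy.deepcopy(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssignmentState):
            return NotImplemented
        return (self.mapping == other.mapping and self.manual == other.manual
                and self.history == other.history and self.edits == other.edits)


@dataclass
class AutoPolicy:
    chi2_accept: float = 50.0
    ambiguity_ratio: float = 2.0
    min_match: int = 1
    # forced deadlock resolution is only trusted for multi-nucleus chains
    min_force_match: int = 2
    # optional safety valve: disable forced resolution when the spin
    # systems' slot completeness falls below this fraction (the forcing
    # argument assumes the candidate pool covers all true alternatives;
    # orphan rescue during labeling normally keeps the pool complete
    # enough, so the gate is off by default)
    force_completeness_min: float = 0.0
    # reject placements scoring implausibly far below the calibrated
    # reduced-chi2 expectation (z standard-normal deviations; 0 disables)
    too_good_z: float = 3.09
    score_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.ambiguity_ratio <= 1:
            raise ValueError("ambiguity_ratio must exceed 1")

    def chi2_floor(self, n_shifts: int) -> float:
        """Lower plausibility bound for a correct placement's chi2.

        The consensus spreads calibrate a correct placement to a reduced
        chi2 of ~1 (times the score scale); the Wilson-Hilferty cube
        approximation gives the lower tail quantile of chi2_n / n.  A
        placement fitting the database far better than the database's
        own spread allows is a coincidental decoy, not a good match.
        """
        if self.too_good_z <= 0 or n_shifts <= 0:
            return 0.0
        h = 2.0 / (9.0 * n_shifts)
        cube = 1.0 - h - self.too_good_z * h ** 0.5
        if cube <= 0:
            return 0.0
        return self.score_scale * cube ** 3


def apply_placement(state: AssignmentState, placement: ScoredPlacement,
                    manual: bool = False) -> AssignmentState:
    """Extend the mapping with one placement (mutates and returns state).

    Raises ConflictError, reporting the clashing residue/system pairs,
    without changing the state.
    """
    pairs = list(zip(placement.amide_residues, placement.fragment.system_ids))
    if len(set(placement.fragment.system_ids)) != len(pairs):
        raise ConflictError("placement repeats a spin system")
    clashes = []
    for res, sid in pairs:
        cur = state.mapping.get(res)
        if cur is not None and cur != sid:
            clashes.append(f"residue {res} already holds system {cur} "
                           f"(placement wants {sid})")
        prev_res = state.reverse.get(sid)
        if prev_res is not None and prev_res != res:
            clashes.append(f"system {sid} already assigned to residue {prev_res} "
                           f"(placement wants {res})")
    if clashes:
        raise ConflictError("; ".join(clashes))
    changed = False
    for res, sid in pairs:
        if state.mapping.get(res) != sid:
            state.mapping[res] = sid
            state.reverse[sid] = res
            if manual:
                state.manual.add(res)
            changed = True
    if changed and placement.result_index:
        state.history.append(placement.result_index)
    state.audit()
    return state


def linkage_status(state: AssignmentState, systems: Sequence[SpinSystem],
                   match_config: MatchConfig | None = None) -> dict[int, bool]:
    """Per assigned residue: linked (True) iff its system matches an
    assigned sequential neighbor at match level >= 1."""
    cfg = match_config or MatchConfig()
    by_id = {s.id: s for s in systems}
    linked: dict[int, bool] = {}
    for res, sid in state.mapping.items():
        ok = False
        sys_ = by_id[sid]
        prev_sid = state.mapping.get(res - 1)
        if prev_sid is not None and match_level(by_id[prev_sid], sys_, cfg) >= 1:
            ok = True
        next_sid = state.mapping.get(res + 1)
        if not ok and next_sid is not None \
                and match_level(sys_, by_id[next_sid], cfg) >= 1:
            ok = True
        linked[res] = ok
    return linked


def completeness_stats(state: AssignmentState,
                       peak_lists: dict[Experiment, PeakList],
                       sequence: ProteinSequence,
                       systems: Sequence[SpinSystem],
                       nh_denominator: str = "all") -> tuple[float, float]:
    """(peaks %, NH %) completeness.

    peaks % — fraction of peaks in the submitted lists belonging to an
    assigned spin system.  NH % — assigned amides over either all residues
    (default, tag-inclusive convention) or only amide-bearing residues
    (excluding prolines and the N-terminal residue).
    """
    total = sum(len(pl) for pl in peak_lists.values())
    assigned_sids = set(state.reverse)
    assigned_peaks = sum(
        1 for s in systems if s.id in assigned_sids for _ in s.source_peaks)
    peaks_pct = 100.0 * assigned_peaks / total if total else 0.0
    if nh_denominator == "all":
        denom = len(sequence)
    elif nh_denominator == "amide-bearing":
        denom = sum(1 for r in sequence.numbers()
                    if sequence.residue(r) != "P" and r != sequence.first)
    else:
        raise ValueError("nh_denominator must be 'all' or 'amide-bearing'")
    nh_pct = 100.0 * len(state.mapping) / denom if denom else 0.0
    return peaks_pct, nh_pct


def scan_position(residue: int, analysis: AnalysisResult,
                  state: AssignmentState, sequence: ProteinSequence,
                  mode: str = "all") -> list[ScoredPlacement]:
    """All placements whose probed window covers ``residue``, by chi2.

    ``mode='unassigned_only'`` keeps only placements that could still be
    applied: the queried residue unassigned and no conflict with the
    current state.
    """
    if not sequence.first <= residue <= sequence.last:
        raise ValueError(f"residue {residue} outside the sequence")
    out = []
    for _, rl in analysis.all_lists():
        for p in rl.placements:
            lo = p.start_residue - 1
            hi = p.start_residue + len(p.fragment) - 1
            if not lo <= residue <= hi:
                continue
            if mode == "unassigned_only":
                if residue in state.mapping:
                    continue
                if _conflicts(state, p):
                    continue
            out.append(p)
    out.sort(key=lambda p: (p.chi2, p.start_residue))
    return out


def _conflicts(state: AssignmentState, p: ScoredPlacement) -> bool:
    for res, sid in zip(p.amide_residues, p.fragment.system_ids):
        cur = state.mapping.get(res)
        if cur is not None and cur != sid:
            return True
        prev = state.reverse.get(sid)
        if prev is not None and prev != res:
            return True
    return False


def _is_noop(state: AssignmentState, p: ScoredPlacement) -> bool:
    return all(state.mapping.get(res) == sid
               for res, sid in zip(p.amide_residues, p.fragment.system_ids))


def manual_assign(state: AssignmentState, system: SpinSystem, residue: int,
                  seqarr: SequenceArrays,
                  scoring: ScoringConfig | None = None,
                  ) -> tuple[AssignmentState, float]:
    """Assign one spin system to one residue; report the chi2 of the
    corresponding single-system placement for comparison."""
    seq = seqarr.sequence
    if seq.residue(residue) == "P":
        raise ConflictError(f"residue {residue} is a proline and bears no amide")
    frag = Fragment((system.id,), 0)
    obs = fragment_observations(frag, {system.id: system})
    labels, chi2, n = best_ss_combination(obs, seqarr, residue, scoring)
    placement = ScoredPlacement(frag, residue, labels, chi2, n,
                                result_index=f"manual:{system.id}@{residue}")
    apply_placement(state, placement, manual=True)
    return state, chi2


def edit_shift(state: AssignmentState, systems: Sequence[SpinSystem],
               system_id: int, nucleus: str, slot: str,
               value: float | None) -> None:
    """Change, add or delete (value=None) a 13C shift of a spin system.

    The edit is logged in the state; already-computed result lists are
    deliberately left untouched, while exports and the propensity profile
    see the new value.
    """
    if slot not in ("internal", "sequential"):
        raise ValueError("slot must be 'internal' or 'sequential'")
    if nucleus not in ("CA", "CB", "CO"):
        raise ValueError("nucleus must be CA, CB or CO")
    by_id = {s.id: s for s in systems}
    if system_id not in by_id:
        raise KeyError(f"unknown spin system {system_id}")
    target = getattr(by_id[system_id], slot)
    old = target.get(nucleus)
    if value is None:
        target.pop(nucleus, None)
    else:
        target[nucleus] = value
    state.edits.append({"system": system_id, "nucleus": nucleus, "slot": slot,
                        "old": old, "new": value})


def save_session(state: AssignmentState, path: str) -> None:
    """Persist the state as a versioned, human-diffable JSON document."""
    doc = {
        "version": SESSION_VERSION,
        "mapping": {str(k): v for k, v in sorted(state.mapping.items())},
        "manual": sorted(state.manual),
        "history": state.history,
        "edits": state.edits,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_session(path: str) -> AssignmentState:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise FileNotFoundError(f"no session file at {path}") from None
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt session file {path}: {e}") from None
    if doc.get("version") != SESSION_VERSION:
        raise ValueError(f"unsupported session version {doc.get('version')!r}")
    state = AssignmentState(
        mapping={int(k): v for k, v in doc["mapping"].items()},
        manual=set(doc["manual"]),
        history=list(doc["history"]),
        edits=list(doc["edits"]),
    )
    state.reverse = {v: k for k, v in state.mapping.items()}
    state.audit()
    return state


def _pairs(p: ScoredPlacement) -> tuple[tuple[int, int], ...]:
    return tuple(zip(p.amide_residues, p.fragment.system_ids))


def _mutually_conflicting(a: ScoredPlacement, b: ScoredPlacement) -> bool:
    """Two placements disagree on some residue or some spin system."""
    return _maps_conflict(_placement_maps(a), _placement_maps(b))


def _placement_maps(p: ScoredPlacement) -> tuple[dict[int, int], dict[int, int]]:
    pairs = _pairs(p)
    return dict(pairs), {sid: res for res, sid in pairs}


def _maps_conflict(am: tuple[dict, dict], bm: tuple[dict, dict]) -> bool:
    amap, arev = am
    bmap, _ = bm
    for res, sid in bmap.items():
        if amap.get(res, sid) != sid or arev.get(sid, res) != res:
            return True
    return False


def auto_assign(analysis: AnalysisResult, state: AssignmentState,
                policy: AutoPolicy | None = None,
                systems: Sequence[SpinSystem] | None = None,
                ) -> tuple[AssignmentState, list[str]]:
    """Batch surrogate for interactive approval.

    Candidates are the rank-1 placements of every result list (match
    level >= min_match) that clear the absolute chi2 threshold and are
    unambiguous within their own list (second-best/best >= ambiguity
    ratio, or a single entry).  They are then accepted in ascending chi2
    order — the score is the reliability indicator — under a global
    consistency rule: a candidate is deferred while any *other* live
    candidate of comparable quality (chi2 below candidate chi2 times the
    ambiguity ratio) claims one of its residues or systems differently.
    This blocks chimeric fragments produced by coincidental matches: the
    true sub-chain placements contest the same residues, and with no
    clear score winner neither side is auto-assigned (an omission, never
    a commission).  Passes repeat until stable.
    """
    policy = policy or AutoPolicy()
    log: list[str] = []
    candidates: list[ScoredPlacement] = []
    for (size, match), rl in analysis.all_lists():
        if match < policy.min_match or not rl.placements:
            continue
        best = rl.placements[0]
        if best.chi2 > policy.chi2_accept:
            continue
        if best.chi2 < policy.chi2_floor(best.n_shifts):
            log.append(f"{best.result_index} implausibly low chi2 "
                       f"({best.chi2:.2f} < {policy.chi2_floor(best.n_shifts):.2f})")
            continue
        if len(rl.placements) > 1:
            second = rl.placements[1].chi2
            if best.chi2 == 0:
                if second == 0:
                    log.append(f"{best.result_index} ambiguous (tied at zero)")
                    continue
            elif second / best.chi2 < policy.ambiguity_ratio:
                log.append(f"{best.result_index} ambiguous within list "
                           f"(ratio {second / best.chi2:.2f})")
                continue
        candidates.append(best)
    candidates.sort(key=lambda p: (p.chi2, p.start_residue,
                                   -p.fragment.match_level_used,
                                   p.result_index))
    # deduplicate placements identical in substance across result lists,
    # keeping the highest-match instance
    seen: set[tuple] = set()
    unique: list[ScoredPlacement] = []
    for c in candidates:
        key = (c.fragment.system_ids, c.start_residue)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    candidates = unique
    maps = {id(c): _placement_maps(c) for c in candidates}
    by_res: dict[int, list[ScoredPlacement]] = {}
    by_sid: dict[int, list[ScoredPlacement]] = {}
    for c in candidates:
        for res, sid in maps[id(c)][0].items():
            by_res.setdefault(res, []).append(c)
            by_sid.setdefault(sid, []).append(c)

    dead: set[int] = set()

    def rivals_of(c: ScoredPlacement) -> list[ScoredPlacement]:
        cm = maps[id(c)]
        out = []
        seen_ids = {id(c)}
        for res in cm[0]:
            for d in by_res.get(res, []):
                if id(d) not in seen_ids and id(d) not in dead:
                    seen_ids.add(id(d))
                    if d.chi2 < c.chi2 * policy.ambiguity_ratio \
                            and _maps_conflict(cm, maps[id(d)]):
                        out.append(d)
        for sid in cm[1]:
            for d in by_sid.get(sid, []):
                if id(d) not in seen_ids and id(d) not in dead:
                    seen_ids.add(id(d))
                    if d.chi2 < c.chi2 * policy.ambiguity_ratio \
                            and _maps_conflict(cm, maps[id(d)]):
                        out.append(d)
        return out

    npass = 0
    while True:
        npass += 1
        accepted_any = False
        for c in candidates:
            if id(c) in dead:
                continue
            if _is_noop(state, c):
                dead.add(id(c))
                continue
            if _conflicts(state, c):
                dead.add(id(c))
                log.append(f"pass {npass}: {c.result_index} conflicts with "
                           f"current state")
                continue
            if rivals_of(c):
                continue
            apply_placement(state, c)
            dead.add(id(c))
            log.append(f"pass {npass}: accepted {c.result_index} "
                       f"start={c.start_residue} chi2={c.chi2:.3f}")
            accepted_any = True
        if accepted_any:
            continue
        live = [c for c in candidates if id(c) not in dead]
        if live and _forcing_allowed(systems, policy) \
                and _break_deadlock(live, maps, state, policy, rivals_of,
                                    npass, log):
            continue
        break
    return state, log


def _forcing_allowed(systems: Sequence[SpinSystem] | None,
                     policy: AutoPolicy) -> bool:
    if systems is None:
        return True
    filled = sum(len(s.internal) + len(s.sequential) for s in systems)
    expected = 6 * len(systems)
    return expected > 0 and filled / expected >= policy.force_completeness_min


def _break_deadlock(live, maps, state, policy, rivals_of, npass, log) -> bool:
    """Resolve a mutual-deferral standoff by coverage parsimony.

    Near-identical spin systems ("twins") can each fit the same residue;
    score comparisons then defer the chimeric and the true placements
    forever.  Globally, however, every residue and system claimed by any
    live candidate must remain claimable: accepting a chimera consumes
    the twin systems and leaves their true residues with no remaining
    claimant.  A candidate is forced when accepting it orphans nothing
    while accepting any of its rivals would orphan some residue or
    system.  Accepts at most one candidate per call.
    """
    all_res: set[int] = set()
    all_sid: set[int] = set()
    for d in live:
        dm = maps[id(d)]
        all_res.update(dm[0])
        all_sid.update(dm[1])

    def orphans(c) -> int:
        cm = maps[id(c)]
        res_cov: set[int] = set(cm[0])
        sid_cov: set[int] = set(cm[1])
        for d in live:
            if d is c or not _maps_conflict(cm, maps[id(d)]):
                dm = maps[id(d)]
                res_cov.update(dm[0])
                sid_cov.update(dm[1])
        return len(all_res - res_cov) + len(all_sid - sid_cov)

    cache: dict[int, int] = {}

    def orphans_cached(c) -> int:
        if id(c) not in cache:
            cache[id(c)] = orphans(c)
        return cache[id(c)]

    for c in live:
        if c.fragment.match_level_used < policy.min_force_match:
            continue
        if orphans_cached(c) != 0:
            continue
        rivals = rivals_of(c)
        if rivals and all(orphans_cached(d) > 0 for d in rivals):
            apply_placement(state, c)
            log.append(f"pass {npass}: forced {c.result_index} "
                       f"start={c.start_residue} chi2={c.chi2:.3f} "
                       f"(rival placements would orphan coverage)")
            return True
    return False


def export_assigned(state: AssignmentState,
                    peak_lists: dict[Experiment, PeakList],
                    systems: Sequence[SpinSystem],
                    sequence: ProteinSequence) -> dict[Experiment, PeakList]:
    """Rename every peak of an assigned spin system per the name grammar;
    all other peaks keep the unassigned name."""
    ref_to_name: dict[tuple[Experiment, int], str] = {}
    for s in systems:
        res = state.reverse.get(s.id)
        if res is None:
            continue
        res_letter = sequence.residue(res)
        for (exp, row), (nuc, slot) in s.source_peaks.items():
            if slot == "amide":
                pn = PeakName(res_letter, res)
            elif slot == "internal":
                pn = PeakName(res_letter, res, nuc, False)
            else:
                prev_num = res - 1
                try:
                    prev_letter = sequence.residue(prev_num)
                except IndexError:
                    continue
                pn = PeakName(res_letter, res, nuc, True, (prev_letter, prev_num))
            ref_to_name[(exp, row)] = format_peak_name(pn)
    out: dict[Experiment, PeakList] = {}
    for exp, plist in peak_lists.items():
        new = PeakList(experiment=exp, has_ca_in_hncb=plist.has_ca_in_hncb,
                       header=plist.header)
        for p in plist.peaks:
            q = copy.copy(p)
            q.name = ref_to_name.get((exp, p.row), q.name)
            new.peaks.append(q)
        out[exp] = new
    return out


def statistics_report(state: AssignmentState,
                      peak_lists: dict[Experiment, PeakList],
                      sequence: ProteinSequence,
                      systems: Sequence[SpinSystem],
                      match_config: MatchConfig | None = None) -> str:
    """Text block mirroring the interactive statistics display."""
    peaks_pct, nh_pct = completeness_stats(state, peak_lists, sequence, systems)
    linked = linkage_status(state, systems, match_config)
    n_linked = sum(1 for v in linked.values() if v)
    total_peaks = sum(len(pl) for pl in peak_lists.values())
    lines = [
        f"assigned residues: {len(state.mapping)}/{len(sequence)}",
        f"assigned peaks: {peaks_pct:.1f}%" if total_peaks
        else "assigned peaks: n/a (no peak lists loaded)",
        f"assigned amide groups: {nh_pct:.1f}%",
        f"linked residues (green): {n_linked}",
        f"unlinked residues (yellow): {len(linked) - n_linked}",
        f"manual assignments: {len(state.manual)}",
    ]
    return "\n".join(lines)
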