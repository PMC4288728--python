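"""Group picked peaks into amide-rooted spin systems.

A spin system collects every resonance scalar-coupled to one backbone
amide: N(i), HN(i), the internal carbons CA/CB/CO of residue i and the
sequential carbons CA/CB/CO of residue i-1.  Two peaks belong to the same
system when their 15N and 1HN coordinates agree within user tolerances.

Reference modes decide which amide roots exist: the HSQC list, the
HNCO(i-1) list, their union, or single-linkage clustering over all lists.
Triple-resonance peaks are then attached to the nearest root (normalized
distance ``|dN|/dev_N + |dHN|/dev_HN``) that lies within both tolerances;
peaks with no root in range become warnings.

Within each system, rows from (i)(i-1) lists that match a row of the
companion (i-1) list within ``dev_C`` are classified sequential (keeping
the (i)(i-1) ppm value), the rest internal.  Where no companion row
exists and two candidates compete for one nucleus, the stronger absolute
intensity is taken as internal — internal transfers dominate in
HNCA/HNCACB-type experiments (invertible by config).  HNCB rows may carry
CA correlations; the sign of the intensity routes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .formats import Experiment, EXPERIMENT_ORDER, Peak, PeakList, NUCLEI

__all__ = [
    "ReferenceMode",
    "LabelConfig",
    "SpinSystem",
    "LabelWarning",
    "LabelReport",
    "build_spin_systems",
    "label_summary",
]

PeakRef = tuple[Experiment, int]  # (list type, data-row index)


class ReferenceMode(str, Enum):
    HSQC = "HSQC"
    HNCO_i1 = "HNCO_i1"
    HSQC_or_HNCO = "HSQC_or_HNCO"
    ALL_LISTS = "all_lists"


@dataclass
class LabelConfig:
    dev_n: float = 0.15
    dev_hn: float = 0.02
    dev_c: float = 0.05
    reference_mode: ReferenceMode = ReferenceMode.HSQC_or_HNCO
    hncb_negative: str = "CB"     # which of CA/CB has negative HNCB intensity
    stronger_is_internal: bool = True
    # cluster unattachable peaks into extra spin systems (>= 2 peaks per
    # cluster) instead of leaving all of them as warnings; recovers amides
    # whose reference peaks were not picked
    rescue_orphans: bool = True

    def __post_init__(self) -> None:
        if min(self.dev_n, self.dev_hn, self.dev_c) <= 0:
            raise ValueError("tolerances must be positive")
        if self.hncb_negative not in ("CA", "CB"):
            raise ValueError("hncb_negative must be 'CA' or 'CB'")


@dataclass
class SpinSystem:
    """All resonances coupled to one amide."""

    id: int
    n: float
    hn: float
    internal: dict[str, float] = field(default_factory=dict)    # nucleus -> ppm
    sequential: dict[str, float] = field(default_factory=dict)  # nucleus -> ppm
    source_peaks: dict[PeakRef, tuple[str, str]] = field(default_factory=dict)
    # peak ref -> (nucleus or 'N', slot: 'internal'/'sequential'/'amide')

    def shift(self, nucleus: str, slot: str) -> float | None:
        d = self.internal if slot == "internal" else self.sequential
        return d.get(nucleus)


@dataclass
class LabelWarning:
    peak_ref: PeakRef
    peak: Peak
    reason: str


@dataclass
class LabelReport:
    warnings: list[LabelWarning] = field(default_factory=list)
    systems_built: int = 0
    peaks_attached: int = 0


def _norm_dist(peak: Peak, root_n: float, root_hn: float, cfg: LabelConfig) -> float:
    return abs(peak.w_n - root_n) / cfg.dev_n + abs(peak.w_hn - root_hn) / cfg.dev_hn


def _within(peak: Peak, root_n: float, root_hn: float, cfg: LabelConfig) -> bool:
    return (abs(peak.w_n - root_n) <= cfg.dev_n
            and abs(peak.w_hn - root_hn) <= cfg.dev_hn)


def build_spin_systems(
    peak_lists: dict[Experiment, PeakList],
    config: LabelConfig | None = None,
) -> tuple[list[SpinSystem], LabelReport]:
    """Build spin systems from the submitted peak lists.

    Every input peak ends up in exactly one system or in the warning list
    (partition property).  Deterministic given input order: lists are
    processed in a fixed experiment order and rows in file order.
    """
    cfg = config or LabelConfig()
    report = LabelReport()

    roots = _collect_roots(peak_lists, cfg, report)
    if not roots:
        raise ValueError(f"no reference peaks available for mode "
                         f"{cfg.reference_mode.value}")
    systems = [SpinSystem(id=i + 1, n=n, hn=hn) for i, (n, hn, src) in enumerate(roots)]
    attached: dict[int, list[tuple[Experiment, Peak]]] = {s.id: [] for s in systems}
    for sys_, (_, _, src) in zip(systems, roots):
        for exp, row in sorted(src, key=lambda r: (EXPERIMENT_ORDER.index(r[0]), r[1])):
            peak = peak_lists[exp].peaks[row]
            if exp is Experiment.HSQC:
                sys_.source_peaks[(exp, row)] = ("N", "amide")
                report.peaks_attached += 1
            else:
                # a triple-resonance root row still carries a 13C correlation
                attached[sys_.id].append((exp, peak))

    # attach remaining peaks to the nearest in-tolerance root
    root_refs = _root_refs(roots)
    for exp in EXPERIMENT_ORDER:
        if exp not in peak_lists:
            continue
        for peak in peak_lists[exp].peaks:
            ref = (exp, peak.row)
            if ref in root_refs:
                continue
            best = None
            for s in systems:
                if _within(peak, s.n, s.hn, cfg):
                    d = _norm_dist(peak, s.n, s.hn, cfg)
                    if best is None or d < best[0]:
                        best = (d, s)
            if best is None:
                report.warnings.append(LabelWarning(
                    ref, peak, "no spin-system root within tolerance"))
            elif exp is Experiment.HSQC:
                best[1].source_peaks[ref] = ("N", "amide")
                report.peaks_attached += 1
            else:
                attached[best[1].id].append((exp, peak))

    if cfg.rescue_orphans and report.warnings:
        _rescue_orphans(systems, attached, peak_lists, cfg, report)

    by_id = {s.id: s for s in systems}
    thresholds = _intensity_thresholds(peak_lists)
    for sid, items in attached.items():
        _resolve_system(by_id[sid], items, peak_lists, cfg, report, thresholds)

    report.systems_built = len(systems)
    return systems, report


def _rescue_orphans(systems, attached, peak_lists, cfg: LabelConfig,
                    report: LabelReport) -> None:
    """Cluster unattachable peaks into additional spin systems.

    Peaks beyond tolerance of every reference root are grouped among
    themselves (deterministic nearest-cluster linkage in input order); a
    cluster of at least two peaks is a credible unreferenced amide and
    becomes a new system rooted at the cluster's mean coordinates.
    Singleton clusters stay warnings.
    """
    orphan_warnings = [w for w in report.warnings
                       if w.reason == "no spin-system root within tolerance"]
    clusters: list[list[LabelWarning]] = []
    for w in orphan_warnings:
        best = None
        for i, members in enumerate(clusters):
            n0 = sum(m.peak.w_n for m in members) / len(members)
            hn0 = sum(m.peak.w_hn for m in members) / len(members)
            if abs(w.peak.w_n - n0) <= cfg.dev_n \
                    and abs(w.peak.w_hn - hn0) <= cfg.dev_hn:
                d = abs(w.peak.w_n - n0) / cfg.dev_n \
                    + abs(w.peak.w_hn - hn0) / cfg.dev_hn
                if best is None or d < best[0]:
                    best = (d, i)
        if best is None:
            clusters.append([w])
        else:
            clusters[best[1]].append(w)
    rescued: set[tuple] = set()
    next_id = max((s.id for s in systems), default=0) + 1
    for members in clusters:
        if len(members) < 2:
            continue
        n = sum(m.peak.w_n for m in members) / len(members)
        hn = sum(m.peak.w_hn for m in members) / len(members)
        sys_ = SpinSystem(id=next_id, n=n, hn=hn)
        next_id += 1
        systems.append(sys_)
        attached[sys_.id] = []
        for m in members:
            exp = m.peak_ref[0]
            if exp is Experiment.HSQC:
                sys_.source_peaks[m.peak_ref] = ("N", "amide")
                report.peaks_attached += 1
            else:
                attached[sys_.id].append((exp, m.peak))
            rescued.add(m.peak_ref)
    report.warnings = [w for w in report.warnings
                       if w.peak_ref not in rescued]


def _root_refs(roots) -> set[PeakRef]:
    out = set()
    for _, _, src in roots:
        out.update(src)
    return out


def _collect_roots(peak_lists, cfg: LabelConfig, report: LabelReport):
    """Return [(n, hn, {peak refs})] reference amides for the chosen mode."""
    mode = cfg.reference_mode
    roots: list[tuple[float, float, set[PeakRef]]] = []

    def add_list(exp: Experiment, merge: bool) -> None:
        plist = peak_lists.get(exp)
        if plist is None:
            return
        for peak in plist.peaks:
            ref = (exp, peak.row)
            if merge:
                best = None
                for i, (n, hn, _) in enumerate(roots):
                    if (abs(peak.w_n - n) <= cfg.dev_n
                            and abs(peak.w_hn - hn) <= cfg.dev_hn):
                        d = abs(peak.w_n - n) / cfg.dev_n + abs(peak.w_hn - hn) / cfg.dev_hn
                        if best is None or d < best[0]:
                            best = (d, i)
                if best is not None:
                    roots[best[1]][2].add(ref)
                    continue
            roots.append((peak.w_n, peak.w_hn, {ref}))

    if mode is ReferenceMode.HSQC:
        add_list(Experiment.HSQC, merge=False)
    elif mode is ReferenceMode.HNCO_i1:
        add_list(Experiment.HNCO_i1, merge=False)
    elif mode is ReferenceMode.HSQC_or_HNCO:
        add_list(Experiment.HSQC, merge=False)
        add_list(Experiment.HNCO_i1, merge=True)
    else:  # ALL_LISTS: single-linkage clustering in fixed order
        for exp in EXPERIMENT_ORDER:
            add_list(exp, merge=True)
    return roots


def _hncb_nucleus(peak: Peak, plist: PeakList, cfg: LabelConfig) -> str:
    if not plist.has_ca_in_hncb:
        return "CB"
    if peak.intensity is None:
        return "CB"
    neg = peak.intensity < 0
    return cfg.hncb_negative if neg else ("CA" if cfg.hncb_negative == "CB" else "CB")


_COMPANION = {
    Experiment.HNCA_ii1: Experiment.HNCA_i1,
    Experiment.HNCB_ii1: Experiment.HNCB_i1,
    Experiment.HNCO_ii1: Experiment.HNCO_i1,
}


def _intensity_thresholds(peak_lists) -> dict[Experiment, float | None]:
    """Per (i)(i-1) list: the geometric mean of absolute intensities.

    These lists mix internal and sequential rows in roughly equal numbers,
    so in log space the geometric mean sits midway between the two
    intensity populations and separates them; it classifies rows whose
    internal/sequential identity cannot be resolved by shift matching.
    """
    import math
    out: dict[Experiment, float | None] = {}
    for exp, plist in peak_lists.items():
        vals = [abs(p.intensity) for p in plist.peaks
                if p.intensity not in (None, 0)]
        out[exp] = math.exp(sum(math.log(v) for v in vals) / len(vals)) \
            if vals else None
    return out


def _resolve_system(system: SpinSystem, items, peak_lists, cfg: LabelConfig,
                    report: LabelReport,
                    thresholds: dict[Experiment, float | None]) -> None:
    """Fill internal/sequential carbon slots from the peaks attached to one root."""
    # bucket candidate peaks by nucleus
    seq_only: dict[str, list[tuple[Experiment, Peak]]] = {n: [] for n in NUCLEI}
    both: dict[str, list[tuple[Experiment, Peak]]] = {n: [] for n in NUCLEI}
    for exp, peak in items:
        if exp in (Experiment.HNCB_ii1, Experiment.HNCB_i1):
            nuc = _hncb_nucleus(peak, peak_lists[exp], cfg)
        else:
            nuc = exp.nucleus
        (seq_only if exp.sequential_only else both)[nuc].append((exp, peak))

    def set_slot(nuc: str, slot: str, exp: Experiment, peak: Peak,
                 extra_refs: list[tuple[Experiment, Peak]] = ()) -> bool:
        target = system.sequential if slot == "sequential" else system.internal
        if nuc in target:
            return False
        target[nuc] = peak.w_c
        system.source_peaks[(exp, peak.row)] = (nuc, slot)
        report.peaks_attached += 1
        for xexp, xpeak in extra_refs:
            system.source_peaks[(xexp, xpeak.row)] = (nuc, slot)
            report.peaks_attached += 1
        return True

    for nuc in NUCLEI:
        companions = list(seq_only[nuc])
        candidates = list(both[nuc])
        matched_companions: set[int] = set()
        # sequential/internal: (exp, value peak, companion refs riding along)
        sequential: list[tuple[Experiment, Peak, list]] = []
        internal: list[tuple[Experiment, Peak, list]] = []
        # match (i)(i-1) rows against companion (i-1) rows, globally by
        # ascending distance so a sequential row close to both cannot be
        # stolen by the internal row.  When two candidates both lie within
        # tolerance of one companion the shifts alone cannot orient the
        # pair (internal and sequential values coincide within noise);
        # there the peak intensities decide, internal transfers being the
        # stronger.  The (i)(i-1) ppm value is kept, the companion rides
        # along.
        matched_candidates: dict[int, int] = {}
        for j, (cexp, cpeak) in enumerate(companions):
            in_range = [ci for ci, (exp, peak) in enumerate(candidates)
                        if ci not in matched_candidates
                        and abs(peak.w_c - cpeak.w_c) <= cfg.dev_c]
            if not in_range:
                continue
            if len(in_range) >= 2:
                def strength(ci):
                    inten = candidates[ci][1].intensity
                    return abs(inten) if inten is not None else 0.0
                ordered = sorted(in_range, key=strength)
                ci = ordered[0] if cfg.stronger_is_internal else ordered[-1]
            else:
                ci = in_range[0]
                if len(candidates) == 1:
                    # the sibling (i)(i-1) row is missing: a strong lone row
                    # is the internal one whose value merely coincides with
                    # the sequential; leave the companion to carry the
                    # sequential slot itself
                    c_exp, c_peak = candidates[ci]
                    thr = thresholds.get(c_exp)
                    if (thr is not None and c_peak.intensity is not None
                            and (abs(c_peak.intensity) >= thr)
                            == cfg.stronger_is_internal):
                        continue
            matched_candidates[ci] = j
            matched_companions.add(j)
        for ci, (exp, peak) in enumerate(candidates):
            if ci in matched_candidates:
                sequential.append((exp, peak, [companions[matched_candidates[ci]]]))
            else:
                internal.append((exp, peak, []))
        # unmatched companion rows carry sequential information themselves
        for j, (cexp, cpeak) in enumerate(companions):
            if j not in matched_companions:
                sequential.append((cexp, cpeak, []))
        # intensity fallback: two unmatched (i)(i-1) candidates for one nucleus
        if len(internal) == 2 and not sequential:
            a, b = internal
            ia = abs(a[1].intensity) if a[1].intensity is not None else 0.0
            ib = abs(b[1].intensity) if b[1].intensity is not None else 0.0
            strong, weak = (a, b) if ia >= ib else (b, a)
            if not cfg.stronger_is_internal:
                strong, weak = weak, strong
            internal = [strong]
            sequential = [weak]
        elif len(internal) == 1 and not sequential:
            # a lone unmatched (i)(i-1) row may equally be a sequential row
            # whose companion peak was not picked; when the companion list
            # was submitted at all, classify the row against the list-wide
            # intensity threshold
            exp, peak, extras = internal[0]
            companion_exp = _COMPANION.get(exp)
            thr = thresholds.get(exp)
            if (companion_exp in peak_lists and peak.intensity is not None
                    and thr is not None):
                weak_side = abs(peak.intensity) < thr
                if weak_side == cfg.stronger_is_internal:
                    internal = []
                    sequential = [(exp, peak, extras)]

        if len(internal) > 2 or len(sequential) > 2:
            for exp, peak, _ in internal + sequential:
                report.warnings.append(LabelWarning(
                    (exp, peak.row), peak,
                    f"more than two unresolved {nuc} candidates"))
            continue
        for slot, bucket in (("sequential", sequential), ("internal", internal)):
            for exp, peak, extras in bucket:
                if not set_slot(nuc, slot, exp, peak, extras):
                    for xexp, xpeak in [(exp, peak)] + list(extras):
                        report.warnings.append(LabelWarning(
                            (xexp, xpeak.row), xpeak,
                            f"duplicate {slot} {nuc} value"))


def label_summary(systems: list[SpinSystem], report: LabelReport) -> str:
    """Human-readable labeling summary with stable ordering."""
    lines = [f"spin systems built: {report.systems_built}",
             f"peaks attached: {report.peaks_attached}",
             f"warnings: {len(report.warnings)}"]
    for slot in ("internal", "sequential"):
        for nuc in NUCLEI:
            count = sum(1 for s in systems if s.shift(nuc, slot) is not None)
            lines.append(f"  {slot} {nuc} filled: {count}/{len(systems)}")
    for w in report.warnings:
        exp, row = w.peak_ref
        lines.append(f"  warning: {exp.value} row {row} "
                     f"(N={w.peak.w_n:.3f}, HN={w.peak.w_hn:.3f}): {w.reason}")
    return "\n".join(lines)
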