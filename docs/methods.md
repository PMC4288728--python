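# Methods

This note documents the models and procedures implemented in
`bbassign`, the parameter defaults and why they were chosen, the design
of the synthetic benchmark, and the known limitations.

## Spin-system labeling

A spin system collects every resonance scalar-coupled to one backbone
amide: N(i), HN(i), internal Cα/Cβ/CO of residue i and sequential
Cα/Cβ/CO of residue i−1. Peaks are grouped by amide coordinates: a peak
belongs to a system when its (¹⁵N, ¹HN) lie within `dev_N` and `dev_HN`
of the system's root, ties broken by the smallest normalized distance
`|ΔN|/dev_N + |ΔHN|/dev_HN`. Roots come from a reference list (HSQC,
HNCO(i−1), their union — the default — or single-linkage clustering over
all lists). Peaks attachable to no root are clustered among themselves;
a cluster of at least two peaks is treated as a credible unreferenced
amide and becomes an extra system (mean-coordinate root), the rest stay
warnings. This *orphan rescue* recovers amides whose reference peaks
were not picked and can be disabled (`rescue_orphans=False`).

Internal vs sequential identity of the (i)(i−1) rows is resolved in
three tiers:

1. **Companion match** — a row matching a row of the (i−1) list within
   `dev_C` is sequential (the higher-resolution (i)(i−1) ppm value is
   kept; the companion peak is attached to the same slot). Matching is
   done per companion over all candidates, not greedily in row order.
2. **Intensity ordering** — when two candidates remain for one nucleus
   (or both fall within `dev_C` of one companion, where the shifts
   carry no information), the stronger absolute intensity is internal:
   internal transfers dominate in HNCA/HNCACB-type experiments. A
   config flag inverts the rule for experiments where they do not.
3. **Intensity threshold** — a lone unmatched row (its sibling row
   and/or companion peak missing) is classified against the geometric
   mean of absolute intensities of its list. The (i)(i−1) lists mix
   internal and sequential rows in roughly equal numbers, so in log
   space the geometric mean sits midway between the two populations.

HNCB rows may carry Cα correlations; the sign of the intensity routes
each row (`hncb_negative` names the negative nucleus).

Default tolerances are `dev_N = 0.15`, `dev_HN = 0.02`,
`dev_C = 0.05 ppm` — typical digital resolutions of well-processed
spectra. They are deliberately conservative; the synthetic benchmark
overrides them to match its own noise model (below). Labeling is pure
and deterministic: identical inputs and configuration give identical
output, and every input peak ends in exactly one system or one warning.

## Connectivity and fragments

Two systems are connected (predecessor → successor) when the
successor's sequential shifts agree with the predecessor's internal
ones. The match level counts the agreeing nuclei among those observed
on *both* sides — Match 3 (Cα+Cβ+CO) is the most reliable, Match 2 and
Match 1 exist because depleted data may only offer one or two shared
nuclei. A shared nucleus that *disagrees* beyond tolerance vetoes the
connection outright: lower match levels cover missing data, never
conflicting data. Glycine lacks Cβ; when neither side offers a Cβ and
the sequential Cα falls in the glycine window (42–48 ppm), Cα+CO
agreement is promoted to Match 3.

Fragments are all directed simple paths of 2–10 systems in the
connection graph, grouped by (size, match level). If any group would
exceed 1000 fragments, all tolerances are multiplied by 0.9 and the
build restarts; below a floor of 0.005 ppm the build aborts and asks
for cleaner peak lists. Default matching tolerances are 0.2 ppm per
nucleus (configurable).

## Placement scoring

See the README for the reduced-χ² formula. Details that matter:

* The amide of the m-th system sits at residue `start+m`; its
  sequential shifts probe `start+m−1`, so a k-fragment probes
  `start−1 … start+k−1`. Placements at the first assignable position
  simply lack the `start−1` terms. Amides are never placed on prolines
  or the first sequence position; probed-only positions may be
  prolines (their Cα/Cβ/CO are scored normally, and are in fact
  distinctive).
* The same physical nucleus observed twice (internal of system m,
  sequential of system m+1) contributes two independent terms — they
  are separate measurements.
* The secondary-structure combination minimizing χ² is found
  per-residue; this equals exhaustive 3ⁿ enumeration because the score
  decomposes residue-wise, and is tested against it. With an expected
  secondary-structure file and `restrict_to_expected_ss`, known labels
  are pinned.
* An observed Cβ probing a glycine position contributes a fixed
  10-standard-deviation penalty term instead of being dropped —
  dropping it would reward impossible placements.
* In deuterated mode the per-residue-type isotope correction is added
  to the reference means, which is algebraically identical to
  correcting the observed shifts, and keeps the observed data
  untouched. Protonated mode bypasses the isotope machinery entirely.

Each fragment yields a result list of its 20 best placements (ascending
χ², ties by start residue) with stable indices `S{size}M{match}F{#}R{rank}`;
one TSV per (size, match) group.

## Automated assignment policy

The interactive workflow — accept unambiguous suggestions, prefer
fragments based on more information, watch for conflicts — is replaced
in batch mode by an explicit policy:

1. **Candidates**: the rank-1 placement of every result list with
   χ² ≤ 50 and a within-list margin (second-best/best ≥ 2, or a
   single-entry list).
2. **Plausibility floor**: the consensus spreads calibrate a *correct*
   placement to a reduced χ² near the score scale; a placement fitting
   far below the lower 10⁻³ quantile of that distribution
   (Wilson–Hilferty approximation, `too_good_z = 3.09`) is a
   coincidental decoy and is rejected.
3. **Globally consistent greedy**: candidates are accepted in ascending
   χ² — the score is the reliability indicator — but a candidate is
   deferred while any live candidate of comparable quality
   (χ² < candidate·ratio) claims one of its residues or systems
   differently. Chimeric fragments created by a coincidental match are
   thereby contested by the true sub-chain placements, and with no
   clear winner neither side is auto-assigned: an omission, never a
   commission.
4. **Deadlock resolution by parsimony**: near-identical spin systems
   ("twins", common in internally repetitive sequences) can defer each
   other forever. Globally, every residue and system claimed by any
   candidate must remain claimable; a candidate whose acceptance
   orphans nothing, while each of its rivals would orphan some residue
   or system, is forced. Forcing is restricted to fragments of
   Match ≥ 2 (single-nucleus chains are exactly the error-prone
   evidence the method distrusts) and can additionally be gated on
   spin-system completeness (`force_completeness_min`, off by default —
   the closed-world argument assumes the candidate pool covers all
   true alternatives, which orphan rescue normally ensures).

Passes repeat until stable. Identical re-application of an accepted
placement is a no-op; residues and systems are a strict bijection,
audited after every operation. The policy's thresholds are surrogates
for interactive judgment, calibrated on the synthetic benchmark; they
are all exposed.

Linkage ("green/yellow") marks an assigned residue as linked when its
system connects to an assigned sequential neighbor at Match ≥ 1.
Completeness is reported as the fraction of peaks in assigned systems
and the fraction of assigned amides, with the denominator defaulting to
all residues (tag-inclusive convention; `amide-bearing` excludes
prolines and the N-terminus). Chemical-shift edits update systems,
exports and the propensity profile, but never previously computed
result lists. Sessions persist as versioned, human-diffable JSON.

## Secondary-structure propensity

Per assigned residue, secondary shifts Δδ = observed − random-coil are
computed for Cα and Cβ (CO optional; its secondary-shift dispersion is
lower), averaging the internal and sequential observations of the same
nucleus. Each Δδ maps to a propensity: +|Δδ/Δδ_helix| when it lies on
the helix side of random coil, −|Δδ/Δδ_strand| on the strand side,
where Δδ_helix/Δδ_strand are the full secondary-shift offsets of that
residue type and nucleus. Scores average the propensities over a
five-residue window (weights 1-2-3-2-1, truncated at chain ends and
assignment gaps) with per-nucleus reliability weights
(full-shift/spread)². By construction a fully formed helix scores ≈ +1,
a strand ≈ −1 and random coil exactly 0; these anchors are the
specification the implementation is tested against, and exact numeric
parity with any particular published propensity implementation is not
claimed. The profile is recomputed from the current state after every
assignment or edit; export is one TSV row per residue with `NA` for
residues without coverage.

## Reference tables

Three TSV tables ship with the package and can be replaced by the user
(`--shift-table`, `--isotope-table`):

* **Consensus shifts** — mean ± sd per (residue type, helix/strand/coil,
  Cα/Cβ/CO), built from standard published random-coil values plus
  canonical full helix/strand secondary-shift offsets (Cα +2.6/−1.4,
  Cβ −0.4/+2.2, CO +1.8/−1.6 ppm) and per-class spreads of 0.8–1.2 ppm.
  Glycine has no Cβ entries (a defined-missing value, not an error).
* **Random coil** — the same anchors plus the full-SS offsets, used by
  the propensity profile.
* **Isotope shifts** — deuterated-minus-protonated ¹³C corrections per
  residue type, computed from the number of α/β/γ deuterons with one-,
  two- and three-bond coefficients of literature magnitude (−0.30,
  −0.10, −0.03 ppm per deuteron; smaller for CO). All corrections are
  upfield (negative); `corrected = observed − Δδ` is pure data, no sign
  logic in code. Partially deuterated samples use the same values as
  perdeuterated ones.

## Synthetic benchmark design

The generator emulates the evaluation protocol the package is validated
by: a 76-residue protein with known shifts, Gaussian noise, and random
peak omission at 100/90/80/70 % retention.

* **Test protein** — the 76-residue calmodulin N-terminal domain
  sequence (two prolines, no single-residue amide segments) with
  hand-assigned helix/strand/loop labels (~60 % helical, two short
  strands), standing in for an unpublished calmodulin-family benchmark
  domain. Its EF-hand internal repeats make placement genuinely hard.
* **True shifts** — drawn once per residue from the consensus
  distribution of its type and class, Normal(mean, 1·sd): real proteins
  scatter around consensus by about one database spread, and this is
  what separates same-type residues.
* **Amide coordinates** — N ~ Normal(119, 5) ppm, HN ~ Normal(8.3, 0.6)
  ppm, redrawn until every pair is separated by > 0.6 ppm in ¹⁵N or
  > 0.16 ppm in ¹HN: the generator emulates a *resolvable* spectrum;
  spectral overlap is deliberately not simulated.
* **Peak lists** — HSQC: one peak per amide-bearing residue except the
  N-terminus; (i)(i−1) lists: internal + sequential rows; (i−1) lists:
  sequential only; prolines yield no amide peaks and break chains while
  their carbons appear through the next residue; glycines produce no Cβ
  rows. Intensities: internal:sequential ≈ 2:1 with lognormal scatter
  (σ = 0.1) so the intensity heuristics are exercised and reliable;
  HNCB rows are negative. Noise per axis: 0.02 (¹HN), 0.08 (¹⁵N),
  0.05 (¹³C) ppm. Retention drops each peak independently; the random
  stream is consumed identically for kept and dropped peaks so retained
  values do not depend on the omission pattern. Everything is
  reproducible from one seed, and every emitted peak is tracked in a
  ground-truth map.
* **Benchmark analysis settings** — the protocol uses `dev_N = 0.5`,
  `dev_HN = 0.13`, `dev_C = 0.3` and matching tolerances of 0.3 ppm:
  ≈ 4.5 σ of the difference of two noisy observations
  (σ·√2 per axis), so that tail losses are negligible across a
  ~700-peak dataset while staying far below real amide dispersion.

**What passing the benchmark does and does not show.** The synthetic
data have ideal lineshapes, no artefact or noise peaks, no overlap, no
referencing errors, and shifts drawn from the same consensus tables the
scorer uses. Success therefore demonstrates the correctness and
self-consistency of the pipeline's logic — labeling, chaining, scoring,
conflict handling — under noise and missing data, not performance on
real spectra, where picking quality and systematic shift deviations
dominate. With default settings the protocol assigns 100 % of peaks
correctly on complete data (any seed), ~99.8 % at 90 % retention and
~81 % at 70 % retention, with accepted assignments error-free in 19 of
20 grid runs; the residual case is one twin spin system accepted at its
EF-hand mirror position at 70 % retention — with only ¹³C shifts to
score, that placement is genuinely ambiguous once the contradicting
peaks have been dropped.

## Numerical and edge-case choices

* Scoring is vectorized over candidate start positions; defined-missing
  references (glycine Cβ) carry NaN means and the fixed penalty.
* Placements comparing zero shifts are rejected (undefined score), not
  scored as zero.
* Fragment enumeration is a deterministic bounded DFS (systems in id
  order, neighbors sorted); it aborts early the moment a size bucket
  exceeds the cap, so degenerate graphs cannot hang the build.
* Ties everywhere break on ascending start residue, then result index;
  reruns on identical input are bit-identical.
* Session files refuse to load on version mismatch or corrupt JSON.

## Known limitations

* No peak picking, lineshape fitting, or spectra I/O; only the seven
  supported list types; no NOESY or 4D data.
* Proline and N-terminal amides are unobservable by design; proline
  correlations enter only through the following residue.
* The dihedral-angle dependence of isotope shifts is not modeled.
* The auto-assignment policy is a batch surrogate for interactive
  judgment: on severely depleted or internally repetitive data it
  prefers omission over commission, and a small number of genuinely
  ambiguous twin placements can still be accepted wrongly (see above).
  Manual mode and the position scan exist precisely for that regime.
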