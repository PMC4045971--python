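"""Model of DSN cleavage of probe-hybridized circular cDNA inserts.

A library molecule is a circular single-stranded cDNA carrying one insert;
a single duplex-specific nuclease (DSN) cut anywhere in it prevents
amplification, so an insert is lost as soon as any probe forms a duplex of
at least ``min_duplex`` (default 10) perfectly matched base pairs with it.
The circular geometry is otherwise irrelevant and inserts are modelled as
intervals on the target RNA sense strand, 0-based half-open.

From this single rule follow the observable depletion zones: the 5' ends
whose inserts a probe can remove span from ``probe_start - L + min_duplex``
(widening with insert length L) to ``probe_end - min_duplex``, i.e. the
zone's right edge sits ``min_duplex`` nucleotides upstream of the probe 3'
end.  Continuous depletion of a target therefore requires adjacent probe
footprints to be spaced no further apart than the minimum library insert
size minus 20 nt (the published spacing rule; the exact model bound is one
nucleotide looser, ``min_insert - 2*(min_duplex - 1)`` = min_insert - 18
for the default threshold, and the validator reports both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .probescan import (
    Probe,
    ScanConfig,
    TranscriptRecord,
    scan,
    summarize_offtargets,
)
from .thermo import HybridizationConditions, melting_temperature

__all__ = [
    "ProbeFootprint",
    "CleavageModel",
    "SpacingRule",
    "InsertSizeRange",
    "GapCheck",
    "TerminalCheck",
    "SpacingReport",
    "is_cleavable",
    "survival_profile",
    "max_recommended_gap",
    "validate_spacing",
    "design_probe_set",
    "footprints_from_hits",
]


@dataclass(frozen=True)
class ProbeFootprint:
    """Interval on the target covered by a full-length exact probe match."""

    probe_id: str
    target_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid footprint interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CleavageModel:
    """DSN capability: cuts duplexes of >= min_duplex perfect base pairs.

    ``p_cut`` is the per-molecule probability that a cleavable insert is
    actually destroyed; 1.0 models a complete digestion, smaller values the
    empirically sub-complete efficiency of a real reaction.
    """

    min_duplex: int = 10
    p_cut: float = 1.0

    def __post_init__(self) -> None:
        if self.min_duplex < 1:
            raise ValueError("min_duplex must be >= 1")
        if not 0.0 < self.p_cut <= 1.0:
            raise ValueError("p_cut must be in (0, 1]")


@dataclass(frozen=True)
class SpacingRule:
    """Maximum inter-probe gap = minimum anticipated insert size - offset."""

    offset: int = 20


@dataclass(frozen=True)
class InsertSizeRange:
    """Inclusive insert-length bounds of a (real or in silico) size selection."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("require 0 < min_len <= max_len")

    def lengths(self) -> range:
        return range(self.min_len, self.max_len + 1)


def is_cleavable(
    five_prime: int,
    insert_len: int,
    footprints: Sequence[ProbeFootprint],
    model: CleavageModel | None = None,
) -> bool:
    """True iff the insert overlaps some footprint by >= min_duplex bases."""
    if insert_len < 0 or five_prime < 0:
        raise ValueError("five_prime and insert_len must be non-negative")
    model = model or CleavageModel()
    end = five_prime + insert_len
    for f in footprints:
        if min(end, f.end) - max(five_prime, f.start) >= model.min_duplex:
            return True
    return False


def survival_profile(
    target_len: int,
    footprints: Sequence[ProbeFootprint],
    size_range: InsertSizeRange,
    model: CleavageModel | None = None,
    length_weights: Sequence[tuple[int, float]] | None = None,
) -> np.ndarray:
    """Expected surviving fraction of read 5' ends at each target position.

    For each 5' position ``s`` the profile averages, over insert lengths in
    the size range (uniform unless ``length_weights`` supplies (length,
    weight) pairs), 1 for non-cleavable inserts and ``1 - p_cut`` for
    cleavable ones.  Lengths are truncated at the transcript end; positions
    too close to the 3' end to start any in-range insert report 1.0.
    """
    model = model or CleavageModel()
    if size_range.max_len > target_len:
        warnings.warn(
            f"max insert length {size_range.max_len} exceeds target length "
            f"{target_len}; lengths truncated at the transcript end",
            stacklevel=2,
        )
    if length_weights is None:
        pairs = [(L, 1.0) for L in size_range.lengths()]
    else:
        pairs = [(int(L), float(w)) for L, w in length_weights]
        if any(w < 0 for _, w in pairs) or not any(w > 0 for _, w in pairs):
            raise ValueError("length weights must be non-negative, not all zero")

    positions = np.arange(target_len)
    surv_weighted = np.zeros(target_len)
    weight_total = np.zeros(target_len)
    for L, w in pairs:
        if w == 0 or L > target_len:
            continue
        valid = positions <= target_len - L  # insert fits
        cleavable = np.zeros(target_len, dtype=bool)
        for f in footprints:
            lo = f.start - L + model.min_duplex
            hi = f.end - model.min_duplex  # inclusive
            if hi >= lo:
                cleavable[max(lo, 0) : hi + 1] = True
        surv = np.where(cleavable, 1.0 - model.p_cut, 1.0)
        surv_weighted += np.where(valid, w * surv, 0.0)
        weight_total += np.where(valid, w, 0.0)
    out = np.ones(target_len)
    covered = weight_total > 0
    out[covered] = surv_weighted[covered] / weight_total[covered]
    return out


def max_recommended_gap(min_insert: int, rule: SpacingRule | None = None) -> int:
    """The published spacing rule: largest gap = min insert size - offset."""
    rule = rule or SpacingRule()
    if min_insert <= rule.offset:
        raise ValueError(
            f"minimum insert size ({min_insert}) must exceed the spacing "
            f"offset ({rule.offset}): the rule is gap <= min_insert - {rule.offset}"
        )
    return min_insert - rule.offset


@dataclass(frozen=True)
class GapCheck:
    """One adjacent-footprint gap versus the spacing rule and the exact model."""

    left_probe: str
    right_probe: str
    gap: int
    passes_rule: bool
    escaping_inserts: int  # exact enumeration, lengths >= min_insert
    rule_exact_disagree: bool


@dataclass(frozen=True)
class TerminalCheck:
    side: str  # "5prime" | "3prime"
    uncovered: int
    escaping_inserts: int


@dataclass(frozen=True)
class SpacingReport:
    target_id: str
    min_insert: int
    max_gap: int
    gaps: tuple[GapCheck, ...]
    terminals: tuple[TerminalCheck, ...]
    short_probes: tuple[str, ...]
    n_failures: int

    @property
    def ok(self) -> bool:
        return self.n_failures == 0


def _count_escapes(
    footprints: Sequence[ProbeFootprint],
    target_len: int,
    s_lo: int,
    s_hi: int,
    min_insert: int,
    max_len: int,
    model: CleavageModel,
) -> int:
    """Exact count of non-cleavable inserts of length >= min_insert with a
    5' end in [s_lo, s_hi]."""
    n = 0
    for s in range(max(0, s_lo), min(s_hi, target_len - min_insert) + 1):
        for L in range(min_insert, min(max_len, target_len - s) + 1):
            if not is_cleavable(s, L, footprints, model):
                n += 1
    return n


def validate_spacing(
    footprints: Sequence[ProbeFootprint],
    target_len: int,
    min_insert: int,
    model: CleavageModel | None = None,
    rule: SpacingRule | None = None,
) -> SpacingReport:
    """Check a probe set for continuous depletion of one target.

    Each adjacent-footprint gap passes iff gap <= min_insert - offset (the
    published rule).  Alongside, an exact enumeration counts inserts of
    length >= min_insert that escape every footprint; the report flags the
    single-nucleotide band where the rule is more conservative than the
    exact model bound (gap <= min_insert - 2*(min_duplex - 1)).  Uncovered
    transcript ends and probes of <= 22 nt are also reported.
    """
    model = model or CleavageModel()
    rule = rule or SpacingRule()
    max_gap = max_recommended_gap(min_insert, rule)
    fps = sorted(footprints, key=lambda f: (f.start, f.end))

    merged: list[ProbeFootprint] = []
    for f in fps:
        if merged and f.start < merged[-1].end:
            prev = merged[-1]
            warnings.warn(
                f"footprints {prev.probe_id!r} and {f.probe_id!r} overlap; "
                f"collapsed for gap analysis",
                stacklevel=2,
            )
            merged[-1] = ProbeFootprint(
                probe_id=f"{prev.probe_id}+{f.probe_id}",
                target_id=prev.target_id,
                start=prev.start,
                end=max(prev.end, f.end),
            )
        else:
            merged.append(f)
    if not merged:
        raise ValueError("no footprints to validate")

    # Longest insert that could escape through a gap bounded by two probes.
    escape_cap = max(min_insert, max(
        (b.start - a.end for a, b in zip(merged, merged[1:])), default=0
    ) + 2 * (model.min_duplex - 1))

    gaps = []
    n_fail = 0
    for a, b in zip(merged, merged[1:]):
        gap = b.start - a.end
        passes = gap <= max_gap
        escapes = _count_escapes(
            footprints, target_len, a.end - min_insert, b.start,
            min_insert, escape_cap, model,
        ) if gap <= max_gap + 2 * model.min_duplex else -1  # -1: not enumerated (hopeless gap)
        if escapes == -1:
            escapes = 1  # a gap far beyond the rule certainly leaks
        disagree = passes != (escapes == 0)
        if not passes:
            n_fail += 1
        gaps.append(GapCheck(a.probe_id, b.probe_id, gap, passes, escapes, disagree))

    terminals = []
    first, last = merged[0], merged[-1]
    lead = first.start
    lead_escapes = _count_escapes(
        footprints, target_len, 0, first.start, min_insert,
        min(target_len, first.start + model.min_duplex - 1 + 1), model,
    ) if lead > 0 else 0
    terminals.append(TerminalCheck("5prime", lead, lead_escapes))
    tail = target_len - last.end
    tail_escapes = _count_escapes(
        footprints, target_len, max(0, last.end - model.min_duplex + 1),
        target_len - min_insert, min_insert, target_len, model,
    ) if tail > 0 else 0
    terminals.append(TerminalCheck("3prime", tail, tail_escapes))

    short = tuple(f.probe_id for f in fps if f.length <= 22)
    return SpacingReport(
        target_id=merged[0].target_id,
        min_insert=min_insert,
        max_gap=max_gap,
        gaps=tuple(gaps),
        terminals=tuple(terminals),
        short_probes=short,
        n_failures=n_fail,
    )


def footprints_from_hits(hits, probes: Sequence[Probe]) -> list[ProbeFootprint]:
    """Footprints = full-length exact matches of each probe on an intended target."""
    lengths = {p.id: len(p.sequence) for p in probes}
    out = []
    for h in hits:
        if h.is_target and h.probe_strand == "+" and h.length == lengths.get(h.probe_id):
            out.append(
                ProbeFootprint(h.probe_id, h.transcript_id, h.transcript_start,
                               h.transcript_start + h.length)
            )
    return sorted(out, key=lambda f: (f.target_id, f.start))


def design_probe_set(
    target: TranscriptRecord,
    transcriptome: Sequence[TranscriptRecord],
    min_insert: int,
    probe_len: int = 25,
    conditions: HybridizationConditions | None = None,
    model: CleavageModel | None = None,
    rule: SpacingRule | None = None,
    scan_config: ScanConfig | None = None,
    slack: int = 5,
    hybridization_temp: float = 48.0,
    margin: float = 3.0,
) -> list[Probe]:
    """Greedy left-to-right tiling of a target with depletion probes.

    Each successive probe window is placed as far right as the spacing rule
    allows; among candidate start positions within ``slack`` nt to the left
    of that ideal, the window with the largest Tm differential (intended
    target Tm minus hottest off-target Tm elsewhere in the transcriptome)
    wins, rightmost on ties.  A window whose best off-target Tm reaches
    ``hybridization_temp - margin`` is disqualified; if every candidate in
    a step is disqualified, the blocked interval is reported as an error.
    The returned set passes ``validate_spacing`` with zero rule failures.
    """
    if probe_len < 23:
        raise ValueError("probe_len must be >= 23 (probes of >22 nt are recommended)")
    model = model or CleavageModel()
    rule = rule or SpacingRule()
    conditions = conditions or HybridizationConditions()
    scan_config = scan_config or ScanConfig()
    target_len = len(target)
    if target_len < probe_len:
        raise ValueError(
            f"target {target.id!r} ({target_len} nt) is shorter than probe_len {probe_len}"
        )
    max_gap = max_recommended_gap(min_insert, rule)
    others = [t for t in transcriptome if t.id != target.id]

    def window_scores(starts: list[int]) -> dict[int, tuple[float, float | None]]:
        scores = {}
        for s in starts:
            seq = target.sequence[s : s + probe_len]
            t_tm = melting_temperature(seq, conditions)
            off_tm = None
            if others:
                probe = Probe(id=f"cand_{s}", sequence=seq,
                              intended_target_ids=frozenset({target.id}))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hits = scan([probe], others, scan_config, conditions)
                off_tm = max((h.tm for h in hits), default=None)
            scores[s] = (t_tm, off_tm)
        return scores

    probes: list[Probe] = []
    prev_end = 0
    while target_len - prev_end > max_gap:
        ideal = min(prev_end + max_gap, target_len - probe_len)
        if ideal <= prev_end and probes:
            break  # remaining tail cannot hold another non-overlapping probe
        candidates = [s for s in range(max(prev_end, ideal - slack), ideal + 1)]
        scores = window_scores(candidates)
        admissible = [
            s for s in candidates
            if scores[s][1] is None or scores[s][1] < hybridization_temp - margin
        ]
        if not admissible:
            raise ValueError(
                f"no admissible probe window in [{candidates[0]}, "
                f"{candidates[-1] + probe_len}) on {target.id!r}: every candidate "
                f"has an off-target Tm within {margin} C of {hybridization_temp} C"
            )
        def differential(s: int) -> float:
            t_tm, off_tm = scores[s]
            return float("inf") if off_tm is None else t_tm - off_tm

        best = max(admissible, key=lambda s: (differential(s), s))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probes.append(
                Probe(
                    id=f"{target.id}_p{len(probes) + 1:02d}_{best + 1}",
                    sequence=target.sequence[best : best + probe_len],
                    intended_target_ids=frozenset({target.id}),
                )
            )
        prev_end = best + probe_len
    return probes
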