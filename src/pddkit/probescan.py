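"""Off-target screening of depletion probes against a transcriptome.

Finds every maximal exact same-orientation shared substring between each
probe and each transcript (length above a configurable threshold, default
>10 nt), annotates each match with the nearest-neighbor Tm of the matched
segment, classifies matches as intended-target or off-target, and derives
a feasible hybridization-temperature window for the probe panel.

Probes are sense-strand copies of their intended target RNA; they hybridize
to the antisense first-strand cDNA, so a probe threatens any transcript
whose sense sequence contains the probe subsequence.  Matching is therefore
same-orientation substring search (``both_strands=True`` exists for
exploratory scans of the opposite orientation).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .thermo import (
    HybridizationConditions,
    NNParameterTable,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "Probe",
    "TranscriptCategory",
    "TranscriptRecord",
    "ScanConfig",
    "MatchHit",
    "ProbeSummary",
    "TemperatureRecommendation",
    "scan",
    "summarize_offtargets",
    "recommend_hybridization_temperature",
]

#: Probes at or below this length are flagged as risky (short probes deplete
#: less reliably; designs of >22 nt are recommended).
SHORT_PROBE_LENGTH = 22

_DNA = frozenset("ACGT")


class TranscriptCategory(str, Enum):
    rRNA_target = "rRNA_target"
    other_ncRNA = "other_ncRNA"
    mRNA = "mRNA"


@dataclass(frozen=True)
class Probe:
    """An unmodified sense-strand DNA depletion probe."""

    id: str
    sequence: str
    intended_target_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(
            self, "intended_target_ids", frozenset(self.intended_target_ids)
        )
        if len(self.sequence) <= SHORT_PROBE_LENGTH:
            warnings.warn(
                f"probe {self.id!r} is {len(self.sequence)} nt; probes of "
                f">{SHORT_PROBE_LENGTH} nt are recommended for reliable depletion",
                stacklevel=2,
            )

    @property
    def is_short(self) -> bool:
        return len(self.sequence) <= SHORT_PROBE_LENGTH


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with its category; weight is used only by the simulator."""

    id: str
    sequence: str
    category: TranscriptCategory = TranscriptCategory.mRNA
    abundance_weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "category", TranscriptCategory(self.category))
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        if self.abundance_weight < 0:
            raise ValueError(f"transcript {self.id!r} has a negative weight")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScanConfig:
    """Matching threshold: report matches of length >= min_match_len.

    The default of 11 reports matches of more than 10 nt, the minimum
    duplex the nuclease can cleave.
    """

    min_match_len: int = 11
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.min_match_len < 2:
            raise ValueError("min_match_len must be >= 2")


@dataclass(frozen=True)
class MatchHit:
    """A maximal exact shared substring between a probe and a transcript."""

    probe_id: str
    transcript_id: str
    probe_start: int
    transcript_start: int
    length: int
    tm: float
    is_target: bool
    probe_strand: str = "+"


@dataclass(frozen=True)
class ProbeSummary:
    """Per-probe target/off-target Tm summary.

    ``best_offtarget_tm`` is None (never 0) when the probe has no off-target
    hit; ``failed`` marks a probe with no full-length match to any intended
    target — such a probe cannot act as designed.
    """

    probe_id: str
    target_tm: float | None
    best_offtarget_tm: float | None
    n_offtarget_hits: int
    failed: bool
    is_short: bool


@dataclass(frozen=True)
class TemperatureRecommendation:
    feasible: bool
    window: tuple[float, float]
    recommended: float | None
    offending_probes: tuple[str, ...] = ()


def _kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if _DNA.issuperset(kmer):
            index[kmer].append(i)
    return index


def _maximal_matches(
    probe_seq: str, transcript_seq: str, index: dict[str, list[int]], k: int
) -> set[tuple[int, int, int]]:
    """All maximal exact matches of length >= k as (probe_start, t_start, length).

    Seeds every shared k-mer from the transcript index and extends both ways;
    distinct seeds inside one maximal match extend to the same triple, which
    the set collapses.  Non-ACGT bases break matches because they are never
    indexed.
    """
    out: set[tuple[int, int, int]] = set()
    n_p, n_t = len(probe_seq), len(transcript_seq)
    for i in range(n_p - k + 1):
        kmer = probe_seq[i : i + k]
        for j in index.get(kmer, ()):
            ps, ts = i, j
            while ps > 0 and ts > 0 and probe_seq[ps - 1] == transcript_seq[ts - 1] \
                    and probe_seq[ps - 1] in _DNA:
                ps -= 1
                ts -= 1
            pe, te = i + k, j + k
            while pe < n_p and te < n_t and probe_seq[pe] == transcript_seq[te] \
                    and probe_seq[pe] in _DNA:
                pe += 1
                te += 1
            out.add((ps, ts, pe - ps))
    return out


def scan(
    probes: Sequence[Probe],
    transcripts: Sequence[TranscriptRecord],
    config: ScanConfig | None = None,
    conditions: HybridizationConditions | None = None,
    table: NNParameterTable | None = None,
) -> list[MatchHit]:
    """All maximal exact probe/transcript matches above threshold, Tm-annotated.

    Deterministic and order-stable: hits are sorted by
    (probe_id, transcript_id, transcript_start, probe_start).  ``is_target``
    is True when the transcript is one of the probe's intended targets.
    """
    config = config or ScanConfig()
    conditions = conditions or HybridizationConditions()
    ids = [p.id for p in probes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate probe ids: {dupes}")
    t_ids = [t.id for t in transcripts]
    if len(set(t_ids)) != len(t_ids):
        raise ValueError("duplicate transcript ids")

    k = config.min_match_len
    hits: list[MatchHit] = []
    indices = {t.id: _kmer_index(t.sequence, k) for t in transcripts}
    for probe in probes:
        strands = [("+", probe.sequence)]
        if config.both_strands:
            strands.append(("-", reverse_complement(probe.sequence)))
        for strand, pseq in strands:
            for t in transcripts:
                for ps, ts, length in _maximal_matches(pseq, t.sequence, indices[t.id], k):
                    segment = pseq[ps : ps + length]
                    hits.append(
                        MatchHit(
                            probe_id=probe.id,
                            transcript_id=t.id,
                            probe_start=ps,
                            transcript_start=ts,
                            length=length,
                            tm=melting_temperature(segment, conditions, table),
                            is_target=t.id in probe.intended_target_ids,
                            probe_strand=strand,
                        )
                    )
    hits.sort(key=lambda h: (h.probe_id, h.transcript_id, h.transcript_start, h.probe_start))
    return hits


def summarize_offtargets(
    hits: Iterable[MatchHit], probes: Sequence[Probe]
) -> list[ProbeSummary]:
    """One row per probe: full-length target Tm and the hottest off-target.

    A probe's ``target_tm`` comes from a full-length match to an intended
    target; a probe lacking one is flagged ``failed``.  Probes with no
    off-target hit carry ``best_offtarget_tm = None``.
    """
    by_probe: dict[str, list[MatchHit]] = defaultdict(list)
    for h in hits:
        by_probe[h.probe_id].append(h)
    summaries = []
    for probe in probes:
        mine = by_probe.get(probe.id, [])
        full = [
            h for h in mine
            if h.is_target and h.length == len(probe.sequence) and h.probe_strand == "+"
        ]
        off = [h for h in mine if not h.is_target]
        target_tm = max((h.tm for h in full), default=None)
        if target_tm is None:
            warnings.warn(
                f"probe {probe.id!r} has no full-length match to any intended "
                f"target; it cannot act as designed",
                stacklevel=2,
            )
        summaries.append(
            ProbeSummary(
                probe_id=probe.id,
                target_tm=target_tm,
                best_offtarget_tm=max((h.tm for h in off), default=None),
                n_offtarget_hits=len(off),
                failed=target_tm is None,
                is_short=probe.is_short,
            )
        )
    return summaries


def recommend_hybridization_temperature(
    summary: Sequence[ProbeSummary], margin: float = 3.0
) -> TemperatureRecommendation:
    """Feasible hybridization window above off-targets, below targets.

    The window is (max off-target Tm + margin, min target Tm - margin); the
    run is infeasible when the window is empty, in which case the probes
    whose target Tm sits at or below the off-target ceiling are listed.
    """
    if not summary:
        raise ValueError("empty probe summary")
    missing = [s.probe_id for s in summary if s.target_tm is None]
    if missing:
        raise ValueError(f"probes without a target Tm: {missing}")
    target_tms = {s.probe_id: s.target_tm for s in summary}
    off_tms = [s.best_offtarget_tm for s in summary if s.best_offtarget_tm is not None]
    ceiling = max(off_tms) if off_tms else float("-inf")
    low = ceiling + margin if off_tms else float("-inf")
    high = min(target_tms.values()) - margin
    if low >= high:
        offenders = tuple(
            pid for pid, tm in sorted(target_tms.items()) if tm - margin <= low
        )
        return TemperatureRecommendation(False, (low, high), None, offenders)
    recommended = (low + high) / 2.0 if off_tms else high
    return TemperatureRecommendation(True, (low, high), recommended)
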