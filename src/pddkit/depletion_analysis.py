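"""Quantify depletion and bias from aligned reads of treated/untreated pairs.

All analyses operate on the minimal alignment record (library, transcript,
5' position, insert length) and mirror the standard readouts of a
probe-directed degradation experiment:

* per-position 5'-end read densities, smoothed with a 9-nt moving average,
  expressed as treated / untreated x 100 after normalizing each library by
  its mRNA-mapped read count within the insert-size group;
* probe-anchored pileups of those ratio profiles (x relative to the probe
  3' end, individually smoothed with a 7-nt window, averaged over probes);
* per-gap inter-probe read ratios (counting 5' ends between adjacent
  probes, extended 10 nt into each footprint);
* depletion efficiency (100 minus the minimum of the probe-averaged ratio
  curve over the full-cleavage plateau);
* per-ORF read counts annotated with the hottest off-target probe match;
* GC content of mRNA-mapped reads; and
* the reshuffling PCR-duplication test (observed coincident 5' ends versus
  the mean over repeated uniform placements on the ORF's available
  positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .depletion_model import CleavageModel, InsertSizeRange, ProbeFootprint
from .libsim import Insert
from .probescan import MatchHit, TranscriptCategory, TranscriptRecord

__all__ = [
    "AlignedRead",
    "AnalysisConfig",
    "RatioProfile",
    "GapRatio",
    "reads_from_inserts",
    "clip_and_filter",
    "moving_average",
    "mrna_mapped_count",
    "ratio_profile",
    "probe_pileup",
    "full_cleavage_window",
    "depletion_efficiency",
    "interprobe_ratio",
    "orf_counts_with_offtarget_tm",
    "gc_content",
    "duplication_analysis",
    "expected_duplicates",
]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned insert: the unit of every density analysis."""

    library_id: str
    transcript_id: str
    five_prime: int
    insert_len: int

    def __post_init__(self) -> None:
        if self.insert_len < 1:
            raise ValueError("insert_len must be >= 1")
        if self.five_prime < 0:
            raise ValueError("five_prime must be >= 0")


@dataclass(frozen=True)
class AnalysisConfig:
    """Windows, thresholds and size groups of the read-density analyses."""

    min_read_len: int = 11
    density_window: int = 9
    pileup_window: int = 7
    interprobe_extension: int = 10
    size_groups: tuple[InsertSizeRange, ...] = ()
    untreated_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name, w in (("density_window", self.density_window),
                        ("pileup_window", self.pileup_window)):
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1")
        if self.interprobe_extension < 0:
            raise ValueError("interprobe_extension must be >= 0")


@dataclass(frozen=True)
class RatioProfile:
    """Smoothed treated/untreated 5'-density percentage along one transcript."""

    transcript_id: str
    size_group: InsertSizeRange
    values: np.ndarray  # percentage, NaN where masked
    treated_smoothed: np.ndarray
    untreated_smoothed: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GapRatio:
    left_probe: str
    right_probe: str
    distance: int
    treated_count: int
    untreated_count: int
    percentage: float | None  # None where the untreated segment is empty


def reads_from_inserts(inserts: Iterable[Insert], library_id: str) -> list[AlignedRead]:
    """Wrap simulator inserts as aligned reads of one library."""
    return [
        AlignedRead(library_id, ins.transcript_id, ins.start, ins.length)
        for ins in inserts
    ]


def clip_and_filter(
    reads: Iterable[str],
    adapter: str,
    config: AnalysisConfig | None = None,
    min_adapter_prefix: int = 8,
    min_polya: int = 5,
) -> list[str]:
    """Trim 3' adapter and poly(A) tracts, discard short reads.

    The adapter is located by an exact match to its first
    ``min_adapter_prefix`` bases (leftmost occurrence) and everything from
    there on is removed; a trailing run of >= ``min_polya`` A's is then
    stripped; reads shorter than ``config.min_read_len`` are discarded.
    Quality trimming is delegated to external tools and not performed here.
    """
    config = config or AnalysisConfig()
    adapter = adapter.upper()
    probe = adapter[:min_adapter_prefix]
    out = []
    for read in reads:
        seq = read.upper()
        if len(probe) >= min_adapter_prefix:
            pos = seq.find(probe)
            if pos >= 0:
                seq = seq[:pos]
        n_a = len(seq) - len(seq.rstrip("A"))
        if n_a >= min_polya:
            seq = seq[: len(seq) - n_a]
        if len(seq) >= config.min_read_len:
            out.append(seq)
    return out


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated (not NaN-padded) at the edges.

    NaN-aware: each output is the mean of the non-NaN values in the window;
    all-NaN windows stay NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    half = window // 2
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite)))
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out


def _in_group(read: AlignedRead, group: InsertSizeRange | None) -> bool:
    return group is None or group.min_len <= read.insert_len <= group.max_len


def mrna_mapped_count(
    reads: Iterable[AlignedRead],
    categories: Mapping[str, TranscriptCategory],
    size_group: InsertSizeRange | None = None,
) -> int:
    """Number of reads mapped to mRNA transcripts within the size group."""
    return sum(
        1
        for r in reads
        if categories.get(r.transcript_id) == TranscriptCategory.mRNA
        and _in_group(r, size_group)
    )


def five_prime_counts(
    reads: Iterable[AlignedRead],
    transcript_id: str,
    transcript_len: int,
    size_group: InsertSizeRange | None = None,
) -> np.ndarray:
    """Per-position counts of read 5' ends on one transcript."""
    counts = np.zeros(transcript_len)
    for r in reads:
        if r.transcript_id == transcript_id and _in_group(r, size_group):
            if r.five_prime >= transcript_len:
                raise ValueError(
                    f"read 5' position {r.five_prime} beyond transcript "
                    f"{transcript_id!r} of length {transcript_len}"
                )
            counts[r.five_prime] += 1
    return counts


def ratio_profile(
    treated: Sequence[AlignedRead],
    untreated: Sequence[AlignedRead],
    transcript: TranscriptRecord,
    size_group: InsertSizeRange,
    categories: Mapping[str, TranscriptCategory],
    config: AnalysisConfig | None = None,
) -> RatioProfile:
    """Smoothed treated/untreated 5'-density percentage for one transcript.

    Per-position 5'-end counts are smoothed with the density window, each
    library is scaled by its mRNA-mapped read count within the size group
    (library-loading normalization), and the ratio is reported as a
    percentage, masked (NaN) wherever the untreated smoothed density falls
    below ``untreated_floor`` of the untreated library total.
    """
    config = config or AnalysisConfig()
    norm_t = mrna_mapped_count(treated, categories, size_group)
    norm_u = mrna_mapped_count(untreated, categories, size_group)
    for name, n in (("treated", norm_t), ("untreated", norm_u)):
        if n == 0:
            raise ValueError(
                f"{name} library has zero mRNA-mapped reads in size group "
                f"[{size_group.min_len}, {size_group.max_len}]"
            )
    t_raw = five_prime_counts(treated, transcript.id, len(transcript), size_group)
    u_raw = five_prime_counts(untreated, transcript.id, len(transcript), size_group)
    t_sm = moving_average(t_raw, config.density_window)
    u_sm = moving_average(u_raw, config.density_window)
    floor = config.untreated_floor * len(untreated)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (t_sm / norm_t) / (u_sm / norm_u) * 100.0
    ratio = np.where(u_sm >= floor, ratio, np.nan)
    return RatioProfile(
        transcript_id=transcript.id,
        size_group=size_group,
        values=ratio,
        treated_smoothed=t_sm,
        untreated_smoothed=u_sm,
    )


def probe_pileup(
    profiles: Sequence[RatioProfile],
    footprints: Sequence[ProbeFootprint],
    config: AnalysisConfig | None = None,
    x_range: tuple[int, int] = (-150, 50),
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Probe-anchored pileup of ratio profiles.

    Each footprint's profile is re-indexed to x = position - footprint end
    (x = 0 is the first base past the probe 3' end, so the probe's last
    base is at x = -1), individually smoothed with the pileup window, then
    averaged across probes at each x.  Returns (x, per-probe matrix with
    one column per footprint, mean curve).  Probes close to a transcript
    end contribute only their defined positions.
    """
    config = config or AnalysisConfig()
    if not footprints:
        raise ValueError("probe_pileup needs at least one footprint")
    by_transcript = {p.transcript_id: p for p in profiles}
    x = np.arange(x_range[0], x_range[1] + 1)
    columns = {}
    for f in footprints:
        prof = by_transcript.get(f.target_id)
        if prof is None:
            continue
        pos = x + f.end
        curve = np.full(len(x), np.nan)
        ok = (pos >= 0) & (pos < len(prof))
        curve[ok] = prof.values[pos[ok]]
        columns[f.probe_id] = moving_average(curve, config.pileup_window)
    if not columns:
        raise ValueError("no footprint lies on a profiled transcript")
    mat = pd.DataFrame(columns, index=x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(mat.to_numpy(), axis=1)
    return x, mat, mean


def full_cleavage_window(
    footprint_len: int, min_insert: int, model: CleavageModel | None = None
) -> tuple[int, int]:
    """Pileup x-interval where every in-range insert is cleavable.

    A 5' end at x (relative to the probe 3' end) is removable by every
    insert length >= min_insert iff
    -(footprint_len + min_insert - min_duplex) <= x <= -min_duplex.
    """
    model = model or CleavageModel()
    return (-(footprint_len + min_insert - model.min_duplex), -model.min_duplex)


def depletion_efficiency(
    profiles: Sequence[RatioProfile],
    footprints: Sequence[ProbeFootprint],
    config: AnalysisConfig | None = None,
    min_insert: int | None = None,
    model: CleavageModel | None = None,
    exclude: Iterable[str] = (),
) -> float:
    """Depletion efficiency in percent from probe-averaged ratio profiles.

    Per-probe ratio profiles are aligned on the probe 3' ends, smoothed and
    averaged across all functional probes (``exclude`` removes known-failed
    ones), and the efficiency is 100 minus the minimum of the averaged
    curve over the full-cleavage plateau shared by all probes.  Probes
    whose plateau is fully masked are dropped with a warning.
    """
    config = config or AnalysisConfig()
    model = model or CleavageModel()
    functional = [f for f in footprints if f.probe_id not in set(exclude)]
    if not functional:
        raise ValueError("no functional probe footprint supplied")
    if min_insert is None:
        min_insert = min(p.size_group.min_len for p in profiles)
    x_lo, x_hi = full_cleavage_window(
        min(f.length for f in functional), min_insert, model
    )
    x, mat, _ = probe_pileup(
        profiles, functional, config, x_range=(x_lo, x_hi)
    )
    keep = []
    for pid in mat.columns:
        if mat[pid].notna().any():
            keep.append(pid)
        else:
            warnings.warn(
                f"probe {pid!r} has a fully masked depletion zone; excluded "
                f"from the efficiency average",
                stacklevel=2,
            )
    if not keep:
        raise ValueError("every probe's depletion zone is masked")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_curve = np.nanmean(mat[keep].to_numpy(), axis=1)
    if not np.isfinite(mean_curve).any():
        raise ValueError("probe-averaged ratio curve is fully masked")
    return 100.0 - float(np.nanmin(mean_curve))


def interprobe_ratio(
    treated: Sequence[AlignedRead],
    untreated: Sequence[AlignedRead],
    footprints: Sequence[ProbeFootprint],
    categories: Mapping[str, TranscriptCategory],
    size_group: InsertSizeRange | None = None,
    config: AnalysisConfig | None = None,
) -> list[GapRatio]:
    """Normalized treated/untreated read ratio of each inter-probe segment.

    For each adjacent footprint pair on a target, reads whose 5' end falls
    between the probes -- extended ``interprobe_extension`` nt into each
    footprint -- are counted per library, scaled by the libraries'
    mRNA-mapped counts, and reported as a percentage against the gap
    distance.  Gaps with an empty untreated segment are masked (None).
    """
    config = config or AnalysisConfig()
    fps = sorted(footprints, key=lambda f: (f.target_id, f.start))
    if len(fps) < 2:
        raise ValueError("interprobe_ratio needs at least two footprints")
    norm_t = mrna_mapped_count(treated, categories, size_group)
    norm_u = mrna_mapped_count(untreated, categories, size_group)
    if norm_t == 0 or norm_u == 0:
        raise ValueError("zero mRNA-mapped reads in one library")
    ext = config.interprobe_extension
    out = []
    for a, b in zip(fps, fps[1:]):
        if a.target_id != b.target_id:
            continue
        lo, hi = a.end - ext, b.start + ext  # half-open [lo, hi)
        def count(reads: Sequence[AlignedRead]) -> int:
            return sum(
                1
                for r in reads
                if r.transcript_id == a.target_id
                and lo <= r.five_prime < hi
                and _in_group(r, size_group)
            )
        ct, cu = count(treated), count(untreated)
        pct = None if cu == 0 else (ct / norm_t) / (cu / norm_u) * 100.0
        out.append(GapRatio(a.probe_id, b.probe_id, b.start - a.end, ct, cu, pct))
    if not out:
        raise ValueError("no adjacent footprint pair shares a target")
    return out


def orf_counts_with_offtarget_tm(
    treated: Sequence[AlignedRead],
    untreated: Sequence[AlignedRead],
    orf_ids: Sequence[str],
    hits: Sequence[MatchHit] = (),
) -> pd.DataFrame:
    """Per-ORF read counts in both libraries plus the hottest off-target Tm.

    ``best_offtarget_tm`` is the maximum Tm of any off-target probe match
    inside the ORF, or None when no probe matches it -- the annotation for
    a treated-vs-untreated bias scatter.
    """
    best: dict[str, float] = {}
    for h in hits:
        if not h.is_target and h.transcript_id in set(orf_ids):
            best[h.transcript_id] = max(best.get(h.transcript_id, -np.inf), h.tm)
    ct = pd.Series([r.transcript_id for r in treated]).value_counts()
    cu = pd.Series([r.transcript_id for r in untreated]).value_counts()
    return pd.DataFrame(
        {
            "orf_id": list(orf_ids),
            "count_treated": [int(ct.get(o, 0)) for o in orf_ids],
            "count_untreated": [int(cu.get(o, 0)) for o in orf_ids],
            # object dtype keeps the explicit None sentinel (never 0, never NaN)
            "best_offtarget_tm": pd.Series(
                [best.get(o) for o in orf_ids], dtype=object
            ),
        }
    )


def gc_content(read_sequences: Iterable[str]) -> float:
    """G+C bases as a percentage of all bases across the given reads."""
    gc = total = 0
    for seq in read_sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        total += len(s)
    if total == 0:
        raise ValueError("no read bases supplied")
    return 100.0 * gc / total


def expected_duplicates(n_reads: int, positions: int) -> float:
    """Closed-form expected duplicate count for n uniform draws on P positions.

    E[duplicates] = n - P * (1 - (1 - 1/P)^n): the birthday-problem
    expectation of coincident 5' ends.
    """
    if positions <= 0:
        raise ValueError("positions must be > 0")
    return n_reads - positions * (1.0 - (1.0 - 1.0 / positions) ** n_reads)


def duplication_analysis(
    reads_by_orf: Mapping[str, Sequence[int]],
    orf_lengths: Mapping[str, int],
    median_read_len: int,
    seed: int = 0,
    min_sims_large: int = 100,
    min_sims_small: int = 500,
) -> pd.DataFrame:
    """Observed vs reshuffled-expected exact 5'-end duplicates per ORF.

    Available positions P = ORF length - median read length; coverage =
    n / P; observed duplicates = n - distinct 5' positions; the expectation
    is the mean over repeated uniform placements of n reads on P positions
    (at least ``min_sims_large`` reshuffles for ORFs with more than 10
    reads, at least ``min_sims_small`` for ORFs with 2-10 reads).  ORFs
    with fewer than 2 reads are skipped; ORFs with P <= 0 are skipped with
    a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for orf in sorted(reads_by_orf):
        positions_5p = list(reads_by_orf[orf])
        n = len(positions_5p)
        if n < 2:
            continue
        P = orf_lengths[orf] - median_read_len
        if P <= 0:
            warnings.warn(
                f"ORF {orf!r}: no available positions (length "
                f"{orf_lengths[orf]} <= median read length {median_read_len}); skipped",
                stacklevel=2,
            )
            continue
        observed = n - len(set(positions_5p))
        n_sims = min_sims_large if n > 10 else min_sims_small
        draws = rng.integers(0, P, size=(n_sims, n))
        distinct = np.array([len(np.unique(d)) for d in draws])
        expected = float(np.mean(n - distinct))
        rows.append(
            {
                "orf_id": orf,
                "n_reads": n,
                "available_positions": P,
                "coverage": n / P,
                "observed_duplicates": observed,
                "expected_duplicates": expected,
                "n_sims": n_sims,
            }
        )
    return pd.DataFrame(rows)
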