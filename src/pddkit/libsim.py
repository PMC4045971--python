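"""Seeded simulator of fragment libraries and their probe-directed depletion.

Generates a synthetic transcript pool dominated by an rRNA-like species,
fragments it into adapter-flanked inserts (modelled directly as a uniform
draw of 5' position and length within a size-selection window, which is the
joint distribution the downstream density analyses depend on), and emits
paired treated/untreated libraries in which the treated aliquot has had
probe-overlapping inserts removed according to the cleavage model.

All randomness flows through a single integer seed; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .depletion_model import CleavageModel, InsertSizeRange, ProbeFootprint
from .probescan import TranscriptCategory, TranscriptRecord

__all__ = [
    "LibraryConfig",
    "Insert",
    "synthetic_pool",
    "simulate_fragments",
    "apply_pdd",
    "split_aliquots",
    "simulate_paired_libraries",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "write_fastq",
]


@dataclass(frozen=True)
class LibraryConfig:
    """Simulation parameters for one library.

    Defaults mirror a typical small-insert run: a 25-200 nt size selection
    sequenced with 150 nt reads from the 5' end.
    """

    n_inserts: int = 100_000
    size_selection: InsertSizeRange = field(
        default_factory=lambda: InsertSizeRange(25, 200)
    )
    read_len: int = 150
    seed: int = 0
    p_cut: float = 1.0

    def __post_init__(self) -> None:
        if self.n_inserts < 0:
            raise ValueError("n_inserts must be >= 0")


@dataclass(frozen=True)
class Insert:
    """One library molecule: an interval on a transcript's sense strand."""

    transcript_id: str
    start: int
    length: int


def synthetic_pool(
    seed: int = 0,
    rrna_len: int = 1800,
    n_mrna: int = 50,
    mrna_len_range: tuple[int, int] = (500, 2000),
    rrna_weight: float = 200.0,
    gc: float = 0.45,
) -> list[TranscriptRecord]:
    """A transcript pool with one dominant rRNA-like species.

    One rRNA-like transcript at ``rrna_weight`` (default 200x) plus
    ``n_mrna`` mRNA-like transcripts at weight 1, emulating the dominance
    of rRNA fragments in a real total-RNA library.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n, p=p))

    pool = [
        TranscriptRecord(
            id="rRNA_18S_like",
            sequence=random_seq(rrna_len),
            category=TranscriptCategory.rRNA_target,
            abundance_weight=rrna_weight,
        )
    ]
    lo, hi = mrna_len_range
    for i in range(n_mrna):
        pool.append(
            TranscriptRecord(
                id=f"mRNA_{i + 1:03d}",
                sequence=random_seq(int(rng.integers(lo, hi + 1))),
                category=TranscriptCategory.mRNA,
                abundance_weight=1.0,
            )
        )
    return pool


def simulate_fragments(
    pool: Sequence[TranscriptRecord], config: LibraryConfig
) -> list[Insert]:
    """Draw size-selected inserts from a weighted transcript pool.

    Transcripts are chosen proportional to ``abundance_weight * length``
    (a fragmentation of abundance-weighted RNA mass); the 5' position and
    length are uniform over the valid positions and the size-selection
    range, truncated at the transcript length.  Transcripts shorter than
    the minimum insert are excluded with a warning.
    """
    sel = config.size_selection
    usable = [t for t in pool if len(t) >= sel.min_len]
    dropped = [t.id for t in pool if len(t) < sel.min_len]
    if dropped:
        warnings.warn(
            f"transcripts shorter than the minimum insert excluded: {dropped}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no transcript is long enough for the size selection")
    weights = np.array([t.abundance_weight * len(t) for t in usable], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("pool weights are all zero")
    if config.n_inserts == 0:
        return []

    rng = np.random.default_rng(config.seed)
    lens = np.array([len(t) for t in usable])
    idx = rng.choice(len(usable), size=config.n_inserts, p=weights / weights.sum())
    eff_max = np.minimum(sel.max_len, lens[idx])
    L = rng.integers(sel.min_len, eff_max + 1)
    start = rng.integers(0, lens[idx] - L + 1)
    ids = [t.id for t in usable]
    return [
        Insert(ids[i], int(s), int(l)) for i, s, l in zip(idx, start, L)
    ]


def _cleavable_mask(
    inserts: Sequence[Insert],
    footprints: Sequence[ProbeFootprint],
    model: CleavageModel,
) -> np.ndarray:
    by_target: dict[str, list[ProbeFootprint]] = {}
    for f in footprints:
        by_target.setdefault(f.target_id, []).append(f)
    tids = np.array([ins.transcript_id for ins in inserts])
    starts = np.array([ins.start for ins in inserts])
    ends = starts + np.array([ins.length for ins in inserts])
    mask = np.zeros(len(inserts), dtype=bool)
    for tid, fps in by_target.items():
        on_t = tids == tid
        for f in fps:
            overlap = np.minimum(ends, f.end) - np.maximum(starts, f.start)
            mask |= on_t & (overlap >= model.min_duplex)
    return mask


def apply_pdd(
    inserts: Sequence[Insert],
    footprints: Sequence[ProbeFootprint],
    model: CleavageModel | None = None,
    seed: int = 0,
) -> list[Insert]:
    """Remove each cleavable insert independently with probability p_cut."""
    model = model or CleavageModel()
    if not inserts:
        return []
    cleavable = _cleavable_mask(inserts, footprints, model)
    rng = np.random.default_rng(seed)
    cut = cleavable & (rng.random(len(inserts)) < model.p_cut)
    return [ins for ins, c in zip(inserts, cut) if not c]


def split_aliquots(inserts: Sequence[Insert], seed: int = 0) -> tuple[list[Insert], list[Insert]]:
    """Split one insert set into two equal aliquots (random, seeded).

    The union of the two halves is exactly the input set; the first half is
    the one destined for treatment.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(inserts))
    half = len(inserts) // 2
    first = sorted(order[:half])
    second = sorted(order[half:])
    return [inserts[i] for i in first], [inserts[i] for i in second]


def simulate_paired_libraries(
    pool: Sequence[TranscriptRecord],
    footprints: Sequence[ProbeFootprint],
    config: LibraryConfig,
) -> tuple[list[Insert], list[Insert]]:
    """One fragmentation, split in two; one aliquot treated, one untreated.

    Returns (treated, untreated).  Seeds for the split and the cleavage
    draw are derived from ``config.seed`` so the whole pair is reproducible
    from one integer.
    """
    inserts = simulate_fragments(pool, config)
    to_treat, untreated = split_aliquots(inserts, seed=config.seed + 1)
    model = CleavageModel(p_cut=config.p_cut)
    treated = apply_pdd(to_treat, footprints, model, seed=config.seed + 2)
    return treated, untreated


def write_alignments_tsv(
    inserts: Sequence[Insert], path: str | Path, library_id: str
) -> None:
    """Plain-text alignment table: library_id, transcript_id, five_prime, insert_len."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("library_id\ttranscript_id\tfive_prime\tinsert_len\n")
        for ins in inserts:
            fh.write(f"{library_id}\t{ins.transcript_id}\t{ins.start}\t{ins.length}\n")


def read_alignments_tsv(path: str | Path) -> dict[str, list[Insert]]:
    """Inverse of ``write_alignments_tsv``; returns inserts per library id."""
    out: dict[str, list[Insert]] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["library_id", "transcript_id", "five_prime", "insert_len"]:
            raise ValueError(f"unexpected alignment TSV header in {path}: {header}")
        for line in fh:
            lib, tid, fp, il = line.rstrip("\n").split("\t")
            out.setdefault(lib, []).append(Insert(tid, int(fp), int(il)))
    return out


def write_fastq(
    inserts: Sequence[Insert],
    pool: Sequence[TranscriptRecord],
    path: str | Path,
    read_len: int = 150,
    quality_char: str = "I",
) -> int:
    """Write 5'-end reads (first ``read_len`` nt of each insert) as FASTQ.

    Returns the number of records written (one per insert).
    """
    seqs = {t.id: t.sequence for t in pool}
    n = 0
    with Path(path).open("w") as fh:
        for i, ins in enumerate(inserts):
            read = seqs[ins.transcript_id][ins.start : ins.start + min(ins.length, read_len)]
            fh.write(f"@insert_{i}_{ins.transcript_id}_{ins.start}_{ins.length}\n")
            fh.write(read + "\n+\n" + quality_char * len(read) + "\n")
            n += 1
    return n
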