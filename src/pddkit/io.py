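"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA goes through Biopython, SAM/BAM through pysam (primary alignments
only), tables are tab-separated with fixed, documented headers.  All
coordinates in TSV reports are 1-based inclusive (stated in each header);
the in-memory API is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depletion_analysis import AlignedRead, GapRatio
from .depletion_model import ProbeFootprint, SpacingReport
from .probescan import (
    MatchHit,
    Probe,
    ProbeSummary,
    TranscriptCategory,
    TranscriptRecord,
)

__all__ = [
    "read_probes",
    "read_probes_fasta",
    "read_probes_tsv",
    "write_probes_fasta",
    "read_transcripts",
    "write_transcripts",
    "read_sam",
    "write_hits_tsv",
    "write_probe_summary_tsv",
    "write_spacing_report_tsv",
    "write_survival_profile_tsv",
    "write_ratio_profile_tsv",
    "write_pileup_tsv",
    "write_interprobe_tsv",
    "write_orf_counts_tsv",
    "NONE_SENTINEL",
]

#: Written wherever a Tm or ratio is undefined (e.g. no off-target hit).
NONE_SENTINEL = "none"


def read_probes_fasta(path: str | Path) -> list[Probe]:
    """Probes from FASTA; intended targets parsed from a ``targets=a;b``
    token in the description (absent token = no declared targets)."""
    probes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        targets: frozenset[str] = frozenset()
        for token in rec.description.split():
            if token.startswith("targets="):
                targets = frozenset(t for t in token[8:].split(";") if t)
        probes.append(Probe(id=rec.id, sequence=str(rec.seq), intended_target_ids=targets))
    return probes


def read_probes_tsv(path: str | Path) -> list[Probe]:
    """Probes from TSV with columns: id, sequence, intended_targets
    (semicolon-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "sequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe TSV {path} must have columns {sorted(required)}")
    probes = []
    for _, row in df.iterrows():
        raw = row.get("intended_targets", "") or ""
        probes.append(
            Probe(
                id=row["id"],
                sequence=row["sequence"],
                intended_target_ids=frozenset(t for t in raw.split(";") if t),
            )
        )
    return probes


def read_probes(path: str | Path) -> list[Probe]:
    """Dispatch on extension: .tsv -> TSV, anything else -> FASTA."""
    p = Path(path)
    if p.suffix.lower() in {".tsv", ".txt"}:
        return read_probes_tsv(p)
    return read_probes_fasta(p)


def write_probes_fasta(probes: Sequence[Probe], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.id,
            description=f"targets={';'.join(sorted(p.intended_target_ids))}",
        )
        for p in probes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcripts(
    fasta: str | Path, categories_tsv: str | Path | None = None
) -> list[TranscriptRecord]:
    """Transcripts from FASTA plus an optional category table.

    categories.tsv columns: transcript_id, category
    (rRNA_target | other_ncRNA | mRNA), optional abundance_weight.
    Transcripts absent from the table default to mRNA at weight 1.
    """
    cats: dict[str, TranscriptCategory] = {}
    weights: dict[str, float] = {}
    if categories_tsv is not None:
        df = pd.read_csv(categories_tsv, sep="\t", dtype=str, keep_default_na=False)
        if not {"transcript_id", "category"}.issubset(df.columns):
            raise ValueError(
                f"category TSV {categories_tsv} must have columns "
                f"transcript_id, category"
            )
        for _, row in df.iterrows():
            cats[row["transcript_id"]] = TranscriptCategory(row["category"])
            if row.get("abundance_weight", ""):
                weights[row["transcript_id"]] = float(row["abundance_weight"])
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        out.append(
            TranscriptRecord(
                id=rec.id,
                sequence=str(rec.seq),
                category=cats.get(rec.id, TranscriptCategory.mRNA),
                abundance_weight=weights.get(rec.id, 1.0),
            )
        )
    if not out:
        raise ValueError(f"no FASTA records in {fasta}")
    return out


def write_transcripts(
    transcripts: Sequence[TranscriptRecord],
    fasta: str | Path,
    categories_tsv: str | Path,
) -> None:
    SeqIO.write(
        [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts],
        str(fasta),
        "fasta",
    )
    with Path(categories_tsv).open("w") as fh:
        fh.write("transcript_id\tcategory\tabundance_weight\n")
        for t in transcripts:
            fh.write(f"{t.id}\t{t.category.value}\t{t.abundance_weight:g}\n")


def read_sam(path: str | Path, library_id: str) -> list[AlignedRead]:
    """Primary alignments from SAM/BAM as AlignedRead records.

    The 5' position is the reference start; the insert length is the query
    length.  Secondary, supplementary and unmapped records are skipped.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            qlen = aln.query_length or aln.infer_query_length() or 0
            if qlen < 1:
                continue
            reads.append(
                AlignedRead(
                    library_id=library_id,
                    transcript_id=aln.reference_name,
                    five_prime=aln.reference_start,
                    insert_len=qlen,
                )
            )
    return reads


def _fmt(value, digits: int = 2) -> str:
    if value is None:
        return NONE_SENTINEL
    return f"{value:.{digits}f}"


def write_hits_tsv(hits: Sequence[MatchHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write(
            "probe_id\ttranscript_id\tprobe_start\ttranscript_start\t"
            "length\ttm\tis_target\tprobe_strand\n"
        )
        for h in hits:
            fh.write(
                f"{h.probe_id}\t{h.transcript_id}\t{h.probe_start + 1}\t"
                f"{h.transcript_start + 1}\t{h.length}\t{h.tm:.2f}\t"
                f"{'yes' if h.is_target else 'no'}\t{h.probe_strand}\n"
            )


def write_probe_summary_tsv(summaries: Sequence[ProbeSummary], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "probe_id\ttarget_tm\tbest_offtarget_tm\tn_offtarget_hits\t"
            "failed\tshort_probe\n"
        )
        for s in summaries:
            fh.write(
                f"{s.probe_id}\t{_fmt(s.target_tm)}\t{_fmt(s.best_offtarget_tm)}\t"
                f"{s.n_offtarget_hits}\t{'yes' if s.failed else 'no'}\t"
                f"{'yes' if s.is_short else 'no'}\n"
            )


def read_probe_summary_tsv(path: str | Path) -> list[ProbeSummary]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            ProbeSummary(
                probe_id=r["probe_id"],
                target_tm=None if r["target_tm"] == NONE_SENTINEL else float(r["target_tm"]),
                best_offtarget_tm=(
                    None if r["best_offtarget_tm"] == NONE_SENTINEL
                    else float(r["best_offtarget_tm"])
                ),
                n_offtarget_hits=int(r["n_offtarget_hits"]),
                failed=r["failed"] == "yes",
                is_short=r["short_probe"] == "yes",
            )
        )
    return out


def write_spacing_report_tsv(report: SpacingReport, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# target={report.target_id} min_insert={report.min_insert} "
                 f"max_recommended_gap={report.max_gap}\n")
        fh.write(f"# short probes (<=22 nt): "
                 f"{';'.join(report.short_probes) or NONE_SENTINEL}\n")
        for t in report.terminals:
            fh.write(f"# terminal {t.side}: uncovered={t.uncovered} "
                     f"escaping_inserts={t.escaping_inserts}\n")
        fh.write("left_probe\tright_probe\tgap\tpasses_rule\t"
                 "escaping_inserts\trule_exact_disagree\n")
        for g in report.gaps:
            fh.write(
                f"{g.left_probe}\t{g.right_probe}\t{g.gap}\t"
                f"{'yes' if g.passes_rule else 'no'}\t{g.escaping_inserts}\t"
                f"{'yes' if g.rule_exact_disagree else 'no'}\n"
            )


def write_survival_profile_tsv(
    target_id: str,
    size_label: str,
    survival,
    path: str | Path,
    append: bool = False,
) -> None:
    mode = "a" if append else "w"
    with Path(path).open(mode) as fh:
        if not append:
            fh.write("# position is 1-based\n")
            fh.write("target_id\tsize_group\tposition\tsurvival\n")
        for i, v in enumerate(survival):
            fh.write(f"{target_id}\t{size_label}\t{i + 1}\t{v:.6g}\n")


def write_ratio_profile_tsv(profiles, path: str | Path) -> None:
    import numpy as np

    with Path(path).open("w") as fh:
        fh.write("# position is 1-based; ratio is treated/untreated percent, "
                 f"{NONE_SENTINEL} where masked\n")
        fh.write("transcript_id\tsize_group\tposition\tratio_percent\n")
        for p in profiles:
            label = f"{p.size_group.min_len}-{p.size_group.max_len}"
            for i, v in enumerate(p.values):
                txt = NONE_SENTINEL if not np.isfinite(v) else f"{v:.4g}"
                fh.write(f"{p.transcript_id}\t{label}\t{i + 1}\t{txt}\n")


def write_pileup_tsv(x, mat, mean, path: str | Path) -> None:
    import numpy as np

    with Path(path).open("w") as fh:
        fh.write("# x is relative to the probe 3' end (x=0: first base past "
                 "the probe)\n")
        fh.write("x\t" + "\t".join(mat.columns) + "\tmean\n")
        for i, xv in enumerate(x):
            row = [
                NONE_SENTINEL if not np.isfinite(v) else f"{v:.4g}"
                for v in mat.iloc[i]
            ]
            m = NONE_SENTINEL if not np.isfinite(mean[i]) else f"{mean[i]:.4g}"
            fh.write(f"{xv}\t" + "\t".join(row) + f"\t{m}\n")


def write_interprobe_tsv(gaps: Sequence[GapRatio], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("left_probe\tright_probe\tdistance\ttreated_count\t"
                 "untreated_count\tratio_percent\n")
        for g in gaps:
            pct = NONE_SENTINEL if g.percentage is None else f"{g.percentage:.4g}"
            fh.write(
                f"{g.left_probe}\t{g.right_probe}\t{g.distance}\t"
                f"{g.treated_count}\t{g.untreated_count}\t{pct}\n"
            )


def write_orf_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["best_offtarget_tm"] = [
        NONE_SENTINEL if v is None else f"{v:.2f}" for v in out["best_offtarget_tm"]
    ]
    out.to_csv(path, sep="\t", index=False)
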