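"""Screen a small probe panel against a transcriptome and pick a temperature.

Builds a toy transcriptome (one rRNA-like target, a few mRNAs, one of which
carries a planted 14-nt off-target site), scans two probes for every exact
match above the >10 nt threshold, and derives the hybridization window.
"""

import random

from pddkit import (
    Probe,
    TranscriptRecord,
    recommend_hybridization_temperature,
    scan,
    summarize_offtargets,
)

rng = random.Random(1)
dna = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

rrna = TranscriptRecord(id="rRNA", sequence=dna(600), category="rRNA_target")
probes = [
    Probe("probe_1", rrna.sequence[100:125], intended_target_ids={"rRNA"}),
    Probe("probe_2", rrna.sequence[300:325], intended_target_ids={"rRNA"}),
]
mrnas = [TranscriptRecord(id=f"mRNA_{i}", sequence=dna(400)) for i in range(4)]
# plant a 14-nt off-target site for probe_1 inside mRNA_0
s = mrnas[0].sequence
mrnas[0] = TranscriptRecord(id="mRNA_0", sequence=s[:200] + probes[0].sequence[:14] + s[214:])

hits = scan(probes, [rrna] + mrnas)
summary = summarize_offtargets(hits, probes)
for row in summary:
    off = "none" if row.best_offtarget_tm is None else f"{row.best_offtarget_tm:.1f} C"
    print(f"{row.probe_id}: target Tm {row.target_tm:.1f} C, best off-target {off}")

rec = recommend_hybridization_temperature(summary)
lo, hi = rec.window
print(f"hybridization window ({lo:.1f}, {hi:.1f}) C, recommended {rec.recommended:.1f} C")
print("-> hybridize above every off-target Tm and below every target Tm, so only")
print("   intended probe/cDNA duplexes form and get cut.")
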