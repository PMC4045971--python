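"""Estimate expected PCR-duplicate counts by reshuffling read 5' ends.

Compares observed coincident 5' ends per ORF with the mean over repeated
uniform placements of the same read count on the ORF's available positions,
alongside the closed-form birthday expectation.
"""

import numpy as np

from pddkit import duplication_analysis, expected_duplicates

rng = np.random.default_rng(5)
orf_lengths = {"ORF_A": 460, "ORF_B": 210}
reads_by_orf = {
    "ORF_A": list(rng.integers(0, 400, size=120)),
    "ORF_B": list(rng.integers(0, 150, size=8)),
}

df = duplication_analysis(reads_by_orf, orf_lengths, median_read_len=60, seed=5)
for _, row in df.iterrows():
    analytic = expected_duplicates(row.n_reads, row.available_positions)
    print(
        f"{row.orf_id}: {row.n_reads} reads on {row.available_positions} positions "
        f"(coverage {row.coverage:.2f}) -> observed {row.observed_duplicates} "
        f"duplicates, reshuffled expectation {row.expected_duplicates:.2f} "
        f"(closed form {analytic:.2f}, {row.n_sims} reshuffles)"
    )
print("-> observed duplicates near the expectation indicate coincidental 5' end")
print("   overlap, not PCR over-amplification.")
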