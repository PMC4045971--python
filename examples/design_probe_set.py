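"""Design a spacing-valid probe set for a synthetic rRNA-like target.

Greedy left-to-right tiling: each probe sits as far right as the spacing
rule allows, nudged within a 5-nt slack toward the window with the best
target-vs-off-target Tm differential.
"""

from pddkit import design_probe_set, footprints_from_hits, scan, validate_spacing
from pddkit.libsim import synthetic_pool

pool = synthetic_pool(seed=3)
target = pool[0]
probes = design_probe_set(target, pool, min_insert=50, probe_len=25)
print(f"designed {len(probes)} probes of 25 nt for the {len(target)} nt target")

footprints = footprints_from_hits(scan(probes, pool), probes)
report = validate_spacing(footprints, len(target), 50)
gaps = [g.gap for g in report.gaps]
print(f"inter-probe gaps: min {min(gaps)}, max {max(gaps)} "
      f"(rule allows up to {report.max_gap})")
print(f"spacing failures: {report.n_failures}, "
      f"escaping inserts across all gaps: {sum(g.escaping_inserts for g in report.gaps)}")
print("-> every insert of >= 50 nt overlaps some probe by >= 10 bp, so a")
print("   complete digestion would remove the target entirely.")
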