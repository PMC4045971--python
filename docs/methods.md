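# Methods

## The model

Probe-directed degradation operates on a directional RNA-seq library at the
single-stranded circular cDNA stage. Each library molecule carries one
insert (the cDNA copy of an RNA fragment) between adapter sequences;
sense-strand DNA probes hybridize to the antisense cDNA, and duplex-specific
nuclease (DSN) cuts any duplex of at least ten perfectly matched base
pairs. A single cut anywhere prevents amplification, so the circular
geometry reduces to interval arithmetic on the target RNA sense strand
(0-based, half-open): an insert `[s, s+L)` is *cleavable* iff it overlaps
some probe footprint by ≥ `min_duplex` (default 10) bases. Adapters are
never modelled as targets — no complementary strand exists for them.

Everything observable follows from that rule:

* **Depletion zones.** A probe with footprint `[b, e)` can remove read 5′
  ends at positions `b − L + min_duplex … e − min_duplex` for insert length
  `L`: zones widen with insert length on the left flank and end exactly
  `min_duplex` nt upstream of the probe 3′ end on the right.
  `survival_profile` averages the indicator (weighted by an insert-length
  distribution, uniform by default) and scales cleavable inserts by
  `1 − p_cut`.
* **Spacing.** The longest insert that slips between two footprints
  separated by `gap` is `gap + 2·(min_duplex − 1)`. The published design
  rule — gap ≤ minimum insert size − 20 — is one nucleotide more
  conservative than this exact bound (− 18); `validate_spacing` applies
  the published rule for pass/fail and reports the exact enumeration
  alongside, flagging the single-nucleotide band where they disagree.
* **Sub-complete digestion.** Real reactions do not cut every cleavable
  molecule; the model's handle is `p_cut ∈ (0, 1]`, the independent
  per-molecule cut probability. (An identity treatment is the `p_cut → 0`
  limit; the parameter itself is kept strictly positive.)

## Thermodynamics

Probe/cDNA duplex stability uses the unified nearest-neighbor parameter
set (Allawi & SantaLucia lineage), shipped as a plain-text table
(`data/nn_unified.tsv`) with a `source_label` so an alternative table can
be swapped in. The two-state melting temperature is

```
Tm(°C) = 1000·ΔH° / (ΔS° + 0.368·(N−1)·ln[Na+] + R·ln(C_T/x)) − 273.15
```

with ΔH° in kcal/mol, ΔS° in cal/(mol·K), R = 1.987 cal/(mol·K), and
initiation terms for both terminal base pairs. Defaults: `C_T = 0.81 µM`
(the per-probe concentration of the depletion reaction), `x = 4` (probe and
cDNA are distinct strands), 50 mM monovalent salt. The reaction buffer's
ionic strength is not standardized, so the salt term is a configurable
condition rather than a constant; the entropic correction was chosen as the
standard companion of the unified table. Only perfect-match duplexes are
scored — matches are exact substrings by construction — so mismatch and
dangling-end terms, RNA:DNA hybrids and Mg²⁺ corrections are out of scope.
Tm is computed on the matched segment, not the full probe.

## Probe screening

`scan` finds **all maximal exact same-orientation shared substrings** of
length ≥ 11 (i.e. >10 nt, the cleavable minimum) between probes and
transcripts, via a k-mer index (k = threshold) with bidirectional extension;
every maximal match is reported once, sorted stably. Orientation: probes
are sense-strand, cDNA is antisense, so a probe threatens any transcript
*containing* the probe subsequence in sense orientation; opposite-strand
scanning exists behind a flag for exploratory use. Genome annotation
parsing is deliberately avoided: the user supplies transcript FASTA plus a
category table (rRNA_target / other_ncRNA / mRNA), which any genome can be
reduced to with standard tools.

The per-probe summary separates the full-length intended-target Tm from the
hottest off-target Tm (an explicit `none`, never 0, when there is no
off-target hit); the hybridization window is
`(max off-target Tm + margin, min target Tm − margin)` with a 3 °C default
margin, recommending the midpoint. Whether the original screening tool
reported every match or only the best per pair is not documented; this
implementation reports every maximal match and summarizes separately.

`design_probe_set` tiles a target greedily left to right: each next window
sits as far right as the spacing rule allows, and among candidate starts
within a 5-nt slack the window with the largest (target Tm − best
off-target Tm) differential wins, rightmost on ties. Windows whose best
off-target Tm comes within the margin of the hybridization temperature
(default 48 °C) are disqualified; a fully blocked step is an error naming
the interval. Probes of ≤ 22 nt deplete less reliably and are flagged
wherever they appear.

## Simulator

`libsim` emulates the experiment the analyses consume:

* **Pool**: one rRNA-like transcript (1800 nt, abundance weight 200) plus
  50 mRNA-like transcripts (500–2000 nt, weight 1), random sequence at 45%
  GC — a caricature of rRNA dominance in total-RNA libraries, fully
  configurable.
* **Fragmentation** is modelled directly as transcript choice proportional
  to `weight × length` followed by a uniform draw of (5′ position, length)
  within the size selection (default 25–200 nt, reconciling the
  slightly wider range quoted elsewhere in favour of the gel-selection
  figure). The analyses depend only on this joint distribution, so explicit
  breakpoint chains would add nothing controllable.
* **Treatment**: one fragmentation is split into two equal aliquots
  (mirroring the split-aliquot experimental design); each cleavable insert
  in the treated half is removed independently with probability `p_cut`.
* **Emission**: alignment TSV (library, transcript, 5′ position, insert
  length) and/or FASTQ of the first 150 nt from each insert 5′ end at
  constant quality. A fixed seed yields byte-identical files.

Not emulated: sequencing errors, adapter/poly(A) artifacts, PCR bias,
positional fragmentation bias, and probe failure beyond the length flag.
Passing tests therefore demonstrate correctness of the depletion arithmetic
and estimators under ideal sampling, not robustness to real-data artifacts.

## Read-density analyses

Reads are the minimal record (library, transcript, 5′ position, insert
length); SAM/BAM input keeps primary alignments only, with insert length
taken from the query length. Hierarchical read mapping and quality trimming
are delegated to external tools; `clip_and_filter` performs only the exact
3′-adapter prefix trim (≥ 8 nt), poly(A) stripping (runs ≥ 5), and the
11-nt minimum-length filter.

* **Ratio profiles**: per-position 5′-end counts → centered moving average,
  window 9 nt, truncated (not NaN-padded) at transcript ends so profiles
  stay defined at termini → each library divided by its mRNA-mapped read
  count within the insert-size group (library-loading normalization) →
  treated/untreated × 100. Positions where the untreated smoothed density
  falls below `1e-6` of the untreated library total are masked rather than
  reported as unstable ratios (how zero-coverage positions were originally
  handled is unstated; masking is this package's choice).
* **Pileups**: per-probe profile segments re-indexed to x = position −
  footprint end (x = −1 is the probe's last base), smoothed with a 7-nt
  window, averaged across probes at each x.
* **Depletion efficiency** = 100 − min of the probe-averaged curve over
  the full-cleavage plateau `x ∈ [−(probe_len + min_insert − min_duplex),
  −min_duplex]`. Averaging across probes *before* taking the minimum is
  deliberate: the minimum of per-probe noisy curves is biased low, whereas
  the minimum of the averaged curve recovers `100·p_cut` to well within 2
  percentage points at 2×10⁵ inserts (verified for p_cut 0.5/0.9/1.0).
  "Functional" probes are all probes minus an explicit exclusion list.
* **Inter-probe ratios**: reads with 5′ ends between adjacent footprints,
  extended 10 nt into each, counted per library, mRNA-normalized as above,
  against the footprint-edge gap distance (the exact edge convention for
  "distance" is not printed anywhere authoritative; footprint-edge gap is
  used and documented).
* **ORF bias table**: raw per-ORF counts per library annotated with the
  hottest off-target probe match inside the ORF (`none` when unmatched),
  ready for a treated-vs-untreated scatter.
* **Duplication test**: available positions P = ORF length − median read
  length; coverage = n/P; observed duplicates = n − distinct 5′ positions;
  the expectation is the *mean* (the summary statistic is this package's
  choice) over ≥ 100 uniform reshuffles for ORFs with > 10 reads and ≥ 500
  for 2–10 reads; ORFs with < 2 reads or P ≤ 0 are skipped.

## Numerical and design notes

* Degenerate inputs fail loudly: ambiguous bases reaching the
  thermodynamic model, non-positive Tm denominators, zero mRNA reads in a
  normalization group, empty GC input, overlapping footprints (collapsed
  with a warning).
* Insert-size group membership uses inclusive bounds on the insert length.
* The survival profile reports 1.0 at 3′-terminal positions too close to
  start any in-range insert (no reads can originate there).
* Test problem sizes: oracle equivalence runs 1,000 random scanner
  instances and a 2,000-nt exhaustive survival enumeration; parameter
  recovery and the bias check simulate 2×10⁵-insert pairs — sizes at which
  the binomial sampling error is several times smaller than the asserted
  tolerances.
* The command-line layer is a thin wrapper: every subcommand echoes its
  effective configuration, seed and version into `run.log`, accepts a flat
  YAML defaults file, and uses exit codes 0/2/3 (success/usage/data).
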