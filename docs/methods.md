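# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Array detection

`find_arrays` is a seed-and-extend periodic-repeat finder in the spirit of
CRISPRfinder/CRT-class tools, with explicit, testable rules:

1. every k-mer of the genome is indexed (`seed_kmer`, default 16 nt);
2. k-mers recurring ≥ `min_units` (3) times whose consecutive occurrence
   gaps fall in the plausible repeat+spacer period window are chained
   (bounds derive from `min_dr_len`/`max_dr_len`, default 23–55 nt, and
   the spacer/DR length ratios 0.6–2.5);
3. each chain is extended left and right while the column is **unanimous**
   across the chained units, capped by `max_dr_len` and by unit
   non-overlap;
4. the positionwise majority consensus is derived (ties go to the
   lexicographically smallest base, for determinism);
5. degenerate repeat units with up to `max_unit_mismatches` (4) mismatches
   against the consensus are absorbed greedily — beyond either end of the
   chain (terminal repeats carrying SNPs) and inside any gap too long to
   be a single spacer (units whose seed k-mer was broken by a SNP);
6. boundary columns that the full unit set reveals as unconserved (more
   than `n_units // 4` deviants) are trimmed;
7. overlapping candidates are resolved preferring more units, then a
   longer consensus, then the leftmost start; arrays are reported on the
   forward strand, spacers numbered left to right.

Strict unanimity in step 3 rather than a tolerant majority is deliberate:
a chain can exclude a SNP-bearing unit, and a tolerance calibrated to the
full array then lets the window creep past the true boundary; degenerate
units are recovered by absorption instead, and step 6 removes the rare
creep that a small chain can still produce. Orientation (leader-side)
calling and reverse-strand array search are out of scope; cas genes are
not annotated.

## Spacer→protospacer matching

`align_spacer` runs Smith–Waterman local alignment of each spacer against
both strands of each target, with blastn-short-like scoring for 29–30-nt
queries: match +1, mismatch −3, and BLAST-style affine gaps where a gap of
length L costs 5 + 2L (realized in Biopython's `PairwiseAligner` as
open −7 / extend −2). Locally optimal non-overlapping hits above
`min_score` (default 18) are reported by recursing into the target
segments left and right of each accepted hit. Per hit:

* `%ID` = matches / alignment columns (gap columns included — BLAST
  `pident` convention);
* `%cov` = spacer positions inside the local alignment / spacer length;
* `%HQ` = `%ID × %cov / 100`, kept at full precision; display rounding is
  nearest integer, half up (so 82.56 → 83 and 86.49 → 86), which keeps
  printed values reproducible without losing ranking fidelity.

The reporting filter is strictly greater than `hq_threshold` (80). Ties in
the ranking break by spacer id, target id, then coordinate. E-values are
deliberately not computed — they are inadequate for queries this short —
and no remote databases are queried; `ingest_tabular_hits` accepts BLAST
`-outfmt 6` files for searches run elsewhere (1-based inclusive
coordinates converted, `sstart > send` read as a minus-strand hit).

## PAM inference

Flanks of length `flank_len` (10) are cut adjacent to each passing hit's
footprint and reoriented so that "3′" always means 3′ of the protospacer;
contig edges are N-padded and flagged, and N observations are dropped from
that position's denominator rather than imputed. The consensus keeps, per
position, every base with frequency ≥ `min_base_freq` (default 0.2, which
guarantees a non-empty set) and maps the set through the IUPAC code. Both
sides are always reported so the user can judge which flank carries
signal; the headline consensus defaults to the 3′ side by analogy with the
well-characterized *S. pyogenes* 5′-NGG-3′, since for a novel Cas9 the
informative side is an empirical question. Reports with support < 10
carry an explicit low-support warning.

## GC content and the HGT test

`sliding_gc` computes the per-window GC fraction (window 120 bp, step 1 by
default; the step is configurable, step 1 being the most conservative
profile) via cumulative sums, with results identical to naive per-window
recounting. N bases are excluded from numerator and denominator
everywhere.

`locus_vs_background_test` builds the 2×2 table of G+C vs A+T counts for
the locus (minus excluded regions — typically the CRISPR array, whose
repeat structure skews composition) against the whole chromosome, and
computes the two-tailed Fisher exact p: the sum over all tables with the
observed margins whose hypergeometric probability is at most that of the
observed table, evaluated in log space (log-gamma) over the support, with
a relative tolerance of 1e−7 when comparing log-probabilities so that
equal-probability tables land on the correct side. When every table in
the support is included the p-value is exactly 1 by construction. The
Fisher exact test is the primary method; the pooled two-proportion z-test
is reported alongside as a cross-check and substitutes for the exact
computation (flagged `normal_approx`) only when the smallest table margin
exceeds 100,000. `gc_delta` reports feature-vs-genome GC differences in
percentage points at one decimal, signed.

When the pipeline has no user-supplied locus BED, the GC stage defaults
the locus to the detected array plus a 5-kb upstream margin standing in
for the cas operon (array excluded from counting); the definition used is
always echoed in the report.

## Synthetic data: what it emulates, and what it does not

`generate_dataset` draws every base from one `numpy` PCG64 generator
seeded from the spec, so identical spec+seed gives byte-identical FASTA.
Defaults encode the study conditions: a 100-kb background at per-base G+C
probability 0.665; a 5.6-kb cas-like insert at 0.56; an array of 22 36-nt
repeats alternating with 21 unique spacers (nineteen 30-mers, two
29-mers); a repeat-SNP plan of 19 identical units, 3 substitutions in the
terminal unit, 1 in an interior unit and 1 in the opposite terminal unit;
eight planted protospacer hits at (%ID, %cov) pairs
(100,100) ×2, (100,97), (90,100), (93,97), (93,93) ×2, (96,86) split
across strands; a 3′ PAM template `WGR`; and two decoy targets.

Three generator properties make the ground truth exactly recoverable, and
are design choices rather than accidents:

* **Balanced sampling of degenerate positions.** The concrete letters
  behind each degenerate PAM position, and every 5′-flank column, are
  stratified across the planted hits (counts differ by at most one)
  instead of sampled i.i.d. With eight supporting flanks, i.i.d. sampling
  would leave the frequency matrix off its expectation often enough that
  neither the planted motif nor the no-signal null would be read back
  reliably; stratification makes the small-support matrix reflect the
  intended distributions, which is the property the inference stage is
  being tested against.
* **Alignment-stable substitutions.** Planted substitutions sit ≥ 5 nt
  from either end of the planted copy and ≥ 6 nt apart, and the target
  base just past a coverage-truncated copy is forced to differ from the
  spacer base it would pair with. Every match run around a substitution
  then outweighs the mismatch penalty, so the optimal local alignment
  footprint equals the planted footprint exactly and realized %ID/%cov
  match the request to single-substitution granularity.
* **Decodable array boundaries.** Spacer draws are rejection-checked so
  the columns immediately outside each repeat are not (near-)unanimously
  conserved; without this, a small array can be genuinely ambiguous (a
  chance-conserved flanking column is indistinguishable from a repeat
  column) and no detector could recover the planted boundary.

Coverage below 100 % is realized by truncating the planted copy from its
3′ end (one documented convention rather than an unstated mixture), with
the PAM kept adjacent to the truncated end. Substitution counts use
round-half-up. The generator does **not** emulate phage genome realism
(no genes or modules), indel variation in protospacers, repeat
degeneracy beyond the SNP plan, compositional heterogeneity along the
background, or sequencing artefacts — so passing tests demonstrate
correctness of the decomposition, scoring, inference and testing
machinery under the stated statistical model, not performance on real
assemblies with diverged repeats or indel-containing protospacers.

## Problem sizes and numerical conventions

Tests and the acceptance script use the default 100-kb genome (seconds
per replicate): 20-seed batches for GC-recovery/significance and PAM
recovery, 100 replicates at 55 kb for the type-I-error calibration of the
exact test, and property sweeps with sequences ≤ 40 nt (alignment vs a
textbook Gotoh oracle) and margins ≤ 30 (Fisher vs full enumeration).
Coordinates are 0-based half-open internally, converted to 1-based
inclusive only at GFF3/BLAST boundaries. Consensus ties, hit-ranking
ties and absorption ties all have fixed documented tie-breaks so every
stage is deterministic given its inputs. CLI exit codes: 0 for success
(including empty biological results), 2 for data errors, and click's
native handling for usage errors.

## Known limitations

* The detector assumes spacer lengths within 0.6–2.5× the repeat length
  and at least three repeat units; arrays outside that geometry are
  invisible by design.
* PAM inference reports what eight-ish flanks can support: a degenerate
  consensus plus an explicit warning, not a validated motif.
* The GC test treats bases as independent Bernoulli events; real genomes
  have autocorrelated composition, so on real data the p-value is best
  read as a strength-of-evidence summary rather than a calibrated error
  rate (the type-I calibration holds under the generator's i.i.d. model).
* The locus-vs-chromosome table overlaps (the chromosome counts include
  the locus), matching the stated two-proportion framing; for a 5.6-kb
  locus in a 100-kb chromosome the effect is a slight conservatism.
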