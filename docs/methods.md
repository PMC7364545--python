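# Methods

## Pipeline model

`vdjflow` treats repertoire annotation as a pure function of the input
file and the run configuration. The stages run in a fixed order:

1. **Count estimation.** The first 500 records are parsed; the mean
   decompressed bytes per record divides the total decompressed file size.
   Files with ≤ 500 records are counted exactly, and the estimate is exact
   whenever all records occupy equal bytes. For gzip inputs the remainder
   of the stream is decompressed (without parsing) to measure the true
   decompressed size; extrapolating from compressed byte counts is
   unreliable because the decompressor reads ahead of what it returns.
2. **Chunk planning.** Records per chunk defaults to
   `min(50000, max(1, ceil(N / (4 × workers))))`: about four chunks per
   worker evens out stragglers, and the cap bounds temp-file size. A
   user-supplied chunk size always wins. Chunks preserve input order and
   concatenate back to the input exactly.
3. **Annotation.** One worker process per chunk slot; a worker owns a
   whole chunk (annotate → parse → finalize → filter) and shares no
   mutable state with the driver. The external backend is invoked once
   per chunk, never per read. Finished chunks are merged strictly in
   chunk-index order, which makes the output invariant to worker count
   and chunk size; the queueing discipline is FIFO by chunk index.
4. **Filtering, serialization, accounting.** Kept records stream to
   gzip-NDJSON (one JSON object per line; gzip header mtime pinned to 0
   so reruns are byte-identical) or AIRR TSV. A sibling
   `*.stats.json` carries the run summary; `--emit-removed` writes the
   discarded reads with reasons.

## Built-in annotator

The built-in backend exists so the pipeline is complete and testable
without an external aligner; it is a deliberately simple annotator, not a
re-implementation of IgBLAST's composition-based statistics or gapped
IMGT numbering.

* Local alignment uses the Smith–Waterman recurrence with affine gaps
  (match +2, mismatch −1, gap open −5, gap extend −2).
* Orientation is decided by the best V-gene score of the read versus its
  reverse complement (ties keep the forward strand); all downstream
  coordinates live on the annotation-orientation sequence.
* Segment order follows the biology: top-3 V hits on the whole read; J
  genes aligned right of the best V end; D genes between best V end and
  best J start, requiring ≥ 5 aligned bases (shorter D matches are
  noise).
* E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with fixed
  K = 0.1 and λ = 0.5, m the full read length and n the summed length of
  the searched segment's germline set. Only ordering and thresholding
  matter to the pipeline, so fixed constants are preferred over
  estimated ones: they make expected values exactly reproducible. Hits
  sort by ascending E-value, then descending score, then germline file
  order (a deterministic tie-break); a segment whose best E-value
  exceeds 1000 is reported as no call. Uncallable reads produce empty
  hit lists, never errors.

### Junction and flags

Junction anchors (the conserved cysteine codon near the V 3' end; the
conserved tryptophan/phenylalanine codon in J) travel in a two-column
sidecar TSV next to the germline FASTA files, keeping the FASTA standard.
An anchor codon is projected through the alignment blocks onto query
coordinates; if it is clipped, gapped or split, the junction is absent —
a legitimate outcome, not an error. The CDR3 is the junction minus the
two anchor codons (IMGT convention); `cdr3_start`/`cdr3_end` are emitted
1-based inclusive per the AIRR wire format while all internal intervals
are 0-based half-open.

Backend-supplied fields always win; derivation only fills gaps:

* `vj_in_frame` falls back to junction length divisible by three (a
  junction-less read is treated as out of frame);
* `stop_codon` is scanned over the aligned V-through-J region translated
  in the V-gene reading frame — untranslated primer tails outside the
  alignment should not fail a read;
* `productive` = `vj_in_frame AND NOT stop_codon`.

## Filters

| filter | rule | default |
|---|---|---|
| evalue | V **and** J support ≤ threshold | on, 1.0e-6 |
| stop_codon | translated V–J region stop-free | on |
| in_frame | junction length ≡ 0 (mod 3) | on |
| cdr3_present | non-empty CDR3 called | on |
| cdr3_phred | every CDR3 base ≥ min Phred | off until a threshold is given |

Unannotatable reads fail the applicable filters rather than raising, so
the pipeline never halts on a bad read; all enabled filters are evaluated
on every read (no short-circuit) so per-reason counts are complete. FASTA
input (no qualities) passes the Phred filter by definition, and a read
without a CDR3 passes it too — the presence filter owns that failure.

## Synthetic repertoire generator

Each read is `V[0 .. end−trim] + N-insert + D-core + N-insert +
J[trim .. end]` over the packaged toy IGH database (3 V of 288 nt, 2 D,
2 J of 48 nt, all anchors known), followed by somatic hypermutation as
uniform per-base substitutions and sequencing errors as further
substitutions that drop the Phred score at the error position (40
elsewhere, 10 at errors). Defaults: trims uniform 0–3 per junction end,
N-inserts uniform 0–6 nt, mutation rate 2%, error rate 0.5% — 2% is a
typical bulk somatic-hypermutation load for class-switched antibody
repertoires and 0.5% a conservative short-read substitution error rate.

Rearrangements are resampled (bounded attempts) until the junction is in
frame and the pre-mutation read is stop-free: the generator emulates an
expressed cDNA repertoire, in which non-productive chains are a small
minority, rather than the raw two-thirds-out-of-frame genomic
recombination odds. Mutation and sequencing noise can still break frames
or introduce stops downstream, which is what the filters are for. Each
read uses its own RNG stream (`seed, read-index`), so outputs are
byte-identical under a fixed seed and the rearrangement draw is
independent of how many random numbers the noise model consumes.

What the generator does **not** emulate: clonal/lineage structure, indel
sequencing errors, position-dependent quality decay, biased gene usage,
hotspot-targeted hypermutation, or realistic germline-set sizes. Passing
tests therefore demonstrate the pipeline's correctness contracts
(recovery, determinism, accounting, round trips) on idealized reads, not
annotator accuracy on real repertoires — that depends on the external
backend and germline database a user supplies.

The six-read filter fixture is engineered so each quality rule trips
exactly once: a clean read; a read keeping only the last 22 V bases (V
E-value ≈ 2e-6, just above threshold, while the anchor still maps); an
in-frame TAA; a 1-nt junction insertion whose frameshifted tail is
verified stop-free (so only the frame rule fires); a V truncated at the
cysteine codon joined directly to a J anchor codon, giving a junction of
exactly C+W/F and a zero-length CDR3 (junction present and in frame, so
only the CDR3-presence rule fires — the J gene is chosen analytically so
the V alignment cannot chance-extend across the join); and a clean read
with one CDR3 base at Phred 2.

## Numerical and design choices

* Quality encoding is fixed to Phred+33; characters below `!` raise an
  encoding error rather than guessing Phred+64.
* The estimator samples 500 records — enough for a stable mean at
  negligible cost; chunk-balancing constants (4 chunks/worker, 50,000
  cap) are package choices and config-overridable.
* "Zipped JSON" output is gzip NDJSON, not a JSON array: it streams and
  inserts line-by-line into document databases.
* Translation uses the standard genetic code; stops print `*`, codons
  with unresolvable ambiguity print `X`, trailing partial codons drop.
* `best_only` output drops the hit lists but never changes rank-1 fields.
* The AIRR TSV parser folds consecutive rows sharing a `sequence_id`
  (the one-row-per-hit dialect) into one record's hit lists and preserves
  unknown columns verbatim in an `extras` map.

## Problem sizes

The test suite simulates repertoires of 200–10,000 reads (a 10,000-read
run exercises the output-footprint measurement; 1,000 reads the
parallel-determinism and recovery checks), sizes at which every contract
the pipeline makes is already observable. `scripts/acceptance.py` uses
10,000 reads.

## Known limitations

* The built-in backend has no indel-aware frame logic beyond what the
  alignment blocks imply, no IMGT region delineation (FR/CDR1/CDR2), and
  fixed Karlin–Altschul constants; treat its E-values as an ordering, not
  a calibrated significance.
* Light-chain/TCR loci work (D genes optional) but the packaged toy
  database is heavy-chain-shaped.
* No paired-end merging, trimming, UMI consensus or clonotype clustering;
  those belong upstream/downstream of annotation.
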