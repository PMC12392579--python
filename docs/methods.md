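# Methods

## Model and procedure

`lrassign` treats long-read quantification as a latent-origin problem:
each read was sequenced from exactly one transcript, the transcript was
chosen with probability equal to its relative abundance ρ<sub>t</sub>, and
the read's alignment evidence (score, end positions, position on the
transcript) is informative about which transcript that was. The
observed-data likelihood is a product over reads of
Σ<sub>t</sub> ρ<sub>t</sub>·υ<sub>rt</sub>·ω<sub>rt</sub>·f<sub>η</sub>(r,t)·σ<sub>rt</sub>,
and EM maximizes it in ρ while the per-pair prior factors are held fixed.
The pipeline has three stages:

1. **Alignment intake** (`alignment_io`). SAM/BAM (pysam) or PAF records
   of reads aligned to transcript *sequences* by a non-spliced aligner.
   Coordinates are normalized to 0-based half-open; the score comes from
   the `ms` tag with `AS` as fallback. Multiple alignments of the same
   (read, transcript) pair are reduced to the maximum-score one (ties:
   smaller start, then end). Reverse-strand hits are discarded by default
   because reads should come from the transcript's sense strand.
   Supplementary alignments are treated as secondary. If the dedup or the
   strand filter removes a read's primary record, its best surviving
   record is promoted to primary — the end filters need a well-defined
   reference alignment per read.
2. **Compatibility construction** (`compatibility`). One pass converts the
   deduplicated records into the sparse prior matrix
   X<sub>rt</sub> = υ·ω·f<sub>η</sub>·σ. X is computed once and never
   changes during EM (except for the drop pruning below).
3. **EM** (`em`), exposed as the scikit-learn estimator
   `AlignmentGuidedEM`: uniform initialization over the transcripts that
   received at least one alignment, E-step
   α<sub>rt</sub> = ρ<sub>t</sub>X<sub>rt</sub>/Σ<sub>t′</sub>ρ<sub>t′</sub>X<sub>rt′</sub>,
   M-step rc<sub>t</sub> = Σ<sub>r</sub>α<sub>rt</sub>, ρ = rc/N with N
   fixed at the number of assigned reads.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lambda_decay`) | 5 | score-gap decay scale (score units); σ = e^(−gap/λ), so a 5-point gap ≈ e⁻¹ |
| β<sub>s</sub>, β<sub>e</sub> | −∞ (off) | 5′/3′ end-distance tolerances relative to the primary alignment; presets: direct RNA (−800, off), cDNA/PacBio (−600, −500) |
| `psw` | off | position-specific coverage weights f<sub>η</sub> |
| convergence threshold | 10 | absolute L1 change of the read-count vector; sized for datasets with millions of reads — tighten to ~1e−6 on small instances |
| `max_iter` | 5000 | iteration cap; hitting it warns but returns |
| drop fraction f | 0.1 | drop threshold τ′<sub>r</sub> = (1+f)/\|T<sub>r</sub>\| |
| push seed | 0 | RNG seed for sampling hard assignments |
| `-N` (aligner wrapper) | 181 | secondary alignments requested from minimap2, matching the deepest human locus so no candidate isoform is lost |

## Numerical and design choices

- **End filters.** The pass rule is
  δ<sup>rt</sup> − δ<sup>rt′</sup> ≤ |β| (candidate's end distance may
  exceed the primary's by at most the tolerance); β = −∞ disables a
  filter. The primary alignment always passes (difference 0), so every
  read keeps at least one compatible transcript. Filters are off by
  default: optimal tolerances vary by protocol, and they change results
  little in practice.
- **Position weights.** η<sub>k</sub> = c<sup>t</sup> − c<sub>k</sub><sup>t</sup>
  is the per-base coverage deficit; since c<sup>t</sup> is the mean of the
  c<sub>k</sub>, the η sum to zero per transcript, and the zero-shifted
  vector η + |min η| sums to l(t)·|min η|. Uniformly covered transcripts
  therefore have no usable signal; they are flagged degenerate and their
  alignments use f<sub>η</sub> = 1. Likewise, if *all* of a read's entries
  end up zero under psw (its alignments sit entirely on zero-weight
  positions), the row is rebuilt with f<sub>η</sub> = 1 so the read is
  never silently lost. The coverage profile is computed once, from all
  deduplicated alignments, before EM.
- **Convergence bookkeeping.** "Total change in read counts" is the L1
  distance between successive rc vectors. The previous-rc vector starts
  at zero, so iteration 1's change equals N; with the default threshold
  of 10 this means instances under 10 reads stop after one cycle — the
  default is an absolute count intended for realistic library sizes.
- **Drop.** Applied exactly once, right after the first E-step, then a
  second E-step re-normalizes against the pruned X before the first
  M-step. |T<sub>r</sub>| is the read's compatibility count at drop time.
  The literal rule can empty a row (three-way tie with f > 0), so the
  row's argmax (tie: lowest transcript index) is always retained. After
  the drop, X is fixed, which restores the standard EM guarantee that the
  log likelihood is non-decreasing (a property the test suite checks).
- **Determinism.** Sparse rows keep sorted transcript indices and all
  reductions run in that fixed order, so repeated runs are bit-identical.
  Push sampling uses a single seeded `numpy` generator.
- **Outputs.** Transcripts present in the annotation but never aligned
  are reported with zero counts rather than omitted. CPM normalizes by
  the number of reads with at least one retained alignment (not the raw
  FASTQ read count). Fractions are printed with 6 significant digits.
- **Evaluation.** TP is the read mass placed on the true origin, FP the
  assigned mass elsewhere, FN the mass not on the origin (1 − TP per
  read), so TP + FN equals the number of reads under fractional,
  even-split and unassigned input shapes alike. Recall divides TP by the
  total number of sequenced reads; precision by TP + FP. The log-scale
  Pearson correlation uses log2(count + 1) — base and pseudocount are a
  package choice, recorded here because other conventions exist. An
  optional `min_count` filter drops transcripts estimated below a cutoff
  (commonly 1 read) before comparing abundances.

## The synthetic data generator

`simulate` emulates the conditions the method is built for, without
external downloads:

- **Transcriptome**: 10 loci × 5 isoforms (50 transcripts). Isoforms of a
  locus share a random 3′ suffix of 200–400 nt and carry unique 5′
  prefixes of 100–800 nt (an alternative-transcription-start structure),
  giving total lengths of roughly 300–1200 nt — scaled-down but
  structurally faithful multi-mapping.
- **Abundances**: Dirichlet(0.5) across transcripts — sparse-ish, with a
  realistic dynamic range — unless an explicit ρ is supplied.
- **Reads**: 10,000 by default; origins multinomial in ρ; length uniform
  between 30% and 100% of the transcript; 70% of reads are 3′-anchored
  (direct-RNA-like coverage bias), the rest uniformly placed; 2%
  per-base substitution errors, the scale of current ONT basecallers.
- **Alignments**: score-faithful, not sequence-faithful — scores are
  match_reward × aligned_length − penalty × (errors in the aligned part),
  with the same-locus isoforms receiving clipped alignments over the
  shared suffix. This reproduces exactly the geometry and score structure
  the EM consumes, which is what the tests target; it does not model
  indels, chimeras, spurious cross-locus hits, or aligner heuristics, so
  passing tests demonstrate correctness of the assignment machinery, not
  end-to-end accuracy on real nanopore data.
- The `unambiguous` variant (error-free reads forced to cover ≥50 nt of
  unique sequence) makes every read resolvable: the pipeline must then
  achieve perfect precision/recall and integer-exact counts, which the
  acceptance tests assert.

Problem sizes in the test suite (≤20×5 random instances for oracle
comparisons, 10,000 reads for statistical recovery, 10,000 seeded draws
for push consistency) were chosen so the whole suite runs in seconds
while keeping the statistical assertions well-powered.

## Known limitations

- Quantification assumes the supplied transcriptome is complete; novel
  isoforms absent from it will absorb reads incorrectly (pairing with an
  assembler that emits sample-specific transcripts is the intended
  workflow).
- The drop step is greedy and irreversible; with very low-coverage data
  it can prune a correct low-prior compatibility.
- Effective-length/TPM modeling is deliberately absent: each long read
  represents one transcript molecule, so CPM is the natural unit.
- The position-specific weights need meaningful coverage to help; on
  shallow data they degenerate to the unweighted model by design.
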