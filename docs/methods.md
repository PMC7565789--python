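# Methods

## Generative model of blocked-rRNA capture

The simulator (`embrseq.simulate`) follows the causal chain of a
poly-A-tailing, T7-amplified bacterial RNA-seq protocol with rRNA blocking
primers. Each emitted read is produced by:

1. **Pool draw.** A source transcript is drawn with probability proportional
   to `class_abundance[class] × gene_weight`. Defaults place 95% of the pool
   mass on rRNA, 3% on tRNA and 2% on mRNA, the composition typical of
   bacterial total RNA. Within classes, rRNA weight is proportional to
   transcript length (long transcripts contribute more molecules to a
   fragment pool), tRNAs are uniform, and mRNA gene weights are log-normal
   (σ = 1 by default), giving the multi-order-of-magnitude expression spread
   seen in real libraries.
2. **3′-end placement.** With probability `1 − δ` (`frag_rate`) the
   capturable 3′ end `E` is the native terminus. Otherwise the molecule is a
   fragment whose reads concentrate at *hotspots*: a hotspot component plants
   the read start at the hotspot coordinate ± uniform jitter (`τ_j = 5` nt)
   and draws the fragment 3′ end a further `d` nt downstream of the read end,
   with `d` induced by the fragment-length mixture; the remaining fragment
   mass (`frag_uniform_weight`, default 1.5 against weight 1 per hotspot) is
   a uniform background. Hotspot coordinates are therefore *read-start*
   (mapped-position) coordinates — the convention in which hotspots are
   observed and reported — and the fragment 3′ ends they generate lie
   ~R to ~R+(f_max−R) nt downstream, which is exactly the region a hotspot
   blocker placed ~100 nt downstream of the coordinate covers. This is the
   one place where the model structure was genuinely open; anchoring the
   point mass on the read start makes the observed-profile coordinates, the
   blocker-placement rule and the caller's recovery tolerance mutually
   consistent.
3. **Capture.** Poly-A tailing/capture succeeds with probability
   `polyA_baseline[class] × (1 − β(E))`, where `β(E)` is the efficiency of
   the strongest blocker whose annealing interval contains `E` within
   `block_tolerance` (20 nt, reflecting that a hybrid near the 3′ end still
   suppresses tailing). mRNA has baseline 1.0; rRNA and tRNA baselines are
   far smaller, encoding preferential poly-adenylation of mRNA. Rejected
   molecules are redrawn until `n_reads` are emitted (rejection sampling, the
   direct analogue of sequencing a library to fixed depth).
4. **Read synthesis.** The right mate is `R = 50` consecutive sense-strand
   bases ending within the fragment, with per-base substitution rate
   `ε = 0.001`; the left mate is the 6-nt sample barcode followed by poly-T.
   Base qualities are constant placeholders; quality modeling is out of
   scope.

Because capture is plain rejection sampling, the emitted class composition is
`f_c = Σ_{t∈c} a_t p_t / Σ_t a_t p_t` with
`p_t = polyA · Σ_x P(E = x)(1 − β(x))`. `expected_class_fractions` evaluates
this exactly by enumerating the discrete distribution of `E` per reference
(native point mass, uniform background, and the jitter ⊗ fragment-length
convolution per hotspot). The same per-position `β` array drives both the
closed form and the sampler, so the oracle is exact by construction rather
than approximate.

**Presets.** The `control` preset (no blockers) solves the poly-A baselines in
closed form so the expected fractions are rRNA 64%, tRNA 0.37% — the
composition a no-blocker library shows when mRNA is preferentially tailed.
The `embr` preset adds 30-nt 3′-terminal blocker intervals on all three rRNAs
and solves a single shared efficiency β (Brent's method on the closed form)
so the expected rRNA fraction is 16%, i.e. a calibrated 4-fold depletion;
with the default pool this lands at β ≈ 0.97. The preset fragmentation rate
is δ = 0.08: large enough that hotspot structure is clearly visible in the
blocked library's residual rRNA (most residual reads are fragment-derived,
since native-end capture is efficiently blocked), small enough that a 16%
rRNA fraction is attainable with 3′-end blockers alone — with δ much above
0.1, unblockable fragment ends alone exceed 16% of captures. Fragment
lengths are uniform on 60–160 nt.

## Demultiplexing and alignment

Barcodes are the first 6 nt of the left mate; exact whitelist match by
default (an opt-in single-mismatch rescue discards barcodes equidistant from
two whitelist entries). Assigned plus discarded always equals input. Only
the right mate is aligned.

`align_exact` is a deterministic k-mer-seed (k = 25), ungapped, sense-strand
matcher for synthetic data: candidate diagonals from two non-overlapping
seeds per read, best hit by fewest mismatches, ties within a reference
resolved leftmost, ties across references reported unmapped-ambiguous and
excluded from counting — a deliberate determinism-over-yield divergence from
production aligners, which assign multi-mappers arbitrarily. Real data
should be mapped externally and ingested with `read_sam` (primary alignments
only; SAM 1-based positions become internal 0-based).

## Quantification conventions

Class fractions use mapped reads as denominator. RPM is
`count × 10⁶ / total mapped reads` (configurable to an mRNA-only
denominator); a gene is detected above threshold *T* when RPM > *T*
strictly, and detected at all when it has ≥ 1 read. Expression correlation
is Pearson's r on `log10(RPM + 1)` over the union of detected genes — the
log scale matches the dynamic range over which such libraries are compared;
replicate-overlap analyses pool replicate counts before thresholding.
Downsampling is uniform without replacement and seed-deterministic.

## Hotspot calling

The profile counts read starts per position; the cumulative curve is its
normalized partial sum (5′→3′, in percent). The caller slides a
`w = 50` nt window and marks it candidate when its read share exceeds
`max(c·w/L, s)` with `c = 5` (fold over uniform) and `s = 0.02` (absolute
share); overlapping candidates merge, and each merged region is reported at
its read-start argmax, 1-based. The thresholds are the package's own
defaults — chosen so that point masses holding a few percent of a
reference's reads are called while multinomial fluctuations of uniform data
essentially never are (the test suite bounds the false-call rate at < 0.05
calls per reference over 200 uniform simulations) — and are fully
configurable. In a blocked library the residual native-3′-end cluster is
itself called as a terminal hotspot; this is real structure, not an
artifact, and downstream primer design may simply skip terminal calls
already covered by a 3′ blocker.

## Melting temperatures and primer design

Tm uses the unified DNA/DNA nearest-neighbor table (stacked-pair ΔH/ΔS with
duplex-initiation terms per terminal base pair and a symmetry correction),
the entropy salt correction `ΔS + 0.368(N−1)ln[Na+]`, and
`Tm = ΔH/(ΔS + R ln(C_T/4)) − 273.15`. Defaults are 50 mM monovalent salt
and 250 nM total strand concentration — ordinary primer-design conditions;
both are configurable, and the engine is cross-checked in the tests against
an independent implementation and a hand-summed 8-mer.

3′-end blockers are fixed 30-mers (reverse complement of the 3′-terminal 30
bases), reported with their Tm but not thresholded — terminal position, not
Tm, is what makes them work. Hotspot blockers start at
`hotspot + 100` nt (downstream = toward the transcript 3′ end, where the
hotspot-derived fragment ends lie), length 30, and are adjusted until
Tm ≥ 65 °C: lengths up to 36 nt, then start shifts within ±20 nt, taking the
smallest satisfying design (shortest, then least-shifted, downstream shift
preferred). An unreachable threshold returns an explicit failure carrying
the best candidate and its Tm rather than raising.

## Conservation entropy

Aligned rRNA 3′ tails (last 100 columns by default) are scored per column by
Shannon entropy over the five symbols {A, T, C, G, −} in base 5, so a
uniform column scores exactly 1 and a monomorphic column 0; `U` is mapped to
`T` on ingest, any other symbol is rejected. Row order never matters.

## Operon 3′-bias profiles

For each read mapping wholly within a multi-gene operon (boundary-straddling
reads are excluded), the strand-aware distance of its 3′-most aligned base
from the operon 3′ boundary is discretized into 50 equal-width bins over the
operon length. "Unique reads" deduplicates by (start, strand) within the
operon — the package's interpretation of read uniqueness, configurable off —
and operons qualify with ≥ 2 genes and strictly more than 200 unique reads.
Per-operon bin vectors are normalized to sum to 1 before averaging, so the
mean profile is itself a probability vector (tested to 1e-9). Bin 1 is
5′-most. Note one geometric subtlety: with reads of length R, the 5′-most
stretch of the distance axis is truncated by R−1 positions, so the 5′-most
bin of even perfectly uniform data sits below the uniform share — the test
suite pins this down with single-base reads (exactly flat) and 50-nt reads
(flat interior, truncated edge bin).

## Pipeline

`run_pipeline` executes simulate → demux → align → quant → hotspots → design
(→ operon-bias when a genome-coordinate SAM and operon table are supplied,
since the transcriptome simulator emits no genome coordinates) and writes
`report.json` with the resolved configuration, per-file SHA-256 checksums and
headline metrics; identical configurations reproduce identical checksums.
Hotspots are read off the blocked sample's residual rRNA when present.

## Problem sizes and determinism

Default analysis-scale runs use 50,000 read pairs per library — enough that
the binomial standard error on a 16% class fraction is ~0.16%, so calibrated
fractions and 4-fold depletion are recovered within a few percent — and
hotspot-recovery simulations use 20,000 fragment-dominated rRNA reads per
seed. All randomness flows from explicit integer seeds through numpy
generators; identical (config, seed) reproduces byte-identical FASTQ, truth
tables and reports.

## What the simulator does and does not show

The generator reproduces the *structure* of blocked-capture data: pool
dominance of rRNA, preferential mRNA capture, blocker suppression at
targeted 3′ ends, hotspot-concentrated fragmentation, log-normal expression
spread and substitution noise. It does not model amplification (IVT) noise,
UMI structure, base-quality profiles, insert-size distributions, secondary
structure or sequence-dependent capture bias, and its reference sequences
are random rather than genomic — so passing tests demonstrate correctness of
the analysis machinery under the stated model, not performance claims about
any particular organism's libraries. Parameters of the capture model are
fit-for-purpose defaults, not values inferred from any deposited dataset.

## Known limitations

* The exact-seed aligner is ungapped and sense-strand only; use an external
  aligner for real data.
* Hotspot-caller defaults are tuned for point-mass-like hotspots atop a
  roughly uniform background; broad, diffuse enrichments may merge or be
  missed at default thresholds.
* A single blocker efficiency β per preset is a simplification; per-blocker
  efficiencies are supported in configuration but not calibrated.
* Conservation scoring ingests an existing alignment; it does not run an
  aligner.
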