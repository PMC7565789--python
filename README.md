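# embrseq

Simulation and analysis toolkit for **blocking-primer rRNA depletion** in
bacterial RNA sequencing.

Bacterial total RNA is roughly 95% ribosomal, and bacterial mRNA carries no
poly-A tail, so poly-A-tailing capture chemistries must be steered away from
rRNA. One effective strategy anneals DNA *blocking primers* to the 3′ ends of
the 5S, 16S and 23S rRNAs: the RNA–DNA hybrid suppresses poly-adenylation
there, blocked cDNA never receives a T7 promoter, and rRNA is excluded from
downstream linear amplification. Residual rRNA reads then concentrate at
narrow fragmentation/capture **hotspots** along 16S and 23S, which can be
suppressed in turn with additional blockers annealing ~100 nt downstream of
each hotspot.

`embrseq` implements the computational side of this workflow for method
developers and bioinformaticians:

* a **generative simulator** of the capture chemistry (class abundances,
  preferential mRNA poly-adenylation, fragmentation with read-start hotspots,
  blocker suppression of capture at targeted 3′ ends) with an exact
  closed-form expectation for the emitted class composition,
* **demultiplexing** by the 6-nt left-mate barcode, a minimal exact-seed
  aligner for synthetic data, and SAM ingestion for externally mapped reads,
* **depletion quantification**: rRNA/tRNA/mRNA fractions over mapped reads,
  fold depletion/enrichment, RPM gene-detection curves, downsampling,
  detection overlap and expression correlation,
* **hotspot analysis**: per-position read-start profiles, 5′→3′ cumulative
  curves and a sliding-window hotspot caller,
* **primer design**: a nearest-neighbor Tm engine (unified duplex parameters,
  entropy salt correction), fixed 30-mer 3′-end blockers, and Tm-thresholded
  hotspot blockers placed ~100 nt downstream of each hotspot,
* **conservation scoring** of aligned rRNA 3′ tails by normalized base-5
  Shannon entropy over {A, T, C, G, −},
* **operon 3′-bias** metagene profiles (50 bins over multi-gene operons).

## The model in brief

A simulated molecule from transcript *t* of class *c* is captured with
probability

```
p_t = polyA_c · (1 − β(E))
```

where `E` is its capturable 3′ end — the native terminus with probability
`1 − δ`, otherwise a fragment end concentrated at hotspots — and `β(E)` is
the efficiency of the strongest blocker whose annealing interval contains `E`
within a tolerance. Rejected molecules are redrawn until the target depth is
reached, so the emitted class composition is exactly

```
f_c = Σ_{t∈c} a_t p_t / Σ_t a_t p_t
```

with `a_t` the pool weight. The package evaluates this closed form from the
discrete distribution of `E` and uses it both to calibrate presets (control:
64% rRNA; blocked: 16% rRNA — a 4-fold depletion) and as the oracle in tests.

Oligo melting temperatures use the unified nearest-neighbor model

```
Tm = ΔH / (ΔS + 0.368 (N−1) ln[Na+] + R ln(C_T/4)) − 273.15
```

at 50 mM monovalent salt and 250 nM total strand concentration by default.

## Worked example

Run the full pipeline — simulate a no-blocker control and a 3′-blocked
library (50,000 read pairs each), demultiplex, align, classify and call
hotspots:

```bash
embrseq run --seed 0 --out demo/
```

The report (`demo/report.json`) metrics from this exact invocation:

```json
{
  "control": {"rRNA": 0.640172, "tRNA": 0.003703, "mRNA": 0.356125},
  "embr":    {"rRNA": 0.161501, "tRNA": 0.008544, "mRNA": 0.829955},
  "fold_rRNA_depletion": 3.9638957479947527,
  "fold_mRNA_enrichment": 2.3305165622379533,
  "hotspots": {
    "rRNA_16S": [104, 683, 1238, 1485],
    "rRNA_23S": [379, 1419, 1637, 2841]
  }
}
```

Reading this: the control library is 64.0% rRNA while the blocked library is
16.2% rRNA with 83.0% of mapped reads from mRNA — a 3.96-fold rRNA depletion
and 2.33-fold mRNA enrichment, matching the preset calibration (closed-form
fractions 0.64 and 0.16) to within sampling noise. The caller recovers the
three hotspots planted on each of the 16S-like (107, 682, 1241) and 23S-like
(375, 1421, 1641) references within a few nt, plus the residual native-3′-end
clusters near each transcript's terminus (1485 and 2841) — real structure in
a blocked library, since 3′-end blocking is efficient but not perfect.
`demo/primers.tsv` then lists the designed 30-mer 3′-end blockers and the
Tm ≥ 65 °C hotspot blockers annealing ~100 nt downstream of each called
hotspot.

Individual stages are available as subcommands (`embrseq simulate`, `demux`,
`align`, `quant`, `hotspots`, `design-primers`, `conservation`,
`operon-bias`) and as plain library functions.

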