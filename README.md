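# tucr — expression analysis of transcribed ultra-conserved regions

Ultra-conserved regions (UCRs) are 481 genomic segments ≥ 200 bp that are
100% identical between human, mouse and rat. Many are transcribed
(T-UCRs), often as long non-coding RNAs, from either genomic strand. This
package implements the analysis pipeline for a strand-specific UCR
microarray — a sense ("plus") and antisense ("minus") probe per UCR,
spotted in quadruplicate, hybridized across tissue panels — for
computational biologists who want each stage of such an analysis as a
tested, reusable library function:

* replicate-spot summarization, absent-call flooring, and the dual
  retention rule (present in ≥ 20% of samples, and > 1.5-fold from the
  probe median in ≥ 20% of samples);
* quantile normalization and log2 transformation;
* tissue-selectivity scoring by information content,
  `IC = log2(N) − H(p)` bits, where `H(p)` is the Shannon entropy of a
  probe's normalized mean-expression profile over `N` tissue systems
  (IC = 0: uniform; IC = log2 N: single-system);
* bidirectional-transcription calling (both strands of a UCR retained);
* differential expression (Welch/pooled t, one-way ANOVA F,
  Benjamini–Hochberg), Wilcoxon rank-sum with exact small-sample p, and
  qPCR ΔCt statistics;
* genomic-context classification of UCR loci (exonic > putative exonic >
  non-exonic) with BED I/O.

Because the platform's real intensity files are not needed to develop or
validate the method, a first-class synthetic generator
(`tucr.synthetic`) emulates the study design — 481 UCRs × 2 strands ×
quadruplicate spots over 16 histological systems — with planted
group-selective probes, planted bidirectional UCRs, log-normal spot noise
and absent calls, all seeded and exactly recoverable.

## Worked example

The `analysis/` scripts run the full narrative on a simulated experiment
with 57 planted bidirectional UCRs and 15 epidermis-selective probes:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_selectivity.py
```

which prints, for the preprocessing and selectivity stages:

```
retained 523/962 probes (floor=32, present>=20%, |FC|>1.5 in >=20%)
  466 sense probes, 57 antisense probes

top 15 probes by IC (bits):
   1 * uc.409-plus    IC=2.697  epidermis
   2 * uc.411-plus    IC=2.653  epidermis
   ...
  15 * uc.413-plus    IC=2.403  epidermis
planted epidermis-selective probes in the top 15: 15/15
bidirectional UCRs called: 57 (planted 57; exact match: True)
```

Reading: of the 962 probes, the 466 tissue-restricted sense probes and
exactly the 57 planted antisense partners survive the retention filter;
all 15 probes planted as epidermis-only occupy the top 15 IC ranks (their
IC ≈ 2.4–2.7 bits of a 4-bit maximum — high, but below 4 because
off-target groups sit at the detection floor rather than zero); and the
bidirectional caller returns exactly the planted 57 UCRs.
`analysis/04_differential.py` and `analysis/05_genomic_context.py`
continue with the differential tests and the ~48/26/26%
non-exonic/putative/exonic class split of the catalog.

The same stages are available as a CLI (`tucr simulate`, `tucr preprocess`,
`tucr selectivity`, `tucr bidirectional`, `tucr diff`, `tucr qpcr`,
`tucr annotate`, `tucr run-all --config cfg.yaml --outdir out`), each
writing TSV artifacts; `run-all` reports are byte-identical for identical
config and seed.

As a library:

```python
from tucr import SyntheticConfig, generate_dataset, preprocess_pipeline, \
    selectivity_table, call_bidirectional, information_content

spots, annotation, catalog = generate_dataset(SyntheticConfig(seed=7))
res = preprocess_pipeline(spots)
table = selectivity_table(res.normalized, annotation, level="system")
ucrs = call_bidirectional(res.retained, catalog)
information_content([0.5, 0.25, 0.25, 0.0])   # -> 0.5 bits
```

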