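#!/usr/bin/env python
"""Classify UCR genomic context and summarize the expressed fraction.

Exon/EST annotation tracks consistent with the simulated catalog are
generated, every UCR is classified (exonic > putative_exonic > non_exonic,
any 1-bp overlap counts), and the class split is reported for all UCRs and
for the bidirectionally transcribed subset.

Writes genomic_context.tsv under results/genomics/.
"""

from pathlib import Path

import pandas as pd

from tucr.genomics import classify_catalog, read_bed
from tucr.synthetic import generate_annotation_tracks

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7  # matches 01_simulate so the tracks fit the catalog


def main() -> None:
    catalog = read_bed(RESULTS / "dataset" / "ucr_catalog.bed", as_catalog=True)
    tracks = generate_annotation_tracks(catalog, SEED)
    context = classify_catalog(catalog, tracks)
    out = RESULTS / "genomics"
    out.mkdir(parents=True, exist_ok=True)
    context.to_csv(out / "genomic_context.tsv", sep="\t", index=False)

    pct = context["genomic_class"].value_counts(normalize=True).mul(100).round(1)
    print(f"classified {len(context)} UCRs "
          f"({len(tracks.exons)} exon intervals, {len(tracks.ests)} EST intervals):")
    for cls in ("non_exonic", "putative_exonic", "exonic"):
        print(f"  {cls:<16} {pct.get(cls, 0.0):>5}%")

    bidir = pd.read_csv(RESULTS / "selectivity" / "bidirectional.tsv", sep="\t")
    sub = context[context["ucr_id"].isin(bidir["ucr_id"])]
    if len(sub):
        sub_pct = sub["genomic_class"].value_counts(normalize=True).mul(100).round(1)
        print(f"bidirectional subset (n={len(sub)}):")
        for cls in ("non_exonic", "putative_exonic", "exonic"):
            print(f"  {cls:<16} {sub_pct.get(cls, 0.0):>5}%")


if __name__ == "__main__":
    main()
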