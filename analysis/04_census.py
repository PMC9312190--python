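#!/usr/bin/env python
"""Call and rank MR-PrLDs over the classified proteome.

Aggregation-class proteins are scanned for Met-biased low-complexity
regions (binomial tail < 1e-5 against the proteome background Met
frequency) and prion-like regions (two-state HMM posterior >= 0.9); each
overlapping pair's intersection with >= 5 Met becomes a census record,
scored by the exact binomial upper tail P[X >= x] under the protein's own
Met frequency and ranked ascending.

Writes results/census.tsv (reference-table schema) and prints the top rows.
"""

from pathlib import Path

import pandas as pd

from metcensus import domain_detection as dd
from metcensus import proteome_io as pio

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pio.read_proteome(OUT / "proteome.fasta")
    cls = pd.read_csv(OUT / "spatial_classes.tsv", sep="\t")
    classes = dict(zip(cls.accession, cls.spatial_class))
    table = dd.census_pipeline(records, classes)
    table.to_csv(OUT / "census.tsv", sep="\t", index=False)
    n_prot = table.ID.nunique() if len(table) else 0
    print(f"census: {len(table)} MR-PrLDs in {n_prot} proteins")
    if len(table):
        print(table.head(6).to_string(index=False))


if __name__ == "__main__":
    main()
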