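"""Lineage and motif statistics from the bundled reference totals.

Per-genome ratios use the reporting convention of the regulog
collection (integers at >= 10, one decimal below), and the regulog
accounting replaces the 9 lineage-level T-box regulogs with the 92
amino acid-specific ones.
"""

from importlib import resources

import pandas as pd

from rnaregulon import lineage_stats, regulog_accounting
from rnaregulon.stats import motif_stats_from_totals


def load(name):
    ref = resources.files("rnaregulon.data").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


table = lineage_stats(load("lineage_regulog_totals.tsv"))
print(table[["taxgroup", "genomes", "sites", "sites_per_genome",
             "target_genes", "genes_per_genome"]].to_string(index=False))

print()
motif = motif_stats_from_totals(load("motif_regulon_totals.tsv"))
print(motif[["motif_id", "sites", "genes", "genes_per_genome",
             "genes_per_riboswitch"]].to_string(index=False))

print()
print("regulogs after the T-box specificity split:",
      regulog_accounting(310, 9, 92))
print("(310 lineage regulogs - 9 T-box + 92 amino acid-specific = 393)")
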