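"""Reanalyze a deposited raw guide-count table.

Expects a TSV with guide and gene identifier columns followed by one
column per sample: 'plasmid' (the control), optional unsorted timepoints
('d7', 'd12-transduced'), pooled-antibody replicates ('8aB_rep1..3') and
one column per protein probe. This is the layout screens of this kind are
published in; export the spreadsheet to TSV and pass its path.

Runs the pooled-antibody test (no gene exclusions) and one test per probe
column (ITGB3 and MEGF10 excluded), printing the FDR <= 0.1 calls of each.
"""

import sys
from pathlib import Path

from crispra_screen import enrichment_rra as rra
from crispra_screen import screen_counts as sc

path = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("data/raw_guide_counts.tsv")
if not path.exists():
    sys.exit(f"count table not found at {path}; pass its path as an argument")

table = sc.read_count_table(path)
print(f"{len(table.guide_ids)} guides x {len(table.samples)} samples")

screens = rra.reanalyze_screens(table, n_perm=10_000, seed=1)
for name, res in screens.items():
    called = res.index[res["fdr"] <= 0.1].tolist()
    print(f"\n{name}: {len(called)} genes at FDR <= 0.1")
    for gene in called:
        row = res.loc[gene]
        print(f"  {gene:10} p={row['p_value']:.2e} fdr={row['fdr']:.3f}")
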