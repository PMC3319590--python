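#!/usr/bin/env python
"""Reciprocal-best-hit orthologs and cross-species stemness conservation.

Computes RBH pairs from the forward/reverse hit tables (e-value <= 1e-10,
ties broken by bit score), cross-tabulates per-species enrichment classes
over the pairs, and compares the X1-hESC vs Xins-hEB conserved proportions
with the pooled two-proportion Z test.
"""

import argparse
import json
from pathlib import Path

from stemtx.orthology_conservation import (
    best_hits,
    conserved_enrichment,
    read_hit_table,
    reciprocal_best_hits,
    two_proportion_ztest,
    write_pairs_tsv,
)
from stemtx.pipeline import _read_class_map

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--fwd", type=Path, default=Path("results/synthetic/forward_hits.tsv"))
parser.add_argument("--rev", type=Path, default=Path("results/synthetic/reverse_hits.tsv"))
parser.add_argument("--class-a", type=Path, default=Path("results/synthetic/class_a.tsv"))
parser.add_argument("--class-b", type=Path, default=Path("results/synthetic/class_b.tsv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

forward = best_hits(read_hit_table(args.fwd))
reverse = best_hits(read_hit_table(args.rev))
pairs = reciprocal_best_hits(forward, reverse)
args.out.mkdir(parents=True, exist_ok=True)
write_pairs_tsv(pairs, args.out / "ortholog_pairs.tsv")
print(f"{len(pairs)} reciprocal-best-hit ortholog pairs "
      f"(from {len(forward)} forward / {len(reverse)} reverse best hits)")

table = conserved_enrichment(pairs, _read_class_map(args.class_a), _read_class_map(args.class_b))
(args.out / "conservation.json").write_text(json.dumps(table.to_dict(), indent=2) + "\n")
d_x1 = table.denominators.get("X1", 0)
d_xins = table.denominators.get("Xins", 0)
print(f"conserved stem (X1 & hESC): {table.conserved_stem}/{d_x1}")
print(f"conserved differentiated (Xins & hEB): {table.conserved_diff}/{d_xins}")
z = two_proportion_ztest(table.conserved_stem, d_x1, table.conserved_diff, d_xins)
print(f"two-proportion Z test: z = {z['z']:.2f}, p = {z['p_two_sided']:.2g}")
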