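"""Rank candidate reference genes in one culture condition.

Loads the packaged ASC housekeeping-gene Ct table, restricts it to the
serum condition (F), runs the four stability methods and aggregates them
into the geometric-mean consensus ranking.
"""

import refstab as rs

table = rs.load_asc_table()
serum = table.select_conditions("F")

results = rs.all_methods(serum)
for method, res in results.items():
    print(f"{method:11s}", {g: round(v, 2) for g, v in res.ordered().items()})

consensus = rs.consensus_rank(results)
print()
print(consensus.table.round(2))
print()
print(f"best reference gene in F: {consensus.best} "
      f"(geomean {consensus.geomean[consensus.best]:.2f})")

# Lower stability values mean a steadier gene; the consensus geomean is the
# fourth root of the gene's rank product across the four methods, so a gene
# every method ranks first would score exactly 1.00.
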