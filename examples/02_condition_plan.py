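"""Run the full condition-combinatorial study plan.

The default plan analyses each culture condition alone, six biologically
motivated condition pairs, and all samples together — showing how the best
reference gene changes with the experimental contrast.
"""

import refstab as rs

table = rs.load_asc_table()
for analysis in rs.run_plan(table):
    cons = analysis.consensus
    print(
        f"{analysis.label:20s} best {cons.best:6s} "
        f"(geomean {cons.geomean[cons.best]:.2f})   "
        f"worst {cons.worst:6s} ({cons.geomean[cons.worst]:.2f})"
    )

# A worst-gene geomean of 5.00 means all four methods ranked that gene last
# among the five candidates in that subset.
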