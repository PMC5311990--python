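"""Score a tiny network and condense it at one threshold triple.

Builds a five-gene toy: genes A (up, LFC +2) and B (down, LFC -2) sit on
an activating edge, C is flat, E is flat but highly expressed. Prints the
three scores and which elements survive a moderately strict condensation.
"""

import numpy as np
import pandas as pd

from focusheur import (
    ExpressionDataset,
    InteractionNetwork,
    ThresholdTriple,
    condense,
    score_network,
)

genes = list("ABCDE")
samples = [f"h{i}" for i in range(3)] + [f"d{i}" for i in range(3)]
values = pd.DataFrame(
    [
        [2, 2, 2, 4, 4, 4],        # A: LFC +2
        [5, 5, 5, 3, 3, 3],        # B: LFC -2
        [1, 1, 1, 1, 1, 1],        # C: flat, low
        [3, 3, 3, 3.5, 3.5, 3.5],  # D: LFC +0.5
        [8, 8, 8, 8, 8, 8],        # E: flat, high
    ],
    index=genes, columns=samples, dtype=float,
)
expr = ExpressionDataset(values, pd.Series(["healthy"] * 3 + ["disease"] * 3,
                                           index=samples))
net = InteractionNetwork.from_edges(
    [("A", "B", "activation", 0.9), ("A", "C", "inhibition", 0.8),
     ("B", "D", "unspecified", 0.7), ("D", "E", "unspecified", 0.9),
     ("C", "E", "unspecified", 0.6)]
)

gscores, escores = score_network(expr, net)
print("per-gene LFC (disease - healthy, log2):")
print(gscores.lfc.to_string(), "\n")
print("per-edge link scores (LS_d: activity change, LS_i: joint activity):")
print(escores.table.to_string(index=False), "\n")

t = ThresholdTriple(t_lfc=1.5, t_d=1.5, t_i=10.0)
kept = condense(net, gscores, escores, t)
print(f"condensed at |LFC|>={t.t_lfc}, |LS_d|>={t.t_d}, LS_i>={t.t_i}:")
print("  kept nodes:", {g: sorted(r) for g, r in sorted(kept.node_admission.items())})
print("  kept edges:", {e: sorted(r) for e, r in sorted(kept.edge_admission.items())})
print("\nA and B pass on their fold change; the inhibition edge A-C passes on")
print("|LS_d| = |2-0| = 2 and drags C in; B-D sits exactly at the inclusive")
print("|LS_d| threshold of 1.5; the D-E edge passes on LS_i = 11 (both genes")
print("stay expressed in both conditions), keeping D and E.")
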