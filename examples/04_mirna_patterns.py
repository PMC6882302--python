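"""miRNA presence patterns and procedure exclusivity.

Builds a toy miRNA count matrix in which one miRNA appears only in the
(ALPPS, 1 h) cell and another appears at 4 h in ALPPS but only at 8 h in
PVL, then derives the exclusivity/earlier-appearance report.
"""

import numpy as np
import pandas as pd

import paskit

design = paskit.make_design(procedures=("ALPPS", "PVL"),
                            timepoints=(1.0, 4.0, 8.0), n_replicates=2)
mirnas = ["miR-466i-3p", "miR-3470a", "miR-ubiquitous"]
expr = pd.DataFrame(0, index=pd.Index(mirnas, name="gene_id"),
                    columns=design.index)
expr.loc["miR-466i-3p", "ALPPS_1h_r1"] = 40
expr.loc["miR-3470a", ["ALPPS_4h_r1", "ALPPS_8h_r2", "PVL_8h_r1"]] = 25
expr.loc["miR-ubiquitous"] = 100

patterns = paskit.presence_patterns(expr, design, threshold=10)
report = paskit.exclusive_mirnas(patterns, "ALPPS")
print("ALPPS-exclusive miRNAs (first timepoint h):", report.exclusive)
print("first appearance (h) by procedure:")
print(report.first_seen.to_string())
# miR-466i-3p is ALPPS-exclusive from 1 h; miR-3470a is shared but appears
# 4 h earlier in ALPPS than PVL — the earlier-appearance signature of
# accelerated regeneration.
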