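"""Bundled reference PAS tables from the mouse liver-regeneration study
design this package analyses.

Two small curated tables ship with the package so the cross-condition
machinery can be exercised and checked against known values without any
download:

* ``hx68_vs_alpps_pas_4h.tsv`` — pathway activation scores of the
  intracellular signaling pathways (ISPs) surviving the stringent filter
  (|PAS| >= 0.1, p < 0.05) 4 h after standard 68% hepatectomy vs ALPPS
  surgery (46 pathway branches; note the four hypoxia/EMT branches are
  ~8.2-fold higher under ALPPS, and the IL-10 stability-determination
  branch dominates the ALPPS column).
* ``exclusive_isps_4h.tsv`` — ISPs affected exclusively by one procedure
  4 h post-surgery: 4 for ALPPS, 20 for PVL, 3 for transection, with their
  PAS values.

Values are transcribed digit-for-digit from the study's published summary
tables, including the source's own spelling quirks in pathway names.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_hx68_alpps_table",
    "load_exclusive_isp_table",
    "exclusive_sets",
]


def _data(name: str) -> pd.DataFrame:
    ref = resources.files("paskit.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_hx68_alpps_table() -> pd.DataFrame:
    """46 ISP branches x {pas_hx68, pas_alpps}, indexed by pathway name."""
    return _data("hx68_vs_alpps_pas_4h.tsv").set_index("pathway")


def load_exclusive_isp_table() -> pd.DataFrame:
    """Procedure-exclusive ISPs at 4 h: columns procedure, pathway, pas."""
    return _data("exclusive_isps_4h.tsv")


def exclusive_sets() -> dict[str, set[str]]:
    """The exclusive ISP names grouped by procedure (ALPPS, PVL, transection)."""
    table = load_exclusive_isp_table()
    return {
        procedure: set(block["pathway"])
        for procedure, block in table.groupby("procedure", sort=False)
    }
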