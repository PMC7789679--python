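"""Packaged reference data.

Currently one table: the curated list of proteins upregulated (log2 fold
change > 1.5 vs the unstimulated baseline) in MSC secretomes after
stimulation with healthy, traumatic, or degenerative intervertebral-disc
conditioned medium or IL-1b, keyed by gene symbol with UniProt accession
and the set of stimulation conditions each protein was upregulated in.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

UPREGULATED_CONDITIONS = ("healthy", "traumatic", "degenerative", "IL1b")


def load_msc_secretome_memberships() -> dict[str, set[str]]:
    """Condition -> set of gene ids upregulated under that stimulus."""
    df = load_msc_secretome_table()
    out: dict[str, set[str]] = {c: set() for c in UPREGULATED_CONDITIONS}
    for row in df.itertuples():
        for cond in row.conditions.split(";"):
            out[cond].add(row.gene_id)
    return out


def load_msc_secretome_table() -> pd.DataFrame:
    """The raw membership table (gene_id, protein_id, conditions)."""
    ref = resources.files("secretoscope.data") / "msc_secretome_upregulated.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
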