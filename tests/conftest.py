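"""Shared fixtures: small synthetic designs and peptide tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from secretoscope.containers import PeptideTable, SampleDesign
from secretoscope.simulate import SimulationConfig, simulate_peptide_table


def make_design(
    conditions: dict[str, int], reference: str = "baseline", batch: str = "batch1"
) -> SampleDesign:
    """Single-batch design with ``n`` samples (donors) per condition."""
    rows = []
    for cond, n in conditions.items():
        for d in range(1, n + 1):
            rows.append((f"D{d:02d}_{cond}", f"D{d:02d}", cond, batch))
    frame = pd.DataFrame(
        rows, columns=["sample", "donor", "condition", "batch"]
    ).set_index("sample")
    return SampleDesign(frame, reference=reference)


def make_table(values: dict[tuple[str, str], dict[str, float]], log2: bool = False) -> PeptideTable:
    """Peptide table from {(protein, sequence): {sample: value}}; NaN = missing."""
    frame = pd.DataFrame.from_dict(values, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["protein", "sequence"])
    return PeptideTable(frame, is_log2=log2)


def random_table(
    rng: np.random.Generator,
    design: SampleDesign,
    n_proteins: int = 20,
    max_peptides: int = 4,
    missing_rate: float = 0.4,
) -> PeptideTable:
    """Raw-scale random table with heavy missingness over a given design."""
    rows = {}
    for i in range(n_proteins):
        prot = f"P{i:03d}"
        for j in range(rng.integers(1, max_peptides + 1)):
            vals = np.power(2.0, rng.normal(24, 2, size=len(design.samples)))
            vals[rng.random(len(vals)) < missing_rate] = np.nan
            rows[(prot, f"{prot}_pep{j}")] = dict(zip(design.samples, vals))
    return make_table(rows)


@pytest.fixture
def default_sim():
    """Small full-design simulation (5 conditions, 2 batches, 12 donors)."""
    config = SimulationConfig(
        n_proteins=30,
        seed=11,
        true_log2fc={
            ("P0003", c): 2.0
            for c in ("healthy", "traumatic", "degenerative", "IL1b")
        },
    )
    table, design, truth = simulate_peptide_table(config)
    return config, table, design, truth
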