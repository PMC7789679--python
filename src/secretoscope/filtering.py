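"""Peptide-occupancy and two-peptide quantification filters.

A peptide counts as quantified only if it was observed in more than 50%
of the samples of at least one condition; proteins then need at least two
quantified peptides to be carried into fold-change estimation. Both rules
are exposed as scikit-learn-style transformers over
:class:`~secretoscope.containers.PeptideTable` plus thin functional
wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import DataError, PeptideTable, SampleDesign


@dataclass
class FilterReport:
    """What a filter kept, dropped, and why."""

    n_peptides_in: int
    n_peptides_out: int
    n_proteins_in: int
    n_proteins_out: int
    peptide_flags: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-peptide: kept flag + the condition that qualified it (or "")
    protein_reasons: dict[str, str] = field(default_factory=dict)
    # excluded protein -> {"single_peptide", "no_quantified_peptides"}

    def __post_init__(self) -> None:
        assert self.n_peptides_out <= self.n_peptides_in
        assert self.n_proteins_out <= self.n_proteins_in

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("peptides_in", self.n_peptides_in),
            ("peptides_out", self.n_peptides_out),
            ("proteins_in", self.n_proteins_in),
            ("proteins_out", self.n_proteins_out),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])


class PeptideOccupancyFilter(BaseEstimator):
    """Keep peptides observed in > ``min_fraction`` of samples of some condition.

    The inequality is strict: with 12 samples in a condition, 7
    observations qualify and 6 do not. Occupancy is evaluated per
    condition pooled across batches by default (the reference condition
    exists in every batch and is treated as a single condition);
    ``per_batch=True`` instead evaluates every (condition, batch) group.

    Attributes set by :meth:`fit`: ``kept_`` (boolean Series over
    peptides), ``report_``.
    """

    def __init__(self, min_fraction: float = 0.5, per_batch: bool = False):
        self.min_fraction = min_fraction
        self.per_batch = per_batch

    def fit(self, table: PeptideTable, design: SampleDesign) -> "PeptideOccupancyFilter":
        design.check_samples(table.sample_ids)
        observed = table.observed
        if self.per_batch:
            groups = design.frame.groupby(["condition", "batch"]).groups
            labels = {k: f"{k[0]}/{k[1]}" for k in groups}
        else:
            groups = design.frame.groupby("condition").groups
            labels = {k: k for k in groups}
        kept = pd.Series(False, index=observed.index)
        qualifier = pd.Series("", index=observed.index, dtype=object)
        for key, samples in groups.items():
            samples = list(samples)
            if len(samples) == 0:
                raise DataError(f"condition group {key!r} has no samples")
            counts = observed[samples].sum(axis=1)
            ok = counts > self.min_fraction * len(samples)
            newly = ok & ~kept
            qualifier[newly] = labels[key]
            kept |= ok
        proteins_in = table.proteins
        surviving = set(
            table.intensities.index[kept.to_numpy()].get_level_values("protein")
        )
        self.kept_ = kept
        self.report_ = FilterReport(
            n_peptides_in=table.n_peptides,
            n_peptides_out=int(kept.sum()),
            n_proteins_in=len(proteins_in),
            n_proteins_out=len(surviving),
            peptide_flags=pd.DataFrame({"kept": kept, "qualified_by": qualifier}),
            protein_reasons={
                p: "no_quantified_peptides" for p in proteins_in if p not in surviving
            },
        )
        return self

    def transform(self, table: PeptideTable) -> PeptideTable:
        return table.subset_peptides(self.kept_.reindex(table.intensities.index, fill_value=False).to_numpy())

    def fit_transform(self, table: PeptideTable, design: SampleDesign) -> PeptideTable:
        return self.fit(table, design).transform(table)


class ProteinPeptideFilter(BaseEstimator):
    """Drop proteins with fewer than ``min_peptides`` surviving peptides.

    Attributes set by :meth:`fit`: ``kept_proteins_``, ``report_``.
    """

    def __init__(self, min_peptides: int = 2):
        self.min_peptides = min_peptides

    def fit(self, table: PeptideTable, design: SampleDesign | None = None) -> "ProteinPeptideFilter":
        counts = table.peptides_per_protein()
        keep = counts[counts >= self.min_peptides]
        self.kept_proteins_ = set(keep.index)
        dropped = counts[counts < self.min_peptides]
        reasons = {
            p: ("single_peptide" if n == 1 else "no_quantified_peptides")
            for p, n in dropped.items()
        }
        kept_mask = table.intensities.index.get_level_values("protein").isin(
            self.kept_proteins_
        )
        self.report_ = FilterReport(
            n_peptides_in=table.n_peptides,
            n_peptides_out=int(kept_mask.sum()),
            n_proteins_in=len(counts),
            n_proteins_out=len(keep),
            protein_reasons=reasons,
        )
        return self

    def transform(self, table: PeptideTable) -> PeptideTable:
        mask = table.intensities.index.get_level_values("protein").isin(
            self.kept_proteins_
        )
        return table.subset_peptides(mask)

    def fit_transform(self, table: PeptideTable, design: SampleDesign | None = None) -> PeptideTable:
        return self.fit(table, design).transform(table)


def filter_peptides(
    table: PeptideTable, design: SampleDesign, min_fraction: float = 0.5,
    per_batch: bool = False,
) -> tuple[PeptideTable, FilterReport]:
    """Functional wrapper around :class:`PeptideOccupancyFilter`."""
    f = PeptideOccupancyFilter(min_fraction=min_fraction, per_batch=per_batch)
    out = f.fit_transform(table, design)
    return out, f.report_


def filter_proteins(
    table: PeptideTable, min_peptides: int = 2
) -> tuple[PeptideTable, FilterReport]:
    """Functional wrapper around :class:`ProteinPeptideFilter`."""
    f = ProteinPeptideFilter(min_peptides=min_peptides)
    out = f.fit_transform(table)
    return out, f.report_


def apply_quantification_filters(
    table: PeptideTable, design: SampleDesign, min_fraction: float = 0.5,
    per_batch: bool = False, min_peptides: int = 2,
) -> tuple[PeptideTable, FilterReport, FilterReport]:
    """Occupancy filter followed by the two-peptide rule."""
    t1, rep1 = filter_peptides(table, design, min_fraction, per_batch)
    t2, rep2 = filter_proteins(t1, min_peptides)
    return t2, rep1, rep2
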