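"""In-memory containers for the secretome quantification pipeline.

The pipeline operates on peptide-level label-free quantification (LFQ)
data: a peptide x sample intensity matrix with a peptide -> protein-group
mapping, plus a sample design table describing the repeated-measures
structure (donor, stimulation condition, acquisition batch).

Missing intensities are represented as NaN and are semantically distinct
from zero: an MS1 intensity of zero means "not observed", never "absent at
zero abundance", so readers coerce zeros to NaN on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORY_LABELS = (
    "ECM",
    "anabolic",
    "catabolic",
    "growth factor",
    "immune system",
    "other",
)


class DataError(ValueError):
    """Malformed or internally inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass
class PeptideTable:
    """Peptide x sample intensity matrix with protein-group mapping.

    Parameters
    ----------
    intensities
        DataFrame with a two-level row MultiIndex ``(protein, sequence)``
        and one column per sample. Cells are positive reals or NaN
        (missing). On the raw scale unless ``is_log2``.
    is_log2
        Whether the values are log2-transformed (possibly normalized).
    """

    intensities: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.nlevels != 2:
            raise DataError(
                "peptide table needs a (protein, sequence) row MultiIndex, "
                f"got {idx.nlevels} level(s)"
            )
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].tolist()[:5]
            raise DataError(f"duplicate (protein, sequence) rows: {dupes}")
        if list(idx.names) != ["protein", "sequence"]:
            self.intensities.index = idx.set_names(["protein", "sequence"])
        vals = self.intensities.to_numpy(dtype=float)
        if not self.is_log2 and np.any(vals[np.isfinite(vals)] <= 0):
            raise DataError("raw intensities must be positive or missing")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index.get_level_values("protein").unique())

    @property
    def n_peptides(self) -> int:
        return self.intensities.shape[0]

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean mask of observed (non-missing) cells."""
        return self.intensities.notna()

    def peptides_per_protein(self) -> pd.Series:
        return self.intensities.groupby(level="protein").size()

    def log2(self) -> "PeptideTable":
        """Return a log2-scale view (identity if already log2)."""
        if self.is_log2:
            return self
        return PeptideTable(np.log2(self.intensities), is_log2=True)

    def subset_peptides(self, mask: pd.Series | np.ndarray) -> "PeptideTable":
        return PeptideTable(self.intensities.loc[mask], is_log2=self.is_log2)

    def equals(self, other: "PeptideTable") -> bool:
        return self.is_log2 == other.is_log2 and self.intensities.equals(
            other.intensities
        )


@dataclass
class SampleDesign:
    """Per-sample donor / condition / batch metadata.

    ``reference`` names the condition all contrasts are computed against
    (the unstimulated baseline secretome in the study design this package
    models).
    """

    frame: pd.DataFrame  # index: sample; columns: donor, condition, batch
    reference: str

    def __post_init__(self) -> None:
        need = {"donor", "condition", "batch"}
        missing = need - set(self.frame.columns)
        if missing:
            raise DataError(f"design table lacks column(s): {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise DataError("duplicate sample ids in design")
        counts = self.frame["condition"].value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            raise DataError(
                f"every condition needs >=2 samples; too few: {list(thin.index)}"
            )
        if self.reference not in set(self.frame["condition"]):
            raise DataError(
                f"reference condition {self.reference!r} absent from design"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def conditions(self) -> list[str]:
        """Conditions with the reference first, then alphabetical."""
        rest = sorted(set(self.frame["condition"]) - {self.reference})
        return [self.reference] + rest

    @property
    def contrasts(self) -> list[str]:
        return [c for c in self.conditions if c != self.reference]

    def samples_of(self, condition: str) -> list[str]:
        return list(self.frame.index[self.frame["condition"] == condition])

    def check_samples(self, sample_ids: Iterable[str]) -> None:
        """Require exact set equality with a peptide table's samples."""
        table_set = set(sample_ids)
        design_set = set(self.frame.index)
        only_table = sorted(table_set - design_set)
        only_design = sorted(design_set - table_set)
        if only_table or only_design:
            raise DataError(
                "sample mismatch between intensity table and design: "
                f"missing from design {only_table}, "
                f"missing from table {only_design}"
            )


@dataclass
class GeneSetCollection:
    """Named gene/protein sets (GMT semantics: name, description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise DataError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        members = tuple(dict.fromkeys(members))
        if not members:
            raise DataError(f"gene set {name!r} is empty")
        self.sets[name] = (description, members)


@dataclass
class CategoryMap:
    """Protein -> functional category (six-way secretome classification)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in CATEGORY_LABELS}
        if bad:
            raise DataError(
                f"unknown categories {sorted(bad)}; allowed: {CATEGORY_LABELS}"
            )

    def get(self, protein: str) -> str:
        return self.mapping.get(protein, "other")


@dataclass
class AssayTable:
    """Immunoassay concentrations plus per-sample DNA content.

    ``measurements`` is long-format: one row per (analyte, sample) with
    ``concentration`` in pg/mL and a boolean ``detected`` flag.
    ``samples`` is indexed by sample id with ``donor``, ``condition`` and
    ``dna`` (DNA content used for normalization; must be positive).
    """

    measurements: pd.DataFrame  # analyte, sample, concentration, detected
    samples: pd.DataFrame  # index sample; donor, condition, dna

    def __post_init__(self) -> None:
        need = {"analyte", "sample", "concentration", "detected"}
        missing = need - set(self.measurements.columns)
        if missing:
            raise DataError(f"assay table lacks column(s): {sorted(missing)}")
        need_s = {"donor", "condition", "dna"}
        missing_s = need_s - set(self.samples.columns)
        if missing_s:
            raise DataError(f"assay sample table lacks: {sorted(missing_s)}")
        if (self.samples["dna"] <= 0).any():
            bad = list(self.samples.index[self.samples["dna"] <= 0])[:5]
            raise DataError(f"non-positive DNA content for sample(s) {bad}")
        det = self.measurements.loc[self.measurements["detected"], "concentration"]
        if (det < 0).any():
            raise DataError("detected concentrations must be >= 0")

    @property
    def analytes(self) -> list[str]:
        return list(pd.unique(self.measurements["analyte"]))
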