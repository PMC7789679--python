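"""Synthetic secretome LFQ data with known ground truth.

Emulates the study design this pipeline targets: 12 donors, five
stimulation conditions (an unstimulated baseline plus healthy / traumatic
/ degenerative conditioned-medium stimuli and an IL-1b control), acquired
in two MS batches with baseline samples present in both batches so that
batch differences are estimable.

Peptide-level log2 intensities follow the additive model the downstream
mixed model assumes:

    log2 x(i,j,s) = base_i + pep_ij + donor_d(s) + batch_b(s)
                    + log2fc(i, cond(s)) + eps

with missingness from two mechanisms: completely-at-random cell dropout
(MCAR) and intensity-dependent dropout (MNAR) whose probability is a
decreasing logistic function of the log2 intensity — low-abundance
peptides vanish first, as in real MS1 quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AssayTable,
    ConfigError,
    GeneSetCollection,
    PeptideTable,
    SampleDesign,
)

DEFAULT_CONDITIONS = ("baseline", "healthy", "traumatic", "degenerative", "IL1b")
DEFAULT_BATCHES: dict[str, tuple[str, ...]] = {
    "batch1": ("baseline", "traumatic", "degenerative", "IL1b"),
    "batch2": ("baseline", "healthy"),
}


@dataclass
class SimulationConfig:
    """Parameters of the peptide-level intensity simulation.

    Defaults mirror the emulated study: 12 donors, 5 conditions, two
    batches (48 + 24 samples) with baseline replicated in both. Effect
    sizes are log2 units throughout.
    """

    n_donors: int = 12
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    batches: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BATCHES)
    )
    n_proteins: int = 300
    mean_peptides: float = 4.0  # 1 + Poisson(mean - 1) peptides per protein
    fixed_peptides: int | None = None  # overrides the draw with a constant
    true_log2fc: Mapping[tuple[str, str], float] = field(default_factory=dict)
    base_log2_range: tuple[float, float] = (22.0, 27.0)
    donor_sd: float = 0.3
    peptide_offset_sd: float = 1.0
    batch_shift: Mapping[str, float] = field(
        default_factory=lambda: {"batch1": 0.0, "batch2": 0.5}
    )
    noise_sd: float = 0.4
    missing_mcar_rate: float = 0.05
    missing_mnar_scale: float = 0.8  # logistic slope per log2 unit; 0 = off
    mnar_midpoint_quantile: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_donors <= 0:
            raise ConfigError("n_proteins and n_donors must be positive")
        if self.mean_peptides < 1:
            raise ConfigError("mean_peptides must be >= 1")
        if self.fixed_peptides is not None and self.fixed_peptides < 1:
            raise ConfigError("fixed_peptides must be >= 1")
        if not (0 <= self.missing_mcar_rate <= 1):
            raise ConfigError("missing_mcar_rate must be in [0, 1]")
        if not (0 <= self.mnar_midpoint_quantile <= 1):
            raise ConfigError("mnar_midpoint_quantile must be in [0, 1]")
        for name in ("donor_sd", "peptide_offset_sd", "missing_mnar_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        ref = self.reference
        assigned: dict[str, str] = {}
        for batch, conds in self.batches.items():
            if ref not in conds:
                raise ConfigError(
                    f"reference condition {ref!r} must be present in every "
                    f"batch; missing from {batch!r}"
                )
            for c in conds:
                if c not in self.conditions:
                    raise ConfigError(f"batch {batch!r} lists unknown condition {c!r}")
                if c != ref and c in assigned:
                    raise ConfigError(
                        f"condition {c!r} assigned to both {assigned[c]!r} and {batch!r}"
                    )
                assigned[c] = batch
        unassigned = set(self.conditions) - set(assigned)
        if unassigned:
            raise ConfigError(f"condition(s) not assigned to a batch: {sorted(unassigned)}")
        for (protein, cond), fc in self.true_log2fc.items():
            if cond not in self.conditions:
                raise KeyError(f"true_log2fc references unknown condition {cond!r}")
            if cond == ref and fc != 0:
                raise ConfigError("baseline log2 fold changes must all be zero")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    def protein_ids(self) -> list[str]:
        width = max(4, len(str(self.n_proteins)))
        return [f"P{i:0{width}d}" for i in range(1, self.n_proteins + 1)]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    protein_log2fc: dict[tuple[str, str], float]
    enriched_sets: dict[str, tuple[str, str]]  # set name -> (condition, direction)
    missing_pattern: pd.DataFrame  # True where the cell was removed

    def log2fc(self, protein: str, condition: str) -> float:
        return self.protein_log2fc.get((protein, condition), 0.0)


def random_effects(
    protein_ids: Sequence[str],
    conditions: Sequence[str],
    n_de: int,
    effect_size: float,
    seed: int,
    frac_down: float = 0.5,
) -> dict[tuple[str, str], float]:
    """Draw a sparse map of true condition effects for ``n_de`` proteins.

    Each differential protein gets +/- ``effect_size`` in every
    non-reference condition (sign drawn once per protein).
    """
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(protein_ids), size=min(n_de, len(protein_ids)), replace=False)
    out: dict[tuple[str, str], float] = {}
    for idx in chosen:
        sign = -1.0 if rng.random() < frac_down else 1.0
        for cond in conditions[1:]:
            out[(protein_ids[idx], cond)] = sign * effect_size
    return out


def _design_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for d in range(1, config.n_donors + 1):
        donor = f"D{d:02d}"
        for batch, conds in config.batches.items():
            for cond in conds:
                sample = f"{donor}_{cond}_{batch}"
                rows.append((sample, donor, cond, batch))
    frame = pd.DataFrame(rows, columns=["sample", "donor", "condition", "batch"])
    return frame.set_index("sample")


def simulate_peptide_table(
    config: SimulationConfig,
) -> tuple[PeptideTable, SampleDesign, GroundTruth]:
    """Generate a raw-scale peptide table, its design, and the ground truth.

    Deterministic: the same config (including seed) yields identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    design = _design_frame(config)
    samples = list(design.index)
    n_samples = len(samples)
    proteins = config.protein_ids()

    if config.fixed_peptides is not None:
        n_pep = np.full(config.n_proteins, config.fixed_peptides)
    else:
        n_pep = 1 + rng.poisson(config.mean_peptides - 1.0, size=config.n_proteins)
    lo, hi = config.base_log2_range
    base = rng.uniform(lo, hi, size=config.n_proteins)
    donor_ids = sorted(design["donor"].unique())
    donor_eff = dict(
        zip(donor_ids, rng.normal(0.0, config.donor_sd, size=len(donor_ids)))
    )

    index = []
    pep_protein_idx = []
    for i, (prot, k) in enumerate(zip(proteins, n_pep)):
        for j in range(k):
            index.append((prot, f"{prot}_pep{j + 1:02d}"))
            pep_protein_idx.append(i)
    pep_protein_idx = np.asarray(pep_protein_idx)
    n_peptides = len(index)
    pep_offset = rng.normal(0.0, config.peptide_offset_sd, size=n_peptides)

    fc = np.zeros((config.n_proteins, n_samples))
    cond_of = design["condition"].to_numpy()
    prot_pos = {p: i for i, p in enumerate(proteins)}
    for (prot, cond), val in config.true_log2fc.items():
        if prot not in prot_pos:
            raise KeyError(f"true_log2fc references unknown protein {prot!r}")
        fc[prot_pos[prot], cond_of == cond] = val

    donor_col = np.array([donor_eff[d] for d in design["donor"]])
    batch_col = np.array(
        [config.batch_shift.get(b, 0.0) for b in design["batch"]]
    )

    log2x = (
        base[pep_protein_idx][:, None]
        + pep_offset[:, None]
        + donor_col[None, :]
        + batch_col[None, :]
        + fc[pep_protein_idx, :]
    )
    if config.noise_sd > 0:
        log2x = log2x + rng.normal(0.0, config.noise_sd, size=log2x.shape)

    missing = np.zeros(log2x.shape, dtype=bool)
    if config.missing_mcar_rate > 0:
        missing |= rng.random(log2x.shape) < config.missing_mcar_rate
    if config.missing_mnar_scale > 0:
        midpoint = np.quantile(log2x, config.mnar_midpoint_quantile)
        p_drop = 1.0 / (1.0 + np.exp(config.missing_mnar_scale * (log2x - midpoint)))
        missing |= rng.random(log2x.shape) < p_drop

    values = np.power(2.0, log2x)
    values[missing] = np.nan
    frame = pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(index, names=["protein", "sequence"]),
        columns=samples,
    )
    truth = GroundTruth(
        protein_log2fc=dict(config.true_log2fc),
        enriched_sets={},
        missing_pattern=pd.DataFrame(missing, index=frame.index, columns=samples),
    )
    table = PeptideTable(frame, is_log2=False)
    return table, SampleDesign(design, reference=config.reference), truth


def simulate_genesets(
    truth: GroundTruth,
    protein_ids: Sequence[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    seed: int,
    n_planted: int = 0,
    planted_condition: str | None = None,
    planted_direction: str = "up",
) -> GeneSetCollection:
    """Draw gene sets over the simulated proteins, optionally planting
    enriched sets.

    Planted sets are sampled from the proteins whose true log2 fold
    change in ``planted_condition`` has the requested sign, so a
    downstream preranked enrichment on accurately estimated fold changes
    should score them highly. Remaining sets are uniform draws (the
    permutation null). Planted set names and directions are recorded in
    ``truth.enriched_sets``.
    """
    lo, hi = set_size_range
    if lo < 2:
        raise ConfigError("minimum set size must be >= 2")
    if lo > hi:
        raise ConfigError(f"set size range {set_size_range} is empty")
    if hi > len(protein_ids):
        raise ConfigError(
            f"max set size {hi} exceeds protein count {len(protein_ids)}"
        )
    if n_planted > n_sets:
        raise ConfigError("n_planted cannot exceed n_sets")
    if n_planted > 0 and planted_condition is None:
        raise ConfigError("planting requires planted_condition")

    rng = np.random.default_rng(seed)
    collection = GeneSetCollection({})
    ids = np.asarray(protein_ids, dtype=object)

    if n_planted > 0:
        sign = 1.0 if planted_direction == "up" else -1.0
        pool = [
            p
            for p in protein_ids
            if sign * truth.log2fc(p, planted_condition) > 0
        ]
        if len(pool) < hi:
            raise ConfigError(
                "not enough proteins with the requested effect sign to plant "
                f"sets of size up to {hi} (pool has {len(pool)})"
            )
        pool = np.asarray(pool, dtype=object)
        for i in range(n_planted):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(pool, size=size, replace=False)
            name = f"planted_{planted_direction}_{i + 1:03d}"
            collection.add(name, members.tolist(), f"planted {planted_direction}")
            truth.enriched_sets[name] = (planted_condition, planted_direction)

    for i in range(n_sets - n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ids, size=size, replace=False)
        collection.add(f"uniform_{i + 1:03d}", members.tolist(), "uniform")
    return collection


def simulate_immunoassay(
    config: SimulationConfig,
    analytes: Sequence[str],
    seed: int,
    multipliers: Mapping[tuple[str, str], float] | None = None,
    noise_sd: float = 0.3,
    donor_sd: float = 0.3,
    detection_limit: float = 1.0,
    base_concentration: float = 100.0,
) -> AssayTable:
    """Simulate a multiplex immunoassay plate with per-sample DNA content.

    Secreted concentration scales with the amount of cells (DNA) in the
    well, so DNA normalization exactly cancels the per-sample DNA factor:
    with ``noise_sd = 0`` the per-donor DNA-normalized fold change of an
    analyte equals its condition multiplier. ``multipliers`` maps
    ``(analyte, condition)`` to the true fold effect vs baseline
    (default 1.0 everywhere); ``noise_sd``/``donor_sd`` are SDs on the
    natural-log scale. Concentrations below ``detection_limit`` (pg/mL)
    are flagged undetected.
    """
    if len(analytes) == 0:
        raise ConfigError("analyte list must be non-empty")
    multipliers = dict(multipliers or {})
    for (analyte, cond), m in multipliers.items():
        if cond not in config.conditions:
            raise KeyError(f"multiplier references unknown condition {cond!r}")
        if m <= 0:
            raise ConfigError("multipliers must be positive")

    rng = np.random.default_rng(seed)
    donors = [f"D{d:02d}" for d in range(1, config.n_donors + 1)]
    conds = list(config.conditions)
    base = {
        a: base_concentration * float(np.exp(rng.normal(0.0, 1.0)))
        for a in analytes
    }
    donor_fac = {d: float(np.exp(rng.normal(0.0, donor_sd))) for d in donors}

    sample_rows = []
    meas_rows = []
    for d in donors:
        for c in conds:
            sample = f"{d}_{c}"
            dna = float(np.exp(rng.normal(0.0, 0.2)))
            sample_rows.append((sample, d, c, dna))
            for a in analytes:
                mult = multipliers.get((a, c), 1.0)
                conc = base[a] * donor_fac[d] * mult * dna
                if noise_sd > 0:
                    conc *= float(np.exp(rng.normal(0.0, noise_sd)))
                detected = conc >= detection_limit
                meas_rows.append((a, sample, conc if detected else 0.0, detected))

    samples = pd.DataFrame(
        sample_rows, columns=["sample", "donor", "condition", "dna"]
    ).set_index("sample")
    measurements = pd.DataFrame(
        meas_rows, columns=["analyte", "sample", "concentration", "detected"]
    )
    return AssayTable(measurements=measurements, samples=samples)
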