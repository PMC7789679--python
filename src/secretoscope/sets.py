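"""Multi-condition secretome set comparison.

Given per-condition sets of upregulated proteins, computes the full Venn
decomposition (all 2^k - 1 disjoint cells), pairwise intersection counts,
a protein -> condition-membership listing, and the functional-category
composition of each condition's secretome. Also exports plain id lists
per condition for external interaction-network tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .containers import CategoryMap, DataError

logger = logging.getLogger(__name__)


@dataclass
class SecretomePartition:
    """Disjoint Venn cells plus derived views over k condition sets."""

    condition_sets: dict[str, set[str]]
    venn_cells: dict[frozenset[str], set[str]]  # cells keyed by condition combo
    membership: dict[str, frozenset[str]]  # protein -> conditions containing it

    def pairwise(self) -> pd.DataFrame:
        """|A n B| for every unordered condition pair."""
        rows = []
        for a, b in combinations(sorted(self.condition_sets), 2):
            rows.append((a, b, len(self.condition_sets[a] & self.condition_sets[b])))
        return pd.DataFrame(rows, columns=["condition_a", "condition_b", "n_shared"])

    def intersection(self, a: str, b: str) -> int:
        return len(self.condition_sets[a] & self.condition_sets[b])

    def cells_frame(self) -> pd.DataFrame:
        rows = [
            (",".join(sorted(combo)), len(members), ";".join(sorted(members)))
            for combo, members in sorted(
                self.venn_cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["conditions", "n", "proteins"])

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            (p, ",".join(sorted(self.membership[p])))
            for p in sorted(self.membership)
        ]
        return pd.DataFrame(rows, columns=["protein", "conditions"])


def build_partition(condition_sets: dict[str, set[str]]) -> SecretomePartition:
    """Exact set algebra over per-condition protein sets.

    Venn cells are disjoint by construction and their union equals the
    union of all condition sets; listing order is deterministic.
    """
    if len(set(condition_sets)) != len(condition_sets):
        raise DataError("condition labels must be unique")
    sets = {c: set(s) for c, s in condition_sets.items()}
    membership: dict[str, frozenset[str]] = {}
    for protein in sorted(set().union(*sets.values())) if sets else []:
        membership[protein] = frozenset(c for c, s in sets.items() if protein in s)
    cells: dict[frozenset[str], set[str]] = {}
    for protein, combo in membership.items():
        cells.setdefault(combo, set()).add(protein)
    return SecretomePartition(
        condition_sets=sets, venn_cells=cells, membership=membership
    )


def categorize(
    condition_sets: dict[str, set[str]], category_map: CategoryMap
) -> pd.DataFrame:
    """Per-condition functional-category counts and percentages.

    Proteins absent from the map fall into "other" with a warning. Empty
    condition sets are reported with zero counts and undefined (NA)
    percentages rather than dividing by zero.
    """
    uncovered = sorted(
        {p for s in condition_sets.values() for p in s if p not in category_map.mapping}
    )
    if uncovered:
        logger.warning(
            "%d protein(s) not in the category map, assigned 'other': %s",
            len(uncovered),
            uncovered[:10],
        )
    rows = []
    for cond in sorted(condition_sets):
        proteins = condition_sets[cond]
        counts: dict[str, int] = {}
        for p in proteins:
            cat = category_map.get(p)
            counts[cat] = counts.get(cat, 0) + 1
        total = len(proteins)
        if total == 0:
            logger.warning("condition %r has an empty protein set", cond)
        for cat, n in sorted(counts.items()):
            rows.append((cond, cat, n, 100.0 * n / total if total else pd.NA))
        if total == 0:
            rows.append((cond, "other", 0, pd.NA))
    return pd.DataFrame(rows, columns=["condition", "category", "count", "percent"])


def export_for_network(
    condition_sets: dict[str, set[str]], out_dir: str | Path
) -> dict[str, Path]:
    """One plain-text protein-id list per condition, for external network
    tools (e.g. STRING). No network computation happens here."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for cond in sorted(condition_sets):
        path = out_dir / f"upregulated_{cond}.txt"
        path.write_text("".join(f"{p}\n" for p in sorted(condition_sets[cond])))
        written[cond] = path
    return written
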