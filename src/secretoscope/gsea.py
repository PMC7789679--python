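"""Preranked gene-set enrichment with a permutation null.

Implements the weighted running-sum enrichment statistic: walking the
ranked list (scores descending), a set member at rank r adds
``|score_r|^weight / sum_set |score|^weight`` and a non-member subtracts
``1/(N - N_set)``; the enrichment score (ES) is the running-sum value of
maximal absolute deviation from zero. The null is built by gene-label
permutation (one shared relabeling per permutation across all sets); the
normalized enrichment score (NES) divides ES by the mean magnitude of
same-sign permuted ES, the p-value is the same-sign tail frequency, and
the set-level FDR is the standard ratio of permuted to observed NES tail
fractions, clipped to [0, 1]. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import DataError, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class GseaConfig:
    """Settings for a preranked GSEA run (defaults: sets of >=10 in-list
    members, 1000 gene-label permutations, weight exponent 1)."""

    min_set_size: int = 10
    n_permutations: int = 1000
    weight: float = 1.0
    seed: int = 0
    p_report: float = 0.01
    fdr_highlight: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise DataError("n_permutations must be >= 1")
        if self.min_set_size < 1:
            raise DataError("min_set_size must be >= 1")


def make_ranked_list(effects: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Build a ranked list (id, score) from a differential-effects table.

    Scores are the estimated log2 fold changes for ``condition``; ties
    break on protein id ascending so the ranking is deterministic.
    """
    sub = effects.loc[effects["condition"] == condition, ["protein", "log2fc"]]
    sub = sub.rename(columns={"protein": "id", "log2fc": "score"})
    sub = sub.dropna(subset=["score"])
    sub = sub.sort_values(["score", "id"], ascending=[False, True], kind="mergesort")
    if sub["id"].duplicated().any():
        raise DataError("ranked list ids must be unique")
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment statistic
# ---------------------------------------------------------------------------

def _es_batch(
    positions: np.ndarray, pos_weights: np.ndarray, n_total: int
) -> np.ndarray:
    """ES for a batch of position placements of one set.

    ``positions``: (B, k) sorted member positions (0-based ranks);
    ``pos_weights``: |score|^weight at those positions. Evaluates the
    running sum only at hit boundaries: its extrema can only occur right
    at a hit (candidate maxima) or right before one (candidate minima).
    """
    B, k = positions.shape
    if n_total == k:
        return np.ones(B)
    wsum = pos_weights.sum(axis=1, keepdims=True)
    flat = wsum[:, 0] == 0
    if np.any(flat):  # all-zero scores in the set: fall back to equal steps
        pos_weights = pos_weights.copy()
        pos_weights[flat] = 1.0
        wsum = pos_weights.sum(axis=1, keepdims=True)
    H = np.cumsum(pos_weights, axis=1) / wsum
    miss = 1.0 / (n_total - k)
    j = np.arange(k)
    at_hit = H - (positions - j) * miss
    before_hit = np.concatenate([np.zeros((B, 1)), H[:, :-1]], axis=1) - (
        positions - j
    ) * miss
    up = at_hit.max(axis=1)
    down = before_hit.min(axis=1)
    return np.where(up >= -down, up, down)


def enrichment_score(
    ranked: pd.DataFrame, members, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum, and leading edge of one set.

    ``ranked`` has columns (id, score), already sorted descending. The
    leading edge is the members at or before the running-sum extremum
    (at or after it for a negative ES).
    """
    ids = ranked["id"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    n = len(ids)
    member_set = set(members)
    hit = np.fromiter((i in member_set for i in ids), bool, count=n)
    k = int(hit.sum())
    if k == 0:
        raise DataError("set has no members in the ranked list")
    w = np.abs(scores) ** weight
    wh = np.where(hit, w, 0.0)
    wsum = wh.sum()
    if wsum == 0:
        wh = hit.astype(float)
        wsum = float(k)
    steps = wh / wsum
    if n > k:
        steps = steps - (~hit) / (n - k)
    running = np.cumsum(steps)
    # single source of truth for the ES value (shared with the permutation
    # path, so knife-edge sign ties resolve identically everywhere)
    positions = np.flatnonzero(hit)
    es = float(_es_batch(positions[None, :], w[positions][None, :], n)[0])
    extremum = int(np.argmax(running) if es >= 0 else np.argmin(running))
    if es >= 0:
        leading = [i for i, h in zip(ids[: extremum + 1], hit[: extremum + 1]) if h]
    else:
        leading = [i for i, h in zip(ids[extremum:], hit[extremum:]) if h]
    return es, running, leading


# ---------------------------------------------------------------------------
# full GSEA
# ---------------------------------------------------------------------------

class PrerankedGSEA(BaseEstimator):
    """Preranked GSEA over a gene-set collection.

    ``exact_null=True`` replaces the sampled permutation null by full
    enumeration of all C(N, k) member placements (only sensible for tiny
    lists; used as its own oracle in testing). Attributes set by
    :meth:`fit`: ``results_`` (DataFrame: name, size, es, nes, p, fdr,
    leading_edge), ``skipped_`` (name -> reason).
    """

    def __init__(
        self,
        min_set_size: int = 10,
        n_permutations: int = 1000,
        weight: float = 1.0,
        seed: int = 0,
        exact_null: bool = False,
    ):
        self.min_set_size = min_set_size
        self.n_permutations = n_permutations
        self.weight = weight
        self.seed = seed
        self.exact_null = exact_null

    def fit(self, ranked: pd.DataFrame, collection: GeneSetCollection) -> "PrerankedGSEA":
        if self.n_permutations < 10:
            warnings.warn("fewer than 10 permutations: unstable p/NES estimates")
        ids = ranked["id"].to_numpy()
        scores = ranked["score"].to_numpy(float)
        order = np.lexsort((ids, -scores))
        if not np.array_equal(order, np.arange(len(ids))):
            ranked = ranked.iloc[order].reset_index(drop=True)
            ids = ranked["id"].to_numpy()
            scores = ranked["score"].to_numpy(float)
        n = len(ids)
        pos_of = {g: i for i, g in enumerate(ids)}
        pos_w = np.abs(scores) ** self.weight

        usable: list[tuple[str, np.ndarray]] = []
        skipped: dict[str, str] = {}
        for name in collection.names():
            members = collection.members(name)
            in_list = np.array(sorted(pos_of[m] for m in members if m in pos_of))
            if len(in_list) == 0:
                skipped[name] = "no members in ranked list"
                continue
            if len(in_list) < self.min_set_size:
                skipped[name] = (
                    f"in-list size {len(in_list)} < min_set_size {self.min_set_size}"
                )
                continue
            usable.append((name, in_list))
        self.skipped_ = skipped
        if not usable:
            warnings.warn("no gene set passes the size filter")
            self.results_ = pd.DataFrame(
                columns=["name", "size", "es", "nes", "p", "fdr", "leading_edge"]
            )
            return self

        rng = np.random.default_rng(self.seed)
        if self.exact_null:
            perms = None
        else:
            perms = np.array(
                [rng.permutation(n) for _ in range(self.n_permutations)]
            )

        rows = []
        nes_perm_all = []
        for name, positions in usable:
            es, _, leading = enrichment_score(
                ranked, [ids[i] for i in positions], weight=self.weight
            )
            k = len(positions)
            if perms is None:
                placements = np.array(list(combinations(range(n), k)))
                null_pos = placements
            else:
                null_pos = np.sort(perms[:, positions], axis=1)
            es_null = _es_batch(null_pos, pos_w[null_pos], n)
            pos_null = es_null[es_null >= 0]
            neg_null = es_null[es_null < 0]
            mean_pos = pos_null.mean() if len(pos_null) else np.nan
            mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
            if es >= 0:
                same = pos_null
                nes = es / mean_pos if len(pos_null) else 0.0
            else:
                same = neg_null
                nes = es / mean_neg if len(neg_null) else 0.0
            n_extreme = int(np.sum(np.abs(same) >= abs(es)))
            p = (1 + n_extreme) / (1 + len(same)) if len(same) else 1.0
            # per-set NES-normalized null, for the FDR tail ratio
            with np.errstate(invalid="ignore", divide="ignore"):
                nes_null = np.where(
                    es_null >= 0, es_null / mean_pos, es_null / mean_neg
                )
            nes_perm_all.append(nes_null[np.isfinite(nes_null)])
            rows.append(
                {
                    "name": name,
                    "size": k,
                    "es": es,
                    "nes": float(nes),
                    "p": float(p),
                    "fdr": np.nan,
                    "leading_edge": ";".join(leading),
                }
            )

        results = pd.DataFrame(rows)
        all_null = np.concatenate(nes_perm_all)
        obs = results["nes"].to_numpy()
        n_null_pos = max(int(np.sum(all_null >= 0)), 1)
        n_null_neg = max(int(np.sum(all_null < 0)), 1)
        n_obs_pos = max(int(np.sum(obs >= 0)), 1)
        n_obs_neg = max(int(np.sum(obs < 0)), 1)
        fdr = np.empty(len(obs))
        for i, nes in enumerate(obs):
            if nes >= 0:
                num = np.sum(all_null >= nes) / n_null_pos
                den = np.sum(obs >= nes) / n_obs_pos
            else:
                num = np.sum(all_null <= nes) / n_null_neg
                den = np.sum(obs <= nes) / n_obs_neg
            fdr[i] = min(1.0, num / den) if den > 0 else 1.0
        results["fdr"] = fdr
        results = results.sort_values(
            ["nes", "name"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        self.results_ = results
        return self


def gsea(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    config: GseaConfig | None = None,
    exact_null: bool = False,
) -> pd.DataFrame:
    """Functional wrapper around :class:`PrerankedGSEA`."""
    cfg = config or GseaConfig()
    est = PrerankedGSEA(
        min_set_size=cfg.min_set_size,
        n_permutations=cfg.n_permutations,
        weight=cfg.weight,
        seed=cfg.seed,
        exact_null=exact_null,
    )
    return est.fit(ranked, collection).results_


def top_terms(
    results: pd.DataFrame, k: int = 10, p_threshold: float = 0.01
) -> pd.DataFrame:
    """Top-k upregulated and downregulated sets by NES among reportable sets.

    Reportable means permutation p below ``p_threshold``. Ordering is
    stable with ties broken on set name; if fewer than k qualify, all are
    returned.
    """
    ok = results.loc[results["p"] < p_threshold].copy()
    pos = ok.loc[ok["nes"] > 0].sort_values(
        ["nes", "name"], ascending=[False, True], kind="mergesort"
    )
    neg = ok.loc[ok["nes"] < 0].sort_values(
        ["nes", "name"], ascending=[True, True], kind="mergesort"
    )
    out = pd.concat([pos.head(k).assign(direction="up"),
                     neg.head(k).assign(direction="down")])
    return out.reset_index(drop=True)
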