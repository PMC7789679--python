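"""Companion immunoassay and viability statistics.

Covers the quantitative assays that accompany the MS pipeline:
DNA-normalized per-donor fold changes of immunoassay concentrations
against the baseline condition, LDH cytotoxicity percentages anchored at
the negative (0%) and lysed positive (100%) controls, and a
normality-gated group comparison (one-way ANOVA when no normality test
rejects in any group, Kruskal-Wallis otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .containers import AssayTable, DataError

logger = logging.getLogger(__name__)

_DAGOSTINO_MIN_N = 8  # scipy's omnibus test needs >= 8 observations


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def fold_change(
    assay: AssayTable,
    baseline: str = "baseline",
    drop_undetected_frac: float = 0.9,
) -> pd.DataFrame:
    """Per-donor, per-condition DNA-normalized fold change vs baseline.

    fc(donor, condition) = (conc/DNA)(donor, condition) /
    (conc/DNA)(donor, baseline). Undetected values are excluded, not
    zero-imputed; donors without a detected baseline are dropped for that
    analyte (logged), and analytes undetected in at least
    ``drop_undetected_frac`` of samples are dropped entirely.
    """
    meas = assay.measurements.join(assay.samples, on="sample")
    if baseline not in set(meas["condition"]):
        raise DataError(f"baseline condition {baseline!r} absent from assay")
    rows = []
    for analyte, sub in meas.groupby("analyte", sort=True):
        undet_frac = 1.0 - sub["detected"].mean()
        if undet_frac >= drop_undetected_frac:
            logger.warning(
                "analyte %r undetected in %.0f%% of samples; dropped",
                analyte,
                100 * undet_frac,
            )
            continue
        det = sub.loc[sub["detected"]].copy()
        det["norm"] = det["concentration"] / det["dna"]
        base = det.loc[det["condition"] == baseline].set_index("donor")["norm"]
        for row in det.itertuples():
            if row.condition == baseline:
                continue
            if row.donor not in base.index:
                logger.warning(
                    "analyte %r donor %s: baseline undetected; donor excluded",
                    analyte,
                    row.donor,
                )
                continue
            rows.append(
                (analyte, row.donor, row.condition, row.norm / base[row.donor])
            )
    return pd.DataFrame(rows, columns=["analyte", "donor", "condition", "fold_change"])


# ---------------------------------------------------------------------------
# LDH cytotoxicity
# ---------------------------------------------------------------------------

def ldh_cytotoxicity(sample, neg_control, pos_control):
    """Percent cytotoxicity: 100 * (sample - neg) / (pos - neg).

    The negative control maps to 0% and the lysed positive control to
    100%. Accepts scalars or arrays.
    """
    sample = np.asarray(sample, dtype=float)
    neg = np.asarray(neg_control, dtype=float)
    pos = np.asarray(pos_control, dtype=float)
    if np.any(pos == neg):
        raise DataError("positive and negative LDH controls must differ")
    out = 100.0 * (sample - neg) / (pos - neg)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# normality-gated group comparison
# ---------------------------------------------------------------------------

@dataclass
class GateEvidence:
    """Per-group normality-test p-values behind a gate decision."""

    frame: pd.DataFrame  # group, test, n, p, rejected
    rejected: bool

    def __bool__(self) -> bool:  # truthy when normality was rejected
        return self.rejected


@dataclass
class AssayResult:
    """Outcome of the gated comparison for one analyte/endpoint."""

    analyte: str
    test_used: str  # "anova" | "kruskal" | "skipped" | "degenerate"
    p: float
    evidence: GateEvidence | None = None
    skipped_groups: dict[str, str] = field(default_factory=dict)
    note: str = ""


def _normality_pvalues(name: str, values: np.ndarray) -> list[tuple[str, str, int, float]]:
    out = []
    n = len(values)
    if n >= _DAGOSTINO_MIN_N:
        out.append((name, "dagostino_pearson", n, float(stats.normaltest(values).pvalue)))
    if n >= 3:
        out.append((name, "shapiro_wilk", n, float(stats.shapiro(values).pvalue)))
    if n >= 4:
        out.append((name, "lilliefors", n, float(lilliefors(values, dist="norm")[1])))
    return out


def gated_test(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    gate: str = "any",
    analyte: str = "",
) -> AssayResult:
    """Compare >=2 groups, choosing the test by normality screening.

    Each group is screened with the D'Agostino-Pearson omnibus,
    Shapiro-Wilk, and Lilliefors tests at ``alpha``. With ``gate='any'``
    (strictest) a single rejecting test in any group routes to
    Kruskal-Wallis; ``gate='all'`` requires every applicable test in some
    group to reject. Otherwise one-way ANOVA is used. Groups with n < 3
    are skipped with a reason; identical data across all groups yields
    the degenerate p = 1 convention.
    """
    if gate not in {"any", "all"}:
        raise DataError(f"gate must be 'any' or 'all', got {gate!r}")
    usable: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 3:
            skipped[name] = f"n={len(arr)} < 3"
        else:
            usable[name] = arr
    if len(usable) < 2:
        return AssayResult(
            analyte, "skipped", np.nan, None, skipped, "fewer than 2 usable groups"
        )
    pooled = np.concatenate(list(usable.values()))
    if np.ptp(pooled) == 0:
        ev = GateEvidence(pd.DataFrame(columns=["group", "test", "n", "p", "rejected"]), False)
        return AssayResult(analyte, "degenerate", 1.0, ev, skipped, "all values identical")

    records = []
    for name, arr in usable.items():
        if np.ptp(arr) == 0:
            # constant group: trivially non-Gaussian for screening purposes
            records.append((name, "constant", len(arr), 0.0))
            continue
        records.extend(_normality_pvalues(name, arr))
    frame = pd.DataFrame(records, columns=["group", "test", "n", "p"])
    frame["rejected"] = frame["p"] < alpha
    if gate == "any":
        non_normal = bool(frame["rejected"].any())
    else:
        non_normal = bool(
            frame.groupby("group")["rejected"].all().any()
        )
    evidence = GateEvidence(frame, non_normal)
    if non_normal:
        stat = stats.kruskal(*usable.values())
        return AssayResult(analyte, "kruskal", float(stat.pvalue), evidence, skipped)
    stat = stats.f_oneway(*usable.values())
    p = float(stat.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return AssayResult(analyte, "anova", p, evidence, skipped)


def analyze_assay(
    assay: AssayTable,
    baseline: str = "baseline",
    alpha: float = 0.05,
    gate: str = "any",
    drop_undetected_frac: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full companion-assay analysis: fold changes + gated test per analyte.

    Returns (fold-change table, per-analyte results table with the test
    used and its p-value).
    """
    fc = fold_change(assay, baseline=baseline, drop_undetected_frac=drop_undetected_frac)
    rows = []
    for analyte, sub in fc.groupby("analyte", sort=True):
        groups = {
            str(cond): g["fold_change"].to_numpy()
            for cond, g in sub.groupby("condition")
        }
        res = gated_test(groups, alpha=alpha, gate=gate, analyte=str(analyte))
        rows.append(
            {
                "analyte": analyte,
                "test_used": res.test_used,
                "p": res.p,
                "significant": bool(np.isfinite(res.p) and res.p < alpha),
                "n_groups": len(groups),
                "note": res.note,
            }
        )
    return fc, pd.DataFrame(rows)
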