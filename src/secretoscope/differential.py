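"""Per-protein differential abundance from peptide-level intensities.

Each protein's normalized log2 peptide intensities are modeled with a
linear mixed model

    y = b0 + b_condition + b_batch + u_donor + u_peptide + eps,

where condition contrasts are taken against the reference (baseline)
condition, batch is a fixed effect (the baseline condition is measured in
every batch, which makes the batch shift estimable), and donor and
peptide enter as independent random intercepts: donors are the
repeated-measures unit and peptides carry systematic ionization offsets.
The estimated condition coefficient is the protein's log2 fold change;
its p-value uses a t-statistic with a Satterthwaite approximation to the
degrees of freedom, computed from the REML expected information.

Singular or non-converging fits fall back along a fixed ladder: drop the
donor intercept (``reduced``), then fit ordinary least squares with
peptide as a fixed covariate (``ols_fallback``). Small proteins with only
two peptides regularly land on this ladder, so it is part of the method,
not an afterthought.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import DataError, PeptideTable, SampleDesign

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12

EFFECT_COLUMNS = [
    "protein",
    "condition",
    "log2fc",
    "se",
    "df",
    "p",
    "q",
    "n_peptides",
    "fit_note",
]


@dataclass
class SignificanceRule:
    """Fold-change / significance filter for calling differential proteins.

    ``fc_threshold`` is in log2 units and the comparison is inclusive
    (>=); ``use_absolute=False`` selects upregulated proteins only, the
    convention used for secretome membership lists. ``strict_fc`` switches
    to a strictly-greater comparison. ``use_q`` applies the rule to the
    BH-adjusted q instead of the raw p.
    """

    alpha: float = 0.05
    fc_threshold: float = 1.5
    use_absolute: bool = True
    strict_fc: bool = False
    use_q: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise DataError("alpha must be in (0, 1)")
        if self.fc_threshold < 0:
            raise DataError("fc_threshold must be >= 0")

    def passes(self, log2fc: float, p: float, q: float | None = None) -> bool:
        sig = (q if self.use_q else p) < self.alpha
        mag = abs(log2fc) if self.use_absolute else log2fc
        big = mag > self.fc_threshold if self.strict_fc else mag >= self.fc_threshold
        return bool(sig and big)


# ---------------------------------------------------------------------------
# Satterthwaite df from REML quantities
# ---------------------------------------------------------------------------

def _satterthwaite_df(
    X: np.ndarray,
    Zs: list[np.ndarray],
    theta: np.ndarray,
    y: np.ndarray,
    contrast_indices: list[int],
) -> np.ndarray:
    """Approximate denominator df for single-coefficient contrasts.

    ``theta`` holds the variance components for each Z plus the residual
    variance last. Uses the REML expected information for Var(theta) and
    the analytic gradient of c'Vb(theta)c; df = 2 f^2 / (g' A g).
    """
    n, p = X.shape
    Gs = [Z @ Z.T for Z in Zs] + [np.eye(n)]
    Sigma = theta[-1] * np.eye(n)
    for G, v in zip(Gs[:-1], theta[:-1]):
        Sigma += v * G
    try:
        cho = linalg.cho_factor(Sigma, lower=True)
    except linalg.LinAlgError:
        return np.full(len(contrast_indices), float(max(n - p, 1)))
    Si_X = linalg.cho_solve(cho, X)
    XtSiX = X.T @ Si_X
    Vb = np.linalg.inv(XtSiX)
    # P = Sigma^-1 - Si_X Vb Si_X'
    Si = linalg.cho_solve(cho, np.eye(n))
    P = Si - Si_X @ Vb @ Si_X.T
    m = len(Gs)
    # expected information I_ij = 0.5 tr(P G_i P G_j)
    PGs = [P @ G for G in Gs]
    info = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            info[i, j] = info[j, i] = 0.5 * np.sum(PGs[i] * PGs[j].T)
    A = np.linalg.pinv(info)
    dfs = np.empty(len(contrast_indices))
    for out_i, k in enumerate(contrast_indices):
        f = Vb[k, k]
        a = Si_X @ Vb[:, k]  # Sigma^-1 X Vb c
        g = np.array([a @ (G @ a) for G in Gs[:-1]] + [a @ a])
        denom = float(g @ A @ g)
        if denom <= 0 or not np.isfinite(denom):
            dfs[out_i] = float(max(n - p, 1))
        else:
            dfs[out_i] = float(np.clip(2.0 * f * f / denom, 1.0, n))
    return dfs


# ---------------------------------------------------------------------------
# single-protein fit
# ---------------------------------------------------------------------------

def _long_frame(protein_df: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    long = (
        protein_df.droplevel("protein")
        .reset_index()
        .melt(id_vars="sequence", var_name="sample", value_name="y")
        .dropna(subset=["y"])
        .join(design.frame, on="sample")
    )
    long = long.rename(columns={"sequence": "peptide"})
    # canonical row order: estimates must not depend on input ordering
    return long.sort_values(["peptide", "sample"], kind="mergesort").reset_index(
        drop=True
    )


def _design_matrices(
    long: pd.DataFrame, design: SampleDesign, with_peptide_fixed: bool = False
) -> tuple[np.ndarray, list[str], list[int]]:
    """Fixed-effects matrix: intercept, condition dummies vs reference,
    batch dummies (if >1 batch observed), optionally peptide dummies."""
    conds = [c for c in design.contrasts if c in set(long["condition"])]
    cols = [np.ones(len(long))]
    names = ["Intercept"]
    for c in conds:
        cols.append((long["condition"] == c).to_numpy(float))
        names.append(f"condition[{c}]")
    batches = sorted(set(long["batch"]))
    for b in batches[1:]:
        cols.append((long["batch"] == b).to_numpy(float))
        names.append(f"batch[{b}]")
    if with_peptide_fixed:
        peps = sorted(set(long["peptide"]))
        for pep in peps[1:]:
            cols.append((long["peptide"] == pep).to_numpy(float))
            names.append(f"peptide[{pep}]")
    X = np.column_stack(cols)
    contrast_idx = [names.index(f"condition[{c}]") for c in conds]
    return X, names, contrast_idx


def _dummies(values: pd.Series) -> np.ndarray:
    cats = pd.Categorical(values)
    return np.eye(len(cats.categories))[cats.codes]


def _effects_frame(
    protein: str,
    conds: list[str],
    beta: np.ndarray,
    se: np.ndarray,
    dfs: np.ndarray,
    n_peptides: int,
    note: str,
) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = np.empty(len(beta))
    for i in range(len(beta)):
        if se[i] > 0:
            p[i] = 2.0 * stats.t.sf(abs(beta[i] / se[i]), dfs[i])
        else:
            # zero-variance fit: no evidence against 0 unless the point
            # estimate itself is non-zero
            p[i] = 1.0 if beta[i] == 0 else 0.0
    return pd.DataFrame(
        {
            "protein": protein,
            "condition": conds,
            "log2fc": beta,
            "se": se,
            "df": dfs,
            "p": p,
            "q": np.nan,
            "n_peptides": n_peptides,
            "fit_note": note,
        }
    )


def _fit_ols(
    protein: str, long: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    n_peptides = long["peptide"].nunique()
    X, names, cidx = _design_matrices(
        long, design, with_peptide_fixed=n_peptides > 1
    )
    y = long["y"].to_numpy(float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - rank, 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    if s2 < _ZERO_VAR_TOL:
        se = np.zeros(len(cidx))
        # exact fit: round coefficients that are numerically zero
        beta = np.where(np.abs(beta) < 1e-9, 0.0, beta)
    else:
        se = np.sqrt(s2 * np.diag(XtX_inv)[cidx])
    conds = [names[k].split("[")[1][:-1] for k in cidx]
    return _effects_frame(
        protein,
        conds,
        beta[cidx],
        se,
        np.full(len(cidx), float(dof)),
        n_peptides,
        "ols_fallback",
    )


def _fit_mixed(
    protein: str,
    long: pd.DataFrame,
    design: SampleDesign,
    random_effects: tuple[str, ...],
) -> pd.DataFrame | None:
    """One MixedLM fit with the requested random intercepts, or None."""
    X, names, cidx = _design_matrices(long, design)
    y = long["y"].to_numpy(float)
    Zs = []
    used = []
    for term in random_effects:
        Z = _dummies(long[term])
        if Z.shape[1] >= 2:
            Zs.append(Z)
            used.append(term)
    if not Zs:
        return None
    exog_vc = {t: {"all": Z} for t, Z in zip(used, Zs)}
    groups = np.zeros(len(y))  # single group: donor and peptide are crossed
    from statsmodels.regression.mixed_linear_model import VCSpec

    vcs = VCSpec(
        names=used,
        colnames=[[[f"{t}{i}" for i in range(Z.shape[1])]] for t, Z in zip(used, Zs)],
        mats=[[Z] for Z in Zs],
    )
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups, exog_re=None, exog_vc=vcs)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            ok = np.all(np.isfinite(cand.params)) and np.all(
                np.isfinite(np.asarray(cand.bse)[: len(names)])
            )
            if not ok:
                continue
            # variance components on the boundary routinely trip the
            # optimizer's own success flag; a finite boundary solution is
            # still a valid REML fit, so keep the best candidate
            if res is None or cand.converged:
                res = cand
            if cand.converged:
                break
    if res is None:
        return None
    beta = np.asarray(res.fe_params)
    se = np.asarray(res.bse[: len(names)])
    # variance components on the data scale: vcomp is scaled by `scale`
    theta = np.append(np.asarray(res.vcomp) * res.scale, res.scale)
    dfs = _satterthwaite_df(X, Zs, theta, y, cidx)
    conds = [names[k].split("[")[1][:-1] for k in cidx]
    note = "full" if set(used) == set(random_effects) and len(random_effects) == 2 else "reduced"
    return _effects_frame(
        protein, conds, beta[cidx], se[cidx], dfs, long["peptide"].nunique(), note
    )


def fit_protein(
    protein_df: pd.DataFrame,
    design: SampleDesign,
    random_effects: tuple[str, ...] = ("donor", "peptide"),
) -> pd.DataFrame:
    """Fit one protein; returns one effect row per non-reference condition.

    ``protein_df`` is the (protein, sequence)-indexed slice of a
    normalized log2 table for a single protein. Raises
    :class:`~secretoscope.containers.DataError` if the contrast is
    inestimable (reference unobserved, or fewer than two conditions).
    """
    protein = protein_df.index.get_level_values("protein")[0]
    long = _long_frame(protein_df, design)
    observed_conds = set(long["condition"])
    if len(observed_conds) < 2:
        raise DataError(
            f"protein {protein}: fewer than 2 conditions observed; inestimable"
        )
    if design.reference not in observed_conds:
        raise DataError(
            f"protein {protein}: reference condition has no observations"
        )
    # center the response: contrasts are location-invariant, and this makes
    # the optimization identical whether or not the normalization re-added
    # its pooled location constant
    long = long.assign(y=long["y"] - long["y"].mean())
    y = long["y"].to_numpy(float)
    if np.ptp(y) < 1e-9:
        # constant input: all contrasts are exactly zero, no evidence
        X, names, cidx = _design_matrices(long, design)
        conds = [names[k].split("[")[1][:-1] for k in cidx]
        return _effects_frame(
            protein,
            conds,
            np.zeros(len(cidx)),
            np.zeros(len(cidx)),
            np.full(len(cidx), float(max(len(y) - X.shape[1], 1))),
            long["peptide"].nunique(),
            "ols_fallback",
        )
    # an (essentially) exact fixed-effects fit leaves no residual variance
    # for the mixed model to work with: take the exact answer directly
    n_peptides = long["peptide"].nunique()
    X_sat, _, _ = _design_matrices(long, design, with_peptide_fixed=n_peptides > 1)
    beta_sat, _, rank_sat, _ = np.linalg.lstsq(X_sat, y, rcond=None)
    resid_sat = y - X_sat @ beta_sat
    if len(y) > rank_sat and float(resid_sat @ resid_sat) / (len(y) - rank_sat) < 1e-10:
        return _fit_ols(protein, long, design)
    ladders = [tuple(random_effects)]
    if "donor" in random_effects and len(random_effects) > 1:
        ladders.append(tuple(t for t in random_effects if t != "donor"))
    for ladder in ladders:
        out = _fit_mixed(protein, long, design, ladder)
        if out is not None:
            if ladder != tuple(random_effects):
                out["fit_note"] = "reduced"
            return out
    return _fit_ols(protein, long, design)


# ---------------------------------------------------------------------------
# estimator over all proteins
# ---------------------------------------------------------------------------

class PeptideMixedModelDifferential(BaseEstimator):
    """Protein-level log2 fold changes vs the reference condition.

    Fits the peptide-level mixed model per protein and collects effects
    in deterministic (protein, condition) order with per-contrast BH
    adjustment across proteins. Attributes set by :meth:`fit`:
    ``effects_`` (DataFrame with columns protein, condition, log2fc, se,
    df, p, q, n_peptides, fit_note) and ``failures_`` (protein -> reason
    for inestimable fits; the batch never aborts).
    """

    def __init__(self, random_effects: tuple[str, ...] = ("donor", "peptide")):
        self.random_effects = random_effects

    def fit(self, table: PeptideTable, design: SampleDesign) -> "PeptideMixedModelDifferential":
        design.check_samples(table.sample_ids)
        log2 = table.log2().intensities
        rows = []
        failures: dict[str, str] = {}
        for protein, sub in log2.groupby(level="protein", sort=True):
            try:
                rows.append(
                    fit_protein(sub, design, random_effects=tuple(self.random_effects))
                )
            except DataError as exc:
                failures[str(protein)] = str(exc)
                logger.warning("skipping %s: %s", protein, exc)
        if rows:
            effects = pd.concat(rows, ignore_index=True)
            effects = effects.sort_values(["protein", "condition"], kind="mergesort")
            effects = effects.reset_index(drop=True)
            for cond, idx in effects.groupby("condition").groups.items():
                p = effects.loc[idx, "p"].to_numpy()
                effects.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
        else:
            effects = pd.DataFrame(columns=EFFECT_COLUMNS)
        self.effects_ = effects
        self.failures_ = failures
        return self


def run_differential(
    table: PeptideTable,
    design: SampleDesign,
    random_effects: tuple[str, ...] = ("donor", "peptide"),
) -> pd.DataFrame:
    """Functional wrapper: effects table for all proteins x contrasts."""
    return PeptideMixedModelDifferential(random_effects=random_effects).fit(
        table, design
    ).effects_


def select_significant(
    effects: pd.DataFrame, rule: SignificanceRule | None = None
) -> dict[str, set[str]]:
    """Apply the fold-change / significance rule per condition.

    Returns condition -> set of protein ids passing the rule.
    """
    rule = rule or SignificanceRule()
    out: dict[str, set[str]] = {}
    for cond, sub in effects.groupby("condition"):
        hits = {
            str(r.protein)
            for r in sub.itertuples()
            if np.isfinite(r.log2fc)
            and rule.passes(r.log2fc, r.p, None if np.isnan(r.q) else r.q)
        }
        out[str(cond)] = hits
    return out


def membership_table(selected: dict[str, set[str]]) -> pd.DataFrame:
    """Protein -> comma-joined condition memberships (reference-style list)."""
    proteins = sorted(set().union(*selected.values())) if selected else []
    rows = [
        (p, ",".join(sorted(c for c, s in selected.items() if p in s)))
        for p in proteins
    ]
    return pd.DataFrame(rows, columns=["protein", "conditions"])
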