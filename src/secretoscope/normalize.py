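"""Rescaled z-score normalization of log2 peptide intensities.

Removes per-sample loading differences: within each sample the observed
log2 intensities are z-scored and then mapped back onto a common scale by
multiplying with the average per-sample standard deviation and re-adding
the average per-sample mean,

    x'(i,s) = ((log2 x(i,s) - mu_s) / sigma_s) * sigma_bar + mu_bar.

After the transform every sample has observed-cell mean ``mu_bar`` and SD
``sigma_bar``. The location constant ``mu_bar`` keeps values on a
recognisable intensity scale; it is shared by all samples and therefore
cancels in every baseline-referenced contrast (fold changes are invariant
to ``add_location``, which is unit-tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import DataError, PeptideTable


@dataclass
class NormalizationParams:
    """Per-sample moments and the pooled scale/location."""

    sample_mean: pd.Series  # mu_s over observed log2 cells
    sample_sd: pd.Series  # sigma_s (ddof=1)
    pooled_sd: float  # sigma_bar = mean of sigma_s
    pooled_mean: float  # mu_bar = mean of mu_s

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"mean_log2": self.sample_mean, "sd_log2": self.sample_sd}
        )
        df["pooled_sd"] = self.pooled_sd
        df["pooled_mean"] = self.pooled_mean
        return df.reset_index(names="sample")


class RescaledZScoreNormalizer(BaseEstimator):
    """Per-sample z-score of log2 intensities, rescaled by the average SD.

    ``fit`` learns per-sample means/SDs over observed cells (sample SD,
    ddof=1); ``transform`` applies the affine map above, leaving missing
    cells missing. Attributes set by fit: ``params_``.
    """

    def __init__(self, add_location: bool = True):
        self.add_location = add_location

    def fit(self, table: PeptideTable) -> "RescaledZScoreNormalizer":
        log2 = table.log2().intensities
        mean = log2.mean(axis=0, skipna=True)
        counts = log2.notna().sum(axis=0)
        too_few = counts[counts < 2]
        if not too_few.empty:
            raise DataError(
                "normalization needs >=2 observed peptides per sample; "
                f"too few in {list(too_few.index)}"
            )
        sd = log2.std(axis=0, ddof=1, skipna=True)
        flat = sd[sd <= 0]
        if not flat.empty:
            raise DataError(
                f"zero variance of observed log2 intensities in sample(s) "
                f"{list(flat.index)}; cannot z-score"
            )
        self.params_ = NormalizationParams(
            sample_mean=mean,
            sample_sd=sd,
            pooled_sd=float(sd.mean()),
            pooled_mean=float(mean.mean()),
        )
        return self

    def transform(self, table: PeptideTable) -> PeptideTable:
        p = self.params_
        log2 = table.log2().intensities
        z = (log2 - p.sample_mean) / p.sample_sd
        out = z * p.pooled_sd
        if self.add_location:
            out = out + p.pooled_mean
        return PeptideTable(out, is_log2=True)

    def fit_transform(self, table: PeptideTable) -> PeptideTable:
        return self.fit(table).transform(table)


def normalize(
    table: PeptideTable, add_location: bool = True
) -> tuple[PeptideTable, NormalizationParams]:
    """Functional wrapper: normalized log2 table plus the learned params."""
    norm = RescaledZScoreNormalizer(add_location=add_location)
    out = norm.fit_transform(table)
    return out, norm.params_
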