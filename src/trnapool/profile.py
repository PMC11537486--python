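"""Decoder-family abundance summaries: fold changes, pool-fraction profile,
Z-score matrices, tissue comparison and DE-set overlap.

The *pool profile* expresses each decoder family's normalized reads as a
percentage of the total cytoplasmic decoder pool per sample, then summarizes
per genotype (mean +/- SEM).  Plotting the KI percentage against the WT
percentage and fitting an ordinary least-squares line makes compositional
shifts visible: decoders that lost proportionally more than the pool average
fall below the line.  Significance flags come from decoder-level differential
expression (adjusted p <= threshold and fold change < 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change_table",
    "decoder_fold_changes",
    "PoolProfile",
    "pool_profile",
    "zscore_matrix",
    "PairedComparison",
    "compare_tissue_distributions",
    "OverlapResult",
    "de_overlap",
]

logger = logging.getLogger(__name__)


def fold_change_table(norm: pd.DataFrame, genotypes: pd.Series) -> pd.DataFrame:
    """Per-feature group means and KI/WT fold change on normalized counts.

    Returns columns wt_mean, ki_mean, fold_change and log10_wt_mean (for
    MA-style plotting).  A WT mean of zero leaves fold_change as NaN with a
    logged warning.
    """
    geno = genotypes.reindex(norm.columns)
    if geno.isna().any():
        raise ValueError(f"genotype missing for samples {list(geno.index[geno.isna()])}")
    wt = norm.loc[:, (geno == "WT").to_numpy()].mean(axis=1)
    ki = norm.loc[:, (geno == "KI").to_numpy()].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = ki / wt
        log10_wt = np.log10(wt)
    fc = fc.where(wt > 0)
    zero_wt = list(fc.index[wt <= 0])
    if zero_wt:
        logger.warning("WT mean of 0 for features %s; fold change undefined", zero_wt)
    return pd.DataFrame(
        {"wt_mean": wt, "ki_mean": ki, "fold_change": fc, "log10_wt_mean": log10_wt}
    )


def decoder_fold_changes(
    norm_iso: pd.DataFrame,
    registry,
    genotypes: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change tables at decoder and isodecoder level.

    The decoder table aggregates member normalized counts (sum) per family
    before taking group means.  The isodecoder table carries the family id and
    a within-family ordering by fold change (1 = largest fold change).
    """
    fam_members = registry.family_members()
    rows = {}
    for fam_id, members in fam_members.items():
        present = [m for m in members if m in norm_iso.index]
        if present:
            rows[fam_id] = norm_iso.loc[present].sum(axis=0)
    decoder_norm = pd.DataFrame(rows).T
    decoder_norm.columns = norm_iso.columns
    decoder_tab = fold_change_table(decoder_norm, genotypes)

    iso_ids = [
        m for members in fam_members.values() for m in members if m in norm_iso.index
    ]
    iso_tab = fold_change_table(norm_iso.loc[iso_ids], genotypes)
    fam_of = {m: fid for fid, members in fam_members.items() for m in members}
    iso_tab["family_id"] = [fam_of[i] for i in iso_tab.index]
    iso_tab["family_rank"] = (
        iso_tab.groupby("family_id")["fold_change"].rank(ascending=False, method="first")
    )
    return decoder_tab, iso_tab


@dataclass
class PoolProfile:
    """Pool-fraction profile per decoder with the KI% ~ WT% regression."""

    table: pd.DataFrame          # wt_pct, wt_pct_sem, ki_pct, ki_pct_sem, fold_change, padj, significant_lower
    slope: float
    intercept: float
    r_value: float


def pool_profile(
    decoder_norm: pd.DataFrame,
    genotypes: pd.Series,
    de: pd.DataFrame | None = None,
    sig_threshold: float = 0.05,
    through_origin: bool = False,
) -> PoolProfile:
    """Per-decoder pool fractions (percent of the total decoder pool).

    Each sample's decoder counts are divided by that sample's total decoder
    reads and scaled to percent, then summarized per genotype as mean +/- SEM.
    An OLS line (with intercept by default; ``through_origin`` forces it
    through zero) of KI mean% on WT mean% is fitted across decoders.
    ``significant_lower`` requires a decoder-level adjusted p <= threshold
    together with a fold change < 1.
    """
    totals = decoder_norm.sum(axis=0)
    zero = list(totals.index[totals <= 0])
    if zero:
        raise ValueError(f"samples with zero total decoder reads: {zero}")
    frac = decoder_norm / totals * 100.0
    geno = genotypes.reindex(decoder_norm.columns)
    out = {}
    for grp, tag in (("WT", "wt"), ("KI", "ki")):
        cols = frac.loc[:, (geno == grp).to_numpy()]
        if cols.shape[1] < 2:
            raise ValueError(f"need >= 2 samples in group {grp}")
        out[f"{tag}_pct"] = cols.mean(axis=1)
        out[f"{tag}_pct_sem"] = cols.std(axis=1, ddof=1) / np.sqrt(cols.shape[1])
    tab = pd.DataFrame(out)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_fc = fold_change_table(decoder_norm, genotypes)["fold_change"]
    tab["fold_change"] = norm_fc

    if through_origin:
        slope = float(
            (tab["wt_pct"] * tab["ki_pct"]).sum() / (tab["wt_pct"] ** 2).sum()
        )
        intercept, r_value = 0.0, float("nan")
    else:
        fit = stats.linregress(tab["wt_pct"], tab["ki_pct"])
        slope, intercept, r_value = float(fit.slope), float(fit.intercept), float(fit.rvalue)

    if de is not None:
        padj = de["padj"].reindex(tab.index)
        tab["padj"] = padj
        tab["significant_lower"] = (padj <= sig_threshold) & (tab["fold_change"] < 1)
    else:
        tab["padj"] = np.nan
        tab["significant_lower"] = False
    tab["below_line"] = tab["ki_pct"] < slope * tab["wt_pct"] + intercept
    return PoolProfile(table=tab, slope=slope, intercept=intercept, r_value=r_value)


def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores: (v - row mean) / row SD with the n-1 divisor.

    Zero-variance rows are dropped with a logged warning; every remaining row
    has mean 0 and SD 1.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples to compute Z-scores")
    sd = values.std(axis=1, ddof=1)
    constant = list(sd.index[~(sd > 0)])
    if constant:
        logger.warning("zero-variance features dropped from Z-score matrix: %s", constant)
    kept = values.loc[sd > 0]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)


@dataclass
class PairedComparison:
    """Paired t-test on per-decoder log2 fold changes between two tissues."""

    t_statistic: float
    p_value: float
    mean_log2_difference: float
    n_decoders: int


def compare_tissue_distributions(
    fc_a: pd.Series, fc_b: pd.Series
) -> PairedComparison:
    """Two-sided paired t-test on log2 fold changes, paired by decoder family.

    The tables are inner-joined on decoder id (unmatched decoders are logged
    and dropped).  When every paired difference is zero the test is degenerate
    and p = 1 is returned by convention.
    """
    shared = fc_a.index.intersection(fc_b.index)
    dropped = fc_a.index.symmetric_difference(fc_b.index)
    if len(dropped):
        logger.info("decoders present in only one tissue dropped: %s", sorted(dropped))
    a = fc_a.loc[shared].astype(float)
    b = fc_b.loc[shared].astype(float)
    ok = (a > 0) & (b > 0) & a.notna() & b.notna()
    if (~ok).any():
        logger.info("decoders with undefined fold change dropped: %s", sorted(shared[~ok]))
    d = np.log2(a[ok].to_numpy()) - np.log2(b[ok].to_numpy())
    if len(d) < 3:
        raise ValueError("need >= 3 shared decoders with defined fold changes")
    if np.allclose(d, 0.0):
        return PairedComparison(0.0, 1.0, 0.0, len(d))
    sd = d.std(ddof=1)
    if sd == 0:
        # constant nonzero difference: infinitely strong evidence
        return PairedComparison(math.inf if d.mean() > 0 else -math.inf, 0.0, float(d.mean()), len(d))
    t = stats.ttest_rel(np.log2(a[ok].to_numpy()), np.log2(b[ok].to_numpy()))
    return PairedComparison(
        float(t.statistic), float(t.pvalue), float(d.mean()), len(d)
    )


@dataclass
class OverlapResult:
    only_a: tuple[str, ...]
    shared: tuple[str, ...]
    only_b: tuple[str, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.shared), len(self.only_b))


def de_overlap(
    de_a: pd.DataFrame, de_b: pd.DataFrame, threshold: float = 0.05
) -> OverlapResult:
    """Venn-style overlap of significant decoder sets (p_adjusted < threshold)."""
    set_a = set(de_a.index[de_a["padj"] < threshold])
    set_b = set(de_b.index[de_b["padj"] < threshold])
    return OverlapResult(
        only_a=tuple(sorted(set_a - set_b)),
        shared=tuple(sorted(set_a & set_b)),
        only_b=tuple(sorted(set_b - set_a)),
    )
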