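"""Low-count filtering, control-anchored size factors and the total-abundance statistic.

Because a global reduction of the tRNA pool is invisible to library-size
normalization (every library is sequenced to an arbitrary depth), counts are
anchored to *control* features whose cellular abundance is condition-invariant:
a synthetic spike-in added at known mass per unit input RNA, and the
mitochondrially encoded tRNAs (whose levels are unaffected in the condition
under study).  Two estimators are provided:

``sum_of_controls``
    per-sample factor = the summed raw counts of the control features.

``median_of_ratios``
    the classic control-gene median-of-ratios estimator: each control feature
    is divided by its geometric mean across samples and the per-sample factor
    is the median of those ratios over controls (controls containing a zero
    have geometric mean zero and are excluded).

The total-abundance statistic divides each sample's summed nuclear tRNA counts
by its size factor and expresses the result relative to the mean WT value, so
a global deficit appears directly as a mean KI value below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .registry import TRNARegistry

__all__ = [
    "SizeFactors",
    "TotalAbundanceResult",
    "filter_low",
    "sum_of_controls_factors",
    "median_of_ratios_factors",
    "normalized_counts",
    "total_trna_abundance",
]

logger = logging.getLogger(__name__)


@dataclass
class SizeFactors:
    """Per-sample positive scaling factors estimated from control features."""

    factors: pd.Series
    method: str
    control_set: str | None = None

    def __post_init__(self):
        f = self.factors.astype(float)
        if len(f) == 0:
            raise ValueError("no samples")
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            bad = list(f.index[~(f > 0)])
            raise ValueError(f"non-positive size factor for samples {bad}")
        self.factors = f


def filter_low(
    cm: CountMatrix,
    registry: TRNARegistry | None = None,
    threshold: float = 10,
    stat: str = "mean",
) -> CountMatrix:
    """Drop features whose raw-count summary is not strictly above ``threshold``.

    ``stat`` selects the per-feature summary across samples: ``mean`` (default),
    ``min`` or ``total``.  Control features (mito/spike) are exempt from removal
    so that size-factor estimation never loses its anchors; a control falling
    below the threshold is logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if stat == "mean":
        summary = cm.counts.mean(axis=1)
    elif stat == "min":
        summary = cm.counts.min(axis=1)
    elif stat == "total":
        summary = cm.counts.sum(axis=1)
    else:
        raise ValueError(f"unknown filter stat {stat!r} (expected mean|min|total)")
    keep = summary > threshold
    if registry is not None:
        controls = set(registry.control_ids("both"))
        for fid in cm.feature_ids:
            if fid in controls and not keep.loc[fid]:
                logger.warning(
                    "control feature %s below filter threshold (%s=%.3g); retained",
                    fid, stat, summary.loc[fid],
                )
                keep.loc[fid] = True
    kept = [f for f in cm.feature_ids if keep.loc[f]]
    if not kept:
        raise ValueError("no features survive low-count filtering")
    return cm.subset_features(kept)


def sum_of_controls_factors(
    cm: CountMatrix, registry: TRNARegistry, control_set: str = "both"
) -> SizeFactors:
    """Size factor = summed raw counts of the selected control features."""
    controls = [c for c in registry.control_ids(control_set) if c in cm.counts.index]
    if not controls:
        raise ValueError(f"no control features ({control_set}) present in the matrix")
    factors = cm.counts.loc[controls].sum(axis=0).astype(float)
    zero = list(factors.index[factors <= 0])
    if zero:
        raise ValueError(f"zero control reads in samples {zero}")
    return SizeFactors(factors, method="sum_of_controls", control_set=control_set)


def median_of_ratios_factors(
    cm: CountMatrix, control_ids, control_set: str | None = None
) -> SizeFactors:
    """Control-gene median-of-ratios size factors.

    For each control feature i the geometric mean g_i over samples is computed;
    features with g_i = 0 (any zero count) are excluded; the factor for sample j
    is the median over remaining controls of K_ij / g_i, used as-is.
    """
    controls = [c for c in control_ids if c in cm.counts.index]
    if not controls:
        raise ValueError("no control features present in the matrix")
    sub = cm.counts.loc[controls].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_g = np.log(sub).mean(axis=1)
    usable = np.isfinite(log_g)
    if not usable.any():
        raise ValueError("every control feature contains a zero count; no usable controls")
    dropped = [c for c, u in zip(controls, usable) if not u]
    if dropped:
        logger.info("controls with zero counts excluded from median-of-ratios: %s", dropped)
    ratios = sub[usable] / np.exp(log_g[usable])[:, None]
    factors = pd.Series(np.median(ratios, axis=0), index=cm.counts.columns)
    return SizeFactors(factors, method="median_of_ratios", control_set=control_set)


def normalized_counts(cm: CountMatrix, factors: SizeFactors) -> pd.DataFrame:
    """Counts divided per sample by the size factor."""
    f = factors.factors.reindex(cm.counts.columns)
    if f.isna().any():
        missing = list(f.index[f.isna()])
        raise ValueError(f"size factors missing for samples {missing}")
    return cm.counts / f


@dataclass
class TotalAbundanceResult:
    """Per-sample relative total nuclear tRNA abundance and the group contrast."""

    relative: pd.Series          # T_j / mean(T over WT)
    group_stats: pd.DataFrame    # mean, sd, n per genotype
    p_value: float               # two-sided Welch t on the relative values
    reduction_percent: float     # 100 * (1 - mean KI relative value)


def total_trna_abundance(
    cm: CountMatrix, factors: SizeFactors, registry: TRNARegistry
) -> TotalAbundanceResult:
    """Normalized total nuclear tRNA abundance, relative to the WT mean.

    T_j = (sum of nuclear counts in sample j) / factor_j; r_j = T_j / mean_WT(T).
    Reports per-group mean +/- SD and a two-sided Welch t-test p on r_j.
    """
    nuclear = [g for g in registry.nuclear_ids if g in cm.counts.index]
    if not nuclear:
        raise ValueError("no nuclear features present in the matrix")
    totals = cm.counts.loc[nuclear].sum(axis=0) / factors.factors.reindex(cm.counts.columns)
    geno = cm.genotypes
    for grp in ("WT", "KI"):
        if (geno == grp).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {grp}")
    relative = totals / totals[geno == "WT"].mean()
    r_wt = relative[geno == "WT"].to_numpy()
    r_ki = relative[geno == "KI"].to_numpy()
    t = stats.ttest_ind(r_wt, r_ki, equal_var=False)
    group_stats = pd.DataFrame(
        {
            "mean": [r_wt.mean(), r_ki.mean()],
            "sd": [r_wt.std(ddof=1), r_ki.std(ddof=1)],
            "n": [len(r_wt), len(r_ki)],
        },
        index=pd.Index(["WT", "KI"], name="genotype"),
    )
    return TotalAbundanceResult(
        relative=relative,
        group_stats=group_stats,
        p_value=float(t.pvalue),
        reduction_percent=100.0 * (1.0 - r_ki.mean()),
    )
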