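"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KI")


@dataclass
class CountMatrix:
    """Features x samples integer read counts plus per-sample annotation.

    ``counts`` rows are tRNA feature ids resolvable in a registry; columns are
    sample ids.  ``samples`` is indexed by sample id and carries at least a
    ``genotype`` column (WT/KI) and optionally ``tissue``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dupes = sorted(c.index[c.index.duplicated()].unique())
            raise ValueError(f"duplicate feature ids {dupes}")
        if c.columns.has_duplicates:
            dupes = sorted(c.columns[c.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids {dupes}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if not np.array_equal(arr, np.floor(arr)):
            i, j = np.argwhere(arr != np.floor(arr))[0]
            raise ValueError(
                f"non-integer count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        missing = [s for s in c.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        if "genotype" not in self.samples.columns:
            raise ValueError("sample sheet lacks a 'genotype' column")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes {sorted(bad)} (expected WT/KI)")
        # align annotation to column order
        self.samples = self.samples.loc[list(c.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genotypes(self) -> pd.Series:
        return self.samples["genotype"]

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.samples.copy())

    def subset_samples(self, sample_ids) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.samples.loc[ids])
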