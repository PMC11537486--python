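"""Plain-TSV readers and writers for every pipeline artifact.

Count matrices in this domain are small (a few hundred features), so all
interchange is uncompressed TSV: a counts table (first column feature ids,
header row of sample ids), a sample sheet (sample_id, genotype, tissue), a
registry table and per-stage result tables.  Reading is strict: duplicate
ids, ragged rows, negative or non-integer counts are errors that name the
offending cell.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .containers import CountMatrix
from .registry import TRNAGene, TRNARegistry, build_registry

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_count_matrix",
    "write_count_matrix",
    "read_registry",
    "write_registry",
    "read_table",
    "write_table",
]


def read_counts(path) -> pd.DataFrame:
    """Strictly parse a counts TSV: integer cells, unique ids, rectangular."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty counts file") from None
        sample_ids = header[1:]
        if not sample_ids:
            raise ValueError(f"{path}: no sample columns")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"{path}: duplicate sample ids {dupes}")
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {len(header)})"
                )
            fid = row[0]
            values = []
            for sid, cell in zip(sample_ids, row[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer count {cell!r} at feature {fid!r}, sample {sid!r}"
                    ) from None
                if v < 0:
                    raise ValueError(
                        f"{path}: negative count {v} at feature {fid!r}, sample {sid!r}"
                    )
                values.append(v)
            feature_ids.append(fid)
            rows.append(values)
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise ValueError(f"{path}: duplicate feature ids {dupes}")
    return pd.DataFrame(rows, index=feature_ids, columns=sample_ids)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns or "genotype" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet needs sample_id and genotype columns")
    if sheet["sample_id"].duplicated().any():
        dupes = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    return sheet.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_sample_sheet(samples_path))


def write_count_matrix(cm: CountMatrix, counts_path, samples_path) -> None:
    write_counts(cm.counts, counts_path)
    write_sample_sheet(cm.samples, samples_path)


_REGISTRY_COLUMNS = ["gene_id", "isotype", "anticodon", "compartment", "locus_ids", "unique_locus"]


def write_registry(registry: TRNARegistry, path) -> None:
    rows = []
    for g in registry.genes.values():
        rows.append(
            {
                "gene_id": g.gene_id,
                "isotype": g.isotype,
                "anticodon": g.anticodon,
                "compartment": g.compartment,
                "locus_ids": ",".join(g.locus_ids),
                "unique_locus": str(g.unique_locus).lower(),
            }
        )
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_registry(path, alias_map=None, merge_imet: bool = False) -> TRNARegistry:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_REGISTRY_COLUMNS[:5]) - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: registry missing columns {sorted(missing)}")
    genes = [
        TRNAGene(
            row.gene_id,
            row.isotype,
            row.anticodon,
            row.compartment,
            tuple(row.locus_ids.split(",")) if isinstance(row.locus_ids, str) and row.locus_ids else (),
        )
        for row in tab.itertuples()
    ]
    # aliases pointing outside this registry's gene set are irrelevant here
    present = {g.gene_id for g in genes}
    alias_map = {a: t for a, t in dict(alias_map or {}).items() if t in present}
    return build_registry(genes, alias_map=alias_map, merge_imet=merge_imet)


def read_table(path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
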