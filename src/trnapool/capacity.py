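"""Wobble-rule decoding capacity of decoder families.

A tRNA reads a codon by pairing its anticodon (written 5'->3') with the codon
(5'->3') in antiparallel orientation: codon positions 1-2 pair strictly
Watson-Crick with anticodon positions 36-35 (the reverse complement), while
codon position 3 pairs with anticodon position 34 under relaxed *wobble*
rules.  The default wobble table

    A34 -> {T, C}      G34 -> {C, T}      C34 -> {G}      T34 -> {A, G}

lets one decoder read one or two codons of its amino acid's codon box.  The
*decoding fraction* of a family is the usage-weighted share of its amino
acid's codons that the family can read; with genome-wide mouse codon usage
this reproduces, e.g., 100% for Tyr-GTA (both Tyr codons), ~41% for Ser-AGA
and ~42% for Val-AAC.  An alternate table treating A34 as inosine-like
(reading T, C and A) is provided; it broadens A34 families' reach and is not
the default.

The suppressor/selenocysteine family (Sup, anticodon TCA) would read the TGA
stop codon, which carries no amino-acid assignment under the standard code:
its decoding fraction is reported as explicitly undefined, never as a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WOBBLE",
    "INOSINE_WOBBLE",
    "UndefinedDecodingError",
    "decoded_codons",
    "synonymous_codons",
    "decoding_fraction",
    "decoding_potential_report",
    "load_mouse_usage",
    "read_usage_table",
    "read_wobble_table",
    "write_wobble_table",
]

#: anticodon position-34 base -> codon third-position bases it pairs with
DEFAULT_WOBBLE: dict[str, frozenset[str]] = {
    "A": frozenset("TC"),
    "G": frozenset("CT"),
    "C": frozenset("G"),
    "T": frozenset("AG"),
}

#: alternate table with eukaryotic A34 -> inosine reading {T, C, A}
INOSINE_WOBBLE: dict[str, frozenset[str]] = {
    **DEFAULT_WOBBLE,
    "A": frozenset("TCA"),
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: 3-letter isotype -> 1-letter amino acid of the standard code
_ISO_TO_AA = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


class UndefinedDecodingError(ValueError):
    """The isotype has no codons under the (standard) genetic code."""


def _standard_code() -> dict[str, str]:
    """codon -> 1-letter amino acid (sense codons only), standard code."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    return dict(table.forward_table)


def _validate_anticodon(anticodon: str) -> None:
    if len(anticodon) != 3 or set(anticodon) - set("ACGT"):
        raise ValueError(f"anticodon {anticodon!r} is not a 3-mer over A/C/G/T")


def decoded_codons(
    anticodon: str, wobble: dict[str, frozenset[str]] | None = None
) -> frozenset[str]:
    """Codons readable by an anticodon under the wobble table.

    Codon positions 1-2 are the reverse complement of anticodon positions
    36-35; position 3 ranges over the wobble set of the position-34 base.
    """
    _validate_anticodon(anticodon)
    wobble = wobble or DEFAULT_WOBBLE
    first_two = _COMPLEMENT[anticodon[2]] + _COMPLEMENT[anticodon[1]]
    thirds = wobble[anticodon[0]]
    if not thirds:
        raise ValueError(f"wobble table maps {anticodon[0]!r} to an empty set")
    return frozenset(first_two + b3 for b3 in thirds)


def synonymous_codons(
    isotype: str, code: dict[str, str] | None = None
) -> frozenset[str]:
    """All codons of the family's amino acid; iMet maps to the Met codon ATG.

    Raises :class:`UndefinedDecodingError` for isotypes without sense codons
    under the code (Sup/SeC read the TGA stop; Und has no assignment).
    """
    code = code or _standard_code()
    if isotype == "iMet":
        aa = "M"
    elif isotype in _ISO_TO_AA:
        aa = _ISO_TO_AA[isotype]
    else:
        raise UndefinedDecodingError(
            f"isotype {isotype!r} has no codons under the standard code"
        )
    return frozenset(c for c, a in code.items() if a == aa)


def decoding_fraction(
    isotype: str,
    anticodon: str,
    usage: pd.DataFrame,
    wobble: dict[str, frozenset[str]] | None = None,
    code: dict[str, str] | None = None,
) -> float:
    """Usage-weighted fraction of the amino acid's codons the family decodes.

    fraction = sum(usage over decoded & synonymous) / sum(usage over synonymous);
    invariant under rescaling of the usage weights.
    """
    syn = synonymous_codons(isotype, code)
    missing = syn - set(usage.index)
    if missing:
        raise ValueError(f"usage weights missing for codons {sorted(missing)}")
    weights = usage["per_1000"].astype(float)
    if (weights < 0).any():
        raise ValueError("usage weights must be >= 0")
    total = weights.loc[sorted(syn)].sum()
    if total <= 0:
        raise ValueError(f"zero total usage over the {isotype} codon box")
    decoded = decoded_codons(anticodon, wobble) & syn
    return float(weights.loc[sorted(decoded)].sum() / total)


def load_mouse_usage() -> pd.DataFrame:
    """Packaged genome-wide mouse codon-usage table (per-1000 frequencies)."""
    with resources.files("trnapool.data").joinpath("mouse_codon_usage.tsv").open() as fh:
        return read_usage_table(fh)


def read_usage_table(path_or_buf) -> pd.DataFrame:
    """Read a codon-usage TSV with columns codon, amino_acid, per_1000."""
    tab = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype={"codon": str})
    required = {"codon", "amino_acid", "per_1000"}
    if not required <= set(tab.columns):
        raise ValueError(f"usage table must have columns {sorted(required)}")
    tab = tab.set_index("codon")
    bad = [c for c in tab.index if len(c) != 3 or set(c) - set("ACGT")]
    if bad:
        raise ValueError(f"invalid codons in usage table: {bad}")
    if tab.index.has_duplicates:
        raise ValueError("duplicate codons in usage table")
    return tab


def read_wobble_table(path_or_buf) -> dict[str, frozenset[str]]:
    """Read a wobble TSV with columns base34, reads (comma-joined bases)."""
    tab = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    if not {"base34", "reads"} <= set(tab.columns):
        raise ValueError("wobble table must have columns base34, reads")
    wobble = {
        row.base34: frozenset(b.strip() for b in row.reads.split(","))
        for row in tab.itertuples()
    }
    for b34, reads in wobble.items():
        if b34 not in "ACGT" or not reads or reads - set("ACGT"):
            raise ValueError(f"invalid wobble entry {b34!r} -> {sorted(reads)}")
    missing = set("ACGT") - set(wobble)
    if missing:
        raise ValueError(f"wobble table missing bases {sorted(missing)}")
    return wobble


def write_wobble_table(wobble: dict[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("base34\treads\n")
        for b34 in "ACGT":
            fh.write(f"{b34}\t{','.join(sorted(wobble[b34]))}\n")


@dataclass
class DecodingPotentialReport:
    """Per-decoder decoding capacity joined with abundance fold changes."""

    table: pd.DataFrame
    #: usage share of sense codons whose decoder is significantly reduced
    reduced_codon_usage_fraction: float


def decoding_potential_report(
    profile_table: pd.DataFrame,
    usage: pd.DataFrame | None = None,
    wobble: dict[str, frozenset[str]] | None = None,
) -> DecodingPotentialReport:
    """Join the decoder profile with per-family decoding capacity.

    ``profile_table`` is indexed by family id (``Iso-Anticodon``) and carries
    ``fold_change`` and ``significant_lower``.  The pool summary is the share
    of total sense-codon usage covered by codons decoded by at least one
    significantly reduced decoder.
    """
    usage = load_mouse_usage() if usage is None else usage
    code = _standard_code()
    weights = usage["per_1000"].astype(float)
    sense = [c for c in usage.index if c in code]
    total_sense = weights.loc[sense].sum()

    rows = []
    flagged_codons: set[str] = set()
    for fam_id in profile_table.index:
        isotype, _, anticodon = fam_id.rpartition("-")
        row = {
            "isotype": isotype,
            "anticodon": anticodon,
            "decoded_codons": "",
            "decoding_fraction": np.nan,
            "note": "",
        }
        try:
            codons = decoded_codons(anticodon, wobble)
            syn = synonymous_codons(isotype, code)
            row["decoded_codons"] = ",".join(sorted(codons & syn))
            row["decoding_fraction"] = decoding_fraction(
                isotype, anticodon, usage, wobble, code
            )
        except UndefinedDecodingError:
            row["note"] = "undefined under standard code"
        rows.append(row)
        if bool(profile_table.loc[fam_id].get("significant_lower", False)) and not row["note"]:
            flagged_codons |= set(codons & syn)
    tab = pd.DataFrame(rows, index=profile_table.index)
    for col in ("fold_change", "significant_lower"):
        if col in profile_table.columns:
            tab[col] = profile_table[col]
    flagged_usage = weights.loc[sorted(flagged_codons)].sum() if flagged_codons else 0.0
    return DecodingPotentialReport(
        table=tab,
        reduced_codon_usage_fraction=float(flagged_usage / total_sense),
    )
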