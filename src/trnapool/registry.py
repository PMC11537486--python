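"""tRNA gene registry: naming, compartments, locus collapsing and decoder families.

Mature tRNA quantification works at the level of distinct mature sequences.
Several genomic loci can encode byte-identical mature tRNAs; those loci are
collapsed into a single transcript entry whose ``locus_ids`` record every
contributor.  Nuclear transcripts are grouped into *decoder families* keyed by
(isotype, anticodon): all tRNAs read the same codons through the same anticodon,
so their reads are summed when the decoding pool is analysed.  The initiator
methionine tRNA (iMet) shares the CAT anticodon with elongator Met but serves a
distinct function and forms its own family (a merge flag is provided).

Compartments:

``nuclear``
    gtRNAdb-style names, ``tRNA-<Iso>-<Anticodon>-<transcript>-<locus>``.
``mito``
    mitochondrially encoded tRNAs, recognised by a configurable prefix
    (``mt-`` / ``MT-T`` by default).
``spike``
    the synthetic spike-in added at known mass before library prep; it anchors
    counts to input RNA and is condition-invariant by design.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TRNAGene",
    "DecoderFamily",
    "TRNARegistry",
    "parse_trna_name",
    "collapse_identical",
    "build_families",
    "build_registry",
    "format_trna_name",
    "read_fasta_sequences",
    "load_default_aliases",
    "DEFAULT_SPIKE_IDS",
    "DEFAULT_MITO_PREFIXES",
]

#: amino-acid isotypes accepted in gtRNAdb-style names
ISOTYPES = frozenset(
    {
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
        "iMet", "Sup", "SeC", "Und",
    }
)

DEFAULT_MITO_PREFIXES = ("mt-", "MT-T")
DEFAULT_SPIKE_IDS = frozenset({"Ecoli-Gln-spike"})

# mouse mitochondrial tRNA single-letter codes -> (isotype, anticodon);
# standard vertebrate mito anticodons.  Mito genes never join decoder
# families, so the anticodon is annotation only.
MITO_CODES: dict[str, tuple[str, str]] = {
    "a": ("Ala", "TGC"), "r": ("Arg", "TCG"), "n": ("Asn", "GTT"),
    "d": ("Asp", "GTC"), "c": ("Cys", "GCA"), "e": ("Glu", "TTC"),
    "q": ("Gln", "TTG"), "g": ("Gly", "TCC"), "h": ("His", "GTG"),
    "i": ("Ile", "GAT"), "l1": ("Leu", "TAA"), "l2": ("Leu", "TAG"),
    "k": ("Lys", "TTT"), "m": ("Met", "CAT"), "f": ("Phe", "GAA"),
    "p": ("Pro", "TGG"), "s1": ("Ser", "TGA"), "s2": ("Ser", "GCT"),
    "t": ("Thr", "TGT"), "w": ("Trp", "TCA"), "y": ("Tyr", "GTA"),
    "v": ("Val", "TAC"),
}

_ANTICODON_ALPHABET = frozenset("ACGT")


class TRNANameError(ValueError):
    """A tRNA identifier could not be parsed."""


@dataclass(frozen=True)
class TRNAGene:
    """One mature tRNA transcript (possibly encoded by several loci)."""

    gene_id: str
    isotype: str
    anticodon: str
    compartment: str  # nuclear | mito | spike
    locus_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.compartment not in ("nuclear", "mito", "spike"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        ac = self.anticodon
        if len(ac) != 3 or (set(ac) - _ANTICODON_ALPHABET and not (self.isotype == "Und" and ac == "NNN")):
            raise ValueError(
                f"anticodon {ac!r} of {self.gene_id!r} is not a 3-mer over A/C/G/T"
            )
        if not self.locus_ids:
            object.__setattr__(self, "locus_ids", (self.gene_id,))

    @property
    def unique_locus(self) -> bool:
        return len(self.locus_ids) == 1


@dataclass(frozen=True)
class DecoderFamily:
    """All nuclear tRNAs sharing an (isotype, anticodon) pair."""

    isotype: str
    anticodon: str
    member_gene_ids: tuple[str, ...]

    @property
    def family_id(self) -> str:
        return f"{self.isotype}-{self.anticodon}"


def parse_trna_name(
    name: str,
    *,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    spike_ids: Iterable[str] = DEFAULT_SPIKE_IDS,
    alias_map: Mapping[str, str] | None = None,
) -> TRNAGene:
    """Parse a tRNA identifier into a :class:`TRNAGene`.

    Aliases (legacy ``n-TR*`` names and similar) are resolved first; the gene
    keeps its canonical ``gene_id``.  Unknown names raise
    :class:`TRNANameError` naming the offending token.
    """
    if not name:
        raise TRNANameError("empty tRNA name")
    if alias_map and name in alias_map:
        name = alias_map[name]
    if name in set(spike_ids):
        # The study's spike-in is a synthetic tRNA based on E. coli tRNA-Gln.
        return TRNAGene(name, "Gln", "TTG", "spike")
    for prefix in mito_prefixes:
        if name.startswith(prefix):
            code = name[len(prefix):].lower()
            # "mt-Tf" style carries the T of "tRNA" after the prefix; "MT-TF" does not
            if prefix.endswith("-") and len(code) > 1 and code.startswith("t"):
                code = code[1:]
            if code not in MITO_CODES:
                raise TRNANameError(f"unknown mitochondrial tRNA code {code!r} in {name!r}")
            isotype, anticodon = MITO_CODES[code]
            return TRNAGene(name, isotype, anticodon, "mito")
    parts = name.split("-")
    if len(parts) < 3 or parts[0] != "tRNA":
        raise TRNANameError(f"cannot parse tRNA name {name!r} (token {parts[0]!r})")
    isotype, anticodon = parts[1], parts[2]
    if isotype not in ISOTYPES:
        raise TRNANameError(f"unknown isotype {isotype!r} in {name!r}")
    if len(anticodon) != 3 or (set(anticodon) - _ANTICODON_ALPHABET and anticodon != "NNN"):
        raise TRNANameError(f"invalid anticodon {anticodon!r} in {name!r}")
    if anticodon == "NNN" and isotype != "Und":
        raise TRNANameError(f"invalid anticodon {anticodon!r} in {name!r}")
    for token in parts[3:]:
        if not token.isdigit():
            raise TRNANameError(f"invalid numeric token {token!r} in {name!r}")
    return TRNAGene(name, isotype, anticodon, "nuclear")


def format_trna_name(gene: TRNAGene) -> str:
    """Inverse of :func:`parse_trna_name` for registered genes."""
    return gene.gene_id


@dataclass
class TRNARegistry:
    """Gene annotation plus the decoder-family index."""

    genes: dict[str, TRNAGene]
    families: tuple[DecoderFamily, ...] = ()
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for alias, target in self.alias_map.items():
            if target not in self.genes:
                raise KeyError(f"alias {alias!r} points at unregistered gene {target!r}")

    # -- lookups ---------------------------------------------------------
    def resolve(self, name: str) -> TRNAGene:
        gene_id = self.alias_map.get(name, name)
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown tRNA {name!r}") from None

    def ids(self, compartment: str | None = None) -> list[str]:
        if compartment is None:
            return list(self.genes)
        return [g.gene_id for g in self.genes.values() if g.compartment == compartment]

    @property
    def nuclear_ids(self) -> list[str]:
        return self.ids("nuclear")

    def control_ids(self, control_set: str = "both") -> list[str]:
        """Control features used to anchor normalization."""
        if control_set == "spike":
            return self.ids("spike")
        if control_set == "mito":
            return self.ids("mito")
        if control_set == "both":
            return self.ids("mito") + self.ids("spike")
        raise ValueError(f"unknown control_set {control_set!r} (expected spike|mito|both)")

    def family_of(self, gene_id: str) -> DecoderFamily | None:
        for fam in self.families:
            if gene_id in fam.member_gene_ids:
                return fam
        return None

    def family_members(self) -> dict[str, tuple[str, ...]]:
        return {f.family_id: f.member_gene_ids for f in self.families}


def build_families(
    genes: Iterable[TRNAGene], *, merge_imet: bool = False
) -> tuple[DecoderFamily, ...]:
    """Group nuclear genes into decoder families keyed by (isotype, anticodon).

    ``Und`` (undetermined-anticodon) entries carry reads but no decoder
    assignment: they stay out of every family while remaining in the nuclear
    total.  ``merge_imet=True`` folds iMet into the elongator Met-CAT family.
    """
    members: dict[tuple[str, str], list[str]] = defaultdict(list)
    for g in genes:
        if g.compartment != "nuclear" or g.isotype == "Und":
            continue
        isotype = "Met" if (merge_imet and g.isotype == "iMet") else g.isotype
        members[(isotype, g.anticodon)].append(g.gene_id)
    return tuple(
        DecoderFamily(iso, ac, tuple(sorted(ids)))
        for (iso, ac), ids in sorted(members.items())
    )


def collapse_identical(
    sequences: Mapping[str, str], **parse_kwargs
) -> list[TRNAGene]:
    """Merge loci with byte-identical mature sequences into single transcripts.

    ``sequences`` maps locus names to mature sequences over {A,C,G,T,U};
    U is normalized to T before comparison.  The representative ``gene_id``
    is the lexicographically first locus name of each group; merging two
    identical sequences annotated with different anticodons is an error.
    """
    by_seq: dict[str, list[str]] = defaultdict(list)
    for locus in sorted(sequences):
        seq = sequences[locus].upper().replace("U", "T")
        if set(seq) - _ANTICODON_ALPHABET:
            bad = sorted(set(seq) - _ANTICODON_ALPHABET)
            raise ValueError(f"sequence of {locus!r} contains non-ACGTU characters {bad}")
        by_seq[seq].append(locus)
    genes = []
    for seq, loci in by_seq.items():
        parsed = [parse_trna_name(l, **parse_kwargs) for l in loci]
        anticodons = {p.anticodon for p in parsed}
        if len(anticodons) > 1:
            raise ValueError(
                f"identical sequences annotated with different anticodons: {loci} -> {sorted(anticodons)}"
            )
        rep = parsed[0]
        genes.append(
            TRNAGene(rep.gene_id, rep.isotype, rep.anticodon, rep.compartment, tuple(loci))
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def build_registry(
    genes: Iterable[TRNAGene],
    *,
    alias_map: Mapping[str, str] | None = None,
    merge_imet: bool = False,
) -> TRNARegistry:
    gene_list = list(genes)
    ids = [g.gene_id for g in gene_list]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids {dupes}")
    families = build_families(gene_list, merge_imet=merge_imet)
    return TRNARegistry(
        genes={g.gene_id: g for g in gene_list},
        families=families,
        alias_map=dict(alias_map or {}),
    )


def registry_from_names(
    names: Iterable[str],
    *,
    alias_map: Mapping[str, str] | None = None,
    merge_imet: bool = False,
    **parse_kwargs,
) -> TRNARegistry:
    """Build a registry by parsing a list of feature names (e.g. count-matrix rows)."""
    alias_map = dict(alias_map or {})
    genes = [parse_trna_name(n, alias_map=alias_map, **parse_kwargs) for n in names]
    # keep only aliases that point at genes present
    present = {g.gene_id for g in genes}
    alias_map = {a: t for a, t in alias_map.items() if t in present}
    return build_registry(genes, alias_map=alias_map, merge_imet=merge_imet)


def read_fasta_sequences(path) -> dict[str, str]:
    """Read a gtRNAdb-style mature tRNA FASTA: header token before the first
    whitespace is the gene name."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA entry {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def load_default_aliases() -> dict[str, str]:
    """Legacy alias table shipped with the package (editable TSV)."""
    with resources.files("trnapool.data").joinpath("trna_aliases.tsv").open() as fh:
        reader = csv.reader(
            (line for line in fh if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        return {alias: gene_id for alias, gene_id in reader}
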