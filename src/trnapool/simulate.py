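"""Seeded negative-binomial count simulator emulating the tRNA-seq study design.

The generator draws a genes x samples count matrix

    K_ij ~ NB(mean = s_j * q_i * 2^(x_j * LFC_i), dispersion = alpha_i)

where ``s_j`` is a per-sample depth factor, ``q_i`` a per-gene baseline
abundance, ``x_j`` an indicator for the mutant (KI) condition and ``alpha_i``
a per-gene dispersion so that Var = mu + alpha * mu^2.  Baselines are drawn
log-uniformly over ~5 orders of magnitude, matching the read-depth spread of
real mature tRNA-seq.  Nuclear genes receive a condition effect composed of a
global log2 fold change plus seeded per-family and per-gene Gaussian
deviations; the mitochondrial tRNAs and the spike-in — the normalization
anchors — receive a condition effect of exactly zero.

Defaults mirror the study: 6 WT vs 4 KI cerebra, 187 detectable nuclear
isodecoders in 50 decoder families, 22 mitochondrial tRNAs and one spike-in,
and a ~25% global reduction of the nuclear pool in KI with decoder-specific
deviations around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .registry import TRNAGene, TRNARegistry, build_registry

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_counts",
    "nb_sample",
    "MOUSE_DECODER_FAMILIES",
    "MOUSE_MITO_TRNAS",
]

#: the (isotype, anticodon) decoder families of the mouse high-confidence
#: nuclear tRNA set (50 families; iMet-CAT distinct from Met-CAT).
MOUSE_DECODER_FAMILIES: tuple[tuple[str, str], ...] = (
    ("Ala", "AGC"), ("Ala", "CGC"), ("Ala", "TGC"),
    ("Arg", "ACG"), ("Arg", "CCG"), ("Arg", "CCT"), ("Arg", "TCG"), ("Arg", "TCT"),
    ("Asn", "GTT"), ("Asp", "GTC"), ("Cys", "GCA"),
    ("Gln", "CTG"), ("Gln", "TTG"),
    ("Glu", "CTC"), ("Glu", "TTC"),
    ("Gly", "CCC"), ("Gly", "GCC"), ("Gly", "TCC"),
    ("His", "GTG"), ("Ile", "AAT"), ("Ile", "TAT"),
    ("Leu", "AAG"), ("Leu", "CAA"), ("Leu", "CAG"), ("Leu", "TAA"), ("Leu", "TAG"),
    ("Lys", "CTT"), ("Lys", "TTT"),
    ("Met", "CAT"), ("iMet", "CAT"), ("Phe", "GAA"),
    ("Pro", "AGG"), ("Pro", "CGG"), ("Pro", "TGG"),
    ("Ser", "AGA"), ("Ser", "CGA"), ("Ser", "GCT"), ("Ser", "TGA"),
    ("Sup", "TCA"),
    ("Thr", "AGT"), ("Thr", "CGT"), ("Thr", "TGT"),
    ("Trp", "CCA"), ("Tyr", "GTA"),
    ("Val", "AAC"), ("Val", "CAC"), ("Val", "TAC"),
    ("Leu", "GAG"), ("Ile", "GAT"), ("Arg", "GCG"),
)

#: mouse mitochondrially encoded tRNA gene names (22)
MOUSE_MITO_TRNAS: tuple[str, ...] = (
    "mt-Ta", "mt-Tr", "mt-Tn", "mt-Td", "mt-Tc", "mt-Te", "mt-Tq", "mt-Tg",
    "mt-Th", "mt-Ti", "mt-Tl1", "mt-Tl2", "mt-Tk", "mt-Tm", "mt-Tf", "mt-Tp",
    "mt-Ts1", "mt-Ts2", "mt-Tt", "mt-Tw", "mt-Ty", "mt-Tv",
)

SPIKE_ID = "Ecoli-Gln-spike"


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic count generator.

    The defaults are the study's conditions: unbalanced groups (6 WT vs 4 KI),
    187 nuclear isodecoders in 50 decoder families, 22 mitochondrial tRNAs and
    one spike-in, baselines spanning ~5 decades, and a global ~25% KI
    reduction (log2 0.75) with decoder- and gene-level deviations.
    """

    n_wt: int = 6
    n_ki: int = 4
    n_nuclear_genes: int = 187
    n_families: int = 50
    n_mito: int = 22
    baseline_log10_range: tuple[float, float] = (0.5, 5.5)
    depth_factor_range: tuple[float, float] = (0.5, 1.5)
    global_lfc: float = math.log2(0.75)
    family_lfc_sd: float = 0.25
    gene_lfc_sd: float = 0.15
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    affected_family_fraction: float = 0.0
    affected_family_lfc: float = 0.0
    multi_locus_fraction: float = 0.25
    spike_log10_abundance: float = 5.0
    tissue: str = "cerebrum"
    seed: int = 0

    def validate(self) -> None:
        if self.n_wt < 2 or self.n_ki < 2:
            raise ValueError("need at least 2 samples per group")
        if not (1 <= self.n_families <= len(MOUSE_DECODER_FAMILIES)):
            raise ValueError(
                f"n_families must be in [1, {len(MOUSE_DECODER_FAMILIES)}]"
            )
        if self.n_nuclear_genes < self.n_families:
            raise ValueError("n_nuclear_genes must be >= n_families")
        if not (1 <= self.n_mito <= len(MOUSE_MITO_TRNAS)):
            raise ValueError(f"n_mito must be in [1, {len(MOUSE_MITO_TRNAS)}]")
        lo, hi = self.baseline_log10_range
        if not lo < hi:
            raise ValueError("baseline_log10_range must be a non-degenerate interval")
        dlo, dhi = self.depth_factor_range
        if not (0 < dlo <= dhi):
            raise ValueError("depth_factor_range must be positive")
        for name in ("family_lfc_sd", "gene_lfc_sd", "dispersion_a0", "dispersion_a1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.affected_family_fraction <= 1:
            raise ValueError("affected_family_fraction must be in [0, 1]")
        if not 0 <= self.multi_locus_fraction <= 1:
            raise ValueError("multi_locus_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    """Counts, sample sheet, registry and the exact generating parameters."""

    counts: CountMatrix
    registry: TRNARegistry
    truth_genes: pd.DataFrame    # baseline_mean, log2fc, dispersion per gene
    truth_samples: pd.DataFrame  # depth_factor per sample
    config: SimulationConfig


def nb_sample(
    rng: np.random.Generator, mu: np.ndarray, alpha: float, size=None
) -> np.ndarray:
    """Draw NB counts with mean ``mu`` and variance ``mu + alpha*mu^2``.

    ``alpha = 0`` is the Poisson limit.
    """
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def _build_registry(cfg: SimulationConfig, rng: np.random.Generator) -> TRNARegistry:
    fams = MOUSE_DECODER_FAMILIES[: cfg.n_families]
    # every family gets one member; the rest are spread at random
    extra = rng.multinomial(cfg.n_nuclear_genes - cfg.n_families, np.full(cfg.n_families, 1.0 / cfg.n_families))
    genes: list[TRNAGene] = []
    for (iso, ac), n_extra in zip(fams, extra):
        for t in range(1, int(n_extra) + 2):
            gene_id = f"tRNA-{iso}-{ac}-{t}-1"
            if rng.random() < cfg.multi_locus_fraction:
                n_loci = int(rng.integers(2, 5))
                loci = tuple(f"tRNA-{iso}-{ac}-{t}-{k}" for k in range(1, n_loci + 1))
            else:
                loci = (gene_id,)
            genes.append(TRNAGene(gene_id, iso, ac, "nuclear", loci))
    for name in MOUSE_MITO_TRNAS[: cfg.n_mito]:
        from .registry import parse_trna_name

        genes.append(parse_trna_name(name))
    genes.append(TRNAGene(SPIKE_ID, "Gln", "TTG", "spike"))
    return build_registry(genes)


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Generate a seeded dataset with the statistical structure of the study."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    registry = _build_registry(cfg, rng)
    nuclear = registry.nuclear_ids
    mito = registry.ids("mito")
    spike = registry.ids("spike")
    gene_ids = nuclear + mito + spike

    lo, hi = cfg.baseline_log10_range
    q = {}
    for g in nuclear:
        q[g] = 10.0 ** rng.uniform(lo, hi)
    mid = (lo + hi) / 2.0
    for g in mito:
        # mito tRNAs sit in the upper half of the abundance range
        q[g] = 10.0 ** rng.uniform(mid, hi)
    for g in spike:
        q[g] = 10.0 ** cfg.spike_log10_abundance

    # per-family then per-gene log2 deviations around the global effect
    fam_of = {}
    for fam in registry.families:
        for g in fam.member_gene_ids:
            fam_of[g] = fam.family_id
    family_ids = [f.family_id for f in registry.families]
    fam_dev = dict(zip(family_ids, rng.normal(0.0, cfg.family_lfc_sd, len(family_ids))))
    if cfg.affected_family_fraction > 0:
        n_aff = int(round(cfg.affected_family_fraction * len(family_ids)))
        affected = rng.choice(family_ids, size=n_aff, replace=False)
        for f in affected:
            fam_dev[f] = fam_dev[f] + cfg.affected_family_lfc

    lfc = {}
    for g in gene_ids:
        if g in fam_of:  # nuclear, family-assigned
            lfc[g] = cfg.global_lfc + fam_dev[fam_of[g]] + rng.normal(0.0, cfg.gene_lfc_sd)
        elif registry.genes[g].compartment == "nuclear":  # Und-style stragglers
            lfc[g] = cfg.global_lfc + rng.normal(0.0, cfg.gene_lfc_sd)
        else:  # controls: condition-invariant by construction
            lfc[g] = 0.0

    sample_ids = [f"WT_{i+1}" for i in range(cfg.n_wt)] + [f"KI_{i+1}" for i in range(cfg.n_ki)]
    genotype = ["WT"] * cfg.n_wt + ["KI"] * cfg.n_ki
    x = np.array([0.0] * cfg.n_wt + [1.0] * cfg.n_ki)
    dlo, dhi = cfg.depth_factor_range
    s = rng.uniform(dlo, dhi, len(sample_ids))

    alpha = {g: cfg.dispersion_a0 + cfg.dispersion_a1 / q[g] for g in gene_ids}

    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for i, g in enumerate(gene_ids):
        mu = s * q[g] * 2.0 ** (x * lfc[g])
        counts[i] = nb_sample(rng, mu, alpha[g])

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    samples_df = pd.DataFrame(
        {"genotype": genotype, "tissue": cfg.tissue},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_genes = pd.DataFrame(
        {
            "baseline_mean": [q[g] for g in gene_ids],
            "log2fc": [lfc[g] for g in gene_ids],
            "dispersion": [alpha[g] for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth_samples = pd.DataFrame(
        {"depth_factor": s}, index=pd.Index(sample_ids, name="sample_id")
    )
    return SimulatedDataset(
        counts=CountMatrix(counts_df, samples_df),
        registry=registry,
        truth_genes=truth_genes,
        truth_samples=truth_samples,
        config=cfg,
    )
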