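"""Normalized PN/PS: observed nonsynonymous/synonymous polymorphism ratio over
the neutral expectation derived from codon composition and a mutation matrix.

The mutation matrix holds the relative frequencies of the 12 single-nucleotide
substitution types, estimated from intronic SNPs (neutral proxy).  For a set
of coding sequences, the expected ratio enumerates, for every codon
occurrence, its nine single-nucleotide mutants weighted by the matrix; the
observed ratio counts CDS SNPs as nonsynonymous (PN) or synonymous (PS)
against the reference codon.  normalized = (PN/PS)_obs / (EN/ES)_exp; values
near 1 indicate absence of purifying selection, values below 1 purifying
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codon import (
    BASES,
    CODON_TO_AA,
    STOP_CODONS,
    codons_of,
    single_nt_mutants,
)
from .phylo_io import GeneRecord, SnpRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
MUTATION_TYPES = tuple(
    (x, y) for x in BASES for y in BASES if x != y
)  # 12 ordered types


@dataclass
class MutationMatrix:
    """Relative frequencies of the 12 single-nucleotide substitution types."""

    rates: dict[tuple[str, str], float]
    n_source_snps: int = 0
    symmetrized: bool = False

    def __post_init__(self):
        missing = [t for t in MUTATION_TYPES if t not in self.rates]
        if missing:
            raise ValueError(f"matrix lacks entries for {missing}")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("matrix entries must be >= 0")
        total = sum(self.rates[t] for t in MUTATION_TYPES)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"matrix entries must sum to 1 (got {total})")

    def __getitem__(self, key: tuple[str, str]) -> float:
        if key[0] == key[1]:
            raise KeyError("diagonal entries are undefined")
        return self.rates[key]

    @classmethod
    def uniform(cls) -> "MutationMatrix":
        return cls({t: 1.0 / 12.0 for t in MUTATION_TYPES})

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], float]) -> "MutationMatrix":
        total = sum(counts.get(t, 0.0) for t in MUTATION_TYPES)
        if total <= 0:
            raise ValueError("no substitution counts")
        return cls(
            {t: counts.get(t, 0.0) / total for t in MUTATION_TYPES},
            n_source_snps=int(round(total)),
        )

    def symmetrize(self) -> "MutationMatrix":
        """Average each entry with its strand complement (X→Y with X'→Y')."""
        rates = {}
        for x, y in MUTATION_TYPES:
            comp = (_COMPLEMENT[x], _COMPLEMENT[y])
            rates[(x, y)] = 0.5 * (self.rates[(x, y)] + self.rates[comp])
        return MutationMatrix(rates, n_source_snps=self.n_source_snps, symmetrized=True)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref": x, "alt": y, "frequency": self.rates[(x, y)]}
            for x, y in MUTATION_TYPES
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationMatrix":
        return cls(
            {(r.ref, r.alt): float(r.frequency) for r in df.itertuples(index=False)}
        )


def build_mutation_matrix(intron_snps: list[SnpRecord]) -> MutationMatrix:
    """Estimate the matrix from intronic SNPs (ref→alt orientation as recorded)."""
    snps = [s for s in intron_snps if s.context == "intron"]
    if not snps:
        raise ValueError("no intronic SNPs to estimate the mutation matrix from")
    counts: dict[tuple[str, str], float] = {}
    for s in snps:
        key = (s.ref_base, s.alt_base)
        counts[key] = counts.get(key, 0.0) + 1.0
    return MutationMatrix.from_counts(counts)


# --------------------------------------------------------------------------
# expected and observed ratios
# --------------------------------------------------------------------------


def codon_counts(cds_iter) -> dict[str, float]:
    """Sense-codon occurrence counts over an iterable of CDS strings."""
    counts: dict[str, float] = {}
    for cds in cds_iter:
        for codon in codons_of(cds):
            if codon in CODON_TO_AA:
                counts[codon] = counts.get(codon, 0.0) + 1.0
    return counts


def expected_pnps(
    cds_set,
    matrix: MutationMatrix,
    count_nonsense_as_nonsyn: bool = False,
):
    """Neutral-expected (EN, ES, EN/ES) for a set of coding sequences.

    Every codon occurrence contributes its nine single-nucleotide mutants,
    weighted by the matrix entry of the base change: amino-acid-changing
    mutants add to EN, silent ones to ES.  Stop-gaining mutants are excluded
    from both by default (``count_nonsense_as_nonsyn`` folds them into EN).
    Returns (EN, ES, ratio) with ratio None when ES == 0.
    """
    counts = codon_counts(cds_set if not isinstance(cds_set, str) else [cds_set])
    en = es = 0.0
    for codon, n in counts.items():
        aa = CODON_TO_AA[codon]
        for _, ref, alt, mutant in single_nt_mutants(codon):
            w = n * matrix[(ref, alt)]
            if mutant in STOP_CODONS:
                if count_nonsense_as_nonsyn:
                    en += w
            elif CODON_TO_AA[mutant] == aa:
                es += w
            else:
                en += w
    ratio = en / es if es > 0 else None
    return en, es, ratio


def _codon_position(gene: GeneRecord, snp: SnpRecord):
    """Map a genomic SNP onto (codon, offset-in-codon, ref-base-on-CDS-strand, alt)."""
    if snp.contig != gene.contig or not (gene.start <= snp.position < gene.end):
        raise ValueError(f"SNP {snp.contig}:{snp.position + 1} outside gene {gene.gene_id}")
    if gene.strand == "+":
        offset = snp.position - gene.start
        ref, alt = snp.ref_base, snp.alt_base
    else:
        offset = gene.end - 1 - snp.position
        ref, alt = _COMPLEMENT[snp.ref_base], _COMPLEMENT[snp.alt_base]
    codon_idx, within = divmod(offset, 3)
    codon = gene.cds_na[3 * codon_idx : 3 * codon_idx + 3]
    if codon[within] != ref:
        raise ValueError(
            f"SNP ref base {ref!r} disagrees with CDS of {gene.gene_id} "
            f"at codon {codon_idx + 1} ({codon})"
        )
    return codon, within, ref, alt


def classify_snp(gene: GeneRecord, snp: SnpRecord) -> str:
    """'syn', 'nonsyn' or 'nonsense' for one CDS SNP against the reference codon."""
    codon, within, _, alt = _codon_position(gene, snp)
    mutant = codon[:within] + alt + codon[within + 1 :]
    if codon in STOP_CODONS or mutant in STOP_CODONS:
        return "nonsense"
    return "syn" if CODON_TO_AA[mutant] == CODON_TO_AA[codon] else "nonsyn"


def observed_pnps(
    cds_snps: list[SnpRecord],
    genes: list[GeneRecord] | dict[str, GeneRecord],
    maf_min: float = 0.0,
    count_nonsense_as_nonsyn: bool = False,
):
    """(PN, PS) counts over CDS SNPs; each SNP scored independently against the
    reference codon; SNPs with MAF below ``maf_min`` are excluded."""
    gene_map = genes if isinstance(genes, dict) else {g.gene_id: g for g in genes}
    pn = ps = 0
    for snp in cds_snps:
        if snp.context != "cds" or snp.minor_allele_freq < maf_min:
            continue
        gene = gene_map[snp.gene_id]
        kind = classify_snp(gene, snp)
        if kind == "syn":
            ps += 1
        elif kind == "nonsyn" or (kind == "nonsense" and count_nonsense_as_nonsyn):
            pn += 1
    return pn, ps


@dataclass
class PnPsResult:
    group: str
    pn_obs: int
    ps_obs: int
    en: float
    es: float
    n_genes: int
    sd: float | None = None

    @property
    def ratio_obs(self) -> float | None:
        return self.pn_obs / self.ps_obs if self.ps_obs > 0 else None

    @property
    def ratio_exp(self) -> float | None:
        return self.en / self.es if self.es > 0 else None

    @property
    def normalized(self) -> float | None:
        if not self.ratio_obs or not self.ratio_exp:
            return None
        return self.ratio_obs / self.ratio_exp

    @property
    def defined(self) -> bool:
        return self.normalized is not None


def _per_gene_counts(genes, snps_by_gene, matrix, maf_min, count_nonsense_as_nonsyn):
    rows = []
    for gene in genes:
        pn, ps = observed_pnps(
            snps_by_gene.get(gene.gene_id, ()),
            {gene.gene_id: gene},
            maf_min=maf_min,
            count_nonsense_as_nonsyn=count_nonsense_as_nonsyn,
        )
        en, es, _ = expected_pnps(
            [gene.cds_na], matrix, count_nonsense_as_nonsyn=count_nonsense_as_nonsyn
        )
        rows.append((pn, ps, en, es))
    return np.asarray(rows, dtype=float)


def normalized_pnps(
    genes: list[GeneRecord],
    snps: list[SnpRecord],
    matrix: MutationMatrix,
    group: str = "all",
    maf_min: float = 0.0,
    count_nonsense_as_nonsyn: bool = False,
) -> PnPsResult:
    """Pooled normalized PN/PS over a group of genes (counts are pooled, not
    per-gene ratios)."""
    if not genes:
        raise ValueError("gene group is empty")
    snps_by_gene: dict[str, list[SnpRecord]] = {}
    for s in snps:
        if s.context == "cds" and s.gene_id is not None:
            snps_by_gene.setdefault(s.gene_id, []).append(s)
    arr = _per_gene_counts(genes, snps_by_gene, matrix, maf_min, count_nonsense_as_nonsyn)
    pn, ps, en, es = arr.sum(axis=0)
    return PnPsResult(
        group=group, pn_obs=int(pn), ps_obs=int(ps), en=en, es=es, n_genes=len(genes)
    )


def subsample_sd(
    genes: list[GeneRecord],
    snps: list[SnpRecord],
    matrix: MutationMatrix,
    frac: float = 1.0 / 3.0,
    reps: int = 1000,
    seed: int = 0,
    maf_min: float = 0.0,
    count_nonsense_as_nonsyn: bool = False,
) -> float:
    """SD of normalized PN/PS over ``reps`` random subsets of ⌈frac·n⌉ genes,
    sampled without replacement."""
    n = len(genes)
    if n < 3:
        raise ValueError("subsampling needs at least 3 genes")
    if reps < 2:
        raise ValueError("subsampling needs at least 2 replicates")
    snps_by_gene: dict[str, list[SnpRecord]] = {}
    for s in snps:
        if s.context == "cds" and s.gene_id is not None:
            snps_by_gene.setdefault(s.gene_id, []).append(s)
    arr = _per_gene_counts(genes, snps_by_gene, matrix, maf_min, count_nonsense_as_nonsyn)
    k = math.ceil(frac * n)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(reps):
        idx = rng.choice(n, size=k, replace=False)
        pn, ps, en, es = arr[idx].sum(axis=0)
        if ps > 0 and es > 0 and en > 0:
            values.append((pn / ps) / (en / es))
    if len(values) < 2:
        raise ValueError("too few defined replicates to estimate an SD")
    return float(np.std(values, ddof=1))


# --------------------------------------------------------------------------
# grouping
# --------------------------------------------------------------------------

POOLING_SCHEMES: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    # reference-species age classes pooled for SNP paucity
    "yeast": [
        ("N0", ("N0",)),
        ("N1-N4", ("N1", "N2", "N3", "N4")),
        ("N5", ("N5",)),
    ],
    "flies": [
        ("N0", ("N0",)),
        ("N1-N2", ("N1", "N2")),
        ("N3-N4", ("N3", "N4")),
        ("N5", ("N5",)),
        ("N6", ("N6",)),
    ],
}


def group_pool(classifications, scheme="yeast") -> dict[str, list]:
    """Partition classified genes into pooled age groups plus 'conserved'.

    ``classifications`` is an iterable of objects with ``klass`` and
    ``birth_branch`` attributes (see gene_birth.GeneClassification).  The
    scheme may be a named preset ('yeast', 'flies'), 'none' (one group per
    label) or an explicit list of (group_name, labels) pairs.  Genes born de
    novo and subsequently duplicated are excluded from property comparisons,
    as are WGD-derived and homology-removed genes.
    """
    if scheme == "none":
        label_to_group = None
    else:
        pairs = POOLING_SCHEMES[scheme] if isinstance(scheme, str) else list(scheme)
        label_to_group = {}
        for name, labels in pairs:
            for lab in labels:
                label_to_group[lab] = name
    groups: dict[str, list] = {}
    for c in classifications:
        if c.klass in ("putative_de_novo", "duplicated"):
            label = c.birth_branch
            if label_to_group is None:
                name = label
            else:
                if label not in label_to_group:
                    raise ValueError(f"branch label {label!r} not covered by scheme")
                name = label_to_group[label]
            groups.setdefault(f"{name}_{'de_novo' if c.klass == 'putative_de_novo' else 'dup'}", []).append(c)
        elif c.klass == "conserved":
            groups.setdefault("conserved", []).append(c)
    return groups
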