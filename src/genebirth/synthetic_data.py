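"""Synthetic-data generators with the statistical structure the pipeline
assumes, plus ground-truth tables for recovery tests.

Four generators share one ``SimConfig``: gene family histories (birth–death
on a fixed species tree, emitting orthogroups, duplication records and
outgroup homology hits), coding sequences with SNPs drawn under a 4×4
mutation matrix and a tunable purifying factor, diverged protein pairs or
triples under a site-independent codon model, and genome pairs with planted
syntenic blocks and insertions.  A single top-level seed deterministically
derives a child seed per generator, so each can be regenerated independently
and identical seed + config gives byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import (
    BASES,
    CODON_TO_AA,
    DEFAULT_CLASS_SCHEME,
    SENSE_CODONS,
    STOP_CODONS,
    single_nt_mutants,
)
from .phylo_io import (
    DuplicationRecord,
    GeneRecord,
    HomologyHit,
    Orthogroup,
    SnpRecord,
    SpeciesTree,
    parse_species_tree,
)
from .selection_pnps import MutationMatrix

# --------------------------------------------------------------------------
# species-tree presets
# --------------------------------------------------------------------------

YEAST11_NEWICK = (
    "(((((S_cerevisiae:0.043,S_paradoxus:0.047):0.041,S_mikatae:0.062):0.029,"
    "S_kudriavzevii:0.066):0.072,((S_uvarum:0.070,(L_kluyveri:0.170,"
    "L_thermotolerans:0.160):0.090):0.050,(K_lactis:0.280,"
    "E_cymbalariae:0.240):0.110):0.100):0.180,"
    "(S_pombe:0.450,S_japonicus:0.480):0.300);"
)

FLIES16_NEWICK = (
    "((((((D_melanogaster:0.011,(D_simulans:0.015,D_sechellia:0.016):0.008):0.020,"
    "(D_yakuba:0.030,D_erecta:0.028):0.012):0.040,(D_pseudoobscura:0.060,"
    "D_persimilis:0.058):0.035):0.050,(D_willistoni:0.110,(D_mojavensis:0.100,"
    "D_virilis:0.095):0.030):0.040):0.060,(D_grimshawi:0.130,D_busckii:0.140):0.050):0.200,"
    "(M_domestica:0.300,((A_gambiae:0.280,A_mellifera:0.320):0.060,"
    "T_castaneum:0.350):0.050):0.150);"
)

TREE_PRESETS: dict[str, tuple[str, str, dict[str, set[str]]]] = {
    # preset -> (newick, reference species, tip groups)
    "yeast11-like": (YEAST11_NEWICK, "S_cerevisiae", {}),
    "flies16-like": (
        FLIES16_NEWICK,
        "D_melanogaster",
        {"D_willistoni": {"D_willistoni", "D_paulistorum"}},
    ),
}

# transition-biased single-nucleotide mutation spectrum (transitions twice as
# frequent as each transversion), the generator default
_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
DEFAULT_MUTATION_MATRIX = MutationMatrix(
    {
        (x, y): (2.0 if (x, y) in _TS else 1.0) / 16.0
        for x in BASES
        for y in BASES
        if x != y
    }
)


# average proteome amino-acid composition (rounded Swiss-Prot-style values);
# the default codon usage spreads each amino acid uniformly over its
# synonymous codons
_AA_COMPOSITION = {
    "A": 8.3, "R": 5.5, "N": 4.1, "D": 5.4, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 6.0, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.9,
}


def default_codon_freqs() -> dict[str, float]:
    """Sense-codon frequencies from an average proteome composition."""
    syn: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        syn.setdefault(aa, []).append(codon)
    raw = {
        codon: _AA_COMPOSITION[aa] / len(codons)
        for aa, codons in syn.items()
        for codon in codons
    }
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def uniform_codon_freqs() -> dict[str, float]:
    return {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}


@dataclass
class SimConfig:
    """Shared configuration of the four generators.

    Rates are expected events per branch; ``loss_prob`` applies per
    descendant lineage per family; ``purifying_factor`` multiplies the
    acceptance of nonsynonymous SNPs relative to neutral (1 = neutral);
    ``divergence`` is expected substitutions per codon on a simulated branch;
    ``charge_shift`` multiplies the acceptance of basic→acidic amino-acid
    changes in protein-family simulation.
    """

    seed: int = 0
    tree_preset: str = "yeast11-like"
    denovo_rate: float = 2.0
    dup_rate: float = 2.0
    denovo_dup_rate: float = 0.25
    n_conserved_families: int = 20
    loss_prob: float = 0.0
    contaminant_fraction: float = 0.05
    codon_freqs: dict[str, float] = field(default_factory=default_codon_freqs)
    mutation_matrix: MutationMatrix = field(
        default_factory=lambda: DEFAULT_MUTATION_MATRIX
    )
    purifying_factor: float = 1.0
    n_genes: int = 500
    codons_per_gene: int = 300
    n_snps: int = 10_000
    n_intron_snps: int = 10_000
    divergence: float = 0.05
    charge_shift: float = 1.0
    n_blocks: int = 5
    block_length: int = 500
    insertion_length: int = 300
    block_mutation_rate: float = 0.0

    def __post_init__(self):
        for name in ("denovo_rate", "dup_rate", "denovo_dup_rate", "purifying_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.loss_prob <= 1.0):
            raise ValueError("loss_prob must lie in [0, 1]")
        total = sum(self.codon_freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"codon_freqs must sum to 1 (got {total})")

    def tree(self) -> SpeciesTree:
        newick, ref, groups = TREE_PRESETS[self.tree_preset]
        return parse_species_tree(newick, ref, tip_groups=groups)

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator derived deterministically from the top-level seed."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class TruthTable:
    """Ground truth: per-gene birth branch and mechanism, per-SNP labels,
    per-genome-pair block intervals."""

    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "orthogroup", "branch", "mechanism", "lost_species"]
        )
    )
    snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["contig", "pos", "ref", "alt", "label"]
        )
    )
    blocks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["block", "start_a", "end_a", "start_b", "end_b"]
        )
    )


# --------------------------------------------------------------------------
# gene family histories
# --------------------------------------------------------------------------


def simulate_gene_histories(cfg: SimConfig):
    """Birth–death gene family histories on the preset tree.

    Returns (orthogroups, duplication records, outgroup homology hits,
    truth).  A gene born on branch B is present, absent losses, in exactly
    the species descending from B; duplication records carry their true
    branch with support 1.0; a ``contaminant_fraction`` of clade-restricted
    families receives hits in two outgroup species (E = 1e-10) so the
    outgroup-homology filter is exercised.
    """
    tree = cfg.tree()
    if not tree.tip_names:
        raise ValueError("empty species tree")
    rng = cfg.rng("histories")
    ref = tree.reference_species
    birth_labels = tree.labels[:-1]  # the root hosts no in-tree birth
    all_species = sorted(tree.clade_species(tree.root_label))

    orthogroups: list[Orthogroup] = []
    dup_records: list[DuplicationRecord] = []
    hits: list[HomologyHit] = []
    truth_rows: list[dict] = []
    counter = 0

    def new_og_id():
        nonlocal counter
        counter += 1
        return f"OG{counter:07d}"

    def apply_loss(species: set[str]) -> tuple[set[str], list[str]]:
        kept, lost = set(), []
        for sp in sorted(species):
            if sp != ref and rng.random() < cfg.loss_prob:
                lost.append(sp)
            else:
                kept.add(sp)
        return kept, lost

    def members_of(gene_map: dict[str, list[str]]) -> dict[str, tuple[str, ...]]:
        return {sp: tuple(genes) for sp, genes in gene_map.items() if genes}

    # de novo births (optionally followed by a duplication)
    for label in birth_labels:
        clade = tree.clade_species(label)
        for kind in ("de_novo", "de_novo_plus_duplicated"):
            rate = cfg.denovo_rate if kind == "de_novo" else cfg.denovo_dup_rate
            for _ in range(rng.poisson(rate)):
                og_id = new_og_id()
                present, lost = apply_loss(clade)
                gene_map = {sp: [f"{sp}.dn{og_id}"] for sp in sorted(present)}
                contaminant = kind == "de_novo" and rng.random() < cfg.contaminant_fraction
                if kind == "de_novo_plus_duplicated":
                    # post-birth duplication on an equal-or-more-recent branch
                    dup_idx = int(rng.integers(0, tree.label_index(label) + 1))
                    dup_label = f"N{dup_idx}"
                    dup_clade = tree.clade_species(dup_label) & present
                    if ref not in dup_clade:
                        dup_clade |= {ref}
                    g1 = [gene_map[sp][0] for sp in sorted(dup_clade) if sp in gene_map]
                    g2 = []
                    for sp in sorted(dup_clade):
                        if sp in gene_map:
                            child = f"{sp}.dnx{og_id}"
                            gene_map[sp].append(child)
                            g2.append(child)
                    dup_records.append(
                        DuplicationRecord(og_id, dup_label, 1.0, tuple(g1), tuple(g2))
                    )
                mechanism = "contaminant" if contaminant else kind
                if contaminant:
                    for osp in ("Outgroup_sp1", "Outgroup_sp2"):
                        hits.append(
                            HomologyHit(f"{ref}.dn{og_id}", osp, f"{osp}.hom{og_id}", 1e-10)
                        )
                orthogroups.append(Orthogroup(og_id, members_of(gene_map)))
                for sp, genes in gene_map.items():
                    for g in genes:
                        truth_rows.append(
                            {
                                "gene_id": g,
                                "orthogroup": og_id,
                                "branch": label,
                                "mechanism": mechanism,
                                "lost_species": ",".join(lost),
                            }
                        )

    # duplications inside conserved (clade-unrestricted) families
    for label in birth_labels:
        clade = tree.clade_species(label)
        for _ in range(rng.poisson(cfg.dup_rate)):
            og_id = new_og_id()
            gene_map = {sp: [f"{sp}.par{og_id}"] for sp in all_species}
            child_species, lost = apply_loss(clade)
            g1 = [gene_map[sp][0] for sp in sorted(child_species)]
            g2 = []
            for sp in sorted(child_species):
                child = f"{sp}.dup{og_id}"
                gene_map[sp].append(child)
                g2.append(child)
            dup_records.append(
                DuplicationRecord(og_id, label, 1.0, tuple(g1), tuple(g2))
            )
            orthogroups.append(Orthogroup(og_id, members_of(gene_map)))
            for sp in all_species:
                in_event = sp in child_species
                for g in gene_map[sp]:
                    truth_rows.append(
                        {
                            "gene_id": g,
                            "orthogroup": og_id,
                            "branch": label if in_event else "",
                            "mechanism": "duplication" if in_event else "conserved",
                            "lost_species": ",".join(lost),
                        }
                    )
            # conserved families have outgroup homologs
            for osp in ("Outgroup_sp1", "Outgroup_sp2"):
                hits.append(
                    HomologyHit(f"{ref}.par{og_id}", osp, f"{osp}.hom{og_id}", 1e-8)
                )

    # plain conserved families
    for _ in range(cfg.n_conserved_families):
        og_id = new_og_id()
        gene_map = {sp: [f"{sp}.cons{og_id}"] for sp in all_species}
        orthogroups.append(Orthogroup(og_id, members_of(gene_map)))
        for sp in all_species:
            truth_rows.append(
                {
                    "gene_id": gene_map[sp][0],
                    "orthogroup": og_id,
                    "branch": "",
                    "mechanism": "conserved",
                    "lost_species": "",
                }
            )
        for osp in ("Outgroup_sp1", "Outgroup_sp2"):
            hits.append(
                HomologyHit(f"{ref}.cons{og_id}", osp, f"{osp}.hom{og_id}", 1e-8)
            )

    truth = TruthTable(genes=pd.DataFrame(truth_rows, columns=[
        "gene_id", "orthogroup", "branch", "mechanism", "lost_species"
    ]))
    return orthogroups, dup_records, hits, truth


# --------------------------------------------------------------------------
# CDS + SNPs under the mutation matrix with a purifying factor
# --------------------------------------------------------------------------


def _draw_codons(rng, freqs: dict[str, float], n: int) -> list[str]:
    codons = sorted(freqs)
    p = np.array([freqs[c] for c in codons])
    p = p / p.sum()
    return [codons[i] for i in rng.choice(len(codons), size=n, p=p)]


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_cds_snps(cfg: SimConfig):
    """Coding sequences plus CDS and intronic SNPs.

    CDS SNPs: a codon occurrence is chosen uniformly, one of its nine
    single-nucleotide mutants is chosen with probability proportional to the
    mutation matrix, stop-gaining mutants are discarded, and nonsynonymous
    mutants are accepted with probability ``purifying_factor`` (synonymous
    with probability 1).  Intronic SNP types are drawn directly from the
    matrix, so the downstream matrix estimate converges to the truth.

    Returns (genes, snps, intron_sequence, truth); ``snps`` holds both
    contexts.
    """
    rng = cfg.rng("snps")
    m = cfg.mutation_matrix
    f = cfg.purifying_factor

    genes: list[GeneRecord] = []
    for i in range(cfg.n_genes):
        body = _draw_codons(rng, cfg.codon_freqs, cfg.codons_per_gene)
        cds = "ATG" + "".join(body) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        contig = f"chr_g{i}"
        genes.append(
            GeneRecord(
                gene_id=f"g{i}",
                species="simulated",
                contig=contig,
                start=0,
                end=len(cds),
                strand=strand,
                cds_na=cds,
            )
        )

    snps: list[SnpRecord] = []
    truth_rows: list[dict] = []
    n_codons = cfg.codons_per_gene + 1  # ATG start included, stop excluded
    # per-codon mutants, normalized weights, and total mutability W(c): a SNP
    # lands on route c1→c2 with probability ∝ f(c1)·m(base change), realized
    # by uniform codon choice + acceptance W(c)/Wmax (thinning)
    mutant_cache: dict[str, tuple[list[tuple[int, str, str, str]], np.ndarray, float]] = {}

    def _codon_entry(codon: str):
        if codon not in mutant_cache:
            muts = list(single_nt_mutants(codon))
            w = np.array([m[(ref, alt)] for _, ref, alt, _ in muts])
            mutant_cache[codon] = (muts, w / w.sum(), float(w.sum()))
        return mutant_cache[codon]

    w_max = max(_codon_entry(c)[2] for c in SENSE_CODONS)
    placed = 0
    while placed < cfg.n_snps:
        gene = genes[int(rng.integers(0, len(genes)))]
        codon_idx = int(rng.integers(0, n_codons))
        codon = gene.cds_na[3 * codon_idx : 3 * codon_idx + 3]
        muts, w, w_tot = _codon_entry(codon)
        if rng.random() >= w_tot / w_max:
            continue
        within, ref_b, alt_b, mutant = muts[int(rng.choice(9, p=w))]
        if mutant in STOP_CODONS:
            continue
        nonsyn = CODON_TO_AA[mutant] != CODON_TO_AA[codon]
        if nonsyn and rng.random() >= f:
            continue
        cds_offset = 3 * codon_idx + within
        if gene.strand == "+":
            pos = gene.start + cds_offset
            g_ref, g_alt = ref_b, alt_b
        else:
            pos = gene.end - 1 - cds_offset
            g_ref, g_alt = _COMPLEMENT[ref_b], _COMPLEMENT[alt_b]
        snps.append(
            SnpRecord(
                contig=gene.contig,
                position=pos,
                ref_base=g_ref,
                alt_base=g_alt,
                minor_allele_freq=float(rng.uniform(0.0, 0.5)),
                context="cds",
                gene_id=gene.gene_id,
            )
        )
        truth_rows.append(
            {
                "contig": gene.contig,
                "pos": pos,
                "ref": g_ref,
                "alt": g_alt,
                "label": "nonsyn" if nonsyn else "syn",
            }
        )
        placed += 1

    # intronic SNPs on a neutral contig
    intron_len = max(4 * cfg.n_intron_snps, 1000)
    intron_seq = "".join(
        np.array(list("ACGT"))[rng.integers(0, 4, size=intron_len)]
    )
    base_positions = {b: list(np.flatnonzero(np.frombuffer(intron_seq.encode(), dtype=np.uint8) == ord(b))) for b in "ACGT"}
    used: set[int] = set()
    types = sorted(m.rates)
    type_p = np.array([m.rates[t] for t in types])
    type_p = type_p / type_p.sum()
    for _ in range(cfg.n_intron_snps):
        ref_b, alt_b = types[int(rng.choice(len(types), p=type_p))]
        candidates = base_positions[ref_b]
        pos = int(candidates[int(rng.integers(0, len(candidates)))])
        while pos in used:
            pos = int(candidates[int(rng.integers(0, len(candidates)))])
        used.add(pos)
        snps.append(
            SnpRecord(
                contig="intron_1",
                position=pos,
                ref_base=ref_b,
                alt_base=alt_b,
                minor_allele_freq=float(rng.uniform(0.0, 0.5)),
                context="intron",
            )
        )
        truth_rows.append(
            {"contig": "intron_1", "pos": pos, "ref": ref_b, "alt": alt_b, "label": "intron"}
        )

    truth = TruthTable(
        snps=pd.DataFrame(truth_rows, columns=["contig", "pos", "ref", "alt", "label"])
    )
    return genes, snps, intron_seq, truth


# --------------------------------------------------------------------------
# diverged protein families under a codon model
# --------------------------------------------------------------------------

_BASIC = {aa for aa, c in DEFAULT_CLASS_SCHEME.items() if c == "basic"}
_ACIDIC = {aa for aa, c in DEFAULT_CLASS_SCHEME.items() if c == "acidic"}


def _mutability_tables(m: MutationMatrix):
    """Per-codon mutant lists, normalized weights and total mutability W(c)."""
    tables = {}
    for codon in list(SENSE_CODONS) + list(STOP_CODONS):
        muts = list(single_nt_mutants(codon))
        w = np.array([m[(x, y)] for _, x, y, _ in muts])
        tables[codon] = (muts, w / w.sum(), float(w.sum()))
    return tables


def _evolve_codons(codons: list[str], rng, m: MutationMatrix, d: float, s: float,
                   codon_freqs: dict[str, float]):
    """Site-independent codon evolution; returns (new codons, substitutions).

    The model is strictly first-order: a codon experiences at most one
    candidate event per branch, with probability ``d``·W(c)/W̄ (W(c) = total
    single-nucleotide mutability of the codon under the matrix, W̄ its mean
    over the codon distribution), so realized route frequencies follow
    f(c1)·m(base change) exactly, matching the single-nucleotide expectation
    model.  The event picks one of the nine mutants ∝ matrix, discards
    stop-gaining ones, and is accepted with relative probability ``s`` for
    basic→acidic amino-acid changes and 1 otherwise.
    """
    smax = max(s, 1.0)
    tables = _mutability_tables(m)
    w_bar = sum(codon_freqs.get(c, 0.0) * tables[c][2] for c in SENSE_CODONS)
    out = []
    subs = []
    for idx, codon in enumerate(codons):
        current = codon
        muts, p, w_tot = tables[current]
        if rng.random() < min(1.0, d * w_tot / w_bar):
            _, _, _, mutant = muts[int(rng.choice(9, p=p))]
            aa_from = CODON_TO_AA[current]
            if mutant not in STOP_CODONS:
                aa_to = CODON_TO_AA[mutant]
                weight = s if (aa_from in _BASIC and aa_to in _ACIDIC) else 1.0
                if rng.random() < weight / smax:
                    if aa_from != aa_to:
                        subs.append((idx, aa_from, aa_to))
                    current = mutant
        out.append(current)
    return out, subs


def simulate_protein_family(cfg: SimConfig, n_species: int = 2):
    """Aligned protein pairs (reference + one sister) or triples (reference +
    two sisters), each sister evolved independently from the ancestral
    sequence.  Returns (aa_alignments, cds_alignments, truth substitutions
    DataFrame); alignments are gap-free (no indels are simulated).
    """
    if n_species not in (2, 3):
        raise ValueError("n_species must be 2 or 3")
    if cfg.divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = cfg.rng("family")
    m = cfg.mutation_matrix
    labels = ["reference", "sister1", "sister2"][:n_species]

    aa_alignments: list[dict[str, str]] = []
    cds_alignments: list[dict[str, str]] = []
    truth_rows: list[dict] = []
    for g in range(cfg.n_genes):
        ancestor = _draw_codons(rng, cfg.codon_freqs, cfg.codons_per_gene)
        seqs = {"reference": ancestor}
        for sister in labels[1:]:
            evolved, subs = _evolve_codons(
                ancestor, rng, m, cfg.divergence, cfg.charge_shift, cfg.codon_freqs
            )
            seqs[sister] = evolved
            for idx, aa_from, aa_to in subs:
                truth_rows.append(
                    {
                        "gene": f"fam{g}",
                        "column": idx,
                        "branch": sister,
                        "ancestral": aa_from,
                        "derived": aa_to,
                    }
                )
        aa_alignments.append(
            {sp: "".join(CODON_TO_AA[c] for c in seqs[sp]) for sp in labels}
        )
        cds_alignments.append({sp: "".join(seqs[sp]) for sp in labels})
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "column", "branch", "ancestral", "derived"]
    )
    return aa_alignments, cds_alignments, truth


# --------------------------------------------------------------------------
# genome pairs with planted synteny
# --------------------------------------------------------------------------


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_genome_pair(cfg: SimConfig):
    """Genome A = concatenated conserved blocks; genome B = the same blocks
    separated by unrelated insertions, with point mutations inside blocks at
    ``block_mutation_rate``.  Returns (genome_a, genome_b, truth)."""
    if cfg.n_blocks < 1 or cfg.block_length < 1:
        raise ValueError("need at least one nonempty block")
    rng = cfg.rng("genomes")
    blocks = [_random_seq(rng, cfg.block_length) for _ in range(cfg.n_blocks)]

    a_parts, b_parts, rows = [], [], []
    pos_a = pos_b = 0
    for i, block in enumerate(blocks):
        ins = _random_seq(rng, cfg.insertion_length)
        b_parts.append(ins)
        pos_b += len(ins)
        mutated = list(block)
        if cfg.block_mutation_rate > 0:
            for j in range(len(mutated)):
                if rng.random() < cfg.block_mutation_rate:
                    mutated[j] = "ACGT"[
                        int(rng.choice([k for k in range(4) if "ACGT"[k] != mutated[j]]))
                    ]
        a_parts.append(block)
        b_parts.append("".join(mutated))
        rows.append(
            {
                "block": i,
                "start_a": pos_a,
                "end_a": pos_a + len(block),
                "start_b": pos_b,
                "end_b": pos_b + len(block),
            }
        )
        pos_a += len(block)
        pos_b += len(block)
    b_parts.append(_random_seq(rng, cfg.insertion_length))
    truth = TruthTable(
        blocks=pd.DataFrame(rows, columns=["block", "start_a", "end_a", "start_b", "end_b"])
    )
    return "".join(a_parts), "".join(b_parts), truth
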