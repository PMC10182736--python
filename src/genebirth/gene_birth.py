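"""Branch-wise classification of gene birth events from orthogroup data.

Given a rooted species tree with a reference species, orthogroup membership,
reconciled duplication records, a WGD-derived gene list and outgroup homology
hits, this module classifies every reference-species gene as putative de
novo, duplicated, de novo + duplicated, conserved, WGD-excluded or removed
for outgroup homology; dates birth events on reference-path branches
(N0 = species-specific); and normalizes per-branch event counts by branch
length (events per amino-acid substitutions per 100 sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .phylo_io import DuplicationRecord, HomologyHit, Orthogroup, SpeciesTree

KLASSES = (
    "putative_de_novo",
    "duplicated",
    "de_novo_plus_duplicated",
    "conserved",
    "excluded_wgd",
    "removed_outgroup_homology",
)


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    klass: str
    birth_branch: str | None  # N-label, None for conserved/excluded classes
    og_id: str | None = None

    def __post_init__(self):
        if self.klass not in KLASSES:
            raise ValueError(f"unknown class {self.klass!r}")


@dataclass
class BirthEvent:
    og_id: str
    branch: str
    mechanism: str  # 'de_novo' | 'duplication'
    gene_ids: tuple[str, ...]
    reference_less: bool = False  # duplication with no reference-species descendant


# --------------------------------------------------------------------------


def assign_birth_branch(species_present: set[str], tree: SpeciesTree) -> str:
    """Branch label of the deepest reference-path node ancestral to all
    species present (the most distant species in the orthogroup dates the
    birth).  For multi-species tips, one member species suffices."""
    return tree.mrca_label(species_present)


def filter_outgroup_homology(
    candidates,
    hits: list[HomologyHit],
    e_max: float = 0.001,
    min_species: int = 2,
):
    """Partition candidate gene ids into (kept, removed).

    A candidate is removed when hits with e_value < e_max exist in at least
    ``min_species`` distinct outgroup species; hits are assumed restricted to
    species outside the clade.
    """
    by_query: dict[str, set[str]] = {}
    for h in hits:
        if h.e_value < e_max:
            by_query.setdefault(h.query_gene, set()).add(h.subject_species)
    kept, removed = [], []
    for gene in candidates:
        if len(by_query.get(gene, ())) >= min_species:
            removed.append(gene)
        else:
            kept.append(gene)
    return kept, removed


def map_duplications(
    records: list[DuplicationRecord],
    tree: SpeciesTree,
    support_min: float = 0.5,
) -> dict[str, int]:
    """Events per branch label for records with support ≥ support_min."""
    counts: dict[str, int] = {}
    for r in records:
        node = r.species_tree_node
        if node not in tree.branch_labels and node not in tree.tip_names:
            raise ValueError(f"unknown species tree node {node!r}")
        if r.support >= support_min:
            counts[node] = counts.get(node, 0) + 1
    return counts


# --------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    classifications: list[GeneClassification]
    events: list[BirthEvent]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "class": c.klass,
                    "birth_branch": c.birth_branch or "",
                    "orthogroup": c.og_id or "",
                }
                for c in self.classifications
            ]
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "orthogroup": e.og_id,
                    "branch": e.branch,
                    "mechanism": e.mechanism,
                    "genes": ",".join(e.gene_ids),
                    "reference_less": e.reference_less,
                }
                for e in self.events
            ],
            columns=["orthogroup", "branch", "mechanism", "genes", "reference_less"],
        )


def classify_genes(
    orthogroups: list[Orthogroup],
    duplications: list[DuplicationRecord],
    tree: SpeciesTree,
    wgd_genes: set[str] | None = None,
    outgroup_hits: list[HomologyHit] | None = None,
    support_min: float = 0.5,
    e_max: float = 0.001,
    min_outgroup_species: int = 2,
) -> ClassificationResult:
    """Classify every reference-species gene and list birth events.

    Rules (reference-centric; orthogroups lacking the reference are ignored):
    WGD-listed genes are excluded first.  A family whose species span is
    restricted within the clade (MRCA below the root) is a putative de novo
    family born at its MRCA branch; its reference genes are putative_de_novo,
    or de_novo_plus_duplicated when a post-birth duplication event lists
    them, or removed_outgroup_homology when blast hits exist in ≥
    ``min_outgroup_species`` outgroup species at E < ``e_max``.  In
    unrestricted families, reference genes listed in a duplication event are
    duplicated (dated at the most recent event listing them); the rest are
    conserved.  One de novo event is emitted per de novo family retaining at
    least one candidate; one duplication event per supported record.
    """
    wgd_genes = wgd_genes or set()
    outgroup_hits = outgroup_hits or []

    og_by_id = {og.og_id: og for og in orthogroups}
    dups_by_og: dict[str, list[DuplicationRecord]] = {}
    for r in duplications:
        if r.support < support_min:
            continue
        if r.species_tree_node not in tree.branch_labels and r.species_tree_node not in tree.tip_names:
            raise ValueError(f"unknown species tree node {r.species_tree_node!r}")
        og = og_by_id.get(r.og_id)
        if og is None:
            raise ValueError(f"duplication record for unknown orthogroup {r.og_id!r}")
        known = set(og.all_genes)
        stray = [g for g in (*r.genes_1, *r.genes_2) if g not in known]
        if stray:
            raise ValueError(
                f"genes {stray} in a duplication event are absent from {r.og_id}"
            )
        dups_by_og.setdefault(r.og_id, []).append(r)

    ref = tree.reference_species
    ref_aliases = {ref}
    for tip, members in tree.tip_groups.items():
        if ref in members or ref == tip:
            ref_aliases |= {tip} | set(members)

    hits_kept: dict[str, bool] = {}

    classifications: list[GeneClassification] = []
    events: list[BirthEvent] = []

    for og in orthogroups:
        ref_genes = [
            g for sp, genes in og.members.items() if sp in ref_aliases for g in genes
        ]
        if not ref_genes:
            continue
        label = assign_birth_branch(og.species | {ref}, tree)
        restricted = tree.label_index(label) < tree.label_index(tree.root_label)

        # branch label per duplicated gene: most recent event listing it
        dup_branch: dict[str, str] = {}
        for r in dups_by_og.get(og.og_id, ()):
            node = r.species_tree_node
            if node not in tree.branch_labels:
                continue  # duplication on an off-path branch: kept as event only
            for g in (*r.genes_1, *r.genes_2):
                if g not in dup_branch or tree.label_index(node) < tree.label_index(
                    dup_branch[g]
                ):
                    dup_branch[g] = node

        if restricted:
            kept, removed = filter_outgroup_homology(
                ref_genes, outgroup_hits, e_max=e_max, min_species=min_outgroup_species
            )
            hits_kept.update({g: True for g in kept})
            hits_kept.update({g: False for g in removed})

        n_candidates = 0
        for g in ref_genes:
            if g in wgd_genes:
                classifications.append(
                    GeneClassification(g, "excluded_wgd", None, og.og_id)
                )
            elif restricted:
                if not hits_kept[g]:
                    classifications.append(
                        GeneClassification(g, "removed_outgroup_homology", None, og.og_id)
                    )
                elif g in dup_branch:
                    classifications.append(
                        GeneClassification(g, "de_novo_plus_duplicated", label, og.og_id)
                    )
                    n_candidates += 1
                else:
                    classifications.append(
                        GeneClassification(g, "putative_de_novo", label, og.og_id)
                    )
                    n_candidates += 1
            else:
                if g in dup_branch:
                    classifications.append(
                        GeneClassification(g, "duplicated", dup_branch[g], og.og_id)
                    )
                else:
                    classifications.append(
                        GeneClassification(g, "conserved", None, og.og_id)
                    )

        if restricted and n_candidates > 0:
            events.append(
                BirthEvent(
                    og_id=og.og_id,
                    branch=label,
                    mechanism="de_novo",
                    gene_ids=tuple(g for g in ref_genes if hits_kept.get(g) and g not in wgd_genes),
                )
            )
        for r in dups_by_og.get(og.og_id, ()):
            node = r.species_tree_node
            if node not in tree.branch_labels:
                continue
            dup_ref_genes = tuple(
                g for g in (*r.genes_1, *r.genes_2) if g in set(ref_genes)
            )
            events.append(
                BirthEvent(
                    og_id=og.og_id,
                    branch=node,
                    mechanism="duplication",
                    gene_ids=dup_ref_genes,
                    reference_less=not dup_ref_genes,
                )
            )

    return ClassificationResult(classifications, events)


# --------------------------------------------------------------------------


def branch_rates(result: ClassificationResult, tree: SpeciesTree) -> pd.DataFrame:
    """Per-branch event/protein counts and branch-length-normalized rates.

    normalized = events / (100 × branch length in substitutions/site), i.e.
    events per amino-acid substitutions per 100 sites.
    """
    rows = []
    by_branch_events: dict[tuple[str, str], int] = {}
    for e in result.events:
        key = (e.branch, e.mechanism)
        by_branch_events[key] = by_branch_events.get(key, 0) + 1
    by_branch_proteins: dict[tuple[str, str], int] = {}
    for c in result.classifications:
        if c.birth_branch is None:
            continue
        mech = (
            "de_novo"
            if c.klass in ("putative_de_novo", "de_novo_plus_duplicated")
            else "duplication"
        )
        key = (c.birth_branch, mech)
        by_branch_proteins[key] = by_branch_proteins.get(key, 0) + 1

    for label in tree.labels:
        length = tree.branch_length(label)
        n_dn = by_branch_events.get((label, "de_novo"), 0)
        n_dup = by_branch_events.get((label, "duplication"), 0)
        if length == 0 and (n_dn or n_dup):
            raise ValueError(f"branch {label} has events but zero length")
        rows.append(
            {
                "branch": label,
                "branch_length": length,
                "n_denovo_events": n_dn,
                "n_dup_events": n_dup,
                "n_denovo_proteins": by_branch_proteins.get((label, "de_novo"), 0),
                "n_dup_proteins": by_branch_proteins.get((label, "duplication"), 0),
                "normalized_denovo": n_dn / (100 * length) if length > 0 else 0.0,
                "normalized_dup": n_dup / (100 * length) if length > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def yates_chisq_2x2(a: float, b: float, c: float, d: float):
    """Pearson chi-square with Yates continuity correction on [[a, b], [c, d]].

    Returns (statistic, p_value); df = 1.  All margins must be positive.
    """
    for count in (a, b, c, d):
        if count < 0:
            raise ValueError("counts must be nonnegative")
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    res = stats.chi2_contingency([[a, b], [c, d]], correction=True)
    return float(res.statistic), float(res.pvalue)


def synteny_fraction(
    classifications: list[GeneClassification],
    gene_intervals: dict[str, tuple[str, int, int]],
    blocks,
    genome_side: str = "a",
    min_fraction: float = 0.0,
) -> dict[str, float]:
    """Fraction of genes overlapping a synteny block, per class.

    ``gene_intervals`` maps gene id → (contig-agnostic) half-open interval;
    block overlap uses synteny_mum.gene_in_block.
    """
    from .synteny_mum import gene_in_block

    totals: dict[str, int] = {}
    inside: dict[str, int] = {}
    for c in classifications:
        if c.gene_id not in gene_intervals:
            continue
        interval = gene_intervals[c.gene_id]
        start, end = interval[-2], interval[-1]
        totals[c.klass] = totals.get(c.klass, 0) + 1
        if gene_in_block((start, end), blocks, genome_side, min_fraction=min_fraction):
            inside[c.klass] = inside.get(c.klass, 0) + 1
    return {k: inside.get(k, 0) / n for k, n in totals.items()}
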