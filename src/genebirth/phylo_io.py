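"""Readers, writers and preparation filters for the pipeline's external formats.

Covers: rooted species trees (newick) with reference-path branch labels,
OrthoFinder-style orthogroup and duplication tables, blast outfmt-6 homology
hits, SNPs (VCF subset or 5-column TSV) with CDS/intron context assignment,
proteome preparation (isoform selection, stop-codon and overlap filters),
counts-to-TPM conversion and NTG→stop ORF extraction.

Coordinates are 1-based inclusive at file boundaries (GFF/VCF convention) and
half-open 0-based internally; conversions happen only in the parse/write
functions of this module.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from ._codon import STOP_CODONS, codons_of, translate_cds

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene (or one isoform of it, before preparation)."""

    gene_id: str
    species: str
    contig: str
    start: int  # 0-based half-open genomic span of the CDS
    end: int
    strand: str  # '+' or '-'
    cds_na: str
    protein_aa: str = ""
    isoform_id: str | None = None
    is_wgd_derived: bool = False
    expression_tpm: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.cds_na) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if not self.protein_aa:
            object.__setattr__(self, "protein_aa", translate_cds(self.cds_na))


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: dict[str, tuple[str, ...]]  # species -> gene ids

    def __post_init__(self):
        if not any(self.members.values()):
            raise ValueError(f"{self.og_id}: orthogroup has no members")

    @property
    def species(self) -> set[str]:
        return {sp for sp, genes in self.members.items() if genes}

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(g for genes in self.members.values() for g in genes)


@dataclass(frozen=True)
class DuplicationRecord:
    og_id: str
    species_tree_node: str
    support: float
    genes_1: tuple[str, ...]
    genes_2: tuple[str, ...]

    def __post_init__(self):
        if not (0.0 <= self.support <= 1.0):
            raise ValueError(f"{self.og_id}: support {self.support} outside [0, 1]")
        if not self.genes_1 or not self.genes_2:
            raise ValueError(f"{self.og_id}: both gene lists must be nonempty")


@dataclass(frozen=True)
class HomologyHit:
    query_gene: str
    subject_species: str
    subject_gene: str
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class SnpRecord:
    contig: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    minor_allele_freq: float
    context: str  # 'cds' or 'intron'
    gene_id: str | None = None

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt alleles are identical")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"allele {b!r} is not a single A/C/G/T base")
        if not (0.0 <= self.minor_allele_freq <= 0.5):
            raise ValueError("minor allele frequency must lie in [0, 0.5]")
        if self.context not in ("cds", "intron"):
            raise ValueError(f"unknown context {self.context!r}")


class SpeciesTree:
    """Rooted species tree with N-labels along the reference→root path.

    N0 labels the reference species' terminal branch; labels increase toward
    the root, which carries the last label Nk.  A tip may stand for a group of
    species (multi-species terminal nodes): presence of any member counts the
    tip as present.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        reference_species: str,
        tip_groups: dict[str, set[str]] | None = None,
    ):
        self._tree = tree
        self.reference_species = reference_species
        self.tip_groups = {k: frozenset(v) for k, v in (tip_groups or {}).items()}

        self._species_to_tip: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label
            self._species_to_tip[name] = leaf
            for sp in self.tip_groups.get(name, ()):
                self._species_to_tip[sp] = leaf

        if reference_species not in self._species_to_tip:
            raise ValueError(
                f"reference species {reference_species!r} not found in tree"
            )
        ref_tip = self._species_to_tip[reference_species]

        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValueError("tree must be rooted (bifurcating root)")

        self._path_nodes: list[dendropy.Node] = []
        node = ref_tip
        while node is not None:
            self._path_nodes.append(node)
            node = node.parent_node
        self.branch_labels: dict[str, dendropy.Node] = {
            f"N{i}": n for i, n in enumerate(self._path_nodes)
        }
        self._node_to_label = {id(n): f"N{i}" for i, n in enumerate(self._path_nodes)}
        for node in self._path_nodes:
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("negative branch length on reference path")

    # -- basic accessors ---------------------------------------------------

    @property
    def labels(self) -> list[str]:
        """N0..Nk from the reference tip to the root."""
        return [f"N{i}" for i in range(len(self._path_nodes))]

    @property
    def root_label(self) -> str:
        return self.labels[-1]

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def species_names(self) -> set[str]:
        return set(self._species_to_tip)

    def label_index(self, label: str) -> int:
        if label not in self.branch_labels:
            raise KeyError(f"unknown branch label {label!r}")
        return int(label[1:])

    def branch_length(self, label: str) -> float:
        """Length of the branch above the labelled node (root edge → 0)."""
        length = self.branch_labels[label].edge.length
        return 0.0 if length is None else float(length)

    # -- queries -----------------------------------------------------------

    def mrca_label(self, species_present: set[str] | frozenset[str]) -> str:
        """N-label of the MRCA of the species set (must include the reference)."""
        if self.reference_species not in species_present:
            raise ValueError("species set must contain the reference species")
        tips = set()
        for sp in species_present:
            if sp not in self._species_to_tip:
                raise ValueError(f"species {sp!r} not in tree")
            tips.add(self._species_to_tip[sp])
        # walk the reference path tipward→rootward; the first node ancestral to
        # every present tip is the MRCA (it always lies on this path)
        for node in self._path_nodes:
            if all(self._is_ancestor(node, t) for t in tips):
                return self._node_to_label[id(node)]
        raise RuntimeError("MRCA search failed")  # pragma: no cover

    @staticmethod
    def _is_ancestor(anc, node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent_node
        return False

    def clade_species(self, label: str) -> set[str]:
        """All species (tip-group expanded) descending from the labelled node."""
        node = self.branch_labels[label]
        out: set[str] = set()
        for leaf in node.leaf_iter():
            name = leaf.taxon.label
            out |= set(self.tip_groups.get(name, {name}))
        return out

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


# --------------------------------------------------------------------------
# parsers / writers
# --------------------------------------------------------------------------


def _as_text_stream(source) -> io.TextIOBase:
    if isinstance(source, (str, os.PathLike)):
        return open(source)
    return source


def parse_species_tree(
    newick_text: str,
    reference_species: str,
    tip_groups: dict[str, set[str]] | None = None,
) -> SpeciesTree:
    """Parse a rooted newick tree and assign N0..Nk reference-path labels."""
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    return SpeciesTree(tree, reference_species, tip_groups)


def parse_orthogroups(tsv) -> list[Orthogroup]:
    """Read an Orthogroups.tsv-dialect table (header = species names)."""
    df = pd.read_csv(_as_text_stream(tsv), sep="\t", dtype=str).fillna("")
    species = list(df.columns[1:])
    out: list[Orthogroup] = []
    seen: dict[str, str] = {}
    for _, row in df.iterrows():
        og_id = row.iloc[0]
        members: dict[str, tuple[str, ...]] = {}
        for sp in species:
            genes = tuple(g.strip() for g in row[sp].split(",") if g.strip())
            if genes:
                members[sp] = genes
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} listed in both {seen[g]} and {og_id}"
                    )
                seen[g] = og_id
        out.append(Orthogroup(og_id=og_id, members=members))
    return out


def write_orthogroups(orthogroups: list[Orthogroup], path) -> None:
    species = sorted({sp for og in orthogroups for sp in og.members})
    rows = []
    for og in orthogroups:
        row = {"Orthogroup": og.og_id}
        for sp in species:
            row[sp] = ", ".join(og.members.get(sp, ()))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *species]).to_csv(
        path, sep="\t", index=False
    )


_DUP_COLUMNS = ["Orthogroup", "Species Tree Node", "Support", "Genes 1", "Genes 2"]


def parse_duplications(tsv, tree: SpeciesTree | None = None) -> list[DuplicationRecord]:
    """Read a Duplications.tsv-dialect table; optionally validate node labels."""
    df = pd.read_csv(_as_text_stream(tsv), sep="\t", dtype=str)
    missing = [c for c in _DUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"duplication table lacks columns: {missing}")
    out = []
    for _, row in df.iterrows():
        for col in ("Genes 1", "Genes 2"):
            if pd.isna(row[col]) or not str(row[col]).strip():
                raise ValueError(f"{row['Orthogroup']}: empty {col!r} field")
        node = row["Species Tree Node"]
        if tree is not None and node not in tree.branch_labels and node not in tree.tip_names:
            raise ValueError(f"unknown species tree node {node!r}")
        out.append(
            DuplicationRecord(
                og_id=row["Orthogroup"],
                species_tree_node=node,
                support=float(row["Support"]),
                genes_1=tuple(g.strip() for g in row["Genes 1"].split(",") if g.strip()),
                genes_2=tuple(g.strip() for g in row["Genes 2"].split(",") if g.strip()),
            )
        )
    return out


def write_duplications(records: list[DuplicationRecord], path) -> None:
    rows = [
        {
            "Orthogroup": r.og_id,
            "Species Tree Node": r.species_tree_node,
            "Support": r.support,
            "Genes 1": ", ".join(r.genes_1),
            "Genes 2": ", ".join(r.genes_2),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_DUP_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_blast_hits(tsv, species_of_subject=None) -> list[HomologyHit]:
    """Read 12-column blast outfmt-6; subject species from a callable or the
    subject id prefix before the first '|'."""
    df = pd.read_csv(_as_text_stream(tsv), sep="\t", header=None, dtype=str)
    if df.shape[1] < 12:
        raise ValueError("expected 12-column blast tabular output")
    hits = []
    for _, row in df.iterrows():
        subject = row[1]
        species = (
            species_of_subject(subject)
            if species_of_subject
            else subject.split("|")[0]
        )
        hits.append(
            HomologyHit(
                query_gene=row[0],
                subject_species=species,
                subject_gene=subject,
                e_value=float(row[10]),
            )
        )
    return hits


def write_blast_hits(hits: list[HomologyHit], path) -> None:
    rows = [
        [
            h.query_gene,
            f"{h.subject_species}|{h.subject_gene.split('|')[-1]}",
            100.0, 0, 0, 0, 0, 0, 0, 0, h.e_value, 0.0,
        ]
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# -- proteome preparation --------------------------------------------------


def _cds_is_clean(cds: str) -> bool:
    codons = codons_of(cds)
    if not codons or codons[0] != "ATG" or codons[-1] not in STOP_CODONS:
        return False
    return not any(c in STOP_CODONS for c in codons[:-1])


def prepare_proteome(isoforms: list[GeneRecord]) -> list[GeneRecord]:
    """Select one clean isoform per gene and drop heavily-overlapping proteins.

    Per gene, the longest protein is kept (ties broken by lexicographically
    smallest isoform id, then gene id).  A CDS must start with ATG, end with a
    stop codon and contain no internal stop.  A surviving protein P is then
    removed when any other same-strand, same-contig protein Q overlaps P over
    more than 10% of P's own genomic span; the rule is applied simultaneously,
    so mutually-overlapping pairs can both be removed, and the whole filter is
    idempotent.
    """
    by_gene: dict[str, list[GeneRecord]] = {}
    for rec in isoforms:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    selected: list[GeneRecord] = []
    for gene_id, recs in by_gene.items():
        clean = [r for r in recs if _cds_is_clean(r.cds_na)]
        if not clean:
            continue
        clean.sort(key=lambda r: (-len(r.protein_aa), r.isoform_id or "", r.gene_id))
        selected.append(clean[0])

    # simultaneous >10% genomic-overlap removal, per protein's own span
    kept = []
    for p in selected:
        p_len = p.end - p.start
        removed = False
        for q in selected:
            if q is p or q.contig != p.contig or q.strand != p.strand:
                continue
            overlap = min(p.end, q.end) - max(p.start, q.start)
            if overlap > 0 and overlap / p_len > 0.10:
                removed = True
                break
        if not removed:
            kept.append(p)
    return kept


# -- SNPs ------------------------------------------------------------------


def _interval_tree(intervals) -> dict[str, IntervalTree]:
    """intervals: iterable of (contig, start, end[, payload]) half-open 0-based."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        contig, start, end = iv[0], iv[1], iv[2]
        payload = iv[3] if len(iv) > 3 else None
        trees.setdefault(contig, IntervalTree()).addi(start, end, payload)
    return trees


def _iter_raw_snps(source):
    """Yield (contig, pos0, ref, alts, maf) from a VCF file or 5-column TSV."""
    path = os.fspath(source) if isinstance(source, (str, os.PathLike)) else None
    if path is not None and path.endswith((".vcf", ".vcf.gz")):
        import pysam

        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                alts = list(rec.alts or ())
                maf = rec.info.get("MAF", None)
                if maf is None:
                    af = rec.info.get("AF", None)
                    if af is not None:
                        af = af[0] if isinstance(af, tuple) else af
                        maf = min(float(af), 1.0 - float(af))
                yield rec.contig, rec.pos - 1, rec.ref, alts, (
                    float(maf[0] if isinstance(maf, tuple) else maf)
                    if maf is not None
                    else 0.5
                )
    else:
        df = pd.read_csv(
            _as_text_stream(source),
            sep="\t",
            comment="#",
            header=None,
            names=["contig", "pos", "ref", "alt", "maf"],
            dtype={"contig": str, "ref": str, "alt": str},
        )
        for row in df.itertuples(index=False):
            yield str(row.contig), int(row.pos) - 1, row.ref, str(row.alt).split(","), float(row.maf)


def parse_snps(source, cds_intervals, intron_intervals, exon_intervals=None) -> list[SnpRecord]:
    """Assign CDS/intron context to biallelic SNPs.

    ``cds_intervals``: (contig, start, end, gene_id) half-open 0-based;
    ``intron_intervals``: (contig, start, end).  Intronic SNPs overlapping any
    exonic interval (``exon_intervals``, defaulting to the CDS set) are
    excluded from the intron context.  Multi-allelic records are split into
    one record per alt allele; indels raise.
    """
    cds_trees = _interval_tree(cds_intervals)
    intron_trees = _interval_tree(intron_intervals)
    exon_trees = _interval_tree(exon_intervals) if exon_intervals is not None else cds_trees

    out: list[SnpRecord] = []
    for contig, pos, ref, alts, maf in _iter_raw_snps(source):
        if len(ref) != 1 or any(len(a) != 1 for a in alts):
            raise ValueError(f"indel at {contig}:{pos + 1} rejected (SNPs only)")
        cds_hits = cds_trees.get(contig, IntervalTree())[pos]
        in_intron = bool(intron_trees.get(contig, IntervalTree())[pos])
        in_exon = bool(exon_trees.get(contig, IntervalTree())[pos])
        for alt in alts:
            if cds_hits:
                gene_id = sorted(h.data for h in cds_hits)[0]
                out.append(SnpRecord(contig, pos, ref, alt, maf, "cds", gene_id))
            elif in_intron and not in_exon:
                out.append(SnpRecord(contig, pos, ref, alt, maf, "intron"))
    return out


def write_snps_tsv(snps: list[SnpRecord], path) -> None:
    rows = [
        {
            "contig": s.contig,
            "pos": s.position + 1,
            "ref": s.ref_base,
            "alt": s.alt_base,
            "maf": s.minor_allele_freq,
            "context": s.context,
            "gene_id": s.gene_id or "",
        }
        for s in snps
    ]
    pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "maf", "context", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def read_snps_tsv(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str})
    return [
        SnpRecord(
            contig=row.contig,
            position=int(row.pos) - 1,
            ref_base=row.ref,
            alt_base=row.alt,
            minor_allele_freq=float(row.maf),
            context=row.context,
            gene_id=(None if pd.isna(row.gene_id) or row.gene_id == "" else str(row.gene_id)),
        )
        for row in df.itertuples(index=False)
    ]


# -- GFF subset ------------------------------------------------------------


def parse_gff_intervals(source, feature_types=("CDS",)):
    """Read a GFF3 subset, returning (contig, start, end, attr_id, strand)
    half-open 0-based tuples for the requested feature types.  Only the
    CDS/exon/intron subset of GFF3 is supported."""
    wanted = set(feature_types)
    out = []
    stream = _as_text_stream(source)
    for line in stream:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ValueError("GFF3 lines must have 9 tab-separated fields")
        contig, _, ftype, start, end, _, strand, _, attrs = fields
        if ftype not in wanted:
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        ident = attr.get("ID") or attr.get("Parent") or ""
        out.append((contig, int(start) - 1, int(end), ident, strand))
    return out


# -- small plumbing --------------------------------------------------------


def counts_to_tpm(read_counts: dict[str, float], lengths: dict[str, float]) -> dict[str, float]:
    """Transcripts-per-million from raw counts and feature lengths (nt)."""
    rpk = {}
    for gene, count in read_counts.items():
        length = lengths[gene]
        if length <= 0:
            raise ValueError(f"{gene}: non-positive length")
        rpk[gene] = count / (length / 1e3)
    total = sum(rpk.values())
    if total == 0:
        return {g: 0.0 for g in rpk}
    return {g: v / total * 1e6 for g, v in rpk.items()}


START_CODONS = frozenset({"ATG", "CTG", "TTG", "GTG"})


def extract_orfs(transcript_na: str, start_codons=START_CODONS, min_aa: int = 10) -> list[str]:
    """Extract NTG→stop ORFs encoding at least ``min_aa`` amino acids.

    ORFs without an in-frame stop are not emitted; nested ORFs sharing a stop
    keep only the longest.
    """
    seq = transcript_na.upper()
    peptides: dict[tuple[int, int], str] = {}  # (frame, stop position) -> longest
    for i in range(len(seq) - 2):
        if seq[i : i + 3] not in start_codons:
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOP_CODONS:
                break
            j += 3
        else:
            continue
        if seq[j : j + 3] not in STOP_CODONS:
            continue
        n_aa = (j - i) // 3
        if n_aa < min_aa:
            continue
        key = (i % 3, j)
        if key not in peptides:  # scanning left→right: first start is longest
            peptides[key] = translate_cds(seq[i:j] )
    return [peptides[k] for k in sorted(peptides)]


# -- FASTA conveniences ----------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")
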