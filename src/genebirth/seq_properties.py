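"""Protein length, isoelectric point, amino-acid class composition, the
translated-intron control set and rank-sum group comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import DEFAULT_CLASS_SCHEME
from .phylo_io import extract_orfs
from ._codon import STOP_CODONS, CODON_TO_AA

# EMBOSS pK values; the exact table is a configuration choice recorded in
# output metadata.
EMBOSS_PK = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_ACIDIC_GROUPS = ("Cterm", "D", "E", "C", "Y")
_BASIC_GROUPS = ("Nterm", "K", "R", "H")


def protein_charge(protein_aa: str, ph: float, pk_table: dict[str, float] | None = None) -> float:
    """Net charge at a given pH (termini + D,E,C,Y,K,R,H side chains,
    Henderson–Hasselbalch)."""
    pk = pk_table or EMBOSS_PK
    seq = protein_aa.upper()
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    charge = 0.0
    for group in _BASIC_GROUPS:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10 ** (ph - pk[group]))
    for group in _ACIDIC_GROUPS:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10 ** (pk[group] - ph))
    return charge


def isoelectric_point(
    protein_aa: str,
    pk_table: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero, by bisection on (0, 14)."""
    if not protein_aa:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = protein_charge(protein_aa, mid, pk_table)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def class_fractions(
    protein_aa: str, scheme: dict[str, str] | None = None
) -> dict[str, float]:
    """Fractions of acidic/basic/polar/nonpolar residues; unclassifiable
    residues are excluded from the denominator."""
    scheme = scheme or DEFAULT_CLASS_SCHEME
    if not protein_aa:
        raise ValueError("empty protein sequence")
    counts: dict[str, int] = {c: 0 for c in sorted(set(scheme.values()))}
    n = 0
    for aa in protein_aa.upper():
        cls = scheme.get(aa)
        if cls is None:
            continue
        counts[cls] += 1
        n += 1
    if n == 0:
        raise ValueError("sequence contains no classifiable residue")
    return {c: k / n for c, k in counts.items()}


def intron_control_set(
    introns_na, policy: str = "orf", min_aa: int = 10
) -> list[str]:
    """Peptides from in-silico-translated introns.

    policy 'orf': NTG→stop ORFs of at least ``min_aa`` amino acids (default);
    policy 'frame1': fixed frame-1 translation with stops removed.
    """
    peptides: list[str] = []
    for intron in introns_na:
        if policy == "orf":
            peptides.extend(extract_orfs(intron, min_aa=min_aa))
        elif policy == "frame1":
            seq = intron.upper()
            aas = [
                CODON_TO_AA[seq[i : i + 3]]
                for i in range(0, len(seq) - len(seq) % 3, 3)
                if seq[i : i + 3] in CODON_TO_AA and seq[i : i + 3] not in STOP_CODONS
            ]
            if len(aas) >= min_aa:
                peptides.append("".join(aas))
        else:
            raise ValueError(f"unknown intron translation policy {policy!r}")
    return peptides


def compare_groups(values_a, values_b) -> tuple[float, str]:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum p-value with significance
    stars (* p<0.05, ** p<1e-2, *** p<1e-3); exact for small samples without
    ties, normal approximation with tie correction otherwise."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    stars = "***" if p < 1e-3 else "**" if p < 1e-2 else "*" if p < 0.05 else "ns"
    return p, stars


@dataclass
class ProteinProfile:
    gene_id: str
    length: int
    pI: float
    class_fractions: dict[str, float]
    group: str


def profile_protein(
    gene_id: str,
    protein_aa: str,
    group: str,
    scheme: dict[str, str] | None = None,
    pk_table: dict[str, float] | None = None,
) -> ProteinProfile:
    return ProteinProfile(
        gene_id=gene_id,
        length=len(protein_aa),
        pI=isoelectric_point(protein_aa, pk_table),
        class_fractions=class_fractions(protein_aa, scheme),
        group=group,
    )


def group_summaries(profiles: list[ProteinProfile]) -> pd.DataFrame:
    """Per-group median length, median pI and median class fractions.

    Medians use the midpoint-of-central-pair convention for even group sizes.
    """
    rows = []
    groups: dict[str, list[ProteinProfile]] = {}
    for p in profiles:
        groups.setdefault(p.group, []).append(p)
    for name in sorted(groups):
        members = groups[name]
        row = {
            "group": name,
            "n": len(members),
            "median_length": float(np.median([m.length for m in members])),
            "median_pI": float(np.median([m.pI for m in members])),
        }
        classes = sorted({c for m in members for c in m.class_fractions})
        for cls in classes:
            row[f"median_frac_{cls}"] = float(
                np.median([m.class_fractions.get(cls, 0.0) for m in members])
            )
        rows.append(row)
    return pd.DataFrame(rows)
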