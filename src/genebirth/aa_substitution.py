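"""Observed vs neutral-expected amino-acid changes and parsimony directionality.

From pairwise protein alignments, count differing amino-acid pairs; compare
with a neutral expectation built from the codon composition of the group and
the single-nucleotide mutation matrix, restricted to changes explainable by a
single-nucleotide substitution (e.g. K→E via AAA→GAA or AAG→GAG).  From
three-species alignments, infer the direction of change by parsimony (the
amino acid shared by the reference and one sister is ancestral) and tally
gains and losses of acidic/basic/polar/nonpolar residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import (
    AMINO_ACIDS,
    CODON_TO_AA,
    DEFAULT_CLASS_SCHEME,
    single_nt_codon_pairs,
)
from .selection_pnps import MutationMatrix

_STANDARD_AA = set(AMINO_ACIDS)


def _pair(aa1: str, aa2: str) -> frozenset[str]:
    return frozenset((aa1, aa2))


# --------------------------------------------------------------------------
# observed pair counts
# --------------------------------------------------------------------------


@dataclass
class PairCounts:
    """Unordered amino-acid pair counts from one or more pairwise alignments."""

    counts: dict[frozenset[str], int] = field(default_factory=dict)

    @property
    def total_changes(self) -> int:
        return sum(self.counts.values())

    @property
    def total_single_nt_explainable(self) -> int:
        reachable = reachable_pairs()
        return sum(n for p, n in self.counts.items() if p in reachable)

    def add(self, other: "PairCounts") -> "PairCounts":
        merged = dict(self.counts)
        for p, n in other.counts.items():
            merged[p] = merged.get(p, 0) + n
        return PairCounts(merged)

    def get(self, aa1: str, aa2: str) -> int:
        return self.counts.get(_pair(aa1, aa2), 0)


def extract_pair_counts(seq1: str, seq2: str) -> PairCounts:
    """Count columns where both residues are standard amino acids and differ;
    gap and ambiguous (X/B/Z/U/*) columns are skipped."""
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    counts: dict[frozenset[str], int] = {}
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a == b or a not in _STANDARD_AA or b not in _STANDARD_AA:
            continue
        p = _pair(a, b)
        counts[p] = counts.get(p, 0) + 1
    return PairCounts(counts)


# --------------------------------------------------------------------------
# single-nucleotide reachability
# --------------------------------------------------------------------------


def single_nt_paths(aa1: str, aa2: str) -> list[tuple[str, str]]:
    """All ordered sense-codon pairs (c1→c2) with one mismatch encoding aa1→aa2."""
    if aa1 == aa2:
        raise ValueError("amino acids must differ")
    for aa in (aa1, aa2):
        if aa not in _STANDARD_AA:
            raise ValueError(f"{aa!r} is not a standard amino acid")
    return [
        (c1, c2)
        for c1, c2 in single_nt_codon_pairs()
        if CODON_TO_AA[c1] == aa1 and CODON_TO_AA[c2] == aa2
    ]


@lru_cache(maxsize=1)
def reachable_pairs() -> frozenset[frozenset[str]]:
    """Unordered amino-acid pairs connected by at least one single-nt change."""
    return frozenset(
        _pair(CODON_TO_AA[c1], CODON_TO_AA[c2])
        for c1, c2 in single_nt_codon_pairs()
        if CODON_TO_AA[c1] != CODON_TO_AA[c2]
    )


# --------------------------------------------------------------------------
# neutral expectation
# --------------------------------------------------------------------------


@dataclass
class ExpectedPairTable:
    """Expected pair counts normalized to the observed total.

    ``raw_ordered``: un-normalized weight of each ordered change aa_i→aa_j
    (Σ over single-nt codon routes of codon frequency × mutation frequency);
    ``expected``: unordered-pair expectations over the included pairs,
    scaled so their sum equals the observed total over the same pairs.
    """

    raw_ordered: dict[tuple[str, str], float]
    expected: dict[frozenset[str], float]
    observed_total: float


def expected_change_table(
    codon_freqs: dict[str, float],
    matrix: MutationMatrix,
    observed: PairCounts,
) -> ExpectedPairTable:
    """Neutral expected frequency of amino-acid pairs.

    The raw weight of an ordered change is the sum over its single-nucleotide
    codon routes of (relative codon frequency × mutation-type frequency); the
    unordered pair weight adds both directions.  The table is restricted to
    pairs that are single-nt reachable AND observed in the focal set, then
    normalized so expected totals equal observed totals over those pairs.
    """
    total_codons = sum(codon_freqs.values())
    if total_codons <= 0:
        raise ValueError("codon frequencies are all zero")
    freqs = {c: f / total_codons for c, f in codon_freqs.items()}

    raw: dict[tuple[str, str], float] = {}
    for c1, c2 in single_nt_codon_pairs():
        aa1, aa2 = CODON_TO_AA[c1], CODON_TO_AA[c2]
        if aa1 == aa2:
            continue
        pos = next(i for i in range(3) if c1[i] != c2[i])
        w = freqs.get(c1, 0.0) * matrix[(c1[pos], c2[pos])]
        key = (aa1, aa2)
        raw[key] = raw.get(key, 0.0) + w

    included = [p for p in observed.counts if p in reachable_pairs()]
    weights = {}
    for p in included:
        aa1, aa2 = sorted(p)
        weights[p] = raw.get((aa1, aa2), 0.0) + raw.get((aa2, aa1), 0.0)
    wsum = sum(weights.values())
    if included and wsum <= 0:
        raise ValueError("all expected weights are zero for the observed pairs")
    obs_total = float(sum(observed.counts[p] for p in included))
    expected = {p: w / wsum * obs_total for p, w in weights.items()}
    return ExpectedPairTable(raw_ordered=raw, expected=expected, observed_total=obs_total)


def log2_oe(
    observed: PairCounts,
    expected: ExpectedPairTable,
    scheme: dict[str, str] | None = None,
    min_cases: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair and per-class-pair log2(O/E) tables.

    Class-pair values aggregate observed and expected counts before taking
    the ratio.  Pairs with expected 0 are reported with log2_oe = NaN; pairs
    with fewer than ``min_cases`` observations are dropped from the per-pair
    table (Fig-style "more than five cases" filtering).
    """
    scheme = scheme or DEFAULT_CLASS_SCHEME
    pair_rows = []
    class_obs: dict[frozenset[str], float] = {}
    class_exp: dict[frozenset[str], float] = {}
    for p, e in expected.expected.items():
        o = observed.counts.get(p, 0)
        aa1, aa2 = sorted(p)
        cls = frozenset((scheme[aa1], scheme[aa2]))
        class_obs[cls] = class_obs.get(cls, 0.0) + o
        class_exp[cls] = class_exp.get(cls, 0.0) + e
        if o < min_cases:
            continue
        pair_rows.append(
            {
                "pair": f"{aa1}/{aa2}",
                "class_pair": "/".join(sorted(cls)),
                "observed": o,
                "expected": e,
                "log2_oe": math.log2(o / e) if o > 0 and e > 0 else float("nan"),
            }
        )
    class_rows = [
        {
            "class_pair": "/".join(sorted(cls)),
            "observed": class_obs[cls],
            "expected": class_exp[cls],
            "log2_oe": (
                math.log2(class_obs[cls] / class_exp[cls])
                if class_obs[cls] > 0 and class_exp[cls] > 0
                else float("nan")
            ),
        }
        for cls in class_obs
    ]
    pair_df = pd.DataFrame(
        pair_rows, columns=["pair", "class_pair", "observed", "expected", "log2_oe"]
    ).sort_values("pair", ignore_index=True)
    class_df = pd.DataFrame(
        class_rows, columns=["class_pair", "observed", "expected", "log2_oe"]
    ).sort_values("class_pair", ignore_index=True)
    return pair_df, class_df


# --------------------------------------------------------------------------
# directionality
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectionalChange:
    ancestral: str
    derived: str
    branch: str  # which non-reference species changed
    gene_id: str | None = None
    column: int | None = None

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived amino acids must differ")


def infer_direction(
    ref_seq: str,
    sister1_seq: str,
    sister2_seq: str,
    labels: tuple[str, str, str] = ("reference", "sister1", "sister2"),
    gene_id: str | None = None,
) -> list[DirectionalChange]:
    """Directional changes from a three-species alignment by parsimony.

    A column counts iff exactly two species share a standard amino acid and
    the reference is one of them: the shared residue is ancestral and the
    differing sister carries the derived state on its own branch.  Columns
    with a gap or ambiguous residue in any species are excluded.
    """
    if not (len(ref_seq) == len(sister1_seq) == len(sister2_seq)):
        raise ValueError("aligned sequences must have equal length")
    out: list[DirectionalChange] = []
    for i, (r, s1, s2) in enumerate(
        zip(ref_seq.upper(), sister1_seq.upper(), sister2_seq.upper())
    ):
        if any(x not in _STANDARD_AA for x in (r, s1, s2)):
            continue
        if r == s1 and r != s2:
            out.append(DirectionalChange(r, s2, labels[2], gene_id, i))
        elif r == s2 and r != s1:
            out.append(DirectionalChange(r, s1, labels[1], gene_id, i))
        # r the odd one out, or all three distinct, or all equal: excluded
    return out


def tally_gain_loss(
    changes: list[DirectionalChange],
    scheme: dict[str, str] | None = None,
):
    """Per-class and per-amino-acid gain/loss tallies of directional changes.

    gain of class C counts changes whose derived residue is in C; loss counts
    ancestral residues in C.  Returns (per_class_df, per_aa_df) with a net
    direction column (gained / lost / equal).
    """
    scheme = scheme or DEFAULT_CLASS_SCHEME
    class_gain: dict[str, int] = {}
    class_loss: dict[str, int] = {}
    aa_gain: dict[str, int] = {}
    aa_loss: dict[str, int] = {}
    for ch in changes:
        class_gain[scheme[ch.derived]] = class_gain.get(scheme[ch.derived], 0) + 1
        class_loss[scheme[ch.ancestral]] = class_loss.get(scheme[ch.ancestral], 0) + 1
        aa_gain[ch.derived] = aa_gain.get(ch.derived, 0) + 1
        aa_loss[ch.ancestral] = aa_loss.get(ch.ancestral, 0) + 1

    def _net(g, l):
        return "gained" if g > l else ("lost" if l > g else "equal")

    classes = sorted(set(scheme.values()))
    per_class = pd.DataFrame(
        [
            {
                "class": c,
                "gains": class_gain.get(c, 0),
                "losses": class_loss.get(c, 0),
                "net": _net(class_gain.get(c, 0), class_loss.get(c, 0)),
            }
            for c in classes
        ]
    )
    aas = sorted(set(aa_gain) | set(aa_loss))
    per_aa = pd.DataFrame(
        [
            {
                "aa": a,
                "class": scheme[a],
                "gains": aa_gain.get(a, 0),
                "losses": aa_loss.get(a, 0),
                "net": _net(aa_gain.get(a, 0), aa_loss.get(a, 0)),
            }
            for a in aas
        ],
        columns=["aa", "class", "gains", "losses", "net"],
    )
    return per_class, per_aa


# --------------------------------------------------------------------------
# enrichment testing
# --------------------------------------------------------------------------


def pair_enrichment_test(
    counts_focal: PairCounts,
    counts_background: PairCounts,
    pairs=None,
    method: str = "bh",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-pair Fisher exact test (pair vs rest, focal vs background) with
    multiple-test correction (Benjamini–Hochberg by default, or 'bonferroni').
    """
    if pairs is None:
        pairs = sorted(
            set(counts_focal.counts) | set(counts_background.counts),
            key=lambda p: tuple(sorted(p)),
        )
    n_focal = counts_focal.total_changes
    n_bg = counts_background.total_changes
    if n_focal == 0 or n_bg == 0:
        raise ValueError("both focal and background totals must be positive")
    rows = []
    pvals = []
    for p in pairs:
        a = counts_focal.counts.get(p, 0)
        c = counts_background.counts.get(p, 0)
        table = [[a, n_focal - a], [c, n_bg - c]]
        res = stats.fisher_exact(table, alternative=alternative)
        pvals.append(res.pvalue)
        rows.append(
            {
                "pair": "/".join(sorted(p)),
                "focal": a,
                "background": c,
                "odds_ratio": res.statistic,
                "p": res.pvalue,
            }
        )
    if method == "bh":
        adjusted = stats.false_discovery_control(pvals, method="bh")
    elif method == "bonferroni":
        adjusted = np.minimum(np.asarray(pvals) * len(pvals), 1.0)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    df = pd.DataFrame(rows)
    df["p_adj"] = adjusted
    return df
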