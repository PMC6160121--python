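"""Cross-species mapping of binding sites on serum albumin.

Binding residues identified on one albumin (e.g. bovine) are carried to
another (e.g. human) through a global pairwise alignment, classified for
conservation (identical / similar physicochemical class / different /
gap) and intersected with reference residue sets such as the seven
crystallographic fatty-acid binding sites.  All residue numbers are
1-based positions in the mature chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import biotite.sequence as bseq
import biotite.sequence.align as balign

__all__ = [
    "AlignmentResult",
    "SimilarityClasses",
    "SiteOverlap",
    "align_global",
    "conservation_of_sites",
    "overlap_classify",
    "map_sites_across_species",
]

# Physicochemical grouping used to call "similar" substitutions.
DEFAULT_CLASSES = {
    "aliphatic": frozenset("AVLIM"),
    "aromatic": frozenset("FWY"),
    "hydroxyl": frozenset("ST"),
    "amide": frozenset("NQ"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
    "cysteine": frozenset("C"),
    "glycine": frozenset("G"),
    "proline": frozenset("P"),
}


@dataclass(frozen=True)
class SimilarityClasses:
    """A named partition of the 20 amino acids into property groups."""

    groups: dict = field(default_factory=lambda: dict(DEFAULT_CLASSES))

    def __post_init__(self):
        seen: set[str] = set()
        for name, members in self.groups.items():
            members = frozenset(members)
            if seen & members:
                raise ValueError(f"group {name!r} overlaps another group")
            seen |= members
        if seen != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("groups must cover exactly the 20 standard amino acids")

    def same_class(self, a: str, b: str) -> bool:
        for members in self.groups.values():
            if a in members:
                return b in members
        return False


@dataclass(frozen=True)
class AlignmentResult:
    """Global pairwise alignment with identity/similarity percentages.

    ``column_map`` maps 1-based residue positions of sequence A to the
    aligned 1-based positions of sequence B for every gap-free column.
    Identity/similarity use the aligned span excluding terminal-gap
    columns as denominator.
    """

    gapped_a: str
    gapped_b: str
    identity_pct: float
    similarity_pct: float
    column_map: dict[int, int]
    score: float

    def __post_init__(self):
        if not (0 <= self.identity_pct
                and self.identity_pct + self.similarity_pct <= 100.0 + 1e-9):
            raise ValueError("identity + similarity must lie within [0, 100]%")


def align_global(
    seq_a: str,
    seq_b: str,
    matrix: balign.SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    classes: SimilarityClasses | None = None,
) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch, affine gaps).

    Defaults to BLOSUM62 with gap open/extend 10/0.5.  Identity counts
    identical columns over the aligned span (terminal-gap columns
    excluded); similarity counts non-identical columns whose residues
    share a physicochemical class.
    """
    classes = classes or SimilarityClasses()
    sa = bseq.ProteinSequence(seq_a)
    sb = bseq.ProteinSequence(seq_b)
    if matrix is None:
        matrix = balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62
    aln = balign.align_optimal(
        sa, sb, matrix,
        gap_penalty=(-abs(gap_open), -abs(gap_extend)),
        terminal_penalty=False,
    )[0]
    gapped_a, gapped_b = aln.get_gapped_sequences()
    trace = aln.trace
    # aligned span: drop leading/trailing columns where either side is a gap
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    first, last = int(both.argmax()), int(len(both) - both[::-1].argmax() - 1)
    n_aligned = last - first + 1
    n_ident = n_sim = 0
    column_map: dict[int, int] = {}
    for col in range(len(trace)):
        ia, ib = int(trace[col, 0]), int(trace[col, 1])
        if ia >= 0 and ib >= 0:
            column_map[ia + 1] = ib + 1
            if first <= col <= last:
                ca, cb = str(sa[ia]), str(sb[ib])
                if ca == cb:
                    n_ident += 1
                elif classes.same_class(ca, cb):
                    n_sim += 1
    return AlignmentResult(
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        identity_pct=100.0 * n_ident / n_aligned,
        similarity_pct=100.0 * n_sim / n_aligned,
        column_map=column_map,
        score=float(aln.score),
    )


def conservation_of_sites(
    aln: AlignmentResult,
    residues_a: set[int],
    classes: SimilarityClasses | None = None,
) -> dict[str, float]:
    """Conservation breakdown of a residue set through an alignment.

    Each residue of ``residues_a`` (1-based in sequence A) is classified
    by its aligned partner in B: identical -> conserved, same
    physicochemical class -> similar, different class -> nonconserved,
    aligned to a gap -> unaligned.  Fractions are over ``|residues_a|``
    and sum to 1.
    """
    if not residues_a:
        raise ValueError("residues_a is empty; fractions undefined")
    classes = classes or SimilarityClasses()
    seq_a = aln.gapped_a.replace("-", "")
    seq_b = aln.gapped_b.replace("-", "")
    counts = {"conserved": 0, "similar": 0, "nonconserved": 0, "unaligned": 0}
    for r in residues_a:
        if not (1 <= r <= len(seq_a)):
            raise ValueError(f"residue {r} outside sequence A (length {len(seq_a)})")
        partner = aln.column_map.get(r)
        if partner is None:
            counts["unaligned"] += 1
            continue
        ca, cb = seq_a[r - 1], seq_b[partner - 1]
        if ca == cb:
            counts["conserved"] += 1
        elif classes.same_class(ca, cb):
            counts["similar"] += 1
        else:
            counts["nonconserved"] += 1
    n = len(residues_a)
    return {
        "conserved_frac": counts["conserved"] / n,
        "similar_frac": counts["similar"] / n,
        "nonconserved_frac": counts["nonconserved"] / n,
        "unaligned_frac": counts["unaligned"] / n,
        "n_sites": n,
    }


@dataclass(frozen=True)
class SiteOverlap:
    """Three-way partition of two residue sets on a common numbering."""

    only_a: frozenset[int]
    only_b: frozenset[int]
    both: frozenset[int]


def overlap_classify(set_a: set[int], set_b: set[int]) -> SiteOverlap:
    """Partition two binding-site residue sets into exclusive/shared parts."""
    a, b = frozenset(set_a), frozenset(set_b)
    return SiteOverlap(only_a=a - b, only_b=b - a, both=a & b)


def map_sites_across_species(
    residues_a: set[int],
    aln: AlignmentResult,
) -> tuple[set[int], int]:
    """Image of a residue set in sequence-B numbering.

    Residues aligned to a gap cannot be mapped and are dropped; the count
    of dropped residues is returned alongside the mapped set.
    """
    mapped = {aln.column_map[r] for r in residues_a if r in aln.column_map}
    return mapped, len(residues_a) - len(mapped)
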