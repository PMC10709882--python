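"""One-to-one ortholog detection and codon-aware alignment.

Cross-species ortholog pairs are found by reciprocal best hit (RBH) over
global protein alignments (Needleman-Wunsch with affine gaps, BLOSUM62 by
default): two genes pair iff each is the other's highest-scoring match and
the alignment clears identity and coverage floors.  Each protein alignment
is then back-threaded onto its source CDS pair; columns with a gap (or an
ambiguous codon) on either side are dropped, yielding the gap-free in-frame
codon alignment Ka/Ks estimation requires.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .cds_io import CdsRecord, translate
from .genetics import codons_of

__all__ = [
    "ProteinAlignment",
    "OrthologPair",
    "AlignmentTooShortError",
    "make_aligner",
    "align_proteins",
    "rbh_pairs",
    "thread_codon_alignment",
    "pair_from_identical_frames",
]

MIN_PAIR_CODONS = 30  # variance floor for downstream Ka/Ks


class AlignmentTooShortError(ValueError):
    """Fewer gap-free codon columns than the Ka/Ks floor allows."""


@dataclass
class ProteinAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


@dataclass
class OrthologPair:
    """A one-to-one cross-species pair with its gap-free codon alignment."""

    species_a: str
    species_b: str
    gene_a: str
    gene_b: str
    codon_aln_a: str
    codon_aln_b: str
    n_codons: int

    def codons(self) -> tuple[list[str], list[str]]:
        return codons_of(self.codon_aln_a), codons_of(self.codon_aln_b)


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    """Global affine-gap protein aligner.

    A gap of length k scores -(gap_open + (k-1) * gap_extend).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _identity_coverage(aligned_a: str, aligned_b: str, len_a: int, len_b: int):
    paired = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    identity = matches / paired if paired else 0.0
    coverage = paired / max(len_a, len_b)
    return identity, coverage


def align_proteins(
    a: str,
    b: str,
    id_a: str = "a",
    id_b: str = "b",
    aligner: Align.PairwiseAligner | None = None,
) -> ProteinAlignment:
    """Optimal global alignment of two proteins; the aligner's first
    traceback is taken, which is deterministic for fixed inputs."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    identity, _ = _identity_coverage(aligned_a, aligned_b, len(a), len(b))
    return ProteinAlignment(
        id_a, id_b, aligned_a, aligned_b, float(alignment.score), identity
    )


def thread_codon_alignment(
    pa: ProteinAlignment,
    cds_a: CdsRecord,
    cds_b: CdsRecord,
    min_codons: int = MIN_PAIR_CODONS,
) -> OrthologPair:
    """Expand each aligned residue column to its source codon; columns with
    a gap or an N-containing codon on either side are dropped."""
    prot_a = translate(cds_a)
    prot_b = translate(cds_b)
    if pa.aligned_a.replace("-", "") != prot_a:
        raise ValueError(f"{cds_a.gene_id}: aligned protein != translation")
    if pa.aligned_b.replace("-", "") != prot_b:
        raise ValueError(f"{cds_b.gene_id}: aligned protein != translation")
    cod_a = codons_of(cds_a.seq)[: len(prot_a)]
    cod_b = codons_of(cds_b.seq)[: len(prot_b)]
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for x, y in zip(pa.aligned_a, pa.aligned_b):
        ca = cod_a[i] if x != "-" else None
        cb = cod_b[j] if y != "-" else None
        if x != "-":
            i += 1
        if y != "-":
            j += 1
        if ca is None or cb is None or "N" in ca or "N" in cb:
            continue
        out_a.append(ca)
        out_b.append(cb)
    if len(out_a) < min_codons:
        raise AlignmentTooShortError(
            f"TOO_SHORT_ALIGNMENT: {cds_a.gene_id}/{cds_b.gene_id} "
            f"({len(out_a)} < {min_codons} codons)"
        )
    return OrthologPair(
        cds_a.species,
        cds_b.species,
        cds_a.gene_id,
        cds_b.gene_id,
        "".join(out_a),
        "".join(out_b),
        len(out_a),
    )


def pair_from_identical_frames(cds_a: CdsRecord, cds_b: CdsRecord) -> OrthologPair:
    """Build an OrthologPair from two equal-length, indel-free CDS (the
    simulator's output) without running an aligner."""
    a = codons_of(cds_a.seq)
    b = codons_of(cds_b.seq)
    if len(a) != len(b):
        raise ValueError("CDS lengths differ")
    from .genetics import STOP_CODONS

    if a and a[-1] in STOP_CODONS:
        a = a[:-1]
    if b and b[-1] in STOP_CODONS:
        b = b[:-1]
    keep = [
        (ca, cb)
        for ca, cb in zip(a, b)
        if "N" not in ca and "N" not in cb
    ]
    return OrthologPair(
        cds_a.species,
        cds_b.species,
        cds_a.gene_id,
        cds_b.gene_id,
        "".join(c for c, _ in keep),
        "".join(c for _, c in keep),
        len(keep),
    )


def _best_hit(
    scores: dict[tuple[str, str], float], query: str, targets: list[str]
) -> str | None:
    """Highest-scoring target; ties by lexicographically smaller id."""
    best: str | None = None
    best_score = -float("inf")
    for t in targets:
        s = scores[(query, t)]
        if s > best_score or (s == best_score and (best is None or t < best)):
            best, best_score = t, s
    return best


def rbh_pairs(
    species_a: list[CdsRecord],
    species_b: list[CdsRecord],
    min_identity: float = 0.3,
    min_coverage: float = 0.5,
    min_score_per_residue: float = 0.25,
    min_codons: int = MIN_PAIR_CODONS,
    aligner: Align.PairwiseAligner | None = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit one-to-one pairs with codon alignments.

    Best hits are determined by global alignment score (score-only pass
    for speed); a candidate pair is kept iff it is mutually best and its
    alignment clears the identity/coverage floors, a length-normalised
    score floor (score / shorter protein length — the desk-scale
    analogue of an E-value cutoff: optimal alignments of unrelated
    same-composition proteins score near zero per residue, genuinely
    homologous ones score well above it), and the codon-column floor.
    The score matrix is symmetric, so swapping the species arguments
    yields the same pair set.
    """
    if not species_a or not species_b:
        raise ValueError("empty species set")
    if aligner is None:
        aligner = make_aligner()
    prot_a = {r.gene_id: translate(r) for r in species_a}
    prot_b = {r.gene_id: translate(r) for r in species_b}
    rec_a = {r.gene_id: r for r in species_a}
    rec_b = {r.gene_id: r for r in species_b}
    ids_a = sorted(prot_a)
    ids_b = sorted(prot_b)
    scores: dict[tuple[str, str], float] = {}
    for ga in ids_a:
        for gb in ids_b:
            scores[(ga, gb)] = float(aligner.score(prot_a[ga], prot_b[gb]))

    best_ab = {ga: _best_hit(scores, ga, ids_b) for ga in ids_a}
    scores_ba = {(gb, ga): s for (ga, gb), s in scores.items()}
    best_ba = {gb: _best_hit(scores_ba, gb, ids_a) for gb in ids_b}

    pairs: list[OrthologPair] = []
    for ga in ids_a:
        gb = best_ab[ga]
        if gb is None or best_ba[gb] != ga:
            continue
        pa = align_proteins(prot_a[ga], prot_b[gb], ga, gb, aligner)
        identity, coverage = _identity_coverage(
            pa.aligned_a, pa.aligned_b, len(prot_a[ga]), len(prot_b[gb])
        )
        per_residue = pa.score / min(len(prot_a[ga]), len(prot_b[gb]))
        if (
            identity < min_identity
            or coverage < min_coverage
            or per_residue < min_score_per_residue
        ):
            continue
        try:
            pairs.append(
                thread_codon_alignment(pa, rec_a[ga], rec_b[gb], min_codons)
            )
        except AlignmentTooShortError:
            continue
    return pairs
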