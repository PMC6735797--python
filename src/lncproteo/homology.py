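"""Toy-scale evolutionary-origin analysis of new proteins.

Homology between a query protein and a subject is operationalized as the
identity-times-coverage percentage of the best local alignment: identical
aligned residues divided by the *query* length, x100.  A protein's
phylostratum is the oldest clade (over user-supplied, oldest-to-youngest
ordered proteome sets) containing a subject with homology above the
threshold (default 10%).  Origin classes are assigned with fixed
precedence: splice variant of a known coding gene (exon overlap, same
strand) > homologous copy of a known protein > microbial homolog >
unknown.  Exon counting backs the single-exon-fraction statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .io import Transcript


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


def homology_percent(query_protein: str, subject_protein: str,
                     min_score: float = 70.0) -> float:
    """Identities in the best local alignment / query length x 100.

    The query-length denominator folds identity and query coverage into
    one number, so a query fully contained in a longer subject scores 100
    while a short perfect match on a long query scores low.  Alignments
    below ``min_score`` (BLOSUM62, gap open -11 / extend -1) are treated
    as no hit and give 0: the default of 70 sits well above the optimal
    local-alignment scores of unrelated random proteins (< ~60 for
    queries up to a few hundred residues) while genuine homologs, even at
    40% identity, score in the hundreds — the score gate plays the role
    of an E-value cutoff in a BLAST-style search.
    """
    if not query_protein or not subject_protein:
        raise ValueError("both proteins must be non-empty")
    try:
        alignments = _ALIGNER.align(query_protein, subject_protein)
        if len(alignments) == 0 or alignments.score < min_score:
            return 0.0
        aln = alignments[0]
    except OverflowError:  # astronomically many co-optimal alignments
        aln = next(iter(_ALIGNER.align(query_protein, subject_protein)))
    identities = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        identities += sum(
            1 for a, b in zip(query_protein[qs:qe], subject_protein[ss:se]) if a == b
        )
    return 100.0 * identities / len(query_protein)


@dataclass
class PhylostratumResult:
    """Per-clade best homology of one protein and its inferred stratum."""

    protein_id: str
    clade_percents: dict[str, float] = field(default_factory=dict)
    oldest_clade_with_hit: str | None = None


def assign_phylostratum(
    protein: str,
    clade_proteomes: list[tuple[str, list[str]]],
    min_pct: float = 10.0,
    protein_id: str = "query",
) -> PhylostratumResult:
    """Oldest clade whose proteome contains a homolog above ``min_pct``.

    ``clade_proteomes`` is ordered oldest -> youngest.  A protein hitting
    nothing has stratum None (it emerged in the query's own clade).
    """
    if not clade_proteomes:
        raise ValueError("clade proteome sets must be non-empty")
    percents: dict[str, float] = {}
    oldest: str | None = None
    for clade, proteome in clade_proteomes:
        best = max((homology_percent(protein, subj) for subj in proteome), default=0.0)
        percents[clade] = best
        if oldest is None and best >= min_pct:
            oldest = clade
    return PhylostratumResult(protein_id, percents, oldest)


ORIGIN_CLASSES = ("splice_variant", "homologous_copy", "microbial", "unknown")


def _loci_overlap(a: Transcript, b: Transcript) -> bool:
    a_exons = a.exons or []
    b_exons = b.exons or []
    if not a_exons or not b_exons:
        raise ValueError("overlap check requested without genomic coordinates")
    if a.chromosome != b.chromosome or a.strand != b.strand:
        return False
    for s1, e1 in a_exons:
        for s2, e2 in b_exons:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def classify_origin(
    new_protein: str,
    gene_model: Transcript,
    known_coding_models: list[Transcript],
    known_proteome: list[str],
    microbial_proteome: list[str],
    homology_threshold: float = 30.0,
) -> str:
    """Assign the evolutionary origin class of one new protein.

    Precedence: exon overlap with a known coding gene on the same strand
    -> splice_variant; else best homology against the known proteome >=
    threshold -> homologous_copy; else best microbial hit >= threshold ->
    microbial; else unknown.
    """
    for model in known_coding_models:
        if _loci_overlap(gene_model, model):
            return "splice_variant"
    if known_proteome:
        best = max(homology_percent(new_protein, p) for p in known_proteome)
        if best >= homology_threshold:
            return "homologous_copy"
    if microbial_proteome:
        best = max(homology_percent(new_protein, p) for p in microbial_proteome)
        if best >= homology_threshold:
            return "microbial"
    return "unknown"


def exon_count(transcript_model: Transcript) -> int:
    """Number of exon features of a gene model (1 when none are recorded)."""
    return transcript_model.n_exons


def single_exon_fraction(models: list[Transcript]) -> float:
    """Fraction of gene models with exactly one exon."""
    if not models:
        raise ValueError("empty model set")
    return sum(1 for m in models if exon_count(m) == 1) / len(models)
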