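"""Canonical ORF prediction on spliced transcripts.

A canonical ORF starts at an AUG, runs in frame to the first stop codon,
and must encode a protein of at least ``min_protein_aa`` residues
(initiator Met counted, stop excluded; i.e. coding length >= 3 *
(min_protein_aa + 1) nt including the stop).  Only the three forward
frames are scanned: transcripts are already stranded, so the antisense
frames are biologically meaningless here.

By default one ORF is reported per (frame, stop codon): the 5'-most AUG
defines it, and internal AUGs are suppressed so the search database is not
flooded with nested fragments of the same protein.  ``all_starts=True``
reports every AUG instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .io import Transcript, normalize_sequence

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

START_CODON = "ATG"
STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA


def translate(nt_seq: str) -> str:
    """Translate a DNA/RNA sequence with the standard genetic code.

    The length must be a multiple of three.  Any codon containing an N is
    rendered 'X'; stop codons are rendered '*'.
    """
    seq = normalize_sequence(nt_seq)
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            aas.append("X")
        else:
            try:
                aas.append(CODON_TO_AA[codon])
            except KeyError:
                raise ValueError(f"invalid codon {codon!r} at position {i}")
    return "".join(aas)


@dataclass
class OrfCandidate:
    """An AUG-initiated ORF on a transcript, with its translated protein.

    ``start_nt`` is the 0-based transcript offset of the A of the AUG;
    ``end_nt`` is one past the stop codon, so (end - start) is a multiple
    of 3 and the protein length is (end - start) / 3 - 1.
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    protein: str
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if (self.end_nt - self.start_nt) % 3 != 0:
            raise ValueError("ORF span not a multiple of 3")
        expected = (self.end_nt - self.start_nt) // 3 - 1
        if len(self.protein) != expected:
            raise ValueError(f"protein length {len(self.protein)} != expected {expected}")
        if "*" in self.protein:
            raise ValueError("protein contains a stop symbol")

    @property
    def accession(self) -> str:
        """Stable database accession: transcriptID|frame|start-end."""
        return f"{self.transcript_id}|{self.frame}|{self.start_nt}-{self.end_nt}"


def find_orfs(
    transcript: Transcript | str,
    min_protein_aa: int = 50,
    all_starts: bool = False,
    transcript_id: str | None = None,
) -> list[OrfCandidate]:
    """Scan the three forward frames for canonical ORFs.

    An ORF requires an in-frame stop within the transcript (run-off ORFs
    are unverifiable and excluded).  Qualifying ORFs are returned sorted by
    protein length descending, ties broken by the 5'-most start.
    """
    if isinstance(transcript, Transcript):
        seq = transcript.sequence
        tid = transcript.transcript_id
    else:
        seq = normalize_sequence(transcript)
        tid = transcript_id or "seq"
    if not seq:
        return []
    orfs: list[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        pending_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                starts = pending_starts if all_starts else pending_starts[:1]
                for start in starts:
                    end = pos + 3
                    protein = translate(seq[start:pos])
                    if len(protein) >= min_protein_aa:
                        orfs.append(OrfCandidate(tid, frame, start, end, protein))
                pending_starts = []
            elif codon == START_CODON:
                pending_starts.append(pos)
        # AUGs after the last stop never reach a stop codon: dropped.
    orfs.sort(key=lambda o: (-len(o.protein), o.start_nt, o.frame))
    return orfs


def canonical_orf(orfs: list[OrfCandidate]) -> OrfCandidate | None:
    """The longest qualifying ORF of one transcript (ties: 5'-most, lowest frame)."""
    if not orfs:
        return None
    best = min(orfs, key=lambda o: (-len(o.protein), o.start_nt, o.frame))
    best.is_canonical = True
    return best


@dataclass
class ProteomeEntry:
    """A deduplicated ORF protein with the ORFs that encode it."""

    protein: str
    orfs: list[OrfCandidate] = field(default_factory=list)

    @property
    def accession(self) -> str:
        return self.orfs[0].accession


def three_frame_proteome(
    transcripts: list[Transcript],
    min_protein_aa: int = 50,
    all_starts: bool = False,
) -> list[ProteomeEntry]:
    """All qualifying ORF proteins across transcripts, deduplicated by sequence.

    Provenance (every ORF encoding the protein) is retained on each entry.
    """
    by_protein: dict[str, ProteomeEntry] = {}
    for t in transcripts:
        for orf in find_orfs(t, min_protein_aa=min_protein_aa, all_starts=all_starts):
            entry = by_protein.get(orf.protein)
            if entry is None:
                by_protein[orf.protein] = ProteomeEntry(orf.protein, [orf])
            else:
                entry.orfs.append(orf)
    return list(by_protein.values())
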