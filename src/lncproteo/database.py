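"""Cell-specific protein reference databases.

The search database for one cell line contains (i) the known proteins of
all genes called translating from the RNC library of that cell line and
(ii) the predicted canonical-ORF proteins (>= 50 aa) of its translating
lncRNAs.  A low-molecular-weight subset (< 25 kDa average mass, strict)
mirrors the gel-based small-protein fraction.  Construction is a pure
function of its inputs, so identical inputs yield byte-identical FASTA.

Deduplication is by exact protein string; I and L are NOT collapsed here
(that happens only in peptide uniqueness logic), keeping the database
faithful to its source sequences.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

from .orfs import ProteomeEntry
from .properties import molecular_weight

logger = logging.getLogger("lncproteo")

SOURCES = ("known_translating", "lncrna_orf")


@dataclass(frozen=True)
class DbEntry:
    accession: str
    source: str  # known_translating | lncrna_orf
    sequence: str
    gene_id: str = ""
    pe_status: str = "none"


@dataclass
class ReferenceDatabase:
    """A search database with provenance of its construction."""

    entries: list[DbEntry]
    provenance: dict = field(default_factory=dict)
    # accessions merged away by exact-sequence deduplication
    duplicates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(accs) != len(set(accs)):
            raise ValueError("accessions must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def by_accession(self, accession: str) -> DbEntry:
        for e in self.entries:
            if e.accession == accession:
                return e
        raise KeyError(accession)

    def to_fasta_records(self) -> list[tuple[str, str, str]]:
        return [(e.accession, e.source, e.sequence) for e in self.entries]


def _digest(items: list[str]) -> str:
    h = hashlib.sha256()
    for item in items:
        h.update(item.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def build_reference_db(
    translating_gene_ids: set[str],
    known_proteins: list[DbEntry],
    lncrna_orf_proteins: list[ProteomeEntry],
    min_protein_aa: int = 50,
    orf_gene_ids: dict[str, str] | None = None,
) -> ReferenceDatabase:
    """Assemble the cell-specific reference database.

    ``known_proteins`` carry gene links and PE status; only those whose
    gene is in ``translating_gene_ids`` are included.  ORF proteins below
    the length rule are rejected (logged).  Exact duplicate sequences are
    merged, first accession wins, merged accessions recorded.
    """
    entries: list[DbEntry] = []
    by_seq: dict[str, str] = {}
    duplicates: dict[str, list[str]] = {}

    def _add(entry: DbEntry) -> None:
        kept = by_seq.get(entry.sequence)
        if kept is None:
            by_seq[entry.sequence] = entry.accession
            entries.append(entry)
        else:
            duplicates.setdefault(kept, []).append(entry.accession)

    n_known = 0
    for kp in known_proteins:
        if kp.gene_id in translating_gene_ids:
            _add(DbEntry(kp.accession, "known_translating", kp.sequence,
                         kp.gene_id, kp.pe_status))
            n_known += 1
    n_orf = 0
    for entry in lncrna_orf_proteins:
        if len(entry.protein) < min_protein_aa:
            logger.info("rejecting ORF %s: protein %d aa < %d",
                        entry.accession, len(entry.protein), min_protein_aa)
            continue
        orf = entry.orfs[0]
        gene = (orf_gene_ids or {}).get(orf.transcript_id, orf.transcript_id)
        if gene in translating_gene_ids or not translating_gene_ids:
            _add(DbEntry(entry.accession, "lncrna_orf", entry.protein, gene))
            n_orf += 1
    provenance = {
        "n_known_translating": n_known,
        "n_lncrna_orf": n_orf,
        "min_protein_aa": min_protein_aa,
        "input_digest": _digest(sorted(by_seq)),
    }
    return ReferenceDatabase(entries, provenance, duplicates)


def small_protein_subset(db: ReferenceDatabase, max_mw: float = 25000.0,
                         min_mw: float = 0.0) -> ReferenceDatabase:
    """Entries with average molecular mass strictly below ``max_mw`` Da.

    Mirrors the gel-based small-protein fraction; idempotent.  An optional
    lower bound (default 0) matches a band-range selection.
    """
    kept = [e for e in db.entries if min_mw <= molecular_weight(e.sequence) < max_mw]
    provenance = dict(db.provenance)
    provenance.update({"small_db_max_mw": max_mw, "small_db_min_mw": min_mw})
    return ReferenceDatabase(kept, provenance, dict(db.duplicates))


def classify_new_protein(
    accession: str,
    db: ReferenceDatabase,
    known_pe_sets: dict[str, str],
    known_pe_sequences: set[str] | None = None,
) -> str:
    """'new' iff the entry matches no PE1-5 protein by accession or sequence.

    ``known_pe_sets`` maps accession -> PE status (PE1..PE5);
    ``known_pe_sequences`` allows a sequence-level match to win even when
    the accession differs (an ORF identical to a PE2 protein is known).
    """
    entry = db.by_accession(accession)
    if accession in known_pe_sets:
        return "known"
    if known_pe_sequences and entry.sequence in known_pe_sequences:
        return "known"
    return "new"
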