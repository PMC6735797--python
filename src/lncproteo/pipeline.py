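"""End-to-end orchestration of the discovery chain.

``run_discovery`` strings the stages together the way a real analysis
runs them: call translating genes from the RNC library, predict ORFs on
the translating lncRNAs, build the cell-specific reference database,
adjudicate the peptide list (uniqueness, length, alignment filter) and
emit new-protein calls.  ``score_against_truth`` compares the calls with
a generator truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .database import ReferenceDatabase, build_reference_db
from .expression import is_true_expression
from .io import ExpressionRecord, Transcript
from .orfs import three_frame_proteome
from .peptides import (
    EquivalenceTable,
    NewProteinCall,
    PeptideEvidence,
    assign_peptides,
    sw_uniqueness_filter,
    validate_new_proteins,
)


@dataclass
class DiscoveryResult:
    translating_gene_ids: set[str]
    database: ReferenceDatabase
    evidences: list[PeptideEvidence]
    calls: list[NewProteinCall]
    called_proteins: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.called_proteins = {c.sequence for c in self.calls}


def call_translating_genes(
    records: list[ExpressionRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    library: str = "RNC",
) -> set[str]:
    """Genes truly expressed in the given (default RNC) library of any sample."""
    return {
        r.gene_id for r in records
        if r.library == library and is_true_expression(r, config)
    }


def run_discovery(
    transcripts: list[Transcript],
    known_proteins,  # list[DbEntry]
    expression_records: list[ExpressionRecord],
    peptide_list: list[str],
    config: PipelineConfig = DEFAULT_CONFIG,
    equivalences: EquivalenceTable | None = None,
    apply_sw_filter: bool = True,
    extra_background: list[tuple[str, str]] | None = None,
) -> DiscoveryResult:
    """Run the full discovery chain on in-memory inputs.

    ``apply_sw_filter=False`` disables the alignment-distance filter (for
    ablation only); length and uniqueness rules still apply.
    """
    translating = call_translating_genes(expression_records, config)
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    lnc_translating = [
        t for t in transcripts
        if t.biotype == "lncRNA" and t.gene_id in translating
    ]
    orf_proteome = three_frame_proteome(lnc_translating, config.min_protein_aa)
    db = build_reference_db(
        translating, known_proteins, orf_proteome,
        min_protein_aa=config.min_protein_aa, orf_gene_ids=gene_of,
    )
    evidences = assign_peptides(peptide_list, db)
    background: list[tuple[str, str]] = [(kp.accession, kp.sequence) for kp in known_proteins]
    background += [(e.accession, e.protein) for e in orf_proteome]
    if extra_background:
        background += extra_background
    if apply_sw_filter:
        evidences = sw_uniqueness_filter(evidences, background, db, config, equivalences)
    else:
        for ev in evidences:
            if ev.is_unique:
                if len(ev.sequence) < config.min_peptide_len:
                    ev.passes_length = False
                    ev.verdict = "rejected_short"
                else:
                    ev.verdict = "accepted_unique"
    known_pe = {kp.accession: kp.pe_status for kp in known_proteins}
    known_seqs = {kp.sequence for kp in known_proteins}
    calls = validate_new_proteins(evidences, db, known_pe, known_seqs)
    return DiscoveryResult(translating, db, evidences, calls)


def score_against_truth(result: DiscoveryResult, truth: pd.DataFrame) -> dict:
    """Sensitivity and false-call count of a run against the truth table.

    Truth positives are the proteins of rows with ``truth_role ==
    'planted'``; any called protein outside that set is a false call.
    """
    planted = set(truth.loc[truth["truth_role"] == "planted", "truth_protein"])
    called = result.called_proteins
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "true_positives": tp,
        "false_calls": len(called - planted),
        "sensitivity": sensitivity,
    }
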