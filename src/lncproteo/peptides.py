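"""Peptide-evidence adjudication for new-protein discovery.

A candidate protein is accepted as a detected lncRNA-encoded "new
protein" only on the strength of its peptides:

* a peptide is *unique* when, with isoleucine and leucine treated as the
  same residue, it occurs in exactly one database entry (entries identical
  under I/L collapse count as one);
* a *supportive* peptide is a non-unique peptide assigned to a protein
  identification;
* every candidate unique peptide must additionally be at least 9 residues
  long and differ from every other protein in a large background
  collection (known proteome + three-frame ORF translations + curated
  proteins) by at least two mismatches/indels.  The distance is the
  minimum, over all placements of the full peptide against any region of
  a background protein, of substitutions + insertions + deletions, with
  residues from a configurable equivalence table (I=L always; N=D and Q=E
  by default, the canonical PTM-mass confusions) counting as matches.
  This semi-global edit distance operationalizes the best-region search a
  scored Smith-Waterman would perform, without arbitrary match/gap scores.

Targeted-MS (MRM/PRM) verification of a precursor requires co-elution of
the light and heavy transitions, at least three transitions with S/N > 3,
and every transition-pair light/heavy ratio within 20% of the precursor's
reference ratio.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .database import ReferenceDatabase
from .properties import STANDARD_AA

VERDICTS = ("accepted_unique", "rejected_similar", "rejected_short", "supportive",
            "unassigned", "rejected_nonstandard")


# ---------------------------------------------------------------------------
# residue equivalence

class EquivalenceTable:
    """Symmetric residue pairs treated as identical during alignment.

    Pairs chain transitively (union-find), so {A=B, B=C} makes A, B and C
    one class.  The default table is {I=L} plus the deamidation mass
    confusions {N=D, Q=E}.
    """

    def __init__(self, pairs: list[tuple[str, str]] | None = None):
        if pairs is None:
            pairs = [("I", "L"), ("N", "D"), ("Q", "E")]
        self._parent: dict[str, str] = {}
        for a, b in pairs:
            if a == b:
                raise ValueError(f"irreflexive pairs only, got ({a}, {b})")
            self._union(a, b)
        self.pairs = list(pairs)

    def _find(self, x: str) -> str:
        self._parent.setdefault(x, x)
        while self._parent[x] != x:
            self._parent[x] = self._parent[self._parent[x]]
            x = self._parent[x]
        return x

    def _union(self, a: str, b: str) -> None:
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((ra, rb))
            self._parent[hi] = lo

    def canonical(self, residue: str) -> str:
        return self._find(residue)

    def collapse(self, seq: str) -> str:
        """Map every residue of ``seq`` to its class representative."""
        return "".join(self._find(aa) for aa in seq)

    def equivalent(self, a: str, b: str) -> bool:
        return a == b or self._find(a) == self._find(b)


IL_ONLY = EquivalenceTable([("I", "L")])
DEFAULT_EQUIVALENCES = EquivalenceTable()


def collapse_il(seq: str) -> str:
    """Collapse I/L only — the rule used for substring-based assignment."""
    return seq.replace("L", "I")


# ---------------------------------------------------------------------------
# semi-global edit distance (peptide global, protein local)

def min_alignment_diffs(
    peptide: str,
    protein: str,
    equivalences: EquivalenceTable | None = None,
) -> int:
    """Minimum mismatches + indels aligning the full peptide to any protein region.

    Semi-global dynamic programming: the peptide is aligned end-to-end,
    the protein contributes a free-floating region (leading/trailing
    protein residues are free).  Equivalence-table pairs count as exact
    matches.  Against an empty protein the answer is the peptide length
    (all insertions).
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    if equivalences is None:
        equivalences = DEFAULT_EQUIVALENCES
    pep = equivalences.collapse(peptide)
    prot = equivalences.collapse(protein)
    m, n = len(pep), len(prot)
    if n == 0:
        return m
    pep_arr = np.frombuffer(pep.encode("ascii"), dtype=np.uint8)
    prot_arr = np.frombuffer(prot.encode("ascii"), dtype=np.uint8)
    offsets = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)  # free leading protein residues
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        sub = prev[:-1] + (prot_arr != pep_arr[i - 1])
        delete = prev[1:] + 1
        cur[1:] = np.minimum(sub, delete)
        # insertion pass: cur[j] = min_{k<=j} cur[k] + (j-k), vectorized
        cur = np.minimum.accumulate(cur - offsets) + offsets
        prev = cur
    return int(prev.min())


def local_alignment_diffs(
    peptide: str,
    protein: str,
    equivalences: EquivalenceTable | None = None,
    match: int = 2,
    mismatch: int = -1,
    gap: int = -2,
) -> int:
    """Score-parameterized local-alignment variant of :func:`min_alignment_diffs`.

    Provided for comparison with the edit-count filter: runs a classic
    Smith-Waterman with simple match/mismatch/gap scores, then counts the
    mismatches + indels of the best local alignment plus the peptide
    residues it leaves unaligned.  Unlike the semi-global edit count, the
    result depends on the score parameters; the default filter does not
    use it.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    if equivalences is None:
        equivalences = DEFAULT_EQUIVALENCES
    pep = equivalences.collapse(peptide)
    prot = equivalences.collapse(protein)
    m, n = len(pep), len(prot)
    if n == 0:
        return m
    score = np.zeros((m + 1, n + 1), dtype=np.int32)
    # diffs[i][j]: mismatches+indels on the best-scoring path ending at (i, j),
    # plus peptide residues before the local start
    diffs = np.zeros((m + 1, n + 1), dtype=np.int32)
    diffs[:, 0] = np.arange(m + 1)
    best_val, best_diffs = 0, m
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            is_match = pep[i - 1] == prot[j - 1]
            cand = (
                (score[i - 1, j - 1] + (match if is_match else mismatch),
                 diffs[i - 1, j - 1] + (0 if is_match else 1)),
                (score[i - 1, j] + gap, diffs[i - 1, j] + 1),
                (score[i, j - 1] + gap, diffs[i, j - 1] + 1),
                (0, i),  # restart: unaligned peptide prefix counts as diffs
            )
            score[i, j], diffs[i, j] = max(cand, key=lambda t: (t[0], -t[1]))
            total = diffs[i, j] + (m - i)  # unaligned peptide suffix
            if (score[i, j], -total) > (best_val, -best_diffs):
                best_val, best_diffs = score[i, j], total
    return int(best_diffs)


# ---------------------------------------------------------------------------
# peptide evidence

@dataclass
class PeptideEvidence:
    """An identified peptide with its assignments and adjudication state."""

    sequence: str
    assigned_accessions: list[str] = field(default_factory=list)
    is_unique: bool = False
    passes_length: bool = True
    min_diffs: int | None = None
    verdict: str = "unassigned"

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def assign_peptides(peptides: list[str], db: ReferenceDatabase) -> list[PeptideEvidence]:
    """Assign each peptide to the database entries containing it.

    Matching is exact-substring with I/L collapsed.  A peptide is unique
    when it matches exactly one entry after grouping entries identical
    under I/L; matching several is supportive (non-unique); matching none
    leaves it unassigned.  Peptides with non-standard residues are
    rejected with a reason.
    """
    collapsed_entries = [(e.accession, collapse_il(e.sequence)) for e in db.entries]
    evidences: list[PeptideEvidence] = []
    for pep in peptides:
        if set(pep) - STANDARD_AA:
            evidences.append(PeptideEvidence(pep, verdict="rejected_nonstandard"))
            continue
        cpep = collapse_il(pep)
        hits = [acc for acc, cseq in collapsed_entries if cpep in cseq]
        groups = {cseq for acc, cseq in collapsed_entries if acc in set(hits)}
        ev = PeptideEvidence(pep, assigned_accessions=hits)
        if len(groups) == 1:
            ev.is_unique = True
        elif len(groups) > 1:
            ev.verdict = "supportive"
        evidences.append(ev)
    return evidences


def sw_uniqueness_filter(
    candidates: list[PeptideEvidence],
    background: list[tuple[str, str]],
    db: ReferenceDatabase,
    config: PipelineConfig = DEFAULT_CONFIG,
    equivalences: EquivalenceTable | None = None,
) -> list[PeptideEvidence]:
    """Adjudicate candidate unique peptides against a background collection.

    ``background`` is (id, protein) pairs: known proteome + three-frame
    ORF translations + curated proteins.  A candidate is accepted when it
    is at least ``min_peptide_len`` residues and its minimum alignment
    distance to every background protein *other than its own source*
    (entries identical to an assigned entry under I/L are the source) is
    at least ``min_alignment_diffs``.  Non-unique candidates pass through
    with verdict 'supportive'.
    """
    if equivalences is None:
        equivalences = DEFAULT_EQUIVALENCES
    acc_to_collapsed = {e.accession: collapse_il(e.sequence) for e in db.entries}
    for ev in candidates:
        if ev.verdict in ("rejected_nonstandard",):
            continue
        if not ev.is_unique:
            if ev.assigned_accessions and ev.verdict != "supportive":
                ev.verdict = "supportive"
            continue
        if len(ev.sequence) < config.min_peptide_len:
            ev.passes_length = False
            ev.verdict = "rejected_short"
            continue
        own = {acc_to_collapsed[acc] for acc in ev.assigned_accessions
               if acc in acc_to_collapsed}
        min_diffs: int | None = None
        for bg_id, bg_seq in background:
            if collapse_il(bg_seq) in own:
                continue
            d = min_alignment_diffs(ev.sequence, bg_seq, equivalences)
            if min_diffs is None or d < min_diffs:
                min_diffs = d
                if min_diffs == 0:
                    break
        ev.min_diffs = min_diffs
        if min_diffs is not None and min_diffs < config.min_alignment_diffs:
            ev.verdict = "rejected_similar"
        else:
            ev.verdict = "accepted_unique"
    return candidates


def evidence_tier(n_accepted_unique: int, n_supportive: int) -> str:
    """Evidence tier of a protein from its adjudicated peptide counts."""
    if n_accepted_unique >= 2:
        return "two_plus_unique"
    if n_accepted_unique == 1 and n_supportive >= 1:
        return "one_unique_plus_supportive"
    if n_accepted_unique == 1:
        return "one_unique_only"
    return "insufficient"


@dataclass
class NewProteinCall:
    """A called lncRNA-encoded protein with its evidence."""

    accession: str
    sequence: str
    tier: str
    unique_peptides: list[str]
    supportive_peptides: list[str]


def validate_new_proteins(
    evidences: list[PeptideEvidence],
    db: ReferenceDatabase,
    known_pe_sets: dict[str, str],
    known_pe_sequences: set[str] | None = None,
) -> list[NewProteinCall]:
    """Compose the end-to-end rule: calls are new-classified entries with
    at least one accepted unique peptide; each call carries its tier and
    peptide provenance."""
    from .database import classify_new_protein

    unique_by_acc: dict[str, list[str]] = defaultdict(list)
    supportive_by_acc: dict[str, list[str]] = defaultdict(list)
    for ev in evidences:
        if ev.verdict == "accepted_unique":
            for acc in ev.assigned_accessions:
                unique_by_acc[acc].append(ev.sequence)
        elif ev.verdict == "supportive":
            for acc in ev.assigned_accessions:
                supportive_by_acc[acc].append(ev.sequence)
    calls: list[NewProteinCall] = []
    for acc, uniques in sorted(unique_by_acc.items()):
        if classify_new_protein(acc, db, known_pe_sets, known_pe_sequences) != "new":
            continue
        supp = supportive_by_acc.get(acc, [])
        calls.append(
            NewProteinCall(
                accession=acc,
                sequence=db.by_accession(acc).sequence,
                tier=evidence_tier(len(uniques), len(supp)),
                unique_peptides=sorted(uniques),
                supportive_peptides=sorted(supp),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# targeted-MS verification

@dataclass(frozen=True)
class TransitionMeasurement:
    """One light/heavy transition pair of a monitored precursor."""

    precursor_id: str
    fragment_id: str
    light_area: float
    heavy_area: float
    light_sn: float
    coelutes: bool

    def __post_init__(self) -> None:
        if self.light_area < 0 or self.heavy_area < 0 or self.light_sn < 0:
            raise ValueError("areas and S/N must be non-negative")


def check_targeted_verification(
    measurements: list[TransitionMeasurement],
    min_transitions: int = 3,
    min_sn: float = 3.0,
    max_ratio_deviation: float = 0.20,
) -> tuple[str, list[str]]:
    """Apply the three targeted-MS verification criteria to one precursor.

    (a) every counted (S/N-qualifying) transition pair must co-elute;
    (b) at least ``min_transitions`` transitions with light S/N > ``min_sn``;
    (c) each pair's light/heavy ratio must deviate from the precursor's
    reference ratio (the median across its qualifying pairs) by strictly
    less than ``max_ratio_deviation``; a pair with zero heavy area fails.

    Returns ('verified' | 'not_verified', list of failed-criterion reasons).
    """
    if not measurements:
        raise ValueError("at least one measurement required")
    ids = {m.precursor_id for m in measurements}
    if len(ids) > 1:
        raise ValueError(f"measurements span precursors {sorted(ids)}")
    reasons: list[str] = []
    qualifying = [m for m in measurements if m.light_sn > min_sn]
    if len(qualifying) < min_transitions:
        reasons.append(
            f"(b) only {len(qualifying)} transitions with S/N > {min_sn}, "
            f"need {min_transitions}"
        )
    not_coeluting = [m.fragment_id for m in qualifying if not m.coelutes]
    if not_coeluting:
        reasons.append(f"(a) transitions not co-eluting: {sorted(not_coeluting)}")
    zero_heavy = [m.fragment_id for m in qualifying if m.heavy_area == 0]
    if zero_heavy:
        reasons.append(f"(c) zero heavy area on pairs: {sorted(zero_heavy)}")
    ratios = {m.fragment_id: m.light_area / m.heavy_area
              for m in qualifying if m.heavy_area > 0}
    if ratios:
        reference = float(np.median(list(ratios.values())))
        if reference > 0:
            deviant = [fid for fid, r in sorted(ratios.items())
                       if abs(r - reference) / reference >= max_ratio_deviation]
            if deviant:
                reasons.append(
                    f"(c) light/heavy ratio deviation >= "
                    f"{max_ratio_deviation:.0%} on pairs: {deviant}"
                )
    return ("verified" if not reasons else "not_verified", reasons)
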