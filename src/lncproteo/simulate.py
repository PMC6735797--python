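"""Synthetic benchmark data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the study design the discovery
chain was built for: a mixed transcriptome of protein-coding genes and
lncRNAs in which a configurable fraction of lncRNAs carries a planted
AUG-initiated ORF (>= 50 aa); paired overdispersed mRNA/RNC/RFP count
libraries with a controllable translation-ratio shift on a designated
gene subset; peptide identification lists mixing true unique peptides,
shared (supportive) peptides and near-miss contaminants within 0-1 edits
of known proteins; and light/heavy transition tables with controllable
signal-to-noise, ratio deviation and co-elution.

Every truth quantity needed to score a downstream stage is recorded in a
``truth_``-prefixed table, and a fixed seed yields bit-identical output
(all randomness flows through one integer-seeded numpy Generator).

Negative lncRNAs (no planted ORF) are rejection-sampled until they
contain no qualifying ORF at all, so a noise-free run has an exact,
deterministic answer.  Planted ORFs carry an in-frame stop codon
immediately 5' of their AUG, pinning the reported (5'-most-AUG) start to
the planted one.  Contaminant peptides are built by a single internal
substitution of a known tryptic peptide, avoiding K/R and residues
equivalent under the default alignment-equivalence table, so their true
edit distance to the known proteome is exactly 1; each contaminant is
embedded in a dedicated decoy lncRNA ORF so that, absent the alignment
filter, it would support a false new-protein call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import DbEntry
from .expression import compute_rpkm
from .io import ExpressionRecord, Transcript
from .orfs import CODON_TO_AA, OrfCandidate, find_orfs
from .peptides import DEFAULT_EQUIVALENCES
from .properties import tryptic_digest

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]

# codon choices per amino acid (deterministic ordering)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, []).append(_codon)
STOPS = ["TAA", "TAG", "TGA"]


@dataclass
class PeptideNoise:
    """Counts of non-true-positive peptides to emit."""

    n_shared: int = 0        # peptides present in a planted AND a known protein
    n_contaminant_d0: int = 0  # exact known-protein tryptic peptides
    n_contaminant_d1: int = 0  # 1-substitution variants embedded in decoy ORFs


@dataclass
class TargetedNoise:
    """Controls for the transition-table generator."""

    sn_range: tuple[float, float] = (4.0, 30.0)
    good_deviation: float = 0.05   # |relative ratio error| for clean pairs
    bad_deviation: float = 0.60    # planted failure-mode deviation
    frac_verified: float = 0.6
    n_transitions_range: tuple[int, int] = (3, 5)


@dataclass
class SimulationParams:
    """Study-scale knobs for the synthetic benchmark.

    Defaults are the desk-scale study conditions: 200 coding genes, 50
    lncRNAs of which 40% carry a planted ORF, 0.6-2 kb transcripts,
    one-million-read mRNA and RNC libraries with negative-binomial
    dispersion 0.3, a 4x translation-ratio shift on the designated
    high-TR subset, and 88% single-exon lncRNA gene models.
    """

    n_coding_genes: int = 200
    n_lncrnas: int = 50
    frac_lncrna_with_orf: float = 0.4
    transcript_length_range: tuple[int, int] = (600, 2000)
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 1_000_000, "RNC": 1_000_000, "RFP": 500_000}
    )
    dispersion: float = 0.3
    tr_shift: float = 4.0
    median_reads: float = 300.0
    min_protein_aa: int = 50
    frac_single_exon_lncrna: float = 0.88
    peptides_per_protein: int = 2
    peptide_noise: PeptideNoise = field(default_factory=PeptideNoise)
    targeted_ms_noise: TargetedNoise = field(default_factory=TargetedNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_lncrna_with_orf", "frac_single_exon_lncrna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_coding_genes", "n_lncrnas", "peptides_per_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.transcript_length_range
        # planted ORF needs guard stop + AUG...stop + minimal UTRs
        if self.min_protein_aa * 3 + 3 + 3 + 10 > hi:
            raise ValueError(
                f"transcript_length_range upper bound {hi} cannot hold a "
                f"{self.min_protein_aa}-aa ORF"
            )
        if lo < 100 or hi < lo:
            raise ValueError(f"invalid transcript_length_range ({lo}, {hi})")


# ---------------------------------------------------------------------------
# low-level helpers

def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT_ALPHABET[i] for i in rng.integers(0, 4, size=n))

def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def _encode_protein(rng: np.random.Generator, protein: str) -> str:
    codons = [AA_TO_CODONS[aa][rng.integers(0, len(AA_TO_CODONS[aa]))] for aa in protein]
    codons.append(STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _unique_tryptic_peptides(protein: str, lo: int = 9, hi: int = 30) -> list[str]:
    return [p for p in tryptic_digest(protein, 0) if lo <= len(p) <= hi]


def _plant_orf(rng: np.random.Generator, protein: str, total_len: int) -> tuple[str, int]:
    """Embed the coding sequence of ``protein`` in a transcript of
    ``total_len`` nt, with an in-frame guard stop immediately 5' of the AUG.
    Returns (transcript sequence, ORF start offset)."""
    cds = _encode_protein(rng, protein)
    flank = total_len - len(cds) - 3  # minus guard stop
    if flank < 10:
        raise ValueError("transcript too short for planted ORF")
    utr5_len = int(rng.integers(5, flank - 4))
    utr3_len = flank - utr5_len
    seq = _random_nt(rng, utr5_len) + "TAA" + cds + _random_nt(rng, utr3_len)
    return seq, utr5_len + 3


def _sample_exons(
    rng: np.random.Generator, transcript_len: int, n_exons: int, chrom_offset: int
) -> list[tuple[int, int]]:
    """Partition a transcript into exon intervals on a genomic axis."""
    if n_exons == 1:
        return [(chrom_offset + 1, chrom_offset + transcript_len)]
    cuts = np.sort(rng.choice(np.arange(1, transcript_len), size=n_exons - 1, replace=False))
    lengths = np.diff(np.concatenate([[0], cuts, [transcript_len]]))
    exons = []
    pos = chrom_offset
    for length in lengths:
        exons.append((pos + 1, pos + int(length)))
        pos += int(length) + int(rng.integers(100, 2000))  # intron
    return exons


def _mutate_peptide(rng: np.random.Generator, peptide: str) -> str | None:
    """One internal substitution avoiding K/R/P and equivalence partners."""
    internal = [i for i in range(1, len(peptide) - 1) if peptide[i] not in "KR"]
    if not internal:
        return None
    idx = internal[int(rng.integers(0, len(internal)))]
    orig = peptide[idx]
    choices = [
        aa for aa in AA_ALPHABET
        if aa != orig and aa not in "KRP"
        and not DEFAULT_EQUIVALENCES.equivalent(aa, orig)
    ]
    new = choices[int(rng.integers(0, len(choices)))]
    return peptide[:idx] + new + peptide[idx + 1:]


# ---------------------------------------------------------------------------
# transcriptome

@dataclass
class SimulatedTranscriptome:
    """A synthetic transcriptome plus all truth needed to score the pipeline."""

    transcripts: list[Transcript]
    known_proteins: list[DbEntry]
    truth: pd.DataFrame
    planted_orfs: list[OrfCandidate]
    shared_peptides: list[tuple[str, str]]  # (planted ORF accession, peptide)
    contaminants_d1: list[tuple[str, str, str]]  # (decoy accession, peptide, source acc)
    params: SimulationParams

    @property
    def lncrna_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.biotype == "lncRNA"]

    @property
    def coding_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.biotype == "coding"]

    def planted_proteins(self) -> set[str]:
        mask = self.truth["truth_role"] == "planted"
        return set(self.truth.loc[mask, "truth_protein"])

    def write(self, fasta_path, gtf_path, truth_path) -> None:
        from .io import write_fasta, write_gtf, write_tsv

        write_fasta(
            [(t.transcript_id, t.biotype, t.sequence) for t in self.transcripts],
            fasta_path,
        )
        write_gtf(self.transcripts, gtf_path)
        write_tsv(self.truth, truth_path)


def simulate_transcriptome(params: SimulationParams) -> SimulatedTranscriptome:
    """Generate the mixed transcriptome, known proteome and truth table.

    Coding genes each carry one canonical ORF whose protein becomes a PE1
    known protein.  ``frac_lncrna_with_orf`` of the lncRNAs carry a
    planted qualifying ORF (rejection-sampled to own at least two unique
    tryptic peptides of 9-30 aa); the remainder are rejection-sampled to
    contain no qualifying ORF at all.  Decoy lncRNAs carrying
    distance-1 contaminant regions are appended when
    ``peptide_noise.n_contaminant_d1`` > 0.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.transcript_length_range
    transcripts: list[Transcript] = []
    known_proteins: list[DbEntry] = []
    planted_orfs: list[OrfCandidate] = []
    truth_rows: list[dict] = []
    shared_peptides: list[tuple[str, str]] = []
    contaminants: list[tuple[str, str, str]] = []
    chrom_cursor = {c: int(r) for c, r in
                    zip(CHROMOSOMES, rng.integers(10_000, 50_000, size=len(CHROMOSOMES)))}

    def _place(tid: str, gid: str, seq: str, biotype: str, n_exons: int,
               pe_status: str = "none") -> Transcript:
        chrom = CHROMOSOMES[int(rng.integers(0, len(CHROMOSOMES)))]
        exons = _sample_exons(rng, len(seq), n_exons, chrom_cursor[chrom])
        chrom_cursor[chrom] = exons[-1][1] + int(rng.integers(5_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            exons = list(reversed(exons))
        return Transcript(tid, gid, chrom, strand, biotype, seq, exons, pe_status)

    # ---- coding genes -----------------------------------------------------
    coding_protein_pool: list[tuple[str, str]] = []  # (accession, protein)
    for i in range(params.n_coding_genes):
        tid, gid = f"t_cod{i:04d}", f"g_cod{i:04d}"
        tlen = int(rng.integers(max(lo, 800), hi + 1))
        max_plen = (tlen - 30) // 3 - 2
        plen = int(rng.integers(100, min(300, max_plen) + 1))
        protein = _random_protein(rng, plen)
        seq, orf_start = _plant_orf(rng, protein, tlen)
        n_exons = int(rng.integers(2, 13))
        transcripts.append(_place(tid, gid, seq, "coding", n_exons, "PE1"))
        acc = f"KP_{gid}"
        known_proteins.append(DbEntry(acc, "known_translating", protein, gid, "PE1"))
        coding_protein_pool.append((acc, protein))
        truth_rows.append(dict(
            transcript_id=tid, gene_id=gid, truth_biotype="coding",
            truth_role="coding", truth_has_orf=True, truth_orf_start=orf_start,
            truth_frame=orf_start % 3, truth_protein=protein,
            truth_n_exons=n_exons,
        ))

    # ---- lncRNAs ----------------------------------------------------------
    n_with_orf = int(round(params.frac_lncrna_with_orf * params.n_lncrnas))
    n_shared_left = params.peptide_noise.n_shared
    # exact allocation (not Bernoulli draws) so the planted single-exon
    # fraction is recovered exactly by downstream exon counting
    single_exon = np.zeros(params.n_lncrnas, dtype=bool)
    single_exon[: int(round(params.frac_single_exon_lncrna * params.n_lncrnas))] = True
    rng.shuffle(single_exon)
    for i in range(params.n_lncrnas):
        tid, gid = f"t_lnc{i:04d}", f"g_lnc{i:04d}"
        n_exons = 1 if single_exon[i] else int(rng.integers(2, 5))
        if i < n_with_orf:
            embed_shared = n_shared_left > 0 and coding_protein_pool
            for _attempt in range(500):
                tlen = int(rng.integers(max(lo, params.min_protein_aa * 3 + 60), hi + 1))
                max_plen = (tlen - 30) // 3 - 2
                plen_cap = min(3 * params.min_protein_aa, max_plen)
                shared_pep = None
                if embed_shared:
                    src_acc, src_prot = coding_protein_pool[
                        int(rng.integers(0, len(coding_protein_pool)))]
                    cands = [p for p in _unique_tryptic_peptides(src_prot, 9, 20)]
                    if not cands:
                        continue
                    shared_pep = cands[int(rng.integers(0, len(cands)))]
                    core = min(plen_cap, params.min_protein_aa + 30)
                    a = _random_protein(rng, max(15, core // 2))
                    b = "".join(AA_ALPHABET[k] for k in rng.integers(0, 20, size=max(15, core // 2)))
                    protein = a + "R" + shared_pep + b
                    if len(protein) > max_plen:
                        continue
                else:
                    plen = int(rng.integers(params.min_protein_aa, plen_cap + 1))
                    protein = _random_protein(rng, plen)
                uniq = [p for p in _unique_tryptic_peptides(protein)
                        if shared_pep is None or p != shared_pep]
                if len(uniq) < 2:
                    continue
                seq, orf_start = _plant_orf(rng, protein, tlen)
                break
            else:
                raise RuntimeError(f"could not plant a qualifying ORF for {tid}")
            transcripts.append(_place(tid, gid, seq, "lncRNA", n_exons))
            end = orf_start + 3 * (len(protein) + 1)
            frame = orf_start % 3
            orf = OrfCandidate(tid, frame, orf_start, end, protein)
            planted_orfs.append(orf)
            if shared_pep is not None:
                shared_peptides.append((orf.accession, shared_pep))
                n_shared_left -= 1
            truth_rows.append(dict(
                transcript_id=tid, gene_id=gid, truth_biotype="lncRNA",
                truth_role="planted", truth_has_orf=True,
                truth_orf_start=orf_start, truth_frame=frame,
                truth_protein=protein, truth_n_exons=n_exons,
            ))
        else:
            for _attempt in range(500):
                tlen = int(rng.integers(lo, hi + 1))
                seq = _random_nt(rng, tlen)
                if not find_orfs(seq, params.min_protein_aa):
                    break
            else:
                raise RuntimeError(f"rejection sampling failed for ORF-free {tid}")
            transcripts.append(_place(tid, gid, seq, "lncRNA", n_exons))
            truth_rows.append(dict(
                transcript_id=tid, gene_id=gid, truth_biotype="lncRNA",
                truth_role="negative", truth_has_orf=False,
                truth_orf_start=-1, truth_frame=-1,
                truth_protein="", truth_n_exons=n_exons,
            ))

    # ---- decoy lncRNAs carrying distance-1 contaminants --------------------
    for i in range(params.peptide_noise.n_contaminant_d1):
        tid, gid = f"t_dec{i:04d}", f"g_dec{i:04d}"
        for _attempt in range(500):
            src_acc, src_prot = coding_protein_pool[int(rng.integers(0, len(coding_protein_pool)))]
            cands = _unique_tryptic_peptides(src_prot, 9, 20)
            if not cands:
                continue
            pep = cands[int(rng.integers(0, len(cands)))]
            mut = _mutate_peptide(rng, pep)
            if mut is None:
                continue
            protein = _random_protein(rng, 20) + "R" + mut + \
                "".join(AA_ALPHABET[k] for k in rng.integers(0, 20, size=20))
            tlen = int(rng.integers(max(lo, len(protein) * 3 + 60), hi + 1))
            if len(protein) * 3 + 30 > tlen:
                continue
            seq, orf_start = _plant_orf(rng, protein, tlen)
            break
        else:
            raise RuntimeError("could not build decoy contaminant ORF")
        transcripts.append(_place(tid, gid, seq, "lncRNA", 1))
        end = orf_start + 3 * (len(protein) + 1)
        orf = OrfCandidate(tid, orf_start % 3, orf_start, end, protein)
        planted_orfs.append(orf)
        contaminants.append((orf.accession, mut, src_acc))
        truth_rows.append(dict(
            transcript_id=tid, gene_id=gid, truth_biotype="lncRNA",
            truth_role="decoy", truth_has_orf=True,
            truth_orf_start=orf_start, truth_frame=orf_start % 3,
            truth_protein=protein, truth_n_exons=1,
        ))

    return SimulatedTranscriptome(
        transcripts=transcripts,
        known_proteins=known_proteins,
        truth=pd.DataFrame(truth_rows),
        planted_orfs=planted_orfs,
        shared_peptides=shared_peptides,
        contaminants_d1=contaminants,
        params=params,
    )


# ---------------------------------------------------------------------------
# expression counts

def simulate_expression(
    sim: SimulatedTranscriptome,
    params: SimulationParams | None = None,
    high_tr_gene_ids: set[str] | None = None,
    libraries: tuple[str, ...] = ("mRNA", "RNC"),
    sample_id: str = "s1",
    rng: np.random.Generator | None = None,
) -> tuple[list[ExpressionRecord], pd.DataFrame]:
    """Draw negative-binomial counts for the requested libraries.

    Per-gene means come from a log-normal baseline (median
    ``median_reads``); genes in ``high_tr_gene_ids`` (default: the
    ORF-bearing lncRNAs) get their RNC/RFP means multiplied by
    ``tr_shift``.  Returns the records (RPKM computed against the actual
    library totals) and a truth table of expected TR per gene.
    """
    params = params or sim.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if high_tr_gene_ids is None:
        high_tr_gene_ids = {
            row.gene_id for row in sim.truth.itertuples()
            if row.truth_role == "planted"
        }
    for lib in libraries:
        if params.library_sizes.get(lib, 0) <= 0:
            raise ValueError(f"library size for {lib} must be positive")
    genes = [(t.gene_id, t.length) for t in sim.transcripts]
    base = np.exp(rng.normal(np.log(params.median_reads), 1.0, size=len(genes)))
    tr = np.array([params.tr_shift if g in high_tr_gene_ids else 1.0 for g, _ in genes])
    records: list[ExpressionRecord] = []
    truth_rows = []
    for lib in libraries:
        means = base * (tr if lib in ("RNC", "RFP") else 1.0)
        means = means * (params.library_sizes[lib] / means.sum())
        if params.dispersion > 0:
            n_param = 1.0 / params.dispersion
            p_param = n_param / (n_param + means)
            counts = rng.negative_binomial(n_param, p_param)
        else:
            counts = rng.poisson(means)
        total = int(counts.sum())
        if total == 0:
            raise ValueError(f"library {lib} drew zero total counts")
        for (gid, glen), count in zip(genes, counts):
            rpkm = compute_rpkm(int(count), glen, total)
            records.append(ExpressionRecord(gid, sample_id, lib, int(count), rpkm))
    for (gid, _), t_exp in zip(genes, tr):
        truth_rows.append({"gene_id": gid, "truth_tr": float(t_exp)})
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ribosome footprints

def simulate_footprints(
    orf: OrfCandidate,
    transcript_len: int,
    n_footprints: int = 200,
    inside_outside_ratio: float = 10.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Place ~28-32 nt footprints with a configurable inside-CDS density bias.

    A footprint start falls inside the CDS with probability proportional
    to ``inside_outside_ratio`` per nt; ``inside_outside_ratio=inf``
    (or an outside length of zero) puts every start inside.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_footprints == 0:
        return []
    cds_len = orf.end_nt - orf.start_nt
    outside_len = transcript_len - cds_len
    if outside_len < 0:
        raise ValueError("ORF longer than transcript")
    w_in = inside_outside_ratio * cds_len
    w_out = float(outside_len)
    intervals: list[tuple[int, int]] = []
    for _ in range(n_footprints):
        length = int(rng.integers(28, 33))
        if np.isinf(w_in) or w_out == 0 or rng.random() < w_in / (w_in + w_out):
            start = orf.start_nt + int(rng.integers(0, cds_len))
        else:
            pos = int(rng.integers(0, outside_len))
            start = pos if pos < orf.start_nt else pos - orf.start_nt + orf.end_nt
        intervals.append((start, min(start + length, transcript_len)))
    return intervals


# ---------------------------------------------------------------------------
# peptide identification lists

def simulate_peptides(
    sim: SimulatedTranscriptome,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit the peptide identification list with hidden truth labels.

    True unique peptides are fully tryptic 9-30 aa peptides of the planted
    proteins; shared peptides are the regions embedded in both a planted
    and a known protein; contaminants are exact (d0) or single-substitution
    (d1) copies of known tryptic peptides (the d1 copies are carried by
    decoy ORFs already present in the transcriptome).
    """
    params = params or sim.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    rows: list[dict] = []
    shared_by_acc = dict()
    for acc, pep in sim.shared_peptides:
        shared_by_acc.setdefault(acc, []).append(pep)
    decoy_accs = {acc for acc, _, _ in sim.contaminants_d1}
    for orf in sim.planted_orfs:
        if orf.accession in decoy_accs:
            continue
        shared_here = set(shared_by_acc.get(orf.accession, []))
        uniq = [p for p in _unique_tryptic_peptides(orf.protein) if p not in shared_here]
        k = min(params.peptides_per_protein, len(uniq))
        chosen = list(rng.choice(uniq, size=k, replace=False)) if k else []
        for pep in chosen:
            rows.append({"peptide": pep, "truth_label": "true_unique",
                         "truth_source": orf.accession})
        for pep in shared_here:
            rows.append({"peptide": pep, "truth_label": "shared_supportive",
                         "truth_source": orf.accession})
    known_peps = [
        (kp.accession, p)
        for kp in sim.known_proteins
        for p in _unique_tryptic_peptides(kp.sequence, 9, 20)
    ]
    for _ in range(params.peptide_noise.n_contaminant_d0):
        acc, pep = known_peps[int(rng.integers(0, len(known_peps)))]
        rows.append({"peptide": pep, "truth_label": "contaminant_d0",
                     "truth_source": acc})
    for acc, pep, src in sim.contaminants_d1:
        rows.append({"peptide": pep, "truth_label": "contaminant_d1",
                     "truth_source": src})
    return pd.DataFrame(rows, columns=["peptide", "truth_label", "truth_source"])


# ---------------------------------------------------------------------------
# targeted-MS transition tables

def simulate_transitions(
    peptides: list[str],
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Light/heavy transition tables with planted verification outcomes.

    Each precursor receives 3-5 transition pairs.  Verified precursors get
    co-eluting pairs with S/N above threshold and small ratio deviations;
    non-verified precursors receive one planted failure mode (too few
    qualifying transitions, a non-co-eluting pair, or one pair with a
    large ratio deviation), recorded in ``truth_fail_mode``.
    """
    noise = (params or SimulationParams()).targeted_ms_noise
    if rng is None:
        rng = np.random.default_rng((params.seed + 3) if params else seed)
    rows: list[dict] = []
    fail_modes = ["too_few_sn", "not_coeluting", "ratio_deviation"]
    for pi, pep in enumerate(peptides):
        precursor = f"prec{pi:04d}"
        verified = rng.random() < noise.frac_verified
        k = int(rng.integers(noise.n_transitions_range[0], noise.n_transitions_range[1] + 1))
        true_ratio = float(rng.uniform(0.2, 5.0))
        mode = None if verified else fail_modes[int(rng.integers(0, 3))]
        devs = rng.uniform(-noise.good_deviation, noise.good_deviation, size=k)
        sns = rng.uniform(*noise.sn_range, size=k)
        coel = [True] * k
        if mode == "too_few_sn":
            for idx in range(k - 2):  # leave only 2 qualifying
                sns[idx] = float(rng.uniform(0.2, 2.5))
        elif mode == "not_coeluting":
            coel[int(rng.integers(0, k))] = False
        elif mode == "ratio_deviation":
            devs[int(rng.integers(0, k))] = noise.bad_deviation
        for ti in range(k):
            heavy = float(rng.uniform(1e4, 1e6))
            light = heavy * true_ratio * (1.0 + devs[ti])
            rows.append({
                "precursor_id": precursor, "fragment_id": f"y{ti + 3}",
                "peptide": pep, "light_area": light, "heavy_area": heavy,
                "light_sn": float(sns[ti]), "coelutes": bool(coel[ti]),
                "truth_verified": verified,
                "truth_fail_mode": mode or "",
            })
    return pd.DataFrame(rows)
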