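# Methods

## The inference chain

`lncproteo` implements a proteogenomic discovery chain for proteins encoded
by transcripts annotated as long non-coding RNAs (lncRNAs). The chain
mirrors how such analyses are run against real translatome and proteome
data:

1. **Translating-gene calls.** A gene is truly expressed in a library when
   it has ≥ `min_read_count` reads (default 10) *and* RPKM ≥ the active
   threshold (0.1 by default; 1.0 selectable — both are in routine use and
   detection is monotone in either threshold). Genes detected in the
   ribosome-nascent-chain (RNC) library are *translating*.
2. **ORF prediction.** On each translating lncRNA the three forward frames
   are scanned for canonical ORFs: AUG → first in-frame stop, protein
   ≥ `min_protein_aa` (default 50 aa counting the initiator Met, i.e.
   coding length ≥ 150 nt excluding the stop). One ORF is reported per
   (frame, stop), defined by the 5'-most AUG; an `all_starts` mode reports
   every AUG. ORFs without an in-frame stop inside the transcript are
   excluded as unverifiable. Transcripts are already stranded, so reverse
   frames are never scanned.
3. **Database construction.** The cell-specific search database contains
   the known proteins of translating genes plus the predicted ORF proteins
   of translating lncRNAs, deduplicated by exact sequence (provenance
   retained; I and L are *not* collapsed at this level). A small-protein
   subset keeps entries with average molecular mass strictly below
   `small_db_max_mw` (default 25 000 Da) — average rather than monoisotopic
   mass because the corresponding experimental fraction is gel-based.
4. **Peptide adjudication.** A peptide is assigned to every database entry
   containing it as a substring with I/L collapsed; it is *unique* when it
   matches exactly one entry (entries identical under I/L count as one) and
   *supportive* when it matches several. A candidate unique peptide is
   accepted only if it has ≥ `min_peptide_len` residues (default 9) and its
   minimum alignment distance to every background protein other than its
   own source is ≥ `min_alignment_diffs` (default 2).
5. **New-protein calls.** Database entries matching no PE1–PE5 protein by
   accession or sequence are *new*; a new entry with ≥ 1 accepted unique
   peptide is called, and carries an evidence tier: ≥ 2 unique peptides;
   1 unique + ≥ 1 supportive; 1 unique only.
6. **Characterization.** Called proteins are contrasted with the PE1 set by
   pI, instability, length, digestion behaviour, amino-acid classes,
   near-AUG folding energy, translation ratio, exon structure and
   evolutionary stratum.

## The alignment filter

The filter that removes single-amino-acid-variant misinterpretations is an
edit count, not a scored alignment: the minimum over all placements of the
*full* peptide against any region of a background protein of
substitutions + insertions + deletions, computed by semi-global dynamic
programming (peptide global, protein ends free). Residue pairs from a
configurable equivalence table count as matches: I≡L always, plus the
deamidation mass confusions N≡D and Q≡E by default (pairs chain
transitively; the table is fully configurable because the exact set of
PTM-mass-equivalent residues is an assumption, not a constant of nature).
This formulation removes any dependence on match/gap scores while keeping
the best-region semantics of a local alignment; a classic score-based
Smith–Waterman mode (`local_alignment_diffs`) is provided for comparison
only. The DP is validated against an independent oracle (minimum over all
protein substrings of the Needleman–Wunsch edit distance, via edlib) on
randomized cases, and the filter is monotone in its threshold.

The candidate's *own source* — the entry (or entries identical under I/L)
it identifies — is excluded from the background, otherwise every peptide
would be at distance 0 from its own protein.

## Targeted-MS verification

A monitored precursor is verified when (a) all S/N-qualifying transition
pairs co-elute, (b) at least 3 transitions have light S/N strictly above 3,
and (c) every qualifying pair's light/heavy ratio deviates strictly less
than 20% from the precursor's reference ratio. The reference ratio is the
**median** across the precursor's qualifying pairs: it is robust to the
single-outlier failure mode these rules exist to catch (with a mean
reference, one aberrant pair of three drags the reference toward itself and
can mask its own deviation). A pair with zero heavy area fails (c)
explicitly. Every failed criterion is reported as a reason string.

## Statistics

Chromosome enrichment uses the two-sided Fisher exact test
(probability-mass ordering; note other tie-breaking conventions can differ
on degenerate tables) on per-chromosome 2×2 tables; raw p-values by
default, Benjamini–Hochberg optionally. Distribution contrasts use the
two-sample Kolmogorov–Smirnov test, exact for n·m ≤ 10⁴ and asymptotic
beyond. Both are scipy-backed and are checked in the test suite against
full hypergeometric enumeration (all small-margin tables) and exhaustive
permutation at n = m = 5.

## Protein properties

* **pI** — bisection on the Henderson–Hasselbalch net charge over
  N-terminus, C-terminus and the D, E, C, Y, H, K, R side chains, to
  |charge| < 10⁻⁴ on pH ∈ [0, 14]. The default pKa set is the Bjellqvist
  table, with the EMBOSS set selectable; absolute pI shifts ~0.2 between
  tables but distribution *contrasts* are robust. Validated against a
  10⁻⁴-step pH grid scan.
* **Instability index** — (10/L) · Σ DIWV(dipeptide) over the L−1
  dipeptides, using the published DIWV weights (imported from Biopython's
  data tables); II > 40 is classed unstable. DIWV is directional:
  reversing a protein changes the value.
* **Trypsinolysis** — cleavage C-terminal to K/R except before P; with m
  missed cleavages all runs of ≤ m+1 consecutive fragments are returned
  (validated against exhaustive enumeration). The per-protein peptide
  *count* statistic uses fully cleaved peptides of 7–50 aa (window
  configurable; no canonical value exists).
* **iBAQ** — summed peptide intensity / number of theoretically observable
  fully-tryptic peptides (default window 6–30 aa); log₁₀ reported, zero
  intensity or zero observable peptides flagged undefined.
* **Molecular weight** — average residue masses + one water, consistently
  with the 25 kDa database gate.
* **Amino-acid classes** — nonpolar AVLIPFWM, uncharged polar STYQNCG,
  negative DE, positive RKH; fractions over classified residues.

## RNA folding near the start codon

Windows of ±19 nt (39 nt total) are slid across centers −50…+50 relative
to the A of the AUG; windows clipped by a transcript end are skipped, not
padded. The energy model is deliberately simplified: nested structures
with Watson–Crick + GU pairs, minimum hairpin loop 3, and energy
contributed *only* by stacked adjacent pairs (a lone pair is neutral), so
ΔG ≤ 0 always and an unpairable window folds to exactly 0. The stacking
constants are representative nearest-neighbour values; absolute kcal/mol
are **not** comparable with a Turner-parameter engine — the model exists
to support relative contrasts between sequence sets, and `window_scan`
accepts an `mfe_fn` hook for delegating to an external folding engine when
calibrated energies matter. The DP is validated against exhaustive
enumeration of all nested structures for windows ≤ 18 nt.

## Homology and origin

Homology between query and subject is the identity-×-coverage percentage:
identical residues in the best local alignment (BLOSUM62, gap open −11,
extend −1) divided by the *query* length, × 100. Alignments scoring below
70 count as no hit: unrelated random proteins of ≤ ~200 aa reach optimal
local scores of at most ~60, while genuine homologs at even 40% identity
score in the hundreds, so the gate plays the role of an E-value cutoff.
A protein's phylostratum is the oldest clade (over user-supplied,
oldest→youngest proteome sets) with a hit ≥ 10%. Origin classes are
assigned with fixed precedence: exon overlap with a known coding gene on
the same strand → splice variant; else ≥ 30% homology to the known
proteome → homologous copy; else ≥ 30% to the microbial set → microbial;
else unknown. The 30% threshold is the classical twilight-zone convention,
configurable.

## The synthetic benchmark

The generator emulates the study design the chain assumes, at desk scale.
Default conditions: 200 coding genes and 50 lncRNAs (40% carrying a
planted AUG-ORF of 50–150 aa), transcripts 0.6–2 kb, mRNA and RNC
libraries of 10⁶ reads with negative-binomial counts (log-normal gene
means with median 300 reads, dispersion 0.3 — the simplest model with the
overdispersion real libraries show), a 4× RNC enrichment on designated
high-TR genes, and 88% single-exon lncRNA gene models planted by exact
allocation. All randomness flows through one integer-seeded generator, so
a fixed seed gives bit-identical output.

Planting is engineered so noise-free runs have exact answers: ORF-free
lncRNAs are rejection-sampled until they contain no qualifying ORF at all;
planted ORFs carry an in-frame stop immediately 5' of their AUG, pinning
the reported 5'-most-AUG start; planted proteins are resampled until they
own at least two unique tryptic peptides of 9–30 aa. Shared (supportive)
peptides are real tryptic peptides of a known protein spliced into a
planted protein between K/R anchors, so they genuinely occur in both.
Distance-1 contaminants are known tryptic peptides with one internal
substitution (avoiding K/R and equivalence-table partners, so the true
distance is exactly 1), each embedded in a dedicated decoy lncRNA ORF —
this makes the contaminant a substring of a database entry, so that
*disabling* the alignment filter provably flips it into a false call.
Transition tables plant one failure mode per non-verified precursor (too
few qualifying transitions, a non-co-eluting pair, or a 60% ratio
deviation — large enough that it cannot hide behind the reference ratio).

What the generator does **not** emulate: search-engine score distributions
and FDR behaviour (the input peptide list is assumed FDR-controlled
upstream), spectra and retention times, positional read biases, correlated
expression structure, paralogous gene families, or realistic codon usage.
Passing tests therefore demonstrate the correctness of the decision rules
and their composition, not the end-to-end error rates expected on real
proteome-scale data, where near-duplicate sequences are vastly more
common.

## Problem sizes

The default benchmark is 250 genes (~2 s end-to-end); the
translation-ratio experiment uses 2000 genes with a 200-gene designated
high-TR subset (with only ~20 shifted genes the ratio-of-medians estimator
is too noisy to resolve a 4× shift reliably); oracle sweeps use 100–500
randomized cases per contract. These sizes keep the full suite under a
minute while leaving every rule exercised at its boundary.

## Known limitations

* Folding energies are model-internal units, not calibrated kcal/mol.
* The PTM-mass equivalence set is a default, not an authority; analyses
  sensitive to it must configure their own table.
* `assign_peptides` is exact-substring based; it does not model engine
  scoring, modified peptides, or semi-tryptic matches.
* Phylostratigraphy runs on user-supplied toy proteome sets; it is not a
  genome-scale pipeline.
* RPKM is the only normalization offered; TR uses RPKM ratios (library-size
  invariant), and whether a raw-count ratio would be preferable for very
  low counts is left to the caller.
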