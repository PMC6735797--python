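"""Minimum-free-energy estimates of RNA structure near the start codon.

Translation initiation efficiency is sensitive to secondary-structure
stability around the AUG, so the pipeline folds 39-nt windows (±19 nt)
slid across the start-codon neighbourhood and records a free-energy
estimate per window.

The energy model is a deliberately simplified nearest-neighbour model:
only stacked base pairs contribute (a helix of k+1 contiguous pairs gains
k stacking terms), lone pairs are energetically neutral, hairpin loops
must hold at least 3 unpaired nt, and pairs are Watson-Crick plus GU
wobble.  This captures the relative contrast between sequence sets; the
absolute kcal/mol are NOT comparable with a full Turner-parameter folding
engine, and a hook (``mfe_fn``) lets callers delegate to one when
Turner-accurate values matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import normalize_sequence

# allowed pairs (RNA alphabet)
PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
MIN_HAIRPIN = 3  # unpaired nt enclosed by a hairpin-closing pair

# Stacking free energies (kcal/mol) for pair (i,j) stacked on (i+1,j-1),
# keyed by the two pair types 5'->3'.  Values follow the usual
# nearest-neighbour ordering (GC-rich stacks strongest, wobble weakest).
_S = {
    ("GC", "CG"): -3.4, ("CG", "GC"): -2.4, ("GC", "GC"): -3.3, ("CG", "CG"): -3.3,
    ("GC", "AU"): -2.4, ("AU", "GC"): -2.1, ("CG", "AU"): -2.1, ("AU", "CG"): -2.2,
    ("GC", "UA"): -2.2, ("UA", "GC"): -2.5, ("CG", "UA"): -2.1, ("UA", "CG"): -2.4,
    ("AU", "AU"): -1.1, ("UA", "UA"): -1.3, ("AU", "UA"): -0.9, ("UA", "AU"): -1.3,
    ("GU", "UG"): -0.5, ("UG", "GU"): -0.6, ("GU", "GU"): -0.5, ("UG", "UG"): -0.5,
    ("GC", "GU"): -1.5, ("GU", "GC"): -1.5, ("CG", "GU"): -1.4, ("GU", "CG"): -2.5,
    ("GC", "UG"): -1.3, ("UG", "GC"): -2.1, ("CG", "UG"): -1.4, ("UG", "CG"): -1.4,
    ("AU", "GU"): -0.6, ("GU", "AU"): -1.4, ("UA", "GU"): -1.0, ("GU", "UA"): -0.8,
    ("AU", "UG"): -0.7, ("UG", "AU"): -1.0, ("UA", "UG"): -0.6, ("UG", "UA"): -0.8,
}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRS


def stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    """Stacking term for pair ``outer`` stacked on adjacent pair ``inner``."""
    return _S.get((outer[0] + outer[1], inner[0] + inner[1]), 0.0)


def _to_rna(seq: str) -> str:
    seq = normalize_sequence(seq, rna_to_dna=True).replace("T", "U")
    bad = sorted(set(seq) - set("ACGU"))
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {bad}")
    return seq


def structure_energy(seq: str, pairs: Sequence[tuple[int, int]]) -> float:
    """Energy of an explicit nested structure under the stacking-only model."""
    pair_set = set(pairs)
    energy = 0.0
    for (i, j) in pair_set:
        if (i + 1, j - 1) in pair_set:
            energy += stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
    return energy


def mfe(rna_window: str) -> float:
    """Minimum free energy over nested structures of the window.

    Dynamic programming with the stacking-only nearest-neighbour model;
    an unpairable sequence folds to 0 and the result is never positive.
    """
    seq = _to_rna(rna_window)
    n = len(seq)
    if n == 0:
        raise ValueError("window must be non-empty")
    if n < MIN_HAIRPIN + 2:
        return 0.0
    NEG = 0.0
    # V[i][j]: best energy with (i,j) paired; W[i][j]: best energy of seq[i..j]
    V = np.full((n, n), np.inf)
    W = np.zeros((n, n)) + 0.0
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can_pair(seq[i], seq[j]):
                best = W[i + 1][j - 1]
                if np.isfinite(V[i + 1][j - 1]):
                    stacked = stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1])) + V[i + 1][j - 1]
                    best = min(best, stacked)
                V[i][j] = best
            w = min(W[i + 1][j], W[i][j - 1])
            if np.isfinite(V[i][j]):
                w = min(w, V[i][j])
            for k in range(i + 1, j):
                w = min(w, W[i][k] + W[k + 1][j])
            W[i][j] = w
    return float(min(W[0][n - 1], NEG))


@dataclass
class FoldingProfile:
    """Per-window folding energies around one transcript's start codon.

    ``window_centers`` are nt offsets of the window centre relative to the
    A of the AUG (position 0); each has one dg value (<= 0).
    """

    transcript_id: str
    window_centers: list[int] = field(default_factory=list)
    dg_values: list[float] = field(default_factory=list)
    window_half: int = 19

    def __post_init__(self) -> None:
        if len(self.window_centers) != len(self.dg_values):
            raise ValueError("one dg per center required")
        if any(c2 <= c1 for c1, c2 in zip(self.window_centers, self.window_centers[1:])):
            raise ValueError("centers must be strictly increasing")
        if any(dg > 0 for dg in self.dg_values):
            raise ValueError("dg values must be <= 0")


def window_scan(
    transcript_seq: str,
    start_codon_pos: int,
    window_half: int = 19,
    center_range: tuple[int, int] = (-50, 50),
    transcript_id: str = "seq",
    mfe_fn: Callable[[str], float] = mfe,
) -> FoldingProfile:
    """Fold ±``window_half`` nt windows slid across the start-codon region.

    For each centre c in ``center_range`` (inclusive, step 1, relative to
    the A of the AUG), the window [c - window_half, c + window_half] is
    folded; windows clipped by a transcript end are skipped, not padded.
    """
    seq = normalize_sequence(transcript_seq)
    n = len(seq)
    if not 0 <= start_codon_pos < n:
        raise ValueError("start codon outside transcript")
    if n < 2 * window_half + 1:
        import logging

        logging.getLogger("lncproteo").warning(
            "%s shorter than one full window; empty profile", transcript_id)
        return FoldingProfile(transcript_id, [], [], window_half)
    centers: list[int] = []
    dgs: list[float] = []
    for c in range(center_range[0], center_range[1] + 1):
        lo = start_codon_pos + c - window_half
        hi = start_codon_pos + c + window_half + 1
        if lo < 0 or hi > n:
            continue
        centers.append(c)
        dgs.append(mfe_fn(seq[lo:hi]))
    return FoldingProfile(transcript_id, centers, dgs, window_half)


def aggregate_profiles(profiles: list[FoldingProfile]) -> pd.DataFrame:
    """Mean and min/max envelope of dg per centre across a set of profiles."""
    rows = []
    for p in profiles:
        for c, dg in zip(p.window_centers, p.dg_values):
            rows.append({"center": c, "dg": dg})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["center", "mean_dg", "lower_dg", "upper_dg"])
    agg = df.groupby("center")["dg"].agg(mean_dg="mean", lower_dg="min", upper_dg="max")
    return agg.reset_index()
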