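"""Pipeline-wide thresholds and their provenance.

Every stage of the discovery chain is driven by a handful of hard
thresholds (minimum read support for calling a gene expressed, minimum
protein length for a candidate ORF, minimum peptide length and alignment
distance for accepting a unique peptide, ...).  They are collected in one
:class:`PipelineConfig` object so a run can log the exact parameter set it
resolved and so tests can probe each boundary in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("lncproteo")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds governing the discovery pipeline.

    Attributes
    ----------
    min_read_count:
        Genes with at least this many mapped reads in a library count as
        truly expressed (default 10).
    rpkm_thresholds:
        The two detection thresholds used for expression-pattern calls
        (default 0.1 and 1.0 RPKM); ``active_rpkm_threshold`` selects which
        one a given analysis applies.
    min_protein_aa:
        Minimum translated length (initiator Met included, stop excluded)
        for a candidate ORF protein, default 50 aa (coding length >= 150 nt).
    min_peptide_len:
        Unique peptides shorter than this are discarded (default 9 residues).
    min_alignment_diffs:
        A candidate unique peptide must differ from every other protein in
        the background collection by at least this many mismatches + indels
        (default 2).
    small_db_max_mw:
        Strict upper bound, in Da of average mass, for membership in the
        low-molecular-weight database (default 25 000 Da).
    missed_cleavages:
        Missed tryptic cleavages allowed when enumerating peptides
        (default 2).
    folding_window_half:
        Half-width in nt of the sliding window used for near-AUG folding
        energy (default 19, i.e. 39-nt windows).
    homology_min_pct:
        Minimum homology percentage for counting a cross-species hit
        (default 10).
    ubiquity_min_samples:
        A gene detected in at least this many samples is classed
        ubiquitous (default 8, of the canonical 9-cell-line panel).
    random_seed:
        Seed recorded with every run for provenance.
    """

    min_read_count: int = 10
    rpkm_thresholds: tuple[float, float] = (0.1, 1.0)
    active_rpkm_threshold: float = 0.1
    min_protein_aa: int = 50
    min_peptide_len: int = 9
    min_alignment_diffs: int = 2
    small_db_max_mw: float = 25000.0
    missed_cleavages: int = 2
    folding_window_half: int = 19
    homology_min_pct: float = 10.0
    ubiquity_min_samples: int = 8
    random_seed: int = 0
    # iBAQ / digestion-count observability window (aa length, inclusive)
    ibaq_peptide_window: tuple[int, int] = (6, 30)
    digest_count_window: tuple[int, int] = (7, 50)

    def __post_init__(self) -> None:
        positive = {
            "min_read_count": self.min_read_count,
            "min_protein_aa": self.min_protein_aa,
            "min_peptide_len": self.min_peptide_len,
            "min_alignment_diffs": self.min_alignment_diffs,
            "small_db_max_mw": self.small_db_max_mw,
            "folding_window_half": self.folding_window_half,
            "homology_min_pct": self.homology_min_pct,
            "ubiquity_min_samples": self.ubiquity_min_samples,
            "active_rpkm_threshold": self.active_rpkm_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if any(t <= 0 for t in self.rpkm_thresholds):
            raise ValueError("rpkm_thresholds must be strictly positive")

    def log_resolved(self) -> None:
        """Log the fully resolved configuration (run provenance)."""
        logger.info("resolved config: %s", dataclasses.asdict(self))


DEFAULT_CONFIG = PipelineConfig()


def config_from_mapping(mapping: dict) -> PipelineConfig:
    """Build a config from a (YAML/JSON-loaded) mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("rpkm_thresholds", "ibaq_peptide_window", "digest_count_window"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return PipelineConfig(**kwargs)
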