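"""Bulk-segregant candidate identification by filtering and profile subtraction.

A pooled-sequencing SNP profile from phenotype-selected homozygous
mutants is reduced to causal-mutation candidates in three steps:

1. frequency filter — keep sites whose alt-allele frequency exceeds a
   cutoff (default strictly > 0.95), since in a homozygote pool the
   causal site and tightly linked markers are near fixation while
   unlinked EMS sites sit near 50%;
2. depth filter — discard sites with excessive coverage (default keep
   depth <= 200), which flags collapsed repeats and reference assembly
   errors where reads pile up;
3. profile subtraction — remove every site also called in any other,
   independently derived mutant line's profile, since reference
   artifacts recur across lines while a true EMS mutation is unique to
   its line.

Each stage's survivor count is recorded, producing the audit trail a
mapping-by-sequencing analysis is normally reported with.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import pandas as pd

from .errors import ConfigError, DataIntegrityError, UsageError

SnpKey = tuple  # (chrom, pos[, ref, alt]) depending on match mode


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic variant call with read support.

    ``frequency`` is normally recomputed from ``alt_count/depth``; an
    explicit value is honoured only when counts are unavailable (e.g. a
    VCF carrying AF but not AO).
    """

    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    _frequency: Optional[float] = None

    def __post_init__(self):
        if self.position < 1:
            raise DataIntegrityError(f"position must be >=1, got {self.position}")
        if self.depth < 0 or not (0 <= self.alt_count <= self.depth):
            raise DataIntegrityError(
                f"{self.chromosome}:{self.position}: require 0 <= alt_count "
                f"({self.alt_count}) <= depth ({self.depth})"
            )
        if self._frequency is not None and not (0.0 <= self._frequency <= 1.0):
            raise DataIntegrityError("frequency must lie in [0, 1]")

    @property
    def frequency(self) -> float:
        if self.depth > 0:
            return self.alt_count / self.depth
        return self._frequency if self._frequency is not None else 0.0

    @property
    def key(self) -> SnpKey:
        return (self.chromosome, self.position, self.ref, self.alt)

    def match_key(self, mode: str) -> SnpKey:
        if mode == "position_only":
            return (self.chromosome, self.position)
        return self.key


class SnpProfile:
    """The set of variant calls for one line, keyed by (chrom,pos,ref,alt)."""

    def __init__(self, line_id: str, records: Iterable[SnpRecord] = ()):
        self.line_id = line_id
        self._records: dict[SnpKey, SnpRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SnpRecord) -> None:
        if rec.key in self._records:
            raise DataIntegrityError(
                f"duplicate record {rec.key} in profile {self.line_id}"
            )
        self._records[rec.key] = rec

    @property
    def records(self) -> list[SnpRecord]:
        return sorted(self._records.values(), key=lambda r: r.key)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: SnpKey) -> bool:
        return key in self._records

    def __iter__(self):
        return iter(self.records)

    def match_keys(self, mode: str) -> set[SnpKey]:
        return {r.match_key(mode) for r in self._records.values()}

    def subset(self, records: Iterable[SnpRecord]) -> "SnpProfile":
        return SnpProfile(self.line_id, records)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and matching semantics for the candidate pipeline.

    ``min_frequency`` is exclusive (a record must be strictly above it);
    ``max_depth`` is inclusive (records strictly above are discarded).
    """

    min_frequency: float = 0.95
    max_depth: int = 200
    match_mode: str = "position_and_allele"

    def __post_init__(self):
        if not (0.0 < self.min_frequency < 1.0):
            raise ConfigError(
                f"min_frequency must lie in (0, 1), got {self.min_frequency}"
            )
        if self.max_depth <= 0:
            raise ConfigError(f"max_depth must be positive, got {self.max_depth}")
        if self.match_mode not in ("position_and_allele", "position_only"):
            raise ConfigError(f"unknown match_mode {self.match_mode!r}")


@dataclass
class AnnotatedSnp:
    """A surviving candidate, optionally carrying its predicted effect."""

    record: SnpRecord
    effect: Any = None  # variant_annotation VariantEffect when available


@dataclass
class CandidateReport:
    """Per-stage survivor counts plus the final (optionally annotated) list."""

    focal_line: str
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    candidates: list[AnnotatedSnp] = field(default_factory=list)

    def check(self) -> None:
        counts = [n for _, n in self.stage_counts]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise DataIntegrityError("stage counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cand in self.candidates:
            r = cand.record
            eff = cand.effect
            rows.append(
                {
                    "chrom": r.chromosome,
                    "pos": r.position,
                    "ref": r.ref,
                    "alt": r.alt,
                    "alt_count": r.alt_count,
                    "depth": r.depth,
                    "frequency": round(r.frequency, 6),
                    "category": getattr(eff, "category", ""),
                    "aa_change": getattr(eff, "aa_change_str", lambda: "")()
                    if eff is not None
                    else "",
                    "conservation": getattr(eff, "conservation_call", ""),
                    "in_repeat": getattr(eff, "in_repeat", ""),
                }
            )
        columns = [
            "chrom", "pos", "ref", "alt", "alt_count", "depth", "frequency",
            "category", "aa_change", "conservation", "in_repeat",
        ]
        return pd.DataFrame(rows, columns=columns)

    def audit_json(self) -> str:
        return json.dumps(
            {
                "focal_line": self.focal_line,
                "stages": [{"stage": s, "snps": n} for s, n in self.stage_counts],
                "n_candidates": len(self.candidates),
            },
            indent=2,
        )


def filter_by_frequency(profile: SnpProfile, min_frequency: float = 0.95) -> SnpProfile:
    """Keep records with alt-allele frequency strictly above the cutoff."""
    if not (0.0 < min_frequency < 1.0):
        raise ConfigError(f"min_frequency must lie in (0, 1), got {min_frequency}")
    return profile.subset(r for r in profile if r.frequency > min_frequency)


def filter_by_depth(profile: SnpProfile, max_depth: int = 200) -> SnpProfile:
    """Discard records with coverage strictly above the cutoff (keep <=)."""
    if max_depth <= 0:
        raise ConfigError(f"max_depth must be positive, got {max_depth}")
    return profile.subset(r for r in profile if r.depth <= max_depth)


def subtract_profiles(
    focal: SnpProfile,
    others: list[SnpProfile],
    config: FilterConfig | None = None,
    apply_filters: bool = True,
) -> CandidateReport:
    """Sequentially remove focal records present in each other profile.

    Other profiles are matched *unfiltered*: any call of the same key
    (per ``match_mode``) in another line removes the focal record, the
    conservative reading of "unique to the focal line".  The final set
    is independent of the order of ``others``; only the per-stage
    counts depend on it.
    """
    config = config or FilterConfig()
    for other in others:
        if other.line_id == focal.line_id:
            raise UsageError(
                f"focal line {focal.line_id!r} also appears in `others`"
            )
    report = CandidateReport(focal_line=focal.line_id)
    current = focal
    report.stage_counts.append(("raw", len(current)))
    if apply_filters:
        current = filter_by_frequency(current, config.min_frequency)
        report.stage_counts.append(
            (f"frequency > {config.min_frequency:g}", len(current))
        )
        current = filter_by_depth(current, config.max_depth)
        report.stage_counts.append((f"depth <= {config.max_depth}", len(current)))
    for other in others:
        drop = other.match_keys(config.match_mode)
        current = current.subset(
            r for r in current if r.match_key(config.match_mode) not in drop
        )
        report.stage_counts.append((f"minus {other.line_id}", len(current)))
    report.candidates = [AnnotatedSnp(r) for r in current]
    report.check()
    return report


def identify_candidates(
    focal: SnpProfile,
    others: list[SnpProfile],
    config: FilterConfig | None = None,
    genome=None,
    genes=None,
    scorer=None,
) -> CandidateReport:
    """Full in-memory pipeline: filters, subtraction, optional annotation.

    When a reference genome and gene models are supplied, each surviving
    candidate is classified (noncoding / synonymous / nonsynonymous,
    with replacement severity) and the list is ranked most-damaging
    first, ties broken by genomic coordinate.
    """
    config = config or FilterConfig()
    report = subtract_profiles(focal, others, config, apply_filters=True)
    if genome is not None:
        from . import annotate as _ann

        genes = genes if genes is not None else genome.genes
        scorer = scorer or _ann.SubstitutionScorer.default()
        for cand in report.candidates:
            cand.effect = _ann.annotate_variant(
                cand.record, genome, genes, scorer=scorer
            )
        report.candidates = _ann.rank_candidates(report.candidates)
    return report


def run_pipeline(
    focal_vcf: str,
    other_vcfs: list[str],
    genome_fasta: str | None = None,
    gene_gff: str | None = None,
    config: FilterConfig | None = None,
) -> CandidateReport:
    """File-level pipeline: read VCF profiles (and optionally the
    reference FASTA + GFF3 gene models), then run ``identify_candidates``.
    Deterministic: the same inputs always give the same report.
    """
    from . import io as _io

    focal = _io.read_vcf(focal_vcf)
    others = [_io.read_vcf(p) for p in other_vcfs]
    genome = None
    if genome_fasta is not None and gene_gff is not None:
        genome = _io.read_genome(genome_fasta, gene_gff)
    return identify_candidates(focal, others, config, genome=genome)
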