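"""Instrument selection: p-value threshold, LD clumping, F filter, blacklist.

Instruments for a taxon-abundance exposure are chosen at the locus-wide
significance level (p < 1e-5 by default), pruned to mutual independence by
greedy clumping (r^2 < 0.001 within a 10,000 kb window), screened for strength
(F = beta^2/se^2 >= 10) and purged of a user-supplied confounder blacklist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ConfigError, GutmrError
from .gwas_io import LdTable, SummaryStatistics, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass
class InstrumentConfig:
    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigError(f"clump_r2 must be in [0, 1], got {self.clump_r2}")
        if not self.clump_window_kb > 0:
            raise ConfigError(f"clump_window_kb must be > 0, got {self.clump_window_kb}")
        if self.f_min < 0:
            raise ConfigError(f"f_min must be >= 0, got {self.f_min}")
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))


def read_blacklist(path: str | Path) -> frozenset[str]:
    """One snp_id per line; blank lines and '#' comments ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return frozenset(ids)


def select_by_pvalue(stats: SummaryStatistics, p_threshold: float) -> SummaryStatistics:
    """Keep exactly the records with pvalue strictly below the threshold."""
    return stats.subset([r for r in stats if r.pvalue < p_threshold])


def compute_f_statistic(record: VariantAssociation) -> float:
    """Instrument strength F = beta^2 / se^2."""
    return record.beta ** 2 / record.se ** 2


def filter_weak_instruments(stats: SummaryStatistics, f_min: float) -> SummaryStatistics:
    """Remove records with F strictly below f_min (F = f_min is retained)."""
    return stats.subset([r for r in stats if compute_f_statistic(r) >= f_min])


def apply_blacklist(stats: SummaryStatistics, blacklist: frozenset[str] | set[str]) -> SummaryStatistics:
    """Drop records whose snp_id is on the confounder blacklist."""
    removed = [r.snp_id for r in stats if r.snp_id in blacklist]
    if removed:
        logger.info("%s: removed %d blacklisted SNP(s): %s", stats.trait_id, len(removed), removed)
    return stats.subset([r for r in stats if r.snp_id not in blacklist])


def _tie_key(record: VariantAssociation) -> tuple:
    # deterministic p-value tie-break: (chrom, pos, snp_id) lexicographic
    return (record.pvalue, str(record.chrom), record.pos or 0, record.snp_id)


def clump(
    candidates: SummaryStatistics,
    ld: LdTable,
    config: InstrumentConfig | None = None,
) -> SummaryStatistics:
    """Greedy LD clumping keeping the lowest-p SNP of each correlated region.

    Repeatedly takes the unprocessed record with the lowest p-value as an index
    SNP and discards every other unprocessed record on the same chromosome
    within ``clump_window_kb`` whose r^2 with the index exceeds ``clump_r2``.
    Cross-chromosome pairs are never clumped; an LD pair absent from the table
    counts as r^2 = 0 (the missing-pair count is logged as a diagnostic).
    """
    config = config or InstrumentConfig()
    window_bp = config.clump_window_kb * 1000.0
    for r in candidates:
        if r.chrom is None or r.pos is None:
            raise GutmrError(f"clumping requires chrom/pos; missing for {r.snp_id}")

    order = sorted(candidates.records, key=_tie_key)
    removed: set[str] = set()
    kept: list[VariantAssociation] = []
    missing_pairs = 0
    for i, index_snp in enumerate(order):
        if index_snp.snp_id in removed:
            continue
        kept.append(index_snp)
        for other in order[i + 1:]:
            if other.snp_id in removed:
                continue
            if other.chrom != index_snp.chrom:
                continue
            if abs(other.pos - index_snp.pos) > window_bp:
                continue
            if not ld.has(index_snp.snp_id, other.snp_id):
                missing_pairs += 1
            if ld.get(index_snp.snp_id, other.snp_id) > config.clump_r2:
                removed.add(other.snp_id)
    if missing_pairs:
        logger.info(
            "%s: %d in-window pair(s) had no LD entry (treated as r^2=0)",
            candidates.trait_id, missing_pairs,
        )
    return candidates.subset(kept)


@dataclass
class SelectionReport:
    """Per-stage record counts for auditing the selection funnel."""

    input: int = 0
    after_pvalue: int = 0
    after_clump: int = 0
    after_f_filter: int = 0
    after_blacklist: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def select_instruments(
    stats: SummaryStatistics,
    ld: LdTable | None = None,
    config: InstrumentConfig | None = None,
) -> tuple[SummaryStatistics, SelectionReport]:
    """Full funnel: p-threshold -> clump -> F filter -> blacklist.

    Returns the surviving instruments and per-stage counts so the order of the
    F filter relative to clumping is auditable.
    """
    config = config or InstrumentConfig()
    ld = ld or LdTable()
    report = SelectionReport(input=len(stats))
    stage = select_by_pvalue(stats, config.p_threshold)
    report.after_pvalue = len(stage)
    stage = clump(stage, ld, config)
    report.after_clump = len(stage)
    stage = filter_weak_instruments(stage, config.f_min)
    report.after_f_filter = len(stage)
    stage = apply_blacklist(stage, config.blacklist)
    report.after_blacklist = len(stage)
    return stage, report
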