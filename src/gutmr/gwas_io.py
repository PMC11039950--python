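"""Reading, validating and writing GWAS summary statistics in delimited text.

Summary statistics arrive as one row per variant (rsID, alleles, beta, SE,
p-value, optionally EAF / chromosome / position / sample size) with arbitrary
column names, so readers take an explicit column mapping.  Pairwise linkage
disequilibrium arrives as a sparse three-column table; absent pairs are treated
as independent (r^2 = 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

#: canonical column names recognised in a column map
REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "n")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is the effect per SD of a continuous exposure, or the log
    odds-ratio for a binary outcome, signed with respect to ``effect_allele``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.chrom is not None:
            object.__setattr__(self, "chrom", str(self.chrom))
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in _VALID_BASES:
                raise FormatError(
                    f"{self.snp_id}: {name} {allele!r} is not a single base (SNVs only)"
                )
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise FormatError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise FormatError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise FormatError(f"{self.snp_id}: EAF must be in (0, 1), got {self.eaf}")
        if self.pos is not None and self.pos < 1:
            raise FormatError(f"{self.snp_id}: position must be 1-based, got {self.pos}")


@dataclass
class SummaryStatistics:
    """An ordered, validated collection of variant associations for one trait."""

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    records: list[VariantAssociation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise FormatError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"{self.trait_id}: duplicate snp_id(s) {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, VariantAssociation]:
        return {r.snp_id: r for r in self.records}

    def subset(self, keep: Iterable[VariantAssociation]) -> "SummaryStatistics":
        """New SummaryStatistics with the given records, original order kept."""
        keep_ids = {r.snp_id for r in keep}
        return SummaryStatistics(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.snp_id in keep_ids],
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": [r.snp_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


class LdTable:
    """Symmetric sparse lookup of pairwise r^2; missing pairs read as 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if r2 < -1e-9 or r2 > 1 + 1e-9:
            raise FormatError(f"r^2 for ({a}, {b}) outside [0, 1]: {r2}")
        self._r2[self._key(a, b)] = min(1.0, max(0.0, float(r2)))

    def get(self, a: str, b: str) -> float:
        if a == b:
            return self._r2.get(self._key(a, b), 1.0)
        return self._r2.get(self._key(a, b), 0.0)

    def has(self, a: str, b: str) -> bool:
        return self._key(a, b) in self._r2

    def __len__(self) -> int:
        return len(self._r2)


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    # delimiter auto-detected among tab/comma unless overridden
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=delimiter)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_id: str | None = None,
    policy: str = "skip",
    delimiter: str | None = None,
    meta: dict | None = None,
) -> SummaryStatistics:
    """Read a delimited summary-statistics table into validated records.

    ``column_map`` maps canonical names (``snp``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``pvalue``, and optionally ``chrom``,
    ``pos``, ``eaf``, ``n``) to the file's column headers; canonical names
    already present in the header need no entry.  ``policy`` is ``"skip"``
    (drop malformed rows, logging counts) or ``"strict"`` (raise naming the
    offending row).
    """
    if policy not in ("skip", "strict"):
        raise FormatError(f"unknown validation policy {policy!r}")
    column_map = dict(column_map or {})
    df = _read_table(path, delimiter)

    resolved: dict[str, str] = {}
    for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        source = column_map.get(canon, canon)
        if source in df.columns:
            resolved[canon] = source
        elif canon in REQUIRED_COLUMNS:
            raise FormatError(
                f"{path}: required column {canon!r} (mapped to {source!r}) not found; "
                f"available columns: {list(df.columns)}"
            )

    records: list[VariantAssociation] = []
    dropped: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))

        def val(canon: str):
            col = resolved.get(canon)
            if col is None:
                return None
            v = row_d[col]
            return None if pd.isna(v) else v

        try:
            records.append(
                VariantAssociation(
                    snp_id=str(val("snp")),
                    effect_allele=str(val("effect_allele")),
                    other_allele=str(val("other_allele")),
                    beta=float(val("beta")),
                    se=float(val("se")),
                    pvalue=float(val("pvalue")),
                    chrom=val("chrom"),
                    pos=None if val("pos") is None else int(val("pos")),
                    eaf=None if val("eaf") is None else float(val("eaf")),
                    n=None if val("n") is None else float(val("n")),
                )
            )
        except (FormatError, TypeError, ValueError) as exc:
            if policy == "strict":
                raise FormatError(f"{path}: row {i + 1}: {exc}") from exc
            dropped[str(exc)] = dropped.get(str(exc), 0) + 1
    if dropped:
        logger.warning(
            "%s: dropped %d malformed row(s): %s", path, sum(dropped.values()), dropped
        )
    return SummaryStatistics(
        trait_id=trait_id or Path(path).stem,
        trait_type=trait_type,
        records=records,
        meta=meta or {},
    )


def write_summary_stats(stats: SummaryStatistics, path: str | Path) -> None:
    """Write a tab-delimited table round-trippable through read_summary_stats."""
    stats.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ld_table(path: str | Path, delimiter: str | None = None) -> LdTable:
    """Read a three-column (snp_a, snp_b, r2) table into a symmetric lookup."""
    df = _read_table(path, delimiter)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: LD table needs 3 columns (snp_a, snp_b, r2)")
    table = LdTable()
    a_col, b_col, r_col = df.columns[:3]
    for a, b, r2 in zip(df[a_col], df[b_col], df[r_col]):
        table.set(str(a), str(b), float(r2))
    return table


def write_ld_table(table: LdTable, path: str | Path) -> None:
    rows = [(a, b, r2) for (a, b), r2 in sorted(table._r2.items())]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


#: display names used in the results table, one row per (pair, method)
METHOD_LABELS = {
    "IVW_fixed": "IVW (fixed)",
    "IVW_random": "IVW (random)",
    "Egger": "MR-Egger (slope)",
    "WeightedMedian": "Weighted median",
    "WeightedMode": "Weighted mode",
    "PRESSO": "MR-PRESSO",
    "Wald": "Wald ratio",
}

RESULTS_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "or",
    "or_ci_low",
    "or_ci_high",
    "pvalue",
    "cochran_q",
    "cochran_q_pvalue",
    "presso_global_rss",
    "presso_global_pvalue",
    "egger_intercept",
    "egger_intercept_pvalue",
    "f_statistic_min",
]


def write_results_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write per-(pair, method) MR results as TSV with 6 significant digits."""
    df = pd.DataFrame(list(rows), columns=RESULTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (config, seed, per-stage counts)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
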