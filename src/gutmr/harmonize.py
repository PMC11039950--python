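"""Allele harmonization of exposure and outcome effects.

Two-sample MR needs the per-SNP exposure effect (gamma) and outcome effect
(Gamma) signed with respect to the same effect allele.  Records are joined on
rsID; swapped allele orderings flip the outcome beta sign, strand complements
are resolved by complementing (optional strict mode drops them instead), and
palindromic A/T and C/G variants — whose strand cannot be resolved from
alleles alone — are always dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import EmptyInstrumentSetError, GutmrError
from .gwas_io import SummaryStatistics, VariantAssociation
from .instruments import compute_f_statistic

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_UNMATCHED = "dropped_unmatched"
DROPPED_INCOMPATIBLE = "dropped_incompatible"


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}."""
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedRecord:
    """Aligned per-SNP effects for one exposure-outcome pair.

    gamma/sigma_x are the exposure effect and SE (per SD of abundance),
    Gamma/sigma_y the outcome effect and SE (log odds), both signed with
    respect to the exposure's effect allele.  Dropped records carry the drop
    reason in ``action`` and no outcome effect.
    """

    snp_id: str
    action: str
    gamma: float | None = None
    sigma_x: float | None = None
    Gamma: float | None = None
    sigma_y: float | None = None
    f_stat: float | None = None
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    @property
    def kept(self) -> bool:
        return self.action in (KEPT, FLIPPED)

    def __post_init__(self) -> None:
        if self.kept:
            if self.sigma_x is None or not self.sigma_x > 0:
                raise GutmrError(f"{self.snp_id}: kept record needs sigma_x > 0")
            if self.sigma_y is None or not self.sigma_y > 0:
                raise GutmrError(f"{self.snp_id}: kept record needs sigma_y > 0")


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    strand_mode: str = "infer",
) -> HarmonizedRecord:
    """Align one outcome record to the exposure's effect allele.

    Orientation cases: identical allele pair -> kept unchanged; swapped pair ->
    kept with outcome beta sign flipped and EAF reflected; strand complement of
    either -> resolved the same way when ``strand_mode="infer"`` (dropped as
    incompatible under ``"strict"``); palindromic exposure pair -> dropped
    regardless; anything else -> dropped as incompatible.
    """
    if exposure.snp_id != outcome.snp_id:
        raise GutmrError(
            f"harmonize_pair: snp_id mismatch {exposure.snp_id!r} vs {outcome.snp_id!r}"
        )
    if strand_mode not in ("infer", "strict"):
        raise GutmrError(f"unknown strand_mode {strand_mode!r}")

    def _make(action: str, Gamma=None, sigma_y=None, eaf_out=None) -> HarmonizedRecord:
        return HarmonizedRecord(
            snp_id=exposure.snp_id,
            action=action,
            gamma=exposure.beta,
            sigma_x=exposure.se,
            Gamma=Gamma,
            sigma_y=sigma_y,
            f_stat=compute_f_statistic(exposure),
            eaf_exposure=exposure.eaf,
            eaf_outcome=eaf_out,
        )

    if is_palindromic(exposure.effect_allele, exposure.other_allele):
        return _make(DROPPED_PALINDROMIC)

    e = (exposure.effect_allele, exposure.other_allele)
    o = (outcome.effect_allele, outcome.other_allele)
    comp = (COMPLEMENT[e[0]], COMPLEMENT[e[1]])

    if o == e:
        return _make(KEPT, outcome.beta, outcome.se, outcome.eaf)
    if o == (e[1], e[0]):
        flipped_eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
        return _make(FLIPPED, -outcome.beta, outcome.se, flipped_eaf)
    if strand_mode == "infer":
        if o == comp:
            return _make(KEPT, outcome.beta, outcome.se, outcome.eaf)
        if o == (comp[1], comp[0]):
            flipped_eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
            return _make(FLIPPED, -outcome.beta, outcome.se, flipped_eaf)
    return _make(DROPPED_INCOMPATIBLE)


@dataclass
class HarmonizedInstrumentSet:
    """Analysis-ready kept records for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    records: list[HarmonizedRecord]
    drop_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise GutmrError(f"duplicate snp_id in harmonized set {self.exposure_id}")
        if any(not r.kept for r in self.records):
            raise GutmrError("HarmonizedInstrumentSet records must all be kept")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_snp(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def gamma(self) -> np.ndarray:
        return np.array([r.gamma for r in self.records], dtype=float)

    @property
    def sigma_x(self) -> np.ndarray:
        return np.array([r.sigma_x for r in self.records], dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        return np.array([r.Gamma for r in self.records], dtype=float)

    @property
    def sigma_y(self) -> np.ndarray:
        return np.array([r.sigma_y for r in self.records], dtype=float)

    @property
    def f_stats(self) -> np.ndarray:
        return np.array([r.f_stat for r in self.records], dtype=float)

    def exclude(self, snp_ids: Iterable[str]) -> "HarmonizedInstrumentSet":
        drop = set(snp_ids)
        return HarmonizedInstrumentSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            records=[r for r in self.records if r.snp_id not in drop],
            drop_log=dict(self.drop_log),
        )

    @classmethod
    def from_arrays(
        cls,
        gamma,
        sigma_x,
        Gamma,
        sigma_y,
        snp_ids=None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
    ) -> "HarmonizedInstrumentSet":
        gamma = np.asarray(gamma, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(gamma.size)]
        records = [
            HarmonizedRecord(
                snp_id=s,
                action=KEPT,
                gamma=float(g),
                sigma_x=float(sx),
                Gamma=float(G),
                sigma_y=float(sy),
                f_stat=float(g) ** 2 / float(sx) ** 2,
            )
            for s, g, sx, G, sy in zip(snp_ids, gamma, np.asarray(sigma_x, float),
                                       np.asarray(Gamma, float), np.asarray(sigma_y, float))
        ]
        return cls(exposure_id=exposure_id, outcome_id=outcome_id, records=records)

    def write_drop_log(self, path) -> None:
        rows = sorted(self.drop_log.items())
        pd.DataFrame(rows, columns=["snp_id", "reason"]).to_csv(path, sep="\t", index=False)


def build_instrument_set(
    exposure_instruments: SummaryStatistics,
    outcome_stats: SummaryStatistics,
    strand_mode: str = "infer",
) -> HarmonizedInstrumentSet:
    """Join selected instruments with outcome effects, per-SNP, on rsID.

    Every exposure instrument is accounted for exactly once: kept (possibly
    sign-flipped) or logged as dropped (unmatched / palindromic / allele-
    incompatible).  Raises if no record survives.
    """
    kept: list[HarmonizedRecord] = []
    drop_log: dict[str, str] = {}
    for exp in exposure_instruments:
        out = outcome_stats.get(exp.snp_id)
        if out is None:
            drop_log[exp.snp_id] = DROPPED_UNMATCHED
            continue
        rec = harmonize_pair(exp, out, strand_mode=strand_mode)
        if rec.kept:
            kept.append(rec)
        else:
            drop_log[exp.snp_id] = rec.action
    if not kept:
        raise EmptyInstrumentSetError(
            f"no usable instrument for {exposure_instruments.trait_id} -> "
            f"{outcome_stats.trait_id} ({len(drop_log)} dropped)"
        )
    return HarmonizedInstrumentSet(
        exposure_id=exposure_instruments.trait_id,
        outcome_id=outcome_stats.trait_id,
        records=kept,
        drop_log=drop_log,
    )
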