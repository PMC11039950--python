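"""Batch orchestration, FDR classification and reverse MR.

One exposure-outcome pair runs the full funnel (instrument selection,
harmonization, five estimators, diagnostics); a batch shares one
Benjamini-Hochberg family per outcome across taxa, classifying each pair as
significant (IVW p < 0.05 and q < 0.1), suggestive (p < 0.05, q >= 0.1) or
null.  Reverse MR re-runs the identical pipeline with the disease GWAS as
the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .diagnostics import (
    HeterogeneityResult,
    LeaveOneOutResult,
    cochran_q,
    leave_one_out,
)
from .estimators import (
    EstimatorConfig,
    MREstimate,
    PleiotropyResult,
    PressoResult,
    _finalize,
    ivw,
    mr_egger,
    mr_presso,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from .exceptions import EmptyInstrumentSetError, GutmrError, InsufficientInstrumentsError
from .gwas_io import METHOD_LABELS, LdTable, SummaryStatistics
from .harmonize import HarmonizedInstrumentSet, build_instrument_set
from .instruments import InstrumentConfig, SelectionReport, select_instruments

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NULL = "null"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise GutmrError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(p: float, q: float) -> str:
    """Two-threshold significance class.

    Significant requires p < 0.05 and q strictly < 0.1; p < 0.05 with q >= 0.1
    is suggestive (the q = 0.1 boundary is assigned conservatively); anything
    else is null.
    """
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise GutmrError(f"invalid probabilities p={p}, q={q}")
    if p < 0.05 and q < 0.1:
        return SIGNIFICANT
    if p < 0.05:
        return SUGGESTIVE
    return NULL


@dataclass(frozen=True)
class FdrRecord:
    exposure_id: str
    outcome_id: str
    primary_p: float
    q: float
    klass: str


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair (one results row set)."""

    exposure_id: str
    outcome_id: str
    status: str = "ok"  # ok | skipped
    skip_reason: str | None = None
    selection: SelectionReport | None = None
    hset: HarmonizedInstrumentSet | None = None
    primary: MREstimate | None = None  # model chosen by the heterogeneity rule
    ivw_fixed: MREstimate | None = None
    ivw_random: MREstimate | None = None
    egger: MREstimate | None = None
    weighted_median: MREstimate | None = None
    weighted_mode: MREstimate | None = None
    presso: PressoResult | None = None
    heterogeneity: HeterogeneityResult | None = None
    pleiotropy: PleiotropyResult | None = None
    loo: LeaveOneOutResult | None = None
    f_min: float | None = None
    direction_consistent: bool | None = None
    fdr: FdrRecord | None = None
    not_applicable: list[str] = field(default_factory=list)

    def estimates(self) -> list[MREstimate]:
        out = [self.primary]
        for est in (self.egger, self.weighted_median, self.weighted_mode):
            if est is not None:
                out.append(est)
        if self.presso is not None:
            out.append(self.presso.estimate)
        return [e for e in out if e is not None]

    def to_rows(self) -> list[dict]:
        """Rows for the results table, one per method."""
        shared = {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "cochran_q": self.heterogeneity.Q if self.heterogeneity else None,
            "cochran_q_pvalue": self.heterogeneity.pvalue if self.heterogeneity else None,
            "presso_global_rss": self.presso.rss_obs if self.presso else None,
            "presso_global_pvalue": self.presso.global_pvalue if self.presso else None,
            "egger_intercept": self.pleiotropy.intercept if self.pleiotropy else None,
            "egger_intercept_pvalue": self.pleiotropy.pvalue if self.pleiotropy else None,
            "f_statistic_min": self.f_min,
        }
        rows = []
        listed = [self.primary, self.egger, self.weighted_median, self.weighted_mode]
        labels = [None, "Egger", "WeightedMedian", "WeightedMode"]
        for est, label in zip(listed, labels):
            if est is None:
                continue
            rows.append(
                {
                    **shared,
                    "method": METHOD_LABELS.get(est.method, est.method),
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.odds_ratio,
                    "or_ci_low": est.or_ci_low,
                    "or_ci_high": est.or_ci_high,
                    "pvalue": est.pvalue,
                }
            )
        if self.presso is not None:
            est = self.presso.estimate
            rows.append(
                {
                    **shared,
                    "method": METHOD_LABELS["PRESSO"],
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.odds_ratio,
                    "or_ci_low": est.or_ci_low,
                    "or_ci_high": est.or_ci_high,
                    "pvalue": est.pvalue,
                }
            )
        return rows


def _wald_as_estimate(hset: HarmonizedInstrumentSet) -> MREstimate:
    ratio = wald_ratio(hset.records[0])
    est = _finalize("Wald", ratio.beta_ratio, ratio.se_ratio, 1)
    return est


def run_pair(
    exposure: SummaryStatistics,
    outcome: SummaryStatistics,
    ld: LdTable | None = None,
    instrument_config: InstrumentConfig | None = None,
    estimator_config: EstimatorConfig | None = None,
    strand_mode: str = "infer",
    preselected: bool = False,
) -> PairResult:
    """Full pipeline for one exposure-outcome pair.

    ``preselected=True`` skips the instrument-selection funnel (inputs are
    already final instruments).  Estimators that need more instruments than
    survive are recorded as not applicable rather than raising; a pair with no
    usable instrument at all becomes a skipped record.
    """
    est_cfg = estimator_config or EstimatorConfig()
    result = PairResult(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)
    try:
        if preselected:
            instruments = exposure
        else:
            instruments, result.selection = select_instruments(
                exposure, ld, instrument_config
            )
        hset = build_instrument_set(instruments, outcome, strand_mode=strand_mode)
    except (EmptyInstrumentSetError, GutmrError) as exc:
        result.status = "skipped"
        result.skip_reason = str(exc)
        return result

    result.hset = hset
    result.f_min = float(hset.f_stats.min())

    if hset.n_snp == 1:
        result.primary = _wald_as_estimate(hset)
        result.not_applicable = ["IVW", "Egger", "WeightedMedian", "WeightedMode", "PRESSO", "Q", "LOO"]
        result.direction_consistent = True
        return result

    result.ivw_fixed = ivw(hset, model="fixed")
    result.ivw_random = ivw(hset, model="random")
    result.primary = ivw(hset, model=est_cfg.ivw_model)
    result.heterogeneity = cochran_q(hset)

    for name, fn in (
        ("Egger", lambda: mr_egger(hset)),
        ("WeightedMedian", lambda: weighted_median(hset, est_cfg)),
        ("WeightedMode", lambda: weighted_mode(hset, est_cfg)),
        ("PRESSO", lambda: mr_presso(hset, est_cfg)),
        ("LOO", lambda: leave_one_out(hset, model="fixed")),
    ):
        try:
            value = fn()
        except InsufficientInstrumentsError:
            result.not_applicable.append(name)
            continue
        if name == "Egger":
            result.egger, result.pleiotropy = value
        elif name == "WeightedMedian":
            result.weighted_median = value
        elif name == "WeightedMode":
            result.weighted_mode = value
        elif name == "PRESSO":
            result.presso = value
        else:
            result.loo = value

    signs = {np.sign(e.beta) for e in result.estimates() if e.beta != 0}
    result.direction_consistent = len(signs) <= 1
    return result


def run_batch(
    exposures: list[SummaryStatistics],
    outcome: SummaryStatistics,
    ld: LdTable | None = None,
    instrument_config: InstrumentConfig | None = None,
    estimator_config: EstimatorConfig | None = None,
    strand_mode: str = "infer",
    preselected: bool = False,
) -> list[PairResult]:
    """All exposures against one outcome; BH-FDR family = this outcome."""
    if not exposures:
        raise GutmrError("run_batch needs at least one exposure")
    results = [
        run_pair(
            exp, outcome, ld=ld,
            instrument_config=instrument_config,
            estimator_config=estimator_config,
            strand_mode=strand_mode,
            preselected=preselected,
        )
        for exp in exposures
    ]
    tested = [r for r in results if r.status == "ok" and r.primary is not None]
    if tested:
        qvals = bh_fdr([r.primary.pvalue for r in tested])
        for r, q in zip(tested, qvals):
            r.fdr = FdrRecord(
                exposure_id=r.exposure_id,
                outcome_id=r.outcome_id,
                primary_p=r.primary.pvalue,
                q=float(q),
                klass=classify(r.primary.pvalue, float(q)),
            )
    return results


def run_reverse(
    outcome_as_exposure: SummaryStatistics,
    exposure_as_outcome: SummaryStatistics,
    ld: LdTable | None = None,
    instrument_config: InstrumentConfig | None = None,
    estimator_config: EstimatorConfig | None = None,
    strand_mode: str = "infer",
    preselected: bool = False,
) -> PairResult:
    """Reverse MR: the disease GWAS supplies instruments, the taxon is outcome."""
    return run_pair(
        outcome_as_exposure,
        exposure_as_outcome,
        ld=ld,
        instrument_config=instrument_config,
        estimator_config=estimator_config,
        strand_mode=strand_mode,
        preselected=preselected,
    )


def reverse_rows(result: PairResult) -> list[dict]:
    """Reverse-MR table rows: fixed and random IVW with beta-scale CIs."""
    rows = []
    for est in (result.ivw_fixed, result.ivw_random):
        if est is None:
            continue
        rows.append(
            {
                "exposure": result.exposure_id,
                "outcome": result.outcome_id,
                "method": METHOD_LABELS[est.method],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
            }
        )
    return rows
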