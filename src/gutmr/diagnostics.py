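"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q tests heterogeneity of the per-SNP Wald ratios around the
fixed-effect IVW estimate; leave-one-out re-estimation flags results driven
by a single variant; funnel coordinates (ratio vs precision) support the
visual symmetry check for directional bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate, _ivw_core, _ratio_arrays, ivw, _require
from .harmonize import HarmonizedInstrumentSet


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class FunnelPoint:
    snp_id: str
    beta_ratio: float
    precision: float  # 1 / se_ratio


@dataclass
class LeaveOneOutResult:
    """Per-SNP IVW re-estimates with the named SNP excluded."""

    rows: pd.DataFrame  # columns: excluded_snp, beta, se, pvalue
    full: MREstimate
    sign_change: bool
    significance_change: bool

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def cochran_q(hset: HarmonizedInstrumentSet) -> HeterogeneityResult:
    """Q = sum w_j (beta_j - beta_IVW_fixed)^2, chi-square with J-1 df."""
    _require(hset, 2, "Cochran's Q")
    b, w = _ratio_arrays(hset)
    _, _, q = _ivw_core(b, w)
    df = hset.n_snp - 1
    return HeterogeneityResult(Q=q, df=df, pvalue=float(sps.chi2.sf(q, df)))


def leave_one_out(
    hset: HarmonizedInstrumentSet, model: str = "fixed"
) -> LeaveOneOutResult:
    """IVW re-estimated J times, each time excluding one SNP.

    ``sign_change`` is set when any reduced estimate's sign differs from the
    full estimate; ``significance_change`` when any reduced p crosses 0.05
    relative to the full p.
    """
    _require(hset, 3, "leave-one-out")
    full = ivw(hset, model=model)
    rows = []
    for snp in hset.snp_ids:
        est = ivw(hset.exclude([snp]), model=model)
        rows.append((snp, est.beta, est.se, est.pvalue))
    df = pd.DataFrame(rows, columns=["excluded_snp", "beta", "se", "pvalue"])
    sign_change = bool(np.any(np.sign(df["beta"]) != np.sign(full.beta)))
    significance_change = bool(np.any((df["pvalue"] < 0.05) != (full.pvalue < 0.05)))
    return LeaveOneOutResult(
        rows=df, full=full, sign_change=sign_change, significance_change=significance_change
    )


def funnel_coordinates(hset: HarmonizedInstrumentSet) -> list[FunnelPoint]:
    """Plotting-ready (ratio, precision) coordinates, one per kept SNP."""
    _require(hset, 1, "funnel coordinates")
    b, w = _ratio_arrays(hset)
    return [
        FunnelPoint(snp_id=s, beta_ratio=float(bi), precision=float(np.sqrt(wi)))
        for s, bi, wi in zip(hset.snp_ids, b, w)
    ]
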