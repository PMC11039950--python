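"""The five summary-data MR causal estimators.

Each SNP j contributes a Wald ratio beta_j = Gamma_j / gamma_j with
first-order SE sigma_Yj / |gamma_j| and inverse-variance weight
w_j = gamma_j^2 / sigma_Yj^2.  On top of the ratios:

* IVW — inverse-variance weighted mean of the ratios; fixed-effect SE
  (sum w)^(-1/2), multiplicative random-effect SE scaled by
  max(1, sqrt(Q/(J-1))), or ``auto`` which picks random iff Cochran's Q has
  p < 0.05.
* MR-Egger — weighted regression of Gamma on gamma with a free intercept
  (records oriented to gamma >= 0); a nonzero intercept signals directional
  horizontal pleiotropy.
* Weighted median — the ratio at the 50% point of the inverse-variance
  cumulative weight distribution, linearly interpolated; consistent when
  valid instruments carry at least half the weight.
* Weighted mode — argmax of a weighted Gaussian kernel density over the
  ratios (modified Silverman bandwidth); consistent when the largest cluster
  of similar ratios comes from valid instruments.
* MR-PRESSO — simulation-based residual-sum-of-squares global pleiotropy
  test, per-SNP outlier tests (Bonferroni), outlier-corrected IVW, and a
  distortion test.

Bootstrap SEs (median/mode) and PRESSO simulations are parametric and fully
seeded; all two-sided p-values use the normal distribution, the convention of
summary-data MR toolchains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats as sps

from .exceptions import (
    ConfigError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .harmonize import HarmonizedInstrumentSet, HarmonizedRecord

Z975 = float(sps.norm.ppf(0.975))

MODE_GRID_POINTS = 512  # density argmax grid resolution


@dataclass
class EstimatorConfig:
    """Tuning constants for the resampling-based estimators."""

    n_boot: int = 1000
    seed: int | None = None
    phi: float = 1.0  # mode bandwidth multiplier
    presso_k: int = 1000
    presso_outlier_alpha: float = 0.05
    ivw_model: str = "auto"  # fixed | random | auto
    wald_se_order: int = 1

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ConfigError(f"n_boot must be >= 100, got {self.n_boot}")
        if self.presso_k < 100:
            raise ConfigError(f"presso_k must be >= 100, got {self.presso_k}")
        if self.ivw_model not in ("fixed", "random", "auto"):
            raise ConfigError(f"ivw_model must be fixed|random|auto, got {self.ivw_model}")
        if self.wald_se_order not in (1, 2):
            raise ConfigError("wald_se_order must be 1 or 2")


@dataclass(frozen=True)
class RatioEstimate:
    snp_id: str
    beta_ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio ** 2


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds-per-SD scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test: intercept ~ 0 means no directional pleiotropy."""

    intercept: float
    se: float
    pvalue: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion tests."""

    rss_obs: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]  # Bonferroni-adjusted, per SNP
    outlier_snps: list[str]
    estimate_all: MREstimate
    estimate_corrected: MREstimate | None
    distortion_pct: float | None
    distortion_pvalue: float | None
    k: int

    @property
    def estimate(self) -> MREstimate:
        """Outlier-corrected IVW when outliers were removed, else the raw IVW."""
        return self.estimate_corrected if self.estimate_corrected is not None else self.estimate_all


def _finalize(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    beta, se = float(beta), float(se)
    p = float(2.0 * sps.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        pvalue=p,
        n_snp=n_snp,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
    )


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, 95% CI low, 95% CI high)."""
    if se < 0:
        raise ConfigError(f"se must be >= 0, got {se}")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z975 * se)),
        float(np.exp(beta + Z975 * se)),
    )


def wald_ratio(record: HarmonizedRecord, se_order: int = 1) -> RatioEstimate:
    """Per-SNP causal estimate Gamma/gamma with first- or second-order SE."""
    if record.gamma == 0:
        raise DegenerateInstrumentError(f"{record.snp_id}: gamma = 0, Wald ratio undefined")
    beta = record.Gamma / record.gamma
    se = record.sigma_y / abs(record.gamma)
    if se_order == 2:
        se = float(
            np.sqrt(
                record.sigma_y ** 2 / record.gamma ** 2
                + record.Gamma ** 2 * record.sigma_x ** 2 / record.gamma ** 4
            )
        )
    return RatioEstimate(snp_id=record.snp_id, beta_ratio=float(beta), se_ratio=float(se))


def _ratio_arrays(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """(ratios, inverse-variance weights) for a harmonized set."""
    gamma, Gamma, sigma_y = hset.gamma, hset.Gamma, hset.sigma_y
    if np.any(gamma == 0):
        bad = [s for s, g in zip(hset.snp_ids, gamma) if g == 0]
        raise DegenerateInstrumentError(f"gamma = 0 for {bad}")
    return Gamma / gamma, gamma ** 2 / sigma_y ** 2


def _require(hset: HarmonizedInstrumentSet, minimum: int, method: str) -> None:
    if hset.n_snp < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} instruments, got {hset.n_snp} "
            f"({hset.exposure_id} -> {hset.outcome_id})"
        )


def _ivw_core(b: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """(estimate, fixed-effect SE, Cochran's Q)."""
    sw = w.sum()
    est = float((w * b).sum() / sw)
    q = float((w * (b - est) ** 2).sum())
    return est, float(sw ** -0.5), q


def ivw(hset: HarmonizedInstrumentSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted meta-analysis of the per-SNP Wald ratios."""
    _require(hset, 2, "IVW")
    b, w = _ratio_arrays(hset)
    est, se_fixed, q = _ivw_core(b, w)
    j = hset.n_snp
    if model == "auto":
        q_p = float(sps.chi2.sf(q, j - 1))
        model = "random" if q_p < 0.05 else "fixed"
    if model == "fixed":
        return _finalize("IVW_fixed", est, se_fixed, j)
    if model == "random":
        scale = max(1.0, float(np.sqrt(q / (j - 1))))
        return _finalize("IVW_random", est, se_fixed * scale, j)
    raise ConfigError(f"unknown IVW model {model!r}")


def mr_egger(hset: HarmonizedInstrumentSet) -> tuple[MREstimate, PleiotropyResult]:
    """Weighted regression of Gamma on gamma with a free intercept.

    Records are oriented so every gamma >= 0 (the estimate is orientation
    dependent); weights are 1/sigma_Y^2 and both SEs carry the multiplicative
    random-effect scale max(1, residual sd).
    """
    _require(hset, 3, "MR-Egger")
    sign = np.where(hset.gamma < 0, -1.0, 1.0)
    g = hset.gamma * sign
    G = hset.Gamma * sign
    w = 1.0 / hset.sigma_y ** 2
    X = np.column_stack([np.ones_like(g), g])
    xtw = X.T * w
    cov_unscaled = np.linalg.inv(xtw @ X)
    coef = cov_unscaled @ (xtw @ G)
    resid = G - X @ coef
    j = hset.n_snp
    sigma2 = float((w * resid ** 2).sum() / (j - 2))
    scale = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    slope = _finalize("Egger", coef[1], se[1], j)
    icpt_p = float(2.0 * sps.norm.sf(abs(coef[0]) / se[0]))
    return slope, PleiotropyResult(intercept=float(coef[0]), se=float(se[0]), pvalue=icpt_p)


def _weighted_median_core(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized weighted median with linear breakpoint interpolation.

    Rows are independent problems: ratios are sorted, normalized weights u_j
    define breakpoints (cumsum u)_j - u_j/2, and the estimate interpolates the
    ratio at cumulative weight 0.5.
    """
    b = np.atleast_2d(np.asarray(b, float))
    w = np.atleast_2d(np.asarray(w, float))
    order = np.argsort(b, axis=1)
    bs = np.take_along_axis(b, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    cw = np.cumsum(ws, axis=1)
    perc = (cw - ws / 2.0) / cw[:, -1:]
    k = np.sum(perc < 0.5, axis=1)  # index of first breakpoint >= 0.5
    est = np.empty(b.shape[0])
    at_start = k == 0
    est[at_start] = bs[at_start, 0]
    mid = ~at_start
    rows = np.nonzero(mid)[0]
    i = k[rows]
    p_lo, p_hi = perc[rows, i - 1], perc[rows, i]
    b_lo, b_hi = bs[rows, i - 1], bs[rows, i]
    est[mid] = b_lo + (b_hi - b_lo) * (0.5 - p_lo) / (p_hi - p_lo)
    return est


def _mode_bandwidth(b: np.ndarray, phi: float) -> np.ndarray:
    """Modified Silverman bandwidth, rows independent: phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5)."""
    b = np.atleast_2d(b)
    j = b.shape[1]
    sd = b.std(axis=1, ddof=1)
    mad = np.median(np.abs(b - np.median(b, axis=1, keepdims=True)), axis=1)
    return phi * 0.9 * np.minimum(sd, mad / 0.6745) * j ** (-0.2)


def _weighted_mode_core(b: np.ndarray, w: np.ndarray, phi: float) -> np.ndarray:
    """Vectorized weighted KDE mode over a fixed grid spanning the ratios."""
    b = np.atleast_2d(np.asarray(b, float))
    w = np.atleast_2d(np.asarray(w, float))
    u = w / w.sum(axis=1, keepdims=True)
    h = _mode_bandwidth(b, phi)
    est = np.empty(b.shape[0])
    degenerate = h <= 0
    est[degenerate] = b[degenerate, 0]  # all ratios identical
    live = np.nonzero(~degenerate)[0]
    if live.size:
        lo = b[live].min(axis=1) - 3 * h[live]
        hi = b[live].max(axis=1) + 3 * h[live]
        t = np.linspace(0.0, 1.0, MODE_GRID_POINTS)
        grid = lo[:, None] + (hi - lo)[:, None] * t[None, :]  # (rows, G)
        # kernel evaluated in float32 in-place: the argmax over a 512-point
        # grid is insensitive to single-precision rounding of the density
        z = (grid[:, :, None] - b[live][:, None, :]).astype(np.float32)
        z /= h[live][:, None, None].astype(np.float32)
        np.multiply(z, z, out=z)
        z *= -0.5
        np.exp(z, out=z)
        z *= u[live][:, None, :].astype(np.float32)
        dens = z.sum(axis=2)
        est[live] = grid[np.arange(live.size), dens.argmax(axis=1)]
    return est


def _parametric_bootstrap(
    hset: HarmonizedInstrumentSet,
    estimator: Callable[[np.ndarray, np.ndarray], np.ndarray],
    config: EstimatorConfig,
    rng: np.random.Generator,
    chunk: int = 250,
) -> float:
    """SD of re-estimates over parametric draws of (gamma_hat, Gamma_hat)."""
    gamma, sigma_x = hset.gamma, hset.sigma_x
    Gamma, sigma_y = hset.Gamma, hset.sigma_y
    out = np.empty(config.n_boot)
    done = 0
    while done < config.n_boot:
        m = min(chunk, config.n_boot - done)
        g = rng.normal(gamma, sigma_x, size=(m, gamma.size))
        G = rng.normal(Gamma, sigma_y, size=(m, gamma.size))
        g = np.where(g == 0, np.finfo(float).tiny, g)
        out[done:done + m] = estimator(G / g, g ** 2 / sigma_y ** 2)
        done += m
    return float(out.std(ddof=1))


def weighted_median(
    hset: HarmonizedInstrumentSet, config: EstimatorConfig | None = None
) -> MREstimate:
    """Inverse-variance weighted median of the ratios, bootstrap SE."""
    config = config or EstimatorConfig()
    _require(hset, 3, "weighted median")
    b, w = _ratio_arrays(hset)
    est = float(_weighted_median_core(b, w)[0])
    rng = np.random.default_rng(config.seed)
    se = _parametric_bootstrap(hset, _weighted_median_core, config, rng)
    return _finalize("WeightedMedian", est, se, hset.n_snp)


def weighted_mode(
    hset: HarmonizedInstrumentSet, config: EstimatorConfig | None = None
) -> MREstimate:
    """Weighted kernel-density mode of the ratios, bootstrap SE."""
    config = config or EstimatorConfig()
    _require(hset, 3, "weighted mode")
    b, w = _ratio_arrays(hset)
    est = float(_weighted_mode_core(b, w, config.phi)[0])
    rng = np.random.default_rng(config.seed)
    se = _parametric_bootstrap(
        hset, lambda bb, ww: _weighted_mode_core(bb, ww, config.phi), config, rng, chunk=200
    )
    return _finalize("WeightedMode", est, se, hset.n_snp)


def _loo_slopes(g: np.ndarray, G: np.ndarray, sigma_y: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for every SNP, rows independent (2-D safe)."""
    w = g ** 2 / sigma_y ** 2
    wb = g * G / sigma_y ** 2  # w * ratio
    s0 = w.sum(axis=-1, keepdims=True)
    s1 = wb.sum(axis=-1, keepdims=True)
    return (s1 - wb) / (s0 - w)


def mr_presso(
    hset: HarmonizedInstrumentSet, config: EstimatorConfig | None = None
) -> PressoResult:
    """MR-PRESSO: global RSS test, per-SNP outlier tests, corrected estimate.

    Observed residuals use the leave-one-out IVW prediction for each SNP;
    the null distribution of the weighted RSS comes from K parametric
    simulations of both sides' effects.  Outliers are SNPs whose observed
    weighted squared residual is extreme among its simulated counterparts
    (Bonferroni over J); the corrected estimate is fixed-effect IVW on the
    non-outliers, with a resampling distortion test.
    """
    config = config or EstimatorConfig()
    _require(hset, 4, "MR-PRESSO")
    rng = np.random.default_rng(config.seed)
    gamma, sigma_x = hset.gamma, hset.sigma_x
    Gamma, sigma_y = hset.Gamma, hset.sigma_y
    j = hset.n_snp
    k = config.presso_k
    wy = 1.0 / sigma_y ** 2

    beta_loo = _loo_slopes(gamma[None, :], Gamma[None, :], sigma_y)[0]
    r_obs = Gamma - beta_loo * gamma
    obs_terms = wy * r_obs ** 2
    rss_obs = float(obs_terms.sum())

    G_sim = rng.normal(beta_loo * gamma, sigma_y, size=(k, j))
    g_sim = rng.normal(gamma, sigma_x, size=(k, j))
    g_sim = np.where(g_sim == 0, np.finfo(float).tiny, g_sim)
    beta_loo_sim = _loo_slopes(g_sim, G_sim, sigma_y)
    r_sim = G_sim - beta_loo_sim * g_sim
    sim_terms = wy * r_sim ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (k + 1))
    p_raw = (1 + (sim_terms >= obs_terms).sum(axis=0)) / (k + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outlier_mask = p_adj < config.presso_outlier_alpha
    outliers = [s for s, m in zip(hset.snp_ids, outlier_mask) if m]

    estimate_all = ivw(hset, model="fixed")
    estimate_corrected = None
    distortion_pct = None
    distortion_p = None
    n_out = int(outlier_mask.sum())
    if 0 < n_out <= j - 2:
        reduced = hset.exclude(outliers)
        est_c = ivw(reduced, model="fixed")
        estimate_corrected = MREstimate(
            method="PRESSO_corrected",
            beta=est_c.beta,
            se=est_c.se,
            pvalue=est_c.pvalue,
            n_snp=est_c.n_snp,
            ci_low=est_c.ci_low,
            ci_high=est_c.ci_high,
        )
        if est_c.beta != 0:
            distortion_pct = float(100.0 * (est_c.beta - estimate_all.beta) / abs(est_c.beta))
            b_all, w_all = _ratio_arrays(hset)
            d_sim = np.empty(k)
            for i in range(k):
                drop = rng.choice(j, size=n_out, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                est_i = float((w_all[mask] * b_all[mask]).sum() / w_all[mask].sum())
                d_sim[i] = 100.0 * (est_i - estimate_all.beta) / abs(est_i) if est_i != 0 else np.inf
            distortion_p = float((1 + (np.abs(d_sim) >= abs(distortion_pct)).sum()) / (k + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=dict(zip(hset.snp_ids, p_adj.astype(float))),
        outlier_snps=outliers,
        estimate_all=estimate_all,
        estimate_corrected=estimate_corrected,
        distortion_pct=distortion_pct,
        distortion_pvalue=distortion_p,
        k=k,
    )
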