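"""Two-sample MR estimators and sensitivity statistics.

Implements the Wald ratio (single instrument), inverse-variance
weighted (IVW) meta-analysis, MR-Egger regression with its pleiotropy
intercept test, the weighted median and weighted mode, and Cochran's Q
heterogeneity statistic.  ``mr_auto`` dispatches on the instrument
count: one instrument gives the Wald ratio only; two give IVW plus Q;
three or more add the pleiotropy-robust estimators.

Conventions: all p-values are two-sided normal and confidence
intervals use +/- 1.96 SE.  IVW defaults to multiplicative
random-effects (residual scale floored at 1); MR-Egger orients every
instrument so the exposure effect is non-negative before regressing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import HarmonizedDataset

Z95 = 1.96


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    ci_low: float = None  # type: ignore[assignment]
    ci_high: float = None  # type: ignore[assignment]
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError("estimate se must be positive and finite")
        if self.ci_low is None:
            self.ci_low = self.beta - Z95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z95 * self.se


@dataclass
class QResult:
    q: float
    df: int
    pval: float


def _p_from_z(beta: float, se: float) -> float:
    p = 2 * stats.norm.sf(abs(beta / se))
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def _as_arrays(data: HarmonizedDataset):
    return data.bx, data.bxse, data.by, data.byse


# ---------------------------------------------------------------------------
# Single-instrument estimator
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, bxse: float, by: float, byse: float) -> MREstimate:
    """Single-instrument causal estimate ``by / bx`` with first-order
    standard error ``byse / |bx|``."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    beta = by / bx
    se = byse / abs(bx)
    return MREstimate(method="wald", beta=beta, se=se,
                      pval=_p_from_z(beta, se), nsnp=1)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(data: HarmonizedDataset, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate: the zero-intercept weighted
    regression of outcome on exposure effects with weights 1/byse².

    ``fixed`` uses the analytic SE ``1/sqrt(sum(bx^2/byse^2))``;
    ``multiplicative_random`` (default) multiplies it by the residual
    standard deviation of the weighted fit, floored at 1.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError("mode must be 'fixed' or 'multiplicative_random'")
    bx, _, by, byse = _as_arrays(data)
    if data.nsnp < 2:
        raise InsufficientInstrumentsError("IVW requires >= 2 instruments")
    w = 1.0 / byse**2
    denom = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / denom
    se = 1.0 / np.sqrt(denom)
    resid = (by - beta * bx) / byse
    scale = np.sqrt(np.sum(resid**2) / (data.nsnp - 1))
    if mode == "multiplicative_random":
        se *= max(1.0, scale)
    return MREstimate(method="ivw", beta=float(beta), se=float(se),
                      pval=_p_from_z(beta, se), nsnp=data.nsnp,
                      extra={"mode": mode, "residual_scale": float(scale)})


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(data: HarmonizedDataset) -> MREstimate:
    """Weighted regression of outcome on exposure effects with a free
    intercept; the intercept estimates directional pleiotropy.

    Instruments are oriented so bx >= 0.  Slope and intercept SEs are
    inflated by the residual SD of the weighted fit, floored at 1 (the
    multiplicative random-effects convention).
    """
    if data.nsnp < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    bx, _, by, byse = _as_arrays(data)
    flip = np.where(bx < 0, -1.0, 1.0)
    x = bx * flip
    y = by * flip
    w = 1.0 / byse**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = (y - X @ coef) * np.sqrt(w)
    scale = np.sqrt(np.sum(resid**2) / (data.nsnp - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, scale) ** 2
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    return MREstimate(
        method="egger", beta=float(slope), se=float(se_slope),
        pval=_p_from_z(slope, se_slope), nsnp=data.nsnp,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": _p_from_z(intercept, se_int),
            "residual_scale": float(scale),
        },
    )


# ---------------------------------------------------------------------------
# Weighted median / mode
# ---------------------------------------------------------------------------

def _ratios_and_weights(data: HarmonizedDataset):
    bx, _, by, byse = _as_arrays(data)
    ratios = by / bx
    w = (bx / byse) ** 2
    return ratios, w / w.sum()


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # standardized cumulative weights
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _bootstrap_se(data: HarmonizedDataset, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample per-SNP effects from their normal
    sampling distributions and recompute the point estimate."""
    rng = np.random.default_rng(seed)
    bx, bxse, by, byse = _as_arrays(data)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + bxse * rng.standard_normal(len(bx))
        by_b = by + byse * rng.standard_normal(len(by))
        bx_b = np.where(bx_b == 0, 1e-300, bx_b)
        ratios = by_b / bx_b
        w = (bx_b / byse) ** 2
        est[b] = point_fn(ratios, w / w.sum())
    return float(np.std(est, ddof=1))


def weighted_median(data: HarmonizedDataset, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of per-SNP Wald ratios; consistent when at least
    half the weight comes from valid instruments.  SE by parametric
    bootstrap."""
    if data.nsnp < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    ratios, w = _ratios_and_weights(data)
    beta = _weighted_median_point(ratios, w)
    se = _bootstrap_se(data, _weighted_median_point, n_boot, seed)
    return MREstimate(method="weighted_median", beta=beta, se=se,
                      pval=_p_from_z(beta, se), nsnp=data.nsnp,
                      extra={"n_boot": n_boot, "seed": seed})


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    mad = np.median(np.abs(ratios - np.median(ratios))) / stats.norm.ppf(0.75)
    spread = min(np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0, mad)
    if spread <= 0:
        spread = max(np.std(ratios, ddof=1), 1e-12)
    return factor * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth: float) -> float:
    if bandwidth <= 0 or np.ptp(ratios) == 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min(), ratios.max(), 512)
    dens = (weights[None, :]
            * stats.norm.pdf(grid[:, None], loc=ratios[None, :], scale=bandwidth)
            ).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(data: HarmonizedDataset, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the inverse-variance-weighted kernel density of per-SNP
    ratios (normal kernel; bandwidth from a MAD-based rule scaled by
    ``bandwidth_factor``).  SE by parametric bootstrap."""
    if data.nsnp < 3:
        raise InsufficientInstrumentsError("weighted mode requires >= 3 instruments")
    ratios, w = _ratios_and_weights(data)
    h = _mode_bandwidth(ratios, bandwidth_factor)
    beta = _weighted_mode_point(ratios, w, h)

    def point_fn(r, wt):
        return _weighted_mode_point(r, wt, _mode_bandwidth(r, bandwidth_factor))

    se = _bootstrap_se(data, point_fn, n_boot, seed)
    return MREstimate(method="weighted_mode", beta=beta, se=se,
                      pval=_p_from_z(beta, se), nsnp=data.nsnp,
                      extra={"bandwidth": h, "n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

def cochran_q(data: HarmonizedDataset) -> QResult:
    """Cochran's Q across instruments' ratio estimates.

    ``Q = sum_j w_j (ratio_j - beta_ivw)^2`` with weights
    ``w_j = (bx_j / byse_j)^2`` and the fixed-effect IVW estimate;
    p-value from the upper chi-square tail at ``nsnp - 1`` df.
    """
    if data.nsnp < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    bx, _, by, byse = _as_arrays(data)
    ratios = by / bx
    w = (bx / byse) ** 2
    beta_ivw = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = data.nsnp - 1
    return QResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def cochran_q_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square probability for a reported Q statistic."""
    if q < 0 or df < 1:
        raise ValueError("require q >= 0 and df >= 1")
    return float(stats.chi2.sf(q, df))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

@dataclass
class MRResult:
    """Primary estimate plus applicable sensitivity analyses."""

    primary: MREstimate
    estimates: dict[str, MREstimate]
    q: QResult | None = None


def mr_auto(data: HarmonizedDataset, ivw_mode: str = "multiplicative_random",
            n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Run every estimator the instrument count permits.

    One instrument: Wald ratio only.  Two: IVW plus Cochran's Q (the
    robust estimators all need >= 3 instruments).  Three or more: IVW,
    MR-Egger, weighted median, weighted mode and Q.
    """
    if data.nsnp < 1:
        raise InsufficientInstrumentsError("no instruments after harmonization")
    if data.nsnp == 1:
        est = wald_ratio(data.bx[0], data.bxse[0], data.by[0], data.byse[0])
        return MRResult(primary=est, estimates={"wald": est}, q=None)
    estimates = {"ivw": ivw(data, mode=ivw_mode)}
    if data.nsnp >= 3:
        estimates["egger"] = mr_egger(data)
        estimates["weighted_median"] = weighted_median(data, n_boot, seed)
        estimates["weighted_mode"] = weighted_mode(data, 1.0, n_boot, seed)
    return MRResult(primary=estimates["ivw"], estimates=estimates,
                    q=cochran_q(data))
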