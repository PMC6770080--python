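"""Core two-sample MR estimators.

Notation: for instrument k, ``E_k`` is the per-allele effect on the exposure
(mg/L of alpha-tocopherol) with standard error ``sigma_Ek``, and ``D_k`` the
per-allele effect on the outcome (log-odds or SD units) with standard error
``sigma_Dk``.

The per-SNP causal estimate is the Wald ratio ``D_k / E_k`` with first-order
delta-method standard error ``sigma_Dk / |E_k|`` (exposure-side uncertainty
ignored; see docs/methods.md). The fixed-effect inverse-variance-weighted
(IVW) pool is

    beta_IVW = sum(E_k * D_k / sigma_Dk^2) / sum(E_k^2 / sigma_Dk^2)
    SE(beta_IVW) = sqrt(1 / sum(E_k^2 / sigma_Dk^2))

which is algebraically identical to the inverse-variance-weighted mean of
the Wald ratios. Between-instrument heterogeneity is quantified by Cochran's
Q, I² and the DerSimonian–Laird tau²; when the heterogeneity test rejects,
pooling switches to an additive random-effects model that re-weights the
Wald ratios by 1/(se_k² + tau²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ScaleMismatchError,
)
from .summary_io import HarmonizedPair, InstrumentSet

#: Two-sided 95% normal quantile used for every confidence interval.
Z_975: float = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal effect of a 1-unit exposure increase, D_k / E_k."""

    rsid: str
    ratio: float
    se: float


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q dispersion of Wald ratios around the fixed-effect pool.

    ``i2`` is the fraction of dispersion beyond chance, max(0, (Q-df)/Q);
    ``tau2`` the DerSimonian–Laird additive between-SNP variance. ``p_het``
    is None when df == 0 (a single instrument carries no dispersion
    information).
    """

    q: float
    df: int
    p_het: float | None
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledEstimate:
    """IVW-pooled causal effect per 1 mg/L of exposure, with 95% Wald CI."""

    outcome_name: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    model: str  # fixed | random
    het: HeterogeneityStats | None
    k: int
    scale: str  # log_odds | continuous
    excluded_rsids: tuple[str, ...] = ()


@dataclass(frozen=True)
class InstrumentStrength:
    """First-stage instrument strength: variance explained and F-statistic."""

    r2: float
    n: float
    k: int
    f: float


@dataclass(frozen=True)
class OddsRatio:
    """Exponentiated log-odds estimate: OR per 1-unit exposure increase."""

    or_point: float
    or_ci_low: float
    or_ci_high: float


def _usable(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    out = [p for p in pairs if p.resolution != "dropped"]
    for p in out:
        if p.exposure.beta == 0.0:
            raise DegenerateInstrumentError(
                f"{p.rsid}: exposure effect is exactly 0; Wald ratio undefined"
            )
    return out


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e = np.array([p.exposure.beta for p in pairs], dtype=float)
    d = np.array([p.outcome.beta for p in pairs], dtype=float)
    sd = np.array([p.outcome.se for p in pairs], dtype=float)
    return e, d, sd


def _finalize(
    outcome_name: str,
    beta: float,
    se: float,
    model: str,
    het: HeterogeneityStats | None,
    k: int,
    scale: str,
    excluded: tuple[str, ...] = (),
) -> PooledEstimate:
    z = beta / se
    return PooledEstimate(
        outcome_name=outcome_name,
        beta=beta,
        se=se,
        ci_low=beta - Z_975 * se,
        ci_high=beta + Z_975 * se,
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        model=model,
        het=het,
        k=k,
        scale=scale,
        excluded_rsids=excluded,
    )


def wald_ratio(pair: HarmonizedPair) -> WaldEstimate:
    """Per-SNP Wald estimate: outcome effect divided by exposure effect."""
    e = pair.exposure.beta
    if e == 0.0:
        raise DegenerateInstrumentError(f"{pair.rsid}: exposure effect is 0")
    return WaldEstimate(rsid=pair.rsid, ratio=pair.outcome.beta / e, se=pair.outcome.se / abs(e))


def heterogeneity(pairs: Iterable[HarmonizedPair], beta_fixed: float) -> HeterogeneityStats:
    """Cochran's Q of the Wald ratios around ``beta_fixed``, with I² and DL tau².

    Weights are the fixed IVW weights on the Wald-ratio scale,
    w_k = E_k² / sigma_Dk².
    """
    pairs = _usable(pairs)
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(f"heterogeneity needs k >= 2, got {k}")
    e, d, sd = _arrays(pairs)
    ratios = d / e
    w = e**2 / sd**2
    q = float(np.sum(w * (ratios - beta_fixed) ** 2))
    df = k - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q == 0.0 else max(0.0, (q - df) / q)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = 0.0 if denom <= 0 else max(0.0, (q - df) / denom)
    return HeterogeneityStats(q=q, df=df, p_het=p_het, i2=i2, tau2=tau2)


def ivw_fixed(
    pairs: Iterable[HarmonizedPair],
    outcome_name: str = "",
    scale: str = "continuous",
    excluded: tuple[str, ...] = (),
) -> PooledEstimate:
    """Fixed-effect IVW pool of the harmonized pairs."""
    pairs = _usable(pairs)
    k = len(pairs)
    if k == 0:
        raise InsufficientInstrumentsError("ivw_fixed needs at least one instrument")
    e, d, sd = _arrays(pairs)
    sw = float(np.sum(e**2 / sd**2))
    beta = float(np.sum(e * d / sd**2) / sw)
    se = math.sqrt(1.0 / sw)
    if k >= 2:
        het = heterogeneity(pairs, beta)
    else:
        het = HeterogeneityStats(q=0.0, df=0, p_het=None, i2=0.0, tau2=0.0)
    return _finalize(outcome_name, beta, se, "fixed", het, k, scale, excluded)


def ivw_random(
    pairs: Iterable[HarmonizedPair],
    outcome_name: str = "",
    scale: str = "continuous",
    excluded: tuple[str, ...] = (),
) -> PooledEstimate:
    """Additive (DerSimonian–Laird) random-effects IVW pool.

    Wald ratios are re-weighted by 1/(se_k² + tau²); with tau² = 0 this
    reduces exactly to the fixed-effect pool.
    """
    pairs = _usable(pairs)
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(f"ivw_random needs k >= 2, got {k}")
    fixed = ivw_fixed(pairs)
    tau2 = fixed.het.tau2
    e, d, sd = _arrays(pairs)
    ratios = d / e
    se_wald = sd / np.abs(e)
    w = 1.0 / (se_wald**2 + tau2)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = math.sqrt(1.0 / float(np.sum(w)))
    return _finalize(outcome_name, beta, se, "random", fixed.het, k, scale, excluded)


def pool_with_model_selection(
    pairs: Iterable[HarmonizedPair],
    het_alpha: float = 0.05,
    outcome_name: str = "",
    scale: str = "continuous",
    excluded: tuple[str, ...] = (),
) -> PooledEstimate:
    """Pool with the fixed model, switching to random effects when the
    heterogeneity test rejects (p_het < het_alpha) and k >= 2."""
    pairs = _usable(pairs)
    fixed = ivw_fixed(pairs, outcome_name, scale, excluded)
    if fixed.k >= 2 and fixed.het.p_het is not None and fixed.het.p_het < het_alpha:
        return ivw_random(pairs, outcome_name, scale, excluded)
    return fixed


def to_odds_ratio(pooled: PooledEstimate) -> OddsRatio:
    """Exponentiate a log-odds pooled estimate and its CI bounds."""
    if pooled.scale != "log_odds":
        raise ScaleMismatchError(
            f"odds-ratio transform needs a log_odds-scale estimate, got {pooled.scale!r}"
        )
    return OddsRatio(
        or_point=math.exp(pooled.beta),
        or_ci_low=math.exp(pooled.ci_low),
        or_ci_high=math.exp(pooled.ci_high),
    )


def instrument_r2(
    instruments: InstrumentSet | Iterable,
    phenotype_variance: float,
) -> float:
    """Exposure variance explained by the instruments, under Hardy–Weinberg
    equilibrium and independence: sum of 2·p·(1−p)·beta² over SNPs, divided
    by the phenotype variance. Clipped into [0, 1)."""
    if phenotype_variance <= 0:
        raise ValueError(f"phenotype_variance must be > 0, got {phenotype_variance}")
    total = 0.0
    for snp in instruments:
        if snp.eaf is None:
            raise ValueError(
                f"{snp.rsid} has no effect-allele frequency; supply r2 directly"
            )
        total += 2.0 * snp.eaf * (1.0 - snp.eaf) * snp.beta**2
    r2 = total / phenotype_variance
    return min(max(r2, 0.0), math.nextafter(1.0, 0.0))


def f_statistic(r2: float, n: float, k: int) -> InstrumentStrength:
    """First-stage F-statistic, F = ((n − k − 1)/k) · r² / (1 − r²).

    Values below ~10 are the conventional weak-instrument warning zone.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    f = ((n - k - 1) / k) * (r2 / (1.0 - r2))
    return InstrumentStrength(r2=r2, n=n, k=k, f=f)
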