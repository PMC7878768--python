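"""Multi-SNP summary-data MR: GLS combination of Wald ratios with
LD-aware weighting, instrument selection, and pleiotropic-outlier removal.

Each instrument SNP i contributes a Wald ratio b_i = beta_y(i)/beta_x(i)
estimating the causal effect b_xy of the exposure on the outcome.  The
ratios are combined by generalized least squares under their delta-method
covariance,

    v_i      = (se_y_i^2 + b_xy^2 se_x_i^2) / beta_x_i^2
    cov(i,j) = r_ij (se_y_i se_y_j + b_xy^2 se_x_i se_x_j) / (beta_x_i beta_x_j)

with r_ij the reference-panel LD correlation.  Because v_i depends on the
estimate itself, the fit starts at b_xy = 0 and iterates the variance
update to convergence.  With identity LD this reduces exactly to the
classic inverse-variance-weighted estimator of Wald ratios.

Instruments must be (a) approximately independent (LD clumping at
r^2 < 0.05), (b) genome-wide-significantly associated with the exposure
(p < 5e-8), and (c) free of visible pleiotropy — their Wald ratio must not
deviate from the consensus ratio (screen at p >= 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.stats import chi2, norm

from .ld import LdMatrix, ld_clump
from .smr import HeidiParams
from .sumstats import SumstatsTable

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


class GsmrError(ValueError):
    pass


class SingularCovarianceError(GsmrError):
    """Instrument covariance is singular (e.g. duplicate instruments)."""


class ConvergenceError(GsmrError):
    def __init__(self, msg: str, last_iterate: float):
        super().__init__(msg)
        self.last_iterate = last_iterate


class NoInstrumentsError(GsmrError):
    """No SNP survives instrument selection; carries per-stage counts."""

    def __init__(self, msg: str, stage_counts: dict[str, int]):
        super().__init__(f"{msg} (stage counts: {stage_counts})")
        self.stage_counts = stage_counts


@dataclass(frozen=True)
class InstrumentCriteria:
    """Thresholds instruments must pass, mirroring standard GSMR practice."""

    p_max: float = 5e-8
    r2_max: float = 0.05
    heidi_p_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("p_max", "r2_max", "heidi_p_min"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class MrResult:
    """Multi-SNP causal estimate for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    b_xy: float
    se: float
    p: float
    n_snps: int
    instruments: list[str]
    removed_outliers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_snps != len(self.instruments):
            raise ValueError("n_snps must equal len(instruments)")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0,1]")
        if self.se <= 0:
            raise ValueError("se must be positive")


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(values[order][min(idx, len(values) - 1)])


def select_instruments(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdMatrix,
    criteria: InstrumentCriteria | None = None,
    heidi_params: HeidiParams | None = None,
    positions: Mapping[str, int] | None = None,
) -> list[str]:
    """Clump, then screen candidate instruments for pleiotropy.

    Clumping keeps genome-wide-significant SNPs that are pairwise
    independent in the reference panel.  The pleiotropy screen compares
    each surviving SNP's Wald ratio with a robust consensus ratio (the
    inverse-variance-weighted median) and drops SNPs whose standardized
    deviation is significant at ``criteria.heidi_p_min`` — i.e. SNPs are
    retained iff their heterogeneity p-value is >= the threshold.  The
    screen needs a consensus to compare against and is skipped when fewer
    than 3 SNPs survive clumping.

    ``heidi_params`` is accepted for interface compatibility (a full
    flanking-window HEIDI screen would use it) but the deviation screen
    implemented here does not consult it.
    """
    criteria = criteria or InstrumentCriteria()
    clumped = ld_clump(exposure, ld, criteria.r2_max, criteria.p_max, positions)
    counts = {"significant_independent": len(clumped), "non_pleiotropic": 0}
    if not clumped:
        raise NoInstrumentsError(
            f"no SNP associated with {exposure.trait_id!r} at p < {criteria.p_max:g} "
            f"after clumping at r2 < {criteria.r2_max:g}", counts,
        )
    if len(clumped) < 3:
        counts["non_pleiotropic"] = len(clumped)
        return clumped
    bx, sx, _, _ = exposure.arrays(clumped)
    by, sy, _, _ = outcome.arrays(clumped)
    b = by / bx
    v0 = (sy * sy) / (bx * bx)
    ref = _weighted_median(b, 1.0 / v0)
    v = (sy * sy + ref * ref * sx * sx) / (bx * bx)
    p_dev = chi2.sf((b - ref) ** 2 / v, df=1)
    keep = p_dev >= criteria.heidi_p_min
    counts["non_pleiotropic"] = int(keep.sum())
    survivors = [snp for snp, k in zip(clumped, keep) if k]
    if not survivors:
        raise NoInstrumentsError(
            f"all candidate instruments for {exposure.trait_id!r} failed the "
            "pleiotropy screen", counts,
        )
    log.debug(
        "instrument selection %s -> %s: %s", exposure.trait_id, outcome.trait_id, counts
    )
    return survivors


def _gls_covariance(
    bx: np.ndarray, sx: np.ndarray, sy: np.ndarray, R: np.ndarray, b_xy: float
) -> np.ndarray:
    return (
        R
        * (np.outer(sy, sy) + b_xy * b_xy * np.outer(sx, sx))
        / np.outer(bx, bx)
    )


def gsmr_estimate(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdMatrix,
    instruments: Sequence[str],
    ld_scaled: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MrResult:
    """GLS estimate of b_xy from per-instrument Wald ratios.

    Tables must be harmonized and every instrument present in both tables
    and in ``ld``.  ``ld_scaled=False`` treats post-clump instruments as
    independent (diagonal covariance).
    """
    instruments = list(instruments)
    if len(instruments) < 1:
        raise GsmrError("need at least one instrument")
    if len(set(instruments)) != len(instruments):
        raise SingularCovarianceError("duplicate instruments give a singular covariance")
    bx, sx, _, _ = exposure.arrays(instruments)
    by, sy, _, _ = outcome.arrays(instruments)
    if np.any(bx == 0):
        raise GsmrError("instrument with beta_x = 0: Wald ratio undefined")
    R = ld.sub(instruments).r if ld_scaled else np.eye(len(instruments))
    b_vec = by / bx
    ones = np.ones(len(instruments))

    b_xy = 0.0
    for _ in range(max_iter):
        V = _gls_covariance(bx, sx, sy, R, b_xy)
        try:
            cf = cho_factor(V)
        except LinAlgError as e:
            raise SingularCovarianceError(
                f"instrument covariance not positive definite: {e}"
            ) from None
        vi_one = cho_solve(cf, ones)
        precision = float(ones @ vi_one)
        b_new = float(vi_one @ b_vec) / precision
        if abs(b_new - b_xy) < tol:
            b_xy = b_new
            break
        b_xy = b_new
    else:
        raise ConvergenceError(
            f"variance update did not converge in {max_iter} iterations "
            f"(last iterate {b_xy:.6g})", b_xy,
        )

    se = float(np.sqrt(1.0 / precision))
    p = float(np.clip(2.0 * norm.sf(abs(b_xy) / se), _P_FLOOR, 1.0))
    return MrResult(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        b_xy=b_xy,
        se=se,
        p=p,
        n_snps=len(instruments),
        instruments=instruments,
    )


def remove_pleiotropic_outliers(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdMatrix,
    instruments: Sequence[str],
    alpha: float = 0.01,
    ld_scaled: bool = True,
) -> tuple[list[str], list[str]]:
    """Iteratively drop the most deviant instrument until none is significant.

    At each step the GLS estimate is refit and each instrument's Wald-ratio
    deviation from it is standardized by sqrt(v_i - var(b_xy)) (the exact
    variance of b_i - b_xy under the GLS fit, since cov(b_i, b_xy) equals
    var(b_xy) for every i).  The most deviant instrument is removed when it
    exceeds the two-sided normal critical value at ``alpha``.  Stops at
    no-removal or one remaining instrument.  Returns (kept, removed).
    """
    kept = list(instruments)
    if len(kept) < 2:
        raise GsmrError("outlier removal needs at least 2 instruments")
    removed: list[str] = []
    crit = norm.ppf(1.0 - alpha / 2.0)
    while len(kept) > 1:
        res = gsmr_estimate(exposure, outcome, ld, kept, ld_scaled=ld_scaled)
        bx, sx, _, _ = exposure.arrays(kept)
        by, sy, _, _ = outcome.arrays(kept)
        b = by / bx
        v = (sy * sy + res.b_xy**2 * sx * sx) / (bx * bx)
        var_d = np.maximum(v - res.se**2, 1e-30)
        t = np.abs(b - res.b_xy) / np.sqrt(var_d)
        worst = int(np.argmax(t))
        if t[worst] <= crit:
            break
        removed.append(kept.pop(worst))
    return kept, removed


def mr_with_outlier_removal(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdMatrix,
    instruments: Sequence[str],
    alpha: float = 0.01,
    ld_scaled: bool = True,
) -> MrResult:
    """Convenience: outlier removal (when possible) followed by the GLS fit."""
    instruments = list(instruments)
    if len(instruments) >= 2:
        kept, removed = remove_pleiotropic_outliers(
            exposure, outcome, ld, instruments, alpha=alpha, ld_scaled=ld_scaled
        )
    else:
        kept, removed = instruments, []
    res = gsmr_estimate(exposure, outcome, ld, kept, ld_scaled=ld_scaled)
    return replace(res, removed_outliers=removed)
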