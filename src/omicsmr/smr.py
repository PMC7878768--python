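"""SMR co-localization test and the HEIDI heterogeneity (linkage) test.

The SMR statistic asks whether the top QTL SNP's effect on a trait is
mediated by a molecular probe.  With Z_x = beta_x/se_x for the probe and
Z_y = beta_y/se_y for the trait, the mediated effect is the Wald ratio
beta_SMR = beta_y / beta_x and its significance is

    T = (Z_y^2 * Z_x^2) / (Z_y^2 + Z_x^2)  ~  chi-square(1 df) under H0.

A significant beta_SMR is compatible with three causal structures: a
shared causal variant acting through the probe (causality), a shared
variant acting on both independently (pleiotropy), or two distinct causal
variants in LD (linkage).  HEIDI separates linkage from the first two by
testing whether the Wald ratio beta_y/beta_x is homogeneous across SNPs in
intermediate LD with the top SNP: under a single shared causal variant all
those ratios estimate the same quantity, whereas under linkage they drift
with LD.  Differences d_i = b_i - b_top are standardized using delta-method
variances with covariances induced by reference-panel LD, and the sum of
squared standardized differences is referred to a weighted sum of 1-df
chi-squares (weights = eigenvalues of the correlation matrix of the
standardized differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy import integrate
from scipy.stats import chi2

from .ld import LdError, LdMatrix
from .sumstats import SumstatsTable

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


class SmrError(ValueError):
    pass


@dataclass
class HeidiParams:
    """Selection knobs for the HEIDI flanking-SNP window.

    Defaults follow the conventions of the reference SMR implementation:
    flanking SNPs must be reasonably strong exposure instruments
    (p < 1.6e-3, i.e. |Z| > ~3.16), in intermediate LD with the top SNP
    (0.05 <= r^2 <= 0.9 — high-LD SNPs carry no independent information and
    are numerically unstable), capped at the 20 strongest-LD SNPs.
    """

    p_instrument_max: float = 1.6e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20

    def __post_init__(self) -> None:
        if not (0 <= self.r2_min < self.r2_max <= 1):
            raise ValueError("need 0 <= r2_min < r2_max <= 1")
        if self.max_snps < 1:
            raise ValueError("max_snps must be >= 1")


@dataclass
class SmrResult:
    """Top-SNP co-localization outcome for one probe-trait pair."""

    probe_id: str
    trait_id: str
    top_snp: str
    beta_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int

    def __post_init__(self) -> None:
        if (self.p_heidi is None) != (self.n_heidi_snps == 0):
            raise ValueError("p_heidi is undefined iff n_heidi_snps == 0")


class SmrTest(NamedTuple):
    beta_smr: float
    se_smr: float
    p_smr: float
    chisq: float


def select_top_snp(
    exposure: SumstatsTable, positions: Mapping[str, int] | None = None
) -> str:
    """SNP with the smallest exposure p; ties broken by position then id."""
    pos = positions or {}
    best = min(
        (row.p, pos.get(row.snp, float("inf")), row.snp)
        for row in exposure.df.itertuples()
    )
    return best[2]


def smr_test(beta_x: float, se_x: float, beta_y: float, se_y: float) -> SmrTest:
    """Single-SNP SMR test of mediation through the exposure.

    Returns (beta_smr, se_smr, p_smr, chisq).  beta_smr = beta_y/beta_x;
    se_smr = |beta_smr|/sqrt(T), infinite when T = 0.
    """
    if se_x <= 0 or se_y <= 0:
        raise SmrError("standard errors must be positive")
    if beta_x == 0:
        raise SmrError("beta_x = 0: Wald ratio undefined")
    zx = beta_x / se_x
    zy = beta_y / se_y
    t = (zy * zy * zx * zx) / (zy * zy + zx * zx)
    beta_smr = beta_y / beta_x
    p = float(np.clip(chi2.sf(t, df=1), _P_FLOOR, 1.0))
    se_smr = abs(beta_smr) / np.sqrt(t) if t > 0 else float("inf")
    return SmrTest(beta_smr, se_smr, p, t)


def _wald_ratio_covariance(
    bx: np.ndarray, sx: np.ndarray, by: np.ndarray, sy: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Delta-method covariance of per-SNP Wald ratios b_i = by_i/bx_i.

    Effect estimates at SNPs i, j within one GWAS cohort are correlated
    through LD: cov(beta_i, beta_j) ~= r_ij se_i se_j.  Exposure and
    outcome cohorts are independent (two-sample design), so

        cov(b_i, b_j) = r_ij (sy_i sy_j + b_i b_j sx_i sx_j) / (bx_i bx_j)
    """
    b = by / bx
    return R * (np.outer(sy, sy) + np.outer(b, b) * np.outer(sx, sx)) / np.outer(bx, bx)


def _satterthwaite_sf(q: float, lam: np.ndarray) -> float:
    """Two-moment approximation to P(sum lam_k chi2_1 > q)."""
    s1 = lam.sum()
    s2 = (lam * lam).sum()
    if s2 <= 0 or s1 <= 0:
        return 1.0
    scale = s2 / s1
    dof = s1 * s1 / s2
    return float(chi2.sf(q / scale, df=dof))


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    """Imhof (1961) numerical inversion for P(sum lam_k chi2_1 > q)."""

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod(1.0 + (lam * u) ** 2) ** 0.25
        return float(np.sin(theta) / (u * rho))

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def heidi_test(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LdMatrix,
    top_snp: str,
    params: HeidiParams | None = None,
    method: str = "satterthwaite",
) -> tuple[float | None, int]:
    """Heterogeneity-in-dependent-instruments test around ``top_snp``.

    Tables must already be harmonized.  Returns ``(p_heidi, n_flanking)``;
    ``(None, 0)`` when no flanking SNP qualifies.  Small p indicates a
    non-homogeneous Wald-ratio pattern, i.e. linkage rather than a shared
    causal variant.  ``method`` selects the tail approximation:
    "satterthwaite" (default) or "imhof" (exact up to quadrature).
    """
    params = params or HeidiParams()
    if top_snp not in exposure or top_snp not in outcome:
        raise SmrError(f"top SNP {top_snp!r} missing from harmonized tables")
    if top_snp not in ld:
        raise LdError(f"top SNP {top_snp!r} missing from LD matrix")

    flanking: list[tuple[float, str]] = []
    for row in exposure.df.itertuples():
        snp = row.snp
        if snp == top_snp or row.p >= params.p_instrument_max or snp not in outcome:
            continue
        if snp not in ld:
            raise LdError(f"flanking SNP {snp!r} missing from LD matrix")
        r2 = ld.r_between(snp, top_snp) ** 2
        if params.r2_min <= r2 <= params.r2_max:
            flanking.append((r2, snp))
    flanking.sort(key=lambda t: (-t[0], t[1]))
    chosen = [snp for _, snp in flanking[: params.max_snps]]
    if not chosen:
        return None, 0

    order = [top_snp] + chosen
    bx, sx, _, _ = exposure.arrays(order)
    by, sy, _, _ = outcome.arrays(order)
    if np.any(bx == 0):
        raise SmrError("flanking SNP with beta_x = 0 slipped past the p filter")
    R = ld.sub(order).r
    Vb = _wald_ratio_covariance(bx, sx, by, sy, R)
    b = by / bx
    d = b[1:] - b[0]
    Vd = Vb[1:, 1:] - Vb[1:, [0]] - Vb[[0], 1:] + Vb[0, 0]
    sd = np.sqrt(np.maximum(np.diag(Vd), 1e-30))
    z = d / sd
    stat = float(z @ z)
    if stat == 0.0:
        return 1.0, len(chosen)
    C = Vd / np.outer(sd, sd)
    lam = np.clip(np.linalg.eigvalsh(C), 0.0, None)
    if method == "satterthwaite":
        p = _satterthwaite_sf(stat, lam)
    elif method == "imhof":
        p = _imhof_sf(stat, lam)
    else:
        raise ValueError(f"unknown tail method {method!r}")
    return float(np.clip(p, _P_FLOOR, 1.0)), len(chosen)
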