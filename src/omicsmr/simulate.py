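"""Synthetic reference panels and two-sample GWAS summary statistics.

Emulates the data the pipeline consumes in the field — blood cis-QTL
studies and trait GWAS conducted in non-overlapping European cohorts, plus
a small reference genotype panel for LD — under explicit, configurable
causal structures so that every stage of the SMR/HEIDI/GSMR chain is
testable without external downloads.

Genotypes: haplotypes are drawn from a Gaussian copula with block-AR(1)
latent correlation (``block_rho`` between adjacent SNPs within a block,
independence across blocks), thresholded at each SNP's MAF quantile;
genotype = sum of two independent haplotypes.  This produces blocky LD
decaying with distance, the feature of real panels the LD-dependent tests
(clumping, HEIDI) rely on.

Traits: the exposure is x = sum_j gamma_j g_j + e, with the QTL effects
scaled so they explain ``qtl_var`` of unit total variance.  The outcome
depends on the scenario:

* ``causal``     y = b_xy x + (optional direct QTLs) + e
* ``pleiotropy`` y = b_xy x + direct effects of a fraction of x's QTLs + e
* ``linkage``    x is driven by SNP set A, y directly by a distinct set B
                 chosen so r2(A_k, B_k) is close to ``linkage_r2_target``
* ``reverse``    y is genetically driven and x = b_xy y + e
* ``null``       b_xy = 0

Summary statistics are per-SNP simple linear regressions within each of
two disjoint cohorts (normal approximation for p).  A binary-outcome
option dichotomizes the liability at a prevalence threshold and fits
per-SNP logistic regressions (log-odds effects).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm

from .ld import GenotypePanel, write_dosage_text
from .sumstats import CANON_COLUMNS, SumstatsTable, TraitKind

log = logging.getLogger(__name__)

SCENARIOS = ("causal", "pleiotropy", "linkage", "reverse", "null")

# ordered allele pairs assigned cyclically; none is strand-ambiguous
_ALLELE_PAIRS = (("A", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


def derive_seed(*keys: int) -> int:
    """Deterministic sub-seed (< 2^31) from a tuple of small integers."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated two-sample MR experiment.

    Defaults mirror the pipeline's real-data setting: GWAS cohorts of
    20 000, a reference panel of 854 (the size of a typical in-house
    LD panel), a cis-region of 200 SNPs in LD blocks of 20, ten QTLs
    explaining 10% of exposure variance, and a causal effect of 0.2
    outcome-SD per exposure-SD.
    """

    scenario: str = "causal"
    m_snps: int = 200
    block_rho: float = 0.85
    block_size: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref: int = 854
    n_x: int = 20_000
    n_y: int = 20_000
    n_qtl: int = 10
    qtl_var: float = 0.1
    b_xy: float = 0.2
    pleio_frac: float = 0.0
    pleio_var: float = 0.05
    linkage_r2_target: float = 0.5
    n_qtl_y_direct: int = 0
    y_direct_var: float = 0.0
    binary_outcome: bool = False
    prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ValueError(f"degenerate maf_range {self.maf_range}")
        if min(self.n_ref, self.n_x, self.n_y) < 2:
            raise ValueError("all sample sizes must be >= 2")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must lie in [0,1)")
        if not (0 <= self.pleio_frac <= 1):
            raise ValueError("pleio_frac must lie in [0,1]")
        induced = self.b_xy**2 + self.y_direct_var + (
            self.pleio_var if self.scenario == "pleiotropy" else 0.0
        )
        if self.qtl_var >= 1 or induced >= 1:
            raise ValueError("variance components must leave room for noise")
        if self.n_qtl < 1 or self.n_qtl > self.m_snps:
            raise ValueError("n_qtl must lie in [1, m_snps]")


@dataclass
class ScenarioTruth:
    """Ground truth recorded alongside a simulated dataset."""

    b_xy_true: float
    causal_snps_x: list[str]
    pleiotropic_snps: list[str]
    causal_snps_y_direct: list[str]


def _snp_ids(m: int) -> list[str]:
    return [f"rs{j + 1}" for j in range(m)]


def snp_positions(snp_ids: list[str]) -> dict[str, int]:
    """1-based bp positions implied by the generator's id scheme (1 kb grid)."""
    return {s: int(s[2:]) * 1000 for s in snp_ids}


def _latent_ar1(
    rng: np.random.Generator, n: int, m: int, rho: float, block_size: int
) -> np.ndarray:
    """Stationary AR(1) latent field per block: z_j = rho z_{j-1} + sqrt(1-rho^2) e_j."""
    eps = rng.standard_normal((n, m))
    if rho == 0:
        return eps
    x = eps * math.sqrt(1.0 - rho * rho)
    x[:, ::block_size] = eps[:, ::block_size]  # each block restarts at N(0,1)
    z = np.empty_like(eps)
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        z[:, lo:hi] = lfilter([1.0], [1.0, -rho], x[:, lo:hi], axis=1)
    return z


def _draw_genotypes(
    rng: np.random.Generator, n: int, thresholds: np.ndarray, rho: float,
    block_size: int,
) -> np.ndarray:
    m = thresholds.size
    h1 = _latent_ar1(rng, n, m, rho, block_size) < thresholds
    h2 = _latent_ar1(rng, n, m, rho, block_size) < thresholds
    return (h1.astype(np.float64) + h2)


def _streams(config: ScenarioConfig, n_children: int = 6):
    """Deterministic child RNGs: population, panel, effects, cohorts..."""
    children = np.random.SeedSequence(config.seed).spawn(n_children)
    return [np.random.default_rng(c) for c in children]


def _population(config: ScenarioConfig, rng: np.random.Generator):
    mafs = rng.uniform(*config.maf_range, size=config.m_snps)
    thresholds = norm.ppf(mafs)
    return mafs, thresholds


def simulate_panel(config: ScenarioConfig) -> GenotypePanel:
    """Reference genotype panel of ``n_ref`` samples; deterministic per seed.

    Identical to the panel returned by :func:`simulate_two_sample` for the
    same config.
    """
    rng_pop, rng_panel, *_ = _streams(config)
    _, thresholds = _population(config, rng_pop)
    G = _draw_genotypes(rng_panel, config.n_ref, thresholds, config.block_rho,
                        config.block_size)
    return GenotypePanel(_snp_ids(config.m_snps), G)


def _block_centers(config: ScenarioConfig) -> list[int]:
    n_blocks = max(1, config.m_snps // config.block_size)
    return [
        b * config.block_size + config.block_size // 2
        for b in range(n_blocks)
        if b * config.block_size + config.block_size // 2 < config.m_snps
    ]


def _pick_qtls(config: ScenarioConfig, rng: np.random.Generator,
               n: int, exclude: set[int] = frozenset()) -> list[int]:
    """Spread causal SNPs across blocks (one per block centre) when possible."""
    centers = [c for c in _block_centers(config) if c not in exclude]
    if n <= len(centers):
        return centers[:n]
    pool = [j for j in range(config.m_snps) if j not in exclude and j not in centers]
    extra = rng.choice(pool, size=n - len(centers), replace=False)
    return centers + sorted(int(e) for e in extra)


def _scaled_effects(
    rng: np.random.Generator, mafs: np.ndarray, idx: list[int], var_target: float
) -> np.ndarray:
    """Per-allele effects at ``idx`` explaining ``var_target`` of variance.

    Scaling uses the model dosage variances 2p(1-p); QTLs placed in
    distinct LD blocks are independent, so the genetic variance is the sum
    of per-SNP terms.
    """
    raw = rng.standard_normal(len(idx))
    var_g = 2.0 * mafs[idx] * (1.0 - mafs[idx])
    scale = math.sqrt(var_target / float(np.sum(raw * raw * var_g)))
    return raw * scale


def _ols_sumstats(
    G: np.ndarray, y: np.ndarray, snp_ids: list[str], trait_id: str,
    trait_kind: TraitKind | str,
) -> SumstatsTable:
    """Per-SNP simple linear regression summary statistics (normal-approx p)."""
    n = y.size
    gm = G.mean(axis=0)
    gc = G - gm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    z = beta / se
    p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    m = len(snp_ids)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    df = pd.DataFrame(
        {
            "snp": snp_ids,
            "a1": [a for a, _ in pairs],
            "a2": [b for _, b in pairs],
            "freq": gm / 2.0,
            "b": beta,
            "se": se,
            "p": p,
            "n": np.full(m, n, dtype=np.int64),
        },
        columns=CANON_COLUMNS,
    )
    return SumstatsTable(trait_id, trait_kind, df)


def _logistic_sumstats(
    G: np.ndarray, case: np.ndarray, snp_ids: list[str], trait_id: str,
    trait_kind: TraitKind | str,
) -> SumstatsTable:
    """Per-SNP logistic regression (intercept + dosage) via Newton iterations."""
    n = case.size
    y = case.astype(float)
    m = G.shape[1]
    beta = np.zeros(m)
    se = np.zeros(m)
    for j in range(m):
        x = G[:, j]
        X = np.column_stack([np.ones(n), x])
        coef = np.zeros(2)
        for _ in range(25):
            eta = X @ coef
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            XtWX = X.T @ (X * w[:, None])
            grad = X.T @ (y - mu)
            step = np.linalg.solve(XtWX, grad)
            coef += step
            if np.max(np.abs(step)) < 1e-10:
                break
        cov = np.linalg.inv(XtWX)
        beta[j] = coef[1]
        se[j] = math.sqrt(cov[1, 1])
    z = beta / se
    p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    df = pd.DataFrame(
        {
            "snp": snp_ids, "a1": [a for a, _ in pairs], "a2": [b for _, b in pairs],
            "freq": G.mean(axis=0) / 2.0, "b": beta, "se": se, "p": p,
            "n": np.full(m, n, dtype=np.int64),
        },
        columns=CANON_COLUMNS,
    )
    return SumstatsTable(trait_id, trait_kind, df)


def _linkage_pairs(
    config: ScenarioConfig, panel: GenotypePanel, qtl_idx: list[int],
    tol: float = 0.15,
) -> tuple[list[int], list[int]]:
    """Per designated LD block, pick the SNP pair (a, b) whose empirical
    panel r2 is closest to ``linkage_r2_target``; a drives the exposure and
    b the outcome.  Error when no pair comes within ``tol`` of the target."""
    ids = panel.snp_ids
    chosen_a, chosen_b = [], []
    for a0 in qtl_idx:
        block = a0 // config.block_size
        lo = block * config.block_size
        hi = min((block + 1) * config.block_size, config.m_snps)
        R = np.corrcoef(panel.dosages[:, lo:hi], rowvar=False)
        diff = np.abs(R * R - config.linkage_r2_target)
        np.fill_diagonal(diff, np.inf)
        i, j = np.unravel_index(np.argmin(diff), diff.shape)
        if diff[i, j] > tol:
            raise ValueError(
                f"linkage_r2_target={config.linkage_r2_target} unattainable in "
                f"the block of {ids[a0]} (closest within {diff[i, j]:.3f})"
            )
        chosen_a.append(lo + int(i))
        chosen_b.append(lo + int(j))
    return chosen_a, chosen_b


def simulate_two_sample(
    config: ScenarioConfig,
) -> tuple[SumstatsTable, SumstatsTable, ScenarioTruth, GenotypePanel]:
    """Simulate (exposure table, outcome table, truth, reference panel).

    The exposure and outcome cohorts are disjoint draws from the same
    population (same allele frequencies and LD), mirroring the two-sample
    MR design.
    """
    rng_pop, rng_panel, rng_eff, rng_cx, rng_cy, rng_noise = _streams(config)
    mafs, thresholds = _population(config, rng_pop)
    ids = _snp_ids(config.m_snps)
    panel = GenotypePanel(
        ids,
        _draw_genotypes(rng_panel, config.n_ref, thresholds, config.block_rho,
                        config.block_size),
    )

    qtl_idx = _pick_qtls(config, rng_eff, config.n_qtl)
    gamma = _scaled_effects(rng_eff, mafs, qtl_idx, config.qtl_var)
    b_xy = 0.0 if config.scenario == "null" else config.b_xy

    direct_idx: list[int] = []
    delta = np.empty(0)
    if config.scenario == "linkage":
        qtl_idx, direct_idx = _linkage_pairs(config, panel, qtl_idx)
        gamma = _scaled_effects(rng_eff, mafs, qtl_idx, config.qtl_var)
        delta = _scaled_effects(rng_eff, mafs, direct_idx,
                                max(b_xy * b_xy * config.qtl_var, 1e-12))
    elif config.n_qtl_y_direct > 0:
        direct_idx = _pick_qtls(config, rng_eff, config.n_qtl_y_direct,
                                exclude=set(qtl_idx))
        delta = _scaled_effects(rng_eff, mafs, direct_idx, config.y_direct_var)

    pleio_idx: list[int] = []
    alpha = np.empty(0)
    if config.scenario == "pleiotropy":
        k = max(1, round(config.pleio_frac * config.n_qtl))
        pleio_idx = qtl_idx[:k]
        alpha = _scaled_effects(rng_eff, mafs, pleio_idx, config.pleio_var)

    Gx = _draw_genotypes(rng_cx, config.n_x, thresholds, config.block_rho,
                         config.block_size)
    Gy = _draw_genotypes(rng_cy, config.n_y, thresholds, config.block_rho,
                         config.block_size)

    noise_sd_x = math.sqrt(1.0 - config.qtl_var)

    def exposure_values(G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return G[:, qtl_idx] @ gamma + rng.normal(0.0, noise_sd_x, size=G.shape[0])

    if config.scenario == "reverse":
        # y is genetically driven; x is its downstream consequence
        y_y = exposure_values(Gy, rng_noise)
        y_x_cohort = exposure_values(Gx, rng_noise)
        x = b_xy * y_x_cohort + rng_noise.normal(
            0.0, math.sqrt(max(1.0 - b_xy * b_xy, 1e-12)), size=config.n_x
        )
        y = y_y
        truth = ScenarioTruth(
            b_xy_true=b_xy,
            causal_snps_x=[],
            pleiotropic_snps=[],
            causal_snps_y_direct=[ids[j] for j in qtl_idx],
        )
    else:
        x = exposure_values(Gx, rng_noise)
        systematic = np.zeros(config.n_y)
        if config.scenario != "linkage":
            x_latent = exposure_values(Gy, rng_noise)
            systematic = b_xy * x_latent
        if len(direct_idx):
            systematic = systematic + Gy[:, direct_idx] @ delta
        if config.scenario == "pleiotropy":
            systematic = systematic + Gy[:, pleio_idx] @ alpha
        var_sys = float(np.var(systematic)) if systematic.any() else 0.0
        if var_sys >= 1.0:
            raise ValueError("systematic outcome variance >= 1; reduce effects")
        y = systematic + rng_noise.normal(0.0, math.sqrt(1.0 - var_sys),
                                          size=config.n_y)
        truth = ScenarioTruth(
            b_xy_true=b_xy,
            causal_snps_x=[ids[j] for j in qtl_idx],
            pleiotropic_snps=[ids[j] for j in pleio_idx],
            causal_snps_y_direct=[ids[j] for j in direct_idx],
        )

    exposure = _ols_sumstats(Gx, x, ids, "exposure", TraitKind.protein)
    if config.binary_outcome:
        case = y > norm.ppf(1.0 - config.prevalence)
        outcome = _logistic_sumstats(Gy, case, ids, "outcome", TraitKind.disease)
    else:
        outcome = _ols_sumstats(Gy, y, ids, "outcome", TraitKind.risk_factor)
    return exposure, outcome, truth, panel


@dataclass
class ChainConfig:
    """Study conditions for a probe -> risk factor -> disease chain.

    Each trait carries its own direct genetic component in distinct LD
    blocks, which is what makes reverse-MR informative: instruments
    selected on a downstream trait are dominated by its own QTLs, not the
    upstream trait's.  ``direction="reverse"`` makes the risk factor cause
    the probe instead (the probe has no QTLs of its own).
    """

    direction: str = "causal"  # "causal" or "reverse"
    m_snps: int = 300
    block_rho: float = 0.85
    block_size: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref: int = 854
    n_cohort: int = 20_000
    n_qtl: int = 5
    probe_qtl_var: float = 0.3
    risk_direct_var: float = 0.3
    cad_direct_var: float = 0.3
    b_probe_risk: float = 0.5
    b_risk_cad: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("causal", "reverse"):
            raise ValueError(f"unknown chain direction {self.direction!r}")
        if 3 * self.n_qtl > self.m_snps // self.block_size:
            raise ValueError("need at least 3*n_qtl LD blocks for disjoint QTL sets")


@dataclass
class ChainData:
    probe: SumstatsTable
    risk_factor: SumstatsTable
    cad: SumstatsTable
    panel: GenotypePanel
    truth: dict


def simulate_chain(config: ChainConfig) -> ChainData:
    """Three-trait, three-cohort simulation for full-pipeline gating tests.

    ``causal``:  probe -> risk factor -> CAD, with the risk factor and CAD
    each carrying independent direct QTLs.  ``reverse``: risk factor ->
    probe (and risk factor -> CAD), so probe-instrument MR shows a strong
    association that reverse-MR exposes as reverse causation.
    """
    base = ScenarioConfig(
        m_snps=config.m_snps, block_rho=config.block_rho,
        block_size=config.block_size, maf_range=config.maf_range,
        n_ref=config.n_ref, seed=config.seed,
    )
    rng_pop, rng_panel, rng_eff, rng_c1, rng_c2, rng_c3 = _streams(base)
    rng_noise = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(7)[6]
    )
    mafs, thresholds = _population(base, rng_pop)
    ids = _snp_ids(config.m_snps)
    panel = GenotypePanel(
        ids, _draw_genotypes(rng_panel, config.n_ref, thresholds,
                             config.block_rho, config.block_size),
    )
    centers = _block_centers(base)
    k = config.n_qtl
    idx_probe, idx_risk, idx_cad = centers[:k], centers[k:2 * k], centers[2 * k:3 * k]
    gam = _scaled_effects(rng_eff, mafs, idx_probe, config.probe_qtl_var)
    dlt = _scaled_effects(rng_eff, mafs, idx_risk, config.risk_direct_var)
    eta = _scaled_effects(rng_eff, mafs, idx_cad, config.cad_direct_var)

    def traits(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = G.shape[0]
        g_probe = G[:, idx_probe] @ gam
        g_risk = G[:, idx_risk] @ dlt
        g_cad = G[:, idx_cad] @ eta
        if config.direction == "causal":
            x = g_probe + rng_noise.normal(
                0.0, math.sqrt(1.0 - config.probe_qtl_var), n)
            y_sys = config.b_probe_risk * x + g_risk
            y = y_sys + rng_noise.normal(
                0.0, math.sqrt(max(1.0 - float(np.var(y_sys)), 1e-6)), n)
        else:
            y_sys = g_risk
            y = y_sys + rng_noise.normal(
                0.0, math.sqrt(1.0 - config.risk_direct_var), n)
            b = config.b_probe_risk
            x = b * y + rng_noise.normal(
                0.0, math.sqrt(max(1.0 - b * b, 1e-6)), n)
        z_sys = config.b_risk_cad * y + g_cad
        z = z_sys + rng_noise.normal(
            0.0, math.sqrt(max(1.0 - float(np.var(z_sys)), 1e-6)), n)
        return x, y, z

    n = config.n_cohort
    G1 = _draw_genotypes(rng_c1, n, thresholds, config.block_rho, config.block_size)
    G2 = _draw_genotypes(rng_c2, n, thresholds, config.block_rho, config.block_size)
    G3 = _draw_genotypes(rng_c3, n, thresholds, config.block_rho, config.block_size)
    x1, _, _ = traits(G1)
    _, y2, _ = traits(G2)
    _, _, z3 = traits(G3)

    probe = _ols_sumstats(G1, x1, ids, "probe", TraitKind.protein)
    risk = _ols_sumstats(G2, y2, ids, "risk_factor", TraitKind.risk_factor)
    cad = _ols_sumstats(G3, z3, ids, "CAD", TraitKind.disease)
    truth = {
        "direction": config.direction,
        "b_probe_risk": config.b_probe_risk,
        "b_risk_cad": config.b_risk_cad,
        "probe_qtls": [ids[j] for j in idx_probe],
        "risk_direct_qtls": [ids[j] for j in idx_risk],
        "cad_direct_qtls": [ids[j] for j in idx_cad],
    }
    return ChainData(probe, risk, cad, panel, truth)


def write_scenario(
    outputs: tuple[SumstatsTable, SumstatsTable, ScenarioTruth, GenotypePanel],
    directory: str | Path,
) -> None:
    """Write exposure/outcome .ma files, the panel as dosage text, and the
    ground truth as JSON, all re-readable by the package's own readers."""
    from .sumstats import write_sumstats  # local import to avoid cycle at module load

    exposure, outcome, truth, panel = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_sumstats(exposure, directory / "exposure.ma")
    write_sumstats(outcome, directory / "outcome.ma")
    write_dosage_text(panel, directory / "panel.dosage.txt")
    with open(directory / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
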