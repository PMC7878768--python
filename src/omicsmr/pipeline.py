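"""The full inference chain linking molecular probes to risk factors and CAD.

Stages, in order, each gating the next:

1. **Co-localization scan** — per probe, the SMR test at the top QTL SNP
   must be significant and the HEIDI test must *not* indicate linkage.
2. **Forward MR** (probe -> risk factor) at genome-wide significance.
3. **Reverse MR** (risk factor -> probe) with instruments selected on the
   risk factor: significant reverse causation (p < 0.05) excludes the pair.
4. **Forward MR to CAD** (probe -> CAD), gated on the Bonferroni-corrected
   p-value across all probe -> CAD tests attempted in the run.
5. **Reverse MR from CAD** (CAD -> probe) with the same exclusion rule.

Findings report every stage's statistics plus a status naming the first
failed gate.  For binary outcomes effects are on the log-odds scale and
the report includes the odds ratio per exposure SD (exp(beta), e.g.
beta = 0.05 -> OR 1.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .gsmr import (
    GsmrError,
    InstrumentCriteria,
    MrResult,
    NoInstrumentsError,
    mr_with_outlier_removal,
    select_instruments,
)
from .ld import GenotypePanel, LdError, compute_ld
from .smr import HeidiParams, SmrResult, heidi_test, select_top_snp, smr_test
from .sumstats import HarmonizationError, ProbeInfo, SumstatsTable, harmonize_pair

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


class ChainStatus(str, Enum):
    passed = "passed"
    failed_coloc = "failed_coloc"
    failed_heidi = "failed_heidi"
    failed_forward = "failed_forward"
    failed_reverse = "failed_reverse"
    failed_cad = "failed_cad"
    failed_cad_reverse = "failed_cad_reverse"
    failed_bonferroni = "failed_bonferroni"


@dataclass
class PipelineConfig:
    """All thresholds of the filtering chain, in one place.

    ``coloc_heidi_p_min`` excludes co-localizations with p_heidi at or
    below it (linkage); the instrument-stage pleiotropy threshold lives in
    ``instrument_criteria.heidi_p_min`` and is deliberately distinct.
    """

    smr_p_max: float = 5e-8
    coloc_heidi_p_min: float = 0.05
    instrument_criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    heidi_params: HeidiParams = field(default_factory=HeidiParams)
    forward_p_max: float = 5e-8
    reverse_p_exclude: float = 0.05
    cad_alpha: float = 0.05
    outlier_alpha: float = 0.01
    ld_scaled: bool = True
    drop_palindromic_maf_window: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("smr_p_max", "coloc_heidi_p_min", "forward_p_max",
                     "reverse_p_exclude", "cad_alpha", "outlier_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class ColocOutcome:
    """Per-probe result of the co-localization scan."""

    probe: ProbeInfo
    result: SmrResult
    status: ChainStatus  # passed / failed_coloc / failed_heidi


@dataclass
class BiomarkerFinding:
    """One probe's journey through the filtering chain."""

    probe: ProbeInfo
    risk_factor_id: str
    status: ChainStatus
    smr: SmrResult | None = None
    forward_mr: MrResult | None = None
    reverse_mr: MrResult | None = None
    cad_forward: MrResult | None = None
    cad_reverse: MrResult | None = None
    p_cad_bonferroni: float | None = None


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p*m)."""
    if not (0 < p <= 1):
        raise ValueError(f"p must lie in (0,1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


def beta_to_or(beta: float) -> float:
    """Odds ratio per exposure SD implied by a log-odds MR effect."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    return math.exp(beta)


def _restrict_to_panel(
    table: SumstatsTable, panel: GenotypePanel
) -> SumstatsTable:
    ids = [s for s in table.snp_ids if s in panel]
    if not ids:
        raise LdError(
            f"no SNP of {table.trait_id!r} is covered by the reference panel"
        )
    if len(ids) < len(table):
        log.debug("%s: %d SNP(s) absent from reference panel, excluded",
                  table.trait_id, len(table) - len(ids))
    return table.subset(ids)


def _run_mr(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    panel: GenotypePanel,
    config: PipelineConfig,
) -> MrResult:
    """Harmonize, select instruments, remove outliers, GLS-estimate."""
    ex, out, _ = harmonize_pair(exposure, outcome,
                                config.drop_palindromic_maf_window)
    ex = _restrict_to_panel(ex, panel)
    out = out.subset(ex.snp_ids)
    ld = compute_ld(panel, ex.snp_ids)
    instruments = select_instruments(ex, out, ld, config.instrument_criteria,
                                     config.heidi_params)
    return mr_with_outlier_removal(
        ex, out, ld, instruments, alpha=config.outlier_alpha,
        ld_scaled=config.ld_scaled,
    )


def run_coloc_scan(
    probes: Sequence[tuple[ProbeInfo, SumstatsTable]],
    trait: SumstatsTable,
    ld_panel: GenotypePanel,
    config: PipelineConfig,
) -> list[ColocOutcome]:
    """SMR + HEIDI per probe against one trait.

    A probe passes iff p_smr < ``smr_p_max`` and p_heidi >
    ``coloc_heidi_p_min``; an undefined HEIDI p (no usable flanking SNPs)
    fails conservatively.  Per-probe errors are logged and the scan
    continues; it is an error for every probe to fail with an exception.
    """
    outcomes: list[ColocOutcome] = []
    n_errors = 0
    for info, ptable in probes:
        try:
            ex, out, _ = harmonize_pair(ptable, trait,
                                        config.drop_palindromic_maf_window)
            ex = _restrict_to_panel(ex, ld_panel)
            out = out.subset(ex.snp_ids)
            ld = compute_ld(ld_panel, ex.snp_ids)
            top = select_top_snp(ex)
            rx = ex.lookup(top)
            ry = out.lookup(top)
            t = smr_test(rx.beta, rx.se, ry.beta, ry.se)
            p_heidi, n_heidi = heidi_test(ex, out, ld, top, config.heidi_params)
            result = SmrResult(
                probe_id=info.probe_id, trait_id=trait.trait_id, top_snp=top,
                beta_smr=t.beta_smr, se_smr=t.se_smr, p_smr=t.p_smr,
                p_heidi=p_heidi, n_heidi_snps=n_heidi,
            )
            if not (t.p_smr < config.smr_p_max):
                status = ChainStatus.failed_coloc
            elif p_heidi is None or not (p_heidi > config.coloc_heidi_p_min):
                if p_heidi is None:
                    log.info("probe %s: HEIDI undefined (no flanking SNPs); "
                             "failing co-localization", info.probe_id)
                status = ChainStatus.failed_heidi
            else:
                status = ChainStatus.passed
            outcomes.append(ColocOutcome(info, result, status))
        except (HarmonizationError, LdError, GsmrError, ValueError) as e:
            n_errors += 1
            log.warning("probe %s: co-localization scan failed: %s",
                        info.probe_id, e)
    if not outcomes:
        raise PipelineError(
            f"co-localization scan failed for all {n_errors} probe(s)"
        )
    return outcomes


def _chain_through_cad(
    probe: tuple[ProbeInfo, SumstatsTable],
    risk_factor: SumstatsTable,
    cad: SumstatsTable,
    ld_panel: GenotypePanel,
    config: PipelineConfig,
    smr: SmrResult | None,
) -> BiomarkerFinding:
    """Stages 1-3 (forward, reverse, CAD forward) with short-circuiting.

    Leaves the Bonferroni gate and the CAD-reverse stage to
    :func:`_apply_cad_gates`, which needs the family size n_tests.
    """
    info, ptable = probe
    finding = BiomarkerFinding(
        probe=info, risk_factor_id=risk_factor.trait_id,
        status=ChainStatus.passed, smr=smr,
    )
    try:
        fwd = _run_mr(ptable, risk_factor, ld_panel, config)
    except (NoInstrumentsError, HarmonizationError, LdError) as e:
        log.info("probe %s: forward MR not possible: %s", info.probe_id, e)
        finding.status = ChainStatus.failed_forward
        return finding
    finding.forward_mr = fwd
    if not (fwd.p < config.forward_p_max):
        finding.status = ChainStatus.failed_forward
        return finding
    try:
        rev = _run_mr(risk_factor, ptable, ld_panel, config)
    except (NoInstrumentsError, HarmonizationError, LdError) as e:
        log.info("probe %s: reverse MR not possible: %s", info.probe_id, e)
        finding.status = ChainStatus.failed_reverse
        return finding
    finding.reverse_mr = rev
    if rev.p < config.reverse_p_exclude:
        finding.status = ChainStatus.failed_reverse
        return finding
    try:
        cadf = _run_mr(ptable, cad, ld_panel, config)
    except (NoInstrumentsError, HarmonizationError, LdError) as e:
        log.info("probe %s: probe->CAD MR not possible: %s", info.probe_id, e)
        finding.status = ChainStatus.failed_cad
        return finding
    finding.cad_forward = cadf
    return finding


def _apply_cad_gates(
    finding: BiomarkerFinding,
    probe_table: SumstatsTable,
    cad: SumstatsTable,
    ld_panel: GenotypePanel,
    config: PipelineConfig,
    n_tests: int,
) -> BiomarkerFinding:
    if finding.status != ChainStatus.passed or finding.cad_forward is None:
        return finding
    finding.p_cad_bonferroni = bonferroni(finding.cad_forward.p, n_tests)
    if not (finding.p_cad_bonferroni < config.cad_alpha):
        finding.status = ChainStatus.failed_bonferroni
        return finding
    try:
        cadr = _run_mr(cad, probe_table, ld_panel, config)
    except (NoInstrumentsError, HarmonizationError, LdError) as e:
        log.info("probe %s: CAD->probe MR not possible: %s",
                 finding.probe.probe_id, e)
        finding.status = ChainStatus.failed_cad_reverse
        return finding
    finding.cad_reverse = cadr
    if cadr.p < config.reverse_p_exclude:
        finding.status = ChainStatus.failed_cad_reverse
    return finding


def run_mr_chain(
    probe: tuple[ProbeInfo, SumstatsTable],
    risk_factor: SumstatsTable,
    cad: SumstatsTable,
    ld_panel: GenotypePanel,
    config: PipelineConfig,
    n_tests: int,
    smr: SmrResult | None = None,
) -> BiomarkerFinding:
    """Forward/reverse MR chain for one probe that already passed
    co-localization.  ``n_tests`` is the Bonferroni family size for the
    probe->CAD test."""
    finding = _chain_through_cad(probe, risk_factor, cad, ld_panel, config, smr)
    return _apply_cad_gates(finding, probe[1], cad, ld_panel, config, n_tests)


def run_pipeline(
    probes: Sequence[tuple[ProbeInfo, SumstatsTable]],
    risk_factor: SumstatsTable,
    cad: SumstatsTable,
    ld_panel: GenotypePanel,
    config: PipelineConfig,
    report_path: str | Path | None = None,
) -> list[BiomarkerFinding]:
    """Full chain over a collection of probes.

    The Bonferroni family size is the number of probe->CAD forward tests
    actually performed in this run (the smallest defensible family).
    """
    outcomes = run_coloc_scan(probes, risk_factor, ld_panel, config)
    table_by_probe = {info.probe_id: tab for info, tab in probes}
    findings: list[BiomarkerFinding] = []
    pending: list[BiomarkerFinding] = []
    for oc in outcomes:
        if oc.status != ChainStatus.passed:
            findings.append(BiomarkerFinding(
                probe=oc.probe, risk_factor_id=risk_factor.trait_id,
                status=oc.status, smr=oc.result,
            ))
            continue
        f = _chain_through_cad(
            (oc.probe, table_by_probe[oc.probe.probe_id]), risk_factor, cad,
            ld_panel, config, oc.result,
        )
        findings.append(f)
        pending.append(f)
    n_tests = sum(1 for f in pending if f.cad_forward is not None)
    for f in pending:
        _apply_cad_gates(f, table_by_probe[f.probe.probe_id], cad, ld_panel,
                         config, max(1, n_tests))
    log.info("pipeline: %d probes, %d Bonferroni family tests, %d passed",
             len(probes), n_tests,
             sum(1 for f in findings if f.status == ChainStatus.passed))
    if report_path is not None:
        write_report(findings, report_path)
    return findings


_REPORT_COLUMNS = [
    "probe_id", "layer", "chrom", "pos", "gene", "risk_factor_id", "top_snp",
    "beta_smr", "se_smr", "p_smr", "p_heidi", "n_heidi_snps",
    "b_forward", "se_forward", "p_forward", "n_snps_forward",
    "b_reverse", "se_reverse", "p_reverse",
    "b_cad", "se_cad", "p_cad", "or_cad", "p_cad_bonferroni",
    "b_cad_reverse", "se_cad_reverse", "p_cad_reverse",
    "removed_outliers", "status",
]


def write_report(
    findings: Sequence[BiomarkerFinding], path: str | Path
) -> None:
    """Tab-separated per-probe report; byte-identical on identical inputs.

    The CAD stage effect is on the log-odds scale, so the report includes
    the implied odds ratio per exposure SD rounded to 2 decimals.
    """
    if not findings:
        raise ValueError("no findings to report")
    rows = []
    for f in findings:
        row: dict[str, object] = {c: None for c in _REPORT_COLUMNS}
        row.update(
            probe_id=f.probe.probe_id, layer=f.probe.layer, chrom=f.probe.chrom,
            pos=f.probe.pos, gene=f.probe.gene, risk_factor_id=f.risk_factor_id,
            status=f.status.value,
        )
        if f.smr is not None:
            row.update(top_snp=f.smr.top_snp, beta_smr=f.smr.beta_smr,
                       se_smr=f.smr.se_smr, p_smr=f.smr.p_smr,
                       p_heidi=f.smr.p_heidi, n_heidi_snps=f.smr.n_heidi_snps)
        if f.forward_mr is not None:
            row.update(b_forward=f.forward_mr.b_xy, se_forward=f.forward_mr.se,
                       p_forward=f.forward_mr.p,
                       n_snps_forward=f.forward_mr.n_snps,
                       removed_outliers=",".join(f.forward_mr.removed_outliers)
                       or None)
        if f.reverse_mr is not None:
            row.update(b_reverse=f.reverse_mr.b_xy, se_reverse=f.reverse_mr.se,
                       p_reverse=f.reverse_mr.p)
        if f.cad_forward is not None:
            row.update(b_cad=f.cad_forward.b_xy, se_cad=f.cad_forward.se,
                       p_cad=f.cad_forward.p,
                       or_cad=round(beta_to_or(f.cad_forward.b_xy), 2))
        if f.p_cad_bonferroni is not None:
            row.update(p_cad_bonferroni=f.p_cad_bonferroni)
        if f.cad_reverse is not None:
            row.update(b_cad_reverse=f.cad_reverse.b_xy,
                       se_cad_reverse=f.cad_reverse.se,
                       p_cad_reverse=f.cad_reverse.p)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
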