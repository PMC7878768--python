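"""GWAS summary statistics: reading, validation, writing, allele harmonization.

The common text dialect throughout the package is the GCTA ``.ma`` format:
a whitespace-delimited table whose header is exactly

    SNP A1 A2 freq b se p N

``A1`` is the effect allele, ``b``/``se`` the per-allele effect and its
standard error (SD units for quantitative traits, log-odds for binary
outcomes), ``freq`` the effect-allele frequency and ``N`` the sample size.
Missing values are encoded ``NA``.  Extra columns are ignored with a
warning.

Two-sample MR requires the exposure and outcome statistics to be expressed
on the same effect allele; :func:`harmonize_pair` aligns the outcome table
to the exposure's allele coding, resolving strand flips by base
complementation and dropping strand-ambiguous palindromic SNPs whose allele
frequency is too close to 0.5 to orient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical .ma header, in order
MA_HEADER = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
#: internal (DataFrame) column names matching MA_HEADER
CANON_COLUMNS = ["snp", "a1", "a2", "freq", "b", "se", "p", "n"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SumstatsError(ValueError):
    """Malformed or invalid summary-statistics input."""


class DuplicateSnpError(SumstatsError):
    """A snp_id occurs more than once within one table."""


class HarmonizationError(SumstatsError):
    """Exposure and outcome tables cannot be harmonized."""


class TraitKind(str, Enum):
    """What kind of trait a summary-statistics table describes."""

    methylation = "biomarker_methylation"
    expression = "biomarker_expression"
    protein = "biomarker_protein"
    risk_factor = "risk_factor"
    disease = "disease"


@dataclass(frozen=True)
class SnpAssoc:
    """One SNP's marginal association with one trait or molecular probe."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float


@dataclass(frozen=True)
class ProbeInfo:
    """Identity and genomic location of a molecular probe (QTL target)."""

    probe_id: str
    layer: str  # one of mQTL / eQTL / pQTL
    chrom: str
    pos: int
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in ("mQTL", "eQTL", "pQTL"):
            raise ValueError(f"unknown omic layer {self.layer!r}")
        if self.pos < 1:
            raise ValueError("probe position must be >= 1 (1-based bp)")


class SumstatsTable:
    """All per-SNP association records for one trait or probe.

    Wraps a :class:`pandas.DataFrame` with columns ``snp a1 a2 freq b se p n``
    in file order.  snp ids are unique and the table is never empty.
    """

    def __init__(self, trait_id: str, trait_kind: TraitKind | str, df: pd.DataFrame):
        missing = [c for c in CANON_COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsError(f"table for {trait_id!r} lacks columns {missing}")
        if df.empty:
            raise SumstatsError(f"table for {trait_id!r} is empty")
        dup = df["snp"][df["snp"].duplicated()]
        if not dup.empty:
            raise DuplicateSnpError(
                f"duplicate snp_id {dup.iloc[0]!r} in table {trait_id!r}"
            )
        self.trait_id = str(trait_id)
        self.trait_kind = TraitKind(trait_kind)
        self.df = df.loc[:, CANON_COLUMNS].reset_index(drop=True)
        self._index: dict[str, int] = {s: i for i, s in enumerate(self.df["snp"])}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp"])

    def lookup(self, snp_id: str) -> SnpAssoc:
        try:
            row = self.df.iloc[self._index[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in table {self.trait_id!r}") from None
        return SnpAssoc(
            snp_id=row["snp"], effect_allele=row["a1"], other_allele=row["a2"],
            eaf=row["freq"], beta=row["b"], se=row["se"], p=row["p"], n=row["n"],
        )

    def records(self) -> Iterator[SnpAssoc]:
        for snp in self.df["snp"]:
            yield self.lookup(snp)

    def subset(self, snp_ids: list[str]) -> "SumstatsTable":
        """New table restricted to ``snp_ids``, in the given order."""
        rows = [self._index[s] for s in snp_ids]
        return SumstatsTable(self.trait_id, self.trait_kind, self.df.iloc[rows])

    def arrays(self, snp_ids: list[str]):
        """(beta, se, p, freq) numpy arrays for the given SNPs, in order."""
        rows = [self._index[s] for s in snp_ids]
        sub = self.df.iloc[rows]
        return (
            sub["b"].to_numpy(float),
            sub["se"].to_numpy(float),
            sub["p"].to_numpy(float),
            sub["freq"].to_numpy(float),
        )


@dataclass(frozen=True)
class HarmonizationReport:
    """Per-reason accounting of what :func:`harmonize_pair` did."""

    n_exposure: int
    n_outcome: int
    n_shared: int
    n_kept: int
    n_flipped: int
    n_dropped_palindromic: int
    n_dropped_mismatch: int


def _valid_mask(df: pd.DataFrame) -> pd.Series:
    """Row-wise SnpAssoc invariant check (vectorized)."""
    allele_ok = (
        df["a1"].str.fullmatch(r"[ACGT]+", na=False)
        & df["a2"].str.fullmatch(r"[ACGT]+", na=False)
        & (df["a1"] != df["a2"])
    )
    num_ok = (
        df["freq"].between(0.0, 1.0)
        & (df["se"] > 0)
        & np.isfinite(df["se"])
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["n"] > 0)
        & np.isfinite(df["b"])
    )
    return allele_ok & num_ok.fillna(False)


def read_sumstats(
    path: str | Path, trait_id: str, trait_kind: TraitKind | str
) -> SumstatsTable:
    """Read a ``.ma`` file into a :class:`SumstatsTable`.

    Rows violating the per-SNP invariants (non-ACGT alleles, se <= 0,
    p outside (0,1], n <= 0, missing frequency, ...) are dropped with a
    logged count.  A duplicated snp_id or a file with no valid rows is a
    hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().split()
    if header[: len(MA_HEADER)] != MA_HEADER:
        raise SumstatsError(
            f"{path}: malformed header {' '.join(header[:8])!r}; "
            f"expected {' '.join(MA_HEADER)!r}"
        )
    if len(header) > len(MA_HEADER):
        log.warning(
            "%s: ignoring %d extra column(s): %s",
            path, len(header) - len(MA_HEADER), header[len(MA_HEADER):],
        )
    df = pd.read_csv(
        path, sep=r"\s+", na_values=["NA"], dtype={"SNP": str, "A1": str, "A2": str}
    )
    df = df.loc[:, MA_HEADER].set_axis(CANON_COLUMNS, axis=1)
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()
    dup = df["snp"][df["snp"].duplicated()]
    if not dup.empty:
        raise DuplicateSnpError(f"{path}: duplicate snp_id {dup.iloc[0]!r}")
    ok = _valid_mask(df)
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("%s: dropped %d invalid row(s)", path, n_bad)
    df = df[ok]
    if df.empty:
        raise SumstatsError(f"{path}: zero valid rows after filtering")
    return SumstatsTable(trait_id, trait_kind, df)


def write_sumstats(table: SumstatsTable, path: str | Path) -> None:
    """Write a table in ``.ma`` format; round-trips through read_sumstats."""
    if len(table) == 0:  # defensive; constructor forbids this
        raise SumstatsError("refusing to write an empty table")
    out = table.df.copy()
    if (out["n"] == out["n"].round()).all():
        out["n"] = out["n"].astype(np.int64)
    out.columns = MA_HEADER
    out.to_csv(path, sep=" ", index=False, na_rep="NA", float_format="%.10g")


def harmonize_pair(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    drop_palindromic_maf_window: float = 0.08,
) -> tuple[SumstatsTable, SumstatsTable, HarmonizationReport]:
    """Align the outcome table to the exposure's effect-allele coding.

    For every shared SNP the outcome record is re-expressed on the
    exposure's A1: if outcome alleles are swapped relative to the exposure
    the outcome beta is negated and its frequency replaced by 1 - freq;
    strand flips are resolved by complementing outcome alleles before
    comparison.  Palindromic SNPs (A/T or C/G) whose frequency in either
    table lies within ``drop_palindromic_maf_window`` of 0.5 cannot be
    oriented and are dropped, as are SNPs with irreconcilable alleles.

    The exposure's betas are never altered.  Harmonization is idempotent.
    """
    m = exposure.df.merge(outcome.df, on="snp", how="inner", suffixes=("_x", "_y"))
    if m.empty:
        raise HarmonizationError(
            f"no shared SNPs between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    a1x, a2x = m["a1_x"], m["a2_x"]
    a1y, a2y = m["a1_y"], m["a2_y"]
    c1y = a1y.str.translate(_COMPLEMENT)
    c2y = a2y.str.translate(_COMPLEMENT)

    same = (a1y == a1x) & (a2y == a2x)
    swap = ~same & (a1y == a2x) & (a2y == a1x)
    comp = ~same & ~swap & (c1y == a1x) & (c2y == a2x)
    comp_swap = ~same & ~swap & ~comp & (c1y == a2x) & (c2y == a1x)
    matched = same | swap | comp | comp_swap

    palindromic = a1x == a2x.str.translate(_COMPLEMENT)
    near_half = (
        ((m["freq_x"] - 0.5).abs() < drop_palindromic_maf_window)
        | ((m["freq_y"] - 0.5).abs() < drop_palindromic_maf_window)
    )
    ambiguous = palindromic & near_half

    keep = matched & ~ambiguous
    flip = (swap | comp_swap) & keep

    report = HarmonizationReport(
        n_exposure=len(exposure),
        n_outcome=len(outcome),
        n_shared=len(m),
        n_kept=int(keep.sum()),
        n_flipped=int(flip.sum()),
        n_dropped_palindromic=int((matched & ambiguous).sum()),
        n_dropped_mismatch=int((~matched).sum()),
    )
    if report.n_kept == 0:
        raise HarmonizationError(
            f"harmonizing {exposure.trait_id!r} vs {outcome.trait_id!r} left no SNPs "
            f"({report})"
        )
    log.debug("harmonize %s vs %s: %s", exposure.trait_id, outcome.trait_id, report)

    kept = m[keep]
    fl = flip[keep].to_numpy()
    out_df = pd.DataFrame(
        {
            "snp": kept["snp"],
            "a1": kept["a1_x"],
            "a2": kept["a2_x"],
            "freq": np.where(fl, 1.0 - kept["freq_y"], kept["freq_y"]),
            "b": np.where(fl, -kept["b_y"], kept["b_y"]),
            "se": kept["se_y"],
            "p": kept["p_y"],
            "n": kept["n_y"],
        }
    )
    exp_df = kept[["snp", "a1_x", "a2_x", "freq_x", "b_x", "se_x", "p_x", "n_x"]]
    exp_df = exp_df.set_axis(CANON_COLUMNS, axis=1)
    return (
        SumstatsTable(exposure.trait_id, exposure.trait_kind, exp_df),
        SumstatsTable(outcome.trait_id, outcome.trait_kind, out_df),
        report,
    )


def read_probe_annotations(path: str | Path) -> list[ProbeInfo]:
    """Read a tab-separated probe annotation table: probe_id layer chrom pos gene."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "layer", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: probe annotation lacks columns {missing}")
    probes = []
    for _, row in df.iterrows():
        gene = row.get("gene")
        probes.append(
            ProbeInfo(
                probe_id=row["probe_id"], layer=row["layer"], chrom=row["chrom"],
                pos=int(row["pos"]), gene=None if pd.isna(gene) else str(gene),
            )
        )
    return probes
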