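"""Reference-panel linkage disequilibrium: panel readers, LD matrices, clumping.

LD here is the Pearson correlation of allele dosages (0/1/2 counts of the
effect allele) across reference-panel samples; r² is its square.  Missing
dosages are handled by pairwise-complete correlation rather than
imputation, matching common practice for small reference panels.

Two panel encodings are supported: PLINK 1 binary bed/bim/fam (SNP-major
bed v1.00) and a plain dosage-text format — a header row of snp ids
followed by one whitespace-delimited row of {0,1,2,NA} per sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats import SumstatsTable

log = logging.getLogger(__name__)

_PLINK_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> dosage of the bim A1 allele (01 = missing)
_PLINK_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PanelFormatError(ValueError):
    """Reference panel file is malformed or internally inconsistent."""


class LdError(ValueError):
    """LD cannot be computed for the requested SNPs."""


@dataclass
class GenotypePanel:
    """Per-sample allele dosages for a set of SNPs (samples x SNPs)."""

    snp_ids: list[str]
    dosages: np.ndarray  # float array, shape (n_samples, n_snps); NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PanelFormatError("dosage matrix must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if n < 2:
            raise PanelFormatError("panel needs at least 2 samples")
        if m != len(self.snp_ids):
            raise PanelFormatError(
                f"{len(self.snp_ids)} snp ids but {m} dosage columns"
            )
        if len(set(self.snp_ids)) != m:
            raise PanelFormatError("snp ids in panel are not unique")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise PanelFormatError("dosages must be in {0,1,2} or missing")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def sample_count(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._index[s] for s in snp_ids]
        except KeyError as e:
            raise LdError(f"SNP {e.args[0]!r} not in panel") from None
        return self.dosages[:, idx]


@dataclass
class LdMatrix:
    """Pairwise dosage correlations for an ordered SNP set."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise LdError(f"r has shape {self.r.shape}, expected ({k},{k})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise LdError("r matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise LdError("r matrix diagonal is not 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise LdError("r entries outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def sub(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    @property
    def r2(self) -> np.ndarray:
        return self.r * self.r


def identity_ld(snp_ids: Sequence[str]) -> LdMatrix:
    """LD matrix for SNPs assumed mutually independent (r = I)."""
    return LdMatrix(list(snp_ids), np.eye(len(snp_ids)))


def _read_dosage_text(path: Path) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().split()
    if not header:
        raise PanelFormatError(f"{path}: empty header row")
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA", "."], skiprows=1, header=None)
    if df.shape[1] != len(header):
        raise PanelFormatError(
            f"{path}: {len(header)} snp ids in header but rows have "
            f"{df.shape[1]} fields"
        )
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise PanelFormatError(
            f"{path}: non-{{0,1,2}} dosage {vals[i, j]!r} at sample row {i + 1}, "
            f"column {header[j]!r}"
        )
    return GenotypePanel(header, vals)


def _read_plink_bed(prefix: Path) -> GenotypePanel:
    bed, bim, fam = (Path(str(prefix) + ext) for ext in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"snp": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    n, m = len(fam_df), len(bim_df)
    raw = bed.read_bytes()
    if raw[:3] != _PLINK_BED_MAGIC:
        raise PanelFormatError(f"{bed}: not a SNP-major PLINK bed v1.00 file")
    bytes_per_snp = (n + 3) // 4
    if len(raw) - 3 != m * bytes_per_snp:
        raise PanelFormatError(
            f"{bed}: size {len(raw) - 3} bytes inconsistent with "
            f"{m} SNPs x {n} samples from .bim/.fam"
        )
    codes = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_snp)
    geno = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        geno[:, k::4] = (codes >> shift) & 3
    dosages = _PLINK_CODE_TO_DOSAGE[geno[:, :n]]  # oriented to the .bim A1 allele
    return GenotypePanel(list(bim_df["snp"]), dosages.T)


def read_panel(path_prefix: str | Path, format: str = "plink_bed") -> GenotypePanel:
    """Load a reference genotype panel.

    ``format="plink_bed"`` expects the ``.bed/.bim/.fam`` triplet at
    ``path_prefix``; dosages count the .bim A1 allele.  ``format=
    "dosage_text"`` expects the file itself: a header of snp ids then one
    row of dosages per sample.
    """
    path = Path(path_prefix)
    if format == "dosage_text":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_dosage_text(path)
    if format == "plink_bed":
        return _read_plink_bed(path)
    raise ValueError(f"unknown panel format {format!r}")


def write_dosage_text(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel in the plain dosage-text format (re-readable)."""
    with open(path, "w") as fh:
        fh.write(" ".join(panel.snp_ids) + "\n")
        for row in panel.dosages:
            fh.write(
                " ".join("NA" if math.isnan(v) else str(int(v)) for v in row) + "\n"
            )


def compute_ld(panel: GenotypePanel, subset: Sequence[str]) -> LdMatrix:
    """Pearson dosage correlations for ``subset``, pairwise-complete.

    Every SNP must be polymorphic among its non-missing samples and every
    pair must share at least 2 non-missing samples.
    """
    subset = list(subset)
    X = panel.columns(subset)
    miss = np.isnan(X)
    for j, snp in enumerate(subset):
        col = X[~miss[:, j], j]
        if col.size < 2 or np.var(col) == 0:
            raise LdError(f"SNP {snp!r} is monomorphic in the panel")
    if not miss.any():
        R = np.corrcoef(X, rowvar=False).reshape(len(subset), len(subset))
    else:
        k = len(subset)
        R = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                both = ~(miss[:, i] | miss[:, j])
                if both.sum() < 2:
                    raise LdError(
                        f"SNPs {subset[i]!r}/{subset[j]!r} share fewer than "
                        "2 non-missing samples"
                    )
                xi, xj = X[both, i], X[both, j]
                if np.var(xi) == 0 or np.var(xj) == 0:
                    raise LdError(
                        f"pairwise-complete dosages are constant for "
                        f"{subset[i]!r}/{subset[j]!r}"
                    )
                R[i, j] = R[j, i] = np.corrcoef(xi, xj)[0, 1]
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return LdMatrix(subset, R)


def ld_clump(
    stats: SumstatsTable,
    ld: LdMatrix,
    r2_max: float,
    p_max: float,
    positions: Mapping[str, int] | None = None,
) -> list[str]:
    """Greedy significance-ranked LD pruning.

    SNPs with p < ``p_max`` are ranked by ascending p (ties broken by
    genomic position when ``positions`` is given, then snp_id) and accepted
    iff their r² with every already-accepted SNP is below ``r2_max``.
    Returns accepted ids in acceptance order; empty if nothing passes
    ``p_max``.
    """
    missing = [s for s in stats.snp_ids if s not in ld]
    if missing:
        raise LdError(f"{len(missing)} SNP(s) absent from LD matrix, e.g. {missing[0]!r}")
    pos = positions or {}
    candidates = sorted(
        (
            (row.p, pos.get(row.snp, float("inf")), row.snp)
            for row in stats.df.itertuples()
            if row.p < p_max
        ),
    )
    accepted: list[str] = []
    for _, _, snp in candidates:
        if all(ld.r_between(snp, a) ** 2 < r2_max for a in accepted):
            accepted.append(snp)
    return accepted
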