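"""Instrument selection: p-value filtering and greedy LD clumping.

A valid genetic instrument must be robustly associated with the exposure
and approximately independent of the other instruments.  Selection is the
standard two-stage screen: keep SNPs below a suggestive significance
threshold (p < 1e-5 by default, the common choice for microbiome GWAS where
few taxa reach 5e-8), then prune correlated SNPs by greedy LD clumping —
repeatedly take the most significant remaining SNP as an index SNP and
remove every SNP on the same chromosome within the physical window whose
r² with it exceeds the threshold.

LD comes from an explicit r² matrix supplied by the caller (square or long
format on disk), not from a reference genotype panel, so the algorithm is
fully reproducible offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import GwasDataset

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise ValueError("duplicate snp_id in LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LDMatrix":
        """Panel of mutually independent SNPs."""
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    @classmethod
    def read(cls, path: str | Path) -> "LDMatrix":
        """Load from square TSV (snp header row + index column), 3-column
        long format ``snp_a  snp_b  r2`` (symmetrised, absent pairs = 0),
        or a single ``snp_id`` column declaring an independent panel
        (identity r²)."""
        path = Path(path)
        head = pd.read_csv(path, sep="\t", nrows=1)
        if list(head.columns) == ["snp_id"]:
            ids = pd.read_csv(path, sep="\t")["snp_id"].astype(str).tolist()
            return cls.identity(ids)
        if list(head.columns[:3]) == ["snp_a", "snp_b", "r2"]:
            long = pd.read_csv(path, sep="\t")
            ids = sorted(set(long["snp_a"]) | set(long["snp_b"]))
            idx = {s: i for i, s in enumerate(ids)}
            r2 = np.eye(len(ids))
            for a, b, v in long.itertuples(index=False):
                r2[idx[a], idx[b]] = v
                r2[idx[b], idx[a]] = v
            return cls(ids, r2)
        square = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in square.columns], square.to_numpy(dtype=float))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")

    def write_panel(self, path: str | Path) -> None:
        """Write only the SNP panel (identity r²) — compact form for
        independent panels."""
        if not np.allclose(self.r2, np.eye(len(self.snp_ids))):
            raise ValueError("write_panel is only valid for an identity (independent) panel")
        pd.DataFrame({"snp_id": self.snp_ids}).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ClumpConfig:
    """Selection thresholds: suggestive p-value cutoff, r² ceiling between
    retained instruments, and the physical clump window in kilobases."""

    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if not self.window_kb > 0:
            raise ValueError("window_kb must be > 0")


def filter_by_pvalue(dataset: GwasDataset, threshold: float) -> GwasDataset:
    """Keep records with pvalue strictly below ``threshold``, order preserved."""
    kept = dataset.df[dataset.df["pvalue"] < threshold].reset_index(drop=True)
    return GwasDataset(dataset.trait_id, dataset.trait_type, kept)


def _candidate_order(df: pd.DataFrame) -> pd.DataFrame:
    # Deterministic, input-order-invariant: p, then chrom, position, snp_id.
    return df.sort_values(
        ["pvalue", "chrom", "pos", "snp_id"], kind="mergesort", na_position="last"
    )


def ld_clump(dataset: GwasDataset, ld: LDMatrix, config: ClumpConfig) -> GwasDataset:
    """Greedy LD clumping; returns index SNPs in selection order.

    Candidates are ranked by ascending p-value (ties: chromosome, position,
    snp_id).  Each round keeps the best remaining SNP and discards every
    remaining SNP on the same chromosome within ``window_kb`` kilobases whose
    r² with it exceeds ``r2_threshold``.  Records absent from the LD matrix
    are dropped up front with a warning.  Different chromosomes are never
    clumped together; the window is inclusive on both ends.
    """
    df = dataset.df
    in_ld = df["snp_id"].map(lambda s: s in ld).astype(bool)
    n_missing = int((~in_ld).sum())
    if n_missing:
        logger.warning(
            "%s: %d instrument(s) absent from LD matrix, dropped", dataset.trait_id, n_missing
        )
    cand = _candidate_order(df[in_ld])

    snp = cand["snp_id"].to_numpy()
    chrom = cand["chrom"].to_numpy(dtype=object)
    pos = cand["pos"].to_numpy(dtype=float)  # NaN if unknown
    window_bp = config.window_kb * 1000.0

    alive = np.ones(len(cand), dtype=bool)
    kept: list[str] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept.append(snp[i])
        alive[i] = False
        rest = np.flatnonzero(alive)
        if rest.size == 0:
            break
        same_chrom = chrom[rest] == chrom[i]
        with np.errstate(invalid="ignore"):
            near = np.abs(pos[rest] - pos[i]) <= window_bp
        near &= same_chrom & ~np.isnan(pos[rest]) & ~np.isnan(pos[i])
        for j, is_near in zip(rest, near):
            if is_near and ld.r2_between(snp[i], snp[j]) > config.r2_threshold:
                alive[j] = False

    out = dataset.subset(kept)
    out.meta["clump_removed_ld"] = int(len(cand) - len(kept))
    out.meta["clump_removed_missing_ld"] = n_missing
    return out


def select_instruments(
    exposure: GwasDataset, ld: LDMatrix, config: ClumpConfig | None = None
) -> GwasDataset:
    """Two-stage instrument selection: p-value filter then LD clumping.

    Stage counts are logged and recorded in the returned dataset's ``meta``:
    ``n_input = n_retained + removed_p + removed_ld + removed_missing_ld``.
    """
    config = config or ClumpConfig()
    n_input = len(exposure)
    suggestive = filter_by_pvalue(exposure, config.p_threshold)
    clumped = ld_clump(suggestive, ld, config)
    clumped.meta.update(
        n_input=n_input,
        removed_p=n_input - len(suggestive),
        removed_ld=clumped.meta.pop("clump_removed_ld"),
        removed_missing_ld=clumped.meta.pop("clump_removed_missing_ld"),
        n_retained=len(clumped),
    )
    logger.info(
        "%s: %d SNPs -> %d suggestive (p<%g) -> %d independent instruments",
        exposure.trait_id, n_input, len(suggestive), config.p_threshold, len(clumped),
    )
    return clumped
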