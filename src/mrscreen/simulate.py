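"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a microbiota-exposure /
binary-outcome screen: many exposure GWAS sharing a SNP panel, one outcome
GWAS, per-SNP betas, standard errors, allele frequencies, p-values and
sample sizes — everything the pipeline consumes, nothing individual-level.

Model, per true instrument j of one exposure:

* MAF_j ~ Uniform(maf_range); SE follows the standardized-trait
  approximation  se = 1 / sqrt(2 · MAF · (1 − MAF) · n), so the F/R²
  strength statistics are internally consistent with the declared sample
  sizes.
* True exposure effect: |N(0, beta_exp_sd)| resampled until it clears a
  z ≥ 6 detection margin at n_exp (so the p < 1e-5 instrument filter keeps
  it with probability ≈ 1).  Effects are oriented positive: the reported
  effect allele is the exposure-increasing allele, which keeps "directional
  pleiotropy with mean m" well defined under MR-Egger's βX ≥ 0 convention.
* Direct (pleiotropic) effect α_j: 0 (``none``), N(0, pleio_sd)
  (``balanced``), or N(pleio_mean, pleio_sd) (``directional`` — violates
  the exclusion-restriction assumption by design).
* True outcome effect θ·βX_true + α_j, plus N(0, het_sd) extra-variance
  heterogeneity; observed effects add sampling noise at their SEs; p-values
  come from the observed z-scores.

Each exposure also carries ``decoy_factor × k_true`` null SNPs so the
p-value filter does nontrivial work.  All SNPs sit on one chromosome at
positions spaced beyond the default clump window, with LD supplied
separately (identity by default, block structure via :func:`simulate_ld`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .sumstats import CANONICAL_COLUMNS, GwasDataset, _coerce_dtypes
import pandas as pd

PLEIOTROPY_MODES = ("none", "balanced", "directional")

#: Non-palindromic ordered allele pairs (effect, other).
_SAFE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
               ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: Detection margin: true |z| for instruments, well past the p < 1e-5 bar
#: (|z| > 4.42) so selection keeps essentially every true instrument.
_Z_MIN = 6.0

#: Physical spacing between simulated SNPs, beyond the 10,000 kb window.
_POS_SPACING = 25_000_000


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters behind one synthetic exposure.

    ``theta`` is the true causal log-OR per unit of exposure; sample sizes
    default to the scale of a large microbiota consortium GWAS (n_exp) and
    a biobank case-control GWAS (n_out = cases + controls).
    """

    seed: int
    theta: float = 0.0
    k_true: int = 10
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    het_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_exp_sd: float = 0.1
    n_exp: int = 18_340
    n_out: int = 77_257
    decoy_factor: int = 50
    palindrome_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none" and (self.pleio_mean != 0 or self.pleio_sd != 0):
            raise ValueError("pleiotropy_mode 'none' requires pleio_mean = pleio_sd = 0")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError(f"degenerate maf_range {self.maf_range}")


def _gwas_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # Extreme z-scores underflow the two-sided tail to exactly 0, which
    # would violate the p in (0, 1] record invariant; clamp to float tiny.
    return np.maximum(p, np.finfo(float).tiny)


def _draw_alleles(rng: np.random.Generator, m: int, palindrome_fraction: float):
    pal = rng.random(m) < palindrome_fraction
    safe_idx = rng.integers(0, len(_SAFE_PAIRS), size=m)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    ea = np.where(pal, [ _PALINDROMIC_PAIRS[i][0] for i in pal_idx],
                  [_SAFE_PAIRS[i][0] for i in safe_idx])
    oa = np.where(pal, [ _PALINDROMIC_PAIRS[i][1] for i in pal_idx],
                  [_SAFE_PAIRS[i][1] for i in safe_idx])
    return ea, oa


def _dataset(trait_id, trait_type, snp_ids, pos, ea, oa, maf, beta, se, n):
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": _pvalues(beta, se),
            "n": float(n),
        },
        columns=CANONICAL_COLUMNS,
    )
    return GwasDataset(trait_id, trait_type, _coerce_dtypes(df))


def simulate_taxon(
    truth: SimulationTruth, trait_id: str = "genus.SimTaxon", snp_prefix: str | None = None
) -> tuple[GwasDataset, GwasDataset, SimulationTruth]:
    """One synthetic exposure GWAS and its matched outcome GWAS.

    The first ``k_true`` SNPs are true instruments; the remaining
    ``decoy_factor × k_true`` SNPs are null on both traits.  Returns
    ``(exposure, outcome, truth)``; the echoed truth is the input unchanged.
    Fixed seed implies byte-identical output through ``write_sumstats``.
    """
    rng = np.random.default_rng(truth.seed)
    k = truth.k_true
    m = k + truth.decoy_factor * k
    prefix = snp_prefix if snp_prefix is not None else "snp"
    snp_ids = [f"{prefix}{i:05d}" for i in range(m)]
    pos = 1 + _POS_SPACING * np.arange(m)

    maf = rng.uniform(*truth.maf_range, size=m)
    se_exp = _gwas_se(maf, truth.n_exp)
    se_out = _gwas_se(maf, truth.n_out)

    # True instrument effects: positive, above the detection margin.
    bx_true = np.zeros(m)
    draws = np.abs(rng.normal(0.0, truth.beta_exp_sd, size=k))
    floor = _Z_MIN * se_exp[:k]
    while np.any(draws < floor):
        redo = draws < floor
        draws[redo] = np.abs(rng.normal(0.0, truth.beta_exp_sd, size=int(redo.sum())))
    bx_true[:k] = draws

    alpha = np.zeros(m)
    if truth.pleiotropy_mode == "balanced":
        alpha[:k] = rng.normal(0.0, truth.pleio_sd, size=k)
    elif truth.pleiotropy_mode == "directional":
        alpha[:k] = rng.normal(truth.pleio_mean, truth.pleio_sd, size=k)

    by_true = truth.theta * bx_true + alpha
    if truth.het_sd > 0:
        by_true = by_true + rng.normal(0.0, truth.het_sd, size=m) * (np.arange(m) < k)

    bx_obs = rng.normal(bx_true, se_exp)
    by_obs = rng.normal(by_true, se_out)
    ea, oa = _draw_alleles(rng, m, truth.palindrome_fraction)

    exposure = _dataset(trait_id, "exposure", snp_ids, pos, ea, oa, maf, bx_obs, se_exp, truth.n_exp)
    outcome = _dataset("outcome", "outcome", snp_ids, pos, ea, oa, maf, by_obs, se_out, truth.n_out)
    return exposure, outcome, truth


def simulate_ld(
    snp_ids: Sequence[str], block_sizes: Sequence[int], within_r2: float
) -> tuple[LDMatrix, dict[str, tuple[str, int]]]:
    """Block-diagonal LD over the given panel, plus consistent positions.

    r² equals ``within_r2`` inside each block, 0 across blocks, 1 on the
    diagonal.  The returned position map places each block within the
    default clump window (SNPs 100 kb apart) and distinct blocks far beyond
    it, so clumping is driven by the r² structure alone.
    """
    snp_ids = list(snp_ids)
    if sum(block_sizes) != len(snp_ids) or any(b < 1 for b in block_sizes):
        raise ValueError(f"block sizes {block_sizes} do not partition {len(snp_ids)} SNPs")
    if not (0 <= within_r2 <= 1):
        raise ValueError("within_r2 must be in [0, 1]")
    m = len(snp_ids)
    r2 = np.zeros((m, m))
    pos_map: dict[str, tuple[str, int]] = {}
    start = 0
    for b, size in enumerate(block_sizes):
        idx = slice(start, start + size)
        r2[idx, idx] = within_r2
        for j in range(size):
            pos_map[snp_ids[start + j]] = ("1", 1 + b * _POS_SPACING + j * 100_000)
        start += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(snp_ids, r2), pos_map


def apply_positions(dataset: GwasDataset, pos_map: dict[str, tuple[str, int]]) -> GwasDataset:
    """Overwrite chrom/pos from a :func:`simulate_ld` position map."""
    df = dataset.df.copy()
    df["chrom"] = [pos_map.get(s, (c, p))[0] for s, c, p in zip(df.snp_id, df.chrom, df.pos)]
    df["pos"] = [pos_map.get(s, (c, p))[1] for s, c, p in zip(df.snp_id, df.chrom, df.pos)]
    return GwasDataset(dataset.trait_id, dataset.trait_type, _coerce_dtypes(df))


def simulate_screen(
    truths: dict[str, SimulationTruth],
) -> tuple[list[GwasDataset], GwasDataset, LDMatrix]:
    """A multi-exposure screen: one outcome GWAS covering every exposure's
    SNPs, mutually independent panels (identity LD).

    ``truths`` maps exposure trait ids to their generating parameters; SNP
    ids are namespaced per exposure so the shared outcome dataset stays
    duplicate-free.
    """
    exposures: list[GwasDataset] = []
    outcome_frames = []
    all_ids: list[str] = []
    for i, (trait_id, truth) in enumerate(sorted(truths.items())):
        exp, out, _ = simulate_taxon(truth, trait_id=trait_id, snp_prefix=f"t{i:03d}_snp")
        exposures.append(exp)
        outcome_frames.append(out.df)
        all_ids.extend(out.snp_ids)
    outcome_df = pd.concat(outcome_frames, ignore_index=True)
    outcome = GwasDataset("outcome", "outcome", outcome_df)
    return exposures, outcome, LDMatrix.identity(all_ids)


# ---------------------------------------------------------------------------
# Named scenarios (CLI and calibration studies)

SCENARIOS = ("null", "causal", "directional", "balanced", "heterogeneous", "weak")


def make_scenario(name: str, k: int = 20, seed: int = 0) -> SimulationTruth:
    """Preset generating conditions for the standard study scenarios.

    ``null``: no causal effect, clean instruments.  ``causal``: θ = 0.2.
    ``directional``/``balanced``: pleiotropy with/without a mean direct
    effect of 0.05.  ``heterogeneous``: extra outcome-effect noise.
    ``weak``: a small exposure GWAS (n = 2,000) so per-SNP F values fall
    near the F > 10 bar.
    """
    base = SimulationTruth(seed=seed, k_true=k)
    presets = {
        "null": {},
        "causal": {"theta": 0.2},
        "directional": {"theta": 0.2, "pleiotropy_mode": "directional",
                        "pleio_mean": 0.05, "pleio_sd": 0.02},
        "balanced": {"theta": 0.2, "pleiotropy_mode": "balanced", "pleio_sd": 0.05},
        "heterogeneous": {"theta": 0.2, "het_sd": 0.05},
        "weak": {"theta": 0.2, "n_exp": 2_000},
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return replace(base, **presets[name])
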