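"""Sensitivity diagnostics: heterogeneity, pleiotropy, influence, strength.

Four checks guard an MR estimate:

* **Cochran's Q** — weighted sum of squared deviations of the per-SNP Wald
  ratios from the pooled fixed-effect estimate, referred to chi-square with
  k − 1 df.  A small p signals heterogeneity: instruments disagree about
  the causal effect, often because some act through other pathways.
* **MR-Egger intercept** (in :mod:`mrscreen.estimators`) — directional
  pleiotropy.
* **Leave-one-out** — IVW re-estimated k times dropping each instrument in
  turn; a row is flagged influential when removing that SNP flips the sign
  of the estimate or moves its p-value across 0.05.
* **Instrument strength** — per-SNP variance explained
  R² = 2·(1 − MAF)·MAF·β² and the F statistic
  F = R²/(1 − R²) · (n − k − 1)/k, with F > 10 the conventional
  weak-instrument bar.  F is reported per SNP with k = 1 (the per-variant
  convention matching published per-SNP F values); a joint-k variant is
  also carried for reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, _ivw_fixed
from .harmonize import HarmonizedSet
from .sumstats import SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity test."""

    q: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("Q must be >= 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP variance explained and F statistic.

    ``r2``/``f`` are NaN when the effect-allele frequency is unavailable
    (the MAF enters the R² formula).  ``f_joint`` is F evaluated with k set
    to the exposure's full instrument count instead of 1.
    """

    snp_id: str
    r2: float
    f: float
    maf: float
    f_joint: float = float("nan")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.f)


@dataclass(frozen=True)
class LeaveOneOutRow:
    """IVW on all instruments except ``excluded_snp``."""

    excluded_snp: str
    estimate: MREstimate
    influential: bool


def cochran_q(h: HarmonizedSet) -> QResult:
    """Heterogeneity of the per-SNP Wald ratios about the IVW estimate.

    Q = Σ_j w_j (θ_j − θ̂)² with w_j = βX_j²/σY_j² and θ̂ the fixed-effect
    IVW estimate; p is the upper chi-square tail on k − 1 df.
    """
    k = len(h)
    if k < 2:
        raise ValueError(f"cochran_q needs >= 2 instruments, got {k}")
    _, _, q, _ = _ivw_fixed(h.beta_exp, h.beta_out, h.se_out)
    df = k - 1
    return QResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def per_snp_q_contributions(h: HarmonizedSet) -> np.ndarray:
    """Each instrument's term w_j (θ_j − θ̂)² of Cochran's Q."""
    beta, _, _, w = _ivw_fixed(h.beta_exp, h.beta_out, h.se_out)
    theta = h.beta_out / h.beta_exp
    return w * (theta - beta) ** 2


def instrument_strength(
    record: SummaryStatRecord, n: float | None = None, k: int = 1
) -> InstrumentStrength:
    """Variance explained and F statistic for one exposure-GWAS SNP.

    R² = 2·(1 − MAF)·MAF·β², MAF = min(eaf, 1 − eaf);
    F = R²/(1 − R²) · (n − k − 1)/k.  ``n`` defaults to the record's sample
    size.  A missing frequency yields a flagged result with NaN r2/f; R² ≥ 1
    marks malformed input (a per-allele beta that large cannot come from a
    real standardized-trait GWAS) and raises.
    """
    n = n if n is not None else record.n
    if record.eaf is None or n is None:
        logger.warning("%s: eaf or n missing, F undefined", record.snp_id)
        return InstrumentStrength(record.snp_id, float("nan"), float("nan"), float("nan"))
    if n <= k + 1:
        raise ValueError(f"{record.snp_id}: need n > k + 1 (n={n}, k={k})")
    maf = min(record.eaf, 1.0 - record.eaf)
    r2 = 2.0 * (1.0 - maf) * maf * record.beta**2
    if r2 >= 1.0:
        raise ValueError(f"{record.snp_id}: R² = {r2:.3f} >= 1, malformed input")
    f = (r2 / (1.0 - r2)) * ((n - k - 1.0) / k)
    f_joint = f if k != 1 else float("nan")
    return InstrumentStrength(record.snp_id, r2=r2, f=f, maf=maf, f_joint=f_joint)


def filter_weak_instruments(
    strengths, f_min: float = 10.0, strict_missing: bool = False
) -> tuple[list[InstrumentStrength], list[InstrumentStrength]]:
    """Split instruments by the weak-instrument bar F > ``f_min``.

    Instruments with F ≤ ``f_min`` are removed; instruments with undefined F
    (missing frequency) are kept with a warning unless ``strict_missing``.
    Returns ``(kept, removed)``, disjoint, exhausting the input.
    """
    kept, removed = [], []
    for s in strengths:
        if not s.defined:
            if strict_missing:
                removed.append(s)
            else:
                logger.warning("%s: F undefined, kept (permissive policy)", s.snp_id)
                kept.append(s)
        elif s.f <= f_min:
            removed.append(s)
        else:
            kept.append(s)
    return kept, removed


def leave_one_out(h: HarmonizedSet, alpha: float = 0.05) -> list[LeaveOneOutRow]:
    """IVW re-estimated without each instrument in turn.

    A row is influential when, relative to the full-set IVW, excluding that
    SNP flips the sign of the estimate or moves the p-value across ``alpha``.
    Requires k ≥ 3 so every reduced set still supports IVW.
    """
    k = len(h)
    if k < 3:
        raise ValueError(f"leave_one_out needs >= 3 instruments, got {k}")
    full = ivw(h)
    rows = []
    for snp_id in h.snp_ids:
        est = ivw(h.drop_snps([snp_id]))
        influential = (np.sign(est.beta) != np.sign(full.beta)) or (
            (est.pvalue < alpha) != (full.pvalue < alpha)
        )
        rows.append(LeaveOneOutRow(snp_id, est, bool(influential)))
    return rows


def loo_table_rows(rows) -> list[dict]:
    """Flatten leave-one-out rows for TSV/JSON serialisation."""
    return [
        {
            "excluded_snp": r.excluded_snp, "beta": r.estimate.beta,
            "se": r.estimate.se, "or": r.estimate.or_,
            "ci_low": r.estimate.ci_low, "ci_high": r.estimate.ci_high,
            "p": r.estimate.pvalue, "influential": r.influential,
        }
        for r in rows
    ]
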