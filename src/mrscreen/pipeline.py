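"""Batch screening of many exposures against one outcome.

``run_taxon`` chains the full per-exposure analysis — instrument selection,
harmonization, weak-instrument filtering, IVW/weighted-median/MR-Egger
estimation, and the sensitivity suite — and applies the verdict rule:

* ``no_instruments`` — no SNP survives selection/harmonization/QC;
* ``unreliable`` — heterogeneity (Q) or directional pleiotropy (Egger
  intercept) detected at level alpha, or too few instruments (< 3) to run
  the sensitivity tests at all;
* ``associated`` — IVW p < alpha with both sensitivity tests clean;
* ``not_associated`` — otherwise.

An associated exposure is additionally labelled ``protective`` (OR < 1) or
``risk`` (OR > 1).  ``annotate_decision_rules`` operationalises the
">50% heterogeneous SNPs → report the weighted median" and ">50%
pleiotropic SNPs → report MR-Egger" headline rules by classifying each
instrument from its Cochran-Q contribution (chi-square(1) tail) and its
studentized MR-Egger residual.

``run_batch`` maps ``run_taxon`` over an exposure collection (sorted by
trait id, unnamed taxa optionally excluded, per-taxon seeds derived as
``seed + index``), captures per-taxon failures without aborting the batch,
and attaches an informational Benjamini–Hochberg column over the IVW
p-values — verdicts themselves use nominal alpha only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sensitivity as sens
from .estimators import EggerIntercept, MREstimate, _egger_fit, ivw, mr_egger, wald_ratio, weighted_median
from .harmonize import HarmonizedSet, harmonize
from .instruments import ClumpConfig, LDMatrix, select_instruments
from .sumstats import GwasDataset

logger = logging.getLogger(__name__)

TAXON_LEVELS = ("phylum", "class", "order", "family", "genus")
VERDICTS = ("associated", "not_associated", "unreliable", "no_instruments")


@dataclass(frozen=True)
class PipelineConfig:
    """Screening-wide settings.

    ``alpha`` drives the IVW significance call and both sensitivity gates;
    ``f_min`` is the weak-instrument F bar; ``exclude_unnamed_taxa`` drops
    exposures whose id contains ``unknown_marker`` (unnamed taxa carry no
    interpretable identity).  ``seed`` feeds the weighted-median bootstrap,
    with per-taxon seeds derived as ``seed + index`` over the sorted batch.
    """

    clump: ClumpConfig = field(default_factory=ClumpConfig)
    alpha: float = 0.05
    f_min: float = 10.0
    n_boot: int = 1000
    seed: int = 0
    exclude_unnamed_taxa: bool = True
    unknown_marker: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class TaxonResult:
    """Everything the screen knows about one exposure."""

    exposure_id: str
    level: str
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    q: sens.QResult | None = None
    egger_intercept: EggerIntercept | None = None
    loo: list[sens.LeaveOneOutRow] = field(default_factory=list)
    strengths: list[sens.InstrumentStrength] = field(default_factory=list)
    verdict: str = "no_instruments"
    direction: str = "none"
    headline: str = "ivw"
    dropped: list[tuple[str, str]] = field(default_factory=list)
    n_heterogeneous: int = 0
    n_pleiotropic: int = 0
    ivw_p_bh: float | None = None
    counts: dict = field(default_factory=dict)
    error: str | None = None
    harmonized: HarmonizedSet | None = None  # retained for annotation; not serialised

    def loo_table(self) -> list[dict]:
        return sens.loo_table_rows(self.loo)


def infer_level(exposure_id: str) -> str:
    """Taxonomic rank from a MiBioGen-style id like ``genus.Blautia.id.123``."""
    prefix = exposure_id.split(".", 1)[0].lower()
    return prefix if prefix in TAXON_LEVELS else "unknown"


def _apply_verdict(result: TaxonResult, alpha: float) -> None:
    est = result.estimates.get("ivw")
    if est is None or result.q is None or result.egger_intercept is None:
        # Not enough instruments for the sensitivity suite: no defensible call.
        if result.estimates:
            result.verdict = "unreliable"
        else:
            result.verdict = "no_instruments"
        result.direction = "none"
        return
    if result.q.pvalue <= alpha or result.egger_intercept.pvalue <= alpha:
        result.verdict = "unreliable"
    elif est.pvalue < alpha:
        result.verdict = "associated"
    else:
        result.verdict = "not_associated"
    if result.verdict == "associated":
        result.direction = "protective" if est.or_ < 1.0 else "risk"
    else:
        result.direction = "none"


def annotate_decision_rules(result: TaxonResult, config: PipelineConfig) -> TaxonResult:
    """Flag per-instrument heterogeneity/pleiotropy and pick the headline.

    An instrument is *heterogeneous* when its Cochran-Q contribution
    w_j (θ_j − θ̂)² exceeds the chi-square(1) upper-alpha quantile, and
    *pleiotropic* when its |studentized MR-Egger residual| exceeds the
    two-sided normal alpha quantile.  More than 50% heterogeneous flips the
    headline estimate to the weighted median; more than 50% pleiotropic to
    MR-Egger.  Annotation only: the IVW estimate is always reported.
    """
    h = result.harmonized
    result.headline = "ivw"
    result.n_heterogeneous = result.n_pleiotropic = 0
    if h is None or len(h) < 2 or "ivw" not in result.estimates:
        return result
    k = len(h)
    contrib = sens.per_snp_q_contributions(h)
    het = stats.chi2.sf(contrib, 1) <= config.alpha
    result.n_heterogeneous = int(het.sum())
    if k >= 3:
        fit = _egger_fit(h)
        z = stats.norm.ppf(1 - config.alpha / 2)
        pleio = np.abs(fit.studentized_residuals()) > z
        result.n_pleiotropic = int(pleio.sum())
    if result.n_heterogeneous > 0.5 * k and "weighted_median" in result.estimates:
        result.headline = "weighted_median"
    elif result.n_pleiotropic > 0.5 * k and "mr_egger" in result.estimates:
        result.headline = "mr_egger"
    return result


def run_taxon(
    exposure: GwasDataset,
    outcome: GwasDataset,
    ld: LDMatrix,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> TaxonResult:
    """Full MR analysis of one exposure against the outcome.

    Stages: instrument selection (p-filter + LD clumping), harmonization,
    per-SNP F computation and weak-instrument removal, estimation (IVW
    primary; weighted median at k ≥ 2, MR-Egger at k ≥ 3), sensitivity
    suite, headline annotation, verdict.  ``seed`` (default: config.seed)
    drives the weighted-median bootstrap.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    result = TaxonResult(exposure.trait_id, infer_level(exposure.trait_id))

    selected = select_instruments(exposure, ld, config.clump)
    result.counts.update(selected.meta)
    if len(selected) == 0:
        return result

    h = harmonize(selected, outcome)
    result.dropped = list(h.dropped)
    result.counts["removed_harmonization"] = len(h.dropped)
    if len(h) == 0:
        return result

    # Per-SNP instrument strength from the exposure records of the
    # harmonized instruments (k = 1 convention drives the F > 10 bar).
    exp_records = {r.snp_id: r for r in selected.records()}
    strengths = [sens.instrument_strength(exp_records[s]) for s in h.snp_ids]
    kept, removed = sens.filter_weak_instruments(strengths, f_min=config.f_min)
    result.strengths = kept + removed
    result.counts["removed_weak"] = len(removed)
    if removed:
        h = h.drop_snps([s.snp_id for s in removed])
    result.harmonized = h
    k = len(h)
    result.counts["n_analyzed"] = k
    if k == 0:
        return result

    if k == 1:
        result.estimates["wald_ratio"] = wald_ratio(next(iter(h)))
    else:
        result.estimates["ivw"] = ivw(h)
        result.estimates["weighted_median"] = weighted_median(h, n_boot=config.n_boot, seed=seed)
        result.q = sens.cochran_q(h)
        if k >= 3:
            egger_est, egger_int = mr_egger(h)
            result.estimates["mr_egger"] = egger_est
            result.egger_intercept = egger_int
            result.loo = sens.leave_one_out(h, alpha=config.alpha)

    annotate_decision_rules(result, config)
    _apply_verdict(result, config.alpha)
    return result


def run_batch(
    exposures: list[GwasDataset],
    outcome: GwasDataset,
    ld: LDMatrix,
    config: PipelineConfig | None = None,
) -> list[TaxonResult]:
    """Screen every exposure against the outcome.

    Exposures are sorted by trait id before seeding so results are stable
    under input reordering; taxa whose id contains the unnamed-taxon marker
    are excluded when configured.  A failure in one taxon is captured in its
    result (verdict ``no_instruments``, ``error`` set) without stopping the
    batch.  The informational BH-adjusted IVW p column is filled across all
    taxa with an IVW estimate.
    """
    config = config or PipelineConfig()
    if not exposures:
        raise ValueError("run_batch needs >= 1 exposure")
    ordered = sorted(exposures, key=lambda d: d.trait_id)
    if config.exclude_unnamed_taxa:
        n0 = len(ordered)
        ordered = [e for e in ordered if config.unknown_marker not in e.trait_id.lower()]
        if len(ordered) < n0:
            logger.info("excluded %d unnamed taxa", n0 - len(ordered))

    results: list[TaxonResult] = []
    for index, exposure in enumerate(ordered):
        try:
            res = run_taxon(exposure, outcome, ld, config, seed=config.seed + index)
        except Exception as exc:  # pragma: no cover - defensive per-taxon capture
            logger.exception("taxon %s failed", exposure.trait_id)
            res = TaxonResult(exposure.trait_id, infer_level(exposure.trait_id), error=str(exc))
        results.append(res)

    with_ivw = [r for r in results if "ivw" in r.estimates]
    if with_ivw:
        pvals = np.array([r.estimates["ivw"].pvalue for r in with_ivw])
        for r, p_adj in zip(with_ivw, stats.false_discovery_control(pvals)):
            r.ivw_p_bh = float(p_adj)
    return results


def summarize_batch(results: list[TaxonResult]) -> pd.DataFrame:
    """Verdict x taxonomic-level count table (plus analyzed-SNP totals)."""
    rows = [
        {
            "level": r.level,
            "verdict": r.verdict,
            "n_snp": r.counts.get("n_analyzed", 0),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["level", "verdict"])
        .agg(n_taxa=("verdict", "size"), n_snp=("n_snp", "sum"))
        .reset_index()
    )
    return table
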