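"""GWAS summary-statistic containers and delimited-text I/O.

Two-sample MR consumes per-SNP association statistics (effect size on the
effect allele, its standard error, p-value, allele frequency, sample size)
from one exposure GWAS and one outcome GWAS.  This module defines the
validated in-memory containers for those statistics and reads/writes them
as tab- or comma-separated text with a configurable column mapping, so any
consortium export (MiBioGen-style exposure files, FinnGen-style outcome
files, TwoSampleMR exchange format) can be loaded without reformatting.

Datasets are DataFrame-backed: validation is vectorised and rows violating
the record invariants (non-ACGT or identical alleles, non-positive SE,
p outside (0, 1], frequency outside [0, 1]) are dropped and counted rather
than aborting the load.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the native TSV format.
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: Columns that must be present (directly or via column map) in any input.
MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]

#: Column names used by the common two-sample-MR exchange format.
TWOSAMPLEMR_COLUMN_MAP = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}


class SumstatsError(ValueError):
    """Malformed summary-statistics input (missing column, empty file...)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association statistics in one GWAS.

    ``beta`` is the per-effect-allele effect; for binary traits it is on the
    log-odds scale.  ``eaf`` (effect-allele frequency) and ``n`` (sample
    size) are optional but required downstream for instrument-strength
    statistics.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumstatsError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise SumstatsError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"{self.snp_id}: pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.pos is not None and self.pos < 1:
            raise SumstatsError(f"{self.snp_id}: pos must be >= 1 (1-based), got {self.pos}")


@dataclass
class GwasDataset:
    """An ordered, validated collection of per-SNP statistics for one trait.

    Parameters
    ----------
    trait_id : str
        Trait label, e.g. a taxon name like ``"genus.Anaerotruncus"`` or
        ``"outcome"``.
    trait_type : {"exposure", "outcome"}
    df : pandas.DataFrame
        One row per SNP with the columns in :data:`CANONICAL_COLUMNS`.
        ``snp_id`` is unique; row order is meaningful and preserved.
    n_dropped : int
        Rows removed during validation/deduplication at construction.
    meta : dict
        Free-form provenance (stage counts from instrument selection etc.).
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("exposure", "outcome"):
            raise SumstatsError(f"trait_type must be exposure|outcome, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"dataset missing canonical columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            raise SumstatsError(f"{self.trait_id}: duplicate snp_id in dataset")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def subset(self, snp_ids: Sequence[str]) -> "GwasDataset":
        """Rows for ``snp_ids``, in the order given."""
        sub = self.df.set_index("snp_id", drop=False).loc[list(snp_ids)].reset_index(drop=True)
        return GwasDataset(self.trait_id, self.trait_type, sub)

    def records(self) -> Iterator[SummaryStatRecord]:
        for row in self.df.itertuples(index=False):
            yield SummaryStatRecord(
                snp_id=row.snp_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=row.beta,
                se=row.se,
                pvalue=row.pvalue,
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
                pos=None if pd.isna(row.pos) else int(row.pos),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )

    @classmethod
    def from_records(
        cls, records: Sequence[SummaryStatRecord], trait_id: str, trait_type: str
    ) -> "GwasDataset":
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(trait_id, trait_type, _coerce_dtypes(df))


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype("string")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        if pd.api.types.is_numeric_dtype(df[col]):
            df[col] = df[col].astype(float)
        else:
            # float() is shortest-round-trip exact; pd.to_numeric is not
            df[col] = df[col].map(_parse_float).astype(float)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    return df


def _parse_float(x) -> float:
    if pd.isna(x):
        return float("nan")
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def _validate_rows(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows satisfying the record invariants (vectorised)."""
    ea, oa = df["effect_allele"], df["other_allele"]
    ok = (
        ea.isin(list(VALID_ALLELES))
        & oa.isin(list(VALID_ALLELES))
        & (ea != oa)
        & df["beta"].notna()
        & np.isfinite(df["beta"].to_numpy())
        & (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["pos"].isna() | (df["pos"] >= 1))
    )
    return ok.fillna(False)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise SumstatsError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    trait_id: str,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "exposure",
) -> GwasDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    ``column_map`` maps canonical field names (:data:`CANONICAL_COLUMNS`) to
    the source file's column names; omitted optional fields are filled with
    NA.  The delimiter (tab or comma) is auto-detected from the header line.
    Rows violating record invariants are dropped and counted; duplicate
    ``snp_id`` rows keep the first occurrence.

    Raises
    ------
    SumstatsError
        If the file is empty or a mandatory column is absent.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", "", "nan"])
    if raw.empty and raw.columns.size == 0:
        raise SumstatsError(f"{path}: empty file")
    cmap = dict(column_map) if column_map is not None else {c: c for c in CANONICAL_COLUMNS}
    for canon in MANDATORY_COLUMNS:
        src = cmap.get(canon, canon)
        if src not in raw.columns:
            raise SumstatsError(f"{path}: mandatory column {canon!r} (source {src!r}) not found")
    df = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        src = cmap.get(canon, canon)
        df[canon] = raw[src] if src in raw.columns else pd.NA
    df = _coerce_dtypes(df)

    n_in = len(df)
    ok = _validate_rows(df)
    n_invalid = int((~ok).sum())
    df = df[ok]
    dup = df["snp_id"].duplicated(keep="first")
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    if n_invalid or n_dup:
        logger.warning(
            "%s (%s): dropped %d invalid and %d duplicate of %d rows",
            trait_id, path.name, n_invalid, n_dup, n_in,
        )
    return GwasDataset(trait_id, trait_type, df, n_dropped=n_invalid + n_dup)


def write_sumstats(dataset: GwasDataset, path: str | Path) -> None:
    """Write a dataset in the canonical tab-separated format.

    Fixed header order (:data:`CANONICAL_COLUMNS`); missing optionals are
    serialised as ``NA``.  Floats use shortest round-trip representation so
    that ``read_sumstats`` recovers the values exactly.
    """
    df = dataset.df[CANONICAL_COLUMNS].copy()

    def _fmt(v) -> str:
        if pd.isna(v):
            return "NA"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Screening report

#: (exposure, method)-level columns of the screening report.
REPORT_COLUMNS = [
    "exposure_id", "level", "method", "n_snp", "beta", "se", "or", "ci_low",
    "ci_high", "pvalue", "q", "q_df", "q_pvalue", "egger_intercept",
    "egger_intercept_se", "egger_intercept_pvalue", "headline", "verdict",
    "direction", "ivw_p_bh",
]


def write_report(results: Sequence, path: str | Path, json_path: str | Path | None = None) -> None:
    """Serialise batch screening results as a TSV plus a JSON twin.

    One TSV row per (exposure, method).  The JSON twin carries the same
    per-method rows plus, per exposure, the harmonization drop log and the
    leave-one-out table, which do not fit the flat layout.

    Parameters
    ----------
    results : sequence of TaxonResult
    path : TSV destination.
    json_path : JSON destination; defaults to ``path`` with ``.json`` suffix.
    """
    if len(results) == 0:
        raise SumstatsError("write_report: empty result collection")
    path = Path(path)
    json_path = Path(json_path) if json_path is not None else path.with_suffix(".json")

    rows, taxa = [], []
    for res in results:
        common = {
            "exposure_id": res.exposure_id,
            "level": res.level,
            "q": None if res.q is None else res.q.q,
            "q_df": None if res.q is None else res.q.df,
            "q_pvalue": None if res.q is None else res.q.pvalue,
            "egger_intercept": None if res.egger_intercept is None else res.egger_intercept.intercept,
            "egger_intercept_se": None if res.egger_intercept is None else res.egger_intercept.se,
            "egger_intercept_pvalue": None if res.egger_intercept is None else res.egger_intercept.pvalue,
            "headline": res.headline,
            "verdict": res.verdict,
            "direction": res.direction,
            "ivw_p_bh": res.ivw_p_bh,
        }
        method_rows = []
        for method, est in res.estimates.items():
            row = dict(common)
            row.update(
                method=method, n_snp=est.n_snp, beta=est.beta, se=est.se,
                **{"or": est.or_}, ci_low=est.ci_low, ci_high=est.ci_high,
                pvalue=est.pvalue,
            )
            method_rows.append(row)
        if not method_rows:  # no estimable method (e.g. no instruments)
            row = dict(common)
            row.update(method="none", n_snp=0, beta=None, se=None,
                       **{"or": None}, ci_low=None, ci_high=None, pvalue=None)
            method_rows.append(row)
        rows.extend(method_rows)
        taxa.append(
            {
                "exposure_id": res.exposure_id,
                "rows": method_rows,
                "dropped": [list(d) for d in res.dropped],
                "leave_one_out": res.loo_table(),
            }
        )

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report.to_csv(path, sep="\t", index=False, na_rep="NA")
    with open(json_path, "w") as fh:
        json.dump({"results": taxa}, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
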