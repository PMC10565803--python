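"""Allele harmonization between exposure and outcome summary statistics.

Exposure and outcome GWAS may report the same SNP against different effect
alleles.  Harmonization aligns the outcome effect to the exposure's effect
allele: identical allele pairs are kept as-is, swapped pairs (outcome effect
allele = exposure other allele) have the outcome beta negated, and anything
else is dropped as an allele mismatch.  Palindromic SNPs (A/T or C/G) are
removed unconditionally — their strand cannot be resolved from the alleles,
so an apparent allele match may in fact be a strand flip.  No allele-
frequency rescue of palindromes and no strand complementing is attempted;
ambiguous variants are dropped and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .sumstats import GwasDataset, VALID_ALLELES

DROP_REASONS = ("palindromic", "allele_mismatch", "missing_in_outcome")


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous: {A,T} or {C,G}."""
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"invalid alleles {a1!r}/{a2!r}")
    if a1 == a2:
        raise ValueError(f"identical alleles {a1!r}: palindromy undefined")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's aligned exposure and outcome effects.

    ``beta_out`` is expressed on the exposure's effect allele; ``flipped``
    records whether the outcome file reported the opposite allele.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_exp > 0:
            raise ValueError(f"{self.snp_id}: se_exp must be > 0")
        if not self.se_out > 0:
            raise ValueError(f"{self.snp_id}: se_out must be > 0")


@dataclass
class HarmonizedSet:
    """Aligned instruments for one exposure, plus the drop log.

    Array access (``beta_exp`` etc.) is what the estimators consume; the
    instruments are also iterable as :class:`HarmonizedInstrument` records.
    """

    exposure_id: str
    df: pd.DataFrame  # snp_id, beta_exp, se_exp, beta_out, se_out, eaf_exp, flipped
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in harmonized set")
        for _, reason in self.dropped:
            if reason not in DROP_REASONS:
                raise ValueError(f"unknown drop reason {reason!r}")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        for row in self.df.itertuples(index=False):
            yield HarmonizedInstrument(
                snp_id=row.snp_id, beta_exp=row.beta_exp, se_exp=row.se_exp,
                beta_out=row.beta_out, se_out=row.se_out,
                eaf_exp=None if pd.isna(row.eaf_exp) else row.eaf_exp,
                flipped=bool(row.flipped),
            )

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(dtype=float)

    def drop_snps(self, snp_ids) -> "HarmonizedSet":
        """Set minus the named instruments (drop log not carried over)."""
        snp_ids = set(snp_ids)
        sub = self.df[~self.df["snp_id"].isin(snp_ids)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_id, sub)

    @classmethod
    def from_instruments(cls, exposure_id, instruments, dropped=()) -> "HarmonizedSet":
        df = pd.DataFrame(
            [
                {
                    "snp_id": i.snp_id, "beta_exp": i.beta_exp, "se_exp": i.se_exp,
                    "beta_out": i.beta_out, "se_out": i.se_out,
                    "eaf_exp": np.nan if i.eaf_exp is None else i.eaf_exp,
                    "flipped": i.flipped,
                }
                for i in instruments
            ],
            columns=["snp_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "flipped"],
        )
        return cls(exposure_id, df, list(dropped))


def harmonize(exposure: GwasDataset, outcome: GwasDataset) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    For each exposure instrument, in order: drop if the SNP is absent from
    the outcome GWAS (``missing_in_outcome``); drop if the allele pair is
    palindromic in either dataset (``palindromic``); keep as-is when the
    outcome reports the same allele pair; negate ``beta_out`` and flag
    ``flipped`` when the outcome reports the swapped pair; otherwise drop
    (``allele_mismatch`` — including strand complements, which are not
    rescued).  ``len(instruments) + len(dropped) == len(exposure)``.
    """
    out_by_snp = {r.snp_id: r for r in outcome.df.itertuples(index=False)}
    kept: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for e in exposure.df.itertuples(index=False):
        o = out_by_snp.get(e.snp_id)
        if o is None:
            dropped.append((e.snp_id, "missing_in_outcome"))
            continue
        if is_palindromic(e.effect_allele, e.other_allele) or is_palindromic(
            o.effect_allele, o.other_allele
        ):
            dropped.append((e.snp_id, "palindromic"))
            continue
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            beta_out, flipped = o.beta, False
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            beta_out, flipped = -o.beta, True
        else:
            dropped.append((e.snp_id, "allele_mismatch"))
            continue
        kept.append(
            HarmonizedInstrument(
                snp_id=e.snp_id, beta_exp=e.beta, se_exp=e.se,
                beta_out=beta_out, se_out=o.se,
                eaf_exp=None if pd.isna(e.eaf) else float(e.eaf),
                flipped=flipped,
            )
        )
    return HarmonizedSet.from_instruments(exposure.trait_id, kept, dropped)
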