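"""Collapse qualifying variants into per-sample burden predictors.

Two collapsing modes are provided:

- CARRIER: the gene-level coding used for the exome-wide scans — a
  sample is coded 1 if it carries at least one qualifying alternate
  allele anywhere in the gene, irrespective of how many qualifying
  variants or alleles it carries, else 0. This mirrors the "dummy
  genotype" convention in which every carrier is represented as a
  heterozygote for one pseudo-variant per gene.
- ADDITIVE: the domain-level score — the per-sample sum of alternate
  allele dosages over the (typically domain-restricted) mask, so a
  homozygote contributes 2 and a carrier of variants in two domains
  contributes one count per allele.

Missing genotypes contribute zero alleles in both modes; samples are
never dropped here (phenotype-side listwise deletion happens in the
association stage).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .annotation_masks import VariantMask
from .variant_io import MISSING, CohortGenotypes


class BurdenMode(enum.Enum):
    CARRIER = "carrier"
    ADDITIVE = "additive"


@dataclasses.dataclass(frozen=True)
class BurdenVector:
    """Per-sample burden predictor for one gene/mask/scope combination."""

    gene_symbol: str
    mask_name: str
    domain_scope: tuple[str, ...] | None
    mode: BurdenMode
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        if len(self.values) != len(self.sample_ids):
            raise ValueError("values and sample_ids length mismatch")
        if self.mode is BurdenMode.CARRIER and not np.isin(self.values, (0, 1)).all():
            raise ValueError("CARRIER values must be 0/1")
        if (self.values < 0).any():
            raise ValueError("burden values must be non-negative")


def _mask_dosage(mask: VariantMask, cohort: CohortGenotypes) -> np.ndarray:
    if not mask.variant_ids:
        raise ValueError(
            f"mask {mask.mask_name} for {mask.gene_symbol} is empty: no testable burden"
        )
    idx = [cohort.variant_index(vid) for vid in sorted(mask.variant_ids)]
    d = cohort.dosage[idx].copy()
    d[d == MISSING] = 0  # missing genotypes contribute no alleles
    return d


def collapse_carriers(mask: VariantMask, cohort: CohortGenotypes) -> BurdenVector:
    """0/1 carrier indicator: 1 iff >= 1 qualifying alternate allele."""
    d = _mask_dosage(mask, cohort)
    return BurdenVector(
        gene_symbol=mask.gene_symbol,
        mask_name=mask.mask_name,
        domain_scope=mask.domain_scope,
        mode=BurdenMode.CARRIER,
        sample_ids=tuple(cohort.samples),
        values=(d.sum(axis=0) > 0).astype(np.int64),
    )


def additive_score(mask: VariantMask, cohort: CohortGenotypes) -> BurdenVector:
    """Integer allele-count score: sum of dosages over mask variants."""
    d = _mask_dosage(mask, cohort)
    return BurdenVector(
        gene_symbol=mask.gene_symbol,
        mask_name=mask.mask_name,
        domain_scope=mask.domain_scope,
        mode=BurdenMode.ADDITIVE,
        sample_ids=tuple(cohort.samples),
        values=d.sum(axis=0),
    )


def collapse(mask: VariantMask, cohort: CohortGenotypes, mode: BurdenMode) -> BurdenVector:
    if mode is BurdenMode.CARRIER:
        return collapse_carriers(mask, cohort)
    return additive_score(mask, cohort)


def carrier_count(v: BurdenVector) -> int:
    """Number of samples with a non-zero burden value."""
    return int((v.values >= 1).sum())
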