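"""Genotype-level and variant-level quality control.

The filter chain reproduces the missingness-based exome QC used for
biobank-scale burden testing:

1. SNV genotypes with depth < 7 or genotype quality < 20, and indel
   genotypes with depth < 10 or genotype quality < 20, are set to missing
   (``./.``). The depth/quality conjunction is configurable (``dp_gq_logic``)
   because the convention is stated ambiguously in most pipeline
   descriptions; OR (either condition suffices) is the default.
2. Heterozygous SNV genotypes whose allele balance departs from the
   expected 50% alternate-read contribution — two-sided exact binomial
   test p <= 1e-3 — are set to missing (genotyping error / somatic signal).
3. Per-variant missingness is recomputed and variants with missingness
   strictly above 50% are dropped.

Applying the chain twice is a no-op: every rule only acts on genotypes
that are still non-missing.
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING, CohortGenotypes, GenotypeEntry

logger = logging.getLogger(__name__)


class VariantClass(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class DpGqLogic(enum.Enum):
    #: either low depth or low quality sets the genotype missing
    OR = "OR"
    #: both must fail (literal reading of "depth < t and GQ < 20")
    AND = "AND"


@dataclasses.dataclass
class QcConfig:
    """Thresholds for the genotype-level and variant-level filters."""

    snv_min_dp: int = 7
    indel_min_dp: int = 10
    min_gq: int = 20
    ab_p_threshold: float = 1e-3
    max_missingness: float = 0.50
    dp_gq_logic: DpGqLogic = DpGqLogic.OR

    def __post_init__(self) -> None:
        if isinstance(self.dp_gq_logic, str):
            self.dp_gq_logic = DpGqLogic(self.dp_gq_logic.upper())
        if min(self.snv_min_dp, self.indel_min_dp, self.min_gq) < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0 < self.ab_p_threshold < 1):
            raise ValueError("ab_p_threshold must be in (0, 1)")
        if not (0 < self.max_missingness < 1):
            raise ValueError("max_missingness must be in (0, 1)")


@dataclasses.dataclass
class QcReport:
    """Per-variant tallies of genotypes set missing and variants dropped."""

    per_variant: pd.DataFrame  # variant_id, n_dp_gq, n_allele_balance, missingness, dropped
    n_variants_in: int
    n_variants_dropped: int

    @property
    def n_variants_retained(self) -> int:
        return self.n_variants_in - self.n_variants_dropped

    @property
    def total_dp_gq(self) -> int:
        return int(self.per_variant["n_dp_gq"].sum())

    @property
    def total_allele_balance(self) -> int:
        return int(self.per_variant["n_allele_balance"].sum())

    @property
    def dropped_variant_ids(self) -> list[str]:
        df = self.per_variant
        return df.loc[df["dropped"], "variant_id"].tolist()

    def is_all_zero(self) -> bool:
        return (
            self.total_dp_gq == 0
            and self.total_allele_balance == 0
            and self.n_variants_dropped == 0
        )

    def write(self, path) -> None:
        self.per_variant.to_csv(path, sep="\t", index=False)


def classify_variant(ref: str, alt: str) -> VariantClass:
    """SNV iff both alleles are single bases; MNVs are grouped with indels."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    return VariantClass.INDEL


def allele_balance_p(ad_ref: int, ad_alt: int) -> float:
    """Two-sided exact binomial p-value for the het allele-balance test.

    Tests ``k = ad_alt`` alternate-supporting reads out of
    ``n = ad_ref + ad_alt`` informative reads against an expected
    alternate contribution of 50%. At p0 = 0.5 the two-sided exact test
    reduces to ``min(1, 2 * P(X <= min(k, n - k)))``.
    """
    if ad_ref < 0 or ad_alt < 0:
        raise ValueError("read counts must be non-negative")
    n = ad_ref + ad_alt
    if n == 0:
        raise ValueError("no informative reads (ad_ref + ad_alt == 0)")
    m = min(ad_alt, n - ad_alt)
    return float(min(1.0, 2.0 * stats.binom.cdf(m, n, 0.5)))


def _ab_p_vector(ad_ref: np.ndarray, ad_alt: np.ndarray) -> np.ndarray:
    n = ad_ref + ad_alt
    m = np.minimum(ad_alt, n - ad_alt)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.binom.cdf(m, n, 0.5)
    return np.minimum(p, 1.0)


def filter_genotype(
    entry: GenotypeEntry, vclass: VariantClass, cfg: QcConfig | None = None
) -> GenotypeEntry:
    """Apply the depth/quality and allele-balance rules to a single call.

    Already-missing entries pass through unchanged. A missing DP, GQ or AD
    value fails the corresponding rule.
    """
    cfg = cfg or QcConfig()
    if entry.is_missing:
        return entry
    min_dp = cfg.snv_min_dp if vclass is VariantClass.SNV else cfg.indel_min_dp
    dp_fail = entry.dp < min_dp  # MISSING == -1 always fails
    gq_fail = entry.gq < cfg.min_gq
    failed = (dp_fail or gq_fail) if cfg.dp_gq_logic is DpGqLogic.OR else (dp_fail and gq_fail)
    if not failed and vclass is VariantClass.SNV and entry.dosage == 1:
        if entry.ad_ref < 0 or entry.ad_alt < 0 or entry.ad_ref + entry.ad_alt == 0:
            failed = True
        else:
            failed = allele_balance_p(entry.ad_ref, entry.ad_alt) <= cfg.ab_p_threshold
    if failed:
        return dataclasses.replace(entry, dosage=MISSING)
    return entry


def variant_missingness(cohort: CohortGenotypes, variant_id: str) -> float:
    """Fraction of samples with a missing genotype at the variant."""
    if cohort.n_samples == 0:
        raise ValueError("cohort has no samples")
    i = cohort.variant_index(variant_id)
    return float(np.mean(cohort.dosage[i] == MISSING))


def apply_qc(
    cohort: CohortGenotypes, cfg: QcConfig | None = None
) -> tuple[CohortGenotypes, QcReport]:
    """Run the full genotype-level + missingness filter chain on a cohort.

    Returns the filtered cohort (variants above the missingness cutoff
    removed) and a report tallying, per variant, how many genotypes each
    rule newly set missing.
    """
    cfg = cfg or QcConfig()
    if cohort.n_samples == 0:
        raise ValueError("cohort has no samples")
    out = cohort.copy()
    V = out.n_variants

    is_snv = np.array([v.is_snv for v in out.variants])
    min_dp = np.where(is_snv, cfg.snv_min_dp, cfg.indel_min_dp)[:, None]
    nonmissing = out.dosage != MISSING

    dp_fail = out.dp < min_dp
    gq_fail = out.gq < cfg.min_gq
    if cfg.dp_gq_logic is DpGqLogic.OR:
        dpgq = dp_fail | gq_fail
    else:
        dpgq = dp_fail & gq_fail
    dpgq &= nonmissing
    n_dpgq = dpgq.sum(axis=1)
    out.dosage[dpgq] = MISSING

    # allele-balance rule: heterozygous SNVs that survived depth/quality
    het = (out.dosage == 1) & is_snv[:, None]
    ab_fail = np.zeros_like(het)
    if het.any():
        vi, sj = np.nonzero(het)
        ar = out.ad_ref[vi, sj]
        aa = out.ad_alt[vi, sj]
        bad_ad = (ar < 0) | (aa < 0) | (ar + aa == 0)
        p = np.ones(len(vi))
        ok = ~bad_ad
        if ok.any():
            p[ok] = _ab_p_vector(ar[ok], aa[ok])
        fail = bad_ad | (p <= cfg.ab_p_threshold)
        ab_fail[vi[fail], sj[fail]] = True
    n_ab = ab_fail.sum(axis=1)
    out.dosage[ab_fail] = MISSING

    miss = np.mean(out.dosage == MISSING, axis=1)
    dropped = miss > cfg.max_missingness

    report = QcReport(
        per_variant=pd.DataFrame(
            {
                "variant_id": out.variant_ids,
                "n_dp_gq": n_dpgq.astype(int),
                "n_allele_balance": n_ab.astype(int),
                "missingness": miss,
                "dropped": dropped,
            }
        ),
        n_variants_in=V,
        n_variants_dropped=int(dropped.sum()),
    )
    logger.info(
        "QC: %d genotypes set missing by DP/GQ, %d by allele balance; "
        "%d/%d variants dropped by missingness > %.2f",
        report.total_dp_gq,
        report.total_allele_balance,
        report.n_variants_dropped,
        V,
        cfg.max_missingness,
    )
    filtered = out.subset_variants(np.nonzero(~dropped)[0])
    return filtered, report
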