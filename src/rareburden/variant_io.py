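"""VCF input/output and per-allele normalisation.

Multi-allelic records are split into one bi-allelic record per ALT allele
and trimmed to parsimonious form (shared suffix, then shared prefix), the
same normalisation ``bcftools norm`` applies, minus reference-FASTA
left-alignment: the implementation is reference-free, which is exact for
SNVs and for indels that are already left-aligned.

Genotype matrices use ``MISSING`` (= -1) as the sentinel for absent
dosage, DP, GQ or AD values. A FORMAT field that is absent from the VCF
is stored as ``MISSING`` and therefore *fails* any downstream threshold
filter — the conservative reading of genotype-level QC.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

#: Sentinel for a missing dosage / DP / GQ / AD value.
MISSING: int = -1

RESULT_COLUMNS = [
    "gene",
    "mask",
    "domain_scope",
    "trait",
    "stratum",
    "n_total",
    "n_carriers",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "or",
    "or_ci_low",
    "or_ci_high",
    "p",
]


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic, parsimony-trimmed variant site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if "," in self.alt:
            raise ValueError("alt must be a single allele (post-split)")
        if self.ref == self.alt:
            raise ValueError(f"non-variant site at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclasses.dataclass(frozen=True)
class GenotypeEntry:
    """One sample's call at one variant; MISSING (-1) marks absent values."""

    sample_id: str
    dosage: int
    dp: int
    gq: int
    ad_ref: int
    ad_alt: int

    @property
    def is_missing(self) -> bool:
        return self.dosage == MISSING


class CohortGenotypes:
    """Genotypes for a sample cohort at a set of bi-allelic variants.

    Per-field values are held as ``(n_variants, n_samples)`` int arrays
    with ``MISSING`` sentinels, which keeps cohort-scale QC vectorised.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        dosage: np.ndarray,
        dp: np.ndarray,
        gq: np.ndarray,
        ad_ref: np.ndarray,
        ad_alt: np.ndarray,
    ):
        self.variants = list(variants)
        self.samples = list(samples)
        shape = (len(self.variants), len(self.samples))
        for name, arr in [
            ("dosage", dosage), ("dp", dp), ("gq", gq),
            ("ad_ref", ad_ref), ("ad_alt", ad_alt),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        self.dosage = np.asarray(dosage, dtype=np.int32)
        self.dp = np.asarray(dp, dtype=np.int32)
        self.gq = np.asarray(gq, dtype=np.int32)
        self.ad_ref = np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(ad_alt, dtype=np.int32)
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids: {dupes}")
        self._index = {vid: i for i, vid in enumerate(ids)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant id: {variant_id}") from None

    def entry(self, variant_id: str, sample_id: str) -> GenotypeEntry:
        i = self.variant_index(variant_id)
        j = self._sample_index[sample_id]
        return GenotypeEntry(
            sample_id=sample_id,
            dosage=int(self.dosage[i, j]),
            dp=int(self.dp[i, j]),
            gq=int(self.gq[i, j]),
            ad_ref=int(self.ad_ref[i, j]),
            ad_alt=int(self.ad_alt[i, j]),
        )

    def subset_variants(self, keep: Sequence[int]) -> "CohortGenotypes":
        keep = list(keep)
        return CohortGenotypes(
            [self.variants[i] for i in keep],
            self.samples,
            self.dosage[keep].copy(),
            self.dp[keep].copy(),
            self.gq[keep].copy(),
            self.ad_ref[keep].copy(),
            self.ad_alt[keep].copy(),
        )

    def copy(self) -> "CohortGenotypes":
        return self.subset_variants(range(self.n_variants))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortGenotypes):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.gq, other.gq)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
        )


def split_and_trim(
    pos: int, ref: str, alts: Sequence[str]
) -> list[tuple[int, str, str]]:
    """Split a (possibly multi-allelic) site into parsimonious bi-allelic tuples.

    For each ALT allele the shared suffix is trimmed first, then the shared
    prefix, always retaining at least one base in each allele; the position
    advances by the number of prefix bases removed.

    Raises ``ValueError`` if an allele pair reduces to a non-variant site.
    """
    if not ref:
        raise ValueError("ref allele must be non-empty")
    out: list[tuple[int, str, str]] = []
    for alt in alts:
        if not alt:
            raise ValueError("alt allele must be non-empty")
        r, a, p = ref, alt, pos
        while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            r, a = r[1:], a[1:]
            p += 1
        if r == a:
            raise ValueError(
                f"ref and alt identical after trimming at pos {pos} ({ref}->{alt})"
            )
        out.append((p, r, a))
    return out


def _parse_region(region) -> tuple[str, int, int] | None:
    if region is None:
        return None
    if isinstance(region, str):
        if ":" in region:
            chrom, span = region.split(":", 1)
            start, end = span.replace(",", "").split("-")
            return chrom, int(start), int(end)
        return region, 1, 2**31 - 1
    chrom, start, end = region
    return str(chrom), int(start), int(end)


def read_vcf(path, region=None) -> CohortGenotypes:
    """Read a VCF into a :class:`CohortGenotypes`, splitting multi-allelics.

    Parameters
    ----------
    path
        VCF (v4.2) with a GT FORMAT field; DP, GQ and AD are optional and
        stored as ``MISSING`` when absent.
    region
        Optional ``(chrom, start, end)`` tuple or ``"chrom:start-end"``
        string, 1-based inclusive. Variants outside it are skipped; the
        sample list is always the file's full sample list.
    """
    region = _parse_region(region)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    if "GT" not in vf.header.formats:
        raise ValueError(f"VCF {path} has no GT FORMAT field")
    samples = list(vf.header.samples)

    variants: list[VariantRecord] = []
    rows: list[tuple[np.ndarray, ...]] = []
    n = len(samples)
    for line_no, rec in enumerate(vf, start=1):
        if rec.alts is None:
            continue
        if region is not None:
            chrom, start, end = region
            if rec.chrom != chrom or not (start <= rec.pos <= end):
                continue
        try:
            trimmed = split_and_trim(rec.pos, rec.ref, list(rec.alts))
        except ValueError as exc:
            raise ValueError(f"VCF record {rec.chrom}:{rec.pos}: {exc}") from exc
        for alt_num, (p, r, a) in enumerate(trimmed, start=1):
            dosage = np.full(n, MISSING, dtype=np.int32)
            dp = np.full(n, MISSING, dtype=np.int32)
            gq = np.full(n, MISSING, dtype=np.int32)
            ad_ref = np.full(n, MISSING, dtype=np.int32)
            ad_alt = np.full(n, MISSING, dtype=np.int32)
            for j, sname in enumerate(samples):
                call = rec.samples[sname]
                gt = call.get("GT")
                # half-calls (./1) and fully missing calls are MISSING
                if gt is not None and len(gt) > 0 and all(x is not None for x in gt):
                    dosage[j] = sum(1 for x in gt if x == alt_num)
                v = call.get("DP")
                if v is not None:
                    dp[j] = v
                v = call.get("GQ")
                if v is not None:
                    gq[j] = v
                ad = call.get("AD")
                if ad is not None and len(ad) > alt_num:
                    if ad[0] is not None:
                        ad_ref[j] = ad[0]
                    if ad[alt_num] is not None:
                        ad_alt[j] = ad[alt_num]
            variants.append(VariantRecord(rec.chrom, p, r, a))
            rows.append((dosage, dp, gq, ad_ref, ad_alt))
    vf.close()

    def stack(k: int) -> np.ndarray:
        if not rows:
            return np.zeros((0, n), dtype=np.int32)
        return np.stack([row[k] for row in rows])

    return CohortGenotypes(
        variants, samples, stack(0), stack(1), stack(2), stack(3), stack(4)
    )


def write_vcf(cohort: CohortGenotypes, path) -> None:
    """Write a cohort back to a bi-allelic VCF v4.2 with GT:DP:GQ:AD."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in cohort.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(cohort.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for j, s in enumerate(cohort.samples):
                d = int(cohort.dosage[i, j])
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (0, 1) if d == 1 else ((0, 0) if d == 0 else (1, 1))
                if cohort.dp[i, j] != MISSING:
                    rec.samples[s]["DP"] = int(cohort.dp[i, j])
                if cohort.gq[i, j] != MISSING:
                    rec.samples[s]["GQ"] = int(cohort.gq[i, j])
                if cohort.ad_ref[i, j] != MISSING and cohort.ad_alt[i, j] != MISSING:
                    rec.samples[s]["AD"] = (
                        int(cohort.ad_ref[i, j]),
                        int(cohort.ad_alt[i, j]),
                    )
            out.write(rec)


def write_results(results: Iterable, path) -> None:
    """Write association results to a fixed-column TSV (see RESULT_COLUMNS)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "mask": r.mask,
                "domain_scope": ",".join(r.domain_scope) if r.domain_scope else ".",
                "trait": r.trait,
                "stratum": r.stratum,
                "n_total": r.n_total,
                "n_carriers": r.n_carriers,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "or": r.or_ if r.or_ is not None else np.nan,
                "or_ci_low": r.or_ci_low if r.or_ci_low is not None else np.nan,
                "or_ci_high": r.or_ci_high if r.or_ci_high is not None else np.nan,
                "p": r.p,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)  # default float repr round-trips


def read_results(path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results file {path} lacks columns: {sorted(missing)}")
    return df


def results_to_records(df: pd.DataFrame) -> list:
    """Convert a results DataFrame back into AssociationResult objects."""
    from .association import AssociationResult

    out = []
    for _, row in df.iterrows():
        scope = None if row["domain_scope"] == "." else tuple(str(row["domain_scope"]).split(","))
        binary = pd.notna(row["or"])
        out.append(
            AssociationResult(
                gene=row["gene"],
                mask=row["mask"],
                domain_scope=scope,
                trait=row["trait"],
                stratum=row["stratum"],
                n_total=int(row["n_total"]),
                n_carriers=int(row["n_carriers"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                or_=float(row["or"]) if binary else None,
                or_ci_low=float(row["or_ci_low"]) if binary else None,
                or_ci_high=float(row["or_ci_high"]) if binary else None,
                p=float(row["p"]),
            )
        )
    return out


def write_burden_tsv(burden, path: Path) -> None:
    """Two-column per-sample export of a burden vector."""
    pd.DataFrame({"sample_id": burden.sample_ids, "value": burden.values}).to_csv(
        path, sep="\t", index=False
    )
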