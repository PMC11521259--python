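"""Consequence annotation handling and qualifying-variant mask construction.

The pipeline consumes a per-transcript annotation table (the output of a
VEP-style annotator with CADD and LOFTEE columns) rather than running the
annotator itself. Per variant and gene, one transcript is chosen —
protein-coding first, then MANE select, then the canonical transcript —
and the most severe consequence on that transcript is resolved against
the standard Ensembl severity ranking (shipped as a data file,
overridable).

Three overlapping qualifying-variant classes are built per gene, each
restricted to rare variants (in-cohort MAF < 0.1% by default):

- ``hc_ptv``          high-confidence protein-truncating variants
                      (stop gained / frameshift / essential splice site,
                      LOFTEE HC);
- ``missense_cadd25`` missense variants with CADD phred >= 25;
- ``damaging``        the union of the two.

Masks can additionally be restricted to protein domains given a table of
1-based inclusive residue ranges (e.g. the SF-1 DNA-binding and
ligand-binding domains); variants whose protein position falls between
domains (the hinge) drop out of the restricted mask.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, CohortGenotypes

PTV_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

MASK_NAMES = ("hc_ptv", "missense_cadd25", "damaging")

ANNOTATION_COLUMNS = [
    "variant_id",
    "gene",
    "transcript",
    "biotype",
    "mane",
    "canonical",
    "consequence",
    "cadd_phred",
    "loftee",
    "protein_position",
]


def default_severity_order() -> list[str]:
    """The Ensembl consequence-severity ranking, most severe first."""
    text = resources.files("rareburden.data").joinpath("consequence_severity.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclasses.dataclass(frozen=True)
class TranscriptConsequence:
    """One (variant, transcript) row of the annotation table."""

    variant_id: str
    gene_symbol: str
    transcript_id: str
    biotype: str
    is_mane: bool
    is_canonical: bool
    consequence_terms: tuple[str, ...]
    cadd_phred: float | None = None
    loftee: str = "NA"  # HC | LC | NA
    protein_position: int | None = None

    def __post_init__(self) -> None:
        if not self.consequence_terms:
            raise ValueError(f"{self.variant_id}: consequence_terms must be non-empty")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be >= 0")
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError("protein_position must be >= 1")


@dataclasses.dataclass(frozen=True)
class ResolvedAnnotation:
    """One resolved annotation per (variant, gene)."""

    variant_id: str
    gene_symbol: str
    transcript_id: str
    most_severe_term: str
    cadd_phred: float | None
    loftee: str
    protein_position: int | None


@dataclasses.dataclass(frozen=True)
class DomainSpan:
    gene_symbol: str
    domain_name: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError(
                f"domain {self.domain_name}: start {self.start_residue} > end {self.end_residue}"
            )

    def contains(self, residue: int) -> bool:
        return self.start_residue <= residue <= self.end_residue


@dataclasses.dataclass(frozen=True)
class VariantMask:
    """A named set of qualifying variant ids for one gene."""

    mask_name: str
    gene_symbol: str
    variant_ids: frozenset[str]
    domain_scope: tuple[str, ...] | None = None


def _parse_protein_position(raw) -> int | None:
    """Parse VEP-style protein positions; 'start-end' ranges use the start."""
    if raw is None:
        return None
    s = str(raw).strip()
    if s in ("", ".", "-", "NA", "nan"):
        return None
    if "-" in s:
        s = s.split("-")[0]
        if s in ("", "?"):
            return None
    return int(s)


def read_annotation_table(path) -> list[TranscriptConsequence]:
    """Read the 10-column per-transcript annotation TSV.

    Columns: variant_id, gene, transcript, biotype, mane (0/1),
    canonical (0/1), consequence (ampersand-joined SO terms), cadd_phred
    (may be empty), loftee (HC/LC/NA), protein_position (int, 'start-end'
    range, or empty).
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {sorted(missing)}")
    rows = []
    for t in df.itertuples(index=False):
        cadd = None if t.cadd_phred.strip() in ("", ".", "NA") else float(t.cadd_phred)
        rows.append(
            TranscriptConsequence(
                variant_id=t.variant_id,
                gene_symbol=t.gene,
                transcript_id=t.transcript,
                biotype=t.biotype,
                is_mane=t.mane.strip() in ("1", "true", "True"),
                is_canonical=t.canonical.strip() in ("1", "true", "True"),
                consequence_terms=tuple(t.consequence.split("&")),
                cadd_phred=cadd,
                loftee=t.loftee.strip() or "NA",
                protein_position=_parse_protein_position(t.protein_position),
            )
        )
    return rows


def write_annotation_table(rows: Iterable[TranscriptConsequence], path) -> None:
    recs = []
    for r in rows:
        recs.append(
            {
                "variant_id": r.variant_id,
                "gene": r.gene_symbol,
                "transcript": r.transcript_id,
                "biotype": r.biotype,
                "mane": int(r.is_mane),
                "canonical": int(r.is_canonical),
                "consequence": "&".join(r.consequence_terms),
                "cadd_phred": "" if r.cadd_phred is None else r.cadd_phred,
                "loftee": r.loftee,
                "protein_position": "" if r.protein_position is None else r.protein_position,
            }
        )
    pd.DataFrame(recs, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domain_table(path) -> list[DomainSpan]:
    """Read the domain TSV (gene, domain, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "domain": str})
    spans = [
        DomainSpan(t.gene, t.domain, int(t.start), int(t.end))
        for t in df.itertuples(index=False)
    ]
    _check_non_overlap(spans)
    return spans


def write_domain_table(spans: Sequence[DomainSpan], path) -> None:
    pd.DataFrame(
        [
            {"gene": s.gene_symbol, "domain": s.domain_name, "start": s.start_residue, "end": s.end_residue}
            for s in spans
        ]
    ).to_csv(path, sep="\t", index=False)


def _check_non_overlap(spans: Sequence[DomainSpan]) -> None:
    by_gene: dict[str, list[DomainSpan]] = {}
    for s in spans:
        by_gene.setdefault(s.gene_symbol, []).append(s)
    for gene, ds in by_gene.items():
        ds = sorted(ds, key=lambda s: s.start_residue)
        for a, b in zip(ds, ds[1:]):
            if b.start_residue <= a.end_residue:
                raise ValueError(
                    f"overlapping domains for {gene}: {a.domain_name} and {b.domain_name}"
                )


def select_transcript(
    rows: Sequence[TranscriptConsequence],
) -> TranscriptConsequence:
    """Pick the annotation transcript for one variant+gene.

    Protein-coding transcripts are preferred when any exist; among the
    candidates MANE select outranks the canonical flag, and remaining ties
    break on the lexicographically smallest transcript id so the choice is
    order-independent.
    """
    if not rows:
        raise ValueError("no annotation rows to select from")
    coding = [r for r in rows if r.biotype == "protein_coding"]
    pool = coding if coding else list(rows)
    return min(pool, key=lambda r: (not r.is_mane, not r.is_canonical, r.transcript_id))


def most_severe_term(
    terms: Sequence[str], severity_order: Sequence[str] | None = None
) -> str:
    """Return the most severe SO term according to the ranking table."""
    order = list(severity_order) if severity_order is not None else default_severity_order()
    rank = {t: i for i, t in enumerate(order)}
    for t in terms:
        if t not in rank:
            raise ValueError(f"unknown consequence term: {t!r}")
    return min(terms, key=rank.__getitem__)


def is_ptv(term: str) -> bool:
    """True for the consequence terms consolidated as protein-truncating."""
    return term in PTV_TERMS


def resolve_annotations(
    rows: Sequence[TranscriptConsequence],
    severity_order: Sequence[str] | None = None,
) -> list[ResolvedAnnotation]:
    """Collapse per-transcript rows to one annotation per (variant, gene)."""
    order = list(severity_order) if severity_order is not None else default_severity_order()
    groups: dict[tuple[str, str], list[TranscriptConsequence]] = {}
    for r in rows:
        groups.setdefault((r.variant_id, r.gene_symbol), []).append(r)
    out = []
    for (vid, gene), grp in groups.items():
        chosen = select_transcript(grp)
        out.append(
            ResolvedAnnotation(
                variant_id=vid,
                gene_symbol=gene,
                transcript_id=chosen.transcript_id,
                most_severe_term=most_severe_term(chosen.consequence_terms, order),
                cadd_phred=chosen.cadd_phred,
                loftee=chosen.loftee,
                protein_position=chosen.protein_position,
            )
        )
    return out


def compute_maf(cohort: CohortGenotypes, variant_id: str) -> float:
    """In-cohort minor allele frequency over non-missing genotypes."""
    i = cohort.variant_index(variant_id)
    d = cohort.dosage[i]
    ok = d != MISSING
    if not ok.any():
        raise ValueError(f"all genotypes missing for {variant_id}")
    f = float(d[ok].sum()) / (2.0 * int(ok.sum()))
    return min(f, 1.0 - f)


def _qualifies(ann: ResolvedAnnotation, mask_name: str) -> bool:
    if mask_name == "hc_ptv":
        return is_ptv(ann.most_severe_term) and ann.loftee == "HC"
    if mask_name == "missense_cadd25":
        return (
            ann.most_severe_term == "missense_variant"
            and ann.cadd_phred is not None
            and ann.cadd_phred >= 25.0
        )
    if mask_name == "damaging":
        return _qualifies(ann, "hc_ptv") or _qualifies(ann, "missense_cadd25")
    raise ValueError(f"unknown mask name: {mask_name!r} (expected one of {MASK_NAMES})")


def build_mask(
    annotations: Sequence[ResolvedAnnotation],
    cohort: CohortGenotypes,
    mask_name: str,
    maf_threshold: float = 0.001,
    gene: str | None = None,
) -> VariantMask:
    """Build one qualifying-variant mask for one gene.

    Qualification is by resolved consequence (plus CADD / LOFTEE as the
    mask requires) intersected with in-cohort MAF strictly below
    ``maf_threshold``. Annotated variants absent from the cohort (e.g.
    removed by QC) are skipped.
    """
    if mask_name not in MASK_NAMES:
        raise ValueError(f"unknown mask name: {mask_name!r} (expected one of {MASK_NAMES})")
    genes = sorted({a.gene_symbol for a in annotations})
    if gene is None:
        if len(genes) != 1:
            raise ValueError(f"annotations cover {genes}; pass gene= to disambiguate")
        gene = genes[0]
    present = set(cohort.variant_ids)
    keep = set()
    for a in annotations:
        if a.gene_symbol != gene or a.variant_id not in present:
            continue
        if not _qualifies(a, mask_name):
            continue
        if compute_maf(cohort, a.variant_id) < maf_threshold:
            keep.add(a.variant_id)
    return VariantMask(mask_name=mask_name, gene_symbol=gene, variant_ids=frozenset(keep))


def restrict_to_domains(
    mask: VariantMask,
    annotations: Sequence[ResolvedAnnotation],
    domains: Sequence[DomainSpan],
    wanted: Iterable[str],
) -> VariantMask:
    """Keep mask variants whose protein position lies in a wanted domain.

    Residue ranges are 1-based inclusive; variants with no protein
    position are dropped (they cannot be placed in any domain).
    """
    wanted = tuple(sorted(set(wanted)))
    gene_domains = [d for d in domains if d.gene_symbol == mask.gene_symbol]
    available = {d.domain_name for d in gene_domains}
    absent = set(wanted) - available
    if absent:
        raise ValueError(
            f"domains {sorted(absent)} not in table for gene {mask.gene_symbol} "
            f"(available: {sorted(available)})"
        )
    spans = [d for d in gene_domains if d.domain_name in wanted]
    pos = {
        a.variant_id: a.protein_position
        for a in annotations
        if a.gene_symbol == mask.gene_symbol
    }
    missing_ann = mask.variant_ids - set(pos)
    if missing_ann:
        raise ValueError(f"mask variants lack annotations: {sorted(missing_ann)}")
    keep = frozenset(
        vid
        for vid in mask.variant_ids
        if pos[vid] is not None and any(s.contains(pos[vid]) for s in spans)
    )
    return VariantMask(
        mask_name=mask.mask_name,
        gene_symbol=mask.gene_symbol,
        variant_ids=keep,
        domain_scope=wanted,
    )


def write_mask(mask: VariantMask, path) -> None:
    pd.DataFrame(
        {
            "gene": mask.gene_symbol,
            "mask": mask.mask_name,
            "domain_scope": ",".join(mask.domain_scope) if mask.domain_scope else ".",
            "variant_id": sorted(mask.variant_ids),
        }
    ).to_csv(path, sep="\t", index=False)


def read_mask(path) -> VariantMask:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"mask file {path} has no variants")
    scope_raw = df["domain_scope"].iloc[0]
    return VariantMask(
        mask_name=df["mask"].iloc[0],
        gene_symbol=df["gene"].iloc[0],
        variant_ids=frozenset(df["variant_id"]),
        domain_scope=None if scope_raw == "." else tuple(scope_raw.split(",")),
    )
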