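"""End-to-end orchestration: QC -> mask -> collapse -> association.

Every stage reads and writes plain files (VCF / TSV) so intermediate
artifacts are independently inspectable and any stage can be re-run in
isolation; :func:`run_pipeline` chains them in order and logs per-stage
variant/sample/carrier counts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_masks as am
from . import association as assoc
from . import collapse_burden as cb
from . import genotype_qc as qc
from . import variant_io as vio

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TraitConfig:
    name: str
    kind: str = "quantitative"  # quantitative | binary
    sex_restriction: str = "all"

    def to_spec(self) -> assoc.TraitSpec:
        return assoc.TraitSpec(
            name=self.name,
            kind=assoc.TraitKind(self.kind),
            sex_restriction=assoc.SexRestriction(self.sex_restriction),
        )


@dataclasses.dataclass
class PipelineConfig:
    vcf: Path
    annotation: Path
    phenotypes: Path
    output_dir: Path
    gene: str
    domains: Path | None = None
    masks: list[str] = dataclasses.field(default_factory=lambda: ["damaging"])
    domain_scope: list[str] | None = None
    traits: list[TraitConfig] = dataclasses.field(default_factory=list)
    strata: list[str] = dataclasses.field(default_factory=lambda: ["all"])
    burden_mode: str | None = None  # default: additive if domain-scoped else carrier
    maf_threshold: float = 0.001
    qc: qc.QcConfig = dataclasses.field(default_factory=qc.QcConfig)
    covariate_columns: list[str] = dataclasses.field(
        default_factory=lambda: list(assoc.DEFAULT_COVARIATES)
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["qc"] = qc.QcConfig(**raw.get("qc", {}))
        raw["traits"] = [TraitConfig(**t) for t in raw.get("traits", [])]
        for key in ("vcf", "annotation", "phenotypes", "output_dir", "domains"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for key in ("vcf", "annotation", "phenotypes", "domains"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"phenotype table {path} lacks a sample_id column")
    return df.set_index("sample_id")


def load_masks(cfg: PipelineConfig, cohort) -> list[am.VariantMask]:
    rows = am.read_annotation_table(cfg.annotation)
    resolved = am.resolve_annotations(rows)
    masks = []
    for name in cfg.masks:
        mask = am.build_mask(
            resolved, cohort, name, maf_threshold=cfg.maf_threshold, gene=cfg.gene
        )
        if cfg.domain_scope:
            if cfg.domains is None:
                raise ValueError("domain_scope requested but no domain table given")
            spans = am.read_domain_table(cfg.domains)
            mask = am.restrict_to_domains(mask, resolved, spans, cfg.domain_scope)
        masks.append(mask)
    return masks


def run_pipeline(cfg: PipelineConfig) -> list[assoc.AssociationResult]:
    """Execute QC, mask construction, collapsing and association in order.

    Writes ``results.tsv``, ``qc_report.tsv`` and the QC'd ``filtered.vcf``
    under ``cfg.output_dir`` and returns the association results.
    """
    cfg.validate_paths()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = vio.read_vcf(cfg.vcf)
    logger.info("pipeline: read %d variants x %d samples", cohort.n_variants, cohort.n_samples)
    cohort, report = qc.apply_qc(cohort, cfg.qc)
    report.write(outdir / "qc_report.tsv")
    vio.write_vcf(cohort, outdir / "filtered.vcf")
    logger.info("pipeline: %d variants retained after QC", cohort.n_variants)

    masks = load_masks(cfg, cohort)
    for m in masks:
        logger.info("pipeline: mask %s has %d qualifying variants", m.mask_name, len(m.variant_ids))

    mode_name = cfg.burden_mode or ("additive" if cfg.domain_scope else "carrier")
    mode = cb.BurdenMode(mode_name)
    burdens = [cb.collapse(m, cohort, mode) for m in masks]
    for b in burdens:
        logger.info(
            "pipeline: mask %s scope %s: %d carriers",
            b.mask_name, b.domain_scope, cb.carrier_count(b),
        )

    phenos = read_phenotypes(cfg.phenotypes)
    missing_cov = set(cfg.covariate_columns) - set(phenos.columns)
    if missing_cov:
        raise ValueError(f"phenotype table lacks covariates: {sorted(missing_cov)}")
    covars = phenos[cfg.covariate_columns]
    traits = [(t.to_spec(), phenos[t.name]) for t in cfg.traits]
    results: list[assoc.AssociationResult] = []
    for stratum in cfg.strata:
        results.extend(
            assoc.stratified_run(traits, burdens, covars, assoc.SexRestriction(stratum))
        )
    vio.write_results(results, outdir / "results.tsv")
    logger.info("pipeline: wrote %d association results", len(results))
    return results
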