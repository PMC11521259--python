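"""Synthetic biobank-like cohorts with known ground truth.

Every stage of the pipeline is testable without restricted data: the
generator emits a cohort VCF (GT:DP:GQ:AD), a per-transcript annotation
table, a protein-domain table, and a phenotype/covariate table, together
with a :class:`GroundTruth` record of the true dosages, the injected QC
violations and the true trait effects.

What is emulated
----------------
- rare variants (panel allele frequencies < 0.1%) in one gene, with
  per-genotype depth, quality and allelic-depth fields; clean genotypes
  always pass the QC thresholds, and violations (low depth, low quality,
  allele imbalance at heterozygous SNVs, variant-level missingness) are
  injected at configured rates and logged, pairwise disjoint so the QC
  report can be checked against the registry exactly;
- covariates: age ~ Uniform(40, 70) years, 10 genetic principal
  components ~ N(0, 1), sex (1 = female), and a 3-level sequencing-batch
  label with frequencies roughly proportional to the 50k/200k/450k
  release increments;
- traits under additive per-allele burden effects: quantitative traits
  are Gaussian around a linear predictor, binary traits Bernoulli under
  a logistic model anchored at a baseline prevalence.

Not emulated: linkage disequilibrium, relatedness, ancestry structure,
genotype-covariate confounding (a deliberately clean null for the GLM);
see the methods note for what this does and does not validate.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import annotation_masks as am
from . import association as assoc
from . import collapse_burden as cb
from . import genotype_qc as qc
from .variant_io import MISSING, CohortGenotypes, VariantRecord, write_vcf

GENE = "NR5A1"
TRANSCRIPT = "ENST00000373588"
CHROM = "9"
GENE_POS0 = 124_481_000  # arbitrary anchor on chr9 for generated sites

BATCH_LEVELS = ("50k", "200k", "450k")
BATCH_PROBS = (50 / 450, 150 / 450, 250 / 450)  # release increments


def default_sf1_domains() -> list[am.DomainSpan]:
    """Illustrative SF-1 domain residue spans (synthetic fixture values).

    The DNA-binding and ligand-binding domain boundaries here are
    plausible placeholders for testing, not curated UniProt coordinates;
    real analyses must supply their own domain table.
    """
    return [
        am.DomainSpan(GENE, "DBD", 10, 85),
        am.DomainSpan(GENE, "LBD", 225, 460),
    ]


def default_covariate_effects() -> dict[str, float]:
    """Modest nonzero covariate effects used by default trait models."""
    eff = {"age": 0.03, "age_sq": -3e-4}
    for i in range(1, 11):
        eff[f"pc{i}"] = 0.05 if i % 2 else -0.05
    return eff


def default_batch_effects() -> dict[str, float]:
    return {"50k": 0.0, "200k": 0.15, "450k": -0.10}


@dataclasses.dataclass
class PanelVariant:
    """One simulated rare variant and its annotation attributes."""

    allele_frequency: float = 0.0
    consequence: str = "missense_variant"
    cadd_phred: float | None = 30.0
    loftee: str = "NA"
    protein_position: int | None = None
    ref: str = "A"
    alt: str = "G"
    #: sample indices forced heterozygous (overrides frequency sampling)
    carrier_samples: tuple[int, ...] | None = None
    #: sample indices forced homozygous alternate
    hom_samples: tuple[int, ...] = ()
    #: if > 0, this fraction of genotypes is set to ./. (missingness torture)
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError("allele_frequency must be in [0, 1]")


@dataclasses.dataclass
class TraitModel:
    """Generative model for one trait.

    Quantitative: y = intercept + covariate terms + effect * burden + N(0, sd).
    Binary: logit P = logit(baseline_prevalence) + centred covariate terms
    + effect * burden (effect on the log-odds scale), y ~ Bernoulli(P).

    ``predictor`` selects whether the true effect multiplies the additive
    allele count or the 0/1 carrier indicator over ``scope`` (panel
    indices; None = all panel variants). ``sex_restriction`` hides the
    trait for the other sex; ``sex_specific_effect`` zeroes the effect
    (not the trait) outside the named sex.
    """

    name: str
    kind: str = "quantitative"  # quantitative | binary
    per_allele_effect: float = 0.0
    intercept: float = 50.0
    baseline_prevalence: float = 0.23
    residual_sd: float = 5.0
    covariate_effects: dict[str, float] = dataclasses.field(
        default_factory=default_covariate_effects
    )
    batch_effects: dict[str, float] = dataclasses.field(
        default_factory=default_batch_effects
    )
    predictor: str = "additive"  # additive | carrier
    scope: tuple[int, ...] | None = None
    sex_restriction: str = "all"  # all | female | male
    sex_specific_effect: str | None = None
    #: sample indices whose trait value is set missing (incomplete data)
    missing_samples: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary" and not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


@dataclasses.dataclass
class SimulationConfig:
    n_samples: int = 1000
    sex_fraction_female: float = 0.5
    panel: list[PanelVariant] = dataclasses.field(default_factory=list)
    domain_table: list[am.DomainSpan] = dataclasses.field(
        default_factory=default_sf1_domains
    )
    qc_violation_rates: dict[str, float] = dataclasses.field(default_factory=dict)
    traits: list[TraitModel] = dataclasses.field(default_factory=list)
    seed: int = 0
    gene: str = GENE

    def __post_init__(self) -> None:
        for rule, r in self.qc_violation_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"violation rate {rule}={r} outside [0, 1]")


@dataclasses.dataclass
class GroundTruth:
    """The generator's bookkeeping: the oracle for QC and recovery tests."""

    variant_ids: list[str]
    true_dosage: np.ndarray  # pre-injection (n_variants, n_samples)
    registry: dict[str, list[tuple[str, str]]]  # rule -> [(variant_id, sample_id)]
    trait_effects: dict[str, float]

    def n_injected(self, rule: str) -> int:
        return len(self.registry.get(rule, []))


@dataclasses.dataclass
class FixtureBundle:
    """An in-memory simulated dataset plus its generating configuration."""

    config: SimulationConfig
    cohort: CohortGenotypes
    ground_truth: GroundTruth
    annotations: list[am.TranscriptConsequence]
    domains: list[am.DomainSpan]
    phenotypes: pd.DataFrame  # indexed by sample_id: covariates + trait columns

    def covariate_frame(self) -> pd.DataFrame:
        cols = ["age", "age_sq", "sex"] + [f"pc{i}" for i in range(1, 11)] + ["wes_batch"]
        return self.phenotypes[cols]

    def trait_series(self, name: str) -> pd.Series:
        return self.phenotypes[name]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:06d}" for i in range(n)]


def simulate_covariates(
    n_samples: int, sex_fraction_female: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariate table indexed by sample id; sex is 1 = female, 0 = male.

    The first round(n * fraction) samples are female so that fixtures can
    place carriers in a known stratum deterministically.
    """
    ids = _sample_ids(n_samples)
    n_f = int(round(n_samples * sex_fraction_female))
    sex = np.zeros(n_samples, dtype=np.int64)
    sex[:n_f] = 1
    age = rng.uniform(40.0, 70.0, size=n_samples)
    df = pd.DataFrame({"age": age, "age_sq": age**2, "sex": sex}, index=ids)
    for i in range(1, 11):
        df[f"pc{i}"] = rng.standard_normal(n_samples)
    df["wes_batch"] = rng.choice(BATCH_LEVELS, size=n_samples, p=BATCH_PROBS)
    df.index.name = "sample_id"
    return df


def _panel_records(cfg: SimulationConfig) -> list[VariantRecord]:
    recs = []
    for i, v in enumerate(cfg.panel):
        recs.append(VariantRecord(CHROM, GENE_POS0 + 50 * i, v.ref, v.alt))
    return recs


def panel_annotations(cfg: SimulationConfig) -> list[am.TranscriptConsequence]:
    """One protein-coding MANE transcript row per panel variant."""
    rows = []
    for rec, v in zip(_panel_records(cfg), cfg.panel):
        rows.append(
            am.TranscriptConsequence(
                variant_id=rec.variant_id,
                gene_symbol=cfg.gene,
                transcript_id=TRANSCRIPT,
                biotype="protein_coding",
                is_mane=True,
                is_canonical=True,
                consequence_terms=(v.consequence,),
                cadd_phred=v.cadd_phred,
                loftee=v.loftee,
                protein_position=v.protein_position,
            )
        )
    return rows


def _clean_format_fields(
    dosage: np.ndarray, is_snv: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """DP/GQ/AD that pass every filter: DP in [15, 35), GQ in [30, 100),
    hets read-balanced."""
    n = dosage.shape[0]
    dp = rng.integers(15, 35, size=n, dtype=np.int32)
    gq = rng.integers(30, 100, size=n, dtype=np.int32)
    ad_alt = np.where(dosage == 2, dp, np.where(dosage == 1, dp // 2, 0)).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)
    return dp, gq, ad_ref, ad_alt


def simulate_genotypes(cfg: SimulationConfig) -> tuple[CohortGenotypes, GroundTruth]:
    """Draw genotypes and FORMAT fields, injecting logged QC violations.

    True dosages are Binomial(2, af) per sample unless a panel entry pins
    its carriers explicitly. Violations of the four QC rules are injected
    at ``cfg.qc_violation_rates`` on cells that are otherwise clean, and
    are pairwise disjoint by construction, so each registry entry maps to
    exactly one action of the corresponding QC rule.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = _sample_ids(n)
    recs = _panel_records(cfg)
    V = len(recs)

    dosage = np.zeros((V, n), dtype=np.int32)
    for i, v in enumerate(cfg.panel):
        if v.carrier_samples is not None or v.hom_samples:
            if v.carrier_samples:
                dosage[i, list(v.carrier_samples)] = 1
            if v.hom_samples:
                dosage[i, list(v.hom_samples)] = 2
        else:
            dosage[i] = rng.binomial(2, v.allele_frequency, size=n)
    true_dosage = dosage.copy()

    dp = np.empty((V, n), dtype=np.int32)
    gq = np.empty((V, n), dtype=np.int32)
    ad_ref = np.empty((V, n), dtype=np.int32)
    ad_alt = np.empty((V, n), dtype=np.int32)
    for i, rec in enumerate(recs):
        dp[i], gq[i], ad_ref[i], ad_alt[i] = _clean_format_fields(
            dosage[i], rec.is_snv, rng
        )

    rates = cfg.qc_violation_rates
    registry: dict[str, list[tuple[str, str]]] = {
        "low_dp": [], "low_gq": [], "allele_imbalance": [], "high_missingness": [],
    }
    vids = [r.variant_id for r in recs]

    # variant-level missingness first, so cell-level rules never land on
    # genotypes that are already ./.
    mrate = rates.get("high_missingness", 0.0)
    for i, v in enumerate(cfg.panel):
        frac = v.missing_fraction
        if frac == 0.0 and mrate > 0.0 and rng.random() < mrate:
            frac = 0.6
        if frac > 0.0:
            k = math.ceil(frac * n)
            cells = rng.choice(n, size=k, replace=False)
            dosage[i, cells] = MISSING
            registry["high_missingness"].extend((vids[i], samples[j]) for j in cells)

    r_dp = rates.get("low_dp", 0.0)
    r_gq = rates.get("low_gq", 0.0)
    r_ab = rates.get("allele_imbalance", 0.0)
    if r_dp or r_gq or r_ab:
        u = rng.random((V, n))
        is_snv = np.array([r.is_snv for r in recs])
        nonmissing = dosage != MISSING
        het_snv = (dosage == 1) & is_snv[:, None]
        pick_dp = (u < r_dp) & nonmissing
        pick_gq = (u >= r_dp) & (u < r_dp + r_gq) & nonmissing
        pick_ab = (u >= r_dp + r_gq) & (u < r_dp + r_gq + r_ab) & het_snv
        min_dp = np.where(is_snv, 7, 10)[:, None]
        low_dp_vals = rng.integers(0, 7, size=(V, n)).astype(np.int32)
        low_dp_vals = np.minimum(low_dp_vals, min_dp - 1)
        dp[pick_dp] = low_dp_vals[pick_dp]
        gq[pick_gq] = rng.integers(0, 20, size=int(pick_gq.sum()), dtype=np.int32)
        # skewed reads at a passing-depth het: p = 2 * 0.5^dp <= 1e-3 for dp >= 15
        ad_ref[pick_ab] = 0
        ad_alt[pick_ab] = dp[pick_ab]
        for rule, pick in [("low_dp", pick_dp), ("low_gq", pick_gq), ("allele_imbalance", pick_ab)]:
            vi, sj = np.nonzero(pick)
            registry[rule].extend((vids[i], samples[j]) for i, j in zip(vi, sj))

    cohort = CohortGenotypes(recs, samples, dosage, dp, gq, ad_ref, ad_alt)
    truth = GroundTruth(
        variant_ids=vids,
        true_dosage=true_dosage,
        registry=registry,
        trait_effects={t.name: t.per_allele_effect for t in cfg.traits},
    )
    return cohort, truth


def _trait_burden(model: TraitModel, true_dosage: np.ndarray) -> np.ndarray:
    scope = list(model.scope) if model.scope is not None else list(range(true_dosage.shape[0]))
    d = true_dosage[scope]
    if model.predictor == "carrier":
        return (d.sum(axis=0) > 0).astype(float)
    return d.sum(axis=0).astype(float)


def simulate_traits(
    cfg: SimulationConfig,
    true_dosage: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate trait columns from true (pre-QC-injection) dosages."""
    out = covariates.copy()
    sex = covariates["sex"].to_numpy()
    for model in cfg.traits:
        burden = _trait_burden(model, true_dosage)
        eff = np.full(len(out), model.per_allele_effect)
        if model.sex_specific_effect == "female":
            eff[sex == 0] = 0.0
        elif model.sex_specific_effect == "male":
            eff[sex == 1] = 0.0
        cov_term = np.zeros(len(out))
        for col, beta in model.covariate_effects.items():
            cov_term += beta * covariates[col].to_numpy(dtype=float)
        batch = covariates["wes_batch"].map(model.batch_effects).to_numpy(dtype=float)
        cov_term += batch
        if model.kind == "quantitative":
            y = (
                model.intercept
                + cov_term
                + eff * burden
                + rng.normal(0.0, model.residual_sd, size=len(out))
            ).astype(float)
        else:
            # centre the covariate contribution so non-carrier prevalence
            # stays at the configured baseline
            eta = logit(model.baseline_prevalence) + (cov_term - cov_term.mean()) + eff * burden
            y = (rng.random(len(out)) < expit(eta)).astype(float)
        if model.sex_restriction == "female":
            y = np.where(sex == 1, y, np.nan)
        elif model.sex_restriction == "male":
            y = np.where(sex == 0, y, np.nan)
        if model.missing_samples:
            y = y.copy()
            y[list(model.missing_samples)] = np.nan
        out[model.name] = y
    return out


def simulate_cohort(cfg: SimulationConfig) -> FixtureBundle:
    """Run the full generator: genotypes, covariates, traits, annotations."""
    cohort, truth = simulate_genotypes(cfg)
    rng = np.random.default_rng((cfg.seed, 1))
    covars = simulate_covariates(cfg.n_samples, cfg.sex_fraction_female, rng)
    phenos = simulate_traits(cfg, truth.true_dosage, covars, rng)
    return FixtureBundle(
        config=cfg,
        cohort=cohort,
        ground_truth=truth,
        annotations=panel_annotations(cfg),
        domains=list(cfg.domain_table),
        phenotypes=phenos,
    )


def write_bundle(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write the bundle as plain files: VCF, annotation/domain/phenotype
    TSVs, and the ground-truth registry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotation": outdir / "annotation.tsv",
        "domains": outdir / "domains.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_vcf(bundle.cohort, paths["vcf"])
    am.write_annotation_table(bundle.annotations, paths["annotation"])
    am.write_domain_table(bundle.domains, paths["domains"])
    bundle.phenotypes.reset_index().to_csv(paths["phenotypes"], sep="\t", index=False)
    reg_rows = [
        {"rule": rule, "variant_id": vid, "sample_id": sid}
        for rule, cells in bundle.ground_truth.registry.items()
        for vid, sid in cells
    ]
    pd.DataFrame(reg_rows, columns=["rule", "variant_id", "sample_id"]).to_csv(
        paths["ground_truth"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("sf1_mirror", "null_cohort", "qc_torture", "tiny_toy")

#: True effects used by the sf1_mirror fixture (per additive burden allele
#: for age at natural menopause; per-allele log-odds for obesity chosen so
#: that women carriers have ~32.3% prevalence against a 23% baseline).
SF1_ANM_EFFECT = -2.36
SF1_OBESITY_LOG_OR = float(logit(0.323) - logit(0.23))


def _sf1_mirror_config(n_samples: int, seed: int) -> SimulationConfig:
    if n_samples < 12_000:
        raise ValueError("sf1_mirror needs >= 12000 samples to keep variants rare")
    n_f = n_samples // 2
    f = np.arange(n_f)
    m = n_f + np.arange(n_samples - n_f)

    def mv(pp: int, carriers: np.ndarray) -> PanelVariant:
        return PanelVariant(
            consequence="missense_variant",
            cadd_phred=30.0,
            protein_position=pp,
            carrier_samples=tuple(int(i) for i in carriers),
        )

    panel = [
        # female carriers with menopause-age data: 27 DBD + 80 LBD = 107
        mv(30, f[0:13]),
        mv(60, f[13:27]),
        mv(250, f[27:54]),
        mv(300, f[54:81]),
        mv(400, f[81:107]),
        # female carriers missing menopause age: 176 female carriers total
        mv(260, f[107:130]),
        mv(310, f[130:153]),
        mv(420, f[153:176]),
        # male carriers: 168, for the obesity strata (344 = 176 + 168)
        mv(35, m[0:28]),
        mv(65, m[28:56]),
        mv(270, m[56:84]),
        mv(320, m[84:112]),
        mv(380, m[112:140]),
        mv(430, m[140:168]),
        # hinge-region variants: carriers of the gene but of neither domain
        mv(140, f[9000:9001]),
        mv(150, f[9001:9002]),
        mv(160, f[9002:9003]),
    ]
    domain_scope = tuple(range(14))  # DBD+LBD variants; hinge carries no effect
    anm_missing = tuple(int(i) for i in f[107:176])
    traits = [
        TraitModel(
            name="menopause_age",
            kind="quantitative",
            per_allele_effect=SF1_ANM_EFFECT,
            intercept=50.0,
            residual_sd=5.0,
            predictor="additive",
            scope=domain_scope,
            sex_restriction="female",
            missing_samples=anm_missing,
        ),
        TraitModel(
            name="obesity",
            kind="binary",
            per_allele_effect=SF1_OBESITY_LOG_OR,
            baseline_prevalence=0.23,
            predictor="additive",
            scope=domain_scope,
            sex_specific_effect="female",
        ),
    ]
    return SimulationConfig(
        n_samples=n_samples,
        sex_fraction_female=0.5,
        panel=panel,
        traits=traits,
        seed=seed,
    )


def _null_cohort_config(n_samples: int, seed: int) -> SimulationConfig:
    panel = [
        PanelVariant(
            allele_frequency=5e-4,
            consequence="missense_variant",
            cadd_phred=28.0,
            protein_position=pp,
        )
        for pp in (20, 40, 70, 240, 280, 320, 360, 400, 430, 455)
    ]
    traits = [
        TraitModel(name="quant_null", kind="quantitative", per_allele_effect=0.0),
        TraitModel(name="binary_null", kind="binary", per_allele_effect=0.0),
    ]
    return SimulationConfig(
        n_samples=n_samples, panel=panel, traits=traits, seed=seed
    )


def _qc_torture_config(n_samples: int, seed: int) -> SimulationConfig:
    # common-frequency sites: QC behaviour does not depend on rarity, and
    # abundant hets give the allele-balance rule plenty of targets
    panel = [
        PanelVariant(allele_frequency=0.15, protein_position=30 + 5 * i)
        for i in range(6)
    ]
    panel.append(
        PanelVariant(
            allele_frequency=0.15, ref="AT", alt="A",
            consequence="frameshift_variant", loftee="HC", protein_position=70,
        )
    )
    panel.append(
        PanelVariant(allele_frequency=0.15, protein_position=250, missing_fraction=0.6)
    )
    return SimulationConfig(
        n_samples=n_samples,
        panel=panel,
        qc_violation_rates={"low_dp": 0.06, "low_gq": 0.06, "allele_imbalance": 0.5},
        traits=[TraitModel(name="quant_null", per_allele_effect=0.0)],
        seed=seed,
    )


def _tiny_toy_config(n_samples: int, seed: int) -> SimulationConfig:
    if n_samples != 8:
        raise ValueError("tiny_toy is fixed at 8 samples")
    panel = [
        PanelVariant(consequence="missense_variant", cadd_phred=28.0,
                     protein_position=30, carrier_samples=(0,)),
        PanelVariant(consequence="missense_variant", cadd_phred=26.0,
                     protein_position=300, carrier_samples=(1,), hom_samples=(2,)),
        PanelVariant(consequence="stop_gained", cadd_phred=40.0, loftee="HC",
                     protein_position=50, carrier_samples=(3,)),
        PanelVariant(consequence="missense_variant", cadd_phred=10.0,
                     protein_position=40, carrier_samples=(4,)),
    ]
    traits = [
        TraitModel(
            name="biomarker",
            kind="quantitative",
            per_allele_effect=-3.0,
            intercept=10.0,
            residual_sd=1.0,
            covariate_effects={},
            batch_effects={b: 0.0 for b in BATCH_LEVELS},
        )
    ]
    return SimulationConfig(n_samples=8, panel=panel, traits=traits, seed=seed)


_FIXTURE_DEFAULTS = {
    "sf1_mirror": (_sf1_mirror_config, 20_000, 2024),
    "null_cohort": (_null_cohort_config, 5_000, 7),
    "qc_torture": (_qc_torture_config, 60, 11),
    "tiny_toy": (_tiny_toy_config, 8, 3),
}


def make_fixture(
    name: str, n_samples: int | None = None, seed: int | None = None
) -> FixtureBundle:
    """Build one of the named study fixtures.

    - ``sf1_mirror``: carrier structure mirroring the SF-1 domain analysis
      (27 DBD / 80 LBD / 107 combined menopause-age carriers among women;
      344 = 176 female + 168 male carriers for the obesity strata; 3
      hinge carriers outside both domains), with the true menopause and
      obesity effects set to the fixture's calibrated values.
    - ``null_cohort``: frequency-sampled rare variants, all trait effects 0.
    - ``qc_torture``: high injected violation rates for every QC rule and
      one variant forced above the missingness cutoff.
    - ``tiny_toy``: 8 samples x 4 variants, small enough to hand-trace
      every downstream statistic. (Tiny cohorts cannot satisfy an
      in-cohort MAF < 0.1% rarity filter; pass an explicit
      ``maf_threshold`` when building masks on them.)
    """
    if name not in _FIXTURE_DEFAULTS:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    builder, default_n, default_seed = _FIXTURE_DEFAULTS[name]
    cfg = builder(
        n_samples if n_samples is not None else default_n,
        seed if seed is not None else default_seed,
    )
    return simulate_cohort(cfg)


# ---------------------------------------------------------------------------
# Simulation experiments: parameter recovery and type-I error
# ---------------------------------------------------------------------------


def _recovery_panel(domains: Sequence[str], carrier_fraction: float) -> list[PanelVariant]:
    """20 rare deleterious missense variants spread over the wanted domains."""
    pps: list[int] = []
    n_per = 20 // len(list(domains))
    spans = {d.domain_name: d for d in default_sf1_domains()}
    for dname in domains:
        s = spans[dname]
        pps.extend(
            np.linspace(s.start_residue, s.end_residue, n_per).astype(int).tolist()
        )
    af = carrier_fraction / (2 * len(pps))
    return [
        PanelVariant(
            allele_frequency=af,
            consequence="missense_variant",
            cadd_phred=30.0,
            protein_position=pp,
        )
        for pp in pps
    ]


def _fit_one_recovery(
    cfg: SimulationConfig,
    kind: str,
    mode: str,
    domains: Sequence[str] | None,
    female_only: bool,
) -> assoc.AssociationResult:
    bundle = simulate_cohort(cfg)
    cohort, _ = qc.apply_qc(bundle.cohort, qc.QcConfig())
    resolved = am.resolve_annotations(bundle.annotations)
    mask = am.build_mask(resolved, cohort, "missense_cadd25")
    if domains is not None:
        mask = am.restrict_to_domains(mask, resolved, bundle.domains, domains)
    burden = cb.collapse(
        mask, cohort, cb.BurdenMode.CARRIER if mode == "carrier" else cb.BurdenMode.ADDITIVE
    )
    covars = bundle.covariate_frame()
    if female_only:
        covars = covars.drop(columns=["sex"])  # constant in a one-sex cohort
    spec = assoc.TraitSpec(
        name="trait",
        kind=assoc.TraitKind.QUANTITATIVE if kind == "quantitative" else assoc.TraitKind.BINARY,
    )
    # rare carriers: Firth bias reduction keeps the binary estimator
    # centred, where plain ML carries an O(1/carriers) bias
    return assoc.burden_glm(
        spec, bundle.phenotypes["trait"], burden, covars, firth=(kind == "binary")
    )


def recovery_experiment(
    true_effect: float,
    kind: str = "quantitative",
    mode: str = "additive",
    domains: Sequence[str] | None = ("DBD", "LBD"),
    n_reps: int = 200,
    n_samples: int = 20_000,
    carrier_fraction: float = 0.01,
    residual_sd: float = 5.0,
    baseline_prevalence: float = 0.23,
    female_only: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Estimate the burden effect on replicate cohorts with known truth.

    Each replicate simulates a fresh cohort (rare deleterious missense
    panel at combined carrier fraction ``carrier_fraction``, full
    covariate set with nonzero effects, trait generated with per-allele —
    or per-carrier, for ``mode='carrier'`` — effect ``true_effect``),
    runs QC, builds the CADD>=25 missense mask, restricts it to
    ``domains`` when given, collapses, and fits the burden GLM. Returns
    the ``n_reps`` coefficient estimates (log-odds scale for binary).
    """
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        trait = TraitModel(
            name="trait",
            kind=kind,
            per_allele_effect=true_effect,
            residual_sd=residual_sd,
            baseline_prevalence=baseline_prevalence,
            predictor=mode,
        )
        cfg = SimulationConfig(
            n_samples=n_samples,
            sex_fraction_female=1.0 if female_only else 0.5,
            panel=_recovery_panel(domains or ("DBD", "LBD"), carrier_fraction),
            traits=[trait],
            seed=np.random.SeedSequence((seed, rep)).generate_state(1)[0],
        )
        res = _fit_one_recovery(cfg, kind, mode, domains, female_only)
        estimates[rep] = res.beta
    return estimates


def type_one_error_experiment(
    n_reps: int = 1000,
    n_samples: int = 5000,
    carrier_fraction: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """p-values of the burden GLM on cohorts simulated with zero effect."""
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_samples=n_samples,
            sex_fraction_female=1.0,
            panel=_recovery_panel(("DBD", "LBD"), carrier_fraction),
            traits=[TraitModel(name="trait", kind="quantitative", per_allele_effect=0.0)],
            seed=np.random.SeedSequence((seed, 7, rep)).generate_state(1)[0],
        )
        res = _fit_one_recovery(cfg, "quantitative", "additive", ("DBD", "LBD"), True)
        pvals[rep] = res.p
    return pvals
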