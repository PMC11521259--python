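"""GLM burden and single-variant association tests."""

import numpy as np
import pandas as pd
import pytest

from rareburden import association as assoc
from rareburden.association import (
    AssociationError,
    NoCarriersError,
    SeparationError,
    SexRestriction,
    TraitKind,
    TraitSpec,
    burden_glm,
    or_from_beta,
    single_variant_glm,
    stratified_run,
)
from rareburden.collapse_burden import BurdenMode, BurdenVector
from rareburden.variant_io import CohortGenotypes, VariantRecord


def burden_from(values, mode=BurdenMode.CARRIER):
    ids = tuple(f"S{i}" for i in range(len(values)))
    return BurdenVector("NR5A1", "damaging", None, mode, ids, np.array(values))


def series(values):
    return pd.Series(values, index=[f"S{i}" for i in range(len(values))], dtype=float)


QUANT = TraitSpec("y", TraitKind.QUANTITATIVE)
BINARY = TraitSpec("y", TraitKind.BINARY)


class TestClosedForms:
    def test_covariate_free_quantitative_equals_mean_difference(self):
        res = burden_glm(QUANT, series([10, 12, 8]), burden_from([0, 0, 1]))
        assert res.beta == pytest.approx(-3.0, abs=1e-8)
        assert res.n_total == 3 and res.n_carriers == 1

    def test_covariate_free_binary_equals_table_log_odds(self):
        # carriers: 3 cases / 10; non-carriers: 1 case / 9
        y = series([1] * 3 + [0] * 7 + [1] * 1 + [0] * 8)
        b = burden_from([1] * 10 + [0] * 9)
        res = burden_glm(BINARY, y, b)
        expected = np.log((3 / 7) / (1 / 8))
        assert res.beta == pytest.approx(expected, abs=1e-8)
        assert res.or_ == pytest.approx(24 / 7, abs=1e-7)

    def test_larger_two_group_problem_matches_lstsq(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(1, 0.3, 200)
        y = 2.0 - 1.3 * x + rng.normal(0, 1, 200)
        res = burden_glm(QUANT, series(y), burden_from(x))
        assert res.beta == pytest.approx(y[x == 1].mean() - y[x == 0].mean(), abs=1e-8)


class TestOrFromBeta:
    def test_closed_form(self):
        or_, lo, hi = or_from_beta(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-1.959963984540054 * 0.1), rel=1e-12)
        assert hi == pytest.approx(np.exp(1.959963984540054 * 0.1), rel=1e-12)

    def test_degenerate_se(self):
        assert or_from_beta(np.log(2), 0.0) == (2.0, 2.0, 2.0)

    def test_monotone_in_beta(self):
        ors = [or_from_beta(b, 0.2)[0] for b in np.linspace(-1, 1, 7)]
        assert ors == sorted(ors)


class TestFitBehaviour:
    def test_zero_carriers_raises(self):
        with pytest.raises(NoCarriersError, match="no carriers"):
            burden_glm(QUANT, series([1, 2, 3]), burden_from([0, 0, 0]))

    def test_listwise_deletion_of_missing_values(self):
        y = series([10, 12, 8, np.nan])
        res = burden_glm(QUANT, y, burden_from([0, 0, 1, 1]))
        assert res.n_total == 3 and res.n_carriers == 1
        assert res.beta == pytest.approx(-3.0, abs=1e-8)

    def test_perfect_separation_is_flagged(self):
        y = series([1, 1, 1, 0, 0, 0, 0, 0])
        with pytest.raises((SeparationError, AssociationError)):
            burden_glm(BINARY, y, burden_from([1, 1, 1, 0, 0, 0, 0, 0]))

    def test_wald_interval_brackets_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(1, 0.2, 500)
        y = series(1.0 + 0.8 * x + rng.normal(0, 1, 500))
        res = burden_glm(QUANT, y, burden_from(x))
        assert res.ci_low <= res.beta <= res.ci_high
        assert res.ci_high - res.beta == pytest.approx(1.959963984540054 * res.se)
        assert 0 < res.p <= 1

    def test_permuting_samples_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.binomial(1, 0.1, n)
        cov = pd.DataFrame(
            {
                "age": rng.uniform(40, 70, n),
                "pc1": rng.standard_normal(n),
                "wes_batch": rng.choice(["50k", "200k", "450k"], n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        y = series(5 + 0.1 * cov["age"].to_numpy() - 2 * x + rng.normal(0, 1, n))
        base = burden_glm(QUANT, y, burden_from(x), cov)
        perm = rng.permutation(n)
        ids = [f"S{i}" for i in perm]
        shuffled = BurdenVector(
            "NR5A1", "damaging", None, BurdenMode.CARRIER, tuple(ids), x[perm]
        )
        res = burden_glm(QUANT, y.loc[ids], shuffled, cov.loc[ids])
        assert res.beta == pytest.approx(base.beta, abs=1e-10)
        assert res.se == pytest.approx(base.se, abs=1e-10)
        assert res.p == pytest.approx(base.p, rel=1e-8)


class TestFirthLogistic:
    def test_agrees_with_ml_when_events_are_plentiful(self):
        rng = np.random.default_rng(4)
        n = 5000
        x = rng.binomial(1, 0.4, n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.7 * x)))
        y = series((rng.random(n) < p).astype(float))
        ml = burden_glm(BINARY, y, burden_from(x))
        fi = burden_glm(BINARY, y, burden_from(x), firth=True)
        # penalisation is O(1/n): negligible with ~2000 carriers
        assert fi.beta == pytest.approx(ml.beta, abs=5e-3)
        assert fi.se == pytest.approx(ml.se, rel=1e-2)

    def test_finite_estimate_under_separation(self):
        y = series([1, 1, 1, 0, 0, 0, 0, 0])
        res = burden_glm(BINARY, y, burden_from([1, 1, 1, 0, 0, 0, 0, 0]), firth=True)
        assert np.isfinite(res.beta) and np.isfinite(res.se)

    def test_rejected_for_quantitative_traits(self):
        with pytest.raises(ValueError, match="binary"):
            burden_glm(QUANT, series([1.0, 2.0, 3.0]), burden_from([0, 1, 0]), firth=True)


class TestSingleVariant:
    def cohort(self, dosages):
        n = len(dosages)
        d = np.array([dosages], dtype=np.int32)
        full = np.full_like(d, 30)
        return CohortGenotypes(
            [VariantRecord("9", 100, "A", "G")],
            [f"S{i}" for i in range(n)], d, full, full, full, full,
        )

    def test_equals_one_variant_additive_mask(self):
        dosages = [1, 0, 0, 2, 0, 0, 1, 0]
        cohort = self.cohort(dosages)
        y = series([8, 10, 12, 6, 11, 9, 7, 10])
        sv = single_variant_glm("9:100:A:G", cohort, QUANT, y)
        bv = burden_from(dosages, BurdenMode.ADDITIVE)
        bg = burden_glm(QUANT, y, bv)
        assert sv.beta == pytest.approx(bg.beta, abs=1e-12)
        assert sv.p == pytest.approx(bg.p, rel=1e-10)
        # reports the alternate allele count, not the carrier count
        assert sv.n_carriers == 4

    def test_monomorphic_variant_raises(self):
        cohort = self.cohort([0, 0, 0])
        with pytest.raises(AssociationError, match="monomorphic"):
            single_variant_glm("9:100:A:G", cohort, QUANT, series([1, 2, 3]))


class TestStratifiedRun:
    def make_inputs(self, rng, n=600, female_effect=-2.0, male_effect=-2.0):
        ids = [f"S{i}" for i in range(n)]
        sex = np.array([1] * (n // 2) + [0] * (n - n // 2))
        cov = pd.DataFrame(
            {
                "age": rng.uniform(40, 70, n),
                "age_sq": 0.0,
                "sex": sex,
                "pc1": rng.standard_normal(n),
                "wes_batch": rng.choice(["50k", "200k", "450k"], n),
            },
            index=ids,
        )
        cov["age_sq"] = cov["age"] ** 2
        x = rng.binomial(1, 0.1, n)
        eff = np.where(sex == 1, female_effect, male_effect)
        y = pd.Series(30 + eff * x + rng.normal(0, 1, n), index=ids)
        burden = BurdenVector(
            "NR5A1", "damaging", None, BurdenMode.CARRIER, tuple(ids), x
        )
        return cov, burden, y, sex

    def test_stratum_carrier_counts(self, sf1_mirror, sf1_qc):
        from rareburden import annotation_masks as am
        from rareburden import collapse_burden as cb

        cohort, _ = sf1_qc
        resolved = am.resolve_annotations(sf1_mirror.annotations)
        mask = am.restrict_to_domains(
            am.build_mask(resolved, cohort, "missense_cadd25"),
            resolved, sf1_mirror.domains, ["DBD", "LBD"],
        )
        burden = cb.additive_score(mask, cohort)
        covars = sf1_mirror.covariate_frame()
        traits = [(TraitSpec("obesity", TraitKind.BINARY), sf1_mirror.phenotypes["obesity"])]
        by_stratum = {
            s.value: stratified_run(traits, [burden], covars, s)[0]
            for s in (SexRestriction.ALL, SexRestriction.FEMALE, SexRestriction.MALE)
        }
        assert by_stratum["all"].n_carriers == 344
        assert by_stratum["female"].n_carriers == 176
        assert by_stratum["male"].n_carriers == 168

    def test_sex_restricted_trait_excludes_other_sex(self, sf1_mirror):
        covars = sf1_mirror.covariate_frame()
        anm = sf1_mirror.phenotypes["menopause_age"]
        n_female = int((covars["sex"] == 1).sum())
        assert anm.dropna().index.isin(covars.index[covars["sex"] == 1]).all()
        assert anm.notna().sum() < n_female  # some women lack the phenotype

    def test_female_only_effect_recovered_per_stratum(self):
        rng = np.random.default_rng(9)
        cov, burden, y, _ = self.make_inputs(rng, n=4000, female_effect=-2.0, male_effect=0.0)
        traits = [(TraitSpec("y", TraitKind.QUANTITATIVE), y)]
        female = stratified_run(traits, [burden], cov, SexRestriction.FEMALE)[0]
        male = stratified_run(traits, [burden], cov, SexRestriction.MALE)[0]
        assert female.beta == pytest.approx(-2.0, abs=3 * female.se)
        assert abs(male.beta) <= 3 * male.se
        assert female.stratum == "female" and male.stratum == "male"
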