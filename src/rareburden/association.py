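"""Burden and single-variant association testing via generalized linear models.

Quantitative traits are fitted with an identity-link Gaussian GLM
(ordinary least squares) and binary traits with a logit-link binomial
GLM, with the burden predictor entered alongside the covariate set used
throughout biobank exome analyses: age, age squared, sex (omitted in
sex-stratified fits), the first 10 genetic principal components and the
exome-sequencing release batch as a categorical covariate. Effects are
reported with Wald standard errors, 95% confidence intervals
(estimate +/- 1.96 SE) and two-sided Wald p-values; binary-trait
coefficients are additionally exponentiated to odds ratios.

Samples with a missing trait or covariate value are dropped listwise
before fitting. Fits with no carriers left after alignment, or with
perfect separation in a binary fit, raise instead of returning a
spuriously precise result.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .collapse_burden import BurdenMode, BurdenVector, carrier_count
from .variant_io import MISSING, CohortGenotypes

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # 97.5% normal quantile for Wald intervals

#: default covariate columns expected in a phenotype/covariate table
DEFAULT_COVARIATES = ["age", "age_sq", "sex"] + [f"pc{i}" for i in range(1, 11)] + ["wes_batch"]


class TraitKind(enum.Enum):
    QUANTITATIVE = "quantitative"
    BINARY = "binary"


class SexRestriction(enum.Enum):
    ALL = "all"
    FEMALE = "female"
    MALE = "male"


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """A trait to be tested: name, measurement kind and sex restriction."""

    name: str
    kind: TraitKind
    sex_restriction: SexRestriction = SexRestriction.ALL
    units: str = ""


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """One fitted burden (or single-variant) association.

    ``beta`` is the per-allele (ADDITIVE) or per-carrier (CARRIER) effect
    in trait units for quantitative traits and in log-odds for binary
    traits; ``or_`` fields are populated for binary traits only.
    """

    gene: str
    mask: str
    domain_scope: tuple[str, ...] | None
    trait: str
    stratum: str
    n_total: int
    n_carriers: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


class AssociationError(RuntimeError):
    pass


class NoCarriersError(AssociationError):
    pass


class SeparationError(AssociationError):
    pass


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its Wald interval."""
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
    )


def build_design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Intercept + covariates, with categorical columns one-hot encoded
    against their first level."""
    X = pd.DataFrame({"const": 1.0}, index=index)
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[index]
        cat_cols = [
            c for c in cov.columns if cov[c].dtype == object or isinstance(cov[c].dtype, pd.CategoricalDtype)
        ]
        num = cov.drop(columns=cat_cols).astype(float)
        X = pd.concat([X, num], axis=1)
        if cat_cols:
            dummies = pd.get_dummies(cov[cat_cols].astype(str), drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    return X


def _fit_firth_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Logistic regression with Firth's bias-reduced penalised likelihood.

    Solves the modified score equations X'(y - p + h(1/2 - p)) = 0, where
    h is the diagonal of the weighted hat matrix. This removes the
    O(1/n) bias of the ML estimator — material when carriers are rare —
    and yields finite estimates under separation. Returns (params, SEs)
    with Wald SEs from the Fisher information at the solution.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(200):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = p * (1.0 - p)
        XtWX = X.T @ (X * w[:, None])
        try:
            inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:
            raise AssociationError(f"singular design in Firth fit: {exc}") from exc
        h = w * np.einsum("ij,jk,ik->i", X, inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = inv @ score
        # damp oversized steps to keep the iteration stable
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if norm < 1e-10:
            break
    else:
        raise AssociationError("Firth logistic fit did not converge")
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def _fit_glm(
    y: pd.Series, X: pd.DataFrame, kind: TraitKind, firth: bool = False
) -> tuple[float, float]:
    if firth:
        if kind is not TraitKind.BINARY:
            raise ValueError("Firth correction applies to binary traits only")
        j = list(X.columns).index("burden")
        params, bse = _fit_firth_logistic(
            y.to_numpy(dtype=float), X.to_numpy(dtype=float)
        )
        return float(params[j]), float(bse[j])
    family = sm.families.Gaussian() if kind is TraitKind.QUANTITATIVE else sm.families.Binomial()
    model = sm.GLM(y.astype(float), X.astype(float), family=family)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit()
        except PerfectSeparationError as exc:
            raise SeparationError(f"perfect separation in binary fit: {exc}") from exc
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            if kind is TraitKind.BINARY:
                raise SeparationError("perfect separation detected in binary fit")
            raise AssociationError(
                "saturated or perfectly predicted fit (too few observations "
                "for the covariate set?)"
            )
    beta = float(res.params["burden"])
    se = float(res.bse["burden"])
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise AssociationError("non-finite burden estimate (degenerate fit)")
    return beta, se


def burden_glm(
    trait: TraitSpec,
    trait_values: pd.Series,
    burden: BurdenVector,
    covariates: pd.DataFrame | None = None,
    stratum: str = "all",
    firth: bool = False,
) -> AssociationResult:
    """Fit the burden GLM for one trait and one burden vector.

    ``trait_values`` and ``covariates`` are indexed by sample id; samples
    missing from any input, or with NaN trait/covariate values, are
    dropped listwise. ``firth=True`` switches binary fits to Firth's
    bias-reduced penalised likelihood (recommended when carriers are
    rare); the default is the plain ML fit.
    """
    b = pd.Series(burden.values, index=list(burden.sample_ids), name="burden")
    idx = b.index.intersection(trait_values.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    frame = pd.DataFrame({"y": trait_values.loc[idx], "burden": b.loc[idx]})
    if covariates is not None:
        frame = frame.join(covariates.loc[idx])
    frame = frame.dropna()
    if frame.empty:
        raise AssociationError(f"no complete observations for trait {trait.name}")
    if trait.kind is TraitKind.BINARY:
        bad = set(frame["y"].unique()) - {0, 1, 0.0, 1.0}
        if bad:
            raise AssociationError(f"binary trait {trait.name} has values {sorted(bad)}")
    n_carriers = int((frame["burden"] >= 1).sum())
    if n_carriers == 0:
        raise NoCarriersError(f"no carriers in stratum {stratum!r} for trait {trait.name}")

    cov_cols = [c for c in frame.columns if c not in ("y", "burden")]
    X = build_design(frame[cov_cols] if cov_cols else None, frame.index)
    X.insert(1, "burden", frame["burden"].astype(float))
    beta, se = _fit_glm(frame["y"], X, trait.kind, firth=firth)

    z = beta / se if se > 0 else np.inf * np.sign(beta)
    from scipy import stats as _st

    p = float(2 * _st.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    p = max(p, np.finfo(float).tiny)
    ors = or_from_beta(beta, se) if trait.kind is TraitKind.BINARY else (None, None, None)
    result = AssociationResult(
        gene=burden.gene_symbol,
        mask=burden.mask_name,
        domain_scope=burden.domain_scope,
        trait=trait.name,
        stratum=stratum,
        n_total=int(len(frame)),
        n_carriers=n_carriers,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        p=min(p, 1.0),
        or_=ors[0],
        or_ci_low=ors[1],
        or_ci_high=ors[2],
    )
    logger.info(
        "fit trait=%s mask=%s scope=%s stratum=%s n=%d carriers=%d beta=%.4g p=%.3g",
        trait.name, burden.mask_name, burden.domain_scope, stratum,
        result.n_total, result.n_carriers, beta, result.p,
    )
    return result


def single_variant_glm(
    variant_id: str,
    cohort: CohortGenotypes,
    trait: TraitSpec,
    trait_values: pd.Series,
    covariates: pd.DataFrame | None = None,
    stratum: str = "all",
) -> AssociationResult:
    """Per-variant association: same GLM with the variant dosage as predictor.

    ``n_carriers`` reports the alternate allele count (AC) among analysed
    samples. Monomorphic variants raise.
    """
    i = cohort.variant_index(variant_id)
    d = cohort.dosage[i].astype(np.int64).copy()
    d[d == MISSING] = 0
    if d.sum() == 0:
        raise AssociationError(f"variant {variant_id} is monomorphic after QC")
    burden = BurdenVector(
        gene_symbol=variant_id,
        mask_name="single_variant",
        domain_scope=None,
        mode=BurdenMode.ADDITIVE,
        sample_ids=tuple(cohort.samples),
        values=d,
    )
    res = burden_glm(trait, trait_values, burden, covariates, stratum=stratum)
    b = pd.Series(d, index=cohort.samples)
    idx = trait_values.dropna().index.intersection(b.index)
    if covariates is not None:
        idx = idx.intersection(covariates.dropna().index)
    return dataclasses.replace(res, n_carriers=int(b.loc[idx].sum()))


def stratified_run(
    traits: list[tuple[TraitSpec, pd.Series]],
    burdens: list[BurdenVector],
    covariates: pd.DataFrame,
    sex: SexRestriction = SexRestriction.ALL,
) -> list[AssociationResult]:
    """Fit every trait x burden combination within a sex stratum.

    ``covariates`` must carry a 0/1 ``sex`` column (1 = female). In
    single-sex strata the sex covariate is dropped (it is constant);
    sex-restricted traits are only fitted in strata containing their sex,
    and in the ALL stratum the opposite sex is excluded automatically by
    the trait's missing values.
    """
    if "sex" not in covariates.columns:
        raise ValueError("covariate table lacks a 'sex' column")
    if sex is SexRestriction.ALL:
        cov = covariates
    else:
        wanted = 1 if sex is SexRestriction.FEMALE else 0
        cov = covariates[covariates["sex"] == wanted].drop(columns=["sex"])
        if cov.empty:
            raise AssociationError(f"empty stratum: {sex.value}")
    results = []
    for spec, values in traits:
        if sex is not SexRestriction.ALL and spec.sex_restriction not in (
            SexRestriction.ALL,
            sex,
        ):
            continue
        use_cov = cov
        if sex is SexRestriction.ALL and spec.sex_restriction is not SexRestriction.ALL:
            # single-sex trait in the combined stratum: drop the constant
            # sex column (the other sex has no trait values anyway)
            wanted = 1 if spec.sex_restriction is SexRestriction.FEMALE else 0
            use_cov = cov[cov["sex"] == wanted].drop(columns=["sex"])
        for burden in burdens:
            results.append(
                burden_glm(spec, values, burden, use_cov, stratum=sex.value)
            )
    return results


def bonferroni(results: list[AssociationResult], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values (helper; not applied by default)."""
    m = m if m is not None else len(results)
    return [min(1.0, r.p * m) for r in results]
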