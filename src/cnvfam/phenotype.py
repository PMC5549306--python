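"""Clinical exclusion and GEE covariate adjustment of the quantitative trait.

Subjects with fasting plasma glucose above the diabetes threshold are
excluded; the remaining trait values are regressed on covariates (age, sex,
BMI, ethnicity, recruiting site, optionally hypertension status) with a
generalized-estimating-equation linear model using an exchangeable working
correlation across siblings, and the residuals serve as the adjusted
phenotype for all association tests.

Covariate coding: sex and ethnicity are binary indicators, site is
dummy-coded against the alphabetically first observed level. Fits are
complete-case: a sample missing the trait or any covariate of the chosen
set is dropped (counted in the fit's log). Samples absent from the pedigree
are treated as singleton clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import linalg as sla
from statsmodels.genmod.cov_struct import Exchangeable, Independence

from .io import sample_family_index
from .types import AdjustedPhenotype, Family, PhenotypeRecord, state_code

log = logging.getLogger(__name__)

COVARIATE_SETS = {
    "base": ("age", "sex", "bmi", "ethnicity", "site"),
    "base_plus_htn": ("age", "sex", "bmi", "ethnicity", "site", "hypertension"),
    "no_bmi": ("age", "sex", "ethnicity", "site"),
}

DIABETES_FPG_LIMIT = 126.0  # mg/dl


def exclude_diabetes(
    records: Iterable[PhenotypeRecord], fpg_limit: float = DIABETES_FPG_LIMIT
) -> list[PhenotypeRecord]:
    """Drop subjects with FPG strictly above ``fpg_limit`` (mg/dl) and
    subjects carrying a diagnosed-diabetes flag.

    A record with a missing trait is retained here; the complete-case rule
    of the model fit removes it later.
    """
    if fpg_limit <= 0:
        raise ValueError("fpg_limit must be > 0")
    kept = []
    for r in records:
        if r.diabetes:
            continue
        if r.trait_value is not None and r.trait_value > fpg_limit:
            continue
        kept.append(r)
    return kept


@dataclass
class CovariateModelFit:
    """A fitted GEE covariate model and everything needed to reuse it."""

    coefficients: dict[str, float]
    intercept: float
    working_correlation: float
    n_clusters: int
    n_samples: int
    covariate_set: str
    n_dropped_missing: int = 0
    site_levels: tuple[str, ...] = ()
    # fitted internals, kept for residual computation and group-mean CIs
    _column_names: list[str] = field(default_factory=list, repr=False)
    _keep_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool), repr=False)
    _params: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _result: object = field(default=None, repr=False)
    _sample_ids: list[str] = field(default_factory=list, repr=False)


def _design_row(r: PhenotypeRecord, covariates: Sequence[str], site_levels: Sequence[str]):
    """Return the encoded covariate row for one record, or None if any
    required covariate is missing/unencodable."""
    row = [1.0]
    for cov in covariates:
        if cov == "age":
            if r.age is None:
                return None
            row.append(r.age)
        elif cov == "sex":
            if r.sex not in (1, 2):
                return None
            row.append(1.0 if r.sex == 1 else 0.0)
        elif cov == "bmi":
            if r.bmi is None:
                return None
            row.append(r.bmi)
        elif cov == "ethnicity":
            if r.ethnicity is None:
                return None
            row.append(1.0 if r.ethnicity == "Japanese" else 0.0)
        elif cov == "hypertension":
            if r.hypertension is None:
                return None
            row.append(float(r.hypertension))
        elif cov == "site":
            if r.site is None or r.site not in site_levels:
                return None
            row.extend(1.0 if r.site == lvl else 0.0 for lvl in site_levels[1:])
    return row


def _column_labels(covariates: Sequence[str], site_levels: Sequence[str]) -> list[str]:
    names = ["intercept"]
    for cov in covariates:
        if cov == "sex":
            names.append("sex_male")
        elif cov == "ethnicity":
            names.append("ethnicity_japanese")
        elif cov == "site":
            names.extend(f"site[{lvl}]" for lvl in site_levels[1:])
        else:
            names.append(cov)
    return names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, _, pivots = sla.qr(X, mode="economic", pivoting=True)
        r = np.linalg.matrix_rank(X)
        collinear = [names[i] for i in sorted(pivots[r:])]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


_CONTINUOUS = {"intercept", "age", "bmi"}


def _drop_degenerate_indicators(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Drop 0/1 indicator columns without variation (e.g. a single observed
    ethnicity) — they carry no information and would only break the rank
    check. Continuous covariates are never dropped; a constant one is a
    genuine design error surfaced by the rank check."""
    keep = np.ones(X.shape[1], dtype=bool)
    for j, name in enumerate(names):
        if name in _CONTINUOUS:
            continue
        if np.ptp(X[:, j]) == 0.0:
            keep[j] = False
            log.warning("covariate column %s has no variation; dropped from the fit", name)
    return X[:, keep], [n for n, k in zip(names, keep) if k], keep


def _build_design(records, covariates, site_levels=None):
    if site_levels is None:
        site_levels = tuple(sorted({r.site for r in records if r.site is not None})) if "site" in covariates else ()
    rows, ys, ids = [], [], []
    n_dropped = 0
    for r in records:
        if r.trait_value is None:
            n_dropped += 1
            continue
        row = _design_row(r, covariates, site_levels)
        if row is None:
            n_dropped += 1
            continue
        rows.append(row)
        ys.append(r.trait_value)
        ids.append(r.sample_id)
    if not rows:
        raise ValueError("no complete-case samples to fit")
    return np.asarray(rows), np.asarray(ys), ids, site_levels, n_dropped


def _cluster_codes(sample_ids: Sequence[str], families: Iterable[Family]) -> np.ndarray:
    fam_of = sample_family_index(families)
    labels = []
    n_orphan = 0
    for sid in sample_ids:
        fid = fam_of.get(sid)
        if fid is None:
            n_orphan += 1
            fid = f"__singleton__{sid}"
        labels.append(fid)
    if n_orphan:
        log.warning("%d samples absent from the pedigree; treated as singleton clusters", n_orphan)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def fit_gee_linear(
    records: Sequence[PhenotypeRecord],
    families: Iterable[Family],
    covariate_set: str = "base",
) -> CovariateModelFit:
    """Fit the covariate model by GEE with exchangeable sibling correlation.

    The cluster is the sibship; individuals outside any family form their
    own cluster. With every cluster of size one the exchangeable structure
    is degenerate and an independence working correlation is used, making
    the estimates coincide with ordinary least squares.
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate_set {covariate_set!r}")
    covariates = COVARIATE_SETS[covariate_set]
    X, y, ids, site_levels, n_dropped = _build_design(records, covariates)
    names = _column_labels(covariates, site_levels)
    X, names, keep_mask = _drop_degenerate_indicators(X, names)
    _check_rank(X, names)
    codes = _cluster_codes(ids, families)
    n_clusters = len(np.unique(codes))
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters to fit a GEE")

    singleton_only = n_clusters == len(ids)
    cov_struct = Independence() if singleton_only else Exchangeable()
    model = sm.GEE(y, X, groups=codes, family=sm.families.Gaussian(), cov_struct=cov_struct)
    result = model.fit(maxiter=100)
    params = np.asarray(result.params)
    rho = 0.0 if singleton_only else float(model.cov_struct.dep_params)
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"estimated working correlation {rho} outside (-1, 1)")

    return CovariateModelFit(
        coefficients=dict(zip(names[1:], params[1:].tolist())),
        intercept=float(params[0]),
        working_correlation=rho,
        n_clusters=n_clusters,
        n_samples=len(ids),
        covariate_set=covariate_set,
        n_dropped_missing=n_dropped,
        site_levels=site_levels,
        _column_names=names,
        _keep_mask=keep_mask,
        _params=params,
        _result=result,
        _sample_ids=ids,
    )


def adjust_phenotype(
    records: Sequence[PhenotypeRecord], fit: CovariateModelFit
) -> list[AdjustedPhenotype]:
    """Residual trait values under a fitted covariate model.

    Residual = observed trait - fitted mean, then centred to mean zero over
    the adjusted samples (the association statistic is a difference of group
    means, which a constant shift cannot affect). Samples missing the trait
    or a covariate of the fitted set are omitted with a log entry.
    """
    covariates = COVARIATE_SETS[fit.covariate_set]
    out: list[AdjustedPhenotype] = []
    n_skipped = 0
    for r in records:
        if r.trait_value is None:
            n_skipped += 1
            continue
        row = _design_row(r, covariates, fit.site_levels)
        if row is None:
            n_skipped += 1
            continue
        fitted = float(np.asarray(row)[fit._keep_mask] @ fit._params)
        out.append(AdjustedPhenotype(sample_id=r.sample_id, residual=r.trait_value - fitted))
    if n_skipped:
        log.info("adjust_phenotype: %d samples omitted (missing trait or covariates)", n_skipped)
    if out:
        centre = float(np.mean([a.residual for a in out]))
        for a in out:
            a.residual -= centre
    return out


def group_means_ci(
    states: Mapping[str, object],
    records: Sequence[PhenotypeRecord],
    families: Iterable[Family],
    covariate_set: str = "base",
    z: float = 1.959963984540054,
) -> tuple[float, tuple[float, float], float, tuple[float, float]]:
    """Model-adjusted trait means for CNV carriers and non-carriers.

    Refits the GEE covariate model with a carrier indicator added and
    evaluates both groups' predicted means at the covariate means, with 95%
    confidence intervals from the robust (sandwich) covariance. ``states``
    maps sample id to a CNV state (anything non-normal marks a carrier).

    Returns ``(mean_carrier, ci_carrier, mean_normal, ci_normal)``.
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate_set {covariate_set!r}")
    covariates = COVARIATE_SETS[covariate_set]
    known = {sid for sid in states}
    usable = [r for r in records if r.sample_id in known]
    X, y, ids, site_levels, _ = _build_design(usable, covariates)
    carrier = np.array([1.0 if state_code(states[sid]) != 0 else 0.0 for sid in ids])
    if carrier.sum() == 0:
        raise ValueError("no carriers among the usable samples")
    if carrier.sum() == len(carrier):
        raise ValueError("no normal-state samples among the usable samples")
    X, names, _ = _drop_degenerate_indicators(X, _column_labels(covariates, site_levels))
    Xc = np.column_stack([X, carrier])
    names = names + ["carrier"]
    _check_rank(Xc, names)
    codes = _cluster_codes(ids, families)
    singleton_only = len(np.unique(codes)) == len(ids)
    cov_struct = Independence() if singleton_only else Exchangeable()
    result = sm.GEE(
        y, Xc, groups=codes, family=sm.families.Gaussian(), cov_struct=cov_struct
    ).fit(maxiter=100)
    params = np.asarray(result.params)
    V = np.asarray(result.cov_params())

    base = Xc.mean(axis=0)
    out = []
    for flag in (1.0, 0.0):
        a = base.copy()
        a[-1] = flag
        mean = float(a @ params)
        se = float(np.sqrt(a @ V @ a))
        out.append((mean, (mean - z * se, mean + z * se)))
    (m1, ci1), (m0, ci0) = out
    return m1, ci1, m0, ci0
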