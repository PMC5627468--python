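"""Covariate-adjusted SNP-SNP interaction scan on a quantitative phenotype.

For every marker pair the phenotype is regressed on the pair's genotype terms
plus the non-genetic covariates (sex, age, BMI, physical activity, calcium
intake), and the interaction is measured as the departure from additivity

    beta_interaction = beta_observed - (beta_SNP1 + beta_SNP2)

where, under the default *carrier* coding, beta_observed is the effect of
carrying a minor allele at both loci versus carrying neither, and beta_SNP1 /
beta_SNP2 are the single-locus carrier effects from the same bivariate fit.
That contrast assigns weights (-1, -1, +1) to the (only-SNP1, only-SNP2,
both) carriage-class indicators, and is algebraically identical to the
coefficient of a carrier1 x carrier2 product term.  Under the alternative
*additive* coding the interaction is the coefficient of the dosage product
d1*d2.  Inference is a Wald t-test on the contrast, with homoskedastic OLS
covariance s²(XᵀX)⁻¹ and residual degrees of freedom; family-wise error over
the k(k-1)/2 pairs is controlled by Bonferroni.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

from .io_panel import COVARIATE_COLUMNS, CovariateTable, GenotypeMatrix, PhenotypeVector

__all__ = [
    "NonEstimableError",
    "RegressionFit",
    "InteractionResult",
    "ScanResult",
    "encode_pair",
    "fit_ols",
    "interaction_test",
    "enumerate_pairs",
    "bonferroni_threshold",
    "render_threshold",
    "scan_all_pairs",
]

logger = logging.getLogger(__name__)

Coding = Literal["carrier", "additive"]


class NonEstimableError(ValueError):
    """The requested fit or contrast cannot be estimated from these data."""


@dataclass
class RegressionFit:
    """An OLS fit: named coefficients, their covariance and residual df."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    residual_df: int
    n_used: int

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Point estimate and standard error of the linear contrast c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        var = float(c @ self.cov @ c)
        return est, float(np.sqrt(max(var, 0.0)))


@dataclass
class InteractionResult:
    """Departure-from-additivity estimate for one SNP pair."""

    rsid1: str
    rsid2: str
    gene1: str
    gene2: str
    coding: str
    estimable: bool
    beta_interaction: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    n_used: int = 0
    beta_observed: float = np.nan
    beta_snp1: float = np.nan
    beta_snp2: float = np.nan
    cell_counts: tuple[int, int, int, int] = (0, 0, 0, 0)
    bonferroni_pass: bool = False
    reason: str = ""


def encode_pair(
    d1: np.ndarray, d2: np.ndarray, coding: Coding = "carrier"
) -> dict[str, np.ndarray]:
    """Genotype design columns for one SNP pair (complete, aligned dosages).

    carrier:  indicators only1 = (d1>=1 & d2==0), only2 = (d1==0 & d2>=1),
              both = (d1>=1 & d2>=1); the reference class carries neither.
    additive: the raw dosages d1, d2 and their product.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dosage columns differ in length")
    if np.isnan(d1).any() or np.isnan(d2).any():
        raise ValueError("encode_pair requires complete (non-missing) dosages")
    if coding == "carrier":
        c1, c2 = d1 >= 1, d2 >= 1
        return {
            "only1": (c1 & ~c2).astype(float),
            "only2": (~c1 & c2).astype(float),
            "both": (c1 & c2).astype(float),
        }
    if coding == "additive":
        return {"snp1": d1, "snp2": d2, "snp1_x_snp2": d1 * d2}
    raise ValueError(f"unknown coding {coding!r}")


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    cov_type: str = "nonrobust",
) -> RegressionFit:
    """Ordinary least squares with the classical covariance s²(XᵀX)⁻¹.

    ``cov_type`` may name any statsmodels covariance estimator (e.g. "HC1"
    for heteroskedasticity-robust standard errors); the default is the
    classical homoskedastic form.  Raises :class:`NonEstimableError` naming
    the collinear columns when the design is rank deficient, or when there
    are no residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("y and X are not conformable")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    names = list(names)
    if n <= k:
        raise NonEstimableError(f"n_used={n} leaves no residual df for {k} terms")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # QR with column pivoting: the trailing pivots are the dependent columns
        _, R, piv = qr(X, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(n, k) * np.finfo(float).eps
        dependent = [names[piv[j]] for j in range(k) if abs(R[j, j]) <= tol]
        raise NonEstimableError(
            f"rank-deficient design (rank {rank} < {k}); "
            f"collinear columns: {', '.join(dependent) or 'unresolved'}"
        )
    res = sm.OLS(y, X).fit(cov_type=cov_type)
    return RegressionFit(
        names=names,
        params=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        residual_df=int(res.df_resid),
        n_used=n,
    )


def _carriage_cells(d1: np.ndarray, d2: np.ndarray) -> tuple[int, int, int, int]:
    c1, c2 = d1 >= 1, d2 >= 1
    return (
        int((~c1 & ~c2).sum()),
        int((c1 & ~c2).sum()),
        int((~c1 & c2).sum()),
        int((c1 & c2).sum()),
    )


def interaction_test(
    d1: np.ndarray,
    d2: np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    covariates: CovariateTable | np.ndarray | None,
    coding: Coding = "carrier",
    rsid1: str = "snp1",
    rsid2: str = "snp2",
    gene1: str = "",
    gene2: str = "",
    cov_type: str = "nonrobust",
) -> InteractionResult:
    """Test one SNP pair for departure from additivity, adjusting for covariates.

    Fits y ~ 1 + covariates + genotype terms on the pair's complete cases and
    returns the interaction contrast with its 95% t-based confidence interval
    and two-sided Wald p-value.  Degenerate pairs (an empty carriage cell,
    a collinear design, or too few complete cases) yield a result flagged
    ``estimable=False`` with the reason recorded, never an exception.
    """
    y = phenotype.bua if isinstance(phenotype, PhenotypeVector) else np.asarray(
        phenotype, dtype=float
    )
    if covariates is None:
        cov = np.empty((y.shape[0], 0))
        cov_names: list[str] = []
    elif isinstance(covariates, CovariateTable):
        cov = covariates.as_array()
        cov_names = list(COVARIATE_COLUMNS)
    else:
        cov = np.asarray(covariates, dtype=float)
        cov_names = [f"cov{j}" for j in range(cov.shape[1])]
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)

    mask = ~(
        np.isnan(d1) | np.isnan(d2) | np.isnan(y) | np.isnan(cov).any(axis=1)
    )
    d1c, d2c, yc, covc = d1[mask], d2[mask], y[mask], cov[mask]
    cells = _carriage_cells(d1c, d2c)

    def _failed(reason: str) -> InteractionResult:
        return InteractionResult(
            rsid1=rsid1, rsid2=rsid2, gene1=gene1, gene2=gene2,
            coding=coding, estimable=False, n_used=int(mask.sum()),
            cell_counts=cells, reason=reason,
        )

    geno = encode_pair(d1c, d2c, coding) if d1c.size else None
    n_terms = 1 + len(cov_names) + 3
    if d1c.size < n_terms + 2:
        return _failed(f"only {d1c.size} complete cases for {n_terms} terms")
    if coding == "carrier" and min(cells) == 0:
        labels = ("neither", "only1", "only2", "both")
        empty = [lab for lab, c in zip(labels, cells) if c == 0]
        return _failed(f"empty carriage cell(s): {', '.join(empty)}")

    names = ["intercept"] + cov_names + list(geno)
    X = np.column_stack([np.ones(d1c.size), covc, *geno.values()])
    try:
        fit = fit_ols(yc, X, names, cov_type=cov_type)
    except NonEstimableError as err:
        return _failed(str(err))

    c = np.zeros(len(names))
    if coding == "carrier":
        i1, i2, ib = names.index("only1"), names.index("only2"), names.index("both")
        c[[i1, i2, ib]] = (-1.0, -1.0, 1.0)
        beta_obs = float(fit.params[ib])
        beta_1 = float(fit.params[i1])
        beta_2 = float(fit.params[i2])
    else:
        i1, i2 = names.index("snp1"), names.index("snp2")
        c[names.index("snp1_x_snp2")] = 1.0
        beta_1 = float(fit.params[i1])
        beta_2 = float(fit.params[i2])
        beta_obs = np.nan  # not a cell contrast on the additive scale

    beta, se = fit.contrast(c)
    if se == 0.0:
        return _failed("zero contrast variance (degenerate fit)")
    tval = beta / se
    p = float(2.0 * stats.t.sf(abs(tval), fit.residual_df))
    tq = float(stats.t.ppf(0.975, fit.residual_df))
    return InteractionResult(
        rsid1=rsid1, rsid2=rsid2, gene1=gene1, gene2=gene2,
        coding=coding, estimable=True,
        beta_interaction=beta, se=se,
        ci_low=beta - tq * se, ci_high=beta + tq * se,
        p_value=max(p, np.finfo(float).tiny),
        n_used=fit.n_used,
        beta_observed=beta_obs, beta_snp1=beta_1, beta_snp2=beta_2,
        cell_counts=cells,
    )


def enumerate_pairs(rsids: Sequence[str]) -> list[tuple[str, str]]:
    """All k(k-1)/2 unordered marker pairs, each once, in panel order."""
    rsids = list(rsids)
    if len(set(rsids)) != len(rsids):
        raise ValueError("duplicate rsids")
    return list(combinations(rsids, 2))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance cut-off alpha / n_tests at full precision."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return alpha / n_tests


def render_threshold(threshold: float) -> str:
    """Round a cut-off to one significant figure for report text (e.g. 0.0001)."""
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    exp = int(np.floor(np.log10(threshold)))
    rounded = round(threshold, -exp)
    return np.format_float_positional(rounded, trim="-")


@dataclass
class ScanResult:
    """Full pairwise scan: ranked results plus the multiplicity bookkeeping."""

    results: list[InteractionResult]
    threshold: float
    alpha: float
    n_pairs: int
    n_estimable: int
    coding: str

    @property
    def significant(self) -> list[InteractionResult]:
        return [r for r in self.results if r.bonferroni_pass]


def _result_order_key(r: InteractionResult):
    p = r.p_value if r.estimable else np.inf
    b = abs(r.beta_interaction) if r.estimable else 0.0
    return (not r.estimable, p, -b, r.rsid1, r.rsid2)


def scan_all_pairs(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    covariates: CovariateTable | None,
    coding: Coding = "carrier",
    alpha: float = 0.05,
) -> ScanResult:
    """Exhaustive covariate-adjusted interaction scan over all marker pairs.

    Each pair is fitted on its own complete cases (n_used may differ across
    pairs).  Results are ranked by ascending p (ties broken by |beta|
    descending, then rsID pair), with non-estimable pairs flagged and kept at
    the end.  The Bonferroni flag compares each p against alpha divided by
    the number of *enumerated* pairs, mirroring the fixed 0.05/435 convention;
    the count of estimable pairs is reported alongside for the stricter reader.
    """
    gene_of = {m.rsid: m.gene for m in genotypes.markers}
    pairs = enumerate_pairs(genotypes.rsids)
    if not pairs:
        return ScanResult([], alpha, alpha, 0, 0, coding)
    threshold = bonferroni_threshold(alpha, len(pairs))
    results = []
    for r1, r2 in pairs:
        res = interaction_test(
            genotypes.column(r1), genotypes.column(r2), phenotype, covariates,
            coding=coding, rsid1=r1, rsid2=r2,
            gene1=gene_of[r1], gene2=gene_of[r2],
        )
        res.bonferroni_pass = bool(res.estimable and res.p_value < threshold)
        results.append(res)
    results.sort(key=_result_order_key)
    n_est = sum(r.estimable for r in results)
    if n_est < len(pairs):
        logger.info("%d of %d pairs non-estimable", len(pairs) - n_est, len(pairs))
    return ScanResult(
        results=results, threshold=threshold, alpha=alpha,
        n_pairs=len(pairs), n_estimable=n_est, coding=coding,
    )
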