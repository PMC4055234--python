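"""Genotype posteriors, derived population statistics, and likelihood-ratio tests.

The posterior of genotype ``g`` for one sample combines its genotype
likelihood with the estimated population genotype frequencies::

    P(g | data) = L(g) P(g | psi_hat) / sum_g' L(g') P(g' | psi_hat)

with ``P(g | psi_hat)`` the HWE prior, or the freely estimated ``psi_g`` /
``phi_g`` when equilibrium is not assumed.  Two likelihood-ratio tests are
provided: Hardy-Weinberg equilibrium (free genotype frequencies vs the HWE
constraint) and equality of allele frequencies between two samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .em import EMConfig, EMResult, FrequencyModel, run_em
from .errors import DegenerateDataError, UndefinedStatisticError, ValidationError
from .io import CountTable, concat_tables
from .likelihood import GenotypeLikelihoods

__all__ = [
    "TestResult",
    "genotype_posteriors",
    "most_probable_genotype",
    "heterozygosity",
    "inbreeding_coefficient",
    "hwe_test",
    "population_difference_test",
    "hudson_fst",
]


@dataclass(frozen=True)
class TestResult:
    """A likelihood-ratio test: statistic 2 (l1 - l0) ~ chi-square(df)."""

    statistic: float
    df: int
    p_value: float
    loglik_null: float
    loglik_alt: float
    fit_null: EMResult | None = None
    fit_alt: tuple[EMResult, ...] | None = None


def _posterior_rows(loglik: np.ndarray, prior: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logpost = loglik + np.log(prior)
    norm = logsumexp(logpost, axis=1)
    if np.any(~np.isfinite(norm)):
        raise DegenerateDataError("a sample has zero posterior mass under every genotype")
    return np.exp(logpost - norm[:, None])


def genotype_posteriors(
    likelihoods: list[GenotypeLikelihoods] | np.ndarray,
    model: FrequencyModel,
    ploidies: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior genotype probabilities, one row per sample.

    ``likelihoods`` may be a list of :class:`GenotypeLikelihoods` or an
    ``(n, 3)`` log-likelihood matrix (then ``ploidies`` is required).
    Rows of the result sum to 1; hemizygous rows have column 2 equal to 0.
    """
    if isinstance(likelihoods, np.ndarray):
        if ploidies is None:
            raise ValidationError("ploidies required with a log-likelihood matrix")
        ll = likelihoods
        m = np.asarray(ploidies, int)
    else:
        m = np.array([gl.ploidy for gl in likelihoods], dtype=int)
        ll = np.full((len(likelihoods), 3), -np.inf)
        for i, gl in enumerate(likelihoods):
            ll[i, : gl.ploidy + 1] = gl.loglik
    return _posterior_rows(ll, model.prior_matrix(m))


def most_probable_genotype(posterior: np.ndarray) -> int | np.ndarray:
    """Index of the highest-posterior genotype.

    Ties are broken toward the heterozygote (g = 1), then toward lower g,
    so the call is deterministic.  Accepts one posterior vector or a matrix
    of row vectors.
    """
    post = np.atleast_2d(np.asarray(posterior, dtype=float))
    # ranking order g = 1, 0, 2: argmax picks the first maximal entry
    order = np.array([1, 0, 2])[: post.shape[1]]
    calls = order[np.argmax(post[:, order], axis=1)]
    if np.asarray(posterior).ndim == 1:
        return int(calls[0])
    return calls


def heterozygosity(model: FrequencyModel) -> float:
    """Heterozygote frequency psi_1 from a free-genotype-frequency fit."""
    if model.mode != "FREE":
        raise UndefinedStatisticError(
            "direct heterozygosity needs FREE-mode estimates; "
            "under HWE use 2 psi (1 - psi)"
        )
    return float(model.psi_g[1])


def inbreeding_coefficient(psi1: float, psi: float) -> float:
    """F = 1 - psi_1 / (2 psi (1 - psi)).

    Compares the estimated heterozygote frequency with its HWE expectation;
    undefined when the allele frequency is 0 or 1.
    """
    if not (0.0 < psi < 1.0):
        raise UndefinedStatisticError(f"F undefined at psi = {psi}")
    return 1.0 - psi1 / (2.0 * psi * (1.0 - psi))


def hudson_fst(p1: float, n1: float, p2: float, n2: float) -> float:
    """Hudson-type two-population single-locus F_ST estimate.

    ``p1``/``p2`` are allele frequencies, ``n1``/``n2`` the numbers of
    chromosomes sampled.  Numerator: squared frequency difference minus the
    within-population sampling variances; denominator: between-population
    heterozygosity ``p1 (1 - p2) + p2 (1 - p1)``.
    """
    for p, n in ((p1, n1), (p2, n2)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"allele frequency out of [0, 1]: {p}")
        if n < 2:
            raise ValidationError(f"need at least 2 chromosomes per population, got {n}")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        raise UndefinedStatisticError("F_ST undefined: both populations fixed")
    return num / den


def _lrt(l0: float, l1: float, df: int) -> tuple[float, float]:
    stat = 2.0 * (l1 - l0)
    # tiny negatives reflect the finite EM tolerance on nested fits
    if stat < -1e-6:
        raise UndefinedStatisticError(
            f"alternative fit has lower likelihood than the null ({stat=}); "
            "check convergence settings"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


def hwe_test(table: CountTable, config: EMConfig | None = None) -> TestResult:
    """Likelihood-ratio test of Hardy-Weinberg equilibrium.

    Fits the HWE model (null) and the free genotype-frequency model
    (alternative) with identical error/bias handling; df is 1 for an
    all-diploid table, 2 when hemizygous genotype frequencies are also
    estimated.  An all-hemizygous table leaves no extra free parameter and
    is rejected.
    """
    config = config or EMConfig()
    ploidies = table.ploidies
    has_dip = bool(np.any(ploidies == 2))
    has_hemi = bool(np.any(ploidies == 1))
    if not has_dip:
        raise UndefinedStatisticError(
            "HWE test undefined for an all-hemizygous table: the free model "
            "has no extra parameters"
        )
    fit0 = run_em(table, replace(config, mode="HWE"))
    fit1 = run_em(table, replace(config, mode="FREE"))
    df = 2 if has_hemi else 1
    stat, p = _lrt(fit0.loglik, fit1.loglik, df)
    return TestResult(stat, df, p, fit0.loglik, fit1.loglik, fit0, (fit1,))


def population_difference_test(
    table_a: CountTable, table_b: CountTable, config: EMConfig | None = None
) -> TestResult:
    """Likelihood-ratio test of equal allele frequency in two samples.

    Three HWE fits: each sample separately (l1 = la + lb) and the pooled
    table (l0); 2 (l1 - l0) ~ chi-square with 1 df.  Error rates and bias
    are held fixed and shared across the fits — co-estimating them per
    population would change the degrees of freedom, so it is refused.
    """
    config = config or EMConfig()
    if config.mode != "HWE":
        raise ValidationError("population difference test is defined for HWE mode")
    if config.estimate_errors:
        raise ValidationError(
            "co-estimating error rates per population changes the df of the "
            "test; supply fixed eps_ref/eps_alt"
        )
    fit_a = run_em(table_a, config)
    fit_b = run_em(table_b, config)
    fit_0 = run_em(concat_tables(table_a, table_b), config)
    l1 = fit_a.loglik + fit_b.loglik
    stat, p = _lrt(fit_0.loglik, l1, df=1)
    return TestResult(stat, 1, p, fit_0.loglik, l1, fit_0, (fit_a, fit_b))
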