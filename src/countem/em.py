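"""Expectation-maximization estimation of allele and genotype frequencies.

Genotypes are treated as missing data.  The E step turns the current
parameters into per-sample genotype posteriors and sufficient statistics;
the M step re-estimates either the alternative-allele frequency ``psi``
under Hardy-Weinberg equilibrium (HWE mode) or the free genotype
frequencies ``psi_g`` (diploids) and ``phi_g`` (hemizygotes), and
optionally the count-error frequencies ``eps_r`` / ``eps_a``.

With genotype posteriors summarised as

* ``D_g`` / ``H_g`` — expected numbers of diploid / hemizygous individuals
  with genotype ``g``,
* ``R0, R2`` (``A0, A2``) — expected reference (alternative) count mass in
  the alternative- and reference-homozygous/hemizygous classes,
* ``C1r, C1a`` — expected reference / alternative count mass in diploid
  heterozygotes,

the frequency updates are::

    psi'   = (2 D0 + D1 + H0) / (2 (D0 + D1 + D2) + H0 + H1)     (HWE)
    psi_g' = D_g / D,   phi_g' = H_g / H                          (free)

and the error updates maximize the error-dependent part of the expected
complete-data log-likelihood,

    Q_r(x) = R0 log x + C1r log(x + lam (1 - x)) + R2 log(1 - x)
    Q_a(x) = A2 log x + C1a log((1 - x) + lam x) + A0 log(1 - x)

over x in [0, 0.5).  At ``lam = 1`` the middle term is constant and the
maximizers reduce to the closed forms ``R0/(R0+R2)`` and ``A2/(A0+A2)``;
otherwise the stationarity condition is a quadratic, solved analytically.
Estimation halts with a flag if an error update would reach 0.5 (erroneous
counts must be a minority for the model to be identifiable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import (
    DegenerateDataError,
    LowInformationWarning,
    NoDataError,
    ValidationError,
)
from .io import CountTable
from .likelihood import ErrorRates, GenotypeLikelihoods, SamplingBias, loglik_matrix

__all__ = [
    "FrequencyModel",
    "ExpectedCounts",
    "EMConfig",
    "EMResult",
    "e_step",
    "m_step_frequencies",
    "m_step_errors",
    "observed_loglik",
    "run_em",
]

Mode = Literal["HWE", "FREE"]


@dataclass(frozen=True)
class FrequencyModel:
    """Population genotype-frequency model.

    In HWE mode a single alternative-allele frequency ``psi`` determines
    genotype priors ``(psi^2, 2 psi (1-psi), (1-psi)^2)`` over ``g = (0, 1, 2)``
    reference alleles for diploids and ``(psi, 1-psi)`` for hemizygotes.
    In FREE mode the genotype frequencies themselves are the parameters.
    """

    mode: Mode
    psi: float | None = None
    psi_g: np.ndarray | None = None
    phi_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode == "HWE":
            if self.psi is None or not (0.0 <= self.psi <= 1.0):
                raise ValidationError(f"HWE mode needs psi in [0, 1], got {self.psi}")
        elif self.mode == "FREE":
            if self.psi_g is None:
                raise ValidationError("FREE mode needs psi_g")
            psi_g = np.asarray(self.psi_g, dtype=float)
            if psi_g.shape != (3,) or np.any(psi_g < 0) or abs(psi_g.sum() - 1) > 1e-9:
                raise ValidationError("psi_g must be a non-negative 3-vector summing to 1")
            object.__setattr__(self, "psi_g", psi_g)
            if self.phi_g is not None:
                phi_g = np.asarray(self.phi_g, dtype=float)
                if phi_g.shape != (2,) or np.any(phi_g < 0) or abs(phi_g.sum() - 1) > 1e-9:
                    raise ValidationError("phi_g must be a non-negative 2-vector summing to 1")
                object.__setattr__(self, "phi_g", phi_g)
        else:
            raise ValidationError(f"unknown mode {self.mode!r}")

    @classmethod
    def hwe(cls, psi: float) -> "FrequencyModel":
        return cls(mode="HWE", psi=float(psi))

    @classmethod
    def free(cls, psi_g: Sequence[float], phi_g: Sequence[float] | None = None) -> "FrequencyModel":
        return cls(mode="FREE", psi_g=np.asarray(psi_g, float),
                   phi_g=None if phi_g is None else np.asarray(phi_g, float))

    def prior_matrix(self, ploidies: np.ndarray) -> np.ndarray:
        """Genotype prior probabilities, shape (n, 3); column 2 is 0 for hemizygotes."""
        ploidies = np.asarray(ploidies, dtype=int)
        n = ploidies.shape[0]
        out = np.zeros((n, 3), dtype=float)
        dip = ploidies == 2
        if self.mode == "HWE":
            p = self.psi
            out[dip] = (p * p, 2 * p * (1 - p), (1 - p) ** 2)
            out[~dip, 0] = p
            out[~dip, 1] = 1 - p
        else:
            out[dip] = self.psi_g
            if np.any(~dip):
                if self.phi_g is None:
                    raise ValidationError("hemizygous samples present but phi_g is unset")
                out[~dip, 0] = self.phi_g[0]
                out[~dip, 1] = self.phi_g[1]
        return out

    def n_free_parameters(self, has_diploid: bool, has_hemizygous: bool) -> int:
        if self.mode == "HWE":
            return 1
        return (2 if has_diploid else 0) + (1 if has_hemizygous else 0)


@dataclass(frozen=True)
class ExpectedCounts:
    """E-step sufficient statistics (all expectations over genotype posteriors)."""

    D_g: np.ndarray            # expected diploid individuals per genotype, shape (3,)
    H_g: np.ndarray            # expected hemizygous individuals per genotype, shape (2,)
    R0: float                  # reference-count mass in alt-homozygous/hemizygous class
    R2: float                  # reference-count mass in ref-homozygous/hemizygous class
    A0: float                  # alternative-count mass in alt class
    A2: float                  # alternative-count mass in ref class
    C1r: float                 # reference-count mass in diploid heterozygotes
    C1a: float                 # alternative-count mass in diploid heterozygotes

    @property
    def D(self) -> float:
        return float(self.D_g.sum())

    @property
    def H(self) -> float:
        return float(self.H_g.sum())

    @property
    def N(self) -> float:
        return self.D + self.H


@dataclass(frozen=True)
class EMConfig:
    """Settings for one EM run.

    ``lam`` is the heterozygote allele-sampling odds (must be supplied; it is
    never estimated inside the EM, to save degrees of freedom).  ``err`` is
    the starting point (or fixed value, when ``estimate_errors`` is off) of
    the count-error frequencies.
    """

    lam: float = 1.0
    err: ErrorRates = field(default_factory=ErrorRates)
    estimate_errors: bool = False
    mode: Mode = "HWE"
    tol: float = 1e-8
    max_iter: int = 10_000
    psi_init: float = 0.5
    psi_g_init: tuple[float, float, float] = (0.25, 0.5, 0.25)
    phi_g_init: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not (self.tol > 0):
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be at least 1")
        object.__setattr__(self, "lam", float(self.lam))
        SamplingBias(self.lam)  # validate

    @property
    def bias(self) -> SamplingBias:
        return SamplingBias(self.lam)


@dataclass
class EMResult:
    """Converged (or halted) estimates plus per-sample output."""

    model: FrequencyModel
    err: ErrorRates
    loglik: float
    n_iter: int
    converged: bool
    halted_eps: bool
    loglik_trajectory: np.ndarray      # observed-data log-likelihood after each update
    loglik_matrix: np.ndarray          # per-sample genotype log-likelihoods, (n, 3)
    posteriors: np.ndarray             # per-sample genotype posteriors, (n, 3)
    sample_ids: list[str]
    ploidies: np.ndarray

    @property
    def psi(self) -> float | None:
        return self.model.psi

    def sample_likelihoods(self) -> list[GenotypeLikelihoods]:
        return [
            GenotypeLikelihoods(self.loglik_matrix[i, : m + 1].copy(), int(m))
            for i, m in enumerate(self.ploidies)
        ]


# ---------------------------------------------------------------------------
# E step


def _posterior_from(logpost_unnorm: np.ndarray, sample_ids: Sequence[str]) -> np.ndarray:
    rowmax = np.max(logpost_unnorm, axis=1)
    bad = ~np.isfinite(rowmax)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise DegenerateDataError(
            f"sample {sample_ids[i]!r} has zero posterior mass under every genotype"
        )
    w = np.exp(logpost_unnorm - rowmax[:, None])
    return w / w.sum(axis=1, keepdims=True)


def _expected_counts(
    post: np.ndarray, ref: np.ndarray, alt: np.ndarray, ploidies: np.ndarray
) -> ExpectedCounts:
    dip = ploidies == 2
    hemi = ~dip
    D_g = post[dip].sum(axis=0) if np.any(dip) else np.zeros(3)
    H_g = post[hemi, :2].sum(axis=0) if np.any(hemi) else np.zeros(2)
    R0 = float(post[dip, 0] @ ref[dip] + post[hemi, 0] @ ref[hemi])
    R2 = float(post[dip, 2] @ ref[dip] + post[hemi, 1] @ ref[hemi])
    A0 = float(post[dip, 0] @ alt[dip] + post[hemi, 0] @ alt[hemi])
    A2 = float(post[dip, 2] @ alt[dip] + post[hemi, 1] @ alt[hemi])
    C1r = float(post[dip, 1] @ ref[dip])
    C1a = float(post[dip, 1] @ alt[dip])
    return ExpectedCounts(D_g=D_g, H_g=H_g, R0=R0, R2=R2, A0=A0, A2=A2, C1r=C1r, C1a=C1a)


def e_step(
    table: CountTable,
    model: FrequencyModel,
    err: ErrorRates,
    bias: SamplingBias,
) -> tuple[np.ndarray, ExpectedCounts]:
    """Posterior genotype probabilities and E-step sufficient statistics."""
    ref, alt, ploidies = table.ref_counts, table.alt_counts, table.ploidies
    ll = loglik_matrix(ref, alt, ploidies, err, bias)
    with np.errstate(divide="ignore"):
        logprior = np.log(model.prior_matrix(ploidies))
    post = _posterior_from(ll + logprior, table.sample_ids)
    return post, _expected_counts(post, ref, alt, ploidies)


# ---------------------------------------------------------------------------
# M steps


def m_step_frequencies(exp: ExpectedCounts, mode: Mode = "HWE") -> FrequencyModel:
    """Re-estimate the frequency parameters from E-step statistics."""
    D_g, H_g = exp.D_g, exp.H_g
    if mode == "HWE":
        denom = 2.0 * D_g.sum() + H_g.sum()
        if denom == 0:
            raise NoDataError("no individuals to estimate psi from")
        psi = (2.0 * D_g[0] + D_g[1] + H_g[0]) / denom
        return FrequencyModel.hwe(min(max(psi, 0.0), 1.0))
    if exp.D == 0 and exp.H == 0:
        raise NoDataError("no individuals to estimate genotype frequencies from")
    psi_g = D_g / exp.D if exp.D > 0 else np.array([0.25, 0.5, 0.25])
    phi_g = H_g / exp.H if exp.H > 0 else None
    return FrequencyModel.free(psi_g, phi_g)


def _argmax_q(u: float, v: float, w: float, p: float, q: float) -> tuple[float, bool]:
    """Maximize Q(x) = u log x + v log(p + q x) + w log(1 - x) over [0, 0.5).

    Q is concave (each term is the log of an affine function).  Returns the
    maximizer and a flag that is True when the unconstrained maximum lies at
    or beyond 0.5 (the halting condition).  Requires p > 0 and p + q/2 > 0,
    which hold for both error updates at any lam > 0.
    """
    if u < 0 or v < 0 or w < 0:
        raise ValidationError("expected count masses must be non-negative")
    if u == 0.0 and w == 0.0:
        # only the middle (heterozygote) term: monotone in x
        return (0.0, False) if v * q <= 0 else (0.5, True)
    # derivative at the upper boundary; >= 0 means the max is at >= 0.5
    d_half = 2.0 * u + (v * q / (p + 0.5 * q) if v else 0.0) - 2.0 * w
    if d_half >= 0.0:
        return 0.5, True
    if u == 0.0:
        d_zero = (v * q / p if v else 0.0) - w  # w > 0 here, so finite
        if d_zero <= 0.0:
            return 0.0, False
    # stationary point: u(p+qx)(1-x) + v q x(1-x) - w x(p+qx) = 0
    a = -q * (u + v + w)
    b = u * (q - p) + v * q - w * p
    c = u * p
    if a == 0.0:
        x = -c / b
        return float(x), False
    disc = b * b - 4.0 * a * c
    disc = max(disc, 0.0)
    sq = math.sqrt(disc)
    roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    inside = [r for r in roots if 0.0 <= r < 0.5]
    if not inside:  # numerical edge: clamp the roots into range
        inside = [min(max(r, 0.0), 0.5 - 1e-15) for r in roots]
    best = max(inside, key=lambda r: _q_value(r, u, v, w, p, q))
    return float(best), False


def _q_value(x: float, u: float, v: float, w: float, p: float, q: float) -> float:
    def term(coef: float, arg: float) -> float:
        if coef == 0.0:
            return 0.0
        return coef * math.log(arg) if arg > 0 else -math.inf
    return term(u, x) + term(v, p + q * x) + term(w, 1.0 - x)


def m_step_errors(
    exp: ExpectedCounts, bias: SamplingBias, current: ErrorRates | None = None
) -> tuple[ErrorRates, bool]:
    """Re-estimate (eps_ref, eps_alt); the flag reports the >= 0.5 halt.

    When the flag is True the returned rates are not valid estimates and the
    caller should stop and keep its previous values.
    """
    lam = bias.lam
    er, er_halt = _argmax_q(exp.R0, exp.C1r, exp.R2, lam, 1.0 - lam)
    ea, ea_halt = _argmax_q(exp.A2, exp.C1a, exp.A0, 1.0, lam - 1.0)
    if er_halt or ea_halt:
        return (current if current is not None else ErrorRates()), True
    return ErrorRates(eps_ref=er, eps_alt=ea), False


# ---------------------------------------------------------------------------
# Observed-data log-likelihood and the EM driver


def _observed_loglik_arrays(ll: np.ndarray, prior: np.ndarray, sample_ids: Sequence[str]) -> float:
    with np.errstate(divide="ignore"):
        logprior = np.log(prior)
    per_sample = logsumexp(ll + logprior, axis=1)
    if np.any(~np.isfinite(per_sample)):
        i = int(np.argmax(~np.isfinite(per_sample)))
        raise DegenerateDataError(
            f"sample {sample_ids[i]!r} has zero likelihood under every genotype"
        )
    return float(per_sample.sum())


def observed_loglik(
    table: CountTable,
    model: FrequencyModel,
    err: ErrorRates,
    bias: SamplingBias,
) -> float:
    """log-likelihood of the data: sum over samples of log sum_g prior(g) L(g)."""
    ll = loglik_matrix(table.ref_counts, table.alt_counts, table.ploidies, err, bias)
    return _observed_loglik_arrays(ll, model.prior_matrix(table.ploidies), table.sample_ids)


def _initial_model(config: EMConfig, has_hemi: bool) -> FrequencyModel:
    if config.mode == "HWE":
        return FrequencyModel.hwe(config.psi_init)
    return FrequencyModel.free(
        config.psi_g_init, config.phi_g_init if has_hemi else None
    )


def run_em(table: CountTable, config: EMConfig | None = None) -> EMResult:
    """Fit the frequency model (and optionally the error rates) by EM.

    Iterates E and M steps until the observed-data log-likelihood changes by
    less than ``config.tol`` or ``config.max_iter`` is reached.  In HWE mode
    an estimate hitting the boundary (psi exactly 0 or 1) stops iteration,
    since the boundary is absorbing under the updates.
    """
    config = config or EMConfig()
    ref, alt, ploidies = table.ref_counts, table.alt_counts, table.ploidies
    if len(table) == 0 or not np.any(ref + alt > 0):
        raise NoDataError("estimation requires at least one sample with counts")
    if config.estimate_errors and (np.mean(ref + alt) < 4 or len(table) < 100):
        warnings.warn(
            "error-rate co-estimation with mean coverage < 4 or fewer than 100 "
            "samples is unreliable; a priori eps_ref/eps_alt are recommended",
            LowInformationWarning,
            stacklevel=2,
        )
    ids = table.sample_ids
    bias = config.bias
    has_hemi = bool(np.any(ploidies == 1))
    model = _initial_model(config, has_hemi)
    err = config.err

    ll_mat = loglik_matrix(ref, alt, ploidies, err, bias)
    ll_prev = _observed_loglik_arrays(ll_mat, model.prior_matrix(ploidies), ids)
    trajectory = [ll_prev]
    converged = False
    halted = False
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        with np.errstate(divide="ignore"):
            logprior = np.log(model.prior_matrix(ploidies))
        post = _posterior_from(ll_mat + logprior, ids)
        exp = _expected_counts(post, ref, alt, ploidies)

        model = m_step_frequencies(exp, config.mode)
        if config.estimate_errors:
            new_err, halted = m_step_errors(exp, bias, current=err)
            if halted:
                break
            if new_err != err:
                err = new_err
                ll_mat = loglik_matrix(ref, alt, ploidies, err, bias)

        ll = _observed_loglik_arrays(ll_mat, model.prior_matrix(ploidies), ids)
        trajectory.append(ll)
        if abs(ll - ll_prev) < config.tol:
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        if config.mode == "HWE" and model.psi in (0.0, 1.0):
            converged = True  # absorbing boundary
            break

    with np.errstate(divide="ignore"):
        logprior = np.log(model.prior_matrix(ploidies))
    posteriors = _posterior_from(ll_mat + logprior, ids)

    return EMResult(
        model=model,
        err=err,
        loglik=ll_prev,
        n_iter=n_iter,
        converged=converged,
        halted_eps=halted,
        loglik_trajectory=np.asarray(trajectory),
        loglik_matrix=ll_mat,
        posteriors=posteriors,
        sample_ids=ids,
        ploidies=ploidies,
    )
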