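"""Genotype log-likelihoods from allele counts.

A genotype is indexed by its number of reference alleles ``g`` in
``{0, ..., m}`` with ploidy ``m`` in {1, 2}.  Given ``l`` reference-labelled
counts out of ``k`` total, error frequencies ``eps_r`` (among reference
counts) and ``eps_a`` (among alternative counts), and the heterozygote
allele-sampling odds ``lam`` (odds of drawing the reference allele from a
diploid heterozygote), the diploid likelihoods are::

    L(0) = eps_r**l * (1 - eps_a)**(k - l)
    L(1) = (1 / (1 + lam))**k * (eps_r + lam*(1 - eps_r))**l
                              * ((1 - eps_a) + lam*eps_a)**(k - l)
    L(2) = (1 - eps_r)**l * eps_a**(k - l)

Hemizygous genotypes reuse the homozygous forms: L(0) is the alternative
hemizygote, L(1) the reference hemizygote.  All computation is in log space
with the convention 0**0 = 1 (zero counts contribute nothing); a zero base
with a positive exponent yields -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import ValidationError
from .io import CountRecord

__all__ = ["ErrorRates", "SamplingBias", "GenotypeLikelihoods", "genotype_logliks",
           "loglik_matrix"]


@dataclass(frozen=True)
class ErrorRates:
    """Frequencies of erroneous counts among reference / alternative counts.

    Erroneous counts are assumed to be a minority, hence the open upper
    bound at 0.5.  Exact zeros are legal (error-free data).
    """

    eps_ref: float = 0.0
    eps_alt: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("eps_ref", self.eps_ref), ("eps_alt", self.eps_alt)):
            if not (0.0 <= v < 0.5):
                raise ValidationError(f"{name} must lie in [0, 0.5), got {v}")


@dataclass(frozen=True)
class SamplingBias:
    """Odds of sampling the reference allele from a diploid heterozygote.

    ``lam = 1`` is unbiased sampling.  Must be finite and positive; an
    effectively infinite bias is approximated by a large value such as 1e6
    (extreme odds are numerically interchangeable at low coverage).
    """

    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValidationError(f"lam must be a positive finite real, got {self.lam}")


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Log-likelihood vector over genotypes g in {0..m} for one sample."""

    loglik: np.ndarray
    ploidy: int

    def __post_init__(self) -> None:
        if len(self.loglik) != self.ploidy + 1:
            raise ValidationError("loglik length must equal ploidy + 1")
        if not np.any(np.isfinite(self.loglik)):
            raise ValidationError("at least one genotype must have non-zero likelihood")


def loglik_matrix(
    ref: np.ndarray, alt: np.ndarray, ploidy: np.ndarray,
    err: ErrorRates, bias: SamplingBias,
) -> np.ndarray:
    """Vectorized genotype log-likelihoods, shape (n, 3).

    Column ``g`` holds log L(g); for hemizygous rows column 2 is -inf and
    columns 0/1 hold the alternative/reference hemizygote log-likelihoods.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    ploidy = np.asarray(ploidy, dtype=int)
    er, ea, lam = err.eps_ref, err.eps_alt, bias.lam

    k = ref + alt
    # homozygous / hemizygous forms (shared between m=1 and m=2)
    l_alt_homo = xlogy(ref, er) + xlogy(alt, 1.0 - ea)       # g = 0
    l_ref_homo = xlogy(ref, 1.0 - er) + xlogy(alt, ea)       # g = m
    l_het = (
        -k * np.log1p(lam)
        + xlogy(ref, er + lam * (1.0 - er))
        + xlogy(alt, (1.0 - ea) + lam * ea)
    )

    out = np.empty((ref.shape[0], 3), dtype=float)
    dip = ploidy == 2
    out[:, 0] = l_alt_homo
    out[:, 1] = np.where(dip, l_het, l_ref_homo)
    out[:, 2] = np.where(dip, l_ref_homo, -np.inf)
    return out


def genotype_logliks(
    record: CountRecord, err: ErrorRates, bias: SamplingBias
) -> GenotypeLikelihoods:
    """Genotype log-likelihoods for a single sample."""
    row = loglik_matrix(
        np.array([record.ref_count]), np.array([record.alt_count]),
        np.array([record.ploidy]), err, bias,
    )[0]
    return GenotypeLikelihoods(loglik=row[: record.ploidy + 1].copy(), ploidy=record.ploidy)
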