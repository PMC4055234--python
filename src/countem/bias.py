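"""Helpers to obtain the allele-sampling-bias parameter before fitting.

The bias ``lam`` — the odds of observing the reference allele in a single
draw from a diploid heterozygote — must be supplied to the estimator; it is
not co-estimated.  Two ways to get a value are provided: log-log size
regressions fitted on a large panel of real deletions and insertions
(detected with 100 bp single-end reads), and the pooled count ratio of
individuals known to be heterozygous from external evidence.  Rough values
suffice: anywhere within a factor of two of the truth produces only minor
biases in frequency estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

from .errors import ApproximateBiasWarning, InfiniteBiasError, NoDataError, ValidationError
from .io import CountTable

__all__ = ["SvDescriptor", "lambda_from_size", "lambda_from_known_hets"]

SvType = Literal["deletion", "insertion", "inversion"]

# log-log regressions of bias on variant length (natural-log convention);
# adjusted R^2 of 0.37 (deletions) and 0.44 (insertions) on the panel they
# were fitted to, hence rough first approximations only.
_DELETION_INTERCEPT, _DELETION_SLOPE = -4.22, 0.94
_INSERTION_INTERCEPT, _INSERTION_SLOPE = 3.84, -0.87


@dataclass(frozen=True)
class SvDescriptor:
    """A structural variant's type and length in base pairs."""

    sv_type: SvType
    size_bp: int

    def __post_init__(self) -> None:
        if self.sv_type not in ("deletion", "insertion", "inversion"):
            raise ValidationError(f"unknown sv_type {self.sv_type!r}")
        if self.size_bp < 1:
            raise ValidationError(f"size_bp must be >= 1, got {self.size_bp}")


def lambda_from_size(sv: SvDescriptor) -> float:
    """Size-regression bias estimate for a deletion or insertion; 1.0 for inversions.

    Longer deletions favour the reference allele (higher odds), longer
    insertions the alternative.  Emits :class:`ApproximateBiasWarning` for
    the regression-based types: these are rough first approximations and do
    not hold near segmental duplications or other repeats.
    """
    if sv.sv_type == "inversion":
        return 1.0
    if sv.sv_type == "deletion":
        lam = math.exp(_DELETION_INTERCEPT + _DELETION_SLOPE * math.log(sv.size_bp))
    else:
        lam = math.exp(_INSERTION_INTERCEPT + _INSERTION_SLOPE * math.log(sv.size_bp))
    warnings.warn(
        f"size-regression bias for a {sv.size_bp} bp {sv.sv_type} is a rough "
        "first approximation; prefer an estimate from known heterozygotes or "
        "read remapping when available",
        ApproximateBiasWarning,
        stacklevel=2,
    )
    return lam


def lambda_from_known_hets(subset: CountTable) -> float:
    """Pooled reference/alternative count ratio over known heterozygotes.

    ``subset`` must contain only individuals known (e.g. by PCR or high
    coverage) to be heterozygous; the ratio of their pooled counts estimates
    the sampling odds directly.
    """
    if len(subset) == 0:
        raise NoDataError("no known-heterozygote samples supplied")
    ref = float(subset.ref_counts.sum())
    alt = float(subset.alt_counts.sum())
    if alt == 0.0:
        raise InfiniteBiasError(
            "pooled alternative count is zero: the bias is effectively "
            "infinite; substitute a large finite value such as 1e6"
        )
    return ref / alt
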