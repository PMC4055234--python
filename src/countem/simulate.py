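"""Synthetic count tables with known ground truth.

The generator reproduces the study conditions every estimator and test in
this package is validated under: genotypes drawn from Hardy-Weinberg
equilibrium at a chosen alternative-allele frequency (or from explicit
genotype frequencies), per-individual total counts Poisson-distributed to
mimic variable sequencing coverage, biased allele sampling from diploid
heterozygotes with odds ``lam``, and a symmetric per-count label-flip error
(default 0.005).  Under symmetric flips the likelihood model with
``eps_ref = eps_alt = flip_error`` is exactly the per-count sampling law.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import CountTable, write_count_table

__all__ = ["SimConfig", "TruthTable", "simulate_counts", "simulate_two_populations"]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one simulated sample of individuals.

    ``genotype_freqs``, when given, overrides HWE: a pair ``(psi_g, phi_g)``
    of diploid and hemizygous genotype-frequency vectors (indexed by the
    number of reference alleles).  ``ploidy`` is a single value or a
    per-individual sequence over {1, 2}.
    """

    n: int = 100
    psi: float = 0.5
    genotype_freqs: tuple[Sequence[float], Sequence[float]] | None = None
    lam: float = 1.0
    flip_error: float = 0.005
    mean_coverage: float = 4.0
    ploidy: int | Sequence[int] = 2
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not (0.0 <= self.psi <= 1.0):
            raise ValidationError("psi must lie in [0, 1]")
        if not (0.0 <= self.flip_error < 0.5):
            raise ValidationError("flip_error must lie in [0, 0.5)")
        if not (self.mean_coverage > 0):
            raise ValidationError("mean_coverage must be positive")
        if not (self.lam > 0):
            raise ValidationError("lam must be positive")

    def ploidies(self) -> np.ndarray:
        if isinstance(self.ploidy, (int, np.integer)):
            arr = np.full(self.n, int(self.ploidy))
        else:
            arr = np.asarray(self.ploidy, dtype=int)
            if arr.shape != (self.n,):
                raise ValidationError("per-individual ploidy must have length n")
        if not np.all((arr == 1) | (arr == 2)):
            raise ValidationError("ploidy values must be 1 or 2")
        return arr


@dataclass
class TruthTable:
    """A generated count table together with the true genotypes behind it."""

    genotypes: np.ndarray          # true number of reference alleles per individual
    table: CountTable
    config: SimConfig

    def write(self, counts_path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write the counts in the standard table format, and optionally a
        truth TSV (sample_id, true_g, ploidy)."""
        write_count_table(self.table, counts_path)
        if truth_path is not None:
            with open(truth_path, "wt", encoding="utf-8") as fh:
                fh.write("#sample_id\ttrue_g\tploidy\n")
                for rec, g in zip(self.table, self.genotypes):
                    fh.write(f"{rec.sample_id}\t{int(g)}\t{rec.ploidy}\n")


def _draw_genotypes(
    config: SimConfig, ploidies: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    dip = ploidies == 2
    g = np.empty(config.n, dtype=int)
    if config.genotype_freqs is not None:
        psi_g = np.asarray(config.genotype_freqs[0], dtype=float)
        phi_g = np.asarray(config.genotype_freqs[1], dtype=float)
        for freqs, name in ((psi_g, "psi_g"), (phi_g, "phi_g")):
            if np.any(freqs < 0) or abs(freqs.sum() - 1) > 1e-9:
                raise ValidationError(f"{name} must be non-negative and sum to 1")
        if psi_g.shape != (3,) or phi_g.shape != (2,):
            raise ValidationError("genotype_freqs must be ((3,), (2,)) vectors")
        g[dip] = rng.choice(3, size=int(dip.sum()), p=psi_g)
        g[~dip] = rng.choice(2, size=int((~dip).sum()), p=phi_g)
    else:
        # HWE: the number of reference alleles is Binomial(m, 1 - psi)
        g[dip] = rng.binomial(2, 1.0 - config.psi, size=int(dip.sum()))
        g[~dip] = rng.binomial(1, 1.0 - config.psi, size=int((~dip).sum()))
    return g


def simulate_counts(config: SimConfig) -> TruthTable:
    """Generate one count table under the configured ground truth.

    Per individual: a genotype (given its ploidy), a Poisson total count,
    true alleles drawn per count (reference with probability 1, 0, or
    ``lam / (1 + lam)`` for a diploid heterozygote), and an independent
    label flip per count with probability ``flip_error``.  Fully
    reproducible from ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    ploidies = config.ploidies()
    g = _draw_genotypes(config, ploidies, rng)
    k = rng.poisson(config.mean_coverage, size=config.n)

    # probability that one count is truly the reference allele
    p_ref = np.where(g == ploidies, 1.0, 0.0)
    het = (ploidies == 2) & (g == 1)
    p_ref[het] = config.lam / (1.0 + config.lam)
    true_ref = rng.binomial(k, p_ref)
    true_alt = k - true_ref

    e = config.flip_error
    ref_labelled = (
        true_ref - rng.binomial(true_ref, e) + rng.binomial(true_alt, e)
        if e > 0
        else true_ref
    )
    alt_labelled = k - ref_labelled

    width = len(str(config.n))
    ids = [f"sim{str(i).zfill(width)}" for i in range(1, config.n + 1)]
    table = CountTable.from_arrays(ids, ref_labelled, alt_labelled, ploidies)
    return TruthTable(genotypes=g, table=table, config=config)


def simulate_two_populations(
    config_a: SimConfig, config_b: SimConfig
) -> tuple[TruthTable, TruthTable]:
    """Two independent tables from independent RNG streams of the two seeds."""
    return simulate_counts(config_a), simulate_counts(config_b)
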