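"""Synthetic-herd generator.

Generates genotype/phenotype tables with the statistical structure the
downstream analyses assume: Hardy–Weinberg genotype proportions at each
locus, a two-locus haplotype distribution with a configurable normalized
disequilibrium D', and per-genotype trait values drawn from
Normal(mean, SE * sqrt(n)) — the population standard deviation implied by a
reported standard error and group size.

Genotypes are coded with the field's gel-reading vocabulary: ``II``
(homozygous insertion), ``ID`` (heterozygous), ``DD`` (homozygous deletion).
Each locus designates which physical allele (I or D) is the rare mutant; the
mutant-allele frequency is the locus' only frequency parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female", "missing")
GENOTYPES = ("II", "ID", "DD")


class InfeasibleHaplotypesError(ValueError):
    """Requested D' and allele frequencies imply a negative haplotype frequency."""


@dataclass(frozen=True)
class LocusSpec:
    """A biallelic InDel locus.

    Parameters
    ----------
    name : str
        Locus label, e.g. ``"P1-Ins-4-bp"``.
    mutant_allele : str
        Which physical allele ("I" or "D") is the rare mutant.
    mutant_freq : float
        Population frequency of the mutant allele, in [0, 1].
    """

    name: str
    mutant_allele: str
    mutant_freq: float

    def __post_init__(self) -> None:
        if self.mutant_allele not in ("I", "D"):
            raise ValueError(f"mutant_allele must be 'I' or 'D', got {self.mutant_allele!r}")
        if not 0.0 <= self.mutant_freq <= 1.0:
            raise ValueError(f"mutant_freq must be in [0, 1], got {self.mutant_freq}")

    def genotype(self, n_mutant: int) -> str:
        """Genotype string for an individual carrying ``n_mutant`` mutant alleles."""
        if self.mutant_allele == "I":
            return ("DD", "ID", "II")[n_mutant]
        return ("II", "ID", "DD")[n_mutant]

    @property
    def reference_homozygote(self) -> str:
        return self.genotype(0)

    @property
    def carrier_frequency(self) -> float:
        """Probability an individual carries at least one mutant allele under HWE."""
        return 1.0 - (1.0 - self.mutant_freq) ** 2


@dataclass(frozen=True)
class TraitSpec:
    """Per-genotype moments for one simulated carcass trait.

    ``genotype_params`` maps genotype label -> (mean, se, n); values are drawn
    Normal(mean, se * sqrt(n)), i.e. the group SD recovered from a reported
    standard error. Individuals whose genotype has no entry, or whose sex does
    not match ``sex_restriction``, receive no value.
    """

    name: str
    locus: str
    genotype_params: Mapping[str, tuple]  # genotype -> (mean_kg, se_kg, n)
    sex_restriction: Optional[str] = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for geno, (mean, se, n) in self.genotype_params.items():
            if geno not in GENOTYPES:
                raise ValueError(f"unknown genotype label {geno!r} in trait {self.name!r}")
            if se < 0:
                raise ValueError(f"SE must be >= 0 (trait {self.name!r}, genotype {geno})")
            if n < 2:
                raise ValueError(f"per-genotype n must be >= 2 (trait {self.name!r}, genotype {geno})")
        if self.sex_restriction is not None and self.sex_restriction not in SEXES:
            raise ValueError(f"sex_restriction must be one of {SEXES}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")

    def sd(self, genotype: str) -> float:
        mean, se, n = self.genotype_params[genotype]
        return se * np.sqrt(n)


@dataclass
class HerdConfig:
    """Configuration of a synthetic herd.

    ``d_prime`` sets the normalized two-locus disequilibrium between the two
    mutant alleles (only meaningful with exactly two loci). ``coupling``
    chooses the phase: ``"mutant"`` puts positive D between the two mutant
    alleles, ``"repulsion"`` the opposite sign.
    """

    n_individuals: int
    sex_counts: Mapping[str, int]
    loci: Sequence[LocusSpec]
    d_prime: float = 0.0
    coupling: str = "mutant"
    trait_specs: Sequence[TraitSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        unknown = set(self.sex_counts) - set(SEXES)
        if unknown:
            raise ValueError(f"unknown sex labels: {sorted(unknown)}")
        if sum(self.sex_counts.values()) != self.n_individuals:
            raise ValueError(
                f"sex counts sum to {sum(self.sex_counts.values())}, expected {self.n_individuals}"
            )
        if not 0.0 <= self.d_prime <= 1.0:
            raise ValueError("d_prime must be in [0, 1]")
        if self.coupling not in ("mutant", "repulsion"):
            raise ValueError("coupling must be 'mutant' or 'repulsion'")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        for spec in self.trait_specs:
            if spec.locus not in names:
                raise ValueError(f"trait {spec.name!r} references unknown locus {spec.locus!r}")


def haplotype_frequencies(p_a: float, p_b: float, d_prime: float, coupling: str = "mutant") -> np.ndarray:
    """Two-locus haplotype frequencies [f11, f10, f01, f00] over mutant-allele states.

    Index 1 = carries the mutant allele at that locus. D = D' * Dmax with
    Dmax the tightest of the two bounding products for the chosen sign;
    raises :class:`InfeasibleHaplotypesError` if any frequency would be
    negative.
    """
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if coupling == "mutant":
        d = d_prime * min(p_a * q_b, q_a * p_b)
    else:
        d = -d_prime * min(p_a * p_b, q_a * q_b)
    freqs = np.array(
        [p_a * p_b + d, p_a * q_b - d, q_a * p_b - d, q_a * q_b + d], dtype=float
    )
    if np.any(freqs < -1e-12):
        raise InfeasibleHaplotypesError(
            f"D'={d_prime} with mutant frequencies ({p_a}, {p_b}) and coupling "
            f"{coupling!r} gives a negative haplotype frequency: {freqs.tolist()}"
        )
    freqs = np.clip(freqs, 0.0, None)
    return freqs / freqs.sum()


def simulate_haplotypes(config: HerdConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw two haplotypes per individual; shape (n, 2, n_loci), 1 = mutant allele.

    With two loci the haplotypes come from the D'-coupled joint distribution;
    with one locus they are Bernoulli draws at the mutant frequency.
    """
    n = config.n_individuals
    loci = config.loci
    if len(loci) == 2:
        freqs = haplotype_frequencies(
            loci[0].mutant_freq, loci[1].mutant_freq, config.d_prime, config.coupling
        )
        states = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
        draws = rng.choice(4, size=(n, 2), p=freqs)
        return states[draws]
    haps = np.empty((n, 2, len(loci)), dtype=np.int8)
    for k, locus in enumerate(loci):
        haps[:, :, k] = rng.random((n, 2)) < locus.mutant_freq
    return haps


def simulate_genotypes(config: HerdConfig) -> pd.DataFrame:
    """Simulate a genotyped herd.

    Returns a table with one row per individual: ``id``, ``sex`` and one
    genotype column (II/ID/DD strings) per locus. Genotypes are the unordered
    pair of haplotypes, so each locus is in Hardy–Weinberg proportions and
    the two-locus structure carries the configured D'. Reproducible for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    haps = simulate_haplotypes(config, rng)
    n = config.n_individuals

    sexes = np.concatenate(
        [np.repeat(sex, config.sex_counts.get(sex, 0)) for sex in SEXES]
    )
    rng.shuffle(sexes)

    table = {"id": [f"ind{i + 1:04d}" for i in range(n)], "sex": sexes}
    for k, locus in enumerate(config.loci):
        n_mut = haps[:, :, k].sum(axis=1)
        table[locus.name] = [locus.genotype(m) for m in n_mut]
    pop = pd.DataFrame(table)
    if config.trait_specs:
        pop = simulate_traits(pop, config.trait_specs, seed=int(rng.integers(2**31)))
    return pop


def simulate_traits(
    pop: pd.DataFrame, specs: Sequence[TraitSpec], seed: int = 0
) -> pd.DataFrame:
    """Add one trait column per spec to a genotyped herd table.

    Values are Normal(mean_genotype, SE * sqrt(n_genotype)), truncated at
    0 kg by resampling (carcass weights cannot be negative). Individuals of
    the wrong sex, with a genotype the spec does not parameterize, or sampled
    missing at ``missing_rate`` get an empty value.
    """
    rng = np.random.default_rng(seed)
    out = pop.copy()
    for spec in specs:
        if spec.locus not in out.columns:
            raise ValueError(f"trait {spec.name!r} references unknown locus {spec.locus!r}")
        genos = out[spec.locus]
        unknown = set(genos.dropna()) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotype labels in column {spec.locus!r}: {sorted(unknown)}")
        values = np.full(len(out), np.nan)
        for geno, (mean, se, n) in spec.genotype_params.items():
            mask = (genos == geno).to_numpy()
            if spec.sex_restriction is not None:
                mask &= (out["sex"] == spec.sex_restriction).to_numpy()
            k = int(mask.sum())
            if k == 0:
                continue
            sd = se * np.sqrt(n)
            draw = rng.normal(mean, sd, size=k)
            # carcass weights are non-negative; resample the rare negative draws
            bad = draw < 0
            while bad.any():
                draw[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = draw < 0
            values[mask] = draw
        if spec.missing_rate > 0:
            values[rng.random(len(out)) < spec.missing_rate] = np.nan
        out[spec.name] = values
    return out
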