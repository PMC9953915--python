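"""Population-genetic characterization of biallelic InDel loci.

Single-locus summaries (allele frequencies by gene counting, expected
heterozygosity He, gene homozygosity Ho, effective allele number Ne,
polymorphism information content PIC, Hardy–Weinberg chi-square) and
two-locus linkage disequilibrium from unphased genotypes via the standard
EM over the double-heterozygote phase ambiguity, reported as D, D' and r^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("II", "ID", "DD")


class MonomorphicLocusError(ValueError):
    """LD is undefined when one locus carries a single allele."""


@dataclass(frozen=True)
class LocusStats:
    """Single-locus summary statistics.

    ``Ho`` is gene homozygosity sum(p_i^2) (not observed homozygote fraction),
    ``He = 1 - Ho``, ``Ne = 1/Ho``, and PIC is Botstein's measure, which for
    two alleles reduces to ``He - 2 p^2 q^2``.
    """

    n: int
    genotype_freqs: Mapping[str, float]
    allele_freqs: Mapping[str, float]
    ho: float
    he: float
    ne: float
    pic: float
    hwe_chi2: float
    hwe_p: float


@dataclass(frozen=True)
class TwoLocusLD:
    """Two-locus haplotype frequencies and LD coefficients.

    Haplotype keys are two-character strings, first locus allele then second
    (e.g. ``"ID"`` = allele I at locus A on the same gamete as allele D at
    locus B). D is measured between allele I at A and allele I at B.
    """

    haplotype_freqs: Mapping[str, float]
    d: float
    d_prime: float
    r2: float
    em_iterations: int
    em_loglik: float
    loglik_history: Tuple[float, ...] = ()


def locus_stats(genotype_counts: Mapping[str, int]) -> LocusStats:
    """Summary statistics from II/ID/DD genotype counts.

    Allele frequencies by gene counting: p_I = (2 n_II + n_ID) / 2n. The HWE
    test is a Pearson chi-square of observed genotype counts against
    (p^2, 2pq, q^2) expectations with 1 df, no continuity correction;
    a monomorphic locus returns chi2 = 0, p = 1.
    """
    counts = {g: int(genotype_counts.get(g, 0)) for g in GENOTYPES}
    if any(c < 0 for c in counts.values()):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("need at least one genotyped individual")
    p = (2 * counts["II"] + counts["ID"]) / (2 * n)
    q = 1.0 - p
    ho = p * p + q * q
    he = 1.0 - ho
    ne = 1.0 / ho
    pic = 1.0 - p * p - q * q - 2.0 * p * p * q * q

    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([counts["II"], counts["ID"], counts["DD"]], dtype=float)
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    hwe_p = 1.0 if p in (0.0, 1.0) else float(stats.chi2.sf(chi2, df=1))
    return LocusStats(
        n=n,
        genotype_freqs={g: counts[g] / n for g in GENOTYPES},
        allele_freqs={"I": p, "D": q},
        ho=ho,
        he=he,
        ne=ne,
        pic=pic,
        hwe_chi2=chi2,
        hwe_p=hwe_p,
    )


def hwe_exact_p(genotype_counts: Mapping[str, int]) -> float:
    """Exact two-sided HWE p-value (Levene/Haldane conditional distribution).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more probable than the observed one.
    """
    n_het = int(genotype_counts.get("ID", 0))
    n_ii = int(genotype_counts.get("II", 0))
    n_dd = int(genotype_counts.get("DD", 0))
    n = n_het + n_ii + n_dd
    n_rare = 2 * min(n_ii, n_dd) + n_het
    if n == 0:
        raise ValueError("need at least one genotyped individual")

    def log_prob(h: int) -> float:
        # P(h hets | n, n_rare) on the log scale; h must share parity with n_rare
        n_aa = (n_rare - h) // 2
        n_bb = n - h - n_aa
        return (
            math.lgamma(n + 1)
            - math.lgamma(n_aa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_bb + 1)
            + h * math.log(2.0)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def two_locus_counts(
    pop: pd.DataFrame, locus_a: str, locus_b: str
) -> np.ndarray:
    """3x3 genotype count table: cell [i, j] = individuals with i copies of
    allele I at ``locus_a`` and j copies at ``locus_b`` (complete cases only)."""
    i_count = {"DD": 0, "ID": 1, "II": 2}
    sub = pop[[locus_a, locus_b]].dropna()
    table = np.zeros((3, 3), dtype=int)
    for a, b in zip(sub[locus_a], sub[locus_b]):
        table[i_count[a], i_count[b]] += 1
    return table


def em_haplotypes(
    two_locus_genotype_counts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> TwoLocusLD:
    """EM estimate of two-locus haplotype frequencies from unphased genotypes.

    Input is the 3x3 table of :func:`two_locus_counts`. All cells except the
    double heterozygote [1, 1] determine their haplotypes; the EM splits the
    double heterozygotes between the cis (II/II + DD/DD gametes) and trans
    phases in proportion to the current haplotype frequencies, starting from
    linkage equilibrium, until the log-likelihood changes by less than
    ``tol`` (or ``max_iter`` iterations).

    D is the frequency of the I–I haplotype minus the product of the I
    marginals; D' = |D| / Dmax with Dmax the tightest admissible bound for
    the sign of D; r^2 = D^2 / (pA qA pB qB). Raises
    :class:`MonomorphicLocusError` when either locus is monomorphic.
    """
    c = np.asarray(two_locus_genotype_counts, dtype=float)
    if c.shape != (3, 3) or (c < 0).any():
        raise ValueError("expected a 3x3 table of non-negative counts")
    n = c.sum()
    if n < 1:
        raise ValueError("need at least one individual")

    # marginal allele-I frequencies by gene counting
    a_dose = c.sum(axis=1)  # index = copies of I at locus A
    b_dose = c.sum(axis=0)
    p_a = (2 * a_dose[2] + a_dose[1]) / (2 * n)
    p_b = (2 * b_dose[2] + b_dose[1]) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicLocusError(
            "a monomorphic locus leaves D' and r^2 undefined "
            f"(allele-I frequencies: {p_a:.4g}, {p_b:.4g})"
        )

    # fixed haplotype contributions from unambiguous cells; order: II, ID, DI, DD
    # (first char = allele at locus A on the gamete, I if dose contributes)
    fixed = np.zeros(4)

    def hap_index(a_allele: int, b_allele: int) -> int:
        return (1 - a_allele) * 2 + (1 - b_allele)  # II=0, ID=1, DI=2, DD=3

    for i in range(3):
        for j in range(3):
            if c[i, j] == 0 or (i == 1 and j == 1):
                continue
            # genotype (i, j) -> two gametes with known alleles
            a_alleles = [1, 1] if i == 2 else ([0, 0] if i == 0 else [1, 0])
            b_alleles = [1, 1] if j == 2 else ([0, 0] if j == 0 else [1, 0])
            if i == 1:
                # A is het, B homozygous: gametes (I, b) and (D, b)
                pairs = [(1, b_alleles[0]), (0, b_alleles[1])]
            elif j == 1:
                pairs = [(a_alleles[0], 1), (a_alleles[1], 0)]
            else:
                pairs = list(zip(a_alleles, b_alleles))
            for a_al, b_al in pairs:
                fixed[hap_index(a_al, b_al)] += c[i, j]

    n_dh = c[1, 1]
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    h = np.array([p_a * p_b, p_a * q_b, q_a * p_b, q_a * q_b])  # LE start

    def loglik(h: np.ndarray) -> float:
        ll = 0.0
        hl = np.log(np.clip(h, 1e-300, None))
        for i in range(3):
            for j in range(3):
                if c[i, j] == 0:
                    continue
                if i == 1 and j == 1:
                    prob = 2 * h[0] * h[3] + 2 * h[1] * h[2]
                    ll += c[i, j] * math.log(max(prob, 1e-300))
                else:
                    a_alleles = [1, 1] if i == 2 else ([0, 0] if i == 0 else [1, 0])
                    b_alleles = [1, 1] if j == 2 else ([0, 0] if j == 0 else [1, 0])
                    if i == 1:
                        pairs = [(1, b_alleles[0]), (0, b_alleles[1])]
                    elif j == 1:
                        pairs = [(a_alleles[0], 1), (a_alleles[1], 0)]
                    else:
                        pairs = list(zip(a_alleles, b_alleles))
                    idx = [hap_index(a, b) for a, b in pairs]
                    term = hl[idx[0]] + hl[idx[1]]
                    if idx[0] != idx[1]:
                        term += math.log(2.0)
                    ll += c[i, j] * term
        return ll

    history = [loglik(h)]
    iters = 0
    for iters in range(1, max_iter + 1):
        # E-step: split double heterozygotes between cis (II+DD) and trans (ID+DI)
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        frac_cis = 0.5 if cis + trans == 0 else cis / (cis + trans)
        counts = fixed.copy()
        counts[0] += n_dh * frac_cis
        counts[3] += n_dh * frac_cis
        counts[1] += n_dh * (1 - frac_cis)
        counts[2] += n_dh * (1 - frac_cis)
        h = counts / counts.sum()
        history.append(loglik(h))
        if abs(history[-1] - history[-2]) < tol:
            break

    d = h[0] - p_a * p_b
    if d >= 0:
        dmax = min(p_a * q_b, q_a * p_b)
    else:
        dmax = min(p_a * p_b, q_a * q_b)
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return TwoLocusLD(
        haplotype_freqs={"II": h[0], "ID": h[1], "DI": h[2], "DD": h[3]},
        d=float(d),
        d_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        em_iterations=iters,
        em_loglik=float(history[-1]),
        loglik_history=tuple(history),
    )


def locus_table(pop: pd.DataFrame, loci: Sequence[str]) -> pd.DataFrame:
    """One summary row per locus from a genotyped herd table (shaped like a
    population-parameters report: N, genotype and allele frequencies, HWE p,
    Ho, He, Ne, PIC)."""
    rows = []
    for locus in loci:
        counts = pop[locus].dropna().value_counts().to_dict()
        st = locus_stats(counts)
        rows.append(
            {
                "locus": locus,
                "n": st.n,
                "freq_II": st.genotype_freqs["II"],
                "freq_ID": st.genotype_freqs["ID"],
                "freq_DD": st.genotype_freqs["DD"],
                "freq_I": st.allele_freqs["I"],
                "freq_D": st.allele_freqs["D"],
                "hwe_chi2": st.hwe_chi2,
                "hwe_p": st.hwe_p,
                "Ho": st.ho,
                "He": st.he,
                "Ne": st.ne,
                "PIC": st.pic,
            }
        )
    return pd.DataFrame(rows)
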