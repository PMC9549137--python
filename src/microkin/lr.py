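"""Kinship likelihood ratios: PI, FSI, HSI and FHSI.

Every index compares two hypotheses about a genotype pair. With IBD
coefficients k = (k0, k1, k2) for the claimed relationship, the conditional
probability of the second genotype given the first decomposes as

    P(g2 | g1, k) = k0 * P(g2) + k1 * P1(g2 | g1) + k2 * [g2 == g1]

where P(g2) is the Hardy-Weinberg genotype probability (2pq for
heterozygotes) and P1 is the one-allele-IBD kernel: a uniformly chosen allele
of g1 is shared, the other allele of g2 is a population draw. The indices are

* PI   = P(pair | parent-child) / P(pair | unrelated)
* FSI  = P(pair | full-sibling) / P(pair | unrelated)
* HSI  = P(pair | half-sibling) / P(pair | unrelated)
* FHSI = P(pair | full-sibling) / P(pair | half-sibling)

so in log10, FHSI = FSI - HSI identically. The parent-child numerator uses
mutation-adjusted transmission, T(a -> b) = 1 - mu if b == a else
mu * m(a, b) with m the mutation model's target law, so a Mendelian
inconsistency yields a large negative (not infinite) log LR whenever mu > 0.
Sibling-class indices use the pure IBD mixture: at microhaplotype mutation
rates (1e-8) the adjustment is numerically invisible there, and pairwise
k-coefficient likelihoods have no single-meiosis factorisation to hang it on.

Panel log10 LRs are sums over loci (linkage equilibrium assumed); -inf from
a true exclusion under mu = 0 is retained and propagates.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .popgen import AlleleFrequencySet
from .sim import GenotypePair, MutationModel, NO_MUTATION, get_relationship, n_genotypes

__all__ = [
    "INDEX_HYPOTHESES",
    "conditional_genotype_prob",
    "transmission_prob",
    "lr_index",
    "panel_log10_lr",
    "lr_matrix",
    "genotype_prob",
]

# index -> (Hp relationship, Hd relationship)
INDEX_HYPOTHESES: dict[str, tuple[str, str]] = {
    "PI": ("parent_child", "unrelated"),
    "FSI": ("full_sibling", "unrelated"),
    "HSI": ("half_sibling", "unrelated"),
    "FHSI": ("full_sibling", "half_sibling"),
}


def _check_alleles(g: tuple[str, str], freqs: AlleleFrequencySet) -> None:
    for a in g:
        if a not in freqs.freqs:
            raise KeyError(f"allele {a!r} absent from frequency set for {freqs.locus_name}")


def genotype_prob(g: tuple[str, str], freqs: AlleleFrequencySet) -> float:
    """Hardy-Weinberg probability of an unordered genotype (2pq convention)."""
    _check_alleles(g, freqs)
    a, b = g
    return freqs[a] * freqs[b] * (1.0 if a == b else 2.0)


def _one_ibd_kernel(g2: tuple[str, str], g1: tuple[str, str], freqs: AlleleFrequencySet) -> float:
    """P(g2 | exactly one allele of g2 is IBD with a uniform allele of g1)."""
    c, d = g2
    total = 0.0
    for s in g1:  # shared allele, each parental slot with probability 1/2
        if c == d:
            p = freqs[c] if s == c else 0.0
        elif s == c:
            p = freqs[d]
        elif s == d:
            p = freqs[c]
        else:
            p = 0.0
        total += 0.5 * p
    return total


def conditional_genotype_prob(
    g2: tuple[str, str],
    g1: tuple[str, str],
    k: tuple[float, float, float] | str,
    freqs: AlleleFrequencySet,
) -> float:
    """P(g2 | g1, k): the IBD mixture over 0/1/2 shared alleles.

    ``k`` may be an IBD triple or a relationship label. Sums to 1 over all g2.
    """
    if isinstance(k, str):
        k = get_relationship(k).k
    _check_alleles(g1, freqs)
    _check_alleles(g2, freqs)
    k0, k1, k2 = k
    ident = 1.0 if tuple(sorted(g1)) == tuple(sorted(g2)) else 0.0
    return k0 * genotype_prob(g2, freqs) + k1 * _one_ibd_kernel(g2, g1, freqs) + k2 * ident


def _mutation_target_prob(a: str, b: str, freqs: AlleleFrequencySet, mutation: MutationModel) -> float:
    """m(a, b): probability that allele a mutates to b, given a mutation occurs."""
    alleles = freqs.alleles
    if mutation.kind == "equal_probability":
        A = len(alleles)
        if A < 2:
            raise ValueError("equal-probability mutation needs >= 2 alleles")
        return 1.0 / (A - 1)
    if mutation.kind == "extended_stepwise":
        ladder = list(alleles)  # canonical order is numeric for repeat alleles
        i, j = ladder.index(a), ladder.index(b)
        if i == j:
            return 0.0
        # geometric step, +/- uniform, reflected off the ladder ends; the
        # target law is computed by summing the geometric mass that folds
        # onto j (truncated at negligible tail mass)
        p = mutation.step_geometric_p
        top = len(ladder) - 1
        total = 0.0
        s = 1
        while True:
            mass = p * (1.0 - p) ** (s - 1)
            if mass < 1e-15 and s > 2 * (top + 1):
                break
            for direction in (1, -1):
                t = i + direction * s
                while not (0 <= t <= top):
                    t = -t if t < 0 else 2 * top - t
                if t == j:
                    total += 0.5 * mass
            s += 1
        return total
    raise ValueError("mutation model 'none' has no target law")


def transmission_prob(
    g_child: tuple[str, str],
    g_parent: tuple[str, str],
    freqs: AlleleFrequencySet,
    mutation: MutationModel = NO_MUTATION,
) -> float:
    """P(child genotype | parent genotype): one (possibly mutated)
    transmitted allele plus one population allele."""
    _check_alleles(g_child, freqs)
    _check_alleles(g_parent, freqs)
    mu = mutation.rate

    def T(t: str, b: str) -> float:
        if mu == 0.0:
            return 1.0 if t == b else 0.0
        same = 1.0 - mu
        return same if t == b else mu * _mutation_target_prob(t, b, freqs, mutation)

    c, d = g_child
    total = 0.0
    for t in g_parent:  # transmitted parental allele, probability 1/2 each
        if c == d:
            total += 0.5 * T(t, c) * freqs[c]
        else:
            total += 0.5 * (T(t, c) * freqs[d] + T(t, d) * freqs[c])
    return total


def lr_index(
    g1: tuple[str, str],
    g2: tuple[str, str],
    index_name: str,
    freqs: AlleleFrequencySet,
    mutation: MutationModel = NO_MUTATION,
) -> float:
    """Single-locus log10 likelihood ratio for one index.

    ``g1`` is the first pair member (the alleged parent for PI). Returns
    -inf for a Mendelian exclusion under PI with mu = 0.
    """
    if index_name not in INDEX_HYPOTHESES:
        raise ValueError(f"unknown index {index_name!r}; choose from {sorted(INDEX_HYPOTHESES)}")
    g1 = tuple(sorted(g1))
    g2 = tuple(sorted(g2))
    if index_name == "PI":
        num = transmission_prob(g2, g1, freqs, mutation)
        den = genotype_prob(g2, freqs)
    elif index_name == "FHSI":
        num = conditional_genotype_prob(g2, g1, "full_sibling", freqs)
        den = conditional_genotype_prob(g2, g1, "half_sibling", freqs)
    else:
        hp, _ = INDEX_HYPOTHESES[index_name]
        num = conditional_genotype_prob(g2, g1, hp, freqs)
        den = genotype_prob(g2, freqs)
    if num == 0.0:
        return -math.inf
    return math.log10(num) - math.log10(den)


def panel_log10_lr(
    pair: GenotypePair,
    index_name: str,
    panel_freqs: Mapping[str, AlleleFrequencySet],
    mutation: MutationModel = NO_MUTATION,
) -> float:
    """Panel log10 LR: the sum of per-locus log10 LRs (loci independent)."""
    missing = set(pair.genotypes_a) ^ set(panel_freqs)
    if missing:
        raise KeyError(f"locus mismatch between pair and frequency sets: {sorted(missing)}")
    return sum(
        lr_index(pair.genotypes_a[l], pair.genotypes_b[l], index_name, panel_freqs[l], mutation)
        for l in panel_freqs
    )


def lr_matrix(
    index_name: str,
    freqs: AlleleFrequencySet,
    mutation: MutationModel = NO_MUTATION,
) -> np.ndarray:
    """Per-locus log10-LR lookup table over genotype-index pairs.

    Entry [i, j] is the log10 LR for member-a genotype index i and member-b
    genotype index j (indices as produced by :func:`microkin.sim.genotype_index`
    on canonically ordered allele codes). Used by the vectorised power studies;
    agrees entry-wise with :func:`lr_index`.
    """
    alleles = freqs.alleles
    A = len(alleles)
    genos = [(alleles[i], alleles[j]) for j in range(A) for i in range(j + 1)]
    # genotype_index(i, j) = j*(j+1)//2 + i for i <= j matches this ordering
    G = n_genotypes(A)
    assert len(genos) == G
    out = np.empty((G, G))
    for gi, g1 in enumerate(genos):
        for gj, g2 in enumerate(genos):
            out[gi, gj] = lr_index(g1, g2, index_name, freqs, mutation)
    return out
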