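"""Pedigree-faithful simulation of genotype pairs for kinship studies.

Pairs are simulated per locus from population allele frequencies under five
relationship hypotheses, named by their IBD-sharing coefficients (k0, k1, k2)
— the probabilities that the pair shares 0, 1 or 2 alleles identical by
descent:

===============  ==================
relationship     (k0, k1, k2)
===============  ==================
unrelated        (1, 0, 0)
parent_child     (0, 1, 0)
full_sibling     (1/4, 1/2, 1/4)
half_sibling     (1/2, 1/2, 0)
first_cousin     (3/4, 1/4, 0)
===============  ==================

Founders are drawn under Hardy-Weinberg proportions; related pairs are built
by explicit Mendelian transmission through the pedigree connecting them, with
mutation applied independently on every transmission edge. Two mutation
models are supported: *equal_probability* (a mutating allele becomes any
other allele of the locus with equal chance — the convention for
microhaplotypes, rate 1e-8 per meiosis) and *extended_stepwise* (repeat
number changes by ±s steps with geometrically decaying step size, reflected
at the allele-ladder boundary — the convention for STRs, rate 1e-3).

Loci are simulated independently (linkage equilibrium is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .popgen import AlleleFrequencySet

__all__ = [
    "RelationshipModel",
    "MutationModel",
    "GenotypePair",
    "RELATIONSHIPS",
    "get_relationship",
    "NO_MUTATION",
    "simulate_individual",
    "transmit_allele",
    "simulate_pair",
    "simulate_study",
    "simulate_study_codes",
    "genotype_index",
    "n_genotypes",
]


@dataclass(frozen=True)
class RelationshipModel:
    """A pairwise relationship hypothesis with IBD coefficients (k0, k1, k2)."""

    label: str
    k: tuple[float, float, float]

    def __post_init__(self):
        if abs(sum(self.k) - 1.0) > 1e-12 or any(not (0.0 <= x <= 1.0) for x in self.k):
            raise ValueError(f"invalid IBD coefficients {self.k}")


RELATIONSHIPS: dict[str, RelationshipModel] = {
    "unrelated": RelationshipModel("unrelated", (1.0, 0.0, 0.0)),
    "parent_child": RelationshipModel("parent_child", (0.0, 1.0, 0.0)),
    "full_sibling": RelationshipModel("full_sibling", (0.25, 0.5, 0.25)),
    "half_sibling": RelationshipModel("half_sibling", (0.5, 0.5, 0.0)),
    "first_cousin": RelationshipModel("first_cousin", (0.75, 0.25, 0.0)),
}


def get_relationship(label: str | RelationshipModel) -> RelationshipModel:
    if isinstance(label, RelationshipModel):
        return label
    try:
        return RELATIONSHIPS[label]
    except KeyError:
        raise ValueError(f"unknown relationship {label!r}; choose from {sorted(RELATIONSHIPS)}") from None


@dataclass(frozen=True)
class MutationModel:
    """Per-meiosis, per-locus mutation law.

    ``rate`` is the mutation probability mu per transmission; for
    ``extended_stepwise`` the step size is geometric with parameter
    ``step_geometric_p`` (1.0 = pure single-step) and alleles must parse as
    repeat numbers.
    """

    kind: str = "none"
    rate: float = 0.0
    step_geometric_p: float = 0.9

    def __post_init__(self):
        if self.kind not in ("none", "equal_probability", "extended_stepwise"):
            raise ValueError(f"unknown mutation model {self.kind!r}")
        if not (0.0 <= self.rate < 1.0):
            raise ValueError(f"mutation rate {self.rate!r} outside [0, 1)")
        if (self.kind == "none") != (self.rate == 0.0) and self.kind == "none":
            raise ValueError("mutation kind 'none' requires rate 0")
        if not (0.0 < self.step_geometric_p <= 1.0):
            raise ValueError("step_geometric_p must be in (0, 1]")


NO_MUTATION = MutationModel("none", 0.0)


@dataclass(frozen=True)
class GenotypePair:
    """Two individuals' unordered genotypes across a panel, labelled with the
    relationship they were simulated under. For parent-child pairs member
    ``a`` is the parent."""

    genotypes_a: Mapping[str, tuple[str, str]]
    genotypes_b: Mapping[str, tuple[str, str]]
    relationship: str
    replicate_id: int = 0


# ---------------------------------------------------------------------------
# Scalar (single-draw) operations


def _draw_allele(freqs: AlleleFrequencySet, rng: np.random.Generator) -> str:
    return freqs.alleles[int(rng.choice(freqs.n_alleles, p=freqs.vector()))]


def simulate_individual(freqs: AlleleFrequencySet, rng: np.random.Generator) -> tuple[str, str]:
    """Two independent allele draws under Hardy-Weinberg proportions,
    canonically ordered."""
    alleles = freqs.alleles
    i, j = rng.choice(len(alleles), size=2, p=freqs.vector())
    return tuple(sorted((alleles[i], alleles[j])))


def _mutate_scalar(allele: str, mutation: MutationModel, universe: Sequence[str], rng) -> str:
    if mutation.kind == "equal_probability":
        others = [a for a in universe if a != allele]
        if not others:
            raise ValueError("equal-probability mutation needs >= 2 alleles in the universe")
        return others[rng.integers(len(others))]
    # extended stepwise: step in ladder-index space, reflected at the ends
    try:
        ladder = sorted({int(a) for a in universe})
    except ValueError:
        raise ValueError("extended_stepwise mutation requires integer repeat-number alleles") from None
    if len(ladder) < 2:
        raise ValueError("stepwise mutation needs a ladder of >= 2 alleles")
    pos = ladder.index(int(allele))
    step = int(rng.geometric(mutation.step_geometric_p))
    direction = 1 if rng.random() < 0.5 else -1
    j = pos + direction * step
    top = len(ladder) - 1
    while not (0 <= j <= top):  # reflect off the boundary
        j = -j if j < 0 else 2 * top - j
    return str(ladder[j])


def transmit_allele(
    parent_genotype: tuple[str, str],
    mutation: MutationModel,
    allele_universe: Sequence[str],
    rng: np.random.Generator,
) -> str:
    """One meiosis: pick a parental allele uniformly, then mutate with
    probability ``mutation.rate``."""
    allele = parent_genotype[int(rng.integers(2))]
    if mutation.rate > 0.0 and rng.random() < mutation.rate:
        return _mutate_scalar(allele, mutation, allele_universe, rng)
    return allele


def _child(father, mother, mutation, universe, rng) -> tuple[str, str]:
    return tuple(sorted((transmit_allele(father, mutation, universe, rng),
                         transmit_allele(mother, mutation, universe, rng))))


def simulate_pair(
    relationship: str | RelationshipModel,
    panel_freqs: Mapping[str, AlleleFrequencySet],
    mutation: MutationModel = NO_MUTATION,
    rng: np.random.Generator | None = None,
    replicate_id: int = 0,
) -> GenotypePair:
    """Simulate one genotype pair across all panel loci.

    Each relationship is realised structurally: parent-child by one
    transmission plus one population allele; full siblings from two shared
    founder parents; half siblings from one shared parent and two independent
    others; first cousins as children of full siblings married to founders;
    unrelated as two founder draws. Mutation acts on every transmission edge.
    """
    rel = get_relationship(relationship)
    rng = np.random.default_rng() if rng is None else rng
    ga: dict[str, tuple[str, str]] = {}
    gb: dict[str, tuple[str, str]] = {}
    for locus, freqs in panel_freqs.items():
        uni = freqs.alleles
        founder = lambda: simulate_individual(freqs, rng)
        if rel.label == "unrelated":
            a, b = founder(), founder()
        elif rel.label == "parent_child":
            a = founder()
            b = tuple(sorted((transmit_allele(a, mutation, uni, rng), _draw_allele(freqs, rng))))
        elif rel.label == "full_sibling":
            f, m = founder(), founder()
            a = _child(f, m, mutation, uni, rng)
            b = _child(f, m, mutation, uni, rng)
        elif rel.label == "half_sibling":
            shared = founder()
            a = _child(shared, founder(), mutation, uni, rng)
            b = _child(shared, founder(), mutation, uni, rng)
        else:  # first_cousin
            gp1, gp2 = founder(), founder()
            pa = _child(gp1, gp2, mutation, uni, rng)
            pb = _child(gp1, gp2, mutation, uni, rng)
            a = _child(pa, founder(), mutation, uni, rng)
            b = _child(pb, founder(), mutation, uni, rng)
        ga[locus] = a
        gb[locus] = b
    return GenotypePair(ga, gb, rel.label, replicate_id)


def simulate_study(
    relationship: str | RelationshipModel,
    panel_freqs: Mapping[str, AlleleFrequencySet],
    mutation: MutationModel = NO_MUTATION,
    n_pairs: int = 100_000,
    seed: int | None = None,
) -> Iterator[GenotypePair]:
    """Yield ``n_pairs`` simulated pairs, reproducibly for a given seed.

    A generator so cohorts can be streamed to disk without materialising
    100,000 pair objects.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    for i in range(n_pairs):
        yield simulate_pair(relationship, panel_freqs, mutation, rng, replicate_id=i)


# ---------------------------------------------------------------------------
# Vectorised engine used by the large power studies
#
# Genotypes are encoded as integers: alleles get codes 0..A-1 in the canonical
# order of AlleleFrequencySet.alleles, and the unordered pair (i <= j) maps to
# index j*(j+1)//2 + i, so a locus with A alleles has A*(A+1)//2 genotypes.


def n_genotypes(n_alleles: int) -> int:
    return n_alleles * (n_alleles + 1) // 2


def genotype_index(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Unordered-pair index from two allele-code arrays."""
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return hi * (hi + 1) // 2 + lo


def _draw_alleles(p_cum: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    return np.searchsorted(p_cum, rng.random(size), side="right")


def _transmit_vec(
    par: np.ndarray,  # (n, 2) parental allele codes
    mutation: MutationModel,
    n_alleles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    pick = rng.integers(0, 2, size=par.shape[0])
    allele = par[np.arange(par.shape[0]), pick]
    if mutation.rate > 0.0:
        hit = rng.random(par.shape[0]) < mutation.rate
        k = int(hit.sum())
        if k:
            if mutation.kind == "equal_probability":
                if n_alleles < 2:
                    raise ValueError("equal-probability mutation needs >= 2 alleles")
                off = rng.integers(1, n_alleles, size=k)
                allele[hit] = (allele[hit] + off) % n_alleles
            else:  # extended_stepwise on ladder indices (codes are ladder positions)
                step = rng.geometric(mutation.step_geometric_p, size=k)
                sign = rng.integers(0, 2, size=k) * 2 - 1
                j = allele[hit] + sign * step
                top = n_alleles - 1
                j = np.abs(j)
                # one reflection pass suffices for steps < 2*top; iterate to be safe
                while np.any(j > top):
                    j = np.where(j > top, 2 * top - j, j)
                    j = np.abs(j)
                allele[hit] = j
    return allele


def simulate_study_codes(
    relationship: str | RelationshipModel,
    freq_sets: Sequence[AlleleFrequencySet],
    mutation: MutationModel = NO_MUTATION,
    n_pairs: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort simulation.

    Returns two (n_loci, n_pairs) integer arrays of genotype indices for the
    two pair members (member a is the parent for parent-child pairs). Same
    pedigree structure and mutation semantics as :func:`simulate_pair`.
    """
    rel = get_relationship(relationship)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ga = np.empty((len(freq_sets), n_pairs), dtype=np.int64)
    gb = np.empty_like(ga)
    for li, freqs in enumerate(freq_sets):
        A = freqs.n_alleles
        if mutation.kind == "extended_stepwise":
            # codes must form the repeat-number ladder in order
            try:
                [int(a) for a in freqs.alleles]
            except ValueError:
                raise ValueError("stepwise mutation requires repeat-number alleles") from None
        p_cum = np.cumsum(freqs.vector())
        p_cum[-1] = 1.0

        def founder(n=n_pairs):
            return _draw_alleles(p_cum, 2 * n, rng).reshape(n, 2)

        def child(f, m):
            return np.stack(
                [
                    _transmit_vec(f, mutation, A, rng),
                    _transmit_vec(m, mutation, A, rng),
                ],
                axis=1,
            )

        if rel.label == "unrelated":
            a, b = founder(), founder()
        elif rel.label == "parent_child":
            a = founder()
            b = np.stack(
                [_transmit_vec(a, mutation, A, rng), _draw_alleles(p_cum, n_pairs, rng)],
                axis=1,
            )
        elif rel.label == "full_sibling":
            f, m = founder(), founder()
            a, b = child(f, m), child(f, m)
        elif rel.label == "half_sibling":
            shared = founder()
            a, b = child(shared, founder()), child(shared, founder())
        else:  # first_cousin
            gp1, gp2 = founder(), founder()
            pa, pb = child(gp1, gp2), child(gp1, gp2)
            a, b = child(pa, founder()), child(pb, founder())
        ga[li] = genotype_index(a[:, 0], a[:, 1])
        gb[li] = genotype_index(b[:, 0], b[:, 1])
    return ga, gb
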