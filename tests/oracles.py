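"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — full enumeration or generic
numerical optimisation — and shares no code path with the implementation it
checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by full table enumeration


def _table_log_weight(table: dict[tuple[int, int], int]) -> float:
    """log of n! 2^h / prod(n_ij!) — proportional to the conditional law."""
    n = sum(table.values())
    h = sum(c for (i, j), c in table.items() if i != j)
    lw = math.lgamma(n + 1) + h * math.log(2.0)
    for c in table.values():
        lw -= math.lgamma(c + 1)
    return lw


def enumerate_hwe_tables(allele_counts: Sequence[int]):
    """All genotype tables with the given allele-count margins, with their
    exact conditional probabilities."""
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    tables = []

    def rec(ci: int, remaining: list[int], acc: dict):
        if ci == len(cells):
            if all(r == 0 for r in remaining):
                tables.append(dict(acc))
            return
        i, j = cells[ci]
        if i == j:
            top = remaining[i] // 2
        else:
            top = min(remaining[i], remaining[j])
        for c in range(top + 1):
            if c:
                acc[(i, j)] = c
            remaining[i] -= c * (2 if i == j else 1)
            if i != j:
                remaining[j] -= c
            rec(ci + 1, remaining, acc)
            remaining[i] += c * (2 if i == j else 1)
            if i != j:
                remaining[j] += c
            acc.pop((i, j), None)

    rec(0, list(allele_counts), {})
    lws = np.array([_table_log_weight(t) for t in tables])
    probs = np.exp(lws - lws.max())
    probs /= probs.sum()
    return tables, probs


def exact_hwe_pvalue(observed: Mapping[tuple[int, int], int]) -> float:
    """Exact conditional p-value: total probability of tables no more
    probable than the observed one."""
    k = 1 + max(a for pair in observed for a in pair)
    counts = [0] * k
    for (i, j), c in observed.items():
        counts[i] += c
        counts[j] += c
    tables, probs = enumerate_hwe_tables(counts)
    obs_key = {tuple(sorted(k2)): v for k2, v in observed.items() if v}
    p_obs = next(p for t, p in zip(tables, probs) if t == obs_key)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


# ---------------------------------------------------------------------------
# Two-locus haplotype ML by direct simplex optimisation


def ml_haplotype_frequencies(samples, n_starts: int = 8, seed: int = 0):
    """Maximise the phase-unknown two-locus likelihood over the haplotype
    simplex with scipy (softmax parametrisation, multiple starts).

    Returns (freqs dict, log-likelihood).
    """
    from scipy.optimize import minimize

    haps = sorted(
        {
            (a, b)
            for g1, g2 in samples
            for a in g1
            for b in g2
        }
    )
    idx = {hp: i for i, hp in enumerate(haps)}

    configs = []
    for g1, g2 in samples:
        (a1, a2), (b1, b2) = sorted(g1), sorted(g2)
        pairs = {
            tuple(sorted(((a1, b1), (a2, b2)))),
            tuple(sorted(((a1, b2), (a2, b1)))),
        }
        ordered = []
        for x, y in pairs:
            ordered.append((idx[x], idx[y], 1.0 if x == y else 2.0))
        configs.append(ordered)

    def negll(z):
        h = np.exp(z - z.max())
        h /= h.sum()
        ll = 0.0
        for ordered in configs:
            p = sum(m * h[i] * h[j] for i, j, m in ordered)
            if p <= 0:
                return 1e9
            ll += math.log(p)
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        z0 = np.zeros(len(haps)) if s == 0 else rng.normal(size=len(haps))
        res = minimize(negll, z0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    h = np.exp(best.x - best.x.max())
    h /= h.sum()
    return {hp: float(f) for hp, f in zip(haps, h)}, -float(best.fun)


# ---------------------------------------------------------------------------
# Exact kinship-pair distributions by pedigree enumeration


def _geno(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def pair_distribution(freqs: Mapping[str, float], relationship: str) -> dict:
    """Exact joint distribution of an (ordered-member) genotype pair at one
    locus under mu = 0, by enumerating founder alleles and transmissions.

    Keys are (genotype_a, genotype_b) with genotypes as sorted allele pairs;
    member a is the parent for parent_child.
    """
    alleles = sorted(freqs)
    p = {a: freqs[a] for a in alleles}
    dist: dict[tuple, float] = {}

    def add(ga, gb, w):
        if w > 0:
            key = (ga, gb)
            dist[key] = dist.get(key, 0.0) + w

    A = alleles
    if relationship == "unrelated":
        for a1, a2, b1, b2 in itertools.product(A, repeat=4):
            add(_geno(a1, a2), _geno(b1, b2), p[a1] * p[a2] * p[b1] * p[b2])
    elif relationship == "parent_child":
        for a1, a2 in itertools.product(A, repeat=2):  # parent
            for t in (a1, a2):  # transmitted
                for m in A:  # mate allele
                    add(_geno(a1, a2), _geno(t, m), p[a1] * p[a2] * 0.5 * p[m])
    elif relationship == "full_sibling":
        for f1, f2, m1, m2 in itertools.product(A, repeat=4):
            w0 = p[f1] * p[f2] * p[m1] * p[m2]
            for cf1, cm1 in itertools.product((f1, f2), (m1, m2)):
                for cf2, cm2 in itertools.product((f1, f2), (m1, m2)):
                    add(_geno(cf1, cm1), _geno(cf2, cm2), w0 / 16.0)
    elif relationship == "half_sibling":
        for s1, s2 in itertools.product(A, repeat=2):  # shared parent
            ws = p[s1] * p[s2]
            for t1 in (s1, s2):
                for t2 in (s1, s2):
                    for o1, o2 in itertools.product(A, repeat=2):  # mate alleles
                        add(_geno(t1, o1), _geno(t2, o2), ws * 0.25 * p[o1] * p[o2])
    elif relationship == "first_cousin":
        # grandparents -> two full-sib parents -> children with founder mates
        for g1a, g1b, g2a, g2b in itertools.product(A, repeat=4):
            wg = p[g1a] * p[g1b] * p[g2a] * p[g2b]
            for pa_f, pa_m in itertools.product((g1a, g1b), (g2a, g2b)):
                for pb_f, pb_m in itertools.product((g1a, g1b), (g2a, g2b)):
                    for t1 in (pa_f, pa_m):
                        for t2 in (pb_f, pb_m):
                            for o1, o2 in itertools.product(A, repeat=2):
                                add(
                                    _geno(t1, o1),
                                    _geno(t2, o2),
                                    wg / 16.0 * 0.25 * p[o1] * p[o2],
                                )
    else:
        raise ValueError(relationship)
    return dist


def exact_power(
    locus_freqs: Sequence[Mapping[str, float]],
    hp_relationship: str,
    hd_relationship: str,
    lr_fn,
    thresholds: Sequence[tuple[float, float]],
):
    """Exact threshold metrics and UCR over the full genotype-pair outcome
    space of a small multi-locus panel (mu = 0).

    ``lr_fn(locus_index, ga, gb)`` returns the per-locus log10 LR.
    Returns ({(t1, t2): metrics dict}, ucr dict).
    """
    per_locus = []
    for li, freqs in enumerate(locus_freqs):
        hp_d = pair_distribution(freqs, hp_relationship)
        hd_d = pair_distribution(freqs, hd_relationship)
        states = sorted(set(hp_d) | set(hd_d))
        per_locus.append(
            [
                (hp_d.get(s, 0.0), hd_d.get(s, 0.0), lr_fn(li, *s))
                for s in states
            ]
        )

    outcomes = [(1.0, 1.0, 0.0)]
    for locus_states in per_locus:
        outcomes = [
            (wp * sp, wd * sd, acc + lr)
            for wp, wd, acc in outcomes
            for sp, sd, lr in locus_states
        ]

    hp_mass = np.array([o[0] for o in outcomes])
    hd_mass = np.array([o[1] for o in outcomes])
    lrs = np.array([o[2] for o in outcomes])

    metrics = {}
    for t1, t2 in thresholds:
        hp_as_hp = hp_mass[lrs > t1].sum()
        hp_as_hd = hp_mass[lrs < t2].sum()
        hd_as_hp = hd_mass[lrs > t1].sum()
        hd_as_hd = hd_mass[lrs < t2].sum()
        metrics[(t1, t2)] = {
            "sensitivity": hp_as_hp,
            "specificity": hd_as_hd,
            "error_rate": (hp_as_hd + hd_as_hp) / 2.0,
            "effectiveness": (hp_as_hp + hd_as_hd) / 2.0,
        }

    max_hd = lrs[hd_mass > 0].max()
    min_hp = lrs[hp_mass > 0].min()
    ucr = {
        "ucr_hp": hp_mass[lrs > max_hd].sum(),
        "ucr_hd": hd_mass[lrs < min_hp].sum(),
        "max_hd": max_hd,
        "min_hp": min_hp,
    }
    return metrics, ucr
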