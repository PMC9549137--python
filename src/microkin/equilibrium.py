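"""Hardy-Weinberg and linkage-equilibrium testing for multi-allelic loci.

Hardy-Weinberg: the exact conditional test. Given the observed allele counts,
the null distribution over genotype tables is Levene's conditional law
``P(table) = n! 2^h prod(c_i!) / ((2n)! prod(n_ij!))`` (``h`` heterozygotes,
``c_i`` allele counts). The p-value is the total probability of tables no more
probable than the observed one. For the multi-allelic tables a microhaplotype
locus produces, full enumeration is infeasible, so the p-value is estimated by
Markov-chain Monte Carlo: the chain state is an explicit pairing of the 2n
alleles into n genotypes, and each step swaps one allele between two randomly
chosen individuals. That proposal is symmetric and every swap is accepted, so
the chain is uniform over allele pairings — which marginalises to exactly the
conditional law over tables (each table's probability is proportional to the
number of pairings realising it).

Linkage: gametic phase is unknown in genotype data, so two-locus haplotype
frequencies are fitted by EM and the test statistic is the likelihood ratio
``2 (logL_EM - logL_LE)`` against the linkage-equilibrium model in which
haplotype frequencies are products of single-locus allele frequencies. Its
null distribution is built by permuting one locus's genotypes across samples,
re-running EM on every permuted dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HweResult",
    "LdResult",
    "EmResult",
    "genotype_counts",
    "hwe_exact_test",
    "em_haplotype_frequencies",
    "ld_permutation_test",
    "bonferroni_threshold",
    "hwe_scan",
    "ld_scan",
]


@dataclass(frozen=True)
class HweResult:
    locus_name: str
    p_value: float
    n_steps: int
    n_burnin: int
    seed: int | None


@dataclass(frozen=True)
class LdResult:
    locus_pair: tuple[str, str]
    lr_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class EmResult:
    """EM-fitted two-locus haplotype frequencies.

    ``phase_ambiguous`` flags datasets containing double heterozygotes, whose
    likelihood can have symmetric optima; the returned solution is then the
    one reached from the deterministic uniform start.
    """

    freqs: dict[tuple[str, str], float]
    log_likelihood: float
    n_iter: int
    converged: bool
    phase_ambiguous: bool

    def __getitem__(self, hap: tuple[str, str]) -> float:
        return self.freqs[hap]


def genotype_counts(genotypes: Iterable[tuple[str, str]]) -> dict[tuple[str, str], int]:
    """Tally unordered genotypes into a dict keyed by sorted allele pairs."""
    counts: dict[tuple[str, str], int] = {}
    for a, b in genotypes:
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _table_log_prob_terms(pairs: np.ndarray) -> tuple[dict[tuple[int, int], int], float]:
    """Counts and the variable part of log P(table): h*log2 - sum(log n_ij!)."""
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    h = sum(c for (a, b), c in counts.items() if a != b)
    lp = h * math.log(2.0) - sum(math.lgamma(c + 1) for c in counts.values())
    return counts, lp


def hwe_exact_test(
    genotype_counts_or_table: Mapping[tuple[str, str], int],
    n_steps: int = 1_000_000,
    n_burnin: int = 100_000,
    seed: int | None = None,
    locus_name: str = "",
) -> HweResult:
    """Exact-test p-value for Hardy-Weinberg proportions, by MCMC.

    ``genotype_counts_or_table`` maps unordered allele pairs to counts. The
    p-value is the post-burn-in fraction of chain states whose conditional
    table probability does not exceed the observed table's. Deterministic
    given ``seed``.
    """
    table = {tuple(sorted(k)): int(v) for k, v in genotype_counts_or_table.items()}
    if any(v < 0 for v in table.values()):
        raise ValueError("negative genotype count")
    n = sum(table.values())
    if n < 2:
        raise ValueError("need at least two individuals")
    alleles = sorted({a for pair in table for a in pair})
    if len(alleles) == 1:
        warnings.warn(f"{locus_name or 'locus'}: monomorphic, exact p-value is 1", stacklevel=2)
        return HweResult(locus_name, 1.0, n_steps, n_burnin, seed)

    code = {a: i for i, a in enumerate(alleles)}
    pairs = np.array(
        [[code[a], code[b]] for (a, b), c in table.items() for _ in range(c)], dtype=np.int64
    )
    counts, lp_obs = _table_log_prob_terms(pairs)
    lp = lp_obs
    rng = np.random.default_rng(seed)

    # pre-draw the whole random stream in blocks for speed
    total = n_burnin + n_steps
    us = rng.integers(0, n, size=total)
    vs = rng.integers(0, n - 1, size=total)
    vs = np.where(vs >= us, vs + 1, vs)  # v != u, uniform over the rest
    sa = rng.integers(0, 2, size=total)
    sb = rng.integers(0, 2, size=total)

    def cell(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    log2 = math.log(2.0)
    hits = 0
    tol = 1e-9
    for t in range(total):
        u, v, i, j = us[t], vs[t], sa[t], sb[t]
        au, av = pairs[u, i], pairs[v, j]
        if au != av:
            old_u = cell(pairs[u, 0], pairs[u, 1])
            old_v = cell(pairs[v, 0], pairs[v, 1])
            pairs[u, i], pairs[v, j] = av, au
            new_u = cell(pairs[u, 0], pairs[u, 1])
            new_v = cell(pairs[v, 0], pairs[v, 1])
            for old in (old_u, old_v):
                c = counts[old]
                lp += math.lgamma(c + 1) - math.lgamma(c)
                if c == 1:
                    del counts[old]
                else:
                    counts[old] = c - 1
                if old[0] != old[1]:
                    lp -= log2
            for new in (new_u, new_v):
                c = counts.get(new, 0)
                lp += math.lgamma(c + 1) - math.lgamma(c + 2)
                counts[new] = c + 1
                if new[0] != new[1]:
                    lp += log2
        if t >= n_burnin and lp <= lp_obs + tol:
            hits += 1

    return HweResult(locus_name, hits / n_steps, n_steps, n_burnin, seed)


# ---------------------------------------------------------------------------
# Two-locus EM and the LD permutation test


def _compatible_pairs(g1: tuple[str, str], g2: tuple[str, str]):
    """Ordered haplotype pairs ((x1,y1),(x2,y2)) compatible with the two
    single-locus genotypes; ordered pairs so P(sample) = sum h_x * h_y."""
    a1, a2 = g1
    b1, b2 = g2
    seen = set()
    out = []
    for (p, q) in ((a1, a2), (a2, a1)):
        for (r, s) in ((b1, b2), (b2, b1)):
            key = ((p, r), (q, s))
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def _aggregate(samples: Sequence[tuple[tuple[str, str], tuple[str, str]]]):
    agg: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    for g1, g2 in samples:
        key = (tuple(sorted(g1)), tuple(sorted(g2)))
        agg[key] = agg.get(key, 0) + 1
    return agg


def em_haplotype_frequencies(
    two_locus_genotypes: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> EmResult:
    """Maximum-likelihood two-locus haplotype frequencies with unknown phase.

    Each sample is ``((a1, a2), (b1, b2))`` — unordered genotypes at the two
    loci. Initialisation is uniform over every haplotype compatible with the
    observed genotypes; the log-likelihood is non-decreasing across
    iterations and iteration stops when its gain drops below ``tol``.
    """
    if not two_locus_genotypes:
        raise ValueError("empty input")
    agg = _aggregate(two_locus_genotypes)
    entries = []  # (weight, list of ordered hap pairs)
    hap_set: set[tuple[str, str]] = set()
    phase_ambiguous = False
    for (g1, g2), w in agg.items():
        pairs = _compatible_pairs(g1, g2)
        if g1[0] != g1[1] and g2[0] != g2[1]:
            phase_ambiguous = True
        entries.append((w, pairs))
        for x, y in pairs:
            hap_set.add(x)
            hap_set.add(y)

    haps = sorted(hap_set)
    idx = {hp: i for i, hp in enumerate(haps)}
    n = sum(w for w, _ in entries)
    h = np.full(len(haps), 1.0 / len(haps))

    # index arrays per aggregated genotype class
    pair_idx = [np.array([(idx[x], idx[y]) for x, y in pairs]) for _, pairs in entries]
    weights = np.array([w for w, _ in entries], dtype=float)

    def loglik(hv: np.ndarray) -> float:
        ll = 0.0
        for w, pi in zip(weights, pair_idx):
            ll += w * math.log(np.sum(hv[pi[:, 0]] * hv[pi[:, 1]]))
        return ll

    prev = loglik(h)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(len(haps))
        for w, pi in zip(weights, pair_idx):
            probs = h[pi[:, 0]] * h[pi[:, 1]]
            post = probs / probs.sum()
            np.add.at(counts, pi[:, 0], w * post)
            np.add.at(counts, pi[:, 1], w * post)
        h = counts / (2.0 * n)
        cur = loglik(h)
        if cur < prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        if cur - prev < tol:
            converged = True
            prev = cur
            break
        prev = cur

    freqs = {hp: float(f) for hp, f in zip(haps, h) if f > 0.0}
    return EmResult(freqs, prev, it, converged, phase_ambiguous)


def _ld_statistic(samples, max_iter: int, tol: float) -> float:
    """2 * (logL_EM - logL_LE); LE haplotype frequencies are products of the
    single-locus allele frequencies."""
    em = em_haplotype_frequencies(samples, max_iter=max_iter, tol=tol)
    f1: dict[str, float] = {}
    f2: dict[str, float] = {}
    for g1, g2 in samples:
        for a in g1:
            f1[a] = f1.get(a, 0.0) + 1.0
        for b in g2:
            f2[b] = f2.get(b, 0.0) + 1.0
    tot = 2.0 * len(samples)
    f1 = {a: c / tot for a, c in f1.items()}
    f2 = {b: c / tot for b, c in f2.items()}

    ll_le = 0.0
    for (g1, g2), w in _aggregate(samples).items():
        p = sum(f1[x[0]] * f2[x[1]] * f1[y[0]] * f2[y[1]] for x, y in _compatible_pairs(g1, g2))
        ll_le += w * math.log(p)
    return max(0.0, 2.0 * (em.log_likelihood - ll_le))


def ld_permutation_test(
    two_locus_genotypes: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    n_permutations: int = 10_000,
    seed: int | None = None,
    locus_pair: tuple[str, str] = ("", ""),
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> LdResult:
    """Likelihood-ratio test of linkage equilibrium with a permutation null.

    The null is built by independently permuting one locus's genotypes across
    samples (breaking any gametic association while preserving both marginal
    genotype distributions) and re-running EM on each permuted dataset. The
    p-value uses the add-one estimator ``(1 + #{perm >= obs}) / (1 + B)``.
    """
    samples = [(tuple(sorted(g1)), tuple(sorted(g2))) for g1, g2 in two_locus_genotypes]
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mono1 = len({a for g1, _ in samples for a in g1}) == 1
    mono2 = len({b for _, g2 in samples for b in g2}) == 1
    if mono1 or mono2:
        warnings.warn(f"{locus_pair}: monomorphic locus, LD p-value is 1", stacklevel=2)
        return LdResult(locus_pair, 0.0, 1.0, n_permutations, seed)

    obs = _ld_statistic(samples, max_iter, tol)
    rng = np.random.default_rng(seed)
    g1s = [g1 for g1, _ in samples]
    g2s = [g2 for _, g2 in samples]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(g2s))
        permuted = [(g1s[i], g2s[perm[i]]) for i in range(len(g1s))]
        if _ld_statistic(permuted, max_iter, tol) >= obs - 1e-9:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return LdResult(locus_pair, obs, p, n_permutations, seed)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha!r} outside (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Table-level scans used by the CLI pipeline


def hwe_scan(genotype_table, loci: Sequence[str], **kwargs) -> list[HweResult]:
    """HWE exact test per locus of a ``sample,locus,allele1,allele2`` table."""
    results = []
    seed = kwargs.pop("seed", None)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(loci))
    for locus, child in zip(loci, children):
        sub = genotype_table[genotype_table["locus"] == locus]
        counts = genotype_counts(zip(sub["allele1"], sub["allele2"]))
        results.append(
            hwe_exact_test(counts, seed=int(child.generate_state(1)[0] % (2**31)), locus_name=locus, **kwargs)
        )
    return results


def ld_scan(genotype_table, loci: Sequence[str], **kwargs) -> list[LdResult]:
    """Pairwise LD permutation test over every locus pair (C(len, 2) tests)."""
    import itertools

    seed = kwargs.pop("seed", None)
    pairs = list(itertools.combinations(loci, 2))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    by_locus = {
        l: dict(
            zip(
                genotype_table[genotype_table["locus"] == l]["sample"],
                zip(
                    genotype_table[genotype_table["locus"] == l]["allele1"],
                    genotype_table[genotype_table["locus"] == l]["allele2"],
                ),
            )
        )
        for l in loci
    }
    results = []
    for (l1, l2), child in zip(pairs, children):
        shared = sorted(set(by_locus[l1]) & set(by_locus[l2]))
        samples = [(by_locus[l1][s], by_locus[l2][s]) for s in shared]
        results.append(
            ld_permutation_test(
                samples, seed=int(child.generate_state(1)[0] % (2**31)), locus_pair=(l1, l2), **kwargs
            )
        )
    return results
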