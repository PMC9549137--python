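"""Per-locus forensic parameters and panel-wide combined powers.

The quantities computed here are the standard single-locus summaries used to
characterise a forensic marker panel:

* ``Ae`` — effective number of alleles, ``1 / sum(p_i^2)``: the allele count of
  a hypothetical locus with equally frequent alleles and the same expected
  homozygosity.
* ``Ho`` — observed heterozygosity, the fraction of typed individuals whose
  two alleles differ.
* ``PD`` — power of discrimination, ``1 - sum(g_j^2)`` over genotype
  frequencies: the probability that two random individuals differ in genotype.
* ``PE`` — probability of exclusion in a trio case, computed from observed
  heterozygosity by the Brenner/Powerstats convention
  ``PE = h^2 * (1 - 2*h*(1-h)^2)``.
* ``CPD``/``CPE`` — panel-wide combinations ``1 - prod(1 - v_i)``, accumulated
  in log space because the complements reach magnitudes like 1e-26.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleFrequencySet",
    "LocusForensics",
    "CombinedPower",
    "allele_frequencies",
    "effective_alleles",
    "observed_heterozygosity",
    "power_of_discrimination",
    "power_of_exclusion",
    "combined_power",
    "combined_powers",
    "locus_forensics",
]


def _allele_sort_key(allele: str):
    """Order alleles numerically when they parse as repeat numbers (STRs),
    lexicographically otherwise (microhaplotype strings)."""
    try:
        return (0, float(allele), allele)
    except ValueError:
        return (1, 0.0, allele)


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Normalised allele frequencies for one locus in one population.

    ``freqs`` always sums to 1; ``raw_total`` records the column sum of the
    input before renormalisation (printed tables rounded to 2 decimals do not
    always sum to exactly 1).
    """

    locus_name: str
    freqs: Mapping[str, float]
    population: str = ""
    raw_total: float = 1.0

    def __post_init__(self):
        if not self.freqs:
            raise ValueError(f"empty frequency set for locus {self.locus_name!r}")
        for a, f in self.freqs.items():
            if not a:
                raise ValueError(f"{self.locus_name}: empty allele key")
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{self.locus_name}: frequency {f!r} for allele {a!r} outside (0, 1]")
        total = float(sum(self.freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.locus_name}: frequencies sum to {total!r}; "
                "use AlleleFrequencySet.from_raw to renormalise"
            )

    @classmethod
    def from_raw(cls, locus_name: str, freqs: Mapping[str, float], population: str = "") -> "AlleleFrequencySet":
        """Build a set from possibly unnormalised (e.g. printed, rounded)
        frequencies, renormalising by the column sum and logging the adjustment."""
        if not freqs:
            raise ValueError(f"empty frequency set for locus {locus_name!r}")
        for a, f in freqs.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{locus_name}: raw frequency {f!r} for allele {a!r} outside (0, 1]")
        total = float(sum(freqs.values()))
        if abs(total - 1.0) > 1e-9:
            logger.info("renormalising %s frequencies by 1/%.4f", locus_name, total)
        norm = {a: f / total for a, f in freqs.items()}
        # push residual rounding error onto the largest allele so the sum is exact
        resid = 1.0 - sum(norm.values())
        if resid != 0.0:
            amax = max(norm, key=norm.get)
            norm[amax] += resid
        return cls(locus_name, norm, population, raw_total=total)

    @classmethod
    def from_counts(cls, locus_name: str, counts: Mapping[str, int], population: str = "") -> "AlleleFrequencySet":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError(f"{locus_name}: no observed alleles")
        return cls(locus_name, {a: c / total for a, c in counts.items() if c > 0}, population)

    @property
    def alleles(self) -> tuple[str, ...]:
        """Canonical allele ordering (numeric for repeat numbers, else lexicographic)."""
        return tuple(sorted(self.freqs, key=_allele_sort_key))

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)

    def vector(self) -> np.ndarray:
        """Frequency vector in canonical allele order."""
        return np.array([self.freqs[a] for a in self.alleles], dtype=float)

    def __getitem__(self, allele: str) -> float:
        return self.freqs[allele]


@dataclass(frozen=True)
class LocusForensics:
    """Single-locus forensic parameter bundle."""

    locus_name: str
    n_alleles: int
    ae: float
    ho: float
    pd: float
    pe: float

    def __post_init__(self):
        if self.ae < 1.0 - 1e-12 or self.n_alleles < 1:
            raise ValueError(f"{self.locus_name}: invalid Ae={self.ae} / n_alleles={self.n_alleles}")
        if not (0.0 <= self.ho <= 1.0) or not (0.0 <= self.pd < 1.0):
            raise ValueError(f"{self.locus_name}: Ho or PD out of range")


@dataclass(frozen=True)
class CombinedPower:
    """Panel-wide discrimination/exclusion power with explicit complements.

    Values like CPD = 1 - 2.96e-26 lose all information in a plain float, so
    the complements ``prod(1 - v_i)`` are first-class fields.
    """

    cpd: float
    cpe: float
    cpd_complement: float
    cpe_complement: float


def _require_locus(table: pd.DataFrame, locus_name: str) -> pd.DataFrame:
    sub = table[table["locus"] == locus_name]
    if sub.empty:
        raise KeyError(f"locus {locus_name!r} absent from genotype table")
    return sub


def allele_frequencies(genotype_table: pd.DataFrame, locus_name: str, population: str = "") -> AlleleFrequencySet:
    """Count allele frequencies at one locus from a genotype table.

    The table holds one row per (sample, locus) with columns
    ``sample, locus, allele1, allele2``; frequency = count / (2 * typed samples).
    """
    sub = _require_locus(genotype_table, locus_name)
    counts: dict[str, int] = {}
    for a in pd.concat([sub["allele1"], sub["allele2"]]):
        counts[a] = counts.get(a, 0) + 1
    return AlleleFrequencySet.from_counts(locus_name, counts, population)


def effective_alleles(freqs: AlleleFrequencySet) -> float:
    """Effective number of alleles Ae = 1 / sum(p_i^2)."""
    p = freqs.vector()
    return float(1.0 / np.sum(p * p))


def observed_heterozygosity(genotype_table: pd.DataFrame, locus_name: str) -> float:
    """Fraction of typed samples whose two alleles differ."""
    sub = _require_locus(genotype_table, locus_name)
    return float((sub["allele1"] != sub["allele2"]).mean())


def _hwe_genotype_freqs(freqs: AlleleFrequencySet) -> np.ndarray:
    p = freqs.vector()
    g = np.outer(p, p)
    # unordered genotype frequencies: homozygotes p_i^2, heterozygotes 2 p_i p_j
    tri = np.triu(g + g.T, k=1)[np.triu_indices(len(p), k=1)]
    return np.concatenate([p * p, tri])


def power_of_discrimination(data, locus_name: str | None = None, mode: str = "auto") -> float:
    """Power of discrimination PD = 1 - sum over genotypes of g_j^2.

    ``mode='observed'`` tallies genotype frequencies from a genotype table
    (the convention of Powerstats on typed data); ``mode='hwe_expected'``
    derives them from allele frequencies under Hardy-Weinberg proportions
    (the only option in simulation studies). ``'auto'`` picks by input type.
    """
    if mode not in ("auto", "observed", "hwe_expected"):
        raise ValueError(f"unknown PD mode {mode!r}")
    if isinstance(data, AlleleFrequencySet):
        if mode == "observed":
            raise ValueError("observed-mode PD requires a genotype table")
        g = _hwe_genotype_freqs(data)
    else:
        if mode == "hwe_expected":
            if locus_name is None:
                raise ValueError("locus_name required")
            g = _hwe_genotype_freqs(allele_frequencies(data, locus_name))
        else:
            sub = _require_locus(data, locus_name)
            geno = sub.apply(lambda r: tuple(sorted((r["allele1"], r["allele2"]))), axis=1)
            g = geno.value_counts(normalize=True).to_numpy()
    return float(1.0 - np.sum(np.asarray(g) ** 2))


def power_of_exclusion(ho: float) -> float:
    """Trio exclusion power from observed heterozygosity.

    PE = h^2 * (1 - 2*h*H^2) with h = Ho and H = 1 - h; monotone increasing
    on [0, 1] with PE(0) = 0 and PE(1) = 1.
    """
    if not (0.0 <= ho <= 1.0):
        raise ValueError(f"observed heterozygosity {ho!r} outside [0, 1]")
    h = float(ho)
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def combined_power(per_locus_values: Sequence[float]) -> tuple[float, float]:
    """Combine per-locus powers: returns (1 - prod(1 - v_i), prod(1 - v_i)).

    The complement is accumulated as sum(log(1 - v_i)) so magnitudes like
    1e-26 survive; any input >= 1 is rejected.
    """
    vals = list(per_locus_values)
    if not vals:
        raise ValueError("no per-locus values to combine")
    for v in vals:
        if not (0.0 <= v < 1.0):
            raise ValueError(f"per-locus power {v!r} outside [0, 1)")
    log_comp = sum(math.log(1.0 - v) for v in vals)
    complement = math.exp(log_comp)
    return 1.0 - complement, complement


def combined_powers(pds: Sequence[float], pes: Sequence[float]) -> CombinedPower:
    cpd, cpd_c = combined_power(pds)
    cpe, cpe_c = combined_power(pes)
    return CombinedPower(cpd=cpd, cpe=cpe, cpd_complement=cpd_c, cpe_complement=cpe_c)


def locus_forensics(genotype_table: pd.DataFrame, locus_name: str, pd_mode: str = "observed") -> LocusForensics:
    """All per-locus parameters from a genotype table in one pass."""
    freqs = allele_frequencies(genotype_table, locus_name)
    ho = observed_heterozygosity(genotype_table, locus_name)
    return LocusForensics(
        locus_name=locus_name,
        n_alleles=freqs.n_alleles,
        ae=effective_alleles(freqs),
        ho=ho,
        pd=power_of_discrimination(genotype_table, locus_name, mode=pd_mode),
        pe=power_of_exclusion(ho),
    )
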