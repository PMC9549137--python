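"""Microhaplotype panel model, candidate screening and VCF allele extraction.

A microhaplotype locus is a short genomic segment (here < 100 bp) containing
two or more SNPs whose phased combination defines multi-allelic haplotype
alleles. Loci follow the community nomenclature ``mh<chromosome><lab><serial>``
with an optional lower-case suffix distinguishing variant SNP combinations of
a previously published locus (e.g. ``mh04zha032a``).

Candidate screening applies the selection rules used when assembling a short,
highly polymorphic panel: at least two SNPs, extent strictly under a length
cap, effective allele number and heterozygosity strictly above floors, and a
minimum physical spacing between retained loci on the same chromosome so they
can be treated as unlinked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MicrohapLocus",
    "LocusScreenStats",
    "Panel",
    "validate_locus_name",
    "filter_candidates",
    "extract_microhap_genotypes",
    "snp_frequencies_differ",
]

# mh + two-digit chromosome + lab code (letters) + serial digits + optional
# single lower-case suffix letter
_NAME_RE = re.compile(r"^mh(\d{2})([a-z]+?)(\d+)([a-z]?)$")


def validate_locus_name(name: str) -> bool:
    """True iff ``name`` follows the mh<NN><lab><serial>[suffix] nomenclature
    with a chromosome number 1-22."""
    m = _NAME_RE.match(name)
    if not m:
        return False
    return 1 <= int(m.group(1)) <= 22


@dataclass(frozen=True)
class MicrohapLocus:
    """One panel entry: name, chromosome, SNP coordinates (1-based, GRCh37)
    and the inclusive extent in bp from first to last SNP."""

    name: str
    chromosome: str
    snp_positions: tuple[int, ...]
    rsids: tuple[str, ...]
    extent_bp: int

    def __post_init__(self):
        object.__setattr__(self, "snp_positions", tuple(self.snp_positions))
        object.__setattr__(self, "rsids", tuple(self.rsids))
        if not validate_locus_name(self.name):
            raise ValueError(f"locus name {self.name!r} does not follow the mh nomenclature")
        if len(self.snp_positions) < 2:
            raise ValueError(f"{self.name}: a microhaplotype needs >= 2 SNPs")
        if any(b <= a for a, b in zip(self.snp_positions, self.snp_positions[1:])):
            raise ValueError(f"{self.name}: SNP positions must be strictly increasing")
        if len(self.rsids) != len(self.snp_positions):
            raise ValueError(f"{self.name}: {len(self.rsids)} rsIDs for {len(self.snp_positions)} positions")
        span = self.snp_positions[-1] - self.snp_positions[0] + 1
        if self.extent_bp != span:
            raise ValueError(
                f"{self.name}: extent_bp {self.extent_bp} != inclusive span {span} "
                "(last - first + 1)"
            )

    @property
    def start(self) -> int:
        return self.snp_positions[0]

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


@dataclass(frozen=True)
class LocusScreenStats:
    """Screening statistics for one candidate locus."""

    locus: MicrohapLocus
    ae: float
    het: float

    def __post_init__(self):
        if self.ae < 1.0:
            raise ValueError(f"{self.locus.name}: Ae {self.ae} < 1")
        if not (0.0 <= self.het <= 1.0):
            raise ValueError(f"{self.locus.name}: heterozygosity {self.het} outside [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.locus.n_snps


@dataclass(frozen=True)
class Panel:
    loci: tuple[MicrohapLocus, ...]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("panel locus names must be unique")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)


def filter_candidates(
    stats: Sequence[LocusScreenStats],
    max_extent_bp: int = 100,
    min_ae: float = 3.00,
    min_het: float = 0.65,
    min_spacing_bp: int = 5_000_000,
    label: str = "filtered",
) -> Panel:
    """Apply the candidate-selection rules and return the retained panel.

    All numeric criteria are strict, mirroring their verbal statement:
    ``extent < max_extent_bp``, ``ae > min_ae``, ``het > min_het`` and
    same-chromosome spacing (between locus start coordinates) ``>
    min_spacing_bp``. Spacing conflicts are resolved greedily in position
    order, keeping the higher-Ae locus of a conflicting pair.
    """
    passing = [
        s
        for s in stats
        if s.n_snps >= 2 and s.locus.extent_bp < max_extent_bp and s.ae > min_ae and s.het > min_het
    ]

    by_chrom: dict[str, list[LocusScreenStats]] = {}
    for s in passing:
        by_chrom.setdefault(s.locus.chromosome, []).append(s)

    kept: list[LocusScreenStats] = []
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        chain: list[LocusScreenStats] = []
        for s in sorted(by_chrom[chrom], key=lambda s: s.locus.start):
            chain.append(s)
            # resolve conflicts with earlier survivors: keep the higher-Ae
            # locus, then re-check the survivor against its new predecessor
            while len(chain) >= 2 and chain[-1].locus.start - chain[-2].locus.start <= min_spacing_bp:
                # on an Ae tie max() keeps the earlier (positionally first) locus
                chain[-2:] = [max(chain[-2:], key=lambda s: s.ae)]
        kept.extend(chain)

    kept.sort(key=lambda s: (int(s.locus.chromosome), s.locus.start))
    return Panel(tuple(s.locus for s in kept), label=label)


def snp_frequencies_differ(minor_allele_freqs: Sequence[float], tol: float = 0.01) -> bool:
    """Optional screening predicate: are the per-SNP minor-allele frequencies
    within one locus pairwise different (by more than ``tol``)?"""
    mafs = sorted(minor_allele_freqs)
    return all(b - a > tol for a, b in zip(mafs, mafs[1:]))


def extract_microhap_genotypes(vcf, locus: MicrohapLocus) -> dict[str, tuple[str, str]]:
    """Extract per-sample microhaplotype allele pairs from a phased VCF.

    For each sample the allele characters at ``locus.snp_positions`` are
    concatenated along each of the two phased haplotype columns in genomic
    order; the pair is returned lexicographically ordered. Only biallelic-SNP
    records are accepted, every listed position must be present (no
    imputation), and every genotype must be phased.

    ``vcf`` is a path to a VCF (plain or bgzipped) or an open
    ``pysam.VariantFile``.
    """
    import pysam

    opened = None
    if isinstance(vcf, (str, bytes)) or hasattr(vcf, "__fspath__"):
        opened = pysam.VariantFile(str(vcf))
        vf = opened
    else:
        vf = vcf
    try:
        wanted = set(locus.snp_positions)
        records: dict[int, "pysam.VariantRecord"] = {}
        contigs = {locus.chromosome, f"chr{locus.chromosome}"}
        for rec in vf:
            if rec.chrom in contigs and rec.pos in wanted:
                records[rec.pos] = rec

        missing = wanted - set(records)
        if missing:
            raise ValueError(
                f"{locus.name}: no variant record at position(s) {sorted(missing)} "
                f"on chromosome {locus.chromosome}"
            )

        samples = list(vf.header.samples)
        haps: dict[str, list[list[str]]] = {s: [[], []] for s in samples}
        for pos in locus.snp_positions:  # genomic order
            rec = records[pos]
            for alle in rec.alleles:
                if alle is None or len(alle) != 1 or alle not in "ACGT":
                    raise ValueError(
                        f"{locus.name}: non-SNP allele {alle!r} at position {pos}"
                    )
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError(f"{locus.name}: missing genotype for sample {s} at {pos}")
                if gt[0] != gt[1] and not call.phased:
                    raise ValueError(
                        f"{locus.name}: unphased genotype for sample {s} at position {pos}"
                    )
                for h in (0, 1):
                    haps[s][h].append(rec.alleles[gt[h]])

        return {s: tuple(sorted("".join(h) for h in pair)) for s, pair in haps.items()}
    finally:
        if opened is not None:
            opened.close()
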