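"""File formats, packaged reference tables and report writers.

All delimited formats are comma-separated UTF-8 with a mandatory header row:

* panel file: ``name,chromosome,positions,rsids,extent_bp`` with "/"-separated
  positions and rsIDs;
* frequency table: ``locus,allele,frequency[,population]``;
* genotype table: ``sample,locus,allele1,allele2`` (alleles ordered);
* pair file: ``replicate,locus,a1_member1,a2_member1,a1_member2,a2_member2``.

Two reference tables ship with the package: the 36-locus microhaplotype panel
definition and the 29-locus allele-frequency table (with the published
per-locus PD/PE/Ho/Ae values) for 96 unrelated Shandong Han individuals.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import MicrohapLocus, Panel
from .popgen import (
    AlleleFrequencySet,
    CombinedPower,
    combined_powers,
    effective_alleles,
    power_of_discrimination,
    power_of_exclusion,
)
from .sim import GenotypePair

logger = logging.getLogger(__name__)

__all__ = [
    "load_panel",
    "write_panel",
    "load_frequency_table",
    "load_frequency_tables",
    "write_frequency_table",
    "load_genotype_table",
    "write_genotype_table",
    "write_pairs",
    "read_pairs",
    "reference_panel",
    "reference_frequencies",
    "reference_forensics",
    "population_ae_matrix",
    "synthetic_str_frequencies",
    "forensics_report",
]


def _data_path(name: str):
    return resources.files("microkin").joinpath("data", name)


# ---------------------------------------------------------------------------
# Panel files


def load_panel(path, label: str = "") -> Panel:
    df = pd.read_csv(path, dtype=str)
    loci = [
        MicrohapLocus(
            name=r["name"],
            chromosome=str(r["chromosome"]),
            snp_positions=tuple(int(p) for p in r["positions"].split("/")),
            rsids=tuple(r["rsids"].split("/")),
            extent_bp=int(r["extent_bp"]),
        )
        for _, r in df.iterrows()
    ]
    return Panel(tuple(loci), label=label or str(path))


def write_panel(panel: Panel, path) -> None:
    pd.DataFrame(
        {
            "name": [l.name for l in panel],
            "chromosome": [l.chromosome for l in panel],
            "positions": ["/".join(map(str, l.snp_positions)) for l in panel],
            "rsids": ["/".join(l.rsids) for l in panel],
            "extent_bp": [l.extent_bp for l in panel],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Frequency tables


def _freq_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"locus": str, "allele": str})
    if df.empty:
        raise ValueError(f"empty frequency table: {path}")
    if "population" not in df.columns:
        df["population"] = ""
    dup = df.duplicated(subset=["locus", "allele", "population"])
    if dup.any():
        raise ValueError(f"duplicate (locus, allele, population) rows in {path}")
    bad = df[(df["frequency"] <= 0) | (df["frequency"] > 1)]
    if not bad.empty:
        raise ValueError(f"frequencies outside (0, 1] in {path}: {bad.to_dict('records')[:3]}")
    return df


def load_frequency_tables(path) -> dict[str, dict[str, AlleleFrequencySet]]:
    """Load a frequency table into {population: {locus: AlleleFrequencySet}},
    renormalising each locus column (the adjustment is logged)."""
    df = _freq_frame(path)
    out: dict[str, dict[str, AlleleFrequencySet]] = {}
    for (pop, locus), sub in df.groupby(["population", "locus"], sort=True):
        out.setdefault(pop, {})[locus] = AlleleFrequencySet.from_raw(
            locus, dict(zip(sub["allele"], sub["frequency"])), population=pop
        )
    return out


def load_frequency_table(path, population: str | None = None) -> dict[str, AlleleFrequencySet]:
    """Load one population's per-locus frequency sets.

    If the file holds several populations, ``population`` must name one.
    """
    tables = load_frequency_tables(path)
    if population is None:
        if len(tables) != 1:
            raise ValueError(f"multiple populations in {path}: {sorted(tables)}; pass population=")
        return next(iter(tables.values()))
    if population not in tables:
        raise KeyError(f"population {population!r} not in {path}; have {sorted(tables)}")
    return tables[population]


def write_frequency_table(freq_sets: Mapping[str, AlleleFrequencySet], path) -> None:
    rows = [
        {"locus": l, "allele": a, "frequency": f, "population": fs.population}
        for l, fs in sorted(freq_sets.items())
        for a, f in zip(fs.alleles, fs.vector())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype tables and pair files


def load_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    need = {"sample", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise ValueError(f"genotype table {path} missing columns {sorted(need - set(df.columns))}")
    return df


def write_genotype_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    swap = out["allele1"] > out["allele2"]
    out.loc[swap, ["allele1", "allele2"]] = out.loc[swap, ["allele2", "allele1"]].to_numpy()
    out.to_csv(path, index=False)


def write_pairs(pairs: Iterable[GenotypePair], path) -> int:
    """Stream simulated pairs to a delimited file; returns pairs written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("replicate,locus,a1_member1,a2_member1,a1_member2,a2_member2\n")
        for pair in pairs:
            for locus in sorted(pair.genotypes_a):
                a = pair.genotypes_a[locus]
                b = pair.genotypes_b[locus]
                fh.write(f"{pair.replicate_id},{locus},{a[0]},{a[1]},{b[0]},{b[1]}\n")
            n += 1
    return n


def read_pairs(path, relationship: str = "unknown") -> list[GenotypePair]:
    df = pd.read_csv(path, dtype={"locus": str})
    pairs = []
    for rid, sub in df.groupby("replicate", sort=True):
        ga = {r["locus"]: (r["a1_member1"], r["a2_member1"]) for _, r in sub.iterrows()}
        gb = {r["locus"]: (r["a1_member2"], r["a2_member2"]) for _, r in sub.iterrows()}
        pairs.append(GenotypePair(ga, gb, relationship, int(rid)))
    return pairs


# ---------------------------------------------------------------------------
# Packaged reference tables


def reference_panel() -> Panel:
    """The packaged 36-locus microhaplotype panel definition."""
    with resources.as_file(_data_path("panel_table1.csv")) as p:
        return load_panel(p, label="mh36")


def reference_frequencies() -> dict[str, AlleleFrequencySet]:
    """The packaged 29-locus allele-frequency table (96 Shandong Han),
    renormalised per locus."""
    with resources.as_file(_data_path("freqs_table2.csv")) as p:
        return load_frequency_table(p, population="Shandong_Han")


def reference_forensics() -> pd.DataFrame:
    """Published per-locus PD/PE/Ho/Ae for the 29 retained loci."""
    with resources.as_file(_data_path("forensics_table2.csv")) as p:
        return pd.read_csv(p, index_col="locus")


def synthetic_str_frequencies(n_loci: int = 15, seed: int = 20220811) -> dict[str, AlleleFrequencySet]:
    """Synthetic STR-like allele frequencies (8-10 repeat-number alleles per
    locus, Dirichlet-distributed) for exercising the stepwise-mutation code
    path; not real population data."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_loci):
        n_alleles = int(rng.integers(8, 11))
        start = int(rng.integers(6, 12))
        alleles = [str(start + k) for k in range(n_alleles)]
        freqs = rng.dirichlet(np.full(n_alleles, 2.0))
        freqs = np.clip(freqs, 1e-3, None)
        out[f"STR{i + 1:02d}"] = AlleleFrequencySet.from_raw(
            f"STR{i + 1:02d}", dict(zip(alleles, freqs)), population="synthetic"
        )
    return out


# ---------------------------------------------------------------------------
# Reports


def population_ae_matrix(
    per_population_freqs: Mapping[str, Mapping[str, AlleleFrequencySet]],
    panel: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, CombinedPower]]:
    """Effective-allele-number matrix (loci x populations) plus per-population
    combined powers.

    Missing (locus, population) cells are NaN and that population's combined
    powers are computed over its available loci only. Per-population PD is
    Hardy-Weinberg-expected from the frequencies and PE is derived from the
    expected heterozygosity (observed genotypes are unavailable here).
    """
    pops = sorted(per_population_freqs)
    loci = list(panel) if panel is not None else sorted({l for p in pops for l in per_population_freqs[p]})
    mat = pd.DataFrame(index=loci, columns=pops, dtype=float)
    combined: dict[str, CombinedPower] = {}
    for pop in pops:
        pds, pes = [], []
        for locus in loci:
            fs = per_population_freqs[pop].get(locus)
            if fs is None:
                continue
            mat.loc[locus, pop] = effective_alleles(fs)
            exp_het = 1.0 - float(np.sum(fs.vector() ** 2))
            pds.append(power_of_discrimination(fs, mode="hwe_expected"))
            pes.append(power_of_exclusion(exp_het))
        if pds:
            combined[pop] = combined_powers(pds, pes)
    return mat, combined


def forensics_report(
    rows: Sequence, combined: CombinedPower | None = None, path=None
) -> pd.DataFrame:
    """One row per locus (n_alleles, Ae, Ho, PD, PE); if ``path`` is given the
    CSV gains a footer row carrying the CPD/CPE complements in scientific
    notation."""
    df = pd.DataFrame(
        [
            {
                "locus": r.locus_name,
                "n_alleles": r.n_alleles,
                "ae": r.ae,
                "ho": r.ho,
                "pd": r.pd,
                "pe": r.pe,
            }
            for r in rows
        ]
    )
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            df.to_csv(fh, index=False)
            if combined is not None:
                fh.write(
                    f"# CPD = 1 - {combined.cpd_complement:.2E}; "
                    f"CPE = 1 - {combined.cpe_complement:.2E}\n"
                )
    return df
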