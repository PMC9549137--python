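"""System-power evaluation: thresholded decision metrics and uncovered rates.

Given log10-LR samples for pairs simulated under the claimed relationship
(Hp) and under the alternative (Hd), a threshold pair (t1, t2) with t1 >= t2
partitions verdicts: log10 LR strictly above t1 supports Hp, strictly below
t2 supports Hd, anything in between (boundaries included) is uncertain. The
six decision metrics are

    sensitivity   = Hp judged Hp / n_Hp
    specificity   = Hd judged Hd / n_Hd
    PPV           = Hp judged Hp / all judged Hp
    NPV           = Hd judged Hd / all judged Hd
    error rate    = (Hp judged Hd + Hd judged Hp) / (n_Hp + n_Hd)
    effectiveness = (Hp judged Hp + Hd judged Hd) / (n_Hp + n_Hd)

PPV/NPV are reported as missing (None) when their denominator is zero.

The uncovered rate (UCR) measures distributional separation without
thresholds: the fraction of Hp samples strictly above the maximum Hd sample,
and the fraction of Hd samples strictly below the minimum Hp sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .lr import INDEX_HYPOTHESES, lr_matrix
from .popgen import AlleleFrequencySet
from .sim import MutationModel, NO_MUTATION, get_relationship, simulate_study_codes

__all__ = [
    "ThresholdMetrics",
    "UcrResult",
    "PowerStudyConfig",
    "PowerReport",
    "classify",
    "threshold_metrics",
    "ucr",
    "run_power_study",
    "panel_log10_lrs_from_codes",
    "plot_lr_distributions",
]

DEFAULT_THRESHOLDS: tuple[tuple[float, float], ...] = ((1, -1), (2, -2), (3, -3), (4, -4))


def classify(log10_lr: float, t1: float, t2: float) -> str:
    """Verdict for one log10 LR: 'support_hp', 'support_hd' or 'uncertain'.

    Strict inequalities; values exactly at t1 or t2 are uncertain.
    """
    if t1 < t2:
        raise ValueError(f"t1 ({t1}) must be >= t2 ({t2})")
    if log10_lr > t1:
        return "support_hp"
    if log10_lr < t2:
        return "support_hd"
    return "uncertain"


@dataclass(frozen=True)
class ThresholdMetrics:
    """Decision metrics and their underlying tallies at one (t1, t2)."""

    t1: float
    t2: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    error_rate: float
    effectiveness: float
    counts: dict[str, int]


@dataclass(frozen=True)
class UcrResult:
    max_hd_log10lr: float
    min_hp_log10lr: float
    ucr_hp: float
    ucr_hd: float


def threshold_metrics(hp_lrs, hd_lrs, t1: float, t2: float) -> ThresholdMetrics:
    """All six decision metrics for Hp- and Hd-cohort log10-LR samples."""
    if t1 < t2:
        raise ValueError(f"t1 ({t1}) must be >= t2 ({t2})")
    hp = np.asarray(hp_lrs, dtype=float)
    hd = np.asarray(hd_lrs, dtype=float)
    if hp.size == 0 or hd.size == 0:
        raise ValueError("both cohorts must be non-empty")

    hp_as_hp = int(np.sum(hp > t1))
    hp_as_hd = int(np.sum(hp < t2))
    hd_as_hp = int(np.sum(hd > t1))
    hd_as_hd = int(np.sum(hd < t2))
    counts = {
        "hp_support_hp": hp_as_hp,
        "hp_uncertain": int(hp.size) - hp_as_hp - hp_as_hd,
        "hp_support_hd": hp_as_hd,
        "hd_support_hd": hd_as_hd,
        "hd_uncertain": int(hd.size) - hd_as_hd - hd_as_hp,
        "hd_support_hp": hd_as_hp,
    }
    total = hp.size + hd.size
    judged_hp = hp_as_hp + hd_as_hp
    judged_hd = hd_as_hd + hp_as_hd
    return ThresholdMetrics(
        t1=t1,
        t2=t2,
        sensitivity=hp_as_hp / hp.size,
        specificity=hd_as_hd / hd.size,
        ppv=hp_as_hp / judged_hp if judged_hp else None,
        npv=hd_as_hd / judged_hd if judged_hd else None,
        error_rate=(hp_as_hd + hd_as_hp) / total,
        effectiveness=(hp_as_hp + hd_as_hd) / total,
        counts=counts,
    )


def ucr(hp_lrs, hd_lrs) -> UcrResult:
    """Uncovered rates: Hp mass strictly beyond the Hd extremum and vice
    versa. -inf values participate normally."""
    hp = np.asarray(hp_lrs, dtype=float)
    hd = np.asarray(hd_lrs, dtype=float)
    if hp.size == 0 or hd.size == 0:
        raise ValueError("both cohorts must be non-empty")
    max_hd = float(np.max(hd))
    min_hp = float(np.min(hp))
    return UcrResult(
        max_hd_log10lr=max_hd,
        min_hp_log10lr=min_hp,
        ucr_hp=float(np.mean(hp > max_hd)),
        ucr_hd=float(np.mean(hd < min_hp)),
    )


# ---------------------------------------------------------------------------
# End-to-end power study


@dataclass(frozen=True)
class PowerStudyConfig:
    """One Hp-vs-Hd comparison: which index, which cohorts, how many pairs."""

    panel_freqs: Mapping[str, AlleleFrequencySet]
    index: str
    n_pairs: int = 100_000
    mutation: MutationModel = NO_MUTATION
    thresholds: Sequence[tuple[float, float]] = DEFAULT_THRESHOLDS
    seed: int | None = None

    def __post_init__(self):
        if self.index not in INDEX_HYPOTHESES:
            raise ValueError(f"unknown index {self.index!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class PowerReport:
    """Outputs of one power study; log10-LR arrays retained for plotting."""

    index: str
    hp_relationship: str
    hd_relationship: str
    n_pairs: int
    seed: int | None
    ucr: UcrResult
    metrics: tuple[ThresholdMetrics, ...]
    hp_log10_lrs: np.ndarray = field(repr=False)
    hd_log10_lrs: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-serialisable report (full precision; arrays omitted)."""
        return {
            "index": self.index,
            "hp_relationship": self.hp_relationship,
            "hd_relationship": self.hd_relationship,
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "ucr": asdict(self.ucr),
            "metrics": [asdict(m) for m in self.metrics],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def panel_log10_lrs_from_codes(
    codes_a: np.ndarray, codes_b: np.ndarray, matrices: Sequence[np.ndarray]
) -> np.ndarray:
    """Sum per-locus log10 LRs looked up from genotype-index code arrays."""
    total = np.zeros(codes_a.shape[1])
    for li, mat in enumerate(matrices):
        total += mat[codes_a[li], codes_b[li]]
    return total


def run_power_study(config: PowerStudyConfig) -> PowerReport:
    """Simulate both cohorts, compute the matching index and evaluate power.

    The Hp cohort is simulated under the index's claimed relationship and the
    Hd cohort under its alternative (unrelated, or half-sibling for FHSI).
    Fully reproducible given ``config.seed``: cohort RNG streams are spawned
    from one seed sequence.
    """
    hp_label, hd_label = INDEX_HYPOTHESES[config.index]
    loci = sorted(config.panel_freqs)
    freq_sets = [config.panel_freqs[l] for l in loci]

    ss = np.random.SeedSequence(config.seed)
    hp_ss, hd_ss = ss.spawn(2)
    hp_a, hp_b = simulate_study_codes(
        hp_label, freq_sets, config.mutation, config.n_pairs, np.random.default_rng(hp_ss)
    )
    hd_a, hd_b = simulate_study_codes(
        hd_label, freq_sets, config.mutation, config.n_pairs, np.random.default_rng(hd_ss)
    )

    matrices = [lr_matrix(config.index, f, config.mutation) for f in freq_sets]
    hp_lrs = panel_log10_lrs_from_codes(hp_a, hp_b, matrices)
    hd_lrs = panel_log10_lrs_from_codes(hd_a, hd_b, matrices)

    metrics = tuple(threshold_metrics(hp_lrs, hd_lrs, t1, t2) for t1, t2 in config.thresholds)
    return PowerReport(
        index=config.index,
        hp_relationship=hp_label,
        hd_relationship=hd_label,
        n_pairs=config.n_pairs,
        seed=config.seed,
        ucr=ucr(hp_lrs, hd_lrs),
        metrics=metrics,
        hp_log10_lrs=hp_lrs,
        hd_log10_lrs=hd_lrs,
    )


def plot_lr_distributions(report: PowerReport, ax=None, bins: int = 80):
    """Overlaid histograms of the Hp and Hd log10-LR distributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    finite_hp = report.hp_log10_lrs[np.isfinite(report.hp_log10_lrs)]
    finite_hd = report.hd_log10_lrs[np.isfinite(report.hd_log10_lrs)]
    ax.hist(finite_hp, bins=bins, alpha=0.6, density=True,
            label=f"Hp: {report.hp_relationship}")
    ax.hist(finite_hd, bins=bins, alpha=0.6, density=True,
            label=f"Hd: {report.hd_relationship}")
    ax.set_xlabel(f"log10 {report.index}")
    ax.set_ylabel("density")
    ax.legend()
    return ax
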