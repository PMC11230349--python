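"""Partition-shuffle null models for the SNR statistic.

The null hypothesis destroyed here is the alignment between the a-priori
communities and the graph topology: node labels are permuted uniformly at
random, which preserves the community-size multiset Omega (and hence P)
exactly while randomizing sigma. The graph itself is never rewired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Partition, WeightedConnectome
from .threshold import SNRProfile, ThresholdGrid, optimal_threshold, snr_profile

__all__ = ["NullEnsemble", "shuffle_partition", "null_snr_distribution", "snr_ordering_report"]


def shuffle_partition(partition: Partition, rng: np.random.Generator) -> Partition:
    """Uniformly random permutation of the label vector; Omega is preserved."""
    sigma = rng.permutation(partition.sigma)
    return Partition(sigma=sigma, k=partition.k, omega=partition.omega.copy(), labels=partition.labels)


@dataclass
class NullEnsemble:
    """SNR profiles under repeated size-preserving partition shuffles."""

    profiles: list[SNRProfile]
    seed: int
    mode: str

    @property
    def n_shuffles(self) -> int:
        return len(self.profiles)

    @property
    def taus(self) -> np.ndarray:
        return self.profiles[0].taus

    @property
    def snr_matrix(self) -> np.ndarray:
        """(n_shuffles, n_taus) array of null SNR values."""
        return np.vstack([p.snr for p in self.profiles])

    @property
    def max_snr(self) -> float:
        """Maximum null SNR over all shuffles and thresholds."""
        return float(self.snr_matrix.max())

    def summary(self) -> pd.DataFrame:
        m = self.snr_matrix
        return pd.DataFrame(
            {
                "tau": self.taus,
                "min": m.min(axis=0),
                "median": np.median(m, axis=0),
                "max": m.max(axis=0),
                "n_shuffles": self.n_shuffles,
                "seed": self.seed,
            }
        )


def null_snr_distribution(
    fc: WeightedConnectome,
    partition: Partition,
    grid: ThresholdGrid | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
    mode: str = "binary",
    positive_only: bool = False,
    cmax_convention: str = "pairs",
) -> NullEnsemble:
    """SNR profiles for ``n_shuffles`` independent label shuffles.

    Deterministic given ``seed``. Binary mode is the default used for the
    comparison against the weak-recovery hard threshold SNR = 1.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    grid = grid or ThresholdGrid()
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_shuffles):
        perm = shuffle_partition(partition, rng)
        profiles.append(
            snr_profile(
                fc,
                perm,
                grid=grid,
                mode=mode,
                source=f"null-{i + 1}",
                positive_only=positive_only,
                cmax_convention=cmax_convention,
            )
        )
    return NullEnsemble(profiles=profiles, seed=seed, mode=mode)


@dataclass
class OrderingReport:
    """Verdict on the empirical SNR ordering null < conditions at their optima."""

    null_max: float
    condition_peaks: dict[str, tuple[float, float]]  # name -> (tau_opt, snr_at_opt)
    null_below_all: bool
    ordering: list[str]  # condition names sorted by peak SNR ascending
    ties: list[tuple[str, str]] = field(default_factory=list)

    def holds(self, *names: str) -> bool:
        """True if the named conditions appear in strictly increasing peak-SNR
        order and all exceed the null maximum."""
        peaks = [self.condition_peaks[n][1] for n in names]
        return self.null_below_all and all(a < b for a, b in zip(peaks, peaks[1:]))

    def __str__(self) -> str:
        parts = [f"max null SNR = {self.null_max:.4g}"]
        for name in self.ordering:
            tau, s = self.condition_peaks[name]
            parts.append(f"{name}: peak SNR {s:.4g} at tau = {tau:.2f}")
        parts.append("null below all conditions: " + ("yes" if self.null_below_all else "NO"))
        if self.ties:
            parts.append("ties: " + ", ".join(f"{a}~{b}" for a, b in self.ties))
        return "\n".join(parts)


def snr_ordering_report(
    condition_profiles: dict[str, SNRProfile], null: NullEnsemble | None = None
) -> OrderingReport:
    """Compare condition SNR peaks against each other and the null maximum.

    All profiles must share the threshold grid. Equal peaks are reported as
    ties rather than an error.
    """
    names = list(condition_profiles)
    if null is not None and names:
        ref = condition_profiles[names[0]].taus
        if not np.array_equal(ref, null.taus):
            raise ValueError("null ensemble grid differs from condition grids")
    for a, b in zip(names, names[1:]):
        if not np.array_equal(condition_profiles[a].taus, condition_profiles[b].taus):
            raise ValueError("condition profiles do not share a grid")
    peaks = {}
    for name, prof in condition_profiles.items():
        tau, _ = optimal_threshold(prof)
        peaks[name] = (tau, float(prof.snr.max()))
    null_max = null.max_snr if null is not None else 0.0
    ordering = sorted(peaks, key=lambda n: peaks[n][1])
    ties = [
        (a, b)
        for a, b in zip(ordering, ordering[1:])
        if peaks[a][1] == peaks[b][1]
    ]
    below = all(null_max < s for _, s in peaks.values()) if peaks else null_max > 0
    return OrderingReport(
        null_max=null_max,
        condition_peaks=peaks,
        null_below_all=below,
        ordering=ordering,
        ties=ties,
    )
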