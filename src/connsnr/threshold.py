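"""Four-step threshold-vetting pipeline for cohorts of functional connectomes.

Step 1 averages individual connectomes into a group representation and sweeps
a threshold grid over its binarized version; Step 2 derives the
weak-recoverability sub-interval [a_w, b_w] (thresholds where the binary SNR
of the group average exceeds 1); Step 3 computes the weighted SNR prominence
profile for the group average and each subject; Step 4 picks the
SNR-maximizing threshold per source and checks membership in [a_w, b_w].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import BinaryConnectome, Cohort, Partition, WeightedConnectome, validate_cohort
from .sbm import SnrValue, block_counts, infer_sbm, snr

__all__ = [
    "ThresholdGrid",
    "SNRProfile",
    "TopologyProfile",
    "WeakInterval",
    "ReconReport",
    "group_average",
    "threshold_graph",
    "snr_profile",
    "weak_recoverability_interval",
    "optimal_threshold",
    "topology_profile",
    "recon_fc",
]


@dataclass
class ThresholdGrid:
    """Strictly increasing threshold values in [0, 1]; default step 0.05."""

    taus: np.ndarray = None
    step: float = 0.05

    def __post_init__(self) -> None:
        if self.taus is None:
            n = int(round(1.0 / self.step))
            self.taus = np.round(np.linspace(0.0, 1.0, n + 1), 10)
        self.taus = np.asarray(self.taus, dtype=float)
        if self.taus.size > 1:
            self.step = float(np.median(np.diff(self.taus)))
        if self.taus.size == 0:
            raise ValueError("empty threshold grid")
        if (np.diff(self.taus) <= 0).any():
            raise ValueError("threshold grid must be strictly increasing")
        if self.taus[0] < 0 or self.taus[-1] > 1:
            raise ValueError("thresholds must lie in [0, 1]")

    def __len__(self) -> int:
        return self.taus.size

    @classmethod
    def with_step(cls, step: float) -> "ThresholdGrid":
        return cls(taus=None, step=step)


@dataclass
class SNRProfile:
    """SNR as a function of threshold for one source (group average or subject)."""

    taus: np.ndarray
    snr: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    mode: str
    source: str = "group_average"

    def __post_init__(self) -> None:
        for arr in ("snr", "lambda1", "lambda2"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        self.taus = np.asarray(self.taus, dtype=float)
        if not (self.taus.size == self.snr.size == self.lambda1.size == self.lambda2.size):
            raise ValueError("profile arrays must share length")

    def values(self) -> list[SnrValue]:
        return [SnrValue(s, l1, l2) for s, l1, l2 in zip(self.snr, self.lambda1, self.lambda2)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source,
                "mode": self.mode,
                "tau": self.taus,
                "snr": self.snr,
                "lambda1": self.lambda1,
                "lambda2": self.lambda2,
            }
        )


def group_average(cohort: Cohort) -> WeightedConnectome:
    """Entrywise arithmetic mean of the cohort's signed couplings (diagonal 0).

    Signs may cancel: members +0.5 and -0.5 average to 0 before any
    thresholding. No Fisher-z transform is applied.
    """
    mean = np.mean([c.weights for c in cohort.connectomes], axis=0)
    np.fill_diagonal(mean, 0.0)
    return WeightedConnectome(weights=mean, node_ids=list(cohort.node_ids))


def threshold_graph(fc: WeightedConnectome, tau: float, mode: str = "binary", positive_only: bool = False):
    """Threshold a connectome at tau, keeping pairs with |w| > tau (strict).

    ``positive_only=True`` keeps w > tau instead (sensitivity analysis).
    Binary mode returns the adjacency of retained pairs; weighted mode keeps
    the retained *signed* weights (magnitudes are taken later, when block
    statistics are accumulated).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep = (fc.weights > tau) if positive_only else (np.abs(fc.weights) > tau)
    np.fill_diagonal(keep, False)
    if mode == "binary":
        return BinaryConnectome(adjacency=keep.astype(np.int8), node_ids=list(fc.node_ids))
    if mode == "weighted":
        return WeightedConnectome(weights=np.where(keep, fc.weights, 0.0), node_ids=list(fc.node_ids))
    raise ValueError(f"unknown mode {mode!r}")


def snr_profile(
    fc: WeightedConnectome,
    partition: Partition,
    grid: ThresholdGrid | None = None,
    mode: str = "binary",
    source: str = "group_average",
    positive_only: bool = False,
    cmax_convention: str = "pairs",
) -> SNRProfile:
    """SNR of the thresholded connectome at every grid point.

    Per tau: threshold -> block counts -> SBM inference -> SNR of PQ.
    """
    grid = grid or ThresholdGrid()
    snrs, l1s, l2s = [], [], []
    for tau in grid.taus:
        g = threshold_graph(fc, float(tau), mode=mode, positive_only=positive_only)
        val = snr(infer_sbm(block_counts(g, partition, cmax_convention), fc.n))
        snrs.append(val.snr)
        l1s.append(val.lambda1)
        l2s.append(val.lambda2)
    return SNRProfile(taus=grid.taus.copy(), snr=snrs, lambda1=l1s, lambda2=l2s, mode=mode, source=source)


@dataclass
class WeakInterval:
    """Threshold sub-interval over which binary SNR exceeds 1."""

    a: float
    b: float
    contiguous: bool = True

    def __contains__(self, tau: float) -> bool:
        return self.a - 1e-12 <= tau <= self.b + 1e-12

    def as_tuple(self) -> tuple[float, float]:
        return (self.a, self.b)


def weak_recoverability_interval(profile: SNRProfile) -> WeakInterval | None:
    """[a_w, b_w]: the smallest and largest grid thresholds with SNR > 1.

    Returns None when no grid point crosses the Kesten-Stigum threshold. A
    non-contiguous super-threshold set is reported as (min, max) with
    ``contiguous=False``.
    """
    if profile.mode != "binary":
        raise ValueError("vetting interval is defined on the binarized group average")
    above = np.flatnonzero(profile.snr > 1.0)
    if above.size == 0:
        return None
    contiguous = bool(above.size == above[-1] - above[0] + 1)
    return WeakInterval(a=float(profile.taus[above[0]]), b=float(profile.taus[above[-1]]), contiguous=contiguous)


def optimal_threshold(profile: SNRProfile) -> tuple[float, bool]:
    """Grid argmax of SNR; ties break toward the smallest tau.

    Returns ``(tau_opt, degenerate)`` where ``degenerate`` flags an all-zero
    profile (tau_opt then defaults to the smallest grid point).
    """
    if profile.taus.size == 0:
        raise ValueError("empty profile")
    idx = int(np.argmax(profile.snr))  # first maximum = smallest tau
    degenerate = bool(np.all(profile.snr == 0.0))
    return float(profile.taus[idx]), degenerate


@dataclass
class TopologyProfile:
    """Per-threshold density and connected-component count."""

    taus: np.ndarray
    density: np.ndarray
    components: np.ndarray
    source: str = "group_average"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"source": self.source, "tau": self.taus, "density": self.density, "components": self.components}
        )


def topology_profile(
    fc: WeightedConnectome,
    grid: ThresholdGrid | None = None,
    positive_only: bool = False,
    source: str = "group_average",
) -> TopologyProfile:
    """Density (retained pairs / all pairs) and component count per threshold."""
    grid = grid or ThresholdGrid()
    n = fc.n
    npairs = n * (n - 1) / 2.0
    dens, comps = [], []
    for tau in grid.taus:
        g = threshold_graph(fc, float(tau), mode="binary", positive_only=positive_only)
        dens.append(g.n_edges / npairs)
        ncomp, _ = connected_components(csr_matrix(g.adjacency), directed=False)
        comps.append(ncomp)
    return TopologyProfile(
        taus=grid.taus.copy(), density=np.asarray(dens), components=np.asarray(comps, dtype=int), source=source
    )


@dataclass
class ReconReport:
    """Everything the four-step pipeline produces for one cohort."""

    weak_interval: WeakInterval | None
    tau_opt_ga: float
    tau_opt_individual: dict[str, float]
    vetting_pass: dict[str, bool]
    profiles: list[SNRProfile]
    topology: list[TopologyProfile]
    degenerate_sources: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def mean_individual_tau_opt(self) -> float:
        return float(np.mean(list(self.tau_opt_individual.values())))

    def profiles_frame(self) -> pd.DataFrame:
        frames = [p.to_frame() for p in self.profiles]
        topo = pd.concat([t.to_frame() for t in self.topology], ignore_index=True)
        prof = pd.concat(frames, ignore_index=True)
        return prof.merge(topo, on=["source", "tau"], how="left")

    def to_dict(self) -> dict:
        return {
            "weak_interval": None if self.weak_interval is None else list(self.weak_interval.as_tuple()),
            "weak_interval_contiguous": None if self.weak_interval is None else self.weak_interval.contiguous,
            "tau_opt_ga": self.tau_opt_ga,
            "tau_opt_individual": self.tau_opt_individual,
            "vetting_pass": self.vetting_pass,
            "degenerate_sources": self.degenerate_sources,
            "config": self.config,
        }


def recon_fc(
    cohort: Cohort,
    partition: Partition,
    grid: ThresholdGrid | None = None,
    positive_only: bool = False,
    cmax_convention: str = "pairs",
    mask: str | None = None,
    include_subject_topology: bool = False,
) -> ReconReport:
    """Run the full group-average/vetting/prominence/optimization pipeline.

    Parameters
    ----------
    mask : {None, "group_average"}
        With ``"group_average"``, each subject's connectome is restricted to
        the support of the thresholded group average before its own profile is
        computed; by default subjects are thresholded on their own entries.
    """
    if mask not in (None, "group_average"):
        raise ValueError(f"unknown mask mode {mask!r}")
    grid = grid or ThresholdGrid()
    validate_cohort(cohort, partition)
    ga = group_average(cohort)

    kw = dict(grid=grid, positive_only=positive_only, cmax_convention=cmax_convention)
    # Steps 1-2: binarized group average and its weak-recoverability interval
    ga_bin_profile = snr_profile(ga, partition, mode="binary", source="group_average", **kw)
    interval = weak_recoverability_interval(ga_bin_profile)

    # Step 3: weighted prominence for the group average and each subject
    ga_wei_profile = snr_profile(ga, partition, mode="weighted", source="group_average", **kw)
    subj_profiles = []
    for sid, conn in zip(cohort.subject_ids, cohort.connectomes):
        if mask == "group_average":
            subj_profiles.append(
                _masked_snr_profile(conn, ga, partition, grid, positive_only, cmax_convention, source=sid)
            )
        else:
            subj_profiles.append(snr_profile(conn, partition, mode="weighted", source=sid, **kw))

    # Step 4: optima and vetting membership
    degenerate = []
    tau_opt_ga, deg = optimal_threshold(ga_wei_profile)
    if deg:
        degenerate.append("group_average")
    tau_opt_ind, vetting = {}, {}
    vetting["group_average"] = interval is not None and tau_opt_ga in interval
    for prof in subj_profiles:
        t, deg = optimal_threshold(prof)
        tau_opt_ind[prof.source] = t
        vetting[prof.source] = interval is not None and t in interval
        if deg:
            degenerate.append(prof.source)

    topo = [topology_profile(ga, grid, positive_only, source="group_average")]
    if include_subject_topology:
        topo += [
            topology_profile(c, grid, positive_only, source=sid)
            for sid, c in zip(cohort.subject_ids, cohort.connectomes)
        ]
    return ReconReport(
        weak_interval=interval,
        tau_opt_ga=tau_opt_ga,
        tau_opt_individual=tau_opt_ind,
        vetting_pass=vetting,
        profiles=[ga_bin_profile, ga_wei_profile] + subj_profiles,
        topology=topo,
        degenerate_sources=degenerate,
        config={
            "grid_step": float(grid.step),
            "positive_only": positive_only,
            "cmax_convention": cmax_convention,
            "mask": mask,
        },
    )


def _masked_snr_profile(
    conn: WeightedConnectome,
    ga: WeightedConnectome,
    partition: Partition,
    grid: ThresholdGrid,
    positive_only: bool,
    cmax_convention: str,
    source: str,
) -> SNRProfile:
    """Weighted subject profile under the group-average mask: at each tau the
    subject keeps its signed weights on exactly the pairs where the group
    average survives the threshold."""
    snrs, l1s, l2s = [], [], []
    for tau in grid.taus:
        keep = (ga.weights > tau) if positive_only else (np.abs(ga.weights) > tau)
        np.fill_diagonal(keep, False)
        masked = WeightedConnectome(
            weights=np.where(keep, conn.weights, 0.0), node_ids=list(conn.node_ids)
        )
        val = snr(infer_sbm(block_counts(masked, partition, cmax_convention), conn.n))
        snrs.append(val.snr)
        l1s.append(val.lambda1)
        l2s.append(val.lambda2)
    return SNRProfile(taus=grid.taus.copy(), snr=snrs, lambda1=l1s, lambda2=l2s, mode="weighted", source=source)
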