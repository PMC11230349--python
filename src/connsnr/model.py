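"""Model/Results presentation layer.

`PartitionedSBM` fits the closed-form block model for one graph and a fixed
a-priori partition; `ConnectomeThreshold` runs the full cohort-level
threshold-vetting pipeline. Both follow the fit()-returns-Results idiom:
estimates, diagnostics and a summary() table live on the Results object, and
simulation (`ConnectomeThreshold.from_simulation`) and plotting hang off the
model and results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BinaryConnectome, Cohort, Partition, WeightedConnectome, validate_cohort
from .nulls import NullEnsemble, null_snr_distribution
from .sbm import BlockCounts, SBMParams, SnrValue, block_counts, infer_sbm, snr
from .threshold import ReconReport, ThresholdGrid, recon_fc
from .simulate import SimConfig, simulate_fc_cohort

__all__ = ["PartitionedSBM", "PartitionedSBMResults", "ConnectomeThreshold", "ConnectomeThresholdResults"]


class PartitionedSBM:
    """Stochastic block model with a fixed (a-priori) partition.

    Parameters
    ----------
    graph : BinaryConnectome or WeightedConnectome
        Binary graphs yield edge-probability blocks; weighted graphs yield
        mean-|coupling| blocks (the prominence extension).
    partition : Partition
        Node-to-community assignment sharing the graph's node order.
    cmax_convention : {"pairs", "literal"}
    """

    def __init__(self, graph, partition: Partition, cmax_convention: str = "pairs"):
        if graph.n != partition.n:
            raise ValueError("graph and partition disagree on node count")
        self.graph = graph
        self.partition = partition
        self.cmax_convention = cmax_convention

    def fit(self) -> "PartitionedSBMResults":
        counts = block_counts(self.graph, self.partition, self.cmax_convention)
        params = infer_sbm(counts, self.graph.n)
        return PartitionedSBMResults(model=self, counts=counts, params=params, snr_=snr(params))


@dataclass
class PartitionedSBMResults:
    """Inferred (p, W, Q, PQ) and the Kesten-Stigum SNR for one graph."""

    model: PartitionedSBM
    counts: BlockCounts
    params: SBMParams
    snr_: SnrValue

    @property
    def snr(self) -> float:
        return self.snr_.snr

    @property
    def weakly_recoverable(self) -> bool:
        """SNR > 1: weak recovery of the planted communities is efficiently solvable."""
        return self.snr > 1.0

    def summary(self) -> str:
        p = self.params
        lines = [
            "Partitioned SBM fit",
            "===================",
            f"nodes: {p.n}    communities: {p.k}    mode: {p.mode}",
            f"community sizes: {self.counts.omega.tolist()}",
            f"lambda1 = {self.snr_.lambda1:.6g}    lambda2 = {self.snr_.lambda2:.6g}",
            f"SNR = lambda2^2/lambda1 = {self.snr:.6g}"
            + ("  (> 1: weakly recoverable)" if self.weakly_recoverable else "  (<= 1)"),
            "",
            "block connectivity W (rows/cols = communities):",
            np.array2string(p.w, precision=4, suppress_small=True),
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        blob = json.dumps(
            {"params": self.params.to_dict(), "snr": self.snr, "lambda1": self.snr_.lambda1, "lambda2": self.snr_.lambda2},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(blob)
        return blob


class ConnectomeThreshold:
    """SNR-guided threshold selection for a cohort of functional connectomes.

    Wraps the four-step pipeline: group-average, binary vetting sweep,
    weighted prominence profiles (group + subjects), optimum + membership
    check against the weak-recoverability interval.
    """

    def __init__(
        self,
        cohort: Cohort,
        partition: Partition,
        grid: ThresholdGrid | None = None,
        positive_only: bool = False,
        cmax_convention: str = "pairs",
        mask: str | None = None,
    ):
        self.cohort = cohort
        self.partition = partition
        self.grid = grid or ThresholdGrid()
        self.positive_only = positive_only
        self.cmax_convention = cmax_convention
        self.mask = mask
        validate_cohort(cohort, partition)

    @classmethod
    def from_simulation(cls, cfg: SimConfig | None = None, split: int = 1, **kwargs) -> "ConnectomeThreshold":
        """Build the model from a simulated planted-partition cohort."""
        cohort, partition = simulate_fc_cohort(cfg or SimConfig(), split=split)
        return cls(cohort, partition, **kwargs)

    def fit(self, include_subject_topology: bool = False) -> "ConnectomeThresholdResults":
        report = recon_fc(
            self.cohort,
            self.partition,
            grid=self.grid,
            positive_only=self.positive_only,
            cmax_convention=self.cmax_convention,
            mask=self.mask,
            include_subject_topology=include_subject_topology,
        )
        return ConnectomeThresholdResults(model=self, report=report)

    def null_distribution(self, n_shuffles: int = 100, seed: int = 0, mode: str = "binary") -> NullEnsemble:
        """Partition-shuffle null SNR ensemble on the group average."""
        from .threshold import group_average

        return null_snr_distribution(
            group_average(self.cohort),
            self.partition,
            grid=self.grid,
            n_shuffles=n_shuffles,
            seed=seed,
            mode=mode,
            positive_only=self.positive_only,
            cmax_convention=self.cmax_convention,
        )


@dataclass
class ConnectomeThresholdResults:
    """Results of the cohort threshold search."""

    model: ConnectomeThreshold
    report: ReconReport

    @property
    def weak_interval(self):
        return self.report.weak_interval

    @property
    def tau_opt(self) -> float:
        return self.report.tau_opt_ga

    @property
    def tau_opt_individual(self) -> dict[str, float]:
        return self.report.tau_opt_individual

    def reconstructed(self, source: str = "group_average") -> WeightedConnectome:
        """The connectome thresholded at its own optimal threshold."""
        from .threshold import group_average, threshold_graph

        if source == "group_average":
            fc, tau = group_average(self.model.cohort), self.report.tau_opt_ga
        else:
            idx = self.model.cohort.subject_ids.index(source)
            fc = self.model.cohort.connectomes[idx]
            tau = self.report.tau_opt_individual[source]
        return threshold_graph(fc, tau, mode="weighted", positive_only=self.model.positive_only)

    def profiles_frame(self) -> pd.DataFrame:
        return self.report.profiles_frame()

    def summary(self) -> str:
        r = self.report
        iv = r.weak_interval
        ind = np.array(list(r.tau_opt_individual.values()))
        lines = [
            "SNR-guided connectome threshold search",
            "======================================",
            f"subjects: {self.model.cohort.gamma}    nodes: {self.model.cohort.n}    "
            f"communities: {self.model.partition.k}",
            f"grid: [{r.profiles[0].taus[0]:.2f}, {r.profiles[0].taus[-1]:.2f}] step {r.config['grid_step']:.2f}",
            (
                f"weak-recoverability interval [a_w, b_w] = [{iv.a:.2f}, {iv.b:.2f}]"
                + ("" if iv.contiguous else "  (warning: non-contiguous SNR>1 set)")
                if iv is not None
                else "weak-recoverability interval: none (binary SNR never exceeds 1)"
            ),
            f"tau_opt (group average, weighted SNR) = {r.tau_opt_ga:.2f}"
            + ("  [inside interval]" if r.vetting_pass.get("group_average") else "  [VETTING FAILED]"),
        ]
        if ind.size:
            inside = sum(r.vetting_pass[s] for s in r.tau_opt_individual)
            lines += [
                f"individual tau_opt: mean {ind.mean():.3f}, median {np.median(ind):.2f}, "
                f"range [{ind.min():.2f}, {ind.max():.2f}]",
                f"individual optima inside [a_w, b_w]: {inside}/{ind.size}",
            ]
        if r.degenerate_sources:
            lines.append(f"degenerate (all-zero) profiles: {r.degenerate_sources}")
        return "\n".join(lines)

    def plot_profiles(self, ax=None):
        """SNR-vs-threshold plot: group average (binary + weighted) and subjects."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for prof in self.report.profiles:
            ga = prof.source == "group_average"
            ax.plot(
                prof.taus,
                prof.snr,
                lw=2.0 if ga else 0.6,
                alpha=1.0 if ga else 0.35,
                label=f"GA ({prof.mode})" if ga else None,
                color=None if ga else "gray",
            )
        iv = self.report.weak_interval
        if iv is not None:
            ax.axvspan(iv.a, iv.b, alpha=0.12, label="weak-recoverability interval")
        ax.axhline(1.0, ls="--", c="k", lw=0.8)
        ax.set_xlabel(r"threshold $\tau$")
        ax.set_ylabel("SNR")
        ax.legend(loc="best", fontsize=8)
        return ax

    def to_json(self, path=None) -> str:
        blob = json.dumps(self.report.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(blob)
        return blob
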