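"""Stochastic-block-model inference for a fixed partition and the SNR statistic.

Given a graph G and an a-priori partition sigma, the block model parameters
are inferred in closed form: p_i = Omega_i / n, W = C / C_max (entrywise),
Q = n W (constant-degree regime, scale factor s_t = 1) and the community
profile matrix PQ = n P W, whose (i, j) entry is the expected number of
community-j neighbours of a community-i node. The prominence statistic is

    SNR = lambda_2^2 / lambda_1

over the eigenvalues of PQ sorted by descending magnitude. SNR > 1 is the
Kesten-Stigum condition: weak recovery of the planted communities is
efficiently solvable above it.

Edge statistics C are accumulated over unordered node pairs u < v (the
diagonal of the connectome is zero, so self-pairs never contribute). In
weighted mode the statistic sums |w_uv|: only the magnitude of a functional
coupling counts towards block connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinaryConnectome, Partition, WeightedConnectome

__all__ = ["BlockCounts", "SBMParams", "SnrValue", "block_counts", "infer_sbm", "snr", "analytic_snr"]

#: leading eigenvalue below this is treated as "no graph signal"
LAMBDA1_FLOOR = 1e-12
#: largest tolerated imaginary part in the PQ spectrum
SPECTRUM_IMAG_TOL = 1e-8


def _cmax(omega: np.ndarray, convention: str) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    cmax = np.outer(omega, omega)
    if convention == "pairs":
        # within-community pairs are unordered and exclude self-pairs
        np.fill_diagonal(cmax, omega * (omega - 1) / 2.0)
    elif convention != "literal":
        raise ValueError(f"unknown cmax convention {convention!r}")
    return cmax


@dataclass
class BlockCounts:
    """Observed within/between-block edge statistics.

    ``c[i, j]`` is the edge count (binary mode) or sum of absolute weights
    (weighted mode) over unordered node pairs spanning communities i and j;
    ``c_max`` is the number of such pairs.
    """

    c: np.ndarray
    c_max: np.ndarray
    omega: np.ndarray
    mode: str
    cmax_convention: str = "pairs"

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "weighted"):
            raise ValueError(f"unknown mode {self.mode!r}")


def block_counts(graph, partition: Partition, cmax_convention: str = "pairs") -> BlockCounts:
    """Accumulate block edge statistics C and capacities C_max.

    Parameters
    ----------
    graph : BinaryConnectome or WeightedConnectome
    partition : Partition
        Shares the graph's node order.
    cmax_convention : {"pairs", "literal"}
        Diagonal of C_max: unordered within-community pairs Omega_i(Omega_i-1)/2
        (default) or the literal outer product Omega_i^2.
    """
    if isinstance(graph, BinaryConnectome):
        a = graph.adjacency.astype(float)
        mode = "binary"
    elif isinstance(graph, WeightedConnectome):
        a = np.abs(graph.weights)
        mode = "weighted"
    else:
        raise TypeError(f"unsupported graph type {type(graph)!r}")
    if graph.n != partition.n:
        raise ValueError(f"graph has {graph.n} nodes but partition covers {partition.n}")
    s = partition.indicator()
    full = s.T @ a @ s  # ordered-pair sums; diagonal double-counts unordered pairs
    c = full.copy()
    np.fill_diagonal(c, np.diag(full) / 2.0)
    c = (c + c.T) / 2.0
    return BlockCounts(
        c=c,
        c_max=_cmax(partition.omega, cmax_convention),
        omega=partition.omega.copy(),
        mode=mode,
        cmax_convention=cmax_convention,
    )


@dataclass
class SBMParams:
    """Closed-form SBM parameters (p, P, W, Q, PQ) for one graph/partition pair."""

    p: np.ndarray
    w: np.ndarray
    n: int
    mode: str
    st: float = 1.0

    @property
    def P(self) -> np.ndarray:
        return np.diag(self.p)

    @property
    def Q(self) -> np.ndarray:
        """Expected-degree matrix n*W (s_t = 1)."""
        return self.n * self.st * self.w

    @property
    def PQ(self) -> np.ndarray:
        """Community profile matrix n P W."""
        return self.P @ self.Q

    @property
    def k(self) -> int:
        return self.p.size

    def to_dict(self) -> dict:
        return {
            "p": self.p.tolist(),
            "W": self.w.tolist(),
            "Q": self.Q.tolist(),
            "PQ": self.PQ.tolist(),
            "n": self.n,
            "st": self.st,
            "mode": self.mode,
        }


def infer_sbm(counts: BlockCounts, n: int) -> SBMParams:
    """Infer (p, W) from block counts: p = Omega/n, W = C / C_max entrywise.

    Entries with zero capacity (the diagonal of a singleton community) use the
    0/0 -> 0 convention.
    """
    omega = np.asarray(counts.omega, dtype=float)
    if int(omega.sum()) != n:
        raise ValueError("community sizes do not sum to n")
    if (omega < 1).any():
        raise ValueError("all communities must be non-empty")
    p = omega / n
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(counts.c_max > 0, counts.c / np.where(counts.c_max > 0, counts.c_max, 1.0), 0.0)
    return SBMParams(p=p, w=w, n=n, mode=counts.mode)


@dataclass
class SnrValue:
    """SNR = lambda_2^2 / lambda_1 of the community profile matrix."""

    snr: float
    lambda1: float
    lambda2: float

    def __float__(self) -> float:
        return self.snr


def _snr_from_pq(pq: np.ndarray) -> SnrValue:
    pq = np.asarray(pq, dtype=float)
    k = pq.shape[0]
    if k == 1:
        lam1 = float(pq[0, 0])
        return SnrValue(snr=0.0, lambda1=lam1, lambda2=0.0)
    ev = np.linalg.eigvals(pq)
    if np.max(np.abs(ev.imag)) > SPECTRUM_IMAG_TOL:
        raise ValueError(
            f"community profile matrix has a complex spectrum (max imag {np.max(np.abs(ev.imag)):.3g}); "
            "PQ should be similar to a symmetric matrix"
        )
    ev = np.real(ev)
    order = np.argsort(-np.abs(ev))
    # PQ is nonnegative, so its spectral radius is itself an eigenvalue
    # (Perron); on magnitude ties (e.g. bipartite-like blocks, lambda = +/-r)
    # take the positive root as lambda_1.
    top = np.abs(ev[order[0]])
    tol = 1e-9 * max(1.0, top)
    tied = [i for i in order if np.abs(ev[i]) >= top - tol]
    i1 = max(tied, key=lambda i: ev[i])
    rest = [i for i in order if i != i1]
    lam1 = float(ev[i1])
    lam2 = float(ev[rest[0]])
    if lam1 < -SPECTRUM_IMAG_TOL:
        raise ValueError("leading eigenvalue of PQ is negative; corrupted input")
    if lam1 <= LAMBDA1_FLOOR:
        return SnrValue(snr=0.0, lambda1=lam1, lambda2=lam2)
    if abs(lam2) <= LAMBDA1_FLOOR * max(1.0, lam1):
        # rank-one PQ (e.g. complete or structureless graph): no signal
        return SnrValue(snr=0.0, lambda1=lam1, lambda2=lam2)
    return SnrValue(snr=lam2 * lam2 / lam1, lambda1=lam1, lambda2=lam2)


def snr(params: SBMParams) -> SnrValue:
    """Kesten-Stigum SNR of inferred SBM parameters.

    Degenerate inputs (single community, empty graph, vanishing leading
    eigenvalue) return SNR = 0: no mesoscopic signal.
    """
    return _snr_from_pq(params.PQ)


def analytic_snr(p, q) -> SnrValue:
    """SNR of a planted model given the probability vector p and expected-degree
    matrix Q (PQ = diag(p) Q).

    For the symmetric two-community model p = (1/2, 1/2), Q = [[a, b], [b, a]]
    this reduces to (a - b)^2 / (2 (a + b)).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 1 or q.shape != (p.size, p.size):
        raise ValueError("p must be length-k and q k-by-k")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("p must sum to 1")
    return _snr_from_pq(np.diag(p) @ q)
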