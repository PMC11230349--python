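"""Synthetic cohorts with planted assortative structure.

The generator emulates the statistical shape of Pearson functional
connectomes rather than BOLD physiology: each community i has a latent factor
signal f_i(t) over T time points, factors are correlated across communities
so that between-community couplings target ``rho_between``, and each node
mixes its community factor with private noise,

    x_u(t) = sqrt(rho_u) * f_{sigma_u}(t) + sqrt(1 - rho_u) * eps_u(t),

so that within-community couplings target ``rho_within``. The connectome is
the sample Pearson correlation matrix of the node signals with the diagonal
zeroed. Subject fingerprints are injected two ways: each subject's node
loadings rho_u are jittered, and a random subset of nodes additionally loads
on a subject-unique latent factor, producing reproducible high-magnitude
couplings that cut across the planted communities (and are damped by
group-averaging). Scan length T controls sampling noise; parcellation
refinement splits every node into m children that inherit the parent's
community and loading but carry independent private noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import BinaryConnectome, Cohort, Partition, WeightedConnectome, write_connectome, write_partition

__all__ = [
    "SimConfig",
    "make_planted_partition",
    "sample_binary_sbm",
    "simulate_fc_cohort",
    "refine_parcellation",
    "write_cohort",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate a mid-resolution cortical parcellation carrying seven
    functional networks scanned for 166 time points across 20 subjects, with
    moderate assortative contrast and a mild subject fingerprint.
    """

    n: int = 112
    k: int = 7
    sizes: tuple[int, ...] | None = None  # None -> as equal as possible
    rho_within: float = 0.40
    rho_within_sd: float = 0.10  # population spread of node loadings
    rho_between: float = 0.10
    rho_between_sd: float = 0.10  # spread of community-pair coupling levels
    T: int = 166
    gamma: int = 20
    fingerprint_sd: float = 0.05
    fingerprint_var: float = 0.06  # variance share of the subject-unique factor
    fingerprint_fraction: float = 0.3  # fraction of nodes carrying that factor
    negative_fraction: float = 0.0  # fraction of nodes with sign-flipped loading
    clone_subjects: bool = False  # all subjects share one random stream (debug)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sizes is not None:
            self.sizes = tuple(int(s) for s in self.sizes)
            if sum(self.sizes) != self.n or len(self.sizes) != self.k:
                raise ValueError("sizes must have length k and sum to n")
        if not 0.0 <= self.rho_between < self.rho_within <= 1.0:
            raise ValueError("need 0 <= rho_between < rho_within <= 1")
        if self.T < 4:
            raise ValueError("need at least 4 time points")
        if self.gamma < 1:
            raise ValueError("need at least one subject")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if not 0.0 <= self.fingerprint_var < 1.0:
            raise ValueError("fingerprint_var must lie in [0, 1)")
        if self.rho_within_sd < 0 or self.rho_between_sd < 0 or self.fingerprint_sd < 0:
            raise ValueError("spread parameters must be nonnegative")
        if not 0.0 <= self.fingerprint_fraction <= 1.0:
            raise ValueError("fingerprint_fraction must lie in [0, 1]")


def make_planted_partition(n: int, k: int, sizes=None) -> Partition:
    """Contiguous label blocks: first Omega_1 nodes in community 1, etc."""
    if k > n:
        raise ValueError("more communities than nodes")
    if sizes is None:
        base = n // k
        sizes = [base + (1 if i < n % k else 0) for i in range(k)]
    sizes = [int(s) for s in sizes]
    if sum(sizes) != n:
        raise ValueError("sizes must sum to n")
    if any(s < 1 for s in sizes):
        raise ValueError("every community needs at least one node")
    sigma = np.repeat(np.arange(len(sizes)), sizes)
    return Partition(sigma=sigma, k=len(sizes), omega=np.asarray(sizes))


def sample_binary_sbm(partition: Partition, w, seed: int = 0) -> BinaryConnectome:
    """Sample a graph where each unordered pair u < v is an edge independently
    with probability w[sigma_u, sigma_v]. Deterministic given ``seed``."""
    w = np.asarray(w, dtype=float)
    if w.shape != (partition.k, partition.k):
        raise ValueError("w must be k-by-k")
    if not np.allclose(w, w.T):
        raise ValueError("w must be symmetric")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("edge probabilities must lie in [0, 1]")
    n = partition.n
    rng = np.random.default_rng(seed)
    probs = w[np.ix_(partition.sigma, partition.sigma)]
    u = rng.random((n, n))
    upper = np.triu(u < probs, k=1)
    adj = (upper | upper.T).astype(np.int8)
    return BinaryConnectome(adjacency=adj)


def _factor_corr(
    k: int,
    rho_within: float,
    rho_between: float,
    rho_between_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Community-factor correlation matrix giving node-level between-community
    correlation ~ N(rho_between, rho_between_sd) per community pair when
    loadings are sqrt(rho_within). Different functional-network pairs couple
    at different strengths; the heterogeneity makes thresholding a genuine
    trade-off rather than a single cliff."""
    if rho_within <= 0:
        return np.eye(k)
    targets = np.full((k, k), rho_between)
    if rho_between_sd > 0 and rng is not None:
        iu = np.triu_indices(k, 1)
        draws = rng.normal(rho_between, rho_between_sd, size=iu[0].size)
        draws = np.clip(draws, 0.0, 0.9 * rho_within)
        targets[iu] = draws
        targets.T[iu] = draws
    f = targets / rho_within
    np.fill_diagonal(f, 1.0)
    ev = np.linalg.eigvalsh(f)
    if ev.min() < -1e-10:
        if rho_between_sd == 0 or rng is None:
            raise ValueError("factor correlation matrix is not positive semidefinite")
        # heterogeneous draws can land outside the elliptope; floor the
        # spectrum and restore the unit diagonal (nearest-PSD repair)
        w, v = np.linalg.eigh(f)
        f = (v * np.maximum(w, 1e-6)) @ v.T
        d = np.sqrt(np.diag(f))
        f = f / np.outer(d, d)
        np.fill_diagonal(f, 1.0)
    # tiny ridge keeps the Cholesky factorization stable
    return f + 1e-10 * np.eye(k)


def _subject_fc(
    sigma: np.ndarray,
    rho: np.ndarray,
    signs: np.ndarray,
    fp_load: np.ndarray,
    chol: np.ndarray,
    T: int,
    rng: np.random.Generator,
    split: int = 1,
) -> np.ndarray:
    """One subject's sample-correlation connectome.

    ``fp_load`` is the per-node loading on this subject's private fingerprint
    factor h(t): nodes with nonzero loading gain subject-unique high-magnitude
    couplings that cut across the planted communities. With ``split`` > 1
    every parent node spawns ``split`` children sharing (community, loading,
    sign, fingerprint loading) but drawing independent private noise."""
    k = chol.shape[0]
    factors = chol @ rng.standard_normal((k, T))
    fingerprint = rng.standard_normal(T)
    sigma_c = np.repeat(sigma, split)
    rho_c = np.repeat(rho, split)
    signs_c = np.repeat(signs, split)
    fp_c = np.repeat(fp_load, split)
    eps = rng.standard_normal((sigma_c.size, T))
    phi = fp_c**2  # variance share of the fingerprint factor
    x = (
        (signs_c * np.sqrt(rho_c * (1.0 - phi)))[:, None] * factors[sigma_c]
        + fp_c[:, None] * fingerprint
        + np.sqrt((1.0 - rho_c) * (1.0 - phi))[:, None] * eps
    )
    fc = np.corrcoef(x)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 0.0)
    return fc


def simulate_fc_cohort(cfg: SimConfig, split: int = 1) -> tuple[Cohort, Partition]:
    """Generate a cohort of correlation-type connectomes with planted
    communities; returns the cohort and the ground-truth partition.

    ``split=m`` re-simulates the same latent structure at an m-fold refined
    parcellation (children inherit their parent's loading), so cohorts at
    different granularities are directly comparable at fixed seed.

    Bit-identical output for identical (cfg, split).
    """
    base = make_planted_partition(cfg.n, cfg.k, cfg.sizes)
    ss = np.random.SeedSequence(cfg.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    chol = np.linalg.cholesky(
        _factor_corr(cfg.k, cfg.rho_within, cfg.rho_between, cfg.rho_between_sd, master)
    )
    # sign flips exercise the |w| convention without changing block structure
    signs = np.ones(cfg.n)
    if cfg.negative_fraction > 0:
        flip = master.random(cfg.n) < cfg.negative_fraction
        signs[flip] = -1.0
    # population-level node loadings are shared by every subject: this
    # heterogeneity survives group-averaging, unlike the subject fingerprint
    rho_base = np.clip(
        cfg.rho_within + cfg.rho_within_sd * master.standard_normal(cfg.n),
        cfg.rho_between + 0.05,
        0.95,
    )
    subject_seeds = ss.spawn(cfg.gamma + 1)[1:]
    lo, hi = cfg.rho_between + 1e-6, 1.0 - 1e-6
    fcs = []
    for g in range(cfg.gamma):
        rng = np.random.default_rng(subject_seeds[0] if cfg.clone_subjects else subject_seeds[g])
        rho = rho_base + cfg.fingerprint_sd * rng.standard_normal(cfg.n)
        rho = np.clip(rho, lo, hi)
        fp_load = np.zeros(cfg.n)
        if cfg.fingerprint_var > 0 and cfg.fingerprint_fraction > 0:
            carriers = rng.random(cfg.n) < cfg.fingerprint_fraction
            fp_sign = np.where(rng.random(cfg.n) < 0.5, -1.0, 1.0)
            fp_load[carriers] = (fp_sign * np.sqrt(cfg.fingerprint_var))[carriers]
        fcs.append(_subject_fc(base.sigma, rho, signs, fp_load, chol, cfg.T, rng, split=split))
    refined, _ = refine_parcellation(base, split) if split > 1 else (base, None)
    cohort = Cohort(
        connectomes=[WeightedConnectome(weights=f) for f in fcs],
        condition=f"synthetic(seed={cfg.seed},split={split})",
    )
    return cohort, refined


def refine_parcellation(partition: Partition, m: int) -> tuple[Partition, dict[int, list[int]]]:
    """Split every node into m children inheriting the parent's community.

    Returns the refined partition and the parent -> children index mapping.
    """
    if m < 1:
        raise ValueError("split factor must be at least 1")
    sigma = np.repeat(partition.sigma, m)
    refined = Partition(
        sigma=sigma, k=partition.k, omega=partition.omega * m, labels=partition.labels
    )
    mapping = {u: list(range(u * m, u * m + m)) for u in range(partition.n)}
    return refined, mapping


def write_cohort(cohort: Cohort, partition: Partition, cfg: SimConfig, outdir) -> dict:
    """Write matrices, partition and a provenance manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for sid, conn in zip(cohort.subject_ids, cohort.connectomes):
        fname = f"{sid}.csv"
        write_connectome(conn, outdir / fname)
        files.append(fname)
    write_partition(partition, cohort.node_ids, outdir / "partition.tsv")
    manifest = {
        "condition": cohort.condition,
        "files": files,
        "subject_ids": list(cohort.subject_ids),
        "provenance": {"generator": "connsnr.simulate.simulate_fc_cohort", "config": asdict(cfg)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
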