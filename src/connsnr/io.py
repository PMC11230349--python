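"""Connectome, partition and cohort containers plus delimited-text readers/writers.

The on-disk contract is deliberately minimal: connectomes are square numeric
matrices in comma- or tab-delimited text (optional header row/column of node
identifiers), partitions are two-column tables ``node_id<TAB>community``, and a
cohort is a YAML/JSON manifest pointing at matrix files. Node order is the
alignment contract everywhere: the partition and every cohort member must list
nodes in the same order; nothing is silently reordered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WeightedConnectome",
    "BinaryConnectome",
    "Partition",
    "Cohort",
    "CohortReport",
    "read_connectome",
    "write_connectome",
    "read_partition",
    "write_partition",
    "read_cohort",
    "validate_cohort",
]

#: tolerance on ``|A - A.T|`` above which a matrix is rejected as asymmetric
ASYMMETRY_TOL = 1e-8
#: tolerance used when *checking* symmetry of an already-built connectome
SYMMETRY_TOL = 1e-10


def _default_node_ids(n: int) -> list[str]:
    return [str(i) for i in range(1, n + 1)]


@dataclass
class WeightedConnectome:
    """Symmetric matrix of functional couplings with zero diagonal.

    Parameters
    ----------
    weights : (n, n) ndarray
        Signed, dimensionless couplings. When ``correlation`` is true every
        entry must satisfy ``|w| <= 1`` (Pearson-like).
    node_ids : sequence of str, optional
        Ordered node identifiers; defaults to ``"1".."n"``.
    correlation : bool
        Whether the entries are correlation-type (bounded by 1 in magnitude).
    """

    weights: np.ndarray
    node_ids: list[str] | None = None
    correlation: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("connectome matrix must be square")
        n = self.weights.shape[0]
        if n < 2:
            raise ValueError("connectome needs at least 2 nodes")
        if self.node_ids is None:
            self.node_ids = _default_node_ids(n)
        self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix size")
        if np.max(np.abs(self.weights - self.weights.T), initial=0.0) > SYMMETRY_TOL:
            raise ValueError("connectome matrix is not symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("connectome diagonal must be exactly zero")
        if self.correlation and np.max(np.abs(self.weights)) > 1.0 + 1e-12:
            raise ValueError("correlation-type connectome has an entry with |w| > 1")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryConnectome:
    """Unweighted undirected graph as a 0/1 adjacency matrix (no self-loops)."""

    adjacency: np.ndarray
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("binary connectome entries must be 0 or 1")
        a = a.astype(np.int8)
        if (a != a.T).any():
            raise ValueError("adjacency is not symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        self.adjacency = a
        if self.node_ids is None:
            self.node_ids = _default_node_ids(a.shape[0])
        self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != a.shape[0]:
            raise ValueError("node_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class Partition:
    """Node-to-community assignment sigma with community sizes Omega.

    ``sigma`` is stored 0-based internally; files and reports use labels
    ``1..k``. ``labels`` optionally keeps the original community names in
    first-appearance order.
    """

    sigma: np.ndarray
    k: int
    omega: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.int64)
        self.omega = np.asarray(self.omega, dtype=np.int64)
        if self.sigma.ndim != 1:
            raise ValueError("sigma must be a vector")
        if self.omega.shape != (self.k,):
            raise ValueError("omega must have length k")
        if self.sigma.size and (self.sigma.min() < 0 or self.sigma.max() >= self.k):
            raise ValueError("sigma labels out of range")
        counts = np.bincount(self.sigma, minlength=self.k)
        if not np.array_equal(counts, self.omega):
            raise ValueError("omega inconsistent with sigma")
        if (self.omega == 0).any():
            raise ValueError("every community must contain at least one node")

    @classmethod
    def from_labels(cls, labels: Sequence) -> "Partition":
        """Build a partition from arbitrary labels, re-encoded to 0..k-1 in
        first-appearance order."""
        seen: dict = {}
        sigma = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(seen)
            sigma[i] = seen[lab]
        k = len(seen)
        if k == 0:
            raise ValueError("empty partition")
        omega = np.bincount(sigma, minlength=k)
        return cls(sigma=sigma, k=k, omega=omega, labels=[str(x) for x in seen])

    @property
    def n(self) -> int:
        return self.sigma.size

    def indicator(self) -> np.ndarray:
        """(n, k) one-hot membership matrix S with S[u, sigma_u] = 1."""
        s = np.zeros((self.n, self.k))
        s[np.arange(self.n), self.sigma] = 1.0
        return s


@dataclass
class Cohort:
    """An ordered collection of same-parcellation connectomes (one per subject)."""

    connectomes: list[WeightedConnectome]
    subject_ids: list[str] | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.connectomes:
            raise ValueError("cohort must contain at least one connectome")
        ref = self.connectomes[0]
        for c in self.connectomes[1:]:
            if c.n != ref.n:
                raise ValueError("cohort members have differing node counts")
            if c.node_ids != ref.node_ids:
                raise ValueError("cohort members disagree on node order")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i + 1}" for i in range(len(self.connectomes))]
        if len(self.subject_ids) != len(self.connectomes):
            raise ValueError("subject_ids length mismatch")

    @property
    def gamma(self) -> int:
        return len(self.connectomes)

    @property
    def n(self) -> int:
        return self.connectomes[0].n

    @property
    def node_ids(self) -> list[str]:
        return self.connectomes[0].node_ids


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_connectome(path, kind: str = "weighted", correlation: bool = True):
    """Read a connectome matrix from delimited text.

    The file may carry a header row (and matching first column) of node ids.
    Matrices with asymmetry at most 1e-8 are symmetrized as ``(A + A.T)/2``;
    larger asymmetry is an error. The diagonal is forced to zero.

    Parameters
    ----------
    path : path-like
    kind : {"weighted", "binary"}
    correlation : bool
        For ``kind="weighted"``, enforce ``|w| <= 1``.
    """
    if kind not in ("weighted", "binary"):
        raise ValueError(f"unknown connectome kind {kind!r}")
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        first_tokens = fh.readline().rstrip("\n").split(sep)
    # a leading empty cell marks a header row over an id column; otherwise a
    # header is any first row that does not parse as numbers
    has_header = first_tokens[0] == "" or not all(_is_number(t) for t in first_tokens)
    if has_header:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        node_ids = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        node_ids = None
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is not square (shape {mat.shape})")
    asym = float(np.max(np.abs(mat - mat.T), initial=0.0))
    if asym > ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL}")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    if kind == "binary":
        if not np.isin(mat, (0.0, 1.0)).all():
            raise ValueError(f"{path}: binary connectome has entries outside {{0,1}}")
        return BinaryConnectome(adjacency=mat.astype(np.int8), node_ids=node_ids)
    return WeightedConnectome(weights=mat, node_ids=node_ids, correlation=correlation)


def write_connectome(conn, path, header: bool = True) -> None:
    """Write a connectome to delimited text with 15 significant digits."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    mat = conn.adjacency if isinstance(conn, BinaryConnectome) else conn.weights
    with open(path, "w") as fh:
        if header:
            fh.write(sep + sep.join(conn.node_ids) + "\n")
        for i, row in enumerate(mat):
            cells = sep.join(f"{v:.15g}" for v in row)
            fh.write((conn.node_ids[i] + sep if header else "") + cells + "\n")


def read_partition(path, node_ids: Sequence[str]) -> Partition:
    """Read a two-column (node id, community label) table aligned to node_ids.

    Every node id must appear exactly once; community labels are re-encoded to
    consecutive integers in first-appearance order (w.r.t. node_ids order).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    mapping: dict[str, str] = {}
    for node, lab in zip(df[0], df[1]):
        node = str(node).strip()
        if node in mapping:
            raise ValueError(f"{path}: duplicate node id {node!r}")
        mapping[node] = str(lab).strip()
    node_ids = [str(x) for x in node_ids]
    missing = [nid for nid in node_ids if nid not in mapping]
    if missing:
        raise ValueError(f"{path}: partition missing node(s) {missing[:5]}")
    extra = set(mapping) - set(node_ids)
    if extra:
        raise ValueError(f"{path}: partition has unknown node(s) {sorted(extra)[:5]}")
    return Partition.from_labels([mapping[nid] for nid in node_ids])


def write_partition(partition: Partition, node_ids: Sequence[str], path) -> None:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    labels = partition.labels or [str(i + 1) for i in range(partition.k)]
    with open(path, "w") as fh:
        for nid, s in zip(node_ids, partition.sigma):
            fh.write(f"{nid}{sep}{labels[s]}\n")


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort from a YAML/JSON manifest.

    The manifest is a mapping with keys ``files`` (list of matrix paths,
    relative to the manifest), optional ``subject_ids`` and ``condition``.
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    spec = json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(spec, dict) or "files" not in spec:
        raise ValueError(f"{manifest_path}: manifest must map 'files' to a list")
    conns = []
    for f in spec["files"]:
        p = Path(f)
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            raise FileNotFoundError(f"manifest entry not found: {p}")
        conns.append(read_connectome(p, kind="weighted"))
    return Cohort(
        connectomes=conns,
        subject_ids=[str(s) for s in spec["subject_ids"]] if "subject_ids" in spec else None,
        condition=str(spec.get("condition", "")),
    )


@dataclass
class CohortReport:
    """Summary of a validated (cohort, partition) pair."""

    n: int
    gamma: int
    k: int
    omega: list[int]
    density_range: tuple[float, float]
    condition: str = ""
    messages: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"cohort: {self.gamma} subject(s), {self.n} nodes, condition={self.condition or '-'}",
            f"partition: k={self.k}, omega={self.omega}",
            f"nonzero-coupling density range: [{self.density_range[0]:.4f}, {self.density_range[1]:.4f}]",
        ]
        lines.extend(self.messages)
        return "\n".join(lines)


def validate_cohort(cohort: Cohort, partition: Partition) -> CohortReport:
    """Check cohort/partition alignment and summarize basic statistics.

    Raises on any dimension or node-order mismatch; density is the fraction of
    node pairs with a nonzero coupling.
    """
    if partition.n != cohort.n:
        raise ValueError(
            f"partition covers {partition.n} nodes but cohort members have {cohort.n}"
        )
    densities = []
    npairs = cohort.n * (cohort.n - 1) / 2
    for c in cohort.connectomes:
        if c.node_ids != cohort.node_ids:
            raise ValueError("cohort member node order mismatch")
        nz = np.count_nonzero(np.triu(c.weights, 1))
        densities.append(nz / npairs)
    return CohortReport(
        n=cohort.n,
        gamma=cohort.gamma,
        k=partition.k,
        omega=partition.omega.tolist(),
        density_range=(float(min(densities)), float(max(densities))),
        condition=cohort.condition,
    )
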