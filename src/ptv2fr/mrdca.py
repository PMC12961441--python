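"""Multi-Radius Dual-Coordinate Attention (MRDCA).

Three parallel KNN branches (default neighbor counts 8/16/24, 16 channels
each) run dual-coordinate attention: per-pair scores combine a scaled
query-key dot product, an MLP of the relative offsets (coordinate and
feature), an MLP of the neighbor's min-max-normalized absolute coordinates,
and a gated MLP of channel statistics (the pair feature difference together
with its neighborhood avg/max pooling).  Branch outputs are concatenated
(or summed) and fused by a linear layer with ReLU-after-PointBN.

Note on the absolute and pooled signals: a score term that is constant over
the neighbor index cancels inside the per-query softmax and would receive
zero gradient, so both signals enter per pair — the absolute encoding uses
the neighbor's normalized coordinates and the pooled statistics are
concatenated with the pair difference.
"""

from __future__ import annotations

import hashlib

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .nn import MLP, Linear, Module, ModuleList, PointBN, Tensor, concat


@dataclass
class NeighborGraph:
    """Ordered K-nearest-neighbor lists (self included, padded with self)."""

    idx: np.ndarray      # (N, K) int64, distance-ordered
    coords: np.ndarray   # (N, 3)

    def __post_init__(self):
        self._scatter = None

    @property
    def k(self) -> int:
        return self.idx.shape[1]

    @property
    def scatter(self) -> sp.csr_matrix:
        """(N, N*K) selection matrix: row v sums every neighbor slot that
        reads point v (used to push gradients back through gathers)."""
        if self._scatter is None:
            n, k = self.idx.shape
            self._scatter = sp.csr_matrix(
                (np.ones(n * k), (self.idx.ravel(), np.arange(n * k))),
                shape=(n, n * k))
        return self._scatter


_GRAPH_CACHE: dict = {}
_GRAPH_CACHE_MAX = 96


def build_knn_graph(points: np.ndarray, k: int) -> NeighborGraph:
    """K nearest neighbors by Euclidean distance (each point is its own
    nearest neighbor).  Clouds with fewer than ``k`` points pad each list
    with the self index.  Results are memoized on the exact coordinate
    bytes, so repeated passes over a fixed cloud reuse the graph."""
    points = np.ascontiguousarray(points, dtype=np.float64)
    n = len(points)
    if n == 0:
        raise ValueError("empty cloud")
    if k < 1:
        raise ValueError("k must be >= 1")
    key = (hashlib.sha1(points.tobytes()).hexdigest(), k)
    hit = _GRAPH_CACHE.get(key)
    if hit is not None:
        return hit
    kk = min(k, n)
    _, idx = cKDTree(points).query(points, k=kk)
    idx = idx.reshape(n, kk).astype(np.int64)
    if kk < k:
        pad = np.repeat(np.arange(n, dtype=np.int64)[:, None], k - kk, axis=1)
        idx = np.concatenate([idx, pad], axis=1)
    graph = NeighborGraph(idx=idx, coords=points)
    if len(_GRAPH_CACHE) >= _GRAPH_CACHE_MAX:
        _GRAPH_CACHE.pop(next(iter(_GRAPH_CACHE)))
    _GRAPH_CACHE[key] = graph
    return graph


def gather_neighbors(t: Tensor, graph: NeighborGraph) -> Tensor:
    """t[graph.idx] with the gradient scattered through the cached sparse
    selection matrix (much faster than np.add.at on large graphs)."""
    n, k = graph.idx.shape
    out = Tensor(t.data[graph.idx], _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(graph.scatter @ g.reshape(n * k, -1))

    out._backward = bw
    return out


def minmax_normalize(coords: np.ndarray) -> np.ndarray:
    """Per-cloud, per-axis min-max normalization to [0, 1].

    A degenerate axis (max == min) maps to 0 rather than NaN.
    """
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    out = np.zeros_like(coords, dtype=np.float64)
    ok = span > 0
    out[:, ok] = (coords[:, ok] - lo[ok]) / span[ok]
    return out


@dataclass
class MultiRadiusConfig:
    k: tuple[int, ...] = (8, 16, 24)
    branch_channels: int = 16
    fusion: str = "concat"            # "concat" | "sum"

    def __post_init__(self):
        if any(kk < 1 for kk in self.k):
            raise ValueError("neighbor counts must be >= 1")
        if self.branch_channels < 1:
            raise ValueError("branch channels must be >= 1")
        if self.fusion not in ("concat", "sum"):
            raise ValueError("fusion must be 'concat' or 'sum'")


class DCABranch(Module):
    """Dual-coordinate attention over one fixed-K neighbor graph."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        c = channels
        self.d = float(c)  # dot-product scale: the branch channel width
        self.w_q = Linear(c, c, rng)
        self.w_k = Linear(c, c, rng)
        self.w_v = Linear(c, c, rng)
        self.bn_q = PointBN(c)
        self.bn_k = PointBN(c)
        self.psi_rel = MLP([3 + c, c, 1], rng)
        self.psi_abs = MLP([3, c, 1], rng)
        self.psi_pool = MLP([3 * c, c, 1], rng)
        # learnable scalar gate on the pooled signal; starts near-silent but
        # nonzero so the pooled pathway is trainable from the first step
        self.alpha = Tensor(np.asarray(0.1), requires_grad=True)

    def _scores(self, features: Tensor, graph: NeighborGraph):
        if not np.isfinite(features.data).all():
            raise ValueError("non-finite features")
        n, c = features.shape
        k = graph.k
        idx = graph.idx
        q = self.bn_q(self.w_q(features)).relu()          # φ = ReLU ∘ PointBN
        key = self.bn_k(self.w_k(features)).relu()
        v = self.w_v(features)
        kj = gather_neighbors(key, graph)                 # (N, K, C)
        vj = gather_neighbors(v, graph)
        fj = gather_neighbors(features, graph)
        df = fj - features.reshape(n, 1, c)               # Δf_ij
        dp = graph.coords[idx] - graph.coords[:, None]    # Δp_ij (constant)
        qk = (q.reshape(n, 1, c) * kj).sum(axis=2) * (1.0 / self.d)
        rel = self.psi_rel(concat([Tensor(dp), df], axis=2)).reshape(n, k)
        p_norm = minmax_normalize(graph.coords)
        abs_term = self.psi_abs(Tensor(p_norm[idx])).reshape(n, k)
        pool_ctx = concat(
            [df,
             df.mean(axis=1, keepdims=True).broadcast_to((n, k, c)),
             df.max(axis=1, keepdims=True).broadcast_to((n, k, c))],
            axis=2)
        pool = self.psi_pool(pool_ctx).reshape(n, k)
        scores = qk + rel + abs_term + self.alpha * pool
        return scores, vj

    def forward(self, features: Tensor, graph: NeighborGraph) -> Tensor:
        n, c = features.shape
        scores, vj = self._scores(features, graph)
        w = scores.softmax(axis=1)                        # Σ_j w_ij = 1
        return (w.reshape(n, graph.k, 1) * vj).sum(axis=1)

    def attention_weights(self, features: Tensor, graph: NeighborGraph) -> np.ndarray:
        """Softmax attention weights (diagnostics / tests)."""
        scores, _ = self._scores(features, graph)
        return scores.softmax(axis=1).data


def dca_attention(features: Tensor | np.ndarray, graph: NeighborGraph,
                  params: DCABranch) -> Tensor:
    """Functional entry point for a single dual-coordinate attention pass."""
    features = features if isinstance(features, Tensor) else Tensor(features)
    return params(features, graph)


class MRDCA(Module):
    """Full multi-radius block: projection, 3 DCA branches, fusion."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 config: MultiRadiusConfig | None = None):
        super().__init__()
        self.config = config or MultiRadiusConfig()
        bc = self.config.branch_channels
        nb = len(self.config.k)
        self.proj = Linear(in_dim, nb * bc, rng)
        self.bn_proj = PointBN(nb * bc)
        self.branches = ModuleList([DCABranch(bc, rng) for _ in self.config.k])
        fused_in = nb * bc if self.config.fusion == "concat" else bc
        self.fuse = Linear(fused_in, out_dim, rng)
        self.bn_fuse = PointBN(out_dim)

    def forward(self, features: Tensor, coords: np.ndarray,
                graphs: list[NeighborGraph] | None = None) -> Tensor:
        cfg = self.config
        bc = cfg.branch_channels
        if features.shape[1] != self.proj.weight.shape[0]:
            raise ValueError(
                f"feature width {features.shape[1]} != expected {self.proj.weight.shape[0]}")
        if graphs is None:
            graphs = [build_knn_graph(coords, k) for k in cfg.k]
        f_proj = self.bn_proj(self.proj(features)).relu()
        enhanced = []
        for b, (branch, graph) in enumerate(zip(self.branches, graphs)):
            f_b = f_proj[:, b * bc:(b + 1) * bc]
            enhanced.append(branch(f_b, graph))
        if cfg.fusion == "concat":
            f_mr = concat(enhanced, axis=1)
        else:
            f_mr = enhanced[0]
            for e in enhanced[1:]:
                f_mr = f_mr + e
        return self.bn_fuse(self.fuse(f_mr)).relu()
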