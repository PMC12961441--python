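"""Point-Graph Involution Feature Refinement (PG-InvFR).

An involution-style refinement applied between the decoder output and the
segmentation head: each point gets its own dynamic kernel (one weight per
neighbor slot of a k-NN point graph), generated from the point's feature
together with geometric cues (per-neighbor distances and the local
principal direction).  A per-point uncertainty gate — the sigmoid of the
Shannon entropy of an auxiliary classifier's softmax — scales the
refinement so ambiguous boundary points are refined more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mrdca import NeighborGraph, build_knn_graph, gather_neighbors
from .nn import Linear, Module, Tensor, concat


def point_entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy (natural log) of each probability row.

    Rows must be valid probability vectors to 1e-6; 0·log 0 is taken as 0.
    The result lies in [0, ln C].
    """
    probs = np.asarray(probs, dtype=np.float64)
    if (probs < 0).any():
        raise ValueError("negative probabilities")
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-6)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(probs), 0.0)
    return np.maximum(-terms.sum(axis=-1), 0.0)


def uncertainty_gate(entropy: np.ndarray) -> np.ndarray:
    """α_i = σ(U_i): logistic gate, strictly increasing in the entropy."""
    entropy = np.asarray(entropy, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-entropy))


def local_geometry(graph: NeighborGraph) -> np.ndarray:
    """Per-point geometric cue d_i: the K neighbor distances concatenated
    with the neighborhood's unit principal direction (top eigenvector of
    the local covariance, sign fixed to non-negative z).  Shape (N, K+3).
    """
    coords = graph.coords
    nb = coords[graph.idx]                        # (N, K, 3)
    diff = nb - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=2)           # (N, K)
    centered = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / graph.k
    # top eigenvector of each 3x3 covariance
    w, v = np.linalg.eigh(cov)
    principal = v[:, :, -1]
    flip = principal[:, 2] < 0
    principal[flip] *= -1.0
    return np.concatenate([dist, principal], axis=1)


@dataclass
class PGInvFRConfig:
    k: int = 16
    residual: bool = True
    aux_head_weight: float = 0.4
    iterations: int = 1
    hidden: int = 32
    neighborhood_mean_probs: bool = False  # entropy of neighborhood-averaged probs


class PGInvFR(Module):
    """Dynamic-kernel feature refinement with uncertainty gating."""

    def __init__(self, dim: int, num_classes: int, rng: np.random.Generator,
                 config: PGInvFRConfig | None = None):
        super().__init__()
        self.config = config or PGInvFRConfig()
        self.dim = dim
        self.num_classes = num_classes
        k = self.config.k
        self.aux_head = Linear(dim, num_classes, rng)
        self.m_c = Linear(dim + k + 3, self.config.hidden, rng)
        # zero-init: kernels start at the bias pattern (all zero), so with
        # the residual the module begins as the identity and the dynamic
        # kernels are learned rather than injected as noise
        self.m_k = Linear(self.config.hidden, k, rng, zero_init=True)

    def generate_kernels(self, features: Tensor, geometry: np.ndarray) -> Tensor:
        """H_i = M_k(M_c([F_i, d_i])): one kernel weight per neighbor slot."""
        if geometry.shape[1] != self.config.k + 3:
            raise ValueError(
                f"geometry has {geometry.shape[1]} cues, expected {self.config.k + 3}")
        return self.m_k(self.m_c(concat([features, Tensor(geometry)], axis=1)).relu())

    @staticmethod
    def refine_features(features: Tensor, kernel_field: Tensor,
                        gate: np.ndarray, graph: NeighborGraph) -> Tensor:
        """f_i^out = α_i Σ_{j∈N(i)} H_{i,j} f_j."""
        if not np.isfinite(kernel_field.data).all():
            raise ValueError("non-finite kernel weights")
        n = features.shape[0]
        fj = gather_neighbors(features, graph)            # (N, K, C)
        agg = (kernel_field.reshape(n, graph.k, 1) * fj).sum(axis=1)
        return agg * np.asarray(gate, dtype=np.float64).reshape(n, 1)

    def forward(self, features: Tensor, coords: np.ndarray,
                graph: NeighborGraph | None = None):
        """Returns (refined features, auxiliary class logits).

        The auxiliary softmax feeding the entropy gate is detached, so the
        gate modulates magnitudes without backpropagating into the
        classifier through the gating path.
        """
        if not np.isfinite(features.data).all():
            raise ValueError("non-finite decoder features")
        if graph is None:
            graph = build_knn_graph(coords, self.config.k)
        aux_logits = self.aux_head(features)
        probs = aux_logits.softmax(axis=1).data           # detached
        if self.config.neighborhood_mean_probs:
            probs = probs[graph.idx].mean(axis=1)
            probs /= probs.sum(axis=1, keepdims=True)
        gate = uncertainty_gate(point_entropy(probs))
        geometry = local_geometry(graph)
        out = features
        for _ in range(self.config.iterations):
            kernels = self.generate_kernels(out, geometry)
            refined = self.refine_features(out, kernels, gate, graph)
            out = out + refined if self.config.residual else refined
        return out, aux_logits
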