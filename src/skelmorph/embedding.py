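"""Unsupervised graph-level embedding of skeleton graphs.

Node (patch) representations come from stacked graph-convolution layers over
the skeleton graph, with the outputs of all layers concatenated; a
permutation-invariant sum pooling followed by a learned projection gives the
graph-level (global) representation, a 100-dimensional vector by default.
Training maximizes a Jensen-Shannon estimate of the mutual information
between patch and global representations: a discriminator scores
(patch, global) pairs, pairs drawn from the same graph are positives and
pairs mixing a node from another graph are negatives. Embeddings are then
clustered with K-means++ for majority-vote classification and used for
inter/intra-class distance analysis with hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans

from .nn import MLP, Adam, Parameter, Tensor, glorot

__all__ = [
    "EmbedConfig",
    "GraphEmbedder",
    "node_encoder",
    "global_pool",
    "discriminator",
    "mi_objective",
    "train_embedder",
    "embed",
    "cluster_classify",
    "distance_analysis",
]


@dataclass
class EmbedConfig:
    n_conv_layers: int = 3
    hidden: int = 64
    out_dim: int = 100
    neg_ratio: int = 1
    epochs: int = 150
    lr: float = 1e-3
    seed: int = 0
    #: negative MI term as printed in the JSD estimator used here
    #: (``-E[-sp(-T)]``); "standard" uses the usual JSD form ``-E[sp(T)]``
    negative_term: str = "as_printed"


def _graph_arrays(g: nx.Graph) -> Tuple[np.ndarray, np.ndarray]:
    """Node attribute matrix (position, radius) and normalized adjacency."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes)
    X = np.array([[*np.asarray(g.nodes[n]["position"], float),
                   float(g.nodes[n].get("radius", 0.0))] for n in nodes])
    A = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    A = A + np.eye(len(nodes))
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return X, A * dinv[:, None] * dinv[None, :]


class GraphEmbedder:
    """GCN patch encoder + sum-pool global projection + JSD discriminator."""

    def __init__(self, config: Optional[EmbedConfig] = None):
        self.config = cfg = config or EmbedConfig()
        rng = np.random.default_rng(cfg.seed)
        widths = [4] + [cfg.hidden] * cfg.n_conv_layers
        self.conv_W = [Parameter(glorot(rng, a, b))
                       for a, b in zip(widths[:-1], widths[1:])]
        patch_dim = cfg.hidden * cfg.n_conv_layers
        self.proj = Parameter(glorot(rng, patch_dim, cfg.out_dim))
        self.f_patch = MLP(rng, [patch_dim, cfg.hidden, cfg.hidden, cfg.hidden])
        self.g_global = MLP(rng, [cfg.out_dim, cfg.hidden, cfg.hidden, cfg.hidden])
        self._rng = rng

    def parameters(self):
        return (self.conv_W + [self.proj] + self.f_patch.parameters()
                + self.g_global.parameters())

    # -- encoder -------------------------------------------------------------
    def patches(self, g: nx.Graph) -> Tensor:
        X, A = _graph_arrays(g)
        h = Tensor(X)
        An = Tensor(A)
        outs = []
        for W in self.conv_W:
            h = (An @ (h @ W)).relu()
            outs.append(h)
        return Tensor.concat(outs, axis=1)           # (n_nodes, patch_dim)

    def pool(self, h: Tensor) -> Tensor:
        return (h.sum(axis=0, keepdims=True) @ self.proj).reshape(-1)

    def discriminate(self, h: Tensor, H: Tensor) -> Tensor:
        """Nonnegative score that (patch, global) come from the same graph."""
        fh = self.f_patch(h)                         # (n, hidden)
        gH = self.g_global(H)                        # (n, hidden) or (hidden,)
        if gH.ndim == 1:
            gH = gH.reshape(1, -1)
        return (fh * gH).sum(axis=1).relu()


def node_encoder(g: nx.Graph, embedder: GraphEmbedder) -> np.ndarray:
    """Per-node patch representations (all conv-layer outputs concatenated)."""
    return embedder.patches(g).numpy()


def global_pool(g: nx.Graph, embedder: GraphEmbedder) -> np.ndarray:
    """Graph-level representation: sum over nodes, projected to out_dim."""
    return embedder.pool(embedder.patches(g)).numpy()


def discriminator(embedder: GraphEmbedder, h_vec, H_vec) -> float:
    """Score a single (patch, global) pair; nonnegative by rectification."""
    h = Tensor(np.atleast_2d(np.asarray(h_vec, float)))
    H = Tensor(np.asarray(H_vec, float))
    return float(embedder.discriminate(h, H).numpy()[0])


def mi_objective(graphs: Sequence[nx.Graph], embedder: GraphEmbedder,
                 rng: Optional[np.random.Generator] = None,
                 negative_pairs: Optional[List[np.ndarray]] = None) -> Tensor:
    """Jensen-Shannon mutual-information objective over global-patch pairs.

    ``MI = (1/K) * sum_i sum_{j in G_i} I(h_i^j, H_i)`` with
    ``I = E[-sp(-T(pos))] - E[-sp(-T(neg))]`` and ``sp(z) = log(1 + e^z)``;
    negatives pair each graph's global vector with a node drawn from another
    graph. ``negative_pairs[i]`` may supply the (graph, node) draws
    explicitly; otherwise they come from ``rng``.
    """
    K = len(graphs)
    if K < 2:
        raise ValueError("mutual information needs at least two graphs")
    rng = rng or np.random.default_rng(0)
    cfg = embedder.config
    patch_list = [embedder.patches(g) for g in graphs]
    globals_list = [embedder.pool(h) for h in patch_list]
    total = None
    for i, (h_i, H_i) in enumerate(zip(patch_list, globals_list)):
        n_i = h_i.shape[0]
        H_row = H_i.reshape(1, -1)
        t_pos = embedder.discriminate(h_i, H_row)
        pos = -((-t_pos).softplus())                 # (n_i,)
        if negative_pairs is not None:
            draws = negative_pairs[i]
        else:
            others = [k for k in range(K) if k != i]
            draws = np.array([
                (o := rng.choice(others),
                 rng.integers(patch_list[o].shape[0]))
                for _ in range(n_i * cfg.neg_ratio)])
        neg_h = Tensor.concat(
            [patch_list[int(o)].gather_rows([int(j)]) for o, j in draws],
            axis=0)
        t_neg = embedder.discriminate(neg_h, H_row)
        if cfg.negative_term == "as_printed":
            neg = -((-t_neg).softplus())
        elif cfg.negative_term == "standard":
            neg = t_neg.softplus()
        else:
            raise ValueError(f"unknown negative_term {cfg.negative_term!r}")
        contrib = pos.sum() - neg.sum() * (1.0 / cfg.neg_ratio)
        total = contrib if total is None else total + contrib
    return total * (1.0 / K)


def train_embedder(graphs: Sequence[nx.Graph],
                   config: Optional[EmbedConfig] = None) -> GraphEmbedder:
    """Gradient ascent on the mutual-information objective (unsupervised)."""
    cfg = config or EmbedConfig()
    embedder = GraphEmbedder(cfg)
    opt = Adam(embedder.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    for epoch in range(cfg.epochs):
        mi = mi_objective(graphs, embedder, rng=rng)
        if not np.isfinite(mi.numpy()):
            raise FloatingPointError(f"embedding diverged at epoch {epoch}")
        loss = -mi
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(mi.item())
    embedder.history = history
    return embedder


def embed(g: nx.Graph, embedder: GraphEmbedder) -> np.ndarray:
    """Embed one skeleton graph into a fixed-length vector."""
    return global_pool(g, embedder)


def cluster_classify(train_vecs: np.ndarray, train_labels: Sequence,
                     test_vecs: np.ndarray, n_classes: int,
                     seed: int = 0) -> Tuple[float, List]:
    """K-means++ clustering with majority-vote cluster labeling.

    K equals the number of classes; each cluster takes the majority label of
    the training points it holds (ties broken by the smallest class index);
    test vectors inherit the label of their Euclidean-nearest center.
    Returns (training accuracy, predicted test labels).
    """
    train_vecs = np.asarray(train_vecs, float)
    train_labels = list(train_labels)
    if n_classes < 2:
        raise ValueError("need at least two classes")
    classes = sorted(set(train_labels))
    if len(classes) < n_classes:
        raise ValueError("every class must appear in the training set")
    km = KMeans(n_clusters=n_classes, init="k-means++", n_init=10,
                random_state=seed)
    assign = km.fit_predict(train_vecs)
    cluster_label: Dict[int, object] = {}
    for c in range(n_classes):
        members = [train_labels[i] for i in np.nonzero(assign == c)[0]]
        if not members:
            cluster_label[c] = classes[0]
            continue
        counts = {lab: members.count(lab) for lab in classes}
        best = max(counts.values())
        cluster_label[c] = min(lab for lab, k in counts.items() if k == best)
    train_pred = [cluster_label[a] for a in assign]
    train_acc = float(np.mean([p == t for p, t in zip(train_pred, train_labels)]))
    test_vecs = np.asarray(test_vecs, float)
    d = cdist(test_vecs, km.cluster_centers_)
    test_pred = [cluster_label[int(i)] for i in np.argmin(d, axis=1)]
    return train_acc, test_pred


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.left, labels)
    right = _tree_to_newick(node.right, labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def distance_analysis(vecs: np.ndarray, labels: Sequence
                      ) -> Tuple[np.ndarray, np.ndarray, List, str]:
    """Pairwise-distance structure of a labeled embedding set.

    Returns the full Euclidean pairwise matrix, the class-block mean-distance
    matrix (diagonal = intra-class, off-diagonal = inter-class), the class
    order, and an average-linkage dendrogram of the class means in Newick
    text.
    """
    vecs = np.asarray(vecs, float)
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    D = cdist(vecs, vecs)
    C = len(classes)
    block = np.zeros((C, C))
    for a, ca in enumerate(classes):
        ia = [i for i, l in enumerate(labels) if l == ca]
        for b, cb in enumerate(classes):
            ib = [i for i, l in enumerate(labels) if l == cb]
            sub = D[np.ix_(ia, ib)]
            if a == b:
                n = len(ia)
                block[a, b] = (sub.sum() / (n * n - n)) if n > 1 else 0.0
            else:
                block[a, b] = sub.mean()
    inter = squareform(0.5 * (block + block.T), checks=False)
    Z = hierarchy.linkage(inter, method="average")
    tree = hierarchy.to_tree(Z)
    newick = _tree_to_newick(tree, classes) + ";"
    return D, block, classes, newick
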