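"""Drug similarity processing: logistic adjustment, cohesiveness clustering
and cluster-informed boosting.

Raw chemical similarity between drugs is weakly discriminative in the
mid-range: many structurally dissimilar drug pairs still carry small but
non-zero similarity that swamps link-prediction features.  The standard fix
in the drug-repositioning literature is an elementwise logistic remap

    L(x) = 1 / (1 + exp(a*x + b))

with a < 0, which pushes non-discriminative similarities towards 0 while
keeping high similarities close to 1 (defaults a = -15, b = ln 9999 give
L(0) = 1e-4 and L(1) ~ 0.997).

On top of that, drugs are grouped with a greedy cohesiveness-maximising
clustering (the ClusterONE scheme): a cluster M of a weighted graph scores

    f(M) = C_in(M) / (C_in(M) + C_bound(M) + P(M))

where C_in is total internal edge weight, C_bound the weight crossing the
boundary and P a per-node penalty.  Pairs of drugs that end up co-clustered
get their pre-adjustment similarity restored (elementwise max), on the
premise that association-derived cluster mates are genuinely related even
when the chemical similarity alone was down-weighted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datasets import EntityIndex, SimilarityMatrix

__all__ = [
    "LogisticParams",
    "Cluster",
    "ClusteringConfig",
    "FingerprintConfig",
    "FingerprintResult",
    "logistic_adjust",
    "cohesiveness",
    "cluster_one",
    "boost_with_clusters",
    "tanimoto_from_smiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LogisticParams:
    """Slope/offset of the logistic similarity adjustment; ``a`` must be nonzero."""

    a: float = -15.0
    b: float = math.log(9999.0)

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("logistic slope a must be nonzero")


def logistic_adjust(
    S: SimilarityMatrix, p: LogisticParams = LogisticParams(), keep_diagonal: bool = True
) -> SimilarityMatrix | np.ndarray:
    """Remap every similarity x to 1/(1+exp(a*x+b)).

    With the default a < 0 the map is strictly increasing, so the relative
    order of similarities is preserved while the low-to-mid range collapses
    towards zero.  With ``keep_diagonal`` (default) the diagonal is forced
    back to 1 and a :class:`SimilarityMatrix` is returned; otherwise the
    adjusted diagonal (L(1) < 1) is kept and the symmetric raw array is
    returned, since it is no longer a unit-diagonal similarity matrix.
    """
    x = S.values
    out = 1.0 / (1.0 + np.exp(p.a * x + p.b))
    if not keep_diagonal:
        return out
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, S.index)


@dataclass(frozen=True)
class Cluster:
    """A cluster of entity indices with its cohesiveness score."""

    members: frozenset[int]
    cohesiveness: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the greedy cohesiveness clustering.

    ``penalty_per_node`` is the per-node contribution to the penalty term
    P(M) = penalty_per_node * |M|; it damps the score of small sets whose
    few internal edges would otherwise look artificially cohesive.
    ``min_density`` filters final clusters by internal weighted density
    2*C_in / (|M|*(|M|-1)).  Clusters whose overlap score
    w(A,B) = |A∩B|^2 / (|A|*|B|) reaches ``overlap_merge_threshold`` are
    merged.  ``edge_threshold`` drops edges with weight below the given
    value before clustering (dense all-positive kernels otherwise present
    a complete graph in which no boundary exists); ``None`` keeps every
    positive weight.
    """

    penalty_per_node: float = 2.0
    min_size: int = 3
    min_density: float = 0.1
    overlap_merge_threshold: float = 0.8
    edge_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty_per_node < 0:
            raise ValueError("penalty_per_node must be >= 0")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if not 0 < self.overlap_merge_threshold <= 1:
            raise ValueError("overlap_merge_threshold must be in (0, 1]")


def cohesiveness(
    weights: np.ndarray, members: Iterable[int], penalty_per_node: float = 0.0
) -> float:
    """Cohesiveness f(M) of a vertex set in a weighted graph.

    f(M) = C_in / (C_in + C_bound + penalty_per_node * |M|), in [0, 1];
    0 when all three terms vanish.
    """
    W = np.asarray(weights, dtype=np.float64)
    idx = np.fromiter(members, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("member set must be nonempty")
    mask = np.zeros(W.shape[0], dtype=bool)
    mask[idx] = True
    sub = W[np.ix_(mask, mask)]
    c_in = (sub.sum() - np.trace(sub)) / 2.0
    c_bound = W[np.ix_(mask, ~mask)].sum()
    denom = c_in + c_bound + penalty_per_node * idx.size
    if denom == 0.0:
        return 0.0
    return float(c_in / denom)


def _grow_cluster(W: np.ndarray, seed_vertex: int, penalty: float) -> frozenset[int]:
    """Greedy add/remove growth from a seed, accepting only strict
    cohesiveness increases; ties broken by lowest vertex index."""
    n = W.shape[0]
    member = np.zeros(n, dtype=bool)
    member[seed_vertex] = True
    deg = W.sum(axis=1)
    # w_to: total edge weight from each vertex into the current cluster
    w_to = W[:, seed_vertex].copy()
    c_in = 0.0
    c_bound = float(deg[seed_vertex])
    size = 1

    def score(ci: float, cb: float, sz: int) -> float:
        den = ci + cb + penalty * sz
        return ci / den if den > 0 else 0.0

    current = score(c_in, c_bound, size)
    while True:
        best_gain = 0.0
        best_action: tuple[str, int] | None = None
        # candidate additions: external vertices with an edge into the cluster
        ext = np.flatnonzero(~member & (w_to > 0))
        for v in ext:
            ci = c_in + w_to[v]
            cb = c_bound - w_to[v] + (deg[v] - w_to[v])
            s = score(ci, cb, size + 1)
            if s - current > best_gain + 1e-15:
                best_gain = s - current
                best_action = ("add", int(v))
        if size > 1:
            for v in np.flatnonzero(member):
                ci = c_in - w_to[v]
                cb = c_bound + w_to[v] - (deg[v] - w_to[v])
                s = score(ci, cb, size - 1)
                if s - current > best_gain + 1e-15:
                    best_gain = s - current
                    best_action = ("remove", int(v))
        if best_action is None:
            break
        op, v = best_action
        if op == "add":
            c_in += w_to[v]
            c_bound += deg[v] - 2.0 * w_to[v]
            member[v] = True
            size += 1
            w_to += W[:, v]
        else:
            member[v] = False
            size -= 1
            w_to -= W[:, v]
            c_in -= w_to[v]
            c_bound -= deg[v] - 2.0 * w_to[v]
        current = score(c_in, c_bound, size)
    return frozenset(int(i) for i in np.flatnonzero(member))


def _overlap_score(a: frozenset[int], b: frozenset[int]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def cluster_one(S: SimilarityMatrix, cfg: ClusteringConfig = ClusteringConfig()) -> list[Cluster]:
    """Greedy cohesiveness clustering of a similarity graph.

    Seeds are taken in decreasing weighted-degree order among vertices not
    yet covered by a cluster; each seed is grown with add/remove steps that
    strictly increase cohesiveness; grown groups are filtered by size and
    internal density and merged when they overlap heavily.  Deterministic
    for a given input (ties broken by vertex index).
    """
    W = S.values.copy()
    np.fill_diagonal(W, 0.0)
    if cfg.edge_threshold is not None:
        W[W < cfg.edge_threshold] = 0.0
    n = W.shape[0]
    deg = W.sum(axis=1)
    covered = np.zeros(n, dtype=bool)
    raw: list[frozenset[int]] = []
    # stable seed order: by (-degree, index)
    order = np.lexsort((np.arange(n), -deg))
    for v in order:
        if covered[v] or deg[v] <= 0:
            continue
        grown = _grow_cluster(W, int(v), cfg.penalty_per_node)
        for u in grown:
            covered[u] = True
        if len(grown) >= cfg.min_size:
            raw.append(grown)

    # merge highly overlapping clusters until stable
    merged = True
    while merged:
        merged = False
        out: list[frozenset[int]] = []
        while raw:
            cur = raw.pop(0)
            i = 0
            while i < len(raw):
                if _overlap_score(cur, raw[i]) >= cfg.overlap_merge_threshold:
                    cur = cur | raw.pop(i)
                    merged = True
                else:
                    i += 1
            out.append(cur)
        raw = out

    clusters: list[Cluster] = []
    for members in raw:
        idx = sorted(members)
        sub = W[np.ix_(idx, idx)]
        k = len(idx)
        density = sub.sum() / (k * (k - 1)) if k > 1 else 0.0
        if density < cfg.min_density:
            continue
        clusters.append(
            Cluster(frozenset(idx), cohesiveness(W, idx, cfg.penalty_per_node))
        )
    clusters.sort(key=lambda c: sorted(c.members))
    return clusters


def boost_with_clusters(
    S_raw: SimilarityMatrix, S_adj: SimilarityMatrix, clusters: Sequence[Cluster]
) -> SimilarityMatrix:
    """Restore the raw similarity for co-clustered pairs.

    For every pair that shares at least one cluster the output entry is
    max(S_adj, S_raw); all other entries come from S_adj.  Never lowers an
    entry below S_adj and never exceeds the elementwise max of the inputs.
    """
    if S_raw.index != S_adj.index:
        raise ValueError("raw and adjusted similarity matrices must share an index")
    n = len(S_raw.index)
    co = np.zeros((n, n), dtype=bool)
    for cl in clusters:
        idx = np.fromiter(cl.members, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("cluster member index outside the similarity index")
        co[np.ix_(idx, idx)] = True
    out = np.where(co, np.maximum(S_adj.values, S_raw.values), S_adj.values)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, S_adj.index)


@dataclass(frozen=True)
class FingerprintConfig:
    """Hashed circular (Morgan) fingerprint settings for the optional
    SMILES-derived similarity path."""

    radius: int = 2
    n_bits: int = 2048


@dataclass
class FingerprintResult:
    similarity: SimilarityMatrix
    skipped: list[tuple[str, str]] = field(default_factory=list)


def tanimoto_from_smiles(
    smiles_records: Sequence[tuple[str, str]],
    config: FingerprintConfig = FingerprintConfig(),
) -> FingerprintResult:
    """Pairwise Tanimoto similarity of hashed 2D fingerprints.

    ``smiles_records`` is a sequence of (id, SMILES) pairs.  Records whose
    SMILES cannot be parsed are skipped with a warning and reported in the
    result.  This path is an approximation of fingerprint similarities
    computed with other toolkits; precomputed similarity matrices remain
    the primary input.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit.DataStructs import BulkTanimotoSimilarity

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )
    ids: list[str] = []
    fps = []
    skipped: list[tuple[str, str]] = []
    for rec_id, smi in smiles_records:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("unparseable SMILES for %s: %r (skipped)", rec_id, smi)
            skipped.append((rec_id, smi))
            continue
        ids.append(rec_id)
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            sim[i, i + 1:] = BulkTanimotoSimilarity(fps[i], fps[i + 1:])
    sim = np.maximum(sim, sim.T)
    return FingerprintResult(
        SimilarityMatrix(sim, EntityIndex.from_iterable(ids)), skipped
    )
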