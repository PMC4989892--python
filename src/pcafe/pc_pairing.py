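"""Cross-modality PC pairing by UPGMA on loading correlations.

Which principal component carries the biology shared by expression and
promoter methylation is decided unsupervised: the loadings of every PC of
both modalities are z-scored over samples, all pairwise correlations
rho_kk' are computed on the joint label set, and the PCs are clustered by
UPGMA under the distance -|rho_kk'|.  A pair of PCs from *different*
modalities that ends up as sibling leaves with a small merge height (high
|correlation|) is the candidate shared axis.  Leave-one-out reruns over
samples measure how often that pairing survives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data_io import AlignmentError, OmicsMatrix
from .pca_fe import Decomposition, DegenerateInputError, embed_features

__all__ = [
    "LoadingCorrelation",
    "ClusterTree",
    "PCPair",
    "standardize_loadings",
    "loading_correlation",
    "upgma",
    "find_coincident_pairs",
    "mutual_nearest_pairs",
    "relabel_components",
    "loo_stability",
]


def standardize_loadings(dec_or_loadings: Decomposition | np.ndarray) -> np.ndarray:
    """z-score each loading column over samples (population sd, divisor J).

    rho is scale-invariant, so using the J-1 divisor instead would change
    nothing downstream; the population form matches the defining mean-over-
    samples notation and is what the tests pin down.
    """
    c = (
        dec_or_loadings.loadings
        if isinstance(dec_or_loadings, Decomposition)
        else np.asarray(dec_or_loadings, dtype=float)
    )
    mu = c.mean(axis=0)
    sd = np.sqrt(((c - mu) ** 2).mean(axis=0))
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateInputError(f"loading column {bad} is constant")
    return (c - mu) / sd


@dataclass
class LoadingCorrelation:
    """All pairwise loading correlations on the joint PC label set.

    Labels carry a modality tag: expression PCs are "PC1".."PCK",
    methylation PCs "PC1M".."PCKM".  ``rho`` is symmetric with unit
    diagonal over that joint set.
    """

    labels: list[str]
    modalities: list[str]
    rho: np.ndarray
    std_loadings: np.ndarray  # samples x labels, z-scored

    def value(self, a: str, b: str) -> float:
        return float(self.rho[self.labels.index(a), self.labels.index(b)])

    def modality_of(self, label: str) -> str:
        return self.modalities[self.labels.index(label)]


def loading_correlation(
    dec_a: Decomposition,
    dec_b: Decomposition,
    n_components: int,
    tags: tuple[str, str] = ("", "M"),
    modality_names: tuple[str, str] = ("expression", "methylation"),
) -> LoadingCorrelation:
    """rho_kk' = <dc_jk dc_jk'>_j over the joint 2K component set.

    Both decompositions must come from the same ordered samples; the
    correlation is the mean over samples of the products of z-scored
    loadings, i.e. the sample Pearson correlation.
    """
    K = int(n_components)
    for d in (dec_a, dec_b):
        if K > d.n_components:
            raise ValueError(f"n_components {K} exceeds decomposition K {d.n_components}")
    if dec_a.loadings.shape[0] != dec_b.loadings.shape[0]:
        raise AlignmentError("decompositions have different sample counts")
    za = standardize_loadings(dec_a)[:, :K]
    zb = standardize_loadings(dec_b)[:, :K]
    z = np.hstack([za, zb])
    labels = [f"PC{k + 1}{tags[0]}" for k in range(K)] + [
        f"PC{k + 1}{tags[1]}" for k in range(K)
    ]
    modalities = [modality_names[0]] * K + [modality_names[1]] * K
    rho = (z.T @ z) / z.shape[0]
    np.fill_diagonal(rho, 1.0)
    return LoadingCorrelation(labels=labels, modalities=modalities, rho=rho, std_loadings=z)


@dataclass
class Merge:
    """One agglomeration step: the two merged clusters and the height."""

    left: frozenset[str]
    right: frozenset[str]
    height: float

    @property
    def members(self) -> frozenset[str]:
        return self.left | self.right


@dataclass
class ClusterTree:
    """A UPGMA merge sequence over PC labels, heights non-decreasing."""

    leaves: list[str]
    merges: list[Merge] = field(default_factory=list)

    def sibling_leaf_pairs(self) -> list[tuple[str, str, float]]:
        """(leaf, leaf, height) for every merge of two singleton clusters."""
        out = []
        for m in self.merges:
            if len(m.left) == 1 and len(m.right) == 1:
                (a,), (b,) = sorted(m.left), sorted(m.right)
                a, b = sorted((a, b))
                out.append((a, b, m.height))
        return out

    def to_newick(self) -> str:
        """Newick with branch lengths derived from merge heights.

        Heights are -|rho| in [-1, 0]; branch lengths are offsets from a
        -1 baseline so they stay non-negative.
        """
        node_height: dict[frozenset[str], float] = {
            frozenset([l]): -1.0 for l in self.leaves
        }
        node_repr: dict[frozenset[str], str] = {
            frozenset([l]): l for l in self.leaves
        }
        for m in self.merges:
            h = m.height
            lrep = node_repr.pop(m.left)
            rrep = node_repr.pop(m.right)
            lh = node_height.pop(m.left)
            rh = node_height.pop(m.right)
            node_repr[m.members] = f"({lrep}:{h - lh:.6g},{rrep}:{h - rh:.6g})"
            node_height[m.members] = h
        roots = sorted(node_repr.values())
        if len(roots) == 1:
            return roots[0] + ";"
        return "(" + ",".join(roots) + ");"


def upgma(labels: list[str], distance: np.ndarray) -> ClusterTree:
    """Agglomerate by unweighted pair-group average linkage.

    Repeatedly merges the pair of clusters at minimum average pairwise
    distance, updating distances as the size-weighted arithmetic mean.
    Ties are broken by the lexicographically smallest (min label, max
    label) pair so the tree is deterministic.
    """
    D = np.asarray(distance, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    clusters: dict[frozenset[str], dict] = {
        frozenset([l]): {"size": 1, "rep": l} for l in labels
    }
    dist: dict[frozenset[frozenset[str]], float] = {}
    idx = {l: i for i, l in enumerate(labels)}
    keys = list(clusters)
    for a, b in itertools.combinations(keys, 2):
        (la,), (lb,) = a, b
        dist[frozenset((a, b))] = float(D[idx[la], idx[lb]])
    tree = ClusterTree(leaves=list(labels))
    while len(clusters) > 1:
        def tiebreak(pair_key):
            a, b = tuple(pair_key)
            la = min(min(a), min(b))
            lb = max(min(a), min(b))
            return (dist[pair_key], la, lb)

        best = min(dist, key=tiebreak)
        a, b = tuple(best)
        h = dist[best]
        # put the lexicographically smaller cluster on the left
        if min(b) < min(a):
            a, b = b, a
        merged = a | b
        na, nb = clusters[a]["size"], clusters[b]["size"]
        tree.merges.append(Merge(left=a, right=b, height=h))
        del clusters[a], clusters[b]
        new_dist = {}
        for key, d in dist.items():
            x, y = tuple(key)
            if a in key or b in key:
                continue
            new_dist[key] = d
        for c in clusters:
            da = dist[frozenset((a, c))]
            db = dist[frozenset((b, c))]
            new_dist[frozenset((merged, c))] = (na * da + nb * db) / (na + nb)
        clusters[merged] = {"size": na + nb, "rep": None}
        dist = new_dist
    return tree


@dataclass(frozen=True)
class PCPair:
    """A cross-modality sibling pair with its loading correlation."""

    expression_pc: str
    methylation_pc: str
    rho: float

    @property
    def abs_rho(self) -> float:
        return abs(self.rho)


def find_coincident_pairs(tree: ClusterTree, rho: LoadingCorrelation) -> list[PCPair]:
    """Sibling leaf pairs whose members belong to different modalities.

    Ordered by merge height (smallest distance, i.e. largest |rho|,
    first).  Same-modality sibling pairs are excluded.
    """
    pairs = []
    for a, b, h in sorted(tree.sibling_leaf_pairs(), key=lambda t: (t[2], t[0], t[1])):
        ma, mb = rho.modality_of(a), rho.modality_of(b)
        if ma == mb:
            continue
        if ma != "expression":
            a, b = b, a
        pairs.append(PCPair(expression_pc=a, methylation_pc=b, rho=rho.value(a, b)))
    return pairs


def mutual_nearest_pairs(rho: LoadingCorrelation) -> list[PCPair]:
    """Alternative pairing rule: mutual nearest neighbours by |rho|.

    For sensitivity checks against the sibling-leaf rule; a pair is kept
    when each member is the other's highest-|rho| partner in the other
    modality.
    """
    labels = rho.labels
    expr = [l for l in labels if rho.modality_of(l) == "expression"]
    meth = [l for l in labels if rho.modality_of(l) != "expression"]
    out = []
    for e in expr:
        best_m = max(meth, key=lambda m: abs(rho.value(e, m)))
        best_e = max(expr, key=lambda x: abs(rho.value(x, best_m)))
        if best_e == e:
            out.append(PCPair(e, best_m, rho.value(e, best_m)))
    return sorted(out, key=lambda p: -p.abs_rho)


def relabel_components(
    reduced: np.ndarray, full: np.ndarray, labels: list[str]
) -> list[str]:
    """Match reduced-sample PCs to full-sample PC labels by |correlation|.

    Both loading matrices are restricted to the same samples and z-scored;
    assignment is greedy, highest |correlation| first, each full label
    used once.  Returns the full-sample label for each reduced column, a
    bijection onto *labels*.
    """
    zr = standardize_loadings(reduced)
    zf = standardize_loadings(full)
    K = zr.shape[1]
    if zf.shape[1] != K or len(labels) != K:
        raise ValueError("reduced and full must have the same number of components")
    corr = np.abs(zr.T @ zf) / zr.shape[0]
    assignment: dict[int, int] = {}
    used_r: set[int] = set()
    used_f: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
    for r, f in order:
        if r in used_r or f in used_f:
            continue
        assignment[int(r)] = int(f)
        used_r.add(int(r))
        used_f.add(int(f))
        if len(assignment) == K:
            break
    return [labels[assignment[r]] for r in range(K)]


def loo_stability(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    target_pairs: list[PCPair],
    n_components: int = 5,
    require_all: bool = True,
) -> tuple[int, list[bool]]:
    """Leave-one-out conservation count of the target PC pairing.

    For each of the J samples, the same sample is removed from both
    modalities, the decompositions are recomputed, the first K
    reduced-sample PCs are relabelled with the full-sample labels of
    maximum |loading correlation| on the shared J-1 samples, the UPGMA
    tree is rebuilt, and the target pairs are checked for cross-modality
    siblinghood under the relabelled names.  Returns the conservation
    count and the per-subset outcomes.
    """
    J = expr.n_samples
    if meth.n_samples != J:
        raise AlignmentError("modalities must be aligned to the same samples")
    K = int(n_components)
    if K > J - 1:
        raise ValueError(f"n_components must be <= J-1 = {J - 1}")
    if not target_pairs:
        return J, [True] * J
    targets = {frozenset((p.expression_pc, p.methylation_pc)) for p in target_pairs}
    full_e = embed_features(expr, K)
    full_m = embed_features(meth, K)
    labels_e = [f"PC{k + 1}" for k in range(K)]
    labels_m = [f"PC{k + 1}M" for k in range(K)]
    outcomes: list[bool] = []
    for j in range(J):
        keep = [x for x in range(J) if x != j]
        red_e = embed_features(expr.subset_samples(keep), K)
        red_m = embed_features(meth.subset_samples(keep), K)
        names_e = relabel_components(red_e.loadings, full_e.loadings[keep], labels_e)
        names_m = relabel_components(red_m.loadings, full_m.loadings[keep], labels_m)
        rho = loading_correlation(red_e, red_m, K)
        # rewrite the joint labels with the relabelled names
        rho = LoadingCorrelation(
            labels=names_e + names_m,
            modalities=rho.modalities,
            rho=rho.rho,
            std_loadings=rho.std_loadings,
        )
        tree = upgma(rho.labels, -np.abs(rho.rho))
        found = {
            frozenset((p.expression_pc, p.methylation_pc))
            for p in find_coincident_pairs(tree, rho)
        }
        ok = targets <= found if require_all else bool(targets & found)
        outcomes.append(ok)
    return sum(outcomes), outcomes
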