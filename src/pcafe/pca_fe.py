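"""Feature-embedding PCA and directional outlier selection.

In the usual PCA convention the samples receive low-dimensional
coordinates.  Here the convention is transposed: the probes (features)
are embedded.  Each sample column is centred by its mean over features,
the orthonormal axes ``c_jk`` of the resulting matrix's sample space are
the PC loadings (contribution of sample ``j`` to component ``k``), and
the score of probe ``i`` on component ``k`` is

    x_ik = sum_j c_jk * (x_ij - <x_i'j>_i')

Probes far out along a chosen component in either direction ("larger" or
"smaller" scores) are the extracted features; cross-modality agreement of
the top-N directional sets defines the selected candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_io import AlignmentError, OmicsMatrix

__all__ = [
    "Decomposition",
    "DirectionalRanking",
    "DegenerateInputError",
    "embed_features",
    "rank_outliers",
    "select_top",
    "intersect_directional",
    "directional_union",
]

Direction = Literal["larger", "smaller"]


class DegenerateInputError(ValueError):
    """The input carries no variance for the requested operation."""


@dataclass
class Decomposition:
    """PCA of one modality under the feature-embedding convention.

    ``loadings[j, k]`` is c_jk (orthonormal columns, PC1 first, variance
    non-increasing); ``scores[i, k]`` is x_ik; ``sample_means[j]`` is the
    per-sample mean over features that was subtracted before the
    decomposition.  Component labels are 1-based ("PC1"..).
    """

    loadings: np.ndarray
    scores: np.ndarray
    feature_ids: list[str]
    sample_means: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def component_labels(self) -> list[str]:
        return [f"PC{k + 1}" for k in range(self.n_components)]

    def pc_index(self, pc: int | str) -> int:
        """0-based column index for a 1-based number or 'PCk' label."""
        if isinstance(pc, str):
            if not pc.upper().startswith("PC"):
                raise ValueError(f"bad component label {pc!r}")
            digits = "".join(ch for ch in pc[2:] if ch.isdigit())
            if not digits or not pc[2:].startswith(digits):
                raise ValueError(f"bad component label {pc!r}")
            pc = int(digits)  # modality tags ("PC3M") are stripped
        if not 1 <= pc <= self.n_components:
            raise ValueError(
                f"component {pc} outside 1..{self.n_components}"
            )
        return pc - 1


@dataclass
class DirectionalRanking:
    """All probes ranked by score along one PC in one direction.

    Rank 1 is the most extreme probe; ties are broken by probe id so the
    ranking is a deterministic function of the decomposition.
    """

    pc: str
    direction: Direction
    probe_ids: list[str]
    scores: np.ndarray


def embed_features(m: OmicsMatrix, n_components: int | None = None) -> Decomposition:
    """Embed probes into PC space via the sample-space axes.

    Centres every sample column by its mean over features (no per-feature
    centring, no scaling), takes the SVD of the centred matrix, and
    returns loadings/scores under a fixed sign convention: each loading
    column is flipped, if needed, so that its largest-magnitude element is
    positive.  Deterministic for a fixed input.
    """
    X = m.values
    I, J = X.shape
    if I < 2 or J < 2:
        raise ValueError("need at least 2 features and 2 samples")
    kmax = min(I, J)
    K = kmax if n_components is None else int(n_components)
    if not 1 <= K <= kmax:
        raise ValueError(f"n_components must be in 1..{kmax}, got {K}")
    sample_means = X.mean(axis=0)
    Xc = X - sample_means[None, :]
    if not np.any(np.abs(Xc) > 0):
        raise DegenerateInputError("centred matrix is identically zero")
    # SVD in the J-dim sample space: columns of V are the loading axes.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T[:, :K]
    scores = (U[:, :K] * s[:K])
    # Sign rule: largest-|element| of each loading column made positive.
    for k in range(K):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    return Decomposition(
        loadings=loadings,
        scores=scores,
        feature_ids=list(m.feature_ids),
        sample_means=sample_means,
        explained_variance=(s[:K] ** 2) / I,
    )


def rank_outliers(dec: Decomposition, pc: int | str, direction: Direction) -> DirectionalRanking:
    """Rank every probe by its score along *pc*.

    ``larger``: descending score; ``smaller``: ascending.  Equal scores
    are ordered by probe id, so the output is stable.
    """
    if direction not in ("larger", "smaller"):
        raise ValueError(f"direction must be 'larger' or 'smaller', got {direction!r}")
    k = dec.pc_index(pc)
    s = dec.scores[:, k]
    ids = np.asarray(dec.feature_ids, dtype=object)
    # lexsort: last key is primary; secondary id sort makes ties stable
    id_order = np.argsort(ids, kind="stable")
    key = -s if direction == "larger" else s
    order = id_order[np.argsort(key[id_order], kind="stable")]
    return DirectionalRanking(
        pc=f"PC{k + 1}",
        direction=direction,
        probe_ids=[str(x) for x in ids[order]],
        scores=s[order],
    )


def select_top(r: DirectionalRanking, n: int = 300) -> set[str]:
    """The first *n* probes of a directional ranking, as a set."""
    if not 1 <= n <= len(r.probe_ids):
        raise ValueError(f"n must be in 1..{len(r.probe_ids)}, got {n}")
    return set(r.probe_ids[:n])


def directional_union(dec: Decomposition, pc: int | str, n: int = 300) -> set[str]:
    """Union of the top-n 'larger' and top-n 'smaller' sets along *pc*."""
    return select_top(rank_outliers(dec, pc, "larger"), n) | select_top(
        rank_outliers(dec, pc, "smaller"), n
    )


def intersect_directional(
    expr_dec: Decomposition,
    meth_dec: Decomposition,
    expr_pc: int | str,
    meth_pc: int | str,
    n: int = 300,
) -> set[str]:
    """Probes commonly extreme in both modalities along the chosen PCs.

    Takes the union over the four direction combinations (expression
    larger/smaller x methylation larger/smaller) of the pairwise top-n
    intersections.  This equals the intersection of the two modality-wise
    unions of both directional top-n sets; the identity is exercised in
    the test suite.
    """
    if set(expr_dec.feature_ids) != set(meth_dec.feature_ids):
        raise AlignmentError("decompositions do not share a probe universe")
    out: set[str] = set()
    for d_e in ("larger", "smaller"):
        e_top = select_top(rank_outliers(expr_dec, expr_pc, d_e), n)
        for d_m in ("larger", "smaller"):
            m_top = select_top(rank_outliers(meth_dec, meth_pc, d_m), n)
            out |= e_top & m_top
    return out
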