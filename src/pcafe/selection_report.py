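"""Combine feature-extraction results into the final candidate table.

Each reported gene carries the methods that selected it and a per-gene
expression/promoter-methylation Pearson correlation across the shared
samples, with a flag for significant negative correlation (r < 0 and
two-sided P < 0.05) — promoter methylation is classically expected to
silence expression, but candidates are not restricted to that direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import OmicsMatrix, ProbeAnnotation
from .pca_fe import DegenerateInputError

__all__ = [
    "GeneReport",
    "per_gene_correlation",
    "combine_methods",
    "gene_correlations",
]

NEGATIVE_ALPHA = 0.05


@dataclass
class GeneReport:
    """One row of the candidate table."""

    gene: str
    methods: frozenset[str]
    r: float | None = None
    p: float | None = None
    negative_significant: bool | None = None


def per_gene_correlation(
    expr_values: np.ndarray, meth_values: np.ndarray
) -> tuple[float, float, bool]:
    """Pearson r between expression and methylation, exact t-based P.

    P is two-sided from t = r*sqrt(J-2)/sqrt(1-r^2) on J-2 degrees of
    freedom; the flag is ``r < 0 and P < 0.05``.
    """
    x = np.asarray(expr_values, dtype=float)
    y = np.asarray(meth_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression and methylation vectors must have equal length")
    J = x.size
    if J < 3:
        raise ValueError("need at least 3 samples for a correlation P-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector has no defined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((J - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), J - 2))
    return r, p, (r < 0 and p < NEGATIVE_ALPHA)


def combine_methods(
    pca_genes_per_pc: dict[str, set[str]], catreg_genes: set[str]
) -> tuple[list[GeneReport], int, int]:
    """Union the per-method gene sets into a report table.

    Returns (rows, unique gene count, count of genes selected by more
    than one method).  Method labels are ``pca_fe_<pc>`` (lower-cased PC
    label) and ``catreg``.
    """
    membership: dict[str, set[str]] = {}
    for pc, genes in pca_genes_per_pc.items():
        tag = f"pca_fe_{str(pc).lower()}"
        for g in genes:
            membership.setdefault(g, set()).add(tag)
    for g in catreg_genes:
        membership.setdefault(g, set()).add("catreg")
    rows = [
        GeneReport(gene=g, methods=frozenset(ms))
        for g, ms in sorted(membership.items())
    ]
    unique = len(rows)
    multi = sum(1 for r in rows if len(r.methods) > 1)
    return rows, unique, multi


def _gene_probes(ids: list[str], ann: ProbeAnnotation | None, gene: str) -> list[int]:
    if ann is None:
        return [i for i, p in enumerate(ids) if p == gene]
    return [i for i, p in enumerate(ids) if ann.symbol(p) == gene]


def gene_correlations(
    rows: list[GeneReport],
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    annotation: ProbeAnnotation | None = None,
    reduction: str = "best_pair",
) -> list[GeneReport]:
    """Fill correlation columns of a report from aligned matrices.

    A gene may have several probes in either modality and the probe
    universes differ; under ``best_pair`` (default) every expression
    probe of the gene is paired with every methylation probe and the
    smallest-P pair is reported.  Under ``mean`` the per-modality probe
    values are averaged first and a single correlation computed.  With
    ``annotation=None`` probe ids are treated as gene ids directly
    (synthetic data).
    """
    if reduction not in ("best_pair", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    out = []
    for row in rows:
        ei = _gene_probes(expr.feature_ids, annotation, row.gene)
        mi = _gene_probes(meth.feature_ids, annotation, row.gene)
        if not ei or not mi:
            out.append(row)
            continue
        if reduction == "mean":
            r, p, flag = per_gene_correlation(
                expr.values[ei].mean(axis=0), meth.values[mi].mean(axis=0)
            )
        else:
            best: tuple[float, float, bool] | None = None
            for a in ei:
                for b in mi:
                    try:
                        cand = per_gene_correlation(expr.values[a], meth.values[b])
                    except DegenerateInputError:
                        continue
                    if best is None or cand[1] < best[1]:
                        best = cand
            if best is None:
                out.append(row)
                continue
            r, p, flag = best
        out.append(
            GeneReport(
                gene=row.gene,
                methods=row.methods,
                r=r,
                p=p,
                negative_significant=flag,
            )
        )
    return out
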