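"""Paired expression/methylation simulator with planted ground truth.

The generator reproduces the statistical structure the pairing analysis
relies on: a latent factor with identical sample scores in both
modalities that is *not* the leading variance component (two stronger
modality-private nuisance factors sit above it, so the shared axis lands
near PC3), per-cell-line mean offsets replicated three times, and a small
planted set of probes loading strongly on the shared factor in both
modalities.  Everything is Gaussian — an analyzability choice for the
test harness, not an assumption of the pipeline.

The default design mirrors the study panel: 8 cell-line categories
(embryonic stem, two NSCLC lines, a fibroblast, three reprogrammed
derivatives and a re-differentiated line) x 3 replicates = 24 samples per
modality, with thousands of probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import OmicsMatrix, SampleInfo

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "write_fixtures"]

DEFAULT_CATEGORIES = (
    "H1",
    "H358",
    "H460",
    "IMR90",
    "iPCH358",
    "iPCH460",
    "iPSIMR90",
    "piPCH358",
)


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the reference study conditions.

    ``nuisance_variances`` are the per-probe loading variances of the
    modality-private factors, strictly decreasing and all larger than
    ``shared_factor_variance`` (the background loading variance on the
    shared factor) so the shared axis cannot become PC1/PC2.  Planted
    probes override the background with loading magnitude
    ``planted_loading``; ``planted_sign_mix`` is the fraction whose signs
    disagree between modalities, exercising all four directional
    selection combinations.  Units are arbitrary array-intensity units.
    """

    seed: int = 0
    n_probes: int = 5000
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_replicates: int = 3
    nuisance_variances: tuple[float, ...] = (9.0, 4.0)
    shared_factor_variance: float = 1.0
    n_planted: int = 50
    planted_loading: float = 5.0
    planted_sign_mix: float = 0.5
    noise_sd: float = 1.0
    category_effect_sd: float = 0.5
    baseline: float = 100.0

    @property
    def n_samples(self) -> int:
        return len(self.categories) * self.n_replicates

    def validate(self) -> None:
        if self.n_probes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 probes and 2 samples")
        if not 0 <= self.n_planted < self.n_probes:
            raise ValueError("n_planted must be in [0, n_probes)")
        if self.nuisance_variances and self.shared_factor_variance >= min(
            self.nuisance_variances
        ):
            raise ValueError(
                "shared_factor_variance must be smaller than every nuisance "
                "variance so the shared factor is not a leading component"
            )
        if any(
            a <= b
            for a, b in zip(self.nuisance_variances, self.nuisance_variances[1:])
        ):
            raise ValueError("nuisance_variances must be strictly decreasing")
        if not 0.0 <= self.planted_sign_mix <= 1.0:
            raise ValueError("planted_sign_mix must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted_probes: list[str]
    shared_scores: np.ndarray  # per-sample pattern of the shared factor
    shared_loadings: dict[str, np.ndarray] = field(default_factory=dict)


def _samples(cfg: SyntheticConfig, modality: str) -> list[SampleInfo]:
    return [
        SampleInfo(
            sample_id=f"{modality[:4]}_{cat}_{rep}",
            category=cat,
            replicate=rep,
            modality=modality,
        )
        for cat in cfg.categories
        for rep in range(1, cfg.n_replicates + 1)
    ]


def generate(
    cfg: SyntheticConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SyntheticTruth]:
    """Draw one paired dataset; byte-reproducible from ``cfg.seed``.

    Model per modality m:
        x_ij = baseline + mu^m_{i,cat(j)} + sum_f w^m_if s^m_fj
               + w^m_{i,shared} s_shared_j + eps^m_ij
    with s_shared shared across modalities and everything else private.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    I, J = cfg.n_probes, cfg.n_samples
    probe_ids = [f"p{i:05d}" for i in range(I)]
    planted = list(rng.choice(I, size=cfg.n_planted, replace=False)) if cfg.n_planted else []
    planted_set = sorted(int(i) for i in planted)

    def _center_scale(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v * np.sqrt(J) / np.linalg.norm(v)

    # Factor scores are centred, unit-variance and mutually orthogonal
    # within each modality: with only J=24 samples, raw Gaussian draws
    # carry chance correlations ~ 1/sqrt(J) that would rotate the shared
    # axis differently per modality and blur the planted ground truth.
    s_shared = _center_scale(rng.standard_normal(J))
    expr_signs = rng.choice([-1.0, 1.0], size=cfg.n_planted)
    n_flip = int(round(cfg.planted_sign_mix * cfg.n_planted))
    meth_signs = expr_signs.copy()
    meth_signs[:n_flip] *= -1.0

    cat_index = np.repeat(np.arange(len(cfg.categories)), cfg.n_replicates)
    truth = SyntheticTruth(
        planted_probes=[probe_ids[i] for i in planted_set],
        shared_scores=s_shared,
    )
    mats = []
    for modality, signs in (("expression", expr_signs), ("methylation", meth_signs)):
        mu = rng.normal(0.0, cfg.category_effect_sd, size=(I, len(cfg.categories)))
        X = cfg.baseline + mu[:, cat_index]
        basis = [s_shared]
        for v in cfg.nuisance_variances:
            w = rng.normal(0.0, np.sqrt(v), size=I)
            s = rng.standard_normal(J)
            for b in basis:
                s = s - (s @ b) / (b @ b) * b
            s = _center_scale(s)
            basis.append(s)
            X += np.outer(w, s)
        w_shared = rng.normal(0.0, np.sqrt(cfg.shared_factor_variance), size=I)
        if cfg.n_planted:
            # planted probes override the background loading
            w_shared[np.array(planted, dtype=int)] = cfg.planted_loading * signs
        X += np.outer(w_shared, s_shared)
        if cfg.noise_sd > 0:
            X += rng.normal(0.0, cfg.noise_sd, size=(I, J))
        truth.shared_loadings[modality] = w_shared
        mats.append(OmicsMatrix(X, list(probe_ids), _samples(cfg, modality)))
    return mats[0], mats[1], truth


def write_fixtures(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    out_dir: str | Path,
    genes_per_probe_pair: bool = True,
) -> dict[str, Path]:
    """Emit file-format fixtures exercised by the readers.

    Writes a probe-profile-style expression table ("AVG Signal" columns
    interleaved with decoy "Detection Pval" columns), a series-matrix
    methylation table fenced by the standard sentinels, and a toy
    annotation mapping consecutive probe pairs to one gene (so gene
    collapse is exercised).  Floats use ``repr`` so re-reading is exact.
    """
    if expr.n_features == 0 or expr.n_samples == 0:
        raise ValueError("cannot write fixtures for an empty matrix")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression_probe_profile.txt",
        "methylation": out_dir / "methylation_series_matrix.txt",
        "annotation": out_dir / "annotation.txt",
        "sample_map": out_dir / "sample_map.yaml",
    }
    with open(paths["expression"], "w", encoding="utf-8") as fh:
        cols = []
        for s in expr.samples:
            cols += [f"{s.sample_id}.AVG Signal", f"{s.sample_id}.Detection Pval"]
        fh.write("ProbeID\t" + "\t".join(cols) + "\n")
        for i, pid in enumerate(expr.feature_ids):
            cells = []
            for v in expr.values[i]:
                cells += [repr(float(v)), "0.01"]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")
    with open(paths["methylation"], "w", encoding="utf-8") as fh:
        fh.write("!Series_title\t\"synthetic methylation fixture\"\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write(
            "\"ID_REF\"\t" + "\t".join(f'"{s.sample_id}"' for s in meth.samples) + "\n"
        )
        for i, pid in enumerate(meth.feature_ids):
            fh.write(
                f'"{pid}"\t' + "\t".join(repr(float(v)) for v in meth.values[i]) + "\n"
            )
        fh.write("!series_matrix_table_end\n")
    with open(paths["annotation"], "w", encoding="utf-8") as fh:
        fh.write("ProbeID\tAccession\tSymbol\n")
        all_ids = list(dict.fromkeys(expr.feature_ids + meth.feature_ids))
        for i, pid in enumerate(all_ids):
            g = i // 2 if genes_per_probe_pair else i
            fh.write(f"{pid}\tNM_{g:06d}\tG{g:05d}\n")
    with open(paths["sample_map"], "w", encoding="utf-8") as fh:
        fh.write("# sample id -> [category, replicate]\n")
        for s in list(expr.samples) + list(meth.samples):
            fh.write(f"{s.sample_id}: [{s.category}, {s.replicate}]\n")
    return paths
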