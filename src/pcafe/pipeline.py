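"""End-to-end orchestration: read/generate -> align -> embed -> pair ->
feature extraction (two methods) -> report -> stability.

Stages communicate through TSV/JSON files under the output directory so
a run is auditable and partially re-runnable; a manifest records the
config snapshot, the selected PC pairs, per-stage outputs and the
headline counts.  For a fixed config (and seed, in synthetic mode) the
run is deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import catreg_fe, data_io, pca_fe, pc_pairing, selection_report
from .data_io import OmicsMatrix, ProbeAnnotation
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "run_all", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """The run configuration is missing or inconsistent."""


DEFAULTS: dict[str, Any] = {
    "mode": "synthetic",          # or "files"
    "n_components": 5,            # PCs per modality entering the clustering
    "top_n": 300,                 # directional / P-value top-N
    "max_pairs": 2,               # coincident PC pairs carried into FE
    "pairing_rule": "sibling",    # or "mutual_nearest"
    "run_stability": True,
    "stability_require_all": True,
    "stability_max_pairs": 1,     # pairs whose conservation is required
    "correlation_reduction": "best_pair",
    "synthetic": {},              # SyntheticConfig overrides
    "seed": 0,
}


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path, "rt", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(
    cfg: dict,
) -> tuple[OmicsMatrix, OmicsMatrix, ProbeAnnotation | None, dict]:
    meta: dict[str, Any] = {}
    if cfg["mode"] == "synthetic":
        syn_kwargs = dict(cfg.get("synthetic") or {})
        syn_kwargs.setdefault("seed", cfg.get("seed", 0))
        if "categories" in syn_kwargs:
            syn_kwargs["categories"] = tuple(syn_kwargs["categories"])
        if "nuisance_variances" in syn_kwargs:
            syn_kwargs["nuisance_variances"] = tuple(syn_kwargs["nuisance_variances"])
        scfg = SyntheticConfig(**syn_kwargs)
        expr, meth, truth = generate(scfg)
        meta["synthetic_config"] = dataclasses.asdict(scfg)
        meta["n_planted"] = len(truth.planted_probes)
        meta["truth"] = truth
        return expr, meth, None, meta
    if cfg["mode"] != "files":
        raise ConfigError(f"unknown mode {cfg['mode']!r}")
    try:
        expr_path = cfg["expression_file"]
        meth_path = cfg["methylation_file"]
    except KeyError as e:
        raise ConfigError(f"files mode requires {e.args[0]!r}") from None
    sample_map_raw = cfg.get("sample_map") or {}
    sample_map = {
        k: (v[0], int(v[1])) for k, v in sample_map_raw.items()
    }
    expr = data_io.read_probe_profile(
        expr_path, cfg.get("signal_column_tag", "AVG Signal")
    )
    if sample_map:
        expr = expr.with_samples(
            [
                data_io.SampleInfo(
                    s.sample_id,
                    *sample_map.get(s.sample_id, (s.sample_id, 1)),
                    modality="expression",
                )
                for s in expr.samples
            ]
        )
    meth = data_io.read_series_matrix(meth_path, sample_map or None)
    ann = None
    if cfg.get("annotation_file"):
        ann = data_io.read_annotation(cfg["annotation_file"])
    meta["input_digests"] = {
        "expression": _sha256(Path(expr_path)),
        "methylation": _sha256(Path(meth_path)),
    }
    return expr, meth, ann, meta


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def run_all(
    config: str | Path | dict | None,
    out_dir: str | Path = "pcafe_run",
    overrides: dict | None = None,
) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    if isinstance(config, dict):
        cfg = {**DEFAULTS, **config, **{k: v for k, v in (overrides or {}).items() if v is not None}}
    else:
        cfg = load_config(config, overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": {k: v for k, v in cfg.items()}, "stages": {}}
    partial_marker = out / ".partial"
    partial_marker.touch()
    stage = "load"
    try:
        expr, meth, ann, meta = _load_inputs(cfg)
        truth = meta.pop("truth", None)
        manifest.update(meta)

        stage = "align"
        expr, meth = data_io.align_modalities(expr, meth)
        expr, meth = data_io.drop_missing_features(expr, meth)
        manifest["stages"]["align"] = {
            "n_samples": expr.n_samples,
            "n_features_expression": expr.n_features,
            "n_features_methylation": meth.n_features,
        }

        stage = "embed"
        K = int(cfg["n_components"])
        dec_e = pca_fe.embed_features(expr, K)
        dec_m = pca_fe.embed_features(meth, K)

        stage = "pair"
        rho = pc_pairing.loading_correlation(dec_e, dec_m, K)
        tree = pc_pairing.upgma(rho.labels, -np.abs(rho.rho))
        if cfg["pairing_rule"] == "mutual_nearest":
            pairs = pc_pairing.mutual_nearest_pairs(rho)
        else:
            pairs = pc_pairing.find_coincident_pairs(tree, rho)
        used_pairs = pairs[: int(cfg["max_pairs"])]
        (out / "pc_tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
        _write_tsv(
            out / "pc_rho.tsv",
            ["pc"] + rho.labels,
            [[lab] + [f"{v:.6g}" for v in rho.rho[i]] for i, lab in enumerate(rho.labels)],
        )
        manifest["stages"]["pair"] = {
            "pairs": [
                {"expression_pc": p.expression_pc, "methylation_pc": p.methylation_pc,
                 "rho": p.rho}
                for p in pairs
            ],
            "used": [[p.expression_pc, p.methylation_pc] for p in used_pairs],
        }
        if not used_pairs:
            raise RuntimeError("no cross-modality PC pair found")

        stage = "pca_fe"
        top_n = int(cfg["top_n"])
        pca_probe_sets: dict[str, set[str]] = {}
        for p in used_pairs:
            sel = pca_fe.intersect_directional(
                dec_e, dec_m, p.expression_pc, p.methylation_pc, top_n
            )
            pca_probe_sets[p.expression_pc] = sel
        _write_tsv(
            out / "pca_fe_selected.tsv",
            ["pc", "probe"],
            [[pc, pr] for pc, sel in pca_probe_sets.items() for pr in sorted(sel)],
        )

        stage = "catreg_fe"
        res_e = catreg_fe.fit_categorical(expr)
        res_m = catreg_fe.fit_categorical(meth)
        sel_e = catreg_fe.select_top_p(res_e, top_n)
        sel_m = catreg_fe.select_top_p(res_m, top_n)
        if ann is None:
            catreg_sel = catreg_fe.intersect_modalities(sel_e, sel_m)
        else:
            catreg_sel = catreg_fe.intersect_modalities(
                data_io.map_probes_to_genes(sel_e, ann),
                data_io.map_probes_to_genes(sel_m, ann),
            )
        _write_tsv(
            out / "catreg_selected.tsv", ["probe_or_gene"], [[p] for p in sorted(catreg_sel)]
        )

        stage = "report"
        if ann is None:
            pca_gene_sets = pca_probe_sets
            catreg_genes = catreg_sel
        else:
            pca_gene_sets = {
                pc: data_io.map_probes_to_genes(sel, ann)
                for pc, sel in pca_probe_sets.items()
            }
            catreg_genes = catreg_sel
        rows, unique, multi = selection_report.combine_methods(
            pca_gene_sets, catreg_genes
        )
        rows = selection_report.gene_correlations(
            rows, expr, meth, ann, reduction=cfg["correlation_reduction"]
        )
        _write_tsv(
            out / "gene_report.tsv",
            ["gene", "methods", "r", "p", "negative_significant"],
            [
                [
                    r.gene,
                    ",".join(sorted(r.methods)),
                    "" if r.r is None else f"{r.r:.6g}",
                    "" if r.p is None else f"{r.p:.6g}",
                    "" if r.negative_significant is None else r.negative_significant,
                ]
                for r in rows
            ],
        )
        manifest["counts"] = {
            "pca_selected_per_pc": {pc: len(s) for pc, s in pca_probe_sets.items()},
            "catreg_selected": len(catreg_sel),
            "unique_genes": unique,
            "multi_method_genes": multi,
        }
        if truth is not None:
            planted = set(truth.planted_probes)
            sel_union = set().union(*pca_probe_sets.values())
            inter = len(sel_union & planted)
            union = len(sel_union | planted)
            manifest["counts"]["planted_jaccard"] = inter / union if union else 1.0

        if cfg["run_stability"]:
            stage = "stability"
            count, outcomes = pc_pairing.loo_stability(
                expr,
                meth,
                target_pairs=used_pairs[: int(cfg["stability_max_pairs"])],
                n_components=K,
                require_all=bool(cfg["stability_require_all"]),
            )
            _write_tsv(
                out / "stability.tsv",
                ["left_out_index", "left_out_sample", "conserved"],
                [
                    [j, expr.samples[j].sample_id, ok]
                    for j, ok in enumerate(outcomes)
                ],
            )
            manifest["counts"]["conservation"] = count
            manifest["counts"]["n_subsets"] = len(outcomes)
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        manifest["failed_stage"] = stage
        with open(out / "manifest.partial.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    partial_marker.unlink(missing_ok=True)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
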