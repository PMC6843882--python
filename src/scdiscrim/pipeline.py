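"""End-to-end orchestration: load -> filter -> rank -> IFS -> signature -> enrichment.

A single :class:`RunConfig` drives the whole analysis; ``run_all`` executes
the stages in order, writes every stage output as plain TSV (so any stage
can be re-entered independently), and records a manifest with the full
configuration, the matrix dimensions at each stage, and the selected peak.
The manifest alone suffices to re-run the analysis bit-identically.

Outputs are written with a ``.partial`` suffix and renamed when their stage
completes, so an aborted run never leaves a truncated file under a final
name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich, enrichment_frame, overlap_test
from .expression_io import (
    ExpressionMatrix,
    read_expression,
    read_gene_list,
    read_gmt,
    write_expression,
    write_gene_list,
    write_gmt,
    write_table,
)
from .ifs import curve_to_records, run_ifs
from .mrmr import annotate_ranking, mrmr_rank
from .preprocessing import discretize, filter_by_max_expression
from .signature import two_way_cluster
from .synthetic_data import SyntheticSpec, generate

logger = logging.getLogger(__name__)

STAGES = ("load", "filter", "rank", "ifs", "signature", "enrich", "overlap")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one analysis run; defaults follow the reference settings
    (expression filter at max FPKM > 5, top 500 ranked transcripts)."""

    matrix_path: str | None = None
    labels_path: str | None = None
    gmt_path: str | None = None
    comparison_list_path: str | None = None
    out_dir: str = "scdiscrim_out"
    filter_threshold: float = 5.0
    top_n: int = 500
    k_max: int = 500
    sigma: float = 1.0
    transform: str = "log2p1"
    cluster_metric: str = "correlation"
    cluster_linkage: str = "complete"
    background_size: int | None = None  # None -> symbols surviving the filter
    simulate: dict | None = None        # SyntheticSpec overrides, instead of paths
    seed: int = 1

    def validate(self) -> None:
        if self.k_max > self.top_n:
            raise ValueError(
                f"k_max ({self.k_max}) cannot exceed top_n ({self.top_n})"
            )
        if self.simulate is None and (self.matrix_path is None or self.labels_path is None):
            raise ValueError("either matrix_path+labels_path or simulate must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _finalize(*paths: Path) -> None:
    """Strip the .partial suffix once a stage's outputs are complete."""
    for p in paths:
        p.rename(Path(str(p)[: -len(".partial")]))


def _partial(out: Path, name: str) -> Path:
    return out / f"{name}.partial"


def run_all(cfg: RunConfig, stop_after: str | None = None) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest."""
    cfg.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; expected one of {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "stages": {},
    }

    def done(stage: str) -> bool:
        manifest["stages"].setdefault(stage, {})
        return stop_after == stage

    # -- load ------------------------------------------------------------
    try:
        truth = None
        if cfg.simulate is not None:
            spec = SyntheticSpec(**{"seed": cfg.seed, **cfg.simulate})
            matrix, truth = generate(spec)
            p = _partial(out, "matrix.tsv"), _partial(out, "labels.tsv")
            write_expression(matrix, p[0], p[1])
            t = _partial(out, "truth.tsv")
            write_table(
                pd.DataFrame({
                    "transcript_id": truth.planted_ids,
                    "gene_symbol": truth.planted_symbols,
                    "direction": [truth.directions[t_] for t_ in truth.planted_ids],
                }),
                t,
            )
            g = _partial(out, "toy_sets.gmt")
            write_gmt(truth.gene_sets, g)
            _finalize(*p, t, g)
            manifest["stages"]["load"] = {
                "simulated": True, "spec": dataclasses.asdict(spec),
                "n_transcripts": matrix.n_transcripts,
                "n_pos": matrix.n_pos, "n_neg": matrix.n_neg,
            }
        else:
            matrix, report = read_expression(cfg.matrix_path, cfg.labels_path)
            manifest["stages"]["load"] = {
                "simulated": False,
                "n_transcripts": matrix.n_transcripts,
                "n_pos": matrix.n_pos, "n_neg": matrix.n_neg,
                "n_cells_dropped": report.n_cells_dropped,
                "n_labels_unmatched": report.n_labels_unmatched,
            }
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("load", e) from e
    if done("load"):
        return _write_manifest(manifest, out)

    # -- filter ----------------------------------------------------------
    try:
        filtered = filter_by_max_expression(matrix, cfg.filter_threshold)
        manifest["stages"]["filter"] = {
            "threshold": cfg.filter_threshold,
            "n_before": matrix.n_transcripts,
            "n_after": filtered.n_transcripts,
        }
    except Exception as e:
        raise StageError("filter", e) from e
    if done("filter"):
        return _write_manifest(manifest, out)

    # -- rank ------------------------------------------------------------
    try:
        disc = discretize(filtered, sigma=cfg.sigma, transform=cfg.transform)
        ranking = mrmr_rank(disc, filtered.labels, top_n=cfg.top_n)
        annotate_ranking(ranking, filtered.transcript_ids, filtered.gene_symbols)
        rp = _partial(out, "ranks.tsv")
        write_table(
            pd.DataFrame({
                "rank": np.arange(1, len(ranking) + 1),
                "transcript_id": ranking.transcript_ids,
                "gene_symbol": ranking.gene_symbols,
                "score": ranking.scores,
                "relevance": ranking.relevance,
            }),
            rp,
        )
        _finalize(rp)
        manifest["stages"]["rank"] = {"top_n": cfg.top_n, "n_ranked": len(ranking)}
    except Exception as e:
        raise StageError("rank", e) from e
    if done("rank"):
        return _write_manifest(manifest, out)

    # -- ifs -------------------------------------------------------------
    try:
        k_max = min(cfg.k_max, len(ranking))
        if k_max < cfg.k_max:
            logger.warning("k_max clamped to ranking length %d", k_max)
        curve = run_ifs(filtered, ranking, k_max=k_max, transform=cfg.transform)
        cp = _partial(out, "curve.tsv")
        write_table(pd.DataFrame(curve_to_records(curve)), cp)
        pk = _partial(out, "peak.txt")
        peak = curve.peak_metrics
        pk.write_text(f"k={curve.peak_k}\tmcc={peak.mcc:.6g}\n")
        _finalize(cp, pk)
        manifest["stages"]["ifs"] = {
            "k_max": k_max, "peak_k": curve.peak_k,
            "peak_metrics": dataclasses.asdict(peak),
        }
    except Exception as e:
        raise StageError("ifs", e) from e
    if done("ifs"):
        return _write_manifest(manifest, out)

    # -- signature -------------------------------------------------------
    try:
        optimal = filtered.subset_transcripts(ranking.order[: curve.peak_k])
        partition = two_way_cluster(
            optimal, transform=cfg.transform,
            metric=cfg.cluster_metric, linkage=cfg.cluster_linkage,
        )
        symbol_of = dict(zip(optimal.transcript_ids, optimal.gene_symbols))
        up = _partial(out, "signature_up.txt")
        down = _partial(out, "signature_down.txt")
        write_gene_list([symbol_of[t] for t in partition.up_in_tumor], up)
        write_gene_list([symbol_of[t] for t in partition.down_in_tumor], down)
        hm = _partial(out, "heatmap.tsv")
        zdf = pd.DataFrame(
            partition.zmatrix, index=partition.transcript_order,
            columns=partition.cell_order,
        )
        zdf.index.name = "transcript_id"
        zdf.reset_index().to_csv(hm, sep="\t", index=False, float_format="%.6g")
        _finalize(up, down, hm)
        manifest["stages"]["signature"] = {
            "method": partition.method,
            "n_up": len(partition.up_in_tumor),
            "n_down": len(partition.down_in_tumor),
        }
    except Exception as e:
        raise StageError("signature", e) from e
    if done("signature"):
        return _write_manifest(manifest, out)

    # -- enrich ----------------------------------------------------------
    try:
        gmt_path = cfg.gmt_path
        if gmt_path is None and truth is not None:
            gmt_path = str(out / "toy_sets.gmt")
        if gmt_path is not None:
            sets = read_gmt(gmt_path)
            background = list(dict.fromkeys(s.upper() for s in filtered.gene_symbols))
            results = {}
            for direction, ids in (("up", partition.up_in_tumor),
                                   ("down", partition.down_in_tumor)):
                rows = enrich([symbol_of[t] for t in ids], sets, background)
                ep = _partial(out, f"{direction}_enrichment.tsv")
                write_table(enrichment_frame(rows), ep)
                _finalize(ep)
                results[direction] = {
                    "n_sets": len(rows),
                    "min_fdr": min((r.fdr for r in rows), default=float("nan")),
                }
            manifest["stages"]["enrich"] = results
        else:
            manifest["stages"]["enrich"] = {"skipped": "no gene sets supplied"}
    except Exception as e:
        raise StageError("enrich", e) from e
    if done("enrich"):
        return _write_manifest(manifest, out)

    # -- overlap ---------------------------------------------------------
    try:
        if cfg.comparison_list_path is not None:
            other = read_gene_list(cfg.comparison_list_path)
            signature_symbols = list(dict.fromkeys(
                symbol_of[t] for t in partition.up_in_tumor + partition.down_in_tumor
            ))
            n_bg = cfg.background_size or len(set(s.upper() for s in filtered.gene_symbols))
            res = overlap_test(signature_symbols, other, n_bg)
            op = _partial(out, "overlap.tsv")
            write_table(pd.DataFrame([dataclasses.asdict(res)]), op)
            _finalize(op)
            manifest["stages"]["overlap"] = dataclasses.asdict(res)
        else:
            manifest["stages"]["overlap"] = {"skipped": "no comparison list supplied"}
    except Exception as e:
        raise StageError("overlap", e) from e

    return _write_manifest(manifest, out)


def _write_manifest(manifest: dict, out: Path) -> dict:
    mp = _partial(out, "manifest.json")
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n")
    _finalize(mp)
    return manifest
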