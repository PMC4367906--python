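"""End-to-end pipeline orchestration.

Stages run in a fixed linear order — simulate, quantify, normalize,
call_hits, enrich, network — each reading the artifacts of its
predecessors from the run directory, so a run is reproducible from its
config and seed alone. Tables are written atomically (a ``.partial`` file
renamed on completion); a failing stage leaves its unfinished output under
the ``.partial`` suffix and aborts the run with the stage name.
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich as kenrich
from . import hits as khits
from . import io as kio
from . import network as knet
from . import normalize as knorm
from . import synthetic as ksyn
from .exceptions import PipelineError

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "quantify", "normalize", "call_hits", "enrich", "network"]
DEFAULT_STAGES = {
    "simulate": True,
    "quantify": False,
    "normalize": True,
    "call_hits": True,
    "enrich": True,
    "network": True,
}


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = Path(kio.atomic_path(path))
    df.to_csv(tmp, index=False, **kwargs)
    os.replace(tmp, path)


def run_pipeline(config: dict) -> dict:
    """Run the configured stages and return the run report.

    ``config`` keys: ``seed`` (int), ``outdir`` (path), ``stages`` (per-stage
    booleans; unlisted stages take :data:`DEFAULT_STAGES`), and one optional
    parameter block per stage mirroring that stage's function arguments.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "kinomescreen_run"))
    stages = {**DEFAULT_STAGES, **(config.get("stages") or {})}
    report: dict = {
        "seed": seed,
        "outdir": str(outdir),
        "params": {s: config.get(s, {}) for s in STAGE_ORDER},
        "stages": {},
    }
    enabled = [s for s in STAGE_ORDER if stages.get(s)]
    if not enabled:
        return report
    outdir.mkdir(parents=True, exist_ok=True)

    for stage in enabled:
        t0 = time.perf_counter()
        try:
            stage_report = _STAGE_FUNCS[stage](config.get(stage) or {}, outdir, seed)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc
        stage_report["elapsed_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = stage_report
        logger.info("stage %s done in %.2fs", stage, stage_report["elapsed_s"])

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(params: dict, outdir: Path, seed: int) -> dict:
    screen_params = dict(params.get("screen", {}))
    screen_params.setdefault("seed", seed)
    config = ksyn.ScreenConfig(**screen_params)
    layout, measurements, truth = ksyn.generate_screen(config)
    _write_csv(layout, outdir / "layout.csv")
    _write_csv(measurements, outdir / "measurements.csv")
    _write_csv(truth, outdir / "truth.csv")

    inter_params = dict(params.get("interactome", {}))
    inter_params.setdefault("seed", seed + 1)
    if "planted_modules" not in inter_params:
        inter_params["planted_modules"] = (ksyn.default_fer_crkl_module(),)
    interactions, itruth = ksyn.generate_interactome(ksyn.InteractomeConfig(**inter_params))
    # planted seeds and a sample of simulated hit genes become hit-kinase
    # aliases so the network stage has mapped hits to build around
    rng = np.random.default_rng(seed + 2)
    hit_genes = truth.loc[truth["is_hit"], ["gene_symbol", "group"]]
    free_nodes = [n for n in itruth["names"].values() if n.startswith("P")]
    chosen = rng.choice(len(free_nodes), min(len(hit_genes), len(free_nodes)), replace=False)
    alias = {free_nodes[i]: g for i, g in zip(chosen, hit_genes["gene_symbol"])}
    interactions = interactions.replace({"source": alias, "target": alias})
    module = ksyn.default_fer_crkl_module()
    _write_csv(interactions, outdir / "interactions.tsv", sep="\t")

    ann_params = dict(params.get("annotations", {}))
    ann_params.setdefault("seed", seed + 3)
    universe = truth["gene_symbol"].tolist()
    high = truth.loc[truth["group"] == "high", "gene_symbol"].tolist()
    low = truth.loc[truth["group"] == "low", "gene_symbol"].tolist()
    planted = [("CELL_CYCLE", high, 0.02), ("SIGNAL_TRANSDUCTION", low, 0.02)]
    annotations, _ = ksyn.generate_annotations(universe, planted, **ann_params)
    kio.write_annotations(annotations, outdir / "annotations.tsv")
    return {
        "n_layout_rows": len(layout),
        "n_measurements": len(measurements),
        "n_interactions": len(interactions),
        "n_annotation_rows": len(annotations),
        "module_seeds": list(module.seeds),
    }


def _stage_quantify(params: dict, outdir: Path, seed: int) -> dict:
    """Quantify a handful of generated image pairs as a self-check.

    The default pipeline uses the simulated count tables directly; this
    stage exists to exercise the imaging path end to end.
    """
    from . import image_quant as kim

    n_pairs = int(params.get("n_pairs", 3))
    n_nuclei = int(params.get("n_nuclei", 60))
    n_mitotic = int(params.get("n_mitotic", 4))
    shape = tuple(params.get("shape", (384, 384)))
    rows = []
    for i in range(n_pairs):
        dapi, ph3, truth = ksyn.generate_image_pair(
            n_nuclei, n_mitotic, shape=shape, seed=seed + i
        )
        n_total, n_mit = kim.quantify_pair(dapi, ph3)
        rows.append(
            {
                "pair": i,
                "planted_total": n_nuclei,
                "counted_total": n_total,
                "planted_mitotic": n_mitotic,
                "counted_mitotic": n_mit,
            }
        )
    table = pd.DataFrame(rows)
    _write_csv(table, outdir / "quantify_check.csv")
    return {
        "n_pairs": n_pairs,
        "max_total_error": int((table["counted_total"] - table["planted_total"]).abs().max()),
        "max_mitotic_error": int(
            (table["counted_mitotic"] - table["planted_mitotic"]).abs().max()
        ),
    }


def _stage_normalize(params: dict, outdir: Path, seed: int) -> dict:
    layout = kio.read_layout(outdir / "layout.csv")
    records, rejects = kio.read_measurements(outdir / "measurements.csv", layout)
    if len(rejects):
        _write_csv(rejects, outdir / "rejects.csv")
    screen = knorm.preprocess_screen(records, **params)
    _write_csv(screen.genes, outdir / "normalized.csv")
    return {
        "n_records_in": screen.report.n_input,
        "n_low_dapi_removed": screen.report.n_low_dapi_removed,
        "n_inconsistent_removed": screen.report.n_inconsistent_removed,
        "n_undefined_mi": screen.report.n_undefined_mi,
        "n_genes": len(screen.genes),
    }


def _stage_call_hits(params: dict, outdir: Path, seed: int) -> dict:
    genes = pd.read_csv(outdir / "normalized.csv")
    values = genes.set_index("gene_symbol")["log2_mi"]
    hit_table = khits.call_hits(values, k=float(params.get("k", 2.0)))
    kio.write_hit_table(hit_table, kio.atomic_path(outdir / "hits.csv"))
    kio.finalize(outdir / "hits.csv")
    low, high = khits.classify_groups(hit_table)
    layout = kio.read_layout(outdir / "layout.csv")
    records, _ = kio.read_measurements(outdir / "measurements.csv", layout)
    qc = khits.qc_controls(records, min_separation=float(params.get("min_separation", 3.0)))
    _write_csv(qc, outdir / "qc.csv")
    return {
        "n_hits": len(low) + len(high),
        "n_low": len(low),
        "n_high": len(high),
        "n_plates_qc_passed": int(qc["passed"].sum()),
        "n_plates": len(qc),
    }


def _stage_enrich(params: dict, outdir: Path, seed: int) -> dict:
    hit_table = pd.read_csv(outdir / "hits.csv")
    annotations = kio.read_annotations(outdir / "annotations.tsv")
    low, high = khits.classify_groups(hit_table)
    universe = hit_table["gene_symbol"].tolist()
    out: dict = {}
    min_term_size = int(params.get("min_term_size", 3))
    for name, genes in (("low", low), ("high", high)):
        if not genes:
            out[f"n_terms_{name}"] = 0
            continue
        res = kenrich.enrich_list(genes, universe, annotations, min_term_size)
        _write_csv(res, outdir / f"enrichment_{name}.csv")
        out[f"n_terms_{name}"] = len(res)
        if len(res):
            out[f"top_term_{name}"] = str(res.iloc[0]["term_id"])
    if low and high:
        comp = kenrich.compare_lists(low, high, annotations)
        _write_csv(comp, outdir / "enrichment_low_vs_high.csv")
        out["n_terms_compared"] = len(comp)
    return out


def _stage_network(params: dict, outdir: Path, seed: int) -> dict:
    hit_table = pd.read_csv(outdir / "hits.csv")
    interactions = kio.read_interactions(outdir / "interactions.tsv")
    low, high = khits.classify_groups(hit_table)
    out: dict = {}
    for name, genes in (("low", low), ("high", high)):
        if not genes:
            continue
        graph, unmapped = knet.build_network(genes, interactions)
        summary = knet.summarize_topology(graph)
        kio.write_graphml(graph, outdir / f"network_{name}.graphml")
        kio.write_edgelist(graph, outdir / f"network_{name}.tsv")
        out[name] = {
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "n_hit_kinases_included": summary.n_hit_kinases_included,
            "n_unmapped_hits": len(unmapped),
            "power_law_gamma": summary.power_law_gamma,
        }
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "normalize": _stage_normalize,
    "call_hits": _stage_call_hits,
    "enrich": _stage_enrich,
    "network": _stage_network,
}
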