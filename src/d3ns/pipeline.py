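"""End-to-end orchestration: smoothing -> encoding -> consensus -> evaluation.

``run_all`` executes the stages in order from a single :class:`RunConfig`,
writes every intermediate artifact (TSV / npz / PNG) under the output
directory, and records a JSON manifest with artifact paths, SHA-256
checksums, stage wall times, package versions and the seeds used — enough to
re-execute the run and to verify that a rerun with the same config and seed
reproduces identical label files.  The master seed fans out to per-stage
seeds by fixed offsets so stages stay independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data_io
from .autoencoder import EncoderConfig, encode, scale_input, train_autoencoder
from .consensus import (
    ConsensusConfig,
    consensus_cluster,
    consensus_diagnostics,
    render_heatmap,
)
from .network import (
    align_gene_universe,
    build_transition_matrix,
    filter_top_confidence,
    load_network,
)
from .propagation import (
    PropagationConfig,
    propagate_closed_form,
    propagate_iterative,
    propagate_one_step,
)
from .survival_eval import association_tests, km_logrank

logger = logging.getLogger("d3ns")

# fixed per-stage seed offsets from the master seed
SEED_OFFSETS = {"autoencoder": 1, "consensus": 2}


@dataclass
class RunConfig:
    mutations: str | None = None
    mutations_dialect: str = "maf"
    network: str | None = None
    clinical: str | None = None
    outdir: str = "d3ns_run"
    keep_fraction: float = 0.10
    normalization: str = "rowwalk"
    unmapped_policy: str = "intersect"
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    seed: int = 0
    render_heatmaps: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("propagation", PropagationConfig),
            ("encoder", EncoderConfig),
            ("consensus", ConsensusConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    cfg: RunConfig,
    mutation_matrix=None,
    gene_network=None,
    clinical=None,
) -> dict:
    """Execute the full pipeline; returns the run manifest.

    In-memory inputs (mutation_matrix, gene_network, clinical) take priority
    over the file paths in the config, which lets the synthetic generator
    feed the pipeline directly.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": {},
        "artifacts": {},
        "versions": _versions(),
    }

    def checkpoint(stage: str, t0: float, **artifacts: Path) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for name, p in artifacts.items():
            manifest["artifacts"][name] = {"path": str(p), "sha256": _sha256(p)}
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

    # --- inputs ------------------------------------------------------------
    t0 = time.time()
    if mutation_matrix is None:
        records = data_io.read_mutations(cfg.mutations, dialect=cfg.mutations_dialect)
        mutation_matrix = data_io.build_mutation_matrix(records)
    if gene_network is None:
        gene_network = load_network(cfg.network)
    if clinical is None and cfg.clinical:
        clinical = data_io.read_clinical(cfg.clinical)
    mm_path = outdir / "mutation_matrix.tsv"
    data_io.write_matrix(mutation_matrix, mm_path)
    manifest["mm_sparsity"] = data_io.matrix_sparsity(mutation_matrix)
    checkpoint("data_io", t0, mutation_matrix=mm_path)

    # --- network -----------------------------------------------------------
    t0 = time.time()
    filtered = filter_top_confidence(gene_network, cfg.keep_fraction)
    aligned, align_report = align_gene_universe(
        mutation_matrix, filtered, policy=cfg.unmapped_policy
    )
    W = build_transition_matrix(filtered, aligned.genes, cfg.normalization)
    manifest["network"] = {
        "edges_in": gene_network.n_edges,
        "edges_kept": filtered.n_edges,
        "align": align_report,
    }
    checkpoint("network", t0)

    # --- propagation -------------------------------------------------------
    t0 = time.time()
    pcfg = cfg.propagation
    if pcfg.mode == "one_step":
        nsm = propagate_one_step(aligned, W, pcfg.alpha)
    elif pcfg.mode == "iterative":
        nsm, _ = propagate_iterative(aligned, W, pcfg)
    else:
        nsm = propagate_closed_form(aligned, W, pcfg.alpha)
    nsm_path = outdir / "nsm.npz"
    data_io.write_matrix(nsm.to_frame(), nsm_path)
    manifest["nsm_sparsity"] = data_io.matrix_sparsity(nsm.values)
    checkpoint("propagation", t0, nsm=nsm_path)

    # --- autoencoder -------------------------------------------------------
    t0 = time.time()
    ecfg = dataclasses.replace(cfg.encoder, seed=cfg.seed + SEED_OFFSETS["autoencoder"])
    scaled = scale_input(nsm)
    enc = train_autoencoder(scaled, ecfg)
    em = encode(enc, scaled)
    em_path = outdir / "em.tsv"
    hist_path = outdir / "training_history.csv"
    data_io.write_matrix(em.to_frame(), em_path)
    enc.training_history.to_csv(hist_path, index=False)
    manifest["final_train_loss"] = float(enc.training_history["train_loss"].iloc[-1])
    checkpoint("autoencoder", t0, em=em_path, training_history=hist_path)

    # --- consensus ---------------------------------------------------------
    t0 = time.time()
    ccfg = dataclasses.replace(cfg.consensus, seed=cfg.seed + SEED_OFFSETS["consensus"])
    results = consensus_cluster(em, ccfg)
    label_paths = {}
    for k, (cm, assignment) in results.items():
        lp = outdir / f"labels_k{k}.tsv"
        with open(lp, "w") as fh:
            fh.write("patient_id\tsubtype\n")
            for p in cm.patients:
                fh.write(f"{p}\t{assignment.labels[p]}\n")
        label_paths[f"labels_k{k}"] = lp
        data_io.write_matrix(cm.to_frame(), outdir / f"consensus_k{k}.npz")
        if cfg.render_heatmaps:
            render_heatmap(cm, assignment, outdir / f"consensus_k{k}.png")
    diag = consensus_diagnostics(results)
    diag_path = outdir / "diagnostics.csv"
    diag.to_csv(diag_path, index=False)
    checkpoint("consensus", t0, diagnostics=diag_path, **label_paths)

    # --- survival evaluation ----------------------------------------------
    if clinical is not None:
        t0 = time.time()
        rows = []
        for k, (cm, assignment) in results.items():
            try:
                lr = km_logrank(clinical, assignment)
                rows.append({"k": k, "logrank_statistic": lr.statistic, "logrank_p": lr.p_value})
            except data_io.D3NSError as err:
                rows.append({"k": k, "logrank_statistic": np.nan, "logrank_p": np.nan,
                             "note": str(err)})
        import pandas as pd

        surv_path = outdir / "logrank_by_k.csv"
        pd.DataFrame(rows).to_csv(surv_path, index=False)
        manifest["logrank_by_k"] = {r["k"]: r.get("logrank_p") for r in rows}
        assoc_rows = []
        for k, (_, assignment) in results.items():
            for res in association_tests(clinical, assignment):
                assoc_rows.append({"k": k, "variable": res.variable, "test": res.test,
                                   "statistic": res.statistic, "p": res.p_value,
                                   "n": res.n, "note": res.note})
        assoc_path = outdir / "associations_by_k.csv"
        pd.DataFrame(assoc_rows).to_csv(assoc_path, index=False)
        checkpoint("survival_eval", t0, logrank=surv_path, associations=assoc_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _versions() -> dict:
    import lifelines
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "d3ns": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }
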