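"""End-to-end orchestration of the nodal-signature workflow.

Stages run in the order of the study design: simulate (or load) counts and
metadata -> sample QC -> node-status differential expression ->
SD-cutoff-selected consensus clustering -> per-cluster DGE contrasts ->
refinement of the node-negative-enriched cluster (removing samples whose
node label disagrees with the cluster majority) -> shrunken-centroids
signature with cross-validation -> leave-one-out MSE centroid validation ->
over-representation analysis -> clinico-pathological comparison.  A JSON
manifest records the seed, thresholds, per-stage sub-seeds and output file
hashes so every stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import string
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, clinical, clustering, dge, enrichment, qc
from .containers import (NODE_NEG, NODE_POS, CountMatrix, read_metadata,
                         write_metadata)
from .simulate import SimConfig, simulate_clinical_table, simulate_counts

logger = logging.getLogger("nodalsig")


@dataclass
class RunConfig:
    """Pipeline configuration; ``seed`` is mandatory (stochastic stages)."""

    seed: int | None = None
    outdir: str = "nodalsig_run"
    # inputs: either paths or a simulation block
    counts_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    sim: SimConfig | None = None
    # thresholds
    fdr: float = dge.FDR_DEFAULT
    min_fc: float = dge.MIN_FC_DEFAULT
    qc_min_aligned: int = qc.MIN_ALIGNED_DEFAULT
    qc_max_zero_genes: int = qc.MAX_ZERO_GENES_DEFAULT
    min_genes: int = clustering.MIN_GENES_DEFAULT
    # clustering
    k: int = 3
    n_iterations: int = clustering.N_ITERATIONS_DEFAULT
    subsample_fraction: float = clustering.SUBSAMPLE_FRACTION_DEFAULT
    # classifier
    delta_min: float = 0.0
    delta_max: float = 5.0
    delta_step: float = 0.1
    n_folds: int = classifier.N_FOLDS_DEFAULT
    n_randomizations: int = classifier.B_RANDOMIZATIONS_DEFAULT

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed: stochastic stages "
                             "(simulation, consensus, CV) refuse to run without one")
        for name in ("fdr", "min_fc", "qc_min_aligned", "qc_max_zero_genes",
                     "min_genes", "k", "n_iterations", "subsample_fraction",
                     "n_folds", "n_randomizations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.counts_path is None and self.sim is None:
            self.sim = SimConfig(seed=int(self.seed))

    @property
    def delta_grid(self) -> np.ndarray:
        return np.round(np.arange(self.delta_min,
                                  self.delta_max + 1e-9, self.delta_step), 10)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_block is not None:
            if "cluster_labels" in sim_block:
                sim_block["cluster_labels"] = {
                    k: tuple(v) for k, v in sim_block["cluster_labels"].items()
                }
            if "libsize_range" in sim_block:
                sim_block["libsize_range"] = tuple(sim_block["libsize_range"])
            cfg.sim = SimConfig(**sim_block)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31) for s in state]


def _attach_covariates(meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw clinical covariates per node-status arm and align to samples."""
    n_neg = int((meta["node_status"] == NODE_NEG).sum())
    n_pos = int((meta["node_status"] == NODE_POS).sum())
    clin = simulate_clinical_table(seed, (n_neg, n_pos))
    neg_rows = clin[clin["node_status"] == NODE_NEG].drop(columns="node_status")
    pos_rows = clin[clin["node_status"] == NODE_POS].drop(columns="node_status")
    neg_rows.index = meta.index[meta["node_status"] == NODE_NEG]
    pos_rows.index = meta.index[meta["node_status"] == NODE_POS]
    covs = pd.concat([neg_rows, pos_rows]).loc[meta.index]
    joined = meta.join(covs)
    joined.attrs = dict(meta.attrs)  # keep simulation truth (module genes)
    return joined


def _synthetic_gene_sets(meta: pd.DataFrame, all_genes: list[str],
                         seed: int) -> enrichment.GeneSetCollection:
    """GMT fixture: the simulation's true DE modules plus random decoys."""
    rng = np.random.Generator(np.random.PCG64(seed))
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    module_genes = meta.attrs.get("module_genes", {})
    for cluster, genes in module_genes.items():
        if genes:
            sets[f"MODULE_CLUSTER_{cluster}"] = list(genes)
            desc[f"MODULE_CLUSTER_{cluster}"] = (
                f"simulation truth: DE module upregulated in cluster {cluster}"
            )
    for i in range(10):
        size = int(rng.integers(30, 200))
        members = [all_genes[j] for j in rng.choice(len(all_genes), size,
                                                    replace=False)]
        sets[f"RANDOM_SET_{i + 1:02d}"] = members
        desc[f"RANDOM_SET_{i + 1:02d}"] = "random decoy set"
    return enrichment.GeneSetCollection(sets, desc)


def _name_clusters_by_npos(assignments: pd.Series,
                           meta: pd.DataFrame) -> pd.Series:
    """Rename numeric clusters to letters by descending N+ fraction.

    The node-positive-enriched cluster becomes "A" and the most
    node-negative one the last letter (the study assigns these by
    inspection; here it is programmatic).
    """
    frac = {}
    for c in assignments.unique():
        members = assignments.index[assignments == c]
        frac[c] = (meta.loc[members, "node_status"] == NODE_POS).mean()
    order = sorted(frac, key=lambda c: (-frac[c], c))
    letters = {c: string.ascii_uppercase[i] for i, c in enumerate(order)}
    return assignments.map(letters)


def _loo_centroid_validation(expr: pd.DataFrame, labels: pd.Series,
                             signature: list[str], n_randomizations: int,
                             seed: int) -> classifier.ValidationReport:
    """Leave-one-out wrapper around the MSE centroid validator."""
    rows = []
    for i, sid in enumerate(expr.columns):
        train_cols = [c for c in expr.columns if c != sid]
        rep = classifier.centroid_validator(
            expr[train_cols], labels.loc[train_cols],
            expr[[sid]], labels.loc[[sid]], signature,
            n_randomizations=n_randomizations, seed=seed + i,
        )
        rows.append(rep.scores)
    scores = pd.concat(rows)
    acc, sens, spec, confusion = classifier._binary_rates(
        scores["expected"], scores["predicted"], NODE_POS,
    )
    return classifier.ValidationReport(scores, confusion, acc, sens, spec,
                                       signature)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also on disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(config.seed))
    manifest: dict = {
        "seed": int(config.seed),
        "stage_seeds": {"sim": seeds[0], "gmt": seeds[1], "consensus": seeds[2],
                        "cv": seeds[3], "validator": seeds[4]},
        "config": {k: v for k, v in asdict(config).items() if k != "sim"},
        "outputs": {}, "stages": {},
    }
    if config.sim is not None:
        manifest["config"]["sim"] = asdict(config.sim)

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "input"
    try:
        t0 = time.time()
        if config.counts_path is not None:
            counts = CountMatrix.read_tsv(config.counts_path)
            meta = read_metadata(config.metadata_path)
            collection = (enrichment.read_gmt(config.gmt_path)
                          if config.gmt_path else None)
        else:
            sim = config.sim
            if sim.seed != seeds[0]:
                sim = SimConfig(**{**asdict(sim), "seed": seeds[0]})
            counts, meta = simulate_counts(sim)
            meta = _attach_covariates(meta, seeds[0])
            collection = _synthetic_gene_sets(meta, counts.gene_ids, seeds[1])
            counts.write_tsv(outdir / "counts.tsv")
            write_metadata(meta, outdir / "metadata.tsv")
            enrichment.write_gmt(collection, outdir / "gene_sets.gmt")
            emit("counts", outdir / "counts.tsv")
            emit("metadata", outdir / "metadata.tsv")
            emit("gene_sets", outdir / "gene_sets.gmt")
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "qc"
        t0 = time.time()
        filtered, report = qc.sample_qc(counts, config.qc_min_aligned,
                                        config.qc_max_zero_genes)
        report.to_csv(outdir / "qc_report.tsv", sep="\t")
        emit("qc_report", outdir / "qc_report.tsv")
        meta = meta.loc[filtered.sample_ids]
        logger.info("QC: %d/%d samples included", filtered.n_samples,
                    counts.n_samples)
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "dge_node_status"
        t0 = time.time()
        res = dge.run_dge(filtered, meta["node_status"],
                          contrast=(NODE_NEG, NODE_POS),
                          fdr=config.fdr, min_fc=config.min_fc)
        res.table.to_csv(outdir / "dge_Npos_vs_Nneg.tsv", sep="\t")
        emit("dge_Npos_vs_Nneg", outdir / "dge_Npos_vs_Nneg.tsv")
        manifest["n_de_node_status"] = int(res.table["is_de"].sum())
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "clustering"
        t0 = time.time()
        expr = pd.DataFrame(dge.logcpm(filtered), index=filtered.gene_ids,
                            columns=filtered.sample_ids)
        selection = clustering.select_sd_cutoff(expr, config.min_genes)
        if selection.status != "ok":
            raise RuntimeError("no SD cutoff achieves negative top-split "
                               "anti-correlation (no cluster structure)")
        retained = expr.loc[selection.chosen_gene_set]
        cons = clustering.consensus_cluster(
            retained, config.k, config.n_iterations,
            config.subsample_fraction, seed=seeds[2],
        )[config.k]
        named = _name_clusters_by_npos(cons.assignments, meta)
        meta = meta.assign(cluster=named)
        cons.consensus.to_csv(outdir / "consensus_matrix.tsv", sep="\t")
        named.to_frame().to_csv(outdir / "cluster_assignments.tsv", sep="\t",
                                index_label="sample_id")
        emit("consensus_matrix", outdir / "consensus_matrix.tsv")
        emit("cluster_assignments", outdir / "cluster_assignments.tsv")
        manifest["sd_cutoff"] = selection.chosen_cutoff
        manifest["n_genes_clustering"] = len(selection.chosen_gene_set)
        manifest["cluster_sizes"] = named.value_counts().to_dict()
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "dge_clusters"
        t0 = time.time()
        letters = sorted(named.unique())
        contrasts: list[tuple[str, list[str], pd.Series]] = []
        for i, a in enumerate(letters):
            for b in letters[i + 1:]:
                ids = named.index[named.isin([a, b])].tolist()
                contrasts.append((f"{a}_vs_{b}", ids, named.loc[ids]))
        rest = named.index[named != letters[0]].tolist()
        pooled = pd.Series(
            [letters[0] if named[s] == letters[0] else "rest"
             for s in named.index], index=named.index,
        )
        contrasts.append((f"{letters[0]}_vs_rest", list(named.index), pooled))
        manifest["n_de_clusters"] = {}
        for name, ids, labels in contrasts:
            sub = filtered.subset_samples(ids)
            r = dge.run_dge(sub, labels.loc[ids], fdr=config.fdr,
                            min_fc=config.min_fc)
            r.table.to_csv(outdir / f"dge_{name}.tsv", sep="\t")
            emit(f"dge_{name}", outdir / f"dge_{name}.tsv")
            manifest["n_de_clusters"][name] = int(r.table["is_de"].sum())
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "refine"
        t0 = time.time()
        # the node-negative-enriched cluster keeps only its majority-label
        # samples (C -> C'): discordant node labels are removed before the
        # signature contrast
        cneg = letters[-1]
        members = named.index[named == cneg]
        majority = meta.loc[members, "node_status"].mode().iloc[0]
        cprime = [s for s in members
                  if meta.loc[s, "node_status"] == majority]
        manifest["refined_cluster"] = {
            "cluster": cneg, "majority_label": majority,
            "n_before": int(len(members)), "n_after": len(cprime),
        }
        a_ids = named.index[named == letters[0]].tolist()
        sig_ids = a_ids + cprime
        sig_labels = pd.Series(
            [letters[0] if s in a_ids else f"{cneg}prime" for s in sig_ids],
            index=sig_ids,
        )
        r = dge.run_dge(filtered.subset_samples(sig_ids), sig_labels,
                        fdr=config.fdr, min_fc=config.min_fc)
        r.table.to_csv(outdir / f"dge_{letters[0]}_vs_{cneg}prime.tsv", sep="\t")
        emit(f"dge_{letters[0]}_vs_{cneg}prime",
             outdir / f"dge_{letters[0]}_vs_{cneg}prime.tsv")
        manifest["n_de_clusters"][f"{letters[0]}_vs_{cneg}prime"] = (
            int(r.table["is_de"].sum())
        )
        refine_dge = r
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "signature"
        t0 = time.time()
        sig_expr = expr[sig_ids]
        node_labels = meta.loc[sig_ids, "node_status"]
        cv = classifier.cross_validate_nsc(
            sig_expr, node_labels, config.delta_grid,
            n_folds=config.n_folds, seed=seeds[3],
        )
        cv.cv_table.to_csv(outdir / "signature_cv.tsv", sep="\t", index=False)
        pd.Series(cv.signature_genes, name="gene_id").to_csv(
            outdir / "signature_genes.txt", index=False, header=False)
        emit("signature_cv", outdir / "signature_cv.tsv")
        emit("signature_genes", outdir / "signature_genes.txt")
        manifest["signature"] = {
            "delta": cv.chosen_delta, "n_genes": len(cv.signature_genes),
            "cv_accuracy": cv.accuracy, "cv_sensitivity": cv.sensitivity,
            "cv_specificity": cv.specificity,
        }
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "validation"
        t0 = time.time()
        if cv.signature_genes:
            rep = _loo_centroid_validation(
                sig_expr, node_labels, cv.signature_genes,
                config.n_randomizations, seeds[4],
            )
            rep.scores.to_csv(outdir / "centroid_validation.tsv", sep="\t")
            emit("centroid_validation", outdir / "centroid_validation.tsv")
            manifest["validation"] = {
                "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
            }
        else:
            manifest["validation"] = None
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "enrichment"
        t0 = time.time()
        if collection is not None:
            calls = dge.call_de(refine_dge, config.fdr, config.min_fc)
            query = calls["up"] + calls["down"]
            universe = filtered.gene_ids
            table = enrichment.ora(query, universe, collection)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            emit("enrichment", outdir / "enrichment.tsv")
            manifest["n_enriched_q05"] = int((table["q"] < 0.05).sum())
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "clinical_stats"
        t0 = time.time()
        covariates = [c for c in meta.columns
                      if c not in ("node_status", "true_cluster", "cluster")]
        if covariates:
            report = clinical.compare_groups(meta, "node_status",
                                             exclude=("true_cluster", "cluster"))
            report.levels.to_csv(outdir / "clinical_levels.tsv", sep="\t",
                                 index=False)
            report.pvalues.to_csv(outdir / "clinical_pvalues.tsv", sep="\t",
                                  index=False)
            emit("clinical_levels", outdir / "clinical_levels.tsv")
            emit("clinical_pvalues", outdir / "clinical_pvalues.tsv")
        manifest["stages"][stage] = round(time.time() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
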