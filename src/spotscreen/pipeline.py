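"""End-to-end orchestration: simulate -> demux -> quantify -> analyse.

One global seed fans out deterministically to per-stage seeds (stable hash
of seed + stage name, kept below 2^31), so a rerun with an identical
config reproduces identical outputs: bit-exact for the exact stages,
seed-exact for the stochastic ones.  Every run writes a manifest recording
parameters, derived seeds and output checksums; manifests of two runs of
the same config differ only in their timestamp.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry, de, demux, io as sio, perturb, quant, roc, sim

__all__ = ["stage_seed", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "demux", "quantify", "assign", "roc", "perturb", "de")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2 ** 31)


def run_pipeline(config: dict, outdir) -> dict:
    """Run the requested stages and write all artifacts under ``outdir``.

    Config keys: ``seed`` (int, default 0), ``stages`` (subset of
    DEFAULT_STAGES, order fixed), ``scene`` (SceneParams overrides),
    ``compute_umap`` (bool, default True), ``gene_sets`` (GMT path,
    enables the gsea step inside "de"), demux options under ``demux``.
    Returns a dict of artifact paths; also writes ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = [s for s in DEFAULT_STAGES if s in config.get("stages", DEFAULT_STAGES)]
    artifacts: dict[str, str] = {}
    seeds = {s: stage_seed(seed, s) for s in stages}

    params = sim.SceneParams(**config.get("scene", {}))
    scene = None
    if "simulate" in stages:
        scene = sim.simulate_scene(params, seed=seeds["simulate"])
        sio.write_fastq(scene.reads1, outdir / "reads_R1.fastq.gz")
        sio.write_fastq(scene.reads2, outdir / "reads_R2.fastq.gz")
        chemistry.write_whitelist(scene.profile.barcode_sets["A"],
                                  outdir / "whitelist_a.tsv")
        chemistry.write_whitelist(scene.profile.barcode_sets["B"],
                                  outdir / "whitelist_b.tsv")
        chemistry.write_library(scene.lib, outdir / "library.tsv")
        sio.write_region_masks(scene.regions, outdir / "regions.tsv")
        scene.pooled.to_csv(outdir / "pooled_table.tsv", sep="\t", index=False)
        sio.write_matrix(scene.truth_matrix(), outdir / "truth_matrix")
        with open(outdir / "truth_triples.tsv", "w") as fh:
            fh.write("x\ty\tsgrna\tumi\n")
            for (x, y), sg, umi in sorted(scene.truth_triples):
                fh.write(f"{x}\t{y}\t{sg}\t{umi}\n")
        artifacts.update(
            reads_r1=str(outdir / "reads_R1.fastq.gz"),
            reads_r2=str(outdir / "reads_R2.fastq.gz"),
            library=str(outdir / "library.tsv"),
        )

    records = attrition = None
    if "demux" in stages:
        if scene is None:
            raise ValueError("demux stage requires the simulate stage here")
        opts = demux.DemuxOptions(**config.get("demux", {}))
        records, attrition = demux.demux_reads(
            outdir / "reads_R1.fastq.gz", outdir / "reads_R2.fastq.gz",
            scene.profile, scene.lib, options=opts,
        )
        sio.write_demux_records(records, outdir / "demux_records.tsv")
        with open(outdir / "attrition.json", "w") as fh:
            json.dump(dict(sorted(attrition.items())), fh, indent=2)
        artifacts["demux_records"] = str(outdir / "demux_records.tsv")

    M = None
    if "quantify" in stages:
        triples = demux.dedup_umis(
            records, collapse=config.get("demux", {}).get("umi_collapse", False)
        )
        M = quant.build_matrix(
            triples, scene.profile.grid_dims, scene.lib.names,
            tissue=scene.tissue, pitch_um=scene.profile.spot_pitch_um,
        )
        sio.write_matrix(M, outdir / "matrix")
        artifacts["matrix"] = str(outdir / "matrix")

    assignment = None
    if "assign" in stages and M is not None:
        assignment = quant.assign_spots(M)
        assignment.to_csv(outdir / "assignment.tsv", sep="\t", index=False)
        burdens = [
            {"region": r.name, **quant.perturbation_burden(M, r)}
            for r in scene.regions
        ]
        pd.DataFrame(burdens).to_csv(outdir / "burden.tsv", sep="\t", index=False)
        artifacts["assignment"] = str(outdir / "assignment.tsv")

    if "roc" in stages and scene is not None:
        bench = roc.build_benchmark(scene.pooled)
        rr = roc.roc_auc(bench["scores"], bench["labels"])
        pd.DataFrame({"fpr": rr["fpr"], "tpr": rr["tpr"]}).to_csv(
            outdir / "roc_curve.tsv", sep="\t", index=False
        )
        with open(outdir / "roc.json", "w") as fh:
            json.dump({"auc": rr["auc"], "n_pos": rr["n_pos"],
                       "n_neg": rr["n_neg"], "confusion": bench["confusion"]},
                      fh, indent=2)
        artifacts["roc"] = str(outdir / "roc.json")

    assay = labels = None
    gex = None
    if "perturb" in stages and M is not None and assignment is not None:
        pseed = seeds["perturb"]
        adata = perturb.normalize_expression(scene.adata)
        gex = perturb.reduce_and_cluster(
            adata.layers["scaled"], seed=pseed,
            compute_umap=bool(config.get("compute_umap", True)),
        )
        pd.DataFrame(
            {"spot": adata.obs_names, "gex_cluster": gex.labels}
        ).to_csv(outdir / "gex_clusters.tsv", sep="\t", index=False)
        # align assignment rows to the (tissue-only) expression spots
        key = assignment.set_index(
            assignment["x"].astype(str) + "_" + assignment["y"].astype(str)
        )
        obs_key = (adata.obs["x"].astype(str) + "_" + adata.obs["y"].astype(str))
        sub = key.loc[obs_key.to_numpy()].reset_index(drop=True)
        status = perturb.spot_status(
            sub, scene.lib, quant.sgrna_areas(M),
            area_min=int(config.get("area_min", 4)),
        )
        status.index = adata.obs_names
        sig = perturb.calc_signature(
            adata, status, pcs=gex.pcs, clusters=gex.labels,
            k=int(config.get("k_neighbors", 20)),
        )
        assay = perturb.calc_scores(sig, status)
        assay.scores.to_csv(outdir / "perturbation_scores.tsv", sep="\t")
        assay.classes.to_frame().assign(status=status).to_csv(
            outdir / "perturbation_classes.tsv", sep="\t"
        )
        try:
            labels = perturb.pumap_cluster(
                assay, seed=pseed,
                compute_umap=bool(config.get("compute_umap", True)),
            )
            pd.DataFrame(
                {
                    "spot": np.asarray(adata.obs_names)[labels.spot_rows],
                    "pumap_cluster": labels.clusters,
                    "cluster_label": [labels.labels[int(c)]
                                      for c in labels.clusters],
                }
            ).to_csv(outdir / "pumap_clusters.tsv", sep="\t", index=False)
        except ValueError as e:
            with open(outdir / "pumap_skipped.txt", "w") as fh:
                fh.write(str(e) + "\n")
        artifacts["perturb"] = str(outdir / "perturbation_scores.tsv")

    if "de" in stages and assay is not None and labels is not None:
        dseed = seeds["de"]
        adata = perturb.normalize_expression(scene.adata)
        row_of = {s: i for i, s in enumerate(adata.obs_names)}
        spot_names = np.asarray(adata.obs_names)[labels.spot_rows]
        np_clusters = [c for c, lab in labels.labels.items()
                       if lab.startswith("NP + ")]
        np_rows = [row_of[s] for s, c in zip(spot_names, labels.clusters)
                   if int(c) in np_clusters]
        if not np_rows:
            np_rows = [row_of[s] for s, cl in
                       zip(adata.obs_names, assay.classes) if cl == "NP"]
        results = {}
        for c, lab in labels.labels.items():
            if c in np_clusters:
                continue
            rows = [row_of[s] for s, cc in zip(spot_names, labels.clusters)
                    if int(cc) == c]
            if len(rows) < 3 or len(np_rows) < 3:
                continue
            res = de.pseudo_replicate_de(adata, rows, np_rows,
                                         seed=stage_seed(dseed, f"de{c}"))
            res.to_csv(outdir / f"de_cluster{c}.tsv", sep="\t")
            results[c] = res
        if "gene_sets" in config:
            sets = sio.read_gmt(config["gene_sets"])
            for c, res in results.items():
                ranks = res.loc[res["padj"] < 0.2, "log2fc"]
                if ranks.empty:
                    continue
                g = de.gsea_preranked(
                    ranks, sets, n_perm=int(config.get("gsea_nperm", 1000)),
                    seed=stage_seed(dseed, f"gsea{c}"),
                )
                g.to_csv(outdir / f"gsea_cluster{c}.tsv", sep="\t", index=False)
        artifacts["de"] = str(outdir)

    out_files = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    checksums = {f: sio.sha256_of(outdir / f) for f in out_files}
    sio.write_manifest(
        outdir / "manifest.json", stage="pipeline",
        params={"config": {k: v for k, v in config.items()},
                "scene": asdict(params)},
        seeds=seeds, outputs=[{"file": f, "sha256": checksums[f]}
                              for f in out_files],
    )
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
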