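"""End-to-end orchestration: simulate -> quantify -> scan -> distance -> topology.

A single YAML-serializable config drives every stage; one root seed spawns
per-stage seeds deterministically, and the run report (headline numbers per
stage plus the config hash) is bit-reproducible for a fixed config+seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distance as dist_mod
from . import quantify as quant_mod
from . import scan as scan_mod
from . import topology as topo_mod
from .annotation import LocusAnnotation, LocusConfig, build_locus_annotation
from .contacts import ContactMatrix
from .core import ProcessivityParams
from .simulate import (
    CountMatrix,
    simulate_chip_and_4c,
    simulate_contact_matrix,
    simulate_expression,
    write_ground_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "config_hash", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a stage cannot run; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 1234,
    "locus": {},  # LocusConfig field overrides
    "model": {},  # ProcessivityParams field overrides
    "expression": {"replicates": 3, "depth": 2.0e7, "nb_dispersion": 0.05},
    "chip": {"replicates": 3, "nb_dispersion": 0.05},
    "contacts": {"bin_size": 10_000, "cis_depth": 5.0e6, "tad_elevation": 3.0},
    "quantify": {"pseudo": 0.01, "lfc_threshold": 0.5, "padj_threshold": 0.05},
    "scan": {"width": 1_000_000, "step": None, "gene_bearing_only": False},
    "distance": {"reference_mode": "midpoint"},
    "topology": {
        "window_bp": 2_000_000,
        "n_states": 3,
        "kr_tolerance": 1.0e-8,
        "depth_target": 1.0e8,
        "mixture_components": 3,
        "min_bins": 3,
        "min_median_posterior": 0.99,
    },
    "stages": {
        "simulate": True,
        "quantify": True,
        "scan": True,
        "distance": True,
        "topology": True,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seeds(root_seed: int) -> dict[str, int]:
    names = ["simulate", "quantify", "scan", "distance", "topology"]
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    seeds = {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}
    for name, s in seeds.items():
        logger.info("stage %s derived seed %d", name, s)
    return seeds


def _require(path: Path, stage: str):
    if not path.exists():
        raise PipelineError(f"stage '{stage}' is missing required input {path.name} "
                            f"(was the producing stage toggled off?)")
    return path


# ---------------------------------------------------------------------------
# Stages (file-oriented so the CLI subcommands stay thin)


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> dict:
    ann = build_locus_annotation(LocusConfig(**cfg["locus"]))
    params = ProcessivityParams(**cfg["model"])
    simdir = outdir / "simulate"
    simdir.mkdir(parents=True, exist_ok=True)
    ann.write(simdir)

    counts, truth = simulate_expression(ann, params, seed=seed, **cfg["expression"])
    counts.write(simdir / "expression_counts.tsv")

    chip, tracks = simulate_chip_and_4c(ann, params, seed=seed + 1, **cfg["chip"])
    chip.counts.write(simdir / "chip_counts.tsv")
    chip.peaks.to_csv(simdir / "chip_peaks.tsv", sep="\t", index=False)
    for (vp, cond), track in tracks.items():
        name = f"4c_{vp.replace('-', '')}_{cond}.bedgraph"
        track.to_csv(simdir / name, sep="\t", header=False, index=False)

    ccfg = cfg["contacts"]
    mats = {}
    contact_info = {}
    for cond, off in (("WT", 2), ("mut", 3)):
        mat, info = simulate_contact_matrix(
            ann, params, condition=cond, seed=seed + off, **ccfg
        )
        mat.write(simdir / f"contacts_{cond}")
        mats[cond] = mat
        contact_info[cond] = info

    truth["planted_boundaries_bp"] = contact_info["WT"]["boundaries_bp"]
    truth["chip_expected_ratio"] = chip.truth["expected_ratio"]
    write_ground_truth(truth, simdir / "ground_truth.json")
    return {
        "n_cluster_genes": int(len(ann.cluster_genes)),
        "n_background_genes": int(len(ann.background_gene_table)),
        "n_enhancers": int(len(ann.enhancers)),
        "contact_bins": mats["WT"].n_bins,
    }


def _read_counts(path: Path, lengths: pd.Series, depth: float) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    cols = list(counts.columns)
    samples = pd.DataFrame(
        {
            "sample_id": cols,
            "condition": [c.split("_")[0] for c in cols],
            "replicate": [int(c.rsplit("rep", 1)[1]) for c in cols],
        }
    )
    return CountMatrix(
        counts=counts,
        samples=samples,
        lengths=lengths.reindex(counts.index),
        library_sizes=pd.Series(float(depth), index=cols),
    )


def stage_quantify(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    qdir = outdir / "quantify"
    qdir.mkdir(parents=True, exist_ok=True)
    ann = LocusAnnotation.read(_require(simdir, "quantify"))
    qcfg = cfg["quantify"]
    pseudo = qcfg["pseudo"]

    # RNA
    gene_lengths = ann.genes.set_index("gene_id")["length"].astype(float)
    rna = _read_counts(
        _require(simdir / "expression_counts.tsv", "quantify"),
        gene_lengths,
        cfg["expression"]["depth"],
    )
    fpkm = quant_mod.compute_fpkm(rna)
    fc_rna = quant_mod.fold_change(
        fpkm[rna.condition_columns("WT")],
        fpkm[rna.condition_columns("mut")],
        pseudo=pseudo,
        modality="RNA",
    )
    fc_rna.to_csv(qdir / "fold_change_RNA.tsv", sep="\t", index=False)
    degs = quant_mod.call_degs(fc_rna, qcfg["lfc_threshold"], qcfg["padj_threshold"])
    pd.DataFrame(
        {"gene_id": degs.all, "direction": ["up"] * len(degs.up) + ["down"] * len(degs.down)}
    ).to_csv(qdir / "degs.tsv", sep="\t", index=False)

    # ChIP
    peaks = pd.read_csv(_require(simdir / "chip_peaks.tsv", "quantify"), sep="\t")
    peak_lengths = peaks.set_index("peak_id")["length"].astype(float)
    chip = _read_counts(
        _require(simdir / "chip_counts.tsv", "quantify"),
        peak_lengths,
        cfg["expression"]["depth"],
    )
    enr = quant_mod.peak_enrichment(chip)
    fc_chip = quant_mod.fold_change(
        enr[chip.condition_columns("WT")],
        enr[chip.condition_columns("mut")],
        pseudo=pseudo,
        modality="ChIP",
    )
    # distance pairing uses gene names: keep promoter peaks only
    promoter_ids = set(peaks.loc[peaks["kind"] == "promoter", "peak_id"])
    fc_chip = fc_chip[fc_chip["gene_id"].isin(promoter_ids)].reset_index(drop=True)
    fc_chip.to_csv(qdir / "fold_change_ChIP.tsv", sep="\t", index=False)

    # Contacts: virtual 4C per cluster from its own enhancer set
    target = cfg["topology"]["depth_target"]
    mats = {
        cond: topo_mod.normalize_depth(
            ContactMatrix.read(_require(simdir / f"contacts_{cond}.mtx", "quantify").with_suffix("")),
            target,
        )
        for cond in ("WT", "mut")
    }
    rows = []
    for cluster in ("alpha", "beta", "gamma"):
        elements = dist_mod.assign_enhancer(cluster)
        genes = ann.cluster_genes[ann.cluster_genes["cluster"] == cluster]
        wt = quant_mod.gene_contact_probability(mats["WT"], elements, ann, genes=genes)
        mut = quant_mod.gene_contact_probability(mats["mut"], elements, ann, genes=genes)
        for gid in wt.index:
            rows.append(
                {
                    "gene_id": gid,
                    "modality": "contact",
                    "mean_wt": wt[gid],
                    "mean_mut": mut[gid],
                    "log2fc": float(np.log2((mut[gid] + pseudo) / (wt[gid] + pseudo))),
                    "p": np.nan,
                    "padj": np.nan,
                }
            )
    fc_contact = pd.DataFrame(rows)
    fc_contact.to_csv(qdir / "fold_change_contact.tsv", sep="\t", index=False)

    return {
        "n_degs_up": len(degs.up),
        "n_degs_down": len(degs.down),
        "modalities": ["RNA", "ChIP", "contact"],
    }


def stage_scan(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    qdir = outdir / "quantify"
    sdir = outdir / "scan"
    sdir.mkdir(parents=True, exist_ok=True)
    ann = LocusAnnotation.read(_require(simdir, "scan"))
    degs = pd.read_csv(_require(qdir / "degs.tsv", "scan"), sep="\t")
    down = degs.loc[degs["direction"] == "down", "gene_id"]
    anchors = ann.genes.set_index("gene_id").loc[down]
    hits = pd.DataFrame({"chrom": anchors["chrom"], "pos": anchors["anchor"]})

    scfg = cfg["scan"]
    bins = scan_mod.bin_genome(ann.genome, width=scfg["width"], step=scfg["step"])
    bins = scan_mod.count_hits(bins, hits, genome=ann.genome)
    gene_iv = None
    if scfg["gene_bearing_only"]:
        gene_iv = ann.genes.rename(columns={"exon_start": "start", "exon_end": "end"})[
            ["chrom", "start", "end"]
        ]
    results = scan_mod.poisson_scan(bins, gene_bearing_only=scfg["gene_bearing_only"],
                                    gene_intervals=gene_iv)
    table = scan_mod.manhattan_table(results, ann.genome)
    table.to_csv(sdir / "manhattan.tsv", sep="\t", index=False)
    top = table[table["rank"] == 1].iloc[0]
    return {
        "n_hits": int(len(hits)),
        "lambda": float(top["lam"]),
        "top_bin": {
            "chrom": str(top["chrom"]),
            "start": int(top["start"]),
            "k": int(top["k"]),
            "fold": float(top["fold"]),
            "minus_log10_p": float(top["minus_log10_p"]),
        },
    }


def stage_distance(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    qdir = outdir / "quantify"
    ddir = outdir / "distance"
    ddir.mkdir(parents=True, exist_ok=True)
    ann = LocusAnnotation.read(_require(simdir, "distance"))
    with open(_require(simdir / "ground_truth.json", "distance")) as fh:
        truth = json.load(fh)
    eta = truth.get("expression_coupling", 1.0)
    lambda_wt = truth.get("lambda_wt", 400_000.0)

    summary: dict = {}
    for modality in ("RNA", "ChIP", "contact"):
        path = _require(qdir / f"fold_change_{modality}.tsv", "distance")
        fc = pd.read_csv(path, sep="\t")
        pairs = dist_mod.make_pairs(fc, ann, modality=modality,
                                    mode=cfg["distance"]["reference_mode"])
        pairs.to_csv(ddir / f"pairs_{modality}.tsv", sep="\t", index=False)
        fit = dist_mod.fit_distance_trend(pairs, modality=modality)
        mod_eta = eta if modality == "RNA" else 1.0
        delta = dist_mod.recover_processivity_delta(fit, eta=mod_eta, lambda_wt=lambda_wt)
        summary[modality] = {
            "slope_per_bp": fit.slope,
            "slope_se": fit.slope_se,
            "n": fit.n,
            "delta_inv_lambda": delta.delta_inv_lambda,
            "lambda_mut_recovered": delta.lambda_mut,
            "consistent": delta.consistent,
        }
        contrast = dist_mod.cluster_contrast(fc, ann, seed=cfg["seed"])
        contrast.to_csv(ddir / f"cluster_contrast_{modality}.tsv", sep="\t", index=False)
    with open(ddir / "fits.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def stage_topology(cfg: dict, outdir: Path, seed: int) -> dict:
    simdir = outdir / "simulate"
    tdir = outdir / "topology"
    tdir.mkdir(parents=True, exist_ok=True)
    tcfg = cfg["topology"]
    mats = {}
    for cond in ("WT", "mut"):
        _require(simdir / f"contacts_{cond}.mtx", "topology")
        mats[cond] = ContactMatrix.read(simdir / f"contacts_{cond}")

    out: dict = {}
    window = max(1, int(tcfg["window_bp"] // mats["WT"].bin_size))
    for cond, mat in mats.items():
        norm = topo_mod.normalize_depth(mat, tcfg["depth_target"])
        balanced = topo_mod.kr_balance(norm, tolerance=tcfg["kr_tolerance"])
        pd.DataFrame({"bin": np.arange(balanced.n_bins), "weight": balanced.weights}).to_csv(
            tdir / f"kr_weights_{cond}.tsv", sep="\t", index=False
        )
        di = topo_mod.directionality_index(balanced, window)
        di.to_bedgraph(tdir / f"di_{cond}.bedgraph")
        post = topo_mod.fit_hmm(di, n_states=tcfg["n_states"], seed=seed,
                                mixture_components=tcfg["mixture_components"])
        tads = topo_mod.call_tads(
            post, min_bins=tcfg["min_bins"],
            min_median_posterior=tcfg["min_median_posterior"],
        )
        bed = pd.DataFrame(
            {
                "chrom": mat.chrom,
                "start": [mat.start + a * mat.bin_size for a, _ in tads.domains],
                "end": [mat.start + b * mat.bin_size for _, b in tads.domains],
                "name": [f"TAD_{cond}_{i + 1}" for i in range(len(tads.domains))],
            }
        )
        bed.to_csv(tdir / f"tads_{cond}.bed", sep="\t", header=False, index=False)
        out[cond] = {
            "n_tads": len(tads.domains),
            "boundaries_bin": tads.boundaries,
        }

    norm_wt = topo_mod.normalize_depth(mats["WT"], tcfg["depth_target"])
    norm_mut = topo_mod.normalize_depth(mats["mut"], tcfg["depth_target"])
    diff = topo_mod.differential_contact_map(norm_wt, norm_mut)
    np.savetxt(tdir / "differential_map.tsv", diff, delimiter="\t", fmt="%.6g")
    out["differential_mean"] = float(diff.mean())
    return out


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run all enabled stages and write ``report.json``; returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    stages = cfg["stages"]
    report: dict = {"config_hash": config_hash(cfg), "seeds": seeds, "stages": {}}

    runners = [
        ("simulate", lambda: stage_simulate(cfg, outdir, seeds["simulate"])),
        ("quantify", lambda: stage_quantify(cfg, outdir)),
        ("scan", lambda: stage_scan(cfg, outdir)),
        ("distance", lambda: stage_distance(cfg, outdir)),
        ("topology", lambda: stage_topology(cfg, outdir, seeds["topology"])),
    ]
    for name, fn in runners:
        if not stages.get(name, True):
            logger.info("stage %s disabled", name)
            continue
        logger.info("running stage %s", name)
        try:
            report["stages"][name] = fn()
        except PipelineError:
            raise
        except FileNotFoundError as exc:
            raise PipelineError(f"stage '{name}' failed: missing input {exc}") from exc

    canon = json.dumps(report, sort_keys=True)
    report["report_hash"] = hashlib.sha256(canon.encode()).hexdigest()[:16]
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
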