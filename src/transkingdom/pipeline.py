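"""End-to-end orchestration: simulate/load -> preprocess -> diversity ->
enterotype -> succinotype -> abundance -> networks -> network statistics.

Every stage draws its seed deterministically from the master seed (hash of
``"<master>:<stage>"``), writes its outputs under a run directory, and the
run ends with a manifest of SHA-256 hashes — identical config + seed gives a
byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import diversity as dv
from . import enterotype as et
from . import netinfer as ni
from . import netstats as ns
from . import succinotype as st
from . import synth
from .tables import (CountTable, rare_taxon_filter, rarefy,
                     read_count_table, read_metadata, read_taxonomy,
                     write_count_table)


class PipelineError(RuntimeError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(),
                             digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the analysis' standing parameters."""

    # inputs: either a synthetic block or explicit paths
    synth: dict | None = field(default_factory=dict)
    bacterial_counts: str | None = None
    fungal_counts: str | None = None
    metadata: str | None = None
    bacterial_taxonomy: str | None = None
    fungal_taxonomy: str | None = None

    rarefaction_depth: dict = field(default_factory=lambda: {
        "bacterial": 2000, "fungal": 1200})
    rare_taxon_fraction: float = 0.001
    da_prevalence: float = 0.10
    network_prevalence: float = 0.20
    dmm_k_range: tuple = (1, 2, 3)
    dmm_restarts: int = 2
    succinotype_hi: float = 0.9
    succinotype_lo: float = 0.1
    succinotype_min_reads: int = 10
    stars_subsample: float = 0.8
    stars_reps: int = 50
    stars_beta: float = 0.05
    n_lambda: int = 30
    leiden_resolution: float = 0.5
    keystone_fraction: float = 0.05
    robustness_reps: int = 50
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        for name in ("rare_taxon_fraction", "da_prevalence",
                     "network_prevalence", "stars_subsample", "stars_beta",
                     "keystone_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise PipelineError(f"{name}={v} outside (0, 1)")
        if not 0 < self.succinotype_lo < self.succinotype_hi < 1:
            raise PipelineError("need 0 < succinotype_lo < hi < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default))


def _fmt_frame(df: pd.DataFrame, path: Path, index: bool = True,
               index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.seed
    manifest: dict = {"seed": master, "stages": {}, "files": {}}

    # --- stage: inputs ---------------------------------------------------
    if config.synth is not None and config.bacterial_counts is None:
        scfg = synth.SynthConfig(**(config.synth or {}))
        scfg.seed = stage_seed(master, "synthgen")
        bact, fung, metadata, taxonomy, truth = synth.generate_cohort(scfg)
        cohort_dir = out / "cohort"
        synth.write_cohort(cohort_dir, bact, fung, metadata, taxonomy, truth)
        manifest["stages"]["synthgen"] = {"seed": scfg.seed,
                                          "n_samples": bact.n_samples}
    else:
        bact = read_count_table(config.bacterial_counts, "bacterial")
        fung = read_count_table(config.fungal_counts, "fungal")
        metadata = read_metadata(config.metadata)
        taxonomy = {
            "bacterial": read_taxonomy(config.bacterial_taxonomy),
            "fungal": read_taxonomy(config.fungal_taxonomy),
        }
        missing = sorted(set(bact.sample_ids) - set(metadata.index))
        if missing:
            raise PipelineError(f"metadata missing samples: {missing}")

    # --- stage: preprocess ----------------------------------------------
    pre = out / "preprocess"
    pre.mkdir(exist_ok=True)
    processed = {}
    for kingdom, table in (("bacterial", bact), ("fungal", fung)):
        filtered, filt_report = rare_taxon_filter(
            table, config.rare_taxon_fraction)
        depth = config.rarefaction_depth[kingdom]
        seed = stage_seed(master, f"rarefy:{kingdom}")
        rare, rare_report = rarefy(filtered, depth, seed)
        processed[kingdom] = rare
        write_count_table(rare, pre / f"{kingdom}_rarefied.tsv",
                          log={"rare_taxon": filt_report,
                               "rarefy": rare_report})
    bact_r = processed["bacterial"]
    fung_r = processed["fungal"]
    md = metadata.loc[bact_r.sample_ids]
    manifest["stages"]["preprocess"] = {
        "bacterial_samples": bact_r.n_samples, "bacterial_taxa": bact_r.n_taxa,
        "fungal_samples": fung_r.n_samples, "fungal_taxa": fung_r.n_taxa}

    # --- stage: diversity ------------------------------------------------
    div = out / "diversity"
    div.mkdir(exist_ok=True)
    alpha = dv.alpha_diversity(bact_r)
    _fmt_frame(alpha, div / "alpha_bacterial.tsv", index_label="sample_id")
    bc = dv.beta_distance(bact_r, "bray_curtis")
    jc = dv.beta_distance(bact_r, "jaccard")
    seed_perm = stage_seed(master, "permanova")
    perm_results = {}
    for name, dm in (("bray_curtis", bc), ("jaccard", jc)):
        res = dv.permanova(dm, md["group"], n_perm=config.n_perm,
                           seed=seed_perm)
        res.to_tsv(div / f"permanova_group_{name}.tsv")
        perm_results[name] = res
        marg = dv.permanova(dm, md["calprotectin"],
                            covariates=md[["group"]],
                            n_perm=config.n_perm, seed=seed_perm)
        marg.to_tsv(div / f"permanova_calprotectin_given_group_{name}.tsv")
    pw = dv.pairwise_permanova(bc, md["group"], n_perm=config.n_perm,
                               seed=seed_perm)
    _fmt_frame(pw, div / "pairwise_group_bray_curtis.tsv", index=False)
    manifest["stages"]["diversity"] = {
        "group_R2_bray_curtis": float(
            perm_results["bray_curtis"].table.iloc[0]["R2"])}

    # --- stage: enterotype ----------------------------------------------
    ent = out / "enterotype"
    ent.mkdir(exist_ok=True)
    seed_dmm = stage_seed(master, "enterotype")
    best, fits, score_table = et.select_k(
        bact_r, k_range=list(config.dmm_k_range),
        n_restarts=config.dmm_restarts, seed=seed_dmm)
    k_star = best["BIC"]
    fit = fits[k_star]
    labels = fit.assign()
    _fmt_frame(score_table, ent / "scores.tsv", index_label="K")
    _fmt_frame(labels.to_frame(), ent / "labels.tsv", index_label="sample_id")
    if k_star > 1:
        contrib = et.genus_contributions(fit, fits[1], space="clr")
        _fmt_frame(contrib.to_frame(), ent / "contributions.tsv",
                   index_label="genus")
    _write_json({"selected_K": {c: int(k) for c, k in best.items()},
                 "weights": fit.weights, "loglik": fit.loglik,
                 "converged": bool(fit.converged)},
                ent / "summary.json")
    manifest["stages"]["enterotype"] = {"selected_K": int(k_star)}

    # --- stage: succinotype ----------------------------------------------
    suc = out / "succinotype"
    suc.mkdir(exist_ok=True)
    calls = st.classify_cohort(bact_r, hi=config.succinotype_hi,
                               lo=config.succinotype_lo,
                               min_reads=config.succinotype_min_reads)
    _fmt_frame(calls, suc / "calls.tsv", index_label="sample_id")
    prev = st.prevalence_summary(calls, md["group"])
    _fmt_frame(prev, suc / "prevalence.tsv", index_label="label")
    assoc = st.association_tests(calls, md, ["group"])
    _fmt_frame(assoc, suc / "associations.tsv", index=False)
    manifest["stages"]["succinotype"] = {
        "cohort_fractions": {l: float(prev.loc[l, "cohort_fraction"])
                             for l in prev.index}}

    # --- stage: abundance ------------------------------------------------
    abd = out / "abundance"
    abd.mkdir(exist_ok=True)
    da = ab.da_screen(bact_r, md, "group", prevalence=config.da_prevalence)
    _fmt_frame(da, abd / "da_bacterial.tsv", index=False)
    ba = ab.ba_ratio(fung_r, taxonomy["fungal"])
    _fmt_frame(ba, abd / "ba_ratio.tsv", index_label="sample_id")
    n_hits = int((da["p_adj"] < 0.05).sum())
    manifest["stages"]["abundance"] = {"bacterial_hits": n_hits}

    # --- stage: networks --------------------------------------------------
    nets = out / "networks"
    nets.mkdir(exist_ok=True)
    subsets = {}
    for label in ("D", "P", "mixed"):
        ids = calls.index[calls["label"] == label]
        subsets[f"succinotype_{label}"] = (
            [CountTable(bact_r.data.loc[ids], "bacterial")], len(ids))
    shared = [s for s in bact_r.sample_ids if s in fung_r.sample_ids]
    for group in sorted(md["group"].unique()):
        ids = [s for s in shared if md.loc[s, "group"] == group]
        subsets[f"group_{group}"] = (
            [CountTable(bact_r.data.loc[ids], "bacterial"),
             CountTable(fung_r.data.loc[ids], "fungal")], len(ids))
    networks = {}
    net_manifest = {}
    for name, (tabs, n_sub) in sorted(subsets.items()):
        if n_sub < 5:
            net_manifest[name] = {"skipped": f"only {n_sub} samples"}
            continue
        model = ni.GraphicalLassoNetwork(
            tabs, prevalence=config.network_prevalence)
        net = model.fit(n_lambda=config.n_lambda,
                        subsample_fraction=config.stars_subsample,
                        n_reps=config.stars_reps, beta=config.stars_beta,
                        seed=stage_seed(master, f"network:{name}"))
        net.write(nets / name)
        networks[name] = net
        net_manifest[name] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                              "lambda": net.selected_lambda}
    manifest["stages"]["networks"] = net_manifest

    # --- stage: netstats ---------------------------------------------------
    nst = out / "netstats"
    nst.mkdir(exist_ok=True)
    stats_manifest = {}
    for name, net in sorted(networks.items()):
        G = net.to_networkx()
        report = ns.network_report(
            G, resolution=config.leiden_resolution,
            keystone_fraction=config.keystone_fraction,
            seed=stage_seed(master, f"netstats:{name}"),
            robustness_reps=config.robustness_reps)
        if report["empty"]:
            stats_manifest[name] = {"empty": True}
            continue
        _fmt_frame(report["nodes"], nst / f"{name}_nodes.tsv",
                   index_label="taxon_id")
        _fmt_frame(report["keystones"], nst / f"{name}_keystones.tsv",
                   index_label="taxon_id")
        ns.write_visualization(G, report["communities"], report["keystones"],
                               nst / f"{name}_viz.graphml")
        rob = report["robustness"]["targeted"]
        frame = rob.to_frame()
        frame.to_csv(nst / f"{name}_robustness_targeted.tsv", sep="\t",
                     index=False, float_format="%.10g")
        _write_json({"global": report["global"],
                     "communities": report["communities"],
                     "robustness": {
                         k: {"auc": r.auc, "r50": r.r50}
                         for k, r in report["robustness"].items()}},
                    nst / f"{name}_global.json")
        stats_manifest[name] = {
            "auc_targeted": report["robustness"]["targeted"].auc,
            "r50_targeted": report["robustness"]["targeted"].r50,
            "modularity": report["global"]["modularity"],
            "keystones": sorted(report["keystones"].index)}
    manifest["stages"]["netstats"] = stats_manifest

    # --- manifest ----------------------------------------------------------
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    _write_json(manifest, out / "manifest.json")
    return manifest


def make_report(outdir: str | Path) -> str:
    """Assemble a human-readable summary from a completed run directory."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    stages = manifest["stages"]
    lines = ["# Multi-kingdom stratification report", ""]
    if "synthgen" in stages:
        lines.append(f"Synthetic cohort: {stages['synthgen']['n_samples']} "
                     f"samples (seed {stages['synthgen']['seed']})")
    pre = stages["preprocess"]
    lines.append(f"After preprocessing: {pre['bacterial_samples']} bacterial "
                 f"samples x {pre['bacterial_taxa']} taxa; "
                 f"{pre['fungal_samples']} fungal samples x "
                 f"{pre['fungal_taxa']} taxa")
    lines.append("")
    lines.append(f"Enterotype components selected (BIC): "
                 f"{stages['enterotype']['selected_K']}")
    succ = stages["succinotype"]["cohort_fractions"]
    lines.append("Succinotype cohort fractions: " + ", ".join(
        f"{k}={v:.1%}" for k, v in sorted(succ.items())))
    lines.append(f"PERMANOVA group R2 (Bray-Curtis): "
                 f"{stages['diversity']['group_R2_bray_curtis']:.3f}")
    hits = stages["abundance"]["bacterial_hits"]
    lines.append(f"Differentially abundant bacterial (genus, comparison) "
                 f"pairs at BH 0.05: {hits if hits else '0 genera'}")
    lines.append("")
    lines.append("## Networks")
    for name, info in sorted(stages["networks"].items()):
        if "skipped" in info:
            lines.append(f"- {name}: skipped ({info['skipped']})")
            continue
        extra = ""
        nstat = stages["netstats"].get(name, {})
        if nstat and not nstat.get("empty"):
            extra = (f"; modularity {nstat['modularity']:.3f}, targeted "
                     f"AUC {nstat['auc_targeted']:.3f}, "
                     f"R50 {nstat['r50_targeted']:.3f}; keystones: "
                     + ", ".join(nstat["keystones"]))
        lines.append(f"- {name}: {info['n_nodes']} nodes, "
                     f"{info['n_edges']} edges{extra}")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
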