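"""End-to-end orchestration over an on-disk synthetic cohort.

Each stage reads the previous stage's plain-text outputs from the run
directory and writes its own, so the stages compose from the CLI
(``methfidelity simulate|preprocess|embed|cnv|dmr|enrich|fidelity|run-all``)
as well as from Python.  Layout of a run directory::

    dataset/      intensities_{M,U,detp,beads}.tsv, manifest.tsv(+bed),
                  samplesheet.tsv, truth.json, genesets.gmt
    preprocess/   beta.tsv (filtered + BMIQ), qc_report.json, mds.tsv,
                  svd_table.tsv
    embed/        embedding.tsv, clusters.tsv, validity.tsv
    cnv/          bins.bed, cnv_profiles.tsv, similarity.tsv, burden.tsv
    dmr/          dmrs.tsv, gene_lists.json
    enrich/       enrichment.tsv, intersection.tsv
    fidelity/     fidelity.tsv, fidelity_report.json
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnvmod
from . import dmr as dmrmod
from . import embed_cluster as emb
from . import enrichment as enr
from . import fidelity as fid
from . import preprocess as pre
from . import synthetic as syn

__all__ = ["DEFAULT_CONFIG", "load_config", "run_simulate", "run_preprocess",
           "run_embed", "run_cnv", "run_dmr", "run_enrich", "run_fidelity",
           "run_all"]

DEFAULT_CONFIG: dict = {
    "manifest": {
        "n_probes": 8000,
        "chrom_sizes": {"chr1": 20_000_000, "chr2": 16_000_000,
                        "chr3": 12_000_000, "chr4": 10_000_000},
        "gene_spacing": 100_000,
    },
    "cohort": {
        "labels": ["MB", "LGG", "HGG", "DMG"],
        "n_tumors_per_class": 5,
        "n_pairs_per_class": 6,
        "n_controls": 6,
        "noise_sd": 0.3,
    },
    "genesets": {"n_random_terms": 20, "term_size": 15},
    "preprocess": {"detp_max": 0.01, "bead_min": 3, "bead_frac": 0.05,
                   "offset": 100.0},
    "embed": {"perplexity": 15, "theta": 0.5, "eei": 200,
              "pca_components": 20, "min_cluster_size": 4},
    "cnv": {"min_size": 50_000, "min_probes": 15, "burden_thresh": 0.1},
    "dmr": {"lambda": 1000, "min_cpgs": 7, "fdr": 0.05, "promoter_only": True},
    "enrich": {"cutoff": 0.3},
    "fidelity": {"sharpness": 10.0, "top_k_probes": 1000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """DEFAULT_CONFIG, optionally overridden by a YAML file."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _make_genesets(manifest, design, cfg, seed) -> dict[str, list[str]]:
    """Synthetic GMT: one term concentrating the divergence signal (panel
    genes plus genes under planted DMRs) among random filler terms."""
    rng = np.random.default_rng(seed + 7)
    universe = sorted(g for g in manifest["gene"].unique() if g)
    dmr_genes: set[str] = set()
    for d in design.planted_dmrs:
        sel = (
            (manifest["chrom"] == d.chrom)
            & (manifest["pos"] >= d.start)
            & (manifest["pos"] <= d.end)
        )
        dmr_genes |= set(g for g in manifest.loc[sel, "gene"] if g)
    sets = {"DIVERGENCE_RESPONSE": sorted(set(design.divergence_genes) | dmr_genes)}
    k = cfg["genesets"]["term_size"]
    for i in range(cfg["genesets"]["n_random_terms"]):
        sets[f"RANDOM_{i:02d}"] = sorted(rng.choice(universe, size=k, replace=False))
    return sets


def run_simulate(outdir: str | Path, config: dict | None = None, seed: int = 0):
    cfg = config or DEFAULT_CONFIG
    outdir = Path(outdir)
    manifest = syn.build_manifest(seed=seed, **cfg["manifest"])
    cohort = dict(cfg["cohort"])
    cohort["labels"] = tuple(cohort["labels"])
    design = syn.default_design(manifest, seed=seed, **cohort)
    intens, sheet, truth = syn.simulate_cohort(manifest, design)
    genesets = _make_genesets(manifest, design, cfg, seed)
    syn.write_dataset(outdir / "dataset", intens, manifest, sheet, truth,
                      genesets=genesets, overwrite=True)
    return intens, manifest, sheet, truth


def run_preprocess(outdir: str | Path, config: dict | None = None, seed: int = 0):
    cfg = (config or DEFAULT_CONFIG)["preprocess"]
    outdir = Path(outdir)
    intens, manifest, sheet, _ = syn.read_dataset(outdir / "dataset")
    keep, report = pre.filter_probes(
        intens, manifest, detp_max=cfg["detp_max"],
        bead_min=cfg["bead_min"], bead_frac=cfg["bead_frac"],
    )
    beta = pre.compute_beta(intens, offset=cfg["offset"]).loc[keep]
    beta, bmiq_log = pre.bmiq(beta, manifest.loc[keep.index[keep], "design_type"], seed=seed)
    coords, outliers = pre.mds_outlier_check(beta)
    report.outlier_samples = outliers
    covars = sheet[["role", "histology", "medium", "timing"]]
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # constant covariates are expected here
        report.svd_table = pre.svd_covariate_scan(beta, covars)

    stage = outdir / "preprocess"
    stage.mkdir(parents=True, exist_ok=True)
    beta.to_csv(stage / "beta.tsv", sep="\t", index_label="probe_id")
    coords.to_csv(stage / "mds.tsv", sep="\t", index_label="sample_id")
    report.svd_table.to_csv(stage / "svd_table.tsv", sep="\t")
    (stage / "qc_report.json").write_text(json.dumps({
        "n_retained": report.n_retained,
        "removed_counts": report.counts().to_dict(),
        "outlier_samples": report.outlier_samples,
        "bmiq_converged": bmiq_log,
    }, indent=1))
    return beta, report


def _load_beta(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "preprocess" / "beta.tsv", sep="\t",
                       index_col="probe_id")


def _load_sheet(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "dataset" / "samplesheet.tsv", sep="\t",
                       keep_default_na=False, dtype=str
                       ).set_index("sample_id", drop=False)


def run_embed(outdir: str | Path, config: dict | None = None, seed: int = 0):
    cfg = (config or DEFAULT_CONFIG)["embed"]
    outdir = Path(outdir)
    beta = _load_beta(outdir)
    sheet = _load_sheet(outdir)
    use = sheet.index[sheet["role"].isin(["tumor", "cell"])]
    embedding = emb.embed(
        beta[use], perplexity=cfg["perplexity"], theta=cfg["theta"],
        eei=cfg["eei"], pca_components=cfg["pca_components"], seed=seed,
    )
    assignment = emb.cluster(embedding, min_cluster_size=cfg["min_cluster_size"])
    validity, overall = emb.dbcv(embedding, assignment.labels)
    assignment.validity, assignment.overall_validity = validity, overall

    stage = outdir / "embed"
    stage.mkdir(parents=True, exist_ok=True)
    embedding.frame().to_csv(stage / "embedding.tsv", sep="\t",
                             index_label="sample_id")
    assignment.labels.to_frame().to_csv(stage / "clusters.tsv", sep="\t",
                                        index_label="sample_id")
    vframe = validity.to_frame()
    vframe["valid"] = vframe["dbcv"] > emb.VALIDITY_THRESHOLD
    vframe.to_csv(stage / "validity.tsv", sep="\t", index_label="cluster")
    return embedding, assignment


def run_cnv(outdir: str | Path, config: dict | None = None, seed: int = 0):
    cfg = (config or DEFAULT_CONFIG)["cnv"]
    outdir = Path(outdir)
    intens, manifest, sheet, _ = syn.read_dataset(outdir / "dataset")
    probes = _load_beta(outdir).index  # QC-filtered probe set
    total = intens.total().loc[probes]
    man = manifest.loc[probes]
    bins = cnvmod.make_bins(man, min_size=cfg["min_size"],
                            min_probes=cfg["min_probes"])

    controls = total[sheet.index[sheet["role"] == "control"]]
    profiles: dict[str, cnvmod.CNVProfile] = {}
    for sid in sheet.index[sheet["role"].isin(["tumor", "cell"])]:
        log2r, fit = cnvmod.probe_log2r(total[sid], controls)
        profiles[sid] = cnvmod.bin_profile(log2r, bins, sample_id=sid, baseline=fit)

    pairs = [
        (sid, sheet.loc[sid, "pair_id"])
        for sid in sheet.index[(sheet["role"] == "cell") & (sheet["pair_id"] != "")]
    ]
    cohort_r = [
        float(np.corrcoef(profiles[c].log2r, profiles[t].log2r)[0, 1])
        for c, t in pairs
    ]
    calls = [
        cnvmod.similarity(profiles[c], profiles[t], cohort_r) for c, t in pairs
    ]
    burdens = {
        sid: cnvmod.alteration_burden(p, thresh=cfg["burden_thresh"])
        for sid, p in profiles.items()
    }

    stage = outdir / "cnv"
    stage.mkdir(parents=True, exist_ok=True)
    usable = bins[~bins["undersized"]]
    pd.DataFrame({
        "chrom": usable["chrom"], "start": usable["start"] - 1,
        "end": usable["end"],
    }).to_csv(stage / "bins.bed", sep="\t", index=False, header=False)
    pd.concat({s: p.log2r for s, p in profiles.items()}, axis=1).to_csv(
        stage / "cnv_profiles.tsv", sep="\t", index_label="bin")
    pd.DataFrame([
        dict(cell_id=c.cell_id, tissue_id=c.tissue_id, r=c.r,
             category=c.category, flags=";".join(c.flags))
        for c in calls
    ]).to_csv(stage / "similarity.tsv", sep="\t", index=False)
    pd.Series(burdens, name="burden").to_csv(stage / "burden.tsv", sep="\t",
                                             index_label="sample_id")
    return profiles, calls


def _dnam_status(beta: pd.DataFrame, sheet: pd.DataFrame, sharpness: float,
                 top_k: int) -> tuple[list[fid.ClassScore], dict[str, str]]:
    """Centroid scores for all cells plus their DNAm status vs histology."""
    tumors = sheet.index[sheet["role"] == "tumor"]
    classes = sorted(set(sheet.loc[tumors, "histology"]))
    centroids = pd.DataFrame(
        {c: beta[tumors[sheet.loc[tumors, "histology"] == c]].mean(axis=1)
         for c in classes}
    )
    sel = beta[tumors].var(axis=1).nlargest(min(top_k, len(beta))).index
    cells = sheet.index[sheet["role"] == "cell"]
    scores = fid.centroid_scores(beta.loc[sel, cells], centroids.loc[sel],
                                 sharpness=sharpness)
    status = {}
    for sc in scores:
        _, st = fid.match_assessment(sc, sheet.loc[sc.sample_id, "histology"])
        status[sc.sample_id] = st
    return scores, status


def run_dmr(outdir: str | Path, config: dict | None = None, seed: int = 0):
    full_cfg = config or DEFAULT_CONFIG
    cfg = full_cfg["dmr"]
    outdir = Path(outdir)
    beta = _load_beta(outdir)
    sheet = _load_sheet(outdir)
    _, manifest, _, _ = syn.read_dataset(outdir / "dataset")
    man = manifest.loc[beta.index]
    mvals = pre.beta_to_m(beta)

    _, status = _dnam_status(beta, sheet, full_cfg["fidelity"]["sharpness"],
                             full_cfg["fidelity"]["top_k_probes"])
    divergent = [s for s, st in status.items() if st == "unfaithful"]
    consistent = [s for s, st in status.items() if st == "maintained"]
    tumors = list(sheet.index[sheet["role"] == "tumor"])

    contrasts = []
    if len(divergent) >= 2:
        contrasts.append(dmrmod.GroupContrast(divergent, tumors + consistent, "DCA"))
    for label in sorted(set(sheet.loc[sheet["role"] == "cell", "histology"])):
        div_c = [s for s in divergent if sheet.loc[s, "histology"] == label]
        ref_c = [t for t in tumors if sheet.loc[t, "histology"] == label]
        if len(div_c) >= 2 and len(ref_c) >= 2:
            contrasts.append(dmrmod.GroupContrast(div_c, ref_c, label))

    all_rows, gene_lists = [], {}
    for contrast in contrasts:
        stats_df = dmrmod.cpg_stats(mvals, contrast)
        records = dmrmod.call_dmrs(stats_df, man, lambda_=cfg["lambda"],
                                   min_cpgs=cfg["min_cpgs"], fdr=cfg["fdr"])
        records = dmrmod.annotate_dmrs(records, beta, man, contrast)
        if cfg["promoter_only"]:
            records = dmrmod.promoter_filter(records, man)
        hypo, hyper = dmrmod.split_hypo_hyper(records)
        gene_lists[contrast.label] = {"hypo": sorted(hypo), "hyper": sorted(hyper)}
        for r in records:
            all_rows.append(dict(
                contrast=contrast.label, chrom=r.chrom, start=r.start,
                end=r.end, n_cpgs=r.n_cpgs, q=r.q, delta_beta=r.delta_beta,
                direction=r.direction, genes=";".join(sorted(r.genes)),
            ))

    stage = outdir / "dmr"
    stage.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(all_rows, columns=["contrast", "chrom", "start", "end",
                                    "n_cpgs", "q", "delta_beta", "direction",
                                    "genes"]).to_csv(
        stage / "dmrs.tsv", sep="\t", index=False)
    (stage / "gene_lists.json").write_text(json.dumps(gene_lists, indent=1))
    return gene_lists


def run_enrich(outdir: str | Path, config: dict | None = None, seed: int = 0):
    cfg = (config or DEFAULT_CONFIG)["enrich"]
    outdir = Path(outdir)
    _, manifest, _, _ = syn.read_dataset(outdir / "dataset")
    genesets = enr.read_gmt(outdir / "dataset" / "genesets.gmt")
    gene_lists = json.loads((outdir / "dmr" / "gene_lists.json").read_text())

    bias = enr.gene_cpg_bias(manifest)
    universe = set(bias.index)
    rows = []
    label = "DCA" if "DCA" in gene_lists else next(iter(gene_lists), None)
    if label is not None and gene_lists[label]["hypo"]:
        query = set(gene_lists[label]["hypo"]) & universe
        wall = enr.wallenius_test(query, genesets, bias, universe)
        fisher = {r.term: r for r in enr.ora_fisher(query, genesets, universe)}
        kept = {r.term for r in enr.reduce_redundancy(wall, genesets, cfg["cutoff"])}
        for r in sorted(wall, key=lambda r: r.p):
            rows.append(dict(
                contrast=label, term=r.term, p_wallenius=r.p, q_wallenius=r.q,
                p_fisher=fisher[r.term].p, overlap=r.k, term_size=r.term_size,
                kept_after_reduction=r.term in kept,
            ))

    hypo_lists = {
        lb: set(v["hypo"]) for lb, v in gene_lists.items()
        if lb != "DCA" and v["hypo"]
    }
    stage = outdir / "enrich"
    stage.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(stage / "enrichment.tsv", sep="\t", index=False)
    if len(hypo_lists) >= 2:
        shared, table = enr.intersect_hypo(hypo_lists)
        table.to_csv(stage / "intersection.tsv", sep="\t", index=False)
        (stage / "shared_genes.json").write_text(json.dumps(sorted(shared)))
    else:
        shared = set()
    return rows, shared


def run_fidelity(outdir: str | Path, config: dict | None = None, seed: int = 0):
    cfg = (config or DEFAULT_CONFIG)["fidelity"]
    outdir = Path(outdir)
    beta = _load_beta(outdir)
    sheet = _load_sheet(outdir)
    scores, status = _dnam_status(beta, sheet, cfg["sharpness"], cfg["top_k_probes"])
    sim = pd.read_csv(outdir / "cnv" / "similarity.tsv", sep="\t").set_index("cell_id")

    records = []
    for sc in scores:
        cid = sc.sample_id
        cnv_cat = sim.loc[cid, "category"] if cid in sim.index else None
        records.append(fid.FidelityRecord(
            cell_id=cid,
            tissue_id=sheet.loc[cid, "pair_id"] or None,
            category=fid.categorize(sc.max_score),
            histology_match=status[cid] == "maintained",
            dnam_status=status[cid],
            cnv_category=cnv_cat,
            condition=fid.assign_condition(status[cid], cnv_cat),
        ))
    report = fid.fidelity_report(records, sheet)

    stage = outdir / "fidelity"
    stage.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        dict(cell_id=r.cell_id, tissue_id=r.tissue_id or "",
             category=r.category, dnam_status=r.dnam_status,
             cnv_category=r.cnv_category or "", condition=r.condition or "")
        for r in records
    ]).to_csv(stage / "fidelity.tsv", sep="\t", index=False)
    (stage / "fidelity_report.json").write_text(json.dumps(report, indent=1,
                                                           default=str))
    return records, report


def run_all(outdir: str | Path, config: dict | None = None, seed: int = 0) -> dict:
    """Run every stage in order; returns a summary dict."""
    cfg = config or DEFAULT_CONFIG
    run_simulate(outdir, cfg, seed)
    beta, qc = run_preprocess(outdir, cfg, seed)
    _, assignment = run_embed(outdir, cfg, seed)
    _, calls = run_cnv(outdir, cfg, seed)
    gene_lists = run_dmr(outdir, cfg, seed)
    run_enrich(outdir, cfg, seed)
    records, report = run_fidelity(outdir, cfg, seed)
    return {
        "n_probes_retained": qc.n_retained,
        "n_clusters": assignment.n_clusters,
        "n_valid_clusters": int((assignment.validity > emb.VALIDITY_THRESHOLD).sum())
        if assignment.validity is not None else 0,
        "similarity_categories": pd.Series(
            [c.category for c in calls]).value_counts().to_dict(),
        "n_dmr_contrasts": len(gene_lists),
        "conditions": pd.Series(
            [r.condition for r in records if r.condition]).value_counts().to_dict(),
    }
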