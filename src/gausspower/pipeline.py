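"""File-based pipeline: filter -> cluster -> fit -> classify -> report.

Every stage reads its inputs from disk and writes TSV outputs into the
configured output directory, so stages can be run individually from the
CLI or all together with :func:`run_pipeline`.  All randomness derives
from one master seed via stable per-stage tags; two runs with the same
config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import cluster as clu
from . import fit as fitmod
from . import preprocess as pre

__all__ = ["PipelineConfig", "run_pipeline", "stage_filter", "stage_cluster",
           "stage_fit", "stage_classify", "stage_report"]

log = logging.getLogger("gausspower")


@dataclass
class PipelineConfig:
    matrix: str = "matrix.tsv"
    metadata: str = "metadata.tsv"
    annotation: str | None = None
    outdir: str = "gausspower_out"
    alpha: float = 0.2
    ttest_variant: str = "welch"
    k_range: tuple = (2, 20)
    n_restarts: int = 10
    n_grid: int = 100
    n_starts: int = 20
    branch_threshold: float = 3.0
    gap_to_nearest: bool = False
    log_base: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def _seed_for(master: int, tag: str) -> int:
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _cond_str(c: pre.ConditionKey) -> str:
    return f"{c.age_days}-{c.time_h}"


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages


def stage_filter(config: PipelineConfig) -> pd.DataFrame:
    """Stationarity filter for every condition; writes filtered.tsv."""
    matrix = pre.read_matrix(config.matrix)
    meta = pre.read_metadata(config.metadata)
    rows = []
    for cond in pre.list_conditions(meta):
        retained, pvals = pre.stationarity_filter(
            matrix, meta, cond, alpha=config.alpha,
            variant=config.ttest_variant)
        kept = set(retained)
        for gene, p in pvals.items():
            rows.append({"gene_id": gene, "condition": _cond_str(cond),
                         "pvalue": p, "retained": gene in kept})
        log.info("filter %s: retained %d/%d genes", cond, len(kept),
                 len(pvals))
    out = pd.DataFrame(rows)
    out.to_csv(_outdir(config) / "filtered.tsv", sep="\t", index=False)
    return out


def stage_cluster(config: PipelineConfig):
    """Cluster standardized eCDF profiles per condition (BIC-selected k)."""
    matrix = pre.read_matrix(config.matrix)
    meta = pre.read_metadata(config.metadata)
    out = _outdir(config)
    filtered = pd.read_csv(out / "filtered.tsv", sep="\t")
    assign_rows, prof_rows, model_info = [], [], {}
    for cond in pre.list_conditions(meta):
        cstr = _cond_str(cond)
        keep = filtered.query("condition == @cstr and retained")["gene_id"]
        samples = pre.condition_samples(meta, cond)["sample_id"].to_numpy()
        profiles, gene_ids = [], []
        n_degenerate = 0
        for gene in keep:
            try:
                prof = clu.build_ecdf_profile(
                    matrix.loc[gene, samples].to_numpy(dtype=float),
                    gene_id=gene, condition=cstr)
            except clu.DegenerateGeneError:
                n_degenerate += 1
                continue
            profiles.append(prof)
            gene_ids.append(gene)
        if len(profiles) <= config.k_range[1]:
            raise ValueError(
                f"condition {cstr}: only {len(profiles)} usable profiles "
                f"for k_range {config.k_range}")
        model = clu.select_k_and_fit(
            profiles, k_range=config.k_range,
            seed=_seed_for(config.seed, f"cluster:{cstr}"),
            n_restarts=config.n_restarts)
        log.info("cluster %s: k=%d (BIC %.1f), %d profiles, %d degenerate",
                 cstr, model.k, model.bic, len(profiles), n_degenerate)
        for gene, a in zip(gene_ids, model.assignments):
            assign_rows.append({"gene_id": gene, "condition": cstr,
                                "cluster_id": int(a)})
        for cid in range(model.k):
            prof = clu.cluster_average_profile(model, profiles, cid)
            for i, (v, p) in enumerate(zip(prof.values, prof.positions)):
                prof_rows.append({"condition": cstr, "cluster_id": cid,
                                  "n_members": prof.n_members, "idx": i,
                                  "value": v, "position": p})
        model_info[cstr] = {"k": model.k, "bic": model.bic,
                            "n_profiles": len(profiles),
                            "n_degenerate": n_degenerate}
    pd.DataFrame(assign_rows).to_csv(out / "assignments.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(prof_rows).to_csv(out / "cluster_profiles.tsv", sep="\t",
                                   index=False)
    with open(out / "cluster_models.json", "w") as fh:
        json.dump(model_info, fh, indent=2, sort_keys=True)
    return model_info


def stage_fit(config: PipelineConfig) -> pd.DataFrame:
    """ePDF estimation and G-P / NB fitting for every cluster profile."""
    out = _outdir(config)
    profs = pd.read_csv(out / "cluster_profiles.tsv", sep="\t")
    fitmod_threshold = config.branch_threshold
    rows = []
    for (cstr, cid), sub in profs.groupby(["condition", "cluster_id"],
                                          sort=True):
        sub = sub.sort_values("idx")
        prof = clu.ClusterProfile(
            cluster_id=int(cid), values=sub["value"].to_numpy(),
            positions=sub["position"].to_numpy(),
            n_members=int(sub["n_members"].iloc[0]))
        curve = fitmod.epdf_from_ecdf(prof, n_grid=config.n_grid)
        seed = _seed_for(config.seed, f"fit:{cstr}:{cid}")
        gp = fitmod.fit_family(curve, "GP", n_starts=config.n_starts,
                               seed=seed,
                               branch_threshold=fitmod_threshold)
        nb = fitmod.fit_family(curve, "NB", n_starts=config.n_starts,
                               seed=seed + 1,
                               branch_threshold=fitmod_threshold)
        preferred, lse_gp, lse_nb, tie = fitmod.compare_fits(gp, nb)
        row = {"condition": cstr, "cluster_id": int(cid),
               "n_members": prof.n_members, "branch": gp.branch,
               "max_epdf": curve.max_density,
               "lse_gp": lse_gp, "lse_nb": lse_nb,
               "preferred": preferred, "tie": tie,
               "gp_converged": gp.converged, "nb_converged": nb.converged}
        if gp.converged:
            row.update({"g": gp.params.g, "f": gp.params.f,
                        "K": gp.params.K, "A": gp.params.A})
        if nb.converged:
            row.update({"s": nb.params.s, "k": nb.params.k,
                        "Q": nb.params.Q, "B": nb.params.B})
        rows.append(row)
        log.info("fit %s cluster %d: branch=%s preferred=%s", cstr, cid,
                 gp.branch, preferred)
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    return fits


def stage_classify(config: PipelineConfig) -> pd.DataFrame:
    """Label clusters from GP fits and propagate labels to genes."""
    out = _outdir(config)
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    assign = pd.read_csv(out / "assignments.tsv", sep="\t")
    matrix = pre.read_matrix(config.matrix)
    meta = pre.read_metadata(config.metadata)
    ann = (pre.read_annotation(config.annotation)
           if config.annotation else None)

    labels = {}
    for _, row in fits.iterrows():
        if row.get("gp_converged", False) and np.isfinite(row.get("g", np.nan)):
            r = cls.log10_K_over_g(row["g"], row["K"])
            lab = cls.classify_cluster(
                _as_gp_fit(row), gap_to_nearest=config.gap_to_nearest)
            labels[(row["condition"], row["cluster_id"])] = (lab.label, r)
        else:
            labels[(row["condition"], row["cluster_id"])] = (
                cls.UNCLASSIFIED, np.nan)

    cond_samples = {}
    for cond in pre.list_conditions(meta):
        sel = pre.condition_samples(meta, cond)
        cond_samples[_cond_str(cond)] = (cond, sel["sample_id"].to_numpy())

    rows = []
    for (cstr, cid), sub in assign.groupby(["condition", "cluster_id"]):
        label, r = labels.get((cstr, cid), (cls.UNCLASSIFIED, np.nan))
        cond, samples = cond_samples[cstr]
        means = matrix.loc[sub["gene_id"], samples].mean(axis=1)
        for gene in sub["gene_id"]:
            rows.append({"gene_id": gene, "condition": cstr,
                         "age_days": cond.age_days, "time_h": cond.time_h,
                         "cluster_id": cid, "label": label,
                         "log10_K_over_g": r,
                         "mean_expression": float(means[gene])})
    table = pd.DataFrame(rows)
    if ann is not None:
        table = table.merge(ann, on="gene_id", how="left")
    table.to_csv(out / "gene_classes.tsv", sep="\t", index=False)
    return table


def _as_gp_fit(row) -> fitmod.FitResult:
    from .distributions import GPParams
    params = GPParams(g=float(row["g"]), f=float(row["f"]),
                      K=float(row["K"]),
                      A=float(row["A"]) if np.isfinite(row.get("A", np.nan))
                      else None)
    return fitmod.FitResult(family="GP", params=params,
                            lse=float(row["lse_gp"]), branch=row["branch"],
                            n_starts=0, converged=True)


def stage_report(config: PipelineConfig) -> dict:
    """Summary tables and the JSON run report."""
    out = _outdir(config)
    table = pd.read_csv(out / "gene_classes.tsv", sep="\t")
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    filtered = pd.read_csv(out / "filtered.tsv", sep="\t")

    by_cond = cls.summarize(table, "condition")
    by_cond.to_csv(out / "summary_by_condition.tsv", sep="\t", index=False)
    by_age = cls.summarize(table, "age")
    by_age.to_csv(out / "summary_by_age.tsv", sep="\t", index=False)
    if "category" in table.columns:
        cls.summarize(table, "category").to_csv(
            out / "summary_by_category.tsv", sep="\t", index=False)

    classified = table[table["label"] != cls.UNCLASSIFIED]
    pooled = {lbl: (float((classified["label"] == lbl).mean())
                    if len(classified) else float("nan"))
              for lbl in cls.LABELS}
    report = {
        "config": config.to_dict(),
        "n_genes_by_condition": {
            c: int(n) for c, n in
            filtered.query("retained").groupby("condition").size().items()},
        "clusters_by_condition": {
            c: int(n) for c, n in
            fits.groupby("condition").size().items()},
        "gp_preferred_fraction": float((fits["preferred"] == "GP").mean()),
        "pooled_label_ratios": pooled,
        "unclassified_fraction": float(
            (table["label"] == cls.UNCLASSIFIED).mean()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; aborts naming the failing stage."""
    stages = [("filter", stage_filter), ("cluster", stage_cluster),
              ("fit", stage_fit), ("classify", stage_classify),
              ("report", stage_report)]
    result = None
    for name, fn in stages:
        try:
            result = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return result
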