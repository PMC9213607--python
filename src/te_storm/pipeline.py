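"""End-to-end orchestration: simulate -> assign -> normalize -> DE ->
enrichment -> chromatin -> classifier, with a consolidated run report.

The pipeline is driven by a flat, schema-checked configuration (YAML on
disk); unknown keys are rejected.  One master seed is carried in the
configuration and every stochastic stage derives its stream from it by a
fixed label, so a rerun of the same configuration reproduces the report
(timestamps aside).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as teio
from .assignment import assign_transcripts, collapse_to_loci, records_from_frame
from .chromatin import (
    DEFAULT_ACTIVE_STATES,
    active_fraction,
    cross_tissue_consistency,
    overlap_states,
    state_enrichment,
)
from .de import age_association, pca_qc, run_de
from .enrichment import (
    cis_genes,
    class_enrichment,
    fold_change_correlation,
    intersection_test,
)
from .errors import ConfigurationError, TEStormError
from .ml import boruta_select, entropy_prefilter, train_evaluate
from .normalize import ExpressionMatrix, logcpm, tmm_factors
from .simulate import SimulationConfig, write_dataset

log = logging.getLogger("te_storm")


@dataclass
class PipelineConfig:
    """Flat run configuration; every CLI flag has a twin here."""

    outdir: str = "te_storm_run"
    seed: int = 0
    simulate: bool = True
    data_dir: str = ""          # input directory when simulate is False
    # synthetic-data scale
    n_loci: int = 300
    n_subjects_conv: int = 12
    n_controls: int = 20
    de_fraction: float = 0.1
    frac_shared: float = 0.65
    planted_lfc: float = 2.0
    dispersion: float = 0.1
    subject_sd: float = 0.7
    frac_multimap: float = 0.2
    frac_lowid: float = 0.1
    frac_lowcov: float = 0.05
    n_tissues: int = 3
    # stage toggles
    stage_assign: bool = True
    stage_de: bool = True
    stage_enrichment: bool = True
    stage_chromatin: bool = True
    stage_ml: bool = True
    # assignment
    min_identity: float = 95.0
    min_coverage: float = 0.90
    # normalization / DE
    min_cpm: float = 1.0
    min_samples: int = 2
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_df: float = 10.0
    p_max: float = 0.01
    lfc_min: float = 1.5
    contrasts: tuple[str, ...] = ("pre_vs_post", "pre_vs_nc")
    # enrichment / annotation
    cis_window: int = 5000
    # ml
    top_k: int = 10_000
    boruta_p: float = 0.05
    n_tree: int = 500
    max_runs: int = 50
    train_frac: float = 0.70
    cv_folds: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if "contrasts" in d:
            d = dict(d, contrasts=tuple(d["contrasts"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["contrasts"] = list(d["contrasts"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_loci=self.n_loci, n_subjects_conv=self.n_subjects_conv,
            n_controls=self.n_controls, de_fraction=self.de_fraction,
            frac_shared=self.frac_shared, planted_lfc=self.planted_lfc,
            dispersion=self.dispersion, subject_sd=self.subject_sd,
            frac_multimap=self.frac_multimap, frac_lowid=self.frac_lowid,
            frac_lowcov=self.frac_lowcov, n_tissues=self.n_tissues,
            seed=self.seed,
        )


def make_demo(outdir: str | Path, seed: int = 0) -> PipelineConfig:
    """Write a small synthetic dataset plus a matching pipeline config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(outdir=str(outdir), seed=seed,
                            data_dir=str(outdir / "data"))
    write_dataset(config.simulation_config(), outdir / "data")
    config.to_yaml(outdir / "config.yaml")
    return config


def _load_inputs(config: PipelineConfig) -> dict:
    data_dir = Path(config.data_dir or Path(config.outdir) / "data")
    if config.simulate and not (data_dir / "metadata.tsv").exists():
        log.info("simulate: writing synthetic dataset to %s", data_dir)
        write_dataset(config.simulation_config(), data_dir)
    required = ["alignments.tsv", "transcript_counts.tsv", "metadata.tsv",
                "te_loci.bed", "genes.bed"]
    for name in required:
        if not (data_dir / name).exists():
            raise TEStormError(f"missing input {data_dir / name}")
    inputs = {
        "data_dir": data_dir,
        "alignments": teio.read_blast_tabular(data_dir / "alignments.tsv"),
        "transcript_counts": pd.read_csv(
            data_dir / "transcript_counts.tsv", sep="\t", index_col=0),
        "meta": teio.read_metadata(data_dir / "metadata.tsv"),
        "te_bed": teio.read_bed6(data_dir / "te_loci.bed"),
        "genes": teio.read_bed6(data_dir / "genes.bed"),
        "tracks": {},
    }
    trackdir = data_dir / "tracks"
    if trackdir.is_dir():
        for p in sorted(trackdir.glob("*.bed")):
            inputs["tracks"][p.stem] = teio.read_bed4(p)
    gt = data_dir / "ground_truth.json"
    inputs["ground_truth"] = teio.read_json(gt) if gt.exists() else None
    return inputs


def _loci_from_bed(bed: pd.DataFrame):
    from .assignment import TELocus

    out = []
    for row in bed.itertuples(index=False):
        out.append(TELocus(
            locus_id=str(row.name), chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), strand=str(row.strand), family="",
            te_class="Other", consensus_len=int(row.end) - int(row.start),
        ))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the run report.

    Stage order: assign -> normalize -> DE per contrast -> enrichment and
    intersection -> chromatin states -> classifier.  Intermediate tables
    are written under ``outdir``; a failure stops the run with the stage
    named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    inputs = _load_inputs(config)
    meta = inputs["meta"]
    te_bed = inputs["te_bed"]
    class_by_locus = _class_lookup(inputs)

    # --- assignment ---------------------------------------------------
    stage = "assign"
    log.info("stage %s: %d alignment records", stage,
             len(inputs["alignments"]))
    records = records_from_frame(inputs["alignments"])
    table = assign_transcripts(records, config.min_identity, config.min_coverage)
    locus_counts = collapse_to_loci(table, inputs["transcript_counts"])
    table.to_frame().to_csv(outdir / "assignment.tsv", sep="\t", index=False)
    teio.write_counts(locus_counts, outdir / "locus_counts.tsv")
    reasons = pd.Series([r for _, r in table.discarded])
    report["stages"][stage] = {
        "transcripts_in": int(inputs["transcript_counts"].shape[0]),
        "assigned": len(table.assigned),
        "discarded": len(table.discarded),
        "discarded_by_reason": reasons.value_counts().to_dict() if len(reasons) else {},
        "loci_with_counts": int(locus_counts.shape[0]),
    }

    em = ExpressionMatrix(counts=locus_counts, meta=meta)

    # --- normalization (whole-matrix view for features/QC) ------------
    norm_all = tmm_factors(em.counts, config.trim_m, config.trim_a)
    lc_all = logcpm(em.counts, norm_all)
    norm_all.factors.rename("factor").to_csv(
        outdir / "tmm_factors.tsv", sep="\t", header=True)
    report["stages"]["normalize"] = {
        "reference_sample": norm_all.reference_sample,
        "factor_range": [float(norm_all.factors.min()),
                         float(norm_all.factors.max())],
    }

    de_runs: dict[str, dict] = {}
    if config.stage_de:
        for contrast in config.contrasts:
            stage = f"de_{contrast}"
            log.info("stage %s", stage)
            run = run_de(
                em, contrast, min_cpm=config.min_cpm,
                min_samples=config.min_samples, prior_df=config.prior_df,
                p_max=config.p_max, lfc_min=config.lfc_min,
            )
            de_runs[contrast] = run
            run["results"].to_csv(outdir / f"de_{contrast}.tsv", sep="\t",
                                  index_label="locus_id")
            report["stages"][stage] = {
                "tested_loci": int(len(run["results"])),
                "up": len(run["up"]), "down": len(run["down"]),
                "common_dispersion": run["dispersion"].common,
                "n_converged": run["n_converged"],
            }

    # --- enrichment / intersection ------------------------------------
    if config.stage_enrichment and len(de_runs) >= 1:
        stage = "enrichment"
        log.info("stage %s", stage)
        enr: dict = {}
        for contrast, run in de_runs.items():
            background = set(run["results"].index)
            for direction, de_set in (("up", run["up"]), ("down", run["down"])):
                tab = class_enrichment(de_set, background, class_by_locus)
                tab.to_csv(outdir / f"enrichment_{contrast}_{direction}.tsv",
                           sep="\t", index=False)
                enr[f"{contrast}_{direction}"] = {
                    "significant": tab[tab["significant"]]["label"].tolist(),
                    "n_de": len(de_set),
                }
        if len(de_runs) >= 2:
            c1, c2 = list(de_runs)[:2]
            r1, r2 = de_runs[c1], de_runs[c2]
            universe = set(r1["results"].index) & set(r2["results"].index)
            s1 = (r1["up"] | r1["down"]) & universe
            s2 = (r2["up"] | r2["down"]) & universe
            inter = intersection_test(
                s1, s2, universe,
                directions1=r1["results"]["direction"].to_dict(),
                directions2=r2["results"]["direction"].to_dict(),
            )
            corr = fold_change_correlation(r1["results"], r2["results"])
            enr["intersection"] = {
                "overlap": inter["overlap"], "p": inter["p"],
                "expected": inter["expected"],
                "direction_concordance": inter["direction_concordance"],
                "shared_ids": inter["overlap_ids"],
            }
            enr["logfc_correlation"] = corr
        loci = _loci_from_bed(te_bed)
        de_all = set().union(*[r["up"] | r["down"] for r in de_runs.values()]) \
            if de_runs else set()
        de_loci = [l for l in loci if l.locus_id in de_all]
        cis = cis_genes(de_loci, inputs["genes"], config.cis_window)
        cis.to_csv(outdir / "cis_genes.tsv", sep="\t", index=False)
        enr["cis_genes"] = {"n_pairs": int(len(cis)),
                            "n_loci_with_gene": int(cis["locus_id"].nunique())}
        report["stages"][stage] = enr

    # --- chromatin states ---------------------------------------------
    if config.stage_chromatin and inputs["tracks"]:
        stage = "chromatin"
        log.info("stage %s", stage)
        loci = _loci_from_bed(te_bed)
        assignment = overlap_states(loci, inputs["tracks"])
        assignment.labels.to_csv(outdir / "chromatin_labels.tsv", sep="\t")
        assignment.breakdown.to_csv(outdir / "chromatin_bp.tsv", sep="\t",
                                    index=False)
        chrom: dict = {"active_states": sorted(DEFAULT_ACTIVE_STATES)}
        tissue = ("blood" if "blood" in inputs["tracks"]
                  else sorted(inputs["tracks"])[0])
        for contrast, run in de_runs.items():
            for direction, de_set in (("up", run["up"]), ("down", run["down"])):
                ids = [i for i in de_set if i in assignment.labels.index]
                if not ids:
                    continue
                frac = active_fraction(assignment, ids, tissue)
                chrom[f"active_{contrast}_{direction}_{tissue}"] = frac
            background = [i for i in run["results"].index
                          if i in assignment.labels.index]
            up_ids = [i for i in run["up"] if i in assignment.labels.index]
            if up_ids:
                st = state_enrichment(assignment, up_ids, background, tissue)
                st.to_csv(outdir / f"state_enrichment_{contrast}.tsv",
                          sep="\t", index=False)
                chrom[f"state_enrichment_{contrast}"] = \
                    st[st["significant"]]["state"].tolist()
        cons = cross_tissue_consistency(assignment)
        chrom["mean_cross_tissue_agreement"] = float(
            cons["per_locus_agreement"].mean())
        report["stages"][stage] = chrom

    # --- classifier -----------------------------------------------------
    if config.stage_ml:
        stage = "ml"
        log.info("stage %s", stage)
        ml_report: dict = {}
        features_all = lc_all.T  # samples x loci
        for contrast in config.contrasts:
            first, second = _contrast_conditions(contrast)
            sub = meta[meta["group"].isin([first, second])]
            Xc = features_all.loc[sub["sample_id"].tolist()]
            yc = sub.set_index("sample_id")["group"].loc[Xc.index]
            retained = entropy_prefilter(Xc.T, top_k=config.top_k)
            bres = boruta_select(
                Xc[retained], yc, p_value=config.boruta_p,
                n_tree=config.n_tree, max_runs=config.max_runs,
                seed=config.seed,
            )
            selected = bres.confirmed or bres.tentative
            if not selected:
                ml_report[contrast] = {"selected": 0, "auc": float("nan")}
                continue
            rep = train_evaluate(
                Xc, yc, selected, meta=sub, train_frac=config.train_frac,
                cv_folds=config.cv_folds, n_tree=config.n_tree,
                seed=config.seed,
            )
            rep.roc.to_csv(outdir / f"roc_{contrast}.csv", index=False)
            _selected_feature_table(
                selected, te_bed, inputs["genes"], config.cis_window
            ).to_csv(outdir / f"ml_features_{contrast}.tsv", sep="\t", index=False)
            ml_report[contrast] = {
                "entropy_retained": len(retained),
                "boruta_confirmed": len(bres.confirmed),
                "boruta_rejected": len(bres.rejected),
                "boruta_tentative": len(bres.tentative),
                "selected": len(selected),
                **rep.summary(),
            }
        # PCA QC on the union of DE loci, plus the age-null check in NC
        de_all = sorted(set().union(
            *[r["up"] | r["down"] for r in de_runs.values()])) if de_runs else []
        if len(de_all) >= 2:
            qc = pca_qc(lc_all.loc[de_all],
                        meta.set_index("sample_id")["group"])
            ml_report["pca_qc"] = {
                "separation": qc["separation"],
                "explained_variance_ratio":
                    [float(v) for v in qc["explained_variance_ratio"]],
            }
            nc_samples = meta.loc[meta["group"] == "NC", "sample_id"]
            if len(nc_samples) >= 5:
                qc_nc = pca_qc(lc_all.loc[de_all, nc_samples],
                               meta.set_index("sample_id")["group"])
                ages = meta.set_index("sample_id").loc[nc_samples, "age"]
                aa = age_association(qc_nc["scores"], ages)
                ml_report["age_null_check"] = {
                    row["component"]: float(row["p"]) for _, row in aa.iterrows()
                }
        report["stages"][stage] = ml_report

    _check_report_consistency(report)
    teio.write_json(report, outdir / "report.json")
    (outdir / "report.md").write_text(_render_markdown(report))
    return report


def _contrast_conditions(contrast: str) -> tuple[str, str]:
    from .de import CONTRAST_CONDITIONS

    return CONTRAST_CONDITIONS[contrast]


def _class_lookup(inputs) -> dict[str, str]:
    gt_path = inputs["data_dir"] / "te_loci.tsv"
    if gt_path.exists():
        tab = pd.read_csv(gt_path, sep="\t")
        return dict(zip(tab["locus_id"].astype(str), tab["class"]))
    return {}


def _selected_feature_table(selected, te_bed, genes, window) -> pd.DataFrame:
    """Mirror of the reported biomarker tables: Chr, Start, End, TE, Gene."""
    bed = te_bed.set_index(te_bed["name"].astype(str))
    loci = _loci_from_bed(bed.loc[[s for s in selected if s in bed.index]])
    cis = cis_genes(loci, genes, window)
    gene_by_locus = cis.groupby("locus_id")["gene_id"].apply(
        lambda g: ",".join(sorted(set(g))))
    rows = []
    for s in selected:
        if s not in bed.index:
            continue
        row = bed.loc[s]
        rows.append({
            "Chr": row["chrom"], "Start": int(row["start"]),
            "End": int(row["end"]), "TE": s,
            "Gene": gene_by_locus.get(s, "NA"),
        })
    return pd.DataFrame(rows, columns=["Chr", "Start", "End", "TE", "Gene"])


def _check_report_consistency(report: dict) -> None:
    st = report["stages"]
    if "assign" in st:
        a = st["assign"]
        if a["assigned"] + a["discarded"] != a["transcripts_in"]:
            raise TEStormError("report inconsistency: assigned + discarded "
                               "!= transcripts_in")
    for key, val in st.items():
        if key.startswith("de_"):
            if val["up"] + val["down"] > val["tested_loci"]:
                raise TEStormError(f"report inconsistency in {key}")


def _render_markdown(report: dict) -> str:
    lines = [f"# te-storm run report", "",
             f"- version: {report['version']}",
             f"- master seed: {report['seed']}", ""]
    for stage, content in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```")
        lines.append(yaml.safe_dump(_plain(content), sort_keys=True).rstrip())
        lines.append("```")
        lines.append("")
    return "\n".join(lines)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_plain(v) for v in sorted(obj, key=str)] \
            if isinstance(obj, set) else [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
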