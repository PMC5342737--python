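"""End-to-end orchestration: synthesize or load inputs, normalize, test,
tier, project, enrich and cluster, writing every artifact under an output
directory together with a manifest sufficient to reproduce the run."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import (
    ConcordantGeneLists,
    PloidyContrast,
    build_tiered_lists,
    quantile_normalize,
)
from .enrichment import binomial_enrichment, double_background_ora, group_summary
from .errors import ConfigError, DesignError, PloidysigError
from .io import (
    ExpressionMatrix,
    SampleSheet,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gene_sets,
    read_orthologs,
    read_sample_sheet,
    write_edge_list,
    write_expression,
    write_gene_list,
    write_gene_sets,
    write_orthologs,
    write_sample_sheet,
)
from .network import build_graph, mcl_cluster, network_summary, write_clusters
from .pca import PloidyPCA
from .simulate import (
    SynthConfig,
    generate_annotations,
    generate_cross_species_dataset,
    generate_two_condition_dataset,
)

logger = logging.getLogger(__name__)

_DE_DEFAULTS = {"p_threshold": 0.01, "change_threshold": 0.15, "require_p": True}
_PCA_DEFAULTS = {"sd_threshold": 2.0}
_ENRICH_DEFAULTS = {"p_gate": 0.01, "q_gate": 0.15, "p0_override": None}
_NETWORK_DEFAULTS = {"stringency": 0.9, "inflation": 2.0}
_INPUT_KEYS = {
    "expression", "sample_sheet", "orthologs", "decidua_expression",
    "decidua_sheet", "gene_sets", "edges", "interactome",
}
_TOP_KEYS = {"synthetic", "inputs", "de", "pca", "enrichment", "network",
             "output_dir", "seed", "log_level"}


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    synthetic: dict | None = None
    inputs: dict | None = None
    de: dict = field(default_factory=lambda: dict(_DE_DEFAULTS))
    pca: dict = field(default_factory=lambda: dict(_PCA_DEFAULTS))
    enrichment: dict = field(default_factory=lambda: dict(_ENRICH_DEFAULTS))
    network: dict = field(default_factory=lambda: dict(_NETWORK_DEFAULTS))

    def echo(self) -> dict:
        return asdict(self)


def _merge_section(user: dict | None, defaults: dict, name: str,
                   errors: list) -> dict:
    out = dict(defaults)
    if user is None:
        return out
    if not isinstance(user, dict):
        errors.append(f"section {name!r} must be a mapping")
        return out
    for key, value in user.items():
        if key not in defaults:
            errors.append(f"unknown key {name}.{key}")
        else:
            out[key] = value
    return out


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML path or a dict, collecting every
    error before raising a single ConfigError."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown key {key}")

    if "output_dir" not in raw:
        errors.append("output_dir is required")
    synthetic = raw.get("synthetic")
    inputs = raw.get("inputs")
    if (synthetic is None) == (inputs is None):
        errors.append("exactly one of 'synthetic' or 'inputs' must be present")
    if inputs is not None:
        if not isinstance(inputs, dict):
            errors.append("section 'inputs' must be a mapping")
        else:
            for key in sorted(set(inputs) - _INPUT_KEYS):
                errors.append(f"unknown key inputs.{key}")
            for key in ("expression", "sample_sheet"):
                if key not in inputs:
                    errors.append(f"inputs.{key} is required")
    if synthetic is not None:
        try:
            SynthConfig.from_dict(dict(synthetic))
        except (ConfigError, TypeError) as exc:
            errors.append(f"synthetic: {exc}")

    de = _merge_section(raw.get("de"), _DE_DEFAULTS, "de", errors)
    pca = _merge_section(raw.get("pca"), _PCA_DEFAULTS, "pca", errors)
    enr = _merge_section(raw.get("enrichment"), _ENRICH_DEFAULTS, "enrichment",
                         errors)
    net = _merge_section(raw.get("network"), _NETWORK_DEFAULTS, "network", errors)

    if not 0 < de["p_threshold"] <= 1:
        errors.append("de.p_threshold must be in (0, 1]")
    if de["change_threshold"] < 0:
        errors.append("de.change_threshold must be >= 0")
    if pca["sd_threshold"] <= 0:
        errors.append("pca.sd_threshold must be > 0")
    if not 0 < enr["p_gate"] <= 1:
        errors.append("enrichment.p_gate must be in (0, 1]")
    if not 0 < enr["q_gate"] <= 1:
        errors.append("enrichment.q_gate must be in (0, 1]")
    if enr["p0_override"] is not None and not 0 < enr["p0_override"] < 1:
        errors.append("enrichment.p0_override must be in (0, 1)")
    if not 0 <= net["stringency"] < 1:
        errors.append("network.stringency must be in [0, 1)")
    if net["inflation"] <= 1:
        errors.append("network.inflation must be > 1")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")

    if errors:
        raise ConfigError("; ".join(errors))
    return PipelineConfig(
        output_dir=str(raw["output_dir"]), seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        synthetic=dict(synthetic) if synthetic is not None else None,
        inputs=dict(inputs) if inputs is not None else None,
        de=de, pca=pca, enrichment=enr, network=net,
    )


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def ploidy_contrasts(sheet: SampleSheet) -> dict:
    """tissue -> (polyploid condition, diploid condition) pairs derivable from
    the sheet."""
    by_tissue: dict = {}
    for cond in sheet.conditions():
        meta = sheet.condition_meta(cond)
        by_tissue.setdefault(meta["tissue"], {})[meta["ploidy_class"]] = cond
    out = {}
    for tissue, classes in by_tissue.items():
        if "polyploid" in classes and "diploid" in classes:
            out[tissue] = (classes["polyploid"], classes["diploid"])
    return out


def summarize_gene_panel(matrix: ExpressionMatrix, sheet: SampleSheet,
                         gene_ids) -> tuple[pd.DataFrame, list]:
    """Per-gene mean polyploid-minus-diploid difference with standard error
    across the sheet's comparisons, starred at p<0.01 (*) and p<0.0001 (**).

    Unknown gene ids are returned in a skipped list, not fatal.  The star uses
    the largest per-comparison p-value, i.e. every comparison must clear the
    level.
    """
    contrasts = ploidy_contrasts(sheet)
    if not contrasts:
        raise DesignError("sample sheet defines no polyploid/diploid contrast")
    tables = {
        tissue: PloidyContrast(matrix, sheet, poly, dip).fit().table
        for tissue, (poly, dip) in contrasts.items()
    }
    known = [g for g in gene_ids if g in matrix.data.index]
    skipped = [g for g in gene_ids if g not in matrix.data.index]
    rows = []
    for gene in known:
        deltas = np.array([t.loc[gene, "delta"] for t in tables.values()])
        pmax = max(t.loc[gene, "p"] for t in tables.values())
        se = (deltas.std(ddof=1) / np.sqrt(len(deltas))
              if len(deltas) > 1 else np.nan)
        stars = "**" if pmax < 1e-4 else ("*" if pmax < 0.01 else "")
        rows.append((gene, deltas.mean(), se, len(deltas), pmax, stars))
    panel = pd.DataFrame(
        rows, columns=["gene", "mean_delta", "se", "n_comparisons",
                       "max_p", "stars"]
    ).set_index("gene")
    return panel, skipped


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """Everything a run produced, plus the manifest that reproduces it."""

    config: PipelineConfig
    tiers: ConcordantGeneLists
    de_tables: dict
    pca_results: dict
    selections: dict          # list name -> frozenset of group ids
    binomial: dict            # list name -> BinomialEnrichment
    ora_records: dict         # list name -> list of EnrichmentRecord
    group_summaries: dict
    network: object | None
    manifest: dict
    output_dir: Path


def _write_tiers(tiers: ConcordantGeneLists, outdir: Path) -> None:
    for name, genes in tiers.as_dict().items():
        write_gene_list(genes, outdir / f"{name}.txt")


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "term": r.term_id, "background": r.background_id, "k": r.k,
            "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q,
            "significant": r.significant, "description": r.description,
        }
        for r in records
    ])


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle under output_dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    warnings_log: list[str] = []
    counts: dict = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # -- inputs ------------------------------------------------------------
    stage("inputs")
    decidua = None
    if config.synthetic is not None:
        synth = dict(config.synthetic)
        synth.setdefault("seed", config.seed)
        scfg = SynthConfig.from_dict(synth)
        matrix, sheet, orthologs, truth = generate_cross_species_dataset(scfg)
        d_matrix, d_sheet, d_truth = generate_two_condition_dataset(scfg)
        gene_sets, edges, truth = generate_annotations(scfg, truth)
        interactome = set(truth.interactome)
        decidua = (d_matrix, d_sheet)
        idir = outdir / "inputs"
        idir.mkdir(exist_ok=True)
        write_expression(matrix, idir / "expression.tsv")
        write_sample_sheet(sheet, idir / "sample_sheet.tsv")
        write_orthologs(orthologs, idir / "orthologs.tsv")
        write_expression(d_matrix, idir / "decidua_expression.tsv")
        write_sample_sheet(d_sheet, idir / "decidua_sheet.tsv")
        write_gene_sets(gene_sets, idir / "gene_sets.gmt")
        write_edge_list(edges, idir / "edges.tsv")
        write_gene_list(interactome, idir / "interactome.txt")
        with open(idir / "truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        logger.info("synthetic inputs written to %s", idir)
    else:
        paths = config.inputs
        matrix = read_expression(paths["expression"])
        sheet = read_sample_sheet(paths["sample_sheet"])
        orthologs = (read_orthologs(paths["orthologs"])
                     if "orthologs" in paths else None)
        if "decidua_expression" in paths:
            decidua = (read_expression(paths["decidua_expression"]),
                       read_sample_sheet(paths["decidua_sheet"]))
        gene_sets = (read_gene_sets(paths["gene_sets"])
                     if "gene_sets" in paths else None)
        edges = (read_edge_list(paths["edges"]) if "edges" in paths else None)
        interactome = (read_gene_list(paths["interactome"])
                       if "interactome" in paths else None)
        truth = None
    sheet.validate_against(matrix)
    done("inputs")

    # -- normalization and per-comparison DE --------------------------------
    stage("de")
    norm = quantile_normalize(matrix)
    contrasts = ploidy_contrasts(sheet)
    de_tables = {}
    for tissue, (poly, dip) in sorted(contrasts.items()):
        res = PloidyContrast(norm, sheet, poly, dip).fit()
        de_tables[tissue] = res.table
        res.table.to_csv(outdir / f"de_{tissue}.tsv", sep="\t",
                         float_format="%.6g")
    decidua_de = None
    if decidua is not None:
        d_norm = quantile_normalize(decidua[0])
        d_contrasts = ploidy_contrasts(decidua[1])
        for tissue, (poly, dip) in sorted(d_contrasts.items()):
            res = PloidyContrast(d_norm, decidua[1], poly, dip).fit()
            decidua_de = res.table
            de_tables[f"decidua:{tissue}"] = res.table
            res.table.to_csv(outdir / f"de_decidua_{tissue}.tsv", sep="\t",
                             float_format="%.6g")
    done("de")

    # -- tiered lists --------------------------------------------------------
    stage("tiers")
    tissue_names = sorted(contrasts)
    if len(tissue_names) < 2:
        raise DesignError(
            "reciprocal design needs two tissues with opposite ploidy classes"
        )
    tiers = build_tiered_lists(
        de_tables[tissue_names[0]], de_tables[tissue_names[1]], decidua_de,
        orthologs,
        p_threshold=config.de["p_threshold"],
        change_threshold=config.de["change_threshold"],
        require_p=config.de["require_p"],
    )
    _write_tiers(tiers, outdir)
    counts.update({k: len(v) for k, v in tiers.as_dict().items()})
    done("tiers")

    # -- PCA -----------------------------------------------------------------
    stage("pca")
    pca_results = {}
    selections: dict = {}
    sd_thr = config.pca["sd_threshold"]
    b2g = orthologs.b_to_group() if orthologs is not None else {}

    def run_pca(tag, mat, sht, id_map=None):
        try:
            res = PloidyPCA(mat, sht).fit()
        except DesignError as exc:
            warnings_log.append(f"pca[{tag}]: {exc}; selection empty")
            selections[f"pca_{tag}_induced"] = frozenset()
            selections[f"pca_{tag}_suppressed"] = frozenset()
            return
        pca_results[tag] = res
        res.loadings.to_csv(outdir / f"pca_{tag}_loadings.tsv", sep="\t",
                            float_format="%.6g")
        res.scores.to_csv(outdir / f"pca_{tag}_scores.tsv", sep="\t",
                          float_format="%.6g")
        with open(outdir / f"pca_{tag}_report.txt", "w") as fh:
            fh.write(res.summary() + "\n")
        try:
            induced, suppressed = res.select_by_score("ploidy", sd_thr)
        except DesignError as exc:
            warnings_log.append(f"pca[{tag}]: {exc}; selection empty")
            induced, suppressed = frozenset(), frozenset()
        if id_map:
            induced = frozenset(id_map[g] for g in induced if g in id_map)
            suppressed = frozenset(id_map[g] for g in suppressed if g in id_map)
        selections[f"pca_{tag}_induced"] = induced
        selections[f"pca_{tag}_suppressed"] = suppressed
        write_gene_list(induced, outdir / f"pca_{tag}_induced.txt")
        write_gene_list(suppressed, outdir / f"pca_{tag}_suppressed.txt")

    run_pca("cross", norm, sheet)
    if decidua is not None:
        run_pca("decidua", quantile_normalize(decidua[0]), decidua[1],
                id_map=b2g or None)
    counts.update({k: len(v) for k, v in selections.items()})
    done("pca")

    # -- enrichment ----------------------------------------------------------
    stage("enrichment")
    gene_lists: dict = {
        "tier_A_up": tiers.tier_A_up, "tier_A_down": tiers.tier_A_down,
        "tier_B_up": tiers.tier_B_up, "tier_B_down": tiers.tier_B_down,
    }
    if b2g:
        gene_lists["tier_C_up"] = frozenset(
            b2g[g] for g in tiers.tier_C_up if g in b2g)
        gene_lists["tier_C_down"] = frozenset(
            b2g[g] for g in tiers.tier_C_down if g in b2g)
    gene_lists.update(selections)

    binomial_results: dict = {}
    ora_records: dict = {}
    summaries: dict = {}
    universe = (set(orthologs.group_ids) if orthologs is not None
                else set(matrix.gene_ids))
    if interactome is not None:
        p0 = config.enrichment["p0_override"]
        for name, genes in sorted(gene_lists.items()):
            if not genes:
                warnings_log.append(f"enrichment[{name}]: empty list, skipped")
                continue
            binomial_results[name] = binomial_enrichment(
                genes, interactome, universe, p0=p0)
        if gene_sets is not None:
            for name, genes in sorted(gene_lists.items()):
                if not genes:
                    continue
                recs = double_background_ora(
                    genes, gene_sets, universe, set(interactome) & universe,
                    p_gate=config.enrichment["p_gate"],
                    q_gate=config.enrichment["q_gate"],
                )
                ora_records[name] = recs
                _records_frame(recs).to_csv(
                    outdir / f"ora_{name}.tsv", sep="\t", index=False,
                    float_format="%.6g")
                groups = {r.term_id: r.description for r in recs}
                summaries[name] = {
                    f"{g}|{b}": v
                    for (g, b), v in group_summary(recs, groups).items()
                }
    with open(outdir / "binomial.json", "w") as fh:
        json.dump({k: asdict(v) for k, v in binomial_results.items()}, fh,
                  indent=1, sort_keys=True)
    done("enrichment")

    # -- network -------------------------------------------------------------
    stage("network")
    net = None
    if edges is not None:
        union = frozenset().union(*gene_lists.values()) if gene_lists else frozenset()
        net = build_graph(edges, union, stringency=config.network["stringency"])
        mcl_cluster(net, inflation=config.network["inflation"])
        if not net.converged:
            warnings_log.append("network: MCL did not converge")
        write_clusters(net, outdir / "clusters.tsv")
        with open(outdir / "network_summary.json", "w") as fh:
            json.dump(network_summary(net), fh, indent=1)
    done("network")

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.echo(),
        "counts": counts,
        "warnings": warnings_log,
        "timings_s": timings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ReportBundle(
        config=config, tiers=tiers, de_tables=de_tables,
        pca_results=pca_results, selections=selections,
        binomial=binomial_results, ora_records=ora_records,
        group_summaries=summaries, network=net, manifest=manifest,
        output_dir=outdir,
    )
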