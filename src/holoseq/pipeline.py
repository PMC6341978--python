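"""End-to-end orchestration on synthetic or user-supplied inputs.

``run_pipeline`` wires the stages together at desk scale: simulate a
holobiont (transcripts, ITS2 reads, counts, genotypes, annotations),
partition host vs symbiont, type the symbiont community per sample,
run differential expression and coexpression analysis, estimate F_ST
from the genotypes, and test GO-term overrepresentation — writing one
TSV per stage plus a JSON run manifest that records the seed and every
threshold actually applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, dge, enrichment, network, partition, popgen, simulate, symbiont
from .io import write_fasta, write_table

DEFAULT_THRESHOLDS = {
    "gc_cutoff": 0.47,
    "marker_e_cutoff": 1e-3,
    "mixed_threshold": 0.25,
    "fpkm_sum_min": 0.5,
    "min_count": 1,
    "min_count_samples": 3,
    "fpkm_min": 1.0,
    "fpkm_min_samples": 3,
    "alpha": 0.05,
    "maf_min": 0.1,
    "call_rate_min": 0.95,
    "depth_min": 20,
    "n_bootstrap": 1000,
    "enrich_min_fraction": 0.02,
}


@dataclass
class ReportBundle:
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def deg_percentage(n_degs: int, n_transcripts: int) -> str:
    """Headline line: DEG count as a percentage of host transcripts."""
    pct = 100.0 * n_degs / n_transcripts
    return f"{n_degs} of {n_transcripts} ({pct:.1f}%)"


def study_association_tests(metadata: pd.DataFrame | None = None,
                            yates: bool = False) -> pd.DataFrame:
    """Colony-level clade association chi-square tests on the study design."""
    md = metadata if metadata is not None else datasets.load_study_design()
    tables = datasets.contingency_tables(md)
    rows = []
    for name, tbl in tables.items():
        t = popgen.chi2_association(tbl, yates=yates)
        rows.append((name, tbl[0][0], tbl[0][1], tbl[1][0], tbl[1][1],
                     round(t.statistic, 2), round(t.p, 2)))
    return pd.DataFrame(rows, columns=["contrast", "n11", "n12", "n21", "n22",
                                       "chi2", "p"])


def run_pipeline(sim_config: simulate.SimulationConfig,
                 outdir: str | Path | None = None,
                 thresholds: dict | None = None,
                 its2_mixtures=(0.0, 0.12, 0.33, 0.67, 0.91, 1.0),
                 n_its2_reads: int = 2000) -> ReportBundle:
    """Run every stage on one synthetic holobiont.

    Stage failures raise with a stage-tagged message; outputs written
    before the failure are retained.  Identical configs produce
    identical bundles.
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    out = ReportBundle()
    out.manifest = {"seed": sim_config.seed, "thresholds": th,
                    "stages": []}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def emit(name: str, df: pd.DataFrame, index=False):
        out.tables[name] = df
        if outdir is not None:
            write_table(df, outdir / f"{name}.tsv", index=index)
        out.manifest["stages"].append(name)

    # --- partition --------------------------------------------------------
    try:
        transcripts, evidence, truth_t = simulate.gen_meta_transcriptome(sim_config)
        calls = partition.classify_transcripts(transcripts, evidence,
                                               gc_cutoff=th["gc_cutoff"])
        calls["true_origin"] = calls["transcript_id"].map(truth_t.transcript_origin)
        emit("partition_calls", calls)
        host_ids = set(calls.loc[calls["label"] == "host", "transcript_id"])
        out.summary["partition_accuracy"] = partition.partition_accuracy(
            calls, truth_t.transcript_origin)
        if outdir is not None:
            write_fasta([t for t in transcripts if t.id in host_ids],
                        outdir / "host_transcripts.fasta")
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[partition] {e}") from e

    # --- symbiont typing --------------------------------------------------
    try:
        its2_cfg = simulate.SimulationConfig(
            seed=sim_config.seed, n_samples=len(its2_mixtures),
            clade_mixtures=tuple(its2_mixtures), n_its2_reads=n_its2_reads,
            error_rate=sim_config.error_rate)
        ref_c, ref_d = simulate.gen_its2_references(its2_cfg)
        reads, truth_m = simulate.gen_its2_reads(its2_cfg, ref_c, ref_d)
        refs = [symbiont.Its2Reference("C31_ref", "C", "C31", ref_c),
                symbiont.Its2Reference("D1a_ref", "D", "D1a", ref_d)]
        rows = []
        for sample, pair_list in reads.items():
            comp = symbiont.type_sample(pair_list, refs, sample,
                                        th["mixed_threshold"])
            rows.append((sample,
                         comp.proportions.get("C", np.nan),
                         comp.proportions.get("D", np.nan),
                         comp.dominant_clade, comp.mixed_outlier,
                         truth_m.true_mixtures[sample]))
        comp_df = pd.DataFrame(rows, columns=[
            "sample_id", "prop_C", "prop_D", "dominant_clade",
            "mixed_outlier", "true_prop_D"])
        emit("clade_composition", comp_df)
        out.summary["max_mixture_error"] = float(
            (comp_df["prop_D"] - comp_df["true_prop_D"]).abs().max())
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[type-symbiont] {e}") from e

    # --- differential expression -----------------------------------------
    try:
        design = simulate.default_design(sim_config)
        counts, fpkm, truth_c = simulate.gen_counts(sim_config, design)
        kept = dge.filter_min_count(counts, th["min_count"],
                                    th["min_count_samples"])
        counts_f = counts.loc[kept]
        factors = dge.tmm_factors(counts_f)
        deg_sets = {}
        for contrast_name in ("site", "clade"):
            lvl = sorted(design[contrast_name].unique())
            ind = (design[contrast_name] == lvl[-1]).astype(float).to_numpy()
            X = np.column_stack([np.ones(len(design)), ind])
            y, w = dge.voom_weights(counts_f, X, factors)
            fit = dge.fit_and_moderate(y, w, X, [0.0, 1.0])
            up, down = dge.call_degs(fit, th["alpha"])
            deg_sets[contrast_name] = up | down
            tbl = pd.DataFrame({
                "gene_id": fit.coefficients.index,
                "logFC": fit.coefficients.values,
                "t": fit.t.values, "p": fit.p.values, "fdr": fit.fdr.values})
            emit(f"dge_{contrast_name}", tbl)
            out.summary[f"degs_{contrast_name}"] = deg_percentage(
                len(up | down), len(counts_f))
        overlaps = dge.set_overlap(deg_sets)
        emit("deg_overlap", pd.DataFrame(
            [("+".join(k), v) for k, v in overlaps.items()],
            columns=["region", "count"]))
        mds = dge.mds_coordinates(dge.logcpm(counts_f, factors))
        emit("mds_coordinates", mds.coordinates.reset_index(names="sample_id"))
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[dge] {e}") from e

    # --- coexpression network --------------------------------------------
    try:
        kept_f = network.filter_fpkm(fpkm, th["fpkm_min"], th["fpkm_min_samples"])
        expr = network.log_fpkm(fpkm.loc[kept_f])
        expr = expr[expr.std(axis=1) > 0]
        beta, fit_table = network.pick_soft_threshold(expr)
        adj = network.adjacency(expr, beta)
        tom = network.tom_similarity(adj)
        assignments = network.detect_modules(tom, expr=expr)
        mods = network.build_module_set(expr, adj, assignments)
        emit("soft_threshold", fit_table)
        emit("module_assignments",
             assignments.rename_axis("gene_id").reset_index())
        trait = (design["clade"] == "D").astype(float)
        if len(mods.eigengenes.columns):
            emit("module_trait",
                 network.module_trait_association(mods.eigengenes, trait))
        out.summary["n_modules"] = int(len(mods.sizes))
        out.summary["soft_power"] = int(beta)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[network] {e}") from e

    # --- popgen -----------------------------------------------------------
    try:
        vcf_text, snp_transcripts, orf_table, truth_g = simulate.gen_genotypes(sim_config)
        if outdir is not None:
            (outdir / "genotypes.vcf").write_text(vcf_text)
        records, samples = _records_from_text(vcf_text)
        records = popgen.filter_snps(records, th["maf_min"],
                                     th["call_rate_min"], th["depth_min"])
        seq_by_id = {t.id: t.sequence for t in snp_transcripts}
        orf_by_id = {t.id: t.orfs[0] for t in snp_transcripts}
        syn = [r for r in records
               if popgen.annotate_synonymous(r, orf_by_id[r.transcript_id],
                                             seq_by_id[r.transcript_id])]
        iso = pd.DataFrame({"gene_id": [t.id for t in snp_transcripts],
                            "isoform_id": [t.id for t in snp_transcripts],
                            "length": [t.length for t in snp_transcripts]})
        thinned = popgen.thin_one_per_transcript(syn, iso)
        n1 = sim_config.n_per_group[0]
        groups = {s: ("g1" if i < n1 else "g2") for i, s in enumerate(samples)}
        est = popgen.estimate_fst(thinned, samples, groups,
                                  n_reps=th["n_bootstrap"],
                                  seed=sim_config.seed)
        emit("fst", pd.DataFrame([{
            "theta": est.theta, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "n_loci": est.n_loci, "n_bootstrap": est.n_bootstrap,
            "true_diff_param": truth_g.true_diff_param}]))
        out.summary["fst"] = est.theta
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[fst] {e}") from e

    # --- enrichment -------------------------------------------------------
    try:
        genes = list(counts_f.index)
        site_degs = deg_sets["site"]
        p2g_text, domain_table, _truth_a = simulate.gen_annotations(
            sim_config, genes, site_degs)
        mapping = enrichment.parse_pfam2go(p2g_text)
        term_genes = enrichment.genes_per_term(domain_table, mapping)
        universe = set().union(*term_genes.values()) if term_genes else set(genes)
        test = site_degs & universe
        stats_list = enrichment.hypergeom_enrich(test, term_genes, universe)
        reported = enrichment.filter_terms(stats_list, len(test), th["alpha"],
                                           th["enrich_min_fraction"])
        emit("enrichment", pd.DataFrame(
            [(s.term_id, s.count, s.size, s.odds_ratio, s.p) for s in stats_list],
            columns=["term", "count", "size", "odds_ratio", "p"]))
        out.summary["n_enriched_terms"] = len(reported)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[enrich] {e}") from e

    # --- report -----------------------------------------------------------
    emit("association_tests", study_association_tests())
    if outdir is not None:
        (outdir / "manifest.json").write_text(
            json.dumps({**out.manifest, "summary": out.summary},
                       indent=2, default=str))
    return out


def _records_from_text(vcf_text: str):
    """Parse the generator's VCF text without touching the filesystem."""
    import io as _io

    records = []
    samples: list[str] = []
    for line in _io.StringIO(vcf_text):
        line = line.rstrip("\n")
        if line.startswith("##") or not line:
            continue
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            continue
        f = line.split("\t")
        gts = np.full(len(samples), np.nan)
        dps = np.zeros(len(samples))
        for i, cell in enumerate(f[9:]):
            gt, dp = cell.split(":")
            if "." not in gt:
                gts[i] = sum(int(x) for x in gt.replace("|", "/").split("/"))
            dps[i] = int(dp)
        records.append(popgen.SnpRecord(f[0], int(f[1]), f[3], f[4], gts, dps))
    return records, samples
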