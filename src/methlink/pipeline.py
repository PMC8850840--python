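"""End-to-end orchestration: simulate or load inputs, run every stage,
write the output tree and a reproducibility manifest.

Stage order: methylome -> dmr -> annotation -> transcriptome ->
integration -> enrichment.  Comparisons are ordered pairs declared once in
the config; the first-named group is the reference everywhere (Fisher
delta, log2 fold change, hyper/hypo, up/down) and the orientation is
stamped into each output's header-adjacent attrs and the manifest.
Re-running with the same config and seed reproduces every output table
byte-for-byte; the manifest differs only in its timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_dmrs, derive_elements, map_dmrs_to_genes, venn_counts
from .dmr import DmrThresholds, call_dmrs, dmrs_to_bed
from .enrichment import length_bias_weights, wallenius_enrich
from .integration import (
    expression_strata,
    gene_tss_methylation,
    intersect_dmg_deg,
    profile_correlation,
    tss_profile,
)
from .methylome import context_summary
from .simulate import SimConfig, generate_reference, simulate_expression, simulate_methylome, simulate_term_map
from .transcriptome import cluster_degs, compute_fpkm, de_analysis
from . import io as mio

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (or a simulation), comparisons, thresholds."""

    out_dir: str = "methlink_out"
    seed: int = 0
    comparisons: tuple = (("LPBB", "HPBB"), ("LPB+", "HPBB"), ("LPB+", "LPBB"))
    min_sites: int = 3
    cg_delta: float = 0.3
    hch_delta: float = 0.2
    alpha: float = 0.05
    de_alpha: float = 0.05
    lfc: float = 1.0
    promoter_bp: int = 3000
    tss_window: int = 2000
    tss_bins: int = 100
    max_gap: int = 300
    window_span: int = 1000
    simulate: dict | None = field(default_factory=dict)
    inputs: dict | None = None  # paths: fasta, genes, reports{sample: path}, counts, lengths, design, terms

    def __post_init__(self):
        for name in ("min_sites", "cg_delta", "hch_delta", "alpha", "de_alpha",
                     "lfc", "promoter_bp", "tss_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.comparisons = tuple(tuple(c) for c in self.comparisons)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @property
    def thresholds(self) -> DmrThresholds:
        return DmrThresholds(
            min_sites=self.min_sites,
            cg_delta=self.cg_delta,
            hch_delta=self.hch_delta,
            alpha=self.alpha,
            max_gap=self.max_gap,
            window_span=self.window_span,
        )


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # analysis parameters only
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write(df: pd.DataFrame, path, manifest, index=False):
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    manifest["row_counts"][os.path.basename(path)] = int(len(df))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "comparisons": [" vs ".join(c) for c in config.comparisons],
        "input_checksums": {},
        "row_counts": {},
    }

    stage = "inputs"
    try:
        if config.inputs:
            reference = mio.read_fasta(config.inputs["fasta"])
            genes = mio.read_gene_models(config.inputs["genes"])
            sites = mio.read_cytosine_reports(config.inputs["reports"])
            counts = mio.read_counts(config.inputs["counts"])
            lengths = pd.read_csv(
                config.inputs["lengths"], sep="\t", index_col=0
            ).iloc[:, 0]
            design = mio.read_design(config.inputs["design"])
            term_map = (
                mio.read_term_map(config.inputs["terms"])
                if config.inputs.get("terms")
                else None
            )
            for key, val in config.inputs.items():
                if isinstance(val, str) and os.path.exists(val):
                    manifest["input_checksums"][key] = _checksum(val)
        else:
            stage = "simulate"
            sim_kwargs = dict(config.simulate or {})
            sim_kwargs.setdefault("seed", config.seed)
            sim_kwargs.setdefault("promoter_bp", config.promoter_bp)
            sim = SimConfig(**sim_kwargs)
            reference, genes = generate_reference(sim)
            sites, truth = simulate_methylome(sim, reference, genes)
            counts, lengths, truth = simulate_expression(
                sim, genes, truth.promoter_methylation, truth
            )
            design = sim.design
            term_map = simulate_term_map(genes, seed=sim.seed)
            in_dir = os.path.join(out, "inputs")
            os.makedirs(in_dir, exist_ok=True)
            mio.write_fasta(reference, os.path.join(in_dir, "reference.fa"))
            mio.write_gff3(genes, os.path.join(in_dir, "genes.gff3"))
            mio.write_bed12(genes, os.path.join(in_dir, "genes.bed"))
            mio.write_cytosine_reports(sites, os.path.join(in_dir, "reports"))
            counts.to_csv(os.path.join(in_dir, "counts.tsv"), sep="\t")
            lengths.rename("length").to_csv(os.path.join(in_dir, "lengths.tsv"), sep="\t")
            design.rename("group").to_csv(os.path.join(in_dir, "design.tsv"), sep="\t")
            term_map.to_csv(os.path.join(in_dir, "terms.tsv"), sep="\t", index=False)
            _write(truth.true_dmrs, os.path.join(in_dir, "truth_dmrs.tsv"), manifest)
            _write(truth.true_degs, os.path.join(in_dir, "truth_degs.tsv"), manifest)
            _write(
                truth.promoter_methylation,
                os.path.join(in_dir, "truth_promoter_methylation.tsv"),
                manifest,
            )

        chrom_sizes = {c: len(s) for c, s in reference.items()}

        stage = "methylome"
        summaries = []
        for group in pd.unique(design.to_numpy()):
            cs = context_summary(sites, samples=list(design.index[design == group]))
            frame = cs.to_frame()
            frame.insert(0, "group", group)
            summaries.append(frame)
        _write(pd.concat(summaries, ignore_index=True),
               os.path.join(out, "context_summary.tsv"), manifest)

        stage = "dmr"
        elements = derive_elements(genes, chrom_sizes, promoter_bp=config.promoter_bp)
        dmg_sets, deg_tables, dmr_tables = {}, {}, {}
        for comp in config.comparisons:
            tag = f"{comp[0]}_vs_{comp[1]}".replace("+", "plus")
            dmrs = call_dmrs(sites, design, comp, thresholds=config.thresholds)
            dmr_tables[comp] = dmrs
            _write(dmrs, os.path.join(out, f"dmrs.{tag}.tsv"), manifest)
            _write(dmrs_to_bed(dmrs), os.path.join(out, f"dmrs.{tag}.bed"), manifest)

        stage = "annotation"
        for comp in config.comparisons:
            tag = f"{comp[0]}_vs_{comp[1]}".replace("+", "plus")
            ann = annotate_dmrs(dmr_tables[comp], elements)
            _write(ann, os.path.join(out, f"dmr_elements.{tag}.tsv"), manifest)
            dist = ann["element"].value_counts().rename_axis("element").reset_index(name="n")
            _write(dist, os.path.join(out, f"dmr_element_distribution.{tag}.tsv"), manifest)
            dmgs = map_dmrs_to_genes(dmr_tables[comp], elements)
            dmg_sets[comp] = dmgs
            _write(dmgs.drop(columns="dmr_rows"),
                   os.path.join(out, f"dmgs.{tag}.tsv"), manifest)
        if len(config.comparisons) >= 2:
            venn = venn_counts(
                {" vs ".join(c): set(dmg_sets[c]["gene_id"]) for c in config.comparisons}
            )
            venn_df = pd.DataFrame(
                [{"sets": " & ".join(k), "n": v} for k, v in sorted(venn.items())]
            )
            _write(venn_df, os.path.join(out, "dmg_venn.tsv"), manifest)

        stage = "transcriptome"
        fpkm = compute_fpkm(counts, lengths)
        fpkm.to_csv(os.path.join(out, "fpkm.tsv"), sep="\t", float_format="%.6g")
        manifest["row_counts"]["fpkm.tsv"] = int(len(fpkm))
        for comp in config.comparisons:
            tag = f"{comp[0]}_vs_{comp[1]}".replace("+", "plus")
            de = de_analysis(
                counts, design, comp, lfc=config.lfc, alpha=config.de_alpha
            )
            deg_tables[comp] = de
            _write(de.reset_index(), os.path.join(out, f"de.{tag}.tsv"), manifest)
            degs = de.index[de["status"] != "ns"]
            if len(degs) >= 2:
                order, _, flagged = cluster_degs(fpkm.loc[degs])
                _write(
                    pd.DataFrame({"gene_id": order, "leaf_rank": range(len(order))}),
                    os.path.join(out, f"deg_cluster_order.{tag}.tsv"),
                    manifest,
                )

        stage = "integration"
        for comp in config.comparisons:
            tag = f"{comp[0]}_vs_{comp[1]}".replace("+", "plus")
            samples_a = list(design.index[design == comp[0]])
            strata = expression_strata(fpkm[samples_a].mean(axis=1))
            profile = tss_profile(
                sites, genes, strata, samples_a,
                window=config.tss_window, n_bins=config.tss_bins,
            )
            _write(profile, os.path.join(out, f"tss_profile.{tag}.tsv"), manifest)
            meth = gene_tss_methylation(sites, genes, samples_a, window=config.tss_window)
            corr = profile_correlation(
                meth, fpkm[samples_a].mean(axis=1), strata=strata, seed=config.seed
            )
            with open(os.path.join(out, f"tss_correlation.{tag}.json"), "w") as fh:
                json.dump(corr, fh, indent=1, sort_keys=True)
            degs_called = deg_tables[comp][deg_tables[comp]["status"] != "ns"]
            degs_called.attrs["comparison"] = " vs ".join(comp)
            records = intersect_dmg_deg(dmg_sets[comp], degs_called, " vs ".join(comp))
            _write(records, os.path.join(out, f"integration.{tag}.tsv"), manifest)
            cats = records["category"].value_counts().rename_axis("category").reset_index(name="n")
            _write(cats, os.path.join(out, f"integration_categories.{tag}.tsv"), manifest)

        stage = "enrichment"
        if term_map is not None and len(term_map):
            background = [g.gene_id for g in genes]
            for comp in config.comparisons:
                tag = f"{comp[0]}_vs_{comp[1]}".replace("+", "plus")
                study = sorted(set(dmg_sets[comp]["gene_id"]) & set(background))
                is_study = pd.Series(
                    [g in set(study) for g in background], index=background
                )
                weights = length_bias_weights(lengths.reindex(background), is_study)
                res = wallenius_enrich(study, background, term_map, weights)
                _write(res, os.path.join(out, f"enrichment_dmg.{tag}.tsv"), manifest)
    except Exception as exc:  # annotate failures with the stage name
        marker = os.path.join(out, "PARTIAL_RESULTS")
        with open(marker, "w") as fh:
            fh.write(f"failed at stage: {stage}\n{exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
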