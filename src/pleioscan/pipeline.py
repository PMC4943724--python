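"""End-to-end pleiotropy-mapping pipeline.

Orchestrates: genotype QC -> dEBV weighting and accuracy filtering -> LOCO
mixed-model scans per trait -> multi-trait meta-analysis with empirical FDR
threshold -> VEGAS gene tests per trait -> cross-trait pleiotropy call ->
trait-correlation report.  Every stage writes a TSV under the run directory
and a manifest records config, seed, library versions and filter counts, so
a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeMatrix, filter_markers, filter_samples, gap_summary
from .lmm import conditional_scan, gwa_loco, loco_grms
from .meta import mean_offdiagonal, meta_scan, stack_t_matrix
from .plink import read_plink
from .vegas import Exclusions, call_pleiotropic, gene_scan, read_gene_table
from .weights import TraitData, accuracy_filter, compute_weights

__all__ = ["PipelineConfig", "run_pipeline", "correlation_report"]


@dataclass
class PipelineConfig:
    plink_prefix: str = ""
    trait_files: dict = field(default_factory=dict)  # trait_id -> TSV path
    trait_h2: dict = field(default_factory=dict)  # trait_id -> heritability
    gene_table: str = ""
    gene_dialect: str = "1-based"
    out_dir: str = "pleioscan_run"
    # QC
    min_sample_call: float = 0.90
    min_marker_call: float = 0.95
    min_maf: float = 0.02
    autosomes: list | None = None
    # weights
    c: float = 0.5
    min_accuracy: float = 0.50
    accuracy_mode: str = "accuracy"
    # LMM
    per_loco_reml: bool = True
    max_iter: int = 200
    tol: float = 1e-8
    # meta
    f: float = 0.05
    diag_mode: str = "signed"
    # VEGAS
    expand_bp: int = 100_000
    max_r2: float = 0.5
    list_alpha: float = 0.01
    min_traits: int = 4
    max_sims: int = 1_000_000
    # pleiotropy exclusions
    exclude_gene_ids: list = field(default_factory=list)
    exclude_chromosomes: list = field(default_factory=list)
    exclude_chromosome_exceptions: list = field(default_factory=list)
    # misc
    conditional_on: list = field(default_factory=list)  # marker ids, optional
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in (
                [Path(self.plink_prefix + ".bed")]
                + [Path(v) for v in self.trait_files.values()]
                + ([Path(self.gene_table)] if self.gene_table else [])
            )
            if not p.exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"config references missing files: {[str(p) for p in missing]}"
            )


def _vegas_stages(max_sims: int) -> tuple[int, ...]:
    stages = [s for s in (1_000, 10_000, 100_000, 1_000_000) if s <= max_sims]
    return tuple(stages) if stages else (int(max_sims),)


def correlation_report(
    traits: dict[str, TraitData], assoc_tables: dict[str, pd.DataFrame]
) -> dict:
    """Cross-trait dEBV and t-value Pearson correlation matrices.

    dEBV correlations are pairwise-complete over each pair's common animals
    (after the accuracy filter); t-value correlations span the common marker
    set.  Returns matrices plus upper-triangle off-diagonal means.
    """
    ids = list(traits)
    if len(ids) < 2:
        raise ValueError("need at least two traits for a correlation report")
    q = len(ids)
    debv_corr = np.eye(q)
    for i in range(q):
        for j in range(i + 1, q):
            a = traits[ids[i]].records.set_index("animal_id")["debv"]
            b = traits[ids[j]].records.set_index("animal_id")["debv"]
            common = a.index.intersection(b.index)
            r = float(np.corrcoef(a.loc[common], b.loc[common])[0, 1])
            debv_corr[i, j] = debv_corr[j, i] = r
    _, T = stack_t_matrix(assoc_tables)
    t_corr = np.corrcoef(T.T)
    return {
        "trait_ids": ids,
        "debv_corr": pd.DataFrame(debv_corr, index=ids, columns=ids),
        "tvalue_corr": pd.DataFrame(t_corr, index=list(assoc_tables), columns=list(assoc_tables)),
        "mean_offdiag_debv": mean_offdiagonal(debv_corr),
        "mean_offdiag_t": mean_offdiagonal(t_corr),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory.

    Any stage failure raises with a stage-labelled message after writing a
    FAILED marker next to the partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pleioscan_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": asdict(config),
        "counts": {},
    }
    stage = "setup"
    try:
        stage = "load_genotypes"
        config.validate_paths()
        gm = read_plink(config.plink_prefix)
        manifest["counts"]["samples_loaded"] = gm.n_samples
        manifest["counts"]["markers_loaded"] = gm.n_markers

        stage = "qc"
        gm = filter_samples(gm, config.min_sample_call)
        manifest["counts"]["samples_after_call_rate"] = gm.n_samples
        autosomes = set(map(str, config.autosomes)) if config.autosomes else None
        gm = filter_markers(gm, autosomes, config.min_marker_call, config.min_maf)
        manifest["counts"]["markers_after_qc"] = gm.n_markers
        mean_gap, median_gap = gap_summary(gm.marker_map)
        manifest["counts"]["mean_gap_bp"] = mean_gap
        manifest["counts"]["median_gap_bp"] = median_gap
        pd.DataFrame(
            [
                ("min_sample_call", config.min_sample_call),
                ("min_marker_call", config.min_marker_call),
                ("min_maf", config.min_maf),
                ("maf_computed", "after_sample_filter"),
                ("samples_retained", gm.n_samples),
                ("markers_retained", gm.n_markers),
                ("mean_gap_bp", mean_gap),
                ("median_gap_bp", median_gap),
            ],
            columns=["key", "value"],
        ).to_csv(out / "qc_report.tsv", sep="\t", index=False)

        stage = "weights"
        traits: dict[str, TraitData] = {}
        for trait_id, path in config.trait_files.items():
            rec = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
            h2 = config.trait_h2.get(trait_id)
            if h2 is None:
                raise ValueError(f"no heritability configured for trait {trait_id}")
            td = TraitData(trait_id=trait_id, h2=float(h2), records=rec, c=config.c)
            td = accuracy_filter(td, config.min_accuracy, config.accuracy_mode)
            td = compute_weights(td)
            # keep only genotyped animals
            keep = td.records["animal_id"].isin(gm.sample_ids)
            td.records = td.records.loc[keep].reset_index(drop=True)
            traits[trait_id] = td
            td.records.to_csv(out / f"weights_{trait_id}.tsv", sep="\t", index=False)
            manifest["counts"][f"records_{trait_id}"] = td.n_records

        stage = "grm"
        grms = loco_grms(gm)

        stage = "gwa"
        assoc: dict[str, pd.DataFrame] = {}
        for trait_id, td in traits.items():
            tab = gwa_loco(
                gm, td, grms,
                per_loco_reml=config.per_loco_reml,
                max_iter=config.max_iter,
                tol=config.tol,
            )
            tab.to_csv(out / f"assoc_{trait_id}.tsv", sep="\t", index=False)
            assoc[trait_id] = tab

        stage = "meta"
        meta_tab, corr, sel = meta_scan(assoc, f=config.f, diag_mode=config.diag_mode)
        meta_tab["neglog10_p"] = -np.log10(np.clip(meta_tab["p"], 1e-300, None))
        meta_tab.to_csv(out / "meta.tsv", sep="\t", index=False)
        ids = list(assoc)
        pd.DataFrame(corr.C_raw, index=ids, columns=ids).to_csv(
            out / "tvalue_corr_raw.tsv", sep="\t"
        )
        pd.DataFrame(corr.C_adj, index=ids, columns=ids).to_csv(
            out / "tvalue_corr_adjusted.tsv", sep="\t"
        )
        manifest["counts"]["meta_markers"] = int(len(meta_tab))
        manifest["counts"]["meta_significant"] = sel.n_significant
        manifest["meta_alpha"] = sel.alpha

        if config.conditional_on:
            stage = "conditional"
            for trait_id, td in traits.items():
                ctab = conditional_scan(
                    gm, td, grms, list(config.conditional_on),
                    per_loco_reml=config.per_loco_reml,
                )
                ctab.to_csv(
                    out / f"assoc_conditional_{trait_id}.tsv", sep="\t", index=False
                )

        stage = "vegas"
        genes = read_gene_table(config.gene_table, config.gene_dialect)
        stages = _vegas_stages(config.max_sims)
        gene_results: dict[str, pd.DataFrame] = {}
        for trait_id in traits:
            gr = gene_scan(
                assoc[trait_id], genes, gm, trait_id,
                seed=config.seed,
                expand_bp=config.expand_bp,
                max_r2=config.max_r2,
                stages=stages,
            )
            gr.to_csv(out / f"vegas_{trait_id}.tsv", sep="\t", index=False)
            gene_results[trait_id] = gr

        stage = "pleiotropy_call"
        excl = Exclusions(
            gene_ids=set(config.exclude_gene_ids),
            chromosomes=set(map(str, config.exclude_chromosomes)),
            chromosome_exceptions=set(config.exclude_chromosome_exceptions),
        )
        calls = call_pleiotropic(
            gene_results,
            min_traits=config.min_traits,
            list_alpha=config.list_alpha,
            exclusions=excl,
        )
        calls.to_csv(out / "pleiotropy_calls.tsv", sep="\t", index=False)
        manifest["counts"]["candidate_genes"] = int(calls["is_candidate"].sum())

        stage = "correlation_report"
        rep = correlation_report(traits, assoc)
        rep["debv_corr"].to_csv(out / "debv_corr.tsv", sep="\t")
        rep["tvalue_corr"].to_csv(out / "tvalue_corr.tsv", sep="\t")
        manifest["mean_offdiag_debv"] = rep["mean_offdiag_debv"]
        manifest["mean_offdiag_t"] = rep["mean_offdiag_t"]

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out
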