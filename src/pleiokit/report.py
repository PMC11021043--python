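"""Pipeline orchestration and the multiple-testing threshold ledger.

Each analysis family gets a Bonferroni-corrected significance threshold of
0.05 divided by its own number of tests: genomic regions for the local
estimates, functional categories and cell-type annotations for the
partitioned heritability, and genes for the gene-based tests.  Thresholds
are always recomputed exactly from their denominators; a two-significant-
figure rendering is provided for report text, and the two never disagree
beyond rounding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetest, hess, ldsc, mixture, simulate, sumstats

__all__ = ["bonferroni", "format_threshold", "ThresholdLedger", "manhattan_table",
           "run_pipeline", "PipelineError"]


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def format_threshold(x: float) -> str:
    """Two-significant-figure rendering for report text (e.g. 2.9e-05)."""
    if x <= 0:
        raise ValueError("threshold must be positive")
    exponent = int(np.floor(np.log10(x)))
    mant = round(x / 10**exponent, 1)
    if mant >= 10:  # rounding carried over a decade
        mant /= 10
        exponent += 1
    return f"{mant:.1f}e{exponent:+03d}"


@dataclass
class ThresholdLedger:
    """Named Bonferroni thresholds, one per analysis family."""

    local: float
    tissue_function: float
    cell_type: float
    cell_group: float
    gene: float

    @classmethod
    def from_counts(
        cls,
        n_regions: int,
        n_categories: int,
        n_annotations: int,
        n_groups: int,
        n_genes: int,
        alpha: float = 0.05,
    ) -> "ThresholdLedger":
        return cls(
            local=bonferroni(alpha, n_regions),
            tissue_function=bonferroni(alpha, n_categories),
            cell_type=bonferroni(alpha, n_annotations),
            cell_group=bonferroni(alpha, n_groups),
            gene=bonferroni(alpha, n_genes),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rendered"] = {k: format_threshold(v) for k, v in asdict(self).items()}
        return d


def manhattan_table(
    gene_results: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    alpha_gene: float | None = None,
) -> pd.DataFrame:
    """Plot-ready per-gene table: midpoint position and -log10 p per ring.

    The threshold line is the -log10 of the gene-level Bonferroni threshold
    (stored in the table attrs and as a constant column, rendered to two
    decimals for axis labelling).
    """
    if len(gene_results) == 0:
        return pd.DataFrame(
            columns=["gene", "position", "neglog10_aspus_1", "neglog10_aspus_2",
                     "neglog10_mtaspusset", "threshold_line"]
        )
    alpha = alpha_gene if alpha_gene is not None else 0.05 / len(gene_results)
    out = pd.DataFrame({"gene": gene_results["gene"]})
    if gene_map is not None:
        pos = gene_map.set_index("name")[["start", "end"]]
        mid = (pos["start"] + pos["end"]) / 2.0
        out["position"] = out["gene"].map(mid)
    else:
        out["position"] = np.arange(len(out))
    for col, ring in [("aspus_p_1", "neglog10_aspus_1"), ("aspus_p_2", "neglog10_aspus_2"),
                      ("mtaspusset_p", "neglog10_mtaspusset")]:
        out[ring] = -np.log10(gene_results[col].to_numpy(dtype=float))
    line = -np.log10(alpha)
    out["threshold_line"] = round(line, 2)
    out.attrs["threshold_line"] = line
    return out


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "m_snps": 5000,
        "n1": 10000,
        "n2": 10000,
        "n_ref": 500,
        "block_size": 25,
        "rho": 0.1,
        "rho_max": 0.9,
        "n_chrom": 2,
        "sample_overlap": 0.0,
        "h2_1": 0.25,
        "h2_2": 0.15,
        "pi1": 0.015,
        "pi2": 0.015,
        "pi12": 0.02,
        "rho12": 0.5,
    },
    "ldsc": {"n_blocks": 50, "window_snps": 25},
    "local": {"enabled": True, "target_snps": 50},
    "mixer": {"enabled": True, "n_starts": 6},
    "genetest": {"enabled": True, "n_genes": 40, "gene_span": 20, "B": 1000},
    # counts for threshold families not produced by this run (functional
    # categories, cell-type annotations, cell-type groups)
    "annotation_counts": {"n_categories": 53, "n_annotations": 220, "n_groups": 10},
    "alpha": 0.05,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | str | Path | None = None, out_dir: str | Path = "pleiokit_out") -> dict:
    """Run the full synthetic-data analysis chain and write a report bundle.

    Stages: simulate -> harmonize -> LDSC (h2, rg) -> local estimates ->
    causal mixture -> gene tests -> pleiotropic-gene rule -> threshold
    ledger.  Any stage can be disabled via its config block.  Outputs are a
    pure function of (config, seed); a failing stage raises PipelineError
    naming the stage, keeping earlier outputs on disk.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_used.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    summary: dict = {"config": cfg, "stages": {}}
    seed = int(cfg["seed"])

    stage = "simulate"
    try:
        sc = cfg["simulate"]
        mix = mixture.MixtureParams.from_h2(
            h2_1=sc["h2_1"], h2_2=sc["h2_2"], m_snps=sc["m_snps"],
            pi1=sc["pi1"], pi2=sc["pi2"], pi12=sc["pi12"], rho12=sc["rho12"],
        )
        sim = simulate.SimConfig(
            m_snps=sc["m_snps"], n1=sc["n1"], n2=sc["n2"], n_ref=sc["n_ref"],
            block_size=sc["block_size"], rho=sc["rho"], rho_max=sc.get("rho_max"),
            mixture=mix, sample_overlap=sc["sample_overlap"], n_chrom=sc["n_chrom"],
            seed=seed,
        )
        panel = simulate.simulate_genotypes(sim)
        b1, b2 = simulate.draw_effects(sim)
        ss1_df, ss2_df = simulate.simulate_sumstats_pair(
            panel, b1, b2, sim.n1, sim.n2, sim.sample_overlap, seed=seed
        )
        simulate.write_sumstats(ss1_df, out / "trait1.sumstats.tsv")
        simulate.write_sumstats(ss2_df, out / "trait2.sumstats.tsv")
        ss1 = sumstats.read_sumstats(out / "trait1.sumstats.tsv")
        ss2 = sumstats.read_sumstats(out / "trait2.sumstats.tsv")
        reference = ss1.df[["snp_id", "a1", "a2"]]
        pair = sumstats.harmonize(ss1, ss2, reference)
        (out / "qc_report.json").write_text(json.dumps(
            {"trait1": ss1.qc, "trait2": ss2.qc, "harmonize": pair.report}, indent=2))
        # restrict the panel to the SNPs surviving QC + harmonization
        idx = pd.Index(panel.snp_ids).get_indexer(pair.ss1.snp_id)
        if (idx < 0).any():
            raise ValueError("aligned SNPs missing from the panel")
        panel = simulate.GenotypePanel(
            genotypes=panel.genotypes[:, idx],
            positions=panel.positions[idx],
            chrom=panel.chrom[idx],
            block_index=panel.block_index[idx],
            rho=panel.rho,
            snp_ids=panel.snp_ids[idx],
            block_rho=panel.block_rho,
        )
        summary["stages"]["simulate"] = {"m_snps": sim.m_snps, "n_aligned": len(pair)}
    except Exception as e:  # noqa: BLE001 - deliberate stage boundary
        raise PipelineError(stage, e) from e

    stage = "ldsc"
    try:
        lc = cfg["ldsc"]
        ld = ldsc.compute_ld_scores(panel, window_snps=lc["window_snps"])
        model = ldsc.CrossTraitLDSC(n_blocks=lc["n_blocks"]).fit(
            ld.total, pair.ss1.z, pair.ss2.z, sim.n1, sim.n2
        )
        ldsc_tab = pd.DataFrame(
            [
                {"quantity": "h2_trait1", "estimate": model.h2_1_.estimate,
                 "se": model.h2_1_.se, "p": model.h2_1_.p,
                 "intercept": model.h2_1_.intercept},
                {"quantity": "h2_trait2", "estimate": model.h2_2_.estimate,
                 "se": model.h2_2_.se, "p": model.h2_2_.p,
                 "intercept": model.h2_2_.intercept},
                {"quantity": "gcov", "estimate": model.gcov_, "se": model.gcov_se_,
                 "p": np.nan, "intercept": model.cross_intercept_},
                {"quantity": "rg", "estimate": model.rg_, "se": model.rg_se_,
                 "p": model.rg_p_, "intercept": model.cross_intercept_},
            ]
        )
        ldsc_tab.to_csv(out / "ldsc.tsv", sep="\t", index=False)
        summary["stages"]["ldsc"] = {
            "h2_1": model.h2_1_.estimate, "h2_2": model.h2_2_.estimate,
            "rg": model.rg_, "rg_se": model.rg_se_,
            "cross_intercept": model.cross_intercept_,
        }
    except Exception as e:
        raise PipelineError(stage, e) from e

    n_regions = 1
    if cfg["local"].get("enabled", True):
        stage = "local"
        try:
            part = hess.partition_genome(
                panel.positions, panel.chrom, target_snps=cfg["local"]["target_snps"]
            )
            Rs = [
                np.corrcoef(panel.genotypes[:, sl], rowvar=False)
                for sl in part.slices()
            ]
            local_tab = hess.analyze_regions(
                pair.ss1.z, pair.ss2.z, part, Rs, sim.n1, sim.n2,
                r_overlap=sim.sample_overlap,
            )
            local_tab.to_csv(out / "local.tsv", sep="\t", index=False)
            n_regions = len(part)
            summary["stages"]["local"] = {
                "n_regions": n_regions,
                "sum_local_h2_1": float(local_tab["h2_1"].sum()),
                "sum_local_h2_2": float(local_tab["h2_2"].sum()),
            }
        except Exception as e:
            raise PipelineError(stage, e) from e

    if cfg["mixer"].get("enabled", True):
        stage = "mixer"
        try:
            fitted = mixture.CausalMixtureModel(
                n_starts=cfg["mixer"]["n_starts"], random_state=seed
            ).fit(pair.ss1.z, pair.ss2.z, ld.total, sim.n1, sim.n2)
            venn = mixture.venn_counts(fitted.params_, sim.m_snps, se=fitted.se_)
            qq = mixture.conditional_qq(pair.ss1.p, pair.ss2.p)
            qq.to_csv(out / "conditional_qq.tsv", sep="\t", index=False)
            params_d = asdict(fitted.params_)
            (out / "mixture.json").write_text(json.dumps(
                {"params": params_d, "se": fitted.se_, "loglik": fitted.loglik_,
                 "venn": asdict(venn)}, indent=2, default=float))
            summary["stages"]["mixer"] = {
                "pi12": fitted.params_.pi12, "rho12": fitted.params_.rho12,
                "shared_k": venn.shared_k, "implied_rg": fitted.params_.implied_rg,
            }
        except Exception as e:
            raise PipelineError(stage, e) from e

    n_genes = 1
    if cfg["genetest"].get("enabled", True):
        stage = "genetest"
        try:
            gc = cfg["genetest"]
            gmap = simulate.make_gene_map(
                panel.m_snps, gc["n_genes"], gc["gene_span"], seed=seed, panel=panel
            )
            simulate.write_gene_map(gmap, out / "genes.bed")
            genes = genetest.gene_scan(
                pair.ss1.z, pair.ss2.z, pair.ss1.p, pair.ss2.p, panel, gmap,
                B=gc["B"], seed=seed, escalate=False,
            )
            genes.to_csv(out / "gene_tests.tsv", sep="\t", index=False)
            n_genes = len(genes)
            pleio = genetest.pleiotropic_genes(genes)
            pleio.to_csv(out / "pleiotropic_genes.tsv", sep="\t", index=False)
            manhattan_table(genes, gmap).to_csv(out / "manhattan.tsv", sep="\t", index=False)
            summary["stages"]["genetest"] = {
                "n_genes": n_genes, "n_pleiotropic": len(pleio),
            }
        except Exception as e:
            raise PipelineError(stage, e) from e

    ac = cfg["annotation_counts"]
    ledger = ThresholdLedger.from_counts(
        n_regions=n_regions, n_categories=ac["n_categories"],
        n_annotations=ac["n_annotations"], n_groups=ac["n_groups"],
        n_genes=n_genes, alpha=cfg["alpha"],
    )
    summary["thresholds"] = ledger.to_dict()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return summary
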