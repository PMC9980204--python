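"""End-to-end orchestration of the synthetic-pool analysis.

``run_pipeline`` wires the stages simulate → qc → demux-hto →
demux-genotype → demux-consensus → score → de → concordance, writing
every intermediate to the output directory together with a JSON manifest
(parameters, per-stage seeds, output digests).  Per-stage seeds are
derived from the master seed by a documented rule:
``(seed + crc32(stage_name)) % 2**31``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import consensus as cns
from . import de as de_mod
from . import genotype as gt
from . import hto as hto_mod
from . import qc as qc_mod
from . import scoring
from . import concordance as conc
from .io import (
    CellMetadataTable,
    write_bundle_dir,
    write_genotypes_vcf,
    write_tsv,
)
from .simulate import (
    SimulationConfig,
    default_metadata_design,
    generate_donor_genotypes,
    generate_expression,
    generate_pool,
)

log = logging.getLogger("snmux")

STAGES = (
    "simulate",
    "qc",
    "demux-hto",
    "demux-genotype",
    "demux-consensus",
    "score",
    "de",
    "concordance",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (master + crc32(stage)) mod 2^31."""
    return (int(master_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Parameters of a full synthetic run (stage defaults mirrored)."""

    seed: int = 0
    output_dir: str = "snmux_run"
    log_level: str = "INFO"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # qc
    qc_min_features: int = 200
    qc_max_features: int = 10_000
    qc_max_mito_fraction: float = 0.05
    qc_first: bool = True
    # hto
    positive_quantile: float = 0.99
    # genotype
    geno_error_rate: float = 0.01
    posterior_threshold: float = 0.9
    doublet_prior: float = 0.05
    # consensus
    lenient: bool = False
    # scoring
    module_set_size: int = 30
    n_bins: int = 24
    n_ctrl: int = 100
    # de
    fdr_alpha: float = 0.05
    n_top_genes: int = 2000


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a freshly simulated pool; return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": [],
        "outputs": {},
    }
    current = "simulate"
    try:
        # ------------------------------------------------ simulate
        sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        log.info("simulate: seed=%d", sim.seed)
        geno, sites = generate_donor_genotypes(
            sim.n_donors, sim.n_sites, sim.maf_range, sim.seed
        )
        hto, alt, dp, truth = generate_pool(geno, sim)
        design = default_metadata_design(geno.donors)
        expr, meta = generate_expression(truth, design, sim)
        write_bundle_dir(expr, out, "expression")
        write_bundle_dir(hto, out, "hto")
        from .io import SparseCountMatrix

        write_bundle_dir(SparseCountMatrix(alt, expr.barcodes, [f"site{i}" for i in range(sim.n_sites)]), out, "alt")
        write_bundle_dir(SparseCountMatrix(dp, expr.barcodes, [f"site{i}" for i in range(sim.n_sites)]), out, "dp")
        write_tsv(sites.to_frame(), os.path.join(out, "sites.tsv"))
        write_genotypes_vcf(geno, sites, os.path.join(out, "donors.vcf"))
        write_tsv(truth.frame, os.path.join(out, "truth.tsv"))
        write_tsv(meta.frame, os.path.join(out, "metadata.tsv"))
        manifest["stages"].append("simulate")

        # ------------------------------------------------ qc
        current = "qc"
        kept, metrics = qc_mod.qc_filter(
            expr,
            mito_feature_ids=[],
            min_features=config.qc_min_features,
            max_features=config.qc_max_features,
            max_mito_fraction=config.qc_max_mito_fraction,
        )
        write_tsv(metrics, os.path.join(out, "qc_metrics.tsv"))
        log.info("qc: kept %d / %d nuclei", len(kept), expr.n_cells)
        if not config.qc_first:
            kept = list(expr.barcodes)
        manifest["stages"].append("qc")

        # ------------------------------------------------ demux-hto
        current = "demux-hto"
        hto_kept = hto.subset_cells(kept)
        hto_calls = hto_mod.classify_hto(
            hto_kept,
            positive_quantile=config.positive_quantile,
            seed=stage_seed(config.seed, "demux-hto"),
        )
        write_tsv(hto_mod.calls_to_frame(hto_calls), os.path.join(out, "hto_calls.tsv"))
        manifest["stages"].append("demux-hto")

        # ------------------------------------------------ demux-genotype
        current = "demux-genotype"
        idx = {b: i for i, b in enumerate(expr.barcodes)}
        rows = [idx[b] for b in kept]
        cells = gt.CellAlleleCounts(alt[rows], dp[rows], kept)
        geno_calls = gt.demux_genotype(
            cells,
            geno,
            error_rate=config.geno_error_rate,
            posterior_threshold=config.posterior_threshold,
            doublet_prior=config.doublet_prior,
        )
        write_tsv(
            gt.geno_calls_to_frame(geno_calls), os.path.join(out, "geno_calls.tsv")
        )
        manifest["stages"].append("demux-genotype")

        # ------------------------------------------------ demux-consensus
        current = "demux-consensus"
        tag_to_sample = {
            f"tag-{d}": f"sample_{d}" for d in geno.donors
        }
        donor_to_sample = {d: f"sample_{d}" for d in geno.donors}
        assignments = cns.integrate_calls(
            hto_calls,
            geno_calls,
            tag_to_sample=tag_to_sample,
            donor_to_sample=donor_to_sample,
            lenient=config.lenient,
        )
        yld = cns.yield_metrics(assignments)
        write_tsv(
            cns.assignments_to_frame(assignments),
            os.path.join(out, "assignments.tsv"),
        )
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "n_hto_only": yld.n_hto_only,
                        "n_geno_only": yld.n_geno_only,
                        "n_integrated": yld.n_integrated,
                        "gain_over_hto_pct": yld.gain_over_hto_pct,
                        "gain_over_geno_pct": yld.gain_over_geno_pct,
                    }
                ]
            ),
            os.path.join(out, "yield_report.tsv"),
        )
        log.info("consensus:\n%s", yld.summary())
        manifest["stages"].append("demux-consensus")
        manifest["yield"] = {
            "n_hto_only": yld.n_hto_only,
            "n_geno_only": yld.n_geno_only,
            "n_integrated": yld.n_integrated,
            "gain_over_hto_pct": yld.gain_over_hto_pct,
            "gain_over_geno_pct": yld.gain_over_geno_pct,
        }

        # ---------------------------------------- analysis set: assigned nuclei
        assigned = [a.barcode for a in assignments if a.final_sample]
        final_sample = {a.barcode: a.final_sample for a in assignments}
        expr_a = expr.subset_cells(assigned)
        meta_a = CellMetadataTable(
            meta.frame[meta.frame["barcode"].isin(assigned)]
            .assign(
                sample_id=lambda df: df["barcode"].map(final_sample)
            )
            .reset_index(drop=True)
        )

        # ------------------------------------------------ score
        current = "score"
        rng = np.random.default_rng(stage_seed(config.seed, "score"))
        gene_set = list(
            rng.choice(expr.features, size=min(config.module_set_size, expr.n_features // 4), replace=False)
        )
        msr = scoring.module_score(
            expr_a,
            gene_set,
            n_bins=config.n_bins,
            n_ctrl=config.n_ctrl,
            seed=stage_seed(config.seed, "score"),
        )
        write_tsv(
            msr.scores.rename_axis("barcode").reset_index(),
            os.path.join(out, "module_scores.tsv"),
        )
        medians = scoring.per_sample_median_score(msr.scores, meta_a)
        write_tsv(
            medians.rename("median_score").rename_axis("sample_id").reset_index(),
            os.path.join(out, "module_score_medians.tsv"),
        )
        comp = scoring.composition_table(meta_a)
        write_tsv(comp.reset_index(), os.path.join(out, "composition.tsv"))
        manifest["stages"].append("score")

        # ------------------------------------------------ de
        current = "de"
        spec = de_mod.DesignSpec(
            fdr_alpha=config.fdr_alpha, n_top_genes=config.n_top_genes
        )
        table = de_mod.de_test(expr_a, meta_a, spec)
        write_tsv(table, os.path.join(out, "de_table.tsv"))
        counts_cmp, flips = de_mod.compare_models(
            table[table["model"] == "adjusted"], table[table["model"] == "unadjusted"]
        )
        write_tsv(counts_cmp, os.path.join(out, "model_comparison.tsv"))
        write_tsv(flips, os.path.join(out, "sign_flips.tsv"))
        manifest["stages"].append("de")

        # ------------------------------------------------ concordance
        current = "concordance"
        adj = table[table["model"] == "adjusted"]
        de_tables = {
            g: sub[["gene", "estimate", "q"]]
            for g, sub in adj.groupby("group")
        }
        sharing = conc.sharing_counts(de_tables, alpha=config.fdr_alpha)
        write_tsv(sharing.reset_index(), os.path.join(out, "sharing.tsv"))
        T = len(de_tables)
        shared_all = sharing[sharing["n_types_significant"] == T]
        if len(shared_all):
            res = conc.concordance_test(sharing)
            conc_row = {
                "n_shared": res.n_shared,
                "n_concordant": res.n_concordant,
                "observed_prop": res.observed_prop,
                "expected_prop": res.expected_prop,
                "p_value": res.p_value,
            }
        else:
            conc_row = {
                "n_shared": 0,
                "n_concordant": 0,
                "observed_prop": None,
                "expected_prop": conc.expected_concordance(T),
                "p_value": None,
            }
        write_tsv(pd.DataFrame([conc_row]), os.path.join(out, "concordance.tsv"))
        manifest["stages"].append("concordance")
    except Exception as exc:
        manifest["failed_stage"] = current
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    for fname in sorted(os.listdir(out)):
        path = os.path.join(out, fname)
        if os.path.isfile(path) and fname != "manifest.json":
            manifest["outputs"][fname] = _digest(path)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
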