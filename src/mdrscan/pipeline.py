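"""End-to-end orchestration: QC -> panels -> search -> permutation -> validation.

Per network, the pipeline first runs the iterative 1-way loop (discovered
main-effect SNPs are removed from the panel), then the 2-way and 3-way
searches on the remaining SNPs, permutation-tests each selected model, and
fits the adjusted logistic regression only for permutation-significant
models (non-significant rows carry a dash in the final report).  All
randomness flows from one master seed; every artifact records it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io, network_panel
from .genotype_io import GenotypeMatrix
from .gmdr_core import (
    EMPTY, HIGH, DEFAULT_COVARIATES, MdrModel, ScoreVector, SearchConfig,
    compute_scores, iterative_oneway, repeat_and_select,
)
from .network_panel import SnpPanel
from .permutation import permutation_pvalue
from .risk_validation import assign_risk, fit_adjusted_logistic, km_logrank

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative pipeline configuration (one master seed)."""

    genotypes: str
    samples: str
    networks: str
    intervals: str
    out_dir: str
    genotype_format: str = "ped_map"
    maf_min: float = 0.05
    hwe_min_p: float = 1e-4
    max_missing: float = 0.0
    ld_prune_enabled: bool = True
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.8
    folds: int = 5
    repeats: int = 20
    orders: tuple[int, ...] = (1, 2, 3)
    permutation_B: int = 1000
    permutation_alpha: float = 0.001
    regression_alpha: float = 0.05
    exclude_oneway_snps: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _genotype_string(variant, dosage: int) -> str:
    if dosage == 0:
        return variant.allele_major + variant.allele_major
    if dosage == 1:
        return variant.allele_major + variant.allele_minor
    return variant.allele_minor + variant.allele_minor


def risk_categorization_lines(model: MdrModel, matrix: GenotypeMatrix) -> list[str]:
    """Cell-by-cell HIGH/LOW listing in the report layout.

    Each observed cell prints ``rsID_minor = alleles`` clauses joined by
    'and'; EMPTY cells are listed separately.
    """
    variants = [matrix.variants[matrix.column_index(s)] for s in model.combo]
    low, high, empty = [], [], []
    for cell in product(range(3), repeat=model.k):
        flat = sum(c * 3**j for j, c in enumerate(cell))
        clause = " and ".join(
            f"{v.label} = {_genotype_string(v, c)}" for v, c in zip(variants, cell)
        )
        lab = model.cell_labels[flat]
        (high if lab == HIGH else empty if lab == EMPTY else low).append(clause)
    lines = []
    for name, group in (("Low Risk", low), ("High Risk", high), ("Empty", empty)):
        for clause in group:
            lines.append(f"{clause} -> {name}")
    return lines


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mdrscan")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    log.info("run starts: seed=%d config_hash=%s", config.seed, config.config_hash())

    try:
        # ---- stage: QC -------------------------------------------------
        matrix = genotype_io.read_genotypes(config.genotypes, config.genotype_format)
        samples = genotype_io.read_samples(config.samples)
        matrix, qc_report = genotype_io.apply_qc(
            matrix, config.maf_min, config.hwe_min_p, config.max_missing
        )
        if config.ld_prune_enabled and matrix.n_snps > 1:
            before = matrix.n_snps
            matrix = genotype_io.ld_prune(
                matrix, config.ld_window, config.ld_step, config.ld_r2_max
            )
            log.info("LD pruning: %d -> %d SNPs", before, matrix.n_snps)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)

        # samples censored before/at 5y (status5y missing) leave the search
        eligible = samples["status5y"].notna()
        if (~eligible).any():
            log.info("%d samples censored before/at 5y excluded from MDR",
                     int((~eligible).sum()))
        mdr_samples = samples[eligible].reset_index(drop=True)
        keep_rows = [matrix.samples.index(s) for s in mdr_samples["sample_id"]]
        mdr_matrix = matrix.subset_samples(keep_rows)
        scores = compute_scores(mdr_samples, DEFAULT_COVARIATES)

        # ---- stage: panels --------------------------------------------
        networks = network_panel.read_networks(config.networks)
        intervals = network_panel.read_intervals(config.intervals)
        mapping = network_panel.map_snps_to_genes(mdr_matrix.variants, intervals)
        panels = [network_panel.build_panel(n, mapping, mdr_matrix) for n in networks]
        pd.DataFrame(
            [(p.network, s, ";".join(p.snp_to_gene[s])) for p in panels for s in p.snp_ids],
            columns=["network", "snp_id", "genes"],
        ).to_csv(out / "panels.tsv", sep="\t", index=False)

        # ---- stage: search + permutation + validation ------------------
        final_rows = []
        perm_rows = []
        model_rows: dict[int, list] = {k: [] for k in config.orders}
        categ_lines: list[str] = []
        km_frames = []
        for panel in panels:
            if panel.size == 0:
                continue
            claimed: list[str] = []
            base_cfg = SearchConfig(
                k=1, folds=config.folds, repeats=config.repeats, seed=config.seed
            )
            if 1 in config.orders:
                found = iterative_oneway(
                    panel, mdr_matrix, scores, base_cfg,
                    alpha=config.permutation_alpha, B=config.permutation_B,
                )
                for model, p in found:
                    claimed.extend(model.combo)
                    row = _validate_and_report(
                        panel.network, model, p, matrix, mdr_samples,
                        samples, config, perm_rows, final_rows, km_frames,
                    )
                    model_rows[1].append(row)
                    categ_lines.append(f"## {panel.network} 1-way {','.join(model.combo)}")
                    categ_lines.extend(risk_categorization_lines(model, mdr_matrix))
            sub = panel
            if config.exclude_oneway_snps and claimed:
                keep = [s for s in panel.snp_ids if s not in claimed]
                sub = SnpPanel(panel.network, keep,
                               {s: panel.snp_to_gene[s] for s in keep})
                log.info("%s: %d SNPs claimed by 1-way loop excluded",
                         panel.network, len(claimed))
            for k in config.orders:
                if k == 1 or sub.size < k:
                    continue
                cfg = SearchConfig(k=k, folds=config.folds, repeats=config.repeats,
                                   seed=config.seed + 17 * k)
                model, trace = repeat_and_select(sub, mdr_matrix, scores, cfg)
                perm = permutation_pvalue(sub, mdr_matrix, scores, cfg,
                                          B=config.permutation_B, observed=model)
                row = _validate_and_report(
                    panel.network, model, perm.p_value, matrix,
                    mdr_samples, samples, config, perm_rows, final_rows, km_frames,
                )
                freq = int((trace["combo"] == ",".join(model.combo)).sum())
                row["frequency"] = freq
                model_rows[k].append(row)
                categ_lines.append(f"## {panel.network} {k}-way {','.join(model.combo)}")
                categ_lines.extend(risk_categorization_lines(model, mdr_matrix))

        # ---- stage: reports -------------------------------------------
        for k, rows in model_rows.items():
            pd.DataFrame(rows).to_csv(out / f"models_k{k}.tsv", sep="\t", index=False)
        pd.DataFrame(perm_rows).to_csv(out / "permutations.tsv", sep="\t", index=False)
        final = pd.DataFrame(final_rows)
        final.to_csv(out / "final_report.tsv", sep="\t", index=False)
        (out / "risk_categorization.txt").write_text("\n".join(categ_lines) + "\n")
        if km_frames:
            pd.concat(km_frames).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        meta = {"seed": config.seed, "config_hash": config.config_hash()}
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
        log.info("run complete")
        return {"final_report": final, "qc_report": qc_report, "meta": meta}
    except Exception as exc:  # partial outputs stay on disk for inspection
        log.error("pipeline stage failed: %s", exc)
        raise
    finally:
        root.removeHandler(fh)
        fh.close()


def _validate_and_report(
    network: str,
    model: MdrModel,
    perm_p: float,
    full_matrix: GenotypeMatrix,
    mdr_samples: pd.DataFrame,
    all_samples: pd.DataFrame,
    config: RunConfig,
    perm_rows: list,
    final_rows: list,
    km_frames: list,
) -> dict:
    labelled = ",".join(
        full_matrix.variants[full_matrix.column_index(s)].label for s in model.combo
    )
    perm_rows.append(
        {"network": network, "k": model.k, "combo": labelled, "p_value": perm_p}
    )
    row = {
        "network": network, "k": model.k, "snp_combo": labelled,
        "mean_TBA": round(model.tba, 4), "CVC": model.cvc,
        "sensitivity": round(model.sensitivity, 4),
        "specificity": round(model.specificity, 4),
        "permutation_p": perm_p,
    }
    if perm_p < config.permutation_alpha:
        # risk assignment on the full post-QC matrix so early-censored
        # samples re-enter the survival analysis to limit bias
        assignment = assign_risk(model, full_matrix)
        reg = fit_adjusted_logistic(assignment, mdr_samples)
        row.update(
            OR=round(reg.or_point, 3),
            CI=f"{reg.ci_low:.3f} - {reg.ci_high:.3f}",
            regression_p=f"{reg.p_value:.3E}",
        )
        if {"time", "event"}.issubset(all_samples.columns):
            surv = km_logrank(assignment, all_samples[all_samples["sample_id"].isin(
                assignment.groups.index)])
            for g, curve in surv.curves.items():
                c = curve.copy()
                c.insert(0, "group", g)
                c.insert(0, "combo", labelled)
                c.insert(0, "network", network)
                km_frames.append(c)
            row["logrank_p"] = f"{surv.p_value:.3E}"
    else:
        # dash convention: permutation-non-significant models get no regression
        row.update(OR="-", CI="-", regression_p="-")
        if {"time", "event"}.issubset(all_samples.columns):
            row["logrank_p"] = "-"
    final_rows.append(dict(row))
    return row
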