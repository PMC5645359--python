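"""End-to-end orchestration of the comparative analysis.

``run_pipeline`` executes, from one :class:`~sticomics.io.RunConfig`:

1. synthetic-data generation (or loading from configured paths),
2. size-factor normalization and log transform,
3. STIC vs NOSTIC class comparison (mRNA and miRNA) with BH FDR,
4. subtype assignment with the 0.2-floor / 1.5x-ratio rule,
5. tissue-of-origin signature derivation and Spearman matching,
6. region-level copy-number frequency comparison,
7. the power-by-simulation table,

and writes every stage's table to the output directory together with a
machine-readable ``summary.json`` (deterministic for a fixed config and
seed; no timestamps) and a ``run.log`` recording seed and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as _io
from .de import GroupComparison
from .matrix import ExpressionMatrix
from .origin import TissueOriginModel, count_tissue_de
from .power import PowerSimConfig, PowerSimulation
from .preprocess import log_normalize, size_factors, total_count_factors
from .scna import RegionFrequencyComparison
from .simulate import (
    TISSUES,
    CohortConfig,
    MirnaConfig,
    NormalPoolConfig,
    ScnaConfig,
    generate_copy_number,
    generate_mirna_counts,
    generate_normal_pools,
    generate_tumor_expression,
    generate_tumors_from_tissue,
    segments_from_calls,
)
from .subtype import SubtypeClassifier

__all__ = ["run_pipeline"]

logger = logging.getLogger("sticomics")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _normalized(matrix: ExpressionMatrix, mirna: bool = False) -> ExpressionMatrix:
    factors = total_count_factors(matrix) if mirna else size_factors(matrix)
    return log_normalize(matrix, factors)


def run_pipeline(config: _io.RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "parameters": _resolved_parameters(config)}
    try:
        logger.info("run starting: seed=%d outdir=%s", config.seed, outdir)
        logger.info("resolved parameters: %s", json.dumps(summary["parameters"], sort_keys=True))

        # ---- inputs -------------------------------------------------
        synth = config.synthetic or {}
        seed = config.seed
        if "matrix" in config.paths:
            cohort_matrix = _io.read_expression(config.paths["matrix"])
            ann = _io.read_annotations(config.paths["annotations"])
            cohort_matrix = ExpressionMatrix(
                cohort_matrix.values, state=cohort_matrix.state, annotations=ann
            )
            de_truth: list[str] = []
        else:
            cohort = _gen_cohort(synth.get("cohort", {}), seed)
            cohort_matrix = cohort.matrix
            de_truth = cohort.de_genes
            _io.write_expression(cohort_matrix, outdir / "expression.tsv")
            _io.write_annotations(cohort_matrix.annotations, outdir / "annotations.tsv")
            _io.write_gene_list(cohort.signature_genes, outdir / "subtype_signature.txt")

        # ---- normalize + class comparison (mRNA) --------------------
        logn = _stage("normalize")(_normalized)(cohort_matrix)
        de_res = _stage("class_comparison")(
            lambda: GroupComparison(logn).fit()
        )()
        de_res.to_tsv(outdir / "de_results.tsv")
        n_raw, n_fdr = de_res.count_significant(config.raw_p, config.fdr)
        summary["class_comparison"] = {
            "n_genes": len(de_res.table),
            "n_raw_p_significant": n_raw,
            "n_bh_significant": n_fdr,
            "raw_p_cut": config.raw_p,
            "fdr_cut": config.fdr,
            "n_true_de_genes": len(de_truth),
        }
        logger.info("class comparison: %s", summary["class_comparison"])

        # ---- miRNA class comparison ---------------------------------
        mirna = _gen_mirna(synth.get("mirna", {}), seed)
        mlog = _stage("normalize_mirna")(_normalized)(mirna.matrix, mirna=True)
        mres = _stage("class_comparison_mirna")(lambda: GroupComparison(mlog).fit())()
        mres.to_tsv(outdir / "mirna_de_results.tsv")
        m_raw, m_fdr = mres.count_significant(config.raw_p, config.fdr)
        summary["mirna_comparison"] = {
            "n_mirnas": len(mres.table),
            "n_raw_p_significant": m_raw,
            "n_bh_significant": m_fdr,
            "n_true_de": len(mirna.de_genes),
        }

        # ---- subtype assignment ------------------------------------
        if "signature" in config.paths:
            signature_genes = _io.read_gene_list(config.paths["signature"])
        elif "matrix" not in config.paths:
            signature_genes = cohort.signature_genes
        else:
            signature_genes = []
        has_subtype = logn.annotations is not None and "subtype" in logn.annotations.columns
        subtype_labels = logn.annotation("subtype") if has_subtype else None
        if subtype_labels is not None and signature_genes:
            clf = _stage("subtype")(SubtypeClassifier.from_reference)(
                logn, subtype_labels, signature_genes, floor=config.floor, ratio=config.ratio
            )
            sub_res = clf.assign_cohort(logn)
            sub_res.to_tsv(outdir / "subtype_assignments.tsv")
            counts = sub_res.counts()
            correct = sum(
                1
                for a in sub_res.assignments
                if a.call == subtype_labels.loc[a.sample]
            )
            summary["subtype_assignment"] = {
                "counts": {str(k): int(v) for k, v in counts.items()},
                "n_assigned": int(counts.drop("UNASSIGNED").sum()),
                "n_matching_generating_subtype": correct,
            }
            logger.info("subtype assignment: %s", summary["subtype_assignment"])

        # ---- tissue of origin --------------------------------------
        normals = _gen_normals(synth.get("normals", {}), seed)
        nlog = _stage("normalize_normals")(_normalized)(normals.matrix)
        origin_model = _stage("origin_fit")(
            lambda: TissueOriginModel(nlog, top_n=config.top_n).fit()
        )()
        de_counts = count_tissue_de(nlog, alpha=config.fdr)
        origin_cfg = dict(synth.get("origin", {}))
        mix = origin_cfg.pop("origin_mix", {"FT": 0.88, "OSE": 0.12, "PER": 0.0})
        labels = normals.tissues
        proto_full = pd.DataFrame(
            {t: nlog.values.loc[:, (labels == t).to_numpy()].mean(axis=1) for t in TISSUES}
        )
        tumors = generate_tumors_from_tissue(proto_full, mix, seed=seed + 1, **origin_cfg)
        origin_res = _stage("origin_match")(origin_model.match)(tumors)
        origin_res.to_tsv(outdir / "origin_assignments.tsv")
        k, n, prop, (lo, hi) = origin_res.ft_better_than_ovary()
        summary["tissue_of_origin"] = {
            "tissue_de_counts": {t: int(v) for t, v in de_counts.items()},
            "n_signature_genes": len(origin_model.signature.combined),
            "mean_rho": {t: round(float(v), 4) for t, v in origin_res.mean_rho().items()},
            "ft_better_than_ovary": {
                "k": k,
                "n": n,
                "percent": round(100 * prop, 1),
                "ci95_percent": [round(100 * lo, 1), round(100 * hi, 1)],
            },
        }
        logger.info("tissue of origin: %s", summary["tissue_of_origin"])

        # ---- copy number -------------------------------------------
        if "seg" in config.paths and "regions" in config.paths:
            segs = _io.read_seg(config.paths["seg"])
            regions = _io.read_regions(config.paths["regions"])
            from .scna import call_regions

            calls = call_regions(segs, regions)
            groups = _io.read_annotations(config.paths["scna_annotations"])["group"]
        else:
            scna = _gen_scna(synth.get("scna", {}), seed)
            calls, groups = scna.calls, scna.groups
            _io.write_seg(segments_from_calls(calls), outdir / "segments.seg")
            _io.write_region_calls(calls, outdir / "region_calls.tsv")
        scna_res = _stage("scna")(lambda: RegionFrequencyComparison(calls, groups).fit())()
        scna_res.table.to_csv(outdir / "scna_results.tsv", sep="\t")
        summary["scna_comparison"] = {
            "n_regions": len(scna_res.table),
            "n_bh_significant": scna_res.n_significant(config.fdr),
        }

        # ---- power --------------------------------------------------
        power_cfg = PowerSimConfig(**{"reps": 5, **config.power, "seed": seed})
        power_res = _stage("power")(PowerSimulation(power_cfg).run)()
        power_res.to_tsv(outdir / "power_table.tsv")
        summary["power"] = {
            "grid": [
                {
                    "effect_sd": float(r.effect_sd),
                    "n_per_group": int(r.n_per_group),
                    "sensitivity": round(float(r.sensitivity), 4),
                    "realized_fdr": round(float(r.realized_fdr), 4),
                }
                for r in power_res.table.itertuples(index=False)
            ],
            "reps": power_cfg.reps,
        }

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("run complete")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _resolved_parameters(config: _io.RunConfig) -> dict:
    params = asdict(config)
    # the output location is run metadata (in the log), not an analysis
    # parameter; leaving it out keeps summaries byte-identical across dirs
    params.pop("outdir", None)
    params["synthetic"] = {
        "cohort": asdict(_gen_config(CohortConfig, config.synthetic.get("cohort", {}), config.seed)),
        "normals": asdict(
            _gen_config(NormalPoolConfig, config.synthetic.get("normals", {}), config.seed)
        ),
        "mirna": asdict(_gen_config(MirnaConfig, config.synthetic.get("mirna", {}), config.seed)),
        "scna": asdict(_gen_config(ScnaConfig, config.synthetic.get("scna", {}), config.seed)),
        "origin": config.synthetic.get("origin", {}),
    }
    return params


def _gen_config(cls, overrides: dict, seed: int):
    return cls(**{**overrides, "seed": overrides.get("seed", seed)})


def _gen_cohort(overrides: dict, seed: int):
    return generate_tumor_expression(_gen_config(CohortConfig, overrides, seed))


def _gen_normals(overrides: dict, seed: int):
    return generate_normal_pools(_gen_config(NormalPoolConfig, overrides, seed))


def _gen_mirna(overrides: dict, seed: int):
    return generate_mirna_counts(_gen_config(MirnaConfig, overrides, seed))


def _gen_scna(overrides: dict, seed: int):
    return generate_copy_number(_gen_config(ScnaConfig, overrides, seed))
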