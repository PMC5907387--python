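"""End-to-end orchestration of the intervention analysis.

A single YAML-able config drives the fixed DAG: simulate (or ingest) a paired study,
ordinate (PCoA + PERMANOVA), compute paired baseline-to-post shifts and subgroup
comparisons, taxon-set ratio tests, per-taxon censored Gehan tests, prevalence tests,
the co-abundance network, the diet classifier, and optionally a strain-level SNP
analysis.  Each stage owns a named seed derived from the run seed, logs its inputs and
row counts, and writes TSV/JSON artifacts plus one machine-readable summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import censored, classify, composition, network, simulate, strains

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

_STAGE_SEED_OFFSETS = {
    "simulate": 1,
    "ordinate": 2,
    "shifts": 3,
    "ratio": 4,
    "intervention": 5,
    "prevalence": 6,
    "network": 7,
    "classify": 8,
    "strain": 9,
}


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _stage(config: Mapping[str, Any], name: str) -> dict:
    return dict(config.get("stages", {}).get(name, {}))


def _enabled(config: Mapping[str, Any], name: str) -> bool:
    return bool(_stage(config, name).get("enabled", True))


def _stage_seed(config: Mapping[str, Any], name: str) -> int:
    return (int(config.get("seed", 0)) * 1000 + _STAGE_SEED_OFFSETS[name]) % (2**31)


def _load_inputs(config: Mapping[str, Any]) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    if ("simulate" in config) == ("inputs" in config):
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        sim_cfg.setdefault("seed", _stage_seed(config, "simulate"))
        study = simulate.simulate_study(simulate.StudyConfig(**sim_cfg))
        return study.abundance, study.metadata, study.truth
    paths = config["inputs"]
    for key in ("abundance", "metadata"):
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"input file for '{key}' not found: {paths[key]}")
    abundance = pd.read_csv(paths["abundance"], sep="\t", index_col=0)
    metadata = pd.read_csv(paths["metadata"], sep="\t")
    return abundance, metadata, {}


def run_pipeline(config: Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns the summary dict.

    Artifacts are written under ``outdir`` (or ``config['outdir']``) when given; on
    failure, files this run created are removed so no partial bundle survives.
    """
    out = Path(outdir or config.get("outdir", ".")) if (outdir or config.get("outdir")) else None
    if out is None:
        return _run_stages(config, None)
    out.mkdir(parents=True, exist_ok=True)
    pre_existing = set(out.iterdir())
    try:
        return _run_stages(config, out)
    except Exception:
        for stale in set(out.iterdir()) - pre_existing:
            if stale.is_file():
                stale.unlink()
        raise


def _run_stages(config: Mapping[str, Any], out: Path | None) -> dict:

    abundance, metadata, truth = _load_inputs(config)
    logger.info("loaded %d features x %d samples", *abundance.shape)
    detection_limit = config.get("simulate", {}).get(
        "detection_limit", config.get("detection_limit", 2e-5)
    )

    summary: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_features": int(abundance.shape[0]),
        "n_samples": int(abundance.shape[1]),
        "detection_limit": detection_limit,
        "stages": {},
    }
    if out is not None:
        abundance.to_csv(out / "abundance.tsv", sep="\t")
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        if truth:
            (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    post_meta = metadata[metadata.timepoint == "post"].set_index("sample_id")
    dogs_by_diet = {
        d: sorted(post_meta.index[post_meta.diet == d]) for d in post_meta.diet.unique()
    }

    if _enabled(config, "ordinate"):
        params = _stage(config, "ordinate")
        logmat = composition.log_transform(abundance, shift_to_nonnegative=True)
        dmat = composition.distance_matrix(logmat, metric="bray_curtis")
        coords, evals = composition.pcoa(dmat, k=int(params.get("k", 2)))
        labels = metadata.set_index("sample_id").loc[dmat.index, "diet"]
        f_stat, p = composition.permanova(
            dmat,
            labels,
            n_permutations=int(params.get("n_permutations", 999)),
            seed=_stage_seed(config, "ordinate"),
        )
        summary["stages"]["ordinate"] = {
            "permanova_F": f_stat,
            "permanova_p": p,
            "top_eigenvalues": [float(e) for e in evals[:5]],
        }
        if out is not None:
            coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            dmat.to_csv(out / "distances.tsv", sep="\t")
        logger.info("ordinate: PERMANOVA F=%.3f p=%.4g over %d samples", f_stat, p, len(labels))

    shifts = None
    if _enabled(config, "shifts"):
        shifts = composition.paired_shift(abundance, metadata)
        comparisons: dict[str, Any] = {}
        if {"HPLC", "LPHC"} <= set(shifts.diet):
            stat, p = composition.compare_shift_groups(
                shifts, shifts.diet == "HPLC", shifts.diet == "LPHC"
            )
            comparisons["HPLC_vs_LPHC"] = {
                "p": p,
                "median_HPLC": float(shifts.loc[shifts.diet == "HPLC", "shift"].median()),
                "median_LPHC": float(shifts.loc[shifts.diet == "LPHC", "shift"].median()),
            }
        subgroup_medians = {
            f"{diet}/{cond}": float(g["shift"].median())
            for (diet, cond), g in shifts.groupby(["diet", "condition"])
        }
        comparisons["subgroup_medians"] = subgroup_medians
        comparisons["largest_subgroup"] = max(subgroup_medians, key=subgroup_medians.get)
        hplc_ow = (shifts.diet == "HPLC") & (shifts.condition == "OW")
        if hplc_ow.any() and (~hplc_ow).any():
            _, p = composition.compare_shift_groups(shifts, hplc_ow, ~hplc_ow)
            comparisons["HPLC_OW_vs_rest"] = {"p": p}
        summary["stages"]["shifts"] = comparisons
        if out is not None:
            shifts.to_csv(out / "paired_shifts.tsv", sep="\t", index=False)
        logger.info("shifts: %d paired dogs", len(shifts))

    if _enabled(config, "ratio") and "ratio" in config.get("stages", {}):
        params = _stage(config, "ratio")
        groups = {
            diet: [
                s
                for s in abundance.columns
                if metadata.set_index("sample_id").loc[s, "diet"] == diet
            ]
            for diet in metadata.diet.unique()
        }
        res = composition.ratio_test(
            abundance, params["numerator"], params["denominator"], groups
        )
        summary["stages"]["ratio"] = {
            "test": res["test"],
            "p_value": res["p_value"],
            "group_medians": {g: float(np.median(v)) for g, v in res["groups"].items()},
        }

    if _enabled(config, "intervention") and {"HPLC", "LPHC"} <= set(dogs_by_diet):
        params = _stage(config, "intervention")
        meta_idx = metadata.set_index("sample_id")
        dogs = [
            meta_idx.loc[s, "dog_id"]
            for d in ("HPLC", "LPHC")
            for s in dogs_by_diet[d]
        ]
        base_cols, post_cols, group = [], [], {}
        for dog in dogs:
            sub = metadata[metadata.dog_id == dog]
            base_cols.append(sub.loc[sub.timepoint == "baseline", "sample_id"].item())
            post_cols.append(sub.loc[sub.timepoint == "post", "sample_id"].item())
            group[dog] = sub.loc[sub.timepoint == "post", "diet"].item()
        baseline = abundance[base_cols].set_axis(dogs, axis=1)
        post = abundance[post_cols].set_axis(dogs, axis=1)
        results = censored.censored_ratio_table(
            baseline,
            post,
            pd.Series(group),
            detection_limit=detection_limit,
            n_permutations=int(params.get("n_permutations", 999)),
            seed=_stage_seed(config, "intervention"),
        )
        top = results.dropna(subset=["p_value"]).nsmallest(10, "p_value")
        summary["stages"]["intervention"] = {
            "n_features_tested": int(results["p_value"].notna().sum()),
            "n_significant": int(results.get("significant", pd.Series(dtype=bool)).sum()),
            "top_hits": [
                {"feature": f, "statistic": float(r.statistic), "p": float(r.p_value), "q": float(r.q_value)}
                for f, r in top.iterrows()
            ],
        }
        if out is not None:
            results.to_csv(out / "censored_ratio_tests.tsv", sep="\t")
        logger.info("intervention: %d features tested", len(results))

    if _enabled(config, "prevalence"):
        presence = abundance >= detection_limit
        diet_labels = metadata.set_index("sample_id").loc[presence.columns, "diet"]
        prev = censored.prevalence_test(presence, diet_labels)
        summary["stages"]["prevalence"] = {
            "n_tests": len(prev),
            "n_significant": int(prev.significant.sum()),
            "significant": prev.loc[prev.significant, ["taxon", "comparison", "p_bonferroni"]]
            .to_dict("records"),
        }
        if out is not None:
            prev.to_csv(out / "prevalence_tests.tsv", sep="\t", index=False)

    if _enabled(config, "network"):
        params = _stage(config, "network")
        net = network.build_network(
            abundance,
            r_threshold=float(params.get("r_threshold", 0.5)),
            fdr=float(params.get("fdr", 0.05)),
            n_permutations=int(params.get("n_permutations", 99)),
            seed=_stage_seed(config, "network"),
        )
        components, sums = network.network_groups(net, abundance)
        multi = [sorted(c) for c in components if len(c) > 1]
        summary["stages"]["network"] = {
            "n_edges": net.number_of_edges(),
            "n_groups": len(multi),
            "groups": multi,
        }
        if out is not None:
            network.write_edge_list(net, out / "network_edges.tsv")
            if sums is not None and not sums.empty:
                sums.to_csv(out / "network_group_abundance.tsv", sep="\t")
        logger.info("network: %d edges, %d multi-node groups", net.number_of_edges(), len(multi))

    if _enabled(config, "classify") and {"HPLC", "LPHC"} <= set(dogs_by_diet):
        params = _stage(config, "classify")
        cols = dogs_by_diet["HPLC"] + dogs_by_diet["LPHC"]
        labels = post_meta.loc[cols, "diet"]
        report = classify.loo_classify(
            abundance[cols],
            labels,
            seed=_stage_seed(config, "classify"),
            **{k: v for k, v in params.items() if k in ("penalty", "inner_folds")},
        )
        summary["stages"]["classify"] = {
            "auc": report.auc,
            "n_samples": len(cols),
            "accuracy": float((report.predicted_labels == report.true_labels).mean()),
        }
        if out is not None:
            report.roc.to_csv(out / "roc.tsv", sep="\t", index=False)
            (out / "classification.json").write_text(
                json.dumps(report.to_json_dict(), indent=2, sort_keys=True)
            )
        logger.info("classify: AUC=%.3f on %d post samples", report.auc, len(cols))

    if _enabled(config, "strain") and "strain" in config.get("stages", {}):
        params = _stage(config, "strain")
        freqs, hosts = simulate.simulate_allele_freqs(
            n_group_a=int(params.get("n_group_a", 10)),
            n_group_b=int(params.get("n_group_b", 10)),
            n_positions=int(params.get("n_positions", 200)),
            within_sd=float(params.get("within_sd", 0.05)),
            between_shift=float(params.get("between_shift", 0.3)),
            seed=_stage_seed(config, "strain"),
        )
        coords, evals, pairs = strains.strain_pcoa(
            freqs, hosts, min_shared=int(params.get("min_shared", 50))
        )
        summary["stages"]["strain"] = {
            "mean_within_host_distance": float(pairs.loc[pairs.same_host, "distance"].mean()),
            "mean_cross_host_distance": float(pairs.loc[~pairs.same_host, "distance"].mean()),
        }
        if out is not None:
            coords.to_csv(out / "strain_pcoa.tsv", sep="\t")
            pairs.to_csv(out / "strain_pairs.tsv", sep="\t", index=False)

    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
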