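"""End-to-end `report` runner: simulate -> score -> describe -> associate -> survive."""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..association import (assign_hr_groups, group_contrast, differential_prevalence,
                           multivariate_fit, mutual_exclusivity, univariate_screen)
from ..cohort_stats import (classify_gloh_high, find_inflection_point,
                            summarize_cohort, summarize_distribution)
from ..errors import NoInflectionError
from ..genome import default_genome
from ..gloh import EngineConfig, run_gloh
from ..survival import run_survival_analysis
from ..synthetic_data import (CohortSpec, SurvivalSpec, make_snp_panel,
                              plant_profile_for_gloh, simulate_cohort,
                              simulate_sample, simulate_survival,
                              cohort_to_alteration_table)
from .config import RunConfig, RunManifest
from .writers import (write_alteration_table, write_cohort_table,
                      write_gloh_report, write_seg_table, write_snp_observations,
                      write_survival_table)

STAGES = ("simulate", "gloh", "cohort", "associate", "survive")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0]) for name, child in zip(STAGES, children)}


def run_report(config: RunConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute the full synthetic-data chain and write the report bundle."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(config_hash=config.config_hash, package_version=__version__,
                           seed=config.seed)
    genome = default_genome()

    # --- simulate: cohort tables ------------------------------------------
    t0 = time.perf_counter()
    spec = CohortSpec(n_samples=config.n_samples, seed=seeds["simulate"])
    cohort = simulate_cohort(spec)
    alterations = cohort_to_alteration_table(cohort)
    cohort_path = out / "cohort.tsv"
    alt_path = out / "alterations.tsv"
    write_cohort_table(cohort, cohort_path)
    write_alteration_table(alterations, alt_path)
    manifest.add_stage("simulate", {"cohort": cohort_path, "alterations": alt_path},
                       time.perf_counter() - t0)

    # --- gloh: demonstrate the per-sample engine on a few genomes ---------
    t0 = time.perf_counter()
    panel = make_snp_panel(genome, config.panel_size, seed=seeds["gloh"])
    engine_cfg = EngineConfig(min_snps=config.min_snps,
                              margin_threshold=config.margin_threshold,
                              arm_span_threshold=config.arm_span_threshold)
    gloh_files = {}
    for i in range(config.n_gloh_demo_samples):
        planted = plant_profile_for_gloh(genome, target_gloh=15.0 + 10.0 * i,
                                         seed=seeds["gloh"] + i + 1)
        sim = simulate_sample(genome, panel, planted, purity=0.7,
                              depth_mean=config.depth_mean,
                              seed=seeds["gloh"] + 1000 + i,
                              sample_id=f"demo{i}")
        result, profile = run_gloh(sim.obs, sim.ref_depth, genome, engine_cfg)
        snp_path = out / f"demo{i}.snps.tsv"
        seg_path = out / f"demo{i}.segments.tsv"
        rep_path = out / f"demo{i}.gloh.json"
        write_snp_observations(sim.obs, snp_path)
        write_seg_table(profile.segments, seg_path, sample_id=profile.sample_id)
        write_gloh_report(result, profile, rep_path)
        gloh_files[f"demo{i}_snps"] = snp_path
        gloh_files[f"demo{i}_segments"] = seg_path
        gloh_files[f"demo{i}_report"] = rep_path
    manifest.add_stage("gloh", gloh_files, time.perf_counter() - t0)

    # --- cohort: distribution summary and cutoff classifications ----------
    t0 = time.perf_counter()
    gloh_values = cohort["gloh"].to_numpy()
    dist = summarize_distribution(gloh_values)
    cutoffs = {str(c): float(c) for c in config.cutoffs}
    inflection = None
    if config.use_inflection_cutoff:
        try:
            inflection = find_inflection_point(gloh_values)
            cutoffs["inflection"] = inflection.cutoff_percent
        except NoInflectionError:
            pass
    classifications = {
        label: asdict(classify_gloh_high(gloh_values, cutoff)) | {
            "fraction_high": classify_gloh_high(gloh_values, cutoff).fraction_high}
        for label, cutoff in cutoffs.items()
    }
    dist_path = out / "distribution.json"
    dist_path.write_text(json.dumps({
        "summary": asdict(dist),
        "cohort_summary": summarize_cohort(cohort),
        "inflection": None if inflection is None else asdict(inflection),
        "classifications": classifications,
    }, indent=2) + "\n")
    manifest.add_stage("cohort", {"distribution": dist_path}, time.perf_counter() - t0)

    # --- associate ---------------------------------------------------------
    t0 = time.perf_counter()
    hr_groups = assign_hr_groups(cohort, config.hr_genes)
    groups = {label: cohort.loc[hr_groups == label, "gloh"].to_numpy()
              for label in hr_groups.unique()}
    contrast = group_contrast(groups, seed=seeds["associate"])
    fits, candidates = univariate_screen(cohort, q_threshold=config.q_threshold,
                                         prevalence_threshold=config.prevalence_threshold)
    multi = multivariate_fit(cohort, candidates) if candidates else []
    uni_by_key = {f.key: f for f in fits}
    rows = []
    for f in multi:
        uni = uni_by_key.get(f.key)
        rows.append({
            "key": f.key,
            "prevalence": None if uni is None else round(uni.prevalence, 4),
            "uni_estimate": None if uni is None else round(uni.estimate, 3),
            "uni_ci_low": None if uni is None else round(uni.ci_low, 3),
            "uni_ci_high": None if uni is None else round(uni.ci_high, 3),
            "uni_p": None if uni is None else uni.p_value,
            "uni_q": None if uni is None else uni.q_value,
            "multi_estimate": round(f.estimate, 3),
            "multi_ci_low": round(f.ci_low, 3),
            "multi_ci_high": round(f.ci_high, 3),
            "multi_p": f.p_value,
        })
    assoc_table = pd.DataFrame(rows)
    assoc_path = out / "association.tsv"
    assoc_table.to_csv(assoc_path, sep="\t", index=False)
    prev_table = differential_prevalence(cohort)
    prev_path = out / "differential_prevalence.tsv"
    prev_table.to_csv(prev_path, sep="\t", index=False)
    contrast_path = out / "hr_contrast.json"
    contrast_path.write_text(json.dumps(asdict(contrast), indent=2) + "\n")
    excl_pairs = [("CDKN2A:homozygous_deletion", "RB1:homozygous_deletion"),
                  ("BRCA2:homozygous_deletion", "RB1:homozygous_deletion")]
    excl = mutual_exclusivity(cohort, excl_pairs)
    excl_path = out / "mutual_exclusivity.tsv"
    excl.to_csv(excl_path, sep="\t", index=False)
    manifest.add_stage("associate", {
        "association": assoc_path, "differential_prevalence": prev_path,
        "hr_contrast": contrast_path, "mutual_exclusivity": excl_path,
    }, time.perf_counter() - t0)

    # --- survive -----------------------------------------------------------
    t0 = time.perf_counter()
    sub = cohort.sample(n=min(config.survival_n, len(cohort)),
                        random_state=seeds["survive"] % (2**32)).reset_index(drop=True)
    surv_spec = SurvivalSpec(baseline_hazard=config.survival_baseline_hazard,
                             hr_gloh_high=config.survival_hr,
                             censoring_rate=config.survival_censoring_rate)
    records = simulate_survival(sub, surv_spec, seed=seeds["survive"])
    surv_path = out / "survival.tsv"
    write_survival_table(records, surv_path)
    fit = run_survival_analysis(records)
    km_rows = []
    for label, curve in fit.km_curves.items():
        for t, s, v in zip(curve.times, curve.survival, curve.variance):
            km_rows.append({"group": label, "time": t, "survival": s, "greenwood_var": v})
    km_path = out / "km_curves.tsv"
    pd.DataFrame(km_rows).to_csv(km_path, sep="\t", index=False)
    fit_path = out / "survival_fit.json"
    fit_path.write_text(json.dumps({
        "hr": fit.hr, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
        "p_value": fit.p_value, "logrank_p": fit.logrank_p,
        "median_cutoff": fit.median_cutoff,
    }, indent=2) + "\n")
    manifest.add_stage("survive", {"survival": surv_path, "km_curves": km_path,
                                   "fit": fit_path}, time.perf_counter() - t0)

    config.to_yaml(out / "config.yaml")
    manifest.write(out / "manifest.json")
    return manifest
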