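"""Canned end-to-end simulation experiments.

These wire the simulator, feature extraction, ensemble training and
evaluation together for the calibration studies the package ships:
held-out accuracy at a given tissue-profile separation, the chance
baseline at zero separation, and the point-mutation vs
point-mutation-plus-copy-number comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import SiteVoteForest
from .evaluation import EvaluationReport, evaluate_results, stratified_split
from .features import assemble_features
from .simulate import SimulationConfig, default_profiles, simulate_cohort

__all__ = ["HoldoutResult", "run_holdout_experiment", "pm_vs_pmcn_accuracies"]

PM_BLOCKS = ("gene_mut", "spec6", "spec96")
PMCN_BLOCKS = ("gene_mut", "spec6", "spec96", "gene_cn")


@dataclass
class HoldoutResult:
    accuracy: float
    n_test: int
    n_sites: int
    report: EvaluationReport


def run_holdout_experiment(
    k_sites: int,
    per_site: int,
    separation: float,
    seed: int,
    blocks: tuple[str, ...] = PM_BLOCKS,
    n_trees: int = 500,
    genome_length: int = 150_000,
    n_genes: int = 20,
    test_fraction: float = 0.2,
) -> HoldoutResult:
    """Simulate a cohort, train on a stratified split, evaluate held out.

    All randomness (simulation, split, forests) derives from ``seed``.
    """
    config = SimulationConfig(
        profiles=default_profiles(k_sites, separation, seed=seed, n_genes=n_genes),
        tumors_per_site=per_site,
        genome_length=genome_length,
        n_genes=n_genes,
        seed=seed,
        separation=separation,
    )
    cohort, ref, gene_model = simulate_cohort(config)
    fm = assemble_features(cohort, gene_model, ref, blocks=blocks)
    y = fm.site_labels.to_numpy()
    tr, te = stratified_split(y, test_fraction, seed=seed)
    model = SiteVoteForest(n_trees=n_trees, random_state=seed).fit(
        fm.values.iloc[tr], y[tr]
    )
    results = model.classify_samples(fm.values.iloc[te])
    report = evaluate_results(
        results, list(y[te]), train_frequencies=model.training_counts_
    )
    return HoldoutResult(
        accuracy=report.overall_accuracy,
        n_test=len(te),
        n_sites=k_sites,
        report=report,
    )


def pm_vs_pmcn_accuracies(
    seeds: list[int],
    k_sites: int = 3,
    per_site: int = 200,
    separation: float = 1.0,
    n_trees: int = 500,
    genome_length: int = 150_000,
    n_genes: int = 20,
) -> dict[str, list[float]]:
    """Held-out accuracy with and without the copy-number block, on the
    same simulated cohorts (CN-informative profiles), across seeds."""
    out: dict[str, list[float]] = {"pm": [], "pmcn": []}
    for seed in seeds:
        config = SimulationConfig(
            profiles=default_profiles(k_sites, separation, seed=seed, n_genes=n_genes),
            tumors_per_site=per_site,
            genome_length=genome_length,
            n_genes=n_genes,
            seed=seed,
            separation=separation,
        )
        cohort, ref, gene_model = simulate_cohort(config)
        y = np.asarray([s.site_label for s in cohort.samples], dtype=object)
        tr, te = stratified_split(y, 0.2, seed=seed)
        for name, blocks in (("pm", PM_BLOCKS), ("pmcn", PMCN_BLOCKS)):
            fm = assemble_features(cohort, gene_model, ref, blocks=blocks)
            model = SiteVoteForest(n_trees=n_trees, random_state=seed).fit(
                fm.values.iloc[tr], y[tr]
            )
            pred = model.predict(fm.values.iloc[te])
            out[name].append(float(np.mean(pred == y[te])))
    return out
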