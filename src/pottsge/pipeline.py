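"""End-to-end orchestration: fit a K grid, select K*, build the consensus
partition, summarise per-subject effects, optionally run the bootstrap
interaction test, and write all artifacts with a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .consensus import ConsensusPartition, consensus_partition
from .interaction_test import InteractionTestResult, resampling_test
from .io import RunConfig, load_study
from .mcmc import INTERACTION, CaseControlData, run_chain
from .model_selection import compute_dic, select_k_one_se, select_k_plus_one

__all__ = ["AnalysisResult", "fit_k_grid", "subject_effect_summary", "run_full_analysis"]


@dataclass
class AnalysisResult:
    """Everything a full run produces."""

    dic_table: pd.DataFrame
    k_plus_one: int
    k_one_se: Optional[int]
    partition: ConsensusPartition
    subject_summary: pd.DataFrame
    genotype_summary: pd.DataFrame
    interaction: Optional[InteractionTestResult]
    manifest: dict


def fit_k_grid(data: CaseControlData, config: RunConfig, model_form: str = INTERACTION):
    """Run ``n_runs`` chains per K; returns (dic_runs, samples of last run per K)."""
    dic_runs = {}
    samples_by_k = {}
    for k in sorted(set(config.k_grid)):
        dic_runs[k] = []
        for r in range(config.n_runs):
            seed = (config.seed + 1009 * k + 9176 * r) % 2**31
            cfg = replace(config.chain, K=k, model_form=model_form, seed=seed)
            samples = run_chain(data, cfg)
            dic_runs[k].append(compute_dic(samples, data).dic)
            samples_by_k[k] = samples
    return dic_runs, samples_by_k


def subject_effect_summary(samples, data: CaseControlData) -> tuple:
    """Posterior-median effect summaries per genotype and per subject.

    The exposure effect is summarised as the posterior median of the
    assigned log odds ratio (and its exponential).  Intercepts are reported
    as odds ratios against the reference genotype — the one with the lowest
    posterior-median intercept — since only intercept contrasts are
    identified under case-control sampling.
    """
    g_alpha = np.median(samples.genotype_coefficient_draws("alpha"), axis=0)
    g_beta = np.median(samples.genotype_coefficient_draws("beta"), axis=0)
    ref = int(np.argmin(g_alpha))
    genotype_summary = pd.DataFrame(
        {
            "genotype_id": np.arange(len(g_alpha)),
            "n_subjects": data.table.counts,
            "alpha_median": g_alpha,
            "intercept_or_vs_ref": np.exp(g_alpha - g_alpha[ref]),
            "beta_median": g_beta,
            "exposure_or": np.exp(g_beta),
        }
    )
    c = data.genotype_id
    subject_summary = pd.DataFrame(
        {
            "subject": np.arange(data.n),
            "disease": data.D.astype(int),
            "exposure": data.E,
            "genotype_id": c,
            "alpha_median": g_alpha[c],
            "intercept_or_vs_ref": np.exp(g_alpha[c] - g_alpha[ref]),
            "beta_median": g_beta[c],
            "exposure_or": np.exp(g_beta[c]),
        }
    )
    return genotype_summary, subject_summary


def run_full_analysis(
    config: RunConfig, data: Optional[CaseControlData] = None
) -> AnalysisResult:
    """The fit -> select K -> consensus -> summarise [-> test] workflow.

    When ``data`` is omitted it is loaded from the paths in ``config``.
    All artifacts are written under ``config.out_dir`` together with a
    manifest (config echo, package version, content hashes).
    """
    if data is None:
        data, rejected = load_study(
            config.genotype_path,
            config.phenotype_path,
            disease_col=config.disease_col,
            exposure_col=config.exposure_col,
            covariate_cols=config.covariate_cols,
            n_neighbors=config.n_neighbors,
        )
    else:
        rejected = []

    dic_runs, samples_by_k = fit_k_grid(data, config)
    means = {k: float(np.mean(v)) for k, v in dic_runs.items()}
    k_plus_one = select_k_plus_one(means)
    k_one_se = select_k_one_se(dic_runs) if config.n_runs >= 2 else None
    k_star = k_one_se if k_one_se is not None else k_plus_one

    samples = samples_by_k[k_star]
    partition = consensus_partition(samples, k_star, data=data, seed=config.seed)
    genotype_summary, subject_summary = subject_effect_summary(samples, data)

    dic_table = pd.DataFrame(
        [
            {"K": k, "run": r, "DIC": dic}
            for k, runs in dic_runs.items()
            for r, dic in enumerate(runs)
        ]
    )

    interaction = None
    grid2 = [k for k in config.k_grid if k >= 2]
    if config.bootstrap_B > 0 and grid2:
        interaction = resampling_test(
            data,
            grid2,
            config.chain,
            B=config.bootstrap_B,
            rng=np.random.default_rng(config.seed + 1),
        )

    manifest = _write_artifacts(
        config, data, dic_table, k_plus_one, k_one_se, partition,
        genotype_summary, subject_summary, interaction, rejected,
    )
    return AnalysisResult(
        dic_table=dic_table,
        k_plus_one=k_plus_one,
        k_one_se=k_one_se,
        partition=partition,
        subject_summary=subject_summary,
        genotype_summary=genotype_summary,
        interaction=interaction,
        manifest=manifest,
    )


def _write_artifacts(config, data, dic_table, k_plus_one, k_one_se, partition,
                     genotype_summary, subject_summary, interaction, rejected):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dic_table.to_csv(out / "dic.tsv", sep="\t", index=False)
    np.savetxt(out / "coassignment.tsv", partition.coassign, delimiter="\t", fmt="%.6f")
    pd.DataFrame(
        {"genotype_id": np.arange(len(partition.labels)), "cluster": partition.labels + 1}
    ).to_csv(out / "genotype_clusters.tsv", sep="\t", index=False)
    genotype_summary.to_csv(out / "genotype_summary.tsv", sep="\t", index=False)
    subject_summary.assign(cluster=partition.subject_labels + 1).to_csv(
        out / "subject_summary.tsv", sep="\t", index=False
    )

    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "n_subjects": int(data.n),
        "n_cases": int(data.n_cases),
        "n_genotypes": int(data.table.n_genotypes),
        "k_plus_one": int(k_plus_one),
        "k_one_se": (int(k_one_se) if k_one_se is not None else None),
        "rejected_rows": [list(map(str, r)) for r in rejected],
        "artifact_sha256": {},
    }
    if interaction is not None:
        manifest["interaction_test"] = {
            "p_obs": interaction.p_obs,
            "statistic": interaction.statistic,
            "df": interaction.df,
            "p_value": interaction.p_value,
            "B": interaction.B,
            "k1_star": interaction.k1_star,
            "k0_star": interaction.k0_star,
        }
        with open(out / "interaction_test.json", "w") as fh:
            json.dump(
                {**manifest["interaction_test"],
                 "bootstrap_stats": interaction.bootstrap_stats.tolist()},
                fh, indent=1,
            )
    for f in sorted(out.glob("*.tsv")):
        manifest["artifact_sha256"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
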