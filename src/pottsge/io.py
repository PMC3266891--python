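"""Reading and writing study files.

Genotypes arrive as delimited text with subject ids in the first column and
one 0/1/2-coded column per SNP (a PLINK .raw-style additive file is accepted
by the same reader); phenotypes as a delimited table with the disease
status, the exposure and any covariates.  The two are joined on subject id.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_space import build_genotype_table, build_neighbor_graph, genotype_distance
from .mcmc import CaseControlData, ChainConfig

__all__ = ["RunConfig", "load_study", "read_genotypes", "read_phenotypes", "write_study"]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    genotype_path: str = ""
    phenotype_path: str = ""
    disease_col: str = "disease"
    exposure_col: str = "exposure"
    covariate_cols: List[str] = field(default_factory=list)
    k_grid: List[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    n_runs: int = 1
    bootstrap_B: int = 0
    n_neighbors: int = 4
    seed: int = 0
    out_dir: str = "pottsge_out"
    chain: ChainConfig = field(default_factory=ChainConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        chain_kw = raw.pop("chain", {})
        cfg = cls(**raw)
        cfg.chain = ChainConfig(**chain_kw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_genotypes(path):
    """(subject_ids, snp_names, n x J code matrix) from a delimited file."""
    df = _read_table(path)
    if list(df.columns[: len(_PLINK_META)]) == _PLINK_META:
        ids = df["IID"].astype(str).to_numpy()
        geno = df.drop(columns=_PLINK_META)
    else:
        ids = df.iloc[:, 0].astype(str).to_numpy()
        geno = df.iloc[:, 1:]
    return ids, list(geno.columns), geno.to_numpy()


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path)
    df = df.rename(columns={df.columns[0]: "subject_id"})
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def load_study(
    genotype_path,
    phenotype_path,
    disease_col: str = "disease",
    exposure_col: str = "exposure",
    covariate_cols: Optional[Sequence[str]] = None,
    n_neighbors: int = 4,
) -> tuple:
    """Join genotype and phenotype files into a validated dataset.

    Rows with missing required fields are dropped and reported.  Returns
    (CaseControlData, report) where ``report`` lists the subject ids
    rejected and why.
    """
    covariate_cols = list(covariate_cols or [])
    ids, snp_names, G = read_genotypes(genotype_path)
    pheno = read_phenotypes(phenotype_path)
    for col in [disease_col, exposure_col] + covariate_cols:
        if col not in pheno.columns:
            raise KeyError(f"phenotype file has no column {col!r}")
    gdf = pd.DataFrame(G, columns=snp_names)
    gdf.insert(0, "subject_id", ids)
    merged = gdf.merge(pheno, on="subject_id", how="inner", validate="one_to_one")
    if merged.empty:
        raise ValueError("no subject ids shared between genotype and phenotype files")
    if len(merged) < len(gdf):
        missing = sorted(set(ids) - set(merged["subject_id"]))
        raise ValueError(f"subject ids missing from phenotype file: {missing[:5]}...")

    required = snp_names + [disease_col, exposure_col] + covariate_cols
    report = []
    bad = merged[required].isna().any(axis=1)
    for _, row in merged[bad].iterrows():
        null_cols = [c for c in required if pd.isna(row[c])]
        report.append((row["subject_id"], f"missing {','.join(null_cols)}"))
    merged = merged[~bad].reset_index(drop=True)

    D = merged[disease_col].to_numpy()
    if not set(np.unique(D)) <= {0, 1}:
        raise ValueError(f"disease column {disease_col!r} is not 0/1")
    E = merged[exposure_col].to_numpy(dtype=float)
    X = merged[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.zeros((len(merged), 0))
    Gm = merged[snp_names].to_numpy()

    table = build_genotype_table(Gm, snp_names=snp_names)
    graph = build_neighbor_graph(genotype_distance(table), n_neighbors=n_neighbors)
    data = CaseControlData(
        D=D.astype(np.int64),
        E=E,
        X=X,
        genotype_id=table.subject_index,
        table=table,
        graph=graph,
    )
    return data, report


def write_study(out_dir, subject_ids, snp_names, G, D, E, X=None, covariate_names=None,
                truth=None):
    """Write genotype/phenotype (and optional truth) files for a study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gdf = pd.DataFrame(np.asarray(G), columns=list(snp_names))
    gdf.insert(0, "subject_id", subject_ids)
    gdf.to_csv(out / "genotypes.tsv", sep="\t", index=False)

    pdf = pd.DataFrame({"subject_id": subject_ids, "disease": np.asarray(D),
                        "exposure": np.asarray(E)})
    if X is not None and np.size(X):
        X = np.atleast_2d(np.asarray(X))
        names = covariate_names or [f"x{j}" for j in range(X.shape[1])]
        for j, name in enumerate(names):
            pdf[name] = X[:, j]
    pdf.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=_jsonable)
    return out / "genotypes.tsv", out / "phenotypes.tsv"


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
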