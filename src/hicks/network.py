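"""Transcript-metabolite Pearson correlation networks.

Feature tables are pandas DataFrames (features x samples) with identical,
ordered sample columns. Edges connect a gene and a metabolite whose Pearson
r passes a threshold (|r| > 0.8 by default; a signed mode keeps only
positive correlations). Candidate genes for a focus metabolite set are those
whose r^2 exceeds a second, stricter threshold (0.96 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AlignmentError

__all__ = ["correlate", "top_candidates", "read_omics_tsv", "write_edges_tsv"]


def read_omics_tsv(path) -> pd.DataFrame:
    """Features-x-samples TSV with feature ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    return df


def _standardise(df: pd.DataFrame):
    """Row-standardised matrix and a boolean vector of non-constant rows."""
    x = df.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(x)
    np.divide(x - mu, sd, out=z, where=sd > 0)
    return z, ok


def correlate(
    genes: pd.DataFrame,
    metabolites: pd.DataFrame,
    threshold: float = 0.8,
    mode: str = "absolute",
) -> pd.DataFrame:
    """All (gene, metabolite) pairs whose Pearson r passes the threshold.

    ``mode="absolute"`` keeps |r| > threshold; ``mode="signed"`` keeps
    r > threshold only. Constant features yield no edges; their count is
    recorded in ``result.attrs["n_constant_skipped"]``. Requires identical
    ordered sample columns and at least 3 samples.
    """
    if list(genes.columns) != list(metabolites.columns):
        raise AlignmentError("sample columns differ between the two tables")
    if genes.shape[1] < 3:
        raise ValueError("insufficient data: need at least 3 samples")
    if mode not in ("absolute", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    if genes.index.has_duplicates or metabolites.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    zg, okg = _standardise(genes)
    zm, okm = _standardise(metabolites)
    n = genes.shape[1]
    r = zg @ zm.T / n
    np.clip(r, -1.0, 1.0, out=r)
    passing = np.abs(r) > threshold if mode == "absolute" else r > threshold
    passing &= okg[:, None] & okm[None, :]
    gi, mi = np.nonzero(passing)
    edges = pd.DataFrame(
        {
            "gene": genes.index.to_numpy()[gi],
            "metabolite": metabolites.index.to_numpy()[mi],
            "r": r[gi, mi],
        }
    )
    edges.attrs["n_constant_skipped"] = int((~okg).sum() + (~okm).sum())
    edges.attrs["threshold"] = threshold
    edges.attrs["mode"] = mode
    return edges


def top_candidates(
    edges: pd.DataFrame,
    focus_metabolites,
    r2_threshold: float = 0.96,
    require_all: bool = False,
) -> list:
    """Genes whose r^2 with a focus metabolite exceeds ``r2_threshold``.

    With ``require_all=True`` a gene must pass for *every* focus metabolite
    (intersection mode) instead of at least one.
    """
    focus = list(focus_metabolites)
    known = set(edges["metabolite"])
    unknown = [m for m in focus if m not in known]
    if unknown:
        raise KeyError(f"focus metabolites not in the edge universe: {unknown}")
    hits = {}
    sub = edges[edges["metabolite"].isin(focus)]
    strong = sub[sub["r"] ** 2 > r2_threshold]
    for m in focus:
        hits[m] = set(strong.loc[strong["metabolite"] == m, "gene"])
    sets = list(hits.values())
    result = set.intersection(*sets) if require_all else set.union(*sets)
    return sorted(result)


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    """Cytoscape-importable edge list: gene <tab> metabolite <tab> r."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.6f")
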