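"""Gene annotation of candidate regions and gene-set overrepresentation.

Coordinates are 1-based inclusive internally (Ensembl convention); BED
input is converted from 0-based half-open at the reader.  Overrepresentation
uses the upper-tail hypergeometric test with Benjamini-Hochberg correction
across gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["read_bed", "annotate_regions", "enrich"]


def read_bed(path) -> pd.DataFrame:
    """Gene annotation from BED (chrom, start, end, name[, score, strand]).

    BED is 0-based half-open; returned coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED file needs at least 4 columns (chrom,start,end,name)")
    out = pd.DataFrame(
        {
            "gene": df[3].astype(str),
            "chr": df[0].astype(str).str.removeprefix("chr"),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
        }
    )
    if (out["start"] > out["end"]).any():
        bad = out.loc[out["start"] > out["end"], "gene"].tolist()[:5]
        raise ValueError(f"invalid gene span(s): {bad}")
    return out


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes whose span overlaps each (already flanked) candidate region.

    Any overlap counts: the capture rule is agnostic to whether a gene
    merely touches the region boundary.  Region and annotation chromosome
    names must agree; disjoint name sets raise with the offenders listed.
    """
    if len(regions) == 0:
        return regions.assign(genes="")
    rchr = set(regions["chr"].astype(str))
    gchr = set(genes["chr"].astype(str))
    if not rchr & gchr:
        raise ValueError(
            f"chromosome naming mismatch: regions use {sorted(rchr)[:5]}, "
            f"annotation uses {sorted(gchr)[:5]}"
        )
    out = regions.copy()
    hits = []
    for _, r in regions.iterrows():
        sub = genes[
            (genes["chr"].astype(str) == str(r["chr"]))
            & (genes["start"] <= r["end"])
            & (genes["end"] >= r["start"])
        ]
        hits.append(",".join(sub["gene"].tolist()))
    out["genes"] = hits
    return out


def enrich(
    query: set[str] | list[str],
    gene_sets: pd.DataFrame | dict[str, set],
    background: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    p = P[X >= overlap] with X ~ Hypergeom(N=len(background),
    K=len(set & background), n=len(query)); BH-adjusted across sets.
    ``gene_sets`` is either a mapping set_id -> genes or a two-column
    (set_id, gene_id) table.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene list")
    query = set(query)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes missing from background: {extra}")
    if isinstance(gene_sets, pd.DataFrame):
        cols = list(gene_sets.columns[:2])
        mapping = {
            k: set(v) for k, v in gene_sets.groupby(cols[0])[cols[1]]
        }
    else:
        mapping = {k: set(v) for k, v in gene_sets.items()}
    N, n = len(background), len(query)
    rows = []
    for set_id, members in mapping.items():
        members = members & background
        k = len(members & query)
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set": set_id, "overlap": k, "set_size": K,
             "background_size": N, "query_size": n, "p": p}
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["p_adj"] <= alpha
        res = res.sort_values("p").reset_index(drop=True)
    return res
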