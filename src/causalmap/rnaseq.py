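"""RPKM quantification and two-group differential expression.

The stage mirrors a classical RNA-seq comparison of mutant versus WT
ovaries: counts are normalised to reads per kilobase of transcript per
million mapped reads (RPKM), genes with mean RPKM >= 1 in at least one group
are considered expressed, expressed genes are tested with per-gene Welch
t-tests on log2(RPKM + 1), p values are FDR-adjusted (Benjamini-Hochberg by
default, Bonferroni available), and genes are called up/down when
|log2 fold ratio| >= 1 with q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "compute_rpkm",
    "filter_expressed",
    "differential_test",
    "overlap_with_list",
]


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with lengths and group labels."""

    counts: pd.DataFrame
    lengths: pd.Series  # bp per gene
    groups: pd.Series   # sample -> group label
    planted: Optional[Dict[str, dict]] = None  # simulation truth, if any
    top_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths must share the same gene index")
        if set(self.counts.columns) != set(self.groups.index):
            raise ValueError("counts columns and group labels disagree")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def compute_rpkm(matrix: CountMatrix) -> pd.DataFrame:
    """RPKM = count / (gene length in kb x library size in millions).

    Library size is the per-sample column total of the count matrix; a
    zero-read library is an input error.
    """
    lib = matrix.counts.sum(axis=0)
    if (lib <= 0).any():
        empty = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {empty}")
    kb = matrix.lengths / 1_000.0
    millions = lib / 1_000_000.0
    return matrix.counts.div(kb, axis=0).div(millions, axis=1)


def filter_expressed(
    rpkm: pd.DataFrame,
    groups: pd.Series,
    threshold: float = 1.0,
) -> pd.Index:
    """Genes whose mean RPKM reaches *threshold* in at least one group."""
    keep = pd.Series(False, index=rpkm.index)
    for group in groups.unique():
        cols = groups.index[groups == group]
        keep |= rpkm[cols].mean(axis=1) >= threshold
    return rpkm.index[keep]


def differential_test(
    rpkm: pd.DataFrame,
    groups: pd.Series,
    expressed: Optional[pd.Index] = None,
    group_ref: str = "wt",
    group_alt: str = "mutant",
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    adjust: str = "fdr_bh",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test with multiple-testing adjustment.

    Tests run on log2(RPKM + pseudocount); q values are computed across the
    expressed genes only. The default is Student's pooled t: with three
    replicates per group the Welch-Satterthwaite degrees of freedom collapse
    towards 2 whenever one group's variance estimate happens to be small,
    which makes even enormous t statistics insignificant; pass
    ``equal_var=False`` for Welch when replicate numbers are larger. The returned frame has one row per gene
    of *rpkm* with columns mean_ref / mean_alt (group mean RPKM), log2fc
    (of pseudocounted group means, alt vs ref), p, q, call in
    {up, down, unchanged, not-expressed} and a ``degenerate`` flag for genes
    where both groups had zero variance and the test is undefined.

    ``adjust`` is a :func:`statsmodels.stats.multitest.multipletests`
    method name (``fdr_bh`` default, ``bonferroni`` supported).
    """
    if expressed is None:
        expressed = rpkm.index
    ref_cols = groups.index[groups == group_ref]
    alt_cols = groups.index[groups == group_alt]
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValueError("each group needs at least two replicates")
    mean_ref = rpkm[ref_cols].mean(axis=1)
    mean_alt = rpkm[alt_cols].mean(axis=1)
    log2fc = np.log2((mean_alt + pseudocount) / (mean_ref + pseudocount))

    log_rpkm = np.log2(rpkm + pseudocount)
    a = log_rpkm.loc[expressed, alt_cols].to_numpy()
    b = log_rpkm.loc[expressed, ref_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = pd.Series(p, index=expressed)
    degenerate = p.isna()
    q = pd.Series(np.nan, index=expressed)
    testable = expressed[~degenerate]
    if len(testable):
        q.loc[testable] = multipletests(p.loc[testable].to_numpy(), method=adjust)[1]

    out = pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "log2fc": log2fc,
            "p": p.reindex(rpkm.index),
            "q": q.reindex(rpkm.index),
        },
        index=rpkm.index,
    )
    degenerate_full = pd.Series(False, index=rpkm.index)
    degenerate_full.loc[degenerate.index] = degenerate.to_numpy()
    out["degenerate"] = degenerate_full
    call = pd.Series("unchanged", index=rpkm.index, dtype=object)
    call[~rpkm.index.isin(expressed)] = "not-expressed"
    sig = (out["q"] < q_threshold) & out.index.isin(expressed)
    call[sig & (out["log2fc"] >= lfc_threshold)] = "up"
    call[sig & (out["log2fc"] <= -lfc_threshold)] = "down"
    out["call"] = call
    out.index.name = "gene_id"
    return out


def overlap_with_list(
    de_results: pd.DataFrame,
    reference: pd.DataFrame,
) -> Dict[str, int]:
    """Compare up/down calls with an external direction-annotated gene list.

    *reference* needs columns ``gene_id`` and ``direction`` ("up"/"down").
    Returns counts of concordant overlaps (up_up, down_down), discordant
    overlaps, and of our differentially expressed genes absent from the
    reference list.
    """
    ours_up = set(de_results.index[de_results["call"] == "up"])
    ours_down = set(de_results.index[de_results["call"] == "down"])
    ref_up = set(reference.loc[reference["direction"] == "up", "gene_id"])
    ref_down = set(reference.loc[reference["direction"] == "down", "gene_id"])
    ref_all = ref_up | ref_down
    return {
        "up_up": len(ours_up & ref_up),
        "down_down": len(ours_down & ref_down),
        "discordant": len(ours_up & ref_down) + len(ours_down & ref_up),
        "absent": len((ours_up | ours_down) - ref_all),
    }
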