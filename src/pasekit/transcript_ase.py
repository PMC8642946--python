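"""Transcript-level allele-specific expression and the cross-level comparison.

Hybrid RNA-seq reads sorted to the B6 or D2 allele give per-gene allele
counts; allelic imbalance is tested with an exact two-sided binomial test
(minimum-likelihood convention) against p0 = 0.5 on counts pooled across
hybrid samples, BH-adjusted across genes.  The same five-way cis/trans
classifier used at the protein level is applied to transcript-level ratios
(parental ratio from parental expression, F1 ratio from allele counts with a
pseudocount), and protein and transcript calls are compared by a Fisher
exact test on ASE co-membership over shared genes.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .pase import classify_regulation
from .synthetic import CATEGORIES

log = logging.getLogger(__name__)


def _allele_columns(counts: pd.DataFrame) -> tuple[list[str], list[str]]:
    b_cols = [c for c in counts.columns if c.endswith("_B")]
    d_cols = [c for c in counts.columns if c.endswith("_D")]
    if not b_cols or len(b_cols) != len(d_cols):
        raise ValueError("count table needs paired *_B and *_D columns")
    return b_cols, d_cols


def binomial_ase_test(counts: pd.DataFrame, p0: float = 0.5, min_total: int = 10
                      ) -> pd.DataFrame:
    """Exact two-sided binomial test of allelic imbalance per gene.

    Counts are pooled (summed) across hybrid samples; genes below
    ``min_total`` reads are skipped with a reason.  Adjusted p-values are BH
    across tested genes.
    """
    b_cols, d_cols = _allele_columns(counts)
    b = counts[b_cols].sum(axis=1).astype(int)
    d = counts[d_cols].sum(axis=1).astype(int)
    total = b + d
    tested = total >= min_total
    skipped = int((~tested).sum())
    if skipped:
        log.info("binomial_ase_test: skipped %d gene(s) below %d reads",
                 skipped, min_total)
    p = pd.Series(np.nan, index=counts.index, dtype=float)
    for gene in counts.index[tested]:
        p.loc[gene] = stats.binomtest(int(b.loc[gene]), int(total.loc[gene]),
                                      p0).pvalue
    p_adj = pd.Series(np.nan, index=counts.index, dtype=float)
    if tested.any():
        p_adj.loc[tested] = bh_adjust(p.loc[tested].to_numpy())
    return pd.DataFrame({"b_count": b, "d_count": d, "total": total,
                         "tested": tested,
                         "reason": np.where(tested, "", "low_depth"),
                         "p_value": p, "p_adjusted": p_adj})


def transcript_ratios(counts: pd.DataFrame, parental: pd.DataFrame,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene (r_parental, r_f1) log2 ratios at the transcript level.

    The parental ratio is log2(mean B6 expression) - log2(mean D2
    expression); the F1 ratio is log2 of pooled B over D allele counts with a
    pseudocount on each.
    """
    b_cols, d_cols = _allele_columns(counts)
    b6_cols = [c for c in parental.columns if c.startswith("B6")]
    d2_cols = [c for c in parental.columns if c.startswith("D2")]
    if not b6_cols or not d2_cols:
        raise ValueError("parental expression table needs B6* and D2* columns")
    shared = counts.index.intersection(parental.index)
    b = counts.loc[shared, b_cols].sum(axis=1)
    d = counts.loc[shared, d_cols].sum(axis=1)
    r_f1 = np.log2(b + pseudocount) - np.log2(d + pseudocount)
    with np.errstate(divide="ignore"):
        r_p = (np.log2(parental.loc[shared, b6_cols].mean(axis=1))
               - np.log2(parental.loc[shared, d2_cols].mean(axis=1)))
    return pd.DataFrame({"r_parental": r_p, "r_f1": r_f1})


def classify_transcript_regulation(counts: pd.DataFrame, parental: pd.DataFrame,
                                   tau: float = 1.0, pseudocount: float = 0.5,
                                   mode: str = "quadrant") -> pd.DataFrame:
    """Five-way regulatory category per gene (shared classifier with pASE)."""
    ratios = transcript_ratios(counts, parental, pseudocount)
    ok = ratios.notna().all(axis=1) & np.isfinite(ratios).all(axis=1)
    cats = pd.Series("", index=ratios.index, dtype=object)
    for gene in ratios.index[ok]:
        cats.loc[gene] = classify_regulation(float(ratios.loc[gene, "r_parental"]),
                                             float(ratios.loc[gene, "r_f1"]),
                                             tau, mode)
    out = ratios.copy()
    out["category"] = cats
    return out


def compare_levels(protein_calls: pd.DataFrame, transcript_calls: pd.DataFrame,
                   gene_map: Mapping[str, str] | pd.Series | None = None
                   ) -> dict:
    """Protein-vs-transcript ASE overlap over shared genes.

    ``protein_calls`` needs ``gene`` (or a ``gene_map`` from pair id to gene)
    plus an ``ase`` boolean and a ``category``; ``transcript_calls`` is
    indexed by gene with the same two columns.  Returns the 2x2 contingency
    table (ASE vs non-ASE at each level), a two-sided Fisher exact test, and
    per-category intersection counts.
    """
    prot = protein_calls.copy()
    if gene_map is not None:
        gm = pd.Series(gene_map)
        prot["gene"] = gm.reindex(prot.index).to_numpy()
    if "gene" not in prot.columns:
        raise ValueError("protein calls need a 'gene' column or a gene_map")
    prot = prot.dropna(subset=["gene"]).drop_duplicates(subset=["gene"]).set_index("gene")
    shared = prot.index.intersection(transcript_calls.index)
    if len(shared) == 0:
        raise ValueError("protein and transcript gene universes do not intersect")
    p_ase = prot.loc[shared, "ase"].astype(bool)
    t_ase = transcript_calls.loc[shared, "ase"].astype(bool)
    table = np.array([
        [int((p_ase & t_ase).sum()), int((p_ase & ~t_ase).sum())],
        [int((~p_ase & t_ase).sum()), int((~p_ase & ~t_ase).sum())],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    cross = pd.crosstab(prot.loc[shared, "category"],
                        transcript_calls.loc[shared, "category"])
    cross = cross.reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    return {"table": table, "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
            "p_value": float(p), "n_shared": int(len(shared)),
            "category_crosstab": cross}
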