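"""Protein allele-specific expression: allelic ratios and cis/trans classification.

The allelic expression ratio is log2(B6-allele peptide abundance) -
log2(D2-allele peptide abundance), computed separately in the parental
strains (B allele in B6 samples vs D allele in D2 samples) and within the F1
hybrids (both alleles in the same samples).  Comparing the two ratios
partitions regulation into five categories: an imbalance shared by parents
and F1s is cis (the allele-linked element travels with the allele); an
imbalance seen only between parents is trans (the diffusible factor acts on
both F1 alleles equally); only in F1s is compensatory (offsetting cis and
trans effects in the parents); neither is conserved; and opposite-sign
imbalances are an unexpected bias.

Because the two allelic peptides differ chemically, their ionization
efficiencies differ and absolute B/D signals are not comparable; the
classification compares ratios across genotypes, where that bias cancels.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .design import HYBRIDS, StrainDesign
from .diffexpr import moderated_ttest
from .synthetic import CATEGORIES

log = logging.getLogger(__name__)


def compute_allelic_ratios(abundances: pd.DataFrame, design: StrainDesign
                           ) -> pd.DataFrame:
    """Parental and F1 log2 allelic ratios per complete variant-peptide pair.

    ``abundances`` is long form: columns ``pair_id``, ``allele`` (B/D), plus
    per-sample linear abundances (NaN where undetected).  The parental ratio
    is mean log2(B in B6 samples) - mean log2(D in D2 samples); the F1 ratio
    is the mean over F1 samples of log2(B) - log2(D) within the sample.
    Pairs with an allele entirely missing in its carrier samples are excluded
    with a reason.
    """
    b6 = design.samples_of("B6")
    d2 = design.samples_of("D2")
    f1 = design.samples_of(*HYBRIDS)
    rows = []
    for pid, grp in abundances.groupby("pair_id", sort=True):
        alleles = grp.set_index("allele")
        if not {"B", "D"} <= set(alleles.index):
            rows.append({"pair_id": pid, "r_parental": np.nan, "r_f1": np.nan,
                         "n_parental_b6": 0, "n_parental_d2": 0, "n_f1": 0,
                         "excluded": True, "reason": "allele_missing"})
            continue
        b_vals = alleles.loc["B", b6].astype(float)
        d_vals = alleles.loc["D", d2].astype(float)
        b_f1 = alleles.loc["B", f1].astype(float)
        d_f1 = alleles.loc["D", f1].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lb = np.log2(b_vals.where(b_vals > 0))
            ld = np.log2(d_vals.where(d_vals > 0))
            diff_f1 = (np.log2(b_f1.where(b_f1 > 0))
                       - np.log2(d_f1.where(d_f1 > 0)))
        n_b6, n_d2 = int(lb.notna().sum()), int(ld.notna().sum())
        n_f1 = int(diff_f1.notna().sum())
        if n_b6 == 0 or n_d2 == 0 or n_f1 == 0:
            rows.append({"pair_id": pid, "r_parental": np.nan, "r_f1": np.nan,
                         "n_parental_b6": n_b6, "n_parental_d2": n_d2,
                         "n_f1": n_f1, "excluded": True,
                         "reason": "no_carrier_quantification"})
            continue
        rows.append({"pair_id": pid, "r_parental": float(lb.mean() - ld.mean()),
                     "r_f1": float(diff_f1.mean()), "n_parental_b6": n_b6,
                     "n_parental_d2": n_d2, "n_f1": n_f1, "excluded": False,
                     "reason": ""})
    out = pd.DataFrame(rows).set_index("pair_id")
    n_exc = int(out["excluded"].sum())
    if n_exc:
        log.info("compute_allelic_ratios: excluded %d of %d pairs", n_exc, len(out))
    return out


def pase_test(abundances: pd.DataFrame, design: StrainDesign) -> pd.DataFrame:
    """Moderated t-test between the two allele peptides within the F1 hybrids.

    Each pair contributes a B-allele and a D-allele log2 abundance profile
    across the F1 samples; the shared empirical-Bayes engine contrasts them
    and BH adjusts across pairs.  Pairs with fewer than two quantified F1
    samples per allele are flagged untestable (NaN p).
    """
    f1 = design.samples_of(*HYBRIDS)
    b_cols = [f"{s}__B" for s in f1]
    d_cols = [f"{s}__D" for s in f1]
    profiles = {}
    for pid, grp in abundances.groupby("pair_id", sort=True):
        alleles = grp.set_index("allele")
        if not {"B", "D"} <= set(alleles.index):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.concatenate([
                np.log2(alleles.loc["B", f1].astype(float)
                        .where(alleles.loc["B", f1].astype(float) > 0)),
                np.log2(alleles.loc["D", f1].astype(float)
                        .where(alleles.loc["D", f1].astype(float) > 0)),
            ])
        profiles[pid] = row
    matrix = pd.DataFrame.from_dict(profiles, orient="index",
                                    columns=b_cols + d_cols)
    counts_ok = (matrix[b_cols].notna().sum(axis=1) >= 2) & \
                (matrix[d_cols].notna().sum(axis=1) >= 2)
    complete = matrix.notna().all(axis=1) & counts_ok
    testable = matrix.loc[complete]
    out = pd.DataFrame(index=matrix.index,
                       columns=["log2_fc", "t", "p_value", "p_adjusted"],
                       dtype=float)
    out["testable"] = complete
    if len(testable):
        res = moderated_ttest(testable, b_cols, d_cols)
        out.loc[testable.index, ["log2_fc", "t", "p_value", "p_adjusted"]] = \
            res[["log2_fc", "t", "p_value", "p_adjusted"]]
    out.index.name = "pair_id"
    return out


def classify_regulation(r_parental: float, r_f1: float, tau: float = 1.0,
                        mode: str = "quadrant") -> str:
    """Five-way regulatory category of one (parental, F1) log2 ratio point.

    Quadrant mode (default) partitions the plane by |ratio| against ``tau``
    (1 log2 unit): both super-threshold with the same sign is cis; parental
    only is trans; F1 only is compensatory; neither is conserved; opposite
    signs is unexpected bias.  Band mode instead calls cis when the parental
    imbalance is super-threshold and the F1 ratio lies within ``tau`` of it.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (np.isfinite(r_parental) and np.isfinite(r_f1)):
        raise ValueError("ratios must be finite")
    ap, af = abs(r_parental) >= tau, abs(r_f1) >= tau
    if mode == "band":
        if ap and abs(r_f1 - r_parental) < tau:
            return "cis"
    elif mode != "quadrant":
        raise ValueError(f"unknown mode {mode!r}")
    if ap and af:
        if mode == "quadrant" and np.sign(r_parental) == np.sign(r_f1):
            return "cis"
        return "unexpected"
    if ap:
        return "trans"
    if af:
        return "compensatory"
    return "conserved"


def classify_table(ratios: pd.DataFrame, tau: float = 1.0, mode: str = "quadrant",
                   significance: pd.Series | None = None, alpha: float = 0.05
                   ) -> pd.DataFrame:
    """Apply the regulatory classifier to a table of (r_parental, r_f1) rows.

    With ``significance`` (BH-adjusted p per pair) given, pairs whose allelic
    imbalance is not significant at ``alpha`` are gated to conserved/trans as
    appropriate — the significance-gated variant; by default classification
    is purely ratio-based.
    """
    ok = ratios["r_parental"].notna() & ratios["r_f1"].notna()
    cats = pd.Series("", index=ratios.index, name="category", dtype=object)
    for pid in ratios.index[ok]:
        r_p, r_f1 = ratios.loc[pid, "r_parental"], ratios.loc[pid, "r_f1"]
        cat = classify_regulation(float(r_p), float(r_f1), tau, mode)
        if significance is not None and cat in ("cis", "compensatory", "unexpected"):
            p = significance.get(pid, np.nan)
            if not (np.isfinite(p) and p < alpha):
                # F1 imbalance not supported statistically
                cat = "trans" if abs(float(r_p)) >= tau else "conserved"
        cats.loc[pid] = cat
    out = ratios.copy()
    out["category"] = cats
    out["tau"] = tau
    return out


def category_counts(calls: pd.DataFrame) -> pd.Series:
    """Tally of pairs per regulatory category (the quadrant summary)."""
    counts = calls.loc[calls["category"] != "", "category"].value_counts()
    return counts.reindex(CATEGORIES, fill_value=0)
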