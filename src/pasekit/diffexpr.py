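"""Differential expression, single-parent expression, and the hybrid screen.

The workhorse is an empirical-Bayes moderated t-test: per-feature pooled
sample variances s^2 with d degrees of freedom are shrunk toward a prior
variance s0^2 with prior degrees of freedom d0,

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d),

where (d0, s0^2) are estimated by moment-matching a scaled-inverse-chi-square
model on the distribution of log sample variances (Smyth-style: solve
trigamma(d0/2) = var(log s^2) - trigamma(d/2)).  The moderated t uses
s2_post with d0 + d degrees of freedom.

On top of it sit the B6-vs-D2 DEP caller, the coefficient-of-variation /
high-variation screen, single-parent-expression (SPE) calling, the
reciprocal-hybrid (imprinting-candidate) screen, and a statistical power
simulation.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .design import HYBRIDS, StrainDesign

log = logging.getLogger(__name__)

_MAX_D0 = 1e8  # effectively infinite prior df


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    nan_idx = np.flatnonzero(np.isnan(p))
    if nan_idx.size:
        raise ValueError(f"NaN p-values at indices {nan_idx.tolist()}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log sample variances; d0 may be inf."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        # no information to shrink with; behave like an ordinary t-test
        return 0.0, float(positive.mean()) if positive.size else 0.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_ttest(matrix: pd.DataFrame, group_a: Sequence[str],
                    group_b: Sequence[str], *, d0_override: float | None = None
                    ) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per feature (pooled variance).

    ``matrix`` is features x samples on the log2 scale; ``group_a`` and
    ``group_b`` are disjoint sample-column sets of size >= 2.  The log2 fold
    change is mean(group_a) - mean(group_b).  Zero-variance features receive
    the prior variance s0^2 rather than being dropped.  ``d0_override``
    forces the prior degrees of freedom (e.g. np.inf for the fully shrunk
    limit, 0 for the ordinary t-test).

    Returns a DataFrame with columns mean_a, mean_b, log2_fc, s2, s2_post, t,
    p_value, p_adjusted; the fitted prior is in ``attrs`` (d0, s0_sq, df_resid).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    df_resid = na + nb - 2
    s2 = ((a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))) / df_resid

    if d0_override is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(d0_override)
        _, s0_sq = estimate_variance_prior(s2, df_resid)
    d0_eff = min(d0, _MAX_D0)
    if d0_eff > 0:
        s2_post = (d0_eff * s0_sq + df_resid * s2) / (d0_eff + df_resid)
    else:
        s2_post = s2.copy()
    s2_post = np.where(s2 == 0, s0_sq if d0_eff > 0 else 0.0, s2_post)

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1.0), 0.0)
    df_total = d0_eff + df_resid
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": mean_a - mean_b,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
        },
        index=matrix.index,
    )
    out.attrs.update({"d0": d0, "s0_sq": s0_sq, "df_resid": df_resid})
    return out


def call_deps(results: pd.DataFrame, fc_cut: float = 1.5, fdr: float = 0.05
              ) -> pd.DataFrame:
    """Flag differentially expressed proteins: adjusted p < fdr and |log2FC| > fc_cut."""
    out = results.copy()
    out["dep"] = (out["p_adjusted"] < fdr) & (out["log2_fc"].abs() > fc_cut)
    out["direction"] = np.where(~out["dep"], "",
                                np.where(out["log2_fc"] > 0, "a_higher", "b_higher"))
    log.info("call_deps: %d DEPs of %d features (FDR < %g, |log2FC| > %g)",
             int(out["dep"].sum()), len(out), fdr, fc_cut)
    return out


def compute_cv_and_high_variation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation on the linear scale, plus high-variation flags.

    CV = sd / mean across all samples of the four strains (linear abundance,
    back-transformed from log2); a protein is high-variation iff its CV
    exceeds mean(CV) + 2 * sd(CV).  Features with non-positive mean are
    excluded (logged).
    """
    linear = 2.0 ** matrix.to_numpy(dtype=float)
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=1)
    ok = mean > 0
    if (~ok).any():
        log.info("compute_cv: excluded %d feature(s) with non-positive mean",
                 int((~ok).sum()))
    cv = np.full(mean.shape, np.nan)
    cv[ok] = sd[ok] / mean[ok]
    valid = cv[ok]
    cut = valid.mean() + 2.0 * valid.std(ddof=1) if valid.size > 1 else np.inf
    out = pd.DataFrame({"cv": cv}, index=matrix.index)
    out["high_variation"] = (out["cv"] > cut).fillna(False)
    out.attrs["cv_cutoff"] = float(cut)
    return out


def call_spe(matrix: pd.DataFrame, design: StrainDesign,
             high_pct: float = 25.0, low_pct: float = 5.0) -> pd.DataFrame:
    """Single-parent expression: one parent expressed, the other silent.

    Per parental strain the mean log2 abundance is z-scored across proteins;
    a protein is SPE iff one parent's z-score exceeds that strain's
    ``high_pct`` percentile cutoff while the other parent's z-score falls
    below its ``low_pct`` percentile cutoff.
    """
    if len(matrix) < 20:
        warnings.warn("fewer than 20 proteins: SPE percentile cutoffs are unstable",
                      stacklevel=2)
    zs = {}
    for strain in ("B6", "D2"):
        v = matrix[design.samples_of(strain)].mean(axis=1)
        zs[strain] = (v - v.mean()) / v.std(ddof=1)
    z_b6, z_d2 = zs["B6"], zs["D2"]
    hi_b6, lo_b6 = np.percentile(z_b6, [high_pct, low_pct])
    hi_d2, lo_d2 = np.percentile(z_d2, [high_pct, low_pct])
    d2_silent = (z_b6 > hi_b6) & (z_d2 < lo_d2)
    b6_silent = (z_d2 > hi_d2) & (z_b6 < lo_b6)
    out = pd.DataFrame({"z_b6": z_b6, "z_d2": z_d2,
                        "spe": d2_silent | b6_silent,
                        "silent_parent": np.where(d2_silent, "D2",
                                                  np.where(b6_silent, "B6", ""))},
                       index=matrix.index)
    log.info("call_spe: %d SPE proteins of %d", int(out["spe"].sum()), len(out))
    return out


def compare_reciprocal_hybrids(matrix: pd.DataFrame, design: StrainDesign,
                               p_cut: float = 0.01, fc_cut: float = 0.3
                               ) -> pd.DataFrame:
    """Screen for parent-of-origin candidates: B6D2F1 vs D2B6F1 expression.

    Candidates satisfy raw p < ``p_cut`` and |log2FC| > ``fc_cut``; direction
    reports which maternal background is higher.
    """
    res = moderated_ttest(matrix, design.samples_of("B6D2F1"),
                          design.samples_of("D2B6F1"))
    res["candidate"] = (res["p_value"] < p_cut) & (res["log2_fc"].abs() > fc_cut)
    res["direction"] = np.where(~res["candidate"], "",
                                np.where(res["log2_fc"] > 0,
                                         "maternal_B6_higher", "maternal_D2_higher"))
    return res


def simulate_power(n_per_group: int, effect_sizes: Sequence[float],
                   n_features: int = 1000, n_reps: int = 5, alpha: float = 0.05,
                   seed: int = 0, fraction_nonnull: float = 0.1,
                   noise_sd: float = 0.25) -> pd.DataFrame:
    """Monte-Carlo power of the moderated test at BH-FDR ``alpha``.

    For each effect size (log2 units), ``fraction_nonnull`` of features get
    the effect added to one group; power is the mean fraction of planted
    features detected, and the observed false-discovery proportion among
    detections is reported alongside.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    n_nonnull = int(round(fraction_nonnull * n_features))
    cols_a = [f"a{i}" for i in range(n_per_group)]
    cols_b = [f"b{i}" for i in range(n_per_group)]
    rows = []
    for effect in effect_sizes:
        powers, fdps = [], []
        for _ in range(n_reps):
            data = rng.normal(0.0, noise_sd, size=(n_features, 2 * n_per_group))
            data[:n_nonnull, :n_per_group] += effect
            matrix = pd.DataFrame(data, columns=cols_a + cols_b)
            res = moderated_ttest(matrix, cols_a, cols_b)
            sig = res["p_adjusted"].to_numpy() < alpha
            n_sig = int(sig.sum())
            tp = int(sig[:n_nonnull].sum())
            powers.append(tp / n_nonnull if n_nonnull else np.nan)
            fdps.append((n_sig - tp) / n_sig if n_sig else 0.0)
        rows.append({"effect_size": effect, "power": float(np.mean(powers)),
                     "observed_fdp": float(np.mean(fdps)),
                     "n_per_group": n_per_group, "n_reps": n_reps})
    return pd.DataFrame(rows)
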