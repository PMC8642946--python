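"""PSM-to-protein TMT quantification chain.

Reporter-ion quantification proceeds in a fixed order: isotope-impurity
correction, low-intensity filtering, sample-loading normalization by trimmed
median, then protein summarization (mean-centered log2 PSM profiles averaged
per protein, with an absolute intensity scalar from the top-3 PSMs).

PSM tables are pandas DataFrames indexed by ``psm_id`` with ``peptide`` and
``protein`` columns followed by one linear-intensity column per sample.
Missing reporter values stay missing (NaN); they are excluded from medians
and means rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StrainDesign, require_samples

log = logging.getLogger(__name__)

PSM_META_COLUMNS = ("peptide", "protein")


def sample_columns(psms: pd.DataFrame) -> list[str]:
    return [c for c in psms.columns
            if c not in PSM_META_COLUMNS and not c.startswith("flag_")]


@dataclass
class ProteinQuant:
    """Protein abundance matrix: log2 relative (mean-centered) + absolute scalar."""

    log2_rel: pd.DataFrame  # proteins x samples, row mean == 0
    absolute: pd.Series     # per-protein absolute intensity (> 0)

    def to_frame(self) -> pd.DataFrame:
        out = self.log2_rel.copy()
        out.insert(0, "absolute_intensity", self.absolute)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProteinQuant":
        if "absolute_intensity" not in frame.columns:
            raise ValueError("protein table lacks 'absolute_intensity' column")
        return cls(frame.drop(columns=["absolute_intensity"]),
                   frame["absolute_intensity"])


def correct_isotope_impurity(psms: pd.DataFrame, impurity: np.ndarray) -> pd.DataFrame:
    """Deconvolve reporter-channel cross-talk by solving ``M x = observed`` per PSM.

    ``impurity[i, j]`` is the fraction of channel j's signal observed in
    channel i.  Negative solutions are clipped to 0 and flagged in a
    ``flag_isotope_clipped`` column.  Missing values are treated as zero
    signal during the solve and restored as missing afterwards.
    """
    cols = sample_columns(psms)
    m = np.asarray(impurity, dtype=float)
    if m.shape != (len(cols), len(cols)):
        raise ValueError(
            f"impurity matrix shape {m.shape} does not match {len(cols)} channels")
    if np.linalg.matrix_rank(m) < len(cols):
        raise ValueError("impurity matrix is singular and cannot be inverted")
    observed = psms[cols].to_numpy(dtype=float)
    mask = np.isnan(observed)
    filled = np.where(mask, 0.0, observed)
    corrected = np.linalg.solve(m, filled.T).T
    clipped = corrected < 0
    corrected[clipped] = 0.0
    corrected[mask] = np.nan
    out = psms.copy()
    out[cols] = corrected
    out["flag_isotope_clipped"] = clipped.any(axis=1)
    n_clip = int(out["flag_isotope_clipped"].sum())
    if n_clip:
        log.info("isotope correction clipped negatives in %d PSM(s)", n_clip)
    return out


def filter_low_intensity(psms: pd.DataFrame, min_intensity: float = 1000.0,
                         min_median: float = 5000.0,
                         max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Drop PSMs whose cross-channel minimum or median intensity is too low.

    A PSM is removed iff its minimum (over non-missing channels) is below
    ``min_intensity`` or its median is below ``min_median``; PSMs missing in
    more than ``max_missing_fraction`` of channels are dropped as well.
    Removal counts are logged, never silent.
    """
    if min_intensity < 0 or min_median < 0:
        raise ValueError("intensity thresholds must be >= 0")
    cols = sample_columns(psms)
    if psms.empty:
        log.warning("filter_low_intensity: empty PSM table")
        return psms.copy()
    vals = psms[cols].to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        mins = np.nanmin(vals, axis=1)
        medians = np.nanmedian(vals, axis=1)
    missing_frac = np.isnan(vals).mean(axis=1)
    all_missing = missing_frac >= 1.0
    keep = (
        ~all_missing
        & (missing_frac <= max_missing_fraction)
        & (np.where(all_missing, -np.inf, mins) >= min_intensity)
        & (np.where(all_missing, -np.inf, medians) >= min_median)
    )
    removed = int((~keep).sum())
    log.info("filter_low_intensity: removed %d of %d PSMs (min >= %g, median >= %g)",
             removed, len(psms), min_intensity, min_median)
    out = psms.loc[keep].copy()
    out.attrs["n_removed_low_intensity"] = removed
    return out


def _trimmed_median(values: np.ndarray, trim_fraction: float) -> float:
    vals = np.sort(values[np.isfinite(values)])
    if vals.size == 0:
        return np.nan
    k = int(np.floor(trim_fraction * vals.size))
    trimmed = vals[k: vals.size - k] if vals.size - 2 * k > 0 else vals
    return float(np.median(trimmed))


def normalize_loading(psms: pd.DataFrame, trim_fraction: float = 0.1) -> pd.DataFrame:
    """Equalize sample loading: match trimmed medians of log2 intensity per channel.

    Each channel is scaled (multiplicatively) so that the trimmed median of
    its log2 intensities equals the across-channel grand mean of those
    trimmed medians.  Scaling factors are logged and stored in
    ``attrs['loading_factors_log2']``.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    cols = sample_columns(psms)
    if psms.empty:
        raise ValueError("normalize_loading requires at least one PSM")
    vals = psms[cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    medians = np.array([_trimmed_median(logv[:, j], trim_fraction)
                        for j in range(len(cols))])
    bad = [cols[j] for j in range(len(cols)) if not np.isfinite(medians[j])]
    if bad:
        raise ValueError(f"channel(s) with no usable intensities: {bad}")
    target = medians.mean()
    shift = target - medians  # additive on log2 scale
    out = psms.copy()
    out[cols] = vals * (2.0 ** shift)[None, :]
    out.attrs["loading_factors_log2"] = dict(zip(cols, shift))
    log.info("normalize_loading: log2 scaling factors %s",
             {c: round(float(s), 4) for c, s in zip(cols, shift)})
    return out


def summarize_proteins(psms: pd.DataFrame) -> ProteinQuant:
    """Roll PSMs up to proteins.

    Per protein the relative log2 profile is the mean of its PSMs'
    mean-centered log2 profiles, and the absolute intensity scalar is the
    grand mean of the three most intense PSMs (by summed cross-channel
    intensity, ties broken by psm_id; all PSMs if fewer than three).
    """
    cols = sample_columns(psms)
    vals = psms[cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    centered = logv - np.nanmean(logv, axis=1, keepdims=True)
    centered_df = pd.DataFrame(centered, index=psms.index, columns=cols)
    centered_df["protein"] = psms["protein"].to_numpy()
    rel = centered_df.groupby("protein", sort=True).mean()

    totals = pd.Series(np.nansum(vals, axis=1), index=psms.index, name="total")
    ranked = (
        pd.DataFrame({"protein": psms["protein"].to_numpy(), "total": totals})
        .rename_axis("psm_id")
        .sort_values(["protein", "total", "psm_id"],
                     ascending=[True, False, True], kind="stable")
    )
    top3 = ranked.groupby("protein", sort=True).head(3)
    grand = pd.Series(np.nanmean(vals, axis=1), index=psms.index)
    absolute = grand.loc[top3.index].groupby(top3["protein"]).mean()
    absolute.name = "absolute_intensity"
    return ProteinQuant(log2_rel=rel, absolute=absolute.reindex(rel.index))


def quantify(psms: pd.DataFrame, impurity: np.ndarray, *,
             min_intensity: float = 1000.0, min_median: float = 5000.0,
             trim_fraction: float = 0.1) -> ProteinQuant:
    """The full chain in its enforced order: correct, filter, normalize, summarize."""
    corrected = correct_isotope_impurity(psms, impurity)
    kept = filter_low_intensity(corrected, min_intensity, min_median)
    if kept.empty:
        raise ValueError("no PSMs survive the intensity filter")
    normalized = normalize_loading(kept, trim_fraction)
    return summarize_proteins(normalized)


def abundance_matrix(quant: ProteinQuant, design: StrainDesign) -> pd.DataFrame:
    """Log2 abundance matrix (relative profile anchored at the absolute scalar)."""
    require_samples(design, quant.log2_rel.columns)
    return quant.log2_rel[design.sample_ids].add(
        np.log2(quant.absolute.clip(lower=np.finfo(float).tiny)), axis=0)
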