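"""Synthetic-data generators emulating the reciprocal-F1 brain proteome design.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes, so all downstream stages are testable without
any external download:

* :func:`simulate_proteome` — per-protein additive/dominance/sex/noise
  structure on the log2 scale plus PSM-level reporter intensities with channel
  loading bias and isotope impurity mixing;
* :func:`simulate_variant_peptides` — B-allele / D-allele peptide pairs
  planted under the five regulatory categories (cis, trans, compensatory,
  conserved, unexpected bias);
* :func:`simulate_allele_counts` — binomially sampled hybrid allele read
  counts plus parental expression levels;
* :func:`simulate_reference_fasta` — a small reference proteome and missense
  variant table so the proteogenomic enumeration stage can run end to end.

Protein matrices are on the log2 scale; PSM tables are linear
(reporter-intensity-like).  Fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import GENOTYPES, HYBRIDS, PARENTS, StrainDesign

CATEGORIES: tuple[str, ...] = ("cis", "trans", "compensatory", "conserved", "unexpected")

#: additive genotype code: B6-like = -1, D2-like = +1, F1s = 0 (mid-parent)
ADDITIVE_CODE = {"B6": -1.0, "D2": 1.0, "B6D2F1": 0.0, "D2B6F1": 0.0}
#: heterozygosity code: 1 for F1 hybrids, 0 for inbred parents
DOMINANCE_CODE = {"B6": 0.0, "D2": 0.0, "B6D2F1": 1.0, "D2B6F1": 1.0}

# residues that never create or destroy a tryptic cleavage context
_SAFE_RESIDUES = "ACDEFGHILMNQSTVWY"


@dataclass
class SimParams:
    """Parameters of the proteome generator (log2 units unless noted).

    Defaults are the study conditions the generator emulates: an 8-sample
    TMT run (4 genotypes x 2 sexes) with most proteins genetically null and
    a minority carrying additive/dominance effects of the order of the
    residual noise.
    """

    n_proteins: int = 1000
    sigma_additive: float = 1.0  # sd of per-protein additive effect a
    sigma_dominance: float = 0.5  # sd of per-protein dominance effect d
    sigma_sex: float = 0.2  # sd of per-protein sex effect
    sigma_residual: float = 0.5  # residual sd per sample
    fraction_null: float = 0.3  # proteins with a = d = 0
    baseline_mean: float = 16.0  # mean log2 absolute abundance
    baseline_sd: float = 1.5
    psm_mean: float = 4.0  # mean PSMs per protein (>= 1)
    psm_log2_sd: float = 1.0  # spread of per-PSM ionization efficiency
    psm_cv: float = 0.1  # multiplicative reporter noise (lognormal CV)
    loading_bias: Optional[np.ndarray] = None  # per-channel multipliers (> 0)
    impurity: Optional[np.ndarray] = None  # channels x channels mixing matrix
    seed: int = 0

    def validate(self, n_channels: int) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        for name in ("sigma_additive", "sigma_dominance", "sigma_sex",
                     "sigma_residual", "psm_cv", "psm_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must be in [0, 1]")
        if self.psm_mean < 1:
            raise ValueError("psm_mean must be >= 1")
        if self.loading_bias is not None:
            lb = np.asarray(self.loading_bias, dtype=float)
            if lb.shape != (n_channels,) or np.any(lb <= 0):
                raise ValueError("loading_bias must be positive with one entry per channel")
        if self.impurity is not None:
            m = np.asarray(self.impurity, dtype=float)
            if m.shape != (n_channels, n_channels):
                raise ValueError(
                    f"impurity matrix shape {m.shape} does not match {n_channels} channels"
                )
            if np.any(m < 0) or np.any(m.sum(axis=0) > 1.0 + 1e-6):
                raise ValueError("impurity columns must be non-negative and sum to <= 1")


@dataclass
class SimTruth:
    """Ground truth backing the generators; one table per simulated layer."""

    proteins: Optional[pd.DataFrame] = None       # a, d, sex effect, realized H2
    variant_pairs: Optional[pd.DataFrame] = None  # category, rP, rF1, sequences
    genes: Optional[pd.DataFrame] = None          # category, rP, rF1, binomial p


def default_impurity_matrix(n_channels: int, adjacent: float = 0.03,
                            next_adjacent: float = 0.005) -> np.ndarray:
    """Typical TMT isotope-impurity mixing: small leakage into +/-1, +/-2 channels.

    Entry (i, j) is the fraction of channel j's true signal observed in
    channel i; columns sum to <= 1.
    """
    m = np.zeros((n_channels, n_channels))
    for j in range(n_channels):
        for di, frac in ((1, adjacent), (-1, adjacent), (2, next_adjacent), (-2, next_adjacent)):
            i = j + di
            if 0 <= i < n_channels:
                m[i, j] = frac
        m[j, j] = 1.0 - m[:, j].sum()
    return m


def _loading_bias(params: SimParams, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    if params.loading_bias is not None:
        return np.asarray(params.loading_bias, dtype=float)
    # modest sample-loading differences, the thing trimmed-median normalization removes
    return 2.0 ** rng.uniform(-0.75, 0.75, size=n_channels)


def simulate_proteome(
    design: StrainDesign, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a PSM reporter-intensity table and the true protein matrix.

    Per protein the genotype mean is ``mu + a*g + d*h`` with additive code
    ``g`` in {-1, +1, 0, 0} for {B6, D2, F1, F1} and heterozygosity ``h`` in
    {0, 0, 1, 1}; each sample adds a sex effect (F = 1 coding) and
    N(0, sigma_residual^2) noise, all on the log2 scale.  PSM intensities are
    linear-scale lognormal draws around the protein level, multiplied by the
    channel loading bias and mixed by the isotope-impurity matrix.

    Returns ``(psm_table, protein_matrix, truth)`` where ``protein_matrix``
    holds the true per-sample log2 abundances (proteins x samples).
    """
    n_ch = design.n_channels
    params.validate(n_ch)
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    ids = [f"prot_{i:05d}" for i in range(n)]

    a = rng.normal(0.0, params.sigma_additive, size=n) if params.sigma_additive else np.zeros(n)
    d = rng.normal(0.0, params.sigma_dominance, size=n) if params.sigma_dominance else np.zeros(n)
    s = rng.normal(0.0, params.sigma_sex, size=n) if params.sigma_sex else np.zeros(n)
    is_null = rng.random(n) < params.fraction_null
    a[is_null] = 0.0
    d[is_null] = 0.0
    mu = rng.normal(params.baseline_mean, params.baseline_sd, size=n)

    g = np.array([ADDITIVE_CODE[x.genotype] for x in design.samples])
    h = np.array([DOMINANCE_CODE[x.genotype] for x in design.samples])
    x_sex = design.sex_indicator()

    y = (
        mu[:, None]
        + np.outer(a, g)
        + np.outer(d, h)
        + np.outer(s, x_sex)
        + (rng.normal(0.0, params.sigma_residual, size=(n, len(g)))
           if params.sigma_residual else 0.0)
    )
    matrix = pd.DataFrame(y, index=pd.Index(ids, name="protein"), columns=design.sample_ids)

    # realized variance fractions across the design (ddof=0), for reference
    var_g, var_h, var_x = (np.var(v) for v in (g, h, x_sex))
    genetic = a**2 * var_g + d**2 * var_h
    total = genetic + s**2 * var_x + params.sigma_residual**2
    with np.errstate(invalid="ignore"):
        h2_true = np.where(total > 0, genetic / np.where(total > 0, total, 1.0), 0.0)

    truth = SimTruth(
        proteins=pd.DataFrame(
            {
                "protein": ids,
                "mu": mu,
                "additive": a,
                "dominance": d,
                "sex_effect": s,
                "is_null": is_null,
                "h2_realized": h2_true,
            }
        ).set_index("protein")
    )

    # ---- PSM layer (linear scale) ----------------------------------------
    n_psm = 1 + rng.poisson(params.psm_mean - 1.0, size=n)
    lam = _loading_bias(params, n_ch, rng)
    impurity = (params.impurity if params.impurity is not None
                else default_impurity_matrix(n_ch))
    impurity = np.asarray(impurity, dtype=float)

    prot_idx = np.repeat(np.arange(n), n_psm)
    total_psms = prot_idx.size
    eff = 2.0 ** rng.normal(0.0, params.psm_log2_sd, size=total_psms)
    base = 2.0 ** y[prot_idx]  # linear per-sample protein level
    noise_sigma = np.sqrt(np.log1p(params.psm_cv**2))
    mult_noise = (
        np.exp(rng.normal(0.0, noise_sigma, size=(total_psms, n_ch)))
        if params.psm_cv else 1.0
    )
    true_intensity = base * eff[:, None] * lam[None, :] * mult_noise
    observed = true_intensity @ impurity.T

    counter: dict[int, int] = {}
    psm_ids = []
    for p in prot_idx:
        counter[p] = counter.get(p, 0) + 1
        psm_ids.append(f"psm_{p:05d}_{counter[p]:02d}")
    psms = pd.DataFrame(observed, columns=design.sample_ids)
    psms.insert(0, "psm_id", psm_ids)
    psms.insert(1, "peptide", [f"PEP{p:05d}x{counter_i:02d}" for p, counter_i in
                               zip(prot_idx, (int(x.rsplit('_', 1)[1]) for x in psm_ids))])
    psms.insert(2, "protein", [ids[p] for p in prot_idx])
    psms = psms.set_index("psm_id")
    return psms, matrix, truth


# ---------------------------------------------------------------------------
# variant peptide pairs


def _category_counts(n: int, mix: Sequence[float] | dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n pairs to categories."""
    if isinstance(mix, dict):
        props = np.array([float(mix.get(c, 0.0)) for c in CATEGORIES])
    else:
        props = np.asarray(list(mix), dtype=float)
        if props.size != len(CATEGORIES):
            raise ValueError(f"category_mix needs {len(CATEGORIES)} proportions")
    if np.any(props < 0) or np.any(props > 1):
        raise ValueError("category proportions must be in [0, 1]")
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("category proportions must sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return dict(zip(CATEGORIES, counts))


def _true_ratios(category: str, effect: float, sign: float) -> tuple[float, float]:
    if category == "cis":
        return sign * effect, sign * effect
    if category == "trans":
        return sign * effect, 0.0
    if category == "compensatory":
        return 0.0, sign * effect
    if category == "conserved":
        return 0.0, 0.0
    if category == "unexpected":
        return sign * effect, -sign * effect
    raise ValueError(f"unknown category {category!r}")


def _random_peptide_pair(rng: np.random.Generator) -> tuple[str, str, int]:
    """A tryptic-looking B/D peptide pair differing at one internal site."""
    length = int(rng.integers(7, 12))
    body = rng.choice(list(_SAFE_RESIDUES), size=length)
    pos = int(rng.integers(1, length - 1))
    ref, alt = rng.choice(list(_SAFE_RESIDUES), size=2, replace=False)
    body[pos] = ref
    b_seq = "".join(body) + ("K" if rng.random() < 0.5 else "R")
    d_seq = b_seq[:pos] + alt + b_seq[pos + 1:]
    return b_seq, d_seq, pos + 1


def simulate_variant_peptides(
    design: StrainDesign,
    n_pairs: int = 100,
    category_mix: Sequence[float] | dict[str, float] = (0.2, 0.2, 0.2, 0.2, 0.2),
    effect: float = 2.0,
    noise: float = 0.25,
    seed: int = 0,
    pairs: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Plant B/D-allele peptide abundance profiles under each regulatory category.

    cis pairs carry the same super-threshold log2 allelic ratio in parents and
    F1s; trans pairs only in parents; compensatory only in F1s; conserved in
    neither; unexpected pairs flip sign between parents and F1s.  The B-allele
    peptide is missing (undetected) in D2 samples and vice versa; both alleles
    are detected in the F1 hybrids.

    Abundances are returned on the linear scale (one row per pair x allele,
    sample columns; NaN where the allele is undetectable).  If ``pairs`` (an
    enumerated variant-peptide-pair table with ``pair_id``, ``b_peptide``,
    ``d_peptide`` columns) is given, its sequences and ids are used and
    ``n_pairs`` is capped at its length.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    if pairs is not None:
        pairs = pairs.reset_index(drop=True)
        n_pairs = min(n_pairs, len(pairs))
    counts = _category_counts(n_pairs, category_mix)
    categories = [c for c in CATEGORIES for _ in range(counts[c])]

    b6 = design.samples_of("B6")
    d2 = design.samples_of("D2")
    f1 = design.samples_of(*HYBRIDS)

    rows, truth_rows = [], []
    for i, cat in enumerate(categories):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        r_p, r_f1 = _true_ratios(cat, effect, sign)
        if pairs is not None:
            pid = str(pairs.loc[i, "pair_id"])
            b_seq, d_seq = str(pairs.loc[i, "b_peptide"]), str(pairs.loc[i, "d_peptide"])
            if "gene" in pairs.columns and pairs.loc[i, "gene"]:
                gene = str(pairs.loc[i, "gene"])
            elif "protein" in pairs.columns:
                gene = str(pairs.loc[i, "protein"])
            else:
                gene = f"gene_{i:05d}"
        else:
            b_seq, d_seq, _ = _random_peptide_pair(rng)
            pid, gene = f"pair_{i:05d}", f"gene_{i:05d}"
        b0 = rng.normal(10.0, 1.0)

        def noisy(x: float) -> float:
            return x + (rng.normal(0.0, noise) if noise else 0.0)

        b_row = {s: np.nan for s in design.sample_ids}
        d_row = {s: np.nan for s in design.sample_ids}
        for s in b6:
            b_row[s] = noisy(b0 + r_p / 2.0)
        for s in d2:
            d_row[s] = noisy(b0 - r_p / 2.0)
        for s in f1:
            b_row[s] = noisy(b0 - 1.0 + r_f1 / 2.0)
            d_row[s] = noisy(b0 - 1.0 - r_f1 / 2.0)
        for allele, seq, vals in (("B", b_seq, b_row), ("D", d_seq, d_row)):
            rows.append({"pair_id": pid, "allele": allele, "peptide": seq, "gene": gene,
                         **{k: (2.0 ** v if np.isfinite(v) else np.nan)
                            for k, v in vals.items()}})
        truth_rows.append({"pair_id": pid, "gene": gene, "category": cat,
                           "r_parental": r_p, "r_f1": r_f1,
                           "b_peptide": b_seq, "d_peptide": d_seq})

    cols = ["pair_id", "allele", "peptide", "gene", *design.sample_ids]
    table = pd.DataFrame(rows, columns=cols)
    truth = SimTruth(variant_pairs=pd.DataFrame(
        truth_rows, columns=["pair_id", "gene", "category", "r_parental", "r_f1",
                             "b_peptide", "d_peptide"]))
    return table, truth


# ---------------------------------------------------------------------------
# transcript-level allele counts


def simulate_allele_counts(
    n_genes: int = 1000,
    depth: float = 100.0,
    category_mix: Sequence[float] | dict[str, float] = (0.2, 0.2, 0.2, 0.2, 0.2),
    effect: float = 2.0,
    seed: int = 0,
    n_hybrid_samples: int = 2,
    n_parent_samples: int = 2,
    noise: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Hybrid allele read counts plus parental expression levels per gene.

    Counts are Binomial(n_g, p_g) with ``p_g = 2^r / (1 + 2^r)`` for true F1
    log2 allelic ratio ``r`` and per-sample totals ``n_g ~ Poisson(depth)``;
    parental expression levels encode the parental log2 ratio.

    Returns ``(counts, parental_expression, truth)``.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    counts_per_cat = _category_counts(n_genes, category_mix)
    categories = [c for c in CATEGORIES for _ in range(counts_per_cat[c])]

    count_rows, expr_rows, truth_rows = [], [], []
    hyb_cols = [f"hyb{j+1}" for j in range(n_hybrid_samples)]
    for i, cat in enumerate(categories):
        gene = f"gene_{i:05d}"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        r_p, r_f1 = _true_ratios(cat, effect, sign)
        p_g = 2.0 ** r_f1 / (1.0 + 2.0 ** r_f1)
        crow: dict[str, object] = {"gene": gene}
        for col in hyb_cols:
            n_tot = int(rng.poisson(depth))
            b = int(rng.binomial(n_tot, p_g)) if n_tot > 0 else 0
            crow[f"{col}_B"] = b
            crow[f"{col}_D"] = n_tot - b
        count_rows.append(crow)
        e0 = rng.normal(8.0, 1.0)
        erow: dict[str, object] = {"gene": gene}
        for j in range(n_parent_samples):
            erow[f"B6_{j+1}"] = 2.0 ** (e0 + r_p / 2.0 + rng.normal(0.0, noise))
            erow[f"D2_{j+1}"] = 2.0 ** (e0 - r_p / 2.0 + rng.normal(0.0, noise))
        expr_rows.append(erow)
        truth_rows.append({"gene": gene, "category": cat, "r_parental": r_p,
                           "r_f1": r_f1, "p_binomial": p_g})

    counts = pd.DataFrame(count_rows).set_index("gene") if count_rows else pd.DataFrame(
        columns=[f"{c}_{a}" for c in hyb_cols for a in "BD"])
    parental = pd.DataFrame(expr_rows).set_index("gene") if expr_rows else pd.DataFrame()
    truth = SimTruth(genes=pd.DataFrame(
        truth_rows, columns=["gene", "category", "r_parental", "r_f1", "p_binomial"]
    ).set_index("gene") if truth_rows else None)
    return counts, parental, truth


# ---------------------------------------------------------------------------
# reference proteome + missense variants (proteogenomics stage input)


def simulate_reference_fasta(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (120, 300),
    variants_per_protein: float = 1.5,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """A small synthetic reference proteome and a missense-variant table.

    Sequences contain regular K/R sites so tryptic digestion yields
    MS-observable peptides; variants substitute non-K/R/P residues so most
    create a clean variant-peptide pair (occasional K/R gains are left in to
    exercise the cleavage-site-change path downstream).
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    rng = np.random.default_rng(seed)
    residues = list(_SAFE_RESIDUES + "KR")
    records: dict[str, str] = {}
    var_rows = []
    for i in range(n_proteins):
        acc = f"PROT{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(residues, size=length,
                                 p=[0.85 / len(_SAFE_RESIDUES)] * len(_SAFE_RESIDUES)
                                 + [0.075, 0.075]))
        records[acc] = seq
        n_var = int(rng.poisson(variants_per_protein))
        positions = rng.choice(np.arange(2, length), size=min(n_var, length - 2),
                               replace=False)
        for pos in sorted(int(p) for p in positions):
            ref = seq[pos - 1]
            choices = [r for r in _SAFE_RESIDUES if r != ref]
            alt = str(rng.choice(choices))
            var_rows.append({"gene": f"gene_{i:05d}", "protein": acc,
                             "position": pos, "ref": ref, "alt": alt})
    variants = pd.DataFrame(var_rows,
                            columns=["gene", "protein", "position", "ref", "alt"])
    return records, variants
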