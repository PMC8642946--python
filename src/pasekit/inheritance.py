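"""Genetic inheritance of protein expression: D/A, REML variance components, H².

The mixed model per protein is

    y = mu + A + D + S + e,    A ~ N(0, sigma_a^2 R1),  D ~ N(0, sigma_d^2 R2),
                               e ~ N(0, sigma_e^2 I),   S = fixed sex effect,

with R1 the additive and R2 the dominance relatedness matrix derived from the
pedigree expectations of the two-parent reciprocal-F1 design.  Broad-sense
heritability is H^2 = (Va + Vd) / (Va + Vd + Vs + Ve) where Vs is the
variance across samples of the fitted sex term (beta^2 / 4 with balanced
sexes and 0/1 coding).

Variance components are estimated by REML with a bounded derivative-free
search over log variances from three fixed starting points.  The response is
standardized to unit variance internally, making the estimator exactly
scale-equivariant (components scale with var(y), H^2 is invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .design import GENOTYPES, StrainDesign, genotype_means

log = logging.getLogger(__name__)

#: strain-level additive relatedness (order B6, D2, B6D2F1, D2B6F1):
#: parents mutually unrelated, each parent-F1 0.5, F1-F1 0.5, unit diagonal.
R1_STRAIN = np.array(
    [
        [1.0, 0.0, 0.5, 0.5],
        [0.0, 1.0, 0.5, 0.5],
        [0.5, 0.5, 1.0, 0.5],
        [0.5, 0.5, 0.5, 1.0],
    ]
)

#: strain-level dominance relatedness: off-diagonal 0 except F1-F1 = 0.25.
R2_STRAIN = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, 0.25],
        [0.0, 0.0, 0.25, 1.0],
    ]
)


@dataclass(frozen=True)
class RelatednessMatrices:
    """Sample-level expansions of the strain-level R1/R2 matrices."""

    r1: np.ndarray
    r2: np.ndarray
    sample_ids: tuple[str, ...]

    @property
    def strain_r1(self) -> pd.DataFrame:
        return pd.DataFrame(R1_STRAIN, index=GENOTYPES, columns=GENOTYPES)

    @property
    def strain_r2(self) -> pd.DataFrame:
        return pd.DataFrame(R2_STRAIN, index=GENOTYPES, columns=GENOTYPES)

    def r1_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r1, index=list(self.sample_ids),
                            columns=list(self.sample_ids))

    def r2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=list(self.sample_ids),
                            columns=list(self.sample_ids))


def build_relatedness_matrices(design: StrainDesign) -> RelatednessMatrices:
    """Expand the strain-level R1/R2 to sample level.

    Animals of the same genotype are isogenic (inbred or F1), so
    same-genotype pairs get relatedness 1 in both matrices; cross-genotype
    pairs take the strain-level entries.
    """
    geno = design.genotypes()
    idx = {g: i for i, g in enumerate(GENOTYPES)}
    n = design.n_samples
    r1 = np.empty((n, n))
    r2 = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if geno[i] == geno[j]:
                r1[i, j] = r2[i, j] = 1.0
            else:
                r1[i, j] = R1_STRAIN[idx[geno[i]], idx[geno[j]]]
                r2[i, j] = R2_STRAIN[idx[geno[i]], idx[geno[j]]]
    return RelatednessMatrices(r1, r2, tuple(design.sample_ids))


# ---------------------------------------------------------------------------
# dominance / additivity


@dataclass(frozen=True)
class InheritanceRow:
    additivity: float          # max(B6, D2) - mid-parent (always >= 0)
    dominance: float           # mean(F1s) - mid-parent
    da_ratio: float            # dominance / additivity (NaN when undefined)
    inheritance_class: str     # additive / dominant / over_under_dominant / undefined


def dominance_additivity_ratio(b6_mean: float, d2_mean: float,
                               f1_means: tuple[float, float],
                               tol: float = 1e-12) -> InheritanceRow:
    """D/A = (mean of the F1 genotype means - mid-parent) / (high parent - mid-parent).

    Undefined (NaN, class "undefined") when the parents are equal within
    ``tol``; such proteins are excluded from the D/A distribution.  Class
    convention: |D/A| <= 0.25 additive, 0.25 < |D/A| <= 1.25 dominant
    (partial to complete), |D/A| > 1.25 over/under-dominant.
    """
    mid = (b6_mean + d2_mean) / 2.0
    dom = (f1_means[0] + f1_means[1]) / 2.0 - mid
    add = max(b6_mean, d2_mean) - mid
    if add <= tol:
        return InheritanceRow(add, dom, float("nan"), "undefined")
    ratio = dom / add
    if abs(ratio) <= 0.25:
        cls = "additive"
    elif abs(ratio) <= 1.25:
        cls = "dominant"
    else:
        cls = "over_under_dominant"
    return InheritanceRow(add, dom, ratio, cls)


def inheritance_summary(matrix: pd.DataFrame, design: StrainDesign) -> pd.DataFrame:
    """Per-protein D/A statistics from genotype means of a log2 matrix."""
    gm = genotype_means(matrix, design)
    rows = [
        dominance_additivity_ratio(r.B6, r.D2, (r.B6D2F1, r.D2B6F1))
        for r in gm.itertuples()
    ]
    return pd.DataFrame(
        {
            "additivity": [r.additivity for r in rows],
            "dominance": [r.dominance for r in rows],
            "da_ratio": [r.da_ratio for r in rows],
            "inheritance_class": [r.inheritance_class for r in rows],
        },
        index=gm.index,
    )


# ---------------------------------------------------------------------------
# REML variance components


@dataclass
class VarianceComponents:
    va: float
    vd: float
    vs: float
    ve: float
    h2: float
    converged: bool = True
    degenerate: bool = False
    boundary: dict = field(default_factory=dict)  # component -> pinned at 0
    loglik: float = float("nan")


def heritability(vc: VarianceComponents | tuple[float, float, float, float]) -> float:
    """H^2 = (Va + Vd) / (Va + Vd + Vs + Ve); 0/0 reported as 0 (degenerate)."""
    if isinstance(vc, VarianceComponents):
        va, vd, vs, ve = vc.va, vc.vd, vc.vs, vc.ve
    else:
        va, vd, vs, ve = vc
    for name, v in (("Va", va), ("Vd", vd), ("Vs", vs), ("Ve", ve)):
        if v < 0:
            raise ValueError(f"negative variance component {name} = {v}")
    total = va + vd + vs + ve
    if total == 0:
        return 0.0
    return (va + vd) / total


_START_FRACTIONS = (
    (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),  # balanced
    (0.70, 0.15, 0.15),                 # genetic-heavy
    (0.05, 0.05, 0.90),                 # residual-heavy
)
_LOG_LOWER, _LOG_UPPER = -34.0, 6.0
_BOUNDARY_FRACTION = 1e-6


def _reml_nll(theta: np.ndarray, y: np.ndarray, x: np.ndarray,
              parts: list[np.ndarray], ridge: float) -> float:
    if np.any(theta < _LOG_LOWER) or np.any(theta > _LOG_UPPER):
        return np.inf
    v = sum(np.exp(t) * m for t, m in zip(theta, parts))
    v = v + ridge * np.eye(len(y))
    try:
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vi_x = linalg.cho_solve((c, low), x, check_finite=False)
    vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    xtvix = x.T @ vi_x
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvix, vi_x.T @ y)
    ytpy = float(y @ vi_y - (x.T @ vi_y) @ beta)
    return 0.5 * (logdet_v + logdet_x + ytpy)


def estimate_variance_components(
    y: np.ndarray | pd.Series,
    design: StrainDesign,
    matrices: RelatednessMatrices | None = None,
    *,
    sex_as_random: bool = False,
    ridge: float = 1e-8,
    tol: float = 1e-8,
    max_iter: int = 400,
) -> VarianceComponents:
    """REML estimates of (Va, Vd, Ve) plus the fixed-sex variance Vs and H^2.

    The restricted likelihood of ``y = X beta + A + D + e`` is maximized over
    non-negative components by Nelder-Mead on log variances, restarted from
    three fixed points.  A small ridge stabilizes the rank-deficient
    sample-level expansions of R1/R2.  Components pinned near zero are
    flagged in ``boundary``.  With ``sex_as_random=True`` sex becomes a
    fourth random component (same-sex relatedness 1) and Vs its estimated
    variance; otherwise sex is a fixed effect and Vs is the variance across
    samples of the fitted sex term.
    """
    y = np.asarray(y, dtype=float)
    n = design.n_samples
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, design has {n} samples")
    if n < 6:
        raise ValueError("variance-component estimation needs >= 6 samples")
    if matrices is None:
        matrices = build_relatedness_matrices(design)
    x_sex = design.sex_indicator()

    vy = float(np.var(y, ddof=1))
    if vy == 0.0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, converged=True,
                                  degenerate=True,
                                  boundary={"va": True, "vd": True, "ve": True})
    ys = y / np.sqrt(vy)

    parts = [matrices.r1, matrices.r2, np.eye(n)]
    names = ["va", "vd", "ve"]
    if sex_as_random:
        sex_rel = (x_sex[:, None] == x_sex[None, :]).astype(float)
        parts.insert(2, sex_rel)
        names.insert(2, "vs")
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), x_sex])

    k = len(parts)
    best: optimize.OptimizeResult | None = None
    for frac in _START_FRACTIONS:
        if k == 4:
            f = (frac[0], frac[1], 0.5 * frac[2], 0.5 * frac[2])
        else:
            f = frac
        theta0 = np.log(np.asarray(f))
        res = optimize.minimize(
            _reml_nll, theta0, args=(ys, x, parts, ridge), method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-6, "maxiter": max_iter,
                     "maxfev": 2 * max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    v_std = np.exp(best.x)
    comps = dict(zip(names, v_std * vy))
    boundary = {name: bool(v_std[i] < _BOUNDARY_FRACTION) for i, name in enumerate(names)}

    # GLS fixed effects at the estimate (original scale)
    v_full = sum(c * m for c, m in zip(v_std * vy, parts)) + ridge * vy * np.eye(n)
    c_fac = linalg.cho_factor(v_full, lower=True, check_finite=False)
    vi_x = linalg.cho_solve(c_fac, x, check_finite=False)
    beta = np.linalg.solve(x.T @ vi_x, vi_x.T @ y)
    if sex_as_random:
        vs = comps["vs"]
    else:
        sex_term = x_sex * beta[1]
        vs = float(np.var(sex_term))  # population variance; beta^2/4 when balanced
    va, vd, ve = comps["va"], comps["vd"], comps["ve"]
    # zero out components pinned at the numerical floor
    va = 0.0 if boundary["va"] else va
    vd = 0.0 if boundary["vd"] else vd
    ve = 0.0 if boundary["ve"] else ve
    if sex_as_random and boundary.get("vs"):
        vs = 0.0
    total = va + vd + vs + ve
    degenerate = total == 0.0
    h2 = 0.0 if degenerate else (va + vd) / total
    if not best.success:
        log.warning("REML did not converge; reporting best point found")
    return VarianceComponents(va, vd, vs, ve, h2, converged=bool(best.success),
                              degenerate=degenerate, boundary=boundary,
                              loglik=-float(best.fun))


def reml_loglik(y: np.ndarray, design: StrainDesign,
                matrices: RelatednessMatrices, components: tuple[float, float, float],
                *, ridge: float = 1e-8) -> float:
    """Restricted log-likelihood at given (Va, Vd, Ve), for diagnostics/tests."""
    y = np.asarray(y, dtype=float)
    x = np.column_stack([np.ones(design.n_samples), design.sex_indicator()])
    parts = [matrices.r1, matrices.r2, np.eye(design.n_samples)]
    with np.errstate(divide="ignore"):
        theta = np.log(np.maximum(np.asarray(components, dtype=float), 1e-300))
    return -_reml_nll(theta, y, x, parts, ridge)


def variance_components_table(matrix: pd.DataFrame, design: StrainDesign,
                              *, sex_as_random: bool = False) -> pd.DataFrame:
    """Per-protein Va, Vd, Vs, Ve, H^2, D/A, and class for a log2 matrix."""
    matrices = build_relatedness_matrices(design)
    cols = design.sample_ids
    rows = []
    for pid, row in matrix[cols].iterrows():
        vc = estimate_variance_components(row.to_numpy(), design, matrices,
                                          sex_as_random=sex_as_random)
        rows.append({"protein": pid, "va": vc.va, "vd": vc.vd, "vs": vc.vs,
                     "ve": vc.ve, "h2": vc.h2, "converged": vc.converged,
                     "degenerate": vc.degenerate,
                     "boundary": ";".join(k for k, v in vc.boundary.items() if v)})
    vc_df = pd.DataFrame(rows).set_index("protein")
    da = inheritance_summary(matrix, design)
    return vc_df.join(da)
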