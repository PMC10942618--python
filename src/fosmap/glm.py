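"""Overdispersed-count GLM screening of brain regions.

Each region's c-Fos+ cell counts are modeled with a log-link quasi-Poisson
GLM. A null model carries the nuisance design (sex S, timepoint T as a
linear + quadratic polynomial, block B); the bonding model adds partner
type P and its interactions (P, PxS, PxT, PxT^2). The two fits are
compared with a quasi-likelihood ANOVA F statistic

    F = [(D_null - D_full) / df_num] / phi_full,

where D is the Poisson deviance and phi the Pearson dispersion of the
fuller model. Significance is calibrated by a Monte-Carlo permutation
null (shuffling partner labels, one shared shuffle across regions per
draw), and Benjamini-Hochberg FDR is applied across regions.

Point estimates of a quasi-Poisson fit coincide with Poisson maximum
likelihood, so the IRLS here targets the Poisson score equations; the
dispersion only scales inference. The IRLS is vectorized across regions
(and reused across permutation draws with warm starts), which is what
makes 10^4-shuffle screens tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats, special
from statsmodels.stats.multitest import multipletests

from .core import AnimalDesign, CountMatrix, FosmapError, ValidationError

__all__ = [
    "NULL_TERMS",
    "FULL_TERMS",
    "SEX_REDUCED_TERMS",
    "GlmError",
    "DesignRankWarning",
    "GlmFit",
    "ModelComparison",
    "ScreenResult",
    "build_design",
    "fit_quasipoisson",
    "compare_models",
    "permutation_screen",
    "sex_interaction_screen",
    "fdr_adjust",
    "compare_region_volumes",
    "detect_count_outliers",
]

#: Nuisance-only model terms (intercept is always included).
NULL_TERMS = ("S", "T", "T2", "B")
#: Bonding model terms: nuisance + partner main effect and interactions.
FULL_TERMS = ("S", "T", "T2", "B", "P", "PxS", "PxT", "PxT2")
#: Bonding model without the partner-by-sex interaction.
SEX_REDUCED_TERMS = ("S", "T", "T2", "B", "P", "PxT", "PxT2")

_KNOWN_TERMS = {"S", "T", "T2", "B", "P", "PxS", "PxT", "PxT2"}


class GlmError(FosmapError):
    """GLM fitting failure (rank deficiency, non-convergence)."""


class DesignRankWarning(UserWarning):
    """A requested design column is constant (zero after coding)."""


@dataclass
class GlmFit:
    coefficients: dict[str, float]
    deviance: float
    pearson_dispersion: float
    df_residual: int
    fitted_means: np.ndarray
    converged: bool


@dataclass
class ModelComparison:
    f_stat: float
    df_num: int
    df_den: int
    p_parametric: float
    direction: int


@dataclass
class ScreenResult:
    roi_id: str
    f_stat: float
    p_perm: float
    q_value: float
    direction: int
    n_permutations: int


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def _term_columns(design: list[AnimalDesign]) -> dict[str, np.ndarray]:
    S = np.array([1.0 if r.sex == "M" else 0.0 for r in design])
    T = np.array([float(r.timepoint) for r in design])
    B = np.array([float(r.block) for r in design])
    P = np.array([1.0 if r.partner == "mate" else 0.0 for r in design])
    return {
        "S": S,
        "T": T,
        "T2": T**2,
        "B": B,
        "P": P,
        "PxS": P * S,
        "PxT": P * T,
        "PxT2": P * T**2,
    }


def build_design(
    design: list[AnimalDesign], terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + requested term columns, in term order.

    Sex and partner are coded 0/1 (reference female / sibling); timepoint
    enters as its raw ordinal value 1..4 and its square; block as a single
    linear numeric column. Columns that come out constant (e.g. any P term
    on an all-sibling design) raise a :class:`DesignRankWarning`.
    """
    unknown = [t for t in terms if t not in _KNOWN_TERMS]
    if unknown:
        raise GlmError(f"unknown model terms: {unknown}")
    cols = _term_columns(design)
    X = [np.ones(len(design))]
    names = ["const"]
    for t in terms:
        c = cols[t]
        if np.ptp(c) == 0:
            warnings.warn(
                f"design column {t!r} is constant and will make the model rank-deficient",
                DesignRankWarning,
                stacklevel=2,
            )
        X.append(c)
        names.append(t)
    return np.column_stack(X), names


# ---------------------------------------------------------------------------
# IRLS (single and batched)
# ---------------------------------------------------------------------------


def _poisson_deviance(Y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    # 2 * sum[y log(y/mu) - (y - mu)], with y log(y/mu) = 0 at y = 0
    return 2.0 * (special.xlogy(Y, Y / mu) - (Y - mu)).sum(axis=-1)


def _irls_batched(
    Y: np.ndarray,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Log-link Poisson IRLS for many responses sharing one design.

    Y is (R, n), X is (n, p). Returns (beta (R, p), deviance (R,),
    pearson_phi (R,), converged (R,) bool). Rows are iterated jointly;
    convergence is tracked per row on the relative deviance change.
    """
    R, n = Y.shape
    p = X.shape[1]
    if beta0 is None:
        mu = Y + 0.5
        eta = np.log(mu)
    else:
        eta = beta0 @ X.T
        mu = np.exp(eta)
    dev = _poisson_deviance(Y, mu)
    beta = np.zeros((R, p)) if beta0 is None else beta0.copy()
    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        z = eta + (Y - mu) / mu
        XW = X[None, :, :] * mu[:, :, None]  # (R, n, p)
        A = XW.transpose(0, 2, 1) @ X
        b = (mu * z) @ X
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise GlmError(f"singular weighted design: {exc}") from exc
        eta = np.clip(beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(Y, mu)
        converged = np.abs(new_dev - dev) <= tol * (np.abs(new_dev) + 0.1)
        dev = new_dev
        if converged.all():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = (((Y - mu) ** 2) / mu).sum(axis=1)
    df_resid = n - p
    phi = pearson / df_resid if df_resid > 0 else np.full(R, np.nan)
    return beta, dev, phi, converged


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by QR with pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = [names[i] for i in piv[rank:]]
        raise GlmError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> GlmFit:
    """Quasi-Poisson (log-link) fit of one count response.

    Point estimates are the Poisson MLE; ``pearson_dispersion`` is
    phi-hat = Pearson chi^2 / (n - p). Raises :class:`GlmError` on rank
    deficiency (naming the collinear columns) or non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise GlmError("y must be 1-D and aligned with the rows of X")
    if (y < 0).any() or (y != np.floor(y)).any():
        raise ValidationError("counts must be non-negative integers")
    names = names or [f"x{i}" for i in range(X.shape[1])]
    _check_rank(X, names)
    beta, dev, phi, conv = _irls_batched(y[None, :], X, max_iter=max_iter, tol=tol)
    if not conv[0]:
        raise GlmError(
            f"IRLS did not converge in {max_iter} iterations (deviance {dev[0]:.6g})"
        )
    mu = np.exp(np.clip(beta[0] @ X.T, -30.0, 30.0))
    return GlmFit(
        coefficients=dict(zip(names, beta[0])),
        deviance=float(dev[0]),
        pearson_dispersion=float(phi[0]),
        df_residual=int(y.shape[0] - X.shape[1]),
        fitted_means=mu,
        converged=True,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def compare_models(
    y: np.ndarray,
    design: list[AnimalDesign],
    null_terms: tuple[str, ...] = NULL_TERMS,
    full_terms: tuple[str, ...] = FULL_TERMS,
    dispersion: float | None = None,
) -> ModelComparison:
    """Quasi-likelihood ANOVA comparison of two nested GLMs.

    F = [(D_null - D_full)/df_num] / phi with phi the Pearson dispersion
    of the full model (overridable via ``dispersion``; forcing 1 reduces F
    to the likelihood-ratio chi^2 / df_num). ``direction`` is the sign of
    the partner main-effect coefficient in the full model when partner is
    part of the added terms, otherwise the sign of the first added term.
    """
    added = [t for t in full_terms if t not in null_terms]
    if not added or any(t not in full_terms for t in null_terms):
        raise GlmError("null terms must be a strict subset of full terms")
    Xn, names_n = build_design(design, tuple(null_terms))
    Xf, names_f = build_design(design, tuple(full_terms))
    fit_n = fit_quasipoisson(y, Xn, names_n)
    fit_f = fit_quasipoisson(y, Xf, names_f)
    df_num = Xf.shape[1] - Xn.shape[1]
    df_den = fit_f.df_residual
    phi = fit_f.pearson_dispersion if dispersion is None else float(dispersion)
    delta = max(fit_n.deviance - fit_f.deviance, 0.0)
    f = 0.0 if delta < 1e-12 else delta / df_num / phi
    key = "P" if "P" in added else added[0]
    direction = int(np.sign(fit_f.coefficients[key]))
    return ModelComparison(
        f_stat=float(f),
        df_num=df_num,
        df_den=df_den,
        p_parametric=float(stats.f.sf(f, df_num, df_den)),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Permutation screens
# ---------------------------------------------------------------------------


def _batched_f(
    Y: np.ndarray,
    X_null: np.ndarray,
    X_full: np.ndarray,
    beta0_null: np.ndarray | None = None,
    beta0_full: np.ndarray | None = None,
    dev_null: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """F statistics for all regions at once; returns (F, beta_full, dev_null)."""
    if dev_null is None:
        _, dev_null, _, _ = _irls_batched(Y, X_null, beta0=beta0_null)
    beta_f, dev_f, phi_f, _ = _irls_batched(Y, X_full, beta0=beta0_full)
    df_num = X_full.shape[1] - X_null.shape[1]
    delta = np.maximum(dev_null - dev_f, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(delta < 1e-9, 0.0, delta / df_num / np.maximum(phi_f, 1e-12))
    return F, beta_f, dev_null


def _replace_partner(design: list[AnimalDesign], partner: np.ndarray) -> list[AnimalDesign]:
    from dataclasses import replace

    return [
        replace(r, partner=("mate" if p else "sibling"), pair_id=r.pair_id)
        for r, p in zip(design, partner)
    ]


def _design_with(design: list[AnimalDesign], *, partner=None, sex=None) -> np.ndarray:
    """Raw term columns with partner and/or sex vectors substituted."""
    cols = _term_columns(design)
    if partner is not None:
        P = np.asarray(partner, dtype=float)
        cols["P"] = P
        cols["PxS"] = P * cols["S"]
        cols["PxT"] = P * cols["T"]
        cols["PxT2"] = P * cols["T2"]
    if sex is not None:
        S = np.asarray(sex, dtype=float)
        cols["S"] = S
        cols["PxS"] = cols["P"] * S
    return cols


def _assemble(cols: dict[str, np.ndarray], terms: tuple[str, ...], n: int) -> np.ndarray:
    return np.column_stack([np.ones(n)] + [cols[t] for t in terms])


def permutation_screen(
    counts: CountMatrix,
    design: list[AnimalDesign],
    null_terms: tuple[str, ...] = NULL_TERMS,
    full_terms: tuple[str, ...] = FULL_TERMS,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[list[ScreenResult], list[tuple[str, str]]]:
    """Permutation-calibrated model-comparison screen across regions.

    For each Monte-Carlo draw the partner-label vector is shuffled across
    animals (one shared shuffle for every region) and the bonding model is
    refit; the nuisance model contains no partner term, so its deviance is
    unchanged by the shuffle and is computed once. p-values use the
    plus-one rule p = (1 + #{F* >= F_obs}) / (1 + n_perm), and q-values
    are Benjamini-Hochberg across the screened family.

    Returns (results sorted as the input ROI order, skipped) where
    ``skipped`` lists (roi_id, reason) for regions that could not be fit
    (e.g. all-zero counts).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(design)
    if counts.shape[0] != n:
        raise ValidationError("count matrix and design have different numbers of animals")

    roi_ids = counts.roi_ids
    Y_all = counts.values.T.astype(float)  # (R, n)
    keep = Y_all.sum(axis=1) > 0
    skipped = [(roi_ids[i], "all-zero counts") for i in np.nonzero(~keep)[0]]
    Y = Y_all[keep]
    kept_ids = [r for r, k in zip(roi_ids, keep) if k]
    if Y.shape[0] == 0:
        return [], skipped

    cols = _term_columns(design)
    X_null = _assemble(cols, tuple(null_terms), n)
    X_full = _assemble(cols, tuple(full_terms), n)
    _check_rank(X_full, ["const", *full_terms])
    added = [t for t in full_terms if t not in null_terms]
    if not added:
        raise GlmError("null and full models are identical")

    F_obs, beta_full, dev_null = _batched_f(Y, X_null, X_full)
    p_idx = 1 + list(full_terms).index("P") if "P" in full_terms else None
    direction = (
        np.sign(beta_full[:, p_idx]).astype(int)
        if p_idx is not None
        else np.sign(beta_full[:, 1 + list(full_terms).index(added[0])]).astype(int)
    )

    partner = cols["P"].copy()
    exceed = np.zeros(Y.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(partner)
        cols_b = _design_with(design, partner=perm)
        Xf_b = _assemble(cols_b, tuple(full_terms), n)
        F_b, _, _ = _batched_f(
            Y, X_null, Xf_b, beta0_full=beta_full, dev_null=dev_null
        )
        exceed += F_b >= F_obs
    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    q = fdr_adjust(p_perm)
    results = [
        ScreenResult(rid, float(F_obs[i]), float(p_perm[i]), float(q[i]), int(direction[i]), n_perm)
        for i, rid in enumerate(kept_ids)
    ]
    return results, skipped


def sex_interaction_screen(
    counts: CountMatrix,
    design: list[AnimalDesign],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[list[ScreenResult], list[tuple[str, str]]]:
    """Screen for partner-by-sex interaction effects.

    Compares the bonding model to the same model without the PxS term.
    The permuted label is sex, shuffled *within* partner groups so the
    partner main effect and partner-time structure are preserved under
    the null; both models contain sex terms, so both are refit per draw.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(design)
    roi_ids = counts.roi_ids
    Y_all = counts.values.T.astype(float)
    keep = Y_all.sum(axis=1) > 0
    skipped = [(roi_ids[i], "all-zero counts") for i in np.nonzero(~keep)[0]]
    Y = Y_all[keep]
    kept_ids = [r for r, k in zip(roi_ids, keep) if k]
    if Y.shape[0] == 0:
        return [], skipped

    null_terms, full_terms = SEX_REDUCED_TERMS, FULL_TERMS
    cols = _term_columns(design)
    X_null = _assemble(cols, null_terms, n)
    X_full = _assemble(cols, full_terms, n)
    F_obs, beta_full, _ = _batched_f(Y, X_null, X_full)
    pxs_idx = 1 + list(full_terms).index("PxS")
    direction = np.sign(beta_full[:, pxs_idx]).astype(int)

    sex = cols["S"].copy()
    groups = [np.nonzero(cols["P"] == v)[0] for v in (0.0, 1.0)]
    exceed = np.zeros(Y.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        s_perm = sex.copy()
        for g in groups:
            s_perm[g] = sex[g][rng.permutation(len(g))]
        cols_b = _design_with(design, sex=s_perm)
        Xn_b = _assemble(cols_b, null_terms, n)
        Xf_b = _assemble(cols_b, full_terms, n)
        F_b, _, _ = _batched_f(Y, Xn_b, Xf_b, beta0_full=beta_full)
        exceed += F_b >= F_obs
    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    q = fdr_adjust(p_perm)
    results = [
        ScreenResult(rid, float(F_obs[i]), float(p_perm[i]), float(q[i]), int(direction[i]), n_perm)
        for i, rid in enumerate(kept_ids)
    ]
    return results, skipped


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Region-volume comparison (negative binomial)
# ---------------------------------------------------------------------------


def compare_region_volumes(
    volumes,
    group: np.ndarray,
    relative: bool = False,
    whole_brain: np.ndarray | None = None,
):
    """Per-region negative-binomial comparison of voxel volumes between 2 groups.

    ``volumes`` is a regions x animals DataFrame of positive voxel counts,
    ``group`` a length-n_animals label vector with exactly two levels.
    With ``relative=True`` a log(whole-brain volume) offset is included so
    the group coefficient tests the region's *relative* volume (the ratio
    to whole brain); ``whole_brain`` defaults to the column sums.

    Returns a DataFrame with columns region, coef, z, p, q, skipped_reason
    (q is BH across the tested regions; exp(coef) is the fold change of
    the second group level over the first).
    """
    import pandas as pd
    import statsmodels.api as sm

    group = np.asarray(group)
    levels = sorted(pd.unique(group))
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {levels}")
    g = (group == levels[1]).astype(float)
    X = np.column_stack([np.ones(len(g)), g])
    offset = None
    if relative:
        wb = np.asarray(whole_brain, dtype=float) if whole_brain is not None else volumes.sum(axis=0).to_numpy(dtype=float)
        offset = np.log(wb)

    rows = []
    for region in volumes.index:
        y = volumes.loc[region].to_numpy(dtype=float)
        reason = None
        if min((group == lv).sum() for lv in levels) < 2:
            reason = "fewer than 2 animals per group"
        if reason is None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.NegativeBinomial(y, X, offset=offset)
                    res = model.fit(disp=0, maxiter=200)
                coef = float(res.params[1])
                z = float(res.tvalues[1])
                p = float(res.pvalues[1])
                rows.append((region, coef, z, p, None))
                continue
            except Exception as exc:  # convergence failures on degenerate regions
                reason = f"fit failed: {exc}"
        rows.append((region, np.nan, np.nan, np.nan, reason))
    out = pd.DataFrame(rows, columns=["region", "coef", "z", "p", "skipped_reason"])
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = fdr_adjust(out.loc[tested, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Rosner (generalized ESD) outlier screen
# ---------------------------------------------------------------------------


@dataclass
class OutlierResult:
    flagged: list[int]
    r_statistics: list[float]
    critical_values: list[float]
    candidates: list[int]
    notice: str | None = None


def detect_count_outliers(totals, max_k: int, alpha: float = 0.05) -> OutlierResult:
    """Rosner's generalized extreme studentized deviate (ESD) test.

    Iteratively removes the point with the largest studentized deviation
    R_i = max|x - mean| / sd and compares each R_i against the two-sided
    t-based critical value lambda_i at level ``alpha``; the largest i with
    R_i > lambda_i determines the flagged set (that removal and all
    earlier ones). ``flagged`` holds indices into ``totals``.
    """
    x = np.asarray(totals, dtype=float)
    n = x.size
    if max_k >= n - 2:
        raise ValidationError("max_k must be < n - 2")
    if np.ptp(x) == 0:
        return OutlierResult([], [], [], [], notice="zero variance: R undefined")
    idx = np.arange(n)
    work = x.copy()
    r_stats, lambdas, candidates = [], [], []
    for i in range(1, max_k + 1):
        m = work.size
        sd = work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - work.mean())
        j = int(np.argmax(dev))
        r_stats.append(float(dev[j] / sd))
        candidates.append(int(idx[j]))
        pt = 1 - alpha / (2 * (n - i + 1))
        t = stats.t.ppf(pt, n - i - 1)
        lam = (n - i) * t / np.sqrt((n - i - 1 + t**2) * (n - i + 1))
        lambdas.append(float(lam))
        work = np.delete(work, j)
        idx = np.delete(idx, j)
    k_star = 0
    for i, (r, lam) in enumerate(zip(r_stats, lambdas), start=1):
        if r > lam:
            k_star = i
    return OutlierResult(
        flagged=candidates[:k_star],
        r_statistics=r_stats,
        critical_values=lambdas,
        candidates=candidates,
    )
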