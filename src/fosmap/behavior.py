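"""Brain-behavior coupling and within-pair coordination statistics.

Canonical correlation analysis (CCA) links the behavioral measures to
regional c-Fos counts; Wilk's lambda (Bartlett's chi-square
approximation) tests which canonical factors carry signal, and loadings
(correlations of raw variables with factor scores) interpret them.
Within-pair coordination is quantified by Pearson correlations of
female vs male regional counts across mate pairs, with partial
correlations controlling for the pair's ejaculation count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnimalDesign, BehaviorTable, CountMatrix, ValidationError
from .glm import fdr_adjust

__all__ = [
    "CcaResult",
    "PairSimilarityMatrix",
    "cca",
    "loading_correlations",
    "pair_similarity",
    "partial_pair_similarity",
    "group_ttests",
]


@dataclass
class CcaResult:
    canonical_correlations: np.ndarray
    scores_x: np.ndarray
    scores_y: np.ndarray
    loadings_x: pd.DataFrame
    loadings_y: pd.DataFrame
    #: per-factor rows: (wilks_lambda, chi_square, df, p)
    wilks: pd.DataFrame
    x_names: list[str]
    y_names: list[str]


@dataclass
class PairSimilarityMatrix:
    roi_rows: list[str]
    roi_cols: list[str]
    r: pd.DataFrame
    n_pairs: int
    kind: str = "raw"
    covariate: str | None = None


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------


def _standardize(M: np.ndarray, names: list[str]) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    zero = [names[i] for i in np.nonzero(sd == 0)[0]]
    if zero:
        raise ValidationError(f"zero-variance columns: {zero}")
    return (M - M.mean(axis=0)) / sd


def _whitener(M: np.ndarray, names: list[str]) -> np.ndarray:
    """Inverse symmetric square root of the covariance; errors on collinearity."""
    cov = np.cov(M, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    w, V = np.linalg.eigh(cov)
    if w.min() <= 1e-10 * w.max():
        bad = [names[i] for i in np.argsort(np.abs(V[:, 0]))[::-1][:3]]
        raise ValidationError(
            f"collinear columns within a set (near-singular covariance; involved: {bad})"
        )
    return V @ np.diag(w**-0.5) @ V.T


def cca(X: pd.DataFrame, Y: pd.DataFrame, standardize: bool = True) -> CcaResult:
    """Canonical correlation analysis of two variable sets.

    Canonical weights come from the SVD of the whitened cross-covariance
    Sx^{-1/2} Sxy Sy^{-1/2}; factor scores have unit sample variance and
    are mutually uncorrelated within a set. For factor k (1-based),
    Wilk's Lambda_k = prod_{j>=k} (1 - r_j^2) with Bartlett's
    chi^2 = -[n - 1 - (p+q+1)/2] ln Lambda_k on (p-k+1)(q-k+1) df,
    testing that factors k..m jointly carry no association. Each factor
    is oriented so that its largest-|loading| X variable loads positively.
    """
    if list(X.index) != list(Y.index):
        raise ValidationError("X and Y must cover the same animals in the same order")
    n, p = X.shape
    q = Y.shape[1]
    if n <= max(p, q):
        raise ValidationError(f"need n > max(p, q); got n={n}, p={p}, q={q}")
    x_names, y_names = list(X.columns), list(Y.columns)
    Xa = X.to_numpy(dtype=float)
    Ya = Y.to_numpy(dtype=float)
    if standardize:
        Xa = _standardize(Xa, x_names)
        Ya = _standardize(Ya, y_names)
    else:
        Xa = Xa - Xa.mean(axis=0)
        Ya = Ya - Ya.mean(axis=0)

    Wx = _whitener(Xa, x_names)
    Wy = _whitener(Ya, y_names)
    Sxy = (Xa.T @ Ya) / (n - 1)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    m = min(p, q)
    r = np.clip(s[:m], 0.0, 1.0)
    A = Wx @ U[:, :m]  # x weights
    B = Wy @ Vt[:m].T  # y weights
    scores_x = Xa @ A
    scores_y = Ya @ B
    # unit sample variance per factor
    scores_x /= scores_x.std(axis=0, ddof=1)
    scores_y /= scores_y.std(axis=0, ddof=1)

    lx = loading_correlations(pd.DataFrame(Xa, columns=x_names), scores_x)
    for k in range(m):
        top = int(np.nanargmax(np.abs(lx.iloc[:, k].to_numpy())))
        if lx.iloc[top, k] < 0:
            scores_x[:, k] *= -1
            scores_y[:, k] *= -1
    loadings_x = loading_correlations(pd.DataFrame(Xa, columns=x_names), scores_x)
    loadings_y = loading_correlations(pd.DataFrame(Ya, columns=y_names), scores_y)

    rows = []
    for k in range(1, m + 1):
        lam = float(np.prod(1.0 - r[k - 1 :] ** 2))
        df = (p - k + 1) * (q - k + 1)
        chi2 = -(n - 1 - (p + q + 1) / 2.0) * np.log(max(lam, np.finfo(float).tiny))
        rows.append((lam, chi2, df, float(stats.chi2.sf(chi2, df))))
    wilks = pd.DataFrame(rows, columns=["lambda", "chi_square", "df", "p"],
                         index=[f"CC{k}" for k in range(1, m + 1)])
    return CcaResult(
        canonical_correlations=r,
        scores_x=scores_x,
        scores_y=scores_y,
        loadings_x=loadings_x,
        loadings_y=loadings_y,
        wilks=wilks,
        x_names=x_names,
        y_names=y_names,
    )


def loading_correlations(variables: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of each raw variable with each factor score.

    Zero-variance variables yield NaN loadings (recorded, not dropped).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != variables.shape[0]:
        raise ValidationError("variables and scores must cover the same animals")
    out = np.full((variables.shape[1], scores.shape[1]), np.nan)
    V = variables.to_numpy(dtype=float)
    for i in range(V.shape[1]):
        if V[:, i].std() == 0:
            continue
        for k in range(scores.shape[1]):
            out[i, k] = np.corrcoef(V[:, i], scores[:, k])[0, 1]
    return pd.DataFrame(out, index=variables.columns,
                        columns=[f"CC{k + 1}" for k in range(scores.shape[1])])


# ---------------------------------------------------------------------------
# Within-pair similarity
# ---------------------------------------------------------------------------


def paired_arrays(
    values: pd.DataFrame,
    design: list[AnimalDesign],
    timepoints: tuple[int, ...] = (2, 3),
    partner: str = "mate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split per-animal values into aligned (pairs x columns) F and M frames.

    For mate pairs rows are (female member, male member); for sibling
    pairs the two same-sex members are ordered by animal id.
    """
    by_pair: dict[str, list[AnimalDesign]] = {}
    for r in design:
        if r.partner == partner and r.timepoint in timepoints and r.animal_id in values.index:
            by_pair.setdefault(r.pair_id, []).append(r)
    rows_a, rows_b, pids = [], [], []
    for pid in sorted(by_pair):
        members = by_pair[pid]
        if len(members) != 2:
            continue
        if partner == "mate":
            members = sorted(members, key=lambda r: r.sex)  # F first
        else:
            members = sorted(members, key=lambda r: r.animal_id)
        rows_a.append(values.loc[members[0].animal_id])
        rows_b.append(values.loc[members[1].animal_id])
        pids.append(pid)
    A = pd.DataFrame(rows_a, index=pids)
    B = pd.DataFrame(rows_b, index=pids)
    return A, B


def pair_similarity(
    counts: CountMatrix | pd.DataFrame,
    design: list[AnimalDesign],
    rois: list[str],
    timepoints: tuple[int, ...] = (2, 3),
    partner: str = "mate",
) -> PairSimilarityMatrix:
    """Across-pair Pearson correlation of female vs male regional activity.

    r[i, j] correlates, across included pairs, the female member's count
    in region i with the male member's count in region j; the diagonal is
    the same-region coordination profile. Scalar per-animal measures
    (e.g. CC1 scores) can be passed as a single-column frame.
    """
    values = counts.df if isinstance(counts, CountMatrix) else counts
    missing = [r for r in rois if r not in values.columns]
    if missing:
        raise ValidationError(f"ROIs not in table: {missing}")
    F, M = paired_arrays(values[rois].astype(float), design, timepoints, partner)
    if len(F) < 3:
        raise ValidationError(f"need >= 3 pairs, got {len(F)}")
    r = np.full((len(rois), len(rois)), np.nan)
    Fa, Ma = F.to_numpy(), M.to_numpy()
    for i in range(len(rois)):
        if Fa[:, i].std() == 0:
            continue
        for j in range(len(rois)):
            if Ma[:, j].std() == 0:
                continue
            r[i, j] = np.corrcoef(Fa[:, i], Ma[:, j])[0, 1]
    return PairSimilarityMatrix(
        roi_rows=list(rois),
        roi_cols=list(rois),
        r=pd.DataFrame(r, index=rois, columns=rois),
        n_pairs=len(F),
        kind="raw",
    )


def partial_pair_similarity(
    counts: CountMatrix | pd.DataFrame,
    design: list[AnimalDesign],
    rois: list[str],
    covariate: pd.Series,
    timepoints: tuple[int, ...] = (2, 3),
    partner: str = "mate",
    covariate_name: str = "covariate",
) -> PairSimilarityMatrix:
    """Pair similarity with a per-pair covariate partialed out.

    Applies r_xy.z = (r_xy - r_xz r_yz) / sqrt[(1-r_xz^2)(1-r_yz^2)]
    cellwise with z the covariate (e.g. the pair's ejaculation count).
    Cells where |r_xz| = 1 or |r_yz| = 1 are left undefined (NaN).
    """
    values = counts.df if isinstance(counts, CountMatrix) else counts
    F, M = paired_arrays(values[rois].astype(float), design, timepoints, partner)
    if len(F) < 3:
        raise ValidationError(f"need >= 3 pairs, got {len(F)}")
    missing = [p for p in F.index if p not in covariate.index]
    if missing:
        raise ValidationError(f"covariate missing for pairs: {missing}")
    z = covariate.loc[F.index].to_numpy(dtype=float)
    if z.std() == 0:
        raise ValidationError("covariate has zero variance across included pairs")
    r = np.full((len(rois), len(rois)), np.nan)
    Fa, Ma = F.to_numpy(), M.to_numpy()

    def corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return np.corrcoef(a, b)[0, 1]

    rxz = np.array([corr(Fa[:, i], z) for i in range(len(rois))])
    ryz = np.array([corr(Ma[:, j], z) for j in range(len(rois))])
    for i in range(len(rois)):
        for j in range(len(rois)):
            rxy = corr(Fa[:, i], Ma[:, j])
            if np.isnan(rxy) or np.isnan(rxz[i]) or np.isnan(ryz[j]):
                continue
            if abs(rxz[i]) >= 1.0 - 1e-12 or abs(ryz[j]) >= 1.0 - 1e-12:
                continue
            r[i, j] = (rxy - rxz[i] * ryz[j]) / np.sqrt(
                (1 - rxz[i] ** 2) * (1 - ryz[j] ** 2)
            )
    return PairSimilarityMatrix(
        roi_rows=list(rois),
        roi_cols=list(rois),
        r=pd.DataFrame(r, index=rois, columns=rois),
        n_pairs=len(F),
        kind="partial",
        covariate=covariate_name,
    )


# ---------------------------------------------------------------------------
# Behavioral group tests
# ---------------------------------------------------------------------------


def group_ttests(
    behavior: BehaviorTable,
    design: list[AnimalDesign],
    per_timepoint: bool = False,
) -> pd.DataFrame:
    """Welch (mate vs sibling) and paired (F vs M mates) tests per measure.

    Dyad-level measures are tested once per dyad; individual-level
    measures per animal. Paired tests compare the female and male member
    of each mate pair. BH q-values are computed across the pooled family;
    optional follow-ups repeat the Welch test per timepoint.

    Returns columns: measure, comparison, timepoint, n1, n2, t, df, p, q,
    skipped_reason. Degenerate cases (zero-variance difference, group
    < 2) are flagged, not silently dropped.
    """
    info = {r.animal_id: r for r in design}
    levels = dict(behavior.levels)
    rows = []
    tps: list[tuple[int, ...] | None] = [None]
    if per_timepoint:
        tps += [(t,) for t in sorted({r.timepoint for r in design})]

    def unit_values(measure: str, pred) -> np.ndarray:
        lvl = levels.get(measure, "individual")
        if lvl == "dyad":
            seen = {}
            for aid in behavior.df.index:
                r = info.get(str(aid))
                if r is None or not pred(r):
                    continue
                seen.setdefault(r.pair_id, behavior.df.loc[aid, measure])
            return np.array(list(seen.values()), dtype=float)
        return np.array(
            [
                behavior.df.loc[aid, measure]
                for aid in behavior.df.index
                if str(aid) in info and pred(info[str(aid)])
            ],
            dtype=float,
        )

    for measure in behavior.measures:
        for tp in tps:
            in_tp = (lambda r: True) if tp is None else (lambda r: r.timepoint in tp)
            a = unit_values(measure, lambda r: r.partner == "mate" and in_tp(r))
            b = unit_values(measure, lambda r: r.partner == "sibling" and in_tp(r))
            if len(a) < 2 or len(b) < 2:
                rows.append((measure, "mate-vs-sibling", tp, len(a), len(b),
                             np.nan, np.nan, np.nan, "group size < 2"))
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                df = stats.ttest_ind(a, b, equal_var=False).df
                rows.append((measure, "mate-vs-sibling", tp, len(a), len(b),
                             float(t), float(df), float(p), None))
            # paired F vs M within mate pairs (individual-level measures only)
            if levels.get(measure, "individual") == "dyad":
                continue
            pairs: dict[str, dict[str, float]] = {}
            for aid in behavior.df.index:
                r = info.get(str(aid))
                if r is None or r.partner != "mate" or not in_tp(r):
                    continue
                pairs.setdefault(r.pair_id, {})[r.sex] = float(behavior.df.loc[aid, measure])
            fvals = [v["F"] for v in pairs.values() if {"F", "M"} <= set(v)]
            mvals = [v["M"] for v in pairs.values() if {"F", "M"} <= set(v)]
            if len(fvals) < 2:
                rows.append((measure, "female-vs-male", tp, len(fvals), len(mvals),
                             np.nan, np.nan, np.nan, "group size < 2"))
            elif np.std(np.array(fvals) - np.array(mvals)) == 0:
                rows.append((measure, "female-vs-male", tp, len(fvals), len(mvals),
                             np.nan, np.nan, np.nan, "zero-variance paired differences"))
            else:
                t, p = stats.ttest_rel(fvals, mvals)
                rows.append((measure, "female-vs-male", tp, len(fvals), len(mvals),
                             float(t), float(len(fvals) - 1), float(p), None))
    out = pd.DataFrame(
        rows,
        columns=["measure", "comparison", "timepoint", "n1", "n2", "t", "df", "p",
                 "skipped_reason"],
    )
    out["timepoint"] = out["timepoint"].map(lambda v: v[0] if isinstance(v, tuple) else None)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = fdr_adjust(out.loc[tested, "p"].to_numpy())
    return out
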