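"""Linear shape models with randomized residual permutation (RRPP) inference.

The shape data are rows of combined tangent coordinates; predictors are
log centroid size (the allometric covariate) and categorical factors
(group/subspecies, sex, developmental stage).  Effects are assessed by
non-parametric MANOVA with Type I (sequential) sums of squares, null
distributions built by permuting reduced-model residuals (RRPP), effect
sizes reported as standard deviates (Z) of the observed SS in its
sampling distribution, and pairwise group differences tested as
distances between least-squares means under the same permutation
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ShapeDataset",
    "RrppFitTable",
    "PairwiseDistanceTable",
    "fit_rrpp_manova",
    "select_model",
    "pairwise_group_distances",
    "allometry_free_shapes",
]

_TIE_TOL = 1e-12  # permuted statistics within this of the observed count as >=


@dataclass
class ShapeDataset:
    """Shape residual matrix plus per-specimen covariates.

    ``covariates`` must carry ``log_cs`` (float) and may carry ``group``,
    ``sex``, ``stage`` (categorical, possibly with missing values).
    """

    Y: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, float)
        if self.Y.ndim != 2 or self.Y.shape[1] < 1:
            raise ValueError("Y must be an n x q matrix with q >= 1")
        if len(self.covariates) != self.Y.shape[0]:
            raise ValueError("covariate table does not align with Y rows")
        if "log_cs" in self.covariates and not np.all(
            np.isfinite(self.covariates["log_cs"].to_numpy(float))
        ):
            raise ValueError("non-finite log_cs values")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.Y.shape[0]


# ---------------------------------------------------------------------------
# design construction (sequential / Type I)
# ---------------------------------------------------------------------------


def _factor_levels(cov: pd.DataFrame, terms: list[str]) -> dict[str, list[str]]:
    """Observed levels of every factor appearing in the terms."""
    levels: dict[str, list[str]] = {}
    for term in terms:
        for part in term.split(":"):
            part = part.strip()
            if part not in cov.columns:
                raise ValueError(f"unknown covariate {part!r} in term {term!r}")
            col = cov[part]
            if not pd.api.types.is_numeric_dtype(col):
                if col.isna().any():
                    raise ValueError(f"factor {part!r} has missing values")
                levs = sorted(col.astype(str).unique())
                if len(levs) < 2:
                    raise ValueError(f"factor {part!r} has fewer than 2 levels")
                levels[part] = levs
    return levels


def _term_columns(
    cov: pd.DataFrame, term: str, levels: dict[str, list[str]]
) -> np.ndarray:
    """Design columns for one term (treatment coding, first level dropped)."""
    blocks = []
    for part in term.split(":"):
        part = part.strip()
        col = cov[part]
        if part in levels:
            dummies = np.column_stack(
                [(col.astype(str) == lev).to_numpy(float) for lev in levels[part][1:]]
            )
            blocks.append(dummies)
        else:
            blocks.append(col.to_numpy(float)[:, None])
    out = blocks[0]
    for b in blocks[1:]:
        out = (out[:, :, None] * b[:, None, :]).reshape(len(cov), -1)
    return out


def _build_design(
    cov: pd.DataFrame, terms: list[str], levels: dict[str, list[str]] | None = None
) -> tuple[np.ndarray, list[slice]]:
    """Full design (intercept first) and the column slice of each term."""
    n = len(cov)
    if levels is None:
        levels = _factor_levels(cov, terms)
    cols = [np.ones((n, 1))]
    slices: list[slice] = []
    start = 1
    for term in terms:
        block = _term_columns(cov, term, levels)
        cols.append(block)
        slices.append(slice(start, start + block.shape[1]))
        start += block.shape[1]
    return np.hstack(cols), slices


def _nested_bases(x_full: np.ndarray, slices: list[slice]) -> list[np.ndarray]:
    """Orthonormal bases of the nested models intercept, +term1, +term2, ...

    Errors if a term adds no rank (aliased with preceding terms).
    """
    bases = []
    prev_rank = 0
    for i in range(len(slices) + 1):
        stop = 1 if i == 0 else slices[i - 1].stop
        xm = x_full[:, :stop]
        q, r = np.linalg.qr(xm)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))))
        if rank < xm.shape[1]:
            raise ValueError(
                f"rank-deficient design: term {i} "
                "is aliased with preceding terms"
            )
        if i > 0 and rank - prev_rank != slices[i - 1].stop - slices[i - 1].start:
            raise ValueError(f"rank-deficient design at term {i}")
        prev_rank = rank
        bases.append(q)
    return bases


def _permutation_indices(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)


# ---------------------------------------------------------------------------
# RRPP MANOVA
# ---------------------------------------------------------------------------


@dataclass
class RrppFitTable:
    """Sequential MANOVA table with RRPP P-values and Z effect sizes."""

    table: pd.DataFrame
    terms: list[str]
    n_perm: int
    ss_distributions: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.10g")

    def __str__(self) -> str:  # pragma: no cover
        return self.table.to_string()


def fit_rrpp_manova(
    data: ShapeDataset,
    formula: list[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    z_log_ss: bool = False,
) -> RrppFitTable:
    """Non-parametric MANOVA with Type I SS and RRPP null distributions.

    For the i-th term, SS is the drop in summed squared residuals between
    the model of preceding terms and the model through the term;
    F = (SS/df) / MS_residual of the full model.  The null distribution
    of each SS permutes the reduced model's residuals, adds back its
    fitted values, and recomputes the statistic; the observed case
    counts as one of ``n_perm``, so the smallest attainable P is
    ``1/n_perm``.  Z is the standard deviate of the observed SS in its
    sampling distribution (on the raw SS scale by default; set
    ``z_log_ss`` for log-scale effect sizes).
    """
    if not formula:
        raise ValueError("formula must contain at least one term")
    y = data.Y
    n, q = y.shape
    x_full, slices = _build_design(data.covariates, formula)
    if n <= x_full.shape[1]:
        raise ValueError("n must exceed the total model df")
    bases = _nested_bases(x_full, slices)
    rng = np.random.default_rng(seed)

    ss_total = float(np.sum((y - y.mean(axis=0)) ** 2))
    rss = [float(np.sum(y**2) - np.sum((b.T @ y) ** 2)) for b in bases]
    rss_full = rss[-1]
    df_res = n - bases[-1].shape[1]
    ms_res = rss_full / df_res

    rows = []
    ss_dists: dict[str, np.ndarray] = {}
    perms = _permutation_indices(rng, n, n_perm - 1) if n_perm > 1 else np.empty((0, n), int)
    for i, term in enumerate(formula):
        ss_obs = rss[i] - rss[i + 1]
        df_term = slices[i].stop - slices[i].start
        q_red, q_thr = bases[i], bases[i + 1]
        fitted = q_red @ (q_red.T @ y)
        resid = y - fitted
        ss_perm = np.empty(n_perm)
        ss_perm[0] = ss_obs
        for chunk in range(0, len(perms), 500):
            sub = perms[chunk : chunk + 500]
            y_star = fitted[None, :, :] + resid[sub]
            p_thr = np.einsum("nr,mnq->mrq", q_thr, y_star)
            p_red = np.einsum("nr,mnq->mrq", q_red, y_star)
            ss_perm[1 + chunk : 1 + chunk + len(sub)] = np.einsum(
                "mrq,mrq->m", p_thr, p_thr
            ) - np.einsum("mrq,mrq->m", p_red, p_red)
        p_val = float(np.mean(ss_perm >= ss_obs - _TIE_TOL))
        dist = np.log(np.maximum(ss_perm, 1e-300)) if z_log_ss else ss_perm
        obs_stat = dist[0]
        sd = dist.std()
        z = float((obs_stat - dist.mean()) / sd) if sd > 0 else 0.0
        rows.append(
            {
                "df": df_term,
                "SS": ss_obs,
                "MS": ss_obs / df_term,
                "R2": ss_obs / ss_total if ss_total > 0 else 0.0,
                "F": (ss_obs / df_term) / ms_res if ms_res > 0 else np.inf,
                "Z": z,
                "P": p_val,
            }
        )
        ss_dists[term] = ss_perm
    rows.append(
        {"df": df_res, "SS": rss_full, "MS": ms_res, "R2": np.nan, "F": np.nan, "Z": np.nan, "P": np.nan}
    )
    rows.append(
        {"df": n - 1, "SS": ss_total, "MS": np.nan, "R2": np.nan, "F": np.nan, "Z": np.nan, "P": np.nan}
    )
    table = pd.DataFrame(rows, index=[*formula, "Residuals", "Total"])
    return RrppFitTable(table, list(formula), n_perm, ss_dists)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def select_model(
    data: ShapeDataset,
    candidate_factors: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Screen candidate terms and return the retained model formula.

    Candidate terms are the allometric covariate ``log_cs``, each factor,
    and each factor-by-size interaction, entered sequentially.  Terms
    with RRPP P below ``alpha`` are retained (main effects of retained
    interactions are kept regardless), ranked by effect size Z in the
    report.  This screening rule is this package's own selection
    criterion.  With a size effect and group mean offsets but no
    group-specific slopes it returns the common-allometry model
    ``[log_cs, group]``.
    """
    cov = data.covariates
    if candidate_factors is None:
        candidate_factors = [
            f
            for f in ("group", "sex", "stage")
            if f in cov.columns
            and not cov[f].isna().any()
            and cov[f].astype(str).nunique() > 1
        ]
    terms = ["log_cs"] + list(candidate_factors) + [
        f"log_cs:{f}" for f in candidate_factors
    ]
    fit = fit_rrpp_manova(data, terms, n_perm=n_perm, seed=seed)
    tab = fit.table.loc[terms]
    retained = set(tab.index[tab["P"] < alpha])
    for term in list(retained):
        if ":" in term:
            retained.update(term.split(":"))
    chosen = [t for t in terms if t in retained]
    report = tab.copy()
    report["retained"] = [t in retained for t in tab.index]
    report = report.sort_values("Z", ascending=False)
    if not chosen:
        report.attrs["note"] = "no terms retained: null (intercept-only) model"
    return chosen, report


# ---------------------------------------------------------------------------
# pairwise least-squares-mean distances
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDistanceTable:
    """Pairwise LS-mean shape distances with RRPP permutation P-values."""

    distances: pd.DataFrame
    p_values: pd.DataFrame
    ls_means: pd.DataFrame
    n_perm: int

    def combined_layout(self) -> pd.DataFrame:
        """Distances below the diagonal, P-values above (Table-2 layout)."""
        k = len(self.distances)
        out = self.distances.copy().astype(object)
        for i in range(k):
            out.iat[i, i] = ""
            for j in range(i + 1, k):
                out.iat[i, j] = self.p_values.iat[i, j]
        return out

    def to_csv(self, path) -> None:
        self.combined_layout().to_csv(path)


def _ls_mean_rows(
    cov: pd.DataFrame, terms: list[str], groups: list[str]
) -> np.ndarray:
    """Prediction design rows for group LS means.

    For each group the whole covariate table is counterfactually set to
    that group with ``log_cs`` at its grand mean, the design rebuilt and
    its rows averaged — the population-averaged least-squares mean.
    With the common-allometry model this is exactly the group prediction
    at grand-mean size.
    """
    levels = _factor_levels(cov, terms)
    rows = []
    for g in groups:
        cf = cov.copy()
        cf["group"] = g
        cf["log_cs"] = cov["log_cs"].astype(float).mean()
        x_g, _ = _build_design(cf, terms, levels)
        rows.append(x_g.mean(axis=0))
    return np.array(rows)


def pairwise_group_distances(
    data: ShapeDataset,
    formula: list[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PairwiseDistanceTable:
    """Distances between group LS means, tested by RRPP permutation.

    The null model drops every term involving ``group``; permuting its
    residuals and re-adding its fitted values yields datasets with no
    group structure, from which the full model's LS-mean distances form
    the null distribution for every pair.  P per pair is the proportion
    of permuted distances at least as large as the observed one (the
    observed case counting as one of ``n_perm``).
    """
    if not any("group" in t.split(":") for t in formula):
        raise ValueError("formula must include a group term")
    cov = data.covariates
    counts = cov["group"].value_counts()
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise ValueError(f"groups with fewer than 2 specimens: {small}")
    groups = sorted(cov["group"].astype(str).unique())
    y = data.Y
    n = data.n

    x_full, slices = _build_design(cov, formula)
    _nested_bases(x_full, slices)  # rank check
    pinv_x = np.linalg.pinv(x_full)
    pred_rows = _ls_mean_rows(cov, formula, groups)

    reduced_terms = [t for t in formula if "group" not in t.split(":")]
    if reduced_terms:
        x_red, _ = _build_design(cov, reduced_terms)
    else:
        x_red = np.ones((n, 1))
    q_red = np.linalg.qr(x_red)[0]
    fitted = q_red @ (q_red.T @ y)
    resid = y - fitted

    def pair_dists(beta: np.ndarray) -> np.ndarray:
        means = pred_rows @ beta
        diff = means[:, None, :] - means[None, :, :]
        return np.sqrt(np.einsum("ijq,ijq->ij", diff, diff))

    d_obs = pair_dists(pinv_x @ y)
    rng = np.random.default_rng(seed)
    perms = _permutation_indices(rng, n, n_perm - 1)
    count = np.ones_like(d_obs)
    for chunk in range(0, len(perms), 250):
        sub = perms[chunk : chunk + 250]
        y_star = fitted[None, :, :] + resid[sub]
        betas = np.einsum("cn,mnq->mcq", pinv_x, y_star)
        means = np.einsum("kc,mcq->mkq", pred_rows, betas)
        diff = means[:, :, None, :] - means[:, None, :, :]
        d_star = np.sqrt(np.einsum("mijq,mijq->mij", diff, diff))
        count += np.sum(d_star >= d_obs[None] - _TIE_TOL, axis=0)
    p = count / n_perm
    np.fill_diagonal(p, np.nan)
    dist_df = pd.DataFrame(d_obs, index=groups, columns=groups)
    p_df = pd.DataFrame(p, index=groups, columns=groups)
    ls_means = pd.DataFrame(pred_rows @ (pinv_x @ y), index=groups)
    return PairwiseDistanceTable(dist_df, p_df, ls_means, n_perm)


# ---------------------------------------------------------------------------
# allometry-free shapes
# ---------------------------------------------------------------------------


def allometry_free_shapes(data: ShapeDataset) -> np.ndarray:
    """Shapes with the pooled size effect removed.

    Residuals of the pooled regression of Y on log centroid size, plus
    the prediction at grand-mean log_cs, so the output lives in shape
    space (column-wise covariance with log_cs is zero).
    """
    log_cs = data.covariates["log_cs"].to_numpy(float)
    if np.ptp(log_cs) < 1e-12:
        raise ValueError("log_cs is constant: allometry cannot be estimated")
    x = np.column_stack([np.ones_like(log_cs), log_cs])
    beta = np.linalg.lstsq(x, data.Y, rcond=None)[0]
    resid = data.Y - x @ beta
    at_mean = np.array([1.0, log_cs.mean()]) @ beta
    return resid + at_mean
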