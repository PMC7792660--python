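"""Association analysis between PVS burden and retinal measures.

The statistical stage mirrors a standard cross-sectional cohort analysis:

1. descriptive statistics, with an included-vs-excluded comparison
   (Welch two-sample t-tests for continuous variables, chi-squared
   without continuity correction for binary ones);
2. bootstrapped bivariate Spearman cross-correlations between every pair
   of brain and retinal variables, with Benjamini-Hochberg FDR control
   over all cells of the matrix (both eyes jointly);
3. Gaussian-identity generalized linear models of each PVS outcome on
   each retinal predictor, adjusted for age, sex and six binary vascular
   risk factors, reporting unstandardised B/SE alongside standardised
   Beta/SE from a fully z-scored refit.

Missing data: pairwise-complete observations for correlations,
complete-case rows for models; nothing is imputed. Eyes are never
averaged — each retinal predictor enters separately per eye.

The module exposes the individual operations as functions and a
statsmodels-style surface: ``RetinaPVSAssociation(table).fit()`` returns
an :class:`AssociationResults` carrying the descriptives, the correlation
cells and the fitted models, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .cohort import BRAIN_VARIABLES, RETINAL_VARIABLES, RISK_FACTORS
from .config import StatsParams

__all__ = [
    "CorrelationCell",
    "GLMResult",
    "describe_cohort",
    "spearman_matrix",
    "fdr_adjust",
    "fit_adjusted_model",
    "RetinaPVSAssociation",
    "AssociationResults",
]

DEFAULT_COVARIATES = ["age", "sex"] + RISK_FACTORS


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def describe_cohort(table: pd.DataFrame,
                    continuous_vars=None,
                    binary_vars=None,
                    split_col: str = "included") -> pd.DataFrame:
    """Descriptive table with an included-vs-excluded comparison.

    Continuous variables: mean (SD) per group plus a Welch t-test p value.
    Binary variables: % (n) per group plus a chi-squared p value on the
    2x2 table without continuity correction. A zero-variance continuous
    variable has its test skipped with a note.
    """
    if split_col not in table.columns:
        raise ValueError(f"inclusion flag column {split_col!r} missing")
    continuous_vars = ["age"] if continuous_vars is None else list(continuous_vars)
    binary_vars = (["sex"] + RISK_FACTORS) if binary_vars is None else list(binary_vars)
    inc = table[table[split_col] == 1]
    exc = table[table[split_col] == 0]
    rows = []
    for var in continuous_vars:
        a = inc[var].dropna().astype(float)
        b = exc[var].dropna().astype(float)
        note = ""
        if len(a) < 2 or len(b) < 2:
            p = np.nan
            note = "insufficient observations"
        elif a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = np.nan
            note = "zero variance; test skipped"
        elif np.allclose(a.mean(), b.mean()) and a.var(ddof=1) == 0 == b.var(ddof=1):
            p, note = 1.0, ""
        else:
            _, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "variable": var, "type": "continuous",
            "included": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
            "excluded": f"{b.mean():.2f} ({b.std(ddof=1):.2f})" if len(b) else "",
            "included_mean": a.mean(), "included_sd": a.std(ddof=1),
            "excluded_mean": b.mean() if len(b) else np.nan,
            "excluded_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
            "p_value": p, "note": note,
        })
    for var in binary_vars:
        a = inc[var].dropna().astype(float)
        b = exc[var].dropna().astype(float)
        counts = np.array([[int(a.sum()), int(len(a) - a.sum())],
                           [int(b.sum()), int(len(b) - b.sum())]])
        note = ""
        if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
            p = np.nan
            note = "degenerate 2x2 table; test skipped"
        else:
            _, p, _, _ = stats.chi2_contingency(counts, correction=False)
        rows.append({
            "variable": var, "type": "binary",
            "included": f"{100 * a.mean():.2f} ({int(a.sum())})",
            "excluded": f"{100 * b.mean():.2f} ({int(b.sum())})" if len(b) else "",
            "included_mean": a.mean(), "included_sd": np.nan,
            "excluded_mean": b.mean() if len(b) else np.nan, "excluded_sd": np.nan,
            "p_value": p, "note": note,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman cross-correlations with bootstrap CIs
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCell:
    """One cell of the cross-correlation matrix."""

    var_a: str
    var_b: str
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    q_value: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and not (-1 - 1e-12 <= self.rho <= 1 + 1e-12):
            raise ValueError("rho must lie in [-1, 1]")


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation."""
    if n < 3 or not np.isfinite(rho):
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _rank_corr_matrix(x: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix of columns (no missing values)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    return np.corrcoef(ranks, rowvar=False)


def spearman_matrix(table: pd.DataFrame, variables, n_boot: int = 2000,
                    seed: int = 0, min_pairs: int = 10) -> list[CorrelationCell]:
    """Bootstrapped Spearman correlations for every pair of ``variables``.

    Point estimates use pairwise-complete observations with average ranks
    for ties; p values come from the t approximation; 95% CIs are 2.5-97.5
    percentiles over ``n_boot`` paired resamples of subjects. A constant
    variable yields a cell flagged undefined (NaN rho).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    variables = list(variables)
    data = table[variables].astype(float)
    rng = np.random.default_rng(seed)
    n_rows = len(data)
    x = data.to_numpy()
    complete = not np.isnan(x).any()

    cells: list[CorrelationCell] = []
    if complete:
        if n_rows < min_pairs:
            raise ValueError(f"need >= {min_pairs} complete pairs, got {n_rows}")
        rho_mat = _rank_corr_matrix(x)
        boots = np.empty((n_boot, len(variables), len(variables)))
        for b in range(n_boot):
            idx = rng.integers(0, n_rows, size=n_rows)
            boots[b] = _rank_corr_matrix(x[idx])
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
        for i, va in enumerate(variables):
            for j, vb in enumerate(variables):
                if j <= i:
                    continue
                rho = float(rho_mat[i, j])
                if np.isnan(rho):  # constant column
                    cells.append(CorrelationCell(va, vb, np.nan, np.nan, np.nan, np.nan, n_rows))
                else:
                    cells.append(CorrelationCell(va, vb, rho, _spearman_p(rho, n_rows),
                                                 float(lo[i, j]), float(hi[i, j]), n_rows))
        return cells

    # missing data: per-pair pairwise-complete bootstrap
    for i, va in enumerate(variables):
        for j in range(i + 1, len(variables)):
            vb = variables[j]
            pair = data[[va, vb]].dropna().to_numpy()
            n = pair.shape[0]
            if n < min_pairs:
                raise ValueError(f"cell ({va}, {vb}) has {n} < {min_pairs} complete pairs")
            if np.ptp(pair[:, 0]) == 0 or np.ptp(pair[:, 1]) == 0:
                cells.append(CorrelationCell(va, vb, np.nan, np.nan, np.nan, np.nan, n))
                continue
            rho = float(stats.spearmanr(pair[:, 0], pair[:, 1]).statistic)
            reps = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, n, size=n)
                reps[b] = stats.spearmanr(pair[idx, 0], pair[idx, 1]).statistic
            cells.append(CorrelationCell(va, vb, rho, _spearman_p(rho, n),
                                         float(np.nanpercentile(reps, 2.5)),
                                         float(np.nanpercentile(reps, 97.5)), n))
    return cells


def fdr_adjust(p_values, level: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, rejected) arrays.

    q values are monotone in p; the rejection set is every p at or below
    the step-up threshold at the configured level.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return q, rejected


def attach_fdr(cells: list[CorrelationCell], level: float = 0.05) -> list[CorrelationCell]:
    """FDR-adjust all cells of the matrix as one family (both eyes jointly)."""
    finite = [c for c in cells if np.isfinite(c.p_value)]
    if finite:
        q, _ = fdr_adjust([c.p_value for c in finite], level)
        for c, qv in zip(finite, q):
            c.q_value = float(qv)
    return cells


# ---------------------------------------------------------------------------
# covariate-adjusted models
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    """One fitted outcome ~ predictor + covariates model.

    ``table`` holds the full coefficient table (term, B, SE, beta,
    beta_se, p_value); the headline fields summarise the retinal
    predictor's row, matching the dual unstandardised/standardised
    reporting convention.
    """

    outcome: str
    predictor: str
    covariates: list[str]
    b: float
    se: float
    beta: float
    beta_se: float
    p_value: float
    n: int
    table: pd.DataFrame = field(repr=False, default=None)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns: perfectly correlated or constant ones
        bad: list[str] = [c for c in X.columns if X[c].nunique() <= 1 and c != "const"]
        cols = [c for c in X.columns if c != "const"]
        corr = X[cols].corr().to_numpy()
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if np.isclose(abs(corr[i, j]), 1.0, atol=1e-10):
                    bad.extend([cols[i], cols[j]])
        bad = sorted(set(bad))
        raise ValueError(f"rank-deficient design matrix; offending columns: {bad or cols}")


def fit_adjusted_model(table: pd.DataFrame, outcome: str, predictor: str,
                       covariates=None) -> GLMResult:
    """Gaussian-identity GLM of ``outcome`` on ``predictor`` + covariates.

    Fitted by least squares on complete cases. Unstandardised B/SE come
    from the raw-scale fit (binary covariates left 0/1); standardised
    Beta/SE come from a refit with every variable z-scored. The identity
    beta = B * SD(predictor) / SD(outcome) is checked internally for the
    continuous predictor. Requires >= 10 complete rows per parameter.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    cols = [outcome, predictor] + covariates
    dup = [c for c in set(cols) if cols.count(c) > 1]
    if dup:
        raise ValueError(f"rank-deficient design: duplicated terms {sorted(dup)}")
    work = table[cols].astype(float).dropna()
    n = len(work)
    n_params = len(covariates) + 2
    if n < 10 * n_params:
        raise ValueError(f"need >= {10 * n_params} complete cases for {n_params} parameters, got {n}")

    X = sm.add_constant(work[[predictor] + covariates])
    _check_rank(X)
    fit = sm.OLS(work[outcome], X).fit()

    zwork = (work - work.mean()) / work.std(ddof=1)
    Xz = sm.add_constant(zwork[[predictor] + covariates])
    fitz = sm.OLS(zwork[outcome], Xz).fit()

    # internal consistency of the standardisation
    ratio = work[predictor].std(ddof=1) / work[outcome].std(ddof=1)
    if not np.isclose(fitz.params[predictor], fit.params[predictor] * ratio,
                      rtol=1e-8, atol=1e-10):
        raise AssertionError("standardised beta identity violated")

    terms = [predictor] + covariates
    tab = pd.DataFrame({
        "term": terms,
        "B": [fit.params[t] for t in terms],
        "SE": [fit.bse[t] for t in terms],
        "beta": [fitz.params[t] for t in terms],
        "beta_se": [fitz.bse[t] for t in terms],
        "p_value": [fit.pvalues[t] for t in terms],
    })
    return GLMResult(outcome, predictor, covariates,
                     float(fit.params[predictor]), float(fit.bse[predictor]),
                     float(fitz.params[predictor]), float(fitz.bse[predictor]),
                     float(fit.pvalues[predictor]), n, tab)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class RetinaPVSAssociation:
    """Association model between PVS burden and retinal measures.

    Parameters
    ----------
    table : DataFrame
        Cohort table (one row per subject) with brain, retinal and
        covariate columns.
    brain_vars, retinal_vars : sequences of str
        Outcome and predictor sets; default to the standard five PVS
        aggregates and the ten per-eye retinal measures present in the
        table.
    covariates : sequence of str
        Adjustment set for the models (default: age, sex, six risk
        factors).
    params : StatsParams
        Bootstrap replicates and FDR level.
    """

    def __init__(self, table: pd.DataFrame, brain_vars=None, retinal_vars=None,
                 covariates=None, params: StatsParams | None = None):
        self.table = table
        self.brain_vars = list(brain_vars or [v for v in BRAIN_VARIABLES if v in table.columns])
        self.retinal_vars = list(retinal_vars or [v for v in RETINAL_VARIABLES if v in table.columns])
        if not self.brain_vars or not self.retinal_vars:
            raise ValueError("need at least one brain and one retinal variable")
        self.covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
        self.params = params or StatsParams()
        self.params.validate()

    def fit(self, seed: int = 0, skip_failures: bool = False) -> "AssociationResults":
        """Run correlations, FDR and adjusted models; deterministic given seed.

        With ``skip_failures`` a model whose preconditions fail (too few
        complete cases, rank deficiency) is recorded as a failure note
        instead of aborting the stage — the pipeline's log-and-continue
        contract.
        """
        cells = spearman_matrix(self.table, self.brain_vars + self.retinal_vars,
                                n_boot=self.params.n_boot, seed=seed)
        attach_fdr(cells, self.params.fdr_level)
        models = []
        failures = []
        for outcome in self.brain_vars:
            for predictor in self.retinal_vars:
                try:
                    models.append(fit_adjusted_model(self.table, outcome, predictor,
                                                     self.covariates))
                except ValueError as exc:
                    if not skip_failures:
                        raise
                    failures.append((outcome, predictor, str(exc)))
        descriptives = None
        if "included" in self.table.columns and self.table["included"].nunique() > 1:
            descriptives = describe_cohort(self.table)
        res = AssociationResults(self, cells, models, descriptives, seed)
        res.failures = failures
        return res


class AssociationResults:
    """Fitted association stage: correlation cells, models, descriptives."""

    def __init__(self, model: RetinaPVSAssociation, cells, models, descriptives, seed):
        self.model = model
        self.cells: list[CorrelationCell] = cells
        self.models: list[GLMResult] = models
        self.descriptives = descriptives
        self.seed = seed
        self.failures: list[tuple] = []

    # -- tabular views -------------------------------------------------
    def correlations_long(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "var_a": c.var_a, "var_b": c.var_b, "rho": c.rho, "p_value": c.p_value,
            "q_value": c.q_value, "ci_low": c.ci_low, "ci_high": c.ci_high, "n": c.n,
        } for c in self.cells])

    def correlation_matrix(self) -> pd.DataFrame:
        """Square rho matrix over brain + retinal variables (diagonal 1)."""
        variables = self.model.brain_vars + self.model.retinal_vars
        mat = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
        for c in self.cells:
            mat.loc[c.var_a, c.var_b] = c.rho
            mat.loc[c.var_b, c.var_a] = c.rho
        return mat

    def models_table(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            t = m.table.copy()
            t.insert(0, "outcome", m.outcome)
            t.insert(1, "predictor", m.predictor)
            t["n"] = m.n
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def get_cell(self, var_a: str, var_b: str) -> CorrelationCell:
        for c in self.cells:
            if {c.var_a, c.var_b} == {var_a, var_b}:
                return c
        raise KeyError(f"no correlation cell for ({var_a}, {var_b})")

    def summary(self) -> str:
        lines = ["Retina-PVS association results",
                 f"  subjects: {len(self.model.table)}   seed: {self.seed}",
                 f"  bootstrap replicates: {self.model.params.n_boot}   "
                 f"FDR level: {self.model.params.fdr_level}", ""]
        lines.append("Brain x retinal Spearman correlations (FDR-adjusted):")
        for c in self.cells:
            if c.var_a in self.model.brain_vars and c.var_b in self.model.retinal_vars:
                flag = "*" if np.isfinite(c.q_value) and c.q_value < self.model.params.fdr_level else " "
                lines.append(f"  {c.var_a:>18s} x {c.var_b:<12s} rho={c.rho:+.3f} "
                             f"[{c.ci_low:+.3f}, {c.ci_high:+.3f}] q={c.q_value:.4f}{flag}")
        lines.append("")
        lines.append("Adjusted models (standardised Beta for the retinal predictor):")
        for m in self.models:
            lines.append(f"  {m.outcome:>18s} ~ {m.predictor:<12s} "
                         f"beta={m.beta:+.3f} (SE {m.beta_se:.3f}) p={m.p_value:.4f} n={m.n}")
        return "\n".join(lines)

    def plot_correlations(self, ax=None):
        """Heatmap of the Spearman matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        mat = self.correlation_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90)
        ax.set_yticks(range(len(mat)), mat.index)
        ax.figure.colorbar(im, ax=ax, label="Spearman rho")
        return ax
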