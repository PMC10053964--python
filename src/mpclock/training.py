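"""Clock construction: screening, consensus selection, and the final fit.

The pipeline mirrors how the tissue-specific clocks were built:

1. split the cohort into a training set and a testing set (35% of
   subjects, drawn from samples with at least 90% observed CpGs);
2. univariable screen — each CpG is regressed against age separately in
   linear and quadratic form; terms significant at the 10% level become
   candidates;
3. three independent selection procedures over the candidates:
   AIC-guided bidirectional stepwise regression, the Lasso with the
   penalty chosen by 30-fold cross-validation, and recursive feature
   elimination scored by repeated (30-fold x 10) cross-validated RMSE;
4. the union of the three selections enters a multivariable OLS fit,
   backward-pruned one term at a time while any p-value exceeds 0.10;
5. the surviving polynomial is packaged as a clock whose normality
   half-width is the centered MAD of the training deviations.

:class:`ConsensusClockRegressor` wraps the whole pipeline as a
scikit-learn estimator; :func:`train_clock` is a thin functional wrapper
over it.  A single-hidden-layer neural-network baseline with
bootstrap-tuned width is provided for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import KFold, RepeatedKFold
from sklearn.neural_network import MLPRegressor
import statsmodels.api as sm

from .bioage import DeviationSummary, mad, summarize_deviations
from .io import CohortTable, MethylationMatrix
from .models import ClockModel, ClockTerm
from .panel import default_panel, parse_site_id

__all__ = [
    "Term",
    "TrainingConfig",
    "SelectionReport",
    "ConsensusClockRegressor",
    "split_train_test",
    "univariable_screen",
    "stepwise_select",
    "lasso_select",
    "rfe_select",
    "combine_and_fit",
    "train_clock",
    "nn_baseline",
    "NNBaselineResult",
]


class Term(NamedTuple):
    """A candidate polynomial term: a CpG site raised to power 1 or 2."""

    site_id: str
    power: int

    @property
    def label(self) -> str:
        return self.site_id if self.power == 1 else f"{self.site_id}^2"


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the clock-construction pipeline.

    Defaults are the study conditions: a 35% test split restricted to
    samples with >= 90% observed CpGs, 10% significance for screening
    and final pruning, 30-fold cross-validation for the Lasso penalty,
    and 30-fold x 10-repeat cross-validation for RFE scoring.
    """

    test_fraction: float = 0.35
    completeness_threshold: float = 0.90
    p_enter: float = 0.10
    p_keep: float = 0.10
    cv_folds: int = 30
    rfe_repeats: int = 10
    lasso_lambda_grid: Optional[tuple[float, ...]] = None
    include_quadratic: bool = True
    rng_seed: int = 0
    nn_hidden_grid: tuple[int, ...] = (1, 2, 4, 8, 16)
    nn_bootstrap: int = 25

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        for name in ("p_enter", "p_keep"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def lambda_grid(self) -> np.ndarray:
        if self.lasso_lambda_grid is not None:
            return np.asarray(self.lasso_lambda_grid, dtype=float)
        return np.logspace(-3.0, 1.0, 30)


def _term_design(values: pd.DataFrame, terms: Sequence[Term]) -> pd.DataFrame:
    """Design matrix with one column per term (methylation ** power)."""
    cols = {}
    for t in terms:
        cols[t.label] = values[t.site_id] ** t.power
    return pd.DataFrame(cols, index=values.index)


def split_train_test(
    cohort: CohortTable,
    matrix: MethylationMatrix,
    config: TrainingConfig,
) -> tuple[list[str], list[str]]:
    """Seeded train/test split with completeness-gated test eligibility.

    The test set is a random draw of ceil(test_fraction * n) samples
    from those with at least ``completeness_threshold`` observed CpGs;
    everything else trains.
    """
    ids = [s for s in cohort.sample_ids if s in set(matrix.sample_ids)]
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    n_test = math.ceil(config.test_fraction * n)
    completeness = matrix.completeness()
    eligible = [s for s in ids if completeness[s] >= config.completeness_threshold]
    if len(eligible) < n_test:
        raise ValueError(
            f"only {len(eligible)} samples meet the completeness threshold "
            f"{config.completeness_threshold:.2f}; {n_test} needed for the test set"
        )
    rng = np.random.default_rng(config.rng_seed)
    test = sorted(rng.choice(np.array(eligible, dtype=object), size=n_test, replace=False))
    test_set = set(test)
    train = [s for s in ids if s not in test_set]
    return train, list(test)


def univariable_screen(
    matrix: MethylationMatrix,
    ages: pd.Series,
    config: TrainingConfig,
) -> pd.DataFrame:
    """Single-term regressions of age on each CpG (linear and quadratic).

    Returns a frame indexed by term label with columns ``site``,
    ``power``, ``coef``, ``p`` and ``candidate`` (p < p_enter).  Each
    site uses pairwise deletion; constant predictors get p = 1 and never
    enter.
    """
    powers = (1, 2) if config.include_quadratic else (1,)
    rows = []
    ages = ages.reindex(matrix.values.index)
    for site in matrix.site_ids:
        m = matrix.values[site]
        ok = m.notna() & ages.notna()
        x0, y = m[ok].to_numpy(), ages[ok].to_numpy()
        for power in powers:
            x = x0**power
            if len(x) < 3 or np.ptp(x) == 0.0:
                coef, p = 0.0, 1.0
            else:
                res = stats.linregress(x, y)
                coef, p = float(res.slope), float(res.pvalue)
                if not np.isfinite(p):
                    coef, p = 0.0, 1.0
            term = Term(site, power)
            rows.append(
                {
                    "term": term.label,
                    "site": site,
                    "power": power,
                    "coef": coef,
                    "p": p,
                    "candidate": p < config.p_enter,
                }
            )
    return pd.DataFrame(rows).set_index("term")


def _complete_cases(
    matrix: MethylationMatrix, ages: pd.Series, terms: Sequence[Term]
) -> tuple[pd.DataFrame, pd.Series]:
    sites = sorted({t.site_id for t in terms})
    sub = matrix.values[sites] if sites else matrix.values.iloc[:, :0]
    ages = ages.reindex(matrix.values.index)
    ok = sub.notna().all(axis=1) & ages.notna()
    return matrix.values.loc[ok], ages[ok]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


def _aic(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    k = (X.shape[1] if X.ndim == 2 else 0) + 1
    rss = max(_ols_rss(X, y), 1e-300)
    return n * math.log(rss / n) + 2 * (k + 1)


def stepwise_select(
    candidates: Sequence[Term],
    matrix: MethylationMatrix,
    ages: pd.Series,
) -> list[Term]:
    """AIC-guided bidirectional stepwise selection from the null model."""
    candidates = list(candidates)
    if not candidates:
        return []
    values, y_series = _complete_cases(matrix, ages, candidates)
    n = len(y_series)
    if n <= len(candidates):
        raise ValueError(
            f"stepwise refuses: {n} complete samples for {len(candidates)} "
            "candidate terms; tighten the univariable screen (lower p_enter) "
            "or provide more samples"
        )
    design = _term_design(values, candidates)
    y = y_series.to_numpy()
    X_full = design.to_numpy()
    col = {t: i for i, t in enumerate(candidates)}

    current: list[Term] = []
    current_aic = _aic(np.empty((n, 0)), y)
    while True:
        best_move, best_aic = None, current_aic
        in_set = set(current)
        for t in candidates:
            if t in in_set:
                continue
            cols = [col[u] for u in current] + [col[t]]
            a = _aic(X_full[:, cols], y)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("add", t), a
        for t in current:
            cols = [col[u] for u in current if u != t]
            a = _aic(X_full[:, cols], y)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("drop", t), a
        if best_move is None:
            break
        action, t = best_move
        if action == "add":
            current.append(t)
        else:
            current.remove(t)
        current_aic = best_aic
    return sorted(current)


def lasso_select(
    candidates: Sequence[Term],
    matrix: MethylationMatrix,
    ages: pd.Series,
    config: TrainingConfig,
) -> list[Term]:
    """Lasso over internally standardized candidate terms.

    The penalty is chosen by minimizing K-fold cross-validated squared
    error over the configured grid (K = ``cv_folds``); selected terms
    are those with a nonzero coefficient at the optimum.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    values, y_series = _complete_cases(matrix, ages, candidates)
    n = len(y_series)
    if n < config.cv_folds:
        raise ValueError(
            f"{n} complete samples is fewer than cv_folds={config.cv_folds}"
        )
    design = _term_design(values, candidates).to_numpy()
    sd = design.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return []
    Xs = (design[:, keep] - design[:, keep].mean(axis=0)) / sd[keep]
    y = y_series.to_numpy()
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.rng_seed)
    model = LassoCV(alphas=config.lambda_grid(), cv=cv, max_iter=100000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    kept_terms = [t for t, k in zip(candidates, keep) if k]
    return sorted(t for t, c in zip(kept_terms, model.coef_) if abs(c) > 1e-10)


def _rfe_ranking(Xs: np.ndarray, y: np.ndarray, terms: list[Term]) -> list[Term]:
    """Elimination order: repeatedly drop the smallest |standardized coef|.

    Returns terms ordered from first-eliminated to last-surviving, so
    the best subset of size m is the last m entries.
    """
    active = list(range(len(terms)))
    order: list[int] = []
    while active:
        A = np.column_stack([np.ones(len(y)), Xs[:, active]])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        weakest = int(np.argmin(np.abs(coef[1:])))
        order.append(active.pop(weakest))
    return [terms[i] for i in order]


def rfe_select(
    candidates: Sequence[Term],
    matrix: MethylationMatrix,
    ages: pd.Series,
    config: TrainingConfig,
) -> list[Term]:
    """Recursive feature elimination scored by repeated K-fold CV RMSE.

    Terms are ranked once by recursive elimination of the weakest
    standardized coefficient; every subset size (including the
    intercept-only model) is then scored by repeated cross-validated
    RMSE and the size with the smallest mean RMSE wins (ties go to the
    smaller model).
    """
    candidates = list(candidates)
    if not candidates:
        return []
    values, y_series = _complete_cases(matrix, ages, candidates)
    n = len(y_series)
    if n < config.cv_folds:
        raise ValueError(
            f"{n} complete samples is fewer than cv_folds={config.cv_folds}"
        )
    design = _term_design(values, candidates).to_numpy()
    sd = design.std(axis=0)
    keep = sd > 0
    terms = [t for t, k in zip(candidates, keep) if k]
    if not terms:
        return []
    Xs = (design[:, keep] - design[:, keep].mean(axis=0)) / sd[keep]
    y = y_series.to_numpy()

    elimination = _rfe_ranking(Xs, y, terms)
    label_to_col = {t: i for i, t in enumerate(terms)}
    # subsets[m] = the m strongest terms
    subsets = [elimination[len(terms) - m :] for m in range(len(terms) + 1)]

    cv = RepeatedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.rfe_repeats,
        random_state=config.rng_seed,
    )
    sse = np.zeros(len(subsets))
    count = 0
    for train_idx, test_idx in cv.split(Xs):
        y_tr, y_te = y[train_idx], y[test_idx]
        count += len(test_idx)
        for m, subset in enumerate(subsets):
            if m == 0:
                pred = np.full(len(test_idx), y_tr.mean())
            else:
                cols = [label_to_col[t] for t in subset]
                A = np.column_stack([np.ones(len(train_idx)), Xs[train_idx][:, cols]])
                coef, _, _, _ = np.linalg.lstsq(A, y_tr, rcond=None)
                B = np.column_stack([np.ones(len(test_idx)), Xs[test_idx][:, cols]])
                pred = B @ coef
            sse[m] += float(np.sum((pred - y_te) ** 2))
    rmse = np.sqrt(sse / count)
    best_size = int(np.argmin(rmse))  # ties -> smaller model
    return sorted(subsets[best_size])


@dataclass
class SelectionReport:
    """Everything the pipeline decided and measured, heat-map ready."""

    univariable: pd.DataFrame
    inclusion: pd.DataFrame
    final_table: pd.DataFrame
    r_squared: float
    train_summary: Optional[DeviationSummary]
    test_summary: Optional[DeviationSummary] = None
    r_squared_test: Optional[float] = None
    config: Optional[TrainingConfig] = None
    train_ids: Optional[list[str]] = None
    test_ids: Optional[list[str]] = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def summary(s: Optional[DeviationSummary]):
            return None if s is None else vars(s).copy()

        return {
            "univariable": self.univariable.reset_index().to_dict(orient="records"),
            "inclusion": self.inclusion.reset_index().to_dict(orient="records"),
            "final_table": self.final_table.reset_index().to_dict(orient="records"),
            "r_squared": self.r_squared,
            "r_squared_test": self.r_squared_test,
            "train_summary": summary(self.train_summary),
            "test_summary": summary(self.test_summary),
            "config": None if self.config is None else vars(self.config).copy(),
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "warnings": list(self.warnings),
        }


def _clock_from_fit(
    terms: list[Term],
    params: pd.Series,
    name: str,
    tissue: str,
    halfwidth: Optional[float],
) -> ClockModel:
    clock_terms = tuple(
        ClockTerm(site=parse_site_id(t.site_id), power=t.power, coefficient=float(params[t.label]))
        for t in terms
    )
    return ClockModel(
        name=name,
        tissue=tissue,
        intercept=float(params["const"]),
        terms=clock_terms,
        halfwidth=halfwidth,
    )


def combine_and_fit(
    selections: dict[str, Sequence[Term]],
    matrix: MethylationMatrix,
    ages: pd.Series,
    config: TrainingConfig,
    *,
    univariable: Optional[pd.DataFrame] = None,
    name: str = "trained-clock",
    tissue: str = "other",
) -> tuple[ClockModel, SelectionReport]:
    """OLS on the union of procedure selections, backward-pruned at p_keep.

    The union of the three selections is fitted by ordinary least
    squares; while any term's p-value exceeds ``p_keep`` the worst term
    is dropped and the model refitted.  The returned clock's half-width
    is the centered MAD of the training deviations (omitted when zero).
    """
    union = sorted({t for sel in selections.values() for t in sel})
    notes: list[str] = []
    values, y_series = _complete_cases(matrix, ages, union)
    y = y_series.to_numpy()

    current = list(union)
    if not current:
        notes.append("empty selection union: constant model predicting mean age")
    while True:
        X = _term_design(values, current)
        Xc = sm.add_constant(X.to_numpy(), has_constant="add")
        fit = sm.OLS(y, Xc).fit()
        if not current:
            break
        pvals = pd.Series(fit.pvalues[1:], index=[t.label for t in current])
        if pvals.isna().all():  # perfect fit: nothing to prune on
            break
        worst = pvals.idxmax()
        if pvals[worst] > config.p_keep:
            current = [t for t in current if t.label != worst]
            if not current:
                notes.append("all terms pruned at p_keep: constant model returned")
        else:
            break

    labels = ["const"] + [t.label for t in current]
    params = pd.Series(fit.params, index=labels)
    bse = pd.Series(fit.bse, index=labels)
    pvalues = pd.Series(fit.pvalues, index=labels)

    fitted = pd.Series(fit.fittedvalues, index=values.index)
    deviations = fitted - y_series
    halfwidth = None
    train_summary = None
    if len(deviations) >= 2:
        train_summary = summarize_deviations(deviations)
        h = train_summary.mad
        halfwidth = h if h > 0 else None

    clock = _clock_from_fit(current, params, name, tissue, halfwidth)

    final_table = pd.DataFrame(
        {"coef": params, "se": bse, "p": pvalues}
    )
    final_table.index.name = "term"

    all_terms = sorted(
        union
        if univariable is None
        else {Term(r.site, int(r.power)) for r in univariable.itertuples()} | set(union)
    )
    incl = pd.DataFrame(
        {
            proc: [t in set(sel) for t in all_terms]
            for proc, sel in selections.items()
        },
        index=[t.label for t in all_terms],
    )
    incl["union"] = [t in set(union) for t in all_terms]
    incl["final"] = [t in set(current) for t in all_terms]
    incl.index.name = "term"

    report = SelectionReport(
        univariable=univariable if univariable is not None else pd.DataFrame(),
        inclusion=incl,
        final_table=final_table,
        r_squared=float(fit.rsquared) if current else 0.0,
        train_summary=train_summary,
        config=config,
        warnings=notes,
    )
    return clock, report


class ConsensusClockRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapping the full clock-training pipeline.

    ``fit(X, y)`` takes a percent-methylation table (a
    :class:`MethylationMatrix` or a DataFrame whose columns are CpG site
    ids) and chronological ages in years; it splits off an internal test
    set, screens, runs the three selection procedures, and fits the
    pruned polynomial.  ``predict`` evaluates the fitted clock.

    Fitted attributes: ``clock_`` (the ClockModel), ``report_``
    (SelectionReport with train/test deviation summaries),
    ``train_ids_`` / ``test_ids_``, and ``feature_names_in_``.
    """

    def __init__(
        self,
        test_fraction: float = 0.35,
        completeness_threshold: float = 0.90,
        p_enter: float = 0.10,
        p_keep: float = 0.10,
        cv_folds: int = 30,
        rfe_repeats: int = 10,
        lasso_lambda_grid: Optional[tuple[float, ...]] = None,
        include_quadratic: bool = True,
        rng_seed: int = 0,
        tissue: str = "other",
        name: str = "trained-clock",
    ):
        self.test_fraction = test_fraction
        self.completeness_threshold = completeness_threshold
        self.p_enter = p_enter
        self.p_keep = p_keep
        self.cv_folds = cv_folds
        self.rfe_repeats = rfe_repeats
        self.lasso_lambda_grid = lasso_lambda_grid
        self.include_quadratic = include_quadratic
        self.rng_seed = rng_seed
        self.tissue = tissue
        self.name = name

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            test_fraction=self.test_fraction,
            completeness_threshold=self.completeness_threshold,
            p_enter=self.p_enter,
            p_keep=self.p_keep,
            cv_folds=self.cv_folds,
            rfe_repeats=self.rfe_repeats,
            lasso_lambda_grid=self.lasso_lambda_grid,
            include_quadratic=self.include_quadratic,
            rng_seed=self.rng_seed,
        )

    @staticmethod
    def _as_matrix(X) -> MethylationMatrix:
        if isinstance(X, MethylationMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return MethylationMatrix(X)
        raise TypeError(
            "X must be a MethylationMatrix or a DataFrame with CpG site-id "
            "columns; a bare array has no site identities to build a clock from"
        )

    def fit(self, X, y) -> "ConsensusClockRegressor":
        matrix = self._as_matrix(X)
        config = self._config()
        ages = (
            y.astype(float)
            if isinstance(y, pd.Series)
            else pd.Series(np.asarray(y, dtype=float), index=matrix.values.index)
        )
        cohort = CohortTable(
            pd.DataFrame(
                {"tissue": self.tissue if self.tissue in ("blood", "heart") else "blood",
                 "chronological_age": ages},
                index=matrix.values.index,
            )
        )
        train_ids, test_ids = split_train_test(cohort, matrix, config)
        train_m = matrix.subset_samples(train_ids)
        train_ages = ages.loc[train_ids]

        uni = univariable_screen(train_m, train_ages, config)
        candidates = sorted(
            Term(r.site, int(r.power)) for r in uni[uni["candidate"]].itertuples()
        )
        selections = {
            "stepwise": stepwise_select(candidates, train_m, train_ages),
            "lasso": lasso_select(candidates, train_m, train_ages, config),
            "rfe": rfe_select(candidates, train_m, train_ages, config),
        }
        clock, report = combine_and_fit(
            selections,
            train_m,
            train_ages,
            config,
            univariable=uni,
            name=self.name,
            tissue=self.tissue,
        )
        report.train_ids = list(train_ids)
        report.test_ids = list(test_ids)

        test_m = matrix.subset_samples(test_ids)
        try:
            pred = clock.predict(test_m, missing_policy="median_impute")
            test_dev = pred - ages.loc[test_ids]
            if len(test_dev) >= 2:
                report.test_summary = summarize_deviations(test_dev)
                ss_res = float(np.sum(test_dev.to_numpy() ** 2))
                ss_tot = float(
                    np.sum((ages.loc[test_ids] - ages.loc[test_ids].mean()) ** 2)
                )
                report.r_squared_test = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        except (KeyError, ValueError) as exc:
            report.warnings.append(f"test-set evaluation skipped: {exc}")

        self.clock_ = clock
        self.report_ = report
        self.train_ids_ = list(train_ids)
        self.test_ids_ = list(test_ids)
        self.feature_names_in_ = np.asarray(matrix.site_ids, dtype=object)
        self.n_features_in_ = matrix.n_sites
        return self

    def predict(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "clock_")
        matrix = self._as_matrix(X)
        return self.clock_.predict(matrix, missing_policy="median_impute").to_numpy()


def train_clock(
    matrix: MethylationMatrix,
    cohort: CohortTable,
    config: Optional[TrainingConfig] = None,
    *,
    tissue: str = "other",
    name: str = "trained-clock",
) -> tuple[ClockModel, SelectionReport]:
    """Run the full pipeline on a matrix + cohort; see the module docs."""
    config = config or TrainingConfig()
    common = [s for s in cohort.sample_ids if s in set(matrix.sample_ids)]
    est = ConsensusClockRegressor(
        test_fraction=config.test_fraction,
        completeness_threshold=config.completeness_threshold,
        p_enter=config.p_enter,
        p_keep=config.p_keep,
        cv_folds=config.cv_folds,
        rfe_repeats=config.rfe_repeats,
        lasso_lambda_grid=config.lasso_lambda_grid,
        include_quadratic=config.include_quadratic,
        rng_seed=config.rng_seed,
        tissue=tissue,
        name=name,
    )
    est.fit(matrix.subset_samples(common), cohort.ages().loc[common])
    return est.clock_, est.report_


@dataclass
class NNBaselineResult:
    """Fitted neural-network baseline and its train/test MADs."""

    model: object
    hidden_size: int
    train_mad: float
    test_mad: Optional[float]
    feature_names: list[str]
    scale_min: np.ndarray
    scale_range: np.ndarray

    def predict(self, matrix: MethylationMatrix) -> pd.Series:
        values = matrix.values[self.feature_names]
        values = values.fillna(values.median(axis=0))
        Xs = (values.to_numpy() - self.scale_min) / self.scale_range
        return pd.Series(self.model.predict(Xs), index=values.index, name="dnam_age")


def nn_baseline(
    matrix: MethylationMatrix,
    ages: pd.Series,
    config: Optional[TrainingConfig] = None,
) -> NNBaselineResult:
    """Single-hidden-layer regression on all panel CpGs.

    Inputs are median-imputed and min-max scaled; the hidden-layer width
    is tuned over ``nn_hidden_grid`` by bootstrap out-of-bag MAD
    (``nn_bootstrap`` resamples).  Width 0 collapses to a linear model.
    """
    config = config or TrainingConfig()
    sites = [s for s in default_panel().site_ids if s in set(matrix.site_ids)]
    values = matrix.values[sites]
    values = values.fillna(values.median(axis=0))
    if values.isna().any().any():
        dead = list(values.columns[values.isna().any()])
        raise ValueError(f"sites with no observed values at all: {dead}")
    ages = ages.reindex(values.index)

    lo = values.to_numpy().min(axis=0)
    rng_span = values.to_numpy().max(axis=0) - lo
    if np.any(rng_span == 0):
        dead = [s for s, r in zip(sites, rng_span) if r == 0]
        raise ValueError(f"constant input sites: {dead}")
    Xs = (values.to_numpy() - lo) / rng_span
    y = ages.to_numpy()

    cohort = CohortTable(
        pd.DataFrame({"tissue": "blood", "chronological_age": ages}, index=values.index)
    )
    wrapped = MethylationMatrix(values)
    train_ids, test_ids = split_train_test(cohort, wrapped, config)
    pos = {s: i for i, s in enumerate(values.index)}
    tr = np.array([pos[s] for s in train_ids])
    te = np.array([pos[s] for s in test_ids])

    def make(h: int):
        if h == 0:
            return LinearRegression()
        return MLPRegressor(
            hidden_layer_sizes=(h,),
            solver="lbfgs",
            max_iter=5000,
            random_state=config.rng_seed,
        )

    rng = np.random.default_rng(config.rng_seed + 1)
    scores = {}
    for h in config.nn_hidden_grid:
        oob_mads = []
        for _ in range(config.nn_bootstrap):
            boot = rng.integers(0, len(tr), size=len(tr))
            oob = np.setdiff1d(np.arange(len(tr)), np.unique(boot))
            if len(oob) < 2:
                continue
            mdl = make(h)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mdl.fit(Xs[tr[boot]], y[tr[boot]])
            dev = mdl.predict(Xs[tr[oob]]) - y[tr[oob]]
            oob_mads.append(mad(dev))
        scores[h] = float(np.mean(oob_mads)) if oob_mads else np.inf
    best_h = min(config.nn_hidden_grid, key=lambda h: (scores[h], h))

    final = make(best_h)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xs[tr], y[tr])
    train_mad = mad(final.predict(Xs[tr]) - y[tr])
    test_mad = mad(final.predict(Xs[te]) - y[te]) if len(te) >= 1 else None
    return NNBaselineResult(
        model=final,
        hidden_size=best_h,
        train_mad=train_mad,
        test_mad=test_mad,
        feature_names=sites,
        scale_min=lo,
        scale_range=rng_span,
    )
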