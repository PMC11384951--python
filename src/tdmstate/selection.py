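"""Genetic-algorithm wrapper feature selection for severity prediction.

A GA evolves fixed-cardinality feature subsets scored by the cross-validated
negative mean absolute error of a supervised estimator predicting the
severity total (grouped by patient, so no patient's days straddle a fold).
The protocol around it: hold 10 patients out entirely, split the rest 4:1 by
patient, sweep the subset size k, repeat the stochastic search many times,
keep features picked more than a frequency threshold, and run one final
search over that candidate pool.

Four scenarios differ in estimator family and feature-space treatment:
raw features with an information-based forest, or encoded + scaled features
with a distance-based linear model; each either on the whole feature
universe or independently per feature kind (continuous / discrete /
pathogen).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .encoding import StateSpaceEncoder
from .prep import FeatureSchema

logger = logging.getLogger(__name__)

ESTIMATORS = ("information_based_forest", "distance_based_linear")


@dataclass
class GAConfig:
    """Wrapper-search settings; defaults follow the full-scale protocol."""

    population_size: int = 160
    generations: int = 100
    cv_folds: int = 5
    estimator: str = "distance_based_linear"
    subset_size: int = 15
    repetitions: int = 100
    frequency_threshold: float = 0.10
    tournament_size: int = 3
    mutation_rate: float = 0.1
    elitism: int = 1
    forest_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.frequency_threshold < 1.0:
            raise ValueError("frequency_threshold must lie in (0, 1)")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


@dataclass
class SelectionReport:
    """Outcome of one selection scenario."""

    scenario_id: int
    frequencies: pd.Series
    chosen: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    per_k_scores: pd.DataFrame | None = None
    fallback_used: bool = False


def split_patients(
    states: pd.DataFrame,
    holdout_n: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Partition patients into (holdout, train, test); always by patient."""
    ids = np.array(sorted(states["patient_id"].unique()))
    if len(ids) < holdout_n + 5:
        raise ValueError(
            f"too few patients ({len(ids)}) for holdout_n={holdout_n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    holdout = perm[:holdout_n]
    rest = perm[holdout_n:]
    n_train = int(round(train_fraction * len(rest)))
    train, test = rest[:n_train], rest[n_train:]
    return (
        tuple(sorted(holdout)), tuple(sorted(train)), tuple(sorted(test))
    )


def grouped_fold_indices(
    groups, n_folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row-index folds that never split one group across train/validation."""
    groups = np.asarray(groups)
    uniq = np.array(sorted(pd.unique(groups)))
    if len(uniq) < n_folds:
        raise ValueError("fewer groups than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    folds = np.array_split(perm, n_folds)
    out = []
    all_idx = np.arange(len(groups))
    for fold_groups in folds:
        mask = np.isin(groups, fold_groups)
        out.append((all_idx[~mask], all_idx[mask]))
    return out


def _linear_cv_neg_mae(
    X: np.ndarray, y: np.ndarray, folds, subset: tuple[int, ...]
) -> float:
    """Mean negative MAE over folds for an OLS fit on the subset columns."""
    cols = np.fromiter(subset, dtype=int)
    scores = np.empty(len(folds))
    for i, (tr, va) in enumerate(folds):
        A = np.column_stack([np.ones(len(tr)), X[np.ix_(tr, cols)]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        B = np.column_stack([np.ones(len(va)), X[np.ix_(va, cols)]])
        pred = B @ coef
        scores[i] = -np.abs(pred - y[va]).mean()
    return float(scores.mean())


def _forest_cv_neg_mae(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    subset: tuple[int, ...],
    n_estimators: int,
    seed: int,
) -> float:
    cols = np.fromiter(subset, dtype=int)
    scores = np.empty(len(folds))
    for i, (tr, va) in enumerate(folds):
        model = RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        model.fit(X[np.ix_(tr, cols)], y[tr])
        pred = model.predict(X[np.ix_(va, cols)])
        scores[i] = -np.abs(pred - y[va]).mean()
    return float(scores.mean())


def fitness(
    X,
    y,
    groups,
    subset,
    estimator: str = "distance_based_linear",
    cv_folds: int = 5,
    seed: int = 0,
    forest_size: int = 100,
) -> float:
    """Grouped-CV negative mean absolute error of a subset's estimator.

    ``subset`` may hold feature names (when X is a DataFrame) or column
    indices.  Higher is better; 0 is a perfect fit.
    """
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        idx = []
        for f in subset:
            if isinstance(f, str):
                if f not in names:
                    raise ValueError(f"unknown feature {f!r}")
                idx.append(names.index(f))
            else:
                idx.append(int(f))
        subset = tuple(idx)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        subset = tuple(int(i) for i in subset)
        if max(subset) >= X.shape[1]:
            raise ValueError("subset references an unknown feature index")
    y = np.asarray(y, dtype=float)
    folds = grouped_fold_indices(groups, cv_folds, seed)
    if estimator == "distance_based_linear":
        return _linear_cv_neg_mae(X, y, folds, subset)
    if estimator == "information_based_forest":
        return _forest_cv_neg_mae(X, y, folds, subset, forest_size, seed)
    raise ValueError(f"unknown estimator {estimator!r}")


class GeneticSubsetSelector(BaseEstimator):
    """GA search over fixed-size feature subsets, scored by grouped-CV -MAE.

    Operators: tournament parent selection, set-preserving crossover (child
    = parents' intersection filled up to k from the symmetric difference),
    single-swap mutation, one elite carried per generation (making the
    best-so-far trace monotone).

    Attributes after fit: ``support_`` (boolean mask), ``best_features_``
    (column names when fit on a DataFrame), ``best_score_`` and ``trace_``
    (best-so-far fitness per generation).
    """

    def __init__(
        self,
        k: int = 15,
        population_size: int = 40,
        generations: int = 25,
        cv_folds: int = 5,
        estimator: str = "distance_based_linear",
        tournament_size: int = 3,
        mutation_rate: float = 0.1,
        elitism: int = 1,
        forest_size: int = 100,
        random_state: int = 0,
    ):
        self.k = k
        self.population_size = population_size
        self.generations = generations
        self.cv_folds = cv_folds
        self.estimator = estimator
        self.tournament_size = tournament_size
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.forest_size = forest_size
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        n = Xa.shape[1]
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds feature count {n}")
        if groups is None:
            groups = np.arange(len(y))
        rng = np.random.default_rng(self.random_state)
        folds = grouped_fold_indices(groups, self.cv_folds, self.random_state)

        cache: dict[frozenset, float] = {}

        def score(ind: tuple[int, ...]) -> float:
            key = frozenset(ind)
            if key not in cache:
                if self.estimator == "distance_based_linear":
                    cache[key] = _linear_cv_neg_mae(Xa, y, folds, ind)
                else:
                    cache[key] = _forest_cv_neg_mae(
                        Xa, y, folds, ind, self.forest_size, self.random_state
                    )
            return cache[key]

        if self.k == n:
            full = tuple(range(n))
            best, best_fit = full, score(full)
            trace = [best_fit] * max(1, self.generations + 1)
        else:
            pop = [
                tuple(sorted(rng.choice(n, size=self.k, replace=False)))
                for _ in range(self.population_size)
            ]
            fits = np.array([score(ind) for ind in pop])
            best_i = int(np.argmax(fits))
            best, best_fit = pop[best_i], float(fits[best_i])
            trace = [best_fit]
            for _ in range(self.generations):
                new = [best] * min(self.elitism, 1)
                while len(new) < self.population_size:
                    p1 = self._tournament(pop, fits, rng)
                    p2 = self._tournament(pop, fits, rng)
                    child = self._crossover(p1, p2, rng)
                    if rng.uniform() < self.mutation_rate:
                        child = self._mutate(child, n, rng)
                    new.append(child)
                pop = new
                fits = np.array([score(ind) for ind in pop])
                gen_best = int(np.argmax(fits))
                if fits[gen_best] > best_fit:
                    best, best_fit = pop[gen_best], float(fits[gen_best])
                trace.append(best_fit)

        self.n_features_in_ = n
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.zeros(n, dtype=bool)
        self.support_[list(best)] = True
        self.best_features_ = tuple(names[i] for i in sorted(best))
        self.best_score_ = best_fit
        self.trace_ = np.asarray(trace)
        self.n_evaluations_ = len(cache)
        return self

    def _tournament(self, pop, fits, rng) -> tuple[int, ...]:
        idx = rng.integers(0, len(pop), size=self.tournament_size)
        return pop[idx[np.argmax(fits[idx])]]

    def _crossover(self, p1, p2, rng) -> tuple[int, ...]:
        s1, s2 = set(p1), set(p2)
        inter = s1 & s2
        pool = np.array(sorted(s1 ^ s2))
        need = self.k - len(inter)
        if need > 0:
            fill = rng.choice(pool, size=need, replace=False)
            inter = inter | set(int(i) for i in fill)
        return tuple(sorted(inter))

    def _mutate(self, ind, n, rng) -> tuple[int, ...]:
        outside = np.array(sorted(set(range(n)) - set(ind)))
        if outside.size == 0:
            return ind
        new = list(ind)
        new[int(rng.integers(0, len(new)))] = int(rng.choice(outside))
        return tuple(sorted(set(new))) if len(set(new)) == self.k else ind

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X[list(self.best_features_)]
        return np.asarray(X)[:, self.support_]


def ga_search(
    X, y, groups, ga_config: GAConfig, k: int | None = None, seed: int | None = None
) -> GeneticSubsetSelector:
    """Run one GA subset search with settings from ``ga_config``."""
    return GeneticSubsetSelector(
        k=ga_config.subset_size if k is None else k,
        population_size=ga_config.population_size,
        generations=ga_config.generations,
        cv_folds=ga_config.cv_folds,
        estimator=ga_config.estimator,
        tournament_size=ga_config.tournament_size,
        mutation_rate=ga_config.mutation_rate,
        elitism=ga_config.elitism,
        forest_size=ga_config.forest_size,
        random_state=ga_config.seed if seed is None else seed,
    ).fit(X, y, groups=groups)


def repeated_grouped_cv_scores(
    X,
    y,
    groups,
    estimator: str,
    n_splits: int = 10,
    n_repeats: int = 3,
    seed: int = 0,
    forest_size: int = 100,
) -> np.ndarray:
    """Repeated grouped k-fold negative-MAE scores (n_splits x n_repeats)."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    subset = tuple(range(Xa.shape[1]))
    scores = []
    for rep in range(n_repeats):
        folds = grouped_fold_indices(groups, n_splits, seed + rep)
        for tr, va in folds:
            if estimator == "distance_based_linear":
                scores.append(_linear_cv_neg_mae(Xa, y, [(tr, va)], subset))
            else:
                scores.append(
                    _forest_cv_neg_mae(
                        Xa, y, [(tr, va)], subset, forest_size, seed + rep
                    )
                )
    return np.asarray(scores)


def sweep_k(
    X, y, groups, ga_config: GAConfig, k_range
) -> pd.DataFrame:
    """GA search per subset size k, scored by repeated grouped k-fold CV.

    Returns one row per k with the mean and sd of the 30 (10 x 3 by
    default) fold scores of the best-found subset — the curve from which
    the operating subset size is chosen.
    """
    rows = []
    for k in k_range:
        sel = ga_search(X, y, groups, ga_config, k=k)
        Xsub = sel.transform(X)
        scores = repeated_grouped_cv_scores(
            Xsub, y, groups, ga_config.estimator,
            seed=ga_config.seed, forest_size=ga_config.forest_size,
        )
        rows.append(
            {
                "k": k,
                "mean_score": scores.mean(),
                "sd_score": scores.std(ddof=1),
                "n_scores": len(scores),
                "subset": sel.best_features_,
            }
        )
    return pd.DataFrame(rows)


def frequency_analysis(
    repetition_subsets: list,
    universe: list[str],
    ga_config: GAConfig,
    X=None,
    y=None,
    groups=None,
    scenario_id: int = 0,
    holdout_ids: tuple[str, ...] = (),
) -> SelectionReport:
    """Pick frequencies across repetitions and the final consolidation run.

    The candidate pool is every feature picked in more than
    ``frequency_threshold`` of the repetitions; a final GA over the pool
    yields the chosen set.  An empty pool falls back (loudly) to the
    top-k-by-frequency set.
    """
    if len(repetition_subsets) == 0:
        raise ValueError("need at least one repetition")
    counts = pd.Series(0.0, index=list(universe))
    for subset in repetition_subsets:
        for f in subset:
            counts[f] += 1
    freqs = counts / len(repetition_subsets)
    pool = list(freqs.index[freqs > ga_config.frequency_threshold])
    fallback = False
    if len(pool) == 0:
        fallback = True
        k = min(ga_config.subset_size, len(universe))
        pool = list(freqs.sort_values(ascending=False).index[:k])
        warnings.warn(
            "empty candidate pool after frequency thresholding; "
            f"falling back to the top {k} features by frequency",
            stacklevel=2,
        )
        logger.warning("frequency_analysis fallback: pool=%s", pool)
    if X is not None and len(pool) > 1:
        k_final = min(ga_config.subset_size, len(pool))
        sel = ga_search(
            X[pool] if isinstance(X, pd.DataFrame) else X,
            y, groups, ga_config, k=k_final,
        )
        chosen = sel.best_features_
    else:
        chosen = tuple(pool)
    return SelectionReport(
        scenario_id=scenario_id,
        frequencies=freqs,
        chosen=chosen,
        holdout_ids=tuple(holdout_ids),
        fallback_used=fallback,
    )


def _encode_block(train_df, block_cols, discrete_cols, y_train):
    enc = StateSpaceEncoder(
        discrete_columns=[c for c in block_cols if c in discrete_cols]
    ).fit(train_df[block_cols], y_train)
    return enc


def run_scenario(
    states: pd.DataFrame,
    scenario_id: int,
    ga_config: GAConfig,
    schema: FeatureSchema,
    holdout_n: int = 10,
    train_fraction: float = 0.8,
) -> SelectionReport:
    """One of the four selection scenarios over a prepared cohort table.

    1: whole universe, raw features, forest estimator.
    2: whole universe, encoded + scaled, linear estimator.
    3: per-kind independent searches, raw, forest; chosen sets concatenated.
    4: per-kind independent searches, encoded + scaled, linear; concatenated.

    Each repetition re-draws the 4:1 patient split with a derived seed; the
    encoder (scenarios 2 and 4) refits on that repetition's training rows
    only.
    """
    if scenario_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown scenario id {scenario_id}")
    encoded_path = scenario_id in (2, 4)
    grouped_path = scenario_id in (3, 4)
    estimator = (
        "distance_based_linear" if encoded_path else "information_based_forest"
    )
    cfg = replace(ga_config, estimator=estimator)

    holdout, train_all, test = split_patients(
        states, holdout_n=holdout_n,
        train_fraction=train_fraction, seed=cfg.seed,
    )
    analysis = states[~states["patient_id"].isin(holdout)]
    universe = [f for f in schema.all_features if f in states.columns]
    blocks: list[list[str]]
    if grouped_path:
        blocks = [
            [f for f in getattr(schema, kind) if f in states.columns]
            for kind in ("continuous", "discrete", "pathogen")
        ]
        empty = [i for i, b in enumerate(blocks) if not b]
        if empty:
            logger.warning(
                "scenario %d: %d empty feature group(s); running %d sub-searches",
                scenario_id, len(empty), len(blocks) - len(empty),
            )
        blocks = [b for b in blocks if b]
    else:
        blocks = [universe]

    rep_subsets: list[tuple[str, ...]] = []
    for rep in range(cfg.repetitions):
        rep_seed = (cfg.seed * 1000003 + rep * 7919 + 1) % (2**31)
        _, train_ids, _ = split_patients(
            analysis, holdout_n=0, train_fraction=train_fraction, seed=rep_seed,
        )
        train_df = analysis[analysis["patient_id"].isin(train_ids)]
        y_train = train_df["sofa_total"].to_numpy(dtype=float)
        g_train = train_df["patient_id"].to_numpy()
        chosen_this_rep: list[str] = []
        for block in blocks:
            Xb = train_df[block]
            if encoded_path:
                enc = _encode_block(
                    train_df, block,
                    set(schema.discrete) | set(schema.pathogen), y_train,
                )
                Xb = enc.transform(Xb)
            k = min(cfg.subset_size, len(block))
            sel = ga_search(Xb, y_train, g_train, cfg, k=k, seed=rep_seed)
            chosen_this_rep.extend(sel.best_features_)
        rep_subsets.append(tuple(chosen_this_rep))

    # Final consolidation on a fresh derived split of the analysis set.
    final_seed = (cfg.seed * 1000003 + 999331) % (2**31)
    _, final_train_ids, _ = split_patients(
        analysis, holdout_n=0, train_fraction=train_fraction, seed=final_seed,
    )
    final_df = analysis[analysis["patient_id"].isin(final_train_ids)]
    y_final = final_df["sofa_total"].to_numpy(dtype=float)
    g_final = final_df["patient_id"].to_numpy()
    X_final = final_df[universe]
    if encoded_path:
        enc = _encode_block(
            final_df, universe, set(schema.discrete) | set(schema.pathogen), y_final
        )
        X_final = enc.transform(X_final)
    report = frequency_analysis(
        rep_subsets, universe, replace(cfg, seed=final_seed),
        X=X_final, y=y_final, groups=g_final,
        scenario_id=scenario_id, holdout_ids=holdout,
    )
    return report
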