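"""Feature-subset selection: PCA variance thresholding and a wrapper GA.

PCA route: mean-centred (not standardized) covariance PCA; retain the
minimal number of leading components whose cumulative explained
variance reaches the requested fraction (97/98/99% in the reference
protocol); the "selected features" are the component scores.

GA route: a generational genetic algorithm over 89-bit feature masks.
Fitness of a mask is the mean accuracy (%) of a cubic-kernel SVM,
K(x, y) = (1 + x.y)^3, under stratified 10-fold cross-validation on
the masked columns.  Folds are frozen for the whole run (one cv_seed)
so that selection pressure acts on the subset, not on fold noise.
Operators: tournament selection (best two of five randomly chosen
individuals), one-point crossover, per-gene bit-flip mutation, and
elitism (the all-time best individual survives every generation, so
the best-fitness history is nondecreasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "PcaSelection",
    "pca_select",
    "FitnessEvaluator",
    "GAConfig",
    "GAResult",
    "ga_select",
    "one_point_crossover",
]


# ---------------------------------------------------------------------------
# PCA variance thresholding
# ---------------------------------------------------------------------------

@dataclass
class PcaSelection:
    """Result of PCA variance thresholding."""

    variance_fraction: float
    n_components: int
    components: np.ndarray          # (n_components, n_features) loadings
    explained_variance: np.ndarray  # per retained component
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def pca_select(X: np.ndarray, variance_fraction: float):
    """Retain the minimal leading components reaching ``variance_fraction``.

    Returns ``(PcaSelection, scores)`` where ``scores`` is the data
    projected onto the retained components (the "new data set").
    Centring subtracts the column means only; features are not
    standardized.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError(f"variance_fraction must be in (0, 1], got {variance_fraction}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred data == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (X.shape[0] - 1)
    total = ev.sum()
    ratio = ev / total if total > 0 else np.zeros_like(ev)
    cum = np.cumsum(ratio)
    # minimal k with cumulative ratio >= threshold (tiny eps absorbs
    # round-off when the threshold is exactly attainable)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, len(ev))
    sel = PcaSelection(
        variance_fraction=variance_fraction,
        n_components=k,
        components=Vt[:k],
        explained_variance=ev[:k],
        explained_variance_ratio=ratio[:k],
        mean=mean,
    )
    return sel, Xc @ Vt[:k].T


# ---------------------------------------------------------------------------
# Wrapper-GA fitness
# ---------------------------------------------------------------------------

class FitnessEvaluator:
    """Cross-validated cubic-SVM accuracy of a feature mask, in percent.

    The polynomial kernel (1 + x.y)^degree is evaluated once per mask
    as a full Gram matrix and sliced per fold, which is substantially
    cheaper than recomputing it inside each fold.  Results are cached
    by mask, and an empty mask scores 0 so it can never become elite.

    ``tol`` is the SVM solver tolerance; the default is looser than
    the library default because fitness only has to rank masks, and
    ranking is stable well before full dual convergence.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cv_seed: int = 0,
        folds: int = 10,
        degree: int = 3,
        C: float = 1.0,
        tol: float = 0.1,
    ):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y)
        classes, counts = np.unique(self.y, return_counts=True)
        if counts.min() < folds:
            small = classes[counts.argmin()]
            raise ValueError(
                f"class {small!r} has {counts.min()} members; "
                f"{folds}-fold stratification needs at least {folds} per class"
            )
        self.degree = degree
        self.C = C
        self.tol = tol
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
        self._splits = list(skf.split(self.X, self.y))
        self._cache: dict = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.X.shape[1],):
            raise ValueError("mask length does not match feature count")
        key = mask.tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if not mask.any():
            self._cache[key] = 0.0
            return 0.0
        self.n_evaluations += 1
        Xm = self.X[:, mask]
        G = (1.0 + Xm @ Xm.T) ** self.degree
        acc = 0.0
        for tr, te in self._splits:
            clf = SVC(kernel="precomputed", C=self.C, tol=self.tol, shrinking=False)
            clf.fit(G[np.ix_(tr, tr)], self.y[tr])
            acc += float((clf.predict(G[np.ix_(te, tr)]) == self.y[te]).mean())
        value = acc / len(self._splits) * 100.0
        self._cache[key] = value
        return value


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Parameters of the generational GA.

    Defaults follow the reference protocol: population 20, 250
    generations, parents = best two of five randomly chosen
    individuals, one-point crossover, per-gene bit-flip mutation at
    rate 1/m (the canonical "simple mutation" rate), single-individual
    elitism.
    """

    population_size: int = 20
    generations: int = 250
    tournament_pool: int = 5
    mutation_rate: Optional[float] = None  # None -> 1/m
    rng_seed: int = 0
    cv_seed: Optional[int] = None  # None -> rng_seed

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mutation_rate is not None and not 0.0 < self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in (0, 1)")


@dataclass
class GAResult:
    best_mask: np.ndarray
    best_fitness: float
    fitness_history: List[float]  # all-time best after init and each generation
    generation_of_convergence: int
    n_evaluations: int = 0
    config: Optional[GAConfig] = None

    @property
    def n_selected(self) -> int:
        return int(self.best_mask.sum())


def one_point_crossover(parent_a: np.ndarray, parent_b: np.ndarray, cut: int):
    """Splice two binary parents at position ``cut`` (1 <= cut <= m-1)."""
    m = len(parent_a)
    if not 1 <= cut <= m - 1:
        raise ValueError(f"cut {cut} outside [1, {m - 1}]")
    child_a = np.concatenate([parent_a[:cut], parent_b[cut:]])
    child_b = np.concatenate([parent_b[:cut], parent_a[cut:]])
    return child_a, child_b


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[GAConfig] = None,
    fitness: Optional[Callable[[np.ndarray], float]] = None,
) -> GAResult:
    """Run the wrapper GA and return the best mask over all generations.

    A custom ``fitness`` callable may be supplied (used by tests and
    by PCA/GA comparisons); by default a :class:`FitnessEvaluator`
    with a cubic SVM is built on (X, y).
    """
    config = config or GAConfig()
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if fitness is None:
        fitness = FitnessEvaluator(
            X, y, cv_seed=config.cv_seed if config.cv_seed is not None else config.rng_seed
        )
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / m
    rng = np.random.default_rng(config.rng_seed)
    pop_size = config.population_size

    pop = rng.random((pop_size, m)) < 0.5
    fit = np.array([fitness(ind) for ind in pop])
    best_idx = int(np.argmax(fit))
    best_mask, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    history = [best_fit]
    convergence_gen = 0

    for gen in range(1, config.generations + 1):
        offspring = np.empty_like(pop)
        for t in range(pop_size // 2):
            pool = rng.choice(pop_size, size=config.tournament_pool, replace=False)
            ranked = pool[np.argsort(-fit[pool], kind="stable")]
            cut = int(rng.integers(1, m))
            c1, c2 = one_point_crossover(pop[ranked[0]], pop[ranked[1]], cut)
            offspring[2 * t], offspring[2 * t + 1] = c1, c2
        offspring ^= rng.random(offspring.shape) < mut
        off_fit = np.array([fitness(ind) for ind in offspring])
        # elitism: the all-time best replaces the worst offspring
        worst = int(np.argmin(off_fit))
        offspring[worst], off_fit[worst] = best_mask, best_fit
        pop, fit = offspring, off_fit
        gen_best = int(np.argmax(fit))
        if float(fit[gen_best]) > best_fit:
            best_mask, best_fit = pop[gen_best].copy(), float(fit[gen_best])
            convergence_gen = gen
        history.append(best_fit)

    return GAResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        fitness_history=history,
        generation_of_convergence=convergence_gen,
        n_evaluations=getattr(fitness, "n_evaluations", 0),
        config=config,
    )
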