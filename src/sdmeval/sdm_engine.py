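"""The six-algorithm modelling panel and the replicated experiment runner.

Algorithms (one contract each, fulfilled by standard learners):

* ``GLM`` — binomial regression with polynomial terms (degree <= 2),
  forward stepwise selection by AIC;
* ``GAM`` — binomial regression on smooth per-variable spline bases with
  three effective degrees of freedom per variable;
* ``GBM`` — gradient boosting, up to 5000 trees, iteration count chosen
  by k-fold cross-validation;
* ``RF`` — random forest, 500 trees;
* ``ANN`` — single-hidden-layer neural network, weight decay and hidden
  units chosen by k-fold cross-validation over a small grid;
* ``MAXENT_LIKE`` — L1-penalized logistic regression on an expanded
  feature set (linear, quadratic, pairwise products, hinges) whose
  complexity grows with sample size — an emulation of maximum-entropy
  presence-background modelling with logistic output, not a
  reimplementation of the Maxent software.

Each species is modelled under replicated 75/25 presence/pseudo-absence
splits (10 replicates; species with fewer than 10 records get one
replicate per record), and a strict-majority consensus ensemble pools
the threshold-binarized maps of the five non-Maxent algorithms across
all replicates.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .geodata import EnvStack, FeatureTable, extract_features, features_for_all_cells
from .map_eval import BinaryMap, binarize, compute_auc, consensus_map, \
    consensus_vote_fraction, select_threshold
from .synthdata import SpeciesPool, sample_pseudo_absences

logger = logging.getLogger("sdmeval")

ALGORITHMS = ("GLM", "GAM", "GBM", "RF", "ANN", "MAXENT_LIKE")
CONSENSUS_ID = "CONSENSUS"
#: Members of the consensus ensemble (the Maxent-like learner runs on a
#: separate platform in the emulated workflow and is excluded).
CONSENSUS_MEMBERS = ("GLM", "GAM", "GBM", "RF", "ANN")
#: Species with fewer records than this get one replicate per record.
SMALL_SAMPLE_CUTOFF = 10

PredictFn = Callable[[pd.DataFrame], np.ndarray]


class ModelFitError(RuntimeError):
    def __init__(self, algorithm_id: str, replicate: int, message: str):
        super().__init__(f"{algorithm_id} replicate {replicate}: {message}")
        self.algorithm_id = algorithm_id
        self.replicate = replicate


# ---------------------------------------------------------------------------
# Specs and defaults
# ---------------------------------------------------------------------------

_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "GLM": {"max_degree": 2},
    "GAM": {"df": 3},
    "GBM": {"n_trees_max": 5000, "cv_folds": 5, "learning_rate": 0.1,
            "max_depth": 3},
    "RF": {"n_trees": 500},
    "ANN": {"decay_grid": (0.001, 0.01, 0.1), "units_grid": (2, 4, 8),
            "cv_folds": 5, "max_iter": 300},
    "MAXENT_LIKE": {"C": 1.0, "hinge_knots": 4},
}


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one algorithm of the panel."""

    algorithm_id: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm '{self.algorithm_id}'; "
                f"expected one of {ALGORITHMS}"
            )
        unknown = set(self.hyperparameters) - set(
            _DEFAULT_HYPERPARAMS[self.algorithm_id])
        if unknown:
            raise ValueError(
                f"{self.algorithm_id}: unknown hyperparameters {sorted(unknown)}")

    @property
    def params(self) -> dict:
        p = dict(_DEFAULT_HYPERPARAMS[self.algorithm_id])
        p.update(self.hyperparameters)
        return p


@dataclass
class Split:
    """Replicate-specific 75/25 partition, stratified by label."""

    train_presence: np.ndarray
    test_presence: np.ndarray
    train_absence: np.ndarray
    test_absence: np.ndarray
    seed: int

    @property
    def train_all(self) -> np.ndarray:
        return np.concatenate([self.train_presence, self.train_absence])

    @property
    def test_all(self) -> np.ndarray:
        return np.concatenate([self.test_presence, self.test_absence])


@dataclass
class ModelRun:
    """One algorithm x species x replicate fit with its evaluation slots."""

    species_id: str
    algorithm_id: str
    replicate: int
    seed: int
    split: Split | None
    suitability_map: np.ndarray | None = None
    predict_fn: PredictFn | None = None
    auc: float = float("nan")
    threshold: float = float("nan")
    binary_map: BinaryMap | None = None
    importance: pd.Series | None = None


# ---------------------------------------------------------------------------
# Seeding and splitting
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *parts) -> int:
    """Stable stream-decoupling seed below 2**31 from hashed identifiers."""
    key = ":".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(key.encode()) % (2**31)


def split_data(presences: np.ndarray, absences: np.ndarray,
               train_frac: float = 0.75, replicate_index: int = 0,
               master_seed: int = 0, species_id: str = "") -> Split:
    """Stratified random 75/25 partition of row indices.

    Presences and absences are split independently; train size is
    ``floor(train_frac * n)`` with at least one point forced into each
    side.  The replicate-specific seed derives from
    ``(master_seed, species_id, replicate_index)``.
    """
    presences = np.asarray(presences)
    absences = np.asarray(absences)
    if len(presences) < 2 or len(absences) < 2:
        raise ValueError("each stratum needs at least two points to split")
    seed = derive_seed(master_seed, "split", species_id, replicate_index)
    rng = np.random.default_rng(seed)

    def _part(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = len(idx)
        n_train = int(np.floor(train_frac * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        return idx[perm[:n_train]], idx[perm[n_train:]]

    tr_p, te_p = _part(presences)
    tr_a, te_a = _part(absences)
    return Split(train_presence=tr_p, test_presence=te_p,
                 train_absence=tr_a, test_absence=te_a, seed=seed)


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _poly_design(X: np.ndarray, terms: Sequence[tuple[int, int]]) -> np.ndarray:
    """Columns x_j**d for (j, d) in terms, plus intercept."""
    cols = [np.ones(len(X))]
    cols += [X[:, j] ** d for j, d in terms]
    return np.column_stack(cols)


def _spline_basis(x: np.ndarray, lo: float, hi: float, df: int = 3) -> np.ndarray:
    """``df`` smooth basis columns on [lo, hi] (Bernstein cubic, first
    column dropped against the intercept); values are clipped to the
    training range so whole-map prediction cannot extrapolate wildly."""
    if hi <= lo:
        return np.zeros((len(x), df))
    xc = np.clip(x, lo, hi)
    t = np.array([lo] * 4 + [hi] * 4)
    dm = BSpline.design_matrix(xc, t, 3).toarray()
    return dm[:, 1:1 + df]


def _aic_logistic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Near-ML logistic fit (tiny ridge for separable data); returns
    (AIC, coefficient vector incl. intercept column already in X)."""
    lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=500,
                            fit_intercept=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(X, y)
    p = lr.predict_proba(X)[:, 1]
    llf = -log_loss(y, p, normalize=False, labels=[0, 1])
    k = X.shape[1]
    return 2 * k - 2 * llf, lr.coef_.ravel()


# ---------------------------------------------------------------------------
# Per-algorithm fitters: each returns a PredictFn mapping a feature
# DataFrame (stack layer order) to scores in [0, 1]
# ---------------------------------------------------------------------------

def _fit_glm(Xdf: pd.DataFrame, y: np.ndarray, params: dict, seed: int) -> PredictFn:
    cols = list(Xdf.columns)
    mu, sd = Xdf.mean().to_numpy(), Xdf.std().replace(0, 1).to_numpy()

    def _design(df: pd.DataFrame, terms) -> np.ndarray:
        Z = (df[cols].to_numpy() - mu) / sd
        return _poly_design(Z, terms)

    candidates = [(j, d) for j in range(len(cols))
                  for d in range(1, params["max_degree"] + 1)]
    terms: list[tuple[int, int]] = []
    best_aic, _ = _aic_logistic(_design(Xdf, terms), y)
    improved = True
    while improved and len(terms) < len(candidates):
        improved = False
        trial = [(c, *_aic_logistic(_design(Xdf, terms + [c]), y))
                 for c in candidates if c not in terms]
        cand, aic, coef = min(trial, key=lambda t: t[1])
        if aic < best_aic - 1e-9:
            terms.append(cand)
            best_aic, best_coef = aic, coef
            improved = True
    if not terms:  # intercept-only model
        _, best_coef = _aic_logistic(_design(Xdf, terms), y)
    chosen = list(terms)

    def predict(df: pd.DataFrame) -> np.ndarray:
        return expit(_design(df, chosen) @ best_coef)

    return predict


def _fit_gam(Xdf: pd.DataFrame, y: np.ndarray, params: dict, seed: int) -> PredictFn:
    cols = list(Xdf.columns)
    df_per_var = params["df"]
    bounds = {c: (float(Xdf[c].min()), float(Xdf[c].max())) for c in cols}

    def _design(df: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(df), 1))]
        blocks += [_spline_basis(df[c].to_numpy(), *bounds[c], df_per_var)
                   for c in cols]
        return np.hstack(blocks)

    _, coef = _aic_logistic(_design(Xdf), y)

    def predict(df: pd.DataFrame) -> np.ndarray:
        return expit(_design(df) @ coef)

    return predict


def _safe_folds(y: np.ndarray, requested: int) -> int:
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    return min(requested, minority)


def _fit_gbm(Xdf: pd.DataFrame, y: np.ndarray, params: dict, seed: int) -> PredictFn:
    X = Xdf.to_numpy()
    n_max = params["n_trees_max"]
    folds = _safe_folds(y, params["cv_folds"])
    kw = dict(learning_rate=params["learning_rate"],
              max_depth=params["max_depth"], random_state=seed)
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        losses = np.zeros(n_max)
        for tr, va in cv.split(X, y):
            m = GradientBoostingClassifier(n_estimators=n_max, **kw)
            m.fit(X[tr], y[tr])
            for i, p in enumerate(m.staged_predict_proba(X[va])):
                losses[i] += log_loss(y[va], p[:, 1], labels=[0, 1])
        best_n = int(np.argmin(losses)) + 1
    else:
        best_n = n_max
    model = GradientBoostingClassifier(n_estimators=best_n, **kw)
    model.fit(X, y)
    cols = list(Xdf.columns)

    def predict(df: pd.DataFrame) -> np.ndarray:
        return model.predict_proba(df[cols].to_numpy())[:, 1]

    return predict


def _fit_rf(Xdf: pd.DataFrame, y: np.ndarray, params: dict, seed: int) -> PredictFn:
    model = RandomForestClassifier(n_estimators=params["n_trees"],
                                   random_state=seed, n_jobs=1)
    model.fit(Xdf.to_numpy(), y)
    cols = list(Xdf.columns)

    def predict(df: pd.DataFrame) -> np.ndarray:
        return model.predict_proba(df[cols].to_numpy())[:, 1]

    return predict


def _fit_ann(Xdf: pd.DataFrame, y: np.ndarray, params: dict, seed: int) -> PredictFn:
    scaler = StandardScaler().fit(Xdf.to_numpy())
    X = scaler.transform(Xdf.to_numpy())
    grid = [(d, u) for d in params["decay_grid"] for u in params["units_grid"]]
    folds = _safe_folds(y, params["cv_folds"])

    def _make(decay: float, units: int, rs: int) -> MLPClassifier:
        return MLPClassifier(hidden_layer_sizes=(units,), alpha=decay,
                             solver="lbfgs", max_iter=params["max_iter"],
                             random_state=rs)

    best = grid[len(grid) // 2]
    if folds >= 2 and len(grid) > 1:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = []
        for decay, units in grid:
            aucs = []
            for fold_i, (tr, va) in enumerate(cv.split(X, y)):
                m = _make(decay, units, seed + fold_i)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(X[tr], y[tr])
                p = m.predict_proba(X[va])[:, 1]
                aucs.append(roc_auc_score(y[va], p) if len(set(y[va])) == 2 else 0.5)
            scores.append(np.mean(aucs))
        best = grid[int(np.argmax(scores))]
    model = _make(best[0], best[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    cols = list(Xdf.columns)

    def predict(df: pd.DataFrame) -> np.ndarray:
        p = model.predict_proba(scaler.transform(df[cols].to_numpy()))[:, 1]
        return np.clip(p, 0.0, 1.0)

    return predict


def _maxent_expansion(Xdf: pd.DataFrame, n_train: int,
                      knots: dict[str, np.ndarray] | None,
                      cols: list[str]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Auto-feature expansion: linear always; quadratic for n >= 10;
    hinge for n >= 15; pairwise products for n >= 80 (sample-size
    schedule in the spirit of maximum-entropy auto-features)."""
    X = Xdf[cols].to_numpy()
    feats = [X]
    if n_train >= 10:
        feats.append(X**2)
    if knots is None:
        knots = {c: np.quantile(Xdf[c], [0.2, 0.4, 0.6, 0.8]) for c in cols}
    if n_train >= 15:
        for j, c in enumerate(cols):
            for k in knots[c]:
                feats.append(np.maximum(0.0, X[:, j] - k)[:, None])
                feats.append(np.maximum(0.0, k - X[:, j])[:, None])
    if n_train >= 80:
        prods = [(X[:, i] * X[:, j])[:, None]
                 for i in range(len(cols)) for j in range(i + 1, len(cols))]
        feats.extend(prods)
    return np.hstack(feats), knots


def _fit_maxent_like(Xdf: pd.DataFrame, y: np.ndarray, params: dict,
                     seed: int) -> PredictFn:
    cols = list(Xdf.columns)
    n_train = int((y == 1).sum())
    Z, knots = _maxent_expansion(Xdf, n_train, None, cols)
    scaler = StandardScaler().fit(Z)
    model = LogisticRegression(l1_ratio=1.0, C=params["C"],
                               solver="liblinear", max_iter=500,
                               random_state=seed)
    model.fit(scaler.transform(Z), y)

    def predict(df: pd.DataFrame) -> np.ndarray:
        Zp, _ = _maxent_expansion(df, n_train, knots, cols)
        return model.predict_proba(scaler.transform(Zp))[:, 1]

    return predict


_FITTERS = {
    "GLM": _fit_glm,
    "GAM": _fit_gam,
    "GBM": _fit_gbm,
    "RF": _fit_rf,
    "ANN": _fit_ann,
    "MAXENT_LIKE": _fit_maxent_like,
}


# ---------------------------------------------------------------------------
# fit_predict
# ---------------------------------------------------------------------------

def fit_predict(spec: ModelSpec, train: FeatureTable, stack: EnvStack,
                species_id: str = "", replicate: int = 0) -> ModelRun:
    """Fit one model and predict suitability over the whole grid.

    Returns a :class:`ModelRun` with ``predict_fn`` (feature DataFrame ->
    scores in [0, 1]) and ``suitability_map`` (NaN at nodata) populated;
    AUC, threshold and the binary map are filled in by the experiment
    runner, which knows the replicate split.
    """
    y = train.labels
    if len(set(y.tolist())) < 2:
        raise ModelFitError(spec.algorithm_id, replicate,
                            "training set contains a single label")
    fitter = _FITTERS[spec.algorithm_id]
    try:
        predict = fitter(train.features, y, spec.params, spec.seed)
    except ModelFitError:
        raise
    except Exception as exc:  # non-convergence and numerical failures
        raise ModelFitError(spec.algorithm_id, replicate, str(exc)) from exc

    def predict_clipped(df: pd.DataFrame) -> np.ndarray:
        return np.clip(predict(df), 0.0, 1.0)

    all_feats, all_cells = features_for_all_cells(stack)
    scores = predict_clipped(all_feats)
    smap = np.full(stack.shape, np.nan)
    smap[all_cells[:, 0], all_cells[:, 1]] = scores
    return ModelRun(species_id=species_id, algorithm_id=spec.algorithm_id,
                    replicate=replicate, seed=spec.seed, split=None,
                    suitability_map=smap, predict_fn=predict_clipped)


# ---------------------------------------------------------------------------
# Experiment runner and ledger
# ---------------------------------------------------------------------------

@dataclass
class EngineConfig:
    """Runtime configuration of the replicated experiment.

    ``pa_factor`` and ``pa_max`` control the pseudo-absence sample per
    replicate: ``min(pa_factor * n_presences, pa_max, available)``,
    resampled independently each replicate.
    """

    n_replicates: int = 10
    train_frac: float = 0.75
    pa_factor: int = 10
    pa_max: int | None = None
    include_consensus: bool = True
    hyperparameters: dict[str, dict] = field(default_factory=dict)

    def spec_for(self, algorithm_id: str, seed: int) -> ModelSpec:
        return ModelSpec(algorithm_id=algorithm_id,
                         hyperparameters=self.hyperparameters.get(algorithm_id, {}),
                         seed=seed)


def replicates_for(n_records: int, n_replicates: int,
                   small_cutoff: int = SMALL_SAMPLE_CUTOFF) -> int:
    """Data-poor species (fewer records than the cutoff) get one
    replicate per record; everyone else gets the full count."""
    return n_records if n_records < small_cutoff else n_replicates


def plan_experiment(record_counts: Sequence[int], n_algorithms: int = 7,
                    n_replicates: int = 10,
                    small_cutoff: int = SMALL_SAMPLE_CUTOFF) -> int:
    """Total model instances in the ledger (consensus counted per
    replicate like any other algorithm)."""
    return sum(replicates_for(n, n_replicates, small_cutoff) * n_algorithms
               for n in record_counts)


@dataclass
class ExperimentResult:
    runs: list[ModelRun]
    ledger: pd.DataFrame

    def runs_for(self, species_id: str, algorithm_id: str) -> list[ModelRun]:
        return [r for r in self.runs
                if r.species_id == species_id and r.algorithm_id == algorithm_id]


def run_experiment(stack: EnvStack, pool: SpeciesPool,
                   algorithm_panel: Sequence[str] = ALGORITHMS,
                   config: EngineConfig | None = None,
                   master_seed: int = 0,
                   on_run: Callable[[ModelRun, FeatureTable], None] | None = None,
                   ) -> ExperimentResult:
    """Fit the full panel over the species pool under replicated splits.

    Per species and replicate: pseudo-absences are drawn from the
    target-group background, the data split 75/25, every algorithm of
    the panel fitted on the training rows, evaluated (AUC on test rows,
    threshold where sensitivity ≈ specificity on training rows) and
    binarized.  The consensus ensemble then pools the binary maps of the
    non-Maxent members across all replicates by strict majority.  Every
    model instance — including each consensus replicate and any failed
    fit — is a ledger row.

    ``on_run`` (if given) is called with each completed single-algorithm
    run and its full feature table, before the heavyweight fitted model
    is released; use it to compute permutation importance.
    """
    if len(algorithm_panel) == 0:
        raise ValueError("algorithm panel must be non-empty")
    cfg = config or EngineConfig()
    runs: list[ModelRun] = []
    ledger_rows: list[dict] = []
    for vs in pool.species:
        occ = pool.occurrences[vs.species_id]
        n_rec = occ.n_records
        reps = replicates_for(n_rec, cfg.n_replicates)
        per_rep_runs: dict[int, dict[str, ModelRun]] = {}
        per_rep_tables: dict[int, FeatureTable] = {}
        for r in range(reps):
            pa_seed = derive_seed(master_seed, "pa", vs.species_id, r)
            avail = len({tuple(c) for c in occ.background_cells}
                        - {tuple(c) for c in occ.presence_cells})
            n_pa = min(cfg.pa_factor * n_rec, avail)
            if cfg.pa_max is not None:
                n_pa = min(n_pa, cfg.pa_max)
            pas = sample_pseudo_absences(occ.background_cells,
                                         occ.presence_cells, n_pa, pa_seed)
            table = extract_features(stack, occ.presence_cells, pas)
            pres_idx = np.arange(n_rec)
            abs_idx = np.arange(n_rec, len(table))
            split = split_data(pres_idx, abs_idx, cfg.train_frac, r,
                               master_seed, vs.species_id)
            train = table.subset_rows(split.train_all)
            per_rep_tables[r] = table
            per_rep_runs[r] = {}
            for alg in algorithm_panel:
                seed = derive_seed(master_seed, "fit", vs.species_id, alg, r)
                spec = cfg.spec_for(alg, seed)
                row = dict(species_id=vs.species_id, algorithm_id=alg,
                           replicate=r, seed=seed, n_records=n_rec,
                           n_pseudo_absences=n_pa, status="ok", error="")
                try:
                    run = fit_predict(spec, train, stack,
                                      species_id=vs.species_id, replicate=r)
                    run.split = split
                    _evaluate_run(run, table, stack)
                    if on_run is not None:
                        on_run(run, table)
                    run.predict_fn = None  # release the fitted model
                    per_rep_runs[r][alg] = run
                    runs.append(run)
                except ModelFitError as exc:
                    row["status"] = "failed"
                    row["error"] = str(exc)
                    logger.warning("fit failed: %s %s", vs.species_id, exc)
                ledger_rows.append(row)
        if cfg.include_consensus:
            members = [per_rep_runs[r][alg].binary_map
                       for r in range(reps)
                       for alg in CONSENSUS_MEMBERS
                       if alg in per_rep_runs[r]]
            if len(members) >= 2:
                cons_bin = consensus_map(members, species_id=vs.species_id,
                                         algorithm_id=CONSENSUS_ID)
                vote = consensus_vote_fraction(members)
                for r in range(reps):
                    row = dict(species_id=vs.species_id,
                               algorithm_id=CONSENSUS_ID, replicate=r,
                               seed=-1, n_records=n_rec,
                               n_pseudo_absences=len(per_rep_tables[r])
                               - n_rec, status="ok", error="")
                    run = _consensus_run(vs.species_id, r, vote, cons_bin,
                                         per_rep_tables[r],
                                         _find_split(per_rep_runs[r]))
                    if run is None:
                        row["status"] = "failed"
                        row["error"] = "no member runs for replicate"
                    else:
                        runs.append(run)
                    ledger_rows.append(row)
            else:
                for r in range(reps):
                    ledger_rows.append(dict(
                        species_id=vs.species_id, algorithm_id=CONSENSUS_ID,
                        replicate=r, seed=-1, n_records=n_rec,
                        n_pseudo_absences=0, status="failed",
                        error="not enough member maps"))
    ledger = pd.DataFrame(ledger_rows)
    logger.info("experiment complete: %d ledger rows, %d successful runs",
                len(ledger), len(runs))
    return ExperimentResult(runs=runs, ledger=ledger)


def _find_split(rep_runs: dict[str, ModelRun]) -> Split | None:
    for alg in CONSENSUS_MEMBERS:
        if alg in rep_runs and rep_runs[alg].split is not None:
            return rep_runs[alg].split
    return None


def _evaluate_run(run: ModelRun, table: FeatureTable, stack: EnvStack) -> None:
    """Fill AUC (test rows), threshold (training rows) and binary map."""
    split = run.split
    assert split is not None and run.predict_fn is not None
    scores = run.predict_fn(table.features)
    test_p = scores[split.test_presence]
    test_a = scores[split.test_absence]
    run.auc = compute_auc(test_p, test_a)
    train_scores = scores[split.train_all]
    train_labels = table.labels[split.train_all]
    try:
        run.threshold, _, _ = select_threshold(train_scores, train_labels)
    except ValueError:
        run.threshold = 0.5  # degenerate scores: fall back to midpoint
    run.binary_map = binarize(run.suitability_map, run.threshold,
                              valid_mask=stack.valid_mask,
                              species_id=run.species_id,
                              algorithm_id=run.algorithm_id,
                              replicate=run.replicate)


def _consensus_run(species_id: str, replicate: int, vote: np.ndarray,
                   cons_bin: BinaryMap, table: FeatureTable,
                   split: Split | None) -> ModelRun | None:
    if split is None:
        return None
    cells = table.cells
    scores = vote[cells[:, 0], cells[:, 1]]
    auc = compute_auc(scores[split.test_presence], scores[split.test_absence])
    bm = replace(cons_bin, replicate=replicate)
    return ModelRun(species_id=species_id, algorithm_id=CONSENSUS_ID,
                    replicate=replicate, seed=-1, split=split,
                    suitability_map=vote, predict_fn=None, auc=auc,
                    threshold=0.5, binary_map=bm)
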