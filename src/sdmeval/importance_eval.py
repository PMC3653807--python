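"""Permutation variable importance and its cross-replicate consistency.

Importance of one predictor for one fitted model: permute that single
column of the feature table, re-predict, and take ``1 - max(0, r)``
where ``r`` is the Pearson correlation between the original and the
permuted predictions — averaged over several seeded permutations.  A
variable the model ignores scores 0; one that fully drives the
predictions scores near 1.  Per run the raw importances are normalized
to percentages summing to 100.

Consistency across replicate runs is summarized by the deviance from
average variable contribution (DFAC): per species, algorithm and
variable, the absolute difference between each replicate's importance
and the mean over replicates.  Low DFAC means the algorithm
characterizes the species' niche the same way run after run.  The
consensus ensemble is excluded: a combined variable contribution is not
meaningful for a majority vote over heterogeneous members.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .geodata import FeatureTable
from .sdm_engine import ModelRun, PredictFn, derive_seed

logger = logging.getLogger("sdmeval")

DEFAULT_N_PERMUTATIONS = 5


def variable_importance(predict_fn: PredictFn, features: FeatureTable | pd.DataFrame,
                        variable: str, n_perm: int = DEFAULT_N_PERMUTATIONS,
                        seed: int = 0) -> float:
    """Raw permutation importance of one variable, in [0, 1].

    Mean over ``n_perm`` seeded permutations of ``1 - max(0, r)``, where
    ``r`` correlates predictions on the original table with predictions
    on the table with that single column permuted.  Negative
    correlations are treated as complete signal loss.  Constant original
    predictions yield importance 0 with a logged warning.
    """
    df = features.features if isinstance(features, FeatureTable) else features
    if variable not in df.columns:
        raise ValueError(f"'{variable}' is not a feature column")
    if len(df) < 10:
        raise ValueError("need at least 10 rows for permutation importance")
    base = np.asarray(predict_fn(df), dtype=float)
    if np.std(base) == 0:
        logger.warning("constant predictions: importance of '%s' set to 0",
                       variable)
        return 0.0
    rng = np.random.default_rng(seed)
    vals = []
    col = df[variable].to_numpy()
    for _ in range(n_perm):
        perm_df = df.copy()
        perm_df[variable] = col[rng.permutation(len(col))]
        perm = np.asarray(predict_fn(perm_df), dtype=float)
        if np.std(perm) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(base, perm)[0, 1])
        vals.append(1.0 - max(0.0, r))
    return float(np.mean(vals))


def importance_profile(run: ModelRun, features: FeatureTable,
                       n_perm: int = DEFAULT_N_PERMUTATIONS,
                       master_seed: int = 0) -> pd.Series:
    """Percent importance of every variable for one run (sums to 100)."""
    if run.predict_fn is None:
        raise ValueError("run has no predict_fn (consensus runs are excluded)")
    names = features.variable_names
    raw = np.array([
        variable_importance(
            run.predict_fn, features, v, n_perm=n_perm,
            seed=derive_seed(master_seed, "perm", run.species_id,
                             run.algorithm_id, run.replicate, v))
        for v in names
    ])
    total = raw.sum()
    if total <= 0:
        logger.warning("all raw importances zero for %s/%s rep %d: "
                       "uniform profile", run.species_id, run.algorithm_id,
                       run.replicate)
        pct = np.full(len(names), 100.0 / len(names))
    else:
        pct = 100.0 * raw / total
    return pd.Series(pct, index=names, name=(run.species_id,
                                             run.algorithm_id, run.replicate))


def dfac(importance_vectors: Sequence[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Deviance from average variable contribution across replicates.

    Input: one percent-importance vector per replicate (identical
    variable sets).  Output: long frame (replicate, variable, deviance)
    with deviance = |importance - mean over replicates|, in percentage
    points.
    """
    if isinstance(importance_vectors, pd.DataFrame):
        mat = importance_vectors
    else:
        if len(importance_vectors) < 2:
            raise ValueError("DFAC needs at least two replicates")
        cols = [set(v.index) for v in importance_vectors]
        if any(c != cols[0] for c in cols[1:]):
            raise ValueError("replicates have mismatched variable sets")
        mat = pd.DataFrame([v.reindex(importance_vectors[0].index)
                            for v in importance_vectors]).reset_index(drop=True)
    if len(mat) < 2:
        raise ValueError("DFAC needs at least two replicates")
    dev = (mat - mat.mean(axis=0)).abs()
    out = dev.reset_index(names="replicate").melt(
        id_vars="replicate", var_name="variable", value_name="deviance")
    return out
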