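"""Gradient-forest-style allele-frequency turnover model.

Each adaptive locus gets a forest of fully grown CART regression trees fit
to population allele frequencies with environmental predictors, populations
bootstrapped as the sampling unit.  Every split's variance reduction is
logged at its threshold; split importances are normalized within a locus,
weighted by the locus's out-of-bag R^2, aggregated over loci, and globally
normalized so the cumulative-importance functions F_p sum to 1 at +inf.
Transforming a climate matrix through the F_p turns raw climate into
"genomic composition" space, where Euclidean distances are genomic offsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .core_data import AlleleFreqMatrix, EnvMatrix


@dataclass
class TurnoverModel:
    """Monotone cumulative-importance step functions per predictor."""

    predictors: list[str]
    breakpoints: dict[str, np.ndarray]  # sorted split thresholds
    cumulative: dict[str, np.ndarray]  # cumulative importance at breakpoints
    locus_r2: pd.Series  # out-of-bag R^2 of retained loci
    split_log: pd.DataFrame  # locus_id, tree, predictor, threshold, delta

    @property
    def importance(self) -> pd.Series:
        """Total cumulative importance per predictor (sums to 1)."""
        vals = {
            p: (self.cumulative[p][-1] if len(self.cumulative[p]) else 0.0)
            for p in self.predictors
        }
        return pd.Series(vals, name="importance")

    def evaluate(self, predictor: str, x: np.ndarray) -> np.ndarray:
        """Right-continuous step evaluation of F_p, clamped at the ends."""
        bp = self.breakpoints[predictor]
        cum = self.cumulative[predictor]
        if len(bp) == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        idx = np.searchsorted(bp, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], cum])
        return padded[idx]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "predictors": self.predictors,
            "breakpoints": {p: self.breakpoints[p].tolist() for p in self.predictors},
            "cumulative": {p: self.cumulative[p].tolist() for p in self.predictors},
            "locus_r2": self.locus_r2.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _tree_splits(tree: DecisionTreeRegressor) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(feature, threshold, variance-reduction delta) for every internal node."""
    t = tree.tree_
    internal = t.children_left != -1
    left, right = t.children_left[internal], t.children_right[internal]
    w = t.weighted_n_node_samples
    delta = (
        w[internal] * t.impurity[internal]
        - w[left] * t.impurity[left]
        - w[right] * t.impurity[right]
    )
    return t.feature[internal], t.threshold[internal], np.maximum(delta, 0.0)


def fit_turnover(
    F_adaptive: AlleleFreqMatrix,
    E_pop: EnvMatrix,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> TurnoverModel:
    """Fit the turnover model on adaptive-locus population frequencies.

    Loci with out-of-bag R^2 <= 0 carry no predictive turnover and are
    dropped; if every locus is dropped the model is undefined and an error
    is raised.
    """
    if len(F_adaptive.variants) < 1:
        raise ValueError("need at least one locus")
    E_pop = E_pop.reindex(F_adaptive.populations)
    X = E_pop.values
    predictors = list(E_pop.variables)
    P = len(predictors)
    n = len(F_adaptive.populations)
    if mtry is None:
        mtry = max(1, math.ceil(P / 3))
    Y = F_adaptive.imputed()
    rng = np.random.default_rng(seed)

    r2: dict[str, float] = {}
    per_locus_splits: dict[str, list[tuple[int, int, float, float]]] = {}
    for li, locus in enumerate(F_adaptive.variants):
        y = Y[:, li]
        var_y = y.var()
        if var_y == 0:
            continue
        oob_sum = np.zeros(n)
        oob_count = np.zeros(n, dtype=int)
        splits: list[tuple[int, int, float, float]] = []
        for t in range(n_trees):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeRegressor(
                max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(X[boot], y[boot])
            if len(oob):
                oob_sum[oob] += tree.predict(X[oob])
                oob_count[oob] += 1
            feat, thr, delta = _tree_splits(tree)
            for f, th, d in zip(feat, thr, delta):
                if d > 0:
                    splits.append((t, int(f), float(th), float(d)))
        seen = oob_count > 0
        if not seen.any():
            continue
        mse = np.mean((y[seen] - oob_sum[seen] / oob_count[seen]) ** 2)
        r2_l = 1.0 - mse / var_y
        if r2_l <= 0 or not splits:
            continue
        r2[locus] = r2_l
        per_locus_splits[locus] = splits

    if not r2:
        raise ValueError("no predictive turnover: all loci have out-of-bag R^2 <= 0")

    # per-locus normalization: split weights sum to the locus R^2; then
    # global normalization over the summed R^2 so total importance is 1
    total_r2 = sum(r2.values())
    log_rows = []
    agg: dict[int, list[tuple[float, float]]] = {p: [] for p in range(P)}
    for locus, splits in per_locus_splits.items():
        total_delta = sum(d for _, _, _, d in splits)
        scale = r2[locus] / (total_delta * total_r2)
        for t, f, th, d in splits:
            agg[f].append((th, d * scale))
            log_rows.append((locus, t, predictors[f], th, d))

    breakpoints: dict[str, np.ndarray] = {}
    cumulative: dict[str, np.ndarray] = {}
    for f, p_name in enumerate(predictors):
        if agg[f]:
            arr = np.array(agg[f])
            order = np.argsort(arr[:, 0], kind="stable")
            thr_sorted = arr[order, 0]
            w_sorted = np.cumsum(arr[order, 1])
            # merge duplicate thresholds, keep the last cumulative value
            keep = np.r_[thr_sorted[1:] != thr_sorted[:-1], True]
            breakpoints[p_name] = thr_sorted[keep]
            cumulative[p_name] = w_sorted[keep]
        else:
            breakpoints[p_name] = np.array([])
            cumulative[p_name] = np.array([])

    split_log = pd.DataFrame(
        log_rows, columns=["locus_id", "tree", "predictor", "threshold", "delta"]
    )
    return TurnoverModel(
        predictors, breakpoints, cumulative, pd.Series(r2, name="oob_r2"), split_log
    )


def variable_importance(model: TurnoverModel) -> pd.DataFrame:
    """Predictors ranked by total cumulative importance (ties alphabetical)."""
    imp = model.importance
    df = imp.rename_axis("predictor").reset_index()
    df = df.sort_values(["importance", "predictor"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def transform_climate(model: TurnoverModel, E: EnvMatrix) -> pd.DataFrame:
    """Map a climate matrix into cumulative-importance ("genomic composition")
    space: cell (site, p) = F_p(e_site_p)."""
    missing = [p for p in model.predictors if p not in E.variables]
    if missing:
        raise KeyError(f"climate matrix lacks model predictors: {missing}")
    out = np.column_stack(
        [model.evaluate(p, E.column(p)) for p in model.predictors]
    )
    return pd.DataFrame(out, index=E.site_ids, columns=model.predictors)
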