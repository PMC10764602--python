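"""'Fit-the-fit' interpretable summary of a fitted regime.

A single shallow regression tree is fit to the per-individual posterior
mean treatment differences (log-time scale) produced by the flexible
model, and judged by R^2 = 1 - SSE/SST.  Leaf-level credible bounds come
from averaging the per-draw differences over each leaf's members, so the
summary retains calibrated uncertainty despite its simplicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor, export_text

from .exceptions import InvalidInputError

__all__ = ["SurrogateTree", "fit_surrogate_tree"]


@dataclass
class SurrogateTree:
    """Shallow variance-reduction tree over Stage-1 covariates."""

    tree: DecisionTreeRegressor | None
    r_squared: float
    leaves: pd.DataFrame
    feature_names: list[str]
    _constant: float | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if self.tree is None:
            n = len(X)
            return np.full(n, self._constant)
        X = np.asarray(X, float)
        return self.tree.predict(X)

    def leaf_assignments(self, X) -> np.ndarray:
        if self.tree is None:
            return np.zeros(len(X), int)
        return self.tree.apply(np.asarray(X, float))

    def render(self) -> str:
        if self.tree is None:
            return f"leaf: {self._constant:.4f} (single leaf)"
        return export_text(self.tree, feature_names=self.feature_names)


def fit_surrogate_tree(covariates: pd.DataFrame, target: np.ndarray,
                       max_leaves: int = 4,
                       draw_differences: np.ndarray | None = None,
                       level: float = 0.95) -> SurrogateTree:
    """Greedy variance-reduction tree of the posterior mean differences.

    ``draw_differences`` (n_draws, n) optionally supplies the per-draw
    posterior treatment differences used for leaf-level credible bounds.
    A constant target yields a single leaf with R^2 defined as 1;
    ``max_leaves=1`` yields the mean-only fit with R^2 = 0.
    """
    X = pd.DataFrame(covariates)
    y = np.asarray(target, float)
    if len(X) != y.size:
        raise InvalidInputError("one target value per individual required")
    names = list(X.columns)
    sst = float(np.sum((y - y.mean()) ** 2))

    def leaf_table(assign: np.ndarray) -> pd.DataFrame:
        rows = []
        for leaf_id in np.unique(assign):
            mask = assign == leaf_id
            row = {"leaf": int(leaf_id), "n": int(mask.sum()),
                   "mean_difference": float(y[mask].mean())}
            if draw_differences is not None:
                per_draw = np.asarray(draw_differences, float)[:, mask].mean(axis=1)
                a = (1 - level) / 2
                row["lower"] = float(np.quantile(per_draw, a))
                row["upper"] = float(np.quantile(per_draw, 1 - a))
            rows.append(row)
        return pd.DataFrame(rows)

    if sst <= 1e-12 * max(1.0, float(np.abs(y).max(initial=0.0)) ** 2):
        assign = np.zeros(y.size, int)
        return SurrogateTree(tree=None, r_squared=1.0, leaves=leaf_table(assign),
                             feature_names=names, _constant=float(y.mean()))
    if max_leaves <= 1:
        assign = np.zeros(y.size, int)
        return SurrogateTree(tree=None, r_squared=0.0, leaves=leaf_table(assign),
                             feature_names=names, _constant=float(y.mean()))

    tree = DecisionTreeRegressor(max_leaf_nodes=max_leaves,
                                 criterion="squared_error", random_state=0)
    tree.fit(X.to_numpy(float), y)
    pred = tree.predict(X.to_numpy(float))
    sse = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - sse / sst
    assign = tree.apply(X.to_numpy(float))
    return SurrogateTree(tree=tree, r_squared=r2, leaves=leaf_table(assign),
                         feature_names=names)
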