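"""Classification tree over genotype predictors with Gini splitting.

Binary recursive partitioning for case-control screening of multilocus
genotype combinations: every candidate split sends a nonempty proper
subset of a variant's observed genotype categories (0/1/2) left, the
complement right; the split maximizing the Gini impurity decrease wins,
subject to node-size floors (min_parent samples to attempt a split,
min_child samples per resulting branch).  Missing genotypes at the split
variant follow the majority branch.  No cost-complexity pruning: growth
stops on the size floors or zero achievable decrease, and 10-fold
stratified cross-validation reports predictive misclassification.

Tie rule (determinism): among equal-decrease splits, lowest variant
index wins, then the lexicographically smallest left subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import build_design, fit_logistic, wald_effect
from .datamodel import ADJUSTMENT_COVARIATES, EffectEstimate


def gini(n_cases: int, n_controls: int) -> float:
    """Gini impurity 1 - p^2 - (1-p)^2 of a two-class node."""
    n = n_cases + n_controls
    if n == 0:
        raise ValueError("empty node")
    p = n_cases / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


@dataclass
class Split:
    variant_index: int
    variant_id: str
    left_categories: tuple[int, ...]  # genotype dosages sent left
    missing_left: bool                # majority branch for missing calls
    decrease: float


@dataclass
class TreeNode:
    node_id: int
    n_cases: int
    n_controls: int
    split: Optional[Split] = None
    children: Optional[tuple[int, int]] = None

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def gini(self) -> float:
        return gini(self.n_cases, self.n_controls)

    @property
    def is_terminal(self) -> bool:
        return self.children is None

    @property
    def case_proportion(self) -> float:
        return self.n_cases / self.n


@dataclass
class Tree:
    nodes: dict[int, TreeNode]
    root_id: int
    variant_ids: list[str]
    min_parent: int
    min_child: int
    cv_misclassification: Optional[float] = None

    def terminal_ids(self) -> list[int]:
        return [i for i, nd in sorted(self.nodes.items()) if nd.is_terminal]

    def predict_node(self, dosages: np.ndarray) -> np.ndarray:
        """Terminal node id for each sample (rows of the dosage matrix,
        columns ordered as ``variant_ids``)."""
        n = dosages.shape[0]
        out = np.empty(n, dtype=int)
        for i in range(n):
            nid = self.root_id
            while not self.nodes[nid].is_terminal:
                nd = self.nodes[nid]
                v = dosages[i, nd.split.variant_index]
                if np.isnan(v):
                    go_left = nd.split.missing_left
                else:
                    go_left = int(v) in nd.split.left_categories
                nid = nd.children[0] if go_left else nd.children[1]
            out[i] = nid
        return out

    def to_dict(self) -> dict:
        def node_dict(nd: TreeNode) -> dict:
            d = {"node_id": nd.node_id, "n_cases": nd.n_cases,
                 "n_controls": nd.n_controls, "gini": round(nd.gini, 6),
                 "terminal": nd.is_terminal}
            if nd.split is not None:
                d["split"] = {"variant": nd.split.variant_id,
                              "left_categories": list(nd.split.left_categories),
                              "missing_left": nd.split.missing_left,
                              "gini_decrease": round(nd.split.decrease, 6)}
                d["children"] = list(nd.children)
            return d
        return {"root": self.root_id,
                "min_parent": self.min_parent, "min_child": self.min_child,
                "cv_misclassification": self.cv_misclassification,
                "nodes": [node_dict(self.nodes[i]) for i in sorted(self.nodes)]}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _candidate_subsets(categories: Sequence[int]):
    """Nonempty proper subsets of the observed categories, one per
    complement pair (the lexicographically smaller member)."""
    cats = sorted(int(c) for c in categories)
    seen = set()
    for r in range(1, len(cats)):
        for sub in combinations(cats, r):
            comp = tuple(c for c in cats if c not in sub)
            if comp in seen:
                continue
            seen.add(sub)
            yield sub


def best_split(dosages: np.ndarray, y: np.ndarray, idx: np.ndarray,
               variant_ids: Sequence[str], min_parent: int, min_child: int
               ) -> Optional[Split]:
    """Exhaustive best Gini split at one node (``idx`` = sample rows)."""
    n_cases = int(y[idx].sum())
    n_controls = len(idx) - n_cases
    if len(idx) < min_parent or n_cases == 0 or n_controls == 0:
        return None
    parent_gini = gini(n_cases, n_controls)
    best: Optional[Split] = None
    for j, vid in enumerate(variant_ids):
        col = dosages[idx, j]
        missing = np.isnan(col)
        observed = col[~missing]
        cats = np.unique(observed).astype(int)
        if len(cats) < 2:
            continue
        for sub in _candidate_subsets(cats):
            left_obs = np.isin(col, sub) & ~missing
            right_obs = ~left_obs & ~missing
            missing_left = left_obs.sum() >= right_obs.sum()
            left = left_obs | (missing & missing_left)
            right = ~left
            nl, nr = int(left.sum()), int(right.sum())
            if nl < min_child or nr < min_child:
                continue
            yl = y[idx][left]
            yr = y[idx][right]
            gl = gini(int(yl.sum()), nl - int(yl.sum()))
            gr = gini(int(yr.sum()), nr - int(yr.sum()))
            decrease = parent_gini - (nl * gl + nr * gr) / (nl + nr)
            cand = Split(j, vid, tuple(int(c) for c in sub),
                         bool(missing_left), float(decrease))
            if best is None or _better(cand, best):
                best = cand
    if best is None or best.decrease <= 1e-12:
        return None
    return best


def _better(cand: Split, best: Split) -> bool:
    if cand.decrease > best.decrease + 1e-12:
        return True
    if cand.decrease < best.decrease - 1e-12:
        return False
    if cand.variant_index != best.variant_index:
        return cand.variant_index < best.variant_index
    return cand.left_categories < best.left_categories


def grow_tree(dosages: np.ndarray, y: np.ndarray,
              variant_ids: Sequence[str],
              min_parent: int = 100, min_child: int = 50) -> Tree:
    """Recursive partitioning until no admissible positive-decrease split."""
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    nodes: dict[int, TreeNode] = {}
    next_id = [1]

    def build(idx: np.ndarray) -> int:
        nid = next_id[0]
        next_id[0] += 1
        nc = int(y[idx].sum())
        node = TreeNode(nid, nc, len(idx) - nc)
        nodes[nid] = node
        sp = best_split(dosages, y, idx, variant_ids, min_parent, min_child)
        if sp is not None:
            node.split = sp
            col = dosages[idx, sp.variant_index]
            missing = np.isnan(col)
            left = (np.isin(col, sp.left_categories) & ~missing) | (
                missing & sp.missing_left)
            left_id = build(idx[left])
            right_id = build(idx[~left])
            node.children = (left_id, right_id)
        return nid

    root = build(np.arange(len(y)))
    return Tree(nodes=nodes, root_id=root, variant_ids=list(variant_ids),
                min_parent=min_parent, min_child=min_child)


def cross_validate(dosages: np.ndarray, y: np.ndarray,
                   variant_ids: Sequence[str], k: int = 10, seed: int = 0,
                   min_parent: int = 100, min_child: int = 50) -> float:
    """Stratified k-fold misclassification of majority-vote terminal nodes.

    Folds are stratified by status; held-out samples are classified by the
    majority status of their terminal node in the fold's tree (overall
    majority when a tree cannot grow past the root)."""
    if k < 2 or len(y) < k:
        raise ValueError("need k >= 2 and at least k samples")
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        rows = np.flatnonzero(y == cls)
        rng.shuffle(rows)
        fold[rows] = np.arange(len(rows)) % k
    errors = []
    for f in range(k):
        train = fold != f
        test = ~train
        tree = grow_tree(dosages[train], y[train], variant_ids,
                         min_parent, min_child)
        node_ids = tree.predict_node(dosages[test])
        pred = np.empty(test.sum())
        for nid in np.unique(node_ids):
            nd = tree.nodes[nid]
            pred[node_ids == nid] = 1.0 if nd.case_proportion > 0.5 else 0.0
        errors.append(float(np.mean(pred != y[test])))
    return float(np.mean(errors))


def terminal_node_or(tree: Tree, cohort: pd.DataFrame,
                     dosages: np.ndarray,
                     covariates: Sequence[str] = ADJUSTMENT_COVARIATES
                     ) -> pd.DataFrame:
    """Adjusted OR of each terminal node against the lowest-case-proportion
    terminal node (ties broken toward the lowest node id)."""
    node_ids = tree.predict_node(np.asarray(dosages, dtype=float))
    terminals = tree.terminal_ids()
    ref = min(terminals,
              key=lambda i: (tree.nodes[i].case_proportion, i))
    indicators = pd.DataFrame(
        {f"node{t}": (node_ids == t).astype(float)
         for t in terminals if t != ref})
    X, y, terms, _ = build_design(cohort, covariates, extra=indicators)
    fit = fit_logistic(X, y, terms)
    rows = []
    for t in terminals:
        nd = tree.nodes[t]
        row = {"node": t, "n_cases": nd.n_cases, "n_controls": nd.n_controls,
               "case_proportion": nd.case_proportion, "is_reference": t == ref}
        if t == ref:
            row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        else:
            eff = wald_effect(fit, f"node{t}")
            row.update(odds_ratio=eff.or_point, ci_low=eff.ci_low,
                       ci_high=eff.ci_high, p=eff.p)
        rows.append(row)
    return pd.DataFrame(rows)
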