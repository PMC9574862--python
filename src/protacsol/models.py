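"""Statistical layer: regressions, solubility decision tree, pair logic.

Three groups of tools:

* simple OLS (`fit_linear`) for the descriptor-solubility correlations;
* a three-class solubility classifier on (TPSA, BRlogD): both the fixed
  published rule (TPSA >= 289.31 Å² -> high; else BRlogD >= 2.58 -> low;
  else intermediate) and a refittable CART learner (Gini impurity,
  midpoint thresholds, exhaustive search) with stratified k-fold
  cross-validation and pooled confusion matrices;
* building-block pair comparison: does the solubility ordering of two
  degraders that differ in a single moiety follow the ordering of the
  swapped building blocks?
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .datatypes import Dataset, GskClass, Moiety
from .errors import DegenerateDesignError, DomainError, InsufficientDataError

# thresholds of the published two-split classification rule
RULE_TPSA_HIGH = 289.31   # Å²
RULE_BRLOGD_LOW = 2.58

CLASS_ORDER = (GskClass.LOW, GskClass.INTERMEDIATE, GskClass.HIGH)


# ---------------------------------------------------------------------------
# linear regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearModel:
    x_name: str
    y_name: str
    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_linear(x, y, x_name: str = "x", y_name: str = "y") -> LinearModel:
    """Ordinary least squares of y on x with R² = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} x vs {y.size} y")
    if x.size < 3:
        raise InsufficientDataError(f"regression needs n >= 3, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("non-finite values in regression input")
    if np.var(x) == 0:
        raise DegenerateDesignError("constant x: slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    # constant y: no variance to explain, R2 defined as 0
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return LinearModel(x_name, y_name, float(slope), float(intercept), r2, int(x.size))


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Internal split (feature/threshold, < goes left) or leaf (label)."""

    label: Optional[GskClass] = None
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class DecisionTreeModel:
    features: tuple[str, ...]
    root: TreeNode = field(default_factory=TreeNode)
    provenance: str = "refit"  # "fixed_rule" | "refit"

    def predict_one(self, values: dict[str, float]) -> GskClass:
        node = self.root
        while not node.is_leaf():
            node = node.left if values[node.feature] < node.threshold else node.right
        return node.label

    def predict(self, matrix: np.ndarray) -> list[GskClass]:
        matrix = np.asarray(matrix, dtype=float)
        return [self.predict_one(dict(zip(self.features, row))) for row in matrix]

    def splits(self) -> list[tuple[str, float]]:
        """All (feature, threshold) splits in depth-first order."""
        out: list[tuple[str, float]] = []

        def walk(node: TreeNode):
            if node.is_leaf():
                return
            out.append((node.feature, node.threshold))
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return out


def classify_solubility_rule(tpsa: float, brlogd: float) -> GskClass:
    """The fixed two-split rule on polarity and lipophilicity.

    TPSA >= 289.31 Å² -> high; otherwise BRlogD >= 2.58 -> low; the
    remaining region (polar enough? no; but not too lipophilic) -> intermediate.
    """
    if not (math.isfinite(tpsa) and math.isfinite(brlogd)):
        raise DomainError("rule needs finite TPSA and BRlogD")
    if tpsa >= RULE_TPSA_HIGH:
        return GskClass.HIGH
    if brlogd >= RULE_BRLOGD_LOW:
        return GskClass.LOW
    return GskClass.INTERMEDIATE


def reference_rule_tree() -> DecisionTreeModel:
    """The fixed rule expressed as a two-split tree object."""
    root = TreeNode(
        feature="tpsa", threshold=RULE_TPSA_HIGH,
        left=TreeNode(
            feature="brlogd", threshold=RULE_BRLOGD_LOW,
            left=TreeNode(label=GskClass.INTERMEDIATE),
            right=TreeNode(label=GskClass.LOW),
        ),
        right=TreeNode(label=GskClass.HIGH),
    )
    return DecisionTreeModel(features=("tpsa", "brlogd"), root=root, provenance="fixed_rule")


def _gini(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return 1.0 - float(np.sum(p * p))


def _majority(labels: np.ndarray) -> GskClass:
    values, counts = np.unique(labels, return_counts=True)
    # deterministic tie-break: class order low < intermediate < high
    best = max(zip(counts, [-CLASS_ORDER.index(GskClass(v)) for v in values], values))
    return GskClass(best[2])


def learn_tree(
    matrix,
    labels: Sequence[GskClass],
    features: Sequence[str],
    *,
    max_depth: Optional[int] = None,
    min_leaf: int = 1,
    feature_subset: Optional[int] = None,
    seed: Optional[int] = None,
) -> DecisionTreeModel:
    """CART: top-down exhaustive search minimising weighted Gini impurity.

    Candidate thresholds are midpoints of consecutive distinct sorted
    feature values. Deterministic unless ``feature_subset`` requests
    seeded per-node feature subsampling (the "random tree" behaviour).
    Single-class input yields a single-leaf tree with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray([GskClass(l).value for l in labels])
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DomainError(f"matrix {X.shape} does not match {y.size} labels")
    if not np.all(np.isfinite(X)):
        raise DomainError("non-finite feature values")
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training data: returning a single-leaf tree")
    rng = np.random.default_rng(seed)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = y[idx]
        if (len(np.unique(sub_y)) == 1
                or (max_depth is not None and depth >= max_depth)
                or idx.size < 2 * min_leaf):
            return TreeNode(label=_majority(sub_y))
        cand_features = range(X.shape[1])
        if feature_subset is not None and feature_subset < X.shape[1]:
            cand_features = sorted(rng.choice(X.shape[1], size=feature_subset, replace=False))
        best = None  # (impurity, feature_idx, threshold, mask)
        for f in cand_features:
            vals = np.sort(np.unique(X[idx, f]))
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2.0
                mask = X[idx, f] < thr
                n_left = int(mask.sum())
                if n_left < min_leaf or idx.size - n_left < min_leaf:
                    continue
                imp = (n_left * _gini(sub_y[mask])
                       + (idx.size - n_left) * _gini(sub_y[~mask])) / idx.size
                key = (imp, f, thr)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (imp, f, thr, mask)
        if best is None or best[0] >= _gini(sub_y) - 1e-12:
            return TreeNode(label=_majority(sub_y))
        _, f, thr, mask = best
        return TreeNode(
            feature=features[f], threshold=float(thr),
            left=build(idx[mask], depth + 1),
            right=build(idx[~mask], depth + 1),
        )

    model = DecisionTreeModel(features=tuple(features), provenance="refit")
    model.root = build(np.arange(y.size), 0)
    return model


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Pooled 3x3 confusion counts indexed (true class, predicted class)."""

    labels: tuple[GskClass, ...]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def recall(self, cls: GskClass) -> float:
        i = self.labels.index(cls)
        row = self.counts[i].sum()
        return float(self.counts[i, i]) / row if row else float("nan")


def confusion_matrix(true_labels, predicted_labels,
                     labels: Sequence[GskClass] = CLASS_ORDER) -> ConfusionMatrix:
    labels = tuple(labels)
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[labels.index(GskClass(t)), labels.index(GskClass(p))] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def cross_validate(
    matrix,
    labels: Sequence[GskClass],
    features: Sequence[str],
    *,
    k: int = 10,
    seed: int = 0,
    max_depth: Optional[int] = None,
    min_leaf: int = 1,
) -> tuple[float, ConfusionMatrix]:
    """Stratified k-fold cross-validation of the tree learner.

    Folds are stratified when every class has at least k members, else plain
    shuffled k-fold with a warning. Predictions are pooled into one
    confusion matrix; accuracy is pooled correct / n.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    X = np.asarray(matrix, dtype=float)
    y = np.asarray([GskClass(l).value for l in labels])
    if k > y.size:
        raise InsufficientDataError(f"k={k} folds exceed n={y.size} instances")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        warnings.warn(
            f"smallest class has {class_counts.min()} < k={k} members; "
            "using unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X)
    true_pool: list[str] = []
    pred_pool: list[str] = []
    for train_idx, test_idx in split:
        tree = learn_tree(X[train_idx], y[train_idx], features,
                          max_depth=max_depth, min_leaf=min_leaf)
        preds = tree.predict(X[test_idx])
        true_pool.extend(y[test_idx])
        pred_pool.extend(p.value for p in preds)
    cm = confusion_matrix(true_pool, pred_pool)
    return cm.accuracy, cm


# ---------------------------------------------------------------------------
# tree (de)serialisation
# ---------------------------------------------------------------------------

def tree_to_json(model: DecisionTreeModel, path: Optional[Union[str, Path]] = None) -> str:
    def encode(node: TreeNode):
        if node.is_leaf():
            return {"label": node.label.value}
        return {"feature": node.feature, "threshold": node.threshold,
                "left": encode(node.left), "right": encode(node.right)}

    payload = json.dumps({"features": list(model.features),
                          "provenance": model.provenance,
                          "root": encode(model.root)}, indent=2)
    if path is not None:
        Path(path).write_text(payload)
    return payload


def tree_from_json(source: Union[str, Path]) -> DecisionTreeModel:
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    data = json.loads(text)

    def decode(obj) -> TreeNode:
        if "label" in obj:
            return TreeNode(label=GskClass(obj["label"]))
        return TreeNode(feature=obj["feature"], threshold=obj["threshold"],
                        left=decode(obj["left"]), right=decode(obj["right"]))

    return DecisionTreeModel(features=tuple(data["features"]), root=decode(data["root"]),
                             provenance=data.get("provenance", "refit"))


# ---------------------------------------------------------------------------
# chemical-space export
# ---------------------------------------------------------------------------

def chemical_space_export(dataset: Dataset, axes: Sequence[str] = ("log_kw_iam", "brlogd", "tpsa")):
    """Long-format plot-ready table (id, x, y, z, gsk_class, censored).

    Compounds missing any requested axis are dropped with a warning. The
    default axes span the lipophilicity/polarity space; ("nc", "phi",
    "tpsa") gives the 2D chemical-space view.
    """
    import pandas as pd

    if len(axes) != 3:
        raise DomainError(f"need exactly three axes, got {len(axes)}")
    rows = []
    for comp in dataset.compounds:
        prof = dataset.descriptors.get(comp.id)
        values = [getattr(prof, ax, None) if prof else None for ax in axes]
        if any(v is None for v in values):
            warnings.warn(f"{comp.id}: missing axis value, row dropped")
            continue
        sol = dataset.solubility.get(comp.id)
        rows.append({
            "id": comp.id,
            axes[0]: values[0], axes[1]: values[1], axes[2]: values[2],
            "gsk_class": sol.gsk_class.value if sol and sol.gsk_class else None,
            "censored": bool(sol.censored) if sol else None,
        })
    return pd.DataFrame(rows, columns=["id", *axes, "gsk_class", "censored"])


# ---------------------------------------------------------------------------
# building-block pair comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogS:
    """A log S value that may be an interval bound rather than a point.

    ``censor`` is "none" for a quantified value, "above" when only a lower
    bound is known (compound more soluble than the assay ceiling) and
    "below" for sub-LOQ measurements.
    """

    value: Optional[float]
    censor: str = "none"  # none | above | below

    def compare(self, other: "LogS") -> Optional[int]:
        """-1/0/+1 ordering, or None when the censoring leaves it open."""
        if self.value is None or other.value is None:
            return None
        lo_a, hi_a = self._interval()
        lo_b, hi_b = other._interval()
        if lo_a > hi_b:
            return 1
        if hi_a < lo_b:
            return -1
        if self.censor == "none" and other.censor == "none":
            return (self.value > other.value) - (self.value < other.value)
        return None

    def _interval(self) -> tuple[float, float]:
        if self.censor == "above":
            return (self.value, math.inf)
        if self.censor == "below":
            return (-math.inf, self.value)
        return (self.value, self.value)


@dataclass
class PairReport:
    protac_a: str
    protac_b: str
    varied: Moiety
    delta_log_s: Optional[float]          # PROTAC A - B, None if censored
    block_a: Optional[str] = None
    block_b: Optional[str] = None
    block_deltas: dict[str, float] = field(default_factory=dict)
    concordance: str = "indeterminate"    # concordant | discordant | indeterminate


def compare_pair(
    protac_a: tuple[str, LogS],
    protac_b: tuple[str, LogS],
    varied: Moiety,
    block_a: Optional[tuple[str, LogS]] = None,
    block_b: Optional[tuple[str, LogS]] = None,
    block_properties: Optional[dict[str, tuple[Optional[float], Optional[float]]]] = None,
) -> PairReport:
    """Compare a PROTAC pair differing in one moiety with the swapped blocks.

    Concordant iff the building-block log S ordering matches the PROTAC
    log S ordering; indeterminate when a value is censored/missing or the
    orderings involve a tie. ``block_properties`` maps descriptor names to
    (value_A, value_B) pairs; available deltas (A - B) are reported.
    """
    id_a, s_a = protac_a
    id_b, s_b = protac_b
    delta = None
    if s_a.censor == "none" and s_b.censor == "none" and s_a.value is not None and s_b.value is not None:
        delta = s_a.value - s_b.value
    report = PairReport(protac_a=id_a, protac_b=id_b, varied=Moiety(varied), delta_log_s=delta)
    if block_a:
        report.block_a = block_a[0]
    if block_b:
        report.block_b = block_b[0]
    for name, (va, vb) in (block_properties or {}).items():
        if va is not None and vb is not None:
            report.block_deltas[name] = va - vb
    protac_order = s_a.compare(s_b)
    block_order = block_a[1].compare(block_b[1]) if block_a and block_b else None
    if protac_order in (None, 0) or block_order in (None, 0):
        report.concordance = "indeterminate"
    elif protac_order == block_order:
        report.concordance = "concordant"
    else:
        report.concordance = "discordant"
    return report
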