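"""Same-genus classification from (ANI, AF) pairs.

A logistic regression maps ANI (or AAI) and AF of a genome pair to the
probability that the two genomes share a genus.  Splitting is done at
the genus level (65/35 by default) so no genus leaks between train and
test, and cross-validation folds group all pairs sharing a genus-pair
key.  Evaluation uses precision-recall metrics, which ignore the large
mass of true-negative pairs: PR-AUC with a percentile bootstrap CI, and
precision / recall / F1 / FDR at chosen thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "LabeledPair",
    "LogisticModel",
    "PRReport",
    "load_genus_labels",
    "build_labeled_pairs",
    "genus_split",
    "grouped_cv_folds",
    "fit_logistic",
    "pr_evaluate",
    "threshold_scan",
    "simulate_labeled_pairs",
]


@dataclass(frozen=True)
class LabeledPair:
    """One genome pair with predictors and the same-genus outcome."""

    id_a: str
    id_b: str
    ani: float
    af: float
    genus_a: str
    genus_b: str

    @property
    def same_genus(self) -> bool:
        return self.genus_a == self.genus_b

    @property
    def genus_pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.genus_a, self.genus_b)))


def load_genus_labels(path: str | Path) -> dict[str, str]:
    """Read a TSV of (genome_id, genus[, ...]) into a mapping."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gid = cols.get("genome_id", df.columns[0])
    genus = cols.get("genus", df.columns[1])
    return dict(zip(df[gid].astype(str), df[genus].astype(str)))


def build_labeled_pairs(
    relatedness: pd.DataFrame,
    labels: dict[str, str],
    ani_col: str = "ani",
    af_col: str = "af_mean",
) -> list[LabeledPair]:
    """Join a relatedness table with genus labels.

    Pairs whose genomes both carry a label are kept; same-genus pairs that
    never aligned should be present with ani=af=0 upstream so that recall
    can penalize them.
    """
    pairs = []
    for row in relatedness.itertuples(index=False):
        ga = labels.get(str(row.id_a))
        gb = labels.get(str(row.id_b))
        if ga is None or gb is None:
            continue
        pairs.append(
            LabeledPair(
                id_a=str(row.id_a),
                id_b=str(row.id_b),
                ani=float(getattr(row, ani_col)),
                af=float(getattr(row, af_col)),
                genus_a=ga,
                genus_b=gb,
            )
        )
    return pairs


def genus_split(
    genera: Sequence[str],
    train_frac: float = 0.65,
    seed: int = 0,
    pairs: Sequence[LabeledPair] | None = None,
    pair_frac_window: tuple[float, float] = (0.60, 0.70),
    max_attempts: int = 1000,
) -> tuple[set[str], set[str]]:
    """Split genera (not pairs) into train and test sets.

    When ``pairs`` is supplied, seeds are tried until the *pair-level*
    train fraction also falls inside ``pair_frac_window`` (the split is
    made at genus level, so pair counts can deviate from 65/35 by chance);
    gives up after ``max_attempts`` and keeps the last split.
    """
    unique = sorted(set(genera))
    n_train = int(round(train_frac * len(unique)))
    rng_seed = seed
    train: set[str] = set()
    test: set[str] = set()
    for _ in range(max_attempts):
        rng = np.random.default_rng(rng_seed)
        perm = rng.permutation(len(unique))
        train = {unique[i] for i in perm[:n_train]}
        test = {unique[i] for i in perm[n_train:]}
        if pairs is None:
            return train, test
        n_tr = sum(1 for p in pairs if p.genus_a in train and p.genus_b in train)
        n_te = sum(1 for p in pairs if p.genus_a in test and p.genus_b in test)
        total = n_tr + n_te
        if total and pair_frac_window[0] <= n_tr / total <= pair_frac_window[1]:
            return train, test
        rng_seed += 1
    return train, test


def assign_side(
    pairs: Iterable[LabeledPair], train: set[str], test: set[str]
) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Pairs whose genera both fall on one side; cross-side pairs dropped."""
    tr, te = [], []
    for p in pairs:
        if p.genus_a in train and p.genus_b in train:
            tr.append(p)
        elif p.genus_a in test and p.genus_b in test:
            te.append(p)
    return tr, te


def grouped_cv_folds(
    pairs: Sequence[LabeledPair], k: int = 10, seed: int = 0
) -> np.ndarray:
    """Fold index per pair; all pairs of one genus-pair key share a fold.

    Greedy balancing: keys are processed from largest to smallest and each
    goes to the currently lightest fold (ties broken by fold index after a
    seeded shuffle of equally-sized keys).
    """
    keys: dict[tuple[str, str], list[int]] = {}
    for i, p in enumerate(pairs):
        keys.setdefault(p.genus_pair_key, []).append(i)
    rng = np.random.default_rng(seed)
    items = list(keys.items())
    rng.shuffle(items)
    items.sort(key=lambda kv: -len(kv[1]))
    loads = np.zeros(k, dtype=np.int64)
    folds = np.empty(len(pairs), dtype=np.int64)
    for key, idx in items:
        f = int(np.argmin(loads))
        loads[f] += len(idx)
        folds[idx] = f
    return folds


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic regression over a subset of {ani, af}."""

    intercept: float
    coefficients: dict[str, float]

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)

    def predict_proba(self, pairs: Sequence[LabeledPair]) -> np.ndarray:
        x = _design(pairs, self.predictors)
        beta = np.array([self.coefficients[p] for p in self.predictors])
        z = self.intercept + x @ beta
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}


def _design(pairs: Sequence[LabeledPair], predictors: Sequence[str]) -> np.ndarray:
    return np.column_stack([[getattr(p, name) for p in pairs] for name in predictors])


def fit_logistic(
    pairs: Sequence[LabeledPair], predictors: Sequence[str] = ("ani", "af")
) -> LogisticModel:
    """Maximum-likelihood logistic fit (unpenalized, lbfgs)."""
    if not pairs:
        raise ValueError("no pairs to fit")
    y = np.array([p.same_genus for p in pairs], dtype=int)
    if y.min() == y.max():
        raise ValueError("outcome is constant; cannot fit")
    x = _design(pairs, predictors)
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000)
    clf.fit(x, y)
    coefs = dict(zip(predictors, (float(c) for c in clf.coef_[0])))
    return LogisticModel(intercept=float(clf.intercept_[0]), coefficients=coefs)


def _pr_curve(y: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Precision-recall points over the score sweep, sorted by recall."""
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    n_pos = int(y.sum())
    # keep one point per distinct threshold (last index of each score run)
    distinct = np.nonzero(np.diff(scores[order], append=-np.inf))[0]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([1.0], precision))
    return r, p


def pr_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoid area under the PR curve over the recall axis."""
    r, p = _pr_curve(np.asarray(y, dtype=int), np.asarray(scores, dtype=float))
    return float(np.trapezoid(p, r))


@dataclass(frozen=True)
class PRReport:
    """Precision-recall evaluation of one model on one pair set."""

    curve: list[tuple[float, float]]  # (recall, precision)
    auc: float
    ci95: tuple[float, float]
    n_boot: int
    precision: float
    recall: float
    f1: float
    fdr: float
    threshold: float
    best_f1_threshold: float


def point_metrics(y: np.ndarray, scores: np.ndarray, threshold: float) -> dict:
    pred = scores >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "fdr": 1.0 - precision}


def pr_evaluate(
    model: LogisticModel,
    pairs: Sequence[LabeledPair],
    n_boot: int = 100,
    seed: int = 0,
    threshold: float | None = None,
) -> PRReport:
    """PR curve, PR-AUC with bootstrap CI, and threshold metrics.

    The CI resamples predictions and labels jointly with replacement.
    ``threshold`` defaults to the F1-optimal probability found by the
    sweep.
    """
    y = np.array([p.same_genus for p in pairs], dtype=int)
    scores = model.predict_proba(pairs)
    r, p = _pr_curve(y, scores)
    auc = float(np.trapezoid(p, r))

    # F1-optimal probability threshold over the sweep of distinct scores
    best_f1 = -1.0
    best_thr = 0.5
    for thr in np.unique(scores):
        m = point_metrics(y, scores, float(thr))
        if m["f1"] > best_f1:
            best_f1 = m["f1"]
            best_thr = float(thr)
    thr = best_thr if threshold is None else threshold
    metrics = point_metrics(y, scores, thr)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while y[idx].sum() == 0:
            idx = rng.integers(0, n, size=n)
        boot[b] = pr_auc(y[idx], scores[idx])
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

    return PRReport(
        curve=list(zip(r.tolist(), p.tolist())),
        auc=auc,
        ci95=ci,
        n_boot=n_boot,
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        fdr=metrics["fdr"],
        threshold=thr,
        best_f1_threshold=best_thr,
    )


def threshold_scan(
    pairs: Sequence[LabeledPair],
    ani_grid: Sequence[float],
    af_grid: Sequence[float],
) -> pd.DataFrame:
    """F1 of the joint rule (ani >= a AND af >= b) over a grid.

    Degenerate grid points predicting no positives report precision and
    recall of 0 with ``no_positive_predictions`` flagged.
    """
    ani = np.array([p.ani for p in pairs])
    af = np.array([p.af for p in pairs])
    y = np.array([p.same_genus for p in pairs], dtype=int)
    n_pos = int(y.sum())
    rows = []
    for a in ani_grid:
        sel_a = ani >= a
        for b in af_grid:
            pred = sel_a & (af >= b)
            tp = int((pred & (y == 1)).sum())
            n_pred = int(pred.sum())
            degenerate = n_pred == 0
            precision = tp / n_pred if n_pred else 0.0
            recall = tp / n_pos if n_pos else 0.0
            f1 = (
                2 * precision * recall / (precision + recall)
                if precision + recall
                else 0.0
            )
            rows.append(
                {
                    "ani_thr": float(a),
                    "af_thr": float(b),
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                    "no_positive_predictions": degenerate,
                }
            )
    return pd.DataFrame(rows)


def simulate_labeled_pairs(
    n: int,
    beta0: float = -10.0,
    beta_ani: float = 8.0,
    beta_af: float = 6.0,
    n_genera: int = 40,
    seed: int = 0,
) -> list[LabeledPair]:
    """Synthetic labeled pairs from a known logistic generating model.

    ANI and AF are drawn uniformly on [0, 1]; the same-genus flag is
    Bernoulli with logit ``beta0 + beta_ani*ani + beta_af*af``.  Genus
    labels are attached so that the label of each pair is consistent with
    the sampled outcome (same-genus pairs share a genus).  Intended for
    parameter-recovery and calibration tests of the classifier stack.
    """
    rng = np.random.default_rng(seed)
    ani = rng.uniform(0, 1, size=n)
    af = rng.uniform(0, 1, size=n)
    z = beta0 + beta_ani * ani + beta_af * af
    y = rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-z))
    pairs = []
    for i in range(n):
        if y[i]:
            g = f"genus{rng.integers(n_genera)}"
            ga = gb = g
        else:
            ga, gb = rng.choice(n_genera, size=2, replace=False)
            ga, gb = f"genus{ga}", f"genus{gb}"
        pairs.append(
            LabeledPair(
                id_a=f"v{2 * i}",
                id_b=f"v{2 * i + 1}",
                ani=float(ani[i]),
                af=float(af[i]),
                genus_a=ga,
                genus_b=gb,
            )
        )
    return pairs
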