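"""Partition network nodes into hub (H), intermediate (I) and peripheral (P).

The partition is seeded from metric percentiles — the top 1% of
betweenness seeds H, the top 10% of neighborhood connectivity seeds I,
and the top 10% of average shortest path length seeds P — then the
minority classes are balanced with SMOTE-style interpolation and a
radial-basis-function support-vector machine, trained on the balanced
seed set, labels every remaining node.  Predictions whose calibrated
class probability falls below a decision-support threshold are
declassified as ``uncertain``.

Hubs are the rarest class in scale-free PPI networks, hence the 1% cut
for BC and the H > I > P priority when a node clears several percentile
cuts at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "TrainingSet",
    "CVReport",
    "seed_labels",
    "oversample_minority",
    "cross_validate",
    "summarize_cv",
    "classify_nodes",
    "classify_network",
]

FEATURES = ("aspl", "bc", "nc")
CLASSES = ("H", "I", "P")


@dataclass
class TrainingSet:
    """Balanced, standardized training table for the node classifier.

    ``features`` are (aspl, bc, nc) standardized to zero mean / unit
    variance on the *seed* rows only; the same transform (``center``,
    ``scale``) is applied to unlabeled nodes at prediction time so no
    information leaks from them.
    """

    features: pd.DataFrame           # standardized; synthetic rows included
    labels: pd.Series                # aligned with features
    synthetic: pd.Series             # bool, True for SMOTE-interpolated rows
    center: pd.Series                # per-feature mean of seed rows
    scale: pd.Series                 # per-feature SD of seed rows
    seed_nodes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    # seed_nodes: node id -> seed label, for the real (non-synthetic) rows

    def transform(self, metrics: pd.DataFrame) -> pd.DataFrame:
        """Apply the seed-fitted standardization to a raw metrics table."""
        return (metrics[list(FEATURES)] - self.center) / self.scale


@dataclass
class CVReport:
    replicate: int
    fold_accuracies: list[float]
    precision: dict[str, float]
    recall: dict[str, float]
    stratified: bool

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def seed_labels(
    metrics: pd.DataFrame,
    pct_bc: float = 0.01,
    pct_nc: float = 0.10,
    pct_aspl: float = 0.10,
) -> pd.Series:
    """Percentile-seed preclassified nodes.

    Top ``pct_bc`` of BC -> H, top ``pct_nc`` of NC -> I, top
    ``pct_aspl`` of ASPL -> P.  A node clearing several cuts gets the
    highest-priority label (H > I > P).  Returns a Series mapping seeded
    node ids to labels; counts and conflicts are logged.
    """
    n = len(metrics)
    cuts = [("H", "bc", pct_bc), ("I", "nc", pct_nc), ("P", "aspl", pct_aspl)]
    chosen: dict[str, list[str]] = {}
    for label, col, pct in cuts:
        k = int(np.ceil(pct * n))
        if k < 1:
            raise ValueError(f"percentile cut for class {label} selects no nodes")
        if metrics[col].nunique() < 2:
            raise ValueError(
                f"metric {col!r} is constant; the top-{pct:.0%} quantile is degenerate")
        order = metrics[col].sort_values(ascending=False, kind="mergesort")
        # deterministic tie-break: value desc, then node id asc (mergesort stable
        # on the id-sorted frame)
        chosen[label] = list(order.index[:k])

    out: dict[str, str] = {}
    conflicts = 0
    for label in ("P", "I", "H"):  # later assignment wins => H highest priority
        for node in chosen[label]:
            if node in out:
                conflicts += 1
            out[node] = label
    seeds = pd.Series(out, name="seed_label")
    counts = seeds.value_counts().to_dict()
    if any(counts.get(c, 0) == 0 for c in CLASSES):
        raise ValueError(f"a seed class is empty after conflict resolution: {counts}")
    logger.info("seeds: %s (%d percentile conflicts resolved H>I>P)", counts, conflicts)
    return seeds


def oversample_minority(
    seeds: pd.Series,
    metrics: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
) -> TrainingSet:
    """Balance seed classes by SMOTE interpolation in standardized feature space.

    Each synthetic point is ``x + u * (x' - x)`` with ``u ~ U(0, 1)``,
    where ``x'`` is one of the ``k_neighbors`` nearest same-class seeds
    of ``x`` — a convex combination of two real same-class rows.  Every
    class is raised to the majority-class count.  Deterministic under
    ``seed``.
    """
    raw = metrics.loc[seeds.index, list(FEATURES)].astype(float)
    center = raw.mean()
    scale = raw.std(ddof=0).replace(0.0, 1.0)
    x = (raw - center) / scale

    counts = seeds.value_counts()
    target = int(counts.max())
    for label, c in counts.items():
        if c < k_neighbors + 1:
            raise ValueError(
                f"class {label} has {c} seeds, fewer than k_neighbors+1="
                f"{k_neighbors + 1}; use a smaller k_neighbors")

    rng = np.random.default_rng(seed)
    frames = [x]
    labels = [seeds.astype(str)]
    flags = [pd.Series(False, index=x.index)]
    for label in sorted(counts.index):
        need = target - int(counts[label])
        if need == 0:
            continue
        members = x.loc[seeds[seeds == label].index].to_numpy()
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(members)
        _, idx = nn.kneighbors(members)
        base = rng.integers(0, len(members), size=need)
        pick = rng.integers(1, k_neighbors + 1, size=need)  # skip self at col 0
        u = rng.random(need)
        neigh = members[idx[base, pick]]
        synth = members[base] + u[:, None] * (neigh - members[base])
        sidx = pd.Index([f"_smote_{label}_{i}" for i in range(need)])
        frames.append(pd.DataFrame(synth, columns=list(FEATURES), index=sidx))
        labels.append(pd.Series(label, index=sidx))
        flags.append(pd.Series(True, index=sidx))
        logger.info("SMOTE: +%d synthetic %s rows", need, label)

    return TrainingSet(
        features=pd.concat(frames),
        labels=pd.concat(labels).rename("label"),
        synthetic=pd.concat(flags).rename("synthetic"),
        center=center,
        scale=scale,
        seed_nodes=seeds.astype(str),
    )


def _make_svm(seed: int | None = None) -> SVC:
    # C=1, RBF kernel, gamma="scale" = 1/(n_features * Var(X)); pinned for
    # reproducibility since only "support vector machine" is prescribed.
    return SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)


def _make_calibrated_svm(labels: np.ndarray, seed: int | None = None):
    # Platt-sigmoid calibration, cross-fitted; cv capped by the smallest class
    cv = int(min(5, pd.Series(labels).value_counts().min()))
    return CalibratedClassifierCV(_make_svm(seed=seed), method="sigmoid",
                                  cv=max(2, cv), ensemble=False)


def cross_validate(
    training: TrainingSet,
    folds: int = 9,
    replicates: int = 1000,
    stratified: bool = False,
    seed: int = 0,
) -> list[CVReport]:
    """Replicated k-fold cross-validation of the SVM on the training table.

    Each replicate reshuffles the fold partition (seeded).  Runs either
    plain or stratified folds; running both and comparing checks that
    residual class imbalance does not drive the accuracy.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = training.features.to_numpy()
    y = training.labels.to_numpy()
    if stratified:
        smallest = pd.Series(y).value_counts().min()
        if smallest < folds:
            raise ValueError(
                f"smallest class ({smallest}) below fold count {folds} "
                "under stratification")
    reports = []
    for rep in range(replicates):
        rs = (seed + 9973 * rep) % (2**31)
        splitter = (StratifiedKFold if stratified else KFold)(
            n_splits=folds, shuffle=True, random_state=rs)
        accs = []
        pred = np.empty_like(y)
        for tr, te in splitter.split(x, y):
            clf = _make_svm()
            clf.fit(x[tr], y[tr])
            p = clf.predict(x[te])
            pred[te] = p
            accs.append(float(np.mean(p == y[te])))
        prec, rec, _, _ = precision_recall_fscore_support(
            y, pred, labels=list(CLASSES), zero_division=0)
        reports.append(CVReport(
            replicate=rep,
            fold_accuracies=accs,
            precision=dict(zip(CLASSES, prec.tolist())),
            recall=dict(zip(CLASSES, rec.tolist())),
            stratified=stratified,
        ))
    return reports


def summarize_cv(reports: list[CVReport]) -> dict[str, float]:
    accs = [r.accuracy for r in reports]
    return {
        "replicates": len(reports),
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
    }


def classify_nodes(
    training: TrainingSet,
    metrics: pd.DataFrame,
    support_threshold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Label every network node as H, I, P or uncertain.

    The SVM (one-vs-one, Platt-calibrated probabilities) is trained on
    the full balanced training set; every non-seed node receives the
    most probable class with ``support`` equal to that probability.
    Predictions with ``support < support_threshold`` are declassified as
    ``uncertain``; the pre-filter label is kept in ``raw_label`` for
    audit.  Seed nodes keep their seed label with ``source="seed"``.

    Returns a DataFrame indexed by node with columns ``label``,
    ``support``, ``source``, ``raw_label``.
    """
    y = training.labels.to_numpy()
    clf = _make_calibrated_svm(y, seed=seed)
    clf.fit(training.features.to_numpy(), y)

    out = pd.DataFrame(index=metrics.index.copy(),
                       columns=["label", "support", "source", "raw_label"])
    seed_ix = training.seed_nodes.index.intersection(out.index)
    out.loc[seed_ix, "label"] = training.seed_nodes.loc[seed_ix]
    out.loc[seed_ix, "raw_label"] = training.seed_nodes.loc[seed_ix]
    out.loc[seed_ix, "source"] = "seed"

    rest = out.index.difference(seed_ix)
    if len(rest):
        z = training.transform(metrics.loc[rest]).to_numpy()
        proba = clf.predict_proba(z)
        best = proba.argmax(axis=1)
        label = np.asarray(clf.classes_)[best]
        support = proba[np.arange(len(rest)), best]
        out.loc[rest, "raw_label"] = label
        out.loc[rest, "support"] = support
        out.loc[rest, "source"] = "predicted"
        out.loc[rest, "label"] = np.where(
            support < support_threshold, "uncertain", label)
    counts = out["label"].value_counts().to_dict()
    logger.info("classification: %s (support threshold %.2f)", counts,
                support_threshold)
    return out


def classify_network(
    metrics: pd.DataFrame,
    pct_bc: float = 0.01,
    pct_nc: float = 0.10,
    pct_aspl: float = 0.10,
    k_neighbors: int = 5,
    support_threshold: float = 0.5,
    seed: int = 0,
    adapt_k: bool = True,
) -> tuple[pd.DataFrame, TrainingSet]:
    """Seed, oversample and classify in one call.

    With ``adapt_k`` (default) the SMOTE neighbor count is reduced to
    ``smallest seed class - 1`` when the 1% hub cut yields fewer than
    ``k_neighbors + 1`` seeds — unavoidable on small networks — and the
    adjustment is logged.
    """
    seeds = seed_labels(metrics, pct_bc=pct_bc, pct_nc=pct_nc, pct_aspl=pct_aspl)
    smallest = int(seeds.value_counts().min())
    k = k_neighbors
    if adapt_k and smallest - 1 < k:
        k = max(1, smallest - 1)
        logger.info("k_neighbors reduced %d -> %d (smallest seed class has %d members)",
                    k_neighbors, k, smallest)
    training = oversample_minority(seeds, metrics, k_neighbors=k, seed=seed)
    table = classify_nodes(training, metrics,
                           support_threshold=support_threshold, seed=seed)
    return table, training
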