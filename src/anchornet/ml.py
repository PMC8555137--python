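"""Machine-learning refinement layer: features, training, evaluation.

For each training pathway, the base reconstruction engine is run three
times (alpha = 0, 0.25, 0.5) and the per-node ensemble confidences from the
three runs form the first three features of every candidate node.  Two
network propagations — seeded from the pathway's anchors and terminals —
contribute two proximity features.  Nodes are labeled 1 when they belong to
the true pathway; true nodes the base runs never output are appended as
all-zero feature vectors with label 1 so the classifier sees the recall
failure mode.  Columns are z-scored (mean 0, variance 1) and a 100-tree
random forest is fit on the standardized matrix.  Evaluation uses
stratified five-fold cross-validation with ROC and precision-recall AUCs;
the ensemble margin is tuned over a grid by re-running the whole pipeline
per margin.  At inference time the same five features are generated for a
query, standardized with the stored training statistics and scored by the
stored forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ModelError, QueryError
from .network_io import InteractionNetwork
from .propagation import PropagationConfig, proximity_features
from .reconstruct import QueryInstance, enumerate_ensemble

logger = logging.getLogger(__name__)

ALPHA_GRID = (0.0, 0.25, 0.5)
MARGIN_GRID = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)

FEATURE_COLUMNS = ("f_a0", "f_a25", "f_a50", "prop_anchor", "prop_terminal")
FEATURE_SETS = {
    "all5": FEATURE_COLUMNS,
    "conf3": FEATURE_COLUMNS[:3],
    "prop2": FEATURE_COLUMNS[3:],
}
N_TREES = 100


@dataclass(frozen=True, eq=False)
class FeatureTable:
    """Per (pathway, node) feature rows plus normalization bookkeeping."""

    frame: pd.DataFrame
    margin: float
    normalization: dict[str, tuple[float, float]] | None = None
    constant_columns: frozenset[str] = frozenset()
    skipped_pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = {"pathway", "node", *FEATURE_COLUMNS, "label"}
        missing = expected - set(self.frame.columns)
        if missing:
            raise ModelError(f"feature table lacks columns {sorted(missing)}")


@dataclass(frozen=True, eq=False)
class TrainedModel:
    """Random forest plus the normalization statistics it was fit under."""

    classifier: RandomForestClassifier
    normalization: dict[str, tuple[float, float]]
    margin: float
    feature_set: str

    @property
    def columns(self) -> Sequence[str]:
        return FEATURE_SETS[self.feature_set]

    def predict_proba(self, raw: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class for raw (unstandardized) rows."""
        z = apply_normalization(raw, self.normalization)
        return self.classifier.predict_proba(
            z[list(self.columns)].to_numpy())[:, 1]


@dataclass(frozen=True, eq=False)
class EvalEntry:
    margin: float
    feature_set: str
    auroc: float
    auprc: float
    folds: int


@dataclass(frozen=True, eq=False)
class EvalReport:
    entries: tuple[EvalEntry, ...]

    def for_margin(self, margin: float) -> list[EvalEntry]:
        return [e for e in self.entries if e.margin == margin]

    def entry(self, margin: float, feature_set: str) -> EvalEntry:
        for e in self.entries:
            if e.margin == margin and e.feature_set == feature_set:
                return e
        raise KeyError((margin, feature_set))

    def to_records(self) -> list[dict]:
        return [vars(e) for e in self.entries]


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def _pathway_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def query_features(net: InteractionNetwork, anchors, terminals, margin: float,
                   seed: int, *, alphas: Sequence[float] = ALPHA_GRID,
                   n_samples: int = 20,
                   prop_cfg: PropagationConfig = PropagationConfig(),
                   extra_candidates: Iterable[str] = ()) -> pd.DataFrame:
    """The 5-feature matrix for one anchors/terminals query.

    Candidate nodes are the union of the margin ensembles at each alpha
    (plus the anchors, terminals and any `extra_candidates`); confidence is
    0 for ensembles a node is absent from.
    """
    conf_by_alpha = []
    sub_seeds = _pathway_seeds(seed, len(alphas))
    for a, s in zip(alphas, sub_seeds):
        q = QueryInstance(net, anchors, terminals, alpha=a, margin=margin)
        ens = enumerate_ensemble(q, n_samples=n_samples, seed=int(s))
        conf_by_alpha.append(ens.node_confidence)
    candidates = set(anchors) | set(terminals) | set(extra_candidates)
    for conf in conf_by_alpha:
        candidates.update(conf)
    prox = proximity_features(net, anchors, terminals, prop_cfg)
    rows = []
    for node in sorted(candidates):
        rows.append({
            "node": node,
            "f_a0": conf_by_alpha[0].get(node, 0.0),
            "f_a25": conf_by_alpha[1].get(node, 0.0),
            "f_a50": conf_by_alpha[2].get(node, 0.0),
            "prop_anchor": prox[node][0],
            "prop_terminal": prox[node][1],
        })
    return pd.DataFrame(rows,
                        columns=["node", *FEATURE_COLUMNS])


def build_feature_table(pathways, net: InteractionNetwork, margin: float,
                        seed: int, *, alphas: Sequence[float] = ALPHA_GRID,
                        n_samples: int = 20,
                        prop_cfg: PropagationConfig = PropagationConfig()
                        ) -> FeatureTable:
    """Training table over a pathway corpus at one ensemble margin.

    `pathways` are objects exposing name, anchors, terminals and
    truth_nodes (e.g. :class:`anchornet.benchmark.PlantedPathway`).
    Pathways whose terminals are unreachable are skipped with a warning and
    recorded in the table's provenance.  True-pathway nodes missed by every
    base run are appended as all-zero rows with label 1.
    """
    pathways = list(pathways)
    frames = []
    skipped = []
    pw_seeds = _pathway_seeds(seed, len(pathways))
    for pw, pw_seed in zip(pathways, pw_seeds):
        try:
            feats = query_features(net, pw.anchors, pw.terminals, margin,
                                   int(pw_seed), alphas=alphas,
                                   n_samples=n_samples, prop_cfg=prop_cfg)
        except QueryError as exc:
            logger.warning("skipping pathway %s: %s", pw.name, exc)
            skipped.append(pw.name)
            continue
        feats.insert(0, "pathway", pw.name)
        feats["label"] = feats["node"].isin(pw.truth_nodes).astype(int)
        missed = sorted(set(pw.truth_nodes) - set(feats["node"]))
        if missed:
            zero_rows = pd.DataFrame({
                "pathway": pw.name,
                "node": missed,
                **{c: 0.0 for c in FEATURE_COLUMNS},
                "label": 1,
            })
            feats = pd.concat([feats, zero_rows], ignore_index=True)
        frames.append(feats)
    if not frames:
        raise ModelError("no usable pathway produced any feature rows")
    frame = pd.concat(frames, ignore_index=True)
    return FeatureTable(frame=frame, margin=margin,
                        skipped_pathways=tuple(skipped))


def normalize(table: FeatureTable) -> FeatureTable:
    """Z-score each feature column (population sd) and store the stats.

    Constant columns (sd = 0) are mapped to all zeros and flagged.  Raises
    on tables with fewer than two rows.
    """
    if len(table.frame) < 2:
        raise ModelError("cannot normalize a table with fewer than 2 rows")
    stats: dict[str, tuple[float, float]] = {}
    constant = set()
    frame = table.frame.copy()
    for col in FEATURE_COLUMNS:
        x = frame[col].to_numpy(dtype=float)
        mean, sd = float(x.mean()), float(x.std(ddof=0))
        stats[col] = (mean, sd)
        if sd == 0.0:
            constant.add(col)
            frame[col] = 0.0
        else:
            frame[col] = (x - mean) / sd
    return replace(table, frame=frame, normalization=stats,
                   constant_columns=frozenset(constant))


def apply_normalization(raw: pd.DataFrame,
                        stats: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Standardize raw feature rows with previously stored (mean, sd)."""
    missing = set(stats) - set(raw.columns)
    if missing:
        raise ModelError(f"feature columns missing from input: {sorted(missing)}")
    out = raw.copy()
    for col, (mean, sd) in stats.items():
        x = out[col].to_numpy(dtype=float)
        out[col] = np.zeros_like(x) if sd == 0.0 else (x - mean) / sd
    return out


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ModelError("training data contains a single class")


def train(table: FeatureTable, feature_set: str = "all5",
          seed: int = 0) -> TrainedModel:
    """Fit the random forest on a normalized table."""
    if table.normalization is None:
        raise ModelError("table must be normalized before training")
    if feature_set not in FEATURE_SETS:
        raise ModelError(f"unknown feature set {feature_set!r}")
    y = table.frame["label"].to_numpy(dtype=int)
    _check_two_classes(y)
    x = table.frame[list(FEATURE_SETS[feature_set])].to_numpy(dtype=float)
    clf = RandomForestClassifier(n_estimators=N_TREES, random_state=seed,
                                 n_jobs=1)
    clf.fit(x, y)
    return TrainedModel(classifier=clf, normalization=table.normalization,
                        margin=table.margin, feature_set=feature_set)


def auroc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by exhaustive positive-negative pair comparison.

    Mann-Whitney convention: a tie contributes 0.5 per pair.  Quadratic in
    the number of rows; intended as an oracle for small tables.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ModelError("both classes required for AUROC")
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))


def cross_validate(table: FeatureTable, feature_set: str = "all5",
                   k: int = 5, seed: int = 0) -> EvalEntry:
    """Stratified k-fold CV; out-of-fold probabilities are pooled before
    computing AUROC (rank statistic) and AUPRC (step-interpolated)."""
    if table.normalization is None:
        raise ModelError("table must be normalized before cross-validation")
    if k < 2:
        raise ModelError("k must be >= 2")
    y = table.frame["label"].to_numpy(dtype=int)
    _check_two_classes(y)
    x = table.frame[list(FEATURE_SETS[feature_set])].to_numpy(dtype=float)
    folds = None
    for attempt in range(20):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + attempt)
        cand = list(skf.split(x, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in cand):
            folds = cand
            break
    if folds is None:
        raise ModelError("could not draw folds with both classes present")
    oof = np.empty(len(y))
    for tr, te in folds:
        clf = RandomForestClassifier(n_estimators=N_TREES, random_state=seed,
                                     n_jobs=1)
        clf.fit(x[tr], y[tr])
        oof[te] = clf.predict_proba(x[te])[:, 1]
    return EvalEntry(margin=table.margin, feature_set=feature_set,
                     auroc=float(roc_auc_score(y, oof)),
                     auprc=float(average_precision_score(y, oof)), folds=k)


def evaluate_baseline(table: FeatureTable) -> EvalEntry:
    """Single-run baseline: the alpha = 0.25 ensemble confidence used
    directly as the ranking score, no classifier."""
    y = table.frame["label"].to_numpy(dtype=int)
    _check_two_classes(y)
    scores = table.frame["f_a25"].to_numpy(dtype=float)
    return EvalEntry(margin=table.margin, feature_set="baseline",
                     auroc=float(roc_auc_score(y, scores)),
                     auprc=float(average_precision_score(y, scores)), folds=0)


def tune_margin(pathways, net: InteractionNetwork,
                margins: Sequence[float] = MARGIN_GRID, seed: int = 0, *,
                k: int = 5, alphas: Sequence[float] = ALPHA_GRID,
                n_samples: int = 20,
                prop_cfg: PropagationConfig = PropagationConfig()
                ) -> tuple[EvalReport, float, dict[float, FeatureTable]]:
    """Evaluate all feature sets (plus the baseline) across a margin grid.

    Returns the full report, the margin maximizing mean(AUROC, AUPRC) of
    the all-feature model (ties go to the smaller margin), and the
    normalized feature table per margin.
    """
    entries: list[EvalEntry] = []
    tables: dict[float, FeatureTable] = {}
    best_margin, best_score = None, -np.inf
    for margin in margins:
        table = normalize(build_feature_table(
            pathways, net, margin, seed, alphas=alphas,
            n_samples=n_samples, prop_cfg=prop_cfg))
        tables[margin] = table
        for fs in FEATURE_SETS:
            entries.append(cross_validate(table, fs, k=k, seed=seed))
        entries.append(evaluate_baseline(table))
        e = entries[-1 - len(FEATURE_SETS)]  # the all5 entry of this margin
        assert e.feature_set == "all5"
        score = 0.5 * (e.auroc + e.auprc)
        if score > best_score + 1e-12:
            best_score, best_margin = score, margin
    return EvalReport(tuple(entries)), float(best_margin), tables


def refine(q: QueryInstance, model: TrainedModel, threshold: float = 0.5, *,
           seed: int = 0, n_samples: int = 20,
           prop_cfg: PropagationConfig = PropagationConfig()
           ) -> dict[str, float]:
    """Classifier-rescored candidate node set for a query.

    Features are generated with the model's training margin, standardized
    with its stored statistics and scored by its forest.  Nodes with
    probability >= threshold are returned with their probabilities; anchors
    and terminals are always retained regardless of score.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ModelError(f"threshold {threshold} outside [0, 1]")
    feats = query_features(q.network, q.anchors, q.terminals, model.margin,
                           seed, n_samples=n_samples, prop_cfg=prop_cfg)
    probs = model.predict_proba(feats)
    out: dict[str, float] = {}
    for node, p in zip(feats["node"], probs):
        if p >= threshold or node in q.anchors or node in q.terminals:
            out[node] = float(p)
    return out


# ---------------------------------------------------------------------------
# Persistence and plotting
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({
        "classifier": model.classifier,
        "normalization": model.normalization,
        "margin": model.margin,
        "feature_set": model.feature_set,
    }, path)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    payload = joblib.load(path)
    required = {"classifier", "normalization", "margin", "feature_set"}
    if not isinstance(payload, dict) or not required <= set(payload):
        raise ModelError(f"incompatible model archive: {path}")
    if payload["feature_set"] not in FEATURE_SETS:
        raise ModelError(f"unknown feature set {payload['feature_set']!r}")
    if set(payload["normalization"]) != set(FEATURE_COLUMNS):
        raise ModelError("model normalization width does not match the "
                         "expected 5 feature columns")
    return TrainedModel(**payload)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path, margin: float) -> FeatureTable:
    frame = pd.read_csv(path, sep="\t")
    return FeatureTable(frame=frame, margin=margin)


def plot_auc_vs_margin(report: EvalReport, path: str | Path) -> None:
    """AUROC/AUPRC per feature set across margins, one panel per metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    series: dict[str, list[EvalEntry]] = {}
    for e in report.entries:
        series.setdefault(e.feature_set, []).append(e)
    for ax, metric in zip(axes, ("auroc", "auprc")):
        for fs, entries in sorted(series.items()):
            entries = sorted(entries, key=lambda e: e.margin)
            ax.plot([e.margin for e in entries],
                    [getattr(e, metric) for e in entries],
                    marker="o", label=fs)
        ax.set_xlabel("margin")
        ax.set_ylabel(metric.upper())
        ax.set_ylim(0, 1.05)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
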