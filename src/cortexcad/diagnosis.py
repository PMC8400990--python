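"""Two-layer regional → global diagnosis and its evaluation harness.

Layer 1 trains, for every cortical region, a probabilistic margin
classifier (SVM with Platt sigmoid calibration fit by inner 3-fold CV)
on that region's fused features, yielding a per-region probability of
MCI — the personalized severity map.  Layer 2 is a standard SVM on the
vector of regional probabilities producing the global NC/MCI call.

Per cross-validation fold, the normalization statistics, the CCA
fusion chains and both classifier layers are fitted on the training
portion only and replayed on the test portion; metrics pool the
confusion counts over folds with MCI as the positive class.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cca_fusion import FusionChain, sequential_fuse
from .region_table import NormStats, RegionFeatureTable, impute_missing, normalize_features

logger = logging.getLogger(__name__)

POSITIVE = "MCI"  # positive class for sensitivity
NEGATIVE = "NC"

KERNELS = ("linear", "polynomial", "rbf")


def _binarize(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iufb":
        return labels.astype(int)
    y = np.where(labels == POSITIVE, 1, 0)
    bad = set(np.unique(labels)) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return y


def _svc(kernel: str, C: float, seed: int) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C, random_state=seed)
    if kernel == "polynomial":
        return SVC(kernel="poly", degree=3, C=C, gamma="scale", random_state=seed)
    if kernel == "rbf":
        return SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


@dataclass
class DiagnosisModel:
    """Fitted per-region probabilistic classifiers plus the global classifier."""

    regions: list[int]
    chains: dict[int, FusionChain]
    regional: dict[int, CalibratedClassifierCV]
    global_clf: object
    norm_stats: NormStats
    impute_means: np.ndarray
    kernel: str = "linear"
    seed: int = 0
    feature_order: tuple[int, ...] = (0, 1, 2, 3, 4)
    dropped_regions: list[int] = field(default_factory=list)


def _prepare(table: RegionFeatureTable, norm_stats=None, impute_means=None):
    """Impute → normalize with training or replayed statistics."""
    imputed, means = impute_missing(table, impute_means)
    norm, stats = normalize_features(imputed, norm_stats)
    return norm, stats, means


def train(
    table: RegionFeatureTable,
    labels,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    feature_order: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> DiagnosisModel:
    """Fit the full two-layer model on one training set.

    Regions missing in more than half the training subjects are dropped
    with a warning; remaining missing cells are imputed with training
    column means before min–max normalization and CCA chain fitting.
    Fully reproducible from ``seed``.
    """
    y = _binarize(labels)
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("need at least 3 subjects per class")
    frac_missing = table.missing.mean(axis=0)
    dropped = [r for r, f in zip(table.regions, frac_missing) if f > 0.5]
    if dropped:
        logger.warning("dropping %d region(s) missing in >50%% of subjects: %s",
                       len(dropped), dropped[:10])
    norm, stats, means = _prepare(table)
    chains: dict[int, FusionChain] = {}
    regional: dict[int, CalibratedClassifierCV] = {}
    kept: list[int] = []
    prob_cols = []
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for j, r in enumerate(table.regions):
        if r in dropped:
            continue
        block = norm.features[:, j, :].T  # 5×n
        Z, chain = sequential_fuse(block, feature_order)
        clf = CalibratedClassifierCV(_svc(kernel, C, seed), method="sigmoid", cv=inner)
        clf.fit(Z.T, y)
        chains[r] = chain
        regional[r] = clf
        kept.append(r)
        prob_cols.append(clf.predict_proba(Z.T)[:, list(clf.classes_).index(1)])
    if not kept:
        raise ValueError("no usable regions to train on")
    P = np.column_stack(prob_cols)
    global_clf = _svc(kernel, C, seed)
    global_clf.fit(P, y)
    return DiagnosisModel(
        regions=kept, chains=chains, regional=regional, global_clf=global_clf,
        norm_stats=stats, impute_means=means, kernel=kernel, seed=seed,
        feature_order=feature_order, dropped_regions=dropped,
    )


def regional_probabilities(model: DiagnosisModel, table: RegionFeatureTable) -> np.ndarray:
    """n_subjects × n_kept_regions matrix of per-region MCI probabilities."""
    norm, _, _ = _prepare(table, model.norm_stats, model.impute_means)
    cols = []
    for r in model.regions:
        j = table.regions.index(r)
        block = norm.features[:, j, :].T
        Z = model.chains[r].transform(block)
        clf = model.regional[r]
        cols.append(clf.predict_proba(Z.T)[:, list(clf.classes_).index(1)])
    return np.column_stack(cols)


def predict(model: DiagnosisModel, table: RegionFeatureTable):
    """Regional probabilities, global labels and global decision scores.

    The global score is the SVM decision value oriented so positive
    means MCI; the tie at exactly 0 is resolved toward MCI (favoring
    sensitivity).
    """
    P = regional_probabilities(model, table)
    score = np.asarray(model.global_clf.decision_function(P), dtype=float).ravel()
    if list(model.global_clf.classes_).index(1) == 0:
        score = -score
    labels = np.where(score >= 0, POSITIVE, NEGATIVE)
    return P, labels, score


# ---------------------------------------------------------------------------
# metrics and k-fold evaluation

def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity in % from confusion counts.

    MCI is the positive class: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).  Zero denominators yield NaN (flagged
    undefined), never 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (tp + tn) / total
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    if np.isnan(sens) or np.isnan(spec):
        logger.warning("zero-denominator metric flagged as undefined (NaN)")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


@dataclass
class EvalReport:
    """Pooled confusion counts and rates from a k-fold evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    k: int
    seed: int
    per_fold: list[dict] = field(default_factory=list)
    fold_hash: str = ""
    method: str = "linear"

    @property
    def metrics(self) -> dict[str, float]:
        return compute_metrics(self.tp, self.fp, self.tn, self.fn)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]

    @property
    def sensitivity(self) -> float:
        return self.metrics["sensitivity"]

    @property
    def specificity(self) -> float:
        return self.metrics["specificity"]

    def to_dict(self) -> dict:
        return {
            "method": self.method, "k": self.k, "seed": self.seed,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            **self.metrics, "per_fold": self.per_fold, "fold_hash": self.fold_hash,
        }


def _folds(y: np.ndarray, k: int, seed: int):
    if k > len(y):
        raise ValueError("k cannot exceed the number of subjects")
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError("each fold needs at least one subject of each class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def fold_hash(splits) -> str:
    h = hashlib.sha256()
    for _, test_idx in splits:
        h.update(np.sort(np.asarray(test_idx)).astype(np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()


def kfold_evaluate(
    table: RegionFeatureTable,
    labels,
    k: int = 10,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    global_clf_factory=None,
) -> EvalReport:
    """Stratified k-fold evaluation with per-fold refitting of everything.

    Normalization statistics, CCA chains, regional calibration and the
    global classifier are all fitted on each fold's training portion
    only; confusion counts are pooled over folds (per-fold rates are
    also reported).
    """
    y = _binarize(labels)
    splits = _folds(y, k, seed)
    tp = fp = tn = fn = 0
    per_fold = []
    for fold_i, (tr, te) in enumerate(splits):
        model = train(table.subset(tr), y[tr], kernel=kernel, C=C, seed=seed)
        if global_clf_factory is not None:
            P_tr = regional_probabilities(model, table.subset(tr))
            g = global_clf_factory()
            g.fit(P_tr, y[tr])
            model.global_clf = g
        P_te = regional_probabilities(model, table.subset(te))
        if hasattr(model.global_clf, "decision_function"):
            score = np.asarray(model.global_clf.decision_function(P_te)).ravel()
            if list(model.global_clf.classes_).index(1) == 0:
                score = -score
            pred = (score >= 0).astype(int)
        else:
            pred = np.asarray(model.global_clf.predict(P_te)).astype(int)
        truth = y[te]
        ftp = int(((pred == 1) & (truth == 1)).sum())
        ffp = int(((pred == 1) & (truth == 0)).sum())
        ftn = int(((pred == 0) & (truth == 0)).sum())
        ffn = int(((pred == 0) & (truth == 1)).sum())
        tp, fp, tn, fn = tp + ftp, fp + ffp, tn + ftn, fn + ffn
        per_fold.append({"fold": fold_i, "tp": ftp, "fp": ffp, "tn": ftn, "fn": ffn,
                         **compute_metrics(ftp, ffp, ftn, ffn)})
    return EvalReport(tp, fp, tn, fn, k=k, seed=seed, per_fold=per_fold,
                      fold_hash=fold_hash(splits), method=kernel)


def compare_classifiers(
    table: RegionFeatureTable, labels, k: int = 10, seed: int = 0, C: float = 1.0
) -> dict[str, EvalReport]:
    """Evaluate the SVM kernels and standard comparison methods on identical folds.

    The three SVM kernels drive both layers; decision tree, ensemble
    (random forest) and k-nearest-neighbors replace the global layer on
    top of the calibrated linear regional layer.  Identical folds are
    guaranteed by the shared seed and verified by fold hash.
    """
    reports: dict[str, EvalReport] = {}
    for kern in KERNELS:
        rep = kfold_evaluate(table, labels, k=k, kernel=kern, C=C, seed=seed)
        rep.method = f"{kern}_svm"
        reports[f"{kern}_svm"] = rep
    others = {
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "ensemble": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
    }
    for name, factory in others.items():
        rep = kfold_evaluate(table, labels, k=k, kernel="linear", C=C, seed=seed,
                             global_clf_factory=factory)
        rep.method = name
        reports[name] = rep
    hashes = {r.fold_hash for r in reports.values()}
    if len(hashes) != 1:
        raise RuntimeError("comparison methods ran on different folds")
    return reports


# ---------------------------------------------------------------------------
# behavioral correlation and severity export

def behavioral_correlation(
    probabilities: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between regional probabilities and behavioral scores.

    Missing scores are pairwise-deleted; constant columns are flagged
    undefined.  Raw two-sided t-based p-values are reported alongside
    Benjamini–Hochberg q-values.
    """
    rows = []
    for region in probabilities.columns:
        for task in scores.columns:
            x = probabilities[region].to_numpy(dtype=float)
            yv = scores[task].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(yv))
            xo, yo = x[ok], yv[ok]
            if ok.sum() < 4:
                raise ValueError("need at least 4 paired observations")
            if np.ptp(xo) == 0 or np.ptp(yo) == 0:
                rows.append((region, task, float("nan"), float("nan"), True))
                continue
            r, p = sps.pearsonr(xo, yo)
            rows.append((region, task, float(r), float(p), False))
    df = pd.DataFrame(rows, columns=["region", "task", "r", "p", "undefined"])
    valid = ~df["undefined"]
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid.to_numpy()] = sps.false_discovery_control(df.loc[valid, "p"].to_numpy())
    df["q"] = q
    return df


def export_severity(
    regional_probs: dict[int, float],
    mesh,
    vertex_labels: np.ndarray,
    ply_path=None,
    csv_path=None,
) -> np.ndarray:
    """Paint per-region MCI probabilities onto the mesh.

    Every vertex carries its region's probability as a scalar in [0,1]
    (background vertices get 0); the per-region table goes to CSV.
    Returns the per-vertex severity scalar.
    """
    vertex_labels = np.asarray(vertex_labels)
    sev = np.zeros(len(vertex_labels), dtype=float)
    for r, pval in regional_probs.items():
        sev[vertex_labels == r] = pval
    if ply_path is not None:
        from .surface_recon import save_mesh

        save_mesh(mesh, ply_path, vertex_scalars={"severity": sev})
    if csv_path is not None:
        pd.DataFrame(
            {"region": list(regional_probs), "probability": list(regional_probs.values())}
        ).to_csv(csv_path, index=False)
    return sev


# ---------------------------------------------------------------------------
# fingerprint for leakage audits

def model_fingerprint(model: DiagnosisModel, n_probe: int = 32) -> str:
    """Deterministic hash of everything fitted: normalization, chains, classifiers.

    Classifier layers are fingerprinted behaviorally on a fixed probe
    grid, so any change in fitted parameters shows up.
    """
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.norm_stats.mins).tobytes())
    h.update(np.ascontiguousarray(model.norm_stats.maxs).tobytes())
    h.update(np.ascontiguousarray(model.impute_means).tobytes())
    rng = np.random.default_rng(0)
    probe2 = rng.normal(size=(n_probe, 2))
    for r in model.regions:
        chain = model.chains[r]
        for m in chain.models:
            for arr in (m.Wx, m.Wy, m.correlations, m.mean_x, m.mean_y):
                h.update(np.ascontiguousarray(arr).tobytes())
        h.update(np.ascontiguousarray(
            model.regional[r].predict_proba(probe2)).tobytes())
    probeP = rng.uniform(size=(n_probe, len(model.regions)))
    h.update(np.ascontiguousarray(
        model.global_clf.decision_function(probeP)).tobytes())
    return h.hexdigest()
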