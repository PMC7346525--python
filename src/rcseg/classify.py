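"""Ensemble plant/background classification of AC-KMR color regions.

No single conventional classifier separates plant from background colors
reliably across species, camera views and developmental stages, so eight
alternative binary models are trained on the same region table and their
votes combined:

========  =============================================
acronym   model
========  =============================================
bayes     naive Bayes
da        linear discriminant analysis
glm       logistic regression (binomial GLM)
gpr       Gaussian-process regression on 0/1 targets
linmod    ordinary linear regression on 0/1 targets
svm       support-vector classifier (linear kernel)
svmreg    support-vector regression on 0/1 targets
net       feed-forward net, one hidden layer, sigmoid out
========  =============================================

Regression-type members (glm, gpr, linmod, svmreg, net) produce a fuzzy
estimate FE in [0, 1] (clipped) which is thresholded at exactly 0.5:
``FE >= 0.5`` is plant.  Two combination rules are offered: *fusion*
(logical OR over the eight member votes) and *median* (per-region median
of the binary votes, the 4-4 tie value 0.5 resolving to plant, i.e.
plant iff at least four members vote plant).  Median is the default.

Features are min-max normalized with statistics stored at training time,
since the mixed color channels feed several scale-sensitive members.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, SVR

from .colorspace import RegionPartition
from .errors import ModelError, TrainingError, ValidationError
from .io import BinaryMask

logger = logging.getLogger(__name__)

#: Fixed member order of the ensemble.
MEMBER_ACRONYMS = ("bayes", "da", "glm", "gpr", "linmod", "svm", "svmreg", "net")
#: Members whose raw output is a fuzzy estimate rather than a hard label.
FUZZY_MEMBERS = frozenset({"glm", "gpr", "linmod", "svmreg", "net"})
#: The fuzzy-estimate decision threshold (FE >= 0.5 -> plant).
FE_THRESHOLD = 0.5

_FORMAT_VERSION = 1


def threshold_fe(fe: np.ndarray) -> np.ndarray:
    """Binarize fuzzy estimates: plant iff FE >= 0.5 (ties are plant)."""
    fe = np.clip(np.asarray(fe, dtype=np.float64), 0.0, 1.0)
    return (fe >= FE_THRESHOLD).astype(np.intp)


class _MajorityStub:
    """Degenerate fallback member predicting the training majority class."""

    def __init__(self, label: int):
        self.label = int(label)

    def predict(self, x):  # noqa: D102 - sklearn-style duck typing
        return np.full(np.asarray(x).shape[0], self.label)


def _build_estimators(seed: int, net_hidden: int) -> dict:
    return {
        "bayes": GaussianNB(),
        "da": LinearDiscriminantAnalysis(),
        "glm": LogisticRegression(max_iter=1000),
        "gpr": GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * RBF(length_scale=1.0)
            + WhiteKernel(noise_level=1e-3),
            normalize_y=False,
            random_state=seed,
        ),
        "linmod": LinearRegression(),
        "svm": SVC(kernel="linear"),
        "svmreg": SVR(kernel="linear"),
        "net": MLPClassifier(
            hidden_layer_sizes=(net_hidden,),
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        ),
    }


@dataclass
class EnsembleModel:
    """Eight trained plant/background region classifiers plus normalization."""

    members: dict
    feature_min: np.ndarray
    feature_range: np.ndarray
    feature_dim: int
    fe_threshold: float = FE_THRESHOLD

    def __post_init__(self) -> None:
        if set(self.members) != set(MEMBER_ACRONYMS):
            missing = sorted(set(MEMBER_ACRONYMS) - set(self.members))
            raise ValidationError(f"ensemble must have exactly 8 members; missing {missing}")

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.feature_dim:
            raise ValidationError(
                f"expected (n, {self.feature_dim}) features, got {x.shape}"
            )
        return (x - self.feature_min) / self.feature_range

    def fuzzy_single(self, acronym: str, x: np.ndarray) -> np.ndarray | None:
        """Clipped fuzzy estimate of one member, or None for hard classifiers."""
        if acronym not in FUZZY_MEMBERS:
            return None
        est = self.members[acronym]
        if isinstance(est, _MajorityStub):
            return np.full(np.asarray(x).shape[0], float(est.label))
        xn = self._normalize(x)
        if hasattr(est, "predict_proba"):
            fe = est.predict_proba(xn)[:, 1]
        else:
            fe = est.predict(xn)
        return np.clip(fe, 0.0, 1.0)

    def predict_single(self, acronym: str, x: np.ndarray) -> np.ndarray:
        """Hard 0/1 labels of one member (fuzzy members thresholded at 0.5)."""
        if acronym not in self.members:
            raise ValidationError(f"unknown member acronym {acronym!r}")
        fe = self.fuzzy_single(acronym, x)
        if fe is not None:
            return threshold_fe(fe)
        est = self.members[acronym]
        if isinstance(est, _MajorityStub):
            return est.predict(np.asarray(x))
        return est.predict(self._normalize(x)).astype(np.intp)

    def predict_members(self, x: np.ndarray) -> np.ndarray:
        """An ``(8, n)`` matrix of member votes in the fixed acronym order."""
        return np.stack([self.predict_single(a, x) for a in MEMBER_ACRONYMS])

    def predict(self, x: np.ndarray, combine: str = "median") -> np.ndarray:
        """Combined 0/1 labels under ``median``, ``fusion`` or ``single:<acronym>``."""
        if combine.startswith("single:"):
            return self.predict_single(combine.split(":", 1)[1], x)
        votes = self.predict_members(x)
        return combine_predictions(votes)[combine]


def train_ensemble(
    x: np.ndarray, y: np.ndarray, net_hidden: int = 10, seed: int = 0
) -> EnsembleModel:
    """Train the eight-member ensemble on a region table.

    ``x`` is the ``(m, D)`` AC-KMR table, ``y`` the 0/1 region labels
    (0 = background, 1 = plant); both classes must be present and m >= 8.
    A member whose fit fails on degenerate data is replaced by a
    majority-vote stub with a logged warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).astype(np.intp).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValidationError("X rows and Y entries must align")
    if x.shape[0] < 8:
        raise TrainingError("need at least 8 training rows")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValidationError("Y must be binary 0/1")
    if np.unique(y).size < 2:
        raise TrainingError("both classes must be present in the training table")

    fmin = x.min(axis=0)
    frange = x.max(axis=0) - fmin
    degenerate = frange <= 0
    if degenerate.any():
        logger.warning(
            "constant training features at indices %s", np.flatnonzero(degenerate)
        )
    frange = np.where(degenerate, 1.0, frange)
    xn = (x - fmin) / frange

    majority = int(np.bincount(y).argmax())
    members = {}
    for acronym, est in _build_estimators(seed, net_hidden).items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(xn, y)
            members[acronym] = est
        except Exception as exc:
            logger.warning("member %s failed to train (%s); using majority stub",
                           acronym, exc)
            members[acronym] = _MajorityStub(majority)
    return EnsembleModel(
        members=members, feature_min=fmin, feature_range=frange,
        feature_dim=x.shape[1],
    )


def combine_predictions(labels: np.ndarray) -> dict:
    """Combine an ``(8, n)`` binary vote matrix into median and fusion labels.

    Fusion is the logical OR of the member votes.  Median is the
    per-region median of the eight binary votes with the tie value 0.5
    mapped to plant, i.e. plant iff at least 4 of 8 members vote plant.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] != 8:
        raise ValidationError(f"expected an (8, n) vote matrix, got {labels.shape}")
    votes = labels.sum(axis=0)
    return {
        "median": (votes >= 4).astype(np.intp),
        "fusion": (votes >= 1).astype(np.intp),
    }


def segment_regions(
    partition: RegionPartition, ensemble: EnsembleModel, combine: str = "median"
) -> BinaryMask:
    """Broadcast region-level plant predictions back to a pixel mask."""
    region_labels = ensemble.predict(partition.ackmr, combine=combine)
    out = np.zeros(partition.labels.shape, dtype=bool)
    sel = partition.labels >= 0
    out[sel] = region_labels[partition.labels[sel]] == 1
    return BinaryMask(out)


@dataclass
class CaseScenarioModel:
    """A persisted bundle: region ensemble + object filter + scenario metadata.

    ``meta`` records species, camera view, modality (FLU, VIS or
    FLU+VIS), the developmental-stage set the model was trained on, the
    region count ``n_reg`` that segmentation must reuse, and the seeds.
    """

    ensemble: EnsembleModel
    object_filter: "object" = None  # ObjectFilterModel or None (permissive)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        stages = self.meta.get("stages")
        if stages is not None and len(stages) == 0:
            raise ValidationError("stage set must be non-empty")


def save_model(model: CaseScenarioModel, path: str | Path) -> None:
    """Persist a case-scenario model bundle as a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _FORMAT_VERSION,
        "members": list(MEMBER_ACRONYMS),
        "feature_dim": model.ensemble.feature_dim,
        "feature_min": model.ensemble.feature_min.tolist(),
        "feature_range": model.ensemble.feature_range.tolist(),
        "fe_threshold": model.ensemble.fe_threshold,
        "has_object_filter": model.object_filter is not None,
        "scenario": model.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    joblib.dump(model.ensemble.members, path / "members.joblib")
    if model.object_filter is not None:
        joblib.dump(model.object_filter, path / "object_filter.joblib")


def load_model(path: str | Path) -> CaseScenarioModel:
    """Load a bundle written by :func:`save_model`; round trip is lossless."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ModelError(f"model bundle not found at {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except Exception as exc:
        raise ModelError(f"corrupt model metadata in {meta_path}: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ModelError(
            f"unsupported model format version {meta.get('format_version')}"
        )
    try:
        members = joblib.load(path / "members.joblib")
    except Exception as exc:
        raise ModelError(f"cannot load ensemble members: {exc}") from exc
    missing = sorted(set(MEMBER_ACRONYMS) - set(members))
    if missing:
        raise ModelError(f"model bundle is missing members: {missing}")
    ensemble = EnsembleModel(
        members={a: members[a] for a in MEMBER_ACRONYMS},
        feature_min=np.asarray(meta["feature_min"]),
        feature_range=np.asarray(meta["feature_range"]),
        feature_dim=int(meta["feature_dim"]),
        fe_threshold=float(meta["fe_threshold"]),
    )
    object_filter = None
    if meta.get("has_object_filter"):
        object_filter = joblib.load(path / "object_filter.joblib")
    return CaseScenarioModel(
        ensemble=ensemble, object_filter=object_filter, meta=meta.get("scenario", {})
    )
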