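"""Synthetic cohort generation and pathology classification.

The diagnostic-discriminability experiment builds a cohort of simulated
"subjects" under three conditions — healthy, right-upper-lobe fibrosis and
right-lower-lobe fibrosis — with 30 realizations per class (n = 90).  Each
realization is the noisy FRF magnitude at all four DOFs over 300 frequency
points in 5–150 Hz, flattened DOF-major into a 1200-wide feature vector.
Optional inter-subject variability multiplies every mass, stiffness and
damping value by an independent lognormal jitter factor before the class
pathology is applied.

The pipeline mirrors a standard supervised-learning protocol: stratified
70/30 train/test split, PCA to six components (fitted on the training rows
only, to avoid leakage), and a multinomial logistic-regression classifier
(iteration cap 1000), scored by per-class precision/recall/F1 and the
confusion matrix on the held-out set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .frf import ExcitationSpec, FrequencyGrid, default_grid, solve_frf
from .model import (
    DamperSpec,
    PathologySpec,
    SpringSpec,
    ThoraxModel,
    apply_pathology,
    default_pathologies,
)
from .noise import NoiseSpec, add_magnitude_noise

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "ClassificationReport",
    "generate_cohort",
    "split_stratified",
    "reduce_pca",
    "train_and_evaluate",
    "run_classification_experiment",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the reference experiment: 3 conditions x 30
    realizations, 300 frequency points over 5–150 Hz, 2 % relative
    magnitude noise, no inter-subject jitter.
    """

    conditions: tuple[str, ...] = ("healthy", "fibrosis_RU", "fibrosis_RL")
    per_class: int = 30
    grid: FrequencyGrid = field(default_factory=default_grid)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    jitter_sigma: float = 0.0
    seed: int = 0
    pathologies: dict[str, PathologySpec] | None = None

    def __post_init__(self) -> None:
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        if len(self.conditions) == 0 or len(set(self.conditions)) != len(
            self.conditions
        ):
            raise ValueError("conditions must be nonempty and distinct")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    def resolve_pathologies(self) -> dict[str, PathologySpec]:
        specs = self.pathologies or default_pathologies()
        missing = [c for c in self.conditions if c not in specs]
        if missing:
            raise ValueError(f"no pathology spec for conditions {missing}")
        return specs


@dataclass(frozen=True)
class CohortDataset:
    """Labeled feature matrix of noisy FRF magnitudes.

    ``features`` is (n_realizations, n_dofs * n_frequencies), flattened
    DOF-major (all frequencies of DOF 0, then DOF 1, ...).  ``provenance``
    records the per-realization perturbed spring values for audit.
    """

    features: np.ndarray
    labels: np.ndarray
    grid: FrequencyGrid
    n_dof: int
    provenance: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must align")
        if self.features.shape[1] != self.n_dof * len(self.grid):
            raise ValueError("feature width must equal n_dof * n_frequencies")

    @property
    def n_realizations(self) -> int:
        return self.features.shape[0]

    def subset(self, index: np.ndarray) -> "CohortDataset":
        return CohortDataset(
            features=self.features[index],
            labels=self.labels[index],
            grid=self.grid,
            n_dof=self.n_dof,
            provenance=tuple(self.provenance[i] for i in index)
            if self.provenance
            else (),
        )


@dataclass(frozen=True)
class ClassificationReport:
    """Held-out evaluation of the cohort classifier."""

    classes: tuple[str, ...]
    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    n_train: int
    n_test: int
    pc_scores: np.ndarray | None = None
    pc_labels: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    converged: bool = True

    def metrics_frame(self) -> pd.DataFrame:
        """Per-class metrics table (precision, recall, F1, support)."""
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1_score": self.f1,
                "support": self.support,
            }
        ).rename_axis("class")

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1_score": self.f1,
            "support": self.support,
            "accuracy": self.accuracy,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "converged": self.converged,
        }


def _jittered(model: ThoraxModel, sigma: float, rng: np.random.Generator):
    """Multiplicative lognormal jitter on every mass, spring and damper."""
    if sigma == 0:
        return model
    masses = tuple(m * rng.lognormal(0.0, sigma) for m in model.masses)
    springs = tuple(
        SpringSpec(s.endpoint_a, s.endpoint_b, s.stiffness * rng.lognormal(0.0, sigma))
        for s in model.springs
    )
    dampers = tuple(
        DamperSpec(
            d.endpoint_a, d.endpoint_b, d.coefficient * rng.lognormal(0.0, sigma)
        )
        for d in model.dampers
    )
    return replace(model, masses=masses, springs=springs, dampers=dampers)


def generate_cohort(
    config: CohortConfig,
    baseline: ThoraxModel,
    excitation: ExcitationSpec = ExcitationSpec(),
) -> CohortDataset:
    """Simulate the labeled cohort of noisy FRF-magnitude feature vectors.

    Per realization: jitter the baseline (if ``jitter_sigma`` > 0), apply
    the class pathology, solve the FRF on the configured grid, corrupt the
    magnitudes, and flatten DOF-major.  The whole dataset is a pure
    function of ``config`` (including its seed).
    """
    pathologies = config.resolve_pathologies()
    rng = np.random.default_rng(config.seed)
    rows, labels, provenance = [], [], []
    for condition in config.conditions:
        spec = pathologies[condition]
        for _ in range(config.per_class):
            subject = _jittered(baseline, config.jitter_sigma, rng)
            diseased = apply_pathology(subject, spec)
            frf = solve_frf(diseased, config.grid, excitation)
            noisy = add_magnitude_noise(frf, config.noise, rng=rng)
            rows.append(noisy.magnitude.ravel())
            labels.append(condition)
            provenance.append(
                {
                    "condition": condition,
                    "springs": {
                        s.name: s.stiffness for s in diseased.springs
                    },
                }
            )
    return CohortDataset(
        features=np.array(rows),
        labels=np.array(labels),
        grid=config.grid,
        n_dof=baseline.n_dof,
        provenance=tuple(provenance),
    )


def split_stratified(
    dataset: CohortDataset, test_fraction: float = 0.30, seed: int = 0
) -> tuple[CohortDataset, CohortDataset]:
    """Stratified train/test partition preserving class proportions.

    On the default balanced 90-row cohort a 0.30 test fraction yields
    63 training and 27 test rows, 9 test rows per class.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(dataset.n_realizations)
    try:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=test_fraction,
            stratify=dataset.labels,
            random_state=seed,
        )
    except ValueError as exc:
        raise ValueError(f"cannot stratify: {exc}") from exc
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def reduce_pca(
    train_features: np.ndarray,
    test_features: np.ndarray,
    n_components: int = 6,
):
    """Mean-centered PCA fitted on training rows; both sets projected.

    Returns ``(train_reduced, test_reduced, pca)`` where ``pca`` carries
    the explained-variance ratios and components; the first two columns of
    the reduced sets are the 2-D ordination scores.
    """
    if n_components > min(train_features.shape):
        raise ValueError(
            "n_components exceeds min(n_train_rows, n_features)"
        )
    if np.allclose(train_features.var(axis=0), 0.0):
        raise ValueError("training features have zero variance overall")
    pca = PCA(n_components=n_components)
    train_red = pca.fit_transform(train_features)
    test_red = pca.transform(test_features)
    return train_red, test_red, pca


def train_and_evaluate(
    train: CohortDataset | tuple[np.ndarray, np.ndarray],
    test: CohortDataset | tuple[np.ndarray, np.ndarray],
    max_iterations: int = 1000,
    n_components: int = 6,
) -> ClassificationReport:
    """PCA + multinomial logistic regression, evaluated on the held-out set.

    Accepts either ``CohortDataset`` objects or ``(features, labels)``
    pairs.  Non-convergence of the logistic solver is recorded in the
    report (metrics are still computed).
    """
    X_train, y_train = (
        (train.features, train.labels)
        if isinstance(train, CohortDataset)
        else train
    )
    X_test, y_test = (
        (test.features, test.labels) if isinstance(test, CohortDataset) else test
    )
    classes = tuple(str(c) for c in sorted(set(y_train)))
    if set(y_test) - set(classes):
        raise ValueError("test set contains classes absent from training")

    train_red, test_red, pca = reduce_pca(X_train, X_test, n_components)

    clf = LogisticRegression(max_iter=max_iterations)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(train_red, y_train)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "logistic regression did not converge within "
                f"{max_iterations} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
    y_pred = clf.predict(test_red)

    prec, rec, f1, support = precision_recall_fscore_support(
        y_test, y_pred, labels=list(classes), zero_division=0
    )
    conf = confusion_matrix(y_test, y_pred, labels=list(classes))
    return ClassificationReport(
        classes=classes,
        confusion=conf,
        precision={c: float(p) for c, p in zip(classes, prec)},
        recall={c: float(r) for c, r in zip(classes, rec)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        support={c: int(s) for c, s in zip(classes, support)},
        accuracy=float(np.trace(conf) / conf.sum()),
        n_train=len(y_train),
        n_test=len(y_test),
        pc_scores=np.vstack([train_red[:, :2], test_red[:, :2]]),
        pc_labels=np.concatenate([y_train, y_test]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        converged=converged,
    )


def run_classification_experiment(
    baseline: ThoraxModel,
    config: CohortConfig | None = None,
    test_fraction: float = 0.30,
    split_seed: int = 0,
    max_iterations: int = 1000,
    n_components: int = 6,
) -> ClassificationReport:
    """End-to-end experiment: cohort -> split -> PCA -> classifier -> report."""
    config = config or CohortConfig()
    dataset = generate_cohort(config, baseline)
    train, test = split_stratified(dataset, test_fraction, seed=split_seed)
    return train_and_evaluate(
        train, test, max_iterations=max_iterations, n_components=n_components
    )
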