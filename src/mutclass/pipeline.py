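"""Orchestration: feature assembly, cross-validation, and evaluation.

The classifier input for each sample is the concatenation of two
independently computed views of its binary gene vector: the values of the
genes retained by clustered gene filtering (a short binary block) and the
fixed-length indexed-sparsity-reduction encoding of the *full* gene
vector (an index block, scaled into [0, 1] by default).  The two
pre-processing steps are fitted side by side on the same training
partition and concatenated, never chained — chaining would discard the
binary view.

Cross-validation is stratified: within every cancer class the samples
are randomly dealt into k subgroups, and each fold unions one subgroup
per class, so every fold mirrors the class distribution.  The featurizer
and the classifier are fitted per fold on the k−1 training folds only
and applied frozen to the held-out fold; a ``fit_on_all`` switch exists
for deliberately global featurizer fitting, but the leakage-free default
is what the reported numbers mean.  The reported cross-validation
accuracy is the mean of the per-fold accuracies (whose standard
deviation is what the accompanying t-test consumes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import cgf as _cgf
from . import dnn as _dnn
from . import isr as _isr
from .io_mut import BinaryMutationMatrix, CohortLabels

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """``fold_of[j]`` is the fold (1..k) of sample j; within each class
    fold sizes differ by at most one."""

    fold_of: np.ndarray
    k: int


def make_folds(labels: CohortLabels, k: int, seed: int) -> FoldAssignment:
    """Stratified fold assignment: per-class random permutation under
    ``seed``, dealt round-robin into the k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(len(labels.labels), dtype=np.int64)
    for c in range(1, labels.n_cancer + 1):
        members = np.flatnonzero(labels.labels == c)
        if members.size < k:
            raise ValueError(
                f"class {labels.class_names[c - 1]!r} has {members.size} samples, "
                f"fewer than k={k}"
            )
        perm = rng.permutation(members)
        fold_of[perm] = np.arange(perm.size) % k + 1
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass
class Featurizer:
    """Fitted CGF ⊕ ISR feature map.

    ``use_cgf`` / ``use_isr`` toggle the two blocks for ablation runs;
    with both off the raw binary gene vector passes through unchanged.
    """

    cgf_params: _cgf.CgfParams = field(default_factory=_cgf.CgfParams)
    isr_params: _isr.IsrParams = field(default_factory=_isr.IsrParams)
    use_cgf: bool = True
    use_isr: bool = True
    # fitted state
    subset: _cgf.DiscriminatorySubset | None = None
    ranking: _cgf.FrequencyRanking | None = None
    m: int | None = None
    n_fit_samples: int | None = None

    def fit(self, train_matrix: BinaryMutationMatrix) -> "Featurizer":
        self.m = train_matrix.m
        self.n_fit_samples = train_matrix.n
        self.ranking = _cgf.rank_genes(train_matrix)
        if self.use_cgf:
            grouping = _cgf.group_genes(train_matrix, self.ranking, self.cgf_params.d_cgf)
            self.subset = _cgf.select_subset(
                train_matrix, grouping, self.ranking, self.cgf_params.n_cgf
            )
            if self.subset.gene_indices.size == 0:
                raise _cgf.EmptyGeneSubsetError(
                    "gene filtering retained no genes on this training partition; "
                    "lower n_cgf or d_cgf"
                )
        return self

    @property
    def layout(self) -> tuple[int, int]:
        """(binary block width, index block width) of the output."""
        n_bin = len(self.subset.gene_indices) if self.use_cgf else 0
        n_idx = self.isr_params.n_isr if self.use_isr else 0
        if not self.use_cgf and not self.use_isr:
            return (self.m, 0)
        return (n_bin, n_idx)

    @property
    def output_dim(self) -> int:
        return sum(self.layout)

    def transform(self, matrix: BinaryMutationMatrix) -> np.ndarray:
        """(n_samples, output_dim) feature rows for the matrix's columns."""
        if self.ranking is None:
            raise RuntimeError("featurizer is not fitted")
        if matrix.m != self.m:
            raise ValueError(f"matrix has {matrix.m} genes, featurizer fitted on {self.m}")
        blocks = []
        if self.use_cgf:
            blocks.append(
                matrix.values[self.subset.gene_indices - 1].T.astype(np.float64)
            )
        if self.use_isr:
            blocks.append(_isr.isr_transform_matrix(matrix.values, self.isr_params, self.ranking))
        if not blocks:  # raw-input ablation
            blocks.append(matrix.values.T.astype(np.float64))
        return np.hstack(blocks)


def fit_features(
    train_matrix: BinaryMutationMatrix,
    cgf_params: _cgf.CgfParams | None = None,
    isr_params: _isr.IsrParams | None = None,
    use_cgf: bool = True,
    use_isr: bool = True,
) -> Featurizer:
    """Fit the CGF subset and the ISR frequency ranking on a training
    partition; both stay frozen for subsequent transforms."""
    return Featurizer(
        cgf_params=cgf_params or _cgf.CgfParams(),
        isr_params=isr_params or _isr.IsrParams(),
        use_cgf=use_cgf,
        use_isr=use_isr,
    ).fit(train_matrix)


@dataclass
class EvalReport:
    """Accuracy, confusion counts (rows = true class), and the per-fold
    accuracy vector (length 1 for a single hold-out split)."""

    accuracy: float
    confusion: np.ndarray
    per_fold_accuracies: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_fold_accuracies": self.per_fold_accuracies.tolist(),
            "confusion": self.confusion.tolist(),
        }


def _default_classifier(net_cfg, train_cfg, n_classes: int):
    base = net_cfg or _dnn.NetworkConfig(input_dim=1)
    cfg = replace(base, output_dim=n_classes)
    return _dnn.DnnClassifier(net_cfg=cfg, train_cfg=train_cfg or _dnn.TrainConfig())


def _run_split(
    matrix, labels, train_idx, test_idx, cgf_params, isr_params,
    net_cfg, train_cfg, use_cgf, use_isr, classifier_factory, fit_on_all,
):
    fit_matrix = matrix if fit_on_all else matrix.select_samples(train_idx)
    featurizer = fit_features(fit_matrix, cgf_params, isr_params, use_cgf, use_isr)
    x_train = featurizer.transform(matrix.select_samples(train_idx))
    x_test = featurizer.transform(matrix.select_samples(test_idx))
    if classifier_factory is None:
        clf = _default_classifier(net_cfg, train_cfg, labels.n_cancer)
    else:
        clf = classifier_factory()
    clf.fit(x_train, labels.labels[train_idx])
    return clf.predict(x_test)


def crossval(
    matrix: BinaryMutationMatrix,
    labels: CohortLabels,
    cgf_params: _cgf.CgfParams | None = None,
    isr_params: _isr.IsrParams | None = None,
    net_cfg: _dnn.NetworkConfig | None = None,
    train_cfg: _dnn.TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
    use_cgf: bool = True,
    use_isr: bool = True,
    classifier_factory=None,
    fit_on_all: bool = False,
) -> EvalReport:
    """Stratified k-fold cross-validation (default k=10).

    Per fold the featurizer and classifier are fitted on the training
    folds and scored on the held-out fold.  ``classifier_factory`` may
    supply any object with sklearn-style ``fit``/``predict`` (the
    baseline classifiers qualify); the default is the feed-forward
    network.
    """
    folds = make_folds(labels, k, seed)
    n_cls = labels.n_cancer
    confusion = np.zeros((n_cls, n_cls), dtype=np.int64)
    per_fold = []
    for fold in range(1, k + 1):
        test_idx = np.flatnonzero(folds.fold_of == fold)
        train_idx = np.flatnonzero(folds.fold_of != fold)
        pred = _run_split(
            matrix, labels, train_idx, test_idx, cgf_params, isr_params,
            net_cfg, train_cfg, use_cgf, use_isr, classifier_factory, fit_on_all,
        )
        true = labels.labels[test_idx]
        per_fold.append(float((pred == true).mean()))
        np.add.at(confusion, (true - 1, pred - 1), 1)
        logger.info("fold %d/%d accuracy %.3f", fold, k, per_fold[-1])
    per_fold = np.array(per_fold)
    return EvalReport(
        accuracy=float(per_fold.mean()), confusion=confusion,
        per_fold_accuracies=per_fold,
    )


def holdout_eval(
    matrix: BinaryMutationMatrix,
    labels: CohortLabels,
    split_fraction: float = 0.1,
    seed: int = 0,
    cgf_params: _cgf.CgfParams | None = None,
    isr_params: _isr.IsrParams | None = None,
    net_cfg: _dnn.NetworkConfig | None = None,
    train_cfg: _dnn.TrainConfig | None = None,
    use_cgf: bool = True,
    use_isr: bool = True,
    classifier_factory=None,
) -> EvalReport:
    """Stratified hold-out split (default 90% train / 10% test), train on
    the large part, report testing accuracy on the rest."""
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(labels.labels), dtype=bool)
    for c in range(1, labels.n_cancer + 1):
        members = rng.permutation(np.flatnonzero(labels.labels == c))
        n_test = max(1, round(split_fraction * members.size))
        test_mask[members[:n_test]] = True
    test_idx = np.flatnonzero(test_mask)
    train_idx = np.flatnonzero(~test_mask)
    pred = _run_split(
        matrix, labels, train_idx, test_idx, cgf_params, isr_params,
        net_cfg, train_cfg, use_cgf, use_isr, classifier_factory, fit_on_all=False,
    )
    true = labels.labels[test_idx]
    n_cls = labels.n_cancer
    confusion = np.zeros((n_cls, n_cls), dtype=np.int64)
    np.add.at(confusion, (true - 1, pred - 1), 1)
    acc = float((pred == true).mean())
    return EvalReport(accuracy=acc, confusion=confusion,
                      per_fold_accuracies=np.array([acc]))


@dataclass
class TTestInputs:
    """Summary statistics of two classifiers' per-fold accuracies."""

    mean_1: float
    mean_2: float
    s_1: float
    s_2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two folds")
        if self.s_1 < 0 or self.s_2 < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class TTestResult:
    pooled_value: float       # (s1² + s2²)/2 — mean of the two variances
    t: float                  # statistic with pooled_value itself as scale
    t_student: float          # textbook two-sample pooled-s.d. Student t
    df: int
    infinite: bool = False


def accuracy_ttest(inputs: TTestInputs) -> TTestResult:
    """Compare two classifiers' fold accuracies under equal-accuracy null.

    Two variants are returned.  ``t`` divides the mean difference by
    ``pooled_value · sqrt(2/n)`` where ``pooled_value = (s1² + s2²)/2``
    is the *un-square-rooted* mean of the variances — a nonstandard scale
    some SMCC comparisons report, kept here verbatim for comparability.
    ``t_student`` is the textbook equal-variance two-sample statistic,
    using the pooled standard deviation ``sqrt((s1² + s2²)/2)``.
    """
    pooled_value = (inputs.s_1 ** 2 + inputs.s_2 ** 2) / 2.0
    diff = inputs.mean_1 - inputs.mean_2
    scale = np.sqrt(2.0 / inputs.n)
    if pooled_value == 0.0:
        infinite = diff != 0.0
        t_val = float(np.inf * np.sign(diff)) if infinite else 0.0
        return TTestResult(pooled_value, t_val, t_val, inputs.n - 1, infinite)
    t_val = diff / (pooled_value * scale)
    t_student = diff / (np.sqrt(pooled_value) * scale)
    return TTestResult(float(pooled_value), float(t_val), float(t_student),
                       df=inputs.n - 1)


def relative_improvement(a: float, b: float) -> float:
    """Percent improvement of accuracy ``a`` over baseline ``b``:
    ``100 · (a − b)/b``."""
    if b == 0:
        raise ValueError("baseline accuracy is 0; relative improvement undefined")
    return 100.0 * (a - b) / b


def ablation_report(
    matrix: BinaryMutationMatrix,
    labels: CohortLabels,
    seeds: tuple[int, ...] = (0, 1, 2),
    k: int = 10,
    **kwargs,
) -> dict[str, float]:
    """Median cross-validation accuracy over seeds for the four input
    structures: both pre-processing steps, each alone, and raw input."""
    configs = {
        "cgf+isr": dict(use_cgf=True, use_isr=True),
        "cgf": dict(use_cgf=True, use_isr=False),
        "isr": dict(use_cgf=False, use_isr=True),
        "raw": dict(use_cgf=False, use_isr=False),
    }
    out = {}
    for name, flags in configs.items():
        accs = [
            crossval(matrix, labels, k=k, seed=s, **flags, **kwargs).accuracy
            for s in seeds
        ]
        out[name] = float(np.median(accs))
    return out
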