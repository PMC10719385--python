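"""Movement decoding model and results objects.

:class:`MovementDecoder` is built from per-session envelope series and event
tables for one sensor modality; ``fit()`` runs the stratified five-fold
cross-validated training of the residual 1-D convolutional classifier and
returns a :class:`DecodingResults` carrying per-fold predictions, accuracies,
loss curves, the trained networks, and diagnostics (confusion matrix,
channel-importance attribution, summary table).

Module-level functions (:func:`cross_validate`, :func:`compare_5x2`,
:func:`permuted_accuracy_pipeline`) operate on several modalities at once so
that the EMG and MMG models are evaluated on the same test windows — a
requirement for the agreement and McNemar statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .attribution import AttributionConfig, channel_importance
from .containers import CLASS_LABELS, Channel, EnvelopeSeries, EventTable, build_trial_table
from .nn import ModelConfig, ResidualConv1DNet
from .stats import CVFTestResult, five_by_two_ftest
from .util import child_seed
from .windows import FoldPlan, WindowDataset, build_fold_datasets, split_trials

__all__ = [
    "ModelConfig",
    "FoldResult",
    "DecodingResults",
    "MovementDecoder",
    "cross_validate",
    "compare_5x2",
    "permuted_accuracy_pipeline",
]


@dataclass
class FoldResult:
    """Predictions of one cross-validation fold."""

    fold: int
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray  # (N, F), rows sum to 1
    accuracy: float

    def __post_init__(self) -> None:
        if not np.allclose(self.proba.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("prediction probabilities must sum to 1 per window")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of [0, 1]")


class DecodingResults:
    """Cross-validation results for one modality.

    Attributes
    ----------
    fold_results : list of FoldResult
    networks : list of ResidualConv1DNet
        One trained network per fold (used for attribution).
    test_sets : list of WindowDataset
        The z-scored test windows each network was evaluated on.
    """

    def __init__(
        self,
        modality: str,
        config: ModelConfig,
        channels: list[Channel],
        plan: FoldPlan,
        fold_results: list[FoldResult],
        networks: list[ResidualConv1DNet],
        test_sets: list[WindowDataset],
        epochs: int,
    ):
        self.modality = modality
        self.config = config
        self.channels = channels
        self.plan = plan
        self.fold_results = fold_results
        self.networks = networks
        self.test_sets = test_sets
        self.epochs = epochs

    # -- headline numbers ------------------------------------------------ #
    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.fold_results])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def loss_curves(self) -> np.ndarray:
        return np.stack([net.loss_curve for net in self.networks])

    # -- pooled predictions (fold order) --------------------------------- #
    @property
    def y_true(self) -> np.ndarray:
        return np.concatenate([f.y_true for f in self.fold_results])

    @property
    def y_pred(self) -> np.ndarray:
        return np.concatenate([f.y_pred for f in self.fold_results])

    @property
    def proba(self) -> np.ndarray:
        return np.concatenate([f.proba for f in self.fold_results])

    def confusion_matrix(self) -> np.ndarray:
        """Pooled confusion matrix (rows: true class, columns: predicted)."""
        return _sk_confusion(self.y_true, self.y_pred, labels=range(len(CLASS_LABELS)))

    def predictions_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fold_results:
            for i in range(len(f.y_true)):
                rows.append(
                    {
                        "fold": f.fold,
                        "true": CLASS_LABELS[f.y_true[i]],
                        "pred": CLASS_LABELS[f.y_pred[i]],
                        **{f"p_{c}": f.proba[i, j] for j, c in enumerate(CLASS_LABELS)},
                    }
                )
        return pd.DataFrame(rows)

    # -- attribution ------------------------------------------------------ #
    def channel_importance(self, m: int = 6) -> pd.DataFrame:
        """Integrated-gradients channel importance, one row per fold and
        channel (signed and absolute variants)."""
        cfg = AttributionConfig(m=m)
        rows = []
        for net, ds in zip(self.networks, self.test_sets):
            res = channel_importance(net, ds.X, ds.y, cfg)
            for c, ch in enumerate(self.channels):
                rows.append(
                    {
                        "fold": len(rows) // len(self.channels),
                        "channel": ch.name,
                        "modality": ch.modality,
                        "axis": ch.axis,
                        "side": ch.side,
                        "importance": res.signed[c],
                        "importance_abs": res.absolute[c],
                    }
                )
        return pd.DataFrame(rows)

    # -- presentation ------------------------------------------------------ #
    def summary(self) -> str:
        cm = self.confusion_matrix()
        lines = [
            f"Movement decoding results ({self.modality})",
            "=" * 46,
            f"{'channels':<22}{self.config.C}",
            f"{'folds':<22}{self.plan.k}",
            f"{'epochs':<22}{self.epochs}",
            f"{'mean accuracy':<22}{self.mean_accuracy:.4f}",
            f"{'fold accuracies':<22}"
            + ", ".join(f"{a:.3f}" for a in self.fold_accuracies),
            "",
            "confusion matrix (rows: true, cols: predicted)",
            "      " + "".join(f"{c:>8}" for c in CLASS_LABELS),
        ]
        for i, c in enumerate(CLASS_LABELS):
            lines.append(f"{c:<6}" + "".join(f"{v:>8d}" for v in cm[i]))
        return "\n".join(lines)

    def plot_loss_curves(self, ax=None):
        """Per-fold training loss curves (categorical cross-entropy)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, curve in enumerate(self.loss_curves):
            ax.plot(curve, label=f"fold {i}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        ax.set_title(f"{self.modality} model")
        ax.legend()
        return ax


# ------------------------------------------------------------------------- #
# cross-validation engine (one or more modalities, shared test windows)
# ------------------------------------------------------------------------- #
def cross_validate(
    env_sets: dict[str, list[EnvelopeSeries]],
    events: list[EventTable],
    configs: dict[str, ModelConfig],
    k: int = 5,
    seed: int = 0,
    n_train: int = 500,
    n_test: int = 100,
    epochs: int | None = None,
    trial_len: float = 5.0,
    permute_seed: int | None = None,
) -> dict[str, DecodingResults]:
    """Stratified k-fold cross-validation over trials.

    Window positions are sampled once per fold and shared across modalities.
    One network per modality per fold is trained from scratch. When
    ``permute_seed`` is given, each fold's training labels are randomly
    permuted before training (the empirical-chance pipeline).
    """
    some = next(iter(env_sets.values()))
    session_lens = [e.duration for e in some]
    trials = build_trial_table(events, trial_len, session_lens)
    plan = split_trials(trials, k=k, seed=child_seed(seed, 101))

    folds: dict[str, list[FoldResult]] = {m: [] for m in env_sets}
    nets: dict[str, list[ResidualConv1DNet]] = {m: [] for m in env_sets}
    tests: dict[str, list[WindowDataset]] = {m: [] for m in env_sets}
    for fold in range(k):
        datasets = build_fold_datasets(
            env_sets, trials, plan, fold, n_train=n_train, n_test=n_test,
            seed=child_seed(seed, 202),
        )
        for mi, (modality, ds) in enumerate(sorted(datasets.items())):
            cfg = configs[modality]
            train, test = ds["train"], ds["test"]
            y_train = train.y
            if permute_seed is not None:
                rng = np.random.default_rng(child_seed(permute_seed, fold, mi))
                y_train = rng.permutation(y_train)
            net_seed = child_seed(seed, 303, fold, mi)
            net = ResidualConv1DNet(dataclasses.replace(cfg, seed=net_seed))
            net.fit(train.X, y_train, epochs=epochs, seed=child_seed(net_seed, 1))
            proba = net.predict_proba(test.X)
            y_pred = proba.argmax(axis=1)
            folds[modality].append(
                FoldResult(
                    fold=fold,
                    y_true=test.y,
                    y_pred=y_pred,
                    proba=proba,
                    accuracy=float(np.mean(y_pred == test.y)),
                )
            )
            nets[modality].append(net)
            tests[modality].append(test)

    used_epochs = epochs if epochs is not None else next(iter(configs.values())).epochs
    return {
        m: DecodingResults(
            modality=m,
            config=configs[m],
            channels=env_sets[m][0].channels,
            plan=plan,
            fold_results=folds[m],
            networks=nets[m],
            test_sets=tests[m],
            epochs=used_epochs,
        )
        for m in env_sets
    }


class MovementDecoder:
    """Finger-movement decoder for one sensor modality.

    Parameters
    ----------
    envelopes : list of EnvelopeSeries
        One 200 Hz envelope per recording session.
    events : list of EventTable
        Movement onsets per session, aligned with ``envelopes``.
    config : ModelConfig, optional
        Network and training hyperparameters; the channel count is taken
        from the envelopes.
    """

    def __init__(
        self,
        envelopes: list[EnvelopeSeries],
        events: list[EventTable],
        config: ModelConfig | None = None,
        trial_len: float = 5.0,
    ):
        if len(envelopes) != len(events):
            raise ValueError("need one event table per envelope session")
        mods = {c.modality for e in envelopes for c in e.channels}
        if len(mods) != 1:
            raise ValueError("all sessions must share one modality")
        self.modality = mods.pop()
        self.envelopes = envelopes
        self.events = events
        self.trial_len = trial_len
        C = envelopes[0].n_channels
        self.config = dataclasses.replace(config or ModelConfig(), C=C)

    @classmethod
    def from_recordings(cls, recordings, events, config=None, trial_len: float = 5.0, **pp):
        """Build a decoder directly from raw recordings (runs the
        preprocessing pipeline)."""
        from .preprocess import preprocess_recording

        envs = [preprocess_recording(r, **pp) for r in recordings]
        return cls(envs, events, config=config, trial_len=trial_len)

    def fit(
        self,
        k: int = 5,
        seed: int = 0,
        n_train: int = 500,
        n_test: int = 100,
        epochs: int | None = None,
        permute_seed: int | None = None,
    ) -> DecodingResults:
        """Run the stratified k-fold cross-validated training."""
        results = cross_validate(
            {self.modality: self.envelopes},
            self.events,
            {self.modality: self.config},
            k=k,
            seed=seed,
            n_train=n_train,
            n_test=n_test,
            epochs=epochs,
            trial_len=self.trial_len,
            permute_seed=permute_seed,
        )
        return results[self.modality]


def permuted_accuracy_pipeline(
    env_sets: dict[str, list[EnvelopeSeries]],
    events: list[EventTable],
    configs: dict[str, ModelConfig],
    modality: str,
    k: int = 5,
    seed: int = 0,
    n_train: int = 500,
    n_test: int = 100,
    epochs: int | None = None,
    trial_len: float = 5.0,
):
    """Statistic callable for :func:`mmgdecode.stats.permutation_null`:
    given a permutation seed, permutes the train labels, reruns the full
    cross-validation, and returns the mean accuracy."""

    def statistic(perm_seed: int) -> float:
        res = cross_validate(
            {modality: env_sets[modality]},
            events,
            {modality: configs[modality]},
            k=k,
            seed=seed,
            n_train=n_train,
            n_test=n_test,
            epochs=epochs,
            trial_len=trial_len,
            permute_seed=perm_seed,
        )
        return res[modality].mean_accuracy

    return statistic


def compare_5x2(
    env_sets: dict[str, list[EnvelopeSeries]],
    events: list[EventTable],
    configs: dict[str, ModelConfig],
    modality_a: str,
    modality_b: str,
    seed: int = 0,
    n_train: int = 500,
    n_test: int = 100,
    epochs: int | None = None,
    trial_len: float = 5.0,
) -> CVFTestResult:
    """5x2-CV F-test between two modality models.

    Five replications of a fresh stratified 50/50 trial split; in each
    replication both models are trained on each half and tested on the other,
    on the same test windows; the F statistic is computed from the 5x2 matrix
    of accuracy differences (modality A minus modality B).
    """
    some = next(iter(env_sets.values()))
    session_lens = [e.duration for e in some]
    trials = build_trial_table(events, trial_len, session_lens)
    labels = np.array([t.label for t in trials])

    d = np.empty((5, 2))
    for rep in range(5):
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=child_seed(seed, rep))
        plan = FoldPlan(k=2, folds=list(skf.split(np.zeros(len(trials)), labels)),
                        seed=child_seed(seed, rep))
        for j in range(2):
            datasets = build_fold_datasets(
                {m: env_sets[m] for m in (modality_a, modality_b)},
                trials, plan, j, n_train=n_train, n_test=n_test,
                seed=child_seed(seed, rep, j),
            )
            accs = {}
            for mi, m in enumerate((modality_a, modality_b)):
                cfg = dataclasses.replace(configs[m], seed=child_seed(seed, rep, j, mi))
                net = ResidualConv1DNet(cfg)
                train, test = datasets[m]["train"], datasets[m]["test"]
                net.fit(train.X, train.y, epochs=epochs, seed=child_seed(cfg.seed, 1))
                accs[m] = float(np.mean(net.predict(test.X) == test.y))
            d[rep, j] = accs[modality_a] - accs[modality_b]
    return five_by_two_ftest(d)
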