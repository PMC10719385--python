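"""Window sampling and dataset construction.

Classification operates on 100 ms windows of the 200 Hz envelope (20 samples
x C channels). Movement-class windows are drawn from 0-300 ms after each
movement onset, no-movement windows from -1500-0 ms before onset. Trials —
not windows — are the unit of the stratified k-fold split, so that no test
window shares a trial (and hence autocorrelated signal) with any training
window. Windows are z-scored with moments fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .containers import CLASS_LABELS, EnvelopeSeries, MOVEMENT_LABELS, Trial
from .util import child_seed

#: sampling intervals relative to movement onset, seconds
MOVE_INTERVAL = (0.0, 0.3)
NOMOVE_INTERVAL = (-1.5, 0.0)
#: window length, seconds
WIN_S = 0.1
#: session-edge guard: no window may start/end in the first/last 0.5 s
EDGE_GUARD_S = 0.5


@dataclass(frozen=True)
class WindowPosition:
    """A sampled window: session index and start sample at envelope rate."""

    session: int
    start: int  # sample index into the envelope
    trial: int  # global trial index (for leakage audits)


@dataclass
class FoldPlan:
    """Stratified k-fold partition of trials."""

    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_trial_idx, test_trial_idx)
    seed: int

    def __post_init__(self) -> None:
        for train, test in self.folds:
            if np.intersect1d(train, test).size:
                raise ValueError("train and test trials overlap within a fold")


def split_trials(trials: list[Trial], k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold split over trials (class proportions preserved)."""
    if k < 2:
        raise ValueError("k must be at least 2 to cross-validate")
    labels = np.array([t.label for t in trials])
    for lab in np.unique(labels):
        if np.sum(labels == lab) < k:
            raise ValueError(f"class {lab!r} has fewer trials than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(train, test) for train, test in skf.split(np.zeros(len(trials)), labels)]
    return FoldPlan(k=k, folds=folds, seed=seed)


def _admissible_range(
    trial: Trial,
    interval: tuple[float, float],
    win_s: float,
    fs: float,
    session_len: float,
    edge_guard: float,
) -> tuple[int, int] | None:
    """Inclusive range of admissible start samples, or None if empty.

    A window must lie inside [onset+interval[0], onset+interval[1]], inside its
    trial, and clear of the session-edge guard.
    """
    lo = max(trial.onset + interval[0], trial.trial_start, edge_guard)
    hi = min(trial.onset + interval[1], trial.trial_end, session_len - edge_guard) - win_s
    start_lo = int(np.ceil(lo * fs - 1e-9))
    start_hi = int(np.floor(hi * fs + 1e-9))
    if start_hi < start_lo:
        return None
    return start_lo, start_hi


def sample_window_positions(
    trials: list[Trial],
    trial_subset: np.ndarray,
    interval: tuple[float, float],
    n: int,
    fs: float,
    session_lens: list[float],
    win_s: float = WIN_S,
    edge_guard: float = EDGE_GUARD_S,
    seed: int = 0,
) -> list[WindowPosition]:
    """Sample ``n`` window start positions uniformly, with replacement, over
    all admissible (trial, start-sample) pairs of the given trial subset."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if interval[1] - interval[0] < win_s:
        raise ValueError("interval shorter than the window length")
    ranges = []
    for ti in trial_subset:
        t = trials[ti]
        r = _admissible_range(t, interval, win_s, fs, session_lens[t.session], edge_guard)
        if r is not None:
            ranges.append((int(ti), r[0], r[1]))
    if not ranges:
        raise ValueError("no eligible trials for the requested interval")
    counts = np.array([hi - lo + 1 for _, lo, hi in ranges])
    cum = np.cumsum(counts)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=n)
    positions = []
    for d in draws:
        i = int(np.searchsorted(cum, d, side="right"))
        ti, lo, _ = ranges[i]
        offset = int(d - (cum[i] - counts[i]))
        positions.append(WindowPosition(session=trials[ti].session, start=lo + offset, trial=ti))
    return positions


def extract_windows(
    envs: list[EnvelopeSeries], positions: list[WindowPosition], win_samples: int
) -> np.ndarray:
    """Materialize an N x T x C tensor from window positions."""
    out = np.empty((len(positions), win_samples, envs[0].n_channels))
    for i, p in enumerate(positions):
        seg = envs[p.session].data[:, p.start : p.start + win_samples]
        if seg.shape[1] != win_samples:
            raise ValueError("window extends past the end of the envelope")
        out[i] = seg.T
    return out


@dataclass
class Moments:
    """Per-feature (time x channel) mean and standard deviation, fitted on the
    training windows only."""

    mean: np.ndarray  # (T, C)
    sd: np.ndarray  # (T, C)


def zscore_fit(train_X: np.ndarray) -> Moments:
    """Fit z-scoring moments over the window (first) dimension of the train set."""
    if train_X.size == 0:
        raise ValueError("empty training set")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    zero = np.argwhere(sd == 0)
    if zero.size:
        t, c = zero[0]
        raise ValueError(f"zero standard deviation at feature (t={t}, channel={c})")
    return Moments(mean=mean, sd=sd)


def zscore_apply(X: np.ndarray, moments: Moments) -> np.ndarray:
    """Apply previously fitted moments (never refit on test data)."""
    return (X - moments.mean) / moments.sd


@dataclass
class WindowDataset:
    """Fixed-length windows with integer labels for one modality and split."""

    X: np.ndarray  # (N, T, C)
    y: np.ndarray  # (N,) integer codes into labels
    labels: tuple[str, ...]
    split: str  # "train" | "test"
    positions: list[WindowPosition]
    moments: Moments | None = None

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.positions):
            raise ValueError("X, y and positions must agree in length")

    @property
    def trial_ids(self) -> np.ndarray:
        return np.array([p.trial for p in self.positions])


def sample_fold_positions(
    trials: list[Trial],
    plan: FoldPlan,
    fold: int,
    fs: float,
    session_lens: list[float],
    n_train: int = 500,
    n_test: int = 100,
    win_s: float = WIN_S,
    seed: int = 0,
) -> dict[str, tuple[list[WindowPosition], np.ndarray]]:
    """Sample shared window positions (modality-independent) for one fold.

    Per split: ``n`` windows per class. Movement classes are drawn from their
    own trials 0-300 ms post-onset; no-movement windows -1500-0 ms pre-onset,
    in equal proportion from DII and DV trials.

    Returns ``{"train": (positions, y), "test": (positions, y)}`` with y as
    integer codes into :data:`~mmgdecode.containers.CLASS_LABELS`.
    """
    train_idx, test_idx = plan.folds[fold]
    labels = np.array([t.label for t in trials])
    out = {}
    for split, subset, n in (("train", train_idx, n_train), ("test", test_idx, n_test)):
        positions: list[WindowPosition] = []
        y: list[int] = []
        for ci, cls in enumerate(CLASS_LABELS):
            s = child_seed(seed, fold, {"train": 0, "test": 1}[split], ci)
            if cls in MOVEMENT_LABELS:
                sub = subset[labels[subset] == cls]
                pos = sample_window_positions(
                    trials, sub, MOVE_INTERVAL, n, fs, session_lens, win_s=win_s, seed=s
                )
            else:
                # NoMove: half from DII trials, half from DV trials
                pos = []
                for mi, mcls in enumerate(MOVEMENT_LABELS):
                    sub = subset[labels[subset] == mcls]
                    n_half = n // 2 if mi == 0 else n - n // 2
                    pos += sample_window_positions(
                        trials,
                        sub,
                        NOMOVE_INTERVAL,
                        n_half,
                        fs,
                        session_lens,
                        win_s=win_s,
                        seed=child_seed(s, mi),
                    )
            positions += pos
            y += [ci] * n
        out[split] = (positions, np.array(y))
    return out


def build_fold_datasets(
    env_sets: dict[str, list[EnvelopeSeries]],
    trials: list[Trial],
    plan: FoldPlan,
    fold: int,
    n_train: int = 500,
    n_test: int = 100,
    win_s: float = WIN_S,
    seed: int = 0,
) -> dict[str, dict[str, WindowDataset]]:
    """Build z-scored train/test datasets for one fold, for every modality.

    Window positions are sampled once and shared across modalities so that
    the modality models are later tested on the same windows (required for
    agreement and McNemar comparisons). Moments are fitted per modality on its
    train split and applied unchanged to its test split.
    """
    some_env = next(iter(env_sets.values()))
    fs = some_env[0].fs
    session_lens = [e.duration for e in some_env]
    win_samples = int(round(win_s * fs))
    shared = sample_fold_positions(
        trials, plan, fold, fs, session_lens, n_train=n_train, n_test=n_test, win_s=win_s, seed=seed
    )
    out: dict[str, dict[str, WindowDataset]] = {}
    for modality, envs in env_sets.items():
        train_pos, train_y = shared["train"]
        test_pos, test_y = shared["test"]
        X_train = extract_windows(envs, train_pos, win_samples)
        X_test = extract_windows(envs, test_pos, win_samples)
        moments = zscore_fit(X_train)
        out[modality] = {
            "train": WindowDataset(
                X=zscore_apply(X_train, moments),
                y=train_y,
                labels=CLASS_LABELS,
                split="train",
                positions=train_pos,
                moments=moments,
            ),
            "test": WindowDataset(
                X=zscore_apply(X_test, moments),
                y=test_y,
                labels=CLASS_LABELS,
                split="test",
                positions=test_pos,
                moments=moments,
            ),
        }
    return out
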