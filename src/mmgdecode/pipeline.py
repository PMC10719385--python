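"""End-to-end analysis driver.

``run_full_analysis`` sequences the whole study on synthetic (or user
supplied) data: generate the three-session experiment, preprocess both
modalities to 200 Hz envelopes, run the stratified five-fold cross-validated
training of the EMG and MMG classifiers on shared test windows, compute
integrated-gradients channel importances, the between-modality agreement
(consensus matrix, percentage agreement, Cohen's kappa), the McNemar test,
the 5x2-CV F-test, and (optionally) the permutation-based empirical chance
level with p-value and Cohen's d.  All randomness derives from one master
seed; artifacts are written with deterministic names and SHA-256 provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats
from .containers import CLASS_LABELS, EnvelopeSeries, EventTable
from .model import (
    DecodingResults,
    ModelConfig,
    compare_5x2,
    cross_validate,
    permuted_accuracy_pipeline,
)
from .preprocess import DEFAULT_BAND, DEFAULT_FS_OUT, DEFAULT_NOTCH, preprocess_recording
from .synthetic import GeneratorConfig, generate_experiment
from .util import child_seed


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    low: float = DEFAULT_BAND[0]
    high: float = DEFAULT_BAND[1]
    notch: tuple[float, float] = DEFAULT_NOTCH
    fs_out: float = DEFAULT_FS_OUT
    k: int = 5
    n_train: int = 500
    n_test: int = 100
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 100  # epochs for the main cross-validation
    n_perm: int = 100  # permutations for the empirical chance level (0 skips)
    perm_epochs: int = 10  # reduced epochs inside the permutation pipeline
    run_5x2: bool = True
    ig_levels: int = 6
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("gain_emg", "gain_mmg"):
            d["generator"][key] = np.asarray(d["generator"][key]).tolist()
        d["generator"]["emg_channels"] = [c["name"] for c in d["generator"]["emg_channels"]]
        d["generator"]["mmg_channels"] = [c["name"] for c in d["generator"]["mmg_channels"]]
        return d


@dataclass
class RunReport:
    """Everything the analysis produced, plus provenance."""

    results: dict[str, DecodingResults]
    importance: pd.DataFrame
    agreement: stats.AgreementResult
    mcnemar: stats.McNemarResult | None
    ftest: stats.CVFTestResult | None
    nulls: dict[str, stats.NullDistribution]
    pvalues: dict[str, stats.PermutationPValue]
    effect_sizes: dict[str, float]
    permutation_skipped: bool
    config: RunConfig
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def summary_dict(self) -> dict:
        out: dict = {
            "accuracy": {m: r.mean_accuracy for m, r in self.results.items()},
            "fold_accuracies": {m: r.fold_accuracies.tolist() for m, r in self.results.items()},
            "percentage_agreement": self.agreement.percentage_agreement,
            "kappa": self.agreement.kappa,
            "consensus_matrix": self.agreement.matrix.tolist(),
            "permutation_skipped": self.permutation_skipped,
            "seed": self.config.seed,
        }
        if self.mcnemar is not None:
            out["mcnemar"] = {
                "chi2": self.mcnemar.chi2, "b": self.mcnemar.b, "c": self.mcnemar.c,
                "p": self.mcnemar.p_value, "cohens_g": self.mcnemar.cohens_g,
            }
        if self.ftest is not None:
            out["ftest_5x2"] = {
                "f": self.ftest.f_statistic, "p": self.ftest.p_value,
                "df": list(self.ftest.df),
            }
        if not self.permutation_skipped:
            out["permutation"] = {
                m: {
                    "null_mean": float(np.mean(self.nulls[m].values)),
                    "null_sd": float(np.std(self.nulls[m].values, ddof=1)),
                    "p": self.pvalues[m].display,
                    "cohens_d": self.effect_sizes[m],
                }
                for m in self.nulls
            }
        return out


def movement_locked_average(
    env: EnvelopeSeries,
    events: EventTable,
    window: tuple[float, float] = (1.0, 2.5),
    labels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-channel mean envelope time-locked to movement onsets.

    ``window = (pre_s, post_s)``: averages run from ``onset - pre_s`` to
    ``onset + post_s``. Returns (times relative to onset, {label: C x n_t}).
    """
    pre, post = window
    n_pre = int(round(pre * env.fs))
    n_post = int(round(post * env.fs))
    times = np.arange(-n_pre, n_post) / env.fs
    wanted = labels if labels is not None else tuple(dict.fromkeys(events.labels))
    out = {}
    for lab in wanted:
        idx = np.where(events.labels == lab)[0]
        if idx.size == 0:
            raise ValueError(f"no events with label {lab!r}")
        segs = []
        for i in idx:
            c = int(round(events.onsets[i] * env.fs))
            if c - n_pre < 0 or c + n_post > env.n_samples:
                raise ValueError("averaging window extends past the recording bounds")
            segs.append(env.data[:, c - n_pre : c + n_post])
        out[lab] = np.mean(segs, axis=0)
    return times, out


def _movement_locked_frame(
    envs: list[EnvelopeSeries], events: list[EventTable], window=(0.25, 2.5)
) -> pd.DataFrame:
    """Session-aggregated movement-locked average envelopes, long format."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    times = None
    for env, ev in zip(envs, events):
        present = tuple(dict.fromkeys(ev.labels))
        times, avg = movement_locked_average(env, ev, window=window, labels=present)
        for lab in present:
            n = int(np.sum(ev.labels == lab))
            sums[lab] = sums.get(lab, 0.0) + avg[lab] * n
            counts[lab] = counts.get(lab, 0) + n
    rows = []
    channels = envs[0].channels
    for lab, total in sums.items():
        mean = total / counts[lab]
        for c, ch in enumerate(channels):
            for ti, t in enumerate(times):
                rows.append(
                    {"label": lab, "channel": ch.name, "time_s": float(t),
                     "envelope": float(mean[c, ti])}
                )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline; see the module docstring."""
    # 1. simulate
    sessions = generate_experiment(cfg.generator, seed=cfg.seed)
    events = [ev for _, _, ev in sessions]

    # 2. preprocess
    env_sets: dict[str, list[EnvelopeSeries]] = {"EMG": [], "MMG": []}
    for rec_emg, rec_mmg, _ in sessions:
        for mod, rec in (("EMG", rec_emg), ("MMG", rec_mmg)):
            env_sets[mod].append(
                preprocess_recording(
                    rec, low=cfg.low, high=cfg.high, notch=cfg.notch, fs_out=cfg.fs_out
                )
            )

    configs = {
        m: dataclasses.replace(cfg.model, C=env_sets[m][0].n_channels) for m in env_sets
    }

    # 3. cross-validated training, shared test windows across modalities
    results = cross_validate(
        env_sets, events, configs,
        k=cfg.k, seed=cfg.seed, n_train=cfg.n_train, n_test=cfg.n_test,
        epochs=cfg.epochs, trial_len=cfg.generator.trial_len,
    )

    # 4. attribution
    frames = []
    for m, res in results.items():
        f = res.channel_importance(m=cfg.ig_levels)
        frames.append(f)
    importance = pd.concat(frames, ignore_index=True)

    # 5. agreement + McNemar between the two modality models (same windows)
    emg, mmg = results["EMG"], results["MMG"]
    agree = stats.agreement(emg.y_pred, mmg.y_pred, n_classes=len(CLASS_LABELS))
    try:
        mcn = stats.mcnemar(emg.y_pred, mmg.y_pred, emg.y_true)
    except ValueError:
        mcn = None  # no discordant predictions

    # 6. 5x2-CV F-test
    ftest = None
    if cfg.run_5x2:
        ftest = compare_5x2(
            env_sets, events, configs, "EMG", "MMG",
            seed=child_seed(cfg.seed, 52), n_train=cfg.n_train, n_test=cfg.n_test,
            epochs=cfg.epochs, trial_len=cfg.generator.trial_len,
        )

    # 7. permutation-based empirical chance level
    nulls: dict[str, stats.NullDistribution] = {}
    pvals: dict[str, stats.PermutationPValue] = {}
    ds: dict[str, float] = {}
    skipped = cfg.n_perm == 0
    if not skipped:
        for m in results:
            pipe = permuted_accuracy_pipeline(
                env_sets, events, configs, m,
                k=cfg.k, seed=cfg.seed, n_train=cfg.n_train, n_test=cfg.n_test,
                epochs=cfg.perm_epochs, trial_len=cfg.generator.trial_len,
            )
            nulls[m] = stats.permutation_null(pipe, cfg.n_perm, seed=child_seed(cfg.seed, 77))
            pvals[m] = stats.perm_pvalue(results[m].mean_accuracy, nulls[m])
            ds[m] = stats.cohens_d_vs_null(results[m].mean_accuracy, nulls[m])

    report = RunReport(
        results=results, importance=importance, agreement=agree, mcnemar=mcn,
        ftest=ftest, nulls=nulls, pvalues=pvals, effect_sizes=ds,
        permutation_skipped=skipped, config=cfg,
    )
    if cfg.out_dir is not None:
        _write_artifacts(report, Path(cfg.out_dir), env_sets, events)
    return report


def _write_artifacts(report: RunReport, out: Path, env_sets=None, events=None) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(report.config.to_dict()))
    report.importance.to_csv(out / "importance.tsv", sep="\t", index=False)
    if env_sets is not None:
        for m, envs in env_sets.items():
            _movement_locked_frame(envs, events).to_csv(
                out / f"movement_locked_{m}.tsv", sep="\t", index=False
            )
    pd.DataFrame(
        report.agreement.matrix,
        index=[f"EMG_{c}" for c in CLASS_LABELS],
        columns=[f"MMG_{c}" for c in CLASS_LABELS],
    ).to_csv(out / "consensus.tsv", sep="\t")
    for m, res in report.results.items():
        res.predictions_frame().to_csv(out / f"predictions_{m}.tsv", sep="\t", index=False)

    artifacts = {}
    for p in sorted(out.iterdir()):
        if p.name != "report.json":
            artifacts[p.name] = _sha256(p)
    report.artifacts = artifacts

    payload = report.summary_dict()
    payload["provenance"] = {
        "seed": report.config.seed,
        "config_sha256": _sha256(cfg_path),
        "artifacts": artifacts,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))


def verify_artifacts(out_dir: str | Path) -> None:
    """Re-hash every artifact recorded in report.json; raise on mismatch."""
    out = Path(out_dir)
    payload = json.loads((out / "report.json").read_text())
    for name, digest in payload["provenance"]["artifacts"].items():
        actual = _sha256(out / name)
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name}: expected {digest}, got {actual}")
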