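"""Wake/sleep classification of 30 s EDR epochs and total sleep time.

Epochs are cut from the 4 Hz EDR grid (120 samples, channels heart period
and R-wave amplitude). The default stager is a logistic regression on
summary features (mean heart rate, heart-period SD, RWA variance and mean)
— wake epochs carry a faster, more variable rhythm and noisier amplitudes
than sleep — with an optional MLP head for a nonlinear decision surface.
It is trained on synthetic labeled studies; a harness, not frozen clinical
weights. Predicted labels are median-smoothed (5 epochs) for physiological
continuity, and TST is 30 s times the number of sleep epochs.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .config import StagingConfig
from .edr import EdrSet

FEATURES = ("hr_mean_bpm", "hrv_sd_s", "rwa_var", "rwa_mean")


@dataclass
class EpochSet:
    """Per-epoch tensors and summary features."""

    onsets: np.ndarray            # epoch start times (s)
    tensors: np.ndarray           # (n, 2, samples) z-scored per channel
    features: np.ndarray          # (n, len(FEATURES)) raw summary features
    scorable: np.ndarray          # False where gaps dominate the epoch

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class Hypnogram:
    labels: list[str]             # {wake, sleep, unscored}
    epoch_s: float = 30.0

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class StagerModel:
    model: object
    kind: str
    config_hash: str
    feature_names: tuple[str, ...] = FEATURES

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_bytes(pickle.dumps(self.model, protocol=4))
        meta = {"kind": self.kind, "config_hash": self.config_hash,
                "feature_names": list(self.feature_names)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "StagerModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(model=pickle.loads(path.read_bytes()), kind=meta["kind"],
                   config_hash=meta["config_hash"],
                   feature_names=tuple(meta["feature_names"]))


def epoch_edr(edr: EdrSet, cfg: StagingConfig | None = None) -> EpochSet:
    """Cut the EDR grid into 30 s epochs with tensors and summary features."""
    cfg = cfg or StagingConfig()
    spe = int(round(cfg.epoch_s * edr.grid_hz))
    n_ep = int(np.ceil(edr.t.size / spe)) if edr.t.size else 0
    onsets, tensors, features, scorable = [], [], [], []
    for i in range(n_ep):
        sl = slice(i * spe, (i + 1) * spe)
        hrv, rwa, gap = edr.hrv[sl], edr.rwa[sl], edr.gap_mask[sl]
        pad = spe - hrv.size
        if pad:
            hrv = np.pad(hrv, (0, pad), constant_values=np.nan)
            rwa = np.pad(rwa, (0, pad), constant_values=np.nan)
            gap = np.pad(gap, (0, pad), constant_values=True)
        ok = ~gap
        onsets.append(i * cfg.epoch_s)
        if gap.mean() > cfg.max_gap_fraction or ok.sum() < 8:
            tensors.append(np.zeros((2, spe)))
            features.append(np.zeros(len(FEATURES)))
            scorable.append(False)
            continue
        h, r = hrv[ok], rwa[ok]
        feats = [60.0 / h.mean() if h.mean() > 0 else 0.0, h.std(), r.var(), r.mean()]
        chans = []
        for x in (hrv, rwa):
            x = np.where(np.isfinite(x), x, np.nanmean(x))
            sd = x.std()
            chans.append((x - x.mean()) / sd if sd > 0 else np.zeros(spe))
        tensors.append(np.stack(chans))
        features.append(feats)
        scorable.append(True)
    return EpochSet(
        onsets=np.asarray(onsets), tensors=np.asarray(tensors),
        features=np.asarray(features, dtype=float), scorable=np.asarray(scorable),
    )


def train_stager(
    epochs: EpochSet,
    labels: np.ndarray,
    seed: int = 0,
    cfg: StagingConfig | None = None,
) -> StagerModel:
    """Fit the wake/sleep classifier on labeled epochs (1 = sleep)."""
    cfg = cfg or StagingConfig()
    y = np.asarray(labels)
    X = epochs.features[epochs.scorable]
    y = y[epochs.scorable]
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both wake and sleep epochs")
    if cfg.model == "logistic":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    elif cfg.model == "mlp":
        model = MLPClassifier(hidden_layer_sizes=(16, 8), max_iter=1500,
                              random_state=seed)
    else:
        raise ValueError(f"unknown stager model {cfg.model!r}")
    # per-feature scaling baked into the artifact for portability
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    model.fit((X - mu) / sd, y)
    payload = {"model": model, "mu": mu, "sd": sd}
    h = hashlib.sha256(
        json.dumps({"model": cfg.model, "seed": seed, "n": int(y.size)},
                   sort_keys=True).encode()
    ).hexdigest()[:16]
    return StagerModel(model=payload, kind=cfg.model, config_hash=h)


def classify_epochs(
    epochs: EpochSet,
    stager: StagerModel,
    cfg: StagingConfig | None = None,
) -> Hypnogram:
    cfg = cfg or StagingConfig()
    payload = stager.model
    X = epochs.features
    if X.shape[1] != payload["mu"].size:
        raise ValueError("epoch feature shape does not match the trained model")
    pred = np.zeros(len(epochs), dtype=int)
    if epochs.scorable.any():
        Xs = (X[epochs.scorable] - payload["mu"]) / payload["sd"]
        pred[epochs.scorable] = payload["model"].predict(Xs).astype(int)
    if cfg.smooth_epochs > 1 and epochs.scorable.any():
        sm = ndimage.median_filter(pred, size=cfg.smooth_epochs, mode="nearest")
        pred = np.where(epochs.scorable, sm, pred)
    labels = [
        ("sleep" if p else "wake") if ok else "unscored"
        for p, ok in zip(pred, epochs.scorable)
    ]
    return Hypnogram(labels=labels, epoch_s=cfg.epoch_s)


def total_sleep_time(h: Hypnogram) -> float:
    """TST in hours: epoch length times the number of sleep epochs."""
    return h.epoch_s * sum(1 for l in h.labels if l == "sleep") / 3600.0


# ------------------------------------------------- synthetic training data

def synthetic_training_set(
    seed: int = 2024,
    n_studies: int = 2,
    duration_h: float = 3.0,
    cfg: StagingConfig | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Labeled epochs from synthetic studies, via the truth beat stream.

    Uses the generator's beat times/amplitudes directly (no waveform
    rendering), which keeps the harness fast while exposing the same
    heart-rate and amplitude contrasts the pipeline sees.
    """
    from .intervals import Interval  # noqa: F401  (doc cross-ref)
    from .rhythm import AnalyzableSegments, Beat, BeatSeries
    from .edr import extract_edr
    from .synth import SynthConfig, simulate_rr

    all_feats, all_tensors, all_onsets, all_scorable, labels = [], [], [], [], []
    for k in range(n_studies):
        scfg = SynthConfig(duration_h=duration_h, target_ahi=10.0 + 10.0 * k,
                           seed=int(seed) + 7919 * k, ectopic_rate_per_h=0.0)
        sim = simulate_rr(scfg)
        beats = []
        prev = None
        for t, s, w in zip(sim.times, sim.scales, sim.widths):
            beats.append(Beat(qrs_onset=t - w / 2, r_peak=t, qrs_offset=t + w / 2,
                              height=scfg.r_amp_mv * s, width=w,
                              rr_prev=None if prev is None else t - prev))
            prev = t
        bs = BeatSeries(beats)
        seg = AnalyzableSegments(intervals=[(0.0, duration_h * 3600.0)],
                                 duration=duration_h * 3600.0)
        edr = extract_edr(bs, None, seg, series=("hrv", "rwa"))
        eps = epoch_edr(edr, cfg)
        truth = np.array([1 if l == "sleep" else 0 for l in sim.hypnogram])
        n = min(len(eps), truth.size)
        all_feats.append(eps.features[:n])
        all_tensors.append(eps.tensors[:n])
        all_onsets.append(eps.onsets[:n])
        all_scorable.append(eps.scorable[:n])
        labels.append(truth[:n])
    eps = EpochSet(
        onsets=np.concatenate(all_onsets), tensors=np.concatenate(all_tensors),
        features=np.concatenate(all_feats), scorable=np.concatenate(all_scorable),
    )
    return eps, np.concatenate(labels)


_DEFAULT_STAGER: dict[tuple, StagerModel] = {}


def default_stager(cfg: StagingConfig | None = None) -> StagerModel:
    """Process-cached stager trained on the synthetic harness."""
    cfg = cfg or StagingConfig()
    key = (cfg.model, cfg.train_seed)
    if key not in _DEFAULT_STAGER:
        eps, y = synthetic_training_set(seed=cfg.train_seed, cfg=cfg)
        _DEFAULT_STAGER[key] = train_stager(eps, y, seed=cfg.train_seed, cfg=cfg)
    return _DEFAULT_STAGER[key]
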