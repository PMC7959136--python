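"""Evaluation metrics, MCC-driven training and k-fold cross-validation.

Evaluation is at the *scenario* level: one binary verdict per labelled
recording (a recording is positive when the detection signal fires at least
once), because reference corpora label whole scenario executions, not
samples.

The binary-test metrics are the detection probability PD = TP/P, the
false-alarm probability PFA = FP/N, the accuracy (TP+TN)/(P+N), and the
Matthews correlation coefficient

.. math::

    MCC = (TP \\cdot TN - FP \\cdot FN) /
          \\sqrt{(TP+FP)(TP+FN)(TN+FP)(TN+FN)}

with MCC defined as 0 whenever a denominator factor vanishes.  MCC is the
training objective for detection thresholds and window sizes; the down
threshold instead fixes the miss rate (PD target 0.99) on state-positive
training scenarios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .detectors import (
    DetectorBank,
    DetectorConfig,
    FeatureSpec,
    default_bank,
    fall_likelihood,
    immobility_likelihood,
    run_pipeline,
)
from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    MandownError,
    UndefinedRateError,
)
from .features import ExtremeValueSignal
from .imu_core import FeatureSignals, compute_features
from .io_formats import ImuRecording
from .statmodels import fit_auto

logger = logging.getLogger(__name__)

METRICS = ("pd", "pfa", "mcc", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    """Scenario-level confusion counts with the derived binary-test rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.p + self.n < 1:
            raise ValueError("need at least one labelled scenario")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def pd(self) -> float:
        if self.p == 0:
            raise UndefinedRateError("PD undefined without positives")
        return self.tp / self.p

    @property
    def pfa(self) -> float:
        if self.n == 0:
            raise UndefinedRateError("PFA undefined without negatives")
        return self.fp / self.n

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.p + self.n)

    @property
    def mcc(self) -> float:
        factors = ((self.tp + self.fp), (self.tp + self.fn),
                   (self.tn + self.fp), (self.tn + self.fn))
        if 0 in factors:
            return 0.0
        num = self.tp * self.tn - self.fp * self.fn
        return num / math.sqrt(math.prod(factors))


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(PD, PFA, accuracy, MCC) of a confusion table."""
    return (c.pd, c.pfa, c.accuracy, c.mcc)


def scenario_confusion(verdicts, labels) -> ConfusionCounts:
    """Tally scenario-level counts from aligned verdict/label sequences.

    Both arguments may be mappings keyed by recording id or plain aligned
    sequences of booleans."""
    if isinstance(verdicts, dict) or isinstance(labels, dict):
        if not (isinstance(verdicts, dict) and isinstance(labels, dict)):
            raise MandownError("mixing keyed and positional verdicts")
        if set(verdicts) != set(labels):
            missing = set(verdicts).symmetric_difference(labels)
            raise MandownError(f"verdict/label ids do not match: {sorted(missing)}")
        keys = sorted(verdicts)
        v = np.array([bool(verdicts[k]) for k in keys])
        y = np.array([bool(labels[k]) for k in keys])
    else:
        v = np.asarray(verdicts, dtype=bool)
        y = np.asarray(labels, dtype=bool)
        if v.shape != y.shape:
            raise MandownError("verdicts and labels differ in length")
    return ConfusionCounts(
        tp=int(np.sum(v & y)), fp=int(np.sum(v & ~y)),
        tn=int(np.sum(~v & ~y)), fn=int(np.sum(~v & y)),
    )


# ---------------------------------------------------------------------------
# threshold and window optimization

def _mcc_at(scores: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    return scenario_confusion(scores > gamma, labels).mcc


def optimize_threshold(scores, labels, grid=None) -> tuple[float, float]:
    """Pick the detection threshold maximizing scenario-level MCC.

    *scores* are per-recording peak likelihoods; a recording's verdict is
    ``peak > gamma`` (strict).  The default grid places candidates at the
    midpoints between consecutive sorted unique peaks, plus one sentinel
    below the smallest and one above the largest peak so the all-positive
    and all-negative decisions are always on the grid; ties in MCC resolve
    to the smallest gamma.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise MandownError("scores and labels differ in length")
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("threshold training needs both classes")
    if grid is None:
        u = np.unique(scores)
        margin = max(np.ptp(u), 1.0) * 1e-3
        grid = np.concatenate([[u[0] - margin], (u[:-1] + u[1:]) / 2.0,
                               [u[-1] + margin]])
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise MandownError("empty threshold grid")
    mccs = np.array([_mcc_at(scores, labels, g) for g in grid])
    best = int(np.argmax(mccs))  # argmax takes the first (smallest) maximizer
    return float(grid[best]), float(mccs[best])


def train_down_threshold(peaks, pd_target: float = 0.99) -> float:
    """Down threshold from the miss-rate target.

    gamma_D is placed at the ``(1 - pd_target)`` quantile of the tilt
    extreme-value peaks of state-positive training scenarios, so the
    training-set detection rate (strict ``>``) is at least *pd_target*.
    """
    peaks = np.sort(np.asarray(peaks, dtype=float))
    if peaks.size == 0:
        raise InsufficientDataError("no down-positive scenarios to train on")
    k = int(np.floor(peaks.size * (1.0 - pd_target)))
    if k >= 1:
        gamma = float(peaks[k - 1])
    else:
        gamma = float(peaks[0]) - 1e-6 * max(1.0, abs(peaks[0]))
    return float(np.clip(gamma, 0.0, np.pi))


# ---------------------------------------------------------------------------
# corpus-level training

class _Corpus:
    """Cached per-recording features and extreme-value signals."""

    def __init__(self, recordings: list[ImuRecording],
                 feats: list[FeatureSignals] | None = None,
                 filter_gain: float | None = None):
        self.recordings = recordings
        if feats is None:
            kw = {} if filter_gain is None else {"gain": filter_gain}
            feats = [compute_features(r, **kw) for r in recordings]
        self.feats = feats
        self._cache: list[dict[str, ExtremeValueSignal]] = [dict() for _ in recordings]

    def __len__(self) -> int:
        return len(self.recordings)

    def extreme(self, i: int, spec: FeatureSpec) -> ExtremeValueSignal:
        cache = self._cache[i]
        if spec.key not in cache:
            cache[spec.key] = spec.compute(self.feats[i])
        return cache[spec.key]

    def state_labels(self, state: str) -> np.ndarray:
        return np.array([r.has_state(state) for r in self.recordings])

    def mds_labels(self) -> np.ndarray:
        return np.array([bool(r.is_mds) for r in self.recordings])


def _likelihood(corpus: _Corpus, i: int, cfg: DetectorConfig) -> np.ndarray:
    E = [corpus.extreme(i, spec) for spec in cfg.features]
    fs = corpus.feats[i].fs
    if cfg.state == "F":
        return fall_likelihood(E, cfg, fs)
    return immobility_likelihood(E, cfg, fs)


def _train_state(corpus: _Corpus, idx: np.ndarray,
                 cfg: DetectorConfig) -> DetectorConfig:
    """Fit per-feature models on state-positive recordings and optimize the
    detection threshold by scenario-level MCC (fall/immobility), or by the
    miss-rate target (down)."""
    labels = corpus.state_labels(cfg.state)[idx]
    if not labels.any():
        raise DegenerateLabelsError(
            f"no {cfg.state}-positive recordings in the training set")
    pos = idx[labels]

    if cfg.state == "D":
        spec = cfg.features[0]
        peaks = [corpus.extreme(i, spec).peak() for i in pos]
        gamma = train_down_threshold(peaks)
        return DetectorConfig(cfg.state, cfg.features, gamma=gamma)

    if not (~labels).any():
        raise DegenerateLabelsError(
            f"no {cfg.state}-negative recordings in the training set")
    models = {}
    for spec in cfg.features:
        sample = np.array([corpus.extreme(i, spec).peak() for i in pos])
        models[spec.key] = fit_auto(sample)
    fitted = DetectorConfig(cfg.state, cfg.features, gamma=0.0,
                            fusion_ms=cfg.fusion_ms, models=models)
    peaks = np.array([_likelihood(corpus, i, fitted).max() for i in idx])
    gamma, mcc = optimize_threshold(peaks, labels)
    gamma = max(gamma, 0.0)  # likelihoods live in [0, 1]
    logger.info("state %s: gamma=%.4g training MCC=%.3f", cfg.state, gamma, mcc)
    return DetectorConfig(cfg.state, cfg.features, gamma=gamma,
                          fusion_ms=cfg.fusion_ms, models=models)


def train_detector_bank(recordings: list[ImuRecording],
                        bank: DetectorBank | None = None,
                        allow_partial: bool = False,
                        _corpus: _Corpus | None = None,
                        _idx: np.ndarray | None = None,
                        ) -> tuple[DetectorBank, dict[str, MandownError]]:
    """Train all three state detectors on a labelled corpus.

    Returns the fitted bank and a mapping of per-state training errors.
    With ``allow_partial=False`` any state failure raises; otherwise the
    failing state is left out (``None`` in the bank) and detection falls
    back to the remaining MDS pathways.
    """
    template = bank if bank is not None else default_bank()
    corpus = _corpus if _corpus is not None else _Corpus(recordings)
    idx = _idx if _idx is not None else np.arange(len(corpus))
    trained: dict[str, DetectorConfig | None] = {}
    errors: dict[str, MandownError] = {}
    for name, cfg in (("fall", template.fall),
                      ("immobility", template.immobility),
                      ("down", template.down)):
        if cfg is None:
            trained[name] = None
            continue
        try:
            trained[name] = _train_state(corpus, idx, cfg)
        except MandownError as exc:
            if not allow_partial:
                raise
            logger.warning("state %s not trained: %s", cfg.state, exc)
            trained[name] = None
            errors[cfg.state] = exc
    return DetectorBank(fall=trained["fall"], immobility=trained["immobility"],
                        down=trained["down"], comb=template.comb), errors


def optimize_window(recordings: list[ImuRecording], state: str,
                    feature_index: int, candidates,
                    bank: DetectorBank | None = None) -> tuple[float, float]:
    """Marginal window-size search for one feature of one state detector.

    For every candidate tau the extreme-value signal is recomputed, the
    models refit and the threshold re-optimized; the tau with the best
    training MCC wins (ties resolve to the smallest tau).
    """
    candidates = sorted(float(c) for c in candidates)
    if not candidates:
        raise MandownError("no window candidates")
    template = bank if bank is not None else default_bank()
    attr = {"F": "fall", "I": "immobility", "D": "down"}[state]
    base_cfg: DetectorConfig = getattr(template, attr)
    corpus = _Corpus(recordings)
    idx = np.arange(len(corpus))
    labels = corpus.state_labels(state)
    best: tuple[float, float] | None = None
    for tau in candidates:
        feats = list(base_cfg.features)
        old = feats[feature_index]
        feats[feature_index] = FeatureSpec(old.source, old.statistic,
                                           old.extremum, tau)
        cfg = DetectorConfig(state, tuple(feats), gamma=base_cfg.gamma,
                             fusion_ms=base_cfg.fusion_ms)
        fitted = _train_state(corpus, idx, cfg)
        if state == "D":
            verdicts = np.array([
                bool((corpus.extreme(i, fitted.features[0]).values
                      > fitted.gamma).any()) for i in idx])
            mcc = scenario_confusion(verdicts, labels).mcc
        else:
            peaks = np.array([_likelihood(corpus, i, fitted).max() for i in idx])
            mcc = scenario_confusion(peaks > fitted.gamma, labels).mcc
        if best is None or mcc > best[1]:
            best = (tau, mcc)
    return best


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CvResult:
    """Per-fold metrics plus their mean and standard deviation."""

    per_fold: pd.DataFrame
    summary: pd.DataFrame

    def mean(self, state: str, metric: str) -> float:
        return float(self.summary.loc[state, f"{metric}_mean"])

    def sd(self, state: str, metric: str) -> float:
        return float(self.summary.loc[state, f"{metric}_sd"])


def _evaluate_fold(corpus: _Corpus, test_idx: np.ndarray,
                   bank: DetectorBank) -> dict[str, ConfusionCounts]:
    """MDS confusion of the fused detector on held-out recordings, plus the
    confusion each single-state detector would earn if used alone as the
    MDS alarm (the false-alarm-suppression comparison)."""
    mds_labels = corpus.mds_labels()[test_idx]
    verdicts: dict[str, list[bool]] = {k: [] for k in ("MDS", "F", "I", "D")}
    for i in test_idx:
        result = run_pipeline(corpus.feats[i], bank, E_cache=corpus._cache[i])
        sv = result.state_verdicts()
        for k in verdicts:
            verdicts[k].append(sv[k])
    return {k: scenario_confusion(np.array(v), mds_labels)
            for k, v in verdicts.items()}


def kfold_cv(recordings: list[ImuRecording], k: int = 10, seed: int = 42,
             bank: DetectorBank | None = None,
             filter_gain: float | None = None) -> CvResult:
    """Stratified k-fold cross-validation of the full MDS pipeline.

    Folds are stratified by scenario label with a fixed shuffling seed.
    Each fold trains the models and thresholds on the remaining folds and
    evaluates scenario-level MDS detection on the held-out recordings;
    single-state detectors are also scored against the MDS labels to
    quantify how much combinatorial fusion suppresses false alarms.
    """
    if len(recordings) < 2 * k:
        raise InsufficientDataError(
            f"{len(recordings)} recordings cannot support {k}-fold CV")
    corpus = _Corpus(recordings, filter_gain=filter_gain)
    strata = [r.label for r in recordings]
    mds = corpus.mds_labels()
    if mds.all() or not mds.any():
        raise DegenerateLabelsError("cross-validation needs both MDS classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(len(corpus)), strata)):
        fold_bank, _ = train_detector_bank(
            recordings, bank=bank, allow_partial=False,
            _corpus=corpus, _idx=train_idx)
        confusions = _evaluate_fold(corpus, test_idx, fold_bank)
        for state, c in confusions.items():
            rows.append({
                "fold": fold, "state": state,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "pd": c.pd, "pfa": c.pfa,
                "mcc": c.mcc, "accuracy": c.accuracy,
            })
        logger.info("fold %d: MDS PD=%.3f PFA=%.3f",
                    fold, confusions["MDS"].pd, confusions["MDS"].pfa)
    per_fold = pd.DataFrame(rows)
    agg = per_fold.groupby("state")[list(METRICS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}".replace("_std", "_sd") for m, s in agg.columns]
    return CvResult(per_fold=per_fold, summary=agg)
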