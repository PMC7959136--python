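"""Critical-state detectors, combinatorial fusion and the MDS decision.

Three critical states are detected from the extreme-value signals:

* **Fall (F)** — the product, over four features (min/max of the windowed
  mean acceleration norm, max of the windowed mean rotational-speed norm,
  max of the windowed mean tilt rate), of the *maximum* normalized density
  over a common fusion window; a fall fires where this likelihood strictly
  exceeds the threshold gamma_F.
* **Immobility (I)** — the product, over three log10-variance minima
  features, of the *mean* normalized density over the fusion window
  (immobility is sustained, not transient), thresholded by gamma_I.
* **Down (D)** — the max of the windowed mean tilt angle thresholded
  directly at gamma_D radians (no statistical model; the threshold is set
  from the detection-rate target during training).

Pairwise combinatorial states apply a windowed logical AND over ANY
occurrence: ``y_ab(t) = 1`` iff both y_a and y_b fire at least once inside
the closed window ``[t, t + tau_ab]`` — the order of the two states inside
the window is deliberately irrelevant.  The man-down decision is the
inclusive OR of the three pairwise states; a recording is classified MDS
iff the decision signal fires at least once.

Windows at the end of a recording are truncated rather than padded, so the
last samples still carry (flagged) detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AlignmentError, WindowTooLongError
from .features import (
    LOG_VARIANCE,
    MEAN,
    ExtremeValueSignal,
    extreme_value_signal,
    window_samples,
)
from .imu_core import FeatureSignals
from .statmodels import DistributionModel, normalized_pdf

STATES = ("F", "I", "D")
PAIR_STATES = ("F-D", "F-I", "I-D")


@dataclass(frozen=True)
class FeatureSpec:
    """One extreme-value feature: source signal, statistic, extremum, window."""

    source: str
    statistic: str
    extremum: str
    tau_ms: float

    def __post_init__(self):
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")

    @property
    def key(self) -> str:
        return f"{self.source}:{self.statistic}:{self.extremum}:{self.tau_ms:g}"

    def compute(self, feats: FeatureSignals) -> ExtremeValueSignal:
        return extreme_value_signal(feats.get(self.source), self.tau_ms,
                                    self.statistic, self.extremum, feats.fs,
                                    source=self.source)

    def to_dict(self) -> dict:
        return {"source": self.source, "statistic": self.statistic,
                "extremum": self.extremum, "tau_ms": float(self.tau_ms)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(d["source"], d["statistic"], d["extremum"],
                   float(d["tau_ms"]))


#: Fall features: min/max windowed-mean acceleration norm, max windowed-mean
#: rotational speed norm, max windowed-mean tilt rate (windows in ms).
FALL_FEATURES = (
    FeatureSpec("A", MEAN, "min", 730.0),
    FeatureSpec("A", MEAN, "max", 125.0),
    FeatureSpec("W", MEAN, "max", 405.0),
    FeatureSpec("rho_dot", MEAN, "max", 300.0),
)

#: Immobility features: minima of windowed log10-variance of A, W, rho_dot.
IMMOBILITY_FEATURES = (
    FeatureSpec("A", LOG_VARIANCE, "min", 4500.0),
    FeatureSpec("W", LOG_VARIANCE, "min", 4500.0),
    FeatureSpec("rho_dot", LOG_VARIANCE, "min", 4500.0),
)

#: Down feature: maximum of the windowed mean tilt angle.
DOWN_FEATURES = (FeatureSpec("rho", MEAN, "max", 4500.0),)

_STATE_FEATURE_COUNT = {"F": 4, "I": 3, "D": 1}


@dataclass
class DetectorConfig:
    """Configuration of one critical-state detector.

    ``models`` maps feature keys to fitted :class:`DistributionModel`
    instances (fall and immobility only; the down detector thresholds the
    tilt feature directly, with gamma in radians).
    """

    state: str
    features: tuple[FeatureSpec, ...]
    gamma: float
    fusion_ms: float | None = None
    models: dict[str, DistributionModel] | None = None

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        self.features = tuple(self.features)
        if len(self.features) != _STATE_FEATURE_COUNT[self.state]:
            raise ValueError(
                f"state {self.state} uses exactly "
                f"{_STATE_FEATURE_COUNT[self.state]} feature(s), "
                f"got {len(self.features)}"
            )
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.state in ("F", "I") and self.fusion_ms is not None \
                and self.fusion_ms <= 0:
            raise ValueError("fusion window must be positive")

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "features": [f.to_dict() for f in self.features],
            "gamma": float(self.gamma),
            "fusion_ms": None if self.fusion_ms is None else float(self.fusion_ms),
            "models": None if self.models is None else {
                k: m.to_dict() for k, m in self.models.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        models = d.get("models")
        return cls(
            state=d["state"],
            features=tuple(FeatureSpec.from_dict(f) for f in d["features"]),
            gamma=float(d["gamma"]),
            fusion_ms=d.get("fusion_ms"),
            models=None if models is None else {
                k: DistributionModel.from_dict(m) for k, m in models.items()
            },
        )


@dataclass
class CombinatorialConfig:
    """Closed time windows (ms) of the three pairwise combinatorial states."""

    fd_ms: float = 4800.0
    fi_ms: float = 7500.0
    id_ms: float = 3850.0

    def __post_init__(self):
        for name in ("fd_ms", "fi_ms", "id_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {"fd_ms": float(self.fd_ms), "fi_ms": float(self.fi_ms),
                "id_ms": float(self.id_ms)}

    @classmethod
    def from_dict(cls, d: dict) -> "CombinatorialConfig":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class DetectorBank:
    """The full MDS detector: three state detectors plus fusion windows.

    A state entry may be ``None`` (for example when training data carried
    no occurrence of that state), in which case that state simply never
    fires and MDS detection proceeds through the remaining pathways.
    """

    fall: DetectorConfig | None
    immobility: DetectorConfig | None
    down: DetectorConfig | None
    comb: CombinatorialConfig = field(default_factory=CombinatorialConfig)

    def to_dict(self) -> dict:
        return {
            "fall": None if self.fall is None else self.fall.to_dict(),
            "immobility": None if self.immobility is None
            else self.immobility.to_dict(),
            "down": None if self.down is None else self.down.to_dict(),
            "comb": self.comb.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorBank":
        def cfg(x):
            return None if x is None else DetectorConfig.from_dict(x)

        return cls(fall=cfg(d.get("fall")), immobility=cfg(d.get("immobility")),
                   down=cfg(d.get("down")),
                   comb=CombinatorialConfig.from_dict(d["comb"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DetectorBank":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_bank() -> DetectorBank:
    """Reference configuration: windows and thresholds from waist-mounted
    corpus training (fusion windows 1475/2650 ms, pairwise windows
    4800/7500/3850 ms, gammas 0.0254 / 0.038 / 0.87 rad).  Models are not
    shipped; fit them on a labelled corpus before likelihood detection."""
    return DetectorBank(
        fall=DetectorConfig("F", FALL_FEATURES, gamma=0.0254, fusion_ms=1475.0),
        immobility=DetectorConfig("I", IMMOBILITY_FEATURES, gamma=0.038,
                                  fusion_ms=2650.0),
        down=DetectorConfig("D", DOWN_FEATURES, gamma=0.87),
        comb=CombinatorialConfig(),
    )


# ---------------------------------------------------------------------------
# forward-looking window helpers (truncated at the tail, stride 1)

def _forward_extremum(x: np.ndarray, n: int, mode: str) -> np.ndarray:
    """max/min over ``[t, t+n)`` for every t, truncating trailing windows."""
    if n > x.size:
        raise WindowTooLongError(
            f"window of {n} samples exceeds the {x.size}-sample signal")
    fill = -np.inf if mode == "max" else np.inf
    padded = np.concatenate([x, np.full(n - 1, fill)])
    win = sliding_window_view(padded, n)
    return win.max(axis=-1) if mode == "max" else win.min(axis=-1)


def _forward_mean(x: np.ndarray, n: int) -> np.ndarray:
    """mean over ``[t, t+n)`` for every t, truncating trailing windows."""
    if n > x.size:
        raise WindowTooLongError(
            f"window of {n} samples exceeds the {x.size}-sample signal")
    c = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(x.size)
    end = np.minimum(t + n, x.size)
    return (c[end] - c[t]) / (end - t)


def _forward_any(y: np.ndarray, n: int) -> np.ndarray:
    """ANY (logical OR) over the closed-ended sample window of length n."""
    return _forward_extremum(y.astype(np.int8), n, "max").astype(bool)


# ---------------------------------------------------------------------------
# likelihood fusion and thresholding

def _check_models(cfg: DetectorConfig) -> None:
    if cfg.models is None or any(f.key not in cfg.models for f in cfg.features):
        missing = [] if cfg.models is None else \
            [f.key for f in cfg.features if f.key not in cfg.models]
        raise ValueError(
            f"{cfg.state} detector lacks fitted models"
            + (f" for {missing}" if missing else "")
        )


def fall_likelihood(E: list[ExtremeValueSignal], cfg: DetectorConfig,
                    fs: float) -> np.ndarray:
    """Fused fall likelihood L_F(t) in [0, 1].

    Product over the four features of the maximum normalized density inside
    the common fusion window ``[t, t + tau_F,L)``.
    """
    _check_models(cfg)
    n = window_samples(cfg.fusion_ms, fs)
    length = min(len(e) for e in E)
    if n > length:
        raise WindowTooLongError(
            f"fusion window ({n} samples) exceeds the shortest extreme-value "
            f"signal ({length} samples)")
    L = np.ones(length)
    for spec, e in zip(cfg.features, E):
        w = normalized_pdf(cfg.models[spec.key], e.values[:length])
        L *= _forward_extremum(w, n, "max")
    return L


def immobility_likelihood(E: list[ExtremeValueSignal], cfg: DetectorConfig,
                          fs: float) -> np.ndarray:
    """Fused immobility likelihood L_I(t): product of windowed *means* of the
    normalized densities (the state is sustained, so averaging is used
    instead of the transient-friendly maximum)."""
    _check_models(cfg)
    n = window_samples(cfg.fusion_ms, fs)
    length = min(len(e) for e in E)
    if n > length:
        raise WindowTooLongError(
            f"fusion window ({n} samples) exceeds the shortest extreme-value "
            f"signal ({length} samples)")
    L = np.ones(length)
    for spec, e in zip(cfg.features, E):
        w = normalized_pdf(cfg.models[spec.key], e.values[:length])
        L *= _forward_mean(w, n)
    return L


def detect_threshold(L: np.ndarray, gamma: float) -> np.ndarray:
    """Binary detection with the strict inequality ``L > gamma``."""
    return np.asarray(L) > gamma


def detect_fall(L_F: np.ndarray, gamma_F: float) -> np.ndarray:
    if not 0.0 <= gamma_F <= 1.0:
        raise ValueError("gamma_F must lie in [0, 1]")
    return detect_threshold(L_F, gamma_F)


def detect_immobility(L_I: np.ndarray, gamma_I: float) -> np.ndarray:
    if not 0.0 <= gamma_I <= 1.0:
        raise ValueError("gamma_I must lie in [0, 1]")
    return detect_threshold(L_I, gamma_I)


def detect_down(E_rho_max: ExtremeValueSignal, gamma_D: float) -> np.ndarray:
    """Down detection: tilt extreme-value signal strictly above gamma_D rad."""
    if not 0.0 <= gamma_D <= np.pi:
        raise ValueError("gamma_D must lie in [0, pi] radians")
    return detect_threshold(E_rho_max.values, gamma_D)


def feature_threshold_detect(E: ExtremeValueSignal,
                             threshold: float) -> np.ndarray:
    """Diagnostic single-feature detector: min-extremum features trigger at
    or below the threshold, max-extremum features at or above it."""
    if E.extremum == "min":
        return E.values <= threshold
    return E.values >= threshold


# ---------------------------------------------------------------------------
# combinatorial fusion

def combinatorial_state(y_a: np.ndarray, y_b: np.ndarray, tau_ms: float,
                        fs: float) -> np.ndarray:
    """Windowed AND-over-ANY: fires at t iff each input fires at least once
    inside the closed window ``[t, t + tau]``."""
    y_a = np.asarray(y_a, dtype=bool)
    y_b = np.asarray(y_b, dtype=bool)
    if y_a.shape != y_b.shape:
        raise AlignmentError("combinatorial inputs must share a sample grid")
    n = window_samples(tau_ms, fs) + 1  # closed window [t, t+tau]
    if n > y_a.size:
        raise WindowTooLongError(
            f"combinatorial window ({n} samples) exceeds the "
            f"{y_a.size}-sample signals")
    return _forward_any(y_a, n) & _forward_any(y_b, n)


def detect_mds(y_fd: np.ndarray, y_fi: np.ndarray,
               y_id: np.ndarray) -> np.ndarray:
    """Man-down decision: inclusive OR of the pairwise combinatorial states."""
    y_fd = np.asarray(y_fd, dtype=bool)
    if y_fd.shape != np.shape(y_fi) or y_fd.shape != np.shape(y_id):
        raise AlignmentError("combinatorial signals must share a sample grid")
    return y_fd | np.asarray(y_fi, dtype=bool) | np.asarray(y_id, dtype=bool)


# ---------------------------------------------------------------------------
# end-to-end pipeline on one recording

@dataclass
class DetectionResult:
    """Per-recording detection output: binary signals on the full sample
    grid, the fused likelihood series and the extreme-value signals."""

    signals: dict[str, np.ndarray]
    likelihoods: dict[str, np.ndarray]
    extreme_signals: dict[str, ExtremeValueSignal]
    fs: float

    @property
    def verdict(self) -> bool:
        """Scenario-level MDS classification: fired at least once."""
        return bool(self.signals["MDS"].any())

    def state_verdicts(self) -> dict[str, bool]:
        return {k: bool(v.any()) for k, v in self.signals.items()}


def _pad_to(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n, dtype=bool)
    out[: len(y)] = y
    return out


def run_pipeline(feats: FeatureSignals, bank: DetectorBank,
                 E_cache: dict[str, ExtremeValueSignal] | None = None,
                 ) -> DetectionResult:
    """Run the full detection chain on one recording's feature signals.

    Detection signals are left-aligned with the recording (index t refers
    to the analysis window starting at sample t) and zero-padded at the
    tail where no full extreme-value window exists.  *E_cache* may hold
    precomputed extreme-value signals keyed by feature key; missing
    entries are computed and stored there.
    """
    n = len(feats)
    fs = feats.fs
    E: dict[str, ExtremeValueSignal] = E_cache if E_cache is not None else {}

    def get_E(spec):
        if spec.key not in E:
            E[spec.key] = spec.compute(feats)
        return E[spec.key]
    likelihoods: dict[str, np.ndarray] = {}
    signals: dict[str, np.ndarray] = {}

    if bank.fall is not None:
        E_F = [get_E(spec) for spec in bank.fall.features]
        L_F = fall_likelihood(E_F, bank.fall, fs)
        likelihoods["F"] = L_F
        signals["F"] = _pad_to(detect_fall(L_F, bank.fall.gamma), n)
    else:
        signals["F"] = np.zeros(n, dtype=bool)

    if bank.immobility is not None:
        E_I = [get_E(spec) for spec in bank.immobility.features]
        L_I = immobility_likelihood(E_I, bank.immobility, fs)
        likelihoods["I"] = L_I
        signals["I"] = _pad_to(detect_immobility(L_I, bank.immobility.gamma), n)
    else:
        signals["I"] = np.zeros(n, dtype=bool)

    if bank.down is not None:
        e = get_E(bank.down.features[0])
        signals["D"] = _pad_to(detect_down(e, bank.down.gamma), n)
    else:
        signals["D"] = np.zeros(n, dtype=bool)

    signals["F-D"] = combinatorial_state(signals["F"], signals["D"],
                                         bank.comb.fd_ms, fs)
    signals["F-I"] = combinatorial_state(signals["F"], signals["I"],
                                         bank.comb.fi_ms, fs)
    signals["I-D"] = combinatorial_state(signals["I"], signals["D"],
                                         bank.comb.id_ms, fs)
    signals["MDS"] = detect_mds(signals["F-D"], signals["F-I"], signals["I-D"])
    return DetectionResult(signals=signals, likelihoods=likelihoods,
                           extreme_signals=E, fs=fs)


def signals_to_intervals(result: DetectionResult, rec_id: str):
    """Flatten detection signals to a BED-like interval table.

    Returns a list of ``(rec_id, state, start_s, end_s, truncated)`` rows;
    ``truncated`` flags intervals that touch the end of the recording,
    where analysis windows were shortened.
    """
    rows = []
    for state, y in result.signals.items():
        y = np.asarray(y, dtype=int)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], y, [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            rows.append((
                rec_id, state,
                start / result.fs, stop / result.fs,
                bool(stop >= len(y)),
            ))
    return rows
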