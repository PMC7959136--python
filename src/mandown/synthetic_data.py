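"""Seeded generator of labelled IMU scenario recordings.

The generator emulates the scenario taxonomy used to exercise man-down
detection — walking, bending, sitting, jumping, standing still, crawling,
forward/backward falls with configurable post-fall phases, lying still and
a slow collapse (the worker feels unwell and goes down without a proper
fall).  Motion is built from piecewise-smooth kinematic templates rather
than biomechanical simulation: a tilt-angle trajectory drives a consistent
gravity vector in the device frame (so the tilt reconstructed from the
quaternion filter matches the template) and the gyroscope x axis carries
its derivative, while structured oscillations plus white sensor noise
provide the activity signature the detectors consume (norms, tilt and
windowed variances).

Every fall scenario contains, in order: pre-fall walking, a free-fall
segment whose acceleration norm dips well below 1 g, an impact spike above
2 g, and a tilt transition from below 20 degrees to above 70 degrees within
one second.  Still segments keep the windowed log10 acceleration variance
below -4.4 (g^2).  Ground-truth intervals for the F, I and D critical
states are emitted alongside each recording, and scenarios whose ground
truth combines at least two states carry a positive man-down label.

Identical spec + seed yields a bit-identical recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MandownError
from .io_formats import ImuRecording

ADL = "ADL"
MDS = "MDS"

KINDS = ("walk", "bend", "sit", "jump", "stand_still", "lie_still",
         "crawl", "fall_forward", "fall_backward", "slow_collapse")
POST_FALL = ("lie", "still_upright", "recover")

#: Default scenario mixes (class -> weight).  Keys are ``(kind, post_fall)``.
#: The ADL side covers routine work motion plus the classic confusers:
#: upright stillness (immobility without down), crawling (down without
#: immobility) and a fall with recovery (fall without either).
DEFAULT_ADL_MIX = {
    ("walk", None): 20,
    ("bend", None): 15,
    ("sit", None): 15,
    ("jump", None): 15,
    ("stand_still", None): 10,
    ("crawl", None): 10,
    ("fall_forward", "recover"): 15,
}

#: The MDS side represents each combinatorial pathway: falls ending lying
#: (F-D and F-I and I-D), falls ending slumped but upright (F-I only) and
#: the slow collapse (I-D only, no fall signature at all).
DEFAULT_MDS_MIX = {
    ("fall_forward", "lie"): 20,
    ("fall_backward", "lie"): 15,
    ("fall_forward", "still_upright"): 15,
    ("fall_backward", "still_upright"): 15,
    ("slow_collapse", None): 35,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario to simulate.

    Parameters
    ----------
    kind
        Scenario class (see :data:`KINDS`).
    duration
        Length in seconds.
    fs
        Sampling rate in Hz (200 matches the reference corpus; 100 the
        in-ear prototype).
    accel_noise, gyro_noise
        White sensor-noise RMS per axis, in g and rad/s.
    seed
        Seed of the scenario's random stream.
    post_fall
        Post-fall phase for fall classes: ``"lie"`` (man down),
        ``"still_upright"`` (immobile but not down) or ``"recover"``
        (stand up and walk on — an ADL).
    attachment
        ``"waist"`` or ``"head"``; head mounting amplifies rotational and
        translational activity (effect sizes are user-set, not calibrated
        against measured head kinematics).
    """

    kind: str
    duration: float = 20.0
    fs: float = 200.0
    accel_noise: float = 0.004
    gyro_noise: float = 0.01
    seed: int = 0
    post_fall: str | None = None
    attachment: str = "waist"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise MandownError(f"unknown scenario class {self.kind!r}")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        # scenario templates place their events on a fixed timeline; the
        # post-event stillness needs enough room for the longest analysis
        # windows, so short recordings are rejected up front
        if self.kind in ("fall_forward", "fall_backward", "slow_collapse",
                         "sit", "bend", "jump", "crawl") and self.duration < 16:
            raise ValueError(
                f"{self.kind} scenarios need a duration of at least 16 s")
        if self.accel_noise < 0 or self.gyro_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if self.post_fall is not None and self.post_fall not in POST_FALL:
            raise MandownError(f"unknown post-fall phase {self.post_fall!r}")
        if self.attachment not in ("waist", "head"):
            raise MandownError(f"unknown attachment {self.attachment!r}")

    @property
    def label(self) -> str:
        if self.kind.startswith("fall"):
            return f"{self.kind}+{self.post_fall or 'lie'}"
        return self.kind


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


class _Builder:
    """Assembles one scenario: tilt trajectory, gravity scale, additive
    device-frame acceleration/rotation, and ground-truth intervals."""

    def __init__(self, spec: ScenarioSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.n = int(round(spec.duration * spec.fs))
        self.fs = spec.fs
        self.t = np.arange(self.n) / spec.fs
        self.theta = np.zeros(self.n)
        self.gscale = np.ones(self.n)
        self.a_extra = np.zeros((self.n, 3))
        self.w_extra = np.zeros((self.n, 3))
        self.gt: dict[str, list[tuple[float, float]]] = {}
        # head mounting swings through larger arcs than the waist
        self.motion_amp = 1.15 if spec.attachment == "head" else 1.0
        self.rot_amp = 1.4 if spec.attachment == "head" else 1.0

    def idx(self, t: float) -> int:
        return int(np.clip(round(t * self.fs), 0, self.n))

    def sl(self, t0: float, t1: float) -> slice:
        return slice(self.idx(t0), self.idx(t1))

    def mark(self, state: str, t0: float, t1: float) -> None:
        self.gt.setdefault(state, []).append(
            (max(0.0, t0), min(self.spec.duration, t1)))

    # -- trajectory primitives ------------------------------------------

    def set_theta(self, value: float) -> None:
        self.theta[:] = value

    def ramp_theta(self, t0: float, t1: float, target: float) -> None:
        """Smooth tilt transition over [t0, t1]; holds the target after."""
        i0, i1 = self.idx(t0), self.idx(t1)
        if i0 >= self.n:
            return
        start = self.theta[min(i0, self.n - 1)]
        x = (self.t[i0:i1] - t0) / max(t1 - t0, 1e-9)
        self.theta[i0:i1] = start + (target - start) * _smoothstep(x)
        self.theta[i1:] = target

    def walk(self, t0: float, t1: float, amp: float = 1.0) -> None:
        s = self.sl(t0, t1)
        tt = self.t[s]
        r = self.rng
        f = 1.7 + 0.3 * r.random()
        ph = r.random(6) * 2 * np.pi
        amp *= self.motion_amp
        self.a_extra[s, 2] += amp * (0.22 * np.sin(2 * np.pi * f * tt + ph[0])
                                     + 0.08 * np.sin(4 * np.pi * f * tt + ph[1]))
        self.a_extra[s, 0] += amp * 0.10 * np.sin(2 * np.pi * f * tt + ph[2])
        self.a_extra[s, 1] += amp * 0.08 * np.sin(2 * np.pi * f * tt + ph[3])
        ra = amp * self.rot_amp
        self.w_extra[s, 0] += ra * 0.40 * np.sin(2 * np.pi * f * tt + ph[4])
        self.w_extra[s, 1] += ra * 0.30 * np.sin(2 * np.pi * f * tt + ph[5])
        self.w_extra[s, 2] += ra * 0.25 * np.sin(2 * np.pi * f * tt + ph[0])

    def jitter(self, t0: float, t1: float, a_amp: float = 0.06,
               w_amp: float = 0.15) -> None:
        """Low-level fidgeting: enough variance to defeat the immobility
        detector without looking like locomotion."""
        s = self.sl(t0, t1)
        tt = self.t[s]
        ph = self.rng.random(2) * 2 * np.pi
        self.a_extra[s, 2] += a_amp * np.sin(2 * np.pi * 1.1 * tt + ph[0])
        self.w_extra[s, 1] += w_amp * self.rot_amp * np.sin(
            2 * np.pi * 0.9 * tt + ph[1])

    def bump(self, at: float, amp: float, width: float = 0.022,
             axis: int = 2) -> None:
        """Gaussian acceleration spike (impacts, settling thuds)."""
        s = self.sl(at - 4 * width, at + 4 * width)
        self.a_extra[s, axis] += amp * np.exp(
            -(((self.t[s] - at) / width) ** 2))

    def half_sine(self, t0: float, t1: float, amp: float, axis: int = 2) -> None:
        s = self.sl(t0, t1)
        x = (self.t[s] - t0) / max(t1 - t0, 1e-9)
        self.a_extra[s, axis] += amp * np.sin(np.pi * np.clip(x, 0, 1))

    def gravity_dip(self, t0: float, t1: float, level: float,
                    edge: float = 0.12) -> None:
        """Free-fall signature: the gravity scale ramps 1 -> level -> 1."""
        i0, i1 = self.idx(t0), self.idx(t1)
        e = max(1, self.idx(t0 + edge) - i0)
        prof = np.ones(i1 - i0)
        prof[:e] = 1.0 + (level - 1.0) * _smoothstep(np.linspace(0, 1, e))
        prof[-e:] = level + (1.0 - level) * _smoothstep(np.linspace(0, 1, e))
        prof[e:-e] = level
        self.gscale[i0:i1] = np.minimum(self.gscale[i0:i1], prof)

    def tumble(self, t0: float, t1: float, amp_y: float, amp_z: float) -> None:
        s = self.sl(t0, t1)
        x = (self.t[s] - t0) / max(t1 - t0, 1e-9)
        env = np.sin(np.pi * np.clip(x, 0, 1))
        ra = self.rot_amp
        self.w_extra[s, 1] += ra * amp_y * env
        self.w_extra[s, 2] += ra * amp_z * env

    # -- event templates ------------------------------------------------

    def fall_event(self, t0: float, theta_fall: float) -> tuple[float, float]:
        """Free fall + impact + rapid tilt transition starting at t0.

        Returns (impact time, end of the fall event)."""
        r = self.rng
        self.ramp_theta(t0, t0 + 0.65, theta_fall)
        dip = 0.20 + 0.15 * r.random()
        self.gravity_dip(t0 + 0.05, t0 + 0.58, dip)
        ti = t0 + 0.60
        amp = 2.5 + 3.0 * r.random()
        self.bump(ti, 0.8 * amp, axis=2)
        self.bump(ti, 0.6 * amp, axis=1)
        # post-impact ringing
        s = self.sl(ti, ti + 0.8)
        tt = self.t[s] - ti
        self.a_extra[s, 2] += 0.30 * np.exp(-3.0 * tt) * np.sin(
            2 * np.pi * 4.0 * tt)
        self.tumble(t0, t0 + 0.70, amp_y=1.2, amp_z=0.7)
        self.mark("F", t0, ti + 0.2)
        return ti, t0 + 1.0

    def jump_event(self, e0: float) -> None:
        r = self.rng
        self.half_sine(e0, e0 + 0.3, -0.30)          # crouch
        self.half_sine(e0 + 0.3, e0 + 0.5, 1.10)     # launch
        self.gravity_dip(e0 + 0.5, e0 + 0.87, 0.06)  # flight
        self.bump(e0 + 0.89, 2.0 + 1.5 * r.random())  # landing
        s = self.sl(e0 + 0.89, e0 + 1.4)
        tt = self.t[s] - (e0 + 0.89)
        self.a_extra[s, 2] += 0.25 * np.exp(-4.0 * tt) * np.sin(
            2 * np.pi * 5.0 * tt)
        self.tumble(e0 + 0.2, e0 + 1.1, amp_y=0.7, amp_z=0.4)

    # -- final assembly -------------------------------------------------

    def build(self, label: str, is_mds: bool) -> ImuRecording:
        r = self.rng
        theta_dot = np.gradient(self.theta, 1.0 / self.fs)
        a = self.gscale[:, None] * np.column_stack([
            np.zeros(self.n), np.sin(self.theta), np.cos(self.theta)])
        a += self.a_extra
        a += r.normal(0.0, self.spec.accel_noise, (self.n, 3))
        w = self.w_extra.copy()
        w[:, 0] += theta_dot
        w += r.normal(0.0, self.spec.gyro_noise, (self.n, 3))
        return ImuRecording(a=a, w=w, fs=self.fs, label=label,
                            ground_truth=self.gt, is_mds=is_mds)


def generate(spec: ScenarioSpec) -> ImuRecording:
    """Simulate one labelled scenario recording with ground-truth intervals."""
    b = _Builder(spec)
    r = b.rng
    dur = spec.duration
    kind = spec.kind
    is_mds = False

    if kind == "walk":
        b.set_theta(0.10)
        b.walk(0.0, dur)

    elif kind == "stand_still":
        b.set_theta(0.07 + 0.02 * r.random())
        b.mark("I", 0.5, dur)

    elif kind == "lie_still":
        b.set_theta(1.42 + 0.12 * r.random())
        b.mark("I", 0.5, dur)
        b.mark("D", 0.0, dur)
        is_mds = True  # lying immobile is the I-D pathway by definition

    elif kind == "sit":
        b.set_theta(0.10)
        b.walk(0.0, 2.5)
        b.ramp_theta(2.5, 3.5, 0.22)
        b.half_sine(2.5, 3.0, -0.25)
        b.half_sine(3.0, 3.4, 0.35)
        b.mark("I", 4.0, dur)

    elif kind == "bend":
        b.set_theta(0.10)
        b.walk(0.0, 4.0)
        b.ramp_theta(4.0, 5.2, 1.15)
        b.jitter(5.2, 8.3)           # rummaging at ground level, not still
        b.ramp_theta(8.3, 9.5, 0.10)
        b.walk(9.5, dur)

    elif kind == "jump":
        b.set_theta(0.08)
        b.walk(0.0, dur, amp=0.4)
        for base in (5.0, 10.0, 15.0):
            e0 = base + 0.3 * r.random()
            if e0 + 1.6 < dur:
                b.jump_event(e0)

    elif kind == "crawl":
        b.set_theta(0.15)
        b.ramp_theta(1.2, 2.4, 1.50)
        s = b.sl(2.4, dur)
        tt = b.t[s]
        ph = r.random(4) * 2 * np.pi
        b.a_extra[s, 0] += 0.20 * np.sin(2 * np.pi * 1.2 * tt + ph[0])
        b.a_extra[s, 2] += 0.30 * np.sin(2 * np.pi * 1.2 * tt + ph[1])
        b.w_extra[s, 0] += 0.50 * b.rot_amp * np.sin(2 * np.pi * 1.2 * tt + ph[2])
        b.w_extra[s, 1] += 0.35 * b.rot_amp * np.sin(2 * np.pi * 1.2 * tt + ph[3])
        b.mark("D", 2.6, dur)

    elif kind in ("fall_forward", "fall_backward"):
        post = spec.post_fall or "lie"
        b.set_theta(0.10)
        t0 = 3.2
        b.walk(0.0, t0)
        theta_fall = 1.45 + 0.10 * (r.random() - 0.5)
        ti, t1 = b.fall_event(t0, theta_fall)
        if post == "lie":
            b.ramp_theta(t1, t1 + 0.4, 1.42 + 0.10 * r.random())
            b.jitter(t1, t1 + 0.5, a_amp=0.04, w_amp=0.08)
            b.mark("D", ti, dur)
            b.mark("I", t1 + 0.5, dur)
            is_mds = True
        elif post == "still_upright":
            b.ramp_theta(t1, t1 + 0.8, 0.32)
            b.mark("I", t1 + 1.0, dur)
            is_mds = True
        else:  # recover: brief lie, stand back up, walk on
            b.ramp_theta(t1 + 1.3, t1 + 2.5, 0.12)
            b.jitter(t1, t1 + 1.3, a_amp=0.05, w_amp=0.12)
            b.walk(t1 + 2.8, dur)

    elif kind == "slow_collapse":
        b.set_theta(0.08)
        b.jitter(0.0, 3.0, a_amp=0.05, w_amp=0.10)  # swaying, feeling unwell
        b.ramp_theta(3.0, 6.0, 1.45 + 0.08 * r.random())
        b.gravity_dip(3.5, 5.5, 0.88, edge=0.5)
        b.bump(6.1, 0.30)
        b.mark("D", 5.8, dur)
        b.mark("I", 6.5, dur)
        is_mds = True

    else:  # pragma: no cover - guarded by ScenarioSpec validation
        raise MandownError(f"unknown scenario class {kind!r}")

    return b.build(spec.label, is_mds)


def _allocate(n: int, mix: dict) -> list[tuple]:
    """Largest-remainder allocation of n recordings over a class mix."""
    if n < 1:
        raise MandownError("need at least one recording per corpus side")
    if not mix:
        raise MandownError("empty class mix")
    items = list(mix.items())
    total = float(sum(w for _, w in items))
    if total <= 0:
        raise MandownError("class-mix weights must sum to a positive value")
    quotas = [n * w / total for _, w in items]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for i in sorted(range(len(items)), key=lambda i: -remainders[i]):
        if sum(counts) >= n:
            break
        counts[i] += 1
    out = []
    for (cls, _), c in zip(items, counts):
        out.extend([cls] * c)
    return out[:n]


def generate_corpus(n_adl: int, n_mds: int, adl_mix: dict | None = None,
                    mds_mix: dict | None = None, seed: int = 0,
                    fs: float = 200.0, duration: float = 20.0,
                    ) -> tuple[list[ImuRecording], pd.DataFrame]:
    """Generate a reproducible labelled corpus.

    Returns the recordings plus a manifest table (rec_id, label, is_mds).
    Scenario counts follow the requested mixes exactly (largest-remainder
    allocation); per-recording seeds derive deterministically from *seed*.
    """
    adl_classes = _allocate(
        n_adl, DEFAULT_ADL_MIX if adl_mix is None else adl_mix)
    mds_classes = _allocate(
        n_mds, DEFAULT_MDS_MIX if mds_mix is None else mds_mix)
    classes = ([(cls, False) for cls in adl_classes]
               + [(cls, True) for cls in mds_classes])
    children = np.random.SeedSequence(seed).spawn(len(classes))
    recordings = []
    rows = []
    for i, ((cls, want_mds), child) in enumerate(zip(classes, children)):
        kind, post = cls if isinstance(cls, tuple) else (cls, None)
        spec = ScenarioSpec(kind=kind, post_fall=post, fs=fs,
                            duration=duration,
                            seed=int(child.generate_state(1)[0] & 0x7FFFFFFF))
        rec = generate(spec)
        if bool(rec.is_mds) != want_mds:
            raise MandownError(
                f"scenario class {cls!r} produced an "
                f"{'MDS' if rec.is_mds else 'ADL'} recording on the "
                f"{'MDS' if want_mds else 'ADL'} side of the corpus")
        rec.rec_id = f"rec{i:04d}"
        recordings.append(rec)
        rows.append({"rec_id": rec.rec_id, "label": rec.label,
                     "is_mds": bool(rec.is_mds)})
    return recordings, pd.DataFrame(rows)
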