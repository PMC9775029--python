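"""Synthetic fNIRS signal generation with known respiratory ground truth.

Every stage of the RR-estimation pipeline is verifiable against signals
whose respiratory rate, cardiac trough locations, and motion-artifact
positions are known exactly. A synthetic O2Hb trace is assembled additively
from:

* a quasi-periodic cardiac component -- a Gaussian-mixture pulse per cycle
  (systolic peak, a smaller delayed dicrotic bump whose saddle forms the
  dicrotic notch, and a diastolic undershoot forming the deep per-cycle
  trough); the notch's shallow secondary minima exercise the Th1 candidate
  threshold;
* a sinusoidal respiratory baseline wander at the commanded rate, the
  quantity the pipeline must recover;
* a Mayer-wave sinusoid near 0.1 Hz and a slow drift, the confounders the
  moving-average detrend and search band must suppress;
* white Gaussian measurement noise;
* optional sparse motion artifacts -- brief (0.5-1 s) excursions an order of
  magnitude larger than the respiratory wander, which create the abnormally
  deep troughs the Th2 screen must reject. Artifacts model a single event
  class (negative-going, the deep-trough polarity Th2 targets, +-10%
  amplitude jitter, centers at least 5 s apart): the depth-outlier screen is
  a mean +- B*std rule, and strongly heterogeneous outliers mask one
  another, which is a property of the published rule rather than something
  the generator should manufacture.

Default amplitudes are in arbitrary uM-equivalent units with the cardiac
pulsation as the dominant oscillation and the respiratory wander a fraction
of it, the typical situation in frontal-lobe O2Hb recordings. The ratio is
chosen so that the cardiac trough depth clearly exceeds the wander
amplitude: trough-based baseline synthesis assumes every cycle trough falls
below the signal mean, which fails when the wander can lift a trough above
it.

The breathing-protocol generator reproduces a paced-breathing session:
60 s rest, five 50 s constant-rate steps at 6/12/24/12/6 BPM, 30 s rest,
five 50 s steps at 9/18/24/18/9 BPM, all repeated once -- 1180 s and twenty
constant-rate trials per simulated subject. Rest periods breathe at a
spontaneous rate drawn uniformly from 12-18 BPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .preprocess import DEFAULT_DPF, extinction_matrix

__all__ = [
    "SimConfig",
    "Segment",
    "SimTruth",
    "synthesize_o2hb",
    "synthesize_protocol",
    "synthesize_recording",
    "inject_artifacts",
    "sample_artifact_centers",
    "hemo_to_od",
    "PROTOCOL_BLOCK_1_BPM",
    "PROTOCOL_BLOCK_2_BPM",
    "PROTOCOL_STEP_S",
    "PROTOCOL_REST_INITIAL_S",
    "PROTOCOL_REST_BETWEEN_S",
]

# Paced-breathing protocol structure: initial rest, two five-step blocks of
# 50 s constant-rate breathing separated by a short rest, repeated once.
PROTOCOL_BLOCK_1_BPM = (6.0, 12.0, 24.0, 12.0, 6.0)
PROTOCOL_BLOCK_2_BPM = (9.0, 18.0, 24.0, 18.0, 9.0)
PROTOCOL_STEP_S = 50.0
PROTOCOL_REST_INITIAL_S = 60.0
PROTOCOL_REST_BETWEEN_S = 30.0

# Cardiac pulse template, in fractions of one cycle: a systolic peak, a
# smaller dicrotic bump on the downstroke (their saddle is the dicrotic
# notch, a shallow local minimum that sits well above the cycle mean), and
# a diastolic undershoot that forms the deep per-cycle trough. Keeping the
# notch high and the trough deep is what lets a mean-based threshold
# separate the two kinds of local minima.
_SYSTOLIC_CENTER = 0.20
_SYSTOLIC_WIDTH = 0.055
_DICROTIC_CENTER = 0.38
_DICROTIC_WIDTH = 0.06
_UNDERSHOOT_CENTER = 0.72
_UNDERSHOOT_WIDTH = 0.10
_UNDERSHOOT_DEPTH = 0.3
# Trough search window within each cycle: after the dicrotic bump, before
# the next systolic upstroke.
_TROUGH_WINDOW = (0.55, 1.05)

_HHB_RATIO = -0.3  # physiological O2Hb/HHb anti-correlation in the pulse


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic O2Hb trace.

    Amplitudes are uM-equivalent (arbitrary but consistent) units;
    ``artifact_amplitude`` is expressed in multiples of ``resp_amplitude``
    and ``artifact_rate`` in events per minute.
    """

    sampling_rate: float = 50.0
    duration: float = 50.0
    heart_rate: float = 1.1
    resp_rate: float = 0.25
    cardiac_amplitude: float = 1.5
    resp_amplitude: float = 0.25
    mayer_amplitude: float = 0.08
    drift_amplitude: float = 0.3
    noise_sd: float = 0.05
    dicrotic_depth: float = 0.5
    artifact_rate: float = 0.0
    artifact_amplitude: float = 16.0
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.sampling_rate <= 2 * self.heart_rate:
            raise ValidationError("sampling_rate must exceed twice the heart rate")
        if not (0 <= self.resp_rate < self.heart_rate):
            raise ValidationError("resp_rate must lie in [0, heart_rate)")
        for name in (
            "cardiac_amplitude",
            "resp_amplitude",
            "mayer_amplitude",
            "drift_amplitude",
            "noise_sd",
            "artifact_rate",
            "artifact_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not (0 < self.dicrotic_depth < 1):
            raise ValidationError("dicrotic_depth must be in (0, 1)")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval [start, stop) breathing at ``rr_bpm``."""

    start: int
    stop: int
    rr_bpm: float
    kind: str = "trial"  # "trial" (constant commanded rate) or "rest"


@dataclass
class SimTruth:
    """Ground truth accompanying a synthetic trace.

    ``components`` maps component names (cardiac, respiratory, mayer, drift,
    noise, artifact) to per-sample tracks; they sum exactly to the returned
    signal. ``true_trough_indices`` are the per-cycle minima of the
    noise-free, artifact-free assembly.
    """

    segments: list[Segment]
    true_trough_indices: np.ndarray
    artifact_indices: np.ndarray
    components: dict[str, np.ndarray]

    @property
    def trials(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "trial"]

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"start": s.start, "stop": s.stop, "rr_bpm": s.rr_bpm, "kind": s.kind}
                for s in self.segments
            ],
            "true_trough_indices": self.true_trough_indices.tolist(),
            "artifact_indices": self.artifact_indices.tolist(),
        }


def _cardiac_waveform(cycle_pos: np.ndarray, dicrotic_depth: float) -> np.ndarray:
    """Zero-mean pulse template evaluated at cycle positions in [0, 1)."""
    w = np.exp(-0.5 * ((cycle_pos - _SYSTOLIC_CENTER) / _SYSTOLIC_WIDTH) ** 2)
    w += dicrotic_depth * np.exp(
        -0.5 * ((cycle_pos - _DICROTIC_CENTER) / _DICROTIC_WIDTH) ** 2
    )
    w -= _UNDERSHOOT_DEPTH * np.exp(
        -0.5 * ((cycle_pos - _UNDERSHOOT_CENTER) / _UNDERSHOOT_WIDTH) ** 2
    )
    # continuous cycle mean of the three Gaussians (tails beyond the cycle
    # are negligible at these widths)
    mean = np.sqrt(2 * np.pi) * (
        _SYSTOLIC_WIDTH
        + dicrotic_depth * _DICROTIC_WIDTH
        - _UNDERSHOOT_DEPTH * _UNDERSHOOT_WIDTH
    )
    return w - mean


def inject_artifacts(
    n_samples: int,
    fs: float,
    centers_s: np.ndarray,
    durations_s: np.ndarray,
    amplitudes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive Gaussian-bump excursion track for motion artifacts.

    Each event is a Gaussian bump centered at ``centers_s`` with standard
    deviation ``duration/4`` (the +-2 sigma support spans ``duration``) and
    signed amplitude ``amplitudes``. Returns the additive track and the
    event center sample indices.
    """
    t = np.arange(n_samples) / fs
    track = np.zeros(n_samples)
    centers_s = np.atleast_1d(np.asarray(centers_s, dtype=float))
    durations_s = np.atleast_1d(np.asarray(durations_s, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    for c, d, a in zip(centers_s, durations_s, amplitudes):
        track += a * np.exp(-0.5 * ((t - c) / (d / 4.0)) ** 2)
    centers_idx = np.sort(np.round(centers_s * fs).astype(int))
    return track, centers_idx


def sample_artifact_centers(
    rng: np.random.Generator,
    n_events: int,
    t_min: float,
    t_max: float,
    min_separation: float = 5.0,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw artifact center times at least ``min_separation`` apart.

    Motion events are modelled as temporally isolated; overlapping
    excursions would merge into one long compound excursion, a different
    phenomenon. The event count is capped at what the interval can hold.
    """
    if t_max <= t_min:
        return np.asarray([], dtype=float)
    capacity = int((t_max - t_min) / min_separation) + 1
    n_events = min(n_events, capacity)
    if n_events <= 0:
        return np.asarray([], dtype=float)
    for _ in range(max_tries):
        centers = np.sort(rng.uniform(t_min, t_max, size=n_events))
        if n_events < 2 or np.min(np.diff(centers)) >= min_separation:
            return centers
    # extremely unlikely fallback: evenly spaced deterministic placement
    return np.linspace(t_min, t_max, n_events + 2)[1:-1]


def _true_troughs(base: np.ndarray, heart_rate: float, fs: float) -> np.ndarray:
    """Per-cycle minima of the clean assembly, verified as local minima."""
    n = base.size
    troughs = []
    n_cycles = int(np.floor(heart_rate * n / fs))
    for k in range(n_cycles):
        lo = int(np.ceil((k + _TROUGH_WINDOW[0]) / heart_rate * fs))
        hi = int(np.floor((k + _TROUGH_WINDOW[1]) / heart_rate * fs))
        if lo < 1 or hi >= n - 1 or hi <= lo:
            continue
        seg = base[lo : hi + 1]
        i = lo + int(np.argmin(seg))
        if base[i] < base[i - 1] and base[i] < base[i + 1]:
            troughs.append(i)
    return np.asarray(troughs, dtype=int)


def _assemble(
    config: SimConfig,
    resp_hz: np.ndarray,
    segments: list[Segment],
    rng_noise: np.random.Generator,
    rng_artifact: np.random.Generator,
    rng_misc: np.random.Generator,
) -> tuple[np.ndarray, SimTruth]:
    n = resp_hz.size
    fs = config.sampling_rate
    t = np.arange(n) / fs

    cycle_pos = np.mod(config.heart_rate * t, 1.0)
    cardiac = config.cardiac_amplitude * _cardiac_waveform(cycle_pos, config.dicrotic_depth)

    # integrate the (possibly time-varying) respiratory frequency so that
    # rate changes do not produce phase jumps
    phase = 2 * np.pi * np.concatenate(([0.0], np.cumsum(resp_hz[:-1]))) / fs
    respiratory = config.resp_amplitude * np.sin(phase)

    mayer = config.mayer_amplitude * np.sin(2 * np.pi * 0.1 * t + 0.7)
    drift_phase = rng_misc.uniform(0, 2 * np.pi)
    drift = config.drift_amplitude * np.sin(2 * np.pi * 0.01 * t + drift_phase)

    noise = config.noise_sd * rng_noise.standard_normal(n)

    duration = n / fs
    n_events = rng_artifact.poisson(config.artifact_rate * duration / 60.0)
    if n_events > 0 and config.artifact_amplitude > 0:
        centers = sample_artifact_centers(rng_artifact, n_events, 2.0, duration - 2.0)
        widths = rng_artifact.uniform(0.5, 1.0, size=centers.size)
        amps = -config.artifact_amplitude * config.resp_amplitude * rng_artifact.uniform(
            0.9, 1.1, size=centers.size
        )
        artifact, artifact_idx = inject_artifacts(n, fs, centers, widths, amps)
    else:
        artifact = np.zeros(n)
        artifact_idx = np.asarray([], dtype=int)

    base = cardiac + respiratory + mayer + drift
    signal = base + noise + artifact
    truth = SimTruth(
        segments=segments,
        true_trough_indices=_true_troughs(base, config.heart_rate, fs),
        artifact_indices=artifact_idx,
        components={
            "cardiac": cardiac,
            "respiratory": respiratory,
            "mayer": mayer,
            "drift": drift,
            "noise": noise,
            "artifact": artifact,
        },
    )
    return signal, truth


def _rngs(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def synthesize_o2hb(config: SimConfig) -> tuple[np.ndarray, SimTruth]:
    """Synthesize one constant-rate O2Hb trace with ground truth.

    Identical configs (including the seed) produce bitwise-identical
    output. The component tracks recorded in the truth object sum exactly
    to the returned signal.
    """
    n = int(round(config.duration * config.sampling_rate))
    resp_hz = np.full(n, config.resp_rate)
    segments = [Segment(0, n, config.resp_rate * 60.0, "trial")]
    rng_misc, rng_noise, rng_artifact = _rngs(config.seed)
    return _assemble(config, resp_hz, segments, rng_noise, rng_artifact, rng_misc)


def _protocol_schedule(fs: float, rest_rr_bpm: list[float]) -> tuple[np.ndarray, list[Segment]]:
    """Per-sample respiratory frequency and segment table for one session."""
    plan: list[tuple[float, float, str]] = []  # (duration_s, rr_bpm, kind)
    rest_iter = iter(rest_rr_bpm)
    for _ in range(2):  # the whole rest+block+rest+block structure repeats
        plan.append((PROTOCOL_REST_INITIAL_S, next(rest_iter), "rest"))
        plan.extend((PROTOCOL_STEP_S, bpm, "trial") for bpm in PROTOCOL_BLOCK_1_BPM)
        plan.append((PROTOCOL_REST_BETWEEN_S, next(rest_iter), "rest"))
        plan.extend((PROTOCOL_STEP_S, bpm, "trial") for bpm in PROTOCOL_BLOCK_2_BPM)
    resp_hz_parts = []
    segments = []
    start = 0
    for dur_s, bpm, kind in plan:
        n_seg = int(round(dur_s * fs))
        resp_hz_parts.append(np.full(n_seg, bpm / 60.0))
        segments.append(Segment(start, start + n_seg, bpm, kind))
        start += n_seg
    return np.concatenate(resp_hz_parts), segments


def synthesize_protocol(
    subject_seed: int, config: SimConfig | None = None
) -> tuple[np.ndarray, SimTruth]:
    """Synthesize a full 1180 s paced-breathing session for one subject.

    The session is 60 s rest, five 50 s steps at 6/12/24/12/6 BPM, 30 s
    rest, five 50 s steps at 9/18/24/18/9 BPM, repeated once: twenty
    constant-rate trials. Rest-period rates are drawn uniformly from
    12-18 BPM and the subject's heart rate uniformly from 0.9-1.3 Hz;
    both draws are reproducible from ``subject_seed``.
    """
    base = config if config is not None else SimConfig()
    rng_misc, rng_noise, rng_artifact = _rngs(subject_seed)
    heart_rate = rng_misc.uniform(0.9, 1.3)
    rest_rr = list(rng_misc.uniform(12.0, 18.0, size=4))
    resp_hz, segments = _protocol_schedule(base.sampling_rate, rest_rr)
    cfg = replace(
        base, heart_rate=heart_rate, duration=resp_hz.size / base.sampling_rate,
        seed=subject_seed,
    )
    return _assemble(cfg, resp_hz, segments, rng_noise, rng_artifact, rng_misc)


def hemo_to_od(
    o2hb: np.ndarray,
    hhb: np.ndarray,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    distance_mm: float = 35.0,
    dpf: float = DEFAULT_DPF,
    extinction: dict[int, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward optical model: concentration changes -> two-wavelength OD.

    Exact inverse of the MBLL conversion in :mod:`nirsrr.preprocess`, so a
    round trip through the two recovers the concentrations to floating
    tolerance. Returns an (n_samples, 2) OD matrix.
    """
    e = extinction_matrix(wavelengths, extinction)
    if distance_mm <= 0 or dpf <= 0:
        raise ValidationError("distance and DPF must be positive")
    conc = np.column_stack([np.asarray(o2hb, dtype=float), np.asarray(hhb, dtype=float)])
    return conc @ e.T * (dpf * distance_mm / 10.0)


def synthesize_recording(
    config: SimConfig,
    protocol: bool = False,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    distance_mm: float = 35.0,
    dpf: float = DEFAULT_DPF,
) -> tuple[np.ndarray, SimTruth, list[str]]:
    """Multichannel OD recording via the forward optical model.

    All channels share the same physiology; channel k carries independent
    measurement noise scaled by (1 + k/2), so channel 1 is the cleanest and
    quality-based channel selection has something to choose between. HHb is
    modelled as the anti-correlated pulsatile fraction of O2Hb. Returns the
    (n_samples, 2 * n_channels) OD matrix, the ground truth of the shared
    physiology (noise track = channel 1's), and the channel labels.
    """
    if protocol:
        o2hb, truth = synthesize_protocol(config.seed, config)
    else:
        o2hb, truth = synthesize_o2hb(config)
    clean = o2hb - truth.components["noise"]
    hhb_clean = _HHB_RATIO * (clean - truth.components["drift"])
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    columns = []
    labels = []
    for ch in range(config.n_channels):
        scale = 1.0 + 0.5 * ch
        if ch == 0:
            o2hb_ch = o2hb
        else:
            o2hb_ch = clean + scale * config.noise_sd * rng.standard_normal(clean.size)
        hhb_ch = hhb_clean + scale * config.noise_sd * rng.standard_normal(clean.size)
        od = hemo_to_od(o2hb_ch, hhb_ch, wavelengths, distance_mm, dpf)
        columns.append(od)
        labels.append(f"ch{ch + 1}")
    return np.hstack(columns), truth, labels
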