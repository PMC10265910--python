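"""Synthetic lower-back acceleration with exact ground truth.

The forward model is deliberately minimal: per bout, the vertical axis is a
sinusoid at step frequency whose amplitude comes from the inverted-pendulum
relation for the requested stride length and leg length (differentiated twice
analytically), with short raised-cosine impact transients at the IC times.
The AP axis oscillates at step frequency, the ML axis at stride frequency,
rests are gravity plus noise.  Asymmetry alternates the per-step amplitude
(and pendulum excursion) between feet while keeping every stride's true
length equal to the requested one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dsp import G_MPS2
from .exceptions import ProtocolError
from .io import (BOUT_BREAK_S, ImuRecording, Stride, WalkingBout,
                 STRIDE_MIN_LENGTH_M)

__all__ = ["BoutSpec", "SimProtocol", "SuiteFixture", "generate_recording",
           "standard_fixture_suite", "DEFAULT_K_GEN"]

#: pendulum constant used by the forward model; the classic small-angle
#: inverted pendulum.  Parameter-recovery tests supply this same constant to
#: the estimator to close the loop.
DEFAULT_K_GEN = 2.0
#: impact transient: 30 ms biphasic jolt (derivative-of-raised-cosine shape,
#: zero net area) at each IC.  Zero area keeps the double-integrated
#: displacement faithful to the pendulum model while giving event detectors a
#: sharp feature centred on the IC.  The amplitude is half the smooth vertical
#: amplitude (capped at 0.3 g) so the transient stays subordinate to the gait
#: cycle and zero-crossing detectors see one crossing pair per step.
IMPACT_WIDTH_S = 0.03
IMPACT_AMP_MAX_G = 0.3
IMPACT_AMP_REL = 0.5
AP_AMP_G = 0.08
ML_AMP_G = 0.03


@dataclass(frozen=True)
class BoutSpec:
    start_s: float
    n_strides: int
    cadence_spm: float
    stride_length_m: float
    asymmetry: float = 1.0     # ratio of alternate step amplitudes, (0, 1]

    def __post_init__(self) -> None:
        if self.n_strides < 3:
            raise ProtocolError("a bout needs at least 3 strides")
        stride_dur = 120.0 / self.cadence_spm
        if not (0.2 < stride_dur <= 3.0):
            raise ProtocolError(
                f"cadence {self.cadence_spm} gives stride duration "
                f"{stride_dur:.2f} s outside (0.2, 3] s")
        if self.stride_length_m < STRIDE_MIN_LENGTH_M:
            raise ProtocolError("stride length below the 0.15 m validity floor")
        if not (0 < self.asymmetry <= 1):
            raise ProtocolError("asymmetry must lie in (0, 1]")

    @property
    def step_dt_s(self) -> float:
        return 60.0 / self.cadence_spm

    @property
    def n_ics(self) -> int:
        return 2 * self.n_strides + 1

    @property
    def duration_s(self) -> float:
        return self.n_strides * 120.0 / self.cadence_spm

    @property
    def speed_mps(self) -> float:
        return self.stride_length_m * self.cadence_spm / 120.0


@dataclass(frozen=True)
class SimProtocol:
    bouts: tuple[BoutSpec, ...]
    leg_length_m: float = 0.9
    foot_length_m: float = 0.25
    noise_sd_g: float = 0.0
    seed: int = 0
    k_gen: float = DEFAULT_K_GEN
    trailing_rest_s: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple(self.bouts))
        if not self.bouts:
            raise ProtocolError("protocol needs at least one bout")
        prev_end = -np.inf
        for b in sorted(self.bouts, key=lambda b: b.start_s):
            if b.start_s - prev_end < BOUT_BREAK_S and np.isfinite(prev_end):
                raise ProtocolError("bouts must be separated by >= 3 s of rest")
            if b.start_s < 0:
                raise ProtocolError("bout starts before the recording")
            prev_end = b.start_s + b.duration_s

    @property
    def duration_s(self) -> float:
        last = max(b.start_s + b.duration_s for b in self.bouts)
        return last + self.trailing_rest_s


def _pendulum_h(step_level_length: float, leg_length: float) -> float:
    """Vertical excursion solving ``length = sqrt(2 l h - h^2)``."""
    if step_level_length >= leg_length:
        raise ProtocolError(
            f"stride length infeasible for leg length {leg_length} m "
            f"(requires h >= 2l)")
    return leg_length - np.sqrt(leg_length ** 2 - step_level_length ** 2)


def _bout_excursions(spec: BoutSpec, leg_length: float, k_gen: float
                     ) -> tuple[float, float]:
    """Per-step pendulum excursions (strong, weak) whose stride-level
    estimates average to the requested stride length."""
    r = spec.asymmetry
    q1 = 2.0 * spec.stride_length_m / (k_gen * (1.0 + np.sqrt(r)))
    h1 = _pendulum_h(q1, leg_length)
    return h1, r * h1


def generate_recording(protocol: SimProtocol, fs_hz: float = 100.0
                       ) -> tuple[ImuRecording, list[WalkingBout]]:
    """Render a protocol to an acceleration stream plus exact ground truth.

    Ground truth carries the IC times (as interleaved stride boundaries),
    per-stride durations and lengths and the per-bout mean speed.  Noise is
    seeded from the protocol; the truth never depends on the seed.
    """
    rng = np.random.default_rng(protocol.seed)
    n = int(round(protocol.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    acc_v = np.zeros(n)
    acc_ap = np.zeros(n)
    acc_ml = np.zeros(n)
    truth: list[WalkingBout] = []

    for spec in sorted(protocol.bouts, key=lambda b: b.start_s):
        ics = spec.start_s + np.arange(spec.n_ics) * spec.step_dt_s
        omega = 2.0 * np.pi / spec.step_dt_s
        h1, h2 = _bout_excursions(spec, protocol.leg_length_m, protocol.k_gen)

        i0 = int(round(spec.start_s * fs_hz))
        i1 = min(int(round(ics[-1] * fs_hz)) + 1, n)
        tb = t[i0:i1] - spec.start_s
        # per-step envelope: excursion alternates h1 (strong) / h2 (weak)
        step_idx = np.clip((tb / spec.step_dt_s).astype(int), 0, spec.n_ics - 2)
        h_step = np.where(step_idx % 2 == 0, h1, h2)
        amp_mps2 = (h_step / 2.0) * omega ** 2
        # phase: sin() puts the post-CWT positive maxima of the vertical-axis
        # detector exactly on the IC times
        acc_v[i0:i1] += amp_mps2 / G_MPS2 * np.sin(omega * tb)
        acc_ap[i0:i1] += AP_AMP_G * np.cos(omega * tb)
        acc_ap[i0:i1] += 0.25 * AP_AMP_G * (1 - spec.asymmetry) * np.sin(omega * tb / 2)
        acc_ml[i0:i1] += ML_AMP_G * np.sin(omega * tb / 2)

        half_w = IMPACT_WIDTH_S / 2.0
        amp1_g = (h1 / 2.0) * omega ** 2 / G_MPS2
        base_amp = min(IMPACT_AMP_MAX_G, IMPACT_AMP_REL * amp1_g)
        for j, tic in enumerate(ics):
            amp = base_amp * (1.0 if j % 2 == 0 else spec.asymmetry)
            j0 = max(int(round((tic - half_w) * fs_hz)), 0)
            j1 = min(int(round((tic + half_w) * fs_hz)) + 1, n)
            if j1 <= j0:
                continue
            u = (t[j0:j1] - tic) / half_w          # in [-1, 1]
            mask = np.abs(u) <= 1.0
            acc_v[j0:j1][mask] += amp * np.sin(np.pi * u[mask])

        strides = []
        for j in range(len(ics) - 2):
            strides.append(Stride(start_s=float(ics[j]), end_s=float(ics[j + 2]),
                                  length_m=spec.stride_length_m,
                                  foot="left" if j % 2 == 0 else "right"))
        truth.append(WalkingBout(start_s=float(ics[0]), end_s=float(ics[-1]),
                                 strides=strides,
                                 mean_speed_mps=spec.speed_mps))

    acc_v += 1.0  # gravity: at rest the vertical channel reads +1 g
    if protocol.noise_sd_g > 0:
        acc_v = acc_v + rng.normal(0.0, protocol.noise_sd_g, n)
        acc_ap = acc_ap + rng.normal(0.0, protocol.noise_sd_g, n)
        acc_ml = acc_ml + rng.normal(0.0, protocol.noise_sd_g, n)

    rec = ImuRecording(sampling_rate_hz=fs_hz, acc_v=acc_v, acc_ap=acc_ap,
                       acc_ml=acc_ml)
    return rec, truth


# ---------------------------------------------------------------------------
# Standard fixture suite
# ---------------------------------------------------------------------------

#: stride length paired with each cadence so bout speeds span ~0.35-1.4 m/s
SUITE_STRIDE_FOR_CADENCE = {60: 0.70, 80: 0.66, 100: 0.90, 120: 1.10, 140: 0.90}
SUITE_CADENCES = (60, 80, 100, 120, 140)
SUITE_DURATIONS_S = (5, 10, 30, 60, 120)
SUITE_ASYMMETRIES = (1.0, 0.5)
SUITE_NOISES_G = (0.0, 0.02, 0.05)
SUITE_LEAD_REST_S = 5.0


@dataclass(frozen=True)
class SuiteFixture:
    cadence_spm: float
    duration_s: float
    asymmetry: float
    noise_sd_g: float
    protocol: SimProtocol
    recording: ImuRecording
    truth: list[WalkingBout]

    @property
    def speed_mps(self) -> float:
        return self.truth[0].mean_speed_mps


def standard_fixture_suite(seed: int,
                           cadences=SUITE_CADENCES,
                           durations=SUITE_DURATIONS_S,
                           asymmetries=SUITE_ASYMMETRIES,
                           noises=SUITE_NOISES_G,
                           fs_hz: float = 100.0) -> list[SuiteFixture]:
    """Deterministic factorial suite over cadence x duration x asymmetry x
    noise, one single-bout recording per cell."""
    fixtures = []
    sub = 0
    for cad in cadences:
        stride = SUITE_STRIDE_FOR_CADENCE.get(cad, 0.9)
        for dur in durations:
            n_strides = max(3, int(round(dur * cad / 120.0)))
            for asym in asymmetries:
                for noise in noises:
                    sub += 1
                    spec = BoutSpec(start_s=SUITE_LEAD_REST_S,
                                    n_strides=n_strides, cadence_spm=cad,
                                    stride_length_m=stride, asymmetry=asym)
                    protocol = SimProtocol(bouts=(spec,), noise_sd_g=noise,
                                           seed=seed * 100003 + sub)
                    rec, truth = generate_recording(protocol, fs_hz)
                    fixtures.append(SuiteFixture(
                        cadence_spm=cad, duration_s=dur, asymmetry=asym,
                        noise_sd_g=noise, protocol=protocol, recording=rec,
                        truth=truth))
    return fixtures
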