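"""Synthetic pulse-like recordings and canonical reference processes.

The study's human recordings are not public, so this module generates
stand-ins with known statistical structure:

* :func:`generate_pulse` — a quasi-periodic arterial-pulse-like waveform:
  each cardiac cycle is a sum of three positive Gaussian lobes (percussion,
  tidal and dicrotic waves), beat-to-beat intervals jitter around the mean
  RR interval, and the trace is corrupted by sinusoidal baseline wander and
  additive broadband noise.
* :func:`generate_reference` — white noise, 1/f noise, the fully chaotic
  logistic map, a constant and a ramp; the standard validation processes for
  multiscale entropy estimators.
* :func:`generate_cohort` — a two-group design (labelled male/female) with a
  controllable complexity difference: group B's beat jitter and noise level
  are inflated by ``1 + effect``.

Everything is deterministic given the seed; per-record seeds are spawned
from the root seed via a counter so adding records never reshuffles
existing ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .io_formats import (
    CohortManifest,
    Hand,
    ManifestEntry,
    PulseRecord,
    Sex,
    write_manifest,
    write_pulse_csv,
)

__all__ = [
    "BeatMorphology",
    "SyntheticCohortSpec",
    "generate_pulse",
    "generate_reference",
    "generate_cohort",
    "write_cohort",
]

#: minimum physiologically plausible beat interval (s); RR jitter is
#: truncated so no interval falls below this.
MIN_RR_S = 0.3


@dataclass(frozen=True)
class BeatMorphology:
    """Shape of one cardiac cycle as three positive Gaussian lobes.

    Offsets and widths are fractions of the RR interval; amplitudes are
    relative to the percussion wave.  Defaults visually resemble a radial
    pressure pulse: a dominant percussion wave, a tidal wave on the falling
    edge and a small dicrotic wave.
    """

    amplitudes: tuple[float, float, float] = (1.0, 0.4, 0.25)
    offsets: tuple[float, float, float] = (0.15, 0.40, 0.65)
    widths: tuple[float, float, float] = (0.05, 0.07, 0.08)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a two-group synthetic pulse study.

    Defaults mirror the study design this generator stands in for: two
    groups of 100 subjects, 10 s records sampled at 200 Hz, resting heart
    rates centred near the middle of the 60-90 bpm band.  ``effect``
    multiplies group B's ``rr_jitter_sd`` and ``noise_sd`` by ``1 + effect``;
    ``effect = 0`` makes the two groups exchangeable.
    """

    n_per_group: int = 100
    fs: float = 200.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 75.0
    hr_between_sd_bpm: float = 6.0
    rr_jitter_sd: float = 0.04
    noise_sd: float = 0.03
    drift_amp: float = 0.3
    effect: float = 0.0
    seed: int = 0
    morphology: BeatMorphology = field(default_factory=BeatMorphology)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.fs * self.duration_s < 64:
            raise ValueError("record too short: fs * duration_s must be >= 64")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


def generate_pulse(
    fs: float = 200.0,
    duration_s: float = 10.0,
    heart_rate_bpm: float = 75.0,
    rr_jitter_sd: float = 0.04,
    noise_sd: float = 0.03,
    drift_amp: float = 0.3,
    morphology: BeatMorphology | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
    sex: Sex = Sex.UNKNOWN,
    hand: Hand = Hand.UNKNOWN,
) -> PulseRecord:
    """Generate one pulse-like recording.

    Beat onsets follow ``RR_i = 60/heart_rate_bpm + eps_i`` with iid normal
    jitter truncated to keep every interval above 0.3 s.  Each beat
    contributes three Gaussian lobes scaled to its own RR interval.  Baseline
    wander is a sinusoid of amplitude ``drift_amp`` with a random frequency
    in [0.05, 0.5] Hz and random phase; broadband noise is iid normal with
    SD ``noise_sd``.  Deterministic given the seed.
    """
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")
    if heart_rate_bpm <= 0:
        raise ValueError("heart_rate_bpm must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    morphology = morphology or BeatMorphology()

    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    mean_rr = 60.0 / heart_rate_bpm

    # beat onset times covering [0, duration]; start one beat early so a
    # (possibly partial) cycle is present at t = 0, as in a real recording
    onsets = [-mean_rr * rng.uniform(0.0, 1.0)]
    while onsets[-1] < duration_s:
        rr = mean_rr + rng.normal(0.0, rr_jitter_sd) if rr_jitter_sd > 0 else mean_rr
        onsets.append(onsets[-1] + max(rr, MIN_RR_S))
    onsets_arr = np.array(onsets)
    rrs = np.diff(onsets_arr)

    x = np.zeros(n)
    for onset, rr in zip(onsets_arr[:-1], rrs):
        for amp, off, width in zip(
            morphology.amplitudes, morphology.offsets, morphology.widths
        ):
            mu = onset + off * rr
            sigma = width * rr
            x += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    f_b = rng.uniform(0.05, 0.5)
    x += drift_amp * np.sin(2.0 * np.pi * f_b * t + phase)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)

    return PulseRecord(samples=x, fs=fs, subject_id=subject_id, sex=sex, hand=hand)


ReferenceProcess = Literal["white_noise", "one_over_f", "logistic_map", "constant", "ramp"]


def generate_reference(process: str, n: int, seed: int = 0) -> PulseRecord:
    """Generate a canonical reference series of length ``n``.

    ``white_noise`` — iid standard normal; ``one_over_f`` — spectral
    synthesis with amplitude proportional to 1/sqrt(f) and random phases,
    standardized to zero mean and unit variance; ``logistic_map`` — the fully
    chaotic map x -> 4x(1-x) after a 1000-step burn-in; ``constant`` — all
    ones; ``ramp`` — 1..n.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    if process == "white_noise":
        x = rng.standard_normal(n)
    elif process == "one_over_f":
        freqs = np.fft.rfftfreq(n, d=1.0)
        amp = np.zeros_like(freqs)
        amp[1:] = 1.0 / np.sqrt(freqs[1:])
        phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
        spectrum = amp * np.exp(1j * phases)
        spectrum[0] = 0.0
        x = np.fft.irfft(spectrum, n=n)
        x = (x - x.mean()) / x.std()
    elif process == "logistic_map":
        v = rng.uniform(0.05, 0.95)
        for _ in range(1000):
            v = 4.0 * v * (1.0 - v)
        x = np.empty(n)
        for i in range(n):
            x[i] = v
            v = 4.0 * v * (1.0 - v)
    elif process == "constant":
        x = np.ones(n)
    elif process == "ramp":
        x = np.arange(1, n + 1, dtype=float)
    else:
        raise ValueError(f"unknown reference process: {process!r}")
    return PulseRecord(samples=x, fs=1.0, subject_id=f"{process}-{seed}")


def _record_seed(root_seed: int, counter: int) -> np.random.Generator:
    # counter-keyed seed sequence: adding records never reshuffles earlier ones
    return np.random.default_rng(np.random.SeedSequence((root_seed, counter)))


def generate_cohort(
    spec: SyntheticCohortSpec,
    hand: Hand = Hand.LEFT,
) -> tuple[CohortManifest, list[PulseRecord]]:
    """Generate a two-group cohort of pulse records.

    Group A (labelled male) uses baseline parameters; group B (labelled
    female) has ``rr_jitter_sd`` and ``noise_sd`` scaled by ``1 + effect``.
    Per-subject resting heart rate varies around ``heart_rate_bpm`` with SD
    ``hr_between_sd_bpm`` (clipped to the 50-100 bpm band) in both groups.
    """
    entries: list[ManifestEntry] = []
    records: list[PulseRecord] = []
    counter = 0
    for sex, scale in ((Sex.MALE, 1.0), (Sex.FEMALE, 1.0 + spec.effect)):
        for i in range(spec.n_per_group):
            rng = _record_seed(spec.seed, counter)
            counter += 1
            hr = float(
                np.clip(
                    rng.normal(spec.heart_rate_bpm, spec.hr_between_sd_bpm),
                    50.0,
                    100.0,
                )
            )
            subject_id = f"{sex.value[0].upper()}{i:03d}"
            rec = generate_pulse(
                fs=spec.fs,
                duration_s=spec.duration_s,
                heart_rate_bpm=hr,
                rr_jitter_sd=spec.rr_jitter_sd * scale,
                noise_sd=spec.noise_sd * scale,
                drift_amp=spec.drift_amp,
                morphology=spec.morphology,
                seed=rng,
                subject_id=subject_id,
                sex=sex,
                hand=hand,
            )
            records.append(rec)
            entries.append(
                ManifestEntry(
                    record_path=f"{subject_id}_{hand.value}.csv",
                    subject_id=subject_id,
                    sex=sex,
                    hand=hand,
                )
            )
    return CohortManifest(entries), records


def write_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path, hand: Hand = Hand.LEFT
) -> Path:
    """Materialize a cohort on disk: sample CSVs, manifest and the spec as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, records = generate_cohort(spec, hand=hand)
    for entry, rec in zip(manifest, records):
        write_pulse_csv(rec, out_dir / entry.record_path)
    write_manifest(manifest, out_dir / "manifest.csv")
    spec_dict = asdict(spec)
    (out_dir / "cohort_spec.json").write_text(json.dumps(spec_dict, indent=2) + "\n")
    return out_dir / "manifest.csv"
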