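"""Construction of harmonic, jittered, onset-shifted, and pure-tone stimuli.

Harmonic stacks are built from integer multiples of a fundamental frequency
F0, temporal "coincidence" manipulations shift the onset of a designated
subgroup of components (the lower half of the stack, or the fundamental
alone) by a signed Δonset in milliseconds, and spectral jitter perturbs each
component frequency by an independent uniform draw.  Waveform synthesis sums
sine-phase components with linear rise/fall ramps.

Levels are nominal dB labels relative to a configurable full-scale
reference; no physical speaker calibration is modeled.  Times are in ms and
component intervals are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 192_000.0

ShiftGroup = Literal["lower_half", "fundamental", "none"]


@dataclass(frozen=True)
class ToneComponent:
    """One sine component: frequency (Hz), onset/duration/ramp (ms), level (dB)."""

    frequency: float
    onset: float = 0.0
    duration: float = 100.0
    level: float = 70.0
    ramp: float = 5.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.ramp < 0 or 2 * self.ramp > self.duration:
            raise ValueError("ramp must satisfy 0 <= 2*ramp <= duration")


@dataclass(frozen=True)
class StimulusSpec:
    """A multi-component sound with coincidence/jitter metadata.

    ``components`` are kept sorted by frequency.  ``f0`` is present only for
    exact harmonic stacks; jittered and pure-tone specs carry ``f0=None``.
    ``delta_onset`` (ms, signed) applies to ``shift_group`` only; negative
    values mean the shifted group leads the rest.
    """

    components: tuple[ToneComponent, ...]
    f0: float | None = None
    delta_onset: float = 0.0
    shift_group: ShiftGroup = "none"
    jitter_seed: int | None = None
    total_level: float = 70.0
    stim_id: str | None = None

    def __post_init__(self) -> None:
        freqs = [c.frequency for c in self.components]
        if freqs != sorted(freqs):
            object.__setattr__(
                self, "components", tuple(sorted(self.components, key=lambda c: c.frequency))
            )

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.components], dtype=float)

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class PresentationSchedule:
    """Block-randomized trial order: each block holds every stimulus once."""

    trials: tuple[tuple[int, str], ...]
    n_blocks: int

    @property
    def stimulus_ids(self) -> list[str]:
        return [s for _, s in self.trials]


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: float
    t0_ms: float = 0.0

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate


def make_harmonic_stack(
    f0: float,
    fmax: float,
    duration: float = 100.0,
    level: float = 70.0,
    ramp: float = 5.0,
    stim_id: str | None = None,
) -> StimulusSpec:
    """Harmonic stack with components at k*F0 for every k with k*F0 <= fmax.

    Component frequencies are computed as exact integer multiples, so
    harmonicity holds to the last float bit.
    """
    if f0 <= 0:
        raise ValueError(f"f0 must be > 0, got {f0}")
    if fmax < f0:
        raise ValueError(f"fmax ({fmax}) must be >= f0 ({f0})")
    n = int(np.floor(fmax / f0 + 1e-9))
    comps = tuple(
        ToneComponent(frequency=k * f0, onset=0.0, duration=duration, level=level, ramp=ramp)
        for k in range(1, n + 1)
    )
    return StimulusSpec(components=comps, f0=f0, total_level=level, stim_id=stim_id)


def apply_onset_shift(spec: StimulusSpec, delta: float, group: ShiftGroup) -> StimulusSpec:
    """Shift the onset of the designated component group by ``delta`` ms.

    ``lower_half`` shifts the floor(n/2) lowest-frequency components;
    ``fundamental`` shifts the single component at F0.  Unshifted components
    keep onset 0, which defines the stimulus reference time.
    """
    if group not in ("lower_half", "fundamental"):
        raise ValueError(f"group must be 'lower_half' or 'fundamental', got {group!r}")
    if spec.n_components < 2:
        raise ValueError("onset shift requires a spec with >= 2 components")
    if group == "fundamental":
        if spec.f0 is None:
            raise ValueError("fundamental shift requires a harmonic spec with F0")
        shifted = {0}  # components are frequency-sorted; the fundamental is first
    else:
        shifted = set(range(spec.n_components // 2))
    comps = tuple(
        replace(c, onset=float(delta) if i in shifted else 0.0)
        for i, c in enumerate(spec.components)
    )
    return replace(spec, components=comps, delta_onset=float(delta), shift_group=group)


def make_jittered(
    spec: StimulusSpec,
    jitter_halfwidth: float,
    seed: int,
    on_nonpositive: Literal["redraw", "reject"] = "redraw",
) -> StimulusSpec:
    """Perturb each component frequency by Uniform(-halfwidth, +halfwidth).

    The same seed reproduces the same frequency set, so a jittered stimulus
    can be held fixed within a block while its Δonset varies.  A draw that
    would make a frequency non-positive is redrawn (default, logged) or
    rejected depending on ``on_nonpositive``.
    """
    if spec.f0 is None:
        raise ValueError("make_jittered expects a harmonic spec (f0 set)")
    if jitter_halfwidth < 0:
        raise ValueError("jitter_halfwidth must be >= 0")
    rng = np.random.default_rng(seed)
    comps = []
    for c in spec.components:
        f = c.frequency + rng.uniform(-jitter_halfwidth, jitter_halfwidth)
        n_redraw = 0
        while f <= 0:
            if on_nonpositive == "reject":
                raise ValueError(f"jittered frequency {f} <= 0 for component at {c.frequency} Hz")
            f = c.frequency + rng.uniform(-jitter_halfwidth, jitter_halfwidth)
            n_redraw += 1
        if n_redraw:
            logger.info("redrew jitter %d time(s) for component at %g Hz", n_redraw, c.frequency)
        comps.append(replace(c, frequency=float(f)))
    return replace(spec, components=tuple(comps), f0=None, jitter_seed=int(seed))


def make_pure_tone_set(
    fmin: float,
    fmax: float,
    n_freqs: int,
    levels: Sequence[float],
    duration: float = 100.0,
    ramp: float = 5.0,
) -> list[StimulusSpec]:
    """Log-spaced pure tones, one spec per (frequency, level), endpoints inclusive."""
    if fmin <= 0 or fmax <= 0:
        raise ValueError("frequencies must be positive")
    if not fmin < fmax:
        raise ValueError("fmin must be < fmax")
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    freqs = np.geomspace(fmin, fmax, n_freqs)
    specs = []
    for level in levels:
        for f in freqs:
            comp = ToneComponent(frequency=float(f), duration=duration, level=level, ramp=ramp)
            specs.append(
                StimulusSpec(
                    components=(comp,),
                    total_level=level,
                    stim_id=f"tone_{f:.0f}Hz_{level:g}dB",
                )
            )
    return specs


def db_to_amplitude(level_db: float, ref_db: float) -> float:
    """Linear amplitude for a dB label relative to ``ref_db`` (amplitude 1.0)."""
    return 10.0 ** ((level_db - ref_db) / 20.0)


def synthesize_waveform(
    spec: StimulusSpec,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    ref_db: float | None = None,
    normalize: bool = True,
) -> Waveform:
    """Render a spec to samples: sine-phase components with linear ramps.

    With ``normalize=True`` (default) every component gets the same amplitude
    and the coherent sine-phase peak sum equals the linear amplitude of
    ``total_level`` re ``ref_db`` (default: ``ref_db = total_level``, i.e.
    full-scale peak 1.0).  ``normalize=False`` gives each component unit
    amplitude, which exposes coherent summation directly.

    The returned waveform spans the earliest component onset (``t0_ms``) to
    the latest offset.
    """
    if not spec.components:
        return Waveform(samples=np.zeros(0), sample_rate=sample_rate)
    fmax = max(c.frequency for c in spec.components)
    if fmax >= sample_rate / 2:
        raise ValueError(
            f"component at {fmax} Hz >= Nyquist ({sample_rate / 2} Hz); raise sample_rate"
        )
    t0 = min(c.onset for c in spec.components)
    t1 = max(c.onset + c.duration for c in spec.components)
    n = int(round((t1 - t0) / 1000.0 * sample_rate))
    y = np.zeros(n)
    if normalize:
        amp = db_to_amplitude(spec.total_level, spec.total_level if ref_db is None else ref_db)
        per_comp = amp / spec.n_components
    else:
        per_comp = 1.0
    t = t0 + np.arange(n) / sample_rate * 1000.0  # ms
    for c in spec.components:
        local = (t - c.onset) / 1000.0  # s since component onset
        active = (local >= 0) & (local < c.duration / 1000.0)
        env = np.zeros(n)
        env[active] = 1.0
        if c.ramp > 0:
            ramp_s = c.ramp / 1000.0
            rise = active & (local < ramp_s)
            fall = active & (local >= c.duration / 1000.0 - ramp_s)
            env[rise] = local[rise] / ramp_s
            env[fall] = (c.duration / 1000.0 - local[fall]) / ramp_s
        y += per_comp * env * np.sin(2 * np.pi * c.frequency * np.where(active, local, 0.0))
    return Waveform(samples=y, sample_rate=sample_rate, t0_ms=float(t0))


def build_schedule(
    stimulus_ids: Sequence[str], n_blocks: int, seed: int
) -> PresentationSchedule:
    """Blockwise-randomized schedule: each block is a fresh permutation of all ids."""
    if len(stimulus_ids) == 0:
        raise ValueError("stimulus list must be non-empty")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[tuple[int, str]] = []
    ids = list(stimulus_ids)
    for b in range(n_blocks):
        order = rng.permutation(len(ids))
        trials.extend((b, ids[i]) for i in order)
    return PresentationSchedule(trials=tuple(trials), n_blocks=n_blocks)


def write_wav(path: str, wave: Waveform) -> None:
    """Write a waveform as 32-bit float PCM."""
    wavfile.write(path, int(wave.sample_rate), wave.samples.astype(np.float32))


def stimulus_table(specs: Iterable[StimulusSpec]) -> pd.DataFrame:
    """Tabulate specs (one row each) for CSV export."""
    rows = []
    for i, s in enumerate(specs):
        rows.append(
            {
                "stim_id": s.stim_id if s.stim_id is not None else f"stim{i:03d}",
                "F0_Hz": s.f0,
                "delta_onset_ms": s.delta_onset,
                "shift_group": s.shift_group,
                "jitter_seed": s.jitter_seed,
                "component_freqs": ";".join(f"{c.frequency:.1f}" for c in s.components),
            }
        )
    return pd.DataFrame(rows)
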