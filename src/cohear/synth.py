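"""Ground-truthed synthetic inputs for every pipeline stage.

Four generators emulate the data modalities the analysis consumes:

* ``generate_population`` — a two-photon session with planted response
  archetypes (coincidence-, negative-shift-, positive-shift-preferring and
  nonresponsive cells), shared-latent "subnetwork" noise among same-F0
  coincidence cells, calcium-kernel dynamics, background (neuropil)
  contamination, and spatial clustering of subnetwork members.
* ``generate_vocal_audio`` — harmonic syllables with known fundamentals in
  white noise at a stated SNR.
* ``generate_ephys_session`` — inhomogeneous-Poisson spike trains with an
  optional exponential optogenetic-suppression profile.
* ``generate_behavior_session`` — Bernoulli lick outcomes from a planted
  logistic psychometric function on the log-modulus Δonset scale, with an
  optional light-trial threshold shift.

Every generator is deterministic under a fixed seed.  Planted amplitudes
are in calibrated ΔF/F·s units: traces are constructed so that the analysis
side's normalization and trapezoidal response integration return exactly
the planted values in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import DFF_OFFSET, NEUROPIL_R, RoiSession
from .stimuli import build_schedule

ARCHETYPES = ("negative_shift", "positive_shift", "coincidence", "nonresponsive")


@dataclass(frozen=True)
class ArchetypeSpec:
    """A response archetype: peak ΔF/F·s amplitude and per-Δonset weights."""

    kind: str
    peak_amplitude: float
    weights: dict  # delta_onset (ms) -> weight in [0, 1]

    def __post_init__(self) -> None:
        w = self.weights
        if self.kind == "nonresponsive":
            if any(v != 0 for v in w.values()):
                raise ValueError("nonresponsive archetype must have all-zero weights")
            return
        if not w:
            raise ValueError("archetype needs weights")
        peak_delta = max(w, key=w.get)
        if self.kind == "coincidence" and peak_delta != 0:
            raise ValueError("coincidence archetype must peak at delta_onset = 0")
        if self.kind == "negative_shift" and peak_delta >= 0:
            raise ValueError("negative_shift archetype must peak at a negative delta")
        if self.kind == "positive_shift" and peak_delta <= 0:
            raise ValueError("positive_shift archetype must peak at a positive delta")


def default_archetypes(
    delta_onsets: tuple = (-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0),
    peak_amplitude: float = 0.5,
) -> dict[str, ArchetypeSpec]:
    """Archetypes resembling the three empirical response-profile clusters."""
    deltas = tuple(float(d) for d in delta_onsets)
    neg = {d: (1.0 if d < 0 else (0.1 if d == 0 else 0.0)) for d in deltas}
    pos = {d: (1.0 if d > 0 else (0.1 if d == 0 else 0.0)) for d in deltas}
    coin = {d: (1.0 if d == 0 else (0.1 if abs(d) == 15 else 0.0)) for d in deltas}
    none = {d: 0.0 for d in deltas}
    return {
        "negative_shift": ArchetypeSpec("negative_shift", peak_amplitude, neg),
        "positive_shift": ArchetypeSpec("positive_shift", peak_amplitude, pos),
        "coincidence": ArchetypeSpec("coincidence", peak_amplitude, coin),
        "nonresponsive": ArchetypeSpec("nonresponsive", 0.0, none),
    }


@dataclass(frozen=True)
class PopulationConfig:
    """Study conditions for a synthetic imaging session.

    Defaults follow the emulated protocol: five fundamentals, seven Δonsets
    from −45 to 45 ms in 15 ms steps, five randomized blocks (five trials
    per stimulus), 30 Hz imaging, GCaMP6s-like kinetics (50 ms rise, 1 s
    decay).  ``trial_noise_sd`` is multiplicative on response amplitudes;
    ``trace_noise_sd`` is additive per-frame ΔF/F noise;
    ``latent_sd`` scales the shared within-subnetwork amplitude noise.
    """

    f0s: tuple = (2000.0, 2800.0, 4000.0, 5700.0, 8000.0)
    delta_onsets: tuple = (-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0)
    n_per_archetype: tuple = (
        ("negative_shift", 4),
        ("positive_shift", 4),
        ("coincidence", 4),
        ("nonresponsive", 2),
    )
    n_blocks: int = 5
    frame_rate: float = 30.0
    trial_interval_s: float = 4.0
    baseline_s: float = 1.0
    response_window_s: float = 1.0
    peak_amplitude: float = 0.5
    trial_noise_sd: float = 0.2
    trace_noise_sd: float = 0.02
    latent_sd: float = 0.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 1.0
    cell_baseline: float = 200.0
    bg_baseline: float = 100.0
    bg_noise_sd: float = 2.0
    neuropil_r: float = NEUROPIL_R
    dff_offset: float = DFF_OFFSET
    field_um: float = 620.0
    cluster_radius_um: float = 50.0
    seed: int = 0


@dataclass
class SyntheticSession:
    """A synthetic RoiSession plus its full ground truth."""

    session: RoiSession
    truth: pd.DataFrame  # per ROI: archetype, f0, subnetwork, x, y
    stim_table: pd.DataFrame  # per stimulus: stim_id, f0, delta_onset
    planted_weights: pd.DataFrame  # stim_id x roi planted mean amplitudes
    trial_amplitudes: np.ndarray  # (n_rois, n_stimuli, n_trials) planted
    config: PopulationConfig


def calcium_kernel(config: PopulationConfig) -> np.ndarray:
    """Difference-of-exponentials kernel, unit trapezoidal area over the
    response window, truncated before the next trial's baseline."""
    fr = config.frame_rate
    support_s = max(
        config.response_window_s,
        config.trial_interval_s - config.baseline_s - 0.5,
    )
    t = np.arange(0.0, support_s, 1.0 / fr)
    k = np.exp(-t / config.kernel_decay_s) - np.exp(-t / config.kernel_rise_s)
    n_win = int(round(config.response_window_s * fr))
    area = np.trapezoid(k[:n_win], dx=1.0 / fr)
    return k / area


def latent_sd_for_target_r(target_r: float, amplitude_noise_sd: float) -> float:
    """Latent SD giving pairwise noise correlation target_r for cells whose
    per-trial amplitude noise SD is ``amplitude_noise_sd``:
    r = σ_l² / (σ_l² + σ_n²)."""
    if not 0 <= target_r < 1:
        raise ValueError("target_r must be in [0, 1)")
    return amplitude_noise_sd * np.sqrt(target_r / (1.0 - target_r))


def subnetwork_amplitude_noise_rms(
    config: PopulationConfig, archetypes: dict[str, ArchetypeSpec] | None = None
) -> float:
    """RMS (across stimuli) per-trial amplitude-noise SD of a coincidence cell.

    The multiplicative trial noise has SD w·peak·trial_noise_sd at each
    stimulus; noise correlation pools residuals over all stimuli, so the
    closed form r = σ_l²/(σ_l² + σ_n²) holds with σ_n equal to this RMS.
    Use it with :func:`latent_sd_for_target_r` to plant a target r.
    """
    if archetypes is None:
        archetypes = default_archetypes(config.delta_onsets, config.peak_amplitude)
    spec = archetypes["coincidence"]
    n_stim = len(config.f0s) * len(config.delta_onsets)
    # nonzero weights only at the cell's own F0
    w2 = [spec.weights[d] ** 2 for d in config.delta_onsets]
    mean_w2 = sum(w2) / n_stim
    return float(spec.peak_amplitude * config.trial_noise_sd * np.sqrt(mean_w2))


def _stimulus_table(config: PopulationConfig) -> pd.DataFrame:
    rows = [
        {"stim_id": f"h{int(f0)}_d{int(d):+d}", "f0": f0, "delta_onset": d}
        for f0 in config.f0s
        for d in config.delta_onsets
    ]
    return pd.DataFrame(rows)


def _make_rois(config: PopulationConfig, archetypes: dict[str, ArchetypeSpec]) -> pd.DataFrame:
    rows = []
    for f0 in config.f0s:
        for kind, count in config.n_per_archetype:
            if kind not in archetypes:
                raise ValueError(f"unknown archetype {kind!r}")
            for _ in range(count):
                rows.append(
                    {
                        "archetype": kind,
                        "f0": f0,
                        "subnetwork": f"coin_{int(f0)}" if kind == "coincidence" else "",
                    }
                )
    df = pd.DataFrame(rows)
    df.index.name = "roi"
    return df


def generate_trial_amplitudes(
    config: PopulationConfig,
    archetypes: dict[str, ArchetypeSpec] | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planted per-trial amplitudes without trace rendering.

    Returns ``(amps, truth, stim_table, weights)`` where ``amps`` has shape
    (n_rois, n_stimuli, n_blocks); trial index within a stimulus is the
    block index.  Amplitude model per trial:

        a = w(archetype, Δonset) * peak * (1 + ε) + λ

    with ε ~ N(0, trial_noise_sd) i.i.d. per (roi, trial) and λ ~
    N(0, latent_sd) shared by all members of the roi's subnetwork on that
    trial (0 for cells without a subnetwork).
    """
    if archetypes is None:
        archetypes = default_archetypes(config.delta_onsets, config.peak_amplitude)
    for a in archetypes.values():
        missing = set(config.delta_onsets) - set(a.weights)
        if missing:
            raise ValueError(f"archetype {a.kind} lacks weights for Δonsets {sorted(missing)}")
    stim = _stimulus_table(config)
    truth = _make_rois(config, archetypes)
    n_rois, n_stim = len(truth), len(stim)
    rng = np.random.default_rng(config.seed)

    w = np.zeros((n_rois, n_stim))
    for roi, row in truth.iterrows():
        spec = archetypes[row["archetype"]]
        for s, srow in stim.iterrows():
            if srow["f0"] == row["f0"]:
                w[roi, s] = spec.weights[srow["delta_onset"]] * spec.peak_amplitude

    eps = rng.normal(0.0, config.trial_noise_sd, size=(n_rois, n_stim, config.n_blocks))
    amps = w[:, :, None] * (1.0 + eps)
    subnets = [s for s in truth["subnetwork"].unique() if s]
    # one latent draw per (subnetwork, stimulus, block): shared across members
    for sub in subnets:
        members = truth.index[truth["subnetwork"] == sub].to_numpy()
        lat = rng.normal(0.0, config.latent_sd, size=(n_stim, config.n_blocks))
        amps[members] += lat[None, :, :]
    weights = pd.DataFrame(w.T, index=stim["stim_id"], columns=truth.index)
    return amps, truth, stim, weights


def generate_population(
    config: PopulationConfig,
    archetypes: dict[str, ArchetypeSpec] | None = None,
) -> SyntheticSession:
    """Render a full synthetic imaging session with ground truth.

    Planted trial amplitudes drive a truncated difference-of-exponentials
    calcium kernel; fluorescence is written as
    F_cell = B + (B + offset)·ΔF/F so the analysis normalization
    (F − F₀)/(F₀ + offset) is exactly inverted, and neuropil contamination
    F_measured = F_cell + r·F_bg is added so the correction step is
    exercised.  Same-F0 coincidence cells are placed in a compact spatial
    cluster; everyone else is uniform over the field.
    """
    amps, truth, stim, weights = generate_trial_amplitudes(config, archetypes)
    n_rois, n_stim, n_blocks = amps.shape
    rng = np.random.default_rng(config.seed + 1)
    fr = config.frame_rate

    schedule = build_schedule(list(stim["stim_id"]), n_blocks, seed=config.seed + 2)
    n_trials = len(schedule.trials)
    pre_pad_s = config.baseline_s + 0.5
    onset_frames = np.array(
        [int(round((pre_pad_s + i * config.trial_interval_s) * fr)) for i in range(n_trials)]
    )
    t_frames = onset_frames[-1] + int(round(config.trial_interval_s * fr)) + 1

    kernel = calcium_kernel(config)
    stim_index = {sid: k for k, sid in enumerate(stim["stim_id"])}
    block_counter = {sid: 0 for sid in stim["stim_id"]}
    trial_rows = []
    dff = np.zeros((n_rois, t_frames))
    for i, (block, sid) in enumerate(schedule.trials):
        s = stim_index[sid]
        b = block_counter[sid]
        block_counter[sid] += 1
        on = onset_frames[i]
        seg = slice(on, min(t_frames, on + kernel.size))
        dff[:, seg] += amps[:, s, b, None] * kernel[: seg.stop - seg.start]
        trial_rows.append({"stim_id": sid, "onset_frame": on, "block": block})
    trials = pd.DataFrame(trial_rows)

    if config.trace_noise_sd > 0:
        dff += rng.normal(0.0, config.trace_noise_sd, size=dff.shape)
    b_cell, off = config.cell_baseline, config.dff_offset
    f_true = b_cell + (b_cell + off) * dff
    f_bg = np.full_like(dff, config.bg_baseline)
    if config.bg_noise_sd > 0:
        f_bg += rng.normal(0.0, config.bg_noise_sd, size=dff.shape)
    f_measured = f_true + config.neuropil_r * f_bg

    coords = rng.uniform(0.0, config.field_um, size=(n_rois, 2))
    margin = 3 * config.cluster_radius_um
    for sub in [s for s in truth["subnetwork"].unique() if s]:
        members = truth.index[truth["subnetwork"] == sub].to_numpy()
        center = rng.uniform(margin, config.field_um - margin, size=2)
        coords[members] = rng.normal(center, config.cluster_radius_um, size=(members.size, 2))
    truth = truth.assign(x=coords[:, 0], y=coords[:, 1])

    session = RoiSession(
        f_cell=f_measured,
        f_bg=f_bg,
        coords=coords,
        frame_rate=fr,
        trials=trials,
        cell_type="pyr",
    )
    return SyntheticSession(
        session=session,
        truth=truth.reset_index(),
        stim_table=stim,
        planted_weights=weights,
        trial_amplitudes=amps,
        config=config,
    )


def generate_vocal_audio(
    f0_sequence: list[float],
    syllable_ms: float = 60.0,
    gap_ms: float = 80.0,
    n_harmonics: int = 3,
    snr_db: float = 20.0,
    sample_rate: float = 96_000.0,
    ramp_ms: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Harmonic syllables at the listed fundamentals embedded in white noise.

    Each syllable is a sum of ``n_harmonics`` equal-amplitude sine
    components at k·F0 with linear ramps; silent gaps separate syllables and
    pad both ends.  Noise RMS is set ``snr_db`` below the syllable RMS
    (``snr_db=None`` → no noise).  Returns the waveform and a ground-truth
    table (onset_s, offset_s, f0).
    """
    if any(f <= 0 for f in f0_sequence):
        raise ValueError("fundamentals must be positive")
    rng = np.random.default_rng(seed)
    n_syl = int(round(syllable_ms / 1000.0 * sample_rate))
    n_gap = int(round(gap_ms / 1000.0 * sample_rate))
    t = np.arange(n_syl) / sample_rate
    env = np.ones(n_syl)
    n_ramp = int(round(ramp_ms / 1000.0 * sample_rate))
    if n_ramp > 0:
        env[:n_ramp] = np.linspace(0, 1, n_ramp, endpoint=False)
        env[-n_ramp:] = np.linspace(1, 0, n_ramp)
    pieces = [np.zeros(n_gap)]
    rows = []
    pos = n_gap
    for f0 in f0_sequence:
        syl = np.zeros(n_syl)
        for k in range(1, n_harmonics + 1):
            if k * f0 < sample_rate / 2:
                syl += np.sin(2 * np.pi * k * f0 * t) / n_harmonics
        syl *= env
        rows.append(
            {
                "onset_s": pos / sample_rate,
                "offset_s": (pos + n_syl) / sample_rate,
                "f0": float(f0),
            }
        )
        pieces.extend([syl, np.zeros(n_gap)])
        pos += n_syl + n_gap
    audio = np.concatenate(pieces)
    if snr_db is not None and len(f0_sequence) > 0:
        syl_rms = np.sqrt(np.mean(np.concatenate([p for p in pieces if p.any()]) ** 2))
        noise_rms = syl_rms / 10.0 ** (snr_db / 20.0)
        audio = audio + rng.normal(0.0, noise_rms, size=audio.size)
    return audio, pd.DataFrame(rows)


def generate_ephys_session(
    rate_fn,
    n_trials: int,
    t_range_ms: tuple[float, float] = (0.0, 1000.0),
    suppression: tuple[float, float, float] | None = None,
    led: bool = False,
    dt_ms: float = 0.1,
    seed: int = 0,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains (times in ms, one array per trial).

    ``rate_fn(t_ms)`` gives the instantaneous rate in Hz.  On LED trials
    (``led=True``) with ``suppression=(latency_ms, tau_ms, floor)``, the
    rate is multiplied by floor + (1 − floor)·exp(−(t − latency)/tau)
    for t ≥ latency (light onset at t = 0).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_range_ms[0], t_range_ms[1], dt_ms)
    rate = np.clip(np.asarray(rate_fn(t), dtype=float), 0.0, None)
    if led and suppression is not None:
        latency, tau, floor = suppression
        mod = np.ones_like(t)
        after = t >= latency
        mod[after] = floor + (1.0 - floor) * np.exp(-(t[after] - latency) / tau)
        rate = rate * mod
    p = rate * dt_ms / 1000.0
    trains = []
    for _ in range(n_trials):
        spikes = t[rng.random(t.size) < p]
        trains.append(spikes + rng.uniform(0, dt_ms, size=spikes.size))
    return trains


def generate_behavior_session(
    midpoint_ms: float = 20.0,
    slope: float = 4.0,
    n_trials: int = 250,
    delta_grid_ms: tuple = (0.0, -15.0, -30.0, -45.0, -60.0, -75.0),
    led_fraction: float = 0.30,
    led_midpoint_shift_ms: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli lick outcomes from a planted log-modulus logistic.

    Lick probability is 1/(1 + exp(slope·(x − x_mid))) with
    x = log10(1 + |Δonset|) and x_mid = log10(1 + midpoint_ms): high for
    near-coincident stimuli, 50% at |Δ| = midpoint.  A fraction of trials
    (default 30%, randomly interleaved) carries the light flag and uses the
    shifted midpoint.  Returns a trial table (trial, delta_onset_ms, led,
    lick).
    """
    if len(delta_grid_ms) == 0:
        raise ValueError("delta grid must be non-empty")
    rng = np.random.default_rng(seed)
    deltas = rng.choice(np.asarray(delta_grid_ms, dtype=float), size=n_trials)
    led = rng.random(n_trials) < led_fraction
    mids = np.where(led, midpoint_ms + led_midpoint_shift_ms, midpoint_ms)
    x = np.log10(1.0 + np.abs(deltas))
    x_mid = np.log10(1.0 + np.abs(mids))
    if np.isinf(slope):
        p = (x < x_mid).astype(float)
    else:
        p = 1.0 / (1.0 + np.exp(slope * (x - x_mid)))
    lick = rng.random(n_trials) < p
    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "delta_onset_ms": deltas,
            "led": led,
            "lick": lick,
        }
    )
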