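"""Synthetic oximetry records with ground truth.

Emulates the regimes seen in intradialytic SaO2: a quasi-constant
baseline near 94.3% with slow drift and low-amplitude white measurement
noise, interrupted by episodes of repetitive sawtooth desaturation
trains (slow fall, fast recovery; per-cycle depth 3-10 percentage
points, per-cycle period 30-90 s) and, optionally, isolated rectangular
desaturations.  Depth and baseline are independent, so oscillation
trains that never cross the conventional 90% hypoxemia line are just as
generatable as ones that do.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import OximetryRecord

__all__ = ["Episode", "SyntheticConfig", "GroundTruth", "generate_record", "generate_corpus"]


@dataclass
class Episode:
    start_s: float
    end_s: float
    kind: str = "ihhop"  # or "isolated_desat"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("episode must have start < end")
        if self.kind not in ("ihhop", "isolated_desat"):
            raise ValueError(f"unknown episode kind {self.kind!r}")


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions."""

    duration_s: float = 10800.0
    fs: float = 1.0
    baseline_mean: float = 94.3  # cohort mean SaO2, percent
    baseline_sd: float = 2.1  # across-record spread of the mean
    noise_sd: float = 0.3  # within-record white measurement noise
    drift_amplitude: float = 0.5  # slow physiological wandering, percent
    drift_period_s: float = 1800.0
    episodes: list[Episode] = field(default_factory=list)
    cycle_period_range_s: tuple[float, float] = (30.0, 90.0)
    dip_depth_range_pct: tuple[float, float] = (3.0, 10.0)
    waveform: str = "sawtooth"  # or "sine"
    episode_irregularity: float = 0.25  # relative sd of the dip-train modulation
    episode_irregularity_tau_s: float = 8.0  # correlation time of that modulation
    desat_depth_pct: float = 5.0  # isolated rectangular dips
    desat_duration_s: float = 30.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.waveform not in ("sawtooth", "sine"):
            raise ValueError("waveform must be 'sawtooth' or 'sine'")
        eps = sorted(self.episodes, key=lambda e: e.start_s)
        for e in eps:
            if e.start_s < 0 or e.end_s > self.duration_s:
                raise ValueError("episode outside record span")
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise ValueError("episodes must not overlap")
        self.episodes = eps


@dataclass
class GroundTruth:
    """What was injected: per-sample episode mask and event list."""

    episode_mask: np.ndarray
    episodes: list[Episode]
    injected: list[dict]  # onset_s / duration_s / depth_pct per dip cycle


#: fraction of a sawtooth cycle spent desaturating (the recovery is fast)
SAWTOOTH_FALL_FRACTION = 0.75


def _dip_train(t: np.ndarray, episode: Episode, cfg: SyntheticConfig, rng) -> tuple[np.ndarray, list[dict]]:
    """Subtractive dip profile for one ihhop episode, plus its cycle log."""
    dip = np.zeros_like(t)
    injected = []
    cursor = episode.start_s
    while cursor < episode.end_s:
        period = rng.uniform(*cfg.cycle_period_range_s)
        depth = rng.uniform(*cfg.dip_depth_range_pct)
        period = min(period, episode.end_s - cursor)
        if period < 2.0 / cfg.fs:
            break
        phase = (t - cursor) / period
        inside = (phase >= 0) & (phase < 1)
        if cfg.waveform == "sawtooth":
            f = SAWTOOTH_FALL_FRACTION
            shape = np.where(phase < f, phase / f, (1 - phase) / (1 - f))
        else:
            shape = np.sin(np.pi * phase) ** 2
        dip[inside] += depth * shape[inside]
        injected.append({"onset_s": cursor, "duration_s": period, "depth_pct": depth})
        cursor += period
    if cfg.episode_irregularity > 0 and dip.any():
        # Obstructed-breathing desaturations are not clean ramps: breath-to-
        # breath variability and arousal artifacts make the saturation
        # trajectory irregular in proportion to how deep it has fallen.  A
        # smooth AR(1) relative modulation of the dip train reproduces that
        # heteroscedastic jitter; without it the trains are deterministic
        # periodic signals, the opposite of the intermittent phenotype.
        from scipy.signal import lfilter

        a = float(np.exp(-1.0 / (cfg.fs * cfg.episode_irregularity_tau_s)))
        w = rng.normal(0.0, 1.0, size=t.size)
        j = lfilter([np.sqrt(1 - a * a)], [1.0, -a], w)
        dip = dip * np.clip(1.0 + cfg.episode_irregularity * j, 0.0, 2.0)
    return dip, injected


def generate_record(config: SyntheticConfig, rng: np.random.Generator | None = None) -> tuple[OximetryRecord, GroundTruth]:
    """One synthetic SaO2 record plus its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    if n < 2:
        raise ValueError("record too short")
    t = np.arange(n) / config.fs
    # slow drift: two incommensurate sinusoids with random phases
    ph = rng.uniform(0, 2 * np.pi, size=2)
    drift = config.drift_amplitude * (
        0.6 * np.sin(2 * np.pi * t / config.drift_period_s + ph[0])
        + 0.4 * np.sin(2 * np.pi * t / (config.drift_period_s / 2.7) + ph[1])
    )
    values = config.baseline_mean + drift + rng.normal(0.0, config.noise_sd, size=n)
    mask = np.zeros(n, dtype=bool)
    injected: list[dict] = []
    for ep in config.episodes:
        sel = (t >= ep.start_s) & (t < ep.end_s)
        mask |= sel
        if ep.kind == "ihhop":
            dip, log = _dip_train(t, ep, config, rng)
            values -= dip
            injected.extend(log)
        else:
            values[sel] -= config.desat_depth_pct
            injected.append(
                {
                    "onset_s": ep.start_s,
                    "duration_s": ep.end_s - ep.start_s,
                    "depth_pct": config.desat_depth_pct,
                }
            )
    values = np.clip(values, 0.0, 100.0)
    record = OximetryRecord.from_values(values, fs=config.fs)
    return record, GroundTruth(episode_mask=mask, episodes=list(config.episodes), injected=injected)


def _auto_schedule(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    n_episodes_range: tuple[int, int],
    episode_duration_range_s: tuple[float, float] | None,
    start_margin_s: float,
) -> list[Episode]:
    """Place non-overlapping ihhop episodes at random within the record.

    Short records (at most one episode-duration long) get a single
    episode spanning the whole record — the homogeneous-segment case.
    """
    if episode_duration_range_s is None:
        return [Episode(0.0, cfg.duration_s, "ihhop")]
    k = int(rng.integers(n_episodes_range[0], n_episodes_range[1] + 1))
    lo = min(start_margin_s, cfg.duration_s / 4)
    for _ in range(200):  # rejection-sample a non-overlapping layout
        eps = []
        ok = True
        for _ in range(k):
            dur = rng.uniform(*episode_duration_range_s)
            if lo + dur >= cfg.duration_s:
                ok = False
                break
            start = rng.uniform(lo, cfg.duration_s - dur)
            eps.append(Episode(start, start + dur, "ihhop"))
        if not ok:
            continue
        eps.sort(key=lambda e: e.start_s)
        if all(b.start_s - a.end_s >= 60.0 for a, b in zip(eps, eps[1:])):
            return eps
    raise ValueError("could not place the requested episodes")


def generate_corpus(
    n_records: int,
    mix: float,
    template: SyntheticConfig,
    seed: int,
    n_episodes_range: tuple[int, int] = (1, 1),
    episode_duration_range_s: tuple[float, float] | None = None,
    start_margin_s: float = 600.0,
) -> list[tuple[OximetryRecord, GroundTruth]]:
    """A corpus of records, a fraction ``mix`` of which carry episodes.

    Per-record baseline means are drawn from Normal(baseline_mean,
    baseline_sd); all per-record randomness derives from one master seed
    via numpy's SeedSequence spawning, so the corpus is reproducible and
    records are independent.  The first round(mix * n) records carry
    episodes (shuffle downstream if order matters).
    """
    if n_records < 2:
        raise ValueError("need at least 2 records")
    if not 0 <= mix <= 1:
        raise ValueError("mix must be in [0, 1]")
    children = np.random.SeedSequence(seed).spawn(n_records)
    n_with = int(round(mix * n_records))
    out = []
    for i in range(n_records):
        rng = np.random.default_rng(children[i])
        base = rng.normal(template.baseline_mean, template.baseline_sd)
        base = float(np.clip(base, 80.0, 99.5))
        if i < n_with:
            episodes = _auto_schedule(
                template, rng, n_episodes_range, episode_duration_range_s, start_margin_s
            )
        else:
            episodes = []
        cfg = replace(template, baseline_mean=base, episodes=episodes, seed=None)
        out.append(generate_record(cfg, rng=rng))
    return out
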