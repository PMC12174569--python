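"""Synthetic mosquito flight-trajectory generator.

Emulates free-flight video-tracking trials around a human-baited bednet:
25 mosquitoes released per 2-hour trial, positions recorded at 50 frames
per second in a ~1.2 m x 1.0 m telecentric field of view.  Flight is a
discrete-time correlated random walk whose knobs map one-to-one onto the
behavioural contrast between an untreated net (UT: fairly directed flight
with regular hovering pauses) and a permethrin-incorporated Olyset net
(OL: convoluted, tremor-ridden flight with frequent horizontal direction
reversals and almost no pausing).
Insecticide-susceptible (IS) mosquitoes at the treated net are censored
after a mortality cutoff (default 30 min), after which no new tracks start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "BehaviourParams",
    "TrackDurationLaw",
    "GapLaw",
    "TrialSpec",
    "Track",
    "STRAIN_RESISTANCE",
    "UT_PARAMS",
    "OL_PARAMS",
    "simulate_track",
    "inject_gaps",
    "drop_samples",
    "simulate_trial",
    "simulate_study",
    "study_metadata",
    "study_tracks",
    "contrast_study",
]

#: fraction of flight time free of tremor (calm spells) and the mean calm
#: spell length in frames, when ``turn_floor`` > 0
TREMOR_CALM_FRAC = 0.12
TREMOR_CALM_RUN = 40.0

#: canonical strains of the study design: two insecticide-susceptible,
#: two pyrethroid-resistant.
STRAIN_RESISTANCE = {
    "Kisumu": "IS",
    "NGousso": "IS",
    "VK7": "IR",
    "Banfora": "IR",
}


@dataclass(frozen=True)
class BehaviourParams:
    """Knobs of the correlated-random-walk flight model.

    Parameters
    ----------
    mean_speed, speed_sd
        Per-frame flight speed is drawn from N(mean_speed, speed_sd),
        clipped at zero; units mm/s.
    turn_concentration
        von Mises concentration of the per-frame heading increment
        (dimensionless, >= 0).  Higher means straighter flight; 0 is a
        uniform turn (no heading persistence); ``inf`` is noise-free.
    turn_floor
        Scale (radians) of an additive per-frame heading tremor: the
        magnitude of each heading increment grows by turn_floor times a
        half-normal deviate.  Models insecticide-induced tremor -- the
        animal can no longer hold a straight course, so its calmest
        frames still carry angle change, lifting the lower quantiles of
        the angle-change distribution in particular.
    reversal_rate
        Expected number of horizontal direction reversals per second
        (heading mirrored about the vertical axis, i.e. vx changes sign),
        modelled as per-frame Bernoulli thinning of a Poisson process.
    pause_prob
        Stationary fraction of zero-displacement (hover/rest) frames.
        Pauses occur in runs with mean length ``pause_mean_frames``
        (mosquitoes hover or rest for stretches, not single frames).
    saccade_prob
        Stationary fraction of frames spent in casting bouts, during
        which the heading is redrawn uniformly each frame; bouts have
        mean length ``saccade_mean_frames``.
    speed_persistence
        Lag-1 autocorrelation of the AR(1) speed process in [0, 1);
        flight speed varies smoothly rather than frame-to-frame.
    variability
        Log-scale standard deviation of per-individual jitter on the
        behavioural rates (heading persistence, tremor, reversal, pause
        and saccade odds); 0 disables individual variability.
    speed_variability
        Log-scale standard deviation of per-individual jitter on the
        mean flight speed; speeds vary less between individuals than the
        behavioural rates do.
    """

    mean_speed: float
    speed_sd: float
    turn_concentration: float
    reversal_rate: float
    pause_prob: float
    pause_mean_frames: float = 5.0
    turn_floor: float = 0.0
    saccade_prob: float = 0.0
    saccade_mean_frames: float = 20.0
    speed_persistence: float = 0.9
    variability: float = 0.0
    speed_variability: float = 0.15

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean_speed) and self.mean_speed >= 0):
            raise ValueError(f"mean_speed must be finite and >= 0, got {self.mean_speed}")
        if not (math.isfinite(self.speed_sd) and self.speed_sd >= 0):
            raise ValueError(f"speed_sd must be finite and >= 0, got {self.speed_sd}")
        if math.isnan(self.turn_concentration) or self.turn_concentration < 0:
            raise ValueError(
                f"turn_concentration must be >= 0, got {self.turn_concentration}"
            )
        if not (math.isfinite(self.reversal_rate) and self.reversal_rate >= 0):
            raise ValueError(f"reversal_rate must be finite and >= 0, got {self.reversal_rate}")
        if not (0.0 <= self.pause_prob <= 1.0):
            raise ValueError(f"pause_prob must be in [0, 1], got {self.pause_prob}")
        if not (math.isfinite(self.pause_mean_frames) and self.pause_mean_frames >= 1):
            raise ValueError(
                f"pause_mean_frames must be >= 1, got {self.pause_mean_frames}"
            )
        if not (0.0 <= self.turn_floor <= math.pi):
            raise ValueError(f"turn_floor must be in [0, pi], got {self.turn_floor}")
        if not (0.0 <= self.saccade_prob <= 1.0):
            raise ValueError(f"saccade_prob must be in [0, 1], got {self.saccade_prob}")
        if not (math.isfinite(self.saccade_mean_frames) and self.saccade_mean_frames >= 1):
            raise ValueError(
                f"saccade_mean_frames must be >= 1, got {self.saccade_mean_frames}"
            )
        if not (0.0 <= self.speed_persistence < 1.0):
            raise ValueError(
                f"speed_persistence must be in [0, 1), got {self.speed_persistence}"
            )
        if not (math.isfinite(self.variability) and self.variability >= 0):
            raise ValueError(f"variability must be >= 0, got {self.variability}")
        if not (math.isfinite(self.speed_variability) and self.speed_variability >= 0):
            raise ValueError(
                f"speed_variability must be >= 0, got {self.speed_variability}"
            )

    def jitter(self, rng: np.random.Generator) -> "BehaviourParams":
        """One individual's parameters: multiplicative log-normal jitter on
        speed, heading persistence, reversal and saccade rates, and the
        pause odds.  Individuals of one condition thus overlap in their
        flight statistics, as real mosquitoes do."""
        if self.variability == 0.0 and self.speed_variability == 0.0:
            return self
        v = self.variability

        def mult(sd: float = -1.0) -> float:
            return float(np.exp(rng.normal(0.0, v if sd < 0 else sd)))

        def jitter_prob(p: float) -> float:
            if p <= 0.0 or p >= 1.0:
                return p
            odds = p / (1.0 - p) * mult()
            return odds / (1.0 + odds)

        return replace(
            self,
            mean_speed=self.mean_speed * mult(self.speed_variability),
            turn_concentration=self.turn_concentration * mult(),
            turn_floor=min(math.pi, self.turn_floor * mult()),
            reversal_rate=self.reversal_rate * mult(),
            pause_prob=jitter_prob(self.pause_prob),
            saccade_prob=jitter_prob(self.saccade_prob),
            variability=0.0,
            speed_variability=0.0,
        )


#: Default untreated-net regime: directed flight (strong heading
#: persistence), moderate speed, regular hovering/resting pauses near the
#: attractive host.
UT_PARAMS = BehaviourParams(
    mean_speed=475.0, speed_sd=120.0, turn_concentration=8.0, turn_floor=0.05,
    reversal_rate=0.1, pause_prob=0.06, pause_mean_frames=6.0,
    saccade_prob=0.08, saccade_mean_frames=20.0, speed_persistence=0.98,
    variability=0.45, speed_variability=0.08,
)

#: Default Olyset regime: highly convoluted flight with many large angle
#: changes and frequent horizontal direction reversals, almost no pausing
#: -- the irritant response to permethrin exposure.  The flight-speed
#: process matches UT; observed average speed is still higher at OL
#: because UT mosquitoes pause near the host.
OL_PARAMS = BehaviourParams(
    mean_speed=475.0, speed_sd=120.0, turn_concentration=5.0, turn_floor=0.20,
    reversal_rate=7.0, pause_prob=0.006, pause_mean_frames=6.0,
    saccade_prob=0.08, saccade_mean_frames=20.0, speed_persistence=0.98,
    variability=0.45, speed_variability=0.08,
)


@dataclass(frozen=True)
class TrackDurationLaw:
    """Log-normal track duration sampler, truncated to [min_s, remainder].

    Defaults give a mean of ~22 s with a heavy right tail, matching the
    10-25 s average durations (with maxima of hundreds of seconds) seen in
    real tracking data.
    """

    meanlog: float = 2.7
    sdlog: float = 0.9
    min_s: float = 1.0

    def sample(self, rng: np.random.Generator, max_s: float) -> float | None:
        if max_s < self.min_s:
            return None
        d = float(rng.lognormal(self.meanlog, self.sdlog))
        return float(min(max(d, self.min_s), max_s))


@dataclass(frozen=True)
class GapLaw:
    """Per-frame dropout of observed positions in runs.

    ``dropout_prob`` is the marginal probability that any interior frame is
    missing; runs of consecutive missing frames have length uniform on
    {1..max_run}.  The run-start probability is solved from the renewal
    equation so the stationary removed fraction equals ``dropout_prob``.
    """

    dropout_prob: float = 0.0
    max_run: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError(
                f"dropout_prob must be in [0, 1), got {self.dropout_prob}"
            )
        if self.max_run < 1:
            raise ValueError(f"max_run must be >= 1, got {self.max_run}")

    @property
    def start_prob(self) -> float:
        mean_run = (1 + self.max_run) / 2.0
        p = self.dropout_prob
        return p / (mean_run * (1.0 - p) + p)


@dataclass(frozen=True)
class TrialSpec:
    """One tracking experiment: a net type, a strain, 25 released mosquitoes."""

    trial_id: str
    net_type: str
    strain: str
    resistance: str
    n_mosquitoes: int = 25
    duration_s: float = 7200.0
    fps: float = 50.0
    arena: tuple[float, float] = (1200.0, 1000.0)
    mortality_cutoff_s: float | None = None
    track_duration_law: TrackDurationLaw = field(default_factory=TrackDurationLaw)
    gap_law: GapLaw = field(default_factory=GapLaw)
    tracks_per_mosquito: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.net_type not in ("UT", "OL"):
            raise ValueError(f"net_type must be 'UT' or 'OL', got {self.net_type!r}")
        if self.resistance not in ("IS", "IR"):
            raise ValueError(f"resistance must be 'IS' or 'IR', got {self.resistance!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_mosquitoes < 1:
            raise ValueError("n_mosquitoes must be >= 1")
        if self.track_duration_law.min_s < 1.0:
            raise ValueError("minimum track duration must be >= 1 s")
        if self.mortality_cutoff_s is not None and self.mortality_cutoff_s > self.duration_s:
            raise ValueError("mortality_cutoff_s may not exceed duration_s")
        if self.tracks_per_mosquito < 1:
            raise ValueError("tracks_per_mosquito must be >= 1")


@dataclass
class Track:
    """Time-ordered 2D positions of one mosquito within one trial.

    ``frames`` are strictly increasing integer frame indices (gaps allowed
    before interpolation); ``t = frames / fps`` in seconds; ``x``/``y`` in
    mm; ``real`` flags observed (True) versus interpolated (False) samples.
    """

    trial_id: str
    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    real: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.real = np.asarray(self.real, dtype=bool)
        n = len(self.frames)
        if n < 2:
            raise ValueError(f"track {self.track_id!r} needs >= 2 samples, got {n}")
        if not (len(self.x) == len(self.y) == len(self.real) == n):
            raise ValueError("frames, x, y, real must have equal length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id!r} frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.track_id!r} has non-finite positions")

    @property
    def t(self) -> np.ndarray:
        return self.frames / self.fps

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) / self.fps)

    @property
    def n_samples(self) -> int:
        return len(self.frames)


def _pause_mask(
    rng: np.random.Generator, n: int, pause_prob: float, mean_run: float
) -> np.ndarray:
    """Two-state (fly/pause) Markov pause indicator with the given
    stationary pause fraction and mean pause-run length in frames."""
    mask = np.zeros(n, dtype=bool)
    if pause_prob <= 0.0 or n == 0:
        return mask
    if pause_prob >= 1.0:
        return ~mask
    exit_p = 1.0 / mean_run
    enter_p = min(1.0, pause_prob * exit_p / (1.0 - pause_prob))
    i = 0
    paused = rng.random() < pause_prob
    while i < n:
        run = int(rng.geometric(exit_p if paused else enter_p))
        if paused:
            mask[i : i + run] = True
        i += run
        paused = not paused
    return mask


def _reflect(u: np.ndarray, length: float) -> np.ndarray:
    """Fold coordinates into [0, length] by specular reflection."""
    period = 2.0 * length
    v = np.mod(u, period)
    return np.where(v > length, period - v, v)


def simulate_track(
    params: BehaviourParams,
    duration_s: float,
    fps: float,
    arena: tuple[float, float],
    seed: int,
    *,
    trial_id: str = "sim",
    track_id: str = "0",
    start_frame: int = 0,
) -> Track:
    """Simulate one correlated-random-walk flight track.

    The heading evolves by wrapped von Mises noise with concentration
    ``turn_concentration``; at Poisson reversal events with rate
    ``reversal_rate`` the heading is mirrored about the vertical axis
    (a horizontal direction reversal: vx changes sign).  Per-frame
    displacement is speed/fps, zero on pause frames, which occur in runs
    of mean length ``pause_mean_frames``; positions are reflected at the
    arena boundary.  All samples are flagged real.  Identical seeds give
    identical tracks.
    """
    if duration_s < 2.0 / fps:
        raise ValueError("duration_s must span at least two frames")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s * fps))
    width, height = arena

    # AR(1) speed process: smooth speed variation around the mean
    phi = params.speed_persistence
    innov = rng.normal(0.0, params.speed_sd, n_steps)
    x0 = float(rng.normal(0.0, params.speed_sd)) if params.speed_sd > 0 else 0.0
    scale = math.sqrt(1.0 - phi * phi)
    if phi > 0.0:
        dev, _ = sp_signal.lfilter([scale], [1.0, -phi], innov, zi=[phi * x0])
    else:
        dev = innov
    speeds = np.clip(params.mean_speed + dev, 0.0, None)
    speeds[_pause_mask(rng, n_steps, params.pause_prob, params.pause_mean_frames)] = 0.0

    kappa = params.turn_concentration
    if math.isinf(kappa) or kappa > 1e8:
        turns = np.zeros(n_steps)
    elif kappa == 0.0:
        turns = rng.uniform(-np.pi, np.pi, n_steps)
    else:
        turns = rng.vonmises(0.0, kappa, n_steps)
    if params.turn_floor > 0.0:
        signs = np.where(turns == 0.0, rng.choice([-1.0, 1.0], n_steps), np.sign(turns))
        tremor = params.turn_floor * np.abs(rng.normal(0.0, 1.0, n_steps))
        # tremor is intermittent: calm spells (no tremor) cover a small
        # fraction of flight in clustered stretches
        calm = _pause_mask(rng, n_steps, TREMOR_CALM_FRAC, TREMOR_CALM_RUN)
        tremor[calm] = 0.0
        turns = signs * np.minimum(np.abs(turns) + tremor, np.pi)
    if params.saccade_prob > 0.0:
        saccades = _pause_mask(
            rng, n_steps, params.saccade_prob, params.saccade_mean_frames
        )
        turns = np.where(saccades, rng.uniform(-np.pi, np.pi, n_steps), turns)
    mirrors = rng.random(n_steps) < params.reversal_rate / fps

    # heading under interleaved rotations R_d: h -> h + d and mirrors
    # M: h -> pi - h.  Composing (sign, offset) affine maps gives
    # h_T = s_T * (h_0 + sum_t s_t * phi_t) with s_t = (-1)^{#mirrors<=t}
    # and phi_t = pi - d_t at a mirror step, d_t otherwise.
    sign = np.where(np.cumsum(mirrors) % 2 == 0, 1.0, -1.0)
    phi = np.where(mirrors, np.pi - turns, turns)
    heading = sign * (rng.uniform(-np.pi, np.pi) + np.cumsum(sign * phi))
    step = speeds / fps
    x0 = rng.uniform(0.0, width)
    y0 = rng.uniform(0.0, height)
    x = _reflect(x0 + np.concatenate([[0.0], np.cumsum(step * np.cos(heading))]), width)
    y = _reflect(y0 + np.concatenate([[0.0], np.cumsum(step * np.sin(heading))]), height)

    frames = start_frame + np.arange(n_steps + 1, dtype=np.int64)
    return Track(
        trial_id=trial_id,
        track_id=track_id,
        frames=frames,
        x=x,
        y=y,
        real=np.ones(n_steps + 1, dtype=bool),
        fps=fps,
    )


def drop_samples(track: Track, indices: np.ndarray) -> Track:
    """Return a copy of ``track`` with the given sample indices removed."""
    keep = np.ones(track.n_samples, dtype=bool)
    keep[np.asarray(indices, dtype=np.int64)] = False
    if keep.sum() < 2:
        raise ValueError("cannot drop samples: fewer than 2 would remain")
    return replace(
        track,
        frames=track.frames[keep],
        x=track.x[keep],
        y=track.y[keep],
        real=track.real[keep],
    )


def inject_gaps(track: Track, gap_law: GapLaw, seed: int) -> Track:
    """Remove interior samples in runs drawn from ``gap_law``.

    The first and last samples are never removed, frames stay strictly
    increasing, and the removed fraction is reproducible under the seed.
    """
    if track.n_samples < 2:
        raise ValueError("track needs >= 2 samples")
    if gap_law.dropout_prob == 0.0:
        return track
    n = track.n_samples
    if n <= 2:
        return track
    rng = np.random.default_rng(seed)
    q = gap_law.start_prob
    removed = np.zeros(n, dtype=bool)
    starts = rng.random(n) < q
    run_lengths = rng.integers(1, gap_law.max_run + 1, size=n)
    i = 1
    while i < n - 1:
        if starts[i]:
            run_end = min(i + int(run_lengths[i]), n - 1)
            removed[i:run_end] = True
            i = run_end
        else:
            i += 1
    if removed.sum() == 0:
        return track
    return drop_samples(track, np.nonzero(removed)[0])


def simulate_trial(
    spec: TrialSpec,
    ut_params: BehaviourParams,
    ol_params: BehaviourParams,
) -> list[Track]:
    """Simulate all tracks of one trial.

    Each mosquito produces one or more tracks with uniform start times in
    the trial.  Under a mortality cutoff, starts after the cutoff are
    discarded (the mosquito is dead or incapacitated) and tracks crossing
    it are truncated.  Tracking dropout is applied via :func:`inject_gaps`.
    """
    params = ol_params if spec.net_type == "OL" else ut_params
    rng = np.random.default_rng(spec.seed)
    law = spec.track_duration_law
    cutoff = spec.mortality_cutoff_s
    horizon = spec.duration_s if cutoff is None else cutoff

    tracks: list[Track] = []
    for m in range(spec.n_mosquitoes):
        individual = params.jitter(rng)
        if spec.tracks_per_mosquito <= 1.0:
            n_tracks = 1
        else:
            n_tracks = 1 + int(rng.poisson(spec.tracks_per_mosquito - 1.0))
        for j in range(n_tracks):
            start_s = float(rng.uniform(0.0, spec.duration_s - law.min_s))
            if start_s > horizon - law.min_s:
                continue  # censored: mosquito dead/incapacitated past cutoff
            dur = law.sample(rng, max_s=horizon - start_s)
            if dur is None:
                continue
            track_seed = int(rng.integers(0, 2**31 - 1))
            gap_seed = int(rng.integers(0, 2**31 - 1))
            track = simulate_track(
                individual,
                dur,
                spec.fps,
                spec.arena,
                track_seed,
                trial_id=spec.trial_id,
                track_id=f"m{m:02d}t{j}",
                start_frame=int(round(start_s * spec.fps)),
            )
            tracks.append(inject_gaps(track, spec.gap_law, gap_seed))
    return tracks


def _resolve_params(
    params_by_condition: dict,
    net_type: str,
    resistance: str,
) -> BehaviourParams:
    """Look up behaviour parameters by (net, resistance), falling back to net."""
    if (net_type, resistance) in params_by_condition:
        return params_by_condition[(net_type, resistance)]
    if net_type in params_by_condition:
        return params_by_condition[net_type]
    raise KeyError(f"no behaviour parameters for condition ({net_type}, {resistance})")


def simulate_study(
    n_ut_trials: int,
    n_ol_trials: int,
    strain_plan: list[str] | None = None,
    params_by_condition: dict | None = None,
    seed: int = 0,
    *,
    require_balance: bool = False,
    is_ol_mortality_cutoff_s: float | None = 1800.0,
    trial_prefix: str = "",
    **trial_kwargs,
) -> list[tuple[TrialSpec, list[Track]]]:
    """Simulate a full study of UT and OL trials.

    Strains are assigned by cycling ``strain_plan`` (default: the four
    canonical strains) independently within each arm.  IS strains at the
    OL net receive ``is_ol_mortality_cutoff_s`` (default 30 min) as their
    mortality cutoff.  Per-trial seeds derive from the master seed.
    """
    if params_by_condition is None:
        params_by_condition = {"UT": UT_PARAMS, "OL": OL_PARAMS}
    if strain_plan is None:
        strain_plan = list(STRAIN_RESISTANCE)
    rng = np.random.default_rng(seed)

    plan: list[tuple[str, str, str]] = []  # (net, strain, resistance)
    for arm, n in (("UT", n_ut_trials), ("OL", n_ol_trials)):
        for i in range(n):
            strain = strain_plan[i % len(strain_plan)]
            plan.append((arm, strain, STRAIN_RESISTANCE.get(strain, "IS")))

    if require_balance:
        cells = {(net, res) for net, _, res in plan}
        missing = {(n, r) for n in ("UT", "OL") for r in ("IS", "IR")} - cells
        if missing:
            raise ValueError(f"empty condition cells: {sorted(missing)}")

    study = []
    counter = {"UT": 0, "OL": 0}
    for net, strain, res in plan:
        counter[net] += 1
        cutoff = (
            is_ol_mortality_cutoff_s if (net == "OL" and res == "IS") else None
        )
        duration = trial_kwargs.get("duration_s", 7200.0)
        if cutoff is not None and cutoff >= duration:
            cutoff = None  # cutoff beyond the trial: no censoring
        spec = TrialSpec(
            trial_id=f"{trial_prefix}{net}{counter[net]:02d}_{strain}",
            net_type=net,
            strain=strain,
            resistance=res,
            mortality_cutoff_s=cutoff,
            seed=int(rng.integers(0, 2**31 - 1)),
            **trial_kwargs,
        )
        params = _resolve_params(params_by_condition, net, res)
        base = params_by_condition.get("UT", params)
        alt = params_by_condition.get("OL", params)
        if net == "OL":
            tracks = simulate_trial(spec, base, params)
        else:
            tracks = simulate_trial(spec, params, alt)
        study.append((spec, tracks))
    return study


def study_metadata(study: list[tuple[TrialSpec, list[Track]]]) -> pd.DataFrame:
    """Per-trial metadata table for a simulated study."""
    return pd.DataFrame(
        {
            "trial_id": [s.trial_id for s, _ in study],
            "net_type": [s.net_type for s, _ in study],
            "strain": [s.strain for s, _ in study],
            "resistance": [s.resistance for s, _ in study],
        }
    )


def study_tracks(study: list[tuple[TrialSpec, list[Track]]]) -> list[Track]:
    """Flatten a study into its track list."""
    return [t for _, tracks in study for t in tracks]


def contrast_study(
    n_per_arm: int = 8,
    seed: int = 0,
    *,
    identical_regimes: bool = False,
    tracks_per_trial: int = 25,
    gap_law: GapLaw | None = None,
) -> list[tuple[TrialSpec, list[Track]]]:
    """Two-regime benchmark study: n trials per arm, 25 single-track mosquitoes each.

    With ``identical_regimes=True`` both arms use the UT behaviour
    parameters, giving a null study where no net-type signal exists.
    """
    params = {
        "UT": UT_PARAMS,
        "OL": UT_PARAMS if identical_regimes else OL_PARAMS,
    }
    return simulate_study(
        n_per_arm,
        n_per_arm,
        params_by_condition=params,
        seed=seed,
        n_mosquitoes=tracks_per_trial,
        tracks_per_mosquito=1.0,
        gap_law=gap_law if gap_law is not None else GapLaw(0.03, 12),
    )
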