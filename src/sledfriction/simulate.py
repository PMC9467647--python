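"""Synthetic force-distance curve generator.

Emulates the trace a sled friction test produces on a microspine-bearing
stem: an elastic loading ramp that ends in a static peak, then a sliding
regime whose force fluctuates in sawtooth stick-slip events around a
drifting baseline, plus additive sensor noise.  Every stochastic element
(event positions, amplitudes, noise) is recorded as ground truth so that
the measurement pipeline can be validated by parameter recovery.

The model is phenomenological: events are placed by a homogeneous
Poisson process (with a small hard-core separation so neighbouring
events stay resolvable at the sampling density) and each event is an
asymmetric triangle — a slow linear rise to the event position followed
by a fast linear collapse, the canonical stick-slip shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Direction, DIRECTIONS, ForceCurve, SledTestConfig, ValidationError, log

__all__ = ["SimParams", "GroundTruth", "simulate_curve", "simulate_study", "PRESETS"]


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of one simulated test.

    ``anisotropy_true`` scales the static force, sliding baseline and
    event amplitudes in the basal direction relative to apical, so the
    basal/apical force ratios recovered downstream should estimate it.
    ``post_peak_drop`` is the fraction of the static-to-sliding force
    drop taken instantly at slip; any remainder relaxes linearly over
    0.5 mm.
    """

    static_force_true: float = 60.0  # mN, apical-direction static peak
    loading_stiffness: float = 40.0  # mN mm^-1 ramp slope
    post_peak_drop: float = 1.0  # fraction of the drop taken instantly
    sliding_baseline: float = 30.0  # mN, apical-direction sliding level
    drift_slope: float = 0.0  # mN mm^-1 linear trend during sliding
    event_rate: float = 1.0  # peaks mm^-1 (Poisson intensity)
    amplitude_log_mean: float = 1.5  # lognormal log-mean of event height, mN
    amplitude_log_sd: float = 0.4
    event_shape: float = 0.8  # rise fraction of the inter-event span
    noise_sd: float = 1.0  # mN additive white sensor noise
    direction: Direction = "apical"
    anisotropy_true: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if not self.static_force_true >= self.sliding_baseline >= 0:
            raise ValidationError(
                "need static_force_true >= sliding_baseline >= 0"
            )
        if self.event_rate < 0 or self.noise_sd < 0:
            raise ValidationError("event_rate and noise_sd must be >= 0")
        if not self.anisotropy_true > 0:
            raise ValidationError("anisotropy_true must be positive")
        if not 0 < self.post_peak_drop <= 1:
            raise ValidationError("post_peak_drop must be in (0, 1]")
        if not 0 < self.event_shape < 1:
            raise ValidationError("event_shape must be in (0, 1)")

    @property
    def dir_factor(self) -> float:
        return self.anisotropy_true if self.direction == "basal" else 1.0


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew for one curve."""

    test_id: str
    direction: Direction
    static_force: float  # direction-scaled static peak, mN
    static_peak_distance: float  # mm
    sliding_baseline: float  # direction-scaled, mN
    drift_slope: float
    event_rate: float
    event_positions: tuple[float, ...]  # mm
    event_amplitudes: tuple[float, ...]  # mN above local baseline
    params: SimParams = field(repr=False, default=None)  # type: ignore[assignment]


#: Minimum event separation, in samples.  The peak identifier's
#: separation filter spans 3 samples; grid quantisation and noise can
#: shift a detected peak by one sample, so resolvability needs one more.
MIN_EVENT_SEPARATION_SAMPLES = 4

#: Distance over which any non-instant post-peak drop relaxes, mm.
RELAXATION_MM = 0.5


def _poisson_hardcore_positions(
    rng: np.random.Generator,
    rate: float,
    lo: float,
    hi: float,
    min_sep: float,
    grid: float = 0.0,
) -> np.ndarray:
    """Event positions on (lo, hi): count ~ Poisson(rate*(hi-lo)), placed
    uniformly subject to a hard-core minimum separation.

    Uses the shrink-and-spread construction (uniforms on the interval
    shortened by n*min_sep, then shifted apart by min_sep) so the count
    keeps its exact Poisson law while gaps stay >= min_sep.  With
    ``grid`` > 0 positions are snapped to the sampling grid: an event
    registers at the sample where the transducer sees it, and snapping
    keeps the slip apex representable in the sampled trace.
    """
    length = hi - lo
    if rate <= 0 or length <= 0:
        return np.empty(0)
    n = rng.poisson(rate * length)
    while n > 0 and length - n * min_sep <= 0:
        n -= 1  # window physically cannot hold more events
    if n == 0:
        return np.empty(0)
    u = np.sort(rng.uniform(0.0, length - n * min_sep, size=n))
    pos = lo + u + min_sep * (np.arange(1, n + 1))
    if grid > 0:
        pos = np.round(pos / grid) * grid
    return pos


def simulate_curve(
    params: SimParams,
    config: SledTestConfig | None = None,
    seed: int | np.random.Generator = 0,
    test_id: str = "sim",
    species: str = "synthetic",
) -> tuple[ForceCurve, GroundTruth]:
    """Simulate one force-distance trace.

    The curve has ``ceil(travel * sample_rate / speed) + 1`` samples on a
    uniform distance grid.  Phase 1 is the elastic ramp
    ``force = loading_stiffness * distance`` up to the grid point where
    the (direction-scaled) static force is reached; that sample is set to
    the static force exactly, so the noise-free trace has a local
    maximum equal to it.  Phase 2 is baseline + drift + sawtooth events
    + Gaussian noise.
    """
    config = config or SledTestConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dx = config.sample_spacing
    n = int(np.ceil(config.travel * config.sample_rate / config.speed)) + 1
    dist = np.arange(n) * dx

    f = params.dir_factor
    f_static = params.static_force_true * f
    baseline0 = params.sliding_baseline * f

    d_star = f_static / params.loading_stiffness
    if d_star >= config.travel - dx:
        raise ValidationError(
            f"ramp would need {d_star:.2f} mm to reach the static force; "
            "increase travel or lower static_force_true/raise loading_stiffness"
        )
    i_peak = int(np.ceil(d_star / dx))
    d_peak = dist[i_peak]

    force = np.empty(n)
    force[: i_peak + 1] = params.loading_stiffness * dist[: i_peak + 1]
    force[i_peak] = f_static  # exact noise-free static maximum

    # Sliding phase on (d_peak, travel].
    post = dist[i_peak + 1 :]
    baseline = baseline0 + params.drift_slope * (post - d_peak)

    events = _poisson_hardcore_positions(
        rng,
        params.event_rate,
        d_peak + dx,
        dist[-1],
        MIN_EVENT_SEPARATION_SAMPLES * dx,
        grid=dx,
    )
    amps = (
        rng.lognormal(params.amplitude_log_mean, params.amplitude_log_sd, len(events))
        * f
    )
    elevation = _sawtooth_train(post, events, amps, params.event_shape, d_peak, dist[-1])

    sliding = baseline + elevation

    # Post-peak transition: the instant drop leaves residual
    # (1 - post_peak_drop) * (f_static - level), relaxing over 0.5 mm.
    residual0 = (1.0 - params.post_peak_drop) * (f_static - baseline0)
    if residual0 > 0:
        w = np.clip(1.0 - (post - d_peak) / RELAXATION_MM, 0.0, 1.0)
        sliding = np.maximum(sliding, baseline + residual0 * w)

    force[i_peak + 1 :] = sliding
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, n)
    force = np.maximum(force, 0.0)  # transducer reports tension only

    curve = ForceCurve(
        test_id=test_id,
        species=species,
        direction=params.direction,
        distance=dist,
        force=force,
        sample_rate=config.sample_rate,
        speed=config.speed,
    )
    truth = GroundTruth(
        test_id=test_id,
        direction=params.direction,
        static_force=f_static,
        static_peak_distance=d_peak,
        sliding_baseline=baseline0,
        drift_slope=params.drift_slope,
        event_rate=params.event_rate,
        event_positions=tuple(events),
        event_amplitudes=tuple(amps),
        params=params,
    )
    return curve, truth


def _sawtooth_train(
    x: np.ndarray,
    positions: np.ndarray,
    amplitudes: np.ndarray,
    shape: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Superpose asymmetric triangular events peaking at ``positions``.

    Event j rises linearly from zero over ``shape`` of the gap to its
    left neighbour (or window start) and falls to zero over
    ``1 - shape`` of the gap to its right neighbour (or window end).
    """
    out = np.zeros_like(x)
    if len(positions) == 0:
        return out
    left = np.concatenate(([lo], positions[:-1]))
    right = np.concatenate((positions[1:], [hi]))
    for p, a, l, r in zip(positions, amplitudes, left, right):
        rise = shape * (p - l)
        fall = (1.0 - shape) * (r - p)
        if rise > 0:
            m = (x > p - rise) & (x <= p)
            out[m] += a * (x[m] - (p - rise)) / rise
        if fall > 0:
            m = (x > p) & (x < p + fall)
            out[m] += a * (1.0 - (x[m] - p) / fall)
    return out


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------

#: Parameter presets bracketing the observed force range: a weak
#: close twiner (forces ~10 mN, sparse peaks) and a strong scrambler
#: (basal forces >150 mN, dense peaks, strong anisotropy).
PRESETS: dict[str, SimParams] = {
    "weak_close_twiner": SimParams(
        static_force_true=10.5,
        loading_stiffness=20.0,
        sliding_baseline=7.0,
        event_rate=0.7,
        amplitude_log_mean=1.1,
        amplitude_log_sd=0.4,
        noise_sd=1.0,
        anisotropy_true=1.4,
    ),
    "strong_scrambler": SimParams(
        static_force_true=31.0,
        loading_stiffness=40.0,
        sliding_baseline=25.0,
        event_rate=1.5,
        amplitude_log_mean=1.7,
        amplitude_log_sd=0.5,
        noise_sd=1.0,
        anisotropy_true=5.6,
    ),
}


def _spawn_seed(master_seed: int, *labels: str) -> np.random.Generator:
    """Stable per-test substream: hashing (labels) into a child seed so
    adding a species does not perturb the streams of the others."""
    ss = np.random.SeedSequence(
        [master_seed] + [abs(hash_stable(lbl)) % (2**31) for lbl in labels]
    )
    return np.random.default_rng(ss)


def hash_stable(s: str) -> int:
    """Deterministic string hash (Python's ``hash`` is salted per run)."""
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


def simulate_study(
    n_species: int | None = None,
    tests_per_species: int = 20,
    param_table: dict[str, SimParams] | None = None,
    seed: int = 0,
    config: SledTestConfig | None = None,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Simulate a multi-species study of paired apical/basal tests.

    ``param_table`` maps species label -> apical-direction
    :class:`SimParams` (the basal member of each pair reuses them with
    ``direction="basal"``, so ``anisotropy_true`` takes effect).  When
    omitted, ``n_species`` species are generated by interpolating
    between the two presets.  Returns all curves plus a tidy
    ground-truth table.
    """
    config = config or SledTestConfig()
    if param_table is None:
        if n_species is None:
            raise ValidationError("give either n_species or param_table")
        param_table = default_param_table(n_species)
    if len(set(param_table)) != len(param_table):
        raise ValidationError("duplicate species labels")
    curves: list[ForceCurve] = []
    rows = []
    for species, base in param_table.items():
        for t in range(tests_per_species):
            test_id = f"{species}-{t:03d}"
            for direction in DIRECTIONS:
                p = replace(base, direction=direction)
                rng = _spawn_seed(seed, species, test_id, direction)
                curve, truth = simulate_curve(
                    p, config, rng, test_id=test_id, species=species
                )
                curves.append(curve)
                rows.append(
                    {
                        "test_id": test_id,
                        "species": species,
                        "direction": direction,
                        "static_force_true": truth.static_force,
                        "static_peak_distance": truth.static_peak_distance,
                        "sliding_baseline_true": truth.sliding_baseline,
                        "drift_slope": truth.drift_slope,
                        "event_rate_true": truth.event_rate,
                        "anisotropy_true": base.anisotropy_true,
                        "n_events": len(truth.event_positions),
                        "event_positions": ";".join(
                            f"{v:.6g}" for v in truth.event_positions
                        ),
                        "event_amplitudes": ";".join(
                            f"{v:.6g}" for v in truth.event_amplitudes
                        ),
                    }
                )
    log.info(
        "simulated %d species x %d paired tests -> %d curves",
        len(param_table),
        tests_per_species,
        len(curves),
    )
    return curves, pd.DataFrame(rows)


def default_param_table(n_species: int) -> dict[str, SimParams]:
    """Interpolate ``n_species`` parameter sets between the weak-twiner
    and strong-scrambler presets (log-spaced forces, linear rates)."""
    lo, hi = PRESETS["weak_close_twiner"], PRESETS["strong_scrambler"]
    table = {}
    for i in range(n_species):
        w = i / max(n_species - 1, 1)
        table[f"species_{i:02d}"] = SimParams(
            static_force_true=float(
                np.exp(
                    (1 - w) * np.log(lo.static_force_true)
                    + w * np.log(hi.static_force_true)
                )
            ),
            loading_stiffness=(1 - w) * lo.loading_stiffness + w * hi.loading_stiffness,
            sliding_baseline=float(
                np.exp(
                    (1 - w) * np.log(lo.sliding_baseline)
                    + w * np.log(hi.sliding_baseline)
                )
            ),
            event_rate=(1 - w) * lo.event_rate + w * hi.event_rate,
            amplitude_log_mean=(1 - w) * lo.amplitude_log_mean
            + w * hi.amplitude_log_mean,
            amplitude_log_sd=(1 - w) * lo.amplitude_log_sd + w * hi.amplitude_log_sd,
            noise_sd=lo.noise_sd,
            anisotropy_true=(1 - w) * lo.anisotropy_true + w * hi.anisotropy_true,
        )
    return table
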