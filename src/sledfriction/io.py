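"""Domain types and file I/O for sled friction-test data.

A sled friction test drags a pair of stem segments across a standard
substrate at constant speed while a transducer records pulling force
against crosshead travel.  Each record is one force-distance trace for
one specimen pulled in one direction (towards the stem apex, "apical",
or towards the stem base, "basal").  This module defines the containers
shared by every pipeline stage and the tidy-CSV readers/writers used to
move data between them.

Units are millimetres and millinewtons throughout; sampling is nominally
50 measurements per second at a crosshead speed of 3 mm s^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Direction",
    "ForceCurve",
    "SledTestConfig",
    "SpeciesMorphology",
    "FrictionFeatures",
    "PairedFeatures",
    "StatResult",
    "ValidationError",
    "FormatError",
    "read_curves",
    "write_curves",
    "read_morphology",
    "write_features",
    "read_features",
    "load_config",
]

log = logging.getLogger("sledfriction")

#: Allowed pull directions.  Tokens are exact lowercase strings so that
#: apical/basal pairing joins are unambiguous.
DIRECTIONS = ("apical", "basal")
Direction = str

CURVE_COLUMNS = ("test_id", "species", "direction", "distance_mm", "force_mN")
OPTIONAL_CURVE_COLUMNS = ("normal_force_mN", "sample_rate", "speed")

HABITS = ("close_twiner", "lax_twiner", "scrambler")


class ValidationError(ValueError):
    """Raised when data violate a domain-type invariant."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SledTestConfig:
    """Physical constants of a sled test plus analysis knobs.

    Parameters
    ----------
    speed : crosshead speed, mm s^-1.
    sample_rate : force sampling rate, measurements s^-1.
    travel : total crosshead travel, mm.
    sliding_window : length of the sliding-phase analysis window that
        starts just after the static peak, mm.
    top_k_peaks : number of highest sliding peaks averaged into the
        maximum sliding force.
    gravity : gravitational acceleration used for mass-to-force
        conversion, m s^-2.  9.8 exactly reproduces the published
        gram-to-millinewton arithmetic.
    rng_seed : seed for any stochastic step run under this config.
    """

    speed: float = 3.0
    sample_rate: float = 50.0
    travel: float = 20.0
    sliding_window: float = 15.0
    top_k_peaks: int = 10
    gravity: float = 9.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("speed", "sample_rate", "travel", "sliding_window", "gravity"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"SledTestConfig.{name} must be positive")
        if self.sliding_window > self.travel:
            raise ValidationError(
                f"sliding_window ({self.sliding_window} mm) exceeds travel "
                f"({self.travel} mm)"
            )
        if self.top_k_peaks < 1:
            raise ValidationError("top_k_peaks must be >= 1")

    @property
    def sample_spacing(self) -> float:
        """Nominal distance between samples, mm (0.06 at defaults)."""
        return self.speed / self.sample_rate


@dataclass(frozen=True)
class ForceCurve:
    """One sled-test trace: ordered (distance, force) series plus metadata."""

    test_id: str
    species: str
    direction: Direction
    distance: np.ndarray  # mm, strictly non-decreasing
    force: np.ndarray  # mN
    sample_rate: float = 50.0
    speed: float = 3.0
    normal_force: float = float("nan")  # mN applied by sled mass

    def __post_init__(self) -> None:
        object.__setattr__(self, "distance", np.asarray(self.distance, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r} "
                f"(test {self.test_id})"
            )
        if self.distance.ndim != 1 or self.force.ndim != 1:
            raise ValidationError(f"series must be 1-D (test {self.test_id})")
        if len(self.distance) != len(self.force):
            raise ValidationError(
                f"distance and force lengths differ (test {self.test_id})"
            )
        if len(self.distance) < 2:
            raise ValidationError(f"curve needs >= 2 samples (test {self.test_id})")
        if not np.all(np.isfinite(self.force)) or not np.all(np.isfinite(self.distance)):
            raise ValidationError(f"non-finite values in curve (test {self.test_id})")
        if np.any(np.diff(self.distance) < 0):
            raise ValidationError(
                f"distance must be non-decreasing (test {self.test_id})"
            )

    def __len__(self) -> int:
        return len(self.distance)


@dataclass(frozen=True)
class SpeciesMorphology:
    """Stem morphology summary for one species (one table row).

    ``stem_mass_g`` is the median fresh mass of the whole searcher stem;
    half of it, converted to millinewtons, approximates the normal force
    the searcher exerts when resting on a support.  Cane-like climbers
    (``n_internodes`` set) use the whole mass divided by the internode
    count instead.
    """

    species: str
    n_stems: int
    stem_mass_g: float
    stem_length_cm: float
    stem_diameter_mm: float
    climbing_habit: str
    internode_tested: int
    n_internodes: int | None = None

    def __post_init__(self) -> None:
        if self.climbing_habit not in HABITS:
            raise ValidationError(
                f"climbing_habit must be one of {HABITS}, got {self.climbing_habit!r}"
            )
        for name in ("stem_mass_g", "stem_length_cm", "stem_diameter_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive ({self.species})")
        if self.n_stems < 1:
            raise ValidationError(f"n_stems must be >= 1 ({self.species})")
        if self.n_internodes is not None and self.n_internodes < 1:
            raise ValidationError(f"n_internodes must be >= 1 ({self.species})")


#: Flags attached to extracted features.
FLAG_TRUNCATED_WINDOW = "TRUNCATED_WINDOW"
FLAG_FEWER_THAN_K_PEAKS = "FEWER_THAN_K_PEAKS"
FLAG_NO_PEAKS = "NO_PEAKS"
FLAG_SHORT_WINDOW = "SHORT_WINDOW"  # truncated window < 10 mm


@dataclass(frozen=True)
class FrictionFeatures:
    """The measured parameters of one force-distance curve.

    static_force
        Maximum of the first force peak: the force needed to set the
        sled in motion.
    sliding_mean_force
        Mean force over the sliding window after the static peak: the
        force needed to keep it moving.
    max_sliding_force
        Mean of the ``top_k`` highest raw peak forces during sliding --
        the momentary "stopping" capacity of the stem surface.
    peak_frequency
        Identified sliding peaks per millimetre: density of momentary
        anchorage events.
    cv_sliding
        Coefficient of variation of the raw force within the sliding
        window.
    """

    test_id: str
    species: str
    direction: Direction
    static_force: float
    sliding_mean_force: float
    max_sliding_force: float
    peak_frequency: float
    n_peaks: int
    peak_positions: tuple[float, ...]
    peak_forces: tuple[float, ...]
    static_peak_distance: float
    window_start: float
    window_end: float
    cv_sliding: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"bad direction {self.direction!r}")
        for name in ("static_force", "sliding_mean_force", "max_sliding_force"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 (test {self.test_id})")
        if self.window_end < self.window_start:
            raise ValidationError(f"empty window (test {self.test_id})")
        object.__setattr__(self, "flags", frozenset(self.flags))
        object.__setattr__(self, "peak_positions", tuple(self.peak_positions))
        object.__setattr__(self, "peak_forces", tuple(self.peak_forces))

    @property
    def window_length(self) -> float:
        return self.window_end - self.window_start


@dataclass(frozen=True)
class PairedFeatures:
    """Apical and basal features of the same specimen, with anisotropies.

    Anisotropy is the basal/apical force ratio: values above 1 mean the
    stem resists backward slipping more than forward motion (a ratchet).
    """

    test_id: str
    apical: FrictionFeatures
    basal: FrictionFeatures

    def __post_init__(self) -> None:
        if self.apical.direction != "apical" or self.basal.direction != "basal":
            raise ValidationError(
                f"members must be apical/basal as named (test {self.test_id})"
            )
        for r in (self.static_anisotropy, self.sliding_anisotropy):
            if not (np.isfinite(r) and r > 0):
                raise ValidationError(
                    f"anisotropy must be positive finite (test {self.test_id})"
                )

    @property
    def static_anisotropy(self) -> float:
        if self.apical.static_force == 0:
            raise ValidationError(f"DIV_BY_ZERO: zero apical static force (test {self.test_id})")
        return self.basal.static_force / self.apical.static_force

    @property
    def sliding_anisotropy(self) -> float:
        if self.apical.sliding_mean_force == 0:
            raise ValidationError(f"DIV_BY_ZERO: zero apical sliding force (test {self.test_id})")
        return self.basal.sliding_mean_force / self.apical.sliding_mean_force

    @property
    def species(self) -> str:
        return self.apical.species


@dataclass
class StatResult:
    """Generic container for the output of one statistical procedure."""

    method: str
    statistic: float = float("nan")
    df: float | tuple[float, float] | None = None
    p_value: float = float("nan")
    estimate: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    group_letters: dict[str, str] | None = None
    extra: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value}")
        if (
            self.estimate is not None
            and self.ci_lower is not None
            and self.ci_upper is not None
            and not (self.ci_lower <= self.estimate <= self.ci_upper)
        ):
            raise ValidationError("CI must bracket the estimate")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_curves(path: str | Path) -> list[ForceCurve]:
    """Read a tidy curve CSV into a list of :class:`ForceCurve`.

    The file holds one row per sample with columns ``test_id, species,
    direction, distance_mm, force_mN`` and optionally ``normal_force_mN,
    sample_rate, speed``.  One curve is returned per unique
    ``(test_id, direction)`` with rows sorted by distance order as read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"curve file {path} is missing column(s): {', '.join(missing)}")
    curves: list[ForceCurve] = []
    for (test_id, direction), grp in df.groupby(["test_id", "direction"], sort=True):
        if direction not in DIRECTIONS:
            raise ValidationError(
                f"unknown direction {direction!r} for test {test_id!r}"
            )
        species = str(grp["species"].iloc[0])
        kwargs = {}
        if "normal_force_mN" in grp.columns:
            kwargs["normal_force"] = float(grp["normal_force_mN"].iloc[0])
        if "sample_rate" in grp.columns:
            kwargs["sample_rate"] = float(grp["sample_rate"].iloc[0])
        if "speed" in grp.columns:
            kwargs["speed"] = float(grp["speed"].iloc[0])
        dist = grp["distance_mm"].to_numpy(dtype=float)
        if np.any(np.diff(dist) < 0):
            raise ValidationError(
                f"distance not monotone non-decreasing for test {test_id!r} "
                f"({direction})"
            )
        curves.append(
            ForceCurve(
                test_id=str(test_id),
                species=species,
                direction=str(direction),
                distance=dist,
                force=grp["force_mN"].to_numpy(dtype=float),
                **kwargs,
            )
        )
    log.info("read %d curve(s) from %s", len(curves), path)
    return curves


def write_curves(curves: Iterable[ForceCurve], path: str | Path) -> None:
    """Write curves to the tidy CSV layout read by :func:`read_curves`."""
    curves = list(curves)
    if not curves:
        raise ValidationError("refusing to write an empty curve collection")
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "test_id": c.test_id,
                    "species": c.species,
                    "direction": c.direction,
                    "distance_mm": c.distance,
                    "force_mN": c.force,
                    "normal_force_mN": c.normal_force,
                    "sample_rate": c.sample_rate,
                    "speed": c.speed,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        Path(path), index=False, float_format="%.9g"
    )
    log.info("wrote %d curve(s) to %s", len(curves), path)


def read_morphology(path: str | Path) -> list[SpeciesMorphology]:
    """Read the per-species morphology table (one row per species)."""
    df = pd.read_csv(Path(path))
    required = (
        "species",
        "n_stems",
        "stem_mass_g",
        "stem_length_cm",
        "stem_diameter_mm",
        "climbing_habit",
        "internode_tested",
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"morphology file missing column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        n_int = None
        if "n_internodes" in df.columns and not pd.isna(row.get("n_internodes")):
            n_int = int(row["n_internodes"])
        out.append(
            SpeciesMorphology(
                species=str(row["species"]),
                n_stems=int(row["n_stems"]),
                stem_mass_g=float(row["stem_mass_g"]),
                stem_length_cm=float(row["stem_length_cm"]),
                stem_diameter_mm=float(row["stem_diameter_mm"]),
                climbing_habit=str(row["climbing_habit"]),
                internode_tested=int(row["internode_tested"]),
                n_internodes=n_int,
            )
        )
    return out


_FEATURE_COLUMNS = (
    "test_id",
    "species",
    "direction",
    "static_force",
    "sliding_mean_force",
    "max_sliding_force",
    "peak_frequency",
    "n_peaks",
    "static_peak_distance",
    "window_start",
    "window_end",
    "cv_sliding",
    "peak_positions",
    "flags",
)


def features_to_frame(
    features: Sequence[FrictionFeatures | PairedFeatures],
) -> pd.DataFrame:
    """Flatten features into a tidy DataFrame (paired records → 2 rows
    plus anisotropy columns)."""
    rows = []
    for f in features:
        if isinstance(f, PairedFeatures):
            for member in (f.apical, f.basal):
                rows.append(_feature_row(member, f))
        else:
            rows.append(_feature_row(f, None))
    return pd.DataFrame(rows)


def _feature_row(f: FrictionFeatures, pair: PairedFeatures | None) -> dict:
    row = {
        "test_id": f.test_id,
        "species": f.species,
        "direction": f.direction,
        "static_force": f.static_force,
        "sliding_mean_force": f.sliding_mean_force,
        "max_sliding_force": f.max_sliding_force,
        "peak_frequency": f.peak_frequency,
        "n_peaks": f.n_peaks,
        "static_peak_distance": f.static_peak_distance,
        "window_start": f.window_start,
        "window_end": f.window_end,
        "cv_sliding": f.cv_sliding,
        "peak_positions": ";".join(f"{p:.6g}" for p in f.peak_positions),
        "flags": ";".join(sorted(f.flags)),
    }
    if pair is not None:
        row["static_anisotropy"] = pair.static_anisotropy
        row["sliding_anisotropy"] = pair.sliding_anisotropy
    return row


def write_features(
    features: Sequence[FrictionFeatures | PairedFeatures], path: str | Path
) -> None:
    """Write a feature table as CSV; numeric fields keep >= 6 significant
    digits and flags are semicolon-joined."""
    features = list(features)
    if not features:
        raise ValidationError("refusing to write an empty feature collection")
    df = features_to_frame(features)
    df.to_csv(Path(path), index=False, float_format="%.9g")
    log.info("wrote %d feature row(s) to %s", len(df), path)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back as a DataFrame (tabular downstream use)."""
    df = pd.read_csv(Path(path))
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature file missing column(s): {', '.join(missing)}")
    df["flags"] = df["flags"].fillna("")
    return df


_CONFIG_KEYS = (
    "speed",
    "sample_rate",
    "travel",
    "sliding_window",
    "top_k_peaks",
    "gravity",
    "rng_seed",
)


def load_config(path: str | Path | None = None) -> SledTestConfig:
    """Load a :class:`SledTestConfig` from a flat YAML key-value file.

    Unspecified keys take the instrument defaults; unknown keys log a
    warning and are ignored; invalid values raise ``ValidationError``.
    ``path=None`` returns the all-defaults config.
    """
    if path is None:
        return SledTestConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise FormatError(f"config {path} is not a flat key-value mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _CONFIG_KEYS:
            log.warning("config %s: ignoring unknown key %r", path, key)
            continue
        kwargs[key] = value
    return SledTestConfig(**kwargs)
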