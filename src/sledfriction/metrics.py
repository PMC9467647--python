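"""Normal-force calibration and directional anisotropy metrics.

The sled test presses the specimen onto the substrate with a normal
force chosen to match the resting force of the species' searcher stem:
half the median fresh mass of the stem, converted to millinewtons.  A
searcher attached at its base but resting on a support near its apex
loads the support with roughly half its weight, hence the half-mass
rule.  Cane-like climbers, which rest one stiff internode at a time,
use the whole stem mass divided by the internode count instead.

Gravity is taken as 9.8 m s^-2 exactly: the published gram-to-mN
conversions are exact multiples of 9.8 (e.g. 4.35 g -> 42.63 mN), which
9.80665 would not reproduce.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PairedFeatures, SpeciesMorphology, ValidationError

__all__ = [
    "normal_force_from_mass",
    "normal_force_cane",
    "normal_force_for",
    "anisotropy",
    "pair_features",
    "species_anisotropy_summary",
]

GRAVITY = 9.8  # m s^-2; exact for reproducing published conversions


def normal_force_from_mass(stem_mass_g: float, gravity: float = GRAVITY) -> float:
    """Normal force (mN) from the half-mass rule: (m/2 g) x g m s^-2.

    Grams x m s^-2 gives millinewtons directly (1 g x 1 m s^-2 = 1 mN).
    """
    if not stem_mass_g > 0:
        raise ValidationError("stem_mass_g must be positive")
    return stem_mass_g / 2.0 * gravity


def normal_force_cane(
    stem_mass_g: float, n_internodes: int, gravity: float = GRAVITY
) -> float:
    """Normal force (mN) for cane-like climbers: whole stem mass divided
    by the number of cane-like internodes, times g."""
    if not stem_mass_g > 0:
        raise ValidationError("stem_mass_g must be positive")
    if n_internodes < 1:
        raise ValidationError("n_internodes must be >= 1")
    return stem_mass_g / n_internodes * gravity


def normal_force_for(morph: SpeciesMorphology, gravity: float = GRAVITY) -> float:
    """Normal force for a species row: cane rule when ``n_internodes``
    is given, half-mass rule otherwise."""
    if morph.n_internodes is not None:
        return normal_force_cane(morph.stem_mass_g, morph.n_internodes, gravity)
    return normal_force_from_mass(morph.stem_mass_g, gravity)


def anisotropy(pair: PairedFeatures, which: str = "static") -> float:
    """Basal/apical force ratio for one paired test.

    ``which`` selects ``"static"`` (first-peak forces) or ``"sliding"``
    (window-mean forces).  Values above 1 mean the stem resists backward
    slipping more than forward motion.
    """
    if which == "static":
        return pair.static_anisotropy
    if which == "sliding":
        return pair.sliding_anisotropy
    raise ValueError("which must be 'static' or 'sliding'")


def pair_features(features) -> list[PairedFeatures]:
    """Join apical and basal feature records of the same test_id."""
    by_test: dict[str, dict[str, object]] = {}
    for f in features:
        by_test.setdefault(f.test_id, {})[f.direction] = f
    pairs = []
    for test_id, members in sorted(by_test.items()):
        if "apical" in members and "basal" in members:
            pairs.append(
                PairedFeatures(
                    test_id=test_id,
                    apical=members["apical"],
                    basal=members["basal"],
                )
            )
    return pairs


def species_anisotropy_summary(
    pairs: list[PairedFeatures], which: str = "static", confidence: float = 0.95
) -> pd.DataFrame:
    """Species-level anisotropy: the MEAN OF PER-TEST RATIOS with a
    t-based confidence interval.

    Averaging per-test ratios (rather than taking the ratio of mean
    forces) matches how published species-level anisotropies exceed the
    ratio of the published mean forces.
    """
    rows = []
    by_species: dict[str, list[float]] = {}
    for p in pairs:
        by_species.setdefault(p.species, []).append(anisotropy(p, which))
    for species, ratios in sorted(by_species.items()):
        r = np.asarray(ratios)
        n = len(r)
        mean = float(np.mean(r))
        if n > 1:
            sem = float(np.std(r, ddof=1) / np.sqrt(n))
            tcrit = float(sps.t.ppf(0.5 + confidence / 2, n - 1))
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            lo = hi = mean
        rows.append(
            {
                "species": species,
                "n": n,
                "anisotropy_mean": mean,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)
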