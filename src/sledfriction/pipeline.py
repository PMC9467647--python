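"""End-to-end orchestration: simulate -> extract -> derive -> stats.

The library functions here back the command-line interface but are
usable directly.  Each stage reads/writes the tidy CSV layouts of
:mod:`sledfriction.io` so intermediate products can be inspected or
swapped for real instrument exports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as fx
from . import io as sio
from . import metrics, simulate, stats

__all__ = [
    "run_simulate",
    "run_extract",
    "run_stats",
    "run_all",
]

FEATURE_PARAMS = (
    "static_force",
    "sliding_mean_force",
    "max_sliding_force",
    "peak_frequency",
)


def _manifest(out_dir: Path, seed: int, config: sio.SledTestConfig, **extra) -> None:
    payload = {"seed": seed, "config": asdict(config), **extra}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    n_species: int = 10,
    tests_per_species: int = 20,
    param_table: dict[str, simulate.SimParams] | None = None,
    config: sio.SledTestConfig | None = None,
    force: bool = False,
) -> tuple[Path, Path]:
    """Simulate a study and write ``curves.csv`` + ``ground_truth.csv``."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or sio.SledTestConfig(rng_seed=seed)
    curves, truth = simulate.simulate_study(
        n_species=n_species,
        tests_per_species=tests_per_species,
        param_table=param_table,
        seed=seed,
        config=config,
    )
    curves_path = out_dir / "curves.csv"
    truth_path = out_dir / "ground_truth.csv"
    sio.write_curves(curves, curves_path)
    truth.to_csv(truth_path, index=False, float_format="%.9g")
    _manifest(out_dir, seed, config, n_curves=len(curves))
    return curves_path, truth_path


def run_extract(
    curves_path: str | Path,
    out_path: str | Path,
    config: sio.SledTestConfig | None = None,
    plots_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Extract features for every curve; skip (and count) curves with no
    static peak; pair directions where both exist."""
    config = config or sio.SledTestConfig()
    curves = sio.read_curves(curves_path)
    feats: list[sio.FrictionFeatures] = []
    skipped = 0
    for c in curves:
        try:
            feats.append(fx.extract_features(c, config))
        except (fx.NoStaticPeakError, fx.WindowTooShortError) as err:
            skipped += 1
            sio.log.warning("skipping %s/%s: %s", c.test_id, c.direction, err)
        if plots_dir is not None:
            plot_curve_diagnostics(c, Path(plots_dir), config)
    if skipped:
        sio.log.info("skipped %d curve(s) without a usable static peak", skipped)
    pairs = metrics.pair_features(feats)
    records: list = list(pairs)
    paired_ids = {p.test_id for p in pairs}
    records += [f for f in feats if f.test_id not in paired_ids]
    sio.write_features(records, out_path)
    df = sio.read_features(out_path)
    df.attrs["skipped"] = skipped
    return df


def run_stats(
    features_path: str | Path,
    out_dir: str | Path,
    morphology_path: str | Path | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Produce the five summary artifacts from a feature table.

    (i) species x parameter summary with 95% CIs and Tukey letters,
    (ii) per-species direction-comparison Wilcoxon table,
    (iii) anisotropy-vs-1 Wilcoxon table,
    (iv) OLS of basal static force on normal (resting) force and on stem
    diameter (needs a morphology table),
    (v) SMA of max vs mean sliding force per direction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = sio.read_features(features_path)
    if df["species"].nunique() < 2:
        raise sio.ValidationError("need features for >= 2 species")
    tables = {
        "species_summary": species_summary_table(df, alpha),
        "direction_wilcoxon": direction_wilcoxon_table(df),
        "anisotropy_vs_one": anisotropy_vs_one_table(df),
        "sma_max_vs_mean": sma_table(df),
    }
    tables["morphology_ols"] = (
        morphology_ols_table(df, sio.read_morphology(morphology_path))
        if morphology_path is not None
        else pd.DataFrame()
    )
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.9g")
    return tables


# ---------------------------------------------------------------------------
# Summary-table builders
# ---------------------------------------------------------------------------


def _ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    from scipy import stats as sps

    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        return m, m
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    t = float(sps.t.ppf(0.5 + confidence / 2, n - 1))
    return m - t * sem, m + t * sem


def species_summary_table(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Species x parameter x direction summary: mean, 95% CI, group
    letters from the omnibus-plus-Tukey pipeline."""
    rows = []
    for param in FEATURE_PARAMS:
        for direction, sub in df.groupby("direction"):
            sample = stats.GroupedSample.from_frame(sub, "species", param)
            omnibus = stats.one_way_anova(sample)
            letters = stats.tukey_hsd_letters(
                sample, alpha, on_ranks=bool(omnibus.extra.get("switched"))
            ).group_letters
            for species, grp in sub.groupby("species"):
                v = grp[param].to_numpy()
                lo, hi = _ci(v)
                rows.append(
                    {
                        "parameter": param,
                        "direction": direction,
                        "species": species,
                        "n": len(v),
                        "mean": float(np.mean(v)),
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "letters": letters[str(species)],
                        "omnibus": omnibus.method,
                        "omnibus_p": omnibus.p_value,
                    }
                )
    return pd.DataFrame(rows)


def _paired_frame(df: pd.DataFrame) -> pd.DataFrame:
    a = df[df["direction"] == "apical"].set_index("test_id")
    b = df[df["direction"] == "basal"].set_index("test_id")
    common = a.index.intersection(b.index)
    return a.loc[common], b.loc[common]


def direction_wilcoxon_table(df: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon (basal vs apical) per species per parameter."""
    apical, basal = _paired_frame(df)
    rows = []
    for param in FEATURE_PARAMS:
        for species in sorted(df["species"].unique()):
            mask = apical["species"] == species
            if mask.sum() < 3:
                continue
            res = stats.paired_wilcoxon(
                basal.loc[mask, param].to_numpy(),
                apical.loc[mask, param].to_numpy(),
            )
            rows.append(
                {
                    "parameter": param,
                    "species": species,
                    "n": int(mask.sum()),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.p_value < 0.05,
                }
            )
    return pd.DataFrame(rows)


def anisotropy_vs_one_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-species anisotropy (mean of per-test ratios, 95% CI) with a
    Wilcoxon test of ratio != 1."""
    apical, basal = _paired_frame(df)
    rows = []
    for which, param in (("static", "static_force"), ("sliding", "sliding_mean_force")):
        for species in sorted(df["species"].unique()):
            mask = apical["species"] == species
            if mask.sum() < 3:
                continue
            ratios = (
                basal.loc[mask, param].to_numpy() / apical.loc[mask, param].to_numpy()
            )
            res = stats.paired_wilcoxon(ratios, 1.0)
            lo, hi = _ci(ratios)
            rows.append(
                {
                    "which": which,
                    "species": species,
                    "n": len(ratios),
                    "anisotropy_mean": float(np.mean(ratios)),
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "p_value": res.p_value,
                    "significant": res.p_value < 0.05,
                }
            )
    return pd.DataFrame(rows)


def sma_table(df: pd.DataFrame) -> pd.DataFrame:
    """SMA of max sliding force on mean sliding force, per direction."""
    rows = []
    for direction, sub in df.groupby("direction"):
        res = stats.sma_fit(
            sub["sliding_mean_force"].to_numpy(), sub["max_sliding_force"].to_numpy()
        )
        rows.append(
            {
                "direction": direction,
                "n": res.extra["n"],
                "slope": res.estimate,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "intercept": res.extra["intercept"],
                "r_squared": res.extra["r_squared"],
                "ci_excludes_one": res.extra["excludes_one"],
            }
        )
    return pd.DataFrame(rows)


def morphology_ols_table(
    df: pd.DataFrame, morphology: list[sio.SpeciesMorphology]
) -> pd.DataFrame:
    """OLS of species-mean basal static force on resting (normal) force
    and on stem diameter."""
    basal = df[df["direction"] == "basal"]
    mean_static = basal.groupby("species")["static_force"].mean()
    rows = []
    morph = {m.species: m for m in morphology}
    common = [s for s in mean_static.index if s in morph]
    if len(common) < 3:
        return pd.DataFrame()
    y = mean_static.loc[common].to_numpy()
    for predictor, values in (
        ("normal_force_mN", np.array([metrics.normal_force_for(morph[s]) for s in common])),
        ("stem_diameter_mm", np.array([morph[s].stem_diameter_mm for s in common])),
    ):
        res = stats.ols_fit(values, y)
        rows.append(
            {
                "predictor": predictor,
                "n": len(common),
                "slope": res.estimate,
                "intercept": res.extra["intercept"],
                "r_squared": res.extra["r_squared"],
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics and full run
# ---------------------------------------------------------------------------


def plot_curve_diagnostics(
    curve: sio.ForceCurve, out_dir: Path, config: sio.SledTestConfig | None = None
) -> Path | None:
    """Annotated trace: raw force, trend line, identified peaks, and the
    static/sliding/max markers.  Returns the written path (or None if
    the curve has no static peak)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or sio.SledTestConfig()
    try:
        feats = fx.extract_features(curve, config)
    except (fx.NoStaticPeakError, fx.WindowTooShortError):
        return None
    seg = fx.sliding_window(curve, feats.static_peak_distance, config)
    ext_idx, _, _ = fx.detect_extrema(seg)
    _, (slope, intercept) = fx.detrend(seg, ext_idx)

    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(curve.distance, curve.force, lw=0.8, color="0.3", label="force")
    ax.plot(
        seg.distance, slope * seg.distance + intercept, color="orange", label="trend"
    )
    ax.plot(feats.peak_positions, feats.peak_forces, "ks", ms=3, label="peaks")
    ax.plot(feats.static_peak_distance, feats.static_force, "b+", ms=12, mew=2,
            label="static force")
    mid = (feats.window_start + feats.window_end) / 2
    ax.plot(mid, feats.sliding_mean_force, "k+", ms=12, mew=2, label="sliding mean")
    ax.plot(mid, feats.max_sliding_force, "r+", ms=12, mew=2, label="max sliding")
    ax.set_xlabel("distance (mm)")
    ax.set_ylabel("force (mN)")
    ax.set_title(f"{curve.test_id} ({curve.direction})")
    ax.legend(fontsize=7)
    path = out_dir / f"{curve.test_id}_{curve.direction}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    n_species: int = 10,
    tests_per_species: int = 20,
    config: sio.SledTestConfig | None = None,
    plots: bool = False,
    force: bool = False,
) -> Path:
    """Chain simulate -> extract -> stats and write a markdown report."""
    out_dir = Path(out_dir)
    curves_path, _truth = run_simulate(
        out_dir, seed=seed, n_species=n_species,
        tests_per_species=tests_per_species, config=config, force=force,
    )
    features_path = out_dir / "features.csv"
    run_extract(
        curves_path, features_path, config,
        plots_dir=out_dir / "plots" if plots else None,
    )
    tables = run_stats(features_path, out_dir / "tables")
    report = out_dir / "report.md"
    lines = [
        "# Sled friction-test analysis report",
        "",
        f"Simulated study: {n_species} species x {tests_per_species} paired tests "
        f"(seed {seed}).",
        "",
    ]
    for name, table in tables.items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append(
            "```\n" + table.to_string(index=False) + "\n```" if len(table) else "_no data_"
        )
        lines.append("")
    report.write_text("\n".join(lines))
    return report
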