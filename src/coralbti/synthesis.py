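"""Synthetic bleaching studies: heating programs, trajectories, images.

Everything the analysis pipeline consumes can be generated here with a
known ground truth, so each stage is testable end to end without any
external data:

* temperature programs for the fast (1 °C/day) and slow (1 °C/3 days)
  heating regimes, ramping 27 °C -> 35 °C;
* per-species bleaching-curve profiles (modified-Gaussian parameter
  means with between-colony spread and additive RG% measurement noise),
  calibrated so the fast-regime bleaching-start days fall in the 3-8 day
  range typical of scleractinian corals, with a *Millepora*-like profile
  showing an initial RG% rise;
* rendered photograph series: uniform-ish patches for coral and the
  black/white strip with per-image affine brightness/contrast jitter,
  plus the manifest consumed by the imaging module.

All randomness is driven by an explicit seed; the same seed regenerates
a study bit-exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import RegionSpec
from .modelfit import ModGaussParams, predict
from .trajectory import RGSeries

__all__ = [
    "TemperatureProgram",
    "SpeciesProfile",
    "StudyDesign",
    "SyntheticStudy",
    "FHP_PROGRAM",
    "SHP_PROGRAM",
    "temperature_at",
    "paper_like_profiles",
    "ranking_benchmark_profiles",
    "true_threshold_time",
    "gen_trajectory",
    "generate_study",
    "render_image_series",
    "render_study",
]


# ---------------------------------------------------------------------------
# temperature programs


@dataclass(frozen=True)
class TemperatureProgram:
    """A stepwise heating schedule: +step_C every days_per_step days."""

    label: str
    start_C: float = 27.0
    max_C: float = 35.0
    step_C: float = 1.0
    days_per_step: float = 1.0
    acclimation_days: float = 0.0


FHP_PROGRAM = TemperatureProgram("FHP", days_per_step=1.0)
SHP_PROGRAM = TemperatureProgram(
    "SHP", days_per_step=3.0, acclimation_days=3.0
)


def temperature_at(prog: TemperatureProgram, t: float) -> float:
    """Tank temperature (°C) at time ``t`` days after heating onset.

    Negative times within the acclimation window sit at the start
    temperature; the first +1 °C increment is applied on day 0 (the
    thermostat is stepped at noon), then one step per ``days_per_step``
    until the cap.
    """
    if t < -prog.acclimation_days:
        raise ValueError(
            f"t={t} precedes the acclimation window of {prog.label}"
        )
    if t < 0:
        return prog.start_C
    steps = 1 + int(np.floor(t / prog.days_per_step))
    return min(prog.start_C + prog.step_C * steps, prog.max_C)


# ---------------------------------------------------------------------------
# species profiles


@dataclass(frozen=True)
class SpeciesProfile:
    """Mean curve parameters and variability for one species x regime.

    ``b_sd`` is the approximate between-colony SD of the width parameter
    in days; internally the width is drawn lognormally (multiplicative
    spread ``b_sd / mean.b``) from a colony susceptibility factor that is
    shared across heating regimes, so the two fragments cut from one
    colony bleach consistently fast or slow in both tanks.
    """

    name: str
    mean: ModGaussParams
    y0_sd: float = 1.0
    a_sd: float = 2.0
    x0_sd: float = 0.2
    b_sd: float = 0.5
    c_sd: float = 0.2
    noise_sd: float = 3.0  # additive RG% measurement noise

    def __post_init__(self) -> None:
        for v in (self.y0_sd, self.a_sd, self.x0_sd, self.b_sd, self.c_sd,
                  self.noise_sd):
            if v < 0:
                raise ValueError("SDs must be non-negative")


def _solve_b(t_start: float, x0: float, y0: float, a: float, c: float
             ) -> float:
    """Width b such that the curve first drops to RG% = 95 at t_start."""
    u = (2.0 * np.log(a / (95.0 - y0))) ** (1.0 / c)
    return (t_start - x0) / u


def _profile(name, t_start, *, y0=2.0, a=98.0, x0=0.0, c=4.0,
             b_sd=0.5, x0_sd=0.2, noise_sd=3.0) -> SpeciesProfile:
    b = _solve_b(t_start, x0, y0, a, c)
    return SpeciesProfile(
        name=name,
        mean=ModGaussParams(y0=y0, a=a, x0=x0, b=b, c=c),
        b_sd=b_sd,
        x0_sd=x0_sd,
        noise_sd=noise_sd,
    )


def paper_like_profiles(regime: str) -> list[SpeciesProfile]:
    """Demo profiles emulating the five-species tank assay.

    Bleaching-start days (the 5%-drop criterion) are centred near 3.2,
    5.5, 6.4, 6.8 and 8.4 days under the fast regime and stretch out
    (7.9-22.5 days) under the slow regime; the *Millepora*-like species
    carries an initial RG% rise (~10% fast, ~40% slow).  Between-colony
    spreads are wider under slow heating, mirroring the poorer
    repeatability of long assays.
    """
    if regime == "FHP":
        return [
            _profile("Seriatopora caliendrum", 3.2, b_sd=0.5),
            _profile("Pocillopora verrucosa", 5.5, b_sd=0.7),
            _profile("Pocillopora damicornis", 6.4, b_sd=1.9),
            _profile("Favites complanata", 6.8, b_sd=1.6),
            _profile(
                "Millepora intricata", 8.4, a=108.0, x0=2.76, c=2.0,
                b_sd=1.4,
            ),
        ]
    if regime == "SHP":
        return [
            _profile("Seriatopora caliendrum", 7.9, b_sd=2.8, x0_sd=0.4),
            _profile("Pocillopora verrucosa", 9.9, b_sd=7.0, x0_sd=0.4),
            _profile("Pocillopora damicornis", 7.9, b_sd=5.6, x0_sd=0.4),
            _profile("Favites complanata", 12.2, b_sd=4.6, x0_sd=0.4),
            _profile(
                "Millepora intricata", 22.5, a=138.0, x0=10.0, b_sd=2.3
            ),
        ]
    raise ValueError(f"unknown regime {regime!r}")


def ranking_benchmark_profiles(regime: str) -> list[SpeciesProfile]:
    """Five species with evenly separated susceptibility.

    Adjacent species' true BTI at the 30% cutoff differ by >= 2 days in
    both regimes, the separation at which mean-BTI ranking should be
    essentially always recoverable from 5 colony replicates.
    """
    scale = {"FHP": 1.0, "SHP": 1.25}[regime]
    starts = [3.2, 4.8, 6.4, 8.0, 9.6]
    return [
        _profile(f"species_{i + 1}", scale * s, b_sd=0.05 * scale * s)
        for i, s in enumerate(starts)
    ]


def true_threshold_time(
    p: ModGaussParams, cutoff: float
) -> float:
    """Closed-form post-peak crossing time of RG% = 100 - cutoff.

    Returns NaN when the curve never reaches the threshold (floor too
    high, or fitted peak below the threshold).
    """
    thr = 100.0 - cutoff
    if thr <= p.y0 or thr > p.y0 + p.a:
        return float("nan")
    u = (2.0 * np.log(p.a / (thr - p.y0))) ** (1.0 / p.c)
    return p.x0 + p.b * u


# ---------------------------------------------------------------------------
# trajectory generation


def _fragment_rng(
    seed: int, regime: str, species: str, colony_index: int
) -> np.random.Generator:
    """Stable per-fragment stream, independent of generation order."""
    return np.random.default_rng(
        [
            seed,
            zlib.crc32(regime.encode()),
            zlib.crc32(species.encode()),
            colony_index,
        ]
    )


def _colony_factor(seed: int, species: str, colony_index: int) -> float:
    """Standard-normal susceptibility factor shared by a colony's fragments.

    Keyed without the regime, so the fragment placed in the fast tank
    and its sibling in the slow tank inherit the same factor.
    """
    rng = np.random.default_rng(
        [seed, zlib.crc32(species.encode()), colony_index, 11]
    )
    return float(rng.standard_normal())


def _draw_params(
    profile: SpeciesProfile,
    rng: np.random.Generator,
    colony_z: float,
) -> ModGaussParams:
    m = profile.mean
    y0 = rng.normal(m.y0, profile.y0_sd)
    a = max(rng.normal(m.a, profile.a_sd), 1.0)
    x0 = rng.normal(m.x0, profile.x0_sd)
    # widths are positive and right-skewed: lognormal draw around the
    # species mean, driven by the shared colony factor
    cv_b = profile.b_sd / m.b
    b = m.b * float(np.exp(colony_z * cv_b))
    cv_c = profile.c_sd / m.c
    c = m.c * float(np.exp(rng.normal(0.0, cv_c)))
    return ModGaussParams(y0=y0, a=a, x0=x0, b=b, c=c)


def gen_trajectory(
    profile: SpeciesProfile,
    colony_index: int,
    times: np.ndarray,
    seed: int,
    regime: str = "FHP",
) -> tuple[RGSeries, ModGaussParams]:
    """Draw one colony's curve and sample a noisy RG% trajectory.

    Deterministic for a given (seed, regime, species, colony): the RNG
    stream is keyed on all four, so adding species or colonies to a
    study does not perturb the others.
    """
    times = np.asarray(times, dtype=float)
    rng = _fragment_rng(seed, regime, profile.name, colony_index)
    z = _colony_factor(seed, profile.name, colony_index)
    truth = _draw_params(profile, rng, z)
    clean = predict(truth, times)
    noisy = clean + rng.normal(0.0, profile.noise_sd, size=len(times))
    frag_id = f"{profile.name.replace(' ', '_')}-{regime}-c{colony_index}"
    series = RGSeries(
        fragment_id=frag_id,
        times=times,
        rg_values=np.asarray(noisy, dtype=float),
        species=profile.name,
        colony=f"c{colony_index}",
        regime=regime,
    )
    return series, truth


# ---------------------------------------------------------------------------
# whole studies


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic tank study.

    Twice-daily sampling (0.5-day steps) over a regime-specific duration;
    by default 2 regimes x 5 species x 5 colonies, the five-species
    single-tank design.
    """

    seed: int
    profiles: dict = field(
        default_factory=lambda: {
            r: paper_like_profiles(r) for r in ("FHP", "SHP")
        }
    )
    n_colonies: int = 5
    time_step: float = 0.5
    durations: dict = field(
        default_factory=lambda: {"FHP": 25.0, "SHP": 40.0}
    )


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated trajectories plus the ground-truth parameter table."""

    design: StudyDesign
    rg_series: list
    truth: pd.DataFrame  # one row per fragment, with true params and BTIs


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Generate every fragment trajectory of a study design."""
    series_list = []
    truth_rows = []
    for regime, profiles in design.profiles.items():
        duration = design.durations[regime]
        times = np.arange(0.0, duration + 1e-9, design.time_step)
        for profile in profiles:
            for colony in range(design.n_colonies):
                series, truth = gen_trajectory(
                    profile, colony, times, design.seed, regime
                )
                series_list.append(series)
                truth_rows.append(
                    {
                        "fragment_id": series.fragment_id,
                        "species": profile.name,
                        "colony": series.colony,
                        "regime": regime,
                        "y0": truth.y0,
                        "a": truth.a,
                        "x0": truth.x0,
                        "b": truth.b,
                        "c": truth.c,
                        "noise_sd": profile.noise_sd,
                        "true_bti5": true_threshold_time(truth, 5.0),
                        "true_bti30": true_threshold_time(truth, 30.0),
                        "true_bti50": true_threshold_time(truth, 50.0),
                    }
                )
    return SyntheticStudy(
        design=design,
        rg_series=series_list,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# image rendering

_PATCH = 21  # patch side in pixels; 21x21 keeps the dither texture zero-mean
_MARGIN = 10
_IMG_H = _PATCH + 2 * _MARGIN
_IMG_W = 3 * _PATCH + 4 * _MARGIN

#: ROIs of the three patches in every rendered frame (coral, black, white).
CORAL_ROI = RegionSpec(_MARGIN, _MARGIN, _PATCH, _PATCH)
BLACK_ROI = RegionSpec(2 * _MARGIN + _PATCH, _MARGIN, _PATCH, _PATCH)
WHITE_ROI = RegionSpec(3 * _MARGIN + 2 * _PATCH, _MARGIN, _PATCH, _PATCH)

# zero-mean integer texture (exactly zero over a 21-wide row) so that a
# patch spans ~21 gray levels; per-pixel rounding errors under affine
# jitter then average out instead of biasing the patch mean
_TEXTURE = np.tile(np.arange(_PATCH) - _PATCH // 2, (_PATCH, 1))


class RenderClippingError(ValueError):
    """Requested jitter would push pixels outside [0, 255]."""


def _fill_patch(value: float, rng: np.random.Generator) -> np.ndarray:
    """A patch whose float mean equals ``value`` to ~1/880 gray level."""
    base = int(np.floor(value))
    frac = value - base
    n = _PATCH * _PATCH
    n_hi = int(round(frac * n))
    flat = np.full(n, base, dtype=np.int64)
    idx = rng.permutation(n)[:n_hi]
    flat[idx] += 1
    return flat.reshape(_PATCH, _PATCH) + _TEXTURE


def _timestamp(day: float) -> str:
    """Map a day offset to an ISO timestamp (6 AM = +0.0, 6 PM = +0.5)."""
    base = pd.Timestamp("2021-06-01 06:00:00")
    return (base + pd.Timedelta(days=float(day))).isoformat()


def render_image_series(
    g0_values: np.ndarray,
    times: np.ndarray,
    out_dir: str | Path,
    *,
    fragment_id: str = "frag",
    species: str = "synthetic",
    colony: str = "c0",
    regime: str = "FHP",
    strip_black_level: float = 30.0,
    strip_white_level: float = 225.0,
    alpha_range: tuple[float, float] = (1.0, 1.0),
    beta_range: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Render one fragment's G_0 series as PNG frames plus manifest rows.

    Each frame holds three textured patches — coral, black reference,
    white reference — whose mean grays encode the requested ``G_0`` given
    the strip levels.  A per-frame affine jitter ``g -> alpha*g + beta``
    emulates session-to-session exposure drift; generation fails rather
    than clip.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g0_values = np.asarray(g0_values, dtype=float)
    times = np.asarray(times, dtype=float)
    if g0_values.shape != times.shape:
        raise ValueError("g0_values and times must have equal length")
    rng = np.random.default_rng(
        [seed, zlib.crc32(fragment_id.encode()), 7]
    )
    rows = []
    for i, (day, g0) in enumerate(zip(times, g0_values)):
        coral_level = strip_white_level + g0 * (
            strip_black_level - strip_white_level
        )
        frame = np.full((_IMG_H, _IMG_W), 128.0)
        for roi, level in (
            (CORAL_ROI, coral_level),
            (BLACK_ROI, strip_black_level),
            (WHITE_ROI, strip_white_level),
        ):
            frame[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w] = (
                _fill_patch(level, rng)
            )
        alpha = rng.uniform(*alpha_range)
        beta = rng.uniform(*beta_range)
        jittered = alpha * frame + beta
        if jittered.min() < -0.5 or jittered.max() > 255.49:
            raise RenderClippingError(
                f"frame {i}: jitter alpha={alpha:.3f}, beta={beta:.1f} "
                f"clips (range {jittered.min():.1f}..{jittered.max():.1f})"
            )
        pixels = np.rint(jittered).astype(np.uint8)
        fname = f"{fragment_id}_{i:04d}.png"
        Image.fromarray(pixels, mode="L").save(out / fname)
        rows.append(
            {
                "image_path": fname,
                "timestamp_iso": _timestamp(day),
                "fragment_id": fragment_id,
                "species": species,
                "colony": colony,
                "regime": regime,
                "coral_roi": CORAL_ROI.unparse(),
                "black_roi": BLACK_ROI.unparse(),
                "white_roi": WHITE_ROI.unparse(),
            }
        )
    return pd.DataFrame(rows)


def render_study(
    study: SyntheticStudy,
    out_dir: str | Path,
    *,
    g0_normal: float = 0.75,
    g0_bleach: float = 0.10,
    alpha_range: tuple[float, float] = (1.0, 1.0),
    beta_range: tuple[float, float] = (0.0, 0.0),
) -> Path:
    """Render every fragment of a study and write ``manifest.csv``.

    RG% trajectories are mapped back to G_0 with the given baselines
    (RG = 100 maps to ``g0_normal``, RG = 0 to ``g0_bleach``) before
    rendering.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in study.rg_series:
        g0 = g0_bleach + (s.rg_values / 100.0) * (g0_normal - g0_bleach)
        frames.append(
            render_image_series(
                g0,
                s.times,
                out,
                fragment_id=s.fragment_id,
                species=s.species,
                colony=s.colony,
                regime=s.regime,
                alpha_range=alpha_range,
                beta_range=beta_range,
                seed=study.design.seed,
            )
        )
    manifest = pd.concat(frames, ignore_index=True)
    path = out / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
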