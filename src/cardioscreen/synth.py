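"""Synthetic beating-heart movies and fly tables with known ground truth.

Every downstream stage of the screen (diameter extraction, dilatation
indexes, hit selection, validation statistics) is testable against this
generator because the generated data carry exact, analytically known
geometry and group structure.

The movie model: a fluorescent heart tube seen side-on, extruded along the
frame's vertical axis. Two bright wall bands flank a dark lumen whose
half-width follows a periodic contraction waveform

    r(t) = r_sys + (r_dia - r_sys) * s(t),

where ``s`` holds a diastolic plateau at 1, falls to a *systolic plateau* at
0 occupying ``systolic_fraction`` of each beat, with raised-cosine
transitions. Walls are flat-top bands with Gaussian-smoothed edges: the
inner edge tracks the lumen radius while the outer contour stays fixed, the
wall thickening as the lumen narrows (cross-section conservation in a
contracting tube). This matters for the primary-screen measurement: the
pixel-wise minimum projection over time is then dark exactly on the union of
lumen positions — the diastolic lumen — and bright on the wall annulus.

Tabular records are drawn per fly from log-normal distributions whose
*median* equals the design mean, keeping diameters positive and letting
group medians (the quantities the dilatation indexes use) converge exactly
to the design values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .imaging import DiameterTrace, MovieStack

__all__ = [
    "SimulationSpec",
    "GroupDesign",
    "LibraryManifest",
    "ScreenBaseline",
    "GeometryError",
    "simulate_movie",
    "true_diameter_trace",
    "contraction_waveform",
    "simulate_fly_table",
    "draw_group_diameters",
    "simulate_screen",
    "simulate_group_movies",
    "spec_for_diameters",
    "default_library",
    "UNTREATED",
]

UNTREATED = "untreated"

#: raised-cosine fall/rise duration on each side of systole, as beat fraction
TRANSITION_FRACTION = 0.15

#: log-scale correlation between a fly's diastolic and systolic draws
EDD_ESD_RHO = 0.6


class GeometryError(ValueError):
    """Heart geometry does not fit in the frame."""


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of a synthetic movie.

    Defaults match the screen's acquisition (50 frames/s, 501 frames per
    movie) with a control-like heart at 1 µm/pixel so printed µm-scale
    diameters map directly to pixels. Identical spec + identical seed give a
    bit-identical movie.
    """

    frame_rate: float = 50.0  # frames/s
    n_frames: int = 501
    image_height: int = 64  # pixels
    image_width: int = 160  # pixels
    pixel_size: float = 1.0  # µm/pixel
    heart_center: float = 80.0  # pixel coordinate along the transverse axis
    diastolic_diameter: float = 60.0  # µm
    systolic_diameter: float = 25.0  # µm
    wall_thickness_sigma: float = 2.0  # µm, Gaussian edge softness
    wall_depth: float = 8.0  # µm, diastolic wall band depth beyond the lumen
    heart_rate: float = 2.5  # beats/s
    systolic_fraction: float = 0.3  # beat fraction spent at the systolic plateau
    wall_peak_intensity: float = 200.0  # a.u.
    background_intensity: float = 10.0  # a.u.
    noise_model: str = "gaussian"  # {gaussian, poisson}
    noise_scale: float = 5.0  # a.u. (gaussian sd; poisson gain)
    center_drift_amplitude: float = 0.0  # µm, slow transverse drift
    rate_jitter_cv: float = 0.05  # per-beat period CV
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.systolic_diameter < self.diastolic_diameter:
            raise ValueError("need 0 < systolic_diameter < diastolic_diameter")
        if not 0 < self.systolic_fraction < 1 - 2 * TRANSITION_FRACTION:
            raise ValueError(
                f"systolic_fraction must be in (0, {1 - 2 * TRANSITION_FRACTION})"
            )
        if self.heart_rate <= 0 or self.frame_rate <= 0:
            raise ValueError("heart_rate and frame_rate must be positive")
        if self.n_frames < 1 or self.image_height < 1 or self.image_width < 1:
            raise ValueError("movie geometry must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.noise_scale < 0 or self.center_drift_amplitude < 0:
            raise ValueError("noise_scale and drift amplitude must be >= 0")
        if self.rate_jitter_cv < 0:
            raise ValueError("rate_jitter_cv must be >= 0")

    def replace(self, **changes) -> "SimulationSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class GroupDesign:
    """One experimental group of flies (design medians, not samples)."""

    group_label: str  # {control, disease_untreated, disease_treated}
    n_flies: int
    edd_mean: float  # µm, log-normal median of per-fly EDD
    esd_mean: float  # µm, log-normal median of per-fly ESD
    between_fly_cv: float = 0.10
    compound_id: str | None = None
    subset_id: str = "S01"
    concentration_um: float | None = None

    GROUPS = ("control", "disease_untreated", "disease_treated")

    def validate(self) -> None:
        if self.group_label not in self.GROUPS:
            raise ValueError(f"group_label must be one of {self.GROUPS}")
        if not 0 < self.esd_mean < self.edd_mean:
            raise ValueError("need 0 < esd_mean < edd_mean")
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.between_fly_cv < 0:
            raise ValueError("between_fly_cv must be >= 0")
        if self.group_label == "disease_treated" and not self.compound_id:
            raise ValueError("disease_treated groups need a compound_id")


@dataclass(frozen=True)
class LibraryManifest:
    """Drug-library manifest: one row per compound with its screening subset."""

    entries: pd.DataFrame  # columns: compound_id, concentration_um, toxic_flag, subset_id

    COLUMNS = ("compound_id", "concentration_um", "toxic_flag", "subset_id")
    MAX_PER_SUBSET = 80

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries).reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if df["compound_id"].duplicated().any():
            dup = df.loc[df["compound_id"].duplicated(), "compound_id"].iloc[0]
            raise ValueError(f"duplicate compound_id {dup!r} in manifest")
        per_subset = df.groupby("subset_id").size()
        if (per_subset > self.MAX_PER_SUBSET).any():
            bad = per_subset.idxmax()
            raise ValueError(
                f"subset {bad!r} holds {per_subset.max()} compounds "
                f"(max {self.MAX_PER_SUBSET})"
            )
        object.__setattr__(self, "entries", df)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def toxic_ids(self) -> list[str]:
        return list(self.entries.loc[self.entries["toxic_flag"], "compound_id"])

    @classmethod
    def from_csv(cls, path) -> "LibraryManifest":
        df = pd.read_csv(path)
        df["toxic_flag"] = df["toxic_flag"].astype(bool)
        return cls(df)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass(frozen=True)
class ScreenBaseline:
    """Baseline group medians and arm sizes of one experiment subset.

    Defaults encode the screen's design — 12 treated disease-model flies per
    compound with 70 untreated disease-model and 20 wild-type control anchors
    per subset — and a disease model whose diastolic/systolic diameters are
    elevated 81% / 141% over control, with 10% between-fly variability.
    """

    control_edd: float = 60.0  # µm
    control_esd: float = 25.0  # µm
    disease_edd: float = 60.0 * 1.81  # µm, +81% over control
    disease_esd: float = 25.0 * 2.41  # µm, +141% over control
    between_fly_cv: float = 0.10
    n_treated: int = 12
    n_disease: int = 70
    n_control: int = 20


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------

def contraction_waveform(phase: np.ndarray, systolic_fraction: float) -> np.ndarray:
    """Relaxation waveform s(phase) in [0, 1] over one beat (phase in [0, 1)).

    1 on the diastolic plateau, 0 on the systolic plateau (of width
    ``systolic_fraction``), raised-cosine transitions of width
    ``TRANSITION_FRACTION`` on each side. The beat starts in diastole.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    tr = TRANSITION_FRACTION
    sf = systolic_fraction
    d = 1.0 - sf - 2 * tr  # diastolic plateau duration
    s = np.ones_like(phase)
    falling = (phase >= d) & (phase < d + tr)
    s[falling] = 0.5 * (1 + np.cos(np.pi * (phase[falling] - d) / tr))
    systole = (phase >= d + tr) & (phase < d + tr + sf)
    s[systole] = 0.0
    rising = phase >= d + tr + sf
    s[rising] = 0.5 * (1 - np.cos(np.pi * (phase[rising] - d - tr - sf) / tr))
    return s


def _beat_phases(spec: SimulationSpec) -> np.ndarray:
    """Per-frame beat phase in [0, 1), with per-beat period jitter.

    Uses a dedicated child stream of the spec seed so the analytic oracle
    :func:`true_diameter_trace` reproduces the exact same beat sequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed).spawn(2)[0])
    duration = spec.n_frames / spec.frame_rate
    mean_period = 1.0 / spec.heart_rate
    cv = spec.rate_jitter_cv
    sigma = np.sqrt(np.log1p(cv**2))
    periods = []
    total = 0.0
    while total < duration + mean_period:
        p = mean_period * np.exp(sigma * rng.standard_normal()) if cv > 0 else mean_period
        periods.append(p)
        total += p
    starts = np.concatenate(([0.0], np.cumsum(periods)))
    times = np.arange(spec.n_frames) / spec.frame_rate
    beat = np.searchsorted(starts, times, side="right") - 1
    return (times - starts[beat]) / np.asarray(periods)[beat]


def _lumen_radius(spec: SimulationSpec) -> np.ndarray:
    """Per-frame lumen half-width r(t) in µm (the exact generator geometry)."""
    r_dia = spec.diastolic_diameter / 2.0
    r_sys = spec.systolic_diameter / 2.0
    s = contraction_waveform(_beat_phases(spec), spec.systolic_fraction)
    return r_sys + (r_dia - r_sys) * s


def _center_positions(spec: SimulationSpec) -> np.ndarray:
    """Per-frame tube centre (µm along the transverse axis): slow sinusoidal drift."""
    c0 = spec.heart_center * spec.pixel_size
    if spec.center_drift_amplitude == 0:
        return np.full(spec.n_frames, c0)
    times = np.arange(spec.n_frames) / spec.frame_rate
    return c0 + spec.center_drift_amplitude * np.sin(2 * np.pi * 0.1 * times)


def true_diameter_trace(spec: SimulationSpec) -> DiameterTrace:
    """The exact per-frame lumen diameter (µm) the movie renders — the oracle."""
    spec.validate()
    return DiameterTrace(values=2.0 * _lumen_radius(spec), frame_rate=spec.frame_rate)


def simulate_movie(spec: SimulationSpec) -> MovieStack:
    """Render a synthetic beating-heart movie.

    Deterministic in the spec (including its seed): the same spec always
    yields a bit-identical stack. Raises :class:`GeometryError` naming the
    first frame whose wall band would leave the frame.
    """
    spec.validate()
    radius = _lumen_radius(spec)
    centers = _center_positions(spec)
    sigma = spec.wall_thickness_sigma
    outer = spec.diastolic_diameter / 2.0 + spec.wall_depth  # fixed outer contour

    extent = outer + 3.0 * sigma
    width_um = (spec.image_width - 1) * spec.pixel_size
    over = (centers + extent > width_um) | (centers - extent < 0)
    if over.any():
        t = int(np.argmax(over))
        raise GeometryError(
            f"frame {t}: wall band (centre {centers[t]:.1f} µm ± {extent:.1f} µm) "
            f"exceeds frame width {width_um:.1f} µm"
        )

    xs = np.arange(spec.image_width) * spec.pixel_size  # (W,)
    d = np.abs(xs[None, :] - centers[:, None])  # (T, W) distance from centre
    # flat-top wall band on [r(t), outer], Gaussian-smoothed edges
    band = ndtr((d - radius[:, None]) / sigma) * ndtr((outer - d) / sigma)
    profiles = spec.background_intensity + spec.wall_peak_intensity * band  # (T, W)
    frames = np.broadcast_to(
        profiles[:, None, :], (spec.n_frames, spec.image_height, spec.image_width)
    ).copy()

    if spec.noise_scale > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed).spawn(2)[1])
        if spec.noise_model == "gaussian":
            frames += rng.normal(0.0, spec.noise_scale, size=frames.shape)
        else:  # poisson: intensity -> photon counts at gain noise_scale
            frames = rng.poisson(frames / spec.noise_scale) * spec.noise_scale
    return MovieStack(
        frames=frames.astype(np.float32),
        frame_rate=spec.frame_rate,
        pixel_size=spec.pixel_size,
    )


def spec_for_diameters(
    edd: float, esd: float, base: SimulationSpec | None = None, **overrides
) -> SimulationSpec:
    """A movie spec for a fly with the given EDD/ESD, frame sized to fit.

    The frame width is grown as needed so dilated (disease-model) hearts
    never trip the geometry check; the tube stays centred.
    """
    base = base or SimulationSpec()
    margin = 12.0  # µm beyond the wall band on each side
    needed = 2 * (edd / 2.0 + base.wall_depth + 3 * base.wall_thickness_sigma + margin)
    width = max(base.image_width, int(np.ceil(needed / base.pixel_size)))
    spec = base.replace(
        diastolic_diameter=edd,
        systolic_diameter=esd,
        image_width=width,
        heart_center=width / 2.0,
        **overrides,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Tabular fly records
# ---------------------------------------------------------------------------

_GENOTYPE = {
    "control": "control",
    "disease_untreated": "disease",
    "disease_treated": "disease",
}


def draw_group_diameters(
    design: GroupDesign, z_edd: np.ndarray, z_esd: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """True per-fly (EDD, ESD) at given standard-normal quantiles.

    Exposing the quantiles lets two groups be drawn from *common* random
    numbers — a paired design that cancels between-fly sampling noise when
    the quantity of interest is a between-group contrast (classic
    common-random-number variance reduction).
    """
    sigma = np.sqrt(np.log1p(design.between_fly_cv**2))
    z_edd = np.asarray(z_edd, dtype=float)
    z_esd = np.asarray(z_esd, dtype=float)
    z2 = EDD_ESD_RHO * z_edd + np.sqrt(1 - EDD_ESD_RHO**2) * z_esd
    edd = design.edd_mean * np.exp(sigma * z_edd)
    esd = np.minimum(design.esd_mean * np.exp(sigma * z2), edd)
    return edd, esd


def _draw_group(design: GroupDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_flies
    edd, esd = draw_group_diameters(
        design, rng.standard_normal(n), rng.standard_normal(n)
    )
    treatment = design.compound_id if design.group_label == "disease_treated" else UNTREATED
    return pd.DataFrame(
        {
            "genotype": _GENOTYPE[design.group_label],
            "treatment": treatment,
            "subset_id": design.subset_id,
            "age_days": rng.integers(4, 7, size=n),
            "concentration_um": float(design.concentration_um)
            if design.concentration_um is not None
            else np.nan,
            "DD": edd,  # primary-screen diastolic estimate of the same lumen
            "EDD": edd,
            "ESD": esd,
            "FS": 100.0 * (edd - esd) / edd,
        }
    )


def simulate_fly_table(designs: list[GroupDesign], seed: int) -> pd.DataFrame:
    """Per-fly cardiac records drawn from the given group designs.

    EDD is log-normal with median ``edd_mean`` and CV ``between_fly_cv``;
    ESD likewise (correlated on the log scale), truncated below EDD.
    Reproducible under ``seed``.
    """
    if not designs:
        raise ValueError("empty design list")
    for d in designs:
        d.validate()
    rng = np.random.default_rng(seed)
    parts = [_draw_group(d, rng) for d in designs]
    table = pd.concat(parts, ignore_index=True)
    table.insert(0, "fly_id", [f"fly{idx:06d}" for idx in range(len(table))])
    return table


def simulate_screen(
    manifest: LibraryManifest,
    effect_profile: dict[str, tuple[float, float]] | None,
    base: ScreenBaseline | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A whole-screen fly table mirroring the subset design.

    Per subset: ``n_disease`` untreated disease-model flies, ``n_control``
    wild-type controls, and ``n_treated`` treated disease-model flies per
    non-toxic compound. ``effect_profile`` maps compound ids to
    ``(edd_multiplier, esd_multiplier)``: the treated group median is
    ``control + m * (disease - control)``, so m=1 is a null compound, m=0
    maps the mean onto control (expected index 0), m>1 aggravates.
    Toxic-flagged compounds yield no treated flies.
    """
    base = base or ScreenBaseline()
    effect_profile = effect_profile or {}
    known = set(manifest.entries["compound_id"])
    unknown = set(effect_profile) - known
    if unknown:
        raise ValueError(f"effect_profile compounds absent from manifest: {sorted(unknown)}")

    designs: list[GroupDesign] = []
    for subset_id, sub in manifest.entries.groupby("subset_id", sort=True):
        designs.append(
            GroupDesign(
                "disease_untreated",
                base.n_disease,
                base.disease_edd,
                base.disease_esd,
                base.between_fly_cv,
                subset_id=subset_id,
            )
        )
        designs.append(
            GroupDesign(
                "control",
                base.n_control,
                base.control_edd,
                base.control_esd,
                base.between_fly_cv,
                subset_id=subset_id,
            )
        )
        for row in sub.itertuples(index=False):
            if row.toxic_flag:
                continue
            m_edd, m_esd = effect_profile.get(row.compound_id, (1.0, 1.0))
            edd = base.control_edd + m_edd * (base.disease_edd - base.control_edd)
            esd = base.control_esd + m_esd * (base.disease_esd - base.control_esd)
            designs.append(
                GroupDesign(
                    "disease_treated",
                    base.n_treated,
                    edd,
                    min(esd, edd * 0.98),
                    base.between_fly_cv,
                    compound_id=row.compound_id,
                    subset_id=subset_id,
                    concentration_um=row.concentration_um,
                )
            )
    return simulate_fly_table(designs, seed)


def simulate_group_movies(
    design: GroupDesign,
    seed: int,
    base_spec: SimulationSpec | None = None,
) -> tuple[pd.DataFrame, list[MovieStack]]:
    """Per-fly movies for one group design, with the drawn ground truth.

    Draws each fly's true (EDD, ESD) from the group's log-normal design,
    renders one movie per fly (frame width sized to fit its heart) and
    returns the truth table alongside the stacks, so measured diameters can
    be checked fly by fly.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    records = _draw_group(design, rng)
    movie_seeds = rng.integers(0, 2**31, size=len(records))
    movies = []
    for (_, row), mseed in zip(records.iterrows(), movie_seeds):
        spec = spec_for_diameters(
            row["EDD"], row["ESD"], base=base_spec, rng_seed=int(mseed)
        )
        movies.append(simulate_movie(spec))
    records = records.reset_index(drop=True)
    records.insert(0, "fly_id", [f"fly{idx:04d}" for idx in range(len(records))])
    return records, movies


def default_library(
    n_compounds: int = 1280,
    n_subsets: int = 16,
    n_toxic: int = 5,
    concentration_um: float = 10.0,
    seed: int = 0,
) -> LibraryManifest:
    """A library manifest with the screen's shape: 16 subsets x 80 compounds, 5 toxic."""
    per_subset = int(np.ceil(n_compounds / n_subsets))
    if per_subset > LibraryManifest.MAX_PER_SUBSET:
        raise ValueError("too many compounds per subset")
    rng = np.random.default_rng(seed)
    ids = [f"C{i + 1:04d}" for i in range(n_compounds)]
    subsets = [f"S{(i // per_subset) + 1:02d}" for i in range(n_compounds)]
    toxic = np.zeros(n_compounds, dtype=bool)
    toxic[rng.choice(n_compounds, size=n_toxic, replace=False)] = True
    return LibraryManifest(
        pd.DataFrame(
            {
                "compound_id": ids,
                "concentration_um": concentration_um,
                "toxic_flag": toxic,
                "subset_id": subsets,
            }
        )
    )
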