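"""Synthetic transflectance FTIR phantoms of intervertebral disc sections.

Real IVD imaging data are bilinear Beer-Lambert mixtures: every pixel
spectrum is a non-negative combination of a handful of matrix-component
spectra (collagens, proteoglycans, elastin, embedding paraffin), zoned
across the section -- collagen I in the outer annulus fibrosus (AF), the
native proteoglycan population (PG1) in inner-annulus lobes, collagen II
ringing the nucleus pulposus (NP), the altered proteoglycan population
(PG2) in the elliptical nucleus core -- and corrupted by additive
baselines, multiplicative intensity variation and detector noise.
Degeneration manifests as a loss of PG1 and a gain of PG2, whose sulfated
C-O-S stretch sits 2 cm-1 lower (1124 vs 1126 cm-1): the annulus
environment carries the 1126 signature and the nucleus the 1124 one.

This module generates such cubes with full ground truth (component spectra,
abundance grids, tissue mask, regional abundances) plus a matched covariate
table (histological grade 0-6, GAG, hydroxyproline, MRI T2*) whose planted
monotone associations with the true NP proteoglycan content mirror the
degeneration biology the analysis is meant to detect.

Reference spectra are Gaussian band models built from published band
positions; band amplitudes and widths are synthetic choices (documented in
the methods note) since no measured spectra are distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .spectra import HyperspectralImage, PixelMask, WavenumberAxis

__all__ = [
    "BandModel",
    "ReferenceSpectrum",
    "ReferenceLibrary",
    "PhantomConfig",
    "PhantomGroundTruth",
    "default_library",
    "generate_phantom",
    "generate_cohort",
    "add_distortions",
    "REGION_WINDOWS",
]

# Percent-of-width windows for the three standard disc regions
# (anterior AF, nucleus pulposus, posterior AF).
REGION_WINDOWS: dict[str, tuple[float, float]] = {
    "aAF": (10.0, 20.0),
    "NP": (51.0, 61.0),
    "pAF": (85.0, 95.0),
}

DEFAULT_COMPONENTS = ("collagen_I", "collagen_II", "PG1", "PG2", "paraffin")


@dataclass(frozen=True)
class BandModel:
    """A single Gaussian absorbance band."""

    center: float   # cm-1
    width: float    # Gaussian sigma, cm-1
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise InvalidParameterError("band width must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("band amplitude must be non-negative")


@dataclass(frozen=True)
class ReferenceSpectrum:
    """A named component spectrum: a sum of Gaussian bands, max-normalized."""

    name: str
    bands: tuple[BandModel, ...]
    axis: WavenumberAxis
    intensities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        nu = self.axis.values
        y = np.zeros_like(nu)
        for b in self.bands:
            y += b.amplitude * np.exp(-((nu - b.center) / b.width) ** 2 / 2.0)
        peak = y.max()
        if peak > 0:
            y = y / peak
        object.__setattr__(self, "intensities", y)
        object.__setattr__(self, "bands", tuple(self.bands))

    def band_centers(self) -> tuple[float, ...]:
        return tuple(b.center for b in self.bands)


class ReferenceLibrary:
    """A collection of uniquely named reference spectra on one axis."""

    def __init__(self, entries: list[ReferenceSpectrum]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise InvalidParameterError("library names must be unique")
        if not entries:
            raise InvalidParameterError("library is empty")
        axis = entries[0].axis
        for e in entries[1:]:
            if e.axis != axis:
                raise InvalidParameterError("library entries share one axis")
        self.axis = axis
        self._entries = {e.name: e for e in entries}
        self._deriv_cache: dict[str, np.ndarray] = {}

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def __getitem__(self, name: str) -> ReferenceSpectrum:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def second_derivative(self, name: str, window_length: int = 15,
                          poly_order: int = 3) -> np.ndarray:
        """2nd-derivative version of an entry (cached)."""
        key = f"{name}:{window_length}:{poly_order}"
        if key not in self._deriv_cache:
            from .spectra import Spectrum, second_derivative
            spec = Spectrum(self.axis, self._entries[name].intensities)
            self._deriv_cache[key] = second_derivative(
                spec, window_length, poly_order
            ).intensities
        return self._deriv_cache[key]

    def spectra_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_channels, n_components) absorbance matrix S*."""
        names = names or self.names
        return np.column_stack([self._entries[n].intensities for n in names])


# Band tables. Positions (cm-1) are the published assignments: collagen
# amide II at 1558 (type I) / 1552 (type II), the amide III complex at
# 1282/1240/1204 cm-1 (type I) and 1238 cm-1 (type II), the glycosylation
# carbohydrate band of type II collagen near 1080 cm-1, proteoglycan
# polysaccharide bands at 1030/1064/1160 cm-1 with the sulfate C-O-S
# stretch at 1126 (native PG1) shifting to 1124 in the altered PG2
# population, elastin at 1516 cm-1, paraffin at 1473/1464/1378 cm-1 plus
# the weak long-chain-alkane CH3 rock near 1168 cm-1. Widths (Gaussian
# sigma) and relative amplitudes are synthetic modelling choices; widths
# are kept narrow (4-7 cm-1) because second-derivative processing resolves
# tissue bands to roughly that effective width, and the amplitudes give
# each component in-region (950-1300 cm-1) bands it dominates -- both are
# required for the unmixing problem the phantom poses to be well-posed.
_BAND_TABLES: dict[str, list[tuple[float, float, float]]] = {
    "collagen_I": [(1558, 8, 0.90), (1282, 6, 0.55), (1240, 6, 0.50),
                   (1204, 6, 0.30), (1032, 7, 0.20)],
    "collagen_II": [(1552, 8, 0.90), (1238, 6, 0.60), (1080, 7, 0.45),
                    (1060, 7, 0.20)],
    "PG1": [(1030, 6, 0.80), (1064, 6, 0.90), (1126, 5, 0.70),
            (1160, 6, 0.50), (1228, 6, 0.35), (1376, 6, 0.30)],
    # PG2 = PG1 with the C-O-S band shifted down by pg_shift and the
    # 1064 cm-1 band accentuated / 1030 attenuated, the reproducible
    # signature of the altered (degenerate) proteoglycan population.
    "PG2": [(1030, 6, 0.55), (1064, 6, 1.20), (1126, 5, 0.70),
            (1160, 6, 0.40), (1228, 6, 0.30), (1376, 6, 0.30)],
    "elastin": [(1516, 8, 0.90), (1160, 6, 0.50)],
    "paraffin": [(1473, 4, 1.00), (1464, 4, 0.90), (1378, 5, 0.60),
                 (1168, 5, 0.35)],
    # An optional extra factor with mixed collagen/elastin character
    # (amide II + 1516 cm-1), reported only in late-stage human discs.
    "extra": [(1554, 8, 0.90), (1516, 8, 0.80)],
}

_PG_COS_CENTER = 1126.0


def default_library(axis: WavenumberAxis, pg_shift: float = 2.0,
                    amplitudes: dict[str, dict[float, float]] | None = None
                    ) -> ReferenceLibrary:
    """Build the default six-component reference library (+ 'extra').

    ``pg_shift`` moves the PG2 C-O-S band down from 1126 cm-1 (default
    2 cm-1, i.e. to 1124). ``amplitudes`` optionally overrides band
    amplitudes, keyed by component name then band center.
    """
    lo, hi = axis.values.min(), axis.values.max()
    if lo > 950 or hi < 1600:
        raise InvalidParameterError(
            "axis must span at least 950-1600 cm-1 for the default library"
        )
    entries = []
    for name, table in _BAND_TABLES.items():
        bands = []
        for center, width, amp in table:
            if name == "PG2" and center == _PG_COS_CENTER:
                center = center - pg_shift
            if amplitudes and name in amplitudes:
                amp = amplitudes[name].get(center, amp)
            bands.append(BandModel(center, width, amp))
        entries.append(ReferenceSpectrum(name, tuple(bands), axis))
    return ReferenceLibrary(entries)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic IVD section.

    Defaults reproduce the acquisition geometry of the correlation study
    (60 x 208 pixel sections, 2 cm-1 point spacing for 4 cm-1 resolution
    data over 950-1800 cm-1) with mild realistic distortions.
    """

    n_rows: int = 60
    n_cols: int = 208
    axis_lo: float = 950.0
    axis_hi: float = 1800.0
    axis_spacing: float = 2.0
    degeneration_level: float = 0.5   # mild degeneration, the study condition
    pg_shift: float = 2.0
    noise_sigma: float = 0.005      # absorbance units (max band height = 1)
    baseline_order: int = 2         # -1 disables baselines
    baseline_scale: float = 0.1     # absorbance units
    multiplicative_range: tuple[float, float] = (1.0, 1.0)
    paraffin_everywhere: bool = True
    border_rows: int = 4            # non-tissue margin (rows each side)
    border_cols: int = 6            # non-tissue margin (cols each side)
    components: tuple[str, ...] = DEFAULT_COMPONENTS
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.degeneration_level <= 1.0:
            raise InvalidParameterError("degeneration_level must be in [0, 1]")
        if self.axis_spacing <= 0:
            raise InvalidParameterError("axis spacing must be positive")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be non-negative")
        if self.n_rows <= 2 * self.border_rows or self.n_cols <= 2 * self.border_cols + 2:
            raise InvalidParameterError("grid too small for the border margins")

    def make_axis(self) -> WavenumberAxis:
        return WavenumberAxis.regular(self.axis_lo, self.axis_hi,
                                      self.axis_spacing)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Everything the generator knows: C*, S*, mask, width, regional truth."""

    true_concentrations: dict[str, np.ndarray]   # name -> (n_rows, n_cols)
    true_spectra: ReferenceLibrary
    tissue_mask: PixelMask
    width_extent: tuple[int, int]                # first, last tissue column
    regional_true_abundance: pd.DataFrame        # region x component -> value

    def concentration_matrix(self, names: list[str] | None = None
                             ) -> np.ndarray:
        """(n_pixels, k) flattened true concentration matrix C*."""
        names = names or list(self.true_concentrations)
        return np.column_stack(
            [self.true_concentrations[n].ravel() for n in names]
        )


# ---------------------------------------------------------------------------
# Spatial abundance model over the tissue grid
# ---------------------------------------------------------------------------
# The disc is zoned the way histology and the 1126/1124 cm-1 C-O-S split
# describe it: collagen I confined to the outer annulus fibrosus at both
# ends of the width axis, the native proteoglycan population (PG1) peaking
# in two inner-annulus lobes (the 1126 cm-1 environment) with a smaller
# nucleus contribution, collagen II forming a ring around the nucleus core,
# and the altered population (PG2, 1124 cm-1) concentrated in an elliptical
# nucleus-core blob. The nucleus components carry a Gaussian row envelope
# (the nucleus is a blob, not a stripe), which also gives every component
# pixels it dominates -- the spatial counterpart of the band-table design
# note above. Paraffin infiltrates all tissue at a constant low level and
# fills the non-tissue border. Degeneration level ``d`` trades PG1
# (factor 1 - 0.8 d) for PG2 (factor 0.2 + 0.8 d).

_PARAFFIN_TISSUE = 0.3
_PARAFFIN_BORDER = 1.2
_NP_ROW_SIGMA = 0.25


def _component_grid(name: str, x: np.ndarray, r: np.ndarray,
                    d: float) -> np.ndarray:
    """Component abundance over the tissue grid.

    ``x``: fractional width, shape (1, n_cols); ``r``: fractional height,
    shape (n_rows, 1); result broadcasts to (n_rows, n_cols).
    """
    ones_r = np.ones_like(r)
    blob = np.exp(-((r - 0.5) / _NP_ROW_SIGMA) ** 2)
    if name == "collagen_I":
        return (np.exp(-(x / 0.12) ** 2)
                + np.exp(-((1.0 - x) / 0.12) ** 2)) * ones_r
    if name == "collagen_II":
        return 0.02 + 0.98 * np.exp(-((x - 0.5) / 0.20) ** 2) \
            * (1.0 - 0.7 * np.exp(-((x - 0.5) / 0.11) ** 2) * blob)
    if name == "PG1":
        lobes = (np.exp(-((x - 0.24) / 0.10) ** 2)
                 + np.exp(-((x - 0.76) / 0.10) ** 2)) * ones_r
        core = 0.25 * np.exp(-((x - 0.5) / 0.12) ** 2) * blob
        return (1.0 - 0.8 * d) * (lobes + core)
    if name == "PG2":
        return (0.2 + 0.8 * d) * np.exp(-((x - 0.5) / 0.08) ** 2) * blob
    if name == "elastin":
        return (0.05 + 0.95 * (np.exp(-((x - 0.04) / 0.12) ** 2)
                               + np.exp(-((x - 0.96) / 0.12) ** 2))) * ones_r
    if name == "paraffin":
        return np.full(np.broadcast_shapes(x.shape, r.shape),
                       _PARAFFIN_TISSUE)
    if name == "extra":
        return (0.05 + 0.45 * d * np.exp(-((x - 0.85) / 0.15) ** 2)) * ones_r
    raise InvalidParameterError(f"unknown component {name!r}")


def _aoi_row_fractions(config: PhantomConfig, aoi_rows: int = 10
                       ) -> np.ndarray:
    """Fractional heights of the centred analysis rows of the tissue grid."""
    n_t = config.n_rows - 2 * config.border_rows
    count = min(aoi_rows, n_t)
    start = (n_t - count) // 2
    return np.arange(start, start + count) / max(n_t - 1, 1)


def _true_regional_abundance(config: PhantomConfig,
                             degeneration_level: float | None = None
                             ) -> pd.DataFrame:
    """Mean abundance over each percent-of-width window.

    Averaged over the centred analysis rows, matching what the gradient
    stage of the pipeline measures.
    """
    d = (config.degeneration_level if degeneration_level is None
         else degeneration_level)
    x = np.linspace(0.0, 1.0, 1001)[None, :]
    r = _aoi_row_fractions(config)[:, None]
    rows = []
    for region, (lo, hi) in REGION_WINDOWS.items():
        sel = (x[0] >= lo / 100.0) & (x[0] <= hi / 100.0)
        for name in config.components:
            grid = _component_grid(name, x, r, d)
            rows.append({"region": region, "component": name,
                         "value": float(grid[:, sel].mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distortions
# ---------------------------------------------------------------------------

def add_distortions(image: HyperspectralImage, baseline_order: int = 2,
                    multiplicative_range: tuple[float, float] = (0.95, 1.05),
                    noise_sigma: float = 0.005, seed: int = 0,
                    baseline_scale: float = 0.1) -> HyperspectralImage:
    """Apply per-pixel baseline + multiplicative variation + white noise.

    out = m_p * in + baseline_p(nu) + N(0, sigma); deterministic given seed.
    Baselines are random polynomials of the given order in a [-1, 1]-scaled
    channel coordinate (order -1 disables them).
    """
    if image.derivative_order != 0:
        raise InvalidParameterError("distortions apply to absorbance data")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be non-negative")
    lo_m, hi_m = multiplicative_range
    if lo_m > hi_m or lo_m <= 0:
        raise InvalidParameterError("invalid multiplicative range")

    rng = np.random.default_rng(seed)
    n_pix, n_ch = image.n_pixels, len(image.axis)
    out = image.as_matrix().copy()

    m = rng.uniform(lo_m, hi_m, size=n_pix)
    out *= m[:, None]

    if baseline_order >= 0:
        u = np.linspace(-1.0, 1.0, n_ch)
        # higher orders get geometrically smaller coefficients
        for j in range(baseline_order + 1):
            coef = rng.uniform(-baseline_scale, baseline_scale, size=n_pix)
            out += (coef / (j + 1.0))[:, None] * u[None, :] ** j

    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma, size=(n_pix, n_ch))

    return HyperspectralImage(image.axis,
                              out.reshape(image.n_rows, image.n_cols, n_ch),
                              derivative_order=0,
                              pixel_size_um=image.pixel_size_um)


# ---------------------------------------------------------------------------
# Phantom and cohort generation
# ---------------------------------------------------------------------------

# Covariate model: monotone maps from true regional abundances, scaled to
# the magnitudes reported for caprine discs (GAG a few hundred ug per mg dry
# weight in a healthy NP, hydroxyproline ~ 50-150 ug/mg, NP T2* tens of ms).
_GAG_BASE, _GAG_GAIN = 60.0, 300.0
_HYP_BASE, _HYP_GAIN = 40.0, 90.0
_T2S_BASE, _T2S_GAIN = 15.0, 45.0
_ECHO_TIMES_MS = np.array([5.7, 10.9, 16.05, 21.2, 26.4])
# sd of the (1 - 0.8 d) PG1 scaling under d ~ U[0, 1]; used to express
# covariate noise as a signal-to-noise ratio without needing a cohort.
_PG1_SCALE_SD = 0.8 / np.sqrt(12.0)
_DEFAULT_SNR = 3.0


def _covariate_rows(sample_id: str, config: PhantomConfig,
                    regional: pd.DataFrame, rng: np.random.Generator,
                    snr: float = _DEFAULT_SNR) -> pd.DataFrame:
    """Per-region covariates planted on the true abundances.

    GAG and T2* are affine in the region's true PG1 abundance plus Gaussian
    noise at the requested signal-to-noise ratio; hydroxyproline follows
    total collagen; grade is the inverse NP PG1 fraction discretized onto
    the 0 (non-degenerate) .. 6 (degenerate) histological scale. T2* is
    produced the way the MRI covariate is in practice: a mono-exponential
    echo train at the five standard echo times with log-normal noise,
    refit by the log-linear least-squares estimator.
    """
    from .stats import t2star_fit

    reg = regional.set_index(["region", "component"])["value"]
    rows = []
    # non-degenerate NP PG1 abundance: the normalizing reference
    ref = _true_regional_abundance(config, degeneration_level=0.0)
    pg1_full = float(ref[(ref.region == "NP")
                         & (ref.component == "PG1")]["value"].iloc[0])
    for region in REGION_WINDOWS:
        pg1 = float(reg[(region, "PG1")])
        collagen = sum(float(reg[(region, c)])
                       for c in ("collagen_I", "collagen_II")
                       if (region, c) in reg.index)
        noise_sd = _PG1_SCALE_SD * pg1_full / snr
        gag = _GAG_BASE + _GAG_GAIN * pg1 + _GAG_GAIN * rng.normal(0, noise_sd)
        hyp = _HYP_BASE + _HYP_GAIN * collagen \
            + _HYP_GAIN * rng.normal(0, noise_sd)
        t2s_true = _T2S_BASE + _T2S_GAIN * pg1 \
            + _T2S_GAIN * rng.normal(0, noise_sd)
        t2s_true = max(t2s_true, 2.0)
        train = 100.0 * np.exp(-_ECHO_TIMES_MS / t2s_true)
        train *= np.exp(rng.normal(0.0, 0.01, size=train.size))
        t2s, _ = t2star_fit(_ECHO_TIMES_MS, train)
        rows.append({"sample_id": sample_id, "region": region,
                     "gag_ug_per_mg": max(gag, 0.0),
                     "hyp_ug_per_mg": max(hyp, 0.0),
                     "t2star_ms": t2s})
    # grade from the inverse NP PG1 fraction, linear bins on the 0-6 scale
    np_pg1 = float(reg[("NP", "PG1")])
    frac = np.clip(np_pg1 / pg1_full, 0.2, 1.0)
    grade = int(round(6.0 * (1.0 - frac) / 0.8))
    out = pd.DataFrame(rows)
    out.insert(2, "grade", grade)
    return out[["sample_id", "region", "grade", "gag_ug_per_mg",
                "hyp_ug_per_mg", "t2star_ms"]]


def generate_phantom(config: PhantomConfig,
                     library: ReferenceLibrary | None = None,
                     sample_id: str = "phantom",
                     ) -> tuple[HyperspectralImage, PhantomGroundTruth,
                                pd.DataFrame]:
    """Generate one synthetic IVD section with ground truth and covariates.

    The cube is C* S*^T (+ baseline + multiplicative variation + noise, all
    seeded). Non-tissue border pixels contain paraffin only, except the
    outermost one-pixel frame which is bare substrate (baseline/noise only)
    -- the two failure modes the amide II mask must reject.
    """
    axis = config.make_axis()
    if library is None:
        library = default_library(axis, pg_shift=config.pg_shift)
    elif library.axis != axis:
        raise InvalidParameterError("library axis does not match the config")
    for name in config.components:
        if name not in library:
            raise InvalidParameterError(f"component {name!r} not in library")

    nr, nc = config.n_rows, config.n_cols
    br, bc = config.border_rows, config.border_cols
    tissue = np.zeros((nr, nc), dtype=bool)
    tissue[br:nr - br, bc:nc - bc] = True
    first_col, last_col = bc, nc - bc - 1
    x = np.linspace(0.0, 1.0, last_col - first_col + 1)[None, :]
    r = np.linspace(0.0, 1.0, nr - 2 * br)[:, None]

    d = config.degeneration_level
    conc: dict[str, np.ndarray] = {}
    for name in config.components:
        grid = np.zeros((nr, nc))
        grid[br:nr - br, first_col:last_col + 1] = \
            _component_grid(name, x, r, d)
        if not config.paraffin_everywhere and name == "paraffin":
            grid[:] = 0.0
        if name == "paraffin":
            # paraffin-only border (all but the outer substrate frame)
            border = ~tissue
            frame = np.zeros((nr, nc), dtype=bool)
            frame[0, :] = frame[-1, :] = True
            frame[:, 0] = frame[:, -1] = True
            grid[border & ~frame] = _PARAFFIN_BORDER
        conc[name] = grid

    S = library.spectra_matrix(list(config.components))     # (ch, k)
    C = np.column_stack([conc[n].ravel() for n in config.components])
    cube = (C @ S.T).reshape(nr, nc, len(axis))
    image = HyperspectralImage(axis, cube, derivative_order=0)
    image = add_distortions(image, config.baseline_order,
                            config.multiplicative_range, config.noise_sigma,
                            seed=config.seed,
                            baseline_scale=config.baseline_scale)

    regional = _true_regional_abundance(config)
    rng = np.random.default_rng(config.seed + 1)
    covariates = _covariate_rows(sample_id, config, regional, rng)

    truth = PhantomGroundTruth(
        true_concentrations=conc,
        true_spectra=library,
        tissue_mask=PixelMask(tissue),
        width_extent=(first_col, last_col),
        regional_true_abundance=regional,
    )
    return image, truth, covariates


def generate_cohort(n_samples: int, seed: int = 0,
                    base_config: PhantomConfig | None = None,
                    snr: float = _DEFAULT_SNR,
                    ) -> tuple[list[PhantomConfig], pd.DataFrame,
                               pd.DataFrame]:
    """A graded cohort: degeneration levels spread over [0, 1].

    Returns per-sample configs, the pooled covariate table (grades assigned
    by quantile binning of the inverse NP PG1 abundance onto the 0-6 scale),
    and the pooled ground-truth regional-abundance table. Cubes are not
    synthesized here -- call :func:`generate_phantom` on each returned config
    (sample ids ``S000``, ``S001``, ...) for a full imaging run; the
    covariate and truth tables alone are what cohort-level statistics need.
    """
    if n_samples < 2:
        raise InvalidParameterError("a cohort needs at least 2 samples")
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    levels = rng.permutation(np.linspace(0.0, 1.0, n_samples))
    configs, cov_rows, truth_rows = [], [], []
    for i, d in enumerate(levels):
        cfg = PhantomConfig(**{**base.__dict__,
                               "degeneration_level": float(d),
                               "seed": int(rng.integers(0, 2**31 - 1))})
        configs.append(cfg)
        sid = f"S{i:03d}"
        regional = _true_regional_abundance(cfg)
        regional.insert(0, "sample_id", sid)
        truth_rows.append(regional)
        cov_rows.append(_covariate_rows(
            sid, cfg, regional.drop(columns="sample_id"),
            np.random.default_rng(cfg.seed + 1), snr=snr))
    covariates = pd.concat(cov_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)

    # cohort-level grade: quantile bins of inverse NP PG1 abundance, 7 levels
    np_pg1 = (truth[(truth.region == "NP") & (truth.component == "PG1")]
              .set_index("sample_id")["value"])
    ranks = np_pg1.rank(method="first", ascending=False) - 1
    grades = np.floor(ranks * 7 / len(np_pg1)).astype(int).clip(0, 6)
    covariates["grade"] = covariates["sample_id"].map(grades).astype(int)
    return configs, covariates, truth
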