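"""Synthetic LIBS and Raman spot spectra with taxon-specific structure.

The generator emulates a pellet-based zooplankton study: 29 samples over four
taxa plus one mixed sample, three visually distinct spot colours per pellet,
at least three interrogated spots per colour and modality, LIBS spectra on a
12,275-point 186-1049 nm grid and Raman spectra on a 2,801-point
450-3150 cm^-1 grid.  Each taxon carries a characteristic inventory of
emission lines (LIBS) and vibrational bands (Raman); spectra are rendered as
sums of Gaussian profiles over a smooth polynomial background with
heteroscedastic noise, modulated by spot colour and by sample-level lognormal
intensity factors that create realistic between-sample variance.

Strong resonance lines (Na I D, K I doublet, Ca II H&K, Mg II, Li I 670.8 nm)
and the saturating Raman C-H stretch region receive an extra per-spot
lognormal jitter: self-absorbed or detector-saturating signals are poorly
reproducible in practice, which is why downstream masking of these regions
exists at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LIBS = "LIBS"
RAMAN = "Raman"
MODALITIES = (LIBS, RAMAN)
COLOURS = ("dark", "medium", "light")
TAXA = ("Calanoida", "Euphausiacea", "Parasagitta", "Limacina", "Mixed")

#: (lo, hi, n_points) of the instrument grids.
LIBS_GRID = (186.0, 1049.0, 12275)
RAMAN_GRID = (450.0, 3150.0, 2801)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
#: integral of a unit-height Gaussian expressed per unit FWHM: sqrt(pi/(4 ln 2))
GAUSS_AREA_PER_FWHM = math.sqrt(math.pi / (4.0 * math.log(2.0)))

_LIBS_STEP = (LIBS_GRID[1] - LIBS_GRID[0]) / (LIBS_GRID[2] - 1)
#: default LIBS line FWHM: 3 detector pixels.
LIBS_LINE_FWHM = 3.0 * _LIBS_STEP
#: default Raman band FWHM in cm^-1 (4 cm^-1 resolution, natural widths larger).
RAMAN_BAND_FWHM = 10.0


def libs_axis(n: int | None = None) -> np.ndarray:
    lo, hi, npts = LIBS_GRID
    return np.linspace(lo, hi, n or npts)


def raman_axis(n: int | None = None) -> np.ndarray:
    lo, hi, npts = RAMAN_GRID
    return np.linspace(lo, hi, n or npts)


@dataclass(frozen=True)
class SpectralFeature:
    """One emission line or vibrational band of a taxon template.

    ``center`` is in nm (LIBS) or cm^-1 (Raman); ``width`` is the FWHM in the
    same units.  ``resonance_flag`` marks strongly self-absorbed or saturating
    features that are candidates for downstream masking and that receive
    per-spot intensity jitter when a dataset is generated.
    """

    center: float
    relative_intensity: float
    width: float
    label: str = ""
    resonance_flag: bool = False

    def __post_init__(self) -> None:
        if self.relative_intensity < 0:
            raise ValueError("relative_intensity must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")


@dataclass
class TaxonTemplate:
    """Spectral forward model of one taxon (or of the mixed sample)."""

    taxon: str
    libs_features: list[SpectralFeature]
    raman_features: list[SpectralFeature]
    colour_modulation: dict[str, float]
    #: polynomial background coefficients per modality, lowest order first,
    #: evaluated on the axis rescaled to [0, 1].
    background: dict[str, tuple[float, ...]]
    #: relative noise scale per modality.
    noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.colour_modulation) != set(COLOURS):
            raise ValueError(
                f"colour_modulation must be defined for exactly {set(COLOURS)}"
            )
        if any(f <= 0 for f in self.colour_modulation.values()):
            raise ValueError("colour modulation factors must be > 0")

    def features(self, modality: str) -> list[SpectralFeature]:
        if modality == LIBS:
            return self.libs_features
        if modality == RAMAN:
            return self.raman_features
        raise ValueError(f"unknown modality {modality!r}")


@dataclass
class StudyDesign:
    """Geometry of the synthetic study (who is measured, where, how often)."""

    taxon_counts: dict[str, int] = field(
        default_factory=lambda: {
            "Calanoida": 14,
            "Euphausiacea": 11,
            "Parasagitta": 2,
            "Limacina": 1,
            "Mixed": 1,
        }
    )
    spots_per_colour: int = 3
    libs_grid: tuple[float, float, int] = LIBS_GRID
    raman_grid: tuple[float, float, int] = RAMAN_GRID
    outlier_rate: float = 0.05
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spots_per_colour < 3:
            raise ValueError("spots_per_colour must be >= 3 (Grubbs needs n >= 3)")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.outlier_scale <= 1.0:
            raise ValueError("outlier_scale must be > 1")
        if self.libs_grid[2] <= 0 or self.raman_grid[2] <= 0:
            raise ValueError("grid lengths must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.taxon_counts.values())

    def axis(self, modality: str) -> np.ndarray:
        lo, hi, n = self.libs_grid if modality == LIBS else self.raman_grid
        return np.linspace(lo, hi, n)


@dataclass
class Spectrum:
    """One spot's intensity vector on a fixed axis, with acquisition metadata.

    ``signal`` keeps the rendered noise-free feature component so that outlier
    injection can scale feature-bearing intensities without touching the
    background; it is not serialised.
    """

    axis: np.ndarray
    intensities: np.ndarray
    modality: str
    sample_id: str = ""
    taxon: str = ""
    colour: str = ""
    spot_id: str = ""
    planted_outlier: bool = False
    signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.shape != self.intensities.shape:
            raise ValueError("axis and intensities must have the same length")
        if len(self.axis) > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")


def _gauss(center: float, fwhm: float, axis: np.ndarray, out: np.ndarray,
           height: float) -> None:
    """Add a Gaussian in place, evaluated only within +-6 sigma of the centre."""
    sigma = fwhm * _FWHM_TO_SIGMA
    lo = np.searchsorted(axis, center - 6.0 * sigma)
    hi = np.searchsorted(axis, center + 6.0 * sigma)
    if hi <= lo:
        return
    x = axis[lo:hi]
    out[lo:hi] += height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def render_spectrum(
    template: TaxonTemplate,
    modality: str,
    colour: str,
    grid: np.ndarray,
    seed: int | np.random.Generator,
    feature_multipliers: np.ndarray | None = None,
    **metadata,
) -> Spectrum:
    """Render one spot spectrum from a taxon template.

    Intensities are the sum of Gaussian feature profiles (height =
    relative_intensity x colour factor x optional per-feature multiplier),
    a smooth polynomial background, and heteroscedastic Gaussian noise whose
    standard deviation scales with the local noise-free intensity; the result
    is clipped at zero.  Deterministic for a fixed integer seed.
    """
    if colour not in COLOURS:
        raise ValueError(f"invalid colour {colour!r}; expected one of {COLOURS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    features = template.features(modality)
    if feature_multipliers is None:
        feature_multipliers = np.ones(len(features))
    elif len(feature_multipliers) != len(features):
        raise ValueError("one multiplier per feature is required")

    signal = np.zeros_like(grid)
    cfac = template.colour_modulation[colour]
    for feat, mult in zip(features, feature_multipliers):
        _gauss(feat.center, feat.width, grid, signal,
               feat.relative_intensity * cfac * mult)

    coeffs = template.background.get(modality, ())
    if coeffs:
        x01 = (grid - grid[0]) / max(grid[-1] - grid[0], 1.0)
        background = np.polynomial.polynomial.polyval(x01, coeffs)
        background = np.clip(background, 0.0, None)
    else:
        background = np.zeros_like(grid)

    clean = signal + background
    noise_sd = template.noise_sd.get(modality, 0.0)
    if noise_sd > 0:
        scale = noise_sd * (0.1 * clean + 0.02 * max(clean.max(), 1e-300))
        noise = rng.normal(0.0, 1.0, size=grid.shape) * scale
    else:
        noise = 0.0
    intensities = np.clip(clean + noise, 0.0, None)
    return Spectrum(
        axis=grid,
        intensities=intensities,
        modality=modality,
        taxon=template.taxon,
        colour=colour,
        signal=signal,
        **metadata,
    )


def inject_outlier(spectrum: Spectrum, scale: float) -> Spectrum:
    """Scale all feature-bearing intensities of a spot by ``scale`` (> 1).

    Emulates an anomalous ablation/acquisition event; the returned spectrum is
    flagged as a planted outlier so that downstream filter tests have ground
    truth.  When the noise-free feature component is unavailable the whole
    vector is scaled.
    """
    if scale <= 1.0:
        raise ValueError("outlier scale must be > 1")
    if spectrum.signal is not None:
        intensities = spectrum.intensities + (scale - 1.0) * spectrum.signal
        signal = spectrum.signal * scale
    else:
        intensities = spectrum.intensities * scale
        signal = None
    return replace(
        spectrum,
        intensities=np.clip(intensities, 0.0, None),
        signal=signal,
        planted_outlier=True,
    )


# ---------------------------------------------------------------------------
# Default taxon templates
# ---------------------------------------------------------------------------

def _f(center, intensity, width, label, resonance=False):
    return SpectralFeature(center, intensity, width, label, resonance)


def _libs_common(na=3.0, res=1.0):
    """LIBS features shared by all organic pellets.

    ``res`` scales the block of strongly self-absorbed resonance lines, whose
    large and irreproducible intensity is what region masking later removes.
    """
    w = LIBS_LINE_FWHM
    return [
        _f(247.86, 8.0, w, "C I 247.8"),
        _f(388.34, 5.0, 1.2, "CN 388.3"),
        _f(656.28, 4.0, w, "H I 656.3"),
        _f(568.26, na, w, "Na I 568.3"),
        _f(285.21, 2.0, w, "Mg I 285.2"),
        _f(588.995, 40.0 * res, w, "Na I 589.0", True),
        _f(589.592, 35.0 * res, w, "Na I 589.6", True),
        _f(766.49, 30.0 * res, w, "K I 766.5", True),
        _f(769.90, 28.0 * res, w, "K I 769.9", True),
        _f(393.37, 35.0 * res, w, "Ca II 393.4", True),
        _f(396.85, 30.0 * res, w, "Ca II 396.8", True),
        _f(279.55, 20.0 * res, w, "Mg II 279.6", True),
        _f(280.27, 18.0 * res, w, "Mg II 280.3", True),
    ]


def _raman_common(fatty=1.0, ch=1.0):
    """Raman bands shared by nearly all animals (fatty acids, C-H stretch)."""
    w = RAMAN_BAND_FWHM
    return [
        _f(1268.0, 3.0 * fatty, w, "fatty 1268"),
        _f(1302.0, 4.0 * fatty, w, "fatty 1302"),
        _f(1446.0, 6.0 * fatty, w, "fatty 1446"),
        _f(1656.0, 5.5 * fatty, w, "fatty 1656"),
        _f(2850.0, 10.0 * ch, 18.0, "CH 2850", True),
        _f(2885.0, 12.0 * ch, 18.0, "CH 2885", True),
        _f(2930.0, 14.0 * ch, 20.0, "CH 2930", True),
    ]


def default_templates() -> dict[str, TaxonTemplate]:
    """Taxon templates encoding the qualitative spectral inventory of the study.

    Calanoida copepods carry intense Li I lines at 610.4 and 670.8 nm and
    strong carotenoid bands at 1004/1157/1518 cm^-1; Euphausiacea show the
    1609 cm^-1 phenyl-ring band and stronger Sr/Cu emission; Parasagitta arrow
    worms are weakly mineralised (strong C2 473.6 nm and CN emission, amino
    acid bands at 755/945/486/503/3013 cm^-1); the Limacina sea snail has the
    line-richest LIBS spectrum (Ca I/II, CaOH, CaCl, Na, K, Mg from the shell)
    and feeble Raman features; all taxa share fatty-acid bands at
    1268/1302/1446/1656 cm^-1.  Relative intensities are free parameters of
    the generator, not measurements.
    """
    w = LIBS_LINE_FWHM
    wr = RAMAN_BAND_FWHM
    templates: dict[str, TaxonTemplate] = {}

    templates["Calanoida"] = TaxonTemplate(
        taxon="Calanoida",
        libs_features=_libs_common(na=3.0, res=1.0) + [
            _f(610.36, 10.0, w, "Li I 610.4"),
            _f(670.78, 14.0, w, "Li I 670.8", True),
            _f(422.67, 3.0, w, "Ca I 422.7"),
            _f(407.77, 0.4, w, "Sr II 407.8"),
        ],
        raman_features=_raman_common() + [
            _f(1004.0, 8.0, wr, "carotenoid 1004"),
            _f(1157.0, 9.0, wr, "carotenoid 1157"),
            _f(1518.0, 10.0, wr, "carotenoid 1518"),
            _f(1609.0, 0.5, wr, "phenyl 1609"),
        ],
        colour_modulation={"dark": 1.35, "medium": 1.0, "light": 0.65},
        background={LIBS: (0.4, 0.3), RAMAN: (28.0, 25.0, -40.0, 18.0, 0.0, 0.0, -5.0)},
        noise_sd={LIBS: 0.03, RAMAN: 0.08},
    )

    templates["Euphausiacea"] = TaxonTemplate(
        taxon="Euphausiacea",
        libs_features=_libs_common(na=3.5, res=1.15) + [
            _f(422.67, 6.0, w, "Ca I 422.7"),
            _f(407.77, 3.0, w, "Sr II 407.8"),
            _f(421.55, 2.0, w, "Sr II 421.6"),
            _f(324.75, 1.5, w, "Cu I 324.8"),
            _f(327.40, 1.2, w, "Cu I 327.4"),
        ],
        raman_features=_raman_common() + [
            _f(1609.0, 4.0, wr, "phenyl 1609"),
            _f(1004.0, 1.5, wr, "carotenoid 1004"),
            _f(1157.0, 1.5, wr, "carotenoid 1157"),
            _f(1518.0, 1.8, wr, "carotenoid 1518"),
        ],
        colour_modulation={"dark": 1.25, "medium": 1.0, "light": 0.75},
        background={LIBS: (0.4, 0.3), RAMAN: (30.0, 20.0, -35.0, 15.0, 0.0, 0.0, -4.0)},
        noise_sd={LIBS: 0.03, RAMAN: 0.08},
    )

    templates["Parasagitta"] = TaxonTemplate(
        taxon="Parasagitta",
        libs_features=[
            _f(247.86, 12.0, w, "C I 247.8"),
            _f(473.6, 10.0, 1.0, "C2 473.6"),
            _f(516.5, 4.0, 1.0, "C2 516.5"),
            _f(388.34, 9.0, 1.2, "CN 388.3"),
            _f(656.28, 6.0, w, "H I 656.3"),
            _f(568.26, 1.5, w, "Na I 568.3"),
            _f(422.67, 1.0, w, "Ca I 422.7"),
            _f(588.995, 16.0, w, "Na I 589.0", True),
            _f(589.592, 14.0, w, "Na I 589.6", True),
            _f(766.49, 12.0, w, "K I 766.5", True),
            _f(769.90, 11.0, w, "K I 769.9", True),
            _f(393.37, 12.0, w, "Ca II 393.4", True),
            _f(396.85, 10.0, w, "Ca II 396.8", True),
            _f(279.55, 7.0, w, "Mg II 279.6", True),
            _f(280.27, 6.0, w, "Mg II 280.3", True),
        ],
        raman_features=_raman_common() + [
            _f(755.0, 5.0, wr, "tryptophan 755"),
            _f(945.0, 4.0, wr, "valine 945"),
            _f(486.0, 3.0, 8.0, "NH2 486"),
            _f(503.0, 3.0, 8.0, "NH2 503"),
            _f(3013.0, 3.5, wr, "NH2 3013"),
        ],
        colour_modulation={"dark": 1.2, "medium": 1.0, "light": 0.8},
        background={LIBS: (0.35, 0.25), RAMAN: (26.0, 22.0, -36.0, 16.0, 0.0, 0.0, -4.0)},
        noise_sd={LIBS: 0.03, RAMAN: 0.08},
    )

    templates["Limacina"] = TaxonTemplate(
        taxon="Limacina",
        libs_features=_libs_common(na=5.0, res=1.7) + [
            _f(422.67, 12.0, w, "Ca I 422.7"),
            _f(443.50, 6.0, w, "Ca I 443.5"),
            _f(445.48, 5.0, w, "Ca I 445.5"),
            _f(317.93, 8.0, w, "Ca II 317.9"),
            _f(554.0, 6.0, 8.0, "CaOH 554"),
            _f(622.0, 5.0, 8.0, "CaOH 622"),
            _f(593.4, 4.0, 5.0, "CaCl 593"),
            _f(618.8, 3.5, 5.0, "CaCl 619"),
            _f(407.77, 2.0, w, "Sr II 407.8"),
        ],
        raman_features=[
            _f(1085.0, 2.0, wr, "carbonate 1085"),
            _f(1268.0, 0.8, wr, "fatty 1268"),
            _f(1302.0, 0.9, wr, "fatty 1302"),
            _f(1446.0, 1.5, wr, "fatty 1446"),
            _f(1656.0, 1.2, wr, "fatty 1656"),
            _f(2850.0, 3.0, 18.0, "CH 2850", True),
            _f(2885.0, 4.0, 18.0, "CH 2885", True),
            _f(2930.0, 5.0, 20.0, "CH 2930", True),
        ],
        colour_modulation={"dark": 1.2, "medium": 1.0, "light": 0.8},
        background={LIBS: (0.5, 0.4), RAMAN: (32.0, 18.0, -30.0, 12.0, 0.0, 0.0, -3.0)},
        noise_sd={LIBS: 0.03, RAMAN: 0.08},
    )

    templates["Mixed"] = TaxonTemplate(
        taxon="Mixed",
        libs_features=_libs_common(na=3.0, res=1.2) + [
            _f(610.36, 3.0, w, "Li I 610.4"),
            _f(670.78, 4.0, w, "Li I 670.8", True),
            _f(473.6, 3.0, 1.0, "C2 473.6"),
            _f(422.67, 5.0, w, "Ca I 422.7"),
            _f(407.77, 1.0, w, "Sr II 407.8"),
        ],
        raman_features=_raman_common() + [
            _f(1004.0, 4.0, wr, "carotenoid 1004"),
            _f(1157.0, 4.5, wr, "carotenoid 1157"),
            _f(1518.0, 5.0, wr, "carotenoid 1518"),
            _f(1609.0, 1.5, wr, "phenyl 1609"),
            _f(755.0, 1.5, wr, "tryptophan 755"),
        ],
        colour_modulation={"dark": 1.25, "medium": 1.0, "light": 0.75},
        background={LIBS: (0.4, 0.3), RAMAN: (28.0, 22.0, -35.0, 15.0, 0.0, 0.0, -4.0)},
        noise_sd={LIBS: 0.03, RAMAN: 0.08},
    )
    return templates


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

#: lognormal sigma of sample-level per-feature intensity multipliers.
SAMPLE_LOGNORMAL_SIGMA = 0.2
#: lognormal sigma of per-spot jitter applied to resonance/saturating features.
RESONANCE_JITTER_SIGMA = 0.6


def generate_dataset(
    design: StudyDesign,
    templates: dict[str, TaxonTemplate] | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate all spot spectra of a study plus their metadata table.

    Per sample: ``spots_per_colour`` spots for each of the three colours and
    each modality (>= 18 spot spectra per sample at the default of 3).  Each
    sample draws lognormal per-feature multipliers shared by all its spots
    (between-sample biological variance); resonance-flagged features draw an
    additional per-spot lognormal jitter.  Spots become planted outliers with
    probability ``outlier_rate``.  Bit-reproducible for a fixed seed.
    """
    if templates is None:
        templates = default_templates()
    missing = set(design.taxon_counts) - set(templates)
    if missing:
        raise ValueError(f"no template for taxa: {sorted(missing)}")

    root = np.random.SeedSequence(design.seed)
    ss_samples, ss_outlier = root.spawn(2)
    rng_outlier = np.random.default_rng(ss_outlier)

    sample_rows = []
    for taxon in design.taxon_counts:
        for _ in range(design.taxon_counts[taxon]):
            sample_rows.append(taxon)
    sample_ids = [f"S{i + 1:02d}" for i in range(len(sample_rows))]

    spectra: list[Spectrum] = []
    meta_rows = []
    for sample_seq, (sample_id, taxon) in zip(
        ss_samples.spawn(len(sample_rows)), zip(sample_ids, sample_rows)
    ):
        template = templates[taxon]
        rng_sample = np.random.default_rng(sample_seq)
        sample_mult = {
            mod: rng_sample.lognormal(
                0.0, SAMPLE_LOGNORMAL_SIGMA, size=len(template.features(mod))
            )
            for mod in MODALITIES
        }
        for modality in MODALITIES:
            grid = design.axis(modality)
            features = template.features(modality)
            res_idx = np.array(
                [i for i, f in enumerate(features) if f.resonance_flag], dtype=int
            )
            for colour in COLOURS:
                for spot in range(1, design.spots_per_colour + 1):
                    mult = sample_mult[modality].copy()
                    if res_idx.size:
                        mult[res_idx] *= rng_sample.lognormal(
                            0.0, RESONANCE_JITTER_SIGMA, size=res_idx.size
                        )
                    spec = render_spectrum(
                        template, modality, colour, grid, rng_sample,
                        feature_multipliers=mult,
                        sample_id=sample_id,
                        spot_id=f"{colour[0]}{spot}",
                    )
                    if rng_outlier.random() < design.outlier_rate:
                        spec = inject_outlier(spec, design.outlier_scale)
                    spectra.append(spec)
                    meta_rows.append(
                        {
                            "sample_id": sample_id,
                            "taxon": taxon,
                            "colour": colour,
                            "spot_id": spec.spot_id,
                            "modality": modality,
                            "planted_outlier": spec.planted_outlier,
                        }
                    )
    metadata = pd.DataFrame(meta_rows)
    return spectra, metadata


# ---------------------------------------------------------------------------
# On-disk format: wide CSV per modality + metadata TSV
# ---------------------------------------------------------------------------

def write_dataset(
    spectra: list[Spectrum], metadata: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Write one wide CSV per modality (axis column + one column per spot,
    header ``sample|colour|spot``) and a metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for modality in MODALITIES:
        specs = [s for s in spectra if s.modality == modality]
        if not specs:
            continue
        axis = specs[0].axis
        cols = {"axis": axis}
        for s in specs:
            cols[f"{s.sample_id}|{s.colour}|{s.spot_id}"] = s.intensities
        path = outdir / f"spectra_{modality.lower()}.csv"
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
        paths[modality] = path
    meta_path = outdir / "metadata.tsv"
    metadata.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    return paths


def read_dataset(outdir: str | Path) -> tuple[list[Spectrum], pd.DataFrame]:
    """Inverse of :func:`write_dataset` (the ``signal`` component is not
    persisted, so re-read spectra cannot be outlier-injected precisely)."""
    outdir = Path(outdir)
    metadata = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    lookup = {
        (r.sample_id, r.colour, r.spot_id, r.modality): bool(r.planted_outlier)
        for r in metadata.itertuples()
    }
    spectra: list[Spectrum] = []
    for modality in MODALITIES:
        path = outdir / f"spectra_{modality.lower()}.csv"
        if not path.exists():
            continue
        wide = pd.read_csv(path)
        axis = wide["axis"].to_numpy()
        taxon_of = dict(zip(metadata.sample_id, metadata.taxon))
        for col in wide.columns[1:]:
            sample_id, colour, spot_id = col.split("|")
            spectra.append(
                Spectrum(
                    axis=axis,
                    intensities=wide[col].to_numpy(),
                    modality=modality,
                    sample_id=sample_id,
                    taxon=taxon_of.get(sample_id, ""),
                    colour=colour,
                    spot_id=spot_id,
                    planted_outlier=lookup.get(
                        (sample_id, colour, spot_id, modality), False
                    ),
                )
            )
    return spectra, metadata
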