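"""Spot spectra -> analysis matrices.

The processing chain mirrors standard LIBS/Raman chemometric practice:
replicate spots of one (sample, colour, modality) group are screened for
outliers with an iterative two-sided Grubbs test on net peak intensities of a
few diagnostic lines, surviving spots are averaged, Raman spectra are
normalised to total intensity, self-absorbed resonance regions are masked
out, the three colour spectra of each sample are chained (concatenated, never
averaged) into one feature vector, vectors are stacked into per-modality
blocks, and blocks are fused by scaling each to unit Frobenius norm and
concatenating columns (low-level fusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COLOURS, LIBS, RAMAN, Spectrum

__all__ = [
    "PeakWindow",
    "MaskRegion",
    "DataBlock",
    "default_peak_windows",
    "default_mask_regions",
    "li_mask_regions",
    "integrate_peak",
    "grubbs_critical_value",
    "grubbs_outliers",
    "filter_spots",
    "average_spots",
    "normalize_total",
    "apply_mask",
    "chain_colours",
    "assemble_block",
    "fuse_blocks",
]


@dataclass(frozen=True)
class PeakWindow:
    """Integration window around one line/band, in axis units."""

    label: str
    center: float
    half_width: float
    modality: str | None = None

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")


@dataclass(frozen=True)
class MaskRegion:
    """Axis interval [lo, hi] to discard, with a human-readable reason.

    ``modality`` restricts the region to features of one modality; this
    matters for fused blocks where nm and cm^-1 positions share one table.
    """

    lo: float
    hi: float
    reason: str = ""
    modality: str | None = None

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("mask region requires lo < hi")


@dataclass
class DataBlock:
    """Samples x features matrix for one modality (or fused), with per-feature
    axis labels and mask provenance."""

    matrix: np.ndarray
    row_ids: list[str]
    feature_axis: pd.DataFrame  # columns: modality, colour, position
    block_name: str
    frobenius_norm_applied: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains missing/non-finite values")
        if len(self.row_ids) != self.matrix.shape[0]:
            raise ValueError("row_ids length must match the number of rows")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")
        if len(self.feature_axis) != self.matrix.shape[1]:
            raise ValueError("feature_axis length must match the column count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


# Grubbs screening lines: Li I 610.3, C I 247.8, Na I 568.3, Ca II 396.8 nm
# and the C2 band head at 473.6 nm.
def default_peak_windows() -> list[PeakWindow]:
    return [
        PeakWindow("Li I 610.3", 610.36, 0.5, LIBS),
        PeakWindow("C I 247.8", 247.86, 0.5, LIBS),
        PeakWindow("Na I 568.3", 568.26, 0.5, LIBS),
        PeakWindow("Ca II 396.8", 396.85, 0.5, LIBS),
        PeakWindow("C2 473.6", 473.6, 1.5, LIBS),
    ]


def default_mask_regions() -> list[MaskRegion]:
    """Self-absorbed resonance lines (LIBS) and the saturating C-H stretch
    region (Raman) discarded before decomposition."""
    regions = [
        MaskRegion(588.5, 590.1, "Na I D resonance doublet", LIBS),
        MaskRegion(765.99, 770.40, "K I resonance doublet", LIBS),
        MaskRegion(392.87, 397.35, "Ca II H&K resonance", LIBS),
        MaskRegion(279.05, 280.77, "Mg II resonance doublet", LIBS),
        MaskRegion(2780.0, 3000.0, "saturating C-H stretch", RAMAN),
    ]
    return regions


def li_mask_regions(half_width: float = 0.5) -> list[MaskRegion]:
    return [
        MaskRegion(610.36 - half_width, 610.36 + half_width, "Li I 610.4", LIBS),
        MaskRegion(670.78 - half_width, 670.78 + half_width, "Li I 670.8", LIBS),
    ]


def integrate_peak(spectrum: Spectrum, window: PeakWindow) -> float:
    """Net peak area: trapezoidal integral over the window after subtracting
    the straight line joining the window's endpoint intensities.

    Robust to one-pixel wavelength jitter, exact (zero) for any purely linear
    baseline; may be negative on noise-only windows.
    """
    axis = spectrum.axis
    if not axis[0] <= window.center <= axis[-1]:
        raise ValueError(
            f"window {window.label!r} centre {window.center} outside axis range"
        )
    lo = np.searchsorted(axis, window.center - window.half_width)
    hi = np.searchsorted(axis, window.center + window.half_width, side="right")
    if hi - lo < 3:
        # coarse grid: widen to the 3 grid points nearest the centre
        mid = int(np.searchsorted(axis, window.center))
        lo = max(mid - 1, 0)
        hi = min(lo + 3, len(axis))
        lo = hi - 3
    x = axis[lo:hi]
    y = spectrum.intensities[lo:hi]
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return float(np.trapezoid(y - baseline, x))


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t formula."""
    if n < 3:
        raise ValueError("Grubbs critical value requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs test; returns a boolean keep-mask.

    Repeatedly removes the point furthest from the mean while
    G = max|x_i - mean| / sd exceeds the critical value.  The test needs at
    least 3 remaining points to run, so no removal happens below n = 3 and
    at least 2 points always survive.  Zero-variance input is kept whole.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    keep = np.ones(x.size, dtype=bool)
    while keep.sum() >= 3:
        xs = x[keep]
        mean = xs.mean()
        sd = xs.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(xs - mean)
        g = dev.max() / sd
        if g <= grubbs_critical_value(xs.size, alpha):
            break
        worst = np.flatnonzero(keep)[int(np.argmax(dev))]
        keep[worst] = False
    return keep


def filter_spots(
    spots: list[Spectrum],
    windows: list[PeakWindow] | None = None,
    alpha: float = 0.05,
) -> list[Spectrum]:
    """Sequential Grubbs screening of replicate spots.

    For each window in order, the net peak areas of the currently kept spots
    are Grubbs-tested; a spot removed at any stage stays removed.  At least
    one spot always survives.
    """
    if not spots:
        raise ValueError("no spots given")
    first = spots[0]
    for s in spots[1:]:
        if s.modality != first.modality:
            raise ValueError("mixed modalities in filter_spots input")
        if (s.sample_id, s.colour) != (first.sample_id, first.colour):
            raise ValueError("spots must share sample and colour")
        if not np.array_equal(s.axis, first.axis):
            raise ValueError("spots must share the axis")
    if windows is None:
        windows = [w for w in default_peak_windows() if w.modality in (None, first.modality)]
    kept = list(spots)
    for window in windows:
        if window.modality not in (None, first.modality):
            continue
        if len(kept) < 3:
            break
        areas = [integrate_peak(s, window) for s in kept]
        mask = grubbs_outliers(areas, alpha)
        kept = [s for s, k in zip(kept, mask) if k]
    return kept


def average_spots(spots: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spots."""
    if not spots:
        raise ValueError("no spots to average")
    first = spots[0]
    for s in spots[1:]:
        if not np.array_equal(s.axis, first.axis):
            raise ValueError("axis mismatch in average_spots")
        if (s.sample_id, s.colour, s.modality) != (
            first.sample_id,
            first.colour,
            first.modality,
        ):
            raise ValueError("spots must share (sample, colour, modality)")
    mean = np.mean([s.intensities for s in spots], axis=0)
    return Spectrum(
        axis=first.axis,
        intensities=mean,
        modality=first.modality,
        sample_id=first.sample_id,
        taxon=first.taxon,
        colour=first.colour,
        spot_id="mean",
    )


def normalize_total(spectrum: Spectrum) -> Spectrum:
    """Divide by the total spectral intensity; the output sums to one.

    Idempotent and invariant to positive rescaling of the input.
    """
    total = float(spectrum.intensities.sum())
    if total <= 0:
        raise ValueError("total intensity must be > 0 for normalisation")
    out = Spectrum(
        axis=spectrum.axis,
        intensities=spectrum.intensities / total,
        modality=spectrum.modality,
        sample_id=spectrum.sample_id,
        taxon=spectrum.taxon,
        colour=spectrum.colour,
        spot_id=spectrum.spot_id,
        planted_outlier=spectrum.planted_outlier,
    )
    return out


def _region_mask(positions: np.ndarray, modalities, regions, modality=None):
    """Boolean drop-mask over features covered by any region."""
    drop = np.zeros(len(positions), dtype=bool)
    for region in regions:
        hit = (positions >= region.lo) & (positions <= region.hi)
        if region.modality is not None:
            hit &= np.asarray(modalities) == region.modality
        drop |= hit
    return drop


def apply_mask(obj, regions: list[MaskRegion]):
    """Drop all features whose axis position falls inside any region.

    Accepts a :class:`Spectrum` or a :class:`DataBlock`; block provenance
    records what was removed.  An empty region list is the identity; removing
    every feature is an error.
    """
    if not regions:
        return obj
    if isinstance(obj, Spectrum):
        drop = _region_mask(obj.axis, [obj.modality] * len(obj.axis), regions)
        if drop.all():
            raise ValueError("mask regions cover the entire axis")
        return Spectrum(
            axis=obj.axis[~drop],
            intensities=obj.intensities[~drop],
            modality=obj.modality,
            sample_id=obj.sample_id,
            taxon=obj.taxon,
            colour=obj.colour,
            spot_id=obj.spot_id,
            planted_outlier=obj.planted_outlier,
        )
    if isinstance(obj, DataBlock):
        positions = obj.feature_axis["position"].to_numpy()
        modalities = obj.feature_axis["modality"].to_numpy()
        drop = _region_mask(positions, modalities, regions)
        if drop.all():
            raise ValueError("mask regions cover the entire feature axis")
        note = "; ".join(
            f"masked [{r.lo}, {r.hi}] ({r.reason or 'unspecified'}): "
            f"{int(((positions >= r.lo) & (positions <= r.hi) & ((modalities == r.modality) if r.modality else True)).sum())} features"
            for r in regions
        )
        return DataBlock(
            matrix=obj.matrix[:, ~drop],
            row_ids=list(obj.row_ids),
            feature_axis=obj.feature_axis.loc[~drop].reset_index(drop=True),
            block_name=obj.block_name,
            frobenius_norm_applied=obj.frobenius_norm_applied,
            provenance=obj.provenance + [note],
        )
    raise TypeError("apply_mask expects a Spectrum or DataBlock")


def chain_colours(
    dark: Spectrum, medium: Spectrum, light: Spectrum
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate one sample's three colour spectra in the fixed order
    dark || medium || light; returns the feature vector and its per-feature
    (modality, colour, position) metadata."""
    triple = {"dark": dark, "medium": medium, "light": light}
    for colour, spec in triple.items():
        if spec is None:
            raise ValueError(f"missing colour {colour!r}")
        if spec.colour and spec.colour != colour:
            raise ValueError(f"spectrum in slot {colour!r} is labelled {spec.colour!r}")
    ref = triple["dark"]
    for spec in (medium, light):
        if spec.modality != ref.modality or spec.sample_id != ref.sample_id:
            raise ValueError("chained spectra must share sample and modality")
        if not np.array_equal(spec.axis, ref.axis):
            raise ValueError("chained spectra must share the axis")
    values = np.concatenate([triple[c].intensities for c in COLOURS])
    features = pd.DataFrame(
        {
            "modality": ref.modality,
            "colour": np.repeat(list(COLOURS), len(ref.axis)),
            "position": np.tile(ref.axis, 3),
        }
    )
    return values, features


def assemble_block(
    vectors: list[tuple[str, np.ndarray]],
    feature_axis: pd.DataFrame,
    block_name: str,
) -> DataBlock:
    """Stack per-sample chained vectors into a samples x features block."""
    if not vectors:
        raise ValueError("no vectors to assemble")
    ids = [v[0] for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    lengths = {len(v[1]) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("vector length mismatch")
    if lengths.pop() != len(feature_axis):
        raise ValueError("feature_axis length mismatch")
    matrix = np.vstack([np.asarray(v[1], dtype=float) for v in vectors])
    return DataBlock(
        matrix=matrix,
        row_ids=ids,
        feature_axis=feature_axis.reset_index(drop=True),
        block_name=block_name,
    )


def fuse_blocks(blocks: list[DataBlock]) -> DataBlock:
    """Low-level fusion: divide each block by its Frobenius norm and chain
    the columns in the given order; each scaled sub-block then has unit
    Frobenius norm."""
    if not blocks:
        raise ValueError("no blocks to fuse")
    ref_ids = blocks[0].row_ids
    scaled = []
    feats = []
    for block in blocks:
        if block.row_ids != ref_ids:
            raise ValueError("blocks must share row_ids and their order")
        norm = np.linalg.norm(block.matrix)
        if norm == 0:
            raise ValueError(f"block {block.block_name!r} has zero Frobenius norm")
        scaled.append(block.matrix / norm)
        fa = block.feature_axis.copy()
        fa["block"] = block.block_name
        feats.append(fa)
    return DataBlock(
        matrix=np.hstack(scaled),
        row_ids=list(ref_ids),
        feature_axis=pd.concat(feats, ignore_index=True),
        block_name="+".join(b.block_name for b in blocks),
        frobenius_norm_applied=True,
        provenance=sum((b.provenance for b in blocks), []),
    )
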