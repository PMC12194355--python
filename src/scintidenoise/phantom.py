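"""Synthetic planar bone-scintigraphy phantoms and low-count acquisition.

Planar scintigraphy pixels are photon counts, so a noise-free "activity
map" of expected counts per pixel (at the full acquisition time) fully
determines the acquisition statistics: a pixel acquired for a fraction
``f`` of the standard time is Poisson with mean ``f`` times the map value.
Shortening the acquisition is therefore statistically identical to
binomial thinning of the full-dose count image — each recorded photon is
kept independently with probability ``f`` — which is how paired low/full
dose images sharing the same anatomy and correlated noise are produced
here, mirroring a same-patient same-session shortened-time protocol.

Anatomy is procedural: parametric ellipses, arcs and bands sketch a
thorax (spine column plus rib arcs) or a pelvis (iliac wings, sacrum,
optional bladder hot spot), with per-subject jitter drawn from the
subject seed. No atlas or external data is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, DomainError

REGIONS = ("pelvis", "thorax")
VIEWS = ("anterior", "posterior")

#: acquisition-time fractions of the dose-reduction protocol
PROTOCOL_FRACTIONS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
#: the low-dose subset used as network inputs
LOW_DOSE_FRACTIONS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def protocol_pair_count(n_subjects: int, n_views: int = 2,
                        n_low_fractions: int = len(LOW_DOSE_FRACTIONS),
                        n_regions: int = 1) -> int:
    """Number of (low, full) pairs the protocol yields per region block."""
    return n_subjects * n_views * n_low_fractions * n_regions


@dataclass(frozen=True)
class Lesion:
    """Focal hot spot: radially decaying uptake added to the activity map."""
    row: float
    col: float
    radius: float
    intensity: float  # peak added rate, in units of background_rate


@dataclass(frozen=True)
class PhantomSpec:
    region: str
    image_size: tuple[int, int] = (64, 64)
    background_rate: float = 10.0
    bone_rate_scale: float = 5.0
    lesions: tuple[Lesion, ...] = ()
    subject_seed: int = 0

    def validate(self, divisor: int = 4) -> None:
        if self.region not in REGIONS:
            raise ConfigurationError(
                f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if self.bone_rate_scale < 1:
            raise ConfigurationError("bone_rate_scale must be >= 1")
        for les in self.lesions:
            if les.radius <= 0:
                raise ConfigurationError("lesion radius must be > 0")
        h, w = self.image_size
        if h % divisor or w % divisor:
            raise ConfigurationError(
                f"image_size {self.image_size} must be divisible by {divisor} "
                "(encoder downsampling stages)")


@dataclass
class ActivityMap:
    """Noise-free expected counts per pixel at full acquisition time."""
    values: np.ndarray
    region: str
    spec: PhantomSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("activity map must be finite and nonnegative")


@dataclass
class CountImage:
    counts: np.ndarray
    dose_fraction: float
    region: str
    view: str = "anterior"
    subject_id: str = ""
    seed_used: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integer")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


# --------------------------------------------------------------------------
# procedural anatomy

def _thorax_template(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Spine column with vertebral modulation plus lateral rib arcs."""
    rr, cc = np.mgrid[0:h, 0:w]
    y = rr / (h - 1)
    x = cc / (w - 1)
    t = np.zeros((h, w))

    cx = 0.5 + rng.uniform(-0.03, 0.03)
    half_width = 0.045 * (1 + rng.uniform(-0.15, 0.15))
    spine = (np.abs(x - cx) < half_width) & (y > 0.08) & (y < 0.95)
    # vertebral bodies: periodic brightness modulation along the column
    n_vert = 9 + int(rng.integers(0, 3))
    modulation = 0.75 + 0.25 * np.cos(2 * np.pi * n_vert * y)
    t[spine] = np.maximum(t[spine], modulation[spine])

    n_ribs = 7 + int(rng.integers(0, 3))
    for k in range(n_ribs):
        yc = 0.12 + 0.08 * k + rng.uniform(-0.01, 0.01)
        a = 0.42 * (1 + rng.uniform(-0.08, 0.08))   # lateral semi-axis
        b = 0.09 * (1 + rng.uniform(-0.15, 0.15))   # vertical semi-axis
        d = ((x - cx) / a) ** 2 + ((y - yc - b) / b) ** 2
        arc = (np.abs(d - 1.0) < 0.16) & (y < yc + b) & (np.abs(x - cx) > half_width)
        t[arc] = np.maximum(t[arc], 0.8)
    return t


def _pelvis_template(h: int, w: int, rng: np.random.Generator,
                     include_bladder: bool = True) -> np.ndarray:
    """Iliac-wing annuli, sacrum wedge, optional bladder hot spot."""
    rr, cc = np.mgrid[0:h, 0:w]
    y = rr / (h - 1)
    x = cc / (w - 1)
    t = np.zeros((h, w))

    cx = 0.5 + rng.uniform(-0.02, 0.02)
    for side in (-1.0, 1.0):
        wx = cx + side * (0.24 + rng.uniform(-0.02, 0.02))
        wy = 0.35 + rng.uniform(-0.03, 0.03)
        a = 0.17 * (1 + rng.uniform(-0.1, 0.1))
        b = 0.22 * (1 + rng.uniform(-0.1, 0.1))
        d = ((x - wx) / a) ** 2 + ((y - wy) / b) ** 2
        ring = np.abs(d - 1.0) < 0.45
        t[ring] = np.maximum(t[ring], 1.0)

    # sacrum: central wedge narrowing toward the bottom
    top, bottom = 0.30, 0.72
    in_y = (y >= top) & (y <= bottom)
    width = 0.14 * (1 - 0.75 * (y - top) / (bottom - top))
    wedge = in_y & (np.abs(x - cx) < width)
    t[wedge] = np.maximum(t[wedge], 0.9)

    if include_bladder:
        bx = cx + rng.uniform(-0.02, 0.02)
        by = 0.82 + rng.uniform(-0.02, 0.02)
        r2 = ((x - bx) ** 2 + (y - by) ** 2) / (0.06 ** 2)
        t = np.maximum(t, 1.2 * np.exp(-0.5 * r2))
    return t


def generate_activity_map(spec: PhantomSpec) -> ActivityMap:
    """Deterministic, smooth activity map for one synthetic subject.

    Skeletal structures emit at ``background_rate * bone_rate_scale``;
    soft tissue at ``background_rate``; lesions add Gaussian-profile hot
    spots with peak ``intensity * background_rate``.
    """
    spec.validate()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.subject_seed)
    if spec.region == "thorax":
        template = _thorax_template(h, w, rng)
    else:
        template = _pelvis_template(h, w, rng)
    template = ndimage.gaussian_filter(template, sigma=1.2)

    values = spec.background_rate * (
        1.0 + (spec.bone_rate_scale - 1.0) * template)
    rr, cc = np.mgrid[0:h, 0:w]
    for les in spec.lesions:
        r2 = ((rr - les.row) ** 2 + (cc - les.col) ** 2) / (les.radius / 2.0) ** 2
        values = values + les.intensity * spec.background_rate * np.exp(-0.5 * r2)
    return ActivityMap(values=values, region=spec.region, spec=spec)


# --------------------------------------------------------------------------
# counting statistics

def acquire_counts(activity: ActivityMap, dose_fraction: float, seed: int, *,
                   view: str = "anterior", subject_id: str = "") -> CountImage:
    """Poisson acquisition at a fraction of the standard acquisition time."""
    if not 0.0 < dose_fraction <= 1.0:
        raise DomainError(f"dose_fraction must be in (0, 1], got {dose_fraction}")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(activity.values * dose_fraction).astype(np.int64)
    return CountImage(counts=counts, dose_fraction=float(dose_fraction),
                      region=activity.region, view=view,
                      subject_id=subject_id, seed_used=int(seed))


def thin_counts(full: CountImage, fraction: float, seed: int) -> CountImage:
    """Binomial thinning: keep each recorded photon with probability ``fraction``.

    This is the exact count-level realization of shortening a Poisson
    acquisition, and guarantees the thinned image is pixelwise <= its
    full-dose parent (shared anatomy, correlated noise).
    """
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction must be in (0, 1], got {fraction}")
    if full.dose_fraction != 1.0:
        raise DomainError("thin_counts requires a full-dose (fraction 1.0) parent")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(full.counts, fraction).astype(np.int64)
    return CountImage(counts=counts, dose_fraction=float(fraction),
                      region=full.region, view=full.view,
                      subject_id=full.subject_id, seed_used=int(seed))


@dataclass
class PointSourceResult:
    """Observed totals per fraction and the through-origin linearity fit."""
    table: pd.DataFrame     # columns: fraction, observed_total_counts
    slope: float            # least-squares slope through the origin
    r_squared: float


def simulate_point_source(total_mean_counts: float, fractions: list[float],
                          seed: int, *, image_size: tuple[int, int] = (64, 64),
                          kernel_sigma: float = 2.0) -> PointSourceResult:
    """Count-linearity check with a Gaussian-blurred point source.

    A point kernel (collimator-blur sigma ``kernel_sigma`` px) scaled to
    ``total_mean_counts`` is acquired at each fraction; observed totals are
    fitted against fraction by least squares through the origin.
    """
    if len(fractions) == 0:
        raise DomainError("fractions list must be non-empty")
    if total_mean_counts <= 0:
        raise DomainError("total_mean_counts must be > 0")
    h, w = image_size
    impulse = np.zeros((h, w))
    impulse[h // 2, w // 2] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=kernel_sigma)
    values = kernel / kernel.sum() * float(total_mean_counts)
    amap = ActivityMap(values=values, region="pelvis",
                       spec=PhantomSpec(region="pelvis", image_size=(h, w)))

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(fractions)) % (2 ** 31)
    totals = []
    for frac, s in zip(fractions, seeds):
        img = acquire_counts(amap, frac, int(s))
        totals.append(int(img.counts.sum()))
    table = pd.DataFrame({"fraction": list(fractions),
                          "observed_total_counts": totals})
    f = table["fraction"].to_numpy(dtype=float)
    t = table["observed_total_counts"].to_numpy(dtype=float)
    slope = float((f * t).sum() / (f * f).sum())
    ss_res = float(((t - slope * f) ** 2).sum())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PointSourceResult(table=table, slope=slope, r_squared=r2)


# --------------------------------------------------------------------------
# paired dataset on disk

MANIFEST_COLUMNS = ("subject_id", "region", "view", "dose_fraction",
                    "path_low", "path_full", "count_scale", "seed")


def _write_png(path: Path, counts: np.ndarray, scale: float) -> None:
    arr = np.clip(np.rint(counts * scale), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _subject_lesions(rng: np.random.Generator, h: int, w: int) -> tuple:
    lesions = []
    for _ in range(int(rng.integers(0, 3))):
        lesions.append(Lesion(row=float(rng.uniform(0.15 * h, 0.85 * h)),
                              col=float(rng.uniform(0.15 * w, 0.85 * w)),
                              radius=float(rng.uniform(0.04, 0.09) * min(h, w)),
                              intensity=float(rng.uniform(2.0, 4.0))))
    return tuple(lesions)


def generate_paired_dataset(n_subjects: int, regions: list[str],
                            fractions: list[float], base_seed: int,
                            out_dir: str | Path, *,
                            image_size: tuple[int, int] = (64, 64),
                            background_rate: float = 10.0,
                            bone_rate_scale: float = 5.0,
                            independent_redraw: bool = False) -> pd.DataFrame:
    """Write paired low/full-dose PNGs plus a manifest CSV.

    For each subject x region x view one full-dose image is acquired; every
    low-dose fraction is derived from that same acquisition by binomial
    thinning (or by an independent Poisson re-draw when
    ``independent_redraw`` is set). Counts are rescaled to 8-bit by a scale
    shared within each pair (the full-dose maximum), recorded in the
    manifest. Fully reproducible from ``base_seed``.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    for region in regions:
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rows = []
    for subj in range(n_subjects):
        subject_seed = int(base_seed) + subj
        subject_id = f"s{subj:03d}"
        lesion_rng = np.random.default_rng(np.random.SeedSequence(
            [int(base_seed), subj, 999]))
        for ri, region in enumerate(regions):
            spec = PhantomSpec(region=region, image_size=image_size,
                               background_rate=background_rate,
                               bone_rate_scale=bone_rate_scale,
                               lesions=_subject_lesions(lesion_rng, *image_size),
                               subject_seed=subject_seed)
            amap = generate_activity_map(spec)
            for vi, view in enumerate(VIEWS):
                view_values = amap.values if view == "anterior" \
                    else np.fliplr(amap.values)
                view_map = ActivityMap(values=view_values, region=region,
                                       spec=spec)
                seeds = np.random.SeedSequence(
                    [int(base_seed), subj, ri, vi]).generate_state(
                        1 + len(fractions)) % (2 ** 31)
                full = acquire_counts(view_map, 1.0, int(seeds[0]),
                                      view=view, subject_id=subject_id)
                peak = int(full.counts.max())
                scale = 255.0 / peak if peak > 0 else 1.0
                full_name = f"{subject_id}_{region}_{view}_full.png"
                _write_png(out_dir / full_name, full.counts, scale)
                for fi, frac in enumerate(fractions):
                    seed = int(seeds[1 + fi])
                    if independent_redraw:
                        low = acquire_counts(view_map, frac, seed,
                                             view=view, subject_id=subject_id)
                    else:
                        low = thin_counts(full, frac, seed)
                    low_name = (f"{subject_id}_{region}_{view}"
                                f"_f{int(round(frac * 100)):03d}.png")
                    _write_png(out_dir / low_name, low.counts, scale)
                    rows.append({"subject_id": subject_id, "region": region,
                                 "view": view, "dose_fraction": float(frac),
                                 "path_low": low_name, "path_full": full_name,
                                 "count_scale": scale, "seed": seed})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    manifest.attrs["path"] = str(out_dir / "manifest.csv")
    return manifest
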