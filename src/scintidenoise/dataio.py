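"""Image/manifest I/O, intensity normalization, pairing, splitting, batching.

The canonical on-disk format is 8-bit grayscale PNG (the PSNR convention
assumes an 8-bit peak of 255); a thin adapter reads single-frame DICOM.
Values are mapped to [0, 1] by dividing by 255. Because low-dose images
carry proportionally fewer counts, they are dimmer on the shared per-pair
count scale; pair building therefore offers per-image max normalization
(the default, emulating the standard clinical intensity normalization that
removes administered-activity variability from the model input) alongside
a mode that keeps the stored intensities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, FormatError, PairingError


@dataclass
class NormalizedImage:
    """2-D image with values in [0, 1]."""
    values: np.ndarray
    dose_fraction: float = 1.0
    source_path: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("NormalizedImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("NormalizedImage values must be finite")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("NormalizedImage values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DosePair:
    """Supervised training example: low-dose input, full-dose target."""
    low: NormalizedImage
    full: NormalizedImage
    subject_id: str = ""
    region: str = ""
    view: str = ""

    def __post_init__(self):
        if self.low.shape != self.full.shape:
            raise PairingError(
                f"low/full dimension mismatch: {self.low.shape} vs "
                f"{self.full.shape} (subject {self.subject_id!r})")
        if not self.low.dose_fraction < 1.0:
            raise PairingError("low image must have dose_fraction < 1.0")
        if self.full.dose_fraction != 1.0:
            raise PairingError("full image must have dose_fraction = 1.0")

    @property
    def pair_id(self) -> str:
        return (f"{self.subject_id}:{self.region}:{self.view}"
                f":{self.low.dose_fraction:g}")


def read_grayscale(path: str | Path, *, dicom: bool = False) -> NormalizedImage:
    """Read an 8-bit grayscale PNG (or single-frame DICOM) into [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if dicom:
        import pydicom
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise FormatError(f"{path}: only single-frame 2-D DICOM supported")
        peak = float(2 ** int(ds.BitsStored) - 1)
        return NormalizedImage(arr.astype(np.float64) / peak,
                               source_path=str(path))
    img = Image.open(path)
    if img.mode != "L":
        raise FormatError(
            f"{path}: expected 8-bit grayscale (mode 'L'), got mode "
            f"{img.mode!r}")
    arr = np.asarray(img, dtype=np.float64)
    return NormalizedImage(arr / 255.0, source_path=str(path))


def write_grayscale(path: str | Path, image: NormalizedImage) -> None:
    """Write a [0, 1] image as 8-bit grayscale PNG (round to nearest)."""
    arr = np.clip(np.rint(image.values * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def _renormalize(img: NormalizedImage, mode: str) -> NormalizedImage:
    if mode == "stored":
        return img
    if mode == "per_image_max":
        peak = img.values.max()
        vals = img.values / peak if peak > 0 else img.values
        return NormalizedImage(vals, dose_fraction=img.dose_fraction,
                               source_path=img.source_path)
    raise ConfigurationError(f"unknown intensity mode {mode!r}")


def build_pairs(manifest: pd.DataFrame | str | Path, *,
                root: str | Path | None = None,
                intensity_mode: str = "per_image_max") -> list[DosePair]:
    """Materialize one :class:`DosePair` per manifest row.

    ``root`` resolves relative manifest paths; it defaults to the manifest's
    own directory when a path is given, else the current directory.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        df = pd.read_csv(manifest_path)
        root = Path(root) if root is not None else manifest_path.parent
    else:
        df = manifest
        if root is None:
            root = Path(df.attrs["path"]).parent if "path" in df.attrs else Path(".")
        root = Path(root)

    pairs: list[DosePair] = []
    full_cache: dict[str, NormalizedImage] = {}
    for idx, row in df.iterrows():
        try:
            low = read_grayscale(root / row["path_low"])
            if row["path_full"] not in full_cache:
                full_cache[row["path_full"]] = read_grayscale(
                    root / row["path_full"])
            full = full_cache[row["path_full"]]
        except FileNotFoundError as exc:
            raise PairingError(f"manifest row {idx}: {exc}") from exc
        low.dose_fraction = float(row["dose_fraction"])
        if low.shape != full.shape:
            raise PairingError(
                f"manifest row {idx}: dimension mismatch "
                f"{low.shape} vs {full.shape}")
        pairs.append(DosePair(low=_renormalize(low, intensity_mode),
                              full=_renormalize(full, intensity_mode),
                              subject_id=str(row["subject_id"]),
                              region=str(row["region"]),
                              view=str(row["view"])))
    return pairs


# --------------------------------------------------------------------------
# splitting

@dataclass
class SplitAssignment:
    train: list[str]
    validation: list[str]
    test: list[str]
    ratios: tuple[float, float, float]
    seed: int
    group_by_subject: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train": self.train, "validation": self.validation,
            "test": self.test, "ratios": list(self.ratios),
            "seed": self.seed, "group_by_subject": self.group_by_subject,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(train=d["train"], validation=d["validation"],
                   test=d["test"], ratios=tuple(d["ratios"]),
                   seed=d["seed"], group_by_subject=d["group_by_subject"])

    def split_of(self, pair_id: str) -> str:
        for name in ("train", "validation", "test"):
            if pair_id in getattr(self, name):
                return name
        raise KeyError(pair_id)


def _target_counts(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to three splits."""
    raw = [r * n for r in ratios]
    counts = [math.floor(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def split_dataset(pairs: list[DosePair],
                  ratios: tuple[float, float, float] = (0.75, 0.15, 0.10),
                  seed: int = 0, *,
                  group_by_subject: bool = True) -> SplitAssignment:
    """Random train/validation/test partition of dose pairs.

    With subject grouping (the default) every pair of a subject lands in
    the same split, preventing anatomy leakage between train and test;
    subjects are dealt greedily to whichever split is furthest below its
    target pair count. Without grouping the realized sizes match the
    ratios exactly up to apportionment (within one item).
    """
    if not pairs:
        raise ConfigurationError("cannot split an empty pair list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    ids = [p.pair_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("pair ids are not unique")

    buckets: tuple[list[str], list[str], list[str]] = ([], [], [])
    if group_by_subject:
        subjects = sorted({p.subject_id for p in pairs})
        order = rng.permutation(len(subjects))
        per_subject = {s: [p.pair_id for p in pairs if p.subject_id == s]
                       for s in subjects}
        targets = [r * len(pairs) for r in ratios]
        filled = [0.0, 0.0, 0.0]
        for si in order:
            sid = subjects[si]
            deficits = [(targets[i] - filled[i]) / max(targets[i], 1e-12)
                        if ratios[i] > 0 else -np.inf for i in range(3)]
            k = int(np.argmax(deficits))
            buckets[k].extend(per_subject[sid])
            filled[k] += len(per_subject[sid])
    else:
        order = rng.permutation(len(ids))
        counts = _target_counts(len(ids), ratios)
        shuffled = [ids[i] for i in order]
        buckets[0].extend(shuffled[:counts[0]])
        buckets[1].extend(shuffled[counts[0]:counts[0] + counts[1]])
        buckets[2].extend(shuffled[counts[0] + counts[1]:])
    return SplitAssignment(train=buckets[0], validation=buckets[1],
                           test=buckets[2], ratios=tuple(ratios),
                           seed=int(seed), group_by_subject=group_by_subject)


# --------------------------------------------------------------------------
# batching

@dataclass
class BatchPlan:
    """Full mini-batches for one epoch plus the randomly excluded remainder."""
    batches: list[list]
    excluded: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.batches)


def make_batches(items: list, batch_size: int = 16, seed: int = 0) -> BatchPlan:
    """Shuffle items into full batches, dropping the remainder at random.

    Mirrors a training protocol in which the dataset size must be divisible
    by the batch size: the ``len(items) mod batch_size`` leftover items are
    excluded for this epoch (re-drawn per epoch by varying ``seed``).
    """
    if batch_size < 1:
        raise ConfigurationError("batch_size must be >= 1")
    if batch_size > len(items):
        raise ConfigurationError(
            f"batch_size {batch_size} exceeds number of items {len(items)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_keep = (len(items) // batch_size) * batch_size
    kept, dropped = order[:n_keep], order[n_keep:]
    batches = [[items[i] for i in kept[b:b + batch_size]]
               for b in range(0, n_keep, batch_size)]
    return BatchPlan(batches=batches, excluded=[items[i] for i in dropped])
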