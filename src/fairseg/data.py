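"""Synthetic radiograph-like segmentation data with controllable subgroup disparity.

This module generates grayscale image / integer mask pairs whose appearance
(noise level, contrast) depends on the race-gender subgroup of the simulated
patient, so that a model trained naively exhibits measurable performance
disparity between subgroups — the phenomenon the rest of the package is built
to quantify and mitigate.  It also bundles the demographic fixture tables of
a real multi-site hip/knee radiograph cohort (761 hip and 707 knee patients
across five acquisition sites A-E) so that federated partitions reproduce a
realistic non-IID site structure.

Anatomy is emulated, not imitated: each mask contains C=6 foreground classes
drawn as three left/right pairs of elliptical structures (a large "head", an
elongated "shaft" capsule and a small "joint space"), mirroring the paired
left/right layout of hip radiograph annotations without any claim of
anatomical realism.

Difficulty has two axes:

* a *group-level* appearance shift (per-group noise SD and contrast) that
  induces unfairness between subgroups, and
* a *per-sample* multiplicative noise jitter that creates a within-group
  difficulty signal for curriculum schedulers to exploit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .groups import GROUP_ORDER, SITES, SPLITS, GroupKey, substream

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """One image/mask pair with its demographic and partition labels."""

    sample_id: str
    image: np.ndarray  # H x W float in [0, 1]
    mask: np.ndarray  # H x W uint8 labels in {0..C}, 0 = background
    group: GroupKey
    site: str | None = None  # one of SITES once assigned
    split: str | None = None  # one of SPLITS once assigned

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


@dataclass(frozen=True)
class GroupAppearance:
    """Appearance parameters for one subgroup (the disparity dial)."""

    noise_sd: float = 0.06
    contrast: float = 1.0
    blur: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")


def default_group_appearance() -> dict[GroupKey, GroupAppearance]:
    """Baseline study conditions: Black subgroups get noisier, lower-contrast
    images than White subgroups.  The gap is deliberately moderate — combined
    with cohort-proportioned under-representation (see the benchmark module)
    it induces a baseline fairness skew that training strategies can
    mitigate, rather than an irreducible appearance ceiling."""
    out: dict[GroupKey, GroupAppearance] = {}
    for g in GROUP_ORDER:
        if g.race == "Black":
            out[g] = GroupAppearance(noise_sd=0.16, contrast=0.85)
        else:
            out[g] = GroupAppearance(noise_sd=0.08, contrast=1.0)
    return out


@dataclass
class DemographicTable:
    """Counts of patients per (race-gender group, acquisition site)."""

    name: str
    counts: dict[tuple[GroupKey, str], int] = field(default_factory=dict)

    def __post_init__(self):
        for (g, s), c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for ({g.code}, {s})")
            if s not in SITES:
                raise ValueError(f"unknown site {s!r}")

    def cell(self, group: GroupKey, site: str) -> int:
        return self.counts.get((group, site), 0)

    def group_total(self, group: GroupKey) -> int:
        return sum(c for (g, _), c in self.counts.items() if g == group)

    def site_total(self, site: str) -> int:
        return sum(c for (_, s), c in self.counts.items() if s == site)

    def attribute_total(self, race: str | None = None, gender: str | None = None) -> int:
        tot = 0
        for (g, _), c in self.counts.items():
            if race is not None and g.race != race:
                continue
            if gender is not None and g.gender != gender:
                continue
            tot += c
        return tot

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"race": g.race, "gender": g.gender, "site": s, "count": c}
            for (g, s), c in sorted(
                self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1])
            )
        ]
        return pd.DataFrame(rows, columns=["race", "gender", "site", "count"])

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "DemographicTable":
        counts = {}
        for row in frame.itertuples(index=False):
            key = (GroupKey(row.race, row.gender), row.site)
            counts[key] = counts.get(key, 0) + int(row.count)
        return cls(name=name, counts=counts)


@dataclass
class GenerationSpec:
    """Everything needed to render a dataset deterministically."""

    n_samples: int | None = None
    fixture: str | None = None  # "hip" or "knee"; overrides n_samples
    image_size: tuple[int, int] = (96, 96)
    n_foreground_classes: int = 6
    group_appearance: dict[GroupKey, GroupAppearance] = field(
        default_factory=default_group_appearance
    )
    jitter_range: tuple[float, float] = (0.6, 1.4)
    site_table: DemographicTable | None = None
    group_counts: dict[GroupKey, int] | None = None  # explicit per-group sizes
    seed: int = 0

    def __post_init__(self):
        if self.n_foreground_classes < 1:
            raise ValueError("need at least one foreground class")
        if self.n_foreground_classes % 2 != 0:
            raise ValueError("foreground classes come in left/right pairs; use an even C")
        if not (0 < self.jitter_range[0] <= self.jitter_range[1]):
            raise ValueError("jitter range must satisfy 0 < lo <= hi")


# ---------------------------------------------------------------------------
# Demographic fixtures
# ---------------------------------------------------------------------------

FIXTURE_FILES = {"hip": "hip_sites.csv", "knee": "knee_sites.csv"}


def build_demographic_fixture(dataset_name: str) -> DemographicTable:
    """Load the bundled per-site demographic table for ``hip`` or ``knee``.

    The tables reproduce the site-level race-gender counts of the cohort the
    package emulates (hip: 761 patients, knee: 707, five sites A-E).
    """
    if dataset_name not in FIXTURE_FILES:
        raise ValueError(
            f"unknown dataset {dataset_name!r}; expected one of {sorted(FIXTURE_FILES)}"
        )
    ref = resources.files("fairseg.fixtures") / FIXTURE_FILES[dataset_name]
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    return DemographicTable.from_frame(dataset_name, frame)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_MIN_SIZE = 24  # below this the three structure pairs cannot be placed

# (center_y, center_x, ry, rx) in fractional image coordinates for the three
# left-side structures; the right side mirrors x about the vertical midline.
_STRUCTURES = (
    (0.32, 0.28, 0.16, 0.12),  # "head": large ellipse
    (0.68, 0.30, 0.20, 0.08),  # "shaft": elongated capsule
    (0.47, 0.24, 0.06, 0.05),  # "joint space": small ellipse
)
_BASE_INTENSITY = (0.85, 0.65, 0.45)
_BACKGROUND = 0.08


def _draw_ellipse(mask, cy, cx, ry, rx, label):
    h, w = mask.shape
    yy, xx = np.ogrid[:h, :w]
    inside = ((yy - cy) / max(ry, 1.0)) ** 2 + ((xx - cx) / max(rx, 1.0)) ** 2 <= 1.0
    mask[inside] = label


def render_noiseless(
    spec: GenerationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the structure pairs; returns (image in [0,1], mask) before any
    group appearance shift is applied."""
    h, w = spec.image_size
    if min(h, w) < _MIN_SIZE:
        raise ValueError(
            f"image_size {spec.image_size} too small to place structures "
            f"(need at least {_MIN_SIZE} px per side)"
        )
    mask = np.zeros((h, w), dtype=np.uint8)
    image = np.full((h, w), _BACKGROUND, dtype=np.float64)
    n_pairs = spec.n_foreground_classes // 2
    for p in range(n_pairs):
        cy0, cx0, ry0, rx0 = _STRUCTURES[p % len(_STRUCTURES)]
        # per-sample geometric jitter: +-6% of image size on centers, +-15% on radii
        for side in (0, 1):  # 0 = left, 1 = mirrored right
            label = 2 * p + side + 1
            cy = (cy0 + rng.uniform(-0.06, 0.06)) * h
            cx_frac = cx0 + rng.uniform(-0.04, 0.04)
            cx = (cx_frac if side == 0 else 1.0 - cx_frac) * w
            ry = ry0 * h * rng.uniform(0.85, 1.15)
            rx = rx0 * w * rng.uniform(0.85, 1.15)
            _draw_ellipse(mask, cy, cx, ry, rx, label)
            intensity = _BASE_INTENSITY[p % len(_BASE_INTENSITY)] * rng.uniform(0.95, 1.05)
            image[mask == label] = intensity
    if not (mask > 0).any():
        raise ValueError("rendering produced no foreground; image_size too small")
    return image, mask


def render_sample(spec: GenerationSpec, group: GroupKey, sample_seed: int) -> SampleRecord:
    """Render one sample for a subgroup: noiseless structures, then the
    group's contrast scaling, optional blur, and Gaussian noise whose SD is
    the group noise level times a per-sample jitter factor.

    Deterministic given (spec.seed, group, sample_seed).
    """
    rng = substream(spec.seed, "render", group.code, sample_seed)
    image, mask = render_noiseless(spec, rng)
    app = spec.group_appearance.get(group, GroupAppearance())
    if app.blur > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, app.blur)
    image = image * app.contrast
    jitter = rng.uniform(*spec.jitter_range)
    if app.noise_sd > 0:
        image = image + rng.normal(0.0, app.noise_sd * jitter, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SampleRecord(
        sample_id=f"{group.code}-{sample_seed:05d}",
        image=image,
        mask=mask,
        group=group,
    )


# ---------------------------------------------------------------------------
# Dataset generation, splitting, site partitioning
# ---------------------------------------------------------------------------


def _largest_remainder(total: int, weights: np.ndarray, tie_order: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``; ties in the
    fractional parts are broken by ascending ``tie_order``."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    frac = raw - base
    order = np.lexsort((tie_order, -frac))
    for i in order[:short]:
        base[i] += 1
    return base


def generate_dataset(spec: GenerationSpec) -> list[SampleRecord]:
    """Generate a full dataset.

    In fixture mode (``spec.fixture`` or ``spec.site_table`` set), the per
    (group, site) counts match the demographic table exactly and the site
    label is attached at generation time.  Otherwise ``n_samples`` samples
    are allocated as evenly as possible over the four subgroups.
    """
    table = spec.site_table
    if spec.fixture is not None and table is None:
        table = build_demographic_fixture(spec.fixture)
    records: list[SampleRecord] = []
    counter = 0
    if table is not None:
        for g in GROUP_ORDER:
            for s in SITES:
                for _ in range(table.cell(g, s)):
                    rec = render_sample(spec, g, counter)
                    rec.site = s
                    records.append(rec)
                    counter += 1
    elif spec.group_counts is not None:
        for g in GROUP_ORDER:
            for _ in range(spec.group_counts.get(g, 0)):
                records.append(render_sample(spec, g, counter))
                counter += 1
    else:
        if spec.n_samples is None:
            raise ValueError("either n_samples or a fixture/site_table is required")
        if spec.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        quotas = _largest_remainder(
            spec.n_samples,
            np.ones(len(GROUP_ORDER)),
            np.arange(len(GROUP_ORDER)),
        )
        for g, q in zip(GROUP_ORDER, quotas):
            for _ in range(q):
                records.append(render_sample(spec, g, counter))
                counter += 1
    return records


def stratified_split(
    samples: list[SampleRecord],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> dict[str, str]:
    """Assign train/val/test splits with the demographic (race-gender)
    distribution kept consistent across splits.

    Within every subgroup the split sizes follow largest-remainder rounding
    of the target fractions, so per-group proportions deviate from the
    targets by less than one sample.  Returns ``sample_id -> split`` and also
    writes the assignment onto the records.
    """
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fr.sum()}")
    if (fr < 0).any() or (fr > 1).any():
        raise ValueError("fractions must lie in [0, 1]")
    rng = substream(seed, "split")
    assignment: dict[str, str] = {}
    by_group: dict[GroupKey, list[SampleRecord]] = {}
    for rec in samples:
        by_group.setdefault(rec.group, []).append(rec)
    for g in sorted(by_group, key=lambda k: (k.race, k.gender)):
        recs = sorted(by_group[g], key=lambda r: r.sample_id)
        perm = rng.permutation(len(recs))
        sizes = _largest_remainder(len(recs), np.maximum(fr, 1e-12), np.arange(3))
        # groups with 0 samples never reach here; empty split lists are fine
        bounds = np.cumsum(sizes)
        for pos, idx in enumerate(perm):
            which = int(np.searchsorted(bounds, pos, side="right"))
            recs[idx].split = SPLITS[which]
            assignment[recs[idx].sample_id] = SPLITS[which]
    return assignment


def partition_by_site(
    samples: list[SampleRecord], table: DemographicTable, seed: int = 0
) -> dict[str, list[str]]:
    """Assign samples to acquisition sites so that per-(group, site) counts
    equal the demographic table exactly.

    Samples already carrying a site label are reassigned.  Raises if any
    (group, site) cell cannot be filled from the available samples of that
    group, naming the deficient cell.
    """
    rng = substream(seed, "sites")
    by_group: dict[GroupKey, list[SampleRecord]] = {}
    for rec in samples:
        by_group.setdefault(rec.group, []).append(rec)
    partition: dict[str, list[str]] = {s: [] for s in SITES}
    for g in GROUP_ORDER:
        need = [(s, table.cell(g, s)) for s in SITES]
        total_need = sum(c for _, c in need)
        pool = sorted(by_group.get(g, []), key=lambda r: r.sample_id)
        if len(pool) < total_need:
            deficient = next(s for s, c in need if c > 0)
            raise ValueError(
                f"cannot fill cell (group={g.code}, site={deficient}): table needs "
                f"{total_need} samples of group {g.code}, only {len(pool)} available"
            )
        perm = rng.permutation(len(pool))
        cursor = 0
        for s, c in need:
            for idx in perm[cursor : cursor + c]:
                pool[idx].site = s
                partition[s].append(pool[idx].sample_id)
            cursor += c
    return {s: ids for s, ids in partition.items() if ids}


# ---------------------------------------------------------------------------
# Disk I/O: PNG pairs + metadata CSV
# ---------------------------------------------------------------------------


def save_dataset(samples: list[SampleRecord], out_dir: str | Path) -> None:
    """Write 8-bit grayscale image PNGs, raw-label mask PNGs and metadata.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in samples:
        img8 = np.round(rec.image * 255.0).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / "images" / f"{rec.sample_id}.png")
        Image.fromarray(rec.mask.astype(np.uint8), mode="L").save(
            out / "masks" / f"{rec.sample_id}.png"
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "race": rec.group.race,
                "gender": rec.group.gender,
                "site": rec.site or "",
                "split": rec.split or "",
            }
        )
    with open(out / "metadata.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["sample_id", "race", "gender", "site", "split"])
        writer.writeheader()
        writer.writerows(rows)


def load_dataset(in_dir: str | Path) -> list[SampleRecord]:
    """Load a dataset written by :func:`save_dataset` (images rescaled to [0,1])."""
    root = Path(in_dir)
    meta = pd.read_csv(root / "metadata.csv", keep_default_na=False)
    records = []
    for row in meta.itertuples(index=False):
        image = np.asarray(Image.open(root / "images" / f"{row.sample_id}.png"), dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(root / "masks" / f"{row.sample_id}.png"), dtype=np.uint8)
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                image=image,
                mask=mask,
                group=GroupKey(row.race, row.gender),
                site=row.site or None,
                split=row.split or None,
            )
        )
    return records


def metadata_groups(samples: list[SampleRecord]) -> dict[str, GroupKey]:
    return {rec.sample_id: rec.group for rec in samples}
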