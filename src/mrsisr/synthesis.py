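"""Synthetic metabolite-map construction from tissue segmentations.

High-resolution (128x128) metabolite maps are built as a concentration-
weighted combination of tissue occupancy planes,

    map(p) = C_GM * gm(p) + C_WM * wm(p) + 0 * csf(p),

with the tumor contribution replacing the tissue contribution inside the
tumor mask (an additive variant is available via ``tumor_additive``).  CSF
carries zero concentration.  Concentrations come from a literature-derived
table of per-compartment ranges with point estimates for three metabolites
(tCr, tCho, NAA) and two diagnostic ratios (tCho/NAA, tCho/tCr); tumor
ratio ranges are split at their midpoint into an LGG (lower) and an HGG
(upper) sub-range.  Maps are min-max normalized to [0, 1] and paired with
4x block-averaged 32x32 counterparts, emulating the coarse voxel grid of
clinical MRSI relative to anatomical MRI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .phantom import Grade, PhantomSlice, TissueSegmentation, TumorMask, select_slices

#: default in-plane field of view (mm) and slice thickness (mm)
DEFAULT_FOV_MM = 220.0
DEFAULT_SLICE_MM = 10.0


class MapType(str, Enum):
    """The three metabolites and two metabolic ratios that are mapped."""

    tCho = "tCho"
    tCr = "tCr"
    NAA = "NAA"
    tCho_over_NAA = "tCho/NAA"
    tCho_over_tCr = "tCho/tCr"


METABOLITES = (MapType.tCho, MapType.tCr, MapType.NAA)
RATIOS = (MapType.tCho_over_NAA, MapType.tCho_over_tCr)


def estimated_concentration(lo: float, hi: float) -> float:
    """Point estimate for a literature concentration range: the midpoint."""
    if lo > hi:
        raise ValueError("range lower bound exceeds upper bound")
    return (lo + hi) / 2.0


def grade_threshold(lo: float, hi: float) -> float:
    """Ratio value separating LGG from HGG tumors: the range average.

    LGG tumor ratios are drawn from [lo, threshold], HGG from [threshold, hi].
    """
    if lo > hi:
        raise ValueError("range lower bound exceeds upper bound")
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class Entry:
    """A concentration (or ratio) range with its point estimate."""

    lo: float
    hi: float
    estimate: float

    def __post_init__(self):
        if not (self.lo <= self.estimate <= self.hi):
            raise ValueError("estimate must lie within [lo, hi]")


def _mid(lo: float, hi: float) -> Entry:
    return Entry(lo, hi, estimated_concentration(lo, hi))


@dataclass(frozen=True)
class ConcentrationTable:
    """Literature metabolite concentrations (mM) and ratios per compartment.

    ``metabolites[m][c]`` gives the entry for metabolite ``m`` in compartment
    ``c`` ("GM", "WM" or "Tumor"); ``tumor_ratios`` / ``nontumor_ratios``
    hold the ratio rows.  CSF concentration is fixed at zero.  The default
    nontumor ratio estimates are the literature's printed values, which are
    not all range midpoints.
    """

    metabolites: dict = field(default_factory=lambda: {
        MapType.tCr: {"GM": _mid(6.4, 9.7), "WM": _mid(5.2, 5.7), "Tumor": _mid(2.5, 6.0)},
        MapType.tCho: {"GM": _mid(1.6, 2.0), "WM": _mid(1.3, 1.6), "Tumor": _mid(2.5, 5.5)},
        MapType.NAA: {"GM": _mid(8.0, 11.0), "WM": _mid(6.0, 9.0), "Tumor": _mid(1.5, 3.5)},
    })
    tumor_ratios: dict = field(default_factory=lambda: {
        MapType.tCho_over_NAA: _mid(0.7, 4.0),
        MapType.tCho_over_tCr: _mid(0.5, 3.0),
    })
    nontumor_ratios: dict = field(default_factory=lambda: {
        MapType.tCho_over_NAA: {"GM": Entry(0.15, 0.25, 0.20), "WM": Entry(0.14, 0.28, 0.22)},
        MapType.tCho_over_tCr: {"GM": Entry(0.40, 1.40, 0.80), "WM": Entry(0.25, 1.20, 0.50)},
    })
    csf_concentration: float = 0.0

    def tissue_entry(self, map_type: MapType, compartment: str) -> Entry:
        """Nontumor GM/WM entry for any map type."""
        map_type = MapType(map_type)
        if map_type in METABOLITES:
            return self.metabolites[map_type][compartment]
        return self.nontumor_ratios[map_type][compartment]

    def tumor_entry(self, map_type: MapType) -> Entry:
        map_type = MapType(map_type)
        if map_type in METABOLITES:
            return self.metabolites[map_type]["Tumor"]
        return self.tumor_ratios[map_type]


@dataclass
class MetaboliteMap:
    """A single-channel 2-D metabolite (or ratio) map with its geometry."""

    values: np.ndarray
    map_type: MapType
    normalized: bool = False
    fov_mm: float = DEFAULT_FOV_MM
    slice_thickness_mm: float = DEFAULT_SLICE_MM
    subject_id: str = ""
    slice_index: int = 0
    grade: Grade | None = None

    def __post_init__(self):
        self.map_type = MapType(self.map_type)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("map values must be a square 2-D grid")
        if self.normalized and (self.values.min() < 0 or self.values.max() > 1.0 + 1e-9):
            raise ValueError("normalized map values must lie in [0, 1]")

    @property
    def resolution(self) -> int:
        return self.values.shape[0]

    @property
    def voxel_edge_mm(self) -> float:
        """In-plane voxel edge length: fov / resolution."""
        return self.fov_mm / self.resolution


def tumor_value(table: ConcentrationTable, map_type: MapType, grade: Grade | str,
                mode: str = "deterministic", seed: int | None = None) -> float:
    """Concentration (metabolite) or ratio value assigned to tumor pixels.

    Ratios use the grade sub-range: LGG below the range average, HGG above.
    ``deterministic`` returns the tumor estimate (metabolites) or the grade
    sub-range midpoint (ratios); ``sampled`` draws uniformly from the full
    tumor range (metabolites) or the grade sub-range (ratios).
    """
    map_type = MapType(map_type)
    grade = Grade(grade)
    if mode not in ("deterministic", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    entry = table.tumor_entry(map_type)
    if map_type in METABOLITES:
        lo, hi = entry.lo, entry.hi
        if mode == "deterministic":
            return entry.estimate
    else:
        thr = grade_threshold(entry.lo, entry.hi)
        lo, hi = (entry.lo, thr) if grade is Grade.LGG else (thr, entry.hi)
        if mode == "deterministic":
            return (lo + hi) / 2.0
    rng = np.random.default_rng(seed)
    return float(rng.uniform(lo, hi))


def synthesize_map(seg: TissueSegmentation, tumor: TumorMask,
                   table: ConcentrationTable | None = None,
                   map_type: MapType = MapType.tCho,
                   mode: str = "deterministic", seed: int | None = None,
                   tumor_additive: bool = False,
                   fov_mm: float = DEFAULT_FOV_MM) -> MetaboliteMap:
    """Build an unnormalized high-resolution metabolite map for one slice."""
    table = table or ConcentrationTable()
    map_type = MapType(map_type)
    if seg.gm.shape != tumor.mask.shape:
        raise ValueError("segmentation and tumor mask shapes disagree")
    c_gm = table.tissue_entry(map_type, "GM").estimate
    c_wm = table.tissue_entry(map_type, "WM").estimate
    values = c_gm * seg.gm + c_wm * seg.wm + table.csf_concentration * seg.csf
    t_val = tumor_value(table, map_type, tumor.grade, mode=mode, seed=seed)
    inside = tumor.mask == 1
    if tumor_additive:
        values[inside] += t_val
    else:  # tumor overrides tissue: distinct concentration inside the lesion
        values[inside] = t_val
    return MetaboliteMap(values=values, map_type=map_type, normalized=False,
                         fov_mm=fov_mm, subject_id=seg.subject_id,
                         slice_index=seg.slice_index, grade=tumor.grade)


def normalize_map(m: MetaboliteMap) -> MetaboliteMap:
    """Min-max normalize to [0, 1] by dividing by the map maximum."""
    if m.values.min() < 0:
        raise ValueError("cannot normalize a map with negative values")
    peak = m.values.max()
    values = m.values if peak == 0 else m.values / peak
    return replace(m, values=values, normalized=True)


def downsample(hr: MetaboliteMap, factor: int = 4) -> MetaboliteMap:
    """Block-average downsampling by an integer factor.

    Each low-resolution pixel is the mean of its factor x factor block,
    emulating the larger-voxel signal integration of an MRSI acquisition;
    the global mean is conserved exactly.
    """
    n = hr.resolution
    if factor < 1 or n % factor != 0:
        raise ValueError("resolution must be divisible by the downsampling factor")
    lo = hr.values.reshape(n // factor, factor, n // factor, factor).mean(axis=(1, 3))
    return replace(hr, values=lo)


def block_average(plane: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a square 2-D array by an integer factor."""
    n = plane.shape[0]
    if plane.shape[0] != plane.shape[1] or n % factor != 0:
        raise ValueError("plane must be square with side divisible by factor")
    return plane.reshape(n // factor, factor, n // factor, factor).mean(axis=(1, 3))


@dataclass
class TrainingExample:
    """One paired super-resolution instance.

    ``lr_input`` stacks the 32x32 metabolite map with the 32x32
    block-averaged, min-max normalized FLAIR slice; ``hr_target`` is the
    normalized 128x128 map.
    """

    lr_input: np.ndarray   # (2, 32, 32), values in [0, 1]
    hr_target: np.ndarray  # (1, 128, 128), values in [0, 1]
    subject_id: str
    slice_index: int
    map_type: MapType
    grade: Grade

    def __post_init__(self):
        if self.lr_input.ndim != 3 or self.lr_input.shape[0] != 2:
            raise ValueError("lr_input must be (2, H, W)")
        if self.hr_target.ndim != 3 or self.hr_target.shape[0] != 1:
            raise ValueError("hr_target must be (1, H, W)")


def _minmax(plane: np.ndarray) -> np.ndarray:
    lo, hi = plane.min(), plane.max()
    if hi - lo <= 0:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def build_dataset(subjects: list[list[PhantomSlice]],
                  table: ConcentrationTable | None = None,
                  mode: str = "deterministic", seed: int = 0,
                  factor: int = 4, max_slices: int = 10) -> list[TrainingExample]:
    """Per selected slice and map type, build one paired training example.

    Tumor concentrations in ``sampled`` mode are drawn once per subject and
    map type (the lesion, not the slice, carries the concentration), from a
    stream derived from ``seed``.
    """
    table = table or ConcentrationTable()
    children = np.random.SeedSequence(seed).spawn(max(len(subjects), 1))
    examples: list[TrainingExample] = []
    for subj_idx, slices in enumerate(subjects):
        selected = set(select_slices(slices, max_k=max_slices))
        subj_seeds = children[subj_idx].generate_state(len(MapType))
        for seg, tumor, flair in slices:
            if seg.slice_index not in selected:
                continue
            flair_lr = _minmax(block_average(flair.intensity, factor))
            for mt_idx, map_type in enumerate(MapType):
                mseed = int(subj_seeds[mt_idx] % (2 ** 31))
                hr = normalize_map(synthesize_map(
                    seg, tumor, table, map_type, mode=mode, seed=mseed))
                lr = downsample(hr, factor)
                examples.append(TrainingExample(
                    lr_input=np.stack([lr.values, flair_lr]).astype(np.float32),
                    hr_target=hr.values[None].astype(np.float32),
                    subject_id=seg.subject_id, slice_index=seg.slice_index,
                    map_type=map_type, grade=tumor.grade))
    if not examples:
        warnings.warn("no eligible slices: dataset is empty", stacklevel=2)
    return examples
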