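"""Synthetic brain-slice anatomies for metabolite-map synthesis.

Generates, per subject, a stack of 2-D axial slices on a 128x128 grid:
soft GM/WM/CSF occupancy fractions (emulating partial-volume tissue
segmentation of a skull-stripped T1w image), a contiguous glioma mask with a
grade label (LGG or HGG), and a FLAIR-like intensity slice in which tumor
tissue is hyperintense.  Geometry is an invented ellipsoidal-head phantom:
an elliptical brain outline, a cortical GM band, central WM, ventricular and
peripheral CSF, and a tumor blob carved from thresholded smoothed noise.
Slice geometry varies smoothly across the stack, mimicking movement through
the head.

Everything is deterministic in the subject seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

GRID = 128


class Grade(str, Enum):
    """Glioma grade: lower-grade glioma or high-grade glioma (glioblastoma)."""

    LGG = "LGG"
    HGG = "HGG"


@dataclass
class TissueSegmentation:
    """Soft GM/WM/CSF occupancy fractions for one axial slice.

    Invariant: at every pixel gm + wm + csf <= 1 (remainder is background).
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    subject_id: str
    slice_index: int

    def __post_init__(self):
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError("tissue planes must share one shape")
        total = self.gm + self.wm + self.csf
        if total.max() > 1.0 + 1e-6:
            raise ValueError("occupancy fractions exceed 1 at some pixel")

    def binarized(self) -> "TissueSegmentation":
        """Hard labels: each pixel assigned to its dominant compartment."""
        stack = np.stack([self.gm, self.wm, self.csf])
        winner = stack.argmax(axis=0)
        present = stack.sum(axis=0) > 0.5
        planes = [(winner == i) & present for i in range(3)]
        return TissueSegmentation(
            gm=planes[0].astype(self.gm.dtype), wm=planes[1].astype(self.wm.dtype),
            csf=planes[2].astype(self.csf.dtype), subject_id=self.subject_id,
            slice_index=self.slice_index)


@dataclass
class TumorMask:
    """Binary tumor mask with its glioma grade."""

    mask: np.ndarray
    grade: Grade

    def __post_init__(self):
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("tumor mask must be binary")
        self.grade = Grade(self.grade)


@dataclass
class FlairSlice:
    """A FLAIR-contrast intensity slice (nonnegative, finite)."""

    intensity: np.ndarray
    subject_id: str
    slice_index: int

    def __post_init__(self):
        if not np.isfinite(self.intensity).all():
            raise ValueError("FLAIR intensities must be finite")
        if self.intensity.min() < 0:
            raise ValueError("FLAIR intensities must be nonnegative")


PhantomSlice = tuple[TissueSegmentation, TumorMask, FlairSlice]


def _elliptic(xx, yy, cx, cy, ax, ay):
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2


def generate_subject(seed: int, grade: Grade | str = Grade.HGG,
                     n_slices: int = 8, grid: int = GRID,
                     pv_sigma: float = 0.7) -> list[PhantomSlice]:
    """Generate one subject's stack of (segmentation, tumor, FLAIR) slices.

    Parameters
    ----------
    seed:
        Subject seed; identical seeds give bit-identical output.
    grade:
        Glioma grade assigned to the subject's tumor.
    n_slices:
        Number of axial slices (>= 1); geometry varies smoothly across them.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    grade = Grade(grade)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subject_id = f"sub{seed:010d}"

    coords = np.linspace(-1.0, 1.0, grid)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")

    # per-subject anatomy parameters
    ax = rng.uniform(0.70, 0.80)
    ay = rng.uniform(0.84, 0.92)
    vent_dx = rng.uniform(0.10, 0.16)
    vent_ay = rng.uniform(0.18, 0.26)
    gm_inner = rng.uniform(0.55, 0.65)   # elliptic level where the GM band starts
    rim_inner = rng.uniform(0.88, 0.94)  # level where the peripheral CSF rim starts
    # tumor placement inside the brain, avoiding the very center (ventricles)
    t_r = rng.uniform(0.25, 0.55)
    t_theta = rng.uniform(0.0, 2.0 * np.pi)
    tcx = t_r * np.cos(t_theta) * ax * 0.9
    tcy = t_r * np.sin(t_theta) * ay * 0.9
    t_radius = rng.uniform(0.14, 0.24)
    tumor_noise = ndimage.gaussian_filter(rng.standard_normal((grid, grid)), sigma=8.0)
    tumor_noise /= max(tumor_noise.std(), 1e-9)
    flair_bias = ndimage.gaussian_filter(rng.standard_normal((grid, grid)), sigma=16.0)
    flair_bias /= max(np.abs(flair_bias).max(), 1e-9)

    out: list[PhantomSlice] = []
    for s in range(n_slices):
        # through-plane profile: slices shrink smoothly away from the stack center
        t = (s - (n_slices - 1) / 2.0) / max(n_slices, 2)
        scale = float(np.sqrt(max(0.3, 1.0 - (1.1 * t) ** 2)))

        e = _elliptic(xx, yy, 0.0, 0.05, ax * scale, ay * scale)
        brain = e < 1.0
        vent = np.minimum(
            _elliptic(xx, yy, -vent_dx, -0.02, 0.09, vent_ay * scale),
            _elliptic(xx, yy, vent_dx, -0.02, 0.09, vent_ay * scale)) < 1.0
        csf_hard = brain & (vent | (e > rim_inner))
        gm_hard = brain & ~csf_hard & (e > gm_inner)
        wm_hard = brain & ~csf_hard & ~gm_hard

        # soft partial-volume fractions: smoothing one-hot planes conserves
        # their sum, so gm + wm + csf = smoothed(brain) <= 1 everywhere.
        # The sub-voxel sigma emulates the ~1-voxel transition width of
        # partial-volume tissue segmentation.
        gm = ndimage.gaussian_filter(gm_hard.astype(np.float64), pv_sigma)
        wm = ndimage.gaussian_filter(wm_hard.astype(np.float64), pv_sigma)
        csf = ndimage.gaussian_filter(csf_hard.astype(np.float64), pv_sigma)
        np.clip(gm, 0.0, 1.0, out=gm)
        np.clip(wm, 0.0, 1.0, out=wm)
        np.clip(csf, 0.0, 1.0, out=csf)
        total = gm + wm + csf
        over = np.maximum(total, 1.0)  # strict occupancy conservation
        gm /= over
        wm /= over
        csf /= over

        # contiguous tumor blob; radius follows the through-plane profile
        r_s = t_radius * float(np.sqrt(max(0.15, 1.0 - (1.6 * t) ** 2)))
        d2 = ((xx - tcx) ** 2 + (yy - tcy) ** 2) / r_s ** 2
        blob = (d2 - 1.0 + 0.9 * tumor_noise < 0) & (e < rim_inner)
        labels, n_comp = ndimage.label(blob)
        mask = np.zeros((grid, grid), dtype=np.uint8)
        if n_comp:
            ci = int(np.clip(np.searchsorted(coords, tcy), 0, grid - 1))
            cj = int(np.clip(np.searchsorted(coords, tcx), 0, grid - 1))
            lab = labels[ci, cj]
            if lab == 0:  # center fell outside: keep the largest component
                lab = int(np.argmax(np.bincount(labels.ravel())[1:]) + 1)
            mask[labels == lab] = 1
        if mask.sum() < 16:  # guarantee a nonempty, visible lesion
            disk = ((xx - tcx) ** 2 + (yy - tcy) ** 2) < (0.06 ** 2)
            mask[disk & brain] = 1
            if mask.sum() == 0:
                mask[grid // 2 - 3: grid // 2 + 3, grid // 2 - 3: grid // 2 + 3] = 1

        flair = 0.75 * gm + 0.50 * wm + 0.12 * csf
        flair *= 1.0 + 0.10 * flair_bias
        flair += 0.02 * rng.standard_normal((grid, grid)) * (gm + wm + csf)
        # tumor hyperintensity: safely above the whole-slice mean
        flair[mask == 1] = 1.05 + 0.05 * tumor_noise[mask == 1]
        np.clip(flair, 0.0, None, out=flair)

        seg = TissueSegmentation(gm=gm, wm=wm, csf=csf,
                                 subject_id=subject_id, slice_index=s)
        out.append((seg, TumorMask(mask=mask, grade=grade),
                    FlairSlice(intensity=flair, subject_id=subject_id, slice_index=s)))
    return out


def select_slices(slices: list[PhantomSlice], min_k: int = 5, max_k: int = 10) -> list[int]:
    """Indices of slices whose tumor is FLAIR-hyperintense, capped at ``max_k``.

    A slice is eligible iff the mean FLAIR intensity over tumor pixels is
    strictly greater than the mean intensity of the entire slice.  Between
    ``min_k`` and ``max_k`` eligible slices are returned when available,
    otherwise all eligible ones, ordered by slice index.
    """
    if not slices:
        raise ValueError("no slices given")
    eligible = []
    for seg, tumor, flair in slices:
        inten = flair.intensity
        tumor_px = inten[tumor.mask == 1]
        if tumor_px.size and tumor_px.mean() > inten.mean():
            eligible.append(flair.slice_index)
    eligible.sort()
    return eligible[:max_k]
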