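"""Quantification: CNR, volumetrics, SV/EF/CO, mass, echo formulas.

Volumes follow the slice-summation rule (segmented area per slice times
slice thickness); stroke volume, ejection fraction and cardiac output
derive from the end-diastolic and end-systolic blood volumes; myocardial
mass uses a tissue density of 1.05 g/cm^3.  Contrast-to-noise ratio is
(mean blood - mean myocardium) / noise standard deviation.

Segmentation is deliberately simple: thresholds between the known tissue
intensity levels, applied within regions of interest seeded from the
phantom's ground-truth geometry.  It is a recovery-test instrument, not
a segmentation method (the reference procedure traces borders manually).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from .phantom import DynamicPhantom, background_mask, compartment_mask
from .recon import CineFrameSet

__all__ = [
    "VentricleReport",
    "FunctionalReport",
    "compute_cnr",
    "volume_from_masks",
    "functional_params",
    "myocardial_mass",
    "teichholz_volume",
    "simpson_volume",
    "segment_compartments",
    "functional_report_from_cine",
]

TISSUE_DENSITY_G_PER_CM3 = 1.05


# ---------------------------------------------------------------------------
# formula layer
# ---------------------------------------------------------------------------

def compute_cnr(image: np.ndarray, blood_mask: np.ndarray,
                myo_mask: np.ndarray, noise_mask: np.ndarray) -> float:
    """(mean blood - mean myocardium) / std of noise; may be negative."""
    for name, m in (("blood", blood_mask), ("myo", myo_mask), ("noise", noise_mask)):
        if not np.any(m):
            raise ValueError(f"empty {name} mask")
    if np.any(blood_mask & myo_mask):
        raise ValueError("blood and myocardium masks overlap")
    sd = float(np.std(image[noise_mask]))
    if sd == 0.0:
        raise ValueError("zero noise standard deviation")
    return float((image[blood_mask].mean() - image[myo_mask].mean()) / sd)


def volume_from_masks(masks, pixel_size: float, slice_thickness: float) -> float:
    """Slice-summation volume in microliters from per-slice boolean masks."""
    if pixel_size <= 0 or slice_thickness <= 0:
        raise ValueError("pixel_size and slice_thickness must be positive")
    total_px = sum(int(np.count_nonzero(m)) for m in masks)
    return float(total_px * pixel_size ** 2 * slice_thickness)


def functional_params(edv: float, esv: float, heart_rate: float):
    """(SV ul, EF %, CO ml/min) from EDV/ESV (ul) and heart rate (bpm)."""
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    if not edv > esv >= 0:
        raise ValueError("need edv > esv >= 0")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * heart_rate / 1000.0
    return sv, ef, co


def myocardial_mass(v_myo: float) -> float:
    """Myocardial mass in mg from volume in ul at 1.05 g/cm^3."""
    if v_myo < 0:
        raise ValueError("myocardial volume must be non-negative")
    return TISSUE_DENSITY_G_PER_CM3 * v_myo


def teichholz_volume(lvid: float, units: str = "mm") -> float:
    """Teichholz m-mode volume: V = 7/(2.4 + D) * D^3.

    With ``units="mm"`` the diameter is in mm and the result in ul
    (small-animal convention); ``units="cm"`` takes cm and returns ml.
    """
    if lvid < 0:
        raise ValueError("diameter must be non-negative")
    if units not in ("mm", "cm"):
        raise ValueError("units must be 'mm' or 'cm'")
    return 7.0 / (2.4 + lvid) * lvid ** 3


def simpson_volume(diameter_pairs, disk_height: float) -> float:
    """Method-of-disks volume: sum of pi/4 * a_i * b_i * h, in ul (mm)."""
    if disk_height <= 0:
        raise ValueError("disk height must be positive")
    total = 0.0
    for a, b in diameter_pairs:
        if a < 0 or b < 0:
            raise ValueError("diameters must be non-negative")
        total += np.pi / 4.0 * a * b * disk_height
    return float(total)


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VentricleReport:
    edv: float    # ul
    esv: float    # ul
    sv: float     # ul
    ef: float     # %
    co: float     # ml/min
    mass: float   # mg

    @classmethod
    def from_volumes(cls, edv, esv, v_myo, heart_rate) -> "VentricleReport":
        sv, ef, co = functional_params(edv, esv, heart_rate)
        return cls(edv=edv, esv=esv, sv=sv, ef=ef, co=co,
                   mass=myocardial_mass(v_myo))


@dataclass
class FunctionalReport:
    lv: VentricleReport
    rv: VentricleReport | None
    heart_rate: float                       # bpm
    cnr_entries: list = field(default_factory=list)  # (name, value) pairs
    ed_frame: int = -1
    es_frame: int = -1

    def to_dict(self) -> dict:
        return {
            "heart_rate_bpm": self.heart_rate,
            "ed_frame": self.ed_frame,
            "es_frame": self.es_frame,
            "LV": dataclasses.asdict(self.lv),
            "RV": dataclasses.asdict(self.rv) if self.rv else None,
            "cnr": [[n, v] for n, v in self.cnr_entries],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FunctionalReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(lv=VentricleReport(**d["LV"]),
                   rv=VentricleReport(**d["RV"]) if d["RV"] else None,
                   heart_rate=d["heart_rate_bpm"],
                   cnr_entries=[(n, v) for n, v in d["cnr"]],
                   ed_frame=d["ed_frame"], es_frame=d["es_frame"])


# ---------------------------------------------------------------------------
# ground-truth-assisted segmentation
# ---------------------------------------------------------------------------

def _roi_and_cores(phantom, phase, slice_index, ventricle, matrix, fov, dilate_px):
    blood_gt = compartment_mask(phantom, phase, slice_index, f"{ventricle}_blood",
                                matrix, fov)
    myo_gt = compartment_mask(phantom, phase, slice_index, f"{ventricle}_myo",
                              matrix, fov)
    roi = binary_dilation(blood_gt | myo_gt, iterations=dilate_px)
    blood_core = binary_erosion(blood_gt, iterations=1)
    myo_core = binary_erosion(myo_gt, iterations=1)
    if not blood_core.any():
        blood_core = blood_gt
    if not myo_core.any():
        myo_core = myo_gt
    return roi, blood_gt, myo_gt, blood_core, myo_core


def segment_compartments(image: np.ndarray, phantom: DynamicPhantom, phase: float,
                         slice_index: int, ventricle: str, fov: float,
                         dilate_px: int = 3):
    """Threshold segmentation of one ventricle in one reconstructed slice.

    The ground-truth geometry at the frame's phase seeds a region of
    interest and provides core samples of the blood and myocardial
    intensity levels; the blood/myocardium threshold is the midpoint of
    those levels.  Returns (blood_mask, myo_mask).
    """
    matrix = image.shape[0]
    roi, blood_gt, myo_gt, blood_core, myo_core = _roi_and_cores(
        phantom, phase, slice_index, ventricle, matrix, fov, dilate_px)
    lvl_blood = float(np.median(image[blood_core]))
    lvl_myo = float(np.median(image[myo_core]))
    thr = 0.5 * (lvl_blood + lvl_myo)
    blood_mask = (image > thr) & binary_dilation(blood_gt, iterations=dilate_px)
    # myocardium: between the body level and the blood threshold, near the shell
    body = background_mask(phantom, matrix, fov)
    lvl_out = float(np.median(image[binary_dilation(myo_gt, iterations=dilate_px)
                                    & ~blood_gt & ~myo_gt]))
    thr_lo = 0.5 * (lvl_myo + lvl_out)
    myo_mask = (image > thr_lo) & (image <= thr) & binary_dilation(myo_gt, iterations=2)
    return blood_mask, myo_mask


def functional_report_from_cine(cine: CineFrameSet, phantom: DynamicPhantom,
                                heart_rate_bpm: float,
                                ventricles=("LV", "RV"),
                                noise_sigma_hint: float | None = None) -> FunctionalReport:
    """End-to-end functional quantification of a reconstructed cine.

    ED and ES frames are selected as the frames with maximal/minimal
    thresholded LV blood area (the reference picks them visually); blood
    and myocardial volumes use slice summation over all slices; CNR uses
    ground-truth core masks on the ED and ES frames with the noise taken
    from object-free background pixels.
    """
    matrix = cine.frames.shape[-1]
    fov = cine.pixel_size * matrix
    n_slices, n_frames = cine.n_slices, cine.n_frames
    mid = n_slices // 2

    # ED/ES frame selection from LV blood area in the central slice
    areas = np.zeros(n_frames)
    for f in range(n_frames):
        bm, _ = segment_compartments(cine.frames[mid, f], phantom,
                                     cine.frame_phase_centers[f], mid, "LV", fov)
        areas[f] = bm.sum()
    ed_frame = int(np.argmax(areas))
    es_frame = int(np.argmin(areas))

    noise = background_mask(phantom, matrix, fov)
    reports = {}
    cnr_entries = []
    for vent in ventricles:
        vols = {}
        myo_ed = 0.0
        for label, f in (("ED", ed_frame), ("ES", es_frame)):
            masks_blood, masks_myo = [], []
            for s in range(n_slices):
                bm, mm = segment_compartments(cine.frames[s, f], phantom,
                                              cine.frame_phase_centers[f], s, vent, fov)
                masks_blood.append(bm)
                masks_myo.append(mm)
            vols[label] = volume_from_masks(masks_blood, cine.pixel_size,
                                            cine.slice_thickness)
            if label == "ED":
                myo_ed = volume_from_masks(masks_myo, cine.pixel_size,
                                           cine.slice_thickness)
        reports[vent] = VentricleReport.from_volumes(vols["ED"], vols["ES"],
                                                     myo_ed, heart_rate_bpm)
        # CNR with ground-truth core masks, averaged convention: one value
        # per (ventricle, frame) pair as in the reference tables
        for label, f in (("ED", ed_frame), ("ES", es_frame)):
            phase = cine.frame_phase_centers[f]
            img = cine.frames[mid, f]
            _, _, _, blood_core, myo_core = _roi_and_cores(
                phantom, phase, mid, vent, matrix, fov, 2)
            try:
                cnr = compute_cnr(img, blood_core, myo_core & ~blood_core, noise)
            except ValueError:
                cnr = float("nan")
            cnr_entries.append((f"{vent} blood - {vent} myo ({label})", cnr))
    return FunctionalReport(lv=reports.get("LV"),
                            rv=reports.get("RV"),
                            heart_rate=heart_rate_bpm,
                            cnr_entries=cnr_entries,
                            ed_frame=ed_frame, es_frame=es_frame)
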