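"""Dynamic analytic ellipse phantom of a beating mouse heart.

The phantom is an additive composition of ellipses, each with its own
end-diastolic (ED) and end-systolic (ES) geometry, so the 2D Fourier
transform of the whole object is available in closed form at any time
point (sum of shifted/rotated jinc terms).  That makes the phantom an
exact oracle for the radial acquisition simulator and for the gridding
reconstruction: every k-space sample and every compartment volume can be
computed analytically.

Cardiac contraction interpolates each ellipse's semi-axes between ED and
ES along a periodic contraction waveform; respiration displaces centers
in-plane and, via a small intensity-modulation term, emulates
through-plane motion of tissue across the imaged slice (the k-space
origin is invariant under pure in-plane translation, so without that
term a k = 0 navigator would carry no respiratory information).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import j1

__all__ = [
    "DynamicEllipse",
    "DynamicPhantom",
    "Ellipse",
    "ellipse_kspace",
    "phantom_state",
    "ground_truth_volumes",
    "rasterize",
    "compartment_mask",
    "background_mask",
    "mouse_heart_phantom",
    "raised_cosine_contraction",
    "raised_cosine_burst",
    "make_waveform",
    "COMPARTMENTS",
]

#: canonical compartment tags used by the quantification layer
COMPARTMENTS = ("LV_blood", "RV_blood", "LV_myo", "RV_myo")


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def raised_cosine_contraction(phase, es_phase: float = 0.4):
    """Smooth periodic contraction waveform on [0, 1) -> [0, 1].

    Zero at phase 0 (end-diastole), one at ``es_phase`` (end-systole),
    raised-cosine ramps in between; C1-continuous across the cycle.
    """
    p = np.asarray(phase, dtype=float) % 1.0
    up = 0.5 * (1.0 - np.cos(np.pi * p / es_phase))
    down = 0.5 * (1.0 + np.cos(np.pi * (p - es_phase) / (1.0 - es_phase)))
    return np.where(p <= es_phase, up, down)


def raised_cosine_burst(phase, duty: float = 0.3):
    """Respiratory waveform: a raised-cosine inspiration burst of the given
    duty cycle followed by a quiescent end-expiration plateau at 0."""
    p = np.asarray(phase, dtype=float) % 1.0
    burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * p / duty))
    return np.where(p < duty, burst, 0.0)


_WAVEFORMS = {
    "raised_cosine_contraction": raised_cosine_contraction,
    "raised_cosine_burst": raised_cosine_burst,
}


def make_waveform(name: str, **params):
    """Build a phase -> value callable from a registered waveform name."""
    if name not in _WAVEFORMS:
        raise ValueError(f"unknown waveform {name!r}; known: {sorted(_WAVEFORMS)}")
    base = _WAVEFORMS[name]
    return lambda p: base(p, **params)


# ---------------------------------------------------------------------------
# ellipse types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicEllipse:
    """One additive ellipse with cardiac/respiratory motion laws.

    ``intensity`` is additive and may be negative (blood pools are carved
    out of myocardium by a negative ellipse plus a positive blood
    ellipse).  ``volume_weight`` gives the signed contribution of this
    ellipse's area to its compartment's ground-truth volume (e.g. +1 for
    a myocardial outer shell, -1 for the cavity carved out of it).
    """

    center: tuple[float, float]                  # mm
    semi_axes_ed: tuple[float, float]            # mm at end-diastole
    semi_axes_es: tuple[float, float]            # mm at end-systole
    rotation: float = 0.0                        # rad, in [0, 2*pi)
    intensity: float = 1.0                       # arbitrary signal units
    resp_amplitude: tuple[float, float] = (0.0, 0.0)  # mm displacement
    flow_velocity: float = 0.0                   # mm/s; nonzero marks blood
    compartment: str = "background"
    volume_weight: float = 0.0
    tapered: bool = False                        # subject to per-slice scaling
    resp_intensity_amp: float = 0.0              # fractional loss at peak inspiration

    def __post_init__(self):
        if min(self.semi_axes_ed) <= 0 or min(self.semi_axes_es) <= 0:
            raise ValueError("semi-axes must be strictly positive at ED and ES")
        if not (0.0 <= self.rotation < 2.0 * np.pi):
            raise ValueError("rotation must lie in [0, 2*pi)")


@dataclass(frozen=True)
class Ellipse:
    """Instantaneous (static) ellipse snapshot."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    intensity: float


@dataclass
class DynamicPhantom:
    """A set of dynamic ellipses plus the global motion clocks."""

    ellipses: list[DynamicEllipse]
    cardiac_period: float = 0.125        # s (480 bpm mouse heart)
    respiratory_period: float = 1.0      # s (60 breaths/min anesthetized)
    contraction: tuple[str, dict] = ("raised_cosine_contraction", {"es_phase": 0.4})
    respiration: tuple[str, dict] = ("raised_cosine_burst", {"duty": 0.3})
    n_slices: int = 5
    slice_thickness: float = 1.0         # mm
    slice_scales: tuple[float, ...] = ()  # apex-to-base tapering; empty -> all 1

    def __post_init__(self):
        if not (0.0 < self.cardiac_period < self.respiratory_period):
            raise ValueError("need 0 < cardiac_period < respiratory_period")
        if not self.slice_scales:
            self.slice_scales = (1.0,) * self.n_slices
        if len(self.slice_scales) != self.n_slices:
            raise ValueError("slice_scales length must equal n_slices")
        if min(self.slice_scales) <= 0 or max(self.slice_scales) > 1.0:
            raise ValueError("slice scale factors must lie in (0, 1]")
        w0 = float(self.contraction_waveform(0.0))
        if abs(w0) > 1e-12:
            raise ValueError("contraction waveform must vanish at phase 0")

    # -- clocks ----------------------------------------------------------
    @property
    def contraction_waveform(self):
        return make_waveform(self.contraction[0], **self.contraction[1])

    @property
    def resp_waveform(self):
        return make_waveform(self.respiration[0], **self.respiration[1])

    @property
    def es_phase(self) -> float:
        return self.contraction[1].get("es_phase", 0.4)

    def cardiac_phase(self, t):
        return (np.asarray(t, dtype=float) / self.cardiac_period) % 1.0

    def resp_phase(self, t):
        return (np.asarray(t, dtype=float) / self.respiratory_period) % 1.0

    def slice_scale(self, slice_index: int) -> float:
        if not 0 <= slice_index < self.n_slices:
            raise IndexError(
                f"slice index {slice_index} out of range for {self.n_slices} slices"
            )
        return self.slice_scales[slice_index]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ellipses"] = [dataclasses.asdict(e) for e in self.ellipses]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicPhantom":
        d = dict(d)
        ells = []
        for e in d.pop("ellipses"):
            e = dict(e)
            for key in ("center", "semi_axes_ed", "semi_axes_es", "resp_amplitude"):
                if key in e:
                    e[key] = tuple(e[key])
            ells.append(DynamicEllipse(**e))
        for key in ("contraction", "respiration"):
            if key in d:
                d[key] = (d[key][0], dict(d[key][1]))
        if "slice_scales" in d:
            d["slice_scales"] = tuple(d["slice_scales"])
        return cls(ellipses=ells, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DynamicPhantom":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# state evaluation
# ---------------------------------------------------------------------------

def _ellipse_trajectory(phantom: DynamicPhantom, ell: DynamicEllipse, t, slice_index: int):
    """Vectorised instantaneous parameters of one ellipse at times ``t``.

    Returns (cx, cy, a, b, intensity) arrays broadcast to t's shape.
    """
    scale = phantom.slice_scale(slice_index) if ell.tapered else 1.0
    t = np.asarray(t, dtype=float)
    w = phantom.contraction_waveform(phantom.cardiac_phase(t))
    r = phantom.resp_waveform(phantom.resp_phase(t))
    a = (ell.semi_axes_ed[0] + (ell.semi_axes_es[0] - ell.semi_axes_ed[0]) * w) * scale
    b = (ell.semi_axes_ed[1] + (ell.semi_axes_es[1] - ell.semi_axes_ed[1]) * w) * scale
    cx = ell.center[0] + ell.resp_amplitude[0] * r
    cy = ell.center[1] + ell.resp_amplitude[1] * r
    inten = ell.intensity * (1.0 - ell.resp_intensity_amp * r)
    return cx, cy, a, b, inten


def phantom_state(phantom: DynamicPhantom, t: float, slice_index: int = 0) -> list[Ellipse]:
    """Instantaneous ellipse snapshots of the phantom at time ``t`` (s)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    phantom.slice_scale(slice_index)  # range check
    out = []
    for ell in phantom.ellipses:
        cx, cy, a, b, inten = _ellipse_trajectory(phantom, ell, float(t), slice_index)
        out.append(Ellipse((float(cx), float(cy)), (float(a), float(b)),
                           ell.rotation, float(inten)))
    return out


# ---------------------------------------------------------------------------
# closed-form Fourier transform
# ---------------------------------------------------------------------------

def _jinc(z):
    """2*J1(z)/z with the analytic z -> 0 limit of 1."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-8
    zsafe = np.where(small, 1.0, z)
    return np.where(small, 1.0 - z * z / 8.0, 2.0 * j1(zsafe) / zsafe)


def ellipse_kspace(ellipse: Ellipse, kx, ky):
    """Closed-form 2D Fourier transform of a uniform ellipse.

    ``kx``/``ky`` are spatial frequencies in cycles/mm.  The value at
    k = 0 is intensity times the ellipse area.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    a, b = ellipse.semi_axes
    x0, y0 = ellipse.center
    c, s = np.cos(ellipse.rotation), np.sin(ellipse.rotation)
    ku = kx * c + ky * s
    kv = -kx * s + ky * c
    rho = np.hypot(a * ku, b * kv)
    amp = ellipse.intensity * np.pi * a * b * _jinc(2.0 * np.pi * rho)
    return amp * np.exp(-2j * np.pi * (kx * x0 + ky * y0))


def phantom_kspace(phantom: DynamicPhantom, t: float, kx, ky, slice_index: int = 0):
    """Closed-form k-space of the whole phantom at time ``t``."""
    out = np.zeros(np.broadcast(np.asarray(kx), np.asarray(ky)).shape, dtype=complex)
    for e in phantom_state(phantom, t, slice_index):
        out += ellipse_kspace(e, kx, ky)
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def ground_truth_volumes(phantom: DynamicPhantom, cardiac_phase: float,
                         compartment: str) -> float:
    """Analytic compartment volume in microliters at a cardiac phase.

    Sums the signed ellipse areas of the tagged compartment over all
    slices, times the slice thickness (mm^3 == ul).  Respiration does
    not change areas, so the volume depends on cardiac phase only.
    """
    tags = {e.compartment for e in phantom.ellipses}
    if compartment not in set(COMPARTMENTS) | tags:
        raise KeyError(f"unknown compartment {compartment!r}")
    w = float(phantom.contraction_waveform(cardiac_phase % 1.0))
    total = 0.0
    for e in phantom.ellipses:
        if e.compartment != compartment or e.volume_weight == 0.0:
            continue
        a = e.semi_axes_ed[0] + (e.semi_axes_es[0] - e.semi_axes_ed[0]) * w
        b = e.semi_axes_ed[1] + (e.semi_axes_es[1] - e.semi_axes_ed[1]) * w
        for s in range(phantom.n_slices):
            scale = phantom.slice_scale(s) if e.tapered else 1.0
            total += e.volume_weight * np.pi * (a * scale) * (b * scale) * phantom.slice_thickness
    return float(total)


# ---------------------------------------------------------------------------
# rasterization (numerical oracle for image-domain comparisons)
# ---------------------------------------------------------------------------

def _pixel_centers(matrix: int, fov: float):
    return (np.arange(matrix) - matrix / 2) * (fov / matrix)


def _inside(e: Ellipse, x, y):
    c, s = np.cos(e.rotation), np.sin(e.rotation)
    dx, dy = x - e.center[0], y - e.center[1]
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a, b = e.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def rasterize(phantom: DynamicPhantom, t: float, slice_index: int,
              matrix: int, fov: float, supersample: int = 4) -> np.ndarray:
    """Anti-aliased raster image of the phantom, indexed [y, x].

    Each pixel is the mean of ``supersample**2`` sub-pixel evaluations of
    the additive ellipse composition.
    """
    ss = supersample
    delta = fov / matrix
    # sub-pixel offsets symmetric about each pixel center
    base = _pixel_centers(matrix, fov)
    offs = (np.arange(ss) - (ss - 1) / 2) * (delta / ss)
    xs = (base[:, None] + offs[None, :]).ravel()
    X, Y = np.meshgrid(xs, xs)
    img = np.zeros_like(X)
    for e in phantom_state(phantom, t, slice_index):
        img += e.intensity * _inside(e, X, Y)
    return img.reshape(matrix, ss, matrix, ss).mean(axis=(1, 3))


def compartment_mask(phantom: DynamicPhantom, cardiac_phase: float, slice_index: int,
                     compartment: str, matrix: int, fov: float) -> np.ndarray:
    """Boolean pixel mask of a compartment at a cardiac phase, [y, x].

    Uses the signed ``volume_weight`` composition: a pixel belongs to the
    compartment where the summed weights of its ellipses reach 1 (outer
    shells count +1, carved cavities -1).  Respiratory displacement is
    ignored (masks describe the reference end-expiration geometry).
    """
    tags = {e.compartment for e in phantom.ellipses}
    if compartment not in set(COMPARTMENTS) | tags:
        raise KeyError(f"unknown compartment {compartment!r}")
    t = (cardiac_phase % 1.0) * phantom.cardiac_period
    base = _pixel_centers(matrix, fov)
    X, Y = np.meshgrid(base, base)
    acc = np.zeros((matrix, matrix))
    w = float(phantom.contraction_waveform(cardiac_phase % 1.0))
    for ell in phantom.ellipses:
        if ell.compartment != compartment or ell.volume_weight == 0.0:
            continue
        scale = phantom.slice_scale(slice_index) if ell.tapered else 1.0
        a = (ell.semi_axes_ed[0] + (ell.semi_axes_es[0] - ell.semi_axes_ed[0]) * w) * scale
        b = (ell.semi_axes_ed[1] + (ell.semi_axes_es[1] - ell.semi_axes_ed[1]) * w) * scale
        snap = Ellipse(ell.center, (a, b), ell.rotation, 1.0)
        acc += ell.volume_weight * _inside(snap, X, Y)
    return acc >= 0.5


def background_mask(phantom: DynamicPhantom, matrix: int, fov: float,
                    margin_mm: float = 0.8) -> np.ndarray:
    """Pixels outside every ellipse (with a safety margin): pure noise."""
    base = _pixel_centers(matrix, fov)
    X, Y = np.meshgrid(base, base)
    occupied = np.zeros((matrix, matrix), dtype=bool)
    for ell in phantom.ellipses:
        a = max(ell.semi_axes_ed[0], ell.semi_axes_es[0]) + margin_mm + abs(ell.resp_amplitude[0])
        b = max(ell.semi_axes_ed[1], ell.semi_axes_es[1]) + margin_mm + abs(ell.resp_amplitude[1])
        occupied |= _inside(Ellipse(ell.center, (a, b), ell.rotation, 1.0), X, Y)
    return ~occupied


# ---------------------------------------------------------------------------
# the shipped default phantom
# ---------------------------------------------------------------------------

def mouse_heart_phantom(n_slices: int = 5) -> DynamicPhantom:
    """Default beating-mouse-heart phantom.

    Bright-blood contrast (blood 1.0, myocardium 0.55, body 0.25, liver
    0.60 in absolute units via additive composition).  The LV cavity
    contracts from r = 1.5 mm to r = 0.8 mm, giving a ground-truth
    ejection fraction of 1 - (0.8/1.5)^2 = 71.6%.  Cardiac period
    0.125 s (480 bpm), respiratory period 1 s (60 breaths/min) with a
    30% inspiration duty cycle.  Respiration displaces the thorax
    in-plane and modulates diaphragm-adjacent signal (through-plane
    proxy) so the k = 0 navigator carries both motions.
    """
    resp_heart = (0.05, 0.25)
    lv_c = (-1.8, 0.2)
    rv_c = (2.6, 0.4)
    ells = [
        # chest wall / body
        DynamicEllipse(center=(0.0, -0.5), semi_axes_ed=(8.5, 7.5), semi_axes_es=(8.5, 7.5),
                       intensity=0.25, resp_amplitude=(0.0, 0.10), compartment="body",
                       resp_intensity_amp=0.04),
        # liver proxy (half-plane stand-in below the heart)
        DynamicEllipse(center=(0.0, -5.3), semi_axes_ed=(6.0, 1.8), semi_axes_es=(6.0, 1.8),
                       intensity=0.35, resp_amplitude=(0.0, 0.35), compartment="liver",
                       resp_intensity_amp=0.25),
        # LV myocardial shell: outer ellipse ...
        DynamicEllipse(center=lv_c, semi_axes_ed=(2.5, 2.5), semi_axes_es=(2.15, 2.15),
                       intensity=0.30, resp_amplitude=resp_heart, compartment="LV_myo",
                       volume_weight=1.0, tapered=True, resp_intensity_amp=0.03),
        # ... minus the cavity (carve at full myocardial intensity) ...
        DynamicEllipse(center=lv_c, semi_axes_ed=(1.5, 1.5), semi_axes_es=(0.8, 0.8),
                       intensity=-0.55, resp_amplitude=resp_heart, compartment="LV_myo",
                       volume_weight=-1.0, tapered=True, resp_intensity_amp=0.03),
        # ... plus the blood pool
        DynamicEllipse(center=lv_c, semi_axes_ed=(1.5, 1.5), semi_axes_es=(0.8, 0.8),
                       intensity=1.0, resp_amplitude=resp_heart, compartment="LV_blood",
                       volume_weight=1.0, tapered=True, flow_velocity=60.0,
                       resp_intensity_amp=0.03),
        # RV: same additive construction, elliptical and thinner-walled
        DynamicEllipse(center=rv_c, semi_axes_ed=(1.9, 1.5), semi_axes_es=(1.55, 1.2),
                       intensity=0.30, resp_amplitude=resp_heart, compartment="RV_myo",
                       volume_weight=1.0, tapered=True, resp_intensity_amp=0.03),
        DynamicEllipse(center=rv_c, semi_axes_ed=(1.4, 1.0), semi_axes_es=(0.74, 0.53),
                       intensity=-0.55, resp_amplitude=resp_heart, compartment="RV_myo",
                       volume_weight=-1.0, tapered=True, resp_intensity_amp=0.03),
        DynamicEllipse(center=rv_c, semi_axes_ed=(1.4, 1.0), semi_axes_es=(0.74, 0.53),
                       intensity=1.0, resp_amplitude=resp_heart, compartment="RV_blood",
                       volume_weight=1.0, tapered=True, flow_velocity=40.0,
                       resp_intensity_amp=0.03),
    ]
    scales = {
        1: (1.0,),
        3: (0.9, 1.0, 0.95),
        5: (0.85, 0.95, 1.0, 1.0, 0.9),
        9: (0.75, 0.82, 0.9, 0.96, 1.0, 1.0, 0.97, 0.9, 0.8),
    }.get(n_slices, (1.0,) * n_slices)
    return DynamicPhantom(ellipses=ells, n_slices=n_slices, slice_scales=scales)
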