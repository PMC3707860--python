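"""Cardiac-frame binning and Kaiser-Bessel convolution gridding.

Accepted spokes are sorted into cardiac frames by their self-gated
phase.  Each frame is reconstructed by the standard convolution-gridding
recipe: ramp density compensation, convolution of the samples onto a
2x-oversampled Cartesian grid with a separable Kaiser-Bessel kernel,
inverse FFT, deapodization by the kernel's analytic transform, and a
central crop.  A direct (brute-force) adjoint non-uniform DFT with
identical coordinate conventions serves as the independent oracle.

Conventions (shared by gridder and oracle): pixel centers at
(n - matrix/2) * fov/matrix for n = 0..matrix-1; spatial frequency k in
cycles/mm; adjoint sign exp(+2*pi*i k.x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.special import i0

from .selfgate import GatingResult
from .sequencer import SpokeSet

__all__ = [
    "GridParams",
    "CineFrameSet",
    "beatty_beta",
    "kb_kernel",
    "kb_fourier",
    "bin_spokes",
    "density_weights",
    "grid_and_reconstruct_frame",
    "adjoint_ndft_oracle",
    "reconstruct_cine",
]


def beatty_beta(kernel_width: float, oversampling: float) -> float:
    """Standard Kaiser-Bessel shape parameter for a width/oversampling pair."""
    w, a = kernel_width, oversampling
    return float(np.pi * np.sqrt((w / a) ** 2 * (a - 0.5) ** 2 - 0.8))


@dataclass(frozen=True)
class GridParams:
    matrix: int
    kernel_width: int = 4
    oversampling: float = 2.0
    beta: float | None = None

    def __post_init__(self):
        if self.kernel_width < 2:
            raise ValueError("kernel_width must be >= 2")
        if self.oversampling < 1.25:
            raise ValueError("oversampling must be >= 1.25")
        if self.beta is None:
            object.__setattr__(self, "beta",
                               beatty_beta(self.kernel_width, self.oversampling))
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def grid_size(self) -> int:
        return int(round(self.matrix * self.oversampling))


def kb_kernel(u, params: GridParams):
    """Kaiser-Bessel kernel in grid-cell units; 1 at u = 0, 0 outside W/2."""
    u = np.asarray(u, dtype=float)
    w, beta = params.kernel_width, params.beta
    arg = 1.0 - (2.0 * u / w) ** 2
    inside = arg > 0
    val = np.zeros_like(u)
    val[inside] = i0(beta * np.sqrt(arg[inside])) / i0(beta)
    return val


def kb_fourier(xi, kernel_width: float, beta: float):
    """Continuous Fourier transform of the (unit-peak) KB kernel.

    ``xi`` is in cycles per grid cell; the analytic pair is
    F(xi) = W/I0(beta) * sinh(sqrt(beta^2 - (pi W xi)^2)) / sqrt(...),
    with sinh -> sin for imaginary argument.
    """
    xi = np.asarray(xi, dtype=float)
    w = kernel_width
    z2 = beta ** 2 - (np.pi * w * xi) ** 2
    out = np.empty_like(xi)
    pos = z2 > 1e-12
    neg = z2 < -1e-12
    mid = ~(pos | neg)
    zp = np.sqrt(z2[pos])
    out[pos] = np.sinh(zp) / zp
    zn = np.sqrt(-z2[neg])
    out[neg] = np.sin(zn) / zn
    out[mid] = 1.0
    return w / i0(beta) * out


# ---------------------------------------------------------------------------

def bin_spokes(gating: GatingResult, n_frames: int) -> np.ndarray:
    """Frame index per spoke: floor(phase * n_frames); rejected -> -1."""
    if n_frames < 2:
        raise ValueError("need at least 2 cardiac frames")
    frame = np.floor(gating.cardiac_phase * n_frames).astype(int)
    frame = np.clip(frame, 0, n_frames - 1)
    frame[~gating.accepted] = -1
    return frame


def density_weights(k_radii: np.ndarray, spokes_in_frame: int) -> np.ndarray:
    """Ramp density-compensation weights per radial sample.

    w_j is proportional to |k_j| (the analytic radial density correction:
    each sample owns an annular sector of area |k_j| * dk * 2*pi/spokes),
    scaled so the weighted adjoint approximates the continuous inverse
    Fourier integral and the reconstruction amplitude is independent of
    how many spokes land in a frame.  The k = 0 sample is shared by all
    spokes of the frame: its finite weight |k_1|/8 makes the summed
    center weight equal the area of the center disc of radius dk/2.
    """
    if spokes_in_frame < 1:
        raise ValueError("spokes_in_frame must be >= 1")
    k = np.asarray(k_radii, dtype=float)
    dk = k[1] - k[0] if len(k) > 1 else 1.0
    w = np.abs(k) * dk * (2.0 * np.pi / spokes_in_frame)
    w[0] = (dk / 8.0) * dk * (2.0 * np.pi / spokes_in_frame)
    return w


def _spoke_k_coords(angles: np.ndarray, k_radii: np.ndarray):
    kx = np.cos(angles)[:, None] * k_radii[None, :]
    ky = np.sin(angles)[:, None] * k_radii[None, :]
    return kx, ky


def _grid_complex(data, angles, k_radii, weights, params: GridParams, fov: float):
    """Complex gridded image before the magnitude is taken."""
    G = params.grid_size
    W = params.kernel_width
    dk = 1.0 / (fov * params.oversampling)
    kx, ky = _spoke_k_coords(np.asarray(angles, float), np.asarray(k_radii, float))
    wd = (np.asarray(data) * np.broadcast_to(weights, np.asarray(data).shape)).ravel()
    gx = (kx / dk + G / 2).ravel()
    gy = (ky / dk + G / 2).ravel()
    grid = np.zeros((G, G), dtype=complex)
    base_x = np.ceil(gx - W / 2.0).astype(int)
    base_y = np.ceil(gy - W / 2.0).astype(int)
    # precompute separable kernel values for the W cells in each dimension
    kern_x = np.empty((len(gx), W))
    kern_y = np.empty((len(gy), W))
    cells_x = np.empty((len(gx), W), dtype=int)
    cells_y = np.empty((len(gy), W), dtype=int)
    for o in range(W):
        cx = base_x + o
        cy = base_y + o
        kern_x[:, o] = kb_kernel(cx - gx, params)
        kern_y[:, o] = kb_kernel(cy - gy, params)
        cells_x[:, o] = cx % G
        cells_y[:, o] = cy % G
    for ox in range(W):
        for oy in range(W):
            np.add.at(grid,
                      (cells_y[:, oy], cells_x[:, ox]),
                      wd * kern_x[:, ox] * kern_y[:, oy])
    # image_grid[x_n] = sum_m grid[m] exp(+2 pi i k_m . x_n)
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * G * G
    # central crop and deapodization
    m = params.matrix
    lo = (G - m) // 2
    img = img[lo:lo + m, lo:lo + m]
    x = np.arange(m) - m / 2
    xi = x / (m * params.oversampling)  # = x_pixel * dk in cycles/cell
    deap = kb_fourier(xi, W, params.beta)
    img = img / np.outer(deap, deap)
    return img


def grid_and_reconstruct_frame(data, angles, k_radii, weights,
                               params: GridParams, fov: float) -> np.ndarray:
    """Magnitude image of one frame's spokes via KB gridding."""
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError("cannot reconstruct an empty frame")
    return np.abs(_grid_complex(data, angles, k_radii, weights, params, fov))


def adjoint_ndft_oracle(data, angles, k_radii, weights, matrix: int,
                        fov: float) -> np.ndarray:
    """Brute-force adjoint NDFT: image[x] = sum_j w_j d_j exp(+2 pi i k_j.x).

    O(N_samples * matrix^2); matrix is capped at 64 to keep it a test
    oracle, not a reconstruction path.
    """
    if matrix > 64:
        raise ValueError("oracle restricted to matrix <= 64")
    data = np.asarray(data)
    kx, ky = _spoke_k_coords(np.asarray(angles, float), np.asarray(k_radii, float))
    wd = (data * np.broadcast_to(weights, data.shape)).ravel()
    x = (np.arange(matrix) - matrix / 2) * (fov / matrix)
    ex = np.exp(2j * np.pi * np.outer(kx.ravel(), x))
    ey = np.exp(2j * np.pi * np.outer(ky.ravel(), x))
    return np.einsum("j,jy,jx->yx", wd, ey, ex)


# ---------------------------------------------------------------------------

@dataclass
class CineFrameSet:
    """Reconstructed magnitude cine, [n_slices, n_frames, matrix, matrix]."""

    frames: np.ndarray
    frame_phase_centers: np.ndarray     # [0,1) per frame
    spokes_per_frame: np.ndarray        # [n_slices, n_frames]
    pixel_size: float                   # mm
    slice_thickness: float = 1.0        # mm

    @property
    def n_slices(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    def save_nifti(self, path) -> None:
        """NIfTI-1 with dims [x, y, slice, frame] and a JSON phase sidecar."""
        arr = np.transpose(self.frames, (3, 2, 0, 1))  # x, y, slice, frame
        affine = np.diag([self.pixel_size, self.pixel_size, self.slice_thickness, 1.0])
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))
        sidecar = {"frame_phase_centers": self.frame_phase_centers.tolist(),
                   "spokes_per_frame": self.spokes_per_frame.tolist(),
                   "pixel_size_mm": self.pixel_size,
                   "slice_thickness_mm": self.slice_thickness}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load_nifti(cls, path) -> "CineFrameSet":
        img = nib.load(str(path))
        arr = np.transpose(np.asarray(img.dataobj), (2, 3, 1, 0))
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        return cls(frames=arr.astype(float),
                   frame_phase_centers=np.asarray(side["frame_phase_centers"]),
                   spokes_per_frame=np.asarray(side["spokes_per_frame"]),
                   pixel_size=side["pixel_size_mm"],
                   slice_thickness=side["slice_thickness_mm"])


def reconstruct_cine(spokes: SpokeSet, gating: GatingResult, n_frames: int = 16,
                     grid_params: GridParams | None = None) -> CineFrameSet:
    """Per-slice, per-frame KB-gridding reconstruction of the cine."""
    if gating.n_spokes != spokes.n_spokes:
        raise ValueError("gating does not cover the SpokeSet")
    params = spokes.params
    gp = grid_params or GridParams(matrix=params.matrix)
    frame_of = bin_spokes(gating, n_frames)
    slices = spokes.slices
    frames = np.zeros((len(slices), n_frames, gp.matrix, gp.matrix))
    counts = np.zeros((len(slices), n_frames), dtype=int)
    for si, s in enumerate(slices):
        in_slice = spokes.slice_index == s
        for f in range(n_frames):
            sel = in_slice & (frame_of == f)
            nsp = int(sel.sum())
            if nsp == 0:
                raise ValueError(f"frame {f} of slice {s} is empty after gating")
            counts[si, f] = nsp
            w = density_weights(spokes.k_radii, nsp)
            frames[si, f] = grid_and_reconstruct_frame(
                spokes.data[sel], spokes.angle[sel], spokes.k_radii, w, gp, params.fov)
    return CineFrameSet(frames=frames,
                        frame_phase_centers=(np.arange(n_frames) + 0.5) / n_frames,
                        spokes_per_frame=counts,
                        pixel_size=params.fov / params.matrix,
                        slice_thickness=params.slice_thickness)
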