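"""Interferogram demodulation, Goldstein branch-cut unwrapping and height conversion.

An off-axis interferogram encodes the object phase on a spatial carrier,

    I(x, y) = a(x, y) + b(x, y) * cos(2*pi*(fy*y + fx*x) + phi(x, y)),

so a single frame suffices to recover ``phi`` by isolating one spectral
side lobe, shifting it to DC and taking the complex argument
(Fourier-transform fringe analysis).  The recovered phase is wrapped into
(-pi, pi]; the Goldstein branch-cut method restores continuity by pairing
phase residues with opposite-charge partners (or the image border) and
integrating along paths that avoid the cuts.  Under the uniform
refractive-index approximation the continuous phase maps linearly to
physical height:

    h = phi * lambda / (2*pi * pass_factor * delta_n)

with ``pass_factor`` 2 for a reflective (double-pass) geometry and
``delta_n`` the cell-medium refractive-index contrast.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Interferogram",
    "WrappedPhase",
    "UnwrappedPhase",
    "HeightMap",
    "NoCarrierError",
    "wrap_phase",
    "demodulate_fringes",
    "detect_residues",
    "unwrap_goldstein",
    "phase_to_height",
]

TWO_PI = 2.0 * np.pi

#: default illumination wavelength, red LED (um)
DEFAULT_WAVELENGTH_UM = 0.633
#: default refractive-index contrast: cytoplasm 1.37 vs medium 1.333
DEFAULT_DELTA_N = 0.037
#: default optical-path pass factor (reflective Linnik geometry, double pass)
DEFAULT_PASS_FACTOR = 2


class NoCarrierError(ValueError):
    """Raised when no off-axis carrier peak is present in the spectrum."""


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phase, dtype=float)))


@dataclass
class Interferogram:
    """Raw intensity fringe image with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    carrier_cycles_per_px: Optional[tuple[float, float]] = None  # (fy, fx)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("interferogram must be a 2D image")
        if min(self.pixels.shape) < 16:
            raise ValueError("interferogram dimensions must be >= 16 px")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("interferogram contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("interferogram intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class WrappedPhase:
    """Phase known modulo 2*pi, values in (-pi, pi]."""

    phase: np.ndarray
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("wrapped phase must be 2D")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("wrapped phase contains non-finite values")
        if np.any(self.phase > np.pi) or np.any(self.phase <= -np.pi):
            self.phase = wrap_phase(self.phase)


@dataclass
class UnwrappedPhase:
    """Continuous phase plus residue / branch-cut bookkeeping.

    ``offset_rad`` is the global constant subtracted so that the minimum of
    ``phase`` is zero; ``phase + offset_rad`` is congruent to the wrapped
    input modulo 2*pi at every pixel.
    """

    phase: np.ndarray
    n_residues_pos: int = 0
    n_residues_neg: int = 0
    branch_cut_px: int = 0
    offset_rad: float = 0.0


@dataclass
class HeightMap:
    """Physical height map (um) with calibration provenance."""

    height_um: np.ndarray
    pixel_size_um: float = 1.0
    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    delta_n: float = DEFAULT_DELTA_N
    pass_factor: int = DEFAULT_PASS_FACTOR

    def __post_init__(self) -> None:
        self.height_um = np.asarray(self.height_um, dtype=float)
        if not np.all(np.isfinite(self.height_um)):
            raise ValueError("height map contains non-finite values")
        for name in ("pixel_size_um", "wavelength_um", "delta_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _wrap_freq(f: np.ndarray) -> np.ndarray:
    """Map frequencies onto the principal interval [-0.5, 0.5)."""
    return (f + 0.5) % 1.0 - 0.5


def _find_carrier_peak(spectrum: np.ndarray, shape: tuple[int, int]) -> tuple[int, int]:
    """Locate the dominant non-DC peak; raise if none qualifies.

    The candidate is restricted to the canonical half-plane (fx > 0, or
    fx == 0 and fy > 0) so that the recovered phase keeps the sign of the
    rendered object term.
    """
    ny, nx = shape
    mag = np.abs(spectrum)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    half = (fx > 0) | ((fx == 0) & (fy > 0))
    # exclude a small DC neighbourhood (2 bins) where background leakage lives
    dc = (np.abs(fy) <= 2.0 / ny) & (np.abs(fx) <= 2.0 / nx)
    cand = half & ~dc
    if not np.any(cand):
        raise NoCarrierError("no carrier detected")
    masked = np.where(cand, mag, 0.0)
    ky, kx = np.unravel_index(int(np.argmax(masked)), mag.shape)
    peak = masked[ky, kx]
    if peak <= 0.0 or peak < 3.0 * np.median(mag):
        raise NoCarrierError("no carrier detected")
    return ky, kx


def demodulate_fringes(
    img: Interferogram,
    carrier: Optional[Sequence[float]] = None,
    window_halfwidth_factor: float = 0.4,
) -> WrappedPhase:
    """Recover the wrapped object phase from an off-axis interferogram.

    Parameters
    ----------
    img : Interferogram
        Fringe image containing a spatial carrier.
    carrier : (fy, fx), optional
        Carrier frequency in cycles/pixel.  Auto-detected from the spectrum
        when omitted (dominant non-DC peak, required to exceed 3x the median
        spectral magnitude).
    window_halfwidth_factor : float
        Half-width of the Gaussian side-lobe window, as a fraction of the
        carrier magnitude (in cycles/pixel).

    Returns
    -------
    WrappedPhase
        Object phase with the carrier removed, values in (-pi, pi].
    """
    pix = img.pixels
    ny, nx = pix.shape
    # Hann apodization suppresses the spectral leakage of a non-integer
    # carrier; the amplitude envelope it imposes does not affect the angle
    apod = np.outer(np.hanning(ny), np.hanning(nx))
    spectrum = np.fft.fft2((pix - pix.mean()) * apod)

    if carrier is None:
        carrier = img.carrier_cycles_per_px
    if carrier is not None:
        fcy, fcx = float(carrier[0]), float(carrier[1])
        if abs(fcy) >= 0.5 or abs(fcx) >= 0.5:
            raise ValueError("carrier must be below Nyquist (0.5 cycles/px)")
        if fcy == 0.0 and fcx == 0.0:
            raise NoCarrierError("no carrier detected")
        ky = int(np.round(fcy * ny)) % ny
        kx = int(np.round(fcx * nx)) % nx
        known_carrier = True
    else:
        ky, kx = _find_carrier_peak(spectrum, (ny, nx))
        fcy = np.fft.fftfreq(ny)[ky]
        fcx = np.fft.fftfreq(nx)[kx]
        known_carrier = False

    fmag = float(np.hypot(fcy, fcx))
    sigma = window_halfwidth_factor * fmag
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    d2 = _wrap_freq(fy - np.fft.fftfreq(ny)[ky]) ** 2 + _wrap_freq(
        fx - np.fft.fftfreq(nx)[kx]
    ) ** 2
    window = np.exp(-0.5 * d2 / sigma**2)

    # shift the windowed side lobe to DC by integer bins, then remove the
    # fractional carrier remainder as an exact linear ramp
    lobe = np.roll(spectrum * window, (-ky, -kx), axis=(0, 1))
    analytic = np.fft.ifft2(lobe)
    yy, xx = np.mgrid[0:ny, 0:nx]
    if known_carrier:
        ry = fcy - np.fft.fftfreq(ny)[ky]
        rx = fcx - np.fft.fftfreq(nx)[kx]
        analytic = analytic * np.exp(-1j * TWO_PI * (ry * yy + rx * xx))
    else:
        # residual (sub-bin) carrier removal: amplitude-weighted circular
        # mean of the phase slope, iterated to convergence
        for _ in range(2):
            ry = float(np.angle(np.mean(analytic[1:, :] * np.conj(analytic[:-1, :])))) / TWO_PI
            rx = float(np.angle(np.mean(analytic[:, 1:] * np.conj(analytic[:, :-1])))) / TWO_PI
            analytic = analytic * np.exp(-1j * TWO_PI * (ry * yy + rx * xx))
    return WrappedPhase(phase=np.angle(analytic))


def _loop_sums(phase: np.ndarray) -> np.ndarray:
    """Wrapped-gradient circulation around every 2x2 pixel loop / (2*pi)."""
    dx = wrap_phase(np.diff(phase, axis=1))  # (H, W-1) rightward steps
    dy = wrap_phase(np.diff(phase, axis=0))  # (H-1, W) downward steps
    circ = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return np.rint(circ / TWO_PI).astype(int)


def detect_residues(wp: WrappedPhase) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Find phase residues: 2x2 loops with +/-2*pi wrapped circulation.

    Returns (positive, negative) residue coordinates, each the (row, col) of
    the loop's top-left pixel, in row-major order.
    """
    charge = _loop_sums(wp.phase)
    pos = [tuple(rc) for rc in np.argwhere(charge > 0)]
    neg = [tuple(rc) for rc in np.argwhere(charge < 0)]
    return pos, neg


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """8-connected pixel chain between two pixels, endpoints included."""
    pts = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        pts.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


def _plan_branch_cuts(
    pos: list[tuple[int, int]],
    neg: list[tuple[int, int]],
    shape: tuple[int, int],
) -> np.ndarray:
    """Greedy nearest-partner branch cuts, rasterized onto the pixel grid.

    Candidates are all opposite-charge pairs plus each residue's nearest
    border exit; accepted in ascending distance order (ties row-major), each
    residue used once.  Returns a boolean cut mask.
    """
    ny, nx = shape
    cuts = np.zeros(shape, dtype=bool)
    residues = [(r, c, +1) for r, c in pos] + [(r, c, -1) for r, c in neg]
    if not residues:
        return cuts

    candidates = []  # (distance, i, j) with j == -1 meaning the border
    for i, (ra, ca, qa) in enumerate(residues):
        border_d = min(ra + 1, ca + 1, ny - 1 - ra, nx - 1 - ca)
        candidates.append((float(border_d), i, -1))
        for j in range(i + 1, len(residues)):
            rb, cb, qb = residues[j]
            if qa + qb == 0:
                candidates.append((float(np.hypot(ra - rb, ca - cb)), i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    paired = [False] * len(residues)
    for _, i, j in candidates:
        if paired[i] or (j >= 0 and paired[j]):
            continue
        ra, ca, _ = residues[i]
        if j >= 0:
            rb, cb, _ = residues[j]
            paired[j] = True
        else:
            # shortest straight run to the nearest border
            dists = {
                (0, ca): ra + 1, (ra, 0): ca + 1,
                (ny - 1, ca): ny - 1 - ra, (ra, nx - 1): nx - 1 - ca,
            }
            rb, cb = min(dists, key=lambda k: (dists[k], k))
        paired[i] = True
        for r, c in _bresenham(ra, ca, rb, cb):
            cuts[r, c] = True
    return cuts


def unwrap_goldstein(wp: WrappedPhase) -> UnwrappedPhase:
    """Unwrap a 2D phase image with the Goldstein branch-cut method.

    Residues are paired greedily by ascending Euclidean distance with
    opposite-charge partners or the nearest border; 4-connected breadth-first
    integration then propagates from the first non-cut pixel (row-major),
    never crossing a cut.  Cut pixels and regions isolated by cuts are filled
    afterwards from their nearest unwrapped neighbours, preserving congruence
    with the wrapped input modulo 2*pi; their count is reported in
    ``branch_cut_px``.  The output's global offset is chosen so its minimum
    is zero, with the subtracted constant recorded in ``offset_rad``.
    """
    phase = wp.phase
    ny, nx = phase.shape
    pos, neg = detect_residues(wp)
    cuts = _plan_branch_cuts(pos, neg, phase.shape)

    out = np.array(phase, dtype=float)
    if not pos and not neg:
        # residue-free: any integration path is valid; row/column cumsum
        col = np.concatenate(([phase[0, 0]], phase[0, 0] + np.cumsum(wrap_phase(np.diff(phase[:, 0])))))
        rows = np.concatenate(
            (col[:, None], wrap_phase(np.diff(phase, axis=1))), axis=1
        )
        out = np.cumsum(rows, axis=1)
        n_filled = 0
    else:
        visited = np.zeros(phase.shape, dtype=bool)
        free = ~cuts
        ref = None
        flat = np.flatnonzero(free.ravel())
        if flat.size:
            ref = divmod(int(flat[0]), nx)
        if ref is None:  # pathological: everything cut
            ref = (0, 0)
            free[:] = True
        queue = deque([ref])
        visited[ref] = True
        while queue:
            r, c = queue.popleft()
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < ny and 0 <= cc < nx and free[rr, cc] and not visited[rr, cc]:
                    out[rr, cc] = out[r, c] + wrap_phase(phase[rr, cc] - out[r, c])
                    visited[rr, cc] = True
                    queue.append((rr, cc))
        # second pass: fill cut pixels and cut-isolated regions from the
        # unwrapped frontier (nearest-neighbour in BFS order)
        n_filled = int(np.count_nonzero(~visited))
        queue = deque(map(tuple, np.argwhere(visited)))
        while queue:
            r, c = queue.popleft()
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < ny and 0 <= cc < nx and not visited[rr, cc]:
                    out[rr, cc] = out[r, c] + wrap_phase(phase[rr, cc] - out[r, c])
                    visited[rr, cc] = True
                    queue.append((rr, cc))

    offset = float(out.min())
    return UnwrappedPhase(
        phase=out - offset,
        n_residues_pos=len(pos),
        n_residues_neg=len(neg),
        branch_cut_px=int(np.count_nonzero(cuts)) + (n_filled if (pos or neg) else 0),
        offset_rad=offset,
    )


def phase_to_height(
    up: UnwrappedPhase | np.ndarray,
    wavelength_um: float = DEFAULT_WAVELENGTH_UM,
    delta_n: float = DEFAULT_DELTA_N,
    pass_factor: int = DEFAULT_PASS_FACTOR,
    pixel_size_um: float = 1.0,
) -> HeightMap:
    """Convert continuous phase (rad) to physical height (um).

    h = phi * lambda / (2*pi * pass_factor * delta_n); linear in phase.
    """
    if delta_n <= 0:
        raise ValueError("delta_n must be positive")
    if pass_factor not in (1, 2):
        raise ValueError("pass_factor must be 1 (single pass) or 2 (double pass)")
    phi = up.phase if isinstance(up, UnwrappedPhase) else np.asarray(up, dtype=float)
    h = phi * wavelength_um / (TWO_PI * pass_factor * delta_n)
    return HeightMap(
        height_um=h,
        pixel_size_um=pixel_size_um,
        wavelength_um=wavelength_um,
        delta_n=delta_n,
        pass_factor=pass_factor,
    )
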