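"""Complex 2-D Morlet filter banks and the Gaussian scaling filter.

Filters are designed and applied in the frequency domain.  A scattering
configuration induces two oriented Morlet banks (one per cascade stage) and a
single isotropic Gaussian low-pass whose spatial support is bounded by the
invariance scale.  Each bank spans ``J = floor(log2 s)`` octaves with ``q``
wavelets per octave at geometric spacing ``2^(1/q)``, each realized at ``r``
rotations linearly spaced over [0, pi).

The Morlet wavelet is an oriented complex exponential tapered by an
anisotropic Gaussian, minus a Gaussian-weighted correction that makes the
spatial mean exactly zero (admissibility).  With a zero-phase (centred)
envelope its frequency response is real:

    psi_hat(w) = exp(-((u - xi)^2 / (2 su^2) + v^2 / (2 sv^2)))
                 - beta * exp(-(u^2 / (2 su^2) + v^2 / (2 sv^2)))

where (u, v) are frequency coordinates rotated into the wavelet frame,
``xi`` is the radial centre frequency and ``beta = exp(-xi^2 / (2 su^2))``
zeroes the DC response.  The radial width ``su`` shrinks as ``1/q`` (finer
scale resolution at higher quality factor) while the angular width ``sv``
is tied to the rotation count so that the ``r`` orientations tile angle
uniformly at every quality factor; at q = 1 and r = 6 this reproduces the
conventional Morlet aspect ratio of about one half.

After construction every bank is rescaled by a single Littlewood-Paley
factor so that the summed filter energy never exceeds one anywhere on the
frequency grid, which makes each cascade stage non-expansive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.fft import next_fast_len

from .preprocessing import ConfigurationError

#: Radial centre frequency of the finest wavelet (radians/pixel).
XI_MAX = 3.0 * np.pi / 4.0

#: Radial bandwidth factor: frequency std of a wavelet is 1/(SIGMA0 * q * a).
SIGMA0 = 0.8

#: Angular width divisor: the cross (angular) frequency std of a wavelet is
#: xi * sin(pi / (2 r)) / ANGULAR_TIGHTNESS.  Values below 1 widen the
#: orientation lobes so the r rotations tile angle without deep gaps.
ANGULAR_TIGHTNESS = 0.8

#: Fraction of the scaling filter's mass that must fit inside the invariance
#: scale (diameter), defining its Gaussian std: sigma = s / PHI_SUPPORT_FACTOR.
#: 2*sqrt(chi2_2(0.99)) ~ 6.07 puts 99% of a 2-D Gaussian's radial mass inside
#: the diameter; the extra 3% margin absorbs pixel-grid quantization so the
#: bound holds for the sampled kernel as well.
PHI_SUPPORT_FACTOR = 2.0 * math.sqrt(9.21034) * 1.03


@dataclass(frozen=True)
class ScatteringConfig:
    """Parameter triple (invariance scale, quality factors, rotations).

    ``invariance_scale`` bounds the spatial support of every filter in
    pixels; ``quality_factors`` gives the wavelets per octave in banks 1 and
    2; ``num_rotations`` applies per wavelet per bank.  ``boundary`` selects
    symmetric padding (default; suppresses wrap-around) or plain periodic
    convolutions.
    """

    invariance_scale: float = 150.0
    quality_factors: tuple[int, int] = (1, 1)
    num_rotations: int = 6
    image_size: tuple[int, int] = (300, 300)
    boundary: str = "symmetric"
    xi_max: float = XI_MAX
    sigma0: float = SIGMA0

    def __post_init__(self) -> None:
        s = self.invariance_scale
        if s < 4:
            raise ConfigurationError(
                f"invariance scale {s} supports fewer than 2 octaves (need s >= 4)"
            )
        q1, q2 = self.quality_factors
        if q1 < 1 or q2 < 1 or q1 != int(q1) or q2 != int(q2):
            raise ConfigurationError(f"quality factors must be positive integers, got {q1, q2}")
        if self.num_rotations < 1:
            raise ConfigurationError("num_rotations must be >= 1")
        if min(self.image_size) < 2:
            raise ConfigurationError(f"degenerate image size {self.image_size}")
        if self.boundary not in ("symmetric", "periodic"):
            raise ConfigurationError(f"unknown boundary mode {self.boundary!r}")

    @property
    def num_octaves(self) -> int:
        """Dyadic octave count J = floor(log2 s)."""
        return int(math.floor(math.log2(self.invariance_scale)))

    @property
    def pad_width(self) -> int:
        return int(self.invariance_scale) // 2 if self.boundary == "symmetric" else 0

    @property
    def grid_shape(self) -> tuple[int, int]:
        """FFT grid: image plus padding, rounded up to an FFT-friendly size
        divisible by the largest second-stage subsampling stride 2^(J-2)."""
        divisor = max(2 ** (self.num_octaves - 2), 1)

        def fit(n: int) -> int:
            n = next_fast_len(n)
            while n % divisor:
                n = next_fast_len(n + 1)
            return n

        r, c = self.image_size
        p = self.pad_width
        return fit(r + 2 * p), fit(c + 2 * p)

    @property
    def subsample_stride(self) -> int:
        return 2 ** self.num_octaves

    @property
    def output_shape(self) -> tuple[int, int]:
        r, c = self.image_size
        d = self.subsample_stride
        return math.ceil(r / d), math.ceil(c / d)

    def to_dict(self) -> dict:
        return {
            "invariance_scale": self.invariance_scale,
            "quality_factors": list(self.quality_factors),
            "num_rotations": self.num_rotations,
            "image_size": list(self.image_size),
            "boundary": self.boundary,
            "xi_max": self.xi_max,
            "sigma0": self.sigma0,
            "num_octaves": self.num_octaves,
            "grid_shape": list(self.grid_shape),
            "subsample_stride": self.subsample_stride,
        }


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Angular frequency grids (radians/pixel) for rows and columns."""
    wr = 2.0 * np.pi * np.fft.fftfreq(shape[0])[:, None]
    wc = 2.0 * np.pi * np.fft.fftfreq(shape[1])[None, :]
    return wr, wc


def _negate_freq(a: np.ndarray) -> np.ndarray:
    """a(w) -> a(-w) on the FFT index grid."""
    return np.roll(a[::-1, ::-1], shift=1, axis=(0, 1))


def morlet_response(
    shape: tuple[int, int],
    scale: float,
    theta: float,
    q: int = 1,
    num_rotations: int = 6,
    xi_max: float = XI_MAX,
    sigma0: float = SIGMA0,
) -> np.ndarray:
    """Raw (unnormalized) Morlet frequency response on an FFT grid.

    ``scale`` is the dilation a > 0: the centre frequency is xi_max / a and
    the radial frequency width 1/(sigma0 * q * a).
    """
    if scale <= 0:
        raise ConfigurationError(f"wavelet scale must be positive, got {scale}")
    xi = xi_max / scale
    sigma_u = 1.0 / (sigma0 * q * scale)
    sigma_v = xi * math.sin(np.pi / (2.0 * num_rotations)) / ANGULAR_TIGHTNESS
    wr, wc = _freq_grids(shape)
    # rotate frequency coordinates into the wavelet frame
    u = wc * math.cos(theta) + wr * math.sin(theta)
    v = -wc * math.sin(theta) + wr * math.cos(theta)
    envelope = np.exp(-(u - xi) ** 2 / (2 * sigma_u**2) - v**2 / (2 * sigma_v**2))
    correction = np.exp(-(u**2) / (2 * sigma_u**2) - v**2 / (2 * sigma_v**2))
    beta = math.exp(-(xi**2) / (2 * sigma_u**2))
    return envelope - beta * correction


@dataclass
class Wavelet:
    """One oriented Morlet, stored lazily in the frequency domain."""

    bank: int                 # cascade stage, 1 or 2
    scale_index: int          # m: fractional-octave index, scale a = 2^(m/q)
    rotation_index: int
    theta: float              # radians in [0, pi)
    scale: float
    center_frequency: float   # radial, radians/pixel
    quality_factor: int
    _owner: "FilterBank" = field(repr=False, default=None)

    @property
    def octave(self) -> int:
        return self.scale_index // self.quality_factor

    @property
    def is_octave_representative(self) -> bool:
        return self.scale_index % self.quality_factor == 0

    @property
    def freq_response(self) -> np.ndarray:
        """Littlewood-Paley-normalized frequency response (real array)."""
        return self._owner._response(self)


class FilterBank:
    """An ordered Morlet bank sharing one scaling filter and one LP factor."""

    def __init__(self, config: ScatteringConfig, bank: int):
        self.config = config
        self.bank = bank
        q = config.quality_factors[bank - 1]
        self.quality_factor = q
        r = config.num_rotations
        self.wavelets: list[Wavelet] = []
        for m in range(q * config.num_octaves):
            a = 2.0 ** (m / q)
            for l in range(r):
                theta = l * np.pi / r
                self.wavelets.append(
                    Wavelet(
                        bank=bank,
                        scale_index=m,
                        rotation_index=l,
                        theta=theta,
                        scale=a,
                        center_frequency=config.xi_max / a,
                        quality_factor=q,
                        _owner=self,
                    )
                )
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        self._norm: tuple[np.ndarray, float, np.ndarray] | None = None

    @property
    def num_octaves(self) -> int:
        return self.config.num_octaves

    @cached_property
    def scaling_filter(self) -> np.ndarray:
        return gaussian_scaling(self.config.invariance_scale, self.config.grid_shape)

    def _raw(self, w: Wavelet) -> np.ndarray:
        return morlet_response(
            self.config.grid_shape, w.scale, w.theta,
            q=self.quality_factor, num_rotations=self.config.num_rotations,
            xi_max=self.config.xi_max, sigma0=self.config.sigma0,
        )

    def _normalization(self) -> tuple[np.ndarray, float, np.ndarray]:
        """Littlewood-Paley normalization: per-scale weights plus safety factor.

        The coarsest wavelets of a bank overlap the scaling filter's passband
        (their centre frequencies lie inside it whenever q > 1 or J is close
        to log2 s), so a single global factor would be dragged far below one
        by the low-frequency crossover and leave the mid-band badly
        under-covered.  Instead each scale m receives a weight gamma_m that
        shapes the summed wavelet energy toward the complement 1 - |phi|^2 of
        the scaling filter (evaluated on the scale's own frequency ring), and
        a final global factor c <= 1 enforces the hard frame bound
        |phi|^2 + E <= 1 everywhere off the Nyquist ring.

        Returns (gamma per scale_index, c, weighted energy E before c).
        """
        if self._norm is not None:
            return self._norm
        cfg = self.config
        grid = cfg.grid_shape
        wr, wc = _freq_grids(grid)
        radius = np.hypot(*np.broadcast_arrays(wr, wc))
        phi2 = self.scaling_filter**2
        sigma_phi = cfg.invariance_scale / PHI_SUPPORT_FACTOR

        raw = np.zeros(grid)
        for w in self.wavelets:
            p2 = self._raw(w) ** 2
            raw += 0.5 * (p2 + _negate_freq(p2))

        q = self.quality_factor
        half = 2.0 ** (1.0 / (2 * q))
        n_scales = q * cfg.num_octaves
        gammas = np.ones(n_scales)
        for m in range(n_scales):
            xi = cfg.xi_max / 2.0 ** (m / q)
            ring = (radius >= xi / half) & (radius <= xi * half)
            if not ring.any():  # degenerate tiny grids: nearest point
                ring = np.abs(radius - xi) <= np.abs(radius - xi).min() + 1e-12
            target = 1.0 - math.exp(-(sigma_phi**2) * xi**2)
            achieved = float(raw[ring].mean())
            gammas[m] = min(math.sqrt(max(target, 1e-12) / max(achieved, 1e-12)), 3.0)

        energy = np.zeros(grid)
        for w in self.wavelets:
            p2 = (gammas[w.scale_index] * self._raw(w)) ** 2
            energy += 0.5 * (p2 + _negate_freq(p2))
        mask = _off_nyquist_mask(grid) & (energy > 1e-12 * energy.max())
        c = float(np.min((1.0 - phi2[mask]) / energy[mask]))
        self._norm = (gammas, c, energy)
        return self._norm

    @property
    def lp_factor(self) -> float:
        """Global safety factor c of the Littlewood-Paley normalization."""
        return self._normalization()[1]

    def _response(self, w: Wavelet) -> np.ndarray:
        key = (w.scale_index, w.rotation_index)
        if key not in self._cache:
            gammas, c, _ = self._normalization()
            self._cache[key] = math.sqrt(c) * gammas[w.scale_index] * self._raw(w)
        return self._cache[key]

    def octave_representatives(self) -> list[Wavelet]:
        """First wavelet of each octave, all rotations (dyadic skeleton)."""
        return [w for w in self.wavelets if w.is_octave_representative]

    def __len__(self) -> int:
        return len(self.wavelets)


def gaussian_scaling(s: float, shape: tuple[int, int]) -> np.ndarray:
    """Isotropic Gaussian low-pass with unit DC gain.

    The spatial std is s / PHI_SUPPORT_FACTOR, so the disc containing 99% of
    the kernel's mass has diameter <= s pixels (the invariance scale bounds
    the filter's effective support).
    """
    if s <= 0:
        raise ConfigurationError(f"invariance scale must be positive, got {s}")
    sigma = s / PHI_SUPPORT_FACTOR
    wr, wc = _freq_grids(shape)
    return np.exp(-(sigma**2) * (wr**2 + wc**2) / 2.0)


def build_filterbanks(config: ScatteringConfig) -> tuple[FilterBank, FilterBank, np.ndarray]:
    """Construct the two Morlet banks and the shared Gaussian scaling filter.

    Filter arrays are realized lazily, so building is cheap; the first access
    to any frequency response triggers the Littlewood-Paley normalization of
    its bank.
    """
    bank1 = FilterBank(config, 1)
    bank2 = FilterBank(config, 2)
    return bank1, bank2, bank1.scaling_filter


def _off_nyquist_mask(shape: tuple[int, int]) -> np.ndarray:
    """True away from the outermost (Nyquist) frequency ring."""
    masks = []
    for n in shape:
        idx = np.abs(np.fft.fftfreq(n) * n)
        masks.append(idx != idx.max())
    return masks[0][:, None] & masks[1][None, :]


@dataclass(frozen=True)
class FrameBounds:
    """Littlewood-Paley energy summary for one bank plus the scaling filter.

    ``min``/``max`` are taken over the retained band (the closed disc of
    radius xi_max, i.e. up to the finest wavelet's centre frequency, which
    excludes the outermost Nyquist ring); ``max_grid`` is the maximum over
    the whole grid away from the Nyquist ring.
    """

    min: float
    max: float
    max_grid: float


def littlewood_paley(bank: FilterBank, phi: np.ndarray | None = None) -> FrameBounds:
    """Frame-bound summary min/max of |phi|^2 + 1/2 sum(|psi|^2 + |psi(-.)|^2)."""
    config = bank.config
    if phi is None:
        phi = bank.scaling_filter
    total = phi.astype(np.float64) ** 2
    if len(bank.wavelets) > 0:
        _, c, energy = bank._normalization()
        total = total + c * energy
    wr, wc = _freq_grids(config.grid_shape)
    radius = np.sqrt(wr**2 + wc**2)
    off_ny = _off_nyquist_mask(config.grid_shape)
    band = (radius <= config.xi_max) & off_ny
    return FrameBounds(
        min=float(total[band].min()),
        max=float(total[band].max()),
        max_grid=float(total[off_ny].max()),
    )
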