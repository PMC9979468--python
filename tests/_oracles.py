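"""Brute-force reference computations, independent of the fast transform.

These implement the scattering cascade with direct circular spatial
convolutions and explicit per-cell pooling loops, at a cost only bearable on
tiny grids.  They deliberately avoid the package's FFT pipeline and pooling
matrices so the two routes stay independent.
"""

import numpy as np


def circular_convolve(f: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N^4) circular convolution (no fast transform)."""
    n1, n2 = f.shape
    out = np.zeros(f.shape, dtype=complex)
    flipped = kernel[::-1, ::-1]
    for a in range(n1):
        rolled_a = np.roll(flipped, a + 1, axis=0)
        for b in range(n2):
            out[a, b] = np.sum(f * np.roll(rolled_a, b + 1, axis=1))
    return out


def cell_means(field: np.ndarray, y: int, z: int) -> np.ndarray:
    """Equal-area fractional-cell averages by explicit per-pixel overlap."""
    n1, n2 = field.shape
    h1, h2 = n1 / y, n2 / z
    out = np.zeros((y, z))
    for i in range(y):
        for j in range(z):
            acc = 0.0
            for p in range(n1):
                w1 = max(0.0, min(p + 1, (i + 1) * h1) - max(p, i * h1))
                if w1 == 0.0:
                    continue
                for q in range(n2):
                    w2 = max(0.0, min(q + 1, (j + 1) * h2) - max(q, j * h2))
                    if w2 > 0.0:
                        acc += w1 * w2 * field[p, q]
            out[i, j] = acc / (h1 * h2)
    return out


def coarse_cell_means(field_c: np.ndarray, d: int, y: int, z: int) -> np.ndarray:
    """Cell averages from a stride-d sampled field, each sample standing for
    the d-pixel segment it was drawn from (weights renormalized per cell)."""
    n1, n2 = field_c.shape
    h1, h2 = n1 * d / y, n2 * d / z
    out = np.zeros((y, z))
    for i in range(y):
        for j in range(z):
            acc, wsum = 0.0, 0.0
            for p in range(n1):
                w1 = max(0.0, min((p + 1) * d, (i + 1) * h1) - max(p * d, i * h1))
                if w1 == 0.0:
                    continue
                for q in range(n2):
                    w2 = max(0.0, min((q + 1) * d, (j + 1) * h2) - max(q * d, j * h2))
                    if w2 > 0.0:
                        acc += w1 * w2 * field_c[p, q]
                        wsum += w1 * w2
            out[i, j] = acc / wsum
    return out


def scatter_direct(f: np.ndarray, bank1, bank2, phi: np.ndarray,
                   octave_gap: int, y: int, z: int) -> np.ndarray:
    """Full cascade via direct spatial convolution (periodic, unpadded).

    Second-order maps are critically sampled at stride d = 2^(j2 - 1): the
    modulus field is subsampled, smoothed with the stride-sampled periodic
    Gaussian kernel (times d^2, the subsampling identity for kernels), and
    cell-averaged on the coarse grid — mirroring the documented algorithm
    through an independent spatial-domain route.
    """
    n1, n2 = f.shape
    phi_kernel = np.fft.ifft2(phi)
    maps = [cell_means(circular_convolve(f, phi_kernel).real, y, z)]
    second = []
    reps2 = [w for w in bank2.wavelets if w.is_octave_representative]
    for w1 in bank1.wavelets:
        u1 = np.abs(circular_convolve(f, np.fft.ifft2(w1.freq_response)))
        maps.append(cell_means(circular_convolve(u1, phi_kernel).real, y, z))
        if w1.is_octave_representative:
            for w2 in reps2:
                if w2.octave >= w1.octave + octave_gap:
                    d = 2 ** (w2.octave - 1)
                    u2 = np.abs(circular_convolve(u1, np.fft.ifft2(w2.freq_response)))
                    u2c = u2[::d, ::d]
                    idx1 = (np.arange(n1 // d) * d) % n1
                    idx2 = (np.arange(n2 // d) * d) % n2
                    phi_c = d * d * phi_kernel.real[np.ix_(idx1, idx2)]
                    smooth = circular_convolve(u2c, phi_c).real
                    second.append(coarse_cell_means(smooth, d, y, z))
    return np.stack(maps + second, axis=0)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return float(t), float(p)
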