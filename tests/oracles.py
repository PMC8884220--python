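"""Independent brute-force oracles shared across test modules."""

import numpy as np

from edofuse.metrics import gaussian_window


def ssim_windowed_oracle(x, y, data_range):
    """Direct per-window evaluation of the SSIM formula (11x11 Gaussian)."""
    win = gaussian_window(11, 1.5)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = x.shape
    vals = []
    for i in range(h - 10):
        for j in range(w - 10):
            wx = x[i : i + 11, j : j + 11]
            wy = y[i : i + 11, j : j + 11]
            mx = (win * wx).sum()
            my = (win * wy).sum()
            vx = (win * wx * wx).sum() - mx**2
            vy = (win * wy * wy).sum() - my**2
            cov = (win * wx * wy).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * cov + c2))
                        / ((mx**2 + my**2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def dft_oracle(d):
    """2-D DFT via explicit basis matrices (independent of np.fft)."""
    h, w = d.shape
    jh = np.arange(h)
    jw = np.arange(w)
    wh = np.exp(-2j * np.pi * np.outer(jh, jh) / h)
    ww = np.exp(-2j * np.pi * np.outer(jw, jw) / w)
    return wh @ d @ ww
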