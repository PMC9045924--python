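"""Independent reference implementations used only to validate the package.

These deliberately share no code path with ``desmoke``: the Mie oracle
evaluates the partial-wave coefficients through arbitrary-precision complex
Bessel functions (mpmath) instead of recurrences, and the color-difference
oracle is a literal step-by-step transcription of the CIEDE2000 formula.
"""

from __future__ import annotations

import math

import mpmath as mp
import numpy as np


def mie_oracle(diameter: float, wavelength: float, particle_index: complex,
               medium_index: float = 1.0, dps: int = 40,
               order_factor: float = 1.0) -> tuple[float, float, float]:
    """(q_ext, q_sca, g) via high-precision Bessel-function evaluation.

    ``order_factor`` multiplies the Wiscombe truncation order to verify
    series convergence (e.g. 10 for a 10x-order check).
    """
    mp.mp.dps = dps
    x = mp.pi * diameter * medium_index / wavelength
    nmax = int(math.ceil(float(x) + 4.0 * float(x) ** (1 / 3) + 2.0)
               * order_factor)
    m = mp.mpc(particle_index) / medium_index
    mx = m * x

    def psi(n, z):
        return mp.sqrt(mp.pi * z / 2) * mp.besselj(n + mp.mpf(1) / 2, z)

    def xi(n, z):
        return mp.sqrt(mp.pi * z / 2) * (
            mp.besselj(n + mp.mpf(1) / 2, z)
            + 1j * mp.bessely(n + mp.mpf(1) / 2, z))

    q_sca = mp.mpf(0)
    q_ext = mp.mpf(0)
    ab = []
    for n in range(1, nmax + 1):
        pmx, pmx1 = psi(n, mx), psi(n - 1, mx)
        px, px1 = psi(n, x), psi(n - 1, x)
        xx, xx1 = xi(n, x), xi(n - 1, x)
        dpmx = pmx1 - n / mx * pmx
        dpx = px1 - n / x * px
        dxx = xx1 - n / x * xx
        a = (m * pmx * dpx - px * dpmx) / (m * pmx * dxx - xx * dpmx)
        b = (pmx * dpx - m * px * dpmx) / (pmx * dxx - m * xx * dpmx)
        ab.append((a, b))
        q_sca += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
        q_ext += (2 * n + 1) * (a.real + b.real)
    g_num = mp.mpf(0)
    for n in range(1, nmax):
        a, b = ab[n - 1]
        a1, b1 = ab[n]
        g_num += (mp.mpf(n) * (n + 2) / (n + 1)
                  * (a * mp.conj(a1) + b * mp.conj(b1)).real)
    for n in range(1, nmax + 1):
        a, b = ab[n - 1]
        g_num += mp.mpf(2 * n + 1) / (n * (n + 1)) * (a * mp.conj(b)).real
    q_sca *= 2 / x**2
    q_ext *= 2 / x**2
    g = 4 / x**2 * g_num / q_sca
    return float(q_ext), float(q_sca), float(g)


def ciede2000_oracle(lab1, lab2) -> float:
    """Literal CIEDE2000 (Sharma, Wu & Dalal 2005) for one Lab pair."""
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = (C1 + C2) / 2.0
    G = 0.5 * (1.0 - math.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    ap1 = (1.0 + G) * a1
    ap2 = (1.0 + G) * a2
    Cp1 = math.hypot(ap1, b1)
    Cp2 = math.hypot(ap2, b2)

    def hue(ap, b):
        if ap == 0.0 and b == 0.0:
            return 0.0
        h = math.degrees(math.atan2(b, ap))
        return h + 360.0 if h < 0 else h

    hp1 = hue(ap1, b1)
    hp2 = hue(ap2, b2)

    dLp = L2 - L1
    dCp = Cp2 - Cp1
    if Cp1 * Cp2 == 0.0:
        dhp = 0.0
    else:
        dh = hp2 - hp1
        if dh > 180.0:
            dh -= 360.0
        elif dh < -180.0:
            dh += 360.0
        dhp = dh
    dHp = 2.0 * math.sqrt(Cp1 * Cp2) * math.sin(math.radians(dhp) / 2.0)

    Lbp = (L1 + L2) / 2.0
    Cbp = (Cp1 + Cp2) / 2.0
    if Cp1 * Cp2 == 0.0:
        hbp = hp1 + hp2
    else:
        s = hp1 + hp2
        d = abs(hp1 - hp2)
        if d <= 180.0:
            hbp = s / 2.0
        elif s < 360.0:
            hbp = (s + 360.0) / 2.0
        else:
            hbp = (s - 360.0) / 2.0
    T = (1.0 - 0.17 * math.cos(math.radians(hbp - 30.0))
         + 0.24 * math.cos(math.radians(2.0 * hbp))
         + 0.32 * math.cos(math.radians(3.0 * hbp + 6.0))
         - 0.20 * math.cos(math.radians(4.0 * hbp - 63.0)))
    dtheta = 30.0 * math.exp(-(((hbp - 275.0) / 25.0) ** 2))
    Rc = 2.0 * math.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    Sl = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / math.sqrt(20.0 + (Lbp - 50.0) ** 2)
    Sc = 1.0 + 0.045 * Cbp
    Sh = 1.0 + 0.015 * Cbp * T
    Rt = -math.sin(math.radians(2.0 * dtheta)) * Rc
    return math.sqrt((dLp / Sl) ** 2 + (dCp / Sc) ** 2 + (dHp / Sh) ** 2
                     + Rt * (dCp / Sc) * (dHp / Sh))


def ssim_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Plain uniform-window 8x8 SSIM used only for sanity bounds."""
    k1, k2 = 0.01, 0.03
    c1, c2 = (k1) ** 2, (k2) ** 2
    step = 8
    vals = []
    for y in range(0, a.shape[0] - step + 1, step):
        for x in range(0, a.shape[1] - step + 1, step):
            pa = a[y:y + step, x:x + step].ravel()
            pb = b[y:y + step, x:x + step].ravel()
            ma, mb = pa.mean(), pb.mean()
            va, vb = pa.var(), pb.var()
            cov = ((pa - ma) * (pb - mb)).mean()
            vals.append(((2 * ma * mb + c1) * (2 * cov + c2))
                        / ((ma**2 + mb**2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))
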