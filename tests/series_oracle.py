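"""Independent closed-form oracle: transient conduction in a slab.

Classical separation-of-variables series for a uniform slab of
half-thickness L, initially at T_init, suddenly exposed on its surface to a
fluid at T_inf through a convection coefficient h (symmetry at the
mid-plane). Eigenvalues solve mu·tan(mu) = Bi. Used to check that both
frying solvers collapse to pure conduction when the latent heat is
negligible; coded only from the textbook solution, independent of the
solver implementations.
"""

import numpy as np
from scipy.optimize import brentq


def eigenvalues(Bi: float, nterms: int) -> np.ndarray:
    mus = []
    for n in range(nterms):
        lo = n * np.pi + 1e-9
        hi = n * np.pi + np.pi / 2 - 1e-9
        mus.append(brentq(lambda m: m * np.tan(m) - Bi, lo, hi, xtol=1e-14))
    return np.array(mus)


def center_temperature(t, L, alpha, h, k, T_init, T_inf, nterms=80):
    """Mid-plane temperature history of the convectively heated slab."""
    Bi = h * L / k
    mus = eigenvalues(Bi, nterms)
    C = 2 * np.sin(mus) / (mus + np.sin(mus) * np.cos(mus))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    Fo = alpha * t[:, None] / L**2
    theta = (C[None, :] * np.exp(-(mus[None, :] ** 2) * Fo)).sum(axis=1)
    return T_inf + (T_init - T_inf) * theta
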