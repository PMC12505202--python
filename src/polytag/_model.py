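"""Shared read-count emission model.

The allele-dosage caller and the simulator use the same parametrization of
the expected alternative-read fraction and the same beta-binomial read model,
so that simulated data are exactly within the fitted model family.

Parameters
----------
d : allele dosage, integer 0..m
m : ploidy (number of allele copies interrogated at the locus)
h : allele bias (>0); amplification asymmetry between Ref and Alt products.
    h = 1 means no bias; h > 1 depresses the Alt fraction.
eps : sequencing error rate in [0, 0.5)
rho : beta-binomial overdispersion in [0, 1); rho -> 0 recovers the binomial.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_XI_FLOOR = 1e-9


def expected_alt_fraction(d, m, h=1.0, eps=0.0):
    """Expected Alt-read fraction xi(d) for dosage d at ploidy m.

    xi0 = (d/m)(1-eps) + (1-d/m) eps   (error-perturbed allele fraction)
    xi  = xi0 / (h (1-xi0) + xi0)      (bias-distorted sequencing fraction)

    Strictly increasing in d for any h > 0 and eps < 0.5.
    """
    d = np.asarray(d, dtype=float)
    frac = d / m
    xi0 = frac * (1.0 - eps) + (1.0 - frac) * eps
    xi = xi0 / (h * (1.0 - xi0) + xi0)
    return np.clip(xi, _XI_FLOOR, 1.0 - _XI_FLOOR)


def betabinom_logpmf(alt, depth, xi, rho):
    """Log-likelihood of alt reads out of depth at mean fraction xi.

    Beta-binomial with mean xi and intraclass correlation rho; the binomial
    limit is used below rho = 1e-8 (the beta parametrization degenerates).
    Broadcasts over any compatible shapes.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    xi = np.clip(np.asarray(xi, dtype=float), _XI_FLOOR, 1 - _XI_FLOOR)
    if rho < 1e-8:
        return stats.binom.logpmf(alt, depth, xi)
    a = xi * (1.0 - rho) / rho
    b = (1.0 - xi) * (1.0 - rho) / rho
    return stats.betabinom.logpmf(alt, depth, a, b)


def sample_alt_reads(rng, depth, xi, rho):
    """Draw Alt read counts given total depth and expected fraction xi."""
    depth = np.asarray(depth)
    xi = np.clip(np.broadcast_to(np.asarray(xi, float), depth.shape),
                 _XI_FLOOR, 1 - _XI_FLOOR)
    if rho < 1e-8:
        return rng.binomial(depth, xi)
    a = xi * (1.0 - rho) / rho
    b = (1.0 - xi) * (1.0 - rho) / rho
    p = rng.beta(a, b)
    return rng.binomial(depth, p)


def haldane_cm(r):
    """Map distance in centimorgans from a recombination fraction (Haldane)."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * np.clip(r, 0.0, 0.5 - 1e-12))


def haldane_r(d_cm):
    """Recombination fraction from a map distance in cM (Haldane inverse)."""
    d_cm = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
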