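"""Allele-dosage calling from Ref/Alt read counts.

Per marker, the alternative read count of sample s is modeled as

    alt_s | d_s ~ BetaBinomial(depth_s, xi(d_s), rho)

where d_s in 0..m is the latent allele dosage and xi(d) distorts the
allele fraction d/m by sequencing error eps and allele bias h (see
``polytag._model``).  Two genotype priors are available:

* "norm"  — a discretized normal over 0..m with free (mu, sigma), suited to
  cohorts of unrelated individuals at an arbitrary allele frequency;
* "f1"    — Mendelian offspring-class probabilities given the two parents'
  dosages (diploid biparental populations); parents are genotyped from
  their own reads first and then held fixed.

Fitting maximizes the marginal likelihood by expectation-maximization over
the latent dosages: closed-form (mu, sigma) updates and a bounded
quasi-Newton step for (h, rho, eps), accepted only when the marginal
log-likelihood does not decrease, so the EM ascent property holds exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from ._model import betabinom_logpmf, expected_alt_fraction
from .madc import CountMatrix
from .qc import DEFAULT_MIN_READS

# post-dosage marker filters: 0.05 < bias < 2, prop_mis < 0.1, od < 0.05
BIAS_BOUNDS = (0.05, 2.0)
MAX_PROP_MIS = 0.1
MAX_OVERDISPERSION = 0.05

_PRIOR_FLOOR = 1e-10


@dataclass
class DosageModelFit:
    marker_id: str
    m: int
    h: float = 1.0
    rho: float = 0.01
    eps: float = 0.005
    mu: float | None = None
    sigma: float | None = None
    parent_dosages: tuple | None = None
    prop_mis: float = np.nan
    loglik: float = np.nan
    n_used: int = 0
    converged: bool = True
    note: str = ""


@dataclass
class GenotypeMatrix:
    """Integer dosages (NaN = missing) with per-call max posterior."""

    dosage: pd.DataFrame
    max_posterior: pd.DataFrame
    ploidy: pd.Series
    fits: dict = field(default_factory=dict)

    def subset_samples(self, samples):
        return GenotypeMatrix(self.dosage[samples], self.max_posterior[samples],
                              self.ploidy.loc[samples], self.fits)


def _norm_prior(m, mu, sigma):
    """Normal density at integer dosages, renormalized over 0..m."""
    d = np.arange(m + 1)
    logp = stats.norm.logpdf(d, loc=mu, scale=max(sigma, 1e-3))
    logp -= logsumexp(logp)
    return np.maximum(np.exp(logp), _PRIOR_FLOOR)


def gamete_dist(dosage: int) -> np.ndarray:
    """Diploid gamete allele distribution over {0, 1} given parent dosage."""
    return {0: np.array([1.0, 0.0]),
            1: np.array([0.5, 0.5]),
            2: np.array([0.0, 1.0])}[int(dosage)]


def f1_prior(p1_dosage: int, p2_dosage: int) -> np.ndarray:
    """Mendelian offspring dosage distribution (diploid biparental)."""
    g1, g2 = gamete_dist(p1_dosage), gamete_dist(p2_dosage)
    prior = np.convolve(g1, g2)
    return np.maximum(prior, _PRIOR_FLOOR)


def _emission(alt, depth, m, h, rho, eps):
    """(m+1) x n log-likelihood matrix over dosages."""
    d = np.arange(m + 1)[:, None]
    xi = expected_alt_fraction(d, m, h=h, eps=eps)
    return betabinom_logpmf(alt[None, :], depth[None, :], xi, rho)


def _marginal_ll(alt, depth, m, h, rho, eps, log_prior):
    le = _emission(alt, depth, m, h, rho, eps)
    return float(logsumexp(le + log_prior[:, None], axis=0).sum())


def _em_fit(alt, depth, m, prior=None, init=(1.0, 0.01, 0.005),
            tol=1e-6, max_iter=200, n_restarts=3, rng=None):
    """EM for one marker.  prior=None fits the "norm" prior (mu, sigma
    updated each iteration); a fixed array fits against that prior.

    Returns (h, rho, eps, mu, sigma, posterior (m+1 x n), loglik, converged,
    loglik trace).  The trace is non-decreasing: closed-form prior updates
    maximize the expected complete-data log-likelihood exactly and the
    emission-parameter step is accepted only when the marginal
    log-likelihood does not drop.
    """
    rng = rng or np.random.default_rng(0)
    n = alt.size
    best = None
    for attempt in range(1 + n_restarts):
        h, rho, eps = init
        if attempt:
            h = float(np.exp(rng.normal(0, 0.3)))
            rho = float(np.clip(rng.uniform(0.001, 0.1), 1e-6, 0.4))
            eps = float(np.clip(rng.uniform(0.0005, 0.02), 1e-6, 0.4))
        if prior is None:
            mu = m * float(alt.sum()) / max(float(depth.sum()), 1.0)
            sigma = m / 4.0
            log_prior = np.log(_norm_prior(m, mu, sigma))
        else:
            mu = sigma = None
            log_prior = np.log(np.maximum(prior, _PRIOR_FLOOR))

        ll = _marginal_ll(alt, depth, m, h, rho, eps, log_prior)
        trace = [ll]
        converged = False
        for _ in range(max_iter):
            # E-step
            le = _emission(alt, depth, m, h, rho, eps)
            joint = le + log_prior[:, None]
            post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))
            # M-step: prior parameters ("norm" only).  The moment update is
            # exact for a continuous normal but only approximate after
            # renormalizing over 0..m, so it is accepted under the same
            # ascent guard as the emission step.
            if prior is None:
                dvals = np.arange(m + 1)[:, None]
                w = post.sum(axis=1)
                mu_new = float((w * np.arange(m + 1)).sum() / n)
                var = float((post * (dvals - mu_new) ** 2).sum() / n)
                sigma_new = max(math.sqrt(var), 0.05)
                log_prior_new = np.log(_norm_prior(m, mu_new, sigma_new))
                if (_marginal_ll(alt, depth, m, h, rho, eps, log_prior_new)
                        >= ll - 1e-9):
                    mu, sigma, log_prior = mu_new, sigma_new, log_prior_new
            # M-step: emission parameters via bounded quasi-Newton on Q
            def neg_q(theta):
                hh, rr, ee = np.exp(theta[0]), theta[1], theta[2]
                le_t = _emission(alt, depth, m, hh, rr, ee)
                return -float((post * le_t).sum())

            res = optimize.minimize(
                neg_q, x0=[math.log(h), rho, eps], method="L-BFGS-B",
                bounds=[(-7, 7), (1e-6, 0.5), (1e-6, 0.49)],
                options={"maxiter": 15})
            h_new = float(np.exp(res.x[0]))
            rho_new, eps_new = float(res.x[1]), float(res.x[2])
            ll_new = _marginal_ll(alt, depth, m, h_new, rho_new, eps_new,
                                  log_prior)
            if ll_new >= ll - 1e-9:      # generalized-EM safeguard
                h, rho, eps = h_new, rho_new, eps_new
            else:
                ll_new = _marginal_ll(alt, depth, m, h, rho, eps, log_prior)
            trace.append(ll_new)
            if abs(ll_new - ll) < tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        le = _emission(alt, depth, m, h, rho, eps)
        joint = le + log_prior[:, None]
        post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))
        cand = (h, rho, eps, mu, sigma, post, ll, converged, trace)
        if best is None or ll > best[6]:
            best = cand
        if converged:
            break
    return best


def _call_from_post(post):
    calls = post.argmax(axis=0).astype(float)
    maxp = post.max(axis=0)
    return calls, maxp


def fit_norm_model(counts: CountMatrix, m: int,
                   min_reads: int = DEFAULT_MIN_READS, min_samples: int = 5,
                   max_iter: int = 200, tol: float = 1e-6,
                   seed: int = 0):
    """Fit the "norm" prior marker-by-marker at ploidy m.

    Cells with depth < min_reads are missing and never enter the fit;
    markers with fewer than min_samples observed cells are left uncalled
    (flagged in the fit note).  Non-convergence triggers up to 3 jittered
    restarts; the marker is retained with a warning either way.
    """
    rng = np.random.default_rng(seed)
    ref = counts.ref.to_numpy()
    alt = counts.alt.to_numpy()
    tot = ref + alt
    L, S = tot.shape
    dosage = np.full((L, S), np.nan)
    maxpost = np.full((L, S), np.nan)
    fits = {}
    for i, marker_id in enumerate(counts.loci):
        ok = tot[i] >= min_reads
        fit = DosageModelFit(marker_id, m, n_used=int(ok.sum()))
        if ok.sum() < min_samples:
            fit.note = "too few observed samples; not fitted"
            fits[marker_id] = fit
            continue
        h, rho, eps, mu, sigma, post, ll, conv, _tr = _em_fit(
            alt[i, ok].astype(float), tot[i, ok].astype(float), m,
            tol=tol, max_iter=max_iter, rng=rng)
        calls, mp = _call_from_post(post)
        dosage[i, ok] = calls
        maxpost[i, ok] = mp
        fit.h, fit.rho, fit.eps, fit.mu, fit.sigma = h, rho, eps, mu, sigma
        fit.loglik, fit.converged = ll, conv
        fit.prop_mis = float(1.0 - mp.mean())
        if not conv:
            fit.note = "EM did not converge"
            warnings.warn(f"marker {marker_id}: EM did not converge")
        fits[marker_id] = fit
    G = GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=counts.loci, columns=counts.samples),
        max_posterior=pd.DataFrame(maxpost, index=counts.loci,
                                   columns=counts.samples),
        ploidy=pd.Series(m, index=counts.samples), fits=fits)
    return fits, G


def fit_f1_model(counts: CountMatrix, parents, m: int = 2,
                 min_reads: int = DEFAULT_MIN_READS, min_samples: int = 5,
                 max_iter: int = 200, tol: float = 1e-6, seed: int = 0):
    """Fit the "f1" Mendelian prior for a diploid biparental population.

    ``parents`` is a pair of sample ids present in ``counts``.  Parent
    dosages are estimated from their own reads (maximum likelihood under a
    flat prior with nominal emission parameters) and then fixed; offspring
    priors are the gamete-combination distributions.  A marker whose parent
    is missing falls back to the "norm" prior with a warning note.
    """
    p1, p2 = parents
    for p in (p1, p2):
        if p not in counts.samples:
            raise ValueError(f"parent {p} not in count matrix")
    rng = np.random.default_rng(seed)
    offspring = [s for s in counts.samples if s not in (p1, p2)]
    ref = counts.ref.to_numpy()
    alt = counts.alt.to_numpy()
    tot = ref + alt
    L, S = tot.shape
    sample_pos = {s: j for j, s in enumerate(counts.samples)}
    off_idx = np.array([sample_pos[s] for s in offspring])
    par_idx = np.array([sample_pos[p1], sample_pos[p2]])
    dosage = np.full((L, S), np.nan)
    maxpost = np.full((L, S), np.nan)
    fits = {}
    flat_log_prior = np.log(np.full(m + 1, 1.0 / (m + 1)))
    for i, marker_id in enumerate(counts.loci):
        ok_off = tot[i, off_idx] >= min_reads
        fit = DosageModelFit(marker_id, m, n_used=int(ok_off.sum()))
        if ok_off.sum() < min_samples:
            fit.note = "too few observed offspring; not fitted"
            fits[marker_id] = fit
            continue
        ok_par = tot[i, par_idx] >= min_reads
        if ok_par.all():
            # parent dosages by ML under nominal emission parameters
            le_par = _emission(alt[i, par_idx].astype(float),
                               tot[i, par_idx].astype(float), m,
                               h=1.0, rho=0.01, eps=0.005)
            pd1, pd2 = le_par.argmax(axis=0)
            prior = f1_prior(pd1, pd2)
            fit.parent_dosages = (int(pd1), int(pd2))
            dosage[i, par_idx] = [pd1, pd2]
            maxpost[i, par_idx] = np.exp(
                le_par.max(axis=0) - logsumexp(le_par + flat_log_prior[:, None],
                                               axis=0))
        else:
            prior = None
            fit.note = "parent missing at marker; fell back to norm prior"
            warnings.warn(f"marker {marker_id}: {fit.note}")
        a = alt[i, off_idx[ok_off]].astype(float)
        t = tot[i, off_idx[ok_off]].astype(float)
        h, rho, eps, mu, sigma, post, ll, conv, _tr = _em_fit(
            a, t, m, prior=prior, tol=tol, max_iter=max_iter, rng=rng)
        calls, mp = _call_from_post(post)
        dosage[i, off_idx[ok_off]] = calls
        maxpost[i, off_idx[ok_off]] = mp
        fit.h, fit.rho, fit.eps, fit.mu, fit.sigma = h, rho, eps, mu, sigma
        fit.loglik, fit.converged = ll, conv
        fit.prop_mis = float(1.0 - mp.mean())
        if not conv:
            fit.note = (fit.note + "; " if fit.note else "") + "EM did not converge"
            warnings.warn(f"marker {marker_id}: EM did not converge")
        fits[marker_id] = fit
    G = GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=counts.loci, columns=counts.samples),
        max_posterior=pd.DataFrame(maxpost, index=counts.loci,
                                   columns=counts.samples),
        ploidy=pd.Series(m, index=counts.samples), fits=fits)
    return fits, G


# ---------------------------------------------------------------------------
# post-dosage filtering


def fits_to_frame(fits: dict) -> pd.DataFrame:
    rows = [{"marker_id": f.marker_id, "m": f.m, "h": f.h, "rho": f.rho,
             "eps": f.eps, "mu": f.mu, "sigma": f.sigma,
             "prop_mis": f.prop_mis, "loglik": f.loglik, "n_used": f.n_used,
             "converged": f.converged, "note": f.note}
            for f in fits.values()]
    return pd.DataFrame(rows).set_index("marker_id")


def filter_postdosage(fits: dict, bias_bounds=BIAS_BOUNDS,
                      max_prop_mis: float = MAX_PROP_MIS,
                      max_od: float = MAX_OVERDISPERSION):
    """Keep markers with bias strictly inside bias_bounds, prop_mis below
    max_prop_mis, and overdispersion below max_od.

    Returns (kept marker ids, removal DataFrame with per-rule verdicts).
    """
    lo, hi = bias_bounds
    rows = []
    kept = []
    for f in fits.values():
        ok_bias = lo < f.h < hi
        ok_mis = f.prop_mis < max_prop_mis
        ok_od = f.rho < max_od
        fitted = np.isfinite(f.prop_mis)
        keep = bool(fitted and ok_bias and ok_mis and ok_od)
        rows.append({"marker_id": f.marker_id, "fitted": fitted,
                     "bias_ok": ok_bias, "prop_mis_ok": ok_mis, "od_ok": ok_od,
                     "kept": keep})
        if keep:
            kept.append(f.marker_id)
    return kept, pd.DataFrame(rows).set_index("marker_id")


def informative_markers(G: GenotypeMatrix) -> list:
    """Markers with at least two distinct non-missing called dosages."""
    out = []
    for marker_id, row in G.dosage.iterrows():
        vals = row.dropna().unique()
        if len(vals) >= 2:
            out.append(marker_id)
    return out
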