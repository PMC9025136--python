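"""Crossover reconstruction and gamma interference-strength estimation.

Observed crossovers are haplotype switches along each progeny's transmitted
gamete, read from the phase-canonicalized het/hom signal of one parent's
informative markers.  Interference strength is the shape parameter nu of
the stationary gamma renewal chiasma model: chiasma spacings on the
chromatid genetic scale are Gamma(nu, rate 2*nu) and each chiasma reaches
the observed chromatid with probability 1/2, so the observed inter-event
distances are the 2^-k - weighted convolutions Gamma(k*nu, 2*nu).  nu = 1
is no interference, nu > 1 positive (regular spacing), nu < 1 negative
(clustering).

The per-meiosis likelihood of events x_1 < ... < x_k on (0, L):

    g(x_1) * prod f(x_{i+1} - x_i) * S(L - x_k),      or S0(L) if k = 0,

with f the thinned inter-event density, g the stationary first-event
density (from the equilibrium residual of the renewal process), S the
thinned survival beyond the last event and S0 the stationary probability
of an event-free chromosome.  All four have closed forms in gamma CDFs;
the 2^-k series is truncated at k = 27 (weight < 1e-8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import corate
from .genotypes import MISSING, GenotypeDataset
from .interference import SEG_OF_PARENT

__all__ = [
    "CrossoverEvent", "GammaFit",
    "call_crossovers", "genetic_scale", "canonical_haplotypes",
    "chromosome_meioses", "thinned_renewal_loglik", "fit_gamma_nu",
    "fit_chromosome", "compare_strength",
]

_SERIES_TERMS = 27  # 2^-27 < 1e-8
_MIN_GAP = 1e-6  # Morgans; zero gaps (events split only by r=0 intervals) are clipped


@dataclass(frozen=True)
class CrossoverEvent:
    individual: str
    chrom: str
    left_bp: int
    right_bp: int
    mid_bp: float
    genetic_pos: float  # Morgans


@dataclass
class GammaFit:
    parent: str
    chrom: str
    nu_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_meioses: int
    n_events: int
    genetic_length: float
    loglik: float
    at_bound: bool


# ---------------------------------------------------------------------------
# event reconstruction
# ---------------------------------------------------------------------------

def call_crossovers(alleles: np.ndarray, positions_bp: np.ndarray) -> list[tuple[int, int]]:
    """Crossover brackets from one gamete's 0/1 haplotype signal.

    One event per sign change between consecutive non-missing markers;
    missing markers widen the bracket.  Returns (left_bp, right_bp) per
    event; fewer than two non-missing markers yield none.
    """
    ok = alleles != MISSING
    if ok.sum() < 2:
        return []
    vals = alleles[ok]
    pos = np.asarray(positions_bp)[ok]
    switch = np.flatnonzero(vals[1:] != vals[:-1])
    return [(int(pos[i]), int(pos[i + 1])) for i in switch]


def genetic_scale(adjacent_r: np.ndarray, cap: float = 0.499) -> np.ndarray:
    """Cumulative Morgan positions of markers from adjacent recombination fractions.

    Marker k sits at the sum of the adjacent-pair fractions up to k (the
    additive small-interval approximation).  A fraction of exactly 1/2
    (unlinked neighbours) is capped with a warning since its map distance
    is unbounded.
    """
    r = np.asarray(adjacent_r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("adjacent recombination fractions must be in [0, 0.5]")
    if np.any(r >= 0.5):
        warnings.warn("unlinked adjacent pair (r = 0.5); map distance capped")
        r = np.minimum(r, cap)
    return np.concatenate([[0.0], np.cumsum(r)])


def canonical_haplotypes(
    dataset: GenotypeDataset, parent: str, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase-canonicalize one parent's markers on one chromosome.

    Chains the two-point phase of every adjacent marker pair and flips
    het/hom at markers cumulatively so that every adjacent pair is in
    coupling; the resulting matrix is a consistent 0/1 haplotype signal per
    progeny.  Returns (positions_bp, alleles[m, n], adjacent_r).
    """
    idx = dataset.markers_of_type(SEG_OF_PARENT[parent], chrom)
    if len(idx) == 0:
        return np.empty(0, dtype=int), np.empty((0, dataset.n_progeny), dtype=np.int8), np.empty(0)
    pos = dataset.markers["pos"].to_numpy()[idx]
    calls = dataset.calls[idx].copy()
    flip = 0
    for k in range(len(idx) - 1):
        counts = corate.counts_from_calls(calls[k], calls[k + 1])
        if counts.total == 0:
            continue  # unflippable; keep current orientation
        if corate.infer_phase(counts).phase == corate.REPULSION:
            # flipping only marker k+1 while walking left-to-right applies the
            # cumulative chain flip: pair (k, k+1) is re-tested on flipped data
            sub = calls[k + 1]
            calls[k + 1] = np.where(sub == MISSING, MISSING, 1 - sub)
    adjacent_r = np.empty(len(idx) - 1)
    for k in range(len(idx) - 1):
        counts = corate.counts_from_calls(calls[k], calls[k + 1])
        adjacent_r[k] = counts.recombinant / counts.total if counts.total else 0.0
    return pos, calls, adjacent_r


def chromosome_meioses(
    dataset: GenotypeDataset, parent: str, chrom: str
) -> tuple[list[np.ndarray], float, list[CrossoverEvent]]:
    """Reconstruct genetic-scale crossover positions per progeny.

    Returns (meioses, genetic_length, events): one array of event positions
    (Morgans) per progeny with at least two informative markers; the
    chromosome genetic length is the map position of the last marker.
    """
    pos, calls, adjacent_r = canonical_haplotypes(dataset, parent, chrom)
    if len(pos) < 2:
        return [], 0.0, []
    gpos = genetic_scale(adjacent_r)
    glen = float(gpos[-1])
    bp_to_g = dict(zip(pos.tolist(), gpos.tolist()))
    meioses, events = [], []
    for j in range(dataset.n_progeny):
        brackets = call_crossovers(calls[:, j], pos)
        ok = calls[:, j] != MISSING
        if ok.sum() < 2:
            continue
        xs = []
        for left, right in brackets:
            g = 0.5 * (bp_to_g[left] + bp_to_g[right])
            xs.append(g)
            events.append(
                CrossoverEvent(
                    dataset.progeny[j], chrom, left, right, 0.5 * (left + right), g
                )
            )
        meioses.append(np.asarray(sorted(xs)))
    return meioses, glen, events


# ---------------------------------------------------------------------------
# thinned gamma renewal likelihood
# ---------------------------------------------------------------------------

def _gamma_cdf(x: np.ndarray, shapes: np.ndarray, nu: float) -> np.ndarray:
    """F_{a}(x) for a vector of gamma shapes at rate 2*nu; shape a=0 -> 1."""
    scale = 1.0 / (2.0 * nu)
    out = np.empty((len(shapes),) + np.shape(x))
    for i, a in enumerate(shapes):
        out[i] = 1.0 if a == 0 else stats.gamma.cdf(x, a, scale=scale)
    return out


def thinned_renewal_loglik(
    nu: float,
    first: np.ndarray,
    gaps: np.ndarray,
    censored: np.ndarray,
    n_empty: int,
    genetic_length: float,
) -> float:
    """Log-likelihood of observed chromatid crossovers under interference nu.

    ``first``: distance from the chromosome start to the first event of
    each meiosis that has one; ``gaps``: all inter-event distances pooled;
    ``censored``: distance from the last event to the chromosome end;
    ``n_empty``: meioses with no event on a chromosome of ``genetic_length``
    Morgans (they contribute the stationary no-event probability).
    """
    if nu <= 0:
        raise ValueError("nu must be > 0")
    j = np.arange(1, _SERIES_TERMS + 1)
    w = 0.5 ** j
    scale = 1.0 / (2.0 * nu)
    tiny = 1e-300

    ll = 0.0
    if len(gaps):
        gaps = np.maximum(gaps, _MIN_GAP)
        pdf = stats.gamma.pdf(gaps[None, :], (j * nu)[:, None], scale=scale)
        ll += float(np.sum(np.log(np.maximum(w @ pdf, tiny))))
    if len(first):
        cdf_hi = _gamma_cdf(first, j * nu, nu)
        cdf_lo = _gamma_cdf(first, (j - 1) * nu, nu)
        dens = 2.0 * np.tensordot(w, cdf_lo - cdf_hi, axes=1)
        ll += float(np.sum(np.log(np.maximum(dens, tiny))))
    if len(censored):
        cdf = _gamma_cdf(censored, j * nu, nu)
        surv = 1.0 - np.tensordot(w, cdf, axes=1)
        ll += float(np.sum(np.log(np.maximum(surv, tiny))))
    if n_empty:
        L = np.array([genetic_length])
        H = np.empty(_SERIES_TERMS)
        for i, jj in enumerate(j):
            f_lo = _gamma_cdf(L, np.array([(jj - 1) * nu]), nu)[0, 0]
            f_hi = _gamma_cdf(L, np.array([jj * nu]), nu)[0, 0]
            f_lo1 = _gamma_cdf(L, np.array([(jj - 1) * nu + 1]), nu)[0, 0]
            f_hi1 = _gamma_cdf(L, np.array([jj * nu + 1]), nu)[0, 0]
            # H_j(L) = P(j-th chiasma arrival <= L) under the stationary process;
            # P(no surviving chiasma) = 1 - sum_j 2^-j H_j by partial summation
            H[i] = 2 * genetic_length * (f_lo - f_hi) - (jj - 1) * f_lo1 + jj * f_hi1
        s0 = 1.0 - float(w @ H)
        ll += n_empty * float(np.log(max(s0, tiny)))
    return ll


def fit_gamma_nu(
    meioses: list[np.ndarray],
    genetic_length: float,
    parent: str = "",
    chrom: str = "",
    bounds: tuple[float, float] = (0.05, 20.0),
) -> GammaFit:
    """Maximum-likelihood interference strength from per-meiosis crossovers.

    ``meioses`` holds one sorted array of event positions (Morgans, within
    (0, genetic_length)) per observed gamete; empty arrays are event-free
    meioses and contribute the censoring term.  1-D bounded optimization
    over nu; standard error from the numerical observed information.
    """
    if genetic_length <= 0:
        raise ValueError("genetic length must be > 0")
    if not meioses:
        raise ValueError("at least one meiosis required")
    n_events = int(sum(len(m) for m in meioses))
    if n_events == 0:
        raise ValueError("no crossover events observed; nu is unidentifiable")
    first = np.array([m[0] for m in meioses if len(m)])
    gaps = np.concatenate([np.diff(m) for m in meioses if len(m) > 1] or [np.empty(0)])
    censored = np.array([genetic_length - m[-1] for m in meioses if len(m)])
    n_empty = sum(1 for m in meioses if len(m) == 0)

    def nll(nu: float) -> float:
        return -thinned_renewal_loglik(nu, first, gaps, censored, n_empty, genetic_length)

    res = optimize.minimize_scalar(
        nll, bounds=bounds, method="bounded", options={"xatol": 1e-4}
    )
    nu_hat = float(res.x)
    at_bound = min(nu_hat - bounds[0], bounds[1] - nu_hat) < 1e-2
    if at_bound:
        warnings.warn(f"nu estimate {nu_hat:.3f} at optimization bound")
    h = max(1e-3 * nu_hat, 1e-4)
    d2 = (nll(nu_hat + h) - 2 * res.fun + nll(nu_hat - h)) / h**2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")
    return GammaFit(
        parent=parent,
        chrom=chrom,
        nu_hat=nu_hat,
        se=se,
        ci_low=nu_hat - 1.96 * se if np.isfinite(se) else float("nan"),
        ci_high=nu_hat + 1.96 * se if np.isfinite(se) else float("nan"),
        n_meioses=len(meioses),
        n_events=n_events,
        genetic_length=genetic_length,
        loglik=-float(res.fun),
        at_bound=at_bound,
    )


def fit_chromosome(dataset: GenotypeDataset, parent: str, chrom: str) -> GammaFit | None:
    """Reconstruct crossovers on one chromosome for one parent and fit nu."""
    meioses, glen, _ = chromosome_meioses(dataset, parent, chrom)
    if not meioses or glen <= 0 or sum(len(m) for m in meioses) == 0:
        return None
    return fit_gamma_nu(meioses, glen, parent=parent, chrom=chrom)


def fit_all_chromosomes(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-chromosome, per-parent gamma fits as a tidy frame."""
    rows = []
    for parent in ("female", "male"):
        for chrom in dataset.chromosomes():
            fit = fit_chromosome(dataset, parent, chrom)
            if fit is None:
                continue
            rows.append(
                {
                    "parent": parent, "chrom": chrom, "nu_hat": fit.nu_hat, "se": fit.se,
                    "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                    "n_meioses": fit.n_meioses, "n_events": fit.n_events,
                    "genetic_length": fit.genetic_length, "loglik": fit.loglik,
                    "at_bound": fit.at_bound,
                }
            )
    return pd.DataFrame(rows)


def compare_strength(nu_f, nu_m) -> dict:
    """Two-sided paired t test of per-chromosome interference strengths."""
    x = np.asarray(nu_f, dtype=float)
    y = np.asarray(nu_m, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length paired vectors with >= 2 chromosomes")
    diffs = x - y
    if np.allclose(np.std(diffs), 0.0):
        if np.allclose(diffs, 0.0):
            warnings.warn("zero paired differences everywhere; t test degenerate")
            t, p = 0.0, 1.0
        else:
            # constant non-zero difference: infinite t, p -> 0
            t, p = float(np.sign(diffs.mean()) * np.inf), 0.0
    else:
        res = stats.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "t": t,
        "p": p,
        "mean_female": float(x.mean()),
        "mean_male": float(y.mean()),
        "n_chromosomes": len(x),
    }
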