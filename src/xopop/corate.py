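"""Two-point linkage: phase inference, sex-specific CO-rate MLEs, LR test.

At two same-type SNPs the progeny fall into four classes — (het,het),
(het,hom), (hom,het), (hom,hom) — with multinomial probabilities
((1-r)/2, r/2, r/2, (1-r)/2) under coupling.  Because the linkage phase of
the informative parent is unknown in an outbred F1, it is inferred first:
if the "recombinant" classes are the majority the pair is in repulsion and
classes are relabelled (1<->2, 3<->4), after which the coupling likelihood
applies and the MLE is the canonical recombinant fraction, guaranteed
<= 1/2.  Equality of the female and male rates over the same physical
interval is tested with a 1-df likelihood-ratio statistic against the
pooled-rate null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .genotypes import HET, HOM, MISSING, GenotypeDataset
from .tagselect import TagInterval

__all__ = [
    "TwoPointCounts", "PhasedCounts",
    "counts_from_calls", "infer_phase", "estimate_rate", "lr_equal_rates",
    "scan_intervals", "find_significant_regions",
    "chromosome_summary_and_paired_test", "PairedTestResult",
]

COUPLING = "coupling"
REPULSION = "repulsion"


@dataclass(frozen=True)
class TwoPointCounts:
    """Genotype-class counts at two same-type SNPs.

    Classes ordered (het,het), (het,hom), (hom,het), (hom,hom).
    """

    n11: int
    n12: int
    n13: int
    n14: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n13, self.n14) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n13 + self.n14

    @property
    def recombinant(self) -> int:
        return self.n12 + self.n13

    @property
    def parental(self) -> int:
        return self.n11 + self.n14

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n13, self.n14)


@dataclass(frozen=True)
class PhasedCounts:
    """Phase-canonicalized counts: ``counts`` satisfy the coupling likelihood."""

    phase: str
    counts: TwoPointCounts
    unlinked: bool  # canonical r-hat exactly 1/2


def counts_from_calls(calls_a: np.ndarray, calls_b: np.ndarray) -> TwoPointCounts:
    """Tabulate the four genotype classes, pairwise-complete over progeny."""
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    a, b = calls_a[ok], calls_b[ok]
    return TwoPointCounts(
        int(np.sum((a == HET) & (b == HET))),
        int(np.sum((a == HET) & (b == HOM))),
        int(np.sum((a == HOM) & (b == HET))),
        int(np.sum((a == HOM) & (b == HOM))),
    )


def infer_phase(counts: TwoPointCounts) -> PhasedCounts:
    """Maximum-likelihood linkage phase, with ties broken toward coupling.

    Coupling iff the recombinant-class fraction is <= the parental-class
    fraction; otherwise the pair is in repulsion and classes 1<->2, 3<->4
    are swapped so the returned counts are canonical (coupling) with
    r-hat <= 1/2.
    """
    if counts.total == 0:
        raise ValueError("phase undefined with zero informative progeny")
    if counts.recombinant <= counts.parental:
        canonical, phase = counts, COUPLING
    else:
        n11, n12, n13, n14 = counts.as_tuple()
        canonical, phase = TwoPointCounts(n12, n11, n14, n13), REPULSION
    return PhasedCounts(phase, canonical, unlinked=2 * canonical.recombinant == canonical.total)


def estimate_rate(counts: TwoPointCounts) -> float:
    """Closed-form MLE of the recombination fraction from canonical counts."""
    if counts.total == 0:
        raise ValueError("rate undefined with zero informative progeny")
    return counts.recombinant / counts.total


def _loglik(parental: float, recombinant: float, r: float) -> float:
    # multinomial kernel of the coupling likelihood; 0*log(0) := 0
    return float(xlogy(parental, (1.0 - r) / 2.0) + xlogy(recombinant, r / 2.0))


def lr_equal_rates(
    counts_f: TwoPointCounts, counts_m: TwoPointCounts
) -> tuple[float, float]:
    """LR test of equal female/male CO rates over one interval.

    Full model: separate rates (closed-form MLEs); null: one pooled rate
    over both parents' tables.  Returns (LR, p) with the p-value from the
    asymptotic chi-square with 1 df.
    """
    if counts_f.total == 0 or counts_m.total == 0:
        raise ValueError("LR test needs informative progeny for both parents")
    rf = estimate_rate(counts_f)
    rm = estimate_rate(counts_m)
    rp = (counts_f.recombinant + counts_m.recombinant) / (counts_f.total + counts_m.total)
    lr = 2.0 * (
        _loglik(counts_f.parental, counts_f.recombinant, rf)
        + _loglik(counts_m.parental, counts_m.recombinant, rm)
        - _loglik(counts_f.parental, counts_f.recombinant, rp)
        - _loglik(counts_m.parental, counts_m.recombinant, rp)
    )
    lr = max(lr, 0.0)  # guard rounding at rf == rm
    return lr, float(stats.chi2.sf(lr, df=1))


def scan_intervals(
    dataset: GenotypeDataset,
    intervals: list[TagInterval],
    alpha_levels: tuple[float, float] = (0.05, 0.01),
    min_informative: int = 20,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-interval two-point results for both parents.

    For each interval the female pair is formed from the ab x aa SNPs of its
    two boundary tags and the male pair from the aa x ab SNPs; progeny with
    a missing call at either SNP of a pair are dropped pairwise.  Intervals
    with fewer than ``min_informative`` progeny in either pair are flagged
    ``low_n`` but still reported; intervals where a pair has no data at all
    are reported untested.
    """
    a_loose, a_strict = alpha_levels
    rows = []
    for iv in intervals:
        row = {
            "chrom": iv.chrom,
            "left_pos": iv.left.tag_pos,
            "right_pos": iv.right.tag_pos,
            "length_bp": iv.length_bp,
        }
        results = {}
        for parent, ia, ib in (
            ("f", iv.left.f_index, iv.right.f_index),
            ("m", iv.left.m_index, iv.right.m_index),
        ):
            counts = counts_from_calls(dataset.calls[ia], dataset.calls[ib])
            if counts.total == 0:
                results[parent] = None
                row.update({f"n_{parent}": 0, f"r_{parent}": np.nan, f"phase_{parent}": ""})
                continue
            phased = infer_phase(counts)
            results[parent] = phased
            row.update(
                {
                    f"n_{parent}": counts.total,
                    f"r_{parent}": estimate_rate(phased.counts),
                    f"phase_{parent}": phased.phase,
                }
            )
        tested = results["f"] is not None and results["m"] is not None
        if tested:
            cf, cm = results["f"].counts, results["m"].counts
            rp = (cf.recombinant + cm.recombinant) / (cf.total + cm.total)
            lr, p = lr_equal_rates(cf, cm)
            row.update({"r_pooled": rp, "lr": lr, "p": p})
        else:
            row.update({"r_pooled": np.nan, "lr": np.nan, "p": np.nan})
        row["tested"] = tested
        row["low_n"] = tested and min(row["n_f"], row["n_m"]) < min_informative
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    pcol = "p"
    if bh_correct and out["p"].notna().any():
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
        pcol = "p_bh"
    out["sig_05"] = out[pcol] < a_loose
    out["sig_01"] = out[pcol] < a_strict
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def find_significant_regions(
    results: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group successive significant intervals into regions.

    A region is a maximal run of >= 2 consecutive intervals (sharing a
    boundary tag) with p < alpha; significant intervals without a
    significant neighbour are returned separately as singletons.
    Returns ``(regions, singletons)``.
    """
    regions, singles = [], []
    sig = (results["p"] < alpha).to_numpy() if len(results) else np.empty(0, bool)
    i = 0
    while i < len(results):
        if not sig[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(results)
            and sig[j + 1]
            and results["chrom"].iat[j + 1] == results["chrom"].iat[j]
            and results["left_pos"].iat[j + 1] == results["right_pos"].iat[j]
        ):
            j += 1
        entry = {
            "chrom": results["chrom"].iat[i],
            "start": results["left_pos"].iat[i],
            "end": results["right_pos"].iat[j],
            "n_intervals": j - i + 1,
        }
        (regions if j > i else singles).append(entry)
        i = j + 1
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_intervals"]), pd.DataFrame(
        singles, columns=["chrom", "start", "end", "n_intervals"]
    )


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    n_pairs: int
    unit: str
    mean_f: float
    mean_m: float


def chromosome_summary_and_paired_test(
    results: pd.DataFrame, unit: str = "chromosome"
) -> tuple[pd.DataFrame, PairedTestResult]:
    """Per-chromosome mean rates and a paired Wilcoxon signed-rank test.

    ``unit="chromosome"`` pairs the per-chromosome mean rates (exact null
    distribution for <= 25 chromosomes); ``unit="interval"`` pairs the raw
    per-interval rates, which is the only unit with any power when few
    chromosomes are available.
    """
    tested = results[results["tested"]]
    summary = (
        tested.groupby("chrom", sort=True)
        .agg(
            n_intervals=("p", "size"),
            mean_r_f=("r_f", "mean"),
            mean_r_m=("r_m", "mean"),
            min_r_f=("r_f", "min"),
            max_r_f=("r_f", "max"),
            min_r_m=("r_m", "min"),
            max_r_m=("r_m", "max"),
        )
        .reset_index()
    )
    if unit == "chromosome":
        if len(summary) < 2:
            raise ValueError("paired chromosome test needs >= 2 chromosomes")
        x = summary["mean_r_f"].to_numpy()
        y = summary["mean_r_m"].to_numpy()
    elif unit == "interval":
        x = tested["r_f"].to_numpy()
        y = tested["r_m"].to_numpy()
    else:
        raise ValueError("unit must be 'chromosome' or 'interval'")

    diffs = x - y
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; signed-rank test degenerate")
        stat, p = 0.0, 1.0
    else:
        method = "exact" if len(x) <= 25 else "approx"
        try:
            res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties/zeros on some inputs
            res = stats.wilcoxon(x, y, alternative="two-sided", method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
    return summary, PairedTestResult(stat, p, len(x), unit, float(np.mean(x)), float(np.mean(y)))
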