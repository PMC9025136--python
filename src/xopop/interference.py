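"""Three-point coefficient-of-coincidence estimation and the MIL scan.

Across two adjacent intervals the joint crossover-occurrence probabilities
are parameterized by the interval rates r1, r2 and the coefficient of
coincidence C: p11 = r1*r2*C, p01 = r2 - p11, p10 = r1 - p11,
p00 = 1 - r1 - r2 + p11.  C = 1 means independent crossovers; C < 1
positive interference (doubles suppressed); C > 1 negative interference.
The 8 progeny genotype classes at three same-type SNPs collapse onto these
four probabilities, the MLEs are closed-form, and the 1-df LR statistic
against C = 1 is exactly the G-test of independence of the two intervals'
crossover indicators.

Phase handling: each sub-pair's linkage phase is inferred marginally; the
four coupling/repulsion combinations are reduced to the canonical
coupling-coupling class order by flipping het/hom at a single marker
(case 2 flips marker 3, case 3 marker 1, case 4 marker 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from . import corate
from .genotypes import AA_X_AB, AB_X_AA, HOM, MISSING, GenotypeDataset
from .simdata import PHASE_CASE_PERMUTATION
from .tagselect import genome_coverage

logger = logging.getLogger(__name__)

__all__ = [
    "ThreePointCounts", "counts_from_calls3", "resolve_phase_case",
    "estimate_coc", "lr_interference", "select_mil_triples",
    "scan_triples", "mil_scan",
]

SEG_OF_PARENT = {"female": AB_X_AA, "male": AA_X_AB}


@dataclass(frozen=True)
class ThreePointCounts:
    """Counts of the 8 genotype classes at three same-type SNPs.

    Classes are lexicographic with het before hom:
    1=(H,H,H) 2=(H,H,O) 3=(H,O,H) 4=(H,O,O)
    5=(O,H,H) 6=(O,H,O) 7=(O,O,H) 8=(O,O,O).
    In canonical (coupling-coupling) order the likelihood exponents group as
    parental n1+n8, crossover-in-2nd-only n2+n7, crossover-in-1st-only
    n4+n5, double n3+n6.
    """

    n: tuple

    def __post_init__(self) -> None:
        if len(self.n) != 8 or min(self.n) < 0:
            raise ValueError("need 8 non-negative class counts")
        object.__setattr__(self, "n", tuple(int(x) for x in self.n))

    @property
    def total(self) -> int:
        return sum(self.n)

    # canonical-order groupings
    @property
    def parental(self) -> int:
        return self.n[0] + self.n[7]

    @property
    def co_second(self) -> int:
        return self.n[1] + self.n[6]

    @property
    def co_first(self) -> int:
        return self.n[3] + self.n[4]

    @property
    def double(self) -> int:
        return self.n[2] + self.n[5]

    def permute(self, perm: np.ndarray) -> "ThreePointCounts":
        arr = np.asarray(self.n)
        out = np.empty(8, dtype=int)
        out[perm] = arr  # class i is relabelled to perm[i]
        return ThreePointCounts(tuple(out))

    def subpair_counts(self) -> tuple[corate.TwoPointCounts, corate.TwoPointCounts]:
        """Marginal two-point tables of the (1,2) and (2,3) sub-pairs."""
        n = self.n
        pair12 = corate.TwoPointCounts(
            n[0] + n[1], n[2] + n[3], n[4] + n[5], n[6] + n[7]
        )
        pair23 = corate.TwoPointCounts(
            n[0] + n[4], n[1] + n[5], n[2] + n[6], n[3] + n[7]
        )
        return pair12, pair23


def counts_from_calls3(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> ThreePointCounts:
    """Tabulate the 8 classes over progeny with all three calls present."""
    ok = (a != MISSING) & (b != MISSING) & (c != MISSING)
    ai, bi, ci = (a[ok] == HOM).astype(int), (b[ok] == HOM).astype(int), (c[ok] == HOM).astype(int)
    idx = 4 * ai + 2 * bi + ci
    return ThreePointCounts(tuple(np.bincount(idx, minlength=8)))


def resolve_phase_case(counts: ThreePointCounts) -> tuple[int, ThreePointCounts, bool]:
    """Infer the phase case (1..4) and canonicalize the class order.

    The phase of each sub-pair is inferred marginally with the two-point
    rule; (coupling, coupling) -> case 1, (coupling, repulsion) -> case 2,
    (repulsion, coupling) -> case 3, (repulsion, repulsion) -> case 4.  The
    returned counts are permuted to canonical coupling-coupling order.  The
    third element is False when either sub-pair is uninformative
    (r-hat = 1/2), in which case the triple should be skipped.
    """
    pair12, pair23 = counts.subpair_counts()
    ph12 = corate.infer_phase(pair12)
    ph23 = corate.infer_phase(pair23)
    case = {
        (corate.COUPLING, corate.COUPLING): 1,
        (corate.COUPLING, corate.REPULSION): 2,
        (corate.REPULSION, corate.COUPLING): 3,
        (corate.REPULSION, corate.REPULSION): 4,
    }[(ph12.phase, ph23.phase)]
    canonical = counts.permute(PHASE_CASE_PERMUTATION[case])
    informative = not (ph12.unlinked or ph23.unlinked)
    return case, canonical, informative


def estimate_coc(counts: ThreePointCounts) -> tuple[float, float, float]:
    """Closed-form MLEs (r1, r2, C) from canonical counts.

    r1 = (n3+n4+n5+n6)/n, r2 = (n2+n3+n6+n7)/n, C = doubles / (n r1 r2).
    C is undefined (nan) when either marginal rate is zero.
    """
    n = counts.total
    if n == 0:
        raise ValueError("CoC undefined with zero informative progeny")
    r1 = (counts.co_first + counts.double) / n
    r2 = (counts.co_second + counts.double) / n
    if r1 == 0.0 or r2 == 0.0:
        return r1, r2, float("nan")
    return r1, r2, counts.double / (n * r1 * r2)


def lr_interference(
    counts: ThreePointCounts, alpha: float = 0.05
) -> tuple[float, float, str]:
    """LR test of C = 1 (no interference) on canonical counts.

    The null keeps r1, r2 free (their MLEs are the marginal frequencies
    under either model), so the statistic is twice the log-ratio of the
    saturated 2x2 cell frequencies to the independence cells — a G-test
    with the asymptotic chi-square 1-df null.  Direction: ``negative`` if
    C-hat > 1 and p < alpha, ``positive`` if C-hat < 1 and p < alpha, else
    ``none``.
    """
    r1, r2, coc = estimate_coc(counts)
    if not np.isfinite(coc):
        raise ValueError("CoC undefined (a marginal rate is zero); no interference test")
    n = counts.total
    cells = np.array([counts.parental, counts.co_second, counts.co_first, counts.double], float)
    null_p = np.array([(1 - r1) * (1 - r2), (1 - r1) * r2, r1 * (1 - r2), r1 * r2])
    full = float(np.sum(xlogy(cells, cells / n)))
    null = float(np.sum(xlogy(cells, null_p)))
    lr = max(2.0 * (full - null), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    if p < alpha and coc > 1:
        direction = "negative"
    elif p < alpha and coc < 1:
        direction = "positive"
    else:
        direction = "none"
    return lr, p, direction


def select_mil_triples(positions: np.ndarray, mil_bp: float) -> list[tuple[int, int, int]]:
    """Greedy chain of markers with every consecutive gap >= mil_bp.

    Returns index triples (k, k+1, k+2) along the chain; consecutive
    triples overlap by one interval, mirroring the scan design.
    """
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    chain: list[int] = []
    for i, p in enumerate(positions):
        if not chain or p - positions[chain[-1]] >= mil_bp:
            chain.append(i)
    if len(chain) < 3:
        return []
    return [(chain[k], chain[k + 1], chain[k + 2]) for k in range(len(chain) - 2)]


def scan_triples(
    dataset: GenotypeDataset,
    parent: str,
    mil_bp: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-point interference scan for one parent at one MIL.

    Each row is one pair of adjacent intervals (a marker triple) on the
    greedy MIL chain of that parent's informative markers.
    """
    seg = SEG_OF_PARENT[parent]
    pos_all = dataset.markers["pos"].to_numpy()
    rows = []
    for chrom in dataset.chromosomes():
        idx = dataset.markers_of_type(seg, chrom)
        if len(idx) < 3:
            if len(idx):
                logger.debug("%s %s: <3 markers, no triples", chrom, parent)
            continue
        pos = pos_all[idx]
        for ia, ib, ic in select_mil_triples(pos, mil_bp):
            counts = counts_from_calls3(
                dataset.calls[idx[ia]], dataset.calls[idx[ib]], dataset.calls[idx[ic]]
            )
            row = {
                "chrom": chrom,
                "parent": parent,
                "pos1": int(pos[ia]),
                "pos2": int(pos[ib]),
                "pos3": int(pos[ic]),
                "n": counts.total,
            }
            if counts.total == 0:
                rows.append({**row, "tested": False, "note": "no data"})
                continue
            case, canonical, informative = resolve_phase_case(counts)
            row["phase_case"] = case
            if not informative:
                rows.append({**row, "tested": False, "note": "ambiguous phase"})
                continue
            r1, r2, coc = estimate_coc(canonical)
            row.update({"r1": r1, "r2": r2, "coc": coc})
            if not np.isfinite(coc):
                rows.append({**row, "tested": False, "note": "zero marginal rate"})
                continue
            lr, p, direction = lr_interference(canonical, alpha=alpha)
            rows.append(
                {**row, "lr": lr, "p": p, "direction": direction,
                 "significant": p < alpha, "tested": True, "note": ""}
            )
    columns = ["chrom", "parent", "pos1", "pos2", "pos3", "n", "phase_case",
               "r1", "r2", "coc", "lr", "p", "direction", "significant", "tested", "note"]
    return pd.DataFrame(rows, columns=columns)


def _significant_spans(table: pd.DataFrame) -> list[tuple[str, int, int]]:
    sig = table[(table.get("tested", False) == True) & (table["significant"] == True)]  # noqa: E712
    return [(r.chrom, int(r.pos1), int(r.pos3)) for r in sig.itertuples()]


def mil_scan(
    dataset: GenotypeDataset,
    chrom_sizes: dict,
    mils_bp=(500_000, 1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Interference landscape over a ladder of minimum interval lengths.

    For each MIL and parent: the number of tested adjacent-interval pairs,
    the number significant (split by CoC > 1 vs < 1), and the genome
    coverage of the significant pairs' physical spans; plus the pairs
    significant in both parents at overlapping spans.  Returns the summary
    frame and a dict of the per-triple tables keyed (mil_bp, parent).
    """
    rows, details = [], {}
    for mil in mils_bp:
        spans = {}
        for parent in ("female", "male"):
            table = scan_triples(dataset, parent, mil, alpha=alpha)
            details[(mil, parent)] = table
            tested = table[table.get("tested", pd.Series(dtype=bool)) == True] if len(table) else table  # noqa: E712
            sig = tested[tested["significant"] == True] if len(tested) else tested  # noqa: E712
            spans[parent] = _significant_spans(table)
            rows.append(
                {
                    "mil_bp": mil,
                    "parent": parent,
                    "n_pairs": int(len(tested)),
                    "n_significant": int(len(sig)),
                    "n_coc_gt1": int((sig["coc"] > 1).sum()) if len(sig) else 0,
                    "n_coc_lt1": int((sig["coc"] < 1).sum()) if len(sig) else 0,
                    "coverage": genome_coverage(spans[parent], chrom_sizes) if spans[parent] else 0.0,
                }
            )
        common, inter_spans = _common_pairs(spans["female"], spans["male"])
        rows.append(
            {
                "mil_bp": mil,
                "parent": "both",
                "n_pairs": 0,
                "n_significant": common,
                "n_coc_gt1": 0,
                "n_coc_lt1": 0,
                "coverage": genome_coverage(inter_spans, chrom_sizes) if inter_spans else 0.0,
            }
        )
    return pd.DataFrame(rows), details


def _common_pairs(f_spans, m_spans):
    """Female significant spans overlapping any male one, plus the intersections."""
    count = 0
    inters = []
    m_by_chrom: dict[str, list] = {}
    for c, s, e in m_spans:
        m_by_chrom.setdefault(c, []).append((s, e))
    for c, s, e in f_spans:
        hit = False
        for s2, e2 in m_by_chrom.get(c, []):
            lo, hi = max(s, s2), min(e, e2)
            if lo < hi:
                hit = True
                inters.append((c, lo, hi))
        if hit:
            count += 1
    return count, inters
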