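"""Forward simulation of F1 pseudo-testcross populations with known truth.

Chiasmata on the four-strand bundle follow a stationary gamma renewal
process with inter-arrival distances Gamma(shape nu, rate 2*nu) on the
chromatid genetic scale, so the bundle sees 2 chiasmata per Morgan and each
chiasma is passed to the observed chromatid independently with probability
1/2, giving the expected 1 crossover per Morgan per gamete.  nu = 1 reduces
to a homogeneous Poisson process (no interference); nu > 1 gives regularly
spaced chiasmata (positive interference, CoC < 1); nu < 1 clustered
chiasmata (negative interference, CoC > 1).

Because thinning preserves parity per interval, the map function of this
model has the closed (Mather) form r(d) = (1 - p0(d)) / 2 with p0 the
stationary probability of zero chiasmata in a window of genetic length d;
the simulator exposes it (:func:`recombination_fraction`) together with the
model-implied coefficient of coincidence (:func:`coincidence_coefficient`)
so parameter-recovery tests can compare against exact truth.

Stationarity is achieved by starting the renewal process 8 Morgans before
the chromosome (16 mean chiasma gaps of burn-in; the residual-life
distribution converges geometrically, so the error is far below Monte
Carlo resolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import AA_X_AB, AB_X_AA, HET, HOM, MISSING, GenotypeDataset

__all__ = [
    "ChromosomeSpec", "SimConfig", "TruthRecord",
    "simulate_chromatid_crossovers", "simulate_meioses", "simulate_population",
    "simulate_count_table", "two_point_class_probs", "three_point_class_probs",
    "recombination_fraction", "coincidence_coefficient",
    "stationary_zero_chiasma_prob", "default_layout", "write_vcf",
]

_BURNIN_MORGANS = 8.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical size and sex-specific genetic lengths (Morgans)."""

    name: str
    length_bp: int
    genetic_length_female: float
    genetic_length_male: float

    def genetic_length(self, parent: str) -> float:
        return self.genetic_length_female if parent == "female" else self.genetic_length_male


def _as_chromosome_spec(item) -> ChromosomeSpec:
    if isinstance(item, ChromosomeSpec):
        return item
    name, length_bp, rest = item[0], item[1], item[2:]
    if len(rest) == 1 and not np.iterable(rest[0]):
        gf = gm = float(rest[0])
    elif len(rest) == 1:
        gf, gm = (float(x) for x in rest[0])
    else:
        gf, gm = float(rest[0]), float(rest[1])
    return ChromosomeSpec(str(name), int(length_bp), gf, gm)


@dataclass
class SimConfig:
    """Study conditions for a synthetic F1 pseudo-testcross population.

    Defaults mirror the real design this simulator emulates: ~250 progeny,
    RAD tags (two opposite-type SNPs < 1 kb apart) spaced ~250 kb, interval
    recombination fractions of a few percent, and up to 20% missing calls.

    ``chromosomes`` entries may be ``ChromosomeSpec`` or tuples
    ``(name, length_bp, genetic_length)`` /
    ``(name, length_bp, genetic_length_female, genetic_length_male)``.
    ``layout`` optionally maps chromosome name to a list of
    ``(tag_pos_bp, intra_tag_offset_bp)``; otherwise tags are laid out every
    ``tag_spacing_bp``.  ``phase`` is ``"random"`` (independent fair coin per
    SNP per parent) or ``"coupling"`` (all alternate alleles on one homolog).
    ``distortion``, when set, redraws calls i.i.d. with the given alternate
    transmission probability at a fraction ``distorted_fraction`` of SNPs —
    a deliberately crude injector used only to exercise the 1:1 filter.
    """

    n_progeny: int
    chromosomes: list
    nu_female: float = 1.0
    nu_male: float = 1.0
    tag_spacing_bp: int = 250_000
    intra_tag_offset_bp: int = 400
    layout: dict | None = None
    phase: str = "random"
    missing_rate: float = 0.0
    miscall_rate: float = 0.0
    distortion: float | None = None
    distorted_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_progeny <= 0:
            raise ValueError("n_progeny must be positive")
        self.chromosomes = [_as_chromosome_spec(c) for c in self.chromosomes]
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for c in self.chromosomes:
            if c.length_bp <= 0 or c.genetic_length_female <= 0 or c.genetic_length_male <= 0:
                raise ValueError(f"chromosome {c.name}: lengths must be positive")
        if self.nu_female <= 0 or self.nu_male <= 0:
            raise ValueError("interference strength nu must be > 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if not (0.0 <= self.miscall_rate <= 1.0):
            raise ValueError("miscall_rate must be in [0, 1]")
        if self.phase not in ("random", "coupling"):
            raise ValueError("phase must be 'random' or 'coupling'")
        if self.layout is not None:
            for name, tags in self.layout.items():
                pos = [p for p, _ in tags]
                if any(b <= a for a, b in zip(pos, pos[1:])):
                    raise ValueError(f"layout for {name}: tag positions must be strictly increasing")

    def nu(self, parent: str) -> float:
        return self.nu_female if parent == "female" else self.nu_male


def default_layout(length_bp: int, spacing_bp: int = 250_000, offset_bp: int = 400):
    """Evenly spaced tags starting half a spacing in from the chromosome start."""
    start = spacing_bp // 2
    return [(p, offset_bp) for p in range(start, length_bp - offset_bp, spacing_bp)]


@dataclass
class TruthRecord:
    """Ground truth of a simulated population, for parameter-recovery tests.

    ``interval_rates``: model-implied recombination fraction of every
    adjacent-tag interval per parent.  ``interval_coc``: model-implied CoC of
    every adjacent interval pair per parent.  ``crossovers``: every realized
    chromatid crossover (parent, progeny index, chrom, Morgan and bp
    position).  ``marker_phase``: 0/1 per marker — which homolog of the
    informative parent carries the alternate allele (row-aligned with the
    returned dataset's markers).
    """

    interval_rates: pd.DataFrame
    interval_coc: pd.DataFrame
    crossovers: pd.DataFrame
    nu: dict
    marker_phase: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))


# ---------------------------------------------------------------------------
# the gamma renewal chiasma model
# ---------------------------------------------------------------------------

def _check_model_params(genetic_length: float, nu: float) -> None:
    if not genetic_length > 0:
        raise ValueError("genetic length must be > 0 Morgans")
    if not nu > 0:
        raise ValueError("interference strength nu must be > 0")


def stationary_zero_chiasma_prob(d, nu: float):
    """P(no chiasma in a window of genetic length d) under the stationary process.

    Closed form from the equilibrium residual distribution of the
    Gamma(nu, rate 2*nu) renewal process:
    ``p0(d) = (1 - F_{nu+1}(d)) - 2 d (1 - F_nu(d))`` with ``F_a`` the
    Gamma(a, scale 1/(2*nu)) CDF.  Reduces to exp(-2d) at nu = 1.
    """
    _check_model_params(1.0, nu)
    d = np.asarray(d, dtype=float)
    scale = 1.0 / (2.0 * nu)
    return (1.0 - stats.gamma.cdf(d, nu + 1.0, scale=scale)) - 2.0 * d * (
        1.0 - stats.gamma.cdf(d, nu, scale=scale)
    )


def recombination_fraction(d, nu: float = 1.0):
    """Model-implied recombination fraction over genetic distance d (Morgans).

    Mather's formula r = (1 - p0) / 2: given at least one chiasma, the
    binomial 1/2-thinning makes an odd crossover count on the chromatid
    exactly probability 1/2.  nu = 1 gives Haldane's map function.
    """
    return 0.5 * (1.0 - stationary_zero_chiasma_prob(d, nu))


def coincidence_coefficient(d1: float, d2: float, nu: float = 1.0) -> float:
    """Model-implied CoC across two adjacent windows of lengths d1, d2 Morgans.

    Parity thinning gives C = P(N1>=1, N2>=1) / (P(N1>=1) P(N2>=1)) in terms
    of chiasma counts; the joint term follows from p0 over the union window.
    """
    p1 = stationary_zero_chiasma_prob(d1, nu)
    p2 = stationary_zero_chiasma_prob(d2, nu)
    p12 = stationary_zero_chiasma_prob(d1 + d2, nu)
    return float((1.0 - p1 - p2 + p12) / ((1.0 - p1) * (1.0 - p2)))


def simulate_meioses(
    genetic_length: float,
    nu: float,
    n_meioses: int,
    rng: np.random.Generator,
    burnin: float = _BURNIN_MORGANS,
) -> list[np.ndarray]:
    """Crossover positions (Morgans) on one observed chromatid per meiosis."""
    _check_model_params(genetic_length, nu)
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    span = burnin + genetic_length
    shape, scale = nu, 1.0 / (2.0 * nu)
    # expected 2*span chiasmata; over-allocate by ~6 sd of the count
    m = int(2 * span + 6 * math.sqrt(2 * span / min(nu, 1.0)) + 20)
    gaps = rng.gamma(shape, scale, size=(n_meioses, m))
    times = np.cumsum(gaps, axis=1) - burnin
    kept = rng.random((n_meioses, m)) < 0.5
    out = []
    for i in range(n_meioses):
        t, k = times[i], kept[i]
        while t[-1] < genetic_length:  # rare top-up
            extra = rng.gamma(shape, scale, size=m)
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
            k = np.concatenate([k, rng.random(m) < 0.5])
        sel = (t > 0.0) & (t < genetic_length) & k
        out.append(np.ascontiguousarray(t[sel]))
    return out


def simulate_chromatid_crossovers(
    genetic_length: float, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """Ordered crossover positions of a single chromatid (one meiosis)."""
    return simulate_meioses(genetic_length, nu, 1, rng)[0]


# ---------------------------------------------------------------------------
# multinomial count tables (unit-test fuel for the estimators)
# ---------------------------------------------------------------------------

def two_point_class_probs(r: float, phase: str = "coupling") -> np.ndarray:
    """Class probabilities of the two-point genotype table.

    Classes ordered (het,het), (het,hom), (hom,het), (hom,hom).  Coupling:
    parental classes carry (1-r)/2, recombinant classes r/2; repulsion swaps
    classes 1<->2 and 3<->4.
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    p = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    if phase == "repulsion":
        p = p[[1, 0, 3, 2]]
    elif phase != "coupling":
        raise ValueError("phase must be 'coupling' or 'repulsion'")
    return p


# class index permutations for flipping het/hom at one of three markers
_FLIP_M1 = np.array([4, 5, 6, 7, 0, 1, 2, 3])
_FLIP_M2 = np.array([2, 3, 0, 1, 6, 7, 4, 5])
_FLIP_M3 = np.array([1, 0, 3, 2, 5, 4, 7, 6])
# phase case -> canonicalizing flip (identity for coupling-coupling)
PHASE_CASE_PERMUTATION = {
    1: np.arange(8),  # coupling, coupling
    2: _FLIP_M3,      # coupling, repulsion
    3: _FLIP_M1,      # repulsion, coupling
    4: _FLIP_M2,      # repulsion, repulsion
}


def _interval_joint_probs(r1: float, r2: float, coc: float) -> np.ndarray:
    """(p00, p01, p10, p11): joint crossover-occurrence probabilities."""
    for r in (r1, r2):
        if not (0.0 <= r <= 0.5):
            raise ValueError("interval rates must be in [0, 0.5]")
    if coc < 0:
        raise ValueError("CoC must be >= 0")
    p11 = r1 * r2 * coc
    p = np.array([1.0 - r1 - r2 + p11, r2 - p11, r1 - p11, p11])
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"CoC {coc} implies invalid class probabilities with r1={r1}, r2={r2}")
    return p


def three_point_class_probs(r1: float, r2: float, coc: float, phase_case: int = 1) -> np.ndarray:
    """Probabilities of the 8 genotype classes at three same-type SNPs.

    Canonical (coupling-coupling) ordering is lexicographic het-before-hom:
    (H,H,H), (H,H,O), (H,O,H), (H,O,O), (O,H,H), (O,H,O), (O,O,H), (O,O,O);
    parental classes 1,8 carry p00/2, single-crossover classes 2,7 (second
    interval) p01/2 and 4,5 (first interval) p10/2, double classes 3,6 p11/2.
    Other phase cases permute the classes by a single-marker het/hom flip.
    """
    p00, p01, p10, p11 = _interval_joint_probs(r1, r2, coc)
    probs = 0.5 * np.array([p00, p01, p11, p10, p10, p11, p01, p00])
    if phase_case not in PHASE_CASE_PERMUTATION:
        raise ValueError("phase_case must be 1..4")
    return probs[PHASE_CASE_PERMUTATION[phase_case]]


def simulate_count_table(
    rates, coc, n: int, phase, rng: np.random.Generator
) -> np.ndarray:
    """Draw a multinomial genotype count table.

    Two-point: ``rates`` a scalar r, ``coc`` None, ``phase`` "coupling" or
    "repulsion" -> 4-class counts.  Three-point: ``rates`` = (r1, r2),
    ``coc`` the coefficient of coincidence, ``phase`` a case 1..4 -> 8-class
    counts.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if np.isscalar(rates):
        probs = two_point_class_probs(float(rates), phase)
    else:
        r1, r2 = rates
        if coc is None:
            raise ValueError("three-point tables need a CoC value")
        probs = three_point_class_probs(float(r1), float(r2), float(coc), phase)
    return rng.multinomial(n, probs)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def simulate_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate genotypes of an F1 pseudo-testcross population.

    Each progeny receives one gamete per parent per chromosome; a SNP of the
    informative parent is het iff the transmitted homolog carries that
    parent's alternate allele.  Deterministic given ``config.seed`` (or a
    supplied generator).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    progeny = [f"F1_{i + 1:04d}" for i in range(config.n_progeny)]

    marker_rows, call_blocks, phase_bits_rows = [], [], []
    rate_rows, coc_rows, xo_rows = [], [], []

    for chrom in config.chromosomes:
        if config.layout is not None:
            layout = config.layout.get(chrom.name)
            if layout is None:
                raise ValueError(f"layout missing chromosome {chrom.name}")
        else:
            layout = default_layout(chrom.length_bp, config.tag_spacing_bp, config.intra_tag_offset_bp)
        if not layout:
            raise ValueError(f"chromosome {chrom.name}: no markers in layout")
        tag_pos = np.array([p for p, _ in layout], dtype=np.int64)
        offsets = np.array([o for _, o in layout], dtype=np.int64)
        if tag_pos[0] < 1 or (tag_pos + offsets)[-1] > chrom.length_bp:
            raise ValueError(f"chromosome {chrom.name}: tags outside chromosome bounds")

        per_parent = {}
        for parent, seg_type in (("female", AB_X_AA), ("male", AA_X_AB)):
            nu = config.nu(parent)
            glen = chrom.genetic_length(parent)
            snp_pos = tag_pos if parent == "female" else tag_pos + offsets
            g = snp_pos / chrom.length_bp * glen

            meioses = simulate_meioses(glen, nu, config.n_progeny, rng)
            h0 = rng.integers(0, 2, config.n_progeny)
            if config.phase == "coupling":
                phase_bits = np.zeros(len(snp_pos), dtype=np.int8)
            else:
                phase_bits = rng.integers(0, 2, len(snp_pos)).astype(np.int8)

            calls = np.empty((len(snp_pos), config.n_progeny), dtype=np.int8)
            for i, xs in enumerate(meioses):
                hap = (h0[i] + np.searchsorted(xs, g)) % 2
                calls[:, i] = np.where(hap == phase_bits, HET, HOM)
                for x in xs:
                    xo_rows.append(
                        (parent, i, chrom.name, float(x), float(x / glen * chrom.length_bp))
                    )
            per_parent[parent] = (snp_pos, calls, phase_bits)

            # model-implied truth on the adjacent-tag intervals
            d = np.diff(g)
            r_true = recombination_fraction(d, nu)
            for k in range(len(d)):
                rate_rows.append(
                    (chrom.name, parent, int(tag_pos[k]), int(tag_pos[k + 1]), float(d[k]), float(r_true[k]))
                )
            for k in range(len(d) - 1):
                coc_rows.append(
                    (chrom.name, parent, int(tag_pos[k]), int(tag_pos[k + 1]), int(tag_pos[k + 2]),
                     coincidence_coefficient(d[k], d[k + 1], nu))
                )

        # interleave the two SNPs of each tag, sorted by position
        for k in range(len(tag_pos)):
            for parent, seg_type in (("female", AB_X_AA), ("male", AA_X_AB)):
                snp_pos, calls, phase_bits = per_parent[parent]
                marker_rows.append((chrom.name, int(snp_pos[k]), seg_type))
                call_blocks.append(calls[k])
                phase_bits_rows.append(phase_bits[k])

    markers = pd.DataFrame(marker_rows, columns=["chrom", "pos", "seg_type"])
    calls = np.vstack(call_blocks).astype(np.int8)
    phase_bits = np.asarray(phase_bits_rows, dtype=np.int8)

    # optional corruption layers, applied marker-wise over the whole matrix
    if config.distortion is not None:
        n_markers = calls.shape[0]
        n_distort = int(round(config.distorted_fraction * n_markers))
        idx = rng.choice(n_markers, size=n_distort, replace=False)
        draw = rng.random((n_distort, config.n_progeny)) < config.distortion
        calls[idx] = np.where(draw, HET, HOM)
    if config.miscall_rate > 0:
        flip = rng.random(calls.shape) < config.miscall_rate
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    dataset = GenotypeDataset(markers, calls, progeny).sort()
    # re-align phase bits with the sorted marker order
    order = markers.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    truth = TruthRecord(
        interval_rates=pd.DataFrame(
            rate_rows, columns=["chrom", "parent", "left_pos", "right_pos", "d_morgans", "rate"]
        ),
        interval_coc=pd.DataFrame(
            coc_rows, columns=["chrom", "parent", "pos1", "pos2", "pos3", "coc"]
        ),
        crossovers=pd.DataFrame(
            xo_rows, columns=["parent", "progeny", "chrom", "pos_morgans", "pos_bp"]
        ),
        nu={"female": config.nu_female, "male": config.nu_male},
        marker_phase=phase_bits[order],
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(dataset: GenotypeDataset, path, chrom_sizes: dict | None = None) -> None:
    """Write a minimal VCF v4.2 with the two parents as the first samples.

    Encodes the pseudo-testcross convention: the informative parent is 0/1,
    the other parent 0/0; progeny het -> 0/1, hom -> 0/0, missing -> ./.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        sizes = chrom_sizes or {
            c: int(dataset.markers.loc[dataset.markers["chrom"] == c, "pos"].max())
            for c in dataset.chromosomes()
        }
        for c, size in sizes.items():
            fh.write(f"##contig=<ID={c},length={size}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                dataset.female, dataset.male, *dataset.progeny]
        fh.write("\t".join(cols) + "\n")
        gt_map = {HET: "0/1", HOM: "0/0", MISSING: "./."}
        for i, row in dataset.markers.iterrows():
            if row.seg_type == AB_X_AA:
                parents = ("0/1", "0/0")
            elif row.seg_type == AA_X_AB:
                parents = ("0/0", "0/1")
            else:
                parents = ("./.", "./.")
            geno = [gt_map[int(v)] for v in dataset.calls[i]]
            fh.write(
                "\t".join(
                    [row.chrom, str(int(row.pos)), f"{row.chrom}:{int(row.pos)}",
                     "A", "C", ".", "PASS", ".", "GT", *parents, *geno]
                )
                + "\n"
            )
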