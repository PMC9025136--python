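"""Genotype containers, segregation typing, and marker-level filters.

An outbred F1 cross gives backcross-like (pseudo-testcross) information at
SNPs where exactly one parent is heterozygous.  A marker segregating
``ab x aa`` (female het, male hom) is informative for female meioses; its
mirror ``aa x ab`` for male meioses.  Progeny calls are coded relative to
the informative parent: ``het`` means the progeny carries the informative
parent's alternate allele, ``hom`` means it equals the homozygous parent's
genotype, and everything else (including low-confidence calls) is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# call codes (int8 matrix values)
HOM = 0
HET = 1
MISSING = -1

# segregation types
AB_X_AA = "ab_x_aa"  # female-informative (first pair = female genotype)
AA_X_AB = "aa_x_ab"  # male-informative
OTHER = "other"

_CALL_TO_STR = {HOM: "hom", HET: "het", MISSING: "missing"}
_STR_TO_CALL = {v: k for k, v in _CALL_TO_STR.items()}

__all__ = [
    "HOM", "HET", "MISSING", "AB_X_AA", "AA_X_AB", "OTHER",
    "GenotypeDataset", "FilterConfig", "FilterReport",
    "read_genotypes", "classify_segregation", "test_segregation_ratio",
    "apply_filters", "write_tsv", "read_tsv",
]


@dataclass
class GenotypeDataset:
    """SNP markers x progeny matrix of pseudo-testcross calls.

    Parameters
    ----------
    markers : pandas.DataFrame
        One row per marker with columns ``chrom`` (str), ``pos`` (1-based bp)
        and ``seg_type`` (one of :data:`AB_X_AA`, :data:`AA_X_AB`,
        :data:`OTHER`).  Rows are kept sorted by (chrom, pos).
    calls : numpy.ndarray
        ``int8`` array of shape (n_markers, n_progeny) holding :data:`HET`,
        :data:`HOM` or :data:`MISSING`.
    progeny : list of str
        Progeny sample names, one per column of ``calls``.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    progeny: list[str]
    female: str = "female"
    male: str = "male"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.progeny)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.progeny)} progeny"
            )
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_progeny(self) -> int:
        return len(self.progeny)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def subset(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            markers=self.markers.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            progeny=list(self.progeny),
            female=self.female,
            male=self.male,
        )

    def markers_of_type(self, seg_type: str, chrom: str | None = None) -> np.ndarray:
        """Indices of markers with the given segregation type (optionally per chrom)."""
        m = (self.markers["seg_type"] == seg_type).to_numpy()
        if chrom is not None:
            m &= (self.markers["chrom"] == chrom).to_numpy()
        return np.flatnonzero(m)

    def sort(self) -> "GenotypeDataset":
        order = self.markers.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return self.subset(order)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.markers.equals(other.markers)
            and np.array_equal(self.calls, other.calls)
            and self.progeny == other.progeny
        )


@dataclass(frozen=True)
class FilterConfig:
    """Marker- and call-level filter thresholds.

    ``seg_ratio_alpha`` is the significance floor of the 1:1 segregation
    chi-square test (markers with p >= alpha are kept); ``max_missing`` the
    tolerated missing-call fraction (strictly more is removed); the DP/GQ
    thresholds apply per call when the VCF carries those FORMAT fields
    (GQ gates heterozygous calls only).
    """

    seg_ratio_alpha: float = 0.01
    max_missing: float = 0.20
    min_dp_het: int = 3
    min_dp_hom: int = 5
    min_gq: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.seg_ratio_alpha <= 1.0):
            raise ValueError("seg_ratio_alpha must be in [0, 1]")
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must be in [0, 1]")
        if min(self.min_dp_het, self.min_dp_hom, self.min_gq) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    removed_unclassified: int = 0
    removed_segregation: int = 0
    removed_missing: int = 0
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_unclassified": self.removed_unclassified,
            "removed_segregation": self.removed_segregation,
            "removed_missing": self.removed_missing,
            **self.counts,
        }


def classify_segregation(female_gt: str, male_gt: str) -> str:
    """Classify a marker by parental genotypes into a segregation type.

    Genotypes are ``"het"``, ``"hom"`` (either homozygote) or ``"missing"``.
    het x hom -> female-informative ``ab x aa``; hom x het -> ``aa x ab``;
    anything else (both het, both hom) is uninformative.

    Raises
    ------
    ValueError
        If either parental genotype is missing: the marker cannot be
        classified at all, which callers should treat as a flag, not a type.
    """
    if female_gt == "missing" or male_gt == "missing":
        raise ValueError("parental genotype missing; marker unclassifiable")
    if female_gt == "het" and male_gt == "hom":
        return AB_X_AA
    if female_gt == "hom" and male_gt == "het":
        return AA_X_AB
    return OTHER


def test_segregation_ratio(n_het: int, n_hom: int) -> tuple[float, float]:
    """Chi-square test of the 1:1 Mendelian segregation ratio.

    chi2 = (n_het - n_hom)^2 / (n_het + n_hom), 1 df, no continuity
    correction.  Returns ``(chi2, p)``.
    """
    total = n_het + n_hom
    if total <= 0:
        raise ValueError("segregation test undefined with zero genotyped progeny")
    chi2 = (n_het - n_hom) ** 2 / total
    return chi2, float(stats.chi2.sf(chi2, df=1))


def apply_filters(
    dataset: GenotypeDataset, config: FilterConfig | None = None
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the marker-level filters and return the retained dataset.

    A marker is kept iff its segregation type is informative, its 1:1 test
    p-value is >= ``seg_ratio_alpha`` and its missing fraction across progeny
    is <= ``max_missing``.  Filtering is idempotent.
    """
    config = config or FilterConfig()
    report = FilterReport(n_input=dataset.n_markers)

    seg = dataset.markers["seg_type"].to_numpy()
    informative = (seg == AB_X_AA) | (seg == AA_X_AB)

    n_het = (dataset.calls == HET).sum(axis=1)
    n_hom = (dataset.calls == HOM).sum(axis=1)
    n_miss = (dataset.calls == MISSING).sum(axis=1)
    total = n_het + n_hom

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(total > 0, (n_het - n_hom) ** 2 / np.maximum(total, 1), np.inf)
    pvals = stats.chi2.sf(chi2, df=1)
    seg_ok = (total > 0) & (pvals >= config.seg_ratio_alpha)

    miss_ok = n_miss / max(dataset.n_progeny, 1) <= config.max_missing

    keep = informative & seg_ok & miss_ok
    report.removed_unclassified = int((~informative).sum())
    report.removed_segregation = int((informative & ~seg_ok).sum())
    report.removed_missing = int((informative & seg_ok & ~miss_ok).sum())
    report.n_kept = int(keep.sum())
    if report.n_kept == 0:
        logger.warning("all %d markers removed by filtering", dataset.n_markers)
    return dataset.subset(keep), report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_FIXED = ["chrom", "pos", "id", "seg_type"]


def write_tsv(dataset: GenotypeDataset, path) -> None:
    """Write the simplified TSV genotype dialect.

    Columns: chrom, pos (1-based), id, seg_type (``ab_x_aa``/``aa_x_ab``/
    ``other``), then one column per progeny with values het/hom/missing.
    """
    df = dataset.markers[["chrom", "pos", "seg_type"]].copy()
    df.insert(2, "id", [f"{c}:{p}" for c, p in zip(df["chrom"], df["pos"])])
    calls = pd.DataFrame(
        np.vectorize(_CALL_TO_STR.get)(dataset.calls),
        columns=dataset.progeny,
    )
    pd.concat([df.reset_index(drop=True), calls], axis=1).to_csv(path, sep="\t", index=False)


def read_tsv(path, female: str = "female", male: str = "male") -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in _TSV_FIXED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"TSV genotype file lacks required columns {missing_cols}")
    progeny = [c for c in df.columns if c not in _TSV_FIXED]
    bad = ~df[progeny].isin(list(_STR_TO_CALL)).all(axis=1)
    if bad.any():
        raise ValueError(
            f"malformed genotype value at line {int(np.flatnonzero(bad)[0]) + 2}"
        )
    calls = df[progeny].apply(lambda col: col.map(_STR_TO_CALL)).to_numpy(dtype=np.int8)
    markers = df[["chrom", "pos", "seg_type"]].copy()
    return GenotypeDataset(markers, calls, progeny, female=female, male=male).sort()


def _classify_from_codes(f_code: int, m_code: int) -> str:
    # cyvcf2 gts012 codes: 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
    names = {0: "hom", 1: "het", 2: "hom", 3: "missing"}
    try:
        return classify_segregation(names[f_code], names[m_code])
    except ValueError:
        return OTHER


def read_vcf(
    path,
    female: str | None = None,
    male: str | None = None,
    config: FilterConfig | None = None,
) -> GenotypeDataset:
    """Read a VCF (v4.x) into a :class:`GenotypeDataset`.

    The two parents are identified by sample name (default: first two
    samples, female first).  Multiallelic sites are skipped and counted.
    Progeny calls failing the DP/AD/GQ thresholds, or incompatible with the
    cross (the impossible homozygote), are set to missing.
    """
    from cyvcf2 import VCF

    config = config or FilterConfig()
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(samples) < 3:
        raise ValueError("VCF must contain two parents and at least one progeny sample")
    female = female or samples[0]
    male = male or samples[1]
    for name in (female, male):
        if name not in samples:
            raise ValueError(f"parent sample {name!r} not in VCF")
    fi, mi = samples.index(female), samples.index(male)
    prog_idx = [i for i in range(len(samples)) if i not in (fi, mi)]
    progeny = [samples[i] for i in prog_idx]

    rows, calls = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gt = variant.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        seg = _classify_from_codes(int(gt[fi]), int(gt[mi]))
        hom_parent_code = int(gt[mi]) if seg == AB_X_AA else int(gt[fi])

        dp = _maybe_format(variant, "DP")
        ad = _maybe_format(variant, "AD")
        gq = _maybe_format(variant, "GQ")

        row_calls = np.full(len(prog_idx), MISSING, dtype=np.int8)
        for out_j, j in enumerate(prog_idx):
            code = int(gt[j])
            if code == 3:
                continue
            if code == 1:
                call = HET
            elif seg in (AB_X_AA, AA_X_AB) and code != hom_parent_code:
                continue  # homozygote impossible under the cross
            else:
                call = HOM
            if not _call_passes_depth(call, code, j, dp, ad, gq, config):
                continue
            row_calls[out_j] = call
        rows.append((variant.CHROM, variant.POS, seg))
        calls.append(row_calls)
    if n_multi:
        logger.info("skipped %d multiallelic sites", n_multi)
    if not rows:
        raise ValueError("no biallelic SNP records found in VCF")
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "seg_type"])
    return GenotypeDataset(
        markers, np.array(calls, dtype=np.int8), progeny, female=female, male=male
    ).sort()


def _maybe_format(variant, key: str):
    try:
        return variant.format(key)
    except KeyError:
        return None


def _call_passes_depth(call, code, j, dp, ad, gq, config: FilterConfig) -> bool:
    """DP>=3 & GQ>30 for het; DP>=5 for hom; allele depths used when present."""
    if ad is not None and ad.shape[1] >= 2:
        ref_d, alt_d = int(ad[j, 0]), int(ad[j, 1])
        if ref_d >= 0 and alt_d >= 0:
            if call == HET:
                if min(ref_d, alt_d) < config.min_dp_het:
                    return False
            else:
                called = alt_d if code == 2 else ref_d
                if called < config.min_dp_hom:
                    return False
    elif dp is not None:
        d = int(np.ravel(dp[j])[0])
        if d >= 0:
            threshold = config.min_dp_het if call == HET else config.min_dp_hom
            if d < threshold:
                return False
    if call == HET and gq is not None:
        q = float(np.ravel(gq[j])[0])
        if q >= 0 and not q > config.min_gq:
            return False
    return True


def read_genotypes(
    path,
    format: str = "auto",
    female: str | None = None,
    male: str | None = None,
    config: FilterConfig | None = None,
) -> GenotypeDataset:
    """Read genotypes from a VCF or the simplified TSV dialect."""
    fmt = format
    if fmt == "auto":
        s = str(path)
        fmt = "vcf" if s.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if fmt == "vcf":
        return read_vcf(path, female=female, male=male, config=config)
    if fmt == "tsv":
        return read_tsv(path, female=female or "female", male=male or "male")
    raise ValueError(f"unknown genotype format {format!r}")
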