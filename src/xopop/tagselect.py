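"""RAD-tag pairing, spacing selection, intervals and genome coverage.

A RAD tag here is a pair of nearby SNPs of opposite segregation types
(< 1 kb apart), so each tag reads out both the female and the male meiosis
at essentially the same genomic point.  Tags spaced > 100 kb apart define
the intervals over which crossover rates are compared between parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genotypes import AA_X_AB, AB_X_AA, GenotypeDataset

__all__ = [
    "RadTagPair", "TagInterval",
    "pair_snps_into_tags", "select_spaced_tags", "build_intervals",
    "genome_coverage", "merge_spans", "tags_to_frame",
]


@dataclass(frozen=True)
class RadTagPair:
    """Two opposite-type SNPs forming one tag; tag_pos is their midpoint (bp)."""

    chrom: str
    f_index: int  # dataset row of the ab x aa SNP
    m_index: int  # dataset row of the aa x ab SNP
    f_pos: int
    m_pos: int

    @property
    def tag_pos(self) -> float:
        return 0.5 * (self.f_pos + self.m_pos)

    @property
    def span(self) -> int:
        return abs(self.m_pos - self.f_pos)


@dataclass(frozen=True)
class TagInterval:
    """The stretch between two adjacent selected tags on one chromosome."""

    chrom: str
    left: RadTagPair
    right: RadTagPair

    @property
    def length_bp(self) -> float:
        return self.right.tag_pos - self.left.tag_pos


def pair_snps_into_tags(
    dataset: GenotypeDataset, max_intra_bp: int = 1000
) -> list[RadTagPair]:
    """Pair each female-informative SNP with a male-informative one < max_intra_bp away.

    When several opposite-type SNPs are within range, the closest two are
    paired first; every SNP is used in at most one tag.  SNPs left without a
    partner are simply unpaired.
    """
    tags: list[RadTagPair] = []
    for chrom in dataset.chromosomes():
        fi = dataset.markers_of_type(AB_X_AA, chrom)
        mi = dataset.markers_of_type(AA_X_AB, chrom)
        if len(fi) == 0 or len(mi) == 0:
            continue
        fpos = dataset.markers["pos"].to_numpy()[fi]
        mpos = dataset.markers["pos"].to_numpy()[mi]
        # candidate pairs within the intra-tag window, closest first
        cands = []
        start = 0
        for a, pa in enumerate(fpos):
            while start < len(mpos) and mpos[start] < pa - max_intra_bp:
                start += 1
            b = start
            while b < len(mpos) and mpos[b] < pa + max_intra_bp:
                cands.append((abs(int(mpos[b]) - int(pa)), a, b))
                b += 1
        cands.sort()
        used_f, used_m = set(), set()
        for dist, a, b in cands:
            if dist >= max_intra_bp or a in used_f or b in used_m:
                continue
            used_f.add(a)
            used_m.add(b)
            tags.append(
                RadTagPair(chrom, int(fi[a]), int(mi[b]), int(fpos[a]), int(mpos[b]))
            )
    tags.sort(key=lambda t: (t.chrom, t.tag_pos))
    return tags


def select_spaced_tags(tags: list[RadTagPair], min_gap_bp: int = 100_000) -> list[RadTagPair]:
    """Greedy left-to-right selection keeping adjacent tags > min_gap_bp apart.

    The first tag of each chromosome anchors the walk; the next selected tag
    is the earliest one strictly more than ``min_gap_bp`` downstream.
    """
    selected: list[RadTagPair] = []
    last: RadTagPair | None = None
    for tag in tags:
        if last is None or tag.chrom != last.chrom or tag.tag_pos - last.tag_pos > min_gap_bp:
            selected.append(tag)
            last = tag
    return selected


def build_intervals(selected: list[RadTagPair]) -> list[TagInterval]:
    """Adjacent selected tags -> intervals; k tags on a chromosome give k-1."""
    intervals = []
    for left, right in zip(selected, selected[1:]):
        if left.chrom == right.chrom:
            intervals.append(TagInterval(left.chrom, left, right))
    return intervals


def merge_spans(spans) -> list[tuple[float, float]]:
    """Union of (start, end) spans; overlapping or touching spans merge."""
    spans = sorted((float(s), float(e)) for s, e in spans)
    merged: list[list[float]] = []
    for s, e in spans:
        if e < s:
            raise ValueError(f"span ({s}, {e}) has negative length")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def genome_coverage(regions, chrom_sizes: dict) -> float:
    """Fraction of the genome covered by the union of regions.

    ``regions`` is an iterable of ``(chrom, start_bp, end_bp)``; touching or
    overlapping spans are merged per chromosome before summing, and the
    union length is divided by the total size of ``chrom_sizes``.
    """
    per_chrom: dict[str, list] = {}
    for chrom, start, end in regions:
        if chrom not in chrom_sizes:
            raise ValueError(f"region on unknown chromosome {chrom!r}")
        if start < 0 or end > chrom_sizes[chrom]:
            raise ValueError(f"region ({chrom}, {start}, {end}) outside chromosome bounds")
        per_chrom.setdefault(chrom, []).append((start, end))
    covered = 0.0
    for chrom, spans in per_chrom.items():
        covered += sum(e - s for s, e in merge_spans(spans))
    total = float(sum(chrom_sizes.values()))
    return covered / total if total > 0 else 0.0


def tags_to_frame(tags: list[RadTagPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.chrom, t.tag_pos, t.f_pos, t.m_pos, t.span) for t in tags],
        columns=["chrom", "tag_pos", "f_pos", "m_pos", "intra_span"],
    )


def tags_to_bed(tags: list[RadTagPair]) -> pd.DataFrame:
    """Tags as BED (0-based half-open over the two SNP positions)."""
    rows = [
        (t.chrom, min(t.f_pos, t.m_pos) - 1, max(t.f_pos, t.m_pos), f"tag_{i}")
        for i, t in enumerate(tags)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
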