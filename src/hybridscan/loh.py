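"""Marker-based loss-of-heterozygosity calling.

Because the simulated parents are collinear (substitution-only
divergence), every differing site is a single-nucleotide marker
distinguishing the two parental subgenomes.  Reads placed on the shared
coordinate system vote for the parent 1 or parent 2 allele at each marker
they cover; markers are genotyped HOM_P1 / HOM_P2 / HET (NO_CALL below a
depth floor), and maximal runs of same-parent homozygous calls form LOH
segments.  Cohort-level maps report, per genomic bin, the fraction of
samples bearing LOH toward each parent — restricted to hybrids that
inherited at least 20% of their nuclear genome from each parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._encoding import _CODE, encode
from .simulate import MITO, ParentGenome, ReadSet

HOM_P1, HOM_P2, HET, NO_CALL = "HOM_P1", "HOM_P2", "HET", "NO_CALL"

__all__ = [
    "LOHSegment",
    "derive_markers",
    "count_alleles",
    "genotype_markers",
    "call_loh_segments",
    "loh_fraction",
    "region_frequency",
]


def derive_markers(parent1: ParentGenome, parent2: ParentGenome) -> pd.DataFrame:
    """One marker per site where the collinear parents differ.

    Returns columns chromosome, position (0-based), allele_p1, allele_p2,
    with positions strictly increasing within each chromosome.
    """
    if parent1.chrom_names != parent2.chrom_names:
        raise ValueError("parents are not collinear: chromosome sets differ")
    rows = []
    for (name, s1), (_n2, s2) in zip(parent1.chromosomes, parent2.chromosomes):
        if len(s1) != len(s2):
            raise ValueError(f"parents are not collinear: {name} lengths differ")
        a1 = encode(s1)
        a2 = encode(s2)
        diff = np.flatnonzero(a1 != a2)
        for pos in diff:
            rows.append((name, int(pos), s1[pos], s2[pos]))
    return pd.DataFrame(rows, columns=["chromosome", "position", "allele_p1", "allele_p2"])


def count_alleles(
    markers: pd.DataFrame,
    reads: ReadSet,
    assignments: pd.DataFrame,
    exclude_bed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parental allele depths per marker from placed reads.

    Uses every confidently placed nuclear read regardless of which parent
    it was assigned to (within an LOH tract the lost subgenome carries the
    retained parent's sequence and its reads are assigned accordingly —
    position on the shared coordinate system is what matters).  Bases are
    read strand-aware at each covered marker.  ``exclude_bed`` optionally
    masks regions (e.g. subtelomeres) with columns chromosome/start/end.
    """
    rl = reads.read_length
    out = markers.copy()
    depth1 = np.zeros(len(markers), dtype=np.int64)
    depth2 = np.zeros(len(markers), dtype=np.int64)
    pos_by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    for chrom, g in markers.groupby("chromosome"):
        pos_by_chrom[chrom] = g["position"].to_numpy()
        idx_by_chrom[chrom] = g.index.to_numpy()
    a1_codes = _CODE[np.frombuffer("".join(markers["allele_p1"]).encode(), np.uint8)]
    a2_codes = _CODE[np.frombuffer("".join(markers["allele_p2"]).encode(), np.uint8)]
    placed = assignments[
        ~assignments["species"].isin(["AMBIGUOUS", "UNASSIGNED"])
        & (assignments["chromosome"] != MITO)
    ]
    read_index = {name: i for i, name in enumerate(reads.names)}
    for name, chrom, start, strand in zip(
        placed["read"], placed["chromosome"], placed["position"], placed["strand"]
    ):
        mpos = pos_by_chrom.get(chrom)
        if mpos is None:
            continue
        lo = np.searchsorted(mpos, start, side="left")
        hi = np.searchsorted(mpos, start + rl, side="left")
        if lo == hi:
            continue
        seq_codes = encode(reads.seqs[read_index[name]])
        covered = mpos[lo:hi]
        offsets = covered - start
        if strand == "-":
            bases = 3 - seq_codes[rl - 1 - offsets]
        else:
            bases = seq_codes[offsets]
        rows = idx_by_chrom[chrom][lo:hi]
        depth1[rows] += bases == a1_codes[rows]
        depth2[rows] += bases == a2_codes[rows]
    out["depth_p1"] = depth1
    out["depth_p2"] = depth2
    if exclude_bed is not None and len(exclude_bed):
        drop = np.zeros(len(out), dtype=bool)
        for chrom, s, e in zip(exclude_bed["chromosome"], exclude_bed["start"], exclude_bed["end"]):
            drop |= (out["chromosome"] == chrom) & (out["position"] >= s) & (out["position"] < e)
        out = out[~drop].reset_index(drop=True)
    return out


def genotype_markers(
    counts: pd.DataFrame, min_depth: int = 3, purity: float = 0.9
) -> pd.DataFrame:
    """Genotype each marker from its allele depths.

    HOM_P1 when the parent-1 fraction of informative depth is >= purity,
    HOM_P2 symmetrically, HET otherwise; NO_CALL when total informative
    depth is below ``min_depth``.
    """
    out = counts.copy()
    d1 = out["depth_p1"].to_numpy(dtype=float)
    d2 = out["depth_p2"].to_numpy(dtype=float)
    total = d1 + d2
    call = np.full(len(out), HET, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(total > 0, d1 / np.where(total > 0, total, 1), 0.0)
    call[frac1 >= purity] = HOM_P1
    call[(1.0 - frac1 >= purity) & (total > 0)] = HOM_P2
    call[total < min_depth] = NO_CALL
    out["call"] = call
    return out


@dataclass
class LOHSegment:
    chromosome: str
    start: int
    end: int  # half-open; last marker position + 1
    retained_parent: str  # "P1" | "P2"
    n_markers: int


def call_loh_segments(genotypes: pd.DataFrame, min_run: int = 10) -> list[LOHSegment]:
    """Maximal runs of >= min_run same-parent homozygous markers.

    NO_CALL markers are transparent (missing data neither extends nor
    breaks a run); HET or opposite-parent calls terminate runs.  Segment
    coordinates span the first to last marker of the run.
    """
    segments: list[LOHSegment] = []
    for chrom, g in genotypes.groupby("chromosome", sort=False):
        g = g.sort_values("position")
        calls = g["call"].to_numpy()
        pos = g["position"].to_numpy()
        informative = calls != NO_CALL
        calls, pos = calls[informative], pos[informative]
        i = 0
        n = len(calls)
        while i < n:
            c = calls[i]
            if c not in (HOM_P1, HOM_P2):
                i += 1
                continue
            j = i
            while j < n and calls[j] == c:
                j += 1
            run = j - i
            if run >= min_run:
                segments.append(LOHSegment(
                    chromosome=chrom, start=int(pos[i]), end=int(pos[j - 1]) + 1,
                    retained_parent="P1" if c == HOM_P1 else "P2", n_markers=run))
            i = j
    return segments


def loh_fraction(segments: list[LOHSegment], genome_length: int) -> float:
    """Percentage of the genome covered by LOH segments."""
    by_chrom: dict[str, list[LOHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    total = 0
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping LOH segments on {chrom}")
        total += sum(s.end - s.start for s in segs)
    return 100.0 * total / genome_length


def region_frequency(
    segments_by_sample: dict[str, list[LOHSegment]],
    contributions_by_sample: dict[str, dict[str, float]],
    chrom_lengths: dict[str, int],
    bin_size: int = 10_000,
    min_parent_frac: float = 0.20,
    min_bin_cover: float = 0.5,
) -> pd.DataFrame:
    """Per-bin fraction of samples bearing LOH toward each parent.

    Samples are included only if both parental contributions are at least
    ``min_parent_frac`` of their total (the >=20%-per-parent rule).  A
    sample bears LOH in a bin when matching segments cover at least
    ``min_bin_cover`` of the bin.  Returns columns chromosome, start, end,
    freq_p1, freq_p2 (fractions in [0, 1]).
    """
    included = []
    for sample, contrib in contributions_by_sample.items():
        vals = sorted(contrib.values(), reverse=True)[:2]
        total = sum(contrib.values())
        if len(vals) == 2 and total > 0 and min(vals) / total >= min_parent_frac:
            included.append(sample)
    if not included:
        raise ValueError("no samples pass the per-parent contribution filter")
    rows = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L, bin_size)
        ends = np.minimum(starts + bin_size, L)
        bearing = {p: np.zeros(starts.size) for p in ("P1", "P2")}
        for sample in included:
            cover = {p: np.zeros(L) for p in ("P1", "P2")}
            for seg in segments_by_sample.get(sample, []):
                if seg.chromosome == chrom:
                    cover[seg.retained_parent][seg.start : seg.end] = 1
            for p in ("P1", "P2"):
                cs = np.concatenate(([0.0], np.cumsum(cover[p])))
                frac = (cs[ends] - cs[starts]) / (ends - starts)
                bearing[p] += frac >= min_bin_cover
        for i in range(starts.size):
            rows.append((chrom, int(starts[i]), int(ends[i]),
                         bearing["P1"][i] / len(included), bearing["P2"][i] / len(included)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "freq_p1", "freq_p2"])
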