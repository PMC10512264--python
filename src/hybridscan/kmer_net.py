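"""Alignment-free shared-k-mer profiling and distance matrices.

Each sample (a read set or a genome) is reduced to the set of canonical
17-mers observed at least ``min_count`` times (default 5; a lower cut-off
of 2 serves as a read-depth sensitivity variant).  Pairwise shared-k-mer
counts give both the distributions used to compare hybrid crosses and an
AAF-style distance D_ij = -(1/k) * ln(S_ij / min(|A|, |B|)), exportable as
square PHYLIP or a NEXUS Distances block for network software.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._encoding import canonical_set

__all__ = [
    "KmerProfile",
    "SharedMatrix",
    "kmer_profile",
    "shared_kmers",
    "distance_matrix",
    "export_distances",
    "read_distances",
    "cross_statistics",
]


@dataclass
class KmerProfile:
    sample_id: str
    k: int
    min_count: int
    codes: np.ndarray  # sorted unique canonical k-mer codes
    flags: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.codes.size)


def kmer_profile(seqs, k: int = 17, min_count: int = 5, sample_id: str = "") -> KmerProfile:
    """Canonical k-mer set of a sample, thresholded at ``min_count``
    occurrences (inclusive: a k-mer seen exactly ``min_count`` times is
    kept).  ``seqs`` is an iterable of sequences, a ReadSet, or a
    ParentGenome."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if hasattr(seqs, "seqs"):  # ReadSet
        seq_list = seqs.seqs
    elif hasattr(seqs, "chromosomes"):  # ParentGenome
        seq_list = [s for _n, s in seqs.chromosomes]
    else:
        seq_list = list(seqs)
    flags = []
    if not any(len(s) >= k for s in seq_list):
        flags.append("no sequence of length >= k")
        return KmerProfile(sample_id, k, min_count, np.empty(0, dtype=np.int64), flags)
    codes = canonical_set(seq_list, k, min_count)
    return KmerProfile(sample_id, k, min_count, codes, flags)


def shared_kmers(a: KmerProfile, b: KmerProfile) -> int:
    """Size of the intersection of two profiles' canonical k-mer sets."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    return int(np.intersect1d(a.codes, b.codes, assume_unique=True).size)


@dataclass
class SharedMatrix:
    samples: list[str]
    shared: np.ndarray  # symmetric counts; diagonal = profile totals
    distance: np.ndarray  # AAF-style distances; zero diagonal
    capped: list[tuple[str, str]] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)


def distance_matrix(profiles: list[KmerProfile]) -> SharedMatrix:
    """Pairwise shared counts and distances for a set of profiles.

    D_ij = -(1/k) ln(S_ij / min(total_i, total_j)); identical profiles are
    at distance 0.  A pair sharing no k-mer has no finite distance; those
    entries are set to 1.1x the largest finite distance in the matrix and
    recorded in ``capped`` so exports can carry a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    k = profiles[0].k
    if any(p.k != k for p in profiles):
        raise ValueError("profiles disagree on k")
    n = len(profiles)
    labels = [p.sample_id for p in profiles]
    flagged = [p.sample_id for p in profiles if p.total == 0]
    shared = np.zeros((n, n), dtype=np.int64)
    dist = np.zeros((n, n))
    capped_pairs: list[tuple[int, int]] = []
    for i in range(n):
        shared[i, i] = profiles[i].total
        for j in range(i + 1, n):
            s = shared_kmers(profiles[i], profiles[j])
            shared[i, j] = shared[j, i] = s
            denom = min(profiles[i].total, profiles[j].total)
            if s > 0 and denom > 0:
                d = -math.log(s / denom) / k
            else:
                d = math.nan
                capped_pairs.append((i, j))
            dist[i, j] = dist[j, i] = d
    finite = dist[np.isfinite(dist)]
    cap = 1.1 * float(finite.max()) if finite.size else 1.0
    capped_labels = []
    for i, j in capped_pairs:
        dist[i, j] = dist[j, i] = cap
        capped_labels.append((labels[i], labels[j]))
    return SharedMatrix(labels, shared, dist, capped_labels, flagged)


# ---------------------------------------------------------------------------
# export (square PHYLIP / NEXUS Distances block)
# ---------------------------------------------------------------------------

def _sanitize(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


def export_distances(matrix: SharedMatrix, path, fmt: str = "phylip") -> None:
    path = Path(path)
    labels = [_sanitize(l) for l in matrix.samples]
    n = len(labels)
    d = matrix.distance
    lines = []
    if fmt == "phylip":
        lines.append(f"{n}")
        for i in range(n):
            row = " ".join(f"{d[i, j]:.8f}" for j in range(n))
            lines.append(f"{labels[i]:<12s}{row}")
    elif fmt == "nexus":
        lines += ["#NEXUS", ""]
        if matrix.capped:
            pairs = "; ".join(f"{a}-{b}" for a, b in matrix.capped)
            lines.append(f"[WARNING: capped distances (no shared k-mers): {pairs}]")
        lines += [
            "BEGIN Taxa;",
            f"DIMENSIONS ntax={n};",
            "TAXLABELS " + " ".join(labels) + ";",
            "END;",
            "",
            "BEGIN Distances;",
            f"DIMENSIONS ntax={n};",
            "FORMAT labels=left diagonal triangle=both;",
            "MATRIX",
        ]
        for i in range(n):
            row = " ".join(f"{d[i, j]:.8f}" for j in range(n))
            lines.append(f"{labels[i]} {row}")
        lines += [";", "END;"]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def read_distances(path, fmt: str = "phylip") -> tuple[list[str], np.ndarray]:
    """Parse files written by :func:`export_distances` (round-trip check)."""
    text = Path(path).read_text()
    labels: list[str] = []
    rows: list[list[float]] = []
    if fmt == "phylip":
        lines = [l for l in text.splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    elif fmt == "nexus":
        m = re.search(r"BEGIN Distances;.*?MATRIX\n(.*?)\n;", text, re.S | re.I)
        if not m:
            raise ValueError("no Distances block found")
        for line in m.group(1).splitlines():
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return labels, np.array(rows)


# ---------------------------------------------------------------------------
# cross-level statistics
# ---------------------------------------------------------------------------

def cross_statistics(
    matrix: SharedMatrix,
    cross_of: dict[str, str],
    parent_distance: dict[str, float] | None = None,
) -> dict:
    """Intra/inter-cross shared-k-mer distributions and the correlation of
    per-cross mean shared k-mers with parental genetic distance.

    ``cross_of`` maps sample label -> cross; crosses with fewer than two
    samples have no intra pairs and are excluded from the correlation.
    Returns a dict with per_cross (DataFrame), intra/inter/total arrays of
    shared counts, and (r, p) when ``parent_distance`` is supplied.
    """
    labels = matrix.samples
    n = len(labels)
    intra: dict[str, list[int]] = {}
    inter: list[int] = []
    total: list[int] = []
    for i in range(n):
        for j in range(i + 1, n):
            s = int(matrix.shared[i, j])
            total.append(s)
            ci, cj = cross_of[labels[i]], cross_of[labels[j]]
            if ci == cj:
                intra.setdefault(ci, []).append(s)
            else:
                inter.append(s)
    rows = []
    excluded = []
    for cross in sorted({cross_of[l] for l in labels}):
        vals = intra.get(cross, [])
        if not vals:
            excluded.append(cross)
            continue
        rows.append({
            "cross": cross,
            "n_pairs": len(vals),
            "mean_shared": float(np.mean(vals)),
            "sd_shared": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        })
    per_cross = pd.DataFrame(rows)
    result = {
        "per_cross": per_cross,
        "intra": {c: np.array(v) for c, v in intra.items()},
        "inter": np.array(inter),
        "total": np.array(total),
        "excluded_crosses": excluded,
        "r": None,
        "p": None,
    }
    if parent_distance is not None and len(per_cross) >= 2:
        x = per_cross["cross"].map(parent_distance).to_numpy(dtype=float)
        y = per_cross["mean_shared"].to_numpy(dtype=float)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r, p = stats.pearsonr(x, y)
            result["r"], result["p"] = float(r), float(p)
    return result
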