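"""Species-contribution estimation from reads via diagnostic k-mers.

Competitive mapping of hybrid reads against a combined multi-species
reference assigns each read to the parental subgenome it matches best,
keeping only confident placements.  This module implements that idea
alignment-free: k-mers occurring in exactly one parental genome are
*diagnostic* for that species, and a read is assigned to the species
collecting the most diagnostic hits, provided the hit count and the
margin over the runner-up clear configurable floors (the analogue of a
mapping-quality filter).  Mitochondrial inheritance is classified the
same way against a separate index of mitochondrial haplotypes, with
species that harbour several divergent mitochondrial clades scored by
their best clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._encoding import canonical_codes, encode
from .simulate import MITO, ParentGenome, ReadSet

AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

__all__ = [
    "DiagnosticIndex",
    "ContributionProfile",
    "InclusionDecision",
    "WelchResult",
    "build_diagnostic_index",
    "build_mito_index",
    "ReadKmers",
    "prepare_read_kmers",
    "assign_reads",
    "species_contributions",
    "compute_profile",
    "inclusion_filter",
    "mito_assign",
    "welch_t",
    "concordance_test",
]


# ---------------------------------------------------------------------------
# diagnostic index
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticIndex:
    """Sorted arrays of canonical k-mers unique to one source genome.

    ``codes`` is sorted; parallel arrays give the source label index, the
    chromosome index within that source, the 0-based position of the
    k-mer's first occurrence, and the forward-strand packed code at that
    reference position (used to orient reads).
    """

    k: int
    labels: list[str]
    chrom_names: list[list[str]]
    codes: np.ndarray
    label_idx: np.ndarray
    chrom_idx: np.ndarray
    pos: np.ndarray
    ref_fwd: np.ndarray
    ambiguous_count: int

    @property
    def n_diagnostic(self) -> int:
        return int(self.codes.size)


def _genome_kmers(seqs: list[str], k: int):
    """Unique canonical codes of a genome with first-occurrence metadata."""
    canons, fwds, chroms, poss = [], [], [], []
    for ci, seq in enumerate(seqs):
        if len(seq) < k:
            raise ValueError(f"sequence {ci} shorter than k={k}")
        canon, fwd, valid = canonical_codes(encode(seq), k)
        canons.append(canon[valid])
        fwds.append(fwd[valid])
        n = int(valid.sum())
        chroms.append(np.full(n, ci, dtype=np.int32))
        poss.append(np.flatnonzero(valid).astype(np.int64))
    canon = np.concatenate(canons)
    order_codes, first = np.unique(canon, return_index=True)
    fwd = np.concatenate(fwds)[first]
    chrom = np.concatenate(chroms)[first]
    pos = np.concatenate(poss)[first]
    return order_codes, fwd, chrom, pos


def _build_index(sources: list[tuple[str, list[str], list[str]]], k: int) -> DiagnosticIndex:
    """sources: (label, chrom_names, sequences)."""
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    if len(sources) < 2:
        raise ValueError("need at least two source genomes")
    per = [(_genome_kmers(seqs, k)) for _label, _names, seqs in sources]
    all_codes = np.concatenate([p[0] for p in per])
    uniq, counts = np.unique(all_codes, return_counts=True)
    diag = uniq[counts == 1]
    ambiguous = int((counts > 1).sum())
    codes_l, fwd_l, lab_l, chrom_l, pos_l = [], [], [], [], []
    for li, (codes, fwd, chrom, pos) in enumerate(per):
        keep = np.isin(codes, diag, assume_unique=True)
        codes_l.append(codes[keep])
        fwd_l.append(fwd[keep])
        chrom_l.append(chrom[keep])
        pos_l.append(pos[keep])
        lab_l.append(np.full(int(keep.sum()), li, dtype=np.int16))
    codes = np.concatenate(codes_l)
    order = np.argsort(codes)
    return DiagnosticIndex(
        k=k,
        labels=[s[0] for s in sources],
        chrom_names=[s[1] for s in sources],
        codes=codes[order],
        label_idx=np.concatenate(lab_l)[order],
        chrom_idx=np.concatenate(chrom_l)[order],
        pos=np.concatenate(pos_l)[order],
        ref_fwd=np.concatenate(fwd_l)[order],
        ambiguous_count=ambiguous,
    )


def build_diagnostic_index(parents: list[ParentGenome], k: int = 17) -> DiagnosticIndex:
    """Index nuclear k-mers unique to exactly one parental species."""
    sources = [(p.species_id, p.chrom_names, [s for _n, s in p.chromosomes]) for p in parents]
    return _build_index(sources, k)


def build_mito_index(parents: list[ParentGenome], k: int = 17) -> DiagnosticIndex:
    """Index mitochondrial k-mers; one source per (species, clade) haplotype."""
    sources = []
    for p in parents:
        for clade, seq in p.mito:
            sources.append((f"{p.species_id}:{clade}", [MITO], [seq]))
    return _build_index(sources, k)


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

@dataclass
class ReadKmers:
    """Canonical/forward k-mer codes of a read set, computed once and
    reusable across indexes sharing the same k."""

    names: list[str]
    n_reads: int
    read_length: int
    k: int
    pos: np.ndarray  # global window position of each usable k-mer
    canon: np.ndarray
    fwd: np.ndarray


def prepare_read_kmers(reads: ReadSet, k: int) -> ReadKmers:
    rl = reads.read_length
    if len(reads) == 0 or rl < k:
        empty = np.empty(0, dtype=np.int64)
        return ReadKmers(list(reads.names), len(reads), rl, k, empty, empty.copy(), empty.copy())
    big = encode("".join(reads.seqs))
    canon, fwd, valid = canonical_codes(big, k)
    pos_all = np.arange(canon.size)
    usable = valid & (pos_all % rl <= rl - k)
    u = pos_all[usable]
    return ReadKmers(list(reads.names), len(reads), rl, k, u, canon[u], fwd[u])


def assign_reads(
    reads: "ReadSet | ReadKmers",
    index: DiagnosticIndex,
    min_hits: int = 2,
    min_margin: int = 2,
) -> pd.DataFrame:
    """Assign every read to a source genome by diagnostic k-mer vote.

    A read is assigned to the top-scoring source when its hit count is at
    least ``min_hits`` and exceeds the runner-up by at least
    ``min_margin`` (ties are always AMBIGUOUS); reads with no diagnostic
    hit (or shorter than k) are UNASSIGNED.  The placement position is the
    reference position of the read's first diagnostic k-mer minus that
    k-mer's offset in the read, with strand inferred from forward-code
    identity.

    Returns a DataFrame with columns read, species, chromosome, position,
    strand, n_hits, margin.
    """
    prep = reads if isinstance(reads, ReadKmers) else prepare_read_kmers(reads, index.k)
    if prep.k != index.k:
        raise ValueError(f"prepared k={prep.k} does not match index k={index.k}")
    rl = prep.read_length
    n_reads = prep.n_reads
    n_lab = len(index.labels)
    out = {
        "read": prep.names,
        "species": np.full(n_reads, UNASSIGNED, dtype=object),
        "chromosome": np.full(n_reads, "", dtype=object),
        "position": np.full(n_reads, -1, dtype=np.int64),
        "strand": np.full(n_reads, ".", dtype=object),
        "n_hits": np.zeros(n_reads, dtype=np.int32),
        "margin": np.zeros(n_reads, dtype=np.int32),
    }
    if prep.canon.size == 0:
        return pd.DataFrame(out)

    k = index.k
    idx = np.searchsorted(index.codes, prep.canon)
    idx[idx >= index.codes.size] = 0
    hit_idx = np.flatnonzero(index.codes[idx] == prep.canon)

    h_pos = prep.pos[hit_idx]
    h_read = h_pos // rl
    h_entry = idx[hit_idx]
    h_lab = index.label_idx[h_entry].astype(np.int64)

    counts = np.bincount(h_read * n_lab + h_lab,
                         minlength=n_reads * n_lab).reshape(n_reads, n_lab)
    top_lab = counts.argmax(axis=1)
    top = counts[np.arange(n_reads), top_lab]
    second = (np.partition(counts, n_lab - 2, axis=1)[:, n_lab - 2]
              if n_lab > 1 else np.zeros(n_reads, dtype=counts.dtype))
    margin = top - second
    assigned = (top >= min_hits) & (margin >= min_margin) & (margin > 0)

    out["n_hits"] = top.astype(np.int32)
    out["margin"] = margin.astype(np.int32)
    ambiguous = (top > 0) & ~assigned
    out["species"][ambiguous] = AMBIGUOUS

    # first hit of the winning source per read; hits are already ordered by
    # (read, offset) because prep.pos is ascending
    pick_all = np.flatnonzero(h_lab == top_lab[h_read])
    fr = h_read[pick_all]
    first_i = np.flatnonzero(np.diff(fr, prepend=-1) != 0)
    uniq_reads = fr[first_i]
    keep = assigned[uniq_reads]
    uniq_reads = uniq_reads[keep]
    pick = pick_all[first_i[keep]]
    e = h_entry[pick]
    o = h_pos[pick] % rl
    is_fwd = prep.fwd[hit_idx[pick]] == index.ref_fwd[e]
    start = np.where(is_fwd, index.pos[e] - o, index.pos[e] - (rl - k - o))
    labels_arr = np.array(index.labels, dtype=object)
    out["species"][uniq_reads] = labels_arr[index.label_idx[e]]
    out["position"][uniq_reads] = start
    out["strand"][uniq_reads] = np.where(is_fwd, "+", "-")
    chrom_names = index.chrom_names
    out["chromosome"][uniq_reads] = [
        chrom_names[li][ci] for li, ci in zip(index.label_idx[e], index.chrom_idx[e])
    ]
    return pd.DataFrame(out)


def species_contributions(table: pd.DataFrame) -> tuple[dict[str, float], float, float]:
    """Per-species fraction over ALL reads, plus ambiguous and unassigned
    fractions (the three groups close to 1)."""
    if len(table) == 0:
        raise ValueError("empty assignment table")
    n = len(table)
    counts = table["species"].value_counts()
    ambiguous = counts.get(AMBIGUOUS, 0) / n
    unassigned = counts.get(UNASSIGNED, 0) / n
    fractions = {
        sp: c / n for sp, c in counts.items() if sp not in (AMBIGUOUS, UNASSIGNED)
    }
    return fractions, float(ambiguous), float(unassigned)


# ---------------------------------------------------------------------------
# sample profiles
# ---------------------------------------------------------------------------

@dataclass
class ContributionProfile:
    """Nuclear and mitochondrial contribution estimates for one sample."""

    sample_id: str
    nuclear_fraction: dict[str, float]
    mito_fraction: dict[tuple[str, str], float]
    ambiguous: float
    unassigned: float
    majority_nuclear: str | None
    majority_mito: str | None
    majority_mito_clade: str | None
    concordant: bool | None
    flags: list[str] = field(default_factory=list)

    @property
    def assigned_fraction(self) -> float:
        return sum(self.nuclear_fraction.values()) + sum(self.mito_fraction.values())

    @property
    def majority_nuclear_pct(self) -> float:
        if self.majority_nuclear is None:
            return float("nan")
        return 100.0 * self.nuclear_fraction[self.majority_nuclear]


def mito_assign(
    reads: "ReadSet | ReadKmers",
    mito_index: DiagnosticIndex,
    min_hits: int = 2,
    min_margin: int = 2,
) -> tuple[dict[tuple[str, str], float], str | None, str | None, pd.DataFrame]:
    """Mitochondrial fractions per (species, clade) and the majority species.

    A species' score is the maximum over its clades (reads from a
    homoplasmic donor map predominantly to one clade haplotype); the
    majority is the argmax species, undefined on ties or when no read is
    mito-assigned.
    """
    table = assign_reads(reads, mito_index, min_hits, min_margin)
    fractions, _amb, _un = species_contributions(table)
    by_pair = {}
    for label, frac in fractions.items():
        sp, clade = label.split(":", 1)
        by_pair[(sp, clade)] = frac
    major, clade = mito_majority(by_pair)
    return by_pair, major, clade, table


def mito_majority(fractions: dict[tuple[str, str], float]) -> tuple[str | None, str | None]:
    """Majority mitochondrial species from per-(species, clade) fractions.

    A species' score is the maximum over its clades; the majority species
    is the argmax, undefined (None) on exact ties or when no fraction is
    positive.
    """
    scores: dict[str, float] = {}
    best_clade: dict[str, str] = {}
    for (sp, clade), frac in fractions.items():
        if frac > scores.get(sp, -1.0):
            scores[sp] = frac
            best_clade[sp] = clade
    if not scores or max(scores.values()) == 0:
        return None, None
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None, None  # tie: majority undefined
    return ranked[0][0], best_clade[ranked[0][0]]


def compute_profile(
    sample_id: str,
    reads: "ReadSet | ReadKmers",
    nuclear_index: DiagnosticIndex,
    mito_index: DiagnosticIndex | None = None,
    min_hits: int = 2,
    min_margin: int = 2,
    return_table: bool = False,
):
    """Run nuclear and mitochondrial assignment and merge into a profile.

    Reads are routed to whichever index claims them; a read confidently
    assigned by the mitochondrial index counts as mitochondrial (organelle
    copy number gives mito diagnostics priority on ties).  Fractions are
    over all reads.  With ``return_table=True`` also returns the nuclear
    assignment table for downstream depth analysis.
    """
    prep = reads if isinstance(reads, ReadKmers) else prepare_read_kmers(reads, nuclear_index.k)
    flags: list[str] = []
    mito_frac: dict[tuple[str, str], float] = {}
    majority_mito = mito_clade = None
    mito_assigned_mask = np.zeros(prep.n_reads, dtype=bool)
    if mito_index is not None:
        mito_frac, majority_mito, mito_clade, mito_table = mito_assign(
            prep, mito_index, min_hits, min_margin)
        mito_assigned_mask = (~mito_table["species"].isin([AMBIGUOUS, UNASSIGNED])).to_numpy()
        if majority_mito is None:
            flags.append("mito majority undefined")
    table = assign_reads(prep, nuclear_index, min_hits, min_margin)
    nuclear = table.loc[~mito_assigned_mask]
    n_total = prep.n_reads
    counts = nuclear["species"].value_counts()
    nuclear_fraction = {
        sp: c / n_total for sp, c in counts.items() if sp not in (AMBIGUOUS, UNASSIGNED)
    }
    ambiguous = counts.get(AMBIGUOUS, 0) / n_total
    unassigned = counts.get(UNASSIGNED, 0) / n_total
    if nuclear_fraction:
        majority_nuclear = max(nuclear_fraction, key=nuclear_fraction.get)
    else:
        majority_nuclear = None
        flags.append("no nuclear assignments")
    concordant = None
    if majority_nuclear is not None and majority_mito is not None:
        concordant = majority_nuclear == majority_mito
    profile = ContributionProfile(
        sample_id=sample_id,
        nuclear_fraction=nuclear_fraction,
        mito_fraction=mito_frac,
        ambiguous=float(ambiguous),
        unassigned=float(unassigned),
        majority_nuclear=majority_nuclear,
        majority_mito=majority_mito,
        majority_mito_clade=mito_clade,
        concordant=concordant,
        flags=flags,
    )
    if return_table:
        return profile, table
    return profile


@dataclass
class InclusionDecision:
    include: bool
    reason: str
    parents: list[str]


def inclusion_filter(
    profile: ContributionProfile,
    min_assigned: float = 0.85,
    parent_floor: float = 0.05,
) -> InclusionDecision:
    """Two-parent high-confidence inclusion rule.

    A sample enters the depth analysis only if at least ``min_assigned``
    of its reads were confidently assigned (the >85% high-quality mapping
    rule) and exactly two species each contribute more than
    ``parent_floor`` of the assigned reads (separating true parents from
    small introgressions).
    """
    assigned = profile.assigned_fraction
    if assigned < min_assigned:
        return InclusionDecision(False, "low assignment", [])
    total = sum(profile.nuclear_fraction.values())
    if total == 0:
        return InclusionDecision(False, "no nuclear assignments", [])
    parents = sorted(
        sp for sp, f in profile.nuclear_fraction.items() if f / total >= parent_floor
    )
    if len(parents) != 2:
        return InclusionDecision(False, "not two-parent", parents)
    return InclusionDecision(True, "ok", parents)


# ---------------------------------------------------------------------------
# nuclear/mito concordance statistics
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    testable: bool = True

    NOT_TESTABLE = "NOT_TESTABLE"


def welch_t(a, b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, closed form.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch–Satterthwaite
    degrees of freedom; returns NOT_TESTABLE when either group has fewer
    than two members.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return WelchResult(float("nan"), float("nan"), float("nan"), testable=False)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def concordance_test(profiles: list[ContributionProfile]) -> WelchResult:
    """Does the majority-nuclear percentage differ between samples whose
    mitochondria follow the nuclear majority and those whose do not?"""
    conc = [p.majority_nuclear_pct for p in profiles if p.concordant is True]
    disc = [p.majority_nuclear_pct for p in profiles if p.concordant is False]
    return welch_t(conc, disc)
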