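"""Read-depth karyotyping: windowed depth, repeat masking, aneuploidy calls.

Depth of sequencing along each parental subgenome is summarised in ~10 kbp
windows; windows whose depth exceeds twice their chromosome's mean (one
log2 unit) are flagged as unresolved repeats and excluded.  Chromosome
depth is the sum of the two subgenome means (total depth); a chromosome is
called GAIN or LOSS when its total depth deviates more than 30% from the
genome-wide mean.  Genome-level instability statistics — chromosomal
variance, per-chromosome delta depth, and the regression of delta on
chromosome size — follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MITO, ReadSet, parse_read_name

GAIN, LOSS, EUPLOID = "GAIN", "LOSS", "EUPLOID"

__all__ = [
    "ChromosomeDepthSummary",
    "AneuploidyReport",
    "SizeRegression",
    "placements_from_assignments",
    "placements_from_truth",
    "read_bedgraph",
    "window_depth",
    "windows_from_track",
    "mask_repetitive_windows",
    "chromosome_summary",
    "call_aneuploidy",
    "genome_metrics",
    "analyze_sample",
    "size_regression",
    "cross_heatmap",
    "contribution_balance",
]


# ---------------------------------------------------------------------------
# placements
# ---------------------------------------------------------------------------

def placements_from_assignments(table: pd.DataFrame, read_length: int) -> pd.DataFrame:
    """Confidently assigned nuclear reads as (species, chromosome, start, end)."""
    keep = table[
        ~table["species"].isin(["AMBIGUOUS", "UNASSIGNED"]) & (table["chromosome"] != MITO)
    ]
    return pd.DataFrame({
        "species": keep["species"].to_numpy(),
        "chromosome": keep["chromosome"].to_numpy(),
        "start": keep["position"].to_numpy(),
        "end": keep["position"].to_numpy() + read_length,
    })


def placements_from_truth(reads: ReadSet) -> pd.DataFrame:
    """True read origins decoded from simulated read names (oracle path)."""
    rows = [parse_read_name(n) for n in reads.names]
    df = pd.DataFrame(rows, columns=["sample", "species", "chromosome", "start", "strand"])
    df = df[df["chromosome"] != MITO]
    return pd.DataFrame({
        "species": df["species"].to_numpy(),
        "chromosome": df["chromosome"].to_numpy(),
        "start": df["start"].to_numpy(),
        "end": df["start"].to_numpy() + reads.read_length,
    })


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _window_table(depth_per_base: np.ndarray, window_size: int):
    L = depth_per_base.size
    starts = np.arange(0, L, window_size)
    ends = np.minimum(starts + window_size, L)
    cs = np.concatenate(([0.0], np.cumsum(depth_per_base)))
    sums = cs[ends] - cs[starts]
    widths = ends - starts
    return starts, ends, sums / widths


def window_depth(
    placements: pd.DataFrame,
    chrom_lengths: dict[str, dict[str, int]],
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Mean depth per tiling window from read placements.

    ``chrom_lengths`` maps species -> chromosome -> length.  Windows tile
    each chromosome without overlap; the last window may be short.
    Returns columns species, chromosome, start, end, mean_depth, masked
    (all False; see :func:`mask_repetitive_windows`).
    """
    if window_size < 1000:
        raise ValueError("window_size below 1000 gives degenerate statistics")
    rows = []
    groups = {k: v for k, v in placements.groupby(["species", "chromosome"])} if len(placements) else {}
    for sp, chroms in chrom_lengths.items():
        for chrom, L in chroms.items():
            diff = np.zeros(L + 1)
            g = groups.get((sp, chrom))
            if g is not None:
                s = np.clip(g["start"].to_numpy(), 0, L)
                e = np.clip(g["end"].to_numpy(), 0, L)
                np.add.at(diff, s, 1.0)
                np.add.at(diff, e, -1.0)
            depth = np.cumsum(diff[:-1])
            starts, ends, means = _window_table(depth, window_size)
            for a, b, m in zip(starts, ends, means):
                rows.append((sp, chrom, int(a), int(b), float(m), False))
    return pd.DataFrame(rows, columns=["species", "chromosome", "start", "end", "mean_depth", "masked"])


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph (chrom, start, end, depth), 0-based half-open."""
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["chromosome", "start", "end", "depth"])


def windows_from_track(
    track: pd.DataFrame,
    species: str,
    chrom_lengths: dict[str, int],
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Windowed depth from an external per-interval depth track (bedGraph
    dialect) for one species."""
    if window_size < 1000:
        raise ValueError("window_size below 1000 gives degenerate statistics")
    rows = []
    for chrom, L in chrom_lengths.items():
        depth = np.zeros(L)
        sub = track[track["chromosome"] == chrom]
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            depth[max(0, int(s)) : min(L, int(e))] += d
        starts, ends, means = _window_table(depth, window_size)
        for a, b, m in zip(starts, ends, means):
            rows.append((species, chrom, int(a), int(b), float(m), False))
    return pd.DataFrame(rows, columns=["species", "chromosome", "start", "end", "mean_depth", "masked"])


def mask_repetitive_windows(
    windows: pd.DataFrame, fold: float = 2.0, iterative: bool = False
) -> pd.DataFrame:
    """Flag suspected repeat windows: depth strictly greater than ``fold``
    times the chromosome's width-weighted mean window depth.

    The chromosome mean is computed in one pass over all windows including
    the candidate (default); ``iterative=True`` re-computes the mean after
    each exclusion round until stable.  A chromosome with zero mean depth
    masks nothing.
    """
    out = windows.copy()
    masked = np.zeros(len(out), dtype=bool)
    widths = (out["end"] - out["start"]).to_numpy(dtype=float)
    depths = out["mean_depth"].to_numpy(dtype=float)
    for _sp_chrom, idx in out.groupby(["species", "chromosome"]).indices.items():
        active = np.ones(len(idx), dtype=bool)
        while True:
            w, d = widths[idx][active], depths[idx][active]
            if w.sum() == 0:
                break
            mean = float((w * d).sum() / w.sum())
            if mean == 0:
                break
            newly = active & (depths[idx] > fold * mean)
            if not newly.any():
                break
            active &= ~newly
            if not iterative:
                break
        masked[idx] = ~active
    out["masked"] = masked
    return out


# ---------------------------------------------------------------------------
# chromosome summaries and calls
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeDepthSummary:
    """Per-chromosome depth on the total (sp1 + sp2) scale.

    ``per_species`` holds the width-weighted mean of unmasked windows for
    each (species, chromosome); ``totals`` sums the species means per
    chromosome.  The genome-wide mean ``genome_mean`` is the
    chromosome-length-weighted mean of the totals, i.e. the width-weighted
    mean of total depth over the unmasked genome.
    """

    per_species: pd.DataFrame  # species, chromosome, depth
    totals: pd.DataFrame  # chromosome, total_depth, length
    genome_mean: float
    flagged: list[str] = field(default_factory=list)  # fully masked chromosomes


def chromosome_summary(
    windows: pd.DataFrame, chrom_lengths: dict[str, dict[str, int]]
) -> ChromosomeDepthSummary:
    unmasked = windows[~windows["masked"]]
    rows = []
    flagged = []
    for sp, chroms in chrom_lengths.items():
        for chrom in chroms:
            sub = unmasked[(unmasked["species"] == sp) & (unmasked["chromosome"] == chrom)]
            if len(sub) == 0:
                flagged.append(f"{sp}:{chrom}")
                continue
            w = (sub["end"] - sub["start"]).to_numpy(dtype=float)
            d = sub["mean_depth"].to_numpy(dtype=float)
            rows.append((sp, chrom, float((w * d).sum() / w.sum())))
    per_species = pd.DataFrame(rows, columns=["species", "chromosome", "depth"])
    lengths = next(iter(chrom_lengths.values()))
    totals = (per_species.groupby("chromosome")["depth"].sum()
              .rename("total_depth").reset_index())
    totals["length"] = totals["chromosome"].map(lengths)
    flagged_chroms = {f.split(":", 1)[1] for f in flagged}
    totals = totals[~totals["chromosome"].isin(flagged_chroms)].reset_index(drop=True)
    if len(totals):
        genome_mean = float(
            (totals["total_depth"] * totals["length"]).sum() / totals["length"].sum()
        )
    else:
        genome_mean = float("nan")
    return ChromosomeDepthSummary(per_species, totals, genome_mean, flagged)


def call_aneuploidy(summary: ChromosomeDepthSummary, threshold: float = 0.30) -> dict[str, str]:
    """GAIN/LOSS/EUPLOID per chromosome on total depth vs the genome mean.

    Strict inequalities: a chromosome exactly at the 30% boundary is not
    called.
    """
    dg = summary.genome_mean
    if not (dg > 0):
        raise ValueError("genome-wide mean depth must be positive")
    calls = {}
    for chrom, dc in zip(summary.totals["chromosome"], summary.totals["total_depth"]):
        if dc > (1.0 + threshold) * dg:
            calls[chrom] = GAIN
        elif dc < (1.0 - threshold) * dg:
            calls[chrom] = LOSS
        else:
            calls[chrom] = EUPLOID
    return calls


@dataclass
class AneuploidyReport:
    sample_id: str
    calls: dict[str, str]
    n_gain: int
    n_loss: int
    variance: float | None  # sample variance (ddof=1) of chromosome totals
    delta: dict[str, float]  # |D_c - D_G| per chromosome
    slope: float | None  # per-genome OLS of delta on chromosome length
    r: float | None
    genome_mean: float
    per_species_mean: dict[str, float]
    lengths: dict[str, int] = field(default_factory=dict)
    both_gain_and_loss: bool = False
    flags: list[str] = field(default_factory=list)


def genome_metrics(
    summary: ChromosomeDepthSummary, calls: dict[str, str], sample_id: str = ""
) -> AneuploidyReport:
    totals = summary.totals
    dg = summary.genome_mean
    dc = totals["total_depth"].to_numpy(dtype=float)
    lengths = totals["length"].to_numpy(dtype=float)
    delta = {c: abs(d - dg) for c, d in zip(totals["chromosome"], dc)}
    n_gain = sum(1 for v in calls.values() if v == GAIN)
    n_loss = sum(1 for v in calls.values() if v == LOSS)
    flags = list(summary.flagged)
    variance = float(np.var(dc, ddof=1)) if dc.size >= 2 else None
    if variance is None:
        flags.append("variance undefined (<2 chromosomes)")
    slope = r = None
    dvals = np.abs(dc - dg)
    if dc.size >= 3 and np.ptp(lengths) > 0:
        if np.ptp(dvals) == 0:
            slope, r = 0.0, 0.0
            flags.append("degenerate regression (all deltas equal)")
        else:
            fit = stats.linregress(lengths, dvals)
            slope, r = float(fit.slope), float(fit.rvalue)
    else:
        flags.append("regression undefined")
    per_sp = {}
    if "species" in summary.per_species.columns:
        per_sp = {
            sp: float(np.mean(g["depth"]))
            for sp, g in summary.per_species.groupby("species")
        }
    return AneuploidyReport(
        sample_id=sample_id, calls=calls, n_gain=n_gain, n_loss=n_loss,
        variance=variance, delta=delta, slope=slope, r=r, genome_mean=dg,
        per_species_mean=per_sp,
        lengths=dict(zip(totals["chromosome"], totals["length"])),
        both_gain_and_loss=(n_gain > 0 and n_loss > 0),
        flags=flags,
    )


def analyze_sample(
    placements: pd.DataFrame,
    chrom_lengths: dict[str, dict[str, int]],
    sample_id: str = "",
    window_size: int = 10_000,
    mask_fold: float = 2.0,
    threshold: float = 0.30,
    mask: bool = True,
) -> AneuploidyReport:
    """Windows -> masking -> summary -> calls -> metrics, in one step."""
    windows = window_depth(placements, chrom_lengths, window_size)
    if mask:
        windows = mask_repetitive_windows(windows, mask_fold)
    summary = chromosome_summary(windows, chrom_lengths)
    calls = call_aneuploidy(summary, threshold)
    return genome_metrics(summary, calls, sample_id)


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------

@dataclass
class SizeRegression:
    pooled_slope: float
    pooled_intercept: float
    pooled_r: float
    pooled_p: float
    per_genome: pd.DataFrame  # sample, slope, r
    fraction_negative: float


def size_regression(reports: list[AneuploidyReport]) -> SizeRegression:
    """OLS of delta depth on chromosome size, pooled across genomes and
    per genome; reports the fraction of negative per-genome slopes."""
    xs, ys, rows = [], [], []
    for rep in reports:
        rows.append((rep.sample_id, rep.slope, rep.r))
        for chrom, d in rep.delta.items():
            xs.append(rep.lengths[chrom])
            ys.append(d)
    per_genome = pd.DataFrame(rows, columns=["sample", "slope", "r"])
    if np.ptp(xs) == 0:
        raise ValueError("zero variance in chromosome lengths: fit undefined")
    fit = stats.linregress(xs, ys)
    slopes = per_genome["slope"].dropna()
    frac_neg = float((slopes < 0).mean()) if len(slopes) else float("nan")
    return SizeRegression(float(fit.slope), float(fit.intercept), float(fit.rvalue),
                          float(fit.pvalue), per_genome, frac_neg)


def cross_heatmap(reports_by_cross: dict[str, list[AneuploidyReport]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cross mean delta depth per chromosome, plus the two-sided
    normalised matrix used for cross comparisons.

    Normalisation per chromosome column: the minimum cross mean maps to 0,
    the overall (cross-averaged) mean to 0.5, and the maximum to 1, with
    linear interpolation on each side; a column with no spread maps to 0.5.
    """
    if len(reports_by_cross) < 2:
        raise ValueError("need at least two crosses")
    rows = {}
    for cross, reports in reports_by_cross.items():
        if not reports:
            continue
        acc: dict[str, list[float]] = {}
        for rep in reports:
            for chrom, d in rep.delta.items():
                acc.setdefault(chrom, []).append(d)
        rows[cross] = {c: float(np.mean(v)) for c, v in acc.items()}
    means = pd.DataFrame(rows).T.sort_index()
    norm = means.copy()
    for col in means.columns:
        v = means[col].to_numpy(dtype=float)
        lo, hi, mid = v.min(), v.max(), v.mean()
        scaled = np.full_like(v, 0.5)
        below = v <= mid
        if mid > lo:
            scaled[below] = 0.5 * (v[below] - lo) / (mid - lo)
        if hi > mid:
            scaled[~below] = 0.5 + 0.5 * (v[~below] - mid) / (hi - mid)
        norm[col] = scaled
    return means, norm


def contribution_balance(profile, report: AneuploidyReport) -> dict:
    """Join ancestry and karyotype outputs for balance-vs-instability
    analysis: balance = sp1_fraction - sp2_fraction over the two parents."""
    fracs = sorted(profile.nuclear_fraction.items(), key=lambda kv: kv[0])
    if len(fracs) < 2:
        raise ValueError("two-parent sample required")
    (sp1, f1), (sp2, f2) = fracs[0], fracs[1]
    return {
        "sample": profile.sample_id,
        "balance": f1 - f2,
        "n_gain": report.n_gain,
        "n_loss": report.n_loss,
        "variance": report.variance,
    }
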