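"""Parameter-recovery studies on synthetic cohorts.

Every analysis stage is validated by simulating hybrid cohorts whose true
parameters are known and measuring how well the stage recovers them:
aneuploidy sensitivity/specificity, repeat-masking efficacy, contribution
and mitochondrial-donor recovery, the chromosome-size/instability
direction, shared-k-mer monotonicity in parental divergence, and LOH
breakpoint accuracy.  The study conditions (divergence 0.10, 20x
coverage, 100 bp reads, 0.1% error, a scaled-down eight-chromosome
karyotype spanning a three-fold size range) are fixed here so tests and
reports measure the same experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ancestry, karyotype, kmer_net, loh as loh_mod, simulate

# scaled-down karyotype: 8 chromosomes spanning the ~6-8x relative size
# range of real yeast chromosomes (230 kb - 1.5 Mb), 179 kb total
CHROM_LENGTHS_8 = [48_000, 36_000, 28_000, 22_000, 17_000, 13_000, 9_000, 6_000]
# compact 6-chromosome variant for read-assignment-heavy studies, 95 kb
CHROM_LENGTHS_6 = [24_000, 20_000, 17_000, 14_000, 11_000, 9_000]

DIVERGENCE = 0.10
COVERAGE = 20.0
READ_LENGTH = 100
ERROR_RATE = 0.001


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _full_karyotype(reads, parents, k=17):
    """Assignment-surrogate path: reads -> diagnostic placement -> calls."""
    idx = ancestry.build_diagnostic_index(list(parents), k)
    table = ancestry.assign_reads(reads, idx)
    placements = karyotype.placements_from_assignments(table, reads.read_length)
    lengths = {p.species_id: p.chrom_lengths for p in parents}
    return karyotype.analyze_sample(placements, lengths, "s")


def aneuploidy_recovery(seed: int, n_samples: int = 40) -> dict:
    """Half-euploid, half single-aneuploidy cohort at 20x, divergence 0.10.

    Returns sensitivity over aneuploid genomes, specificity (zero-call
    rate) over euploid genomes, and the off-target-free rate.
    """
    p1, p2 = simulate.generate_parent_pair(CHROM_LENGTHS_6, DIVERGENCE, seed=seed)
    idx = ancestry.build_diagnostic_index([p1, p2], 17)
    lengths = {p.species_id: p.chrom_lengths for p in (p1, p2)}
    chroms = p1.chrom_names
    hits = misses = clean_euploid = n_euploid = off_target_free = 0
    for i, s in enumerate(_seeds(seed + 1, n_samples)):
        rng = np.random.default_rng(s)
        aneu = []
        if i % 2 == 1:
            chrom = chroms[int(rng.integers(len(chroms)))]
            sp = (p1, p2)[int(rng.integers(2))].species_id
            delta = 1 if rng.random() < 0.5 else -1
            aneu = [(sp, chrom, delta)]
        truth = simulate.generate_hybrid((p1, p2), 0.5, aneu, sample_id=f"s{i}", seed=s)
        reads = simulate.simulate_reads(truth, (p1, p2), COVERAGE, READ_LENGTH, ERROR_RATE, seed=s + 1)
        table = ancestry.assign_reads(reads, idx)
        placements = karyotype.placements_from_assignments(table, READ_LENGTH)
        rep = karyotype.analyze_sample(placements, lengths, truth.sample_id)
        if aneu:
            _sp, chrom, delta = aneu[0]
            want = karyotype.GAIN if delta > 0 else karyotype.LOSS
            if rep.calls.get(chrom) == want:
                hits += 1
            else:
                misses += 1
            others = {c: v for c, v in rep.calls.items() if c != chrom}
            if all(v == karyotype.EUPLOID for v in others.values()):
                off_target_free += 1
        else:
            n_euploid += 1
            if rep.n_gain == 0 and rep.n_loss == 0:
                clean_euploid += 1
    return {
        "sensitivity": hits / max(hits + misses, 1),
        "specificity": clean_euploid / max(n_euploid, 1),
        "off_target_free": off_target_free / max(hits + misses, 1),
        "n": n_samples,
    }


def masking_efficacy(seed: int, n_seeds: int = 10) -> dict:
    """Planted 50-copy repeat: with masking the chromosome stays EUPLOID,
    with masking disabled it flips to GAIN; evaluated per seed as a pair."""
    both_hold = 0
    for s in _seeds(seed, n_seeds):
        p1, p2 = simulate.generate_parent_pair(CHROM_LENGTHS_8, DIVERGENCE, seed=s)
        lengths = {p.species_id: p.chrom_lengths for p in (p1, p2)}
        # on a 30 kb chromosome (3 windows) so the inflated window can exceed
        # twice the chromosome mean
        repeat = (p1.species_id, "chr01", 2000, 4000, 50)
        truth = simulate.generate_hybrid((p1, p2), 0.5, repeat_inserts=[repeat],
                                         sample_id="rep", seed=s)
        reads = simulate.simulate_reads(truth, (p1, p2), COVERAGE, READ_LENGTH, ERROR_RATE, seed=s + 1)
        placements = karyotype.placements_from_truth(reads)
        masked = karyotype.analyze_sample(placements, lengths, "rep", mask=True)
        unmasked = karyotype.analyze_sample(placements, lengths, "rep", mask=False)
        if (masked.calls["chr01"] == karyotype.EUPLOID
                and unmasked.calls["chr01"] == karyotype.GAIN):
            both_hold += 1
    return {"pair_holds_fraction": both_hold / n_seeds, "n": n_seeds}


def contribution_recovery(seed: int, levels=(0.5, 0.6, 0.7, 0.8, 0.9),
                          per_level: int = 4) -> dict:
    """Nuclear contribution estimates vs truth across skew levels."""
    p1, p2 = simulate.generate_parent_pair(CHROM_LENGTHS_6, DIVERGENCE, seed=seed)
    nuc = ancestry.build_diagnostic_index([p1, p2], 17)
    mito = ancestry.build_mito_index([p1, p2], 17)
    errors = []
    seeds = iter(_seeds(seed + 1, len(levels) * per_level))
    for level in levels:
        for _ in range(per_level):
            s = next(seeds)
            truth = simulate.generate_hybrid((p1, p2), level, sample_id="c", seed=s)
            reads = simulate.simulate_reads(truth, (p1, p2), COVERAGE, READ_LENGTH, ERROR_RATE, seed=s + 1)
            prof = ancestry.compute_profile("c", reads, nuc, mito)
            nuclear_total = sum(prof.nuclear_fraction.values())
            est = prof.nuclear_fraction.get(p1.species_id, 0.0) / nuclear_total
            errors.append(abs(est - level))
    errors = np.array(errors)
    return {
        "within_5pts_fraction": float((errors <= 0.05).mean()),
        "max_error_pts": float(100 * errors.max()),
        "n": errors.size,
    }


def mito_recovery(seed: int, n_samples: int = 20) -> dict:
    """Homoplasmic mitochondrial donors, including a two-clade species
    scored by its best clade; accuracy of the majority species call."""
    p1, p2 = simulate.generate_parent_pair(
        [20_000, 16_000], DIVERGENCE, seed=seed, n_mito_clades=(1, 2))
    nuc = ancestry.build_diagnostic_index([p1, p2], 17)
    mito = ancestry.build_mito_index([p1, p2], 17)
    correct = 0
    for i, s in enumerate(_seeds(seed + 1, n_samples)):
        donor = (p1, p2)[i % 2]
        clade = donor.mito[i % len(donor.mito)][0]
        truth = simulate.generate_hybrid((p1, p2), 0.5, mito_donor=(donor.species_id, clade),
                                         sample_id=f"m{i}", seed=s)
        reads = simulate.simulate_reads(truth, (p1, p2), 10.0, READ_LENGTH, ERROR_RATE, seed=s + 1)
        prof = ancestry.compute_profile(f"m{i}", reads, nuc, mito)
        if prof.majority_mito == donor.species_id:
            correct += 1
    return {"majority_accuracy": correct / n_samples, "n": n_samples}


def size_direction(seed: int, n_genomes: int = 50) -> dict:
    """Aneuploidy probability proportional to 1/length: the delta-depth vs
    chromosome-size regression should be negative, pooled and per genome."""
    p1, p2 = simulate.generate_parent_pair(CHROM_LENGTHS_8, DIVERGENCE, seed=seed)
    lengths = {p.species_id: p.chrom_lengths for p in (p1, p2)}
    chroms = p1.chrom_names
    inv = np.array([1.0 / p1.chrom_lengths[c] for c in chroms])
    # ~1.5 expected aneuploidies per genome, distributed as 1/L: an unstable
    # cohort in which most genomes carry at least one depth deviation
    probs = np.minimum(1.5 * inv / inv.sum(), 0.9)
    reports = []
    for i, s in enumerate(_seeds(seed + 1, n_genomes)):
        rng = np.random.default_rng(s)
        aneu = []
        for chrom, p in zip(chroms, probs):
            if rng.random() < p:
                sp = (p1, p2)[int(rng.integers(2))].species_id
                aneu.append((sp, chrom, 1 if rng.random() < 0.7 else -1))
        truth = simulate.generate_hybrid((p1, p2), 0.5, aneu, sample_id=f"g{i}", seed=s)
        reads = simulate.simulate_reads(truth, (p1, p2), COVERAGE, READ_LENGTH, ERROR_RATE, seed=s + 1)
        placements = karyotype.placements_from_truth(reads)
        reports.append(karyotype.analyze_sample(placements, lengths, truth.sample_id))
    reg = karyotype.size_regression(reports)
    return {
        "pooled_slope": reg.pooled_slope,
        "pooled_r": reg.pooled_r,
        "fraction_negative": reg.fraction_negative,
        "n": n_genomes,
    }


def _mosaic_hybrid(parents, rng, sample_id, seed):
    """Segregant-like hybrid: every chromosome fully homozygous for a
    randomly retained parent (genome-wide LOH mosaic).  Two mosaics share
    all k-mers where their retained parents coincide but only conserved
    k-mers elsewhere, so expected sharing falls with parental divergence;
    balanced heterozygous hybrids would instead share the whole (growing)
    union and reverse the trend."""
    p1, p2 = parents
    tracts = []
    for chrom, L in p1.chrom_lengths.items():
        retained = (p1, p2)[int(rng.integers(2))].species_id
        tracts.append((chrom, 0, L, retained))
    return simulate.generate_hybrid(parents, 0.5, loh_tracts=tracts,
                                    sample_id=sample_id, seed=seed)


def kmer_monotonicity(seed: int, divergences=(0.05, 0.10, 0.20), n_seeds: int = 10) -> dict:
    """Shared k-mers between two mosaic hybrids of a cross should fall as
    the parents diverge; measured as a rank correlation over matched seeds."""
    rows = []
    for s in _seeds(seed, n_seeds):
        for div in divergences:
            p1, p2 = simulate.generate_parent_pair([12_000, 11_000, 10_000, 9_000],
                                                   div, seed=s)
            rng = np.random.default_rng(s + 5)
            profs = []
            for j in range(2):
                truth = _mosaic_hybrid((p1, p2), rng, f"d{div}_{j}", s + j)
                reads = simulate.simulate_reads(truth, (p1, p2), 10.0, READ_LENGTH, ERROR_RATE,
                                                seed=s + 10 + j)
                profs.append(kmer_net.kmer_profile(reads, 17, 5, truth.sample_id))
            rows.append({"seed": s, "divergence": div,
                         "shared": kmer_net.shared_kmers(*profs)})
    df = pd.DataFrame(rows)
    rho, p = stats.spearmanr(df["divergence"], df["shared"])
    monotone = 0
    for _s, g in df.groupby("seed"):
        vals = g.sort_values("divergence")["shared"].to_numpy()
        monotone += bool(np.all(np.diff(vals) <= 0))
    return {
        "spearman_rho": float(rho),
        "p": float(p),
        "monotone_seed_fraction": monotone / n_seeds,
        "n": len(df),
    }


def kmer_threshold_ordering(seed: int, divergences=(0.05, 0.10, 0.20),
                            per_cross: int = 4) -> dict:
    """Per-cross mean shared k-mers with the default (5) and the
    read-depth-sensitivity (2) count thresholds; both should rank the
    crosses identically, and the per-cross means should correlate with
    parental distance with the built-in (negative) sign."""
    orderings = {}
    stats_out = {}
    for min_count in (5, 2):
        profiles = []
        cross_of = {}
        pdist = {}
        for div in divergences:
            s = int(np.random.SeedSequence([seed, int(div * 1000)]).generate_state(1)[0] % (2**31))
            # eight chromosomes: averages the random mosaic composition so
            # cross-level means are dominated by divergence, not sampling
            p1, p2 = simulate.generate_parent_pair(
                [9_000, 8_500, 8_000, 7_500, 7_000, 6_500, 6_000, 5_500], div, seed=s)
            cross = f"d{div}"
            pdist[cross] = simulate.realized_divergence(p1, p2)
            rng = np.random.default_rng(s + 5)
            for j in range(per_cross):
                truth = _mosaic_hybrid((p1, p2), rng, f"{cross}_{j}", s + j)
                reads = simulate.simulate_reads(truth, (p1, p2), 10.0, READ_LENGTH,
                                                ERROR_RATE, seed=s + 10 + j)
                profiles.append(kmer_net.kmer_profile(reads, 17, min_count, truth.sample_id))
                cross_of[truth.sample_id] = cross
        matrix = kmer_net.distance_matrix(profiles)
        cs = kmer_net.cross_statistics(matrix, cross_of, pdist)
        per = cs["per_cross"].sort_values("mean_shared", ascending=False)
        orderings[min_count] = tuple(per["cross"])
        stats_out[min_count] = {"r": cs["r"], "p": cs["p"]}
    return {
        "same_ordering": orderings[5] == orderings[2],
        "ordering": list(orderings[5]),
        "r_min_count_5": stats_out[5]["r"],
        "r_min_count_2": stats_out[2]["r"],
        "n": len(divergences) * per_cross * 2,
    }


def loh_recovery(seed: int, n_false_seeds: int = 20) -> dict:
    """Planted-tract breakpoint accuracy, false-segment control on fully
    heterozygous genomes, and the 3-of-5 shared-locus bin frequency."""
    p1, p2 = simulate.generate_parent_pair([30_000, 25_000], DIVERGENCE, seed=seed)
    idx = ancestry.build_diagnostic_index([p1, p2], 17)
    markers = loh_mod.derive_markers(p1, p2)
    spacing = (sum(p1.chrom_lengths.values()) / len(markers))

    # shared locus on chr01 in 3 of 5 samples; per-sample breakpoint error
    locus = ("chr01", 8_000, 20_000)
    segments_by_sample = {}
    contributions = {}
    bp_errors = []
    for i, s in enumerate(_seeds(seed + 1, 5)):
        tracts = []
        if i < 3:
            tracts.append((locus[0], locus[1], locus[2], p1.species_id))
        truth = simulate.generate_hybrid((p1, p2), 0.5, loh_tracts=tracts,
                                         sample_id=f"l{i}", seed=s)
        reads = simulate.simulate_reads(truth, (p1, p2), COVERAGE, READ_LENGTH, ERROR_RATE, seed=s + 1)
        table = ancestry.assign_reads(reads, idx)
        counts = loh_mod.count_alleles(markers, reads, table)
        geno = loh_mod.genotype_markers(counts)
        segs = loh_mod.call_loh_segments(geno)
        segments_by_sample[truth.sample_id] = segs
        contributions[truth.sample_id] = truth.contribution
        if tracts:
            on_chrom = [g for g in segs if g.chromosome == locus[0]]
            if on_chrom:
                best = max(on_chrom, key=lambda g: g.end - g.start)
                # breakpoints cannot resolve below marker resolution: compare
                # against the first/last marker inside the planted tract
                mpos = markers.loc[markers["chromosome"] == locus[0], "position"].to_numpy()
                inside = mpos[(mpos >= locus[1]) & (mpos < locus[2])]
                bp_errors += [abs(best.start - int(inside[0])),
                              abs(best.end - (int(inside[-1]) + 1))]
            else:
                bp_errors += [float("inf"), float("inf")]
    freq = loh_mod.region_frequency(segments_by_sample, contributions,
                                    p1.chrom_lengths, bin_size=10_000)
    in_locus = freq[(freq["chromosome"] == locus[0])
                    & (freq["start"] >= locus[1]) & (freq["end"] <= locus[2])]
    locus_freq = float(in_locus["freq_p1"].mean()) if len(in_locus) else float("nan")

    false_segments = 0
    for s in _seeds(seed + 2, n_false_seeds):
        truth = simulate.generate_hybrid((p1, p2), 0.5, sample_id="h", seed=s)
        reads = simulate.simulate_reads(truth, (p1, p2), COVERAGE, READ_LENGTH, ERROR_RATE, seed=s + 1)
        table = ancestry.assign_reads(reads, idx)
        counts = loh_mod.count_alleles(markers, reads, table)
        geno = loh_mod.genotype_markers(counts)
        false_segments += len(loh_mod.call_loh_segments(geno))
    return {
        "mean_breakpoint_error_bp": float(np.mean(bp_errors)),
        "marker_spacing_bp": float(spacing),
        "false_segments": false_segments,
        "shared_locus_frequency": locus_freq,
        "n": 5 + n_false_seeds,
    }


def pipeline_determinism(seed: int, workdir) -> dict:
    """Two runs of the full pipeline with one seed must write byte-identical
    summaries."""
    from pathlib import Path

    from . import report

    cfg = {
        "seed": seed,
        "stages": ["ancestry", "karyotype", "kmer", "loh"],
        "crosses": [
            {"name": "AxB", "divergence": 0.10, "n_samples": 2,
             "chrom_lengths": [24_000, 18_000], "coverage": 10.0,
             "aneuploidy_prob": 0.05, "loh_tracts_per_sample": 1},
            {"name": "CxD", "divergence": 0.20, "n_samples": 2,
             "chrom_lengths": [24_000, 18_000], "coverage": 10.0},
        ],
    }
    digests = []
    for run in ("run1", "run2"):
        out = Path(workdir) / run
        report.run_pipeline({**cfg, "out_dir": str(out)})
        digests.append(tuple(
            simulate.file_digest(out / name)
            for name in ("summary.tsv", "crosses.tsv", "loh_segments.bed", "distances.phylip")
        ))
    return {"identical": digests[0] == digests[1], "n": 4}
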