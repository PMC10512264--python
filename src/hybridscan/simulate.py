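"""Synthetic hybrid cohorts: parent genomes, hybrid templates, and reads.

The generator emulates the data structure of interspecific *Saccharomyces*
hybrids sequenced at moderate short-read coverage: two parental species at
10--22% genome-wide nucleotide divergence, hybrid genomes carrying one
subgenome copy from each parent (with whole-chromosome gains/losses),
skewed genomic contributions from ~50:50 to ~95:5, homoplasmic
mitochondrial inheritance (one species may carry several divergent
mitochondrial clades), loss-of-heterozygosity tracts in which one parent's
sequence replaces the homeologous region of the other, and high-copy
repeats that inflate local read depth.

The divergence model is substitution-only, which keeps the two parent
coordinate systems collinear; read sampling is single-end with uniform
start positions, Poisson read counts per template and uniform substitution
errors.  Every read identifier encodes its true origin so downstream
stages can be scored by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encoding import _BASES, decode, encode, revcomp

MITO = "mito"

__all__ = [
    "ParentGenome",
    "HybridTruth",
    "ReadSet",
    "CrossSpec",
    "Cohort",
    "generate_parent_pair",
    "generate_hybrid",
    "hybrid_templates",
    "simulate_reads",
    "generate_cohort",
    "write_fasta",
    "write_fastq",
    "parse_read_name",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ParentGenome:
    """A parental species genome: nuclear chromosomes plus mitochondrial
    haplotype(s), one per clade."""

    species_id: str
    chromosomes: list[tuple[str, str]]  # (name, sequence)
    mito: list[tuple[str, str]]  # (clade_label, sequence)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT bases")
        min_nuc = min(len(s) for _, s in self.chromosomes)
        for clade, seq in self.mito:
            if set(seq) - set("ACGT"):
                raise ValueError(f"mito {clade} contains non-ACGT bases")
            if len(seq) >= min_nuc:
                raise ValueError("mitochondrial sequence must be shorter than any nuclear chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    def sequence(self, chrom: str) -> str:
        for n, s in self.chromosomes:
            if n == chrom:
                return s
        raise KeyError(chrom)

    def mito_sequence(self, clade: str) -> str:
        for c, s in self.mito:
            if c == clade:
                return s
        raise KeyError(clade)


@dataclass
class HybridTruth:
    """Ground truth for one simulated hybrid genome."""

    sample_id: str
    copy_number: dict[tuple[str, str], int]  # (species, chromosome) -> copies
    contribution: dict[str, float]  # species -> expected read fraction
    mito_donor: tuple[str, str]  # (species, clade)
    loh_tracts: list[tuple[str, int, int, str]]  # (chrom, start, end, retained species)
    repeat_inserts: list[tuple[str, str, int, int, int]]  # (sp, chrom, start, end, extra copies)
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.contribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"contributions must sum to 1, got {total}")
        if any(c < 0 for c in self.copy_number.values()):
            raise ValueError("copy numbers must be non-negative")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _sp in self.loh_tracts:
            if end <= start:
                raise ValueError("LOH tract must have end > start")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping LOH tracts on {chrom}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["copy_number"] = [[sp, c, n] for (sp, c), n in sorted(self.copy_number.items())]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HybridTruth":
        d = json.loads(text)
        d["copy_number"] = {(sp, c): n for sp, c, n in d["copy_number"]}
        d["mito_donor"] = tuple(d["mito_donor"])
        d["loh_tracts"] = [tuple(t) for t in d["loh_tracts"]]
        d["repeat_inserts"] = [tuple(t) for t in d["repeat_inserts"]]
        return cls(**d)


@dataclass
class ReadSet:
    """Single-end reads; names encode sample, true origin species,
    chromosome, 0-based start, and strand."""

    names: list[str]
    seqs: list[str]
    read_length: int
    error_rate: float

    def __len__(self) -> int:
        return len(self.names)


def parse_read_name(name: str) -> tuple[str, str, str, int, str]:
    """Decode ``sample|species|chrom|start|strand`` read identifiers."""
    sample, sp, chrom, start, strand = name.split("|")
    return sample, sp, chrom, int(start), strand


# ---------------------------------------------------------------------------
# parent genomes
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, divergence: float) -> np.ndarray:
    """Substitute each site with probability ``divergence``, always to a
    different base."""
    out = codes.copy()
    hit = rng.random(codes.size) < divergence
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def generate_parent_pair(
    chrom_lengths: list[int],
    divergence: float,
    mito_length: int = 5000,
    n_mito_clades: tuple[int, int] = (1, 1),
    seed: int = 0,
    mito_divergence: float | None = None,
    clade_divergence: float = 0.10,
    species_ids: tuple[str, str] = ("sp1", "sp2"),
) -> tuple[ParentGenome, ParentGenome]:
    """Simulate two collinear parent genomes at a given nucleotide divergence.

    ``divergence`` is the per-site substitution probability of parent 2
    relative to parent 1 (substitutions always change the base).  The model
    breaks down near saturation, so divergence is capped at 0.25.  Each
    species gets ``n_mito_clades`` mitochondrial haplotypes; within-species
    clades differ by ``clade_divergence``, between-species mitochondria by
    ``mito_divergence`` (defaults to the nuclear divergence).
    """
    if not (0.0 <= divergence <= 0.25):
        raise ValueError(f"divergence must be in [0, 0.25], got {divergence}")
    if any(l <= 0 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be positive")
    if mito_divergence is None:
        mito_divergence = divergence
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1:02d}" for i in range(len(chrom_lengths))]
    chroms1, chroms2 = [], []
    for name, length in zip(names, chrom_lengths):
        c1 = _random_seq(rng, length)
        c2 = _mutate(rng, c1, divergence)
        chroms1.append((name, decode(c1)))
        chroms2.append((name, decode(c2)))
    mito_base = _random_seq(rng, mito_length)
    mito_other = _mutate(rng, mito_base, mito_divergence)

    def clades(base: np.ndarray, n: int) -> list[tuple[str, str]]:
        out = [("cladeA", decode(base))]
        for i in range(1, n):
            out.append((f"clade{chr(ord('A') + i)}", decode(_mutate(rng, base, clade_divergence))))
        return out

    p1 = ParentGenome(species_ids[0], chroms1, clades(mito_base, n_mito_clades[0]))
    p2 = ParentGenome(species_ids[1], chroms2, clades(mito_other, n_mito_clades[1]))
    return p1, p2


# ---------------------------------------------------------------------------
# hybrids
# ---------------------------------------------------------------------------

def generate_hybrid(
    parents: tuple[ParentGenome, ParentGenome],
    contribution: float,
    aneuploidies: list[tuple[str, str, int]] = (),
    loh_tracts: list[tuple[str, int, int, str]] = (),
    repeat_inserts: list[tuple[str, str, int, int, int]] = (),
    mito_donor: tuple[str, str] | None = None,
    sample_id: str = "hyb",
    seed: int = 0,
) -> HybridTruth:
    """Build the truth table for one hybrid.

    ``contribution`` is the expected read fraction of the first parent.
    ``aneuploidies`` are (species, chromosome, delta_copies) on top of the
    balanced 1+1 baseline.  ``loh_tracts`` are (chrom, start, end,
    retained_species): in the emitted hybrid template, the *other*
    parent's homeologous sequence over that interval is replaced by the
    retained parent's.  The mitochondrial donor defaults to the majority
    parent's first clade.
    """
    p1, p2 = parents
    if not (0.0 < contribution < 1.0):
        raise ValueError("contribution must be in (0, 1)")
    copy_number = {(p.species_id, name): 1 for p in (p1, p2) for name in p.chrom_names}
    for sp, chrom, delta in aneuploidies:
        key = (sp, chrom)
        if key not in copy_number:
            raise ValueError(f"aneuploidy names absent chromosome {key}")
        copy_number[key] += delta
        if copy_number[key] < 0:
            raise ValueError(f"copy number below zero for {key}")
    lengths = p1.chrom_lengths
    for chrom, start, end, retained in loh_tracts:
        if chrom not in lengths:
            raise ValueError(f"LOH tract names absent chromosome {chrom}")
        if not (0 <= start < end <= lengths[chrom]):
            raise ValueError(f"LOH tract out of bounds on {chrom}")
        if retained not in (p1.species_id, p2.species_id):
            raise ValueError(f"unknown retained parent {retained}")
    if mito_donor is None:
        major = p1 if contribution >= 0.5 else p2
        mito_donor = (major.species_id, major.mito[0][0])
    return HybridTruth(
        sample_id=sample_id,
        copy_number=copy_number,
        contribution={p1.species_id: contribution, p2.species_id: 1.0 - contribution},
        mito_donor=mito_donor,
        loh_tracts=list(loh_tracts),
        repeat_inserts=[tuple(r) for r in repeat_inserts],
        seed=seed,
    )


def hybrid_templates(
    truth: HybridTruth, parents: tuple[ParentGenome, ParentGenome]
) -> dict[str, dict[str, str]]:
    """Per-subgenome template sequences with LOH tracts applied.

    Within an LOH tract the lost parent's chromosome carries the retained
    parent's sequence (gene conversion to homozygosity); the retained
    parent's template is unchanged.
    """
    p1, p2 = parents
    by_sp = {p.species_id: p for p in (p1, p2)}
    templates = {p.species_id: {n: s for n, s in p.chromosomes} for p in (p1, p2)}
    for chrom, start, end, retained in truth.loh_tracts:
        donor_seq = by_sp[retained].sequence(chrom)
        lost = p2.species_id if retained == p1.species_id else p1.species_id
        old = templates[lost][chrom]
        templates[lost][chrom] = old[:start] + donor_seq[start:end] + old[end:]
    return templates


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _sample_template(
    rng: np.random.Generator,
    sample_id: str,
    species: str,
    chrom: str,
    seq: str,
    expected_reads: float,
    read_length: int,
    error_rate: float,
    origin_offset: int = 0,
    names: list[str] | None = None,
    seqs: list[str] | None = None,
) -> None:
    n = int(rng.poisson(expected_reads))
    if n == 0:
        return
    codes = encode(seq)
    starts = rng.integers(0, len(seq) - read_length + 1, size=n)
    strands = rng.random(n) < 0.5
    reads = np.empty((n, read_length), dtype=np.uint8)
    for i, s in enumerate(starts):
        reads[i] = codes[s : s + read_length]
    if error_rate > 0:
        err = rng.random((n, read_length)) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        reads[err] = (reads[err] + shift) % 4
    for i in range(n):
        bases = _BASES[reads[i]].tobytes().decode("ascii")
        if strands[i]:
            bases = revcomp(bases)
        strand = "-" if strands[i] else "+"
        names.append(f"{sample_id}|{species}|{chrom}|{int(starts[i]) + origin_offset}|{strand}")
        seqs.append(bases)


def simulate_reads(
    truth: HybridTruth,
    parents: tuple[ParentGenome, ParentGenome],
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.001,
    seed: int = 0,
    mito_ratio: float = 10.0,
) -> ReadSet:
    """Draw single-end reads from the hybrid template.

    ``coverage`` is the expected genome-wide depth of the balanced hybrid:
    a chromosome copy from parent ``sp`` is sequenced to an expected depth
    of ``coverage * 2 * contribution[sp]``, so a balanced 1+1 hybrid has
    total depth ``2 * coverage`` per homeologous chromosome pair and
    aneuploid chromosomes scale with copy number.  Mitochondrial reads come
    only from the donor haplotype at ``mito_ratio`` times the nuclear
    per-copy depth.  Repeat inserts add ``copies`` extra sampled copies of
    their interval, inflating local depth.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    p1, p2 = parents
    by_sp = {p.species_id: p for p in (p1, p2)}
    templates = hybrid_templates(truth, parents)
    min_len = min(len(s) for t in templates.values() for s in t.values())
    if read_length > min_len:
        raise ValueError("read_length exceeds shortest chromosome")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    seqs: list[str] = []
    for sp in (p1.species_id, p2.species_id):
        depth = coverage * 2.0 * truth.contribution[sp]
        for chrom, seq in templates[sp].items():
            copies = truth.copy_number[(sp, chrom)]
            if copies == 0 or depth == 0:
                continue
            expected = depth * copies * len(seq) / read_length
            _sample_template(rng, truth.sample_id, sp, chrom, seq, expected,
                             read_length, error_rate, 0, names, seqs)
    for sp, chrom, start, end, copies in truth.repeat_inserts:
        depth = coverage * 2.0 * truth.contribution[sp]
        sub = templates[sp][chrom][start:end]
        if len(sub) < read_length:
            raise ValueError("repeat insert shorter than read length")
        expected = depth * copies * len(sub) / read_length
        _sample_template(rng, truth.sample_id, sp, chrom, sub, expected,
                         read_length, error_rate, start, names, seqs)
    donor_sp, donor_clade = truth.mito_donor
    mito_seq = by_sp[donor_sp].mito_sequence(donor_clade)
    if len(mito_seq) >= read_length:
        expected = coverage * mito_ratio * len(mito_seq) / read_length
        _sample_template(rng, truth.sample_id, donor_sp, MITO, mito_seq, expected,
                         read_length, error_rate, 0, names, seqs)
    return ReadSet(names=names, seqs=seqs, read_length=read_length, error_rate=error_rate)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CrossSpec:
    """Configuration of one hybrid cross within a cohort."""

    name: str
    divergence: float
    n_samples: int
    chrom_lengths: list[int]
    contribution: float | tuple[float, float] = 0.5
    aneuploidy_prob: float = 0.0  # per-chromosome probability of a gain/loss
    gain_fraction: float = 0.7  # gains outnumber losses in hybrid cohorts
    loh_tracts_per_sample: int = 0
    loh_tract_length: int = 20000
    repeat_inserts: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    mito_donor_species: int | None = None  # 0/1 parent index, None = majority
    n_mito_clades: tuple[int, int] = (1, 1)
    mito_length: int = 5000
    coverage: float = 20.0
    read_length: int = 100
    error_rate: float = 0.001
    species_ids: tuple[str, str] | None = None


@dataclass
class Cohort:
    parents: dict[str, tuple[ParentGenome, ParentGenome]]
    samples: list[tuple[str, HybridTruth, ReadSet]]  # (cross name, truth, reads)
    manifest: "object"  # pandas DataFrame


def _draw_contribution(rng: np.random.Generator, spec) -> float:
    if isinstance(spec, (tuple, list)):
        return float(rng.uniform(spec[0], spec[1]))
    return float(spec)


def generate_cohort(crosses: list[CrossSpec], seed: int, out_dir: str | Path | None = None) -> Cohort:
    """Simulate a multi-cross cohort; deterministic given ``seed``.

    When ``out_dir`` is given, writes parent FASTA, per-sample FASTQ and
    truth JSON, LOH/repeat BED, and a cohort manifest TSV.
    """
    import pandas as pd

    if not crosses:
        raise ValueError("cohort needs at least one cross")
    root = np.random.SeedSequence(seed)
    cross_seeds = root.spawn(len(crosses))
    parents: dict[str, tuple[ParentGenome, ParentGenome]] = {}
    samples: list[tuple[str, HybridTruth, ReadSet]] = []
    rows = []
    for cross, cseq in zip(crosses, cross_seeds):
        sp_ids = cross.species_ids or (f"{cross.name}_a", f"{cross.name}_b")
        pseed, *sseeds = cseq.spawn(cross.n_samples + 1)
        p1, p2 = generate_parent_pair(
            cross.chrom_lengths, cross.divergence, mito_length=cross.mito_length,
            n_mito_clades=cross.n_mito_clades,
            seed=int(pseed.generate_state(1)[0] % (2**31)), species_ids=sp_ids)
        parents[cross.name] = (p1, p2)
        lengths = p1.chrom_lengths
        for i, sseq in enumerate(sseeds):
            s = int(sseq.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(s)
            contribution = _draw_contribution(rng, cross.contribution)
            aneuploidies = []
            for sp in sp_ids:
                for chrom in p1.chrom_names:
                    if rng.random() < cross.aneuploidy_prob:
                        delta = 1 if rng.random() < cross.gain_fraction else -1
                        aneuploidies.append((sp, chrom, delta))
            loh = []
            for _ in range(cross.loh_tracts_per_sample):
                chrom = p1.chrom_names[int(rng.integers(len(p1.chrom_names)))]
                L = lengths[chrom]
                tl = min(cross.loh_tract_length, L)
                start = int(rng.integers(0, L - tl + 1))
                retained = sp_ids[int(rng.integers(2))]
                cand = (chrom, start, start + tl, retained)
                if not any(c == chrom and s0 < cand[2] and cand[1] < e0 for c, s0, e0, _ in loh):
                    loh.append(cand)
            mito_donor = None
            if cross.mito_donor_species is not None:
                donor = (p1, p2)[cross.mito_donor_species]
                mito_donor = (donor.species_id, donor.mito[0][0])
            sample_id = f"{cross.name}_s{i:03d}"
            truth = generate_hybrid(
                (p1, p2), contribution, aneuploidies, loh, cross.repeat_inserts,
                mito_donor, sample_id=sample_id, seed=s)
            reads = simulate_reads(truth, (p1, p2), cross.coverage, cross.read_length,
                                   cross.error_rate, seed=s + 1)
            samples.append((cross.name, truth, reads))
            rows.append({
                "sample": sample_id, "cross": cross.name,
                "contribution_p1": round(contribution, 6),
                "n_aneuploidies": len(aneuploidies), "n_loh_tracts": len(loh),
                "n_reads": len(reads), "seed": s,
            })
    manifest = pd.DataFrame(rows)
    cohort = Cohort(parents=parents, samples=samples, manifest=manifest)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for cross, (p1, p2) in sorted(cohort.parents.items()):
        for p in (p1, p2):
            recs = list(p.chromosomes) + [(f"{MITO}_{c}", s) for c, s in p.mito]
            write_fasta(out / f"{cross}.{p.species_id}.fasta", recs)
    for cross, truth, reads in cohort.samples:
        write_fastq(out / f"{truth.sample_id}.fastq", reads)
        (out / f"{truth.sample_id}.truth.json").write_text(truth.to_json() + "\n")
        with open(out / f"{truth.sample_id}.loh.bed", "w") as fh:
            for chrom, start, end, sp in truth.loh_tracts:
                fh.write(f"{chrom}\t{start}\t{end}\t{sp}\n")
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def realized_divergence(p1: ParentGenome, p2: ParentGenome) -> float:
    """Observed per-site mismatch fraction between two collinear parents."""
    diff = total = 0
    for (_n1, s1), (_n2, s2) in zip(p1.chromosomes, p2.chromosomes):
        a, b = encode(s1), encode(s2)
        diff += int((a != b).sum())
        total += a.size
    return diff / total


def derive_cross_distance_map(cohort: "Cohort") -> dict[str, float]:
    """Parental genetic distance (realized mismatch fraction) per cross."""
    return {cross: realized_divergence(p1, p2) for cross, (p1, p2) in cohort.parents.items()}


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(path: str | Path, reads: ReadSet) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(reads.names, reads.seqs):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> ReadSet:
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.description or rec.id)
        seqs.append(str(rec.seq))
    rl = max((len(s) for s in seqs), default=0)
    return ReadSet(names=names, seqs=seqs, read_length=rl, error_rate=float("nan"))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
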