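"""Seeded synthetic data: genomes, parents, ddRAD libraries, F2s, panels.

The generator emulates the study design of a biparental seed-colour cross:
two fully inbred parents differing by scattered SNPs/InDels, one of which
is a causal stop-codon SNP in a small MYB-like gene; PacI+NlaIII
double-digest libraries sequenced as 100 bp paired ends; an F2 of ~96
individuals; and a cultivar panel segregating for the causal allele.

Every function is deterministic under the configured seed, and the truth
(variant table, F2 genotypes, phenotypes) is available both as objects and
as machine-readable TSV.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .enzymes import Enzyme, cut_positions, get_enzyme, scan_sites

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Stage-specific generator derived from one global seed.

    Hierarchical splitting (seed + CRC32 of a stage label) lets every
    pipeline stage be re-run standalone and still reproduce the full run.
    """
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(label.encode())])


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=length, p=p).tobytes().decode()


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReferenceGenome:
    """Ordered named chromosomes over the ACGT alphabet."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, s in self.chromosomes:
            if not s:
                raise ValueError(f"chromosome {n} is empty")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def seq(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True, order=True)
class Variant:
    """Anchored variant: SNP (1/1), INS (alt longer), DEL (ref longer)."""

    chrom: str
    pos: int  # 1-based on the reference
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | INS | DEL

    def __post_init__(self) -> None:
        if self.vtype == "SNP" and (len(self.ref_allele) != 1 or len(self.alt_allele) != 1):
            raise ValueError("SNP alleles must both be single bases")
        if self.vtype in ("INS", "DEL") and len(self.ref_allele) == len(self.alt_allele):
            raise ValueError("indel alleles must differ in length")


@dataclass
class ParentHaplotype:
    """One haplotype of a fully inbred (homozygous) parent."""

    parent_id: str
    variants: list[Variant]

    def variants_on(self, chrom: str) -> list[Variant]:
        return [v for v in self.variants if v.chrom == chrom]


@dataclass
class GeneModel:
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]  # 1-based closed
    id: str

    @property
    def cds_start(self) -> int:
        return self.cds_intervals[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds_intervals[-1][1]


@dataclass
class CausalSpec:
    """The planted recessive causal variant and its phenotype rule."""

    gene: GeneModel
    variant: Variant
    recessive_phenotype: str = "white"
    dominant_phenotype: str = "black"


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 1-based closed interval
    end: int
    left_enzyme: str
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Gamete:
    """Mosaic of the two parent haplotypes with recorded crossovers."""

    start_parent: dict[str, str]  # chrom -> 'A' | 'B'
    breakpoints: dict[str, np.ndarray]  # chrom -> sorted positions

    def origin(self, chrom: str, pos: int | np.ndarray):
        """Parent of origin ('A'/'B') at one or many positions."""
        k = np.searchsorted(self.breakpoints[chrom], np.asarray(pos))
        first = self.start_parent[chrom]
        other = "B" if first == "A" else "A"
        return np.where(k % 2 == 0, first, other)

    def n_crossovers(self, chrom: str) -> int:
        return len(self.breakpoints[chrom])


@dataclass
class F2Individual:
    id: str
    gametes: tuple[Gamete, Gamete]
    phenotype: str

    def genotype_at(self, chrom: str, pos) -> np.ndarray:
        """'AA'/'AB'/'BB' by parental origin at reference positions."""
        o1 = self.gametes[0].origin(chrom, pos)
        o2 = self.gametes[1].origin(chrom, pos)
        swap = o1 <= o2
        lo = np.where(swap, o1, o2)
        hi = np.where(swap, o2, o1)
        return np.char.add(lo, hi)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cross.

    Defaults mirror the emulated design: 100 bp paired-end reads, an F2 of
    96, a PacI+NlaIII double digest, and an AT-rich plant-like genome so
    the 8-bp PacI site cuts at reduced-representation density.  Coverage
    25 matches a reads-per-tag ratio of a few tens, typical of ddRAD
    parent libraries.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 1_000_000
    chromosome_lengths: tuple[int, ...] | None = None
    gc_content: float = 0.4
    divergence_rate: float = 0.005
    enzyme_a: str = "PacI"
    enzyme_b: str = "NlaIII"
    size_min: int = 200
    size_max: int = 600
    read_length: int = 100
    coverage: float = 25.0
    error_rate: float = 0.001
    n_f2: int = 96
    crossover_rate: float = 1.0
    panel_size: int = 84
    panel_alt_freq: float = 45 / 84
    panel_discordance: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("gc_content", "divergence_rate", "error_rate", "panel_alt_freq",
                     "panel_discordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_chromosomes < 1 or self.n_f2 < 1 or self.panel_size < 1:
            raise ValueError("n_chromosomes, n_f2 and panel_size must be >= 1")
        if self.size_min > self.size_max:
            raise ValueError("size window min > max")
        if self.read_length > self.size_min:
            raise ValueError("read length must not exceed the minimum retained fragment length")
        if self.coverage <= 0 or self.crossover_rate < 0:
            raise ValueError("coverage must be positive and crossover_rate non-negative")
        get_enzyme(self.enzyme_a), get_enzyme(self.enzyme_b)

    @property
    def lengths(self) -> tuple[int, ...]:
        if self.chromosome_lengths is not None:
            return tuple(self.chromosome_lengths)
        return (self.chromosome_length,) * self.n_chromosomes

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["chromosome_lengths"] is not None:
            d["chromosome_lengths"] = list(d["chromosome_lengths"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("chromosome_lengths") is not None:
            d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        return cls(**d)


# ---------------------------------------------------------------------------
# causal-gene cassette

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def _build_cassette(rng: np.random.Generator, enzyme_a: Enzyme, enzyme_b: Enzyme,
                    target_len: int = 380) -> tuple[str, int, int, int]:
    """Design the causal locus (wild-type allele).

    Layout on the top strand: a PacI site inside the small CDS, the stop
    codon TGA ~20 bp downstream of the PacI cut with a HinfI site (GANTC)
    spanning it, a 78-nt stop-free read-through frame ending in TAA, and a
    NlaIII site placed so the PacI->NlaIII fragment falls in the size
    window.  Returns (cassette, cds_offset0, stop_offset0, cassette_cut0):
    0-based offsets of the CDS start, the stop codon and the PacI cut
    within the cassette.
    """
    for _ in range(200):
        # CDS: ATG + 7 codons + TTA ATT AAx (PacI at a codon boundary) + 6 codons + TGA
        head = "ATG" + _random_codons(rng, 7)
        aa_codon = "AA" + rng.choice(list("ACGT"))
        cds = head + "TTAATT" + aa_codon + _random_codons(rng, 6) + "TGA"
        assert len(cds) % 3 == 0 and cds[24:32] == "TTAATTAA"
        # read-through: ATC anchors the HinfI site over the stop, then 24
        # stop-free codons and the next in-frame stop 78 nt downstream.
        readthrough = "ATC" + _random_codons(rng, 24) + "TAA"
        body = cds + readthrough
        cut0 = 24 + enzyme_a.cut_offset  # 0-based PacI cut offset in cassette
        # pad so the PacI->NlaIII fragment lands mid-window
        pad = target_len - enzyme_b.cut_offset - (len(body) - cut0)
        spacer = random_sequence(rng, pad, gc=0.4)
        cassette = body + spacer + enzyme_b.recognition
        frag_region = cassette[cut0:]
        hinf = scan_sites(cassette, "HinfI")  # planted site starts at stop[1] = 1-based 53
        ok = (
            len(scan_sites(cassette, enzyme_a)) == 1
            and len(scan_sites(frag_region, enzyme_b)) == 1
            and 53 in hinf
            and all(s == 53 or abs(s - 53) > 60 for s in hinf)
        )
        if ok:
            return cassette, 0, 51, cut0
    raise RuntimeError("could not design a causal cassette satisfying site constraints")


# ---------------------------------------------------------------------------
# operations


def build_parent_genomes(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[ReferenceGenome, ParentHaplotype, ParentHaplotype, CausalSpec]:
    """Reference plus two homozygous parents and the planted causal SNP.

    The reference carries the dominant (black) allele; parent A is the
    white (recessive) parent and privately carries the causal stop-codon
    SNP.  Divergence variants are sampled at ``cfg.divergence_rate`` per
    base, assigned to one parent each, and kept clear of the causal
    cassette.  If ``out_dir`` is given, FASTA and truth TSV are written.
    """
    rng = rng_for(cfg.seed, "parents")
    enz_a, enz_b = get_enzyme(cfg.enzyme_a), get_enzyme(cfg.enzyme_b)
    cassette, cds_off, stop_off, _ = _build_cassette(rng, enz_a, enz_b)

    chroms: list[tuple[str, str]] = []
    causal_chrom = "chr1"
    cass_start0 = None
    for i, length in enumerate(cfg.lengths):
        name = f"chr{i + 1}"
        seq = random_sequence(rng, length, cfg.gc_content)
        if name == causal_chrom:
            if length < len(cassette) + 2000:
                raise ValueError("chromosome too short for the causal cassette")
            cass_start0 = length // 2
            seq = seq[:cass_start0] + cassette + seq[cass_start0 + len(cassette):]
        chroms.append((name, seq))
    ref = ReferenceGenome(chroms)

    cds_start = cass_start0 + cds_off + 1  # 1-based
    cds_end = cds_start + 53
    gene = GeneModel(causal_chrom, "+", [(cds_start, cds_end)], "gene_seedcolor")
    stop_pos = cass_start0 + stop_off + 1  # 1-based first base of TGA
    causal_variant = Variant(causal_chrom, stop_pos + 2, "A", "G", "SNP")
    causal = CausalSpec(gene, causal_variant)

    exclude = (cass_start0 + 1 - 150, cass_start0 + len(cassette) + 150)
    var_a: list[Variant] = [causal_variant]
    var_b: list[Variant] = []
    for name, seq in chroms:
        hits = np.flatnonzero(rng.random(len(seq)) < cfg.divergence_rate) + 1
        if name == causal_chrom:
            hits = hits[(hits < exclude[0]) | (hits > exclude[1])]
        # keep variants >=10 bp apart so anchored indels never overlap
        if len(hits) > 1:
            keep = np.concatenate([[True], np.diff(hits) >= 10])
            hits = hits[keep]
        hits = hits[hits <= len(seq) - 5]
        owners = rng.choice(["A", "B"], size=len(hits))
        kinds = rng.choice(["SNP", "INS", "DEL"], size=len(hits), p=[0.9, 0.05, 0.05])
        for pos, owner, kind in zip(hits.tolist(), owners, kinds):
            ref_base = seq[pos - 1]
            if kind == "SNP":
                alt = rng.choice([b for b in "ACGT" if b != ref_base])
                v = Variant(name, pos, ref_base, str(alt), "SNP")
            elif kind == "INS":
                ins = random_sequence(rng, int(rng.integers(1, 4)), cfg.gc_content)
                v = Variant(name, pos, ref_base, ref_base + ins, "INS")
            else:
                d = int(rng.integers(1, 4))
                v = Variant(name, pos, seq[pos - 1 : pos + d], ref_base, "DEL")
            (var_a if owner == "A" else var_b).append(v)

    hap_a = ParentHaplotype("parentA", sorted(var_a))
    hap_b = ParentHaplotype("parentB", sorted(var_b))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "reference.fa", ref.chromosomes)
        for hap, fn in ((hap_a, "parentA.fa"), (hap_b, "parentB.fa")):
            write_fasta(out / fn, haplotype_sequences(ref, hap))
        write_variant_truth(out / "variants_truth.tsv", hap_a, hap_b)
    return ref, hap_a, hap_b, causal


def apply_variants(seq: str, variants: Sequence[Variant]) -> str:
    """Apply sorted, non-overlapping anchored variants to one sequence."""
    parts: list[str] = []
    cur = 0  # 0-based cursor
    for v in variants:
        i = v.pos - 1
        if i < cur:
            raise ValueError(f"overlapping variant at {v.chrom}:{v.pos}")
        if seq[i : i + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(f"reference mismatch at {v.chrom}:{v.pos}")
        parts.append(seq[cur:i])
        parts.append(v.alt_allele)
        cur = i + len(v.ref_allele)
    parts.append(seq[cur:])
    return "".join(parts)


def haplotype_sequences(ref: ReferenceGenome, hap: ParentHaplotype) -> list[tuple[str, str]]:
    return [(name, apply_variants(seq, hap.variants_on(name))) for name, seq in ref.chromosomes]


def digest_double(
    sequences: ReferenceGenome | Iterable[tuple[str, str]],
    enzyme_a: str | Enzyme,
    enzyme_b: str | Enzyme,
    size_window: tuple[int, int] | None = None,
) -> list[Fragment]:
    """Double-digest: retained mixed-end fragments inside the size window.

    Fragments are the maximal intervals between adjacent top-strand cut
    positions of either enzyme; only fragments with one end cut by each
    enzyme (A-B or B-A) and a length inside the window are retained.  Pass
    ``size_window=None`` to keep every mixed-end fragment.
    """
    enz_a = get_enzyme(enzyme_a) if isinstance(enzyme_a, str) else enzyme_a
    enz_b = get_enzyme(enzyme_b) if isinstance(enzyme_b, str) else enzyme_b
    if isinstance(sequences, ReferenceGenome):
        sequences = sequences.chromosomes
    out: list[Fragment] = []
    for name, seq in sequences:
        cuts = [(c, enz_a.name) for c in cut_positions(seq, enz_a)]
        cuts += [(c, enz_b.name) for c in cut_positions(seq, enz_b)]
        cuts.sort()
        for (c1, e1), (c2, e2) in zip(cuts, cuts[1:]):
            if e1 == e2 or c1 == c2:
                continue
            length = c2 - c1
            if size_window is None or size_window[0] <= length <= size_window[1]:
                out.append(Fragment(name, c1 + 1, c2, e1, e2))
    return out


def all_intercut_intervals(seq: str, enzyme_a, enzyme_b) -> list[tuple[int, int]]:
    """Every interval between adjacent cuts, plus the two chromosome ends.

    Used to check that digestion tiles the chromosome exactly once.
    """
    cuts = sorted(set(cut_positions(seq, enzyme_a)) | set(cut_positions(seq, enzyme_b)))
    bounds = [0] + cuts + [len(seq)]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def simulate_read_pairs(
    fragments: Sequence[Fragment],
    sequences: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, read1, read2) pairs for one haplotype library.

    Read 1 is the first L bases from the rare-cutter (enzyme A) end of the
    fragment; read 2 is the first L bases from the other end on the
    opposite strand (i.e. the reverse complement).  Pair counts per
    fragment are Poisson(coverage); substitution errors are applied per
    base at ``cfg.error_rate``.
    """
    L = cfg.read_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for frag in fragments:
        fs = sequences[frag.chrom][frag.start - 1 : frag.end]
        if len(fs) < L:
            log.warning("fragment %s:%d-%d shorter than read length; skipped",
                        frag.chrom, frag.start, frag.end)
            continue
        if frag.left_enzyme == cfg.enzyme_a:
            r1t, r2t = fs[:L], revcomp(fs)[:L]
        else:
            r1t, r2t = revcomp(fs)[:L], fs[:L]
        n = int(rng.poisson(cfg.coverage))
        if n == 0:
            continue
        arr = np.frombuffer((r1t + r2t).encode(), dtype=np.uint8)
        reads = np.tile(arr, (n, 1))
        if cfg.error_rate > 0:
            mask = rng.random(reads.shape) < cfg.error_rate
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()))
                idx = np.searchsorted(bases, reads[mask])
                reads[mask] = bases[(idx + shift) % 4]
        blob = reads.tobytes().decode()
        for i in range(n):
            rec = blob[i * 2 * L : (i + 1) * 2 * L]
            rid = f"{sample_id}:{frag.chrom}:{frag.start}:{i}"
            yield rid, rec[:L], rec[L:]


def write_fastq_pair(pairs: Iterable[tuple[str, str, str]],
                     path1: str | Path, path2: str | Path,
                     quality_char: str = "I") -> int:
    """Write paired 4-line FASTQ records (Phred+33, constant quality)."""
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{quality_char * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{quality_char * len(r2)}\n")
            n += 1
    return n


def simulate_library(
    fragments: Sequence[Fragment],
    sequences: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
    path1: str | Path,
    path2: str | Path,
) -> int:
    """Simulate one library and write the paired FASTQ; returns pair count."""
    return write_fastq_pair(
        simulate_read_pairs(fragments, sequences, cfg, rng, sample_id), path1, path2
    )


def _make_gamete(cfg: SimConfig, rng: np.random.Generator, lengths: dict[str, int]) -> Gamete:
    start, breaks = {}, {}
    for chrom, length in lengths.items():
        n = int(rng.poisson(cfg.crossover_rate))
        breaks[chrom] = np.sort(rng.integers(1, length, size=n))
        start[chrom] = "A" if rng.random() < 0.5 else "B"
    return Gamete(start, breaks)


def simulate_f2_population(
    ref: ReferenceGenome, causal: CausalSpec, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[F2Individual]:
    """Selfed-F1 progeny: each individual is two independent F1 gametes.

    Crossovers per chromosome are Poisson(cfg.crossover_rate) with uniform
    placement (no interference).  The phenotype is recessive exactly when
    both gametes carry the recessive parent's (A) allele at the causal
    site.
    """
    if rng is None:
        rng = rng_for(cfg.seed, "f2")
    lengths = {name: len(seq) for name, seq in ref.chromosomes}
    pop = []
    for i in range(cfg.n_f2):
        g1, g2 = _make_gamete(cfg, rng, lengths), _make_gamete(cfg, rng, lengths)
        v = causal.variant
        homo_alt = (g1.origin(v.chrom, v.pos) == "A") and (g2.origin(v.chrom, v.pos) == "A")
        pheno = causal.recessive_phenotype if homo_alt else causal.dominant_phenotype
        pop.append(F2Individual(f"F2_{i + 1:03d}", (g1, g2), str(pheno)))
    return pop


def gamete_variants(gamete: Gamete, hap_a: ParentHaplotype, hap_b: ParentHaplotype,
                    chrom: str) -> list[Variant]:
    """Variants carried by a mosaic gamete on one chromosome."""
    out = []
    for hap, parent in ((hap_a, "A"), (hap_b, "B")):
        vs = hap.variants_on(chrom)
        if not vs:
            continue
        pos = np.array([v.pos for v in vs])
        keep = gamete.origin(chrom, pos) == parent
        out.extend(v for v, k in zip(vs, keep) if k)
    return sorted(out)


def gamete_sequences(gamete: Gamete, ref: ReferenceGenome,
                     hap_a: ParentHaplotype, hap_b: ParentHaplotype) -> dict[str, str]:
    return {
        name: apply_variants(seq, gamete_variants(gamete, hap_a, hap_b, name))
        for name, seq in ref.chromosomes
    }


def simulate_cultivar_panel(
    cfg: SimConfig,
    causal: CausalSpec,
    extra_sites: Sequence[tuple[str, int]] = (),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Homozygous cultivar panel segregating for the causal allele.

    Returns a DataFrame indexed by cultivar id with one 'A'/'B' column per
    site ('A' = recessive parent's allele) and a 'phenotype' column.  The
    causal-site allele frequency follows ``cfg.panel_alt_freq`` exactly
    (rounded count); non-causal sites start fully linked and are then
    shuffled at ``cfg.panel_discordance`` per cultivar, so some markers
    are discordant in some cultivars.
    """
    if rng is None:
        rng = rng_for(cfg.seed, "panel")
    n = cfg.panel_size
    n_alt = int(round(cfg.panel_alt_freq * n))
    causal_alleles = np.array(["A"] * n_alt + ["B"] * (n - n_alt))
    rng.shuffle(causal_alleles)
    v = causal.variant
    data = {f"{v.chrom}:{v.pos}": causal_alleles}
    for chrom, pos in extra_sites:
        col = causal_alleles.copy()
        flip = rng.random(n) < cfg.panel_discordance
        col[flip] = np.where(col[flip] == "A", "B", "A")
        data[f"{chrom}:{pos}"] = col
    df = pd.DataFrame(data, index=[f"cv_{i + 1:03d}" for i in range(n)])
    df["phenotype"] = np.where(
        causal_alleles == "A", causal.recessive_phenotype, causal.dominant_phenotype
    )
    df.index.name = "cultivar"
    return df


# ---------------------------------------------------------------------------
# writers


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_variant_truth(path: str | Path, hap_a: ParentHaplotype,
                        hap_b: ParentHaplotype) -> None:
    rows = [
        (v.chrom, v.pos, v.ref_allele, v.alt_allele, v.vtype, hap.parent_id)
        for hap in (hap_a, hap_b)
        for v in hap.variants
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype", "parent"])
    df.sort_values(["chrom", "pos"]).to_csv(path, sep="\t", index=False)


def write_phenotypes(path: str | Path, pop: Sequence[F2Individual]) -> None:
    pd.DataFrame(
        {"individual_id": [p.id for p in pop], "phenotype": [p.phenotype for p in pop]}
    ).to_csv(path, sep="\t", index=False)


def write_config(path: str | Path, cfg: SimConfig) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
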