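"""Biallelic tag markers: placement, pairing, genotyping, collapsing.

Parent-unique tags are placed on the reference by exact k-mer seeding
(pigeonhole: a tag within ``max_edit`` edits of a reference window must
share one of ``max_edit + 1`` non-overlapping exact segments) followed by
edit-distance verification.  Ambiguous tags — two or more distinct
placements at the best edit distance — are discarded rather than placed
randomly: determinism over sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import pandas as pd

from .radtags import TagSet
from .simdata import ReferenceGenome, revcomp

MISSING = "NA"


@dataclass(frozen=True)
class TagPlacement:
    tag: str
    chrom: str
    pos: int  # 1-based leftmost reference coordinate
    strand: str
    edit_distance: int


@dataclass(frozen=True)
class BiallelicMarker:
    """A parent-A/parent-B tag pair at one reference locus (one co-dominant marker)."""

    marker_id: str
    chrom: str
    pos: int
    allele_a_tag: str  # in read orientation, as counted in TagSets
    allele_b_tag: str
    difference: str  # SNP | InDel
    n_edits: int


@dataclass
class GenotypeMatrix:
    """Loci x individuals co-dominant calls plus optional phenotype vector.

    ``calls`` values are 'AA' (only the A-allele tag present), 'BB', 'AB'
    (both) or 'NA' (neither).
    """

    calls: pd.DataFrame
    loci: pd.DataFrame  # indexed by marker id; columns chrom, pos
    phenotype: pd.Series | None = None
    collapse_members: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.loci.index):
            raise ValueError("calls and loci indexes differ")
        if self.phenotype is not None and not self.phenotype.index.equals(
            pd.Index(self.calls.columns)
        ):
            raise ValueError("phenotype index must match individuals")

    @property
    def n_loci(self) -> int:
        return len(self.calls)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)


def _seed_candidates(query: str, seq: str, max_edit: int, k: int | None) -> set[int]:
    """0-based candidate start offsets from exact segment hits (pigeonhole)."""
    L = len(query)
    n_seg = max_edit + 1
    seg_len = k if k is not None else L // n_seg
    if seg_len < 1 or seg_len > L:
        raise ValueError("seed length must be in [1, tag length]")
    cands: set[int] = set()
    for i in range(n_seg):
        off = min(i * seg_len, L - seg_len)
        seg = query[off : off + seg_len]
        j = seq.find(seg)
        while j != -1:
            cands.add(j - off)
            j = seq.find(seg, j + 1)
    return cands


def place_tag(
    tag: str,
    reference: ReferenceGenome | Sequence[tuple[str, str]],
    max_edit: int = 2,
    k: int | None = None,
) -> TagPlacement | None:
    """Best unique placement of a tag (either strand), or None.

    Returns None when no placement has edit distance <= ``max_edit`` or
    when the best distance is achieved at more than one distinct location
    (multi-mapping).  Placements whose starts differ by at most
    ``max_edit`` are treated as one location (indel wobble).
    """
    chroms = reference.chromosomes if isinstance(reference, ReferenceGenome) else reference
    L = len(tag)
    hits: list[tuple[int, str, int, str]] = []  # (dist, chrom, start0, strand)
    for name, seq in chroms:
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            for c in _seed_candidates(query, seq, max_edit, k):
                w0 = max(0, c - max_edit)
                window = seq[w0 : c + L + max_edit]
                res = edlib.align(query, window, mode="HW", task="locations", k=max_edit)
                if res["editDistance"] == -1:
                    continue
                for s, _e in res["locations"]:
                    hits.append((res["editDistance"], name, w0 + (s or 0), strand))
    if not hits:
        return None
    best = min(h[0] for h in hits)
    placements: list[tuple[str, int, str]] = []
    for d, name, s0, strand in sorted(hits):
        if d != best:
            continue
        if any(
            n == name and st == strand and abs(s0 - p) <= max_edit
            for n, p, st in placements
        ):
            continue
        placements.append((name, s0, strand))
    if len(placements) != 1:
        return None
    name, s0, strand = placements[0]
    return TagPlacement(tag, name, s0 + 1, strand, best)


def _oriented(p: TagPlacement) -> str:
    return p.tag if p.strand == "+" else revcomp(p.tag)


def classify_difference(seq_a: str, seq_b: str) -> tuple[str, int]:
    """(SNP|InDel, edit distance) from a global pairwise alignment."""
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    cigar = res["cigar"] or ""
    has_indel = "I" in cigar or "D" in cigar
    return ("InDel" if has_indel else "SNP"), res["editDistance"]


def pair_biallelic_tags(
    placed_a: Sequence[TagPlacement], placed_b: Sequence[TagPlacement]
) -> list[BiallelicMarker]:
    """Pair A- and B-parent placements whose reference intervals overlap.

    The difference between the two tags (compared in reference
    orientation) is classified as SNP or InDel by pairwise alignment.
    Markers are ordered by (chrom, pos) with a deterministic tie-break on
    the allele-A tag.
    """
    by_chrom: dict[str, list[TagPlacement]] = {}
    for p in placed_b:
        by_chrom.setdefault(p.chrom, []).append(p)
    markers = []
    for pa in placed_a:
        la = len(pa.tag)
        for pb in by_chrom.get(pa.chrom, ()):
            lb = len(pb.tag)
            if pa.pos <= pb.pos + lb - 1 and pb.pos <= pa.pos + la - 1:
                if pa.tag == pb.tag:
                    continue
                diff, ne = classify_difference(_oriented(pa), _oriented(pb))
                if ne == 0:
                    continue
                markers.append(
                    (min(pa.pos, pb.pos), pa.tag, pa, pb, diff, ne)
                )
    markers.sort(key=lambda m: (m[2].chrom, m[0], m[1]))
    out = []
    for i, (pos, _ta, pa, pb, diff, ne) in enumerate(markers):
        out.append(
            BiallelicMarker(
                f"{pa.chrom}:{pos}", pa.chrom, pos, pa.tag, pb.tag, diff, ne
            )
        )
    return out


def genotype_population(
    tagsets: Mapping[str, TagSet],
    markers: Sequence[BiallelicMarker],
    presence_min: int = 1,
    phenotype: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Presence/absence genotyping of every individual at every marker.

    An allele is present when its tag count is at least ``presence_min``
    in the individual's (already thresholded) TagSet.
    """
    ids = list(tagsets)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    table = {}
    for ind in ids:
        ts = tagsets[ind]
        col = []
        for m in markers:
            a = ts.count(m.allele_a_tag) >= presence_min
            b = ts.count(m.allele_b_tag) >= presence_min
            col.append("AB" if a and b else "AA" if a else "BB" if b else MISSING)
        table[ind] = col
    idx = pd.Index([m.marker_id for m in markers], name="locus")
    calls = pd.DataFrame(table, index=idx)
    loci = pd.DataFrame(
        {"chrom": [m.chrom for m in markers], "pos": [m.pos for m in markers]}, index=idx
    )
    pheno = None
    if phenotype is not None:
        pheno = pd.Series({i: phenotype[i] for i in ids}, name="phenotype")
        pheno = pheno.reindex(calls.columns)
    return GenotypeMatrix(calls, loci, pheno)


def collapse_cosegregating(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Merge loci with identical call vectors across all individuals.

    The representative of each group is the locus with the smallest
    (chrom, pos); the member -> representative mapping is retained on the
    result.  Mirrors summarising co-segregating biallelic tag loci into
    co-dominant markers.
    """
    groups: dict[tuple, list[str]] = {}
    for locus, row in zip(matrix.calls.index, matrix.calls.itertuples(index=False)):
        groups.setdefault(tuple(row), []).append(locus)
    reps, members = [], {}
    for loci in groups.values():
        rep = min(loci, key=lambda l: (matrix.loci.at[l, "chrom"], matrix.loci.at[l, "pos"]))
        reps.append(rep)
        members[rep] = sorted(loci)
    order = [l for l in matrix.calls.index if l in members]
    return GenotypeMatrix(
        matrix.calls.loc[order],
        matrix.loci.loc[order],
        matrix.phenotype,
        collapse_members={r: members[r] for r in order},
    )


def filter_missing(matrix: GenotypeMatrix, max_missing_fraction: float = 0.0) -> GenotypeMatrix:
    """Drop loci whose fraction of missing calls exceeds the threshold.

    The default of 0 reproduces strict exclusion of loci with any missing
    data.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = (matrix.calls == MISSING).mean(axis=1)
    keep = frac[frac <= max_missing_fraction].index
    cm = None
    if matrix.collapse_members is not None:
        cm = {r: m for r, m in matrix.collapse_members.items() if r in set(keep)}
    return GenotypeMatrix(
        matrix.calls.loc[keep], matrix.loci.loc[keep], matrix.phenotype, cm
    )


def write_markers(path: str | Path, markers: Sequence[BiallelicMarker]) -> None:
    pd.DataFrame(
        [
            (m.marker_id, m.chrom, m.pos, m.allele_a_tag, m.allele_b_tag, m.difference, m.n_edits)
            for m in markers
        ],
        columns=["marker_id", "chrom", "pos", "allele_a", "allele_b", "difference", "n_edits"],
    ).to_csv(path, sep="\t", index=False)


def write_genotype_matrix(path: str | Path, matrix: GenotypeMatrix) -> None:
    matrix.calls.to_csv(path, sep="\t")


def read_genotype_matrix(path: str | Path, loci: pd.DataFrame | None = None,
                         phenotype: pd.Series | None = None) -> GenotypeMatrix:
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    calls.index.name = "locus"
    if loci is None:
        parts = calls.index.str.rsplit(":", n=1)
        loci = pd.DataFrame(
            {"chrom": [p[0] for p in parts], "pos": [int(p[1]) for p in parts]},
            index=calls.index,
        )
    return GenotypeMatrix(calls, loci, phenotype)
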