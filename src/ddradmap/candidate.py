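"""CAPS marker discovery and coding-consequence classification.

A CAPS (cleaved amplified polymorphic sequence) marker is a sequence
difference that creates or destroys a restriction site in one allele, so
the two alleles' digestion patterns differ.  Discovery aligns the two
allele sequences, and for every difference tests each enzyme for a site
present in exactly one allele within a window around the difference.

Consequence classification covers synonymous/missense/nonsense SNVs,
stop-loss read-through (extension to the next in-frame stop), and
frameshift / in-frame indels, with translate-until-stop peptides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import edlib
from Bio.Seq import Seq

from .enzymes import Enzyme, get_enzyme, scan_sites
from .simdata import STOP_CODONS, revcomp

__all__ = [
    "scan_sites",
    "insilico_pcr",
    "digest_fragments",
    "find_caps_markers",
    "classify_coding_variant",
    "format_marker_name",
    "CdsModel",
    "Consequence",
    "CapsCandidate",
]


@dataclass(frozen=True)
class CapsCandidate:
    """A candidate CAPS marker at one allele-A position."""

    position: int  # 1-based on allele A
    enzyme: str
    fragment_lengths_a: tuple[int, ...]
    fragment_lengths_b: tuple[int, ...]
    marker_name: str


@dataclass
class CdsModel:
    """Spliced coding sequence (strand resolved) plus downstream genomic context."""

    seq: str
    downstream: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def protein(self) -> str:
        return str(Seq(self.seq).translate(to_stop=True))


@dataclass
class Consequence:
    kind: str  # synonymous|missense|nonsense|stop_loss|frameshift|in_frame_indel
    extension_nt: int = 0
    extension_aa: int = 0
    peptide: str = ""
    notes: str = ""


def insilico_pcr(
    template: str, forward_primer: str, reverse_primer: str, max_len: int = 5000
) -> str | None:
    """Exact-match in-silico PCR; returns the amplicon or None.

    The amplicon spans the unique forward-primer match to the unique
    reverse-complemented reverse-primer match, inclusive of both primers.
    Absent, ambiguous (multiple) matches or a product longer than
    ``max_len`` give None.  Primer thermodynamics are out of scope.
    """
    if len(forward_primer) < 15 or len(reverse_primer) < 15:
        raise ValueError("primers must be >= 15 nt")

    def find_all(needle: str) -> list[int]:
        out, j = [], template.find(needle)
        while j != -1:
            out.append(j)
            j = template.find(needle, j + 1)
        return out

    fw = find_all(forward_primer)
    rv = find_all(revcomp(reverse_primer))
    if len(fw) != 1 or len(rv) != 1:
        return None
    start = fw[0]
    end = rv[0] + len(reverse_primer)
    if end <= start or end - start > max_len:
        return None
    return template[start:end]


def digest_fragments(amplicon: str, enzyme: Enzyme | str) -> list[int]:
    """Fragment lengths, left to right, after cutting at every site.

    Cuts are at recognition-site start + cut offset; lengths always sum
    to the amplicon length.
    """
    if not amplicon:
        raise ValueError("amplicon is empty")
    enz = get_enzyme(enzyme) if isinstance(enzyme, str) else enzyme
    cuts = sorted(
        {s - 1 + enz.cut_offset for s in scan_sites(amplicon, enz)} - {0, len(amplicon)}
    )
    bounds = [0] + cuts + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _alignment_diffs(allele_a: str, allele_b: str) -> list[tuple[int, int]]:
    """(pos_a, pos_b) 1-based anchors of each difference run, from a global alignment."""
    res = edlib.align(allele_a, allele_b, mode="NW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return []
    diffs = []
    ia = ib = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            ia += n
            ib += n
        else:
            diffs.append((ia + 1, ib + 1))
            if ch == "X":
                ia += n
                ib += n
            elif ch == "D":  # edlib D consumes the target (allele B)
                ib += n
            elif ch == "I":  # I consumes the query (allele A)
                ia += n
    return diffs


def find_caps_markers(
    allele_a: str,
    allele_b: str,
    enzymes: Sequence[str | Enzyme] = ("HinfI", "EcoRI", "PacI", "NlaIII"),
    window: int = 50,
    namer=None,
) -> list[CapsCandidate]:
    """CAPS candidates distinguishing two allele sequences.

    For every aligned difference and every enzyme, the two alleles are
    scanned within ``window`` bases of the difference; a candidate is
    emitted when the local site count differs and the two full digestion
    patterns differ.  ``namer(position, enzyme_name)`` may supply marker
    names; the default is ``pos<position>_<enzyme>``.
    """
    if not allele_a or not allele_b:
        raise ValueError("allele sequences must be non-empty")
    diffs = _alignment_diffs(allele_a, allele_b)
    if len(diffs) > max(len(allele_a), len(allele_b)) // 4:
        raise ValueError("alleles share no usable alignment anchor")
    out = []
    seen = set()
    for pos_a, pos_b in diffs:
        for enzyme in enzymes:
            enz = get_enzyme(enzyme) if isinstance(enzyme, str) else enzyme
            la = allele_a[max(0, pos_a - 1 - window) : pos_a - 1 + window]
            lb = allele_b[max(0, pos_b - 1 - window) : pos_b - 1 + window]
            if len(scan_sites(la, enz)) == len(scan_sites(lb, enz)):
                continue
            fa = tuple(digest_fragments(allele_a, enz))
            fb = tuple(digest_fragments(allele_b, enz))
            if fa == fb or (pos_a, enz.name) in seen:
                continue
            seen.add((pos_a, enz.name))
            name = namer(pos_a, enz.name) if namer else f"pos{pos_a}_{enz.name}"
            out.append(CapsCandidate(pos_a, enz.name, fa, fb, name))
    return out


def _translate_until_stop(seq: str) -> tuple[str, bool]:
    """(peptide, stopped): translate codons until a stop or sequence end."""
    pep = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(pep), True
        pep.append(str(Seq(codon).translate()))
    return "".join(pep), False


def classify_coding_variant(cds: CdsModel, pos: int, ref: str, alt: str) -> Consequence:
    """Consequence of a variant at 1-based CDS position ``pos``.

    Substitutions in the stop codon that destroy it are stop-loss: the
    extension runs to the next in-frame stop through ``cds.downstream``
    (flagged ``open-ended`` when none exists).  Length-changing variants
    are frameshift (length difference not a multiple of 3, peptide
    translated to the first stop) or in-frame indels.  Other
    substitutions are classified by codon-table comparison.
    """
    seq = cds.seq
    if not 1 <= pos <= len(seq):
        raise ValueError("variant outside the CDS")
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(f"reference allele mismatch at CDS position {pos}")
    mutant = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    delta = len(alt) - len(ref)

    if delta != 0:
        if delta % 3 != 0:
            pep, stopped = _translate_until_stop(mutant + cds.downstream)
            return Consequence(
                "frameshift", peptide=pep,
                notes="" if stopped else "no stop before sequence end",
            )
        pep, _ = _translate_until_stop(mutant + cds.downstream)
        return Consequence("in_frame_indel", peptide=pep,
                           notes=f"{abs(delta) // 3} codon(s) {'inserted' if delta > 0 else 'deleted'}")

    old_codon_i = (pos - 1) // 3
    old_codon = seq[old_codon_i * 3 : old_codon_i * 3 + 3]
    new_codon = mutant[old_codon_i * 3 : old_codon_i * 3 + 3]
    in_stop = old_codon_i == len(seq) // 3 - 1 and old_codon in STOP_CODONS

    if in_stop:
        if new_codon in STOP_CODONS:
            return Consequence("synonymous", notes="stop codon retained")
        # stop-loss: read through into downstream sequence
        tail = new_codon + cds.downstream
        ext_pep, stopped = _translate_until_stop(tail)
        ext_aa = len(ext_pep)
        ext_nt = 3 * ext_aa
        pep = str(Seq(seq[: len(seq) - 3]).translate()) + ext_pep
        return Consequence(
            "stop_loss", extension_nt=ext_nt, extension_aa=ext_aa, peptide=pep,
            notes="" if stopped else "open-ended: no downstream in-frame stop",
        )
    if new_codon in STOP_CODONS:
        pep, _ = _translate_until_stop(mutant)
        return Consequence("nonsense", peptide=pep)
    aa_old = str(Seq(old_codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if aa_old == aa_new:
        return Consequence("synonymous")
    return Consequence("missense", notes=f"{aa_old}->{aa_new}")


def format_marker_name(
    linkage_group: str, genome_version: str, position_bp: int, enzyme: str | None = None
) -> str:
    """Marker name: (LG)_(version)_(position in Mbp, floored to 3 dp)[_enzyme].

    The position is a coordinate, not a measurement, so it is truncated
    rather than rounded: 49,251,000 -> ``LG7_v8_49.251Mbp_HinfI``.
    """
    if position_bp < 1:
        raise ValueError("position must be >= 1")
    mbp = math.floor(position_bp / 1000) / 1000
    name = f"{linkage_group}_{genome_version}_{mbp:.3f}Mbp"
    if enzyme:
        name += f"_{enzyme}"
    return name
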