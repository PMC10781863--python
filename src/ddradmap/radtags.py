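"""RAD-tag extraction, counting, thresholding and parental partitioning.

A tag is the first L bases of read 1 (the rare-cutter end); a both-mates
mode also counts read-2 tags.  Tags are *not* reverse-complement
collapsed: in ddRAD the tag orientation is fixed by the cut site.
Thresholding keeps tags with count >= min_count; the default min_count of
3 reads "more than 2 read counts" strictly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_MIN_COUNT = 3  # "> 2 read counts", read strictly


@dataclass
class TagSet:
    """Distinct fixed-length tags with read counts for one sample."""

    sample_id: str
    tag_length: int
    tags: dict[str, int] = field(default_factory=dict)
    min_count: int = 1

    def __len__(self) -> int:
        return len(self.tags)

    def count(self, tag: str) -> int:
        return self.tags.get(tag, 0)

    def threshold(self, min_count: int) -> "TagSet":
        return TagSet(
            self.sample_id,
            self.tag_length,
            {t: c for t, c in self.tags.items() if c >= min_count},
            max(self.min_count, min_count),
        )


@dataclass
class TagPartition:
    unique_a: set[str]
    unique_b: set[str]
    shared: set[str]


def _iter_fastq(path: str | Path):
    with open(path) as fh:
        n = 0
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                n += 1
                yield title, seq.upper()
        except ValueError as e:
            raise ValueError(f"malformed FASTQ record near record {n + 1} in {path}: {e}") from e


def extract_tags(
    fastq_pair: tuple[str | Path, str | Path] | str | Path,
    tag_length: int = 100,
    min_count: int = DEFAULT_MIN_COUNT,
    sample_id: str = "",
    use_both_mates: bool = False,
) -> TagSet:
    """Count first-``tag_length``-base tags from read 1 (optionally both mates).

    Reads shorter than ``tag_length`` are rejected; counts are exact read
    multiplicities, then tags below ``min_count`` are removed.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if isinstance(fastq_pair, (str, Path)):
        fastq_pair = (fastq_pair, None)
    path1, path2 = fastq_pair
    counts: Counter[str] = Counter()
    sources = [path1] + ([path2] if (use_both_mates and path2 is not None) else [])
    for path in sources:
        for i, (_title, seq) in enumerate(_iter_fastq(path)):
            if len(seq) < tag_length:
                raise ValueError(f"read {i + 1} in {path} shorter than tag length {tag_length}")
            counts[seq[:tag_length]] += 1
    tags = {t: c for t, c in counts.items() if c >= min_count}
    return TagSet(sample_id or str(path1), tag_length, tags, min_count)


def partition_tags(set_a: TagSet, set_b: TagSet) -> TagPartition:
    """Exact set arithmetic on the distinct tag sequences of two samples."""
    if set_a.tag_length != set_b.tag_length:
        raise ValueError(
            f"tag length mismatch: {set_a.tag_length} vs {set_b.tag_length}"
        )
    a, b = set(set_a.tags), set(set_b.tags)
    return TagPartition(unique_a=a - b, unique_b=b - a, shared=a & b)


def write_tagset(path: str | Path, tagset: TagSet) -> None:
    df = pd.DataFrame(
        sorted(tagset.tags.items()), columns=["tag", "count"]
    )
    df.insert(0, "sample_id", tagset.sample_id)
    df.to_csv(path, sep="\t", index=False)


def write_partition(path: str | Path, part: TagPartition) -> None:
    rows = [(t, cls) for cls, tags in
            (("unique_a", part.unique_a), ("unique_b", part.unique_b), ("shared", part.shared))
            for t in sorted(tags)]
    pd.DataFrame(rows, columns=["tag", "class"]).to_csv(path, sep="\t", index=False)
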