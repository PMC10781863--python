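"""Qualitative trait mapping against a co-dominant genotype matrix.

A binary recessive trait is placed by recombinant counting: an individual
is discordant at a locus when its phenotype and genotype disagree under
the single-recessive-locus model.  Completely co-segregating loci have
zero discordant individuals; the flanking interval is given by the
nearest loci with at least one discordant individual along the linkage
group order.  The trait is never inserted into the map as a pseudo-marker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linkmap import LinkageGroup
from .markers import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class SegregationTest:
    observed: list[int]
    expected: list[float]
    chi2: float
    df: int
    p_value: float


@dataclass
class TraitPlacement:
    """Discordant-individual counts per locus and the derived interval."""

    counts: pd.Series  # locus -> discordant individuals
    cosegregating: list[str]  # loci with 0 discordant individuals
    best_locus: str
    flanking: tuple[str | None, str | None]  # nearest loci with >= 1 discordant
    n_individuals: int


@dataclass
class ConcordanceTable:
    """Phenotype x genotype cross-classification per panel marker."""

    table: pd.DataFrame  # rows (phenotype, genotype_class), one column per marker
    discordant: pd.Series  # marker -> discordant cultivar count
    completely_linked: pd.Series  # marker -> bool (discordant == 0)


def segregation_chi2(observed: Sequence[int], ratio: Sequence[float]) -> SegregationTest:
    """Pearson chi-square (no continuity correction) against an expected ratio.

    With observed seed-colour classes 74:22 against 3:1 this gives
    p = 0.64, fixing the uncorrected-test convention.
    """
    obs = np.asarray(observed, dtype=float)
    if len(obs) < 2 or (obs < 0).any():
        raise ValueError("need >= 2 non-negative class counts")
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) != len(obs) or (ratio <= 0).any():
        raise ValueError("expected ratio must be positive for every class")
    exp = obs.sum() * ratio / ratio.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationTest(list(map(int, obs)), exp.tolist(), chi2, df, p)


def _discordant_matrix(matrix: GenotypeMatrix, recessive_parent: str,
                       recessive_label: str | None = None) -> pd.DataFrame:
    """Boolean loci x individuals discordance grid (recessive model).

    Discordant: recessive phenotype without the homozygous
    recessive-parent genotype, or dominant phenotype with it.  Missing
    genotype calls are uninformative, hence concordant.
    """
    if matrix.phenotype is None:
        raise ValueError("genotype matrix carries no phenotype vector")
    if recessive_parent not in ("A", "B"):
        raise ValueError("recessive_parent must be 'A' or 'B'")
    homo = recessive_parent * 2
    pheno = matrix.phenotype
    missing_ind = pheno[pheno.isna()].index
    if len(missing_ind):
        log.warning("excluding %d individuals with missing phenotype", len(missing_ind))
    keep = [c for c in matrix.calls.columns if c not in set(missing_ind)]
    calls = matrix.calls[keep]
    labels = pheno[keep]
    if recessive_label is None:
        recessive_label = _recessive_label(labels)
    is_rec = labels == recessive_label
    is_homo = calls == homo
    informative = calls != MISSING
    return (is_homo ^ is_rec.to_numpy()) & informative


def _recessive_label(labels: pd.Series) -> str:
    """The minority phenotype class is the recessive one in an F2 (3:1)."""
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError(f"expected a binary phenotype, got classes {list(counts.index)}")
    return counts.index[-1]


def map_trait_locus(
    matrix: GenotypeMatrix,
    recessive_parent: str = "A",
    groups: Sequence[LinkageGroup] | None = None,
    recessive_label: str | None = None,
) -> TraitPlacement:
    """Place a recessive binary trait by per-locus discordant counting.

    ``recessive_parent`` names the parent whose homozygous genotype is
    expected in recessive-phenotype individuals.  When linkage groups are
    supplied, the flanking markers are the nearest discordant loci on each
    side of the best locus along its group's order; otherwise along the
    matrix locus order.
    """
    disc = _discordant_matrix(matrix, recessive_parent, recessive_label)
    counts = disc.sum(axis=1)
    counts.name = "discordant"
    coseg = list(counts[counts == 0].index)
    best = counts.idxmin()
    order = list(matrix.calls.index)
    if groups is not None:
        for g in groups:
            if best in g.loci:
                order = list(g.loci)
                break
    i = order.index(best)
    left = next((l for l in reversed(order[:i]) if counts.get(l, 0) >= 1), None)
    right = next((l for l in order[i + 1 :] if counts.get(l, 0) >= 1), None)
    return TraitPlacement(counts, coseg, best, (left, right), disc.shape[1])


def panel_concordance(
    genotypes: pd.DataFrame,
    phenotypes: pd.Series,
    recessive_parent: str = "A",
    recessive_label: str | None = None,
) -> ConcordanceTable:
    """Cross-classify panel cultivars by phenotype and marker genotype.

    ``genotypes``: cultivars x markers with values 'A' (recessive
    parent's homozygous class), 'B', or anything else (heterozygous /
    failed), counted as 'other' and excluded from the discordance count.
    Markers are ranked by discordant count; ``completely_linked`` is
    discordant == 0.
    """
    phenotypes = phenotypes.reindex(genotypes.index)
    if phenotypes.isna().any():
        raise ValueError("every cultivar needs a phenotype")
    if recessive_label is None:
        recessive_label = _recessive_label(phenotypes)
    classes = ("A", "B", "other")
    rows = []
    for pheno in sorted(phenotypes.unique()):
        sub = genotypes[phenotypes == pheno]
        for cls in classes:
            if cls == "other":
                vals = (~sub.isin(["A", "B"])).sum()
            else:
                vals = (sub == cls).sum()
            rows.append(((pheno, cls), vals))
    table = pd.DataFrame(dict(rows)).T
    table.index = pd.MultiIndex.from_tuples(table.index, names=["phenotype", "genotype"])
    rec_parent, dom_parent = (
        (recessive_parent, "B" if recessive_parent == "A" else "A")
    )
    is_rec = phenotypes == recessive_label
    disc = {}
    for m in genotypes.columns:
        g = genotypes[m]
        disc[m] = int(
            ((is_rec & (g == dom_parent)) | (~is_rec & (g == rec_parent))).sum()
        )
    discordant = pd.Series(disc, name="discordant").sort_values(kind="stable")
    return ConcordanceTable(table, discordant, discordant == 0)


@dataclass
class PigmentSummary:
    mean_white: float
    mean_black: float
    se_white: float | None
    se_black: float | None
    ratio: float  # white / black, exact

    @property
    def ratio_display(self) -> float:
        return round(self.ratio, 2)


def pigment_ratio(group_white: Sequence[float], group_black: Sequence[float]) -> PigmentSummary:
    """Mean, standard error and white/black ratio of absorbance groups.

    SE = sd / sqrt(n) with the n-1 denominator; undefined (None) for a
    group of size 1.
    """
    w, b = np.asarray(group_white, float), np.asarray(group_black, float)
    if len(w) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")

    def se(x: np.ndarray) -> float | None:
        if len(x) < 2:
            log.warning("group of size 1: SE undefined")
            return None
        return float(x.std(ddof=1) / math.sqrt(len(x)))

    mw, mb = float(w.mean()), float(b.mean())
    return PigmentSummary(mw, mb, se(w), se(b), mw / mb)


def write_trait_placement(path: str | Path, placement: TraitPlacement) -> None:
    df = placement.counts.rename("discordant").to_frame()
    df["cosegregating"] = df.index.isin(placement.cosegregating)
    df.to_csv(path, sep="\t")


def write_concordance(path: str | Path, table: ConcordanceTable) -> None:
    with open(path, "w") as fh:
        table.table.to_csv(fh, sep="\t")
        fh.write("\n")
        summary = pd.DataFrame(
            {"discordant": table.discordant, "completely_linked": table.completely_linked}
        )
        summary.to_csv(fh, sep="\t")
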