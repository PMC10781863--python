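"""Two-point F2 linkage mapping.

Recombination fractions between co-dominant loci with known phase
(parents homozygous AA x BB) are estimated by EM over the nine observable
F2 genotype classes; the double heterozygote mixes the two phases and is
the only ambiguous class.  Loci are grouped by single-linkage transitive
closure over (LOD, rf) thresholds, ordered within groups by minimum sum
of adjacent recombination fractions (greedy nearest-neighbour + 2-opt),
and spaced in centimorgans with the Kosambi (default) or Haldane mapping
function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .markers import MISSING, GenotypeMatrix

EM_TOL = 1e-8
EM_MAX_ITER = 200
EM_INIT = 0.25

_CODE = {"AA": 2, "AB": 1, "BB": 0, MISSING: -1}

# 16 gamete-pair combos: (i, j, R) with i/j = A-allele counts at the two
# loci and R = number of recombinant gametes; combo prob = (1-r)^(2-R) r^R / 4.
_COMBOS: list[tuple[int, int, int]] = []
for _g1 in (("A", "A", 0), ("B", "B", 0), ("A", "B", 1), ("B", "A", 1)):
    for _g2 in (("A", "A", 0), ("B", "B", 0), ("A", "B", 1), ("B", "A", 1)):
        _COMBOS.append(
            (
                (_g1[0] == "A") + (_g2[0] == "A"),
                (_g1[1] == "A") + (_g2[1] == "A"),
                _g1[2] + _g2[2],
            )
        )


@dataclass(frozen=True)
class RFEstimate:
    locus_i: str
    locus_j: str
    rf: float  # in [0, 0.5]; NaN when undefined
    lod: float
    n_informative: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rf)


@dataclass
class LinkageGroup:
    group_id: str
    loci: list[str]
    positions: np.ndarray  # cumulative cM, starts at 0, non-decreasing
    mapping_function: str

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.loci)


@dataclass
class MapSummary:
    """Per-group marker counts, lengths and mean intervals, plus totals.

    The mean interval is map length / marker count (exact internally;
    round for display).
    """

    table: pd.DataFrame

    def display(self) -> pd.DataFrame:
        out = self.table.copy()
        out["length_cm"] = out["length_cm"].round(1)
        out["mean_interval_cm"] = out["mean_interval_cm"].round(1)
        return out


def encode_calls(calls) -> np.ndarray:
    """Genotype strings -> A-allele counts (2/1/0; -1 = missing)."""
    arr = np.asarray(calls)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for s, v in _CODE.items():
        out[arr == s] = v
    return out


def _class_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    ok = (gi >= 0) & (gj >= 0)
    return np.bincount(3 * gi[ok] + gj[ok], minlength=9).astype(float)


def _class_probs(r: float) -> np.ndarray:
    p = np.zeros(9)
    for i, j, R in _COMBOS:
        p[3 * i + j] += (1 - r) ** (2 - R) * r**R / 4.0
    return p


def _expected_recombinants(r: float) -> np.ndarray:
    """E[recombinant gametes | class] at rf r (classes with prob 0 get 0)."""
    num = np.zeros(9)
    den = np.zeros(9)
    for i, j, R in _COMBOS:
        w = (1 - r) ** (2 - R) * r**R / 4.0
        num[3 * i + j] += R * w
        den[3 * i + j] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(den > 0, num / den, 0.0)
    return e


def estimate_rf(calls_i, calls_j, locus_i: str = "i", locus_j: str = "j") -> RFEstimate:
    """Maximum-likelihood two-point rf and LOD for one locus pair.

    Pairs with a missing call at either locus are excluded pairwise; fewer
    than two informative individuals gives an undefined (NaN) estimate.
    """
    gi, gj = encode_calls(calls_i), encode_calls(calls_j)
    n_inf = int(_class_counts(gi, gj).sum())
    r, lod = _estimate_from_codes(gi, gj)
    return RFEstimate(locus_i, locus_j, r, lod, n_inf)


def rf_matrix(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs rf and LOD matrices (symmetric, rf diagonal 0)."""
    loci = list(matrix.calls.index)
    codes = encode_calls(matrix.calls.to_numpy())
    k = len(loci)
    rf = np.zeros((k, k))
    lod = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            r, l = _estimate_from_codes(codes[a], codes[b])
            rf[a, b] = rf[b, a] = r
            lod[a, b] = lod[b, a] = l
    return (
        pd.DataFrame(rf, index=loci, columns=loci),
        pd.DataFrame(lod, index=loci, columns=loci),
    )


def _estimate_from_codes(gi: np.ndarray, gj: np.ndarray) -> tuple[float, float]:
    n = _class_counts(gi, gj)
    total = n.sum()
    if total < 2:
        return float("nan"), float("nan")
    r = EM_INIT
    for _ in range(EM_MAX_ITER):
        r_new = float(np.dot(n, _expected_recombinants(r)) / (2 * total))
        if abs(r_new - r) < EM_TOL:
            r = r_new
            break
        r = r_new
    r = min(max(r, 0.0), 0.5)
    p_hat, p_null = _class_probs(r), _class_probs(0.5)
    obs = n > 0
    lod = float(np.dot(n[obs], np.log10(p_hat[obs] / p_null[obs])))
    return r, max(lod, 0.0)


def kosambi(r: float) -> float:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = min(max(r, 0.0), 0.499999)
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def haldane(r: float) -> float:
    """Haldane map distance in cM: d = -50 ln(1-2r)."""
    r = min(max(r, 0.0), 0.499999)
    return -50.0 * math.log(1 - 2 * r)


MAP_FUNCTIONS = {"kosambi": kosambi, "haldane": haldane}


def group_loci(
    rf: pd.DataFrame,
    lod: pd.DataFrame,
    lod_min: float = 4.0,
    rf_max: float = 0.35,
    loci: pd.DataFrame | None = None,
) -> list[list[str]]:
    """Single-linkage grouping over edges with lod >= lod_min and rf <= rf_max.

    Groups are numbered deterministically by descending marker count, then
    by smallest reference coordinate (when ``loci`` metadata is given) or
    smallest locus id.
    """
    g = nx.Graph()
    ids = list(rf.index)
    g.add_nodes_from(ids)
    arr_rf, arr_lod = rf.to_numpy(), lod.to_numpy()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            r, l = arr_rf[a, b], arr_lod[a, b]
            if not math.isnan(r) and l >= lod_min and r <= rf_max:
                g.add_edge(ids[a], ids[b])

    def anchor(members: list[str]):
        if loci is not None:
            return min((loci.at[m, "chrom"], loci.at[m, "pos"]) for m in members)
        return min(members)

    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), anchor(c)))
    return comps


def _sarf(order: list[int], rf: np.ndarray) -> float:
    return float(sum(rf[a, b] for a, b in zip(order, order[1:])))


def _greedy_path(rf: np.ndarray, tie: list) -> list[int]:
    k = rf.shape[0]
    if k == 1:
        return [0]
    pairs = [(rf[a, b], tie[a], tie[b], a, b) for a in range(k) for b in range(a + 1, k)]
    _, _, _, a, b = min(pairs)
    path = [a, b]
    used = {a, b}
    while len(path) < k:
        cands = []
        for end, pos in ((path[0], 0), (path[-1], len(path))):
            for c in range(k):
                if c not in used:
                    cands.append((rf[end, c], tie[c], pos, c))
        _, _, pos, c = min(cands)
        path.insert(0 if pos == 0 else len(path), c)
        used.add(c)
    return path


def _two_opt(order: list[int], rf: np.ndarray, max_passes: int = 50) -> list[int]:
    k = len(order)
    for _ in range(max_passes):
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                if _sarf(cand, rf) < _sarf(order, rf) - 1e-12:
                    order = cand
                    improved = True
        if not improved:
            break
    return order


def order_and_space(
    group: Sequence[str],
    rf: pd.DataFrame,
    map_function: str = "kosambi",
    group_id: str = "LG1",
    loci: pd.DataFrame | None = None,
) -> LinkageGroup:
    """Order one group by minimum SARF and assign cumulative cM positions.

    Greedy nearest-neighbour construction refined by 2-opt; deterministic
    tie-break by reference coordinate (or locus id).  The orientation is
    canonicalised so the first locus's tie-break key is the smaller of the
    two ends.
    """
    fn = MAP_FUNCTIONS[map_function]
    ids = list(group)
    if len(ids) == 1:
        return LinkageGroup(group_id, ids, np.zeros(1), map_function)
    sub = rf.loc[ids, ids].to_numpy()
    if loci is not None:
        tie = [(loci.at[m, "chrom"], int(loci.at[m, "pos"])) for m in ids]
    else:
        tie = ids
    order = _two_opt(_greedy_path(sub, tie), sub)
    if tie[order[-1]] < tie[order[0]]:
        order = order[::-1]
    dists = [fn(sub[a, b]) for a, b in zip(order, order[1:])]
    positions = np.concatenate([[0.0], np.cumsum(dists)])
    return LinkageGroup(group_id, [ids[i] for i in order], positions, map_function)


def build_linkage_groups(
    matrix: GenotypeMatrix,
    lod_min: float = 4.0,
    rf_max: float = 0.35,
    map_function: str = "kosambi",
) -> tuple[list[LinkageGroup], pd.DataFrame, pd.DataFrame]:
    """Group and order a full genotype matrix; returns (groups, rf, lod)."""
    rf, lod = rf_matrix(matrix)
    comps = group_loci(rf, lod, lod_min, rf_max, matrix.loci)
    groups = [
        order_and_space(c, rf, map_function, f"LG{i + 1}", matrix.loci)
        for i, c in enumerate(comps)
    ]
    return groups, rf, lod


def summarize_map(groups: Sequence[LinkageGroup]) -> MapSummary:
    """Per-group and total marker counts, lengths, and mean intervals."""
    rows = []
    for g in groups:
        n = g.n_markers
        length = g.length_cm
        rows.append((g.group_id, n, length, length / n if n else 0.0))
    total_n = sum(r[1] for r in rows)
    total_len = sum(r[2] for r in rows)
    rows.append(("Total", total_n, total_len, total_len / total_n if total_n else 0.0))
    return MapSummary(
        pd.DataFrame(rows, columns=["group", "n_markers", "length_cm", "mean_interval_cm"])
    )


def write_map(path: str | Path, groups: Sequence[LinkageGroup],
              loci: pd.DataFrame | None = None) -> None:
    rows = []
    for g in groups:
        for i, (locus, cm) in enumerate(zip(g.loci, g.positions)):
            chrom = loci.at[locus, "chrom"] if loci is not None else ""
            pos = loci.at[locus, "pos"] if loci is not None else ""
            rows.append((locus, g.group_id, i, round(float(cm), 3), chrom, pos))
    pd.DataFrame(
        rows, columns=["locus", "group", "order", "cM", "chrom", "ref_pos"]
    ).to_csv(path, sep="\t", index=False)
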