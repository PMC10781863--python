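"""End-to-end orchestration: simulate -> tags -> genotype -> map -> trait
-> caps -> consequence.

Each stage reads its inputs from, and writes its outputs to, one run
directory, so stages can be re-run standalone; ``run_all`` executes them
in order and writes a manifest with a content hash per output file.
Re-running with the same configuration reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import candidate, linkmap, markers, radtags, simdata, traitmap
from .simdata import SimConfig, rng_for

log = logging.getLogger(__name__)

STAGES = ("simulate", "tags", "genotype", "map", "trait", "caps", "consequence")


@dataclass
class RunConfig:
    """Pipeline configuration: embedded simulation config + stage parameters."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_count: int = radtags.DEFAULT_MIN_COUNT
    presence_min: int = 1
    max_missing: float = 0.0
    max_edit: int = 2
    lod_min: float = 4.0
    rf_max: float = 0.35
    map_function: str = "kosambi"
    collapse: bool = True
    caps_window: int = 50
    genome_version: str = "v1"
    write_rf_matrix: bool = False

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _ref_to_hap_offset(hap: simdata.ParentHaplotype, chrom: str, pos: int) -> int:
    """Coordinate shift between reference and haplotype at a reference position."""
    return sum(
        len(v.alt_allele) - len(v.ref_allele)
        for v in hap.variants_on(chrom)
        if v.pos + len(v.ref_allele) - 1 < pos
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(rc: RunConfig, out: Path) -> None:
    cfg = rc.sim
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    ref, hap_a, hap_b, causal = simdata.build_parent_genomes(cfg, sim_dir)
    simdata.write_config(sim_dir / "config.json", cfg)

    seqs_a = dict(simdata.haplotype_sequences(ref, hap_a))
    seqs_b = dict(simdata.haplotype_sequences(ref, hap_b))
    window = (cfg.size_min, cfg.size_max)
    for pid, seqs in (("parentA", seqs_a), ("parentB", seqs_b)):
        frags = simdata.digest_double(list(seqs.items()), cfg.enzyme_a, cfg.enzyme_b, window)
        n = simdata.simulate_library(
            frags, seqs, cfg, rng_for(cfg.seed, f"lib:{pid}"), pid,
            sim_dir / f"{pid}_R1.fastq", sim_dir / f"{pid}_R2.fastq",
        )
        log.info("parent %s: %d retained fragments, %d read pairs", pid, len(frags), n)

    pop = simdata.simulate_f2_population(ref, causal, cfg)
    simdata.write_phenotypes(sim_dir / "phenotypes.tsv", pop)
    xo_rows = []
    f2_dir = sim_dir / "f2"
    f2_dir.mkdir(exist_ok=True)
    for ind in pop:
        pairs_all = []
        for gi, gamete in enumerate(ind.gametes):
            seqs = simdata.gamete_sequences(gamete, ref, hap_a, hap_b)
            frags = simdata.digest_double(
                list(seqs.items()), cfg.enzyme_a, cfg.enzyme_b, window
            )
            rng = rng_for(cfg.seed, f"lib:{ind.id}:g{gi}")
            pairs_all.append(
                list(simdata.simulate_read_pairs(frags, seqs, cfg, rng, f"{ind.id}:g{gi}"))
            )
            for chrom in seqs:
                xo_rows.append(
                    (ind.id, gi, chrom, gamete.start_parent[chrom],
                     ",".join(map(str, gamete.breakpoints[chrom].tolist())))
                )
        simdata.write_fastq_pair(
            (p for pairs in pairs_all for p in pairs),
            f2_dir / f"{ind.id}_R1.fastq", f2_dir / f"{ind.id}_R2.fastq",
        )
    pd.DataFrame(
        xo_rows, columns=["individual_id", "gamete", "chrom", "start_parent", "breakpoints"]
    ).to_csv(sim_dir / "crossovers.tsv", sep="\t", index=False)

    sites = sorted(
        (v.chrom, v.pos)
        for hap in (hap_a, hap_b)
        for v in hap.variants_on(causal.variant.chrom)
        if v.pos != causal.variant.pos
    )
    sites.sort(key=lambda s: abs(s[1] - causal.variant.pos))
    panel = simdata.simulate_cultivar_panel(cfg, causal, extra_sites=sorted(sites[:4]))
    panel.to_csv(sim_dir / "panel.tsv", sep="\t")

    v, g = causal.variant, causal.gene
    (sim_dir / "causal.json").write_text(json.dumps({
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref_allele, "alt": v.alt_allele,
        "gene_id": g.id, "strand": g.strand,
        "cds_start": g.cds_start, "cds_end": g.cds_end,
        "recessive_phenotype": causal.recessive_phenotype,
        "dominant_phenotype": causal.dominant_phenotype,
        "region_start": max(1, g.cds_start - 60),
        "region_end": g.cds_end + 420,
    }, indent=2) + "\n")


def stage_tags(rc: RunConfig, out: Path) -> None:
    cfg = rc.sim
    sim_dir, tag_dir = out / "sim", out / "tags"
    tag_dir.mkdir(parents=True, exist_ok=True)
    sets = {}
    for pid in ("parentA", "parentB"):
        ts = radtags.extract_tags(
            (sim_dir / f"{pid}_R1.fastq", sim_dir / f"{pid}_R2.fastq"),
            tag_length=cfg.read_length, min_count=rc.min_count, sample_id=pid,
        )
        radtags.write_tagset(tag_dir / f"{pid}_tags.tsv", ts)
        sets[pid] = ts
    part = radtags.partition_tags(sets["parentA"], sets["parentB"])
    radtags.write_partition(tag_dir / "partition.tsv", part)
    log.info(
        "tags: A=%d B=%d unique_a=%d unique_b=%d shared=%d",
        len(sets["parentA"]), len(sets["parentB"]),
        len(part.unique_a), len(part.unique_b), len(part.shared),
    )


def stage_genotype(rc: RunConfig, out: Path) -> None:
    cfg = rc.sim
    sim_dir, tag_dir, geno_dir = out / "sim", out / "tags", out / "genotype"
    geno_dir.mkdir(parents=True, exist_ok=True)
    ref = _read_fasta(sim_dir / "reference.fa")
    part = pd.read_csv(tag_dir / "partition.tsv", sep="\t")
    unique = {
        cls: part.loc[part["class"] == cls, "tag"].tolist()
        for cls in ("unique_a", "unique_b")
    }
    placed = {
        cls: [
            p for t in tags
            if (p := markers.place_tag(t, ref, max_edit=rc.max_edit)) is not None
        ]
        for cls, tags in unique.items()
    }
    mks = markers.pair_biallelic_tags(placed["unique_a"], placed["unique_b"])
    markers.write_markers(geno_dir / "markers.tsv", mks)
    log.info("placed %d/%d A and %d/%d B unique tags; %d biallelic markers",
             len(placed["unique_a"]), len(unique["unique_a"]),
             len(placed["unique_b"]), len(unique["unique_b"]), len(mks))

    pheno = pd.read_csv(sim_dir / "phenotypes.tsv", sep="\t").set_index("individual_id")[
        "phenotype"
    ]
    tagsets = {
        ind: radtags.extract_tags(
            (sim_dir / "f2" / f"{ind}_R1.fastq", sim_dir / "f2" / f"{ind}_R2.fastq"),
            tag_length=cfg.read_length, min_count=rc.min_count, sample_id=ind,
        )
        for ind in pheno.index
    }
    matrix = markers.genotype_population(tagsets, mks, rc.presence_min, pheno.to_dict())
    markers.write_genotype_matrix(geno_dir / "genotypes_raw.tsv", matrix)
    if rc.collapse:
        matrix = markers.collapse_cosegregating(matrix)
        pd.DataFrame(
            [(rep, m) for rep, ms in matrix.collapse_members.items() for m in ms],
            columns=["representative", "member"],
        ).to_csv(geno_dir / "collapse_members.tsv", sep="\t", index=False)
    matrix = markers.filter_missing(matrix, rc.max_missing)
    markers.write_genotype_matrix(geno_dir / "genotypes.tsv", matrix)
    log.info("genotype matrix: %d loci x %d individuals", matrix.n_loci,
             len(matrix.individuals))


def _load_matrix(rc: RunConfig, out: Path) -> markers.GenotypeMatrix:
    pheno = pd.read_csv(out / "sim" / "phenotypes.tsv", sep="\t").set_index(
        "individual_id"
    )["phenotype"]
    m = markers.read_genotype_matrix(out / "genotype" / "genotypes.tsv")
    return markers.GenotypeMatrix(m.calls, m.loci, pheno.reindex(m.calls.columns))


def stage_map(rc: RunConfig, out: Path) -> None:
    map_dir = out / "map"
    map_dir.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(rc, out)
    groups, rf, lod = linkmap.build_linkage_groups(
        matrix, rc.lod_min, rc.rf_max, rc.map_function
    )
    linkmap.write_map(map_dir / "map.tsv", groups, matrix.loci)
    summary = linkmap.summarize_map(groups)
    summary.display().to_csv(map_dir / "map_summary.tsv", sep="\t", index=False)
    if rc.write_rf_matrix:
        rf.round(5).to_csv(map_dir / "rf.tsv", sep="\t")
        lod.round(3).to_csv(map_dir / "lod.tsv", sep="\t")
    log.info("%d linkage groups, total %.1f cM",
             len(groups), summary.table["length_cm"].iloc[-1])


def _load_groups(out: Path) -> list[linkmap.LinkageGroup]:
    df = pd.read_csv(out / "map" / "map.tsv", sep="\t")
    groups = []
    for gid, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("order")
        groups.append(
            linkmap.LinkageGroup(gid, sub["locus"].tolist(), sub["cM"].to_numpy(), "")
        )
    return groups


def stage_trait(rc: RunConfig, out: Path) -> None:
    trait_dir = out / "trait"
    trait_dir.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(rc, out)
    causal = json.loads((out / "sim" / "causal.json").read_text())
    counts = matrix.phenotype.value_counts()
    dominant = causal["dominant_phenotype"]
    observed = [int(counts.get(dominant, 0)),
                int(counts.sum() - counts.get(dominant, 0))]
    seg = traitmap.segregation_chi2(observed, [3, 1])
    (trait_dir / "segregation.json").write_text(json.dumps({
        "observed": seg.observed, "expected": seg.expected,
        "chi2": seg.chi2, "df": seg.df, "p_value": seg.p_value,
    }, indent=2) + "\n")
    placement = traitmap.map_trait_locus(matrix, "A", _load_groups(out),
                                     causal["recessive_phenotype"])
    traitmap.write_trait_placement(trait_dir / "trait_placement.tsv", placement)
    (trait_dir / "trait.json").write_text(json.dumps({
        "best_locus": placement.best_locus,
        "cosegregating": placement.cosegregating,
        "flanking": list(placement.flanking),
        "segregation_p": seg.p_value,
    }, indent=2) + "\n")

    panel = pd.read_csv(out / "sim" / "panel.tsv", sep="\t", index_col=0)
    conc = traitmap.panel_concordance(
        panel.drop(columns="phenotype"), panel["phenotype"], "A",
        causal["recessive_phenotype"],
    )
    traitmap.write_concordance(trait_dir / "panel_concordance.tsv", conc)
    log.info("trait: best locus %s (%d co-segregating), flanks %s",
             placement.best_locus, len(placement.cosegregating), placement.flanking)


def stage_caps(rc: RunConfig, out: Path) -> None:
    caps_dir = out / "caps"
    caps_dir.mkdir(parents=True, exist_ok=True)
    causal = json.loads((out / "sim" / "causal.json").read_text())
    truth = pd.read_csv(out / "sim" / "variants_truth.tsv", sep="\t")
    chrom = causal["chrom"]
    alleles = {}
    for pid in ("parentA", "parentB"):
        hap = simdata.ParentHaplotype(pid, [
            simdata.Variant(r.chrom, int(r.pos), str(r.ref), str(r.alt), str(r.vtype))
            for r in truth[truth.parent == pid].itertuples()
        ])
        seq = dict(_read_fasta(out / "sim" / f"{pid}.fa"))[chrom]
        shift = _ref_to_hap_offset(hap, chrom, causal["region_start"])
        alleles[pid] = seq[causal["region_start"] - 1 + shift : causal["region_end"] + shift]

    lg = "LG1"
    map_path = out / "map" / "map.tsv"
    if map_path.exists():
        df = pd.read_csv(map_path, sep="\t")
        on_chrom = df[df["chrom"] == chrom]
        if len(on_chrom):
            near = on_chrom.iloc[(on_chrom["ref_pos"] - causal["pos"]).abs().argsort()]
            lg = str(near["group"].iloc[0])

    def namer(pos_a: int, enz: str) -> str:
        return candidate.format_marker_name(
            lg, rc.genome_version, causal["region_start"] + pos_a - 1, enz
        )

    cands = candidate.find_caps_markers(
        alleles["parentA"], alleles["parentB"], window=rc.caps_window, namer=namer
    )
    pd.DataFrame(
        [
            (c.marker_name, c.enzyme, causal["region_start"] + c.position - 1,
             ",".join(map(str, c.fragment_lengths_a)),
             ",".join(map(str, c.fragment_lengths_b)))
            for c in cands
        ],
        columns=["marker_name", "enzyme", "ref_pos", "fragments_allele_a",
                 "fragments_allele_b"],
    ).to_csv(caps_dir / "caps_candidates.tsv", sep="\t", index=False)
    log.info("caps: %d candidate(s): %s", len(cands), [c.marker_name for c in cands])


def stage_consequence(rc: RunConfig, out: Path) -> None:
    cons_dir = out / "consequence"
    cons_dir.mkdir(parents=True, exist_ok=True)
    causal = json.loads((out / "sim" / "causal.json").read_text())
    ref = dict(_read_fasta(out / "sim" / "reference.fa"))
    chrom_seq = ref[causal["chrom"]]
    cds = candidate.CdsModel(
        chrom_seq[causal["cds_start"] - 1 : causal["cds_end"]],
        chrom_seq[causal["cds_end"] : causal["cds_end"] + 300],
    )
    cds_pos = causal["pos"] - causal["cds_start"] + 1
    cons = candidate.classify_coding_variant(cds, cds_pos, causal["ref"], causal["alt"])
    (cons_dir / "consequence.json").write_text(json.dumps({
        "gene_id": causal["gene_id"], "kind": cons.kind,
        "extension_nt": cons.extension_nt, "extension_aa": cons.extension_aa,
        "peptide": cons.peptide, "notes": cons.notes,
    }, indent=2) + "\n")
    log.info("consequence: %s (+%d nt / +%d aa)", cons.kind, cons.extension_nt,
             cons.extension_aa)


_STAGE_FN = {
    "simulate": stage_simulate,
    "tags": stage_tags,
    "genotype": stage_genotype,
    "map": stage_map,
    "trait": stage_trait,
    "caps": stage_caps,
    "consequence": stage_consequence,
}


def run_stage(name: str, rc: RunConfig, out: str | Path) -> None:
    _STAGE_FN[name](rc, Path(out))


def run_all(rc: RunConfig, out: str | Path, seed: int | None = None) -> dict:
    """Run every stage in order and write a hashed run manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        rc.sim = simdata.SimConfig.from_dict({**rc.sim.to_dict(), "seed": int(seed)})
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ddradmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings = {}
    try:
        for name in STAGES:
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                _STAGE_FN[name](rc, out)
            except Exception:
                log.exception("stage %s failed", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s: done in %.2fs", name, timings[name])
    finally:
        root.removeHandler(handler)
        handler.close()
    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            files[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config": rc.to_dict(), "stage_seconds": timings, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
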