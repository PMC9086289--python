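"""Deterministic synthetic fixtures: toy genome and annotation with a
controllable gene-density gradient, desert/sweep region sets with known
gene membership, and structure x stage RPKM matrices with planted
effects.

Every generator output is a pure function of its config; a JSON-able
truth manifest records planted memberships, shifts and trajectories so
downstream modules can be scored without re-derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (
    DEFAULT_STRUCTURES,
    ExpressionMatrix,
    SampleMetadata,
    STAGE_ORDER,
)
from .regions import (
    Annotation,
    GeneRecord,
    GenomicRegion,
    RegionSet,
    write_annotation,
    write_chrom_sizes,
    write_regions,
)

__all__ = [
    "PlantedShift",
    "PlantedTrajectory",
    "SyntheticConfig",
    "Fixture",
    "make_genome_and_annotation",
    "make_region_fixture",
    "make_expression",
    "make_full_fixture",
    "default_config",
    "null_config",
    "write_fixture",
]

#: Postnatal stages where the default planted divergence acts.
DEFAULT_SHIFT_STAGES = ["Birth-Infancy", "Childhood", "Adolescence", "Adulthood"]


@dataclass
class PlantedShift:
    """Additive log2 shift for a gene set in one structure at given stages,
    expressed in units of the within-group (noise) SD."""

    genes: list[str]
    structure: str
    stages: list[str]
    shift_sd: float = 2.0


@dataclass
class PlantedTrajectory:
    """Piecewise-linear mean trajectory for one gene in one structure.

    ``slopes`` has one more entry than ``breakpoints``; times are stage
    ranks (0..n_stages-1)."""

    gene: str
    structure: str
    breakpoints: list[float]
    slopes: list[float]
    base: float = 4.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 60_000_000,
            "chr2": 55_000_000,
            "chr3": 50_000_000,
            "chr4": 45_000_000,
        }
    )
    n_genes: int = 300
    density_bias: float = 1.5  # Beta(1, bias) start positions: high-left
    gene_length_range: tuple[int, int] = (20_000, 100_000)
    protein_coding_fraction: float = 0.8
    structures: list[str] = field(default_factory=lambda: list(DEFAULT_STRUCTURES))
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    samples_per_cell: int = 3
    baseline_log2: float = 5.0
    structure_effects: dict[str, float] = field(default_factory=dict)
    stage_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    planted_shifts: list[PlantedShift] = field(default_factory=list)
    planted_trajectories: list[PlantedTrajectory] = field(default_factory=list)
    n_deserts: int = 4
    desert_length: int = 15_000_000
    sweep_inside_length: int = 8_000_000
    n_sweeps_outside: int = 3
    sweep_outside_length: int = 3_000_000

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.samples_per_cell <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for s in self.planted_shifts:
            if not np.isfinite(s.shift_sd):
                raise ValueError("planted shift must be finite")


@dataclass
class Fixture:
    """Everything the pipeline reads, plus the truth manifest."""

    chrom_sizes: dict[str, int]
    annotation: Annotation
    deserts: RegionSet
    sweeps: RegionSet
    matrix: ExpressionMatrix  # raw RPKM
    metadata: SampleMetadata
    manifest: dict


def make_genome_and_annotation(
    cfg: SyntheticConfig,
) -> tuple[dict[str, int], Annotation]:
    """Place non-overlapping genes with density decreasing along each
    chromosome (Beta-distributed starts), mixing biotypes."""
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_lengths)
    total_len = sum(cfg.chrom_lengths.values())
    # allocate gene counts proportional to length, remainder to the largest
    alloc = {
        c: int(cfg.n_genes * cfg.chrom_lengths[c] / total_len) for c in chroms
    }
    remainder = cfg.n_genes - sum(alloc.values())
    for c in sorted(chroms, key=lambda c: -cfg.chrom_lengths[c])[:remainder]:
        alloc[c] += 1

    genes: list[GeneRecord] = []
    gi = 0
    lo_len, hi_len = cfg.gene_length_range
    for chrom in chroms:
        n = alloc[chrom]
        clen = cfg.chrom_lengths[chrom]
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 200 * n + 1000:
                raise ValueError(
                    f"cannot place {n} non-overlapping genes on {chrom}"
                )
            glen = int(rng.integers(lo_len, hi_len + 1))
            start = int(rng.beta(1.0, cfg.density_bias) * (clen - glen))
            end = start + glen
            if any(start < e and s < end for s, e in placed):
                continue
            placed.append((start, end))
        placed.sort()
        for start, end in placed:
            gi += 1
            biotype = (
                "protein_coding"
                if rng.random() < cfg.protein_coding_fraction
                else "lncRNA"
            )
            genes.append(
                GeneRecord(
                    gene_id=f"G{gi:05d}",
                    symbol=f"SYN{gi:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    biotype=biotype,
                )
            )
    return dict(cfg.chrom_lengths), Annotation(genes)


def make_region_fixture(
    cfg: SyntheticConfig, annotation: Annotation
) -> tuple[RegionSet, RegionSet, dict]:
    """Four desert regions plus sweeps with a known subset inside deserts.

    The manifest records contained protein-coding gene ids for deserts and
    for the desert-sweep intersection.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    chroms = list(cfg.chrom_lengths)
    genome_len = sum(cfg.chrom_lengths.values())
    n_pc = sum(1 for g in annotation if g.biotype == "protein_coding")
    # deserts must stay at-or-below average gene density, otherwise the
    # >=count constraint of the matched sampler becomes unsatisfiable
    expected = (
        n_pc * cfg.n_deserts * cfg.desert_length / genome_len
    )
    for _redraw in range(200):
        deserts: list[GenomicRegion] = []
        for i in range(cfg.n_deserts):
            chrom = chroms[i % len(chroms)]
            clen = cfg.chrom_lengths[chrom]
            dlen = cfg.desert_length
            if dlen >= clen:
                raise ValueError(f"desert longer than {chrom}")
            taken = [r for r in deserts if r.chrom == chrom]
            for _ in range(1000):
                start = int(rng.integers(0, clen - dlen))
                end = start + dlen
                if not any(start < r.end and r.start < end for r in taken):
                    break
            else:
                raise ValueError(f"cannot place desert {i} on {chrom}")
            deserts.append(GenomicRegion(chrom, start, end, f"desert{i + 1}"))
        desert_set = RegionSet("deserts", deserts)
        count = sum(
            annotation.count_contained(r, "protein_coding") for r in deserts
        )
        if count <= expected:
            break
    else:
        raise ValueError("cannot place gene-sparse deserts")

    sweeps: list[GenomicRegion] = []
    # one sweep inside each desert, centered
    for i, d in enumerate(deserts):
        slen = min(cfg.sweep_inside_length, d.length // 2)
        mid = (d.start + d.end) // 2
        sweeps.append(
            GenomicRegion(
                d.chrom, mid - slen // 2, mid - slen // 2 + slen,
                f"sweep_in{i + 1}",
            )
        )
    # sweeps outside deserts
    placed_out = 0
    guard = 0
    while placed_out < cfg.n_sweeps_outside:
        guard += 1
        if guard > 10_000:
            raise ValueError("cannot place outside sweeps")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = cfg.chrom_lengths[chrom]
        slen = cfg.sweep_outside_length
        start = int(rng.integers(0, clen - slen))
        end = start + slen
        blockers = [r for r in deserts + sweeps if r.chrom == chrom]
        if any(start < r.end and r.start < end for r in blockers):
            continue
        placed_out += 1
        sweeps.append(GenomicRegion(chrom, start, end, f"sweep_out{placed_out}"))
    sweep_set = RegionSet("sweeps", sweeps)

    from .regions import genes_in_regions, intersect_region_sets

    desert_genes = genes_in_regions(annotation, desert_set, "protein_coding")
    inter = intersect_region_sets(desert_set, sweep_set)
    inter_genes = genes_in_regions(annotation, inter, "protein_coding")
    manifest = {
        "desert_genes": [g.gene_id for g in desert_genes],
        "desert_sweep_genes": [g.gene_id for g in inter_genes],
        "n_desert_genes": len(desert_genes),
        "n_desert_sweep_genes": len(inter_genes),
    }
    return desert_set, sweep_set, manifest


def _trajectory_mean(traj: PlantedTrajectory, t: float) -> float:
    val = traj.base
    prev = 0.0
    for bp, slope in zip([*traj.breakpoints, np.inf], traj.slopes):
        seg_end = min(t, bp)
        if seg_end > prev:
            val += slope * (seg_end - prev)
        if t <= bp:
            break
        prev = bp
    return val


def make_expression(
    cfg: SyntheticConfig, annotation: Annotation
) -> tuple[ExpressionMatrix, SampleMetadata, dict]:
    """RPKM matrix ``2**(log2 mean + noise) - 1`` (floored at 0) with
    structure/stage effects, planted shifts and planted trajectories."""
    rng = np.random.default_rng(cfg.seed + 2)
    gene_ids = [g.gene_id for g in annotation]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sample_ids, structures_col, stages_col, donors = [], [], [], []
    for structure in cfg.structures:
        for stage in cfg.stages:
            for rep in range(cfg.samples_per_cell):
                sample_ids.append(f"{structure}.{stage}.{rep + 1}")
                structures_col.append(structure)
                stages_col.append(stage)
                donors.append(f"donor{rep + 1}")
    n_g, n_s = len(gene_ids), len(sample_ids)
    stage_rank = {s: i for i, s in enumerate(cfg.stages)}

    log2_mean = np.full((n_g, n_s), cfg.baseline_log2, dtype=float)
    for j, (st, sg) in enumerate(zip(structures_col, stages_col)):
        log2_mean[:, j] += cfg.structure_effects.get(st, 0.0)
        log2_mean[:, j] += cfg.stage_effects.get(sg, 0.0)
    for shift in cfg.planted_shifts:
        rows = [gene_index[g] for g in shift.genes if g in gene_index]
        delta = shift.shift_sd * cfg.noise_sd
        for j, (st, sg) in enumerate(zip(structures_col, stages_col)):
            if st == shift.structure and sg in shift.stages:
                log2_mean[np.ix_(rows, [j])] += delta
    for traj in cfg.planted_trajectories:
        if traj.gene not in gene_index:
            continue
        row = gene_index[traj.gene]
        for j, (st, sg) in enumerate(zip(structures_col, stages_col)):
            if st == traj.structure:
                log2_mean[row, j] = _trajectory_mean(traj, stage_rank[sg])

    noise = rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
    rpkm = np.maximum(0.0, 2.0 ** (log2_mean + noise) - 1.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(rpkm, index=gene_ids, columns=sample_ids), scale="rpkm"
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "structure": structures_col,
                "stage": stages_col,
                "donor": donors,
            }
        )
    )
    manifest = {
        "shifts": [asdict(s) for s in cfg.planted_shifts],
        "trajectories": [asdict(t) for t in cfg.planted_trajectories],
        "noise_sd": cfg.noise_sd,
        "baseline_log2": cfg.baseline_log2,
    }
    return matrix, meta, manifest


def default_config(seed: int = 0) -> SyntheticConfig:
    """Baseline fixture config (no planted effects yet; those are attached
    by :func:`make_full_fixture`)."""
    return SyntheticConfig(seed=seed)


def null_config(seed: int = 0) -> SyntheticConfig:
    """No planted effects, no structure/stage effects: pure noise around
    the baseline, for type-I-error calibration."""
    return SyntheticConfig(seed=seed)


def make_full_fixture(
    seed: int = 0,
    planted_structure: str | None = "CBC",
    planted_stages: list[str] | None = None,
    n_subset_genes: int = 12,
    shift_sd: float = 2.0,
    cfg: SyntheticConfig | None = None,
) -> Fixture:
    """Generate genome, regions and expression in one call.

    When ``planted_structure`` is given, a ``shift_sd``-SD shift is planted
    for that structure at ``planted_stages`` (default: the four postnatal
    stages) on ``n_subset_genes`` genes drawn from the desert-sweep
    intersection. ``planted_structure=None`` yields a null fixture.
    """
    if cfg is None:
        cfg = default_config(seed)
    chrom_sizes, annotation = make_genome_and_annotation(cfg)
    deserts, sweeps, region_manifest = make_region_fixture(cfg, annotation)
    subset = region_manifest["desert_sweep_genes"][:n_subset_genes]
    if len(subset) < n_subset_genes:
        raise ValueError(
            f"fixture yields only {len(subset)} desert-sweep genes; "
            f"{n_subset_genes} requested"
        )
    if planted_structure is not None:
        stages = planted_stages or list(DEFAULT_SHIFT_STAGES)
        cfg.planted_shifts = cfg.planted_shifts + [
            PlantedShift(
                genes=list(subset),
                structure=planted_structure,
                stages=stages,
                shift_sd=shift_sd,
            )
        ]
    matrix, meta, expr_manifest = make_expression(cfg, annotation)
    manifest = {
        **region_manifest,
        **expr_manifest,
        "subset_genes": list(subset),
        "seed": seed,
    }
    return Fixture(chrom_sizes, annotation, deserts, sweeps, matrix, meta, manifest)


def write_fixture(fx: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Emit the fixture in the plain-text formats the pipeline reads."""
    from .expression import write_matrix, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "annotation": outdir / "genes.tsv",
        "deserts": outdir / "deserts.bed",
        "sweeps": outdir / "sweeps.bed",
        "matrix": outdir / "matrix.tsv",
        "metadata": outdir / "metadata.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_chrom_sizes(fx.chrom_sizes, paths["chrom_sizes"])
    write_annotation(fx.annotation, paths["annotation"])
    write_regions(fx.deserts, paths["deserts"])
    write_regions(fx.sweeps, paths["sweeps"])
    write_matrix(fx.matrix, paths["matrix"])
    write_metadata(fx.metadata, paths["metadata"])
    with open(paths["manifest"], "w") as fh:
        json.dump(fx.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
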