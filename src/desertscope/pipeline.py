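"""End-to-end orchestration: regions -> gene subset -> log transform
(with the global-mode-only median filter) -> divergence test, plus
optional trajectory fits, from a single YAML config.

All outputs are plain text (TSV/JSON) with the config and seed embedded,
and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import divergence as dv
from . import expression as xp
from . import regions as rg
from . import trajectory as tj

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "StageError"]

MODES = ("deserts", "deserts_sweeps", "sweeps_minus_deserts", "global", "per_chromosome")


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    deserts_bed: str
    annotation: str
    matrix: str
    metadata: str
    sweeps_bed: str | None = None
    chrom_sizes: str | None = None
    mode: str = "deserts"
    alpha_divergence: float = 0.01
    alpha_pcs: float = 0.05
    r2_min: float = 0.5
    median_filter_threshold: float = 2.0
    jackstraw_perms: int = 100
    jackstraw_fraction: float = 0.1
    fallback_k: int = 2
    bonferroni_family: str = "stage"
    trajectory_structures: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("alpha_divergence", "alpha_pcs", "r2_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.mode in {"deserts_sweeps", "sweeps_minus_deserts"} and not self.sweeps_bed:
            raise ValueError(f"mode {self.mode!r} requires sweeps_bed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _select_genes(
    cfg: RunConfig,
    annotation: rg.Annotation,
    deserts: rg.RegionSet,
    sweeps: rg.RegionSet | None,
) -> list[str]:
    if cfg.mode == "deserts":
        genes = rg.genes_in_regions(annotation, deserts, "protein_coding")
    elif cfg.mode == "deserts_sweeps":
        inter = rg.intersect_region_sets(deserts, sweeps)
        genes = rg.genes_in_regions(annotation, inter, "protein_coding")
    elif cfg.mode == "sweeps_minus_deserts":
        in_sweeps = rg.genes_in_regions(annotation, sweeps, "protein_coding")
        in_deserts = {
            g.gene_id
            for g in rg.genes_in_regions(annotation, deserts, "protein_coding")
        }
        genes = [g for g in in_sweeps if g.gene_id not in in_deserts]
    else:  # global
        genes = [g for g in annotation if g.biotype == "protein_coding"]
        genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    return [g.gene_id for g in genes]


def run_full_analysis(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured analysis and write a report bundle.

    Returns the JSON summary as a dict. Partial outputs are preserved on
    failure; errors carry the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        deserts = rg.read_regions(cfg.deserts_bed, name="deserts")
        sweeps = (
            rg.read_regions(cfg.sweeps_bed, name="sweeps")
            if cfg.sweeps_bed
            else None
        )
        annotation = rg.read_annotation(cfg.annotation)
        matrix, meta = xp.read_matrix(cfg.matrix, cfg.metadata)
    except Exception as exc:
        raise StageError("load_inputs", exc) from exc
    logger.info(
        "loaded %d genes, %d x %d matrix", len(annotation),
        matrix.n_genes, matrix.n_samples,
    )

    if cfg.mode == "per_chromosome":
        return _run_per_chromosome(cfg, outdir, deserts, sweeps, annotation)

    try:
        gene_ids = _select_genes(cfg, annotation, deserts, sweeps)
        if not gene_ids:
            raise ValueError(f"mode {cfg.mode!r} selected no genes")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("gene_selection", exc) from exc
    logger.info("mode %s: %d genes selected", cfg.mode, len(gene_ids))

    try:
        logm = xp.log_transform(matrix)
        if cfg.mode == "global":
            # median filter applies to the global profile only; subsets keep
            # their outliers
            logm = xp.median_filter(logm, cfg.median_filter_threshold)
        sub = xp.subset_genes(logm, gene_ids)
    except Exception as exc:
        raise StageError("expression_prep", exc) from exc
    logger.info("matrix after prep: %d genes", sub.n_genes)

    try:
        result, pca, js, comps = dv.run_divergence(
            sub,
            meta,
            alpha=cfg.alpha_divergence,
            alpha_pcs=cfg.alpha_pcs,
            n_perm=cfg.jackstraw_perms,
            fraction=cfg.jackstraw_fraction,
            seed=cfg.seed,
            fallback_k=cfg.fallback_k,
            family=cfg.bonferroni_family,
        )
    except Exception as exc:
        raise StageError("divergence", exc) from exc

    trajectory_rows = []
    for structure in cfg.trajectory_structures:
        try:
            trajectory_rows.extend(
                _fit_structure_trajectories(sub, meta, structure, cfg.r2_min)
            )
        except Exception as exc:
            raise StageError(f"trajectory:{structure}", exc) from exc

    summary = _write_report(
        outdir, cfg, gene_ids, sub, result, comps, js, trajectory_rows
    )
    return summary


def _fit_structure_trajectories(
    m: xp.ExpressionMatrix,
    meta: xp.SampleMetadata,
    structure: str,
    r2_min: float,
) -> list[dict]:
    tab = meta.table
    stage_rank = {s: i for i, s in enumerate(xp.STAGE_ORDER)}
    samples = tab[tab["structure"] == structure]
    if samples.empty:
        raise ValueError(f"no samples for structure {structure!r}")
    times = samples["stage"].map(stage_rank).to_numpy(dtype=float)
    cols = samples["sample_id"].to_list()
    rows = []
    for gene in m.gene_ids:
        ts = tj.TimeSeries(
            times=times,
            values=m.values.loc[gene, cols].to_numpy(dtype=float),
            gene=gene,
            structure=structure,
        )
        fit = tj.fit_segmented(ts)
        passed = fit.accepted and fit.adj_r2 >= r2_min
        rows.append(
            {
                "structure": structure,
                "gene": gene,
                "k": fit.k if fit.accepted else None,
                "breakpoints": ",".join(f"{b:g}" for b in fit.breakpoints),
                "slopes": ",".join(f"{s:.6g}" for s in fit.slopes),
                "adj_r2": round(fit.adj_r2, 10) if fit.accepted else None,
                "shape": tj.classify_shape(fit) if fit.accepted else None,
                "retained": bool(passed),
                "rejection_reason": fit.rejected_reason or "",
            }
        )
    return rows


def _write_report(
    outdir: Path,
    cfg: RunConfig,
    gene_ids: list[str],
    sub: xp.ExpressionMatrix,
    result: dv.DivergenceResult,
    comps: list[int],
    js: dv.JackStrawResult,
    trajectory_rows: list[dict],
) -> dict:
    import pandas as pd

    (outdir / "genes_used.txt").write_text("\n".join(gene_ids) + "\n")
    result.pair_table.to_csv(
        outdir / "divergence_pairs.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    result.structure_table.to_csv(
        outdir / "divergence_structures.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    result.distances.to_csv(
        outdir / "distances.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if trajectory_rows:
        pd.DataFrame(trajectory_rows).to_csv(
            outdir / "trajectories.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
    flags = {
        f"{r.structure}|{r.stage}": bool(r.divergent)
        for r in result.structure_table.itertuples()
    }
    summary = {
        "config": dataclasses.asdict(cfg),
        "n_genes_selected": len(gene_ids),
        "n_genes_analyzed": sub.n_genes,
        "selected_components": list(comps),
        "jackstraw_component_p": [float(p) for p in js.component_p],
        "divergent": flags,
        "n_trajectories_retained": sum(
            1 for r in trajectory_rows if r["retained"]
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _run_per_chromosome(
    cfg: RunConfig,
    outdir: Path,
    deserts: rg.RegionSet,
    sweeps: rg.RegionSet | None,
    annotation: rg.Annotation,
) -> dict:
    """One deserts-mode sub-run per chromosome carrying a desert region."""
    chroms = deserts.chromosomes()
    sub_summaries = {}
    all_genes: list[str] = []
    for chrom in chroms:
        sub_bed = outdir / f"deserts_{chrom}.bed"
        rg.write_regions(
            rg.RegionSet(
                f"deserts_{chrom}",
                [r for r in deserts if r.chrom == chrom],
            ),
            sub_bed,
        )
        sub_cfg = dataclasses.replace(
            cfg, mode="deserts", deserts_bed=str(sub_bed)
        )
        sub_out = outdir / chrom
        summary = run_full_analysis(sub_cfg, sub_out)
        sub_summaries[chrom] = summary
        all_genes.extend(
            (sub_out / "genes_used.txt").read_text().split()
        )
    combined = {
        "config": dataclasses.asdict(cfg),
        "chromosomes": chroms,
        "n_genes_total": len(all_genes),
        "per_chromosome": sub_summaries,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(combined, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return combined
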