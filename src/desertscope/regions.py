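"""Genomic intervals, gene-to-region assignment, matched random-region
sampling, and region-level permutation testing.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Readers accept 1-based inclusive input via an explicit flag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "GeneRecord",
    "Annotation",
    "SamplerConfig",
    "PermutationResult",
    "RegionParseError",
    "InfeasibleSamplingError",
    "read_regions",
    "write_regions",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_annotation",
    "write_annotation",
    "genes_in_regions",
    "intersect_region_sets",
    "merge_regions",
    "sample_matched_regions",
    "region_permutation_test",
]

# Gene counts reported for the four large deserts; the source is internally
# inconsistent (265 in the text, 255 in a figure caption), so both are
# surfaced as named constants and neither is asserted anywhere.
DESERT_GENE_COUNT_TEXT = 265
DESERT_GENE_COUNT_FIGURE = 255


class RegionParseError(ValueError):
    """Raised for malformed region/annotation input, naming the line."""


class InfeasibleSamplingError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the constraints."""


@dataclass(frozen=True)
class GenomicRegion:
    """A labeled half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= start and end <= self.end


@dataclass
class RegionSet:
    """Named, ordered collection of :class:`GenomicRegion`."""

    name: str
    regions: list[GenomicRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regions)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def has_self_overlap(self) -> bool:
        by_chrom: dict[str, list[GenomicRegion]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    return True
        return False

    def sorted(self) -> "RegionSet":
        return RegionSet(
            self.name,
            sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)),
        )


def merge_regions(rs: RegionSet) -> RegionSet:
    """Merge overlapping/adjacent intervals. Merging is always explicit;
    no other operation silently collapses overlaps."""
    merged: list[GenomicRegion] = []
    for r in rs.sorted():
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = replace(last, end=max(last.end, r.end))
        else:
            merged.append(r)
    return RegionSet(rs.name, merged)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end must exceed start "
                f"({self.start}, {self.end})"
            )


class Annotation:
    """Gene annotation with unique ids and fast per-chromosome lookup."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end))
            self._by_chrom[chrom] = {
                "start": np.array([g.start for g in gs], dtype=np.int64),
                "end": np.array([g.end for g in gs], dtype=np.int64),
                "genes": np.array(gs, dtype=object),
            }

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def contained_in(
        self, region: GenomicRegion, biotype: str | None = None
    ) -> list[GeneRecord]:
        """Genes whose full body lies within ``region``."""
        idx = self._by_chrom.get(region.chrom)
        if idx is None:
            return []
        mask = (idx["start"] >= region.start) & (idx["end"] <= region.end)
        genes = idx["genes"][mask]
        if biotype is not None:
            genes = [g for g in genes if g.biotype == biotype]
        return list(genes)

    def overlapping(
        self, region: GenomicRegion, biotype: str | None = None
    ) -> list[GeneRecord]:
        idx = self._by_chrom.get(region.chrom)
        if idx is None:
            return []
        mask = (idx["start"] < region.end) & (idx["end"] > region.start)
        genes = idx["genes"][mask]
        if biotype is not None:
            genes = [g for g in genes if g.biotype == biotype]
        return list(genes)

    def count_contained(
        self, region: GenomicRegion, biotype: str | None = None
    ) -> int:
        if biotype is not None:
            return len(self.contained_in(region, biotype))
        idx = self._by_chrom.get(region.chrom)
        if idx is None:
            return 0
        return int(
            np.sum((idx["start"] >= region.start) & (idx["end"] <= region.end))
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_regions(
    path: str | Path,
    name: str | None = None,
    one_based: bool = False,
) -> RegionSet:
    """Read a BED (3-6 column) file into a :class:`RegionSet`.

    Parameters
    ----------
    one_based
        Treat coordinates as 1-based inclusive and convert to the internal
        0-based half-open convention.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RegionParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if one_based:
                start -= 1
            label = fields[3] if len(fields) > 3 else ""
            try:
                regions.append(GenomicRegion(chrom, start, end, label))
            except ValueError as exc:
                raise RegionParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(name or path.stem, regions)


def write_regions(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise RegionParseError(
                    f"{path}:{lineno}: expected 2 columns"
                )
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str | Path, one_based: bool = False) -> Annotation:
    """Read gene annotation from GTF (gene features only) or a 6-column TSV
    ``gene_id symbol chrom start end biotype`` (header optional)."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf_genes(path)
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":  # header row
                continue
            if len(fields) < 6:
                raise RegionParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise RegionParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if one_based:
                start -= 1
            try:
                genes.append(
                    GeneRecord(fields[0], fields[1], fields[2], start, end, fields[5])
                )
            except ValueError as exc:
                raise RegionParseError(f"{path}:{lineno}: {exc}") from exc
    return Annotation(genes)


def _read_gtf_genes(path: Path) -> Annotation:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise RegionParseError(
                    f"{path}:{lineno}: expected 9 GTF columns"
                )
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise RegionParseError(f"{path}:{lineno}: missing gene_id")
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    symbol=attrs.get("gene_name", gene_id),
                    chrom=fields[0],
                    start=int(fields[3]) - 1,  # GTF is 1-based inclusive
                    end=int(fields[4]),
                    biotype=attrs.get("gene_biotype", attrs.get("gene_type", "")),
                )
            )
    return Annotation(genes)


def write_annotation(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tbiotype\n")
        for g in ann:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.biotype}\n"
            )


# ---------------------------------------------------------------------------
# Assignment and intersection
# ---------------------------------------------------------------------------

def genes_in_regions(
    annotation: Annotation,
    regions: RegionSet,
    biotype: str | None = None,
    mode: str = "contained",
) -> list[GeneRecord]:
    """Genes assigned to a region set.

    ``mode='contained'`` (default) requires the full gene body inside some
    region; ``mode='overlap'`` accepts any overlap. Regions on chromosomes
    absent from the annotation are skipped with a warning. Result is
    deduplicated and ordered by (chrom, start).
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    if mode not in {"contained", "overlap"}:
        raise ValueError(f"unknown mode {mode!r}")
    known = set(annotation.chromosomes())
    hits: dict[str, GeneRecord] = {}
    for region in regions:
        if region.chrom not in known:
            logger.warning(
                "region %s:%d-%d on unknown chromosome; skipped",
                region.chrom, region.start, region.end,
            )
            continue
        found = (
            annotation.contained_in(region, biotype)
            if mode == "contained"
            else annotation.overlapping(region, biotype)
        )
        for g in found:
            hits[g.gene_id] = g
    return sorted(hits.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def intersect_region_sets(a: RegionSet, b: RegionSet) -> RegionSet:
    """Per-base intersection. Output regions carry both parent labels."""
    out: list[GenomicRegion] = []
    b_by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in b:
        b_by_chrom.setdefault(r.chrom, []).append(r)
    for ra in a.sorted():
        for rb in sorted(b_by_chrom.get(ra.chrom, []), key=lambda r: r.start):
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if lo < hi:
                label = "&".join(x for x in (ra.label, rb.label) if x)
                out.append(GenomicRegion(ra.chrom, lo, hi, label))
    return RegionSet(f"{a.name}&{b.name}", out)


# ---------------------------------------------------------------------------
# Matched random-region sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Constraints for length- and gene-density-matched random regions.

    Defaults mirror the published control design: 1,000 replicate sets,
    ~15 Mb regions with a 1 Mb length tolerance, and a floor of 265 total
    contained genes per replicate.
    """

    n_replicates: int = 1000
    target_length: int = 15_000_000
    length_tolerance: int = 1_000_000
    min_total_genes: int = DESERT_GENE_COUNT_TEXT
    excluded: RegionSet | None = None
    seed: int = 0
    biotype: str | None = None
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")
        if self.length_tolerance >= self.target_length:
            raise ValueError("length_tolerance must be < target_length")
        if self.min_total_genes < 0:
            raise ValueError("min_total_genes must be >= 0")


def _overlaps_any(
    chrom: str, start: int, end: int, regions: Sequence[GenomicRegion]
) -> bool:
    return any(
        r.chrom == chrom and start < r.end and r.start < end for r in regions
    )


def sample_matched_regions(
    genome: dict[str, int],
    annotation: Annotation,
    cfg: SamplerConfig,
    template: RegionSet,
) -> list[RegionSet]:
    """Draw ``cfg.n_replicates`` random region sets matched to ``template``.

    Each replicate has one region per template region with length within
    ``±cfg.length_tolerance`` of that template region's length, avoids
    ``cfg.excluded`` and the other regions of the same replicate, and holds
    at least ``cfg.min_total_genes`` contained genes in total. Rejection
    sampling; raises :class:`InfeasibleSamplingError` when an attempt cap
    is exhausted rather than relaxing any constraint.
    """
    if len(template) == 0:
        raise ValueError("template region set is empty")
    rng = np.random.default_rng(cfg.seed)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    excluded = list(cfg.excluded.regions) if cfg.excluded is not None else []
    template_lengths = [r.length for r in template]

    replicates: list[RegionSet] = []
    for rep_i in range(cfg.n_replicates):
        for _attempt in range(cfg.max_attempts):
            picked: list[GenomicRegion] = []
            ok = True
            for j, tlen in enumerate(template_lengths):
                lo = max(1, tlen - cfg.length_tolerance)
                hi = tlen + cfg.length_tolerance
                rlen = int(rng.integers(lo, hi + 1))
                eligible = np.maximum(lengths - rlen, 0)
                total = int(eligible.sum())
                if total == 0:
                    raise InfeasibleSamplingError(
                        f"no chromosome can hold a region of {rlen} bp"
                    )
                # uniform over all eligible start positions genome-wide
                pos = int(rng.integers(0, total))
                ci = int(np.searchsorted(np.cumsum(eligible), pos, side="right"))
                start = pos - int(np.cumsum(eligible)[ci - 1]) if ci else pos
                chrom = chroms[ci]
                end = start + rlen
                if _overlaps_any(chrom, start, end, excluded) or _overlaps_any(
                    chrom, start, end, picked
                ):
                    ok = False
                    break
                picked.append(
                    GenomicRegion(chrom, start, end, label=f"rand{rep_i}_{j}")
                )
            if not ok:
                continue
            n_genes = sum(
                annotation.count_contained(r, cfg.biotype) for r in picked
            )
            if n_genes >= cfg.min_total_genes:
                replicates.append(RegionSet(f"replicate_{rep_i}", picked))
                break
        else:
            raise InfeasibleSamplingError(
                f"replicate {rep_i}: constraints unsatisfied after "
                f"{cfg.max_attempts} attempts (length ±{cfg.length_tolerance}, "
                f">= {cfg.min_total_genes} genes, exclusion)"
            )
    return replicates


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    p_value: float
    null_values: np.ndarray
    observed: float
    alternative: str


def region_permutation_test(
    observed_stat: float,
    stat_fn: Callable[[RegionSet], float],
    replicates: Sequence[RegionSet],
    alternative: str = "two-sided",
) -> PermutationResult:
    """Empirical permutation p-value with the add-one correction
    ``p = (1 + #extreme) / (1 + n)``.

    ``alternative='greater'`` counts null values >= observed, ``'less'``
    counts <=, and ``'two-sided'`` doubles the smaller one-sided p (capped
    at 1).
    """
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    null = np.empty(len(replicates), dtype=float)
    for i, rep in enumerate(replicates):
        try:
            null[i] = stat_fn(rep)
        except Exception as exc:
            raise RuntimeError(f"stat_fn failed on replicate {i}: {exc}") from exc
    n = len(null)
    p_greater = (1 + int(np.sum(null >= observed_stat))) / (1 + n)
    p_less = (1 + int(np.sum(null <= observed_stat))) / (1 + n)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return PermutationResult(p, null, float(observed_stat), alternative)
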