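"""Expression-matrix I/O, log transformation, filtering, subsetting and
structure x stage summaries.

The matrix is genes x samples RPKM (or log2(RPKM+1) after transform); a
scale flag records which, and the transform refuses to run twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "STAGE_ORDER",
    "STAGE_WINDOWS",
    "NEOCORTEX_AREAS",
    "DEFAULT_STRUCTURES",
    "read_matrix",
    "write_matrix",
    "write_metadata",
    "log_transform",
    "median_filter",
    "subset_genes",
    "summarize",
    "collapse_neocortex",
]

#: Ordered developmental stages with their age windows.
STAGE_WINDOWS: list[tuple[str, str]] = [
    ("Fetal1", "12-13 PCW"),
    ("Fetal2", "16-18 PCW"),
    ("Fetal3", "19-22 PCW"),
    ("Birth-Infancy", "35-37 PCW & 0-0.3 y"),
    ("Infancy-Child", "0.5-2.5 y"),
    ("Childhood", "2.8-10.7 y"),
    ("Adolescence", "13-19 y"),
    ("Adulthood", "21-64 y"),
]

STAGE_ORDER: list[str] = [name for name, _ in STAGE_WINDOWS]

DEFAULT_STRUCTURES = ["AMY", "CBC", "HIP", "MD", "NCX", "STR"]

#: Neocortical area labels collapsed to NCX for the six-structure view.
#: User-editable: pass your own mapping to :func:`collapse_neocortex`.
NEOCORTEX_AREAS: dict[str, str] = {
    area: "NCX"
    for area in [
        "OFC", "DFC", "VFC", "MFC", "M1C", "S1C", "IPC", "A1C", "STC",
        "ITC", "V1C",
    ]
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    scale: str = "rpkm"  # "rpkm" | "log2"

    def __post_init__(self) -> None:
        if self.scale not in {"rpkm", "log2"}:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        if self.scale == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative RPKM values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleMetadata:
    """Per-sample structure / stage / donor labels."""

    table: pd.DataFrame  # columns: sample_id, structure, stage, donor

    def __post_init__(self) -> None:
        required = {"sample_id", "structure", "stage"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if "donor" not in self.table.columns:
            self.table = self.table.assign(donor="")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        unknown = set(self.table["stage"]) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(
                f"stages not in the known stage windows: {sorted(unknown)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def structures(self) -> list[str]:
        return sorted(self.table["structure"].unique())

    def stages(self) -> list[str]:
        present = set(self.table["stage"])
        return [s for s in STAGE_ORDER if s in present]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = set(sample_ids)
        return SampleMetadata(
            self.table[self.table["sample_id"].isin(ids)].reset_index(drop=True)
        )


def read_matrix(
    matrix_path: str | Path, metadata_path: str | Path
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read a genes-as-rows TSV matrix plus a sample metadata TSV.

    Samples present in only one of the two files are dropped with a logged
    count; duplicate gene ids or negative values raise.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta_df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    meta = SampleMetadata(meta_df)

    matrix_samples = set(values.columns)
    meta_samples = set(meta.sample_ids)
    common = [s for s in values.columns if s in meta_samples]
    dropped = (matrix_samples - meta_samples) | (meta_samples - matrix_samples)
    if dropped:
        logger.warning(
            "dropping %d unmatched sample(s): %s",
            len(dropped), sorted(dropped)[:10],
        )
    if not common:
        raise ValueError("no samples shared between matrix and metadata")
    values = values[common]
    meta = meta.subset(common)
    return ExpressionMatrix(values, scale="rpkm"), meta


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def log_transform(
    m: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """``value <- log_base(value + pseudocount)``; errors if already log."""
    if m.scale == "log2":
        raise ValueError("matrix already log-transformed")
    values = np.log(m.values + pseudocount) / np.log(base)
    return ExpressionMatrix(values, scale="log2")


def median_filter(
    m: ExpressionMatrix, threshold: float = 2.0
) -> ExpressionMatrix:
    """Keep genes whose per-gene median is strictly above ``threshold``
    (interpreted on the matrix's current scale)."""
    medians = m.values.median(axis=1)
    keep = medians > threshold
    logger.info(
        "median filter (> %g): kept %d, dropped %d genes",
        threshold, int(keep.sum()), int((~keep).sum()),
    )
    return ExpressionMatrix(m.values.loc[keep], scale=m.scale)


def subset_genes(m: ExpressionMatrix, genes: Sequence[str]) -> ExpressionMatrix:
    """Restrict rows to requested genes; missing ids are logged, an empty
    intersection raises."""
    requested = list(dict.fromkeys(genes))
    present = [g for g in requested if g in m.values.index]
    missing = [g for g in requested if g not in m.values.index]
    if missing:
        logger.warning(
            "%d requested gene(s) absent from matrix: %s",
            len(missing), missing[:10],
        )
    if not present:
        raise ValueError("no requested genes present in the matrix")
    return ExpressionMatrix(m.values.loc[present], scale=m.scale)


def summarize(m: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Median and SD over all (gene, sample) values per structure x stage.

    Returns a tidy frame (structure, stage, median, sd, n_values); cells
    with no samples are omitted. Single-value cells report SD = 0 and are
    flagged low-confidence.
    """
    rows = []
    tab = meta.table
    for structure in sorted(tab["structure"].unique()):
        for stage in STAGE_ORDER:
            ids = tab.loc[
                (tab["structure"] == structure) & (tab["stage"] == stage),
                "sample_id",
            ]
            cols = [s for s in ids if s in m.values.columns]
            if not cols:
                logger.debug("empty cell (%s, %s) omitted", structure, stage)
                continue
            block = m.values[cols].to_numpy().ravel()
            rows.append(
                {
                    "structure": structure,
                    "stage": stage,
                    "median": float(np.median(block)),
                    "sd": float(np.std(block, ddof=1)) if block.size > 1 else 0.0,
                    "n_values": int(block.size),
                    "low_confidence": bool(block.size == 1),
                }
            )
    return pd.DataFrame(rows)


def collapse_neocortex(
    meta: SampleMetadata, mapping: dict[str, str] | None = None
) -> SampleMetadata:
    """Collapse neocortical area labels to NCX (or apply a custom mapping)."""
    mapping = NEOCORTEX_AREAS if mapping is None else mapping
    table = meta.table.copy()
    table["structure"] = table["structure"].map(lambda s: mapping.get(s, s))
    return SampleMetadata(table)
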