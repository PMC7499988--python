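"""Assembling the experiment matrix and preprocessing it.

The preprocessing order is fixed: background subtraction on the linear
(count) scale, then technical-replicate averaging, then a log2 transform.
Averaging therefore happens on the linear scale, and downstream effect
sizes are log2 fold changes.

Stages are explicit and monotone: ``raw`` → ``background_corrected`` →
``averaged`` → ``logged`` → ``normalized``; every operation refuses
out-of-order input so a pipeline bug surfaces as a contract error instead
of silently wrong numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Optional, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import ContractError
from .gpr import ColumnCatalog, GPRFile

STAGES = ("raw", "background_corrected", "averaged", "logged", "normalized")

#: Marker for a row whose replicates came from more than one block.
MIXED_BLOCK = -1


@dataclass
class ExperimentMatrix:
    """Proteins × samples matrix of intensities with row annotations.

    Attributes
    ----------
    values
        Float array, one row per spot (or per protein after averaging), one
        column per sample; NaN marks missing.
    stage
        Current preprocessing stage (see :data:`STAGES`).
    annotations
        Per-row ``name``, ``id``, ``n_replicates``, ``block`` (block of
        origin, :data:`MIXED_BLOCK` if replicates spanned blocks) and
        ``source_blocks`` (tuple of contributing blocks).
    sample_names
        Per-column labels (GPR source names).
    sample_to_array_index
        Per-column 1-based array index used by the normalization model.
    n_floored
        How many cells were clipped to the floor during background
        correction (0 before that stage).
    """

    values: np.ndarray
    stage: str
    annotations: pd.DataFrame
    sample_names: list[str]
    sample_to_array_index: list[int]
    n_floored: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}")
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ContractError("matrix must have at least one row and column")
        if len(self.annotations) != self.values.shape[0]:
            raise ContractError("annotation rows must match matrix rows")
        if len(self.sample_names) != self.values.shape[1]:
            raise ContractError("sample names must match matrix columns")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row_keys(self) -> pd.Series:
        """Replicate key per row: protein ID, falling back to name."""
        ids = self.annotations["id"].astype(str)
        names = self.annotations["name"].astype(str)
        return ids.where(ids.str.strip() != "", names)

    def copy(self) -> "ExperimentMatrix":
        return ExperimentMatrix(
            values=self.values.copy(),
            stage=self.stage,
            annotations=self.annotations.copy(),
            sample_names=list(self.sample_names),
            sample_to_array_index=list(self.sample_to_array_index),
            n_floored=self.n_floored,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: name, id, n_replicates, then one column per sample."""
        out = self.annotations[["name", "id", "n_replicates"]].copy()
        for j, s in enumerate(self.sample_names):
            out[s] = self.values[:, j]
        return out

    def to_csv(self, sink: TextIO | str) -> None:
        self.to_frame().to_csv(sink, index=False)

    def _require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise ContractError(
                f"operation requires stage in {allowed}, matrix is at "
                f"{self.stage!r}"
            )


def assemble_matrix(
    files: Sequence[GPRFile], catalog: ColumnCatalog
) -> tuple[ExperimentMatrix, ExperimentMatrix]:
    """Build raw foreground and background matrices from consistent files.

    One column per file (input order), one row per spot in the first file's
    layout order; other files are aligned to that layout by their
    (Block, Column, Row, ID) key, so a permuted spot order in an export does
    not change the result.
    """
    if catalog.foreground is None or catalog.background is None:
        raise ContractError("channels must be selected before assembly")
    reference = files[0]
    ref_keys = list(map(tuple, reference.layout_key().itertuples(index=False)))

    n_spots, n_samples = len(ref_keys), len(files)
    fg = np.empty((n_spots, n_samples))
    bg = np.empty((n_spots, n_samples))
    for j, f in enumerate(files):
        if f is reference:
            order = np.arange(n_spots)
        else:
            index = {k: i for i, k in
                     enumerate(map(tuple, f.layout_key().itertuples(index=False)))}
            try:
                order = np.fromiter((index[k] for k in ref_keys), dtype=int,
                                    count=n_spots)
            except KeyError as e:
                raise ContractError(
                    f"{f.source_name} lacks spot {e.args[0]}; run "
                    f"validate_consistency first"
                ) from None
        fg[:, j] = f.spots[catalog.foreground].to_numpy(dtype=float)[order]
        bg[:, j] = f.spots[catalog.background].to_numpy(dtype=float)[order]

    annotations = pd.DataFrame(
        {
            "name": reference.spots["Name"].astype(str).to_numpy(),
            "id": reference.spots["ID"].astype(str).to_numpy(),
            "n_replicates": np.ones(n_spots, dtype=int),
            "block": reference.spots["Block"].to_numpy(dtype=int),
        }
    )
    annotations["source_blocks"] = [(int(b),) for b in annotations["block"]]
    sample_names = [f.source_name for f in files]
    array_index = list(range(1, n_samples + 1))

    make = lambda v: ExperimentMatrix(
        values=v,
        stage="raw",
        annotations=annotations.copy(),
        sample_names=sample_names,
        sample_to_array_index=array_index,
    )
    return make(fg), make(bg)


def background_correct(
    foreground: ExperimentMatrix,
    background: ExperimentMatrix,
    floor: float = 0.5,
) -> ExperimentMatrix:
    """Subtract local background from foreground, flooring the result.

    Any difference below ``floor`` (including negative differences, which
    are common for empty spots) is clipped to ``floor`` so the later log2
    transform is defined; the number of clipped cells is recorded on the
    result. Missing in either operand propagates to missing.
    """
    foreground._require_stage("raw")
    background._require_stage("raw")
    if foreground.values.shape != background.values.shape:
        raise ContractError(
            f"foreground shape {foreground.values.shape} != background "
            f"shape {background.values.shape}"
        )
    if floor <= 0:
        raise ContractError("floor must be positive (values are logged later)")
    diff = foreground.values - background.values
    with np.errstate(invalid="ignore"):
        floored = diff < floor
    n_floored = int(np.count_nonzero(floored))
    diff = np.where(floored, floor, diff)
    out = foreground.copy()
    out.values = diff
    out.stage = "background_corrected"
    out.n_floored = n_floored
    return out


def average_replicates(
    matrix: ExperimentMatrix,
    control_ids: Collection[str] = (),
) -> ExperimentMatrix:
    """Collapse technical replicates to their per-sample arithmetic mean.

    Rows sharing the same protein ID (name when ID is empty) within a
    sample are averaged on the linear scale; missing values are excluded
    from the mean, an all-missing group stays missing. Row order follows
    first occurrence.

    Rows whose key is in ``control_ids`` are only collapsed *within* a
    block: positive controls anchor the block-level bias model, and
    averaging them across blocks would destroy the block covariate. For
    ordinary proteins collapsed across blocks, the block of origin is
    recorded as mixed and all source blocks are kept.
    """
    matrix._require_stage("background_corrected")
    keys = matrix.row_keys()
    control_ids = set(control_ids)
    blocks = matrix.annotations["block"].to_numpy()

    group_keys = [
        (k, int(b)) if k in control_ids else (k, None)
        for k, b in zip(keys, blocks)
    ]
    order: dict[tuple, int] = {}
    members: list[list[int]] = []
    for i, gk in enumerate(group_keys):
        if gk not in order:
            order[gk] = len(members)
            members.append([])
        members[order[gk]].append(i)

    n_groups = len(members)
    values = np.empty((n_groups, matrix.n_samples))
    ann_rows = []
    for g, idx in enumerate(members):
        sub = matrix.values[idx, :]
        n_present = np.count_nonzero(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            sums = np.nansum(sub, axis=0)
            values[g, :] = np.where(n_present > 0, sums / np.maximum(n_present, 1),
                                    np.nan)
        first = matrix.annotations.iloc[idx[0]]
        source_blocks = tuple(sorted({int(b) for b in blocks[idx]}))
        ann_rows.append(
            {
                "name": first["name"],
                "id": first["id"],
                "n_replicates": len(idx),
                "block": source_blocks[0] if len(source_blocks) == 1 else MIXED_BLOCK,
                "source_blocks": source_blocks,
            }
        )

    out = ExperimentMatrix(
        values=values,
        stage="averaged",
        annotations=pd.DataFrame(ann_rows),
        sample_names=list(matrix.sample_names),
        sample_to_array_index=list(matrix.sample_to_array_index),
        n_floored=matrix.n_floored,
    )
    return out


def log_transform(matrix: ExperimentMatrix) -> ExperimentMatrix:
    """Apply log2 elementwise; requires every present value to be positive."""
    matrix._require_stage("averaged")
    present = ~np.isnan(matrix.values)
    if np.any(matrix.values[present] <= 0):
        raise ContractError(
            "nonpositive value reached log_transform — the background "
            "floor was bypassed"
        )
    out = matrix.copy()
    out.values = np.where(present, np.log2(matrix.values,
                                           where=present,
                                           out=np.full_like(matrix.values, np.nan)),
                          np.nan)
    out.stage = "logged"
    return out
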