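"""Seeded synthetic GPR experiments with full ground truth.

The generator emulates the data an autoantibody profiling experiment
produces: one GPR file per serum sample, spots laid out in blocks, every
ordinary protein printed as technical replicates spread across blocks, and
a small panel of positive-control proteins printed once per block so that
block-level bias is identifiable.

Signal model, on the log2 scale, for a spot of protein i in block b of
array (sample) a:

    y = baseline + protein_i + group_effect + alpha_a + beta_b + N(0, sigma)

where ``group_effect`` is the effect size Delta for differential proteins
in the test group and 0 otherwise. Control spots replace
``protein_i + group_effect`` by their control-type mean — their expected
signal depends only on (type, array, block), the assumption the robust
normalization relies on. Biases are additive on the log2 scale, i.e.
multiplicative on raw counts. The linear-scale foreground written to the
GPR file is ``2**y + background`` with the same background written to the
background column, so background subtraction is exactly identifiable.

Everything is driven by one integer seed; the same config reproduces the
same files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gpr import GPRFile


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a typical two-group autoantibody screen: 5 vs 5
    samples, 2000 proteins in technical duplicate over 12 blocks, 12
    control proteins of 3 types, 20 differential proteins at a 2.0 log2
    effect with 0.4 log2 noise. Array and block offsets default to seeded
    draws (sd 0.5 and 0.25 log2) unless given explicitly.
    """

    n_samples_per_group: tuple[int, int] = (5, 5)
    n_proteins: int = 2000
    n_blocks: int = 12
    replicates_per_protein: int = 2
    n_control_proteins: int = 12
    control_types: tuple[tuple[str, float], ...] = (
        ("IgG", 13.0),
        ("Biotin", 11.5),
        ("Alexa", 12.5),
    )
    array_offsets: Optional[tuple[float, ...]] = None
    block_offsets: Optional[tuple[float, ...]] = None
    array_offset_sd: float = 0.5
    block_offset_sd: float = 0.25
    baseline_mean: float = 10.0
    protein_sd: float = 1.5
    noise_sd: float = 0.4
    n_differential: int = 20
    effect_size: float = 2.0
    background_level: float = 150.0
    background_sd: float = 30.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 5.0
    group_labels: tuple[str, str] = ("case", "control")
    seed: int = 0

    def validate(self) -> None:
        counts = (
            *self.n_samples_per_group,
            self.n_proteins,
            self.n_blocks,
            self.replicates_per_protein,
            self.n_control_proteins,
        )
        if any(c < 1 for c in counts):
            raise ConfigError(f"all counts must be >= 1, got {counts}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.n_differential > self.n_proteins:
            raise ConfigError("n_differential cannot exceed n_proteins")
        if not self.control_types:
            raise ConfigError("at least one control type is required")
        n_samples = sum(self.n_samples_per_group)
        if self.array_offsets is not None and len(self.array_offsets) != n_samples:
            raise ConfigError(
                f"array_offsets must have one entry per sample ({n_samples})"
            )
        if self.block_offsets is not None and len(self.block_offsets) != self.n_blocks:
            raise ConfigError(
                f"block_offsets must have one entry per block ({self.n_blocks})"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows, for testing every pipeline stage."""

    config: SyntheticConfig
    protein_ids: list[str]
    control_ids: list[str]
    control_type_of: dict[str, str]
    differential_ids: list[str]
    true_means: pd.DataFrame  # index protein id, one column per group (log2)
    array_offsets: np.ndarray
    block_offsets: np.ndarray
    sample_names: list[str]
    sample_groups: list[str]
    column_names: list[str]
    n_spots_per_file: int
    #: per-spot linear intensity before noise and before background,
    #: one column per sample, rows in file spot order
    pre_noise_linear: np.ndarray
    #: per-spot log2 noise-free signal (same layout)
    spot_expected_log2: np.ndarray
    spot_ids: list[str]
    spot_blocks: np.ndarray

    def metadata_csv(self) -> str:
        lines = ["filename,group"]
        lines += [f"{s}.gpr,{g}" for s, g in
                  zip(self.sample_names, self.sample_groups)]
        return "\n".join(lines) + "\n"


_COLUMNS = ["Block", "Column", "Row", "Name", "ID", "F635 Median", "B635 Median"]


def _layout(config: SyntheticConfig):
    """Spot order: per-block grids; replicates of protein i land in
    consecutive blocks starting at ``i mod n_blocks``; each control protein
    appears once in every block."""
    spots: list[tuple[int, str, str, Optional[str], Optional[int]]] = []
    # (block, name, id, control_type, protein_index)
    B = config.n_blocks
    for i in range(config.n_proteins):
        pid = f"PROT{i + 1:05d}"
        for r in range(config.replicates_per_protein):
            spots.append(((i + r) % B + 1, f"protein {i + 1}", pid, None, i))
    type_labels = [t for t, _ in config.control_types]
    for c in range(config.n_control_proteins):
        t = type_labels[c % len(type_labels)]
        cid = f"CTRL{c + 1:03d}"
        name = {
            "IgG": f"Anti-Human IgG {c + 1}",
            "Biotin": f"Biotin marker {c + 1}",
            "Alexa": f"Alexa conjugate {c + 1}",
        }.get(t, f"{t} control {c + 1}")
        for b in range(1, B + 1):
            spots.append((b, name, cid, t, None))
    # sort into block order, assign within-block column/row on a grid
    spots.sort(key=lambda s: s[0])
    per_block: dict[int, int] = {}
    geometry = []
    max_per_block = max(
        sum(1 for s in spots if s[0] == b) for b in range(1, B + 1)
    )
    n_cols = int(np.ceil(np.sqrt(max_per_block)))
    for b, name, pid, ctype, pidx in spots:
        k = per_block.get(b, 0)
        per_block[b] = k + 1
        geometry.append((b, k % n_cols + 1, k // n_cols + 1, name, pid,
                         ctype, pidx))
    return geometry


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[list[GPRFile], GroundTruth]:
    """Generate one GPR file per sample plus the full ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_test, n_ref = config.n_samples_per_group
    n_samples = n_test + n_ref
    test_label, ref_label = config.group_labels
    sample_groups = [test_label] * n_test + [ref_label] * n_ref
    sample_names = [f"sample_{j + 1:02d}_{g}" for j, g in
                    enumerate(sample_groups)]

    protein_effects = rng.normal(0.0, config.protein_sd, config.n_proteins)
    diff_idx = rng.choice(config.n_proteins, size=config.n_differential,
                          replace=False)
    diff_mask = np.zeros(config.n_proteins, dtype=bool)
    diff_mask[diff_idx] = True

    if config.array_offsets is not None:
        alpha = np.asarray(config.array_offsets, dtype=float)
    else:
        alpha = rng.normal(0.0, config.array_offset_sd, n_samples)
    if config.block_offsets is not None:
        beta = np.asarray(config.block_offsets, dtype=float)
    else:
        beta = rng.normal(0.0, config.block_offset_sd, config.n_blocks)

    geometry = _layout(config)
    n_spots = len(geometry)
    type_mean = dict(config.control_types)

    # noise-free log2 signal per (spot, sample), before array/block bias
    base = np.empty(n_spots)
    group_bump = np.zeros((n_spots, n_samples))
    spot_blocks = np.empty(n_spots, dtype=int)
    spot_ids = []
    for s, (b, col, row, name, pid, ctype, pidx) in enumerate(geometry):
        spot_blocks[s] = b
        spot_ids.append(pid)
        if ctype is not None:
            base[s] = type_mean[ctype]
        else:
            base[s] = config.baseline_mean + protein_effects[pidx]
            if diff_mask[pidx]:
                group_bump[s, :n_test] = config.effect_size

    expected_log2 = (
        base[:, None]
        + group_bump
        + alpha[None, :]
        + beta[spot_blocks - 1, None]
    )
    noise = rng.normal(0.0, config.noise_sd, size=(n_spots, n_samples))
    if config.outlier_fraction > 0:
        hits = rng.random((n_spots, n_samples)) < config.outlier_fraction
        noise = noise + hits * config.outlier_shift
    y = expected_log2 + noise

    background = np.maximum(
        rng.normal(config.background_level, config.background_sd,
                   size=(n_spots, n_samples)),
        0.0,
    )
    pre_noise_linear = np.exp2(expected_log2)
    foreground = np.exp2(y) + background

    files: list[GPRFile] = []
    header = {
        "Type": "GenePix Results 3",
        "Wavelengths": "635",
        "Creator": "proma synthetic generator",
    }
    for j, sname in enumerate(sample_names):
        spots = pd.DataFrame(
            {
                "Block": [g[0] for g in geometry],
                "Column": [g[1] for g in geometry],
                "Row": [g[2] for g in geometry],
                "Name": [g[3] for g in geometry],
                "ID": [g[4] for g in geometry],
                "F635 Median": foreground[:, j],
                "B635 Median": background[:, j],
            }
        )
        files.append(
            GPRFile(
                source_name=sname,
                atf_version="1.0",
                header_records=dict(header),
                column_names=list(_COLUMNS),
                spots=spots,
            )
        )

    protein_ids = [f"PROT{i + 1:05d}" for i in range(config.n_proteins)]
    control_ids = [f"CTRL{c + 1:03d}" for c in
                   range(config.n_control_proteins)]
    type_labels = [t for t, _ in config.control_types]
    control_type_of = {
        cid: type_labels[c % len(type_labels)]
        for c, cid in enumerate(control_ids)
    }
    true_means = pd.DataFrame(
        {
            test_label: config.baseline_mean + protein_effects
            + np.where(diff_mask, config.effect_size, 0.0),
            ref_label: config.baseline_mean + protein_effects,
        },
        index=pd.Index(protein_ids, name="id"),
    )

    truth = GroundTruth(
        config=config,
        protein_ids=protein_ids,
        control_ids=control_ids,
        control_type_of=control_type_of,
        differential_ids=[protein_ids[i] for i in sorted(diff_idx)],
        true_means=true_means,
        array_offsets=alpha,
        block_offsets=beta,
        sample_names=sample_names,
        sample_groups=sample_groups,
        column_names=list(_COLUMNS),
        n_spots_per_file=n_spots,
        pre_noise_linear=pre_noise_linear,
        spot_expected_log2=expected_log2,
        spot_ids=spot_ids,
        spot_blocks=spot_blocks,
    )
    return files, truth
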