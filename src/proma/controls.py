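"""Positive-control detection and robust-linear-model normalization.

Positive controls are spots expected to show a constant signal level
regardless of the biology of the sample — anti-IgG dilution series, biotin
or Alexa-labelled markers, and explicitly "control"-named spots on
ProtoArray/HuProt-style arrays. Their log2 signal is modelled additively as

    y = mu + gamma_type + alpha_array + beta_block + error

with treatment (reference-level) coding: the first array and first block
are the baseline, so ``alpha_1 = beta_1 = 0`` exactly. In a noise-free
experiment the fit depends only on the control type; non-zero array or
block coefficients measure technical bias, and normalization subtracts the
fitted ``alpha_a + beta_b`` from every protein's signal. The type effects
and intercept describe the controls themselves and are never subtracted.

The model is fitted by Huber M-estimation (iteratively reweighted least
squares) so that a handful of reactive or failed control spots cannot
distort the bias estimates the way they would under ordinary least
squares.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DesignMatrixError, PanelError
from .preprocess import MIXED_BLOCK, ExperimentMatrix

class NormalizationWarning(UserWarning):
    """Non-fatal normalization issues (unseen levels, non-convergence)."""


#: Default control-name patterns (case-insensitive, matched against the
#: protein name and ID): ProtoArray/HuProt conventions. First match wins.
DEFAULT_CONTROL_PATTERNS: list[tuple[str, str]] = [
    (r"anti[\-\s_]*human[\-\s_]*igg", "IgG"),
    (r"\bhuman[\-\s_]*igg\b", "IgG"),
    (r"biotin", "Biotin"),
    (r"alexa", "Alexa"),
    (r"\bcontrol\b", "Control"),
]


@dataclass
class ControlPanel:
    """Proteins treated as positive controls, each with a type label."""

    entries: list[tuple[str, str]]  # (protein key, control type)
    source: str = "auto"  # auto | user | merged

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ContractError(f"duplicate control protein ids: {dup}")
        if any(not t for _, t in self.entries):
            raise ContractError("every control must carry a non-empty type")

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]

    def type_of(self, pid: str) -> str:
        for p, t in self.entries:
            if p == pid:
                return t
        raise PanelError(f"protein {pid!r} is not in the control panel")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["id", "type"])


@dataclass
class ControlObservations:
    """Long table: one row per control spot per sample.

    ``table`` columns: ``y`` (log2 signal), ``array`` (1-based sample/array
    index), ``block`` (1-based block index), ``type`` (control-type label).
    Level orderings are fixed at construction; the first level of each
    factor is the model's reference.
    """

    table: pd.DataFrame
    array_levels: list[int]
    block_levels: list[int]
    type_levels: list[str]


@dataclass
class RLMFit:
    """Fitted robust control model in treatment coding.

    ``array_effects``/``block_effects``/``type_effects`` map each observed
    level to its coefficient; the reference (first) level maps to exactly
    0.0. The fitted mean signal of a control of type t in array a, block b
    is ``intercept + type_effects[t] + array_effects[a] + block_effects[b]``.
    """

    intercept: float
    type_effects: dict[str, float]
    array_effects: dict[int, float]
    block_effects: dict[int, float]
    huber_c: float
    scale: float
    n_iterations: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [("intercept", "", self.intercept)]
        rows += [("type", t, v) for t, v in self.type_effects.items()]
        rows += [("array", str(a), v) for a, v in self.array_effects.items()]
        rows += [("block", str(b), v) for b, v in self.block_effects.items()]
        return pd.DataFrame(rows, columns=["term", "level", "estimate"])


def match_control_types(
    annotations: pd.DataFrame,
    patterns: Sequence[tuple[str, str]] = tuple(DEFAULT_CONTROL_PATTERNS),
) -> pd.Series:
    """Per-row control-type label (or None) from name/ID pattern matching.

    Usable on annotations at any stage; the first matching pattern wins.
    """
    compiled = [(re.compile(rx, re.IGNORECASE), t) for rx, t in patterns]
    out = []
    for name, pid in zip(annotations["name"].astype(str),
                         annotations["id"].astype(str)):
        label = None
        for rx, t in compiled:
            if rx.search(name) or rx.search(pid):
                label = t
                break
        out.append(label)
    return pd.Series(out, index=annotations.index, dtype=object)


def detect_controls(
    matrix: ExperimentMatrix,
    patterns: Sequence[tuple[str, str]] = tuple(DEFAULT_CONTROL_PATTERNS),
) -> ControlPanel:
    """Scan protein annotations for likely positive controls.

    Every protein whose name or ID matches any pattern is listed with the
    first matching pattern's type. An empty panel is legal (and warnable) —
    the caller decides whether to proceed without normalization.
    """
    matrix._require_stage("averaged", "logged")
    types = match_control_types(matrix.annotations, patterns)
    keys = matrix.row_keys()
    entries: list[tuple[str, str]] = []
    seen = set()
    for key, t in zip(keys, types):
        if t is not None and key not in seen:
            entries.append((key, t))
            seen.add(key)
    return ControlPanel(entries=entries, source="auto")


def edit_panel(
    panel: ControlPanel,
    add: Iterable[tuple[str, str]] = (),
    remove: Iterable[str] = (),
    known_ids: Optional[Iterable[str]] = None,
) -> ControlPanel:
    """Apply user edits to a detected panel (set semantics).

    Removals win over additions on conflict; removing a non-member is a
    no-op. When ``known_ids`` is given, added proteins must be among them.
    """
    add = list(add)
    remove = set(remove)
    if known_ids is not None:
        known = set(known_ids)
        unknown = sorted({pid for pid, _ in add} - known)
        if unknown:
            raise PanelError(f"cannot add unknown protein ids: {unknown}")
    merged: dict[str, str] = {pid: t for pid, t in panel.entries}
    for pid, t in add:
        merged[pid] = t
    for pid in remove:
        merged.pop(pid, None)
    return ControlPanel(entries=list(merged.items()), source="merged")


def build_control_observations(
    matrix: ExperimentMatrix, panel: ControlPanel
) -> ControlObservations:
    """Extract the long (control spot × sample) table the model fits.

    Requires a logged matrix and a known block of origin for every control
    row — controls must not have been averaged across blocks (see
    :func:`proma.preprocess.average_replicates`).
    """
    matrix._require_stage("logged")
    if not panel.entries:
        raise ContractError("control panel is empty; nothing to fit")
    keys = matrix.row_keys().to_numpy()
    panel_types = dict(panel.entries)
    missing = sorted(set(panel_types) - set(keys))
    if missing:
        raise PanelError(
            f"control proteins absent from the matrix: {missing}"
        )

    rows = []
    blocks = matrix.annotations["block"].to_numpy()
    for i in range(matrix.n_proteins):
        t = panel_types.get(keys[i])
        if t is None:
            continue
        if blocks[i] == MIXED_BLOCK:
            raise ContractError(
                f"control {keys[i]!r} was averaged across blocks; exempt "
                f"controls from cross-block averaging before normalization"
            )
        for j in range(matrix.n_samples):
            y = matrix.values[i, j]
            if np.isnan(y):
                continue
            rows.append(
                (float(y), matrix.sample_to_array_index[j], int(blocks[i]), t)
            )
    table = pd.DataFrame(rows, columns=["y", "array", "block", "type"])

    observed_arrays = set(table["array"])
    silent = [matrix.sample_names[j]
              for j, a in enumerate(matrix.sample_to_array_index)
              if a not in observed_arrays]
    if silent:
        raise DesignMatrixError(
            f"no control observations for sample(s) {silent}; their array "
            f"offsets cannot be estimated — extend the control panel or "
            f"skip normalization"
        )

    return ControlObservations(
        table=table,
        array_levels=sorted(set(table["array"])),
        block_levels=sorted(set(table["block"])),
        type_levels=list(dict.fromkeys(table["type"])),
    )


def _design_matrix(obs: ControlObservations) -> tuple[np.ndarray, list[str]]:
    """Intercept + drop-first dummies for type, array and block."""
    t = obs.table
    n = len(t)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for label, levels, series in (
        ("type", obs.type_levels, t["type"]),
        ("array", obs.array_levels, t["array"]),
        ("block", obs.block_levels, t["block"]),
    ):
        for level in levels[1:]:
            cols.append((series == level).to_numpy(dtype=float))
            names.append(f"{label}[{level}]")
    return np.column_stack(cols), names


def fit_rlm(
    obs: ControlObservations,
    huber_c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RLMFit:
    """Fit the control model by Huber IRLS.

    Starts from the ordinary least-squares solution; each iteration
    re-estimates the robust residual scale as MAD/0.6745 and solves a
    weighted least-squares problem with Huber weights
    ``min(1, c·scale/|r|)``. Deterministic for fixed input. The default
    ``huber_c = 1.345`` gives 95% efficiency under Gaussian noise; as
    ``huber_c → ∞`` the fit converges to ordinary least squares.

    Raises
    ------
    DesignMatrixError
        If the design is fully degenerate (a single level for every
        factor) or rank deficient, naming the collinear columns.
    """
    t = obs.table
    if len(t) == 0:
        raise ContractError("no control observations")
    if (len(obs.type_levels) < 2 and len(obs.array_levels) < 2
            and len(obs.block_levels) < 2):
        raise DesignMatrixError(
            "model is fully degenerate: one type, one array, one block"
        )
    X, names = _design_matrix(obs)
    y = t["y"].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        collinear = sorted(names[i] for i in piv[rank:])
        raise DesignMatrixError(
            f"design matrix is rank deficient (rank {rank} of "
            f"{X.shape[1]}); collinear columns: {collinear}"
        )

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    scale = np.nan
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r = y - X @ beta
        scale = float(np.median(np.abs(r)) / 0.6745)
        if scale == 0.0:
            converged = True
            break
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, huber_c * scale / np.abs(r))
        w[np.abs(r) == 0.0] = 1.0
        sw = np.sqrt(w)
        beta_new = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"robust fit did not converge in {max_iter} iterations "
            f"(last max coefficient change ≥ {tol})",
            NormalizationWarning,
            stacklevel=2,
        )

    coef = dict(zip(names, beta))
    type_effects = {obs.type_levels[0]: 0.0} if obs.type_levels else {}
    for lv in obs.type_levels[1:]:
        type_effects[lv] = float(coef[f"type[{lv}]"])
    array_effects = {obs.array_levels[0]: 0.0}
    for lv in obs.array_levels[1:]:
        array_effects[lv] = float(coef[f"array[{lv}]"])
    block_effects = {obs.block_levels[0]: 0.0}
    for lv in obs.block_levels[1:]:
        block_effects[lv] = float(coef[f"block[{lv}]"])

    return RLMFit(
        intercept=float(coef["intercept"]),
        type_effects=type_effects,
        array_effects=array_effects,
        block_effects=block_effects,
        huber_c=huber_c,
        scale=scale,
        n_iterations=n_iter,
        converged=converged,
    )


def apply_normalization(matrix: ExperimentMatrix, fit: RLMFit) -> ExperimentMatrix:
    """Subtract fitted array and block offsets from every protein signal.

    Each value at (protein in block b, sample a) becomes
    ``value − alpha_a − beta_b``; type effects and the intercept describe
    the controls and are left in place. Rows averaged across blocks receive
    the mean of their source blocks' offsets. Levels never seen by the fit
    get offset 0 with a warning. Row/column order and annotations are
    untouched.
    """
    matrix._require_stage("logged")

    unseen_arrays = [a for a in matrix.sample_to_array_index
                     if a not in fit.array_effects]
    alphas = np.array([fit.array_effects.get(a, 0.0)
                       for a in matrix.sample_to_array_index])

    betas = np.empty(matrix.n_proteins)
    unseen_blocks: set[int] = set()
    for i, src in enumerate(matrix.annotations["source_blocks"]):
        vals = []
        for b in src:
            if b not in fit.block_effects:
                unseen_blocks.add(b)
            vals.append(fit.block_effects.get(b, 0.0))
        betas[i] = float(np.mean(vals))

    if unseen_arrays or unseen_blocks:
        warnings.warn(
            f"levels unseen by the control fit get offset 0: "
            f"arrays {sorted(set(unseen_arrays))}, "
            f"blocks {sorted(unseen_blocks)}",
            NormalizationWarning,
            stacklevel=2,
        )

    out = matrix.copy()
    out.values = matrix.values - alphas[None, :] - betas[:, None]
    out.stage = "normalized"
    return out
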