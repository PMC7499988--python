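"""Differential reactivity: moderated t-tests with BH FDR control.

Per protein g a group-means linear model is fitted by least squares on the
complete (non-missing) samples, giving an effect ``b_g`` (log2 fold change
of the test group over the reference), a residual variance ``s2_g`` on
``d_g`` degrees of freedom, and the unscaled standard error ``u_g`` with
``SE = s_g * u_g``.

The per-protein variances are then shrunk toward a common prior by the
empirical-Bayes scheme of the moderated t-test: assuming
``s2_g ~ s0^2 * F(d_g, d0)``, the prior degrees of freedom ``d0`` and prior
variance ``s0^2`` are estimated by moment matching on the log variances
(digamma/trigamma identities, with ``d0`` recovered by Newton inversion of
the trigamma function), and each protein's posterior variance is the
precision-weighted pool

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g).

The moderated statistic ``t_g = b_g / (s_tilde_g * u_g)`` is referred to a
t distribution on ``d0 + d_g`` degrees of freedom (normal when ``d0`` is
infinite), gaining stability at the small sample sizes typical of protein
microarray studies. Two-sided p-values are adjusted by the
Benjamini–Hochberg step-up procedure over all tested proteins; adjusted
p < 0.05 is flagged significant by default.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .errors import AnalysisError, ContractError, DesignError, MetadataError
from .preprocess import ExperimentMatrix


class ModerationWarning(UserWarning):
    """Non-fatal moderation issues (too few proteins, zero variances)."""


@dataclass
class DesignInfo:
    """Sample-to-group assignment and the contrast to test.

    The contrast is an ordered pair (test, reference); effects are
    test-group mean minus reference-group mean. A valid design needs at
    least two groups and more samples than groups (so at least three
    samples in the minimal two-group case).
    """

    sample_to_group: list[str]
    groups: list[str]
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise DesignError(
                f"need at least 2 groups, got {self.groups}"
            )
        if len(self.sample_to_group) <= len(self.groups):
            raise DesignError(
                f"{len(self.sample_to_group)} samples with "
                f"{len(self.groups)} groups: the number of samples must "
                f"exceed the number of groups by at least one"
            )
        unknown = sorted(set(self.sample_to_group) - set(self.groups))
        if unknown:
            raise DesignError(f"samples assigned to unknown groups: {unknown}")
        test, ref = self.contrast
        if test == ref or test not in self.groups or ref not in self.groups:
            raise DesignError(f"invalid contrast {self.contrast!r}")


def _stem(filename: str) -> str:
    base = filename.replace("\\", "/").rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base


def read_metadata(
    stream: TextIO | str,
    sample_names: Sequence[str],
    reference: Optional[str] = None,
) -> DesignInfo:
    """Parse a two-column (filename, group) table into a design.

    Filenames are matched to sample names by stem, extension-insensitively;
    a header row is tolerated. The default contrast is the first group seen
    against the second (or against ``reference`` when given).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    raw = pd.read_csv(stream, sep=None, engine="python", header=None,
                      dtype=str, comment=None, skip_blank_lines=True)
    if raw.shape[1] != 2:
        raise MetadataError(
            f"metadata must have exactly two columns (filename, group), "
            f"got {raw.shape[1]}"
        )
    rows = [(str(a).strip(), str(b).strip()) for a, b in
            raw.itertuples(index=False)]

    stems = {_stem(s): s for s in sample_names}
    if len(stems) != len(sample_names):
        raise MetadataError("sample names collide after dropping extensions")

    assigned: dict[str, str] = {}
    unknown: list[str] = []
    for i, (fname, group) in enumerate(rows):
        stem = _stem(fname)
        if stem not in stems:
            if i == 0 and len(rows) == len(sample_names) + 1:
                continue  # header row
            unknown.append(fname)
            continue
        sample = stems[stem]
        if sample in assigned:
            raise MetadataError(f"sample {sample!r} listed more than once")
        assigned[sample] = group
    if unknown:
        raise MetadataError(
            f"metadata filenames not among the uploaded samples: {unknown}"
        )
    unmatched = [s for s in sample_names if s not in assigned]
    if unmatched:
        raise MetadataError(f"samples without metadata: {unmatched}")

    sample_to_group = [assigned[s] for s in sample_names]
    groups = list(dict.fromkeys(sample_to_group))
    if len(groups) < 2:
        raise DesignError(f"need at least 2 groups, got {groups}")
    if reference is None:
        reference = groups[1]
    elif reference not in groups:
        raise DesignError(
            f"reference group {reference!r} not among groups {groups}"
        )
    test = next(g for g in groups if g != reference)
    return DesignInfo(sample_to_group=sample_to_group, groups=groups,
                      contrast=(test, reference))


@dataclass
class ProteinFit:
    """Per-protein least-squares summary for one contrast."""

    index: int
    name: str
    id: str
    effect: float  # log2 fold change, test minus reference
    s2: float  # residual variance
    df: int  # residual degrees of freedom
    u: float  # unscaled SE multiplier: SE = s * u
    usable: bool  # enters moderation (df > 0, both contrast groups present)
    reason: str = ""


def fit_protein_models(
    matrix: ExperimentMatrix, design: DesignInfo
) -> list[ProteinFit]:
    """Fit the group-means model to every protein, complete cases only.

    Residual variance pools across all design groups; the effect and the
    SE multiplier ``u = sqrt(1/n_test + 1/n_ref)`` are for the design's
    contrast. Proteins with no residual degrees of freedom or with a design
    group entirely missing are flagged unusable (excluded from moderation).
    """
    matrix._require_stage("logged", "normalized")
    if matrix.n_samples != len(design.sample_to_group):
        raise ContractError(
            f"matrix has {matrix.n_samples} samples but the design "
            f"describes {len(design.sample_to_group)}"
        )
    groups = design.groups
    test, ref = design.contrast
    membership = {
        g: np.array([sg == g for sg in design.sample_to_group]) for g in groups
    }

    fits: list[ProteinFit] = []
    names = matrix.annotations["name"].astype(str).to_numpy()
    ids = matrix.row_keys().to_numpy()
    for i in range(matrix.n_proteins):
        y = matrix.values[i, :]
        present = ~np.isnan(y)
        n_g = {g: int(np.count_nonzero(membership[g] & present)) for g in groups}
        n_complete = int(np.count_nonzero(present))
        df = n_complete - len(groups)
        empty = [g for g in groups if n_g[g] == 0]
        if empty or df <= 0 or n_g[test] == 0 or n_g[ref] == 0:
            reason = (f"group(s) {empty} entirely missing" if empty
                      else "no residual degrees of freedom")
            fits.append(ProteinFit(i, names[i], ids[i], np.nan, np.nan,
                                   max(df, 0), np.nan, False, reason))
            continue
        rss = 0.0
        means = {}
        for g in groups:
            vals = y[membership[g] & present]
            means[g] = float(np.mean(vals))
            rss += float(np.sum((vals - means[g]) ** 2))
        s2 = rss / df
        u = math.sqrt(1.0 / n_g[test] + 1.0 / n_g[ref])
        fits.append(ProteinFit(i, names[i], ids[i],
                               means[test] - means[ref], s2, df, u, True))
    if not any(f.usable for f in fits):
        raise AnalysisError(
            "no protein has enough complete observations for testing"
        )
    return fits


@dataclass
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0² variance.

    ``d0 = 0`` disables moderation (posterior = sample variance);
    ``d0 = inf`` pools completely (posterior = s0² everywhere).
    """

    d0: float
    s02: float

    def posterior(self, s2: np.ndarray, df: np.ndarray) -> np.ndarray:
        s2 = np.asarray(s2, dtype=float)
        df = np.asarray(df, dtype=float)
        if self.d0 == 0:
            return s2.copy()
        if math.isinf(self.d0):
            return np.full_like(s2, self.s02)
        return (self.d0 * self.s02 + df * s2) / (self.d0 + df)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, decreasing and convex on (0, inf), so Newton from
    the asymptotic start ``x = 0.5 + 1/y`` converges monotonically.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) / x < tol:
            break
    return x


def estimate_prior(
    s2: Sequence[float], df: Sequence[int]
) -> ModerationPrior:
    """Moment-match the variance prior on the log scale.

    With ``s2_g ~ s0² F(d_g, d0)``, ``log s2_g`` has known mean and
    variance in terms of digamma/trigamma functions; equating sample
    moments of ``e_g = log s2_g − digamma(d_g/2) + log(d_g/2)`` to their
    expectations yields ``d0`` (via the trigamma inverse) and then ``s0²``.
    Zero excess spread in the observed log variances means the prior is
    infinitely informative (``d0 = inf``). Fewer than two usable proteins
    disables moderation (``d0 = 0``) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    usable = (df > 0) & (s2 > 0) & np.isfinite(s2)
    s2u, dfu = s2[usable], df[usable]
    G = len(s2u)
    if G < 2:
        warnings.warn(
            "fewer than 2 proteins with positive variance: moderation "
            "disabled (d0 = 0)",
            ModerationWarning,
            stacklevel=2,
        )
        s0 = float(s2u[0]) if G == 1 else float("nan")
        return ModerationPrior(d0=0.0, s02=s0)

    e = np.log(s2u) - digamma(dfu / 2.0) + np.log(dfu / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) * (G - 1) / G - float(
        np.mean(polygamma(1, dfu / 2.0))
    )
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return ModerationPrior(d0=d0, s02=s02)


#: Zero sample variances cannot enter the log-moment method; they are
#: pooled as if their variance were the smallest positive one scaled down
#: by this factor, and flagged.
ZERO_VARIANCE_SCALE = 1e-3


def moderated_test(
    fits: Sequence[ProteinFit], prior: ModerationPrior
) -> pd.DataFrame:
    """Moderated t statistic and two-sided p-value per usable protein.

    Returns an unsorted, unadjusted table with one row per usable protein:
    id, name, log2fc, t, p_value, plus the posterior variance and total
    degrees of freedom used.
    """
    usable = [f for f in fits if f.usable]
    if not usable:
        raise AnalysisError("no usable protein fits")
    s2 = np.array([f.s2 for f in usable])
    df = np.array([f.df for f in usable], dtype=float)
    b = np.array([f.effect for f in usable])
    u = np.array([f.u for f in usable])

    zero = s2 == 0.0
    s2_in = s2.copy()
    if zero.any():
        positive = s2[~zero]
        if positive.size:
            s2_in[zero] = positive.min() * ZERO_VARIANCE_SCALE
            warnings.warn(
                f"{int(zero.sum())} protein(s) with zero sample variance "
                f"pooled at {ZERO_VARIANCE_SCALE}× the smallest positive "
                f"variance",
                ModerationWarning,
                stacklevel=2,
            )
    post = prior.posterior(s2_in, df)

    denom = np.sqrt(post) * u
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, b / denom, np.where(b == 0, 0.0, np.inf * np.sign(b)))
    df_total = df + prior.d0
    if math.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)

    return pd.DataFrame(
        {
            "id": [f.id for f in usable],
            "name": [f.name for f in usable],
            "log2fc": b,
            "t": t,
            "p_value": p,
            "posterior_s2": post,
            "df_total": df_total,
            "zero_variance": zero,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the ascending order
    statistics, mapped back to the original positions.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class DiffExpResult:
    """Ranked differential-reactivity table plus the shared prior.

    ``table`` columns: id, name, log2fc, t, p_value, adj_p_value,
    significant — sorted ascending by adjusted p (ties broken by raw p,
    then id). The full table is retained; ``significant`` flags adjusted
    p below the threshold.
    """

    table: pd.DataFrame
    prior: ModerationPrior
    threshold: float
    contrast: tuple[str, str]
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant_ids(self) -> list[str]:
        return self.table.loc[self.table["significant"], "id"].tolist()

    def to_csv(self, sink: TextIO | str) -> None:
        cols = ["id", "name", "log2fc", "t", "p_value", "adj_p_value",
                "significant"]
        self.table[cols].to_csv(sink, index=False)


def build_results(
    rows: pd.DataFrame,
    prior: ModerationPrior,
    contrast: tuple[str, str],
    threshold: float = 0.05,
    excluded: Optional[pd.DataFrame] = None,
) -> DiffExpResult:
    """Adjust, flag and rank the per-protein test rows.

    BH is applied over all tested proteins (one family per contrast);
    adjusted p below ``threshold`` is significant.
    """
    if not 0.0 < threshold < 1.0:
        raise ContractError(f"threshold must be in (0, 1), got {threshold}")
    table = rows.copy()
    table["adj_p_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["adj_p_value"] < threshold
    table = table.sort_values(
        ["adj_p_value", "p_value", "id"], kind="stable"
    ).reset_index(drop=True)
    return DiffExpResult(
        table=table,
        prior=prior,
        threshold=threshold,
        contrast=contrast,
        excluded=excluded if excluded is not None else pd.DataFrame(),
    )


def differential_expression(
    matrix: ExperimentMatrix,
    design: DesignInfo,
    threshold: float = 0.05,
) -> DiffExpResult:
    """Full per-contrast analysis: fit, moderate, test, adjust, rank."""
    fits = fit_protein_models(matrix, design)
    usable = [f for f in fits if f.usable]
    prior = estimate_prior([f.s2 for f in usable], [f.df for f in usable])
    rows = moderated_test(fits, prior)
    excluded = pd.DataFrame(
        [(f.id, f.name, f.reason) for f in fits if not f.usable],
        columns=["id", "name", "reason"],
    )
    return build_results(rows, prior, design.contrast, threshold, excluded)


def group_summary(
    matrix: ExperimentMatrix, design: DesignInfo
) -> pd.DataFrame:
    """Per-protein, per-group five-number summary (boxplot statistics)."""
    matrix._require_stage("logged", "normalized")
    ids = matrix.row_keys().to_numpy()
    rows = []
    for g in design.groups:
        mask = np.array([sg == g for sg in design.sample_to_group])
        sub = matrix.values[:, mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanpercentile(sub, [0, 25, 50, 75, 100], axis=1)
        for i in range(matrix.n_proteins):
            rows.append((ids[i], g, *q[:, i]))
    return pd.DataFrame(
        rows, columns=["id", "group", "min", "q1", "median", "q3", "max"]
    )


def plot_protein(
    matrix: ExperimentMatrix,
    design: DesignInfo,
    protein_id: str,
    path: str,
) -> None:
    """Static per-group boxplot of one protein's processed signal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = matrix.row_keys().to_numpy()
    rows = np.nonzero(ids == protein_id)[0]
    if rows.size == 0:
        raise AnalysisError(f"protein {protein_id!r} not found")
    y = matrix.values[rows[0], :]
    data, labels = [], []
    for g in design.groups:
        mask = np.array([sg == g for sg in design.sample_to_group])
        vals = y[mask]
        data.append(vals[~np.isnan(vals)])
        labels.append(g)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("log2 signal")
    ax.set_title(protein_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
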