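"""Gene-set log-fold-change shift statistics.

The central readout of the transcriptomic analysis: given a per-gene table of
log2 fold changes (LFC) between two conditions and a named gene set, how far
is the set's LFC distribution shifted relative to the background?  The shift
statistic is a difference of medians,

    shift = median(LFC of set genes) - median(LFC of background genes),

where the background is either *all* table genes (the default) or the set's
complement.  Applied to the "sarcomere" GO category this statistic is called
sLFC; applied to genes upregulated in vivo between E18 and P2 it is called
vLFC.  Significance of the distribution shift is assessed with a two-sided
Wilcoxon rank-sum test of set versus complement (the set is never compared
against a background that contains it).

Also here: ECDF construction for the cumulative-distribution plots, derivation
of in vivo up/down gene sets from a developmental differential-expression
table, filtering of gene sets to genes expressed in a TPM matrix, and the
Z-score comparison of one shift value against a group of shift values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GeneSetError, ValidationError

logger = logging.getLogger(__name__)

BackgroundMode = Literal["all_genes", "complement"]

#: product-of-sample-sizes bound below which the rank-sum null is enumerated
#: exactly (given no ties) instead of normally approximated
EXACT_ENUMERATION_LIMIT = 400


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self):
        ids = frozenset(g.strip() for g in self.gene_ids)
        object.__setattr__(self, "gene_ids", ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class LfcTable:
    """Per-gene log2 fold changes and q-values for one comparison.

    ``data`` must have columns ``gene_id``, ``lfc``, ``qval`` with unique gene
    identifiers, finite LFC and q-values in [0, 1].
    """

    data: pd.DataFrame
    comparison_label: str = ""

    def __post_init__(self):
        required = {"gene_id", "lfc", "qval"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"LfcTable missing columns: {sorted(missing)}")
        df = self.data.copy()
        df["gene_id"] = df["gene_id"].astype(str).str.strip()
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id in LfcTable: {dup!r}")
        lfc = df["lfc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lfc)):
            raise ValidationError("non-finite lfc values in LfcTable")
        q = df["qval"].to_numpy(dtype=float)
        if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
            raise ValidationError("qval outside [0, 1] in LfcTable")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


# a developmental DE table has the same shape as an LFC table
DeTable = LfcTable


@dataclass(frozen=True)
class ShiftResult:
    """A set-vs-background LFC shift statistic with its Wilcoxon p-value."""

    statistic: float
    wilcoxon_p: float
    n_set: int
    n_background: int
    background_mode: BackgroundMode
    n_dropped: int = 0  # set genes absent from the table
    set_name: str = ""
    comparison_label: str = ""


@dataclass(frozen=True)
class Ecdf:
    """Right-continuous empirical CDF: F(x) = (# values <= x) / n."""

    values: np.ndarray  # sorted, unique
    fractions: np.ndarray  # non-decreasing, final element 1.0
    n: int

    def __call__(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        out = np.where(idx > 0, self.fractions[np.maximum(idx - 1, 0)], 0.0)
        return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class ZScoreResult:
    """A single value located within a reference group of values."""

    z: float
    p: float
    group_mean: float
    group_sd: float
    n_group: int


def compute_shift(
    table: LfcTable,
    gene_set: GeneSet,
    background_mode: BackgroundMode = "all_genes",
) -> ShiftResult:
    """Difference-of-medians shift of a gene set's LFCs against the background.

    The statistic uses ``background_mode`` (all table genes by default); the
    Wilcoxon rank-sum p-value always compares set versus complement so the two
    samples are disjoint.  Set genes absent from the table are dropped and
    counted in ``n_dropped``.
    """
    if background_mode not in ("all_genes", "complement"):
        raise ValidationError(f"unknown background_mode: {background_mode!r}")
    if len(gene_set) == 0:
        raise GeneSetError(f"gene set {gene_set.name!r} is empty")
    if len(table) == 0:
        raise GeneSetError("LFC table is empty")

    in_set = table.data["gene_id"].isin(gene_set.gene_ids).to_numpy()
    n_present = int(in_set.sum())
    n_dropped = len(gene_set) - n_present
    if n_present == 0:
        raise GeneSetError(
            f"no genes of set {gene_set.name!r} are present in table "
            f"{table.comparison_label!r}"
        )
    if n_dropped:
        logger.info(
            "set %r: %d of %d genes absent from table %r (dropped)",
            gene_set.name, n_dropped, len(gene_set), table.comparison_label,
        )

    lfc = table.data["lfc"].to_numpy(dtype=float)
    set_vals = lfc[in_set]
    complement_vals = lfc[~in_set]
    bg_vals = lfc if background_mode == "all_genes" else complement_vals
    if bg_vals.size == 0:
        raise GeneSetError("background is empty (set covers the whole table)")

    statistic = float(np.median(set_vals) - np.median(bg_vals))
    if complement_vals.size == 0:
        p = float("nan")  # set == whole table: no two-sample test possible
    else:
        p = wilcoxon_shift_test(set_vals, complement_vals)
    return ShiftResult(
        statistic=statistic,
        wilcoxon_p=p,
        n_set=n_present,
        n_background=int(bg_vals.size),
        background_mode=background_mode,
        n_dropped=n_dropped,
        set_name=gene_set.name,
        comparison_label=table.comparison_label,
    )


def _exact_ranksum_sf_cdf(ranks_x: np.ndarray, n: int, m: int) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) for the rank-sum W of the first sample under the
    null, by dynamic-programming enumeration over all C(n+m, n) assignments."""
    total = n + m
    w = int(ranks_x.sum())
    # count[k][s]: number of k-subsets of ranks 1..j with sum s
    max_sum = total * (total + 1) // 2
    counts = np.zeros((n + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, total + 1):
        kmax = min(r, n)
        for k in range(kmax, 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum - r + 1]
    dist = counts[n]
    norm = dist.sum()
    cdf = float(dist[: w + 1].sum() / norm)
    sf = float(dist[w:].sum() / norm)
    return cdf, sf


def wilcoxon_shift_test(
    set_values: Sequence[float], complement_values: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    The null distribution is enumerated exactly when the product of sample
    sizes is at most ``EXACT_ENUMERATION_LIMIT`` and there are no ties;
    otherwise a normal approximation with tie correction and a 0.5 continuity
    correction is used.
    """
    x = np.asarray(set_values, dtype=float)
    y = np.asarray(complement_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_shift_test requires two non-empty samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in rank-sum input")

    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    has_ties = np.unique(combined).size < combined.size
    ranks_x = ranks[:n]

    if n * m <= EXACT_ENUMERATION_LIMIT and not has_ties:
        cdf, sf = _exact_ranksum_sf_cdf(ranks_x, n, m)
        return min(1.0, 2.0 * min(cdf, sf))

    w = ranks_x.sum()
    u = w - n * (n + 1) / 2.0
    mu = n * m / 2.0
    total = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (total * (total - 1))
    sigma2 = n * m / 12.0 * ((total + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0  # all observations tied: no evidence of a shift
    num = u - mu
    num -= 0.5 * np.sign(num)  # continuity correction
    z = num / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def compute_ecdf(values: Iterable[float]) -> Ecdf:
    """ECDF of a sample, as plotted in the cumulative LFC distributions."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise ValidationError("compute_ecdf requires a non-empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite values in ECDF input")
    n = arr.size
    fracs = np.arange(1, n + 1) / n
    uniq, last_idx = np.unique(arr, return_index=True)
    # fraction at a value = fraction of the *last* occurrence of that value
    idx = np.searchsorted(arr, uniq, side="right") - 1
    return Ecdf(values=uniq, fractions=fracs[idx], n=n)


def derive_invivo_sets(
    de_table: DeTable, q_threshold: float = 0.05
) -> tuple[GeneSet, GeneSet]:
    """Split a developmental DE table into up/down-regulated gene sets.

    up = {q < threshold, lfc > 0}; down = {q < threshold, lfc < 0}; genes with
    lfc exactly 0 belong to neither.
    """
    df = de_table.data
    sig = df["qval"].to_numpy(dtype=float) < q_threshold
    lfc = df["lfc"].to_numpy(dtype=float)
    up_ids = frozenset(df.loc[sig & (lfc > 0), "gene_id"])
    down_ids = frozenset(df.loc[sig & (lfc < 0), "gene_id"])
    return (GeneSet("invivo_up", up_ids), GeneSet("invivo_down", down_ids))


def filter_expressed(
    gene_set: GeneSet,
    tpm: pd.DataFrame,
    min_tpm: float = 1.0,
    min_samples: int = 1,
) -> GeneSet:
    """Restrict a gene set to genes expressed in a TPM matrix (genes x samples).

    A gene is expressed if its TPM is >= ``min_tpm`` in at least
    ``min_samples`` samples.  Genes absent from the matrix are dropped.
    """
    if (tpm.to_numpy(dtype=float) < 0).any():
        raise ValidationError("TPM matrix contains negative values")
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    index = tpm.index.astype(str).str.strip()
    present = [g for g in gene_set.gene_ids if g in set(index)]
    sub = tpm.set_axis(index, axis=0).loc[present]
    n_ok = (sub.to_numpy(dtype=float) >= min_tpm).sum(axis=1)
    kept = frozenset(np.asarray(present, dtype=object)[n_ok >= min_samples])
    return GeneSet(f"{gene_set.name}_expressed", kept)


def zscore_vs_group(value: float, group: Sequence[float]) -> ZScoreResult:
    """Locate one shift value within a reference group of shift values.

    z uses the group's sample standard deviation (n-1 denominator); p is the
    two-sided standard-normal tail probability.
    """
    g = np.asarray(group, dtype=float)
    if g.size < 2:
        raise ValidationError("zscore_vs_group requires a group of >= 2 values")
    sd = float(np.std(g, ddof=1))
    if sd <= 0:
        raise ValidationError("group standard deviation is zero")
    mean = float(np.mean(g))
    z = (float(value) - mean) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ZScoreResult(z=z, p=min(1.0, p), group_mean=mean, group_sd=sd, n_group=g.size)


def run_shift_panel(
    tables: Sequence[LfcTable],
    sets: Sequence[GeneSet],
    background_mode: BackgroundMode = "all_genes",
) -> pd.DataFrame:
    """Shift statistic for every (table, set) pair, as in the bar-panel figures.

    Rows are ordered by comparison label then set name.  A cell whose set has
    no genes in its table is flagged ``missing`` instead of aborting the panel.
    """
    if not tables or not sets:
        raise ValidationError("run_shift_panel requires >= 1 table and >= 1 set")
    rows = []
    for table in sorted(tables, key=lambda t: t.comparison_label):
        for gs in sorted(sets, key=lambda s: s.name):
            try:
                r = compute_shift(table, gs, background_mode)
                rows.append(
                    dict(
                        comparison=table.comparison_label, set=gs.name,
                        statistic=r.statistic, wilcoxon_p=r.wilcoxon_p,
                        n_set=r.n_set, n_background=r.n_background,
                        n_dropped=r.n_dropped, status="ok",
                    )
                )
            except GeneSetError as exc:
                logger.warning("panel cell (%s, %s) missing: %s",
                               table.comparison_label, gs.name, exc)
                rows.append(
                    dict(
                        comparison=table.comparison_label, set=gs.name,
                        statistic=np.nan, wilcoxon_p=np.nan,
                        n_set=0, n_background=0, n_dropped=len(gs),
                        status="missing",
                    )
                )
    return pd.DataFrame(rows)
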