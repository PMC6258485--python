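"""Gene-level enrichment testing for positive-selection pooled screens.

The analysis follows the MAGeCK-style pipeline in three stages:

1. **Guide-level null.** A mean-variance model fitted across guides maps a
   guide's control abundance m to a null variance v(m) = m + exp(a) m^b
   (negative binomial; v(m) clamped at the Poisson floor m). Each guide's
   enrichment p-value is the upper tail P(X >= treatment count) under this
   null with mean equal to the control count (floored at a pseudocount).
   With a single control column replicate variance is unavailable and the
   model falls back to Poisson; downstream gene tests are rank-based, so
   miscalibration of the absolute guide p-values largely cancels.

2. **Modified robust rank aggregation (alpha-RRA).** Guide p-values are
   converted to percentile ranks over the whole library (non-targeting
   controls included in the ranking pool). For a gene with k guides whose
   sorted ranks are r(1) <= ... <= r(k), only guides significant at the
   `alpha` cutoff contribute; the gene score is
   rho = min_j BetaCDF(r(j); j, k - j + 1) over contributing j, the
   classical order-statistic tail. Genes with no contributing guide score
   rho = 1. Significance of rho comes from a permutation null: k ranks are
   drawn at random (without replacement from the observed rank pool when
   the library is small, the iid-uniform limit otherwise) and rho is
   recomputed under the same selection rule; the p-value is
   (1 + #{null rho <= observed}) / (1 + n_perm). Nulls are cached per k.

3. **FDR.** Benjamini-Hochberg across genes; candidate hits are typically
   called at FDR < 0.1.

Multiple sorted-cell replicates are combined by taking each guide's median
p-value across replicates before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .guide_design import CONTROL_GENE
from .screen_counts import CountTable, NormalizedCounts, normalize_total

logger = logging.getLogger(__name__)

#: Library size below which the permutation null samples ranks without
#: replacement from the observed finite rank pool (exact exchangeability);
#: above it the iid-uniform approximation is indistinguishable and cheaper.
FINITE_POOL_THRESHOLD = 1000


@dataclass(frozen=True)
class MeanVarianceModel:
    """Power-law excess-variance model v(m) = m + exp(intercept) m^slope."""

    intercept: float
    slope: float
    fallback_poisson: bool = False

    def variance(self, mean: np.ndarray | float) -> np.ndarray:
        m = np.asarray(mean, dtype=float)
        if self.fallback_poisson:
            return m.copy()
        with np.errstate(divide="ignore"):
            excess = np.exp(self.intercept + self.slope * np.log(np.maximum(m, 1e-300)))
        return np.maximum(m + excess, m)


def fit_mean_variance(
    control_values: pd.DataFrame,
    *,
    min_usable_guides: int = 10,
    n_bins: int = 20,
) -> MeanVarianceModel:
    """Fit the excess-variance power law from replicate control columns.

    Per-guide means and variances are pooled into mean-quantile bins and
    the mean excess variance (var - mean) per bin is regressed on the bin
    mean, both on the log scale. Binning averages away the large sampling
    noise of per-guide variance estimates, so Poisson-distributed input
    recovers near-zero excess instead of the upward bias a per-guide
    var>mean regression would give. Falls back to Poisson when fewer than
    two replicates, too few usable guides, or fewer than two bins with
    positive excess are available.
    """
    if control_values.shape[1] < 2:
        return MeanVarianceModel(0.0, 0.0, fallback_poisson=True)
    m = control_values.mean(axis=1).to_numpy(dtype=float)
    v = control_values.var(axis=1, ddof=1).to_numpy(dtype=float)
    ok = m > 0
    if (v[ok] > m[ok]).sum() < min_usable_guides:
        logger.warning("mean-variance fit: too few overdispersed guides; "
                       "falling back to Poisson")
        return MeanVarianceModel(0.0, 0.0, fallback_poisson=True)
    m, v = m[ok], v[ok]
    order = np.argsort(m)
    bins = np.array_split(order, min(n_bins, max(2, len(order) // 50)))
    bin_mean, bin_excess = [], []
    for idx in bins:
        if len(idx) == 0:
            continue
        mu = m[idx].mean()
        ex = (v[idx] - m[idx]).mean()
        if mu > 0 and ex > 0:
            bin_mean.append(mu)
            bin_excess.append(ex)
    if len(bin_mean) < 2:
        return MeanVarianceModel(0.0, 0.0, fallback_poisson=True)
    slope, intercept = np.polyfit(np.log(bin_mean), np.log(bin_excess), 1)
    return MeanVarianceModel(float(intercept), float(slope))


def guide_pvalues(
    norm: NormalizedCounts,
    control: str,
    treatment: str,
    model: MeanVarianceModel,
    *,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-sided enrichment p-values per guide.

    p_enrich = P(X >= treatment count) with X negative-binomial (or
    Poisson) with mean = control count floored at `pseudocount` and
    variance from the model. Treatment counts are normalized reals; the
    tail is evaluated at their ceiling, so a count of 0 gives p = 1.
    """
    for col in (control, treatment):
        if col not in norm.values.columns:
            raise KeyError(f"sample {col!r} not in normalized table")
    m = np.maximum(norm.values[control].to_numpy(dtype=float), pseudocount)
    t = np.ceil(norm.values[treatment].to_numpy(dtype=float)).astype(np.int64)
    v = model.variance(m)
    # work in log space: extreme enrichments underflow double precision,
    # and their ordering must survive for the rank aggregation
    logp = np.empty(len(m), dtype=float)
    nb = v > m * (1 + 1e-9)
    if nb.any():
        r = m[nb] ** 2 / (v[nb] - m[nb])
        prob = r / (r + m[nb])
        logp[nb] = stats.nbinom.logsf(t[nb] - 1, r, prob)
    if (~nb).any():
        logp[~nb] = stats.poisson.logsf(t[~nb] - 1, m[~nb])
    logp = np.minimum(logp, 0.0)
    p = np.clip(np.exp(logp), np.nextafter(0, 1), 1.0)
    return pd.DataFrame({
        "guide_id": norm.values.index,
        "gene": norm.gene_map.loc[norm.values.index].to_numpy(),
        "control_mean": m,
        "treatment_count": norm.values[treatment].to_numpy(dtype=float),
        "p_enrich": p,
        "log_p_enrich": logp,
    }).set_index("guide_id")


def assign_percentile_ranks(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Attach rank_index (1..n, unique; ties broken by guide id) and
    percentile_rank = rank_index / n over all guides jointly.

    Ordering uses the log tail probability when available, so guides whose
    p-values underflow to the same clipped double still rank by evidence.
    """
    df = stats_df.copy()
    key = (df["log_p_enrich"] if "log_p_enrich" in df.columns
           else df["p_enrich"]).to_numpy()
    order = np.lexsort((df.index.to_numpy(), key))
    rank = np.empty(len(df), dtype=np.int64)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank_index"] = rank
    df["percentile_rank"] = rank / len(df)
    return df


def _rho_from_sorted(sorted_ranks: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """rho for rows of sorted percentile ranks with a boolean selection
    mask; rows with no selected entry get rho = 1."""
    n_row, k = sorted_ranks.shape
    j = np.arange(1, k + 1)
    betas = stats.beta.cdf(sorted_ranks, j[None, :], (k - j + 1)[None, :])
    betas = np.where(selected, betas, 1.0)
    rho = betas.min(axis=1)
    return rho


class _NullCache:
    """Permutation null distributions of rho, cached per guide count k."""

    def __init__(self, n_total: int, n_below: int, n_perm: int, seed: int):
        self.n_total = n_total
        self.n_below = n_below
        self.n_perm = n_perm
        self.seed = seed
        self._cache: dict[int, np.ndarray] = {}

    def null_rho(self, k: int) -> np.ndarray:
        if k not in self._cache:
            rng = np.random.default_rng([self.seed % (2**31), k])
            if self.n_total < FINITE_POOL_THRESHOLD:
                # exact exchangeability: k of the n observed grid ranks,
                # without replacement
                keys = rng.random((self.n_perm, self.n_total))
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
                idx.sort(axis=1)
                ranks = (idx + 1) / self.n_total
                selected = idx + 1 <= self.n_below
            else:
                u = rng.random((self.n_perm, k))
                u.sort(axis=1)
                ranks = u
                selected = u <= self.n_below / self.n_total
            self._cache[k] = _rho_from_sorted(ranks, selected)
        return self._cache[k]


def alpha_rra(
    ranked_stats: pd.DataFrame,
    *,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Gene-level alpha-RRA scores and permutation p-values.

    `ranked_stats` must carry gene, p_enrich, rank_index and
    percentile_rank columns (see :func:`assign_percentile_ranks`). Only
    guides with p_enrich < alpha contribute to a gene's rho; the
    permutation null applies the matching selection rule (a drawn rank is
    selected iff it falls below the library-wide selected fraction).
    Returns a DataFrame indexed by gene: n_guides, n_selected, rho,
    p_value.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_total = len(ranked_stats)
    n_below = int((ranked_stats["p_enrich"] < alpha).sum())
    cache = _NullCache(n_total, n_below, n_perm, seed)

    if genes is None:
        genes = sorted(ranked_stats["gene"].unique())
    rows = []
    grouped = ranked_stats.groupby("gene")
    for gene in genes:
        try:
            grp = grouped.get_group(gene)
        except KeyError:
            raise ValueError(f"gene {gene!r} has no guides")
        k = len(grp)
        idx = np.sort(grp["rank_index"].to_numpy())
        sel = idx <= n_below
        rho = float(_rho_from_sorted((idx / n_total)[None, :], sel[None, :])[0])
        null = cache.null_rho(k)
        p = (1 + int((null <= rho).sum())) / (1 + n_perm)
        rows.append((gene, k, int(sel.sum()), rho, p))
    return pd.DataFrame(
        rows, columns=["gene", "n_guides", "n_selected", "rho", "p_value"]
    ).set_index("gene")


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return multipletests(p, method="fdr_bh")[1]


def run_screen_test(
    table: CountTable,
    control: str,
    treatments: str | Sequence[str],
    *,
    exclude_genes: Iterable[str] = (),
    control_gene: str = CONTROL_GENE,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    pseudocount: float = 1.0,
    variance_columns: Sequence[str] | None = None,
    model: MeanVarianceModel | None = None,
) -> pd.DataFrame:
    """Full gene-level enrichment test for one screen.

    Normalizes to CPM, computes guide p-values per treatment replicate
    against `control`, combines replicates by the per-guide median, ranks
    all guides jointly (non-targeting controls stay in the ranking pool but
    are not tested as a gene), runs alpha-RRA per gene, and attaches BH
    FDR and 1-based ranks ordered by significance.

    `variance_columns` names the replicate columns used to fit the
    mean-variance model (default: the control column alone, i.e. Poisson
    fallback).
    """
    if isinstance(treatments, str):
        treatments = [treatments]
    if control in treatments:
        raise ValueError("control and treatment must be different samples")
    norm = normalize_total(table)
    if model is None:
        vcols = list(variance_columns) if variance_columns else [control]
        model = fit_mean_variance(norm.values[vcols])

    per_rep = [
        guide_pvalues(norm, control, t, model, pseudocount=pseudocount)
        for t in treatments
    ]
    combined = per_rep[0].copy()
    if len(per_rep) > 1:
        # median commutes with exp, so combining in log space preserves
        # both the p-values and the saturation-safe ordering
        combined["log_p_enrich"] = np.median(
            np.column_stack([d["log_p_enrich"].to_numpy() for d in per_rep]), axis=1
        )
        combined["p_enrich"] = np.clip(
            np.exp(combined["log_p_enrich"]), np.nextafter(0, 1), 1.0)
    ranked = assign_percentile_ranks(combined)

    excluded = set(exclude_genes) | {control_gene}
    test_genes = sorted(set(ranked["gene"].unique()) - excluded)
    res = alpha_rra(ranked, alpha=alpha, n_perm=n_perm, seed=seed, genes=test_genes)
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    res = res.sort_values(["p_value", "rho", "gene"], kind="mergesort")
    res["rank"] = np.arange(1, len(res) + 1)
    return res


def write_gene_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", float_format="%.6g")


def reanalyze_screens(
    table: CountTable,
    *,
    control: str = "plasmid",
    pooled_antibody_prefix: str = "8aB_rep",
    exclude_genes: tuple[str, ...] = ("ITGB3", "MEGF10"),
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> Mapping[str, pd.DataFrame]:
    """Standard reanalysis of a deposited screen count table.

    Runs one pooled-antibody test (the replicate columns sharing
    `pooled_antibody_prefix` against `control`, no gene exclusions) and
    one single-column test per remaining probe column with `exclude_genes`
    removed. Columns named like unsorted timepoints (d7/d12*) are skipped.
    """
    screens: dict[str, pd.DataFrame] = {}
    cols = [c for c in table.samples if c != control]
    pooled = [c for c in cols if c.startswith(pooled_antibody_prefix)]
    if pooled:
        screens["pooled_antibody"] = run_screen_test(
            table, control, pooled, alpha=alpha, n_perm=n_perm, seed=seed,
        )
    for col in cols:
        if col in pooled or col.startswith(("d7", "d12")):
            continue
        screens[col] = run_screen_test(
            table, control, [col], exclude_genes=exclude_genes,
            alpha=alpha, n_perm=n_perm, seed=seed,
        )
    return screens
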