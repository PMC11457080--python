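"""Per-species two-group differential expression on read-count matrices.

The model is the standard negative-binomial (NB) count model with variance
``mu + alpha * mu**2``. The pipeline is:

1. median-of-ratios size factors (rescaled to geometric mean 1);
2. per-gene method-of-moments dispersion from the pooled within-group
   variance of normalized counts, floored at 1e-8;
3. log2 fold change (HL over LL) from normalized group means with a 0.5
   pseudo-count guard, a delta-method standard error, and a Wald statistic
   referred to a Student-t distribution with ``n1 + n2 - 2`` degrees of
   freedom (the t reference accounts for the dispersion being estimated
   from few replicates; a plain normal reference is anticonservative at
   n = 5 per group);
4. Benjamini-Hochberg adjustment over tested genes and up/down/ns calls at
   ``alpha_sig`` applied to the adjusted p-value.

Independent filtering: genes whose base mean falls below a low quantile of
the nonzero base means are reported with ``padj`` absent and
``call = "untested"`` — mirroring analyses whose universe is "genes for
which an adjusted P-value could be calculated".
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, validate_sample_table

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "wald_de_test",
    "adjust_bh",
    "summarize_deg_counts",
    "deg_percentages",
]

DISPERSION_FLOOR = 1e-8
CALL_CATEGORIES = ["up", "down", "ns", "untested"]


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples, computed
    over genes with nonzero counts in every sample.
    """
    values = counts.counts.to_numpy(dtype=float)
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    logs = np.log(values[all_nonzero])
    log_ref = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_ref, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.sample_ids, name="size_factor")


def _group_indices(samples: pd.DataFrame, sample_ids) -> Tuple[np.ndarray, np.ndarray]:
    sub = samples.set_index("sample_id").loc[list(sample_ids)]
    hl = np.flatnonzero((sub["treatment"] == "HL").to_numpy())
    ll = np.flatnonzero((sub["treatment"] == "LL").to_numpy())
    return hl, ll


def estimate_dispersion(
    norm_counts: pd.DataFrame, samples: pd.DataFrame
) -> pd.Series:
    """Method-of-moments NB dispersion per gene.

    ``alpha = max(0, (pooled within-group variance - mean) / mean**2)``,
    floored at 1e-8. Zero-mean genes get alpha 0 (they are flagged as
    untestable downstream).
    """
    hl, ll = _group_indices(samples, norm_counts.columns)
    if len(hl) < 2 or len(ll) < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates per group")
    y = norm_counts.to_numpy(dtype=float)
    parts = []
    for idx in (hl, ll):
        g = y[:, idx]
        parts.append(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    pooled_var = (parts[0] + parts[1]) / (len(hl) + len(ll) - 2)
    mean = y.mean(axis=1)
    alpha = np.zeros_like(mean)
    nz = mean > 0
    alpha[nz] = np.maximum((pooled_var[nz] - mean[nz]) / mean[nz] ** 2, 0.0)
    return pd.Series(alpha, index=norm_counts.index, name="dispersion")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement.

    NaN entries are excluded from the adjustment and stay NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def wald_de_test(
    counts: CountMatrix,
    samples: pd.DataFrame,
    alpha_sig: float = 0.05,
    min_basemean_quantile: float = 0.10,
) -> pd.DataFrame:
    """NB Wald contrast of HL vs LL for one species.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc``, ``se_log2fc``, ``pvalue``, ``padj`` and ``call`` in
    {up, down, ns, untested}.
    """
    samples = validate_sample_table(samples)
    sub = samples[samples["sample_id"].isin(counts.sample_ids)]
    sub = sub[sub["species_id"] == counts.species_id] if (
        (sub["species_id"] == counts.species_id).any()
    ) else sub
    sample_ids = [s for s in counts.sample_ids if s in set(sub["sample_id"])]
    if not sample_ids:
        raise ValueError("no samples in the table match the count matrix")
    mat = CountMatrix(
        counts.species_id, counts.counts[sample_ids], counts.gene_lengths
    )
    hl, ll = _group_indices(sub, sample_ids)
    if len(hl) < 2 or len(ll) < 2:
        raise ValueError("need >= 2 replicates in both HL and LL")

    sf = size_factors(mat)
    norm = mat.counts.to_numpy(dtype=float) / sf.to_numpy()
    norm_df = pd.DataFrame(norm, index=mat.gene_ids, columns=sample_ids)
    alpha = estimate_dispersion(norm_df, sub).to_numpy()
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    n1, n2 = len(hl), len(ll)
    m_hl = norm[:, hl].mean(axis=1)
    m_ll = norm[:, ll].mean(axis=1)
    base_mean = norm.mean(axis=1)

    g_hl = m_hl + 0.5
    g_ll = m_ll + 0.5
    log2fc = np.log2(g_hl / g_ll)
    var_hl = (g_hl + alpha * g_hl**2) / n1
    var_ll = (g_ll + alpha * g_ll**2) / n2
    se = np.sqrt(var_hl / g_hl**2 + var_ll / g_ll**2) / np.log(2)
    wald = log2fc / se
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)

    zero = base_mean == 0
    pvalue[zero] = np.nan

    nonzero_bm = base_mean[base_mean > 0]
    threshold = (
        np.quantile(nonzero_bm, min_basemean_quantile) if len(nonzero_bm) else 0.0
    )
    untested = zero | (base_mean < threshold) | np.isnan(pvalue)

    p_for_adjust = np.where(untested, np.nan, pvalue)
    padj = adjust_bh(p_for_adjust)

    call = np.full(len(base_mean), "ns", dtype=object)
    call[untested] = "untested"
    sig = ~np.isnan(padj) & (padj < alpha_sig)
    call[sig & (log2fc > 0)] = "up"
    call[sig & (log2fc < 0)] = "down"

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "pvalue": pvalue,
            "padj": padj,
            "call": pd.Categorical(call, categories=CALL_CATEGORIES),
        },
        index=mat.gene_ids,
    )


def deg_percentages(n_up: int, n_down: int, n_unchanged: int) -> Tuple[float, float, float]:
    """One-decimal percentages of up/down/unchanged over their total."""
    total = n_up + n_down + n_unchanged
    if total == 0:
        raise ValueError("empty DEG summary")
    return tuple(round(100.0 * n / total, 1) for n in (n_up, n_down, n_unchanged))


def summarize_deg_counts(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-species counts and one-decimal percentages of up/down/unchanged.

    Untested genes are excluded from both the counts and the denominator.
    """
    rows = {}
    for species, table in results.items():
        n_up = int((table["call"] == "up").sum())
        n_down = int((table["call"] == "down").sum())
        n_ns = int((table["call"] == "ns").sum())
        pct = deg_percentages(n_up, n_down, n_ns)
        rows[species] = {
            "n_up": n_up,
            "n_down": n_down,
            "n_unchanged": n_ns,
            "pct_up": pct[0],
            "pct_down": pct[1],
            "pct_unchanged": pct[2],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species_id"
    return out


def read_de_table(path) -> pd.DataFrame:
    """Read a DE result TSV produced by :func:`write_de_table`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["call"] = pd.Categorical(df["call"], categories=CALL_CATEGORIES)
    return df


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
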