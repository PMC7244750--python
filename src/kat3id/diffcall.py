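"""Negative-binomial two-group differential testing with BH correction.

A deliberately small stand-in for DESeq2/DiffBind-style callers, applied
uniformly to gene counts and region counts: median-of-ratios normalization,
per-feature method-of-moments dispersion (Var = mu + alpha * mu^2), a Wald
test on the log2 fold change with a delta-method standard error, and
Benjamini-Hochberg adjustment. Its validity is established by simulation
calibration, not by matching any external tool's output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["feature", "baseMean", "log2FC", "p", "padj", "status"]


def _as_matrix(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("count matrix contains negative entries")
    return x


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean over features positive in
    every sample. If no such feature exists, ``pseudo_reference=True`` falls
    back to an add-1 reference over all features.
    """
    x = _as_matrix(counts)
    allpos = (x > 0).all(axis=1)
    if allpos.any():
        ref = np.exp(np.log(x[allpos]).mean(axis=1))
        ratios = x[allpos] / ref[:, None]
    elif pseudo_reference:
        x1 = x + 1.0
        ref = np.exp(np.log(x1).mean(axis=1))
        ratios = x1 / ref[:, None]
    else:
        raise ValueError(
            "no feature has positive counts in all samples; "
            "enable the pseudo-reference fallback (add-1 reference)"
        )
    s = np.median(ratios, axis=0)
    if (s <= 0).any():
        raise ValueError("degenerate size factors; counts too sparse")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def _split_groups(
    counts: pd.DataFrame, samples: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    samples = samples.set_index("sample").loc[counts.columns]
    geno = samples["genotype"].to_numpy()
    is_ko = geno == "KO"
    is_ctrl = geno == "control"
    if is_ko.sum() < 2 or is_ctrl.sum() < 2:
        raise ValueError(
            "need both genotypes ('control' and 'KO') with >= 2 replicates"
        )
    return is_ko, is_ctrl


def nb_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Per-feature Wald test of KO vs control on normalized NB counts.

    log2FC = log2((mean_KO + c0) / (mean_ctrl + c0)) with c0 = 0.5. The
    variance of each group mean is (mu + alpha * mu^2) / n with a pooled
    within-group method-of-moments dispersion floored at 1e-8, propagated to
    the log scale by the delta method. The Wald statistic is referred to a
    Student t with n1 + n2 - 2 degrees of freedom, the small-sample reference
    under which the test is calibrated (see docs/methods.md). ``padj`` and
    ``status`` are left unset (NaN / "ns"); see :func:`bh_adjust` and
    :func:`call_significant`.
    """
    is_ko, is_ctrl = _split_groups(counts, samples)
    x = _as_matrix(counts)
    sf = size_factors(counts, pseudo_reference=pseudo_reference).to_numpy()
    norm = x / sf[None, :]
    ko, ct = norm[:, is_ko], norm[:, is_ctrl]
    n1, n2 = ko.shape[1], ct.shape[1]
    m1, m2 = ko.mean(axis=1), ct.mean(axis=1)
    v1, v2 = ko.var(axis=1, ddof=1), ct.var(axis=1, ddof=1)
    mu = norm.mean(axis=1)
    # Var(X_j / s_j) = q / s_j + alpha q^2 for X_j ~ NB(s_j q, alpha), so the
    # Poisson part of the normalized-count variance carries a mean 1/s factor
    inv1 = np.mean(1.0 / sf[is_ko])
    inv2 = np.mean(1.0 / sf[is_ctrl])
    w = ((n1 - 1) * inv1 + (n2 - 1) * inv2) / (n1 + n2 - 2)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            mu > 0, (pooled_var - mu * w) / np.maximum(mu, 1e-300) ** 2, 0.0
        )
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    var_m1 = (m1 * inv1 + alpha * m1**2) / n1
    var_m2 = (m2 * inv2 + alpha * m2**2) / n2
    lfc = np.log2((m1 + PSEUDOCOUNT) / (m2 + PSEUDOCOUNT))
    se = np.sqrt(
        var_m1 / (m1 + PSEUDOCOUNT) ** 2 + var_m2 / (m2 + PSEUDOCOUNT) ** 2
    ) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    allzero = (x == 0).all(axis=1)
    p = np.where(allzero, 1.0, np.clip(p, 0.0, 1.0))
    lfc = np.where(allzero, 0.0, lfc)
    return pd.DataFrame(
        {
            "feature": counts.index,
            "baseMean": mu,
            "log2FC": lfc,
            "p": p,
            "padj": np.nan,
            "status": "ns",
        },
        columns=DE_COLUMNS,
    )


def bh_adjust(pvals: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-free)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    strict_lfc: bool = False,
) -> pd.DataFrame:
    """Label features up/down/ns at FDR < alpha and |log2FC| >= min_abs_lfc.

    The boundary |log2FC| == min_abs_lfc counts as significant by default;
    ``strict_lfc=True`` switches the comparator to a strict inequality.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = results.copy()
    if out["padj"].isna().any():
        raise ValueError("padj is unset; run bh_adjust first")
    lfc = out["log2FC"].to_numpy()
    passes = (
        np.abs(lfc) > min_abs_lfc if strict_lfc else np.abs(lfc) >= min_abs_lfc
    )
    sig = (out["padj"].to_numpy() < alpha) & passes
    status = np.where(sig & (lfc < 0), "down", np.where(sig & (lfc > 0), "up", "ns"))
    out["status"] = status
    return out


def run_diffcall(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    strict_lfc: bool = False,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """nb_test -> bh_adjust -> call_significant in one step."""
    res = nb_test(counts, samples, pseudo_reference=pseudo_reference)
    res["padj"] = bh_adjust(res["p"].to_numpy())
    return call_significant(res, alpha=alpha, min_abs_lfc=min_abs_lfc,
                            strict_lfc=strict_lfc)
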