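"""The three significance procedures on condition-grouped effective densities.

Genes with condition-dependent fitness are called three ways, each looking
at the same per-gene effective densities from a different angle:

1. log2 fold change of condition-mean ED (reference / treatment), flagged
   when |log2FC| > 1, i.e. more than a two-fold difference;
2. ordinary least squares of treatment mean ED on reference mean ED, with
   Cook's distance flagging genes whose removal would materially move the
   fit (threshold 4/n, n = genes in the regression);
3. Welch's unequal-variance t-test across replicates, two-sided, flagged at
   p <= 0.05 and p <= 0.01 on the raw p-value (Benjamini-Hochberg adjusted
   p is reported alongside but drives no flag).

Genes called by all three are the consensus set. The statistics are computed
from explicit closed forms here; library implementations serve as
cross-checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .formats_io import SampleSheet
from .gene_assignment import GeneSiteMatrix

logger = logging.getLogger(__name__)


def comparison_conditions(sheet: SampleSheet) -> tuple[str, str]:
    """The (reference, treatment) condition pair, in sheet order."""
    conds = sheet.conditions()
    if len(conds) != 2:
        raise ValidationError(
            f"a comparison needs exactly 2 conditions among included samples, "
            f"got {conds}"
        )
    return conds[0], conds[1]


def _ed_pivot(div: pd.DataFrame) -> pd.DataFrame:
    """locus_tag x sample_id matrix of effective densities."""
    return div.pivot(index="locus_tag", columns="sample_id", values="ED")


def mean_ed_by_condition(
    div: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """Arithmetic mean ED per gene per condition (columns mean_ED_A, mean_ED_B)."""
    cond_a, cond_b = comparison_conditions(sheet)
    pivot = _ed_pivot(div)
    out = pd.DataFrame(index=pivot.index)
    for label, cond in (("mean_ED_A", cond_a), ("mean_ED_B", cond_b)):
        samples = [s for s in sheet.samples_for(cond) if s in pivot.columns]
        if not samples:
            raise ValidationError(f"condition {cond!r} has no samples in the matrix")
        if len(samples) == 1:
            logger.warning(
                "condition %r has a single replicate; means equal that replicate "
                "and only fold-change statistics are meaningful", cond,
            )
        out[label] = pivot[samples].mean(axis=1)
    return out.reset_index()


def log2_fold_change(
    mean_ed_a: np.ndarray, mean_ed_b: np.ndarray, cutoff: float = 1.0
) -> pd.DataFrame:
    """log2(mean_ED_A / mean_ED_B) with hit flags and depletion direction.

    Positive values mean transposon diversity is lower in condition B, i.e.
    disrupting the gene carries a fitness cost there. A condition mean of
    zero gives a signed infinite fold change (still a hit); both zero gives
    0 with no hit. The hit rule is strict: |log2FC| > cutoff.
    """
    a = np.asarray(mean_ed_a, dtype=float)
    b = np.asarray(mean_ed_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("mean effective densities must be non-negative")
    with np.errstate(divide="ignore"):
        fc = np.where(
            (a == 0) & (b == 0), 0.0,
            np.where(
                b == 0, np.inf,
                np.where(a == 0, -np.inf, np.log2(np.divide(a, b, out=np.ones_like(a), where=b > 0))),
            ),
        )
    hit = np.abs(fc) > cutoff
    direction = np.where(
        a > b, "lower_in_B", np.where(b > a, "lower_in_A", "none")
    )
    return pd.DataFrame({"log2FC": fc, "log2fc_hit": hit, "direction": direction})


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    n: int
    cooks_d: np.ndarray          # aligned with the finite-mask entries
    influential: np.ndarray
    residual_sign: np.ndarray
    finite_mask: np.ndarray      # which input genes entered the regression


def regression_cooks(
    mean_ed_a: np.ndarray, mean_ed_b: np.ndarray, threshold_factor: float = 4.0
) -> RegressionResult:
    """OLS of treatment mean ED on reference mean ED, plus Cook's distances.

    Cook's distance D_g = r_g^2 h_g / (p * MSE * (1 - h_g)^2) with p = 2
    parameters (intercept and slope); genes with D > 4/n are influential.
    Genes with non-finite means (infinite fold changes) are excluded from
    the fit but preserved via ``finite_mask``.
    """
    a = np.asarray(mean_ed_a, dtype=float)
    b = np.asarray(mean_ed_b, dtype=float)
    finite = np.isfinite(a) & np.isfinite(b)
    x, y = a[finite], b[finite]
    n = x.size
    if n < 10:
        raise ValidationError(f"regression needs >= 10 genes with finite means, got {n}")
    x_bar = x.mean()
    sxx = np.sum((x - x_bar) ** 2)
    if sxx == 0 or np.ptp(x) == 0:
        raise ValidationError("zero variance in the reference condition means")
    slope = np.sum((x - x_bar) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x_bar
    resid = y - (intercept + slope * x)
    rss = np.sum(resid**2)
    tss = np.sum((y - y.mean()) ** 2)
    p = 2
    mse = rss / (n - p)
    leverage = 1.0 / n + (x - x_bar) ** 2 / sxx
    if mse == 0:
        cooks = np.zeros(n)
    else:
        cooks = resid**2 * leverage / (p * mse * (1 - leverage) ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        adj_r2=float(adj_r2),
        n=n,
        cooks_d=cooks,
        influential=cooks > threshold_factor / n,
        residual_sign=np.sign(resid),
        finite_mask=finite,
    )


def welch_test(div: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Welch's two-sided t-test on per-replicate ED, gene by gene.

    Satterthwaite degrees of freedom; p from the t distribution. Genes where
    both conditions have zero variance are degenerate: equal means report
    t = 0, p = 1; different means report p = 0 (the data admit no noise
    model), both flagged in the ``degenerate`` column. Raw p drives the
    sig05/sig01 flags; the p_adj column carries Benjamini-Hochberg adjusted
    values computed across all tested genes.
    """
    cond_a, cond_b = comparison_conditions(sheet)
    pivot = _ed_pivot(div)
    sa = [s for s in sheet.samples_for(cond_a) if s in pivot.columns]
    sb = [s for s in sheet.samples_for(cond_b) if s in pivot.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError(
            f"Welch's test needs >= 2 replicates per condition, got "
            f"{len(sa)} vs {len(sb)}"
        )
    xa = pivot[sa].to_numpy(dtype=float)
    xb = pivot[sb].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    sea, seb = va / na, vb / nb
    se2 = sea + seb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sea**2 / (na - 1) + seb**2 / (nb - 1))
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(ma == mb, 0.0, np.inf * np.sign(ma - mb)), t)
    df = np.where(degenerate, float(na + nb - 2), df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(ma == mb, 1.0, 0.0), p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "locus_tag": pivot.index,
            "welch_t": t,
            "welch_df": df,
            "welch_p": p,
            "p_adj": p_adj,
            "sig05": p <= 0.05,
            "sig01": p <= 0.01,
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)


def compare(
    div: pd.DataFrame,
    sheet: SampleSheet,
    log2fc_cutoff: float = 1.0,
    cooks_threshold_factor: float = 4.0,
) -> pd.DataFrame:
    """Run all three procedures and assemble the per-gene comparison table."""
    means = mean_ed_by_condition(div, sheet)
    fc = log2_fold_change(means["mean_ED_A"], means["mean_ED_B"], cutoff=log2fc_cutoff)
    reg = regression_cooks(
        means["mean_ED_A"].to_numpy(),
        means["mean_ED_B"].to_numpy(),
        threshold_factor=cooks_threshold_factor,
    )
    cooks = np.full(len(means), np.nan)
    infl = np.zeros(len(means), dtype=bool)
    cooks[reg.finite_mask] = reg.cooks_d
    infl[reg.finite_mask] = reg.influential
    welch = welch_test(div, sheet).set_index("locus_tag")
    out = means.copy()
    out[["log2FC", "log2fc_hit", "direction"]] = fc[["log2FC", "log2fc_hit", "direction"]]
    out["cooksD"] = cooks
    out["influential"] = infl
    for col in ["welch_t", "welch_df", "welch_p", "p_adj", "sig05", "sig01", "degenerate"]:
        out[col] = welch.loc[out["locus_tag"], col].to_numpy()
    out["consensus_all3"] = out["log2fc_hit"] & out["influential"] & out["sig05"]
    out["consensus_cooks_welch"] = out["influential"] & out["sig05"]
    out.attrs["regression"] = {
        "slope": reg.slope,
        "intercept": reg.intercept,
        "adj_r2": reg.adj_r2,
        "n": reg.n,
    }
    return out.sort_values("locus_tag").reset_index(drop=True)


def consensus(results: pd.DataFrame) -> dict:
    """Hit sets of each method and their intersections, with sizes."""
    tags = results["locus_tag"]
    sets = {
        "log2fc": set(tags[results["log2fc_hit"]]),
        "cooks": set(tags[results["influential"]]),
        "welch05": set(tags[results["sig05"]]),
        "welch01": set(tags[results["sig01"]]),
    }
    sets["all3"] = sets["log2fc"] & sets["cooks"] & sets["welch05"]
    sets["cooks_welch"] = sets["cooks"] & sets["welch05"]
    sets["log2fc_cooks"] = sets["log2fc"] & sets["cooks"]
    return {
        "sets": sets,
        "sizes": {name: len(s) for name, s in sets.items()},
    }


def run_subset_analyses(
    matrix_or_div,
    sheet: SampleSheet,
    subsets: dict[str, list[str]],
    **compare_kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Re-run the comparison on named replicate subsets and cross-tabulate hits.

    ``subsets`` maps a name (e.g. "AI-1", "AI-2") to the sample ids it keeps.
    Accepts either a per-replicate diversity frame or a GeneSiteMatrix plus
    precomputed diversity via the frame. Returns per-subset comparison tables
    and a long-form overlap report: for every subset pair and method, the hit
    set sizes, intersection, and Jaccard distance.
    """
    div = matrix_or_div
    if isinstance(div, GeneSiteMatrix):
        raise ValidationError(
            "pass the diversity frame (diversity_matrix output), not the site matrix"
        )
    results = {}
    for name, sample_ids in subsets.items():
        sub_sheet = sheet.subset(sample_ids)
        sub_div = div[div["sample_id"].isin(sample_ids)]
        results[name] = compare(sub_div, sub_sheet, **compare_kwargs)

    rows = []
    names = list(results)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            c1, c2 = consensus(results[n1])["sets"], consensus(results[n2])["sets"]
            for method in ["log2fc", "cooks", "welch05", "welch01", "all3"]:
                s1, s2 = c1[method], c2[method]
                union = s1 | s2
                inter = s1 & s2
                rows.append(
                    {
                        "subset_1": n1,
                        "subset_2": n2,
                        "method": method,
                        "n_1": len(s1),
                        "n_2": len(s2),
                        "n_common": len(inter),
                        "jaccard_distance": 1.0 - len(inter) / len(union) if union else 0.0,
                    }
                )
    return results, pd.DataFrame(rows)
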