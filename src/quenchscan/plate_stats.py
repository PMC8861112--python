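"""Screen-level statistics: rank-sum tests, paired t on log10 ρ plate means,
Benjamini–Hochberg FDR control, the conductance-vs-membrane-proximity
reference line, and the mCherry expression quality-control comparison.

The screen's planned comparisons are (i) one-tailed Wilcoxon rank-sum tests
on per-well conductance/membrane potential between conditions or variants,
and (ii) paired t-tests on per-plate means of log10 ρ, with the family of
planned comparisons controlled by Benjamini–Hochberg at a 10 % false
discovery rate. Since G = N·P_o·γ, a line through the origin fitted to WT
(ρ, G) points describes the conductance expected from membrane proximity
alone if a variant had WT single-channel behaviour; variants falling below
it are gating/conduction-defective beyond their trafficking defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WilcoxonResult",
    "PairedTResult",
    "BHResult",
    "GRModel",
    "wilcoxon_rank_sum",
    "paired_t_log_rho",
    "bh_adjust",
    "gr_reference_slope",
    "mcherry_qc",
    "screen_comparisons",
]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "approx"


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_value: float


@dataclass(frozen=True)
class BHResult:
    reject: np.ndarray
    p_adjusted: np.ndarray
    q: float


@dataclass(frozen=True)
class GRModel:
    """Through-origin least squares of G on ρ over WT reference points;
    the slope is proportional to N·P_o·γ per unit membrane proximity."""

    slope: float
    wt_points: tuple[tuple[float, float], ...]

    def predict(self, rho: float) -> float:
        return self.slope * rho

    def classify(self, rho: float, G: float, rel_tol: float = 0.05) -> str:
        """Position of a variant's (ρ, G) point relative to the WT line:
        'above', 'on' (within ``rel_tol`` of the prediction), or 'below'."""
        expected = self.predict(rho)
        if abs(G - expected) <= rel_tol * max(abs(expected), 1e-12):
            return "on"
        return "above" if G > expected else "below"


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> WilcoxonResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of y's location versus x's.

    ``alternative="greater"`` tests whether y (e.g. the stimulated group)
    tends to exceed x (the control). The exact null distribution is used for
    min(n_x, n_y) ≤ 10 without ties; otherwise the normal approximation with
    mid-ranks, tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    scipy_alt = "greater" if alternative == "greater" else "two-sided"
    exact_ok = min(x.size, y.size) <= 10 and not _has_ties(x, y)
    method = "exact" if exact_ok else "asymptotic"
    # mannwhitneyu tests its FIRST argument against the second
    res = stats.mannwhitneyu(
        y, x, alternative=scipy_alt, method=method,
        use_continuity=(method == "asymptotic"),
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if method == "exact" else "approx",
    )


def paired_t_log_rho(means_with, means_without) -> PairedTResult:
    """Paired t-test on plate-matched mean log10 ρ values.

    Each entry of the two sequences is one plate's mean log10 ρ for the two
    variants being compared (e.g. F508del with vs without a second-site
    mutation); pairing is by plate. df = n - 1.
    """
    a = np.asarray(means_with, dtype=float)
    b = np.asarray(means_without, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length (plate-aligned)")
    if a.size < 2:
        raise ValueError("need at least 2 plate pairs")
    if np.allclose(a, b):
        return PairedTResult(t=0.0, df=a.size - 1, p_value=1.0)
    res = stats.ttest_rel(a, b)
    return PairedTResult(t=float(res.statistic), df=a.size - 1, p_value=float(res.pvalue))


def bh_adjust(pvalues, q: float = 0.10) -> BHResult:
    """Benjamini–Hochberg step-up procedure at FDR ``q``.

    Returns the rejection set (largest k with p_(k) ≤ k·q/m) and monotone
    adjusted p-values; both are returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return BHResult(np.zeros(0, dtype=bool), np.zeros(0), q)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return BHResult(reject=reject, p_adjusted=p_adj, q=q)


def gr_reference_slope(wt_points) -> GRModel:
    """Fit G = slope·ρ through the origin on WT (ρ, G) reference points.

    slope = Σ(ρ·G) / Σ(ρ²), the least-squares solution with zero intercept
    (zero channels at the membrane means zero conductance).
    """
    pts = [(float(r), float(g)) for r, g in wt_points]
    if not pts:
        raise ValueError("need at least one WT reference point")
    rho = np.array([p[0] for p in pts])
    g = np.array([p[1] for p in pts])
    denom = float(np.sum(rho**2))
    if denom == 0:
        raise ValueError("all reference points have rho = 0")
    return GRModel(slope=float(np.sum(rho * g)) / denom, wt_points=tuple(pts))


def mcherry_qc(
    variant_intensities,
    all_other_intensities,
    *,
    alpha: float = 0.05,
    median_ratio_threshold: float = 0.5,
) -> tuple[bool, float]:
    """Flag a variant whose mCherry expression is abnormally low.

    Low mCherry means low bicistronic message, so conductance and ρ for that
    variant are not comparable to the rest of the screen. The variant is
    flagged when a two-sided rank-sum test is significant at ``alpha`` AND
    its median is below ``median_ratio_threshold`` times the others' median
    (one-sided in effect: only a deficit flags). Returns (flagged, p).
    """
    v = np.asarray(variant_intensities, dtype=float)
    rest = np.asarray(all_other_intensities, dtype=float)
    if v.size == 0 or rest.size == 0:
        raise ValueError("both groups must be non-empty")
    res = wilcoxon_rank_sum(rest, v, alternative="two_sided")
    med_rest = float(np.median(rest))
    ratio = float(np.median(v)) / med_rest if med_rest > 0 else np.inf
    flagged = (res.p_value < alpha) and (ratio < median_ratio_threshold)
    return flagged, res.p_value


def screen_comparisons(
    fits,
    rho_cells,
    *,
    reference: str = "F508del",
    wt: str = "WT",
    q: float = 0.10,
    condition: str = "forskolin",
):
    """Planned comparisons of every second-site variant against the reference.

    For each variant other than the reference and WT: (i) a one-tailed
    rank-sum test of per-well fitted conductance under ``condition`` versus
    the reference's wells (is the variant's G increased?), and (ii) a paired
    t-test of per-plate mean log10 rho versus the reference, paired by plate.
    The whole family is then adjusted by Benjamini-Hochberg at FDR ``q``.

    ``fits``: DataFrame with columns variant, condition, G_hat (one row per
    well). ``rho_cells``: DataFrame with columns plate, variant, rho (one row
    per cell). Returns a DataFrame with one row per (variant, test).
    """
    import pandas as pd

    fits = pd.DataFrame(fits)
    rho_cells = pd.DataFrame(rho_cells)
    variants = [v for v in fits["variant"].unique() if v not in (reference, wt)]

    plate_means = (
        rho_cells.assign(log_rho=np.log10(rho_cells["rho"]))
        .groupby(["plate", "variant"])["log_rho"].mean().unstack()
        if len(rho_cells) else None
    )

    rows = []
    ref_g = fits.query("variant == @reference and condition == @condition")["G_hat"]
    for var in variants:
        var_g = fits.query("variant == @var and condition == @condition")["G_hat"]
        if len(var_g) and len(ref_g):
            res = wilcoxon_rank_sum(ref_g.to_numpy(), var_g.to_numpy(),
                                    alternative="greater")
            rows.append({"variant": var, "test": "G_rank_sum",
                         "statistic": res.statistic, "p": res.p_value})
        if plate_means is not None and var in plate_means and reference in plate_means:
            paired = plate_means[[var, reference]].dropna()
            if len(paired) >= 2:
                t_res = paired_t_log_rho(paired[var], paired[reference])
                rows.append({"variant": var, "test": "rho_paired_t",
                             "statistic": t_res.t, "p": t_res.p_value})
    out = pd.DataFrame(rows, columns=["variant", "test", "statistic", "p"])
    if len(out):
        bh = bh_adjust(out["p"].to_numpy(), q=q)
        out["p_adjusted"] = bh.p_adjusted
        out["reject"] = bh.reject
    else:
        out["p_adjusted"] = []
        out["reject"] = []
    return out
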