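"""Curvature–intensity statistics: exclusion rules, equal-count binned
correlation with Student confidence intervals, and two-group comparisons
with a bilateral (two-sided) Student test.

Per-bin confidence intervals are classic Student intervals at α = 0.05:
half-width t_{0.975, n-1} · s / √n.  The overall association is summarised by
Pearson r, Spearman ρ and the least-squares slope, and by a two-sample
t-test between the lowest- and highest-curvature bins (the extreme-bin
contrast, which avoids the implicit multiplicity of all-pairs bin tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BinnedCorrelation",
    "GroupComparison",
    "exclusion_filter",
    "binned_correlation",
    "group_compare",
    "student_ci_halfwidth",
    "mesh_units",
]

ALPHA = 0.05


def student_ci_halfwidth(x: np.ndarray, alpha: float = ALPHA) -> float:
    """Half-width of the Student confidence interval of the mean."""
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2:
        return np.nan
    t = sps.t.ppf(1 - alpha / 2, df=n - 1)
    return float(t * x.std(ddof=1) / np.sqrt(n))


@dataclass
class BinnedCorrelation:
    bin_edges: np.ndarray  # (n_bins + 1,) μm⁻²
    bin_n: np.ndarray
    bin_mean_K: np.ndarray
    bin_mean_I: np.ndarray
    bin_ci_halfwidth: np.ndarray
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    slope: float
    extreme_bin_t: float
    extreme_bin_p: float
    n_cells_used: int
    n_excluded_extremity: int = 0
    n_excluded_old_organs: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K_low": self.bin_edges[:-1],
                "K_high": self.bin_edges[1:],
                "n": self.bin_n,
                "mean_K": self.bin_mean_K,
                "mean_intensity": self.bin_mean_I,
                "ci_halfwidth": self.bin_ci_halfwidth,
            }
        )

    def means_nonincreasing(self, ci_slack: bool = True) -> bool:
        """True when bin mean intensities do not increase with curvature,
        allowing (by default) each step up to the adjacent bins' combined CI
        half-widths — the statistical reading of a monotone decreasing trend
        for noisy bin means."""
        m = self.bin_mean_I
        slack = self.bin_ci_halfwidth if ci_slack else np.zeros_like(m)
        for i in range(len(m) - 1):
            allowed = (slack[i] + slack[i + 1]) if ci_slack else 0.0
            if m[i + 1] > m[i] + allowed:
                return False
        return True

    def __str__(self) -> str:  # compact report
        return (
            f"BinnedCorrelation(n={self.n_cells_used}, r={self.pearson_r:+.3f} "
            f"(p={self.pearson_p:.2g}), rho={self.spearman_rho:+.3f}, "
            f"slope={self.slope:.3g}, extreme-bin p={self.extreme_bin_p:.2g}, "
            f"excluded: {self.n_excluded_extremity} extremity, "
            f"{self.n_excluded_old_organs} old-organ)"
        )


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    ci_halfwidths: tuple[float, float]
    t_statistic: float
    p_value: float
    equal_variance: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.labels,
                "n": self.n,
                "mean": self.means,
                "ci_halfwidth": self.ci_halfwidths,
            }
        )


def mesh_units(mesh, patch_size: float | None = 5.0) -> pd.DataFrame:
    """Analysis units from a mesh carrying ``gaussian_curvature`` and
    ``projected_intensity`` attributes.

    With ``patch_size`` set (default 5 μm, about one epidermal cell), vertices
    are aggregated into cell-proxy patches on a cubic lattice: mesh vertices a
    fraction of a micrometre apart are not independent observations, and the
    patch unit matches quantification per cell.  ``patch_size=None`` returns
    raw per-vertex units.  Any per-vertex ``organ_stage`` attribute is carried
    through (max within patch); a patch touched by an extremity-flagged vertex
    is flagged."""
    df = pd.DataFrame(
        {
            "K": mesh.attributes["gaussian_curvature"],
            "intensity": mesh.attributes["projected_intensity"],
            "extremity": mesh.boundary_vertex_flags,
        }
    )
    if "organ_stage" in mesh.attributes:
        df["organ_stage"] = mesh.attributes["organ_stage"]
    if patch_size is None:
        return df
    cells = np.floor(mesh.vertices / patch_size).astype(np.int64)
    df["patch_id"] = [f"{a}_{b}_{c}" for a, b, c in cells]
    agg = {"K": "mean", "intensity": "mean", "extremity": "max"}
    if "organ_stage" in df:
        agg["organ_stage"] = "max"
    out = df.groupby("patch_id", sort=True).agg(agg).reset_index()
    out["extremity"] = out["extremity"].astype(bool)
    return out


def exclusion_filter(
    units: pd.DataFrame,
    stage_cutoff: float | None = None,
    stage_column: str = "organ_stage",
) -> tuple[pd.DataFrame, dict]:
    """Apply the standard exclusion rules before quantification: drop units
    flagged as mesh extremities (curvature aberrations at mesh borders) and
    units belonging to organs older than ``stage_cutoff``; drop units with
    missing values.  Returns (filtered units, exclusion counts)."""
    n0 = len(units)
    extremity = units["extremity"].astype(bool) if "extremity" in units else pd.Series(False, index=units.index)
    n_ext = int(extremity.sum())
    keep = ~extremity
    n_old = 0
    if stage_cutoff is not None and stage_column in units:
        old = units[stage_column] > stage_cutoff
        n_old = int((old & keep).sum())
        keep &= ~old
    out = units[keep]
    numeric = out.select_dtypes(include=[np.number]).columns
    out = out.dropna(subset=list(numeric))
    if len(out) == 0:
        raise ValueError(
            f"all {n0} units excluded ({n_ext} extremity, {n_old} old-organ, rest missing)"
        )
    counts = {
        "n_input": n0,
        "n_excluded_extremity": n_ext,
        "n_excluded_old_organs": n_old,
        "n_used": len(out),
    }
    return out, counts


def binned_correlation(
    K: np.ndarray,
    I: np.ndarray,
    n_bins: int = 8,
    equal_var: bool = False,
    n_excluded_extremity: int = 0,
    n_excluded_old_organs: int = 0,
) -> BinnedCorrelation:
    """Equal-count binning of intensity over Gaussian curvature.

    Bins hold (near) equal numbers of units across the K range; per-bin mean
    intensity carries a Student CI (α = 0.05).  The association is tested by
    a bilateral two-sample t-test between the lowest-K and highest-K bins.
    """
    K = np.asarray(K, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if K.shape != I.shape:
        raise ValueError("K and I must have equal length")
    ok = np.isfinite(K) & np.isfinite(I)
    K, I = K[ok], I[ok]
    n = len(K)
    if n < 3 * n_bins:
        raise ValueError(f"need at least {3 * n_bins} units for {n_bins} bins, got {n}")

    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(K, qs)
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("curvature values too degenerate to form 2 bins")
    which = np.clip(np.searchsorted(edges, K, side="right") - 1, 0, len(edges) - 2)

    bin_n, mean_K, mean_I, ci = [], [], [], []
    groups = []
    for b in range(len(edges) - 1):
        sel = which == b
        vals = I[sel]
        groups.append(vals)
        bin_n.append(int(sel.sum()))
        mean_K.append(float(K[sel].mean()) if sel.any() else np.nan)
        mean_I.append(float(vals.mean()) if sel.any() else np.nan)
        ci.append(student_ci_halfwidth(vals))

    r, rp = sps.pearsonr(K, I)
    rho = sps.spearmanr(K, I).statistic
    slope = float(np.polyfit(K, I, 1)[0])
    lo, hi = groups[0], groups[-1]
    if len(lo) >= 2 and len(hi) >= 2:
        if lo.std(ddof=1) == 0 and hi.std(ddof=1) == 0:
            tt, tp = (0.0, 1.0) if lo.mean() == hi.mean() else (np.inf, 0.0)
        else:
            res = sps.ttest_ind(lo, hi, equal_var=equal_var)
            tt, tp = float(res.statistic), float(res.pvalue)
    else:
        tt, tp = np.nan, np.nan

    return BinnedCorrelation(
        bin_edges=edges,
        bin_n=np.array(bin_n),
        bin_mean_K=np.array(mean_K),
        bin_mean_I=np.array(mean_I),
        bin_ci_halfwidth=np.array(ci),
        pearson_r=float(r),
        pearson_p=float(rp),
        spearman_rho=float(rho),
        slope=slope,
        extreme_bin_t=tt,
        extreme_bin_p=tp,
        n_cells_used=n,
        n_excluded_extremity=n_excluded_extremity,
        n_excluded_old_organs=n_excluded_old_organs,
    )


def group_compare(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
    equal_var: bool = False,
) -> GroupComparison:
    """Bilateral two-sample Student test (Welch by default) with group means
    and Student CIs at α = 0.05."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no variance anywhere
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        labels=labels,
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        ci_halfwidths=(student_ci_halfwidth(a), student_ci_halfwidth(b)),
        t_statistic=t,
        p_value=p,
        equal_variance=equal_var,
    )
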