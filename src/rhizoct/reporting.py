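"""Association analyses on core-level derived tables and figure-style outputs.

These operate purely on the tables the image pipeline emits (environment
shares, decomposition profiles, total-porosity changes, rhizosheath data):
ordinary least-squares regressions, tie-corrected Spearman rank correlations,
and per-distance-bin paired comparisons of the two rhizosphere mechanisms
(growth preference vs. root-induced change) across replicate cores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _finite_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def fit_linear(x, y) -> tuple[float, float, float, float]:
    """OLS fit of y on x: (slope, intercept, r_squared, two-sided slope p)."""
    x, y = _finite_pairs(x, y)
    if len(x) < 3:
        raise ValueError(f"need at least 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance: slope is undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), float(res.pvalue)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p value."""
    x, y = _finite_pairs(x, y)
    if len(x) < 4:
        raise ValueError(f"need at least 4 finite pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("all-tied input: rank correlation is undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho, p = stats.spearmanr(x, y)
    # perfectly concordant/discordant rankings are exactly +/-1, not 1-eps
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx, len(ry) + 1 - ry):
        rho = -1.0
    return float(rho), float(p)


def compare_mechanisms_per_bin(preference: np.ndarray, induced: np.ndarray,
                               bin_edges_mm=None,
                               holm: bool = False) -> pd.DataFrame:
    """Per-bin paired comparison of the two mechanisms across replicate cores.

    ``preference`` and ``induced`` are (n_cores, n_bins) arrays of per-core
    profiles.  For each distance bin the per-core differences
    ``preference − induced`` are tested against zero with a two-sided paired
    t test; each bin gets its own error variance, since both the means and the
    spread of rhizosphere responses are largest near the root and shrink with
    distance.  An optional Holm correction across bins is available; none is
    applied by default.
    """
    pref = np.atleast_2d(np.asarray(preference, dtype=float))
    ind = np.atleast_2d(np.asarray(induced, dtype=float))
    if pref.shape != ind.shape:
        raise ValueError("preference and induced must have identical shapes")
    n_cores, n_bins = pref.shape
    if n_cores < 3:
        raise ValueError(f"need at least 3 replicate cores, got {n_cores}")
    diffs = pref - ind
    mean_diff = np.nanmean(diffs, axis=0)
    p_values = np.empty(n_bins)
    for j in range(n_bins):
        d = diffs[:, j]
        d = d[np.isfinite(d)]
        if len(d) < 3:
            p_values[j] = np.nan
        elif np.allclose(d, 0.0):
            p_values[j] = 1.0  # identical mechanism profiles: no evidence of a difference
        else:
            p_values[j] = stats.ttest_1samp(d, 0.0).pvalue
    out = pd.DataFrame({"bin": np.arange(n_bins), "difference": mean_diff,
                        "p_value": p_values})
    if bin_edges_mm is not None:
        edges = np.asarray(bin_edges_mm, dtype=float)
        out["bin_lower_mm"] = edges[:-1]
        out["bin_upper_mm"] = edges[1:]
    if holm:
        order = np.argsort(p_values)
        adj = np.full(n_bins, np.nan)
        running = 0.0
        m = np.isfinite(p_values).sum()
        for rank, j in enumerate(order):
            if not np.isfinite(p_values[j]):
                continue
            running = max(running, (m - rank) * p_values[j])
            adj[j] = min(running, 1.0)
        out["p_holm"] = adj
    return out


def build_core_summary(shares: pd.DataFrame,
                       decompositions: pd.DataFrame,
                       totals: pd.DataFrame,
                       rhizosheath: pd.DataFrame | None = None,
                       plot_path=None) -> pd.DataFrame:
    """Join per-core inputs into one summary row per core.

    ``shares``: one row per core with the environment-share columns;
    ``decompositions``: long table (core_id, bin_lower_mm, induced, preference);
    ``totals``: per-core total-macroporosity-change rows;
    ``rhizosheath``: optional; cores missing from it are flagged, not dropped.
    """
    for name, df in (("shares", shares), ("totals", totals)):
        if df["core_id"].duplicated().any():
            raise ValueError(f"duplicate core_ids in {name}")
    wide = decompositions.pivot(index="core_id", columns="bin_lower_mm",
                                values=["induced", "preference"])
    wide.columns = [f"{kind}_at_{lo:.4g}mm" for kind, lo in wide.columns]
    # volume-weighted induced mean over the whole <1 mm rhizosphere and the first bin
    agg = (decompositions
           .assign(w=lambda d: d.get("n_domain_voxels", 1.0))
           .groupby("core_id")
           .apply(lambda g: pd.Series({
               "induced_lt1mm": np.average(g["induced"], weights=g["w"])
               if np.isfinite(g["induced"]).all() else np.nan,
               "induced_first_bin": g.sort_values("bin_lower_mm")["induced"].iloc[0],
           }), include_groups=False))
    out = shares.merge(wide, on="core_id", how="left")
    out = out.merge(agg, on="core_id", how="left")
    out = out.merge(totals, on="core_id", how="left", suffixes=("", "_total"))
    if rhizosheath is not None:
        keep = ["core_id"] + [c for c in ("rhizosheath_mass_g", "tracer_activity_kBq")
                              if c in rhizosheath.columns]
        out = out.merge(rhizosheath[keep], on="core_id", how="left")
        out["rhizosheath_missing"] = out["rhizosheath_mass_g"].isna()
    else:
        out["rhizosheath_missing"] = True
    if set(out["core_id"]) != set(shares["core_id"]):
        raise ValueError("core_ids inconsistent across inputs")
    if plot_path is not None:
        plot_mechanism_profiles(decompositions, plot_path)
    return out


def plot_mechanism_profiles(decompositions: pd.DataFrame, path,
                            condition: str | None = None) -> None:
    """Mean ± SE profile plot of both mechanisms across cores (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = (decompositions.groupby(condition) if condition
              else [("all cores", decompositions)])
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, g in groups:
        stats_ = g.groupby("bin_lower_mm")[["induced", "preference"]].agg(["mean", "sem"])
        x = stats_.index.to_numpy()
        for mech, style in (("induced", "-o"), ("preference", "--s")):
            ax.errorbar(x, stats_[(mech, "mean")], yerr=stats_[(mech, "sem")],
                        fmt=style, capsize=2, label=f"{mech} ({name})")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("distance to root surface (mm, bin lower edge)")
    ax.set_ylabel("local macroporosity change")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
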