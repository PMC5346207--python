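"""Marey-map recombination analysis.

A Marey map plots the genetic position (cM) of each mapped marker
against its physical position (Mb) along a chromosome; the slope of the
cumulative curve is the local recombination rate.  This module fits
cubic smoothing splines with cross-validated smoothing to Marey points,
derives the rate profile, localizes putative centromeres as extended
minimal-rate regions, computes whole-chromosome cM/Mb ratios and runs
the multi-map comparison statistics (ANOVA + Tukey, Kruskal-Wallis +
Mann-Whitney/Bonferroni, with Levene and Shapiro-Wilk assumption
checks).

Notes on the Tukey post-hoc: with unequal group sizes the pairwise
standard error uses the harmonic mean of *all* group sizes (the classic
unequal-n Tukey, as implemented in the PAST statistics package), not
the Tukey-Kramer per-pair form.  ``tukey_kramer=True`` switches to the
per-pair form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "MareyFit",
    "MapComparisonResult",
    "marey_points",
    "fit_marey",
    "locate_centromere",
    "chromosome_cmmb",
    "compare_maps",
    "kosambi_cm",
    "haldane_cm",
    "haldane_to_kosambi",
]


# ---------------------------------------------------------------------------
# mapping functions


def kosambi_cm(r: float) -> float:
    """Kosambi map distance (cM) for recombination fraction ``r``.

    d = 25 * ln((1 + 2r) / (1 - 2r)); accounts for interference.
    """
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def haldane_cm(r: float) -> float:
    """Haldane map distance (cM), d = -50 * ln(1 - 2r) (no interference)."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * math.log(1 - 2 * r)


def haldane_to_kosambi(d_haldane_cm: float) -> float:
    """Convert a Haldane distance to Kosambi units via the implied r."""
    r = (1.0 - math.exp(-d_haldane_cm / 50.0)) / 2.0
    return kosambi_cm(r)


# ---------------------------------------------------------------------------
# Marey points and spline fits


def marey_points(
    object_placements: pd.DataFrame,
    maps: pd.DataFrame,
    map_id: str,
    suspect_markers: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-chromosome (Mb, cM) point sets for one map.

    ``object_placements`` holds marker positions on pseudomolecules
    (columns ``marker_id``, ``object``, ``pos``); ``maps`` is the marker
    table (columns ``marker_id``, ``map_id``, ``linkage_group``, ``cM``,
    ``level``).  Bin-level markers and markers flagged suspect upstream
    are excluded.
    """
    suspect_markers = suspect_markers or set()
    sub = maps[(maps["map_id"] == map_id) & (maps["level"] == "full")]
    merged = object_placements.merge(sub, on="marker_id", how="inner")
    merged = merged[~merged["marker_id"].isin(suspect_markers)]
    out: dict[str, pd.DataFrame] = {}
    for obj, grp in merged.groupby("object"):
        pts = pd.DataFrame(
            {"Mb": grp["pos"].to_numpy() / 1e6, "cM": grp["cM"].to_numpy()}
        ).sort_values("Mb", ignore_index=True)
        out[obj] = pts
    return out


@dataclass
class MareyFit:
    """Cubic smoothing-spline fit of a chromosome's Marey curve."""

    chromosome: str
    mb: np.ndarray          # deduplicated, sorted physical positions (Mb)
    cm: np.ndarray          # genetic positions (cM), averaged over duplicate Mb
    lam: float              # selected smoothing parameter
    spline: object = field(repr=False)
    grid: np.ndarray = field(repr=False)       # uniform physical grid (Mb)
    rate: np.ndarray = field(repr=False)       # cM/Mb on the grid, clamped >= 0
    rate_integral_ratio: float = float("nan")  # integral of rate / observed cM span

    def __call__(self, x):
        return self.spline(x)

    @property
    def span_mb(self) -> float:
        return float(self.mb[-1] - self.mb[0])


class MareyFitError(ValueError):
    """Raised when a chromosome has too few usable points to fit."""


def _loo_cv_score(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    err = 0.0
    idx = np.arange(len(x))
    for i in idx:
        keep = idx != i
        try:
            sp = make_smoothing_spline(x[keep], y[keep], lam=lam)
        except Exception:
            return float("inf")
        err += float(y[i] - sp(x[i])) ** 2
    return err / len(x)


def fit_marey(
    points: pd.DataFrame,
    cv: bool = True,
    chromosome: str = "",
    grid_points: int = 200,
    lam_grid: np.ndarray | None = None,
) -> MareyFit:
    """Fit a cubic smoothing spline to Marey points.

    The smoothing parameter is chosen by ordinary (leave-one-out)
    cross-validation over a log-spaced grid when ``cv`` is true,
    otherwise by generalized cross-validation.  Duplicate physical
    positions are averaged before the fit.  The recombination rate is
    the first derivative on a uniform grid, clamped at zero; the
    integral of the clamped rate over the span is reported relative to
    the observed cM span as a fit diagnostic.
    """
    pts = points.groupby("Mb", as_index=False)["cM"].mean().sort_values("Mb")
    x = pts["Mb"].to_numpy(float)
    y = pts["cM"].to_numpy(float)
    if len(x) < 5 or len(np.unique(x)) < 3:
        raise MareyFitError(
            f"chromosome {chromosome!r}: need >= 5 points over >= 3 distinct "
            f"positions, got {len(x)}"
        )
    if cv:
        if lam_grid is None:
            # scale-aware grid: lam has units of x^3 per unit weight
            span = x[-1] - x[0]
            lam_grid = np.logspace(-9, 1, 21) * span**3
        scores = [_loo_cv_score(x, y, lam) for lam in lam_grid]
        lam = float(lam_grid[int(np.argmin(scores))])
        spline = make_smoothing_spline(x, y, lam=lam)
    else:
        spline = make_smoothing_spline(x, y)  # GCV-selected
        lam = float("nan")
    grid = np.linspace(x[0], x[-1], grid_points)
    rate = np.clip(spline.derivative()(grid), 0.0, None)
    integral = float(np.trapezoid(rate, grid))
    cm_span = float(y.max() - y.min())
    ratio = integral / cm_span if cm_span > 0 else float("nan")
    return MareyFit(
        chromosome=chromosome,
        mb=x,
        cm=y,
        lam=lam,
        spline=spline,
        grid=grid,
        rate=rate,
        rate_integral_ratio=ratio,
    )


def locate_centromere(
    fit: MareyFit, rel_threshold: float = 0.1, min_span_frac: float = 0.02
) -> tuple[float, float, float] | None:
    """Putative centromeric interval by recombination suppression.

    Returns ``(start_mb, end_mb, midpoint_mb)`` of the longest
    contiguous grid region whose rate falls below ``rel_threshold``
    times the chromosome-mean rate and whose span is at least
    ``min_span_frac`` of the chromosome length, or ``None``.
    """
    mean_rate = float(fit.rate.mean())
    if mean_rate <= 0:
        return None
    low = fit.rate < rel_threshold * mean_rate
    best: tuple[float, float] | None = None
    start = None
    for i, flag in enumerate(np.append(low, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            s, e = fit.grid[start], fit.grid[i - 1]
            if best is None or (e - s) > (best[1] - best[0]):
                best = (s, e)
            start = None
    if best is None:
        return None
    span = best[1] - best[0]
    if span < min_span_frac * fit.span_mb:
        return None
    return (float(best[0]), float(best[1]), float((best[0] + best[1]) / 2))


# ---------------------------------------------------------------------------
# whole-chromosome cM/Mb ratios


def chromosome_cmmb(
    spans: pd.DataFrame, pseudomolecule_lengths: pd.DataFrame | None = None
) -> pd.DataFrame:
    """cM/Mb ratio table from per map x chromosome span rows.

    ``spans`` columns: ``map_id``, ``chromosome``, ``cM_span``,
    ``bp_span`` (NaN where a map does not cover a chromosome).  A totals
    row per map uses the summed spans.  Ratios are additionally reported
    rounded to 3 decimals (``ratio_display``); entries without physical
    span are marked unavailable (NaN).
    """
    rows = []
    for map_id, grp in spans.groupby("map_id", sort=False):
        for _, r in grp.iterrows():
            avail = pd.notna(r["bp_span"]) and r["bp_span"] > 0
            ratio = r["cM_span"] / (r["bp_span"] / 1e6) if avail else float("nan")
            cov = float("nan")
            if avail and pseudomolecule_lengths is not None:
                plen = pseudomolecule_lengths.set_index("chromosome").loc[
                    r["chromosome"], "length_bp"
                ]
                cov = float(r["bp_span"]) / float(plen)
            rows.append(
                {
                    "map_id": map_id,
                    "chromosome": r["chromosome"],
                    "cM_span": r["cM_span"],
                    "bp_span": r["bp_span"],
                    "ratio": ratio,
                    "ratio_display": round(ratio, 3) if avail else float("nan"),
                    "coverage_fraction": cov,
                }
            )
        sub = grp.dropna(subset=["bp_span"])
        tot_cm, tot_bp = sub["cM_span"].sum(), sub["bp_span"].sum()
        tot_ratio = tot_cm / (tot_bp / 1e6) if tot_bp > 0 else float("nan")
        tot_cov = float("nan")
        if pseudomolecule_lengths is not None:
            tot_cov = tot_bp / pseudomolecule_lengths["length_bp"].sum()
        rows.append(
            {
                "map_id": map_id,
                "chromosome": "total",
                "cM_span": tot_cm,
                "bp_span": tot_bp,
                "ratio": tot_ratio,
                "ratio_display": round(tot_ratio, 3),
                "coverage_fraction": tot_cov,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multi-map comparison statistics


@dataclass
class MapComparisonResult:
    groups: dict[str, np.ndarray]
    excluded: pd.DataFrame
    levene_stat: float
    levene_p: float
    shapiro_p: dict[str, float]
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame
    kruskal_h: float
    kruskal_p: float
    mannwhitney_p: pd.DataFrame
    endorsed: str  # "anova" or "kruskal"


def _tukey_matrix(
    groups: dict[str, np.ndarray], tukey_kramer: bool = False
) -> pd.DataFrame:
    names = list(groups)
    k = len(names)
    ns = {n: len(groups[n]) for n in names}
    df_w = sum(ns.values()) - k
    means = {n: float(np.mean(groups[n])) for n in names}
    ssw = sum(float(((groups[n] - means[n]) ** 2).sum()) for n in names)
    msw = ssw / df_w
    nh = k / sum(1.0 / ns[n] for n in names)  # harmonic mean of group sizes
    mat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        if tukey_kramer:
            se = math.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        else:
            se = math.sqrt(msw / nh)
        q = abs(means[a] - means[b]) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def _mannwhitney_matrix(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    k = len(names)
    n_pairs = k * (k - 1) // 2
    mat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        mat.loc[a, b] = mat.loc[b, a] = min(1.0, float(p) * n_pairs)  # Bonferroni
    return mat


def compare_maps(
    entries: pd.DataFrame,
    coverage_cutoff: float = 0.5,
    alpha: float = 0.05,
    tukey_kramer: bool = False,
) -> MapComparisonResult:
    """Compare whole-chromosome recombination rates across linkage maps.

    ``entries`` columns: ``map_id``, ``chromosome``, ``ratio``,
    ``coverage_fraction``.  Chromosome entries covering less than
    ``coverage_cutoff`` of the pseudomolecule (their ratio reflects a
    local rather than a chromosome-wide rate) and unavailable entries
    are excluded.  Both the parametric branch (one-way ANOVA with the
    Tukey post-hoc) and the nonparametric branch (tie-corrected
    Kruskal-Wallis with pairwise Mann-Whitney under Bonferroni) are
    always computed; Levene and per-group Shapiro-Wilk at ``alpha``
    decide which branch the assumptions endorse.
    """
    entries = entries[entries["chromosome"].astype(str) != "total"]
    avail = entries.dropna(subset=["ratio"])
    mask = avail["coverage_fraction"] >= coverage_cutoff
    kept, excluded = avail[mask], avail[~mask]
    groups = {
        str(m): g["ratio"].to_numpy(float)
        for m, g in kept.groupby("map_id", sort=False)
    }
    groups = {m: v for m, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 maps with >= 2 retained chromosomes each")
    arrays = list(groups.values())
    lev = stats.levene(*arrays, center="mean")
    shapiro = {m: float(stats.shapiro(v).pvalue) for m, v in groups.items()}
    anova = stats.f_oneway(*arrays)
    kw = stats.kruskal(*arrays)
    endorsed = (
        "anova"
        if lev.pvalue > alpha and all(p > alpha for p in shapiro.values())
        else "kruskal"
    )
    return MapComparisonResult(
        groups=groups,
        excluded=excluded.reset_index(drop=True),
        levene_stat=float(lev.statistic),
        levene_p=float(lev.pvalue),
        shapiro_p=shapiro,
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        tukey_p=_tukey_matrix(groups, tukey_kramer=tukey_kramer),
        kruskal_h=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        mannwhitney_p=_mannwhitney_matrix(groups),
        endorsed=endorsed,
    )


def plot_marey(fits: dict[str, MareyFit], path: str) -> None:
    """Panel of Marey maps with fitted curves and rate profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(fits)
    ncol = min(4, n)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, (name, fit) in zip(axes.ravel(), fits.items()):
        ax.plot(fit.mb, fit.cm, ".", ms=3, alpha=0.6)
        ax.plot(fit.grid, fit.spline(fit.grid), "-", lw=1.5)
        twin = ax.twinx()
        twin.plot(fit.grid, fit.rate, "-", color="tab:red", lw=0.8, alpha=0.7)
        twin.set_ylabel("cM/Mb", fontsize=7)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
        ax.set_ylabel("cM", fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
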