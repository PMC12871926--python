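"""Group-level statistics: mean +/- SD summaries, one-way ANOVA with Tukey
(-Kramer) post hoc comparisons, and the delta-delta / delta-delta-delta
synergy construction.

The synergy diagnostic asks whether a membrane protein enhances the CA
boost of a flux metric: with a CA axis (e.g. injected hCA II) and a
modifier axis (e.g. hAQP5 expression),

    dd_base = values(-mod, +CA) - mean(values(-mod, -CA))
    dd_mod  = values(+mod, +CA) - mean(values(+mod, -CA))
    ddd     = mean(dd_mod) - mean(dd_base)

with significance from a one-way ANOVA / Tukey contrast of dd_base vs
dd_mod. The subtracted control means are treated as constants (no
uncertainty propagation) - the construction's documented limitation; see
``delta_delta``'s ``control_means`` argument for supplying known means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05
CONDITION_COLS = ("hAQP5", "hCAII_ng", "bCA")


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def group_label(df: pd.DataFrame, by=CONDITION_COLS) -> pd.Series:
    def lab(row):
        parts = []
        for c in by:
            v = row[c]
            if isinstance(v, (bool, np.bool_)):
                parts.append(("+" if v else "-") + c)
            else:
                parts.append(f"{c}={v:g}" if isinstance(v, float) else f"{c}={v}")
        return "/".join(parts)
    return df.apply(lab, axis=1)


def summarize(df: pd.DataFrame, metric: str, by=CONDITION_COLS) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n for one metric."""
    if metric not in df.columns:
        raise StatsError(f"unknown metric '{metric}'")
    g = df.groupby(list(by))[metric]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2]
        raise StatsError(f"group(s) with fewer than 2 values:\n{bad}")
    if not np.isfinite(df[metric]).all():
        raise StatsError(f"metric '{metric}' contains non-finite values")
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------
@dataclass
class TukeyReport:
    F: float
    p_omnibus: float
    pairs: pd.DataFrame          # group1, group2, meandiff, p_adj, significant
    alpha: float = ALPHA
    degenerate: bool = False

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def anova_tukey(df: pd.DataFrame, metric: str, by=CONDITION_COLS,
                alpha: float = ALPHA) -> TukeyReport:
    """One-way ANOVA over the named groups followed by Tukey's HSD
    (Tukey-Kramer for unbalanced groups), alpha = 0.05 by default.

    If every value in every group is identical the report is flagged
    degenerate with the p = 1 convention.
    """
    labels = group_label(df, by) if not isinstance(by, str) else df[by]
    values = df[metric].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise StatsError(f"metric '{metric}' contains non-finite values")
    groups = [values[labels == g] for g in labels.unique()]
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise StatsError("every group needs n >= 2")
    if np.ptp(values) == 0.0:
        k = len(groups)
        pairs = pd.DataFrame({
            "group1": [labels.unique()[i] for i in range(k) for _ in range(i + 1, k)],
            "group2": [labels.unique()[j] for i in range(k) for j in range(i + 1, k)],
            "meandiff": 0.0, "p_adj": 1.0, "significant": False})
        return TukeyReport(F=0.0, p_omnibus=1.0, pairs=pairs, alpha=alpha,
                           degenerate=True)
    F, p = sps.f_oneway(*groups)
    if len(groups) == 2:
        # Tukey HSD with two groups reduces exactly to the pooled t test
        # (q_{2,df} = sqrt(2) |t|); closed form avoids the numerically
        # integrated studentized-range CDF
        g1l, g2l = labels.unique()
        a, b = groups
        df_w = a.size + b.size - 2
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df_w
        se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        tstat = (b.mean() - a.mean()) / se
        p_adj = float(2.0 * sps.t.sf(abs(tstat), df_w))
        pairs = pd.DataFrame({
            "group1": [g1l], "group2": [g2l],
            "meandiff": [float(b.mean() - a.mean())],
            "p_adj": [p_adj], "significant": [p_adj < alpha]})
        return TukeyReport(F=float(F), p_omnibus=float(p), pairs=pairs,
                           alpha=alpha)
    hsd = pairwise_tukeyhsd(values, labels.to_numpy(), alpha=alpha)
    from itertools import combinations
    g1, g2 = zip(*combinations(hsd.groupsunique, 2))
    pairs = pd.DataFrame({
        "group1": g1,
        "group2": g2,
        "meandiff": hsd.meandiffs,
        "p_adj": hsd.pvalues,
        "significant": hsd.reject,
    })
    return TukeyReport(F=float(F), p_omnibus=float(p), pairs=pairs, alpha=alpha)


def anova_f_oneway_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """Explicit sums-of-squares one-way ANOVA (independent of the library
    route): returns (F, p)."""
    allv = np.concatenate(groups)
    gm = allv.mean()
    ss_between = sum(g.size * (g.mean() - gm) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(sps.f.sf(F, df_b, df_w))


# ---------------------------------------------------------------------------
# delta-delta / delta-delta-delta
# ---------------------------------------------------------------------------
@dataclass
class DeltaDeltaReport:
    dd_base: np.ndarray
    dd_mod: np.ndarray
    ddd: float
    p_value: float
    significant: bool
    ca_axis: str
    mod_axis: str
    metric: str
    tukey: TukeyReport | None = field(default=None, repr=False)

    def summary(self) -> str:
        return (f"dd_base (n={self.dd_base.size}) mean {self.dd_base.mean():+.4g}; "
                f"dd_mod (n={self.dd_mod.size}) mean {self.dd_mod.mean():+.4g}; "
                f"ddd = {self.ddd:+.4g}, p = {self.p_value:.3g}"
                f" ({'significant' if self.significant else 'n.s.'} at 0.05)")


def _ca_indicator(df: pd.DataFrame, ca_axis: str) -> pd.Series:
    if ca_axis == "hCAII":
        return df["hCAII_ng"].astype(float) > 0
    if ca_axis in df.columns:
        return df[ca_axis].astype(bool)
    raise StatsError(f"unknown CA axis '{ca_axis}'")


def delta_delta(df: pd.DataFrame, metric: str, ca_axis: str = "hCAII",
                mod_axis: str = "hAQP5",
                control_means: tuple[float, float] | None = None,
                alpha: float = ALPHA) -> DeltaDeltaReport:
    """The synergy construction over a four-group table.

    ``ca_axis`` selects which CA manipulation is toggled ("hCAII" uses any
    nonzero injected dose, "bCA" the extracellular enzyme); ``mod_axis`` is
    the candidate-channel flag. ``control_means`` optionally supplies the
    (-mod,-CA) and (+mod,-CA) means as known constants instead of
    estimating them from the table (the construction treats them as
    constants either way).
    """
    if metric not in df.columns:
        raise StatsError(f"unknown metric '{metric}'")
    ca = _ca_indicator(df, ca_axis)
    mod = df[mod_axis].astype(bool)
    vals = df[metric].to_numpy(dtype=float)
    cells = {}
    for m in (False, True):
        for c in (False, True):
            sel = (mod == m) & (ca == c)
            if not sel.any():
                raise StatsError(
                    f"missing group ({'+' if m else '-'}{mod_axis}, "
                    f"{'+' if c else '-'}{ca_axis})")
            cells[(m, c)] = vals[sel.to_numpy()]
    if control_means is None:
        mean_base_ctrl = cells[(False, False)].mean()
        mean_mod_ctrl = cells[(True, False)].mean()
    else:
        mean_base_ctrl, mean_mod_ctrl = control_means
    dd_base = cells[(False, True)] - mean_base_ctrl
    dd_mod = cells[(True, True)] - mean_mod_ctrl
    ddd = float(dd_mod.mean() - dd_base.mean())

    dd_df = pd.DataFrame({
        "group": ["dd_base"] * dd_base.size + ["dd_mod"] * dd_mod.size,
        "value": np.concatenate([dd_base, dd_mod])})
    rep = anova_tukey(dd_df, "value", by="group", alpha=alpha)
    p = float(rep.pairs["p_adj"].iloc[0])
    return DeltaDeltaReport(dd_base=dd_base, dd_mod=dd_mod, ddd=ddd,
                            p_value=p, significant=p < alpha,
                            ca_axis=ca_axis, mod_axis=mod_axis,
                            metric=metric, tukey=rep)


# ---------------------------------------------------------------------------
# statistical-level synthetic group generators
# ---------------------------------------------------------------------------
#: Default per-group means for the upward surface-pH excursion (pH units),
#: taken from the forward simulator's own condition grid at its default
#: parameters, with a 25% coefficient of variation as the between-oocyte
#: spread. Keys: (hAQP5, CA present).
DEFAULT_SYNERGY_MEANS = {
    (False, False): 0.0132,
    (False, True): 0.0186,
    (True, False): 0.0258,
    (True, True): 0.0438,
}
DEFAULT_CV = 0.25


def generate_group_table(means: dict[tuple[bool, bool], float] | None = None,
                         cv: float = DEFAULT_CV,
                         n_per_group: int = 10,
                         seed: int = 0,
                         metric: str = "dpHS_up",
                         ca_axis: str = "hCAII") -> pd.DataFrame:
    """Draw a four-group cohort table at the statistical level (normal
    within-group spread around configured condition means)."""
    means = means if means is not None else DEFAULT_SYNERGY_MEANS
    rng = np.random.default_rng(seed)
    rows = []
    for (m, c), mu in means.items():
        x = rng.normal(mu, abs(mu) * cv if mu != 0 else cv, n_per_group)
        for i, v in enumerate(x):
            rows.append({
                "oocyte_id": f"{'A' if m else 'c'}{'C' if c else 'o'}{i}",
                "hAQP5": m,
                "hCAII_ng": 10.0 if (c and ca_axis == "hCAII") else 0.0,
                "bCA": bool(c and ca_axis == "bCA"),
                metric: v})
    return pd.DataFrame(rows)


def null_group_table(mu: float = 0.02, sd: float = 0.005,
                     n_per_group: int = 10, seed: int = 0,
                     metric: str = "dpHS_up") -> pd.DataFrame:
    """Null generator: all four groups share one distribution."""
    means = {k: mu for k in DEFAULT_SYNERGY_MEANS}
    return generate_group_table(means, cv=sd / mu, n_per_group=n_per_group,
                                seed=seed, metric=metric)
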