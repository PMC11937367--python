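"""Organoid assay outcomes and the associated statistical battery.

Lung organoid cultures are seeded with a known number of epithelial
progenitor cells; structures larger than 50 µm at day 14 are counted and
measured. The module quantifies:

* colony-forming efficiency (CFE), the percentage of seeded cells that
  formed an organoid;
* diameter distributions (compared across conditions with two-sample
  Kolmogorov–Smirnov tests under a Bonferroni-corrected alpha, displayed on
  a log scale);
* organoid-type proportions (alveolar SPC+, airway ACT+, double-positive,
  double-negative);
* treatment effects versus a shared control via one-way ANOVA with
  Dunnett's many-to-one comparisons (paired / repeated-measures variant on
  within-replicate differences) and a paired percent-change CFE effect
  estimate with a bootstrap confidence interval.

Parametric-versus-nonparametric routing follows a four-test normality
battery (D'Agostino–Pearson, Anderson–Darling, Shapiro–Wilk,
Kolmogorov–Smirnov/Lilliefors): data are treated as normal when at least
three of the four tests fail to reject at alpha = 0.05.

:class:`OrganoidAssay` is the model object; :meth:`OrganoidAssay.fit`
returns :class:`OrganoidAssayResults` with comparison tables and
``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from ._util import round_half_up

__all__ = [
    "OrganoidExperiment",
    "ComparisonResult",
    "cfe",
    "filter_diameters",
    "ks_two_sample",
    "bonferroni_alpha",
    "normality_battery",
    "anova_dunnett",
    "effect_estimate",
    "organoid_type_proportions",
    "dunnett_max_abs_t_sf",
    "OrganoidAssay",
    "OrganoidAssayResults",
]

TYPE_CATEGORIES = ("SPC+", "ACT+", "SPC+/ACT+", "SPC-/ACT-")
MIN_DIAMETER_UM = 50.0


@dataclass
class OrganoidExperiment:
    """One organoid culture readout (one condition x one replicate)."""

    condition: str
    replicate_id: str
    n_seeded: int
    n_organoids: int
    diameters: list[float] = field(default_factory=list)
    type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_seeded < 0 or self.n_organoids < 0:
            raise ValueError("counts must be non-negative")
        if any(d < 0 for d in self.diameters):
            raise ValueError("diameters must be non-negative")
        if self.type_counts:
            bad = set(self.type_counts) - set(TYPE_CATEGORIES)
            if bad:
                raise ValueError(f"unknown organoid type categories: {sorted(bad)}")
            if any(v < 0 for v in self.type_counts.values()):
                raise ValueError("type counts must be non-negative")
            if sum(self.type_counts.values()) > self.n_organoids:
                raise ValueError("type counts exceed n_organoids")

    @property
    def cfe_percent(self) -> float:
        return cfe(self.n_organoids, self.n_seeded)


@dataclass
class ComparisonResult:
    """One statistical comparison (group versus control)."""

    group: str
    control: str
    statistic: float
    p_raw: float
    p_adjusted: float | None
    alpha_adjusted: float | None
    method: str
    n_per_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "control": self.control,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "alpha_adjusted": self.alpha_adjusted,
            "method": self.method,
            "n_per_group": dict(self.n_per_group),
        }


def cfe(n_organoids: int, n_seeded: int) -> float:
    """Colony-forming efficiency in percent: 100 * organoids / cells seeded."""
    if n_seeded <= 0:
        raise ValueError("n_seeded must be > 0")
    if n_organoids < 0:
        raise ValueError("n_organoids must be >= 0")
    return 100.0 * n_organoids / n_seeded


def filter_diameters(
    diameters: Sequence[float], min_diameter: float = MIN_DIAMETER_UM
) -> list[float]:
    """Strictly-greater-than size gate (> 50 µm by default), order preserved."""
    return [d for d in diameters if d > min_diameter]


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup_t |ECDF_x(t) - ECDF_y(t)|, with the asymptotic two-sided
    p-value at the effective sample size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(
    family_alpha: float = 0.05, m: int = 1
) -> tuple[float, str]:
    """Per-comparison alpha = family_alpha / m, plus a display string.

    The display convention renders four decimals (half-up) and drops to
    three when the fourth decimal shifts the value by at most 2e-4 —
    0.05/3 -> "0.0167", 0.05/4 -> "0.0125", 0.05/12 -> "0.004".
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must be in (0,1]")
    alpha = family_alpha / m
    r4 = round_half_up(alpha, 4)
    r3 = round_half_up(alpha, 3)
    display = f"{r3:.3f}" if abs(r3 - r4) <= 2e-4 + 1e-12 else f"{r4:.4f}"
    return alpha, display


def normality_battery(
    x: Sequence[float], alpha: float = 0.05
) -> tuple[dict[str, bool], bool]:
    """Run four normality tests; data count as normal if >= 3 do not reject.

    Tests: D'Agostino–Pearson omnibus, Anderson–Darling, Shapiro–Wilk and
    Kolmogorov–Smirnov (Lilliefors, parameters estimated). Returns
    ({test name: normal?}, parametric flag). Requires n >= 8.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(
            "normality battery needs n >= 8; use a nonparametric test instead"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        verdicts = {
            "dagostino_pearson": stats.normaltest(x).pvalue > alpha,
            "anderson_darling": normal_ad(x)[1] > alpha,
            "shapiro_wilk": stats.shapiro(x).pvalue > alpha,
            "kolmogorov_smirnov": lilliefors(x, dist="norm")[1] > alpha,
        }
    verdicts = {k: bool(v) for k, v in verdicts.items()}
    return verdicts, sum(verdicts.values()) >= 3


def dunnett_max_abs_t_sf(q: float, k: int, df: int) -> float:
    """P(max_j |T_j| >= q) for Dunnett's many-to-one statistics.

    T_1..T_k are equicorrelated (rho = 1/2) multivariate-t with ``df``
    degrees of freedom — the distribution of the k treatment-vs-control t
    statistics under a balanced design with a common error variance.
    Evaluated by Gauss–Hermite quadrature over the shared control variate
    and adaptive quadrature over the pooled scale.
    """
    if q <= 0:
        return 1.0
    if k < 1 or df < 1:
        raise ValueError("need k >= 1 and df >= 1")
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    z = nodes * math.sqrt(2.0)  # standard-normal nodes
    w = weights / math.sqrt(math.pi)

    def inner(s: float) -> float:
        b = math.sqrt(2.0) * q * s
        probs = stats.norm.cdf(b - z) - stats.norm.cdf(-b - z)
        return float(np.sum(w * probs**k))

    # density of S = sqrt(chi2_df / df)
    log_c = (
        math.log(2.0)
        + 0.5 * df * math.log(df / 2.0)
        - math.lgamma(df / 2.0)
    )

    def outer(s: float) -> float:
        if s <= 0:
            return 0.0
        log_f = log_c + (df - 1) * math.log(s) - df * s * s / 2.0
        return math.exp(log_f) * inner(s)

    cdf, _ = integrate.quad(outer, 0.0, np.inf, limit=200)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def _paired_differences(
    groups: Mapping[str, Sequence[float]], control: str
) -> dict[str, np.ndarray]:
    ctrl = np.asarray(groups[control], dtype=float)
    n = ctrl.size
    diffs = {}
    for name, vals in groups.items():
        if name == control:
            continue
        v = np.asarray(vals, dtype=float)
        if v.size != n:
            raise ValueError(
                "paired analysis requires equal group lengths with shared "
                f"replicate order; {name!r} has {v.size}, control has {n}"
            )
        diffs[name] = v - ctrl
    return diffs


def _rm_anova_f(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA F and p (conditions x subjects)."""
    k, n = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=1)
    subj_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    if ss_err <= 0 or df_err <= 0:
        return float("inf") if ss_cond > 0 else 0.0, 1.0 if ss_cond == 0 else 0.0
    f = (ss_cond / df_cond) / (ss_err / df_err)
    return float(f), float(stats.f.sf(f, df_cond, df_err))


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    paired: bool = False,
    family_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """One-way ANOVA with Dunnett many-to-one comparisons versus control.

    Unpaired: ordinary one-way ANOVA; Dunnett-adjusted p-values from the
    multivariate-t many-to-one distribution. Paired (repeated measures):
    within-replicate differences versus control are tested jointly, with
    the equicorrelated (rho = 1/2) max-|t| adjustment at df = n - 1.
    All-identical inputs yield adjusted p = 1.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    others = [g for g in groups if g != control]
    n_per = {g: len(np.asarray(groups[g])) for g in groups}

    if paired:
        diffs = _paired_differences(groups, control)
        mat = np.vstack([np.asarray(groups[g], dtype=float) for g in groups])
        _, _ = _rm_anova_f(mat)  # omnibus computed for completeness
        k = len(diffs)
        results = []
        for name in others:
            d = diffs[name]
            n = d.size
            if n < 2:
                raise ValueError("paired comparison needs >= 2 replicates")
            sd = d.std(ddof=1)
            if sd == 0:
                t = 0.0 if d.mean() == 0 else math.copysign(float("inf"), d.mean())
            else:
                t = float(d.mean() / (sd / math.sqrt(n)))
            p_raw = (
                float(2 * stats.t.sf(abs(t), n - 1)) if math.isfinite(t) else 0.0
            )
            if t == 0.0:
                p_adj = 1.0
            elif not math.isfinite(t):
                p_adj = 0.0
            else:
                p_adj = dunnett_max_abs_t_sf(abs(t), k, n - 1)
            results.append(
                ComparisonResult(
                    group=name,
                    control=control,
                    statistic=t,
                    p_raw=p_raw,
                    p_adjusted=min(p_adj, 1.0),
                    alpha_adjusted=None,
                    method="paired one-way ANOVA, Dunnett test",
                    n_per_group={name: n, control: n},
                )
            )
        return results

    samples = [np.asarray(groups[g], dtype=float) for g in others]
    ctrl = np.asarray(groups[control], dtype=float)
    if np.ptp(np.concatenate(samples + [ctrl])) == 0:
        return [
            ComparisonResult(
                group=name,
                control=control,
                statistic=0.0,
                p_raw=1.0,
                p_adjusted=1.0,
                alpha_adjusted=None,
                method="one-way ANOVA, Dunnett test",
                n_per_group={name: n_per[name], control: n_per[control]},
            )
            for name in others
        ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dres = stats.dunnett(*samples, control=ctrl, alternative="two-sided")
    results = []
    for i, name in enumerate(others):
        t_raw, p_raw = stats.ttest_ind(samples[i], ctrl)
        results.append(
            ComparisonResult(
                group=name,
                control=control,
                statistic=float(dres.statistic[i]),
                p_raw=float(p_raw),
                p_adjusted=float(dres.pvalue[i]),
                alpha_adjusted=None,
                method="one-way ANOVA, Dunnett test",
                n_per_group={name: n_per[name], control: n_per[control]},
            )
        )
    return results


def effect_estimate(
    treated: Iterable[OrganoidExperiment],
    control: Iterable[OrganoidExperiment],
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Paired percent change in CFE of treated versus control cultures.

    Experiments are matched on ``replicate_id``; per pair the change is
    100 * (CFE_t - CFE_c) / CFE_c. Returns (mean percent change, percentile
    bootstrap CI over pairs, per-pair table). Pairs with zero control CFE
    are excluded with a warning.
    """
    t_by = {e.replicate_id: e for e in treated}
    c_by = {e.replicate_id: e for e in control}
    shared = sorted(set(t_by) & set(c_by))
    if not shared:
        raise ValueError("no matched replicate pairs")
    rows = []
    for rid in shared:
        cfe_c = c_by[rid].cfe_percent
        cfe_t = t_by[rid].cfe_percent
        if cfe_c == 0:
            warnings.warn(
                f"replicate {rid!r} excluded: control CFE is zero", stacklevel=2
            )
            continue
        rows.append(
            {
                "replicate_id": rid,
                "cfe_control": cfe_c,
                "cfe_treated": cfe_t,
                "percent_change": 100.0 * (cfe_t - cfe_c) / cfe_c,
            }
        )
    if not rows:
        raise ValueError("all pairs excluded (control CFE zero)")
    table = pd.DataFrame(rows)
    changes = table["percent_change"].to_numpy()
    mean = float(changes.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, changes.size, size=(n_boot, changes.size))
    boot = changes[idx].mean(axis=1)
    lo, hi = np.quantile(boot, [(1 - ci_level) / 2, (1 + ci_level) / 2])
    return mean, (float(lo), float(hi)), table


def organoid_type_proportions(
    type_counts: Mapping[str, int]
) -> dict[str, float]:
    """Percentage of organoids per immunostaining category (sums to 100)."""
    total = sum(type_counts.values())
    if total <= 0:
        raise ValueError("total type count must be > 0")
    return {k: 100.0 * v / total for k, v in type_counts.items()}


class OrganoidAssay:
    """Organoid assay analysis model.

    Built from a set of :class:`OrganoidExperiment` readouts spanning
    conditions (one of which is the control) and replicates. ``fit()``
    compares CFE across conditions (ANOVA + Dunnett, paired when requested),
    compares log-diameter distributions against control with two-sample KS
    tests under a Bonferroni-corrected alpha, and estimates the paired
    percent CFE change per condition.
    """

    def __init__(
        self,
        experiments: Sequence[OrganoidExperiment],
        control: str,
        paired: bool = False,
        min_diameter: float = MIN_DIAMETER_UM,
        family_alpha: float = 0.05,
        seed: int = 0,
    ):
        if not experiments:
            raise ValueError("no experiments supplied")
        conditions = {e.condition for e in experiments}
        if control not in conditions:
            raise ValueError(f"control condition {control!r} not present")
        self.experiments = list(experiments)
        self.control = control
        self.paired = paired
        self.min_diameter = min_diameter
        self.family_alpha = family_alpha
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        diameters: pd.DataFrame | None = None,
        control: str = "control",
        **kwargs,
    ) -> "OrganoidAssay":
        """Build from tidy frames.

        ``counts``: condition, replicate_id, n_seeded, n_organoids and
        optionally one column per type category. ``diameters`` (long
        format): condition, replicate_id, diameter_um.
        """
        experiments = []
        for _, row in counts.iterrows():
            tc = {
                c: int(row[c])
                for c in TYPE_CATEGORIES
                if c in counts.columns and not pd.isna(row[c])
            }
            diams: list[float] = []
            if diameters is not None:
                sel = diameters[
                    (diameters["condition"] == row["condition"])
                    & (diameters["replicate_id"].astype(str) == str(row["replicate_id"]))
                ]
                diams = sel["diameter_um"].astype(float).tolist()
            experiments.append(
                OrganoidExperiment(
                    condition=str(row["condition"]),
                    replicate_id=str(row["replicate_id"]),
                    n_seeded=int(row["n_seeded"]),
                    n_organoids=int(row["n_organoids"]),
                    diameters=diams,
                    type_counts=tc,
                )
            )
        return cls(experiments, control=control, **kwargs)

    def _by_condition(self) -> dict[str, list[OrganoidExperiment]]:
        out: dict[str, list[OrganoidExperiment]] = {}
        for e in self.experiments:
            out.setdefault(e.condition, []).append(e)
        for exps in out.values():
            exps.sort(key=lambda e: str(e.replicate_id))
        return out

    def fit(self) -> "OrganoidAssayResults":
        by_cond = self._by_condition()
        others = [c for c in by_cond if c != self.control]

        cfe_groups = {
            cond: [e.cfe_percent for e in exps] for cond, exps in by_cond.items()
        }
        cfe_comparisons = anova_dunnett(
            cfe_groups, self.control, paired=self.paired,
            family_alpha=self.family_alpha,
        )

        m = max(len(others), 1)
        alpha_adj, alpha_display = bonferroni_alpha(self.family_alpha, m)
        diam_comparisons = []
        ctrl_d = np.log(
            filter_diameters(
                [d for e in by_cond[self.control] for d in e.diameters],
                self.min_diameter,
            )
        )
        for cond in others:
            d = np.log(
                filter_diameters(
                    [x for e in by_cond[cond] for x in e.diameters],
                    self.min_diameter,
                )
            )
            if ctrl_d.size == 0 or d.size == 0:
                continue
            D, p = ks_two_sample(d, ctrl_d)
            diam_comparisons.append(
                ComparisonResult(
                    group=cond,
                    control=self.control,
                    statistic=D,
                    p_raw=p,
                    p_adjusted=None,
                    alpha_adjusted=alpha_adj,
                    method=(
                        "Kolmogorov-Smirnov test, Bonferroni correction: "
                        f"alpha = {alpha_display}"
                    ),
                    n_per_group={cond: int(d.size), self.control: int(ctrl_d.size)},
                )
            )

        effects = {}
        for cond in others:
            try:
                mean, ci, table = effect_estimate(
                    by_cond[cond], by_cond[self.control], seed=self.seed
                )
                effects[cond] = {"mean_percent_change": mean, "ci95": ci,
                                 "pairs": table}
            except ValueError:
                continue

        type_props = {}
        for cond, exps in by_cond.items():
            total: dict[str, int] = {}
            for e in exps:
                for k, v in e.type_counts.items():
                    total[k] = total.get(k, 0) + v
            if total:
                type_props[cond] = organoid_type_proportions(total)

        return OrganoidAssayResults(
            model=self,
            cfe_by_condition=cfe_groups,
            cfe_comparisons=cfe_comparisons,
            diameter_comparisons=diam_comparisons,
            effects=effects,
            type_proportions=type_props,
            alpha_adjusted_display=alpha_display,
        )


@dataclass
class OrganoidAssayResults:
    """Fitted organoid assay: comparisons, effects, proportions."""

    model: OrganoidAssay
    cfe_by_condition: dict[str, list[float]]
    cfe_comparisons: list[ComparisonResult]
    diameter_comparisons: list[ComparisonResult]
    effects: dict[str, dict]
    type_proportions: dict[str, dict[str, float]]
    alpha_adjusted_display: str

    def summary(self) -> str:
        lines = ["Organoid assay analysis", "=" * 25]
        lines.append(
            f"control = {self.model.control!r}, "
            f"{'paired' if self.model.paired else 'unpaired'} design"
        )
        lines.append("")
        lines.append("CFE (%) by condition (mean +/- SEM):")
        for cond, vals in self.cfe_by_condition.items():
            v = np.asarray(vals)
            sem = v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else float("nan")
            lines.append(f"  {cond:<14} {v.mean():7.3f} +/- {sem:.3f} (n={v.size})")
        lines.append("")
        lines.append("CFE comparisons vs control (Dunnett-adjusted):")
        for c in self.cfe_comparisons:
            lines.append(
                f"  {c.group:<14} t={c.statistic:7.3f}  p_adj={c.p_adjusted:.4g}"
            )
        if self.diameter_comparisons:
            lines.append("")
            lines.append(
                "Diameter distributions vs control "
                f"(KS, Bonferroni alpha = {self.alpha_adjusted_display}):"
            )
            for c in self.diameter_comparisons:
                verdict = "significant" if c.p_raw < c.alpha_adjusted else "ns"
                lines.append(
                    f"  {c.group:<14} D={c.statistic:.4f}  p={c.p_raw:.4g} "
                    f"[{verdict}]"
                )
        if self.effects:
            lines.append("")
            lines.append("Paired CFE percent change vs control:")
            for cond, eff in self.effects.items():
                lo, hi = eff["ci95"]
                lines.append(
                    f"  {cond:<14} {eff['mean_percent_change']:+7.1f}% "
                    f"(95% CI {lo:+.1f} .. {hi:+.1f})"
                )
        if self.type_proportions:
            lines.append("")
            lines.append("Organoid type proportions (%):")
            for cond, props in self.type_proportions.items():
                body = ", ".join(f"{k}={v:.1f}" for k, v in props.items())
                lines.append(f"  {cond:<14} {body}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "control": self.model.control,
            "paired": self.model.paired,
            "cfe_by_condition": {k: list(v) for k, v in self.cfe_by_condition.items()},
            "cfe_comparisons": [c.to_dict() for c in self.cfe_comparisons],
            "diameter_comparisons": [c.to_dict() for c in self.diameter_comparisons],
            "effects": {
                k: {
                    "mean_percent_change": v["mean_percent_change"],
                    "ci95": list(v["ci95"]),
                }
                for k, v in self.effects.items()
            },
            "type_proportions": self.type_proportions,
        }
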