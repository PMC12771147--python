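"""Two-factor full factorial design with centre points for acquisition tuning.

The image-acquisition conditions — camera-to-sample distance (5-16 cm) and
internal LED intensity (minimum to maximum, about 1124 lx) — are optimised
with a 2x2 full factorial design augmented with five centre points: the four
corner runs estimate the main and interaction effects, the replicated centre
estimates pure error and curvature.  The response is the relative error (%)
of the calibration predictions, to be minimised.

Effects are corner-mean contrasts: ``effect = mean(+1) - mean(-1)`` (the
interaction uses the product column).  With unreplicated corners the standard
error of an effect comes from the centre replicates,
``se = 2 * s_centre / sqrt(4)``, with ``n_centre - 1`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Factor",
    "FactorialDesign",
    "EffectEstimates",
    "build_design",
    "estimate_effects",
    "desirability_minimize",
]


@dataclass(frozen=True)
class Factor:
    """One design factor with its actual low/high levels."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be below high")

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def actual(self, coded: float) -> float:
        return self.mid + coded * self.half_range


@dataclass
class FactorialDesign:
    """2x2 design with centre points: run table plus factor definitions.

    ``runs`` has columns ``run, coded_a, coded_b, actual_a, actual_b,
    response`` (response NaN until filled); corners are in standard Yates
    order, centre runs last.
    """

    factor_a: Factor
    factor_b: Factor
    runs: pd.DataFrame

    @property
    def n_center(self) -> int:
        return int(((self.runs["coded_a"] == 0) & (self.runs["coded_b"] == 0)).sum())

    def randomized_order(self, seed: int) -> np.ndarray:
        """Run execution order, randomised reproducibly under *seed*."""
        rng = np.random.default_rng(seed)
        return rng.permutation(self.runs["run"].to_numpy())

    def with_responses(self, responses) -> "FactorialDesign":
        responses = np.asarray(responses, dtype=float).ravel()
        if responses.size != len(self.runs):
            raise ValueError(f"need {len(self.runs)} responses, got {responses.size}")
        runs = self.runs.copy()
        runs["response"] = responses
        return FactorialDesign(self.factor_a, self.factor_b, runs)


def build_design(factor_a: Factor, factor_b: Factor, n_center: int = 5) -> FactorialDesign:
    """Build the 2x2 + centre-point run table in standard order.

    The four corners appear once each in Yates order ((-,-), (+,-), (-,+),
    (+,+)), followed by *n_center* centre runs; actual factor settings map
    from coded levels via ``actual = mid + coded * half_range``.
    """
    if n_center < 2:
        raise ValueError("need at least two centre points to estimate pure error")
    coded = [(-1, -1), (1, -1), (-1, 1), (1, 1)] + [(0, 0)] * n_center
    runs = pd.DataFrame(
        {
            "run": np.arange(1, len(coded) + 1),
            "coded_a": [a for a, _ in coded],
            "coded_b": [b for _, b in coded],
        }
    )
    runs["actual_a"] = [factor_a.actual(a) for a in runs["coded_a"]]
    runs["actual_b"] = [factor_b.actual(b) for b in runs["coded_b"]]
    runs["response"] = np.nan
    return FactorialDesign(factor_a, factor_b, runs)


@dataclass(frozen=True)
class EffectEstimates:
    """Estimated effects with centre-point-based significance assessment."""

    effect_a: float
    effect_b: float
    effect_ab: float
    se_effect: float
    t_a: float
    t_b: float
    t_ab: float
    p_a: float
    p_b: float
    p_ab: float
    curvature: float
    df: int
    pareto_order: tuple[str, ...]
    half_normal_coords: tuple[tuple[float, float], ...]

    def effects(self) -> dict[str, float]:
        return {"A": self.effect_a, "B": self.effect_b, "AB": self.effect_ab}

    def summary(self) -> str:
        lines = [
            "2x2 factorial effects (centre-point error)",
            "-" * 46,
            f"{'term':<6}{'effect':>12}{'t':>10}{'p':>10}",
        ]
        for name, eff, t, p in [
            ("A", self.effect_a, self.t_a, self.p_a),
            ("B", self.effect_b, self.t_b, self.p_b),
            ("AB", self.effect_ab, self.t_ab, self.p_ab),
        ]:
            lines.append(f"{name:<6}{eff:>12.4g}{t:>10.3g}{p:>10.3g}")
        lines += [
            f"se(effect)  {self.se_effect:.4g}  (df={self.df})",
            f"curvature (corner mean - centre mean)  {self.curvature:.4g}",
            "Pareto order  " + " > ".join(self.pareto_order),
        ]
        return "\n".join(lines)

    def plot_pareto(self, ax=None):
        """Horizontal Pareto chart of |t| per effect."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ts = {"A": abs(self.t_a), "B": abs(self.t_b), "AB": abs(self.t_ab)}
        names = list(self.pareto_order)[::-1]
        ax.barh(names, [ts[n] for n in names])
        t_crit = stats.t.ppf(0.975, self.df)
        ax.axvline(t_crit, color="red", linestyle="--", label="t crit (95%)")
        ax.set_xlabel("|t|")
        ax.legend()
        return ax


def estimate_effects(design: FactorialDesign) -> EffectEstimates:
    """Estimate main and interaction effects from a completed design.

    Centre points do not enter the effect contrasts; they supply the pure
    error (``se = 2 s_centre / sqrt(4)``, df = n_centre - 1) and the
    curvature check (corner mean minus centre mean).
    """
    runs = design.runs
    if runs["response"].isna().any():
        raise ValueError("design has missing responses")
    corners = runs[(runs["coded_a"] != 0) | (runs["coded_b"] != 0)]
    centers = runs[(runs["coded_a"] == 0) & (runs["coded_b"] == 0)]
    if len(corners) != 4 or len(centers) < 2:
        raise ValueError("expected 4 corner runs and at least 2 centre runs")
    y = corners["response"].to_numpy()
    a = corners["coded_a"].to_numpy()
    b = corners["coded_b"].to_numpy()
    ab = a * b
    effects = {
        "A": float(y[a == 1].mean() - y[a == -1].mean()),
        "B": float(y[b == 1].mean() - y[b == -1].mean()),
        "AB": float(y[ab == 1].mean() - y[ab == -1].mean()),
    }
    s_center = float(centers["response"].std(ddof=1))
    se = 2.0 * s_center / np.sqrt(4.0)
    df = len(centers) - 1
    ts = {}
    ps = {}
    for name, eff in effects.items():
        if se == 0.0:
            t = 0.0 if eff == 0.0 else float(np.sign(eff)) * float("inf")
        else:
            t = eff / se
        ts[name] = t
        ps[name] = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    curvature = float(y.mean() - centers["response"].to_numpy().mean())
    pareto = tuple(sorted(effects, key=lambda k: (-abs(ts[k]), k)))
    # half-normal plot: ordered |effects| against half-normal quantiles
    ordered = sorted(effects.values(), key=abs)
    m = len(ordered)
    coords = tuple(
        (float(stats.norm.ppf(0.5 + 0.5 * (i - 0.5) / m)), abs(e))
        for i, e in enumerate(ordered, start=1)
    )
    return EffectEstimates(
        effect_a=effects["A"],
        effect_b=effects["B"],
        effect_ab=effects["AB"],
        se_effect=se,
        t_a=ts["A"],
        t_b=ts["B"],
        t_ab=ts["AB"],
        p_a=ps["A"],
        p_b=ps["B"],
        p_ab=ps["AB"],
        curvature=curvature,
        df=df,
        pareto_order=pareto,
        half_normal_coords=coords,
    )


def desirability_minimize(y: float, low: float, high: float) -> float:
    """Linear minimise-type desirability: 1 at *low* (best), 0 at *high*.

    ``d = (high - y) / (high - low)`` clipped to [0, 1]; used to score a
    relative-error response where smaller is better.
    """
    if not low < high:
        raise ValueError("low must be below high")
    return float(np.clip((high - y) / (high - low), 0.0, 1.0))
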