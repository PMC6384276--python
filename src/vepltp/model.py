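"""The LTP-memory statistical battery as a fitted-model object.

``LTPMemoryModel`` is constructed from a participant-level table (genotype,
early/late LTP scores in microvolts, memory index in percent) and ``fit()``
returns an ``LTPMemoryResults`` carrying the full default-prior Bayes-factor
battery: regression and correlation tests of each LTP phase against memory,
one-way genotype ANOVAs on each measure, and all pairwise genotype
contrasts, with ``summary()`` rendering the table the analysis reports.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes
from .bayes import BayesResult, format_probability
from .simulate import GENOTYPES

MEASURES = ("late_ltp", "early_ltp", "memory")
_MEASURE_LABEL = {"late_ltp": "late LTP", "early_ltp": "early LTP",
                  "memory": "Memory performance"}


@dataclass
class StatsParams:
    r_scale_regression: float = 0.354
    kappa_correlation: float = 1.0
    r_scale_anova: float = 0.5
    r_scale_pairwise: float = 0.701


class LTPMemoryModel:
    """Bayesian battery relating sensory LTP, memory and genotype.

    Parameters
    ----------
    data:
        One row per participant with columns ``genotype`` (Val/Val, Val/Met
        or Met/Met), ``early_ltp``, ``late_ltp`` (pre-minus-post N1b
        amplitude, uV) and ``memory`` (percent correct).
    """

    required_columns = ("genotype", "early_ltp", "late_ltp", "memory")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.required_columns if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if data[list(self.required_columns)].isna().any().any():
            raise ValueError("table contains missing values")
        unknown = set(data["genotype"]) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotypes: {sorted(unknown)}")
        if len(data) < 6:
            raise ValueError("need at least 6 participants")
        self.data = data.reset_index(drop=True)
        self.genotypes = [g for g in GENOTYPES if g in set(data["genotype"])]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "LTPMemoryModel":
        return cls(data)

    def group_values(self, measure: str) -> dict[str, np.ndarray]:
        return {g: self.data.loc[self.data["genotype"] == g, measure].to_numpy()
                for g in self.genotypes}

    def fit(self, params: StatsParams | None = None) -> "LTPMemoryResults":
        params = params if params is not None else StatsParams()
        n = len(self.data)
        memory = self.data["memory"].to_numpy()

        regression, correlation = {}, {}
        for phase in ("late_ltp", "early_ltp"):
            ltp = self.data[phase].to_numpy()
            r = bayes.pearson_r(ltp, memory)
            regression[phase] = (
                r, bayes.jzs_regression_bf(n, r ** 2,
                                           r_scale=params.r_scale_regression))
            correlation[phase] = (
                r, bayes.correlation_bf(r, n, kappa=params.kappa_correlation))

        anova, pairwise = {}, {}
        for measure in MEASURES:
            groups = self.group_values(measure)
            anova[measure] = bayes.anova_bf_oneway(
                list(groups.values()), r_scale=params.r_scale_anova)
            pairwise[measure] = {
                (g1, g2): bayes.ttest_bf_independent(
                    groups[g1], groups[g2], r_scale=params.r_scale_pairwise)
                for g1, g2 in itertools.combinations(self.genotypes, 2)
            }

        group_means = {
            measure: {g: float(v.mean())
                      for g, v in self.group_values(measure).items()}
            for measure in MEASURES}
        return LTPMemoryResults(
            model=self, params=params, n=n, regression=regression,
            correlation=correlation, anova=anova, pairwise=pairwise,
            group_means=group_means)


@dataclass
class LTPMemoryResults:
    """Fitted battery: Bayes factors, posterior model probabilities and
    group descriptives, with tabular/JSON/plot output."""

    model: LTPMemoryModel
    params: StatsParams
    n: int
    regression: dict[str, tuple[float, BayesResult]]
    correlation: dict[str, tuple[float, BayesResult]]
    anova: dict[str, BayesResult]
    pairwise: dict[str, dict[tuple[str, str], BayesResult]]
    group_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        rows = []
        for phase, (r, res) in self.regression.items():
            rows.append({"analysis": "regression",
                         "measure": phase, "contrast": "memory",
                         "family": res.prior.family,
                         "r_scale": res.prior.r_scale, "statistic": r,
                         "bf10": res.bf10, "posterior_prob": res.posterior_prob,
                         "bfm": res.bfm, "n": self.n})
        for phase, (r, res) in self.correlation.items():
            rows.append({"analysis": "correlation",
                         "measure": phase, "contrast": "memory",
                         "family": res.prior.family,
                         "r_scale": res.prior.r_scale, "statistic": r,
                         "bf10": res.bf10, "posterior_prob": res.posterior_prob,
                         "bfm": res.bfm, "n": self.n})
        for measure, res in self.anova.items():
            rows.append({"analysis": "anova", "measure": measure,
                         "contrast": "genotype", "family": res.prior.family,
                         "r_scale": res.prior.r_scale, "statistic": np.nan,
                         "bf10": res.bf10, "posterior_prob": res.posterior_prob,
                         "bfm": res.bfm, "n": self.n})
        for measure, tests in self.pairwise.items():
            for (g1, g2), res in tests.items():
                rows.append({"analysis": "pairwise", "measure": measure,
                             "contrast": f"{g1} vs {g2}",
                             "family": res.prior.family,
                             "r_scale": res.prior.r_scale, "statistic": np.nan,
                             "bf10": res.bf10,
                             "posterior_prob": res.posterior_prob,
                             "bfm": res.bfm, "n": self.n})
        return rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_records())

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "prior_scales": {
                "regression": self.params.r_scale_regression,
                "correlation_kappa": self.params.kappa_correlation,
                "anova": self.params.r_scale_anova,
                "pairwise": self.params.r_scale_pairwise,
            },
            "group_means": self.group_means,
            "tests": self.to_records(),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def largest_pairwise(self, measure: str) -> tuple[str, str]:
        tests = self.pairwise[measure]
        return max(tests, key=lambda k: tests[k].bf10)

    def summary(self) -> str:
        lines = [
            "LTP-memory Bayesian battery",
            "=" * 60,
            f"Participants: n = {self.n}",
            "",
            "Group means",
            "-" * 60,
        ]
        for measure in MEASURES:
            means = ", ".join(f"{g}: {m:.2f}"
                              for g, m in self.group_means[measure].items())
            lines.append(f"  {_MEASURE_LABEL[measure]:18s} {means}")
        lines += ["", "LTP as a predictor of memory", "-" * 60]
        for phase in ("late_ltp", "early_ltp"):
            r, reg = self.regression[phase]
            _, cor = self.correlation[phase]
            lines.append(
                f"  {_MEASURE_LABEL[phase]:10s} regression (r scale "
                f"{reg.prior.r_scale:.3f}): P(M|data) = "
                f"{format_probability(reg.posterior_prob)}, "
                f"BF_M = {reg.bfm:.2f}")
            lines.append(
                f"  {_MEASURE_LABEL[phase]:10s} correlation r = {r:.2f}, "
                f"BF10 = {cor.bf10:.2f}")
        lines += ["", "Genotype effects", "-" * 60]
        for measure in MEASURES:
            res = self.anova[measure]
            lines.append(
                f"  ANOVA on {_MEASURE_LABEL[measure]} (r scale "
                f"{res.prior.r_scale:.2f}): P(M|data) = "
                f"{format_probability(res.posterior_prob)}, "
                f"BF_M = {res.bfm:.2f}")
            for (g1, g2), t in self.pairwise[measure].items():
                lines.append(f"      {g1} vs {g2}: BF10 = {t.bf10:.2f}")
        return "\n".join(lines)

    # ---------------------------------------------------------------- plots

    def plot_association(self, phase: str = "late_ltp", ax=None):
        """Scatter of memory against an LTP phase with the least-squares line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        for g, sub in df.groupby("genotype"):
            ax.scatter(sub[phase], sub["memory"], label=g, s=25)
        x = df[phase].to_numpy()
        b, a = np.polyfit(x, df["memory"].to_numpy(), 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, "k--", lw=1)
        r, res = self.correlation[phase]
        ax.set_xlabel(f"{_MEASURE_LABEL[phase]} (uV)")
        ax.set_ylabel("Memory score (%)")
        ax.set_title(f"r = {r:.2f}, BF10 = {res.bf10:.2f}")
        ax.legend()
        return ax

    def plot_by_genotype(self, measure: str = "late_ltp", ax=None):
        """Per-genotype distribution of a measure (strip + group mean)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        for i, g in enumerate(self.model.genotypes):
            vals = df.loc[df["genotype"] == g, measure].to_numpy()
            jitter = (np.arange(vals.size) - vals.size / 2) * 0.02
            ax.scatter(np.full(vals.size, i) + jitter, vals, s=20, alpha=0.7)
            ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k")
        ax.set_xticks(range(len(self.model.genotypes)),
                      self.model.genotypes)
        ax.set_ylabel(_MEASURE_LABEL[measure])
        return ax
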