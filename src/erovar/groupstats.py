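"""Statistical layer: rank-based group comparison, KS tests, bootstrap
standard errors, log reduction, and the single-cell survival analysis.

Two statsmodels-style model objects expose the headline analyses:

* :class:`StabilityClassModel` — Kruskal-Wallis with Dunn's post hoc z-tests
  over the labelled ddG classes (selected / accessible / natural).
* :class:`MicrocolonySurvivalModel` — survival fractions with bootstrap
  standard errors, the PA+/PA- survival ratio, and pairwise
  Kolmogorov-Smirnov comparisons of resuscitation-time distributions, from a
  per-cell microcolony outcome table.

Each model is built from data, ``fit()`` returns a results object carrying
the estimates and diagnostics, and ``summary()`` renders a table.

The published per-colony random-effects model for survival (a GLMM) is not
reimplemented; a colony-clustered bootstrap (resample colonies, then cells
within colonies) is provided as the documented alternative and is labelled
as such in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "MicrocolonyOutcome",
    "SurvivalSummary",
    "kruskal_wallis_dunn",
    "ks_two_sample",
    "bootstrap_se_fraction",
    "log_reduction",
    "microcolony_survival_analysis",
    "StabilityClassModel",
    "MicrocolonySurvivalModel",
]


def _tier(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _adjust(p_raw: Sequence[float], method: str) -> List[float]:
    if method == "bonferroni":
        m = len(p_raw)
        return [min(1.0, m * p) for p in p_raw]
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(p_raw, method=method)[1])


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis H/p plus Dunn pairwise z-tests over all group pairs."""

    H: float
    p: float
    pairwise: Tuple[Tuple[str, str, float, float, float, str], ...]
    group_sizes: Dict[str, int] = field(default_factory=dict)
    adjust_method: str = "bonferroni"

    def significant_pairs(self, alpha: float = 0.05) -> List[Tuple[str, str]]:
        return [(a, b) for a, b, _, _, padj, _ in self.pairwise if padj <= alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairwise,
            columns=["group_a", "group_b", "z", "p_raw", "p_adjusted", "tier"],
        )


def kruskal_wallis_dunn(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> GroupTestResult:
    """Kruskal-Wallis test (tie-corrected) with Dunn's post hoc z-tests.

    Dunn's statistic for groups i, j compares mean ranks over the pooled
    sample: z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    Two-sided normal p-values are adjusted by ``adjust`` (Bonferroni by
    default, the correction used elsewhere in the study design).
    """
    names = [k for k in groups if len(groups[k]) > 0]
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups")
    vecs = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(vecs)
    n = np.array([len(v) for v in vecs])
    N = int(n.sum())

    if np.all(pooled == pooled[0]):
        # no variation anywhere: H = 0, nothing to flag
        pairs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append((names[i], names[j], 0.0, 1.0, 1.0, "ns"))
        return GroupTestResult(
            H=0.0, p=1.0, pairwise=tuple(pairs),
            group_sizes={k: int(len(groups[k])) for k in names},
            adjust_method=adjust,
        )

    H, p = stats.kruskal(*vecs)

    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + list(n[:-1]))
    mean_ranks = np.array(
        [ranks[o:o + ni].mean() for o, ni in zip(offsets, n)]
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term

    raw: List[float] = []
    zs: List[Tuple[int, int, float]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = math.sqrt(base_var * (1.0 / n[i] + 1.0 / n[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_ij = 2.0 * stats.norm.sf(abs(z))
            zs.append((i, j, z))
            raw.append(min(1.0, p_ij))
    adj = _adjust(raw, adjust)
    pairs = tuple(
        (names[i], names[j], float(z), float(pr), float(pa), _tier(pa))
        for (i, j, z), pr, pa in zip(zs, raw, adj)
    )
    return GroupTestResult(
        H=float(H), p=float(p), pairwise=pairs,
        group_sizes={k: int(len(groups[k])) for k in names},
        adjust_method=adjust,
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup|ECDF_a - ECDF_b|, asymptotic p."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bootstrap_se_fraction(
    outcomes: Sequence[int],
    B: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Bootstrap SE of a success fraction.

    Resamples the n binary outcomes with replacement B times, takes the
    fraction each time, and returns the standard deviation of the B
    fractions. Deterministic for a fixed seed.
    """
    x = np.asarray(outcomes, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty outcome vector")
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # chunk to bound memory at ~8e6 draws per block
    block = max(1, int(8e6) // n)
    fracs = np.empty(B)
    done = 0
    while done < B:
        b = min(block, B - done)
        idx = rng.integers(0, n, size=(b, n))
        fracs[done:done + b] = x[idx].mean(axis=1)
        done += b
    return float(fracs.std(ddof=0))


def log_reduction(N0: float, N: float) -> float:
    """Logarithmic reduction factor log10(N0/N) for viable counts (CFU/ml)."""
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    if N <= 0:
        raise ValueError(
            "N must be positive; counts below the limit of quantification "
            "(1,000 CFU/ml) should be set to that limit before computing"
        )
    return math.log10(N0 / N)


# ---------------------------------------------------------------------------
# microcolony outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrocolonyOutcome:
    """One cell of a microcolony after heat challenge.

    ``pa_status`` is "PA_plus" for cells bearing a protein aggregate,
    "PA_minus" otherwise; ``induced`` marks colonies whose founder was
    induced (and therefore contains one PA-bearing cell).
    ``resuscitation_time`` (hours to the first division after the heat
    shock) is present iff the cell survived.
    """

    colony_id: str
    cell_id: str
    pa_status: str
    induced: bool
    survived: bool
    resuscitation_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pa_status not in ("PA_plus", "PA_minus"):
            raise ValueError(f"invalid pa_status {self.pa_status!r}")
        if self.survived and self.resuscitation_time is None:
            raise ValueError("surviving cell must carry a resuscitation time")
        if self.resuscitation_time is not None and self.resuscitation_time < 0:
            raise ValueError("resuscitation time must be >= 0")

    @property
    def bin_label(self) -> str:
        if self.induced:
            return "PA_plus_induced" if self.pa_status == "PA_plus" else "PA_minus_induced"
        return "PA_minus_noninduced"


@dataclass(frozen=True)
class BinSummary:
    label: str
    n: int
    survivors: int
    fraction: float
    bootstrap_se: float


@dataclass(frozen=True)
class SurvivalSummary:
    """Per-bin survival with bootstrap SEs, the PA+/PA- ratio, lag-time
    ECDFs over survivors, and pairwise Bonferroni-adjusted KS tests."""

    bins: Dict[str, BinSummary]
    survival_ratio: Optional[float]
    lag_times: Dict[str, Tuple[float, ...]]
    ks_tests: Tuple[Tuple[str, str, float, float, float], ...]
    bootstrap_B: int
    cluster_bootstrap: bool
    se_method: str

    def lag_median(self, label: str) -> float:
        return float(np.median(self.lag_times[label]))

    def lag_median_shift(self, a: str, b: str) -> float:
        """Median resuscitation-time difference, bin b minus bin a."""
        return self.lag_median(b) - self.lag_median(a)


def _clustered_bootstrap_se(
    df: pd.DataFrame, B: int, rng: np.random.Generator
) -> float:
    """SE of the survival fraction under colony-resampling.

    Colonies are drawn with replacement, then cells within each drawn colony
    are drawn with replacement; the fraction is over all drawn cells.
    """
    groups = [g["survived"].to_numpy(dtype=float) for _, g in df.groupby("colony_id")]
    k = len(groups)
    fracs = np.empty(B)
    for b in range(B):
        chosen = rng.integers(0, k, size=k)
        tot = 0.0
        cnt = 0
        for ci in chosen:
            cells = groups[ci]
            idx = rng.integers(0, cells.size, size=cells.size)
            tot += cells[idx].sum()
            cnt += cells.size
        fracs[b] = tot / cnt
    return float(fracs.std(ddof=0))


def microcolony_survival_analysis(
    data: Iterable[MicrocolonyOutcome],
    B: int = 10_000,
    seed: Optional[int] = None,
    cluster_bootstrap: bool = False,
    adjust: str = "bonferroni",
) -> SurvivalSummary:
    """Bin cells by (induced, PA status) and summarise survival and lag.

    Survival fractions get bootstrap SEs (per-cell resampling by default,
    matching the study's SE estimator; ``cluster_bootstrap=True`` switches
    to colony-respecting resampling, the substitute for a per-colony
    random-effects model). The PA+/PA- survival ratio is computed within the
    induced arm. Resuscitation-time distributions cover survivors only, and
    all pairwise KS tests are Bonferroni-adjusted over the number of
    comparisons made.
    """
    cells = list(data)
    if not cells:
        raise ValueError("no microcolony outcomes provided")
    df = pd.DataFrame(
        {
            "colony_id": [c.colony_id for c in cells],
            "bin": [c.bin_label for c in cells],
            "survived": [c.survived for c in cells],
            "lag": [c.resuscitation_time for c in cells],
        }
    )
    rng = np.random.default_rng(seed)
    bins: Dict[str, BinSummary] = {}
    lags: Dict[str, Tuple[float, ...]] = {}
    for label, sub in df.groupby("bin", sort=True):
        outcomes = sub["survived"].to_numpy(dtype=int)
        frac = float(outcomes.mean())
        if cluster_bootstrap:
            se = _clustered_bootstrap_se(sub, B, rng)
        else:
            se = bootstrap_se_fraction(outcomes, B=B, rng=rng)
        bins[label] = BinSummary(
            label=label, n=int(outcomes.size), survivors=int(outcomes.sum()),
            fraction=frac, bootstrap_se=se,
        )
        lag = sub.loc[sub["survived"], "lag"].to_numpy(dtype=float)
        lags[label] = tuple(np.sort(lag))

    ratio: Optional[float] = None
    if "PA_plus_induced" in bins and "PA_minus_induced" in bins:
        denom = bins["PA_minus_induced"].fraction
        if denom == 0:
            raise ValueError("PA- survival fraction is 0; ratio undefined")
        ratio = bins["PA_plus_induced"].fraction / denom

    labels = [k for k in sorted(lags) if len(lags[k]) > 0]
    raw: List[float] = []
    ds: List[Tuple[str, str, float]] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            D, p = ks_two_sample(lags[labels[i]], lags[labels[j]])
            ds.append((labels[i], labels[j], D))
            raw.append(p)
    adj = _adjust(raw, adjust) if raw else []
    ks = tuple(
        (a, b, D, float(pr), float(pa))
        for (a, b, D), pr, pa in zip(ds, raw, adj)
    )
    return SurvivalSummary(
        bins=bins, survival_ratio=ratio, lag_times=lags, ks_tests=ks,
        bootstrap_B=B, cluster_bootstrap=cluster_bootstrap,
        se_method="colony-clustered bootstrap" if cluster_bootstrap
        else "per-cell bootstrap",
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class StabilityClassResults:
    """Results of the three-class ddG comparison."""

    def __init__(self, model: "StabilityClassModel", test: GroupTestResult):
        self.model = model
        self.test = test
        self.medians = {
            k: float(np.median(v)) for k, v in model.groups.items() if len(v)
        }
        self.quartiles = {
            k: tuple(np.percentile(v, [25, 75])) for k, v in model.groups.items()
            if len(v)
        }

    def summary(self) -> str:
        lines = [
            "Stability class comparison (Kruskal-Wallis + Dunn)",
            "=" * 52,
            f"H = {self.test.H:.4f}   p = {self.test.p:.3g}",
            "",
            f"{'class':<16}{'n':>6}{'median':>10}{'Q1':>8}{'Q3':>8}",
        ]
        for k, v in self.model.groups.items():
            if not len(v):
                continue
            q1, q3 = self.quartiles[k]
            lines.append(
                f"{k:<16}{len(v):>6}{self.medians[k]:>10.2f}{q1:>8.2f}{q3:>8.2f}"
            )
        lines.append("")
        lines.append(
            f"{'pair':<36}{'z':>8}{'p_raw':>10}{'p_adj':>10}  tier"
        )
        for a, b, z, pr, pa, tier in self.test.pairwise:
            lines.append(f"{a + ' vs ' + b:<36}{z:>8.3f}{pr:>10.3g}{pa:>10.3g}  {tier}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "H": self.test.H,
            "p": self.test.p,
            "medians": self.medians,
            "group_sizes": self.test.group_sizes,
            "pairwise": [list(row) for row in self.test.pairwise],
            "adjust_method": self.test.adjust_method,
        }


class StabilityClassModel:
    """Rank-based comparison of labelled ddG distributions.

    Built either from a ``ClassedDdg`` (``from_classes``) or from any
    mapping of labels to numeric vectors.
    """

    def __init__(self, groups: Mapping[str, Sequence[float]]):
        self.groups = {k: tuple(float(x) for x in v) for k, v in groups.items()}

    @classmethod
    def from_classes(cls, classes) -> "StabilityClassModel":
        return cls(classes.as_groups())

    def fit(self, adjust: str = "bonferroni") -> StabilityClassResults:
        test = kruskal_wallis_dunn(
            {k: v for k, v in self.groups.items() if len(v)}, adjust=adjust
        )
        return StabilityClassResults(self, test)


class MicrocolonySurvivalResults:
    """Results of the single-cell survival/resuscitation analysis."""

    def __init__(self, model: "MicrocolonySurvivalModel", summary: SurvivalSummary):
        self.model = model
        self._summary = summary

    @property
    def bins(self) -> Dict[str, BinSummary]:
        return self._summary.bins

    @property
    def survival_ratio(self) -> Optional[float]:
        return self._summary.survival_ratio

    @property
    def ks_tests(self):
        return self._summary.ks_tests

    @property
    def lag_times(self):
        return self._summary.lag_times

    def lag_median_shift(self, a: str = "PA_plus_induced",
                         b: str = "PA_minus_induced") -> float:
        return self._summary.lag_median_shift(a, b)

    def summary(self) -> str:
        s = self._summary
        lines = [
            "Single-cell survival and resuscitation",
            "=" * 46,
            f"SE method: {s.se_method} (B = {s.bootstrap_B})",
            "",
            f"{'bin':<22}{'n':>6}{'surv':>6}{'frac':>8}{'SE':>8}",
        ]
        for label, b in s.bins.items():
            lines.append(
                f"{label:<22}{b.n:>6}{b.survivors:>6}{b.fraction:>8.3f}"
                f"{b.bootstrap_se:>8.3f}"
            )
        if s.survival_ratio is not None:
            lines.append(f"\nPA+/PA- survival ratio (induced arm): "
                         f"{s.survival_ratio:.3f}")
        for label, lag in s.lag_times.items():
            if lag:
                lines.append(
                    f"median lag {label}: {float(np.median(lag)):.2f} h "
                    f"(n = {len(lag)} survivors)"
                )
        if s.ks_tests:
            lines.append("\nPairwise KS on resuscitation times "
                         "(Bonferroni-adjusted):")
            for a, b, D, pr, pa in s.ks_tests:
                lines.append(
                    f"  {a} vs {b}: D = {D:.3f}, p_raw = {pr:.3g}, "
                    f"p_adj = {pa:.3g} {_tier(pa)}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        s = self._summary
        return {
            "bins": {
                k: {
                    "n": b.n, "survivors": b.survivors,
                    "fraction": b.fraction, "bootstrap_se": b.bootstrap_se,
                }
                for k, b in s.bins.items()
            },
            "survival_ratio": s.survival_ratio,
            "lag_medians": {
                k: float(np.median(v)) for k, v in s.lag_times.items() if v
            },
            "ks_tests": [list(row) for row in s.ks_tests],
            "bootstrap_B": s.bootstrap_B,
            "se_method": s.se_method,
        }


class MicrocolonySurvivalModel:
    """Survival/resuscitation model over per-cell microcolony outcomes."""

    def __init__(self, outcomes: Sequence[MicrocolonyOutcome]):
        self.outcomes = list(outcomes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MicrocolonySurvivalModel":
        """Build from a table with columns colony_id, cell_id, induced,
        pa_status, survived, resuscitation_time_h."""
        out = []
        for row in df.itertuples(index=False):
            lag = getattr(row, "resuscitation_time_h", None)
            if lag is not None and (isinstance(lag, float) and math.isnan(lag)):
                lag = None
            out.append(
                MicrocolonyOutcome(
                    colony_id=str(row.colony_id),
                    cell_id=str(row.cell_id),
                    pa_status=str(row.pa_status),
                    induced=bool(row.induced),
                    survived=bool(row.survived),
                    resuscitation_time=None if lag is None else float(lag),
                )
            )
        return cls(out)

    def fit(
        self,
        B: int = 10_000,
        seed: Optional[int] = None,
        cluster_bootstrap: bool = False,
        adjust: str = "bonferroni",
    ) -> MicrocolonySurvivalResults:
        summary = microcolony_survival_analysis(
            self.outcomes, B=B, seed=seed,
            cluster_bootstrap=cluster_bootstrap, adjust=adjust,
        )
        return MicrocolonySurvivalResults(self, summary)
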