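"""Loss/gain rate estimation and treatment comparison for MA cohorts.

Rates follow the MA-experiment conventions: a lineage's loss rate is its
number of scored losses per generation per ancestral element copy (copies
counted as ancestral TD loci, since the assay sees presence only); the
germline transposition rate divides observed gains by ancestral copies x
total line-generations surveyed; the somatic gain rate divides
non-replicable new peaks by ancestral peaks at the assay endpoint.
Treatment means are compared with a t-test (pooled one-tailed by default:
segregation predicts higher loss in sexuals a priori), across families
with ANCOVA using ancestral copy number as a covariate, and the relation
between per-copy somatic activity and family size with ordinary least
squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scoring import PeakCall, PresenceMatrix, identify_high_loss_loci
from .segregation import Genotype, state_after_k_selfings

__all__ = [
    "RateSummary",
    "ComparisonResult",
    "RegressionResult",
    "loss_rate_per_lineage",
    "summarize_rates",
    "germline_gain_rate",
    "somatic_gain_rate",
    "somatic_rates_per_lineage",
    "compare_treatments",
    "regress_somatic_vs_copy_number",
    "ancova_rates",
    "expected_vs_observed_high_loss",
]


@dataclass
class RateSummary:
    """Per-treatment loss-rate summary for one transposon family."""

    family_id: str
    treatment: str
    n_lineages: int
    per_lineage_rates: list[float]
    mean_rate: float
    se_rate: float
    n_high_loss_loci: int

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.per_lineage_rates):
            raise ValueError("rates must be >= 0")
        if self.se_rate < 0:
            raise ValueError("se_rate must be >= 0")


@dataclass
class ComparisonResult:
    """Two-sample t-test between treatments on per-lineage rates."""

    t_statistic: float
    p_value: float
    df: float
    direction: str  # "sexual_greater" | "asexual_greater" | "none"


@dataclass
class RegressionResult:
    """Ordinary least-squares fit of a rate against copy number."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_model: int
    p_value: float


def loss_rate_per_lineage(losses: int, generations: int, ancestral_copies: int) -> float:
    """Losses per lineage per generation per ancestral element copy."""
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    if ancestral_copies < 1:
        raise ValueError(f"ancestral_copies must be >= 1, got {ancestral_copies}")
    if losses < 0:
        raise ValueError("losses must be >= 0")
    return losses / (generations * ancestral_copies)


def summarize_rates(
    matrix: PresenceMatrix,
    generations: Mapping[str, int],
    family_id: str = "family",
    high_loss_min: int = 3,
) -> dict[str, RateSummary]:
    """Per-treatment loss-rate summaries from a presence/absence matrix.

    Each lineage's rate uses its own generation count and the family's
    ancestral copy count (= number of matrix columns).  The standard error
    is the sample SD across lineages divided by sqrt(n), the usual MA
    convention.
    """
    n_loci = matrix.n_ancestral_loci
    if n_loci < 1:
        raise ValueError("matrix has no ancestral loci")
    losses = matrix.losses_per_lineage()
    n_high = len(identify_high_loss_loci(matrix, min_lineages=high_loss_min))
    out: dict[str, RateSummary] = {}
    for treatment in ("sexual", "asexual"):
        ids = matrix.treatments[matrix.treatments == treatment].index
        if len(ids) == 0:
            raise ValueError(f"treatment {treatment!r} has no lineages")
        rates = [
            loss_rate_per_lineage(int(losses[lid]), int(generations[lid]), n_loci)
            for lid in ids
        ]
        arr = np.asarray(rates, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out[treatment] = RateSummary(
            family_id=family_id,
            treatment=treatment,
            n_lineages=len(ids),
            per_lineage_rates=rates,
            mean_rate=float(arr.mean()),
            se_rate=se,
            n_high_loss_loci=n_high,
        )
    return out


def germline_gain_rate(
    gains: int, ancestral_copies: int, total_line_generations: int
) -> float:
    """Transposition rate per element per generation from observed gains.

    ``total_line_generations`` is the summed generation count over all
    surveyed lineages, so a single gain across a whole cohort yields a
    rate of order 1e-4 to 1e-5.
    """
    if ancestral_copies < 1:
        raise ValueError("ancestral_copies must be >= 1")
    if total_line_generations < 1:
        raise ValueError("total_line_generations must be >= 1")
    if gains < 0:
        raise ValueError("gains must be >= 0")
    return gains / (ancestral_copies * total_line_generations)


def somatic_gain_rate(n_somatic_peaks: int, n_ancestral_peaks: int) -> float:
    """New non-replicable peaks per ancestral peak (per assay endpoint)."""
    if n_ancestral_peaks < 1:
        raise ValueError("n_ancestral_peaks must be >= 1")
    if n_somatic_peaks < 0:
        raise ValueError("n_somatic_peaks must be >= 0")
    return n_somatic_peaks / n_ancestral_peaks


def somatic_rates_per_lineage(
    matrix: PresenceMatrix, calls: Iterable[PeakCall] | None = None
) -> pd.Series:
    """Per-lineage somatic gain rate: somatic calls / ancestral peaks present."""
    calls = matrix.new_calls if calls is None else list(calls)
    somatic_counts = pd.Series(0, index=matrix.presence.index, dtype=int)
    for c in calls:
        if c.category == "somatic" and c.lineage_id in somatic_counts.index:
            somatic_counts[c.lineage_id] += 1
    ancestral_present = matrix.presence.sum(axis=1)
    if (ancestral_present < 1).any():
        bad = ancestral_present[ancestral_present < 1].index.tolist()
        raise ValueError(f"lineages with zero ancestral peaks: {bad}")
    return somatic_counts / ancestral_present


def compare_treatments(
    rates_sexual: Sequence[float],
    rates_asexual: Sequence[float],
    variant: str = "pooled",
    tails: int = 1,
) -> ComparisonResult:
    """t-test of mean per-lineage loss rates, sexual vs asexual.

    Defaults to Student's pooled-variance test, one-tailed with
    H1: sexual > asexual (the direction segregation predicts a priori);
    Welch and two-tailed variants are available by flag.
    """
    a = np.asarray(rates_sexual, dtype=float)
    b = np.asarray(rates_asexual, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each treatment needs >= 2 lineages (variance undefined)")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    alternative = "greater" if tails == 1 else "two-sided"
    with warnings.catch_warnings():
        # A zero-loss treatment (constant sample) is a real, expected outcome
        # for segregation-only families; scipy's precision warning is noise.
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"),
                            alternative=alternative)
    t = float(res.statistic)
    if np.isnan(t):  # both samples constant and equal
        t = 0.0
        p = 0.5 if tails == 1 else 1.0
    else:
        p = float(res.pvalue)
    if t > 0:
        direction = "sexual_greater"
    elif t < 0:
        direction = "asexual_greater"
    else:
        direction = "none"
    return ComparisonResult(t_statistic=t, p_value=p, df=float(res.df), direction=direction)


def regress_somatic_vs_copy_number(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    log_copy_number: bool = False,
) -> RegressionResult:
    """OLS of per-copy somatic gain rate on ancestral family copy number.

    ``points`` are (copy_number, somatic_rate) pairs, one per family (or
    per family x treatment if treatments are not pooled).  Copy number may
    optionally be log-transformed.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (copy_number, rate) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("regression requires >= 3 points")
    if log_copy_number:
        if (x <= 0).any():
            raise ValueError("copy numbers must be positive for a log transform")
        x = np.log10(x)
    if np.ptp(y) == 0.0:
        # Constant response: zero explainable variance.
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                f_statistic=0.0, df_model=1, p_value=1.0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df_model=int(model.df_model),
        p_value=float(model.f_pvalue),
    )


def ancova_rates(
    data: pd.DataFrame, interaction: bool = False
) -> pd.DataFrame:
    """ANCOVA of per-lineage loss rates across families.

    Fits ``rate ~ treatment + copy_number`` (ancestral copy number as the
    covariate; optional treatment x copy-number interaction) and reports a
    Type II F test per term.  ``data`` needs columns ``family``,
    ``treatment``, ``rate``, ``copy_number`` with >= 2 families and both
    treatments represented.
    """
    required = {"family", "treatment", "rate", "copy_number"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if data["family"].nunique() < 2:
        raise ValueError("ANCOVA requires >= 2 families")
    if set(data["treatment"].unique()) != {"sexual", "asexual"}:
        raise ValueError(
            "rank-deficient design: both treatments (sexual, asexual) must be "
            "present to estimate a treatment effect"
        )
    formula = "rate ~ C(treatment) + copy_number"
    if interaction:
        formula += " + C(treatment):copy_number"
    if np.ptp(data["rate"].to_numpy(dtype=float)) == 0.0:
        # All responses identical: every effect explains exactly nothing.
        terms = ["C(treatment)", "copy_number"]
        if interaction:
            terms.append("C(treatment):copy_number")
        return pd.DataFrame({"F": 0.0, "p": 1.0, "df": 1.0}, index=terms)
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(
            "rank-deficient design: the covariate is collinear with the "
            "treatment/intercept terms; check that copy_number varies"
        )
    table = sm.stats.anova_lm(model, typ=2)
    out = table.loc[table.index != "Residual", ["F", "PR(>F)", "df"]]
    out = out.rename(columns={"PR(>F)": "p"})
    return out


def expected_vs_observed_high_loss(
    matrix: PresenceMatrix,
    high_loss_loci: Iterable[int] | None = None,
    n_selfing_bouts: int = 1,
) -> pd.DataFrame:
    """Observed vs independent-assortment-expected losses at high-loss loci.

    The expectation treats each high-loss locus as ancestrally heterozygous:
    with n sexual lineages and k selfing bouts, expected losses are
    ``n * P(absent after k selfings)`` (11.25 for n=45, k=1).  Loci with
    observed counts above expectation are flagged — the signature of local
    removal (excision/deletion) acting on top of chromosomal segregation.
    """
    if high_loss_loci is None:
        high_loss_loci = identify_high_loss_loci(matrix)
    sexual_ids = matrix.treatments[matrix.treatments == "sexual"].index
    n_sexual = len(sexual_ids)
    p_loss = state_after_k_selfings(Genotype.HET, n_selfing_bouts).p_absent
    expected = n_sexual * p_loss
    rows = []
    sexual_presence = matrix.presence.loc[sexual_ids]
    for locus in sorted(high_loss_loci):
        observed = int((~sexual_presence[locus]).sum())
        rows.append(
            {
                "locus": int(locus),
                "observed": observed,
                "expected": float(expected),
                "excess": observed > expected,
            }
        )
    return pd.DataFrame(rows, columns=["locus", "observed", "expected", "excess"])
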