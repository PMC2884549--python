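"""Scoring of triplicate transposon-display peak tables.

Implements the scoring rubric of a replicated TD assay: peaks below a
height threshold are discarded; sizes replicable in all three reactions
and shared across many lineages are ancestral loci; a novel size replicable
in all three reactions is a germline gain; a robust but non-replicable
novel peak is a putative somatic insertion.  Losses are scored purely as
the absence of a band at an ancestrally occupied size.  The central object
is the lineage x ancestral-locus presence/absence matrix from which loss
rates are estimated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import PeakTable

__all__ = [
    "PeakCall",
    "PresenceMatrix",
    "DEFAULT_HEIGHT_THRESHOLD",
    "bin_peaks",
    "identify_ancestral_loci",
    "classify_new_peaks",
    "build_matrix",
    "identify_high_loss_loci",
]

#: Default peak-height cutoff, calibrated below the floor of the synthetic
#: height distributions so no true peak is discarded.  Real fragment-analysis
#: exports need a user-supplied threshold.
DEFAULT_HEIGHT_THRESHOLD = 100.0

CATEGORIES = ("ancestral", "germline_gain", "somatic")


@dataclass(frozen=True)
class PeakCall:
    """One scored peak: a fragment size in one lineage with its category."""

    lineage_id: str
    fragment_bp: int
    category: str
    replicate_count: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.replicate_count not in (1, 2, 3):
            raise ValueError("replicate_count must be in {1, 2, 3}")
        if self.category == "germline_gain" and self.replicate_count != 3:
            raise ValueError("a germline gain must be replicable in all 3 reactions")
        if self.category == "somatic" and self.replicate_count == 3:
            raise ValueError("a somatic call cannot be replicable in all 3 reactions")


@dataclass
class PresenceMatrix:
    """Lineage x ancestral-locus occupancy, plus novel-peak calls.

    ``presence`` is a boolean DataFrame (rows: lineages, columns: ancestral
    fragment sizes in bp); ``treatments`` labels each lineage sexual or
    asexual; ``new_calls`` holds the germline-gain and somatic calls that
    fall outside the ancestral columns.
    """

    presence: pd.DataFrame
    treatments: pd.Series
    new_calls: list[PeakCall] = field(default_factory=list)

    def losses_per_lineage(self) -> pd.Series:
        """Number of absent entries (scored losses) in each lineage's row."""
        return (~self.presence).sum(axis=1)

    def absences_per_locus(self) -> pd.Series:
        """Number of lineages lacking each ancestral locus."""
        return (~self.presence).sum(axis=0)

    @property
    def n_ancestral_loci(self) -> int:
        return self.presence.shape[1]


def _cluster_sizes(sizes: np.ndarray, tolerance: int) -> dict[int, int]:
    """Greedy global binning of fragment sizes within ``tolerance`` bp.

    Sizes are sorted and chained into a cluster while within tolerance of
    the cluster's anchor (its smallest member); each member maps to the
    anchor.  With tolerance 0 this is the identity.
    """
    mapping: dict[int, int] = {}
    anchor: int | None = None
    for s in np.sort(sizes):
        s = int(s)
        if anchor is None or s - anchor > tolerance:
            anchor = s
        mapping[s] = anchor
    return mapping


def bin_peaks(
    tables: Iterable[PeakTable],
    height_threshold: float = DEFAULT_HEIGHT_THRESHOLD,
    size_tolerance: int = 0,
) -> pd.DataFrame:
    """Collapse triplicate peak tables into per-lineage replicate counts.

    Peaks below ``height_threshold`` are discarded; surviving sizes are
    binned across the whole cohort (exact integer match by default, or
    within ``size_tolerance`` bp) and counted by the number of distinct
    replicates in which they appear.

    Returns
    -------
    pandas.DataFrame
        Tidy table with columns ``lineage_id``, ``fragment_bp`` (bin
        anchor), ``replicate_count`` (1-3).

    Raises
    ------
    ValueError
        If any lineage does not have exactly the three replicates 1, 2, 3.
    """
    tables = list(tables)
    reps: dict[str, set[int]] = {}
    for t in tables:
        reps.setdefault(t.lineage_id, set()).add(t.replicate)
    for lid, rset in reps.items():
        if rset != {1, 2, 3}:
            raise ValueError(
                f"lineage {lid!r} has replicates {sorted(rset)}; "
                "exactly replicates 1, 2, 3 are required"
            )
    rows = [
        (t.lineage_id, t.replicate, int(bp), float(h))
        for t in tables
        for bp, h in t.peaks
        if h >= height_threshold
    ]
    if not rows:
        return pd.DataFrame(columns=["lineage_id", "fragment_bp", "replicate_count"])
    df = pd.DataFrame(rows, columns=["lineage_id", "replicate", "fragment_bp", "height"])
    if size_tolerance > 0:
        mapping = _cluster_sizes(df["fragment_bp"].unique(), int(size_tolerance))
        df["fragment_bp"] = df["fragment_bp"].map(mapping)
    counts = (
        df.groupby(["lineage_id", "fragment_bp"], sort=True)["replicate"]
        .nunique()
        .rename("replicate_count")
        .reset_index()
    )
    return counts


def identify_ancestral_loci(
    counts: pd.DataFrame, min_share: float = 0.5, n_lineages: int | None = None
) -> set[int]:
    """Fragment sizes presumed occupied in the common ancestor.

    A size is ancestral when it is fully replicable (3/3 reactions) in at
    least ``min_share`` of the cohort's lineages — loci shared across many
    lines cannot be independent new insertions.  The default share of 0.5
    tolerates the ~25% segregational loss expected at heterozygous loci in
    selfed lines.
    """
    if n_lineages is None:
        n_lineages = counts["lineage_id"].nunique() if len(counts) else 0
    if n_lineages < 2:
        raise ValueError("ancestral-locus identification requires >= 2 lineages")
    full = counts[counts["replicate_count"] == 3]
    share = full.groupby("fragment_bp")["lineage_id"].nunique() / n_lineages
    return set(int(bp) for bp in share[share >= min_share].index)


def classify_new_peaks(
    counts: pd.DataFrame, ancestral: set[int]
) -> list[PeakCall]:
    """Assign every retained peak to exactly one scoring category.

    Sizes in the ancestral set are ``ancestral``; novel sizes replicable in
    all three reactions are ``germline_gain``; novel sizes seen in only one
    or two reactions are ``somatic``.
    """
    calls: list[PeakCall] = []
    for row in counts.itertuples(index=False):
        bp = int(row.fragment_bp)
        rc = int(row.replicate_count)
        if bp in ancestral:
            category = "ancestral"
        elif rc == 3:
            category = "germline_gain"
        else:
            category = "somatic"
        calls.append(PeakCall(str(row.lineage_id), bp, category, rc))
    return calls


def build_matrix(
    counts: pd.DataFrame,
    ancestral: set[int],
    treatments: Mapping[str, str] | pd.Series,
) -> PresenceMatrix:
    """Assemble the lineage x ancestral-locus presence/absence matrix.

    An entry is absent iff the ancestral size shows zero peaks in all three
    of that lineage's reactions — losses are scored purely from band
    absence.  Novel-peak calls (germline gains, somatic insertions) ride
    along in ``new_calls``.
    """
    treatments = pd.Series(dict(treatments) if not isinstance(treatments, pd.Series)
                           else treatments)
    lineages = sorted(treatments.index)
    observed = set(counts["lineage_id"].unique()) if len(counts) else set()
    missing = observed - set(lineages)
    if missing:
        raise ValueError(
            f"lineages missing from treatment map: {sorted(missing)}"
        )
    cols = sorted(ancestral)
    presence = pd.DataFrame(False, index=pd.Index(lineages, name="lineage_id"),
                            columns=pd.Index(cols, name="fragment_bp"), dtype=bool)
    anc = counts[counts["fragment_bp"].isin(ancestral)] if len(counts) else counts
    for row in anc.itertuples(index=False):
        presence.at[str(row.lineage_id), int(row.fragment_bp)] = True
    calls = classify_new_peaks(counts, ancestral) if len(counts) else []
    new_calls = [c for c in calls if c.category != "ancestral"]
    return PresenceMatrix(presence=presence, treatments=treatments.loc[lineages],
                          new_calls=new_calls)


def identify_high_loss_loci(
    matrix: PresenceMatrix, min_lineages: int = 3
) -> set[int]:
    """Loci lost in strictly more than ``min_lineages`` lineages.

    Repeated losses at the same ancestral locus across independent lines
    are the signature of ancestral heterozygosity segregating after sex;
    the default calls a locus high-loss when absent in more than three
    lineages.
    """
    absences = matrix.absences_per_locus()
    return set(int(bp) for bp in absences[absences > min_lineages].index)
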