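"""Forward simulation of a transposon mutation-accumulation experiment.

Emulates the design of a *Daphnia pulex*-style MA assay: a single diploid
ancestor carrying a family of transposon insertion loci (a mix of
heterozygous and homozygous sites) founds a cohort of lineages propagated
through single-individual bottlenecks for ~40 generations.  "Asexual" lines
reproduce clonally throughout; "sexual" lines experience one or more bouts
of selfing (induced sex where a female mates with her sons, i.e. selfing of
the clonal genotype).  Per generation, each element copy may excise (with
homologue-templated reconstitution possible at homozygous loci) or spawn a
new heterozygous insertion elsewhere.  At assay time, triplicate
transposon-display (TD) reactions are emulated: every occupied locus yields
a peak at its diagnostic fragment size in all three replicates (TD cannot
distinguish one from two copies), and somatic insertions yield robust peaks
that fail to replicate across all three reactions.

A single seed fully determines a cohort: each lineage draws from its own
substream derived from ``(seed, lineage index)``, so event logs and peak
tables are bit-identical across reruns.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields
from typing import Iterable, NamedTuple

import numpy as np

from .segregation import Genotype, selfing_offspring_distribution

__all__ = [
    "SimulationConfig",
    "LocusState",
    "Event",
    "LineageRecord",
    "PeakTable",
    "init_ancestor",
    "propagate_clonal_generation",
    "apply_selfing",
    "run_experiment",
    "emulate_td",
]

# TD peak-height emulation (arbitrary fluorescence units).  Germline peaks
# (ancestral loci and new heritable insertions) are drawn well above somatic
# peaks, and both floors sit above the default scoring threshold so that no
# true peak is discarded by default.
GERMLINE_HEIGHT_MEAN = 1200.0
GERMLINE_HEIGHT_SD = 150.0
GERMLINE_HEIGHT_MIN = 600.0
SOMATIC_HEIGHT_MEAN = 350.0
SOMATIC_HEIGHT_SD = 80.0
SOMATIC_HEIGHT_MIN = 150.0

EVENT_TYPES = (
    "segregational_loss",
    "excision_loss",
    "reconstitution",
    "germline_gain",
    "somatic_peak",
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated MA cohort (one transposon family).

    Defaults mirror the experimental design being emulated: 47 exclusively
    clonal lines plus 47 lines with one selfing bout, ~40 generations each,
    and per-copy event rates at the small magnitudes typical of DNA
    transposons (loss ~1e-4 per element per generation, transposition of
    the same order, frequent non-heritable somatic activity at assay time).
    """

    n_asexual: int = 47
    n_sexual: int = 47
    generations_mean: int = 40
    generations_sd: float = 0.0
    n_ancestral_loci: int = 25
    fraction_heterozygous: float = 0.2
    excision_rate: float = 1e-4
    reconstitution_prob: float = 1.0
    germline_transposition_rate: float = 1e-4
    somatic_rate: float = 0.05
    somatic_replicate_detection: float = 0.4
    selfing_generation: int | None = None
    n_selfings: int = 1
    fragment_size_range: tuple[int, int] = (60, 1200)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_asexual", "n_sexual", "generations_mean",
                     "n_ancestral_loci", "n_selfings"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.generations_mean < 1:
            raise ValueError("generations_mean must be >= 1")
        if self.generations_sd < 0:
            raise ValueError("generations_sd must be >= 0")
        for name in ("fraction_heterozygous", "excision_rate",
                     "reconstitution_prob", "germline_transposition_rate",
                     "somatic_replicate_detection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        if self.somatic_rate < 0:
            raise ValueError("somatic_rate must be >= 0")
        lo, hi = self.fragment_size_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("fragment_size_range bounds must be integers (bp)")
        if hi <= lo:
            raise ValueError("fragment_size_range must satisfy lo < hi")
        if self.selfing_generation is not None and not (
            1 <= self.selfing_generation <= self.generations_mean
        ):
            raise ValueError(
                "selfing_generation must lie within [1, generations_mean]"
            )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["fragment_size_range"] = list(self.fragment_size_range)
        return d


@dataclass
class LocusState:
    """One insertion locus in one lineage: diagnostic TD fragment + dosage."""

    locus_id: str
    fragment_bp: int
    copies: int
    origin: str = "ancestral"  # "ancestral" | "germline_gain"


class Event(NamedTuple):
    generation: int
    locus_id: str
    event: str


@dataclass
class LineageRecord:
    """One MA line: treatment, propagation history, loci, and event log."""

    lineage_id: str
    treatment: str  # "sexual" | "asexual"
    generations: int
    selfing_generations: list[int]
    loci: list[LocusState]
    event_log: list[Event] = field(default_factory=list)

    def copy_number(self) -> int:
        return sum(loc.copies for loc in self.loci)

    def presence_vector(self, only_ancestral: bool = True) -> dict[int, bool]:
        return {
            loc.fragment_bp: loc.copies >= 1
            for loc in self.loci
            if loc.origin == "ancestral" or not only_ancestral
        }


@dataclass
class PeakTable:
    """One TD replicate for one lineage: (fragment size, peak height) pairs."""

    lineage_id: str
    replicate: int
    peaks: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2, 3):
            raise ValueError(f"replicate must be 1, 2, or 3, got {self.replicate}")
        if any(h <= 0 for _, h in self.peaks):
            raise ValueError("peak heights must be positive")


def _lineage_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # Deterministic substream per (seed, stage, lineage).
    return np.random.default_rng([int(seed), int(stream), int(index)])


def init_ancestor(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[LocusState]:
    """Construct the ancestral locus set shared by every lineage.

    Draws ``n_ancestral_loci`` unique integer fragment sizes from the
    configured range and makes ``round(fraction_heterozygous * n)`` of them
    heterozygous (one copy), the remainder homozygous (two copies).
    Deterministic given the config seed.
    """
    if config.n_ancestral_loci < 1:
        raise ValueError("n_ancestral_loci must be >= 1")
    lo, hi = config.fragment_size_range
    available = hi - lo + 1
    if config.n_ancestral_loci > available:
        raise ValueError(
            f"n_ancestral_loci={config.n_ancestral_loci} exceeds the "
            f"{available} distinct fragment sizes in {config.fragment_size_range}"
        )
    if rng is None:
        rng = _lineage_rng(config.seed, 0, 0)
    sizes = np.sort(rng.choice(np.arange(lo, hi + 1), size=config.n_ancestral_loci,
                               replace=False))
    n_het = int(round(config.fraction_heterozygous * config.n_ancestral_loci))
    het_idx = set(rng.choice(config.n_ancestral_loci, size=n_het, replace=False).tolist())
    return [
        LocusState(
            locus_id=f"L{int(s):04d}",
            fragment_bp=int(s),
            copies=int(Genotype.HET if i in het_idx else Genotype.HOM),
            origin="ancestral",
        )
        for i, s in enumerate(sizes)
    ]


def _draw_new_size(
    rng: np.random.Generator, used: set[int], size_range: tuple[int, int]
) -> int:
    lo, hi = size_range
    if len(used) >= hi - lo + 1:
        raise RuntimeError("fragment size range exhausted; widen fragment_size_range")
    while True:
        s = int(rng.integers(lo, hi + 1))
        if s not in used:
            return s


def propagate_clonal_generation(
    line: LineageRecord, config: SimulationConfig, rng: np.random.Generator
) -> LineageRecord:
    """Advance one clonal (ameiotic) generation in place.

    Each element copy independently excises with ``excision_rate``.  An
    excised copy at a homozygous locus is restored from the intact
    homologue with ``reconstitution_prob`` (logged ``reconstitution``);
    otherwise one copy is lost (logged ``excision_loss``; a heterozygous
    locus drops to zero copies).  Independently, each copy spawns a new
    heterozygous insertion at a fresh unique fragment size with
    ``germline_transposition_rate`` (logged ``germline_gain``).
    """
    line.generations += 1
    gen = line.generations
    e = config.excision_rate
    u = config.germline_transposition_rate
    if e == 0.0 and u == 0.0:
        return line

    copies = np.fromiter((loc.copies for loc in line.loci), dtype=np.int64,
                         count=len(line.loci))
    total_copies = int(copies.sum())

    if e > 0.0 and total_copies:
        n_exc = rng.binomial(copies, e)
        for idx in np.nonzero(n_exc)[0]:
            loc = line.loci[int(idx)]
            for _ in range(int(n_exc[idx])):
                if loc.copies == 2:
                    if rng.random() < config.reconstitution_prob:
                        line.event_log.append(Event(gen, loc.locus_id, "reconstitution"))
                    else:
                        loc.copies = 1
                        line.event_log.append(Event(gen, loc.locus_id, "excision_loss"))
                elif loc.copies == 1:
                    loc.copies = 0
                    line.event_log.append(Event(gen, loc.locus_id, "excision_loss"))
                # copies already 0: the drawn excision targeted a copy lost
                # earlier in this generation; nothing left to excise.

    if u > 0.0 and total_copies:
        n_new = rng.binomial(total_copies, u)
        if n_new:
            used = {loc.fragment_bp for loc in line.loci}
            for _ in range(int(n_new)):
                s = _draw_new_size(rng, used, config.fragment_size_range)
                used.add(s)
                new = LocusState(
                    locus_id=f"G{int(s):04d}",
                    fragment_bp=s,
                    copies=int(Genotype.HET),
                    origin="germline_gain",
                )
                line.loci.append(new)
                line.event_log.append(Event(gen, new.locus_id, "germline_gain"))

    return line


def apply_selfing(line: LineageRecord, rng: np.random.Generator) -> LineageRecord:
    """Apply one bout of selfing (meiosis + self-fertilization) in place.

    Every locus segregates independently: heterozygous loci become
    absent/het/hom with probabilities 1/4, 1/2, 1/4; absent and homozygous
    loci are fixed points.  Losses are logged as ``segregational_loss``.
    """
    if line.treatment != "sexual":
        raise ValueError(
            f"cannot self asexual lineage {line.lineage_id!r}: "
            "selfing applies only to sexual-treatment lines"
        )
    line.generations += 1
    gen = line.generations
    dist = selfing_offspring_distribution(Genotype.HET)
    for loc in line.loci:
        if loc.copies != 1:
            continue  # 0 and 2 copies are absorbing under selfing
        r = rng.random()
        if r < dist.p_absent:
            loc.copies = 0
            line.event_log.append(Event(gen, loc.locus_id, "segregational_loss"))
        elif r < dist.p_absent + dist.p_het:
            pass
        else:
            loc.copies = 2
    return line


def _selfing_schedule(config: SimulationConfig, generations: int) -> list[int]:
    k = config.n_selfings
    if k == 0:
        return []
    if k == 1:
        g = config.selfing_generation
        if g is None:
            g = max(1, generations // 2)
        return [min(g, generations)]
    # Multiple bouts: spread evenly across the line's lifetime.
    return sorted({max(1, round(j * generations / (k + 1))) for j in range(1, k + 1)})


def run_experiment(config: SimulationConfig) -> list[LineageRecord]:
    """Simulate a full MA cohort from a common ancestor.

    Returns ``n_sexual + n_asexual`` lineages, all descended from the same
    ancestral locus set.  Asexual lines receive only clonal generations;
    sexual lines additionally self at their scheduled generations (default:
    one bout mid-experiment).  Fully reproducible from ``config.seed``.
    """
    ancestor = init_ancestor(config)
    lines: list[LineageRecord] = []
    n_total = config.n_sexual + config.n_asexual
    for i in range(n_total):
        sexual = i < config.n_sexual
        treatment = "sexual" if sexual else "asexual"
        lineage_id = f"{'S' if sexual else 'A'}{(i if sexual else i - config.n_sexual) + 1:03d}"
        rng = _lineage_rng(config.seed, 1, i)
        if config.generations_sd > 0:
            generations = max(
                1, int(round(rng.normal(config.generations_mean, config.generations_sd)))
            )
        else:
            generations = config.generations_mean
        schedule = _selfing_schedule(config, generations) if sexual else []
        line = LineageRecord(
            lineage_id=lineage_id,
            treatment=treatment,
            generations=0,
            selfing_generations=schedule,
            loci=copy.deepcopy(ancestor),
            event_log=[],
        )
        bouts = set(schedule)
        for g in range(1, generations + 1):
            if g in bouts:
                apply_selfing(line, rng)
            else:
                propagate_clonal_generation(line, config, rng)
        lines.append(line)
    return lines


def _somatic_pattern(rng: np.random.Generator, p: float) -> list[int]:
    """Replicate indices (1-based) in which one somatic peak is detected.

    Conditional on detection in at least one and at most two of the three
    replicates (a peak in all three would be indistinguishable from a
    germline gain, and the emulator models somatic peaks as non-replicable
    by definition).
    """
    w1 = 3.0 * p * (1.0 - p) ** 2
    w2 = 3.0 * p**2 * (1.0 - p)
    if w1 + w2 <= 0.0:
        # Degenerate detection probability (0 or 1): fall back to the
        # nearest attainable pattern.
        k = 1 if p < 0.5 else 2
    else:
        k = 1 if rng.random() < w1 / (w1 + w2) else 2
    return sorted(int(r) + 1 for r in rng.choice(3, size=k, replace=False))


def emulate_td(
    lines: Iterable[LineageRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[PeakTable]:
    """Emulate triplicate transposon-display reactions at assay time.

    Every locus with >=1 copy produces a peak at its fragment size in all
    three replicates — TD sees presence only, so heterozygous and
    homozygous loci are indistinguishable.  Somatic insertions (Poisson
    count with mean ``somatic_rate`` x occupied loci per lineage) produce
    peaks at fresh fragment sizes in one or two replicates, never all
    three, and are logged as ``somatic_peak`` events.  Germline peak
    heights are drawn higher than somatic ones on average.

    When ``rng`` is omitted, per-lineage substreams are derived from
    ``config.seed`` so that repeated pipeline runs are byte-identical.
    Call once per assay: somatic events are appended to the lineage logs.
    """
    tables: list[PeakTable] = []
    for i, line in enumerate(lines):
        line_rng = rng.spawn(1)[0] if rng is not None else _lineage_rng(config.seed, 2, i)
        present = [loc for loc in line.loci if loc.copies >= 1]
        replicate_peaks: dict[int, list[tuple[int, float]]] = {1: [], 2: [], 3: []}
        for loc in present:
            for rep in (1, 2, 3):
                h = max(
                    GERMLINE_HEIGHT_MIN,
                    line_rng.normal(GERMLINE_HEIGHT_MEAN, GERMLINE_HEIGHT_SD),
                )
                replicate_peaks[rep].append((loc.fragment_bp, float(h)))
        n_somatic = int(line_rng.poisson(config.somatic_rate * len(present)))
        if n_somatic:
            used = {loc.fragment_bp for loc in line.loci}
            for _ in range(n_somatic):
                s = _draw_new_size(line_rng, used, config.fragment_size_range)
                used.add(s)
                for rep in _somatic_pattern(line_rng, config.somatic_replicate_detection):
                    h = max(
                        SOMATIC_HEIGHT_MIN,
                        line_rng.normal(SOMATIC_HEIGHT_MEAN, SOMATIC_HEIGHT_SD),
                    )
                    replicate_peaks[rep].append((s, float(h)))
                line.event_log.append(
                    Event(line.generations, f"soma_{s:04d}", "somatic_peak")
                )
        for rep in (1, 2, 3):
            tables.append(
                PeakTable(
                    lineage_id=line.lineage_id,
                    replicate=rep,
                    peaks=sorted(replicate_peaks[rep]),
                )
            )
    return tables
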