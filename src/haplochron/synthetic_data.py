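"""Synthetic data with known truth for the temporal haplotype pipeline.

The generator emulates the statistical structure of a century-scale
mtDNA time series from a small, bottlenecked lake population: haploid
Wright-Fisher drift of haplotype frequencies along a piecewise-linear
census trajectory (default: ~1000 animals in the 1890s crashing to ~140
by the mid-1980s, recovering to ~425 by 2011), period-wise multinomial
sampling into haplotype-by-period count tables, star-genealogy sequence
simulation (each haplotype a Poisson number of substitutions from a
common root, optionally one lineage carrying a long contiguous deletion),
and IUPAC ambiguity injection mimicking post-mortem DNA damage in museum
specimens.

Because mtDNA is maternally inherited, drift is governed by the number
of breeding females; the census is converted to a female effective size
through a single configurable fraction (default 0.25).  The trajectory
and fraction are illustrative defaults, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from haplochron.seqio import (
    Alignment,
    CODE_FOR_SET,
    HaplotypeTable,
    InputError,
    SequenceRecord,
    TemporalGrouping,
    assign_period,
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise-linear census history with an mtDNA effective-size knob.

    ``anchors`` are (calendar year, census size) points; the census is
    linearly interpolated between them.  The female effective size at a
    year is round(census * female_effective_fraction).  Generations step
    by ``generation_years`` (default 11, a typical phocid generation
    time).
    """

    anchors: tuple[tuple[int, float], ...]
    female_effective_fraction: float = 0.25
    generation_years: float = 11.0

    def __post_init__(self) -> None:
        years = [y for y, _ in self.anchors]
        if len(years) < 2 or any(b <= a for a, b in zip(years, years[1:])):
            raise InputError("anchors need >= 2 strictly increasing years")
        if any(n < 2 for _, n in self.anchors):
            raise InputError("census sizes must be >= 2")
        if not 0 < self.female_effective_fraction <= 1:
            raise InputError("female_effective_fraction outside (0, 1]")

    def census(self, year: float) -> float:
        years = np.array([y for y, _ in self.anchors], dtype=float)
        sizes = np.array([n for _, n in self.anchors], dtype=float)
        return float(np.interp(year, years, sizes))

    def n_female(self, year: float) -> int:
        return int(round(self.census(year) * self.female_effective_fraction))

    @property
    def start_year(self) -> int:
        return self.anchors[0][0]

    @property
    def end_year(self) -> int:
        return self.anchors[-1][0]


def default_trajectory() -> TrajectorySpec:
    """Illustrative census history of a 20th-century crash-and-recovery.

    Anchored at (1890, 1000), (1985, 140), (2011, 425): roughly a
    thousand animals at the end of the 19th century, a hunting/pollution
    low of well under 150 in the mid-1980s, and slightly over 400 today.
    """
    return TrajectorySpec(anchors=((1890, 1000.0), (1985, 140.0), (2011, 425.0)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic run."""

    init_freqs: Mapping[str, float]
    trajectory: TrajectorySpec = field(default_factory=default_trajectory)
    sampling: Mapping[str, int] = field(default_factory=dict)
    mutation_rate: float = 2.0  # Poisson mean substitutions per haplotype (sequence mode)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.init_freqs.values())
        if abs(total - 1.0) > 1e-8:
            raise InputError(f"initial frequencies sum to {total}, expected 1")
        if any(v < 0 for v in self.init_freqs.values()):
            raise InputError("negative initial frequency")
        if any(n < 0 for n in self.sampling.values()):
            raise InputError("negative sample size")


@dataclass
class SimResult:
    """Output of a synthetic run.

    ``freq_path`` rows are generations (indexed by calendar year),
    columns are haplotypes; every row sums to 1.  ``sampled_table`` and
    ``alignment``/``truth`` are filled by the sampling and sequence
    stages respectively.
    """

    freq_path: pd.DataFrame
    config: SimConfig
    sampled_table: HaplotypeTable | None = None
    truth: dict[str, str] | None = None
    alignment: Alignment | None = None

    def truth_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth or {}, indent=1) + "\n")


def wf_simulate(config: SimConfig) -> SimResult:
    """Haploid Wright-Fisher drift along the census trajectory.

    Starting from ``init_freqs`` at the first anchor year, each
    generation draws haplotype counts from Multinomial(N_f(t), previous
    frequencies) with N_f(t) the female effective size at that year, then
    renormalises to frequencies.  Deterministic given (config, seed).
    """
    traj = config.trajectory
    labels = list(config.init_freqs)
    freqs = np.array([config.init_freqs[h] for h in labels], dtype=float)
    rng = np.random.default_rng(config.seed)

    years = []
    year = float(traj.start_year)
    while year <= traj.end_year:
        years.append(year)
        year += traj.generation_years

    path = np.empty((len(years), len(labels)))
    path[0] = freqs
    for t, yr in enumerate(years[1:], start=1):
        n_f = traj.n_female(yr)
        if n_f < 1:
            raise SimulationError(f"female effective size < 1 in year {yr:.0f}")
        counts = rng.multinomial(n_f, path[t - 1])
        path[t] = counts / n_f
    freq_path = pd.DataFrame(path, index=pd.Index(years, name="year"), columns=labels)
    return SimResult(freq_path=freq_path, config=config)


def sample_table(
    result: SimResult,
    grouping: TemporalGrouping,
    sampling: Mapping[str, int],
    seed: int = 0,
) -> HaplotypeTable:
    """Draw period samples from the simulated frequency path.

    For each period, the haplotype frequencies at the generation nearest
    the period midpoint define a multinomial from which the configured
    number of individuals is drawn.
    """
    rng = np.random.default_rng(seed)
    years = result.freq_path.index.to_numpy()
    labels = list(result.freq_path.columns)
    cols = {}
    for label, start, end in grouping.periods:
        if label not in sampling:
            continue
        mid = (start + end) / 2.0
        if mid < years.min() - result.config.trajectory.generation_years or \
           mid > years.max() + result.config.trajectory.generation_years:
            raise InputError(f"period {label!r} outside the simulated range")
        gen = int(np.argmin(np.abs(years - mid)))
        freqs = result.freq_path.iloc[gen].to_numpy()
        cols[label] = rng.multinomial(sampling[label], freqs)
    if not cols:
        raise InputError("no sampled periods")
    counts = pd.DataFrame(cols, index=labels)
    return HaplotypeTable(counts)


def _star_haplotypes(
    labels: list[str],
    root_length: int,
    mutation_rate: float,
    deletion: tuple[int, int] | None,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Distinct sequences, each a Poisson number of substitutions off a root.

    The first label is the root haplotype itself; the last label carries
    the deletion when one is requested.  Collisions are resolved by
    re-drawing, so the catalog is guaranteed distinct (gap treated as a
    fifth state).
    """
    bases = np.array(list("ACGT"))
    root = "".join(rng.choice(bases, size=root_length))
    seqs: dict[str, str] = {labels[0]: root}
    seen = {root}
    for lab in labels[1:]:
        for _ in range(1000):
            k = max(1, rng.poisson(mutation_rate))
            sites = rng.choice(root_length, size=min(k, root_length), replace=False)
            s = list(root)
            for site in sites:
                s[site] = rng.choice([b for b in "ACGT" if b != s[site]])
            cand = "".join(s)
            if cand not in seen:
                seqs[lab] = cand
                seen.add(cand)
                break
        else:
            raise SimulationError("could not generate distinct haplotypes")
    if deletion is not None:
        start, length = deletion
        if start < 0 or start + length > root_length:
            raise InputError("deletion span outside the sequence")
        lab = labels[-1]
        s = list(seqs[lab])
        s[start:start + length] = "-" * length
        seqs[lab] = "".join(s)
    return seqs


def evolve_sequences(
    config: SimConfig,
    grouping: TemporalGrouping,
    root_length: int = 663,
    deletion: tuple[int, int] | None = None,
) -> SimResult:
    """Full sequence-level simulation: drift, sampling, and an alignment.

    Haplotype sequences come from a star genealogy (independent Poisson
    substitution loads on a common root; no coalescent structure), one
    haplotype optionally carrying a contiguous deletion rendered as '-'
    columns.  Each sampled individual gets a record with a year drawn
    uniformly within its period, and the truth map records its haplotype,
    so collapsing the emitted alignment must recover the truth exactly on
    ambiguity-free data.
    """
    if deletion is not None and deletion[1] > root_length:
        raise InputError("deletion longer than the sequence")
    result = wf_simulate(config)
    table = sample_table(result, grouping, config.sampling, seed=config.seed + 1)
    rng = np.random.default_rng(config.seed + 2)
    labels = list(result.freq_path.columns)
    seqs = _star_haplotypes(labels, root_length, config.mutation_rate, deletion, rng)

    records = []
    truth: dict[str, str] = {}
    i = 0
    for label, start, end in grouping.periods:
        if label not in table.period_labels:
            continue
        for hap in labels:
            for _ in range(int(table.counts.loc[hap, label])):
                sid = f"s{i:04d}"
                year = int(rng.integers(start, end + 1))
                records.append(SequenceRecord.make(sid, seqs[hap], year))
                truth[sid] = hap
                i += 1
    if not records:
        raise InputError("sampling produced no individuals")
    result.sampled_table = table
    result.truth = truth
    result.alignment = Alignment(tuple(records))
    return result


def inject_ambiguities(aln: Alignment, rate: float, seed: int = 0) -> Alignment:
    """Randomly degrade base calls into two-state IUPAC ambiguity codes.

    Each (record, column) independently with probability ``rate`` has its
    base replaced by the code pairing it with a random other base, and
    the column marked unreplicated for that record -- mimicking damaged,
    single-read museum sequence.
    """
    if not 0 <= rate < 1:
        raise InputError("rate must be in [0, 1)")
    if rate == 0:
        return aln
    rng = np.random.default_rng(seed)
    out = []
    for rec in aln:
        seq = list(rec.seq)
        mask = list(rec.replicated)
        hits = rng.random(len(seq)) < rate
        for col in np.nonzero(hits)[0]:
            base = seq[col]
            if base not in "ACGT":
                continue
            other = rng.choice([b for b in "ACGT" if b != base])
            seq[col] = CODE_FOR_SET[frozenset({base, other})]
            mask[col] = False
        out.append(replace(rec, seq="".join(seq), replicated=tuple(mask)))
    return Alignment(tuple(out))


def write_fasta_metadata(
    aln: Alignment, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write an alignment back to FASTA + metadata TSV consumable by seqio."""
    with open(fasta_path, "w") as fh:
        for rec in aln:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    rows = []
    for rec in aln:
        unrep = []
        start = None
        for col, ok in enumerate(rec.replicated):
            if not ok and start is None:
                start = col
            elif ok and start is not None:
                unrep.append((start, col - 1))
                start = None
        if start is not None:
            unrep.append((start, len(rec.replicated) - 1))
        spec = ",".join(
            f"{a + 1}-{b + 1}" if a != b else f"{a + 1}" for a, b in unrep
        )
        rows.append({
            "id": rec.id, "year": rec.year, "site": rec.site,
            "region": rec.region, "replicated_ranges": spec,
        })
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)
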