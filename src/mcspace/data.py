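"""Input containers, CSV readers, and sequential quality filters.

Particle co-localization sequencing (SAMPL-seq / MaPS-seq style) produces a
table of read counts per barcoded particle for each OTU, together with a
taxonomy table and a study design giving the sampling time of each sample and
which time points fall inside experimental perturbations.  This module houses
the validated in-memory forms of those three inputs and the pre-processing
filters applied before model fitting:

1. remove particles with implausibly large amplification (total reads above a
   cap, by default 10,000 — removal is strictly ``> max_reads``),
2. remove low-coverage particles (total reads below ``min_reads``, default 250;
   the boundary is kept, i.e. particles with exactly ``min_reads`` survive),
3. remove OTUs that never exceed a relative-abundance threshold (default
   0.005) when reads are pooled per (subject, time) sample, in at least
   ``min_subjects`` subjects at some time point.

Filters are sequential: OTU abundances are aggregated over the particles that
survive steps 1–2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleCountMatrix",
    "StudyDesign",
    "TaxonomyTable",
    "read_inputs",
    "read_counts_csv",
    "read_taxonomy_csv",
    "read_design_csv",
    "filter_particles",
    "filter_otus",
    "threshold_sweep",
    "FilterReport",
]


class InputValidationError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


@dataclass
class ParticleCountMatrix:
    """Integer read counts per particle (rows) and OTU (columns).

    Each particle belongs to exactly one (subject, time-point) sample.
    ``times`` holds the numeric time-point index of each particle and must
    match entries of the study design.
    """

    counts: np.ndarray
    particle_ids: np.ndarray
    otu_ids: np.ndarray
    subjects: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.particle_ids = np.asarray(self.particle_ids, dtype=object)
        self.otu_ids = np.asarray(self.otu_ids, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        if self.counts.ndim != 2:
            raise InputValidationError("counts must be a 2-D particles x OTUs matrix")
        L, O = self.counts.shape
        if not (len(self.particle_ids) == len(self.subjects) == len(self.times) == L):
            raise InputValidationError("per-particle metadata length mismatch")
        if len(self.otu_ids) != O:
            raise InputValidationError("otu_ids length does not match counts columns")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(self.counts != as_int)[0]
                raise InputValidationError(
                    f"non-integer count at particle {self.particle_ids[bad[0]]}, "
                    f"OTU {self.otu_ids[bad[1]]}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise InputValidationError(
                f"negative count at particle {self.particle_ids[bad[0]]}, "
                f"OTU {self.otu_ids[bad[1]]}"
            )
        if len(set(self.particle_ids)) != L:
            raise InputValidationError("duplicate particle ids")

    @property
    def n_particles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def total_reads(self) -> np.ndarray:
        """Total reads per particle."""
        return self.counts.sum(axis=1)

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique time-point indices present in the data."""
        return np.unique(self.times)

    @property
    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects.astype(str))

    def select(self, particles=None, otus=None) -> "ParticleCountMatrix":
        """Row/column subset preserving order; boolean or integer indexers."""
        pr = slice(None) if particles is None else np.asarray(particles)
        ot = slice(None) if otus is None else np.asarray(otus)
        return ParticleCountMatrix(
            counts=self.counts[pr][:, ot],
            particle_ids=self.particle_ids[pr],
            otu_ids=self.otu_ids[ot],
            subjects=self.subjects[pr],
            times=self.times[pr],
        )

    def relative_abundances(self) -> np.ndarray:
        tot = self.total_reads.astype(float)
        if (tot == 0).any():
            raise InputValidationError("zero-read particle present; filter first")
        return self.counts / tot[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.otu_ids))
        df.insert(0, "time", self.times)
        df.insert(0, "subject", self.subjects)
        df.insert(0, "particle_id", self.particle_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class StudyDesign:
    """Sampling time grid and the perturbation on/off schedule.

    ``perturbations`` maps a perturbation name to the set of time points at
    which it is active; each on-set must be a contiguous block of the time
    grid.  A perturbation "turns on" at the first time point of its block and
    "turns off" at the first time point after the block.
    """

    timepoints: np.ndarray
    perturbations: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.timepoints.ndim != 1 or len(self.timepoints) == 0:
            raise InputValidationError("timepoints must be a non-empty 1-D sequence")
        if not (np.diff(self.timepoints) > 0).all():
            raise InputValidationError("timepoints must be strictly increasing")
        tp = list(self.timepoints)
        perts = {}
        for name, onset in self.perturbations.items():
            onset = frozenset(float(t) for t in onset)
            if not onset:
                raise InputValidationError(f"perturbation {name!r} has empty on-set")
            if not onset.issubset(tp):
                raise InputValidationError(
                    f"perturbation {name!r} references unknown time points"
                )
            idx = sorted(tp.index(t) for t in onset)
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise InputValidationError(
                    f"perturbation {name!r} on-set is not a contiguous block"
                )
            perts[name] = onset
        self.perturbations = perts

    @property
    def delta_t(self) -> np.ndarray:
        """Gaps between consecutive time points (length T-1)."""
        return np.diff(self.timepoints)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def perturbation_names(self) -> list[str]:
        return list(self.perturbations)

    def transition(self, name: str, i: int) -> str:
        """Transition of perturbation ``name`` at time index ``i`` (i >= 1).

        Returns "on" if it starts at timepoints[i], "off" if it was active at
        timepoints[i-1] and no longer is, "none" otherwise.
        """
        if i <= 0 or i >= len(self.timepoints):
            raise IndexError("transition defined for interior indices 1..T-1")
        onset = self.perturbations[name]
        now = float(self.timepoints[i]) in onset
        before = float(self.timepoints[i - 1]) in onset
        if now and not before:
            return "on"
        if before and not now:
            return "off"
        return "none"

    def transition_signs(self) -> np.ndarray:
        """(T, P) matrix: +1 where a perturbation turns on, -1 where it turns off."""
        T, P = self.n_timepoints, len(self.perturbations)
        signs = np.zeros((T, P))
        for j, name in enumerate(self.perturbations):
            for i in range(1, T):
                tr = self.transition(name, i)
                if tr == "on":
                    signs[i, j] = 1.0
                elif tr == "off":
                    signs[i, j] = -1.0
        return signs


@dataclass
class TaxonomyTable:
    """OTU id -> free-form taxonomic lineage label."""

    labels: dict[str, str]

    def label(self, otu_id: str) -> str:
        return self.labels.get(str(otu_id), str(otu_id))

    def covers(self, otu_ids) -> bool:
        return all(str(o) in self.labels for o in otu_ids)


def read_counts_csv(path) -> ParticleCountMatrix:
    """Read a particle count table; wide or long format.

    Wide: columns ``particle_id, subject, time, <otu1>, <otu2>, ...``.
    Long: columns ``particle_id, subject, time, otu, count`` (normalized to
    wide with missing combinations set to zero).
    """
    df = pd.read_csv(path)
    required = {"particle_id", "subject", "time"}
    missing = required - set(df.columns)
    if missing:
        raise InputValidationError(f"{path}: missing columns {sorted(missing)}")
    if {"otu", "count"}.issubset(df.columns):
        wide = (
            df.pivot_table(
                index=["particle_id", "subject", "time"],
                columns="otu",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reset_index()
        )
        wide.columns.name = None
        df = wide
    otu_cols = [c for c in df.columns if c not in required]
    if not otu_cols:
        raise InputValidationError(f"{path}: no OTU columns found")
    counts = df[otu_cols].to_numpy()
    try:
        return ParticleCountMatrix(
            counts=counts,
            particle_ids=df["particle_id"].astype(str).to_numpy(),
            otu_ids=np.array([str(c) for c in otu_cols], dtype=object),
            subjects=df["subject"].astype(str).to_numpy(),
            times=df["time"].to_numpy(),
        )
    except InputValidationError as e:
        raise InputValidationError(f"{path}: {e}") from e


def read_taxonomy_csv(path) -> TaxonomyTable:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    otu_col = cols.get("otu") or cols.get("otu_id")
    tax_col = cols.get("taxonomy") or cols.get("label") or cols.get("lineage")
    if otu_col is None or tax_col is None:
        raise InputValidationError(
            f"{path}: expected columns (otu|otu_id) and (taxonomy|label|lineage)"
        )
    return TaxonomyTable(
        labels=dict(zip(df[otu_col].astype(str), df[tax_col].astype(str)))
    )


def read_design_csv(path) -> StudyDesign:
    """Read the study design: one row per time point.

    Columns: ``time`` plus either a single 0/1 ``perturbed`` column or one 0/1
    column per named perturbation.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise InputValidationError(f"{path}: missing 'time' column")
    df = df.sort_values("time")
    times = df["time"].to_numpy(dtype=float)
    pert_cols = [c for c in df.columns if c != "time"]
    perturbations = {}
    for c in pert_cols:
        flags = df[c].to_numpy()
        if not np.isin(flags, [0, 1]).all():
            raise InputValidationError(f"{path}: column {c!r} must be 0/1 flags")
        on = frozenset(times[flags == 1])
        if on:
            perturbations[str(c)] = on
    try:
        return StudyDesign(timepoints=times, perturbations=perturbations)
    except InputValidationError as e:
        raise InputValidationError(f"{path}: {e}") from e


def read_inputs(counts_path, taxonomy_path, design_path):
    """Read and cross-validate the three CSV inputs.

    Returns ``(ParticleCountMatrix, TaxonomyTable, StudyDesign)``.  The
    taxonomy must cover every OTU in the counts, and every particle's time
    index must appear on the design's time grid.
    """
    m = read_counts_csv(counts_path)
    tax = read_taxonomy_csv(taxonomy_path)
    design = read_design_csv(design_path)
    missing_tax = [o for o in m.otu_ids if str(o) not in tax.labels]
    if missing_tax:
        raise InputValidationError(
            f"{taxonomy_path}: no taxonomy for OTUs {missing_tax[:5]}"
        )
    unknown = set(m.times) - set(design.timepoints)
    if unknown:
        raise InputValidationError(
            f"{counts_path}: particles reference time points {sorted(unknown)} "
            f"absent from {design_path}"
        )
    return m, tax, design


@dataclass
class FilterReport:
    """Survivor counts per sequential filtering step, serializable to JSON."""

    thresholds: dict
    steps: list

    def to_json(self, path=None) -> str:
        text = json.dumps({"thresholds": self.thresholds, "steps": self.steps}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def filter_particles(
    m: ParticleCountMatrix, min_reads: int = 250, max_reads: int = 10_000
) -> ParticleCountMatrix:
    """Keep particles with total reads in ``[min_reads, max_reads]``.

    The upper rule removes particles with totals strictly above ``max_reads``
    (large-amplification artifacts); the lower boundary is inclusive.
    """
    tot = m.total_reads
    keep = (tot >= min_reads) & (tot <= max_reads)
    if not keep.any():
        raise InputValidationError(
            f"no particles retained with total reads in [{min_reads}, {max_reads}]"
        )
    return m.select(particles=keep)


def filter_otus(
    m: ParticleCountMatrix,
    min_rel_abund: float = 0.005,
    min_subjects: int = 1,
) -> ParticleCountMatrix:
    """Keep OTUs exceeding ``min_rel_abund`` in >= ``min_subjects`` subjects.

    Relative abundance of an OTU in a (subject, time) sample is its read total
    pooled over that sample's particles divided by the sample's total reads.
    An OTU is retained iff at some time point its abundance strictly exceeds
    the threshold in at least ``min_subjects`` subjects.  Particles whose
    retained-OTU reads drop to zero are dropped with a logged count.
    """
    subjects = m.subject_ids
    if min_subjects > len(subjects):
        raise InputValidationError(
            f"min_subjects={min_subjects} exceeds the {len(subjects)} subjects present"
        )
    keep = np.zeros(m.n_otus, dtype=bool)
    for t in m.timepoints:
        n_above = np.zeros(m.n_otus, dtype=int)
        for s in subjects:
            rows = (m.times == t) & (m.subjects.astype(str) == s)
            if not rows.any():
                continue
            pooled = m.counts[rows].sum(axis=0).astype(float)
            tot = pooled.sum()
            if tot == 0:
                continue
            n_above += (pooled / tot) > min_rel_abund
        keep |= n_above >= min_subjects
    if min_rel_abund <= 0:
        keep |= m.counts.sum(axis=0) >= 1
    if not keep.any():
        raise InputValidationError("no OTUs retained by abundance filter")
    out = m.select(otus=keep)
    nonzero = out.total_reads > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d particles with zero retained-OTU reads", n_dropped)
        out = out.select(particles=nonzero)
    return out


def apply_filters(
    m: ParticleCountMatrix,
    min_reads: int = 250,
    max_reads: int = 10_000,
    min_rel_abund: float = 0.005,
    min_subjects: int = 1,
):
    """Run the sequential particle and OTU filters; returns (matrix, report)."""
    steps = [
        {"step": "input", "n_particles": m.n_particles, "n_otus": m.n_otus}
    ]
    m1 = filter_particles(m, min_reads=min_reads, max_reads=max_reads)
    steps.append(
        {"step": "particle_reads", "n_particles": m1.n_particles, "n_otus": m1.n_otus}
    )
    m2 = filter_otus(m1, min_rel_abund=min_rel_abund, min_subjects=min_subjects)
    steps.append(
        {"step": "otu_abundance", "n_particles": m2.n_particles, "n_otus": m2.n_otus}
    )
    report = FilterReport(
        thresholds={
            "min_reads": min_reads,
            "max_reads": max_reads,
            "min_rel_abund": min_rel_abund,
            "min_subjects": min_subjects,
        },
        steps=steps,
    )
    return m2, report


def threshold_sweep(
    m: ParticleCountMatrix,
    read_thresholds=None,
    abund_thresholds=None,
    max_reads: int = 10_000,
) -> pd.DataFrame:
    """Survivor counts over a grid of filtering thresholds (elbow plots).

    For each minimum-read threshold, reports the number of particles
    surviving; for each abundance threshold, the number of OTUs surviving
    (after read filtering at the smallest read threshold).  Counts are
    monotone non-increasing in the thresholds.
    """
    rows = []
    if read_thresholds is not None:
        read_thresholds = list(read_thresholds)
        if not read_thresholds:
            raise InputValidationError("empty read threshold list")
        if sorted(read_thresholds) != read_thresholds:
            raise InputValidationError("thresholds must be sorted ascending")
        tot = m.total_reads
        for thr in read_thresholds:
            n = int(((tot >= thr) & (tot <= max_reads)).sum())
            rows.append({"kind": "particles", "threshold": thr, "retained": n})
    if abund_thresholds is not None:
        abund_thresholds = list(abund_thresholds)
        if not abund_thresholds:
            raise InputValidationError("empty abundance threshold list")
        if sorted(abund_thresholds) != abund_thresholds:
            raise InputValidationError("thresholds must be sorted ascending")
        base = (
            filter_particles(m, min_reads=read_thresholds[0], max_reads=max_reads)
            if read_thresholds
            else m
        )
        for thr in abund_thresholds:
            try:
                mt = filter_otus(base, min_rel_abund=thr)
                n = mt.n_otus
            except InputValidationError:
                n = 0
            rows.append({"kind": "otus", "threshold": thr, "retained": n})
    if not rows:
        raise InputValidationError("no thresholds given")
    return pd.DataFrame(rows)
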