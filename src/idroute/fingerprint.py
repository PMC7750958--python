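"""ID-fingerprint data model and genetic distances.

An *ID fingerprint* is the set of internal-deletion breakpoint pairs found
in a sample together with their frequencies among all TE copies.  Treating
every ID — and the full-length (FL) element — as an allele of a single TE
"locus", the pairwise genetic distance between samples is Jost's D, which
behaves well for highly multiallelic loci.

Pipeline steps implemented here:

* reading/writing DeviaTE-style tab-separated fingerprint tables with a
  minimum read-support filter,
* merging breakpoints across samples with a positional tolerance (split-read
  breakpoint estimates jitter by a few bp),
* deriving the FL frequency as ``1 - sum(f_i)``,
* removing population-private IDs (they carry no relational information and
  add noise),
* appending an artificial all-FL reference sample marking the origin of an
  invasion, and
* pairwise Jost's D distance matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "FingerprintEntry",
    "Fingerprint",
    "FrequencyMatrix",
    "read_fingerprint_table",
    "write_fingerprint_table",
    "cluster_breakpoints",
    "fl_frequency",
    "drop_private_ids",
    "add_fl_reference",
    "jost_d_pair",
    "distance_matrix",
    "id_overlap",
]

FL_LABEL = "FL"
_TOL = 1e-9


@dataclass
class FingerprintEntry:
    """One internal deletion in one sample."""

    start: int
    end: int
    frequency: float
    support: int = 0
    label: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.start < self.end:
            raise ValueError(f"invalid breakpoints ({self.start}, {self.end})")
        if not -_TOL <= self.frequency <= 1 + _TOL:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.support < 0:
            raise ValueError("support must be >= 0")


@dataclass
class Fingerprint:
    """All IDs of one sample."""

    sample_id: str
    entries: list = field(default_factory=list)

    def total_id_frequency(self) -> float:
        return float(sum(e.frequency for e in self.entries))


def fl_frequency(fp: Fingerprint) -> float:
    """FL frequency of a sample: 1 - sum of its ID frequencies."""
    s = fp.total_id_frequency()
    if s > 1 + _TOL:
        raise ValueError(
            f"sample {fp.sample_id}: ID frequencies sum to {s} > 1"
        )
    return float(min(1.0, max(0.0, 1.0 - s)))


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

_COLUMNS = ["sample_id", "start", "end", "support", "frequency"]


def read_fingerprint_table(path, min_support: int = 0) -> list:
    """Read a tab-separated fingerprint table.

    Expected columns: ``sample_id  start  end  support  frequency`` with a
    header line; lines starting with '#' are comments.  Entries with
    ``support < min_support`` are dropped.  Malformed rows raise an error
    naming the offending line.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    header = None
    fingerprints: dict = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            missing = [c for c in _COLUMNS if c not in header]
            if missing:
                raise ValueError(f"line {lineno}: missing columns {missing}")
            idx = {c: header.index(c) for c in _COLUMNS}
            continue
        if len(fields) < len(header):
            raise ValueError(f"line {lineno}: expected {len(header)} fields")
        try:
            sample = fields[idx["sample_id"]]
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
            support = int(fields[idx["support"]])
            freq = float(fields[idx["frequency"]])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
        if start >= end:
            raise ValueError(f"line {lineno}: start {start} >= end {end}")
        if support < min_support:
            continue
        fingerprints.setdefault(sample, Fingerprint(sample)).entries.append(
            FingerprintEntry(start, end, freq, support)
        )
    return list(fingerprints.values())


def write_fingerprint_table(fingerprints: Iterable[Fingerprint], path) -> None:
    buf = io.StringIO()
    buf.write("\t".join(_COLUMNS) + "\n")
    for fp in fingerprints:
        for e in fp.entries:
            buf.write(
                f"{fp.sample_id}\t{e.start}\t{e.end}\t{e.support}\t{e.frequency:.12g}\n"
            )
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# frequency matrix
# ---------------------------------------------------------------------------


@dataclass
class FrequencyMatrix:
    """Samples x alleles frequency table.

    The allele set is the clustered ID variants plus the FL column; each row
    sums to 1 (the FL column is the complement of the ID frequencies).
    """

    table: pd.DataFrame
    private_filtered: bool = False
    fl_reference_added: bool = False

    def __post_init__(self):
        if FL_LABEL not in self.table.columns:
            raise ValueError("frequency matrix must contain an FL column")
        sums = self.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("rows of a frequency matrix must sum to 1")

    @property
    def samples(self) -> list:
        return list(self.table.index)

    @property
    def id_alleles(self) -> list:
        return [c for c in self.table.columns if c != FL_LABEL]

    def id_table(self) -> pd.DataFrame:
        return self.table[self.id_alleles]

    def row(self, sample) -> np.ndarray:
        return self.table.loc[sample].to_numpy(dtype=float)


def cluster_breakpoints(
    fingerprints: Sequence[Fingerprint],
    tolerance_bp: int = 3,
) -> FrequencyMatrix:
    """Merge IDs across samples into alleles, allowing a positional
    tolerance on both breakpoints.

    Exact (start, end) pairs are pooled first; the pooled pairs are then
    clustered greedily in order of decreasing total support (ties broken by
    the smaller (start, end)): the highest-support unassigned pair becomes a
    representative and absorbs every unassigned pair within
    ``tolerance_bp`` of it on *both* breakpoints.  Within a sample, merged
    entries sum their frequencies.  The FL column is appended as the
    complement.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance must be >= 0")
    # pool exact breakpoint pairs
    pooled: dict = {}
    for fp in fingerprints:
        for e in fp.entries:
            key = (e.start, e.end)
            supp, per_sample = pooled.setdefault(key, [0, {}])
            pooled[key][0] += e.support
            per_sample[fp.sample_id] = per_sample.get(fp.sample_id, 0.0) + e.frequency
    # greedy clustering against fixed representatives
    order = sorted(pooled, key=lambda k: (-pooled[k][0], k))
    assigned: dict = {}
    reps: list = []
    for key in order:
        if key in assigned:
            continue
        reps.append(key)
        assigned[key] = key
        for other in order:
            if other in assigned:
                continue
            if abs(other[0] - key[0]) <= tolerance_bp and abs(other[1] - key[1]) <= tolerance_bp:
                assigned[other] = key
    samples = [fp.sample_id for fp in fingerprints]
    reps_sorted = sorted(reps)
    labels = {rep: f"{rep[0]}_{rep[1]}" for rep in reps_sorted}
    data = pd.DataFrame(
        0.0, index=samples, columns=[labels[r] for r in reps_sorted], dtype=float
    )
    for key, (_supp, per_sample) in pooled.items():
        col = labels[assigned[key]]
        for sample, freq in per_sample.items():
            data.loc[sample, col] += freq
    fl = 1.0 - data.sum(axis=1)
    if (fl < -_TOL).any():
        bad = fl.idxmin()
        raise ValueError(f"sample {bad}: ID frequencies sum to more than 1")
    data[FL_LABEL] = fl.clip(lower=0.0)
    return FrequencyMatrix(data)


def drop_private_ids(matrix: FrequencyMatrix) -> FrequencyMatrix:
    """Remove ID alleles with nonzero frequency in exactly one sample and
    recompute the FL column as the complement of the retained IDs."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples to define private IDs")
    ids = matrix.id_table()
    n_carriers = (ids > 0).sum(axis=0)
    keep = n_carriers[n_carriers >= 2].index
    data = ids[keep].copy()
    data[FL_LABEL] = 1.0 - data.sum(axis=1)
    return FrequencyMatrix(
        data,
        private_filtered=True,
        fl_reference_added=matrix.fl_reference_added,
    )


def add_fl_reference(matrix: FrequencyMatrix, label: str = FL_LABEL) -> FrequencyMatrix:
    """Append an artificial sample consisting solely of FL elements; it
    marks the origin of the invasion in downstream trees."""
    if label in matrix.table.index:
        raise ValueError(f"sample label {label!r} already present")
    row = pd.Series(0.0, index=matrix.table.columns, name=label)
    row[FL_LABEL] = 1.0
    table = pd.concat([matrix.table, row.to_frame().T])
    return FrequencyMatrix(
        table,
        private_filtered=matrix.private_filtered,
        fl_reference_added=True,
    )


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------


def jost_d_pair(p, q) -> float:
    """Two-deme Jost's D from allele-frequency vectors over a shared allele
    set.

    With H_S the mean within-sample heterozygosity ``1 - sum p_i^2`` and
    H_T the heterozygosity of the pooled frequencies ``(p + q) / 2``::

        D = (H_T - H_S) / (1 - H_S) * n / (n - 1),   n = 2 demes

    D is 0 for identical samples and 1 for samples with disjoint alleles.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frequency vectors must share the allele set")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1 (sum={v.sum()})")
    hs = 1.0 - 0.5 * (np.dot(p, p) + np.dot(q, q))
    mean = 0.5 * (p + q)
    ht = 1.0 - np.dot(mean, mean)
    if hs >= 1.0 - 1e-12:
        return 0.0
    d = (ht - hs) / (1.0 - hs) * 2.0
    return float(min(1.0, max(0.0, d)))


def distance_matrix(matrix: FrequencyMatrix) -> DistanceMatrix:
    """Pairwise Jost's D among all samples of a frequency matrix."""
    samples = matrix.samples
    if len(samples) < 3:
        raise ValueError("need at least three samples for tree building")
    arr = matrix.table.to_numpy(dtype=float)
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jost_d_pair(arr[i], arr[j])
    return DistanceMatrix(out, ids=[str(s) for s in samples])


# ---------------------------------------------------------------------------
# fingerprint overlap
# ---------------------------------------------------------------------------


def id_overlap(finger_a: Fingerprint, finger_b: Fingerprint, tolerance_bp: int = 3):
    """One-to-one matching of the IDs of two fingerprints within a
    breakpoint tolerance; greedy by proximity.

    Returns ``(shared, unique_to_a, unique_to_b)`` counts.
    """
    pairs = []
    for i, ea in enumerate(finger_a.entries):
        for j, eb in enumerate(finger_b.entries):
            ds = abs(ea.start - eb.start)
            de = abs(ea.end - eb.end)
            if ds <= tolerance_bp and de <= tolerance_bp:
                pairs.append((ds + de, i, j))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    shared = 0
    for _dist, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    return shared, len(finger_a.entries) - shared, len(finger_b.entries) - shared
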