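"""File formats, run manifests, the synthetic fixture generator and the
end-to-end reconstruction pipeline.

Formats: Newick trees (branch lengths to 6 significant digits, bootstrap
supports as internal node labels), PHYLIP square distance matrices,
YAML/JSON simulation configs, and the tab-separated fingerprint tables of
:mod:`idroute.fingerprint`.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import yaml
from skbio import DistanceMatrix

from . import __version__
from .fingerprint import (
    Fingerprint,
    FingerprintEntry,
    add_fl_reference,
    cluster_breakpoints,
    distance_matrix,
    drop_private_ids,
    read_fingerprint_table,
    write_fingerprint_table,
)
from .simcore import SimConfig
from .trees import bionj, bootstrap_consensus, classical_mds

__all__ = [
    "read_newick",
    "write_newick",
    "read_phylip_square",
    "write_phylip_square",
    "read_config",
    "write_config",
    "RunManifest",
    "generate_fixture_fingerprints",
    "pipeline_reconstruct",
]


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree in Newick; internal node labels (bootstrap supports)
    are preserved, branch lengths use 6 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )
    if hasattr(path, "write"):
        path.write(s)
    else:
        Path(path).write_text(s)


def read_newick(path) -> dendropy.Tree:
    src = path.read() if hasattr(path, "read") else Path(path).read_text()
    try:
        tree = dendropy.Tree.get(
            data=src, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from None
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------


def write_phylip_square(D: DistanceMatrix, path) -> None:
    lines = [f"{len(D.ids)}"]
    for label, row in zip(D.ids, np.asarray(D.data, dtype=float)):
        lines.append(label + "\t" + "\t".join(f"{x:.12g}" for x in row))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_phylip_square(path) -> DistanceMatrix:
    src = path.read() if hasattr(path, "read") else Path(path).read_text()
    lines = [l for l in src.splitlines() if l.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError("line 1: expected taxon count") from None
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ValueError(f"line {i}: expected label + {n} distances")
        labels.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError:
            raise ValueError(f"line {i}: non-numeric distance") from None
    return DistanceMatrix(np.array(rows), ids=labels)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def read_config(path) -> SimConfig:
    p = Path(path)
    data = yaml.safe_load(p.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{p}: config must be a mapping")
    return SimConfig.from_dict(data)


def write_config(cfg: SimConfig, path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record: re-running with the recorded config and seed
    reproduces all stochastic outputs bit-identically."""

    command: str
    seed: Optional[int]
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.datetime.now().isoformat(timespec="seconds")

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# synthetic fixture fingerprints
# ---------------------------------------------------------------------------


def generate_fixture_fingerprints(
    n_pops: int,
    n_shared_ids: int,
    n_private_ids: int,
    rng: np.random.Generator,
    te_length: int = 2907,
    id_fraction_range: tuple = (0.1, 0.5),
    coverage: int = 200,
) -> tuple:
    """Synthetic fingerprint tables emulating successively invaded demes.

    This stands in for split-read fingerprints of real pooled samples.  Each
    shared ID originates in one deme and is carried by that deme and all
    later ones (with population-level Dirichlet/Gamma weight noise), so
    neighbouring demes share more alleles; the total ID mass grows linearly
    from the first to the last deme across ``id_fraction_range``; each deme
    additionally receives ``n_private_ids`` private IDs.  Returns
    ``(fingerprints, truth_order)`` where ``truth_order`` is the generating
    deme order (sample ids).
    """
    if n_pops < 2:
        raise ValueError("need at least two populations")
    names = [f"pop{i + 1}" for i in range(n_pops)]
    lo, hi = id_fraction_range
    id_mass = np.linspace(lo, hi, n_pops)

    def draw_breakpoints(k):
        out = []
        for _ in range(k):
            while True:
                a, b = rng.integers(1, te_length + 1, size=2)
                if a != b:
                    break
            out.append((int(min(a, b)), int(max(a, b))))
        return out

    shared_bp = draw_breakpoints(n_shared_ids)
    # origin deme of each shared ID (must be carried by >= 2 demes)
    origins = rng.integers(0, n_pops - 1, size=n_shared_ids)
    base_w = rng.gamma(2.0, 1.0, size=n_shared_ids)

    fingerprints = []
    for j, name in enumerate(names):
        weights, bps = [], []
        for v in range(n_shared_ids):
            if origins[v] <= j:
                weights.append(base_w[v] * rng.lognormal(0.0, 0.4))
                bps.append(shared_bp[v])
        for bp in draw_breakpoints(n_private_ids):
            weights.append(0.3 * rng.gamma(2.0, 1.0))
            bps.append(bp)
        entries = []
        if weights:
            w = np.array(weights)
            freqs = w / w.sum() * id_mass[j]
            for bp, f in zip(bps, freqs):
                support = max(2, int(round(f * coverage)))
                entries.append(FingerprintEntry(bp[0], bp[1], float(f), support))
        fingerprints.append(Fingerprint(name, entries))
    return fingerprints, names


# ---------------------------------------------------------------------------
# reconstruction pipeline
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    tree: dendropy.Tree              # single BIONJ tree on the full matrix
    consensus: dendropy.Tree         # majority-rule bootstrap consensus
    supports: dict                   # split -> support fraction
    mds: "object"                    # samples x axes coordinates
    distances: DistanceMatrix
    report: dict                     # counts after each filtering stage


def pipeline_reconstruct(
    fingerprints,
    min_support: int = 3,
    tolerance_bp: int = 3,
    drop_private: bool = True,
    fl_reference: bool = True,
    bootstrap: int = 100,
    collapse: float = 0.5,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> ReconstructionResult:
    """Full reconstruction chain: read -> support filter -> breakpoint
    clustering -> private-ID removal -> FL reference -> Jost's D -> BIONJ +
    bootstrap consensus -> classical MDS.

    ``fingerprints`` is a path to a fingerprint TSV or a list of
    :class:`Fingerprint`.  With ``out_dir`` set, Newick/PHYLIP/TSV outputs
    and a manifest are written there.
    """
    report: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if isinstance(fingerprints, (str, Path)):
        fps = stage("read", lambda: read_fingerprint_table(fingerprints, min_support))
    else:
        fps = [
            Fingerprint(fp.sample_id,
                        [e for e in fp.entries if e.support >= min_support])
            for fp in fingerprints
        ]
    report["samples"] = len(fps)
    report["entries_after_support_filter"] = sum(len(f.entries) for f in fps)

    matrix = stage("cluster", lambda: cluster_breakpoints(fps, tolerance_bp))
    report["alleles_after_clustering"] = len(matrix.id_alleles)
    if drop_private:
        matrix = stage("drop_private", lambda: drop_private_ids(matrix))
        report["alleles_after_private_filter"] = len(matrix.id_alleles)
    if fl_reference:
        matrix = stage("fl_reference", lambda: add_fl_reference(matrix))
    report["final_samples"] = len(matrix.samples)

    D = stage("distances", lambda: distance_matrix(matrix))
    tree = stage("bionj", lambda: bionj(D))
    rng = np.random.default_rng(seed)
    consensus, supports = stage(
        "consensus",
        lambda: bootstrap_consensus(matrix, B=bootstrap, threshold=collapse, rng=rng),
    )
    coords = stage("mds", lambda: classical_mds(D, k=2))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_phylip_square(D, out_dir / "distances.phylip")
        write_newick(tree, out_dir / "bionj.nwk")
        write_newick(consensus, out_dir / "consensus.nwk")
        coords.to_csv(out_dir / "mds.tsv", sep="\t")
        RunManifest(
            command="reconstruct",
            seed=seed,
            config={
                "min_support": min_support,
                "tolerance_bp": tolerance_bp,
                "drop_private": drop_private,
                "fl_reference": fl_reference,
                "bootstrap": bootstrap,
                "collapse": collapse,
            },
            inputs={"fingerprints": str(fingerprints)},
            outputs={k: str(out_dir / k) for k in
                     ("distances.phylip", "bionj.nwk", "consensus.nwk", "mds.tsv")},
            extra={"report": report},
        ).write(out_dir / "manifest.json")

    return ReconstructionResult(
        tree=tree, consensus=consensus, supports=supports,
        mds=coords, distances=D, report=report,
    )
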