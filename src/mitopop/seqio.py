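"""Aligned-sequence I/O, haplotype collapsing and distance matrices.

The central container is :class:`Alignment`: a rectangular matrix of
mitochondrial sequences over ``{A, C, G, T, -, N}``, one record per specimen,
each specimen tagged with the sampling site it came from.  Everything
downstream (diversity statistics, mismatch distributions, F_ST, networks)
consumes either the alignment itself, the :class:`HaplotypeTable` produced by
:func:`collapse_haplotypes`, or a :class:`DistanceMatrix` from
:func:`pairwise_differences`.

Missing data (``-`` and ``N``) are handled by *pairwise deletion* by default
(``ignore_missing_sites``): a site missing in either member of a pair is
skipped for that pair.  ``strict_identity`` treats ``-``/``N`` as ordinary
states, which is the conservative choice when collapsing haplotypes.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    CoordinateError,
    MetadataError,
    UndefinedDistanceError,
)

ALPHABET = frozenset("ACGT-N")
MISSING = frozenset("-N")

MissingRule = str  # "ignore_missing_sites" | "strict_identity"


def _check_missing_rule(rule: str) -> None:
    if rule not in ("ignore_missing_sites", "strict_identity"):
        raise ValueError(f"unknown missing_rule: {rule!r}")


@dataclass(frozen=True)
class Alignment:
    """Rectangular multiple-sequence alignment with per-specimen site labels."""

    specimen_ids: tuple[str, ...]
    site_labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if not (len(self.specimen_ids) == len(self.site_labels) == len(self.sequences)):
            raise AlignmentError("specimen_ids, site_labels and sequences must align")
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            raise AlignmentError("duplicate specimen ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        for sid, seq in zip(self.specimen_ids, self.sequences):
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(f"{sid}: illegal characters {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of ASCII codes."""
        return np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8).reshape(
            self.n, self.length
        )

    def subset(self, indices: Sequence[int]) -> "Alignment":
        return Alignment(
            tuple(self.specimen_ids[i] for i in indices),
            tuple(self.site_labels[i] for i in indices),
            tuple(self.sequences[i] for i in indices),
        )

    def site_subset(self, site_label: str) -> "Alignment":
        idx = [i for i, s in enumerate(self.site_labels) if s == site_label]
        if not idx:
            raise MetadataError(f"no specimens from site {site_label!r}")
        return self.subset(idx)


def make_alignment(records: Iterable[tuple[str, str, str]]) -> Alignment:
    """Build an :class:`Alignment` from (specimen_id, site_label, sequence) triples.

    Sequences are upper-cased; validation happens in the constructor.
    """
    ids, sites, seqs = [], [], []
    for sid, site, seq in records:
        ids.append(str(sid))
        sites.append(str(site))
        seqs.append(str(seq).upper())
    if not ids:
        raise AlignmentError("empty alignment")
    return Alignment(tuple(ids), tuple(sites), tuple(seqs))


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_site_metadata(metadata_source) -> pd.DataFrame:
    """Read the specimen table: TSV with header ``specimen_id site latitude longitude``.

    Returns the per-specimen frame (indexed by specimen_id).  Use
    :func:`site_table` for the per-site aggregate.
    """
    df = pd.read_csv(metadata_source, sep="\t", dtype={"specimen_id": str, "site": str})
    required = {"specimen_id", "site", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata missing columns: {sorted(missing)}")
    if df["specimen_id"].duplicated().any():
        raise MetadataError("duplicate specimen_id in metadata")
    bad = df[(df["latitude"].abs() > 90) | (df["longitude"].abs() > 180)]
    if len(bad):
        raise CoordinateError(f"invalid coordinates for {bad['specimen_id'].tolist()}")
    return df.set_index("specimen_id")


def site_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-specimen metadata to one row per site (lat, lon, n)."""
    grouped = metadata.groupby("site").agg(
        latitude=("latitude", "first"),
        longitude=("longitude", "first"),
        n=("latitude", "size"),
    )
    return grouped


def read_alignment(fasta_source, metadata_source) -> tuple[Alignment, pd.DataFrame]:
    """Read a FASTA alignment plus specimen metadata.

    Every FASTA record id must appear in the metadata table; the returned
    frame is the per-site aggregate from :func:`site_table`.
    """
    meta = read_site_metadata(metadata_source)
    records = []
    with _open_text(fasta_source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id not in meta.index:
                raise MetadataError(f"specimen {rec.id!r} not in metadata")
            records.append((rec.id, meta.loc[rec.id, "site"], str(rec.seq)))
    aln = make_alignment(records)
    return aln, site_table(meta.loc[list(aln.specimen_ids)])


def write_alignment(alignment: Alignment, fasta_path, metadata_path=None,
                    coordinates: dict[str, tuple[float, float]] | None = None) -> None:
    """Write FASTA (and optionally the specimen metadata TSV) for round-tripping."""
    with open(fasta_path, "w") as fh:
        for sid, seq in zip(alignment.specimen_ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")
    if metadata_path is not None:
        coords = coordinates or {}
        rows = []
        for sid, site in zip(alignment.specimen_ids, alignment.site_labels):
            lat, lon = coords.get(site, (0.0, 0.0))
            rows.append((sid, site, lat, lon))
        pd.DataFrame(rows, columns=["specimen_id", "site", "latitude", "longitude"]).to_csv(
            metadata_path, sep="\t", index=False
        )


def strip_segment(alignment: Alignment, start: int, length: int) -> Alignment:
    """Remove ``length`` columns starting at 1-based position ``start``.

    Used e.g. to excise a tandem duplication block identified in a handful of
    records (the block shows as gap columns in the unaffected records, so
    dropping the columns keeps the alignment rectangular).  ``length == 0``
    returns the alignment unchanged.
    """
    if length < 0:
        raise CoordinateError("length must be >= 0")
    if length == 0:
        return alignment
    if start < 1 or start + length - 1 > alignment.length:
        raise CoordinateError(
            f"segment [{start}, {start + length - 1}] outside 1..{alignment.length}"
        )
    a, b = start - 1, start - 1 + length
    seqs = tuple(s[:a] + s[b:] for s in alignment.sequences)
    return Alignment(alignment.specimen_ids, alignment.site_labels, seqs)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-site frequency counts.

    ``counts[i, j]`` is the number of specimens from site ``site_labels[j]``
    carrying haplotype ``i``; ``assignments[r]`` maps alignment record ``r``
    to its haplotype row.
    """

    haplotypes: list[str]
    site_labels: list[str]
    counts: np.ndarray
    assignments: list[int]
    missing_rule: str = "ignore_missing_sites"

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def total_n(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Global haplotype relative frequencies p_i."""
        return self.counts.sum(axis=1) / self.total_n

    def site_counts(self, site_label: str) -> np.ndarray:
        j = self.site_labels.index(site_label)
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.site_labels)
        df.insert(0, "haplotype_id", [f"H{i + 1}" for i in range(self.k)])
        df.insert(1, "sequence", self.haplotypes)
        return df


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x in MISSING or y in MISSING for x, y in zip(a, b))


def collapse_haplotypes(
    alignment: Alignment, missing_rule: MissingRule = "ignore_missing_sites"
) -> HaplotypeTable:
    """Collapse specimens into distinct haplotypes.

    Under ``strict_identity`` two sequences are the same haplotype iff the
    strings are identical.  Under ``ignore_missing_sites`` a sequence joins the
    first existing haplotype it is compatible with (agrees at every site where
    both are called); compatibility is not transitive, so assignment order is
    the record order — deterministic for a given alignment.
    """
    _check_missing_rule(missing_rule)
    if alignment.n == 0:
        raise AlignmentError("empty alignment")
    sites = sorted(set(alignment.site_labels))
    site_index = {s: j for j, s in enumerate(sites)}

    haplotypes: list[str] = []
    assignments: list[int] = []
    if missing_rule == "strict_identity":
        index: dict[str, int] = {}
        for seq in alignment.sequences:
            if seq not in index:
                index[seq] = len(haplotypes)
                haplotypes.append(seq)
            assignments.append(index[seq])
    else:
        for seq in alignment.sequences:
            for h_i, hap in enumerate(haplotypes):
                if _compatible(seq, hap):
                    assignments.append(h_i)
                    break
            else:
                haplotypes.append(seq)
                assignments.append(len(haplotypes) - 1)

    counts = np.zeros((len(haplotypes), len(sites)), dtype=int)
    for rec, h_i in enumerate(assignments):
        counts[h_i, site_index[alignment.site_labels[rec]]] += 1
    return HaplotypeTable(haplotypes, sites, counts, assignments, missing_rule)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str  # "pairwise_differences" | "p_distance"

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal not zero")

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.metric)


def _sequence_matrix(sequences: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    return arr.reshape(len(sequences), -1)


def pairwise_differences(
    source,
    missing_rule: MissingRule = "ignore_missing_sites",
    metric: str = "pairwise_differences",
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise difference counts (or p-distances) between sequences.

    ``source`` is an :class:`Alignment`, a :class:`HaplotypeTable`, or a plain
    sequence of equal-length strings.  With ``ignore_missing_sites`` a pair
    with no jointly called site raises :class:`UndefinedDistanceError`.
    """
    _check_missing_rule(missing_rule)
    if metric not in ("pairwise_differences", "p_distance"):
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(source, Alignment):
        seqs = source.sequences
        labs = labels or source.specimen_ids
    elif isinstance(source, HaplotypeTable):
        seqs = source.haplotypes
        labs = labels or [f"H{i + 1}" for i in range(source.k)]
    else:
        seqs = [str(s).upper() for s in source]
        labs = labels or [str(i) for i in range(len(seqs))]
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("sequences of unequal length")

    mat = _sequence_matrix(seqs)
    n, L = mat.shape
    if missing_rule == "ignore_missing_sites":
        miss = (mat == ord("-")) | (mat == ord("N"))
    else:
        miss = np.zeros_like(mat, dtype=bool)

    out = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        both_called = ~miss[i] & ~miss[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both_called
        d = diff.sum(axis=1).astype(float)
        valid = both_called.sum(axis=1)
        if np.any(valid == 0):
            j = int(np.argmax(valid == 0)) + i + 1
            raise UndefinedDistanceError(
                f"no overlapping called sites for {labs[i]!r} vs {labs[j]!r}"
            )
        if metric == "p_distance":
            d = d / valid
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return DistanceMatrix(tuple(labs), out, metric)


def group_distances(
    dm: DistanceMatrix, partition: dict[str, Sequence[str]]
) -> tuple[dict[str, float], float, float]:
    """Within-group means, between-group mean, and net between-group distance.

    ``net = between_mean − (within_X + within_Y)/2`` — the net divergence d_A
    used to correct between-clade distance for within-clade polymorphism.
    A singleton group has no within pairs; its within mean is NaN (with a
    warning) and the net distance is then NaN rather than silently zero.
    """
    if len(partition) != 2:
        raise ValueError("partition must define exactly two groups")
    groups = list(partition.items())
    sets = [set(ms) for _, ms in groups]
    identical = sets[0] == sets[1]
    if not identical and sets[0] & sets[1]:
        raise ValueError("groups overlap")
    unknown = (sets[0] | sets[1]) - set(dm.labels)
    if unknown:
        raise ValueError(f"labels not in distance matrix: {sorted(unknown)}")

    idx = {g: [dm.labels.index(m) for m in ms] for g, ms in groups}
    within: dict[str, float] = {}
    for g, ii in idx.items():
        if len(ii) < 2:
            warnings.warn(f"group {g!r} is a singleton; within mean undefined")
            within[g] = float("nan")
        else:
            sub = dm.values[np.ix_(ii, ii)]
            within[g] = float(sub[np.triu_indices(len(ii), k=1)].mean())
    (g1, i1), (g2, i2) = idx.items()
    if identical:
        # the "between" mean of a group against itself is its within mean,
        # so the net distance vanishes identically
        between = within[g1]
    else:
        between = float(dm.values[np.ix_(i1, i2)].mean())
    net = between - (within[g1] + within[g2]) / 2.0
    return within, between, float(net)
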