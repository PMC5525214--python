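"""OTU abundance profiles: IO, normalization and transformations.

A community profile is stored sparsely — a mapping from OTU label to a
non-negative count (or corrected fraction).  Zero entries are never
stored.  Supported table dialects are the classic TSV OTU table
("#OTU ID" header, samples in columns, optional trailing taxonomy
column) and BIOM-JSON v1.0 (sparse or dense matrix).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from microsearch.errors import ProfileFormatError, ProfileValueError

__all__ = [
    "AbundanceProfile",
    "SampleDatabase",
    "DistanceStore",
    "CopyNumberTable",
    "TaxonomyTable",
    "read_profiles",
    "read_copy_numbers",
    "read_taxonomy",
    "read_metadata",
    "to_relative",
    "copy_number_correct",
    "rarefy_pair",
    "phyla_key",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceProfile:
    """Sparse OTU -> abundance mapping for one sample."""

    sample_id: str
    counts: dict[str, float]

    def __post_init__(self):
        bad = [o for o, v in self.counts.items() if v < 0]
        if bad:
            raise ProfileValueError(f"negative abundances for {sorted(bad)}")
        self.counts = {o: v for o, v in self.counts.items() if v != 0}

    @property
    def depth(self) -> float:
        return sum(self.counts.values())

    @property
    def support(self) -> int:
        return len(self.counts)

    def is_integer(self) -> bool:
        return all(float(v).is_integer() for v in self.counts.values())


@dataclass
class DistanceStore:
    """Symmetric all-vs-all distance matrix keyed by sample id."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ProfileFormatError(
                f"distance matrix shape {self.matrix.shape} != ({n}, {n})"
            )
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ProfileFormatError("distance matrix diagonal is not zero")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ProfileFormatError("distance matrix is not symmetric")
        self._pos = {s: i for i, s in enumerate(self.ids)}

    def __contains__(self, pair) -> bool:
        a, b = pair
        return a in self._pos and b in self._pos

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self._pos[a], self._pos[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle pair distances (scipy condensed order)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]


@dataclass
class SampleDatabase:
    """Profiles plus metadata and an optional pre-computed distance store."""

    profiles: list[AbundanceProfile]
    metadata: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    precalc: DistanceStore | None = None

    def __post_init__(self):
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ProfileFormatError("duplicate sample ids in database")
        self._by_id = {p.sample_id: p for p in self.profiles}

    @property
    def size(self) -> int:
        return len(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def __getitem__(self, sample_id: str) -> AbundanceProfile:
        return self._by_id[sample_id]

    def ecosystem(self, sample_id: str) -> str:
        return self.metadata.get(sample_id, ("unknown", []))[0]


class CopyNumberTable(dict):
    """OTU label -> 16S operon copy number (>= 1)."""

    def __init__(self, mapping):
        super().__init__(mapping)
        bad = {o: v for o, v in self.items() if v <= 0}
        if bad:
            raise ProfileValueError(f"non-positive copy numbers: {bad}")


class TaxonomyTable(dict):
    """OTU label -> 7-rank lineage (kingdom ... species)."""

    def lineage(self, otu: str) -> tuple[str, ...]:
        return self.get(otu, (UNCLASSIFIED,) * len(RANKS))

    def rank_of(self, otu: str, rank: str) -> str:
        name = self.lineage(otu)[RANKS.index(rank)]
        return name if name else UNCLASSIFIED


# ---------------------------------------------------------------------------
# readers


def _profiles_from_frame(df: pd.DataFrame) -> list[AbundanceProfile]:
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ProfileFormatError(f"duplicate OTU rows: {dups}")
    if (df.values < 0).any():
        raise ProfileFormatError("negative counts in OTU table")
    out = []
    for sample in df.columns:
        col = df[sample]
        counts = {str(o): float(v) for o, v in col.items() if v != 0}
        out.append(AbundanceProfile(str(sample), counts))
    return out


def _read_tsv(path: Path) -> list[AbundanceProfile]:
    lines = path.read_text().splitlines()
    header_at = next(
        (i for i, ln in enumerate(lines) if ln.startswith("#OTU ID")), None
    )
    if header_at is None:
        raise ProfileFormatError(f"{path}: no '#OTU ID' header row")
    try:
        df = pd.read_csv(
            path, sep="\t", skiprows=header_at, header=0, index_col=0,
            comment=None,
        )
    except Exception as exc:
        raise ProfileFormatError(f"{path}: {exc}") from exc
    # optional trailing taxonomy column is metadata, not a sample
    drop = [c for c in df.columns if c.strip().lower() == "taxonomy"]
    df = df.drop(columns=drop)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: non-numeric count: {exc}") from exc
    return _profiles_from_frame(df)


def _read_biom_json(path: Path) -> list[AbundanceProfile]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ProfileFormatError(f"{path}: malformed JSON: {exc}") from exc
    try:
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mtype = doc["matrix_type"]
        data = doc["data"]
        shape = doc["shape"]
    except (KeyError, TypeError) as exc:
        raise ProfileFormatError(f"{path}: not a BIOM-JSON v1.0 table: {exc}") from exc
    if shape != [len(rows), len(cols)]:
        raise ProfileFormatError(f"{path}: shape {shape} disagrees with ids")
    dense = np.zeros((len(rows), len(cols)))
    if mtype == "sparse":
        for i, j, v in data:
            dense[i, j] = v
    elif mtype == "dense":
        dense[:] = np.asarray(data, dtype=float)
    else:
        raise ProfileFormatError(f"{path}: unknown matrix_type {mtype!r}")
    df = pd.DataFrame(dense, index=rows, columns=cols)
    return _profiles_from_frame(df)


def read_profiles(path, dialect: str = "tsv") -> list[AbundanceProfile]:
    """Read an OTU table into one profile per sample column.

    Parameters
    ----------
    path : path-like
    dialect : {"tsv", "biom-json"}
        Classic TSV OTU table or BIOM-JSON v1.0.  Both dialects of the
        same matrix yield identical profiles.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'biom-json')")


def read_copy_numbers(path) -> CopyNumberTable:
    """Two-column TSV: OTU label, copy number."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return CopyNumberTable(
        {str(o): float(v) for o, v in zip(df[0], df[1])}
    )


def read_taxonomy(path) -> TaxonomyTable:
    """Eight-column TSV: OTU label then kingdom..species."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 1 + len(RANKS):
        raise ProfileFormatError(
            f"taxonomy table needs {1 + len(RANKS)} columns, got {df.shape[1]}"
        )
    return TaxonomyTable(
        {
            str(row[0]): tuple(str(x) for x in row[1:])
            for row in df.itertuples(index=False)
        }
    )


def read_metadata(path) -> dict[str, tuple[str, list[str]]]:
    """TSV: sample id, ecosystem label, optional annotation columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        vals = [x for x in row if isinstance(x, str)]
        out[vals[0]] = (vals[1], vals[2:])
    return out


# ---------------------------------------------------------------------------
# transformations


def to_relative(p: AbundanceProfile) -> AbundanceProfile:
    """Scale to relative abundances (sum exactly 1, support unchanged)."""
    d = p.depth
    if d <= 0:
        raise ProfileValueError(f"sample {p.sample_id!r} has no reads")
    return AbundanceProfile(p.sample_id, {o: v / d for o, v in p.counts.items()})


def copy_number_correct(
    p: AbundanceProfile, table: CopyNumberTable
) -> AbundanceProfile:
    """Divide each OTU count by its 16S copy number.

    OTUs absent from the table default to copy number 1; their labels
    are reported through a ``UserWarning``.
    """
    missing = sorted(o for o in p.counts if o not in table)
    if missing:
        warnings.warn(
            f"sample {p.sample_id!r}: no copy number for {missing}; using 1",
            UserWarning,
            stacklevel=2,
        )
    corrected = {o: v / table.get(o, 1.0) for o, v in p.counts.items()}
    return AbundanceProfile(p.sample_id, corrected)


def _pair_rng(seed: int, id_a: str, id_b: str) -> np.random.Generator:
    # Stream keyed on the *sorted* id pair: the same pair always rarefies
    # identically regardless of comparison order.
    key = "\x1f".join(sorted((id_a, id_b))).encode()
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(key)])
    )


def _subsample(p: AbundanceProfile, n: int, rng: np.random.Generator) -> AbundanceProfile:
    otus = sorted(p.counts)
    counts = np.array([p.counts[o] for o in otus], dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(counts, n)
    return AbundanceProfile(
        p.sample_id, {o: int(c) for o, c in zip(otus, drawn) if c}
    )


def rarefy_pair(
    p: AbundanceProfile, q: AbundanceProfile, seed: int
) -> tuple[AbundanceProfile, AbundanceProfile]:
    """Subsample the deeper of two profiles to the shallower's depth.

    Uniform subsampling without replacement; the shallower profile is
    returned unchanged (equal depths: both unchanged).  Deterministic for
    a given seed and pair of sample ids, independent of argument order.

    Requires integer counts: rarefaction must precede copy-number
    correction, which produces fractional counts.
    """
    if p.depth <= 0 or q.depth <= 0:
        raise ProfileValueError("cannot rarefy an empty profile")
    if not (p.is_integer() and q.is_integer()):
        raise ProfileValueError(
            "rarefaction needs integer read counts; rarefy before "
            "copy-number correction"
        )
    dp, dq = int(p.depth), int(q.depth)
    target = min(dp, dq)
    rng = _pair_rng(seed, p.sample_id, q.sample_id)
    p_out = _subsample(p, target, rng) if dp > target else p
    q_out = _subsample(q, target, rng) if dq > target else q
    return p_out, q_out


def phyla_key(p: AbundanceProfile, tax: TaxonomyTable) -> tuple[str, ...]:
    """Ordered top-5 phyla of a sample (the key Meta-Storms indexes on).

    Phylum abundances are aggregated over OTUs; the key lists the up-to-5
    most abundant phyla in descending order.  Ties break lexicographically
    by phylum name, with the reserved ``unclassified`` bucket sorted last
    on ties.  Samples with fewer than five phyla yield shorter keys.
    """
    totals: dict[str, float] = {}
    for otu, v in p.counts.items():
        phylum = tax.rank_of(otu, "phylum")
        totals[phylum] = totals.get(phylum, 0.0) + v

    def sort_key(item):
        name, total = item
        # unclassified loses every lexicographic tie
        return (-total, name == UNCLASSIFIED, name)

    ordered = sorted(totals.items(), key=sort_key)
    return tuple(name for name, _ in ordered[:5])
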