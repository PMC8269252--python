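"""ASV table containers, file formats, and pre-analysis hygiene filters.

The central object is :class:`AsvTable`: an integer count matrix over
samples x ASVs with aligned per-sample metadata (material type, cylinder
series, months since pour, 30-day mean temperature, replicate id). All
downstream stages — co-occurrence inference, decontamination, diversity,
source tracking — consume and return this container.

On-disk formats are deliberately plain: a classic OTU-table-style TSV
(ASVs as rows, ``#ASV_ID`` header), a QIIME-style metadata TSV
(``#SampleID`` first column), FASTA for representative sequences, and a
minimal BIOM-style JSON (id, shape, integer data triples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SAMPLE_TYPES = (
    "concrete",
    "gravel",
    "sand",
    "cement",
    "fly_ash",
    "water",
    "negative_control",
)
SERIES = ("reactive", "mitigated", "none")

METADATA_COLUMNS = ("sample_type", "series", "months", "temperature", "replicate")

_DNA_ALPHABET = frozenset("ACGT")


class FormatError(ValueError):
    """A malformed table, metadata, or sequence file; names the offender."""


@dataclass(frozen=True)
class AsvRecord:
    """An ASV representative sequence (id + DNA string over {A,C,G,T})."""

    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"ASV {self.id!r}: non-ACGT characters {sorted(bad)} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AsvTable:
    """Integer counts (samples x ASVs) with aligned sample metadata.

    ``counts`` is a DataFrame indexed by sample id with ASV ids as
    columns; ``metadata`` is indexed by the same sample ids.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self):
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate ASV ids: {dup}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = counts.columns[np.where(~np.isclose(arr, np.round(arr)))[1][:1]]
                raise FormatError(f"non-integer counts (e.g. ASV {bad[0]!r})")
            counts = counts.round().astype(np.int64)
        if arr.size and (arr < 0).any():
            raise FormatError("negative counts")
        self.counts = counts.astype(np.int64) if counts.size else counts
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=counts.index.copy())
        else:
            missing = counts.index.difference(self.metadata.index)
            if len(missing):
                raise FormatError(
                    f"sample {missing[0]!r} present in counts but absent from metadata"
                )
            orphan = self.metadata.index.difference(counts.index)
            if len(orphan):
                raise FormatError(
                    f"orphan metadata row for sample {orphan[0]!r} not in counts"
                )
            self.metadata = self.metadata.loc[counts.index]

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Library size (total reads) per sample."""
        return self.counts.sum(axis=1)

    def is_negative(self) -> pd.Series:
        return self.metadata["sample_type"] == "negative_control"

    def select_samples(self, sample_ids) -> "AsvTable":
        ids = list(sample_ids)
        return AsvTable(self.counts.loc[ids].copy(), self.metadata.loc[ids].copy())

    def select_asvs(self, asv_ids) -> "AsvTable":
        ids = list(asv_ids)
        return AsvTable(self.counts[ids].copy(), self.metadata.copy())

    def drop_asvs(self, asv_ids) -> "AsvTable":
        drop = set(asv_ids)
        keep = [a for a in self.asv_ids if a not in drop]
        return self.select_asvs(keep)

    def __eq__(self, other):
        return (
            isinstance(other, AsvTable)
            and self.counts.equals(other.counts)
            and self.metadata.equals(other.metadata)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_table(table: AsvTable, counts_path, metadata_path=None) -> None:
    """Write counts as TSV (ASVs as rows, ``#ASV_ID`` header) and metadata."""
    out = table.counts.T
    out.index.name = "#ASV_ID"
    out.to_csv(counts_path, sep="\t")
    if metadata_path is not None:
        md = table.metadata.copy()
        md.index.name = "#SampleID"
        md.to_csv(metadata_path, sep="\t")


def read_table(counts_path, metadata_path=None) -> AsvTable:
    """Read a TSV ASV table (ASVs as rows) plus optional metadata TSV."""
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = raw.T
    counts.index.name = None
    counts.columns.name = None
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        metadata.index.name = None
    return AsvTable(counts, metadata)


def write_biom_json(table: AsvTable, path) -> None:
    """Minimal BIOM-style JSON: ids, shape, and sparse integer triples."""
    counts = table.counts
    rows, cols = np.nonzero(counts.to_numpy())
    data = [
        [int(j), int(i), int(counts.iat[i, j])] for i, j in zip(rows, cols)
    ]  # BIOM convention: observation (ASV) major
    doc = {
        "id": "concreta-table",
        "format": "minimal-biom-json",
        "type": "OTU table",
        "matrix_type": "sparse",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a} for a in table.asv_ids],
        "columns": [{"id": s} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_biom_json(path, metadata=None) -> AsvTable:
    with open(path) as fh:
        doc = json.load(fh)
    asv_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_asv, n_samp = doc["shape"]
    if len(asv_ids) != n_asv or len(sample_ids) != n_samp:
        raise FormatError(f"BIOM shape {doc['shape']} does not match id lists")
    mat = np.zeros((n_samp, n_asv), dtype=np.int64)
    for i, j, v in doc["data"]:
        if v != int(v):
            raise FormatError(f"non-integer count for ASV {asv_ids[i]!r}")
        mat[j, i] = int(v)
    counts = pd.DataFrame(mat, index=sample_ids, columns=asv_ids)
    return AsvTable(counts, metadata)


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fasta(path) -> list[AsvRecord]:
    records = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(AsvRecord(name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records.append(AsvRecord(name, "".join(chunks)))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate FASTA ids: {dup}")
    return records


# ---------------------------------------------------------------------------
# hygiene filters
# ---------------------------------------------------------------------------


def _records_by_id(records, table: AsvTable) -> dict[str, AsvRecord]:
    by_id = {r.id: r for r in records}
    for asv in table.asv_ids:
        if asv not in by_id:
            raise FormatError(f"no sequence record for table ASV {asv!r}")
    return by_id


def filter_short_asvs(table: AsvTable, records, min_len: int = 400):
    """Drop ASVs with unexpectedly short sequences (strictly < ``min_len``).

    Returns the filtered table and the list of dropped ASV ids, in input
    order.
    """
    by_id = _records_by_id(records, table)
    dropped = [a for a in table.asv_ids if by_id[a].length < min_len]
    return table.drop_asvs(dropped), dropped


def merge_length_variants(table: AsvTable, records):
    """Merge ASVs identical over their overlap but differing in length.

    Defined as exact-substring containment: an ASV whose sequence is a
    substring of another's is absorbed into it (counts summed; the
    longest sequence is kept as representative). Chains are resolved
    transitively into the longest container. Returns (table, merge_map)
    where merge_map maps each absorbed id to its surviving id.
    """
    by_id = _records_by_id(records, table)
    asvs = table.asv_ids
    # order by descending length so containers are visited first
    order = sorted(asvs, key=lambda a: (-by_id[a].length, a))
    target: dict[str, str] = {}
    for i, short in enumerate(asvs):
        seq = by_id[short].sequence
        best = None
        for cand in order:
            if cand == short:
                continue
            cseq = by_id[cand].sequence
            if len(cseq) <= len(seq):
                break  # remaining candidates are no longer than us
            if seq in cseq:
                best = cand
                break  # longest container, ties by id
        if best is not None:
            target[short] = best
    # transitive closure: follow chains to the final survivor
    def resolve(a):
        while a in target:
            a = target[a]
        return a

    merge_map = {a: resolve(a) for a in target}
    if not merge_map:
        return table, {}
    counts = table.counts.copy()
    for src, dst in merge_map.items():
        counts[dst] = counts[dst] + counts[src]
    keep = [a for a in asvs if a not in merge_map]
    return AsvTable(counts[keep], table.metadata.copy()), merge_map


def default_min_reads(table: AsvTable) -> int:
    """Default low-depth cutoff: 5% of the median library size."""
    return int(np.floor(0.05 * float(table.depths().median())))


def drop_low_depth_samples(table: AsvTable, min_reads: int | None = None):
    """Remove samples whose total reads fall below ``min_reads``.

    ``min_reads=None`` uses :func:`default_min_reads`. Errors if every
    sample would be dropped (downstream stages are undefined).
    """
    if min_reads is None:
        min_reads = default_min_reads(table)
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.depths()
    dropped = [s for s in table.sample_ids if depths[s] < min_reads]
    if len(dropped) == table.n_samples:
        raise ValueError(
            f"min_reads={min_reads} would drop every sample (max depth "
            f"{int(depths.max()) if len(depths) else 0})"
        )
    keep = [s for s in table.sample_ids if s not in set(dropped)]
    return table.select_samples(keep), dropped
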