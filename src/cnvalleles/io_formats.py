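"""File formats: base-count TSV, allele FASTA, samtools-mpileup text, and the
variable-site selection filters applied before model fitting."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inference import BASE_INDEX, BASES, N_BASES, BaseCountTensor
from .simulate import AlleleSet

_COUNT_COLUMNS = ["sample", "site", *BASES]


def write_counts_tsv(counts: BaseCountTensor, path: str | Path) -> None:
    """One row per (sample, site) with A/C/G/T columns."""
    rows = []
    for n, sid in enumerate(counts.sample_ids):
        for x, pos in enumerate(counts.site_positions):
            rows.append([sid, pos, *counts.counts[n, x].tolist()])
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> BaseCountTensor:
    """Read the count TSV; missing (sample, site) pairs become zeros.

    Sample and site ordering follow first appearance in the file (sites are
    typically already in ascending position).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed counts TSV {path}: {exc}") from exc
    if list(df.columns) != _COUNT_COLUMNS:
        raise ValueError(
            f"counts TSV must have columns {_COUNT_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("site", *BASES):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(f"malformed {col!r} value at line {line}")
        df[col] = vals.astype(np.int64)
    neg = (df[list(BASES)] < 0).any(axis=1)
    if neg.any():
        raise ValueError(f"negative count at line {int(df.index[neg][0]) + 2}")
    dup = df.duplicated(subset=["sample", "site"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample, site) row at line {int(df.index[dup][0]) + 2}"
        )

    samples = list(dict.fromkeys(df["sample"]))
    sites = list(dict.fromkeys(df["site"]))
    tensor = np.zeros((len(samples), len(sites), N_BASES), dtype=np.int64)
    s_idx = {s: i for i, s in enumerate(samples)}
    x_idx = {p: i for i, p in enumerate(sites)}
    for row in df.itertuples(index=False):
        tensor[s_idx[row.sample], x_idx[row.site]] = [
            getattr(row, b) for b in BASES
        ]
    return BaseCountTensor(tensor, tuple(samples), tuple(sites))


def write_alleles_fasta(alleles: AlleleSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="")
        for seq, label in zip(alleles.sequences, alleles.labels)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alleles_fasta(path: str | Path) -> AlleleSet:
    seqs, labels = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        s = str(record.seq)
        if s != s.upper():
            warnings.warn(f"lowercase bases in record {record.id}; upcasing")
            s = s.upper()
        if any(ch not in BASE_INDEX for ch in s):
            bad = next(ch for ch in s if ch not in BASE_INDEX)
            raise ValueError(f"non-ACGT character {bad!r} in record {record.id}")
        seqs.append(s)
        labels.append(record.id)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return AlleleSet(tuple(seqs), tuple(labels))


@dataclass
class RawSiteCounts:
    """Per-sample, per-position counts of A, C, G, T and deletions."""

    sample_ids: tuple[str, ...]
    positions: tuple[int, ...]       # 1-based, strictly increasing
    ref_bases: tuple[str, ...]
    counts: np.ndarray               # (N, P, 5): A, C, G, T, deletion

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n, p = len(self.sample_ids), len(self.positions)
        if self.counts.shape != (n, p, 5):
            raise ValueError("counts must be (n_samples, n_positions, 5)")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("positions must be strictly increasing")


# mpileup base-column tokens: read-start marker (skip mapping quality char),
# read end, indels (skip the inserted/deleted sequence), deletions, ref match.
_INDEL_RE = re.compile(r"[+-](\d+)")


def _parse_bases_field(field: str, ref: str) -> np.ndarray:
    """Count A/C/G/T/deletion occurrences in one mpileup bases column."""
    out = np.zeros(5, dtype=np.int64)
    ref_i = BASE_INDEX.get(ref.upper())
    i = 0
    while i < len(field):
        ch = field[i]
        if ch == "^":
            i += 2  # caret + mapping-quality character
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(field, i)
            if m is None:
                raise ValueError(f"malformed indel token at column offset {i}")
            length = int(m.group(1))
            i = m.end() + length
            continue
        if ch in ".,":
            if ref_i is None:
                raise ValueError(f"reference-match symbol with non-ACGT ref {ref!r}")
            out[ref_i] += 1
        elif ch.upper() in BASE_INDEX:
            out[BASE_INDEX[ch.upper()]] += 1
        elif ch == "*":
            out[4] += 1
        # 'N'/'n' (ambiguous) and '<'/'>' (reference skips) are ignored
        i += 1
    return out


def parse_pileup(lines, sample_ids: tuple[str, ...] | list) -> RawSiteCounts:
    """Parse samtools-mpileup text into per-sample base/deletion counts.

    Expects the standard layout: chrom, pos, ref, then (depth, bases, quals)
    column triples, one per sample.
    """
    sample_ids = tuple(sample_ids)
    positions: list[int] = []
    refs: list[str] = []
    rows: list[np.ndarray] = []
    expected = 3 + 3 * len(sample_ids)
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != expected:
            raise ValueError(
                f"line {lineno}: expected {expected} columns for "
                f"{len(sample_ids)} samples, got {len(cols)}"
            )
        positions.append(int(cols[1]))
        refs.append(cols[2])
        row = np.zeros((len(sample_ids), 5), dtype=np.int64)
        for s in range(len(sample_ids)):
            row[s] = _parse_bases_field(cols[3 + 3 * s + 1], cols[2])
        rows.append(row)
    if not rows:
        raise ValueError("empty pileup input")
    counts = np.stack(rows, axis=1)  # (N, P, 5)
    return RawSiteCounts(sample_ids, tuple(positions), tuple(refs), counts)


def identify_variable_sites(raw: RawSiteCounts, minor_min: int = 15,
                            del_ratio_max: float = 0.1) -> pd.DataFrame:
    """Select variable sites by minor-base support and deletion content.

    A site passes the minor-base filter if, in at least one sample, the count
    of that sample's second-most-frequent nucleotide is >= ``minor_min``.  The
    deletion ratio is deletions / (deletions + all ACGT bases), pooled over
    samples; sites with ratio >= ``del_ratio_max`` are omitted (boundary
    inclusive).  Returns one row per position with columns ``position``,
    ``passes_minor_filter``, ``deletion_ratio``, ``kept``.
    """
    acgt = raw.counts[:, :, :4]
    dels = raw.counts[:, :, 4]
    # second-largest ACGT count per (sample, position)
    top2 = np.sort(acgt, axis=2)[:, :, -2]
    passes_minor = (top2 >= minor_min).any(axis=0)
    pooled_del = dels.sum(axis=0)
    pooled_total = pooled_del + acgt.sum(axis=(0, 2))
    with np.errstate(invalid="ignore"):
        del_ratio = np.where(pooled_total > 0, pooled_del / np.maximum(pooled_total, 1), 0.0)
    kept = passes_minor & (del_ratio < del_ratio_max)
    return pd.DataFrame({
        "position": raw.positions,
        "passes_minor_filter": passes_minor,
        "deletion_ratio": del_ratio,
        "kept": kept,
    })


def counts_from_sites(raw: RawSiteCounts,
                      sites: pd.DataFrame) -> BaseCountTensor:
    """Base-count tensor restricted to kept variable sites (deletions dropped)."""
    keep = np.flatnonzero(sites["kept"].to_numpy())
    if keep.size == 0:
        raise ValueError("no variable sites passed the filters")
    tensor = raw.counts[:, keep, :4]
    positions = tuple(int(sites["position"].iloc[i]) for i in keep)
    return BaseCountTensor(tensor, raw.sample_ids, positions)
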