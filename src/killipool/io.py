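"""File formats: FASTA, GTF (CDS annotation), and PoPoolation2-style sync counts.

Internal coordinates are 0-based half-open throughout the package; GTF and
sync files are 1-based on disk and converted at the boundary.  Sequences
are held as int8 base codes (0..3 = ACGT, -1 = N/ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simgen import sequence_to_str, str_to_sequence

__all__ = [
    "SyncCounts",
    "read_fasta",
    "write_fasta",
    "read_gtf_cds",
    "write_gtf_cds",
    "read_sync",
    "write_sync",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Read a FASTA file into {name: int8 base-code array}."""
    return {
        rec.id: str_to_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: dict[str, np.ndarray]) -> None:
    records = []
    for name, seq in sequences.items():
        s = sequence_to_str(np.where(np.asarray(seq) < 0, 0, seq))
        # restore N for ambiguous codes
        arr = np.frombuffer(s.encode(), dtype="S1").copy()
        arr[np.asarray(seq) < 0] = b"N"
        records.append(SeqRecord(Seq(arr.tobytes().decode()), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF (CDS features only)
# ---------------------------------------------------------------------------


def read_gtf_cds(path: str | Path) -> pd.DataFrame:
    """Read CDS features from a GTF into a frame with 0-based half-open coords.

    Columns: chrom, start, end, strand, frame, gene_id.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom",
            "source",
            "feature",
            "start1",
            "end1",
            "score",
            "strand",
            "frame",
            "attributes",
        ],
        dtype={"chrom": str},
    )
    df = df[df["feature"] == "CDS"].copy()
    gene_id = df["attributes"].str.extract(r'gene_id "([^"]+)"')[0]
    if gene_id.isna().any():
        bad = df.index[gene_id.isna()][0]
        raise ValueError(f"GTF CDS record without gene_id attribute (line index {bad})")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start1"].to_numpy(dtype=np.int64) - 1,
            "end": df["end1"].to_numpy(dtype=np.int64),
            "strand": df["strand"].to_numpy(),
            "frame": pd.to_numeric(df["frame"], errors="coerce").fillna(0).astype(int).to_numpy(),
            "gene_id": gene_id.to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def write_gtf_cds(path: str | Path, cds: pd.DataFrame, source: str = "killipool") -> None:
    """Write CDS features (0-based half-open in memory) as 1-based closed GTF."""
    with open(path, "w") as fh:
        fh.write("##coordinates: 1-based closed (GTF)\n")
        for row in cds.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tCDS\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t{getattr(row, 'frame', 0)}\t"
                f'gene_id "{row.gene_id}"; transcript_id "{row.gene_id}.t1";\n'
            )


# ---------------------------------------------------------------------------
# sync counts
# ---------------------------------------------------------------------------


@dataclass
class SyncCounts:
    """Per-site pooled allele counts for one or more populations.

    ``counts`` has shape (n_pops, n_sites, 4) with columns A, C, G, T;
    ``positions`` are 0-based; ``ref`` are int8 base codes (-1 = N).
    ``pool_sizes`` are haploid pool sizes per population.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    pool_sizes: list[int]
    pop_names: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int32)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_pops, n_sites, 4)")
        if len(self.pool_sizes) != self.counts.shape[0]:
            raise ValueError("one pool size per population required")

    @property
    def n_pops(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def depth(self, pop: int) -> np.ndarray:
        return self.counts[pop].sum(axis=1)


_BASE_TO_CHAR = np.array(list("ACGT"))


def write_sync(path: str | Path, sync: SyncCounts) -> None:
    """Write counts in the 6-field sync dialect (A:C:G:T:N:del per pool).

    Positions are written 1-based; a header comment records the dialect.
    """
    ref_char = np.where(sync.ref >= 0, _BASE_TO_CHAR[np.clip(sync.ref, 0, 3)], "N")
    cols = {"chrom": sync.chrom, "pos": sync.positions + 1, "ref": ref_char}
    df = pd.DataFrame(cols)
    for p in range(sync.n_pops):
        c = sync.counts[p]
        df[f"pop{p}"] = [f"{a}:{cc}:{g}:{t}:0:0" for a, cc, g, t in c]
    with open(path, "w") as fh:
        fh.write("##sync: chrom, 1-based pos, ref, per-pool A:C:G:T:N:del\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_sync(
    path: str | Path,
    pool_sizes: Sequence[int],
    pop_names: Sequence[str] | None = None,
) -> SyncCounts:
    """Read a sync file (single chromosome) into a :class:`SyncCounts`."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    n_pops = df.shape[1] - 3
    if n_pops < 1:
        raise ValueError("sync file has no population columns")
    if len(pool_sizes) != n_pops:
        raise ValueError(
            f"sync file has {n_pops} populations but {len(pool_sizes)} pool sizes given"
        )
    chroms = df[0].unique()
    if len(chroms) != 1:
        raise ValueError("multi-chromosome sync files are not supported")
    positions = df[1].to_numpy(dtype=np.int64) - 1
    ref = str_to_sequence("".join(df[2].to_numpy()))
    counts = np.zeros((n_pops, len(df), 4), dtype=np.int32)
    for p in range(n_pops):
        parts = df[3 + p].str.split(":", expand=True).to_numpy(dtype=np.int64)
        counts[p] = parts[:, :4]
    names = list(pop_names) if pop_names else [f"pop{p + 1}" for p in range(n_pops)]
    return SyncCounts(
        chrom=str(chroms[0]),
        positions=positions,
        ref=ref,
        counts=counts,
        pool_sizes=list(pool_sizes),
        pop_names=names,
    )
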