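"""Read counting, depth normalization and library-representation QC.

Screens are sequenced with a 19-cycle custom primer that reads exactly the
variable N19 of each guide (the cloned 20th base is the constant G supplied
by the vector flank), so reads are matched to the designed 19-mer by exact
hash lookup. Counts are depth-normalized to a common scale (counts per
million by default).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .guide_design import GuideLibrary, SPACER_LEN

CPM_SCALE = 1_000_000.0


@dataclass
class CountTable:
    """Guide x sample matrix of non-negative integer read counts.

    `counts` is a DataFrame indexed by guide_id with one column per sample;
    `gene_map` maps guide_id -> gene (controls under their pooled label);
    `metadata[sample]` records total and unassigned read numbers so that
    assigned + unassigned = total always holds.
    """

    counts: pd.DataFrame
    gene_map: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_map.index)
        if missing:
            raise ValueError(f"guides without gene assignment: {sorted(missing)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class NormalizedCounts:
    values: pd.DataFrame
    gene_map: pd.Series
    size_factors: pd.Series
    scale: float = CPM_SCALE


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_seqs(source: str | Path | IO[str]) -> Iterator[str]:
    """Sequences from a FASTQ file (optionally gzipped) or open handle."""
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as fh:
            for _, seq, _ in FastqGeneralIterator(fh):
                yield seq
    else:
        for _, seq, _ in FastqGeneralIterator(source):
            yield seq


def count_reads(
    reads: str | Path | IO[str] | Iterable[str],
    library: GuideLibrary,
    sample_name: str,
    table: CountTable | None = None,
) -> CountTable:
    """Count exact 19-nt prefix matches of reads against the library.

    `reads` may be a FASTQ path/handle or any iterable of sequence strings.
    The first 19 nt of each read are looked up in the spacer set; matches
    increment the owning guide, everything else is tallied as unassigned.
    Passing an existing `table` appends the new sample as a column.
    """
    if not library.guides and not library.controls:
        raise ValueError("empty guide library")
    spacer_to_guide: dict[str, str] = {}
    order: list[str] = []
    for g in library.guides:
        spacer_to_guide[g.spacer19] = g.guide_id
        order.append(g.guide_id)
    for c in library.controls:
        spacer_to_guide[c.spacer19] = c.control_id
        order.append(c.control_id)

    if isinstance(reads, (str, Path)) or hasattr(reads, "read"):
        seqs: Iterable[str] = iter_fastq_seqs(reads)  # type: ignore[arg-type]
    else:
        seqs = reads

    counts = dict.fromkeys(order, 0)
    total = unassigned = 0
    for seq in seqs:
        total += 1
        guide = spacer_to_guide.get(seq[:SPACER_LEN])
        if guide is None:
            unassigned += 1
        else:
            counts[guide] += 1

    col = pd.Series(counts, name=sample_name, dtype=np.int64)
    gene_map = pd.Series(library.gene_of()).loc[order]
    if table is None:
        df = col.to_frame()
        meta = {}
    else:
        if sample_name in table.counts.columns:
            raise ValueError(f"sample {sample_name!r} already present")
        df = table.counts.join(col)
        meta = dict(table.metadata)
    meta[sample_name] = {"total_reads": total, "unassigned": unassigned}
    return CountTable(df, gene_map, meta)


def normalize_total(table: CountTable | NormalizedCounts,
                    scale: float = CPM_SCALE) -> NormalizedCounts:
    """Scale each sample to a common total (CPM by default); within-sample
    ratios are preserved exactly. Idempotent: re-normalizing an
    already-normalized table yields size factors of 1. Zero-total samples
    are an error."""
    matrix = table.counts if isinstance(table, CountTable) else table.values
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    size_factors = scale / totals.astype(float)
    values = matrix.astype(float) * size_factors
    return NormalizedCounts(values, table.gene_map, size_factors, scale=scale)


@dataclass(frozen=True)
class ComplexityQC:
    sample: str
    n_guides: int
    fraction_detected: float
    fraction_within_window: float
    fold_window: float
    reference_count: float
    gini: float
    ranked_abundance: pd.DataFrame


def gini_coefficient(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector (0 = perfectly even)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    total = x.sum()
    if n == 0 or total == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / total).sum()) / n)


def library_complexity_stats(
    table: CountTable,
    sample: str,
    *,
    fold_window: float = 100.0,
    reference_percentile: float = 99.9,
) -> ComplexityQC:
    """Representation QC for one sample.

    The headline statistic is the fraction of guides whose counts fall
    within `fold_window` of a high-abundance reference count C (the
    `reference_percentile` of the count distribution), i.e. in
    [C / fold_window, C]. Zero-count guides can never be inside the
    window. Also reports detected fraction, Gini coefficient, and a
    ranked-abundance table for plotting.
    """
    if sample not in table.counts.columns:
        raise KeyError(f"sample {sample!r} not in table")
    counts = table.counts[sample].to_numpy(dtype=float)
    n = len(counts)
    ref = float(np.percentile(counts, reference_percentile))
    lo = ref / fold_window
    within = float(np.mean((counts >= lo) & (counts <= ref) & (counts > 0))) if n else 0.0
    ranked = pd.DataFrame({
        "rank": np.arange(1, n + 1),
        "count": np.sort(counts)[::-1],
    })
    return ComplexityQC(
        sample=sample,
        n_guides=n,
        fraction_detected=float(np.mean(counts > 0)) if n else 0.0,
        fraction_within_window=within,
        fold_window=fold_window,
        reference_count=ref,
        gini=gini_coefficient(counts),
        ranked_abundance=ranked,
    )


# ---------------------------------------------------------------------------
# Count-table I/O (sgRNA, gene, sample columns)
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "gene", table.gene_map.loc[df.index])
    df.index.name = "sgRNA"
    df.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> CountTable:
    """Read a guide count TSV whose first two columns identify the guide
    and its gene, followed by one integer column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected sgRNA, gene and >=1 sample column")
    guide_col, gene_col = df.columns[:2]
    df = df.set_index(guide_col)
    gene_map = df[gene_col]
    counts = df.drop(columns=[gene_col])
    counts = counts.round().astype(np.int64)
    return CountTable(counts, gene_map)
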