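"""Transcription start site selection and promoter-window extraction.

CRISPRa guides only work within a narrow window upstream of the TSS, so the
choice of TSS per gene matters more than in most annotation tasks. This
module implements a three-tier evidence hierarchy:

1. CAGE tag clusters (empirical TSS evidence): the two broadest peaks per
   gene are kept, for sensitivity to alternative transcripts; the peak
   summit anchors the TSS.
2. Transcripts flagged as principal isoforms (APPRIS-style annotation).
3. Any curated transcript model (RefSeq NM accessions).

Tiers never mix within a gene: a gene with CAGE evidence uses only CAGE.

From each selected TSS a promoter window covering 450-50 bp upstream is
extracted. Read as an inclusive coordinate range this is 401 nt; the span
is configurable. Internally coordinates are 0-based half-open (BED
convention); serialized tables are 1-based inclusive with an explicit
strand column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyfaidx import Fasta

from .sequence import validate_dna

logger = logging.getLogger(__name__)

TIER_CAGE = "cage"
TIER_PRINCIPAL = "principal"
TIER_REFSEQ_NM = "refseq_nm"
_TIERS = (TIER_CAGE, TIER_PRINCIPAL, TIER_REFSEQ_NM)


@dataclass
class GenomeSequence:
    """In-memory genome: contig name -> uppercase ACGTN string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            validate_dna(seq, allow_n=True, context=f"contig {name!r}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = Fasta(str(path), sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript's TSS with its evidence tier."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    tss_position: int  # 1-based
    tier: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.tss_position < 1:
            raise ValueError("tss_position is 1-based and must be >= 1")
        if self.tier not in (TIER_PRINCIPAL, TIER_REFSEQ_NM, TIER_CAGE):
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class CagePeak:
    """A CAGE tag cluster; 0-based half-open interval, 1-based summit."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    summit: int | None = None  # 1-based; None -> midpoint used
    tag_count: float = 0.0
    peak_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"peak {self.peak_id or self.gene_id}: start >= end")
        if self.summit is not None and not (self.start < self.summit <= self.end):
            raise ValueError(
                f"peak {self.peak_id or self.gene_id}: summit {self.summit} "
                f"outside interval ({self.start}, {self.end}]"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def tss_position(self) -> int:
        """TSS anchor: the summit, else the interval midpoint (1-based)."""
        if self.summit is not None:
            return self.summit
        return self.start + (self.end - self.start + 1) // 2


@dataclass(frozen=True)
class TssSelection:
    gene_id: str
    tss_id: str
    contig: str
    strand: str
    tss_position: int  # 1-based
    tier: str
    provenance: str

    def __post_init__(self) -> None:
        if self.tier not in _TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class PromoterWindow:
    """Plus-strand genomic interval (0-based half-open) with its sequence."""

    gene_id: str
    tss_id: str
    contig: str
    strand: str
    start: int
    end: int
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval")


def select_tss(
    genes: Sequence[str],
    cage_peaks: Iterable[CagePeak] = (),
    transcripts: Iterable[TranscriptRecord] = (),
    *,
    max_cage_peaks: int = 2,
    max_fallback_tss: int | None = None,
) -> list[TssSelection]:
    """Pick TSSs per gene by the CAGE > principal > NM hierarchy.

    With CAGE evidence, the `max_cage_peaks` broadest peaks are kept (ties
    broken by higher tag count, then by the 5'-most position on the gene
    strand). Fallback tiers keep all distinct TSS positions unless
    `max_fallback_tss` caps them (most-5' first). Genes without any source
    yield no selection and log a warning.
    """
    gene_set = set(genes)
    peaks_by_gene: dict[str, list[CagePeak]] = {}
    for pk in cage_peaks:
        if pk.gene_id not in gene_set:
            raise ValueError(f"CAGE peak references unknown gene {pk.gene_id!r}")
        peaks_by_gene.setdefault(pk.gene_id, []).append(pk)
    tx_by_gene: dict[str, list[TranscriptRecord]] = {}
    for tx in transcripts:
        if tx.gene_id not in gene_set:
            raise ValueError(f"transcript references unknown gene {tx.gene_id!r}")
        tx_by_gene.setdefault(tx.gene_id, []).append(tx)

    selections: list[TssSelection] = []
    for gene in genes:
        picked = _select_for_gene(
            gene,
            peaks_by_gene.get(gene, []),
            tx_by_gene.get(gene, []),
            max_cage_peaks,
            max_fallback_tss,
        )
        if not picked:
            logger.warning("gene %s: no TSS source (CAGE/principal/NM); skipped", gene)
        seen_ids = set()
        for sel in picked:
            if sel.tss_id in seen_ids:
                raise ValueError(f"duplicate tss_id {sel.tss_id!r} for gene {gene}")
            seen_ids.add(sel.tss_id)
        selections.extend(picked)
    return selections


def _select_for_gene(
    gene: str,
    peaks: list[CagePeak],
    txs: list[TranscriptRecord],
    max_cage_peaks: int,
    max_fallback_tss: int | None,
) -> list[TssSelection]:
    if peaks:
        # Broadest first; ties -> higher tag_count, then 5'-most on gene strand.
        def key(pk: CagePeak):
            five_prime = pk.start if pk.strand == "+" else -pk.end
            return (-pk.width, -pk.tag_count, five_prime)

        chosen = sorted(peaks, key=key)[:max_cage_peaks]
        return [
            TssSelection(
                gene_id=gene,
                tss_id=f"{gene}_tss{i + 1}",
                contig=pk.contig,
                strand=pk.strand,
                tss_position=pk.tss_position,
                tier=TIER_CAGE,
                provenance=pk.peak_id or f"cage:{pk.contig}:{pk.start}-{pk.end}",
            )
            for i, pk in enumerate(chosen)
        ]

    for tier in (TIER_PRINCIPAL, TIER_REFSEQ_NM):
        tier_txs = [t for t in txs if t.tier == tier]
        if not tier_txs:
            continue
        # Deduplicate identical TSS positions; keep deterministic order.
        by_pos: dict[tuple[str, str, int], TranscriptRecord] = {}
        for t in sorted(tier_txs, key=lambda t: t.transcript_id):
            by_pos.setdefault((t.contig, t.strand, t.tss_position), t)
        records = sorted(
            by_pos.values(),
            key=lambda t: (t.contig, t.tss_position if t.strand == "+" else -t.tss_position),
        )
        if max_fallback_tss is not None:
            records = records[:max_fallback_tss]
        return [
            TssSelection(
                gene_id=gene,
                tss_id=f"{gene}_tss{i + 1}",
                contig=t.contig,
                strand=t.strand,
                tss_position=t.tss_position,
                tier=tier,
                provenance=t.transcript_id,
            )
            for i, t in enumerate(records)
        ]
    return []


def extract_promoter_window(
    sel: TssSelection,
    genome: GenomeSequence,
    *,
    upstream_far: int = 450,
    upstream_near: int = 50,
) -> PromoterWindow:
    """Extract the promoter window `upstream_far`..`upstream_near` bp
    upstream of the TSS (inclusive range; 401 nt at the defaults).

    For a plus-strand TSS at 1-based position t the window covers 1-based
    positions [t-450, t-50]; on the minus strand, [t+50, t+450]. Windows
    running off a contig end are clipped and flagged `truncated`; a window
    entirely off-contig is an error. The stored sequence is always the
    plus-strand substring.
    """
    if sel.contig not in genome:
        raise KeyError(f"contig {sel.contig!r} not in genome")
    if upstream_far <= upstream_near:
        raise ValueError("upstream_far must exceed upstream_near")
    clen = genome.length(sel.contig)
    t = sel.tss_position
    if sel.strand == "+":
        lo1, hi1 = t - upstream_far, t - upstream_near
    else:
        lo1, hi1 = t + upstream_near, t + upstream_far
    # to 0-based half-open, then clip
    start, end = lo1 - 1, hi1
    cstart, cend = max(start, 0), min(end, clen)
    if cstart >= cend:
        raise ValueError(
            f"promoter window for {sel.gene_id}/{sel.tss_id} lies entirely "
            f"outside contig {sel.contig} (len {clen})"
        )
    truncated = (cstart, cend) != (start, end)
    seq = genome.contigs[sel.contig][cstart:cend]
    return PromoterWindow(
        gene_id=sel.gene_id,
        tss_id=sel.tss_id,
        contig=sel.contig,
        strand=sel.strand,
        start=cstart,
        end=cend,
        sequence=seq,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def read_cage_bed(path: str | Path) -> list[CagePeak]:
    """CAGE clusters from BED: chrom, start, end, name(=gene id), score
    (=tag count), strand; an optional 7th column (thickStart, 0-based) is
    taken as the summit."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: line {i + 1}: BED6 requires 6 columns")
            summit = int(f[6]) + 1 if len(f) > 6 and f[6] not in (".", "") else None
            peaks.append(
                CagePeak(
                    gene_id=f[3],
                    contig=f[0],
                    strand=f[5],
                    start=int(f[1]),
                    end=int(f[2]),
                    summit=summit,
                    tag_count=float(f[4]),
                    peak_id=f"{f[3]}@{f[0]}:{f[1]}-{f[2]}",
                )
            )
    return peaks


def read_transcripts_gtf(
    path: str | Path, *, tier_attribute: str = "tier"
) -> list[TranscriptRecord]:
    """Transcript TSSs from GTF `transcript` features.

    The evidence tier is read from the attribute named `tier_attribute`
    ("principal" / "refseq_nm"); features without it are skipped. The TSS is
    the feature start on + and the feature end on -.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = _parse_gtf_attributes(f[8])
            tier = attrs.get(tier_attribute)
            if tier is None:
                continue
            strand = f[6]
            tss = int(f[3]) if strand == "+" else int(f[4])
            records.append(
                TranscriptRecord(
                    gene_id=attrs.get("gene_id", ""),
                    transcript_id=attrs.get("transcript_id", ""),
                    contig=f[0],
                    strand=strand,
                    tss_position=tss,
                    tier=tier,
                )
            )
    return records


def read_transcripts_tsv(path: str | Path) -> list[TranscriptRecord]:
    """6-column TSV dialect: gene_id, transcript_id, contig, strand,
    tss_position (1-based), tier. Header line optional."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if i == 0 and f[0] == "gene_id":
                continue
            if len(f) < 6:
                raise ValueError(f"{path}: line {i + 1}: expected 6 columns")
            records.append(
                TranscriptRecord(f[0], f[1], f[2], f[3], int(f[4]), f[5])
            )
    return records


def _parse_gtf_attributes(text: str) -> Mapping[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def write_tss_table(selections: Iterable[TssSelection], path: str | Path) -> None:
    """Serialize selections as TSV with 1-based TSS coordinates."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttss_id\tcontig\tstrand\ttss_position\ttier\tprovenance\n")
        for s in selections:
            fh.write(
                f"{s.gene_id}\t{s.tss_id}\t{s.contig}\t{s.strand}\t"
                f"{s.tss_position}\t{s.tier}\t{s.provenance}\n"
            )


def read_tss_table(path: str | Path) -> list[TssSelection]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: missing TSS table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(TssSelection(f[0], f[1], f[2], f[3], int(f[4]), f[5], f[6]))
    return out
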