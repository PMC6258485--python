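"""Guide enumeration, filtering, ranking, off-target screening and selection.

The design procedure, per promoter window:

1. Enumerate every 19-nt protospacer 5' of an NGG PAM on either strand.
2. Discard guides with GC content outside 30-75%, a polyT stretch (a run of
   more than three T), or a BbsI recognition site on either strand (BbsI is
   the Golden-Gate cloning enzyme; an internal site would cut the insert).
3. Rank survivors by proximity of the protospacer midpoint to the TSS.
4. Remove guides whose 19-mer occurs exactly (either orientation) in the
   promoter window of a different gene, unless the genes belong to a shared
   promoter group or declared family.
5. Select up to seven guides per TSS in rank order; if fewer than seven
   survive, the GC rule and then the polyT rule are relaxed so that every
   target retains at least two guides where possible. BbsI and off-target
   rules are never relaxed.
6. Prepend a 5' G to the spacer for efficient U6 transcription (the cloned
   spacer is 20 nt regardless of the genomic base).

Non-targeting controls are drawn from a user pool and accepted only if no
genomic 19-mer on either strand lies within Hamming distance 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation_tss import GenomeSequence, PromoterWindow
from .sequence import (
    BBSI_FWD,
    BBSI_REV,
    gc_fraction,
    revcomp,
    validate_dna,
)

logger = logging.getLogger(__name__)

SPACER_LEN = 19
SITE_LEN = SPACER_LEN + 3  # spacer + PAM

FLAG_GC_LOW = "gc_low"
FLAG_GC_HIGH = "gc_high"
FLAG_POLYT = "polyT"
FLAG_BBSI = "bbsi"
FLAG_OFFTARGET = "offtarget"
RELAX_GC = "gc_relaxed"
RELAX_POLYT = "polyT_relaxed"


@dataclass
class GuideCandidate:
    gene_id: str
    tss_id: str
    spacer19: str
    strand_of_genome: str  # strand carrying the protospacer
    contig: str
    protospacer_start: int  # 0-based half-open genomic interval
    protospacer_end: int
    pam: str
    gc_fraction: float
    flags: frozenset = frozenset()
    relaxations: frozenset = frozenset()
    distance_to_tss: float | None = None
    rank: int | None = None
    offtarget_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.spacer19) != SPACER_LEN:
            raise ValueError(f"spacer must be {SPACER_LEN} nt, got {self.spacer19!r}")
        validate_dna(self.spacer19, context="spacer19")
        if self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def midpoint(self) -> float:
        """Center of the protospacer's half-open genomic interval."""
        return (self.protospacer_start + self.protospacer_end) / 2

    @property
    def guide_id(self) -> str:
        return f"{self.tss_id}:{self.contig}:{self.protospacer_start}:{self.strand_of_genome}"


@dataclass(frozen=True)
class NontargetingControl:
    control_id: str
    spacer19: str
    min_genome_mismatches: int

    def __post_init__(self) -> None:
        if len(self.spacer19) != SPACER_LEN:
            raise ValueError("control spacer must be 19 nt")
        if self.min_genome_mismatches < 3:
            raise ValueError("control must be >= 3 mismatches from any genomic site")


@dataclass
class GeneDesignSummary:
    gene_id: str
    tss_id: str
    n_selected: int
    relaxation_used: str  # "", "gc", or "gc+polyT"
    warning: str = ""


@dataclass
class GuideLibrary:
    guides: list[GuideCandidate]
    controls: list[NontargetingControl]
    design_config: dict
    summaries: list[GeneDesignSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides] + [c.control_id for c in self.controls]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate guide ids in library")

    @property
    def spacer_set(self) -> set[str]:
        return {g.spacer19 for g in self.guides} | {c.spacer19 for c in self.controls}

    def gene_of(self) -> dict[str, str]:
        """guide_id -> gene map; controls map to the reserved CONTROL gene."""
        m = {g.guide_id: g.gene_id for g in self.guides}
        m.update({c.control_id: CONTROL_GENE for c in self.controls})
        return m


#: Gene label under which non-targeting controls are pooled in count tables.
CONTROL_GENE = "NonTargeting"


# ---------------------------------------------------------------------------
# Enumeration and filtering
# ---------------------------------------------------------------------------

def enumerate_protospacers(window: PromoterWindow) -> list[GuideCandidate]:
    """All 19-nt spacers immediately 5' of an NGG PAM, both strands.

    Minus-strand sites are found as CCN on the plus-strand sequence with the
    19-mer 3' of it; spacers are reported in protospacer-strand orientation.
    Spacers containing N are dropped. Windows shorter than 22 nt yield an
    empty list with a warning.
    """
    seq = window.sequence
    if len(seq) < SITE_LEN:
        logger.warning(
            "window %s/%s is %d nt (< %d); no guides possible",
            window.gene_id, window.tss_id, len(seq), SITE_LEN,
        )
        return []
    out: list[GuideCandidate] = []
    for i in range(len(seq) - SITE_LEN + 1):
        # plus strand: [spacer19][N G G]
        if seq[i + SPACER_LEN + 1] == "G" and seq[i + SPACER_LEN + 2] == "G":
            spacer = seq[i : i + SPACER_LEN]
            if "N" not in spacer:
                out.append(_make_candidate(window, spacer, seq[i + SPACER_LEN : i + SITE_LEN], "+", i))
        # minus strand: plus-strand pattern [C C N][revcomp(spacer19)]
        if seq[i] == "C" and seq[i + 1] == "C":
            spacer = revcomp(seq[i + 3 : i + SITE_LEN])
            if "N" not in spacer:
                out.append(_make_candidate(window, spacer, revcomp(seq[i : i + 3]), "-", i))
    return out


def _make_candidate(
    window: PromoterWindow, spacer: str, pam: str, strand: str, offset: int
) -> GuideCandidate:
    if strand == "+":
        start = window.start + offset
    else:
        start = window.start + offset + 3
    return GuideCandidate(
        gene_id=window.gene_id,
        tss_id=window.tss_id,
        spacer19=spacer,
        strand_of_genome=strand,
        contig=window.contig,
        protospacer_start=start,
        protospacer_end=start + SPACER_LEN,
        pam=pam,
        gc_fraction=gc_fraction(spacer),
    )


def sequence_filter_flags(spacer: str, *, gc_min: float = 0.30, gc_max: float = 0.75,
                          max_t_run: int = 3) -> frozenset:
    """Filter failures for one spacer, independent of relaxation."""
    flags = set()
    gc = gc_fraction(spacer)
    if gc < gc_min:
        flags.add(FLAG_GC_LOW)
    elif gc > gc_max:
        flags.add(FLAG_GC_HIGH)
    if "T" * (max_t_run + 1) in spacer:
        flags.add(FLAG_POLYT)
    # internal site, or a 5' prefix that completes a site against the
    # constant CACCG cloning flank (unclonable by Golden Gate either way)
    if (BBSI_FWD in spacer or BBSI_REV in spacer
            or spacer.startswith(("AAGAC", "TCTTC"))):
        flags.add(FLAG_BBSI)
    return frozenset(flags)


def apply_sequence_filters(
    candidates: Iterable[GuideCandidate],
    *,
    gc_min: float = 0.30,
    gc_max: float = 0.75,
    max_t_run: int = 3,
    relaxations: frozenset | set = frozenset(),
) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Split candidates into (kept, rejected) under the sequence rules.

    `relaxations` may waive the GC rule (RELAX_GC) and/or the polyT rule
    (RELAX_POLYT); the BbsI rule is never waived. Rejected candidates carry
    all applicable failure flags; kept candidates that survived only thanks
    to a relaxation carry the corresponding relaxation marker.
    """
    bad = set(relaxations) - {RELAX_GC, RELAX_POLYT}
    if bad:
        raise ValueError(f"unknown relaxations: {sorted(bad)}")
    kept, rejected = [], []
    for c in candidates:
        flags = sequence_filter_flags(c.spacer19, gc_min=gc_min, gc_max=gc_max,
                                      max_t_run=max_t_run)
        c = replace(c, flags=flags)
        blocking = set()
        used = set()
        for f in flags:
            if f in (FLAG_GC_LOW, FLAG_GC_HIGH):
                if RELAX_GC in relaxations:
                    used.add(RELAX_GC)
                else:
                    blocking.add(f)
            elif f == FLAG_POLYT:
                if RELAX_POLYT in relaxations:
                    used.add(RELAX_POLYT)
                else:
                    blocking.add(f)
            else:  # BbsI: unconditional
                blocking.add(f)
        if blocking:
            rejected.append(c)
        else:
            kept.append(replace(c, relaxations=frozenset(used)))
    return kept, rejected


def rank_by_tss_proximity(
    candidates: Sequence[GuideCandidate], tss_position: int
) -> list[GuideCandidate]:
    """Rank by |protospacer midpoint - TSS|, ascending; ties broken by plus
    strand first, then lexicographic spacer. Returns new ranked candidates."""
    def key(c: GuideCandidate):
        return (abs(c.midpoint - tss_position), 0 if c.strand_of_genome == "+" else 1,
                c.spacer19)

    ranked = sorted(candidates, key=key)
    return [
        replace(c, distance_to_tss=abs(c.midpoint - tss_position), rank=i + 1)
        for i, c in enumerate(ranked)
    ]


# ---------------------------------------------------------------------------
# Off-target screening over promoter windows
# ---------------------------------------------------------------------------

def derive_shared_groups(
    windows: Sequence[PromoterWindow],
    declared_families: Sequence[Iterable[str]] = (),
) -> list[frozenset]:
    """Union of user-declared families and automatic groups of genes whose
    promoter windows overlap genomically (>= 1 bp). Groups are merged
    transitively (union-find)."""
    genes = sorted({w.gene_id for w in windows})
    gene_index = {g: i for i, g in enumerate(genes)}
    parent = list(range(len(genes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for fam in declared_families:
        fam = list(fam)
        for g in fam:
            if g not in gene_index:
                raise ValueError(f"shared group names unknown gene {g!r}")
        for g in fam[1:]:
            union(gene_index[fam[0]], gene_index[g])

    by_contig: dict[str, list[PromoterWindow]] = {}
    for w in windows:
        by_contig.setdefault(w.contig, []).append(w)
    for ws in by_contig.values():
        ws.sort(key=lambda w: w.start)
        for i, a in enumerate(ws):
            for b in ws[i + 1 :]:
                if b.start >= a.end:
                    break
                if a.gene_id != b.gene_id:
                    union(gene_index[a.gene_id], gene_index[b.gene_id])

    groups: dict[int, set[str]] = {}
    for g, i in gene_index.items():
        groups.setdefault(find(i), set()).add(g)
    return [frozenset(s) for s in groups.values() if len(s) > 1]


class PromoterMatchIndex:
    """Exact-match index of every 19-mer (both orientations) in a set of
    promoter windows, mapping k-mer -> genes whose windows contain it."""

    def __init__(self, windows: Sequence[PromoterWindow]):
        self._hits: dict[str, set[str]] = {}
        for w in windows:
            seq = w.sequence
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - SPACER_LEN + 1):
                    kmer = s[i : i + SPACER_LEN]
                    if "N" not in kmer:
                        self._hits.setdefault(kmer, set()).add(w.gene_id)

    def genes_with(self, spacer: str) -> set[str]:
        return set(self._hits.get(spacer, ()))


def offtarget_filter(
    candidates: Iterable[GuideCandidate],
    all_windows: Sequence[PromoterWindow] | PromoterMatchIndex,
    shared_groups: Sequence[Iterable[str]] = (),
) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Remove candidates whose spacer occurs exactly in a foreign gene's
    promoter window, unless all hit genes share a declared/derived group
    with the candidate's gene. Kept multi-hit guides record the foreign
    genes in `offtarget_genes`."""
    index = (
        all_windows
        if isinstance(all_windows, PromoterMatchIndex)
        else PromoterMatchIndex(all_windows)
    )
    groups = [frozenset(g) for g in shared_groups]
    kept, removed = [], []
    for c in candidates:
        foreign = index.genes_with(c.spacer19) - {c.gene_id}
        if not foreign:
            kept.append(c)
            continue
        hit_set = foreign | {c.gene_id}
        if any(hit_set <= grp for grp in groups):
            kept.append(replace(c, offtarget_genes=frozenset(foreign)))
        else:
            removed.append(replace(c, flags=c.flags | {FLAG_OFFTARGET},
                                   offtarget_genes=frozenset(foreign)))
    return kept, removed


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_guides_for_target(
    strict_pool: Sequence[GuideCandidate],
    gc_relaxed_pool: Sequence[GuideCandidate] = (),
    polyt_relaxed_pool: Sequence[GuideCandidate] = (),
    *,
    quota: int = 7,
    min_guides: int = 2,
    gene_id: str = "",
    tss_id: str = "",
) -> tuple[list[GuideCandidate], GeneDesignSummary | None]:
    """Take top-ranked strict candidates up to `quota`; top up from the
    GC-relaxed, then polyT-relaxed pools in rank order. Returns the
    selection (re-ranked 1..n) and a warning summary when fewer than
    `min_guides` could be found (None when the target is healthy)."""
    selection: list[GuideCandidate] = []
    relax_used = ""
    for pool, tag in ((strict_pool, ""), (gc_relaxed_pool, "gc"),
                      (polyt_relaxed_pool, "gc+polyT")):
        for c in sorted(pool, key=lambda c: c.rank if c.rank is not None else 1 << 30):
            if len(selection) >= quota:
                break
            selection.append(c)
            if tag:
                relax_used = tag
    selection = [replace(c, rank=i + 1) for i, c in enumerate(selection)]
    summary = None
    if len(selection) < min_guides:
        first = next(iter(selection), None) or next(
            (p[0] for p in (strict_pool, gc_relaxed_pool, polyt_relaxed_pool) if p), None)
        gene = gene_id or (first.gene_id if first else "?")
        tss = tss_id or (first.tss_id if first else "?")
        summary = GeneDesignSummary(
            gene_id=gene, tss_id=tss, n_selected=len(selection),
            relaxation_used=relax_used,
            warning=f"only {len(selection)} guides available (min {min_guides})",
        )
        logger.warning("%s/%s: %s", gene, tss, summary.warning)
    return selection, summary


def finalize_cloned_spacer(candidate: GuideCandidate | str) -> str:
    """20-nt cloned spacer: unconditional 5' G + the 19-nt spacer."""
    spacer = candidate if isinstance(candidate, str) else candidate.spacer19
    return "G" + spacer


# ---------------------------------------------------------------------------
# Non-targeting controls
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def min_hamming_to_genome(spacer: str, genome: GenomeSequence) -> int:
    """Minimum Hamming distance between `spacer` and any 19-mer window of
    the genome, both strands. Exhaustive vectorized scan."""
    best = SPACER_LEN
    queries = (_encode(spacer), _encode(revcomp(spacer)))
    for seq in genome.contigs.values():
        arr = _encode(seq)
        n_win = len(arr) - SPACER_LEN + 1
        if n_win <= 0:
            continue
        for q in queries:
            mism = np.zeros(n_win, dtype=np.int16)
            for j in range(SPACER_LEN):
                mism += arr[j : j + n_win] != q[j]
            best = min(best, int(mism.min()))
            if best == 0:
                return 0
    return best


def select_nontargeting_controls(
    pool: Sequence[str],
    genome: GenomeSequence,
    *,
    n: int = 500,
    max_mismatch: int = 2,
    id_prefix: str = "NTC",
) -> list[NontargetingControl]:
    """First `n` pool spacers with no genomic site within `max_mismatch`
    mismatches on either strand. Raises if the pool runs out."""
    controls = []
    for spacer in pool:
        validate_dna(spacer, context="control spacer")
        d = min_hamming_to_genome(spacer, genome)
        if d > max_mismatch:
            controls.append(
                NontargetingControl(f"{id_prefix}{len(controls) + 1:04d}", spacer, d)
            )
            if len(controls) == n:
                return controls
    raise ValueError(
        f"control pool exhausted: {len(controls)} of {n} requested spacers accepted"
    )


def random_spacer_pool(n: int, seed: int) -> list[str]:
    """Seeded random 19-mer pool passing the sequence filters, for use as a
    control source against synthetic genomes."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pool = []
    while len(pool) < n:
        spacer = "".join(bases[rng.integers(0, 4, SPACER_LEN)])
        if not sequence_filter_flags(spacer):
            pool.append(spacer)
    return pool


# ---------------------------------------------------------------------------
# Library assembly and serialization
# ---------------------------------------------------------------------------

def design_library(
    windows: Sequence[PromoterWindow],
    tss_positions: dict[str, int],
    *,
    declared_families: Sequence[Iterable[str]] = (),
    quota: int = 7,
    min_guides: int = 2,
    gc_min: float = 0.30,
    gc_max: float = 0.75,
    max_t_run: int = 3,
    control_pool: Sequence[str] = (),
    genome: GenomeSequence | None = None,
    n_controls: int = 0,
    config_extra: dict | None = None,
) -> GuideLibrary:
    """Run the full design pipeline over a set of promoter windows.

    `tss_positions` maps tss_id -> 1-based TSS coordinate used for
    proximity ranking. Guides from the (up to two) windows of one gene are
    deduplicated on spacer sequence, best rank kept.
    """
    groups = derive_shared_groups(windows, declared_families)
    index = PromoterMatchIndex(windows)
    fkw = dict(gc_min=gc_min, gc_max=gc_max, max_t_run=max_t_run)

    selected: list[GuideCandidate] = []
    summaries: list[GeneDesignSummary] = []
    seen_per_gene: dict[str, set[str]] = {}
    for w in windows:
        cands = enumerate_protospacers(w)
        clean, _ = offtarget_filter(cands, index, groups)
        strict, _ = apply_sequence_filters(clean, **fkw)
        gc_pool_all, _ = apply_sequence_filters(clean, relaxations={RELAX_GC}, **fkw)
        both_all, _ = apply_sequence_filters(
            clean, relaxations={RELAX_GC, RELAX_POLYT}, **fkw)
        strict_sp = {c.spacer19 for c in strict}
        gc_pool = [c for c in gc_pool_all if c.spacer19 not in strict_sp]
        gc_sp = strict_sp | {c.spacer19 for c in gc_pool}
        polyt_pool = [c for c in both_all if c.spacer19 not in gc_sp]

        tss = tss_positions[w.tss_id]
        sel, summary = select_guides_for_target(
            rank_by_tss_proximity(strict, tss),
            rank_by_tss_proximity(gc_pool, tss),
            rank_by_tss_proximity(polyt_pool, tss),
            quota=quota, min_guides=min_guides,
            gene_id=w.gene_id, tss_id=w.tss_id,
        )
        seen = seen_per_gene.setdefault(w.gene_id, set())
        for c in sel:
            if c.spacer19 not in seen:
                seen.add(c.spacer19)
                selected.append(c)
        if summary is not None:
            summaries.append(summary)
        else:
            relax = "gc+polyT" if any(RELAX_POLYT in c.relaxations for c in sel) else (
                "gc" if any(RELAX_GC in c.relaxations for c in sel) else "")
            summaries.append(GeneDesignSummary(w.gene_id, w.tss_id, len(sel), relax))

    controls: list[NontargetingControl] = []
    if n_controls:
        if genome is None:
            raise ValueError("a genome is required to vet non-targeting controls")
        controls = select_nontargeting_controls(
            control_pool, genome, n=n_controls)

    config = dict(quota=quota, min_guides=min_guides, gc_min=gc_min, gc_max=gc_max,
                  max_t_run=max_t_run, n_controls=n_controls,
                  families=[sorted(f) for f in declared_families])
    config.update(config_extra or {})
    return GuideLibrary(selected, controls, config, summaries)


def build_library(
    selections: Sequence[GuideCandidate],
    controls: Sequence[NontargetingControl] = (),
    config: dict | None = None,
) -> GuideLibrary:
    """Aggregate already-selected guides and controls into a library with
    per-target summaries. Validates id uniqueness and the cross-gene
    spacer-uniqueness rule (duplicates allowed only when both guides
    declare each other via offtarget_genes, i.e. a shared-promoter group)."""
    owners: dict[str, GuideCandidate] = {}
    for g in selections:
        prev = owners.get(g.spacer19)
        if prev is not None and prev.gene_id != g.gene_id:
            allowed = g.gene_id in prev.offtarget_genes or prev.gene_id in g.offtarget_genes
            if not allowed:
                raise ValueError(
                    f"spacer {g.spacer19} shared by disjoint genes "
                    f"{prev.gene_id} and {g.gene_id}"
                )
        owners.setdefault(g.spacer19, g)
    summaries = []
    by_target: dict[tuple[str, str], list[GuideCandidate]] = {}
    for g in selections:
        by_target.setdefault((g.gene_id, g.tss_id), []).append(g)
    for (gene, tss), gs in sorted(by_target.items()):
        relax = "gc+polyT" if any(RELAX_POLYT in g.relaxations for g in gs) else (
            "gc" if any(RELAX_GC in g.relaxations for g in gs) else "")
        summaries.append(GeneDesignSummary(gene, tss, len(gs), relax))
    return GuideLibrary(list(selections), list(controls), dict(config or {}), summaries)


_LIBRARY_COLUMNS = [
    "guide_id", "gene", "spacer_19nt", "cloned_spacer_20nt", "contig",
    "start", "end", "strand", "tss_id", "distance_to_tss", "rank", "pam",
    "relaxations", "offtarget_genes", "is_control",
]


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Library table TSV; coordinates 1-based inclusive. Deterministic:
    identical libraries serialize byte-identically. For control rows the
    distance_to_tss column records the minimum genomic Hamming distance."""
    with open(path, "w") as fh:
        fh.write("\t".join(_LIBRARY_COLUMNS) + "\n")
        for g in lib.guides:
            fh.write("\t".join([
                g.guide_id, g.gene_id, g.spacer19, finalize_cloned_spacer(g),
                g.contig, str(g.protospacer_start + 1), str(g.protospacer_end),
                g.strand_of_genome, g.tss_id,
                "" if g.distance_to_tss is None else repr(g.distance_to_tss),
                "" if g.rank is None else str(g.rank), g.pam,
                ",".join(sorted(g.relaxations)),
                ",".join(sorted(g.offtarget_genes)), "0",
            ]) + "\n")
        for c in lib.controls:
            fh.write("\t".join([
                c.control_id, CONTROL_GENE, c.spacer19,
                finalize_cloned_spacer(c.spacer19), "", "", "", "", "",
                str(c.min_genome_mismatches), "", "", "", "", "1",
            ]) + "\n")


def read_library(path: str | Path) -> GuideLibrary:
    """Inverse of :func:`write_library`; filter flags are recomputed from
    the spacer sequence (exact for selected guides, which by construction
    carry no blocking flags)."""
    guides, controls = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LIBRARY_COLUMNS:
            raise ValueError(f"{path}: unexpected library header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = dict(zip(_LIBRARY_COLUMNS, f))
            if row["is_control"] == "1":
                controls.append(NontargetingControl(
                    row["guide_id"], row["spacer_19nt"],
                    int(float(row["distance_to_tss"])),
                ))
            else:
                guides.append(GuideCandidate(
                    gene_id=row["gene"], tss_id=row["tss_id"],
                    spacer19=row["spacer_19nt"],
                    strand_of_genome=row["strand"], contig=row["contig"],
                    protospacer_start=int(row["start"]) - 1,
                    protospacer_end=int(row["end"]),
                    pam=row["pam"],
                    gc_fraction=gc_fraction(row["spacer_19nt"]),
                    flags=sequence_filter_flags(row["spacer_19nt"]),
                    distance_to_tss=float(row["distance_to_tss"]) if row["distance_to_tss"] else None,
                    rank=int(row["rank"]) if row["rank"] else None,
                    relaxations=frozenset(x for x in row["relaxations"].split(",") if x),
                    offtarget_genes=frozenset(x for x in row["offtarget_genes"].split(",") if x),
                ))
    return GuideLibrary(guides, controls, design_config={})
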