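"""Generative simulator for FACS-enrichment CRISPRa screens, plus synthetic
reference genomes with planted guide sites for testing the designer by
construction.

The screen model mirrors the wet workflow: a plasmid pool with log-normal
guide representation is transduced at low MOI so each cell carries one
guide; a fixed per-guide fraction of guides are functional (activation
heterogeneity); cells carrying a functional guide against a "hit" gene
(one bound by the selection probe) gain a log-normal surface-staining
boost on top of log-normal background staining; the brightest
`sort_fraction` of cells are collected; and sequencing counts for the
plasmid, presort and sorted pools are drawn Dirichlet-multinomial to model
PCR/sequencing jackpotting. Every sample's column sums to
`reads_per_sample` exactly, and a truth manifest records which guides were
active so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_tss import CagePeak, GenomeSequence
from .guide_design import (
    CONTROL_GENE,
    FLAG_BBSI,
    GuideCandidate,
    GuideLibrary,
    NontargetingControl,
    SPACER_LEN,
    sequence_filter_flags,
)
from .screen_counts import CountTable
from .sequence import BBSI_FWD, random_dna_no_pam, revcomp

PLASMID, PRESORT, SORTED = "plasmid", "presort", "sorted"


@dataclass
class SimulationConfig:
    """Screen-simulation parameters.

    The defaults are the desk-scale profile: 1,000 genes x 5 guides plus
    controls, 2e5 cells and 2e6 reads per sample, with the experimental
    constants (MOI 0.3, top-5% sort gate) and a plasmid log-normal spread
    chosen so roughly 89% of guides fall within a 100-fold abundance
    window. `overdispersion` is the per-guide Dirichlet concentration at
    uniform representation (larger = less PCR jackpotting).
    """

    n_genes: int = 1000
    guides_per_gene: int = 5
    n_controls: int = 500
    hit_genes: tuple = ("G0001", "G0002", "G0003", "G0004", "G0005")
    p_guide_active: float = 0.95
    activation_lognorm: tuple = (2.5, 0.5)  # (mu, sigma) of staining boost
    background_lognorm: tuple = (0.0, 1.0)  # (mu, sigma) of staining noise
    plasmid_lognorm_sigma: float = 1.07
    n_cells: int = 200_000
    moi: float = 0.3
    sort_fraction: float = 0.05
    reads_per_sample: int = 2_000_000
    overdispersion: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sort_fraction < 1:
            raise ValueError("sort_fraction must be in (0, 1)")
        if self.moi <= 0:
            raise ValueError("moi must be positive")
        for name in ("n_genes", "guides_per_gene", "n_cells", "reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_paper_config(profile: str = "desk", seed: int = 0) -> SimulationConfig:
    """Defaults mimicking the published screen conditions.

    "desk" keeps the experimental constants (MOI 0.3, 5% sort gate,
    log-normal plasmid spread) at a size that runs in seconds; "full"
    scales cells and reads to the screen's ~200x-coverage transductions.
    """
    if profile == "desk":
        return SimulationConfig(seed=seed)
    if profile == "full":
        return SimulationConfig(
            n_genes=6213, guides_per_gene=7, n_controls=500,
            n_cells=12_000_000, reads_per_sample=20_000_000, seed=seed,
        )
    raise ValueError(f"unknown profile {profile!r}")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_library_for_simulation(config: SimulationConfig) -> GuideLibrary:
    """Synthetic guide library (random unique spacers, placeholder
    coordinates) matching the configured genes-x-guides layout, for driving
    screen simulations without running the designer."""
    rng = np.random.default_rng([config.seed % (2**31), 7])
    bases = np.array(list("ACGT"))
    seen: set[str] = set()

    def fresh_spacer() -> str:
        while True:
            s = "".join(bases[rng.integers(0, 4, SPACER_LEN)])
            if s not in seen and FLAG_BBSI not in sequence_filter_flags(s):
                seen.add(s)
                return s

    guides = []
    pos = 0
    for gi in range(1, config.n_genes + 1):
        gene = _gene_name(gi)
        for k in range(config.guides_per_gene):
            pos += 100
            guides.append(GuideCandidate(
                gene_id=gene, tss_id=f"{gene}_tss1", spacer19=fresh_spacer(),
                strand_of_genome="+", contig="sim",
                protospacer_start=pos, protospacer_end=pos + SPACER_LEN,
                pam="AGG", gc_fraction=0.5, rank=k + 1,
            ))
    controls = [
        NontargetingControl(f"NTC{i:04d}", fresh_spacer(), 3)
        for i in range(1, config.n_controls + 1)
    ]
    return GuideLibrary(guides, controls, design_config={"simulated": True})


@dataclass
class SimulatedScreen:
    table: CountTable
    truth: dict

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _dirichlet_multinomial(
    rng: np.random.Generator, freqs: np.ndarray, n_reads: int, concentration: float
) -> np.ndarray:
    """Multinomial reads with Dirichlet-perturbed probabilities.

    `concentration` is scaled per guide: alpha_i = c * K * f_i, so at
    uniform representation every alpha is c. Zero-frequency guides stay at
    zero."""
    k = len(freqs)
    alpha = concentration * k * freqs
    gam = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    total = gam.sum()
    if total == 0:
        raise ValueError("all guide frequencies are zero")
    return rng.multinomial(n_reads, gam / total)


def simulate_screen(library: GuideLibrary, config: SimulationConfig) -> SimulatedScreen:
    """Run the generative screen model; see the module docstring.

    Returns counts for the plasmid, presort and sorted samples plus a
    truth manifest (hit genes, per-guide active flags and expected
    enrichment direction).
    """
    guide_ids = [g.guide_id for g in library.guides] + [c.control_id for c in library.controls]
    genes = [g.gene_id for g in library.guides] + [CONTROL_GENE] * len(library.controls)
    if not guide_ids:
        raise ValueError("empty library")
    hit_set = set(config.hit_genes)
    unknown = hit_set - set(genes)
    if unknown:
        raise ValueError(f"hit genes not in library: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed % (2**31))
    n_guides = len(guide_ids)

    # plasmid representation: log-normal, normalized to probabilities
    plasmid_w = rng.lognormal(0.0, config.plasmid_lognorm_sigma, n_guides)
    plasmid_p = plasmid_w / plasmid_w.sum()

    # one guide per transduced cell (low-MOI design); MOI is reported, not
    # used to assign multiple integrations
    cell_counts = rng.multinomial(config.n_cells, plasmid_p)

    active = rng.random(n_guides) < config.p_guide_active
    is_hit_gene = np.array([g in hit_set for g in genes])
    boosted = active & is_hit_gene

    n_sorted = int(config.n_cells * config.sort_fraction)
    if n_sorted < 1:
        raise ValueError("sorted pool would contain no cells")

    # per-cell staining signal
    owner = np.repeat(np.arange(n_guides), cell_counts)
    bg_mu, bg_sigma = config.background_lognorm
    signal = rng.lognormal(bg_mu, bg_sigma, len(owner))
    boosted_cells = boosted[owner]
    act_mu, act_sigma = config.activation_lognorm
    signal[boosted_cells] += rng.lognormal(act_mu, act_sigma, int(boosted_cells.sum()))

    top = np.argpartition(signal, -n_sorted)[-n_sorted:]
    sorted_counts = np.bincount(owner[top], minlength=n_guides)

    reads = {
        PLASMID: _dirichlet_multinomial(rng, plasmid_p, config.reads_per_sample,
                                        config.overdispersion),
        PRESORT: _dirichlet_multinomial(rng, cell_counts / config.n_cells,
                                        config.reads_per_sample, config.overdispersion),
        SORTED: _dirichlet_multinomial(rng, sorted_counts / n_sorted,
                                       config.reads_per_sample, config.overdispersion),
    }
    counts = pd.DataFrame(reads, index=pd.Index(guide_ids, name="sgRNA"),
                          dtype=np.int64)
    table = CountTable(counts, pd.Series(genes, index=guide_ids))

    truth = {
        "hit_genes": sorted(hit_set),
        "active_guides": {gid: bool(a) for gid, a in zip(guide_ids, active)},
        "expected_direction": {
            gid: ("up" if b else "flat") for gid, b in zip(guide_ids, boosted)
        },
        "expected_transduced_fraction": 1.0 - float(np.exp(-config.moi)),
        "expected_multiplicity": config.moi,
        "n_sorted_cells": n_sorted,
    }
    return SimulatedScreen(table, truth)


# ---------------------------------------------------------------------------
# Read simulation (exercises the counting path)
# ---------------------------------------------------------------------------

def simulate_reads(
    table: CountTable,
    library: GuideLibrary,
    sample: str,
    *,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Emit each guide's 19-nt spacer `count` times with per-base
    substitution errors, shuffled; deterministic for a given seed."""
    rng = np.random.default_rng(seed % (2**31))
    spacer_of = {g.guide_id: g.spacer19 for g in library.guides}
    spacer_of.update({c.control_id: c.spacer19 for c in library.controls})
    counts = table.counts[sample]
    n_reads = int(counts.sum())
    mat = np.empty((n_reads, SPACER_LEN), dtype=np.uint8)
    row = 0
    for gid, cnt in counts.items():
        cnt = int(cnt)
        if cnt:
            mat[row : row + cnt] = np.frombuffer(spacer_of[gid].encode(), dtype=np.uint8)
            row += cnt
    if error_rate > 0:
        hit = rng.random(mat.shape) < error_rate
        # substitute with a uniformly random *different* base
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(np.sort(codes), mat[hit])
        shift = rng.integers(1, 4, hit.sum())
        mat[hit] = np.sort(codes)[(idx + shift) % 4]
    rng.shuffle(mat, axis=0)
    return [bytes(r).decode() for r in mat]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Synthetic reference genomes with planted guide sites
# ---------------------------------------------------------------------------

@dataclass
class ReferenceConfig:
    n_genes: int = 12
    valid_per_gene: int = 3
    duplicate_pairs: int = 1  # trailing gene pairs given byte-identical windows
    gene_spacing: int = 1500
    seed: int = 0


@dataclass
class SyntheticReference:
    genome: GenomeSequence
    cage_peaks: list
    family_groups: list
    truth: dict  # gene -> list of {spacer, category, strand}

    def write_bundle(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(out / "genome.fa")
        with open(out / "cage_peaks.bed", "w") as fh:
            for pk in self.cage_peaks:
                fh.write(f"{pk.contig}\t{pk.start}\t{pk.end}\t{pk.gene_id}\t"
                         f"{pk.tag_count:g}\t{pk.strand}\t{pk.summit - 1}\n")
        with open(out / "families.json", "w") as fh:
            json.dump([sorted(g) for g in self.family_groups], fh)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _spacer_with(rng: np.random.Generator, predicate) -> str:
    """Rejection-sample a GG/CC-free 19-mer satisfying `predicate`."""
    for _ in range(10_000):
        s = random_dna_no_pam(rng, SPACER_LEN)
        if predicate(s):
            return s
    raise RuntimeError("spacer rejection sampling exhausted")


def _planted_spacers(rng: np.random.Generator, n_valid: int, used: set) -> list[tuple[str, str]]:
    """(spacer, category) plants for one gene: n_valid clean guides plus
    one GC-failing, one polyT-failing and one BbsI-failing guide, each
    violating exactly its recorded rule."""
    plants = []
    for _ in range(n_valid):
        s = _spacer_with(rng, lambda s: not sequence_filter_flags(s) and s not in used)
        used.add(s)
        plants.append((s, "valid"))
    s = _spacer_with(rng, lambda s: sequence_filter_flags(s) == {"gc_low"} and s not in used)
    used.add(s)
    plants.append((s, "gc_low"))

    def polyt_only(s: str) -> bool:
        return sequence_filter_flags(s) == {"polyT"} and "GG" not in s and "CC" not in s

    def inject_tttt(s: str) -> str:
        pos = 5
        return s[:pos] + "TTTT" + s[pos + 4 :]

    s = _spacer_with(rng, lambda s: polyt_only(inject_tttt(s)) and inject_tttt(s) not in used)
    s = inject_tttt(s)
    used.add(s)
    plants.append((s, "polyT"))

    def bbsi_only(s: str) -> bool:
        return sequence_filter_flags(s) == {"bbsi"} and "GG" not in s and "CC" not in s

    def inject_bbsi(s: str) -> str:
        pos = 7
        return s[:pos] + BBSI_FWD + s[pos + 6 :]

    s = _spacer_with(rng, lambda s: bbsi_only(inject_bbsi(s)) and inject_bbsi(s) not in used)
    s = inject_bbsi(s)
    used.add(s)
    plants.append((s, "bbsi"))
    return plants


def _build_window(rng: np.random.Generator, plants: list[tuple[str, str]],
                  strand: str, length: int = 401) -> tuple[str, list[dict]]:
    """PAM-free 401-nt window with the plants spliced in at spaced offsets.

    Plus-strand plants are written as spacer + TGG; minus-strand plants as
    CCA + revcomp(spacer). A sentinel 'A' on each side of every plant keeps
    splice junctions from creating accidental GG/CC PAMs."""
    seq = list(random_dna_no_pam(rng, length))
    site_len = SPACER_LEN + 3
    slots = np.arange(5, length - site_len - 5, site_len + 4)
    offsets = sorted(rng.choice(slots, size=len(plants), replace=False))
    records = []
    for (spacer, category), off in zip(plants, offsets):
        segment = spacer + "TGG" if strand == "+" else "CCA" + revcomp(spacer)
        seq[off : off + site_len] = segment
        if off > 0:
            seq[off - 1] = "A"
        if off + site_len < length:
            seq[off + site_len] = "A"
        records.append({"spacer": spacer, "category": category,
                        "strand": strand, "window_offset": int(off)})
    return "".join(seq), records


def make_synthetic_reference(config: ReferenceConfig, seed: int | None = None) -> SyntheticReference:
    """Random genome with one promoter window per gene and planted guides
    of known validity; the trailing `duplicate_pairs` gene pairs share
    byte-identical windows and are declared as families."""
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    if 2 * config.duplicate_pairs > config.n_genes:
        raise ValueError("too many duplicate pairs for the gene count")
    rng = np.random.default_rng((seed if seed is not None else config.seed) % (2**31))
    length = config.n_genes * config.gene_spacing + 1000
    contig = list(random_dna_no_pam(rng, length))

    used: set = set()
    cage, truth, families = [], {}, []
    window_cache: dict[int, tuple[str, list[dict]]] = {}
    dup_partner = {}
    first_dup = config.n_genes - 2 * config.duplicate_pairs
    for p in range(config.duplicate_pairs):
        a, b = first_dup + 2 * p, first_dup + 2 * p + 1
        dup_partner[b] = a
        families.append({_gene_name(a + 1), _gene_name(b + 1)})

    for gi in range(config.n_genes):
        gene = _gene_name(gi + 1)
        strand = "+" if gi % 2 == 0 else "-"
        tss = gi * config.gene_spacing + 600  # 1-based
        if strand == "+":
            w0, w1 = tss - 451, tss - 50
        else:
            w0, w1 = tss + 49, tss + 450
        if gi in dup_partner:
            src = dup_partner[gi]
            window_seq, records = window_cache[src]
            # identical promoter content; strand label follows the source
            strand = "+" if src % 2 == 0 else "-"
            records = [dict(r) for r in records]
        else:
            plants = _planted_spacers(rng, config.valid_per_gene, used)
            window_seq, records = _build_window(rng, plants, strand)
            window_cache[gi] = (window_seq, records)
        contig[w0:w1] = window_seq
        if w0 > 0:
            contig[w0 - 1] = "A"
        if w1 < length:
            contig[w1] = "A"
        # re-anchor the TSS so the extracted window matches what we wrote
        tss_anchor = w1 + 50 if strand == "+" else w0 - 49
        cage.append(CagePeak(
            gene_id=gene, contig="chr1", strand=strand,
            start=tss_anchor - 11, end=tss_anchor + 9, summit=tss_anchor,
            tag_count=100.0, peak_id=f"{gene}_peak",
        ))
        truth[gene] = records

    genome = GenomeSequence({"chr1": "".join(contig)})
    return SyntheticReference(genome, cage, [frozenset(f) for f in families], truth)
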